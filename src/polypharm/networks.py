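"""Cross-submission similarity analyses.

Three questions are answered here, all on molecular-fingerprint Tanimoto
similarity:

* how many *distinct* structures were submitted as top-ranked picks
  (teams may converge on the same molecule written as different SMILES);
* which compounds form structurally similar subclusters, via a thresholded
  similarity network (edges with Tc below the cutoff are dropped, connected
  components are the subclusters);
* which compounds from one prediction set have a close analog in another
  set (cross-team similar pairs, strict inequality).

Edge-threshold conventions follow the analyses they implement: network
edges are kept when Tc >= threshold (values *below* the cutoff filtered
out), while cross-set pairs use strict Tc > threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .chem import Molecule, canonical_key, similarity_matrix
from .io import SubmissionSet

__all__ = [
    "dedup_top_ranked",
    "build_network",
    "components",
    "cross_set_pairs",
    "cross_team_pairs",
    "render_heatmap",
    "render_network",
]


def dedup_top_ranked(
    submissions: SubmissionSet,
) -> tuple[list[tuple[str, str, str]], int]:
    """Distinct top-ranked structures across teams.

    Returns ``(unique, count)`` where ``unique`` lists one
    ``(canonical_key, compound name, team)`` per distinct structure (first
    submitting team in file order wins) and ``count`` is the number of
    distinct rank-1 structures.
    """
    seen: dict[str, tuple[str, str, str]] = {}
    for team in submissions:
        entry = team.top_ranked
        key = canonical_key(entry.smiles)
        if key not in seen:
            seen[key] = (key, entry.name, team.team)
    unique = list(seen.values())
    return unique, len(unique)


def build_network(
    matrix: np.ndarray,
    threshold: float = 0.4,
    labels: Sequence[str] | None = None,
    teams: Sequence[str] | None = None,
    inclusive: bool = True,
) -> nx.Graph:
    """Thresholded similarity network from a square Tanimoto matrix.

    Edge (i, j), i != j, is kept when Tc >= threshold (``inclusive=True``,
    the "filter out below the cutoff" convention) or Tc > threshold
    otherwise.  Node attributes carry labels/team attribution; each node
    gets a deterministic ``component`` label (see :func:`components`).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-9):
        raise ValueError("similarity matrix must be symmetric")
    n = matrix.shape[0]
    if labels is None:
        labels = [str(i) for i in range(n)]
    if len(labels) != n:
        raise ValueError("labels length must match matrix size")
    g = nx.Graph(threshold=threshold, inclusive=inclusive)
    for i, lab in enumerate(labels):
        attrs = {"index": i}
        if teams is not None:
            attrs["team"] = teams[i]
        g.add_node(lab, **attrs)
    for i in range(n):
        for j in range(i + 1, n):
            tc = matrix[i, j]
            keep = tc >= threshold if inclusive else tc > threshold
            if keep:
                g.add_edge(labels[i], labels[j], weight=float(tc))
    for node, comp in components(g).items():
        g.nodes[node]["component"] = comp
    return g


def components(net: nx.Graph) -> dict[str, int]:
    """Connected-component labels, a true partition of the nodes.

    Components are numbered by their smallest member's insertion index so
    labeling is deterministic for a given node order.
    """
    order = {node: i for i, node in enumerate(net.nodes)}
    comps = sorted(
        (sorted(c, key=order.__getitem__) for c in nx.connected_components(net)),
        key=lambda members: order[members[0]],
    )
    labels: dict[str, int] = {}
    for comp_id, members in enumerate(comps):
        for node in members:
            labels[node] = comp_id
    return labels


def cross_set_pairs(
    set_a: Sequence[Molecule | str],
    set_b: Sequence[Molecule | str],
    threshold: float = 0.5,
    dialect: str = "path1024",
    labels_a: Sequence[str] | None = None,
    labels_b: Sequence[str] | None = None,
) -> list[tuple[str, str, float]]:
    """All pairs (a from set_a, b from set_b) with Tc strictly > threshold."""
    matrix = similarity_matrix(set_a, set_b, dialect=dialect)
    if labels_a is None:
        labels_a = [str(i) for i in range(len(set_a))]
    if labels_b is None:
        labels_b = [str(j) for j in range(len(set_b))]
    out = []
    for i in range(matrix.shape[0]):
        for j in range(matrix.shape[1]):
            if matrix[i, j] > threshold:
                out.append((labels_a[i], labels_b[j], float(matrix[i, j])))
    return out


def cross_team_pairs(
    submissions: SubmissionSet,
    threshold: float = 0.5,
    dialect: str = "path1024",
    include_within_team: bool = False,
) -> list[tuple[str, str, float]]:
    """Similar compound pairs submitted by *different* teams.

    Self-pairs and (by default) within-team pairs are excluded — the
    question asked is whether another team submitted a similar molecule.
    Strict Tc > threshold.
    """
    mols, names, teams = [], [], []
    for team in submissions:
        for entry in team.entries:
            mols.append(entry.smiles)
            names.append(f"{team.team}:{entry.name}")
            teams.append(team.team)
    matrix = similarity_matrix(mols, dialect=dialect)
    out = []
    for i in range(len(mols)):
        for j in range(i + 1, len(mols)):
            if teams[i] == teams[j] and not include_within_team:
                continue
            if matrix[i, j] > threshold:
                out.append((names[i], names[j], float(matrix[i, j])))
    return out


def render_heatmap(matrix: np.ndarray, labels: Sequence[str], path) -> None:
    """Write a similarity-matrix heatmap PNG (rows/columns in label order)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, len(labels) * 0.25),) * 2)
    im = ax.imshow(np.asarray(matrix), vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=5)
    ax.set_yticks(range(len(labels)), labels, fontsize=5)
    fig.colorbar(im, ax=ax, label="Tanimoto similarity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_network(net: nx.Graph, path) -> None:
    """Write a network PNG with a deterministic layout, colored by component."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos = nx.spring_layout(net, seed=0)
    comp = [net.nodes[n].get("component", 0) for n in net.nodes]
    fig, ax = plt.subplots(figsize=(6, 6))
    widths = [2 * d.get("weight", 0.5) for _, _, d in net.edges(data=True)]
    nx.draw_networkx(net, pos=pos, ax=ax, node_color=comp, cmap="tab10",
                     width=widths, font_size=5, node_size=120)
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
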