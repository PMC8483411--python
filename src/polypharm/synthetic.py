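"""Deterministic generator of complete synthetic challenge instances.

Emulates every data shape the evaluation pipeline consumes, with no
external downloads:

* **molecule libraries** built by decorating six distinct ring-system
  scaffolds with substituent pairs.  The scaffold cores are large relative
  to the substituents, so path-1024 Tanimoto similarity is high within a
  scaffold family (>= 0.46 pairwise) and low across families (<= 0.40),
  which is what thresholded similarity-network analyses need;
* **Kd panels** with planted binder/non-binder profiles and 30 µM
  censoring (``>30000 nM`` = above the assay detection limit);
* **team submission YAML files** (top-5 ranked compounds with vendor
  fields), optionally planting a duplicate top-ranked structure written as
  two different SMILES forms;
* **reference-active sets** drawn from one scaffold family, so same-family
  candidates fail the novelty criterion (max ECFP6 Tc >= 0.4) and
  other-family candidates pass;
* **pIC50 activity records** centered near pIC50 5, emulating the skew of
  public kinase bioactivity data.

Randomness uses named per-artifact streams derived from one seed, so
generating one extra artifact never shifts the others, and a fixed config
yields byte-identical files.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import canonical_key, parse_smiles
from .io import (
    SubmissionEntry,
    SubmissionSet,
    TeamSubmission,
    write_kd_table,
    write_molecules_smi,
    write_submission,
)
from .rubric import KdPanel, TargetRubric

__all__ = [
    "SCAFFOLDS",
    "SUBSTITUENTS",
    "GeneratorConfig",
    "PlantedProfile",
    "generate_library",
    "generate_kd_panel",
    "generate_submissions",
    "generate_reference_actives",
    "generate_activities",
    "generate_instance",
    "alternate_smiles",
]

#: scaffold family name -> SMILES template with two substituent slots
SCAFFOLDS: dict[str, str] = {
    "quinazolinamine": "c1ccc2c(c1)nc({0})nc2N{1}",
    "piperidine_amide": "O=C(N1CCC(C{0})CC1)C1CCC({1})CC1",
    "sulfonyl_piperazine": "O=S(=O)(N1CCN({0})CC1)c1ccc({1})cc1",
    "chromone": "O=c1cc({0})oc2cc({1})ccc12",
    "thiophene_urea": "O=C(Nc1ccc({0})s1)NC1CCC({1})CC1",
    "naphthamide": "O=C(NC{0})c1ccc2cc(OC{1})ccc2c1",
}

SUBSTITUENTS = (
    "C", "CC", "CCC", "C(C)C", "OC", "OCC", "N(C)C", "CCO", "CCN", "Cl", "F", "CC(C)C",
)

#: scaffold family with pairwise ECFP6 Tc >= 0.4, used for reference actives
REFERENCE_FAMILY = "naphthamide"

# stream indices: adding an artifact appends a new index, never renumbers
_STREAMS = {"library": 0, "panel": 1, "submissions": 2, "reference": 3, "activities": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass(frozen=True)
class PlantedProfile:
    """Binding profile planted for one compound in the Kd panel.

    ``pro_bound``: pro-targets given a measurable Kd at or below the
    10 µM binding threshold ("all" for every pro-target).
    ``anti_bound``: anti-targets given a measurable Kd (neither bound as a
    pro-hit nor avoided); everything else is censored at the detection
    bound, i.e. avoided.
    """

    pro_bound: tuple[str, ...] | str = ()
    anti_bound: tuple[str, ...] = ()


#: convenience roles mirroring the profiles the assay narratives describe
ROLE_PROFILES: dict[str, PlantedProfile] = {
    # binds every pro-target, censored on every anti-target
    "ideal": PlantedProfile(pro_bound="all"),
    # binds a single pro-target, avoids all anti-targets
    "near_miss": PlantedProfile(pro_bound="first"),
    # no measurable binding anywhere
    "inactive": PlantedProfile(),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic instance, under one seed."""

    seed: int = 0
    library_size: int = 60
    n_scaffolds: int = 6
    n_teams: int = 10
    compounds_per_team: int = 5
    problem: str = "1"
    censor_bound_nM: float = 30000.0
    #: log10-scale sigma of multiplicative log-normal Kd noise
    kd_log_sigma: float = 0.2
    #: sampling range for planted pro-target Kds (nM), inside the 10 µM call
    bind_kd_range: tuple[float, float] = (100.0, 8000.0)
    #: fraction of background panel cells that are censored
    background_censor_fraction: float = 1.0
    #: compound id -> role name or PlantedProfile
    planted_profiles: Mapping[str, str | PlantedProfile] = field(default_factory=dict)
    #: pair of team indices sharing a rank-1 structure (None = no duplicate)
    planted_duplicate: tuple[int, int] | None = None
    reference_family: str = REFERENCE_FAMILY
    reference_size: int = 20
    n_activities: int = 300
    pic50_center: float = 5.0
    pic50_sigma: float = 0.8


def _compound_id(index: int) -> str:
    return f"SYN{index:04d}"


def generate_library(config: GeneratorConfig) -> list[tuple[str, str]]:
    """Deterministic, duplicate-free (id, SMILES) library.

    Compounds are drawn round-robin across the first ``n_scaffolds``
    scaffold families; within a family, substituent pairs are sampled
    without replacement.
    """
    if not 1 <= config.n_scaffolds <= len(SCAFFOLDS):
        raise ValueError(f"n_scaffolds must be in [1, {len(SCAFFOLDS)}]")
    families = list(SCAFFOLDS)[: config.n_scaffolds]
    capacity = config.n_scaffolds * len(SUBSTITUENTS) ** 2
    if config.library_size > capacity:
        raise ValueError(
            f"library_size {config.library_size} exceeds enumerable space {capacity}"
        )
    rng = _rng(config.seed, "library")
    combos = list(itertools.product(SUBSTITUENTS, SUBSTITUENTS))
    per_family = {
        fam: [combos[i] for i in rng.permutation(len(combos))] for fam in families
    }
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    cursor = {fam: 0 for fam in families}
    i = 0
    stalled = 0
    while len(out) < config.library_size:
        if stalled >= len(families):
            raise ValueError(
                "scaffold/substituent space exhausted before reaching library_size "
                "(canonical duplicates reduced the enumerable space)"
            )
        fam = families[i % len(families)]
        i += 1
        size_before = len(out)
        while cursor[fam] < len(per_family[fam]):
            a, b = per_family[fam][cursor[fam]]
            cursor[fam] += 1
            smiles = SCAFFOLDS[fam].format(a, b)
            key = canonical_key(parse_smiles(smiles))
            if key not in seen:
                seen.add(key)
                out.append((_compound_id(len(out)), smiles))
                break
        stalled = stalled + 1 if len(out) == size_before else 0
    return out


def library_families(config: GeneratorConfig) -> dict[str, str]:
    """Compound id -> scaffold family for a generated library (by construction)."""
    families = list(SCAFFOLDS)[: config.n_scaffolds]
    lib = generate_library(config)
    return {cid: families[i % len(families)] for i, (cid, _) in enumerate(lib)}


def _sample_kd(rng: np.random.Generator, lo: float, hi: float, sigma: float,
               ceiling: float) -> float:
    """Log-uniform base value with log-normal noise, resampled to stay <= ceiling."""
    for _ in range(100):
        base = 10 ** rng.uniform(np.log10(lo), np.log10(hi))
        noisy = base * 10 ** rng.normal(0.0, sigma)
        if 0 < noisy <= ceiling:
            return float(noisy)
    return float(min(hi, ceiling))  # pragma: no cover - noise never this extreme


def generate_kd_panel(
    library: Sequence[tuple[str, str]],
    rubric: TargetRubric,
    config: GeneratorConfig,
) -> KdPanel:
    """Kd panel with planted binding profiles and 30 µM censoring.

    Compounds named in ``config.planted_profiles`` get their role's
    profile; all other compounds are background: each cell censored with
    probability ``background_censor_fraction``, otherwise given a neutral
    Kd in (10 µM, 30 µM] that creates neither a pro-hit nor an
    anti-avoidance.  Noise never moves a planted value across its role's
    threshold (resampled if it would).
    """
    rng = _rng(config.seed, "panel")
    ids = [cid for cid, _ in library]
    targets = list(rubric.all_targets)
    pro = set(rubric.pro_targets)
    unknown = [c for c in config.planted_profiles if c not in set(ids)]
    if unknown:
        raise KeyError(f"planted profiles reference unknown compounds: {unknown}")
    bound = config.censor_bound_nM
    kd = pd.DataFrame(bound, index=ids, columns=targets, dtype=float)
    cens = pd.DataFrame(True, index=ids, columns=targets)
    lo, hi = config.bind_kd_range

    for cid in ids:
        profile = config.planted_profiles.get(cid)
        if profile is None:
            # background compound
            for t in targets:
                if rng.random() >= config.background_censor_fraction:
                    kd.at[cid, t] = float(rng.uniform(rubric.pro_bind_nM + 1, bound))
                    cens.at[cid, t] = False
            continue
        if isinstance(profile, str):
            if profile not in ROLE_PROFILES:
                raise KeyError(f"unknown planted role {profile!r} for {cid}")
            profile = ROLE_PROFILES[profile]
        if profile.pro_bound == "all":
            pro_bound = tuple(rubric.pro_targets)
        elif profile.pro_bound == "first":
            pro_bound = rubric.pro_targets[:1]
        else:
            pro_bound = tuple(profile.pro_bound)
        bad = [t for t in tuple(pro_bound) + tuple(profile.anti_bound) if t not in targets]
        if bad:
            raise KeyError(f"profile for {cid} references unknown targets: {bad}")
        for t in pro_bound:
            kd.at[cid, t] = _sample_kd(rng, lo, hi, config.kd_log_sigma, rubric.pro_bind_nM)
            cens.at[cid, t] = False
        for t in profile.anti_bound:
            # measurable but not a pro-level hit: neither bound-as-pro nor avoided
            kd.at[cid, t] = float(rng.uniform(rubric.pro_bind_nM + 1, bound))
            cens.at[cid, t] = False
    return KdPanel(kd, cens)


def alternate_smiles(smiles: str) -> str:
    """A chemically identical but textually different SMILES form.

    Prefers the kekulized writing; falls back to re-rooted canonical forms.
    """
    from rdkit import Chem

    mol = parse_smiles(smiles).rdmol
    kek = Chem.MolToSmiles(mol, kekuleSmiles=True)
    if kek != smiles:
        return kek
    for root in range(mol.GetNumAtoms()):
        alt = Chem.MolToSmiles(mol, rootedAtAtom=root, canonical=False)
        if alt != smiles:
            return alt
    return smiles  # pragma: no cover - single-atom molecules only


def generate_submissions(
    library: Sequence[tuple[str, str]], config: GeneratorConfig
) -> SubmissionSet:
    """Per-team ranked top-5 submissions drawn from the library.

    With ``planted_duplicate=(i, j)`` teams i and j share the same rank-1
    structure, written as two distinct SMILES strings; all other picks are
    sampled without replacement so they are structurally distinct.
    """
    rng = _rng(config.seed, "submissions")
    need = config.n_teams * config.compounds_per_team
    if need > len(library):
        raise ValueError(
            f"{config.n_teams} teams x {config.compounds_per_team} compounds "
            f"need {need} library entries, have {len(library)}"
        )
    dup = config.planted_duplicate
    if dup is not None:
        i, j = dup
        if not (0 <= i < config.n_teams and 0 <= j < config.n_teams and i != j):
            raise ValueError(f"planted_duplicate {dup} inconsistent with {config.n_teams} teams")
    order = rng.permutation(len(library))
    pool = [library[k] for k in order]
    teams = []
    cursor = 0
    dup_compound = None
    for t in range(config.n_teams):
        entries = []
        for rank in range(1, config.compounds_per_team + 1):
            if dup is not None and rank == 1 and t == dup[1] and dup_compound is not None:
                cid, smiles = dup_compound
                smiles = alternate_smiles(smiles)
            else:
                cid, smiles = pool[cursor]
                cursor += 1
                if dup is not None and rank == 1 and t == dup[0]:
                    dup_compound = (cid, smiles)
            entries.append(
                SubmissionEntry(
                    rank=rank,
                    name=cid,
                    smiles=smiles,
                    vendor_name=f"SynthVendor-{int(rng.integers(1, 6))}",
                    vendor_id=f"SV-{int(rng.integers(10000, 99999))}",
                    rationale=f"predicted multi-target profile for problem {config.problem}",
                )
            )
        teams.append(
            TeamSubmission(team=f"team_{t:02d}", problem=config.problem, entries=tuple(entries))
        )
    return SubmissionSet(problem=config.problem, teams=teams)


def generate_reference_actives(
    config: GeneratorConfig,
) -> list[tuple[str, str]]:
    """Reference-active (id, SMILES) set from a single scaffold family.

    Drawn from the family with the tightest within-family ECFP6 similarity
    (pairwise Tc >= 0.4), so any same-family candidate fails the novelty
    criterion and any other-family candidate passes it.
    """
    rng = _rng(config.seed, "reference")
    template = SCAFFOLDS[config.reference_family]
    combos = list(itertools.product(SUBSTITUENTS, SUBSTITUENTS))
    if config.reference_size > len(combos):
        raise ValueError("reference_size exceeds enumerable space")
    picks = rng.choice(len(combos), size=config.reference_size, replace=False)
    out = []
    for n, k in enumerate(sorted(int(x) for x in picks)):
        a, b = combos[k]
        out.append((f"REF{n:03d}", template.format(a, b)))
    return out


def generate_activities(
    library: Sequence[tuple[str, str]],
    targets: Sequence[str],
    config: GeneratorConfig,
) -> pd.DataFrame:
    """Synthetic pIC50 records: normal around ``pic50_center`` (default 5).

    Mirrors the centering of public kinase bioactivity data, under which
    inactive + weak records dominate potent ones.
    """
    rng = _rng(config.seed, "activities")
    rows = []
    ids = [cid for cid, _ in library]
    for _ in range(config.n_activities):
        rows.append(
            {
                "compound": ids[int(rng.integers(len(ids)))],
                "target": targets[int(rng.integers(len(targets)))],
                "pic50": float(rng.normal(config.pic50_center, config.pic50_sigma)),
            }
        )
    return pd.DataFrame(rows, columns=["compound", "target", "pic50"])


def generate_instance(config: GeneratorConfig, rubric: TargetRubric, out_dir) -> dict:
    """Write a full synthetic challenge instance to ``out_dir``.

    Files: ``library.smi``, ``kd_panel.csv`` (with ``>30000`` censor
    tokens), ``submissions/team_XX.yaml``, ``reference_actives.smi``,
    ``patent_hits.csv``, ``activities.csv``.  Returns the paths.  Output is
    byte-identical for equal configs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    library = generate_library(config)
    write_molecules_smi(out_dir / "library.smi", library)

    panel = generate_kd_panel(library, rubric, config)
    write_kd_table(out_dir / "kd_panel.csv", panel)

    submissions = generate_submissions(library, config)
    sub_dir = out_dir / "submissions"
    sub_dir.mkdir(exist_ok=True)
    sub_paths = []
    for team in submissions:
        path = sub_dir / f"{team.team}.yaml"
        write_submission(path, team)
        sub_paths.append(path)

    reference = generate_reference_actives(config)
    write_molecules_smi(out_dir / "reference_actives.smi", reference)

    patents = pd.DataFrame(
        {
            "compound": [cid for cid, _ in library],
            "patent_hits": [0] * len(library),
        }
    )
    patents.to_csv(out_dir / "patent_hits.csv", index=False)

    activities = generate_activities(library, list(rubric.all_targets), config)
    activities.to_csv(out_dir / "activities.csv", index=False)

    return {
        "library": out_dir / "library.smi",
        "kd_panel": out_dir / "kd_panel.csv",
        "submissions": sub_paths,
        "reference_actives": out_dir / "reference_actives.smi",
        "patent_hits": out_dir / "patent_hits.csv",
        "activities": out_dir / "activities.csv",
    }
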