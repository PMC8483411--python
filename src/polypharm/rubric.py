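"""Rubric-based polypharmacology scoring of kinase Kd panels.

The scoring engine turns a compound × kinase dissociation-constant panel
into challenge points:

* a **pro-target** is "bound" when Kd <= 10 µM (10 000 nM, not censored);
* an **anti-target** is "avoided" when there is no measurable hit at 30 µM,
  i.e. the value is censored (above the assay detection limit) or
  Kd > 30 000 nM.  Values in (10 000, 30 000] nM are neither a pro-hit nor
  an anti-avoidance.
* each rubric criterion maps its bound/avoided count through a point
  schedule (e.g. 1, 3 or 9 points for binding 1, 2 or 3 targets);
* bonus criteria reward novelty (max ECFP6 Tanimoto vs. reference actives
  < 0.4), patentability (< 2 prior hits), drug-likeness (>= 3 of the 4
  Lipinski rule-of-5 criteria) and — where the rubric includes it — CNS
  penetration (TPSA < 75 Å²);
* a team's final score is problem 1 + problem 2 + a 1-point interactome
  participation bonus.

Anti-target avoidance measures *selectivity*, so avoidance criteria award
points only when the compound binds at least one pro-target: an inert
compound that binds nothing "avoids" every anti-target trivially and earns
no target-based points at all — its score is bonus-only (this is how
non-binding submissions end up with exactly the 7 bonus points).  The
gating can be disabled via ``require_pro_hit_for_avoid=False``.

Starred targets ("binding or avoiding that target was a requirement")
support two documented semantics via ``star_mode``:

``per_criterion`` (default)
    A criterion containing a failed starred requirement awards 0 points;
    other criteria are unaffected.
``gate_all``
    Any failed starred requirement zeroes *all* target-based points of the
    problem (bonus points are kept).

Score cards always carry the full per-criterion breakdown, including which
starred requirements failed, so either reading can be audited.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .chem import DescriptorSet, Fingerprint, tanimoto

logger = logging.getLogger(__name__)

__all__ = [
    "KdPanel",
    "Criterion",
    "TargetRubric",
    "BindingCall",
    "AuxEvidence",
    "CriterionScore",
    "BonusScore",
    "ScoreCard",
    "load_rubric",
    "builtin_rubric",
    "call_binding",
    "evaluate_bonus",
    "score_problem",
    "aggregate_final",
    "lipinski_criteria",
    "STAR_MODES",
]

STAR_MODES = ("per_criterion", "gate_all")

DEFAULT_CENSOR_BOUND_NM = 30000.0


class KdPanel:
    """Compound × kinase Kd matrix (nM) with above-detection censoring flags.

    Censored entries carry the censoring bound (default 30 000 nM, the
    assay's top concentration of 30 µM).
    """

    def __init__(self, kd_nM: pd.DataFrame, censored: pd.DataFrame):
        if not kd_nM.index.equals(censored.index) or not kd_nM.columns.equals(
            censored.columns
        ):
            raise ValueError("kd_nM and censored must share index and columns")
        uncensored = kd_nM.to_numpy()[~censored.to_numpy()]
        if np.any(uncensored <= 0) or np.any(~np.isfinite(uncensored)):
            raise ValueError("uncensored Kd values must be positive and finite")
        if kd_nM.index.duplicated().any():
            raise ValueError("duplicate compound rows in Kd panel")
        self.kd_nM = kd_nM.astype(float)
        self.censored = censored.astype(bool)

    @property
    def compounds(self) -> list[str]:
        return list(self.kd_nM.index)

    @property
    def targets(self) -> list[str]:
        return list(self.kd_nM.columns)

    def entry(self, compound: str, target: str) -> tuple[float, bool]:
        """(kd in nM, censored flag) for one cell; KeyError if absent."""
        return (
            float(self.kd_nM.at[compound, target]),
            bool(self.censored.at[compound, target]),
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"KdPanel({len(self.compounds)} compounds x {len(self.targets)} kinases)"


@dataclass(frozen=True)
class Criterion:
    """One rubric line: a target set with a bound/avoided-count point schedule."""

    name: str
    targets: tuple[str, ...]
    schedule: dict[int, int]
    starred: frozenset[str] = frozenset()

    def __post_init__(self):
        pts = [self.schedule.get(k, 0) for k in sorted(self.schedule)]
        if any(b < a for a, b in zip(pts, pts[1:])):
            raise ValueError(f"criterion {self.name!r}: schedule must be non-decreasing")
        if not self.starred <= set(self.targets):
            raise ValueError(f"criterion {self.name!r}: starred targets not in target set")

    def points_for(self, count: int) -> int:
        return self.schedule.get(count, 0) if count > 0 else 0

    @property
    def max_points(self) -> int:
        return max(self.schedule.values(), default=0)


@dataclass(frozen=True)
class TargetRubric:
    """Pro-/anti-target criteria with point schedules plus bonus point values."""

    problem: str
    bind_criteria: tuple[Criterion, ...]
    avoid_criteria: tuple[Criterion, ...]
    bonus: dict[str, int]
    pro_bind_nM: float = 10000.0
    anti_avoid_nM: float = DEFAULT_CENSOR_BOUND_NM

    def __post_init__(self):
        if self.pro_bind_nM <= 0 or self.anti_avoid_nM <= 0:
            raise ValueError("thresholds must be positive")
        if self.pro_bind_nM > self.anti_avoid_nM:
            raise ValueError("pro_bind_nM must not exceed anti_avoid_nM")

    @property
    def pro_targets(self) -> tuple[str, ...]:
        return tuple(t for c in self.bind_criteria for t in c.targets)

    @property
    def anti_targets(self) -> tuple[str, ...]:
        return tuple(t for c in self.avoid_criteria for t in c.targets)

    @property
    def all_targets(self) -> tuple[str, ...]:
        return self.pro_targets + self.anti_targets

    @property
    def max_target_points(self) -> int:
        return sum(c.max_points for c in self.bind_criteria + self.avoid_criteria)

    @property
    def max_bonus_points(self) -> int:
        return sum(self.bonus.values())


def _parse_criteria(raw: Iterable[Mapping]) -> tuple[Criterion, ...]:
    out = []
    for item in raw:
        out.append(
            Criterion(
                name=str(item.get("name", ",".join(item["targets"]))),
                targets=tuple(item["targets"]),
                schedule={int(k): int(v) for k, v in item["schedule"].items()},
                starred=frozenset(item.get("starred", []) or []),
            )
        )
    return tuple(out)


def load_rubric(source) -> TargetRubric:
    """Load a rubric from a YAML path, file object, or parsed mapping."""
    if isinstance(source, Mapping):
        raw = source
    elif hasattr(source, "read"):
        raw = yaml.safe_load(source.read())
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    thresholds = raw.get("thresholds", {})
    return TargetRubric(
        problem=str(raw["problem"]),
        bind_criteria=_parse_criteria(raw["bind_criteria"]),
        avoid_criteria=_parse_criteria(raw["avoid_criteria"]),
        bonus={str(k): int(v) for k, v in raw.get("bonus", {}).items()},
        pro_bind_nM=float(thresholds.get("pro_bind_nM", 10000)),
        anti_avoid_nM=float(thresholds.get("anti_avoid_nM", 30000)),
    )


def builtin_rubric(problem: str) -> TargetRubric:
    """Bundled challenge rubric for problem '1' or '2'."""
    name = f"problem{problem}.yaml"
    ref = resources.files("polypharm.data").joinpath(name)
    with ref.open() as fh:
        return load_rubric(fh)


@dataclass(frozen=True)
class BindingCall:
    """Binding classification of one compound–kinase measurement."""

    target: str
    kd_nM: float
    censored: bool
    binds_as_pro: bool
    avoids_as_anti: bool


def call_binding(
    kd_nM: float,
    censored: bool,
    pro_bind_nM: float = 10000.0,
    anti_avoid_nM: float = DEFAULT_CENSOR_BOUND_NM,
    target: str = "",
) -> BindingCall:
    """Classify one measurement against the 10 µM / 30 µM thresholds.

    Bound as pro-target iff not censored and Kd <= ``pro_bind_nM``;
    avoided as anti-target iff censored or Kd > ``anti_avoid_nM``.
    """
    if not censored and (not math.isfinite(kd_nM) or kd_nM <= 0):
        raise ValueError(f"Kd must be positive and finite, got {kd_nM}")
    binds = (not censored) and kd_nM <= pro_bind_nM
    avoids = censored or kd_nM > anti_avoid_nM
    return BindingCall(
        target=target, kd_nM=float(kd_nM), censored=bool(censored),
        binds_as_pro=binds, avoids_as_anti=avoids,
    )


@dataclass
class AuxEvidence:
    """Non-assay evidence feeding the bonus criteria.

    ``novelty_reference`` holds ECFP6 fingerprints of known actives against
    the problem's targets; ``patent_hits`` is a prior-art hit count supplied
    as an input column (the original live database query is out of scope).
    """

    novelty_reference: Sequence[Fingerprint] = ()
    patent_hits: int = 0
    interactome: bool = False

    def __post_init__(self):
        if self.patent_hits < 0:
            raise ValueError("patent_hits must be >= 0")


@dataclass(frozen=True)
class CriterionScore:
    name: str
    kind: str  # "bind" or "avoid"
    satisfied_targets: tuple[str, ...]
    failed_stars: tuple[str, ...]
    points: int


@dataclass(frozen=True)
class BonusScore:
    name: str
    passed: bool
    points: int
    detail: str = ""


@dataclass(frozen=True)
class ScoreCard:
    """Per-criterion point breakdown for one compound on one problem."""

    compound: str
    problem: str
    criteria: tuple[CriterionScore, ...]
    bonuses: tuple[BonusScore, ...]
    star_mode: str
    gated: bool = False  # gate_all tripped: target points zeroed
    pro_hit: bool = True  # bound at least one pro-target (avoid points require it)

    @property
    def target_points(self) -> int:
        return sum(c.points for c in self.criteria)

    @property
    def bonus_points(self) -> int:
        return sum(b.points for b in self.bonuses)

    @property
    def problem_total(self) -> int:
        return self.target_points + self.bonus_points

    def to_dict(self) -> dict:
        return {
            "compound": self.compound,
            "problem": self.problem,
            "star_mode": self.star_mode,
            "gated": self.gated,
            "pro_hit": self.pro_hit,
            "criteria": [
                {
                    "name": c.name,
                    "kind": c.kind,
                    "satisfied_targets": list(c.satisfied_targets),
                    "failed_stars": list(c.failed_stars),
                    "points": c.points,
                }
                for c in self.criteria
            ],
            "bonuses": [
                {"name": b.name, "passed": b.passed, "points": b.points, "detail": b.detail}
                for b in self.bonuses
            ],
            "target_points": self.target_points,
            "bonus_points": self.bonus_points,
            "problem_total": self.problem_total,
        }


def lipinski_criteria(d: DescriptorSet) -> dict[str, bool]:
    """The four rule-of-5 criteria; drug-likeness = at least 3 of 4 pass."""
    return {
        "mw<=500": d.mw <= 500,
        "clogp<=5": d.clogp <= 5,
        "hbd<=5": d.hbd <= 5,
        "hba<=10": d.hba <= 10,
    }


def evaluate_bonus(
    fp: Fingerprint | None,
    aux: AuxEvidence,
    desc: DescriptorSet,
    rubric: TargetRubric,
    novelty_threshold: float = 0.4,
    cns_tpsa_max: float = 75.0,
) -> tuple[BonusScore, ...]:
    """Evaluate the rubric's bonus criteria for one compound.

    Novelty requires an ECFP6 fingerprint and passes when the maximum
    Tanimoto similarity to every reference active is strictly below the
    threshold; an empty reference set passes vacuously (logged as a warning).
    """
    out: list[BonusScore] = []
    bonus = rubric.bonus
    if "novelty" in bonus:
        if fp is None:
            raise ValueError("novelty scoring requires a compound fingerprint")
        if not fp.dialect.startswith("ecfp6"):
            raise ValueError(f"novelty requires an ECFP6 fingerprint, got {fp.dialect!r}")
        if len(aux.novelty_reference) == 0:
            logger.warning("empty novelty reference set: novelty passes vacuously")
            passed, detail = True, "no reference actives supplied"
        else:
            max_tc = max(tanimoto(fp, r) for r in aux.novelty_reference)
            passed = max_tc < novelty_threshold
            detail = f"max reference Tc = {max_tc:.3f}"
        out.append(BonusScore("novelty", passed, bonus["novelty"] if passed else 0, detail))
    if "patent" in bonus:
        passed = aux.patent_hits < 2
        out.append(
            BonusScore("patent", passed, bonus["patent"] if passed else 0,
                       f"{aux.patent_hits} prior hits")
        )
    if "druglike" in bonus:
        crit = lipinski_criteria(desc)
        n_pass = sum(crit.values())
        passed = n_pass >= 3
        out.append(
            BonusScore("druglike", passed, bonus["druglike"] if passed else 0,
                       f"{n_pass}/4 Lipinski criteria pass")
        )
    if "cns" in bonus:
        passed = desc.tpsa < cns_tpsa_max
        out.append(
            BonusScore("cns", passed, bonus["cns"] if passed else 0,
                       f"TPSA = {desc.tpsa:.1f} A^2")
        )
    return tuple(out)


def _score_criterion(
    crit: Criterion, kind: str, calls: Mapping[str, BindingCall]
) -> CriterionScore:
    hit = (lambda t: calls[t].binds_as_pro) if kind == "bind" else (
        lambda t: calls[t].avoids_as_anti
    )
    satisfied = tuple(t for t in crit.targets if hit(t))
    failed_stars = tuple(t for t in crit.starred if not hit(t))
    points = 0 if failed_stars else crit.points_for(len(satisfied))
    return CriterionScore(crit.name, kind, satisfied, failed_stars, points)


def score_problem(
    compound: str,
    panel: KdPanel,
    rubric: TargetRubric,
    aux: AuxEvidence,
    desc: DescriptorSet,
    fp: Fingerprint | None = None,
    star_mode: str = "per_criterion",
    novelty_threshold: float = 0.4,
    cns_tpsa_max: float = 75.0,
    require_pro_hit_for_avoid: bool = True,
) -> ScoreCard:
    """Score one compound against one problem's rubric.

    The panel must cover every rubric target for the compound; a missing
    target column is a hard error, never silently skipped.  With
    ``require_pro_hit_for_avoid`` (default), avoidance criteria award 0
    points to compounds that bind no pro-target — selectivity points are
    meaningless for an inert compound.
    """
    if star_mode not in STAR_MODES:
        raise ValueError(f"unknown star_mode {star_mode!r}; expected one of {STAR_MODES}")
    missing = [t for t in rubric.all_targets if t not in panel.kd_nM.columns]
    if missing:
        raise KeyError(f"Kd panel missing rubric targets: {missing}")
    if compound not in panel.kd_nM.index:
        raise KeyError(f"compound {compound!r} not in Kd panel")

    calls: dict[str, BindingCall] = {}
    for target in rubric.all_targets:
        kd, cens = panel.entry(compound, target)
        calls[target] = call_binding(
            kd, cens, rubric.pro_bind_nM, rubric.anti_avoid_nM, target=target
        )

    pro_hit = any(calls[t].binds_as_pro for t in rubric.pro_targets)
    bind_scores = [_score_criterion(c, "bind", calls) for c in rubric.bind_criteria]
    avoid_scores = [_score_criterion(c, "avoid", calls) for c in rubric.avoid_criteria]
    if require_pro_hit_for_avoid and not pro_hit:
        avoid_scores = [
            CriterionScore(c.name, c.kind, c.satisfied_targets, c.failed_stars, 0)
            for c in avoid_scores
        ]
    criteria = bind_scores + avoid_scores

    gated = False
    if star_mode == "gate_all" and any(c.failed_stars for c in criteria):
        gated = True
        criteria = [
            CriterionScore(c.name, c.kind, c.satisfied_targets, c.failed_stars, 0)
            for c in criteria
        ]

    bonuses = evaluate_bonus(
        fp, aux, desc, rubric,
        novelty_threshold=novelty_threshold, cns_tpsa_max=cns_tpsa_max,
    )
    return ScoreCard(
        compound=compound, problem=rubric.problem,
        criteria=tuple(criteria), bonuses=bonuses,
        star_mode=star_mode, gated=gated, pro_hit=pro_hit,
    )


def aggregate_final(
    p1_points: int, p2_points: int, interactome: bool, interactome_bonus: int = 1
) -> int:
    """Final team score: problem 1 + problem 2 + interactome participation bonus."""
    if p1_points < 0 or p2_points < 0 or interactome_bonus < 0:
        raise ValueError("points must be non-negative")
    return int(p1_points) + int(p2_points) + (interactome_bonus if interactome else 0)
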