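"""Medicinal-chemistry profiling and the 0–8 composite prioritization score.

Eight categories are assessed per compound: five physicochemical
drug-likeness rule sets (Lipinski, Ghose, Veber, Egan, Muegge), the
lead-likeness filter, and two structural-alert catalogs (PAINS, Brenk).
A compound earns 1 point per category with zero violations/alerts; the sum
(0–8) is the composite score, higher = cleaner medicinal-chemistry profile.

All numeric thresholds live in :data:`RULE_SETS` so they can be audited or
edited in one place.  One pinned logP flavor (Crippen atom-contribution,
see ``chem.descriptors``) feeds every rule set; published rule sets were
calibrated against assorted logP flavors, so small divergences from other
implementations are expected and documented.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

from rdkit.Chem import FilterCatalog

from .chem import DescriptorSet, Molecule, parse_smiles, substructure_match

__all__ = [
    "RULE_SETS",
    "ALERT_CATALOGS",
    "COMPOSITE_CATEGORIES",
    "RulePanelResult",
    "CompositeScore",
    "rule_violations",
    "structural_alerts",
    "profile_compound",
    "composite_adme_score",
    "rank_by_composite",
]

# Each criterion: (label, predicate over a DescriptorSet). A violation is a
# failed predicate.
RULE_SETS: dict[str, list[tuple[str, callable]]] = {
    "lipinski": [
        ("mw<=500", lambda d: d.mw <= 500),
        ("clogp<=5", lambda d: d.clogp <= 5),
        ("hbd<=5", lambda d: d.hbd <= 5),
        ("hba<=10", lambda d: d.hba <= 10),
    ],
    "ghose": [
        ("160<=mw<=480", lambda d: 160 <= d.mw <= 480),
        ("-0.4<=clogp<=5.6", lambda d: -0.4 <= d.clogp <= 5.6),
        ("40<=MR<=130", lambda d: 40 <= d.molar_refractivity <= 130),
        ("20<=heavy_atoms<=70", lambda d: 20 <= d.heavy_atoms <= 70),
    ],
    "veber": [
        ("rotatable<=10", lambda d: d.rotatable_bonds <= 10),
        ("tpsa<=140", lambda d: d.tpsa <= 140),
    ],
    "egan": [
        ("clogp<=5.88", lambda d: d.clogp <= 5.88),
        ("tpsa<=131.6", lambda d: d.tpsa <= 131.6),
    ],
    "muegge": [
        ("200<=mw<=600", lambda d: 200 <= d.mw <= 600),
        ("-2<=clogp<=5", lambda d: -2 <= d.clogp <= 5),
        ("tpsa<=150", lambda d: d.tpsa <= 150),
        ("rings<=7", lambda d: d.ring_count <= 7),
        ("carbons>4", lambda d: d.carbon_count > 4),
        ("heteroatoms>1", lambda d: d.heteroatom_count > 1),
        ("rotatable<=15", lambda d: d.rotatable_bonds <= 15),
        ("hbd<=5", lambda d: d.hbd <= 5),
        ("hba<=10", lambda d: d.hba <= 10),
    ],
    "leadlikeness": [
        ("250<=mw<=350", lambda d: 250 <= d.mw <= 350),
        ("clogp<=3.5", lambda d: d.clogp <= 3.5),
        ("rotatable<=7", lambda d: d.rotatable_bonds <= 7),
    ],
}

ALERT_CATALOGS = ("pains", "brenk")

#: the eight composite-score categories, in report order
COMPOSITE_CATEGORIES = (
    "lipinski", "ghose", "veber", "egan", "muegge", "leadlikeness", "pains", "brenk",
)


@lru_cache(maxsize=None)
def _builtin_catalog(catalog: str) -> FilterCatalog.FilterCatalog:
    params = FilterCatalog.FilterCatalogParams()
    which = {
        "pains": FilterCatalog.FilterCatalogParams.FilterCatalogs.PAINS,
        "brenk": FilterCatalog.FilterCatalogParams.FilterCatalogs.BRENK,
    }
    if catalog not in which:
        raise ValueError(f"unknown alert catalog {catalog!r}; expected one of {ALERT_CATALOGS}")
    params.AddCatalog(which[catalog])
    return FilterCatalog.FilterCatalog(params)


def rule_violations(d: DescriptorSet, ruleset: str) -> tuple[int, list[str]]:
    """Violation count and failed-criterion labels for one rule set."""
    if ruleset not in RULE_SETS:
        raise ValueError(f"unknown ruleset {ruleset!r}; expected one of {sorted(RULE_SETS)}")
    failed = [label for label, ok in RULE_SETS[ruleset] if not ok(d)]
    return len(failed), failed


def structural_alerts(
    mol: Molecule | str,
    catalog: str = "pains",
    custom_patterns: Sequence[tuple[str, str]] | None = None,
) -> list[str]:
    """Distinct alert labels matched by a molecule, in deterministic order.

    ``catalog`` selects a built-in catalog (PAINS or Brenk, as shipped with
    the chemistry toolkit); ``custom_patterns`` instead matches a
    user-supplied list of (SMARTS, label) pairs.  Each matching pattern
    contributes one label regardless of how many atom mappings it has.
    """
    if isinstance(mol, str):
        mol = parse_smiles(mol)
    if custom_patterns is not None:
        labels = [
            label for smarts, label in custom_patterns if substructure_match(mol, smarts)
        ]
        return sorted(set(labels))
    cat = _builtin_catalog(catalog)
    return sorted({entry.GetDescription() for entry in cat.GetMatches(mol.rdmol)})


@dataclass(frozen=True)
class RulePanelResult:
    """Violation counts per rule set and matched alerts per catalog."""

    violations: Mapping[str, int]      # ruleset -> count
    failed_criteria: Mapping[str, tuple[str, ...]]
    alerts: Mapping[str, tuple[str, ...]]  # catalog -> matched labels

    def __post_init__(self):
        missing = [r for r in RULE_SETS if r not in self.violations]
        missing += [c for c in ALERT_CATALOGS if c not in self.alerts]
        if missing:
            raise ValueError(f"incomplete rule panel: missing {missing}")


@dataclass(frozen=True)
class CompositeScore:
    """Per-category clean indicators (1 = no violations/alerts) and 0–8 total."""

    indicators: Mapping[str, int]
    total: int


def profile_compound(mol: Molecule | str, d: DescriptorSet | None = None) -> RulePanelResult:
    """Run all rule sets and both alert catalogs on one compound."""
    from .chem import descriptors  # local import avoids cycle at module load

    if isinstance(mol, str):
        mol = parse_smiles(mol)
    if d is None:
        d = descriptors(mol)
    violations, failed = {}, {}
    for ruleset in RULE_SETS:
        count, labels = rule_violations(d, ruleset)
        violations[ruleset] = count
        failed[ruleset] = tuple(labels)
    alerts = {cat: tuple(structural_alerts(mol, cat)) for cat in ALERT_CATALOGS}
    return RulePanelResult(violations=violations, failed_criteria=failed, alerts=alerts)


def composite_adme_score(panel: RulePanelResult) -> CompositeScore:
    """0–8 composite: one point per category free of violations/alerts."""
    indicators = {}
    for cat in COMPOSITE_CATEGORIES:
        if cat in ALERT_CATALOGS:
            indicators[cat] = 1 if len(panel.alerts[cat]) == 0 else 0
        else:
            indicators[cat] = 1 if panel.violations[cat] == 0 else 0
    return CompositeScore(indicators=indicators, total=sum(indicators.values()))


def rank_by_composite(
    scored: Mapping[str, CompositeScore],
    mean_cross_tc: Mapping[str, float] | None = None,
) -> list[str]:
    """Compound ids by descending composite score.

    Ties break on higher mean cross-method Tanimoto similarity (compounds
    nearer the consensus chemical space first), then lexicographic id.
    """
    def sort_key(cid: str):
        tc = mean_cross_tc.get(cid, 0.0) if mean_cross_tc else 0.0
        return (-scored[cid].total, -tc, cid)

    return sorted(scored, key=sort_key)
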