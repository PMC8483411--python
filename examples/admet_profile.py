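"""Profile compounds with drug-likeness rules, alerts, and the composite score.

Runs five physicochemical rule sets (Lipinski, Ghose, Veber, Egan, Muegge),
lead-likeness, and the PAINS/Brenk structural-alert catalogs; each of the 8
categories with zero violations/alerts contributes one point to the 0-8
composite prioritization score (higher = cleaner profile).
"""

from polypharm import composite_adme_score, profile_compound
from polypharm.admet import COMPOSITE_CATEGORIES

compounds = {
    "paracetamol-like": "CC(=O)Nc1ccc(O)cc1",
    "kinase-lead-like": "c1ccc2c(c1)nc(CCO)nc2NCC",
    "nitroaromatic": "O=[N+]([O-])c1ccc(cc1)N=Nc1ccccc1",  # azo + nitro alerts
    "greasy-lipid": "CCCCCCCCCCCCCCCCCCCCCCCC(=O)O",
}

print(f"{'compound':<18} " + " ".join(f"{c[:6]:>6}" for c in COMPOSITE_CATEGORIES) + "  score")
for name, smiles in compounds.items():
    panel = profile_compound(smiles)
    score = composite_adme_score(panel)
    cells = []
    for cat in COMPOSITE_CATEGORIES:
        n = panel.violations.get(cat, len(panel.alerts.get(cat, ())))
        cells.append(f"{n:>6}")
    print(f"{name:<18} " + " ".join(cells) + f"  {score.total}/8")
print("\nCells are violation/alert counts per category; a category scores a")
print("point only when its count is zero.")
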