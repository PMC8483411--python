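# polypharm

Scoring and prioritization of **multi-target kinase-inhibitor predictions**.

Polypharmacology challenges ask for a single small molecule that inhibits a
set of disease *pro-targets* (kinases whose inhibition is therapeutic) while
sparing *anti-targets* (kinases whose inhibition is harmful). Evaluating
such predictions needs more than a potency number: binding calls from a
compound × kinase K<sub>d</sub> panel, a point rubric over target sets,
novelty and drug-likeness bonuses, cross-submission similarity analysis,
and medicinal-chemistry prioritization of follow-up candidates. `polypharm`
implements that evaluation stack as a library, with a deterministic
synthetic-data generator so the whole pipeline runs with no external data.

## What it computes

**Binding calls.** A pro-target is *bound* when K<sub>d</sub> ≤ 10 µM
(10 000 nM, not censored); an anti-target is *avoided* when there is no
measurable hit at 30 µM (K<sub>d</sub> > 30 000 nM or above the assay
detection limit, written `>30000` in the panel CSV). Values in
(10 µM, 30 µM] are neither.

**Rubric points.** Each rubric criterion maps a bound/avoided count through
a point schedule (e.g. 1, 3 or 9 points for binding 1, 2 or 3 of
BRAF/SRC/S6K). Starred targets are hard requirements with two documented
semantics (`per_criterion`, `gate_all`). Avoidance points measure
selectivity, so they require at least one pro-target hit — an inert
compound scores bonus-only. Bonuses: novelty (max ECFP6 Tanimoto vs.
reference actives < 0.4), patentability (< 2 prior hits), drug-likeness
(≥ 3 of the 4 Lipinski rule-of-5 criteria), and — where the rubric has
it — CNS penetration (TPSA < 75 Å²). A team's final score is
P1 + P2 + a 1-point interactome-participation bonus.

**Similarity analyses.** Canonical-identity deduplication of top-ranked
picks; Tanimoto matrices on 1024-bit path fingerprints; thresholded
networks (edges below Tc 0.4 filtered out) with connected-component
subclusters; cross-team similar pairs (strict Tc > 0.5).

**ADMET composite.** Lipinski, Ghose, Veber, Egan, Muegge and lead-likeness
rule sets plus PAINS and Brenk structural alerts; each of the 8 categories
with zero violations/alerts adds one point to a 0–8 prioritization score.

**Activity classes.** pIC50 labeling — inactive (< 5), weak ([5, 6)),
potent (≥ 6) — with deterministic, optionally stratified or
compound-disjoint hold-out splits.

## Worked example

```sh
python examples/score_submissions.py
```

generates a 10-team synthetic Problem 1 instance with one planted ideal
binder and one partial binder, scores every team's top-ranked compound,
and prints:

```
team       compound   target  bonus  total
team_02    SYN0022        21      7     28
team_03    SYN0046        12      7     19
team_00    SYN0042         0      7      7
...
team_05    SYN0053         0      5      5
```

The planted ideal binder collects the rubric's maximum 21 target points
(5 for RET<sup>M918T</sup>, 9 for BRAF/SRC/S6K, 3 + 4 for avoiding all
anti-targets) plus 7 bonus points; the partial binder gets 5 + 7 avoidance
points and bonuses; inert compounds keep bonus points only (7, or 5 when
their scaffold family matches the reference actives and novelty fails).

Other examples: `similarity_network.py` (scaffold families recovered as
network components), `admet_profile.py` (rule panel + composite score),
`activity_classes.py` (pIC50 classes and hold-out split),
`simulate_challenge.py` (full report bundle). A thin CLI mirrors the
stages: `polypharm simulate | score | network | consensus | admet |
classes | run`.

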