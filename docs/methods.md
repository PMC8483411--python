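# Methods

## Scoring model

A challenge problem is defined by a rubric: bind-criteria and
avoid-criteria over named kinases, each with a point schedule keyed by the
number of satisfied targets, plus bonus criteria. The evaluation unit is a
compound's row in a K<sub>d</sub> panel (nM, with above-detection
censoring at the assay's top concentration, 30 µM by default).

Binding calls use two thresholds:

* **pro-target bound** ⇔ not censored and K<sub>d</sub> ≤ 10 000 nM
  (a positive hit at 10 µM). The boundary is inclusive: 10 000 nM binds.
* **anti-target avoided** ⇔ censored or K<sub>d</sub> > 30 000 nM
  (no measurable result at 30 µM). 30 000 nM exactly is measurable,
  hence *not* avoided.

K<sub>d</sub> in (10 000, 30 000] nM is a dead zone: measurable binding
too weak for a pro-hit, too strong for avoidance credit.

**Avoidance gating.** Avoid-criteria award points only when the compound
binds at least one pro-target (`require_pro_hit_for_avoid=True`, the
default). Rationale: anti-target avoidance is a selectivity property; a
compound with no measurable binding anywhere "avoids" every anti-target
vacuously and would otherwise outscore genuine but imperfect binders. With
the gate, an inert compound scores exactly its bonus points, which matches
how non-binding submissions populate a scoreboard (all at the 7-point
bonus level). The gate can be disabled per call for sensitivity analyses.

**Starred targets.** Some rubric targets are requirements. Because a
requirement can be read narrowly or broadly, both semantics are
implemented and the breakdown always records which starred requirements
failed:

* `per_criterion` (default): a criterion containing a failed starred
  requirement awards 0 points; other criteria are untouched.
* `gate_all`: any failed starred requirement zeroes all target-based
  points for the problem (bonuses survive).

Published team totals for this style of challenge are not exactly
recoverable from either reading alone, so the engine never asserts them;
it exposes the full per-criterion breakdown instead.

**Bonuses.** Novelty passes when the maximum ECFP6 (radius 3, 2048-bit)
Tanimoto similarity against the reference-active set is strictly below
0.4; an empty reference set passes vacuously and logs a warning.
Patentability passes below 2 prior hits (the hit count is an input column;
no live database is queried). Drug-likeness passes when at least 3 of the
4 Lipinski criteria hold (MW ≤ 500, cLogP ≤ 5, HBD ≤ 5, HBA ≤ 10). CNS
penetration (only in rubrics that include it) passes when TPSA < 75 Å².
The team aggregate is P1 + P2 + 1 point for interactome participation; the
bonus magnitude is configurable and defaults to the value consistent with
the scoreboard identity final = P1 + P2 + interactome.

## Chemistry

All structure handling is RDKit. Canonical identity is the canonical
isomeric SMILES (stereochemistry preserved for identity, ignored by
fingerprints — the analyses are 2-D). Fingerprint dialects are pinned:

| dialect | construction | bits | default use |
|---|---|---|---|
| `path1024` | linear paths to depth 7, hashed (RDKFingerprint) | 1024 | similarity matrices, networks |
| `ecfp4_2048` | Morgan radius 2 | 2048 | general-purpose |
| `ecfp6_2048` | Morgan radius 3 | 2048 | novelty vs. reference actives |

RDKit's hashing is fixed across runs and platforms, which makes bitsets
reproducible. Fingerprints are binary (both cited fingerprint types are
binary; counts are not used). The Tanimoto of two all-zero fingerprints is
defined as 1.0 (identical objects) and is configurable to 0.0.

Descriptors: MW from standard atomic masses including implicit H; cLogP
and molar refractivity from the Wildman–Crippen atom-contribution scheme
(one pinned logP flavor feeds every rule set — published rule sets were
calibrated against assorted logP variants, so small divergences from other
tools are expected); TPSA by Ertl fragment contributions; HBD/HBA by the
Lipinski convention (HBD = N/O with ≥ 1 H; HBA = N + O count), chosen
because the rubric's drug-likeness criterion is a rule-of-5 check —
stricter pharmacophore definitions would undercount.

## Similarity networks

Edges are kept at Tc ≥ threshold (the "filter out below the cutoff"
convention, default 0.4); cross-set/cross-team similar-pair queries use
strict Tc > threshold (default 0.5) and exclude self- and within-team
pairs by default, because the question is whether *another* team submitted
a similar molecule. Connected components are labeled deterministically by
smallest member index. Deduplication of top-ranked picks is by canonical
key, so aromatic vs. kekulized or reordered SMILES of one structure count
once.

## ADMET composite

Rule-set thresholds are fixed in one auditable table
(`polypharm.admet.RULE_SETS`): Lipinski (MW ≤ 500, cLogP ≤ 5, HBD ≤ 5,
HBA ≤ 10), Ghose (160 ≤ MW ≤ 480, −0.4 ≤ cLogP ≤ 5.6, 40 ≤ MR ≤ 130,
20 ≤ heavy atoms ≤ 70), Veber (rotatable ≤ 10, TPSA ≤ 140), Egan
(cLogP ≤ 5.88, TPSA ≤ 131.6), Muegge (200 ≤ MW ≤ 600, −2 ≤ cLogP ≤ 5,
TPSA ≤ 150, rings ≤ 7, C > 4, heteroatoms > 1, rotatable ≤ 15, HBD ≤ 5,
HBA ≤ 10), lead-likeness (250 ≤ MW ≤ 350, cLogP ≤ 3.5, rotatable ≤ 7).
PAINS and Brenk alerts use the catalogs shipped with RDKit (version-pinned
by the RDKit dependency); a matching pattern contributes one label
regardless of how many atom mappings it has, and user-supplied plain-text
SMARTS catalogs are also accepted. The composite score is the count of the
8 categories with zero violations/alerts. Ranking ties break on higher
mean cross-method Tanimoto (closer to consensus chemical space), then
lexicographic identifier.

## Activity classes

pIC50 classes: inactive (< 5), weak ([5, 6)), potent (≥ 6); both lower
boundaries are closed, pinned by tests at 5−ε, 5, 6−ε, 6. Hold-out
splitting is seed-deterministic; stratified and compound-disjoint modes
are both available because which was used upstream is not knowable — the
default splits by record.

## Synthetic data generator

The generator emulates the challenge's data shapes, not medicinal-chemistry
reality. Six scaffold templates (quinazolinamine, piperidine amide,
sulfonyl piperazine, chromone, thiophene urea, naphthamide) are decorated
with two substituents from a 12-member set (144 combinations per family,
864 total). The cores are large relative to the substituents, which yields
the separation the network analyses assume, verified over the full
enumeration:

* path-1024 Tanimoto within a family ≥ 0.46, across families ≤ 0.40;
* ECFP6 across families ≤ 0.30 (novelty always passes for other-family
  candidates); the naphthamide family is pairwise ≥ 0.41 within, so it
  serves as the reference-active family — any same-family candidate fails
  the < 0.4 novelty test against it.

K<sub>d</sub> panels plant roles: *ideal* (binds every pro-target,
censored on every anti-target), *near-miss* (binds one pro-target, avoids
all anti-targets), *inactive*/background (censored everywhere, with an
optional fraction of neutral dead-zone values), plus fully explicit
profiles (specific pro-targets bound, specific anti-targets measurable).
Planted binding values are log-uniform in 100–8 000 nM with multiplicative
log-normal noise (σ = 0.2 log10 units, the scale of inter-replicate spread
in serial-dilution binding assays); noise that would cross the role's
threshold is resampled, so a planted role never flips its binding call.
Activity records are normal around pIC50 5 (σ = 0.8), emulating the
centering of public kinase bioactivity data.

Randomness is split into named per-artifact streams
(library/panel/submissions/reference/activities) derived from one seed, so
adding an artifact never shifts the others; equal configs produce
byte-identical files.

What passing on synthetic data does **not** show: generated molecules span
six scaffolds, not real chemical diversity; Kd noise is well-behaved
log-normal with no assay artifacts; reference actives are a single clean
family rather than a heterogeneous bioactivity database. Results on real
panels depend on data quality the generator does not model.

## Numerical and degenerate-input choices

* SMILES parse errors report the offending position for unbalanced
  branches/rings; valence errors name the string.
* Empty or single-atom molecules never crash: fingerprints may be all-zero
  (with the documented empty-Tanimoto convention), descriptors are defined.
* A rubric target missing from the panel is a hard error, never skipped.
* Kd cells must be positive and finite unless censored; censored cells
  carry the censoring bound.
* Scoreboard ties sort by team name for reproducible output.
* Problem sizes in the default tests and the acceptance script (10 teams ×
  5 compounds, 60–864-molecule libraries, 500-record activity sets) are
  the scale of the original evaluation task itself; every check runs in
  seconds.

## Known limitations

* Rule-set numeric results can differ slightly from web services that use
  other logP flavors; thresholds live in one table for auditing.
* The interactome bonus is a recorded input, not a computed quantity.
* Patent hits are supplied counts; there is no database connector.
* No IC50↔Kd conversion and no bioactivity regression models — labeling
  and dataset preparation only.
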