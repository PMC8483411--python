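"""Score synthetic team submissions against the Problem 1 rubric.

Generates a complete synthetic challenge instance (10 teams, one planted
ideal binder), scores each team's top-ranked compound from its Kd panel,
and prints the scoreboard.  Points come from binding pro-targets, avoiding
anti-targets (only meaningful once something is bound), and the novelty /
patent / drug-likeness bonuses.
"""

import tempfile
from pathlib import Path

from polypharm import builtin_rubric, fingerprint, read_kd_table, read_submissions
from polypharm.io import read_molecules_smi
from polypharm.pipeline import score_submission_set
from polypharm.synthetic import GeneratorConfig, generate_instance, generate_library, generate_submissions

rubric = builtin_rubric("1")

# find the rank-1 compound of team_02 and plant an ideal binding profile on it
base = GeneratorConfig(seed=7, library_size=60, n_teams=10, planted_duplicate=(0, 1))
top = [t.top_ranked.name for t in generate_submissions(generate_library(base), base)]
config = GeneratorConfig(**{**base.__dict__,
                            "planted_profiles": {top[2]: "ideal", top[3]: "near_miss"}})

out = Path(tempfile.mkdtemp())
paths = generate_instance(config, rubric, out)

submissions = read_submissions([str(p) for p in paths["submissions"]])
panel = read_kd_table(paths["kd_panel"])
reference = [fingerprint(m, "ecfp6_2048") for _, m in read_molecules_smi(paths["reference_actives"])]

cards = score_submission_set(submissions, panel, rubric, reference, patent_hits={})
print(f"{'team':<10} {'compound':<10} {'target':>6} {'bonus':>6} {'total':>6}")
for team, card in sorted(cards.items(), key=lambda kv: -kv[1].problem_total):
    print(f"{team:<10} {card.compound:<10} {card.target_points:>6} "
          f"{card.bonus_points:>6} {card.problem_total:>6}")
print("\nThe planted ideal binder collects the rubric's maximum 21 target points;")
print("teams whose compounds bind nothing keep only bonus points.")
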