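"""Generator contracts: determinism, validity, planted structure and profiles."""

import numpy as np
import pytest

from polypharm import (
    AuxEvidence,
    canonical_key,
    descriptors,
    fingerprint,
    parse_smiles,
    score_problem,
    similarity_matrix,
    tanimoto,
)
from polypharm.synthetic import (
    SCAFFOLDS,
    GeneratorConfig,
    PlantedProfile,
    generate_instance,
    generate_kd_panel,
    generate_library,
    generate_reference_actives,
    generate_submissions,
    library_families,
)


class TestLibrary:
    def test_size_and_uniqueness(self):
        lib = generate_library(GeneratorConfig(seed=7, library_size=50))
        assert len(lib) == 50
        keys = {canonical_key(parse_smiles(s)) for _, s in lib}
        assert len(keys) == 50

    def test_determinism(self):
        a = generate_library(GeneratorConfig(seed=7, library_size=40))
        b = generate_library(GeneratorConfig(seed=7, library_size=40))
        assert a == b
        c = generate_library(GeneratorConfig(seed=8, library_size=40))
        assert a != c

    def test_all_parseable(self):
        for _, smiles in generate_library(GeneratorConfig(seed=1, library_size=60)):
            parse_smiles(smiles)

    def test_two_scaffold_separation(self):
        config = GeneratorConfig(seed=13, n_scaffolds=2, library_size=20)
        lib = generate_library(config)
        fam = library_families(config)
        ids = [cid for cid, _ in lib]
        m = similarity_matrix([s for _, s in lib])
        within, between = [], []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                (within if fam[ids[i]] == fam[ids[j]] else between).append(m[i, j])
        assert max(between) < 0.4 < min(within)

    def test_exceeding_space_rejected(self):
        with pytest.raises(ValueError, match="enumerable"):
            generate_library(GeneratorConfig(n_scaffolds=1, library_size=10_000))


class TestKdPanel:
    def test_ideal_profile_maximizes_target_points(self, rubric1):
        config = GeneratorConfig(seed=3, library_size=12,
                                 planted_profiles={"SYN0000": "ideal"})
        lib = generate_library(config)
        panel = generate_kd_panel(lib, rubric1, config)
        desc = descriptors(dict(lib)["SYN0000"])
        card = score_problem("SYN0000", panel, rubric1, AuxEvidence(), desc,
                             fp=fingerprint(dict(lib)["SYN0000"], "ecfp6_2048"))
        # exhaustive evaluation of the schedules: every criterion at its max
        assert card.target_points == rubric1.max_target_points

    def test_all_censored_background_scores_bonus_only(self, rubric1):
        config = GeneratorConfig(seed=3, library_size=12)
        lib = generate_library(config)
        panel = generate_kd_panel(lib, rubric1, config)
        cid, smiles = lib[5]
        card = score_problem(cid, panel, rubric1, AuxEvidence(), descriptors(smiles),
                             fp=fingerprint(smiles, "ecfp6_2048"))
        assert card.target_points == 0
        assert card.problem_total == card.bonus_points

    def test_near_miss_binds_first_pro_target_only(self, rubric1):
        config = GeneratorConfig(seed=4, library_size=12,
                                 planted_profiles={"SYN0001": "near_miss"})
        lib = generate_library(config)
        panel = generate_kd_panel(lib, rubric1, config)
        first = rubric1.pro_targets[0]
        kd, cens = panel.entry("SYN0001", first)
        assert not cens and kd <= rubric1.pro_bind_nM
        for t in rubric1.pro_targets[1:]:
            _, c = panel.entry("SYN0001", t)
            assert c

    def test_explicit_profile_and_anti_bound(self, rubric2):
        profile = PlantedProfile(pro_bound=("AURKA", "PAK1", "STK11"),
                                 anti_bound=("PAK3", "MAP3K7"))
        config = GeneratorConfig(seed=5, library_size=12, problem="2",
                                 planted_profiles={"SYN0002": profile})
        lib = generate_library(config)
        panel = generate_kd_panel(lib, rubric2, config)
        for t in ("AURKA", "PAK1", "STK11"):
            kd, cens = panel.entry("SYN0002", t)
            assert not cens and kd <= 10000
        for t in ("PAK3", "MAP3K7"):
            kd, cens = panel.entry("SYN0002", t)
            assert not cens and 10000 < kd <= 30000  # measurable, not avoided
        kd, cens = panel.entry("SYN0002", "PIK3CA")
        assert cens  # censored -> avoided

    def test_background_censoring_fraction(self, rubric1):
        config = GeneratorConfig(seed=6, library_size=120,
                                 background_censor_fraction=0.9)
        lib = generate_library(config)
        panel = generate_kd_panel(lib, rubric1, config)
        frac = panel.censored.to_numpy().mean()
        # binomial n = 120 * 9 cells: observed fraction within +-5% of 0.9
        assert abs(frac - 0.9) < 0.05

    def test_unknown_profile_compound_rejected(self, rubric1):
        config = GeneratorConfig(seed=1, library_size=5,
                                 planted_profiles={"NOPE": "ideal"})
        lib = generate_library(config)
        with pytest.raises(KeyError, match="NOPE"):
            generate_kd_panel(lib, rubric1, config)


class TestSubmissions:
    def test_duplicate_pair_different_smiles_same_structure(self):
        config = GeneratorConfig(seed=2, n_teams=10, library_size=60,
                                 planted_duplicate=(0, 4))
        subs = generate_submissions(generate_library(config), config)
        a = subs.teams[0].top_ranked
        b = subs.teams[4].top_ranked
        assert a.smiles != b.smiles
        assert canonical_key(a.smiles) == canonical_key(b.smiles)

    def test_no_duplicate_all_distinct(self):
        config = GeneratorConfig(seed=2, n_teams=6, library_size=40)
        subs = generate_submissions(generate_library(config), config)
        keys = {canonical_key(t.top_ranked.smiles) for t in subs}
        assert len(keys) == 6

    def test_yaml_roundtrip(self, tmp_path):
        from polypharm.io import read_submission, write_submission

        config = GeneratorConfig(seed=2, n_teams=3, library_size=30)
        subs = generate_submissions(generate_library(config), config)
        for team in subs:
            path = tmp_path / f"{team.team}.yaml"
            write_submission(path, team)
            assert read_submission(path) == team

    def test_invalid_duplicate_spec(self):
        config = GeneratorConfig(seed=2, n_teams=3, library_size=30,
                                 planted_duplicate=(0, 5))
        with pytest.raises(ValueError, match="inconsistent"):
            generate_submissions(generate_library(config), config)


class TestReferenceActives:
    def test_same_family_fails_novelty_other_family_passes(self):
        config = GeneratorConfig(seed=9, reference_size=20)
        refs = generate_reference_actives(config)
        ref_fps = [fingerprint(s, "ecfp6_2048") for _, s in refs]
        ref_keys = {canonical_key(s) for _, s in refs}

        # a same-family candidate not in the reference set itself
        fam_template = SCAFFOLDS[config.reference_family]
        candidate = None
        from polypharm.synthetic import SUBSTITUENTS
        import itertools

        for a, b in itertools.product(SUBSTITUENTS, SUBSTITUENTS):
            smi = fam_template.format(a, b)
            if canonical_key(smi) not in ref_keys:
                candidate = smi
                break
        max_tc = max(tanimoto(fingerprint(candidate, "ecfp6_2048"), r) for r in ref_fps)
        assert max_tc >= 0.4  # novelty fails

        other = SCAFFOLDS["chromone"].format("CC", "OC")
        max_tc_other = max(tanimoto(fingerprint(other, "ecfp6_2048"), r) for r in ref_fps)
        assert max_tc_other < 0.4  # novelty passes

    def test_reference_compound_itself_not_novel(self):
        refs = generate_reference_actives(GeneratorConfig(seed=9))
        fps = [fingerprint(s, "ecfp6_2048") for _, s in refs]
        assert tanimoto(fps[0], fps[0]) == 1.0


class TestInstanceDeterminism:
    def test_byte_identical_reruns(self, tmp_path, rubric1):
        config = GeneratorConfig(seed=42, library_size=30, n_teams=5,
                                 planted_duplicate=(0, 1))
        p1 = generate_instance(config, rubric1, tmp_path / "a")
        p2 = generate_instance(config, rubric1, tmp_path / "b")
        for key in ("library", "kd_panel", "reference_actives", "patent_hits", "activities"):
            assert p1[key].read_bytes() == p2[key].read_bytes(), key
        for f1, f2 in zip(p1["submissions"], p2["submissions"]):
            assert f1.read_bytes() == f2.read_bytes()

    def test_stream_independence(self):
        # adding a planted duplicate must not change the library
        a = generate_library(GeneratorConfig(seed=3, library_size=30))
        b = generate_library(GeneratorConfig(seed=3, library_size=30,
                                             planted_duplicate=(0, 1)))
        assert a == b
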