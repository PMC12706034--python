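"""Twin analyses, motif aggregation, binding regression, class stats."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from g3k import iupac, motif_stats as ms, synthetic as syn


def _profile(seq, rng, base=50.0, sd=5.0):
    n = iupac.parse(seq).size()
    return {i: float(base + rng.normal(0, sd)) for i in range(1, n + 1)}


def _twin_corpus(n_pairs, rng):
    """n_pairs core-fucosylated/plain sequence pairs with unique backbones."""
    monos = ["Gal", "Glc", "Man"]
    seqs = set()
    pairs = []
    while len(pairs) < n_pairs:
        length = rng.integers(2, 5)
        chain = []
        for _ in range(length):
            chain.append((monos[rng.integers(0, 3)], "ab"[rng.integers(0, 2)],
                          int(rng.integers(2, 5))))
        base = ""
        for name, anomer, x in chain:
            base = f"{name}{anomer}1-{x}" + base
        base += "GlcNAc"
        base = iupac.canonicalize(base)
        if base in seqs:
            continue
        seqs.add(base)
        with_fuc = iupac.canonicalize(_insert_core_fuc(base))
        pairs.append((with_fuc, base))
    return pairs


def _insert_core_fuc(seq):
    # root GlcNAc is the rightmost residue; attach Fuc a1-6 to it
    assert seq.endswith("GlcNAc")
    return seq[: -len("GlcNAc")] + "(Fuca1-6)GlcNAc" if "(" not in seq[-8:] else seq
    # (sequences here never end in a parenthesized branch on the root)


class TestFindTwins:
    def test_toy_pair_found(self):
        pairs = ms.find_twins(["Galb1-4(Fuca1-6)GlcNAc", "Galb1-4GlcNAc"], "Fuca1-6")
        assert len(pairs) == 1
        p = pairs[0]
        assert p.with_motif == "Galb1-4(Fuca1-6)GlcNAc"
        assert p.excluded_with >= {1, 3}  # root attachment + Fuc residue
        assert p.excluded_without == {1}

    def test_no_matches_empty(self):
        assert ms.find_twins(["Galb1-4GlcNAc", "Mana1-2Man"], "Fuca1-6") == []

    def test_planted_twins_all_recovered(self, rng):
        """Exactly the 8 planted pairs are found in a 20-sequence corpus."""
        planted = _twin_corpus(8, rng)
        decoys = [s for s, _ in _twin_corpus(4, np.random.default_rng(99))]
        corpus = [s for pair in planted for s in pair] + decoys[:4]
        found = ms.find_twins(corpus, "Fuca1-6")
        found_set = {(p.with_motif, p.without_motif) for p in found}
        planted_set = {(iupac.canonicalize(w), iupac.canonicalize(wo)) for w, wo in planted}
        # decoys also carry core fucose, so their own deletions may pair up;
        # every planted pair must be present
        assert planted_set <= found_set

    def test_malformed_motif_raises(self):
        with pytest.raises(ms.MotifError):
            ms.find_twins(["Galb1-4GlcNAc"], "Gal")  # not a dangling-linkage motif


class TestTwinDifferenceTest:
    def test_identical_profiles_null(self, rng):
        pairs = []
        profiles = {}
        for w, wo in _twin_corpus(5, rng):
            found = ms.find_twins([w, wo], "Fuca1-6")
            pairs += found
            prof = _profile(wo, rng)
            profiles[wo] = prof
            profiles[w] = {**_profile(w, rng), **{}}
        # force exact equality of the compared means
        for p in pairs:
            base = {i: 40.0 for i in profiles[p.without_motif]}
            profiles[p.without_motif] = base
            profiles[p.with_motif] = {i: 40.0 for i in profiles[p.with_motif]}
        res = ms.twin_difference_test(pairs, profiles)
        assert res.degenerate
        assert res.d_z == 0.0 and res.p_value == 1.0

    def test_planted_offset_recovered(self, rng):
        """Offset -0.5 with pair noise sd 0.2 over 40 pairs: d_z ~ -2.5."""
        pairs = []
        profiles = {}
        for w, wo in _twin_corpus(40, rng):
            found = ms.find_twins([w, wo], "Fuca1-6")
            assert found
            p = found[0]
            pairs.append(p)
            n_wo = iupac.parse(wo).size()
            n_w = iupac.parse(w).size()
            base = 50.0
            offset = -0.5 + rng.normal(0, 0.2)
            profiles[wo] = {i: base for i in range(1, n_wo + 1)}
            profiles[w] = {
                i: base + offset for i in range(1, n_w + 1)
            }
        res = ms.twin_difference_test(pairs, profiles)
        assert res.d_z == pytest.approx(-2.5, rel=0.30)
        assert res.p_value < 0.01

    def test_degenerate_constant_diffs(self, rng):
        pairs = []
        profiles = {}
        for w, wo in _twin_corpus(3, rng):
            p = ms.find_twins([w, wo], "Fuca1-6")[0]
            pairs.append(p)
            profiles[wo] = {i: 10.0 for i in range(1, iupac.parse(wo).size() + 1)}
            profiles[w] = {i: 11.0 for i in range(1, iupac.parse(w).size() + 1)}
        res = ms.twin_difference_test(pairs, profiles)
        assert res.degenerate and res.d_z == float("inf")

    def test_too_few_pairs_raise(self):
        with pytest.raises(ms.MotifError):
            ms.twin_difference_test([], {})


class TestMotifProperty:
    def test_single_occurrence_mean(self):
        prof = {1: 40.0, 2: 60.0}
        assert ms.motif_property(prof, "Galb1-4GlcNAc", "Galb1-4GlcNAc") == 50.0

    def test_two_occurrences_averaged(self):
        seq = "Galb1-4GlcNAcb1-2Mana1-3(Galb1-4GlcNAcb1-2Mana1-6)Man"
        n = iupac.parse(seq).size()
        prof = {i: 0.0 for i in range(1, n + 1)}
        occs = ms.find_motif(seq, "Galb1-4GlcNAc")
        assert len(occs) == 2
        for rid in occs[0]:
            prof[rid] = 50.0
        for rid in occs[1]:
            prof[rid] = 70.0
        assert ms.motif_property(prof, seq, "Galb1-4GlcNAc") == pytest.approx(60.0)

    def test_terminal_constraint_excludes_internal(self):
        seq = "Neu5Aca2-3Galb1-4GlcNAc"  # Gal is substituted by Neu5Ac
        prof = {i: 1.0 for i in range(1, 4)}
        assert ms.motif_property(prof, seq, "Galb1-4GlcNAc", terminal=True) is None
        assert ms.motif_property(prof, seq, "Galb1-4GlcNAc", terminal=False) == 1.0

    def test_absent_motif_returns_none(self):
        assert ms.motif_property({1: 1.0}, "Man", "Fuca1-2Gal") is None

    def test_sum_mode(self):
        prof = {1: 40.0, 2: 60.0}
        assert ms.motif_property(prof, "Galb1-4GlcNAc", "Galb1-4GlcNAc", aggregate="sum") == 100.0

    def test_wildcard_linkage_matches_isoforms(self):
        for seq in ("Neu5Aca2-3Galb1-4GlcNAc", "Neu5Aca2-6Galb1-4GlcNAc"):
            assert ms.find_motif(seq, "Neu5Aca2-?Gal")


class TestLectinCorrelation:
    def _setup(self, rng, slope=0.05, sd=0.2, n=100):
        glycans = {}
        profiles = {}
        for i in range(n):
            seq = f"Galb1-{2 + i % 3}Glc"
            # unique sequences required: vary linkage and chain
            seq = ["Galb1-2Glc", "Galb1-3Glc", "Galb1-4Glc"][i % 3]
            seq = seq if i < 3 else f"Mana1-2{seq}"
            seq = iupac.canonicalize(seq) + ""
            # ensure uniqueness by wrapping with extra Man residues
            for _ in range(i // 3):
                seq = "Mana1-2" + seq
            n_res = iupac.parse(seq).size()
            sasa = float(rng.uniform(20, 120))
            profiles[seq] = {j: sasa for j in range(1, n_res + 1)}
            glycans[seq] = sasa
        binding = syn.simulate_binding(glycans, slope=slope, noise_sd=sd,
                                       seed=int(rng.integers(1 << 31)))
        return binding, profiles

    def test_planted_slope_recovered(self, rng):
        binding, profiles = self._setup(rng, slope=0.05, sd=0.2)
        res = ms.lectin_structure_correlation(binding, "lectin1", "Gal?1-?Glc", profiles)
        assert res.pearson_r > 0.9
        assert res.slope == pytest.approx(0.05, rel=0.2)
        assert res.n >= 90

    def test_shuffled_z_kills_correlation(self, rng):
        binding, profiles = self._setup(rng, slope=0.0, sd=1.0)
        res = ms.lectin_structure_correlation(binding, "lectin1", "Gal?1-?Glc", profiles)
        assert abs(res.pearson_r) < 0.3

    def test_type_one_error_calibrated(self, rng):
        """Under the null (slope 0), p < 0.05 occurs ~5% of the time."""
        glycans = {f"{'Mana1-2' * i}Man": float(rng.uniform(20, 120)) for i in range(50)}
        profiles = {
            s: {j: v for j in range(1, iupac.parse(s).size() + 1)}
            for s, v in glycans.items()
        }
        hits = 0
        reps = 400
        for rep in range(reps):
            binding = syn.simulate_binding(glycans, slope=0.0, noise_sd=1.0, seed=rep)
            res = ms.lectin_structure_correlation(binding, "lectin1", "Man", profiles)
            hits += res.p_value < 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.03)

    def test_too_few_glycans_raise(self):
        binding = pd.DataFrame({"glycan": ["Man", "Gal"], "protein": "l", "z": [0.1, 0.2]})
        with pytest.raises(ms.MotifError):
            ms.lectin_structure_correlation(binding, "l", "Man", {"Man": {1: 1.0}})

    def test_constant_predictor_raises(self):
        seqs = [f"{'Mana1-2' * i}Man" for i in range(4)]
        binding = pd.DataFrame({"glycan": seqs, "protein": "l", "z": [0.1, 0.5, -0.2, 0.9]})
        profiles = {s: {j: 10.0 for j in range(1, iupac.parse(s).size() + 1)} for s in seqs}
        with pytest.raises(ms.MotifError, match="constant"):
            ms.lectin_structure_correlation(binding, "l", "Man", profiles)


class TestClassComparison:
    def test_planted_shift_detected(self, rng):
        groups = {
            "N": rng.normal(0, 1, 30),
            "O": rng.normal(0, 1, 30),
            "lipid": rng.normal(3, 1, 30),
        }
        res = ms.class_comparison(groups)
        assert res.p_value < 0.01
        flagged = res.tukey[res.tukey["p_adj"] < 0.05]
        assert set(map(tuple, flagged[["group_a", "group_b"]].values)) == {
            ("N", "lipid"), ("O", "lipid"),
        }

    def test_null_p_roughly_uniform(self):
        ps = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            groups = {"a": r.normal(size=15), "b": r.normal(size=15), "c": r.normal(size=15)}
            ps.append(ms.class_comparison(groups).p_value)
        # uniformity: KS test against U(0,1) should not reject strongly
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_small_group_dropped_with_warning(self, rng):
        groups = {"a": rng.normal(size=10), "b": rng.normal(size=10), "tiny": [1.0]}
        with pytest.warns(UserWarning, match="tiny"):
            res = ms.class_comparison(groups)
        assert "tiny" not in res.groups

    def test_single_group_raises(self, rng):
        with pytest.raises(ms.MotifError):
            ms.class_comparison({"only": rng.normal(size=10)})


class TestToolkit:
    def test_bh_hand_computed(self):
        q = ms.bh_correct([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_bh_identity_cases(self):
        assert ms.bh_correct([1.0, 1.0]) == pytest.approx([1.0, 1.0])
        assert ms.bh_correct([0.37]) == pytest.approx([0.37])

    def test_bh_rejects_bad_p(self):
        with pytest.raises(ms.MotifError):
            ms.bh_correct([0.5, 1.5])

    def test_mann_whitney_detects_shift(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(2, 1, 40)
        _, p = ms.unpaired_test(a, b)
        assert p < 0.001
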