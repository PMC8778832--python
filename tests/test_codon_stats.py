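import math

import numpy as np
import pytest

from cubkit.codon_stats import (
    CodonCounts,
    aroma,
    cai,
    classify_rscu,
    composition_summary,
    count_codons,
    enc,
    expected_enc,
    gravy,
    rscu_profile,
    translate,
)
from cubkit.genetic_code import FAMILIES, SYNONYMOUS_CODONS
from cubkit.sequence_io import CodingSequence, ReferenceUsageTable


class TestCountCodons:
    def test_example_counts(self):
        counts = count_codons(CodingSequence("x", "ATGAAACCCGGG"))
        assert counts.counts["ATG"] == 1
        assert counts.counts["AAA"] == 1
        assert counts.counts["CCC"] == 1
        assert counts.counts["GGG"] == 1
        assert counts.total == 4

    def test_repeated_codon(self):
        counts = count_codons(CodingSequence("x", "AAAAAA"))
        assert counts.counts["AAA"] == 2
        assert counts.total == 2

    def test_pooling_adds(self):
        a = count_codons(CodingSequence("a", "AAAAAA"))
        b = count_codons(CodingSequence("b", "AAATTT"))
        assert (a + b).counts["AAA"] == 3


class TestComposition:
    def test_hand_counted_example(self):
        comp = composition_summary(CodingSequence("x", "AAATTT"))
        assert comp.a_pct == pytest.approx(50.0)
        assert comp.u_pct == pytest.approx(50.0)
        assert comp.gc3_pct == pytest.approx(0.0)
        assert comp.gc12_pct == pytest.approx(0.0)

    def test_all_gc(self):
        comp = composition_summary(CodingSequence("x", "GGGCCC" * 5))
        assert comp.gc_pct == pytest.approx(100.0)
        assert comp.a_pct == 0.0

    def test_degenerate_input_flags_third_positions(self):
        comp = composition_summary(CodingSequence("x", "ATGTGGATG"))
        assert not comp.third_positions_defined
        assert math.isnan(comp.a3s_pct)

    def test_synonymous_third_positions_sum_to_100(self):
        comp = composition_summary(
            CodingSequence("x", "ATGGGAGGTGGCGGGAAATTTTAA")
        )
        total = comp.a3s_pct + comp.c3s_pct + comp.g3s_pct + comp.u3s_pct
        assert total == pytest.approx(100.0)

    def test_gc12_is_mean_of_gc1_gc2(self):
        comp = composition_summary(CodingSequence("x", "GCTACGTTACCA"))
        assert comp.gc12_pct == (comp.gc1_pct + comp.gc2_pct) / 2


class TestRSCU:
    def test_unbiased_two_fold_family(self):
        profile = rscu_profile(CodonCounts({"TTT": 10, "TTC": 10}))
        assert profile.values["TTT"] == pytest.approx(1.0)
        assert profile.values["TTC"] == pytest.approx(1.0)

    def test_fully_biased_four_fold_family(self):
        profile = rscu_profile(CodonCounts({"GGA": 8}))
        assert profile.values["GGA"] == pytest.approx(4.0)
        assert profile.values["GGC"] == 0.0
        fam_sum = sum(profile.values[c] for c in FAMILIES["G"])
        assert fam_sum == pytest.approx(4.0)

    def test_missing_family_reported(self):
        profile = rscu_profile(CodonCounts({"TTT": 5, "TTC": 5}))
        assert "L" in profile.missing_families
        assert math.isnan(profile.values["CTG"])

    def test_family_sums_equal_degeneracy(self):
        rng = np.random.default_rng(0)
        counts = CodonCounts(
            {c: int(rng.integers(1, 50)) for c in SYNONYMOUS_CODONS}
        )
        profile = rscu_profile(counts)
        for aa, fam in FAMILIES.items():
            assert sum(profile.values[c] for c in fam) == pytest.approx(len(fam))


class TestClassify:
    def test_uniform_usage_has_no_over_or_under(self):
        counts = CodonCounts({c: 10 for c in SYNONYMOUS_CODONS})
        cls = classify_rscu(rscu_profile(counts))
        assert not cls.over and not cls.under
        # alphabetical tie rule picks the first codon of each family
        assert cls.preferred["F"] == "TTC"
        assert len(cls.preferred) == 18

    def test_tie_broken_toward_reference(self):
        counts = CodonCounts({"GAT": 7, "GAC": 7, "TTT": 1, "TTC": 2})
        ref = ReferenceUsageTable.from_values(
            {"GAT": 30, "GAC": 70, "TTT": 50, "TTC": 50}, units="count"
        )
        cls = classify_rscu(rscu_profile(counts), reference=ref)
        assert cls.preferred["D"] == "GAC"

    def test_strict_thresholds(self):
        # RSCU exactly 1.6 / 0.6 in a 4-fold family: boundary values excluded
        counts = CodonCounts({"GGA": 16, "GGC": 6, "GGG": 10, "GGT": 8})
        cls = classify_rscu(rscu_profile(counts))
        assert "GGA" not in cls.over and "GGC" not in cls.under


class TestENC:
    def test_single_codon_per_family_is_20(self):
        counts = CodonCounts({fam[0]: 10 for fam in FAMILIES.values()})
        assert enc(counts).enc == pytest.approx(20.0)

    def test_exact_uniform_is_capped_at_61(self):
        counts = CodonCounts({c: 100 for c in SYNONYMOUS_CODONS})
        assert enc(counts).enc == 61.0

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(42)
        raw = {}
        for fam in FAMILIES.values():
            probs = rng.dirichlet(np.ones(len(fam)))
            draws = rng.multinomial(600 // 18, probs)
            for c, k in zip(fam, draws):
                raw[c] = int(k)
        counts = CodonCounts(raw)

        # independent recomputation straight from the formula
        class_f = {2: [], 3: [], 4: [], 6: []}
        for fam in FAMILIES.values():
            ns = [counts.counts[c] for c in fam]
            n = sum(ns)
            if n >= 2:
                f = (n * sum((x / n) ** 2 for x in ns) - 1) / (n - 1)
                class_f[len(fam)].append(f)
        fbar = {k: sum(v) / len(v) for k, v in class_f.items() if v}
        if 3 not in fbar:
            fbar[3] = (fbar[2] + fbar[4]) / 2
        expected = min(61.0, 2 + 9 / fbar[2] + 1 / fbar[3] + 5 / fbar[4] + 3 / fbar[6])

        assert enc(counts).enc == pytest.approx(expected, abs=1e-9)

    def test_missing_ile_substituted_from_neighbor_classes(self):
        raw = {fam[0]: 5 for aa, fam in FAMILIES.items() if aa != "I"}
        raw.update({fam[1]: 5 for aa, fam in FAMILIES.items() if aa != "I"})
        res = enc(CodonCounts(raw))
        assert res.f_by_class[3] == pytest.approx(
            (res.f_by_class[2] + res.f_by_class[4]) / 2
        )

    def test_empty_class_names_the_class(self):
        # only 2-fold families observed: 3-, 4- and 6-fold classes unusable
        raw = {}
        for aa in "FYHQNKDEC":
            for c in FAMILIES[aa]:
                raw[c] = 5
        with pytest.raises(ValueError, match=r"\[3, 4, 6\]"):
            enc(CodonCounts(raw))

    def test_short_sequence_warns(self):
        counts = CodonCounts({fam[0]: 2 for fam in FAMILIES.values()})
        with pytest.warns(UserWarning, match="noisy"):
            enc(counts)


class TestExpectedENC:
    @pytest.mark.parametrize("s,value", [(0.5, 60.5), (0.0, 31.0), (1.0, 32.0)])
    def test_closed_form_values(self, s, value):
        assert expected_enc(s) == pytest.approx(value)

    @pytest.mark.parametrize("s", [0.2, 0.8])
    def test_reflection_identity(self, s):
        assert expected_enc(s) == pytest.approx(
            expected_enc(1 - s) + (2 * s - 1), abs=1e-12
        )

    @pytest.mark.parametrize("s", [-0.1, 1.1])
    def test_domain_checked(self, s):
        with pytest.raises(ValueError):
            expected_enc(s)


class TestCAI:
    def test_all_optimal_codons_give_one(self, host_reference):
        best = {
            max(fam, key=lambda c: host_reference.weights[c]): 10
            for fam in FAMILIES.values()
        }
        assert cai(CodonCounts(best), host_reference).cai == pytest.approx(1.0)

    def test_geometric_mean_of_two_weights(self):
        # equal use of codons with w=1 and w=0.25 -> sqrt(0.25) = 0.5
        ref = ReferenceUsageTable.from_values(
            {"TTT": 80, "TTC": 20}, units="count"
        )
        counts = CodonCounts({"TTT": 10, "TTC": 10})
        assert cai(counts, ref).cai == pytest.approx(math.sqrt(0.25))

    def test_met_trp_and_stops_never_scored(self, host_reference):
        counts = CodonCounts({"ATG": 50, "TGG": 50, "TTT": 4})
        res = cai(counts, host_reference)
        assert res.n_codons == 4

    def test_no_scorable_codons_raises(self, host_reference):
        with pytest.raises(ValueError, match="no scorable"):
            cai(CodonCounts({"ATG": 3}), host_reference)


class TestProteinIndices:
    def test_poly_ile_gravy(self):
        assert gravy(CodingSequence("x", "ATT" * 10)) == pytest.approx(4.5)

    def test_poly_arg_gravy(self):
        assert gravy(CodingSequence("x", "CGT" * 10)) == pytest.approx(-4.5)

    def test_equal_ile_arg_cancels(self):
        assert gravy(CodingSequence("x", "ATTCGT" * 5)) == pytest.approx(0.0)

    def test_aroma_examples(self):
        assert aroma(CodingSequence("x", "TTT" * 8)) == pytest.approx(1.0)
        assert aroma(CodingSequence("x", "AAA" * 8)) == pytest.approx(0.0)
        assert aroma(CodingSequence("x", "TAC" + "GGG" * 9)) == pytest.approx(0.1)

    def test_terminal_stop_ignored_internal_raises(self):
        assert translate(CodingSequence("x", "ATTTAA")) == "I"
        with pytest.raises(ValueError, match="internal stop"):
            gravy(CodingSequence("x", "ATTTAAATT"))
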