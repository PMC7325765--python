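"""Site summaries, variance coefficients, Tajima's D, Fu & Li's tests and
simulation p-values."""

import math
from fractions import Fraction

import numpy as np
import pytest

from zfbirth.neutrality import (
    PopAlignment,
    coefficients,
    fu_li_tests,
    neutrality_pvalue,
    neutrality_stats,
    simulate_null,
    summarize,
    tajimas_d,
)
from zfbirth.synthetic import skewed_sample

from .oracles import (
    exact_fu_li_coefficients,
    exact_tajima_coefficients,
    oracle_site_summary,
)


def _random_alignment(rng, n, L, gap_rate=0.05):
    bases = np.array(list("ACGT-N"))
    p = np.array([0.28, 0.24, 0.2, 0.18, gap_rate, 0.1 - gap_rate])
    seqs = ["".join(rng.choice(bases, size=L, p=p)) for _ in range(n + 1)]
    return PopAlignment(
        names=[f"s{i}" for i in range(n)],
        seqs=seqs[:n],
        outgroups={"out": seqs[n]},
    )


class TestSummarize:
    def test_identical_sequences_monomorphic(self):
        aln = PopAlignment(names=list("abcd"), seqs=["ACGT"] * 4)
        s = summarize(aln)
        assert (s.S, s.eta, s.pi) == (0, 0, 0.0)
        assert s.L_used == 4

    def test_single_pair_single_difference(self):
        aln = PopAlignment(names=["a", "b"], seqs=["ACGT", "ACTT"])
        s = summarize(aln)
        assert (s.S, s.eta, s.pi) == (1, 1, 1.0)

    def test_toy_alignment_matches_bruteforce(self, toy_alignment):
        s = summarize(toy_alignment, outgroup_label="out")
        o = oracle_site_summary(toy_alignment.seqs, toy_alignment.outgroups["out"])
        assert s.S == o["S"]
        assert s.eta == o["eta"]
        assert s.eta_e == o["eta_e"]
        assert s.L_used == o["L_used"]
        assert s.pi == pytest.approx(o["pi"], abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_on_random_alignments(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(4, 13))
        L = int(rng.integers(20, 201))
        aln = _random_alignment(rng, n, L)
        s = summarize(aln, outgroup_label="out")
        o = oracle_site_summary(aln.seqs, aln.outgroups["out"])
        assert (s.S, s.eta, s.eta_e, s.L_used) == (
            o["S"], o["eta"], o["eta_e"], o["L_used"],
        )
        assert s.pi == pytest.approx(o["pi"], abs=1e-9)
        # invariants: S <= eta, eta_e <= eta, pi = 0 iff S = 0
        assert s.S <= s.eta
        assert s.eta_e <= s.eta
        assert (s.pi == 0) == (s.S == 0)

    def test_permuting_sequences_changes_nothing(self, toy_alignment):
        rev = PopAlignment(
            names=toy_alignment.names[::-1],
            seqs=toy_alignment.seqs[::-1],
            outgroups=toy_alignment.outgroups,
        )
        a = summarize(toy_alignment, "out")
        b = summarize(rev, "out")
        assert a == b

    def test_all_gap_column_error(self):
        aln = PopAlignment(names=["a", "b"], seqs=["-N", "A-"])
        with pytest.raises(ValueError, match="complete deletion"):
            summarize(aln)

    def test_unknown_outgroup_label(self, toy_alignment):
        with pytest.raises(ValueError, match="unknown outgroup"):
            summarize(toy_alignment, outgroup_label="nope")

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            PopAlignment(names=["a", "b"], seqs=["ACG", "AC"])


class TestCoefficients:
    def test_n4_harmonic_sums(self):
        c = coefficients(4)
        assert c.a1 == pytest.approx(11 / 6, abs=1e-15)
        assert c.a2 == pytest.approx(49 / 36, abs=1e-15)
        assert c.e1 > 0

    @pytest.mark.parametrize("n", [4, 10, 25])
    def test_against_exact_fraction_transcription(self, n):
        c = coefficients(n)
        tj = exact_tajima_coefficients(n)
        fl = exact_fu_li_coefficients(n)
        for name in ("a1", "a2", "b1", "b2", "c1", "c2", "e1", "e2"):
            assert getattr(c, name) == pytest.approx(float(tj[name]), rel=1e-12)
        for name in ("u_D", "v_D", "u_F", "v_F"):
            assert getattr(c, name) == pytest.approx(float(fl[name]), rel=1e-12)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            coefficients(3)


class TestTajimasD:
    def test_undefined_without_variation(self):
        aln = PopAlignment(names=list("abcd"), seqs=["ACGT"] * 4)
        assert math.isnan(tajimas_d(summarize(aln)))

    def test_constructed_zero_case(self, tajima_zero_alignment):
        d = tajimas_d(summarize(tajima_zero_alignment))
        assert d == pytest.approx(0.0, abs=1e-9)


class TestFuLi:
    def test_undefined_without_mutations(self):
        aln = PopAlignment(
            names=list("abcd"), seqs=["ACGT"] * 4, outgroups={"out": "ACGT"}
        )
        d, f = fu_li_tests(summarize(aln, "out"))
        assert math.isnan(d) and math.isnan(f)

    def test_requires_outgroup(self, tajima_zero_alignment):
        with pytest.raises(ValueError, match="outgroup"):
            fu_li_tests(summarize(tajima_zero_alignment))

    def test_all_singletons_give_negative_statistics(self):
        aln = skewed_sample(10, 20, {1: 1.0}, rng_seed=3)
        s = summarize(aln, "outgroup")
        assert s.eta_e == s.S == 20
        d, f = fu_li_tests(s)
        assert d < 0
        assert f < 0


class TestPValues:
    def test_null_median_statistic_not_significant(self):
        p = neutrality_pvalue("tajima_d", 0.0, n=10, S=10, n_reps=1000, rng_seed=1)
        assert p > 0.5

    def test_unattainable_statistic_hits_correction_floor(self):
        p = neutrality_pvalue("tajima_d", 10.0, n=10, S=10, n_reps=1000, rng_seed=1)
        assert p == pytest.approx(1 / 1001)

    def test_undefined_statistic_rejected(self):
        with pytest.raises(ValueError):
            neutrality_pvalue("tajima_d", math.nan, n=10, S=10, n_reps=1000, rng_seed=1)

    def test_null_distribution_reproducible(self):
        a = simulate_null("fuli_f", 8, 12, 50, rng_seed=9)
        b = simulate_null("fuli_f", 8, 12, 50, rng_seed=9)
        assert (a == b).all()


class TestSpectrumResponse:
    def test_intermediate_frequency_skew_inflates_d(self):
        meds = []
        for rep in range(50):
            aln = skewed_sample(10, 20, {5: 1.0}, rng_seed=rep)
            meds.append(tajimas_d(summarize(aln)))
        assert np.median(meds) > 1

    def test_singleton_skew_depresses_d(self):
        meds = []
        for rep in range(50):
            aln = skewed_sample(10, 20, {1: 1.0}, rng_seed=rep)
            meds.append(tajimas_d(summarize(aln)))
        assert np.median(meds) < -1


class TestEndToEnd:
    def test_neutrality_stats_bundle(self):
        aln = skewed_sample(10, 15, {1: 1.0, 5: 1.0}, rng_seed=4)
        summary, stats = neutrality_stats(
            aln, outgroup_label="outgroup", n_reps=1000, rng_seed=2
        )
        assert summary.S == 15
        assert stats.defined_flags == {"tajima_d": True, "fuli_d": True, "fuli_f": True}
        for p in (stats.p_tajima, stats.p_fuli_d, stats.p_fuli_f):
            assert 0 < p <= 1
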