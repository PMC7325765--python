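"""Generators: composition, random seeds, motif implanting, coalescent and
skewed alignments, CDS mutagenesis."""

import numpy as np
import pytest

from zfbirth.motif import MotifPattern, scan_dna
from zfbirth.neutrality import summarize
from zfbirth.synthetic import (
    BaseComposition,
    base_composition,
    coalescent_branches,
    coalescent_sample,
    coalescent_sfs_counts,
    implant_motif,
    mutate_cds,
    random_cds,
    random_sequences,
    skewed_sample,
)

from .conftest import MOTIF_PEPTIDE_23


class TestBaseComposition:
    @pytest.mark.parametrize(
        "seq, freqs, counted, skipped",
        [
            ("AAAA", (1, 0, 0, 0), 4, 0),
            ("ACGT", (0.25, 0.25, 0.25, 0.25), 4, 0),
            ("ACGNT", (0.25, 0.25, 0.25, 0.25), 4, 1),
        ],
    )
    def test_counting(self, seq, freqs, counted, skipped):
        comp = base_composition([seq])
        assert comp.as_tuple() == pytest.approx(freqs)
        assert (comp.n_counted, comp.n_skipped) == (counted, skipped)

    def test_multiple_records_case_insensitive(self):
        comp = base_composition(["acgt", "AAAA"])
        assert comp.freq_A == pytest.approx(5 / 8)

    def test_all_ambiguous_rejected(self):
        with pytest.raises(ValueError):
            base_composition(["NNNN"])


class TestRandomSequences:
    def test_degenerate_composition(self):
        seqs = random_sequences(BaseComposition(1, 0, 0, 0), 5, 2, rng_seed=0)
        assert seqs == ["AAAAA", "AAAAA"]

    def test_same_seed_identical(self):
        a = random_sequences(BaseComposition.uniform(), 90, 10, rng_seed=42)
        b = random_sequences(BaseComposition.uniform(), 90, 10, rng_seed=42)
        assert a == b

    def test_composition_within_four_standard_errors(self):
        n_bases = 10_000 * 90
        seqs = random_sequences(BaseComposition.uniform(), 90, 10_000, rng_seed=7)
        joined = "".join(seqs)
        se = (0.25 * 0.75 / n_bases) ** 0.5
        for base in "ACGT":
            assert abs(joined.count(base) / n_bases - 0.25) < 4 * se


class TestImplantMotif:
    @pytest.mark.parametrize("frame, aa_pos", [(1, 0), (1, 2), (-2, 1), (3, 0)])
    def test_scanner_finds_implant(self, frame, aa_pos, c2h2):
        seq = implant_motif("A" * 90, MOTIF_PEPTIDE_23, frame, aa_pos, rng_seed=5)
        assert len(seq) == 90
        hits = [
            m for m in scan_dna(seq, c2h2)
            if m.frame == frame and m.aa_start == aa_pos
        ]
        assert hits

    def test_zero_length_peptide_rejected(self):
        with pytest.raises(ValueError):
            implant_motif("A" * 90, "", 1, 0, rng_seed=0)

    def test_non_matching_peptide_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            implant_motif("A" * 90, "MKL", 1, 0, rng_seed=0)

    def test_implant_must_fit(self):
        with pytest.raises(ValueError, match="fit"):
            implant_motif("A" * 30, MOTIF_PEPTIDE_23, 1, 0, rng_seed=0)


class TestCoalescent:
    def test_branch_count_and_positive_lengths(self):
        rng = np.random.default_rng(0)
        lengths, leafsets = coalescent_branches(6, rng)
        assert len(lengths) == len(leafsets) == 2 * 6 - 2
        assert (lengths > 0).all()
        assert all(1 <= len(s) <= 5 for s in leafsets)

    def test_conditioned_on_zero_sites_identical(self):
        aln = coalescent_sample(5, 1.0, rng_seed=1, condition_on_S=0)
        assert len(set(aln.seqs)) == 1

    def test_conditioned_on_s_exact_columns(self):
        aln = coalescent_sample(8, 1.0, rng_seed=2, condition_on_S=7)
        s = summarize(aln, "outgroup")
        assert s.S == 7
        assert s.eta == 7  # infinite sites: every mutation a fresh column

    def test_outgroup_divergence_columns_private(self):
        aln = coalescent_sample(
            5, 1.0, rng_seed=3, condition_on_S=4, outgroup_divergence_mutations=6
        )
        assert len(aln.seqs[0]) == 10
        s = summarize(aln, "outgroup")
        assert s.S == 4  # private outgroup columns are not segregating

    def test_sfs_counts_range(self):
        rng = np.random.default_rng(4)
        counts = coalescent_sfs_counts(10, 50, rng)
        assert counts.shape == (50,)
        assert counts.min() >= 1 and counts.max() <= 9

    def test_determinism_under_seed(self):
        a = coalescent_sample(6, 2.0, rng_seed=11)
        b = coalescent_sample(6, 2.0, rng_seed=11)
        assert a.seqs == b.seqs

    def test_watterson_recovery_small(self):
        # E[S] = theta * a1 under the neutral coalescent
        theta, n, reps = 5.0, 10, 300
        a1 = sum(1 / i for i in range(1, n))
        Ss = [
            summarize(coalescent_sample(n, theta, rng_seed=r), "outgroup").S
            for r in range(reps)
        ]
        se = np.std(Ss, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(Ss) - theta * a1) < 4 * se


class TestSkewedSample:
    def test_pure_singletons(self):
        aln = skewed_sample(10, 12, {1: 1.0}, rng_seed=5)
        s = summarize(aln, "outgroup")
        assert s.S == 12
        assert s.eta_e == 12

    def test_uniform_weights_biallelic(self):
        aln = skewed_sample(10, 15, {c: 1.0 for c in range(1, 10)}, rng_seed=6)
        s = summarize(aln, "outgroup")
        assert s.eta == s.S == 15

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError):
            skewed_sample(10, 5, {0: 1.0}, rng_seed=0)
        with pytest.raises(ValueError):
            skewed_sample(10, 5, {1: 0.0}, rng_seed=0)


class TestMutateCds:
    def test_random_cds_is_orf(self):
        cds = random_cds(50, rng_seed=1)
        assert len(cds) == 150
        assert cds.startswith("ATG")
        from zfbirth.motif import translate_six_frames

        pep = translate_six_frames(cds)[1]
        assert pep[0] == "M"
        assert "*" not in pep[:-1]
        assert pep[-1] == "*"

    def test_planted_events_sorted_and_typed(self):
        ref = random_cds(100, rng_seed=2)
        qry, events = mutate_cds(ref, k=8, rng_seed=3)
        assert len(events) == 8
        assert [e.ref_start for e in events] == sorted(e.ref_start for e in events)
        for e in events:
            if e.kind == "substitution":
                assert e.frame_effect == "n/a"
            else:
                expected = "in_frame" if e.length % 3 == 0 else "frameshift"
                assert e.frame_effect == expected
        # net length change consistent with planted indels
        delta = sum(
            e.length if e.kind == "insertion" else -e.length
            for e in events
            if e.kind != "substitution"
        )
        assert len(qry) - len(ref) == delta

    def test_too_many_mutations_error(self):
        with pytest.raises(RuntimeError):
            mutate_cds("ATG" + "AAA" * 5 + "TAA", k=10, rng_seed=0)
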