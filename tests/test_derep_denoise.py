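import numpy as np
import pytest

from oracles import chimera_oracle

from gapkit.derep_denoise import (
    UniqueSequence,
    dereplicate,
    flag_chimeras,
    remove_singletons,
    reverse_frame_offset,
    translation_filter,
)
from gapkit.pair_join import ProcessedAmplicon


def _amp(seq, mode="assembly", junction=None):
    return ProcessedAmplicon(seq, mode, gap_junction=junction)


class TestDereplicate:
    def test_exact_string_counting(self):
        out = dereplicate([_amp("AC"), _amp("AC"), _amp("GT")])
        assert [(u.seq, u.size) for u in out] == [("AC", 2), ("GT", 1)]

    def test_simulated_reads_collapse_to_templates(self, rng):
        templates = ["".join(rng.choice(list("ACGT"), 40)) for _ in range(5)]
        reads = [_amp(templates[int(i)])
                 for i in rng.integers(0, 5, size=10_000)]
        out = dereplicate(reads)
        assert len(out) == 5
        assert sum(u.size for u in out) == 10_000
        assert {u.seq for u in out} == set(templates)

    def test_sorted_by_size_then_sequence(self):
        out = dereplicate([_amp(s) for s in ["TT", "AA", "TT", "CC"]])
        assert [(u.seq, u.size) for u in out] == [
            ("TT", 2), ("AA", 1), ("CC", 1)]

    def test_empty_input(self):
        assert dereplicate([]) == []

    def test_mixed_modes_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            dereplicate([_amp("ACGT"), _amp("ACGT", "gap", junction=2)])


class TestTranslationFilter:
    def test_stop_free_sequence_kept(self):
        assert translation_filter(UniqueSequence("ATGAAATTT", 2))

    def test_stop_codon_discards(self):
        assert not translation_filter(UniqueSequence("ATGTAAAAA", 2))

    def test_frame_offset_changes_the_verdict(self):
        # TAA appears in frame 0 but not frame 1
        seq = "TAACCCGGG"
        assert not translation_filter(UniqueSequence(seq, 2), frame_offset=0)
        assert translation_filter(UniqueSequence(seq, 2), frame_offset=1)

    def test_codons_with_N_are_skipped(self):
        assert translation_filter(UniqueSequence("TNAAAATTT", 2))

    def test_gap_segments_translated_independently(self):
        # junction splits 'TA|A...' so no spanning stop exists
        fwd, rev = "ATGTA", "ACCCGGG"
        u = UniqueSequence(fwd + rev, 2, mode="gap", gap_junction=len(fwd))
        assert translation_filter(u, frame_offset=0, rev_frame_offset=1)
        # but a stop inside the reverse segment at its own frame discards
        u2 = UniqueSequence("ATG" + "TGACCC", 2, mode="gap", gap_junction=3)
        assert not translation_filter(u2, frame_offset=0, rev_frame_offset=0)

    def test_gapped_template_keep_and_frameshift_discard(self, small_sim):
        cfg, refdb, _, _, _ = small_sim
        tmpl = refdb.entries[0].sequence
        product = tmpl[:200] + tmpl[448 - 200:]
        u = UniqueSequence(product, 5, mode="gap", gap_junction=200)
        assert translation_filter(u, refdb.frame_offset,
                                  refdb.rev_frame_offset)
        # 1-nt deletion in the forward segment shifts frame; with ~66
        # codons downstream a stop appears with high probability, and for
        # this fixture it does
        shifted = product[:50] + product[51:]
        u_bad = UniqueSequence(shifted, 5, mode="gap", gap_junction=199)
        assert not translation_filter(u_bad, refdb.frame_offset,
                                      refdb.rev_frame_offset)


class TestReverseFrameOffset:
    @pytest.mark.parametrize("amplicon_len, seg_len, expected", [
        (629, 200, 0),   # segment starts at 429, a codon boundary
        (448, 200, 1),   # segment starts at 248; next boundary at 249
        (450, 200, 2),
    ])
    def test_phase_arithmetic(self, amplicon_len, seg_len, expected):
        assert reverse_frame_offset(amplicon_len, seg_len) == expected


class TestFlagChimeras:
    def _uniques(self, seqs_sizes):
        return [UniqueSequence(s, n) for s, n in seqs_sizes]

    def test_constructed_splice_detected(self, rng):
        A = "".join(rng.choice(list("ACGT"), 400))
        B = "".join(rng.choice(list("ACGT"), 400))
        cand = A[:200] + B[200:]
        uniques = self._uniques([(A, 100), (B, 100), (cand, 5)])
        assert flag_chimeras(uniques) == [False, False, True]

    def test_identical_to_single_parent_is_clean(self, rng):
        A = "".join(rng.choice(list("ACGT"), 100))
        uniques = self._uniques([(A, 100), (A[:50] + A[50:], 5)])
        assert flag_chimeras(uniques)[1] is False

    def test_low_abundance_parents_do_not_flag(self, rng):
        A = "".join(rng.choice(list("ACGT"), 100))
        B = "".join(rng.choice(list("ACGT"), 100))
        cand = A[:50] + B[50:]
        # parents only 1.5x the candidate: below the 2x skew
        uniques = self._uniques([(A, 15), (B, 15), (cand, 10)])
        assert flag_chimeras(uniques) == [False, False, False]

    def test_requires_sorted_input(self, rng):
        u = self._uniques([("ACGT", 1), ("AAAA", 5)])
        with pytest.raises(ValueError, match="sorted"):
            flag_chimeras(u)

    def test_agrees_with_exhaustive_oracle(self, rng):
        # many random instances with <= 20 uniques over a tiny alphabet so
        # both accidental chimeras and near-misses arise
        for trial in range(30):
            n = int(rng.integers(3, 21))
            L = int(rng.integers(6, 15))
            sizes = sorted((int(s) for s in rng.integers(1, 200, n)),
                           reverse=True)
            uniques = [
                UniqueSequence("".join(rng.choice(list("AC"), L)), sz)
                for sz in sizes
            ]
            max_diffs = int(rng.integers(0, 3))
            got = flag_chimeras(uniques, max_diffs=max_diffs)
            want = chimera_oracle(uniques, max_diffs=max_diffs)
            assert got == want, f"trial {trial}"


class TestRemoveSingletons:
    def test_drops_size_one(self):
        out = remove_singletons([UniqueSequence("AA", 2),
                                 UniqueSequence("CC", 1)])
        assert [(u.seq, u.size) for u in out] == [("AA", 2)]

    def test_all_singletons_warns_and_empties(self, caplog):
        assert remove_singletons([UniqueSequence("AA", 1)]) == []

    def test_retained_abundance(self):
        uniques = [UniqueSequence(s, n) for s, n in
                   [("AAAA", 5), ("CCCC", 3), ("GGGG", 1), ("TTTT", 1)]]
        assert sum(u.size for u in remove_singletons(uniques)) == 8
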