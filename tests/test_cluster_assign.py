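import numpy as np
import pytest

from oracles import align_oracle

from gapkit.alignment import global_align
from gapkit.cluster_assign import (
    UNASSIGNED,
    assign,
    build_matrices,
    global_identity,
)
from gapkit.derep_denoise import UniqueSequence
from gapkit.formats_io import ReferenceDB, ReferenceEntry


def _db(seqs_labels, **kw):
    return ReferenceDB(
        [ReferenceEntry(f"ref{i}", lab, s)
         for i, (s, lab) in enumerate(seqs_labels)], **kw)


class TestGlobalIdentity:
    def test_identical_sequences(self, rng):
        s = "".join(rng.choice(list("ACGT"), 400))
        assert global_identity(s, s) == 1.0

    def test_five_substitutions_in_hundred(self, rng):
        s = list(rng.choice(list("ACGT"), 100))
        t = list(s)
        for pos in [3, 20, 50, 70, 99]:
            t[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[t[pos]]
        assert global_identity("".join(s), "".join(t)) == pytest.approx(0.95)

    def test_matches_independent_dp_oracle(self, rng):
        for _ in range(40):
            a = "".join(rng.choice(list("ACGT"), 50))
            b = "".join(rng.choice(list("ACGT"), 50))
            res = global_align(a, b)
            score, matches, columns = align_oracle(a, b)
            assert (res.score, res.matches, res.columns) == \
                (score, matches, columns)
            assert global_identity(a, b) == pytest.approx(matches / columns)

    def test_gapped_query_reaches_full_identity(self, rng):
        ref = "".join(rng.choice(list("ACGT"), 448))
        query = ref[:200] + ref[248:]
        assert global_identity(query, ref, gap_junction=200) == 1.0

    def test_score_agrees_with_biopython(self, rng):
        from Bio.Align import PairwiseAligner

        aligner = PairwiseAligner(match_score=1, mismatch_score=-1,
                                  open_gap_score=-2, extend_gap_score=-1)
        for _ in range(25):
            a = "".join(rng.choice(list("ACGT"), int(rng.integers(20, 80))))
            b = "".join(rng.choice(list("ACGT"), int(rng.integers(20, 80))))
            assert global_align(a, b).score == aligner.score(a, b)


class TestAssign:
    def test_exact_match_assigned_at_any_threshold(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 100)) for _ in range(3)]
        db = _db([(seqs[0], "D8"), (seqs[1], "D9"), (seqs[2], "D10")])
        u = UniqueSequence(seqs[0], 10)
        for thr in (0.9, 0.97, 1.0):
            assert assign([u], db, thr) == ["D8"]

    def test_threshold_semantics_around_best_hit(self, rng):
        ref = "".join(rng.choice(list("ACGT"), 100))
        query = list(ref)
        for pos in range(0, 21, 3):  # 7 substitutions: identity 0.93
            query[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[query[pos]]
        db = _db([(ref, "D8")])
        u = UniqueSequence("".join(query), 1)
        assert assign([u], db, 0.97) == [UNASSIGNED]
        assert assign([u], db, 0.9) == ["D8"]

    def test_empty_database_errors(self):
        with pytest.raises(ValueError):
            assign([UniqueSequence("ACGT", 1)],
                   ReferenceDB([]), 0.9)

    def test_reads_with_one_percent_error_assigned_to_source(self, rng):
        # well-separated clusters; 1% substitution noise on the queries
        base = list(rng.choice(list("ACGT"), 300))
        other = list(base)
        for pos in rng.choice(300, 60, replace=False):  # 20% divergence
            other[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[pos]]
        db = _db([("".join(base), "K1"), ("".join(other), "K2")])
        correct = 0
        for _ in range(50):
            q = list(base)
            for pos in rng.choice(300, 3, replace=False):
                q[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[pos]]
            correct += assign([UniqueSequence("".join(q), 1)], db, 0.97) == ["K1"]
        assert correct >= 50 * 0.99


class TestBuildMatrices:
    def test_accumulates_unique_sizes(self, rng):
        s = "".join(rng.choice(list("ACGT"), 60))
        db = _db([(s, "D8")])
        uniques = [UniqueSequence(s, 10), UniqueSequence(s, 5)]
        mats = build_matrices({"soil1": uniques}, db, [0.97])
        assert mats[0.97].counts.loc["soil1", "D8"] == 15

    def test_errored_read_unassigned_at_full_identity(self, rng):
        s = "".join(rng.choice(list("ACGT"), 60))
        mutated = ("A" if s[0] != "A" else "C") + s[1:]
        db = _db([(s, "D8")])
        mats = build_matrices({"x": [UniqueSequence(mutated, 4)]}, db, [1.0])
        assert mats[1.0].counts.loc["x", UNASSIGNED] == 4
        assert mats[1.0].counts.loc["x", "D8"] == 0

    def test_simulated_community_counts_match_truth(self, small_sim):
        from gapkit.pipeline import process_sample

        cfg, refdb, community, _, samples = small_sim
        uniques, _ = process_sample(samples[0].reads, "assembly")
        mats = build_matrices({"S1": uniques}, refdb, [0.97])
        truth_counts = samples[0].truth["cluster"].value_counts()
        for cluster in refdb.cluster_labels:
            assert mats[0.97].counts.loc["S1", cluster] == \
                truth_counts.get(cluster, 0)

    def test_threshold_monotonicity(self, rng):
        refs = [("".join(rng.choice(list("ACGT"), 80)), f"K{i}")
                for i in range(4)]
        db = _db(refs)
        uniques = []
        for _ in range(12):
            src = list(refs[int(rng.integers(0, 4))][0])
            for pos in rng.choice(80, int(rng.integers(0, 10)), replace=False):
                src[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[src[pos]]
            uniques.append(UniqueSequence("".join(src), int(rng.integers(1, 9))))
        mats = build_matrices({"s": uniques}, db, [0.9, 0.95, 0.97, 1.0])
        thr = sorted(mats)
        for lo, hi in zip(thr, thr[1:]):
            assigned_lo = mats[lo].counts.drop(columns=UNASSIGNED)
            assigned_hi = mats[hi].counts.drop(columns=UNASSIGNED)
            assert (assigned_hi <= assigned_lo).all().all()
            assert (mats[hi].counts[UNASSIGNED]
                    >= mats[lo].counts[UNASSIGNED]).all()

    def test_relative_rows_sum_to_one(self, rng):
        s = "".join(rng.choice(list("ACGT"), 60))
        db = _db([(s, "D8")])
        mats = build_matrices({"a": [UniqueSequence(s, 7)]}, db, [0.9])
        rel = mats[0.9].relative()
        assert rel.loc["a"].sum() == pytest.approx(1.0)
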