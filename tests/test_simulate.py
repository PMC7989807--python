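import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gapkit.cluster_assign import global_identity
from gapkit.derep_denoise import translation_filter, UniqueSequence
from gapkit.simulate import (
    SimConfig,
    error_free,
    preset,
    simulate_community,
    simulate_reads,
    simulate_references,
)


class TestSimulateReferences:
    def test_zero_divergence_gives_identical_references(self):
        cfg = SimConfig(n_clusters=3, refs_per_cluster=2,
                        within_cluster_div=0.0, between_cluster_div=0.0,
                        amplicon_len=120, seed=1)
        db = simulate_references(cfg)
        assert len({e.sequence for e in db.entries}) == 1

    def test_references_are_stop_free_in_frame(self):
        cfg = SimConfig(n_clusters=4, refs_per_cluster=2, amplicon_len=300,
                        seed=2)
        db = simulate_references(cfg)
        for e in db.entries:
            assert translation_filter(UniqueSequence(e.sequence, 2),
                                      frame_offset=db.frame_offset)

    def test_within_cluster_identity_exceeds_between(self):
        cfg = SimConfig(n_clusters=4, refs_per_cluster=2,
                        within_cluster_div=0.01, between_cluster_div=0.12,
                        amplicon_len=240, seed=3)
        db = simulate_references(cfg)
        within, between = [], []
        for i, a in enumerate(db.entries):
            for b in db.entries[i + 1:]:
                ident = global_identity(a.sequence, b.sequence)
                (within if a.cluster_label == b.cluster_label
                 else between).append(ident)
        assert min(within) > max(between)

    def test_mutable_region_confines_divergence(self):
        cfg = SimConfig(n_clusters=3, refs_per_cluster=1,
                        within_cluster_div=0.0, between_cluster_div=0.05,
                        amplicon_len=448, seed=4)
        db = simulate_references(cfg, mutable_region=(250, 448))
        seqs = [e.sequence for e in db.entries]
        for a, b in zip(seqs, seqs[1:]):
            assert a[:250] == b[:250]
            assert a[250:] != b[250:]


class TestSimulateCommunity:
    def test_rows_sum_to_one(self):
        cfg = SimConfig(n_samples=5, seed=5)
        db = simulate_references(cfg)
        ab, env = simulate_community(db, cfg)
        assert np.allclose(ab.sum(axis=1), 1.0)
        assert set(env.columns) == {"pH", "C", "N", "C:N", "moisture",
                                    "LOI", "vegetation"}
        assert list(env.index) == list(ab.index)

    def test_gradient_links_abundance_to_ph(self):
        cfg = SimConfig(n_samples=40, n_clusters=4, gradient_strength=2.0,
                        abundance_noise_sd=0.1, seed=6)
        db = simulate_references(cfg)
        ab, env = simulate_community(db, cfg)
        # the lowest-optimum cluster must decline with pH, the highest rise
        lo = stats.spearmanr(env["pH"], ab.iloc[:, 0]).statistic
        hi = stats.spearmanr(env["pH"], ab.iloc[:, -1]).statistic
        assert lo < -0.5 and hi > 0.5

    def test_zero_gradient_is_exchangeable(self):
        cfg = SimConfig(n_samples=30, n_clusters=4, gradient_strength=0.0,
                        abundance_noise_sd=0.3, seed=7)
        db = simulate_references(cfg)
        ab, env = simulate_community(db, cfg)
        rho = stats.spearmanr(env["pH"], ab.iloc[:, 0]).statistic
        assert abs(rho) < 0.5


class TestSimulateReads:
    def test_error_free_reads_reproduce_templates(self, small_sim):
        cfg, refdb, _, _, samples = small_sim
        templates = {e.sequence for e in refdb.entries}
        seen = {
            r.fwd_seq + "|" + r.rev_seq for r in samples[0].reads
        }
        from gapkit.pair_join import reverse_complement

        expected = {
            t[:cfg.read_len] + "|" + reverse_complement(t)[:cfg.read_len]
            for t in templates
        }
        assert seen <= expected

    def test_chimera_fraction_within_binomial_ci(self):
        cfg = SimConfig(n_clusters=4, refs_per_cluster=1, n_samples=1,
                        depth=5000, chimera_rate=0.05, apply_errors=False,
                        within_cluster_div=0.0, between_cluster_div=0.15,
                        gradient_strength=0.0, seed=8)
        db = simulate_references(cfg)
        ab, _ = simulate_community(db, cfg)
        (sample,) = simulate_reads(ab, db, cfg)
        frac = sample.truth["is_chimera"].mean()
        half = 2.576 * np.sqrt(0.05 * 0.95 / 5000)
        assert abs(frac - 0.05) <= half

    def test_seeded_rerun_is_byte_identical(self):
        cfg = SimConfig(n_clusters=3, refs_per_cluster=1, n_samples=1,
                        depth=50, seed=9)

        def run():
            rng = np.random.default_rng(cfg.seed)
            db = simulate_references(cfg, rng)
            ab, _ = simulate_community(db, cfg, rng)
            return simulate_reads(ab, db, cfg, rng)

        a, b = run(), run()
        assert [(r.read_id, r.fwd_seq, r.fwd_qual, r.rev_seq, r.rev_qual)
                for r in a[0].reads] == \
               [(r.read_id, r.fwd_seq, r.fwd_qual, r.rev_seq, r.rev_qual)
                for r in b[0].reads]
        pd.testing.assert_frame_equal(a[0].truth, b[0].truth)

    def test_truth_table_covers_every_read(self, small_sim):
        _, _, _, _, samples = small_sim
        sample = samples[0]
        assert len(sample.truth) == len(sample.reads)
        assert set(sample.truth["read_id"]) == \
            {r.read_id for r in sample.reads}

    def test_error_rate_tracks_emitted_quality(self):
        cfg = SimConfig(n_clusters=1, refs_per_cluster=1, n_samples=1,
                        depth=300, q_start=20, q_end_fwd=20, q_end_rev=20,
                        q_sd=0.0, chimera_rate=0.0, gradient_strength=0.0,
                        amplicon_len=448, seed=10)
        db = simulate_references(cfg)
        ab, _ = simulate_community(db, cfg)
        (sample,) = simulate_reads(ab, db, cfg)
        template = db.entries[0].sequence
        n_err = sum(
            sum(a != b for a, b in zip(r.fwd_seq, template))
            for r in sample.reads
        )
        total = 300 * cfg.read_len
        rate = n_err / total
        assert rate == pytest.approx(0.01, abs=0.002)  # Q20 -> 1%


def test_preset_dimensions():
    assert preset("bacterial448").amplicon_len == 448
    assert preset("archaeal629").amplicon_len == 629
    with pytest.raises(ValueError):
        preset("nope")


def test_error_free_transform_disables_all_noise():
    cfg = error_free(preset("bacterial448"))
    assert not cfg.apply_errors and cfg.chimera_rate == 0.0
    assert cfg.q_start == cfg.q_end_fwd == 40
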