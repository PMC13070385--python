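"""Generator statistics and world construction contracts."""

import numpy as np
import pytest
from scipy import stats

from seq2track.data import one_hot_encode
from seq2track.synthetic import (MotifModel, TaskSpec, WorldConfig,
                                 generate_world, sample_counts, sample_genome,
                                 sample_motifs, task_rates)


class TestMotifs:
    def test_deterministic_given_seed(self):
        m1 = sample_motifs(5, 8, seed=3)
        m2 = sample_motifs(5, 8, seed=3)
        for a, b in zip(m1.pwms, m2.pwms):
            np.testing.assert_array_equal(a, b)

    def test_rows_are_probability_vectors(self):
        m = sample_motifs(4, 10, seed=0)
        for pwm in m.pwms:
            np.testing.assert_allclose(np.asarray(pwm).sum(axis=1), 1.0,
                                       atol=1e-12)

    def test_single_motif_shape(self):
        m = sample_motifs(1, 4, seed=1)
        assert len(m.pwms) == 1 and np.asarray(m.pwms[0]).shape == (4, 4)

    def test_invalid_pwm_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            MotifModel(pwms=[np.full((4, 4), 0.3)], ids=["m"])


class TestGenome:
    def test_gc_content_within_three_standard_errors(self):
        n = 100_000
        seq, _ = sample_genome(n, 0.5, sample_motifs(1, 10, 0), [], 0.0, seed=2)
        gc = (seq.count("G") + seq.count("C")) / n
        assert abs(gc - 0.5) <= 3 * np.sqrt(0.25 / n)

    def test_zero_rate_plants_nothing(self):
        motifs = sample_motifs(2, 10, 0)
        _, occ = sample_genome(5000, 0.4, motifs, motifs.ids, 0.0, seed=1)
        assert occ == []

    def test_deterministic_given_seed(self):
        motifs = sample_motifs(2, 10, 0)
        g1 = sample_genome(5000, 0.4, motifs, motifs.ids, 1.0, seed=9)
        g2 = sample_genome(5000, 0.4, motifs, motifs.ids, 1.0, seed=9)
        assert g1 == g2

    def test_planted_occurrences_look_like_their_pwm(self):
        """Planted instances should score far above background under the
        motif's log-odds: the sequence actually carries the signal."""
        motifs = sample_motifs(1, 10, seed=5)
        pwm = np.asarray(motifs.pwms[0])
        seq, occ = sample_genome(20_000, 0.5, motifs, motifs.ids, 1.0, seed=6)
        assert len(occ) > 5
        oh = one_hot_encode(seq).astype(float)
        logodds = np.log(pwm + 1e-9) - np.log(0.25)
        scores = [sum(oh[p + j] @ logodds[j] for j in range(10))
                  for p, _ in occ if p + 10 <= len(seq)]
        background = [sum(oh[p + j] @ logodds[j] for j in range(10))
                      for p in range(0, 5000, 50)]
        assert np.median(scores) > np.percentile(background, 99)


class TestRates:
    TASK = TaskSpec("t", "sp", {"m0": 2.0}, baseline_rate=2.0, bandwidth=100)

    def test_no_occurrences_constant_softplus_baseline(self):
        lam = task_rates([], self.TASK, 10, 64)
        np.testing.assert_allclose(lam, np.log1p(2.0))

    def test_single_occurrence_peaks_at_containing_bin(self):
        lam = task_rates([(350, "m0")], self.TASK, 10, 64)
        assert lam.argmax() == 5

    def test_zero_weights_ignore_sequence(self):
        task = TaskSpec("t", "sp", {"m0": 0.0}, baseline_rate=2.0)
        lam = task_rates([(100, "m0"), (300, "m0")], task, 10, 64)
        assert np.ptp(lam) == 0.0

    def test_rates_strictly_positive(self):
        task = TaskSpec("t", "sp", {"m0": -5.0}, baseline_rate=0.01)
        lam = task_rates([(100, "m0")], task, 10, 64)
        assert (lam > 0).all()


class TestCounts:
    def test_mean_matches_rate_with_clt_bound(self):
        lam = np.full(10_000, 4.0)
        counts = sample_counts(lam, seed=0)
        assert abs(counts.mean() - 4.0) <= 3 * np.sqrt(4.0 / 10_000)

    def test_tiny_rate_mostly_zero(self):
        counts = sample_counts(np.full(1000, 1e-8), seed=1)
        assert counts.sum() == 0

    def test_deterministic(self):
        lam = np.linspace(0.1, 5, 100)
        np.testing.assert_array_equal(sample_counts(lam, 7), sample_counts(lam, 7))

    def test_poisson_goodness_of_fit_in_aggregate(self):
        """Chi-square GOF of counts against their generating rates, pooled
        over 20 seeds, is not rejected at alpha = 0.01."""
        lam = 3.0
        pvals = []
        for seed in range(20):
            counts = sample_counts(np.full(2000, lam), seed=seed)
            kmax = 10
            observed = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
            probs = stats.poisson.pmf(np.arange(kmax), lam)
            probs = np.append(probs, 1 - probs.sum())
            chi2 = ((observed - 2000 * probs) ** 2 / (2000 * probs)).sum()
            pvals.append(1 - stats.chi2.cdf(chi2, kmax))
        # Fisher's combination across seeds
        stat = -2 * np.sum(np.log(np.clip(pvals, 1e-300, 1)))
        p_comb = 1 - stats.chi2.cdf(stat, 2 * len(pvals))
        assert p_comb > 0.01


class TestWorld:
    def test_full_sharing_unifies_motif_vocabulary(self):
        cfg = WorldConfig.tiny(seed=2, sharing_fraction=1.0,
                               n_windows_reference=24, n_windows_species=12,
                               n_pretrain_tasks=2)
        world = generate_world(cfg)
        ref_motifs = {m for t in world.species["reference"].tasks
                      for m in t.motif_weights}
        sp_motifs = {m for t in world.species["transfer"].tasks
                     for m in t.motif_weights}
        shared_pool = set(world.motif_model.ids[:cfg.n_motifs])
        assert ref_motifs <= shared_pool and sp_motifs <= shared_pool

    def test_zero_sharing_gives_disjoint_motifs(self):
        cfg = WorldConfig.tiny(seed=2, sharing_fraction=0.0,
                               n_windows_reference=24, n_windows_species=12,
                               n_pretrain_tasks=2)
        world = generate_world(cfg)
        ref_motifs = {m for t in world.species["reference"].tasks
                      for m in t.motif_weights}
        sp_motifs = {m for t in world.species["transfer"].tasks
                     for m in t.motif_weights}
        assert ref_motifs.isdisjoint(sp_motifs)

    def test_duplicated_segments_are_exact_and_mapped(self, micro_world):
        ref = micro_world.species["reference"]
        sp = micro_world.species["transfer"]
        ref_seq = ref.genome[list(ref.genome)[0]]
        sp_seq = sp.genome[list(sp.genome)[0]]
        later_overwritten = 0
        for m in micro_world.mappings:
            q = sp_seq[m.q_start:m.q_end]
            t = ref_seq[m.t_start:m.t_end]
            if q != t:
                later_overwritten += 1  # a later paste may clobber an earlier one
        assert later_overwritten < len(micro_world.mappings)

    def test_world_is_deterministic(self):
        cfg = WorldConfig.tiny(seed=5, n_windows_reference=24,
                               n_windows_species=12, n_pretrain_tasks=2)
        w1, w2 = generate_world(cfg), generate_world(cfg)
        assert (w1.species["transfer"].genome == w2.species["transfer"].genome)
        t1 = w1.species["reference"].counts
        t2 = w2.species["reference"].counts
        for k in t1:
            for c in t1[k]:
                np.testing.assert_array_equal(t1[k][c], t2[k][c])

    def test_write_emits_standard_formats(self, tmp_path, micro_world):
        out = micro_world.write(tmp_path / "world")
        assert (out / "reference" / "genome.fa").exists()
        assert (out / "homology.psl").exists()
        assert any(p.suffix == ".bedGraph"
                   for p in (out / "transfer").iterdir())
        assert (out / "transfer" / "occurrences.bed").exists()

    def test_dataset_labels_match_counts_on_bin_grid(self, micro_world):
        ds = micro_world.dataset("reference")
        sp = micro_world.species["reference"]
        chrom = list(sp.genome)[0]
        cfg = micro_world.config
        rec = ds.manifest.records[3]
        off = (cfg.input_length - cfg.crop_length) // 2
        b0 = (rec["start"] + off) // cfg.bin_size
        nb = cfg.crop_length // cfg.bin_size
        expected = sp.counts[sp.tasks[0].task_id][chrom][b0:b0 + nb]
        np.testing.assert_allclose(ds.Y[3, :, 0], expected, rtol=1e-9)
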