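"""Simulator checks against closed forms and an independent coalescent."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

import sweepnet as sn
from sweepnet.presets import get_preset

from oracles import (
    harmonic,
    high_freq_derived_fraction,
    kingman_segsites,
    mean_r2,
    pairwise_diversity,
    tajimas_d,
)


# ---------------------------------------------------------------------------
# sweep trajectory
# ---------------------------------------------------------------------------

class TestSweepTrajectory:
    def test_complete_sweep_reaches_fixation(self):
        tr = sn.sweep_trajectory(s=0.02, pop_size=50_000, start_time=3200)
        assert tr.freqs[-1] == 1.0
        assert tr.freqs[0] <= 1.0 / (2 * 50_000) + 1e-6

    def test_frequencies_monotone(self):
        tr = sn.sweep_trajectory(s=0.05, pop_size=1000, start_time=100)
        assert np.all(np.diff(tr.freqs) >= 0)

    def test_duration_matches_logistic_closed_form(self):
        # fixation time of the genic logistic: (2/s) * ln(2N)
        tr = sn.sweep_trajectory(s=0.02, pop_size=50_000, start_time=0)
        expected = (2 / 0.02) * math.log(100_000)
        assert abs(tr.duration - expected) / expected < 0.10

    def test_anchored_at_start_time(self):
        tr = sn.sweep_trajectory(s=0.02, pop_size=1000, start_time=500)
        assert tr.times[-1] == pytest.approx(500)  # fixation time

    def test_invalid_selection_coefficient(self):
        with pytest.raises(ValueError):
            sn.sweep_trajectory(s=0.0, pop_size=1000, start_time=10)
        with pytest.raises(ValueError):
            sn.sweep_trajectory(s=-0.1, pop_size=1000, start_time=10)


# ---------------------------------------------------------------------------
# neutral expectations
# ---------------------------------------------------------------------------

class TestNeutralExpectations:
    def test_watterson_expected_segsites_n2(self):
        # E[S] = theta * a_n = 1 for n=2, theta=1
        cfg = sn.SimConfig(n_samples=2, theta=1.0, rho=0.0)
        reps = sn.simulate(cfg, 4000, seed=7)
        s = np.array([r.segsites for r in reps])
        se = s.std(ddof=1) / np.sqrt(s.size)
        assert abs(s.mean() - 1.0) < 3 * se

    def test_watterson_expected_segsites_n10(self):
        cfg = sn.SimConfig(n_samples=10, theta=10.0, rho=0.0)
        reps = sn.simulate(cfg, 2000, seed=8)
        s = np.array([r.segsites for r in reps])
        expected = 10.0 * harmonic(10)
        se = s.std(ddof=1) / np.sqrt(s.size)
        assert abs(s.mean() - expected) < 3 * se

    def test_tajimas_d_centred_at_zero_under_equilibrium(self):
        cfg = sn.SimConfig(n_samples=15, theta=20.0, rho=0.0)
        reps = sn.simulate(cfg, 1000, seed=9)
        d = np.array([tajimas_d(r.haplotypes) for r in reps])
        se = d.std(ddof=1) / np.sqrt(d.size)
        assert abs(d.mean()) < 3 * se

    def test_segsites_distribution_matches_independent_coalescent(self, rng):
        """KS agreement with a from-scratch Kingman simulation."""
        cfg = sn.SimConfig(n_samples=8, theta=8.0, rho=0.0)
        reps = sn.simulate(cfg, 1200, seed=10)
        ours = np.array([r.segsites for r in reps])
        oracle = kingman_segsites(8, 8.0, 1200, rng)
        assert stats.ks_2samp(ours, oracle).pvalue > 0.01

    def test_bottleneck_distribution_matches_independent_coalescent(self, rng):
        epochs = ((0.05, 0.1), (0.2, 1.0))
        cfg = sn.SimConfig(n_samples=8, theta=8.0, rho=0.0, epochs=epochs)
        reps = sn.simulate(cfg, 1200, seed=11)
        ours = np.array([r.segsites for r in reps])
        oracle = kingman_segsites(8, 8.0, 1200, rng, epochs=epochs)
        assert stats.ks_2samp(ours, oracle).pvalue > 0.01

    def test_identity_bottleneck_equals_equilibrium(self):
        """Size changes to relative size 1.0 must not change the model."""
        cfg0 = sn.SimConfig(n_samples=10, theta=10.0, rho=0.0)
        cfg1 = replace(cfg0, epochs=((0.01, 1.0), (0.1, 1.0)))
        s0 = np.array([r.segsites for r in sn.simulate(cfg0, 800, seed=12)])
        s1 = np.array([r.segsites for r in sn.simulate(cfg1, 800, seed=13)])
        assert stats.ks_2samp(s0, s1).pvalue > 0.01


# ---------------------------------------------------------------------------
# sweep signatures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def sweep_and_neutral_reps():
    sweep_cfg = get_preset("sweep").scaled(20)  # theta = rho = 100
    neutral_cfg = replace(sweep_cfg, sweep=None)
    sweeps = sn.simulate(sweep_cfg, 200, seed=31)
    neutrals = sn.simulate(neutral_cfg, 200, seed=32)
    return sweeps, neutrals


def _region_stats(rep, lo, hi, fn):
    bp = rep.positions * rep.region_len
    sel = (bp >= lo) & (bp < hi)
    return fn(rep.haplotypes[:, sel])


class TestSweepSignatures:
    def test_diversity_reduced_at_sweep_center(self, sweep_and_neutral_reps):
        sweeps, _ = sweep_and_neutral_reps
        center = np.mean([
            _region_stats(r, 45_000, 55_000, pairwise_diversity)
            for r in sweeps
        ])
        flanks = np.mean([
            (_region_stats(r, 0, 10_000, pairwise_diversity)
             + _region_stats(r, 90_000, 100_000, pairwise_diversity)) / 2
            for r in sweeps
        ])
        assert center < flanks

    def test_excess_high_frequency_derived_near_target(self, sweep_and_neutral_reps):
        sweeps, neutrals = sweep_and_neutral_reps
        sweep_hf = np.mean([
            _region_stats(r, 30_000, 70_000, high_freq_derived_fraction)
            for r in sweeps
        ])
        neutral_hf = np.mean([
            _region_stats(r, 30_000, 70_000, high_freq_derived_fraction)
            for r in neutrals
        ])
        assert sweep_hf > neutral_hf

    def test_elevated_ld_within_flanks_vs_across_target(self, sweep_and_neutral_reps, rng):
        """High LD on each side of the target, low LD across it."""
        sweeps, _ = sweep_and_neutral_reps
        within, across = [], []
        for r in sweeps:
            bp = r.positions * r.region_len
            left = np.flatnonzero((bp > 5_000) & (bp < 45_000))
            right = np.flatnonzero((bp > 55_000) & (bp < 95_000))
            if len(left) < 5 or len(right) < 5:
                continue
            lp = rng.choice(left, size=(20, 2))
            rp = rng.choice(right, size=(20, 2))
            cp = np.column_stack([
                rng.choice(left, 20), rng.choice(right, 20)
            ])
            within.append((mean_r2(r.haplotypes, lp) + mean_r2(r.haplotypes, rp)) / 2)
            across.append(mean_r2(r.haplotypes, cp))
        assert len(within) >= 150
        assert np.mean(within) > np.mean(across)


# ---------------------------------------------------------------------------
# demographic variants and determinism
# ---------------------------------------------------------------------------

class TestModels:
    def test_hotspot_model_runs(self):
        cfg = get_preset("dataset-74").scaled(20)  # 5 kb hotspot, 10x
        reps = sn.simulate(cfg, 5, seed=41)
        assert all(r.segsites > 0 for r in reps)

    def test_migration_sweep_model_runs(self):
        cfg = get_preset("dataset-61").scaled(50)
        reps = sn.simulate(cfg, 3, seed=42)
        assert all(r.n_samples == 20 for r in reps)

    def test_seed_determinism_bytewise(self):
        cfg = get_preset("dataset-61").scaled(50)
        a = sn.write_ms(sn.simulate(cfg, 3, seed=5), command_line="x")
        b = sn.write_ms(sn.simulate(cfg, 3, seed=5), command_line="x")
        assert a == b

    def test_different_seeds_differ(self):
        cfg = sn.SimConfig(theta=20.0, rho=0.0)
        a = sn.write_ms(sn.simulate(cfg, 2, seed=1), command_line="x")
        b = sn.write_ms(sn.simulate(cfg, 2, seed=2), command_line="x")
        assert a != b

    @pytest.mark.parametrize("bad", [
        dict(theta=0.0),
        dict(rho=-1.0),
        dict(epochs=((0.1, 1.0), (0.05, 0.5))),  # times not increasing
        dict(epochs=((0.1, 0.0),)),  # size <= 0
        dict(hotspots=(sn.Hotspot(10, 5, 2.0),)),  # empty interval
        dict(hotspots=(sn.Hotspot(0, 5000, 0.5),)),  # intensity < 1
        dict(hotspots=(sn.Hotspot(0, 5000, 2.0), sn.Hotspot(4000, 9000, 2.0))),
        dict(sweep=sn.SweepParams(s=-0.02, start_time=0.01, position_bp=5e4)),
        dict(sweep=sn.SweepParams(s=0.02, start_time=0.01, position_bp=2e5)),
        dict(migration_rate=3.0),  # join time missing
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            sn.SimConfig(**bad)


# ---------------------------------------------------------------------------
# ms output
# ---------------------------------------------------------------------------

class TestWriteMs:
    def test_replicate_separators(self, tiny_neutral_reps):
        text = sn.write_ms(tiny_neutral_reps[:2])
        assert text.count("//") == 2

    def test_zero_segsites_block(self):
        rep = sn.MsReplicate(
            positions=np.zeros(0), haplotypes=np.zeros((4, 0), np.uint8)
        )
        text = sn.write_ms([rep])
        assert "segsites: 0" in text
        assert "positions:" not in text

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            sn.write_ms([])

    def test_mixed_sample_sizes_rejected(self, tiny_neutral_reps):
        bad = sn.MsReplicate(
            positions=np.array([0.5]), haplotypes=np.array([[1], [0], [1]],
                                                           dtype=np.uint8)
        )
        with pytest.raises(ValueError):
            sn.write_ms([tiny_neutral_reps[0], bad])

    def test_round_trip_preserves_content(self, tiny_neutral_reps):
        text = sn.write_ms(tiny_neutral_reps)
        parsed = sn.parse_ms(text, region_len=tiny_neutral_reps[0].region_len)
        assert len(parsed) == len(tiny_neutral_reps)
        for rep, mat in zip(tiny_neutral_reps, parsed):
            np.testing.assert_array_equal(rep.haplotypes, mat.states)
            # positions agree to the printed precision after bp scaling
            expected_bp = np.ceil(
                np.round(rep.positions, 6) * rep.region_len
            )
            assert np.max(np.abs(mat.positions_bp - expected_bp)) <= 1
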