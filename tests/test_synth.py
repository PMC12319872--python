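import numpy as np
import pytest
from scipy import signal, stats

from mindprobe import (SynthConfig, latent_to_rating, simulate_cohort,
                       simulate_latents, simulate_rest, simulate_session,
                       write_edf)
from mindprobe.containers import DIMENSIONS
from mindprobe.synth import EffectSpec, _POSTERIOR, default_effects


def small_config(**kw):
    base = dict(n_participants=1, n_sessions=1, task_duration=200.0,
                n_probes=6, probe_gap=(25.0, 35.0), window_s=12.0,
                rest_duration=60.0, seed=0)
    base.update(kw)
    return SynthConfig(**base)


class TestLatents:
    def test_identity_correlation_off_diagonals_small(self):
        cfg = small_config(correlation=np.eye(7))
        lat = simulate_latents(cfg, 10_000, seed=1)
        c = np.corrcoef(lat.T)
        assert np.abs(c[~np.eye(7, dtype=bool)]).max() < 0.05

    def test_strong_target_correlation_recovered(self):
        corr = np.eye(7)
        corr[0, 1] = corr[1, 0] = 0.9
        cfg = small_config(correlation=corr)
        lat = simulate_latents(cfg, 10_000, seed=2)
        assert abs(np.corrcoef(lat[:, 0], lat[:, 1])[0, 1] - 0.9) < 0.03

    def test_marginals_standard_normal(self):
        lat = simulate_latents(small_config(), 20_000, seed=3)
        assert np.abs(lat.mean(axis=0)).max() < 0.03
        assert np.abs(lat.std(axis=0) - 1).max() < 0.03

    def test_seeded_repeatability(self):
        cfg = small_config()
        np.testing.assert_array_equal(simulate_latents(cfg, 50, seed=4),
                                      simulate_latents(cfg, 50, seed=4))

    def test_non_positive_definite_correlation_rejected(self):
        corr = np.full((7, 7), 0.99)
        np.fill_diagonal(corr, 1.0)
        corr[0, 1] = corr[1, 0] = -0.99
        with pytest.raises(ValueError, match="positive definite"):
            small_config(correlation=corr)


class TestRatings:
    def test_center_and_clipping(self):
        assert latent_to_rating(0.0, 0.0) == 4
        assert latent_to_rating(3.0, 0.0) == 7
        assert latent_to_rating(-3.0, 0.0) == 1

    def test_rating_distribution_mode_at_center(self):
        rng = np.random.default_rng(5)
        ratings = np.array([
            latent_to_rating(l, 0.5, seed=s)
            for l, s in zip(rng.standard_normal(20_000), range(20_000))])
        counts = np.bincount(ratings, minlength=8)
        assert counts[0] == 0 and set(np.nonzero(counts)[0]) <= set(range(1, 8))
        assert counts.argmax() == 4


class TestSession:
    def test_default_probe_schedule(self):
        """Full-scale sessions carry 35 probes with 90-150 s gaps."""
        rec, reports, _ = simulate_session(SynthConfig(), 0, 0)
        assert len(reports) == 35
        gaps = np.diff(np.concatenate([[0.0], rec.probe_times]))
        assert np.all((gaps >= 90.0) & (gaps <= 150.0))
        assert rec.duration >= rec.probe_times[-1]

    def test_unknown_effect_electrode_rejected(self):
        with pytest.raises(ValueError, match="unknown electrodes"):
            small_config(effects=(
                EffectSpec("off_task", ("Nowhere",), (8.0, 9.0), 0.5),))

    def test_session_determinism(self):
        cfg = small_config()
        r1, p1, _ = simulate_session(cfg, 0, 0)
        r2, p2, _ = simulate_session(cfg, 0, 0)
        np.testing.assert_array_equal(r1.data, r2.data)
        assert [r.ratings for r in p1] == [r.ratings for r in p2]

    def test_ground_truth_mask_matches_band(self):
        cfg = small_config(effects=default_effects(gain=0.4))
        _, _, gt = simulate_session(cfg, 0, 0)
        mask = gt.effect_masks["off_task"]
        freqs = np.arange(4, 31)
        assert mask.shape == (32, 27)
        assert set(freqs[mask.any(axis=0)]) == {8, 9}


def _window_band_power(rec, t0, t1, band, electrodes_idx):
    i0, i1 = int(t0 * rec.sample_rate), int(t1 * rec.sample_rate)
    seg = rec.data[electrodes_idx, i0:i1]
    f, p = signal.periodogram(seg, fs=rec.sample_rate, axis=1)
    sel = (f >= band[0]) & (f <= band[1])
    return p[:, sel].mean()


class TestPlantedEffects:
    def test_planted_effect_raises_band_power_in_upper_windows(self):
        """Direct periodogram oracle: posterior 8-9 Hz power is higher in
        windows whose off-task latent is positive (gain 0.5)."""
        cfg = small_config(
            task_duration=2300.0, n_probes=100, probe_gap=(20.0, 25.0),
            effects=(EffectSpec("off_task", _POSTERIOR, (8.0, 9.0), 0.5),),
            seed=11)
        rec, _, gt = simulate_session(cfg, 0, 0)
        idx = [rec.layout.index(e) for e in _POSTERIOR]
        powers, latents = [], gt.latents[:, DIMENSIONS.index("off_task")]
        for t0, t1 in zip(gt.window_starts, gt.window_ends):
            powers.append(_window_band_power(rec, t0, t1, (8, 9), idx))
        powers = np.log10(powers)
        upper, lower = powers[latents > 0], powers[latents < 0]
        t, p = stats.ttest_ind(upper, lower, alternative="greater")
        assert p < 0.01

    def test_zero_gain_balances_band_power(self):
        cfg = small_config(
            task_duration=2300.0, n_probes=100, probe_gap=(20.0, 25.0),
            effects=(EffectSpec("off_task", _POSTERIOR, (8.0, 9.0), 0.0),),
            seed=12)
        rec, _, gt = simulate_session(cfg, 0, 0)
        idx = [rec.layout.index(e) for e in _POSTERIOR]
        powers, latents = [], gt.latents[:, DIMENSIONS.index("off_task")]
        for t0, t1 in zip(gt.window_starts, gt.window_ends):
            powers.append(_window_band_power(rec, t0, t1, (8, 9), idx))
        powers = np.log10(powers)
        _, p = stats.ttest_ind(powers[latents > 0], powers[latents < 0])
        assert p > 0.01


class TestRest:
    def test_rest_duration_and_scope(self):
        rec, report = simulate_rest(SynthConfig(), 0, 0)
        assert rec.duration == pytest.approx(300.0)
        assert report.scope == "retrospective"
        assert "off_task" not in report.ratings and report.activity is None

    def test_rest_determinism(self):
        cfg = small_config()
        r1, _ = simulate_rest(cfg, 0, 0)
        r2, _ = simulate_rest(cfg, 0, 0)
        np.testing.assert_array_equal(r1.data, r2.data)

    def test_zero_gain_rest_matches_task_background_psd(self):
        cfg = small_config(task_duration=300.0, n_probes=8,
                           effects=default_effects(gain=0.0), seed=13)
        task, _, _ = simulate_session(cfg, 0, 0)
        rest, _ = simulate_rest(cfg, 0, 0)

        def psd(rec):
            f, p = signal.welch(rec.data, fs=rec.sample_rate, nperseg=512)
            sel = (f >= 4) & (f <= 30)
            return np.log10(p[:, sel].mean(axis=0))

        assert np.abs(psd(task) - psd(rest)).mean() < 0.1


class TestCohort:
    def test_cohort_counts(self):
        cfg = small_config(n_participants=2, n_sessions=1)
        cohort = simulate_cohort(cfg)
        assert len(cohort.task_recordings) == 2
        assert len(cohort.rest_recordings) == 4
        assert len(cohort.rest_reports) == 4

    def test_participant_aperiodic_shared_across_sessions(self):
        from mindprobe.synth import participant_aperiodic

        cfg = small_config(n_participants=2, n_sessions=2)
        a = participant_aperiodic(cfg, 0)
        assert participant_aperiodic(cfg, 0) == a
        assert participant_aperiodic(cfg, 1) != a

    def test_same_seed_gives_byte_identical_edf(self, tmp_path):
        cfg = small_config(task_duration=60.0, n_probes=2,
                           probe_gap=(20.0, 25.0))
        for name in ("a", "b"):
            rec, _, _ = simulate_session(cfg, 0, 0)
            write_edf(rec, tmp_path / f"{name}.edf")
        assert (tmp_path / "a.edf").read_bytes() == (tmp_path / "b.edf").read_bytes()


def test_background_psd_recovers_configured_exponent():
    """Log-log regression over 4-30 Hz returns the planted 1/f exponent."""
    from mindprobe.synth import _aperiodic_background

    for true_exp in (0.8, 1.2):
        x = _aperiodic_background(np.random.default_rng(7), 4, 256 * 120,
                                  256.0, 1.0, true_exp)
        f, p = signal.welch(x, fs=256.0, nperseg=256, noverlap=128,
                            window="hamming", detrend=False)
        sel = (f >= 4) & (f <= 30)
        slope = np.polyfit(np.log10(f[sel]), np.log10(p[:, sel].mean(0)), 1)[0]
        assert abs(-slope - true_exp) < 0.1
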