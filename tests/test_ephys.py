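"""Common-average referencing, MUA envelope and evoked-SNR computation."""

import numpy as np
import pytest

from fbrquant.ephys import (
    RawRecording,
    TrialMatrix,
    common_average_reference,
    compute_snr,
    epoch_and_average,
    mua_envelope,
    records_to_frame,
    snr_of_recording,
    weekly_aggregate,
)
from fbrquant.synthetic import EphysModelParams, generate_mua_recording

FS = 24000.0


def make_recording(samples, onsets=(1.0,)):
    return RawRecording(samples=samples, rate_hz=FS, onsets_s=np.asarray(onsets))


class TestCommonAverageReference:
    def test_identical_channels_cancel_completely(self):
        rng = np.random.default_rng(0)
        sig = rng.normal(size=48000)
        rec = make_recording(np.tile(sig, (4, 1)))
        out = common_average_reference(rec)
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-12)

    def test_column_sums_are_zero_for_any_input(self):
        rng = np.random.default_rng(1)
        rec = make_recording(rng.normal(size=(5, 24000)))
        out = common_average_reference(rec)
        np.testing.assert_allclose(out.samples.sum(axis=0), 0.0, atol=1e-9)

    def test_shared_sinusoid_removed_from_distinct_signals(self):
        rng = np.random.default_rng(2)
        t = np.arange(48000) / FS
        sig = rng.normal(size=(3, t.size))
        shared = 5.0 * np.sin(2 * np.pi * 8 * t)
        rec = make_recording(sig + shared)
        out = common_average_reference(rec)
        expected = sig - sig.mean(axis=0)
        np.testing.assert_allclose(out.samples, expected, atol=1e-9)

    def test_single_electrode_is_identity_with_warning(self):
        rec = make_recording(np.ones((1, 24000)))
        with pytest.warns(UserWarning, match="single electrode"):
            out = common_average_reference(rec)
        assert out is rec


class TestMuaEnvelope:
    def test_out_of_band_sine_strongly_attenuated(self):
        t = np.arange(int(2 * FS)) / FS
        x = np.sin(2 * np.pi * 100 * t)  # below the 750 Hz band edge
        env, _ = mua_envelope(x, FS)
        mid = env[len(env) // 4 : -len(env) // 4]
        assert mid.max() < 0.01  # >40 dB down from amplitude 1

    def test_in_band_sine_gives_rectified_mean_level(self):
        amp = 3.0
        t = np.arange(int(2 * FS)) / FS
        x = amp * np.sin(2 * np.pi * 2000 * t)
        env, erate = mua_envelope(x, FS)
        mid = env[int(0.5 * erate) : int(1.5 * erate)]
        assert np.median(mid) == pytest.approx(2 * amp / np.pi, rel=0.05)

    def test_zero_input_zero_output(self):
        env, erate = mua_envelope(np.zeros(int(FS)), FS)
        np.testing.assert_allclose(env, 0.0, atol=1e-12)
        assert erate == pytest.approx(1000.0)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="sampling rate"):
            mua_envelope(np.zeros(100), 8000.0)


class TestEpochAndAverage:
    def test_constant_envelope_gives_constant_trials(self):
        env = np.full(4000, 7.0)
        trials, mean = epoch_and_average(env, 1000.0, [1.0, 2.0])
        assert trials.trials.shape == (2, 1500)
        np.testing.assert_allclose(trials.trials, 7.0)
        np.testing.assert_allclose(mean, 7.0)

    def test_single_trial_mean_is_that_trial(self):
        rng = np.random.default_rng(3)
        env = rng.random(3000)
        trials, mean = epoch_and_average(env, 1000.0, [1.0])
        np.testing.assert_allclose(mean, trials.trials[0])

    def test_truncated_trials_dropped_with_warning(self):
        env = np.ones(2000)
        with pytest.warns(UserWarning, match="dropped 1"):
            trials, _ = epoch_and_average(env, 1000.0, [0.5, 1.9])
        assert trials.trials.shape[0] == 1


def make_trials(rng, n_trials=100, noise_sd=1.0, bumps=()):
    """Trial matrix at 1 kHz covering [-0.25, 1.25] s with optional bumps
    (center_s, height) added to every trial."""
    n_t = 1500
    t = -0.25 + np.arange(n_t) / 1000.0
    x = rng.normal(0, noise_sd, size=(n_trials, n_t))
    for center, height in bumps:
        x += height * np.exp(-0.5 * ((t - center) / 0.02) ** 2)
    return TrialMatrix(trials=x, rate_hz=1000.0)


class TestComputeSnr:
    def test_largest_window_is_reported(self):
        rng = np.random.default_rng(4)
        trials = make_trials(rng, bumps=[(0.1, 2.0), (0.6, 5.0)])
        rec = compute_snr(trials, smooth_sigma_s=None)
        assert rec.window == "reversal"

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        trials = make_trials(rng, bumps=[(0.1, 3.0)])
        r1 = compute_snr(trials)
        r2 = compute_snr(TrialMatrix(trials=7.5 * trials.trials, rate_hz=1000.0))
        assert r1.snr == pytest.approx(r2.snr, rel=1e-9)
        assert r1.window == r2.window

    def test_zero_noise_flagged_infinite(self):
        trials = make_trials(np.random.default_rng(6), noise_sd=0.0, bumps=[(0.1, 1.0)])
        with pytest.warns(UserWarning, match="zero baseline noise"):
            rec = compute_snr(trials)
        assert np.isinf(rec.snr)

    def test_null_recording_snr_is_small(self):
        # the max-over-windows statistic is biased above zero under the null,
        # but stays far below the values of truly evoked responses
        rng = np.random.default_rng(7)
        snrs = [compute_snr(make_trials(rng, n_trials=100)).snr for _ in range(60)]
        assert np.median(snrs) < 2.0
        assert np.mean(np.array(snrs) > 3.0) < 0.1

    def test_known_amplitude_recovered(self):
        # bump height expressed in units of the baseline-mean SD sigma:
        # the computed SNR estimates height/sigma once the evoked response
        # dominates the sampling noise of the trial-mean trace
        rng = np.random.default_rng(8)
        noise_sd = 1.0
        sigma = noise_sd / np.sqrt(250)
        snrs = [
            compute_snr(make_trials(rng, n_trials=100, bumps=[(0.1, 10 * sigma)])).snr
            for _ in range(40)
        ]
        assert np.median(snrs) == pytest.approx(10.0, rel=0.10)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match="trials"):
            compute_snr(TrialMatrix(trials=np.zeros((1, 1500)), rate_hz=1000.0))


class TestWeeklyAggregate:
    def _records(self, rows):
        import pandas as pd

        return pd.DataFrame(rows)

    def test_single_session_is_identity(self):
        df = self._records(
            [{"material": "PI", "electrode": 0, "week": 1, "snr": 2.0}]
        )
        out = weekly_aggregate(df)
        assert out["weekly"]["snr"].tolist() == [2.0]

    def test_sessions_within_week_averaged(self):
        df = self._records(
            [
                {"material": "PI", "electrode": 0, "week": 1, "snr": 2.0},
                {"material": "PI", "electrode": 0, "week": 1, "snr": 4.0},
            ]
        )
        out = weekly_aggregate(df)
        assert out["weekly"]["snr"].tolist() == [3.0]

    def test_useful_cutoff_is_strict(self):
        df = self._records(
            [
                {"material": "Si", "electrode": e, "week": 1, "snr": 0.5}
                for e in range(4)
            ]
        )
        out = weekly_aggregate(df)
        assert out["fractions"]["pct_useful"].tolist() == [0.0]

    def test_four_week_binning(self):
        df = self._records(
            [
                {"material": "PI", "electrode": 0, "week": w, "snr": 2.0}
                for w in range(1, 25)
            ]
        )
        binned = weekly_aggregate(df)["binned"]
        assert sorted(binned["time_bin"].unique()) == [0, 1, 2, 3, 4, 5]
        assert (binned.groupby("time_bin").size() == 4).all()


class TestEndToEnd:
    def test_car_improves_snr_under_shared_artifact(self):
        params = EphysModelParams(
            n_electrodes=4,
            n_trials=15,
            evoked_amplitude=8.0,
            noise_sd=2.0,
            artifact_amplitude=20.0,
            seed=9,
        )
        rec = generate_mua_recording(params, week=0)
        with_car = records_to_frame(snr_of_recording(rec, apply_car=True))
        without = records_to_frame(snr_of_recording(rec, apply_car=False))
        assert with_car["snr"].median() >= without["snr"].median()

    def test_evoked_recording_yields_useful_electrodes(self):
        params = EphysModelParams(
            n_electrodes=3, n_trials=15, evoked_amplitude=10.0, noise_sd=2.0, seed=10
        )
        rec = generate_mua_recording(params, week=0)
        df = records_to_frame(snr_of_recording(rec))
        assert df["useful"].all()
        assert (df["snr"] > 2).all()
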