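"""Visually evoked multi-unit-activity (MUA) SNR of chronic recordings.

Raw extracellular traces are common-average referenced to cancel shared
movement artifacts, converted to an MUA envelope (band-pass 750-5000 Hz,
rectification, 200 Hz low-pass, all zero-phase), epoched around stimulus
onsets and summarised per electrode as a signal-to-noise ratio: the largest
absolute deviation of the trial-mean envelope from its pre-stimulus baseline
within the stimulus-on (0-250 ms), pattern-reversal (500-750 ms) or
stimulus-off (1-1.25 s) window, divided by the across-trial standard
deviation of the per-trial baseline means.  Electrodes with SNR > 1 count as
useful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal as sig

MUA_BAND_HZ = (750.0, 5000.0)
MUA_LOWPASS_HZ = 200.0
FILTER_ORDER = 3
ENVELOPE_RATE_HZ = 1000.0
EPOCH_WINDOW_S = (-0.25, 1.25)
BASELINE_WINDOW_S = (-0.25, 0.0)  # half-open: [-250, 0) ms
RESPONSE_WINDOWS_S = {
    "onset": (0.0, 0.25),
    "reversal": (0.5, 0.75),
    "offset": (1.0, 1.25),
}
SMOOTH_SIGMA_S = 0.005  # Gaussian smoothing of the trial-mean trace
USEFUL_SNR = 1.0


@dataclass
class RawRecording:
    """Multi-electrode voltage matrix with stimulus onsets.

    ``samples`` is (n_electrodes, n_samples) in arbitrary voltage units.
    """

    samples: np.ndarray
    rate_hz: float
    onsets_s: np.ndarray
    week: int = 0
    material: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        if self.rate_hz <= 0:
            raise ValueError("rate must be positive")
        dur = self.samples.shape[1] / self.rate_hz
        if np.any(self.onsets_s < 0) or np.any(self.onsets_s > dur):
            raise ValueError("stimulus onsets outside the recording")

    @property
    def n_electrodes(self) -> int:
        return self.samples.shape[0]


@dataclass
class TrialMatrix:
    """Per-electrode trials x time MUA-envelope matrix, onset-aligned.

    The time axis runs from -0.25 s to +1.25 s relative to stimulus onset.
    """

    trials: np.ndarray  # (n_trials, n_time)
    rate_hz: float
    t_start_s: float = EPOCH_WINDOW_S[0]

    @property
    def times_s(self) -> np.ndarray:
        return self.t_start_s + np.arange(self.trials.shape[1]) / self.rate_hz


@dataclass
class SnrRecord:
    electrode: int
    week: int
    snr: float
    window: str | None = None
    material: str | None = None

    @property
    def useful(self) -> bool:
        return self.snr > USEFUL_SNR


def common_average_reference(raw: RawRecording) -> RawRecording:
    """Subtract the per-sample mean across electrodes from every channel.

    Removes any signal component shared by all electrodes (running and muscle
    artifacts); the channel-mean of the output is identically zero.  A single
    electrode is returned unchanged with a warning.
    """
    if raw.n_electrodes < 2:
        warnings.warn("single electrode: common average reference is a no-op", stacklevel=2)
        return raw
    car = raw.samples - raw.samples.mean(axis=0, keepdims=True)
    return RawRecording(
        samples=car,
        rate_hz=raw.rate_hz,
        onsets_s=raw.onsets_s,
        week=raw.week,
        material=raw.material,
        meta=dict(raw.meta),
    )


def mua_envelope(channel: np.ndarray, rate_hz: float, decimate: bool = True):
    """MUA envelope of one voltage trace.

    Zero-phase 3rd-order Butterworth band-pass 750-5000 Hz, full-wave
    rectification, zero-phase 200 Hz low-pass; optionally decimated to 1 kHz
    (the envelope holds no content above 200 Hz).

    Returns (envelope, envelope_rate_hz).
    """
    if rate_hz < 2 * MUA_BAND_HZ[1]:
        raise ValueError(f"sampling rate {rate_hz} Hz below 2x MUA band edge")
    x = np.asarray(channel, dtype=np.float64)
    sos_bp = sig.butter(FILTER_ORDER, MUA_BAND_HZ, btype="bandpass", fs=rate_hz, output="sos")
    sos_lp = sig.butter(FILTER_ORDER, MUA_LOWPASS_HZ, btype="lowpass", fs=rate_hz, output="sos")
    env = sig.sosfiltfilt(sos_lp, np.abs(sig.sosfiltfilt(sos_bp, x)))
    if decimate:
        step = int(round(rate_hz / ENVELOPE_RATE_HZ))
        if step > 1:
            return env[::step], rate_hz / step
    return env, rate_hz


def epoch_and_average(
    envelope: np.ndarray,
    rate_hz: float,
    onsets_s: np.ndarray,
    window_s: tuple[float, float] = EPOCH_WINDOW_S,
) -> tuple[TrialMatrix, np.ndarray]:
    """Slice the envelope into onset-aligned trials and average them.

    Trials whose window would run off either end of the recording are dropped
    with a warning carrying the count.  Returns the TrialMatrix and the
    trial-mean trace.
    """
    env = np.asarray(envelope, dtype=float)
    n = env.size
    w0 = int(round(window_s[0] * rate_hz))
    w1 = int(round(window_s[1] * rate_hz))
    rows = []
    dropped = 0
    for t in np.asarray(onsets_s, dtype=float):
        c = int(round(t * rate_hz))
        if c + w0 < 0 or c + w1 > n:
            dropped += 1
            continue
        rows.append(env[c + w0 : c + w1])
    if dropped:
        warnings.warn(f"dropped {dropped} truncated trial(s)", stacklevel=2)
    if not rows:
        raise ValueError("no complete trials in recording")
    trials = TrialMatrix(trials=np.vstack(rows), rate_hz=rate_hz, t_start_s=window_s[0])
    return trials, trials.trials.mean(axis=0)


def compute_snr(
    trials: TrialMatrix,
    electrode: int = 0,
    week: int = 0,
    material: str | None = None,
    smooth_sigma_s: float | None = SMOOTH_SIGMA_S,
) -> SnrRecord:
    """Evoked-response SNR of one electrode's trial matrix.

    noise    = SD over trials of the per-trial mean envelope in [-250, 0) ms
    baseline = mean of the (smoothed) trial-mean trace over the same window
    response = max over the three response windows of |trial-mean - baseline|
               (the window with the largest magnitude is reported)
    snr      = response / noise

    Zero noise (degenerate input) yields snr = inf with a warning; callers
    exclude such records.
    """
    x = trials.trials
    if x.shape[0] < 2:
        raise ValueError("need >= 2 trials for the across-trial noise SD")
    t = trials.times_s
    base = (t >= BASELINE_WINDOW_S[0]) & (t < BASELINE_WINDOW_S[1])
    if not base.any():
        raise ValueError("trial window does not cover the baseline")
    noise = float(x[:, base].mean(axis=1).std(ddof=1))
    mean_trace = x.mean(axis=0)
    if smooth_sigma_s:
        from scipy.ndimage import gaussian_filter1d

        mean_trace = gaussian_filter1d(mean_trace, smooth_sigma_s * trials.rate_hz)
    baseline = float(mean_trace[base].mean())
    best_resp, best_win = -np.inf, None
    for name, (lo, hi) in RESPONSE_WINDOWS_S.items():
        m = (t >= lo) & (t <= hi)
        if not m.any():
            continue
        resp = float(np.abs(mean_trace[m] - baseline).max())
        if resp > best_resp:
            best_resp, best_win = resp, name
    if best_win is None:
        raise ValueError("trial window covers none of the response windows")
    if noise <= 1e-9 * max(1e-300, float(np.abs(x).max())):
        warnings.warn("zero baseline noise: SNR undefined (inf)", stacklevel=2)
        snr = float("inf")
    else:
        snr = best_resp / noise
    return SnrRecord(electrode=electrode, week=week, snr=snr, window=best_win, material=material)


def snr_of_recording(raw: RawRecording, apply_car: bool = True) -> list[SnrRecord]:
    """Full per-electrode chain: CAR -> envelope -> epochs -> SNR."""
    rec = common_average_reference(raw) if apply_car and raw.n_electrodes > 1 else raw
    out = []
    for e in range(rec.n_electrodes):
        env, erate = mua_envelope(rec.samples[e], rec.rate_hz)
        trials, _ = epoch_and_average(env, erate, rec.onsets_s)
        out.append(compute_snr(trials, electrode=e, week=rec.week, material=rec.material))
    return out


def records_to_frame(records: list[SnrRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "electrode": [r.electrode for r in records],
            "week": [r.week for r in records],
            "material": [r.material for r in records],
            "snr": [r.snr for r in records],
            "useful": [r.useful for r in records],
            "window": [r.window for r in records],
        }
    )


def weekly_aggregate(records: pd.DataFrame, bin_weeks: int = 4) -> dict[str, pd.DataFrame]:
    """Weekly and binned summaries of per-electrode SNR records.

    Sessions within one electrode-week are averaged to a single SNR; the
    useful flag (SNR > 1) is evaluated on the weekly value.  Returns

    * ``weekly``   — one row per electrode-week (mean snr, useful flag)
    * ``fractions``— percentage of useful electrodes per material-week
    * ``binned``   — weekly rows labeled with consecutive 4-week time bins,
      the grouping used for between-material rank tests.
    """
    df = records[np.isfinite(records["snr"])].copy()
    weekly = (
        df.groupby(["material", "electrode", "week"], dropna=False, observed=True)["snr"]
        .mean()
        .reset_index()
    )
    weekly["useful"] = weekly["snr"] > USEFUL_SNR
    fractions = (
        weekly.groupby(["material", "week"], dropna=False, observed=True)["useful"]
        .mean()
        .mul(100.0)
        .rename("pct_useful")
        .reset_index()
    )
    week0 = int(weekly["week"].min()) if len(weekly) else 0
    binned = weekly.copy()
    binned["time_bin"] = (binned["week"] - week0) // bin_weeks
    return {"weekly": weekly, "fractions": fractions, "binned": binned}
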