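"""Synthetic histology sections and recordings with known ground truth.

Emulates the study material this pipeline quantifies: coronal sections of
mouse cortex stained for neurons (NeuN), reactive astrocytes (GFAP) and
microglia (IBA1), with and without an implanted probe shank, and chronic
multi-electrode recordings of visually evoked multi-unit activity.

The tissue model is deliberately statistical rather than photorealistic —
somata are blurred hard disks, astrocytic processes short random strokes,
microglia small blobs — because the downstream pipeline consumes only
binarized occupancy statistics.  Implanted sections add a vertical lesion
void scaled from the shank width, peri-track neuronal depletion, a GFAP depth
profile elevated at the pial entry point and at the cortex–white-matter
boundary (two Gaussian bumps of width 1/6 of the cortical depth on a uniform
pedestal), and an IBA1 elevation at that boundary.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, gaussian_filter

from .ephys import RawRecording
from .roi import CHANNELS, DEFAULT_PIXEL_SIZE_UM, SectionImage

#: approximate rendered area of one astrocytic stroke / microglial blob, px
_STROKE_LEN = 15
_STROKE_AREA = 34.0
_BLOB_AREA = 13.0
_FG_INTENSITY = 200.0
_TISSUE_BACKGROUND = 30.0  # diffuse staining inside intact tissue
_MAX_OCCUPANCY = 0.85


@dataclass
class TissueModelParams:
    """Geometry, staining densities and noise of a control section.

    Densities are somata per 100x100 px; occupancies are foreground-area
    fractions of the binarized channel.  Control occupancy levels are free
    parameters of the generator (no published reference values exist); the
    defaults approximate a neuron-dense cortex over astrocyte-rich white
    matter with a cell-sparse layer 1.
    """

    image_width_px: int = 900
    pia_row: int = 20
    wm_boundary_row: int = 1420
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    neuron_density_cortex: float = 8.0
    neuron_density_layer1: float = 1.0
    neuron_radius_px: int = 6
    layer1_depth_px: int = 210
    gfap_baseline: float = 0.08
    gfap_wm_level: float = 0.30
    iba1_baseline: float = 0.04
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_width_px <= 0:
            raise ValueError("non-positive image width")
        if not 0 <= self.pia_row < self.wm_boundary_row:
            raise ValueError("need 0 <= pia_row < wm_boundary_row")
        if min(self.neuron_density_cortex, self.neuron_density_layer1) < 0:
            raise ValueError("densities must be >= 0")
        if self.neuron_density_layer1 > self.neuron_density_cortex:
            raise ValueError("layer-1 density must not exceed cortical density")
        for name in ("gfap_baseline", "gfap_wm_level", "iba1_baseline"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def image_height_px(self) -> int:
        # room for the white-matter ROI plus a small margin below it
        return self.wm_boundary_row + 750


@dataclass
class LesionModelParams:
    """Strength of the tissue reaction rendered around one shank track."""

    shank_width_um: float = 70.0
    lesion_scale: float = 1.0  # void width = lesion_scale x shank width
    # peri-track kill zone; wider than the void half-width so that diffuse
    # neuronal loss is visible in the surviving tissue
    depletion_radius_um: float = 100.0
    gfap_entry_gain: float = 1.5
    gfap_wm_gain: float = 1.5
    gfap_uniform_gain: float = 0.3
    iba1_wm_gain: float = 1.5
    upper_loss_prob: float = 0.1  # chance of a through-lesion in upper cortex

    def __post_init__(self) -> None:
        for name in (
            "lesion_scale",
            "depletion_radius_um",
            "gfap_entry_gain",
            "gfap_wm_gain",
            "gfap_uniform_gain",
            "iba1_wm_gain",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.upper_loss_prob <= 1.0:
            raise ValueError("upper_loss_prob must lie in [0, 1]")


@dataclass
class GroundTruth:
    """What the generator actually drew, for recovery tests."""

    lesion_mask: np.ndarray
    neuron_centers: np.ndarray  # (n, 2) of (row, col)
    per_row_gfap_level: np.ndarray  # target occupancy per image row
    per_row_iba1_level: np.ndarray


def _stamp_disks(mask: np.ndarray, centers: np.ndarray, radius: int) -> None:
    """Set True disks of ``radius`` at integer ``centers`` (in place)."""
    if len(centers) == 0:
        return
    dy, dx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    keep = dy * dy + dx * dx <= radius * radius
    offs = np.stack([dy[keep], dx[keep]], axis=1)  # (k, 2)
    pts = centers[:, None, :] + offs[None, :, :]
    pts = pts.reshape(-1, 2)
    h, w = mask.shape
    ok = (pts[:, 0] >= 0) & (pts[:, 0] < h) & (pts[:, 1] >= 0) & (pts[:, 1] < w)
    pts = pts[ok]
    mask[pts[:, 0], pts[:, 1]] = True


def _stamp_strokes(mask: np.ndarray, rng: np.random.Generator, n: int, row_p: np.ndarray) -> None:
    """Draw ``n`` short random strokes with center rows sampled from ``row_p``."""
    if n <= 0 or row_p.sum() <= 0:
        return
    h, w = mask.shape
    rows = rng.choice(h, size=n, p=row_p / row_p.sum())
    cols = rng.uniform(0, w, size=n)
    theta = rng.uniform(0, np.pi, size=n)
    t = np.arange(_STROKE_LEN) - (_STROKE_LEN - 1) / 2.0
    rr = np.rint(rows[:, None] + np.sin(theta)[:, None] * t).astype(int)
    cc = np.rint(cols[:, None] + np.cos(theta)[:, None] * t).astype(int)
    ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    mask[rr[ok], cc[ok]] = True


def _lam(occ: np.ndarray) -> np.ndarray:
    """Poisson-coverage intensity achieving target occupancy under overlap."""
    return -np.log1p(-np.clip(occ, 0.0, _MAX_OCCUPANCY))


def _gfap_depth_gain(params: TissueModelParams, lesion: LesionModelParams | None, h: int) -> np.ndarray:
    """Per-row multiplicative gain of the astrocytic occupancy profile."""
    g = np.ones(h)
    if lesion is None:
        return g
    rows = np.arange(h, dtype=float)
    depth = params.wm_boundary_row - params.pia_row
    sigma = depth / 6.0
    g += lesion.gfap_uniform_gain
    g += lesion.gfap_entry_gain * np.exp(-0.5 * ((rows - params.pia_row) / sigma) ** 2)
    g += lesion.gfap_wm_gain * np.exp(-0.5 * ((rows - params.wm_boundary_row) / sigma) ** 2)
    return g


def _render(
    params: TissueModelParams,
    lesion: LesionModelParams | None,
    rng: np.random.Generator,
    render_channels: tuple[str, ...],
) -> tuple[SectionImage, GroundTruth]:
    h, w = params.image_height_px, params.image_width_px
    pia, wm = params.pia_row, params.wm_boundary_row
    l1 = min(pia + params.layer1_depth_px, wm)
    center = w // 2

    # --- lesion geometry -------------------------------------------------
    lesion_mask = np.zeros((h, w), dtype=bool)
    depletion_px = 0.0
    if lesion is not None:
        width_px = lesion.shank_width_um / params.pixel_size_um * lesion.lesion_scale
        if width_px > w:
            raise ValueError("lesion wider than the image")
        half = width_px / 2.0
        cols = np.arange(w)
        in_void = np.abs(cols - center) < half
        lesion_mask[pia:, :] |= in_void[None, :]
        if half > 0 and rng.random() < lesion.upper_loss_prob:
            # through-lesion: upper cortex void widened threefold
            wide = np.abs(cols - center) < 3.0 * half
            lesion_mask[pia : pia + 700, :] |= wide[None, :]
        depletion_px = lesion.depletion_radius_um / params.pixel_size_um

    # --- neurons ----------------------------------------------------------
    def _sample(density: float, r0: int, r1: int) -> np.ndarray:
        area = max(r1 - r0, 0) * w
        n = rng.poisson(density * area / 1e4)
        if n == 0:
            return np.empty((0, 2), dtype=int)
        rr = rng.integers(r0, r1, size=n)
        cc = rng.integers(0, w, size=n)
        return np.stack([rr, cc], axis=1)

    cand = np.concatenate(
        [
            _sample(params.neuron_density_layer1, pia, l1),
            _sample(params.neuron_density_cortex, l1, wm),
            _sample(params.neuron_density_cortex * 0.05, wm, h),  # sparse WM neurons
        ]
    )
    if len(cand):
        keep = ~lesion_mask[cand[:, 0], cand[:, 1]]
        if depletion_px > 0:
            keep &= ~(
                (np.abs(cand[:, 1] - center) < depletion_px)
                & (cand[:, 0] >= pia)
                & (cand[:, 0] < wm)
            )
        centers = cand[keep]
    else:
        centers = cand

    # --- per-row glial occupancy targets ---------------------------------
    rows = np.arange(h)
    gfap_base = np.where(rows < pia, 0.0, np.where(rows < wm, params.gfap_baseline, params.gfap_wm_level))
    gfap_occ = np.clip(gfap_base * _gfap_depth_gain(params, lesion, h), 0.0, _MAX_OCCUPANCY)
    iba1_gain = np.ones(h)
    if lesion is not None:
        depth = wm - pia
        sigma = depth / 6.0
        iba1_gain += lesion.iba1_wm_gain * np.exp(-0.5 * ((rows - wm) / sigma) ** 2)
    iba1_occ = np.clip(
        np.where(rows < pia, 0.0, params.iba1_baseline) * iba1_gain, 0.0, _MAX_OCCUPANCY
    )

    # --- channel rendering -------------------------------------------------
    tissue = np.zeros((h, w), dtype=bool)
    tissue[pia:, :] = True
    tissue &= ~lesion_mask
    channels: dict[str, np.ndarray] = {}
    for name in CHANNELS:
        if name not in render_channels:
            channels[name] = np.zeros((h, w), dtype=np.uint8)
            continue
        fg = np.zeros((h, w), dtype=bool)
        if name == "NeuN":
            _stamp_disks(fg, centers, params.neuron_radius_px)
        elif name == "GFAP":
            lam = _lam(gfap_occ)
            n = int(np.round(lam.sum() * w / _STROKE_AREA))
            _stamp_strokes(fg, rng, n, lam)
            fg = binary_dilation(fg, structure=np.ones((2, 2), dtype=bool))
        else:  # IBA1
            lam = _lam(iba1_occ)
            total = rng.poisson(lam.sum() * w / _BLOB_AREA)
            if total > 0 and lam.sum() > 0:
                rr = rng.choice(h, size=total, p=lam / lam.sum())
                cc = rng.integers(0, w, size=total)
                _stamp_disks(fg, np.stack([rr, cc], axis=1), 2)
        fg &= ~lesion_mask
        img = np.where(fg, _FG_INTENSITY, 0.0)
        img = gaussian_filter(img, sigma=1.0)
        img += np.where(tissue, _TISSUE_BACKGROUND, 0.0)
        img += rng.normal(0.0, params.noise_sd, size=(h, w))
        channels[name] = np.clip(img, 0, 255).astype(np.uint8)

    section = SectionImage(
        channels=channels,
        pixel_size_um=params.pixel_size_um,
        pia_row=pia,
        wm_boundary_row=wm,
        lesion_columns=[center] if lesion is not None else [],
    )
    truth = GroundTruth(
        lesion_mask=lesion_mask,
        neuron_centers=centers,
        per_row_gfap_level=gfap_occ,
        per_row_iba1_level=iba1_occ,
    )
    return section, truth


def generate_control_section(
    params: TissueModelParams,
    render_channels: tuple[str, ...] = CHANNELS,
) -> tuple[SectionImage, GroundTruth]:
    """Render a non-implanted section: the control condition.

    ``render_channels`` restricts rendering to a channel subset (the others
    stay blank) when only part of the pipeline is exercised.
    """
    rng = np.random.default_rng(params.seed)
    return _render(params, None, rng, render_channels)


def generate_implanted_section(
    params: TissueModelParams,
    lesion: LesionModelParams,
    render_channels: tuple[str, ...] = CHANNELS,
) -> tuple[SectionImage, GroundTruth]:
    """Render a section with one probe track at the image center column."""
    rng = np.random.default_rng(params.seed)
    return _render(params, lesion, rng, render_channels)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

MATERIALS = ("PI", "Si")
TETHERS = ("T", "U")
SHANK_WIDTHS_UM = (35.0, 70.0, 105.0)


def default_effect_map(row: pd.Series) -> LesionModelParams:
    """Map one probe-design row to lesion/reactivity parameters.

    Encodes the study's qualitative phenomenology: stiff silicon shanks lose
    more tissue, deplete neurons over a wider radius and drive a stronger,
    more uniform astrocytic reaction than flexible polyimide shanks; the void
    width scales with the shank width.
    """
    si = row["material"] == "Si"
    return LesionModelParams(
        shank_width_um=float(row["width_um"]),
        lesion_scale=1.2 if si else 0.7,
        depletion_radius_um=120.0 if si else 60.0,
        gfap_entry_gain=2.0 if si else 1.5,
        gfap_wm_gain=2.5 if si else 1.5,
        gfap_uniform_gain=1.0 if si else 0.2,
        iba1_wm_gain=1.5,
        upper_loss_prob=0.25 if si else 0.05,
    )


def generate_cohort(
    design_table: pd.DataFrame,
    params: TissueModelParams,
    seed: int,
    effect_map=default_effect_map,
    n_control: int = 5,
    render_channels: tuple[str, ...] = CHANNELS,
) -> tuple[list[dict], list[dict]]:
    """Generate one implanted section per design row plus control sections.

    ``design_table`` needs columns material (PI|Si), tether (T|U), width_um
    (35|70|105) and thickness_um.  Returns (implanted, controls): lists of
    dicts with the section, ground truth and design metadata.  The master
    seed fully determines the cohort.
    """
    rng = np.random.default_rng(seed)
    implanted = []
    for i, row in design_table.reset_index(drop=True).iterrows():
        if row["material"] not in MATERIALS:
            raise ValueError(f"unknown material {row['material']!r}")
        if row["tether"] not in TETHERS:
            raise ValueError(f"unknown tether {row['tether']!r}")
        if float(row["width_um"]) not in SHANK_WIDTHS_UM:
            raise ValueError(f"unknown shank width {row['width_um']!r}")
        child = int(rng.integers(0, 2**31 - 1))
        p = replace(params, seed=child)
        section, truth = generate_implanted_section(p, effect_map(row), render_channels)
        implanted.append(
            {
                "sample_id": f"shank{i:03d}",
                "section": section,
                "truth": truth,
                "material": row["material"],
                "tether": row["tether"],
                "width_um": float(row["width_um"]),
                "thickness_um": float(row["thickness_um"]),
                "group": f"{row['material']}-{row['tether']}",
            }
        )
    controls = []
    for i in range(n_control):
        child = int(rng.integers(0, 2**31 - 1))
        p = replace(params, seed=child)
        section, truth = generate_control_section(p, render_channels)
        controls.append({"sample_id": f"control{i:03d}", "section": section, "truth": truth})
    return implanted, controls


# ---------------------------------------------------------------------------
# electrophysiology
# ---------------------------------------------------------------------------


@dataclass
class EphysModelParams:
    """Synthetic visually evoked MUA recording model.

    Each 1-s checkerboard trial (pattern reversal at 500 ms, offset at 1 s)
    is followed by a 1-s inter-trial interval; band-limited evoked transients
    of amplitude ``evoked_amplitude x weekly_decay**week`` occur at
    ``evoked_latency_ms`` after the start of each configured response window.
    A shared-mode artifact (low-frequency sinusoid plus broadband bursts,
    identical on all electrodes) makes common-average referencing testable.
    """

    n_electrodes: int = 8
    sampling_rate_hz: float = 24000.0
    n_trials: int = 100
    stim_onset_s: float = 1.0  # first onset; trials repeat every 2 s
    evoked_amplitude: float = 10.0
    evoked_latency_ms: float = 60.0
    evoked_windows: tuple[str, ...] = ("onset", "reversal", "offset")
    weekly_decay: float = 0.95
    noise_sd: float = 3.0
    artifact_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz < 2 * 5000.0:
            raise ValueError("sampling rate below 2x the MUA band upper edge")
        if self.n_trials < 1:
            raise ValueError("need at least one trial")
        if not 0.0 < self.weekly_decay <= 1.0:
            raise ValueError("weekly_decay must lie in (0, 1]")
        bad = set(self.evoked_windows) - {"onset", "reversal", "offset"}
        if bad:
            raise ValueError(f"unknown evoked windows: {bad}")


_WINDOW_START_S = {"onset": 0.0, "reversal": 0.5, "offset": 1.0}
_CARRIER_HZ = 3000.0  # inside the 750-5000 Hz MUA band
_BURST_SIGMA_S = 0.015


def generate_mua_recording(params: EphysModelParams, week: int = 0) -> RawRecording:
    """Simulate one session of checkerboard trials at the given week.

    Per-electrode broadband Gaussian noise carries, at each stimulus event,
    a Gaussian-windowed 3 kHz transient whose peak amplitude decays
    multiplicatively per week of implantation.
    """
    if week < 0:
        raise ValueError("week must be >= 0")
    rng = np.random.default_rng(params.seed + 100003 * week)
    fs = params.sampling_rate_hz
    trial_period = 2.0
    duration = params.stim_onset_s + params.n_trials * trial_period + 0.5
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    onsets = params.stim_onset_s + trial_period * np.arange(params.n_trials)

    x = rng.normal(0.0, params.noise_sd, size=(params.n_electrodes, n))

    amp = params.evoked_amplitude * params.weekly_decay**week
    if amp > 0:
        # per-electrode carrier phase and small latency offset so that the
        # evoked MUA is local, not common-mode (CAR must not cancel it)
        phase = rng.uniform(0, 2 * np.pi, size=params.n_electrodes)
        lat_jitter = rng.uniform(-0.01, 0.01, size=params.n_electrodes)
        half = int(round(4 * _BURST_SIGMA_S * fs))
        tt = (np.arange(2 * half + 1) - half) / fs
        envelope = np.exp(-0.5 * (tt / _BURST_SIGMA_S) ** 2)
        for e in range(params.n_electrodes):
            burst = amp * envelope * np.sin(2 * np.pi * _CARRIER_HZ * tt + phase[e])
            lat = params.evoked_latency_ms / 1e3 + lat_jitter[e]
            for onset in onsets:
                for wname in params.evoked_windows:
                    c = int(round((onset + _WINDOW_START_S[wname] + lat) * fs))
                    lo, hi = c - half, c + half + 1
                    if lo >= 0 and hi <= n:
                        x[e, lo:hi] += burst

    if params.artifact_amplitude > 0:
        shared = params.artifact_amplitude * np.sin(2 * np.pi * 8.0 * t)
        n_bursts = max(2, int(duration / 2))  # frequent movement bursts
        for _ in range(n_bursts):
            c = int(rng.uniform(0.05, 0.95) * n)
            wlen = int(0.05 * fs)
            shared[c : c + wlen] += rng.normal(0.0, 3 * params.artifact_amplitude, size=min(wlen, n - c))
        x += shared[None, :]

    return RawRecording(
        samples=x.astype(np.float32),
        rate_hz=fs,
        onsets_s=onsets,
        week=week,
        meta={"amplitude": amp, "n_trials": params.n_trials},
    )
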