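"""Binarization, morphology filtering and occupancy downsampling of stain ROIs.

Each stained region of interest (ROI) is converted into a binary cell /
non-cell map with the moment-preserving ("Moments") automatic threshold,
cleaned with stain-specific connected-component filters, and summarised as an
11x10 grid of foreground-occupancy intensities (0-255).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import measure

from .roi import ROI_HEIGHT, ROI_WIDTH, RoiImage

#: grid geometry of the downsampled occupancy map: 11 bins across the 800-px
#: width, 10 bins across the 700-px depth
GRID_COLS = 11
GRID_ROWS = 10


@dataclass
class BinaryMap:
    """Binarized ROI; ``pixels`` is a (700, 800) boolean array, True = signal."""

    pixels: np.ndarray
    stain: str
    region: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.shape != (ROI_HEIGHT, ROI_WIDTH):
            raise ValueError(
                f"binary map must be {ROI_HEIGHT}x{ROI_WIDTH}, got {self.pixels.shape}"
            )


@dataclass
class StainFilterProfile:
    """Morphology criteria for one stain's connected-component mask filter.

    Any criterion left ``None`` is inactive.  Components (8-connectivity)
    failing an active criterion are removed wholesale; surviving pixels are
    untouched.
    """

    min_area_px: int | None = None
    max_area_px: int | None = None
    min_eccentricity: float | None = None
    max_eccentricity: float | None = None
    min_solidity: float | None = None

    def __post_init__(self) -> None:
        if (
            self.min_area_px is not None
            and self.max_area_px is not None
            and self.min_area_px > self.max_area_px
        ):
            raise ValueError("min_area_px > max_area_px")
        if (
            self.min_eccentricity is not None
            and self.max_eccentricity is not None
            and self.min_eccentricity > self.max_eccentricity
        ):
            raise ValueError("min_eccentricity > max_eccentricity")

    @property
    def active(self) -> bool:
        return any(
            v is not None
            for v in (
                self.min_area_px,
                self.max_area_px,
                self.min_eccentricity,
                self.max_eccentricity,
                self.min_solidity,
            )
        )


#: Default per-stain filters.  The stains have different morphologies —
#: compact neuron somata (NeuN), thin astrocytic filaments (GFAP), small
#: microglial blobs (IBA1) — so the cleanup criteria differ.  Numeric values
#: are free parameters of this pipeline (see docs/methods.md).
DEFAULT_PROFILES: dict[str, StainFilterProfile] = {
    "NeuN": StainFilterProfile(min_area_px=20, min_solidity=0.7),
    "GFAP": StainFilterProfile(min_area_px=5),
    "IBA1": StainFilterProfile(min_area_px=8),
}


@dataclass
class DownsampledMap:
    """11x10 occupancy summary of a binarized ROI.

    ``grid`` has shape (10, 11): rows index cortical depth, columns the
    horizontal extent.  Each cell holds 255 x (foreground fraction of its
    source area), i.e. values in [0, 255].
    """

    grid: np.ndarray
    region: str | None = None
    stain: str | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.shape != (GRID_ROWS, GRID_COLS):
            raise ValueError(
                f"grid must be {GRID_ROWS}x{GRID_COLS}, got {self.grid.shape}"
            )
        if self.grid.min() < -1e-9 or self.grid.max() > 255 + 1e-9:
            raise ValueError("grid values must lie in [0, 255]")


def moments_threshold(histogram: np.ndarray) -> int:
    """Moment-preserving (Tsai) threshold of a 256-bin intensity histogram.

    Finds the gray level ``t`` such that replacing the image by a two-level
    image (all pixels <= t set to one representative level, all pixels > t to
    another) preserves the first three moments of the input.  The closed-form
    solution yields the background fraction ``p0``; the threshold is the gray
    level at which the cumulative histogram first reaches that fraction (the
    cut bin itself is assigned to background).  Foreground = pixels > t.

    Parameters
    ----------
    histogram : array of 256 non-negative counts.

    Returns
    -------
    int threshold in [0, 255].
    """
    h = np.asarray(histogram, dtype=float)
    if h.shape != (256,):
        raise ValueError("histogram must have 256 bins")
    total = h.sum()
    if total <= 0:
        raise ValueError("histogram is empty")
    p = h / total
    z = np.arange(256, dtype=float)
    m1 = float(p @ z)
    m2 = float(p @ z**2)
    m3 = float(p @ z**3)
    cd = m2 - m1 * m1
    if cd <= 1e-12:
        # single-valued histogram: no separation exists
        level = int(np.flatnonzero(h)[0])
        warnings.warn(
            "degenerate single-valued histogram: threshold set to the sole "
            "gray level, all pixels background",
            stacklevel=2,
        )
        return level
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = c1 * c1 - 4.0 * c0
    disc = max(disc, 0.0)
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    p0 = (z1 - m1) / (z1 - z0)  # fraction of pixels below the cut
    csum = np.cumsum(p)
    # first gray level whose cumulative fraction reaches p0 (tolerance guards
    # exact two-level histograms where the cut coincides with a bin edge)
    idx = np.flatnonzero(csum >= p0 - 1e-9)
    return int(idx[0]) if idx.size else 255


def binarize(roi: RoiImage) -> BinaryMap:
    """Threshold one ROI with the Moments method of its own histogram."""
    pix = roi.pixels
    hist = np.bincount(pix.ravel(), minlength=256).astype(float)
    t = moments_threshold(hist)
    return BinaryMap(pixels=pix > t, stain=roi.channel, region=roi.region)


def filter_mask(mask: BinaryMap, profile: StainFilterProfile) -> BinaryMap:
    """Remove connected components that fail the stain's morphology criteria.

    Components are 8-connected.  An empty profile is the identity.
    """
    if not profile.active:
        return BinaryMap(pixels=mask.pixels.copy(), stain=mask.stain, region=mask.region)
    labels = measure.label(mask.pixels, connectivity=2)
    n = labels.max()
    if n == 0:
        return BinaryMap(pixels=mask.pixels.copy(), stain=mask.stain, region=mask.region)
    keep = np.ones(n + 1, dtype=bool)
    keep[0] = False
    need_shape = (
        profile.min_eccentricity is not None
        or profile.max_eccentricity is not None
        or profile.min_solidity is not None
    )
    if need_shape:
        for rp in measure.regionprops(labels):
            ok = True
            if profile.min_area_px is not None and rp.area < profile.min_area_px:
                ok = False
            if ok and profile.max_area_px is not None and rp.area > profile.max_area_px:
                ok = False
            if ok and profile.min_eccentricity is not None and rp.eccentricity < profile.min_eccentricity:
                ok = False
            if ok and profile.max_eccentricity is not None and rp.eccentricity > profile.max_eccentricity:
                ok = False
            if ok and profile.min_solidity is not None and rp.solidity < profile.min_solidity:
                ok = False
            keep[rp.label] = ok
    else:
        areas = np.bincount(labels.ravel(), minlength=n + 1)
        if profile.min_area_px is not None:
            keep &= areas >= profile.min_area_px
        if profile.max_area_px is not None:
            keep &= areas <= profile.max_area_px
        keep[0] = False
    return BinaryMap(pixels=keep[labels], stain=mask.stain, region=mask.region)


def _bin_weights(n_src: int, n_bins: int) -> np.ndarray:
    """Exact area-overlap weights partitioning ``n_src`` pixels into ``n_bins``.

    Returns a (n_bins, n_src) matrix whose row b gives the fraction of each
    source pixel covered by bin b; bin edges are at multiples of
    n_src / n_bins and need not be integral.
    """
    edges = np.linspace(0.0, n_src, n_bins + 1)
    w = np.zeros((n_bins, n_src))
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        first = int(np.floor(lo))
        last = int(np.ceil(hi))
        for c in range(first, min(last, n_src)):
            w[b, c] = min(hi, c + 1) - max(lo, c)
    return w


_ROW_W = _bin_weights(ROI_HEIGHT, GRID_ROWS)  # (10, 700)
_COL_W = _bin_weights(ROI_WIDTH, GRID_COLS)  # (11, 800)
_BIN_AREA = (ROI_HEIGHT / GRID_ROWS) * (ROI_WIDTH / GRID_COLS)


def downsample(mask: BinaryMap | np.ndarray) -> DownsampledMap:
    """Reduce a 700x800 binary map to the 11x10 occupancy grid.

    Each cell is 255 times the exact area-weighted foreground fraction of its
    source bin (800/11-px-wide by 70-px-tall); total foreground area is
    conserved: ``grid.sum() * bin_area / 255`` equals the foreground pixel
    count up to floating-point rounding.
    """
    if isinstance(mask, BinaryMap):
        pix = mask.pixels.astype(float)
        region, stain = mask.region, mask.stain
    else:
        pix = np.asarray(mask, dtype=float)
        region = stain = None
    if pix.shape != (ROI_HEIGHT, ROI_WIDTH):
        raise ValueError(f"expected {ROI_HEIGHT}x{ROI_WIDTH} input, got {pix.shape}")
    grid = 255.0 * (_ROW_W @ pix @ _COL_W.T) / _BIN_AREA
    return DownsampledMap(grid=np.clip(grid, 0.0, 255.0), region=region, stain=stain)


def segment_roi(roi: RoiImage, profile: StainFilterProfile | None = None) -> DownsampledMap:
    """Full per-ROI chain: Moments binarization -> mask filter -> 11x10 grid."""
    if profile is None:
        profile = DEFAULT_PROFILES.get(roi.channel, StainFilterProfile())
    return downsample(filter_mask(binarize(roi), profile))
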