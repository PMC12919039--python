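"""Tissue vs non-tissue classification and the normalized tissue-loss measure.

The NeuN and GFAP channels of a shank ROI are summed into a total tissue
signal, squared (emphasising true tissue over background), thresholded at 50
on the squared scale, and inverted so that lost tissue carries high intensity.
The inverted binary is downsampled to the 11x10 grid; each cell then reads
255 x (fraction of lost tissue).  ΔTissueLoss is the cell-wise difference to
the control average: higher values mean more tissue loss than control cortex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .roi import ROI_HEIGHT, ROI_WIDTH, RoiImage
from .segmentation import DownsampledMap, downsample

#: threshold on the squared (NeuN + GFAP) signal below which a pixel is non-tissue
TISSUE_THRESHOLD = 50


@dataclass
class TissueLossMap:
    """11x10 grid where high intensity marks tissue LOSS."""

    grid: np.ndarray
    region: str | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.min() < -1e-9 or self.grid.max() > 255 + 1e-9:
            raise ValueError("tissue-loss values must lie in [0, 255]")


def combined_tissue_signal(neun_roi: RoiImage, gfap_roi: RoiImage) -> np.ndarray:
    """Per-pixel squared sum of the NeuN and GFAP intensities.

    Computed in a widened integer range (the maximum, 510**2 = 260100, far
    exceeds 8 bit).  Returns an int64 (700, 800) array.
    """
    a = neun_roi.pixels.astype(np.int64)
    b = gfap_roi.pixels.astype(np.int64)
    if a.shape != b.shape:
        raise ValueError("NeuN and GFAP ROIs must have the same shape")
    s = a + b
    return s * s


def tissue_loss_map(combined: np.ndarray, region: str | None = None) -> TissueLossMap:
    """Binarize the squared tissue signal and summarize loss on the 11x10 grid.

    A pixel is non-tissue iff its squared signal is strictly below 50.  The
    inverted binary (non-tissue -> foreground) is downsampled so each cell
    equals 255 x (lost-tissue fraction of that cell).
    """
    combined = np.asarray(combined)
    if combined.shape != (ROI_HEIGHT, ROI_WIDTH):
        raise ValueError(f"expected {ROI_HEIGHT}x{ROI_WIDTH} input, got {combined.shape}")
    lost = combined < TISSUE_THRESHOLD
    ds = downsample(lost)
    return TissueLossMap(grid=ds.grid, region=region)


def delta_tissue_loss(
    experimental: TissueLossMap, control: TissueLossMap
) -> tuple[float, np.ndarray]:
    """Cell-wise experimental minus control loss, and its mean over cells.

    Higher values imply more tissue loss than control cortex.
    """
    if experimental.region != control.region:
        raise ValueError(
            f"region mismatch: {experimental.region!r} vs {control.region!r}"
        )
    diff = experimental.grid - control.grid
    return float(diff.mean()), diff


def control_mean_loss(controls: list[TissueLossMap]) -> TissueLossMap:
    """Cell-wise mean tissue-loss map over all control sections of a region."""
    if not controls:
        raise ValueError("no control maps")
    regions = {c.region for c in controls}
    if len(regions) != 1:
        raise ValueError(f"controls span several regions: {regions}")
    grid = np.mean([c.grid for c in controls], axis=0)
    return TissueLossMap(grid=grid, region=controls[0].region)


def loss_from_rois(neun_roi: RoiImage, gfap_roi: RoiImage) -> TissueLossMap:
    """Convenience chain: combined signal -> squared threshold -> loss grid."""
    return tissue_loss_map(combined_tissue_signal(neun_roi, gfap_roi), region=neun_roi.region)


def _as_map(x: TissueLossMap | DownsampledMap) -> np.ndarray:
    return x.grid if hasattr(x, "grid") else np.asarray(x)
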