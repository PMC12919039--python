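"""Δ-signal maps, exclusion rules, depth profiles and the tissue-reaction index.

For every stain and depth region the implanted-section occupancy grid is
compared to the mean of the control sections by subtraction (ΔNeuN, ΔGFAP,
ΔIBA1).  Grid cells with more than 75% tissue loss (loss intensity > 190) are
excluded from the experimental maps, and for NeuN in the upper cortex the
first 3 of the 10 depth rows (cortical layer 1, which holds few neurons) are
excluded in both conditions.

The overall tissue reaction of a sample combines neuronal loss and astrocytic
reactivity::

    Idx_TissueReaction = (|min(dNeuN, 0)| + max(dGFAP, 0)) / 510

Positive dNeuN (more neurons than control) and negative dGFAP (less
astrocytic signal) reflect biological variation rather than a reaction and
are zeroed before the addition; with both channels spanning 0-255 the index
ranges from 0 (no reaction) to 1 (complete neuronal loss plus maximal
astrocytic response).  Microglia (dIBA1) are quantified but do not enter the
index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmentation import GRID_COLS, GRID_ROWS, DownsampledMap
from .tissue_loss import TissueLossMap

#: tissue-loss intensity above which a grid cell is excluded (75% of 255)
LOSS_EXCLUSION_THRESHOLD = 190

#: depth rows of the upper-cortex grid treated as cortical layer 1 for NeuN
LAYER1_ROWS = 3

#: normalization of the tissue-reaction index: both channels span 0-255
IDX_DENOMINATOR = 510.0


@dataclass
class DeltaMap:
    """Signed experimental-minus-control grid with an exclusion mask.

    ``grid`` is (10, 11) in [-255, 255]; ``excluded`` marks cells that carry
    no value (total tissue loss, or layer 1 for upper-cortex NeuN).
    """

    grid: np.ndarray
    stain: str
    region: str
    excluded: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.shape != (GRID_ROWS, GRID_COLS):
            raise ValueError(f"delta grid must be {GRID_ROWS}x{GRID_COLS}")
        if np.abs(self.grid).max() > 255 + 1e-9:
            raise ValueError("delta values must lie in [-255, 255]")
        if self.excluded is None:
            self.excluded = np.zeros_like(self.grid, dtype=bool)
        else:
            self.excluded = np.asarray(self.excluded, dtype=bool)
            if self.excluded.shape != self.grid.shape:
                raise ValueError("exclusion mask shape mismatch")


def control_mean_map(
    controls: list[DownsampledMap], stain: str | None = None, region: str | None = None
) -> DownsampledMap:
    """Cell-wise arithmetic mean over the control sections of one stain/region."""
    if not controls:
        raise ValueError("no control maps")
    grid = np.mean([c.grid for c in controls], axis=0)
    return DownsampledMap(
        grid=grid,
        stain=stain if stain is not None else controls[0].stain,
        region=region if region is not None else controls[0].region,
    )


def delta_map(
    exp: DownsampledMap,
    control_mean: DownsampledMap,
    loss: TissueLossMap | None = None,
) -> DeltaMap:
    """Cell-wise experimental minus control, excluding cells of >75% tissue loss.

    Cells whose tissue-loss intensity strictly exceeds 190 are marked excluded
    and never enter any mean (190 itself is kept).
    """
    if exp.region != control_mean.region:
        raise ValueError(f"region mismatch: {exp.region!r} vs {control_mean.region!r}")
    if loss is not None and loss.region not in (None, exp.region):
        raise ValueError(f"loss-map region {loss.region!r} differs from {exp.region!r}")
    grid = exp.grid - control_mean.grid
    excluded = np.zeros(grid.shape, dtype=bool)
    if loss is not None:
        excluded |= loss.grid > LOSS_EXCLUSION_THRESHOLD
    return DeltaMap(grid=grid, stain=exp.stain or "", region=exp.region or "", excluded=excluded)


def strip_layer1(neun_delta: DeltaMap) -> DeltaMap:
    """Exclude the top 3 depth rows (layer 1) of an upper-cortex NeuN map.

    Idempotent; refuses other regions or stains.
    """
    if neun_delta.region != "upper_cortex":
        raise ValueError("layer-1 stripping applies only to the upper cortex")
    if neun_delta.stain != "NeuN":
        raise ValueError("layer-1 stripping applies only to NeuN")
    excluded = neun_delta.excluded.copy()
    excluded[:LAYER1_ROWS, :] = True
    return DeltaMap(
        grid=neun_delta.grid.copy(),
        stain=neun_delta.stain,
        region=neun_delta.region,
        excluded=excluded,
    )


def roi_mean_delta(dmap: DeltaMap) -> float:
    """Mean over non-excluded cells; NaN when every cell is excluded."""
    valid = ~dmap.excluded
    if not valid.any():
        return float("nan")
    return float(dmap.grid[valid].mean())


def tissue_reaction_index(d_neun, d_gfap) -> float | np.ndarray:
    """Tissue-reaction index from the NeuN and GFAP delta signals.

    Accepts scalars (the normative per-sample form, computed from the two
    region-mean deltas) or same-shape arrays (cell-wise variant).  Positive
    dNeuN and negative dGFAP are set to zero before the channel addition;
    the sum of absolute neuronal loss and astrocytic gain is divided by 510.
    """
    dn = np.asarray(d_neun, dtype=float)
    dg = np.asarray(d_gfap, dtype=float)
    if np.any(np.abs(dn) > 255 + 1e-9) or np.any(np.abs(dg) > 255 + 1e-9):
        raise ValueError("delta signals must lie in [-255, 255]")
    idx = (np.abs(np.minimum(dn, 0.0)) + np.maximum(dg, 0.0)) / IDX_DENOMINATOR
    if idx.ndim == 0:
        return float(idx)
    return idx


def depth_profile(dmap: DeltaMap) -> np.ndarray:
    """Per-depth-row mean over non-excluded cells (length-10 vector).

    Rows with every cell excluded yield NaN.
    """
    grid = np.where(dmap.excluded, np.nan, dmap.grid)
    with np.errstate(invalid="ignore"):
        return np.nanmean(grid, axis=1)


def half_means(dmap: DeltaMap) -> tuple[float, float]:
    """Mean delta of the top (rows 0-4) and bottom (rows 5-9) half of the grid."""
    grid = np.where(dmap.excluded, np.nan, dmap.grid)
    half = GRID_ROWS // 2
    with np.errstate(invalid="ignore"):
        top = float(np.nanmean(grid[:half]))
        bottom = float(np.nanmean(grid[half:]))
    return top, bottom


@dataclass
class DeltaSummary:
    """Per-sample (shank x region) scalar summary — the statistics input row."""

    sample_id: str
    region: str
    delta_neun: float
    delta_gfap: float
    delta_iba1: float
    delta_tissue_loss: float
    idx_tissue_reaction: float
    material: str | None = None
    tether: str | None = None
    shank_width_um: float | None = None
    thickness_um: float | None = None
    duration_months: float | None = None

    @property
    def cross_section_um2(self) -> float | None:
        if self.shank_width_um is None or self.thickness_um is None:
            return None
        return self.shank_width_um * self.thickness_um

    def to_dict(self) -> dict:
        d = {
            "sample_id": self.sample_id,
            "region": self.region,
            "delta_neun": self.delta_neun,
            "delta_gfap": self.delta_gfap,
            "delta_iba1": self.delta_iba1,
            "delta_tissue_loss": self.delta_tissue_loss,
            "idx_tissue_reaction": self.idx_tissue_reaction,
            "material": self.material,
            "tether": self.tether,
            "width_um": self.shank_width_um,
            "thickness_um": self.thickness_um,
            "cross_section_um2": self.cross_section_um2,
            "duration_months": self.duration_months,
        }
        return d


def summaries_to_frame(summaries: list[DeltaSummary]) -> pd.DataFrame:
    """Tidy DataFrame of per-shank, per-region delta summaries."""
    return pd.DataFrame([s.to_dict() for s in summaries])
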