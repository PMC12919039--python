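"""End-to-end quantification: sections in, tidy delta-summary tables out.

Chains the per-module operations — shank cropping, depth-ROI extraction,
Moments binarization, mask filtering, 11x10 downsampling, tissue-loss
mapping, Δ-signal computation and the tissue-reaction index — over a cohort
of implanted sections and its control sections.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .reaction import (
    DeltaMap,
    DeltaSummary,
    control_mean_map,
    delta_map,
    roi_mean_delta,
    strip_layer1,
    summaries_to_frame,
    tissue_reaction_index,
)
from .roi import CHANNELS, REGIONS, SectionImage, ShankImage, crop_shank, extract_rois
from .segmentation import DEFAULT_PROFILES, DownsampledMap, segment_roi
from .tissue_loss import TissueLossMap, control_mean_loss, delta_tissue_loss, loss_from_rois


def section_to_shank(
    section: SectionImage,
    lesion_col: int | None = None,
    shank_width_um: float | None = None,
) -> ShankImage:
    """Crop a section around one track center (image center for controls)."""
    if lesion_col is None:
        if section.lesion_columns:
            lesion_col = section.lesion_columns[0]
        else:
            lesion_col = section.shape[1] // 2
    return crop_shank(section, lesion_col, shank_width_um)


def shank_stain_maps(
    shank: ShankImage,
    stains: tuple[str, ...] = CHANNELS,
    profiles: dict | None = None,
) -> dict[tuple[str, str], DownsampledMap]:
    """Occupancy grid per (region, stain) of one shank image."""
    if profiles is None:
        profiles = DEFAULT_PROFILES
    out: dict[tuple[str, str], DownsampledMap] = {}
    for stain in stains:
        rois = extract_rois(shank, stain)
        for region in REGIONS:
            roi = rois[region]
            if roi is None:
                continue
            out[(region, stain)] = segment_roi(roi, profiles.get(stain))
    return out


def shank_loss_maps(shank: ShankImage) -> dict[str, TissueLossMap]:
    """Tissue-loss grid per region (needs the NeuN and GFAP channels)."""
    neun = extract_rois(shank, "NeuN")
    gfap = extract_rois(shank, "GFAP")
    out: dict[str, TissueLossMap] = {}
    for region in REGIONS:
        if neun[region] is None:
            continue
        out[region] = loss_from_rois(neun[region], gfap[region])
    return out


def control_reference(
    control_sections: list[SectionImage],
    stains: tuple[str, ...] = CHANNELS,
    profiles: dict | None = None,
    with_loss: bool = True,
) -> tuple[dict[tuple[str, str], DownsampledMap], dict[str, TissueLossMap]]:
    """Cell-wise mean occupancy and tissue-loss grids over all controls."""
    if not control_sections:
        raise ValueError("no control sections")
    per_key: dict[tuple[str, str], list[DownsampledMap]] = {}
    per_loss: dict[str, list[TissueLossMap]] = {}
    for sec in control_sections:
        shank = section_to_shank(sec)
        for key, m in shank_stain_maps(shank, stains, profiles).items():
            per_key.setdefault(key, []).append(m)
        if with_loss:
            for region, m in shank_loss_maps(shank).items():
                per_loss.setdefault(region, []).append(m)
    mean_maps = {k: control_mean_map(v) for k, v in per_key.items()}
    mean_loss = {r: control_mean_loss(v) for r, v in per_loss.items()}
    return mean_maps, mean_loss


def shank_delta_maps(
    shank: ShankImage,
    ref_maps: dict[tuple[str, str], DownsampledMap],
    ref_loss: dict[str, TissueLossMap] | None = None,
    stains: tuple[str, ...] = CHANNELS,
    profiles: dict | None = None,
) -> tuple[dict[tuple[str, str], DeltaMap], dict[str, tuple[float, np.ndarray]]]:
    """Per-(region, stain) Δ maps and per-region ΔTissueLoss of one shank.

    Cells with >75% tissue loss are excluded from the Δ maps (when the loss
    reference is available), and layer 1 is stripped from upper-cortex NeuN.
    """
    exp_maps = shank_stain_maps(shank, stains, profiles)
    with_loss = ref_loss is not None and {"NeuN", "GFAP"} <= set(shank.channels)
    exp_loss = shank_loss_maps(shank) if with_loss else {}
    deltas: dict[tuple[str, str], DeltaMap] = {}
    dtl: dict[str, tuple[float, np.ndarray]] = {}
    for (region, stain), m in exp_maps.items():
        if (region, stain) not in ref_maps:
            continue
        loss = exp_loss.get(region) if with_loss else None
        d = delta_map(m, ref_maps[(region, stain)], loss)
        if stain == "NeuN" and region == "upper_cortex":
            d = strip_layer1(d)
        deltas[(region, stain)] = d
    if with_loss:
        for region, m in exp_loss.items():
            if region in ref_loss:
                dtl[region] = delta_tissue_loss(m, ref_loss[region])
    return deltas, dtl


def summarize_shank(
    deltas: dict[tuple[str, str], DeltaMap],
    dtl: dict[str, tuple[float, np.ndarray]],
    sample_id: str,
    **design,
) -> list[DeltaSummary]:
    """One DeltaSummary row per region present in the Δ maps."""
    regions = sorted({r for r, _ in deltas}, key=REGIONS.index)
    rows = []
    for region in regions:
        means = {}
        for stain in CHANNELS:
            d = deltas.get((region, stain))
            means[stain] = roi_mean_delta(d) if d is not None else float("nan")
        dn, dg = means["NeuN"], means["GFAP"]
        if np.isnan(dn) or np.isnan(dg):
            idx = float("nan")
        else:
            idx = tissue_reaction_index(np.clip(dn, -255, 255), np.clip(dg, -255, 255))
        rows.append(
            DeltaSummary(
                sample_id=sample_id,
                region=region,
                delta_neun=dn,
                delta_gfap=dg,
                delta_iba1=means["IBA1"],
                delta_tissue_loss=dtl.get(region, (float("nan"), None))[0],
                idx_tissue_reaction=idx,
                material=design.get("material"),
                tether=design.get("tether"),
                shank_width_um=design.get("width_um"),
                thickness_um=design.get("thickness_um"),
                duration_months=design.get("duration_months"),
            )
        )
    return rows


def analyze_cohort(
    implanted: list[dict],
    controls: list[dict],
    stains: tuple[str, ...] = CHANNELS,
    profiles: dict | None = None,
) -> pd.DataFrame:
    """Quantify a full synthetic (or loaded) cohort into a tidy table.

    ``implanted`` and ``controls`` are lists of dicts holding at least a
    ``section`` (SectionImage) and, for implanted entries, design metadata
    (sample_id, material, tether, width_um, thickness_um).  Returns one row
    per shank x region with Δ signals, ΔTissueLoss and the reaction index.
    """
    with_loss = {"NeuN", "GFAP"} <= set(stains)
    ref_maps, ref_loss = control_reference(
        [c["section"] for c in controls], stains, profiles, with_loss=with_loss
    )
    rows: list[DeltaSummary] = []
    for entry in implanted:
        shank = section_to_shank(entry["section"], shank_width_um=entry.get("width_um"))
        deltas, dtl = shank_delta_maps(
            shank, ref_maps, ref_loss if with_loss else None, stains, profiles
        )
        rows.extend(
            summarize_shank(
                deltas,
                dtl,
                sample_id=entry.get("sample_id", "sample"),
                material=entry.get("material"),
                tether=entry.get("tether"),
                width_um=entry.get("width_um"),
                thickness_um=entry.get("thickness_um"),
                duration_months=entry.get("duration_months"),
            )
        )
    return summaries_to_frame(rows)
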