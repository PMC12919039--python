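"""Reading and writing the pipeline's on-disk formats.

Sections travel as multi-page TIFF (one page per channel, order NeuN, GFAP,
IBA1) with a JSON sidecar holding pixel size, anatomical anchors and, for
synthetic data, the ground truth; cohorts get a CSV manifest.  Recordings are
flat binary float32 (channel-major) with a JSON header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .ephys import RawRecording
from .roi import CHANNELS, SectionImage
from .synthetic import GroundTruth


def write_section(path: str | Path, section: SectionImage, truth: GroundTruth | None = None) -> Path:
    """Write one section as multi-page TIFF + JSON sidecar; returns the TIFF path."""
    path = Path(path).with_suffix(".tif")
    stack = np.stack([section.channels[c] for c in CHANNELS])
    tifffile.imwrite(path, stack)
    meta = {
        "channels": list(CHANNELS),
        "pixel_size_um": section.pixel_size_um,
        "pia_row": int(section.pia_row),
        "wm_boundary_row": int(section.wm_boundary_row),
        "lesion_columns": [int(c) for c in section.lesion_columns],
        "has_white_matter": bool(section.has_white_matter),
    }
    if truth is not None:
        meta["ground_truth"] = {
            "neuron_centers": np.asarray(truth.neuron_centers).tolist(),
            "per_row_gfap_level": np.asarray(truth.per_row_gfap_level).tolist(),
            "per_row_iba1_level": np.asarray(truth.per_row_iba1_level).tolist(),
            "lesion_columns_any": bool(truth.lesion_mask.any()),
        }
    path.with_suffix(".json").write_text(json.dumps(meta))
    return path


def read_section(path: str | Path) -> SectionImage:
    """Read a section TIFF and its JSON sidecar (or a CSV annotation row)."""
    path = Path(path)
    stack = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    channels = {c: stack[i] for i, c in enumerate(meta.get("channels", CHANNELS))}
    return SectionImage(
        channels=channels,
        pixel_size_um=float(meta["pixel_size_um"]),
        pia_row=int(meta["pia_row"]),
        wm_boundary_row=int(meta["wm_boundary_row"]),
        lesion_columns=[int(c) for c in meta.get("lesion_columns", [])],
        has_white_matter=bool(meta.get("has_white_matter", True)),
    )


def write_cohort(
    out_dir: str | Path, implanted: list[dict], controls: list[dict]
) -> Path:
    """Write a generated cohort plus a CSV manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for entry in implanted:
        p = write_section(out_dir / entry["sample_id"], entry["section"], entry.get("truth"))
        rows.append(
            {
                "file": p.name,
                "material": entry.get("material"),
                "tether": entry.get("tether"),
                "width_um": entry.get("width_um"),
                "thickness_um": entry.get("thickness_um"),
                "group": entry.get("group", "experimental"),
            }
        )
    for entry in controls:
        p = write_section(out_dir / entry["sample_id"], entry["section"], entry.get("truth"))
        rows.append(
            {
                "file": p.name,
                "material": None,
                "tether": None,
                "width_um": None,
                "thickness_um": None,
                "group": "control",
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest: str | Path) -> tuple[list[dict], list[dict]]:
    """Load a cohort from its manifest into implanted/control entry lists."""
    manifest = Path(manifest)
    df = pd.read_csv(manifest)
    implanted, controls = [], []
    for _, row in df.iterrows():
        section = read_section(manifest.parent / row["file"])
        entry = {
            "sample_id": Path(row["file"]).stem,
            "section": section,
            "material": row["material"] if pd.notna(row["material"]) else None,
            "tether": row["tether"] if pd.notna(row["tether"]) else None,
            "width_um": float(row["width_um"]) if pd.notna(row["width_um"]) else None,
            "thickness_um": float(row["thickness_um"]) if pd.notna(row["thickness_um"]) else None,
        }
        (controls if row["group"] == "control" else implanted).append(entry)
    return implanted, controls


def write_recording(path: str | Path, rec: RawRecording) -> Path:
    """Write a recording as float32 channel-major binary + JSON header."""
    path = Path(path).with_suffix(".bin")
    rec.samples.astype(np.float32).tofile(path)
    header = {
        "rate_hz": rec.rate_hz,
        "n_channels": int(rec.n_electrodes),
        "onsets_s": [float(t) for t in rec.onsets_s],
        "week": int(rec.week),
        "material": rec.material,
    }
    path.with_suffix(".json").write_text(json.dumps(header))
    return path


def read_recording(path: str | Path) -> RawRecording:
    path = Path(path)
    header = json.loads(path.with_suffix(".json").read_text())
    data = np.fromfile(path, dtype=np.float32).reshape(header["n_channels"], -1)
    return RawRecording(
        samples=data,
        rate_hz=float(header["rate_hz"]),
        onsets_s=np.asarray(header["onsets_s"], dtype=float),
        week=int(header.get("week", 0)),
        material=header.get("material"),
    )
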