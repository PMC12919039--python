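"""Section orientation, per-shank cropping and depth-ROI extraction.

Coordinate convention: row 0 is the top of the image at the pial surface and
rows increase with cortical depth; columns are 0-based; all crops are
half-open intervals.  Three anatomically anchored regions of interest are cut
from every shank image, each 800 px wide by 700 px deep:

* ``upper_cortex``  — rows [pia_row, pia_row + 700)
* ``lower_cortex``  — rows [wm_boundary_row - 700, wm_boundary_row)
* ``white_matter``  — rows [wm_boundary_row, wm_boundary_row + 700)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

ROI_WIDTH = 800  # px, horizontal extent of every ROI and shank crop
ROI_HEIGHT = 700  # px, depth extent of every ROI

CHANNELS = ("NeuN", "GFAP", "IBA1")
REGIONS = ("upper_cortex", "lower_cortex", "white_matter")

#: default isotropic pixel size; used only for reporting, all geometry is in px
DEFAULT_PIXEL_SIZE_UM = 0.576


@dataclass
class SectionImage:
    """Registered 3-channel 8-bit image of one brain section.

    ``channels`` maps stain name -> (H, W) uint8 array.  ``lesion_columns``
    are the column indices of the shank-track centers, left to right.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    pia_row: int
    wm_boundary_row: int
    lesion_columns: list[int] = field(default_factory=list)
    has_white_matter: bool = True

    def __post_init__(self) -> None:
        shapes = {c: np.asarray(a).shape for c, a in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        h, w = next(iter(shapes.values()))
        if h <= 0 or w <= 0:
            raise ValueError("non-positive image dimensions")
        if not (0 <= self.pia_row < self.wm_boundary_row < h):
            raise ValueError(
                f"need 0 <= pia_row < wm_boundary_row < height, got "
                f"pia={self.pia_row}, wm={self.wm_boundary_row}, h={h}"
            )
        for c, a in self.channels.items():
            self.channels[c] = np.asarray(a, dtype=np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class ShankImage:
    """800-px-wide crop of one shank track, from the pia to 700 px below the
    cortex–white-matter boundary, in local coordinates (pia_row == 0)."""

    channels: dict[str, np.ndarray]
    shank_width_um: float | None
    pia_row: int
    wm_boundary_row: int
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    padded: bool = False
    has_white_matter: bool = True

    def __post_init__(self) -> None:
        for c, a in self.channels.items():
            a = np.asarray(a, dtype=np.uint8)
            if a.shape[1] != ROI_WIDTH:
                raise ValueError(f"shank image must be {ROI_WIDTH} px wide")
            self.channels[c] = a
        h = self.height
        if self.wm_boundary_row + ROI_HEIGHT > h:
            raise ValueError("shank image too short below the white-matter boundary")

    @property
    def height(self) -> int:
        return next(iter(self.channels.values())).shape[0]


@dataclass
class RoiImage:
    """One 800x700 single-channel crop; ``pixels`` shape is (700, 800)."""

    pixels: np.ndarray
    region: str
    channel: str
    overlap_rows: tuple[int, int] | None = None  # rows shared with the other cortical ROI

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.shape != (ROI_HEIGHT, ROI_WIDTH):
            raise ValueError(
                f"ROI must be {ROI_HEIGHT}x{ROI_WIDTH} (rows x cols), got {self.pixels.shape}"
            )
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")


def orient_section(
    section: SectionImage,
    shank_widths_um: list[float],
    *,
    force: bool = False,
) -> SectionImage:
    """Mirror the section so the narrowest (35 um) shank track is leftmost.

    ``shank_widths_um`` gives the shank widths in the current left-to-right
    order of ``lesion_columns``.  If the narrowest shank already sits on the
    left (or there is a single shank) the section is returned unchanged;
    if it is rightmost, image and lesion columns are flipped horizontally.
    An ambiguous order (all widths equal, several shanks) is refused unless
    ``force`` is set.
    """
    if not section.lesion_columns:
        raise ValueError("section has no lesion columns")
    if len(shank_widths_um) != len(section.lesion_columns):
        raise ValueError("one width per lesion column required")
    if len(section.lesion_columns) == 1:
        return section
    if len(set(shank_widths_um)) == 1 and not force:
        raise ValueError("ambiguous shank order (equal widths); pass force=True")
    order = np.argsort(section.lesion_columns)
    widths = [shank_widths_um[i] for i in order]
    if widths[0] <= widths[-1]:
        return section
    w = section.shape[1]
    flipped = {c: a[:, ::-1].copy() for c, a in section.channels.items()}
    cols = sorted(w - 1 - c for c in section.lesion_columns)
    return replace(section, channels=flipped, lesion_columns=cols)


def crop_shank(
    section: SectionImage,
    lesion_col: int,
    shank_width_um: float | None = None,
) -> ShankImage:
    """Cut an 800-px-wide window centered on one shank track.

    Columns [lesion_col - 400, lesion_col + 400), rows from the pia to 700 px
    below the white-matter boundary; out-of-bounds area is zero-padded and the
    ``padded`` flag set.
    """
    h, w = section.shape
    c0 = lesion_col - ROI_WIDTH // 2
    c1 = lesion_col + ROI_WIDTH // 2
    r0 = section.pia_row
    r1 = section.wm_boundary_row + ROI_HEIGHT
    out_h = r1 - r0
    padded = c0 < 0 or c1 > w or r1 > h
    channels: dict[str, np.ndarray] = {}
    for name, img in section.channels.items():
        out = np.zeros((out_h, ROI_WIDTH), dtype=np.uint8)
        sr0, sr1 = max(r0, 0), min(r1, h)
        sc0, sc1 = max(c0, 0), min(c1, w)
        out[sr0 - r0 : sr1 - r0, sc0 - c0 : sc1 - c0] = img[sr0:sr1, sc0:sc1]
        channels[name] = out
    return ShankImage(
        channels=channels,
        shank_width_um=shank_width_um,
        pia_row=0,
        wm_boundary_row=section.wm_boundary_row - section.pia_row,
        pixel_size_um=section.pixel_size_um,
        padded=padded,
        has_white_matter=section.has_white_matter,
    )


def extract_rois(shank: ShankImage, channel: str) -> dict[str, RoiImage | None]:
    """Cut the three depth ROIs of one channel from a shank image.

    Returns a dict keyed by region.  When the cortical depth is under 1400 px
    the upper and lower cortical ROIs overlap; both are still returned with
    the shared row interval recorded and a warning emitted.  When the section
    has no white matter (probe too posterior) the white-matter entry is None.
    """
    if channel not in shank.channels:
        raise KeyError(f"channel {channel!r} not in shank image")
    img = shank.channels[channel]
    pia, wm = shank.pia_row, shank.wm_boundary_row
    depth = wm - pia
    overlap: tuple[int, int] | None = None
    if depth < 2 * ROI_HEIGHT:
        overlap = (wm - ROI_HEIGHT, pia + ROI_HEIGHT)
        warnings.warn(
            f"cortical depth {depth} px < {2 * ROI_HEIGHT}: upper and lower "
            f"ROIs overlap in rows [{overlap[0]}, {overlap[1]})",
            stacklevel=2,
        )
    rois: dict[str, RoiImage | None] = {
        "upper_cortex": RoiImage(
            pixels=img[pia : pia + ROI_HEIGHT],
            region="upper_cortex",
            channel=channel,
            overlap_rows=overlap,
        ),
        "lower_cortex": RoiImage(
            pixels=img[wm - ROI_HEIGHT : wm],
            region="lower_cortex",
            channel=channel,
            overlap_rows=overlap,
        ),
        "white_matter": None,
    }
    if shank.has_white_matter:
        rois["white_matter"] = RoiImage(
            pixels=img[wm : wm + ROI_HEIGHT],
            region="white_matter",
            channel=channel,
        )
    return rois


def split_roi_halves(obj) -> tuple[np.ndarray, np.ndarray]:
    """Split an ROI or downsampled grid into top and bottom halves by depth.

    Accepts a RoiImage, a DownsampledMap-like object (``.grid``) or a bare
    array with an even number of rows; returns (top_rows, bottom_rows) whose
    vertical concatenation restores the input.
    """
    if isinstance(obj, RoiImage):
        arr = obj.pixels
    elif hasattr(obj, "grid"):
        arr = obj.grid
    elif hasattr(obj, "pixels"):
        arr = obj.pixels
    else:
        arr = np.asarray(obj)
    n = arr.shape[0]
    if n % 2:
        raise ValueError(f"odd row count {n}: halves undefined")
    return arr[: n // 2], arr[n // 2 :]
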