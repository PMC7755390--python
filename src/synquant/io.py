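"""Calibrated images, ROIs, quantification parameters, and table I/O.

The data model keeps every physical quantity in micrometres: images carry
their pixel size (``pixel_size_um``, the edge length of one pixel) so that
downstream areas and lengths are reported in μm² / μm rather than pixels.
Coordinates follow the raster convention: 0-based, origin at the top-left,
rectangles half-open in both axes.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("synquant")

#: Channel roles understood by the pipeline.
CHANNEL_ROLES = (
    "surface_reporter",
    "presyn_marker",
    "postsyn_marker",
    "ais_marker",
    "tag",
    "nuclear",
)

#: Minimum particle sizes (μm²) per synaptic marker class.  Large-bouton
#: markers (GAD67, GAD65, CB1R) use 0.06 μm²; smaller boutons and
#: postsynaptic clusters (Syt2, VGlut1, Gephyrin, PSD95) use 0.05 μm².
DEFAULT_MIN_PUNCTUM_AREA_UM2: dict[str, float] = {
    "GAD67": 0.06,
    "GAD65": 0.06,
    "CB1R": 0.06,
    "Syt2": 0.05,
    "VGlut1": 0.05,
    "Gephyrin": 0.05,
    "PSD95": 0.05,
}


class GeometryError(ValueError):
    """Raised when two grids that must share a geometry do not."""


@dataclass(frozen=True)
class CalibratedImage:
    """A single channel's 2D intensity grid with physical calibration.

    Parameters
    ----------
    pixels : ndarray
        Non-negative 2D intensity grid.
    pixel_size_um : float
        Edge length of one pixel in μm (> 0).
    bit_depth : int
        One of 8, 12, 16; all intensities must be ≤ 2**bit_depth − 1.
    channel_role : str
        One of :data:`CHANNEL_ROLES`.
    """

    pixels: np.ndarray
    pixel_size_um: float
    bit_depth: int = 8
    channel_role: str = "surface_reporter"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2D grid")
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError(f"bit_depth must be 8, 12 or 16, got {self.bit_depth}")
        if self.channel_role not in CHANNEL_ROLES:
            raise ValueError(f"unknown channel_role {self.channel_role!r}")
        if px.min() < 0:
            raise ValueError("intensities must be non-negative")
        if px.max() > self.max_intensity:
            raise ValueError(
                f"intensity {px.max()} exceeds 2**{self.bit_depth}-1"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def max_intensity(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2

    def with_pixels(self, pixels: np.ndarray) -> "CalibratedImage":
        """Same calibration, new pixel grid."""
        return dataclasses.replace(self, pixels=pixels)


@dataclass(frozen=True)
class Roi:
    """A rectangular region of interest: 0-based, half-open in x and y."""

    x0: int
    y0: int
    width: int
    height: int
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("ROI must have positive width and height")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("ROI origin must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def area_um2(self) -> float:
        return self.width * self.height * self.pixel_size_um**2

    def contains_point(self, x: float, y: float) -> bool:
        """Half-open membership test in pixel coordinates."""
        return (self.x0 <= x < self.x0 + self.width) and (
            self.y0 <= y < self.y0 + self.height
        )

    def validate_inside(self, shape: tuple[int, int]) -> None:
        h, w = shape
        if self.x0 + self.width > w or self.y0 + self.height > h:
            raise ValueError(f"ROI {self} exceeds image shape {shape}")


@dataclass
class QuantParams:
    """Quantification thresholds, all in μm² (``≥`` semantics throughout).

    ``min_punctum_area_um2`` maps marker class to the smallest particle
    retained.  The three overlap criteria are: punctum-on-structure contact
    (0.04 μm²), pre/post synapse pairing (0.03 μm²), and assignment of a
    pair to a labeled axonal process (0.025 μm²).
    """

    min_punctum_area_um2: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MIN_PUNCTUM_AREA_UM2)
    )
    circularity_range: tuple[float, float] = (0.0, 1.0)
    contact_min_overlap_um2: float = 0.04
    pair_min_overlap_um2: float = 0.03
    process_min_overlap_um2: float = 0.025
    min_soma_area_um2: float = 50.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for k, v in self.min_punctum_area_um2.items():
            if v <= 0:
                raise ValueError(f"min punctum area for {k} must be > 0")
        lo, hi = self.circularity_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("circularity bounds must satisfy 0 ≤ lo ≤ hi ≤ 1")
        for name in ("contact_min_overlap_um2", "pair_min_overlap_um2",
                     "process_min_overlap_um2", "min_soma_area_um2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")

    def min_area_for(self, marker_class: str) -> float:
        try:
            return self.min_punctum_area_um2[marker_class]
        except KeyError:
            raise KeyError(
                f"unknown marker class {marker_class!r}; known: "
                f"{sorted(self.min_punctum_area_um2)}"
            ) from None

    @classmethod
    def from_dict(cls, d: Mapping) -> "QuantParams":
        d = dict(d)
        if "min_punctum_area_um2" in d:
            merged = dict(DEFAULT_MIN_PUNCTUM_AREA_UM2)
            merged.update(d["min_punctum_area_um2"])
            d["min_punctum_area_um2"] = merged
        if "circularity_range" in d:
            d["circularity_range"] = tuple(d["circularity_range"])
        return cls(**d)


@dataclass(frozen=True)
class SampleKey:
    """Identity of one measured cell (or ROI) within the study hierarchy."""

    cell_id: str
    animal_id: str
    group_label: str
    layer_depth_um: float | None = None


def load_image(
    path: str | Path,
    pixel_size_um: float,
    channel_map: Mapping[int, str],
    bit_depth: int | None = None,
) -> list[CalibratedImage]:
    """Read a single- or multi-page TIFF into calibrated channels.

    ``channel_map`` assigns a role to every page, keyed by 1-based page
    number.  All channels must share one geometry.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    pages = tifffile.imread(str(path))
    if pages.ndim == 2:
        pages = pages[np.newaxis]
    if pages.ndim != 3:
        raise ValueError(f"expected a 2D image or a stack of 2D pages, got shape {pages.shape}")
    if len(channel_map) != pages.shape[0]:
        raise ValueError(
            f"channel_map has {len(channel_map)} entries but file has "
            f"{pages.shape[0]} pages"
        )
    if bit_depth is None:
        bit_depth = {np.uint8: 8, np.uint16: 16}.get(pages.dtype.type, 16)
        # 12-bit data is normally stored in 16-bit containers; honour the
        # data range when it fits.
        if bit_depth == 16 and pages.max() <= 4095:
            bit_depth = 12
    out = []
    for idx in sorted(channel_map):
        role = channel_map[idx]
        out.append(
            CalibratedImage(
                pixels=pages[idx - 1],
                pixel_size_um=pixel_size_um,
                bit_depth=bit_depth,
                channel_role=role,
            )
        )
    return out


def write_image(path: str | Path, channels: Sequence[CalibratedImage] | Sequence[np.ndarray]) -> None:
    """Write channels as a multi-page TIFF (lossless round-trip)."""
    arrs = [c.pixels if isinstance(c, CalibratedImage) else np.asarray(c) for c in channels]
    tifffile.imwrite(str(path), np.stack(arrs))


MEASUREMENT_COLUMNS = ["value", "cell_id", "animal_id", "group_label"]


def write_measurements(table: pd.DataFrame, path: str | Path) -> None:
    """Write a tidy cell-level measurement table to CSV.

    One row per cell with columns value, cell_id, animal_id, group_label.
    Duplicate (cell_id, animal_id) rows violate the table invariant.
    """
    if table.empty:
        raise ValueError("measurement table is empty")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")
    if table.duplicated(subset=["cell_id", "animal_id"]).any():
        raise ValueError("duplicate (cell_id, animal_id) rows in measurement table")
    cols = MEASUREMENT_COLUMNS + [c for c in table.columns if c not in MEASUREMENT_COLUMNS]
    table[cols].to_csv(path, index=False)


def read_measurements(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cell_id": str, "animal_id": str, "group_label": str})
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")
    return df


def cell_density(count: int, area_um2: float) -> tuple[float, float]:
    """Cells per μm² (and per mm²) from a manual count over a mask area."""
    if count < 0:
        raise ValueError("count must be non-negative")
    if area_um2 <= 0:
        raise ValueError("area_um2 must be > 0")
    per_um2 = count / area_um2
    return per_um2, per_um2 * 1e6


def load_config(path: str | Path) -> dict:
    """Load the YAML run configuration; see pipeline.RunConfig."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg
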