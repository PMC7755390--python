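"""Subcellular localization scoring: soma vs neuropil tag distribution,
ROI puncta densities, and apposition splits against interneuron somata.

These readouts quantify where a tagged protein resides within labeled
pyramidal cells: the fraction of reporter-masked somata that contain tag
signal, and the fraction of the neuropil mask overlapped by the tag mask.
Endogenous puncta are scored per ROI with an optional split into clusters
apposed / not apposed to PV+ interneuron cell bodies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GeometryError, Roi
from .segment import PunctaSet, SomaMask


@dataclass(frozen=True)
class LocalizationScore:
    roi_id: str
    pct_tag_positive_somas: float
    pct_neuropil_coloc: float


@dataclass(frozen=True)
class PunctaDensityRecord:
    roi_id: str
    compartment: str
    count: int
    count_per_um2: float
    apposed_count: int | None = None
    non_apposed_count: int | None = None


def score_soma_tag(
    somas: list[SomaMask],
    tag_mask: np.ndarray,
    min_tag_overlap_um2: float | None = None,
) -> float:
    """Percentage of somata containing tag signal.

    A soma counts as tag-positive when its overlap with the tag mask is ≥
    ``min_tag_overlap_um2``; the default is one pixel's area (any overlap
    at all), configurable upward for robustness to speckle.
    """
    if not somas:
        raise ValueError("no somata in ROI: percentage undefined")
    px_area = somas[0].pixel_size_um ** 2
    min_ov = px_area if min_tag_overlap_um2 is None else min_tag_overlap_um2
    positive = 0
    for soma in somas:
        if soma.region.shape != tag_mask.shape:
            raise GeometryError("tag mask geometry differs from soma masks")
        ov = np.count_nonzero(soma.region & tag_mask) * px_area
        if ov >= min_ov:
            positive += 1
    return 100.0 * positive / len(somas)


def score_neuropil_tag(neuropil_mask: np.ndarray, tag_mask: np.ndarray,
                       denominator: str = "neuropil") -> float:
    """Percentage of the neuropil mask overlapped by the tag mask.

    ``denominator="tag"`` instead reports the share of the tag mask lying
    in the neuropil (the alternative reading of the colocalization score).
    """
    if neuropil_mask.shape != tag_mask.shape:
        raise GeometryError("neuropil and tag geometries differ")
    inter = np.count_nonzero(neuropil_mask & tag_mask)
    if denominator == "neuropil":
        denom = np.count_nonzero(neuropil_mask)
        if denom == 0:
            raise ValueError("empty neuropil mask: percentage undefined")
    elif denominator == "tag":
        denom = np.count_nonzero(tag_mask)
        if denom == 0:
            raise ValueError("empty tag mask: percentage undefined")
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return 100.0 * inter / denom


def roi_puncta_density(
    puncta: PunctaSet,
    roi: Roi,
    roi_id: str = "",
    compartment: str = "",
) -> PunctaDensityRecord:
    """Count puncta whose centroid falls in the half-open ROI.

    Centroid membership gives an unambiguous partition when ROIs tile a
    field; density is count per μm² of ROI area.
    """
    count = 0
    for row in puncta.table.itertuples(index=False):
        if roi.contains_point(row.centroid_col, row.centroid_row):
            count += 1
    return PunctaDensityRecord(
        roi_id=roi_id,
        compartment=compartment,
        count=count,
        count_per_um2=count / roi.area_um2,
    )


def split_by_pv_apposition(
    puncta: PunctaSet,
    pv_somas: list[SomaMask],
    min_overlap_um2: float = 0.04,
) -> tuple[list[int], list[int]]:
    """Partition puncta by contact with the union of PV+ soma masks.

    Returns (apposed_labels, non_apposed_labels); the two lists always
    partition the full punctum set.
    """
    if pv_somas:
        union = np.zeros_like(pv_somas[0].region, dtype=bool)
        for s in pv_somas:
            if s.region.shape != union.shape:
                raise GeometryError("PV soma geometries differ")
            union |= s.region
        if union.shape != puncta.labels.shape:
            raise GeometryError("PV somata geometry differs from puncta")
        on = puncta.labels[union]
        counts = np.bincount(on[on > 0], minlength=int(puncta.labels.max()) + 1)
    else:
        counts = np.zeros(int(puncta.labels.max()) + 1, dtype=int)
    px_area = puncta.pixel_size_um**2
    apposed, non_apposed = [], []
    for lab in puncta.table["label"]:
        if counts[int(lab)] * px_area >= min_overlap_um2:
            apposed.append(int(lab))
        else:
            non_apposed.append(int(lab))
    return apposed, non_apposed
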