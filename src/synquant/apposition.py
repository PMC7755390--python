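"""Overlap-area apposition criteria and density conversion.

Every call here reduces to pixel-count intersections scaled by the pixel
area, compared with ``≥`` against a physical threshold in μm²:

* punctum contacts a soma or AIS when ≥ 0.04 μm² of its area lies on the
  structure mask (the same criterion decides whether a postsynaptic
  cluster is contained in a soma);
* a presynaptic bouton and a postsynaptic cluster form a synapse when
  their masks share ≥ 0.03 μm²;
* a synapse originates from a labeled axon when the presynaptic punctum
  shares ≥ 0.025 μm² with the process mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeometryError, SampleKey
from .segment import AisMask, PunctaSet, SomaMask


@dataclass(frozen=True)
class Contact:
    punctum_label: int
    structure_id: int
    overlap_area_um2: float


@dataclass(frozen=True)
class SynapsePair:
    pre_label: int
    post_label: int
    pair_overlap_um2: float
    process_overlap_um2: float | None = None


@dataclass(frozen=True)
class DensityRecord:
    """Count of contacts normalized by structure extent.

    ``density`` is per μm of soma perimeter or AIS length (or per target
    cell for count normalizers); ``per_10um`` is the same value scaled to
    contacts per 10 μm for readability.
    """

    key: SampleKey
    structure_type: str
    count: int
    normalizer: float
    density: float
    per_10um: float


def overlap_area(
    mask_a: np.ndarray, mask_b: np.ndarray, pixel_size_um: float
) -> float:
    """|A ∩ B| in μm²: shared pixel count times the pixel area."""
    if mask_a.shape != mask_b.shape:
        raise GeometryError(f"mask shapes differ: {mask_a.shape} vs {mask_b.shape}")
    return int(np.count_nonzero(mask_a & mask_b)) * pixel_size_um**2


def _per_label_overlap(
    puncta: PunctaSet, structure_region: np.ndarray
) -> dict[int, float]:
    """Overlap in μm² of every punctum with one structure region."""
    if puncta.labels.shape != structure_region.shape:
        raise GeometryError("puncta and structure geometries differ")
    on = puncta.labels[structure_region]
    counts = np.bincount(on[on > 0], minlength=int(puncta.labels.max()) + 1)
    px_area = puncta.pixel_size_um**2
    return {
        int(lab): counts[int(lab)] * px_area
        for lab in puncta.table["label"]
        if counts[int(lab)] > 0
    }


def call_contacts(
    puncta: PunctaSet,
    structures: list[SomaMask] | list[AisMask] | SomaMask | AisMask,
    min_overlap_um2: float = 0.04,
) -> list[Contact]:
    """Call puncta apposed to soma or AIS structures.

    A punctum contacts a structure when their mask overlap is ≥
    ``min_overlap_um2``.  Each punctum is assigned to at most one
    structure: ties broken by larger overlap, then lower structure id.
    """
    if isinstance(structures, (SomaMask, AisMask)):
        structures = [structures]
    best: dict[int, tuple[float, int]] = {}
    for structure in sorted(structures, key=lambda s: s.label):
        overlaps = _per_label_overlap(puncta, structure.region)
        for lab, ov in overlaps.items():
            if ov < min_overlap_um2:
                continue
            if lab not in best or ov > best[lab][0]:
                best[lab] = (ov, structure.label)
    return [
        Contact(punctum_label=lab, structure_id=sid, overlap_area_um2=ov)
        for lab, (ov, sid) in sorted(best.items())
    ]


def call_contained_clusters(
    puncta: PunctaSet,
    soma: SomaMask,
    min_overlap_um2: float = 0.04,
) -> list[Contact]:
    """Postsynaptic clusters contained in a soma: same ≥ 0.04 μm² rule
    applied against the soma interior."""
    return call_contacts(puncta, soma, min_overlap_um2)


def _pair_overlap_table(pre: PunctaSet, post: PunctaSet) -> pd.DataFrame:
    """All (pre, post) label pairs with their overlap in μm²."""
    if pre.labels.shape != post.labels.shape:
        raise GeometryError("pre and post geometries differ")
    both = (pre.labels > 0) & (post.labels > 0)
    if not both.any():
        return pd.DataFrame(columns=["pre_label", "post_label", "overlap_um2"])
    pairs = np.stack([pre.labels[both], post.labels[both]], axis=1)
    uniq, counts = np.unique(pairs, axis=0, return_counts=True)
    px_area = pre.pixel_size_um**2
    return pd.DataFrame(
        {
            "pre_label": uniq[:, 0],
            "post_label": uniq[:, 1],
            "overlap_um2": counts * px_area,
        }
    )


def pair_synapses(
    pre: PunctaSet,
    post: PunctaSet,
    min_overlap_um2: float = 0.03,
) -> list[SynapsePair]:
    """Match presynaptic boutons to postsynaptic clusters one-to-one.

    Candidate pairs need mutual overlap ≥ ``min_overlap_um2``; matching is
    greedy by descending overlap (ties → lower pre label, then lower post
    label), so no punctum is counted toward two synapses.
    """
    cand = _pair_overlap_table(pre, post)
    cand = cand[cand["overlap_um2"] >= min_overlap_um2]
    cand = cand.sort_values(
        ["overlap_um2", "pre_label", "post_label"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    used_pre: set[int] = set()
    used_post: set[int] = set()
    out: list[SynapsePair] = []
    for row in cand.itertuples(index=False):
        if row.pre_label in used_pre or row.post_label in used_post:
            continue
        used_pre.add(row.pre_label)
        used_post.add(row.post_label)
        out.append(
            SynapsePair(
                pre_label=int(row.pre_label),
                post_label=int(row.post_label),
                pair_overlap_um2=float(row.overlap_um2),
            )
        )
    return out


def assign_pairs_to_process(
    pairs: list[SynapsePair],
    pre: PunctaSet,
    process_mask: np.ndarray,
    min_overlap_um2: float = 0.025,
    mode: str = "pre",
    post: PunctaSet | None = None,
) -> list[SynapsePair]:
    """Keep synapse pairs originating from a labeled axonal process.

    ``mode`` selects whose overlap with the process mask must reach
    ``min_overlap_um2``: the presynaptic punctum (``"pre"``, default), the
    union of both members (``"union"``), or either member (``"either"``).
    """
    if pre.labels.shape != process_mask.shape:
        raise GeometryError("process mask geometry differs from puncta")
    if mode not in ("pre", "union", "either"):
        raise ValueError(f"unknown process-assignment mode {mode!r}")
    if mode in ("union", "either") and post is None:
        raise ValueError(f"mode {mode!r} needs the post PunctaSet")
    pre_ov = _per_label_overlap(pre, process_mask)
    post_ov = _per_label_overlap(post, process_mask) if post is not None else {}
    out = []
    for p in pairs:
        a = pre_ov.get(p.pre_label, 0.0)
        b = post_ov.get(p.post_label, 0.0)
        if mode == "pre":
            ov = a
        elif mode == "union":
            ov = a + b
        else:
            ov = max(a, b)
        if ov >= min_overlap_um2:
            out.append(
                SynapsePair(
                    pre_label=p.pre_label,
                    post_label=p.post_label,
                    pair_overlap_um2=p.pair_overlap_um2,
                    process_overlap_um2=ov,
                )
            )
    return out


def linear_density(
    contacts: list[Contact] | int,
    structure: SomaMask | AisMask,
    key: SampleKey | None = None,
) -> DensityRecord:
    """Contacts per μm of soma perimeter or AIS length."""
    count = contacts if isinstance(contacts, int) else len(contacts)
    if isinstance(structure, SomaMask):
        normalizer = structure.perimeter_um
        structure_type = "soma"
    else:
        normalizer = structure.length_um
        structure_type = "ais"
    if normalizer <= 0:
        raise ValueError("structure normalizer must be > 0")
    density = count / normalizer
    return DensityRecord(
        key=key or SampleKey("", "", ""),
        structure_type=structure_type,
        count=count,
        normalizer=normalizer,
        density=density,
        per_10um=density * 10.0,
    )
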