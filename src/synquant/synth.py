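"""Synthetic multichannel confocal scenes with known ground truth.

The generator emulates the measurement situations the pipeline is built
for: bright soma disks on a dimmer textured neuropil, elongated AIS bars,
diffraction-limited synaptic puncta planted tangent to structure borders
with a controlled inside-fraction (so their structure overlap clears the
contact criterion by construction), optional pre/post punctum pairs with
a controlled mutual-overlap fraction, labeled-axon process masks, and a
tag channel confined to soma, neuropil, or a mix.  Channels are rendered
as ideal structures, blurred by a Gaussian PSF, then corrupted by Poisson
shot noise and additive Gaussian read noise; the ground truth is recorded
before noise.

Randomness uses the counter-based Philox generator with per-entity
substreams derived from ``numpy.random.SeedSequence``, so scenes are
reproducible across platforms and adding one entity does not shift the
placement of the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.optimize import brentq
from skimage import draw, measure

from .apposition import call_contacts, linear_density
from .io import CalibratedImage, QuantParams, SampleKey
from .segment import AisMask, SomaMask, detect_puncta

Dist = float | tuple[float, float]  # fixed value or uniform (low, high)


class PlacementError(RuntimeError):
    """Requested geometry could not be placed after bounded retries."""


def _draw_value(rng: np.random.Generator, dist: Dist) -> float:
    if isinstance(dist, (tuple, list)):
        lo, hi = dist
        return float(rng.uniform(lo, hi))
    return float(dist)


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene.

    Lengths are in μm unless the name says px.  Intensity levels target an
    8-bit range; with the default noise settings the peak-signal to noise
    ratio of a rendered punctum is ≈ 8.
    """

    frame_px: int = 1024
    pixel_size_um: float = 0.1
    n_somata: int = 3
    soma_radius_um: Dist = (3.0, 4.5)
    n_boutons_per_soma: Dist = (8, 14)  # uniform integer range
    punctum_radius_um: Dist = (0.17, 0.25)
    bouton_inside_fraction: float = 0.6
    near_miss_offset_px: float = 0.0  # >0 plants boutons off-structure
    pair_overlap_fraction: float = 0.0  # >0 adds a postsynaptic partner
    n_ais: int = 0
    ais_length_um: Dist = (8.0, 15.0)
    ais_width_um: float = 0.4
    n_boutons_per_ais: Dist | None = None
    process_coverage_fraction: float = 0.0  # share of pairs on the process
    tag_compartment: str | None = None  # "soma" | "neuropil" | "mixed"
    tag_mixed_theta: float = 0.5
    psf_sigma_um: float = 0.08
    # intensity model (8-bit scale)
    soma_intensity: float = 180.0
    neuropil_level: float = 30.0
    neuropil_texture_sd: float = 8.0
    synaptic_background: float = 8.0
    bouton_amplitude: float = 160.0
    # noise model: Poisson shot (photons = photon_scale × intensity), then
    # additive Gaussian read noise
    noise_gaussian_sd: float = 8.0
    noise_photon_scale: float = 2.0
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_px <= 0 or self.pixel_size_um <= 0:
            raise ValueError("frame and pixel size must be positive")
        if self.n_somata < 0 or self.n_ais < 0:
            raise ValueError("counts must be non-negative")
        if not (0.0 < self.bouton_inside_fraction <= 1.0):
            raise ValueError("bouton_inside_fraction must lie in (0, 1]")
        if self.tag_compartment not in (None, "soma", "neuropil", "mixed"):
            raise ValueError(f"unknown tag compartment {self.tag_compartment!r}")

    @property
    def suggested_soma_threshold(self) -> float:
        return 0.5 * (self.neuropil_level + self.soma_intensity)

    @property
    def suggested_neuropil_threshold(self) -> float:
        return 0.5 * self.neuropil_level

    @property
    def suggested_puncta_threshold(self) -> float:
        # puncta lose some peak amplitude to the PSF; halfway to the
        # blurred peak keeps detection robust at the default SNR
        return self.synaptic_background + 0.3 * self.bouton_amplitude


@dataclass
class GroundTruth:
    """Pre-noise truth for one scene."""

    somas: list[SomaMask]
    ais: list[AisMask]
    bouton_labels: np.ndarray  # planted presynaptic puncta, labeled
    boutons: pd.DataFrame  # label, structure_type, structure_id, row, col,
    #                        area_um2, structure_overlap_um2
    post_labels: np.ndarray | None = None
    pairs: pd.DataFrame | None = None  # pre_label, post_label, overlap_um2, on_process
    process_mask: np.ndarray | None = None
    tag_mask: np.ndarray | None = None
    neuropil_mask: np.ndarray | None = None

    def bouton_count(self, structure_type: str, structure_id: int) -> int:
        b = self.boutons
        return int(
            ((b["structure_type"] == structure_type) & (b["structure_id"] == structure_id)).sum()
        )


def _lens_area(d: float, r: float, R: float) -> float:
    """Intersection area of circles radius r and R at center distance d."""
    if d >= r + R:
        return 0.0
    if d <= abs(R - r):
        return math.pi * min(r, R) ** 2
    a = r**2 * math.acos((d**2 + r**2 - R**2) / (2 * d * r))
    b = R**2 * math.acos((d**2 + R**2 - r**2) / (2 * d * R))
    c = 0.5 * math.sqrt(
        (-d + r + R) * (d + r - R) * (d - r + R) * (d + r + R)
    )
    return a + b - c


def _center_distance_for_inside_fraction(r: float, R: float, frac: float) -> float:
    """Distance from soma center so `frac` of the bouton disk lies inside."""
    target = frac * math.pi * r**2
    lo, hi = max(R - r, 1e-9), R + r
    if _lens_area(lo, r, R) <= target:
        return lo
    return brentq(lambda d: _lens_area(d, r, R) - target, lo, hi)


def _pair_offset_for_overlap(r: float, frac: float) -> float:
    """Center distance of two equal disks sharing `frac` of one disk's area."""
    target = frac * math.pi * r**2

    def f(d: float) -> float:
        return 2 * r**2 * math.acos(d / (2 * r)) - (d / 2) * math.sqrt(
            4 * r**2 - d**2
        ) - target

    if frac >= 1.0:
        return 0.0
    return brentq(f, 1e-9, 2 * r - 1e-9)


def _disk_mask(shape: tuple[int, int], r0: float, c0: float, radius_px: float) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    rr, cc = draw.disk((r0, c0), max(radius_px, 0.6), shape=shape)
    m[rr, cc] = True
    return m


def _soma_truth_from_region(region: np.ndarray, label: int, pixel_size_um: float) -> SomaMask:
    rp = measure.regionprops(region.astype(np.uint8))[0]
    return SomaMask(
        label=label,
        region=region,
        area_um2=rp.area * pixel_size_um**2,
        perimeter_um=rp.perimeter * pixel_size_um,
        centroid=tuple(rp.centroid),
        pixel_size_um=pixel_size_um,
    )


def _apply_psf_and_noise(
    ideal: np.ndarray, spec: SceneSpec, rng: np.random.Generator, noisy: bool
) -> np.ndarray:
    px = ndi.gaussian_filter(ideal, sigma=spec.psf_sigma_um / spec.pixel_size_um)
    if noisy:
        g = spec.noise_photon_scale
        if g > 0:
            px = rng.poisson(np.clip(px, 0, None) * g) / g
        px = px + rng.normal(0.0, spec.noise_gaussian_sd, size=px.shape)
    max_int = 2**spec.bit_depth - 1
    return np.clip(px, 0, max_int)


def _substream(spec_seed: int, *key: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.Philox(np.random.SeedSequence((spec_seed,) + key))
    )


def _place_somata(
    spec: SceneSpec, rng: np.random.Generator
) -> list[tuple[float, float, float]]:
    """(row, col, radius_px) for each soma, non-overlapping, inside frame."""
    placed: list[tuple[float, float, float]] = []
    margin_px = 6.0
    for _ in range(spec.n_somata):
        radius_um = _draw_value(rng, spec.soma_radius_um)
        r_px = radius_um / spec.pixel_size_um
        pad = r_px + 4 / spec.pixel_size_um * 0.1 + margin_px  # room for boutons
        if 2 * pad >= spec.frame_px:
            raise PlacementError("soma too large for frame")
        ok = False
        for _try in range(400):
            r0 = rng.uniform(pad, spec.frame_px - pad)
            c0 = rng.uniform(pad, spec.frame_px - pad)
            if all(
                math.hypot(r0 - rr, c0 - cc) > r_px + orr + 2 * margin_px
                for rr, cc, orr in placed
            ):
                ok = True
                break
        if not ok:
            raise PlacementError("could not place somata without overlap")
        placed.append((r0, c0, r_px))
    return placed


def _bouton_angles(
    n: int, soma_r_px: float, bouton_r_px: float, psf_px: float, rng: np.random.Generator
) -> np.ndarray:
    """n angles around a soma with guaranteed angular separation."""
    if n == 0:
        return np.array([])
    min_gap = (2 * bouton_r_px + 3 * psf_px + 2.0) / soma_r_px
    if n * min_gap > 2 * math.pi:
        raise PlacementError("too many boutons for this soma perimeter")
    base = np.arange(n) * (2 * math.pi / n)
    jitter_amp = max(0.0, (2 * math.pi / n - min_gap) / 2)
    jitter = rng.uniform(-jitter_amp, jitter_amp, size=n)
    return base + jitter + rng.uniform(0, 2 * math.pi)


def generate_scene(
    spec: SceneSpec,
) -> tuple[dict[str, CalibratedImage], GroundTruth]:
    """Render one multichannel scene and its pre-noise ground truth.

    Returns a dict keyed by channel role — always ``surface_reporter`` and
    ``presyn_marker``; plus ``postsyn_marker`` when pairs are requested,
    ``ais_marker`` when ``n_ais > 0``, ``tag`` when a tag compartment is
    set, and ``process`` when a process mask is requested.
    """
    shape = (spec.frame_px, spec.frame_px)
    px_sz = spec.pixel_size_um
    px_area = px_sz**2
    psf_px = spec.psf_sigma_um / px_sz

    soma_rng = _substream(spec.seed, 0)
    noise_rng = _substream(spec.seed, 1)
    texture_rng = _substream(spec.seed, 2)

    soma_geo = _place_somata(spec, soma_rng)
    soma_masks: list[SomaMask] = []
    surface_ideal = np.zeros(shape, dtype=np.float64)
    # smooth neuropil texture: low-pass filtered white noise around the base level
    texture = texture_rng.normal(0.0, 1.0, size=shape)
    texture = ndi.gaussian_filter(texture, sigma=4.0)
    texture *= spec.neuropil_texture_sd / max(texture.std(), 1e-12)
    surface_ideal += np.clip(spec.neuropil_level + texture, 0, None)
    soma_union = np.zeros(shape, dtype=bool)
    for i, (r0, c0, r_px) in enumerate(soma_geo, start=1):
        region = _disk_mask(shape, r0, c0, r_px)
        soma_union |= region
        soma_masks.append(_soma_truth_from_region(region, i, px_sz))
    surface_ideal[soma_union] = spec.soma_intensity

    # AIS bars: flat-capped rectangles so the rendered extent matches the
    # nominal length
    ais_masks: list[AisMask] = []
    ais_axes: list[tuple[np.ndarray, np.ndarray]] = []  # (p0, p1) per AIS
    ais_ideal = np.zeros(shape, dtype=np.float64)
    half_w_px = max(0.5 * spec.ais_width_um / px_sz, 1.0)
    for j in range(spec.n_ais):
        a_rng = _substream(spec.seed, 10, j)
        length_um = _draw_value(a_rng, spec.ais_length_um)
        L_px = length_um / px_sz
        pad = L_px / 2 + half_w_px + 8
        if 2 * pad >= spec.frame_px:
            raise PlacementError("AIS too long for frame")
        for _try in range(400):
            r0 = a_rng.uniform(pad, spec.frame_px - pad)
            c0 = a_rng.uniform(pad, spec.frame_px - pad)
            theta = a_rng.uniform(0, math.pi)
            axis = np.array([math.sin(theta), math.cos(theta)])
            perp = np.array([-axis[1], axis[0]])
            p0 = np.array([r0, c0]) - axis * L_px / 2
            p1 = np.array([r0, c0]) + axis * L_px / 2
            corners = np.array(
                [p0 + perp * half_w_px, p0 - perp * half_w_px,
                 p1 - perp * half_w_px, p1 + perp * half_w_px]
            )
            region = np.zeros(shape, dtype=bool)
            rr, cc = draw.polygon(corners[:, 0], corners[:, 1], shape=shape)
            region[rr, cc] = True
            if not (region & soma_union).any() and not (
                ais_ideal[region] > 0
            ).any():
                break
        else:
            raise PlacementError("could not place AIS without overlap")
        ais_ideal[region] = spec.soma_intensity
        ais_axes.append((p0, p1))
        ais_masks.append(
            AisMask(label=j + 1, region=region, length_um=length_um, pixel_size_um=px_sz)
        )

    # presynaptic boutons tangent to structure borders
    presyn_ideal = np.full(shape, spec.synaptic_background, dtype=np.float64)
    bouton_labels = np.zeros(shape, dtype=np.int32)
    bouton_rows: list[dict] = []
    next_label = 1

    def plant_bouton(
        center: tuple[float, float], radius_px: float, structure_region: np.ndarray,
        structure_type: str, structure_id: int,
        inward: tuple[float, float] | None = None,
        min_overlap_um2: float | None = None,
    ) -> None:
        nonlocal next_label
        m = _disk_mask(shape, center[0], center[1], radius_px)
        m &= bouton_labels == 0
        overlap_um2 = np.count_nonzero(m & structure_region) * px_area
        # rasterization can undercut the continuous lens geometry; nudge the
        # disk inward until the planted overlap clears the contact criterion
        if inward is not None and min_overlap_um2 is not None:
            center = (float(center[0]), float(center[1]))
            for _ in range(8):
                if overlap_um2 >= min_overlap_um2:
                    break
                center = (center[0] + 0.5 * inward[0], center[1] + 0.5 * inward[1])
                m = _disk_mask(shape, center[0], center[1], radius_px)
                m &= bouton_labels == 0
                overlap_um2 = np.count_nonzero(m & structure_region) * px_area
        bouton_labels[m] = next_label
        presyn_ideal[m] = spec.synaptic_background + spec.bouton_amplitude
        bouton_rows.append(
            {
                "label": next_label,
                "structure_type": structure_type,
                "structure_id": structure_id,
                "row": center[0],
                "col": center[1],
                "radius_px": radius_px,
                "area_um2": np.count_nonzero(m) * px_area,
                "structure_overlap_um2": overlap_um2,
            }
        )
        next_label += 1

    for i, ((r0, c0, r_px), soma) in enumerate(zip(soma_geo, soma_masks), start=1):
        b_rng = _substream(spec.seed, 20, i)
        lo, hi = (
            spec.n_boutons_per_soma
            if isinstance(spec.n_boutons_per_soma, (tuple, list))
            else (spec.n_boutons_per_soma, spec.n_boutons_per_soma)
        )
        n_b = int(b_rng.integers(int(lo), int(hi) + 1))
        radius_um = _draw_value(b_rng, spec.punctum_radius_um)
        b_r_px = radius_um / px_sz
        angles = _bouton_angles(n_b, r_px, b_r_px, psf_px, b_rng)
        if spec.near_miss_offset_px > 0:
            d_px = r_px + b_r_px + spec.near_miss_offset_px
        else:
            d_um = _center_distance_for_inside_fraction(
                radius_um, r_px * px_sz, spec.bouton_inside_fraction
            )
            d_px = d_um / px_sz
        for th in angles:
            center = (r0 + d_px * math.sin(th), c0 + d_px * math.cos(th))
            inward = None
            min_ov = None
            if spec.near_miss_offset_px <= 0:
                inward = (-math.sin(th), -math.cos(th))
                min_ov = 0.04
            plant_bouton(center, b_r_px, soma.region, "soma", i, inward, min_ov)

    for j, ais in enumerate(ais_masks, start=1):
        b_rng = _substream(spec.seed, 30, j)
        dist = spec.n_boutons_per_ais or spec.n_boutons_per_soma
        lo, hi = dist if isinstance(dist, (tuple, list)) else (dist, dist)
        n_b = int(b_rng.integers(int(lo), int(hi) + 1))
        radius_um = _draw_value(b_rng, spec.punctum_radius_um)
        b_r_px = radius_um / px_sz
        # evenly spaced along the bar axis, straddling its long border
        p0, p1 = ais_axes[j - 1]
        axis = p1 - p0
        norm = float(np.hypot(*axis))
        if norm == 0 or n_b == 0:
            continue
        axis = axis / norm
        perp = np.array([-axis[1], axis[0]])
        min_sep = 2 * b_r_px + 3 * psf_px + 2
        usable = norm - 2 * b_r_px
        n_b = min(n_b, max(1, int(usable / min_sep)))
        ts = np.linspace(0.12, 0.88, n_b)
        # center offset from the bar midline so bouton_inside_fraction of
        # the disk chord lies inside the half-width
        offset = half_w_px + b_r_px * (1 - 2 * spec.bouton_inside_fraction)
        for k, t in enumerate(ts):
            side = 1 if (k % 2 == 0) else -1
            center = p0 + axis * (t * norm) + side * perp * offset
            inward = tuple(-side * perp)
            plant_bouton(
                (center[0], center[1]), b_r_px, ais.region, "ais", j,
                inward, 0.04,
            )

    boutons = pd.DataFrame(
        bouton_rows,
        columns=[
            "label", "structure_type", "structure_id", "row", "col",
            "radius_px", "area_um2", "structure_overlap_um2",
        ],
    )

    # postsynaptic partners
    post_labels = None
    pairs = None
    postsyn_ideal = None
    if spec.pair_overlap_fraction > 0 and len(boutons):
        postsyn_ideal = np.full(shape, spec.synaptic_background, dtype=np.float64)
        post_labels = np.zeros(shape, dtype=np.int32)
        pair_rows = []
        p_rng = _substream(spec.seed, 40)
        for b in boutons.itertuples(index=False):
            pre_mask = bouton_labels == b.label
            target_um2 = spec.pair_overlap_fraction * np.count_nonzero(pre_mask) * px_area
            th = p_rng.uniform(0, 2 * math.pi)
            # rasterized lens areas undershoot the analytic ones at few-px
            # radii; scan shifts outward and keep the farthest offset whose
            # pixel overlap still meets the requested fraction
            best_center = (b.row, b.col)
            for d_px in np.arange(2 * b.radius_px, -0.25, -0.5):
                center = (
                    b.row + d_px * math.sin(th),
                    b.col + d_px * math.cos(th),
                )
                m = _disk_mask(shape, center[0], center[1], b.radius_px)
                if np.count_nonzero(m & pre_mask) * px_area >= target_um2:
                    best_center = center
                    break
            m = _disk_mask(shape, best_center[0], best_center[1], b.radius_px)
            m &= post_labels == 0
            post_labels[m] = b.label
            postsyn_ideal[m] = spec.synaptic_background + spec.bouton_amplitude
            ov = np.count_nonzero(m & (bouton_labels == b.label)) * px_area
            pair_rows.append(
                {"pre_label": b.label, "post_label": b.label, "overlap_um2": ov,
                 "on_process": False}
            )
        pairs = pd.DataFrame(pair_rows)

    # labeled-axon process mask covering a fraction of the pairs
    process_mask = None
    process_ideal = None
    if spec.process_coverage_fraction > 0 and pairs is not None and len(pairs):
        pr_rng = _substream(spec.seed, 50)
        n_cover = int(round(spec.process_coverage_fraction * len(pairs)))
        covered = pr_rng.choice(len(pairs), size=n_cover, replace=False)
        process_mask = np.zeros(shape, dtype=bool)
        for idx in sorted(covered):
            b = boutons.iloc[idx]
            process_mask |= _disk_mask(
                shape, b["row"], b["col"], 2.0 * b["radius_px"]
            )
            pairs.loc[idx, "on_process"] = True
        process_ideal = np.where(
            process_mask, spec.soma_intensity, spec.synaptic_background
        ).astype(np.float64)

    # tag channel
    tag_mask = None
    tag_ideal = None
    neuropil_mask = (surface_ideal > 0.5 * spec.neuropil_level) & ~soma_union
    if spec.tag_compartment is not None:
        t_rng = _substream(spec.seed, 60)
        tag_mask = np.zeros(shape, dtype=bool)
        tag_soma = spec.tag_compartment == "soma" or (
            spec.tag_compartment == "mixed"
        )
        tag_neuropil = spec.tag_compartment == "neuropil" or (
            spec.tag_compartment == "mixed"
        )
        if tag_soma:
            which = (
                t_rng.uniform(size=len(soma_masks)) < spec.tag_mixed_theta
                if spec.tag_compartment == "mixed"
                else np.ones(len(soma_masks), dtype=bool)
            )
            for sel, (r0, c0, r_px) in zip(which, soma_geo):
                if sel:
                    tag_mask |= _disk_mask(shape, r0, c0, 0.7 * r_px)
        if tag_neuropil:
            n_blobs = max(3, spec.frame_px // 40)
            for _ in range(n_blobs):
                r0 = t_rng.uniform(5, spec.frame_px - 5)
                c0 = t_rng.uniform(5, spec.frame_px - 5)
                blob = _disk_mask(shape, r0, c0, t_rng.uniform(2, 6))
                tag_mask |= blob & ~soma_union
        tag_ideal = np.where(tag_mask, 150.0, 5.0)

    def render(ideal: np.ndarray, role: str, stream: int) -> CalibratedImage:
        noisy = spec.noise_gaussian_sd > 0 or spec.noise_photon_scale > 0
        out = _apply_psf_and_noise(
            ideal, spec, _substream(spec.seed, 100, stream), noisy
        )
        return CalibratedImage(
            pixels=out, pixel_size_um=px_sz, bit_depth=spec.bit_depth,
            channel_role=role,
        )

    channels: dict[str, CalibratedImage] = {
        "surface_reporter": render(surface_ideal, "surface_reporter", 0),
        "presyn_marker": render(presyn_ideal, "presyn_marker", 1),
    }
    if postsyn_ideal is not None:
        channels["postsyn_marker"] = render(postsyn_ideal, "postsyn_marker", 2)
    if spec.n_ais > 0:
        channels["ais_marker"] = render(ais_ideal, "ais_marker", 3)
    if tag_ideal is not None:
        channels["tag"] = render(tag_ideal, "tag", 4)
    if process_ideal is not None:
        channels["process"] = render(process_ideal, "surface_reporter", 5)

    truth = GroundTruth(
        somas=soma_masks,
        ais=ais_masks,
        bouton_labels=bouton_labels,
        boutons=boutons,
        post_labels=post_labels,
        pairs=pairs,
        process_mask=process_mask,
        tag_mask=tag_mask,
        neuropil_mask=neuropil_mask,
    )
    return channels, truth


def noise_free(spec: SceneSpec) -> SceneSpec:
    """Copy of a spec with the noise model switched off."""
    return replace(spec, noise_gaussian_sd=0.0, noise_photon_scale=0.0)


# ---------------------------------------------------------------------------
# cohorts

def default_cohort_spec() -> SceneSpec:
    """Study conditions for cohort simulations: one soma per small frame.

    Frame 112 px at 0.1 μm/px comfortably holds one 2.8–3.6 μm-radius soma
    with its perisomatic boutons; 8–14 boutons per soma at the default SNR
    give densities around 0.5 per μm of perimeter.
    """
    return SceneSpec(
        frame_px=112,
        pixel_size_um=0.1,
        soma_radius_um=(2.8, 3.6),
        n_boutons_per_soma=(8, 14),
        seed=0,
    )


@dataclass(frozen=True)
class CohortCell:
    key: SampleKey
    spec: SceneSpec
    group_multiplier: float


def generate_cohort(
    base_spec: SceneSpec,
    groups: Sequence[tuple[str, float]],
    n_animals: int,
    n_cells_per_animal: int,
    seed: int,
    animal_rate_sd: float = 0.10,
    n_boutons_max: int = 22,
) -> list[CohortCell]:
    """Lay out a two-level cohort: groups → animals → cells.

    Each cell gets its own scene spec with a seed derived from the master
    seed and its (group, animal, cell) indices.  The group effect scales
    the expected bouton count per soma; an animal-level multiplicative
    log-normal effect (sd ``animal_rate_sd``) makes animals, not cells,
    the unit of independent variation.  Scenes are rendered lazily by
    :func:`measure_cohort` (or by calling :func:`generate_scene` on each
    cell's spec).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for label, mult in groups:
        if mult <= 0:
            raise ValueError(f"non-positive effect multiplier for group {label!r}")
    lo, hi = (
        base_spec.n_boutons_per_soma
        if isinstance(base_spec.n_boutons_per_soma, (tuple, list))
        else (base_spec.n_boutons_per_soma, base_spec.n_boutons_per_soma)
    )
    base_mean = 0.5 * (lo + hi)
    cells: list[CohortCell] = []
    for gi, (label, mult) in enumerate(groups):
        for ai in range(n_animals):
            a_rng = np.random.Generator(
                np.random.Philox(np.random.SeedSequence((seed, gi, ai)))
            )
            animal_effect = float(np.exp(a_rng.normal(0.0, animal_rate_sd)))
            b_r_max = (
                base_spec.punctum_radius_um[1]
                if isinstance(base_spec.punctum_radius_um, (tuple, list))
                else base_spec.punctum_radius_um
            ) / base_spec.pixel_size_um
            psf_px = base_spec.psf_sigma_um / base_spec.pixel_size_um
            for ci in range(n_cells_per_animal):
                lam = base_mean * mult * animal_effect
                # fix this cell's soma radius so the bouton count can be
                # capped at the perimeter's placement capacity; the Poisson
                # tail above the cap is negligible at the default rates
                soma_r_um = _draw_value(a_rng, base_spec.soma_radius_um)
                capacity = int(
                    2 * math.pi * (soma_r_um / base_spec.pixel_size_um)
                    / (2 * b_r_max + 3 * psf_px + 2.0)
                )
                n_b = min(int(a_rng.poisson(lam)), n_boutons_max, capacity)
                cell_seed = int(
                    np.random.SeedSequence((seed, gi, ai, ci)).generate_state(1)[0]
                    % (2**31)
                )
                spec = replace(
                    base_spec, n_somata=1, soma_radius_um=soma_r_um,
                    n_boutons_per_soma=n_b, seed=cell_seed,
                )
                cells.append(
                    CohortCell(
                        key=SampleKey(
                            cell_id=f"g{gi}a{ai}c{ci}",
                            animal_id=f"g{gi}a{ai}",
                            group_label=label,
                        ),
                        spec=spec,
                        group_multiplier=mult,
                    )
                )
    return cells


def measure_cohort(
    cells: Sequence[CohortCell],
    params: QuantParams | None = None,
    marker_class: str = "GAD65",
) -> pd.DataFrame:
    """Render every cohort cell and measure its somatic bouton density.

    The measurement path is the production pipeline: detect puncta at the
    scene's generating threshold, call contacts against the soma mask with
    the ≥ 0.04 μm² criterion, and normalize the count by the soma
    perimeter.  Returns a cell-level measurement table (value = boutons
    per μm of perimeter).
    """
    params = params or QuantParams()
    rows = []
    for cell in cells:
        channels, truth = generate_scene(cell.spec)
        soma = truth.somas[0]
        puncta = detect_puncta(
            channels["presyn_marker"],
            cell.spec.suggested_puncta_threshold,
            params,
            marker_class,
        )
        contacts = call_contacts(puncta, soma, params.contact_min_overlap_um2)
        rec = linear_density(contacts, soma, cell.key)
        rows.append(
            {
                "value": rec.density,
                "cell_id": cell.key.cell_id,
                "animal_id": cell.key.animal_id,
                "group_label": cell.key.group_label,
                "count": rec.count,
                "perimeter_um": rec.normalizer,
                "true_count": truth.bouton_count("soma", 1),
            }
        )
    return pd.DataFrame(rows)
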