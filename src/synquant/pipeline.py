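"""End-to-end runs: preprocess → segment → appose → densities → stats.

A run is driven by a single YAML config (see :class:`RunConfig`): a
manifest of images with channel-role maps and sample keys, fixed
per-experiment thresholds (the same threshold applies to every image of
an experiment), quantification parameters, and an analysis mode.  Outputs
are tidy CSVs plus a JSON statistics report and a plain-text log echoing
every parameter for provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import apposition, localization, segment, stats
from .io import (
    CalibratedImage,
    QuantParams,
    Roi,
    SampleKey,
    load_config,
    load_image,
    write_measurements,
)
from .preprocess import PreprocParams, condition_channel, match_histogram

logger = logging.getLogger("synquant.pipeline")

MODES = (
    "somatic_boutons",
    "ais_boutons",
    "synapse_pairs_on_pv",
    "soma_neuropil_tag",
    "roi_puncta",
)

REQUIRED_CHANNELS: dict[str, tuple[str, ...]] = {
    "somatic_boutons": ("surface_reporter", "presyn_marker"),
    "ais_boutons": ("ais_marker", "presyn_marker"),
    "synapse_pairs_on_pv": ("surface_reporter", "presyn_marker", "postsyn_marker"),
    "soma_neuropil_tag": ("surface_reporter", "tag"),
    "roi_puncta": ("presyn_marker",),
}


class ConfigError(ValueError):
    """Invalid run configuration (maps to CLI exit code 1)."""


@dataclass
class ManifestRow:
    path: str
    key: SampleKey
    channel_map: dict[int, str]
    rois: list[tuple[int, int, int, int]] = field(default_factory=list)


@dataclass
class RunConfig:
    mode: str
    pixel_size_um: float
    manifest: list[ManifestRow]
    thresholds: dict[str, float]
    out_dir: str
    params: QuantParams = field(default_factory=QuantParams)
    preproc: PreprocParams = field(default_factory=PreprocParams)
    marker_class: str = "GAD65"
    min_soma_area_um2: float = 50.0
    min_ais_length_um: float = 2.0
    condition: bool = True
    reference_image: str | None = None  # histogram-matching reference path
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        cfg = load_config(path)
        return cls.from_dict(cfg)

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "RunConfig":
        try:
            mode = cfg["mode"]
            if mode not in MODES:
                raise ConfigError(f"unknown mode {mode!r}; expected one of {MODES}")
            pixel_size = float(cfg["pixel_size_um"])
            manifest = []
            for i, row in enumerate(cfg["manifest"]):
                if "pixel_size_um" in row and float(row["pixel_size_um"]) != pixel_size:
                    raise ConfigError(
                        f"manifest row {i}: mixed pixel sizes within one experiment"
                    )
                key = SampleKey(
                    cell_id=str(row.get("cell_id", f"cell{i}")),
                    animal_id=str(row.get("animal_id", "a0")),
                    group_label=str(row.get("group_label", "group0")),
                    layer_depth_um=row.get("layer_depth_um"),
                )
                chan = {int(k): v for k, v in row["channels"].items()}
                need = REQUIRED_CHANNELS[mode]
                missing = [r for r in need if r not in chan.values()]
                if missing:
                    raise ConfigError(
                        f"manifest row {i} ({row.get('path')}): missing channel(s) "
                        f"{missing} for mode {mode!r}"
                    )
                manifest.append(
                    ManifestRow(
                        path=row["path"], key=key, channel_map=chan,
                        rois=[tuple(r) for r in row.get("rois", [])],
                    )
                )
            params = QuantParams.from_dict(cfg.get("params", {}))
            preproc = PreprocParams(**cfg.get("preprocess", {}))
            return cls(
                mode=mode,
                pixel_size_um=pixel_size,
                manifest=manifest,
                thresholds={str(k): float(v) for k, v in cfg["thresholds"].items()},
                out_dir=cfg.get("out_dir", "."),
                params=params,
                preproc=preproc,
                marker_class=cfg.get("marker_class", "GAD65"),
                min_soma_area_um2=float(cfg.get("min_soma_area_um2", 50.0)),
                min_ais_length_um=float(cfg.get("min_ais_length_um", 2.0)),
                condition=bool(cfg.get("condition", True)),
                reference_image=cfg.get("reference_image"),
                seed=int(cfg.get("seed", 0)),
            )
        except KeyError as exc:
            raise ConfigError(f"missing config key: {exc}") from exc


def _channels_by_role(
    row: ManifestRow, pixel_size_um: float
) -> dict[str, CalibratedImage]:
    images = load_image(row.path, pixel_size_um, row.channel_map)
    by_role: dict[str, CalibratedImage] = {}
    for idx, img in zip(sorted(row.channel_map), images):
        by_role[row.channel_map[idx]] = img
    return by_role


def _prepare(
    img: CalibratedImage, config: RunConfig, reference: CalibratedImage | None
) -> CalibratedImage:
    if reference is not None:
        img = match_histogram(img, reference)
    if config.condition:
        img = condition_channel(img, config.preproc)
    return img


def _measure_row(
    config: RunConfig, row: ManifestRow, reference: CalibratedImage | None
) -> list[dict]:
    ch = _channels_by_role(row, config.pixel_size_um)
    thr = config.thresholds
    p = config.params
    out: list[dict] = []
    base = {
        "cell_id": row.key.cell_id,
        "animal_id": row.key.animal_id,
        "group_label": row.key.group_label,
    }

    if config.mode == "somatic_boutons":
        surface = _prepare(ch["surface_reporter"], config, reference)
        syn = _prepare(ch["presyn_marker"], config, reference)
        somas = segment.segment_somata(surface, thr["soma"], config.min_soma_area_um2)
        puncta = segment.detect_puncta(syn, thr["puncta"], p, config.marker_class)
        if not somas:
            logger.warning("no soma found for cell %s", row.key.cell_id)
            return []
        soma = max(somas, key=lambda s: s.area_um2)  # the imaged cell
        contacts = apposition.call_contacts(puncta, soma, p.contact_min_overlap_um2)
        rec = apposition.linear_density(contacts, soma, row.key)
        out.append({**base, "value": rec.density, "count": rec.count,
                    "normalizer_um": rec.normalizer, "structure": "soma"})

    elif config.mode == "ais_boutons":
        ais_ch = _prepare(ch["ais_marker"], config, reference)
        syn = _prepare(ch["presyn_marker"], config, reference)
        ais_list = segment.segment_ais(ais_ch, thr["ais"], config.min_ais_length_um)
        puncta = segment.detect_puncta(syn, thr["puncta"], p, config.marker_class)
        if not ais_list:
            logger.warning("no AIS found for cell %s", row.key.cell_id)
            return []
        ais = max(ais_list, key=lambda a: a.length_um)
        contacts = apposition.call_contacts(puncta, ais, p.contact_min_overlap_um2)
        rec = apposition.linear_density(contacts, ais, row.key)
        out.append({**base, "value": rec.density, "count": rec.count,
                    "normalizer_um": rec.normalizer, "structure": "ais"})

    elif config.mode == "synapse_pairs_on_pv":
        surface = _prepare(ch["surface_reporter"], config, reference)
        pre_ch = _prepare(ch["presyn_marker"], config, reference)
        post_ch = _prepare(ch["postsyn_marker"], config, reference)
        somas = segment.segment_somata(surface, thr["soma"], config.min_soma_area_um2)
        pre = segment.detect_puncta(pre_ch, thr["puncta"], p, config.marker_class)
        post = segment.detect_puncta(
            post_ch, thr.get("post_puncta", thr["puncta"]), p,
            config.marker_class if config.marker_class in ("Gephyrin", "PSD95")
            else "PSD95",
        )
        pairs = apposition.pair_synapses(pre, post, p.pair_min_overlap_um2)
        if "process" in ch:
            proc_ch = _prepare(ch["process"], config, reference)
            proc_mask = proc_ch.pixels >= thr["process"]
            pairs = apposition.assign_pairs_to_process(
                pairs, pre, proc_mask, p.process_min_overlap_um2
            )
        if not somas:
            logger.warning("no PV soma found for cell %s", row.key.cell_id)
            return []
        soma = max(somas, key=lambda s: s.area_um2)
        pre_on_soma = {
            c.punctum_label
            for c in apposition.call_contacts(pre, soma, p.contact_min_overlap_um2)
        }
        n = sum(1 for pair in pairs if pair.pre_label in pre_on_soma)
        rec = apposition.linear_density(n, soma, row.key)
        out.append({**base, "value": rec.density, "count": n,
                    "normalizer_um": rec.normalizer, "structure": "soma"})

    elif config.mode == "soma_neuropil_tag":
        surface = ch["surface_reporter"]
        tag_ch = ch["tag"]
        if reference is not None:
            surface = match_histogram(surface, reference)
        somas = segment.segment_somata(surface, thr["soma"], config.min_soma_area_um2)
        neuropil = segment.segment_neuropil(surface, thr["neuropil"], somas)
        tag_thr = thr.get("tag")
        if tag_thr is None:
            tag_thr = segment.threshold_isodata(tag_ch)
        tag_mask = tag_ch.pixels >= tag_thr
        if not somas:
            logger.warning("no soma found for ROI %s", row.key.cell_id)
            return []
        pct_soma = localization.score_soma_tag(somas, tag_mask)
        pct_np = localization.score_neuropil_tag(neuropil, tag_mask)
        out.append({**base, "value": pct_soma, "measure": "pct_tag_positive_somas"})
        out.append({**base, "cell_id": row.key.cell_id + "_np", "value": pct_np,
                    "measure": "pct_neuropil_coloc"})

    elif config.mode == "roi_puncta":
        syn = _prepare(ch["presyn_marker"], config, reference)
        puncta = segment.detect_puncta(syn, thr["puncta"], p, config.marker_class)
        if not row.rois:
            raise ConfigError(f"mode roi_puncta needs rois for cell {row.key.cell_id}")
        for ri, (x0, y0, w, h) in enumerate(row.rois):
            roi = Roi(x0, y0, w, h, config.pixel_size_um)
            roi.validate_inside(syn.shape)
            rec = localization.roi_puncta_density(puncta, roi, roi_id=str(ri))
            out.append({**base, "cell_id": f"{row.key.cell_id}_roi{ri}",
                        "value": rec.count_per_um2, "count": rec.count,
                        "roi_area_um2": roi.area_um2})
    return out


def run(config: RunConfig) -> dict:
    """Execute one configured analysis; returns paths of written outputs.

    Writes densities.csv (cell-level values), stats_report.json (the
    normality-gated group comparison on per-animal means, when the design
    allows one), ecdf.csv (per-group cumulative frequencies of cell-level
    values), and run.log (parameter echo).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("mode=%s pixel_size_um=%s", config.mode, config.pixel_size_um)
        logger.info("thresholds=%s", config.thresholds)
        logger.info("quant_params=%s", config.params)
        logger.info("preprocess=%s condition=%s", config.preproc, config.condition)
        reference = None
        if config.reference_image is not None:
            ref_imgs = load_image(
                config.reference_image, config.pixel_size_um, {1: "surface_reporter"}
            )
            reference = ref_imgs[0]
            logger.info("histogram reference=%s", config.reference_image)

        rows: list[dict] = []
        for row in config.manifest:
            rows.extend(_measure_row(config, row, reference))
        if not rows:
            raise RuntimeError("no measurable structures in any manifest row")
        table = pd.DataFrame(rows)

        dens_path = out_dir / "densities.csv"
        write_measurements(table, dens_path)

        report: dict = {"mode": config.mode, "n_cells": len(table)}
        per_animal = stats.animal_means(table)
        groups = per_animal["group_label"].nunique()
        animals_ok = (per_animal.groupby("group_label").size() >= 2).all()
        if groups >= 2 and animals_ok:
            test = stats.compare_groups(per_animal, alpha=config.params.alpha)
            report["comparison"] = test.to_dict()
        else:
            report["comparison"] = None
            logger.info("skipping group comparison: %d group(s)", groups)
        report["per_group"] = stats.sem_summary(per_animal).to_dict(orient="records")
        stats_path = out_dir / "stats_report.json"
        stats_path.write_text(json.dumps(report, indent=2, default=float))

        ecdf_frames = []
        for g, grp in table.groupby("group_label"):
            e = stats.ecdf(grp["value"])
            e.insert(0, "group_label", g)
            ecdf_frames.append(e)
        ecdf_path = out_dir / "ecdf.csv"
        pd.concat(ecdf_frames, ignore_index=True).to_csv(ecdf_path, index=False)

        logger.info("wrote %s, %s, %s", dens_path, stats_path, ecdf_path)
        return {
            "densities": str(dens_path),
            "stats_report": str(stats_path),
            "ecdf": str(ecdf_path),
            "log": str(log_path),
            "table": table,
            "report": report,
        }
    finally:
        logger.removeHandler(handler)
        handler.close()
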