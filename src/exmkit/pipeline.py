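"""End-to-end runner: simulate -> segment -> measure -> analyse.

Given a :class:`~exmkit.config.RunConfig` the runner renders ``n_images``
scenes (or pre/post pairs, or two-channel halo scenes), segments and measures
every image, applies the population analysis matching the mode, and writes a
manifest listing every output file with its SHA-256 checksum.  Re-running
with the same config and seed reproduces identical measurement CSVs.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as eio
from . import morphometry, population, segmentation, synthgen
from .config import RunConfig

__all__ = ["run_pipeline", "truth_to_df", "samples_to_df", "calls_to_df"]

log = logging.getLogger(__name__)


def truth_to_df(cells: Sequence[synthgen.GroundTruthCell]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": c.id,
                "species": c.species,
                "x_um": c.centroid_um[0],
                "y_um": c.centroid_um[1],
                "orientation_rad": c.orientation_rad,
                "length_um": c.length_um,
                "width_um": c.width_um,
                "phenotype": c.phenotype,
                "halo_width_um": c.halo_width_um,
            }
            for c in cells
        ],
        columns=[
            "id",
            "species",
            "x_um",
            "y_um",
            "orientation_rad",
            "length_um",
            "width_um",
            "phenotype",
            "halo_width_um",
        ],
    )


def samples_to_df(samples: Sequence[morphometry.WidthSample]) -> pd.DataFrame:
    rows = []
    for s in samples:
        row = {
            "label": s.label,
            "width_um": s.width_um,
            "length_um": s.length_um,
            "aspect_ratio": s.aspect_ratio,
            "orientation_rad": s.orientation_rad,
        }
        for i, w in enumerate(s.widths_um, start=1):
            row[f"width_{i}_um"] = w
        row["flags"] = ";".join(s.flags)
        rows.append(row)
    cols = [
        "label",
        "width_um",
        "width_1_um",
        "width_2_um",
        "width_3_um",
        "width_4_um",
        "width_5_um",
        "length_um",
        "aspect_ratio",
        "orientation_rad",
        "flags",
    ]
    return pd.DataFrame(rows, columns=cols)


def calls_to_df(calls: Sequence[population.HaloCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": c.label,
                "cyto_width_um": c.cyto_width_um,
                "dna_width_um": c.dna_width_um,
                "ratio": c.ratio,
                "expanded": c.expanded,
            }
            for c in calls
        ],
        columns=["label", "cyto_width_um", "dna_width_um", "ratio", "expanded"],
    )


def _measure_image(
    img: np.ndarray, cfg: RunConfig
) -> tuple[segmentation.LabelImage, list[morphometry.WidthSample]]:
    labels = segmentation.segment(
        img, cfg.segmentation, pixel_size_um=cfg.scene.pixel_size_um
    )
    return labels, morphometry.measure(labels)


def _population(frames: list[pd.DataFrame]) -> population.WidthPopulation:
    widths = np.concatenate([f["width_um"].to_numpy() for f in frames])
    ids = np.concatenate(
        [np.full(len(f), i) for i, f in enumerate(frames)]
    )
    return population.WidthPopulation(widths_um=widths, image_ids=ids)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured pipeline; returns the manifest dict."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20))
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ps = cfg.scene.pixel_size_um
    image_seeds = [
        int(s) for s in np.random.SeedSequence(cfg.seed).generate_state(cfg.n_images)
    ]
    outputs: list[Path] = []
    summary: dict = {"mode": cfg.mode, "seed": cfg.seed}

    def save_image(name: str, arr: np.ndarray) -> None:
        outputs.append(eio.write_image(out / name, arr.astype(np.float32), ps))

    def save_labels(name: str, labels: segmentation.LabelImage) -> None:
        outputs.append(
            eio.write_image(out / name, labels.labels.astype(np.uint16), ps)
        )

    def save_table(name: str, df: pd.DataFrame) -> None:
        outputs.append(eio.write_table(df, out / name))

    try:
        if cfg.mode == "scene":
            frames = []
            for i, s in enumerate(image_seeds):
                img, truth = synthgen.render_scene(cfg.scene, s)
                labels, samples = _measure_image(img, cfg)
                save_image(f"image_{i:03d}.tif", img)
                save_labels(f"labels_{i:03d}.tif", labels)
                save_table(f"truth_{i:03d}.csv", truth_to_df(truth))
                df = samples_to_df(samples)
                df.insert(0, "image", i)
                save_table(f"widths_{i:03d}.csv", df)
                frames.append(df)
            combined = pd.concat(frames, ignore_index=True)
            save_table("widths.csv", combined)
            summary["n_cells"] = int(len(combined))
        elif cfg.mode == "pair":
            pre_frames, post_frames = [], []
            for i, s in enumerate(image_seeds):
                pre, post, pre_t, post_t = synthgen.render_expansion_pair(
                    cfg.scene, s
                )
                for tag, img, truth in (
                    ("pre", pre, pre_t),
                    ("post", post, post_t),
                ):
                    labels, samples = _measure_image(img, cfg)
                    save_image(f"{tag}_{i:03d}.tif", img)
                    save_labels(f"{tag}_labels_{i:03d}.tif", labels)
                    save_table(f"{tag}_truth_{i:03d}.csv", truth_to_df(truth))
                    df = samples_to_df(samples)
                    df.insert(0, "image", i)
                    save_table(f"{tag}_widths_{i:03d}.csv", df)
                    (pre_frames if tag == "pre" else post_frames).append(df)
            result = population.expansion_ratio(
                _population(pre_frames),
                _population(post_frames),
                n_boot=cfg.n_boot,
                seed=cfg.seed,
            )
            summary.update(asdict(result))
        elif cfg.mode == "halo":
            calls_by_rep = []
            for i, s in enumerate(image_seeds):
                cyto, dna, truth = synthgen.render_halo_scene(
                    cfg.scene, cfg.halo_fraction, cfg.halo_factor, s
                )
                labels, _ = _measure_image(cyto, cfg)
                calls = population.detect_halo(
                    labels, dna, cutoff=cfg.halo_cutoff
                )
                save_image(f"cyto_{i:03d}.tif", cyto)
                save_image(f"dna_{i:03d}.tif", dna)
                save_labels(f"cyto_labels_{i:03d}.tif", labels)
                save_table(f"truth_{i:03d}.csv", truth_to_df(truth))
                save_table(f"halo_{i:03d}.csv", calls_to_df(calls))
                calls_by_rep.append(calls)
            frac, sem = population.halo_fraction(calls_by_rep)
            summary.update(
                {
                    "fraction": frac,
                    "sem": sem,
                    "n_cells": int(sum(len(c) for c in calls_by_rep)),
                }
            )
    except Exception:
        # partial manifest for whatever was written before the failure
        manifest = _manifest(cfg, outputs, summary | {"status": "failed"})
        eio.write_json(manifest, out / "manifest.json")
        raise

    manifest = _manifest(cfg, outputs, summary | {"status": "ok"})
    eio.write_json(manifest, out / "manifest.json")
    return manifest


def _manifest(cfg: RunConfig, outputs: list[Path], summary: dict) -> dict:
    return {
        "seed": cfg.seed,
        "summary": summary,
        "outputs": [
            {"path": p.name, "sha256": eio.sha256_of(p)} for p in outputs
        ],
    }
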