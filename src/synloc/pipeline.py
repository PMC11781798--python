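"""End-to-end pipeline orchestration with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .config import load_config
from .group_stats import stats_decision_tree
from .li_core import build_membrane_mask, compute_li_map, region_mean_li
from .puncta import (
    classify_puncta_by_membrane,
    detect_puncta,
    puncta_to_records,
    receptor_adjacency,
)
from .rendering import RenderSpec, render_li_overlay, save_render
from .synthetic_data import NeuronVolumeParams, generate_neuron_volume
from .volume_io import write_group_table, write_label_map, write_volume
from .volume_io import GroupTable
import tifffile

__all__ = ["RunManifest", "PipelineStageError", "run_pipeline"]


class PipelineStageError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    """Record of one pipeline run, sufficient to re-run it bit-identically
    for the deterministic stages."""

    config: dict[str, Any]
    seed: int
    version: str = __version__
    outputs: dict[str, str] = field(default_factory=dict)
    input_hashes: dict[str, str] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)
    error: dict[str, str] | None = None

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict[str, Any] | str | Path | None, outdir: str | Path) -> RunManifest:
    """Run synth -> mask -> LI -> render -> puncta -> stats, writing all
    artifacts plus a manifest under ``outdir``.

    A stage failure is recorded in the manifest (alongside any outputs
    already produced) and re-raised as :class:`PipelineStageError`.
    """
    cfg = config if isinstance(config, dict) else load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=int(cfg["seed"]))
    stage = "setup"
    try:
        stage = "synth"
        t0 = time.perf_counter()
        synth_over = dict(cfg.get("synthetic") or {})
        params = NeuronVolumeParams(**synth_over)
        volume, labels, truth = generate_neuron_volume(params, seed=cfg["seed"])
        vol_path = outdir / "volume.ome.tif"
        lab_path = outdir / "labels.tif"
        write_volume(vol_path, volume)
        write_label_map(lab_path, labels)
        manifest.outputs["volume"] = str(vol_path)
        manifest.outputs["labels"] = str(lab_path)
        manifest.input_hashes[str(vol_path)] = _sha256(vol_path)
        manifest.timings_s[stage] = time.perf_counter() - t0

        stage = "li"
        t0 = time.perf_counter()
        mask, thr = build_membrane_mask(
            volume, "membrane", cfg["mask"]["method"], cfg["mask"]["threshold"]
        )
        limap = compute_li_map(
            volume, "rgfp", "membrane", mask,
            winsorize_quantile=cfg["li"]["winsorize_quantile"],
        )
        li_path = outdir / "li.tif"
        tifffile.imwrite(li_path, limap.li.astype(np.float32))
        summaries = [
            region_mean_li(limap, labels, region, sample_id=f"synthetic-{cfg['seed']}")
            for region in sorted(set(labels.names.values()))
        ]
        summary_path = outdir / "region_summary.csv"
        pd.DataFrame([s.__dict__ for s in summaries]).to_csv(summary_path, index=False)
        manifest.outputs["li_map"] = str(li_path)
        manifest.outputs["region_summary"] = str(summary_path)
        manifest.timings_s[stage] = time.perf_counter() - t0

        stage = "render"
        t0 = time.perf_counter()
        rcfg = cfg["render"]
        spec = RenderSpec(
            colormap=rcfg["colormap"],
            li_range=tuple(rcfg["li_range"]),
            intensity_gamma=rcfg["intensity_gamma"],
            projection=rcfg["projection"],
        )
        rgb = render_li_overlay(limap, volume, "membrane", spec)
        render_path = outdir / "li_render.png"
        save_render(render_path, rgb)
        manifest.outputs["render"] = str(render_path)
        manifest.timings_s[stage] = time.perf_counter() - t0

        if "brp" in volume.channels:
            stage = "puncta"
            t0 = time.perf_counter()
            pcfg = cfg["puncta"]
            found = detect_puncta(
                volume, "brp",
                sigma_range_um=tuple(pcfg["sigma_range_um"]),
                peak_threshold=pcfg["peak_threshold"],
            )
            found = classify_puncta_by_membrane(
                found, mask, volume.voxel_size, theta_overlap=pcfg["theta_overlap"]
            )
            found = receptor_adjacency(
                found, volume, "rgfp",
                theta_adj=pcfg["theta_adj"], auto_k=pcfg["auto_k"],
            )
            puncta_path = outdir / "puncta.csv"
            pd.DataFrame(puncta_to_records(found)).to_csv(puncta_path, index=False)
            manifest.outputs["puncta"] = str(puncta_path)
            manifest.timings_s[stage] = time.perf_counter() - t0

        stage = "stats"
        t0 = time.perf_counter()
        if len(summaries) >= 2:
            # region-wise LI contrast on this single sample is a demo;
            # real comparisons take one data point per brain sample
            table = GroupTable(
                pd.DataFrame(
                    {
                        "sample_id": [s.sample_id for s in summaries],
                        "genotype": "synthetic",
                        "condition": "none",
                        "region": [s.region for s in summaries],
                        "measurement": [s.mean_li for s in summaries],
                    }
                ),
                condition_column="condition",
            )
            stats_path = outdir / "region_means.json"
            with open(stats_path, "w") as fh:
                json.dump(
                    {s.region: {"mean_li": s.mean_li, "n_valid_voxels": s.n_valid_voxels}
                     for s in summaries},
                    fh, indent=2,
                )
            manifest.outputs["stats"] = str(stats_path)
        manifest.timings_s[stage] = time.perf_counter() - t0
    except Exception as exc:  # record partial progress, then propagate
        manifest.error = {"stage": stage, "message": str(exc)}
        manifest.save(outdir / "manifest.json")
        raise PipelineStageError(stage, exc) from exc

    manifest.save(outdir / "manifest.json")
    manifest.outputs["manifest"] = str(outdir / "manifest.json")
    return manifest
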