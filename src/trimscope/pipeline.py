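"""End-to-end orchestration: simulate (optional) → register → segment →
quantify → gate → knockdown/percentile analysis → embedding.

Every stage writes its artifact under the run directory and logs the
parameters used; a manifest ties outputs to a hash of the configuration.
The same building blocks are importable for in-memory use (the acceptance
script and tests drive them directly).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .analyze import (
    estimate_knockdown,
    flag_died,
    gate_positive,
    separation_curve,
    top_percentile_filter,
    usable,
)
from .config import SimConfig
from .embedding import tsne_embed
from .imageset import ImageSet
from .presets import Preset, build_preset
from .quantify import column_name, max_project, measure_cells
from .register import ShiftReport, register_rounds
from .segment import LabelImage, derive_cytosol, expand_cells, segment_nuclei

__all__ = [
    "RunConfig",
    "FieldResult",
    "process_field",
    "simulate_and_measure",
    "run_delivery_experiment",
    "run_knockdown_experiment",
    "run_pipeline",
    "channel_column",
]

log = logging.getLogger("trimscope")


def channel_column(config: SimConfig, channel: str, stat: str = "mean") -> str:
    """CellTable column for a channel's first appearance across rounds."""
    for r, chans in enumerate(config.rounds):
        if channel in chans:
            return column_name(r, channel, stat)
    raise KeyError(f"channel {channel!r} not present in any round")


def _field_seed(base_seed: int, condition_idx: int, field_idx: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), condition_idx, field_idx])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class FieldResult:
    cells: pd.DataFrame
    shift_report: ShiftReport
    nuclei: LabelImage
    cell_labels: LabelImage
    cytosol: LabelImage
    aligned: ImageSet


def process_field(
    images: ImageSet,
    nuclear_channel: str = "Hoechst",
    pi_channel: str | None = None,
    threshold: float | None = None,
    min_area_px: int = 25,
    expand_radius_px: float = 12.0,
    subtract_background: bool = False,
    condition: str | None = None,
) -> FieldResult:
    """Register → segment → measure one field; flags died cells when a
    propidium-iodide-like channel is configured."""
    aligned, report = register_rounds(images, nuclear_channel=nuclear_channel)
    nuclear = max_project(aligned.rounds[0][nuclear_channel])
    nuclei = segment_nuclei(nuclear, threshold=threshold, min_area_px=min_area_px)
    cells = expand_cells(nuclei, radius_px=expand_radius_px)
    cytosol = derive_cytosol(cells, nuclei)
    table = measure_cells(
        cells,
        aligned,
        nuclei=nuclei,
        cytosol=cytosol,
        subtract_background=subtract_background,
        condition=condition,
    )
    if pi_channel is not None and len(table):
        col = None
        for r in range(aligned.n_rounds):
            if pi_channel in aligned.rounds[r]:
                col = column_name(r, pi_channel, "mean")
                break
        if col is not None:
            table = flag_died(table, col)
    return FieldResult(
        cells=table, shift_report=report, nuclei=nuclei,
        cell_labels=cells, cytosol=cytosol, aligned=aligned,
    )


def simulate_and_measure(
    config: SimConfig,
    n_cells_total: int,
    base_seed: int,
    condition_idx: int = 0,
    subtract_background: bool = True,
    keep_fields: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, list[FieldResult]]:
    """Simulate as many fields as needed for ``n_cells_total`` cells, run the
    image pipeline on each, and concatenate the per-cell tables (and ground
    truths). Field seeds derive deterministically from ``base_seed``."""
    from .simulate import simulate_field

    n_fields = max(1, -(-n_cells_total // config.n_cells))
    tables, gts, fields = [], [], []
    for f in range(n_fields):
        cfg = config.replace(seed=_field_seed(base_seed, condition_idx, f))
        field_id = f"{config.condition}_f{f:03d}"
        gt, images = simulate_field(cfg, field_id=field_id)
        res = process_field(
            images,
            nuclear_channel=cfg.nuclear_channel,
            pi_channel=cfg.pi_channel,
            subtract_background=subtract_background,
            condition=cfg.condition,
        )
        tables.append(res.cells)
        gt["field_id"] = field_id
        gts.append(gt)
        if keep_fields:
            fields.append(res)
        log.info(
            "field %s: %d cells segmented (%d usable)",
            field_id, len(res.cells), len(usable(res.cells)),
        )
    cells = pd.concat(tables, ignore_index=True)
    gt_all = pd.concat(gts, ignore_index=True)
    return cells, gt_all, fields


def run_delivery_experiment(
    preset: Preset | str,
    n_cells: int = 2100,
    n_null: int = 1400,
    seed: int = 0,
    gate_q: float = 0.99,
) -> dict:
    """Antibody-delivery readout: simulate treated + no-delivery null wells,
    run the full image pipeline, and gate antibody-positive cells. Returns the
    positive fraction and the excluded died-cell fraction."""
    if isinstance(preset, str):
        preset = build_preset(preset, seed=seed)
    cfg = preset.targeting
    ab_col = channel_column(cfg, cfg.ab_channel)
    cells, _, _ = simulate_and_measure(cfg, n_cells, seed, condition_idx=0)
    null_cfg = preset.null if preset.null is not None else cfg.replace(slo_dose=0.0)
    null_cells, _, _ = simulate_and_measure(null_cfg, n_null, seed, condition_idx=9)

    n_segmented = len(cells)
    died_fraction = float(cells.get("flag_died", pd.Series(False, index=cells.index)).mean())
    cells_ok = usable(cells)
    null_ok = usable(null_cells)
    gating = gate_positive(cells_ok, ab_col, null_ok, rule="quantile", q=gate_q)
    return {
        "preset": preset.name,
        "positive_fraction": gating.positive_fraction,
        "threshold": gating.threshold,
        "n_cells": n_segmented,
        "n_usable": len(cells_ok),
        "died_fraction": died_fraction,
        "gating": gating,
        "cells": cells,
        "null_cells": null_ok,
    }


def run_knockdown_experiment(
    preset: Preset | str,
    n_cells_per_condition: int = 2100,
    seed: int = 0,
    modes: tuple[str, ...] = ("bulk",),
    top_pct: float = 25.0,
    n_boot: int = 200,
) -> dict:
    """Knockdown readout: simulate targeting and NC conditions, run the image
    pipeline on both, and estimate the degradation fraction per mode."""
    if isinstance(preset, str):
        preset = build_preset(preset, seed=seed)
    cfg_t, cfg_c = preset.targeting, preset.nc
    if cfg_c is None:
        raise ValueError(f"preset {preset.name!r} has no NC condition")
    target_col = channel_column(cfg_t, cfg_t.target_channel)
    ab_col = channel_column(cfg_t, cfg_t.ab_channel)

    treated, gt_t, _ = simulate_and_measure(cfg_t, n_cells_per_condition, seed, condition_idx=0)
    control, gt_c, _ = simulate_and_measure(cfg_c, n_cells_per_condition, seed, condition_idx=1)
    treated_ok, control_ok = usable(treated), usable(control)

    null_cfg = preset.null if preset.null is not None else cfg_c.replace(slo_dose=0.0)
    null_cells, _, _ = simulate_and_measure(null_cfg, 1400, seed, condition_idx=9)
    null_ok = usable(null_cells)
    gat_t = gate_positive(treated_ok, ab_col, null_ok)
    gat_c = gate_positive(control_ok, ab_col, null_ok)

    estimates = {}
    for mode in modes:
        estimates[mode] = estimate_knockdown(
            treated_ok,
            control_ok,
            target_col,
            mode=mode,
            positive_treated=gat_t.positive,
            positive_control=gat_c.positive,
            ab_column=ab_col,
            top_pct=top_pct,
            n_boot=n_boot,
            seed=seed,
        )
    return {
        "preset": preset.name,
        "estimates": estimates,
        "positive_fraction": gat_t.positive_fraction,
        "treated": treated_ok,
        "control": control_ok,
        "ground_truth": pd.concat([gt_t, gt_c], ignore_index=True),
        "target_column": target_col,
        "ab_column": ab_col,
    }


# --------------------------------------------------------------------------
# File-based run orchestration
# --------------------------------------------------------------------------

_RUNCONFIG_FIELDS = {
    "preset",
    "n_cells_per_condition",
    "seed",
    "output_dir",
    "nuclear_channel",
    "gate_rule",
    "gate_q",
    "percentile_levels",
    "subtract_background",
    "expand_radius_px",
    "min_area_px",
    "n_boot",
    "embed_perplexity",
    "write_images",
}


@dataclass
class RunConfig:
    """Validated configuration for a file-writing pipeline run."""

    preset: str = "IKKa-3h"
    n_cells_per_condition: int = 1400
    seed: int = 0
    output_dir: str = "trimscope_run"
    nuclear_channel: str = "Hoechst"
    gate_rule: str = "quantile"
    gate_q: float = 0.99
    percentile_levels: tuple[float, ...] = (100, 50, 25, 10, 5)
    subtract_background: bool = True
    expand_radius_px: float = 12.0
    min_area_px: int = 25
    n_boot: int = 200
    embed_perplexity: float = 30.0
    write_images: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _RUNCONFIG_FIELDS
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        if "percentile_levels" in d:
            d = dict(d, percentile_levels=tuple(d["percentile_levels"]))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def validate(self) -> None:
        from .presets import PRESETS

        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {PRESETS}")
        if not 0 < self.gate_q < 1:
            raise ValueError("gate_q must be in (0, 1)")
        built = build_preset(self.preset, seed=self.seed)
        for chans in built.targeting.rounds:
            if self.nuclear_channel not in chans:
                raise ValueError(
                    f"nuclear channel {self.nuclear_channel!r} missing from round {chans}"
                )

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(run_config: RunConfig) -> Path:
    """Execute the full pipeline for a preset and write all stage artifacts.

    Outputs under ``output_dir``: simulated image sets + ground truth, shift
    reports, label summaries, the per-cell table, gating/knockdown JSON,
    separation curves, embedding coordinates, and ``manifest.json`` keyed by
    the config hash. Re-running with identical config reproduces every CSV
    byte for byte.
    """
    run_config.validate()
    outdir = Path(run_config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    preset = build_preset(run_config.preset, seed=run_config.seed)
    artifacts: dict[str, str] = {}

    conditions = ["targeting"]
    if preset.nc is not None and preset.nc.target_channel != preset.nc.ab_channel:
        conditions.append("NC")

    all_cells = []
    for ci, cond in enumerate(conditions):
        cfg = preset.condition_config(cond)
        cells, gt, fields = simulate_and_measure(
            cfg,
            run_config.n_cells_per_condition,
            run_config.seed,
            condition_idx=ci,
            subtract_background=run_config.subtract_background,
            keep_fields=True,
        )
        tio.write_table(gt, outdir / f"ground_truth_{cond}.csv")
        artifacts[f"ground_truth_{cond}"] = f"ground_truth_{cond}.csv"
        shift_all = {}
        for f_idx, fres in enumerate(fields):
            if run_config.write_images:
                tio.write_imageset(fres.aligned, outdir / "images", suffix="_aligned")
            shift_all[fres.aligned.field_id] = fres.shift_report.to_dict()
        tio.write_json(shift_all, outdir / f"shifts_{cond}.json")
        artifacts[f"shifts_{cond}"] = f"shifts_{cond}.json"
        all_cells.append(cells)
    cells = pd.concat(all_cells, ignore_index=True)
    tio.write_table(cells, outdir / "cell_table.csv")
    artifacts["cell_table"] = "cell_table.csv"

    cfg = preset.targeting
    ab_col = channel_column(cfg, cfg.ab_channel)
    null_cfg = preset.null if preset.null is not None else cfg.replace(slo_dose=0.0)
    null_cells, _, _ = simulate_and_measure(
        null_cfg, max(700, run_config.n_cells_per_condition // 2), run_config.seed,
        condition_idx=9, subtract_background=run_config.subtract_background,
    )
    cells_ok = usable(cells)
    gating = gate_positive(
        cells_ok, ab_col, usable(null_cells),
        rule=run_config.gate_rule, q=run_config.gate_q,
    )
    died_fraction = float(
        cells.get("flag_died", pd.Series(False, index=cells.index)).mean()
    )
    report: dict = {
        "gating": gating.to_dict(),
        "died_fraction": died_fraction,
        "n_cells_segmented": int(len(cells)),
        "n_cells_usable": int(len(cells_ok)),
    }

    if "NC" in conditions:
        target_col = channel_column(cfg, cfg.target_channel)
        treated = cells_ok[cells_ok["condition"] == "targeting"]
        control = cells_ok[cells_ok["condition"] == "NC"]
        gt_t = gate_positive(treated, ab_col, usable(null_cells), q=run_config.gate_q)
        gt_c = gate_positive(control, ab_col, usable(null_cells), q=run_config.gate_q)
        report["knockdown"] = {}
        for mode in ("bulk", "gated"):
            est = estimate_knockdown(
                treated, control, target_col, mode=mode,
                positive_treated=gt_t.positive, positive_control=gt_c.positive,
                n_boot=run_config.n_boot, seed=run_config.seed,
            )
            report["knockdown"][mode] = est.to_dict()
        curve = separation_curve(
            treated, control, target_col, ab_col,
            percentiles=run_config.percentile_levels,
        )
        tio.write_table(curve, outdir / "separation_curve.csv")
        artifacts["separation_curve"] = "separation_curve.csv"

        feats = [target_col, ab_col] + [
            channel_column(cfg, ch) for ch in cfg.phospho_link
        ]
        min_cells = int(3 * run_config.embed_perplexity) + 1
        if len(cells_ok) >= min_cells:
            emb = tsne_embed(
                cells_ok, feats,
                perplexity=run_config.embed_perplexity, seed=run_config.seed,
            )
            coords = emb.coords.copy()
            coords["condition"] = cells_ok["condition"].to_numpy()
            tio.write_table(coords, outdir / "embedding.csv")
            tio.write_json(emb.params(), outdir / "embedding_params.json")
            artifacts["embedding"] = "embedding.csv"
            if run_config.write_images:
                from .embedding import plot_embedding

                plot_embedding(emb, cells_ok, outdir / "embedding.png")
                artifacts["embedding_plot"] = "embedding.png"

    tio.write_json(report, outdir / "analysis.json")
    artifacts["analysis"] = "analysis.json"
    manifest = {
        "config": dataclasses.asdict(run_config),
        "config_hash": run_config.config_hash(),
        "preset": preset.name,
        "expected": preset.expected,
        "artifacts": artifacts,
    }
    tio.write_json(manifest, outdir / "manifest.json")
    return outdir
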