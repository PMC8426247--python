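"""Shared I/O, run configuration and the pipeline driver.

Tables are TSV with header rows; images are single-plane grayscale TIFF
(8/12/16-bit acquisitions are preserved as integers); configuration is
YAML with unknown keys rejected; every run writes an atomically-replaced
JSON run record with the config snapshot, software version, timestamps
and per-stage summary metrics.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "RunConfig",
    "RunRecord",
    "read_image",
    "write_image",
    "read_table",
    "write_table",
    "load_config",
    "save_config",
    "run_pipeline",
    "STAGES",
]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (one or more stages)."""

    stage: str
    inputs: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "."
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunRecord:
    config: dict
    version: str
    started: str
    finished: str
    metrics: dict = field(default_factory=dict)


def read_image(path: str | Path) -> np.ndarray:
    """Read a single-plane grayscale TIFF as a 2-D array.

    Integer acquisitions (8/12/16-bit) keep their integer values.
    Multi-channel or multi-plane files require an explicit channel
    selection upstream and are rejected here.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = tifffile.imread(path)
    if img.ndim != 2:
        raise ValueError(
            f"{path.name}: expected a single grayscale plane, got shape {img.shape}"
        )
    return img


def write_image(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(Path(path), image)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run config; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "stage" not in data:
        raise ValueError("config must name a stage")
    return RunConfig(**data)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def _atomic_write_json(payload: dict, path: Path) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# Pipeline driver


def _stage_simulate_cross(cfg: RunConfig, outdir: Path) -> dict:
    from .rescue import rescue_percent
    from .simulate.cross import CrossSimParams, generate_cross

    params = CrossSimParams(seed=cfg.seed, **cfg.params)
    counts = generate_cross(params)
    score = rescue_percent(counts)
    table = pd.DataFrame(
        [
            {
                "n_balanced_mut1": counts.n_balanced_mut1,
                "n_balanced_mut2": counts.n_balanced_mut2,
                "n_transhet": counts.n_transhet,
                "n_total_scored": counts.n_total_scored,
                "percent_rescue": score.percent_rescue,
            }
        ]
    )
    write_table(outdir / "cross.tsv", table)
    return {"percent_rescue": score.percent_rescue, "n_total_scored": counts.n_total_scored}


def _stage_simulate_counts(cfg: RunConfig, outdir: Path) -> dict:
    from .simulate.counts import CountSimParams, generate_count_table

    params_kw = dict(cfg.params)
    if "pattern_counts" in params_kw:
        params_kw["pattern_counts"] = {
            tuple(k.split("/")): v for k, v in params_kw["pattern_counts"].items()
        }
    params = CountSimParams(seed=cfg.seed, **params_kw)
    table, truth = generate_count_table(params)
    write_table(outdir / "counts.tsv", table)
    truth_df = pd.DataFrame(
        {
            "gene_id": table["gene_id"],
            "pattern": ["/".join(p) for p in truth.patterns],
            "planted_short": truth.planted_short,
            "planted_low": truth.planted_low,
        }
    )
    write_table(outdir / "counts_truth.tsv", truth_df)
    return {"n_genes": int(len(table))}


def _stage_rnaseq_categorize(cfg: RunConfig, outdir: Path) -> dict:
    from .expression import categorize_table

    table = read_table(cfg.inputs["counts"])
    analysis = categorize_table(table, **cfg.params)
    write_table(outdir / "assignments.tsv", analysis.assignments)
    write_table(outdir / "category_counts.tsv", analysis.counts)
    for pair, comp in analysis.comparisons.items():
        write_table(outdir / f"comparison_{pair[0]}_vs_{pair[1]}.tsv", comp)
    return {"n_retained": int(analysis.assignments["retained"].sum())}


def _stage_simulate_embryo(cfg: RunConfig, outdir: Path) -> dict:
    from .simulate.embryo import EmbryoSimParams, generate_embryo_pair

    lines = cfg.params.get("lines", {"line0": {"bound_fraction": 0.6, "n_nuclei": 3}})
    shared = {k: v for k, v in cfg.params.items() if k != "lines"}
    manifest = []
    for line, spec in lines.items():
        n_nuclei = spec.get("n_nuclei", 3)
        for i in range(n_nuclei):
            p = EmbryoSimParams(
                seed=cfg.seed + 1000 * len(manifest),
                bound_fraction=spec["bound_fraction"],
                **shared,
            )
            pair, truth = generate_embryo_pair(p)
            stem = f"{line}_n{i}"
            write_image(outdir / f"{stem}_interphase.tif", pair.interphase_image)
            write_image(outdir / f"{stem}_metaphase.tif", pair.metaphase_image)
            manifest.append(
                {
                    "pair_id": stem,
                    "line": line,
                    "embryo_id": i // 10,
                    "interphase": f"{stem}_interphase.tif",
                    "metaphase": f"{stem}_metaphase.tif",
                    "plate_axis_angle": p.plate_axis_angle,
                    "bound_fraction_truth": truth.bound_fraction,
                }
            )
    write_table(outdir / "manifest.tsv", pd.DataFrame(manifest))
    return {"n_pairs": len(manifest)}


def _stage_quantify_mitotic(cfg: RunConfig, outdir: Path) -> dict:
    from .mitotic_binding import NucleusFramePair, quantify_lines

    manifest = read_table(cfg.inputs["manifest"])
    root = Path(cfg.inputs["manifest"]).parent
    pairs_by_line: dict[str, list] = {}
    for _, row in manifest.iterrows():
        axis = row.get("plate_axis_angle")
        pair = NucleusFramePair(
            interphase_image=read_image(root / row["interphase"]).astype(float),
            metaphase_image=read_image(root / row["metaphase"]).astype(float),
            plate_axis_angle=None if pd.isna(axis) else float(axis),
        )
        pairs_by_line.setdefault(row["line"], []).append(pair)
    reference = cfg.params.get("reference_line") or next(iter(pairs_by_line))
    results = quantify_lines(pairs_by_line, reference)
    rows = [
        {
            "line": line,
            "percent_of_reference": r.percent_of_reference,
            "sd": r.sd,
            "n_nuclei": r.n_nuclei,
        }
        for line, r in results.items()
    ]
    write_table(outdir / "binding.tsv", pd.DataFrame(rows))
    profiles = pd.DataFrame(
        {line: r.mean_profile.values for line, r in results.items()}
    )
    write_table(outdir / "mean_profiles.tsv", profiles)
    return {line: float(r.percent_of_reference) for line, r in results.items()}


def _stage_simulate_fcs(cfg: RunConfig, outdir: Path) -> dict:
    from .simulate.fcs import FcsSimParams, generate_acf_dataset

    params = FcsSimParams(seed=cfg.seed, **cfg.params)
    curves, truth = generate_acf_dataset(params)
    rows = []
    for c, keep in zip(curves, truth.keep_flags):
        for lag, g in zip(c.lags, c.g):
            rows.append(
                {"curve_id": c.curve_id, "lag_s": lag, "g": g, "keep_truth": keep}
            )
    write_table(outdir / "curves.tsv", pd.DataFrame(rows))
    return {"n_curves": len(curves)}


def _stage_fit_fcs(cfg: RunConfig, outdir: Path) -> dict:
    from .fcs_kinetics import (
        AcfCurve,
        ObservationVolume,
        average_curves,
        fit_kinetics,
        screen_outliers,
    )

    df = read_table(cfg.inputs["curves"])
    volume = ObservationVolume(
        beam_waist_w=cfg.params.get("beam_waist_w", 0.2),
        structural_parameter_s=cfg.params.get("structural_parameter_s", 5.0),
    )
    model = cfg.params.get("model", "full_model")
    group_col = "nucleus_id" if "nucleus_id" in df.columns else None
    groups = df.groupby(group_col) if group_col else [("nucleus0", df)]
    rows = []
    for nucleus, sub in groups:
        curves = [
            AcfCurve(
                lags=c["lag_s"].to_numpy(),
                g=c["g"].to_numpy(),
                nucleus_id=str(nucleus),
                curve_id=str(cid),
            )
            for cid, c in sub.groupby("curve_id")
        ]
        kept, _ = screen_outliers(curves)
        fit = fit_kinetics(average_curves(kept), model, volume)
        rows.append(
            {
                "nucleus_id": nucleus,
                "model": fit.model,
                "n": fit.n,
                "Df": fit.Df,
                "kstar_on": fit.kstar_on,
                "koff": fit.koff,
                "bound_fraction": fit.bound_fraction,
                "residence_time": fit.residence_time,
                "rss": fit.fit_rss,
                "n_curves_kept": len(kept),
            }
        )
    out = pd.DataFrame(rows)
    write_table(outdir / "fits.tsv", out)
    return {"n_nuclei": int(len(out))}


def _stage_rescue_score(cfg: RunConfig, outdir: Path) -> dict:
    from .rescue import CrossCounts, rescue_percent

    df = read_table(cfg.inputs["counts"])
    rows = []
    for _, row in df.iterrows():
        score = rescue_percent(
            CrossCounts(
                n_balanced_mut1=int(row["n_balanced_mut1"]),
                n_balanced_mut2=int(row["n_balanced_mut2"]),
                n_transhet=int(row["n_transhet"]),
                line_label=str(row.get("line", "")),
            )
        )
        rows.append(
            {
                "line": score.line_label,
                "observed_transhet_fraction": score.observed_transhet_fraction,
                "percent_rescue": score.percent_rescue,
            }
        )
    out = pd.DataFrame(rows)
    write_table(outdir / "rescue.tsv", out)
    return {"n_lines": int(len(out))}


STAGES = {
    "simulate-embryo": _stage_simulate_embryo,
    "quantify-mitotic": _stage_quantify_mitotic,
    "simulate-fcs": _stage_simulate_fcs,
    "fit-fcs": _stage_fit_fcs,
    "simulate-counts": _stage_simulate_counts,
    "rnaseq-categorize": _stage_rnaseq_categorize,
    "simulate-cross": _stage_simulate_cross,
    "rescue-score": _stage_rescue_score,
}


def run_pipeline(config: RunConfig) -> RunRecord:
    """Execute one stage (or a chained list under stage="run") and write
    all outputs plus an atomic JSON run record.

    Deterministic given (config, seed).
    """
    from . import __version__

    started = datetime.datetime.now().isoformat()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    metrics: dict = {}
    if config.stage == "run":
        for sub in config.params.get("stages", []):
            sub_cfg = RunConfig(
                stage=sub["stage"],
                inputs=sub.get("inputs", {}),
                params=sub.get("params", {}),
                seed=sub.get("seed", config.seed),
                output_dir=str(outdir),
            )
            metrics[sub["stage"]] = _run_stage(sub_cfg, outdir)
    else:
        metrics[config.stage] = _run_stage(config, outdir)
    record = RunRecord(
        config=config.to_dict(),
        version=__version__,
        started=started,
        finished=datetime.datetime.now().isoformat(),
        metrics=metrics,
    )
    _atomic_write_json(dataclasses.asdict(record), outdir / "run_record.json")
    return record


def _run_stage(cfg: RunConfig, outdir: Path) -> dict:
    if cfg.stage not in STAGES:
        raise ValueError(f"unknown stage {cfg.stage!r}; known: {sorted(STAGES)}")
    return STAGES[cfg.stage](cfg, outdir)
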