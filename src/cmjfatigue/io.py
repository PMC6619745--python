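"""File formats, configuration and the end-to-end pipeline.

All tables are delimited text with a header row (UTF-8, decimal point).
Trace files are two-column CSVs (time_s, force_N), one per trial, indexed by
a manifest table.  Measurement time points are serialised as the labels
PRE, 0, 0.5, 1, 3, 6, 24, 48 — PRE is never a number.  A reproducibility
manifest (seed, config hash, package/library versions, stage timings) is
written with every pipeline run.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fpca import (DEFAULT_LAMBDAS, DEFAULT_N_BASIS, DEFAULT_N_GRID,
                   normalized_curve_table, run_fpca, run_pooled_fpca, stack_curves)
from .models import DEFAULT_SPECS, ModelSpec, run_all_models
from .pca import build_matrix, run_pca
from .processing import (FEATURE_COLUMNS, META_COLUMNS, ForceTrace,
                         concentric_segments, features_table)
from .synthetic import (FatigueParams, NoiseParams, StudyDesign, StudySimulation,
                        TIME_LABELS, TraceParams, simulate_study)

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.12g"


# ---------------------------------------------------------------------------
# trace and table I/O
# ---------------------------------------------------------------------------

def write_trace(trace: ForceTrace, path) -> None:
    pd.DataFrame({"time_s": trace.time, "force_n": trace.force}).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def read_trace(path, sample_rate: float | None = None, meta: dict | None = None) -> ForceTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    if sample_rate is None:
        sample_rate = 1.0 / float(np.median(np.diff(t)))
    return ForceTrace(t, df["force_n"].to_numpy(dtype=float), sample_rate, meta or {})


def write_study(sim: StudySimulation, out_dir) -> Path:
    """Write a simulated study: per-trial trace files, a manifest and the
    generating-truth table.  Returns the manifest path."""
    out = Path(out_dir)
    traces_dir = out / "traces"
    traces_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for trace in sim.traces:
        m = trace.meta
        name = f"{m['athlete_id']}_{m['workload']}_{m['time_point']}_{m['jump']}.csv"
        write_trace(trace, traces_dir / name)
        rows.append({k: m[k] for k in META_COLUMNS} | {"path": f"traces/{name}"})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    sim.truth.to_csv(out / "truth.csv", index=False, float_format=FLOAT_FMT)
    return manifest


def read_study_traces(manifest_path) -> list[ForceTrace]:
    manifest = pd.read_csv(manifest_path, dtype={"time_point": str})
    base = Path(manifest_path).parent
    return [
        read_trace(base / row.path,
                   meta={k: getattr(row, k) for k in META_COLUMNS})
        for row in manifest.itertuples()
    ]


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"time_point": str})


# ---------------------------------------------------------------------------
# column mapping for third-party exports
# ---------------------------------------------------------------------------

UNIT_VOCAB = {
    "rel_peak_force": ("BW",),
    "rel_peak_power": ("W/kg",),
    "t_con_s": ("s", "ms"),
    "t_peak_force_s": ("s", "ms"),
}
REQUIRED_FIELDS = tuple(META_COLUMNS) + tuple(FEATURE_COLUMNS)


@dataclass(frozen=True)
class ColumnMapping:
    """Maps canonical field names to the column labels of a foreign feature
    table (e.g. a deposited study export whose schema is not ours), with
    unit declarations from a closed vocabulary."""

    columns: Mapping[str, str]
    units: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [f for f in REQUIRED_FIELDS if f not in self.columns]
        if missing:
            raise ValueError(f"column mapping lacks required fields: {missing}")
        if len(set(self.columns.values())) != len(self.columns):
            raise ValueError("two canonical fields map to the same source column")
        for fld, unit in self.units.items():
            allowed = UNIT_VOCAB.get(fld)
            if allowed is None or unit not in allowed:
                raise ValueError(
                    f"unit {unit!r} for {fld!r} not in vocabulary {allowed}"
                )

    @classmethod
    def identity(cls) -> "ColumnMapping":
        return cls({f: f for f in REQUIRED_FIELDS})

    @classmethod
    def from_yaml(cls, path) -> "ColumnMapping":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(raw.get("columns", {}), raw.get("units", {}))


def read_features(path, mapping: ColumnMapping | None = None) -> pd.DataFrame:
    """Read a long-format feature table, canonicalising columns and units.

    Unmapped required columns raise an error listing the candidates present
    in the file; declared millisecond times are converted to seconds.
    """
    mapping = mapping or ColumnMapping.identity()
    df = pd.read_csv(path)
    missing = [src for src in mapping.columns.values() if src not in df.columns]
    if missing:
        raise ValueError(
            f"source columns {missing} not found; file has {list(df.columns)}"
        )
    out = df.rename(columns={v: k for k, v in mapping.columns.items()})
    out = out[[c for c in out.columns if c in REQUIRED_FIELDS]]
    for fld, unit in mapping.units.items():
        if unit == "ms":
            out[fld] = out[fld] / 1000.0
    out["time_point"] = out["time_point"].astype(str)
    logger.info("read %d feature rows from %s", len(out), path)
    return out


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated parameters for a full pipeline run."""

    seed: int = 0
    design: StudyDesign = field(default_factory=StudyDesign)
    fatigue: FatigueParams = field(default_factory=FatigueParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    trace: TraceParams = field(default_factory=TraceParams)
    n_grid: int = DEFAULT_N_GRID
    n_basis: int = DEFAULT_N_BASIS
    lambda_grid: tuple = DEFAULT_LAMBDAS
    specs: tuple = DEFAULT_SPECS
    write_traces: bool = False
    verbose: bool = False

    def validate(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if self.n_grid < 21:
            raise ValueError("n_grid must be >= 21")
        if not 4 <= self.n_basis <= self.n_grid:
            raise ValueError("n_basis must lie in [4, n_grid]")
        if any(l <= 0 for l in self.lambda_grid):
            raise ValueError("lambda grid must be positive")
        # the dataclass constructors validate design/fatigue on creation

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        if "design" in raw:
            kwargs["design"] = StudyDesign(**raw["design"])
        if "fatigue" in raw:
            f = dict(raw["fatigue"])
            kwargs["fatigue"] = FatigueParams(**f)
        if "noise" in raw:
            kwargs["noise"] = NoiseParams(**raw["noise"])
        if "trace" in raw:
            kwargs["trace"] = TraceParams(**raw["trace"])
        for key in ("n_grid", "n_basis", "write_traces", "verbose"):
            if key in raw:
                kwargs[key] = raw[key]
        if "lambda_grid" in raw:
            kwargs["lambda_grid"] = tuple(float(x) for x in raw["lambda_grid"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def hash(self) -> str:
        blob = json.dumps(
            {
                "seed": self.seed,
                "design": asdict(self.design) | {"workloads": list(self.design.workloads),
                                                 "time_labels": list(self.design.time_labels)},
                "fatigue": {"d_w": dict(self.fatigue.d_w), "alpha": self.fatigue.alpha,
                            "tau_m": self.fatigue.tau_m, "tau_p": self.fatigue.tau_p},
                "noise": asdict(self.noise),
                "trace": asdict(self.trace),
                "n_grid": self.n_grid, "n_basis": self.n_basis,
                "lambda_grid": list(self.lambda_grid),
            },
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# the end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    out_dir: Path
    features: pd.DataFrame
    pca_variance: pd.DataFrame
    fpca_variance: pd.DataFrame
    report_table: pd.DataFrame


def pipeline_run(config: RunConfig, out_dir) -> PipelineResult:
    """Simulate -> extract -> stratified PCA -> fPCA -> mixed models.

    Deterministic given the seed; every stage's outputs are written as
    delimited text, and a manifest.json records versions, seed, config hash
    and stage timings.  A stage failure aborts with the stage name while
    preserving the outputs already written.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        sim = simulate_study(
            design=config.design, fatigue=config.fatigue, rng_seed=config.seed,
            trace_params=config.trace, noise=config.noise,
        )
        if config.write_traces:
            write_study(sim, out)
        timings[stage] = time.perf_counter() - t0

        stage = "extract"
        t0 = time.perf_counter()
        feats = features_table(sim.traces)
        segments = concentric_segments(sim.traces)
        curves = normalized_curve_table(segments, n_grid=config.n_grid)
        write_table(feats, out / "features.csv")
        write_table(curves, out / "curves.csv")
        timings[stage] = time.perf_counter() - t0

        stage = "pca"
        t0 = time.perf_counter()
        labels = tuple(config.design.time_labels)
        matrix = build_matrix(feats, time_labels=labels)
        pca_res = run_pca(matrix)
        write_table(
            pd.DataFrame(pca_res.loadings, index=pca_res.columns,
                         columns=[f"PC{i+1}" for i in range(pca_res.n_components)])
            .rename_axis("variable").reset_index(),
            out / "pca_loadings.csv",
        )
        scores_df = pca_res.index.copy()
        for i in range(pca_res.n_components):
            scores_df[f"PC{i+1}"] = pca_res.scores[:, i]
        write_table(scores_df, out / "pca_scores.csv")
        pca_var = pd.DataFrame({
            "PC": np.arange(1, pca_res.n_components + 1),
            "proportion": pca_res.proportions,
            "cumulative": np.cumsum(pca_res.proportions),
        })
        write_table(pca_var, out / "pca_variance.csv")
        timings[stage] = time.perf_counter() - t0

        stage = "fpca"
        t0 = time.perf_counter()
        coefs, index, basis, lam = stack_curves(
            curves, slot_labels=labels, n_basis=config.n_basis,
            lambdas=config.lambda_grid,
        )
        fres = run_fpca(coefs, basis, slot_labels=labels, index=index)
        grid = np.linspace(0.0, 1.0, config.n_grid)
        eig_rows = []
        for pc in range(1, min(4, fres.n_components) + 1):
            for s, lab in enumerate(fres.slot_labels):
                eig_rows.append(
                    {"PC": pc, "time_point": lab}
                    | {f"g{i}": v for i, v in enumerate(fres.evaluate(pc, s, grid))}
                )
        write_table(pd.DataFrame(eig_rows), out / "fpca_eigenfunctions.csv")
        fsc = fres.index.copy()
        for i in range(min(8, fres.n_components)):
            fsc[f"PC{i+1}"] = fres.scores[:, i]
        write_table(fsc, out / "fpca_scores.csv")
        fpca_var = pd.DataFrame({
            "PC": np.arange(1, fres.n_components + 1),
            "proportion": fres.proportions,
            "cumulative": np.cumsum(fres.proportions),
        })
        write_table(fpca_var, out / "fpca_variance.csv")
        pooled = run_pooled_fpca(coefs, basis, slot_labels=labels, index=index)
        heat = pooled.index.copy()
        for s, lab in enumerate(pooled.slot_labels):
            heat[f"PC3@{lab}"] = pooled.slot_scores(3)[:, s]
        write_table(heat, out / "fpca_pooled_pc3_scores.csv")
        timings[stage] = time.perf_counter() - t0

        stage = "predict"
        t0 = time.perf_counter()
        report = run_all_models(feats, curves, specs=config.specs,
                                n_basis=config.n_basis, lam=lam,
                                baseline_labels=labels)
        write_table(report.fit_table, out / "model_fits.csv")
        write_table(report.lrt_table, out / "model_lrt.csv")
        report.to_json(out / "model_report.json")
        timings[stage] = time.perf_counter() - t0
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest = {
        "package_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config_hash": config.hash(),
        "smoothing_lambda": lam,
        "stage_timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("pipeline complete in %.1f s", sum(timings.values()))
    return PipelineResult(out, feats, pca_var, fpca_var, report.fit_table)
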