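"""End-to-end pipeline runner.

Stage order: delta calibration -> prior box -> seed optimization -> local
LHS around the seed point -> PCA rotation/extension -> rotated LHS ->
QOI evaluation and masking -> feasibility report (count cascade, longest
consecutive run, consistency verdicts, GA fallback, relaxed bounds) ->
prediction intervals and growth fit -> surrogate-fidelity sweep ->
non-convexity probe -> feasible/infeasible classification.

Every stage persists plain CSV/JSON artifacts into the run directory and
is resumable: when its artifacts already exist they are loaded instead of
recomputed, so deleting downstream artifacts and re-running reproduces
them byte-identically (synthetic mode).  All randomness flows from the
master seed through named substreams.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Optional, Union

import numpy as np
import yaml

from . import __version__
from ._rng import substream_seed
from .classify import assemble_classes, cv_classify, downsample
from .feasibility import (
    apply_bounds,
    batch_from_csv,
    batch_to_csv,
    consistency_verdict,
    convexity_check,
    count_at_least,
    evaluate_batch,
    feasible_subset,
    find_nonconvex_pair,
    ga_search,
    longest_consecutive_feasible,
    segment_scan,
)
from .prediction import comparison_table, fit_linear_growth, interval_series
from .prior_region import (
    PriorSpec,
    build_box,
    calibrate_all_deltas,
    find_seed_point,
    lhs_sample,
    local_box,
    pca_region,
    samples_from_csv,
    samples_to_csv,
    volume_ratio,
    RotatedRegion,
)
from .qoi_data import load_qoi_table, relax_bounds
from .surrogate_diag import shrink_sweep
from .synthetic_model import PARAMETER_NAMES, SyntheticAlkaneModel, default_config

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "StageError", "run_pipeline", "load_config"]


class ConfigError(ValueError):
    """Invalid run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Resolved pipeline configuration (desk-scale defaults)."""

    seed: int
    outdir: Path
    model: str = "synthetic"
    qoi_table: str = "default"
    calibration_qoi: int = 4
    calibration_target: float = 10.0
    calibration_tol: float = 1e-3
    k_report: float = 0.4
    seed_subset: tuple[int, ...] = (5, 6)
    seed_budget: int = 5000
    local_n: int = 20000
    local_rel: float = 1e-3
    pca_extension: float = 10.0
    rotated_n: int = 100000
    prediction_subset: tuple[int, ...] = (3, 4, 5, 6, 7, 8)
    prediction_molecules: tuple[int, ...] = tuple(range(2, 21))
    growth_fit_range: tuple[int, int] = (8, 20)
    ga_subset: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)
    ga_budget: int = 6000
    relaxed_half_width: float = 1.0
    fidelity_k: tuple[float, ...] = (0.01, 0.02, 0.05, 0.1, 0.2, 0.4, 1.0)
    fidelity_n: int = 3000
    fidelity_folds: int = 5
    probe_qoi: int = 6
    classify_per_class: int = 10000
    classify_trees: int = 500
    classify_folds: int = 5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("config is missing the master seed")
        self.seed = int(self.seed)
        self.outdir = Path(self.outdir)
        if self.model not in ("synthetic",):
            raise ConfigError(
                f"unsupported model {self.model!r}; the pipeline runs the "
                "synthetic model (external adapters are evaluate-only)"
            )
        for name in ("seed_budget", "local_n", "rotated_n", "ga_budget",
                     "fidelity_n", "classify_per_class", "classify_trees"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if not (0 < self.k_report <= 1):
            raise ConfigError("k_report must be in (0, 1]")
        if self.qoi_table != "default" and not Path(self.qoi_table).exists():
            raise ConfigError(f"QOI table file not found: {self.qoi_table}")


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if "seed" not in raw:
        raise ConfigError(f"{path}: config is missing the master seed")
    if "outdir" not in raw:
        raise ConfigError(f"{path}: config is missing the output directory")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("seed_subset", "prediction_subset", "prediction_molecules",
                "growth_fit_range", "ga_subset", "fidelity_k"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def _write_json(path: Path, payload: Any) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8")


def _log_stage(name: str, t0: float, **info: Any) -> None:
    details = " ".join(f"{k}={v}" for k, v in info.items())
    logger.info("stage=%s wall_s=%.2f %s", name, time.time() - t0, details)


STAGE_ORDER = (
    "calibrate", "prior_box", "seed_search", "local_sampling", "pca_region",
    "rotated_sampling", "feasibility", "prediction", "fidelity", "probe",
    "classify",
)


def run_pipeline(
    config: RunConfig, resume: bool = True, until: Optional[str] = None
) -> dict:
    """Execute (or resume) the pipeline; returns the run manifest.

    ``until`` stops after the named stage (see :data:`STAGE_ORDER`), which
    is how the per-stage CLI subcommands reuse the orchestration.
    """
    if until is not None and until not in STAGE_ORDER:
        raise ConfigError(f"unknown stage {until!r}; expected one of {STAGE_ORDER}")
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "config": {
            k: (str(v) if isinstance(v, Path) else list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    table = load_qoi_table(config.qoi_table)
    model = SyntheticAlkaneModel(default_config())

    def run_stage(name, fn):
        t0 = time.time()
        try:
            info, payload = fn()
        except (StageError, ConfigError):
            _write_json(out / "manifest.json", manifest)
            raise
        except Exception as exc:
            _write_json(out / "manifest.json", manifest)
            raise StageError(name, str(exc)) from exc
        manifest["stages"][name] = {"wall_s": round(time.time() - t0, 3), **info}
        _log_stage(name, t0, **info)
        return payload

    def _finish() -> dict:
        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        _write_json(out / "manifest.json", manifest)
        return manifest

    # ---- stage: calibrate -------------------------------------------------
    deltas_path = out / "deltas.csv"

    def _calibrate():
        if resume and deltas_path.exists():
            import pandas as pd
            df = pd.read_csv(deltas_path, float_precision="round_trip")
            deltas, achieved = df["delta"].to_numpy(), df["achieved"].to_numpy()
        else:
            deltas, achieved = calibrate_all_deltas(
                model, n=config.calibration_qoi,
                target=config.calibration_target, tol=config.calibration_tol)
            with open(deltas_path, "w", encoding="utf-8") as fh:
                fh.write("name,delta,achieved\n")
                for name, d, a in zip(PARAMETER_NAMES, deltas, achieved):
                    fh.write(f"{name},{float(d)!r},{float(a)!r}\n")
        info = {"n_parameters": len(deltas),
                "max_target_dev": float(np.max(np.abs(
                    achieved - config.calibration_target)))}
        return info, deltas

    deltas = run_stage("calibrate", _calibrate)
    if until == "calibrate":
        return _finish()
    spec = PriorSpec(np.asarray(model.nominal.values), deltas, 1.0)

    # ---- stage: prior box -------------------------------------------------
    def _prior():
        box = build_box(spec)
        box.to_json(out / "prior_box.json")
        return {"k_report": config.k_report,
                "volume_ratio": volume_ratio(config.k_report, len(deltas))}, box

    run_stage("prior_box", _prior)
    if until == "prior_box":
        return _finish()

    # ---- stage: seed search ----------------------------------------------
    seed_path = out / "seed_point.json"

    def _seed():
        if resume and seed_path.exists():
            d = json.loads(seed_path.read_text(encoding="utf-8"))
        else:
            result = find_seed_point(model, table, config.seed_subset,
                                     budget=config.seed_budget)
            d = {"x_opt": result.x_opt.tolist(),
                 "objective": result.objective,
                 "feasible": result.feasible,
                 "n_evals": result.n_evals,
                 "subset": list(config.seed_subset)}
            _write_json(seed_path, d)
        info = {"objective": d["objective"], "feasible": d["feasible"]}
        return info, np.array(d["x_opt"])

    x_opt = run_stage("seed_search", _seed)
    if until == "seed_search":
        return _finish()

    # ---- stage: local sampling -------------------------------------------
    members_path = out / "local_feasible_members.csv"

    def _local():
        if resume and members_path.exists():
            members = samples_from_csv(members_path)
        else:
            box = local_box(x_opt, config.local_rel)
            X = lhs_sample(box, config.local_n,
                           substream_seed(config.seed, "local-lhs"))
            from .qoi_data import QOITable
            sub_table = QOITable(table[e] for e in config.seed_subset)
            local_batch = apply_bounds(
                evaluate_batch(model, X, config.seed_subset), sub_table)
            fs = feasible_subset(local_batch, config.seed_subset)
            members = local_batch.params[fs.members]
            samples_to_csv(members, members_path)
        if members.shape[0] == 0:
            raise StageError("local_sampling",
                             "no feasible local samples for the seed subset")
        info = {"n_samples": config.local_n, "n_members": int(members.shape[0])}
        return info, members

    members = run_stage("local_sampling", _local)
    if until == "local_sampling":
        return _finish()

    # ---- stage: PCA region ------------------------------------------------
    region_path = out / "rotated_region.json"

    def _pca():
        if resume and region_path.exists():
            region = RotatedRegion.from_json(
                region_path.read_text(encoding="utf-8"))
        else:
            region = pca_region(members, extension=config.pca_extension)
            region.to_json(region_path)
        return {"extension": config.pca_extension,
                "n_input_samples": int(members.shape[0])}, region

    region = run_stage("pca_region", _pca)
    if until == "pca_region":
        return _finish()

    # ---- stage: rotated sampling + masking -------------------------------
    batch_dir = out / "rotated_batch"

    def _rotated():
        stem = "rotated"
        if resume and (batch_dir / f"{stem}_mask.csv").exists():
            b = batch_from_csv(batch_dir, stem)
        else:
            X = lhs_sample(region, config.rotated_n,
                           substream_seed(config.seed, "rotated-lhs"))
            b = apply_bounds(evaluate_batch(model, X, table.indices), table)
            batch_to_csv(b, batch_dir, stem)
        return {"n_samples": b.n_rows, "n_failed": int(np.sum(~b.ok))}, b

    batch = run_stage("rotated_sampling", _rotated)
    if until == "rotated_sampling":
        return _finish()

    # ---- stage: feasibility report ---------------------------------------
    def _feasibility():
        cascade = {m: count_at_least(batch, m)
                   for m in range(1, len(table.indices) + 1)}
        longest = longest_consecutive_feasible(batch, table)
        full = consistency_verdict(batch, table.indices)
        pred = consistency_verdict(batch, config.prediction_subset)
        ga = ga_search(model, table, config.ga_subset, region,
                       budget=config.ga_budget,
                       seed=substream_seed(config.seed, "ga"))
        relaxed = apply_bounds(batch, relax_bounds(table, config.relaxed_half_width))
        relaxed_full = consistency_verdict(relaxed, table.indices)
        summary = {
            "count_at_least": cascade,
            "longest_consecutive": (list(longest.indices) if longest else []),
            "longest_consecutive_members": (longest.n_members if longest else 0),
            "full_subset": {"verdict": full.label, "n_members": full.n_members},
            "prediction_subset": {"subset": list(pred.subset),
                                  "verdict": pred.label,
                                  "n_members": pred.n_members},
            "ga_fallback": {"subset": list(config.ga_subset),
                            "violation": ga.violation,
                            "feasible": ga.feasible},
            "relaxed_full_subset": {"half_width": config.relaxed_half_width,
                                    "verdict": relaxed_full.label,
                                    "n_members": relaxed_full.n_members},
        }
        _write_json(out / "feasibility_summary.json", summary)
        return {"n_feasible_any": cascade[1],
                "longest": summary["longest_consecutive"],
                "full_verdict": full.label}, None

    run_stage("feasibility", _feasibility)
    if until == "feasibility":
        return _finish()

    # ---- stage: predictions ----------------------------------------------
    def _prediction():
        fs = feasible_subset(batch, config.prediction_subset)
        if fs.empty:
            raise StageError("prediction",
                             f"feasible set {config.prediction_subset} empty")
        nominal = {p: model.evaluate(model.nominal, p)
                   for p in config.prediction_molecules}
        cmp = comparison_table(batch, fs, table, nominal,
                               config.prediction_molecules, model)
        cmp.to_csv(out / "prediction_intervals.csv", index=False,
                   float_format="%.17g")
        lo, hi = config.growth_fit_range
        series = interval_series(batch, fs, range(lo, hi + 1), model)
        fit = fit_linear_growth(series, lo, hi)
        _write_json(out / "interval_growth.json", fit)
        return {"n_members": fs.n_members, "slope": fit["slope"],
                "r_squared": fit["r_squared"]}, None

    run_stage("prediction", _prediction)
    if until == "prediction":
        return _finish()

    # ---- stage: fidelity sweep -------------------------------------------
    def _fidelity():
        curve, report = shrink_sweep(
            model, spec, config.fidelity_k, table,
            n=config.calibration_qoi, N=config.fidelity_n,
            folds=config.fidelity_folds,
            seed=substream_seed(config.seed, "fidelity"))
        curve.to_csv(out / "fidelity_curve.csv")
        _write_json(out / "fidelity_report.json", report)
        return {"k_star": report["k_star"]}, None

    run_stage("fidelity", _fidelity)
    if until == "fidelity":
        return _finish()

    # ---- stage: non-convexity probe --------------------------------------
    def _probe():
        x1, x2 = find_nonconvex_pair(
            model, table, n=config.probe_qoi,
            seed=substream_seed(config.seed, "probe"))
        scan = segment_scan(model, x1, x2, config.probe_qoi, table)
        verdict = convexity_check(scan)
        with open(out / "probe_scan.csv", "w", encoding="utf-8") as fh:
            fh.write("t,value,feasible\n")
            for t, v, f in zip(scan.t, scan.values, scan.feasible):
                fh.write(f"{float(t)!r},{float(v)!r},{int(f)}\n")
        return {"qoi": config.probe_qoi, "verdict": verdict,
                "n_crossings": len(scan.crossings)}, None

    run_stage("probe", _probe)
    if until == "probe":
        return _finish()

    # ---- stage: classification -------------------------------------------
    def _classify():
        data = assemble_classes(batch)
        per_class = min(config.classify_per_class,
                        data.n_feasible, data.n_infeasible)
        balanced = downsample(data, per_class,
                              substream_seed(config.seed, "classify"))
        report = cv_classify(balanced, folds=config.classify_folds,
                             n_trees=config.classify_trees,
                             seed=substream_seed(config.seed, "classify"))
        payload = {"per_class": per_class,
                   "n_trees": config.classify_trees,
                   "folds": config.classify_folds,
                   "fold_auc": list(report.fold_auc),
                   "mean_auc": report.mean_auc,
                   "std_auc": report.std_auc}
        _write_json(out / "classification.json", payload)
        for f, curve in enumerate(report.curves):
            curve.to_csv(out / f"roc_fold_{f}.csv")
        return {"mean_auc": report.mean_auc, "per_class": per_class}, None

    run_stage("classify", _classify)

    return _finish()


def summarize_run(outdir: Union[str, Path]) -> str:
    """Human-readable summary of a finished run directory."""
    out = Path(outdir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {out}; run the pipeline first")
    manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    lines = [f"pipeline run in {out} (package version {manifest['version']})"]
    for name, info in manifest["stages"].items():
        details = ", ".join(f"{k}={v}" for k, v in info.items() if k != "wall_s")
        lines.append(f"  {name:>18s}: {details}")
    return "\n".join(lines)
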