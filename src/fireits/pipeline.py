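"""End-to-end orchestration: simulate/load -> classify -> fit -> estimate.

One :class:`PipelineConfig` drives a full reproducible run. A master seed
deterministically derives every stage's seed (by hashing the stage name, so
adding a stage never shifts the randomness of the others); all intermediate
artifacts are persisted as plain CSV/JSON/GeoJSON under the output
directory; and the final :class:`RunReport` regenerates bit-identically from
the same config and seed (timings excluded).
"""

from __future__ import annotations

import dataclasses
import json
import time
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .counterfactual import CVConfig, LearnerSpec, fit_cell, fit_summary_json
from .effects import EffectEstimate, monte_carlo_eci, pool_strata, scale_to_population
from .exposure import classify_exposure
from .synthetic import (
    SimulationConfig,
    generate_covariates,
    generate_geography,
    generate_visits,
)
from .util import derive_seed

__all__ = [
    "Finding",
    "PipelineConfig",
    "RunReport",
    "validate_config",
    "run_pipeline",
    "config_from_dict",
    "config_from_file",
]


@dataclass(frozen=True)
class Finding:
    level: str  # "error" | "warning"
    message: str


@dataclass
class PipelineConfig:
    """Everything one run needs. Exactly one of ``simulation`` or the
    (``visits_csv``, ``covariates_csv``) pair must be active."""

    simulation: SimulationConfig | None = None
    visits_csv: str | None = None
    covariates_csv: str | None = None
    event_date: date = date(2025, 1, 7)
    threshold_km: float = 20.0
    windows: tuple[int, ...] = (7, 14)
    learner: LearnerSpec = field(default_factory=LearnerSpec)
    cv: CVConfig = field(default_factory=lambda: CVConfig(n_folds=3, min_train_days=180))
    n_iter: int = 1000
    block_days: int = 7
    #: health-system share of the target population, per stratum or scalar
    coverage: float | Mapping[str, float] = 0.15
    pooled_strata: tuple[str, ...] = ("high", "moderate")
    make_geography: bool = False
    master_seed: int = 0


def validate_config(config: PipelineConfig) -> list[Finding]:
    """Typed findings; never mutates the config."""
    findings: list[Finding] = []
    has_sim = config.simulation is not None
    has_paths = config.visits_csv is not None and config.covariates_csv is not None
    if has_sim and has_paths:
        findings.append(Finding("error", "both a simulation block and input paths are set"))
    if not has_sim and not has_paths:
        findings.append(Finding("error", "neither a simulation block nor input paths are set"))
    if config.threshold_km <= 0:
        findings.append(Finding("error", f"threshold_km must be positive, got {config.threshold_km}"))
    if not config.windows or any(w < 1 for w in config.windows):
        findings.append(Finding("error", f"windows must be positive day counts, got {config.windows}"))
    if config.n_iter < 100:
        findings.append(Finding("error", f"n_iter={config.n_iter} is below the minimum of 100"))
    elif config.n_iter < 1000:
        findings.append(
            Finding("warning", f"n_iter={config.n_iter} is below the 1,000-iteration default")
        )
    if config.block_days < 1:
        findings.append(Finding("error", "block_days must be >= 1"))
    coverages = (
        config.coverage.values() if isinstance(config.coverage, Mapping) else [config.coverage]
    )
    for c in coverages:
        if not (0.0 < c <= 1.0):
            findings.append(Finding("error", f"coverage fraction {c} outside (0, 1]"))
    if has_sim and config.simulation.event_date != config.event_date:
        findings.append(
            Finding("warning", "pipeline event_date differs from the simulation block's")
        )
    return findings


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    config_echo: dict
    versions: dict
    estimates: list[dict]
    pooled: list[dict]
    truth_comparison: list[dict]
    timings: dict[str, float]

    def identity_json(self) -> str:
        """Serialization excluding timings: bit-identical across reruns of
        the same config and master seed."""
        payload = {
            "config": self.config_echo,
            "versions": self.versions,
            "estimates": self.estimates,
            "pooled": self.pooled,
            "truth_comparison": self.truth_comparison,
        }
        return json.dumps(payload, sort_keys=True, indent=1)

    def to_json(self) -> str:
        payload = json.loads(self.identity_json())
        payload["timings_s"] = self.timings
        return json.dumps(payload, sort_keys=True, indent=1)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _config_echo(config: PipelineConfig) -> dict:
    def _clean(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            o = dataclasses.asdict(o)
        if isinstance(o, Mapping):
            return {
                "/".join(map(str, k)) if isinstance(k, tuple) else str(k): _clean(v)
                for k, v in o.items()
            }
        if isinstance(o, (list, tuple)):
            return [_clean(v) for v in o]
        if isinstance(o, (date, pd.Timestamp)):
            return str(o)
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return o

    return _clean(config)


def _versions() -> dict:
    import shapely
    import xgboost

    from . import __version__

    return {
        "fireits": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "xgboost": xgboost.__version__,
        "shapely": shapely.__version__,
    }


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunReport:
    """Execute every stage in order, persisting all intermediate artifacts.

    A failing stage aborts with the stage name and the underlying diagnostic;
    artifacts persisted by earlier stages are retained.
    """
    findings = validate_config(config)
    errors = [f for f in findings if f.level == "error"]
    if errors:
        raise ValueError("invalid pipeline config: " + "; ".join(f.message for f in errors))

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    truth = None

    # -- data stage --------------------------------------------------------
    t0 = time.perf_counter()
    try:
        if config.simulation is not None:
            sim = config.simulation
            covariates = generate_covariates(sim, derive_seed(config.master_seed, "covariates"))
            visits, truth = generate_visits(
                sim,
                covariates,
                derive_seed(config.master_seed, "visits"),
                windows=config.windows,
            )
        else:
            visits = fio.read_visits_csv(config.visits_csv)
            covariates = fio.read_covariates_csv(config.covariates_csv)
        fio.write_visits_csv(visits, out / "visits.csv")
        fio.write_covariates_csv(covariates, out / "covariates.csv")
        if truth is not None:
            truth_payload = {
                "window_excess": {"/".join(map(str, k)): v for k, v in truth.window_excess.items()},
                "window_pct": {"/".join(map(str, k)): v for k, v in truth.window_pct.items()},
            }
            (out / "ground_truth.json").write_text(json.dumps(truth_payload, sort_keys=True, indent=1))
    except Exception as e:  # noqa: BLE001 - re-raised with stage context
        raise StageError("data", e) from e
    timings["data"] = time.perf_counter() - t0

    # -- geography demo stage (optional) -----------------------------------
    if config.make_geography:
        t0 = time.perf_counter()
        try:
            units, fires = generate_geography(seed=derive_seed(config.master_seed, "geography"))
            assignments = classify_exposure(units, fires, threshold_km=config.threshold_km)
            fio.write_units_geojson(units, out / "units.geojson")
            fio.write_fires_geojson(fires, out / "fires.geojson")
            fio.write_assignments_csv(assignments, out / "assignments.csv")
        except Exception as e:  # noqa: BLE001
            raise StageError("classify", e) from e
        timings["classify"] = time.perf_counter() - t0

    # -- fit + estimate stages ---------------------------------------------
    cells = sorted(
        {(r.stratum, r.modality, r.cause) for r in visits.itertuples()},
    )
    windows = tuple((0, int(w)) for w in config.windows)
    estimates_rows: list[dict] = []
    truth_rows: list[dict] = []
    pooled_rows: list[dict] = []
    by_key: dict[tuple, list[EffectEstimate]] = {}
    pred_frames: list[pd.DataFrame] = []

    t0 = time.perf_counter()
    try:
        for cell in cells:
            result = fit_cell(
                visits,
                covariates,
                config.event_date,
                cell,
                config.learner,
                config.cv,
                seed=derive_seed(config.master_seed, f"fit:{'/'.join(cell)}"),
            )
            (out / f"fit_{'_'.join(cell)}.json").write_text(
                fit_summary_json(result.fit, result.prediction)
            )
            pred_frames.append(
                pd.DataFrame(
                    {
                        "date": result.post_dates,
                        "stratum": cell[0],
                        "modality": cell[1],
                        "cause": cell[2],
                        "observed": result.observed_post,
                        "predicted": result.prediction.values,
                    }
                )
            )
            cell_ests = monte_carlo_eci(
                result.fit,
                result.prediction,
                result.observed_post,
                windows=windows,
                n_iter=config.n_iter,
                block_days=config.block_days,
                seed=derive_seed(config.master_seed, f"eci:{'/'.join(cell)}"),
                scope=cell,
            )
            for est in cell_ests:
                w = est.window[1]
                estimates_rows.append(_estimate_row(cell, w, est))
                by_key.setdefault((cell[1], cell[2], w), []).append(est)
                if truth is not None:
                    tp = truth.window_pct[cell + (w,)]
                    truth_rows.append(
                        {
                            "stratum": cell[0],
                            "modality": cell[1],
                            "cause": cell[2],
                            "window_days": w,
                            "true_pct": tp,
                            "true_excess": truth.window_excess[cell + (w,)],
                            "estimated_pct": est.pct_change,
                            "eci_covers_truth": bool(est.eci_low <= tp <= est.eci_high),
                        }
                    )
        pd.concat(pred_frames, ignore_index=True).assign(
            date=lambda d: pd.DatetimeIndex(d["date"]).strftime("%Y-%m-%d")
        ).to_csv(out / "predictions.csv", index=False)
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("fit", e) from e
    timings["fit_estimate"] = time.perf_counter() - t0

    # -- pooling + scaling -------------------------------------------------
    t0 = time.perf_counter()
    try:
        for (modality, cause, w), ests in sorted(by_key.items()):
            members = [e for e in ests if e.scope[0] in config.pooled_strata]
            if len(members) < 1:
                continue
            pooled = pool_strata(members)
            cov = _pooled_coverage(config.coverage, [e.scope[0] for e in members])
            row = {
                "strata": "+".join(e.scope[0] for e in members),
                "modality": modality,
                "cause": cause,
                "window_days": w,
                "observed": pooled.observed,
                "predicted": pooled.predicted,
                "excess": pooled.excess_count,
                "pct_change": pooled.pct_change,
                "eci_low": pooled.eci_low,
                "eci_high": pooled.eci_high,
                "excess_scaled_to_population": scale_to_population(pooled.excess_count, cov),
                "coverage_fraction": cov,
                "n_iterations": pooled.n_iterations,
            }
            pooled_rows.append(row)
    except Exception as e:  # noqa: BLE001
        raise StageError("pool", e) from e
    timings["pool"] = time.perf_counter() - t0

    pd.DataFrame(estimates_rows).to_csv(out / "estimates.csv", index=False)
    report = RunReport(
        config_echo=_config_echo(config),
        versions=_versions(),
        estimates=estimates_rows,
        pooled=pooled_rows,
        truth_comparison=truth_rows,
        timings=timings,
    )
    (out / "report.json").write_text(report.to_json())
    return report


def _estimate_row(cell: tuple[str, str, str], window_days: int, est: EffectEstimate) -> dict:
    return {
        "stratum": cell[0],
        "modality": cell[1],
        "cause": cell[2],
        "window_days": window_days,
        "observed": est.observed,
        "predicted": est.predicted,
        "excess": est.excess_count,
        "pct_change": est.pct_change,
        "eci_low": est.eci_low,
        "eci_high": est.eci_high,
        "eci_low_count": est.eci_low_count,
        "eci_high_count": est.eci_high_count,
        "n_iterations": est.n_iterations,
    }


def _pooled_coverage(coverage: float | Mapping[str, float], strata: Sequence[str]) -> float:
    if not isinstance(coverage, Mapping):
        return float(coverage)
    vals = [float(coverage[s]) for s in strata]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# config files
# ---------------------------------------------------------------------------


def config_from_dict(raw: Mapping) -> PipelineConfig:
    """Build a PipelineConfig from a plain mapping (parsed JSON/YAML).

    The ``simulation`` block takes SimulationConfig field names, with dates
    as ISO strings, seasonal windows as ``[[start, end], ...]``, and effect
    profile keys written ``"stratum/modality/cause"``.
    """
    raw = dict(raw)
    sim = None
    if "simulation" in raw and raw["simulation"] is not None:
        sim_raw = dict(raw["simulation"])
        if "seasonal_windows" in sim_raw:
            sim_raw["seasonal_windows"] = tuple(
                (pd.Timestamp(a).date(), pd.Timestamp(b).date())
                for a, b in sim_raw["seasonal_windows"]
            )
        if "event_date" in sim_raw:
            sim_raw["event_date"] = pd.Timestamp(sim_raw["event_date"]).date()
        if "effect_profile" in sim_raw:
            sim_raw["effect_profile"] = {
                tuple(k.split("/")): tuple(v) for k, v in sim_raw["effect_profile"].items()
            }
        for key in ("strata", "modalities", "causes", "weekday_multipliers"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        sim = SimulationConfig(**sim_raw)
    kwargs: dict = {"simulation": sim}
    for key in ("visits_csv", "covariates_csv", "threshold_km", "n_iter", "block_days",
                "coverage", "make_geography", "master_seed"):
        if key in raw:
            kwargs[key] = raw[key]
    if "event_date" in raw:
        kwargs["event_date"] = pd.Timestamp(raw["event_date"]).date()
    elif sim is not None:
        kwargs["event_date"] = sim.event_date
    if "windows" in raw:
        kwargs["windows"] = tuple(int(w) for w in raw["windows"])
    if "pooled_strata" in raw:
        kwargs["pooled_strata"] = tuple(raw["pooled_strata"])
    if "learner" in raw:
        lr = raw["learner"]
        kwargs["learner"] = LearnerSpec(
            base_grid=tuple(lr.get("base_grid", [{"n_harmonics": 2}])),
            residual_grid=tuple(lr.get("residual_grid", [None])),
        )
    if "cv" in raw:
        kwargs["cv"] = CVConfig(**raw["cv"])
    return PipelineConfig(**kwargs)


def config_from_file(path: str | Path) -> PipelineConfig:
    import yaml

    text = Path(path).read_text()
    return config_from_dict(yaml.safe_load(text))
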