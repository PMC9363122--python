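"""Simultaneous fit of free model parameters to hybrid datasets.

The objective simulates every hybrid dataset's regimen from its aging
context (a single life-course simulation per dataset, starting from the
premenopausal steady state), evaluates relative BMD at the aging-anchor and
clinical-visit ages and BTM baseline changes at the BTM visit ages, and
returns weighted residuals.  BMD points carry unit weight; BTM points are
down-weighted (default 0.2) — BMD is the primary target variable while the
BTM series mainly pin down each drug's mode of action.

Goodness of fit is reported as MAPE (mean absolute percentage error),
normalized RMSE and, for BTMs, the direction concordance of the dominant
excursion from baseline.  Near-zero BTM observations are excluded from
MAPE (their percentage errors are dominated by the small denominators);
they still enter the least-squares objective.

The optimizer is bounded trust-region least squares with seeded
Latin-hypercube multi-starts.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats.qmc

from .datasets import HybridDataset
from .parameters import ModelParameters
from .simulate import dense_grid, simulate

__all__ = [
    "CalibrationConfig",
    "GoodnessReport",
    "FitResult",
    "mape",
    "nrmse",
    "btm_direction_concordance",
    "predict_dataset",
    "residuals",
    "objective",
    "goodness_report",
    "fit",
]

logger = logging.getLogger(__name__)

_PENALTY = 1e3  # residual magnitude substituted when a simulation fails


@dataclasses.dataclass
class CalibrationConfig:
    btm_weight: float = 0.2
    mape_exclude_threshold: float = 0.05  # |obs| below this excluded from MAPE
    n_starts: int = 32
    seed: int = 42
    start_age: float = 25.0
    rtol: float = 1e-8
    atol: float = 1e-10
    max_nfev: int | None = None
    xtol: float = 1e-10
    ftol: float = 1e-10


# ---------------------------------------------------------------------------
# goodness measures


def mape(simulated, observed) -> float:
    """Mean absolute percentage error, in percent."""
    sim = np.asarray(simulated, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if sim.shape != obs.shape or sim.size == 0:
        raise ValueError("series must have equal, nonzero length")
    if np.any(obs == 0):
        raise ValueError("observed values must be nonzero for MAPE")
    return float(100.0 * np.mean(np.abs(sim - obs) / np.abs(obs)))


def nrmse(simulated, observed) -> float:
    """RMSE normalized by the observed range (or |mean| for flat series)."""
    sim = np.asarray(simulated, dtype=float)
    obs = np.asarray(observed, dtype=float)
    rmse = float(np.sqrt(np.mean((sim - obs) ** 2)))
    denom = float(np.ptp(obs)) or float(np.abs(np.mean(obs))) or 1.0
    return rmse / denom


def btm_direction_concordance(simulated, observed) -> bool | None:
    """Whether the dominant excursion from baseline has the same sign.

    Returns ``None`` (not applicable) when the observed series never
    leaves baseline.
    """
    sim = np.asarray(simulated, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if np.all(obs == 0):
        return None
    obs_dir = np.sign(obs[np.argmax(np.abs(obs))])
    if np.all(sim == 0):
        return False
    sim_dir = np.sign(sim[np.argmax(np.abs(sim))])
    return bool(obs_dir == sim_dir)


# ---------------------------------------------------------------------------
# prediction and residuals


def predict_dataset(
    params: ModelParameters | object,
    dataset: HybridDataset,
    config: CalibrationConfig | None = None,
    untreated_rel: tuple[np.ndarray, np.ndarray] | None = None,
):
    """Simulate a hybrid dataset's life course and evaluate at its ages.

    Returns ``(bmd_ages, bmd_pred, btm_pred)`` where ``btm_pred`` maps each
    marker to predictions at that marker's observation ages, baselined at
    the treatment start.  The aging anchors describe untreated population
    aging, so they are evaluated on an untreated life course (pass
    ``untreated_rel`` — (times, relative BMD) — to reuse one across
    datasets); the treatment series comes from the treated simulation.
    """
    config = config or CalibrationConfig()
    end_age = dataset.max_age + 0.1
    eval_ages = np.concatenate(
        [
            dataset.treat_ages,
            [dataset.treatment_start_age, dataset.aging_ages[0]],
            *[a for a, _ in dataset.btm_changes.values()],
        ]
    )
    traj = simulate(
        params,
        regimen=dataset.regimen,
        age_span=(config.start_age, end_age),
        output_grid=dense_grid(config.start_age, end_age, eval_ages),
        reference_age=dataset.aging_ages[0],
        rtol=config.rtol,
        atol=config.atol,
    )
    t = traj.times
    rel = traj.observables["bmd_relative"]
    if untreated_rel is None:
        if dataset.regimen is None or len(dataset.regimen) == 0:
            untreated_rel = (t, rel)
        else:
            base = simulate(
                params,
                age_span=(config.start_age, dataset.aging_ages[-1] + 0.1),
                output_grid=dense_grid(
                    config.start_age,
                    dataset.aging_ages[-1] + 0.1,
                    dataset.aging_ages,
                ),
                reference_age=dataset.aging_ages[0],
                rtol=config.rtol,
                atol=config.atol,
            )
            untreated_rel = (base.times, base.observables["bmd_relative"])
    aging_pred = np.interp(dataset.aging_ages, *untreated_rel)
    bmd_ages = np.concatenate([dataset.aging_ages, dataset.treat_ages])
    bmd_pred = np.concatenate(
        [aging_pred, np.interp(dataset.treat_ages, t, rel)]
    )
    btm_pred = {}
    start = float(dataset.treatment_start_age)
    for marker, (ages, _) in dataset.btm_changes.items():
        series = traj.observables[f"{marker}_change"]
        base = 1.0 + np.interp(start, t, series)
        btm_pred[marker] = (1.0 + np.interp(ages, t, series)) / base - 1.0
    return bmd_ages, bmd_pred, btm_pred


def residuals(
    free_values: np.ndarray,
    registry: ModelParameters,
    collection: list[HybridDataset],
    config: CalibrationConfig,
) -> np.ndarray:
    """Weighted residual vector over all datasets (BMD and BTM series)."""
    if not collection:
        raise ValueError("dataset collection is empty")
    params = registry.with_free_values(free_values)
    res = []
    untreated_cache: dict[tuple, tuple] = {}
    for ds in collection:
        key = (tuple(ds.aging_ages), config.start_age)
        try:
            if key not in untreated_cache:
                base = simulate(
                    params,
                    age_span=(config.start_age, ds.aging_ages[-1] + 0.1),
                    output_grid=dense_grid(
                        config.start_age,
                        ds.aging_ages[-1] + 0.1,
                        ds.aging_ages,
                    ),
                    reference_age=ds.aging_ages[0],
                    rtol=config.rtol,
                    atol=config.atol,
                )
                untreated_cache[key] = (
                    base.times,
                    base.observables["bmd_relative"],
                )
            _, bmd_pred, btm_pred = predict_dataset(
                params, ds, config, untreated_rel=untreated_cache[key]
            )
            obs = np.concatenate([ds.aging_bmd, ds.treat_bmd])
            res.append(bmd_pred - obs)
            for marker, (ages, changes) in ds.btm_changes.items():
                res.append(config.btm_weight * (btm_pred[marker] - changes))
        except Exception as exc:  # simulation failure -> finite penalty
            logger.warning("simulation failed for %s: %s", ds.label, exc)
            n = len(ds.aging_bmd) + len(ds.treat_bmd) + sum(
                len(a) for a, _ in ds.btm_changes.values()
            )
            res.append(np.full(n, _PENALTY))
    return np.concatenate(res)


def objective(
    free_values: np.ndarray,
    registry: ModelParameters,
    collection: list[HybridDataset],
    config: CalibrationConfig | None = None,
) -> float:
    """Scalar loss: sum of squared weighted residuals."""
    config = config or CalibrationConfig()
    r = residuals(np.asarray(free_values, dtype=float), registry, collection, config)
    return float(np.sum(r**2))


# ---------------------------------------------------------------------------
# goodness report


@dataclasses.dataclass
class GoodnessReport:
    """Per dataset x observable goodness measures plus the global loss."""

    table: pd.DataFrame  # columns: dataset, observable, mape, nrmse, concordance
    global_loss: float

    def bmd_mape(self) -> pd.Series:
        rows = self.table[self.table.observable == "bmd"]
        return rows.set_index("dataset")["mape"]


def goodness_report(
    registry: ModelParameters,
    collection: list[HybridDataset],
    config: CalibrationConfig | None = None,
) -> GoodnessReport:
    config = config or CalibrationConfig()
    rows = []
    params = registry
    for ds in collection:
        _, bmd_pred, btm_pred = predict_dataset(params, ds, config)
        obs = np.concatenate([ds.aging_bmd, ds.treat_bmd])
        rows.append(
            {
                "dataset": ds.label,
                "observable": "bmd",
                "mape": mape(bmd_pred, obs),
                "nrmse": nrmse(bmd_pred, obs),
                "concordance": None,
            }
        )
        for marker, (ages, changes) in ds.btm_changes.items():
            pred = btm_pred[marker]
            keep = np.abs(changes) >= config.mape_exclude_threshold
            rows.append(
                {
                    "dataset": ds.label,
                    "observable": marker,
                    "mape": mape(pred[keep], changes[keep]) if keep.any() else np.nan,
                    "nrmse": nrmse(pred, changes),
                    "concordance": btm_direction_concordance(pred, changes),
                }
            )
    loss = objective(registry.free_values(), registry, collection, config)
    return GoodnessReport(table=pd.DataFrame(rows), global_loss=loss)


# ---------------------------------------------------------------------------
# fitting


@dataclasses.dataclass
class FitResult:
    params: ModelParameters
    report: GoodnessReport
    loss: float
    starts: pd.DataFrame  # per-start diagnostics (start index, loss, status)


def fit(
    registry: ModelParameters,
    collection: list[HybridDataset],
    config: CalibrationConfig | None = None,
) -> FitResult:
    """Bounded least-squares fit of the registry's free parameters.

    Multi-start: the registry's current values plus seeded Latin-hypercube
    points within the bounds.  Deterministic for a fixed seed.
    """
    config = config or CalibrationConfig()
    free = registry.free_names()
    if not free:
        report = goodness_report(registry, collection, config)
        return FitResult(registry.copy(), report, report.global_loss, pd.DataFrame())
    lo, hi = registry.free_bounds()

    starts = [registry.free_values()]
    if config.n_starts > 1:
        sampler = scipy.stats.qmc.LatinHypercube(d=len(free), seed=config.seed)
        unit = sampler.random(config.n_starts - 1)
        starts.extend(lo + unit * (hi - lo))

    best = None
    diag = []
    for i, x0 in enumerate(starts):
        try:
            sol = scipy.optimize.least_squares(
                residuals,
                np.clip(x0, lo, hi),
                args=(registry, collection, config),
                bounds=(lo, hi),
                method="trf",
                x_scale="jac",
                xtol=config.xtol,
                ftol=config.ftol,
                max_nfev=config.max_nfev,
            )
            loss = float(np.sum(sol.fun**2))
            diag.append({"start": i, "loss": loss, "status": sol.status})
            if best is None or loss < best[0]:
                best = (loss, sol.x)
        except Exception as exc:
            logger.warning("start %d failed: %s", i, exc)
            diag.append({"start": i, "loss": np.inf, "status": -99})
    if best is None:
        raise RuntimeError("all optimization starts failed")
    fitted = registry.with_free_values(best[1])
    report = goodness_report(fitted, collection, config)
    return FitResult(fitted, report, best[0], pd.DataFrame(diag))
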