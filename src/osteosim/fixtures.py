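"""Synthetic clinical-style datasets generated from known parameters.

The generator emulates the *structure* of published study-average series:
an aging dataset of decadal BMD bin means (ages 20 to 80+), and treatment
datasets of total-hip BMD at clinic visits plus CTX/P1NP baseline-change
series, with independent additive Gaussian noise on each visit (study
population averages; no autocorrelation).  Because the data come from the
model itself, they carry none of a real trial's structural misfit — tests
passing on them demonstrate pipeline correctness and parameter
recoverability, not clinical validity.

Default noise levels: sd 0.004 on relative BMD, sd 0.05 on BTM fractional
changes.  The default calibration/validation collections mirror the kinds
of study conditions used for osteoporosis drugs: four monotherapy
calibration studies (denosumab, alendronate, romosozumab, blosozumab) and
held-out validation studies with sequential and parallel combinations
(including teriparatide).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .calibration import CalibrationConfig, fit
from .datasets import AgingDataset, HybridDataset, TreatmentDataset, build_hybrid
from .parameters import ModelParameters, reference_parameters
from .pharmacology import make_block_regimen
from .simulate import dense_grid, simulate

__all__ = [
    "FixtureSpec",
    "generate_aging_dataset",
    "generate_dataset",
    "default_collections",
    "recovery_experiment",
]

# arbitrary absolute baselines used to dress relative model output up as
# raw clinical measurements (g/cm^2-like BMD, ng/mL-like markers)
_ABS_BMD_BASELINE = 0.95
_ABS_BTM_BASELINE = {"ctx": 0.35, "p1np": 42.0, "bsap": 12.0}


@dataclasses.dataclass
class FixtureSpec:
    """Recipe for one synthetic treatment study."""

    label: str
    regimen_blocks: list[tuple]  # blocks for make_block_regimen
    start_age: int = 67
    bmd_visits: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
    btm_visits: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
    markers: tuple[str, ...] = ("ctx", "p1np")
    bmd_noise_sd: float = 0.004
    btm_noise_sd: float = 0.05
    n_subjects: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.bmd_noise_sd < 0 or self.btm_noise_sd < 0:
            raise ValueError("noise sd must be nonnegative")


def generate_aging_dataset(
    params: ModelParameters, label: str = "aging-synthetic"
) -> AgingDataset:
    """Decadal BMD bin means (20 to 80+) from an untreated life course.

    The model's relative BMD at each bin-center age, scaled by an
    arbitrary absolute baseline, stands in for the reported bin mean.
    """
    bins = [(20.0, 30.0), (30.0, 40.0), (40.0, 50.0), (50.0, 60.0),
            (60.0, 70.0), (70.0, 80.0), (80.0, 90.0)]
    centers = [0.5 * (lo + hi) for lo, hi in bins]
    traj = simulate(
        params,
        age_span=(25.0, 88.0),
        output_grid=dense_grid(25.0, 88.0, centers),
    )
    rel = np.interp(
        np.clip(centers, traj.times[0], traj.times[-1]),
        traj.times,
        traj.observables["bmd_relative"],
    )
    return AgingDataset(
        age_bins=bins,
        mean_bmd=_ABS_BMD_BASELINE * rel,
        label=label,
        open_ended_top=True,
    )


def generate_dataset(
    spec: FixtureSpec, params: ModelParameters | None = None
) -> tuple[TreatmentDataset, AgingDataset]:
    """Simulate the generating model and sample noisy study-average series.

    With zero noise the emitted values equal the simulated observables at
    the visits exactly (up to the hybrid pipeline's linear-interpolation
    convention for the baseline anchor).
    """
    params = params or reference_parameters()
    aging = generate_aging_dataset(params)
    rng = np.random.default_rng(spec.seed)

    regimen = make_block_regimen(spec.regimen_blocks, start_age=spec.start_age)
    end_age = max(
        regimen.end,
        spec.start_age + max(max(spec.bmd_visits), max(spec.btm_visits)),
    )
    eval_ages = np.concatenate(
        [
            spec.start_age + np.asarray(spec.bmd_visits),
            spec.start_age + np.asarray(spec.btm_visits),
            [spec.start_age],
        ]
    )
    traj = simulate(
        params,
        regimen=regimen,
        age_span=(25.0, end_age + 0.1),
        output_grid=dense_grid(25.0, end_age + 0.1, eval_ages),
    )
    t = traj.times
    rel = traj.observables["bmd_relative"]

    # express the relative series in "absolute" units consistent with the
    # aging dataset's anchors, so build_hybrid's rescaling reproduces it
    from .datasets import bin_centers

    anchor_ages, anchors = bin_centers(aging)
    anchor_at_start = np.interp(spec.start_age, anchor_ages, anchors)
    visits = np.asarray(spec.bmd_visits)
    rel_at_visits = np.interp(spec.start_age + visits, t, rel)
    rel_at_start = np.interp(spec.start_age, t, rel)
    bmd_rel = rel_at_visits / rel_at_start * anchor_at_start
    bmd_raw = _ABS_BMD_BASELINE * (
        bmd_rel + rng.normal(0.0, spec.bmd_noise_sd, size=len(visits))
    )

    btm = {}
    btm_visits = np.asarray(spec.btm_visits)
    for marker in spec.markers:
        series = traj.observables[f"{marker}_change"]
        base = 1.0 + np.interp(spec.start_age, t, series)
        change = (1.0 + np.interp(spec.start_age + btm_visits, t, series)) / base - 1.0
        change = change + rng.normal(0.0, spec.btm_noise_sd, size=len(btm_visits))
        change[0] = 0.0  # the baseline visit defines the reference
        btm[marker] = (
            btm_visits,
            _ABS_BTM_BASELINE[marker] * (1.0 + change),
        )

    treatment = TreatmentDataset(
        label=spec.label,
        baseline_age_mean=float(spec.start_age),
        times=visits,
        bmd=bmd_raw,
        btm=btm,
        regimen=regimen,
        n_subjects=spec.n_subjects,
    )
    return treatment, aging


def default_collections(
    seed: int = 0, params: ModelParameters | None = None
) -> tuple[list[HybridDataset], list[HybridDataset]]:
    """Synthetic calibration and validation collections.

    Calibration: four monotherapy studies (denosumab, alendronate,
    romosozumab, blosozumab).  Validation (held out, combination schemes):
    the alendronate->romosozumab->denosumab sequence and a parallel
    teriparatide+denosumab block followed by denosumab alone.
    """
    params = params or reference_parameters()
    two_year = (0.0, 0.5, 1.0, 1.5, 2.0)
    cal_specs = [
        FixtureSpec("denosumab-60-q6m", [("denosumab", 60, 0.5, 3)],
                    start_age=67, seed=seed + 1),
        FixtureSpec("alendronate-70-qw", [("alendronate", 70, 1 / 52, 2)],
                    start_age=64, bmd_visits=two_year,
                    btm_visits=(0.0, 0.25, 0.5, 1.0, 1.5, 2.0), seed=seed + 2),
        FixtureSpec("romosozumab-210-qm", [("romosozumab", 210, 1 / 12, 1)],
                    start_age=67, bmd_visits=(0.0, 0.5, 1.0, 1.5, 2.0),
                    btm_visits=(0.0, 0.25, 0.5, 1.0, 1.5, 2.0), seed=seed + 3),
        FixtureSpec("blosozumab-180-q2w", [("blosozumab", 180, 1 / 26, 1)],
                    start_age=66, bmd_visits=(0.0, 0.25, 0.5, 0.75, 1.0),
                    btm_visits=(0.0, 0.25, 0.5, 0.75, 1.0), seed=seed + 4),
    ]
    val_specs = [
        FixtureSpec(
            "aln-romo-dmab-sequence",
            [("alendronate", 70, 1 / 52, 1), ("romosozumab", 140, 1 / 12, 1),
             ("denosumab", 60, 0.5, 1)],
            start_age=67, seed=seed + 5,
        ),
        FixtureSpec(
            "teri+dmab-parallel-then-dmab",
            [{"drug": "teriparatide", "dose_mg": 0.02, "every": 1 / 365,
              "for": 1.0, "start": 66},
             {"drug": "denosumab", "dose_mg": 60, "every": 0.5, "for": 1.0,
              "start": 66},
             {"drug": "denosumab", "dose_mg": 60, "every": 0.5, "for": 1.0,
              "start": 67}],
            start_age=66, seed=seed + 6,
        ),
    ]
    calibration = []
    validation = []
    for specs, out in ((cal_specs, calibration), (val_specs, validation)):
        for s in specs:
            treatment, aging = generate_dataset(s, params)
            out.append(build_hybrid(aging, treatment))
    return calibration, validation


def recovery_experiment(
    free_subset: list[str],
    collection: list[HybridDataset],
    fit_config: CalibrationConfig | None = None,
    true_params: ModelParameters | None = None,
    perturbation: float = 0.15,
    seed: int = 0,
):
    """Perturb a free-parameter subset, refit, and report relative errors.

    ``collection`` should be generated (noise-free for the strict check)
    from ``true_params``.  Returns a DataFrame with true/fitted values and
    relative errors per parameter.
    """
    import pandas as pd

    true_params = true_params or reference_parameters()
    registry = true_params.set_free(free_subset)
    names = registry.free_names()  # registry order, not request order
    rng = np.random.default_rng(seed)
    truth = registry.free_values()
    lo, hi = registry.free_bounds()
    start = np.clip(
        truth * (1.0 + perturbation * rng.choice([-1.0, 1.0], size=len(truth))),
        lo,
        hi,
    )
    cfg = fit_config or CalibrationConfig(n_starts=1)
    result = fit(registry.with_free_values(start), collection, cfg)
    fitted = result.params.free_values()
    return pd.DataFrame(
        {
            "parameter": names,
            "true": truth,
            "start": start,
            "fitted": fitted,
            "rel_error": np.abs(fitted - truth) / np.abs(truth),
        }
    )
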