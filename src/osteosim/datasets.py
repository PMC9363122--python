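"""Clinical-style dataset containers and hybrid aging/treatment assembly.

An *aging dataset* holds population-mean BMD in 10-year age bins; a
*treatment dataset* holds a study-time-indexed BMD series plus optional
bone-turnover-marker (BTM) series and regimen metadata.  A *hybrid dataset*
merges the two: the aging bins are reduced to bin-center anchors rescaled
to the earliest bin, the treatment series is rescaled so its baseline
coincides with the linearly interpolated aging BMD at the treatment start
age (the study population's mean baseline age rounded to full years), and
BTMs are expressed as fractional changes from their baseline visit.

Files are UTF-8 comma-delimited tables with a header row, one file per
series, accompanied by a JSON metadata sidecar.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .pharmacology import Regimen, make_block_regimen

__all__ = [
    "AgingDataset",
    "TreatmentDataset",
    "HybridDataset",
    "bin_centers",
    "build_hybrid",
    "load_collection",
]

BTM_MARKERS = ("ctx", "p1np", "bsap")


@dataclasses.dataclass
class AgingDataset:
    """Population-mean BMD by age bin (e.g. decadal bins 20 to 80+)."""

    age_bins: list[tuple[float, float]]
    mean_bmd: np.ndarray
    label: str = "aging"
    open_ended_top: bool = False  # top bin "80 and older" style

    def __post_init__(self):
        self.mean_bmd = np.asarray(self.mean_bmd, dtype=float)
        if len(self.age_bins) != len(self.mean_bmd):
            raise ValueError("bins and means must align")
        edges = np.array(self.age_bins)
        if np.any(np.diff(edges[:, 0]) <= 0) or np.any(edges[:, 1] <= edges[:, 0]):
            raise ValueError("bins must be ascending and non-degenerate")
        if np.any(edges[1:, 0] < edges[:-1, 1] - 1e-9):
            raise ValueError("bins must not overlap")

    def write(self, path: str | Path) -> None:
        path = Path(path)
        df = pd.DataFrame(
            {
                "age_low": [b[0] for b in self.age_bins],
                "age_high": [b[1] for b in self.age_bins],
                "bmd": self.mean_bmd,
            }
        )
        df.to_csv(path, index=False)
        meta = {"label": self.label, "open_ended_top": self.open_ended_top}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def read(cls, path: str | Path) -> "AgingDataset":
        path = Path(path)
        df = pd.read_csv(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            age_bins=list(zip(df["age_low"], df["age_high"])),
            mean_bmd=df["bmd"].to_numpy(),
            label=meta.get("label", path.stem),
            open_ended_top=meta.get("open_ended_top", False),
        )


@dataclasses.dataclass
class TreatmentDataset:
    """Study-average BMD and BTM series from a treatment trial."""

    label: str
    baseline_age_mean: float
    times: np.ndarray  # study time since start (yr); first entry = baseline
    bmd: np.ndarray
    btm: dict[str, tuple[np.ndarray, np.ndarray]] = dataclasses.field(
        default_factory=dict
    )  # marker -> (times, raw concentrations)
    regimen: Regimen | None = None
    n_subjects: int | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.bmd = np.asarray(self.bmd, dtype=float)
        if len(self.times) != len(self.bmd):
            raise ValueError("times and bmd must align")
        if len(self.times) and self.times[0] != min(self.times):
            raise ValueError("first BMD time point must be the baseline visit")

    def write(self, path: str | Path) -> None:
        path = Path(path)
        cols = {"time_yr": self.times, "bmd": self.bmd}
        df = pd.DataFrame(cols)
        for marker, (t, v) in self.btm.items():
            mdf = pd.DataFrame({"time_yr": t, marker: v})
            df = df.merge(mdf, on="time_yr", how="outer")
        df = df.sort_values("time_yr")
        df.to_csv(path, index=False)
        meta = {
            "label": self.label,
            "baseline_age_mean": self.baseline_age_mean,
            "n_subjects": self.n_subjects,
            "regimen_blocks": _regimen_to_blocks(self.regimen),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def read(cls, path: str | Path) -> "TreatmentDataset":
        path = Path(path)
        df = pd.read_csv(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        bmd_rows = df.dropna(subset=["bmd"])
        btm = {}
        for marker in BTM_MARKERS:
            if marker in df.columns:
                rows = df.dropna(subset=[marker])
                if len(rows):
                    btm[marker] = (
                        rows["time_yr"].to_numpy(),
                        rows[marker].to_numpy(),
                    )
        regimen = None
        if meta.get("regimen_blocks"):
            regimen = make_block_regimen(meta["regimen_blocks"])
        return cls(
            label=meta.get("label", path.stem),
            baseline_age_mean=float(meta["baseline_age_mean"]),
            times=bmd_rows["time_yr"].to_numpy(),
            bmd=bmd_rows["bmd"].to_numpy(),
            btm=btm,
            regimen=regimen,
            n_subjects=meta.get("n_subjects"),
        )


def _regimen_to_blocks(regimen: Regimen | None) -> list[dict] | None:
    if regimen is None:
        return None
    blocks = []
    for blk in regimen.blocks:
        ev = [e for e in regimen.events if e.drug_id == blk.drug_id
              and blk.start - 1e-9 <= e.time < blk.end]
        if not ev:
            continue
        interval = ev[1].time - ev[0].time if len(ev) > 1 else blk.end - blk.start
        blocks.append(
            {
                "drug": blk.drug_id,
                "dose_mg": ev[0].dose,
                "every": interval,
                "for": blk.end - blk.start,
                "start": blk.start,
            }
        )
    return blocks


@dataclasses.dataclass
class HybridDataset:
    """Merged aging + treatment series on a common age axis.

    ``aging_ages``/``aging_bmd`` are the rescaled bin-center anchors
    (earliest anchor = 1); the treatment series is rescaled so that its
    baseline equals the interpolated aging BMD at ``treatment_start_age``,
    and BTMs are fractional changes from their baseline visit.
    """

    label: str
    aging_ages: np.ndarray
    aging_bmd: np.ndarray
    treat_ages: np.ndarray
    treat_bmd: np.ndarray
    btm_changes: dict[str, tuple[np.ndarray, np.ndarray]]  # marker -> (ages, change)
    treatment_start_age: int
    regimen: Regimen | None = None
    provenance: dict = dataclasses.field(default_factory=dict)

    @property
    def max_age(self) -> float:
        ages = [self.aging_ages[-1], self.treat_ages[-1] if len(self.treat_ages) else 0]
        ages += [t[-1] for t, _ in self.btm_changes.values() if len(t)]
        return float(max(ages))


def bin_centers(aging: AgingDataset) -> tuple[np.ndarray, np.ndarray]:
    """Reduce age bins to center-age anchors, rescaled to the earliest bin.

    Bin means serve as proxy values at the bin-center age.  An open-ended
    top bin ("80 and older") is assigned the width of the preceding bin.
    """
    if len(aging.age_bins) < 2:
        raise ValueError("need at least two age bins")
    centers = []
    for i, (lo, hi) in enumerate(aging.age_bins):
        if aging.open_ended_top and i == len(aging.age_bins) - 1:
            prev_lo, prev_hi = aging.age_bins[i - 1]
            hi = lo + (prev_hi - prev_lo)
        centers.append(0.5 * (lo + hi))
    centers = np.asarray(centers)
    values = aging.mean_bmd / aging.mean_bmd[0]
    return centers, values


def build_hybrid(aging: AgingDataset, treatment: TreatmentDataset) -> HybridDataset:
    """Merge a treatment dataset into the aging context.

    The treatment start is placed at the study's mean baseline age rounded
    to full years; the BMD series is rescaled so its baseline matches the
    linearly interpolated aging anchor value at that age; BTM raw series
    become fractional changes from the baseline visit.
    """
    ages, anchors = bin_centers(aging)
    start_age = int(round(treatment.baseline_age_mean))
    if not (ages[0] <= start_age <= ages[-1]):
        raise ValueError(
            f"treatment start age {start_age} outside aging anchor range "
            f"[{ages[0]}, {ages[-1]}]; refusing to extrapolate"
        )
    anchor_at_start = float(np.interp(start_age, ages, anchors))
    if len(treatment.bmd) == 0 or treatment.bmd[0] == 0:
        raise ValueError("treatment dataset lacks a baseline BMD value")
    scale = anchor_at_start / treatment.bmd[0]
    btm_changes = {}
    for marker, (t, raw) in treatment.btm.items():
        if raw[0] == 0:
            raise ValueError(f"zero baseline for marker {marker}")
        btm_changes[marker] = (start_age + np.asarray(t), raw / raw[0] - 1.0)
    regimen = treatment.regimen
    return HybridDataset(
        label=treatment.label,
        aging_ages=ages,
        aging_bmd=anchors,
        treat_ages=start_age + treatment.times,
        treat_bmd=treatment.bmd * scale,
        btm_changes=btm_changes,
        treatment_start_age=start_age,
        regimen=regimen,
        provenance={
            "aging_label": aging.label,
            "treatment_label": treatment.label,
            "baseline_age_mean": treatment.baseline_age_mean,
            "bmd_scale_factor": scale,
        },
    )


def load_collection(directory: str | Path) -> list[HybridDataset]:
    """Assemble hybrid datasets from a directory tree.

    Expects one ``aging*.csv`` file and any number of treatment CSVs (each
    with its JSON sidecar); every treatment dataset is merged with the
    aging dataset.
    """
    directory = Path(directory)
    aging_files = sorted(directory.glob("aging*.csv"))
    if not aging_files:
        raise FileNotFoundError(f"no aging dataset found in {directory}")
    aging = AgingDataset.read(aging_files[0])
    hybrids = []
    for f in sorted(directory.glob("*.csv")):
        if f in aging_files:
            continue
        treatment = TreatmentDataset.read(f)
        hybrids.append(build_hybrid(aging, treatment))
    return hybrids
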