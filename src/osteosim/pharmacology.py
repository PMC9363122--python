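"""Dosing regimens, drug pharmacokinetics and effect multipliers.

Five drugs in four classes are represented:

* denosumab (RANKL antibody) — blocks pre-osteoclast differentiation,
* romosozumab and blosozumab (sclerostin antibodies) — reduce the free
  sclerostin seen by all regulatory inputs,
* alendronate (bisphosphonate) — binds to bone matrix (slow-release bone
  compartment), enhances osteoclast apoptosis and reduces resorption
  efficiency,
* teriparatide (PTH analog, anabolic regimes only) — up-regulates
  osteoblast recruitment.

Antiresorptives (denosumab, alendronate) additionally shift the BMC target
upward, standing in for promotion of secondary mineralization.

Pharmacokinetics are linear: each dose is an instantaneous bolus into a
depot compartment (subcutaneous for the antibodies and teriparatide, oral
with low bioavailability for alendronate), first-order absorption into a
central compartment, first-order elimination, and — for the bisphosphonate
only — exchange with a bone-bound compartment with slow release.
Pharmacodynamic responses are saturating Emax/Hill functions of the central
(or, for alendronate, bone-bound) amount; all multipliers are 1 at zero
drug.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path

import numpy as np
import yaml

from .core import DrugEffects, hill_up

__all__ = [
    "DrugSpec",
    "DRUGS",
    "DRUG_LETTERS",
    "DoseEvent",
    "TreatmentBlock",
    "Regimen",
    "make_block_regimen",
    "parse_duration",
    "zero_drug_state",
    "pk_derivatives",
    "apply_dose",
    "drug_effects",
    "load_regimen",
    "save_regimen",
]

logger = logging.getLogger(__name__)

PK_COMPARTMENTS = ("depot", "central", "bone")


@dataclasses.dataclass(frozen=True)
class DrugSpec:
    """Identity and class of a drug; numeric PK/PD constants live in the
    parameter registry under ``pk_<id>_*`` / ``pd_<id>_*`` names."""

    drug_id: str
    drug_class: str
    letter: str


DRUGS: dict[str, DrugSpec] = {
    "denosumab": DrugSpec("denosumab", "rankl_antibody", "D"),
    "romosozumab": DrugSpec("romosozumab", "sclerostin_antibody", "R"),
    "blosozumab": DrugSpec("blosozumab", "sclerostin_antibody", "B"),
    "alendronate": DrugSpec("alendronate", "bisphosphonate", "A"),
    "teriparatide": DrugSpec("teriparatide", "pth_analog", "T"),
}

DRUG_LETTERS = {spec.letter: drug_id for drug_id, spec in DRUGS.items()}

_DURATION_UNITS = {"d": 1.0 / 365.0, "w": 1.0 / 52.0, "mo": 1.0 / 12.0, "yr": 1.0}


def parse_duration(text: str | float) -> float:
    """Parse a duration like ``"6 mo"``, ``"1 w"``, ``"2 yr"`` into years."""
    if isinstance(text, (int, float)):
        return float(text)
    parts = text.strip().split()
    if len(parts) == 1:  # forms like "6mo"
        for unit in sorted(_DURATION_UNITS, key=len, reverse=True):
            if parts[0].endswith(unit):
                parts = [parts[0][: -len(unit)], unit]
                break
    if len(parts) != 2 or parts[1] not in _DURATION_UNITS:
        raise ValueError(f"cannot parse duration {text!r}")
    return float(parts[0]) * _DURATION_UNITS[parts[1]]


@dataclasses.dataclass(frozen=True)
class DoseEvent:
    drug_id: str
    time: float  # subject age in years
    dose: float  # mg

    def __post_init__(self):
        if self.drug_id not in DRUGS:
            raise ValueError(f"unknown drug {self.drug_id!r}")
        if self.dose <= 0:
            raise ValueError("dose must be positive")


@dataclasses.dataclass(frozen=True)
class TreatmentBlock:
    label: str
    drug_id: str
    start: float
    end: float


@dataclasses.dataclass
class Regimen:
    """Ordered dose events grouped into labelled treatment blocks."""

    events: list[DoseEvent] = dataclasses.field(default_factory=list)
    blocks: list[TreatmentBlock] = dataclasses.field(default_factory=list)

    def __post_init__(self):
        self.events = sorted(self.events, key=lambda ev: (ev.time, ev.drug_id))

    def __len__(self) -> int:
        return len(self.events)

    def drug_ids(self) -> list[str]:
        return sorted({ev.drug_id for ev in self.events})

    def total_dose(self) -> dict[str, float]:
        totals: dict[str, float] = {}
        for ev in self.events:
            totals[ev.drug_id] = totals.get(ev.drug_id, 0.0) + ev.dose
        return totals

    @property
    def start(self) -> float | None:
        return self.events[0].time if self.events else None

    @property
    def end(self) -> float | None:
        """End of the last treatment block (or last dose if blocks absent)."""
        if self.blocks:
            return max(b.end for b in self.blocks)
        return self.events[-1].time if self.events else None

    @property
    def label(self) -> str:
        return "".join(DRUGS[b.drug_id].letter for b in self.blocks)


def make_block_regimen(
    blocks: list[tuple | dict], start_age: float | None = None
) -> Regimen:
    """Expand treatment blocks into a bolus-event regimen.

    Each block is ``(drug_id, dose_mg, interval_yr, duration_yr)`` (or a dict
    with those keys plus an optional absolute ``start`` age).  Doses fall at
    the block start and every interval thereafter, strictly before the block
    end.  Blocks without an explicit start follow the previous block
    back-to-back; explicit starts may overlap (parallel administration),
    which is allowed but logged.
    """
    events: list[DoseEvent] = []
    block_meta: list[TreatmentBlock] = []
    cursor = start_age
    for blk in blocks:
        if isinstance(blk, dict):
            drug_id = blk["drug"]
            dose = float(blk["dose_mg"])
            interval = parse_duration(blk["every"])
            duration = parse_duration(blk["for"])
            start = blk.get("start")
        else:
            drug_id, dose, interval, duration = blk[:4]
            start = blk[4] if len(blk) > 4 else None
        if interval <= 0 or duration <= 0:
            raise ValueError("interval and duration must be positive")
        if start is None:
            if cursor is None:
                raise ValueError("first block needs a start age")
            start = cursor
        start = float(start)
        end = start + float(duration)
        for existing in block_meta:
            if start < existing.end and end > existing.start:
                logger.info(
                    "blocks %s and %s overlap (parallel administration)",
                    existing.label,
                    drug_id,
                )
        n_doses = math.ceil(round(duration / interval, 9))
        times = start + interval * np.arange(n_doses)
        times = times[times < end - 1e-12]
        events.extend(DoseEvent(drug_id, float(t), float(dose)) for t in times)
        block_meta.append(
            TreatmentBlock(DRUGS[drug_id].letter, drug_id, start, end)
        )
        cursor = max(end, cursor) if cursor is not None else end
    return Regimen(events=events, blocks=block_meta)


# ---------------------------------------------------------------------------
# pharmacokinetics


def zero_drug_state(drug_ids: list[str]) -> dict[str, np.ndarray]:
    """Empty PK state: per drug, (depot, central, bone) amounts in mg."""
    return {d: np.zeros(3) for d in drug_ids}


def _pk_rates(p, drug_id: str) -> tuple[float, float, float, float]:
    ka = getattr(p, f"pk_{drug_id}_ka")
    ke = getattr(p, f"pk_{drug_id}_ke")
    if DRUGS[drug_id].drug_class == "bisphosphonate":
        kb = p.pk_alendronate_k_bone
        kr = p.pk_alendronate_k_release
    else:
        kb = kr = 0.0
    return ka, ke, kb, kr


def pk_derivatives(
    drug_state: dict[str, np.ndarray], params
) -> dict[str, np.ndarray]:
    """Time derivative of every drug's compartment amounts (mg/yr).

    Dose events are impulses handled by the integrator (see
    :func:`apply_dose`), not part of the continuous derivative.
    """
    p = params if not hasattr(params, "compile") else params.compile()
    out = {}
    for drug_id, amounts in drug_state.items():
        if drug_id not in DRUGS:
            raise ValueError(f"unknown drug {drug_id!r}")
        depot, central, bone = amounts
        ka, ke, kb, kr = _pk_rates(p, drug_id)
        out[drug_id] = np.array(
            [
                -ka * depot,
                ka * depot - (ke + kb) * central + kr * bone,
                kb * central - kr * bone,
            ]
        )
    return out


def apply_dose(drug_state: dict[str, np.ndarray], event: DoseEvent, params) -> None:
    """Add a bolus to the depot compartment (scaled by bioavailability)."""
    p = params if not hasattr(params, "compile") else params.compile()
    F = getattr(p, f"pk_{event.drug_id}_F")
    drug_state[event.drug_id][0] += F * event.dose


# ---------------------------------------------------------------------------
# pharmacodynamics


def drug_effects(drug_state: dict[str, np.ndarray], params) -> DrugEffects:
    """Map PK compartment amounts to per-target effect multipliers.

    All effects are neutral (1) at zero drug, follow saturating Emax/Hill
    responses and combine multiplicatively across drugs hitting the same
    target.  Compartment amounts may be scalars or equal-length arrays
    (the latter is used when post-processing whole trajectories).
    """
    p = params if not hasattr(params, "compile") else params.compile()
    eff = {f.name: 1.0 for f in dataclasses.fields(DrugEffects)}
    mc_shift = 0.0
    for drug_id, amounts in drug_state.items():
        central = np.clip(amounts[1], 0.0, None)
        cls = DRUGS[drug_id].drug_class
        if cls == "rankl_antibody":
            h = hill_up(central, p.pd_denosumab_ec50, p.pd_denosumab_n)
            eff["oc_differentiation"] = eff["oc_differentiation"] * (
                1.0 - p.pd_denosumab_emax * h
            )
            mc_shift = mc_shift + p.pd_denosumab_mc_shift * h
        elif cls == "sclerostin_antibody":
            emax = getattr(p, f"pd_{drug_id}_emax")
            ec50 = getattr(p, f"pd_{drug_id}_ec50")
            n = getattr(p, f"pd_{drug_id}_n")
            eff["free_sclerostin"] = eff["free_sclerostin"] * (
                1.0 - emax * hill_up(central, ec50, n)
            )
        elif cls == "bisphosphonate":
            bone = np.clip(amounts[2], 0.0, None)
            h = hill_up(bone, p.pd_alendronate_ec50, p.pd_alendronate_n)
            eff["oc_apoptosis"] = eff["oc_apoptosis"] * (
                1.0 + p.pd_alendronate_emax_apo * h
            )
            eff["resorption"] = eff["resorption"] * (
                1.0 - p.pd_alendronate_emax_res * h
            )
            mc_shift = mc_shift + p.pd_alendronate_mc_shift * h
        elif cls == "pth_analog":
            h = hill_up(central, p.pd_teriparatide_ec50, p.pd_teriparatide_n)
            eff["ob_recruitment"] = eff["ob_recruitment"] * (
                1.0 + p.pd_teriparatide_emax * h
            )
        else:  # pragma: no cover - registry is closed
            raise ValueError(f"unknown drug class {cls!r}")
    eff["mc_target"] = eff["mc_target"] + mc_shift
    return DrugEffects(**eff)


# ---------------------------------------------------------------------------
# regimen files


def save_regimen(regimen_blocks: list[dict], path: str | Path) -> None:
    """Write a block-format regimen description (YAML list of blocks)."""
    Path(path).write_text(yaml.safe_dump(regimen_blocks, sort_keys=False))


def load_regimen(path: str | Path, start_age: float | None = None) -> Regimen:
    """Read a block-format regimen file and expand it into dose events."""
    blocks = yaml.safe_load(Path(path).read_text())
    if not isinstance(blocks, list):
        raise ValueError("regimen file must contain a list of blocks")
    return make_block_regimen(blocks, start_age=start_age)
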