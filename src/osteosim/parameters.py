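"""Parameter registry for the bone-remodeling model.

All rates are in units of 1/year; cell densities, sclerostin and the
regulatory signals are dimensionless, normalized so that the premenopausal,
drug-free homeostatic state equals 1 in every pool.  Drug amounts are in mg,
so EC50-type thresholds are in mg as well.

Every parameter is a named :class:`Parameter` with a value, a ``free`` flag
(whether it participates in calibration), bounds and a unit string.  Source
terms that are pinned by the homeostatic fixed-point conditions (precursor
formation rates, sclerostin secretion, mature-pool apoptosis) are *derived*
quantities, not registry entries; see :meth:`ModelParameters.compile`.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from types import SimpleNamespace
from typing import Iterator, Mapping

import numpy as np
import yaml

__all__ = ["Parameter", "ModelParameters", "reference_parameters"]


@dataclasses.dataclass
class Parameter:
    """A single model parameter with calibration metadata."""

    value: float
    free: bool = False
    lower: float = -math.inf
    upper: float = math.inf
    unit: str = ""

    def validate(self, name: str) -> None:
        if not (self.lower <= self.value <= self.upper):
            raise ValueError(
                f"parameter {name!r}: value {self.value} outside bounds "
                f"[{self.lower}, {self.upper}]"
            )
        if name.startswith(("rate_", "pk_")) and self.value <= 0:
            raise ValueError(f"rate constant {name!r} must be positive")
        if name.startswith("K_") and self.value <= 0:
            raise ValueError(f"threshold {name!r} must be positive")
        if name.startswith("n_") and self.value < 1:
            raise ValueError(f"Hill exponent {name!r} must be >= 1")


class ModelParameters:
    """Ordered registry of named parameters.

    Behaves like a mapping from name to :class:`Parameter`.  The free subset
    (in registry order) defines the calibration vector.
    """

    def __init__(self, entries: Mapping[str, Parameter] | None = None):
        self._entries: dict[str, Parameter] = dict(entries or {})

    # -- mapping protocol -------------------------------------------------
    def __getitem__(self, name: str) -> Parameter:
        return self._entries[name]

    def __setitem__(self, name: str, param: Parameter) -> None:
        param.validate(name)
        self._entries[name] = param

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def items(self):
        return self._entries.items()

    def value(self, name: str) -> float:
        return self._entries[name].value

    # -- calibration interface -------------------------------------------
    def free_names(self) -> list[str]:
        return [k for k, p in self._entries.items() if p.free]

    def free_values(self) -> np.ndarray:
        return np.array([p.value for p in self._entries.values() if p.free])

    def free_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([p.lower for p in self._entries.values() if p.free])
        hi = np.array([p.upper for p in self._entries.values() if p.free])
        return lo, hi

    def with_free_values(self, vector: np.ndarray) -> "ModelParameters":
        """Return a copy with the free entries replaced by ``vector``."""
        names = self.free_names()
        if len(vector) != len(names):
            raise ValueError(f"expected {len(names)} free values, got {len(vector)}")
        out = self.copy()
        for name, v in zip(names, vector):
            p = out._entries[name]
            out._entries[name] = dataclasses.replace(p, value=float(v))
        return out

    def set_free(self, names: list[str]) -> "ModelParameters":
        """Return a copy in which exactly ``names`` carry the free flag."""
        unknown = set(names) - set(self._entries)
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")
        out = self.copy()
        for k, p in out._entries.items():
            out._entries[k] = dataclasses.replace(p, free=k in names)
        return out

    def copy(self) -> "ModelParameters":
        return ModelParameters(
            {k: dataclasses.replace(p) for k, p in self._entries.items()}
        )

    def validate(self) -> None:
        for name, p in self._entries.items():
            p.validate(name)

    # -- compiled view ----------------------------------------------------
    def compile(self) -> SimpleNamespace:
        """Flatten to an attribute namespace, adding derived constants.

        The homeostatic fixed point (all pools = 1 at estrogen = 1, no
        drugs) pins the precursor source terms, the mature-pool apoptosis
        rates and the sclerostin secretion rate:

        * ``beta_pre_oc = rate_preoc_to_oc + rate_preoc_apoptosis``
        * ``beta_pre_ob = rate_preob_to_ob + rate_preob_apoptosis``
        * ``rate_oc_apoptosis = rate_preoc_to_oc``
        * ``rate_ob_apoptosis = rate_preob_to_ob``
        * ``sigma_scl = rate_scl_clearance`` (secretion per unit osteocyte)
        """
        ns = SimpleNamespace(**{k: p.value for k, p in self._entries.items()})
        ns.beta_pre_oc = ns.rate_preoc_to_oc + ns.rate_preoc_apoptosis
        ns.beta_pre_ob = ns.rate_preob_to_ob + ns.rate_preob_apoptosis
        ns.rate_oc_apoptosis = ns.rate_preoc_to_oc
        ns.rate_ob_apoptosis = ns.rate_preob_to_ob
        ns.sigma_scl = ns.rate_scl_clearance
        return ns

    # -- file round-trip ---------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        data = {
            name: {
                "value": p.value,
                "free": p.free,
                "lower": p.lower,
                "upper": p.upper,
                "unit": p.unit,
            }
            for name, p in self._entries.items()
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParameters":
        data = yaml.safe_load(Path(path).read_text())
        entries = {
            name: Parameter(
                value=float(d["value"]),
                free=bool(d["free"]),
                lower=float(d["lower"]),
                upper=float(d["upper"]),
                unit=str(d.get("unit", "")),
            )
            for name, d in data.items()
        }
        out = cls(entries)
        out.validate()
        return out


def _p(value, free=False, lower=-math.inf, upper=math.inf, unit=""):
    return Parameter(value=value, free=free, lower=lower, upper=upper, unit=unit)


def reference_parameters() -> ModelParameters:
    """The package's reference parameter configuration.

    Values were chosen from physiological anchors: a homeostatic skeletal
    turnover of 6 %/yr, osteoclast/osteoblast lifespans of weeks/months,
    osteocyte lifespans of decades, a postmenopausal bone loss of roughly
    0.6 %/yr (≈ 20–25 % total-hip BMD decline between ages 25 and 85), and
    characteristic magnitudes of BMD/CTX/P1NP responses to the five drugs.
    Exactly 31 entries are flagged free for calibration.
    """
    mp = ModelParameters()

    # cell and tissue rate constants (1/yr)
    mp["rate_turnover"] = _p(0.06, True, 0.01, 0.3, "1/yr")
    mp["rate_preoc_to_oc"] = _p(26.0, True, 5.0, 80.0, "1/yr")
    mp["rate_preoc_apoptosis"] = _p(8.0, True, 0.5, 40.0, "1/yr")
    mp["rate_preob_to_ob"] = _p(4.0, True, 0.5, 20.0, "1/yr")
    mp["rate_preob_apoptosis"] = _p(4.0, True, 0.5, 20.0, "1/yr")
    mp["rate_ocy_apoptosis"] = _p(0.1, True, 0.01, 1.0, "1/yr")
    mp["rate_scl_clearance"] = _p(52.0, False, 1.0, 500.0, "1/yr")
    mp["rate_mineralization"] = _p(0.8, True, 0.05, 5.0, "1/yr")
    mp["K_rho_floor"] = _p(0.01, False, 1e-4, 0.5, "")

    # regulatory couplings (dimensionless thresholds on normalized signals)
    mp["K_scl_oc"] = _p(1.0, True, 0.01, 10.0, "")
    mp["n_scl_oc"] = _p(1.0, True, 1.0, 4.0, "")
    mp["K_scl_ob"] = _p(0.5, True, 0.1, 40.0, "")
    mp["n_scl_ob"] = _p(1.0, False, 1.0, 4.0, "")
    mp["K_rs_ob"] = _p(3.0, True, 0.05, 20.0, "")
    mp["n_rs_ob"] = _p(1.0, False, 1.0, 4.0, "")
    mp["K_est_ocapo"] = _p(0.003, True, 1e-4, 1.0, "")
    mp["n_est_ocapo"] = _p(1.0, False, 1.0, 4.0, "")
    mp["K_est_scl"] = _p(7.4, True, 0.05, 20.0, "")
    mp["n_est_scl"] = _p(1.0, False, 1.0, 4.0, "")

    # bone turnover marker map exponents
    mp["exp_ctx"] = _p(1.0, True, 0.2, 3.0, "")
    mp["exp_p1np"] = _p(1.0, True, 0.2, 3.0, "")
    mp["exp_bsap"] = _p(0.7, True, 0.2, 3.0, "")

    # estrogen curve (fixed from literature, not fitted)
    mp["estrogen_premenopausal"] = _p(1.0, False, 0.5, 2.0, "")
    mp["estrogen_floor"] = _p(0.1, False, 0.01, 1.0, "")
    mp["menopause_age"] = _p(51.0, False, 40.0, 60.0, "yr")
    mp["menopause_width"] = _p(2.0, False, 0.5, 10.0, "yr")

    # pharmacokinetics (1/yr; F dimensionless bioavailability)
    mp["pk_denosumab_ka"] = _p(30.0, False, 1.0, 500.0, "1/yr")
    mp["pk_denosumab_ke"] = _p(9.7, False, 1.0, 100.0, "1/yr")
    mp["pk_denosumab_F"] = _p(1.0, False, 0.0, 1.0, "")
    mp["pk_romosozumab_ka"] = _p(40.0, False, 1.0, 500.0, "1/yr")
    mp["pk_romosozumab_ke"] = _p(19.8, False, 1.0, 100.0, "1/yr")
    mp["pk_romosozumab_F"] = _p(1.0, False, 0.0, 1.0, "")
    mp["pk_blosozumab_ka"] = _p(50.0, False, 1.0, 500.0, "1/yr")
    mp["pk_blosozumab_ke"] = _p(36.0, False, 1.0, 200.0, "1/yr")
    mp["pk_blosozumab_F"] = _p(1.0, False, 0.0, 1.0, "")
    mp["pk_alendronate_ka"] = _p(400.0, False, 10.0, 5000.0, "1/yr")
    mp["pk_alendronate_ke"] = _p(200.0, False, 10.0, 5000.0, "1/yr")
    mp["pk_alendronate_F"] = _p(0.006, False, 0.0, 1.0, "")
    mp["pk_alendronate_k_bone"] = _p(100.0, True, 1.0, 1000.0, "1/yr")
    mp["pk_alendronate_k_release"] = _p(0.7, True, 0.01, 2.0, "1/yr")
    mp["pk_teriparatide_ka"] = _p(3000.0, False, 100.0, 50000.0, "1/yr")
    mp["pk_teriparatide_ke"] = _p(1000.0, False, 100.0, 50000.0, "1/yr")
    mp["pk_teriparatide_F"] = _p(1.0, False, 0.0, 1.0, "")

    # pharmacodynamics (EC50s in mg of compartment amount)
    mp["pd_denosumab_emax"] = _p(0.97, True, 0.0, 1.0, "")
    mp["pd_denosumab_ec50"] = _p(0.5, True, 0.1, 100.0, "mg")
    mp["pd_denosumab_n"] = _p(2.0, False, 1.0, 4.0, "")
    mp["pd_romosozumab_emax"] = _p(0.65, True, 0.0, 1.0, "")
    mp["pd_romosozumab_ec50"] = _p(30.0, True, 1.0, 500.0, "mg")
    mp["pd_romosozumab_n"] = _p(2.0, False, 1.0, 4.0, "")
    mp["pd_blosozumab_emax"] = _p(0.65, True, 0.0, 1.0, "")
    mp["pd_blosozumab_ec50"] = _p(45.0, True, 1.0, 500.0, "mg")
    mp["pd_blosozumab_n"] = _p(2.0, False, 1.0, 4.0, "")
    mp["pd_alendronate_emax_apo"] = _p(0.4, True, 0.0, 5.0, "")
    mp["pd_alendronate_emax_res"] = _p(0.35, True, 0.0, 1.0, "")
    mp["pd_alendronate_ec50"] = _p(3.0, True, 0.1, 100.0, "mg")
    mp["pd_alendronate_n"] = _p(2.0, False, 1.0, 4.0, "")
    mp["pd_teriparatide_emax"] = _p(4.0, True, 0.0, 10.0, "")
    mp["pd_teriparatide_ec50"] = _p(0.005, True, 1e-5, 1.0, "mg")
    mp["pd_teriparatide_n"] = _p(2.0, False, 1.0, 4.0, "")
    mp["pd_denosumab_mc_shift"] = _p(0.015, True, 0.0, 0.2, "")
    mp["pd_alendronate_mc_shift"] = _p(0.02, True, 0.0, 0.2, "")

    mp.validate()
    return mp
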