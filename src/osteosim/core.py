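"""Core ODE model of a representative bone remodeling unit (BRU).

Eight dynamic components: pre-osteoclasts, osteoclasts, pre-osteoblasts,
osteoblasts, osteocytes, sclerostin, bone density and bone mineral content
(BMC).  Cell pools and sclerostin are nondimensionalized so the
premenopausal, drug-free homeostatic state is exactly 1 in every component;
bone density is a fraction of the young-adult reference and BMC a fraction
of its unperturbed steady state.  BMD is the product of bone density and
BMC.

Regulation enters through normalized Hill multipliers ``H(x)/H(1)`` so that
every multiplier equals 1 at the homeostatic reference, which keeps the
all-ones fixed point analytically exact:

* sclerostin promotes osteoclastogenesis and inhibits both osteoblast
  recruitment and osteoblastic bone formation,
* estrogen promotes osteoclast apoptosis and represses sclerostin secretion,
* the resorption signal (bone-matrix-derived factors, released in proportion
  to the instantaneous resorption rate) promotes osteoblast recruitment,
  coupling resorption to subsequent formation.

Drug effects arrive as neutral-at-1 multipliers (see
:mod:`osteosim.pharmacology`) on specific targets.
"""

from __future__ import annotations

import dataclasses
from types import SimpleNamespace

import numpy as np
import scipy.optimize

__all__ = [
    "BoneState",
    "DrugEffects",
    "RegulatorySignals",
    "hill_up",
    "hill_down",
    "resorption_rate",
    "formation_rate",
    "resorption_signal",
    "rhs",
    "steady_state",
]

STATE_FIELDS = ("pre_oc", "oc", "pre_ob", "ob", "ocy", "scl", "rho", "mc")


@dataclasses.dataclass
class BoneState:
    """State of the representative BRU (all components dimensionless)."""

    pre_oc: float = 1.0
    oc: float = 1.0
    pre_ob: float = 1.0
    ob: float = 1.0
    ocy: float = 1.0
    scl: float = 1.0
    rho: float = 1.0
    mc: float = 1.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in STATE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "BoneState":
        return cls(**{f: float(v) for f, v in zip(STATE_FIELDS, arr)})

    @property
    def bmd(self) -> float:
        """Bone mineral density: product of bone density and BMC."""
        return self.rho * self.mc


@dataclasses.dataclass
class DrugEffects:
    """Per-target drug-effect multipliers; the neutral value is 1.

    ``mc_target`` multiplies the BMC set point (antiresorptives shift it
    above 1, transiently raising the degree of mineralization).
    """

    oc_differentiation: float = 1.0  # RANKL antibody: < 1
    free_sclerostin: float = 1.0  # sclerostin antibodies: < 1
    oc_apoptosis: float = 1.0  # bisphosphonate: > 1
    resorption: float = 1.0  # bisphosphonate: < 1
    ob_recruitment: float = 1.0  # PTH analog (anabolic): > 1
    mc_target: float = 1.0

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            if np.any(np.asarray(getattr(self, f.name)) <= 0):
                raise ValueError(f"drug-effect multiplier {f.name} must be > 0")


@dataclasses.dataclass
class RegulatorySignals:
    """Exogenous and algebraic inputs to the BRU dynamics."""

    estrogen: float = 1.0
    resorption_signal: float | None = None  # computed from state if None
    drug_effects: DrugEffects = dataclasses.field(default_factory=DrugEffects)


def _check_hill_args(K, n) -> None:
    if np.any(np.asarray(K) <= 0):
        raise ValueError("Hill threshold K must be > 0")
    if np.any(np.asarray(n) < 1):
        raise ValueError("Hill exponent n must be >= 1")


def hill_up(x, K, n):
    """Saturating activation x^n / (K^n + x^n), in [0, 1)."""
    _check_hill_args(K, n)
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("Hill input must be nonnegative")
    xn = x**n
    return xn / (K**n + xn)


def hill_down(x, K, n):
    """Saturating repression K^n / (K^n + x^n) = 1 - hill_up(x, K, n)."""
    _check_hill_args(K, n)
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("Hill input must be nonnegative")
    Kn = K**n
    return Kn / (Kn + x**n)


def _nh_up(x, K, n):
    """Hill activation normalized to equal 1 at the reference input x = 1."""
    return hill_up(x, K, n) / hill_up(1.0, K, n)


def _nh_down(x, K, n):
    """Hill repression normalized to equal 1 at x = 1."""
    return hill_down(x, K, n) / hill_down(1.0, K, n)


def _as_namespace(params) -> SimpleNamespace:
    return params if isinstance(params, SimpleNamespace) else params.compile()


def _rho_floor(rho, K):
    # smooth factor -> 0 as rho -> 0, normalized to 1 at rho = 1; prevents
    # resorption from driving bone density negative
    return (rho / (rho + K)) * (1.0 + K)


def resorption_rate(state: BoneState, params, effects: DrugEffects | None = None):
    """Instantaneous bone resorption rate (fraction of reference bone/yr)."""
    p = _as_namespace(params)
    e = effects or DrugEffects()
    return (
        p.rate_turnover
        * state.oc
        * e.resorption
        * _rho_floor(state.rho, p.K_rho_floor)
    )


def formation_rate(state: BoneState, params, effects: DrugEffects | None = None):
    """Instantaneous bone formation rate (fraction of reference bone/yr)."""
    p = _as_namespace(params)
    e = effects or DrugEffects()
    s_eff = state.scl * e.free_sclerostin
    return p.rate_turnover * state.ob * _nh_down(s_eff, p.K_scl_ob, p.n_scl_ob)


def resorption_signal(state: BoneState, params, effects: DrugEffects | None = None):
    """Bone-matrix-derived signal, proportional to the resorption rate.

    The proportionality constant is fixed by the nondimensionalization: the
    signal is 1 at the homeostatic reference, hence it equals the resorption
    rate divided by its reference value (the turnover rate constant).
    """
    p = _as_namespace(params)
    return resorption_rate(state, p, effects) / p.rate_turnover


def rhs(state: BoneState, age: float, signals: RegulatorySignals, params) -> BoneState:
    """Time derivative (per year) of the BRU state.

    ``age`` is carried for interface uniformity; all explicit time
    dependence enters through ``signals`` (the estrogen level and drug
    effects are evaluated by the caller).
    """
    arr = state.as_array()
    if np.any(arr < 0):
        raise ValueError("state components must be nonnegative")
    p = _as_namespace(params)
    e = signals.drug_effects
    d = _rhs_array(arr, signals.estrogen, e, p, signals.resorption_signal)
    return BoneState.from_array(d)


def _rhs_array(
    y: np.ndarray,
    estrogen: float,
    e: DrugEffects,
    p: SimpleNamespace,
    rs: float | None = None,
) -> np.ndarray:
    """Array-valued right-hand side (the integrator-facing form)."""
    u, c, v, b, ocy, s, rho, mc = y

    s_eff = s * e.free_sclerostin
    if rs is None:
        rs = c * e.resorption * _rho_floor(rho, p.K_rho_floor)

    # regulatory multipliers, all equal to 1 at the homeostatic reference
    phi_oc_diff = _nh_up(s_eff, p.K_scl_oc, p.n_scl_oc) * e.oc_differentiation
    phi_oc_apo = _nh_up(estrogen, p.K_est_ocapo, p.n_est_ocapo) * e.oc_apoptosis
    phi_ob_rec = (
        _nh_down(s_eff, p.K_scl_ob, p.n_scl_ob)
        * _nh_up(rs, p.K_rs_ob, p.n_rs_ob)
        * e.ob_recruitment
    )
    phi_form = _nh_down(s_eff, p.K_scl_ob, p.n_scl_ob)
    phi_scl_sec = _nh_down(estrogen, p.K_est_scl, p.n_est_scl)

    du = p.beta_pre_oc - (p.rate_preoc_to_oc * phi_oc_diff + p.rate_preoc_apoptosis) * u
    dc = p.rate_preoc_to_oc * phi_oc_diff * u - p.rate_oc_apoptosis * phi_oc_apo * c
    dv = p.beta_pre_ob - (p.rate_preob_to_ob * phi_ob_rec + p.rate_preob_apoptosis) * v
    db = p.rate_preob_to_ob * phi_ob_rec * v - p.rate_ob_apoptosis * b
    docy = p.rate_ocy_apoptosis * (b - ocy)
    ds = p.sigma_scl * phi_scl_sec * ocy - p.rate_scl_clearance * s
    drho = p.rate_turnover * (
        b * phi_form - c * e.resorption * _rho_floor(rho, p.K_rho_floor)
    )
    dmc = p.rate_mineralization * (e.mc_target - mc)

    return np.array([du, dc, dv, db, docy, ds, drho, dmc])


def steady_state(params, estrogen: float = 1.0) -> BoneState:
    """Steady state of the cell/sclerostin subsystem at a given estrogen level.

    At the reference (``estrogen = 1``, no drugs) this is exactly the
    all-ones state and the full right-hand side vanishes.  Away from the
    reference, bone density has no finite steady state (it drifts at the
    constant rate set by the cell imbalance); it is held at 1 and excluded
    from the residual, while BMC sits at its drug-free target 1.
    """
    if estrogen <= 0:
        raise ValueError("estrogen level must be positive")
    p = _as_namespace(params)
    e = DrugEffects()

    def residual(z):
        y = np.concatenate([z, [1.0, 1.0]])
        return _rhs_array(np.abs(y), estrogen, e, p)[:6]

    sol = scipy.optimize.root(residual, np.ones(6), method="hybr", tol=1e-13)
    z = np.abs(sol.x)
    res = np.max(np.abs(residual(z)))
    if not sol.success or res > 1e-10:
        raise RuntimeError(
            f"steady-state solve failed (residual {res:.3e}): {sol.message}"
        )
    return BoneState.from_array(np.concatenate([z, [1.0, 1.0]]))
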