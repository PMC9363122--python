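"""Age-dependent serum estrogen input representing aging and menopause.

The curve is a fixed physiological input (taken from the literature, not
fitted): a smooth logistic decline from the premenopausal plateau
(normalized to 1) to a postmenopausal floor, centered at the menopause age.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["EstrogenCurve", "estrogen_level", "curve_from_parameters"]


@dataclasses.dataclass
class EstrogenCurve:
    premenopausal_level: float = 1.0
    postmenopausal_floor: float = 0.1
    menopause_age: float = 51.0
    transition_width: float = 2.0  # years over which most of the drop occurs

    def __post_init__(self):
        if not (0 < self.postmenopausal_floor <= self.premenopausal_level):
            raise ValueError("floor must be in (0, premenopausal_level]")
        if self.transition_width <= 0:
            raise ValueError("transition width must be positive")

    def __call__(self, age):
        return estrogen_level(self, age)

    @classmethod
    def constant(cls, level: float = 1.0) -> "EstrogenCurve":
        """A flat curve (used e.g. to probe the homeostatic fixed point)."""
        return cls(
            premenopausal_level=level,
            postmenopausal_floor=level,
            menopause_age=51.0,
            transition_width=2.0,
        )


def estrogen_level(curve: EstrogenCurve, age):
    """Relative serum estrogen at a given age (premenopausal = 1).

    Logistic sigmoid: the midpoint of the two plateaus is reached at the
    menopause age and the decline is nonincreasing in age.
    """
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be nonnegative")
    scale = curve.transition_width / 2.0
    z = np.clip((age - curve.menopause_age) / scale, -700.0, 700.0)
    frac = 1.0 / (1.0 + np.exp(z))
    lvl = curve.postmenopausal_floor + (
        curve.premenopausal_level - curve.postmenopausal_floor
    ) * frac
    return float(lvl) if lvl.ndim == 0 else lvl


def curve_from_parameters(params) -> EstrogenCurve:
    """Build the curve from the shared parameter registry (fixed entries)."""
    return EstrogenCurve(
        premenopausal_level=params.value("estrogen_premenopausal"),
        postmenopausal_floor=params.value("estrogen_floor"),
        menopause_age=params.value("menopause_age"),
        transition_width=params.value("menopause_width"),
    )
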