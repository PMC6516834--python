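"""Four-state bending/binding equilibrium model.

The complex can be open or closed (tightly bent), on or off the
microtubule.  With Keq_free and Keq_bound the open/closed equilibrium
constants off and on the microtubule, microscopic reversibility around
the four-state cycle fixes the affinity penalty of the closed form:

    Kd_closed = Kd_open * Keq_bound / Keq_free

Equilibrium constants for opening are obtained from measured high-FRET
(closed-state) fractions as Keq = (1 - f_closed) / f_closed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["EquilibriumModel", "keq_from_fraction", "kd_ratio", "model_from_fractions"]


@dataclass(frozen=True)
class EquilibriumModel:
    keq_free: float
    keq_bound: float
    keq_free_se: float | None = None
    keq_bound_se: float | None = None

    def __post_init__(self):
        if self.keq_free <= 0 or self.keq_bound <= 0:
            raise ValueError("equilibrium constants must be positive")

    @property
    def kd_ratio(self) -> float:
        """Kd_closed / Kd_open; exact microscopic-reversibility identity."""
        return self.keq_bound / self.keq_free

    @property
    def fold_change(self) -> int:
        return round(self.kd_ratio)

    @property
    def kd_ratio_se(self) -> float | None:
        if self.keq_free_se is None or self.keq_bound_se is None:
            return None
        r = self.kd_ratio
        return r * math.sqrt(
            (self.keq_bound_se / self.keq_bound) ** 2
            + (self.keq_free_se / self.keq_free) ** 2
        )


def keq_from_fraction(f_closed: float, f_se: float | None = None):
    """Equilibrium constant for opening from the closed-state fraction.

    Keq = (1 - f) / f.  With ``f_se`` given, also returns the delta-method
    standard error |dKeq/df| * f_se = f_se / f**2.
    """
    if not (0.0 < f_closed < 1.0):
        raise ValueError("fraction must lie strictly between 0 and 1")
    keq = (1.0 - f_closed) / f_closed
    if f_se is None:
        return keq
    return keq, f_se / f_closed**2


def kd_ratio(keq_bound: float, keq_free: float) -> tuple[float, int]:
    """Affinity penalty of the closed conformation.

    Returns (Kd_closed/Kd_open, nearest-integer fold change).  Both the
    raw ratio and the rounded fold change are reported, since published
    fold changes are typically quoted from rounded Keq values.
    """
    model = EquilibriumModel(keq_free=keq_free, keq_bound=keq_bound)
    return model.kd_ratio, model.fold_change


def model_from_fractions(
    f_closed_free: float,
    f_closed_bound: float,
    f_free_se: float | None = None,
    f_bound_se: float | None = None,
) -> EquilibriumModel:
    """Build the equilibrium model directly from measured high-FRET
    fractions of free and microtubule-bound populations."""
    kf = keq_from_fraction(f_closed_free, f_free_se)
    kb = keq_from_fraction(f_closed_bound, f_bound_se)
    kf, kf_se = kf if isinstance(kf, tuple) else (kf, None)
    kb, kb_se = kb if isinstance(kb, tuple) else (kb, None)
    return EquilibriumModel(
        keq_free=kf, keq_bound=kb, keq_free_se=kf_se, keq_bound_se=kb_se
    )
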