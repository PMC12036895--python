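"""Short-time spread model: diffusion plus binding, no replication.

On time scales shorter than the virus replication cycle (< 16 h) the free
virus field obeys a diffusion equation with first-order removal by binding,

    dV/dt = D_V Laplacian(V) - gamma_b V,

started from a point inoculum of V0 virions.  The substitution
``phi = V exp(gamma_b t)`` turns this into the plain heat equation, so the
field is the 2-D heat kernel damped by ``exp(-gamma_b t)``.  The *spread
radius* is the distance at which the field falls to the detection threshold
V_min; it shrinks with increasing binding rate and vanishes at a critical
binding rate beyond which no spread is detectable at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpreadQuery",
    "NO_SPREAD",
    "virus_field",
    "spread_radius",
    "critical_binding_rate",
]

#: Sentinel radius for the "no detectable spread" regime (gamma_b at or
#: beyond the critical binding rate).  A value, not an exception, so that
#: sweeps over the binding rate stay total.
NO_SPREAD = 0.0


@dataclass(frozen=True)
class SpreadQuery:
    """Arguments of the spread-radius formula.

    ``v_ratio`` is the dimensionless ratio V0/V_min of the inoculum size to
    the detection threshold; only this ratio enters the radius.
    """

    t: float        # hours
    D_V: float      # mm^2/hour
    gamma_b: float  # 1/hour
    v_ratio: float  # V0 / V_min

    def __post_init__(self) -> None:
        if self.t <= 0:
            raise ValueError("t must be positive")
        if self.D_V <= 0:
            raise ValueError("D_V must be positive")
        if self.gamma_b < 0:
            raise ValueError("gamma_b must be non-negative")
        if self.v_ratio <= 0:
            raise ValueError("v_ratio must be positive")


def virus_field(x, y, t: float, V0: float, D_V: float, gamma_b: float):
    """Free-virus titre density at (x, y) mm and time t hours.

    The damped 2-D heat kernel

        V(x, y, t) = exp(-gamma_b t) * V0/(4 pi D_V t)
                     * exp(-(x^2 + y^2)/(4 D_V t)),

    i.e. the fundamental solution of the heat equation scaled by the
    surviving (unbound) fraction.  Its integral over the plane is
    ``V0 * exp(-gamma_b t)``.
    """
    if t <= 0:
        raise ValueError("t must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    kernel = V0 / (4 * math.pi * D_V * t) * np.exp(
        -(x ** 2 + y ** 2) / (4 * D_V * t))
    return math.exp(-gamma_b * t) * kernel


def spread_radius(q: SpreadQuery) -> float:
    """Radius (mm) at which the virus field equals the detection threshold.

    Solving ``V(r, 0, t) = V_min`` for r gives

        r = sqrt( 4 D_V t * ( ln[ v_ratio / (4 pi D_V t) ] - gamma_b t ) ).

    When the bracket is non-positive the field never reaches the
    threshold anywhere and :data:`NO_SPREAD` (radius 0) is returned.
    """
    bracket = math.log(q.v_ratio / (4 * math.pi * q.D_V * q.t)) \
        - q.gamma_b * q.t
    if bracket <= 0:
        return NO_SPREAD
    return math.sqrt(4 * q.D_V * q.t * bracket)


def critical_binding_rate(t: float, D_V: float, v_ratio: float) -> float:
    """Binding rate (1/hour) at which the spread radius vanishes.

    The unique zero of the spread-radius bracket:

        gamma_b* = (1/t) * ln( v_ratio / (4 pi D_V t) ).

    For binding rates at or above gamma_b* all virions are bound before the
    field can exceed the detection threshold at any distance.
    """
    if t <= 0 or D_V <= 0 or v_ratio <= 0:
        raise ValueError("t, D_V and v_ratio must be positive")
    arg = v_ratio / (4 * math.pi * D_V * t)
    if arg <= 1:
        raise ValueError(
            "inoculum never exceeds the detection threshold: "
            f"v_ratio/(4 pi D_V t) = {arg:.3g} <= 1")
    return math.log(arg) / t
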