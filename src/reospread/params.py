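"""Kinetic parameter bundles for the reovirus spread models.

All quantities are carried in a single canonical unit system: lengths in
millimetres, times in hours, virus amounts in virions (titre units).  The
:class:`VirusParams` bundle is consumed by every model stage — the
short-time binding/diffusion model, the travelling-wave analysis, and the
reaction-diffusion plaque simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Any


@dataclass(frozen=True)
class VirusParams:
    """Kinetic parameters of a virus strain on a cell monolayer.

    Parameters
    ----------
    D_V : float
        Diffusion coefficient of free virions in the medium, mm^2/hour.
    gamma_b : float
        First-order binding rate of free virions to cells, 1/hour.
        The fraction of virions bound after time ``t`` is ``1 - exp(-gamma_b*t)``.
    alpha : float
        Death (lysis) rate of infected cells, 1/hour.
    nu : float
        Fraction of cell-bound virions that establish a productive
        infection, cells/virion (dimensionless, in [0, 1]).
    b_tilde : float
        Infectious burst size: viable progeny virions released per lysed
        infected cell, virions/cell.
    label : str
        Free-text strain name.
    """

    D_V: float
    gamma_b: float
    alpha: float
    nu: float
    b_tilde: float
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("D_V", "gamma_b", "alpha", "nu", "b_tilde"):
            value = getattr(self, name)
            if not (value >= 0):
                raise ValueError(f"{name} must be >= 0, got {value!r}")
        if self.nu > 1:
            raise ValueError(f"nu must lie in [0, 1], got {self.nu!r}")

    @property
    def b(self) -> float:
        """Virus production rate b = alpha * b_tilde, virions/(cell*hour)."""
        return self.alpha * self.b_tilde

    @property
    def R_V(self) -> float:
        """Viral replication number R_V = b_tilde * nu (dimensionless).

        Mean number of newly infected cells produced per infected cell;
        the infection dies out when R_V < 1.
        """
        return self.b_tilde * self.nu

    def with_(self, **changes: Any) -> "VirusParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


#: Wild-type reovirus T3wt parameter set (estimated from monolayer assays).
T3WT = VirusParams(D_V=0.01, gamma_b=0.96, alpha=0.057, nu=0.01,
                   b_tilde=514, label="T3wt")

#: SV5 "supervirus" mutant: weaker binding, slightly larger burst size.
SV5 = VirusParams(D_V=0.01, gamma_b=0.28, alpha=0.057, nu=0.01,
                  b_tilde=732, label="SV5")

PRESETS = {"t3wt": T3WT, "sv5": SV5}


def preset(name: str) -> VirusParams:
    """Look up a named parameter preset (case-insensitive)."""
    try:
        return PRESETS[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
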