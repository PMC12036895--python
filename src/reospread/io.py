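"""CSV readers/writers for assay tables and result bundles.

The package ships the two printed assay tables it was built around as
fixtures (``data/table1_binding.csv`` — 1-hour percent bound per
replicate; ``data/table4_cell_death.csv`` — percent cell death over
15-36 h), loadable with :func:`load_binding_fixture` and
:func:`load_death_fixture`.  All CSV dialects are plain comma-separated
with a header row.

Column conventions:

* binding assays:        ``virus,replicate,percent_bound``
* cell-death series:     ``virus,time_h,percent_dead``
* diffusion columns:     ``fraction_index,center_mm,percent``
* burst-size series:     ``virus,time_h,virions_per_cell``
* front profiles:        ``position_px,intensity``
* estimate bundles:      ``parameter,virus,point,lower,upper,units,method``
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Union

import pandas as pd

from .estimation import (BindingAssay, DiffusionColumnProfile, EstimateWithCI,
                         TimeSeries)
from .front_validation import FrontProfile

__all__ = [
    "read_binding_csv",
    "read_death_csv",
    "read_column_csv",
    "read_burst_csv",
    "read_front_csv",
    "write_estimates_csv",
    "load_binding_fixture",
    "load_death_fixture",
]

PathLike = Union[str, Path]


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("reospread").joinpath("data", name)))


def read_binding_csv(path: PathLike) -> dict[str, BindingAssay]:
    """Read per-virus binding assays (``virus,replicate,percent_bound``)."""
    df = pd.read_csv(path)
    return {
        virus: BindingAssay.from_percents(sub["percent_bound"].tolist())
        for virus, sub in df.groupby("virus", sort=False)
    }


def read_death_csv(path: PathLike) -> dict[str, TimeSeries]:
    """Read per-virus cell-death series (``virus,time_h,percent_dead``).

    Values are converted from percent to fractions in [0, 1].
    """
    df = pd.read_csv(path)
    return {
        virus: TimeSeries(tuple(sub["time_h"]),
                          tuple(sub["percent_dead"] / 100.0))
        for virus, sub in df.groupby("virus", sort=False)
    }


def read_column_csv(path: PathLike, fraction_width: float = 5.5,
                    elapsed: float = 120.0) -> DiffusionColumnProfile:
    """Read a diffusion-column profile (``fraction_index,center_mm,percent``)."""
    df = pd.read_csv(path).sort_values("center_mm")
    return DiffusionColumnProfile(tuple(df["center_mm"]), tuple(df["percent"]),
                                  fraction_width=fraction_width,
                                  elapsed=elapsed)


def read_burst_csv(path: PathLike) -> dict[str, TimeSeries]:
    """Read per-virus burst series (``virus,time_h,virions_per_cell``)."""
    df = pd.read_csv(path)
    return {
        virus: TimeSeries(tuple(sub["time_h"]), tuple(sub["virions_per_cell"]))
        for virus, sub in df.groupby("virus", sort=False)
    }


def read_front_csv(path: PathLike, scale: float = 445.0,
                   day: int = 0) -> FrontProfile:
    """Read a fluorescence front profile (``position_px,intensity``)."""
    df = pd.read_csv(path).sort_values("position_px")
    return FrontProfile(tuple(df["position_px"]), tuple(df["intensity"]),
                        scale=scale, day=day)


def write_estimates_csv(path: PathLike,
                        estimates: list[dict]) -> None:
    """Write a flat estimate bundle.

    Each record needs keys ``parameter``, ``virus``, ``units`` and either
    an :class:`EstimateWithCI` under ``estimate`` or a plain ``point``.
    """
    rows = []
    for rec in estimates:
        est = rec.get("estimate")
        if isinstance(est, EstimateWithCI):
            point, lower, upper, method = est.point, est.lower, est.upper, est.method
        else:
            point, lower, upper, method = rec["point"], rec.get("lower"), \
                rec.get("upper"), rec.get("method", "")
        rows.append({"parameter": rec["parameter"], "virus": rec.get("virus", ""),
                     "point": point, "lower": lower, "upper": upper,
                     "units": rec.get("units", ""), "method": method})
    pd.DataFrame(rows).to_csv(path, index=False)


def load_binding_fixture() -> dict[str, BindingAssay]:
    """The shipped 1-hour binding table (percent bound per replicate)."""
    return read_binding_csv(_fixture_path("table1_binding.csv"))


def load_death_fixture() -> dict[str, TimeSeries]:
    """The shipped percent-cell-death table (15-36 h time course)."""
    return read_death_csv(_fixture_path("table4_cell_death.csv"))
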