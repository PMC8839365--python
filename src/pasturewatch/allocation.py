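"""Rising-plate-meter calibration and paddock-area allocation.

A rising plate meter measures compressed sward height (CSH, mm).  Monthly
calibration plots (clipped, dried, weighed) give a linear relation between
CSH and standing herbage mass (HM, kg DM/ha).  Herbage below a residual
sward height (default 20 mm) is treated as unavailable to grazing cows.

The paddock sizing rule delivers a target fraction of the group's dry
matter requirement over a multi-day grazing cycle::

    area = allowance * req_per_cow * n_cows * days
           / [(1 - loss) * (available HM per ha + regrowth * days)]

i.e. demand over the cycle divided by net herbage supply per hectare,
where ``loss`` accounts for trampling and rejected patches and regrowth
accrues daily over the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .errors import InfeasibleAllocationError, SingularFitError

__all__ = [
    "CalibrationLine",
    "FeedBudget",
    "PaddockPlan",
    "fit_calibration",
    "estimate_available_hm",
    "required_area",
    "read_calibration_plots",
    "REGROWTH_DEFAULTS",
]

#: Assumed daily herbage regrowth (kg DM/ha/day) by experimental month.
REGROWTH_DEFAULTS: dict[str, float] = {"May": 90.0, "July": 60.0, "September": 30.0}


@dataclass(frozen=True)
class CalibrationLine:
    """OLS line HM = slope * CSH + intercept for one calibration month."""

    slope: float  # kg DM/ha per mm
    intercept: float  # kg DM/ha
    month: str = ""
    n_plots: int = 0
    availability_floor: float = 20.0  # mm of residual sward unavailable to cows

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite")


@dataclass(frozen=True)
class FeedBudget:
    """Daily dry-matter requirement of one cow at 100% allowance.

    Split between pasture herbage and barn supplements (meadow hay plus
    dried whole-plant corn pellets).
    """

    pasture_kg_dm: float = 11.3
    hay_kg_dm: float = 5.7
    pellet_kg_dm: float = 3.1

    @property
    def barn_total_kg_dm(self) -> float:
        """Total barn supplement per cow and day (kg DM)."""
        return self.hay_kg_dm + self.pellet_kg_dm

    @property
    def total_kg_dm(self) -> float:
        return self.pasture_kg_dm + self.barn_total_kg_dm


@dataclass(frozen=True)
class PaddockPlan:
    """Allocation parameters for sizing one paddock."""

    paddock_id: str = ""
    days: int = 6
    allowance_fraction: float = 0.80  # fraction of requirement offered (0.8 = 20% restriction)
    loss_fraction: float = 0.10  # trampling / rejected-patch losses on DM basis
    regrowth_rate: float = 0.0  # kg DM/ha/day

    def __post_init__(self) -> None:
        if not 0.0 <= self.loss_fraction < 1.0:
            raise ValueError("loss_fraction must be in [0, 1)")
        if not 0.0 < self.allowance_fraction <= 1.0:
            raise ValueError("allowance_fraction must be in (0, 1]")
        if self.days < 1:
            raise ValueError("days must be >= 1")


def fit_calibration(
    plots: list[tuple[float, float]] | pd.DataFrame,
    month: str = "",
    availability_floor: float = 20.0,
) -> CalibrationLine:
    """Fit the monthly HM-on-CSH ordinary least squares line.

    ``plots`` is a list of ``(csh_mm, hm_kg_dm_ha)`` pairs or a DataFrame
    with columns ``csh_mm`` and ``hm_kg_dm_ha``.
    """
    if isinstance(plots, pd.DataFrame):
        csh = plots["csh_mm"].to_numpy(dtype=float)
        hm = plots["hm_kg_dm_ha"].to_numpy(dtype=float)
    else:
        arr = np.asarray(plots, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("plots must be (csh, hm) pairs")
        csh, hm = arr[:, 0], arr[:, 1]
    if csh.size < 2:
        raise ValueError("need at least 2 calibration plots")
    if np.ptp(csh) == 0:
        raise SingularFitError("all CSH values identical; cannot fit a line")
    res = scipy.stats.linregress(csh, hm)
    return CalibrationLine(
        slope=float(res.slope),
        intercept=float(res.intercept),
        month=month,
        n_plots=int(csh.size),
        availability_floor=availability_floor,
    )


def estimate_available_hm(cal: CalibrationLine, pre_csh: float) -> float:
    """Herbage mass (kg DM/ha) available above the residual sward floor.

    Difference of the calibration line at ``pre_csh`` and at the
    availability floor; clamped at zero for swards at or below the floor.
    """
    if pre_csh < 0:
        raise ValueError("pre_csh must be >= 0")
    available = cal.slope * (pre_csh - cal.availability_floor)
    return max(float(available), 0.0)


def required_area(
    cal: CalibrationLine,
    pre_csh: float,
    per_cow_requirement: float,
    n_cows: int,
    plan: PaddockPlan | None = None,
) -> float:
    """Paddock area (ha) delivering the planned herbage allowance.

    Demand is ``allowance_fraction`` of the group requirement over the
    cycle; supply per hectare is standing available herbage plus regrowth
    over the cycle, net of the loss fraction.
    """
    plan = plan or PaddockPlan()
    if per_cow_requirement <= 0:
        raise ValueError("per_cow_requirement must be positive")
    if n_cows < 1:
        raise ValueError("n_cows must be >= 1")
    standing = estimate_available_hm(cal, pre_csh)
    net_per_ha = (1.0 - plan.loss_fraction) * (standing + plan.regrowth_rate * plan.days)
    if net_per_ha <= 0:
        raise InfeasibleAllocationError("no net herbage available per hectare")
    demand = plan.allowance_fraction * per_cow_requirement * n_cows * plan.days
    return demand / net_per_ha


def read_calibration_plots(path) -> pd.DataFrame:
    """Read a calibration plot file (CSV columns: csh_mm, hm_kg_dm_ha)."""
    df = pd.read_csv(path)
    missing = {"csh_mm", "hm_kg_dm_ha"} - set(df.columns)
    if missing:
        raise KeyError(f"calibration file missing columns: {sorted(missing)}")
    return df
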