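"""Synthetic herds, cow-day experiments, and two-class training sets.

The generator emulates a rotational grazing experiment in which two groups
of dairy cows graze a sequence of deliberately undersized paddocks: each
group stays six days on one paddock, herbage availability declines towards
day 6, and behavioral variables, milk yield, and rumen fill drift
accordingly.  Every downstream stage of the pipeline (feature filtering,
reference labelling, classification, evaluation, trend screening) can be
exercised on this output without any external data.

The generative model is deliberately simple and fully documented: each
variable is a per-cow random intercept plus a fixed day-of-cycle offset
curve plus independent Gaussian day-to-day noise.  Rumen fill is generated
on a continuous latent scale and then rounded to the 0.5-step visual
scoring grid.  Milk yield is generated per cow and cycle for days 1..7 so
that next-day attribution of milk to grazing days is possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DesignError
from .variables import BEHAVIOR_VARS

__all__ = [
    "CowProfile",
    "ExperimentDesign",
    "EffectConfig",
    "make_herd",
    "simulate_experiment",
    "simulate_training_set",
    "simulate_hourly_day",
]

DAY_GRAZING = "day_grazing"
NIGHT_GRAZING = "night_grazing"


@dataclass(frozen=True)
class CowProfile:
    """Static attributes of one cow used for simulation and subgrouping."""

    cow_id: str
    group: str  # "A" or "B"
    parity: int
    grazing_experience: bool
    body_weight: float  # kg
    bcs: float  # body condition score, 2..5 in 0.25 steps
    days_in_milk: int
    gestation: bool
    mean_milk_yield: float  # kg/day

    def __post_init__(self) -> None:
        if self.parity < 1:
            raise ValueError("parity must be >= 1")
        if not (2.0 <= self.bcs <= 5.0) or round(self.bcs * 4) != self.bcs * 4:
            raise ValueError("bcs must lie in [2, 5] on a 0.25 grid")
        if self.mean_milk_yield <= 0:
            raise ValueError("mean_milk_yield must be positive")
        if self.group not in ("A", "B"):
            raise ValueError("group must be 'A' or 'B'")


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial layout of the grazing experiment.

    Defaults give 3 months x 2 cycles x 6 days x 2 groups x 10 cows
    = 720 cow-days.  ``grazing_mode_per_month`` states, per experimental
    month, whether cows grazed during the day (milk responds on the next
    day) or overnight (milk responds the same day).
    """

    n_months: int = 3
    cycles_per_month: int = 2
    days_per_cycle: int = 6
    n_groups: int = 2
    cows_per_group: int = 10
    grazing_mode_per_month: tuple[str, ...] = (DAY_GRAZING, NIGHT_GRAZING, DAY_GRAZING)

    def __post_init__(self) -> None:
        for name in ("n_months", "cycles_per_month", "days_per_cycle", "n_groups", "cows_per_group"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if len(self.grazing_mode_per_month) != self.n_months:
            raise ValueError("grazing_mode_per_month must have one entry per month")
        bad = set(self.grazing_mode_per_month) - {DAY_GRAZING, NIGHT_GRAZING}
        if bad:
            raise ValueError(f"unknown grazing modes: {sorted(bad)}")

    @property
    def total_cow_days(self) -> int:
        return (
            self.n_months
            * self.cycles_per_month
            * self.days_per_cycle
            * self.n_groups
            * self.cows_per_group
        )


def _default_day_curves() -> dict[str, tuple[float, ...]]:
    # Additive offsets for cycle days 1..6, day 1 = 0.  Eating- and
    # rumination-related variables start high on day 1 (ad libitum hay) and
    # decline towards day 6; bite frequency rises as herbage gets scarce;
    # the three low-relevance variables drift without a consistent
    # direction over days 3..6.
    return {
        "BITEFREQ": (0.0, 2.8, 5.8, 7.2, 7.7, 8.6),
        "RUMINATECHEW": (0.0, -600.0, -900.0, -1100.0, -3016.0, -3600.0),
        "RUMIBOUTTIME": (0.0, -8.0, -12.0, -16.0, -42.5, -50.0),
        "RUMIBOUTLENGTH": (0.0, -0.6, -0.9, -1.2, -2.7, -4.2),
        "GRAZINGSTART": (0.0, -0.8, -1.2, -1.6, -2.0, -3.5),
        "RUMICHEWBOLUS": (0.0, -0.3, -0.2, -0.4, -0.3, -1.3),
        "HACTIVITY": (0.0, -12.0, -4.0, 6.0, -2.0, 3.0),
        "LAYDOWN": (0.0, -0.6, 0.3, -0.2, 0.4, -0.3),
    }


#: Herd-level mean of each behavioral variable on cycle day 1.
DEFAULT_BASE_MEANS: dict[str, float] = {
    "RUMINATECHEW": 26000.0,
    "BITEFREQ": 46.0,
    "RUMICHEWBOLUS": 57.0,
    "HACTIVITY": 280.0,
    "RUMIBOUTLENGTH": 32.0,
    "RUMIBOUTTIME": 480.0,
    "GRAZINGSTART": 28.0,
    "LAYDOWN": 11.0,
}

#: Between-cow SD of the random intercept per variable.
DEFAULT_COW_SD: dict[str, float] = {
    "RUMINATECHEW": 3000.0,
    "BITEFREQ": 4.0,
    "RUMICHEWBOLUS": 6.0,
    "HACTIVITY": 40.0,
    "RUMIBOUTLENGTH": 4.0,
    "RUMIBOUTTIME": 50.0,
    "GRAZINGSTART": 4.0,
    "LAYDOWN": 2.5,
}

#: Within-cow day-to-day SD per variable.
DEFAULT_DAY_SD: dict[str, float] = {
    "RUMINATECHEW": 1500.0,
    "BITEFREQ": 2.5,
    "RUMICHEWBOLUS": 3.0,
    "HACTIVITY": 25.0,
    "RUMIBOUTLENGTH": 2.0,
    "RUMIBOUTTIME": 30.0,
    "GRAZINGSTART": 2.0,
    "LAYDOWN": 1.5,
}

#: Variables elevated on day 1 by the ad libitum hay offered in the barn.
HAY_SENSITIVE_VARS: tuple[str, ...] = (
    "RUMINATECHEW",
    "RUMIBOUTTIME",
    "RUMIBOUTLENGTH",
    "GRAZINGSTART",
)


@dataclass(frozen=True)
class EffectConfig:
    """Generative parameters of the cow-day simulation.

    ``day_curves`` are additive offsets per cycle day (length =
    ``days_per_cycle``) on each behavioral variable; ``milk_decline_curve``
    is the relative milk change per day (fraction of the cow's mean yield);
    ``rumen_decline_curve`` is the absolute latent rumen-fill change per
    day.  ``hay_day1_effect`` keeps the day-1 elevation of eating-related
    variables caused by ad libitum hay on the first cycle day; switching it
    off flattens day 1 onto day 2 for those variables.  ``dropout_prob``
    marks cow-days as excluded (estrus/illness/missing data) at random; it
    defaults to 0 so the full factorial is produced.
    """

    day_curves: dict[str, tuple[float, ...]] = field(default_factory=_default_day_curves)
    base_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASE_MEANS))
    cow_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COW_SD))
    day_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DAY_SD))
    milk_decline_curve: tuple[float, ...] = (0.0, -0.005, -0.02, -0.045, -0.075, -0.115)
    milk_day_rel_sd: float = 0.055
    rumen_decline_curve: tuple[float, ...] = (0.0, -0.1, -0.25, -0.4, -0.6, -0.8)
    rumen_base_mean: float = 3.7
    rumen_cow_sd: float = 0.4
    rumen_day_sd: float = 0.35
    hay_day1_effect: bool = True
    dropout_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for table in (self.cow_sd, self.day_sd):
            if any(v < 0 for v in table.values()):
                raise ValueError("SDs must be non-negative")
        if self.milk_day_rel_sd < 0 or self.rumen_day_sd < 0 or self.rumen_cow_sd < 0:
            raise ValueError("SDs must be non-negative")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ValueError("dropout_prob must be in [0, 1)")

    def curve(self, var: str, days_per_cycle: int) -> np.ndarray:
        """Day-offset curve for ``var``, validated against the design length."""
        c = np.asarray(self.day_curves[var], dtype=float)
        if c.size != days_per_cycle:
            raise ValueError(
                f"day curve for {var} has {c.size} entries, design needs {days_per_cycle}"
            )
        if not self.hay_day1_effect and var in HAY_SENSITIVE_VARS:
            c = c.copy()
            c[0] = c[1] if c.size > 1 else c[0]
        return c


def make_herd(
    n_cows: int,
    seed: int,
    *,
    weight_mean: float = 626.0,
    weight_sd: float = 64.0,
    milk_mean: float = 29.1,
    milk_sd: float = 6.3,
    bcs_mean: float = 2.8,
    bcs_sd: float = 0.4,
    primiparous_frac: float = 0.35,
    experience_frac: float = 0.5,
    gestation_frac: float = 0.6,
) -> list[CowProfile]:
    """Draw ``n_cows`` cow profiles and assign them to groups A and B.

    Group assignment alternates within each grazing-experience stratum,
    starting each stratum with the currently smaller group, so that group
    sizes and experience counts are balanced within one cow.
    Deterministic for a fixed ``seed``.
    """
    if n_cows < 0:
        raise ValueError("n_cows must be >= 0")
    rng = np.random.default_rng(seed)

    draws = []
    for i in range(n_cows):
        if rng.random() < primiparous_frac:
            parity = 1
        else:
            parity = int(rng.integers(2, 6))
        draws.append(
            dict(
                cow_id=f"cow{i + 1:03d}",
                parity=parity,
                grazing_experience=bool(rng.random() < experience_frac),
                body_weight=float(np.clip(rng.normal(weight_mean, weight_sd), 350.0, 1000.0)),
                bcs=float(np.clip(np.round(rng.normal(bcs_mean, bcs_sd) * 4) / 4, 2.0, 5.0)),
                days_in_milk=int(max(5, round(rng.normal(142.0, 44.0)))),
                gestation=bool(rng.random() < gestation_frac),
                mean_milk_yield=float(max(8.0, rng.normal(milk_mean, milk_sd))),
            )
        )

    counts = {"A": 0, "B": 0}
    groups: dict[str, str] = {}
    for experienced in (True, False):
        stratum = [d for d in draws if d["grazing_experience"] is experienced]
        current = "A" if counts["A"] <= counts["B"] else "B"
        for d in stratum:
            groups[d["cow_id"]] = current
            counts[current] += 1
            current = "B" if current == "A" else "A"

    return [CowProfile(group=groups[d["cow_id"]], **d) for d in draws]


def herd_to_frame(herd: list[CowProfile]) -> pd.DataFrame:
    """Tabulate a herd as a DataFrame (one row per cow)."""
    return pd.DataFrame([vars(c) for c in herd])


def _milk_relative_series(effects: EffectConfig, days_per_cycle: int) -> np.ndarray:
    """Relative milk offsets for days 1..days_per_cycle+1.

    The day after the cycle continues the slope of the last two cycle days:
    milk keeps falling for one more day before a fresh paddock restores it.
    """
    curve = np.asarray(effects.milk_decline_curve, dtype=float)
    if curve.size != days_per_cycle:
        raise ValueError(
            f"milk_decline_curve has {curve.size} entries, design needs {days_per_cycle}"
        )
    if curve.size >= 2:
        after = curve[-1] + (curve[-1] - curve[-2])
    else:
        after = curve[-1]
    return np.concatenate([curve, [after]])


def simulate_experiment(
    design: ExperimentDesign,
    herd: list[CowProfile],
    effects: EffectConfig,
) -> pd.DataFrame:
    """Simulate one cow-day record per cow and cycle day of the design.

    Returns a DataFrame with identifier columns (``cow_id``, ``group``,
    ``month``, ``cycle``, ``day``, ``paddock_id``, ``grazing_mode``), the
    eight behavioral variables, ``milk_kg`` (same-day milk), ``milk_next_kg``
    (milk of the following day, for next-day attribution), ``rumen_fill``
    (0.5-step score in [1, 5]) and an ``excluded`` flag.

    Paddocks are numbered sequentially over (month, cycle, group), so the
    default design produces paddocks 1..12.
    """
    if len(herd) != design.n_groups * design.cows_per_group:
        raise DesignError(
            f"herd size {len(herd)} != n_groups x cows_per_group "
            f"({design.n_groups} x {design.cows_per_group})"
        )
    group_names = sorted({c.group for c in herd})
    by_group: dict[str, list[CowProfile]] = {g: [] for g in group_names}
    for c in herd:
        by_group[c.group].append(c)
    if len(by_group) != design.n_groups or any(
        len(v) != design.cows_per_group for v in by_group.values()
    ):
        raise DesignError("herd group sizes do not match the design")

    rng = np.random.default_rng(effects.seed)
    days = design.days_per_cycle
    curves = {v: effects.curve(v, days) for v in BEHAVIOR_VARS}
    rumen_curve = np.asarray(effects.rumen_decline_curve, dtype=float)
    if rumen_curve.size != days:
        raise ValueError(
            f"rumen_decline_curve has {rumen_curve.size} entries, design needs {days}"
        )
    milk_rel = _milk_relative_series(effects, days)

    # One random intercept per cow and variable, drawn once up front.
    cow_eff = {
        c.cow_id: {v: rng.normal(0.0, effects.cow_sd[v]) for v in BEHAVIOR_VARS}
        for c in herd
    }
    rumen_base = {
        c.cow_id: effects.rumen_base_mean + rng.normal(0.0, effects.rumen_cow_sd)
        for c in herd
    }

    records: list[dict] = []
    for m in range(1, design.n_months + 1):
        mode = design.grazing_mode_per_month[m - 1]
        for cyc in range(1, design.cycles_per_month + 1):
            for gi, g in enumerate(group_names):
                paddock = ((m - 1) * design.cycles_per_month + (cyc - 1)) * design.n_groups + gi + 1
                for cow in by_group[g]:
                    milk_noise = rng.normal(0.0, effects.milk_day_rel_sd, size=days + 1)
                    milk_series = cow.mean_milk_yield * (1.0 + milk_rel + milk_noise)
                    milk_series = np.maximum(milk_series, 0.0)
                    for d in range(1, days + 1):
                        rec = {
                            "cow_id": cow.cow_id,
                            "group": g,
                            "month": m,
                            "cycle": cyc,
                            "day": d,
                            "paddock_id": paddock,
                            "grazing_mode": mode,
                        }
                        for v in BEHAVIOR_VARS:
                            val = (
                                effects.base_means[v]
                                + cow_eff[cow.cow_id][v]
                                + curves[v][d - 1]
                                + rng.normal(0.0, effects.day_sd[v])
                            )
                            rec[v] = max(val, 0.0)
                        rec["milk_kg"] = milk_series[d - 1]
                        rec["milk_next_kg"] = milk_series[d]
                        latent = (
                            rumen_base[cow.cow_id]
                            + rumen_curve[d - 1]
                            + rng.normal(0.0, effects.rumen_day_sd)
                        )
                        rec["rumen_fill"] = float(np.clip(np.round(latent * 2) / 2, 1.0, 5.0))
                        rec["excluded"] = bool(
                            effects.dropout_prob > 0 and rng.random() < effects.dropout_prob
                        )
                        records.append(rec)
    return pd.DataFrame(records)


#: Mean feature shift of the scarce class relative to the sufficient class
#: in the synthetic training data: under restriction, cows bite faster and
#: move their heads more while ruminating and lying less.
DEFAULT_TRAINING_SHIFT: dict[str, float] = {
    "RUMINATECHEW": -5000.0,
    "BITEFREQ": 8.0,
    "RUMICHEWBOLUS": -3.0,
    "HACTIVITY": 30.0,
    "RUMIBOUTLENGTH": -4.0,
    "RUMIBOUTTIME": -80.0,
    "GRAZINGSTART": -5.0,
    "LAYDOWN": -2.0,
}

#: Within-class SD of each feature in the synthetic training data.
DEFAULT_TRAINING_SD: dict[str, float] = {
    "RUMINATECHEW": 3500.0,
    "BITEFREQ": 5.0,
    "RUMICHEWBOLUS": 6.0,
    "HACTIVITY": 45.0,
    "RUMIBOUTLENGTH": 4.5,
    "RUMIBOUTTIME": 60.0,
    "GRAZINGSTART": 4.5,
    "LAYDOWN": 3.0,
}


def simulate_training_set(
    n_sufficient: int = 629,
    n_scarce: int = 592,
    shift: dict[str, float] | None = None,
    seed: int = 0,
    *,
    base_means: dict[str, float] | None = None,
    sds: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Simulate a labelled two-class training table of the eight features.

    Class 0 ("sufficient") features are Gaussian around ``base_means``;
    class 1 ("scarce") means are shifted by ``shift``.  Default sizes
    follow the 629 sufficient / 592 scarce records of the model-development
    dataset this pipeline emulates.
    """
    if n_sufficient < 0 or n_scarce < 0:
        raise ValueError("class counts must be >= 0")
    shift = dict(DEFAULT_TRAINING_SHIFT) if shift is None else dict(shift)
    base_means = dict(DEFAULT_BASE_MEANS) if base_means is None else dict(base_means)
    sds = dict(DEFAULT_TRAINING_SD) if sds is None else dict(sds)

    rng = np.random.default_rng(seed)
    n = n_sufficient + n_scarce
    cls = np.concatenate([np.zeros(n_sufficient, dtype=int), np.ones(n_scarce, dtype=int)])
    data = {"cls": cls}
    for v in BEHAVIOR_VARS:
        mu = base_means[v] + cls * shift.get(v, 0.0)
        data[v] = np.maximum(mu + rng.normal(0.0, sds[v], size=n), 0.0)
    return pd.DataFrame(data)


def simulate_hourly_day(
    cow_id: str,
    day: int,
    seed: int,
    *,
    n_pasture_hours: int = 9,
) -> pd.DataFrame:
    """Simulate one cow-day of hourly converter output (24 rows).

    ``n_pasture_hours`` consecutive hours starting at 07:00 are tagged
    ``pasture``, the rest ``barn``.  Useful for exercising the hourly
    aggregation path without sensor data.
    """
    rng = np.random.default_rng(seed)
    rows = []
    pasture_hours = set(range(7, 7 + n_pasture_hours))
    for hour in range(24):
        on_pasture = hour in pasture_hours
        resting = rng.random() < (0.25 if on_pasture else 0.55)
        rum_time = float(rng.uniform(20, 55)) if resting else float(rng.uniform(0, 15))
        rum_bouts = int(rum_time > 5) + int(rng.random() < 0.3)
        rows.append(
            dict(
                cow_id=cow_id,
                day=day,
                hour=hour,
                location="pasture" if on_pasture else "barn",
                bite_freq=float(rng.uniform(40, 65)) if on_pasture else float(rng.uniform(20, 45)),
                rum_chews=float(rum_time * rng.uniform(50, 70)),
                rum_time=rum_time,
                rum_bouts_started=rum_bouts,
                eating_bouts_started=int(rng.integers(0, 4 if on_pasture else 3)),
                chews_per_bolus=float(rng.uniform(45, 70)),
                head_activity=float(rng.uniform(150, 450)),
                lying_bouts=int(rng.integers(0, 2)),
            )
        )
    return pd.DataFrame(rows)
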