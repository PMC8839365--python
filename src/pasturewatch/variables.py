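"""Names and groupings of the daily behavioral variables.

The eight variables are the daily summaries produced by the noseband-sensor
converter software plus the pedometer lying-bout count, under their
converter column names:

==============  =========================================  =========
name            meaning                                    unit
==============  =========================================  =========
RUMINATECHEW    daily rumination chews                     n/day
BITEFREQ        prehension bite frequency while grazing    n/min
RUMICHEWBOLUS   rumination chews per bolus                 n/bolus
HACTIVITY       head movement activity index               units/h
RUMIBOUTLENGTH  mean rumination bout duration              min/bout
RUMIBOUTTIME    daily rumination time                      min/day
GRAZINGSTART    eating bouts started                       n/day
LAYDOWN         lying bouts                                n/day
==============  =========================================  =========
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: All eight behavioral variables, in canonical column order.
BEHAVIOR_VARS: tuple[str, ...] = (
    "RUMINATECHEW",
    "BITEFREQ",
    "RUMICHEWBOLUS",
    "HACTIVITY",
    "RUMIBOUTLENGTH",
    "RUMIBOUTTIME",
    "GRAZINGSTART",
    "LAYDOWN",
)

#: Hour-based variables that are averaged over the day.
MEAN_VARS: tuple[str, ...] = ("BITEFREQ", "RUMICHEWBOLUS", "HACTIVITY")

#: Count/duration variables that are summed over the day.
SUM_VARS: tuple[str, ...] = ("RUMINATECHEW", "RUMIBOUTTIME", "GRAZINGSTART", "LAYDOWN")

#: Variables screened out by the trend analysis as insensitive to a gradual
#: herbage decline (no consistent direction over the last four cycle days).
LOW_RELEVANCE_VARS: tuple[str, ...] = ("RUMICHEWBOLUS", "HACTIVITY", "LAYDOWN")


@dataclass(frozen=True)
class PredictorSet:
    """An ordered set of behavioral predictor columns for the classifiers.

    ``variant`` is ``"full8"`` (all eight variables) or ``"reduced5"``
    (the eight minus the three low-relevance variables).
    """

    names: tuple[str, ...]
    variant: str

    def __post_init__(self) -> None:
        unknown = set(self.names) - set(BEHAVIOR_VARS)
        if unknown:
            raise ValueError(f"unknown behavioral variables: {sorted(unknown)}")


FULL8 = PredictorSet(names=BEHAVIOR_VARS, variant="full8")
REDUCED5 = PredictorSet(
    names=tuple(v for v in BEHAVIOR_VARS if v not in LOW_RELEVANCE_VARS),
    variant="reduced5",
)

#: Lookup by variant name, for configs and the command line.
PREDICTOR_SETS: dict[str, PredictorSet] = {"full8": FULL8, "reduced5": REDUCED5}
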