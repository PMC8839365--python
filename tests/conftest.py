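import numpy as np
import pandas as pd
import pytest

from pasturewatch.simulate import (
    EffectConfig,
    ExperimentDesign,
    make_herd,
    simulate_experiment,
    simulate_hourly_day,
)


@pytest.fixture(scope="session")
def herd20():
    return make_herd(20, seed=7)


@pytest.fixture(scope="session")
def default_cow_days(herd20):
    """One simulated run of the default 720 cow-day design."""
    return simulate_experiment(ExperimentDesign(), herd20, EffectConfig(seed=11))


@pytest.fixture()
def hourly_day():
    """24 hourly converter rows for one cow-day, mixed pasture/barn."""
    return simulate_hourly_day("cow001", day=3, seed=42)


def make_marginal_labels(
    day_n=(91, 92, 101, 101, 99, 99),
    milk_pos=(0, 0, 8, 14, 19, 31),
    rumen_pos=(0, 0, 7, 8, 14, 24),
    overlap=(0, 0, 2, 4, 5, 13),
):
    """Milk and rumen label tables with prescribed per-day marginals.

    Within each day the first ``overlap`` cow-days are positive on both
    indicators, the next ``milk_pos - overlap`` on milk only, then
    ``rumen_pos - overlap`` on rumen only; the rest are negative.
    """
    milk_rows, rumen_rows = [], []
    for day, (n, m, r, o) in enumerate(zip(day_n, milk_pos, rumen_pos, overlap), start=1):
        assert o <= min(m, r) and m + r - o <= n
        for i in range(n):
            key = dict(cow_id=f"d{day}c{i:03d}", month=1, cycle=1, day=day)
            milk_rows.append(dict(key, indicator="milk", cls=int(i < m)))
            rumen_rows.append(
                dict(key, indicator="rumen", cls=int(i < o or m <= i < m + (r - o)))
            )
    return pd.DataFrame(milk_rows), pd.DataFrame(rumen_rows)


@pytest.fixture(scope="session")
def marginal_labels():
    return make_marginal_labels()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


# --- shared trend-fit fixtures -------------------------------------------

from pasturewatch.trends import TrendFit  # noqa: E402

#: Day-wise estimates echoing the qualitative course of each behavioral
#: variable over a six-day cycle: five variables move monotonically over
#: the last four days, three wobble without a consistent direction.
QUALITATIVE_DAY_MEANS = {
    "RUMINATECHEW": [26000, 25400, 25100, 24900, 22984, 22400],
    "BITEFREQ": [46.0, 48.8, 51.8, 53.2, 53.7, 54.6],
    "RUMICHEWBOLUS": [57.0, 56.7, 56.8, 56.6, 56.7, 55.7],
    "HACTIVITY": [280, 268, 276, 286, 278, 283],
    "RUMIBOUTLENGTH": [32.0, 31.4, 31.1, 30.8, 29.3, 27.8],
    "RUMIBOUTTIME": [480, 472, 468, 464, 437.5, 430],
    "GRAZINGSTART": [28.0, 27.2, 26.8, 26.4, 26.0, 24.5],
    "LAYDOWN": [11.0, 10.4, 11.3, 10.8, 11.4, 10.7],
}


def make_trend_fit(variable, estimates, half_width=0.05) -> TrendFit:
    est = np.asarray(estimates, dtype=float)
    return TrendFit(
        variable=variable,
        days=np.arange(1, 7),
        estimates=est,
        ci_lower=est - half_width,
        ci_upper=est + half_width,
    )
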