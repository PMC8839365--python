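import numpy as np
import pandas as pd
import pytest

from pasturewatch.reference import (
    attribute_milk_day,
    classify_days,
    combine,
    compute_baselines,
    compute_limits,
    limits_from_mean_sds,
)

from conftest import make_marginal_labels


def make_outcomes(
    milk7,
    rumen6,
    mode="day_grazing",
    cow="c1",
    month=1,
    cycle=1,
    excluded_days=(),
):
    """Outcome rows for one cow-cycle; ``milk7`` holds milk of days 1..7."""
    rows = []
    for d in range(1, 7):
        rows.append(
            dict(
                cow_id=cow,
                month=month,
                cycle=cycle,
                day=d,
                milk_kg=milk7[d - 1],
                milk_next_kg=milk7[d],
                rumen_fill=rumen6[d - 1],
                grazing_mode=mode,
                excluded=d in excluded_days,
            )
        )
    return pd.DataFrame(rows)


RUMEN_FLAT = [3.5] * 6


class TestAttribution:
    milk7 = [25.0, 24.0, 23.0, 22.0, 21.0, 20.0, 19.0]

    def test_day_grazing_uses_next_day_milk(self):
        out = attribute_milk_day(make_outcomes(self.milk7, RUMEN_FLAT, mode="day_grazing"))
        assert out.loc[out.day == 3, "milk_attr"].iloc[0] == 22.0  # day-4 milk

    def test_night_grazing_uses_same_day_milk(self):
        out = attribute_milk_day(make_outcomes(self.milk7, RUMEN_FLAT, mode="night_grazing"))
        assert out.loc[out.day == 3, "milk_attr"].iloc[0] == 23.0

    def test_shift_fallback_flags_last_day(self):
        df = make_outcomes(self.milk7, RUMEN_FLAT).drop(columns="milk_next_kg")
        out = attribute_milk_day(df, grazing_mode="day_grazing")
        assert bool(out.loc[out.day == 6, "milk_attr_missing"].iloc[0])
        assert out.loc[out.day == 3, "milk_attr"].iloc[0] == 22.0

    def test_mode_toggle_changes_labels_only_where_milk_straddles_limit(self):
        # days 2-4 share the same milk so both modes see the same baseline
        milk7 = [25.0, 25.0, 25.0, 25.0, 22.0, 20.0, 19.0]
        limits = limits_from_mean_sds(0.38, 5.9)  # milk limit 17.7%
        threshold = 25.0 * (1 - limits.milk_rel_limit / 100.0)
        labels = {}
        for mode in ("day_grazing", "night_grazing"):
            out = attribute_milk_day(make_outcomes(milk7, RUMEN_FLAT, mode=mode))
            lab = classify_days(out, compute_baselines(out), limits)
            lab = lab[lab.indicator == "milk"].set_index("day")["cls"]
            labels[mode] = lab
        for d in range(3, 7):
            differs = labels["day_grazing"][d] != labels["night_grazing"][d]
            straddles = (milk7[d - 1] < threshold) != (milk7[d] < threshold)
            assert differs == straddles


class TestBaselines:
    def test_rumen_and_milk_baseline_means(self):
        milk7 = [27.0, 28.0, 26.0, 24.0, 23.0, 22.0, 21.0]
        rumen = [4.0, 3.5, 3.0, 3.0, 2.5, 2.5]
        out = attribute_milk_day(make_outcomes(milk7, rumen, mode="day_grazing"))
        base = compute_baselines(out).iloc[0]
        assert base["rumen_baseline"] == pytest.approx(3.75)  # mean of days 1-2
        assert base["milk_baseline"] == pytest.approx(25.0)  # attributed days 2-3

    def test_excluded_baseline_day_flags_cycle_unlabelable(self):
        out = attribute_milk_day(
            make_outcomes([25.0] * 7, RUMEN_FLAT, excluded_days=(2,))
        )
        base = compute_baselines(out).iloc[0]
        assert not base["rumen_ok"] and not base["milk_ok"]

    def test_flags_match_brute_force_scan(self, rng):
        frames = []
        for i in range(12):
            excl = tuple(rng.choice(range(1, 7), size=rng.integers(0, 3), replace=False))
            frames.append(
                make_outcomes(
                    list(rng.uniform(18, 30, 7)),
                    list(rng.choice(np.arange(2, 9) / 2, 6)),
                    cow=f"c{i}",
                    excluded_days=excl,
                )
            )
        out = attribute_milk_day(pd.concat(frames, ignore_index=True))
        base = compute_baselines(out).set_index("cow_id")
        for cow, g in out.groupby("cow_id"):
            g = g.set_index("day")
            rumen_ok = all(not g.loc[d, "excluded"] for d in (1, 2))
            milk_ok = all(not g.loc[d, "excluded"] for d in (2, 3))
            assert base.loc[cow, "rumen_ok"] == rumen_ok
            assert base.loc[cow, "milk_ok"] == milk_ok


class TestLimits:
    def test_limit_is_three_times_average_sd(self):
        limits = limits_from_mean_sds(0.38, 5.9)
        assert limits.rumen_abs_limit == pytest.approx(1.14)
        assert limits.milk_rel_limit == pytest.approx(17.7)
        assert limits.k == 3.0

    def test_zero_variance_gives_zero_limits(self):
        frames = [
            make_outcomes([25.0] * 7, [3.5] * 6, cow=f"c{i}", cycle=c)
            for i in range(3)
            for c in (1, 2)
        ]
        out = attribute_milk_day(pd.concat(frames, ignore_index=True))
        limits = compute_limits(out)
        assert limits.rumen_abs_limit == 0.0
        assert limits.milk_rel_limit == 0.0

    def test_matches_brute_force_sd_oracle(self, rng):
        frames = []
        for i in range(8):
            for cycle in (1, 2):
                frames.append(
                    make_outcomes(
                        list(rng.uniform(18, 30, 7)),
                        list(rng.choice(np.arange(2, 11) / 2, 6)),
                        cow=f"c{i}",
                        cycle=cycle,
                    )
                )
        out = attribute_milk_day(pd.concat(frames, ignore_index=True))
        limits = compute_limits(out, k=3.0)

        rumen_sds, milk_sds = [], []
        for cow, g in out.groupby("cow_id"):
            rumen_vals = [
                g.loc[(g.day == d) & (g.cycle == c), "rumen_fill"].iloc[0]
                for c in (1, 2)
                for d in (1, 2)
            ]
            milk_vals = [
                g.loc[(g.day == d) & (g.cycle == c), "milk_attr"].iloc[0]
                for c in (1, 2)
                for d in (2, 3)
            ]
            rumen_sds.append(np.std(rumen_vals, ddof=1))
            milk_sds.append(100 * np.std(milk_vals, ddof=1) / np.mean(milk_vals))
        q1, q3 = np.percentile(milk_sds, [25, 75])
        kept = [s for s in milk_sds if s <= q3 + 3 * (q3 - q1)]
        assert limits.rumen_abs_limit == pytest.approx(3 * np.mean(rumen_sds))
        assert limits.milk_rel_limit == pytest.approx(3 * np.mean(kept))
        assert limits.outliers_excluded == len(milk_sds) - len(kept)


class TestClassification:
    LIMITS = limits_from_mean_sds(0.38, 5.9)

    def classify(self, milk7, rumen6):
        out = attribute_milk_day(make_outcomes(milk7, rumen6, mode="day_grazing"))
        return classify_days(out, compute_baselines(out), self.LIMITS)

    def test_twenty_percent_milk_drop_is_scarce(self):
        # baseline 25.0 (attributed days 2-3); day-5 attributed milk 20.0 = -20%
        milk7 = [25.0, 25.0, 25.0, 25.0, 25.0, 20.0, 20.0]
        labels = self.classify(milk7, RUMEN_FLAT)
        milk = labels[labels.indicator == "milk"].set_index("day")
        assert milk.loc[5, "cls"] == 1
        assert milk.loc[4, "cls"] == 0

    def test_rumen_drop_beyond_limit_is_scarce(self):
        rumen = [3.5, 4.0, 3.5, 3.0, 2.5, 2.5]  # baseline 3.75; day 5 drop 1.25
        labels = self.classify([25.0] * 7, rumen)
        rum = labels[labels.indicator == "rumen"].set_index("day")
        assert rum.loc[5, "cls"] == 1
        assert rum.loc[4, "cls"] == 0  # drop 0.75 < 1.14

    def test_milk_increase_is_sufficient(self):
        milk7 = [25.0, 25.0, 25.0, 25.0, 30.0, 31.0, 32.0]
        labels = self.classify(milk7, RUMEN_FLAT)
        assert (labels[labels.indicator == "milk"]["cls"] == 0).all()

    def test_decline_exactly_at_limit_is_sufficient(self):
        drop = 25.0 * (1 - self.LIMITS.milk_rel_limit / 100.0)
        milk7 = [25.0, 25.0, 25.0, 25.0, drop, drop, drop]
        labels = self.classify(milk7, RUMEN_FLAT)
        assert (labels[labels.indicator == "milk"]["cls"] == 0).all()

    def test_baseline_days_always_sufficient(self, rng):
        milk7 = list(rng.uniform(10, 30, 7))
        rumen = list(rng.choice(np.arange(2, 11) / 2, 6))
        labels = self.classify(milk7, rumen)
        assert (labels[labels.day <= 2]["cls"] == 0).all()

    def test_lowering_milk_never_unflags_scarcity(self):
        milk7 = [25.0, 25.0, 25.0, 25.0, 22.0, 20.0, 19.0]
        base_labels = self.classify(milk7, RUMEN_FLAT)
        lowered = [m - 3.0 if i >= 4 else m for i, m in enumerate(milk7)]
        low_labels = self.classify(lowered, RUMEN_FLAT)
        for d in range(3, 7):
            before = base_labels[(base_labels.indicator == "milk") & (base_labels.day == d)]
            after = low_labels[(low_labels.indicator == "milk") & (low_labels.day == d)]
            assert after["cls"].iloc[0] >= before["cls"].iloc[0]


class TestCombine:
    def test_observed_marginals_give_101_positives(self, marginal_labels):
        milk, rumen = marginal_labels
        combined = combine(milk, rumen)
        assert (combined["cls"] == 1).sum() == 101
        assert len(combined) == 583

    def test_inclusion_exclusion_on_random_labels(self, rng):
        milk, rumen = make_marginal_labels(
            day_n=(50, 50, 50, 50, 50, 50),
            milk_pos=(0, 0, 10, 12, 8, 20),
            rumen_pos=(0, 0, 5, 9, 14, 11),
            overlap=(0, 0, 3, 2, 6, 10),
        )
        combined = combine(milk, rumen)
        m, r = (milk["cls"] == 1).sum(), (rumen["cls"] == 1).sum()
        inter = (
            milk.merge(rumen, on=["cow_id", "month", "cycle", "day"])
            .query("cls_x == 1 and cls_y == 1")
            .shape[0]
        )
        assert (combined["cls"] == 1).sum() == m + r - inter

    def test_disjoint_positives_add(self):
        milk, rumen = make_marginal_labels(
            day_n=(30,) * 6, milk_pos=(0, 0, 5, 5, 5, 5), rumen_pos=(0, 0, 5, 5, 5, 5),
            overlap=(0,) * 6,
        )
        combined = combine(milk, rumen)
        assert (combined["cls"] == 1).sum() == 40

    def test_identical_labels_are_idempotent(self, marginal_labels):
        milk, _ = marginal_labels
        combined = combine(milk, milk)
        assert (combined["cls"] == 1).sum() == (milk["cls"] == 1).sum()

    def test_single_indicator_cow_days_pass_through(self, marginal_labels):
        milk, rumen = marginal_labels
        extra = pd.DataFrame(
            [dict(cow_id="only", month=1, cycle=1, day=6, indicator="milk", cls=1)]
        )
        combined = combine(pd.concat([milk, extra], ignore_index=True), rumen)
        row = combined[combined.cow_id == "only"]
        assert len(row) == 1 and row["cls"].iloc[0] == 1
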