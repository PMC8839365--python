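import numpy as np
import pandas as pd
import pytest

from pasturewatch.evaluate import (
    DEFAULT_SUBGROUPS,
    SubgroupSpec,
    auc_hard_label,
    confusion,
    evaluate,
    evaluate_subgroups,
    metrics,
    milk_as_predictor,
    positives_by_day,
    ranked_auc,
)
from pasturewatch.simulate import herd_to_frame, make_herd


class TestConfusion:
    def test_perfect_agreement(self, rng):
        v = rng.integers(0, 2, 100)
        cm = confusion(v, v)
        assert cm.fp == 0 and cm.fn == 0
        assert cm.tp + cm.tn == 100

    def test_total_disagreement(self, rng):
        v = rng.integers(0, 2, 100)
        cm = confusion(1 - v, v)
        assert cm.tp == 0 and cm.tn == 0

    def test_counts_match_paired_loop(self, rng):
        pred = rng.integers(0, 2, 583)
        ref = rng.integers(0, 2, 583)
        cm = confusion(pred, ref)
        tp = sum(1 for p, r in zip(pred, ref) if p == 1 and r == 1)
        tn = sum(1 for p, r in zip(pred, ref) if p == 0 and r == 0)
        fp = sum(1 for p, r in zip(pred, ref) if p == 1 and r == 0)
        fn = sum(1 for p, r in zip(pred, ref) if p == 0 and r == 1)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (tp, tn, fp, fn)
        assert cm.n == 583

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            confusion([0, 1], [0, 1, 0])


class TestMetrics:
    def test_ratio_arithmetic(self):
        cm = metrics(confusion([1, 1, 0, 0, 0] + [0] * 9 + [1], [1] * 5 + [0] * 10))
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (2, 3, 9, 1)
        assert cm.sensitivity == pytest.approx(0.4)
        assert cm.specificity == pytest.approx(0.9)
        assert cm.ppv == pytest.approx(2 / 3)

    def test_degenerate_predictor_has_undefined_ppv(self):
        cm = evaluate([0, 0, 0, 0], [1, 1, 0, 0])
        assert cm.sensitivity == 0.0
        assert cm.ppv is None
        assert "ppv" in cm.undefined

    def test_metrics_match_independent_ratios(self, rng):
        pred = rng.integers(0, 2, 1000)
        ref = rng.integers(0, 2, 1000)
        cm = evaluate(pred, ref)
        assert cm.sensitivity == pytest.approx(cm.tp / (cm.tp + cm.fn))
        assert cm.specificity == pytest.approx(cm.tn / (cm.tn + cm.fp))
        assert cm.ppv == pytest.approx(cm.tp / (cm.tp + cm.fp))

    def test_swapping_class_convention_swaps_sensitivity_specificity(self, rng):
        pred = rng.integers(0, 2, 400)
        ref = rng.integers(0, 2, 400)
        cm = evaluate(pred, ref)
        swapped = evaluate(1 - pred, 1 - ref)
        assert swapped.sensitivity == pytest.approx(cm.specificity)
        assert swapped.specificity == pytest.approx(cm.sensitivity)
        # PPV under the swapped convention is the NPV of the original
        assert swapped.ppv == pytest.approx(cm.tn / (cm.tn + cm.fn))


class TestHardLabelAuc:
    def test_milk_versus_rumen_value(self):
        assert auc_hard_label(0.45, 0.91) == pytest.approx(0.68)

    @pytest.mark.parametrize(
        "sens,spec,expected",
        [
            (0.10, 0.90, 0.50),
            (0.19, 0.84, 0.52),
            (0.06, 0.92, 0.49),
            (0.25, 0.81, 0.53),
            (0.15, 0.91, 0.53),
            (0.25, 0.84, 0.54),
            (0.06, 0.92, 0.49),
            (0.28, 0.82, 0.55),
            (0.12, 0.91, 0.51),
            (0.22, 0.85, 0.53),
            (0.06, 0.92, 0.49),
            (0.24, 0.82, 0.53),
        ],
    )
    def test_reproduces_reported_hard_label_aucs(self, sens, spec, expected):
        # half-a-last-digit rounding band (plus float-representation guard)
        assert auc_hard_label(sens, spec) == pytest.approx(expected, abs=0.005 + 1e-9)

    def test_perfect_classifier(self):
        assert auc_hard_label(1.0, 1.0) == 1.0

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            auc_hard_label(1.2, 0.5)

    def test_ranked_auc_agrees_for_two_valued_probabilities(self, rng):
        ref = rng.integers(0, 2, 500)
        pred = rng.integers(0, 2, 500)
        cm = evaluate(pred, ref)
        assert ranked_auc(pred.astype(float), ref) == pytest.approx(
            auc_hard_label(cm.sensitivity, cm.specificity)
        )


class TestSubgroups:
    @pytest.fixture()
    def compared(self, rng):
        herd = make_herd(20, seed=1)
        cows = [c.cow_id for c in herd]
        rows = []
        for cow in cows:
            for d in range(1, 7):
                rows.append(
                    dict(
                        cow_id=cow,
                        day=d,
                        pred=int(rng.random() < 0.2),
                        ref=int(rng.random() < 0.2),
                    )
                )
        return pd.DataFrame(rows), herd_to_frame(herd)

    def test_parity_subgroups_partition_total(self, compared):
        table, profiles = compared
        res = evaluate_subgroups(table, profiles).set_index("subgroup")
        assert res.loc["primiparous", "n"] + res.loc["multiparous", "n"] == len(table)
        for bands in (("high_milk", "medium_milk", "low_milk"),
                      ("high_bcs", "medium_bcs", "low_bcs")):
            present = [b for b in bands if b in res.index]
            assert sum(res.loc[b, "n"] for b in present) == len(table)

    def test_all_cows_subgroup_equals_overall(self, compared):
        table, profiles = compared
        spec = (SubgroupSpec("everyone", lambda c: True),)
        res = evaluate_subgroups(table, profiles, spec).iloc[0]
        cm = evaluate(table["pred"], table["ref"])
        assert (res["tp"], res["tn"], res["fp"], res["fn"]) == (cm.tp, cm.tn, cm.fp, cm.fn)

    def test_signal_bearing_subgroup_outscores_complement(self, rng):
        herd = make_herd(20, seed=2)
        profiles = herd_to_frame(herd)
        experienced = {c.cow_id for c in herd if c.grazing_experience}
        rows = []
        for c in herd:
            for d in range(1, 7):
                ref = int(rng.random() < 0.3)
                if c.cow_id in experienced:
                    pred = ref if rng.random() < 0.9 else 1 - ref
                else:
                    pred = int(rng.random() < 0.5)
                rows.append(dict(cow_id=c.cow_id, day=d, pred=pred, ref=ref))
        res = evaluate_subgroups(pd.DataFrame(rows), profiles).set_index("subgroup")
        assert res.loc["grazing_experience", "auc"] > res.loc["no_grazing_experience", "auc"]

    def test_empty_subgroup_omitted_with_warning(self, compared):
        table, profiles = compared
        spec = (SubgroupSpec("nobody", lambda c: False),)
        with pytest.warns(UserWarning, match="empty"):
            res = evaluate_subgroups(table, profiles, spec)
        assert res.empty


class TestMilkAsPredictor:
    def test_identical_labels_score_perfectly(self, marginal_labels):
        milk, _ = marginal_labels
        cm = milk_as_predictor(milk, milk)
        assert cm.sensitivity == 1.0 and cm.specificity == 1.0

    def test_all_negative_milk_has_zero_sensitivity(self, marginal_labels):
        milk, rumen = marginal_labels
        silent = milk.assign(cls=0)
        cm = milk_as_predictor(silent, rumen)
        assert cm.sensitivity == 0.0

    def test_equals_generic_confusion_with_roles_swapped(self, marginal_labels):
        milk, rumen = marginal_labels
        cm = milk_as_predictor(milk, rumen)
        key = ["cow_id", "month", "cycle", "day"]
        merged = milk.merge(rumen, on=key, suffixes=("_m", "_r"))
        direct = evaluate(merged["cls_m"], merged["cls_r"])
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (direct.tp, direct.tn, direct.fp, direct.fn)


def test_positives_by_day_counts_and_shares(marginal_labels):
    milk, _ = marginal_labels
    table = positives_by_day(milk).set_index("day")
    assert table.loc["3", "positives"] == 8
    assert table.loc["total", "n"] == 583
    assert table.loc["total", "positives"] == 72
    assert table.loc["total", "share_pct"] == pytest.approx(100 * 72 / 583)
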