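"""AUROC and trade-off analysis against brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from duetmil.evalmetrics import (auroc, curve_frame, mean_auroc_ci,
                                 pick_operating_point, probability_histogram,
                                 roc_points, stratified_auroc, tradeoff_curve)


def brute_force_auroc(p, y):
    """Pairwise concordance oracle: every (positive, negative) pair counted."""
    wins = ties = n = 0
    for (pi, yi), (pj, yj) in itertools.product(zip(p, y), repeat=2):
        if yi == 1 and yj == 0:
            n += 1
            wins += pi > pj
            ties += pi == pj
    return (wins + 0.5 * ties) / n


def _records(p, y, **extra):
    df = pd.DataFrame({"probability": p, "label": y})
    for k, v in extra.items():
        df[k] = v
    return df


class TestAuroc:
    def test_perfect_ranking(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_partial_ranking_matches_pair_count(self):
        assert auroc([0.9, 0.2, 0.8, 0.1], [1, 1, 0, 0]) == 0.75

    def test_all_tied_is_half(self):
        assert auroc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_and_sklearn(self, seed):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 21))
        y = np.zeros(n, dtype=int)
        y[: int(rng.integers(1, n))] = 1
        rng.shuffle(y)
        if y.sum() in (0, n):
            return
        p = rng.choice([0.1, 0.25, 0.5, 0.5, 0.9], size=n)  # ties likely
        got = auroc(p, y)
        assert got == pytest.approx(brute_force_auroc(p, y), abs=1e-12)
        assert got == pytest.approx(roc_auc_score(y, p), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_equals_trapezoid_under_empirical_roc(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 51))
        y = (rng.uniform(size=n) < 0.5).astype(int)
        if y.sum() in (0, n):
            return
        p = np.round(rng.uniform(size=n), 2)
        pts = roc_points(_records(p, y))
        area = np.trapezoid(pts[:, 1], pts[:, 0])
        assert auroc(p, y) == pytest.approx(area, abs=1e-10)


class TestMeanCI:
    def test_identical_folds_zero_width(self):
        mean, (lo, hi) = mean_auroc_ci([0.9, 0.9, 0.9])
        assert mean == lo == hi == 0.9

    def test_hand_computed_t_interval(self):
        # values 0.9 x4 and 1.0: mean .92, sd .04472, sem .02, t_4 = 2.7764
        mean, (lo, hi) = mean_auroc_ci([0.9, 0.9, 0.9, 0.9, 1.0])
        assert mean == pytest.approx(0.92)
        assert lo == pytest.approx(0.92 - 2.7764451 * 0.02, abs=1e-6)
        assert hi == pytest.approx(0.92 + 2.7764451 * 0.02, abs=1e-6)

    def test_symmetric_perturbation_keeps_mean(self):
        m0, _ = mean_auroc_ci([0.8, 0.9])
        m1, _ = mean_auroc_ci([0.8 - 0.05, 0.9 + 0.05])
        assert m0 == pytest.approx(m1)

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError):
            mean_auroc_ci([0.9])


class TestStratified:
    def test_single_group_equals_global(self):
        df = _records([0.9, 0.1, 0.7, 0.3], [1, 0, 1, 0], scanner="philips")
        out = stratified_auroc(df, "scanner")
        assert len(out) == 1
        assert out["auroc"].iloc[0] == auroc(df["probability"], df["label"])

    def test_noisier_stratum_scores_lower(self):
        rng = np.random.default_rng(0)
        n = 400
        y = rng.integers(0, 2, n)
        site = np.where(rng.uniform(size=n) < 0.5, "primary", "metastatic")
        noise = np.where(site == "primary", 0.1, 0.8)
        p = np.clip(0.5 + (y - 0.5) * 0.6 + rng.standard_normal(n) * noise, 0, 1)
        out = stratified_auroc(_records(p, y, site=site), "site").set_index("site")
        assert out.loc["primary", "auroc"] > out.loc["metastatic", "auroc"]

    def test_single_class_group_flagged_not_dropped(self):
        df = _records([0.9, 0.1, 0.8], [1, 0, 1],
                      scanner=["a", "a", "b"])
        out = stratified_auroc(df, "scanner").set_index("scanner")
        assert not out.loc["b", "defined"]
        assert np.isnan(out.loc["b", "auroc"])
        assert out.loc["a", "defined"]

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError):
            stratified_auroc(_records([0.5], [1]), "age")


class TestTradeoff:
    TOY = _records([0.9, 0.8, 0.6, 0.4, 0.2], [1, 1, 0, 1, 0])

    def test_enumerated_confusion_at_threshold(self):
        curve = tradeoff_curve(self.TOY)
        pt = next(p for p in curve if p.threshold == 0.6)
        assert pt.fn_pct == pytest.approx(20.0)
        assert pt.tn_pct == pytest.approx(20.0)
        assert pt.sensitivity == pytest.approx(2 / 3)

    def test_minimal_threshold_catches_every_positive(self):
        pt = tradeoff_curve(self.TOY)[0]
        assert pt.sensitivity == 1.0 and pt.fn_pct == 0.0

    def test_final_point_rejects_everything(self):
        pt = tradeoff_curve(self.TOY)[-1]
        assert pt.sensitivity == 0.0
        assert pt.tn_pct == pytest.approx(40.0)  # the two true negatives

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotonicity_along_threshold_sweep(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        y = (rng.uniform(size=n) < rng.uniform(0.2, 0.8)).astype(int)
        if y.sum() in (0, n):
            return
        p = np.round(rng.uniform(size=n), 2)
        curve = tradeoff_curve(_records(p, y))
        fn = [pt.fn_pct for pt in curve]
        sens = [pt.sensitivity for pt in curve]
        assert all(a <= b + 1e-12 for a, b in zip(fn, fn[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(sens, sens[1:]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            tradeoff_curve(_records([0.1, 0.9], [1, 1]))

    def test_curve_frame_columns(self):
        df = curve_frame(tradeoff_curve(self.TOY))
        assert list(df.columns) == ["threshold", "fn_pct", "tn_pct", "sensitivity"]


class TestOperatingPoint:
    def test_generous_budget_takes_max_tn(self):
        curve = tradeoff_curve(TestTradeoff.TOY)
        pt = pick_operating_point(curve, 100.0)
        assert pt.tn_pct == max(p.tn_pct for p in curve)

    def test_toy_budget_twenty_selects_enumerated_point(self):
        # within the FN% <= 20 budget the 0.8 threshold dominates: same one
        # false negative as 0.6 but both true negatives screened out
        pt = pick_operating_point(tradeoff_curve(TestTradeoff.TOY), 20.0)
        assert pt.threshold == 0.8
        assert pt.tn_pct == pytest.approx(40.0)
        assert pt.sensitivity == pytest.approx(2 / 3)

    def test_zero_budget_on_separable_curve_keeps_full_sensitivity(self):
        df = _records([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        pt = pick_operating_point(tradeoff_curve(df), 0.0)
        assert pt.sensitivity == 1.0 and pt.tn_pct == pytest.approx(50.0)

    def test_unreachable_budget_rejected(self):
        curve = tradeoff_curve(TestTradeoff.TOY)
        shifted = [pt for pt in curve if pt.fn_pct > 0]
        with pytest.raises(ValueError):
            pick_operating_point(shifted, 0.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_never_violates_budget(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        y = (rng.uniform(size=n) < 0.5).astype(int)
        if y.sum() in (0, n):
            return
        p = rng.uniform(size=n)
        target = float(rng.uniform(0, 100))
        curve = tradeoff_curve(_records(p, y))
        try:
            pt = pick_operating_point(curve, target)
        except ValueError:
            return
        assert pt.fn_pct <= target


class TestHistogram:
    def test_half_probability_lands_in_upper_of_two_bins(self):
        df = probability_histogram(_records([0.5] * 5, [1, 1, 1, 0, 0]), n_bins=2)
        upper = df[(df["bin_left"] == 0.5)]
        assert upper["count"].sum() == 5
        assert df[df["bin_left"] == 0.0]["count"].sum() == 0

    def test_counts_sum_to_class_sizes(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 100)
        df = probability_histogram(_records(rng.uniform(size=100), y), n_bins=7)
        for cls in (0, 1):
            assert df[df["label"] == cls]["count"].sum() == (y == cls).sum()

    def test_separated_classes_overlap_less_than_within_class(self):
        rng = np.random.default_rng(1)
        p = np.concatenate([rng.uniform(0.0, 0.3, 200), rng.uniform(0.7, 1.0, 200)])
        y = np.repeat([0, 1], 200)
        df = probability_histogram(_records(p, y), n_bins=10)
        pivot = df.pivot_table(index="bin_left", columns="label", values="count")
        between = np.minimum(pivot[0], pivot[1]).sum() / 200
        # within-class overlap of two random halves of the negatives
        h1, _ = np.histogram(p[:100], bins=np.linspace(0, 1, 11))
        h2, _ = np.histogram(p[100:200], bins=np.linspace(0, 1, 11))
        within = np.minimum(h1, h2).sum() / 100
        assert between < within

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            probability_histogram(_records([0.5], [1]), n_bins=1)
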