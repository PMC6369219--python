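"""ROC/AUC machinery, cutoffs, likelihood ratios and leakage-safe CV."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ftdindex as fi
from ftdindex.evaluation import sens_spec_at_cutoff

from conftest import auc_pairwise


scores_strategy = st.lists(
    st.floats(min_value=-5, max_value=5, allow_nan=False), min_size=1, max_size=25)


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = fi.roc_auc([-3, -2.5, 1, 2], [1, 1, 0, 0])
        assert auc == 1.0

    def test_all_ties(self):
        _, auc = fi.roc_auc([1.0] * 6, [1, 1, 1, 0, 0, 0])
        assert auc == 0.5

    def test_worked_example_matches_pairwise_count(self):
        pos, neg = [-2, -1, 0], [-1.5, 0.5, 1, 2]
        scores = pos + neg
        labels = [1] * 3 + [0] * 4
        _, auc = fi.roc_auc(scores, labels)
        assert auc == pytest.approx(auc_pairwise(pos, neg), abs=1e-12)

    @settings(max_examples=120, derandomize=True, deadline=None)
    @given(pos=scores_strategy, neg=scores_strategy)
    def test_trapezoid_equals_pairwise_oracle(self, pos, neg):
        _, auc = fi.roc_auc(pos + neg, [1] * len(pos) + [0] * len(neg))
        assert auc == pytest.approx(auc_pairwise(pos, neg), abs=1e-12)

    # grid-valued scores: ties survive the transform at float precision
    grid_scores = st.lists(st.integers(-500, 500).map(lambda i: i / 100.0),
                           min_size=1, max_size=25)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(pos=grid_scores, neg=grid_scores)
    def test_invariant_under_monotone_transform(self, pos, neg):
        scores = np.array(pos + neg)
        labels = [1] * len(pos) + [0] * len(neg)
        _, auc = fi.roc_auc(scores, labels)
        _, auc_t = fi.roc_auc(np.arctan(scores / 3.0) * 7 - 2, labels)
        assert auc_t == pytest.approx(auc, abs=1e-12)

    def test_curve_shape_invariants(self):
        rng = np.random.default_rng(4)
        curve, _ = fi.roc_auc(rng.normal(size=40), rng.integers(0, 2, 40))
        assert curve.iloc[0]["fpr"] == 0 and curve.iloc[0]["tpr"] == 0
        assert curve.iloc[-1]["fpr"] == 1 and curve.iloc[-1]["tpr"] == 1
        assert (curve["fpr"].diff().dropna() >= 0).all()
        assert (curve["tpr"].diff().dropna() >= 0).all()

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            fi.roc_auc([1, 2, 3], [1, 1, 1])


class TestCutoffForSpecificity:
    def test_parametric_standard_normal_gives_minus_165(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal(50_000)
        cutoff = fi.cutoff_for_specificity(z, 0.95, method="parametric")
        assert cutoff == pytest.approx(-1.6449, abs=0.03)

    def test_parametric_is_normal_quantile_of_reference(self):
        # exact mean/sd recovery: cutoff = mean + sd * Phi^-1(0.05)
        ref = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        cutoff = fi.cutoff_for_specificity(ref, 0.95)
        from scipy.stats import norm
        assert cutoff == pytest.approx(ref.std(ddof=1) * norm.ppf(0.05))

    def test_empirical_counting_example(self):
        ref = np.arange(-3.0, 17.0)  # 20 values -3..16
        cutoff = fi.cutoff_for_specificity(ref, 0.95, method="empirical")
        assert -3 < cutoff <= -2
        assert (ref < cutoff).sum() == 1
        _, spec = sens_spec_at_cutoff(np.concatenate([ref, [-10.0]]),
                                      [0] * 20 + [1], cutoff)
        assert spec >= 0.95

    def test_empirical_median_case(self):
        ref = np.linspace(-2, 2, 41)
        cutoff = fi.cutoff_for_specificity(ref, 0.5, method="empirical")
        assert cutoff == pytest.approx(np.median(ref), abs=0.11)

    def test_invalid_target_raises(self):
        with pytest.raises(ValueError):
            fi.cutoff_for_specificity([0.0] * 30, 1.0)


class TestOptimalCutoff:
    def test_perfect_separation_in_gap(self):
        scores = [-3, -2, 1, 2, 3]
        labels = [1, 1, 0, 0, 0]
        c = fi.optimal_cutoff(scores, labels)
        assert -2 < c < 1
        sens, spec = sens_spec_at_cutoff(scores, labels, c)
        assert sens == spec == 1.0

    def test_exhaustive_scan_example(self):
        scores = [-3, -2, -1, 0, 1]
        labels = [1, 1, 0, 0, 0]
        c = fi.optimal_cutoff(scores, labels)
        assert -2 < c < -1

    def test_overlapping_distributions_match_scan_oracle(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        c = fi.optimal_cutoff(scores, labels)
        best = max((sum(sens_spec_at_cutoff(scores, labels, x)) / 2)
                   for x in np.linspace(-4, 4, 4001))
        achieved = sum(sens_spec_at_cutoff(scores, labels, c)) / 2
        assert achieved >= best - 1e-9
        assert achieved >= 0.5


class TestLikelihoodRatios:
    @pytest.mark.parametrize("sens,spec,lr_pos,lr_neg", [
        (0.59, 0.95, 11.8, 0.43),
        (0.79, 0.92, 9.875, 0.23),
        (0.82, 0.80, 4.1, 0.225),
    ])
    def test_printed_operating_points(self, sens, spec, lr_pos, lr_neg):
        lp, ln = fi.likelihood_ratios(sens, spec)
        assert lp == pytest.approx(lr_pos, abs=0.05)
        assert ln == pytest.approx(lr_neg, abs=0.01)

    def test_perfect_sensitivity_zero_lr_neg(self):
        _, ln = fi.likelihood_ratios(1.0, 0.5)
        assert ln == 0.0

    def test_undefined_cases_are_none(self):
        lp, ln = fi.likelihood_ratios(0.8, 1.0)
        assert lp is None and ln == pytest.approx(0.2)
        lp, ln = fi.likelihood_ratios(0.8, 0.0)
        assert ln is None and lp == pytest.approx(0.8)

    def test_identities_hold_along_a_roc(self):
        rng = np.random.default_rng(3)
        scores = np.concatenate([rng.normal(-1, 1, 30), rng.normal(0, 1, 50)])
        labels = np.array([1] * 30 + [0] * 50)
        curve, _ = fi.roc_auc(scores, labels)
        for _, row in curve.iloc[1:-1].iterrows():
            sens, spec = row["tpr"], 1 - row["fpr"]
            lp, ln = fi.likelihood_ratios(sens, spec)
            if spec < 1:
                assert lp == pytest.approx(sens / (1 - spec))
            if spec > 0:
                assert ln == pytest.approx((1 - sens) / spec)


class TestStratifyAge:
    def test_boundary_is_strictly_below(self, tiny_atlas):
        from conftest import make_cohort
        cohort = make_cohort(tiny_atlas, n=3, diagnoses=["SCD"] * 3)
        cohort.data["age"] = [60.0, 70.0, 80.0]
        below, above = fi.stratify_age(cohort, 70)
        assert below.data["age"].tolist() == [60.0]
        assert above.data["age"].tolist() == [70.0, 80.0]
        assert len(below) + len(above) == len(cohort)

    def test_threshold_zero_empties_below(self, tiny_atlas):
        from conftest import make_cohort
        cohort = make_cohort(tiny_atlas, n=3, diagnoses=["SCD"] * 3)
        below, above = fi.stratify_age(cohort, 0)
        assert len(below) == 0 and len(above) == 3


@pytest.fixture(scope="module")
def cv_cohort(atlas):
    cfg = fi.SimulationConfig(
        group_sizes={"SCD": 150, "AD": 120, "MCI": 60, "bvFTD": 50,
                     "svPPA": 20}, seed=31)
    return fi.generate_cohort(cfg, atlas)


class TestCrossValidation:
    def test_folds_partition_cohort(self, cv_cohort):
        report = fi.crossvalidate(cv_cohort, "API", k=5, seed=17)
        test_ids = [sid for f in report.folds for sid in f["test_ids"]]
        assert sorted(test_ids) == sorted(cv_cohort.data["subject_id"])
        assert len(report.folds) == 5

    def test_same_seed_reproduces_metrics(self, cv_cohort):
        r1 = fi.crossvalidate(cv_cohort, "API", k=5, seed=17)
        r2 = fi.crossvalidate(cv_cohort, "API", k=5, seed=17)
        assert r1.auc == r2.auc
        assert [f["test_ids"] for f in r1.folds] == [f["test_ids"] for f in r2.folds]
        assert [f["mu"] for f in r1.folds] == [f["mu"] for f in r2.folds]

    def test_training_parameters_blind_to_test_fold(self, cv_cohort):
        """Poisoning a held-out fold must not move that fold's training fit."""
        r1 = fi.crossvalidate(cv_cohort, "API", k=5, seed=17)
        poisoned_ids = set(r1.folds[0]["test_ids"])
        df = cv_cohort.data.copy()
        rows = df["subject_id"].isin(poisoned_ids)
        df.loc[rows, cv_cohort.atlas.names] *= 50.0
        r2 = fi.crossvalidate(fi.Cohort(cv_cohort.atlas, df), "API", k=5, seed=17)
        assert r2.folds[0]["test_ids"] == r1.folds[0]["test_ids"]
        assert r2.folds[0]["mu"] == r1.folds[0]["mu"]
        assert r2.folds[0]["sigma"] == r1.folds[0]["sigma"]
        assert r2.folds[0]["weights"] == r1.folds[0]["weights"]
        assert r2.folds[0]["reference_tiv"] == r1.folds[0]["reference_tiv"]

    def test_pooled_cv_auc_close_to_train_on_all(self, atlas):
        deltas = []
        for rep in range(10):
            cfg = fi.SimulationConfig(
                group_sizes={"SCD": 120, "AD": 100, "bvFTD": 40}, seed=100 + rep)
            cohort = fi.generate_cohort(cfg, atlas)
            cv = fi.crossvalidate(cohort, "API", k=10, seed=rep)
            nm = fi.fit_normalization(cohort)
            full = fi.apply_normalization(nm, cohort)
            model = fi.fit_index(full, "API")
            z = fi.score_cohort(model, full)["z"]
            _, auc_full = fi.roc_auc(z, cohort.mask(("FTD",)))
            deltas.append(abs(cv.auc - auc_full))
        assert max(deltas) < 0.05

    def test_too_few_folds_rejected(self, cv_cohort):
        with pytest.raises(ValueError, match="k must be >= 2"):
            fi.crossvalidate(cv_cohort, "API", k=1, seed=0)
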