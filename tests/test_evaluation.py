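import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nqi.evaluation import (
    adjusted_logistic,
    confusion_stats,
    cross_dataset_validate,
    delong_test,
    per_window_auc,
    roc_auc,
    youden_cutoff,
)
from oracles import brute_auc


def _labels(n_pos, n_neg):
    return np.array(["PD"] * n_pos + ["control"] * n_neg)


def _random_instance(rng, max_n=50):
    n_pos = int(rng.integers(2, max_n // 2 + 1))
    n_neg = int(rng.integers(2, max_n // 2 + 1))
    # discretized scores produce plenty of ties
    scores = rng.integers(0, 10, n_pos + n_neg) / 10.0
    return scores, _labels(n_pos, n_neg)


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([0.9, 0.8, 0.2, 0.1], _labels(2, 2))
        assert res.auc == 1.0

    def test_all_ties_give_half(self):
        res = roc_auc(np.full(10, 0.3), _labels(5, 5))
        assert res.auc == 0.5

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(100)
        for _ in range(50):
            scores, labels = _random_instance(rng)
            assert roc_auc(scores, labels).auc == pytest.approx(
                brute_auc(scores, labels), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], np.array(["PD", "PD"]))

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(2)
        scores, labels = _random_instance(rng)
        curve = roc_auc(scores, labels).curve
        assert (curve.iloc[0][["fpr", "tpr"]] == 0).all()
        assert (curve.iloc[-1][["fpr", "tpr"]] == 1).all()
        assert (curve["fpr"].diff().dropna() >= 0).all()
        assert (curve["tpr"].diff().dropna() >= 0).all()

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_invariant_under_strictly_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores, labels = _random_instance(rng, max_n=30)
        transformed = np.exp(3 * scores) - 1  # strictly increasing
        assert roc_auc(scores, labels).auc == pytest.approx(
            roc_auc(transformed, labels).auc, abs=1e-12
        )

    def test_ci_contains_auc_and_stays_in_unit_interval(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            scores, labels = _random_instance(rng)
            res = roc_auc(scores, labels)
            lo, hi = res.ci95
            assert 0 <= lo <= res.auc <= hi <= 1


class TestDeLong:
    def test_identical_scores_give_p_one(self):
        rng = np.random.default_rng(3)
        scores, labels = _random_instance(rng)
        z, p = delong_test(scores, scores, labels)
        assert z == 0.0 and p == 1.0

    def test_antisymmetric_separable_scores_give_extreme_z(self):
        scores = np.array([0.9, 0.8, 0.7, 0.2, 0.15, 0.1])
        labels = _labels(3, 3)
        z, p = delong_test(scores, -scores, labels)
        assert np.isinf(z) and z > 0
        assert p == 0.0

    def test_detects_a_real_auc_difference(self):
        rng = np.random.default_rng(5)
        n = 60
        labels = _labels(n, n)
        signal = np.concatenate([rng.normal(1.5, 1, n), rng.normal(0, 1, n)])
        noise = rng.normal(0, 1, 2 * n)
        z, p = delong_test(signal, noise, labels)
        assert p < 0.01


class TestYouden:
    def test_separable_scores_reach_perfect_operating_point(self):
        scores = np.array([0.2, 0.3, 0.0, 0.1])
        cut = youden_cutoff(scores, _labels(2, 2))
        assert cut.sensitivity == 1.0 and cut.specificity == 1.0
        assert 0.1 < cut.threshold < 0.2

    def test_equal_costs_balanced_prevalence_is_classical_youden(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(5, 25))
            scores = rng.normal(size=2 * n)
            scores[:n] += rng.uniform(0, 2)
            labels = _labels(n, n)
            cut = youden_cutoff(scores, labels, (1.0, 1.0))
            # exhaustive scan of classical J = se + sp − 1
            best_j = max(
                (np.mean(scores[:n] >= t) + np.mean(scores[n:] < t) - 1)
                for t in np.concatenate([[-np.inf], np.sort(scores) + 1e-9, [np.inf]])
            )
            assert cut.sensitivity + cut.specificity - 1 == pytest.approx(best_j, abs=1e-9)

    def test_higher_fn_cost_never_lowers_sensitivity(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            scores, labels = _random_instance(rng)
            fn_heavy = youden_cutoff(scores, labels, (2.0, 1.0))
            fp_heavy = youden_cutoff(scores, labels, (1.0, 2.0))
            assert fn_heavy.sensitivity >= fp_heavy.sensitivity
            assert fn_heavy.threshold <= fp_heavy.threshold

    def test_confusion_identities_hold(self):
        rng = np.random.default_rng(17)
        scores, labels = _random_instance(rng)
        cut = youden_cutoff(scores, labels, (2.0, 1.0))
        assert cut.sensitivity == cut.tp / (cut.tp + cut.fn)
        assert cut.specificity == cut.tn / (cut.tn + cut.fp)
        assert cut.accuracy == (cut.tp + cut.tn) / (cut.tp + cut.fn + cut.tn + cut.fp)


class TestConfusionStats:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((30, 12, 36, 7), (0.71, 0.84, 0.78)),
            ((31, 11, 34, 9), (0.74, 0.79, 0.76)),
            ((23, 19, 41, 2), (0.55, 0.95, 0.75)),
            ((10, 0, 10, 0), (1.0, 1.0, 1.0)),
        ],
    )
    def test_rounded_ratios(self, counts, expected):
        _, rounded = confusion_stats(*counts)
        assert rounded == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            confusion_stats(0, 0, 5, 5)


class TestCrossDataset:
    def test_overlapping_subjects_rejected(self, small_cohort):
        _, metadata, features = small_cohort
        with pytest.raises(ValueError, match="share subjects"):
            cross_dataset_validate(features, metadata, features, metadata, n_models=2)

    @staticmethod
    def _split(metadata):
        # alternate subjects within each group so both halves keep both classes
        half = metadata.groupby("group")["subject_id"].apply(lambda s: s.iloc[::2])
        return set(half)

    def test_swapping_cohorts_preserves_combined_scores(self, small_cohort):
        _, metadata, features = small_cohort
        half = self._split(metadata)
        ma = metadata[metadata["subject_id"].isin(half)]
        mb = metadata[~metadata["subject_id"].isin(half)]
        fa = features[features["subject_id"].isin(half)]
        fb = features[~features["subject_id"].isin(half)]
        cv1 = cross_dataset_validate(fa, ma, fb, mb, n_models=4, seed=3)
        cv2 = cross_dataset_validate(fb, mb, fa, ma, n_models=4, seed=3)
        s1 = cv1["subject_scores"].sort_values("subject_id").reset_index(drop=True)
        s2 = cv2["subject_scores"].sort_values("subject_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(s1, s2)
        assert cv1["roc_combined"].auc == cv2["roc_combined"].auc

    def test_zero_variance_fold_flagged_and_auc_half(self, small_cohort):
        _, metadata, features = small_cohort
        half = self._split(metadata)
        ma = metadata[metadata["subject_id"].isin(half)].copy()
        mb = metadata[~metadata["subject_id"].isin(half)].copy()
        # collapse training targets inside the tube: flat fits, constant scores
        ma["updrs3"] = 5
        mb["updrs3"] = 5
        fa = features[features["subject_id"].isin(half)]
        fb = features[~features["subject_id"].isin(half)]
        with pytest.warns(UserWarning, match="zero-variance"):
            cv = cross_dataset_validate(fa, ma, fb, mb, n_models=4, seed=3, epsilon=5.0)
        assert cv["roc_combined"].auc == 0.5


class TestPerWindow:
    def test_single_window_subjects_equal_subject_level(self):
        df = pd.DataFrame(
            {
                "subject_id": list("abcdef"),
                "window_index": 0,
                "score": [0.9, 0.8, 0.7, 0.3, 0.2, 0.1],
                "group": _labels(3, 3),
            }
        )
        assert per_window_auc(df).auc == roc_auc(df["score"], df["group"]).auc

    def test_duplicating_windows_leaves_auc_unchanged(self):
        rng = np.random.default_rng(23)
        df = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(20)],
                "window_index": 0,
                "score": rng.normal(size=20),
                "group": _labels(10, 10),
            }
        )
        doubled = pd.concat([df, df], ignore_index=True)
        assert per_window_auc(doubled).auc == pytest.approx(per_window_auc(df).auc)


class TestAdjustedLogistic:
    def _covariates(self, rng, n):
        return pd.DataFrame(
            {
                "age": rng.normal(60, 10, n),
                "sex": rng.choice(["F", "M"], n),
                "education_years": rng.normal(15, 4, n),
                "typing_speed": rng.normal(100, 40, n),
            }
        )

    def test_score_equal_to_label_flags_separation(self):
        rng = np.random.default_rng(29)
        n = 40
        labels = _labels(n // 2, n // 2)
        scores = (labels == "PD").astype(float)
        table = adjusted_logistic(scores, labels, self._covariates(rng, n))
        assert table.attrs["separation"]
        assert np.isnan(table.loc["nqi", "p"]) or not np.isfinite(table.loc["nqi", "p"])

    def test_zeroed_covariates_match_univariate_fit(self):
        rng = np.random.default_rng(31)
        n = 60
        labels = _labels(n // 2, n // 2)
        scores = rng.normal((labels == "PD") * 1.0, 1.0)
        cov = pd.DataFrame(
            {"age": 0.0, "sex": "F", "education_years": 0.0, "typing_speed": 0.0},
            index=range(n),
        )
        adjusted = adjusted_logistic(scores, labels, cov)
        univariate = adjusted_logistic(scores, labels, None)
        assert adjusted.loc["nqi", "estimate"] == pytest.approx(
            univariate.loc["nqi", "estimate"], rel=1e-6
        )
        assert adjusted.loc["nqi", "p"] == pytest.approx(univariate.loc["nqi", "p"], rel=1e-6)

    def test_reports_wald_terms_for_all_covariates(self):
        rng = np.random.default_rng(37)
        n = 80
        labels = _labels(n // 2, n // 2)
        scores = rng.normal((labels == "PD") * 1.0, 1.0)
        table = adjusted_logistic(scores, labels, self._covariates(rng, n))
        assert {"const", "nqi", "age", "sex", "education_years", "typing_speed"} <= set(
            table.index
        )
        assert not table.attrs["separation"]
        assert table.loc["nqi", "p"] < 0.05  # planted effect is detected
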