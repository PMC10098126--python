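"""Agreement and performance statistics against hand and simulation oracles."""

import numpy as np
import pytest

import ddhkit as dk
from ddhkit.metrics import delong_paired


class TestBinaryMetrics:
    def test_junior_rater_counts(self):
        m = dk.binary_metrics(dk.BinaryConfusion(tp=309, fn=54, tn=677, fp=46))
        assert m["sensitivity_pct"] == pytest.approx(85.12, abs=0.005)
        assert m["specificity_pct"] == pytest.approx(93.64, abs=0.005)
        assert m["accuracy_pct"] == pytest.approx(90.79, abs=0.005)
        assert m["auc"] == pytest.approx(0.894, abs=0.0005)

    def test_intermediate_rater_counts(self):
        m = dk.binary_metrics(dk.BinaryConfusion(tp=348, fn=15, tn=691, fp=32))
        assert m["sensitivity_pct"] == pytest.approx(95.87, abs=0.005)
        assert m["auc"] == pytest.approx(0.957, abs=0.0005)

    def test_perfect_classifier(self):
        m = dk.binary_metrics(dk.BinaryConfusion(tp=10, fn=0, tn=20, fp=0))
        assert m["sensitivity_pct"] == 100.0
        assert m["specificity_pct"] == 100.0
        assert m["accuracy_pct"] == 100.0
        assert m["auc"] == 1.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(dk.UndefinedStatisticError, match="sensitivity"):
            dk.binary_metrics(dk.BinaryConfusion(tp=0, fn=0, tn=5, fp=5))

    def test_auc_matches_delong_on_binary_predictions(self):
        """Two-point trapezoid AUC equals the Mann-Whitney AUC when the
        scores are the 0/1 predictions themselves."""
        rng = np.random.default_rng(5)
        truth = rng.integers(0, 2, 200)
        pred = np.where(rng.random(200) < 0.8, truth, 1 - truth)
        c = dk.BinaryConfusion(
            tp=int(((truth == 1) & (pred == 1)).sum()),
            fn=int(((truth == 1) & (pred == 0)).sum()),
            tn=int(((truth == 0) & (pred == 0)).sum()),
            fp=int(((truth == 0) & (pred == 1)).sum()),
        )
        res = delong_paired(truth, pred, pred)
        assert dk.binary_metrics(c)["auc"] == pytest.approx(res["auc_a"])


class TestDelongPaired:
    TRUTH = [1] * 8 + [0] * 12
    A = [1.2, 1.5, 0.93, 0.31, 0.75, 0.21, 1.26, 2.54,
         -0.49, -0.62, 0.49, 0.36, 0.11, -0.93, -0.03, 0.7,
         -1.34, -0.46, -1.9, -1.29]
    B = [-1.14, 0.46, -0.57, 0.97, 0.86, 0.51, -1.82, 0.16,
         -0.05, 0.11, -1.53, -0.48, -0.98, -0.81, 1.06, -0.81,
         -0.03, 0.88, -0.58, -0.11]

    def test_identical_scores_give_p_one(self):
        res = delong_paired(self.TRUTH, self.A, self.A)
        assert res["z"] == 0.0 and res["p"] == 1.0

    def test_endpoint_aucs(self):
        res = delong_paired(self.TRUTH, self.TRUTH, [0.5] * 20)
        assert res["auc_a"] == 1.0
        assert res["auc_b"] == 0.5

    def test_p_close_to_bootstrap_oracle(self):
        """The normal-approximation p agrees with a 20,000-resample case
        bootstrap of the AUC difference."""
        truth = np.asarray(self.TRUTH)
        a, b = np.asarray(self.A), np.asarray(self.B)
        res = delong_paired(truth, a, b)
        assert res["auc_a"] == pytest.approx(0.9375)
        assert res["auc_b"] == pytest.approx(0.59375)

        def auc(t, s):
            pos, neg = s[t == 1][:, None], s[t == 0][None, :]
            return float(((pos > neg) + 0.5 * (pos == neg)).mean())

        rng = np.random.default_rng(12345)
        diffs = []
        n = truth.size
        while len(diffs) < 20_000:
            idx = rng.integers(0, n, n)
            t = truth[idx]
            if 0 < t.sum() < n:
                diffs.append(auc(t, a[idx]) - auc(t, b[idx]))
        diffs = np.asarray(diffs)
        p_boot = min(
            1.0, 2 * min((diffs <= 0).mean(), (diffs >= 0).mean())
        )
        assert abs(res["p"] - p_boot) < 0.02

    def test_single_class_truth_rejected(self):
        with pytest.raises(dk.UndefinedStatisticError):
            delong_paired([1, 1, 1], [0.1, 0.2, 0.3], [0.3, 0.2, 0.1])


class TestBlandAltman:
    def test_hand_computation(self):
        # differences (0, 2, 4): bias 2, sd 2, limits 2 -/+ 1.96*2
        res = dk.bland_altman([10.0, 13.0, 16.0], [10.0, 11.0, 12.0])
        assert res["bias"] == pytest.approx(2.0)
        assert res["loa_low"] == pytest.approx(-1.92)
        assert res["loa_high"] == pytest.approx(5.92)
        assert 0 < res["bias_p"] < 1

    def test_identical_sequences(self):
        res = dk.bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["bias"] == 0.0
        assert res["loa_low"] == res["loa_high"] == 0.0
        assert res["bias_p"] == 1.0

    def test_constant_offset(self):
        res = dk.bland_altman([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert res["bias"] == pytest.approx(1.0)
        assert res["loa_high"] - res["loa_low"] == pytest.approx(0.0)

    def test_limits_symmetric_about_bias(self):
        rng = np.random.default_rng(3)
        res = dk.bland_altman(rng.normal(25, 4, 50), rng.normal(25, 4, 50))
        assert res["loa_high"] - res["bias"] == pytest.approx(
            res["bias"] - res["loa_low"]
        )

    def test_insufficient_data(self):
        with pytest.raises(dk.UndefinedStatisticError):
            dk.bland_altman([1.0], [2.0])


class TestIcc:
    # 6 subjects x 2 raters
    R1 = [20.0, 24.0, 19.0, 30.0, 27.0, 22.0]
    R2 = [21.0, 25.0, 17.0, 31.0, 26.0, 24.0]

    @staticmethod
    def _icc2_ms_oracle(r1, r2):
        """Direct two-way ANOVA mean-square formula for ICC(2,1)."""
        x = np.column_stack([r1, r2]).astype(float)
        n, k = x.shape
        grand = x.mean()
        ms_rows = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        ms_cols = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        resid = x - x.mean(axis=1)[:, None] - x.mean(axis=0)[None, :] + grand
        ms_err = (resid ** 2).sum() / ((n - 1) * (k - 1))
        return (ms_rows - ms_err) / (
            ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
        )

    def test_matches_ms_formula(self):
        icc = dk.icc_agreement(self.R1, self.R2)
        assert icc == pytest.approx(self._icc2_ms_oracle(self.R1, self.R2),
                                    abs=1e-9)

    def test_perfect_agreement(self):
        assert dk.icc_agreement(self.R1, self.R1) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(17)
        a, b = rng.normal(0, 1, 500), rng.normal(0, 1, 500)
        assert abs(dk.icc_agreement(a, b)) < 0.1

    def test_zero_between_subject_variance_rejected(self):
        with pytest.raises(dk.UndefinedStatisticError):
            dk.icc_agreement([5.0, 4.0, 5.0], [5.0, 6.0, 5.0])


class TestWeightedKappa:
    CATS = ["mild", "moderate", "severe"]

    @staticmethod
    def _linear_kappa_oracle(r1, r2, cats):
        """Direct evaluation of 1 - sum(wO)/sum(wE) with linear weights."""
        k = len(cats)
        idx = {c: i for i, c in enumerate(cats)}
        O = np.zeros((k, k))
        for x, y in zip(r1, r2):
            O[idx[x], idx[y]] += 1
        O /= O.sum()
        E = np.outer(O.sum(axis=1), O.sum(axis=0))
        W = np.abs(np.subtract.outer(np.arange(k), np.arange(k))) / (k - 1)
        return 1 - (W * O).sum() / (W * E).sum()

    def test_identical_ratings(self):
        r = ["mild", "severe", "moderate", "mild", "severe"]
        assert dk.weighted_kappa(r, r, self.CATS) == pytest.approx(1.0)

    def test_matches_direct_formula_on_fixture(self):
        r1 = ["mild"] * 20 + ["moderate"] * 15 + ["severe"] * 10 + ["mild"] * 5
        r2 = (["mild"] * 16 + ["moderate"] * 4 + ["moderate"] * 11
              + ["severe"] * 4 + ["severe"] * 9 + ["mild"] * 1
              + ["moderate"] * 5)
        assert dk.weighted_kappa(r1, r2, self.CATS) == pytest.approx(
            self._linear_kappa_oracle(r1, r2, self.CATS), abs=1e-12
        )

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(29)
        r1 = rng.choice(self.CATS, 2000).tolist()
        r2 = rng.choice(self.CATS, 2000).tolist()
        assert abs(dk.weighted_kappa(r1, r2, self.CATS)) < 0.1

    def test_constant_rater_rejected(self):
        with pytest.raises(dk.UndefinedStatisticError):
            dk.weighted_kappa(["mild"] * 5,
                              ["mild", "severe"] * 2 + ["mild"], self.CATS)

    def test_invalid_rating_rejected(self):
        with pytest.raises(dk.ValidationError):
            dk.weighted_kappa(["mild", "huge"], ["mild", "mild"], self.CATS)


class TestMulticlassConfusion:
    LABELS = ["normal", "other", "ddh1", "ddh2", "ddh3", "ddh4"]

    def test_diagonal_for_perfect_prediction(self):
        truth = ["normal", "ddh1", "ddh1", "ddh4", "other"]
        cm = dk.multiclass_confusion(truth, truth, self.LABELS)
        assert int(np.trace(cm.values)) == 5
        assert cm.loc["ddh1", "ddh1"] == 2

    def test_empty_input_gives_zero_matrix(self):
        cm = dk.multiclass_confusion([], [], self.LABELS)
        assert cm.values.sum() == 0 and cm.shape == (6, 6)

    def test_counts_match_tally_oracle(self):
        rng = np.random.default_rng(11)
        truth = rng.choice(self.LABELS, 300).tolist()
        pred = rng.choice(self.LABELS, 300).tolist()
        cm = dk.multiclass_confusion(truth, pred, self.LABELS)
        assert cm.values.sum() == 300
        for i, t in enumerate(self.LABELS):
            for j, p in enumerate(self.LABELS):
                tally = sum(1 for x, y in zip(truth, pred) if x == t and y == p)
                assert cm.iloc[i, j] == tally

    def test_unknown_label_rejected(self):
        with pytest.raises(dk.ValidationError):
            dk.multiclass_confusion(["normal"], ["weird"], self.LABELS)
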