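"""Feature extraction and cross-validated benign/malignant discrimination."""

import numpy as np
import pandas as pd
import pytest

from mexpt2 import (
    METRIC_NAMES,
    FeatureRow,
    extract_features,
    run_classification,
)
from test_summary import synthetic_maps


def make_rows(benign_vals, malignant_vals, metric="pct_mono"):
    rows = []
    for i, v in enumerate(benign_vals):
        kw = {m: 50.0 for m in METRIC_NAMES}
        kw[metric] = v
        rows.append(FeatureRow(roi_id=f"b{i}", class_label="benign", **kw))
    for i, v in enumerate(malignant_vals):
        kw = {m: 50.0 for m in METRIC_NAMES}
        kw[metric] = v
        rows.append(FeatureRow(roi_id=f"m{i}", class_label="malignant", **kw))
    return rows


class TestExtractFeatures:
    def test_prevalence_counting(self):
        maps = synthetic_maps(n_mono=4, n_bi=6)
        row = extract_features(maps, np.ones(maps.shape, bool), "benign")
        assert row.pct_mono == 40.0

    def test_constant_population_stats(self):
        maps = synthetic_maps(n_mono=0, n_bi=5, bi=(300.0, 40.0, 700.0, 200.0))
        row = extract_features(maps, np.ones(maps.shape, bool), "benign")
        assert (row.mean_T2_1, row.sd_T2_1, row.p90_T2_1) == (40.0, 0.0, 40.0)
        assert row.mean_T2_2 == 200.0

    def test_short_population_pools_mono_and_bi_short(self):
        maps = synthetic_maps(n_mono=2, n_bi=2, mono_t2=80.0,
                              bi=(300.0, 40.0, 700.0, 200.0))
        row = extract_features(maps, np.ones(maps.shape, bool), "x")
        assert row.mean_T2_1 == pytest.approx((80 + 80 + 40 + 40) / 4)

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(8)
        maps = synthetic_maps(n_mono=3, n_bi=7)
        sel = maps.model_map == 2
        maps.bi_t2_short[sel] += rng.normal(0, 5, sel.sum())
        maps.bi_t2_long[sel] += rng.normal(0, 20, sel.sum())
        df = maps.to_dataframe(np.ones(maps.shape, bool))
        row = extract_features(maps, np.ones(maps.shape, bool), "x")
        t2_1 = df["T2_1"].to_numpy()
        assert row.mean_T2_1 == pytest.approx(t2_1.mean())
        assert row.p90_T2_1 == pytest.approx(np.percentile(t2_1, 90))
        t2_2 = df.loc[df.model == 2, "T2_2"].to_numpy()
        assert row.sd_T2_2 == pytest.approx(t2_2.std(ddof=1))

    def test_all_mono_roi_flags_missing_long_t2(self):
        maps = synthetic_maps(n_mono=3, n_bi=0)
        with pytest.warns(UserWarning, match="no biexponential"):
            row = extract_features(maps, np.ones(maps.shape, bool), "x")
        assert np.isnan(row.mean_T2_2)


class TestRunClassification:
    def test_separable_feature_perfect_metrics(self):
        rows = make_rows([0.0] * 10, [100.0] * 10)
        rep = run_classification(rows, "pct_mono", n_folds=5, seed=0)
        assert rep.sensitivity == 1.0
        assert rep.specificity == 1.0
        assert rep.n_folds == 5

    def test_seed_deterministic_and_stratified(self):
        rng = np.random.default_rng(0)
        rows = make_rows(rng.normal(30, 20, 20), rng.normal(60, 20, 20))
        a = run_classification(rows, "pct_mono", seed=3)
        b = run_classification(rows, "pct_mono", seed=3)
        pd.testing.assert_frame_equal(a.fold_assignments, b.fold_assignments)
        counts = a.fold_assignments.groupby(["fold", "class_label"]).size()
        per_fold = counts.unstack().to_numpy()
        assert np.all(np.abs(per_fold - per_fold.mean(axis=0)) <= 1)

    def test_metrics_recomputable_from_prediction_table(self):
        rng = np.random.default_rng(1)
        rows = make_rows(rng.normal(30, 25, 15), rng.normal(60, 25, 15))
        rep = run_classification(rows, "pct_mono", seed=0)
        t = rep.fold_assignments
        sens = ((t.prediction == 1) & (t.truth == 1)).sum() / (t.truth == 1).sum()
        spec = ((t.prediction == 0) & (t.truth == 0)).sum() / (t.truth == 0).sum()
        assert rep.sensitivity == pytest.approx(sens)
        assert rep.specificity == pytest.approx(spec)

    def test_permuted_labels_perform_at_chance(self):
        # sensitivity + specificity averages to ~1 under the permutation null
        rng = np.random.default_rng(7)
        vals = rng.normal(50, 10, 200)
        totals = []
        for seed in range(20):
            perm = rng.permutation(200)
            labels = np.array(["benign"] * 100 + ["malignant"] * 100)[perm]
            rows = []
            for i, (v, lab) in enumerate(zip(vals, labels)):
                kw = {m: 50.0 for m in METRIC_NAMES}
                kw["pct_mono"] = v
                rows.append(FeatureRow(roi_id=str(i), class_label=lab, **kw))
            rep = run_classification(rows, "pct_mono", seed=seed)
            totals.append(rep.sensitivity + rep.specificity)
        assert np.mean(totals) == pytest.approx(1.0, abs=0.1)

    def test_single_class_raises(self):
        rows = make_rows([1.0] * 8, [])
        with pytest.raises(ValueError, match="both classes"):
            run_classification(rows, "pct_mono")

    def test_small_class_reduces_folds_with_warning(self):
        rows = make_rows([0.0, 1.0, 2.0], [90.0, 91.0, 92.0, 93.0])
        with pytest.warns(UserWarning, match="reducing folds"):
            rep = run_classification(rows, "pct_mono", n_folds=5)
        assert rep.n_folds == 3

    def test_nan_metric_rows_excluded_with_warning(self):
        rows = make_rows([0.0] * 6, [100.0] * 6, metric="mean_T2_2")
        rows[0].mean_T2_2 = np.nan
        with pytest.warns(UserWarning, match="excluded"):
            rep = run_classification(rows, "mean_T2_2", n_folds=3)
        assert len(rep.fold_assignments) == 11

    def test_unknown_metric_rejected(self):
        rows = make_rows([0.0] * 6, [1.0] * 6)
        with pytest.raises(ValueError, match="unknown metric"):
            run_classification(rows, "kurtosis_T2_1")

    def test_seven_standard_metrics(self):
        assert len(METRIC_NAMES) == 7
        assert set(METRIC_NAMES) == {
            "pct_mono", "mean_T2_1", "sd_T2_1", "p90_T2_1",
            "mean_T2_2", "sd_T2_2", "p90_T2_2",
        }
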