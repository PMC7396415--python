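"""Benign-vs-malignant discrimination from per-ROI fit statistics.

Each ROI (the unit of analysis, one row per patient region) is reduced to
seven statistical metrics: the monoexponential model prevalence and the mean,
SD and 90th percentile of the short (T2_1) and long (T2_2) relaxation-time
populations.  The short-T2 population pools the short component of
biexponential voxels with the single T2 of monoexponential voxels; the long
population is the long component of biexponential voxels only.

Each metric is evaluated in its own univariate logistic regression (plain
maximum likelihood, no regularization) under stratified k-fold cross
validation; sensitivity and specificity are computed from the pooled
out-of-fold confusion counts with malignant as the positive class at a 0.5
probability threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .fitting import ParametricMaps

__all__ = ["FeatureRow", "MetricReport", "extract_features",
           "run_classification", "METRIC_NAMES"]

METRIC_NAMES = (
    "pct_mono",
    "mean_T2_1", "sd_T2_1", "p90_T2_1",
    "mean_T2_2", "sd_T2_2", "p90_T2_2",
)


@dataclass
class FeatureRow:
    """Statistical metrics of one ROI."""

    roi_id: str
    class_label: str  # benign | malignant
    pct_mono: float
    mean_T2_1: float
    sd_T2_1: float
    p90_T2_1: float
    mean_T2_2: float  # NaN when the ROI has no biexponential voxels
    sd_T2_2: float
    p90_T2_2: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("roi_id", "class_label") + METRIC_NAMES}


@dataclass
class MetricReport:
    """Cross-validated discrimination performance of one metric."""

    metric_name: str
    sensitivity: float
    specificity: float
    n_folds: int
    seed: int
    fold_assignments: pd.DataFrame  # roi_id, class_label, fold, prediction

    def to_dict(self) -> dict:
        return {"metric_name": self.metric_name,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "n_folds": self.n_folds, "seed": self.seed}


def _percentile90(values: np.ndarray) -> float:
    # linear interpolation between order statistics
    return float(np.percentile(values, 90, method="linear"))


def extract_features(
    maps: ParametricMaps, roi_mask: np.ndarray, class_label: str,
    roi_id: str = "roi",
) -> FeatureRow:
    """Reduce one ROI's parametric maps to the seven statistical metrics."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    model = maps.model_map[roi_mask]
    n_fitted = int((model > 0).sum())
    if n_fitted == 0:
        raise ValueError("ROI has no fitted voxels")
    pct_mono = 100.0 * float((model == 1).sum()) / n_fitted

    mono_sel = roi_mask & (maps.model_map == 1)
    bi_sel = roi_mask & (maps.model_map == 2)
    t2_1 = np.concatenate([maps.mono_t2[mono_sel], maps.bi_t2_short[bi_sel]])
    t2_1 = t2_1[np.isfinite(t2_1)]
    t2_2 = maps.bi_t2_long[bi_sel]
    t2_2 = t2_2[np.isfinite(t2_2)]

    def stats(v):
        if v.size == 0:
            return np.nan, np.nan, np.nan
        sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
        return float(v.mean()), sd, _percentile90(v)

    m1, s1, p1 = stats(t2_1)
    m2, s2, p2 = stats(t2_2)
    if t2_2.size == 0:
        warnings.warn(f"ROI {roi_id!r} has no biexponential voxels; "
                      "long-T2 metrics are absent", stacklevel=2)
    return FeatureRow(
        roi_id=roi_id, class_label=class_label, pct_mono=pct_mono,
        mean_T2_1=m1, sd_T2_1=s1, p90_T2_1=p1,
        mean_T2_2=m2, sd_T2_2=s2, p90_T2_2=p2,
    )


def features_to_frame(rows: list[FeatureRow]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in rows])


def run_classification(
    rows: list[FeatureRow] | pd.DataFrame,
    metric_name: str,
    n_folds: int = 5,
    seed: int = 0,
) -> MetricReport:
    """Stratified k-fold univariate logistic regression for one metric.

    ROIs with a missing (NaN) value of the metric are dropped with a warning.
    If the smaller class has fewer members than ``n_folds`` the fold count is
    reduced (with a warning) so every fold contains both classes.
    """
    if metric_name not in METRIC_NAMES:
        raise ValueError(f"unknown metric {metric_name!r}; one of {METRIC_NAMES}")
    df = rows if isinstance(rows, pd.DataFrame) else features_to_frame(rows)
    keep = np.isfinite(df[metric_name].to_numpy(dtype=float))
    if not keep.all():
        warnings.warn(
            f"{(~keep).sum()} ROI(s) lack metric {metric_name!r} and were "
            "excluded", stacklevel=2)
        df = df.loc[keep]
    y = (df["class_label"].to_numpy() == "malignant").astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    x = df[metric_name].to_numpy(dtype=float).reshape(-1, 1)

    n_min = int(min((y == 0).sum(), (y == 1).sum()))
    folds = n_folds
    if n_min < folds:
        warnings.warn(f"smallest class has {n_min} ROIs; reducing folds "
                      f"{n_folds} -> {n_min}", stacklevel=2)
        folds = n_min
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.full(y.shape, -1)
    fold_of = np.full(y.shape, -1)
    for k, (tr, te) in enumerate(skf.split(x, y)):
        # C=inf disables regularization: plain maximum likelihood
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000)
        clf.fit(x[tr], y[tr])
        pred[te] = (clf.predict_proba(x[te])[:, 1] >= 0.5).astype(int)
        fold_of[te] = k

    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    assignments = pd.DataFrame({
        "roi_id": df["roi_id"].to_numpy(),
        "class_label": df["class_label"].to_numpy(),
        "fold": fold_of, "prediction": pred, "truth": y,
    })
    return MetricReport(
        metric_name=metric_name,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        n_folds=folds, seed=seed,
        fold_assignments=assignments,
    )
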