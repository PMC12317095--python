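"""Evaluation: AUROC, fold aggregation, stratified tables, probability
histograms, and the screening trade-off (FN% / TN% / sensitivity) analysis.

AUROC is computed as the tie-aware Mann-Whitney concordance: the
probability that a random positive outranks a random negative, ties
counting one half. The trade-off sweep targets the pre-screening use case:
for each candidate threshold (predict positive iff probability >= t) it
reports the percentage of all cases that are false negatives, the
percentage that are true negatives (the testing workload the screen could
remove), and sensitivity; an operating point is then chosen as the maximal
TN% subject to an FN% budget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def _validate(probabilities, labels):
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("probabilities and labels must be 1-D and aligned")
    if not np.isfinite(p).all() or p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must be finite in [0, 1]")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return p, y.astype(int)


def auroc(probabilities, labels) -> float:
    """Mann-Whitney AUROC: P(score_pos > score_neg) + 0.5 P(tie)."""
    p, y = _validate(probabilities, labels)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes present")
    ranks = stats.rankdata(p)  # midranks handle ties
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def mean_auroc_ci(per_fold_values, confidence: float = 0.95):
    """Mean cross-validation AUROC with a Student-t confidence interval."""
    v = np.asarray(per_fold_values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two folds for a confidence interval")
    mean = float(v.mean())
    sem = float(v.std(ddof=1) / np.sqrt(v.size))
    if sem == 0.0:
        return mean, (mean, mean)
    tcrit = float(stats.t.ppf(0.5 + confidence / 2.0, df=v.size - 1))
    return mean, (mean - tcrit * sem, mean + tcrit * sem)


def stratified_auroc(records: pd.DataFrame, key: str) -> pd.DataFrame:
    """Per-group AUROC for a metadata key (scanner, site or mode).

    Groups lacking one of the classes are reported with ``auroc = NaN`` and
    ``defined = False`` rather than silently dropped.
    """
    if key not in ("scanner", "site", "mode"):
        raise ValueError("key must be one of scanner, site, mode")
    rows = []
    for g, df in records.groupby(key, sort=True):
        y = df["label"].to_numpy()
        defined = 0 < y.sum() < len(y)
        rows.append({
            key: g, "n": len(df), "n_pos": int(y.sum()),
            "auroc": auroc(df["probability"].to_numpy(), y) if defined else np.nan,
            "defined": defined,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    fn_pct: float  # false negatives / total cases x 100
    tn_pct: float  # true negatives / total cases x 100
    sensitivity: float


def tradeoff_curve(records: pd.DataFrame) -> list[OperatingPoint]:
    """Sweep every distinct probability as a screening threshold.

    Positive prediction is ``probability >= threshold``. A final
    all-negative point just above the maximum probability is appended so the
    curve spans sensitivity 1 down to 0. FN% is non-decreasing and
    sensitivity non-increasing along the returned list.
    """
    p, y = _validate(records["probability"].to_numpy(), records["label"].to_numpy())
    if y.sum() in (0, len(y)):
        raise ValueError("trade-off analysis requires both classes present")
    total, n_pos = len(y), int(y.sum())
    thresholds = np.unique(p).tolist()
    thresholds.append(float(np.nextafter(thresholds[-1], np.inf)))
    points = []
    for t in thresholds:
        pred = p >= t
        fn = int((~pred & (y == 1)).sum())
        tn = int((~pred & (y == 0)).sum())
        points.append(OperatingPoint(
            threshold=float(t),
            fn_pct=100.0 * fn / total,
            tn_pct=100.0 * tn / total,
            sensitivity=(n_pos - fn) / n_pos,
        ))
    return points


def pick_operating_point(curve: list[OperatingPoint], target_fn_pct: float) -> OperatingPoint:
    """Best workload reduction within an FN% budget: max TN% s.t. FN% <= target."""
    if not curve:
        raise ValueError("empty trade-off curve")
    ok = [pt for pt in curve if pt.fn_pct <= target_fn_pct]
    if not ok:
        raise ValueError(f"no operating point satisfies fn_pct <= {target_fn_pct}")
    return max(ok, key=lambda pt: (pt.tn_pct, -pt.fn_pct))


def curve_frame(curve: list[OperatingPoint]) -> pd.DataFrame:
    return pd.DataFrame([pt.__dict__ for pt in curve])


def probability_histogram(records: pd.DataFrame, n_bins: int = 20) -> pd.DataFrame:
    """Per-class histogram of predicted probabilities over [0, 1].

    Bins are half-open with the last bin closed (numpy convention), so a
    probability of exactly 1.0 lands in the top bin. Counts sum to the class
    sizes.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    p, y = _validate(records["probability"].to_numpy(), records["label"].to_numpy())
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    rows = []
    for cls in (0, 1):
        counts, _ = np.histogram(p[y == cls], bins=edges)
        for i, c in enumerate(counts):
            rows.append({"label": cls, "bin_left": edges[i], "bin_right": edges[i + 1],
                         "count": int(c)})
    return pd.DataFrame(rows)


def roc_points(records: pd.DataFrame) -> np.ndarray:
    """(FPR, TPR) pairs from the shared-threshold sweep, sorted for plotting."""
    p, y = _validate(records["probability"].to_numpy(), records["label"].to_numpy())
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    thresholds = np.concatenate([np.unique(p), [np.inf]])
    pts = []
    for t in thresholds:
        pred = p >= t
        pts.append(((pred & (y == 0)).sum() / n_neg, (pred & (y == 1)).sum() / n_pos))
    pts = np.array(sorted(pts))
    return pts
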