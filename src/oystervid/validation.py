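"""Section-level comparison of video estimates with the field census.

The "probably living" and "possibly living" scoring categories are merged
into a single "living" category, per-section video means are averaged over
observer x reading replicates, and the comparison is summarised by squared
Pearson correlation, recovery rates (video total / field total, the
complement of the method's underestimation bias) and absolute/relative
error profiles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "merge_categories",
    "build_comparison",
    "correlation_r2",
    "recovery_rate",
    "error_profile",
]

_SECTION_KEY = ["site", "transect", "section"]


def merge_categories(readings: pd.DataFrame) -> pd.Series:
    """Merged living count per reading: probably + possibly living."""
    return readings["count_probably_living"] + readings["count_possibly_living"]


def build_comparison(
    readings: pd.DataFrame,
    truth: pd.DataFrame,
    observer: int | None = None,
) -> pd.DataFrame:
    """Join per-section video means to the field census.

    Video means average over all observer x reading replicates (restricted to
    one observer when ``observer`` is given). Every section present in
    ``readings`` must exist in ``truth``.

    Returns one row per section with columns ``field_living``, ``field_dead``,
    ``video_living_mean`` (merged categories), ``video_probably_mean``,
    ``video_dead_mean`` and, when available, ``vegetation_cover``.
    """
    r = readings.copy()
    if observer is not None:
        r = r[r["observer"] == observer]
        if len(r) == 0:
            raise ValueError(f"no readings for observer {observer}")
    r["merged_living"] = merge_categories(r)
    means = r.groupby(_SECTION_KEY, as_index=False).agg(
        video_living_mean=("merged_living", "mean"),
        video_probably_mean=("count_probably_living", "mean"),
        video_dead_mean=("count_dead", "mean"),
    )
    truth_cols = _SECTION_KEY + ["true_living", "true_dead"]
    if "vegetation_cover" in truth.columns:
        truth_cols.append("vegetation_cover")
    joined = means.merge(truth[truth_cols], on=_SECTION_KEY, how="left")
    missing = joined[joined["true_living"].isna()]
    if len(missing):
        keys = missing[_SECTION_KEY].itertuples(index=False, name=None)
        raise KeyError(f"sections absent from field truth: {list(keys)}")
    joined = joined.rename(
        columns={"true_living": "field_living", "true_dead": "field_dead"}
    )
    order = _SECTION_KEY + [
        "field_living",
        "field_dead",
        "video_living_mean",
        "video_probably_mean",
        "video_dead_mean",
    ]
    if "vegetation_cover" in joined.columns:
        order.append("vegetation_cover")
    return joined[order]


def correlation_r2(x, y) -> float:
    """Squared Pearson correlation between two equal-length sequences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    if len(x) < 3:
        raise ValueError("need at least 3 points for a correlation")
    if np.isclose(x.std(), 0.0) or np.isclose(y.std(), 0.0):
        raise ValueError("correlation undefined: a variable has zero variance")
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def recovery_rate(
    comparisons: pd.DataFrame, status: str = "living", category: str = "merged"
) -> float:
    """Total video mean count over total field count for one status.

    ``category`` selects the merged living category or "probably" alone
    (only meaningful for ``status="living"``).
    """
    if status not in ("living", "dead"):
        raise ValueError("status must be 'living' or 'dead'")
    if category not in ("merged", "probably"):
        raise ValueError("category must be 'merged' or 'probably'")
    if status == "living":
        video_col = "video_living_mean" if category == "merged" else "video_probably_mean"
        field_col = "field_living"
    else:
        video_col, field_col = "video_dead_mean", "field_dead"
    field_total = comparisons[field_col].sum()
    if field_total <= 0:
        raise ValueError(f"recovery rate undefined: no field {status} oysters")
    return float(comparisons[video_col].sum() / field_total)


def error_profile(comparisons: pd.DataFrame, status: str = "living") -> pd.DataFrame:
    """Per-section video-minus-field errors.

    Absolute error is ``video mean - field count``; relative error divides by
    the field count and is left NaN (flagged ``relative_defined=False``) for
    field-zero sections rather than reported as infinite.
    """
    if status == "living":
        video_col, field_col = "video_living_mean", "field_living"
    else:
        video_col, field_col = "video_dead_mean", "field_dead"
    out = comparisons[_SECTION_KEY + [field_col]].copy()
    out = out.rename(columns={field_col: "field_count"})
    out["absolute_error"] = comparisons[video_col] - comparisons[field_col]
    positive = out["field_count"] > 0
    out["relative_error"] = np.where(
        positive, out["absolute_error"] / out["field_count"].where(positive, 1), np.nan
    )
    out["relative_defined"] = positive.to_numpy()
    return out
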