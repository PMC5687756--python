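"""Live/dead classification agreement between field and video.

Individually matched oysters carry a field-determined status (the truth) and
a video-determined status. Cross-tabulating them gives a 2x2 confusion
matrix with "living" as the positive class, from which the correct
classification rate, sensitivity (living called living), specificity (dead
called dead) and Cohen's kappa (chance-corrected agreement) are computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "ClassificationMetrics",
    "build_confusion",
    "compute_metrics",
    "UndefinedMetricError",
]

_STATUSES = ("living", "dead")


class UndefinedMetricError(ValueError):
    """A statistic is undefined for this matrix (zero marginal)."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 cross-tabulation: first letter is field status, second video.

    ``n_ll``: field living, video living (true positives);
    ``n_ld``: field living, video dead (false negatives);
    ``n_dl``: field dead, video living (false positives);
    ``n_dd``: field dead, video dead (true negatives).
    """

    n_ll: int
    n_ld: int
    n_dl: int
    n_dd: int

    def __post_init__(self) -> None:
        if min(self.n_ll, self.n_ld, self.n_dl, self.n_dd) < 0:
            raise ValueError("confusion-matrix counts must be >= 0")

    @property
    def total(self) -> int:
        return self.n_ll + self.n_ld + self.n_dl + self.n_dd

    def swapped(self) -> "ConfusionMatrix":
        """Matrix with 'dead' treated as the positive class."""
        return ConfusionMatrix(self.n_dd, self.n_dl, self.n_ld, self.n_ll)

    def as_frame(self) -> pd.DataFrame:
        """Display table with field status in columns, video in rows."""
        return pd.DataFrame(
            [[self.n_ll, self.n_dl], [self.n_ld, self.n_dd]],
            index=pd.Index(_STATUSES, name="video"),
            columns=pd.Index(_STATUSES, name="field"),
        )


@dataclass(frozen=True)
class ClassificationMetrics:
    ccr: float
    sensitivity: float | None
    specificity: float | None
    kappa: float | None
    false_negative_share: float
    false_positive_share: float

    def as_dict(self) -> dict[str, float | None]:
        return {
            "ccr": self.ccr,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "kappa": self.kappa,
            "false_negative_share": self.false_negative_share,
            "false_positive_share": self.false_positive_share,
        }

    def report(self) -> str:
        """Aligned plain-text report; shares shown as whole percentages."""
        lines = ["statistic               value"]
        for name, value in self.as_dict().items():
            if value is None:
                shown = "undefined"
            elif name.endswith("_share"):
                shown = f"{100 * value:.0f}%"
            else:
                shown = f"{value:.2f}"
            lines.append(f"{name:<22}  {shown}")
        return "\n".join(lines)


def build_confusion(records: pd.DataFrame) -> ConfusionMatrix:
    """Cross-tabulate matched oyster records.

    ``records`` needs columns ``field_status`` and ``video_status`` holding
    the literal strings ``"living"`` / ``"dead"``; field status is the truth.
    """
    if len(records) == 0:
        raise ValueError("cannot build a confusion matrix from zero records")
    for col in ("field_status", "video_status"):
        if col not in records.columns:
            raise ValueError(f"missing column {col!r}")
        bad = set(records[col].unique()) - set(_STATUSES)
        if bad:
            raise ValueError(f"non-binary status values in {col}: {sorted(bad)}")
    f = records["field_status"].to_numpy()
    v = records["video_status"].to_numpy()
    return ConfusionMatrix(
        n_ll=int(((f == "living") & (v == "living")).sum()),
        n_ld=int(((f == "living") & (v == "dead")).sum()),
        n_dl=int(((f == "dead") & (v == "living")).sum()),
        n_dd=int(((f == "dead") & (v == "dead")).sum()),
    )


def compute_metrics(m: ConfusionMatrix, strict: bool = False) -> ClassificationMetrics:
    """Classification-success statistics from a confusion matrix.

    ccr = (n_ll + n_dd)/N; sensitivity = n_ll/(n_ll + n_ld);
    specificity = n_dd/(n_dl + n_dd); kappa = (p_o - p_e)/(1 - p_e) with
    p_o = ccr and p_e the product-of-marginals chance agreement. Statistics
    whose marginal is zero are returned as ``None`` (or raised when
    ``strict``); the defined subset is always computed.
    """
    total = m.total
    if total == 0:
        raise UndefinedMetricError("empty confusion matrix")
    ccr = (m.n_ll + m.n_dd) / total

    def _ratio(num: int, den: int, name: str) -> float | None:
        if den == 0:
            if strict:
                raise UndefinedMetricError(f"{name} undefined: zero marginal")
            return None
        return num / den

    sens = _ratio(m.n_ll, m.n_ll + m.n_ld, "sensitivity")
    spec = _ratio(m.n_dd, m.n_dl + m.n_dd, "specificity")

    p_field_living = (m.n_ll + m.n_ld) / total
    p_video_living = (m.n_ll + m.n_dl) / total
    p_e = p_field_living * p_video_living + (1 - p_field_living) * (1 - p_video_living)
    if math.isclose(p_e, 1.0):
        # degenerate marginals: agreement is forced, chance correction undefined
        kappa = None
        if strict:
            raise UndefinedMetricError("kappa undefined: chance agreement is 1")
    else:
        kappa = (ccr - p_e) / (1 - p_e)

    return ClassificationMetrics(
        ccr=ccr,
        sensitivity=sens,
        specificity=spec,
        kappa=kappa,
        false_negative_share=m.n_ld / total,
        false_positive_share=m.n_dl / total,
    )
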