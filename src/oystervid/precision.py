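"""Predicted precision of a monitoring design by error propagation.

The variance of the mean abundance per section estimated from ``a``
transects, ``b`` sections per transect, ``c`` observers and ``n`` readings
per observer is

    V[ybar] = s_tr2/a + s_se2/(a*b) + s_ob2/c + s_e2/(a*b*c*n)

with the variance components in (oysters per section)^2. The observer term
does not shrink with area, so it sets an asymptotic floor on achievable
precision. Site-to-site variance is excluded: the prediction applies within
a spatial unit comparable to one site, and extrapolation across sites needs
an additional between-site component. Per-m^2 figures divide the SE by the
section area at the reporting boundary only.
"""

from __future__ import annotations

import itertools
import math

import pandas as pd

from .design import PrecisionQuery, SurveyDesign, VarianceComponents

__all__ = ["PrecisionModel", "density", "InfeasibleTargetError"]


class InfeasibleTargetError(ValueError):
    """Requested precision is below the observer-variance floor."""


def density(count: float, area: float) -> float:
    """Oysters per square metre."""
    if area <= 0:
        raise ValueError(f"area must be positive, got {area}")
    if count < 0:
        raise ValueError("count must be >= 0")
    return count / area


class PrecisionModel:
    """Error propagation from variance components to survey-design precision.

    Parameters
    ----------
    vc : VarianceComponents
        Components in (oysters per section)^2, e.g. from a
        :class:`~oystervid.model.NestedSurveyResults`.
    design : SurveyDesign, optional
        Supplies the section geometry for per-m^2 conversion (default 3.2 m^2
        sections).
    include_interactions : bool
        When True the observer-by-space interaction terms
        ``s_trob2/(a*c) + s_seob2/(a*b*c)`` are added — the full
        balanced-design variance. Default False: the propagation formula
        keeps only the four leading components.
    """

    def __init__(
        self,
        vc: VarianceComponents,
        design: SurveyDesign | None = None,
        include_interactions: bool = False,
    ) -> None:
        self.vc = vc
        self.design = design if design is not None else SurveyDesign()
        self.include_interactions = include_interactions

    def _query(self, q) -> PrecisionQuery:
        if isinstance(q, PrecisionQuery):
            return q
        return PrecisionQuery(*q)

    def mean_variance(self, q) -> float:
        """Variance of the mean count per section, (oysters per section)^2."""
        q = self._query(q)
        vc = self.vc
        v = (
            vc.s_tr2 / q.a
            + vc.s_se2 / (q.a * q.b)
            + vc.s_ob2 / q.c
            + vc.s_e2 / (q.a * q.b * q.c * q.n)
        )
        if self.include_interactions:
            v += vc.s_trob2 / (q.a * q.c) + vc.s_seob2 / (q.a * q.b * q.c)
        return float(v)

    def se_per_section(self, q) -> float:
        return math.sqrt(self.mean_variance(q))

    def se_per_m2(self, q) -> float:
        """Standard error of mean density, oysters per m^2."""
        return self.se_per_section(q) / self.design.section_area

    def total_area(self, q) -> float:
        q = self._query(q)
        return q.a * q.b * self.design.section_area

    def result(self, q) -> dict[str, float]:
        q = self._query(q)
        v = self.mean_variance(q)
        return {
            "a": q.a,
            "b": q.b,
            "c": q.c,
            "n": q.n,
            "total_area": self.total_area(q),
            "variance_of_mean": v,
            "se_per_section": math.sqrt(v),
            "se_per_m2": math.sqrt(v) / self.design.section_area,
        }

    def scenario_grid(self, a_range, b_range, c_range=(1,), n_range=(1,)) -> pd.DataFrame:
        """Cartesian grid of designs with all precision figures, sorted by
        total area sampled."""
        ranges = [list(r) for r in (a_range, b_range, c_range, n_range)]
        if any(len(r) == 0 for r in ranges):
            raise ValueError("all ranges must be non-empty")
        rows = [
            self.result(PrecisionQuery(a, b, c, n))
            for a, b, c, n in itertools.product(*ranges)
        ]
        return (
            pd.DataFrame(rows)
            .sort_values(["total_area", "a", "c", "n"])
            .reset_index(drop=True)
        )

    def se_vs_area(self, area_grid, c: int = 1, n: int = 1) -> pd.DataFrame:
        """SE envelope over all integer transect/section splits of each area.

        For each total area the number of sections is ``round(area /
        section_area)`` and every factorization ``a*b`` of it is evaluated;
        the min/max SE bracket shows how little the split matters when the
        section component dominates.
        """
        rows = []
        for area in area_grid:
            if area <= 0:
                raise ValueError("areas must be positive")
            m = max(1, round(area / self.design.section_area))
            ses = {}
            for a in range(1, m + 1):
                if m % a == 0:
                    ses[(a, m // a)] = self.se_per_m2(PrecisionQuery(a, m // a, c, n))
            (a_best, b_best), se_min = min(ses.items(), key=lambda kv: kv[1])
            rows.append(
                {
                    "total_area": m * self.design.section_area,
                    "n_sections": m,
                    "se_per_m2_min": se_min,
                    "se_per_m2_max": max(ses.values()),
                    "best_a": a_best,
                    "best_b": b_best,
                }
            )
        return pd.DataFrame(rows)

    def observer_floor(self, c: int = 1) -> float:
        """Asymptotic SE per m^2 as sampled area grows without bound."""
        return math.sqrt(self.vc.s_ob2 / c) / self.design.section_area

    def required_area(
        self, target_se_per_m2: float, c: int = 1, n: int = 1, max_sections: int = 10**6
    ) -> tuple[float, PrecisionQuery]:
        """Smallest total area whose best transect/section split reaches the
        target SE, with a design achieving it.

        The best split of ``m`` sections is ``a=m, b=1`` (both spatial terms
        then scale as 1/m), so the best-split SE is monotone in area and a
        monotone search suffices.
        """
        floor = self.observer_floor(c)
        if target_se_per_m2 <= floor:
            raise InfeasibleTargetError(
                f"target {target_se_per_m2} m^-2 is at or below the observer "
                f"floor sqrt(s_ob2/c)/section_area = {floor:.4g} m^-2"
            )
        lo, hi = 1, 1
        while self.se_per_m2(PrecisionQuery(hi, 1, c, n)) > target_se_per_m2:
            hi *= 2
            if hi > max_sections:
                raise InfeasibleTargetError(
                    f"no design with <= {max_sections} sections reaches the target"
                )
        while lo < hi:
            mid = (lo + hi) // 2
            if self.se_per_m2(PrecisionQuery(mid, 1, c, n)) <= target_se_per_m2:
                hi = mid
            else:
                lo = mid + 1
        m = lo
        # among splits of m sections, prefer the most even feasible layout
        best = None
        for a in range(1, m + 1):
            if m % a == 0:
                q = PrecisionQuery(a, m // a, c, n)
                if self.se_per_m2(q) <= target_se_per_m2:
                    if best is None or abs(q.a - q.b) < abs(best.a - best.b):
                        best = q
        assert best is not None
        return m * self.design.section_area, best
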