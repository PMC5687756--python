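"""Model/Results interface for the nested survey mixed model."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .anova import (
    EMSTable,
    build_anova,
    derive_ems,
    estimate_vc_mom,
    f_tests,
    infer_design,
    resolve_response,
)
from .design import SurveyDesign, VarianceComponents
from .precision import PrecisionModel
from .reml import REMLResult, estimate_vc_reml

__all__ = ["NestedSurveyModel", "NestedSurveyResults"]


class NestedSurveyModel:
    """Mixed linear model for reading-level video survey counts.

    ``y = mu + Si + Tr(Si) + Se(Tr,Si) + Ob + Ob*Si + Tr(Si)*Ob +
    Se(Tr,Si)*Ob + e`` with Site fixed and everything else random. Built
    from a long-format DataFrame with one row per (site, transect, section,
    observer, reading).

    Parameters
    ----------
    data : DataFrame
        Reading records. The default response is the merged living count
        (``count_probably_living + count_possibly_living``).
    response : str, optional
        Alternative response column.
    design : SurveyDesign, optional
        Layout to validate the data against (and section geometry for the
        downstream precision model); inferred from the data when omitted.
    ems_convention : str
        ``"restricted"`` (classical mixed-model ANOVA convention; default)
        or ``"unrestricted"`` (the REML model's convention) for the expected
        mean squares behind F-tests and method-of-moments estimates.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str | None = None,
        design: SurveyDesign | None = None,
        ems_convention: str = "restricted",
    ) -> None:
        self.data = data
        self.response = response
        self.design = infer_design(data, design)
        self.ems_convention = ems_convention
        # fail early on an unusable response column
        resolve_response(data, response)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "NestedSurveyModel":
        from .io import read_readings

        return cls(read_readings(path), **kwargs)

    def fit(self, method: str = "reml", **reml_kwargs) -> "NestedSurveyResults":
        """Fit the model.

        ``method="reml"`` (default) estimates variance components by
        restricted maximum likelihood, started from the method-of-moments
        solution; ``method="anova"`` stops at the EMS-inverted
        method-of-moments estimates. The ANOVA table, EMS and F-tests are
        computed either way.
        """
        if method not in ("reml", "anova"):
            raise ValueError(f"unknown method {method!r}")
        anova = build_anova(self.data, self.response, self.design)
        ems = derive_ems(self.design, self.ems_convention)
        anova = f_tests(anova, ems)
        vc_mom, vc_mom_raw = estimate_vc_mom(anova, ems)
        reml: REMLResult | None = None
        if method == "reml":
            reml = estimate_vc_reml(
                self.data, self.response, start=vc_mom.as_dict(), **reml_kwargs
            )
        return NestedSurveyResults(
            model=self,
            anova=anova,
            ems=ems,
            vc_mom=vc_mom,
            vc_mom_raw=vc_mom_raw,
            reml=reml,
            method=method,
        )


class NestedSurveyResults:
    """Fit results: ANOVA table, EMS, F-tests and variance components.

    Attributes
    ----------
    anova : DataFrame
        Source, df, SS, MS, F, p and the denominator used for each test.
    ems : EMSTable
        Expected-mean-square coefficients.
    vc : VarianceComponents
        The estimates of the requested method (REML when fitted).
    vc_mom, vc_mom_raw : method-of-moments estimates (truncated / raw).
    """

    def __init__(
        self,
        model: NestedSurveyModel,
        anova: pd.DataFrame,
        ems: EMSTable,
        vc_mom: VarianceComponents,
        vc_mom_raw: dict[str, float],
        reml: REMLResult | None,
        method: str,
    ) -> None:
        self.model = model
        self.anova = anova
        self.ems = ems
        self.vc_mom = vc_mom
        self.vc_mom_raw = vc_mom_raw
        self.reml = reml
        self.method = method

    @property
    def vc(self) -> VarianceComponents:
        return self.reml.vc if self.reml is not None else self.vc_mom

    @property
    def loglike(self) -> float | None:
        return self.reml.loglike if self.reml is not None else None

    @property
    def converged(self) -> bool:
        return self.reml.converged if self.reml is not None else True

    def vc_shares(self) -> dict[str, float]:
        """Each random component's fraction of total random variability."""
        return self.vc.shares()

    def precision_model(self, include_interactions: bool = False) -> PrecisionModel:
        """Error-propagation model built on the fitted components."""
        return PrecisionModel(
            self.vc, self.model.design, include_interactions=include_interactions
        )

    def to_frame(self) -> pd.DataFrame:
        """Report table: Source, df, MS, p and the variance components."""
        table = self.anova[["source", "df", "ms", "p"]].copy()
        from .anova import COMPONENTS

        vc = self.vc.as_dict()
        table["vc"] = [
            vc.get(COMPONENTS[s], np.nan) if COMPONENTS[s] != "Q_si" else np.nan
            for s in table["source"]
        ]
        return table

    def summary(self) -> str:
        """Plain-text report in the field's customary layout: one row per
        source with df, mean square, p-value and variance component."""
        table = self.to_frame()
        lines = [
            "Nested mixed-model analysis of video survey counts",
            f"method: {self.method}"
            + (f"  (REML loglike {self.loglike:.3f})" if self.reml else ""),
            f"EMS convention: {self.ems.convention}"
            + ("  [coefficients approximate: unbalanced transects]" if self.ems.approximate else ""),
            "",
            f"{'Source':<16}{'df':>5}{'MS':>10}{'p':>8}{'VC':>8}",
        ]
        for _, r in table.iterrows():
            p = f"{r['p']:.2f}" if np.isfinite(r["p"]) else "-"
            v = f"{r['vc']:.1f}" if np.isfinite(r["vc"]) else "-"
            ms = f"{r['ms']:.1f}" if np.isfinite(r["ms"]) else "-"
            lines.append(f"{r['source']:<16}{int(r['df']):>5}{ms:>10}{p:>8}{v:>8}")
        total = self.vc.total
        if total > 0:
            shares = self.vc_shares()
            dominant = max(shares, key=shares.get)
            lines += [
                "",
                f"total random variability: {total:.1f} (counts/section)^2; "
                f"largest component {dominant} = {100 * shares[dominant]:.0f}%",
            ]
        return "\n".join(lines)
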