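"""Nested mixed-model ANOVA for the towed-video survey layout.

The model is ``y = mu + Si + Tr(Si) + Se(Tr,Si) + Ob + Ob*Si + Tr(Si)*Ob +
Se(Tr,Si)*Ob + e`` with Site fixed (sites are chosen deliberately) and
Observer, Transect and Section random. The residual is the variability
between replicate readings of the same section video by the same observer.

This module computes sums of squares from cell and marginal means, derives
expected mean squares with the Cornfield–Tukey algorithm (restricted or
unrestricted mixed-model convention), builds F-tests — including quasi-F
ratios with Satterthwaite degrees of freedom where no single mean square is
a valid denominator — and inverts the EMS system for method-of-moments
variance components. Only layouts of this shape are supported: one fixed
crossed factor, one random crossed factor and a two-level nested random
chain, balanced everywhere except possibly in transects per site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import SurveyDesign, VarianceComponents

__all__ = [
    "SOURCES",
    "COMPONENTS",
    "infer_design",
    "resolve_response",
    "build_anova",
    "derive_ems",
    "f_tests",
    "estimate_vc_mom",
    "IncompleteDesignError",
]

# Table-ordered source names (residual last)
SOURCES = [
    "Ob",
    "Si",
    "Tr(Si)",
    "Se(Tr,Si)",
    "Ob*Si",
    "Tr(Si)*Ob",
    "Se(Tr,Si)*Ob",
    "Residual",
]

# variance-component column per source; Site contributes a fixed quadratic
COMPONENTS = {
    "Ob": "s_ob2",
    "Si": "Q_si",
    "Tr(Si)": "s_tr2",
    "Se(Tr,Si)": "s_se2",
    "Ob*Si": "s_obsi2",
    "Tr(Si)*Ob": "s_trob2",
    "Se(Tr,Si)*Ob": "s_seob2",
    "Residual": "s_e2",
}

_RANDOM_SOURCES = [s for s in SOURCES if s != "Si"]

_FACTORS = ["Si", "Tr", "Se", "Ob", "R"]

# live and bracketed (nesting-parent) subscripts of each model term
_SUBSCRIPTS = {
    "Ob": ({"Ob"}, set()),
    "Si": ({"Si"}, set()),
    "Tr(Si)": ({"Tr"}, {"Si"}),
    "Se(Tr,Si)": ({"Se"}, {"Tr", "Si"}),
    "Ob*Si": ({"Ob", "Si"}, set()),
    "Tr(Si)*Ob": ({"Tr", "Ob"}, {"Si"}),
    "Se(Tr,Si)*Ob": ({"Se", "Ob"}, {"Tr", "Si"}),
    "Residual": ({"R"}, {"Si", "Tr", "Se", "Ob"}),
}


class IncompleteDesignError(ValueError):
    """The crossed reading structure has missing or unequal cells."""


def infer_design(readings: pd.DataFrame, design: SurveyDesign | None = None) -> SurveyDesign:
    """Infer the survey layout from the data and validate completeness.

    Every section must be read by every observer exactly ``n`` times and
    every transect must hold the same number of sections; only the number of
    transects may differ between sites.
    """
    required = {"site", "transect", "section", "observer", "reading"}
    missing = required - set(readings.columns)
    if missing:
        raise IncompleteDesignError(f"missing identifier columns: {sorted(missing)}")

    cell = readings.groupby(["site", "transect", "section", "observer"]).size()
    if cell.nunique() != 1:
        bad = cell[cell != cell.mode().iloc[0]]
        raise IncompleteDesignError(
            f"unequal replicate readings per (section, observer) cell: "
            f"{list(bad.index[:5])}"
        )
    n = int(cell.iloc[0])

    obs_per_sec = readings.groupby(["site", "transect", "section"])["observer"].nunique()
    if obs_per_sec.nunique() != 1:
        raise IncompleteDesignError("sections read by unequal numbers of observers")
    c = int(obs_per_sec.iloc[0])

    sec_per_tr = readings.groupby(["site", "transect"])["section"].nunique()
    if sec_per_tr.nunique() != 1:
        raise IncompleteDesignError("transects hold unequal numbers of sections")
    b = int(sec_per_tr.iloc[0])

    tr_per_site = tuple(
        int(v)
        for v in readings.groupby("site")["transect"].nunique().sort_index()
    )
    inferred = SurveyDesign(
        n_sites=len(tr_per_site),
        transects_per_site=tr_per_site,
        sections_per_transect=b,
        observers=c,
        readings_per_observer=n,
        section_length=design.section_length if design else 4.0,
        section_width=design.section_width if design else 0.8,
    )
    if design is not None:
        for attr in (
            "n_sites",
            "transects_per_site",
            "sections_per_transect",
            "observers",
            "readings_per_observer",
        ):
            if getattr(design, attr) != getattr(inferred, attr):
                raise IncompleteDesignError(
                    f"data layout disagrees with the supplied design on {attr}: "
                    f"{getattr(inferred, attr)} vs {getattr(design, attr)}"
                )
    return inferred


def resolve_response(readings: pd.DataFrame, response: str | None = None) -> pd.Series:
    """Response column for the model.

    Default is the merged living count (probably + possibly living) when the
    category count columns are present, otherwise a column named ``response``.
    """
    if response is None:
        if "count_probably_living" in readings.columns:
            y = readings["count_probably_living"]
            if "count_possibly_living" in readings.columns:
                y = y + readings["count_possibly_living"]
            return y.astype(float)
        raise ValueError("no count columns found; pass response=<column name>")
    if response not in readings.columns:
        raise ValueError(f"response column {response!r} not in data")
    return readings[response].astype(float)


def build_anova(
    readings: pd.DataFrame,
    response: str | None = None,
    design: SurveyDesign | None = None,
) -> pd.DataFrame:
    """ANOVA table (source, df, ss, ms) for the nested-factorial layout.

    Sums of squares are computed directly from cell and marginal means with
    cell-size weights; for layouts unbalanced only in transects per site the
    cell frequencies are proportional, so the decomposition stays orthogonal
    and the term SS add up to the total SS.
    """
    design = infer_design(readings, design)
    df = readings[["site", "transect", "section", "observer"]].copy()
    df["_y"] = resolve_response(readings, response).to_numpy()

    b, c, n = (
        design.sections_per_transect,
        design.observers,
        design.readings_per_observer,
    )
    N = len(df)
    grand = df["_y"].mean()

    def gmean(keys):
        return df.groupby(keys)["_y"].mean()

    m_si = gmean(["site"])
    m_tr = gmean(["site", "transect"])
    m_se = gmean(["site", "transect", "section"])
    m_ob = gmean(["observer"])
    m_siob = gmean(["site", "observer"])
    m_trob = gmean(["site", "transect", "observer"])
    m_seob = gmean(["site", "transect", "section", "observer"])
    n_si = df.groupby("site").size()

    ss = {}
    ss["Ob"] = (N / c) * ((m_ob - grand) ** 2).sum()
    ss["Si"] = (n_si * (m_si - grand) ** 2).sum()

    dev_tr = m_tr - m_si.reindex(m_tr.index.get_level_values("site")).to_numpy()
    ss["Tr(Si)"] = b * c * n * (dev_tr**2).sum()

    dev_se = m_se - m_tr.reindex(m_se.index.droplevel("section")).to_numpy()
    ss["Se(Tr,Si)"] = c * n * (dev_se**2).sum()

    dev = (
        m_siob
        - m_si.reindex(m_siob.index.get_level_values("site")).to_numpy()
        - m_ob.reindex(m_siob.index.get_level_values("observer")).to_numpy()
        + grand
    )
    w = n_si.reindex(m_siob.index.get_level_values("site")).to_numpy() / c
    ss["Ob*Si"] = (w * dev**2).sum()

    dev = (
        m_trob
        - m_tr.reindex(m_trob.index.droplevel("observer")).to_numpy()
        - m_siob.reindex(
            m_trob.index.droplevel("transect")
        ).to_numpy()
        + m_si.reindex(m_trob.index.get_level_values("site")).to_numpy()
    )
    ss["Tr(Si)*Ob"] = b * n * (dev**2).sum()

    dev = (
        m_seob
        - m_se.reindex(m_seob.index.droplevel("observer")).to_numpy()
        - m_trob.reindex(m_seob.index.droplevel("section")).to_numpy()
        + m_tr.reindex(m_seob.index.droplevel(["section", "observer"])).to_numpy()
    )
    ss["Se(Tr,Si)*Ob"] = n * (dev**2).sum()

    fitted = m_seob.reindex(
        pd.MultiIndex.from_frame(df[["site", "transect", "section", "observer"]])
    ).to_numpy()
    ss["Residual"] = ((df["_y"].to_numpy() - fitted) ** 2).sum()

    s = design.n_sites
    T = design.n_transects
    dfs = {
        "Ob": c - 1,
        "Si": s - 1,
        "Tr(Si)": sum(ti - 1 for ti in design.transects_per_site),
        "Se(Tr,Si)": T * (b - 1),
        "Ob*Si": (c - 1) * (s - 1),
        "Tr(Si)*Ob": (c - 1) * sum(ti - 1 for ti in design.transects_per_site),
        "Se(Tr,Si)*Ob": (c - 1) * T * (b - 1),
        "Residual": T * b * c * (n - 1),
    }
    table = pd.DataFrame(
        {
            "source": SOURCES,
            "df": [dfs[src] for src in SOURCES],
            "ss": [float(ss[src]) for src in SOURCES],
        }
    )
    table["ms"] = np.where(table["df"] > 0, table["ss"] / table["df"].clip(lower=1), np.nan)
    table.attrs["design"] = design
    return table


@dataclass(frozen=True)
class EMSTable:
    """Expected mean squares: one row per source, one column per variance
    component plus the fixed-site quadratic ``Q_si``."""

    coefficients: pd.DataFrame
    convention: str
    approximate: bool

    def row(self, source: str) -> pd.Series:
        return self.coefficients.loc[source]

    def describe(self, source: str) -> str:
        """Human-readable EMS, e.g. ``s_e2 + 2*s_seob2 + 4*s_se2``."""
        parts = []
        for comp, coef in self.row(source).items():
            if coef == 0:
                continue
            parts.append(comp if coef == 1 else f"{coef:g}*{comp}")
        return " + ".join(parts)


def derive_ems(
    design: SurveyDesign, convention: str = "restricted"
) -> EMSTable:
    """Cornfield–Tukey expected-mean-square coefficients.

    ``convention`` selects the restricted mixed model (interactions of random
    factors with the fixed Site factor sum to zero over sites, so they drop
    out of the random main effect's EMS) or the unrestricted model (the
    convention of REML software such as lmer). Designs unbalanced in
    transects per site use the mean transect count in coefficients involving
    it and are flagged ``approximate``.
    """
    if convention not in ("restricted", "unrestricted"):
        raise ValueError(f"unknown EMS convention {convention!r}")
    t_bar = float(np.mean(design.transects_per_site))
    levels = {
        "Si": float(design.n_sites),
        "Tr": t_bar,
        "Se": float(design.sections_per_transect),
        "Ob": float(design.observers),
        "R": float(design.readings_per_observer),
    }
    fixed = {"Si"}

    def entry(term: str, factor: str) -> float:
        live, brackets = _SUBSCRIPTS[term]
        if factor in brackets:
            return 1.0
        if factor in live:
            if factor in fixed and convention == "restricted":
                return 0.0
            return 1.0
        return levels[factor]

    cols = [COMPONENTS[s] for s in SOURCES]
    coef = pd.DataFrame(0.0, index=SOURCES, columns=cols)
    for u in SOURCES:
        u_live, u_brackets = _SUBSCRIPTS[u]
        u_sub = u_live | u_brackets
        for w in SOURCES:
            w_live, w_brackets = _SUBSCRIPTS[w]
            w_sub = w_live | w_brackets
            if not u_sub <= w_sub:
                continue
            prod = 1.0
            for f in _FACTORS:
                if f in u_sub:
                    continue
                prod *= entry(w, f)
            coef.loc[u, COMPONENTS[w]] = prod
    return EMSTable(
        coefficients=coef,
        convention=convention,
        approximate=not design.is_balanced,
    )


def _denominator(source: str, ems: EMSTable) -> tuple[dict[str, float], bool]:
    """Linear combination of other mean squares whose EMS equals the tested
    term's EMS minus its own component. Returns ({source: coeff}, testable)."""
    coef = ems.coefficients
    own = COMPONENTS[source]
    target = coef.loc[source].copy()
    target[own] = 0.0
    candidates = [s for s in SOURCES if s != source]
    A = coef.loc[candidates].to_numpy().T  # components x candidates
    sol, *_ = np.linalg.lstsq(A, target.to_numpy(), rcond=None)
    if not np.allclose(A @ sol, target.to_numpy(), atol=1e-9):
        return {}, False
    combo = {
        s: float(round(c, 10)) for s, c in zip(candidates, sol) if abs(c) > 1e-9
    }
    return combo, True


def f_tests(anova: pd.DataFrame, ems: EMSTable) -> pd.DataFrame:
    """Attach F statistics and p-values to an ANOVA table.

    Each term is tested against the mean square (or linear combination of
    mean squares — a quasi-F with Satterthwaite denominator degrees of
    freedom) whose expectation equals the term's EMS without the tested
    component. Terms with no constructible denominator are left untestable.
    """
    out = anova.copy()
    ms = anova.set_index("source")["ms"]
    dfree = anova.set_index("source")["df"]
    fvals, pvals, denoms = [], [], []
    for src in anova["source"]:
        if src == "Residual":
            fvals.append(np.nan)
            pvals.append(np.nan)
            denoms.append("")
            continue
        combo, testable = _denominator(src, ems)
        if not testable:
            fvals.append(np.nan)
            pvals.append(np.nan)
            denoms.append("untestable")
            continue
        d = sum(c * ms[s] for s, c in combo.items())
        if d <= 0:
            fvals.append(np.nan)
            pvals.append(np.nan)
            denoms.append("negative quasi-F denominator")
            continue
        # Satterthwaite approximation to the denominator df
        df_den = d**2 / sum((c * ms[s]) ** 2 / dfree[s] for s, c in combo.items())
        f = ms[src] / d
        fvals.append(float(f))
        pvals.append(float(stats.f.sf(f, dfree[src], df_den)))
        denoms.append(" + ".join(f"{c:g}*MS[{s}]" for s, c in combo.items()))
    out["f"] = fvals
    out["p"] = pvals
    out["denominator"] = denoms
    return out


def estimate_vc_mom(
    anova: pd.DataFrame, ems: EMSTable
) -> tuple[VarianceComponents, dict[str, float]]:
    """Method-of-moments variance components: solve MS = EMS(VC).

    Uses the seven random-source rows; the fixed Site row carries the
    quadratic form and is excluded. Negative solutions are truncated to zero
    in the returned :class:`VarianceComponents`; the raw (untruncated)
    estimates are returned alongside.
    """
    comp_cols = [COMPONENTS[s] for s in _RANDOM_SOURCES]
    A = ems.coefficients.loc[_RANDOM_SOURCES, comp_cols].to_numpy()
    msv = anova.set_index("source")["ms"].loc[_RANDOM_SOURCES].to_numpy()
    if abs(np.linalg.det(A)) < 1e-12:
        raise ValueError("singular EMS system: design cannot separate components")
    raw_vec = np.linalg.solve(A, msv)
    raw = dict(zip(comp_cols, (float(v) for v in raw_vec)))
    truncated = {k: max(v, 0.0) for k, v in raw.items()}
    return VarianceComponents(**truncated), raw
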