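"""Nested ANOVA: sums of squares, df bookkeeping, expected mean squares,
F-test denominators and method-of-moments inversion."""

import itertools
from statistics import mean

import numpy as np
import pandas as pd
import pytest

import oystervid as ov
from oystervid.anova import (
    COMPONENTS,
    SOURCES,
    IncompleteDesignError,
    _denominator,
    build_anova,
    derive_ems,
    estimate_vc_mom,
    f_tests,
)


def _balanced_dataset(s=2, t=2, b=2, c=2, n=2, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for si, tr, se, ob, rd in itertools.product(
        range(1, s + 1), range(1, t + 1), range(1, b + 1),
        range(1, c + 1), range(1, n + 1)
    ):
        rows.append((si, tr, se, ob, rd, rng.normal(10, 3), 0.0, 0.0))
    return pd.DataFrame(
        rows,
        columns=["site", "transect", "section", "observer", "reading",
                 "count_probably_living", "count_possibly_living", "count_dead"],
    )


def brute_force_ss(data):
    """Independent oracle: each SS from its defining sum over cell means,
    via explicit dictionaries and python loops."""
    y = {}
    for _, r in data.iterrows():
        y[(r.site, r.transect, r.section, r.observer, r.reading)] = (
            r.count_probably_living + r.count_possibly_living
        )
    keys = list(y)
    sites = sorted({k[0] for k in keys})
    trs = sorted({k[1] for k in keys})
    secs = sorted({k[2] for k in keys})
    obs = sorted({k[3] for k in keys})
    rds = sorted({k[4] for k in keys})
    t, b, c, n = len(trs), len(secs), len(obs), len(rds)

    def avg(filt):
        return mean(v for k, v in y.items() if filt(k))

    grand = mean(y.values())
    m_i = {i: avg(lambda k: k[0] == i) for i in sites}
    m_ij = {(i, j): avg(lambda k: k[:2] == (i, j)) for i in sites for j in trs}
    m_ijk = {
        (i, j, kk): avg(lambda k: k[:3] == (i, j, kk))
        for i in sites for j in trs for kk in secs
    }
    m_l = {l: avg(lambda k: k[3] == l) for l in obs}
    m_il = {(i, l): avg(lambda k: k[0] == i and k[3] == l) for i in sites for l in obs}
    m_ijl = {
        (i, j, l): avg(lambda k: k[:2] == (i, j) and k[3] == l)
        for i in sites for j in trs for l in obs
    }
    m_ijkl = {
        (i, j, kk, l): avg(lambda k: k[:4] == (i, j, kk, l))
        for i in sites for j in trs for kk in secs for l in obs
    }

    ss = {}
    ss["Si"] = t * b * c * n * sum((m_i[i] - grand) ** 2 for i in sites)
    ss["Ob"] = len(sites) * t * b * n * sum((m_l[l] - grand) ** 2 for l in obs)
    ss["Tr(Si)"] = b * c * n * sum(
        (m_ij[i, j] - m_i[i]) ** 2 for i in sites for j in trs
    )
    ss["Se(Tr,Si)"] = c * n * sum(
        (m_ijk[i, j, kk] - m_ij[i, j]) ** 2
        for i in sites for j in trs for kk in secs
    )
    ss["Ob*Si"] = t * b * n * sum(
        (m_il[i, l] - m_i[i] - m_l[l] + grand) ** 2 for i in sites for l in obs
    )
    ss["Tr(Si)*Ob"] = b * n * sum(
        (m_ijl[i, j, l] - m_ij[i, j] - m_il[i, l] + m_i[i]) ** 2
        for i in sites for j in trs for l in obs
    )
    ss["Se(Tr,Si)*Ob"] = n * sum(
        (m_ijkl[i, j, kk, l] - m_ijk[i, j, kk] - m_ijl[i, j, l] + m_ij[i, j]) ** 2
        for i in sites for j in trs for kk in secs for l in obs
    )
    ss["Residual"] = sum(
        (v - m_ijkl[k[0], k[1], k[2], k[3]]) ** 2 for k, v in y.items()
    )
    return ss


class TestBuildAnova:
    def test_reference_design_df_column(self, gaussian_readings):
        table = build_anova(gaussian_readings)
        assert table["df"].tolist() == [1, 2, 10, 52, 2, 10, 52, 130]

    def test_df_sums_to_n_minus_one(self, gaussian_readings):
        table = build_anova(gaussian_readings)
        assert table["df"].sum() == len(gaussian_readings) - 1

    def test_constant_response_zero_ss(self, ref_design):
        cfg = ov.GeneratorConfig(mode="gaussian-vc", grand_mean=5.0, seed=0)
        data = ov.generate_vc_dataset(ref_design, cfg)
        table = build_anova(data)
        rows = table[table["source"] != "Si"]
        assert (np.abs(rows["ss"]) < 1e-18).all()

    def test_ss_match_brute_force_oracle(self):
        data = _balanced_dataset()
        table = build_anova(data).set_index("source")
        oracle = brute_force_ss(data)
        for src, expected in oracle.items():
            assert table.loc[src, "ss"] == pytest.approx(expected, abs=1e-10)

    def test_ss_decomposition_is_orthogonal(self, gaussian_readings):
        table = build_anova(gaussian_readings)
        y = (
            gaussian_readings["count_probably_living"]
            + gaussian_readings["count_possibly_living"]
        )
        total = ((y - y.mean()) ** 2).sum()
        assert table["ss"].sum() == pytest.approx(total, rel=1e-8)

    def test_missing_cell_raises_with_key(self, gaussian_readings):
        broken = gaussian_readings.drop(index=[0]).reset_index(drop=True)
        with pytest.raises(IncompleteDesignError):
            build_anova(broken)


class TestDeriveEms:
    def test_residual_row_is_pure_error(self, ref_design):
        ems = derive_ems(ref_design)
        row = ems.row("Residual")
        assert row["s_e2"] == 1.0
        assert (row.drop("s_e2") == 0).all()

    def test_section_row_reference_design(self, ref_design):
        # E[MS_Se(Tr,Si)] = s_e2 + n*s_seob2 + n*c*s_se2 with n = c = 2
        row = derive_ems(ref_design).row("Se(Tr,Si)")
        assert row["s_e2"] == 1.0
        assert row["s_seob2"] == 2.0
        assert row["s_se2"] == 4.0
        assert row[["s_ob2", "s_obsi2", "s_trob2", "Q_si"]].eq(0).all()

    def test_coefficients_count_observations_per_level(self):
        # balanced design: every nonzero coefficient of a component equals
        # the number of observations per level combination of that component
        design = ov.SurveyDesign(
            n_sites=2, transects_per_site=(3, 3), sections_per_transect=4,
            observers=2, readings_per_observer=3,
        )
        N = design.n_readings
        levels = {
            "s_ob2": 2, "Q_si": 2, "s_tr2": 6, "s_se2": 24,
            "s_obsi2": 4, "s_trob2": 12, "s_seob2": 48, "s_e2": N,
        }
        coef = derive_ems(design).coefficients
        for comp, nlev in levels.items():
            col = coef[comp]
            nonzero = col[col != 0]
            assert (nonzero == N / nlev).all(), comp

    def test_restricted_vs_unrestricted_observer_row(self, ref_design):
        restricted = derive_ems(ref_design, "restricted").row("Ob")
        unrestricted = derive_ems(ref_design, "unrestricted").row("Ob")
        assert restricted["s_obsi2"] == 0.0
        assert unrestricted["s_obsi2"] > 0.0
        assert ems_equal_elsewhere(restricted, unrestricted)

    def test_unbalanced_design_flagged_approximate(self, ref_design):
        assert derive_ems(ref_design).approximate
        balanced = ov.SurveyDesign(transects_per_site=(4, 4, 4))
        assert not derive_ems(balanced).approximate


def ems_equal_elsewhere(a, b):
    mask = a.index != "s_obsi2"
    return bool((a[mask] == b[mask]).all())


class TestFTests:
    def test_denominator_structure(self, ref_design):
        ems = derive_ems(ref_design, "restricted")
        assert _denominator("Se(Tr,Si)*Ob", ems) == ({"Residual": 1.0}, True)
        assert _denominator("Se(Tr,Si)", ems) == ({"Se(Tr,Si)*Ob": 1.0}, True)
        assert _denominator("Ob", ems) == ({"Tr(Si)*Ob": 1.0}, True)
        # Site needs a quasi-F: MS_Tr + MS_ObSi - MS_TrOb
        combo, ok = _denominator("Si", ems)
        assert ok
        assert combo == {"Tr(Si)": 1.0, "Ob*Si": 1.0, "Tr(Si)*Ob": -1.0}

    def test_unrestricted_observer_denominator(self, ref_design):
        ems = derive_ems(ref_design, "unrestricted")
        assert _denominator("Ob", ems) == ({"Ob*Si": 1.0}, True)

    def test_p_values_filled(self, gaussian_readings, ref_design):
        table = f_tests(build_anova(gaussian_readings), derive_ems(ref_design))
        tested = table[table["source"] != "Residual"]
        assert tested["p"].between(0, 1).all()


class TestEstimateVcMom:
    def test_exact_recovery_from_manufactured_ms(self, ref_design):
        ems = derive_ems(ref_design)
        comp_cols = [COMPONENTS[s] for s in SOURCES if s != "Si"]
        truth = {"s_ob2": 0.1, "s_tr2": 1.1, "s_se2": 26.2, "s_obsi2": 0.4,
                 "s_trob2": 0.1, "s_seob2": 0.3, "s_e2": 1.6}
        A = ems.coefficients.loc[[s for s in SOURCES if s != "Si"], comp_cols]
        ms = A.to_numpy() @ np.array([truth[c] for c in comp_cols])
        anova = pd.DataFrame(
            {"source": A.index, "df": 1, "ss": ms, "ms": ms}
        )
        vc, raw = estimate_vc_mom(anova, ems)
        for k, v in truth.items():
            assert raw[k] == pytest.approx(v, abs=1e-10)

    def test_negative_raw_truncated_but_preserved(self, ref_design):
        ems = derive_ems(ref_design)
        anova = build_anova(
            ov.generate_vc_dataset(
                ref_design,
                ov.GeneratorConfig(
                    mode="gaussian-vc", grand_mean=10.0,
                    vc=ov.VarianceComponents(s_e2=4.0), seed=13,
                ),
            )
        )
        vc, raw = estimate_vc_mom(anova, ems)
        assert min(raw.values()) < 0  # pure-noise data gives some negatives
        assert min(vc.as_dict().values()) >= 0
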