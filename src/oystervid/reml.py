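"""Restricted maximum likelihood for the survey variance components.

Fits the Gaussian mixed model ``y = X beta + sum_r Z_r u_r + e`` with Site
fixed and six independent random-effect blocks (Observer, Transect(Site),
Section(Tr,Si), Ob*Si, Tr(Si)*Ob, Se(Tr,Si)*Ob) plus the residual. The
residual variance is profiled out analytically, leaving the restricted
log-likelihood a function of the six variance ratios gamma_r = s_r2 / s_e2,
which are maximised by L-BFGS-B with analytic gradients under non-negativity
bounds; a ratio pinned at the bound is reported as a component of exactly
zero. This dense-likelihood route handles the crossed Observer factor and
the transect imbalance exactly, and is the authoritative estimator for
unbalanced layouts (the ANOVA/EMS route is exact only for balanced ones).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .anova import resolve_response
from .design import VarianceComponents

__all__ = ["estimate_vc_reml", "REMLResult", "REMLConvergenceError"]

_BLOCKS = (
    ("s_ob2", ["observer"]),
    ("s_tr2", ["site", "transect"]),
    ("s_se2", ["site", "transect", "section"]),
    ("s_obsi2", ["site", "observer"]),
    ("s_trob2", ["site", "transect", "observer"]),
    ("s_seob2", ["site", "transect", "section", "observer"]),
)

_GAMMA_MAX = 1e8


class REMLConvergenceError(RuntimeError):
    """The optimizer failed to converge; carries the scipy result."""

    def __init__(self, message: str, result) -> None:
        super().__init__(message)
        self.result = result


@dataclass(frozen=True)
class REMLResult:
    vc: VarianceComponents
    loglike: float
    converged: bool
    n_iter: int
    message: str

    def as_dict(self) -> dict[str, float]:
        return self.vc.as_dict()


def _group_codes(readings: pd.DataFrame, keys: list[str]) -> np.ndarray:
    return readings.groupby(keys, sort=True).ngroup().to_numpy()


def estimate_vc_reml(
    readings: pd.DataFrame,
    response: str | None = None,
    start: dict[str, float] | None = None,
    maxiter: int = 500,
    raise_on_failure: bool = True,
) -> REMLResult:
    """REML variance components from reading-level data.

    Parameters
    ----------
    readings : DataFrame
        Reading records with site/transect/section/observer identifiers.
    response : str, optional
        Response column; default is the merged living count.
    start : dict, optional
        Starting values per component (e.g. method-of-moments estimates).
    """
    y = resolve_response(readings, response).to_numpy(dtype=float)
    N = y.size

    X = pd.get_dummies(readings["site"]).to_numpy(dtype=float)
    p = np.linalg.matrix_rank(X)
    if p < X.shape[1]:
        raise ValueError("fixed-effect design matrix is rank deficient")

    # zero-variance degeneracy: nothing to estimate
    if np.ptp(y) == 0.0 or np.var(y) < 1e-14 * max(1.0, np.mean(y) ** 2):
        vc = VarianceComponents()
        return REMLResult(vc, loglike=np.inf, converged=True, n_iter=0, message="degenerate: constant response")

    # Z_r Z_r' as dense equality matrices (N is small for survey layouts)
    gram = []
    for _, keys in _BLOCKS:
        codes = _group_codes(readings, keys)
        gram.append((codes[:, None] == codes[None, :]).astype(float))
    eye = np.eye(N)

    names = [name for name, _ in _BLOCKS]
    df_resid = N - p

    def objective(gamma: np.ndarray) -> tuple[float, np.ndarray]:
        W = eye.copy()
        for g, G in zip(gamma, gram):
            if g:
                W += g * G
        try:
            L = np.linalg.cholesky(W)
        except np.linalg.LinAlgError:
            return np.inf, np.zeros_like(gamma)
        logdet_W = 2.0 * np.log(np.diag(L)).sum()
        Li = np.linalg.inv(L)
        Wi = Li.T @ Li
        WiX = Wi @ X
        XtWiX = X.T @ WiX
        sign, logdet_X = np.linalg.slogdet(XtWiX)
        if sign <= 0:
            return np.inf, np.zeros_like(gamma)
        P = Wi - WiX @ np.linalg.solve(XtWiX, WiX.T)
        Py = P @ y
        q = float(y @ Py)
        if q <= 0:
            return np.inf, np.zeros_like(gamma)
        f = df_resid * np.log(q) + logdet_W + logdet_X
        grad = np.array(
            [float((P * G).sum() - df_resid * (Py @ G @ Py) / q) for G in gram]
        )
        return f, grad

    if start is not None:
        s_e = max(start.get("s_e2", 1.0), 1e-8)
        x0 = np.array([max(start.get(k, 0.0), 0.0) / s_e for k in names])
    else:
        x0 = np.ones(len(names))
    x0 = np.clip(x0, 0.0, _GAMMA_MAX / 10)

    res = optimize.minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, _GAMMA_MAX)] * len(names),
        options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-9},
    )
    gamma = res.x

    # projected gradient: components at the zero bound may have positive grad
    _, grad = objective(gamma)
    proj = np.where((gamma <= 0) & (grad > 0), 0.0, grad)
    converged = bool(res.success) or float(np.max(np.abs(proj))) < 1e-4
    if not converged and raise_on_failure:
        raise REMLConvergenceError(
            f"REML did not converge after {res.nit} iterations: {res.message}", res
        )

    # recover the profiled residual variance and the restricted log-likelihood
    W = eye.copy()
    for g, G in zip(gamma, gram):
        if g:
            W += g * G
    Wi = np.linalg.inv(W)
    WiX = Wi @ X
    XtWiX = X.T @ WiX
    P = Wi - WiX @ np.linalg.solve(XtWiX, WiX.T)
    q = float(y @ P @ y)
    s_e2 = q / df_resid
    _, logdet_X = np.linalg.slogdet(XtWiX)
    logdet_W = np.linalg.slogdet(W)[1]
    m2ll = (
        df_resid * (np.log(2 * np.pi * s_e2) + 1.0) + logdet_W + logdet_X
    )

    comp = {name: float(g * s_e2) if g > 1e-12 else 0.0 for name, g in zip(names, gamma)}
    comp["s_e2"] = float(s_e2)
    return REMLResult(
        vc=VarianceComponents(**comp),
        loglike=-0.5 * m2ll,
        converged=converged,
        n_iter=int(res.nit),
        message=str(res.message),
    )
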