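"""Binomial mixed models for genotype-by-environment interaction in survival.

A vial-level panel table (strain x diet x vial counts of pupated larvae)
is modelled with a binomial GLMM on the logit scale:

    logit p_i = beta_0 + beta_{diet(i)} + b_{strain(i), 0}
                [+ b_{strain(i), diet(i)} with random slopes]

with strain-level random effects b_s ~ N(0, Sigma).  The null model
("intercept only") carries a scalar strain intercept variance; the GxE
model ("intercept plus slopes") carries a full unstructured k x k
covariance over the intercept and the k-1 treatment-coded diet slopes.
The likelihood-ratio comparison of the two models therefore has
k(k+1)/2 - 1 degrees of freedom (20 for six diets), and a significant
improvement of the slopes model indicates non-zero among-strain variance
in the response to diet, i.e. genotype-by-environment interaction.

The marginal likelihood integrates the random effects per strain with a
Laplace approximation: the penalized binomial log-likelihood is maximized
by damped Newton iterations (it is strictly concave), and the Gaussian
curvature correction -0.5 log det(Z'WZ + Sigma^-1) is added.  The outer
optimization runs bounded L-BFGS-B over the fixed effects and the
log-Cholesky factor of Sigma, from fixed all-zero starting values, so
fits are deterministic.  Boundary (near-singular) variance estimates are
reported, not dropped, and the chi-square p-value of the comparison uses
the naive reference distribution — conservative when variance components
sit on the boundary, which is flagged with a warning.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, gammaln

__all__ = [
    "GLMMFit",
    "GxEComparison",
    "count_parameters",
    "fit_binomial_glmm",
    "laplace_loglik",
    "compare_gxe",
]

_log = logging.getLogger(__name__)

_DIAG_LOWER = -7.0  # log-scale lower bound; exp(-7) ~ a numerically-zero SD


def count_parameters(n_diets: int, random_slopes: bool) -> int:
    """Number of estimated parameters of a panel GLMM.

    ``n_diets`` fixed effects (intercept + treatment-coded offsets), plus
    one variance for the intercept-only random structure or
    ``n_diets*(n_diets+1)/2`` covariance parameters with random slopes.
    """
    if n_diets < 1:
        raise ValueError("n_diets must be >= 1")
    if random_slopes:
        return n_diets + n_diets * (n_diets + 1) // 2
    return n_diets + 1


# ---------------------------------------------------------------------------
# data preparation


class _PanelData:
    """Padded per-strain arrays for batched likelihood evaluation."""

    def __init__(
        self,
        panel: pd.DataFrame,
        pool_vials: bool = False,
        reference_diet: str | None = None,
    ):
        required = {"strain", "diet", "n_seeded", "n_pupated"}
        missing = required - set(panel.columns)
        if missing:
            raise ValueError(f"panel is missing columns: {sorted(missing)}")
        df = panel.copy()
        if (df["n_pupated"] > df["n_seeded"]).any() or (df["n_pupated"] < 0).any():
            raise ValueError("counts must satisfy 0 <= n_pupated <= n_seeded")
        if "n_eclosed" in df.columns:
            if (df["n_eclosed"] > df["n_pupated"]).any() or (df["n_eclosed"] < 0).any():
                raise ValueError("counts must satisfy 0 <= n_eclosed <= n_pupated")
        if pool_vials:
            df = (
                df.groupby(["strain", "diet"], sort=False)[["n_seeded", "n_pupated"]]
                .sum()
                .reset_index()
            )
        self.diets = list(dict.fromkeys(df["diet"]))
        if reference_diet is not None:
            if reference_diet not in self.diets:
                raise ValueError(f"reference diet {reference_diet!r} not in panel")
            self.diets.remove(reference_diet)
            self.diets.insert(0, reference_diet)
        self.strains = list(dict.fromkeys(df["strain"]))
        if len(self.strains) < 2:
            raise ValueError("at least 2 strains required")
        ref = self.diets[0]
        seen_ref = set(df.loc[df["diet"] == ref, "strain"])
        if set(self.strains) - seen_ref:
            raise ValueError(f"every strain must be observed on the reference diet {ref!r}")

        k = len(self.diets)
        s_code = df["strain"].map({s: i for i, s in enumerate(self.strains)}).to_numpy()
        d_code = df["diet"].map({d: j for j, d in enumerate(self.diets)}).to_numpy()
        y = df["n_pupated"].to_numpy(dtype=float)
        n = df["n_seeded"].to_numpy(dtype=float)

        S = len(self.strains)
        counts = np.bincount(s_code, minlength=S)
        N = counts.max()
        self.Y = np.zeros((S, N))
        self.Ntot = np.zeros((S, N))
        self.D = np.zeros((S, N), dtype=int)
        fill = np.zeros(S, dtype=int)
        for row in range(len(df)):
            s = s_code[row]
            j = fill[s]
            self.Y[s, j] = y[row]
            self.Ntot[s, j] = n[row]
            self.D[s, j] = d_code[row]
            fill[s] += 1
        self.n_diets = k
        self.n_strains = S
        self.log_choose = float(
            np.sum(gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1))
        )
        # full random-slope design; the intercept-only model uses Z[..., :1]
        self.Z = np.zeros((S, N, k))
        active = self.Ntot > 0
        self.Z[..., 0] = active
        for j in range(1, k):
            self.Z[..., j] = active & (self.D == j)
        self.fingerprint = hashlib.sha1(
            pd.util.hash_pandas_object(
                df[["strain", "diet", "n_seeded", "n_pupated"]].astype(str), index=False
            ).to_numpy()
        ).hexdigest()


def _chol_from_params(params: np.ndarray, k: int) -> np.ndarray:
    L = np.zeros((k, k))
    idx = 0
    for i in range(k):
        for j in range(i + 1):
            L[i, j] = np.exp(params[idx]) if i == j else params[idx]
            idx += 1
    return L


def _diag_positions(k: int) -> list[int]:
    pos, idx = [], 0
    for i in range(k):
        for j in range(i + 1):
            if i == j:
                pos.append(idx)
            idx += 1
    return pos


def _penalized_loglik(data: _PanelData, Z, eta_fixed, b, Om):
    eta = eta_fixed + np.einsum("snk,sk->sn", Z, b)
    ll = np.sum(data.Y * eta - data.Ntot * np.logaddexp(0.0, eta), axis=1)
    pen = 0.5 * np.einsum("sk,kl,sl->s", b, Om, b)
    return ll - pen


def _inner_newton(data: _PanelData, Z, eta_fixed, Om, b0):
    """Maximize the per-strain penalized binomial log-likelihood (concave)."""
    b = b0.copy()
    h = _penalized_loglik(data, Z, eta_fixed, b, Om)
    for _ in range(100):
        eta = eta_fixed + np.einsum("snk,sk->sn", Z, b)
        p = expit(eta)
        mu = data.Ntot * p
        w = np.maximum(data.Ntot * p * (1.0 - p), 0.0)
        g = np.einsum("snk,sn->sk", Z, data.Y - mu) - b @ Om
        H = np.einsum("snk,sn,snl->skl", Z, w, Z) + Om
        if np.max(np.abs(g)) < 1e-9:
            break
        delta = np.linalg.solve(H, g[..., None])[..., 0]
        step = np.ones(data.n_strains)
        for _ in range(25):
            b_new = b + step[:, None] * delta
            h_new = _penalized_loglik(data, Z, eta_fixed, b_new, Om)
            worse = h_new < h - 1e-12
            if not worse.any():
                break
            step[worse] *= 0.5
        if np.max(np.abs(step[:, None] * delta)) < 1e-11:
            b, h = b_new, h_new
            break
        b, h = b_new, h_new
    eta = eta_fixed + np.einsum("snk,sk->sn", Z, b)
    p = expit(eta)
    w = np.maximum(data.Ntot * p * (1.0 - p), 0.0)
    H = np.einsum("snk,sn,snl->skl", Z, w, Z) + Om
    return b, h, H


def _laplace_from_arrays(data: _PanelData, beta, L, k_re, warm):
    Sigma = L @ L.T
    logdet_S = 2.0 * np.sum(np.log(np.diag(L)))
    Om = np.linalg.inv(Sigma + 1e-12 * np.eye(k_re))
    offs = np.concatenate([[0.0], beta[1:]])
    eta_fixed = beta[0] + offs[data.D]
    eta_fixed = np.where(data.Ntot > 0, eta_fixed, 0.0)
    Z = data.Z[..., :k_re]
    b0 = warm.get("b")
    if b0 is None or b0.shape != (data.n_strains, k_re):
        b0 = np.zeros((data.n_strains, k_re))
    b, h, H = _inner_newton(data, Z, eta_fixed, Om, b0)
    warm["b"] = b
    sign, logdet_H = np.linalg.slogdet(H)
    if np.any(sign <= 0):
        return -np.inf, b
    ll = (
        np.sum(h)
        + data.log_choose
        - 0.5 * data.n_strains * logdet_S
        - 0.5 * np.sum(logdet_H)
    )
    return ll, b


def laplace_loglik(
    panel: pd.DataFrame,
    fixed_effects: np.ndarray,
    covariance: np.ndarray,
    random_slopes: bool,
    pool_vials: bool = False,
) -> float:
    """Laplace-approximated marginal log-likelihood at given parameter values.

    ``fixed_effects`` is (intercept, diet offsets...) in panel diet order;
    ``covariance`` is the random-effect covariance (scalar/1x1 for the
    intercept-only structure, k x k with slopes).  Exposed separately from
    :func:`fit_binomial_glmm` so the approximation can be validated
    against direct numerical integration.
    """
    data = _PanelData(panel, pool_vials=pool_vials)
    cov = np.atleast_2d(np.asarray(covariance, dtype=float))
    k_re = data.n_diets if random_slopes else 1
    if cov.shape != (k_re, k_re):
        raise ValueError(f"covariance must be {k_re}x{k_re}")
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(k_re))
    ll, _ = _laplace_from_arrays(data, np.asarray(fixed_effects, float), L, k_re, {})
    return float(ll)


@dataclass
class GLMMFit:
    """A fitted binomial panel GLMM."""

    fixed_effects: pd.Series
    random_structure: str  # "intercept_only" | "intercept_plus_slopes"
    random_covariance: pd.DataFrame
    log_likelihood: float
    deviance: float
    aic: float
    n_parameters: int
    converged: bool
    singular: bool
    diets: tuple
    n_strains: int
    message: str
    data_fingerprint: str


def fit_binomial_glmm(
    panel: pd.DataFrame,
    random_slopes: bool = False,
    pool_vials: bool = False,
    reference_diet: str | None = None,
    maxiter: int = 500,
) -> GLMMFit:
    """Fit the vial-level binomial GLMM by Laplace maximum likelihood.

    ``random_slopes=False`` fits the intercept-only (null) model;
    ``random_slopes=True`` adds per-strain treatment-coded diet slopes
    with a full unstructured covariance.  ``pool_vials`` collapses
    replicate vials to strain x diet totals before fitting.  The
    reference diet defaults to the first one appearing in the panel.
    """
    data = _PanelData(panel, pool_vials=pool_vials, reference_diet=reference_diet)
    if data.n_diets < 2:
        raise ValueError("at least 2 diets required")
    k = data.n_diets
    k_re = k if random_slopes else 1
    n_cov = k_re * (k_re + 1) // 2
    diag_pos = _diag_positions(k_re)

    warm: dict = {}

    def negloglik(x: np.ndarray) -> float:
        beta = x[:k]
        L = _chol_from_params(x[k:], k_re)
        ll, _ = _laplace_from_arrays(data, beta, L, k_re, warm)
        return -ll if np.isfinite(ll) else 1e12

    x0 = np.zeros(k + n_cov)
    bounds = [(None, None)] * k + [(-25.0, 25.0)] * n_cov
    for p in diag_pos:
        bounds[k + p] = (_DIAG_LOWER, 3.0)

    res = optimize.minimize(
        negloglik,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "maxfun": 100 * maxiter},
    )
    beta = res.x[:k]
    L = _chol_from_params(res.x[k:], k_re)
    Sigma = L @ L.T
    ll = -float(res.fun)
    npar = count_parameters(k, random_slopes)
    singular = any(res.x[k + p] <= _DIAG_LOWER + 0.5 for p in diag_pos)
    message = res.message if isinstance(res.message, str) else str(res.message)
    if singular:
        message += "; singular fit: one or more random-effect SDs at the zero boundary"
        _log.warning("singular GLMM fit: random-effect SD estimated at the zero boundary")

    re_labels = ["(Intercept)"] + [f"slope[{d}]" for d in data.diets[1:]]
    re_labels = re_labels[:k_re]
    return GLMMFit(
        fixed_effects=pd.Series(beta, index=["(Intercept)"] + list(data.diets[1:])),
        random_structure="intercept_plus_slopes" if random_slopes else "intercept_only",
        random_covariance=pd.DataFrame(Sigma, index=re_labels, columns=re_labels),
        log_likelihood=ll,
        deviance=-2.0 * ll,
        aic=-2.0 * ll + 2.0 * npar,
        n_parameters=npar,
        converged=bool(res.success),
        singular=singular,
        diets=tuple(data.diets),
        n_strains=data.n_strains,
        message=message,
        data_fingerprint=data.fingerprint,
    )


@dataclass
class GxEComparison:
    """Likelihood-ratio comparison of the null and random-slopes GLMMs."""

    delta_aic: float  # AIC(slopes) - AIC(null)
    chi_square: float  # deviance(null) - deviance(slopes)
    df: int
    p_value: float


def compare_gxe(fit_null: GLMMFit, fit_gxe: GLMMFit) -> GxEComparison:
    """Test for among-strain variance in the diet response (GxE).

    The chi-square statistic is the deviance reduction of the
    random-slopes model over the intercept-only model; its reference
    distribution has k(k+1)/2 - 1 degrees of freedom for k diets.  The
    naive chi-square p-value is conservative because the extra variance
    components lie on the boundary of the parameter space under the null.
    """
    if fit_null.data_fingerprint != fit_gxe.data_fingerprint:
        raise ValueError("fits were not computed on the same panel data")
    if fit_null.random_structure == fit_gxe.random_structure:
        df = 0
    elif (
        fit_null.random_structure != "intercept_only"
        or fit_gxe.random_structure != "intercept_plus_slopes"
    ):
        raise ValueError(
            "expected fit_null with intercept_only and fit_gxe with "
            "intercept_plus_slopes random structures"
        )
    else:
        df = fit_gxe.n_parameters - fit_null.n_parameters
    chi2 = fit_null.deviance - fit_gxe.deviance
    if chi2 < -1e-3:
        _log.warning(
            "random-slopes model has higher deviance than the null by %.4f; "
            "likely an optimizer artefact", -chi2
        )
    if df > 0:
        _log.warning(
            "boundary caveat: the chi-square p-value is conservative because "
            "the null places variance components on the parameter-space boundary"
        )
    p = float(stats.chi2.sf(max(chi2, 0.0), df)) if df > 0 else 1.0
    return GxEComparison(
        delta_aic=fit_gxe.aic - fit_null.aic,
        chi_square=float(chi2),
        df=int(df),
        p_value=p,
    )
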