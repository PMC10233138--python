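"""Causal estimators for summary-level two-sample Mendelian randomization.

Per SNP, the Wald ratio beta_out / beta_exp estimates the causal effect of
one exposure unit on the log-odds of the outcome; its standard error comes
from the Delta method (first order by default).  The pooled estimators are:

* ``ivw`` — inverse-variance-weighted mean of the ratios, equivalently the
  zero-intercept weighted regression of beta_out on beta_exp with weights
  1/se_out^2.  The multiplicative random-effects variant scales the
  fixed-effects SE by the residual dispersion sigma = sqrt(Q/(k-1)),
  deliberately *not* floored at 1: with fewer instruments than expected
  heterogeneity, sigma < 1 tightens the interval, which is the convention
  the reproduced results require.
* ``max_likelihood`` — joint bivariate-normal likelihood over the causal
  effect theta and the k latent true instrument effects.
* ``weighted_median`` — the inverse-variance weighted median of the ratios,
  consistent when at least half the weight comes from valid instruments;
  SE by parametric bootstrap.
* ``egger`` — weighted regression with an unconstrained intercept after
  orienting all SNPs to positive exposure effects; the intercept estimates
  the average directional pleiotropy and its test is the pleiotropy check.

IVW, ML and the weighted median use normal inference; MR-Egger uses the t
distribution with k-2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .exceptions import (
    ConvergenceError,
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
    MRKitError,
)
from .harmonize import HarmonizedPair, InstrumentSet

__all__ = [
    "RatioEstimate",
    "MREstimate",
    "EggerEstimate",
    "wald_ratio",
    "ratio_statistics",
    "ivw",
    "max_likelihood",
    "weighted_median",
    "egger",
]

METHOD_LABELS = (
    "wald",
    "ivw_fe",
    "ivw_mre",
    "max_likelihood",
    "weighted_median",
    "egger_slope",
)


@dataclass(frozen=True)
class RatioEstimate:
    """Per-SNP Wald ratio with its Delta-method SE."""

    snp_id: str
    ratio: float
    se_ratio: float
    order: str  # "first" | "second"


@dataclass(frozen=True)
class MREstimate:
    """A pooled causal estimate on the log-odds scale, with OR and 95% CI."""

    method: str
    k: int
    beta: float
    se: float
    pval: float
    or_point: float
    or_low: float
    or_high: float
    dispersion: float | None = None

    @classmethod
    def from_beta_se(
        cls,
        method: str,
        k: int,
        beta: float,
        se: float,
        dist: str = "norm",
        df: int | None = None,
        dispersion: float | None = None,
    ) -> "MREstimate":
        if method not in METHOD_LABELS:
            raise MRKitError(f"unknown method label {method!r}")
        # A degenerate zero SE (e.g. exactly proportional data give zero
        # residual dispersion) yields an infinite test statistic.
        zstat = np.inf if se == 0 and beta != 0 else (0.0 if se == 0 else abs(beta) / se)
        if dist == "norm":
            z = stats.norm.ppf(0.975)
            pval = 2.0 * stats.norm.sf(zstat)
        elif dist == "t":
            z = stats.t.ppf(0.975, df)
            pval = 2.0 * stats.t.sf(zstat, df)
        else:  # pragma: no cover
            raise MRKitError(f"unknown reference distribution {dist!r}")
        return cls(
            method=method,
            k=k,
            beta=float(beta),
            se=float(se),
            pval=float(pval),
            or_point=float(np.exp(beta)),
            or_low=float(np.exp(beta - z * se)),
            or_high=float(np.exp(beta + z * se)),
            dispersion=dispersion,
        )


@dataclass(frozen=True)
class EggerEstimate:
    """MR-Egger slope plus the pleiotropy intercept test."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_p: float


def wald_ratio(pair: HarmonizedPair, order: str = "first") -> RatioEstimate:
    """Per-SNP causal estimate beta_out/beta_exp with Delta-method SE.

    First order: se_out/|beta_exp|.  Second order adds the exposure
    uncertainty term beta_out^2 * se_exp^2 / beta_exp^4.
    """
    if pair.beta_exp == 0:
        raise DegenerateInstrumentError(f"{pair.snp_id}: beta_exp is zero")
    ratio = pair.beta_out / pair.beta_exp
    if order == "first":
        se = pair.se_out / abs(pair.beta_exp)
    elif order == "second":
        se = np.sqrt(
            pair.se_out**2 / pair.beta_exp**2
            + pair.beta_out**2 * pair.se_exp**2 / pair.beta_exp**4
        )
    else:
        raise MRKitError(f"order must be 'first' or 'second', got {order!r}")
    return RatioEstimate(snp_id=pair.snp_id, ratio=float(ratio), se_ratio=float(se), order=order)


def _ratio_arrays(instruments: InstrumentSet, order: str = "first"):
    est = [wald_ratio(p, order) for p in instruments.pairs]
    return (
        np.array([e.ratio for e in est]),
        np.array([e.se_ratio for e in est]),
    )


def ratio_statistics(instruments: InstrumentSet, order: str = "first"):
    """Shared IVW pooling quantities: (ratios, ratio SEs, weights, pooled
    beta, fixed-effects SE, Cochran's Q, dispersion sigma).

    This is the single source of truth for Q and sigma: the heterogeneity
    diagnostics and the multiplicative random-effects SE both come from
    here.  ``sigma`` is None when k == 1.
    """
    ratio, se_r = _ratio_arrays(instruments, order)
    w = se_r**-2.0
    beta = float(np.sum(w * ratio) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (ratio - beta) ** 2))
    k = instruments.k
    sigma = float(np.sqrt(q / (k - 1))) if k > 1 else None
    return ratio, se_r, w, beta, se_fixed, q, sigma


def ivw(
    instruments: InstrumentSet,
    mode: str = "multiplicative_random",
    order: str = "first",
) -> MREstimate:
    """Inverse-variance-weighted pooled estimate.

    ``mode="fixed"`` uses the fixed-effects SE; ``"multiplicative_random"``
    multiplies it by sigma = sqrt(Q/(k-1)) with no lower cap (falls back to
    fixed effects at k = 1).  Point estimates are identical in both modes.
    """
    if mode not in ("fixed", "multiplicative_random"):
        raise MRKitError(f"unknown IVW mode {mode!r}")
    _, _, _, beta, se_fixed, _, sigma = ratio_statistics(instruments, order)
    if mode == "multiplicative_random" and sigma is not None:
        return MREstimate.from_beta_se(
            "ivw_mre", instruments.k, beta, se_fixed * sigma, dispersion=sigma
        )
    label = "ivw_fe" if mode == "fixed" else "ivw_mre"
    return MREstimate.from_beta_se(label, instruments.k, beta, se_fixed, dispersion=sigma)


def _ml_nll_grad(params, bx, sx2, by, sy2):
    theta, xi = params[0], params[1:]
    rx = bx - xi
    ry = by - theta * xi
    nll = 0.5 * np.sum(rx**2 / sx2) + 0.5 * np.sum(ry**2 / sy2)
    g_theta = -np.sum(xi * ry / sy2)
    g_xi = -rx / sx2 - theta * ry / sy2
    return nll, np.concatenate(([g_theta], g_xi))


def max_likelihood(instruments: InstrumentSet) -> MREstimate:
    """Maximum-likelihood causal estimate under a bivariate normal model.

    Per SNP i the observed beta_exp_i ~ N(xi_i, se_exp_i^2) and
    beta_out_i ~ N(theta * xi_i, se_out_i^2); the likelihood is maximized
    jointly over (theta, xi_1..xi_k) by quasi-Newton with analytic
    gradient, initialized at the fixed-effects IVW solution.  The SE of
    theta comes from the observed information matrix.
    """
    bx, sx, by, sy = instruments.arrays()
    sx2, sy2 = sx**2, sy**2
    _, _, _, beta0, _, _, _ = ratio_statistics(instruments)
    x0 = np.concatenate(([beta0], bx))
    res = optimize.minimize(
        _ml_nll_grad,
        x0,
        args=(bx, sx2, by, sy2),
        jac=True,
        method="BFGS",
        options={"gtol": 1e-10, "maxiter": 2000},
    )
    # Newton polish with the analytic block Hessian: BFGS alone stalls on
    # badly scaled problems (tiny exposure SEs inflate the weights), so
    # convergence is judged by the affine-invariant Newton decrement
    # g' H^-1 g rather than a raw gradient norm.
    x = res.x
    decrement = np.inf
    for _ in range(100):
        nll, g = _ml_nll_grad(x, bx, sx2, by, sy2)
        theta, xi = x[0], x[1:]
        h_tt = np.sum(xi**2 / sy2)
        h_tx = (2.0 * theta * xi - by) / sy2
        h_xx = 1.0 / sx2 + theta**2 / sy2
        schur = h_tt - np.sum(h_tx**2 / h_xx)
        d_t = (-g[0] + np.sum(h_tx * g[1:] / h_xx)) / schur
        d_x = (-g[1:] - h_tx * d_t) / h_xx
        decrement = float(-(g[0] * d_t + np.sum(g[1:] * d_x)))
        if decrement < 1e-12 * (1.0 + abs(nll)):
            break
        x = x + np.concatenate(([d_t], d_x))
    if not decrement < 1e-6 * (1.0 + abs(nll)):
        raise ConvergenceError(
            "ML optimizer did not converge", grad_norm=float(np.max(np.abs(g)))
        )
    theta, xi = float(x[0]), x[1:]
    # Observed information: [[sum xi^2/sy2, row], [col, diag(1/sx2 + theta^2/sy2)]].
    h_tt = np.sum(xi**2 / sy2)
    h_tx = (2.0 * theta * xi - by) / sy2
    h_xx = 1.0 / sx2 + theta**2 / sy2
    # Schur complement of the diagonal xi block gives Var(theta) directly.
    var_theta = 1.0 / (h_tt - np.sum(h_tx**2 / h_xx))
    if not var_theta > 0:
        raise ConvergenceError("observed information not positive definite")
    return MREstimate.from_beta_se(
        "max_likelihood", instruments.k, theta, float(np.sqrt(var_theta))
    )


def _weighted_median_rows(ratios: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise inverse-variance weighted median with linear interpolation
    across cumulative weight midpoints (vectorized over rows)."""
    order = np.argsort(ratios, axis=-1)
    r = np.take_along_axis(ratios, order, axis=-1)
    w = np.take_along_axis(weights, order, axis=-1)
    w = w / np.sum(w, axis=-1, keepdims=True)
    s = np.cumsum(w, axis=-1) - w / 2.0
    # index of the first midpoint >= 0.5 in each row
    idx = np.sum(s < 0.5, axis=-1)
    idx = np.clip(idx, 1, r.shape[-1] - 1)
    rows = np.arange(r.shape[0]) if r.ndim == 2 else None
    if r.ndim == 1:
        if s[0] >= 0.5:
            return r[0]
        lo, hi = int(idx) - 1, int(idx)
        return r[lo] + (r[hi] - r[lo]) * (0.5 - s[lo]) / (s[hi] - s[lo])
    lo = idx - 1
    s_lo = s[rows, lo]
    s_hi = s[rows, idx]
    r_lo = r[rows, lo]
    r_hi = r[rows, idx]
    out = r_lo + (r_hi - r_lo) * (0.5 - s_lo) / (s_hi - s_lo)
    first = s[:, 0] >= 0.5
    out[first] = r[first, 0]
    return out


def weighted_median(
    instruments: InstrumentSet,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    The estimate interpolates the inverse-variance weighted median of the
    per-SNP ratios.  The SE resamples beta_exp and beta_out from their
    normal sampling distributions ``n_boot`` times (seed-controlled) and
    takes the standard deviation of the re-estimated medians.
    """
    if instruments.k < 3:
        raise InsufficientInstrumentsError(
            f"weighted median needs k >= 3, got k = {instruments.k}"
        )
    if n_boot < 100:
        raise MRKitError(f"n_boot must be >= 100, got {n_boot}")
    if seed is None:
        raise MRKitError("weighted_median requires an explicit seed")
    ratio, se_r = _ratio_arrays(instruments)
    w = se_r**-2.0
    point = float(_weighted_median_rows(ratio, w))

    bx, sx, by, sy = instruments.arrays()
    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, instruments.k))
    by_b = rng.normal(by, sy, size=(n_boot, instruments.k))
    ratio_b = by_b / bx_b
    w_b = (bx_b / sy) ** 2  # inverse squared first-order ratio SE
    boots = _weighted_median_rows(ratio_b, w_b)
    se = float(np.std(boots, ddof=1))
    return MREstimate.from_beta_se("weighted_median", instruments.k, point, se)


def egger(instruments: InstrumentSet) -> EggerEstimate:
    """MR-Egger regression: pleiotropy-robust slope and intercept test.

    SNPs are oriented so every exposure beta is positive, then beta_out is
    regressed on beta_exp with an intercept, weights 1/se_out^2.  The
    coefficient covariance carries the unconstrained residual scale (which
    may shrink below 1); inference uses t with k-2 df.
    """
    if instruments.k < 3:
        raise InsufficientInstrumentsError(
            f"MR-Egger needs k >= 3, got k = {instruments.k}"
        )
    bx, _, by, sy = instruments.arrays()
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    fit = sm.WLS(by, sm.add_constant(bx), weights=sy**-2.0).fit()
    intercept, slope = fit.params
    se_int, se_slope = fit.bse
    df = instruments.k - 2
    slope_est = MREstimate.from_beta_se(
        "egger_slope", instruments.k, float(slope), float(se_slope), dist="t", df=df
    )
    return EggerEstimate(
        slope=slope_est,
        intercept=float(intercept),
        intercept_se=float(se_int),
        intercept_p=float(2.0 * stats.t.sf(abs(intercept / se_int), df)),
    )
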