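"""Causal estimators and diagnostics for two-sample Mendelian randomization.

Given harmonized per-SNP effect pairs (gamma_j, se_gamma_j) on the exposure
and (Gamma_j, se_Gamma_j) on the outcome, every estimator here targets the
causal effect b of a one-unit (one-year) increase in the exposure:

- ``wald_ratio``      per-SNP ratio Gamma_j / gamma_j with first-order SE
- ``ivw``             inverse-variance-weighted regression through the origin,
                      fixed or multiplicative random-effects
- ``egger``           weighted regression with an intercept; the intercept
                      tests directional pleiotropy, and I2_GX quantifies how
                      well the no-measurement-error (NOME) assumption holds
- ``weighted_median`` consistent when >50% of the weight is on valid SNPs
- ``weighted_mode``   consistent when the largest cluster of SNPs is valid
- ``mr_raps``         robust adjusted profile score with Huber loss and an
                      overdispersion variance component tau^2
- ``leave_one_out``   per-SNP influence scan on the random-effects IVW

All Wald tests use the normal reference distribution and 95% intervals
b +/- 1.96 se.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .instruments import HarmonizedData, HarmonizedPair

__all__ = [
    "MREstimate",
    "EggerResult",
    "HeterogeneityStats",
    "PerSnpRatio",
    "LeaveOneOutResult",
    "NotComputable",
    "wald_ratio",
    "per_snp_ratios",
    "ivw",
    "egger",
    "weighted_median",
    "weighted_mode",
    "mr_raps",
    "leave_one_out",
]

Z95 = 1.96  # normal 95% multiplier used throughout


@dataclass
class MREstimate:
    """One estimator's causal-effect result."""

    method: str
    b: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    extras: dict = field(default_factory=dict)


@dataclass
class HeterogeneityStats:
    """Cochran's Q over per-SNP Wald ratios."""

    q: float
    df: int
    pval: float


@dataclass
class EggerResult:
    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_p: float
    i2_gx: float


@dataclass
class PerSnpRatio:
    snp_id: str
    ratio: float
    ratio_se: float
    weight: float


@dataclass
class LeaveOneOutResult:
    snp_ids: list[str]
    estimates: list[MREstimate]
    flags: list[bool]
    full: MREstimate


@dataclass
class NotComputable:
    """Structured marker for a battery member that cannot be computed."""

    method: str
    reason: str


class DegenerateInstrumentError(ValueError):
    pass


def _zp(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def _estimate(method: str, b: float, se: float, n_snp: int, **extras) -> MREstimate:
    return MREstimate(
        method=method,
        b=float(b),
        se=float(se),
        ci_low=float(b - Z95 * se),
        ci_high=float(b + Z95 * se),
        pval=_zp(b / se) if se > 0 else (1.0 if b == 0 else 0.0),
        n_snp=int(n_snp),
        extras=extras,
    )


def wald_ratio(pair: HarmonizedPair) -> PerSnpRatio:
    """Single-SNP causal estimate: ratio = Gamma/gamma, SE = se_Gamma/|gamma|."""
    if pair.beta_exp == 0:
        raise DegenerateInstrumentError(f"zero exposure effect for {pair.snp_id}")
    ratio = pair.beta_out / pair.beta_exp
    ratio_se = pair.se_out / abs(pair.beta_exp)
    return PerSnpRatio(
        snp_id=pair.snp_id, ratio=ratio, ratio_se=ratio_se, weight=1.0 / ratio_se**2
    )


def per_snp_ratios(data: HarmonizedData) -> list[PerSnpRatio]:
    return [wald_ratio(p) for p in data.pairs]


def _ivw_arrays(bx, sx, by, sy, model: str = "multiplicative_re"):
    """IVW slope, SE and Cochran's Q from raw arrays.

    b = sum(w gamma Gamma) / sum(w gamma^2) with w = 1/se_Gamma^2 (weighted
    regression through the origin).  Fixed SE is (sum w gamma^2)^{-1/2}; the
    multiplicative random-effects SE multiplies it by max(1, sqrt(Q/(n-1))).
    Q is computed on the per-SNP ratios with first-order weights.
    """
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.asarray(sy, dtype=float)
    n = bx.size
    if np.all(bx == 0):
        raise DegenerateInstrumentError("all exposure effects are zero")
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    b = float(np.sum(w * bx * by)) / denom
    se_fixed = denom**-0.5
    if n < 2:
        return b, se_fixed, float("nan"), 0
    ratios = by / bx
    wq = bx**2 / sy**2  # 1 / ratio_se^2, first order
    q = float(np.sum(wq * (ratios - b) ** 2))
    if model == "fixed":
        se = se_fixed
    elif model == "multiplicative_re":
        se = se_fixed * max(1.0, math.sqrt(q / (n - 1)))
    else:
        raise ValueError(f"unknown IVW model: {model}")
    return b, se, q, n - 1


def ivw(
    data: HarmonizedData, model: str = "multiplicative_re"
) -> tuple[MREstimate, Optional[HeterogeneityStats]]:
    """Inverse-variance-weighted estimate with heterogeneity statistics.

    With a single SNP the estimate degrades to the Wald ratio and no
    heterogeneity statistic is returned.
    """
    bx, sx, by, sy = data.arrays()
    if bx.size == 0:
        raise DegenerateInstrumentError("no SNPs")
    label = "ivw_re" if model == "multiplicative_re" else "ivw_fixed"
    if bx.size == 1:
        r = wald_ratio(data.pairs[0])
        return _estimate("wald", r.ratio, r.ratio_se, 1), None
    b, se, q, df = _ivw_arrays(bx, sx, by, sy, model=model)
    het = HeterogeneityStats(q=q, df=df, pval=float(stats.chi2.sf(q, df)))
    return _estimate(label, b, se, bx.size), het


def _weighted_lsq_line(x, y, w):
    """Weighted least squares y = a + b x; returns (a, b, cov_unscaled, rss_w)."""
    sw = np.sum(w)
    sx = np.sum(w * x)
    sy_ = np.sum(w * y)
    sxx = np.sum(w * x * x)
    sxy = np.sum(w * x * y)
    det = sw * sxx - sx**2
    b = (sw * sxy - sx * sy_) / det
    a = (sy_ - b * sx) / sw
    resid = y - a - b * x
    rss_w = float(np.sum(w * resid**2))
    # unscaled covariance of (a, b): inverse of the weighted normal matrix
    cov = np.array([[sxx, -sx], [-sx, sw]]) / det
    return float(a), float(b), cov, rss_w


def egger(data: HarmonizedData) -> EggerResult | NotComputable:
    """MR-Egger regression: slope is the causal estimate, the intercept tests
    directional pleiotropy (valid under the InSIDE assumption).

    Pairs are oriented so all exposure effects are non-negative before
    fitting (the stored data are not mutated).  Standard errors use
    multiplicative residual scaling floored at 1.  I2_GX near 1 indicates the
    NOME assumption is adequate; low values mean the slope suffers regression
    dilution.
    """
    bx, sx, by, sy = data.arrays()
    n = bx.size
    if n < 3:
        return NotComputable("egger", f"needs >= 3 SNPs, have {n}")
    sign = np.where(bx < 0, -1.0, 1.0)
    x = bx * sign
    y = by * sign
    # I2_GX: heterogeneity of the exposure effects relative to their SEs
    wq = 1.0 / sx**2
    gbar = float(np.sum(wq * x) / np.sum(wq))
    q_gx = float(np.sum((x - gbar) ** 2 * wq))
    i2 = max(0.0, (q_gx - (n - 1)) / q_gx) if q_gx > 0 else 0.0
    w = 1.0 / sy**2
    if np.ptp(x) == 0:
        # slope and intercept are not separable without spread in x
        slope = MREstimate("egger", float("nan"), float("nan"), float("nan"),
                           float("nan"), float("nan"), n, {"degenerate": True})
        return EggerResult(slope=slope, intercept=float("nan"),
                           intercept_se=float("nan"), intercept_p=float("nan"),
                           i2_gx=i2)
    a, b, cov, rss_w = _weighted_lsq_line(x, y, w)
    scale = max(1.0, math.sqrt(rss_w / (n - 2)))
    se_a = scale * math.sqrt(cov[0, 0])
    se_b = scale * math.sqrt(cov[1, 1])
    return EggerResult(
        slope=_estimate("egger", b, se_b, n),
        intercept=a,
        intercept_se=se_a,
        intercept_p=_zp(a / se_a),
        i2_gx=i2,
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median with linear interpolation at cumulative weight 0.5."""
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    cum = np.cumsum(w) - 0.5 * w
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    k = int(np.searchsorted(cum, 0.5))
    # cum[k-1] < 0.5 <= cum[k]
    if cum[k] == cum[k - 1]:
        return float(r[k])
    frac = (0.5 - cum[k - 1]) / (cum[k] - cum[k - 1])
    return float(r[k - 1] + frac * (r[k] - r[k - 1]))


def _parametric_bootstrap_se(point_fn, bx, sx, by, sy, n_boot, seed):
    rng = np.random.default_rng(seed)
    n = bx.size
    ests = np.empty(n_boot)
    for i in range(n_boot):
        bxs = bx + sx * rng.standard_normal(n)
        bys = by + sy * rng.standard_normal(n)
        ests[i] = point_fn(bxs, bys)
    return float(np.std(ests, ddof=1))


def weighted_median(
    data: HarmonizedData, n_boot: int = 1000, seed: Optional[int] = None
) -> MREstimate | NotComputable:
    """Weighted-median estimate; consistent when valid SNPs carry >50% of the
    inverse-variance weight.  SE from a parametric bootstrap resampling the
    exposure and outcome effects from their normal sampling distributions.
    """
    bx, sx, by, sy = data.arrays()
    n = bx.size
    if n < 3:
        return NotComputable("weighted_median", f"needs >= 3 SNPs, have {n}")

    def point(bxs, bys):
        ratios = bys / bxs
        w = bxs**2 / sy**2
        return _weighted_median_point(ratios, w)

    b = point(bx, by)
    se = _parametric_bootstrap_se(point, bx, sx, by, sy, n_boot, seed)
    return _estimate("weighted_median", b, se, n)


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    n = ratios.size
    s = float(np.std(ratios, ddof=1))
    iqr = float(np.subtract(*np.percentile(ratios, [75, 25])))
    spread = min(s, iqr / 1.34) if iqr > 0 else s
    return phi * 0.9 * spread * n ** (-1.0 / 5.0)


def _weighted_mode_point(
    ratios: np.ndarray, weights: np.ndarray, phi: float, n_grid: int = 512
):
    """Argmax of the weighted Gaussian-kernel density of the ratios.

    Ties (several grid maxima) break toward the smaller |b|; the multimodal
    flag records whether the maxima were non-adjacent grid points.
    """
    h = _mode_bandwidth(ratios, phi)
    if h <= 0 or not np.isfinite(h):
        return float(ratios[0]), False
    lo = float(np.min(ratios)) - 3 * h
    hi = float(np.max(ratios)) + 3 * h
    grid = np.linspace(lo, hi, n_grid)
    w = weights / np.sum(weights)
    dens = np.sum(
        w[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2),
        axis=1,
    )
    dmax = float(np.max(dens))
    cand = np.flatnonzero(dens >= dmax * (1.0 - 1e-9))
    multimodal = bool(np.any(np.diff(cand) > 1))
    vals = grid[cand]
    best = vals[np.lexsort((vals, np.abs(vals)))][0]
    return float(best), multimodal


def weighted_mode(
    data: HarmonizedData,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> MREstimate | NotComputable:
    """Mode-based estimate: the peak of a kernel-smoothed weighted density of
    the per-SNP ratios, consistent when the largest homogeneous cluster of
    SNPs is valid.  Bandwidth h = phi * 0.9 min(sd, IQR/1.34) n^{-1/5}.
    """
    bx, sx, by, sy = data.arrays()
    n = bx.size
    if n < 3:
        return NotComputable("weighted_mode", f"needs >= 3 SNPs, have {n}")

    def point(bxs, bys):
        ratios = bys / bxs
        w = bxs**2 / sy**2
        return _weighted_mode_point(ratios, w, phi)[0]

    ratios = by / bx
    w = bx**2 / sy**2
    b, multimodal = _weighted_mode_point(ratios, w, phi)
    se = _parametric_bootstrap_se(point, bx, sx, by, sy, n_boot, seed)
    est = _estimate("weighted_mode", b, se, n, multimodal=multimodal)
    return est


# Huber score constants: E[psi(Z)^2] and E[psi'(Z)] for Z ~ N(0,1)
def _huber_moments(k: float) -> tuple[float, float]:
    phi_k = stats.norm.pdf(k)
    cdf_k = stats.norm.cdf(k)
    tail = 1.0 - cdf_k
    e_psi2 = (2 * cdf_k - 1.0) - 2 * k * phi_k + 2 * k**2 * tail
    e_dpsi = 2 * cdf_k - 1.0
    return float(e_psi2), float(e_dpsi)


def mr_raps(
    data: HarmonizedData,
    k_huber: float = 1.345,
    overdispersion: bool = True,
    seed: Optional[int] = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> MREstimate | NotComputable:
    """Robust adjusted profile score estimate.

    Solves the profile estimating equations for (b, tau^2) where the
    standardized residuals are

        t_j(b, tau^2) = (Gamma_j - b gamma_j) / sqrt(se_Gamma_j^2
                          + b^2 se_gamma_j^2 + tau^2)

    b is the root of  sum psi(t_j) d t_j / d b = 0  with psi the Huber score
    (threshold ``k_huber``); tau^2 solves the second-moment equation
    sum (psi(t_j)^2 - E[psi(Z)^2]) = 0, floored at 0.  The variance is the
    sandwich of the estimating equations.  On bracketing failure the solver
    falls back to a dense grid search on b.
    """
    bx, sx, by, sy = data.arrays()
    n = bx.size
    if n < 3:
        return NotComputable("raps", f"needs >= 3 SNPs, have {n}")
    e_psi2, _ = _huber_moments(k_huber)

    def psi(t):
        return np.clip(t, -k_huber, k_huber)

    def tvals(b, tau2):
        s2 = sy**2 + b**2 * sx**2 + tau2
        return (by - b * bx) / np.sqrt(s2), s2

    def score_b(b, tau2):
        t, s2 = tvals(b, tau2)
        s = np.sqrt(s2)
        # d t_j / d b = -gamma_j / s_j - t_j * b * se_gamma_j^2 / s_j^2
        dt_db = -bx / s - t * b * sx**2 / s2
        return float(np.sum(psi(t) * dt_db))

    def moment_tau(tau2, b):
        t, _ = tvals(b, tau2)
        return float(np.sum(psi(t) ** 2) - n * e_psi2)

    from scipy.optimize import brentq

    # start at the IVW slope
    b0, se0, _, _ = _ivw_arrays(bx, sx, by, sy, model="multiplicative_re")
    tau2 = 0.0
    b = b0

    def solve_b(tau2, b_guess):
        lo, hi = b_guess - 10 * max(se0, 1e-6), b_guess + 10 * max(se0, 1e-6)
        flo, fhi = score_b(lo, tau2), score_b(hi, tau2)
        tries = 0
        while flo * fhi > 0 and tries < 30:
            span = hi - lo
            lo -= span
            hi += span
            flo, fhi = score_b(lo, tau2), score_b(hi, tau2)
            tries += 1
        if flo * fhi > 0:
            return None
        return float(brentq(lambda v: score_b(v, tau2), lo, hi, xtol=tol))

    converged = False
    for _ in range(max_iter):
        b_new = solve_b(tau2, b)
        if b_new is None:
            # grid-search fallback over a wide bracket
            grid = np.linspace(b - 50 * se0, b + 50 * se0, 2001)
            vals = np.array([abs(score_b(g, tau2)) for g in grid])
            b_new = float(grid[int(np.argmin(vals))])
        tau2_new = tau2
        if overdispersion:
            if moment_tau(0.0, b_new) <= 0:
                tau2_new = 0.0
            else:
                hi = max(np.var(by - b_new * bx), 1e-12)
                tries = 0
                while moment_tau(hi, b_new) > 0 and tries < 60:
                    hi *= 2
                    tries += 1
                if moment_tau(hi, b_new) > 0:
                    return NotComputable("raps", "overdispersion moment equation has no root")
                tau2_new = float(brentq(lambda v: moment_tau(v, b_new), 0.0, hi, xtol=tol))
        if abs(b_new - b) < tol * max(1.0, abs(b)) and abs(tau2_new - tau2) < tol:
            b, tau2 = b_new, tau2_new
            converged = True
            break
        b, tau2 = b_new, tau2_new
    if not converged and abs(score_b(b, tau2)) > 1e-4:
        return NotComputable("raps", f"no convergence (score {score_b(b, tau2):.3g})")

    # sandwich variance; tau^2 treated as a nuisance when estimated off the floor
    free_tau = overdispersion and tau2 > 0

    def g_j(theta):
        bb = theta[0]
        tt = theta[1] if free_tau else 0.0
        t, s2 = tvals(bb, tt)
        s = np.sqrt(s2)
        dt_db = -bx / s - t * bb * sx**2 / s2
        g1 = psi(t) * dt_db
        if not free_tau:
            return g1[None, :].T
        g2 = psi(t) ** 2 - e_psi2
        return np.column_stack([g1, g2])

    theta = np.array([b, tau2]) if free_tau else np.array([b])
    G = g_j(theta)
    B = G.T @ G
    p = theta.size
    A = np.zeros((p, p))
    for c in range(p):
        h = 1e-6 * max(1.0, abs(theta[c]))
        tp = theta.copy()
        tp[c] += h
        tm = theta.copy()
        tm[c] -= h
        A[:, c] = (g_j(tp).sum(axis=0) - g_j(tm).sum(axis=0)) / (2 * h)
    try:
        Ainv = np.linalg.inv(A)
        V = Ainv @ B @ Ainv.T
        se = math.sqrt(max(V[0, 0], 0.0))
    except np.linalg.LinAlgError:
        return NotComputable("raps", "singular sandwich matrix")
    return _estimate("raps", b, se, n, tau2=float(tau2), converged=converged)


def leave_one_out(data: HarmonizedData) -> LeaveOneOutResult | NotComputable:
    """Random-effects IVW re-estimated with each SNP excluded in turn.

    A subset is flagged when its estimate changes sign or crosses the 0.05
    significance boundary relative to the full-data estimate.
    """
    n = len(data.pairs)
    if n < 3:
        return NotComputable("leave_one_out", f"needs >= 3 SNPs, have {n}")
    full, _ = ivw(data, model="multiplicative_re")
    ids = []
    ests = []
    flags = []
    for j in range(n):
        sub = data.subset(np.array([i for i in range(n) if i != j]))
        est, _ = ivw(sub, model="multiplicative_re")
        ids.append(data.pairs[j].snp_id)
        ests.append(est)
        sign_change = (est.b > 0) != (full.b > 0) and est.b != 0 and full.b != 0
        signif_change = (est.pval < 0.05) != (full.pval < 0.05)
        flags.append(bool(sign_change or signif_change))
    return LeaveOneOutResult(snp_ids=ids, estimates=ests, flags=flags, full=full)
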