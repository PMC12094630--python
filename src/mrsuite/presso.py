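"""MR-PRESSO: simulation-based pleiotropy residual sum and outlier tests.

Three nested tests on harmonized two-sample data:

1.  **Global test** — the observed leave-one-out weighted residual sum of
    squares (RSS_obs) is compared with its distribution under a no-pleiotropy
    null obtained by parametric simulation of the summary statistics.
2.  **Outlier test** — each SNP's observed residual is compared with its own
    simulated null distribution; calls are Bonferroni-corrected across SNPs.
3.  **Distortion test** — whether removing the flagged outliers changes the
    IVW estimate more than removing random SNP subsets of the same size.

The outlier-corrected random-effects IVW estimate is the analysis pipeline's
primary endpoint.  Outlier removal is one-shot (no iterative re-testing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .estimators import MREstimate, NotComputable, ivw
from .instruments import HarmonizedData

__all__ = ["PressoConfig", "PressoResult", "presso_global", "presso_outliers",
           "presso_distortion", "run_presso"]


@dataclass
class PressoConfig:
    n_sim: int = 10000
    outlier_signif: float = 0.05  # Bonferroni-adjusted across SNPs
    global_signif: float = 0.05
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n_sim < 100:
            raise ValueError("n_sim must be >= 100")


@dataclass
class PressoResult:
    rss_obs: float
    global_p: float
    outlier_indices: list[int]
    outlier_snp_ids: list[str]
    per_snp_p: np.ndarray
    distortion_p: Optional[float]
    estimate_raw: MREstimate
    estimate_corrected: MREstimate
    n_outliers: int
    n_sim: int
    seed: Optional[int]
    residuals_obs: np.ndarray = field(default=None, repr=False)


def _loo_slopes(bx, by, w):
    """Leave-one-out IVW slopes b_{-j}, vectorized.

    Works on 1-D arrays or on (n_sim, n_snp) matrices (row-wise).
    """
    num = np.sum(w * bx * by, axis=-1, keepdims=True) - w * bx * by
    den = np.sum(w * bx**2, axis=-1, keepdims=True) - w * bx**2
    return num / den


def presso_global(data: HarmonizedData, cfg: PressoConfig):
    """Global heterogeneity test.

    Observed statistic: RSS_obs = sum_j (Gamma_j - b_{-j} gamma_j)^2 / se_Gamma_j^2
    with b_{-j} the leave-one-out IVW slope.  The null distribution simulates
    gamma*_j ~ N(gamma_j, se_gamma_j) and Gamma*_j ~ N(b_{-j} gamma_j,
    se_Gamma_j) and recomputes the same statistic (including the simulated
    leave-one-out slopes).  Returns (rss_obs, global_p, residuals_obs,
    simulated per-SNP residual matrix).
    """
    bx, sx, by, sy = data.arrays()
    n = bx.size
    if n < 4:
        return NotComputable("presso_global", f"needs >= 4 SNPs, have {n}")
    w = 1.0 / sy**2
    b_loo = _loo_slopes(bx, by, w)
    resid_obs = w * (by - b_loo * bx) ** 2
    rss_obs = float(np.sum(resid_obs))

    rng = np.random.default_rng(cfg.seed)
    bx_sim = bx + sx * rng.standard_normal((cfg.n_sim, n))
    by_sim = b_loo * bx + sy * rng.standard_normal((cfg.n_sim, n))
    b_loo_sim = _loo_slopes(bx_sim, by_sim, w)
    resid_sim = w * (by_sim - b_loo_sim * bx_sim) ** 2
    rss_sim = np.sum(resid_sim, axis=1)
    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (cfg.n_sim + 1))
    return rss_obs, global_p, resid_obs, resid_sim


def presso_outliers(resid_obs: np.ndarray, resid_sim: np.ndarray, cfg: PressoConfig):
    """Per-SNP empirical outlier test with Bonferroni-corrected threshold."""
    n = resid_obs.size
    per_snp_p = (1 + np.sum(resid_sim >= resid_obs[None, :], axis=0)) / (cfg.n_sim + 1)
    threshold = cfg.outlier_signif / n
    outliers = sorted(int(j) for j in np.flatnonzero(per_snp_p < threshold))
    return outliers, per_snp_p


def presso_distortion(
    estimate_raw: MREstimate,
    estimate_corrected: MREstimate,
    data: HarmonizedData,
    n_outliers: int,
    cfg: PressoConfig,
) -> Optional[float]:
    """Distortion test: is the relative change in the IVW estimate after
    outlier removal larger than under random same-size removals?
    Two-sided empirical p; None when there is no outlier.
    """
    if n_outliers < 1:
        return None
    stat = (estimate_corrected.b - estimate_raw.b) / abs(estimate_raw.b)
    bx, sx, by, sy = data.arrays()
    n = bx.size
    rng = np.random.default_rng(None if cfg.seed is None else cfg.seed + 1)
    w = 1.0 / sy**2
    stats_null = np.empty(cfg.n_sim)
    for i in range(cfg.n_sim):
        drop = rng.choice(n, size=n_outliers, replace=False)
        keep = np.setdiff1d(np.arange(n), drop, assume_unique=True)
        b_sub = np.sum(w[keep] * bx[keep] * by[keep]) / np.sum(w[keep] * bx[keep] ** 2)
        stats_null[i] = (b_sub - estimate_raw.b) / abs(estimate_raw.b)
    p = float((1 + np.sum(np.abs(stats_null) >= abs(stat))) / (cfg.n_sim + 1))
    return p


def run_presso(data: HarmonizedData, cfg: PressoConfig) -> PressoResult | NotComputable:
    """Compose global, outlier and distortion tests.

    If the global test is non-significant no outlier is removed and the
    corrected estimate equals the raw one.  The corrected estimate is the
    random-effects IVW on the non-outlier subset.
    """
    est_raw, _ = ivw(data, model="multiplicative_re")
    out = presso_global(data, cfg)
    if isinstance(out, NotComputable):
        return out
    rss_obs, global_p, resid_obs, resid_sim = out
    if global_p >= cfg.global_signif:
        outliers: list[int] = []
        per_snp_p = (1 + np.sum(resid_sim >= resid_obs[None, :], axis=0)) / (cfg.n_sim + 1)
    else:
        outliers, per_snp_p = presso_outliers(resid_obs, resid_sim, cfg)
    if outliers:
        keep = np.setdiff1d(np.arange(len(data.pairs)), np.array(outliers))
        est_corr, _ = ivw(data.subset(keep), model="multiplicative_re")
    else:
        est_corr = est_raw
    distortion_p = presso_distortion(est_raw, est_corr, data, len(outliers), cfg)
    return PressoResult(
        rss_obs=rss_obs,
        global_p=global_p,
        outlier_indices=outliers,
        outlier_snp_ids=[data.pairs[j].snp_id for j in outliers],
        per_snp_p=np.asarray(per_snp_p),
        distortion_p=distortion_p,
        estimate_raw=est_raw,
        estimate_corrected=est_corr,
        n_outliers=len(outliers),
        n_sim=cfg.n_sim,
        seed=cfg.seed,
        residuals_obs=resid_obs,
    )
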