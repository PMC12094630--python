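"""Multivariable Mendelian randomization (two exposures).

Regresses the per-SNP outcome effects jointly on the genetic effects for the
primary exposure (pubertal timing) and an adjustment exposure (BMI), with no
intercept and inverse-variance weights; the primary coefficient is the direct
causal effect conditional on the adjustment exposure.  Used to probe whether
body-weight-related pleiotropy drives the univariable estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import math

import numpy as np

from .estimators import MREstimate, NotComputable, _estimate
from .instruments import InstrumentSet, _orient
from .summary_io import GwasTable

__all__ = ["MultiHarmonizedData", "harmonize_multi", "mvmr_ivw"]

COND_LIMIT = 1e8


@dataclass
class MultiHarmonizedData:
    """Per-SNP effects for two exposures and one outcome, one orientation."""

    snp_ids: list[str]
    beta_exp_primary: np.ndarray
    se_exp_primary: np.ndarray
    beta_exp_adjust: np.ndarray
    se_exp_adjust: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    primary_name: str = ""
    adjust_name: str = ""
    outcome_name: str = ""
    n_requested: int = 0
    n_dropped_adjust: int = 0
    n_dropped_outcome: int = 0

    def __len__(self) -> int:
        return len(self.snp_ids)


def _lookup_aligned(exp_rec, table_lookup):
    """Find a record for exp_rec's SNP in another table, aligned onto the
    exposure effect allele; returns (beta, se) or None."""
    rec = table_lookup.get(exp_rec.snp_id)
    if rec is None:
        return None
    orientation = _orient(exp_rec, rec)
    if orientation is None:
        return None
    beta = rec.beta if orientation == "same" else -rec.beta
    return beta, rec.se


def harmonize_multi(
    instruments: InstrumentSet,
    adjust_gwas: GwasTable,
    outcome: GwasTable,
    palindromic_policy: str = "drop_ambiguous",
) -> MultiHarmonizedData | NotComputable:
    """Align adjustment-exposure and outcome effects onto the instrument
    orientation; SNPs missing from (or irreconcilable with) either source
    are dropped and counted.

    Palindromic handling is delegated to the pairwise rules only in the sense
    that strand-ambiguous instruments whose partners list the same allele
    pair are accepted as-labelled; instruments whose partners cannot be
    reconciled are dropped.
    """
    adj_lookup = adjust_gwas.by_id()
    out_lookup = outcome.by_id()
    ids, b1, s1, b2, s2, by, sy = [], [], [], [], [], [], []
    n_drop_adj = 0
    n_drop_out = 0
    for rec in instruments.snps:
        adj = _lookup_aligned(rec, adj_lookup)
        if adj is None:
            n_drop_adj += 1
            continue
        out = _lookup_aligned(rec, out_lookup)
        if out is None:
            n_drop_out += 1
            continue
        ids.append(rec.snp_id)
        b1.append(rec.beta)
        s1.append(rec.se)
        b2.append(adj[0])
        s2.append(adj[1])
        by.append(out[0])
        sy.append(out[1])
    if len(ids) < 3:
        return NotComputable("mvmr", f"only {len(ids)} SNPs survive multi-harmonization")
    return MultiHarmonizedData(
        snp_ids=ids,
        beta_exp_primary=np.array(b1),
        se_exp_primary=np.array(s1),
        beta_exp_adjust=np.array(b2),
        se_exp_adjust=np.array(s2),
        beta_out=np.array(by),
        se_out=np.array(sy),
        primary_name=instruments.exposure_name,
        adjust_name=adjust_gwas.trait_name,
        outcome_name=outcome.trait_name,
        n_requested=len(instruments.snps),
        n_dropped_adjust=n_drop_adj,
        n_dropped_outcome=n_drop_out,
    )


def mvmr_ivw(data: MultiHarmonizedData, method_label: str = "ivw_bmicorr") -> MREstimate | NotComputable:
    """Weighted least squares of outcome effects on both exposure-effect
    columns, no intercept, weights 1/se_out^2.

    The reported estimate is the primary-exposure coefficient with
    multiplicative residual scaling floored at 1; the adjustment coefficient
    is carried in ``extras``.  When the adjustment column is identically zero
    the model nests the univariable IVW and that fit is returned (adjustment
    coefficient 0, flagged).  Near-collinear exposure columns yield a
    structured not-computable result with the condition number.
    """
    n = len(data)
    if n < 3:
        return NotComputable("mvmr", f"needs >= 3 SNPs, have {n}")
    w = 1.0 / data.se_out**2
    sw = np.sqrt(w)
    y = data.beta_out * sw

    if np.allclose(data.beta_exp_adjust, 0.0):
        x1 = data.beta_exp_primary * sw
        denom = float(np.sum(x1**2))
        b1 = float(np.sum(x1 * y)) / denom
        rss = float(np.sum((y - b1 * x1) ** 2))
        scale = max(1.0, math.sqrt(rss / (n - 1)))
        se1 = scale / math.sqrt(denom)
        return _estimate(
            method_label, b1, se1, n, b_adjust=0.0, se_adjust=float("nan"),
            adjust_column_zero=True,
        )

    X = np.column_stack([data.beta_exp_primary, data.beta_exp_adjust]) * sw[:, None]
    cond = float(np.linalg.cond(X))
    if not np.isfinite(cond) or cond > COND_LIMIT:
        return NotComputable("mvmr", f"collinear exposure effects (condition number {cond:.3g})")
    xtx = X.T @ X
    coef = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ coef
    rss = float(np.sum(resid**2))
    scale = max(1.0, math.sqrt(rss / (n - 2)))
    cov = scale**2 * np.linalg.inv(xtx)
    b1, b2 = float(coef[0]), float(coef[1])
    se1 = math.sqrt(cov[0, 0])
    se2 = math.sqrt(cov[1, 1])
    return _estimate(
        method_label, b1, se1, n,
        b_adjust=b2, se_adjust=se2, condition_number=cond,
    )
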