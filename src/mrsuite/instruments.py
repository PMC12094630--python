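"""Instrument selection, exposure/outcome harmonization and strength diagnostics.

Instruments are genome-wide-significant SNPs pruned to mutual physical
independence (no two retained SNPs on one chromosome closer than a window,
1 Mb by default).  Harmonization aligns the outcome study's effect estimates
onto the exposure study's effect allele, resolving allele swaps and strand
complements and applying a configurable policy to strand-ambiguous
(palindromic A/T and C/G) variants.  Instrument strength is summarized by
per-SNP F-statistics and the total exposure variance explained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .summary_io import GwasRecord, GwasTable

__all__ = [
    "InstrumentSet",
    "HarmonizedPair",
    "HarmonizedData",
    "InstrumentDiagnostics",
    "EmptyInstrumentError",
    "select_instruments",
    "harmonize",
    "instrument_diagnostics",
    "filter_strong",
    "rescore_instruments",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# default effect-allele-frequency band inside which a palindromic SNP's
# orientation cannot be inferred reliably
AMBIGUITY_BAND = (0.42, 0.58)


class EmptyInstrumentError(ValueError):
    """No SNP qualifies as an instrument."""


@dataclass
class InstrumentSet:
    """Ordered, distance-independent genome-wide-significant SNPs."""

    snps: list[GwasRecord]
    p_threshold: float
    window_bp: int
    exposure_name: str = ""

    def __len__(self) -> int:
        return len(self.snps)


@dataclass
class HarmonizedPair:
    """Exposure and outcome effects for one SNP on a common effect allele."""

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: Optional[float] = None
    eaf_out: Optional[float] = None
    palindromic_flag: bool = False
    flipped_flag: bool = False


@dataclass
class HarmonizedData:
    """Instrument-aligned per-SNP effect pairs for one exposure/outcome study."""

    pairs: list[HarmonizedPair]
    exposure_name: str = ""
    outcome_name: str = ""
    n_requested: int = 0
    n_dropped_palindromic: int = 0
    n_missing: int = 0
    n_irreconcilable: int = 0
    drop_reasons: dict = field(default_factory=dict)

    @property
    def n_available(self) -> int:
        return len(self.pairs)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return (beta_exp, se_exp, beta_out, se_out) as float arrays."""
        bx = np.array([p.beta_exp for p in self.pairs], dtype=float)
        sx = np.array([p.se_exp for p in self.pairs], dtype=float)
        by = np.array([p.beta_out for p in self.pairs], dtype=float)
        sy = np.array([p.se_out for p in self.pairs], dtype=float)
        return bx, sx, by, sy

    def subset(self, keep: np.ndarray) -> "HarmonizedData":
        """New HarmonizedData restricted to boolean mask / index array ``keep``."""
        idx = np.arange(len(self.pairs))[keep] if np.asarray(keep).dtype == bool else np.asarray(keep)
        return HarmonizedData(
            pairs=[self.pairs[i] for i in idx],
            exposure_name=self.exposure_name,
            outcome_name=self.outcome_name,
            n_requested=self.n_requested,
            n_dropped_palindromic=self.n_dropped_palindromic,
            n_missing=self.n_missing,
            n_irreconcilable=self.n_irreconcilable,
        )


@dataclass
class InstrumentDiagnostics:
    """Per-SNP F-statistics and total variance explained."""

    f_stats: np.ndarray
    f_median: float
    f_min: float
    f_max: float
    r2_total: float
    r2_from_eaf: Optional[float] = None
    r2_from_f: Optional[float] = None


def select_instruments(
    exposure: GwasTable,
    p_threshold: float = 5e-8,
    window_bp: int = 1_000_000,
) -> InstrumentSet:
    """Greedy distance pruning of genome-wide-significant SNPs.

    SNPs below ``p_threshold`` are visited in order of ascending p-value
    (ties broken on chrom, pos, snp_id); a SNP is accepted iff no previously
    accepted SNP on the same chromosome lies strictly within ``window_bp``.
    The result is invariant to input row order.
    """
    candidates = [r for r in exposure.records if r.pval < p_threshold]
    if not candidates:
        raise EmptyInstrumentError(
            f"no SNP below p={p_threshold:g} in exposure '{exposure.trait_name}'"
        )
    candidates.sort(key=lambda r: (r.pval, r.chrom, r.pos, r.snp_id))
    accepted: list[GwasRecord] = []
    for rec in candidates:
        clash = any(
            a.chrom == rec.chrom and abs(a.pos - rec.pos) < window_bp for a in accepted
        )
        if not clash:
            accepted.append(rec)
    accepted.sort(key=lambda r: (r.chrom, r.pos))
    return InstrumentSet(
        snps=accepted,
        p_threshold=p_threshold,
        window_bp=window_bp,
        exposure_name=exposure.trait_name,
    )


def _is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT.get(a1) == a2


def _orient(exp: GwasRecord, out: GwasRecord):
    """Classify the outcome record's allele orientation vs the exposure record.

    Returns "same", "flip", or None (irreconcilable).  Strand complements are
    reduced to the exposure strand first; for palindromic SNPs complementing
    equals swapping, so orientation must come from allele frequency instead.
    """
    e1, e2 = exp.effect_allele, exp.other_allele
    o1, o2 = out.effect_allele, out.other_allele
    if (o1, o2) == (e1, e2):
        return "same"
    if (o1, o2) == (e2, e1):
        return "flip"
    c1, c2 = COMPLEMENT.get(o1), COMPLEMENT.get(o2)
    if (c1, c2) == (e1, e2):
        return "same"
    if (c1, c2) == (e2, e1):
        return "flip"
    return None


def harmonize(
    instruments: InstrumentSet,
    outcome: GwasTable,
    palindromic_policy: str = "drop_ambiguous",
    ambiguity_band: tuple[float, float] = AMBIGUITY_BAND,
) -> HarmonizedData:
    """Align outcome effects onto the instrument (exposure) effect alleles.

    Policies for palindromic SNPs:

    - ``drop_ambiguous`` (default): drop when either study's EAF is missing or
      falls inside ``ambiguity_band``; otherwise infer orientation from
      frequency concordance (minor allele matching between studies).
    - ``infer_by_eaf``: always infer from frequencies; drop only when a
      frequency is missing.
    - ``drop_all``: drop every palindromic SNP.

    Instruments absent from the outcome table are dropped and counted, as are
    allele pairs that cannot be reconciled by swap or strand complement.
    """
    if not instruments.snps:
        raise EmptyInstrumentError("instrument set is empty")
    if palindromic_policy not in {"drop_ambiguous", "infer_by_eaf", "drop_all"}:
        raise ValueError(f"unknown palindromic policy: {palindromic_policy}")

    lookup = outcome.by_id()
    pairs: list[HarmonizedPair] = []
    n_pal = 0
    n_missing = 0
    n_irrec = 0
    reasons: dict[str, str] = {}

    for exp in instruments.snps:
        out = lookup.get(exp.snp_id)
        if out is None:
            n_missing += 1
            reasons[exp.snp_id] = "absent_from_outcome"
            continue
        palindromic = _is_palindromic(exp.effect_allele, exp.other_allele)
        if palindromic:
            if palindromic_policy == "drop_all":
                n_pal += 1
                reasons[exp.snp_id] = "palindromic_dropped"
                continue
            if {out.effect_allele, out.other_allele} != {exp.effect_allele, exp.other_allele}:
                n_irrec += 1
                reasons[exp.snp_id] = "irreconcilable_alleles"
                continue
            eafs = (exp.eaf, out.eaf)
            if any(e is None for e in eafs):
                n_pal += 1
                reasons[exp.snp_id] = "palindromic_eaf_missing"
                continue
            if palindromic_policy == "drop_ambiguous" and any(
                ambiguity_band[0] < e < ambiguity_band[1] for e in eafs
            ):
                n_pal += 1
                reasons[exp.snp_id] = "palindromic_ambiguous_eaf"
                continue
            # palindromic allele labels carry no strand information; the
            # outcome effect refers to the exposure effect allele iff both
            # frequencies sit on the same side of 0.5
            same_side = (exp.eaf < 0.5) == (out.eaf < 0.5)
            orientation = "same" if same_side else "flip"
        else:
            orientation = _orient(exp, out)
            if orientation is None:
                n_irrec += 1
                reasons[exp.snp_id] = "irreconcilable_alleles"
                continue

        if orientation == "same":
            pairs.append(
                HarmonizedPair(
                    snp_id=exp.snp_id,
                    beta_exp=exp.beta,
                    se_exp=exp.se,
                    beta_out=out.beta,
                    se_out=out.se,
                    eaf_exp=exp.eaf,
                    eaf_out=out.eaf,
                    palindromic_flag=palindromic,
                    flipped_flag=False,
                )
            )
        else:
            pairs.append(
                HarmonizedPair(
                    snp_id=exp.snp_id,
                    beta_exp=exp.beta,
                    se_exp=exp.se,
                    beta_out=-out.beta,
                    se_out=out.se,
                    eaf_exp=exp.eaf,
                    eaf_out=None if out.eaf is None else 1.0 - out.eaf,
                    palindromic_flag=palindromic,
                    flipped_flag=True,
                )
            )

    return HarmonizedData(
        pairs=pairs,
        exposure_name=instruments.exposure_name,
        outcome_name=outcome.trait_name,
        n_requested=len(instruments.snps),
        n_dropped_palindromic=n_pal,
        n_missing=n_missing,
        n_irreconcilable=n_irrec,
        drop_reasons=reasons,
    )


def instrument_diagnostics(data, n_exposure: int) -> InstrumentDiagnostics:
    """F-statistics and exposure variance explained for an instrument set.

    Accepts an InstrumentSet or HarmonizedData.  ``F_j = (beta_j / se_j)^2``.
    Total R^2 uses the Hardy-Weinberg form ``sum 2 p (1-p) beta^2`` (valid for
    a variance-standardized exposure) when every EAF is present, and the
    F-based approximation ``sum F_j / (F_j + n - 2)`` otherwise; both are
    reported when computable.
    """
    if isinstance(data, HarmonizedData):
        betas = np.array([p.beta_exp for p in data.pairs], dtype=float)
        ses = np.array([p.se_exp for p in data.pairs], dtype=float)
        eafs = [p.eaf_exp for p in data.pairs]
    else:
        betas = np.array([r.beta for r in data.snps], dtype=float)
        ses = np.array([r.se for r in data.snps], dtype=float)
        eafs = [r.eaf for r in data.snps]
    if np.any(ses <= 0):
        raise ValueError("all exposure standard errors must be positive")
    f = (betas / ses) ** 2
    r2_eaf = None
    if len(eafs) > 0 and all(e is not None for e in eafs):
        p = np.array(eafs, dtype=float)
        r2_eaf = float(np.sum(2.0 * p * (1.0 - p) * betas**2))
    r2_f = float(np.sum(f / (f + n_exposure - 2))) if len(f) else None
    r2 = r2_eaf if r2_eaf is not None else r2_f
    return InstrumentDiagnostics(
        f_stats=f,
        f_median=float(np.median(f)) if len(f) else float("nan"),
        f_min=float(np.min(f)) if len(f) else float("nan"),
        f_max=float(np.max(f)) if len(f) else float("nan"),
        r2_total=float(min(max(r2, 0.0), 1.0)) if r2 is not None else float("nan"),
        r2_from_eaf=r2_eaf,
        r2_from_f=r2_f,
    )


def filter_strong(
    instruments: InstrumentSet,
    diagnostics: InstrumentDiagnostics,
    f_min: float = 10.0,
) -> InstrumentSet:
    """Retain instruments with F above ``f_min`` (weak-instrument filter)."""
    if len(diagnostics.f_stats) != len(instruments.snps):
        raise ValueError("diagnostics do not match the instrument set")
    kept = [s for s, f in zip(instruments.snps, diagnostics.f_stats) if f > f_min]
    if not kept:
        raise EmptyInstrumentError(f"no instrument with F > {f_min}")
    return InstrumentSet(
        snps=kept,
        p_threshold=instruments.p_threshold,
        window_bp=instruments.window_bp,
        exposure_name=instruments.exposure_name,
    )


def rescore_instruments(instruments: InstrumentSet, exposure: GwasTable) -> InstrumentSet:
    """Replace instrument effect estimates with those from another exposure GWAS.

    Used for overlap-free sensitivity instruments: the SNP list stays the
    primary exposure's, but betas/SEs come from the alternative study (effects
    aligned onto the instrument effect allele).  SNPs missing from the
    alternative study are dropped.
    """
    lookup = exposure.by_id()
    out: list[GwasRecord] = []
    for rec in instruments.snps:
        alt = lookup.get(rec.snp_id)
        if alt is None:
            continue
        orientation = _orient(rec, alt)
        if orientation is None:
            continue
        beta = alt.beta if orientation == "same" else -alt.beta
        eaf = alt.eaf
        if orientation == "flip" and eaf is not None:
            eaf = 1.0 - eaf
        out.append(
            GwasRecord(
                snp_id=rec.snp_id,
                chrom=rec.chrom,
                pos=rec.pos,
                effect_allele=rec.effect_allele,
                other_allele=rec.other_allele,
                eaf=eaf,
                beta=beta,
                se=alt.se,
                pval=alt.pval,
                n=alt.n,
            )
        )
    if not out:
        raise EmptyInstrumentError("no instrument present in alternative exposure")
    return InstrumentSet(
        snps=out,
        p_threshold=instruments.p_threshold,
        window_bp=instruments.window_bp,
        exposure_name=exposure.trait_name,
    )
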