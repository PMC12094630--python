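"""Per-outcome analysis battery, cross-outcome FDR and diagnostic plots.

For every outcome the pipeline harmonizes the instrument panel, removes
horizontally pleiotropic outliers with MR-PRESSO, and reports the
outlier-corrected random-effects IVW estimate as the primary endpoint,
together with the sensitivity battery (weighted median, weighted mode,
MR-Egger, MR-RAPS, the uncorrected IVW, a BMI-adjusted multivariable IVW,
and an overlap-free alternative-instrument IVW).  Primary-endpoint p-values
are corrected across outcomes by the Benjamini-Hochberg false discovery
rate.  Diagnostic scatter, funnel, forest and leave-one-out plots are
emitted per outcome.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from . import estimators as est
from .estimators import MREstimate, NotComputable
from .instruments import (
    EmptyInstrumentError,
    HarmonizedData,
    InstrumentSet,
    filter_strong,
    harmonize,
    instrument_diagnostics,
    rescore_instruments,
    select_instruments,
)
from .mvmr import harmonize_multi, mvmr_ivw
from .presso import PressoConfig, PressoResult, run_presso
from .summary_io import GwasTable, read_gwas

__all__ = [
    "OutcomeSpec",
    "StudyConfig",
    "OutcomeReport",
    "FdrResult",
    "bh_fdr",
    "run_outcome",
    "run_study",
    "make_plots",
    "load_study_config",
]

BATTERY = (
    "ivw", "mr_presso_raw", "weighted_median", "weighted_mode",
    "egger", "raps", "ivw_bmicorr", "ivw_vb",
)


@dataclass
class OutcomeSpec:
    name: str
    table: Optional[GwasTable] = None
    path: Optional[str] = None
    column_map: dict = field(default_factory=dict)
    trait_type: str = "continuous"
    inverse_coded: bool = False

    def load(self) -> GwasTable:
        if self.table is not None:
            return self.table
        table = read_gwas(
            self.path,
            column_map=self.column_map,
            trait_meta={"trait_name": self.name, "trait_type": self.trait_type},
        )
        return table


@dataclass
class StudyConfig:
    exposure: Union[GwasTable, str]
    outcomes: list[OutcomeSpec]
    vb_exposure: Optional[Union[GwasTable, str]] = None
    bmi: Optional[Union[GwasTable, str]] = None
    p_threshold: float = 5e-8
    window_bp: int = 1_000_000
    palindromic_policy: str = "drop_ambiguous"
    f_min: float = 10.0
    n_sim_presso: int = 10000
    n_boot: int = 1000
    seed: int = 0
    out_dir: Optional[str] = None
    make_plots: bool = False

    def __post_init__(self):
        if not self.outcomes:
            raise ValueError("study needs at least one outcome")


@dataclass
class OutcomeReport:
    outcome: str
    inverse_coded: bool
    n_requested: int
    n_available: int
    n_dropped_palindromic: int
    presso: Union[PressoResult, NotComputable, None]
    estimates: dict  # method label -> MREstimate | NotComputable
    heterogeneity: Optional[est.HeterogeneityStats]
    egger_full: Union[est.EggerResult, NotComputable, None]
    leave_one_out: Union[est.LeaveOneOutResult, NotComputable, None]
    plot_paths: list[str] = field(default_factory=list)

    @property
    def primary(self) -> MREstimate:
        return self.estimates["ivw"]


@dataclass
class FdrResult:
    outcomes: list[str]
    pvals: list[float]
    qvals: list[float]
    m: int


def bh_fdr(pvals, m: Optional[int] = None) -> FdrResult:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{k >= i} p_(k) * m / k, clipped at 1, mapped back to input
    order.  ``m`` defaults to the number of tests.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = int(m) if m is not None else p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return FdrResult(outcomes=[], pvals=p.tolist(), qvals=q.tolist(), m=m)


def _as_table(source, name: str) -> GwasTable:
    if isinstance(source, GwasTable):
        return source
    return read_gwas(source, trait_meta={"trait_name": name})


def run_outcome(
    cfg: StudyConfig,
    instruments: InstrumentSet,
    spec: OutcomeSpec,
    seed: int,
    vb_instruments: Optional[InstrumentSet] = None,
    bmi_table: Optional[GwasTable] = None,
) -> OutcomeReport:
    """Full analysis battery for one outcome.

    The primary endpoint is the random-effects IVW estimate on the
    MR-PRESSO outlier-corrected SNP set; every other battery member is run
    on the corrected set except ``mr_presso_raw`` (full set) and ``ivw_vb``
    (alternative instrument, with its own outlier correction).  Stages that
    cannot run are recorded as structured not-computable entries; the
    battery never aborts.  For inverse-coded outcomes the sign convention is
    annotated on the report; the arithmetic is untouched.
    """
    outcome_table = spec.load()
    data = harmonize(instruments, outcome_table, palindromic_policy=cfg.palindromic_policy)
    estimates: dict[str, object] = {}

    presso_cfg = PressoConfig(n_sim=cfg.n_sim_presso, seed=seed)
    presso = run_presso(data, presso_cfg)
    if isinstance(presso, NotComputable):
        corrected = data
        estimates["mr_presso_raw"] = NotComputable("mr_presso_raw", presso.reason)
        primary, het = est.ivw(corrected)
    else:
        keep = np.setdiff1d(np.arange(data.n_available), np.array(presso.outlier_indices, dtype=int))
        corrected = data.subset(keep)
        estimates["mr_presso_raw"] = presso.estimate_raw
        primary = presso.estimate_corrected
        _, het = est.ivw(corrected)

    if primary is None:
        raise EmptyInstrumentError(f"no usable SNP for outcome {spec.name}")
    estimates["ivw"] = primary

    estimates["weighted_median"] = est.weighted_median(corrected, n_boot=cfg.n_boot, seed=seed + 1)
    estimates["weighted_mode"] = est.weighted_mode(corrected, n_boot=cfg.n_boot, seed=seed + 2)
    egger_res = est.egger(corrected)
    estimates["egger"] = egger_res.slope if isinstance(egger_res, est.EggerResult) else egger_res
    estimates["raps"] = est.mr_raps(corrected, seed=seed + 3)
    loo = est.leave_one_out(corrected)

    # BMI-adjusted multivariable IVW on the corrected SNP set
    if bmi_table is not None:
        kept_ids = {p.snp_id for p in corrected.pairs}
        sub_instruments = InstrumentSet(
            snps=[s for s in instruments.snps if s.snp_id in kept_ids],
            p_threshold=instruments.p_threshold,
            window_bp=instruments.window_bp,
            exposure_name=instruments.exposure_name,
        )
        multi = harmonize_multi(sub_instruments, bmi_table, outcome_table,
                                palindromic_policy=cfg.palindromic_policy)
        estimates["ivw_bmicorr"] = multi if isinstance(multi, NotComputable) else mvmr_ivw(multi)
    else:
        estimates["ivw_bmicorr"] = NotComputable("ivw_bmicorr", "no adjustment GWAS configured")

    # overlap-free alternative instrument, with its own outlier correction
    if vb_instruments is not None:
        try:
            vb_data = harmonize(vb_instruments, outcome_table,
                                palindromic_policy=cfg.palindromic_policy)
            vb_presso = run_presso(vb_data, PressoConfig(n_sim=cfg.n_sim_presso, seed=seed + 4))
            if isinstance(vb_presso, NotComputable):
                vb_est, _ = est.ivw(vb_data)
            else:
                vb_est = vb_presso.estimate_corrected
            vb_est = dataclasses.replace(vb_est, method="ivw_vb")
            estimates["ivw_vb"] = vb_est
        except (EmptyInstrumentError, est.DegenerateInstrumentError) as exc:
            estimates["ivw_vb"] = NotComputable("ivw_vb", str(exc))
    else:
        estimates["ivw_vb"] = NotComputable("ivw_vb", "no alternative instrument configured")

    report = OutcomeReport(
        outcome=spec.name,
        inverse_coded=spec.inverse_coded,
        n_requested=data.n_requested,
        n_available=data.n_available,
        n_dropped_palindromic=data.n_dropped_palindromic,
        presso=presso,
        estimates=estimates,
        heterogeneity=het,
        egger_full=egger_res,
        leave_one_out=loo,
    )
    if cfg.make_plots and cfg.out_dir:
        report.plot_paths = make_plots(report, data, corrected, cfg.out_dir)
    return report


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        return "NA" if not np.isfinite(x) else format(x, ".8g")
    return str(x)


def results_rows(report: OutcomeReport) -> list[dict]:
    """Flatten one outcome report into results-table rows (one per method)."""
    het = report.heterogeneity
    eg = report.egger_full
    rows = []
    for method in BATTERY:
        e = report.estimates.get(method)
        row = {
            "outcome": report.outcome,
            "method": method,
            "inverse_coded": report.inverse_coded,
            "n_requested": report.n_requested,
            "n_available": report.n_available,
        }
        if isinstance(e, MREstimate) and e is not None:
            row.update(
                b=e.b, se=e.se, ci_low=e.ci_low, ci_high=e.ci_high,
                pval=e.pval, n_snp=e.n_snp, not_computable="",
            )
        else:
            reason = e.reason if isinstance(e, NotComputable) else "missing"
            row.update(b=None, se=None, ci_low=None, ci_high=None, pval=None,
                       n_snp=None, not_computable=reason)
        row["q"] = het.q if het else None
        row["q_df"] = het.df if het else None
        row["q_p"] = het.pval if het else None
        if isinstance(eg, est.EggerResult):
            row["egger_intercept"] = eg.intercept
            row["egger_intercept_p"] = eg.intercept_p
            row["i2_gx"] = eg.i2_gx
        else:
            row["egger_intercept"] = row["egger_intercept_p"] = row["i2_gx"] = None
        rows.append(row)
    return rows


RESULT_COLUMNS = (
    "outcome", "method", "inverse_coded", "n_requested", "n_available",
    "b", "se", "ci_low", "ci_high", "pval", "n_snp", "not_computable",
    "q", "q_df", "q_p", "egger_intercept", "egger_intercept_p", "i2_gx",
)


def write_results_tsv(rows: list[dict], fdr: FdrResult, path) -> None:
    qmap = dict(zip(fdr.outcomes, fdr.qvals))
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\tq_fdr\n")
        for row in rows:
            qv = qmap.get(row["outcome"]) if row["method"] == "ivw" else None
            fh.write("\t".join(_fmt(row[c]) for c in RESULT_COLUMNS))
            fh.write("\t" + _fmt(qv) + "\n")


def run_study(cfg: StudyConfig):
    """Run the per-outcome battery over every configured outcome plus the
    cross-outcome FDR; deterministic given ``cfg.seed``.

    Returns (reports, FdrResult); when ``cfg.out_dir`` is set, also writes a
    combined results TSV, per-outcome JSON reports and a settings log.
    """
    exposure = _as_table(cfg.exposure, "exposure")
    instruments = select_instruments(exposure, cfg.p_threshold, cfg.window_bp)

    vb_instruments = None
    if cfg.vb_exposure is not None:
        vb_table = _as_table(cfg.vb_exposure, "vb_exposure")
        rescored = rescore_instruments(instruments, vb_table)
        n_vb = next((r.n for r in rescored.snps if r.n), 4)
        diag = instrument_diagnostics(rescored, n_exposure=n_vb)
        vb_instruments = filter_strong(rescored, diag, f_min=cfg.f_min)

    bmi_table = _as_table(cfg.bmi, "bmi") if cfg.bmi is not None else None

    reports = []
    for i, spec in enumerate(cfg.outcomes):
        seed = cfg.seed * 100_003 + i * 1009 + 1
        reports.append(
            run_outcome(cfg, instruments, spec, seed=seed,
                        vb_instruments=vb_instruments, bmi_table=bmi_table)
        )

    fdr = bh_fdr([r.primary.pval for r in reports])
    fdr.outcomes = [r.outcome for r in reports]

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = [row for r in reports for row in results_rows(r)]
        write_results_tsv(rows, fdr, out / "results.tsv")
        for r in reports:
            with open(out / f"report_{_slug(r.outcome)}.json", "w") as fh:
                json.dump(_report_json(r), fh, indent=2, sort_keys=True)
        with open(out / "study_log.json", "w") as fh:
            json.dump(
                {
                    "seed": cfg.seed,
                    "p_threshold": cfg.p_threshold,
                    "window_bp": cfg.window_bp,
                    "palindromic_policy": cfg.palindromic_policy,
                    "n_sim_presso": cfg.n_sim_presso,
                    "n_boot": cfg.n_boot,
                    "n_outcomes": len(cfg.outcomes),
                },
                fh, indent=2, sort_keys=True,
            )
    return reports, fdr


def _slug(name: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in name.lower())


def _est_json(e):
    if isinstance(e, MREstimate):
        return {"method": e.method, "b": e.b, "se": e.se, "ci_low": e.ci_low,
                "ci_high": e.ci_high, "pval": e.pval, "n_snp": e.n_snp}
    if isinstance(e, NotComputable):
        return {"method": e.method, "not_computable": e.reason}
    return None


def _report_json(r: OutcomeReport) -> dict:
    d = {
        "outcome": r.outcome,
        "inverse_coded": r.inverse_coded,
        "sign_convention": (
            "outcome inversely coded: negative b means earlier outcome with earlier exposure"
            if r.inverse_coded else "as reported by the outcome GWAS"
        ),
        "n_requested": r.n_requested,
        "n_available": r.n_available,
        "n_dropped_palindromic": r.n_dropped_palindromic,
        "estimates": {k: _est_json(v) for k, v in r.estimates.items()},
    }
    if isinstance(r.presso, PressoResult):
        d["presso"] = {
            "rss_obs": r.presso.rss_obs,
            "global_p": r.presso.global_p,
            "n_sim": r.presso.n_sim,
            "seed": r.presso.seed,
            "outlier_snp_ids": r.presso.outlier_snp_ids,
            "distortion_p": r.presso.distortion_p,
        }
    elif isinstance(r.presso, NotComputable):
        d["presso"] = {"not_computable": r.presso.reason}
    if r.heterogeneity:
        d["heterogeneity"] = {"q": r.heterogeneity.q, "df": r.heterogeneity.df,
                              "pval": r.heterogeneity.pval}
    return d


def make_plots(report: OutcomeReport, data: HarmonizedData,
               corrected: Optional[HarmonizedData] = None,
               out_dir: str = ".") -> list[str]:
    """Scatter, funnel, forest and leave-one-out diagnostic plots.

    File names are deterministic (``<outcome-slug>_<kind>.<ext>``); both SVG
    and PNG are written.  Outliers flagged by MR-PRESSO are highlighted in
    the scatter plot.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    slug = _slug(report.outcome)
    corrected = corrected if corrected is not None else data
    paths: list[str] = []

    bx, sx, by, sy = data.arrays()
    outlier_idx = (
        report.presso.outlier_indices if isinstance(report.presso, PressoResult) else []
    )
    mask = np.zeros(len(bx), dtype=bool)
    mask[list(outlier_idx)] = True

    def save(fig, kind):
        for ext in ("svg", "png"):
            p = out / f"{slug}_{kind}.{ext}"
            fig.savefig(p, dpi=300)
            paths.append(str(p))
        plt.close(fig)

    # scatter: per-SNP exposure vs outcome effects with estimator lines
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(bx[~mask], by[~mask], xerr=sx[~mask], yerr=sy[~mask], fmt="o",
                ms=3, lw=0.6, color="tab:blue", label="SNP")
    if mask.any():
        ax.errorbar(bx[mask], by[mask], xerr=sx[mask], yerr=sy[mask], fmt="o",
                    ms=4, lw=0.6, color="tab:red", label="outlier")
    xs = np.linspace(0, max(bx.max(), 0) * 1.05, 50)
    prim = report.estimates.get("ivw")
    if isinstance(prim, MREstimate):
        ax.plot(xs, prim.b * xs, color="k", lw=1, label=f"IVW b={prim.b:.3f}")
    eg = report.egger_full
    if isinstance(eg, est.EggerResult):
        ax.plot(xs, eg.intercept + eg.slope.b * xs, color="tab:green", lw=1,
                ls="--", label="Egger")
    ax.set_xlabel("SNP effect on exposure")
    ax.set_ylabel("SNP effect on outcome")
    ax.set_title(f"{report.outcome}: scatter")
    ax.legend(fontsize=7)
    save(fig, "scatter")

    # funnel: per-SNP ratio vs precision
    ratios = est.per_snp_ratios(corrected)
    rvals = np.array([r.ratio for r in ratios])
    rprec = np.array([1.0 / r.ratio_se for r in ratios])
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(rvals, rprec, s=10)
    if isinstance(prim, MREstimate):
        ax.axvline(prim.b, color="k", lw=1)
    ax.set_xlabel("per-SNP causal estimate")
    ax.set_ylabel("1 / SE")
    ax.set_title(f"{report.outcome}: funnel")
    save(fig, "funnel")

    # forest: per-SNP Wald ratios plus the summary estimate
    fig, ax = plt.subplots(figsize=(5, max(3, 0.16 * len(ratios) + 1)))
    order = np.argsort(rvals)
    for i, j in enumerate(order):
        r = ratios[j]
        ax.errorbar(r.ratio, i, xerr=Z95 * r.ratio_se, fmt="o", ms=2.5,
                    color="tab:blue", lw=0.7)
    if isinstance(prim, MREstimate):
        ax.errorbar(prim.b, len(ratios), xerr=Z95 * prim.se, fmt="D", ms=5,
                    color="k")
        ax.axvline(prim.b, color="k", lw=0.6, ls=":")
    ax.set_yticks(list(range(len(ratios))) + [len(ratios)])
    ax.set_yticklabels([ratios[j].snp_id for j in order] + ["IVW"], fontsize=5)
    ax.set_xlabel("per-SNP causal estimate (95% CI)")
    ax.set_title(f"{report.outcome}: forest")
    save(fig, "forest")

    # leave-one-out forest
    loo = report.leave_one_out
    if isinstance(loo, est.LeaveOneOutResult):
        fig, ax = plt.subplots(figsize=(5, max(3, 0.16 * len(loo.snp_ids) + 1)))
        for i, (sid, e, fl) in enumerate(zip(loo.snp_ids, loo.estimates, loo.flags)):
            ax.errorbar(e.b, i, xerr=Z95 * e.se, fmt="o", ms=2.5,
                        color="tab:red" if fl else "tab:blue", lw=0.7)
        ax.axvline(loo.full.b, color="k", lw=0.6, ls=":")
        ax.set_yticks(range(len(loo.snp_ids)))
        ax.set_yticklabels(loo.snp_ids, fontsize=5)
        ax.set_xlabel("IVW estimate excluding the SNP")
        ax.set_title(f"{report.outcome}: leave-one-out")
        save(fig, "leave_one_out")
    return paths


Z95 = est.Z95


def load_study_config(path) -> StudyConfig:
    """Build a StudyConfig from a YAML file (paths resolved relative to it)."""
    import yaml

    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = path.parent

    def resolve(p):
        return None if p is None else str((base / p).resolve())

    outcomes = [
        OutcomeSpec(
            name=o["name"],
            path=resolve(o["path"]),
            column_map=o.get("column_map", {}),
            trait_type=o.get("trait_type", "continuous"),
            inverse_coded=bool(o.get("inverse_coded", False)),
        )
        for o in raw["outcomes"]
    ]
    return StudyConfig(
        exposure=resolve(raw["exposure"]),
        vb_exposure=resolve(raw.get("vb_exposure")),
        bmi=resolve(raw.get("bmi")),
        outcomes=outcomes,
        p_threshold=float(raw.get("p_threshold", 5e-8)),
        window_bp=int(raw.get("window_bp", 1_000_000)),
        palindromic_policy=raw.get("palindromic_policy", "drop_ambiguous"),
        f_min=float(raw.get("f_min", 10.0)),
        n_sim_presso=int(raw.get("n_sim_presso", 10000)),
        n_boot=int(raw.get("n_boot", 1000)),
        seed=int(raw.get("seed", 0)),
        out_dir=raw.get("out_dir"),
        make_plots=bool(raw.get("make_plots", False)),
    )
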