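"""Reading, validation and writing of GWAS summary-statistics tables.

A summary-statistics table holds one row per SNP with the per-allele
association estimate for a single trait: identifier, genomic location,
effect/other allele, effect-allele frequency, beta, standard error, p-value
and sample size.  Coordinates are 1-based GRCh37; the build is metadata only
and no liftover is attempted.  Missing optional values (``eaf``, ``n``) are
encoded as ``NA`` on disk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "GwasRecord",
    "GwasTable",
    "ValidationReport",
    "CANONICAL_COLUMNS",
    "validate_records",
    "read_gwas",
    "write_gwas",
]

VALID_ALLELES = frozenset("ACGT")

#: canonical on-disk column order
CANONICAL_COLUMNS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)

MANDATORY_FIELDS = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pval")


class ConfigurationError(ValueError):
    """A column map or configuration entry is unusable."""


class InputError(ValueError):
    """An input table cannot yield any valid record."""


@dataclass(frozen=True)
class GwasRecord:
    """One SNP-trait association from a GWAS summary-statistics file.

    ``beta`` is the per-allele effect of ``effect_allele`` on the trait
    (years for pubertal-timing exposures; SD units or log-odds for
    outcomes).  ``eaf`` and ``n`` may be missing (``None``).
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: Optional[float]
    beta: float
    se: float
    pval: float
    n: Optional[int] = None

    def is_valid(self) -> bool:
        """Check the per-record invariants (allele codes, se > 0, ...)."""
        try:
            if self.effect_allele not in VALID_ALLELES:
                return False
            if self.other_allele not in VALID_ALLELES:
                return False
            if self.effect_allele == self.other_allele:
                return False
            if not (math.isfinite(self.beta)):
                return False
            if not (math.isfinite(self.se) and self.se > 0):
                return False
            if not (0 < self.pval <= 1):
                return False
            if self.eaf is not None and not (0 < self.eaf < 1):
                return False
            if self.n is not None and self.n <= 0:
                return False
        except TypeError:
            return False
        return True


@dataclass
class ValidationReport:
    """Counts of rows dropped while validating a raw table."""

    n_input: int = 0
    n_invalid: int = 0
    n_duplicate: int = 0

    @property
    def n_valid(self) -> int:
        return self.n_input - self.n_invalid - self.n_duplicate


@dataclass
class GwasTable:
    """Validated summary statistics for one trait."""

    records: list[GwasRecord]
    trait_name: str = ""
    trait_type: str = "continuous"  # continuous | binary
    ancestry_label: str = ""
    source_label: str = ""
    validation: ValidationReport = field(default_factory=ValidationReport)

    def __len__(self) -> int:
        return len(self.records)

    def by_id(self) -> dict[str, GwasRecord]:
        return {r.snp_id: r for r in self.records}

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "snp_id": r.snp_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pval": r.pval,
                "n": r.n,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


def _dedup(records: Sequence[GwasRecord]) -> tuple[list[GwasRecord], int]:
    """Resolve duplicated snp_id or (chrom, pos) keys.

    The record with the smallest p-value wins; ties break on
    (pval, chrom, pos, snp_id) so the outcome is deterministic.
    Returns the surviving records in their original input order.
    """

    def sort_key(item):
        i, r = item
        return (r.pval, r.chrom, r.pos, r.snp_id, i)

    kept_idx: list[int] = []
    seen_ids: set[str] = set()
    seen_pos: set[tuple[str, int]] = set()
    for i, rec in sorted(enumerate(records), key=sort_key):
        key_pos = (rec.chrom, rec.pos)
        if rec.snp_id in seen_ids or key_pos in seen_pos:
            continue
        seen_ids.add(rec.snp_id)
        seen_pos.add(key_pos)
        kept_idx.append(i)
    kept_idx.sort()
    dropped = len(records) - len(kept_idx)
    return [records[i] for i in kept_idx], dropped


def validate_records(records: Iterable[GwasRecord]) -> tuple[list[GwasRecord], ValidationReport]:
    """Drop invalid records, then deduplicate; idempotent on valid tables."""
    records = list(records)
    report = ValidationReport(n_input=len(records))
    valid = [r for r in records if r.is_valid()]
    report.n_invalid = len(records) - len(valid)
    deduped, n_dup = _dedup(valid)
    report.n_duplicate = n_dup
    return deduped, report


def _opt_float(value) -> Optional[float]:
    if value is None:
        return None
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(v) else v


def _opt_int(value) -> Optional[int]:
    v = _opt_float(value)
    return None if v is None else int(v)


def read_gwas(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    trait_meta: Optional[Mapping[str, str]] = None,
    sep: str = "\t",
) -> GwasTable:
    """Read a delimited summary-statistics file into a validated GwasTable.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    column_map
        Mapping from canonical field names (``snp_id``, ``beta``, ...) to the
        column names used in the file.  Omitted fields default to their
        canonical names.  ``snp_id``, ``effect_allele``, ``other_allele``,
        ``beta``, ``se`` and ``pval`` must resolve to existing columns.
    trait_meta
        Optional metadata: ``trait_name``, ``trait_type``, ``ancestry_label``,
        ``source_label``.

    Rows violating record invariants are dropped and counted in
    ``table.validation``; alleles are uppercased before validation.
    """
    column_map = dict(column_map or {})
    trait_meta = dict(trait_meta or {})
    df = pd.read_csv(path, sep=sep, na_values=["NA", "nan", ""], dtype={"chrom": str})

    resolved = {f: column_map.get(f, f) for f in CANONICAL_COLUMNS}
    missing = [f for f in MANDATORY_FIELDS if resolved[f] not in df.columns]
    if missing:
        raise ConfigurationError(
            f"missing mandatory column(s) {missing} in {path} (columns: {list(df.columns)})"
        )

    def col(f):
        name = resolved[f]
        return df[name] if name in df.columns else pd.Series([None] * len(df))

    records = []
    chrom_series = col("chrom")
    pos_series = col("pos")
    for i in range(len(df)):
        pos = _opt_int(pos_series.iloc[i])
        chrom = chrom_series.iloc[i]
        records.append(
            GwasRecord(
                snp_id=str(col("snp_id").iloc[i]),
                chrom="" if chrom is None or (isinstance(chrom, float) and math.isnan(chrom)) else str(chrom),
                pos=0 if pos is None else pos,
                effect_allele=str(col("effect_allele").iloc[i]).upper(),
                other_allele=str(col("other_allele").iloc[i]).upper(),
                eaf=_opt_float(col("eaf").iloc[i]),
                beta=_opt_float(col("beta").iloc[i]) if _opt_float(col("beta").iloc[i]) is not None else math.nan,
                se=_opt_float(col("se").iloc[i]) if _opt_float(col("se").iloc[i]) is not None else math.nan,
                pval=_opt_float(col("pval").iloc[i]) if _opt_float(col("pval").iloc[i]) is not None else math.nan,
                n=_opt_int(col("n").iloc[i]),
            )
        )

    valid, report = validate_records(records)
    if not valid:
        raise InputError(f"no valid summary-statistic rows in {path}")
    return GwasTable(
        records=valid,
        trait_name=trait_meta.get("trait_name", ""),
        trait_type=trait_meta.get("trait_type", "continuous"),
        ancestry_label=trait_meta.get("ancestry_label", ""),
        source_label=trait_meta.get("source_label", ""),
        validation=report,
    )


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return format(value, ".10g")
    return str(value)


def write_gwas(table: GwasTable, path) -> None:
    """Write a table as TSV in canonical column order.

    Floats are written with 10 significant digits so a write/read round trip
    preserves records exactly for decimal inputs at that precision.
    """
    if not table.records:
        raise InputError("refusing to write a table with no records")
    with open(path, "w") as fh:
        fh.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for r in table.records:
            fh.write(
                "\t".join(
                    [
                        r.snp_id,
                        r.chrom,
                        str(r.pos),
                        r.effect_allele,
                        r.other_allele,
                        _fmt(r.eaf),
                        _fmt(r.beta),
                        _fmt(r.se),
                        _fmt(r.pval),
                        "NA" if r.n is None else str(r.n),
                    ]
                )
                + "\n"
            )
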