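"""GWAS summary-statistics tables and LD matrices.

This module defines the record types every downstream stage consumes:

* :class:`SummaryStatRecord` — one variant's association with one trait
  (effect size ``beta`` per copy of the effect allele, its standard error,
  effect-allele frequency ``eaf``, p-value and sample size).
* :class:`SummaryStatsTable` — an ordered collection of records for one
  trait, backed by a :class:`pandas.DataFrame`.
* :class:`LDMatrix` — a symmetric matrix of squared genotype correlations
  (r²) over an ordered variant list.

Conventions follow GWAS summary-statistics practice: 1-based positions,
uppercase DNA alleles, quantitative effects in SD units and binary-trait
effects on the log-odds scale.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, EmptyOverlapError, FormatError

__all__ = [
    "SummaryStatRecord",
    "SummaryStatsTable",
    "LDMatrix",
    "DEFAULT_COLUMN_MAP",
    "read_sumstats",
    "write_sumstats",
    "read_ld_matrix",
    "write_ld_matrix",
    "align_tables",
]

QUANTITATIVE = "quantitative"
BINARY = "binary"
TRAIT_TYPES = (QUANTITATIVE, BINARY)

_ALLELE_RE = re.compile(r"^[ACGT]+$")

#: internal (canonical) column name -> on-disk header name
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "variant_id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
    "n": "N",
}

_CANONICAL = list(DEFAULT_COLUMN_MAP)


@dataclass(frozen=True)
class SummaryStatRecord:
    """One variant's association with one trait.

    ``beta`` is the per-effect-allele effect: SD units for a quantitative
    trait, log-odds for a binary trait. ``eaf`` may be NaN when the source
    GWAS did not report frequencies; such records are flagged and are
    ineligible for R²/F diagnostics and palindromic-frequency rescue.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: int
    trait_type: str = QUANTITATIVE

    @property
    def z(self) -> float:
        return self.beta / self.se

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def has_eaf(self) -> bool:
        return not math.isnan(self.eaf)

    def flipped(self) -> "SummaryStatRecord":
        """The same association expressed for the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=1.0 - self.eaf if self.has_eaf else float("nan"),
        )


def _validate_row(row: Mapping[str, object]) -> str | None:
    """Return a rejection reason, or None when the row satisfies the hard
    invariants (se > 0, eaf in [0,1] or missing, pos >= 1, DNA alleles,
    effect != other allele, p in (0,1], n > 0)."""
    try:
        se = float(row["se"])
        pos = int(row["pos"])
        p = float(row["pvalue"])
        n = int(row["n"])
        eaf = float(row["eaf"])
    except (TypeError, ValueError):
        return "non-numeric field"
    if not se > 0:
        return "se <= 0"
    if not math.isnan(eaf) and not (0.0 <= eaf <= 1.0):
        return "eaf outside [0, 1]"
    if pos < 1:
        return "pos < 1"
    if not (0.0 < p <= 1.0):
        return "pvalue outside (0, 1]"
    if n <= 0:
        return "n <= 0"
    ea = str(row["effect_allele"]).upper()
    oa = str(row["other_allele"]).upper()
    if not _ALLELE_RE.match(ea) or not _ALLELE_RE.match(oa):
        return "allele outside {A,C,G,T}+"
    if ea == oa:
        return "effect_allele == other_allele"
    return None


class SummaryStatsTable:
    """Ordered GWAS summary statistics for one trait.

    Thin wrapper around a DataFrame with canonical columns
    ``variant_id, chrom, pos, effect_allele, other_allele, eaf, beta, se,
    pvalue, n``. Variant IDs are unique; row order is preserved.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        trait_name: str,
        trait_type: str = QUANTITATIVE,
        n_case: int | None = None,
        n_control: int | None = None,
        rejected: pd.DataFrame | None = None,
    ):
        if trait_type not in TRAIT_TYPES:
            raise ConfigurationError(f"unknown trait_type {trait_type!r}")
        missing = [c for c in _CANONICAL if c not in df.columns]
        if missing:
            raise ConfigurationError(f"missing canonical columns: {missing}")
        df = df.loc[:, _CANONICAL].reset_index(drop=True).copy()
        df["variant_id"] = df["variant_id"].astype(str)
        df["chrom"] = df["chrom"].astype(str)
        df["effect_allele"] = df["effect_allele"].str.upper()
        df["other_allele"] = df["other_allele"].str.upper()
        if df["variant_id"].duplicated().any():
            dup = df.loc[df["variant_id"].duplicated(), "variant_id"].tolist()
            raise ConfigurationError(f"duplicate variant IDs: {dup[:5]}")
        self.df = df
        self.trait_name = trait_name
        self.trait_type = trait_type
        self.n_case = n_case
        self.n_control = n_control
        self.rejected = rejected if rejected is not None else df.iloc[0:0].assign(reason=[])

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in set(self.df["variant_id"])

    @property
    def variant_ids(self) -> list[str]:
        return self.df["variant_id"].tolist()

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    def record(self, variant_id: str) -> SummaryStatRecord:
        sub = self.df[self.df["variant_id"] == variant_id]
        if sub.empty:
            raise KeyError(variant_id)
        return self._row_to_record(sub.iloc[0])

    def records(self) -> list[SummaryStatRecord]:
        return [self._row_to_record(row) for _, row in self.df.iterrows()]

    def _row_to_record(self, row: pd.Series) -> SummaryStatRecord:
        return SummaryStatRecord(
            variant_id=str(row["variant_id"]),
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            effect_allele=str(row["effect_allele"]),
            other_allele=str(row["other_allele"]),
            eaf=float(row["eaf"]),
            beta=float(row["beta"]),
            se=float(row["se"]),
            pvalue=float(row["pvalue"]),
            n=int(row["n"]),
            trait_type=self.trait_type,
        )

    @classmethod
    def from_records(
        cls,
        records: Iterable[SummaryStatRecord],
        trait_name: str,
        trait_type: str = QUANTITATIVE,
        n_case: int | None = None,
        n_control: int | None = None,
    ) -> "SummaryStatsTable":
        rows = [
            {
                "variant_id": r.variant_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pvalue": r.pvalue,
                "n": r.n,
            }
            for r in records
        ]
        df = pd.DataFrame(rows, columns=_CANONICAL)
        return cls(df, trait_name, trait_type, n_case=n_case, n_control=n_control)

    def restrict(self, variant_ids: Sequence[str]) -> "SummaryStatsTable":
        """Subset to ``variant_ids``, in the given order."""
        idx = self.df.set_index("variant_id")
        sub = idx.loc[list(variant_ids)].reset_index()
        return SummaryStatsTable(
            sub, self.trait_name, self.trait_type, self.n_case, self.n_control
        )

    def equals(self, other: "SummaryStatsTable") -> bool:
        return (
            self.trait_name == other.trait_name
            and self.trait_type == other.trait_type
            and self.df.equals(other.df)
        )


def _check_pz_consistency(df: pd.DataFrame, source: str) -> None:
    # warn (never reject) when a reported p disagrees with the normal
    # approximation 2*Phi(-|beta/se|) by more than a factor of 10; exact-test
    # and meta-analysed p-values legitimately drift from the Wald p.
    z = np.abs(df["beta"].to_numpy(float) / df["se"].to_numpy(float))
    log10_expected = (stats.norm.logsf(z) + math.log(2.0)) / math.log(10.0)
    with np.errstate(divide="ignore"):
        log10_reported = np.log10(df["pvalue"].to_numpy(float))
    representable = log10_expected > -290  # beyond this, p underflows to 0
    off = (np.abs(log10_reported - log10_expected) > 1.0) & representable
    n_off = int(off.sum())
    if n_off:
        warnings.warn(
            f"{source}: {n_off} row(s) report a p-value more than 10x away from "
            "the two-sided normal approximation of |beta/se|",
            stacklevel=3,
        )


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_type: str = QUANTITATIVE,
    trait_name: str | None = None,
    n_case: int | None = None,
    n_control: int | None = None,
) -> SummaryStatsTable:
    """Read a tab-separated GWAS summary-statistics file.

    ``column_map`` maps canonical names (``variant_id`` ...) to the file's
    header names; unspecified entries fall back to the defaults
    (``SNP CHR POS EA OA EAF BETA SE P N``). gzip input is handled
    transparently by extension. Rows violating hard invariants are rejected,
    counted and kept (with reasons) on ``table.rejected``; rows are never
    silently dropped.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        unknown = set(column_map) - set(cmap)
        if unknown:
            raise ConfigurationError(f"unknown canonical column names: {sorted(unknown)}")
        cmap.update(column_map)
    raw = pd.read_csv(
        path, sep="\t", dtype={cmap["variant_id"]: str, cmap["chrom"]: str},
        float_precision="round_trip",
    )
    missing = [v for v in cmap.values() if v not in raw.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing required column(s) {missing}")
    df = raw.rename(columns={v: k for k, v in cmap.items()})[_CANONICAL]

    reasons = df.apply(_validate_row, axis=1)
    bad = reasons.notna()
    rejected = df[bad].copy()
    rejected["reason"] = reasons[bad]
    good = df[~bad].copy()
    good["pos"] = good["pos"].astype(int)
    good["n"] = good["n"].astype(int)
    for c in ("eaf", "beta", "se", "pvalue"):
        good[c] = good[c].astype(float)
    if len(good):
        _check_pz_consistency(good, str(path))
    name = trait_name if trait_name is not None else str(path)
    return SummaryStatsTable(
        good.reset_index(drop=True),
        trait_name=name,
        trait_type=trait_type,
        n_case=n_case,
        n_control=n_control,
        rejected=rejected.reset_index(drop=True),
    )


def write_sumstats(table: SummaryStatsTable, path, column_map: Mapping[str, str] | None = None) -> None:
    """Write a table as tab-separated text with the (mapped) default header."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    out = table.df.rename(columns=cmap)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


@dataclass
class LDMatrix:
    """Pairwise squared-correlation (r²) matrix over an ordered variant list."""

    variant_ids: list[str]
    r2: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.variant_ids)
        if self.r2.shape != (k, k):
            raise FormatError(f"LD matrix shape {self.r2.shape} != ({k}, {k})")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def get(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    def subset(self, variant_ids: Sequence[str]) -> "LDMatrix":
        idx = [self._index[v] for v in variant_ids]
        return LDMatrix(list(variant_ids), self.r2[np.ix_(idx, idx)])


def read_ld_matrix(path) -> LDMatrix:
    """Read a tab-separated square r² matrix (first row and column are
    variant IDs). Symmetrized by averaging within 1e-8; diagonal forced to 1;
    entries outside [-1e-8, 1 + 1e-8] are format errors."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    ids = [str(c) for c in df.columns]
    row_ids = [str(i) for i in df.index]
    if len(ids) != len(row_ids) or df.shape[0] != df.shape[1]:
        raise FormatError(f"{path}: LD matrix is not square")
    if ids != row_ids:
        raise FormatError(f"{path}: row and column variant IDs disagree")
    m = df.to_numpy(dtype=float)
    if np.any(m > 1.0 + 1e-8) or np.any(m < -1e-8):
        raise FormatError(f"{path}: r² entries outside [0, 1]")
    if np.max(np.abs(m - m.T)) > 1e-8:
        raise FormatError(f"{path}: matrix is asymmetric beyond tolerance 1e-8")
    m = 0.5 * (m + m.T)
    np.clip(m, 0.0, 1.0, out=m)
    np.fill_diagonal(m, 1.0)
    return LDMatrix(ids, m)


def write_ld_matrix(ld: LDMatrix, path) -> None:
    pd.DataFrame(ld.r2, index=ld.variant_ids, columns=ld.variant_ids).to_csv(
        path, sep="\t", float_format="%.17g"
    )


def align_tables(tables: Sequence[SummaryStatsTable]) -> list[SummaryStatsTable]:
    """Restrict every table to the variant IDs shared by all, in the order of
    the first table. Raises :class:`EmptyOverlapError` when nothing is shared."""
    if len(tables) < 2:
        raise ConfigurationError("align_tables needs at least two tables")
    shared = set(tables[0].variant_ids)
    for t in tables[1:]:
        shared &= set(t.variant_ids)
    if not shared:
        raise EmptyOverlapError("no variant is shared across the supplied tables")
    order = [v for v in tables[0].variant_ids if v in shared]
    return [t.restrict(order) for t in tables]
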