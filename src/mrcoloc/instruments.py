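"""Instrument selection and strength diagnostics.

Instruments are conditionally uncorrelated variants: the operational
selection is greedy LD clumping — repeatedly keep the remaining variant
with the smallest p-value and discard everything in LD with it (r² at or
above the threshold, default 0.001). Strength diagnostics are the standard
single-variant variance explained R² = 2·EAF·(1−EAF)·β² (for a trait in SD
units) and the F statistic (R²/K) / ((1−R²)/(N−K−1)); higher F means lower
risk of weak-instrument bias. Variants are labelled *cis* when they fall
within a window (default 1 Mb) of the protein-coding gene, *trans*
otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .exceptions import (
    ConfigurationError,
    MissingEAFError,
    MissingVariantsError,
)
from .sumstats import LDMatrix, SummaryStatRecord, SummaryStatsTable

__all__ = [
    "ClumpConfig",
    "Instrument",
    "GeneRegion",
    "clump",
    "variance_explained",
    "f_statistic",
    "classify_locus",
    "select_instruments",
]

CIS = "cis"
TRANS = "trans"

#: conventional cis-pQTL window around the gene body, base pairs
DEFAULT_CIS_WINDOW = 1_000_000


@dataclass(frozen=True)
class ClumpConfig:
    """Significance and LD-independence thresholds for clumping."""

    p_threshold: float
    r2_threshold: float = 0.001

    def __post_init__(self):
        if not 0.0 < self.p_threshold < 1.0:
            raise ConfigurationError(f"p_threshold {self.p_threshold} outside (0, 1)")
        if not 0.0 <= self.r2_threshold < 1.0:
            raise ConfigurationError(f"r2_threshold {self.r2_threshold} outside [0, 1)")


@dataclass(frozen=True)
class GeneRegion:
    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self):
        if self.end < self.start or self.start < 1:
            raise ConfigurationError(f"invalid gene interval {self.start}-{self.end}")


@dataclass(frozen=True)
class Instrument:
    """A selected variant plus strength diagnostics."""

    record: SummaryStatRecord
    r2_explained: float
    f_stat: float
    locus_class: str = TRANS
    gene_label: str | None = None

    @property
    def variant_id(self) -> str:
        return self.record.variant_id


def clump(
    table: SummaryStatsTable, ld: LDMatrix, cfg: ClumpConfig
) -> list[SummaryStatRecord]:
    """Greedy LD clumping.

    Candidates are the variants with p <= ``cfg.p_threshold``; every
    candidate must appear in the LD matrix. Repeatedly emit the remaining
    candidate with the smallest p-value and drop all remaining candidates
    with r² >= ``cfg.r2_threshold`` to it. Output is ordered by ascending
    p-value; ties break on larger |beta/se| first, then lexicographic
    variant ID, so the result is invariant to input row order.
    """
    cand = [r for r in table.records() if r.pvalue <= cfg.p_threshold]
    missing = [r.variant_id for r in cand if r.variant_id not in ld]
    if missing:
        raise MissingVariantsError(missing, where="LD matrix")
    cand.sort(key=lambda r: (r.pvalue, -abs(r.z), r.variant_id))
    kept: list[SummaryStatRecord] = []
    while cand:
        lead = cand.pop(0)
        kept.append(lead)
        cand = [
            r for r in cand if ld.get(lead.variant_id, r.variant_id) < cfg.r2_threshold
        ]
    return kept


def variance_explained(eaf: float, beta: float) -> float:
    """Variance of a standardized trait explained by one variant:
    2·EAF·(1−EAF)·β²."""
    if eaf is None or math.isnan(eaf):
        raise MissingEAFError("variance explained needs an effect-allele frequency")
    if not 0.0 <= eaf <= 1.0:
        raise ConfigurationError(f"eaf {eaf} outside [0, 1]")
    return 2.0 * eaf * (1.0 - eaf) * beta * beta


def f_statistic(r2: float, k: int, n: int) -> float:
    """Instrument-strength F statistic (R²/K) / ((1−R²)/(N−K−1))."""
    if not 0.0 <= r2 < 1.0:
        raise ConfigurationError(f"r2 {r2} outside [0, 1)")
    if n <= k + 1 or k < 1:
        raise ConfigurationError(f"need n > k+1 >= 2, got n={n}, k={k}")
    return (r2 / k) / ((1.0 - r2) / (n - k - 1))


def classify_locus(
    record: SummaryStatRecord,
    gene: GeneRegion,
    window: int = DEFAULT_CIS_WINDOW,
) -> str:
    """``cis`` iff the variant lies on the gene's chromosome within the
    closed interval [start − window, end + window]; else ``trans``."""
    if record.chrom != gene.chrom:
        return TRANS
    if gene.start - window <= record.pos <= gene.end + window:
        return CIS
    return TRANS


def select_instruments(
    table: SummaryStatsTable,
    ld: LDMatrix,
    cfg: ClumpConfig,
    gene: GeneRegion | None = None,
    cis_window: int = DEFAULT_CIS_WINDOW,
) -> list[Instrument]:
    """Clump, then attach per-instrument diagnostics.

    R² and F are per-instrument (K = 1), matching how single-variant
    instrument strength is usually reported. Variants without an EAF get
    NaN diagnostics (flagged, not dropped).
    """
    out = []
    for rec in clump(table, ld, cfg):
        if rec.has_eaf:
            r2 = variance_explained(rec.eaf, rec.beta)
            f = f_statistic(r2, 1, rec.n)
        else:
            r2 = float("nan")
            f = float("nan")
        locus = classify_locus(rec, gene, cis_window) if gene is not None else TRANS
        out.append(
            Instrument(
                record=rec,
                r2_explained=r2,
                f_stat=f,
                locus_class=locus,
                gene_label=gene.name if gene is not None else None,
            )
        )
    return out
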