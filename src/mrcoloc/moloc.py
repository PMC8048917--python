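"""Multi-trait Bayesian colocalization.

Under the assumption of a single causal variant per trait per region, the
evidence that several traits share that variant is summarised by posterior
probabilities over *sharing configurations*. For traits a, b, c a
configuration names which traits are associated at all and which of the
associated traits share one causal variant: ``abc`` (all three share),
``ab.c`` (a and b share, c has its own variant), ``a.b.c`` (all distinct),
down to ``null`` (none associated) — 15 configurations for three traits.

Per variant and trait, evidence is the Wakefield approximate Bayes factor
computed from the effect estimate, its standard error and a normal
effect-size prior. A configuration's likelihood sums, over all admissible
assignments of causal variants (shared groups take one variant, distinct
groups take distinct variants), the product of per-trait ABFs; its prior
weights each causal variant by p_m, the prior probability that one variant
associates with exactly m traits. Posteriors are the normalized products,
computed in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from string import ascii_lowercase
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp

from .exceptions import ConfigurationError, MissingVariantsError
from .harmonize import DEFAULT_PALINDROMIC_EAF_LIMIT, harmonize
from .sumstats import BINARY, SummaryStatsTable

__all__ = [
    "ColocPriors",
    "Configuration",
    "Region",
    "RegionIneligible",
    "ColocResult",
    "wakefield_log_abf",
    "enumerate_configurations",
    "extract_region",
    "coloc_posteriors",
]

#: conventional effect-size prior scales (SD of the normal prior on beta)
PRIOR_SD_QUANTITATIVE = 0.15
PRIOR_SD_BINARY = 0.20

DEFAULT_WINDOW = 1_000_000
DEFAULT_MAF_MIN = 0.01
DEFAULT_MIN_VARIANTS = 50


@dataclass(frozen=True)
class ColocPriors:
    """Prior probability that one variant associates with exactly m traits."""

    p1: float = 1e-4
    p2: float = 1e-6
    p3: float = 1e-7
    extra: tuple[float, ...] = ()  # p4, p5, ... for >3 traits

    def __post_init__(self):
        ps = (self.p1, self.p2, self.p3) + self.extra
        if not all(0.0 < p < 1.0 for p in ps):
            raise ConfigurationError("priors must lie strictly in (0, 1)")
        if any(ps[i + 1] > ps[i] for i in range(len(ps) - 1)):
            raise ConfigurationError("priors must be non-increasing: p1 >= p2 >= ...")

    def for_size(self, m: int) -> float:
        ps = (self.p1, self.p2, self.p3) + self.extra
        if not 1 <= m <= len(ps):
            raise ConfigurationError(f"no prior configured for a {m}-trait variant")
        return ps[m - 1]


def wakefield_log_abf(beta: float, se: float, prior_sd: float) -> float:
    """Log approximate Bayes factor for association of one variant with one
    trait: with V = se², W = prior_sd², r = W/(V+W) and z = beta/se,
    logABF = 0.5·log(1−r) + r·z²/2."""
    if se <= 0:
        raise ConfigurationError("se must be positive")
    if prior_sd <= 0:
        raise ConfigurationError("prior_sd must be positive")
    v = se * se
    w = prior_sd * prior_sd
    r = w / (v + w)
    z = beta / se
    return 0.5 * math.log1p(-r) + 0.5 * r * z * z


def _set_partitions(items: list):
    """All set partitions of ``items`` (order canonicalised by first
    appearance)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        # first joins an existing block
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        # first in its own block
        yield [[first]] + part


@dataclass(frozen=True)
class Configuration:
    """One sharing hypothesis: ``groups`` is a tuple of trait-index groups;
    traits in the same group share one causal variant, different groups use
    distinct variants, unlisted traits are unassociated."""

    label: str
    groups: tuple[tuple[int, ...], ...]


def _group_label(group: Iterable[int]) -> str:
    return "".join(ascii_lowercase[i] for i in sorted(group))


def _config_label(groups: Sequence[Sequence[int]]) -> str:
    ordered = sorted(groups, key=lambda g: (-len(g), _group_label(g)))
    return ".".join(_group_label(g) for g in ordered)


def enumerate_configurations(n_traits: int) -> list[Configuration]:
    """All sharing configurations for ``n_traits`` traits: the null plus,
    for every non-empty subset of traits, every set partition of the subset
    (n=1 → 2, n=2 → 5, n=3 → 15 configurations)."""
    if not 1 <= n_traits <= 6:
        raise ConfigurationError("n_traits must be between 1 and 6")
    configs = [Configuration("null", ())]
    traits = list(range(n_traits))
    for mask in range(1, 1 << n_traits):
        subset = [t for t in traits if mask >> t & 1]
        for part in _set_partitions(subset):
            groups = tuple(
                tuple(sorted(g))
                for g in sorted(part, key=lambda g: (-len(g), _group_label(g)))
            )
            configs.append(Configuration(_config_label(groups), groups))
    configs.sort(key=lambda c: (len([t for g in c.groups for t in g]), len(c.groups), c.label))
    return configs


@dataclass
class Region:
    """Aligned per-trait summary statistics around a lead variant."""

    center_variant: str
    window: int
    tables: dict[str, SummaryStatsTable]
    maf_min: float = DEFAULT_MAF_MIN
    min_variants: int = DEFAULT_MIN_VARIANTS

    def __post_init__(self):
        ids = None
        for t in self.tables.values():
            cur = t.variant_ids
            if ids is None:
                ids = cur
            elif cur != ids:
                raise ConfigurationError("region tables must share an identical variant set")
        if ids is None:
            raise ConfigurationError("region needs at least one trait table")
        self.variant_ids = ids
        if len(ids) < self.min_variants:
            raise ConfigurationError(
                f"region holds {len(ids)} variants < min_variants={self.min_variants}"
            )

    @property
    def traits(self) -> list[str]:
        return list(self.tables)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)


@dataclass(frozen=True)
class RegionIneligible:
    """A region that cannot be tested, with the reason (never a silent pass)."""

    reason: str
    detail: str = ""
    eligible: bool = False


@dataclass
class ColocResult:
    trait_names: list[str]
    posterior: dict[str, float]
    ppa_full_share: float
    n_variants: int
    eligible: bool = True

    @property
    def configurations(self) -> list[str]:
        return list(self.posterior)


def extract_region(
    tables: Sequence[SummaryStatsTable],
    center_variant: str,
    window: int = DEFAULT_WINDOW,
    maf_min: float = DEFAULT_MAF_MIN,
    min_variants: int = DEFAULT_MIN_VARIANTS,
    palindromic_eaf_limit: float = DEFAULT_PALINDROMIC_EAF_LIMIT,
) -> Region | RegionIneligible:
    """Lead-variant-centric region extraction.

    Windows each trait's table around the lead variant, harmonizes alleles
    across traits, applies the MAF filter (min(eaf, 1−eaf) > ``maf_min`` in
    every trait) and intersects. Eligibility requires the lead variant to
    survive in all traits and at least ``min_variants`` variants to remain.
    """
    holding = [t for t in tables if center_variant in t]
    if not holding:
        raise MissingVariantsError([center_variant], where="all trait tables")
    if len(holding) < len(tables):
        absent = [t.trait_name for t in tables if center_variant not in t]
        return RegionIneligible("lead variant absent", detail=", ".join(absent))
    center = holding[0].record(center_variant)

    windowed = []
    for t in tables:
        df = t.df
        mask = (df["chrom"] == center.chrom) & (
            (df["pos"] - center.pos).abs() <= window
        )
        sub = df[mask]
        windowed.append(
            SummaryStatsTable(sub, t.trait_name, t.trait_type, t.n_case, t.n_control)
        )

    shared = set(windowed[0].variant_ids)
    for t in windowed[1:]:
        shared &= set(t.variant_ids)
    if center_variant not in shared:
        return RegionIneligible("lead variant absent", detail="outside shared window")
    order = [v for v in windowed[0].variant_ids if v in shared]
    windowed = [t.restrict(order) for t in windowed]

    sets = harmonize(windowed[0], windowed[1:], palindromic_eaf_limit)
    keep: list[str] = []
    for hs in sets:
        if hs.dropped:
            continue
        mafs = [r.maf for r in hs.stats.values()]
        if any(math.isnan(m) or m <= maf_min for m in mafs):
            continue
        keep.append(hs.variant_id)

    if center_variant not in keep:
        return RegionIneligible(
            "lead variant absent", detail="removed by harmonization or MAF filter"
        )
    if len(keep) < min_variants:
        return RegionIneligible(
            "min_variants", detail=f"{len(keep)} < {min_variants}"
        )

    kept_sets = {hs.variant_id: hs for hs in sets if not hs.dropped}
    aligned = {}
    for t in tables:
        recs = [kept_sets[v].stats[t.trait_name] for v in keep]
        aligned[t.trait_name] = SummaryStatsTable.from_records(
            recs, t.trait_name, t.trait_type, t.n_case, t.n_control
        )
    return Region(
        center_variant=center_variant,
        window=window,
        tables=aligned,
        maf_min=maf_min,
        min_variants=min_variants,
    )


def _log_distinct_sum(group_vectors: list[np.ndarray]) -> float:
    """log Σ over assignments of *distinct* variants v_1 ≠ ... ≠ v_m of
    Π_j exp(group_vectors[j][v_j]).

    Inclusion–exclusion over set partitions of the groups: merging a block
    B of groups forces them onto one variant, with Möbius coefficient
    Π_B (−1)^{|B|−1} (|B|−1)!.
    """
    m = len(group_vectors)
    terms: list[float] = []
    signs: list[float] = []
    for part in _set_partitions(list(range(m))):
        coeff = 1
        log_term = 0.0
        for block in part:
            coeff *= (-1) ** (len(block) - 1) * math.factorial(len(block) - 1)
            merged = sum(group_vectors[j] for j in block)
            log_term += float(logsumexp(merged))
        terms.append(log_term + math.log(abs(coeff)))
        signs.append(math.copysign(1.0, coeff))
    total, sign = logsumexp(terms, b=signs, return_sign=True)
    if sign <= 0:
        # all mass cancelled (fewer variants than groups); treat as impossible
        return -math.inf
    return float(total)


def coloc_posteriors(
    region: Region,
    priors: ColocPriors = ColocPriors(),
    prior_sd: dict[str, float] | None = None,
) -> ColocResult:
    """Posterior probability of every sharing configuration for the region.

    ``prior_sd`` maps trait name to the effect-size prior scale; defaults
    are 0.15 for quantitative traits and 0.20 for binary (log-odds) traits.
    The null configuration contributes likelihood 1; everything is computed
    in log space with log-sum-exp.
    """
    traits = region.traits
    k = len(traits)
    if len(region.variant_ids) < len(traits):
        raise ConfigurationError("need at least as many variants as traits")

    labf: list[np.ndarray] = []
    for name in traits:
        t = region.tables[name]
        sd = None if prior_sd is None else prior_sd.get(name)
        if sd is None:
            sd = PRIOR_SD_BINARY if t.trait_type == BINARY else PRIOR_SD_QUANTITATIVE
        beta = t.df["beta"].to_numpy(float)
        se = t.df["se"].to_numpy(float)
        v = se**2
        w = sd * sd
        r = w / (v + w)
        z = beta / se
        labf.append(0.5 * np.log1p(-r) + 0.5 * r * z * z)

    configs = enumerate_configurations(k)
    log_weights = []
    for cfg in configs:
        if not cfg.groups:
            log_weights.append(0.0)
            continue
        vectors = [sum(labf[t] for t in g) for g in cfg.groups]
        log_prior = sum(math.log(priors.for_size(len(g))) for g in cfg.groups)
        log_weights.append(log_prior + _log_distinct_sum(vectors))

    log_weights = np.asarray(log_weights)
    post = np.exp(log_weights - logsumexp(log_weights))
    posterior = {cfg.label: float(p) for cfg, p in zip(configs, post)}
    full_label = _group_label(range(k))
    return ColocResult(
        trait_names=traits,
        posterior=posterior,
        ppa_full_share=posterior[full_label],
        n_variants=region.n_variants,
    )
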