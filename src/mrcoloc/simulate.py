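"""Synthetic linked GWAS summary statistics under a mediation causal model.

The generator emulates the three-study design this package analyses: a
small proteome GWAS of a quantitative exposure (plasma protein level, n =
3,301), a large quantitative mediator GWAS (platelet count, n = 173,480)
and a case-control disease outcome GWAS on the log-odds scale, all linked
by the structural model

    exposure  X  =  G·d_X + e_X
    mediator  M  =  G·d_M + θ_XM·X + e_M
    outcome   Y  ~  logistic(α + G·d_Y + θ_MY·M + θ_XY·X)

with LD-block correlation among variants. Direct variant effects ``d`` are
on the standardized-genotype scale; marginal (GWAS-observed) effects are
the LD-convolved vector R·d. The primary generator
:func:`simulate_region` draws observed effect estimates directly from the
multivariate normal summary-statistics model — fast at realistic sample
sizes — while :func:`simulate_individual_oracle` simulates genotypes and
phenotypes at reduced n and regresses variant by variant, serving as the
ground-truth cross-check for the summary-level shortcut.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .exceptions import ConfigurationError
from .sumstats import BINARY, QUANTITATIVE, LDMatrix, SummaryStatsTable

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_region",
    "simulate_individual_oracle",
    "shared_causal_config",
    "mediation_config",
]

_NON_PALINDROMIC = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

EXPOSURE = "exposure"
MEDIATOR = "mediator"
OUTCOME = "outcome"


@dataclass
class SimConfig:
    """Study conditions for one simulated region.

    Sample sizes default to the emulated studies: exposure proteome GWAS
    n = 3,301; mediator hematologic GWAS n = 173,480; outcome case-control
    GWAS at the scale of a juvenile-arthritis GWAS (2,816 cases / 13,056
    controls). Direct effects are per standardized genotype: SD units for
    the quantitative traits, log-odds for the outcome.
    """

    n_variants: int = 200
    block_size: int = 10
    block_r: float = 0.5          # within-block genotype correlation (LD r² = r²)
    eaf_low: float = 0.05
    eaf_high: float = 0.95
    palindromic_fraction: float = 1.0 / 6.0
    chrom: str = "12"
    start_pos: int = 111_000_000
    pos_step: int = 2_500
    n_exposure: int = 3_301
    n_mediator: int = 173_480
    n_case: int = 2_816
    n_control: int = 13_056
    exposure_effects: dict[int, float] = field(default_factory=dict)
    mediator_effects: dict[int, float] = field(default_factory=dict)
    outcome_effects: dict[int, float] = field(default_factory=dict)
    theta_xm: float = 0.0         # exposure -> mediator (SD per SD)
    theta_my: float = 0.0         # mediator -> outcome (log-odds per SD)
    theta_xy: float = 0.0         # direct exposure -> outcome (log-odds per SD)

    def __post_init__(self):
        if self.n_variants < 1 or self.block_size < 1:
            raise ConfigurationError("n_variants and block_size must be positive")
        if not abs(self.block_r) < 1.0:
            raise ConfigurationError("|block_r| must be < 1")
        for n in (self.n_exposure, self.n_mediator, self.n_case, self.n_control):
            if n < 10:
                raise ConfigurationError("sample sizes must be >= 10")
        if not 0.0 < self.eaf_low < self.eaf_high < 1.0:
            raise ConfigurationError("need 0 < eaf_low < eaf_high < 1")
        for effects in (self.exposure_effects, self.mediator_effects, self.outcome_effects):
            for i in effects:
                if not 0 <= i < self.n_variants:
                    raise ConfigurationError(f"causal index {i} out of range")

    @property
    def blocks(self) -> list[int]:
        """Block sizes; the final block absorbs any remainder (sums to
        n_variants)."""
        full, rem = divmod(self.n_variants, self.block_size)
        sizes = [self.block_size] * full
        if rem:
            sizes.append(rem)
        return sizes

    @property
    def n_eff_outcome(self) -> float:
        return 4.0 / (1.0 / self.n_case + 1.0 / self.n_control)

    def direct_effects(self) -> dict[str, np.ndarray]:
        """Per-trait direct standardized effects after propagating the
        structural coefficients through the mediation DAG."""
        p = self.n_variants
        d_x = np.zeros(p)
        for i, v in self.exposure_effects.items():
            d_x[i] = v
        d_m = np.zeros(p)
        for i, v in self.mediator_effects.items():
            d_m[i] = v
        d_m = d_m + self.theta_xm * d_x
        d_y = np.zeros(p)
        for i, v in self.outcome_effects.items():
            d_y[i] = v
        d_y = d_y + self.theta_my * d_m + self.theta_xy * d_x
        return {EXPOSURE: d_x, MEDIATOR: d_m, OUTCOME: d_y}


@dataclass
class SimTruth:
    """Ground truth behind one simulated region."""

    eaf: np.ndarray
    direct_std: dict[str, np.ndarray]
    marginal_std: dict[str, np.ndarray]
    marginal_per_allele: dict[str, np.ndarray]
    r_signed: np.ndarray
    structural: dict[str, float]


def _signed_correlation(cfg: SimConfig) -> np.ndarray:
    r = cfg.block_r
    mats = []
    for size in cfg.blocks:
        block = np.full((size, size), r)
        np.fill_diagonal(block, 1.0)
        mats.append(block)
    out = np.zeros((cfg.n_variants, cfg.n_variants))
    i = 0
    for block in mats:
        s = block.shape[0]
        out[i:i + s, i:i + s] = block
        i += s
    return out


def _block_chol(cfg: SimConfig) -> list[np.ndarray]:
    chols = []
    for size in cfg.blocks:
        block = np.full((size, size), cfg.block_r)
        np.fill_diagonal(block, 1.0)
        try:
            chols.append(np.linalg.cholesky(block))
        except np.linalg.LinAlgError as exc:
            raise ConfigurationError(
                "LD block is not positive definite; reduce |block_r| or add jitter"
            ) from exc
    return chols


def _draw_alleles(rng: np.random.Generator, cfg: SimConfig) -> list[tuple[str, str]]:
    pairs = []
    for _ in range(cfg.n_variants):
        if rng.random() < cfg.palindromic_fraction:
            pairs.append(_PALINDROMIC[rng.integers(len(_PALINDROMIC))])
        else:
            pairs.append(_NON_PALINDROMIC[rng.integers(len(_NON_PALINDROMIC))])
    return pairs


def _variant_ids(cfg: SimConfig) -> list[str]:
    return [f"rs{1000 + i}" for i in range(cfg.n_variants)]


def _positions(cfg: SimConfig) -> list[int]:
    return [cfg.start_pos + i * cfg.pos_step for i in range(cfg.n_variants)]


def _correlated_normal(rng, chols: list[np.ndarray]) -> np.ndarray:
    parts = []
    for L in chols:
        z = rng.standard_normal(L.shape[0])
        parts.append(L @ z)
    return np.concatenate(parts)


def _table(cfg, name, trait_type, ids, positions, pairs, eaf, beta, se, n,
           n_case=None, n_control=None) -> SummaryStatsTable:
    import pandas as pd

    z2 = (beta / se) ** 2
    p = stats.chi2.sf(z2, df=1)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    df = pd.DataFrame({
        "variant_id": ids,
        "chrom": cfg.chrom,
        "pos": positions,
        "effect_allele": [a for a, _ in pairs],
        "other_allele": [b for _, b in pairs],
        "eaf": eaf,
        "beta": beta,
        "se": se,
        "pvalue": p,
        "n": n,
    })
    return SummaryStatsTable(df, name, trait_type, n_case=n_case, n_control=n_control)


def simulate_region(
    cfg: SimConfig, seed: int
) -> tuple[dict[str, SummaryStatsTable], LDMatrix, SimTruth]:
    """Draw one region's linked summary statistics.

    Observed standardized effects are b̂ = R·d + se_std·(L·z) per trait,
    where R is the block LD correlation, L its Cholesky factor and se_std
    the per-variant sampling SD on the standardized-genotype scale
    (1/√n for the quantitative traits, 2/√n_eff for the log-odds outcome).
    Per-allele effects divide by √(2f(1−f)). Fully deterministic given
    (cfg, seed).
    """
    rng = np.random.default_rng(seed)
    p = cfg.n_variants
    eaf = rng.uniform(cfg.eaf_low, cfg.eaf_high, size=p)
    pairs = _draw_alleles(rng, cfg)
    ids = _variant_ids(cfg)
    positions = _positions(cfg)
    chols = _block_chol(cfg)
    r_signed = _signed_correlation(cfg)

    direct = cfg.direct_effects()
    marginal = {t: r_signed @ d for t, d in direct.items()}
    allele_scale = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf))

    se_std = {
        EXPOSURE: 1.0 / math.sqrt(cfg.n_exposure),
        MEDIATOR: 1.0 / math.sqrt(cfg.n_mediator),
        OUTCOME: 2.0 / math.sqrt(cfg.n_eff_outcome),
    }
    n_col = {
        EXPOSURE: cfg.n_exposure,
        MEDIATOR: cfg.n_mediator,
        OUTCOME: cfg.n_case + cfg.n_control,
    }

    tables: dict[str, SummaryStatsTable] = {}
    marginal_allele = {}
    for trait in (EXPOSURE, MEDIATOR, OUTCOME):
        noise = se_std[trait] * _correlated_normal(rng, chols)
        b_std = marginal[trait] + noise
        beta = b_std * allele_scale
        se = np.full(p, se_std[trait]) * allele_scale
        marginal_allele[trait] = marginal[trait] * allele_scale
        kwargs = {}
        trait_type = QUANTITATIVE
        if trait == OUTCOME:
            trait_type = BINARY
            kwargs = {"n_case": cfg.n_case, "n_control": cfg.n_control}
        tables[trait] = _table(
            cfg, trait, trait_type, ids, positions, pairs, eaf, beta, se,
            n_col[trait], **kwargs,
        )

    ld = LDMatrix(ids, r_signed**2)
    truth = SimTruth(
        eaf=eaf,
        direct_std=direct,
        marginal_std=marginal,
        marginal_per_allele=marginal_allele,
        r_signed=r_signed,
        structural={
            "theta_xm": cfg.theta_xm,
            "theta_my": cfg.theta_my,
            "theta_xy": cfg.theta_xy,
        },
    )
    return tables, ld, truth


def _sample_genotypes(rng, cfg: SimConfig, n: int, eaf: np.ndarray) -> np.ndarray:
    """Haplotype-block sampler: per haplotype, a latent Gaussian copula with
    the block correlation thresholded at each variant's frequency quantile."""
    chols = _block_chol(cfg)
    thresholds = stats.norm.ppf(eaf)
    haps = []
    for _ in range(2):
        cols = []
        start = 0
        for L in chols:
            size = L.shape[0]
            z = rng.standard_normal((n, size)) @ L.T
            cols.append((z < thresholds[start:start + size]).astype(np.int8))
            start += size
        haps.append(np.concatenate(cols, axis=1))
    return haps[0] + haps[1]


def simulate_individual_oracle(
    cfg: SimConfig, n_reduced: int, seed: int
) -> dict[str, SummaryStatsTable]:
    """Individual-level ground-truth simulation at reduced n (≤ 20,000).

    Genotypes come from the haplotype-block sampler; the exposure and
    mediator are generated by the linear structural model and the outcome
    by a logistic model whose intercept matches the configured case
    fraction. Per-variant summary statistics are computed by direct
    marginal regression (closed-form OLS for the quantitative traits, a
    per-variant logistic fit for the outcome). Monomorphic variants have no
    defined SE and are excluded with a log entry.
    """
    if n_reduced > 20_000:
        raise ConfigurationError("individual-level oracle is limited to n <= 20,000")
    rng = np.random.default_rng(seed)
    p = cfg.n_variants
    eaf = rng.uniform(cfg.eaf_low, cfg.eaf_high, size=p)
    pairs = _draw_alleles(rng, cfg)
    ids = _variant_ids(cfg)
    positions = _positions(cfg)

    g = _sample_genotypes(rng, cfg, n_reduced, eaf)
    var_g = g.var(axis=0)
    poly = var_g > 0
    n_dropped = int((~poly).sum())
    if n_dropped:
        dropped = [ids[i] for i in np.flatnonzero(~poly)]
        logger.info("excluded %d monomorphic variant(s): %s", n_dropped, dropped)
    g = g[:, poly]
    g_std = (g - g.mean(axis=0)) / g.std(axis=0)

    d_x = np.zeros(p)
    for i, v in cfg.exposure_effects.items():
        d_x[i] = v
    d_m = np.zeros(p)
    for i, v in cfg.mediator_effects.items():
        d_m[i] = v
    d_y = np.zeros(p)
    for i, v in cfg.outcome_effects.items():
        d_y[i] = v
    d_x, d_m, d_y = d_x[poly], d_m[poly], d_y[poly]

    def _noise_var(systematic: np.ndarray) -> float:
        return max(0.05, 1.0 - float(np.var(systematic)))

    gx = g_std @ d_x
    x = gx + rng.normal(0.0, math.sqrt(_noise_var(gx)), n_reduced)
    gm = g_std @ d_m + cfg.theta_xm * x
    m = gm + rng.normal(0.0, math.sqrt(_noise_var(gm)), n_reduced)
    case_frac = cfg.n_case / (cfg.n_case + cfg.n_control)
    alpha = math.log(case_frac / (1.0 - case_frac))
    eta = alpha + g_std @ d_y + cfg.theta_my * m + cfg.theta_xy * x
    y = (rng.random(n_reduced) < 1.0 / (1.0 + np.exp(-eta))).astype(int)

    kept_ids = [ids[i] for i in np.flatnonzero(poly)]
    kept_pos = [positions[i] for i in np.flatnonzero(poly)]
    kept_pairs = [pairs[i] for i in np.flatnonzero(poly)]
    kept_eaf = eaf[poly]

    def _ols_table(yvec, name, n):
        gc = g - g.mean(axis=0)
        yc = yvec - yvec.mean()
        vg = gc.var(axis=0)
        beta = (gc * yc[:, None]).mean(axis=0) / vg
        resid_var = np.maximum(yc.var() - beta**2 * vg, 1e-12)
        se = np.sqrt(resid_var / (n_reduced * vg) * n_reduced / (n_reduced - 2))
        return _table(cfg, name, QUANTITATIVE, kept_ids, kept_pos, kept_pairs,
                      kept_eaf, beta, se, n)

    def _logit_table(name):
        betas = np.empty(g.shape[1])
        ses = np.empty(g.shape[1])
        X0 = np.ones((n_reduced, 2))
        for j in range(g.shape[1]):
            X0[:, 1] = g[:, j]
            fit = sm.Logit(y, X0).fit(disp=0)
            betas[j] = fit.params[1]
            ses[j] = fit.bse[1]
        return _table(cfg, name, BINARY, kept_ids, kept_pos, kept_pairs,
                      kept_eaf, betas, ses, n_reduced,
                      n_case=int(y.sum()), n_control=int((1 - y).sum()))

    return {
        EXPOSURE: _ols_table(x, EXPOSURE, n_reduced),
        MEDIATOR: _ols_table(m, MEDIATOR, n_reduced),
        OUTCOME: _logit_table(OUTCOME),
    }


def shared_causal_config(
    n_variants: int = 240,
    causal_index: int | None = None,
    z_exposure: float = 10.0,
    z_mediator: float = 10.0,
    z_outcome: float = 10.0,
    **overrides,
) -> tuple[SimConfig, int]:
    """A region in which one variant directly drives all three traits, with
    direct standardized effects chosen so the expected marginal |z| at the
    causal variant equals the requested targets."""
    cfg0 = SimConfig(n_variants=n_variants, **overrides)
    if causal_index is None:
        causal_index = n_variants // 2
    d_x = z_exposure / math.sqrt(cfg0.n_exposure)
    d_m = z_mediator / math.sqrt(cfg0.n_mediator)
    d_y = z_outcome * 2.0 / math.sqrt(cfg0.n_eff_outcome)
    cfg = SimConfig(
        n_variants=n_variants,
        exposure_effects={causal_index: d_x},
        mediator_effects={causal_index: d_m},
        outcome_effects={causal_index: d_y},
        **overrides,
    )
    return cfg, causal_index


def mediation_config(
    n_variants: int = 200,
    cis_index: int = 5,
    trans_index: int = 105,
    r2_cis: float = 0.014,
    r2_trans: float = 0.015,
    theta_xm: float = 0.19,
    theta_my: float = 0.63,
    trans_pleiotropy: float = 0.0,
    **overrides,
) -> SimConfig:
    """The default mediation topology: a cis-like variant affecting the
    exposure only, a trans-like variant affecting the exposure and —
    optionally, via ``trans_pleiotropy`` (an extra direct standardized
    effect on the mediator) — other pathways; the exposure feeds the
    mediator (θ_XM, SD per SD) which feeds the disease (θ_MY, log-odds per
    SD)."""
    mediator_effects = {}
    if trans_pleiotropy:
        mediator_effects[trans_index] = trans_pleiotropy
    return SimConfig(
        n_variants=n_variants,
        exposure_effects={
            cis_index: math.sqrt(r2_cis),
            trans_index: math.sqrt(r2_trans),
        },
        mediator_effects=mediator_effects,
        theta_xm=theta_xm,
        theta_my=theta_my,
        **overrides,
    )
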