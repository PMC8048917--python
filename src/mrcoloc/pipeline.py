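"""Study orchestration: standard MR, two-step mediation MR and reporting.

The study asks three questions per disease outcome:

1. *Standard MR* — does the exposure (a plasma protein) causally affect
   the outcome? Per-instrument Wald ratios, combined by
   inverse-variance-weighted meta-analysis with multiplicative random
   effects when at least two instruments survive Steiger directionality
   filtering.
2. *Two-step MR* — is that effect mediated? Step 1 instruments the
   exposure against the mediator (platelet count); step 2 instruments the
   mediator (at its own genome-wide threshold) against the outcome, with
   weighted-median and MR-Egger sensitivity analyses and a per-exposure-
   instrument rerun of step 2.
3. *Multiple testing* — family-wise Bonferroni correction across the
   outcome panel (α/m; the study's 22-trait panel gives the 2 × 10⁻³
   threshold).

Everything is deterministic given the configuration and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, EmptyOverlapError
from .harmonize import DEFAULT_PALINDROMIC_EAF_LIMIT, HarmonizedSet, harmonize
from .instruments import ClumpConfig, clump, variance_explained
from .mr import (
    MREstimate,
    SteigerResult,
    binary_trait_r2,
    ivw_additive,
    ivw_mre,
    mr_egger,
    steiger_filter,
    wald_ratio,
    weighted_median,
)
from .sumstats import BINARY, LDMatrix, SummaryStatRecord, SummaryStatsTable

__all__ = [
    "StudyConfig",
    "StandardMRResult",
    "MediationFinding",
    "bonferroni_threshold",
    "round_to_one_sigfig",
    "run_standard_mr",
    "run_two_step",
    "render_report",
]

DISEASE_CLASSES = ("cardiovascular", "autoimmune", "autoinflammatory", "atopic")


def bonferroni_threshold(alpha_family: float, n_tests: int) -> float:
    """Family-wise error α divided by the number of outcome traits."""
    if n_tests < 1:
        raise ConfigurationError("n_tests must be >= 1")
    if not 0.0 < alpha_family < 1.0:
        raise ConfigurationError("alpha_family must lie in (0, 1)")
    return alpha_family / n_tests


def round_to_one_sigfig(x: float) -> float:
    """The reporting layer's one-significant-figure rounding (0.002272… →
    0.002, i.e. 2 × 10⁻³)."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round(x, -exponent)


@dataclass
class StudyConfig:
    """Inputs and thresholds for one full run."""

    exposure: SummaryStatsTable
    mediator: SummaryStatsTable
    outcomes: dict[str, SummaryStatsTable]
    ld: LDMatrix
    disease_classes: dict[str, str] = field(default_factory=dict)
    exposure_clump: ClumpConfig = field(default_factory=lambda: ClumpConfig(5e-8, 0.001))
    mediator_clump: ClumpConfig = field(default_factory=lambda: ClumpConfig(8.31e-9, 0.001))
    alpha_family: float = 0.05
    n_tests: int | None = None   # defaults to the number of outcome tables
    palindromic_eaf_limit: float = DEFAULT_PALINDROMIC_EAF_LIMIT
    wm_boot: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not self.outcomes:
            raise ConfigurationError("at least one outcome table is required")
        if self.n_tests is None:
            self.n_tests = len(self.outcomes)
        if self.n_tests < 1:
            raise ConfigurationError("n_tests must be >= 1")
        for label, cls in self.disease_classes.items():
            if cls not in DISEASE_CLASSES:
                raise ConfigurationError(f"unknown disease class {cls!r} for {label!r}")

    @property
    def p_threshold_family(self) -> float:
        return bonferroni_threshold(self.alpha_family, self.n_tests)


@dataclass
class StandardMRResult:
    """Exposure → one outcome, per instrument and combined."""

    outcome: str
    per_instrument: dict[str, MREstimate] = field(default_factory=dict)
    combined: MREstimate | None = None
    steiger: dict[str, SteigerResult] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)
    estimable: bool = False
    note: str = ""


@dataclass
class MediationFinding:
    """Everything the two-step analysis produces for one outcome."""

    outcome: str
    disease_class: str | None
    step0: StandardMRResult
    step1_per_instrument: dict[str, MREstimate]
    step1_combined: MREstimate | None
    step1_additive: MREstimate | None
    step2_ivw: MREstimate | None
    step2_wmedian: MREstimate | None
    step2_egger_slope: MREstimate | None
    step2_egger_intercept: MREstimate | None
    step2_sensitivity: dict[str, MREstimate]
    mediation_consistent: bool
    passes_bonferroni: bool
    product_estimate: float | None   # supplementary product-of-coefficients


def _outcome_r2(rec: SummaryStatRecord, table: SummaryStatsTable) -> float | None:
    """Variance explained by one variant in the outcome, on a scale
    comparable with the quantitative exposure R²; None when the diagnostic
    is unavailable (missing EAF on a quantitative trait)."""
    if table.trait_type == BINARY:
        if table.n_case is None or table.n_control is None:
            raise ConfigurationError(
                f"{table.trait_name}: binary outcome needs n_case/n_control for Steiger"
            )
        return binary_trait_r2(rec.beta, rec.se, table.n_case, table.n_control)
    if not rec.has_eaf:
        return None
    return variance_explained(rec.eaf, rec.beta)


def _steiger_pass(
    x: SummaryStatRecord,
    y: SummaryStatRecord,
    out_table: SummaryStatsTable,
) -> tuple[SteigerResult | None, bool]:
    if not x.has_eaf:
        return None, True  # diagnostic unavailable; keep, flagged by None
    r2_gx = variance_explained(x.eaf, x.beta)
    r2_gy = _outcome_r2(y, out_table)
    if r2_gy is None:
        return None, True
    n_y = (
        out_table.n_case + out_table.n_control
        if out_table.trait_type == BINARY and out_table.n_case is not None
        else y.n
    )
    res = steiger_filter(r2_gx, x.n, r2_gy, n_y)
    return res, res.direction_ok


def _mr_one_outcome(
    exposure_sub: SummaryStatsTable,
    out_table: SummaryStatsTable,
    label: str,
    palindromic_eaf_limit: float,
) -> tuple[StandardMRResult, list[HarmonizedSet]]:
    """Harmonize, Steiger-filter, estimate per instrument, combine."""
    res = StandardMRResult(outcome=label)
    try:
        sets = harmonize(exposure_sub, [out_table], palindromic_eaf_limit)
    except EmptyOverlapError:
        res.note = "no shared variants with outcome"
        return res, []
    kept: list[tuple[str, MREstimate]] = []
    for hs in sets:
        if hs.dropped:
            res.excluded.append(hs.variant_id)
            continue
        x = hs.stats[exposure_sub.trait_name]
        y = hs.stats[out_table.trait_name]
        st, ok = _steiger_pass(x, y, out_table)
        if st is not None:
            res.steiger[hs.variant_id] = st
        if not ok:
            res.excluded.append(hs.variant_id)
            continue
        est = wald_ratio(x.beta, x.se, y.beta, y.se)
        res.per_instrument[hs.variant_id] = est
        kept.append((hs.variant_id, est))
    if len(kept) >= 2:
        res.combined = ivw_mre([(e.beta_xy, e.se) for _, e in kept])
        res.estimable = True
    elif len(kept) == 1:
        res.combined = kept[0][1]
        res.estimable = True
    else:
        res.note = res.note or "no instruments survive filtering"
    return res, sets


def run_standard_mr(cfg: StudyConfig) -> dict[str, StandardMRResult]:
    """Standard MR of the exposure on every outcome."""
    instruments = clump(cfg.exposure, cfg.ld, cfg.exposure_clump)
    results: dict[str, StandardMRResult] = {}
    if not instruments:
        for label in cfg.outcomes:
            results[label] = StandardMRResult(outcome=label, note="no exposure instruments")
        return results
    exposure_sub = cfg.exposure.restrict([r.variant_id for r in instruments])
    for label, out_table in cfg.outcomes.items():
        res, _ = _mr_one_outcome(
            exposure_sub, out_table, label, cfg.palindromic_eaf_limit
        )
        results[label] = res
    return results


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


def run_two_step(cfg: StudyConfig) -> list[MediationFinding]:
    """Two-step mediation MR for every outcome."""
    step0 = run_standard_mr(cfg)

    instruments = clump(cfg.exposure, cfg.ld, cfg.exposure_clump)
    exposure_ids = [r.variant_id for r in instruments]
    exposure_sub = cfg.exposure.restrict(exposure_ids) if exposure_ids else None

    # step 1: exposure -> mediator
    step1_per: dict[str, MREstimate] = {}
    step1_combined = step1_additive = None
    if exposure_sub is not None:
        try:
            sets1 = harmonize(exposure_sub, [cfg.mediator], cfg.palindromic_eaf_limit)
        except EmptyOverlapError:
            sets1 = []
        for hs in sets1:
            if hs.dropped:
                continue
            x = hs.stats[cfg.exposure.trait_name]
            m = hs.stats[cfg.mediator.trait_name]
            step1_per[hs.variant_id] = wald_ratio(x.beta, x.se, m.beta, m.se)
        if len(step1_per) >= 2:
            pairs = [(e.beta_xy, e.se) for e in step1_per.values()]
            step1_combined = ivw_mre(pairs)
            step1_additive = ivw_additive(pairs)
        elif len(step1_per) == 1:
            step1_combined = next(iter(step1_per.values()))

    # step 2 instruments: mediator at its own genome-wide threshold
    med_instruments = clump(cfg.mediator, cfg.ld, cfg.mediator_clump)
    med_sub = (
        cfg.mediator.restrict([r.variant_id for r in med_instruments])
        if med_instruments
        else None
    )

    findings = []
    for label, out_table in cfg.outcomes.items():
        step2_res = StandardMRResult(outcome=label)
        step2_wm = step2_slope = step2_int = None
        egger_pairs: list[tuple[float, float, float]] = []
        if med_sub is not None:
            step2_res, sets2 = _mr_one_outcome(
                med_sub, out_table, label, cfg.palindromic_eaf_limit
            )
            for hs in sets2:
                if hs.dropped or hs.variant_id not in step2_res.per_instrument:
                    continue
                m = hs.stats[cfg.mediator.trait_name]
                y = hs.stats[out_table.trait_name]
                egger_pairs.append((m.beta, y.beta, y.se))
            ests = [(e.beta_xy, e.se) for e in step2_res.per_instrument.values()]
            if len(ests) >= 3:
                step2_wm = weighted_median(ests, n_boot=cfg.wm_boot, seed=cfg.seed)
                step2_slope, step2_int = mr_egger(egger_pairs)

        # sensitivity: mediator -> outcome restricted to each exposure instrument
        sensitivity: dict[str, MREstimate] = {}
        for vid in exposure_ids:
            if vid not in cfg.mediator or vid not in out_table:
                continue
            try:
                sets_v = harmonize(
                    cfg.mediator.restrict([vid]), [out_table.restrict([vid])],
                    cfg.palindromic_eaf_limit,
                )
            except EmptyOverlapError:
                continue
            hs = sets_v[0]
            if hs.dropped:
                continue
            m = hs.stats[cfg.mediator.trait_name]
            y = hs.stats[out_table.trait_name]
            if m.beta != 0:
                sensitivity[vid] = wald_ratio(m.beta, m.se, y.beta, y.se)

        s0 = step0[label]
        consistent = False
        if (
            s0.combined is not None
            and step1_combined is not None
            and step2_res.combined is not None
        ):
            consistent = (
                _sign(step1_combined.beta_xy) * _sign(step2_res.combined.beta_xy)
                == _sign(s0.combined.beta_xy)
                != 0
            )
        passes = (
            s0.combined is not None
            and s0.combined.pvalue <= cfg.p_threshold_family
        )
        product = None
        if step1_combined is not None and step2_res.combined is not None:
            product = step1_combined.beta_xy * step2_res.combined.beta_xy
        findings.append(
            MediationFinding(
                outcome=label,
                disease_class=cfg.disease_classes.get(label),
                step0=s0,
                step1_per_instrument=step1_per,
                step1_combined=step1_combined,
                step1_additive=step1_additive,
                step2_ivw=step2_res.combined,
                step2_wmedian=step2_wm,
                step2_egger_slope=step2_slope,
                step2_egger_intercept=step2_int,
                step2_sensitivity=sensitivity,
                mediation_consistent=consistent,
                passes_bonferroni=passes,
                product_estimate=product,
            )
        )
    return findings


# ---------------------------------------------------------------------------
# reporting

_FMT = "%.17g"


def _est_row(outcome, cls, method, est: MREstimate | None, log_odds=True, **extra):
    row = {"outcome": outcome, "disease_class": cls or "", "method": method}
    if est is None:
        row.update({"nsnp": 0, "b": "NA", "se": "NA", "ci_low": "NA",
                    "ci_high": "NA", "p": "NA", "OR": "NA", "OR_low": "NA",
                    "OR_high": "NA", "note": "not estimable"})
    else:
        or_, lo, hi = est.odds_ratio
        row.update({
            "nsnp": est.n_instruments,
            "b": _FMT % est.beta_xy, "se": _FMT % est.se,
            "ci_low": _FMT % est.ci_low, "ci_high": _FMT % est.ci_high,
            "p": _FMT % est.pvalue,
            "OR": _FMT % or_ if log_odds else "NA",
            "OR_low": _FMT % lo if log_odds else "NA",
            "OR_high": _FMT % hi if log_odds else "NA",
            "note": "",
        })
    row.update(extra)
    return row


def render_report(findings: list[MediationFinding], outdir, make_plots: bool = True) -> dict:
    """Write forest-table TSVs (and forest-plot images) for the three
    reporting surfaces: exposure → outcome per instrument and combined;
    exposure → mediator; mediator → outcome with sensitivity analyses.
    Returns the written paths."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not findings:
        raise ConfigurationError("nothing to report")

    rows0 = []
    for f in findings:
        s0 = f.step0
        for vid, est in s0.per_instrument.items():
            rows0.append(_est_row(f.outcome, f.disease_class, f"wald:{vid}", est,
                                  passes_bonferroni=""))
        rows0.append(_est_row(
            f.outcome, f.disease_class, "combined", s0.combined,
            passes_bonferroni=str(f.passes_bonferroni),
        ))
    exposure_path = outdir / "exposure_outcome.tsv"
    pd.DataFrame(rows0).to_csv(exposure_path, sep="\t", index=False)

    f0 = findings[0]
    rows1 = [
        _est_row("mediator", "", f"wald:{vid}", est, log_odds=False)
        for vid, est in f0.step1_per_instrument.items()
    ]
    rows1.append(_est_row("mediator", "", "combined", f0.step1_combined, log_odds=False))
    if f0.step1_additive is not None:
        rows1.append(_est_row("mediator", "", "combined_additive", f0.step1_additive,
                              log_odds=False))
    mediator_path = outdir / "exposure_mediator.tsv"
    pd.DataFrame(rows1).to_csv(mediator_path, sep="\t", index=False)

    rows2 = []
    for f in findings:
        rows2.append(_est_row(f.outcome, f.disease_class, "ivw_mre", f.step2_ivw,
                              mediation_consistent=str(f.mediation_consistent)))
        rows2.append(_est_row(f.outcome, f.disease_class, "weighted_median",
                              f.step2_wmedian, mediation_consistent=""))
        rows2.append(_est_row(f.outcome, f.disease_class, "egger_slope",
                              f.step2_egger_slope, mediation_consistent=""))
        rows2.append(_est_row(f.outcome, f.disease_class, "egger_intercept",
                              f.step2_egger_intercept, mediation_consistent=""))
        for vid, est in f.step2_sensitivity.items():
            rows2.append(_est_row(f.outcome, f.disease_class, f"sensitivity:{vid}",
                                  est, mediation_consistent=""))
    mediated_path = outdir / "mediator_outcome.tsv"
    pd.DataFrame(rows2).to_csv(mediated_path, sep="\t", index=False)

    paths = {
        "exposure_outcome": exposure_path,
        "exposure_mediator": mediator_path,
        "mediator_outcome": mediated_path,
    }
    if make_plots:
        paths["forest_plot"] = _forest_plot(findings, outdir / "exposure_outcome_forest.png")
    return paths


def _forest_plot(findings, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels, ors, los, his = [], [], [], []
    for f in findings:
        if f.step0.combined is None:
            continue
        or_, lo, hi = f.step0.combined.odds_ratio
        labels.append(f.outcome)
        ors.append(or_)
        los.append(lo)
        his.append(hi)
    fig, ax = plt.subplots(figsize=(6, max(2, 0.4 * len(labels) + 1)))
    ypos = np.arange(len(labels))[::-1]
    ax.errorbar(
        ors, ypos,
        xerr=[np.array(ors) - np.array(los), np.array(his) - np.array(ors)],
        fmt="s", color="black", ecolor="gray", capsize=3,
    )
    ax.axvline(1.0, color="red", linestyle="--", linewidth=0.8)
    ax.set_yticks(ypos)
    ax.set_yticklabels(labels)
    ax.set_xlabel("odds ratio (95% CI)")
    ax.set_xscale("log")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
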