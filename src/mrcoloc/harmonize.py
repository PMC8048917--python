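"""Effect-allele harmonization across traits.

Two-sample MR divides a variant's outcome association by its exposure
association, so both must refer to the same allele. For each shared
variant the exposure record defines the reference allele pair and every
other trait's record is reconciled to it:

* identical allele pair — kept as-is;
* swapped alleles — beta sign flipped, eaf complemented;
* strand-complement alleles (only attempted when direct and swapped
  comparison both fail) — relabelled, with a sign flip when additionally
  swapped;
* palindromic pairs (A/T or C/G), where strand cannot be resolved from
  allele labels — aligned by label, then retained only when every trait's
  aligned EAF sits on the same side of 0.5 and at least
  ``palindromic_eaf_limit`` away from it;
* anything irreconcilable — dropped with reason.

Drops are logged outcomes, never errors. Indel alleles longer than one
base are compared literally (no strand or left-alignment rescue).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .exceptions import EmptyOverlapError
from .sumstats import SummaryStatRecord, SummaryStatsTable

__all__ = [
    "HarmonizedSet",
    "harmonize",
    "harmonized_frame",
    "write_audit",
]

KEPT = "kept"
SIGN_FLIPPED = "sign_flipped"
STRAND_FLIPPED = "strand_flipped"
DROPPED_PALINDROMIC = "dropped_palindromic"
DROPPED_MISMATCH = "dropped_mismatch"

#: default EAF distance from 0.5 needed to keep a palindromic variant
DEFAULT_PALINDROMIC_EAF_LIMIT = 0.08

_COMP = str.maketrans("ACGT", "TGCA")


def _complement(allele: str) -> str:
    return allele.translate(_COMP)


def _is_palindromic(ea: str, oa: str) -> bool:
    return len(ea) == 1 and len(oa) == 1 and _complement(ea) == oa


@dataclass
class HarmonizedSet:
    """All traits' records for one variant, expressed for one reference
    effect allele, plus the per-trait action log."""

    variant_id: str
    effect_allele: str
    other_allele: str
    stats: dict[str, SummaryStatRecord] = field(default_factory=dict)
    actions: dict[str, str] = field(default_factory=dict)
    dropped: bool = False
    drop_reason: str | None = None

    def record(self, trait: str) -> SummaryStatRecord:
        return self.stats[trait]


def _reconcile(ref: SummaryStatRecord, other: SummaryStatRecord):
    """Return (aligned record or None, action) for one trait vs the
    reference allele pair."""
    ea, oa = other.effect_allele, other.other_allele
    if (ea, oa) == (ref.effect_allele, ref.other_allele):
        return other, KEPT
    if (ea, oa) == (ref.other_allele, ref.effect_allele):
        return other.flipped(), SIGN_FLIPPED
    # strand rescue, single-base alleles only, after both direct comparisons fail
    if len(ea) == 1 and len(oa) == 1:
        cea, coa = _complement(ea), _complement(oa)
        if (cea, coa) == (ref.effect_allele, ref.other_allele):
            aligned = replace(other, effect_allele=cea, other_allele=coa)
            return aligned, STRAND_FLIPPED
        if (cea, coa) == (ref.other_allele, ref.effect_allele):
            aligned = replace(other, effect_allele=cea, other_allele=coa).flipped()
            return aligned, STRAND_FLIPPED
    return None, DROPPED_MISMATCH


def _palindromic_ok(records: list[SummaryStatRecord], limit: float) -> bool:
    """After label alignment: every trait's EAF known, on one common side of
    0.5 and at least ``limit`` away from it."""
    if any(not r.has_eaf for r in records):
        return False
    sides = [r.eaf > 0.5 for r in records]
    if any(abs(r.eaf - 0.5) < limit for r in records):
        return False
    return all(s == sides[0] for s in sides)


def harmonize(
    exposure: SummaryStatsTable,
    others: list[SummaryStatsTable],
    palindromic_eaf_limit: float = DEFAULT_PALINDROMIC_EAF_LIMIT,
) -> list[HarmonizedSet]:
    """Harmonize every variant shared by the exposure table and all
    ``others``; one :class:`HarmonizedSet` per shared variant, in exposure
    table order, including dropped variants (with reasons)."""
    shared = set(exposure.variant_ids)
    for t in others:
        shared &= set(t.variant_ids)
    if not shared:
        raise EmptyOverlapError("no variant shared across exposure and other tables")

    out: list[HarmonizedSet] = []
    for vid in exposure.variant_ids:
        if vid not in shared:
            continue
        ref = exposure.record(vid)
        hs = HarmonizedSet(
            variant_id=vid,
            effect_allele=ref.effect_allele,
            other_allele=ref.other_allele,
        )
        hs.stats[exposure.trait_name] = ref
        hs.actions[exposure.trait_name] = KEPT
        for t in others:
            aligned, action = _reconcile(ref, t.record(vid))
            hs.actions[t.trait_name] = action
            if aligned is None:
                hs.dropped = True
                hs.drop_reason = action
                break
            hs.stats[t.trait_name] = aligned
        if not hs.dropped and _is_palindromic(ref.effect_allele, ref.other_allele):
            if not _palindromic_ok(list(hs.stats.values()), palindromic_eaf_limit):
                hs.dropped = True
                hs.drop_reason = DROPPED_PALINDROMIC
                for t in others:
                    hs.actions[t.trait_name] = DROPPED_PALINDROMIC
                hs.actions[exposure.trait_name] = DROPPED_PALINDROMIC
                hs.stats.clear()
        out.append(hs)
    return out


def harmonized_frame(sets: list[HarmonizedSet], traits: list[str]) -> pd.DataFrame:
    """Wide per-variant frame (beta/se/eaf/pvalue/n per trait) over the
    retained sets."""
    rows = []
    for hs in sets:
        if hs.dropped:
            continue
        row = {"variant_id": hs.variant_id, "effect_allele": hs.effect_allele,
               "other_allele": hs.other_allele}
        for t in traits:
            r = hs.stats[t]
            row.update({
                f"beta_{t}": r.beta, f"se_{t}": r.se, f"eaf_{t}": r.eaf,
                f"pvalue_{t}": r.pvalue, f"n_{t}": r.n,
            })
        rows.append(row)
    return pd.DataFrame(rows)


def write_audit(sets: list[HarmonizedSet], path) -> None:
    """Per-variant, per-trait harmonization audit TSV."""
    rows = []
    for hs in sets:
        for trait, action in hs.actions.items():
            rows.append({
                "variant_id": hs.variant_id,
                "trait": trait,
                "action": action,
                "retained": not hs.dropped,
                "drop_reason": hs.drop_reason or "",
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
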