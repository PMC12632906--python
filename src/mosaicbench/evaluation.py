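"""Three-way call classification and stratified performance metrics.

Every reported call is classified against the truth as a true positive
(exact normalized-key match to a positive), a false positive (position
inside the negative-control set — negatives are non-variant *sites*, so
matching is positional), or masked (neither; excluded from all tallies to
avoid penalizing ambiguity). Sensitivity, precision and F1 are computed per
VAF bin and per genomic-context stratum (easy / difficult / extreme from a
pair of nested mappability masks).

Binning VAFs follows the dual rule used for the benchmark: truth-set
variants are binned by their pileup VAF in the evaluated mixture dataset
(permissive q=1/Q=1 tier), while calls outside the truth set fall back to
the VAF the caller reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CallRecord, CallSet, PileupSite, VafBinning, VariantKey
from .regions import GenomeRegions

__all__ = [
    "TruthSet",
    "assemble_truth",
    "classify_call",
    "eval_vaf",
    "compute_metrics",
    "stratify_position",
    "vaf_concordance",
]

STRATA = ("easy", "difficult", "extreme")


@dataclass
class TruthSet:
    """Positives (with provenance), negative positions/regions; everything
    else is implicitly masked."""

    positives: dict[VariantKey, str]
    negatives: GenomeRegions
    negative_positions: set[tuple[str, int]] = field(default_factory=set)

    def is_positive(self, key: VariantKey) -> bool:
        return key in self.positives

    def is_negative(self, chrom: str, pos: int) -> bool:
        return (chrom, pos) in self.negative_positions or self.negatives.contains(
            chrom, pos
        )


def assemble_truth(
    crossval_validated: Iterable[VariantKey],
    culture_set: Iterable[VariantKey] = (),
    negative_regions: GenomeRegions | None = None,
    negative_positions: Iterable[tuple[str, int]] = (),
) -> TruthSet:
    """Assemble the unified truth set; positives must not sit on negatives.

    Cross-validated and culture-derived variants are merged with provenance
    labels; a positive whose position falls inside the negative set is a
    construction error and aborts assembly, listing the offenders.
    """
    positives: dict[VariantKey, str] = {}
    for key in crossval_validated:
        positives[key] = "crossval"
    for key in culture_set:
        positives[key] = "culture"
    truth = TruthSet(
        positives=positives,
        negatives=negative_regions or GenomeRegions(),
        negative_positions=set(negative_positions),
    )
    conflicts = [k for k in positives if truth.is_negative(k.chrom, k.pos)]
    if conflicts:
        listing = ", ".join(str(k) for k in sorted(conflicts)[:10])
        raise ValueError(
            f"{len(conflicts)} positive(s) overlap the negative set: {listing}"
        )
    return truth


def classify_call(call: CallRecord, truth: TruthSet) -> str:
    """'TP' | 'FP' | 'masked' for one normalized call."""
    if truth.is_positive(call.key):
        return "TP"
    if truth.is_negative(call.key.chrom, call.key.pos):
        return "FP"
    return "masked"


def eval_vaf(
    call_key: VariantKey,
    is_truth: bool,
    mixture_pileups: Mapping[tuple[str, int], PileupSite] | None,
    caller_vaf: float | None,
) -> float | None:
    """VAF used for binning: pileup VAF for truth variants, caller VAF
    otherwise.

    A truth variant with no pileup row or zero/undefined pileup VAF bins at
    0 (first bin) — the variant exists but was unsampled in this dataset.
    Non-truth calls with no caller VAF return ``None`` and are excluded
    from binned metrics (still counted in unbinned totals).
    """
    if is_truth:
        pileup = (mixture_pileups or {}).get((call_key.chrom, call_key.pos))
        if pileup is None:
            return 0.0
        v = pileup.vaf(call_key.alt)
        return 0.0 if v is None else v
    return caller_vaf


def stratify_position(
    chrom: str,
    pos: int,
    mask_primary: GenomeRegions,
    mask_secondary: GenomeRegions,
) -> str:
    """Easy / difficult / extreme from two nested mappability masks.

    ``mask_primary`` is the strict short-read-callable mask (easy);
    ``mask_secondary`` the broader accessibility mask. In primary -> easy;
    in secondary only -> difficult; outside both -> extreme. A position in
    the primary but outside the secondary violates nesting and is classified
    easy with a consistency warning.
    """
    in_primary = mask_primary.contains(chrom, pos)
    in_secondary = mask_secondary.contains(chrom, pos)
    if in_primary:
        if not in_secondary:
            warnings.warn(
                f"{chrom}:{pos} inside primary mask but outside secondary; "
                "masks are expected to nest"
            )
        return "easy"
    if in_secondary:
        return "difficult"
    return "extreme"


def _f1(sens: float | None, prec: float | None) -> float | None:
    if sens is None or prec is None:
        return None
    if sens == 0 or prec == 0:
        return 0.0
    return 2 * sens * prec / (sens + prec)


def compute_metrics(
    calls: CallSet | Sequence[CallRecord],
    truth: TruthSet,
    binning: VafBinning | None = None,
    mixture_pileups: Mapping[tuple[str, int], PileupSite] | None = None,
    mask_primary: GenomeRegions | None = None,
    mask_secondary: GenomeRegions | None = None,
    sampled_only: bool = False,
) -> pd.DataFrame:
    """Sensitivity / precision / F1 per VAF bin and genomic stratum.

    FN are truth positives not present in the call set, binned by their
    pileup VAF in the evaluated dataset (0 when unsampled). With
    ``sampled_only`` the sensitivity denominator drops truth variants with
    no alternate read in the pileup; the default counts every positive, so
    unsampled truth variants depress sensitivity in the first bin.

    Returns a DataFrame indexed by (bin, stratum) — stratum 'all' when no
    masks are given — with TP/FP/FN/masked counts and the three metrics
    (NaN where undefined, e.g. precision with no calls).
    """
    binning = binning or VafBinning()
    records = list(calls.records if isinstance(calls, CallSet) else calls)
    keys = {r.key for r in records}
    if len(keys) != len(records):
        raise ValueError("duplicate keys in call set")

    def stratum(chrom: str, pos: int) -> str:
        if mask_primary is None or mask_secondary is None:
            return "all"
        return stratify_position(chrom, pos, mask_primary, mask_secondary)

    strata = STRATA if mask_primary is not None else ("all",)
    index = pd.MultiIndex.from_product(
        [binning.all_labels, strata], names=["bin", "stratum"]
    )
    table = pd.DataFrame(
        0, index=index, columns=["TP", "FP", "FN", "masked"], dtype=int
    )
    unbinned_masked = 0

    for rec in records:
        cls = classify_call(rec, truth)
        if cls == "masked":
            unbinned_masked += 1
            continue
        v = eval_vaf(
            rec.key, truth.is_positive(rec.key), mixture_pileups, rec.caller_vaf
        )
        if v is None:
            unbinned_masked += 1
            continue
        b = binning.assign(min(v, 1.0))
        table.loc[(b, stratum(rec.key.chrom, rec.key.pos)), cls] += 1

    for key in truth.positives:
        if key in keys:
            continue
        v = eval_vaf(key, True, mixture_pileups, None)
        if sampled_only and v == 0.0:
            continue
        b = binning.assign(min(v, 1.0))
        table.loc[(b, stratum(key.chrom, key.pos)), "FN"] += 1

    table.attrs["unbinned_masked"] = unbinned_masked
    with np.errstate(invalid="ignore", divide="ignore"):
        tp = table["TP"].to_numpy(float)
        sens = tp / (tp + table["FN"].to_numpy(float))
        prec = tp / (tp + table["FP"].to_numpy(float))
    table["sensitivity"] = sens
    table["precision"] = prec
    f1 = 2 * sens * prec / (sens + prec)
    f1[(sens == 0) | (prec == 0)] = 0.0
    table["f1"] = f1
    return table


def vaf_concordance(
    expected: Sequence[float],
    observed: Sequence[float],
    tolerance_rule: Mapping[float, tuple[float, float]] | None = None,
    levels: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Per-variant concordance of caller VAF with the designed mixture VAF.

    ``tolerance_rule`` maps each expected-VAF level to its acceptance
    interval. By default the interval around each design level extends half
    way to the adjacent levels (closed), so every observation is judged
    against the nearest achievable design VAF. Returns a per-level table
    (n, concordant fraction) plus an 'overall' row; the Pearson correlation
    between expected and observed is stored in ``attrs['pearson_r']``.
    """
    expected = np.asarray(expected, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if expected.size == 0 or expected.shape != observed.shape:
        raise ValueError("expected/observed must be equal-length, non-empty")

    if levels is None:
        levels = sorted(set(np.round(expected, 12)))
    levels = list(levels)
    if tolerance_rule is None:
        tolerance_rule = {}
        for i, lv in enumerate(levels):
            lo = (levels[i - 1] + lv) / 2 if i > 0 else 0.0
            hi = (lv + levels[i + 1]) / 2 if i + 1 < len(levels) else 1.0
            tolerance_rule[lv] = (lo, hi)

    rows = []
    concordant_total = 0
    for lv in levels:
        sel = np.isclose(expected, lv)
        n = int(sel.sum())
        if n == 0:
            rows.append({"expected_vaf": lv, "n": 0, "concordant": np.nan})
            continue
        lo, hi = tolerance_rule[lv]
        ok = int(((observed[sel] >= lo) & (observed[sel] <= hi)).sum())
        concordant_total += ok
        rows.append({"expected_vaf": lv, "n": n, "concordant": ok / n})
    out = pd.DataFrame(rows).set_index("expected_vaf")
    out.loc["overall"] = {
        "n": expected.size,
        "concordant": concordant_total / expected.size,
    }
    if np.std(expected) > 0 and np.std(observed) > 0:
        out.attrs["pearson_r"] = float(np.corrcoef(expected, observed)[0, 1])
    else:
        out.attrs["pearson_r"] = np.nan
    return out
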