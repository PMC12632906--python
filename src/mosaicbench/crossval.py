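"""Candidate merging and orthogonal validation of short-read variant calls.

Candidates discovered by complementary short-read callers are merged into a
unified set, then each is tested against long-read pileup evidence from the
tumor line and its matched normal. An SNV is validated when at least two
long reads carry the alternate allele in the tumor, none do in the normal,
and the allele is not superseded by a stronger competing allele at a
multi-allelic locus. Indels additionally face an exact binomial
allelic-imbalance test against the heterozygous expectation (p > 0.05), a
tumor VAF floor (> 0.2 in both long- and short-read data), a normal VAF
ceiling (< 0.05 in short-read data), and a 50 bp length cap.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import binomtest

from .core import (
    CallSet,
    IndelReadClassification,
    PileupSite,
    VariantKey,
)

__all__ = [
    "ValidationStatus",
    "ValidationVerdict",
    "merge_candidates",
    "resolve_multiallelic",
    "validate_snv",
    "binomial_het_pvalue",
    "classify_indel_reads",
    "validate_indel",
]


class ValidationStatus(enum.Enum):
    VALIDATED = "validated"
    NO_TUMOR_SUPPORT = "no_tumor_support"
    NORMAL_SUPPORT = "normal_support"
    SUPERSEDED_MULTIALLELIC = "superseded_multiallelic"
    ALLELIC_IMBALANCE_FAIL = "allelic_imbalance_fail"
    TUMOR_VAF_FAIL = "tumor_vaf_fail"
    NORMAL_VAF_FAIL = "normal_vaf_fail"
    LENGTH_FAIL = "length_fail"
    EVIDENCE_MISSING = "evidence_missing"


@dataclass(frozen=True)
class ValidationVerdict:
    """Outcome of validating one candidate, with the evidence used."""

    key: VariantKey
    status: ValidationStatus
    evidence: dict = field(default_factory=dict, hash=False, compare=False)

    @property
    def validated(self) -> bool:
        return self.status is ValidationStatus.VALIDATED


def merge_candidates(
    callsets: Sequence[CallSet],
    pass_only: bool = True,
    max_indel_len: int = 49,
) -> pd.DataFrame:
    """Union of caller call sets keyed by normalized variant.

    Only PASS-equivalent records are kept (``pass_only``) and indels longer
    than ``max_indel_len`` bases are dropped at this stage. Returns a
    DataFrame indexed by VariantKey with one boolean provenance column per
    caller plus ``caller_count``. A call set containing duplicate keys is
    rejected by ``CallSet`` itself on construction.
    """
    if not callsets:
        raise ValueError("no call sets supplied")
    names = [cs.caller for cs in callsets]
    if len(names) != len(set(names)):
        raise ValueError("caller names must be unique across call sets")

    provenance: dict[VariantKey, set[str]] = {}
    for cs in callsets:
        for rec in cs:
            if pass_only and not rec.is_pass:
                continue
            if rec.key.is_indel and rec.key.indel_length > max_indel_len:
                continue
            provenance.setdefault(rec.key, set()).add(cs.caller)

    keys = sorted(provenance)
    table = pd.DataFrame(
        {name: [name in provenance[k] for k in keys] for name in names},
        index=pd.Index(keys, name="key"),
    )
    table["caller_count"] = table[names].sum(axis=1).astype(int)
    return table


def resolve_multiallelic(tumor_pileup: PileupSite) -> str | None:
    """Major alternate allele by tumor read count; lexicographic tie-break.

    Returns ``None`` when no alternate reads are present (no majority).
    """
    alts = tumor_pileup.alt_counts()
    if not alts:
        return None
    return min(alts, key=lambda a: (-alts[a], a))


def validate_snv(
    key: VariantKey,
    pb_tumor: PileupSite | None,
    pb_normal: PileupSite | None,
    min_support: int = 2,
) -> ValidationVerdict:
    """Validate an SNV candidate against long-read tumor/normal pileups.

    Validated iff the tumor carries >= ``min_support`` reads of the target
    allele, the normal carries none, and the target is the major alternate
    at its locus. Missing pileup evidence yields ``EVIDENCE_MISSING`` (the
    variant is masked downstream rather than rejected, so absent long-read
    coverage does not manufacture false negatives in the truth set).
    """
    if pb_tumor is None or pb_normal is None:
        return ValidationVerdict(key, ValidationStatus.EVIDENCE_MISSING)
    tumor_count = pb_tumor.count(key.alt)
    normal_count = pb_normal.count(key.alt)
    evidence = {
        "tumor_depth": pb_tumor.depth,
        "tumor_alt": tumor_count,
        "normal_depth": pb_normal.depth,
        "normal_alt": normal_count,
    }
    if tumor_count < min_support:
        return ValidationVerdict(key, ValidationStatus.NO_TUMOR_SUPPORT, evidence)
    if normal_count > 0:
        return ValidationVerdict(key, ValidationStatus.NORMAL_SUPPORT, evidence)
    major = resolve_multiallelic(pb_tumor)
    if major is not None and major != key.alt:
        evidence["major_alt"] = major
        return ValidationVerdict(
            key, ValidationStatus.SUPERSEDED_MULTIALLELIC, evidence
        )
    return ValidationVerdict(key, ValidationStatus.VALIDATED, evidence)


def binomial_het_pvalue(depth: int, alt_count: int) -> float:
    """Exact two-sided binomial test of k alt reads in N against p = 0.5.

    Two-sided by the minimum-likelihood convention: the p-value sums the
    probabilities of all outcomes no more likely than the observed one.
    Used to separate genuinely heterozygous indels from subclonal events
    and stutter artifacts, which deviate from the 50:50 expectation.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0 <= alt_count <= depth:
        raise ValueError(f"alt count {alt_count} outside [0, {depth}]")
    return binomtest(alt_count, depth, 0.5, alternative="two-sided").pvalue


@dataclass(frozen=True)
class BreakpointRead:
    """Abstraction of one read overlapping an indel breakpoint: its mapping
    quality and the local aligned sequence across the breakpoint window."""

    mapq: int
    local_seq: str


def classify_indel_reads(
    reads: Iterable[BreakpointRead | tuple[int, str]],
    target_indel: VariantKey,
    min_mapq: int = 1,
) -> IndelReadClassification:
    """Tally reads at an indel breakpoint as ref / target-alt / other-alt.

    A read supports the reference when its local sequence equals the ref
    allele, the target when it equals the alt allele; anything else is
    tallied per distinct sequence in ``other_alt``. Reads below ``min_mapq``
    are excluded entirely (an empty read set yields depth 0, AF undefined).
    """
    ref_n = 0
    alt_n = 0
    other: dict[str, int] = {}
    depth = 0
    for read in reads:
        if isinstance(read, tuple):
            read = BreakpointRead(*read)
        if read.mapq < min_mapq:
            continue
        depth += 1
        if read.local_seq == target_indel.ref:
            ref_n += 1
        elif read.local_seq == target_indel.alt:
            alt_n += 1
        else:
            other[read.local_seq] = other.get(read.local_seq, 0) + 1
    return IndelReadClassification(
        depth=depth, ref_support=ref_n, target_alt_support=alt_n, other_alt=other
    )


def validate_indel(
    key: VariantKey,
    pb_tumor: IndelReadClassification,
    il_tumor: IndelReadClassification,
    il_normal: IndelReadClassification,
    min_pb_support: int = 2,
    max_length: int = 50,
    het_p_threshold: float = 0.05,
    tumor_vaf_floor: float = 0.2,
    normal_vaf_ceiling: float = 0.05,
) -> ValidationVerdict:
    """Validate an indel candidate against long- and short-read evidence.

    Checks, in order: length <= ``max_length``; long-read tumor support >=
    ``min_pb_support``; exact binomial heterozygous test p > 0.05 on the
    long-read tumor counts; tumor AF > 0.2 in both long- and short-read
    data; short-read normal AF < 0.05. Inequalities are strict exactly as
    stated; boundary values fail. Undefined AF (depth 0) in any required
    sample yields ``EVIDENCE_MISSING``.
    """
    evidence = {
        "length": key.indel_length,
        "pb_tumor_depth": pb_tumor.depth,
        "pb_tumor_dtv": pb_tumor.target_alt_support,
        "il_tumor_af": il_tumor.af,
        "il_normal_af": il_normal.af,
    }
    if key.indel_length > max_length:
        return ValidationVerdict(key, ValidationStatus.LENGTH_FAIL, evidence)
    if pb_tumor.af is None or il_tumor.af is None or il_normal.af is None:
        return ValidationVerdict(key, ValidationStatus.EVIDENCE_MISSING, evidence)
    if pb_tumor.target_alt_support < min_pb_support:
        return ValidationVerdict(key, ValidationStatus.NO_TUMOR_SUPPORT, evidence)
    pval = binomial_het_pvalue(pb_tumor.depth, pb_tumor.target_alt_support)
    evidence["het_pvalue"] = pval
    if not pval > het_p_threshold:
        return ValidationVerdict(key, ValidationStatus.ALLELIC_IMBALANCE_FAIL, evidence)
    if not (pb_tumor.af > tumor_vaf_floor and il_tumor.af > tumor_vaf_floor):
        return ValidationVerdict(key, ValidationStatus.TUMOR_VAF_FAIL, evidence)
    if not il_normal.af < normal_vaf_ceiling:
        return ValidationVerdict(key, ValidationStatus.NORMAL_VAF_FAIL, evidence)
    return ValidationVerdict(key, ValidationStatus.VALIDATED, evidence)
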