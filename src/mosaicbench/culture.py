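"""Discovery of culture-derived mutations from multi-replicate call sets.

Immortalized cell lines acquire de novo mutations across passages, so an
admixture prepared from later harvests can carry real variants absent from
the parental reference data. Those surface as apparent false positives.
The screen here: (1) drop reference-set variants from each replicate's
merged call set and count in how many of the n replicates each remaining
variant appears; (2) require long-read support in the admixture dataset
while excluding sites "confirmed" in an unrelated control dataset; (3)
categorize provenance against the pure parental lines and the
negative-control regions, keeping only sites with no parental evidence
inside confidently non-variant territory.
"""

from __future__ import annotations

import enum
from collections import Counter
from typing import Iterable, Mapping, Sequence

from .core import CallSet, PileupSite, VariantKey
from .regions import GenomeRegions

__all__ = [
    "replicate_sharing",
    "SupportFlag",
    "longread_support_screen",
    "Provenance",
    "categorize_provenance",
    "culture_reference_set",
]


def replicate_sharing(
    callsets: Sequence[CallSet],
    refset: Iterable[VariantKey] = (),
) -> tuple[dict[VariantKey, int], dict[int, int]]:
    """Replicate-sharing analysis of admixture-specific variants.

    ``callsets`` holds one merged call set per replicate; any variant also
    present in ``refset`` is removed before counting. Returns
    ``(per-variant j, class sizes)`` where ``j`` is the number of replicates
    containing the variant and class sizes cover j = 1..n (upset-plot
    intersection totals).
    """
    n = len(callsets)
    if n < 2:
        raise ValueError("sharing analysis needs >= 2 replicates")
    reference = set(refset)
    counts: Counter[VariantKey] = Counter()
    for cs in callsets:
        counts.update(cs.keys() - reference)
    sharing = dict(counts)
    class_sizes = {j: 0 for j in range(1, n + 1)}
    for j in sharing.values():
        class_sizes[j] += 1
    return sharing, class_sizes


class SupportFlag(enum.Enum):
    SUPPORTED = "supported"
    SPURIOUS = "spurious"          # confirmed in the unrelated control too
    UNSUPPORTED = "unsupported"
    EVIDENCE_MISSING = "evidence_missing"


def longread_support_screen(
    sites: Iterable[VariantKey],
    admix_pileups: Mapping[tuple[str, int], PileupSite],
    control_pileups: Mapping[tuple[str, int], PileupSite],
    min_support: int = 2,
    control_threshold: int | None = None,
) -> dict[VariantKey, SupportFlag]:
    """Long-read support screen with spurious-confirmation control.

    A site is ``SUPPORTED`` when the admixture long-read dataset carries
    >= ``min_support`` reads of the mutant allele while the unrelated
    control dataset stays below ``control_threshold`` (defaults to
    ``min_support``, mirroring the admixture rule); control support at or
    above the threshold flags the locus ``SPURIOUS`` regardless of the
    admixture evidence.
    """
    if control_threshold is None:
        control_threshold = min_support
    flags: dict[VariantKey, SupportFlag] = {}
    for key in sites:
        locus = (key.chrom, key.pos)
        admix = admix_pileups.get(locus)
        control = control_pileups.get(locus)
        if admix is None or control is None:
            flags[key] = SupportFlag.EVIDENCE_MISSING
            continue
        if control.count(key.alt) >= control_threshold:
            flags[key] = SupportFlag.SPURIOUS
        elif admix.count(key.alt) >= min_support:
            flags[key] = SupportFlag.SUPPORTED
        else:
            flags[key] = SupportFlag.UNSUPPORTED
    return flags


class Provenance(enum.Enum):
    ADMIXTURE_ONLY = "admixture_only"    # culture-derived in the mixture
    NORMAL_LINE_ONLY = "normal_line_only"
    REJECTED = "rejected"


def categorize_provenance(
    key: VariantKey,
    tumor_pileups: Sequence[PileupSite],
    normal_pileups: Sequence[PileupSite],
    negative_regions: GenomeRegions,
) -> Provenance:
    """Categorize one screened site against the pure parental lines.

    ``tumor_pileups`` / ``normal_pileups`` carry evidence from the pure
    lines across platforms (long- and short-read). A site with >= 1
    supporting read in the normal line and none in the tumor is a
    normal-line-only mutation; one with no evidence in either pure line and
    lying inside the negative-control regions is admixture-only (culture-
    derived); everything else is rejected as ambiguous.
    """
    tumor_support = sum(p.count(key.alt) for p in tumor_pileups)
    normal_support = sum(p.count(key.alt) for p in normal_pileups)
    if normal_support >= 1 and tumor_support == 0:
        return Provenance.NORMAL_LINE_ONLY
    if normal_support == 0 and tumor_support == 0:
        if negative_regions.contains(key.chrom, key.pos):
            return Provenance.ADMIXTURE_ONLY
        return Provenance.REJECTED
    return Provenance.REJECTED


def culture_reference_set(
    sharing: Mapping[VariantKey, int],
    support: Mapping[VariantKey, SupportFlag],
    provenance: Mapping[VariantKey, Provenance],
) -> set[VariantKey]:
    """Final high-confidence culture-derived set: long-read supported,
    admixture-only, not spurious."""
    return {
        key
        for key in sharing
        if support.get(key) is SupportFlag.SUPPORTED
        and provenance.get(key) is Provenance.ADMIXTURE_ONLY
    }
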