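"""Negative-control (confident non-variant) site construction.

Candidate loci — putative homozygous-reference positions shared by the
tumor line and its matched normal, supplied by upstream germline
genotyping — are classified by an iterative two-tier long-read pileup
procedure: sites clean at a permissive tier (q=1, Q=1) are negatives
outright; sites with residual alternate evidence are re-examined at a
stringent tier (q=30, Q=30) and removed if the evidence survives;
otherwise the permissive-tier allele is checked against short-read data,
and only cross-platform-corroborated alleles disqualify the site.

Germline call curation uses the GATK-style hard filters as printed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .core import PileupSite

__all__ = ["SiteLabel", "SiteClassification", "classify_nonvariant_site", "germline_hard_filter"]


class SiteLabel(enum.Enum):
    NEGATIVE = "negative"                       # clean at the permissive tier
    REMOVED_HIGHQ_ALT = "removed_highq_alt"     # alt survives the stringent tier
    EXCLUDED_BOTH_PLATFORMS = "excluded_both_platforms"  # short-read corroboration
    NEGATIVE_RETAINED = "negative_retained"     # permissive-tier noise only
    EVIDENCE_MISSING = "evidence_missing"

    @property
    def is_negative(self) -> bool:
        return self in (SiteLabel.NEGATIVE, SiteLabel.NEGATIVE_RETAINED)


@dataclass(frozen=True)
class SiteClassification:
    chrom: str
    pos: int
    label: SiteLabel
    evidence: dict = field(default_factory=dict, hash=False, compare=False)


def _low_tier_alt_alleles(*pileups: PileupSite) -> set[str]:
    alleles: set[str] = set()
    for p in pileups:
        alleles |= set(p.alt_counts())
    return alleles


def classify_nonvariant_site(
    pb_tumor_lowq: PileupSite | None,
    pb_normal_lowq: PileupSite | None,
    pb_tumor_highq: PileupSite | None,
    pb_normal_highq: PileupSite | None,
    il_tumor_lowq: PileupSite | None = None,
    il_normal_lowq: PileupSite | None = None,
) -> SiteClassification:
    """Classify one candidate homozygous-reference locus.

    Step 1: no alternate read in either sample at the permissive long-read
    tier -> ``NEGATIVE``. Step 2: any alternate read at the stringent tier
    -> ``REMOVED_HIGHQ_ALT``. Step 3: a permissive-tier alternate allele
    also seen in >=1 short-read (either sample) -> ``EXCLUDED_BOTH_PLATFORMS``
    (the same allele must co-occur — allele-agnostic co-support does not
    count); otherwise ``NEGATIVE_RETAINED``. Missing required evidence at
    the step that needs it leaves the site ``EVIDENCE_MISSING`` (masked).
    """
    if pb_tumor_lowq is None or pb_normal_lowq is None:
        return SiteClassification("?", 0, SiteLabel.EVIDENCE_MISSING)
    chrom, pos = pb_tumor_lowq.chrom, pb_tumor_lowq.pos

    low_alts = _low_tier_alt_alleles(pb_tumor_lowq, pb_normal_lowq)
    if not low_alts:
        return SiteClassification(chrom, pos, SiteLabel.NEGATIVE)

    if pb_tumor_highq is None or pb_normal_highq is None:
        return SiteClassification(
            chrom, pos, SiteLabel.EVIDENCE_MISSING, {"low_tier_alts": sorted(low_alts)}
        )
    high_alt_total = pb_tumor_highq.total_alt() + pb_normal_highq.total_alt()
    if high_alt_total > 0:
        return SiteClassification(
            chrom,
            pos,
            SiteLabel.REMOVED_HIGHQ_ALT,
            {"low_tier_alts": sorted(low_alts), "high_tier_alt_reads": high_alt_total},
        )

    il_pileups = [p for p in (il_tumor_lowq, il_normal_lowq) if p is not None]
    if not il_pileups:
        return SiteClassification(
            chrom, pos, SiteLabel.EVIDENCE_MISSING, {"low_tier_alts": sorted(low_alts)}
        )
    corroborated = {
        a for a in low_alts if any(p.count(a) >= 1 for p in il_pileups)
    }
    if corroborated:
        return SiteClassification(
            chrom,
            pos,
            SiteLabel.EXCLUDED_BOTH_PLATFORMS,
            {"corroborated_alts": sorted(corroborated)},
        )
    return SiteClassification(
        chrom, pos, SiteLabel.NEGATIVE_RETAINED, {"low_tier_alts": sorted(low_alts)}
    )


#: (metric, predicate, human-readable rule) — a call FAILS when the predicate holds
_HARD_FILTER_RULES = (
    ("QD", lambda v: v < 2.0, "QD < 2.0"),
    ("FS", lambda v: v > 60.0, "FS > 60"),
    ("DP", lambda v: v < 10, "DP < 10"),
    ("ReadPosRankSum", lambda v: v < -8.0, "ReadPosRankSum < -8.0"),
    ("MQRankSum", lambda v: v < -2.5 or v > 2.5, "MQRankSum < -2.5 or > 2.5"),
)


def germline_hard_filter(
    QD: float | None = None,
    FS: float | None = None,
    DP: float | None = None,
    ReadPosRankSum: float | None = None,
    MQRankSum: float | None = None,
) -> tuple[bool, list[str]]:
    """Apply the germline hard-filter rules to one call's annotations.

    Returns ``(passed, failed_rules)``. A ``None`` metric skips its rule
    (annotation absent, e.g. RankSum metrics at homozygous sites).
    """
    metrics = {
        "QD": QD,
        "FS": FS,
        "DP": DP,
        "ReadPosRankSum": ReadPosRankSum,
        "MQRankSum": MQRankSum,
    }
    failed = [
        rule
        for name, pred, rule in _HARD_FILTER_RULES
        if metrics[name] is not None and pred(metrics[name])
    ]
    return (not failed, failed)
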