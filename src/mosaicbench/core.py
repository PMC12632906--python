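"""Shared domain types: variant identity, pileups, VAF arithmetic and binning.

Variant identity throughout the package is the normalized
``(chrom, pos, ref, alt)`` tuple: multi-allelic records are split into
single-allele records, indels are trimmed to their minimal representation
and left-aligned against the reference, and matching between call sets and
truth sets is exact on that tuple. Positions are 1-based (VCF convention);
BED inputs are converted at the I/O boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

__all__ = [
    "VariantKey",
    "QualityTier",
    "PileupSite",
    "IndelReadClassification",
    "CallRecord",
    "CallSet",
    "VafBinning",
    "normalize_variant",
    "VariantFormatError",
]

_DNA = re.compile(r"^[ACGTN]+$")


class VariantFormatError(ValueError):
    """Raised for malformed alleles (empty or non-DNA characters)."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """Normalized identity of a single-allele variant.

    Parameters
    ----------
    chrom : str
        Chromosome / contig name.
    pos : int
        1-based reference position of the first allele base.
    ref, alt : str
        Reference and (single) alternate allele, uppercase DNA.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        for allele in (self.ref, self.alt):
            if not allele or not _DNA.match(allele):
                raise VariantFormatError(
                    f"illegal allele {allele!r} at {self.chrom}:{self.pos}"
                )
        if self.ref == self.alt:
            raise VariantFormatError(
                f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}"
            )
        if self.pos < 1:
            raise VariantFormatError(f"position must be 1-based, got {self.pos}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return not self.is_snv

    @property
    def indel_length(self) -> int:
        """Net inserted/deleted bases; 0 for SNVs."""
        return abs(len(self.ref) - len(self.alt))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class QualityTier:
    """Pileup extraction thresholds: min mapping quality q, min base quality Q."""

    q: int
    Q: int
    max_depth: int | None = None

    def __str__(self) -> str:
        cap = f",maxdp={self.max_depth}" if self.max_depth is not None else ""
        return f"q{self.q}Q{self.Q}{cap}"


# the tiers the benchmarking workflow uses, named for reuse
TIER_MAIN = QualityTier(q=1, Q=20, max_depth=3000)   # long-read validation pileups
TIER_LOW = QualityTier(q=1, Q=1)                     # negative-control pass 1 / eval VAF
TIER_HIGH = QualityTier(q=30, Q=30)                  # negative-control pass 2 / HapMap sampling


@dataclass
class PileupSite:
    """Per-sample allele read counts at one site under a stated quality tier."""

    chrom: str
    pos: int
    ref: str
    sample: str
    depth: int
    allele_counts: dict[str, int]
    tier: QualityTier

    def __post_init__(self) -> None:
        if self.depth < 0 or any(c < 0 for c in self.allele_counts.values()):
            raise ValueError("negative depth or allele count")
        if sum(self.allele_counts.values()) > self.depth:
            raise ValueError(
                f"allele counts exceed depth at {self.chrom}:{self.pos} "
                f"({self.allele_counts} > {self.depth})"
            )

    def count(self, allele: str) -> int:
        return self.allele_counts.get(allele, 0)

    def vaf(self, allele: str) -> float | None:
        """Allele fraction count/depth; ``None`` (undefined) when depth == 0.

        Depth-0 sites are deliberately *not* reported as VAF 0 so that an
        unsampled truth variant can be distinguished from one sampled with
        zero alternate reads; callers choose how to handle ``None``.
        """
        if self.depth == 0:
            return None
        return self.count(allele) / self.depth

    def alt_counts(self) -> dict[str, int]:
        """Counts of every allele other than the reference."""
        return {a: c for a, c in self.allele_counts.items() if a != self.ref and c > 0}

    def total_alt(self) -> int:
        return sum(self.alt_counts().values())


@dataclass
class IndelReadClassification:
    """Read-level support tally for a candidate indel at its breakpoint.

    ``ref_support`` (DR) counts reads matching the reference allele,
    ``target_alt_support`` (DTV) reads matching the candidate indel, and
    ``other_alt`` tallies every non-target alternate sequence observed.
    """

    depth: int
    ref_support: int
    target_alt_support: int
    other_alt: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref_support + self.target_alt_support + sum(self.other_alt.values()) > self.depth:
            raise ValueError("support counts exceed depth")

    @property
    def af(self) -> float | None:
        """Target-allele fraction DTV/depth; undefined at depth 0."""
        if self.depth == 0:
            return None
        return self.target_alt_support / self.depth


@dataclass(frozen=True)
class CallRecord:
    """One normalized call from a variant caller."""

    key: VariantKey
    caller_vaf: float | None = None
    filters: frozenset[str] = frozenset({"PASS"})

    @property
    def is_pass(self) -> bool:
        return self.filters <= {"PASS", "."} or not self.filters


@dataclass
class CallSet:
    """All calls from one caller on one dataset; keys unique after normalization."""

    caller: str
    dataset: str
    records: list[CallRecord]

    def __post_init__(self) -> None:
        keys = [r.key for r in self.records]
        if len(keys) != len(set(keys)):
            raise ValueError(f"duplicate variant keys in call set {self.caller}/{self.dataset}")

    def keys(self) -> set[VariantKey]:
        return {r.key for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


# ---------------------------------------------------------------------------
# VAF binning

#: Default evaluation bins: 0–0.5%, 0.5–1%, 1–1.5%, 1.5–2%, 2–3%, plus an
#: explicit overflow bin for everything at or above 3%.
DEFAULT_BIN_EDGES = (0.0, 0.005, 0.01, 0.015, 0.02, 0.03)


@dataclass(frozen=True)
class VafBinning:
    """Half-open VAF bins [e_i, e_{i+1}) over strictly increasing edges.

    Values at or above the last edge fall in a separately reported overflow
    bin covering [last edge, 1].
    """

    edges: tuple[float, ...] = DEFAULT_BIN_EDGES

    def __post_init__(self) -> None:
        if len(self.edges) < 2 or any(
            b <= a for a, b in zip(self.edges, self.edges[1:])
        ):
            raise ValueError("bin edges must be strictly increasing, length >= 2")
        if self.edges[0] < 0 or self.edges[-1] > 1:
            raise ValueError("bin edges must lie in [0, 1]")

    @staticmethod
    def _fmt(x: float) -> str:
        pct = x * 100
        return f"{pct:g}"

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(
            f"{self._fmt(a)}-{self._fmt(b)}%"
            for a, b in zip(self.edges, self.edges[1:])
        )

    @property
    def overflow_label(self) -> str:
        return f">={self._fmt(self.edges[-1])}%"

    @property
    def all_labels(self) -> tuple[str, ...]:
        return self.labels + (self.overflow_label,)

    def assign(self, v: float) -> str:
        """Bin label for VAF ``v``; left-closed/right-open intervals."""
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"VAF {v} outside [0, 1]")
        if v < self.edges[0]:
            raise ValueError(f"VAF {v} below first bin edge {self.edges[0]}")
        for a, b, label in zip(self.edges, self.edges[1:], self.labels):
            if a <= v < b:
                return label
        return self.overflow_label


def assign_bin(v: float, binning: VafBinning | None = None) -> str:
    """Functional form of :meth:`VafBinning.assign` with default bins."""
    return (binning or VafBinning()).assign(v)


# ---------------------------------------------------------------------------
# Normalization

RefFetch = Callable[[str, int, int], str]
"""Reference accessor: fetch(chrom, start, end) -> sequence, 1-based inclusive."""


def _as_fetch(reference: Mapping[str, str] | RefFetch | None) -> RefFetch | None:
    if reference is None:
        return None
    if callable(reference):
        return reference

    def fetch(chrom: str, start: int, end: int) -> str:
        return reference[chrom][start - 1 : end]

    return fetch


def _trim(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    # drop shared suffix (keep >= 1 base each), then shared prefix
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _left_align(
    chrom: str, pos: int, ref: str, alt: str, fetch: RefFetch
) -> tuple[int, str, str]:
    # standard left-shift: while alleles share their last base, rotate the
    # event leftwards by prepending the preceding reference base
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos == 1:
                    # cannot extend left of the contig; restore padding base
                    base = fetch(chrom, pos, pos)
                    ref, alt = base + ref, base + alt
                    break
                base = fetch(chrom, pos - 1, pos - 1)
                pos -= 1
                ref, alt = base + ref, base + alt
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def normalize_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt_list: Sequence[str],
    reference: Mapping[str, str] | RefFetch | None = None,
) -> list[VariantKey]:
    """Split a (possibly multi-allelic) record into normalized VariantKeys.

    Each alternate allele becomes its own key; shared prefix/suffix bases
    are trimmed to the minimal representation and, when a ``reference``
    accessor is supplied, indels are shifted to their 5'-most (left-aligned)
    position. SNVs pass through unchanged. Idempotent on its own output.

    ``reference`` may be a mapping chrom -> full contig sequence or a
    callable ``fetch(chrom, start, end)`` with 1-based inclusive coordinates.
    Without it, trimming is still performed but events that would shift past
    their own padding base stay where they are.
    """
    ref = ref.upper()
    if not ref or not _DNA.match(ref):
        raise VariantFormatError(f"illegal ref allele {ref!r}")
    fetch = _as_fetch(reference)
    out: list[VariantKey] = []
    for alt in alt_list:
        alt = alt.upper()
        if not alt or not _DNA.match(alt):
            raise VariantFormatError(f"illegal alt allele {alt!r}")
        p, r, a = _trim(pos, ref, alt)
        if len(r) != len(a) and fetch is not None:
            p, r, a = _left_align(chrom, p, r, a, fetch)
        out.append(VariantKey(chrom, p, r, a))
    return out
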