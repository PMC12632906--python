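"""Readers and writers for the external formats the workflow exchanges.

VCF 4.x records are read with cyvcf2 and normalized on the way in (only
CHROM/POS/REF/ALT/FILTER and a VAF-like INFO/FORMAT field are consumed).
Pileups travel as a TSV dialect: a ``#tier`` header line recording the
quality tier, then ``chrom pos ref sample depth allele:count...`` rows.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

from cyvcf2 import VCF

from .core import (
    CallRecord,
    CallSet,
    PileupSite,
    QualityTier,
    VariantKey,
    normalize_variant,
)

__all__ = [
    "read_callset_vcf",
    "write_variants_vcf",
    "read_pileup_tsv",
    "write_pileup_tsv",
]

_VAF_INFO_KEYS = ("AF", "VAF")


def _record_vaf(variant, alt_index: int) -> float | None:
    for key in _VAF_INFO_KEYS:
        value = variant.INFO.get(key)
        if value is None:
            continue
        if isinstance(value, tuple):
            value = value[alt_index] if alt_index < len(value) else value[0]
        return float(value)
    # fall back to the first sample's FORMAT/AF
    try:
        af = variant.format("AF")
    except KeyError:
        af = None
    if af is not None and af.size:
        return float(af.flat[min(alt_index, af.size - 1)])
    return None


def read_callset_vcf(
    path: str | Path,
    caller: str,
    dataset: str = "",
    reference: Mapping[str, str] | None = None,
    pass_only: bool = False,
) -> CallSet:
    """Read a caller VCF into a normalized :class:`CallSet`.

    Multi-allelic records are split; alleles are trimmed/left-aligned when a
    ``reference`` mapping is given. Records sharing a normalized key keep
    the first occurrence's VAF (duplicates within one file are an error,
    enforced by ``CallSet``).
    """
    records: list[CallRecord] = []
    for variant in VCF(str(path)):
        filters = frozenset((variant.FILTER or "PASS").split(";"))
        if pass_only and not filters <= {"PASS", "."}:
            continue
        keys = normalize_variant(
            variant.CHROM, variant.POS, variant.REF, variant.ALT, reference
        )
        for i, key in enumerate(keys):
            records.append(
                CallRecord(key=key, caller_vaf=_record_vaf(variant, i), filters=filters)
            )
    return CallSet(caller=caller, dataset=dataset, records=records)


def write_variants_vcf(
    path: str | Path,
    variants: Iterable[tuple[VariantKey, Mapping[str, object]]],
    contigs: Mapping[str, int] | None = None,
    info_fields: Mapping[str, tuple[str, str]] | None = None,
    source: str = "mosaicbench",
) -> None:
    """Write (VariantKey, info-dict) pairs as a minimal sites-only VCF."""
    info_fields = info_fields or {}
    lines = ["##fileformat=VCFv4.2", f"##source={source}"]
    for chrom, length in (contigs or {}).items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    for key, (num_type, desc) in info_fields.items():
        number, vtype = num_type.split(":")
        lines.append(
            f'##INFO=<ID={key},Number={number},Type={vtype},Description="{desc}">'
        )
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    rows = sorted(variants, key=lambda kv: (kv[0].chrom, kv[0].pos, kv[0].ref, kv[0].alt))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for key, info in rows:
            info_str = (
                ";".join(f"{k}={v}" for k, v in info.items()) if info else "."
            )
            fh.write(
                f"{key.chrom}\t{key.pos}\t.\t{key.ref}\t{key.alt}\t.\tPASS\t{info_str}\n"
            )


def write_pileup_tsv(
    path: str | Path, sites: Iterable[PileupSite], tier: QualityTier
) -> None:
    with open(path, "w") as fh:
        cap = tier.max_depth if tier.max_depth is not None else "."
        fh.write(f"#tier\tq={tier.q}\tQ={tier.Q}\tmax_depth={cap}\n")
        fh.write("#chrom\tpos\tref\tsample\tdepth\talleles\n")
        for site in sites:
            if site.tier != tier:
                raise ValueError(
                    f"site at {site.chrom}:{site.pos} has tier {site.tier}, "
                    f"file tier is {tier}"
                )
            alleles = ",".join(
                f"{a}:{c}" for a, c in sorted(site.allele_counts.items())
            )
            fh.write(
                f"{site.chrom}\t{site.pos}\t{site.ref}\t{site.sample}"
                f"\t{site.depth}\t{alleles or '.'}\n"
            )


def read_pileup_tsv(path: str | Path) -> tuple[QualityTier, list[PileupSite]]:
    tier: QualityTier | None = None
    sites: list[PileupSite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("#tier"):
                fields = dict(p.split("=", 1) for p in line.split("\t")[1:])
                cap = None if fields.get("max_depth", ".") == "." else int(fields["max_depth"])
                tier = QualityTier(q=int(fields["q"]), Q=int(fields["Q"]), max_depth=cap)
                continue
            if not line or line.startswith("#"):
                continue
            if tier is None:
                raise ValueError(f"{path}:{lineno}: pileup rows before #tier header")
            chrom, pos, ref, sample, depth, alleles = line.split("\t")
            counts = {}
            if alleles != ".":
                for pair in alleles.split(","):
                    allele, count = pair.rsplit(":", 1)
                    counts[allele] = int(count)
            sites.append(
                PileupSite(
                    chrom=chrom,
                    pos=int(pos),
                    ref=ref,
                    sample=sample,
                    depth=int(depth),
                    allele_counts=counts,
                    tier=tier,
                )
            )
    if tier is None:
        raise ValueError(f"{path}: missing #tier header")
    return tier, sites
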