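"""Synthetic-data generators for every input the benchmarking stages need.

The generators emulate the structure of the benchmarking experiments at
desk scale: a toy contig (default one 10-Mb chromosome), mixture genotypes
drawn over the designed dosage patterns, read counts sampled binomially at
the expected allele fraction with an independent per-site base-error rate,
caller call sets with planted per-bin sensitivity and false-positive
behavior, multi-replicate cohorts carrying culture-acquired mutations, and
nested mappability masks. Everything is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    CallRecord,
    CallSet,
    PileupSite,
    QualityTier,
    TIER_MAIN,
    VafBinning,
    VariantKey,
)
from .mixture import (
    ALLOWED_DOSAGES,
    GenotypeMatrix,
    MixtureDesign,
    expected_vaf,
)
from .regions import GenomeRegions

__all__ = [
    "gen_genotypes",
    "simulate_pileup",
    "simulate_callset",
    "simulate_culture_cohort",
    "gen_masks",
    "CultureCohort",
]

BASES = np.array(["A", "C", "G", "T"])

DosagePattern = tuple[float, ...]


def _random_sites(
    rng: np.random.Generator, n: int, contig: str, contig_length: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if n > contig_length:
        raise ValueError("more variants than contig positions")
    pos = np.sort(rng.choice(contig_length, size=n, replace=False)) + 1
    ref_idx = rng.integers(0, 4, size=n)
    # alt differs from ref by a nonzero offset mod 4
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    return pos, BASES[ref_idx], BASES[alt_idx]


def gen_genotypes(
    n_variants: int,
    design: MixtureDesign,
    vaf_level_weights: Mapping[DosagePattern, float],
    seed: int,
    contig: str = "chr1",
    contig_length: int = 10_000_000,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Draw mixture genotypes over the design's spike-in dosage patterns.

    ``vaf_level_weights`` maps dosage patterns — tuples over
    ``design.spike_ins`` with entries in {0, 0.5, 1} and at least one
    nonzero — to sampling weights. Positions are uniform without
    replacement over the toy contig. Returns the genotype matrix and a
    truth table (chrom, pos, ref, alt, expected_vaf, per-line dosages)
    sorted by position.
    """
    spike_ins = design.spike_ins
    patterns = list(vaf_level_weights)
    for pat in patterns:
        if len(pat) != len(spike_ins):
            raise ValueError(
                f"pattern {pat} does not cover the {len(spike_ins)} spike-in lines"
            )
        if any(d not in ALLOWED_DOSAGES for d in pat) or not any(pat):
            raise ValueError(f"unachievable dosage pattern {pat}")
    weights = np.array([vaf_level_weights[p] for p in patterns], dtype=float)
    if (weights < 0).any() or weights.sum() <= 0:
        raise ValueError("weights must be nonnegative and sum > 0")
    weights = weights / weights.sum()

    rng = np.random.default_rng(seed)
    pos, refs, alts = _random_sites(rng, n_variants, contig, contig_length)
    choice = rng.choice(len(patterns), size=n_variants, p=weights)

    genotypes = GenotypeMatrix(lines=design.lines)
    rows = []
    for p, r, a, c in zip(pos, refs, alts, choice):
        key = VariantKey(contig, int(p), str(r), str(a))
        dosage = dict(zip(spike_ins, patterns[c]))
        genotypes.add(key, {ln: d for ln, d in dosage.items() if d > 0})
        row = {
            "chrom": contig,
            "pos": int(p),
            "ref": str(r),
            "alt": str(a),
            "expected_vaf": expected_vaf(design, dosage),
        }
        for line in design.lines:
            row[f"dosage_{line}"] = dosage.get(line, 0.0)
        rows.append(row)
    return genotypes, pd.DataFrame(rows)


def simulate_pileup(
    truth: pd.DataFrame,
    depth: int,
    error_rate: float = 0.0,
    tier: QualityTier = TIER_MAIN,
    seed: int = 0,
    sample: str = "mixture",
    vaf_column: str = "expected_vaf",
    nontruth_sites: Sequence[tuple[str, int, str]] = (),
    depth_distribution: str | None = None,
) -> dict[tuple[str, int], PileupSite]:
    """Binomial allele-sampling pileups at truth and non-truth sites.

    At each truth site the alternate count is Binomial(D, f); every other
    non-reference base independently accrues Binomial(D, e/3) error reads
    (at truth and non-truth sites alike). Depth is constant, or drawn
    per-site as Poisson(D) when ``depth_distribution='poisson'`` to mimic
    real coverage variation.
    """
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    pileups: dict[tuple[str, int], PileupSite] = {}

    def site_depth() -> int:
        if depth_distribution == "poisson":
            return int(rng.poisson(depth))
        return depth

    def build(chrom: str, pos: int, ref: str, alt: str | None, f: float) -> None:
        d = site_depth()
        counts: dict[str, int] = {}
        remaining = d
        if alt is not None and d > 0:
            k = int(rng.binomial(d, min(f, 1.0)))
            if k:
                counts[alt] = k
            remaining -= k
        if error_rate > 0 and remaining > 0:
            for base in BASES:
                if base == ref or (alt is not None and base == alt):
                    continue
                e = int(rng.binomial(remaining, error_rate / 3))
                if e:
                    counts[base] = counts.get(base, 0) + min(e, remaining)
                    remaining -= counts[base]
                    if remaining <= 0:
                        break
        if remaining > 0:
            counts[ref] = counts.get(ref, 0) + remaining
        pileups[(chrom, pos)] = PileupSite(
            chrom=chrom,
            pos=pos,
            ref=ref,
            sample=sample,
            depth=d,
            allele_counts=counts,
            tier=tier,
        )

    for row in truth.itertuples(index=False):
        build(row.chrom, row.pos, row.ref, row.alt, getattr(row, vaf_column))
    for chrom, pos, ref in nontruth_sites:
        build(chrom, pos, ref, None, 0.0)
    return pileups


def simulate_callset(
    truth: pd.DataFrame,
    sens_curve: Mapping[str, float] | Callable[[float], float],
    fp_rate_per_mb: float = 0.0,
    vaf_noise_sd: float = 0.0,
    seed: int = 0,
    negative_sites: Sequence[tuple[str, int, str]] = (),
    binning: VafBinning | None = None,
    caller: str = "sim",
    dataset: str = "sim",
    fp_vaf_range: tuple[float, float] = (0.001, 0.03),
    vaf_column: str = "expected_vaf",
) -> CallSet:
    """Caller call set with planted per-bin sensitivity and FP behavior.

    Each truth variant is emitted with probability ``sens_curve`` evaluated
    at its VAF bin (mapping keyed by bin label, or a callable on the VAF
    itself). False positives land uniformly on ``negative_sites`` at
    ``fp_rate_per_mb`` (Poisson count over the negatives' 1-bp footprint).
    Emitted caller VAFs are f * (1 + N(0, vaf_noise_sd)) truncated into
    (0, 1]; FP VAFs are uniform over ``fp_vaf_range``.
    """
    binning = binning or VafBinning()
    rng = np.random.default_rng(seed)
    records: list[CallRecord] = []

    for row in truth.itertuples(index=False):
        f = getattr(row, vaf_column)
        if callable(sens_curve):
            s = sens_curve(f)
        else:
            s = sens_curve.get(binning.assign(min(f, 1.0)), 0.0)
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"sensitivity {s} outside [0, 1]")
        if rng.random() >= s:
            continue
        v = f * (1.0 + rng.normal(0.0, vaf_noise_sd)) if vaf_noise_sd else f
        v = min(max(v, 1e-6), 1.0)
        records.append(
            CallRecord(VariantKey(row.chrom, row.pos, row.ref, row.alt), caller_vaf=v)
        )

    if fp_rate_per_mb > 0 and negative_sites:
        span_mb = len(negative_sites) / 1e6
        n_fp = min(int(rng.poisson(fp_rate_per_mb * span_mb)), len(negative_sites))
        lo, hi = fp_vaf_range
        for idx in rng.choice(len(negative_sites), size=n_fp, replace=False):
            chrom, pos, ref = negative_sites[idx]
            alt = str(rng.choice([b for b in BASES if b != ref]))
            records.append(
                CallRecord(
                    VariantKey(chrom, pos, ref, alt),
                    caller_vaf=float(rng.uniform(lo, hi)),
                )
            )
    return CallSet(caller=caller, dataset=dataset, records=records)


@dataclass
class CultureCohort:
    """Everything the culture-mutation discovery stage consumes."""

    culture_truth: pd.DataFrame
    replicate_callsets: list[CallSet]
    replicate_pileups: list[dict[tuple[str, int], PileupSite]]
    admix_longread: dict[tuple[str, int], PileupSite]
    control_longread: dict[tuple[str, int], PileupSite]
    pure_tumor_pileups: list[PileupSite]
    pure_normal_pileups: list[PileupSite]
    negative_regions: GenomeRegions


def simulate_culture_cohort(
    base_truth: pd.DataFrame,
    n_replicates: int,
    culture_truth: pd.DataFrame,
    depths: Sequence[int],
    seed: int = 0,
    admix_longread_depth: int = 387,
    control_longread_depth: int = 200,
    pure_depth: int = 300,
    spurious_control_rate: float = 0.0,
    min_call_support: int = 2,
    trajectory: np.ndarray | None = None,
    tier: QualityTier = TIER_MAIN,
) -> CultureCohort:
    """Multi-replicate cohort carrying culture-acquired mutations.

    ``culture_truth`` rows (chrom, pos, ref, alt, expected_vaf) are the
    planted culture mutations; ``trajectory`` optionally gives each one a
    per-replicate VAF (shape n_culture x n_replicates, nondecreasing across
    harvests), defaulting to its constant ``expected_vaf``. Replicate call
    sets contain every variant (base truth or culture) whose simulated
    alternate count reaches ``min_call_support`` in that replicate's
    pileup. Culture variants never receive alternate reads in the pure-line
    pileups; the unrelated control long-read dataset supports them only at
    ``spurious_control_rate`` (planting exactly two reads, enough to look
    "confirmed"). Negative-control regions cover the culture loci so the
    provenance step can retain them.
    """
    if len(depths) != n_replicates:
        raise ValueError("need one depth per replicate")
    n_culture = len(culture_truth)
    if trajectory is None:
        trajectory = np.tile(
            culture_truth["expected_vaf"].to_numpy()[:, None], (1, n_replicates)
        )
    trajectory = np.asarray(trajectory, dtype=float)
    if trajectory.shape != (n_culture, n_replicates):
        raise ValueError("trajectory shape must be (n_culture, n_replicates)")
    if (np.diff(trajectory, axis=1) < 0).any():
        raise ValueError("culture VAF trajectories must be nondecreasing")

    rng = np.random.default_rng(seed)
    replicate_callsets = []
    replicate_pileups = []
    for r in range(n_replicates):
        rep_truth = pd.concat(
            [
                base_truth[["chrom", "pos", "ref", "alt", "expected_vaf"]],
                culture_truth[["chrom", "pos", "ref", "alt"]].assign(
                    expected_vaf=trajectory[:, r]
                ),
            ],
            ignore_index=True,
        )
        pileup = simulate_pileup(
            rep_truth,
            depth=depths[r],
            tier=tier,
            seed=int(rng.integers(2**31)),
            sample=f"replicate{r + 1}",
        )
        records = []
        for row in rep_truth.itertuples(index=False):
            site = pileup[(row.chrom, row.pos)]
            if site.count(row.alt) >= min_call_support:
                v = site.vaf(row.alt)
                records.append(
                    CallRecord(
                        VariantKey(row.chrom, row.pos, row.ref, row.alt), caller_vaf=v
                    )
                )
        replicate_callsets.append(
            CallSet(caller="merged", dataset=f"replicate{r + 1}", records=records)
        )
        replicate_pileups.append(pileup)

    admix_longread = simulate_pileup(
        culture_truth,
        depth=admix_longread_depth,
        tier=tier,
        seed=int(rng.integers(2**31)),
        sample="admixture_longread",
    )

    control_longread = {}
    for row in culture_truth.itertuples(index=False):
        counts = {}
        if spurious_control_rate > 0 and rng.random() < spurious_control_rate:
            counts[row.alt] = 2
        counts[row.ref] = control_longread_depth - counts.get(row.alt, 0)
        control_longread[(row.chrom, row.pos)] = PileupSite(
            chrom=row.chrom,
            pos=row.pos,
            ref=row.ref,
            sample="control_longread",
            depth=control_longread_depth,
            allele_counts=counts,
            tier=tier,
        )

    def pure_sites(sample: str) -> list[PileupSite]:
        return [
            PileupSite(
                chrom=row.chrom,
                pos=row.pos,
                ref=row.ref,
                sample=sample,
                depth=pure_depth,
                allele_counts={row.ref: pure_depth},
                tier=tier,
            )
            for row in culture_truth.itertuples(index=False)
        ]

    negative_regions = GenomeRegions.from_intervals(
        (row.chrom, row.pos - 1, row.pos)
        for row in culture_truth.itertuples(index=False)
    )
    return CultureCohort(
        culture_truth=culture_truth,
        replicate_callsets=replicate_callsets,
        replicate_pileups=replicate_pileups,
        admix_longread=admix_longread,
        control_longread=control_longread,
        pure_tumor_pileups=pure_sites("pure_tumor"),
        pure_normal_pileups=pure_sites("pure_normal"),
        negative_regions=negative_regions,
    )


def gen_masks(
    contig_length: int,
    easy_frac: float = 0.74,
    difficult_frac: float = 0.10,
    seed: int = 0,
    contig: str = "chr1",
    n_blocks: int = 1000,
) -> tuple[GenomeRegions, GenomeRegions]:
    """Two nested mask interval sets partitioning a contig.

    The contig is tiled into ``n_blocks`` blocks assigned at random to
    easy / difficult / extreme with counts rounded to the target fractions
    (realized coverage within 1% of target for n_blocks >= 100). The
    primary mask holds the easy blocks; the secondary holds easy+difficult,
    so primary is a subset of secondary by construction.
    """
    if easy_frac < 0 or difficult_frac < 0 or easy_frac + difficult_frac > 1:
        raise ValueError("fractions must be >= 0 and sum to <= 1")
    rng = np.random.default_rng(seed)
    edges = np.linspace(0, contig_length, n_blocks + 1).astype(int)
    blocks = list(zip(edges[:-1], edges[1:]))
    order = rng.permutation(n_blocks)
    n_easy = round(easy_frac * n_blocks)
    n_difficult = round(difficult_frac * n_blocks)
    easy_blocks = [blocks[i] for i in order[:n_easy]]
    difficult_blocks = [blocks[i] for i in order[n_easy : n_easy + n_difficult]]
    primary = GenomeRegions.from_intervals(
        (contig, s, e) for s, e in easy_blocks
    )
    secondary = GenomeRegions.from_intervals(
        (contig, s, e) for s, e in easy_blocks + difficult_blocks
    )
    return primary, secondary
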