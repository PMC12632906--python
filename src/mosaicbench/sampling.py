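"""Binomial allele-sampling model and empirical sampling-rate analysis.

Before any caller can detect a mosaic variant, its alternate allele must be
*sampled*: at least ``m`` reads carrying the allele must land in the
dataset. Treating read draws as independent Bernoulli trials at allele
fraction ``f`` and depth ``D``, the sampling probability is the binomial
tail P(X >= m), X ~ Binomial(D, f) — for m = 1 simply 1 - (1 - f)^D.
Across independent replicate datasets at unequal depths, the number of
replicates sampling the variant follows a Poisson-binomial distribution.
"""

from __future__ import annotations

from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import PileupSite, VafBinning
from .regions import GenomeRegions
from .evaluation import stratify_position

__all__ = [
    "analytic_sampling_prob",
    "poisson_binomial_pmf",
    "multi_replicate_sampling",
    "empirical_sampling_rates",
]


def analytic_sampling_prob(
    f: float, depth: int, m: int = 1, effective_depth_scale: float = 1.0
) -> float:
    """P(>= m alternate reads) at allele fraction f and depth D.

    ``effective_depth_scale`` discounts the nominal depth for reads lost to
    quality filtering (default 1.0: no discount).
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"allele fraction {f} outside [0, 1]")
    if depth < 1 or m < 1:
        raise ValueError("depth and m must be >= 1")
    d_eff = int(round(depth * effective_depth_scale))
    if d_eff < 1:
        raise ValueError("effective depth < 1")
    return float(stats.binom.sf(m - 1, d_eff, f))


def poisson_binomial_pmf(probs: Sequence[float]) -> np.ndarray:
    """PMF of the number of successes over independent unequal-p trials.

    Dynamic-programming convolution, exact up to float round-off; returns
    an array of length ``len(probs) + 1``.
    """
    pmf = np.array([1.0])
    for p in probs:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} outside [0, 1]")
        pmf = np.convolve(pmf, [1.0 - p, p])
    return pmf


def multi_replicate_sampling(
    f: float,
    depths: Sequence[int],
    mode: Literal["all", "at_least_once", "at_least_j"] = "all",
    j: int | None = None,
    m: int = 1,
    effective_depth_scale: float = 1.0,
) -> float:
    """Probability of sampling across independent replicate datasets.

    ``all``: sampled in every replicate; ``at_least_once``: in >= 1;
    ``at_least_j``: Poisson-binomial tail P(#replicates >= j).
    """
    if not depths:
        raise ValueError("empty depth list")
    probs = [
        analytic_sampling_prob(f, d, m, effective_depth_scale) for d in depths
    ]
    if mode == "all":
        return float(np.prod(probs))
    if mode == "at_least_once":
        return float(1.0 - np.prod([1.0 - p for p in probs]))
    if mode == "at_least_j":
        if j is None or not 0 <= j <= len(depths):
            raise ValueError("at_least_j mode needs 0 <= j <= n_replicates")
        return float(poisson_binomial_pmf(probs)[j:].sum())
    raise ValueError(f"unknown mode {mode!r}")


def empirical_sampling_rates(
    truth: pd.DataFrame,
    replicate_pileups: Mapping[str, Mapping[tuple[str, int], PileupSite]],
    binning: VafBinning | None = None,
    m: int = 1,
    vaf_column: str = "expected_vaf",
    mask_primary: GenomeRegions | None = None,
    mask_secondary: GenomeRegions | None = None,
) -> dict[str, pd.DataFrame]:
    """Observed sampling rates of truth variants across replicate datasets.

    ``truth`` needs columns chrom/pos/alt plus ``vaf_column`` for binning;
    ``replicate_pileups`` maps dataset name -> {(chrom, pos): PileupSite}.
    A variant counts as sampled in a dataset when its alternate allele has
    >= m reads there; a missing pileup row counts as depth 0 (unsampled).

    Returns three tables: ``per_dataset`` (bin x dataset sampling rate),
    ``sharing`` (bin x j: fraction of variants sampled in exactly j of the
    n datasets, j = 0..n), and — when masks are given — ``stratum_by_class``
    (genomic-context composition of each sharing class).
    """
    binning = binning or VafBinning()
    datasets = list(replicate_pileups)
    n = len(datasets)
    if n == 0:
        raise ValueError("no replicate pileups supplied")

    bins = [binning.assign(min(v, 1.0)) for v in truth[vaf_column]]
    sampled = np.zeros((len(truth), n), dtype=bool)
    for d_idx, name in enumerate(datasets):
        pileups = replicate_pileups[name]
        for v_idx, row in enumerate(truth.itertuples(index=False)):
            site = pileups.get((row.chrom, row.pos))
            if site is not None and site.count(row.alt) >= m:
                sampled[v_idx, d_idx] = True

    frame = pd.DataFrame(sampled, columns=datasets)
    frame["bin"] = bins
    frame["j"] = sampled.sum(axis=1)

    per_dataset = frame.groupby("bin", sort=False)[datasets].mean()
    per_dataset = per_dataset.reindex(
        [b for b in binning.all_labels if b in per_dataset.index]
    )

    sharing = (
        frame.groupby("bin", sort=False)["j"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=range(n + 1), fill_value=0.0)
    )
    sharing = sharing.reindex([b for b in binning.all_labels if b in sharing.index])

    out = {"per_dataset": per_dataset, "sharing": sharing}

    if mask_primary is not None and mask_secondary is not None:
        strata = [
            stratify_position(row.chrom, row.pos, mask_primary, mask_secondary)
            for row in truth.itertuples(index=False)
        ]
        frame["stratum"] = strata
        out["stratum_by_class"] = (
            frame.groupby("j")["stratum"]
            .value_counts(normalize=True)
            .unstack(fill_value=0.0)
        )
    return out
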