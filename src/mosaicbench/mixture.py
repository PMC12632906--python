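"""Expected-VAF arithmetic for designed cell-line mixtures.

A mixture of diploid, copy-number-neutral cell lines at proportions ``p_i``
carries a variant at expected allele fraction ``sum_i p_i * d_i``, where the
dosage ``d_i`` is 0 (absent), 0.5 (heterozygous) or 1 (homozygous) in line
``i``. Two designs from the benchmarking experiments ship as constructors:
the 2% tumor / 98% matched-normal admixture (expected somatic VAFs 1% and
2%) and the six-line HapMap mixture whose spike-in genotype combinations
span 0.25%–16.5%.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import VariantKey
from .regions import GenomeRegions

__all__ = [
    "MixtureDesign",
    "GenotypeMatrix",
    "expected_vaf",
    "enumerate_expected_vafs",
    "build_mixture_reference",
    "colo829blt50_design",
    "hapmap_design",
]

ALLOWED_DOSAGES = (0.0, 0.5, 1.0)


@dataclass(frozen=True)
class MixtureDesign:
    """Cell-line components with mixing proportions summing to 1."""

    components: tuple[tuple[str, float], ...]
    background: str | None = None

    def __post_init__(self) -> None:
        if any(p <= 0 for _, p in self.components):
            raise ValueError("all proportions must be > 0")
        total = sum(p for _, p in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total}, expected 1")
        names = [name for name, _ in self.components]
        if len(names) != len(set(names)):
            raise ValueError("duplicate component names")
        if self.background is not None and self.background not in names:
            raise ValueError(f"background {self.background!r} not a component")

    @classmethod
    def from_mapping(
        cls, proportions: Mapping[str, float], background: str | None = None
    ) -> "MixtureDesign":
        return cls(tuple(proportions.items()), background=background)

    @property
    def proportions(self) -> dict[str, float]:
        return dict(self.components)

    @property
    def lines(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.components)

    @property
    def spike_ins(self) -> tuple[str, ...]:
        """Components other than the background line."""
        return tuple(name for name in self.lines if name != self.background)


def colo829blt50_design() -> MixtureDesign:
    """Two-component tumor/normal admixture: 2% COLO829 in 98% COLO829BL."""
    return MixtureDesign(
        (("COLO829", 0.02), ("COLO829BL", 0.98)), background="COLO829BL"
    )


def hapmap_design() -> MixtureDesign:
    """Six-line HapMap mixture with HG005 as the 83.5% background."""
    return MixtureDesign(
        (
            ("HG00438", 0.005),
            ("HG002", 0.02),
            ("HG02257", 0.02),
            ("HG02486", 0.02),
            ("HG02622", 0.10),
            ("HG005", 0.835),
        ),
        background="HG005",
    )


def _check_dosages(dosages: Mapping[str, float], design: MixtureDesign) -> None:
    known = set(design.lines)
    for line, d in dosages.items():
        if line not in known:
            raise KeyError(f"unknown line id {line!r} in dosage vector")
        if d not in ALLOWED_DOSAGES:
            raise ValueError(f"dosage {d} for {line!r} not in {ALLOWED_DOSAGES}")


def expected_vaf(design: MixtureDesign, dosages: Mapping[str, float]) -> float:
    """Expected mixture allele fraction for one variant.

    ``dosages`` maps line id -> diploid dosage in {0, 0.5, 1}; lines absent
    from the mapping carry dosage 0. Dosages are summed across carrier
    lines, so variants shared by several components stack.
    """
    _check_dosages(dosages, design)
    return sum(p * dosages.get(line, 0.0) for line, p in design.components)


def enumerate_expected_vafs(
    design: MixtureDesign, exclude_background: bool = True
) -> list[float]:
    """All achievable expected VAFs over spike-in dosage vectors.

    Enumerates every dosage vector in {0, 0.5, 1}^k over the spike-in lines
    (background fixed at 0 when ``exclude_background``) with at least one
    nonzero entry, and returns the sorted distinct expected VAFs.
    """
    lines = design.spike_ins if exclude_background else design.lines
    values: set[float] = set()
    for combo in itertools.product(ALLOWED_DOSAGES, repeat=len(lines)):
        if not any(combo):
            continue
        values.add(round(expected_vaf(design, dict(zip(lines, combo))), 12))
    return sorted(values)


@dataclass
class GenotypeMatrix:
    """Per-variant, per-line diploid dosages in {0, 0.5, 1}."""

    lines: tuple[str, ...]
    dosages: dict[VariantKey, dict[str, float]] = field(default_factory=dict)

    def add(self, key: VariantKey, line_dosages: Mapping[str, float]) -> None:
        for line, d in line_dosages.items():
            if line not in self.lines:
                raise KeyError(f"unknown line {line!r}")
            if d not in ALLOWED_DOSAGES:
                raise ValueError(f"dosage {d} not in {ALLOWED_DOSAGES}")
        if not any(d > 0 for d in line_dosages.values()):
            raise ValueError(f"variant {key} absent from every line")
        self.dosages[key] = dict(line_dosages)

    def __len__(self) -> int:
        return len(self.dosages)

    def items(self) -> Iterable[tuple[VariantKey, dict[str, float]]]:
        return self.dosages.items()


def build_mixture_reference(
    genotypes: GenotypeMatrix,
    design: MixtureDesign,
    confident_regions: Mapping[str, GenomeRegions] | Sequence[GenomeRegions] | None = None,
    background: str | None = None,
) -> pd.DataFrame:
    """Build the somatic truth table with expected VAFs for a mixture.

    Filters follow the mixture reference-set construction: SNVs only, no
    ambiguous ("N") reference bases, inside the intersection of every
    supplied per-line confident region set, and variants with any dosage in
    the background line are treated as germline and dropped.

    Returns a DataFrame with columns chrom, pos, ref, alt, expected_vaf and
    one dosage column per line, sorted by position.
    """
    background = background or design.background
    region_sets: list[GenomeRegions] = []
    if confident_regions is not None:
        region_sets = list(
            confident_regions.values()
            if isinstance(confident_regions, Mapping)
            else confident_regions
        )

    rows = []
    for key, dosage in genotypes.items():
        if not key.is_snv:
            continue
        if "N" in key.ref:
            continue
        if background is not None and dosage.get(background, 0.0) > 0:
            continue  # germline in the mixture: present in the background line
        if region_sets and not all(r.contains(key.chrom, key.pos) for r in region_sets):
            continue
        row = {
            "chrom": key.chrom,
            "pos": key.pos,
            "ref": key.ref,
            "alt": key.alt,
            "expected_vaf": expected_vaf(design, dosage),
        }
        for line in design.lines:
            row[f"dosage_{line}"] = dosage.get(line, 0.0)
        rows.append(row)

    if not rows:
        warnings.warn("mixture reference set is empty after filtering")
        columns = ["chrom", "pos", "ref", "alt", "expected_vaf"] + [
            f"dosage_{line}" for line in design.lines
        ]
        return pd.DataFrame(columns=columns)
    return (
        pd.DataFrame(rows)
        .sort_values(["chrom", "pos", "ref", "alt"])
        .reset_index(drop=True)
    )
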