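"""Variant-density mapping: windowed counts, peak detection, candidates.

After several backcrosses to the reference strain, mutagen-induced variants
unlinked to the selected phenotype are progressively lost while variants
linked to the causal site are retained, so the causal region shows up as a
cluster of (homozygous, EMS-type) variants.  This module counts filtered
variant categories in overlapping sliding windows, calls high-density peaks
against the genome-wide distribution, and extracts in-gene candidate
variants from the peak regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genomeio import GeneModel, Genome, Variant, VariantSet
from .variantops import FilterConfig, variant_label

log = logging.getLogger(__name__)

#: category names carried by a DensityProfile, in reporting order
CATEGORIES = ("all", "test_specific", "hom", "ems", "hom_ems")


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in bp; step == size gives plain bins."""

    size: int = 1_000_000
    step: int = 500_000

    def __post_init__(self):
        if not (0 < self.step <= self.size):
            raise ValueError("need 0 < step <= size")


def iter_windows(genome: Genome, spec: WindowSpec) -> list[tuple[str, int, int]]:
    """All windows (chrom, start, end), tiling each chromosome with `step`.

    The last window of a chromosome is clipped at the chromosome end.
    """
    wins = []
    for chrom, length in genome.chromosomes:
        start = 1
        while start <= length:
            wins.append((chrom, start, min(start + spec.size - 1, length)))
            if start + spec.size - 1 >= length:
                break
            start += spec.step
    return wins


@dataclass
class DensityProfile:
    windows: list[tuple[str, int, int]]
    counts: dict[str, np.ndarray]
    spec: WindowSpec

    def category(self, name: str) -> np.ndarray:
        return self.counts[name]


@dataclass(frozen=True)
class RegionOfInterest:
    chrom: str
    start: int
    end: int
    peak_count: int
    basis_category: str

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def bin_counts(vset: VariantSet, genome: Genome, spec: WindowSpec) -> np.ndarray:
    """Count of variants per window; a variant is counted in every window
    whose [start, end] contains its position.

    Variants on chromosomes unknown to the genome are skipped with a warning.
    """
    windows = iter_windows(genome, spec)
    pos_by_chrom: dict[str, list[int]] = {}
    for v in vset:
        if v.chrom not in genome:
            log.warning("variant %s on unknown chromosome skipped", v.key)
            continue
        pos_by_chrom.setdefault(v.chrom, []).append(v.pos)
    sorted_pos = {c: np.sort(np.asarray(p)) for c, p in pos_by_chrom.items()}
    out = np.zeros(len(windows), dtype=int)
    for i, (chrom, start, end) in enumerate(windows):
        p = sorted_pos.get(chrom)
        if p is None:
            continue
        out[i] = np.searchsorted(p, end, "right") - np.searchsorted(p, start, "left")
    return out


def density_profile(
    category_sets: dict[str, VariantSet], genome: Genome, spec: WindowSpec
) -> DensityProfile:
    """Windowed counts for several variant categories at once."""
    windows = iter_windows(genome, spec)
    counts = {
        name: bin_counts(vset, genome, spec) for name, vset in category_sets.items()
    }
    return DensityProfile(windows, counts, spec)


def standard_categories(
    test: VariantSet,
    test_specific: VariantSet,
    hom: VariantSet,
    ems: VariantSet,
    hom_ems: VariantSet,
) -> dict[str, VariantSet]:
    return {
        "all": test,
        "test_specific": test_specific,
        "hom": hom,
        "ems": ems,
        "hom_ems": hom_ems,
    }


def detect_peaks(
    profile: DensityProfile,
    category: str = "hom_ems",
    z: float = 2.0,
    min_count: int = 4,
) -> list[RegionOfInterest]:
    """High-density peak regions of one category.

    A window qualifies when its count strictly exceeds
    max(min_count, mu + z*sigma), with mu and sigma the genome-wide mean and
    standard deviation of the category's window counts.  Overlapping or
    adjacent qualifying windows merge into one region; regions are returned
    sorted by their maximum window count, descending.  The absolute floor
    prevents spurious calls on near-empty genomes.
    """
    if not profile.windows:
        raise ValueError("empty profile")
    counts = profile.counts[category]
    if not np.any(counts):
        return []
    mu = float(np.mean(counts))
    sigma = float(np.std(counts))
    threshold = max(float(min_count), mu + z * sigma)
    regions: list[RegionOfInterest] = []
    cur: Optional[list] = None  # [chrom, start, end, peak]
    for (chrom, start, end), c in zip(profile.windows, counts):
        if c <= threshold:
            continue
        if cur is not None and chrom == cur[0] and start <= cur[2] + 1:
            cur[2] = max(cur[2], end)
            cur[3] = max(cur[3], int(c))
        else:
            if cur is not None:
                regions.append(RegionOfInterest(cur[0], cur[1], cur[2], cur[3], category))
            cur = [chrom, start, end, int(c)]
    if cur is not None:
        regions.append(RegionOfInterest(cur[0], cur[1], cur[2], cur[3], category))
    regions.sort(key=lambda r: (-r.peak_count, r.chrom, r.start))
    return regions


def extract_candidates(
    regions: Sequence[RegionOfInterest],
    vset: VariantSet,
    genes: Sequence[GeneModel],
    cfg: FilterConfig = FilterConfig(),
) -> list[Variant]:
    """Variants inside a region, inside a gene span, and of a reported class.

    With no gene models available the candidate list is empty by definition
    (a warning is logged): the density workflow reports candidates only when
    they can be placed within a gene.
    """
    if not genes:
        log.warning("no annotation available: candidate list is empty")
        return []
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    for v in vset:
        if variant_label(v) not in cfg.report_classes:
            continue
        if not any(r.contains(v.chrom, v.pos) for r in regions):
            continue
        if any(g.contains(v.pos) for g in genes_by_chrom.get(v.chrom, ())):
            out.append(v)
    return out


def genes_overlapping(
    genes: Sequence[GeneModel], chrom: str, pos: int
) -> list[GeneModel]:
    return [g for g in genes if g.chrom == chrom and g.contains(pos)]
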