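"""QTL-seq mapping from two phenotypically opposite bulks.

Two pools of individuals drawn from the extreme tails of a segregating
population are sequenced; at markers linked to a quantitative trait locus
the allele frequencies of the two pools are pushed in opposite directions,
so their difference dAF deviates from 0.  Markers present in both pools with
0 < af < 1 in both are selected (this removes variants shared by the two
parental lines but absent from the reference, which sit at af = 1 in both
pools), dAF is averaged per sliding window, smoothed with a weighted moving
average along each chromosome, and sustained runs of |dAF_WMA| above a
threshold are called as candidate QTL regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .densmap import WindowSpec, iter_windows
from .genomeio import GeneModel, Genome, Variant, VariantKey, VariantSet

log = logging.getLogger(__name__)

DEFAULT_WMA_WEIGHTS = (1.0, 2.0, 3.0, 2.0, 1.0)


@dataclass(frozen=True)
class MappingVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    af1: float
    af2: float

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def daf(self) -> float:
        return self.af1 - self.af2


@dataclass
class DafProfile:
    """Windowed dAF profile; empty windows carry NaN and are bridged
    (excluded from the smoothing support rather than zero-filled)."""

    windows: list[tuple[str, int, int]]
    n_variants: np.ndarray
    daf_mean: np.ndarray
    daf_wma: Optional[np.ndarray] = None
    spec: Optional[WindowSpec] = None


@dataclass(frozen=True)
class QtlRegion:
    chrom: str
    start: int
    end: int
    sign: str  # "+" or "-"
    extremum: float  # max |daf_wma| inside the region

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def select_mapping_variants(
    pool1: VariantSet,
    pool2: VariantSet,
    min_dp: int = 5,
    snp_only: bool = True,
) -> list[MappingVariant]:
    """Segregating markers usable for QTL-seq.

    A marker must be present in both pools with 0 < af < 1 and depth >=
    min_dp in both.  Records without a defined allele frequency are a hard
    error: the pools must have been called with allele depths.
    """
    out = []
    for v1 in pool1:
        v2 = pool2.get(v1.key)
        if v2 is None:
            continue
        if v1.af is None or v2.af is None:
            raise ValueError(f"variant {v1.key} lacks allele depths in a pool")
        if snp_only and v1.vclass != "snp":
            continue
        if v1.depth < min_dp or v2.depth < min_dp:
            continue
        if 0.0 < v1.af < 1.0 and 0.0 < v2.af < 1.0:
            out.append(
                MappingVariant(v1.chrom, v1.pos, v1.ref, v1.alt, v1.af, v2.af)
            )
    return out


def window_daf(
    mvars: Sequence[MappingVariant], genome: Genome, spec: WindowSpec
) -> DafProfile:
    """Arithmetic mean of per-marker dAF in each sliding window."""
    windows = iter_windows(genome, spec)
    by_chrom: dict[str, list[tuple[int, float]]] = {}
    for m in mvars:
        if m.chrom not in genome:
            log.warning("marker %s on unknown chromosome skipped", m.key)
            continue
        by_chrom.setdefault(m.chrom, []).append((m.pos, m.daf))
    arrs = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        pos = np.asarray([p for p, _ in pairs])
        val = np.asarray([d for _, d in pairs])
        csum = np.concatenate([[0.0], np.cumsum(val)])
        arrs[chrom] = (pos, csum)
    n = np.zeros(len(windows), dtype=int)
    mean = np.full(len(windows), np.nan)
    for i, (chrom, start, end) in enumerate(windows):
        if chrom not in arrs:
            continue
        pos, csum = arrs[chrom]
        lo = np.searchsorted(pos, start, "left")
        hi = np.searchsorted(pos, end, "right")
        n[i] = hi - lo
        if hi > lo:
            mean[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return DafProfile(windows, n, mean, None, spec)


def wma_smooth(
    profile: DafProfile, weights: Sequence[float] = DEFAULT_WMA_WEIGHTS
) -> DafProfile:
    """Weighted moving average of daf_mean along each chromosome.

    Empty windows are bridged: the kernel runs over the sequence of defined
    windows only, and weights are renormalized at chromosome edges.  Each
    chromosome is smoothed independently.  The smoothed value is a convex
    combination of observed window means, so it never leaves their range.
    """
    w = np.asarray(weights, dtype=float)
    if len(w) % 2 != 1 or np.any(w <= 0):
        raise ValueError("weights must be an odd-length positive vector")
    half = len(w) // 2
    wma = np.full(len(profile.windows), np.nan)
    chroms = [c for c, _, _ in profile.windows]
    for chrom in dict.fromkeys(chroms):
        idx = [i for i, c in enumerate(chroms) if c == chrom]
        defined = [i for i in idx if not np.isnan(profile.daf_mean[i])]
        m = len(defined)
        for j, i in enumerate(defined):
            lo = max(0, j - half)
            hi = min(m, j + half + 1)
            ws = w[half - (j - lo) : half + (hi - j)]
            vals = profile.daf_mean[defined[lo:hi]]
            wma[i] = float(np.dot(ws, vals) / ws.sum())
    return DafProfile(
        profile.windows, profile.n_variants, profile.daf_mean, wma, profile.spec
    )


def call_qtl_regions(
    profile: DafProfile, daf_min: float = 0.25, min_run: int = 3
) -> list[QtlRegion]:
    """Maximal same-sign runs of >= min_run defined windows with
    |daf_wma| >= daf_min, each reported as one candidate QTL region spanning
    the first window start to the last window end."""
    if profile.daf_wma is None:
        raise ValueError("profile must be smoothed first (wma_smooth)")
    regions: list[QtlRegion] = []
    chroms = [c for c, _, _ in profile.windows]
    for chrom in dict.fromkeys(chroms):
        defined = [
            i
            for i, c in enumerate(chroms)
            if c == chrom and not np.isnan(profile.daf_wma[i])
        ]
        run: list[int] = []
        run_sign = 0

        def flush():
            if len(run) >= min_run:
                vals = profile.daf_wma[run]
                regions.append(
                    QtlRegion(
                        chrom,
                        profile.windows[run[0]][1],
                        profile.windows[run[-1]][2],
                        "+" if run_sign > 0 else "-",
                        float(np.max(np.abs(vals))),
                    )
                )

        for i in defined:
            v = profile.daf_wma[i]
            s = 1 if v > 0 else -1
            if abs(v) >= daf_min and (not run or s == run_sign):
                run.append(i)
                run_sign = s
            else:
                flush()
                run = [i] if abs(v) >= daf_min else []
                run_sign = s if run else 0
        flush()
    return regions


def qtl_candidates(
    regions: Sequence[QtlRegion],
    mvars: Sequence[MappingVariant],
    genes: Optional[Sequence[GeneModel]] = None,
    genome: Optional[Genome] = None,
    cfg=None,
    functional_map: Optional[dict[str, str]] = None,
) -> list:
    """Candidate records for in-region mapping variants.

    With gene models (and the genome), in-region in-gene variants are passed
    through the variant analyzer for full effect annotation.  Without an
    annotation this degrades gracefully: every in-region variant is reported
    with empty gene fields, so the workflow still identifies candidate
    regions for genomes that lack a structural annotation.
    """
    from .annotate import AnnotateConfig, CandidateRecord, analyze_set

    in_region = [
        m for m in mvars if any(r.contains(m.chrom, m.pos) for r in regions)
    ]
    acfg = cfg if cfg is not None else AnnotateConfig()

    if genes and genome is not None:
        keep = []
        for m in in_region:
            if any(
                g.chrom == m.chrom and g.contains(m.pos) for g in genes
            ):
                keep.append(m)
        vset = VariantSet(
            "qtl_candidates",
            (Variant(m.chrom, m.pos, m.ref, m.alt) for m in keep),
            genome.chrom_ids,
        )
        return analyze_set(vset, list(genes), genome, functional_map, acfg)
    # annotation-free mode: region membership only, no gene fields
    records = []
    for m in in_region:
        records.append(
            CandidateRecord(
                variant=Variant(m.chrom, m.pos, m.ref, m.alt),
                effect=None,
                functional_note=None,
                primers=None,
                primer_fail_reason=None,
                flank_left="",
                flank_right="",
            )
        )
    return records
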