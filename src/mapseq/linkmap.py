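"""Simplified allele-frequency linkage mapping for one mutant bulk.

In a bulk of phenotypically mutant F2 individuals (backcross or outcross
design), variants linked to the causal site approach fixation (af → 1)
while unlinked variants segregate around af = 0.5.  The scan subtracts the
control, windows the test-specific allele frequencies, smooths them with
the same weighted moving average used for QTL-seq, and reports the region
where the smoothed af stays near fixation.  The peak threshold sits below
1.0 to tolerate occasional phenotyping errors, to which this design is
highly sensitive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .densmap import RegionOfInterest, WindowSpec, iter_windows
from .genomeio import GeneModel, Genome, Variant, VariantSet
from .qtlmap import DEFAULT_WMA_WEIGHTS, DafProfile, wma_smooth
from .variantops import FilterConfig, filter_by_class, subtract_control

log = logging.getLogger(__name__)


@dataclass
class AfProfile:
    """Windowed mean allele frequency with its smoothed track; empty
    windows carry NaN and are bridged exactly like the dAF profile."""

    windows: list[tuple[str, int, int]]
    n_variants: np.ndarray
    af_mean: np.ndarray
    af_wma: Optional[np.ndarray] = None
    spec: Optional[WindowSpec] = None


def window_af(
    vset: VariantSet, genome: Genome, spec: WindowSpec
) -> AfProfile:
    windows = iter_windows(genome, spec)
    by_chrom: dict[str, list[tuple[int, float]]] = {}
    for v in vset:
        if v.chrom not in genome:
            log.warning("variant %s on unknown chromosome skipped", v.key)
            continue
        if v.af is None:
            raise ValueError(f"variant {v.key} has undefined allele frequency")
        by_chrom.setdefault(v.chrom, []).append((v.pos, v.af))
    n = np.zeros(len(windows), dtype=int)
    mean = np.full(len(windows), np.nan)
    arrs = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        pos = np.asarray([p for p, _ in pairs])
        csum = np.concatenate([[0.0], np.cumsum([a for _, a in pairs])])
        arrs[chrom] = (pos, csum)
    for i, (chrom, start, end) in enumerate(windows):
        if chrom not in arrs:
            continue
        pos, csum = arrs[chrom]
        lo = np.searchsorted(pos, start, "left")
        hi = np.searchsorted(pos, end, "right")
        n[i] = hi - lo
        if hi > lo:
            mean[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return AfProfile(windows, n, mean, None, spec)


def linkage_scan(
    test: VariantSet,
    control: Optional[VariantSet],
    genome: Genome,
    spec: WindowSpec = WindowSpec(),
    cfg: FilterConfig = FilterConfig(),
    genes: Optional[Sequence[GeneModel]] = None,
    af_peak_min: float = 0.9,
    min_run: int = 2,
    weights: Sequence[float] = DEFAULT_WMA_WEIGHTS,
) -> tuple[AfProfile, Optional[RegionOfInterest], list[Variant]]:
    """Fixation scan: subtract control, window af, smooth, call the peak run.

    Returns the full profile, the best region of windows with
    af_wma >= af_peak_min sustained over >= min_run windows (None with a
    warning when no window reaches the threshold), and the in-region,
    in-gene candidate variants with af >= cfg.af_hom_min.
    """
    specific = subtract_control(test, control) if control is not None else test
    specific = filter_by_class(specific, cfg)
    profile = window_af(specific, genome, spec)
    daf_like = DafProfile(
        profile.windows, profile.n_variants, profile.af_mean, None, spec
    )
    smoothed = wma_smooth(daf_like, weights)
    profile = AfProfile(
        profile.windows, profile.n_variants, profile.af_mean, smoothed.daf_wma, spec
    )

    # maximal runs of defined windows at or above the fixation threshold
    chroms = [c for c, _, _ in profile.windows]
    best: Optional[RegionOfInterest] = None
    best_peak = -1.0
    for chrom in dict.fromkeys(chroms):
        defined = [
            i
            for i, c in enumerate(chroms)
            if c == chrom and not np.isnan(profile.af_wma[i])
        ]
        run: list[int] = []

        def consider(run_idx: list[int]):
            nonlocal best, best_peak
            if len(run_idx) < min_run:
                return
            peak = float(np.max(profile.af_wma[run_idx]))
            if peak > best_peak:
                best_peak = peak
                best = RegionOfInterest(
                    chrom,
                    profile.windows[run_idx[0]][1],
                    profile.windows[run_idx[-1]][2],
                    int(np.max(profile.n_variants[run_idx])),
                    "af_wma",
                )

        for i in defined:
            if profile.af_wma[i] >= af_peak_min:
                run.append(i)
            else:
                consider(run)
                run = []
        consider(run)

    candidates: list[Variant] = []
    if best is None:
        log.warning(
            "no window reached af_wma >= %.2f: no linkage region called",
            af_peak_min,
        )
    else:
        genes = genes or []
        for v in specific:
            if not best.contains(v.chrom, v.pos):
                continue
            if v.af is None or v.af < cfg.af_hom_min:
                continue
            if any(g.chrom == v.chrom and g.contains(v.pos) for g in genes):
                candidates.append(v)
    return profile, best, candidates
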