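"""Workflow orchestration: load inputs, run a mapping pipeline, write the
report directory (TSVs, VCFs, SVG plots, plain-text summary, resolved
configuration).

Every workflow is a pure function of its input files: nothing is mutated in
place and all outputs are confined to the run directory, so callers may
parallelize runs externally.  The resolved configuration (every default
filled in) is written beside the outputs to make each run reconstructible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from . import annotate as ann
from . import densmap, linkmap, qtlmap, simpop, variantops
from .genomeio import (
    Genome,
    VariantSet,
    read_fasta,
    read_gff,
    read_vcf,
    write_tsv,
    write_vcf,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    workflow: str
    out_dir: str
    genome: Optional[str] = None
    gff: Optional[str] = None
    test_vcf: Optional[str] = None
    control_vcf: Optional[str] = None
    pool1_vcf: Optional[str] = None
    pool2_vcf: Optional[str] = None
    functional_tsv: Optional[str] = None
    window_size: int = 1_000_000
    window_step: int = 500_000
    af_hom_min: float = 0.85
    min_dp: int = 5
    min_qual: float = 20.0
    report_classes: tuple[str, ...] = variantops.CLASS_LABELS
    peak_z: float = 2.0
    peak_min_count: int = 4
    peak_category: str = "hom_ems"
    daf_min: float = 0.25
    min_run: int = 3
    af_peak_min: float = 0.9
    linkage_min_run: int = 2
    wma_weights: tuple[float, ...] = qtlmap.DEFAULT_WMA_WEIGHTS
    snp_only_mapping_variants: bool = True
    seed: Optional[int] = None
    scenario: Optional[str] = None  # simulate only
    sim: Optional[dict] = None      # simulate only: SimConfig overrides

    def filter_config(self) -> variantops.FilterConfig:
        return variantops.FilterConfig(
            self.af_hom_min, self.min_dp, self.min_qual,
            frozenset(self.report_classes),
        )

    def window_spec(self) -> densmap.WindowSpec:
        return densmap.WindowSpec(self.window_size, self.window_step)


def _setup_run(cfg: RunConfig) -> None:
    os.makedirs(cfg.out_dir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(cfg.out_dir, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logging.getLogger("mapseq").addHandler(handler)
    with open(os.path.join(cfg.out_dir, "resolved_config.json"), "w") as fh:
        json.dump(dataclasses.asdict(cfg), fh, indent=2, sort_keys=True)
    log.info("resolved configuration: %s", dataclasses.asdict(cfg))


def _load_common(cfg: RunConfig):
    if not cfg.genome:
        raise ValueError("missing required input: --genome")
    genome = read_fasta(cfg.genome)
    genes = read_gff(cfg.gff, genome) if cfg.gff else []
    return genome, genes


def _variant_row(v, extra: Optional[dict] = None) -> dict:
    row = dict(
        chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt, qual=v.qual,
        ref_count=v.ref_count, alt_count=v.alt_count,
        af="" if v.af is None else round(v.af, 4), vclass=v.vclass,
        label=variantops.variant_label(v),
    )
    if extra:
        row.update(extra)
    return row


CANDIDATE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "qual", "ref_count", "alt_count", "af",
    "vclass", "gene", "transcript", "element", "consequence", "codon_change",
    "aa_change", "functional_note", "primer_fwd", "primer_rev",
    "primer_product", "primer_fwd_tm", "primer_rev_tm", "primer_fail_reason",
    "flank_left", "flank_right",
]


def _candidate_rows(records: list[ann.CandidateRecord]) -> list[dict]:
    rows = []
    for r in records:
        v = r.variant
        e = r.effect
        rows.append(
            dict(
                chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt, qual=v.qual,
                ref_count="" if v.ref_count is None else v.ref_count,
                alt_count="" if v.alt_count is None else v.alt_count,
                af="" if v.af is None else round(v.af, 4),
                vclass=v.vclass,
                gene="" if e is None or e.gene_id is None else e.gene_id,
                transcript="" if e is None or e.transcript_id is None else e.transcript_id,
                element="" if e is None else e.element,
                consequence="" if e is None else e.consequence,
                codon_change="" if e is None or e.codon_change is None else e.codon_change,
                aa_change=(
                    ""
                    if e is None or e.aa_change is None
                    else f"{e.aa_change[0]}{e.aa_change[1]}{e.aa_change[2]}"
                ),
                functional_note=r.functional_note or "",
                primer_fwd="" if r.primers is None else r.primers.fwd_seq,
                primer_rev="" if r.primers is None else r.primers.rev_seq,
                primer_product="" if r.primers is None else r.primers.product_size,
                primer_fwd_tm="" if r.primers is None else r.primers.fwd_tm,
                primer_rev_tm="" if r.primers is None else r.primers.rev_tm,
                primer_fail_reason=r.primer_fail_reason or "",
                flank_left=r.flank_left,
                flank_right=r.flank_right,
            )
        )
    return rows


def _write_summary(cfg: RunConfig, lines: list[str]) -> None:
    with open(os.path.join(cfg.out_dir, "summary.txt"), "w") as fh:
        fh.write(f"workflow: {cfg.workflow}\n")
        for k in ("genome", "gff", "test_vcf", "control_vcf", "pool1_vcf", "pool2_vcf"):
            v = getattr(cfg, k)
            if v:
                fh.write(f"{k}: {v}\n")
        fh.write("\n")
        for line in lines:
            fh.write(line + "\n")


def _plot_density(profile: densmap.DensityProfile, bins: densmap.DensityProfile,
                  regions, outdir: str) -> None:
    chroms = list(dict.fromkeys(c for c, _, _ in profile.windows))
    for chrom in chroms:
        idx = [i for i, (c, _, _) in enumerate(profile.windows) if c == chrom]
        bidx = [i for i, (c, _, _) in enumerate(bins.windows) if c == chrom]
        mids = [(profile.windows[i][1] + profile.windows[i][2]) / 2 for i in idx]
        bmids = [(bins.windows[i][1] + bins.windows[i][2]) / 2 for i in bidx]
        cats = list(profile.counts)
        fig, axes = plt.subplots(len(cats), 1, figsize=(8, 2 * len(cats)),
                                 sharex=True, squeeze=False)
        for ax, cat in zip(axes[:, 0], cats):
            ax.bar(bmids, bins.counts[cat][bidx], width=bins.spec.size * 0.9,
                   color="0.8", label=f"{cat} per bin")
            ax.plot(mids, profile.counts[cat][idx], color="C3", lw=1.2,
                    label=f"{cat} sliding")
            for r in regions:
                if r.chrom == chrom:
                    ax.axvspan(r.start, r.end, color="pink", alpha=0.4)
            ax.set_ylabel(cat, fontsize=8)
            ax.legend(fontsize=6, loc="upper right")
        axes[-1, 0].set_xlabel(f"{chrom} position (bp)")
        fig.tight_layout()
        fig.savefig(os.path.join(outdir, f"density_{chrom}.svg"))
        plt.close(fig)


def _plot_daf(mvars, profile: qtlmap.DafProfile, regions, outdir: str,
              track: str = "daf") -> None:
    chroms = list(dict.fromkeys(c for c, _, _ in profile.windows))
    for chrom in chroms:
        fig, ax = plt.subplots(figsize=(8, 3))
        xs = [m.pos for m in mvars if m.chrom == chrom]
        ys = [m.daf for m in mvars if m.chrom == chrom]
        ax.plot(xs, ys, "k.", ms=2, alpha=0.5)
        idx = [i for i, (c, _, _) in enumerate(profile.windows) if c == chrom]
        mids = np.array([(profile.windows[i][1] + profile.windows[i][2]) / 2 for i in idx])
        wma = profile.daf_wma[idx]
        ok = ~np.isnan(wma)
        ax.plot(mids[ok], wma[ok], "r-", lw=1.5)
        for r in regions:
            if r.chrom == chrom:
                ax.axvspan(r.start, r.end, color="pink", alpha=0.4)
        ax.axhline(0, color="0.5", lw=0.5)
        ax.set_xlabel(f"{chrom} position (bp)")
        ax.set_ylabel("dAF / dAF_WMA")
        ax.set_ylim(-1.05, 1.05)
        fig.tight_layout()
        fig.savefig(os.path.join(outdir, f"{track}_{chrom}.svg"))
        plt.close(fig)


def _plot_af(test_specific: VariantSet, profile: linkmap.AfProfile, region,
             outdir: str) -> None:
    chroms = list(dict.fromkeys(c for c, _, _ in profile.windows))
    for chrom in chroms:
        fig, ax = plt.subplots(figsize=(8, 3))
        xs = [v.pos for v in test_specific if v.chrom == chrom]
        ys = [v.af for v in test_specific if v.chrom == chrom and v.af is not None]
        if len(xs) == len(ys):
            ax.plot(xs, ys, "k.", ms=2, alpha=0.5)
        idx = [i for i, (c, _, _) in enumerate(profile.windows) if c == chrom]
        mids = np.array([(profile.windows[i][1] + profile.windows[i][2]) / 2 for i in idx])
        wma = profile.af_wma[idx]
        ok = ~np.isnan(wma)
        ax.plot(mids[ok], wma[ok], "r-", lw=1.5)
        if region is not None and region.chrom == chrom:
            ax.axvspan(region.start, region.end, color="pink", alpha=0.4)
        ax.set_xlabel(f"{chrom} position (bp)")
        ax.set_ylabel("af / af_WMA")
        ax.set_ylim(-0.05, 1.05)
        fig.tight_layout()
        fig.savefig(os.path.join(outdir, f"af_{chrom}.svg"))
        plt.close(fig)


def run_dens(cfg: RunConfig) -> str:
    """Variant density mapping workflow; returns the report directory."""
    _setup_run(cfg)
    genome, genes = _load_common(cfg)
    if not cfg.test_vcf:
        raise ValueError("missing required input: --test")
    test = read_vcf(cfg.test_vcf)
    if cfg.control_vcf:
        control = read_vcf(cfg.control_vcf)
    else:
        log.warning("no control sample given: running without subtraction "
                    "is highly unadvisable for most mapping scenarios")
        control = VariantSet("control")
    fc = cfg.filter_config()
    spec = cfg.window_spec()

    specific = variantops.subtract_control(test, control)
    hom = variantops.filter_homozygous(specific, fc)
    ems = variantops.filter_ems(specific)
    hom_ems = variantops.intersect(hom, ems)

    profile = densmap.density_profile(
        densmap.standard_categories(test, specific, hom, ems, hom_ems),
        genome, spec,
    )
    bin_spec = densmap.WindowSpec(spec.size, spec.size)
    bins = densmap.density_profile(
        densmap.standard_categories(test, specific, hom, ems, hom_ems),
        genome, bin_spec,
    )
    regions = densmap.detect_peaks(profile, cfg.peak_category, cfg.peak_z,
                                   cfg.peak_min_count)
    cand_variants = densmap.extract_candidates(regions, specific, genes, fc)
    cand_set = VariantSet("candidates", cand_variants, genome.chrom_ids)
    functional = (
        ann.read_functional_map(cfg.functional_tsv) if cfg.functional_tsv else None
    )
    records = ann.analyze_set(cand_set, genes, genome, functional)

    out = cfg.out_dir
    write_tsv(
        [
            dict(chrom=c, start=s, end=e,
                 **{cat: int(profile.counts[cat][i]) for cat in profile.counts})
            for i, (c, s, e) in enumerate(profile.windows)
        ],
        os.path.join(out, "windows.tsv"),
    )
    write_tsv(
        [dataclasses.asdict(r) for r in regions],
        os.path.join(out, "regions.tsv"),
        columns=["chrom", "start", "end", "peak_count", "basis_category"],
    )
    write_tsv(_candidate_rows(records), os.path.join(out, "candidates.tsv"), columns=CANDIDATE_COLUMNS)
    write_vcf(cand_set, os.path.join(out, "candidates.vcf"), genome)
    _plot_density(profile, bins, regions, out)

    genes_named = sorted(
        {r.effect.gene_id for r in records if r.effect and r.effect.gene_id}
    )
    _write_summary(cfg, [
        f"test variants: {len(test)}",
        f"test-specific variants: {len(specific)}",
        f"homozygous: {len(hom)}; EMS-type: {len(ems)}; homozygous EMS-type: {len(hom_ems)}",
        f"regions of interest ({cfg.peak_category}): {len(regions)}",
        *[f"  region {r.chrom}:{r.start}-{r.end} peak_count={r.peak_count}" for r in regions],
        f"candidate variants: {len(records)}",
        f"candidate genes: {', '.join(genes_named) if genes_named else '(none)'}",
    ])
    return out


def run_qtlseq(cfg: RunConfig) -> str:
    """QTL-seq mapping workflow from two opposite-phenotype pools."""
    _setup_run(cfg)
    genome, genes = _load_common(cfg)
    if not cfg.pool1_vcf or not cfg.pool2_vcf:
        raise ValueError("missing required input: --pool1/--pool2")
    if not cfg.gff:
        log.warning("no structural annotation: candidate regions will be "
                    "reported without gene identification")
    pool1 = read_vcf(cfg.pool1_vcf)
    pool2 = read_vcf(cfg.pool2_vcf)
    spec = cfg.window_spec()

    mvars = qtlmap.select_mapping_variants(
        pool1, pool2, cfg.min_dp, cfg.snp_only_mapping_variants
    )
    profile = qtlmap.window_daf(mvars, genome, spec)
    profile = qtlmap.wma_smooth(profile, cfg.wma_weights)
    regions = qtlmap.call_qtl_regions(profile, cfg.daf_min, cfg.min_run)
    functional = (
        ann.read_functional_map(cfg.functional_tsv) if cfg.functional_tsv else None
    )
    records = qtlmap.qtl_candidates(
        regions, mvars, genes or None, genome, None, functional
    )

    out = cfg.out_dir
    write_tsv(
        [
            dict(chrom=c, start=s, end=e, n_variants=int(profile.n_variants[i]),
                 daf_mean="" if np.isnan(profile.daf_mean[i]) else round(float(profile.daf_mean[i]), 4),
                 daf_wma="" if np.isnan(profile.daf_wma[i]) else round(float(profile.daf_wma[i]), 4))
            for i, (c, s, e) in enumerate(profile.windows)
        ],
        os.path.join(out, "windows.tsv"),
    )
    write_tsv(
        [dataclasses.asdict(r) for r in regions],
        os.path.join(out, "regions.tsv"),
        columns=["chrom", "start", "end", "sign", "extremum"],
    )
    if genes:
        write_tsv(_candidate_rows(records), os.path.join(out, "candidates.tsv"), columns=CANDIDATE_COLUMNS)
    else:
        write_tsv(
            [dict(chrom=r.variant.chrom, pos=r.variant.pos,
                  ref=r.variant.ref, alt=r.variant.alt) for r in records],
            os.path.join(out, "candidates.tsv"),
            columns=["chrom", "pos", "ref", "alt"],
        )
    _plot_daf(mvars, profile, regions, out)
    _write_summary(cfg, [
        f"mapping variants: {len(mvars)}",
        f"candidate QTL regions: {len(regions)}",
        *[f"  region {r.chrom}:{r.start}-{r.end} sign={r.sign} "
          f"extremum={r.extremum:.3f}" for r in regions],
        f"candidate variants: {len(records)}"
        + ("" if genes else " (no gene annotation available)"),
    ])
    return out


def run_linkage(cfg: RunConfig) -> str:
    """Allele-frequency linkage scan for one mutant bulk."""
    _setup_run(cfg)
    genome, genes = _load_common(cfg)
    if not cfg.test_vcf:
        raise ValueError("missing required input: --test")
    test = read_vcf(cfg.test_vcf)
    if cfg.control_vcf:
        control = read_vcf(cfg.control_vcf)
    else:
        log.warning("no control sample given: running without subtraction "
                    "is highly unadvisable for most mapping scenarios")
        control = None
    fc = cfg.filter_config()
    profile, region, candidates = linkmap.linkage_scan(
        test, control, genome, cfg.window_spec(), fc, genes,
        cfg.af_peak_min, cfg.linkage_min_run, cfg.wma_weights,
    )
    cand_set = VariantSet("candidates", candidates, genome.chrom_ids)
    records = ann.analyze_set(cand_set, genes, genome)

    out = cfg.out_dir
    write_tsv(
        [
            dict(chrom=c, start=s, end=e, n_variants=int(profile.n_variants[i]),
                 af_mean="" if np.isnan(profile.af_mean[i]) else round(float(profile.af_mean[i]), 4),
                 af_wma="" if np.isnan(profile.af_wma[i]) else round(float(profile.af_wma[i]), 4))
            for i, (c, s, e) in enumerate(profile.windows)
        ],
        os.path.join(out, "windows.tsv"),
    )
    region_rows = [] if region is None else [dataclasses.asdict(region)]
    write_tsv(region_rows, os.path.join(out, "regions.tsv"),
              columns=["chrom", "start", "end", "peak_count", "basis_category"])
    write_tsv(_candidate_rows(records), os.path.join(out, "candidates.tsv"), columns=CANDIDATE_COLUMNS)
    write_vcf(cand_set, os.path.join(out, "candidates.vcf"), genome)
    spec_set = variantops.subtract_control(test, control) if control else test
    _plot_af(spec_set, profile, region, out)
    genes_named = sorted(
        {r.effect.gene_id for r in records if r.effect and r.effect.gene_id}
    )
    _write_summary(cfg, [
        f"test variants: {len(test)}",
        "linkage region: " + (
            "(none)" if region is None
            else f"{region.chrom}:{region.start}-{region.end}"
        ),
        f"candidate variants: {len(records)}",
        f"candidate genes: {', '.join(genes_named) if genes_named else '(none)'}",
    ])
    return out


def run_annotate(cfg: RunConfig) -> str:
    """Variant analyzer workflow: effect report for a VCF, no mapping."""
    _setup_run(cfg)
    genome, genes = _load_common(cfg)
    if not cfg.test_vcf:
        raise ValueError("missing required input: --test")
    test = read_vcf(cfg.test_vcf)
    if cfg.control_vcf:
        test = variantops.subtract_control(test, read_vcf(cfg.control_vcf))
    functional = (
        ann.read_functional_map(cfg.functional_tsv) if cfg.functional_tsv else None
    )
    records = ann.analyze_set(test, genes, genome, functional)
    out = cfg.out_dir
    write_tsv(_candidate_rows(records), os.path.join(out, "variants.tsv"), columns=CANDIDATE_COLUMNS)
    # one row per variant-transcript as the expanded report
    expanded = []
    for r in records:
        for a in r.annotations:
            expanded.append(
                dict(chrom=r.variant.chrom, pos=r.variant.pos,
                     ref=r.variant.ref, alt=r.variant.alt,
                     gene=a.gene_id or "", transcript=a.transcript_id or "",
                     element=a.element, consequence=a.consequence)
            )
    write_tsv(expanded, os.path.join(out, "variants_by_transcript.tsv"))
    _write_summary(cfg, [
        f"variants analyzed: {len(records)}",
        f"with primers: {sum(1 for r in records if r.primers is not None)}",
    ])
    return out


def run_simulate(cfg: RunConfig) -> str:
    """Generate a simulated mapping dataset (FASTA/GFF3/VCF + truth)."""
    _setup_run(cfg)
    if cfg.seed is None:
        raise ValueError("simulate requires --seed")
    overrides = dict(cfg.sim or {})
    sim_cfg = simpop.SimConfig(seed=cfg.seed, **overrides)
    genome, genes = simpop.simulate_genome(sim_cfg)
    simpop.write_genome(genome, genes, cfg.out_dir)
    scenario = cfg.scenario or "backcross"
    if scenario == "backcross":
        result = simpop.simulate_backcross(sim_cfg, genome, genes)
    elif scenario == "qtlseq":
        result = simpop.simulate_qtlseq(sim_cfg, genome)
    elif scenario == "f2":
        result = simpop.simulate_f2_bulk(sim_cfg, genome, genes)
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    result.write(cfg.out_dir, genome)
    _write_summary(cfg, [
        f"scenario: {scenario}",
        f"samples: {', '.join(result.samples)}",
        *[f"  {name}: {len(vs)} variants" for name, vs in result.samples.items()],
    ])
    return cfg.out_dir


RUNNERS = {
    "dens": run_dens,
    "qtlseq": run_qtlseq,
    "linkage": run_linkage,
    "annotate": run_annotate,
    "simulate": run_simulate,
}


def run(cfg: RunConfig) -> str:
    try:
        runner = RUNNERS[cfg.workflow]
    except KeyError:
        raise ValueError(f"unknown workflow {cfg.workflow!r}") from None
    return runner(cfg)
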