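"""Mapping-population simulator producing standard FASTA/GFF3/VCF fixtures.

The generator emulates the three experimental designs the mapping workflows
target:

* EMS mutagenesis followed by recurrent backcrossing to the reference
  strain (variant density mapping): G/C→A/T point mutations are induced,
  one of them causal inside a gene CDS; a heterozygous non-causal mutation
  survives each backcross with probability (1 - r), where r follows the
  Haldane map function of its physical distance to the causal site at a
  uniform cM/Mb rate (unlinked sites: r = 1/2).  Surviving linked mutations
  are homozygous in the final selected bulk; surviving unlinked mutations
  segregate 1:2:1 across the bulk.

* QTL-seq: two parental haplotypes segregate in an F2 population whose
  gametes follow a Markov recombination process along a regular marker
  grid; an additive QTL shifts the phenotype, and the extreme tails are
  bulked into two pools.

* Single-cross F2 mutant bulk (linkage mapping): selection fixes the
  causal locus and inflates linked allele frequencies through the same
  gamete-level recombination process.

Observed allele counts are binomial samples of the pooled frequency at the
configured read depth.  Truth sidecars record the causal key and per-site
ground truth; they are consumed only by tests, never by the mapping code.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np

from .genomeio import (
    GeneModel,
    Genome,
    Transcript,
    Variant,
    VariantSet,
    write_fasta,
    write_gff3,
    write_tsv,
    write_vcf,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_SIM_QUAL = 99.0

# RNG stream tags so the same config seed drives independent generators
_TAG_GENOME, _TAG_BACKCROSS, _TAG_QTLSEQ, _TAG_F2 = 0, 1, 2, 3


@dataclass(frozen=True)
class SimConfig:
    seed: int
    n_chrom: int = 2
    chrom_len: int = 10_000_000
    cm_per_mb: float = 4.0
    read_depth: int = 25
    population_size: int = 100
    n_backcrosses: int = 4
    n_mutations: int = 60
    n_background: int = 150
    marker_spacing: int = 25_000
    gene_spacing: int = 100_000
    qtl_chrom: Optional[str] = None
    qtl_pos: Optional[int] = None
    qtl_effect: float = 3.0
    tail_fraction: float = 0.1

    def __post_init__(self):
        for name in (
            "n_chrom", "chrom_len", "read_depth", "population_size",
            "n_backcrosses", "n_mutations", "n_background",
            "marker_spacing", "gene_spacing",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cm_per_mb <= 0 or self.tail_fraction <= 0:
            raise ValueError("cm_per_mb and tail_fraction must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class SimResult:
    samples: dict[str, VariantSet]
    truth: dict
    truth_rows: list[dict] = field(default_factory=list)

    def write(self, outdir, genome: Genome) -> None:
        os.makedirs(outdir, exist_ok=True)
        for name, vset in self.samples.items():
            write_vcf(vset, os.path.join(outdir, f"{name}.vcf"), genome)
        if self.truth_rows:
            write_tsv(self.truth_rows, os.path.join(outdir, "truth.tsv"))
        with open(os.path.join(outdir, "truth.json"), "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)


def haldane(d_morgans: float) -> float:
    """Recombination fraction from genetic distance (Haldane map function)."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_morgans))


def _bp_to_morgans(bp: float, cm_per_mb: float) -> float:
    return bp / 1e6 * cm_per_mb / 100.0


def _rng(cfg: SimConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, tag])


def simulate_genome(cfg: SimConfig) -> tuple[Genome, list[GeneModel]]:
    """Random reference genome with a regular grid of protein-coding genes.

    Sequence is i.i.d. uniform ACGT; one gene every gene_spacing bp on
    alternating strands, each with 2-4 exons and a valid CDS (ATG ... stop,
    no internal stops) embedded into the chromosome sequence.  Fully
    reproducible from the config seed.
    """
    rng = _rng(cfg, _TAG_GENOME)
    seqs: dict[str, np.ndarray] = {}
    genes: list[GeneModel] = []
    for ci in range(cfg.n_chrom):
        chrom = f"chr{ci + 1}"
        arr = _BASES[rng.integers(0, 4, cfg.chrom_len)]
        n_genes = cfg.chrom_len // cfg.gene_spacing
        for gi in range(n_genes):
            anchor = gi * cfg.gene_spacing + 1001  # 1-based gene start
            strand = "+" if (gi + ci) % 2 == 0 else "-"
            n_exons = int(rng.integers(2, 5))
            exon_lens = rng.integers(120, 301, n_exons)
            intron_lens = rng.integers(80, 201, max(n_exons - 1, 0))
            utr5, utr3 = 30, 30
            cds_len = int(exon_lens.sum()) - utr5 - utr3
            utr3 += cds_len % 3
            cds_len -= cds_len % 3

            exons: list[tuple[int, int]] = []
            pos = anchor
            for k in range(n_exons):
                exons.append((pos, pos + int(exon_lens[k]) - 1))
                pos = exons[-1][1] + 1
                if k < n_exons - 1:
                    pos += int(intron_lens[k])
            gene_end = exons[-1][1]
            if gene_end > cfg.chrom_len:
                continue

            # transcription-order UTR trimming: utr5 at the 5' end of the mRNA
            first_trim, last_trim = (utr5, utr3) if strand == "+" else (utr3, utr5)
            cds: list[tuple[int, int]] = []
            for k, (s, e) in enumerate(exons):
                cs, ce = s, e
                if k == 0:
                    cs += first_trim
                if k == n_exons - 1:
                    ce -= last_trim
                if cs <= ce:
                    cds.append((cs, ce))

            n_codons = cds_len // 3
            coding = "ATG" + "".join(
                rng.choice(_NON_STOP_CODONS) for _ in range(n_codons - 2)
            ) + "TAA"
            if strand == "-":
                placed = _revcomp(coding)
            else:
                placed = coding
            # fill the CDS intervals (ascending genomic order) with `placed`
            off = 0
            for s, e in cds:
                seg = placed[off : off + (e - s + 1)]
                arr[s - 1 : e] = np.frombuffer(seg.encode(), dtype=np.uint8)
                off += e - s + 1

            # per-interval phases in translation order
            phased: list[tuple[int, int, int]] = []
            order = cds if strand == "+" else list(reversed(cds))
            cum = 0
            phase_by_interval = {}
            for s, e in order:
                phase_by_interval[(s, e)] = (3 - cum % 3) % 3
                cum += e - s + 1
            for s, e in cds:
                phased.append((s, e, phase_by_interval[(s, e)]))

            gid = f"{chrom}g{gi + 1:04d}"
            genes.append(
                GeneModel(
                    gid,
                    chrom,
                    strand,
                    [Transcript(f"{gid}.1", exons, phased)],
                    functional_note=f"simulated gene {gid}",
                )
            )
        seqs[chrom] = arr
    genome = Genome({c: a.tobytes().decode() for c, a in seqs.items()})
    return genome, genes


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _sample_positions(
    rng: np.random.Generator,
    genome: Genome,
    chrom: str,
    n: int,
    base_filter: Optional[set[str]] = None,
    exclude: Optional[set[int]] = None,
) -> list[int]:
    """Distinct 1-based positions on `chrom`, optionally restricted by base."""
    length = genome.length(chrom)
    exclude = exclude or set()
    out: set[int] = set()
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200:
            raise ValueError(
                f"could not find {n} suitable positions on {chrom}"
            )
        cand = rng.integers(1, length + 1, size=max(4 * n, 64))
        for p in cand:
            p = int(p)
            if p in out or p in exclude:
                continue
            if base_filter is not None and genome.fetch(chrom, p, p) not in base_filter:
                continue
            out.add(p)
            if len(out) == n:
                break
    return sorted(out)


def _pick_causal(
    rng: np.random.Generator, genome: Genome, genes: list[GeneModel]
) -> tuple[GeneModel, int]:
    """A G/C position inside a random gene's CDS (EMS-mutable causal site)."""
    if not genes:
        raise ValueError("causal site requires gene models")
    order = rng.permutation(len(genes))
    for gi in order:
        g = genes[int(gi)]
        t = g.transcripts[0]
        cds_pos = [
            p
            for s, e, _ in t.cds
            for p in range(s, e + 1)
            if genome.fetch(g.chrom, p, p) in ("G", "C")
        ]
        if cds_pos:
            return g, int(rng.choice(cds_pos))
    raise ValueError("no G/C position available in any gene CDS")


def _ems_variant(genome: Genome, chrom: str, pos: int) -> tuple[str, str]:
    ref = genome.fetch(chrom, pos, pos)
    if ref == "G":
        return "G", "A"
    if ref == "C":
        return "C", "T"
    raise ValueError(f"EMS site at {chrom}:{pos} is not G/C")


def _depth_sample(
    rng: np.random.Generator, true_af: float, depth: int
) -> tuple[int, int]:
    alt = int(rng.binomial(depth, true_af))
    return depth - alt, alt


def simulate_backcross(
    cfg: SimConfig, genome: Genome, genes: list[GeneModel]
) -> SimResult:
    """Recurrent-backcross bulk for variant density mapping.

    Returns samples {"test", "control"}: the test carries the surviving
    mutagenesis variants plus surviving pre-mutagenesis background variants;
    the control carries all background variants (homozygous), so control
    subtraction leaves exactly the mutagenesis-derived set.
    """
    rng = _rng(cfg, _TAG_BACKCROSS)
    causal_gene, causal_pos = _pick_causal(rng, genome, genes)
    causal_chrom = causal_gene.chrom

    sites: list[dict] = []
    ref, alt = _ems_variant(genome, causal_chrom, causal_pos)
    sites.append(
        dict(chrom=causal_chrom, pos=causal_pos, ref=ref, alt=alt,
             kind="ems", causal=True)
    )
    used = {(causal_chrom, causal_pos)}
    # remaining EMS sites spread uniformly over all chromosomes
    per_chrom = _split_counts(rng, cfg.n_mutations - 1, genome)
    for chrom, n in per_chrom.items():
        excl = {p for c, p in used if c == chrom}
        for p in _sample_positions(rng, genome, chrom, n, {"G", "C"}, excl):
            r, a = _ems_variant(genome, chrom, p)
            sites.append(dict(chrom=chrom, pos=p, ref=r, alt=a, kind="ems", causal=False))
            used.add((chrom, p))
    per_chrom = _split_counts(rng, cfg.n_background, genome)
    for chrom, n in per_chrom.items():
        excl = {p for c, p in used if c == chrom}
        for p in _sample_positions(rng, genome, chrom, n, None, excl):
            r = genome.fetch(chrom, p, p)
            a = _TRANSITION[r]
            sites.append(dict(chrom=chrom, pos=p, ref=r, alt=a, kind="background", causal=False))
            used.add((chrom, p))

    k = cfg.n_backcrosses
    test_records: list[Variant] = []
    control_records: list[Variant] = []
    rows: list[dict] = []
    for s in sites:
        linked = s["chrom"] == causal_chrom
        if s["causal"]:
            survived, true_af = True, 1.0
        else:
            if linked:
                d = _bp_to_morgans(abs(s["pos"] - causal_pos), cfg.cm_per_mb)
                r = haldane(d)
            else:
                r = 0.5
            survived = bool(rng.random() < (1.0 - r) ** k)
            if survived:
                if linked:
                    true_af = 1.0
                else:
                    g = rng.choice([0, 1, 2], size=cfg.population_size,
                                   p=[0.25, 0.5, 0.25])
                    true_af = float(g.mean() / 2.0)
            else:
                true_af = 0.0
        if survived:
            ref_c, alt_c = _depth_sample(rng, true_af, cfg.read_depth)
            if alt_c > 0:
                test_records.append(
                    Variant(s["chrom"], s["pos"], s["ref"], s["alt"],
                            _SIM_QUAL, ref_c, alt_c)
                )
        if s["kind"] == "background":
            control_records.append(
                Variant(s["chrom"], s["pos"], s["ref"], s["alt"],
                        _SIM_QUAL, 0, cfg.read_depth)
            )
        rows.append(
            dict(chrom=s["chrom"], pos=s["pos"], ref=s["ref"], alt=s["alt"],
                 kind=s["kind"], causal=s["causal"], linked=linked,
                 survived=survived, true_af=round(true_af, 6))
        )

    chrom_ids = genome.chrom_ids
    return SimResult(
        samples={
            "test": VariantSet("test", test_records, chrom_ids),
            "control": VariantSet("control", control_records, chrom_ids),
        },
        truth={
            "causal": [causal_chrom, causal_pos,
                       sites[0]["ref"], sites[0]["alt"]],
            "causal_gene": causal_gene.gene_id,
            "n_backcrosses": k,
        },
        truth_rows=rows,
    )


def _split_counts(
    rng: np.random.Generator, n: int, genome: Genome
) -> dict[str, int]:
    """Multinomial split of n sites across chromosomes by length."""
    chroms = genome.chromosomes
    lens = np.array([l for _, l in chroms], dtype=float)
    counts = rng.multinomial(n, lens / lens.sum())
    return {c: int(k) for (c, _), k in zip(chroms, counts) if k > 0}


def _gamete_chains(
    rng: np.random.Generator,
    n_gametes: int,
    rec_fracs: np.ndarray,
    anchor_index: Optional[int] = None,
) -> np.ndarray:
    """Parental-origin Markov chains along a marker grid.

    Returns an (n_gametes, n_markers) 0/1 ancestry matrix.  rec_fracs[i] is
    the recombination fraction between markers i and i+1.  With an
    anchor_index, every gamete is conditioned to carry allele 1 there
    (selection at the causal locus); otherwise the first marker is a fair
    coin.  Conditioned chains extend outward from the anchor, which is exact
    for a Markov recombination process.
    """
    m = len(rec_fracs) + 1
    states = np.empty((n_gametes, m), dtype=np.int8)
    if anchor_index is None:
        states[:, 0] = rng.random(n_gametes) < 0.5
        for i in range(1, m):
            flip = rng.random(n_gametes) < rec_fracs[i - 1]
            states[:, i] = states[:, i - 1] ^ flip
        return states
    states[:, anchor_index] = 1
    for i in range(anchor_index + 1, m):
        flip = rng.random(n_gametes) < rec_fracs[i - 1]
        states[:, i] = states[:, i - 1] ^ flip
    for i in range(anchor_index - 1, -1, -1):
        flip = rng.random(n_gametes) < rec_fracs[i]
        states[:, i] = states[:, i + 1] ^ flip
    return states


def simulate_qtlseq(cfg: SimConfig, genome: Genome) -> SimResult:
    """Two opposite-tail F2 bulks segregating for parental marker alleles.

    The alternate allele at every marker is the parent-A allele.  Phenotype
    is qtl_effect * (genotype at the QTL marker - 1) + N(0, 1); the top and
    bottom tail_fraction of the population form pools 1 and 2.  qtl_effect
    of 0 gives the null generator.
    """
    rng = _rng(cfg, _TAG_QTLSEQ)
    n = cfg.population_size
    bulk = int(round(cfg.tail_fraction * n))
    if bulk < 1:
        raise ValueError("tail_fraction * population_size < 1")

    qtl_chrom = cfg.qtl_chrom or genome.chrom_ids[0]
    qtl_pos = cfg.qtl_pos if cfg.qtl_pos is not None else genome.length(qtl_chrom) // 2

    marker_pos: dict[str, np.ndarray] = {}
    genotypes: dict[str, np.ndarray] = {}
    for chrom, length in genome.chromosomes:
        pos = np.arange(cfg.marker_spacing, length + 1, cfg.marker_spacing)
        marker_pos[chrom] = pos
        r = np.full(
            len(pos) - 1,
            haldane(_bp_to_morgans(cfg.marker_spacing, cfg.cm_per_mb)),
        )
        chains = _gamete_chains(rng, 2 * n, r)
        genotypes[chrom] = (chains[0::2] + chains[1::2]).astype(np.int8)

    qi = int(np.argmin(np.abs(marker_pos[qtl_chrom] - qtl_pos)))
    g_qtl = genotypes[qtl_chrom][:, qi].astype(float)
    phenotype = cfg.qtl_effect * (g_qtl - 1.0) + rng.normal(size=n)
    order = np.argsort(phenotype, kind="stable")
    low_idx, high_idx = order[:bulk], order[-bulk:]

    pools = {"pool1": high_idx, "pool2": low_idx}
    records: dict[str, list[Variant]] = {p: [] for p in pools}
    for chrom, pos in marker_pos.items():
        refs = [genome.fetch(chrom, int(p), int(p)) for p in pos]
        alts = [_TRANSITION[b] for b in refs]
        for pool, idx in pools.items():
            af = genotypes[chrom][idx].sum(axis=0) / (2.0 * bulk)
            alt_counts = rng.binomial(cfg.read_depth, af)
            for j, p in enumerate(pos):
                ac = int(alt_counts[j])
                if ac == 0:
                    continue
                records[pool].append(
                    Variant(chrom, int(p), refs[j], alts[j], _SIM_QUAL,
                            cfg.read_depth - ac, ac)
                )

    chrom_ids = genome.chrom_ids
    qp = int(marker_pos[qtl_chrom][qi])
    return SimResult(
        samples={
            p: VariantSet(p.upper(), recs, chrom_ids)
            for p, recs in records.items()
        },
        truth={
            "qtl_chrom": qtl_chrom,
            "qtl_pos": qp,
            "qtl_marker": [qtl_chrom, qp,
                           genome.fetch(qtl_chrom, qp, qp),
                           _TRANSITION[genome.fetch(qtl_chrom, qp, qp)]],
            "qtl_effect": cfg.qtl_effect,
            "bulk_size": bulk,
        },
    )


def simulate_f2_bulk(
    cfg: SimConfig, genome: Genome, genes: list[GeneModel]
) -> SimResult:
    """Single-cross F2 mutant bulk for the allele-frequency linkage scan.

    The mutant parent is homozygous for n_mutations EMS variants (one causal
    in a gene CDS) and n_background natural variants; the bulk contains only
    individuals homozygous mutant at the causal site, so the causal allele
    frequency is exactly 1 and linked frequencies decay with the Haldane
    recombination fraction through the gamete-level Markov process.
    """
    rng = _rng(cfg, _TAG_F2)
    causal_gene, causal_pos = _pick_causal(rng, genome, genes)
    causal_chrom = causal_gene.chrom

    sites: list[dict] = []
    ref, alt = _ems_variant(genome, causal_chrom, causal_pos)
    sites.append(dict(chrom=causal_chrom, pos=causal_pos, ref=ref, alt=alt,
                      kind="ems", causal=True))
    used = {(causal_chrom, causal_pos)}
    per_chrom = _split_counts(rng, cfg.n_mutations - 1, genome)
    for chrom, cnt in per_chrom.items():
        excl = {p for c, p in used if c == chrom}
        for p in _sample_positions(rng, genome, chrom, cnt, {"G", "C"}, excl):
            r_, a_ = _ems_variant(genome, chrom, p)
            sites.append(dict(chrom=chrom, pos=p, ref=r_, alt=a_, kind="ems", causal=False))
            used.add((chrom, p))
    per_chrom = _split_counts(rng, cfg.n_background, genome)
    for chrom, cnt in per_chrom.items():
        excl = {p for c, p in used if c == chrom}
        for p in _sample_positions(rng, genome, chrom, cnt, None, excl):
            r_ = genome.fetch(chrom, p, p)
            sites.append(dict(chrom=chrom, pos=p, ref=r_, alt=_TRANSITION[r_],
                              kind="background", causal=False))
            used.add((chrom, p))

    by_chrom: dict[str, list[dict]] = {}
    for s in sites:
        by_chrom.setdefault(s["chrom"], []).append(s)
    for lst in by_chrom.values():
        lst.sort(key=lambda s: s["pos"])

    n_gametes = 2 * cfg.population_size
    true_af: dict[tuple[str, int], float] = {}
    for chrom, lst in by_chrom.items():
        pos = np.array([s["pos"] for s in lst], dtype=float)
        r = haldane(_bp_to_morgans(np.abs(np.diff(pos)), cfg.cm_per_mb))
        anchor = None
        if chrom == causal_chrom:
            anchor = int(np.searchsorted(pos, causal_pos))
        chains = _gamete_chains(rng, n_gametes, r, anchor)
        af = chains.mean(axis=0)
        for s, a in zip(lst, af):
            true_af[(chrom, s["pos"])] = float(a)

    test_records: list[Variant] = []
    control_records: list[Variant] = []
    rows: list[dict] = []
    for s in sites:
        a = true_af[(s["chrom"], s["pos"])]
        ref_c, alt_c = _depth_sample(rng, a, cfg.read_depth)
        if alt_c > 0:
            test_records.append(
                Variant(s["chrom"], s["pos"], s["ref"], s["alt"],
                        _SIM_QUAL, ref_c, alt_c)
            )
        if s["kind"] == "background":
            control_records.append(
                Variant(s["chrom"], s["pos"], s["ref"], s["alt"],
                        _SIM_QUAL, 0, cfg.read_depth)
            )
        rows.append(
            dict(chrom=s["chrom"], pos=s["pos"], ref=s["ref"], alt=s["alt"],
                 kind=s["kind"], causal=s["causal"],
                 linked=s["chrom"] == causal_chrom,
                 true_af=round(a, 6))
        )

    chrom_ids = genome.chrom_ids
    return SimResult(
        samples={
            "test": VariantSet("test", test_records, chrom_ids),
            "control": VariantSet("control", control_records, chrom_ids),
        },
        truth={
            "causal": [causal_chrom, causal_pos, sites[0]["ref"], sites[0]["alt"]],
            "causal_gene": causal_gene.gene_id,
        },
        truth_rows=rows,
    )


def write_genome(genome: Genome, genes: list[GeneModel], outdir) -> tuple[str, str]:
    os.makedirs(outdir, exist_ok=True)
    fa = os.path.join(outdir, "genome.fa")
    gff = os.path.join(outdir, "genes.gff3")
    write_fasta(genome, fa)
    write_gff3(genes, gff)
    return fa, gff
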