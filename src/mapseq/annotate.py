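"""Variant analyzer: gene/product effects, genotyping primers, flanks.

For every variant the analyzer reports the gene element hit (CDS, intron,
splice site, UTRs, upstream/downstream margin, or intergenic), the codon and
amino-acid change for coding SNPs (rebuilt from the CDS-concatenated
sequence honoring strand and phase, standard genetic code), a deterministic
pair of genotyping primers, and the reference sequence flanking the variant.
All transcripts overlapping a variant are annotated; no canonical-transcript
selection is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Seq import Seq

from .genomeio import GeneModel, Genome, Transcript, Variant, VariantSet

log = logging.getLogger(__name__)

#: most to least damaging; used only to pick the headline effect per variant
SEVERITY = (
    "start_loss",
    "nonsense",
    "frameshift",
    "stop_loss",
    "splice_disruption",
    "missense",
    "inframe_indel",
    "synonymous",
    "noncoding",
    "intergenic",
)


@dataclass(frozen=True)
class AnnotateConfig:
    flank_len: int = 25
    upstream_margin: int = 500
    primer_min_dist: int = 50
    primer_max_dist: int = 400
    primer_len_min: int = 18
    primer_len_max: int = 24
    primer_opt_len: int = 20
    primer_gc_min: float = 40.0
    primer_gc_max: float = 60.0
    primer_tm_max_diff: float = 3.0
    product_min: int = 150
    product_max: int = 800


@dataclass(frozen=True)
class EffectAnnotation:
    gene_id: Optional[str]
    transcript_id: Optional[str]
    element: str
    consequence: str
    codon_change: Optional[str] = None  # "GCT>ACT"
    aa_change: Optional[tuple[str, int, str]] = None  # (refAA, position, altAA)
    incomplete_model: bool = False


@dataclass(frozen=True)
class PrimerPair:
    fwd_seq: str
    rev_seq: str
    fwd_start: int
    rev_start: int  # 1-based start (leftmost genome base) of the rev primer site
    product_size: int
    fwd_tm: float
    rev_tm: float


@dataclass
class CandidateRecord:
    variant: Variant
    effect: Optional[EffectAnnotation]
    functional_note: Optional[str]
    primers: Optional[PrimerPair]
    primer_fail_reason: Optional[str]
    flank_left: str
    flank_right: str
    annotations: list[EffectAnnotation] = field(default_factory=list)


_INTERGENIC = EffectAnnotation(None, None, "intergenic", "intergenic")


def wallace_tm(seq: str) -> float:
    """Wallace-rule melting temperature: 2(A+T) + 4(G+C), deg C."""
    at = seq.count("A") + seq.count("T")
    gc = seq.count("G") + seq.count("C")
    return 2.0 * at + 4.0 * gc


def gc_percent(seq: str) -> float:
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def _cds_sequence(t: Transcript, chrom: str, strand: str, genome: Genome) -> str:
    """Coding sequence 5'→3', phase-leading bases trimmed."""
    parts = [genome.fetch(chrom, s, e) for s, e, _ in t.cds]
    seq = "".join(parts)
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
        lead = t.cds[-1][2]
    else:
        lead = t.cds[0][2]
    return seq[lead:]


def _cds_offset(t: Transcript, strand: str, pos: int) -> Optional[int]:
    """0-based offset of genomic `pos` within the 5'→3' CDS, before phase trim."""
    if strand == "+":
        off = 0
        for s, e, _ in t.cds:
            if s <= pos <= e:
                return off + (pos - s)
            off += e - s + 1
        return None
    off = 0
    for s, e, _ in reversed(t.cds):
        if s <= pos <= e:
            return off + (e - pos)
        off += e - s + 1
    return None


def _in_intervals(pos: int, ivals: Sequence[tuple[int, int]]) -> bool:
    return any(s <= pos <= e for s, e in ivals)


def _splice_site(pos: int, exons: Sequence[tuple[int, int]]) -> bool:
    """First/last 2 nt of any intron between consecutive exons."""
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        intron = (e1 + 1, s2 - 1)
        if intron[1] < intron[0]:
            continue
        if intron[0] <= pos <= min(intron[0] + 1, intron[1]):
            return True
        if max(intron[1] - 1, intron[0]) <= pos <= intron[1]:
            return True
    return False


def _utr_element(pos: int, t: Transcript, strand: str) -> str:
    cds_span = t.cds_span
    if cds_span is None:
        return "exon_noncoding"
    if pos < cds_span[0]:
        return "five_prime_utr" if strand == "+" else "three_prime_utr"
    if pos > cds_span[1]:
        return "three_prime_utr" if strand == "+" else "five_prime_utr"
    return "exon_noncoding"


def _annotate_transcript(
    v: Variant, gene: GeneModel, t: Transcript, genome: Genome
) -> EffectAnnotation:
    strand = gene.strand
    ref_span = (v.pos, v.pos + len(v.ref) - 1)
    ts, te = t.span

    # indels: does the affected reference span touch CDS / splice sites?
    if v.vclass != "snp":
        affected = range(ref_span[0], ref_span[1] + 1)
        if v.vclass == "insertion":
            affected = [v.pos]  # anchor base; inserted bases follow it
        in_cds = any(_in_intervals(p, [(s, e) for s, e, _ in t.cds]) for p in affected)
        splice = any(_splice_site(p, t.exons) for p in affected)
        if splice:
            return EffectAnnotation(
                gene.gene_id, t.transcript_id, "splice_site", "splice_disruption"
            )
        if in_cds:
            if t.incomplete:
                return EffectAnnotation(
                    gene.gene_id, t.transcript_id, "cds", "noncoding",
                    incomplete_model=True,
                )
            delta = abs(len(v.alt) - len(v.ref))
            cons = "frameshift" if delta % 3 != 0 else "inframe_indel"
            return EffectAnnotation(gene.gene_id, t.transcript_id, "cds", cons)
        # fall through to positional elements with the anchor position
        pos = v.pos
    else:
        pos = v.pos

    if not (ts <= pos <= te):
        # inside gene span but outside this transcript: treat like
        # upstream/downstream relative to the transcript
        before = pos < ts
        if strand == "+":
            element = "upstream" if before else "downstream"
        else:
            element = "downstream" if before else "upstream"
        return EffectAnnotation(gene.gene_id, t.transcript_id, element, "noncoding")

    if _splice_site(pos, t.exons):
        return EffectAnnotation(
            gene.gene_id, t.transcript_id, "splice_site", "splice_disruption"
        )
    if not _in_intervals(pos, t.exons):
        return EffectAnnotation(gene.gene_id, t.transcript_id, "intron", "noncoding")
    if not _in_intervals(pos, [(s, e) for s, e, _ in t.cds]):
        element = _utr_element(pos, t, strand)
        return EffectAnnotation(gene.gene_id, t.transcript_id, element, "noncoding")

    # coding SNP
    if t.incomplete:
        return EffectAnnotation(
            gene.gene_id, t.transcript_id, "cds", "noncoding", incomplete_model=True
        )
    cds_seq = _cds_sequence(t, gene.chrom, strand, genome)
    off = _cds_offset(t, strand, pos)
    lead = t.cds[-1][2] if strand == "-" else t.cds[0][2]
    off -= lead
    if off < 0 or off >= len(cds_seq):
        return EffectAnnotation(gene.gene_id, t.transcript_id, "cds", "noncoding")
    ref_base = v.ref if strand == "+" else str(Seq(v.ref).complement())
    alt_base = v.alt if strand == "+" else str(Seq(v.alt).complement())
    if cds_seq[off] != ref_base:
        log.warning(
            "reference mismatch for %s in %s (CDS has %s, VCF ref %s)",
            v.key, t.transcript_id, cds_seq[off], ref_base,
        )
    codon_i = off // 3
    codon = cds_seq[codon_i * 3 : codon_i * 3 + 3]
    if len(codon) < 3:
        return EffectAnnotation(gene.gene_id, t.transcript_id, "cds", "noncoding")
    within = off % 3
    alt_codon = codon[:within] + alt_base + codon[within + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if codon_i == 0 and ref_aa == "M" and alt_aa != "M":
        cons = "start_loss"
    elif ref_aa != "*" and alt_aa == "*":
        cons = "nonsense"
    elif ref_aa == "*" and alt_aa != "*":
        cons = "stop_loss"
    elif ref_aa != alt_aa:
        cons = "missense"
    else:
        cons = "synonymous"
    return EffectAnnotation(
        gene.gene_id,
        t.transcript_id,
        "cds",
        cons,
        codon_change=f"{codon}>{alt_codon}",
        aa_change=(ref_aa, codon_i + 1, alt_aa),
    )


def annotate_variant(
    v: Variant,
    genes: Sequence[GeneModel],
    genome: Genome,
    upstream_margin: int = 500,
) -> list[EffectAnnotation]:
    """One annotation per overlapping transcript.

    Variants within `upstream_margin` bp of a gene span get an
    upstream/downstream annotation; everything else is intergenic.
    """
    out: list[EffectAnnotation] = []
    near: list[EffectAnnotation] = []
    for g in genes:
        if g.chrom != v.chrom:
            continue
        gs, ge = g.span
        if gs <= v.pos <= ge:
            for t in g.transcripts:
                out.append(_annotate_transcript(v, g, t, genome))
        elif gs - upstream_margin <= v.pos < gs:
            element = "upstream" if g.strand == "+" else "downstream"
            near.append(EffectAnnotation(g.gene_id, None, element, "noncoding"))
        elif ge < v.pos <= ge + upstream_margin:
            element = "downstream" if g.strand == "+" else "upstream"
            near.append(EffectAnnotation(g.gene_id, None, element, "noncoding"))
    if out:
        return out
    if near:
        return near
    return [_INTERGENIC]


def flanks(
    v: Variant, genome: Genome, flank_len: int = 25
) -> tuple[str, str]:
    """Reference sequence on both sides of the variant, clipped at
    chromosome bounds: [pos-flank_len, pos-1] and
    [pos+len(ref), pos+len(ref)+flank_len-1]."""
    n = genome.length(v.chrom)
    ls = max(1, v.pos - flank_len)
    left = genome.fetch(v.chrom, ls, v.pos - 1) if v.pos > 1 else ""
    rs = v.pos + len(v.ref)
    re_ = min(n, rs + flank_len - 1)
    right = genome.fetch(v.chrom, rs, re_) if rs <= n else ""
    return left, right


def _acceptable(seq: str, cfg: AnnotateConfig) -> bool:
    if "N" in seq:
        return False
    return cfg.primer_gc_min <= gc_percent(seq) <= cfg.primer_gc_max


def _len_order(cfg: AnnotateConfig) -> list[int]:
    """Optimum length first, then progressively longer, then shorter."""
    longer = list(range(cfg.primer_opt_len + 1, cfg.primer_len_max + 1))
    shorter = list(range(cfg.primer_opt_len - 1, cfg.primer_len_min - 1, -1))
    return [cfg.primer_opt_len] + longer + shorter


def design_primers(
    v: Variant, genome: Genome, cfg: AnnotateConfig = AnnotateConfig()
) -> tuple[Optional[PrimerPair], Optional[str]]:
    """Deterministic genotyping-primer scan around a variant.

    Candidate primers are evaluated outward from primer_min_dist to
    primer_max_dist on each side; melting temperature follows the Wallace
    rule and GC content must sit in [gc_min, gc_max].  The first pair with
    |Tm difference| <= 3 degC and a product of 150-800 bp spanning the
    variant is returned.  Returns (pair, None) on success or (None, reason).
    """
    n = genome.length(v.chrom)
    lens = _len_order(cfg)

    fwd_cands: list[tuple[int, str]] = []  # (start, seq)
    for dist in range(cfg.primer_min_dist, cfg.primer_max_dist + 1):
        end3 = v.pos - dist  # 3' end of the forward primer
        if end3 < 1:
            break
        for L in lens:
            start = end3 - L + 1
            if start < 1:
                continue
            seq = genome.fetch(v.chrom, start, end3)
            if _acceptable(seq, cfg):
                fwd_cands.append((start, seq))
                break

    rev_cands: list[tuple[int, str]] = []  # (site start, primer seq rc)
    ref_end = v.pos + len(v.ref) - 1
    for dist in range(cfg.primer_min_dist, cfg.primer_max_dist + 1):
        start5 = ref_end + dist  # leftmost genome base of the rev primer site
        for L in lens:
            end = start5 + L - 1
            if end > n:
                continue
            site = genome.fetch(v.chrom, start5, end)
            seq = str(Seq(site).reverse_complement())
            if _acceptable(seq, cfg):
                rev_cands.append((start5, seq))
                break
        if start5 > n:
            break

    if not fwd_cands or not rev_cands:
        return None, "tm_range"

    saw_tm_pair = False
    for fs, fseq in fwd_cands:
        ftm = wallace_tm(fseq)
        for rs, rseq in rev_cands:
            rtm = wallace_tm(rseq)
            if abs(ftm - rtm) > cfg.primer_tm_max_diff:
                continue
            saw_tm_pair = True
            product = (rs + len(rseq) - 1) - fs + 1
            if cfg.product_min <= product <= cfg.product_max:
                return (
                    PrimerPair(fseq, rseq, fs, rs, product, ftm, rtm),
                    None,
                )
    return None, "product_size" if saw_tm_pair else "tm_mismatch"


def pick_primary(annotations: Sequence[EffectAnnotation]) -> EffectAnnotation:
    rank = {c: i for i, c in enumerate(SEVERITY)}
    return min(annotations, key=lambda a: rank.get(a.consequence, len(rank)))


def analyze_set(
    vset: VariantSet,
    genes: Sequence[GeneModel],
    genome: Genome,
    functional_map: Optional[dict[str, str]] = None,
    cfg: AnnotateConfig = AnnotateConfig(),
) -> list[CandidateRecord]:
    """Full analyzer report: exactly one CandidateRecord per variant.

    The headline effect is the most severe annotation across overlapping
    transcripts; every per-transcript annotation is kept on the record.
    """
    functional_map = functional_map or {}
    fm: dict[str, str] = dict(functional_map)
    for g in genes:
        if g.functional_note and g.gene_id not in fm:
            fm[g.gene_id] = g.functional_note
    records = []
    for v in vset:
        anns = annotate_variant(v, genes, genome, cfg.upstream_margin)
        primary = pick_primary(anns)
        left, right = flanks(v, genome, cfg.flank_len)
        pair, reason = design_primers(v, genome, cfg)
        records.append(
            CandidateRecord(
                variant=v,
                effect=primary,
                functional_note=fm.get(primary.gene_id) if primary.gene_id else None,
                primers=pair,
                primer_fail_reason=reason,
                flank_left=left,
                flank_right=right,
                annotations=list(anns),
            )
        )
    return records


def read_functional_map(path) -> dict[str, str]:
    """2-column TSV: gene id -> functional description."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) >= 2:
                out[parts[0]] = parts[1]
    return out
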