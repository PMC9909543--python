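"""Readers, writers and the coordinate/data model shared by every workflow.

All coordinates in this package are 1-based and closed, the convention of
GFF3 and VCF.  The reference genome (FASTA) defines the canonical chromosome
order; variant sets and gene models read from VCF/GFF3 are reordered to
match it.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pysam
from Bio import SeqIO

log = logging.getLogger(__name__)

VariantKey = tuple[str, int, str, str]

_VALID_ALPHABET = set("ACGTN")


class Genome:
    """Reference genome held in memory.

    Chromosome order is the order of construction (FASTA record order) and is
    canonical for every downstream profile and report.
    """

    def __init__(self, chromosomes: dict[str, str]):
        if not chromosomes:
            raise ValueError("genome must contain at least one chromosome")
        self._seqs: dict[str, str] = {}
        for chrom, seq in chromosomes.items():
            seq = seq.upper()
            if not seq:
                raise ValueError(f"chromosome {chrom!r} has empty sequence")
            self._seqs[chrom] = seq

    @property
    def chrom_ids(self) -> list[str]:
        return list(self._seqs)

    @property
    def chromosomes(self) -> list[tuple[str, int]]:
        return [(c, len(s)) for c, s in self._seqs.items()]

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the uppercase sequence of [start, end], 1-based inclusive."""
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        n = len(self._seqs[chrom])
        if start < 1 or end > n or start > end:
            raise ValueError(
                f"slice [{start}, {end}] outside [1, {n}] on {chrom}"
            )
        return self._seqs[chrom][start - 1 : end]

    def chrom_index(self, chrom: str) -> int:
        return self.chrom_ids.index(chrom)


@dataclass
class Transcript:
    transcript_id: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int, int]]  # (start, end, phase)
    incomplete: bool = False

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def cds_span(self) -> Optional[tuple[int, int]]:
        if not self.cds:
            return None
        return self.cds[0][0], self.cds[-1][1]


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript]
    functional_note: Optional[str] = None

    @property
    def span(self) -> tuple[int, int]:
        starts = [t.span[0] for t in self.transcripts]
        ends = [t.span[1] for t in self.transcripts]
        return min(starts), max(ends)

    def contains(self, pos: int) -> bool:
        s, e = self.span
        return s <= pos <= e


@dataclass(frozen=True)
class Variant:
    """One biallelic record in VCF convention (pos = first ref base)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float = 0.0
    ref_count: Optional[int] = None
    alt_count: Optional[int] = None

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.qual < 0:
            raise ValueError("qual must be >= 0")
        for c in (self.ref_count, self.alt_count):
            if c is not None and c < 0:
                raise ValueError("allele counts must be >= 0")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def depth(self) -> Optional[int]:
        if self.ref_count is None or self.alt_count is None:
            return None
        return self.ref_count + self.alt_count

    @property
    def af(self) -> Optional[float]:
        """Alternate allele frequency; None when counts are absent or zero."""
        dp = self.depth
        if dp is None or dp == 0:
            return None
        return self.alt_count / dp

    @property
    def vclass(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "snp"
        if len(self.alt) > len(self.ref):
            return "insertion"
        return "deletion"


class VariantSet:
    """Variants for one sample, keyed by (chrom, pos, ref, alt).

    Iteration is ordered by chromosome (canonical order when known, otherwise
    first-appearance order) and ascending position.
    """

    def __init__(
        self,
        sample_id: str = "",
        records: Optional[Iterable[Variant]] = None,
        chrom_order: Optional[list[str]] = None,
    ):
        self.sample_id = sample_id
        self._records: dict[VariantKey, Variant] = {}
        self._chrom_order: list[str] = list(chrom_order) if chrom_order else []
        for v in records or ():
            self.add(v)

    @property
    def chrom_order(self) -> list[str]:
        return list(self._chrom_order)

    def add(self, v: Variant) -> None:
        if v.key in self._records:
            raise ValueError(f"duplicate variant key {v.key}")
        if v.chrom not in self._chrom_order:
            self._chrom_order.append(v.chrom)
        self._records[v.key] = v

    def get(self, key: VariantKey) -> Optional[Variant]:
        return self._records.get(key)

    def keys(self) -> set[VariantKey]:
        return set(self._records)

    def __contains__(self, item) -> bool:
        key = item.key if isinstance(item, Variant) else item
        return key in self._records

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[Variant]:
        order = {c: i for i, c in enumerate(self._chrom_order)}
        return iter(
            sorted(
                self._records.values(),
                key=lambda v: (order.get(v.chrom, len(order)), v.pos, v.ref, v.alt),
            )
        )

    def spawn(self, records: Iterable[Variant]) -> "VariantSet":
        """New set with the same sample id and chromosome order."""
        return VariantSet(self.sample_id, records, self._chrom_order)


def read_fasta(path: str | os.PathLike) -> Genome:
    """Parse a FASTA file into a Genome.

    Headers are tokenized at the first whitespace; sequences are uppercased.
    Duplicate chromosome ids and empty files are hard errors.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate chromosome id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return Genome(seqs)


def write_fasta(genome: Genome, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, _ in genome.chromosomes:
            fh.write(f">{chrom}\n")
            seq = genome.fetch(chrom, 1, genome.length(chrom))
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _attr_first(feature, *names) -> Optional[str]:
    for name in names:
        vals = feature.attributes.get(name)
        if vals:
            return vals[0]
    return None


def read_gff(path: str | os.PathLike, genome: Genome) -> list[GeneModel]:
    """Parse GFF3 gene/mRNA/exon/CDS features into GeneModels.

    Features on chromosomes absent from the genome are dropped with a
    warning.  A transcript whose CDS length (after phase adjustment) is not
    divisible by 3 is flagged incomplete and excluded from amino-acid calls
    downstream.  An annotation with no gene features yields an empty list.
    """
    import gffutils

    if os.path.getsize(path) == 0:
        return []
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # unparseable file: warn, behave as empty
        log.warning("could not parse GFF3 %s: %s", path, exc)
        return []

    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by="start"):
        if g.seqid not in genome:
            log.warning(
                "gene %s on unknown chromosome %s dropped", g.id, g.seqid
            )
            continue
        transcripts: list[Transcript] = []
        mrnas = list(db.children(g, featuretype=("mRNA", "transcript")))
        for t in mrnas:
            exons = sorted(
                (f.start, f.end)
                for f in db.children(t, featuretype="exon")
            )
            cds = sorted(
                (f.start, f.end, int(f.frame) if f.frame not in (None, ".") else 0)
                for f in db.children(t, featuretype="CDS")
            )
            if not exons and cds:
                exons = [(s, e) for s, e, _ in cds]
            if not exons:
                continue
            incomplete = False
            if cds:
                if g.strand == "-":
                    lead_phase = cds[-1][2]
                else:
                    lead_phase = cds[0][2]
                total = sum(e - s + 1 for s, e, _ in cds) - lead_phase
                if total % 3 != 0:
                    incomplete = True
            transcripts.append(
                Transcript(t.id, exons, cds, incomplete=incomplete)
            )
        if transcripts:
            note = _attr_first(g, "Note", "description")
            genes.append(
                GeneModel(g.id, g.seqid, g.strand, transcripts, note)
            )
    # canonical chromosome order, then coordinate
    genes.sort(key=lambda gm: (genome.chrom_index(gm.chrom), gm.span[0]))
    return genes


def write_gff3(genes: list[GeneModel], path: str | os.PathLike, source: str = "mapseq") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            gs, ge = g.span
            attrs = f"ID={g.gene_id}"
            if g.functional_note:
                attrs += f";Note={g.functional_note}"
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{gs}\t{ge}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for t in g.transcripts:
                ts, te = t.span
                fh.write(
                    f"{g.chrom}\t{source}\tmRNA\t{ts}\t{te}\t.\t{g.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={g.gene_id}\n"
                )
                for s, e in t.exons:
                    fh.write(
                        f"{g.chrom}\t{source}\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                        f"Parent={t.transcript_id}\n"
                    )
                for s, e, phase in t.cds:
                    fh.write(
                        f"{g.chrom}\t{source}\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phase}\t"
                        f"Parent={t.transcript_id}\n"
                    )


def _ad_counts(rec, sample: str, alt_index: int) -> tuple[Optional[int], Optional[int]]:
    """Allele counts for one alt, FORMAT AD first, INFO DP4 fallback.

    Multi-allelic sites follow the convention af_i = alt_i / total depth, so
    ref_count is stored as (total depth - alt_i): every read that does not
    support this alternate allele.  This keeps the per-site sum of allele
    frequencies at or below 1 and makes counts round-trip through AD.
    """
    n_alts = len(rec.alts or ())
    if sample and sample in rec.samples:
        ad = rec.samples[sample].get("AD")
        if ad is not None and all(x is not None for x in ad) and len(ad) >= n_alts + 1:
            total = int(sum(ad))
            alt_c = int(ad[alt_index + 1])
            return total - alt_c, alt_c
    dp4 = rec.info.get("DP4") if "DP4" in rec.info else None
    if dp4 is not None and len(dp4) == 4 and n_alts == 1:
        ref_c = int(dp4[0]) + int(dp4[1])
        alt_c = int(dp4[2]) + int(dp4[3])
        return ref_c, alt_c
    return None, None


def read_vcf(path: str | os.PathLike, sample: Optional[str] = None) -> VariantSet:
    """Read a VCF 4.x file into a VariantSet.

    Multi-allelic rows are split into one Variant per alternate allele with
    per-allele counts.  Records with a FILTER other than PASS or "." are
    dropped.  Symbolic alleles, spanning deletions ("*") and equal-length
    multi-nucleotide substitutions have no class in this data model and are
    skipped with a warning.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(str(path))
    vset_records: list[Variant] = []
    chrom_order: list[str] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if sample is None:
            sample = samples[0] if samples else ""
        elif sample not in samples:
            raise ValueError(f"sample {sample!r} not in {path}")
        for ctg in vf.header.contigs:
            chrom_order.append(ctg)
        for rec in vf:
            filters = list(rec.filter.keys())
            if filters and filters != ["PASS"]:
                continue
            if rec.alts is None:
                continue
            for i, alt in enumerate(rec.alts):
                if alt is None or not set(alt) <= set("ACGTacgt"):
                    log.warning(
                        "skipping non-sequence alt %r at %s:%s", alt, rec.chrom, rec.pos
                    )
                    continue
                ref = rec.ref.upper()
                alt = alt.upper()
                if len(ref) == len(alt) and len(ref) > 1:
                    log.warning(
                        "skipping multi-nucleotide substitution at %s:%s",
                        rec.chrom,
                        rec.pos,
                    )
                    continue
                ref_c, alt_c = _ad_counts(rec, sample, i)
                vset_records.append(
                    Variant(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=ref,
                        alt=alt,
                        qual=float(rec.qual) if rec.qual is not None else 0.0,
                        ref_count=ref_c,
                        alt_count=alt_c,
                    )
                )
    return VariantSet(sample or "", vset_records, chrom_order or None)


def write_vcf(vset: VariantSet, path: str | os.PathLike, genome: Optional[Genome] = None) -> None:
    """Write a VariantSet as an uncompressed single-sample VCF.

    Round-trip stable with read_vcf on (key, qual, counts).
    """
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    chroms = genome.chrom_ids if genome is not None else vset.chrom_order
    lengths = dict(genome.chromosomes) if genome is not None else {}
    for chrom in chroms:
        if chrom in lengths:
            header.contigs.add(chrom, length=lengths[chrom])
        else:
            header.contigs.add(chrom)
    sample = vset.sample_id or "SAMPLE"
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in vset:
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                alleles=(v.ref, v.alt),
                qual=v.qual,
            )
            rec.filter.add("PASS")
            if v.ref_count is not None and v.alt_count is not None:
                rec.samples[sample]["AD"] = (v.ref_count, v.alt_count)
            out.write(rec)


def write_tsv(records: list[dict], path: str | os.PathLike, columns: Optional[list[str]] = None) -> None:
    """Write a list of dicts as a UTF-8 tab-delimited table with header."""
    import pandas as pd

    df = pd.DataFrame(records, columns=columns)
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")
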