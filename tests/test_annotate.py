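"""Variant-effect annotation, primer design and flanking sequences.

Coding consequences are checked against an independent mutate-extract-
translate oracle: rebuild the whole mutated chromosome, pull out the CDS by
coordinates, translate both proteins with Biopython and diff them.
"""

import numpy as np
import pytest
from Bio.Seq import Seq

from mapseq.annotate import (
    AnnotateConfig,
    analyze_set,
    annotate_variant,
    design_primers,
    flanks,
    gc_percent,
    wallace_tm,
)
from mapseq.genomeio import GeneModel, Genome, Transcript, Variant, VariantSet


def oracle_consequence(genome, gene, variant):
    """Independent coding-SNP oracle: translate reference and mutated CDS."""
    t = gene.transcripts[0]
    chrom_seq = genome.fetch(gene.chrom, 1, genome.length(gene.chrom))
    mutated = (
        chrom_seq[: variant.pos - 1] + variant.alt + chrom_seq[variant.pos :]
    )

    def cds_of(seq):
        parts = [seq[s - 1 : e] for s, e, _ in t.cds]
        joined = "".join(parts)
        if gene.strand == "-":
            joined = str(Seq(joined).reverse_complement())
        return joined

    ref_prot = str(Seq(cds_of(chrom_seq)).translate())
    alt_prot = str(Seq(cds_of(mutated)).translate())
    if ref_prot == alt_prot:
        return "synonymous", None
    diffs = [i for i, (a, b) in enumerate(zip(ref_prot, alt_prot)) if a != b]
    i = diffs[0]
    ref_aa, alt_aa = ref_prot[i], alt_prot[i]
    if i == 0 and ref_aa == "M":
        return "start_loss", (ref_aa, 1, alt_aa)
    if alt_aa == "*":
        return "nonsense", (ref_aa, i + 1, alt_aa)
    if ref_aa == "*":
        return "stop_loss", (ref_aa, i + 1, alt_aa)
    return "missense", (ref_aa, i + 1, alt_aa)


class TestCodingSnps:
    def test_missense_in_toy_cds(self, toy_genome, toy_gene):
        # CDS 1-9 = ATG GCT TAA; pos 4 G→A turns GCT into ACT (A2T)
        v = Variant("c1", 4, "G", "A")
        (ann,) = annotate_variant(v, [toy_gene], toy_genome)
        assert ann.element == "cds"
        assert ann.consequence == "missense"
        assert ann.codon_change == "GCT>ACT"
        assert ann.aa_change == ("A", 2, "T")

    def test_stop_loss_in_toy_cds(self, toy_genome, toy_gene):
        # pos 7 T→A turns the TAA stop into AAA (K)
        v = Variant("c1", 7, "T", "A")
        (ann,) = annotate_variant(v, [toy_gene], toy_genome)
        assert ann.consequence == "stop_loss"
        assert ann.codon_change == "TAA>AAA"

    def test_start_loss(self, toy_genome, toy_gene):
        v = Variant("c1", 1, "A", "G")
        (ann,) = annotate_variant(v, [toy_gene], toy_genome)
        assert ann.consequence == "start_loss"

    def test_synonymous(self, toy_genome, toy_gene):
        # GCT→GCA is still alanine
        v = Variant("c1", 6, "T", "A")
        (ann,) = annotate_variant(v, [toy_gene], toy_genome)
        assert ann.consequence == "synonymous"

    def test_minus_strand_mirror(self):
        # same CDS encoded on the minus strand: revcomp(ATGGCTTAA) placed
        # so that genomic 52-60 reads TTAAGCCAT
        seq = "G" * 51 + "TTAAGCCAT" + "G" * 40
        genome = Genome({"c1": seq})
        t = Transcript("tm.1", exons=[(52, 60)], cds=[(52, 60, 0)])
        gene = GeneModel("gm", "c1", "-", [t])
        # genomic C→T at pos 57 is G→A on the coding strand: GCT>ACT (A2T)
        v = Variant("c1", 57, "C", "T")
        (ann,) = annotate_variant(v, [gene], genome)
        assert ann.consequence == "missense"
        assert ann.aa_change == ("A", 2, "T")
        cons, aa = oracle_consequence(genome, gene, v)
        assert (ann.consequence, ann.aa_change) == (cons, aa)

    def test_incomplete_model_gets_no_aa_call(self, toy_genome):
        t = Transcript("ti.1", exons=[(1, 10)], cds=[(1, 10, 0)], incomplete=True)
        gene = GeneModel("gi", "c1", "+", [t])
        (ann,) = annotate_variant(Variant("c1", 4, "G", "A"), [gene], toy_genome)
        assert ann.aa_change is None and ann.incomplete_model


class TestNonCoding:
    @pytest.fixture
    def spliced_gene(self):
        # exon 1001-1200, intron 1201-1500, exon 1501-1700; CDS spans
        # 1051-1200 and 1501-1650 (75 + ... adjust to multiple of 3)
        t = Transcript(
            "ts.1",
            exons=[(1001, 1200), (1501, 1700)],
            cds=[(1051, 1200, 0), (1501, 1650, 0)],
        )
        return GeneModel("gs", "c1", "+", [t])

    @pytest.fixture
    def big_genome(self):
        return Genome({"c1": "ACGT" * 1000})

    def test_intron(self, spliced_gene, big_genome):
        (ann,) = annotate_variant(
            Variant("c1", 1300, "T", "C"), [spliced_gene], big_genome
        )
        assert ann.element == "intron" and ann.consequence == "noncoding"

    @pytest.mark.parametrize("pos", [1201, 1202, 1499, 1500])
    def test_splice_sites(self, spliced_gene, big_genome, pos):
        ref = big_genome.fetch("c1", pos, pos)
        alt = "A" if ref != "A" else "G"
        (ann,) = annotate_variant(
            Variant("c1", pos, ref, alt), [spliced_gene], big_genome
        )
        assert ann.element == "splice_site"
        assert ann.consequence == "splice_disruption"

    def test_utrs_by_strand(self, spliced_gene, big_genome):
        (five,) = annotate_variant(
            Variant("c1", 1010, "C", "G"), [spliced_gene], big_genome
        )
        (three,) = annotate_variant(
            Variant("c1", 1680, "T", "G"), [spliced_gene], big_genome
        )
        assert five.element == "five_prime_utr"
        assert three.element == "three_prime_utr"

    def test_upstream_downstream_margin(self, spliced_gene, big_genome):
        (up,) = annotate_variant(
            Variant("c1", 900, "T", "G"), [spliced_gene], big_genome
        )
        assert up.element == "upstream"
        (down,) = annotate_variant(
            Variant("c1", 2000, "T", "G"), [spliced_gene], big_genome
        )
        assert down.element == "downstream"

    def test_intergenic_far_from_genes(self, spliced_gene, big_genome):
        (ann,) = annotate_variant(
            Variant("c1", 3500, "T", "G"), [spliced_gene], big_genome
        )
        assert ann.element == "intergenic" and ann.gene_id is None


class TestIndels:
    def test_frameshift_deletion(self, toy_genome, toy_gene):
        v = Variant("c1", 4, "GC", "G")
        (ann,) = annotate_variant(v, [toy_gene], toy_genome)
        assert ann.consequence == "frameshift"

    def test_inframe_deletion(self, toy_genome, toy_gene):
        v = Variant("c1", 3, "GGCT", "G")
        (ann,) = annotate_variant(v, [toy_gene], toy_genome)
        assert ann.consequence == "inframe_indel"

    def test_frameshift_insertion(self, toy_genome, toy_gene):
        v = Variant("c1", 4, "G", "GTT")
        (ann,) = annotate_variant(v, [toy_gene], toy_genome)
        assert ann.consequence == "frameshift"


class TestTranslationOracle:
    def test_random_coding_snps_match_oracle(self, sim_bundle, rng):
        """150 seeded coding SNPs across simulated genes, both strands."""
        _, genome, genes = sim_bundle
        checked = 0
        minus_checked = 0
        while checked < 150:
            gene = genes[int(rng.integers(len(genes)))]
            t = gene.transcripts[0]
            s, e, _ = t.cds[int(rng.integers(len(t.cds)))]
            pos = int(rng.integers(s, e + 1))
            ref = genome.fetch(gene.chrom, pos, pos)
            alt = "ACGT"[int(rng.integers(4))]
            if alt == ref:
                continue
            v = Variant(gene.chrom, pos, ref, alt)
            anns = [
                a for a in annotate_variant(v, [gene], genome)
                if a.element == "cds"
            ]
            assert len(anns) == 1
            cons, aa = oracle_consequence(genome, gene, v)
            assert anns[0].consequence == cons, (v, gene.gene_id, gene.strand)
            if cons == "synonymous":
                # the protein diff carries no position; the annotation still
                # reports the unchanged residue
                assert anns[0].aa_change[0] == anns[0].aa_change[2]
            else:
                assert anns[0].aa_change == aa
            checked += 1
            minus_checked += gene.strand == "-"
        assert minus_checked > 20  # both strands genuinely exercised


class TestPrimers:
    def test_wallace_rule(self):
        assert wallace_tm("ATGCATGCATGCATGCATGC") == pytest.approx(60.0)
        assert wallace_tm("AT") == pytest.approx(4.0)
        assert gc_percent("ATGC") == pytest.approx(50.0)

    def test_all_at_flanks_fail_with_reason(self):
        genome = Genome({"c1": "AT" * 2000})
        pair, reason = design_primers(Variant("c1", 2000, "A", "G"), genome)
        assert pair is None and reason == "tm_range"

    def test_deterministic(self, sim_bundle):
        _, genome, _ = sim_bundle
        ref = genome.fetch("chr1", 5_000_000, 5_000_000)
        v = Variant("chr1", 5_000_000, ref, "A" if ref != "A" else "C")
        a = design_primers(v, genome)
        b = design_primers(v, genome)
        assert a == b

    def test_product_spans_variant_on_random_genomes(self, rng):
        """Accepted pairs bracket the variant with the promised product size
        and matched melting temperatures, over 30 seeded random genomes."""
        cfg = AnnotateConfig()
        found = 0
        for trial in range(30):
            seq = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, 2500))
            genome = Genome({"c1": seq})
            pos = 1250
            ref = genome.fetch("c1", pos, pos)
            alt = "A" if ref != "A" else "C"
            v = Variant("c1", pos, ref, alt)
            pair, reason = design_primers(v, genome, cfg)
            if pair is None:
                continue
            found += 1
            product_end = pair.rev_start + len(pair.rev_seq) - 1
            assert pair.fwd_start < pos < product_end
            assert pair.product_size == product_end - pair.fwd_start + 1
            assert cfg.product_min <= pair.product_size <= cfg.product_max
            assert abs(pair.fwd_tm - pair.rev_tm) <= cfg.primer_tm_max_diff
            for seq_ in (pair.fwd_seq, pair.rev_seq):
                assert cfg.primer_gc_min <= gc_percent(seq_) <= cfg.primer_gc_max
            # forward primer is a verbatim genome substring, reverse primer
            # the reverse complement of its site
            assert genome.fetch("c1", pair.fwd_start,
                                pair.fwd_start + len(pair.fwd_seq) - 1) == pair.fwd_seq
            site = genome.fetch("c1", pair.rev_start, product_end)
            assert str(Seq(site).reverse_complement()) == pair.rev_seq
        assert found >= 25  # random sequence rarely defeats the scan


class TestFlanks:
    def test_clipped_at_chromosome_start(self):
        genome = Genome({"c1": "ACGTACGTAC"})
        left, right = flanks(Variant("c1", 3, "G", "A"), genome, flank_len=25)
        assert left == "AC"
        assert right == "TACGTAC"

    def test_full_length_mid_chromosome(self, sim_bundle):
        _, genome, _ = sim_bundle
        ref = genome.fetch("chr1", 5_000_000, 5_000_000)
        left, right = flanks(Variant("chr1", 5_000_000, ref, "A" if ref != "A" else "C"), genome)
        assert len(left) == 25 and len(right) == 25

    def test_left_ref_right_is_reference_substring(self, sim_bundle, rng):
        _, genome, _ = sim_bundle
        for _ in range(50):
            pos = int(rng.integers(100, 1_000_000))
            ref = genome.fetch("chr2", pos, pos)
            v = Variant("chr2", pos, ref, "A" if ref != "A" else "C")
            left, right = flanks(v, genome)
            window = genome.fetch("chr2", pos - len(left), pos + len(v.ref) - 1 + len(right))
            assert window == left + v.ref + right


class TestAnalyzeSet:
    def test_record_per_variant_with_report_fields(self, toy_genome, toy_gene):
        vset = VariantSet("t", [
            Variant("c1", 4, "G", "A", 42.0, 5, 20),
            Variant("c1", 30, "A", "T", 10.0, 3, 3),
            Variant("c1", 50, "G", "GA", 99.0, 0, 9),
        ])
        records = analyze_set(vset, [toy_gene], toy_genome,
                              functional_map={"g1": "toy kinase"})
        assert len(records) == 3
        first = records[0]
        assert first.effect.consequence == "missense"
        assert first.functional_note == "toy kinase"
        assert first.variant.af == pytest.approx(0.8)
        assert first.flank_left == "ATG"

    def test_variant_without_counts_retained(self, toy_genome, toy_gene):
        vset = VariantSet("t", [Variant("c1", 4, "G", "A")])
        (rec,) = analyze_set(vset, [toy_gene], toy_genome)
        assert rec.variant.af is None

    def test_record_count_equals_set_size(self, sim_bundle, rng):
        from tests.conftest import random_variant_set

        _, genome, genes = sim_bundle
        vset = random_variant_set(rng, n=40, chroms=("chr1",), length=9_000_000)
        records = analyze_set(vset, genes, genome)
        assert len(records) == len(vset)
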