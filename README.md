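# mapseq

Mapping-by-sequencing workflows for forward genetics, operating entirely on
standard file formats (FASTA reference, GFF3 annotation, VCF variant calls
with allele depths). `mapseq` locates phenotype-causal variants from pooled
sequencing data through three complementary strategies, analyzes variant
effects on genes and gene products, and ships a mapping-population
simulator so every pipeline can be exercised end to end without external
data.

## Who this is for

Geneticists mapping induced mutations or natural variants in model
organisms and crops: you have called variants from pooled resequencing of a
mapping population (bulked segregant analysis, recurrent backcross bulks,
or two opposite-phenotype QTL-seq pools) and want candidate regions, genes
and ready-to-order genotyping primers.

## The methods

**Variant density mapping** (recurrent-backcross designs). After *k*
backcrosses to the reference strain, a mutagen-induced variant at
recombination fraction *r* from the selected causal site survives with
probability (1 − *r*)<sup>*k*</sup>, with *r* = (1 − e<sup>−2d</sup>)/2
(Haldane) for genetic distance *d*. Unlinked variants are mostly lost while
the causal neighborhood retains a cluster of homozygous, EMS-type (G→A /
C→T) variants. `mapseq dens` subtracts the control sample, derives the
homozygous, EMS-type, and homozygous-EMS sublists, counts each category in
overlapping sliding windows, and calls windows whose count exceeds
max(min_count, μ + zσ) as peak regions; in-region, in-gene variants are
reported as candidates.

**QTL-seq** (two opposite-phenotype bulks). For every SNP present in both
pools with 0 < af < 1 in both (this discards fixed parental differences to
the reference), the allele-frequency difference dAF = af₁ − af₂ is averaged
per window and smoothed along each chromosome with a triangular weighted
moving average (1,2,3,2,1), giving dAF_WMA. Sustained same-sign runs with
|dAF_WMA| ≥ 0.25 over ≥ 3 windows are reported as candidate QTL regions.
Runs without a GFF3 still report regions, just without gene identification.

**Allele-frequency linkage scan** (one mutant bulk). Test-specific variant
allele frequencies approach fixation around the causal site in a bulk of
phenotypically mutant F2 individuals; the scan windows af, smooths it with
the same WMA, and reports the best run of windows with af_WMA ≥ 0.9.

**Variant analyzer.** For any VCF: affected gene and gene element (CDS,
intron, splice site, UTRs, upstream/downstream), codon and amino-acid
change for coding SNPs (strand- and phase-aware, standard genetic code),
frameshift/in-frame calls for indels, functional notes, flanking reference
sequence, and a deterministic genotyping primer pair (Wallace-rule melting
temperature 2(A+T) + 4(G+C), GC 40–60%, |ΔTm| ≤ 3 °C, product 150–800 bp
spanning the variant).

**Simulator.** `mapseq simulate` generates a random annotated genome and
mapping populations for all three designs — EMS mutagenesis, recurrent
backcrossing with Haldane-model retention, F2 bulks under phenotypic
selection, and binomial read-depth sampling of pooled allele counts —
emitting ordinary FASTA/GFF3/VCF files plus a truth sidecar for validation.

## Worked example

Simulate a recurrent-backcross experiment (20-Mb genome, 60 EMS mutations,
4 backcrosses, 25× depth) and map the causal mutation:

```bash
mapseq simulate --scenario backcross --seed 17 --out demo/sim
mapseq dens --genome demo/sim/genome.fa --gff demo/sim/genes.gff3 \
            --test demo/sim/test.vcf --control demo/sim/control.vcf \
            --out demo/dens
cat demo/dens/summary.txt
```

```
workflow: dens
...
test variants: 86
test-specific variants: 30
homozygous: 25; EMS-type: 30; homozygous EMS-type: 25
regions of interest (hom_ems): 2
  region chr2:3000001-4000000 peak_count=5
  region chr2:6000001-7000000 peak_count=5
candidate variants: 1
candidate genes: chr2g0069
```

The 86 test-sample variants shrink to 30 test-specific ones after control
subtraction; 25 are homozygous EMS-type. Two windows on chr2 exceed the
peak threshold, and one in-region variant falls inside a gene — the report
(`candidates.tsv`) shows it with its allele frequency, effect, primers and
flanks:

```
chrom  pos      ref  alt  af   gene        consequence  aa_change
chr2   6801070  C    T    1.0  chr2g0069   synonymous   P182P
```

This is indeed the simulated causal mutation (`demo/sim/truth.json` lists
`chr2:6801070 C>T` in `chr2g0069`): a homozygous (af = 1.0) EMS-type
transition inside a gene in the densest variant window. Per-chromosome SVG
plots of all variant categories, the window table and a candidate VCF are
written alongside the summary.

The other workflows follow the same pattern
(`mapseq qtlseq --pool1 ... --pool2 ...`, `mapseq linkage --test ...`,
`mapseq annotate --test ...`); every run writes its resolved configuration
next to its outputs and is byte-reproducible.

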