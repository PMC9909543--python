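# Methods

This note documents the models behind `mapseq`, the defaults that matter,
what the simulator does and does not emulate, and the numerical choices
made where the design was genuinely open.

## Data model and conventions

All coordinates are 1-based closed (GFF3/VCF convention). The FASTA
reference defines the canonical chromosome order. A `Variant` is one
biallelic record (SNP, insertion or deletion, classified by allele-length
comparison; `pos` anchors the first reference base, the VCF left-anchored
form). Allele frequency is alt reads over informative reads at the site.

**Multi-allelic sites.** A VCF row with several alternate alleles is split
into one record per allele with af_i = alt_i / (ref + Σ alt counts), so the
per-site sum of allele frequencies never exceeds 1. Internally this is
stored as ref_count = depth − alt_i, which makes counts round-trip through
the AD field. Records failing FILTER (other than PASS/`.`) are dropped;
symbolic alleles and equal-length multi-nucleotide substitutions have no
class in this model and are skipped with a warning. Control VCFs need only
CHROM/POS/REF/ALT — no workflow computes control allele frequencies.

**Homozygosity in pools.** Pooled samples have no diploid genotype, so
homozygosity is called as af ≥ 0.85 at depth ≥ 5. The 0.85 threshold
absorbs binomial sampling noise at the recommended depths (at 25×, a truly
fixed allele read at af < 0.85 requires ≥ 4 opposing reads, probability
< 10⁻⁴ per site from sequencing error alone); both knobs are exposed.

**EMS classification.** G→A and C→T only: the mutagen produces G→A
transitions, and C→T is the same lesion on the reverse strand as seen in a
forward-strand VCF.

## Variant density mapping

Window counts use overlapping sliding windows (default 1 Mb, step 500 kb;
step = size gives the classic per-Mb bin track, which the plots show as a
second layer). A window qualifies as a peak when its count strictly exceeds
max(min_count, μ + zσ), with μ, σ the genome-wide mean and standard
deviation of that category's window counts (defaults z = 2, min_count = 4;
the absolute floor prevents spurious calls on near-empty genomes).
Overlapping or adjacent qualifying windows merge into one region; regions
rank by their maximum window count. Detection defaults to the
homozygous-EMS category and is switchable for natural-variant designs.
Candidates are in-region variants that fall inside an annotated gene span
and belong to a reported class; without an annotation the candidate list is
empty by design and the regions stand alone.

Known limitation: with sparse variant sets (a few per Mb) the causal
cluster's expected window count sits near the min_count floor and the
genome-wide σ is inflated by the causal-versus-other-chromosome
bimodality, so the μ + zσ rule fragments or misses the cluster; see
"Statistical power at simulated scale" below. Centromere-like artifact
masking is left to user-supplied exclusion; peaks carry no p-values.

## QTL-seq

Mapping variants are SNPs present in both pools with 0 < af < 1 and depth
≥ 5 in both; fixed parental differences to the reference (af = 1 in both)
and private variants drop out. Indels can be admitted by configuration.
dAF = af₁ − af₂ is averaged per window; empty windows are *bridged* — they
carry an undefined mean and are excluded from the smoothing support —
rather than zero-filled, which would bias the smoothed track toward 0 in
marker deserts. Smoothing is a weighted moving average with the triangular
kernel (1, 2, 3, 2, 1), the minimal symmetric choice; weights renormalize
over the available defined neighbors at chromosome edges. Each chromosome
is smoothed independently, and the smoothed value is a convex combination
of window means, so it stays within their range.

Regions are maximal same-sign runs of ≥ 3 consecutive defined windows with
|dAF_WMA| ≥ 0.25. The threshold is deliberately stringent — tuned to major
QTL; users chasing minor QTL should lower it and inspect the per-chromosome
plots. Under near-complete selection the markers immediately at a major
QTL are fixed in both pools and therefore *removed* by the af < 1 filter:
the signal lives in the flanking markers, and the window containing the
QTL itself can be an empty, bridged window. Consequently, "signal at the
QTL" is evaluated at the nearest defined window inside the covering
region.

## Linkage (allele-frequency fixation) scan

Pipeline: control subtraction → class filter → windowed mean af → the same
WMA smoothing → best run of ≥ 2 windows with af_WMA ≥ 0.9. The threshold
sits below 1.0 because mutant-bulk selection is highly sensitive to
phenotyping errors; a single miscalled individual caps the causal af at
(2n−1)/2n. Candidates are in-region, in-gene variants with af above the
homozygosity threshold. This module is intentionally a single af-fixation
scan sharing the filter/annotation machinery — not a suite of linkage
estimators.

## Variant analyzer

Every transcript overlapping a variant is annotated (no canonical-
transcript priority); the headline consequence per variant is the most
severe one. Elements resolve by coordinate membership: CDS, UTRs (5′/3′ by
strand relative to the CDS span), splice sites (first/last 2 nt of an
intron), intron, non-coding exon, upstream/downstream within a 500-bp
margin, else intergenic. For coding SNPs the codon is rebuilt from the
CDS-concatenated sequence honoring strand and phase and translated with
the standard code; consequences are start_loss, nonsense, stop_loss,
missense or synonymous (precedence in that order). CDS indels get
frameshift/in-frame calls only (length mod 3) — no protein-level indel
prediction. Transcripts whose CDS length is not a phase-consistent
multiple of 3 are flagged incomplete and receive element-level annotation
without amino-acid calls.

Primer design is a deterministic outward scan (50–400 bp from the variant
on each side): 20-mers, extended to 24 then shrunk to 18, accepted at GC
40–60% with no N; melting temperature by the Wallace rule 2(A+T) + 4(G+C).
The first pair with |ΔTm| ≤ 3 °C and a 150–800 bp product spanning the
variant wins; failures report a reason (`tm_range`, `tm_mismatch`,
`product_size`). The Wallace rule was chosen over nearest-neighbor
thermodynamics for determinism and hand-verifiability; for 18–24-mers it
is accurate to a few degrees, which the pair-matching constraint absorbs.

## The simulator

The generator emulates, at desk scale, the three experimental designs:

- **Genome.** i.i.d. uniform ACGT chromosomes (default 2 × 10 Mb) with one
  gene per 100 kb on alternating strands, each 2–4 exons with a valid
  embedded CDS (ATG…stop, no internal stops) and 30-bp UTRs. A uniform
  genetic map of 4 cM/Mb feeds the Haldane function r = (1 − e^(−2d))/2.
- **Recurrent backcross (density design).** 60 EMS sites at G/C positions
  (one causal inside a random gene CDS) plus 150 pre-mutagenesis
  background variants shared with the control. Each non-causal variant
  survives k = 4 backcrosses with probability (1 − r)^k (r = 1/2 if
  unlinked). Linked survivors are homozygous (af = 1) in the final
  selected bulk; unlinked survivors segregate 1:2:1 across the bulk
  (default 100 individuals). Observed counts are Binomial(depth, af) at
  25×.
- **QTL-seq.** Biallelic markers every 25 kb; each F2 gamete is a Markov
  chain of parental origin along the marker grid with Haldane switch
  probabilities; phenotype = effect·(genotype − 1) + N(0,1) with a default
  additive effect of 3 phenotype-SD — an essentially complete-selection
  major QTL; effect 0 is the null generator. The top and bottom 10% of
  200 individuals form the pools (50× depth in the headline checks); rows
  with zero alternate reads are not emitted, as a variant caller would not
  emit them.
- **F2 mutant bulk (linkage design).** The mutant parent is homozygous for
  the EMS and background sets; bulk individuals are conditioned to carry
  the causal allele on both gametes (exact for a Markov recombination
  process by anchoring the chain at the causal site), so causal af is
  exactly 1 and linked af decays with r. Defaults follow the recommended
  linkage design: 100 individuals, 25× depth.

Truth sidecars (TSV/JSON) record the causal key and per-site ground truth;
they are read only by tests and the acceptance script, never by the
mapping code.

What the simulator does **not** emulate: sequencing errors and read-level
artifacts, alignment and variant-calling noise, crossover interference,
non-uniform recombination or marker density, centromeric artifact peaks,
structural variants, and selfing-generation dynamics beyond the modeled
bulks. Passing recovery checks therefore demonstrate the statistical logic
of the scans under clean calls — not robustness to caller artifacts. The
causal site is an unconstrained CDS position, so its simulated coding
effect can be synonymous; candidate identification does not use effect
severity.

## Statistical power at simulated scale

The acceptance checks run each design 100 times at the conditions above.
Two honest findings, measured (seed 1) and reproducible via
`scripts/acceptance.py`:

- Density-mapping top-region recovery is 34/100, not ≥ 95/100. At 60
  mutations over 20 Mb the expected homozygous-EMS count in the causal
  1-Mb window is ≈ 3.8, below the min_count = 4 floor, and enlarging the
  windows inflates the genome-wide σ (half the windows are on the
  non-causal chromosome) faster than the peak count, so the μ + zσ rule
  cannot reach 95% at this variant density. When the top region *is*
  correct, the candidate list contains the causal variant in 100% of runs.
  Denser mutagenesis (hundreds of variants, as in real backcross datasets)
  is what gives this design its power.
- QTL-seq null calibration yields 90/100 clean runs. With 20-individual
  bulks the per-window dAF sampling noise has SD ≈ 0.11, putting the 0.25
  calling threshold at ~2.4σ; bulk-composition noise is almost perfectly
  correlated along a chromosome, so the 3-window run requirement adds
  little protection, leaving a ~10% genome-wide false-call rate. Larger
  bulks or a higher threshold fix this; the recovery side is unaffected
  (100/100 with strong smoothed signal at the QTL).

All other checks — linkage recovery, brute-force oracle equivalence of
every windowed scan and filter, translation-oracle agreement on both
strands, simulator closed forms, format round-trips and byte-level
reproducibility — pass at 100%.

## Numerical and engineering choices

- Window tiling: per chromosome, starts at 1 advancing by `step`; the last
  window clips at the chromosome end. A variant on a window boundary is
  counted in every window containing it; with step = size no window
  double-counts.
- Region ranking ties (equal peak counts) break by chromosome order then
  start coordinate; all regions are reported, not just the best.
- Undefined allele frequencies (zero depth, missing counts) are hard
  errors in the operations that need af, and pass-through otherwise; the
  analyzer keeps such variants with an empty af column.
- All randomness flows through numpy Generators seeded from the
  configuration seed (with fixed stream tags per operation), making every
  simulation and report byte-reproducible.
- Workflows never mutate inputs; all outputs land in the run directory
  together with the resolved configuration and a run log. Per-chromosome
  operations are pure, so callers may parallelize externally.
- Plots are SVG (coordinate-diffable in tests); problem sizes throughout
  the suite (20-Mb genomes, 100-run batches) were chosen so a full
  validation executes in well under a minute on one CPU.
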