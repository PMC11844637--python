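# Methods

## The problem

Pooled ("multiplexed") single-nucleus multiome experiments load nuclei from
several genotyped donors into one droplet run and recover each barcode's
donor after the fact from the genetic variants its reads carry. Ambient
RNA/DNA — cell-free molecules from the pooled suspension that are captured
alongside (or instead of) a nucleus — contaminates every droplet with
alleles from *all* donors and is especially severe in single-nucleus
assays. `ambimux` provides (i) a read-level generative model of such an
experiment in which the ambient fraction of every droplet is controlled and
known, (ii) the pileup and variant-consistency machinery that estimates
residual ambient contamination in demultiplexed singlets post hoc, and
(iii) the accuracy/concordance metrics used to score demultiplexers against
simulation truth and against each other.

## Droplet-level model

Each of the `n_droplets` barcodes draws independently:

* **type** ~ Multinomial(1 − doublet_rate − empty_rate, doublet_rate,
  empty_rate) over {singlet, doublet, empty};
* **donor(s)** — singlets draw one donor from `donor_proportions`; doublets
  draw two *distinct* donors without replacement (heterotypic by
  construction: within-donor doublets are genetically invisible and out of
  scope). Doublets split their native reads by a Beta(5, 5) share for the
  first donor;
* **ambient fraction** ~ Beta(μc, (1 − μ)c) with experiment-level mean μ
  (`ambient_level`) and concentration c (`ambient_concentration`, default
  30, giving ±0.07 droplet-to-droplet SD at μ = 0.2). Beta is the minimal
  bounded-support family with a controllable mean; μ = 0 yields exactly 0
  and empty droplets are ambient-only (fraction exactly 1);
* **depth** ~ NegativeBinomial(mean, dispersion) per modality (variance =
  mean + mean²/dispersion, default dispersion 10; dispersion → ∞ recovers
  Poisson). Defaults follow 10x-scale recommendations: 25,000 RNA reads and
  40,000 ATAC fragments per droplet, with a 7,000/7,000 low-coverage
  profile available. ATAC depth counts *fragments* (read pairs), the unit
  droplet-ATAC depth is conventionally quoted in; each fragment emits two
  50 bp mates. Empty droplets draw depth at 5% of the cell mean
  (`empty_depth_factor`) — real empties are low-count, and no published law
  exists, so this is a package choice.

## Read-level model

Per RNA read / ATAC fragment:

1. **ambient status** ~ Bernoulli(droplet ambient fraction), so the number
   of ambient molecules per droplet is Binomial(depth, fraction) and is
   recorded as ground truth;
2. **locus** — native molecules start uniformly over the informative-region
   bases of their modality (gene bodies for RNA, peaks for ATAC); ambient
   molecules start inside informative regions with probability
   `ambient_informative_weight` (β, default 0.25) and uniformly over the
   whole genome otherwise. Ambient material is enriched outside genes and
   peaks; no published number pins β down, so it is exposed in config;
3. **source donor** — native: the droplet's donor (doublets flip the mix
   coin); ambient: a donor from `ambient_donor_weights` (default uniform
   over the pool, matching equal multiplexing proportions). One donor per
   molecule: all SNPs a molecule covers share provenance, because a read is
   a single physical molecule;
4. **alleles** — at every covered SNP, alt ~ Bernoulli(dosage/2) for the
   source donor's diploid genotype (hom-ref → ref, het → fair coin,
   hom-alt → alt). A missing genotype emits ref and is counted;
5. **sequencing error** — every base substituted independently with
   probability `seq_error_rate` (default 10⁻³), uniformly over the three
   other bases. Truth records the pre-error allele, so an error-free run is
   an *exact* oracle for the pileup stage. Base qualities are constant Q37
   so the explicit error model is the only error source; MAPQ is fixed at
   60 and reads are emitted directly at their true coordinates
   (coordinate-sorted BAM with CB/UB tags), avoiding an aligner dependency.
   ATAC insert sizes are Normal(180, 40) truncated to [60, 600] bp.

UMIs are unique per read (base-4 encoding of the read index): PCR
duplication is not modelled, so UMI collapsing in the pileup is exercised
but never lossy on simulated data.

## Pileup

`pileup_counts` builds sparse droplet × variant reference/alternate count
matrices R and A from a barcode-tagged BAM. Bases matching neither allele
are excluded and tallied ("other"; at error rate ε they arise at (2/3)ε of
counted bases). RNA reads collapse per (barcode, UMI, variant) with
majority vote, ties excluded — cellSNP-style molecule counting. ATAC counts
per read, except a SNP covered by both mates of one pair counts once
(first mate wins; mates carry the same molecule, and double-counting would
double-weight the ~40 bp mate overlap). Default thresholds min_mapq = 20,
min_baseq = 20 are non-filtering on simulated data but meaningful on real
BAMs.

## Variant consistency

For every counted allele of an assigned singlet, with the assigned donor's
allele set S_k (dosage 0 → {ref}, 1 → {ref, alt}, 2 → {alt}):

| observed allele | ∈ S_k | ∈ some other donor's set | category |
|---|---|---|---|
| yes | yes | no | C1 |
| yes | yes | yes | C2 |
| no  | —  | yes | I1 |
| no  | —  | no  | I2 |

I1 alleles must originate from another donor's material, so the per-droplet
I1 count lower-bounds its ambient contamination; I2 alleles match nobody
and measure sequencing/genotyping error. Counts aggregate into F (droplets
× 4), row-normalised into rates. F is read-count weighted — that is what
makes per-droplet I1 counts commensurable with ambient molecule counts —
with a `per_variant` flag for the binarised variant. Donors with missing
genotype are skipped in the "other" comparison; a missing *assigned*
genotype excludes that variant for that droplet rather than fabricating
consistency. Droplets called doublet/unassigned are excluded: the metric is
defined on singlets. Genotype-free methods must be label-harmonized
(`harmonize_labels`, Hungarian assignment on the cluster × donor
contingency table) before the metric applies.

`ambient_correlation` reports the squared Pearson correlation between
per-droplet I1 counts and true ambient molecule counts over correctly
assigned singlets — the simulation-only validation that the metric tracks
contamination.

## Scoring demultiplexers

Droplet-type accuracy counts a truth singlet as correct when the method
calls *some* donor, a truth doublet when it calls doublet, and a truth
empty when the method refuses a singlet call (doublet or unassigned) — the
most charitable reading consistent with singlet-vs-unassigned scoring,
since empties carry no donor. Singleton-donor accuracy divides correct
donor calls by the truth singlets the method called as a donor (isolating
assignment quality from detection quality; a strict variant divides by all
truth singlets). Between-method correlation is Pearson on the binary
is-singlet indicator by default, with Cramér's V over the three-level calls
as an alternative; multi-way intersections report pairwise droplet-type
overlap, the all-method type/donor agreement proportions, and UpSet-style
membership counts.

## Synthetic reference

The toy generator emits a uniform-composition genome (default 1 × 2 Mb, GC
0.41), a biallelic-SNP VCF with Hardy-Weinberg genotypes at allele
frequencies uniform in [0.05, 0.5] (5,000 SNPs ≈ the per-bp density of a
genome-wide imputed SNP panel), non-overlapping gene-body and peak BEDs
scaled to cover 12% and 20% of the genome (peaks deliberately cover more:
ATAC's informative SNP pool is wider than RNA's), and a 16 bp barcode
whitelist with pairwise Hamming distance ≥ 3. By default every SNP is
resampled until at least two donors differ, so all sites can discriminate
donors; `require_informative=False` restores the unconditional
Hardy-Weinberg law. INFO carries synthetic imputation R² (uniform in
[0.6, 1]) and AF so the strict R² > 0.9 / MAF > 0.01 variant filters are
exercisable. What it does *not* emulate: transcript structure (no
splicing/introns), expression or accessibility weights within regions,
indels/multiallelics, barcode sequencing errors, PCR duplicates, batch or
cell-type structure. Passing tests therefore demonstrate correctness of the
counting and classification machinery and of the generative model's own
laws — not that real libraries look like this.

## Numerical and determinism choices

All sampling flows through `numpy.random.Generator` seeded per stage
(modalities consume independent spawn streams, so simulating one modality
reproduces its half of a joint run). Fixed seed ⇒ byte-identical FASTA,
VCF, BED, FASTQ (gzip mtime pinned to 0) and BAM outputs. Reads are
generated pre-sorted by coordinate, so BAMs need no external sort.
Coordinates are 0-based half-open internally; VCF stays 1-based at I/O
boundaries. Variants are handled in a single concatenated-genome coordinate
space, which makes interval overlap a `searchsorted`. Sequence matrices are
held in memory (bytes × read length), sized for desk-scale runs (≤ a few
million reads); full-scale 9,000-droplet × 25k-depth experiments are
intended for droplet-level analyses, not read emission.

## Problem sizes used in the shipped analyses

The ambient sweep that validates I1-based ambient recovery uses 6 ambient
levels {0, 0.1, 0.2, 0.3, 0.4, 0.5} × 250 droplets (1,500 droplets total),
4 donors, 10% doublets, 2,000 RNA reads / 3,200 ATAC fragments per droplet
on the 2 Mb / 5,000-SNP toy reference — a proportional scale-down of a
9,000-droplet 25k/40k-depth genome-wide experiment chosen to keep the whole
sweep at minutes scale on one CPU. At this depth the per-droplet I1 signal
is ~12× smaller than at full depth, which bounds the achievable I1-vs-
ambient R² near 0.92–0.93 (RNA) and 0.95–0.96 (ATAC); the ATAC value
exceeds the RNA value because 3,200 fragments yield roughly twice the SNP
observations of 2,000 91 bp reads. Monotonicity checks use 3 levels × 5
seeds × 60 droplets at ~600 reads/droplet on a 400 kb reference.

## Known limitations

* No aligner is run; BAMs are emitted at true coordinates with uniform
  MAPQ, so mapping ambiguity and multi-mapping artifacts are absent.
* The ambient pool is a donor-weighted mixture of genotypes, not a mixture
  of cell-type-specific expression profiles; ambient composition biases
  beyond donor weights are not modelled.
* The consistency metric requires reference genotypes for the assigned
  donor; it quantifies contamination only for droplets a method calls as
  singlets of a known donor.
* Sequencing error is i.i.d. per base; no quality-dependent or
  context-dependent error structure.
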