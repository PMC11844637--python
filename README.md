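# ambimux

Genotype-aware, read-level simulation of **multiplexed snRNA/snATAC droplet
experiments** with per-droplet control of ambient RNA/DNA contamination —
and the **variant-consistency metric** (C1/C2/I1/I2) that estimates residual
ambient contamination in demultiplexed singlets after the fact.

It is aimed at people who build or benchmark genotype-based demultiplexers:
it produces FASTQ/BAM data whose every read has known droplet type, donor of
origin and ambient status, and it scores demultiplexing output both against
that truth and against other methods.

## What it computes

A pooled experiment with `K` donors is simulated droplet by droplet: type
(singlet / heterotypic doublet / empty), donor identity, per-modality depth
(negative binomial), and an ambient read fraction (Beta with experiment-level
mean μ). Reads are then sampled from a toy genome — native reads uniformly
over informative regions (gene bodies for RNA, peaks for ATAC), ambient
reads mostly genome-wide — and at every covered SNP an allele is drawn from
the source donor's diploid genotype: the droplet's donor for native reads, a
pool-sampled donor for ambient reads.

For QC, allele counts of each assigned singlet are classified against the
assigned donor's genotype `G(v)` and everyone else's:

| category | observed allele consistent with assigned donor | carried by another donor |
|---|---|---|
| **C1** | yes | no |
| **C2** | yes | yes |
| **I1** | no  | yes |
| **I2** | no  | no  |

I1 counts must come from other donors' material, so per droplet they are a
lower bound on ambient contamination; I2 counts measure sequencing/
genotyping error. The per-droplet counts form the matrix `F ∈ N^{D×4}`,
computed from sparse reference/alternate pileup matrices `R, A ∈ N^{D×V}`
and a donor assignment vector `Z`.

## Worked example

Everything below is generated on the fly — no downloads.

```python
import numpy as np, ambimux as ax
from ambimux.read_simulator import SimParams

ref = ax.make_toy_reference("out/ref", chrom_length=500_000,
                            n_variants=1_250, n_donors=4, n_barcodes=300, seed=7)
table, gmat = ax.load_genotypes(ref.vcf_path)
cfg = ax.ExperimentConfig(n_droplets=100, n_donors=4, doublet_rate=0.1,
                          ambient_level=0.2, rna_depth_mean=1_000,
                          atac_depth_mean=1_600, seed=7)
droplets = ax.sample_droplets(cfg, whitelist=ref.whitelist_path.read_text().split())
sim = ax.simulate_experiment(droplets, ref.genome_path, table, gmat,
                             ref.rna_regions_path, ref.atac_regions_path,
                             SimParams(), "out/sim", seed=7)

assignments = sim.truth.assignment_frame(gmat.donor_ids)  # oracle demultiplexing
for modality in ("rna", "atac"):
    pile = ax.pileup_counts(sim.bam_paths[modality], table,
                            [d.barcode for d in droplets], modality=modality)
    res = ax.consistency_counts(pile, gmat, assignments)
    rates = np.nanmean(res.rates(), axis=0)
    r2 = ax.ambient_correlation(res, sim.truth, modality)
    print(f"{modality}: C1={rates[0]:.3f} C2={rates[1]:.3f} "
          f"I1={rates[2]:.3f} I2={rates[3]:.4f}  I1-vs-ambient R2={r2:.3f}")
```

Output:

```
rna: C1=0.047 C2=0.922 I1=0.031 I2=0.0000  I1-vs-ambient R2=0.680
atac: C1=0.048 C2=0.919 I1=0.032 I2=0.0000  I1-vs-ambient R2=0.801
```

Reading it: with perfect assignments at ambient level 0.2, ~3% of allele
counts per singlet are I1 — foreign alleles that can only be ambient
contamination — and the per-droplet I1 count correlates with the droplet's
true ambient molecule count even within a single contamination level
(pooling droplets *across* ambient levels 0–50%, as
`ambimux.presets.run_ambient_sweep` does, raises R² to ~0.93 RNA / ~0.95
ATAC). C2 dominates C1 because most SNPs are shared between some pair of
donors; C1 tracks donor-unique alleles.

The same pipeline is available as a CLI:

```sh
ambimux fixtures --out ref --n-donors 4 --n-snps 5000 --seed 1
ambimux simulate --config cfg.toml --out sim --seed 1
ambimux pileup --bam sim/rna.bam --vcf ref/donors.vcf \
    --whitelist ref/whitelist.txt --out pile --modality rna
ambimux consistency --pileup pile --vcf ref/donors.vcf \
    --assign calls.tsv --out vc
ambimux evaluate --truth sim/truth.tsv --vcf ref/donors.vcf \
    --calls method_a.tsv --calls method_b.tsv --out eval
```

Each run writes a `manifest.json` (config snapshot, seed, input checksums,
outputs) and re-running with the same config and seed reproduces outputs
byte for byte.

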