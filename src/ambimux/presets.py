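"""End-to-end study designs at desk scale.

Two sweep families mirror the standard benchmarking axes of pooled multiome
experiments — sweep A fixes the pool at 4 donors and varies the doublet
rate, sweep B fixes the doublet rate at 10% and varies the pool size — each
crossed with ambient-contamination levels and run at a full (25k/40k reads
per droplet) or low (7k/7k) depth profile. ``run_ambient_sweep`` is the
workhorse: it simulates an ambient sweep on a toy reference, runs pileup and
consistency with oracle assignments, and measures how well per-droplet I1
counts recover the true per-droplet ambient molecule counts.

Default sweep scale — 6 ambient levels x 250 droplets (1,500 droplets
total), 2 Mb genome with 5,000 SNPs, depths 2,000 (RNA) / 3,200 (ATAC)
reads per droplet — is a proportional scale-down of a 9,000-droplet
25k/40k-depth 3 Gb experiment that keeps per-droplet SNP coverage
comparable while running in minutes on one CPU.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .allele_pileup import pileup_counts
from .droplet_sampler import ExperimentConfig, sample_droplets
from .genotype_io import load_genotypes
from .read_simulator import SimParams, simulate_experiment
from .synthetic_reference import ToyReference, make_toy_reference
from .variant_consistency import ambient_correlation, consistency_counts, i1_rate

MODALITIES = ("rna", "atac")


def sweep_configs(
    name: str,
    ambient_levels: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
    full_scale: bool = False,
    low_depth: bool = False,
) -> list[ExperimentConfig]:
    """Experiment configs for sweep "a" (4 donors, doublet rate 0-30%) or
    sweep "b" (2-16 donors, doublet rate 10%), crossed with ambient levels.

    Scaled-down droplet counts by default; ``full_scale`` restores 9,000
    droplets and full depths (read-level simulation at that scale is
    RAM/time hungry — intended for droplet-level analyses).
    """
    if name not in ("a", "b"):
        raise ValueError("sweep name must be 'a' or 'b'")
    n_droplets = 9_000 if full_scale else 250
    if low_depth:
        rna_depth = atac_depth = 7_000.0 if full_scale else 700.0
    else:
        rna_depth = 25_000.0 if full_scale else 2_000.0
        atac_depth = 40_000.0 if full_scale else 3_200.0
    axes = (
        [(4, r) for r in (0.0, 0.1, 0.2, 0.3)]
        if name == "a"
        else [(k, 0.1) for k in (2, 4, 8, 16)]
    )
    return [
        ExperimentConfig(
            n_droplets=n_droplets, n_donors=k, doublet_rate=rate,
            ambient_level=mu, rna_depth_mean=rna_depth, atac_depth_mean=atac_depth,
        )
        for k, rate in axes
        for mu in ambient_levels
    ]


@dataclass
class AmbientSweepResult:
    """Pooled I1-vs-ambient regression over an ambient sweep."""

    levels: tuple[float, ...]
    r_squared: dict = field(default_factory=dict)      # modality -> R^2
    n_singlets: dict = field(default_factory=dict)     # modality -> n in regression
    mean_i1_rate: dict = field(default_factory=dict)   # modality -> per-level means
    i1_counts: dict = field(default_factory=dict)      # modality -> pooled array
    ambient_counts: dict = field(default_factory=dict)


def run_ambient_sweep(
    work_dir: str | Path,
    seed: int = 0,
    ambient_levels: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
    droplets_per_level: int = 250,
    n_donors: int = 4,
    doublet_rate: float = 0.10,
    rna_depth_mean: float = 2_000.0,
    atac_depth_mean: float = 3_200.0,
    chrom_length: int = 2_000_000,
    n_variants: int = 5_000,
    seq_error_rate: float = 0.001,
    modalities: tuple[str, ...] = MODALITIES,
    reference: ToyReference | None = None,
    keep_outputs: bool = False,
) -> AmbientSweepResult:
    """Simulate an ambient sweep end to end and regress per-droplet I1
    counts on true ambient molecule counts (correctly assigned singlets,
    pooled across levels), per modality.

    One toy reference is shared across levels; each level gets its own
    droplets, reads, pileups and consistency run. Deterministic under
    ``seed``; per-level intermediate files are deleted unless
    ``keep_outputs``.
    """
    work = Path(work_dir)
    work.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    ref_seed, *level_seeds = [int(s) for s in ss.generate_state(1 + len(ambient_levels)) % (2**31)]
    if reference is None:
        reference = make_toy_reference(
            work / "reference", chrom_length=chrom_length, n_variants=n_variants,
            n_donors=n_donors, seed=ref_seed,
        )
    table, gmat = load_genotypes(reference.vcf_path)
    whitelist = reference.whitelist_path.read_text().split()
    params = SimParams(seq_error_rate=seq_error_rate)

    pooled_i1 = {m: [] for m in modalities}
    pooled_amb = {m: [] for m in modalities}
    mean_rates = {m: [] for m in modalities}

    for level, lseed in zip(ambient_levels, level_seeds):
        cfg = ExperimentConfig(
            n_droplets=droplets_per_level, n_donors=n_donors,
            doublet_rate=doublet_rate, ambient_level=level,
            rna_depth_mean=rna_depth_mean, atac_depth_mean=atac_depth_mean,
            seed=lseed,
        )
        droplets = sample_droplets(cfg, whitelist=whitelist)
        level_dir = work / f"ambient_{level:.2f}"
        sim = simulate_experiment(
            droplets, reference.genome_path, table, gmat,
            reference.rna_regions_path, reference.atac_regions_path,
            params, level_dir, seed=lseed, modalities=modalities, emit_fastq=False,
        )
        assignments = sim.truth.assignment_frame(gmat.donor_ids)
        barcodes = [d.barcode for d in droplets]
        for m in modalities:
            pile = pileup_counts(sim.bam_paths[m], table, barcodes, modality=m)
            res = consistency_counts(pile, gmat, assignments)
            rates = i1_rate(res)
            mean_rates[m].append(float(rates.mean()) if len(rates) else 0.0)
            mt = getattr(sim.truth, m)
            tidx = {bc: i for i, bc in enumerate(barcodes)}
            for i, bc in enumerate(res.barcodes):
                drop = droplets[tidx[bc]]
                if drop.droplet_type == "singlet" and drop.donors[0] == res.assigned_donor[i]:
                    pooled_i1[m].append(int(res.F[i, 2]))
                    pooled_amb[m].append(int(mt.ambient_per_droplet[tidx[bc]]))
        if not keep_outputs:
            shutil.rmtree(level_dir)

    out = AmbientSweepResult(levels=tuple(ambient_levels))
    for m in modalities:
        x = np.asarray(pooled_amb[m], float)
        y = np.asarray(pooled_i1[m], float)
        r = np.corrcoef(x, y)[0, 1]
        out.r_squared[m] = float(r * r)
        out.n_singlets[m] = len(x)
        out.mean_i1_rate[m] = mean_rates[m]
        out.i1_counts[m] = y
        out.ambient_counts[m] = x
    return out


def mean_i1_rates(
    work_dir: str | Path,
    ambient_levels: tuple[float, ...],
    seeds: tuple[int, ...],
    n_droplets: int = 60,
    rna_depth_mean: float = 600.0,
    atac_depth_mean: float = 600.0,
    n_variants: int = 1_500,
    chrom_length: int = 400_000,
    modality: str = "rna",
) -> np.ndarray:
    """Mean per-droplet I1 rate for each (ambient level, seed) pair on small
    simulations — the replication grid behind monotonicity checks. Returns a
    len(levels) x len(seeds) array."""
    work = Path(work_dir)
    grid = np.zeros((len(ambient_levels), len(seeds)))
    for j, seed in enumerate(seeds):
        res = run_ambient_sweep(
            work / f"seed_{seed}", seed=seed, ambient_levels=tuple(ambient_levels),
            droplets_per_level=n_droplets, rna_depth_mean=rna_depth_mean,
            atac_depth_mean=atac_depth_mean, n_variants=n_variants,
            chrom_length=chrom_length, modalities=(modality,),
        )
        grid[:, j] = res.mean_i1_rate[modality]
    return grid
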