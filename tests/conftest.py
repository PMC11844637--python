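"""Shared fixtures: a toy reference and small simulated experiments.

Everything is generated programmatically at session start; no test reads
external data. The clean (error-free) simulation doubles as an exact oracle
for pileup and consistency, because the simulator records the allele it
emitted at every covered SNP.
"""

from __future__ import annotations

import numpy as np
import pytest

import ambimux as ax
from ambimux.read_simulator import SimParams


@pytest.fixture(scope="session")
def toy_ref(tmp_path_factory):
    return ax.make_toy_reference(
        tmp_path_factory.mktemp("ref"),
        chrom_length=300_000, n_variants=800, n_donors=4, n_barcodes=500,
        seed=11,
    )


@pytest.fixture(scope="session")
def geno(toy_ref):
    return ax.load_genotypes(toy_ref.vcf_path)


@pytest.fixture(scope="session")
def whitelist(toy_ref):
    return toy_ref.whitelist_path.read_text().split()


def _simulate(toy_ref, geno, whitelist, out_dir, *, ambient, seed,
              n_droplets=50, rna_depth=400, atac_depth=250, eps=0.0,
              doublet_rate=0.1, empty_rate=0.05, emit_fastq=True):
    table, gmat = geno
    cfg = ax.ExperimentConfig(
        n_droplets=n_droplets, n_donors=gmat.n_donors, doublet_rate=doublet_rate,
        empty_rate=empty_rate, ambient_level=ambient,
        rna_depth_mean=rna_depth, atac_depth_mean=atac_depth, seed=seed,
    )
    droplets = ax.sample_droplets(cfg, whitelist=whitelist)
    sim = ax.simulate_experiment(
        droplets, toy_ref.genome_path, table, gmat,
        toy_ref.rna_regions_path, toy_ref.atac_regions_path,
        SimParams(seq_error_rate=eps), out_dir, seed=seed + 1,
        emit_fastq=emit_fastq,
    )
    return droplets, sim


@pytest.fixture(scope="session")
def clean_sim(toy_ref, geno, whitelist, tmp_path_factory):
    """Error-free simulation at ambient 0.25 with doublets and empties."""
    return _simulate(
        toy_ref, geno, whitelist, tmp_path_factory.mktemp("clean_sim"),
        ambient=0.25, seed=21,
    )


@pytest.fixture(scope="session")
def zero_ambient_sim(toy_ref, geno, whitelist, tmp_path_factory):
    """Ambient 0, error 0, no empties: every read is native."""
    return _simulate(
        toy_ref, geno, whitelist, tmp_path_factory.mktemp("zero_sim"),
        ambient=0.0, seed=31, n_droplets=40, empty_rate=0.0, emit_fastq=False,
    )


@pytest.fixture(scope="session")
def clean_pileups(clean_sim, geno):
    table, _ = geno
    droplets, sim = clean_sim
    barcodes = [d.barcode for d in droplets]
    return {
        m: ax.pileup_counts(sim.bam_paths[m], table, barcodes, modality=m)
        for m in ("rna", "atac")
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
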