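"""Read-level simulation: conservation, locus/allele laws, emitted formats."""

from __future__ import annotations

import gzip

import numpy as np
import pysam
import pytest

import ambimux as ax
from ambimux._genome import GenomeIndex, RegionSet
from ambimux.read_simulator import (
    SimParams,
    _draw_alleles,
    _sample_loci,
    apply_sequencing_errors,
    assign_allele,
    sample_read_locus,
)


def test_read_counts_conserved_per_droplet(clean_sim):
    droplets, sim = clean_sim
    for m, depth_of in (("rna", lambda d: d.rna_depth), ("atac", lambda d: d.atac_depth)):
        mt = getattr(sim.truth, m)
        total = mt.native_per_droplet + mt.ambient_per_droplet
        assert np.array_equal(total, np.array([depth_of(d) for d in droplets]))


def test_empty_droplets_have_no_native_reads(clean_sim):
    droplets, sim = clean_sim
    empty = np.array([d.droplet_type == "empty" for d in droplets])
    assert empty.any()
    assert np.all(sim.truth.rna.native_per_droplet[empty] == 0)
    assert np.all(sim.truth.atac.native_per_droplet[empty] == 0)


def test_zero_ambient_means_zero_ambient_reads(zero_ambient_sim):
    _, sim = zero_ambient_sim
    assert sim.truth.rna.ambient_per_droplet.sum() == 0
    assert sim.truth.atac.ambient_per_droplet.sum() == 0


def test_realized_ambient_fraction_matches_binomial_aggregation(clean_sim):
    """Total ambient reads ~ sum of Binomial(depth_d, af_d); the realized sum
    stays within 3 SD of its expectation."""
    droplets, sim = clean_sim
    for m, depth_of in (("rna", lambda d: d.rna_depth), ("atac", lambda d: d.atac_depth)):
        depths = np.array([depth_of(d) for d in droplets], float)
        af = np.array([d.ambient_fraction for d in droplets])
        expected = float(np.sum(depths * af))
        sd = np.sqrt(np.sum(depths * af * (1 - af)))
        observed = getattr(sim.truth, m).ambient_per_droplet.sum()
        assert abs(observed - expected) < 3 * sd


def test_native_loci_inside_informative_regions(toy_ref, rng):
    genome = GenomeIndex.from_fasta(str(toy_ref.genome_path))
    regions = RegionSet.from_bed(str(toy_ref.rna_regions_path), genome)
    pos = _sample_loci(np.zeros(10_000, dtype=bool), regions, genome, 0.25, rng)
    assert regions.contains(pos).all()


def test_ambient_loci_informative_weight_extremes(toy_ref, rng):
    genome = GenomeIndex.from_fasta(str(toy_ref.genome_path))
    regions = RegionSet.from_bed(str(toy_ref.atac_regions_path), genome)
    amb = np.ones(10_000, dtype=bool)
    # beta = 1: every ambient locus is informative
    assert regions.contains(_sample_loci(amb, regions, genome, 1.0, rng)).all()
    # beta = 0: genome-uniform, so the in-region fraction matches the
    # informative base fraction within 3 binomial SD
    frac = regions.contains(_sample_loci(amb, regions, genome, 0.0, rng)).mean()
    p = regions.total_bases / genome.total_length
    assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / 10_000)


def test_sample_read_locus_scalar(toy_ref, rng):
    genome = GenomeIndex.from_fasta(str(toy_ref.genome_path))
    regions = RegionSet.from_bed(str(toy_ref.rna_regions_path), genome)
    chrom, start, strand = sample_read_locus(False, regions, genome, rng, span=91)
    assert chrom == "chr1" and 0 <= start <= genome.total_length - 91
    assert strand in "+-"


def test_native_allele_law(geno, rng):
    _, gmat = geno
    dosages = gmat.dosages
    hom_ref = np.argwhere(dosages == 0)[0]
    hom_alt = np.argwhere(dosages == 2)[0]
    het = np.argwhere(dosages == 1)[0]
    # dosage 0 -> never alt; dosage 2 -> always alt
    for (k, v), want in ((hom_ref, False), (hom_alt, True)):
        alt, _ = _draw_alleles(np.full(100, k), np.full(100, v), dosages, rng)
        assert np.all(alt == want)
    # het -> alt fraction within 3 SD of 1/2 over 10,000 draws
    k, v = het
    alt, _ = _draw_alleles(np.full(10_000, k), np.full(10_000, v), dosages, rng)
    assert abs(alt.mean() - 0.5) < 3 * np.sqrt(0.25 / 10_000)


def test_assign_allele_scalar_cases(geno, rng):
    _, gmat = geno
    v_by_dosage = {d: int(np.argwhere(gmat.dosages[0] == d)[0][0]) for d in (0, 2)}
    drop = ax.DropletSpec("A" * 16, "singlet", (0,), 1.0, 0.0, 10, 10)
    assert assign_allele(drop, False, v_by_dosage[0], gmat, rng) == ("ref", 0)
    assert assign_allele(drop, False, v_by_dosage[2], gmat, rng) == ("alt", 0)
    allele, src = assign_allele(drop, True, v_by_dosage[0], gmat, rng)
    assert allele in ("ref", "alt") and 0 <= src < gmat.n_donors


def test_ambient_allele_frequency_matches_pool(clean_sim, geno):
    """Over many ambient reads the alt fraction at covered SNPs converges to
    the donor-weighted mean dosage/2 (uniform ambient weights here)."""
    _, gmat = geno
    _, sim = clean_sim
    obs_alt, expected, n = [], 0.0, 0
    for m in ("rna", "atac"):
        mt = getattr(sim.truth, m)
        amb = mt.obs_is_ambient
        valid = gmat.dosages[:, mt.obs_variant[amb]] >= 0
        p = np.where(gmat.dosages[:, mt.obs_variant[amb]] > 0,
                     gmat.dosages[:, mt.obs_variant[amb]], 0) / 2.0
        expected += float((p.sum(axis=0) / valid.sum(axis=0)).sum())
        obs_alt.append(mt.obs_is_alt[amb])
        n += int(amb.sum())
    observed = np.concatenate(obs_alt).sum()
    sd = np.sqrt(n * 0.25)  # Bernoulli variance bound
    assert abs(observed - expected) < 3 * sd


def test_sequencing_error_operator(rng):
    seq = "ACGT" * 250_000
    assert apply_sequencing_errors(seq, 0.0, rng) == seq
    mutated = apply_sequencing_errors(seq, 0.01, rng)
    mismatches = sum(a != b for a, b in zip(seq, mutated))
    sd = np.sqrt(1e6 * 0.01 * 0.99)
    assert abs(mismatches - 10_000) < 3 * sd
    # a substituted base never equals the original
    small = "A" * 5_000
    out = apply_sequencing_errors(small, 0.1, rng)
    assert set(out) - {"A"} != set() and all(c in "CGT" for c in out if c != "A")


def test_error_rate_out_of_range_rejected(rng):
    with pytest.raises(ValueError):
        apply_sequencing_errors("ACGT", 0.5, rng)
    with pytest.raises(ValueError):
        SimParams(seq_error_rate=0.5)


def test_fastq_layout_and_bam_structure(clean_sim):
    droplets, sim = clean_sim
    with gzip.open(sim.fastq_paths["rna_R1"], "rt") as fh:
        lines = fh.read().splitlines()
    assert len(lines) % 4 == 0
    n_fastq = len(lines) // 4
    assert all(len(lines[i]) == 28 for i in range(1, len(lines), 4))  # 16 bp CB + 12 bp UMI
    with pysam.AlignmentFile(str(sim.bam_paths["rna"])) as bam:
        rna_records = [r for r in bam.fetch(until_eof=True)]
    assert len(rna_records) == n_fastq == sim.truth.rna.n_units
    assert all(r.has_tag("CB") and r.has_tag("UB") for r in rna_records[:50])
    assert all(r.mapping_quality == 60 for r in rna_records[:50])
    with pysam.AlignmentFile(str(sim.bam_paths["atac"])) as bam:
        atac_records = [r for r in bam.fetch(until_eof=True)]
    assert len(atac_records) == 2 * sim.truth.atac.n_units  # mate pairs
    assert all(r.is_paired and r.is_proper_pair for r in atac_records[:50])
    # coordinate sorted
    starts = [r.reference_start for r in rna_records]
    assert starts == sorted(starts)


def test_bam_sequences_match_reference_when_clean(clean_sim, toy_ref, geno):
    """With zero sequencing error, read bases differ from the reference only
    at SNP positions (where the alt allele may be injected)."""
    table, _ = geno
    snp_pos = set(int(p) - 1 for p in table.pos)
    with pysam.FastaFile(str(toy_ref.genome_path)) as fa, pysam.AlignmentFile(
        str(clean_sim[1].bam_paths["rna"])
    ) as bam:
        for r in list(bam.fetch("chr1", 0, 60_000))[:200]:
            ref = fa.fetch("chr1", r.reference_start, r.reference_end)
            for off, (a, b) in enumerate(zip(r.query_sequence, ref)):
                if a != b:
                    assert r.reference_start + off in snp_pos


def test_seed_determinism_and_sensitivity(toy_ref, geno, whitelist, tmp_path):
    table, gmat = geno
    cfg = ax.ExperimentConfig(n_droplets=10, n_donors=4, ambient_level=0.2,
                              rna_depth_mean=50, atac_depth_mean=40, seed=7)
    droplets = ax.sample_droplets(cfg, whitelist=whitelist)

    def run(out, seed):
        return ax.simulate_experiment(
            droplets, toy_ref.genome_path, table, gmat,
            toy_ref.rna_regions_path, toy_ref.atac_regions_path,
            SimParams(), tmp_path / out, seed=seed,
        )
    a, b, c = run("a", 3), run("b", 3), run("c", 4)
    for m in ("rna", "atac"):
        assert (
            a.fastq_paths[f"{m}_R1"].read_bytes() == b.fastq_paths[f"{m}_R1"].read_bytes()
        )
        assert (
            a.fastq_paths[f"{m}_R2"].read_bytes() == b.fastq_paths[f"{m}_R2"].read_bytes()
        )
        assert a.bam_paths[m].read_bytes() == b.bam_paths[m].read_bytes()
    assert a.fastq_paths["rna_R2"].read_bytes() != c.fastq_paths["rna_R2"].read_bytes()


def test_contig_mismatch_rejected(toy_ref, geno, whitelist, tmp_path):
    table, gmat = geno
    bad = table.subset(np.arange(5))
    bad.chrom[:] = "chrX"
    cfg = ax.ExperimentConfig(n_droplets=3, n_donors=4, rna_depth_mean=10,
                              atac_depth_mean=10, seed=1)
    droplets = ax.sample_droplets(cfg, whitelist=whitelist)
    with pytest.raises(ValueError, match="chrX"):
        ax.simulate_experiment(
            droplets, toy_ref.genome_path, bad, gmat,
            toy_ref.rna_regions_path, toy_ref.atac_regions_path,
            SimParams(), tmp_path / "bad", seed=1,
        )
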