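"""C1/C2/I1/I2 classification, F aggregation, and ambient recovery."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

import ambimux as ax
from ambimux.allele_pileup import PileupMatrices
from ambimux.droplet_sampler import DropletSpec
from ambimux.genotype_io import ALLELE_SETS, GenotypeMatrix, VariantTable
from ambimux.read_simulator import ModalityTruth, SimTruth
from ambimux.variant_consistency import ConsistencyResult, _category_lookup

R, RA, A = frozenset("r"), frozenset("ra"), frozenset("a")


@pytest.mark.parametrize(
    "allele,assigned,others,expected",
    [
        ("alt", RA, [R, R, R], "C1"),     # only the assigned donor carries alt
        ("alt", RA, [RA, R], "C2"),       # assigned and another donor carry alt
        ("ref", A, [RA], "I1"),           # ref foreign to assigned, carried elsewhere
        ("alt", R, [R, R], "I2"),         # alt carried by nobody
        ("ref", R, [], "C1"),             # single-donor pool: no others to match
        ("alt", R, [None, RA], "I1"),     # missing other donors are skipped
        ("alt", None, [R], None),         # missing assigned genotype -> excluded
    ],
)
def test_classify_allele_truth_table(allele, assigned, others, expected):
    assert ax.classify_allele(allele, assigned, others) == expected


def test_classify_allele_rejects_bad_allele():
    with pytest.raises(ValueError):
        ax.classify_allele("G", R, [])


def test_category_lookup_matches_scalar_classifier(rng):
    """The vectorised per-(donor, variant) category table agrees with the
    one-allele-at-a-time definition, including missing genotypes."""
    dosages = rng.integers(-1, 3, size=(5, 60)).astype(np.int8)
    cat_ref, cat_alt = _category_lookup(dosages)
    names = ("C1", "C2", "I1", "I2")
    for k in range(5):
        for v in range(60):
            assigned = None if dosages[k, v] < 0 else ALLELE_SETS[dosages[k, v]]
            others = [
                None if dosages[j, v] < 0 else ALLELE_SETS[dosages[j, v]]
                for j in range(5) if j != k
            ]
            for allele, table in (("ref", cat_ref), ("alt", cat_alt)):
                want = ax.classify_allele(allele, assigned, others)
                got = None if table[k, v] < 0 else names[table[k, v]]
                assert got == want


def test_shared_genotype_sites_cannot_be_c1_or_i1(rng):
    """When every donor has the same genotype at a variant, no allele can be
    consistent with *only* one donor (C1) or foreign-yet-matched (I1)."""
    dosages = np.repeat(rng.integers(0, 3, size=(1, 40)).astype(np.int8), 4, axis=0)
    cat_ref, cat_alt = _category_lookup(dosages)
    for table in (cat_ref, cat_alt):
        assert not np.isin(table, [0, 2]).any()


def _manual_pileup(R_mat, A_mat, barcodes, n_var):
    table = VariantTable(
        chrom=np.array(["chr1"] * n_var, dtype=object),
        pos=np.arange(1, n_var + 1), ref=np.array(["A"] * n_var, dtype=object),
        alt=np.array(["C"] * n_var, dtype=object),
        r2=np.full(n_var, np.nan), maf=np.full(n_var, np.nan),
    )
    return PileupMatrices(
        R=sparse.csr_matrix(np.asarray(R_mat)), A=sparse.csr_matrix(np.asarray(A_mat)),
        barcodes=barcodes, variants=table,
    )


def test_single_donor_pool_has_no_c2_or_i1():
    gmat = GenotypeMatrix(np.array([[0, 1, 2]], dtype=np.int8), ["d0"])
    pile = _manual_pileup([[3, 2, 1]], [[1, 2, 3]], ["BC1"], 3)
    assign = pd.DataFrame({"barcode": ["BC1"], "call": ["d0"]})
    res = ax.consistency_counts(pile, gmat, assign)
    assert res.F[0, 1] == 0 and res.F[0, 2] == 0  # C2, I1 impossible
    assert res.F.sum() == 12


def test_zero_count_droplet_has_zero_row():
    gmat = GenotypeMatrix(np.array([[0], [2]], dtype=np.int8), ["d0", "d1"])
    pile = _manual_pileup([[0], [4]], [[0], [0]], ["BC1", "BC2"], 1)
    assign = pd.DataFrame({"barcode": ["BC1", "BC2"], "call": ["d0", "d1"]})
    res = ax.consistency_counts(pile, gmat, assign)
    assert np.array_equal(res.F[0], [0, 0, 0, 0])
    assert res.F[1, 2] == 4  # d1 is hom-alt; 4 ref reads match d0 -> I1


def test_f_equals_per_read_brute_force(clean_sim, clean_pileups, geno):
    """Count-weighted F from the sparse pipeline equals a read-by-read
    reclassification of the simulator's per-read truth records."""
    _, gmat = geno
    droplets, sim = clean_sim
    assign = sim.truth.assignment_frame(gmat.donor_ids)
    donor_of = {r.barcode: r.call for r in assign.itertuples()}
    for m in ("rna", "atac"):
        res = ax.consistency_counts(clean_pileups[m], gmat, assign)
        expect = {bc: np.zeros(4, dtype=int) for bc in res.barcodes}
        mt = getattr(sim.truth, m)
        cat_idx = {c: i for i, c in enumerate(ax.CATEGORIES)}
        for d, v, alt in zip(mt.obs_droplet, mt.obs_variant, mt.obs_is_alt):
            bc = droplets[d].barcode
            call = donor_of[bc]
            if call in ("doublet", "unassigned"):
                continue
            k = gmat.donor_index(call)
            assigned = ALLELE_SETS[gmat.dosages[k, v]]
            others = [
                ALLELE_SETS[gmat.dosages[j, v]]
                for j in range(gmat.n_donors) if j != k
            ]
            cat = ax.classify_allele("alt" if alt else "ref", assigned, others)
            expect[bc][cat_idx[cat]] += 1
        got = {bc: res.F[i] for i, bc in enumerate(res.barcodes)}
        for bc in expect:
            assert np.array_equal(got[bc], expect[bc]), (m, bc)


def test_f_row_sums_conserve_classified_counts(clean_pileups, clean_sim, geno):
    _, gmat = geno
    _, sim = clean_sim
    assign = sim.truth.assignment_frame(gmat.donor_ids)
    pile = clean_pileups["rna"]
    res = ax.consistency_counts(pile, gmat, assign)
    row_of = {bc: i for i, bc in enumerate(pile.barcodes)}
    totals = np.asarray(pile.total_counts().sum(axis=1)).ravel()
    for i, bc in enumerate(res.barcodes):
        assert res.F[i].sum() == totals[row_of[bc]]


def test_per_variant_counting_binarises_streams():
    gmat = GenotypeMatrix(np.array([[1], [0]], dtype=np.int8), ["d0", "d1"])
    pile = _manual_pileup([[7]], [[5]], ["BC1"], 1)
    assign = pd.DataFrame({"barcode": ["BC1"], "call": ["d0"]})
    weighted = ax.consistency_counts(pile, gmat, assign)
    binary = ax.consistency_counts(pile, gmat, assign, per_variant=True)
    assert weighted.F.sum() == 12
    assert binary.F.sum() == 2  # one ref stream + one alt stream


def test_i1_rate_arithmetic_and_exclusions():
    res = ConsistencyResult(
        barcodes=["a", "b"], assigned_donor=np.array([0, 0]),
        F=np.array([[10, 5, 5, 0], [0, 0, 0, 0]]), donor_ids=["d0"],
    )
    rates = ax.i1_rate(res)
    assert rates.loc["a"] == pytest.approx(0.25)
    assert "b" not in rates.index  # zero-count droplets excluded


def test_zero_ambient_zero_error_yields_zero_i1_i2(zero_ambient_sim, geno):
    table, gmat = geno
    droplets, sim = zero_ambient_sim
    assign = sim.truth.assignment_frame(gmat.donor_ids)
    for m in ("rna", "atac"):
        pile = ax.pileup_counts(
            sim.bam_paths[m], table, [d.barcode for d in droplets], modality=m
        )
        res = ax.consistency_counts(pile, gmat, assign)
        assert res.F[:, 2].sum() == 0 and res.F[:, 3].sum() == 0


def test_i1_bounded_by_true_ambient_count(clean_sim, clean_pileups, geno):
    """I1 allele counts can only come from ambient molecules, so per droplet
    they sit at or below the true ambient molecule count."""
    _, gmat = geno
    droplets, sim = clean_sim
    assign = sim.truth.assignment_frame(gmat.donor_ids)
    idx_of = {d.barcode: i for i, d in enumerate(droplets)}
    for m in ("rna", "atac"):
        res = ax.consistency_counts(clean_pileups[m], gmat, assign)
        amb = getattr(sim.truth, m).ambient_per_droplet
        for i, bc in enumerate(res.barcodes):
            assert res.F[i, 2] <= amb[idx_of[bc]]


def test_coverage_profile_matches_groupby_oracle(clean_pileups, clean_sim, geno):
    _, gmat = geno
    _, sim = clean_sim
    pile = clean_pileups["rna"]
    res = ax.consistency_counts(pile, gmat, sim.truth.assignment_frame(gmat.donor_ids))
    edges = [1, 3, 10, 100, 10_000]
    prof = ax.snp_coverage_i1_profile(res, pile, bin_edges=edges)
    coverage = np.asarray(pile.total_counts().sum(axis=0)).ravel()
    df = pd.DataFrame({"cov": coverage, "i1": res.variant_i1, "tot": res.variant_total})
    df = df[df["cov"] > 0]
    df["bin"] = pd.cut(df["cov"], bins=edges, right=False)
    oracle = df.groupby("bin", observed=True)[["i1", "tot"]].sum()
    oracle_rate = (oracle["i1"] / oracle["tot"]).to_numpy()
    assert np.allclose(prof["i1_rate"].to_numpy(), oracle_rate, equal_nan=True)
    assert prof["n_variants"].sum() == len(df)


def _fake_truth(i1_counts, ambient_counts):
    n = len(i1_counts)
    droplets = [
        DropletSpec(f"BC{i:05d}", "singlet", (0,), 1.0, 0.2, 10, 10) for i in range(n)
    ]
    mt = ModalityTruth(
        n_units=int(np.sum(ambient_counts)),
        native_per_droplet=np.zeros(n, dtype=int),
        ambient_per_droplet=np.asarray(ambient_counts),
        R=sparse.csr_matrix((n, 1)), A=sparse.csr_matrix((n, 1)),
        obs_droplet=np.empty(0, int), obs_variant=np.empty(0, int),
        obs_is_alt=np.empty(0, bool), obs_is_ambient=np.empty(0, bool),
        obs_source_donor=np.empty(0, int),
    )
    truth = SimTruth(droplets=droplets, rna=mt)
    result = ConsistencyResult(
        barcodes=[d.barcode for d in droplets],
        assigned_donor=np.zeros(n, dtype=int),
        F=np.column_stack(
            [np.zeros((n, 2), int), np.asarray(i1_counts), np.zeros((n, 1), int)]
        ),
        donor_ids=["d0"],
    )
    return result, truth


def test_ambient_correlation_perfect_and_null(rng):
    amb = rng.integers(0, 200, size=1_000)
    res, truth = _fake_truth((3 * amb).reshape(-1, 1), amb)
    assert ax.ambient_correlation(res, truth, "rna") == pytest.approx(1.0)
    res_perm, truth_perm = _fake_truth(
        (3 * rng.permutation(amb)).reshape(-1, 1), amb
    )
    assert ax.ambient_correlation(res_perm, truth_perm, "rna") < 0.01


def test_ambient_correlation_rejects_constant():
    res, truth = _fake_truth(np.zeros((50, 1), int), np.arange(50))
    with pytest.raises(ValueError, match="constant"):
        ax.ambient_correlation(res, truth, "rna")


def test_atac_c1_rate_exceeds_rna_on_constructed_pool(
    toy_ref, geno, whitelist, tmp_path
):
    """Fixture where every SNP inside gene bodies is shared by all donors
    while peak SNPs stay discriminating: ATAC's informative SNP pool then
    carries more donor-unique alleles, so its C1 rate dominates RNA's."""
    from ambimux._genome import GenomeIndex, RegionSet
    from ambimux.read_simulator import SimParams

    table, gmat = geno
    genome = GenomeIndex.from_fasta(str(toy_ref.genome_path))
    rna_regions = RegionSet.from_bed(str(toy_ref.rna_regions_path), genome)
    gpos = np.array([genome.to_global(c, p - 1) for c, p in zip(table.chrom, table.pos)])
    in_genes = rna_regions.contains(gpos)
    dosages = gmat.dosages.copy()
    dosages[:, in_genes] = dosages[0, in_genes]  # gene SNPs identical across donors
    gmat2 = GenotypeMatrix(dosages, list(gmat.donor_ids))

    cfg = ax.ExperimentConfig(n_droplets=40, n_donors=4, doublet_rate=0.0,
                              ambient_level=0.1, rna_depth_mean=400,
                              atac_depth_mean=300, seed=17)
    droplets = ax.sample_droplets(cfg, whitelist=whitelist)
    sim = ax.simulate_experiment(
        droplets, toy_ref.genome_path, table, gmat2,
        toy_ref.rna_regions_path, toy_ref.atac_regions_path,
        SimParams(seq_error_rate=0.0), tmp_path / "c1", seed=17, emit_fastq=False,
    )
    assign = sim.truth.assignment_frame(gmat2.donor_ids)
    c1 = {}
    for m in ("rna", "atac"):
        pile = ax.pileup_counts(
            sim.bam_paths[m], table, [d.barcode for d in droplets], modality=m
        )
        res = ax.consistency_counts(pile, gmat2, assign)
        c1[m] = np.nanmean(res.rates()[:, 0])
    assert c1["atac"] >= c1["rna"]
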