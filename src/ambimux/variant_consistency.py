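"""The variant-consistency metric: post-hoc ambient-contamination QC for
demultiplexed singlets.

Every counted allele in an assigned singlet is classified against the
assigned donor's genotype and everyone else's:

* C1 — consistent with the assigned donor only;
* C2 — consistent with the assigned donor and with at least one other donor;
* I1 — inconsistent with the assigned donor but carried by another donor:
  such reads must come from other donors' material, so the per-droplet I1
  count is a *lower bound* on ambient contamination;
* I2 — inconsistent with every pooled donor: sequencing or genotyping error.

"Consistent" means the observed allele belongs to the donor's allele set
(hom-ref -> {ref}, het -> {ref, alt}, hom-alt -> {alt}). Counts aggregate to
the droplet x 4 matrix F, row-normalised into per-droplet category rates.

F is read-count weighted: it accumulates allele *counts*, which is what
makes the per-droplet I1 count comparable to the droplet's true number of
ambient molecules; ``per_variant=True`` gives the binarised (distinct
allele-stream) alternative. Droplets called doublet or unassigned are
excluded — the metric is defined on singlets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .allele_pileup import PileupMatrices
from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

CATEGORIES = ("C1", "C2", "I1", "I2")


def classify_allele(
    allele: str,
    assigned_set: frozenset | None,
    other_sets: list[frozenset | None],
) -> str | None:
    """Classify one observed allele ("ref"/"alt") into C1/C2/I1/I2.

    ``assigned_set`` is the assigned donor's allele set ({"r"}, {"r","a"} or
    {"a"}); ``other_sets`` the remaining donors'. Donors with missing
    genotype (None) are skipped in the "other" comparison; a missing
    *assigned* genotype returns None (the variant is excluded for that
    droplet rather than fabricating consistency).
    """
    if allele not in ("ref", "alt"):
        raise ValueError("allele must be 'ref' or 'alt'")
    if assigned_set is None:
        return None
    code = allele[0]  # "r" / "a"
    consistent = code in assigned_set
    matched_other = any(s is not None and code in s for s in other_sets)
    if consistent:
        return "C2" if matched_other else "C1"
    return "I1" if matched_other else "I2"


@dataclass
class ConsistencyResult:
    """Per-droplet C1/C2/I1/I2 counts for assigned singlets."""

    barcodes: list[str]            # assigned singlets present in the pileup
    assigned_donor: np.ndarray     # donor index per row
    F: np.ndarray                  # D x 4 counts (C1, C2, I1, I2)
    donor_ids: list[str]
    per_variant: bool = False
    n_skipped_barcodes: int = 0    # assignments without pileup rows
    n_missing_assigned: int = 0    # allele counts dropped: assigned GT missing
    variant_i1: np.ndarray | None = None      # per-variant I1 counts
    variant_total: np.ndarray | None = None   # per-variant classified counts

    def rates(self) -> np.ndarray:
        """Row-normalised F; rows with zero counts are NaN."""
        total = self.F.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, self.F / total, np.nan)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.F, columns=list(CATEGORIES))
        df.insert(0, "barcode", self.barcodes)
        df.insert(1, "assigned_donor", [self.donor_ids[k] for k in self.assigned_donor])
        rates = self.rates()
        for i, c in enumerate(CATEGORIES):
            df[f"{c.lower()}_rate"] = rates[:, i]
        return df


def _category_lookup(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """For each (donor k, variant v) and each allele, the category index the
    allele falls in when the droplet is assigned to k; -1 where k's genotype
    is missing. Returns (cat_ref, cat_alt), each K x V int8."""
    valid = dosages != MISSING
    in_ref = valid & (dosages <= 1)
    in_alt = valid & (dosages >= 1)
    n_ref = in_ref.sum(axis=0)
    n_alt = in_alt.sum(axis=0)

    def table(in_set: np.ndarray, n_set: np.ndarray) -> np.ndarray:
        other = (n_set[None, :] - in_set.astype(np.int64)) > 0
        cat = np.where(
            in_set,
            np.where(other, 1, 0),   # C2 / C1
            np.where(other, 2, 3),   # I1 / I2
        ).astype(np.int8)
        cat[~valid] = -1
        return cat

    return table(in_ref, n_ref), table(in_alt, n_alt)


def consistency_counts(
    pileup: PileupMatrices,
    genotypes: GenotypeMatrix,
    assignments: pd.DataFrame,
    per_variant: bool = False,
) -> ConsistencyResult:
    """Aggregate classified allele counts into F (droplets x C1/C2/I1/I2).

    ``assignments`` needs columns ``barcode`` and ``call`` where call is a
    donor id (singlet), "doublet" or "unassigned"; only singlet calls whose
    barcode exists in the pileup contribute (others are counted and logged).
    Both observed alleles of a het droplet at one variant are classified
    independently, so its ref and alt streams can land in different
    categories.
    """
    if pileup.n_variants != genotypes.n_variants:
        raise ValueError(
            f"pileup has {pileup.n_variants} variants, genotype matrix "
            f"{genotypes.n_variants}"
        )
    if assignments["barcode"].duplicated().any():
        raise ValueError("duplicate barcodes in assignment table")
    row_of = {bc: i for i, bc in enumerate(pileup.barcodes)}
    singlet = ~assignments["call"].isin(["doublet", "unassigned"])
    kept = assignments.loc[singlet]
    n_skipped = int((~kept["barcode"].isin(row_of)).sum())
    if n_skipped:
        logger.info("%d assigned barcodes absent from pileup; skipped", n_skipped)
    kept = kept.loc[kept["barcode"].isin(row_of)]
    barcodes = kept["barcode"].tolist()
    donor_idx = np.array(
        [genotypes.donor_index(c) for c in kept["call"]], dtype=np.int64
    )
    d = len(barcodes)
    v = pileup.n_variants
    cat_ref, cat_alt = _category_lookup(genotypes.dosages)

    F = np.zeros((d, 4), dtype=np.int64)
    variant_i1 = np.zeros(v, dtype=np.int64)
    variant_total = np.zeros(v, dtype=np.int64)
    n_missing_assigned = 0
    pile_rows = np.array([row_of[bc] for bc in barcodes], dtype=np.int64)

    for mat, cat_table in ((pileup.R, cat_ref), (pileup.A, cat_alt)):
        sub = mat.tocsr()[pile_rows].tocoo()
        if sub.nnz == 0:
            continue
        counts = np.ones(sub.nnz, dtype=np.int64) if per_variant else sub.data.astype(np.int64)
        cats = cat_table[donor_idx[sub.row], sub.col]
        ok = cats >= 0
        n_missing_assigned += int(counts[~ok].sum())
        np.add.at(F, (sub.row[ok], cats[ok].astype(np.int64)), counts[ok])
        np.add.at(variant_total, sub.col[ok], counts[ok])
        i1 = ok & (cats == 2)
        np.add.at(variant_i1, sub.col[i1], counts[i1])

    return ConsistencyResult(
        barcodes=barcodes, assigned_donor=donor_idx, F=F,
        donor_ids=list(genotypes.donor_ids), per_variant=per_variant,
        n_skipped_barcodes=n_skipped, n_missing_assigned=n_missing_assigned,
        variant_i1=variant_i1, variant_total=variant_total,
    )


def consistency_tensor(
    pileup: PileupMatrices,
    genotypes: GenotypeMatrix,
    barcodes: list[str] | None = None,
) -> pd.DataFrame:
    """Sparse long-form view of the full droplet x variant x donor x category
    tensor: each counted allele stream classified *as if* assigned to every
    donor in turn. One row per nonzero (barcode, variant, donor, category)
    with its count. Intended for small inputs (size grows with nnz x K)."""
    row_of = {bc: i for i, bc in enumerate(pileup.barcodes)}
    sel = (
        np.arange(len(pileup.barcodes))
        if barcodes is None
        else np.array([row_of[b] for b in barcodes], dtype=np.int64)
    )
    names = [pileup.barcodes[i] for i in sel]
    cat_ref, cat_alt = _category_lookup(genotypes.dosages)
    frames = []
    for mat, cat_table, allele in ((pileup.R, cat_ref, "ref"), (pileup.A, cat_alt, "alt")):
        sub = mat.tocsr()[sel].tocoo()
        for k, donor in enumerate(genotypes.donor_ids):
            cats = cat_table[k, sub.col]
            ok = cats >= 0
            frames.append(
                pd.DataFrame(
                    {
                        "barcode": [names[r] for r in sub.row[ok]],
                        "variant": sub.col[ok],
                        "allele": allele,
                        "donor": donor,
                        "category": [CATEGORIES[c] for c in cats[ok]],
                        "count": sub.data[ok].astype(np.int64),
                    }
                )
            )
    if not frames:
        return pd.DataFrame(
            columns=["barcode", "variant", "allele", "donor", "category", "count"]
        )
    return pd.concat(frames, ignore_index=True)


def i1_rate(result: ConsistencyResult) -> pd.Series:
    """Per-droplet I1 / (C1+C2+I1+I2); droplets with zero classified counts
    are excluded (and their number logged)."""
    total = result.F.sum(axis=1)
    zero = total == 0
    if zero.any():
        logger.info("%d droplets have no classified counts; excluded", int(zero.sum()))
    idx = np.flatnonzero(~zero)
    return pd.Series(
        result.F[idx, 2] / total[idx],
        index=pd.Index([result.barcodes[i] for i in idx], name="barcode"),
        name="i1_rate",
    )


def snp_coverage_i1_profile(
    result: ConsistencyResult,
    pileup: PileupMatrices,
    bin_edges: list[int] | None = None,
) -> pd.DataFrame:
    """Pooled I1 rate as a function of experiment-wide SNP coverage.

    Coverage of a variant is its total R+A count over *all* droplets in the
    pileup; I1 rates are pooled (sum of I1 counts / sum of classified
    counts) within coverage bins. Uncovered variants are absent.
    """
    if result.variant_i1 is None:
        raise ValueError("result lacks per-variant counters")
    coverage = np.asarray(pileup.total_counts().sum(axis=0)).ravel()
    covered = coverage > 0
    if bin_edges is None:
        top = max(int(coverage.max()), 2)
        bin_edges = list(np.unique(np.geomspace(1, top + 1, num=8).astype(int))) + [
            int(coverage.max()) + 1
        ]
    bins = pd.cut(coverage[covered], bins=sorted(set(bin_edges)), right=False)
    df = pd.DataFrame(
        {
            "coverage_bin": bins,
            "i1": result.variant_i1[covered],
            "total": result.variant_total[covered],
        }
    )
    out = (
        df.groupby("coverage_bin", observed=True)[["i1", "total"]]
        .sum()
        .reset_index()
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        out["i1_rate"] = np.where(out["total"] > 0, out["i1"] / out["total"], np.nan)
    out["n_variants"] = (
        df.groupby("coverage_bin", observed=True).size().to_numpy()
    )
    return out


def ambient_correlation(result, truth, modality: str = "rna") -> float:
    """Squared Pearson correlation between per-droplet I1 counts and the true
    number of ambient molecules, over correctly assigned singlets.

    ``truth`` is the simulator's SimTruth; droplets in ``result`` whose
    assigned donor disagrees with the simulation truth are dropped first.
    Raises on fewer than 3 usable droplets or on constant vectors.
    """
    mt = {"rna": truth.rna, "atac": truth.atac}[modality]
    if mt is None:
        raise ValueError(f"truth has no {modality} modality")
    truth_row = {d.barcode: d for d in truth.droplets}
    truth_idx = {d.barcode: i for i, d in enumerate(truth.droplets)}
    i1, amb = [], []
    for i, bc in enumerate(result.barcodes):
        drop = truth_row.get(bc)
        if (
            drop is not None
            and drop.droplet_type == "singlet"
            and drop.donors[0] == result.assigned_donor[i]
        ):
            i1.append(result.F[i, 2])
            amb.append(mt.ambient_per_droplet[truth_idx[bc]])
    if len(i1) < 3:
        raise ValueError("need at least 3 correctly assigned singlets")
    i1_arr, amb_arr = np.asarray(i1, float), np.asarray(amb, float)
    if np.ptp(i1_arr) == 0 or np.ptp(amb_arr) == 0:
        raise ValueError("constant vector: correlation undefined")
    r = stats.pearsonr(i1_arr, amb_arr).statistic
    return float(r * r)
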