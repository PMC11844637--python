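"""Donor genotypes: VCF -> variant table + K x V dosage matrix.

The in-memory convention is alt-allele dosage per donor per variant
(0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing), the standard encoding of
a genotyping array restricted to biallelic SNPs. Variant coordinates stay
1-based (VCF convention) in the table; conversion to the simulator's 0-based
global space happens at its boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

MISSING = -1

#: dosage -> set of alleles the donor carries ("r" reference, "a" alternate)
ALLELE_SETS = {0: frozenset("r"), 1: frozenset("ra"), 2: frozenset("a")}


@dataclass
class VariantTable:
    """Biallelic SNPs in VCF order: chrom, 1-based pos, ref/alt base, optional
    imputation R2 and allele frequency (NaN where the INFO field is absent)."""

    chrom: np.ndarray
    pos: np.ndarray      # 1-based
    ref: np.ndarray
    alt: np.ndarray
    r2: np.ndarray
    maf: np.ndarray
    n_dropped: int = 0   # non-biallelic-SNP records skipped at load

    def __len__(self) -> int:
        return len(self.pos)

    def subset(self, idx: np.ndarray) -> "VariantTable":
        return VariantTable(
            chrom=self.chrom[idx], pos=self.pos[idx], ref=self.ref[idx],
            alt=self.alt[idx], r2=self.r2[idx], maf=self.maf[idx],
            n_dropped=self.n_dropped,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "pos": self.pos, "ref": self.ref,
             "alt": self.alt, "r2": self.r2, "maf": self.maf}
        )

    def equals(self, other: "VariantTable") -> bool:
        return (
            len(self) == len(other)
            and bool(np.all(self.chrom == other.chrom))
            and bool(np.all(self.pos == other.pos))
            and bool(np.all(self.ref == other.ref))
            and bool(np.all(self.alt == other.alt))
        )


@dataclass
class GenotypeMatrix:
    """K donors x V variants of alt-allele dosage; -1 marks a missing GT."""

    dosages: np.ndarray          # int8 K x V
    donor_ids: list[str]
    _sets: dict = field(default_factory=dict, repr=False)

    @property
    def n_donors(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def subset_variants(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages[:, idx], list(self.donor_ids))

    def donor_index(self, donor: str) -> int:
        try:
            return self.donor_ids.index(donor)
        except ValueError:
            raise KeyError(
                f"donor {donor!r} not found; available: {', '.join(self.donor_ids)}"
            ) from None


def donor_allele_set(g: GenotypeMatrix, donor: int, variant: int) -> frozenset | None:
    """Alleles donor ``donor`` carries at ``variant``: dosage 0 -> {r},
    1 -> {r, a}, 2 -> {a}. Missing genotype -> None (the variant is excluded
    from consistency classification for that donor; see variant_consistency).
    """
    d = int(g.dosages[donor, variant])
    if d == MISSING:
        return None
    return ALLELE_SETS[d]


def load_genotypes(
    vcf_path: str, donor_subset: list[str] | None = None
) -> tuple[VariantTable, GenotypeMatrix]:
    """Parse a VCF into (VariantTable, GenotypeMatrix).

    Only biallelic SNP records are kept (others are dropped and counted in
    ``table.n_dropped``). Row order is VCF order. ``donor_subset`` restricts
    and reorders the donor axis; requesting an unknown donor raises with the
    list of available ones.
    """
    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    if donor_subset is not None:
        missing = [d for d in donor_subset if d not in samples]
        if missing:
            raise KeyError(
                f"donor(s) {missing} not in VCF; available: {samples}"
            )
        cols = np.array([samples.index(d) for d in donor_subset])
        donor_ids = list(donor_subset)
    else:
        cols = np.arange(len(samples))
        donor_ids = samples

    chrom, pos, ref, alt, r2, maf, rows = [], [], [], [], [], [], []
    n_dropped = 0
    n_info_absent = 0
    for rec in vcf:
        if not rec.is_snp or len(rec.ALT) != 1 or len(rec.REF) != 1:
            n_dropped += 1
            continue
        chrom.append(rec.CHROM)
        pos.append(rec.POS)
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
        rec_r2 = rec.INFO.get("R2")
        rec_af = rec.INFO.get("AF")
        if rec_r2 is None or rec_af is None:
            n_info_absent += 1
        r2.append(np.nan if rec_r2 is None else float(rec_r2))
        maf.append(np.nan if rec_af is None else float(rec_af))
        # gts012: 0/1/2 = alt dosage, 3 = missing
        g = rec.gt_types[cols].astype(np.int8)
        g[g == 3] = MISSING
        rows.append(g)
    if n_dropped:
        logger.info("dropped %d non-biallelic-SNP records from %s", n_dropped, vcf_path)
    if n_info_absent:
        logger.info("%d records lack R2/AF INFO fields (treated as passing filters)",
                    n_info_absent)
    table = VariantTable(
        chrom=np.array(chrom, dtype=object), pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object), alt=np.array(alt, dtype=object),
        r2=np.array(r2), maf=np.array(maf), n_dropped=n_dropped,
    )
    dosages = (
        np.stack(rows, axis=1) if rows else np.empty((len(donor_ids), 0), dtype=np.int8)
    )
    return table, GenotypeMatrix(dosages=dosages, donor_ids=donor_ids)


def filter_variants(
    table: VariantTable,
    genotypes: GenotypeMatrix | None = None,
    min_r2: float = 0.0,
    min_maf: float = 0.0,
):
    """Keep variants with imputation R2 > min_r2 and MAF > min_maf (strict
    inequalities). Variants whose INFO lacks the field pass that filter (the
    filter only applies where imputation quality / frequency is annotated);
    the count of such pass-throughs is logged.

    Returns the filtered table, or (table, genotypes) when a genotype matrix
    is supplied — the two are subset in lockstep.
    """
    keep = np.ones(len(table), dtype=bool)
    if min_r2 > 0:
        keep &= np.isnan(table.r2) | (table.r2 > min_r2)
    if min_maf > 0:
        af = table.maf
        folded = np.minimum(af, 1.0 - af)
        keep &= np.isnan(af) | (folded > min_maf)
    n_absent = int((np.isnan(table.r2) | np.isnan(table.maf)).sum())
    if n_absent:
        logger.info("%d variants lack R2/AF annotations and pass by policy", n_absent)
    idx = np.flatnonzero(keep)
    out_table = table.subset(idx)
    if genotypes is None:
        return out_table
    return out_table, genotypes.subset_variants(idx)
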