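"""Self-contained toy inputs: genome, donor VCF, region BEDs, barcode whitelist.

Everything downstream (simulation, pileup, consistency) is testable against
these programmatically generated fixtures; nothing is downloaded. Scale
defaults — 1 chromosome x 2 Mb, 5,000 SNPs, 30 gene bodies, 80 peaks — give
each simulated droplet tens of SNP-overlapping reads at default depths while
keeping whole-pipeline runs at seconds scale.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from ._genome import BASES, GenomeIndex

MIN_CHROM_LENGTH = 10_000  # must exceed read length + max ATAC insert with margin

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=ambimux
{contigs}
##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation R-squared">
##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""

_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


@dataclass(frozen=True)
class ToyReference:
    """Paths of a generated toy input set (plus the in-memory genotype truth)."""

    genome_path: Path
    vcf_path: Path
    rna_regions_path: Path
    atac_regions_path: Path
    whitelist_path: Path
    seed: int
    donor_ids: list[str]
    dosages: np.ndarray  # K x V alt-allele dosage, -1 = missing


def make_toy_genome(
    out_path: str | Path,
    n_chroms: int = 1,
    chrom_length: int = 2_000_000,
    gc_content: float = 0.41,
    seed: int = 0,
) -> Path:
    """Write a random FASTA of ``n_chroms`` chromosomes named chr1..chrN.

    Base composition is i.i.d. with the given GC fraction; deterministic for
    a fixed seed (byte-identical output).
    """
    if n_chroms < 1:
        raise ValueError("n_chroms must be >= 1")
    if chrom_length < MIN_CHROM_LENGTH:
        raise ValueError(
            f"chrom_length {chrom_length} < minimum {MIN_CHROM_LENGTH} "
            "(reads plus maximum insert must fit)"
        )
    if not 0.0 < gc_content < 1.0:
        raise ValueError("gc_content must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p_at = (1.0 - gc_content) / 2.0
    p_gc = gc_content / 2.0
    out_path = Path(out_path)
    with open(out_path, "w") as fh:
        for ci in range(n_chroms):
            codes = rng.choice(4, size=chrom_length, p=[p_at, p_gc, p_gc, p_at])
            seq = BASES[codes].tobytes().decode()
            fh.write(f">chr{ci + 1}\n")
            for i in range(0, chrom_length, 60):
                fh.write(seq[i : i + 60])
                fh.write("\n")
    pysam.faidx(str(out_path))
    return out_path


def make_toy_vcf(
    genome_path: str | Path,
    out_path: str | Path,
    n_variants: int = 5_000,
    n_donors: int = 4,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    seed: int = 0,
    missing_rate: float = 0.0,
    require_informative: bool = True,
    r2_low: float = 0.6,
    r2_high: float = 1.0,
    max_retries: int = 200,
) -> tuple[Path, list[str], np.ndarray]:
    """Write a biallelic-SNP VCF with per-donor Hardy-Weinberg genotypes.

    Each variant draws an allele frequency uniformly in [maf_low, maf_high]
    and each donor an independent dosage ~ Binomial(2, maf). With
    ``require_informative`` (and >= 2 donors) genotypes are resampled, up to
    ``max_retries`` times per variant, until at least one donor pair differs,
    so every site can in principle discriminate donors; disable it to get the
    unconditional Hardy-Weinberg law. INFO carries R2 (simulating imputation
    quality, uniform in [r2_low, r2_high]) and AF so downstream variant
    filters are exercisable.

    Returns (path, donor_ids, K x V dosage matrix) — the in-memory truth that
    parsing the file must reproduce exactly.
    """
    if n_donors < 1:
        raise ValueError("n_donors must be >= 1")
    if not 0.0 < maf_low <= maf_high <= 0.5:
        raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
    rng = np.random.default_rng(seed)
    genome = GenomeIndex.from_fasta(str(genome_path))
    if n_variants > genome.total_length // 2:
        raise ValueError(
            f"cannot place {n_variants} distinct SNPs on a "
            f"{genome.total_length} bp genome without collisions"
        )
    gpos = rng.choice(genome.total_length, size=n_variants, replace=False)
    gpos.sort()
    ref_codes = genome.seq[gpos]
    # alt = ref + shift mod 4, shift in {1,2,3}
    alt_codes = (ref_codes + rng.integers(1, 4, size=n_variants)) % 4

    maf = rng.uniform(maf_low, maf_high, size=n_variants)
    dosages = rng.binomial(2, maf[None, :], size=(n_donors, n_variants)).astype(np.int8)
    if require_informative and n_donors >= 2:
        for v in np.flatnonzero(np.ptp(dosages, axis=0) == 0):
            for _ in range(max_retries):
                cand = rng.binomial(2, maf[v], size=n_donors).astype(np.int8)
                if np.ptp(cand) > 0:
                    dosages[:, v] = cand
                    break
            else:
                raise RuntimeError(
                    f"could not draw discriminating genotypes at variant {v} "
                    f"(maf={maf[v]:.3f}) within {max_retries} retries"
                )
    if missing_rate > 0:
        miss = rng.random((n_donors, n_variants)) < missing_rate
        dosages[miss] = -1

    r2 = rng.uniform(r2_low, r2_high, size=n_variants)
    donor_ids = [f"donor{k}" for k in range(n_donors)]
    ci, pos0 = genome.to_local(gpos)

    out_path = Path(out_path)
    contigs = "\n".join(
        f"##contig=<ID={c},length={genome.lengths[i]}>"
        for i, c in enumerate(genome.chroms)
    )
    opener = gzip.open if str(out_path).endswith(".gz") else open
    with opener(out_path, "wt") as fh:
        fh.write(_VCF_HEADER.format(contigs=contigs, samples="\t".join(donor_ids)))
        for v in range(n_variants):
            gts = "\t".join(_GT_STRING[int(d)] for d in dosages[:, v])
            fh.write(
                f"{genome.chroms[ci[v]]}\t{pos0[v] + 1}\t.\t"
                f"{chr(BASES[ref_codes[v]])}\t{chr(BASES[alt_codes[v]])}\t.\tPASS\t"
                f"R2={r2[v]:.4f};AF={maf[v]:.4f}\tGT\t{gts}\n"
            )
    return out_path, donor_ids, dosages


def make_regions(
    genome_path: str | Path,
    rna_out: str | Path,
    atac_out: str | Path,
    n_rna_regions: int = 30,
    n_atac_regions: int = 80,
    mean_length: int = 5_000,
    seed: int = 0,
    rna_mean_length: int | None = 8_000,
    atac_mean_length: int | None = 5_000,
    max_retries: int = 2_000,
) -> tuple[Path, Path]:
    """Write two BED3 files of non-overlapping intervals: gene bodies (RNA
    informative regions) and peaks (ATAC informative regions).

    Lengths are uniform in [0.5, 1.5] x mean; intervals within one file never
    overlap (overlap across files is allowed and realistic: peaks sit inside
    gene bodies). Total length must stay below 80% of the genome.
    """
    rng = np.random.default_rng(seed)
    genome = GenomeIndex.from_fasta(str(genome_path))
    specs = [
        (Path(rna_out), n_rna_regions, rna_mean_length or mean_length),
        (Path(atac_out), n_atac_regions, atac_mean_length or mean_length),
    ]
    budget = sum(n * 1.5 * m for _, n, m in specs)
    if budget >= 0.8 * genome.total_length:
        raise ValueError(
            f"requested regions (up to {budget:.0f} bp) exceed 80% of the "
            f"{genome.total_length} bp genome"
        )
    for out, n_regions, mean in specs:
        placed: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(genome.chroms))}
        rows = []
        for _ in range(n_regions):
            for attempt in range(max_retries):
                length = int(rng.integers(mean // 2, mean + mean // 2 + 1))
                ci = int(rng.choice(len(genome.chroms), p=genome.lengths / genome.total_length))
                if genome.lengths[ci] <= length:
                    continue
                start = int(rng.integers(0, genome.lengths[ci] - length))
                end = start + length
                if all(end <= s or start >= e for s, e in placed[ci]):
                    placed[ci].append((start, end))
                    rows.append((genome.chroms[ci], start, end))
                    break
            else:
                raise RuntimeError(
                    f"could not place {n_regions} non-overlapping regions "
                    f"(mean {mean} bp) within {max_retries} retries"
                )
        rows.sort(key=lambda r: (r[0], r[1]))
        with open(out, "w") as fh:
            for chrom, s, e in rows:
                fh.write(f"{chrom}\t{s}\t{e}\n")
    return specs[0][0], specs[1][0]


def make_barcodes(
    n: int,
    length: int = 16,
    min_hamming: int = 3,
    seed: int = 0,
    max_retries: int = 10_000,
) -> list[str]:
    """Random ACGT barcodes, pairwise Hamming distance >= ``min_hamming``.

    Mirrors 10x-style whitelist separability so pileup tests cannot collide
    barcodes by accident.
    """
    rng = np.random.default_rng(seed)
    accepted = np.empty((n, length), dtype=np.uint8)
    count = 0
    rejects = 0
    while count < n:
        cand = rng.integers(0, 4, size=length).astype(np.uint8)
        if count == 0 or (accepted[:count] != cand).sum(axis=1).min() >= min_hamming:
            accepted[count] = cand
            count += 1
        else:
            rejects += 1
            if rejects > max_retries:
                raise RuntimeError(
                    f"could not find {n} barcodes at Hamming >= {min_hamming}"
                )
    return [BASES[row].tobytes().decode() for row in accepted]


def make_toy_reference(
    out_dir: str | Path,
    n_chroms: int = 1,
    chrom_length: int = 2_000_000,
    n_variants: int = 5_000,
    n_donors: int = 4,
    n_barcodes: int = 12_000,
    n_rna_regions: int = 30,
    n_atac_regions: int = 80,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    seed: int = 0,
    missing_rate: float = 0.0,
    rna_fraction: float = 0.12,
    atac_fraction: float = 0.20,
) -> ToyReference:
    """Generate a complete toy input set under ``out_dir``.

    Region mean lengths scale with the genome so that gene bodies cover
    ~``rna_fraction`` and peaks ~``atac_fraction`` of it regardless of toy
    size (peaks cover more of the genome than gene bodies, which is what
    makes ATAC SNP pools wider than RNA ones). At the default 2 Mb this
    gives 30 x ~8 kb gene bodies and 80 x ~5 kb peaks.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sub = np.random.SeedSequence(seed).generate_state(4) % (2**31)
    genome = make_toy_genome(
        out / "genome.fa", n_chroms, chrom_length, seed=int(sub[0])
    )
    vcf, donor_ids, dosages = make_toy_vcf(
        genome, out / "donors.vcf", n_variants, n_donors,
        maf_low=maf_low, maf_high=maf_high, seed=int(sub[1]),
        missing_rate=missing_rate,
    )
    total = n_chroms * chrom_length
    rna_bed, atac_bed = make_regions(
        genome, out / "genes.bed", out / "peaks.bed",
        n_rna_regions, n_atac_regions, seed=int(sub[2]),
        rna_mean_length=max(200, int(rna_fraction * total / n_rna_regions)),
        atac_mean_length=max(200, int(atac_fraction * total / n_atac_regions)),
    )
    barcodes = make_barcodes(n_barcodes, seed=int(sub[3]))
    wl = out / "whitelist.txt"
    wl.write_text("\n".join(barcodes) + "\n")
    return ToyReference(
        genome_path=genome, vcf_path=vcf, rna_regions_path=rna_bed,
        atac_regions_path=atac_bed, whitelist_path=wl, seed=seed,
        donor_ids=donor_ids, dosages=dosages,
    )
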