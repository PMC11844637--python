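"""Read-level simulation of a multiplexed joint snRNA/snATAC experiment.

Given sampled droplets, a genome, donor genotypes and informative-region
annotations (gene bodies for RNA, peaks for ATAC), this module emits FASTQ
and truth-tagged, coordinate-sorted BAM files per modality together with
exact ground truth (per-droplet native/ambient molecule counts and the
allele observed at every SNP a read covers).

The generative model per read (RNA) or fragment (ATAC):

1. ambient status ~ Bernoulli(droplet ambient fraction);
2. locus — native molecules start uniformly over the informative-region
   bases of their modality; ambient molecules start inside informative
   regions with probability ``ambient_informative_weight`` and uniformly
   over the whole genome otherwise (ambient material is enriched outside
   genes and peaks);
3. source donor — native: the droplet's donor (doublets split by their mix
   fraction); ambient: a donor drawn from the pool-level ambient weights.
   One source donor per molecule: every SNP the molecule covers shares it;
4. alleles — at each covered SNP, alt ~ Bernoulli(dosage/2) of the source
   donor (hom-ref -> ref, het -> fair coin, hom-alt -> alt);
5. sequencing error — every base substituted independently with probability
   ``seq_error_rate``, uniformly over the three other bases. Ground truth
   records the allele *before* error, so an error-free run is an exact
   oracle for the pileup stage.

BAMs are written directly at the true loci (MAPQ 60, CB tag, UB for RNA) so
no aligner is needed; FASTQs follow 10x layout (RNA R1 = barcode+UMI, R2 =
cDNA; ATAC R1/R3 = genomic pair, R2 = barcode).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from scipy import sparse

from ._genome import BASES, GenomeIndex, RegionSet, revcomp_codes
from .droplet_sampler import DropletSpec
from .genotype_io import MISSING, GenotypeMatrix, VariantTable

logger = logging.getLogger(__name__)

_QUAL_CHAR = "F"  # constant Q37; the error model is the only error source


@dataclass
class SimParams:
    """Read-level simulation knobs (defaults follow 10x multiome geometry)."""

    rna_read_length: int = 91
    atac_read_length: int = 50
    umi_length: int = 12
    barcode_length: int = 16
    seq_error_rate: float = 0.001
    ambient_informative_weight: float = 0.25  # share of ambient reads from regions
    insert_mean: float = 180.0
    insert_sd: float = 40.0
    insert_min: int = 60
    insert_max: int = 600
    ambient_donor_weights: list[float] | None = None  # default: uniform over donors
    mapq: int = 60

    def __post_init__(self) -> None:
        if not 0.0 <= self.seq_error_rate <= 0.1:
            raise ValueError("seq_error_rate must be in [0, 0.1]")
        if not 0.0 <= self.ambient_informative_weight <= 1.0:
            raise ValueError("ambient_informative_weight must be in [0, 1]")
        if self.insert_min < self.atac_read_length:
            raise ValueError("insert_min must be >= atac_read_length")
        if self.ambient_donor_weights is not None:
            if abs(sum(self.ambient_donor_weights) - 1.0) > 1e-9:
                raise ValueError("ambient_donor_weights must sum to 1")


@dataclass
class ModalityTruth:
    """Exact per-modality ground truth.

    ``obs_*`` arrays hold one row per counted allele observation — per read
    for RNA, per fragment for ATAC (a SNP under both mates counts once) —
    which is precisely what an error-free pileup must reproduce.
    """

    n_units: int                      # reads (RNA) / fragments (ATAC)
    native_per_droplet: np.ndarray    # molecules, length D
    ambient_per_droplet: np.ndarray
    R: sparse.csr_matrix              # D x V true reference-allele counts
    A: sparse.csr_matrix              # D x V true alternate-allele counts
    obs_droplet: np.ndarray
    obs_variant: np.ndarray
    obs_is_alt: np.ndarray
    obs_is_ambient: np.ndarray
    obs_source_donor: np.ndarray
    n_missing_gt: int = 0             # alleles emitted as ref for missing GT
    n_seq_errors: int = 0


@dataclass
class SimTruth:
    """Ground truth for a simulated experiment (both modalities)."""

    droplets: list[DropletSpec]
    rna: ModalityTruth | None = None
    atac: ModalityTruth | None = None

    @property
    def barcodes(self) -> list[str]:
        return [d.barcode for d in self.droplets]

    def frame(self) -> pd.DataFrame:
        from .droplet_sampler import droplets_to_frame

        df = droplets_to_frame(self.droplets)
        for name, mt in (("rna", self.rna), ("atac", self.atac)):
            if mt is not None:
                df[f"{name}_native"] = mt.native_per_droplet
                df[f"{name}_ambient"] = mt.ambient_per_droplet
        return df

    def assignment_frame(self, donor_ids: list[str]) -> pd.DataFrame:
        """Oracle demultiplexing calls: singlet -> its donor id, doublet ->
        "doublet", empty -> "unassigned"."""
        calls = []
        for d in self.droplets:
            if d.droplet_type == "singlet":
                calls.append(donor_ids[d.donors[0]])
            elif d.droplet_type == "doublet":
                calls.append("doublet")
            else:
                calls.append("unassigned")
        return pd.DataFrame({"barcode": self.barcodes, "call": calls})

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame().to_csv(path, sep="\t", index=False)
        return path

    def per_read_frame(self, modality: str) -> pd.DataFrame:
        mt = {"rna": self.rna, "atac": self.atac}[modality]
        return pd.DataFrame(
            {
                "droplet": mt.obs_droplet,
                "variant": mt.obs_variant,
                "allele": np.where(mt.obs_is_alt, "alt", "ref"),
                "is_ambient": mt.obs_is_ambient,
                "source_donor": mt.obs_source_donor,
            }
        )


@dataclass
class SimResult:
    out_dir: Path
    truth: SimTruth
    truth_path: Path
    bam_paths: dict = field(default_factory=dict)
    fastq_paths: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# scalar building blocks (the vectorised pipeline below mirrors these)
# ---------------------------------------------------------------------------

def sample_read_locus(
    is_ambient: bool,
    regions: RegionSet,
    genome: GenomeIndex,
    rng: np.random.Generator,
    informative_weight: float = 0.25,
    span: int = 91,
) -> tuple[str, int, str]:
    """One read locus: native -> uniform over informative bases; ambient ->
    informative with probability ``informative_weight``, else genome-uniform.
    Returns (chrom, 0-based start, strand); the read always fits its
    chromosome."""
    if is_ambient and rng.random() >= informative_weight:
        gpos = int(rng.integers(0, genome.total_length))
    else:
        gpos = int(regions.sample_positions(1, rng)[0])
    gpos = int(genome.clamp_span(np.array([gpos]), span)[0])
    ci, pos = genome.to_local(np.array([gpos]))
    strand = "-" if rng.random() < 0.5 else "+"
    return genome.chroms[int(ci[0])], int(pos[0]), strand


def assign_allele(
    droplet: DropletSpec,
    is_ambient: bool,
    variant: int,
    genotypes: GenotypeMatrix,
    rng: np.random.Generator,
    ambient_donor_weights: np.ndarray | None = None,
) -> tuple[str, int]:
    """Allele for one read at one SNP; returns ("ref"|"alt", source donor).

    Native reads draw from the droplet's donor (doublets pick donor 1 with
    probability ``doublet_mix`` first); ambient reads first draw a pool donor
    from the ambient weights. Missing genotype emits ref.
    """
    k = genotypes.n_donors
    if is_ambient:
        w = (
            np.full(k, 1.0 / k)
            if ambient_donor_weights is None
            else np.asarray(ambient_donor_weights)
        )
        src = int(rng.choice(k, p=w))
    elif droplet.droplet_type == "doublet":
        src = droplet.donors[0] if rng.random() < droplet.doublet_mix else droplet.donors[1]
    else:
        src = droplet.donors[0]
    dos = int(genotypes.dosages[src, variant])
    if dos == MISSING:
        return "ref", src
    return ("alt" if rng.random() < dos / 2.0 else "ref"), src


def apply_sequencing_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    """Substitute each base independently with probability ``error_rate``,
    uniformly over the three other bases (the substituted base always
    differs from the original)."""
    if not 0.0 <= error_rate <= 0.1:
        raise ValueError("error_rate must be in [0, 0.1]")
    from ._genome import encode_bases

    codes = encode_bases(seq).copy()
    _substitute(codes.reshape(1, -1), error_rate, rng)
    return BASES[codes].tobytes().decode()


# ---------------------------------------------------------------------------
# vectorised internals
# ---------------------------------------------------------------------------

def _substitute(mat: np.ndarray, eps: float, rng: np.random.Generator) -> int:
    if eps <= 0:
        return 0
    mask = rng.random(mat.shape) < eps
    n = int(mask.sum())
    if n:
        mat[mask] = (mat[mask] + rng.integers(1, 4, size=n).astype(np.uint8)) % 4
    return n


def _sample_loci(
    ambient: np.ndarray,
    regions: RegionSet,
    genome: GenomeIndex,
    beta: float,
    rng: np.random.Generator,
) -> np.ndarray:
    n = len(ambient)
    pos = np.empty(n, dtype=np.int64)
    native = ~ambient
    pos[native] = regions.sample_positions(int(native.sum()), rng)
    n_amb = int(ambient.sum())
    if n_amb:
        informative = rng.random(n_amb) < beta
        apos = np.empty(n_amb, dtype=np.int64)
        apos[informative] = regions.sample_positions(int(informative.sum()), rng)
        apos[~informative] = rng.integers(
            0, genome.total_length, size=int((~informative).sum())
        )
        pos[ambient] = apos
    return pos


def _sample_sources(
    didx: np.ndarray,
    ambient: np.ndarray,
    donor1: np.ndarray,
    donor2: np.ndarray,
    mix: np.ndarray,
    ambient_cum: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    src = np.full(len(didx), -1, dtype=np.int64)
    native = ~ambient
    nd = didx[native]
    first = rng.random(int(native.sum())) < mix[nd]
    src[native] = np.where(first, donor1[nd], donor2[nd])
    n_amb = int(ambient.sum())
    if n_amb:
        src[ambient] = np.searchsorted(ambient_cum, rng.random(n_amb), side="right")
    return src


def _overlap_pairs(
    vpos: np.ndarray, starts: np.ndarray, span: np.ndarray | int
) -> tuple[np.ndarray, np.ndarray]:
    """All (unit index, sorted-variant index) pairs where a SNP falls in
    [start, start + span)."""
    lo = np.searchsorted(vpos, starts)
    hi = np.searchsorted(vpos, starts + span)
    cnt = hi - lo
    total = int(cnt.sum())
    ridx = np.repeat(np.arange(len(starts)), cnt)
    offs = np.arange(total) - np.repeat(np.cumsum(cnt) - cnt, cnt)
    return ridx, np.repeat(lo, cnt) + offs


def _draw_alleles(
    src: np.ndarray, vidx: np.ndarray, dosages: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    dos = dosages[src, vidx].astype(np.int64)
    missing = dos == MISSING
    is_alt = rng.random(len(dos)) < np.where(missing, 0, dos) / 2.0
    is_alt[missing] = False
    return is_alt, int(missing.sum())


def _umi_strings(indices: np.ndarray, length: int) -> list[str]:
    """Unique ACGT UMIs: base-4 encoding of the global read index."""
    shifts = 2 * np.arange(length, dtype=np.int64)
    codes = ((indices[:, None] >> shifts[None, :]) & 3).astype(np.uint8)
    ascii_ = BASES[codes]
    flat = ascii_.tobytes()
    return [flat[i * length : (i + 1) * length].decode() for i in range(len(indices))]


def _bam_header(genome: GenomeIndex) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": c, "LN": int(genome.lengths[i])}
                for i, c in enumerate(genome.chroms)
            ],
            "PG": [{"ID": "ambimux", "PN": "ambimux"}],
        }
    )


def _truth_matrices(
    obs_droplet: np.ndarray,
    obs_variant: np.ndarray,
    obs_is_alt: np.ndarray,
    n_droplets: int,
    n_variants: int,
) -> tuple[sparse.csr_matrix, sparse.csr_matrix]:
    def build(mask: np.ndarray) -> sparse.csr_matrix:
        return sparse.coo_matrix(
            (
                np.ones(int(mask.sum()), dtype=np.int64),
                (obs_droplet[mask], obs_variant[mask]),
            ),
            shape=(n_droplets, n_variants),
        ).tocsr()

    return build(~obs_is_alt), build(obs_is_alt)


class _FastqWriter:
    """Deterministic gzip FASTQ (fixed mtime so equal content means equal bytes)."""

    def __init__(self, path: Path) -> None:
        self.fh = gzip.GzipFile(filename="", mode="wb", fileobj=open(path, "wb"), mtime=0)

    def write(self, name: str, seq: str, qual: str) -> None:
        self.fh.write(f"@{name}\n{seq}\n+\n{qual}\n".encode())

    def close(self) -> None:
        fileobj = self.fh.fileobj
        self.fh.close()
        fileobj.close()


# ---------------------------------------------------------------------------
# per-modality pipelines
# ---------------------------------------------------------------------------

def _droplet_arrays(droplets: list[DropletSpec]):
    d1 = np.array([d.donors[0] if d.donors else -1 for d in droplets], dtype=np.int64)
    d2 = np.array(
        [d.donors[1] if len(d.donors) > 1 else (d.donors[0] if d.donors else -1) for d in droplets],
        dtype=np.int64,
    )
    mix = np.array([d.doublet_mix for d in droplets])
    af = np.array([d.ambient_fraction for d in droplets])
    return d1, d2, mix, af


def _simulate_rna(
    droplets, genome, regions, vpos, ref_codes, alt_codes, dosages,
    params: SimParams, rng, out_dir: Path, emit_fastq: bool,
) -> tuple[ModalityTruth, dict, dict]:
    L = params.rna_read_length
    D = len(droplets)
    d1, d2, mix, af = _droplet_arrays(droplets)
    depths = np.array([d.rna_depth for d in droplets], dtype=np.int64)
    n = int(depths.sum())
    didx = np.repeat(np.arange(D), depths)
    ambient = rng.random(n) < af[didx]
    k = dosages.shape[0]
    w = (
        np.full(k, 1.0 / k)
        if params.ambient_donor_weights is None
        else np.asarray(params.ambient_donor_weights)
    )
    src = _sample_sources(didx, ambient, d1, d2, mix, np.cumsum(w), rng)
    start = genome.clamp_span(
        _sample_loci(ambient, regions, genome, params.ambient_informative_weight, rng), L
    )
    rev = rng.random(n) < 0.5

    order = np.argsort(start, kind="stable")
    didx, ambient, src, start, rev = (
        didx[order], ambient[order], src[order], start[order], rev[order]
    )

    ridx, vidx = _overlap_pairs(vpos, start, L)
    is_alt, n_missing = _draw_alleles(src[ridx], vidx, dosages, rng)

    mat = genome.seq[start[:, None] + np.arange(L)]
    mat[ridx, vpos[vidx] - start[ridx]] = np.where(
        is_alt, alt_codes[vidx], ref_codes[vidx]
    )
    n_err = _substitute(mat, params.seq_error_rate, rng)

    truth = ModalityTruth(
        n_units=n,
        native_per_droplet=np.bincount(didx[~ambient], minlength=D),
        ambient_per_droplet=np.bincount(didx[ambient], minlength=D),
        R=None, A=None,
        obs_droplet=didx[ridx], obs_variant=vidx, obs_is_alt=is_alt,
        obs_is_ambient=ambient[ridx], obs_source_donor=src[ridx],
        n_missing_gt=n_missing, n_seq_errors=n_err,
    )
    truth.R, truth.A = _truth_matrices(didx[ridx], vidx, is_alt, D, len(vpos))

    # --- emit ---
    barcodes = [d.barcode for d in droplets]
    umis = _umi_strings(np.arange(n, dtype=np.int64), params.umi_length)
    ascii_mat = BASES[mat]
    ci, lpos = genome.to_local(start)
    header = _bam_header(genome)
    qual = pysam.qualitystring_to_array(_QUAL_CHAR * L)
    bam_path = out_dir / "rna.bam"
    with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bam:
        for i in range(n):
            a = pysam.AlignedSegment(header)
            a.query_name = f"rna{i:09d}"
            a.flag = 16 if rev[i] else 0
            a.reference_id = int(ci[i])
            a.reference_start = int(lpos[i])
            a.mapping_quality = params.mapq
            a.cigarstring = f"{L}M"
            a.query_sequence = ascii_mat[i].tobytes().decode()
            a.query_qualities = qual
            a.set_tag("CB", barcodes[didx[i]])
            a.set_tag("UB", umis[i])
            bam.write(a)
    pysam.index(str(bam_path))

    fastqs: dict = {}
    if emit_fastq:
        r1 = _FastqWriter(out_dir / "rna_R1.fastq.gz")
        r2 = _FastqWriter(out_dir / "rna_R2.fastq.gz")
        q1 = _QUAL_CHAR * (params.barcode_length + params.umi_length)
        q2 = _QUAL_CHAR * L
        for i in range(n):
            name = f"rna{i:09d}"
            r1.write(name, barcodes[didx[i]] + umis[i], q1)
            seq = (
                BASES[revcomp_codes(mat[i])].tobytes().decode()
                if rev[i]
                else ascii_mat[i].tobytes().decode()
            )
            r2.write(name, seq, q2)
        r1.close()
        r2.close()
        fastqs = {"R1": out_dir / "rna_R1.fastq.gz", "R2": out_dir / "rna_R2.fastq.gz"}
    return truth, {"rna": bam_path}, fastqs


def _simulate_atac(
    droplets, genome, regions, vpos, ref_codes, alt_codes, dosages,
    params: SimParams, rng, out_dir: Path, emit_fastq: bool,
) -> tuple[ModalityTruth, dict, dict]:
    L = params.atac_read_length
    D = len(droplets)
    d1, d2, mix, af = _droplet_arrays(droplets)
    # ATAC depth counts fragments (read pairs) — the unit sequencing depth is
    # quoted in for droplet ATAC; each fragment emits two 50 bp mates.
    nfrag = np.array([d.atac_depth for d in droplets], dtype=np.int64)
    f = int(nfrag.sum())
    didx = np.repeat(np.arange(D), nfrag)
    ambient = rng.random(f) < af[didx]
    k = dosages.shape[0]
    w = (
        np.full(k, 1.0 / k)
        if params.ambient_donor_weights is None
        else np.asarray(params.ambient_donor_weights)
    )
    src = _sample_sources(didx, ambient, d1, d2, mix, np.cumsum(w), rng)
    insert = np.clip(
        np.rint(rng.normal(params.insert_mean, params.insert_sd, size=f)),
        params.insert_min, params.insert_max,
    ).astype(np.int64)
    s = genome.clamp_span(
        _sample_loci(ambient, regions, genome, params.ambient_informative_weight, rng),
        insert,
    )
    rev_frag = rng.random(f) < 0.5
    pos1, pos2 = s, s + insert - L

    # fragment x SNP pairs, kept only where a mate actually covers the SNP
    fidx, vidx = _overlap_pairs(vpos, s, insert)
    covered = (vpos[vidx] < pos1[fidx] + L) | (vpos[vidx] >= pos2[fidx])
    fidx, vidx = fidx[covered], vidx[covered]
    is_alt, n_missing = _draw_alleles(src[fidx], vidx, dosages, rng)

    truth = ModalityTruth(
        n_units=f,
        native_per_droplet=np.bincount(didx[~ambient], minlength=D),
        ambient_per_droplet=np.bincount(didx[ambient], minlength=D),
        R=None, A=None,
        obs_droplet=didx[fidx], obs_variant=vidx, obs_is_alt=is_alt,
        obs_is_ambient=ambient[fidx], obs_source_donor=src[fidx],
        n_missing_gt=n_missing,
    )
    truth.R, truth.A = _truth_matrices(didx[fidx], vidx, is_alt, D, len(vpos))

    # --- per-record (2 mates per fragment) layout, fragment-major ---
    rec_start = np.empty(2 * f, dtype=np.int64)
    rec_start[0::2], rec_start[1::2] = pos1, pos2
    rec_rev = np.zeros(2 * f, dtype=bool)
    rec_rev[1::2] = True                       # right mate always reverse
    rec_read1 = np.empty(2 * f, dtype=bool)
    rec_read1[0::2], rec_read1[1::2] = ~rev_frag, rev_frag

    mat = genome.seq[rec_start[:, None] + np.arange(L)]
    # inject each kept fragment allele into whichever mate(s) cover it
    allele_code = np.where(is_alt, alt_codes[vidx], ref_codes[vidx])
    for mate, recsel in ((0, 2 * fidx), (1, 2 * fidx + 1)):
        under = (vpos[vidx] >= rec_start[recsel]) & (vpos[vidx] < rec_start[recsel] + L)
        mat[recsel[under], vpos[vidx[under]] - rec_start[recsel[under]]] = allele_code[under]
    truth.n_seq_errors = _substitute(mat, params.seq_error_rate, rng)
    ascii_mat = BASES[mat]

    barcodes = [d.barcode for d in droplets]
    header = _bam_header(genome)
    qual = pysam.qualitystring_to_array(_QUAL_CHAR * L)
    ci, lpos = genome.to_local(rec_start)
    order = np.argsort(rec_start, kind="stable")
    bam_path = out_dir / "atac.bam"
    with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bam:
        for r in order:
            frag = r // 2
            left = r % 2 == 0
            a = pysam.AlignedSegment(header)
            a.query_name = f"atac{frag:09d}"
            flag = 1 | 2
            flag |= 16 if rec_rev[r] else 32
            flag |= 64 if rec_read1[r] else 128
            a.flag = flag
            a.reference_id = int(ci[r])
            a.reference_start = int(lpos[r])
            a.mapping_quality = params.mapq
            a.cigarstring = f"{L}M"
            a.query_sequence = ascii_mat[r].tobytes().decode()
            a.query_qualities = qual
            a.next_reference_id = int(ci[r])
            a.next_reference_start = int(lpos[r + 1] if left else lpos[r - 1])
            a.template_length = int(insert[frag]) * (1 if left else -1)
            a.set_tag("CB", barcodes[didx[frag]])
            bam.write(a)
    pysam.index(str(bam_path))

    fastqs: dict = {}
    if emit_fastq:
        r1w = _FastqWriter(out_dir / "atac_R1.fastq.gz")
        r2w = _FastqWriter(out_dir / "atac_R2.fastq.gz")
        r3w = _FastqWriter(out_dir / "atac_R3.fastq.gz")
        qg = _QUAL_CHAR * L
        qb = _QUAL_CHAR * params.barcode_length

        def as_sequenced(rec: int) -> str:
            if rec_rev[rec]:
                return BASES[revcomp_codes(mat[rec])].tobytes().decode()
            return ascii_mat[rec].tobytes().decode()

        for frag in range(f):
            name = f"atac{frag:09d}"
            read1_rec = 2 * frag + (1 if rev_frag[frag] else 0)
            read2_rec = 2 * frag + (0 if rev_frag[frag] else 1)
            r1w.write(name, as_sequenced(read1_rec), qg)
            r2w.write(name, barcodes[didx[frag]], qb)
            r3w.write(name, as_sequenced(read2_rec), qg)
        for wtr in (r1w, r2w, r3w):
            wtr.close()
        fastqs = {
            "R1": out_dir / "atac_R1.fastq.gz",
            "R2": out_dir / "atac_R2.fastq.gz",
            "R3": out_dir / "atac_R3.fastq.gz",
        }
    return truth, {"atac": bam_path}, fastqs


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def simulate_experiment(
    droplets: list[DropletSpec],
    genome_path: str | Path,
    variants: VariantTable,
    genotypes: GenotypeMatrix,
    rna_regions_path: str | Path,
    atac_regions_path: str | Path,
    params: SimParams,
    out_dir: str | Path,
    seed: int = 0,
    modalities: tuple[str, ...] = ("rna", "atac"),
    emit_fastq: bool = True,
    per_read_truth: bool = False,
) -> SimResult:
    """Run the full read-level simulation and write FASTQ/BAM/truth files.

    Deterministic for a fixed (droplets, inputs, params, seed); each modality
    consumes an independent seed stream, so simulating RNA alone gives the
    same RNA output as simulating both.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome = GenomeIndex.from_fasta(str(genome_path))

    unknown = sorted(set(variants.chrom) - set(genome.chroms))
    if unknown:
        raise ValueError(
            f"variant contigs {unknown} absent from genome contigs {genome.chroms}"
        )
    off = {c: genome.offsets[i] for i, c in enumerate(genome.chroms)}
    vglobal = np.array(
        [off[c] + p - 1 for c, p in zip(variants.chrom, variants.pos)], dtype=np.int64
    )
    vorder = np.argsort(vglobal, kind="stable")
    vpos = vglobal[vorder]
    from ._genome import encode_bases

    ref_codes = encode_bases("".join(variants.ref))[vorder]
    alt_codes = encode_bases("".join(variants.alt))[vorder]

    truth = SimTruth(droplets=droplets)
    result = SimResult(out_dir=out_dir, truth=truth, truth_path=out_dir / "truth.tsv")
    runners = {"rna": (_simulate_rna, 0), "atac": (_simulate_atac, 1)}
    for modality in modalities:
        runner, stream = runners[modality]
        regions = RegionSet.from_bed(
            str(rna_regions_path if modality == "rna" else atac_regions_path), genome
        )
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))
        mt, bams, fastqs = runner(
            droplets, genome, regions, vpos, ref_codes, alt_codes,
            genotypes.dosages, params, rng, out_dir, emit_fastq,
        )
        # map sorted-variant indices back to VariantTable order
        mt.obs_variant = vorder[mt.obs_variant]
        mt.R = mt.R[:, np.argsort(vorder)] if not np.array_equal(vorder, np.arange(len(vorder))) else mt.R
        mt.A = mt.A[:, np.argsort(vorder)] if not np.array_equal(vorder, np.arange(len(vorder))) else mt.A
        setattr(truth, modality, mt)
        result.bam_paths.update(bams)
        result.fastq_paths.update({f"{modality}_{k}": v for k, v in fastqs.items()})
        if per_read_truth:
            truth.per_read_frame(modality).to_csv(
                out_dir / f"{modality}_per_read_truth.tsv", sep="\t", index=False
            )
    truth.write(result.truth_path)
    return result
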