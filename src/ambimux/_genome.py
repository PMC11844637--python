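"""Shared genome and interval plumbing.

The simulator works in a single *global* coordinate space: chromosomes are
conceptually concatenated in FASTA order, so every locus is one integer and
interval arithmetic vectorises. Conversions to (chrom, pos) happen only at
I/O boundaries (BAM/VCF/BED are per-chromosome, VCF 1-based, BED half-open
0-based).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

# uint8 base codes 0..3 <-> ACGT; 255 marks non-ACGT input
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i

_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G in code space


def encode_bases(seq: str | bytes) -> np.ndarray:
    """ACGT string -> uint8 codes 0..3."""
    raw = np.frombuffer(seq.encode() if isinstance(seq, str) else seq, dtype=np.uint8)
    return _CODE[raw]


def decode_bases(codes: np.ndarray) -> str:
    return BASES[codes].tobytes().decode()


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes][..., ::-1]


@dataclass
class GenomeIndex:
    """Concatenated in-memory genome with global<->(chrom,pos) mapping."""

    chroms: list[str]
    lengths: np.ndarray          # int64, per chrom
    seq: np.ndarray              # uint8 codes, concatenated
    offsets: np.ndarray = field(init=False)  # cumulative start of each chrom

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        self.offsets = np.concatenate([[0], np.cumsum(self.lengths)])

    @classmethod
    def from_fasta(cls, path: str) -> "GenomeIndex":
        with pysam.FastaFile(str(path)) as fa:
            chroms = list(fa.references)
            lengths = np.array([fa.get_reference_length(c) for c in chroms])
            seq = np.concatenate([encode_bases(fa.fetch(c)) for c in chroms])
        return cls(chroms=chroms, lengths=lengths, seq=seq)

    @property
    def total_length(self) -> int:
        return int(self.offsets[-1])

    def chrom_of(self, gpos: np.ndarray) -> np.ndarray:
        """Global positions -> chromosome indices."""
        return np.searchsorted(self.offsets, np.asarray(gpos), side="right") - 1

    def to_global(self, chrom: str, pos: np.ndarray | int) -> np.ndarray | int:
        return self.offsets[self.chroms.index(chrom)] + pos

    def to_local(self, gpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ci = self.chrom_of(gpos)
        return ci, np.asarray(gpos) - self.offsets[ci]

    def clamp_span(self, gstart: np.ndarray, span: np.ndarray | int) -> np.ndarray:
        """Shift starts so [start, start+span) stays inside its chromosome."""
        gstart = np.asarray(gstart, dtype=np.int64)
        ci = self.chrom_of(gstart)
        lo = self.offsets[ci]
        hi = self.offsets[ci + 1] - span
        return np.clip(gstart, lo, hi)


@dataclass
class RegionSet:
    """Half-open intervals in global coordinates, with length-weighted sampling."""

    start: np.ndarray   # int64 global starts
    length: np.ndarray  # int64 lengths

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=np.int64)
        self.length = np.asarray(self.length, dtype=np.int64)
        self._cum = np.cumsum(self.length)

    @classmethod
    def from_bed(cls, path: str, genome: GenomeIndex) -> "RegionSet":
        bed = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1, 2],
            names=["chrom", "start", "end"], comment="#",
        )
        if bed.empty:
            raise ValueError(f"region file {path} is empty")
        off = np.array([genome.offsets[genome.chroms.index(c)] for c in bed["chrom"]])
        start = off + bed["start"].to_numpy(np.int64)
        return cls(start=start, length=(bed["end"] - bed["start"]).to_numpy(np.int64))

    @property
    def total_bases(self) -> int:
        return int(self._cum[-1])

    def sample_positions(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n global positions uniform over the union of interval bases."""
        u = rng.integers(0, self.total_bases, size=n)
        idx = np.searchsorted(self._cum, u, side="right")
        prev = self._cum[idx] - self.length[idx]
        return self.start[idx] + (u - prev)

    def contains(self, gpos: np.ndarray) -> np.ndarray:
        """Membership of global positions in the interval union (intervals sorted)."""
        order = np.argsort(self.start)
        s, ln = self.start[order], self.length[order]
        i = np.searchsorted(s, gpos, side="right") - 1
        i = np.clip(i, 0, len(s) - 1)
        return (gpos >= s[i]) & (gpos < s[i] + ln[i])
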