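"""Shared domain types and small numeric helpers.

All coordinates are 0-based half-open in memory.  Conversion to the 1-based
inclusive conventions of GFF3/VCF/pileup/coords files happens only in the
readers and writers of :mod:`genopolish.pipeline_io`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "ValidationError",
    "PackingError",
    "ALPHABET",
    "BASES",
    "BASE_INDEX",
    "revcomp",
    "round_half_away",
    "percent",
    "ReferenceGenome",
    "GeneModel",
    "RepeatInterval",
    "GapRecord",
    "AlignmentRecord",
    "SiteCounts",
    "PileupTrack",
]

BASES = "ACGT"
ALPHABET = set("ACGTN")
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class PackingError(ValidationError):
    """Raised when requested features cannot fit into the requested sequence."""


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_away(x: float, digits: int = 0) -> float:
    """Round with ties going away from zero (the convention of printed reports)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, digits: int = 0) -> float:
    """``100 * numerator / denominator`` rounded half away from zero."""
    if denominator == 0:
        raise ValidationError("percent: zero denominator")
    return round_half_away(100.0 * numerator / denominator, digits)


# ---------------------------------------------------------------------------
# Sequence-level types
# ---------------------------------------------------------------------------


@dataclass
class ReferenceGenome:
    """A haploid genome: ordered map of chromosome id -> sequence.

    N runs mark assembly gaps.  Sequences are upper-case strings over
    {A,C,G,T,N}.
    """

    chromosomes: dict[str, str]

    def validate(self) -> None:
        seen: set[str] = set()
        for name, seq in self.chromosomes.items():
            if name in seen:
                raise ValidationError(f"duplicate chromosome id {name!r}")
            seen.add(name)
            if not seq:
                raise ValidationError(f"empty sequence for chromosome {name!r}")
            bad = set(seq) - ALPHABET
            if bad:
                raise ValidationError(
                    f"illegal characters {sorted(bad)} in chromosome {name!r}"
                )

    def length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def non_n_length(self) -> int:
        return sum(len(s) - s.count("N") for s in self.chromosomes.values())

    def copy(self) -> "ReferenceGenome":
        return ReferenceGenome(dict(self.chromosomes))


@dataclass
class GeneModel:
    """A protein-coding gene as an ordered list of CDS exon intervals.

    ``exons`` are 0-based half-open, sorted by genomic coordinate and
    non-overlapping.  For minus-strand genes the coding sequence is the
    reverse complement of the concatenated exons read in genomic order.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValidationError(f"gene {self.gene_id}: bad exon ({s},{e})")
            if s <= prev_end - 1 and prev_end > 0 and s < prev_end:
                raise ValidationError(f"gene {self.gene_id}: overlapping exons")
            if s < prev_end:
                raise ValidationError(f"gene {self.gene_id}: unsorted exons")
            prev_end = e

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def cds_sequence(self, genome: ReferenceGenome) -> str:
        seq = genome.chromosomes[self.chrom]
        cat = "".join(seq[s:e] for s, e in self.exons)
        return cat if self.strand == "+" else revcomp(cat)


@dataclass(frozen=True, order=True)
class RepeatInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValidationError(f"repeat interval ({self.start},{self.end}) invalid")


@dataclass(frozen=True, order=True)
class GapRecord:
    """A maximal N-run: genome[start:end] is all N, flanks are not N."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignmentRecord:
    """One local alignment block of a scaffold against the reference.

    Scaffold coordinates are always on the forward strand of the scaffold;
    ``strand`` says how the block maps onto the reference.
    """

    scaffold: str
    scf_start: int
    scf_end: int
    ref_chrom: str
    ref_start: int
    ref_end: int
    strand: str
    identity: float

    def __post_init__(self) -> None:
        if self.scf_start >= self.scf_end or self.ref_start >= self.ref_end:
            raise ValidationError(f"degenerate alignment block {self}")
        if self.strand not in "+-":
            raise ValidationError(f"bad strand {self.strand!r}")
        if not 0.0 <= self.identity <= 100.0:
            raise ValidationError(f"identity {self.identity} outside [0, 100]")

    @property
    def aligned_length(self) -> int:
        return self.scf_end - self.scf_start


# ---------------------------------------------------------------------------
# Pileup containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteCounts:
    """Per-site read support for one library at one reference position."""

    chrom: str
    pos: int
    counts: tuple[int, int, int, int]  # A, C, G, T
    ins_count: int
    ins_seqs: dict[str, int]
    del_count: int
    del_lens: dict[int, int]

    @property
    def depth(self) -> int:
        return sum(self.counts)


class PileupTrack:
    """Vectorised per-site base and indel counts for one sequencing library.

    ``base_counts[chrom]`` is an ``(L, 4)`` int array in A,C,G,T order;
    ``ins_count``/``del_count`` hold per-site indel-evidence read counts and
    the registries record which sequences / deletion lengths were seen.
    Depth at a site is the sum of its base counts.
    """

    def __init__(self, chromosome_lengths: dict[str, int]):
        self.base_counts: dict[str, np.ndarray] = {
            c: np.zeros((length, 4), dtype=np.int32)
            for c, length in chromosome_lengths.items()
        }
        self.ins_count: dict[str, np.ndarray] = {
            c: np.zeros(length, dtype=np.int32)
            for c, length in chromosome_lengths.items()
        }
        self.del_count: dict[str, np.ndarray] = {
            c: np.zeros(length, dtype=np.int32)
            for c, length in chromosome_lengths.items()
        }
        self.ins_seqs: dict[str, dict[int, Counter]] = {
            c: {} for c in chromosome_lengths
        }
        self.del_lens: dict[str, dict[int, Counter]] = {
            c: {} for c in chromosome_lengths
        }

    @property
    def chromosome_lengths(self) -> dict[str, int]:
        return {c: a.shape[0] for c, a in self.base_counts.items()}

    def depth(self, chrom: str) -> np.ndarray:
        return self.base_counts[chrom].sum(axis=1)

    def mean_depth(self, genome: ReferenceGenome) -> float:
        """Mean depth over all non-N reference positions (zeros included)."""
        total = 0.0
        n_sites = 0
        for chrom, seq in genome.chromosomes.items():
            mask = np.frombuffer(seq.encode(), dtype=np.uint8) != ord("N")
            total += float(self.depth(chrom)[mask].sum())
            n_sites += int(mask.sum())
        if n_sites == 0:
            raise ValidationError("genome has no non-N positions")
        return total / n_sites

    def site(self, chrom: str, pos: int) -> SiteCounts:
        return SiteCounts(
            chrom=chrom,
            pos=pos,
            counts=tuple(int(x) for x in self.base_counts[chrom][pos]),
            ins_count=int(self.ins_count[chrom][pos]),
            ins_seqs=dict(self.ins_seqs[chrom].get(pos, {})),
            del_count=int(self.del_count[chrom][pos]),
            del_lens=dict(self.del_lens[chrom].get(pos, {})),
        )


def sequence_mask(seq: str, char: str = "N") -> np.ndarray:
    """Boolean array, True where ``seq`` equals ``char``."""
    return np.frombuffer(seq.encode(), dtype=np.uint8) == ord(char)


def base_index_array(seq: str) -> np.ndarray:
    """Map a sequence to indices in A,C,G,T order; N maps to -1."""
    lut = np.full(256, -1, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
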