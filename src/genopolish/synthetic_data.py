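"""Seeded toy genomes with machine-readable ground truth.

This module builds everything the downstream stages consume, without any
external data: a small multi-chromosome haploid genome with compact gene
models, repeat intervals and N-gaps; a derived strain carrying injected
substitutions, indels and tandem duplications; simulated pileup tracks at a
configurable depth and error rate; and scaffold sets carrying injected
mis-joins with truth labels.  Every generator is a pure function of
``(config, seed)``.

The default parameters emulate, at reduced scale, a compact haploid algal
genome sequenced at high coverage: a few chromosomes totalling ~150 kb,
GC-rich sequence, dense single- or two-exon gene models (about one fifth of
genes carry an intron), a small repeat fraction, and paired-end libraries in
the 175-205x coverage range.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import (
    AlignmentRecord,
    BASES,
    GapRecord,
    GeneModel,
    PackingError,
    PileupTrack,
    ReferenceGenome,
    RepeatInterval,
    ValidationError,
    base_index_array,
    revcomp,
)

__all__ = [
    "GenomeConfig",
    "SyntheticGenome",
    "MutationSpec",
    "Substitution",
    "Insertion",
    "Deletion",
    "Duplication",
    "TruthSet",
    "MisjoinSpec",
    "MisjoinLabel",
    "FragmentedAssembly",
    "generate_genome",
    "mutate_strain",
    "apply_mutations",
    "simulate_pileup",
    "fragment_with_misjoins",
]

_STOP_CODONS = ("TAA", "TAG", "TGA")
_START_CODON = "ATG"


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeConfig:
    """Knobs of the toy genome.

    Defaults model a compact, GC-rich algal nuclear genome scaled down to
    150 kb over three chromosomes with ~60 genes, a 2% repeat fraction and a
    dozen assembly gaps.
    """

    chromosome_lengths: tuple[int, ...] = (60_000, 50_000, 40_000)
    n_genes: int = 60
    repeat_fraction: float = 0.02
    n_gaps: int = 12
    gc: float = 0.58
    intron_fraction: float = 0.19
    gap_length_range: tuple[int, int] = (60, 400)
    gene_cds_codons: tuple[int, int] = (100, 300)
    intron_length_range: tuple[int, int] = (60, 160)
    repeat_unit_length: int = 250
    gap_margin: int = 300  # min distance of a gap from chromosome ends / other features

    def validate(self) -> None:
        if not self.chromosome_lengths or any(l <= 0 for l in self.chromosome_lengths):
            raise ValidationError("chromosome lengths must be positive")
        if self.n_genes < 0 or self.n_gaps < 0:
            raise ValidationError("feature counts must be >= 0")
        if not 0.0 <= self.repeat_fraction < 1.0:
            raise ValidationError("repeat_fraction must be in [0, 1)")
        if not 0.0 < self.gc < 1.0:
            raise ValidationError("gc must be in (0, 1)")


@dataclass
class SyntheticGenome:
    """Output bundle of :func:`generate_genome`.

    ``genome`` is the gapped reference (gaps masked to N); ``truth_genome``
    retains the real sequence under every gap so that gap-closing stages can
    be scored against it.
    """

    genome: ReferenceGenome
    truth_genome: ReferenceGenome
    genes: list[GeneModel]
    repeats: list[RepeatInterval]
    gaps: list[GapRecord]


class _Occupancy:
    """Per-chromosome interval bookkeeping for rejection-sampled placement."""

    def __init__(self, lengths: dict[str, int]):
        self.lengths = lengths
        self.taken: dict[str, list[tuple[int, int]]] = {c: [] for c in lengths}

    def fits(self, chrom: str, start: int, end: int, margin: int = 0) -> bool:
        if start < 0 or end > self.lengths[chrom]:
            return False
        for s, e in self.taken[chrom]:
            if start - margin < e and s < end + margin:
                return False
        return True

    def claim(self, chrom: str, start: int, end: int) -> None:
        self.taken[chrom].append((start, end))


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=length, p=p)
    return "".join(BASES[i] for i in idx)


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons - 2) non-stop codons + stop codon."""
    codons = [_START_CODON]
    while len(codons) < n_codons - 1:
        c = "".join(BASES[i] for i in rng.integers(0, 4, size=3))
        if c not in _STOP_CODONS:
            codons.append(c)
    codons.append(_STOP_CODONS[rng.integers(0, 3)])
    return "".join(codons)


def _place(
    rng: np.random.Generator,
    occ: _Occupancy,
    length: int,
    margin: int,
    chrom_weights: dict[str, float],
    max_tries: int = 500,
) -> tuple[str, int]:
    chroms = list(chrom_weights)
    w = np.array([chrom_weights[c] for c in chroms], dtype=float)
    w /= w.sum()
    for _ in range(max_tries):
        chrom = chroms[rng.choice(len(chroms), p=w)]
        hi = occ.lengths[chrom] - length - margin
        if hi <= margin:
            continue
        start = int(rng.integers(margin, hi))
        if occ.fits(chrom, start, start + length, margin=margin):
            return chrom, start
    raise PackingError(
        f"could not place a feature of length {length}: requested features "
        "exceed the available sequence space"
    )


def generate_genome(
    config: GenomeConfig | None = None, seed: int = 0
) -> SyntheticGenome:
    """Generate a seeded toy genome with genes, repeats and N-gaps.

    Deterministic for fixed ``(config, seed)``.  Raises
    :class:`~genopolish.core.PackingError` when the requested features cannot
    be packed into the requested chromosome lengths.
    """
    config = config or GenomeConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    names = [f"chr{i + 1}" for i in range(len(config.chromosome_lengths))]
    lengths = dict(zip(names, config.chromosome_lengths))
    seqs = {c: list(_random_sequence(rng, lengths[c], config.gc)) for c in names}
    occ = _Occupancy(lengths)
    weights = {c: float(lengths[c]) for c in names}

    # Genes: single- or two-exon CDS written into the random background.
    genes: list[GeneModel] = []
    for g in range(config.n_genes):
        n_codons = int(rng.integers(*config.gene_cds_codons))
        cds = _random_cds(rng, n_codons)
        strand = "+" if rng.random() < 0.5 else "-"
        has_intron = rng.random() < config.intron_fraction
        oriented = cds if strand == "+" else revcomp(cds)
        if has_intron:
            intron = _random_sequence(rng, int(rng.integers(*config.intron_length_range)), config.gc)
            cut = int(rng.integers(3, len(oriented) - 3))
            pieces = [oriented[:cut], oriented[cut:]]
            genomic = pieces[0] + intron + pieces[1]
        else:
            intron = ""
            pieces = [oriented]
            genomic = oriented
        chrom, start = _place(rng, occ, len(genomic), 2, weights)
        occ.claim(chrom, start, start + len(genomic))
        seqs[chrom][start : start + len(genomic)] = list(genomic)
        exons = []
        offset = start
        for i, piece in enumerate(pieces):
            exons.append((offset, offset + len(piece)))
            offset += len(piece) + (len(intron) if i == 0 else 0)
        genes.append(
            GeneModel(gene_id=f"g{g + 1:04d}", chrom=chrom, strand=strand, exons=exons)
        )

    # Repeats: tandem/dispersed copies of one unit until the requested
    # genome fraction is reached.
    repeats: list[RepeatInterval] = []
    total_len = sum(lengths.values())
    target_repeat_bases = int(config.repeat_fraction * total_len)
    unit = _random_sequence(rng, config.repeat_unit_length, config.gc)
    placed = 0
    while placed + len(unit) <= target_repeat_bases:
        chrom, start = _place(rng, occ, len(unit), 2, weights)
        occ.claim(chrom, start, start + len(unit))
        seqs[chrom][start : start + len(unit)] = list(unit)
        repeats.append(RepeatInterval(chrom, start, start + len(unit)))
        placed += len(unit)

    truth = ReferenceGenome({c: "".join(seqs[c]) for c in names})

    # Gaps: masked in the reference copy, retained in the truth genome.
    gaps: list[GapRecord] = []
    gapped = {c: list(truth.chromosomes[c]) for c in names}
    for _ in range(config.n_gaps):
        glen = int(rng.integers(*config.gap_length_range))
        chrom, start = _place(rng, occ, glen, config.gap_margin, weights)
        occ.claim(chrom, start, start + glen)
        gapped[chrom][start : start + glen] = ["N"] * glen
        gaps.append(GapRecord(chrom, start, start + glen))
    gaps.sort()

    genome = ReferenceGenome({c: "".join(gapped[c]) for c in names})
    genome.validate()
    return SyntheticGenome(
        genome=genome,
        truth_genome=truth,
        genes=sorted(genes, key=lambda g: (g.chrom, g.exons[0][0])),
        repeats=sorted(repeats),
        gaps=gaps,
    )


# ---------------------------------------------------------------------------
# Derived strain
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Substitution:
    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass(frozen=True)
class Insertion:
    """``seq`` inserted immediately after reference position ``pos`` (anchor)."""

    chrom: str
    pos: int
    seq: str


@dataclass(frozen=True)
class Deletion:
    """Reference interval ``[start, start + length)`` absent from the strain."""

    chrom: str
    start: int
    length: int
    seq: str


@dataclass(frozen=True)
class Duplication:
    """Tandem duplication: the strain carries ``copies`` total copies of
    ``[start, end)`` (the reference carries one)."""

    chrom: str
    start: int
    end: int
    copies: int


@dataclass
class TruthSet:
    substitutions: list[Substitution] = field(default_factory=list)
    insertions: list[Insertion] = field(default_factory=list)
    deletions: list[Deletion] = field(default_factory=list)
    duplications: list[Duplication] = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return (
            len(self.substitutions)
            + len(self.insertions)
            + len(self.deletions)
            + len(self.duplications)
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "substitutions": [asdict(s) for s in self.substitutions],
                "insertions": [asdict(i) for i in self.insertions],
                "deletions": [asdict(d) for d in self.deletions],
                "duplications": [asdict(d) for d in self.duplications],
            },
            indent=2,
        )

    def to_tsv(self) -> str:
        """One event per line: kind, chrom, 1-based position, detail."""
        lines = ["kind\tchrom\tpos\tdetail"]
        for s in self.substitutions:
            lines.append(f"substitution\t{s.chrom}\t{s.pos + 1}\t{s.ref}>{s.alt}")
        for i in self.insertions:
            lines.append(f"insertion\t{i.chrom}\t{i.pos + 1}\t+{i.seq}")
        for d in self.deletions:
            lines.append(f"deletion\t{d.chrom}\t{d.start + 1}\t-{d.seq}")
        for d in self.duplications:
            lines.append(
                f"duplication\t{d.chrom}\t{d.start + 1}\tlen={d.end - d.start};copies={d.copies}"
            )
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class MutationSpec:
    substitutions: int = 0
    insertions: int = 0
    deletions: int = 0
    duplications: int = 0
    indel_length_range: tuple[int, int] = (1, 8)
    duplication_length_range: tuple[int, int] = (800, 2000)
    duplication_copies_range: tuple[int, int] = (2, 4)
    avoid_exon_boundaries: bool = True

    def validate(self) -> None:
        if min(self.substitutions, self.insertions, self.deletions, self.duplications) < 0:
            raise ValidationError("mutation counts must be >= 0")


def _event_interval(ev) -> tuple[str, int, int]:
    if isinstance(ev, Substitution):
        return ev.chrom, ev.pos, ev.pos + 1
    if isinstance(ev, Insertion):
        return ev.chrom, ev.pos, ev.pos + 1
    if isinstance(ev, Deletion):
        return ev.chrom, ev.start - 1, ev.start + ev.length
    if isinstance(ev, Duplication):
        return ev.chrom, ev.start, ev.end
    raise TypeError(type(ev))


def mutate_strain(
    genome: ReferenceGenome,
    spec: MutationSpec,
    seed: int = 0,
    genes: list[GeneModel] | None = None,
) -> tuple[ReferenceGenome, TruthSet]:
    """Inject substitutions, indels and tandem duplications into ``genome``.

    Events are rejection-sampled to avoid N runs, each other, and (when
    ``spec.avoid_exon_boundaries`` and ``genes`` are given) indels that would
    straddle an exon boundary, which keeps coding-effect classification
    unambiguous.  Returns the derived genome and the ground-truth event set;
    re-applying the truth set to ``genome`` via :func:`apply_mutations`
    reproduces the derived genome byte-for-byte.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    chroms = list(genome.chromosomes)
    weights = np.array([len(genome.chromosomes[c]) for c in chroms], dtype=float)
    weights /= weights.sum()

    exon_lookup: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    if genes:
        for g in genes:
            exon_lookup[g.chrom].extend(g.exons)

    truth = TruthSet()
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    def free(chrom: str, start: int, end: int, margin: int = 2) -> bool:
        seq = genome.chromosomes[chrom]
        if start < 1 or end >= len(seq) - 1:
            return False
        if "N" in seq[start - 1 : end + 1]:
            return False
        return all(start - margin >= e or end + margin <= s for s, e in taken[chrom])

    def indel_respects_exons(chrom: str, start: int, end: int) -> bool:
        # the affected interval must sit fully inside one exon or fully outside all
        for s, e in exon_lookup[chrom]:
            if start < e and s < end:  # overlaps
                if not (s <= start and end <= e):
                    return False
        return True

    def sample_position(length: int, check_exons: bool, max_tries: int = 2000):
        for _ in range(max_tries):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            seq_len = len(genome.chromosomes[chrom])
            if seq_len <= length + 4:
                continue
            start = int(rng.integers(1, seq_len - length - 2))
            if not free(chrom, start, start + length):
                continue
            if check_exons and not indel_respects_exons(chrom, start, start + length):
                continue
            return chrom, start
        raise PackingError("mutation spec infeasible: no free positions left")

    check = spec.avoid_exon_boundaries and genes is not None

    for _ in range(spec.duplications):
        dlen = int(rng.integers(*spec.duplication_length_range))
        chrom, start = sample_position(dlen, check_exons=False)
        copies = int(rng.integers(spec.duplication_copies_range[0],
                                  spec.duplication_copies_range[1] + 1))
        ev = Duplication(chrom, start, start + dlen, copies)
        truth.duplications.append(ev)
        taken[chrom].append((start, start + dlen))

    for _ in range(spec.deletions):
        dlen = int(rng.integers(spec.indel_length_range[0], spec.indel_length_range[1] + 1))
        chrom, start = sample_position(dlen + 1, check_exons=check)
        start += 1  # keep the anchor base (start - 1) clear of other events
        seq = genome.chromosomes[chrom][start : start + dlen]
        truth.deletions.append(Deletion(chrom, start, dlen, seq))
        taken[chrom].append((start - 1, start + dlen))

    for _ in range(spec.insertions):
        ilen = int(rng.integers(spec.indel_length_range[0], spec.indel_length_range[1] + 1))
        chrom, anchor = sample_position(1, check_exons=check)
        ins = "".join(BASES[i] for i in rng.integers(0, 4, size=ilen))
        truth.insertions.append(Insertion(chrom, anchor, ins))
        taken[chrom].append((anchor, anchor + 1))

    for _ in range(spec.substitutions):
        chrom, pos = sample_position(1, check_exons=False)
        ref = genome.chromosomes[chrom][pos]
        alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
        truth.substitutions.append(Substitution(chrom, pos, ref, alt))
        taken[chrom].append((pos, pos + 1))

    derived = apply_mutations(genome, truth)
    return derived, truth


def apply_mutations(genome: ReferenceGenome, truth: TruthSet) -> ReferenceGenome:
    """Re-apply a truth set to a genome (the round-trip oracle of the tests)."""
    events: dict[str, list] = {c: [] for c in genome.chromosomes}
    for s in truth.substitutions:
        events[s.chrom].append(("sub", s.pos, s))
    for i in truth.insertions:
        events[i.chrom].append(("ins", i.pos, i))
    for d in truth.deletions:
        events[d.chrom].append(("del", d.start, d))
    for d in truth.duplications:
        events[d.chrom].append(("dup", d.start, d))

    out: dict[str, str] = {}
    for chrom, seq in genome.chromosomes.items():
        s = seq
        for kind, pos, ev in sorted(events[chrom], key=lambda t: -t[1]):
            if kind == "sub":
                if s[pos] != ev.ref:
                    raise ValidationError(
                        f"substitution at {chrom}:{pos} expects {ev.ref}, found {s[pos]}"
                    )
                s = s[:pos] + ev.alt + s[pos + 1 :]
            elif kind == "ins":
                s = s[: pos + 1] + ev.seq + s[pos + 1 :]
            elif kind == "del":
                if s[pos : pos + ev.length] != ev.seq:
                    raise ValidationError(f"deletion at {chrom}:{pos} mismatches genome")
                s = s[:pos] + s[pos + ev.length :]
            else:  # dup: (copies - 1) extra tandem copies appended after the unit
                unit = s[ev.start : ev.end]
                s = s[: ev.end] + unit * (ev.copies - 1) + s[ev.end :]
        out[chrom] = s
    return ReferenceGenome(out)


# ---------------------------------------------------------------------------
# Pileup simulation
# ---------------------------------------------------------------------------


def simulate_pileup(
    genome: ReferenceGenome,
    depth: float,
    error_rate: float,
    seed: int = 0,
    truth: TruthSet | None = None,
    read_length: int = 76,
    insert_size: int = 250,
    indel_error_factor: float = 0.1,
) -> tuple[PileupTrack, pd.DataFrame]:
    """Simulate a per-site pileup of one library aligned to ``genome``.

    ``truth`` describes the strain actually sequenced, expressed in the
    coordinates of ``genome``: reads carry the alternate base at substitution
    loci, insertion/deletion evidence at indel anchors, and depth over a
    duplicated source interval scales with its copy count.  Per-site coverage
    is Poisson(depth); each counted base is miscalled with probability
    ``error_rate`` (uniform over the three other bases); spurious
    indel evidence arises at ``error_rate * indel_error_factor``.

    Also emits a paired-read placement table (pair_id, end positions and
    orientations) whose read footprint matches the requested fold-coverage.
    """
    if depth <= 0:
        raise ValidationError("depth must be positive")
    if not 0.0 <= error_rate < 0.25:
        raise ValidationError("error_rate must be in [0, 0.25)")
    rng = np.random.default_rng(seed)
    truth = truth or TruthSet()

    track = PileupTrack({c: len(s) for c, s in genome.chromosomes.items()})
    pair_frames: list[pd.DataFrame] = []
    pair_serial = 0

    subs = {}
    for s in truth.substitutions:
        subs.setdefault(s.chrom, []).append(s)
    dels = {}
    for d in truth.deletions:
        dels.setdefault(d.chrom, []).append(d)
    inss = {}
    for i in truth.insertions:
        inss.setdefault(i.chrom, []).append(i)
    dups = {}
    for d in truth.duplications:
        dups.setdefault(d.chrom, []).append(d)

    for chrom, seq in genome.chromosomes.items():
        L = len(seq)
        true_idx = base_index_array(seq)
        for s in subs.get(chrom, []):
            true_idx[s.pos] = BASES.index(s.alt)

        mult = np.ones(L)
        for d in dups.get(chrom, []):
            mult[d.start : d.end] = d.copies
        # positions deleted in the strain contribute no base calls
        absent = np.zeros(L, dtype=bool)
        for d in dels.get(chrom, []):
            absent[d.start : d.start + d.length] = True

        lam = depth * mult
        lam[true_idx < 0] = 0.0  # N positions
        lam[absent] = 0.0
        n = rng.poisson(lam).astype(np.int64)

        errors = rng.binomial(n, error_rate)
        err_split = rng.multinomial(errors, [1 / 3] * 3)

        counts = np.zeros((L, 4), dtype=np.int64)
        for b in range(4):
            mask = true_idx == b
            if not mask.any():
                continue
            counts[mask, b] = n[mask] - errors[mask]
            others = [x for x in range(4) if x != b]
            for j, ob in enumerate(others):
                counts[mask, ob] += err_split[mask, j]
        track.base_counts[chrom] = counts.astype(np.int32)

        # background indel noise
        indel_rate = error_rate * indel_error_factor
        if indel_rate > 0:
            track.ins_count[chrom] = rng.binomial(n, indel_rate).astype(np.int32)
            track.del_count[chrom] = rng.binomial(n, indel_rate).astype(np.int32)

        # true indel evidence at anchors
        for i in inss.get(chrom, []):
            na = int(n[i.pos])
            miss = int(rng.binomial(na, error_rate))
            track.ins_count[chrom][i.pos] = na - miss
            track.ins_seqs[chrom].setdefault(i.pos, Counter())[
                i.seq
            ] += na - miss
        for d in dels.get(chrom, []):
            anchor = d.start - 1
            na = int(n[anchor])
            miss = int(rng.binomial(na, error_rate))
            track.del_count[chrom][anchor] = na - miss
            track.del_lens[chrom].setdefault(
                anchor, Counter()
            )[d.length] += na - miss

        # paired-read placements (FR orientation, fixed insert size)
        if L > insert_size:
            n_pairs = int(round(L * depth / (2 * read_length)))
            starts = rng.integers(0, L - insert_size, size=n_pairs)
            frame = pd.DataFrame(
                {
                    "pair_id": [f"p{pair_serial + k}" for k in range(n_pairs)],
                    "end1_scaffold": chrom,
                    "end1_pos": starts,
                    "end1_orient": "+",
                    "end2_scaffold": chrom,
                    "end2_pos": starts + insert_size - read_length,
                    "end2_orient": "-",
                }
            )
            pair_serial += n_pairs
            pair_frames.append(frame)

    pairs = (
        pd.concat(pair_frames, ignore_index=True)
        if pair_frames
        else pd.DataFrame(
            columns=[
                "pair_id",
                "end1_scaffold",
                "end1_pos",
                "end1_orient",
                "end2_scaffold",
                "end2_pos",
                "end2_orient",
            ]
        )
    )
    return track, pairs


# ---------------------------------------------------------------------------
# Scaffolds with injected mis-joins
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MisjoinSpec:
    translocation: int = 0
    relocation: int = 0
    inversion: int = 0

    @property
    def total(self) -> int:
        return self.translocation + self.relocation + self.inversion

    def validate(self) -> None:
        if min(self.translocation, self.relocation, self.inversion) < 0:
            raise ValidationError("mis-join counts must be >= 0")


@dataclass(frozen=True)
class MisjoinLabel:
    scaffold: str
    pair_index: int
    kind: str  # translocation | relocation | inversion


@dataclass
class FragmentedAssembly:
    scaffolds: dict[str, str]
    records: list[AlignmentRecord]
    truth_labels: list[MisjoinLabel]


def fragment_with_misjoins(
    genome: ReferenceGenome,
    n_scaffolds: int,
    misjoin_spec: MisjoinSpec | None = None,
    seed: int = 0,
    min_segment: int = 1000,
) -> FragmentedAssembly:
    """Cut the genome into scaffolds and inject labelled mis-joins.

    Each injected event produces one two-block scaffold: a translocation
    joins segments of two different chromosomes; an inversion joins two
    adjacent segments with the second reverse-complemented; a relocation
    joins two adjacent segments in swapped order.  All other scaffolds are
    single colinear segments.  The emitted alignment records describe the
    true placement of every block (identity 100).
    """
    misjoin_spec = misjoin_spec or MisjoinSpec()
    misjoin_spec.validate()
    rng = np.random.default_rng(seed)

    n_events = misjoin_spec.total
    if n_scaffolds < n_events:
        raise ValidationError("more mis-join events requested than scaffolds can host")
    if misjoin_spec.translocation > 0 and len(genome.chromosomes) < 2:
        raise ValidationError("translocations need at least two chromosomes")

    n_blocks = n_scaffolds + n_events
    total_len = genome.length()
    if total_len < n_blocks * min_segment:
        raise ValidationError(
            f"genome too short to cut {n_blocks} segments of >= {min_segment} bp"
        )

    # distribute block counts over chromosomes proportional to length
    chroms = list(genome.chromosomes)
    lengths = np.array([len(genome.chromosomes[c]) for c in chroms], dtype=float)
    alloc = np.maximum(1, np.floor(n_blocks * lengths / lengths.sum()).astype(int))
    while alloc.sum() < n_blocks:
        alloc[int(np.argmax(lengths / alloc))] += 1
    while alloc.sum() > n_blocks:
        alloc[int(np.argmax(alloc))] -= 1
    if (alloc < 1).any():
        raise ValidationError("cannot give every chromosome at least one segment")

    # cut each chromosome into consecutive segments of >= min_segment
    segments: dict[str, list[tuple[int, int]]] = {}
    for c, k in zip(chroms, alloc):
        L = len(genome.chromosomes[c])
        k = int(k)
        if L < k * min_segment:
            raise ValidationError(f"chromosome {c} too short for {k} segments")
        if k == 1:
            cuts = []
        else:
            slack = L - k * min_segment
            inner = np.sort(rng.choice(slack + 1, size=k - 1, replace=False)) if slack + 1 >= k - 1 else np.zeros(k - 1, dtype=int)
            cuts = [int(inner[i]) + (i + 1) * min_segment for i in range(k - 1)]
        bounds = [0] + cuts + [L]
        segments[c] = [(bounds[i], bounds[i + 1]) for i in range(k)]

    # adjacency-preserving pools
    free_adjacent: list[tuple[str, int]] = []  # (chrom, index of left segment)
    for c in chroms:
        for i in range(len(segments[c]) - 1):
            free_adjacent.append((c, i))
    used: set[tuple[str, int]] = set()

    def take_adjacent() -> tuple[str, int]:
        order = rng.permutation(len(free_adjacent))
        for j in order:
            c, i = free_adjacent[int(j)]
            if (c, i) not in used and (c, i + 1) not in used:
                used.add((c, i))
                used.add((c, i + 1))
                return c, i
        raise ValidationError("not enough adjacent free segments for the event spec")

    def take_single(exclude_chrom: str | None = None) -> tuple[str, int]:
        cands = [
            (c, i)
            for c in chroms
            for i in range(len(segments[c]))
            if (c, i) not in used and c != exclude_chrom
        ]
        if not cands:
            raise ValidationError("ran out of free segments for the event spec")
        c, i = cands[int(rng.integers(0, len(cands)))]
        used.add((c, i))
        return c, i

    scaffolds: dict[str, str] = {}
    records: list[AlignmentRecord] = []
    labels: list[MisjoinLabel] = []
    serial = 0

    def block(c: str, i: int) -> tuple[str, int, int]:
        s, e = segments[c][i]
        return c, s, e

    def emit(name: str, blocks: list[tuple[str, int, int, str]]) -> None:
        seq_parts = []
        offset = 0
        for chrom, s, e, strand in blocks:
            piece = genome.chromosomes[chrom][s:e]
            if strand == "-":
                piece = revcomp(piece)
            records.append(
                AlignmentRecord(
                    scaffold=name,
                    scf_start=offset,
                    scf_end=offset + len(piece),
                    ref_chrom=chrom,
                    ref_start=s,
                    ref_end=e,
                    strand=strand,
                    identity=100.0,
                )
            )
            seq_parts.append(piece)
            offset += len(piece)
        scaffolds[name] = "".join(seq_parts)

    def next_name() -> str:
        nonlocal serial
        serial += 1
        return f"scaffold_{serial:04d}"

    for _ in range(misjoin_spec.translocation):
        c1, i1 = take_single()
        c2, i2 = take_single(exclude_chrom=c1)
        name = next_name()
        emit(name, [block(c1, i1) + ("+",), block(c2, i2) + ("+",)])
        labels.append(MisjoinLabel(name, 0, "translocation"))

    for _ in range(misjoin_spec.inversion):
        c, i = take_adjacent()
        name = next_name()
        emit(name, [block(c, i) + ("+",), block(c, i + 1) + ("-",)])
        labels.append(MisjoinLabel(name, 0, "inversion"))

    for _ in range(misjoin_spec.relocation):
        c, i = take_adjacent()
        name = next_name()
        # reference order is (i, i+1); the scaffold carries them swapped
        emit(name, [block(c, i + 1) + ("+",), block(c, i) + ("+",)])
        labels.append(MisjoinLabel(name, 0, "relocation"))

    remaining = [
        (c, i)
        for c in chroms
        for i in range(len(segments[c]))
        if (c, i) not in used
    ]
    for c, i in remaining[: n_scaffolds - n_events]:
        strand = "+" if rng.random() < 0.5 else "-"
        emit(next_name(), [block(c, i) + (strand,)])

    return FragmentedAssembly(scaffolds=scaffolds, records=records, truth_labels=labels)
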