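"""Scoring a scaffold assembly against a reference genome.

Alignment blocks (show-coords-like records) are filtered for identity,
redundant overlap and scaffold length; adjacent blocks of each scaffold are
then inspected for mis-joins — translocations (blocks on two chromosomes),
relocations (out-of-order or wrongly spaced blocks on one chromosome) and
inversions (flipped orientation).  The module also computes contiguity
statistics (N50, covered fractions, complete-CDS counts), a Fisher exact
test of CDS vs intergenic representation, and coverage saturation curves
from subsampled read placements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    AlignmentRecord,
    GeneModel,
    ReferenceGenome,
    RepeatInterval,
    ValidationError,
    percent,
    round_half_away,
    sequence_mask,
)

__all__ = [
    "FilterParams",
    "MisjoinEvent",
    "CorrectnessReport",
    "ContiguityReport",
    "CdsRepresentationTest",
    "filter_alignments",
    "classify_misjoins",
    "correctness_report",
    "contiguity_stats",
    "n50",
    "cds_representation_test",
    "saturation_curve",
]

TRANSLOCATION = "translocation"
RELOCATION = "relocation"
INVERSION = "inversion"
MISJOIN_TYPES = (TRANSLOCATION, RELOCATION, INVERSION)


@dataclass(frozen=True)
class FilterParams:
    """Alignment filtering thresholds.

    Defaults follow the standard short-read benchmarking recipe: drop blocks
    under 95% identity, drop a block overlapped more than 95% (of the shorter
    block, on scaffold coordinates) by a better block, and evaluate only
    scaffolds longer than 500 bp.
    """

    min_identity: float = 95.0
    max_overlap: float = 0.95
    min_scaffold_length: int = 500

    def validate(self) -> None:
        if not 0.0 <= self.min_identity <= 100.0:
            raise ValidationError("min_identity must be in [0, 100]")
        if not 0.0 <= self.max_overlap <= 1.0:
            raise ValidationError("max_overlap must be in [0, 1]")


@dataclass(frozen=True)
class MisjoinEvent:
    scaffold: str
    pair_index: int  # index of the left block of the breakpoint pair
    kind: str
    left_block: tuple[str, int, int]
    right_block: tuple[str, int, int]

    def __post_init__(self) -> None:
        if self.kind not in MISJOIN_TYPES:
            raise ValidationError(f"unknown mis-join type {self.kind!r}")


@dataclass
class CorrectnessReport:
    counts: dict[str, int]
    n_scaffolds: int
    mean_misjoins: float
    pct_misassembled: float

    @property
    def total_events(self) -> int:
        return sum(self.counts.values())

    @property
    def mean_misjoins_rounded(self) -> float:
        return round_half_away(self.mean_misjoins, 3)

    @property
    def pct_misassembled_rounded(self) -> float:
        return round_half_away(self.pct_misassembled, 1)


@dataclass
class ContiguityReport:
    n_scaffolds: int
    n50: int
    total_size: int
    pct_reference_covered: float
    pct_cds_covered: float
    pct_intergenic_covered: float
    n_complete_cds: int
    pct_complete_cds: float


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def _overlap(a: AlignmentRecord, b: AlignmentRecord) -> int:
    return max(0, min(a.scf_end, b.scf_end) - max(a.scf_start, b.scf_start))


def filter_alignments(
    records: list[AlignmentRecord],
    params: FilterParams | None = None,
    scaffold_lengths: dict[str, int] | None = None,
) -> list[AlignmentRecord]:
    """Apply identity, scaffold-length and redundancy filters.

    Overlap between two blocks of one scaffold is measured on scaffold
    coordinates as a fraction of the shorter block; when the fraction exceeds
    ``max_overlap`` the shorter block loses (ties broken by identity, then by
    earlier scaffold start).  The operation is idempotent.
    """
    params = params or FilterParams()
    params.validate()
    if scaffold_lengths is None:
        raise ValidationError("scaffold_lengths are required for the length filter")
    for r in records:
        if r.scaffold not in scaffold_lengths:
            raise ValidationError(f"unknown scaffold id {r.scaffold!r}")

    survivors = [
        r
        for r in records
        if r.identity >= params.min_identity
        and scaffold_lengths[r.scaffold] > params.min_scaffold_length
    ]

    kept: list[AlignmentRecord] = []
    by_scaffold: dict[str, list[AlignmentRecord]] = {}
    for r in survivors:
        by_scaffold.setdefault(r.scaffold, []).append(r)
    for scaffold in by_scaffold:
        ranked = sorted(
            by_scaffold[scaffold],
            key=lambda r: (-r.aligned_length, -r.identity, r.scf_start),
        )
        chosen: list[AlignmentRecord] = []
        for r in ranked:
            ok = True
            for k in chosen:
                shorter = min(r.aligned_length, k.aligned_length)
                if _overlap(r, k) / shorter > params.max_overlap:
                    ok = False
                    break
            if ok:
                chosen.append(r)
        kept.extend(chosen)

    kept.sort(key=lambda r: (r.scaffold, r.scf_start, r.ref_chrom, r.ref_start))
    return kept


# ---------------------------------------------------------------------------
# Mis-join classification
# ---------------------------------------------------------------------------


def _intersects_repeat(
    block: AlignmentRecord, repeats_by_chrom: dict[str, list[tuple[int, int]]]
) -> bool:
    for s, e in repeats_by_chrom.get(block.ref_chrom, ()):
        if block.ref_start < e and s < block.ref_end:
            return True
    return False


def classify_misjoins(
    records: list[AlignmentRecord],
    repeats: list[RepeatInterval] | None = None,
    tolerance: int = 1000,
) -> list[MisjoinEvent]:
    """Classify each adjacent block pair of every scaffold.

    Precedence per breakpoint: translocation > inversion > relocation.  A
    relocation requires the reference order of the two blocks to contradict
    their scaffold order, or the reference-coordinate gap to disagree with
    the scaffold-coordinate gap by more than ``tolerance``.  A breakpoint
    whose two flanking blocks both intersect a repeat interval is skipped.
    Input must be sorted by scaffold start within each scaffold.
    """
    repeats = repeats or []
    repeats_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for rp in repeats:
        repeats_by_chrom.setdefault(rp.chrom, []).append((rp.start, rp.end))

    by_scaffold: dict[str, list[AlignmentRecord]] = {}
    for r in records:
        group = by_scaffold.setdefault(r.scaffold, [])
        if group and r.scf_start < group[-1].scf_start:
            raise ValidationError(
                f"records of scaffold {r.scaffold!r} are not sorted by scaffold start"
            )
        group.append(r)

    events: list[MisjoinEvent] = []
    for scaffold, blocks in by_scaffold.items():
        for i in range(len(blocks) - 1):
            left, right = blocks[i], blocks[i + 1]
            if _intersects_repeat(left, repeats_by_chrom) and _intersects_repeat(
                right, repeats_by_chrom
            ):
                continue
            kind = _classify_pair(left, right, tolerance)
            if kind is not None:
                events.append(
                    MisjoinEvent(
                        scaffold=scaffold,
                        pair_index=i,
                        kind=kind,
                        left_block=(left.ref_chrom, left.ref_start, left.ref_end),
                        right_block=(right.ref_chrom, right.ref_start, right.ref_end),
                    )
                )
    return events


def _classify_pair(
    left: AlignmentRecord, right: AlignmentRecord, tolerance: int
) -> str | None:
    if left.ref_chrom != right.ref_chrom:
        return TRANSLOCATION
    if left.strand != right.strand:
        return INVERSION
    scf_gap = right.scf_start - left.scf_end
    if left.strand == "+":
        ref_gap = right.ref_start - left.ref_end
        order_ok = right.ref_start >= left.ref_start
    else:
        ref_gap = left.ref_start - right.ref_end
        order_ok = right.ref_start <= left.ref_start
    if not order_ok or abs(ref_gap - scf_gap) > tolerance:
        return RELOCATION
    return None


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def correctness_report(
    events: list[MisjoinEvent], n_scaffolds_evaluated: int
) -> CorrectnessReport:
    """Tally mis-joins into per-type counts, the mean per scaffold and the
    percentage of scaffolds carrying at least one event."""
    if n_scaffolds_evaluated <= 0:
        raise ValidationError("n_scaffolds_evaluated must be positive")
    counts = {t: 0 for t in MISJOIN_TYPES}
    bad_scaffolds: set[str] = set()
    for ev in events:
        counts[ev.kind] += 1
        bad_scaffolds.add(ev.scaffold)
    total = sum(counts.values())
    return CorrectnessReport(
        counts=counts,
        n_scaffolds=n_scaffolds_evaluated,
        mean_misjoins=total / n_scaffolds_evaluated,
        pct_misassembled=100.0 * len(bad_scaffolds) / n_scaffolds_evaluated,
    )


def n50(lengths: list[int]) -> int:
    """First length at which the descending cumulative sum reaches half the
    total assembly size."""
    if not lengths:
        raise ValidationError("empty assembly")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for l in ordered:
        acc += l
        if acc >= half:
            return l
    return ordered[-1]


def _coverage_masks(
    records: list[AlignmentRecord], reference: ReferenceGenome
) -> dict[str, np.ndarray]:
    masks = {c: np.zeros(len(s), dtype=bool) for c, s in reference.chromosomes.items()}
    for r in records:
        masks[r.ref_chrom][r.ref_start : r.ref_end] = True
    return masks


def contiguity_stats(
    scaffold_lengths: dict[str, int],
    records: list[AlignmentRecord],
    reference: ReferenceGenome,
    genes: list[GeneModel],
) -> ContiguityReport:
    """Contiguity and representation statistics of a filtered assembly.

    Covered-percentage denominators exclude N positions.  Every non-N base is
    either CDS (inside a CDS exon) or intergenic (introns included).  A gene
    counts as a complete start-to-stop CDS when a single scaffold's blocks
    cover every CDS base of the gene.
    """
    if not scaffold_lengths:
        raise ValidationError("empty assembly")
    lengths = list(scaffold_lengths.values())

    covered = _coverage_masks(records, reference)
    non_n = {c: ~sequence_mask(s) for c, s in reference.chromosomes.items()}
    cds_mask = {c: np.zeros(len(s), dtype=bool) for c, s in reference.chromosomes.items()}
    for g in genes:
        for s, e in g.exons:
            cds_mask[g.chrom][s:e] = True

    tot_non_n = cov_non_n = 0
    tot_cds = cov_cds = 0
    tot_inter = cov_inter = 0
    for c in reference.chromosomes:
        nn = non_n[c]
        cd = cds_mask[c] & nn
        inter = nn & ~cds_mask[c]
        cv = covered[c]
        tot_non_n += int(nn.sum())
        cov_non_n += int((cv & nn).sum())
        tot_cds += int(cd.sum())
        cov_cds += int((cv & cd).sum())
        tot_inter += int(inter.sum())
        cov_inter += int((cv & inter).sum())

    # complete start-to-stop CDS within a single scaffold
    by_chrom_scaffold: dict[str, dict[str, list[AlignmentRecord]]] = {}
    for r in records:
        by_chrom_scaffold.setdefault(r.ref_chrom, {}).setdefault(r.scaffold, []).append(r)
    n_complete = 0
    for g in genes:
        span_s, span_e = g.span
        for scaffold, blocks in by_chrom_scaffold.get(g.chrom, {}).items():
            mask = np.zeros(span_e - span_s, dtype=bool)
            for b in blocks:
                if b.ref_start < span_e and span_s < b.ref_end:
                    mask[max(0, b.ref_start - span_s) : b.ref_end - span_s] = True
            if all(mask[s - span_s : e - span_s].all() for s, e in g.exons):
                n_complete += 1
                break

    return ContiguityReport(
        n_scaffolds=len(lengths),
        n50=n50(lengths),
        total_size=sum(lengths),
        pct_reference_covered=100.0 * cov_non_n / tot_non_n if tot_non_n else 0.0,
        pct_cds_covered=100.0 * cov_cds / tot_cds if tot_cds else 0.0,
        pct_intergenic_covered=100.0 * cov_inter / tot_inter if tot_inter else 0.0,
        n_complete_cds=n_complete,
        pct_complete_cds=100.0 * n_complete / len(genes) if genes else 0.0,
    )


@dataclass
class CdsRepresentationTest:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float


def cds_representation_test(
    cds_covered: int,
    cds_uncovered: int,
    intergenic_covered: int,
    intergenic_uncovered: int,
) -> CdsRepresentationTest:
    """Two-sided Fisher exact test of coverage in CDS vs intergenic bases.

    The exact p-value sums hypergeometric probabilities of all tables at
    least as extreme as the observed one.
    """
    table = ((cds_covered, cds_uncovered), (intergenic_covered, intergenic_uncovered))
    flat = [cds_covered, cds_uncovered, intergenic_covered, intergenic_uncovered]
    if any(x < 0 for x in flat):
        raise ValidationError("table counts must be non-negative")
    if sum(flat) == 0:
        raise ValidationError("all-zero table")
    rows = (flat[0] + flat[1], flat[2] + flat[3])
    cols = (flat[0] + flat[2], flat[1] + flat[3])
    if 0 in rows or 0 in cols:
        raise ValidationError("degenerate table: zero margin")
    res = stats.fisher_exact(np.array(table), alternative="two-sided")
    return CdsRepresentationTest(
        table=table, odds_ratio=float(res.statistic), p_value=float(res.pvalue)
    )


# ---------------------------------------------------------------------------
# Saturation curve
# ---------------------------------------------------------------------------


def saturation_curve(
    placements: pd.DataFrame,
    depths: list[float],
    reference: ReferenceGenome,
    seed: int = 0,
    read_length: int = 76,
) -> list[tuple[float, float]]:
    """Fraction of non-N reference bases covered at nested subsampled depths.

    The placement table is shuffled once (seeded); the subset for each target
    depth is a prefix of that shuffle, so smaller subsets are contained in
    larger ones and the covered fraction is non-decreasing in depth.
    """
    if any(d < 0 for d in depths):
        raise ValidationError("depths must be non-negative")
    genome_len = reference.length()
    n_pairs = len(placements)
    full_depth = 2.0 * read_length * n_pairs / genome_len if genome_len else 0.0
    for d in depths:
        if d > full_depth * (1 + 1e-9) and not (d == 0 and n_pairs == 0):
            raise ValidationError(
                f"requested depth {d} exceeds available depth {full_depth:.1f}"
            )

    rng = np.random.default_rng(seed)
    order = rng.permutation(n_pairs)

    non_n = {c: ~sequence_mask(s) for c, s in reference.chromosomes.items()}
    total_non_n = sum(int(m.sum()) for m in non_n.values())
    if total_non_n == 0:
        raise ValidationError("reference has no non-N bases")

    chrom_of = {c: i for i, c in enumerate(reference.chromosomes)}
    lengths = {c: len(s) for c, s in reference.chromosomes.items()}

    out: list[tuple[float, float]] = []
    for d in depths:
        k = int(round(n_pairs * d / full_depth)) if full_depth > 0 else 0
        subset = placements.iloc[order[:k]]
        frac_covered = 0
        for chrom, L in lengths.items():
            diff = np.zeros(L + read_length + 1, dtype=np.int64)
            for end in ("end1", "end2"):
                sel = subset[subset[f"{end}_scaffold"] == chrom]
                pos = sel[f"{end}_pos"].to_numpy(dtype=np.int64)
                np.add.at(diff, pos, 1)
                np.add.at(diff, pos + read_length, -1)
            covered = np.cumsum(diff)[:L] > 0
            frac_covered += int((covered & non_n[chrom]).sum())
        out.append((d, frac_covered / total_non_n))
    return out
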