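"""Closing gaps and correcting bases in a draft reference genome.

A gapped reference (N-runs mark unresolved sequence) is improved in stages:
scaffolds aligned over a gap with sufficient identity, span and flanking
anchor length donate their sequence (recruitment); read pairs bridging
scaffold ends propose joins or flag inverted scaffolds; sites where enough
reads contradict the reference with a near-unanimous alternative are
corrected.  The module also tallies gaps closed per stage and tests whether
the spacing of the remaining gaps is compatible with uniform random
placement (chi-square against the geometric spacing distribution).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    AlignmentRecord,
    BASES,
    GapRecord,
    PileupTrack,
    ReferenceGenome,
    ValidationError,
    base_index_array,
    revcomp,
)

__all__ = [
    "RecruitParams",
    "ClosureRecord",
    "CorrectionParams",
    "CorrectionRecord",
    "LinkParams",
    "JoinEvidence",
    "GapAccounting",
    "find_gaps",
    "recruit_scaffold_closures",
    "apply_closures",
    "link_by_read_pairs",
    "correct_reference_bases",
    "gap_accounting",
    "gap_spacing_test",
]


# ---------------------------------------------------------------------------
# Gap detection
# ---------------------------------------------------------------------------


def find_gaps(genome: ReferenceGenome) -> list[GapRecord]:
    """All maximal N-runs, sorted by (chromosome, start)."""
    gaps: list[GapRecord] = []
    for chrom, seq in genome.chromosomes.items():
        for m in re.finditer("N+", seq):
            gaps.append(GapRecord(chrom, m.start(), m.end()))
    gaps.sort()
    return gaps


# ---------------------------------------------------------------------------
# Scaffold recruitment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecruitParams:
    """Thresholds for donating scaffold sequence into a gap: at least
    ``min_align`` aligned bases at ``min_identity`` percent identity with at
    least ``min_flank`` aligned bases on each side of the gap."""

    min_align: int = 200
    min_identity: float = 95.0
    min_flank: int = 50
    span_slop: float = 0.20  # tolerated relative disagreement, two-block spans


@dataclass
class ClosureRecord:
    gap: GapRecord
    scaffold: str
    scaffold_interval: tuple[int, int]
    replacement: str
    left_flank: int
    right_flank: int
    stage: str = "recruitment"
    identity: float = 100.0
    aligned_span: int = 0

    def __post_init__(self) -> None:
        if "N" in self.replacement:
            raise ValidationError("closure replacement must not contain N")


def _map_ref_to_scf(record: AlignmentRecord, ref_pos: int) -> int:
    """Project a reference position inside an alignment block onto the
    scaffold (forward) coordinates, assuming a colinear block."""
    if record.strand == "+":
        return record.scf_start + (ref_pos - record.ref_start)
    return record.scf_start + (record.ref_end - ref_pos)


def _single_block_closure(
    gap: GapRecord,
    record: AlignmentRecord,
    scaffolds: dict[str, str],
    params: RecruitParams,
) -> ClosureRecord | None:
    left = gap.start - record.ref_start
    right = record.ref_end - gap.end
    if left < params.min_flank or right < params.min_flank:
        return None
    if record.aligned_length < params.min_align:
        return None
    if record.identity < params.min_identity:
        return None
    a = _map_ref_to_scf(record, gap.start)
    b = _map_ref_to_scf(record, gap.end)
    lo, hi = min(a, b), max(a, b)
    piece = scaffolds[record.scaffold][lo:hi]
    if record.strand == "-":
        piece = revcomp(piece)
    if "N" in piece or not piece:
        return None
    return ClosureRecord(
        gap=gap,
        scaffold=record.scaffold,
        scaffold_interval=(lo, hi),
        replacement=piece,
        left_flank=left,
        right_flank=right,
        identity=record.identity,
        aligned_span=record.aligned_length,
    )


def _two_block_closure(
    gap: GapRecord,
    left_rec: AlignmentRecord,
    right_rec: AlignmentRecord,
    scaffolds: dict[str, str],
    params: RecruitParams,
) -> ClosureRecord | None:
    # one block per flank, same scaffold and strand, abutting the gap edges
    if left_rec.scaffold != right_rec.scaffold or left_rec.strand != right_rec.strand:
        return None
    if left_rec.ref_end != gap.start or right_rec.ref_start != gap.end:
        return None
    left = gap.start - left_rec.ref_start
    right = right_rec.ref_end - gap.end
    if left < params.min_flank or right < params.min_flank:
        return None
    span = left_rec.aligned_length + right_rec.aligned_length
    if span < params.min_align:
        return None
    identity = min(left_rec.identity, right_rec.identity)
    if identity < params.min_identity:
        return None
    if left_rec.strand == "+":
        lo, hi = left_rec.scf_end, right_rec.scf_start
    else:
        lo, hi = right_rec.scf_end, left_rec.scf_start
    if hi < lo:
        return None
    if abs((hi - lo) - gap.length) > params.span_slop * gap.length:
        return None
    piece = scaffolds[left_rec.scaffold][lo:hi]
    if left_rec.strand == "-":
        piece = revcomp(piece)
    if "N" in piece or not piece:
        return None
    return ClosureRecord(
        gap=gap,
        scaffold=left_rec.scaffold,
        scaffold_interval=(lo, hi),
        replacement=piece,
        left_flank=left,
        right_flank=right,
        identity=identity,
        aligned_span=span,
    )


def recruit_scaffold_closures(
    gaps: list[GapRecord],
    alignments: list[AlignmentRecord],
    scaffolds: dict[str, str],
    params: RecruitParams | None = None,
) -> list[ClosureRecord]:
    """Find at most one donor closure per gap under the recruitment thresholds.

    A gap may be spanned by one alignment block (flanks measured inside the
    block) or by two blocks of the same scaffold abutting the gap edges whose
    scaffold-coordinate separation agrees with the gap length within
    ``span_slop``.  The best closure per gap is the one with the longest
    total aligned span, ties broken by identity.
    """
    params = params or RecruitParams()
    by_chrom: dict[str, list[AlignmentRecord]] = {}
    for r in alignments:
        if r.scaffold not in scaffolds:
            raise ValidationError(f"alignment names unknown scaffold {r.scaffold!r}")
        by_chrom.setdefault(r.ref_chrom, []).append(r)

    closures: list[ClosureRecord] = []
    for gap in gaps:
        candidates: list[ClosureRecord] = []
        records = by_chrom.get(gap.chrom, [])
        for r in records:
            if r.ref_start <= gap.start and r.ref_end >= gap.end:
                c = _single_block_closure(gap, r, scaffolds, params)
                if c:
                    candidates.append(c)
        left_flanks = [r for r in records if r.ref_end == gap.start]
        right_flanks = [r for r in records if r.ref_start == gap.end]
        for lr in left_flanks:
            for rr in right_flanks:
                c = _two_block_closure(gap, lr, rr, scaffolds, params)
                if c:
                    candidates.append(c)
        if candidates:
            candidates.sort(key=lambda c: (-c.aligned_span, -c.identity, c.scaffold))
            closures.append(candidates[0])
    return closures


def apply_closures(
    genome: ReferenceGenome, closures: list[ClosureRecord]
) -> ReferenceGenome:
    """Replace each closed gap's N-run with its donor sequence.

    Closures must target distinct, non-overlapping gaps whose interval is all
    N in ``genome``; sequence outside the replaced intervals is preserved
    byte-for-byte.
    """
    by_chrom: dict[str, list[ClosureRecord]] = {}
    for c in closures:
        by_chrom.setdefault(c.gap.chrom, []).append(c)

    out = dict(genome.chromosomes)
    for chrom, items in by_chrom.items():
        items.sort(key=lambda c: c.gap.start)
        prev_end = -1
        for c in items:
            if c.gap.start < prev_end:
                raise ValidationError("overlapping closures")
            prev_end = c.gap.end
        seq = out[chrom]
        for c in sorted(items, key=lambda c: -c.gap.start):
            target = seq[c.gap.start : c.gap.end]
            if set(target) != {"N"}:
                raise ValidationError(
                    f"closure at {chrom}:{c.gap.start}-{c.gap.end} targets non-N sequence"
                )
            seq = seq[: c.gap.start] + c.replacement + seq[c.gap.end :]
        out[chrom] = seq
    return ReferenceGenome(out)


# ---------------------------------------------------------------------------
# Read-pair linkage
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LinkParams:
    min_pairs: int = 10
    min_orientation_consistency: float = 0.8
    end_window: int = 500  # how close to a scaffold end a read must sit


@dataclass
class JoinEvidence:
    end_a: tuple[str, str]  # (scaffold, 'L'|'R')
    end_b: tuple[str, str]
    n_pairs: int
    majority_orientation: tuple[str, str]
    consistency: float
    stage: str  # read_pair | inversion_fix


_PAIR_COLUMNS = [
    "pair_id",
    "end1_scaffold",
    "end1_pos",
    "end1_orient",
    "end2_scaffold",
    "end2_pos",
    "end2_orient",
]


def link_by_read_pairs(
    placements: pd.DataFrame,
    scaffold_lengths: dict[str, int],
    params: LinkParams | None = None,
) -> list[JoinEvidence]:
    """Aggregate read pairs bridging two scaffold ends into join evidence.

    An end pair supported by at least ``min_pairs`` pairs whose orientation
    signature is consistent is a join candidate; a majority signature with
    equal read orientations implies one scaffold is reversed relative to the
    other and is flagged ``inversion_fix``.
    """
    params = params or LinkParams()
    missing = [c for c in _PAIR_COLUMNS if c not in placements.columns]
    if missing:
        raise ValidationError(f"placement table lacks columns {missing}")

    tallies: dict[tuple, dict[tuple[str, str], int]] = {}
    for row_no, row in enumerate(placements.itertuples(index=False)):
        ends = []
        for prefix in ("end1", "end2"):
            scf = getattr(row, f"{prefix}_scaffold")
            pos = getattr(row, f"{prefix}_pos")
            orient = getattr(row, f"{prefix}_orient")
            if scf not in scaffold_lengths:
                raise ValidationError(f"row {row_no}: unknown scaffold {scf!r}")
            if orient not in ("+", "-"):
                raise ValidationError(f"row {row_no}: bad orientation {orient!r}")
            try:
                pos = int(pos)
            except (TypeError, ValueError):
                raise ValidationError(f"row {row_no}: bad position {pos!r}") from None
            if not 0 <= pos < scaffold_lengths[scf]:
                raise ValidationError(f"row {row_no}: position {pos} outside {scf!r}")
            length = scaffold_lengths[scf]
            if pos < params.end_window:
                side = "L"
            elif pos >= length - params.end_window:
                side = "R"
            else:
                side = None
            ends.append(((scf, side), orient))
        (a, oa), (b, ob) = ends
        if a[1] is None or b[1] is None or a[0] == b[0]:
            continue
        if (b, ob) < (a, oa):
            a, oa, b, ob = b, ob, a, oa
        key = (a, b)
        tallies.setdefault(key, {}).setdefault((oa, ob), 0)
        tallies[key][(oa, ob)] += 1

    joins: list[JoinEvidence] = []
    for (a, b), counts in tallies.items():
        n = sum(counts.values())
        majority, m = max(counts.items(), key=lambda kv: kv[1])
        consistency = m / n
        if n < params.min_pairs or consistency < params.min_orientation_consistency:
            continue
        stage = "inversion_fix" if majority[0] == majority[1] else "read_pair"
        joins.append(
            JoinEvidence(
                end_a=a,
                end_b=b,
                n_pairs=n,
                majority_orientation=majority,
                consistency=consistency,
                stage=stage,
            )
        )
    joins.sort(key=lambda j: (j.end_a, j.end_b))
    return joins


# ---------------------------------------------------------------------------
# Base / indel correction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrectionParams:
    """A reference base is corrected when at least ``min_discordant`` reads
    disagree with it in every provided library class and the most frequent
    alternative exceeds ``min_fraction`` of the DNA reads."""

    min_discordant: int = 10
    min_fraction: float = 0.90


@dataclass
class CorrectionRecord:
    chrom: str
    pos: int
    old: str
    new: str
    support: int
    fraction: float
    kind: str = "substitution"  # substitution | insertion | deletion

    def __post_init__(self) -> None:
        if self.old == self.new:
            raise ValidationError("correction must change the sequence")


def correct_reference_bases(
    genome: ReferenceGenome,
    tracks: dict[str, PileupTrack],
    params: CorrectionParams | None = None,
) -> list[CorrectionRecord]:
    """Propose base and indel corrections from one or more pileup tracks.

    ``tracks`` maps library class names to tracks; ``"dna"`` is mandatory and
    supplies the majority allele and its fraction.  The discordant-read
    threshold must hold in every provided class.  Ties with no alternative
    exceeding ``min_fraction`` yield no correction.
    """
    params = params or CorrectionParams()
    if "dna" not in tracks:
        raise ValidationError('tracks must include a "dna" library')
    dna = tracks["dna"]

    corrections: list[CorrectionRecord] = []
    for chrom, seq in genome.chromosomes.items():
        ref_idx = base_index_array(seq)
        valid = ref_idx >= 0
        depth = {name: t.depth(chrom) for name, t in tracks.items()}

        discordant_ok = valid.copy()
        for name, t in tracks.items():
            counts = t.base_counts[chrom]
            ref_count = np.where(
                valid, counts[np.arange(len(seq)), np.maximum(ref_idx, 0)], 0
            )
            discordant_ok &= (depth[name] - ref_count) >= params.min_discordant

        if discordant_ok.any():
            dna_counts = dna.base_counts[chrom].astype(float).copy()
            rows = np.arange(len(seq))
            dna_counts[rows[valid], ref_idx[valid]] = -1  # exclude the reference base
            alt_idx = np.argmax(dna_counts, axis=1)
            alt_count = dna_counts[rows, alt_idx]
            dna_depth = depth["dna"].astype(float)
            with np.errstate(divide="ignore", invalid="ignore"):
                frac = np.where(dna_depth > 0, alt_count / dna_depth, 0.0)
            hits = np.nonzero(discordant_ok & (frac > params.min_fraction))[0]
            for pos in hits:
                corrections.append(
                    CorrectionRecord(
                        chrom=chrom,
                        pos=int(pos),
                        old=seq[pos],
                        new=BASES[int(alt_idx[pos])],
                        support=int(alt_count[pos]),
                        fraction=float(frac[pos]),
                        kind="substitution",
                    )
                )

        # indel corrections under the same thresholds
        for kind in ("insertion", "deletion"):
            evidence = {
                name: (t.ins_count if kind == "insertion" else t.del_count)[chrom]
                for name, t in tracks.items()
            }
            ok = valid.copy()
            for name in tracks:
                ok &= evidence[name] >= params.min_discordant
            if not ok.any():
                continue
            dna_ev = evidence["dna"].astype(float)
            dna_depth = depth["dna"].astype(float)
            with np.errstate(divide="ignore", invalid="ignore"):
                frac = np.where(dna_depth > 0, dna_ev / dna_depth, 0.0)
            for pos in np.nonzero(ok & (frac > params.min_fraction))[0]:
                pos = int(pos)
                if kind == "insertion":
                    registry = dna.ins_seqs[chrom].get(pos)
                    if not registry:
                        continue
                    ins_seq = registry.most_common(1)[0][0]
                    old, new = seq[pos], seq[pos] + ins_seq
                else:
                    registry = dna.del_lens[chrom].get(pos)
                    if not registry:
                        continue
                    dlen = registry.most_common(1)[0][0]
                    old, new = seq[pos : pos + 1 + dlen], seq[pos]
                corrections.append(
                    CorrectionRecord(
                        chrom=chrom,
                        pos=pos,
                        old=old,
                        new=new,
                        support=int(dna_ev[pos]),
                        fraction=float(frac[pos]),
                        kind=kind,
                    )
                )

    corrections.sort(key=lambda c: (c.chrom, c.pos, c.kind))
    return corrections


# ---------------------------------------------------------------------------
# Accounting and spacing test
# ---------------------------------------------------------------------------


@dataclass
class GapAccounting:
    stages: dict[str, int]
    initial: int
    total_closed: int
    remaining: int


def gap_accounting(stage_counts: dict[str, int], initial: int) -> GapAccounting:
    """Sum gaps closed per stage and the gaps remaining out of ``initial``."""
    if initial < 0 or any(v < 0 for v in stage_counts.values()):
        raise ValidationError("counts must be non-negative")
    total = sum(stage_counts.values())
    if total > initial:
        raise ValidationError(
            f"total closed ({total}) exceeds the initial gap count ({initial})"
        )
    return GapAccounting(
        stages=dict(stage_counts),
        initial=initial,
        total_closed=total,
        remaining=initial - total,
    )


def gap_spacing_test(
    gaps: list[GapRecord],
    chromosome_lengths: dict[str, int],
    n_bins: int = 10,
    estimated_params: int = 1,
) -> tuple[float, int, float]:
    """Chi-square test of inter-gap spacings against uniform random placement.

    Under uniform placement at the observed density, the distance from one
    gap to the next follows a geometric distribution.  Observed spacings are
    binned at the equal-probability quantiles of the fitted geometric law;
    adjacent bins are merged until every expected count is at least 5; the
    statistic is referred to a chi-square with (bins - 1 - estimated_params)
    degrees of freedom, the usual correction for the geometric rate being
    fitted from the same spacings (this keeps the test's type-I error at its
    nominal level).  Returns ``(statistic, dof, p_value)``.
    """
    if len(gaps) < 2:
        raise ValidationError("gap spacing test needs at least 2 gaps")
    spacings: list[int] = []
    by_chrom: dict[str, list[GapRecord]] = {}
    for g in gaps:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, items in by_chrom.items():
        items.sort(key=lambda g: g.start)
        for a, b in zip(items, items[1:]):
            spacings.append(b.start - a.end)
    if not spacings:
        raise ValidationError("no two gaps share a chromosome; no spacings to test")

    x = np.asarray(spacings, dtype=float)
    x = np.maximum(x, 1)
    p_hat = 1.0 / x.mean()
    dist = stats.geom(p_hat)

    qs = np.arange(1, n_bins) / n_bins
    edges = np.unique(dist.ppf(qs))
    # integer bin upper bounds; last bin open-ended
    uppers = list(edges) + [np.inf]
    lowers = [0.0] + list(edges)
    observed = []
    expected = []
    n = len(x)
    for lo, hi in zip(lowers, uppers):
        observed.append(int(((x > lo) & (x <= hi)).sum()))
        mass = (dist.cdf(hi) if np.isfinite(hi) else 1.0) - dist.cdf(lo)
        expected.append(n * mass)

    # merge adjacent bins until every expected count >= 5
    obs, exp = observed[:], expected[:]
    i = 0
    while i < len(exp):
        if exp[i] < 5 and len(exp) > 1:
            j = i + 1 if i + 1 < len(exp) else i - 1
            exp[j] += exp[i]
            obs[j] += obs[i]
            del exp[i], obs[i]
            i = 0
        else:
            i += 1
    if len(exp) < 2:
        raise ValidationError("too few spacings to form two bins")

    obs_a = np.array(obs, dtype=float)
    exp_a = np.array(exp, dtype=float)
    exp_a *= obs_a.sum() / exp_a.sum()
    statistic = float(((obs_a - exp_a) ** 2 / exp_a).sum())
    dof = max(1, len(exp_a) - 1 - estimated_params)
    p = float(stats.chi2.sf(statistic, dof))
    return statistic, dof, p
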