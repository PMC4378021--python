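"""Fixed-difference calling and copy-number scanning between two libraries.

Two pileup tracks of a clonal haploid strain resequenced at two timepoints
are compared site by site.  A site is evaluated only where both libraries
fall inside depth bounds (minimum 10 reads; maximum 125% of each library's
mean coverage, overridable).  A fixed substitution is called where at least
99% of one library's reads agree on one base, at least 99% of the other
library's reads agree on a different base; indel calls apply the same
two-sided fractions to indel-evidence counts.  Called variants are
classified for their coding effect (synonymous / non-synonymous / nonsense /
frameshift / in-frame indel / non-coding) against the gene models, and read
depth over fixed windows is scanned for copy-number differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

from .core import (
    BASES,
    GeneModel,
    PileupTrack,
    ReferenceGenome,
    ValidationError,
    base_index_array,
    round_half_away,
)

__all__ = [
    "CallerParams",
    "VariantCall",
    "EffectAnnotation",
    "CNVWindow",
    "compute_depth_bounds",
    "call_fixed_differences",
    "classify_effect",
    "scan_cnv",
    "compare_cnv",
]

SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"


@dataclass(frozen=True)
class CallerParams:
    """Thresholds of the two-timepoint fixed-difference caller."""

    min_depth: int = 10
    max_depth_a: int | None = None  # default: round(1.25 x mean depth of A)
    max_depth_b: int | None = None
    consensus_a: float = 0.99
    consensus_b: float = 0.99
    max_depth_factor: float = 1.25

    def validate(self) -> None:
        if self.min_depth < 1:
            raise ValidationError("min_depth must be >= 1")
        for f in (self.consensus_a, self.consensus_b):
            if not 0.0 < f <= 1.0:
                raise ValidationError("consensus fractions must be in (0, 1]")


@dataclass(frozen=True)
class VariantCall:
    chrom: str
    pos: int  # substitution: the site; indels: the anchor base before the event
    ref_allele: str
    alt_allele: str
    kind: str  # substitution | insertion | deletion
    support_a: float
    support_b: float
    depth_a: int
    depth_b: int

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValidationError("alleles must differ")


def compute_depth_bounds(
    mean_depth: float,
    params: CallerParams | None = None,
    override: int | None = None,
) -> tuple[int, int]:
    """(min, max) depth bounds for one library.

    ``max`` is ``round(1.25 x mean)`` (half away from zero) unless an
    explicit override is supplied; ``min`` is the caller's minimum depth.
    """
    params = params or CallerParams()
    params.validate()
    if mean_depth <= 0:
        raise ValidationError("mean depth must be positive")
    if override is not None:
        return params.min_depth, int(override)
    return params.min_depth, int(round_half_away(params.max_depth_factor * mean_depth))


def _consensus(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (majority base index, majority fraction) from an (L,4) array."""
    depth = counts.sum(axis=1)
    idx = np.argmax(counts, axis=1)
    top = counts[np.arange(counts.shape[0]), idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(depth > 0, top / depth, 0.0)
    return idx, frac


def call_fixed_differences(
    track_a: PileupTrack,
    track_b: PileupTrack,
    genome: ReferenceGenome,
    params: CallerParams | None = None,
) -> list[VariantCall]:
    """Call fixed substitutions and indels between two libraries.

    Mean depths (over all non-N positions, zeros included) set the default
    maximum depth per library.  The caller is symmetric: each library must be
    near-unanimous for its own allele; swapping the tracks swaps the allele
    roles of every call and returns the same loci.  Haploid model: one
    alternate allele per site.
    """
    params = params or CallerParams()
    params.validate()
    if track_a.chromosome_lengths != track_b.chromosome_lengths:
        raise ValidationError("the two tracks cover different coordinate spaces")
    if track_a.chromosome_lengths != {
        c: len(s) for c, s in genome.chromosomes.items()
    }:
        raise ValidationError("tracks do not match the reference coordinate space")

    min_a, max_a = compute_depth_bounds(
        track_a.mean_depth(genome), params, params.max_depth_a
    )
    min_b, max_b = compute_depth_bounds(
        track_b.mean_depth(genome), params, params.max_depth_b
    )

    calls: list[VariantCall] = []
    for chrom, seq in genome.chromosomes.items():
        ref_idx = base_index_array(seq)
        counts_a = track_a.base_counts[chrom]
        counts_b = track_b.base_counts[chrom]
        depth_a = counts_a.sum(axis=1)
        depth_b = counts_b.sum(axis=1)
        evaluable = (
            (ref_idx >= 0)
            & (depth_a >= min_a)
            & (depth_a <= max_a)
            & (depth_b >= min_b)
            & (depth_b <= max_b)
        )

        # substitutions: near-unanimous, different bases in the two libraries
        idx_a, frac_a = _consensus(counts_a)
        idx_b, frac_b = _consensus(counts_b)
        hits = np.nonzero(
            evaluable
            & (frac_a >= params.consensus_a)
            & (frac_b >= params.consensus_b)
            & (idx_a != idx_b)
        )[0]
        for pos in hits:
            pos = int(pos)
            calls.append(
                VariantCall(
                    chrom=chrom,
                    pos=pos,
                    ref_allele=BASES[int(idx_a[pos])],
                    alt_allele=BASES[int(idx_b[pos])],
                    kind=SUBSTITUTION,
                    support_a=float(frac_a[pos]),
                    support_b=float(frac_b[pos]),
                    depth_a=int(depth_a[pos]),
                    depth_b=int(depth_b[pos]),
                )
            )

        # indels: the same two-sided fractions on indel-evidence counts
        for kind in (INSERTION, DELETION):
            ev_a = (track_a.ins_count if kind == INSERTION else track_a.del_count)[chrom]
            ev_b = (track_b.ins_count if kind == INSERTION else track_b.del_count)[chrom]
            with np.errstate(divide="ignore", invalid="ignore"):
                f_a = np.where(depth_a > 0, ev_a / depth_a, 0.0)
                f_b = np.where(depth_b > 0, ev_b / depth_b, 0.0)
            in_b = evaluable & ((1 - f_a) >= params.consensus_a) & (f_b >= params.consensus_b)
            in_a = evaluable & (f_a >= params.consensus_a) & ((1 - f_b) >= params.consensus_b)
            for pos in np.nonzero(in_b | in_a)[0]:
                pos = int(pos)
                carrier = track_b if in_b[pos] else track_a
                anchor = seq[pos]
                if kind == INSERTION:
                    registry = carrier.ins_seqs[chrom].get(pos)
                    if not registry:
                        continue
                    event_seq = registry.most_common(1)[0][0]
                    without, carrying = anchor, anchor + event_seq
                else:
                    registry = carrier.del_lens[chrom].get(pos)
                    if not registry:
                        continue
                    dlen = registry.most_common(1)[0][0]
                    if pos + 1 + dlen > len(seq):
                        continue
                    without, carrying = seq[pos : pos + 1 + dlen], anchor
                if in_b[pos]:
                    ref_allele, alt_allele = without, carrying
                else:
                    ref_allele, alt_allele = carrying, without
                calls.append(
                    VariantCall(
                        chrom=chrom,
                        pos=pos,
                        ref_allele=ref_allele,
                        alt_allele=alt_allele,
                        kind=kind,
                        support_a=float((1 - f_a[pos]) if in_b[pos] else f_a[pos]),
                        support_b=float(f_b[pos] if in_b[pos] else (1 - f_b[pos])),
                        depth_a=int(depth_a[pos]),
                        depth_b=int(depth_b[pos]),
                    )
                )

    order = {c: i for i, c in enumerate(genome.chromosomes)}
    calls.sort(key=lambda v: (order[v.chrom], v.pos, v.kind))
    return calls


# ---------------------------------------------------------------------------
# Effect classification
# ---------------------------------------------------------------------------

SYNONYMOUS = "synonymous"
NON_SYNONYMOUS = "non-synonymous"
NONSENSE = "nonsense"
FRAMESHIFT = "frameshift"
IN_FRAME_INDEL = "in-frame indel"
NON_CODING = "non-coding"


@dataclass(frozen=True)
class EffectAnnotation:
    variant: VariantCall
    gene_id: str | None
    effect: str
    old_codon: str | None = None
    new_codon: str | None = None
    old_aa: str | None = None
    new_aa: str | None = None
    note: str | None = None


def _cds_offset(gene: GeneModel, pos: int) -> int | None:
    """Offset of a genomic position within the gene's spliced CDS, reading
    5' to 3' on the coding strand; None when the position is intronic or
    outside the gene."""
    acc = 0
    for s, e in gene.exons:
        if s <= pos < e:
            fwd = acc + (pos - s)
            if gene.strand == "+":
                return fwd
            return gene.cds_length - 1 - fwd
        acc += e - s
    return None


def _affected_interval(variant: VariantCall) -> tuple[int, int]:
    if variant.kind == SUBSTITUTION:
        return variant.pos, variant.pos + 1
    if variant.kind == DELETION:
        length = abs(len(variant.ref_allele) - len(variant.alt_allele))
        return variant.pos + 1, variant.pos + 1 + length
    # insertion: the point between pos and pos + 1
    return variant.pos, variant.pos + 2


def classify_effect(
    variant: VariantCall,
    genes: list[GeneModel],
    genome: ReferenceGenome,
) -> EffectAnnotation:
    """Codon-level effect of a variant under the standard genetic code.

    Substitutions in a CDS are synonymous, nonsense (stop gained) or
    non-synonymous (start-loss noted); CDS indels are frameshifts unless
    their length is a multiple of three.  Variants outside all CDS exons are
    non-coding.
    """
    seq = genome.chromosomes.get(variant.chrom)
    if seq is None or not 0 <= variant.pos < len(seq):
        raise ValidationError(f"variant position outside genome: {variant}")
    if variant.kind == SUBSTITUTION and seq[variant.pos] != variant.ref_allele:
        raise ValidationError(
            f"variant reference allele {variant.ref_allele!r} does not match "
            f"genome base {seq[variant.pos]!r} at {variant.chrom}:{variant.pos}"
        )

    lo, hi = _affected_interval(variant)
    gene = None
    for g in genes:
        if g.chrom != variant.chrom:
            continue
        for s, e in g.exons:
            if variant.kind == INSERTION:
                # coding only when the insertion point is strictly inside an exon
                if s <= lo and hi <= e:
                    gene = g
                    break
            elif lo < e and s < hi:
                gene = g
                break
        if gene:
            break

    if gene is None:
        return EffectAnnotation(variant=variant, gene_id=None, effect=NON_CODING)

    if variant.kind != SUBSTITUTION:
        length = abs(len(variant.ref_allele) - len(variant.alt_allele))
        effect = FRAMESHIFT if length % 3 else IN_FRAME_INDEL
        return EffectAnnotation(variant=variant, gene_id=gene.gene_id, effect=effect)

    offset = _cds_offset(gene, variant.pos)
    if offset is None:  # intronic
        return EffectAnnotation(variant=variant, gene_id=None, effect=NON_CODING)

    cds = gene.cds_sequence(genome)
    codon_i = offset // 3
    within = offset % 3
    old_codon = cds[codon_i * 3 : codon_i * 3 + 3]
    alt = variant.alt_allele
    if gene.strand == "-":
        alt = str(Seq(alt).reverse_complement())
    new_codon = old_codon[:within] + alt + old_codon[within + 1 :]
    old_aa = str(Seq(old_codon).translate())
    new_aa = str(Seq(new_codon).translate())

    if new_aa == old_aa:
        effect, note = SYNONYMOUS, None
    elif new_aa == "*":
        effect, note = NONSENSE, None
    else:
        effect = NON_SYNONYMOUS
        note = "start_lost" if codon_i == 0 else None
    return EffectAnnotation(
        variant=variant,
        gene_id=gene.gene_id,
        effect=effect,
        old_codon=old_codon,
        new_codon=new_codon,
        old_aa=old_aa,
        new_aa=new_aa,
        note=note,
    )


# ---------------------------------------------------------------------------
# Copy-number scan
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CNVWindow:
    chrom: str
    start: int
    width: int
    mean_depth: float
    ratio: float
    copy_estimate: int


def scan_cnv(
    track: PileupTrack,
    genome: ReferenceGenome,
    window: int = 50,
    ratio_threshold: float = 2.0,
) -> list[CNVWindow]:
    """Flag fixed-width windows whose mean depth is at least
    ``ratio_threshold`` times the genome-wide mean; the integer copy estimate
    is the rounded depth ratio.  The final partial window of each chromosome
    is evaluated with its own mean."""
    if window < 1:
        raise ValidationError("window must be >= 1")
    genome_mean = track.mean_depth(genome)
    if genome_mean <= 0:
        raise ValidationError("track has zero mean depth")

    flagged: list[CNVWindow] = []
    for chrom, seq in genome.chromosomes.items():
        depth = track.depth(chrom).astype(float)
        L = len(depth)
        for start in range(0, L, window):
            w = depth[start : start + window]
            mean = float(w.mean())
            ratio = mean / genome_mean
            if ratio >= ratio_threshold:
                flagged.append(
                    CNVWindow(
                        chrom=chrom,
                        start=start,
                        width=len(w),
                        mean_depth=mean,
                        ratio=ratio,
                        copy_estimate=int(round_half_away(ratio)),
                    )
                )
    return flagged


def compare_cnv(
    flags_a: list[CNVWindow], flags_b: list[CNVWindow]
) -> list[tuple[CNVWindow, str]]:
    """Windows flagged in exactly one strain (symmetric difference).

    An empty result means no copy-number change between the two timepoints,
    even when both strains individually carry (shared) amplifications.
    """
    def keys(flags):
        return {(w.chrom, w.start, w.width): w for w in flags}

    ka, kb = keys(flags_a), keys(flags_b)
    by_pos_a = {(k[0], k[1]) for k in ka}
    by_pos_b = {(k[0], k[1]) for k in kb}
    # same windowing required: a window present in both by position must agree in width
    for (chrom, start) in by_pos_a & by_pos_b:
        wa = next(w for w in flags_a if (w.chrom, w.start) == (chrom, start))
        wb = next(w for w in flags_b if (w.chrom, w.start) == (chrom, start))
        if wa.width != wb.width:
            raise ValidationError("window grids of the two scans differ")

    out: list[tuple[CNVWindow, str]] = []
    for k, w in ka.items():
        if k not in kb:
            out.append((w, "a"))
    for k, w in kb.items():
        if k not in ka:
            out.append((w, "b"))
    out.sort(key=lambda t: (t[0].chrom, t[0].start))
    return out
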