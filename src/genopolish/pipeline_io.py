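"""Readers, writers, configuration and orchestration.

On-disk conventions: FASTA for sequences; GFF3 (1-based inclusive) for gene
and repeat annotations; a show-coords-like TSV dialect (1-based inclusive)
for scaffold-to-reference alignments; a pileup TSV dialect (1-based) for
per-site counts; a pair-placement TSV (1-based positions); minimal VCF-4
style output for variant calls and corrections.  In memory everything is
0-based half-open; conversions happen only here.

:func:`run_pipeline` chains the whole synthetic study: simulate a genome and
two strains, evaluate a fragmented assembly against the reference, close the
reference's gaps from the scaffolds, and call the fixed differences and
copy-number changes between the two strain libraries.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from collections import Counter
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import assembly_eval, genome_improver, strain_compare, synthetic_data
from .core import (
    ALPHABET,
    AlignmentRecord,
    GeneModel,
    PileupTrack,
    ReferenceGenome,
    RepeatInterval,
    ValidationError,
    round_half_away,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_coords",
    "write_coords",
    "read_pileup",
    "write_pileup",
    "read_pairs",
    "write_pairs",
    "write_vcf",
    "PipelineConfig",
    "run_pipeline",
]

logger = logging.getLogger("genopolish")

__version__ = "0.1.0"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> ReferenceGenome:
    """Read a multi-record FASTA into a genome, preserving record order.

    Lowercase input is uppercased with a warning; duplicate ids or illegal
    characters raise an error naming the record; an empty file yields an
    empty genome with a warning.
    """
    chromosomes: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chromosomes:
            raise ValidationError(f"duplicate record id {rec.id!r} in {path}")
        seq = str(rec.seq)
        if seq != seq.upper():
            warnings.warn(f"record {rec.id!r}: lowercase bases uppercased")
            seq = seq.upper()
        bad = set(seq) - ALPHABET
        if bad:
            raise ValidationError(
                f"record {rec.id!r}: illegal characters {sorted(bad)}"
            )
        chromosomes[rec.id] = seq
    if not chromosomes:
        warnings.warn(f"{path}: no FASTA records found")
    return ReferenceGenome(chromosomes)


def write_fasta(
    genome: ReferenceGenome | dict[str, str], path: str | Path, width: int = 80
) -> None:
    chromosomes = (
        genome.chromosomes if isinstance(genome, ReferenceGenome) else genome
    )
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in chromosomes.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def write_gff3(
    genes: list[GeneModel],
    repeats: list[RepeatInterval],
    path: str | Path,
) -> None:
    """Write gene models (gene/mRNA/CDS, with phase) and repeat regions,
    1-based inclusive coordinates."""
    lines = ["##gff-version 3"]
    for g in genes:
        span_s, span_e = g.span
        attrs = f"ID={g.gene_id}"
        lines.append(
            f"{g.chrom}\tgenopolish\tgene\t{span_s + 1}\t{span_e}\t.\t{g.strand}\t.\t{attrs}"
        )
        lines.append(
            f"{g.chrom}\tgenopolish\tmRNA\t{span_s + 1}\t{span_e}\t.\t{g.strand}\t.\t"
            f"ID={g.gene_id}.mRNA;Parent={g.gene_id}"
        )
        exons = g.exons if g.strand == "+" else list(reversed(g.exons))
        acc = 0
        phased = {}
        for s, e in exons:
            phased[(s, e)] = (3 - acc % 3) % 3
            acc += e - s
        for s, e in g.exons:
            lines.append(
                f"{g.chrom}\tgenopolish\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t{phased[(s, e)]}\t"
                f"ID={g.gene_id}.cds;Parent={g.gene_id}.mRNA"
            )
    for i, r in enumerate(repeats):
        lines.append(
            f"{r.chrom}\tgenopolish\trepeat_region\t{r.start + 1}\t{r.end}\t.\t.\t.\t"
            f"ID=repeat{i + 1:04d}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(
    path: str | Path,
) -> tuple[list[GeneModel], list[RepeatInterval]]:
    """Read gene and repeat annotations back into internal 0-based half-open
    coordinates.  A gene whose total CDS length is not a multiple of three is
    kept but logged as a validation warning."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        exons: list[tuple[int, int]] = []
        for mrna in db.children(gene, featuretype="mRNA"):
            for cds in db.children(mrna, featuretype="CDS", order_by="start"):
                exons.append((cds.start - 1, cds.end))
        exons.sort()
        model = GeneModel(
            gene_id=gene.id, chrom=gene.seqid, strand=gene.strand, exons=exons
        )
        if model.cds_length % 3:
            logger.warning(
                "gene %s: CDS length %d is not a multiple of 3",
                model.gene_id,
                model.cds_length,
            )
        genes.append(model)
    repeats = [
        RepeatInterval(r.seqid, r.start - 1, r.end)
        for r in db.features_of_type("repeat_region", order_by="start")
    ]
    return genes, repeats


# ---------------------------------------------------------------------------
# Coords dialect (show-coords-like)
# ---------------------------------------------------------------------------

_COORDS_COLUMNS = [
    "ref_chrom",
    "ref_start",
    "ref_end",
    "scaffold",
    "scf_start",
    "scf_end",
    "strand",
    "pct_identity",
]


def write_coords(records: list[AlignmentRecord], path: str | Path) -> None:
    rows = [
        {
            "ref_chrom": r.ref_chrom,
            "ref_start": r.ref_start + 1,
            "ref_end": r.ref_end,
            "scaffold": r.scaffold,
            "scf_start": r.scf_start + 1,
            "scf_end": r.scf_end,
            "strand": r.strand,
            "pct_identity": r.identity,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_COORDS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_coords(path: str | Path) -> list[AlignmentRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _COORDS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"coords file lacks columns {missing}")
    return [
        AlignmentRecord(
            scaffold=str(row.scaffold),
            scf_start=int(row.scf_start) - 1,
            scf_end=int(row.scf_end),
            ref_chrom=str(row.ref_chrom),
            ref_start=int(row.ref_start) - 1,
            ref_end=int(row.ref_end),
            strand=str(row.strand),
            identity=float(row.pct_identity),
        )
        for row in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Pileup dialect
# ---------------------------------------------------------------------------

_PILEUP_COLUMNS = [
    "chrom",
    "pos",
    "ref_base",
    "depth",
    "count_A",
    "count_C",
    "count_G",
    "count_T",
    "ins_count",
    "ins_seqs",
    "del_count",
    "del_lens",
]


def _fmt_registry(counter: Counter | None) -> str:
    if not counter:
        return "."
    return ",".join(f"{k}:{v}" for k, v in sorted(counter.items(), key=lambda kv: str(kv[0])))


def write_pileup(track: PileupTrack, genome: ReferenceGenome, path: str | Path) -> None:
    """Write only covered or evidence-bearing sites (sparse)."""
    frames = []
    for chrom, seq in genome.chromosomes.items():
        counts = track.base_counts[chrom]
        depth = counts.sum(axis=1)
        ins = track.ins_count[chrom]
        dele = track.del_count[chrom]
        keep = (depth > 0) | (ins > 0) | (dele > 0)
        pos = np.nonzero(keep)[0]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos + 1,
                    "ref_base": [seq[p] for p in pos],
                    "depth": depth[pos],
                    "count_A": counts[pos, 0],
                    "count_C": counts[pos, 1],
                    "count_G": counts[pos, 2],
                    "count_T": counts[pos, 3],
                    "ins_count": ins[pos],
                    "ins_seqs": [
                        _fmt_registry(track.ins_seqs[chrom].get(int(p))) for p in pos
                    ],
                    "del_count": dele[pos],
                    "del_lens": [
                        _fmt_registry(track.del_lens[chrom].get(int(p))) for p in pos
                    ],
                }
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=_PILEUP_COLUMNS)
    )
    df.to_csv(path, sep="\t", index=False)


def read_pileup(path: str | Path, genome: ReferenceGenome) -> PileupTrack:
    df = pd.read_csv(path, sep="\t", dtype={"ins_seqs": str, "del_lens": str})
    missing = [c for c in _PILEUP_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"pileup file lacks columns {missing}")
    track = PileupTrack({c: len(s) for c, s in genome.chromosomes.items()})
    for row in df.itertuples(index=False):
        chrom = str(row.chrom)
        if chrom not in track.base_counts:
            raise ValidationError(f"pileup names unknown chromosome {chrom!r}")
        p = int(row.pos) - 1
        track.base_counts[chrom][p] = [row.count_A, row.count_C, row.count_G, row.count_T]
        track.ins_count[chrom][p] = int(row.ins_count)
        track.del_count[chrom][p] = int(row.del_count)
        if isinstance(row.ins_seqs, str) and row.ins_seqs != ".":
            c = Counter()
            for item in row.ins_seqs.split(","):
                k, v = item.split(":")
                c[k] = int(v)
            track.ins_seqs[chrom][p] = c
        if isinstance(row.del_lens, str) and row.del_lens != ".":
            c = Counter()
            for item in row.del_lens.split(","):
                k, v = item.split(":")
                c[int(k)] = int(v)
            track.del_lens[chrom][p] = c
    return track


# ---------------------------------------------------------------------------
# Pair placements
# ---------------------------------------------------------------------------


def write_pairs(pairs: pd.DataFrame, path: str | Path) -> None:
    out = pairs.copy()
    out["end1_pos"] = out["end1_pos"] + 1
    out["end2_pos"] = out["end2_pos"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_pairs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["end1_pos"] = df["end1_pos"] - 1
    df["end2_pos"] = df["end2_pos"] - 1
    return df


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_vcf(
    calls: list[strain_compare.VariantCall],
    genome: ReferenceGenome,
    path: str | Path,
) -> None:
    """Minimal VCF-4-style output with TYPE, SF_A, SF_B, DP_A, DP_B INFO keys."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=genopolish {__version__}",
    ]
    for chrom, seq in genome.chromosomes.items():
        lines.append(f"##contig=<ID={chrom},length={len(seq)}>")
    for key, desc in [
        ("TYPE", "Variant class"),
        ("SF_A", "Support fraction in library A"),
        ("SF_B", "Support fraction in library B"),
        ("DP_A", "Depth in library A"),
        ("DP_B", "Depth in library B"),
    ]:
        num_type = "String" if key == "TYPE" else ("Integer" if key.startswith("DP") else "Float")
        lines.append(
            f'##INFO=<ID={key},Number=1,Type={num_type},Description="{desc}">'
        )
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in calls:
        info = (
            f"TYPE={v.kind};SF_A={v.support_a:.4f};SF_B={v.support_b:.4f};"
            f"DP_A={v.depth_a};DP_B={v.depth_b}"
        )
        lines.append(
            f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref_allele}\t{v.alt_allele}\t.\tPASS\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """All knobs of the synthetic study, with validated ranges."""

    seed: int = 1
    outdir: str = "genopolish_run"
    verbosity: str = "INFO"

    # genome
    chromosome_lengths: tuple[int, ...] = (60_000, 50_000, 40_000)
    n_genes: int = 60
    repeat_fraction: float = 0.02
    n_gaps: int = 12
    gc: float = 0.58

    # derived strain (event inventory of a lab-evolution comparison)
    substitutions: int = 8
    deletions: int = 2
    insertions: int = 1
    duplications: int = 1

    # sequencing
    depth_a: float = 175.0
    depth_b: float = 205.0
    error_rate: float = 0.002

    # assembly
    n_scaffolds: int = 24
    misjoin_translocations: int = 5
    misjoin_relocations: int = 3
    misjoin_inversions: int = 0

    # thresholds
    min_identity: float = 95.0
    max_overlap: float = 0.95
    min_scaffold_length: int = 500
    relocation_tolerance: int = 1000
    recruit_min_align: int = 200
    recruit_min_identity: float = 95.0
    recruit_min_flank: int = 50
    min_depth: int = 10
    max_depth_a: int | None = None
    max_depth_b: int | None = None
    consensus_a: float = 0.99
    consensus_b: float = 0.99
    cnv_window: int = 50
    cnv_ratio: float = 2.0
    saturation_depths: tuple[float, ...] = (10.0, 25.0, 80.0, 125.0)

    def validate(self) -> None:
        for name, f in [("consensus_a", self.consensus_a), ("consensus_b", self.consensus_b)]:
            if not 0.0 < f <= 1.0:
                raise ValidationError(f"{name} must be in (0, 1], got {f}")
        if not 0.0 <= self.max_overlap <= 1.0:
            raise ValidationError("max_overlap must be in [0, 1]")
        if not 0.0 <= self.min_identity <= 100.0:
            raise ValidationError("min_identity must be in [0, 100]")
        if self.error_rate < 0 or self.error_rate >= 0.25:
            raise ValidationError("error_rate must be in [0, 0.25)")
        if self.depth_a <= 0 or self.depth_b <= 0:
            raise ValidationError("depths must be positive")
        if self.min_depth < 1:
            raise ValidationError("min_depth must be >= 1")
        if any(d <= 0 for d in self.saturation_depths):
            raise ValidationError("saturation depths must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValidationError("config must be a YAML mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("chromosome_lengths", "saturation_depths"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic study and return the aggregate report.

    Stages run in order: simulate -> evaluate assembly -> improve reference
    -> compare strains.  Stage outputs are written under ``config.outdir``
    before the aggregate report; a failure aborts with a stage-named error.
    Deterministic for fixed (config, seed).
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 6)
    report: dict = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
        }
    }

    def stage(name):
        logger.info("stage %s", name)

    # --- simulate -------------------------------------------------------
    stage("simulate")
    try:
        bundle = synthetic_data.generate_genome(
            synthetic_data.GenomeConfig(
                chromosome_lengths=config.chromosome_lengths,
                n_genes=config.n_genes,
                repeat_fraction=config.repeat_fraction,
                n_gaps=config.n_gaps,
                gc=config.gc,
            ),
            seed=seeds[0],
        )
        mut_spec = synthetic_data.MutationSpec(
            substitutions=config.substitutions,
            deletions=config.deletions,
            insertions=config.insertions,
            duplications=config.duplications,
        )
        _, truth = synthetic_data.mutate_strain(
            bundle.genome, mut_spec, seed=seeds[1], genes=bundle.genes
        )
        track_a, _ = synthetic_data.simulate_pileup(
            bundle.genome, config.depth_a, config.error_rate, seed=seeds[2]
        )
        track_b, pairs_b = synthetic_data.simulate_pileup(
            bundle.genome, config.depth_b, config.error_rate, seed=seeds[3], truth=truth
        )
        assembly = synthetic_data.fragment_with_misjoins(
            bundle.truth_genome,
            config.n_scaffolds,
            synthetic_data.MisjoinSpec(
                translocation=config.misjoin_translocations,
                relocation=config.misjoin_relocations,
                inversion=config.misjoin_inversions,
            ),
            seed=seeds[4],
        )
        write_fasta(bundle.genome, outdir / "reference.fasta")
        write_fasta(assembly.scaffolds, outdir / "scaffolds.fasta")
        write_gff3(bundle.genes, bundle.repeats, outdir / "annotation.gff3")
        write_coords(assembly.records, outdir / "alignments.tsv")
        (outdir / "truth.json").write_text(truth.to_json())
        (outdir / "truth.tsv").write_text(truth.to_tsv())
    except Exception as exc:
        raise RuntimeError(f"stage simulate failed: {exc}") from exc

    # --- evaluate -------------------------------------------------------
    stage("eval-assembly")
    try:
        fparams = assembly_eval.FilterParams(
            min_identity=config.min_identity,
            max_overlap=config.max_overlap,
            min_scaffold_length=config.min_scaffold_length,
        )
        scaffold_lengths = {k: len(v) for k, v in assembly.scaffolds.items()}
        logger.info(
            "filter thresholds: identity>=%s overlap<=%s scaffold>%s",
            fparams.min_identity, fparams.max_overlap, fparams.min_scaffold_length,
        )
        filtered = assembly_eval.filter_alignments(
            assembly.records, fparams, scaffold_lengths
        )
        events = assembly_eval.classify_misjoins(
            filtered, bundle.repeats, tolerance=config.relocation_tolerance
        )
        correctness = assembly_eval.correctness_report(events, len(assembly.scaffolds))
        contiguity = assembly_eval.contiguity_stats(
            scaffold_lengths, filtered, bundle.genome, bundle.genes
        )
        saturation = assembly_eval.saturation_curve(
            pairs_b,
            [d for d in config.saturation_depths],
            bundle.genome,
            seed=seeds[5],
        )
        report["correctness"] = {
            "counts": correctness.counts,
            "n_scaffolds": correctness.n_scaffolds,
            "mean_misjoins": correctness.mean_misjoins_rounded,
            "pct_misassembled": correctness.pct_misassembled_rounded,
        }
        report["contiguity"] = {
            "n_scaffolds": contiguity.n_scaffolds,
            "n50": contiguity.n50,
            "total_size": contiguity.total_size,
            "pct_reference_covered": round_half_away(contiguity.pct_reference_covered, 1),
            "pct_cds_covered": round_half_away(contiguity.pct_cds_covered, 1),
            "pct_intergenic_covered": round_half_away(contiguity.pct_intergenic_covered, 1),
            "n_complete_cds": contiguity.n_complete_cds,
            "pct_complete_cds": round_half_away(contiguity.pct_complete_cds, 1),
        }
        report["saturation"] = [
            {"depth": d, "fraction_covered": round(f, 4)} for d, f in saturation
        ]
    except Exception as exc:
        raise RuntimeError(f"stage eval-assembly failed: {exc}") from exc

    # --- improve --------------------------------------------------------
    stage("close-gaps")
    try:
        gaps = genome_improver.find_gaps(bundle.genome)
        rparams = genome_improver.RecruitParams(
            min_align=config.recruit_min_align,
            min_identity=config.recruit_min_identity,
            min_flank=config.recruit_min_flank,
        )
        closures = genome_improver.recruit_scaffold_closures(
            gaps, filtered, assembly.scaffolds, rparams
        )
        improved = genome_improver.apply_closures(bundle.genome, closures)
        corrections = genome_improver.correct_reference_bases(
            bundle.genome, {"dna": track_b}
        )
        accounting = genome_improver.gap_accounting(
            {"recruitment": len(closures)}, len(gaps)
        )
        remaining = genome_improver.find_gaps(improved)
        if len(remaining) >= 3:
            chi2, dof, p = genome_improver.gap_spacing_test(
                remaining, {c: len(s) for c, s in improved.chromosomes.items()}
            )
            spacing = {"chi2": round(chi2, 3), "dof": dof, "p_value": round(p, 4)}
        else:
            spacing = None
        write_fasta(improved, outdir / "improved_reference.fasta")
        report["gap_closing"] = {
            "initial_gaps": accounting.initial,
            "closed": accounting.total_closed,
            "remaining": accounting.remaining,
            "stages": accounting.stages,
            "n_base_corrections": len(corrections),
            "spacing_test": spacing,
        }
    except Exception as exc:
        raise RuntimeError(f"stage close-gaps failed: {exc}") from exc

    # --- compare --------------------------------------------------------
    stage("call-variants")
    try:
        cparams = strain_compare.CallerParams(
            min_depth=config.min_depth,
            max_depth_a=config.max_depth_a,
            max_depth_b=config.max_depth_b,
            consensus_a=config.consensus_a,
            consensus_b=config.consensus_b,
        )
        calls = strain_compare.call_fixed_differences(
            track_a, track_b, bundle.genome, cparams
        )
        effects = [
            strain_compare.classify_effect(v, bundle.genes, bundle.genome)
            for v in calls
        ]
        cnv_a = strain_compare.scan_cnv(
            track_a, bundle.genome, config.cnv_window, config.cnv_ratio
        )
        cnv_b = strain_compare.scan_cnv(
            track_b, bundle.genome, config.cnv_window, config.cnv_ratio
        )
        cnv_diff = strain_compare.compare_cnv(cnv_a, cnv_b)
        write_vcf(calls, bundle.genome, outdir / "variants.vcf")
        var_rows = [
            {
                "chrom": v.chrom,
                "position": v.pos + 1,
                "allele_a": v.ref_allele,
                "allele_b": v.alt_allele,
                "type": e.effect,
                "cds": e.gene_id or "non coding",
                "class": v.kind,
            }
            for v, e in zip(calls, effects)
        ]
        pd.DataFrame(
            var_rows,
            columns=["chrom", "position", "allele_a", "allele_b", "type", "cds", "class"],
        ).to_csv(outdir / "variants.tsv", sep="\t", index=False)
        report["variants"] = {
            "n_calls": len(calls),
            "by_class": dict(Counter(v.kind for v in calls)),
            "by_effect": dict(Counter(e.effect for e in effects)),
            "table": var_rows,
        }
        report["cnv"] = {
            "windows_flagged_a": len(cnv_a),
            "windows_flagged_b": len(cnv_b),
            "windows_differing": len(cnv_diff),
            "copy_estimates_b": sorted({w.copy_estimate for w in cnv_b}),
        }
    except Exception as exc:
        raise RuntimeError(f"stage call-variants failed: {exc}") from exc

    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report
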