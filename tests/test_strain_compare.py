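"""Depth bounds, fixed-difference calling, effect classification and CNV."""

from collections import Counter

import numpy as np
import pytest
from Bio.Seq import Seq

from genopolish import strain_compare as sc
from genopolish import synthetic_data as sd
from genopolish.core import (
    GeneModel,
    PileupTrack,
    ReferenceGenome,
    ValidationError,
    revcomp,
)


class TestDepthBounds:
    def test_mean_205_gives_max_256(self):
        assert sc.compute_depth_bounds(205) == (10, 256)

    def test_degenerate_low_mean(self):
        assert sc.compute_depth_bounds(8) == (10, 10)

    def test_override_wins(self):
        assert sc.compute_depth_bounds(175, override=220) == (10, 220)

    def test_nonpositive_mean_raises(self):
        with pytest.raises(ValidationError):
            sc.compute_depth_bounds(0)


def _uniform_track(genome, depth=100):
    track = PileupTrack({c: len(s) for c, s in genome.chromosomes.items()})
    for chrom, seq in genome.chromosomes.items():
        idx = np.array(["ACGTN".index(b) for b in seq])
        counts = np.zeros((len(seq), 4), dtype=np.int32)
        for b in range(4):
            counts[idx == b, b] = depth
        track.base_counts[chrom] = counts
    return track


class TestCallFixedDifferences:
    def test_clean_fixed_substitution_is_called(self):
        genome = ReferenceGenome({"c": "T" * 2000})
        a = _uniform_track(genome, 100)
        b = _uniform_track(genome, 120)
        b.base_counts["c"][700] = [0, 120, 0, 0]  # all C in library B
        calls = sc.call_fixed_differences(a, b, genome)
        assert [(v.pos, v.ref_allele, v.alt_allele, v.kind) for v in calls] == [
            (700, "T", "C", "substitution")
        ]

    def test_98_percent_alternate_is_not_fixed(self):
        genome = ReferenceGenome({"c": "T" * 2000})
        a = _uniform_track(genome, 100)
        b = _uniform_track(genome, 100)
        b.base_counts["c"][700] = [0, 98, 0, 2]
        assert sc.call_fixed_differences(a, b, genome) == []

    def test_low_depth_site_not_evaluated(self):
        genome = ReferenceGenome({"c": "T" * 2000})
        a = _uniform_track(genome, 100)
        b = _uniform_track(genome, 100)
        a.base_counts["c"][700] = [0, 0, 0, 9]
        b.base_counts["c"][700] = [0, 100, 0, 0]
        calls = sc.call_fixed_differences(
            a, b, genome, sc.CallerParams(max_depth_a=150, max_depth_b=150)
        )
        assert calls == []

    def test_identical_tracks_yield_no_calls(self):
        genome = ReferenceGenome({"c": "ACGT" * 500})
        a = _uniform_track(genome, 100)
        calls = sc.call_fixed_differences(a, _uniform_track(genome, 100), genome)
        assert calls == []

    def test_mismatched_coordinate_spaces_raise(self):
        g1 = ReferenceGenome({"c": "ACGT" * 500})
        g2 = ReferenceGenome({"c": "ACGT" * 400})
        with pytest.raises(ValidationError):
            sc.call_fixed_differences(
                _uniform_track(g1), _uniform_track(g2), g1
            )

    def test_swapping_tracks_swaps_allele_roles(self, strain_pair):
        genome = strain_pair["bundle"].genome
        fwd = sc.call_fixed_differences(
            strain_pair["track_a"], strain_pair["track_b"], genome
        )
        rev = sc.call_fixed_differences(
            strain_pair["track_b"], strain_pair["track_a"], genome
        )
        assert {(v.chrom, v.pos, v.kind) for v in fwd} == {
            (v.chrom, v.pos, v.kind) for v in rev
        }
        rev_by_key = {(v.chrom, v.pos, v.kind): v for v in rev}
        for v in fwd:
            w = rev_by_key[(v.chrom, v.pos, v.kind)]
            assert (v.ref_allele, v.alt_allele) == (w.alt_allele, w.ref_allele)

    def test_raising_consensus_never_adds_calls(self, strain_pair):
        genome = strain_pair["bundle"].genome
        prev = None
        for consensus in (0.95, 0.97, 0.99, 1.0):
            calls = sc.call_fixed_differences(
                strain_pair["track_a"],
                strain_pair["track_b"],
                genome,
                sc.CallerParams(consensus_a=consensus, consensus_b=consensus),
            )
            loci = {(v.chrom, v.pos, v.kind) for v in calls}
            if prev is not None:
                assert loci <= prev
            prev = loci

    def test_recovers_injected_inventory_at_study_depths(self, strain_pair):
        """175x/205x, 0.2% error: the 8+2+1 inventory is recovered exactly."""
        truth = strain_pair["truth"]
        genome = strain_pair["bundle"].genome
        calls = sc.call_fixed_differences(
            strain_pair["track_a"], strain_pair["track_b"], genome
        )
        called = {(v.kind, v.chrom, v.pos) for v in calls}
        expected = (
            {("substitution", s.chrom, s.pos) for s in truth.substitutions}
            | {("insertion", i.chrom, i.pos) for i in truth.insertions}
            | {("deletion", d.chrom, d.start - 1) for d in truth.deletions}
        )
        assert called == expected
        for v in calls:
            if v.kind == "substitution":
                s = next(t for t in truth.substitutions if (t.chrom, t.pos) == (v.chrom, v.pos))
                assert (v.ref_allele, v.alt_allele) == (s.ref, s.alt)


def _variant(genome, chrom, pos, alt, kind="substitution", ref=None):
    seq = genome.chromosomes[chrom]
    if kind == "substitution":
        return sc.VariantCall(chrom, pos, seq[pos], alt, kind, 1.0, 1.0, 100, 100)
    return sc.VariantCall(chrom, pos, ref, alt, kind, 1.0, 1.0, 100, 100)


@pytest.fixture(scope="module")
def toy():
    # + strand gene ATG AAA CTT CAA TGC TAA occupying [10, 28)
    coding = "ATGAAACTTCAATGCTAA"
    seq = "GGGGGGGGGG" + coding + "GGGGGGGGGGGG"
    genome = ReferenceGenome({"c": seq})
    gene = GeneModel("gplus", "c", "+", [(10, 28)])
    return genome, [gene]


class TestClassifyEffect:

    def test_third_position_wobble_is_synonymous(self, toy):
        genome, genes = toy
        # CTT -> CTC, both Leu (codon 2, third base at pos 18)
        ann = sc.classify_effect(_variant(genome, "c", 18, "C"), genes, genome)
        assert ann.effect == "synonymous"
        assert (ann.old_aa, ann.new_aa) == ("L", "L")

    def test_gln_to_stop_is_nonsense(self, toy):
        genome, genes = toy
        # CAA -> TAA at codon 3 (pos 19)
        ann = sc.classify_effect(_variant(genome, "c", 19, "T"), genes, genome)
        assert ann.effect == "nonsense"
        assert ann.new_aa == "*"

    def test_two_base_cds_deletion_is_frameshift(self, toy):
        genome, genes = toy
        ref = genome.chromosomes["c"][13:16]
        v = _variant(genome, "c", 13, ref[0], kind="deletion", ref=ref)
        ann = sc.classify_effect(v, genes, genome)
        assert ann.effect == "frameshift"

    def test_three_base_cds_deletion_is_in_frame(self, toy):
        genome, genes = toy
        ref = genome.chromosomes["c"][13:17]
        v = _variant(genome, "c", 13, ref[0], kind="deletion", ref=ref)
        assert sc.classify_effect(v, genes, genome).effect == "in-frame indel"

    def test_intergenic_substitution_is_non_coding(self, toy):
        genome, genes = toy
        ann = sc.classify_effect(_variant(genome, "c", 2, "A"), genes, genome)
        assert ann.effect == "non-coding" and ann.gene_id is None

    def test_mismatching_reference_allele_raises(self, toy):
        genome, genes = toy
        v = sc.VariantCall("c", 2, "A", "T", "substitution", 1.0, 1.0, 10, 10)
        with pytest.raises(ValidationError):
            sc.classify_effect(v, genes, genome)

    def test_agrees_with_full_cds_rebuild_oracle(self, bundle):
        """Classify every possible substitution in a few real gene models and
        compare against translating the fully rebuilt mutant CDS."""
        genome = bundle.truth_genome
        rng = np.random.default_rng(17)
        genes = [g for g in bundle.genes if len(g.exons) >= 1][:6]
        for gene in genes:
            positions = [p for s, e in gene.exons for p in range(s, e)]
            for pos in rng.choice(positions, size=25, replace=False):
                pos = int(pos)
                ref = genome.chromosomes[gene.chrom][pos]
                alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
                v = _variant(genome, gene.chrom, pos, alt)
                ann = sc.classify_effect(v, [gene], genome)

                # oracle: mutate the chromosome, rebuild and translate the CDS
                chrom_seq = genome.chromosomes[gene.chrom]
                mutant = ReferenceGenome(
                    {gene.chrom: chrom_seq[:pos] + alt + chrom_seq[pos + 1 :]}
                )
                old_prot = str(Seq(gene.cds_sequence(genome)).translate())
                new_prot = str(Seq(gene.cds_sequence(mutant)).translate())
                changed = [
                    (i, a, b) for i, (a, b) in enumerate(zip(old_prot, new_prot)) if a != b
                ]
                if not changed:
                    expect = "synonymous"
                elif changed[0][2] == "*":
                    expect = "nonsense"
                else:
                    expect = "non-synonymous"
                assert ann.effect == expect, (gene.gene_id, pos, ref, alt)


class TestScanCnv:
    def test_flat_track_flags_nothing(self, plain_genome):
        track = _uniform_track(plain_genome.genome, 80)
        for threshold in (1.5, 2.0, 4.0):
            assert sc.scan_cnv(track, plain_genome.genome, ratio_threshold=threshold) == []

    def test_quadrupled_region_flagged_with_copy_four(self, plain_genome):
        genome = plain_genome.genome
        truth = sd.TruthSet(duplications=[sd.Duplication("chr1", 30_000, 32_000, 4)])
        track, _ = sd.simulate_pileup(genome, 100, 0.002, seed=31, truth=truth)
        flagged = sc.scan_cnv(track, genome)
        inside = [w for w in flagged if 30_000 <= w.start < 32_000]
        assert len(inside) >= 0.8 * (2000 / 50)
        assert Counter(w.copy_estimate for w in inside).most_common(1)[0][0] == 4

    def test_injected_duplication_recovered_from_truth_set(self, strain_pair):
        genome = strain_pair["bundle"].genome
        dup = strain_pair["truth"].duplications[0]
        flagged = sc.scan_cnv(strain_pair["track_b"], genome)
        inside = [
            w for w in flagged if w.chrom == dup.chrom and dup.start <= w.start < dup.end
        ]
        n_windows = (dup.end - dup.start) // 50
        assert len(inside) >= 0.8 * n_windows
        assert Counter(w.copy_estimate for w in inside).most_common(1)[0][0] == dup.copies


class TestCompareCnv:
    def test_identical_flag_sets_cancel(self, strain_pair):
        genome = strain_pair["bundle"].genome
        flags = sc.scan_cnv(strain_pair["track_b"], genome)
        assert sc.compare_cnv(flags, flags) == []

    def test_duplication_in_one_strain_only_is_reported(self, strain_pair):
        genome = strain_pair["bundle"].genome
        flags_a = sc.scan_cnv(strain_pair["track_a"], genome)
        flags_b = sc.scan_cnv(strain_pair["track_b"], genome)
        diff = sc.compare_cnv(flags_a, flags_b)
        assert diff
        assert all(strain == "b" for _, strain in diff)

    def test_shared_duplication_cancels(self, plain_genome):
        genome = plain_genome.genome
        truth = sd.TruthSet(duplications=[sd.Duplication("chr1", 30_000, 32_000, 3)])
        ta, _ = sd.simulate_pileup(genome, 100, 0.002, seed=41, truth=truth)
        tb, _ = sd.simulate_pileup(genome, 100, 0.002, seed=42, truth=truth)
        fa = sc.scan_cnv(ta, genome)
        fb = sc.scan_cnv(tb, genome)
        assert fa and fb
        assert sc.compare_cnv(fa, fb) == []
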