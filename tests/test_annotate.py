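"""Folding optimality, hairpin evaluation, alignment, clustering,
classification partition and isomiR consolidation."""

from types import SimpleNamespace

import numpy as np
import pytest

from mirpipe import annotate as ann
from mirpipe import simdata as sd
from mirpipe._util import random_dna, revcomp
from mirpipe.readproc import UniqueTag
from oracles import best_nested_score, spearman_oracle


class TestFoldRna:
    def test_too_short_to_pair(self):
        fold = ann.fold_rna("ACGU")
        assert fold.score == 0 and fold.n_pairs == 0

    def test_forced_triple_gc_stem(self):
        fold = ann.fold_rna("GGGAAAACCC")
        assert fold.score == 9
        assert fold.dot_bracket() == "(((....)))"

    def test_u_and_t_are_equivalent(self):
        assert ann.fold_rna("GGGAAAACCC").score == ann.fold_rna("GGGAAAACCC".replace("T", "U")).score

    @pytest.mark.parametrize("n_seqs,length", [(120, 10), (60, 12)])
    def test_dp_matches_exhaustive_enumeration(self, n_seqs, length):
        rng = np.random.default_rng(length)
        for _ in range(n_seqs):
            seq = random_dna(rng, int(rng.integers(5, length + 1)))
            fold = ann.fold_rna(seq)
            assert fold.score == best_nested_score(seq), seq

    def test_adversarial_repeats(self):
        for seq in ("GCGCGCGCGCGC", "AUAUAUAUAUAU", "GGGGGGCCCCCC", "GUGUGUGUGUGU"):
            assert ann.fold_rna(seq).score == best_nested_score(seq), seq

    def test_traceback_is_deterministic(self):
        a, b = ann.fold_rna("GCGCGCGCGCGC"), ann.fold_rna("GCGCGCGCGCGC")
        assert (a.pairs == b.pairs).all()

    def test_pairing_validity_enforced(self):
        with pytest.raises(ValueError):  # not an involution
            ann.HairpinFold("GAAAACGAAAAC", np.array([5, -1, -1, -1, -1, -1, -1, -1, -1, -1, -1, -1]), 0)
        with pytest.raises(ValueError):  # pseudoknot 0-6 crossing 3-9
            ann.HairpinFold("GAAATTTCAAAG", np.array([6, -1, -1, 9, -1, -1, 0, -1, -1, 3, -1, -1]), 0)
        with pytest.raises(ValueError):  # loop shorter than the minimum
            ann.HairpinFold("GAAC", np.array([3, -1, -1, 0]), 0)


def _perfect_candidate(rng_seed=0, arm=30, loop=8, flank=60):
    rng = np.random.default_rng(rng_seed)
    arm5 = random_dna(rng, arm)
    hairpin = arm5 + random_dna(rng, loop) + revcomp(arm5)
    cand = random_dna(rng, flank) + hairpin + random_dna(rng, flank)
    mature = (flank + 4, flank + 26)  # 22 nt on the 5' arm
    return cand, mature, (flank + arm, flank + arm + loop)


class TestEvaluateHairpin:
    def test_constructed_hairpin_passes(self):
        cand, mature, _ = _perfect_candidate()
        ok, diag = ann.evaluate_hairpin(ann.fold_rna(cand), mature)
        assert ok and diag["mature_arm"] == "5p"

    def test_mature_spanning_loop_fails(self):
        cand, _, loop = _perfect_candidate()
        ok, diag = ann.evaluate_hairpin(ann.fold_rna(cand), (loop[0] - 8, loop[0] + 10))
        assert not ok and not diag["checks"]["mature_on_arm"]

    def test_mature_on_three_prime_arm(self):
        cand, _, loop = _perfect_candidate()
        ok, diag = ann.evaluate_hairpin(ann.fold_rna(cand), (loop[1] + 2, loop[1] + 24))
        assert ok and diag["mature_arm"] == "3p"

    def test_random_candidates_rarely_pass(self):
        rng = np.random.default_rng(42)
        passes = sum(
            ann.evaluate_hairpin(ann.fold_rna(random_dna(rng, 142)), (60, 82))[0]
            for _ in range(200)
        )
        assert passes / 200 < 0.05

    def test_interval_bounds_checked(self):
        with pytest.raises(ValueError):
            ann.evaluate_hairpin(ann.fold_rna("GGGAAAACCC"), (5, 20))


class TestAlignTag:
    PREC = "GATTACA" + "ACGTTGCAACGGTACCGGTTAA" + "CCCGGGTT"

    def test_exact_hit(self):
        hits = ann.align_tag("ACGTTGCAACGGTACCGGTTAA", {"P": self.PREC}, "known-precursor")
        assert len(hits) == 1
        assert hits[0].start == 7 and hits[0].end == 29 and hits[0].mismatches == 0

    def test_absent_tag(self):
        assert ann.align_tag("TTTTTTTTTTTTTTTTTT", {"P": self.PREC}, "known-precursor") == []

    def test_mismatch_tolerance(self):
        tag = "ACGTTGCAACGGTACCGGTTAC"
        assert ann.align_tag(tag, {"P": self.PREC}, "g", max_mismatches=1)
        assert not ann.align_tag(tag, {"P": self.PREC}, "g", max_mismatches=0)

    def test_n_counts_as_mismatch_everywhere(self):
        tag = "ACGTTGCAACGGTACCGGTTAN"
        hits = ann.align_tag(tag, {"P": self.PREC}, "g", max_mismatches=1)
        assert hits and hits[0].mismatches == 1
        assert not ann.align_tag(tag, {"P": self.PREC}, "g", max_mismatches=0)

    def test_minus_strand_on_genome(self):
        tag = "ACGTTGCAACGGTACCGGTTAA"
        hits = ann.align_tag(tag, {"chr": revcomp(self.PREC)}, "genome", strands="+-")
        assert len(hits) == 1 and hits[0].strand == "-"


class TestClustering:
    def _aln(self, start, end, tag="T", contig="c", strand="+"):
        return ann.TagAlignment(tag, contig, "genome", start, end, strand, 0)

    def test_overlapping_tags_one_locus(self):
        loci = ann.cluster_genomic_hits(
            [self._aln(100, 122, "a"), self._aln(102, 124, "b")], {}, 10
        )
        assert len(loci) == 1 and (loci[0].start, loci[0].end) == (100, 124)

    def test_distant_tags_two_loci(self):
        loci = ann.cluster_genomic_hits([self._aln(100, 122, "a"), self._aln(600, 622, "b")], {}, 10)
        assert len(loci) == 2

    def test_single_linkage_chain(self):
        alns = [self._aln(100 + 27 * i, 122 + 27 * i, f"t{i}") for i in range(5)]
        loci = ann.cluster_genomic_hits(alns, {}, 10)  # each gap is 5 nt
        assert len(loci) == 1 and loci[0].span == 130

    def test_strands_do_not_merge(self):
        loci = ann.cluster_genomic_hits(
            [self._aln(100, 122, "a", strand="+"), self._aln(105, 127, "b", strand="-")], {}, 10
        )
        assert len(loci) == 2


class TestExtractCandidate:
    GENOME = {"chr1": random_dna(np.random.default_rng(9), 1000)}

    def test_centered_locus(self):
        locus = ann.Locus("chr1", 489, 511, "+", {})
        cand, off = ann.extract_hairpin_candidate(self.GENOME, locus, 60)
        assert len(cand) == 142 and off == 60
        assert cand == self.GENOME["chr1"][429:571]

    def test_left_truncation(self):
        locus = ann.Locus("chr1", 10, 32, "+", {})
        cand, off = ann.extract_hairpin_candidate(self.GENOME, locus, 60)
        assert off == 10 and len(cand) == 92

    def test_minus_strand_is_reverse_complement(self):
        plus = ann.Locus("chr1", 489, 511, "+", {})
        minus = ann.Locus("chr1", 489, 511, "-", {})
        cp, _ = ann.extract_hairpin_candidate(self.GENOME, plus, 60)
        cm, om = ann.extract_hairpin_candidate(self.GENOME, minus, 60)
        assert cm == revcomp(cp) and om == 60

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            ann.extract_hairpin_candidate(self.GENOME, ann.Locus("chr1", 990, 1012, "+", {}), 60)


class TestIsomirGroups:
    def test_reference_is_most_abundant_and_counts_sum(self):
        groups = ann.build_isomir_groups(
            {("prec", "5p"): {"AAAA": UniqueTag("AAAA", 90, 10), "AAAC": UniqueTag("AAAC", 5, 5)}}
        )
        g = groups[0]
        assert g.reference == "AAAA" and (g.count_a, g.count_b) == (95, 15)

    def test_tie_breaks_longer_then_lexicographic(self):
        g = ann.build_isomir_groups(
            {("p", "5p"): {"CCCC": UniqueTag("CCCC", 10, 0), "AAAAA": UniqueTag("AAAAA", 10, 0)}}
        )[0]
        assert g.reference == "AAAAA"  # longer wins
        g = ann.build_isomir_groups(
            {("p", "5p"): {"CCCC": UniqueTag("CCCC", 10, 0), "AAAA": UniqueTag("AAAA", 10, 0)}}
        )[0]
        assert g.reference == "AAAA"  # then lexicographically smaller

    def test_empty_group_impossible(self):
        with pytest.raises(ValueError):
            ann.IsomiRGroup("p", "5p", {})

    def test_simulated_reference_is_zero_offset_mature(self, sim, classified):
        matures = {l.precursor.mature for l in sim.bundle.loci}
        hits = sum(g.reference in matures for g in classified.groups)
        assert hits / len(classified.groups) > 0.9


class TestSpearmanDiagnostic:
    def test_single_member_groups_give_perfect_correlation(self):
        groups = ann.build_isomir_groups(
            {("p%d" % i, "5p"): {f"SEQ{i}": UniqueTag(f"SEQ{i}", 10 * (i + 1), 1)} for i in range(4)}
        )
        r, _ = ann.isomir_reference_correlation(groups, "a")
        assert r == pytest.approx(1.0)

    def test_reversed_ranks(self):
        groups = [
            ann.IsomiRGroup("p1", "5p", {"A": UniqueTag("A", 1, 0), "X": UniqueTag("X", 0, 30)}),
            ann.IsomiRGroup("p2", "5p", {"B": UniqueTag("B", 2, 0), "Y": UniqueTag("Y", 0, 20)}),
            ann.IsomiRGroup("p3", "5p", {"C": UniqueTag("C", 3, 0), "Z": UniqueTag("Z", 0, 10)}),
        ]
        # references by combined count are X, Y, Z; library-a reference counts
        # are 0,0,0 -> use library b vs constructed totals
        r, _ = ann.isomir_reference_correlation(groups, "b")
        assert r == pytest.approx(1.0)

    def test_matches_definitional_oracle(self):
        rng = np.random.default_rng(1)
        groups = []
        for i in range(20):
            members = {
                f"R{i}": UniqueTag(f"R{i}", int(rng.integers(1, 200)), int(rng.integers(1, 200))),
                f"S{i}": UniqueTag(f"S{i}", int(rng.integers(0, 50)), int(rng.integers(0, 50))),
            }
            groups.append(ann.IsomiRGroup(f"p{i}", "5p", members))
        r, _ = ann.isomir_reference_correlation(groups, "a")
        ref = [g.reference_tag.count_a for g in groups]
        tot = [g.count_a for g in groups]
        assert r == pytest.approx(spearman_oracle(ref, tot), abs=1e-12)

    def test_too_few_groups(self):
        with pytest.raises(ValueError):
            ann.isomir_reference_correlation([], "a")


class TestClassification:
    def test_partition_of_tag_set(self, processed, classified):
        n_assigned = len(classified.assignments)
        n_unclassified = sum(t for t, _ in classified.unclassified.values())
        assert n_assigned + n_unclassified == len(processed.tags)
        groups = {g for g, _, _ in classified.assignments.values()}
        assert groups <= {"known", "conserved", "PPN"}

    def test_truth_agreement(self, sim, processed, classified):
        conf = sd.classification_confusion(
            classified.assignments, sim.bundle, sim.config,
            {s: (t.count_a, t.count_b) for s, t in processed.tags.items()},
        )
        assert sd.offdiagonal_rate(conf) <= 0.01

    def test_conserved_requires_genomic_presence(self):
        rng = np.random.default_rng(5)
        arm = random_dna(rng, 30)
        prec = arm + random_dna(rng, 10) + revcomp(arm)
        tag = arm[4:26]
        tags = {tag: UniqueTag(tag, 10, 10)}
        bundle_without = SimpleNamespace(
            known_precursors={}, conserved_precursors={"c1": prec},
            genome={"chr1": random_dna(rng, 500)},
        )
        res = ann.classify_tags(tags, bundle_without)
        assert res.records == [] and "unmapped" in res.unclassified
        bundle_with = SimpleNamespace(
            known_precursors={}, conserved_precursors={"c1": prec},
            genome={"chr1": random_dna(rng, 200) + prec + random_dna(rng, 200)},
        )
        res = ann.classify_tags(tags, bundle_with)
        assert [r.group for r in res.records] == ["conserved"]

    def test_known_takes_priority_over_conserved(self):
        rng = np.random.default_rng(8)
        arm = random_dna(rng, 30)
        prec = arm + random_dna(rng, 10) + revcomp(arm)
        tag = arm[4:26]
        bundle = SimpleNamespace(
            known_precursors={"k1": prec}, conserved_precursors={"c1": prec},
            genome={"chr1": prec},
        )
        res = ann.classify_tags({tag: UniqueTag(tag, 10, 0)}, bundle)
        assert res.assignments[tag][0] == "known"

    def test_strand_coherence(self, sim, processed, classified):
        """Classifying against the reverse-complemented genome yields the
        same records (groups, sequences, counts); only coordinates move."""
        flipped = SimpleNamespace(
            known_precursors=sim.bundle.known_precursors,
            conserved_precursors=sim.bundle.conserved_precursors,
            genome={c: revcomp(s) for c, s in sim.bundle.genome.items()},
        )
        res = ann.classify_tags(processed.tags, flipped)
        key = lambda r: (r.group, r.reference_sequence, r.count_a, r.count_b)
        assert sorted(map(key, res.records)) == sorted(map(key, classified.records))

    def test_unique_sequence_collapse(self):
        rng = np.random.default_rng(3)
        arm = random_dna(rng, 30)
        prec = arm + random_dna(rng, 10) + revcomp(arm)
        prec2 = random_dna(rng, 4) + arm + random_dna(rng, 8) + revcomp(arm)[:26]
        tag = arm[4:26]
        bundle = SimpleNamespace(
            known_precursors={"k1": prec, "k2": prec2}, conserved_precursors={},
            genome={"chr1": prec},
        )
        res = ann.classify_tags({tag: UniqueTag(tag, 10, 2)}, bundle)
        # the tag is assigned once, so both views carry its counts exactly once
        assert sum(r.count_a for r in res.unique_records) == 10
        assert len(res.unique_records) == 1

    def test_gff_export(self, tmp_path, classified):
        ann.write_loci_gff3(classified.loci, tmp_path / "loci.gff3")
        lines = (tmp_path / "loci.gff3").read_text().splitlines()
        assert lines[0] == "##gff-version 3"
        assert len(lines) == len(classified.loci) + 1
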