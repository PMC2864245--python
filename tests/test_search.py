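"""Six-frame translation, profile construction and the glocal scan."""

import math

import numpy as np
import pytest

from chromomine import search, synthetic as syn
from chromomine import _domains as lib
from chromomine.io import SequenceRecord, AMINO_ACID, NUCLEOTIDE, \
    reverse_complement

from helpers import sw_affine_best


def _aa_records(rows):
    return [SequenceRecord(f"s{i}", row, AMINO_ACID)
            for i, row in enumerate(rows)]


class TestSixFrameTranslate:
    def test_standard_code_frame1(self):
        frames = search.six_frame_translate(
            SequenceRecord("x", "ATGAAATAG"))
        assert frames[0].frame == 1
        assert frames[0].aa_sequence == "MK*"

    def test_reverse_complement_swaps_strands(self):
        rec = SequenceRecord("x", "ATGAAATAGGCATTT")
        rc = SequenceRecord("x", reverse_complement(rec.residues))
        fwd = {f.frame: f.aa_sequence
               for f in search.six_frame_translate(rec)}
        swapped = {f.frame: f.aa_sequence
                   for f in search.six_frame_translate(rc)}
        for i in (1, 2, 3):
            assert fwd[i] == swapped[-i]
            assert fwd[-i] == swapped[i]

    def test_ambiguity_translates_to_x_unless_unanimous(self):
        frames = search.six_frame_translate(SequenceRecord("x", "ATGNGGGGN"))
        # NGG is R or G (not unanimous) -> X; GGN is always G
        assert frames[0].aa_sequence == "MXG"

    def test_amino_acid_input_rejected(self):
        with pytest.raises(ValueError):
            search.six_frame_translate(
                SequenceRecord("p", "MKV", AMINO_ACID))

    def test_frame_map_is_three_nt_per_residue(self):
        rec = SequenceRecord("x", "ATGAAACCCGGGTTT")
        for frame in search.six_frame_translate(rec):
            for i in range(len(frame.aa_sequence)):
                a, b = frame.aa_to_nt(i, i + 1)
                assert b - a == 3
                codon = rec.residues[a:b]
                if frame.frame < 0:
                    codon = reverse_complement(codon)
                from chromomine._domains import translate_cds
                assert translate_cds(codon) == frame.aa_sequence[i]


class TestBuildProfile:
    def test_identical_sequences_no_pseudocount(self):
        profile = search.build_profile(_aa_records(["ACD", "ACD"]),
                                       pseudocount=0.0)
        assert profile.ncolumns == 3
        # emission 1.0 -> log-odds log2(20)
        assert np.isclose(profile.log_odds[0, 0], math.log2(20))
        assert profile.consensus == "ACD"

    def test_column_counting(self):
        profile = search.build_profile(
            _aa_records(["A", "A", "A", "C"]), pseudocount=0.0)
        # P(A)=0.75, P(C)=0.25
        assert np.isclose(2 ** profile.log_odds[0, 0] / 20, 0.75)
        assert np.isclose(2 ** profile.log_odds[0, 1] / 20, 0.25)

    def test_pseudocount_formula(self):
        profile = search.build_profile(_aa_records(["A", "A"]),
                                       pseudocount=1.0)
        # (2+1) / (2 + 20*1) = 3/22
        assert np.isclose(2 ** profile.log_odds[0, 0] / 20, 3 / 22)

    def test_majority_gap_columns_dropped(self):
        profile = search.build_profile(
            _aa_records(["A-C", "A-C", "ADC", "A-C"]))
        assert profile.ncolumns == 2

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            search.build_profile(_aa_records(["AC", "ACD"]))
        with pytest.raises(ValueError):
            search.build_profile(_aa_records(["AC"]))


class TestScanProfile:
    def test_planted_consensus_recovered_with_high_coverage(self, rt_profile,
                                                            rng):
        flank = "".join(lib.AA20[i] for i in rng.integers(0, 20, 200))
        target = flank + rt_profile.consensus + flank
        hits = search.scan_protein(target, rt_profile)
        assert len(hits) == 1
        hit = hits[0]
        assert hit.coverage >= 0.95
        assert hit.aa_start >= 190 and hit.aa_end <= len(target) - 190

    def test_consensus_scores_maximum_attainable(self, rt_profile):
        hit = search.scan_protein(rt_profile.consensus, rt_profile)[0]
        max_score = float(rt_profile.log_odds[:, :20].max(axis=1).sum())
        assert hit.score <= max_score + 1e-6
        assert np.isclose(hit.score, max_score)

    def test_random_sequences_yield_no_hits(self, rt_profile):
        # empirical null calibration: 100 seeded trials
        rng = np.random.default_rng(12345)
        n_hits = 0
        for _ in range(100):
            seq = "".join(lib.AA20[i] for i in rng.integers(0, 20, 2000))
            n_hits += len(search.scan_protein(seq, rt_profile))
        assert n_hits == 0

    def test_empty_frame_empty_result(self, rt_profile):
        frame = search.TranslatedFrame("x", 1, "", 2)
        assert search.scan_profile(frame, rt_profile) == []

    def test_strand_symmetry_of_genome_scan(self, rt_profile,
                                            reference_panel):
        genome, _ = syn.plant_elements(
            60_000, 0.5, [syn.FamilySpec("f", copy_number=1,
                                         within_divergence=0.0)], 21,
            random_strand=False)
        rc = SequenceRecord(genome.id, reverse_complement(genome.residues))
        loci_fwd = search.mine_genome([genome], rt_profile)
        loci_rev = search.mine_genome([rc], rt_profile)
        L = len(genome.residues)
        mirrored = {(L - l.end, L - l.start) for l in loci_rev}
        assert {(l.start, l.end) for l in loci_fwd} == mirrored


class TestVerifyHits:
    def _hit(self, translation):
        return search.DomainHit("x", 1, 0, len(translation), 0,
                                3 * len(translation), "+", 100.0, 1.0,
                                translation)

    def test_identical_translation_kept_with_full_identity(self):
        panel = [SequenceRecord("Tcn1", lib.RT_INT_FRAGMENT[:150], AMINO_ACID)]
        kept = search.verify_hits([self._hit(lib.RT_INT_FRAGMENT[:150])],
                                  panel, min_aligned=100)
        assert len(kept) == 1
        assert kept[0].label == "Tcn1"
        assert kept[0].identity == 1.0

    def test_unrelated_translation_dropped(self, rng):
        random_prot = "".join(lib.AA20[i] for i in rng.integers(0, 20, 150))
        panel = [SequenceRecord("Tcn1", lib.RT_INT_FRAGMENT[:150], AMINO_ACID)]
        assert search.verify_hits([self._hit(random_prot)], panel,
                                  min_aligned=100) == []

    def test_moderate_identity_kept_with_best_label(self, rng):
        diverged = lib.mutate_protein(lib.RT_INT_FRAGMENT[:200], 0.55, rng)
        panel = [
            SequenceRecord("near", lib.RT_INT_FRAGMENT[:200], AMINO_ACID),
            SequenceRecord("far", "".join(
                lib.AA20[i] for i in rng.integers(0, 20, 200)), AMINO_ACID),
        ]
        kept = search.verify_hits([self._hit(diverged)], panel,
                                  min_identity=0.25, min_aligned=100)
        assert len(kept) == 1
        assert kept[0].label == "near"
        assert 0.25 <= kept[0].identity < 0.75

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            search.verify_hits([], [])

    def test_local_identity_score_matches_quadratic_oracle(self, rng):
        a = "".join(lib.AA20[i] for i in rng.integers(0, 20, 60))
        b = a[10:50]
        aligner = search._local_aligner()
        aln = aligner.align(a, b)[0]
        assert aln.score == sw_affine_best(a, b)


class TestMergeHits:
    def _hit(self, start, end, strand="+", frame=1):
        return search.DomainHit("x", frame, 0, (end - start) // 3, start, end,
                                strand, 50.0, 0.5, "M" * ((end - start) // 3))

    def test_nearby_same_strand_hits_merge(self):
        loci = search.merge_hits(
            [self._hit(100, 400), self._hit(450, 700, frame=2)],
            max_gap_nt=500)
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (100, 700)

    def test_opposite_strands_never_merge(self):
        loci = search.merge_hits(
            [self._hit(100, 400), self._hit(450, 700, strand="-", frame=-1)],
            max_gap_nt=500)
        assert len(loci) == 2

    def test_chained_hits_span_union(self):
        loci = search.merge_hits(
            [self._hit(0, 300), self._hit(700, 1000), self._hit(350, 650)],
            max_gap_nt=500)
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (0, 1000)
        assert len(loci[0].hits) == 3

    def test_distant_hits_stay_separate(self):
        loci = search.merge_hits([self._hit(0, 300), self._hit(5000, 5300)],
                                 max_gap_nt=1000)
        assert len(loci) == 2


class TestMineRecall:
    def test_planted_elements_recovered_with_clade_labels(
            self, small_scene, small_scene_loci):
        genome, copies = small_scene
        intact = [c for c in copies if c.intact]
        for c in intact:
            overlapping = [l for l in small_scene_loci
                           if l.start < c.end and c.start < l.end]
            assert len(overlapping) == 1
            assert overlapping[0].strand == c.strand
            assert overlapping[0].best_hit.label is not None

    def test_no_loci_on_pure_background(self, rt_profile, reference_panel):
        genome, _ = syn.plant_elements(100_000, 0.5, [], 3)
        assert search.mine_genome([genome], rt_profile, reference_panel) == []
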