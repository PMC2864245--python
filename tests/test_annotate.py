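"""Element reconstruction: LTR pair, TSD, ORFs, domains, motifs, PCR."""

import numpy as np
import pytest

from chromomine import annotate as ann
from chromomine import search, synthetic as syn
from chromomine import _domains as lib
from chromomine.io import SequenceRecord, reverse_complement
from chromomine.search import SearchLocus, DomainHit


def _locus(seq_id, start, end, strand="+"):
    hit = DomainHit(seq_id, 1, 0, (end - start) // 3, start, end, strand,
                    500.0, 1.0, "M" * ((end - start) // 3))
    return SearchLocus(seq_id, start, end, strand, [hit])


class TestExpandLocus:
    def test_flank_arithmetic(self):
        genome = SequenceRecord("g", "A" * 100_000)
        loc = ann.expand_locus(_locus("g", 20_000, 21_000), genome)
        assert loc.window == (5_000, 36_000)

    def test_clipped_at_sequence_start(self):
        genome = SequenceRecord("g", "A" * 30_000)
        loc = ann.expand_locus(_locus("g", 500, 1_500), genome)
        assert loc.window == (0, 16_500)

    def test_zero_flank_is_hit_span(self):
        genome = SequenceRecord("g", "A" * 30_000)
        loc = ann.expand_locus(_locus("g", 500, 1_500), genome, flank=0)
        assert loc.window == (500, 1_500)


class TestFindLtrPair:
    def _window(self, seed, divergence=0.0):
        rng = np.random.default_rng(seed)
        element, truth = syn.build_element(syn.ElementTemplate(), rng)
        if divergence:
            element = syn.mutate_nucleotides(element, divergence, rng)
        flank = lambda n: "".join("ACGT"[i] for i in rng.integers(0, 4, n))
        left, right = flank(3000), flank(3000)
        tsd = flank(5)  # intact insertions are flanked by a duplication
        window = left + tsd + element + tsd + right
        off = 3005
        anchor = (off + 2200, off + 4100)  # inside pol
        return window, truth, off, anchor

    def test_pristine_ltr_pair_recovered_exactly(self):
        window, truth, off, anchor = self._window(1)
        pair = ann.find_ltr_pair(window, anchor)
        assert pair is not None
        # the raw repeat extent may slip a few nt where flanking bases
        # match by chance; TSD/canonical-end refinement restores exactness
        assert abs(pair.five_prime[0] - off) <= 8
        assert abs(pair.three_prime[1] - (off + 5704)) <= 8
        assert pair.identity >= 0.99
        refined, tsd, _ = ann.refine_element_boundaries(window, pair)
        assert refined.five_prime[0] == off
        assert refined.three_prime[1] == off + 5704
        assert refined.ends_canonical
        assert tsd == window[off - 5:off]

    def test_diverged_ltr_identity_tracks_truth(self):
        window, truth, off, anchor = self._window(2, divergence=0.025)
        pair = ann.find_ltr_pair(window, anchor)
        assert pair is not None
        # each LTR mutated independently at 2.5%
        assert pair.identity == pytest.approx(0.95, abs=0.02)
        refined, _, _ = ann.refine_element_boundaries(window, pair)
        assert abs(refined.five_prime[0] - off) <= 5
        assert abs(refined.three_prime[1] - (off + 5704)) <= 5

    def test_window_without_repeat_returns_absent(self):
        rng = np.random.default_rng(3)
        window = "".join("ACGT"[i] for i in rng.integers(0, 4, 8000))
        assert ann.find_ltr_pair(window, (3500, 4500)) is None

    def test_anchor_outside_window_rejected(self):
        with pytest.raises(ValueError):
            ann.find_ltr_pair("ACGT" * 100, (500, 600))


class TestFindTsd:
    def test_planted_aacac_duplication(self):
        rng = np.random.default_rng(4)
        bg = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        elem = "TG" + "".join("ACGT"[i] for i in rng.integers(0, 4, 96)) + "CA"
        genome = bg[:200] + "AACAC" + elem + "AACAC" + bg[200:]
        bounds = (205, 305)
        assert ann.find_tsd(genome, bounds) == "AACAC"

    def test_no_duplication_absent(self):
        genome = "A" * 50 + "TGCC" + "G" * 30 + "CCCA" + "T" * 50
        assert ann.find_tsd(genome, (54, 88)) is None

    def test_longest_duplication_wins(self):
        # flanks agree at both k=4 and k=5: report the 5-mer
        left = "GATTC"
        genome = "C" * 40 + left + "TG" + "A" * 30 + "CA" + left + "C" * 40
        bounds = (45, 79)
        assert ann.find_tsd(genome, bounds) == "GATTC"


class TestFindOrfs:
    def test_planted_gag_orf_length(self):
        rng = np.random.default_rng(5)
        gag_aa = "M" + lib.random_protein(rng, 322)
        cds = lib.encode_protein(gag_aa, rng) + "TAA"
        # pad with stop-rich flanks so no other ORF appears
        seq = "TAATAGTGA" * 20 + cds + "TAATAGTGA" * 20
        orfs = ann.find_orfs(seq, min_aa=200)
        assert len(orfs) == 1
        orf = orfs[0]
        assert orf.length_nt == 969
        assert len(orf.protein) == 323
        assert orf.protein == gag_aa

    def test_all_stop_sequence_has_no_orfs(self):
        assert ann.find_orfs("TAATAGTGA" * 100) == []

    def test_incomplete_orf_without_stop_excluded(self):
        rng = np.random.default_rng(6)
        cds = lib.encode_protein("M" + lib.random_protein(rng, 250), rng)
        assert ann.find_orfs("TAA" + cds, min_aa=200) == []  # no closing stop

    def test_minus_strand_orf_coordinates(self):
        rng = np.random.default_rng(7)
        gag_aa = "M" + lib.random_protein(rng, 210)
        cds = lib.encode_protein(gag_aa, rng) + "TGA"
        seq = "TAGTAATGA" * 10 + reverse_complement(cds) + "TAGTAATGA" * 10
        orfs = ann.find_orfs(seq, min_aa=200)
        assert len(orfs) == 1
        assert orfs[0].strand == "-"
        assert orfs[0].protein == gag_aa


class TestDetectDomains:
    def test_chromovirus_pol_order(self, domain_profiles, rng):
        pol, _ = syn._family_pol(syn.ElementTemplate(), rng, 0.25)
        doms = ann.detect_domains(pol, domain_profiles)
        assert [d[0] for d in doms] == ["PR", "RT", "RH", "Int", "CHD"]

    def test_dutpase_between_pr_and_rt(self, domain_profiles, rng):
        template = syn.ElementTemplate(
            domain_order=("PR", "dUTPase", "RT", "RH", "Int", "CHD"))
        pol, _ = syn._family_pol(template, rng, 0.25)
        doms = ann.detect_domains(pol, domain_profiles)
        names = [d[0] for d in doms]
        assert names.index("dUTPase") == names.index("PR") + 1

    def test_random_protein_has_no_domains(self, domain_profiles, rng):
        random_prot = "".join(lib.AA20[i] for i in rng.integers(0, 20, 1200))
        assert ann.detect_domains(random_prot, domain_profiles) == []


class TestMotifs:
    def test_cchc_example(self):
        assert ann.find_cchc("ACKTCGKEGHYANRCPA") == [1]

    def test_no_histidine_no_match(self):
        assert ann.find_cchc("CAACAAAAQAAAAC") == []

    def test_overlapping_matches_all_reported(self):
        # the closing C of the first knuckle opens the second
        protein = "CAACAAAAHAAAACAACAAAAHAAAAC"
        assert ann.find_cchc(protein) == [0, 13]

    def test_ppt_purine_run_found(self):
        seq = "CTCTCTCTCT" + "AGGGGAAAGGGA" + "CT" + "TG" + "A" * 50
        ppt = ann.find_ppt(seq, three_prime_ltr_start=24)
        assert ppt is not None
        a, b = ppt
        assert b - a >= 10
        window = seq[a:b]
        assert sum(c in "AG" for c in window) / len(window) >= 0.9

    def test_pyrimidine_rich_upstream_absent(self):
        seq = "CTCTCTCTCTCTCTCTCTCTCTCT" + "TG" + "A" * 50
        assert ann.find_ppt(seq, three_prime_ltr_start=24) is None

    def test_purine_run_outside_20nt_window_absent(self):
        seq = "AGGGGAAAGGGA" + "CT" * 13 + "TG" + "A" * 50
        assert ann.find_ppt(seq, three_prime_ltr_start=38) is None


class TestFindPbs:
    def test_trna_primed_pbs_recovered(self, trna_panel, rng):
        ltr_end = 100
        bg = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        probe = reverse_complement(trna_panel[0].residues[-15:])
        seq = bg[:ltr_end] + "ACT" + probe + bg[ltr_end:]
        hit = ann.find_pbs(seq, ltr_end, trna_panel)
        assert hit is not None
        (a, b), mechanism = hit
        assert mechanism == f"tRNA:{trna_panel[0].id}"
        assert (a, b) == (103, 118)

    def test_smtcn1_like_template_has_no_pbs(self, trna_panel):
        seq, truth = syn.build_element(syn.ElementTemplate(has_pbs=False), 8)
        assert ann.find_pbs(seq, truth.ltr5[1], trna_panel,
                            ltr_seq=seq[:440]) is None

    def test_self_priming_ltr_copy_detected(self, trna_panel, rng):
        bg = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        ltr = bg[:100]
        seq = ltr + "AC" + ltr[:14] + bg[100:]
        hit = ann.find_pbs(seq, 100, [], ltr_seq=ltr)
        assert hit is not None
        assert hit[1] == "self-priming"


class TestInSilicoPcr:
    def test_gyrt1_site_is_code_compatible(self):
        assert syn.iupac_match("AGAATGTGCGTAGATTACAG", lib.GYRT1)

    def test_poly_a_genome_no_products(self):
        genome = SequenceRecord("g", "A" * 5000)
        assert ann.in_silico_pcr(genome, ann.gyrt1_ty3a_pair()) == []

    def test_undefined_primer_code_rejected(self):
        with pytest.raises(ValueError):
            ann.PrimerPair("ACGQ", "ACGT")

    def test_planted_cassettes_amplify_once_each(self, small_scene):
        genome, copies = small_scene
        products = ann.in_silico_pcr(genome, ann.gyrt1_ty3a_pair())
        amplifiable = [c for c in copies if c.cassette_intact]
        assert len(products) == len(amplifiable)
        for c in amplifiable:
            inside = [p for p in products
                      if c.start <= p.start and p.end <= c.end]
            assert len(inside) == 1
            assert 250 <= int(inside[0].attributes["length"]) <= 400

    def test_strand_symmetry(self, small_scene):
        genome, _ = small_scene
        rc = SequenceRecord(genome.id, reverse_complement(genome.residues))
        fwd = ann.in_silico_pcr(genome, ann.gyrt1_ty3a_pair())
        rev = ann.in_silico_pcr(rc, ann.gyrt1_ty3a_pair())
        L = len(genome.residues)
        assert {(p.start, p.end) for p in fwd} == \
            {(L - p.end, L - p.start) for p in rev}


class TestReconstructFromPartials:
    def test_overlapping_fragments_rebuild_the_element(self):
        # true overlaps (500/600 nt) must exceed the 440 nt LTR, which is
        # itself a spurious-full-identity repeat between fragment ends
        element, _ = syn.build_element(syn.ElementTemplate(), 17)
        fragments = [element[:2800], element[2300:4500], element[3900:]]
        contigs = ann.reconstruct_from_partials(fragments)
        assert contigs == [element]

    def test_diverged_overlaps_still_merge(self, rng):
        element, _ = syn.build_element(syn.ElementTemplate(), 18)
        left = element[:3200]
        right = syn.mutate_nucleotides(element[2600:], 0.02, rng)
        contigs = ann.reconstruct_from_partials([left, right])
        assert len(contigs) == 1
        assert len(contigs[0]) == len(element)

    def test_unrelated_fragments_stay_separate(self, rng):
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        b = "".join("ACGT"[i] for i in rng.integers(0, 4, 800))
        assert len(ann.reconstruct_from_partials([a, b])) == 2


class TestAnnotateElement:
    def test_smtcn1_like_element_recovered_end_to_end(
            self, rt_profile, domain_profiles, trna_panel, reference_panel):
        genome, copies = syn.plant_elements(
            60_000, 0.5,
            [syn.FamilySpec("sm", copy_number=1, within_divergence=0.0)],
            11, random_strand=False)
        loci = search.mine_genome([genome], rt_profile, reference_panel)
        assert len(loci) == 1
        a = ann.annotate_element(loci[0], genome, domain_profiles, trna_panel)
        c = copies[0]
        assert a.element == (c.start, c.end)
        assert a.length == 5704
        lp = a.ltr_pair
        assert lp.five_prime[1] - lp.five_prime[0] == 440
        assert lp.three_prime[1] - lp.three_prime[0] == 440
        assert a.ltr_identity == 1.0
        assert a.tsd == c.tsd
        # gag (969 nt / 323 aa) and pol (3714 nt / 1238 aa) on the element
        # strand; chance antisense ORFs may appear in addition
        plus_orfs = {o.length_nt for o in a.orfs if o.strand == "+"}
        assert {969, 3714} <= plus_orfs
        assert max(len(o.protein) for o in a.orfs) == 1238
        assert a.domain_order == ["PR", "RT", "RH", "Int", "CHD"]
        assert a.classification == "chromovirus"
        assert a.cchc_present
        assert a.ppt is not None
        assert a.pbs is None
        assert ("TATA", 20) in a.promoter_boxes
        assert not a.partial

    def test_locus_without_ltrs_flagged_partial(self, rt_profile,
                                                domain_profiles, rng):
        # an isolated RT-Int fragment with no flanking repeats
        frag_aa = lib.RT_INT_FRAGMENT
        cds = lib.encode_protein(frag_aa, rng)
        bg = "".join("ACGT"[i] for i in rng.integers(0, 4, 20_000))
        genome = SequenceRecord("g", bg[:10_000] + cds + bg[10_000:])
        loci = search.mine_genome([genome], rt_profile)
        assert len(loci) == 1
        a = ann.annotate_element(loci[0], genome, domain_profiles)
        assert a.partial
        assert a.element is None
        assert a.ltr_pair is None

    def test_template_without_chd_is_non_chromovirus(
            self, rt_profile, domain_profiles, reference_panel):
        spec = syn.FamilySpec(
            "nc", template=syn.ElementTemplate(
                domain_order=("PR", "RT", "RH", "Int")),
            copy_number=1, within_divergence=0.0)
        genome, _ = syn.plant_elements(60_000, 0.5, [spec], 13,
                                       random_strand=False)
        loci = search.mine_genome([genome], rt_profile, reference_panel)
        a = ann.annotate_element(loci[0], genome, domain_profiles)
        assert a.classification == "non-chromovirus Gypsy"
        assert "CHD" not in a.domain_order
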