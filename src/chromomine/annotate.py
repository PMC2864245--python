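"""Structural annotation of LTR retroelements around verified search loci.

Each locus is expanded (up to 15 kb each side), searched for a flanking
direct-repeat pair (the LTRs), snapped to target-site-duplication and
TG...CA boundary evidence, and annotated with ORFs, enzymatic-domain
architecture (PR, RT, RH, Int, CHD, dUTPase), the Gag CCHC zinc knuckle,
polypurine tract, primer-binding site and LTR promoter boxes.  A degenerate
in-silico PCR reproduces the experimental RT-fragment survey.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib

from .io import (Feature, SequenceRecord, IUPAC_EXPAND, NUCLEOTIDE,
                 reverse_complement)
from .search import DomainHit, ProfileModel, SearchLocus, scan_protein
from .synthetic import iupac_match

PURINES = frozenset("AG")


# ---------------------------------------------------------------------------
# Locus expansion
# ---------------------------------------------------------------------------

@dataclass
class Locus:
    """A search locus with its expanded analysis window."""

    source_id: str
    window: tuple[int, int]
    anchor: tuple[int, int]  # originating hit span, genome coords
    strand: str
    hits: list[DomainHit] = field(default_factory=list)


def expand_locus(locus: SearchLocus, genome: SequenceRecord,
                 flank: int = 15000) -> Locus:
    """Expand the hit span by ``flank`` nt each side, clipped to bounds."""
    if flank < 0 or flank > 15000:
        raise ValueError("flank must be in [0, 15000]")
    w0 = max(0, locus.start - flank)
    w1 = min(len(genome), locus.end + flank)
    return Locus(locus.source_id, (w0, w1), (locus.start, locus.end),
                 locus.strand, list(locus.hits))


# ---------------------------------------------------------------------------
# LTR pair discovery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LTRParams:
    min_len: int = 100
    min_identity: float = 0.80
    seed_k: int = 12
    max_span: int = 15000
    xdrop: int = 20


@dataclass
class LTRPair:
    five_prime: tuple[int, int]
    three_prime: tuple[int, int]
    identity: float
    ends_canonical: bool


def _ungapped_extend(seq: str, u0: int, u1: int, diag: int,
                     lo_bound: int, hi_bound: int, xdrop: int,
                     ) -> tuple[int, int]:
    """Extend the paired region [u0,u1) vs [u0+diag,u1+diag) outward.

    X-drop extension (+1 match, -2 mismatch) trimmed back to the maximal
    scoring extent.  Bounds constrain the upstream copy.
    """
    # leftward
    best_gain, best_i, gain = 0, u0, 0
    i = u0 - 1
    while i >= lo_bound and i + diag < len(seq):
        gain += 1 if seq[i] == seq[i + diag] else -2
        if gain > best_gain:
            best_gain, best_i = gain, i
        if gain < best_gain - xdrop:
            break
        i -= 1
    new_u0 = best_i
    # rightward
    best_gain, best_j, gain = 0, u1, 0
    j = u1
    while j < hi_bound and j + diag < len(seq):
        gain += 1 if seq[j] == seq[j + diag] else -2
        if gain > best_gain:
            best_gain, best_j = gain, j + 1
        if gain < best_gain - xdrop:
            break
        j += 1
    return new_u0, best_j


def find_ltr_candidates(window_sequence: str, internal_anchor: tuple[int, int],
                        params: LTRParams = LTRParams()) -> list[LTRPair]:
    """All direct-repeat pairs flanking the anchor, best-score-first.

    Exact k-mer seeds pair the region upstream of the anchor with the region
    downstream; seeds sharing a diagonal are extended ungapped with x-drop
    and trimmed to the maximal-scoring extent.  Candidates are scored by
    length x identity with a bonus for canonical TG...CA ends.  Tandem
    same-family copies produce cross-copy repeat pairs as well; the caller
    disambiguates with TSD and boundary evidence (see annotate_element).
    """
    a0, a1 = internal_anchor
    if not (0 <= a0 < a1 <= len(window_sequence)):
        raise ValueError("anchor outside window")
    k = params.seed_k
    upstream_end = a0
    if upstream_end < k:
        return []

    index: dict[str, list[int]] = {}
    for i in range(upstream_end - k + 1):
        index.setdefault(window_sequence[i : i + k], []).append(i)

    diag_seeds: dict[int, list[int]] = {}
    for j in range(a1, len(window_sequence) - k + 1):
        kmer = window_sequence[j : j + k]
        for i in index.get(kmer, ()):
            diag = j - i
            if diag <= 0 or diag > params.max_span:
                continue
            diag_seeds.setdefault(diag, []).append(i)

    scored: list[tuple[float, LTRPair]] = []
    seen_spans: set[tuple[int, int, int]] = set()
    for diag, seeds in diag_seeds.items():
        u0, u1 = min(seeds), max(seeds) + k
        u0, u1 = _ungapped_extend(window_sequence, u0, u1, diag,
                                  0, a0, params.xdrop)
        if (u0, u1, diag) in seen_spans:
            continue
        seen_spans.add((u0, u1, diag))
        length = u1 - u0
        if length < params.min_len:
            continue
        up = window_sequence[u0:u1]
        down = window_sequence[u0 + diag : u1 + diag]
        matches = sum(1 for x, y in zip(up, down) if x == y)
        identity = matches / length
        if identity < params.min_identity:
            continue
        canonical = (up.startswith("TG") and up.endswith("CA")
                     and down.startswith("TG") and down.endswith("CA"))
        score = length * identity + (100.0 if canonical else 0.0)
        scored.append((score, LTRPair(
            five_prime=(u0, u1), three_prime=(u0 + diag, u1 + diag),
            identity=identity, ends_canonical=canonical)))
    scored.sort(key=lambda sp: (-sp[0],
                                sp[1].three_prime[1] - sp[1].five_prime[0]))
    return [pair for _, pair in scored]


def find_ltr_pair(window_sequence: str, internal_anchor: tuple[int, int],
                  params: LTRParams = LTRParams()) -> LTRPair | None:
    """The single best direct-repeat pair flanking the anchor, or None."""
    candidates = find_ltr_candidates(window_sequence, internal_anchor, params)
    return candidates[0] if candidates else None


def refine_element_boundaries(seq: str, pair: LTRPair, tsd_min: int = 4,
                              tsd_max: int = 6, search: int = 14,
                              ) -> tuple[LTRPair, str | None, int]:
    """Snap element boundaries to TSD and TG...CA evidence.

    Shifts both LTR starts together (dL) and both LTR ends together (dR),
    within +/- ``search`` nt of the raw repeat extent, preferring shifts
    supported by an identical 4-6 bp flank duplication, then by canonical
    dinucleotide ends, then smallest shift, then longest duplication
    (the repeat extent is primary evidence: a longer chance duplication
    at a shifted boundary must not displace a supported in-place one).
    Returns the refined pair, the TSD string (None if unsupported) and the
    canonical-end count (0-4) of the chosen boundaries.
    """
    (u0, u1), (d0, d1) = pair.five_prime, pair.three_prime
    best_key = None
    best = None
    for dl in range(-search, search + 1):
        s = u0 + dl
        if s - tsd_max < 0:
            continue
        for dr in range(-search, search + 1):
            e = d1 + dr
            if e + tsd_max > len(seq) or s >= e:
                continue
            tsd = None
            for kk in range(tsd_max, tsd_min - 1, -1):
                if seq[s - kk : s] == seq[e : e + kk]:
                    tsd = seq[s - kk : s]
                    break
            # graded TG...CA evidence over both LTR copies: point mutations
            # may erase one terminal dinucleotide, the other three still
            # discriminate the true boundary from chance duplications
            n_canonical = (
                (seq[s : s + 2] == "TG") + (seq[e - 2 : e] == "CA")
                + (seq[d0 + dl : d0 + dl + 2] == "TG")
                + (seq[u1 + dr - 2 : u1 + dr] == "CA"))
            canonical = n_canonical == 4
            if tsd is None and not canonical:
                continue
            key = (tsd is not None, n_canonical, -(abs(dl) + abs(dr)),
                   len(tsd) if tsd else 0)
            if best_key is None or key > best_key:
                best_key = key
                best = (dl, dr, tsd, canonical)
    if best is None:
        return pair, None, 0
    dl, dr, tsd, canonical = best
    refined = LTRPair(
        five_prime=(u0 + dl, u1 + dr),
        three_prime=(d0 + dl, d1 + dr),
        identity=pair.identity,
        ends_canonical=canonical,
    )
    n_canonical = best_key[1] if best_key else 0
    return refined, tsd, n_canonical


def ltr_pair_identity(seq: str, pair: LTRPair) -> float:
    """Alignment identity between the two LTR copies (indel-tolerant)."""
    a = seq[pair.five_prime[0] : pair.five_prime[1]]
    b = seq[pair.three_prime[0] : pair.three_prime[1]]
    res = edlib.align(a, b, task="distance")
    return 1.0 - res["editDistance"] / max(len(a), len(b))


# ---------------------------------------------------------------------------
# TSD, ORFs, domains, motifs
# ---------------------------------------------------------------------------

def find_tsd(genome: str, element_bounds: tuple[int, int],
             min_len: int = 4, max_len: int = 6) -> str | None:
    """Longest identical flank duplication of length min_len..max_len."""
    s, e = element_bounds
    for k in range(max_len, min_len - 1, -1):
        if s - k < 0 or e + k > len(genome):
            continue
        if genome[s - k : s] == genome[e : e + k]:
            return genome[s - k : s]
    return None


@dataclass
class Orf:
    start: int          # nt, excludes the stop codon
    end: int
    strand: str
    protein: str

    @property
    def length_nt(self) -> int:
        return self.end - self.start


_CODON_RE = re.compile(r"(?=(ATG))")


def find_orfs(internal_sequence: str, min_aa: int = 200) -> list[Orf]:
    """All maximal, complete (start-to-stop) ORFs >= min_aa on both strands."""
    from ._domains import translate_cds

    orfs: list[Orf] = []
    L = len(internal_sequence)
    for strand, seq in (("+", internal_sequence),
                        ("-", reverse_complement(internal_sequence))):
        for off in range(3):
            sub = seq[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            if not sub:
                continue
            aa = translate_cds(sub)
            pos = 0
            for segment in aa.split("*"):
                seg_end = pos + len(segment)
                if seg_end < len(aa):  # a stop codon follows: complete ORF
                    m = segment.find("M")
                    if m != -1 and len(segment) - m >= min_aa:
                        c0 = off + 3 * (pos + m)
                        c1 = off + 3 * seg_end
                        if strand == "+":
                            orfs.append(Orf(c0, c1, "+", segment[m:]))
                        else:
                            orfs.append(Orf(L - c1, L - c0, "-", segment[m:]))
                pos = seg_end + 1
    orfs.sort(key=lambda o: (o.start, o.end))
    return orfs


def detect_domains(protein: str, domain_profiles: dict[str, ProfileModel],
                   ) -> list[tuple[str, int, int, float]]:
    """Per-domain profile scan; overlaps resolved best-score-first.

    Returns (name, aa_start, aa_end, score) ordered by position.
    """
    candidates: list[tuple[float, str, int, int]] = []
    for name, profile in domain_profiles.items():
        for hit in scan_protein(protein, profile, name):
            candidates.append((hit.score, name, hit.aa_start, hit.aa_end))
    candidates.sort(key=lambda c: -c[0])
    chosen: list[tuple[str, int, int, float]] = []
    for score, name, a, b in candidates:
        if any(a < cb and ca < b for _, ca, cb, _ in chosen):
            continue
        chosen.append((name, a, b, score))
    chosen.sort(key=lambda c: c[1])
    return chosen


CCHC_RE = re.compile(r"(?=(C.{2}C.{4}H.{4}C))")


def find_cchc(protein: str) -> list[int]:
    """Start offsets of every (possibly overlapping) CCHC zinc-knuckle."""
    return [m.start() for m in CCHC_RE.finditer(protein)]


def find_ppt(sequence: str, three_prime_ltr_start: int, min_len: int = 10,
             purine_fraction: float = 0.9, max_gap: int = 20,
             max_len: int = 40) -> tuple[int, int] | None:
    """Longest >=90%-purine window ending within max_gap nt of the 3'LTR."""
    best = None
    lo_end = max(min_len, three_prime_ltr_start - max_gap)
    for e in range(lo_end, three_prime_ltr_start + 1):
        run_best = None
        npur = 0
        for length in range(1, min(max_len, e) + 1):
            if sequence[e - length] in PURINES:
                npur += 1
            if length >= min_len and npur / length >= purine_fraction:
                run_best = (e - length, e)
        if run_best and (best is None or
                         run_best[1] - run_best[0] > best[1] - best[0]):
            best = run_best
    return best


def find_pbs(sequence: str, five_prime_ltr_end: int,
             trna_panel: list[SequenceRecord], ltr_seq: str | None = None,
             min_match: int = 12, window: int = 30, probe_len: int = 18,
             ) -> tuple[tuple[int, int], str] | None:
    """Search for a primer-binding site just downstream of the 5'LTR.

    Matches the reverse complement of a tRNA 3' terminus (tRNA priming), or
    a sequence copied from the LTR itself (self-priming).  Returns the
    matched interval and mechanism, or None.
    """
    region = sequence[five_prime_ltr_end : five_prime_ltr_end + window + probe_len]
    for trna in trna_panel:
        for m in range(probe_len, min_match - 1, -1):
            probe = reverse_complement(trna.residues[-m:])
            pos = region.find(probe)
            if pos != -1 and pos <= window:
                iv = (five_prime_ltr_end + pos, five_prime_ltr_end + pos + m)
                return iv, f"tRNA:{trna.id}"
    if ltr_seq:
        for m in range(probe_len, min_match - 1, -1):
            for start in range(0, len(ltr_seq) - m + 1):
                probe = ltr_seq[start : start + m]
                pos = region.find(probe)
                if pos != -1 and pos <= window:
                    iv = (five_prime_ltr_end + pos, five_prime_ltr_end + pos + m)
                    return iv, "self-priming"
    return None


# ---------------------------------------------------------------------------
# In-silico PCR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str
    product_range: tuple[int, int] = (250, 400)

    def __post_init__(self) -> None:
        for primer in (self.forward, self.reverse):
            bad = set(primer.upper()) - set(IUPAC_EXPAND)
            if bad:
                raise ValueError(f"primer contains undefined codes {sorted(bad)}")


def _iupac_regex(pattern: str) -> re.Pattern:
    return re.compile("".join(
        c if len(IUPAC_EXPAND[c]) == 1 else "[" + IUPAC_EXPAND[c] + "]"
        for c in pattern.upper()
    ))


def in_silico_pcr(genome: SequenceRecord, primer_pair: PrimerPair,
                  ) -> list[Feature]:
    """Emulate degenerate-primer PCR on both strands.

    The forward primer is matched with full IUPAC degeneracy; the reverse
    primer's reverse complement is matched downstream on the same strand;
    products within the length window are reported with coordinates.
    """
    lo, hi = primer_pair.product_range
    fwd_re = _iupac_regex(primer_pair.forward)
    rev_re = _iupac_regex(reverse_complement(primer_pair.reverse.upper()))
    L = len(genome)
    products: list[Feature] = []
    for strand, seq in (("+", genome.residues),
                        ("-", reverse_complement(genome.residues))):
        rev_ends = [m.end() for m in rev_re.finditer(seq)]
        for m in fwd_re.finditer(seq):
            i = m.start()
            for e in rev_ends:
                if e - i < max(lo, len(primer_pair.forward) + len(primer_pair.reverse)):
                    continue
                if e - i > hi:
                    break
                a, b = (i, e) if strand == "+" else (L - e, L - i)
                products.append(Feature(
                    genome.id, a, b, strand, "PCR_product",
                    {"length": str(e - i),
                     "sequence": seq[i:e]},
                ))
    products.sort(key=lambda f: (f.start, f.end, f.strand))
    return products


# ---------------------------------------------------------------------------
# Full element annotation
# ---------------------------------------------------------------------------

@dataclass
class ElementAnnotation:
    """Structural annotation of one (putative) element, genome coordinates."""

    seq_id: str
    element: tuple[int, int] | None
    strand: str
    ltr_pair: LTRPair | None            # genome coordinates
    ltr_identity: float | None
    tsd: str | None
    orfs: list[Orf]                     # genome coordinates, strand absolute
    domains: list[tuple[str, int, int, float]]   # aa coords within their ORF
    domain_order: list[str]
    cchc_present: bool
    ppt: tuple[int, int] | None
    pbs: tuple[tuple[int, int], str] | None
    promoter_boxes: list[tuple[str, int]]
    classification: str                 # chromovirus | non-chromovirus Gypsy
    partial: bool
    anchor: tuple[int, int]
    label: str | None = None
    rt_int_protein: str = ""            # best verified hit translation

    @property
    def length(self) -> int | None:
        return None if self.element is None else self.element[1] - self.element[0]


PROMOTER_MOTIFS = (("TATA", re.compile("TATA[AT]A")), ("CAAT", re.compile("CAAT")))


def annotate_element(locus: SearchLocus | Locus, genome: SequenceRecord,
                     domain_profiles: dict[str, ProfileModel],
                     trna_panel: list[SequenceRecord] | None = None,
                     ltr_params: LTRParams = LTRParams(),
                     flank: int = 15000, min_orf_aa: int = 200,
                     ) -> ElementAnnotation:
    """Compose the structural annotation for one verified locus."""
    loc = locus if isinstance(locus, Locus) else expand_locus(locus, genome, flank)
    w0, w1 = loc.window
    window = genome.residues[w0:w1]
    strand = loc.strand
    if strand == "-":
        work = reverse_complement(window)
        anchor = (w1 - loc.anchor[1], w1 - loc.anchor[0])
    else:
        work = window
        anchor = (loc.anchor[0] - w0, loc.anchor[1] - w0)

    def to_genome(iv: tuple[int, int]) -> tuple[int, int]:
        if strand == "-":
            return (w1 - iv[1], w1 - iv[0])
        return (w0 + iv[0], w0 + iv[1])

    # Rank candidate repeat pairs by insertion evidence: a pair supported
    # by a flank duplication and canonical ends beats a bare repeat, and
    # the innermost supported pair wins (tandem copies of one family
    # otherwise pair the 5'LTR of one copy with the 3'LTR of the next).
    tsd = None
    pair = None
    element_local: tuple[int, int] | None = None
    best_key = None
    for raw_pair in find_ltr_candidates(work, anchor, ltr_params)[:8]:
        cand, cand_tsd, n_canon = refine_element_boundaries(work, raw_pair)
        span = cand.three_prime[1] - cand.five_prime[0]
        key = (cand_tsd is not None, n_canon, -span,
               (cand.five_prime[1] - cand.five_prime[0]) * cand.identity)
        if best_key is None or key > best_key:
            best_key = key
            pair, tsd = cand, cand_tsd
    if pair is not None:
        element_local = (pair.five_prime[0], pair.three_prime[1])
        if tsd is not None and strand == "-":
            tsd = reverse_complement(tsd)  # report in genome orientation

    if element_local is not None:
        region = work[element_local[0] : element_local[1]]
        region_off = element_local[0]
    else:
        region = work[max(0, anchor[0] - 8000) : anchor[1] + 8000]
        region_off = max(0, anchor[0] - 8000)

    orfs_local = find_orfs(region, min_aa=min_orf_aa)

    all_domains: list[tuple[str, int, int, float]] = []
    domain_positions: list[tuple[int, str]] = []  # (nt pos in work, name)
    cchc = False
    for orf in orfs_local:
        doms = detect_domains(orf.protein, domain_profiles)
        for name, a, b, score in doms:
            all_domains.append((name, a, b, score))
            if orf.strand == "+":
                nt = region_off + orf.start + 3 * a
            else:
                nt = region_off + orf.end - 3 * b
            domain_positions.append((nt, name))
        cchc = cchc or bool(find_cchc(orf.protein))
    domain_positions.sort()
    order = [name for _, name in domain_positions]

    classification = "non-chromovirus Gypsy"
    if "CHD" in order and "Int" in order:
        if order.index("CHD") > order.index("Int"):
            classification = "chromovirus"

    ppt = None
    pbs = None
    promoter: list[tuple[str, int]] = []
    ltr_ident = None
    if pair is not None:
        ltr_ident = ltr_pair_identity(work, pair)
        ppt_local = find_ppt(work, pair.three_prime[0])
        ppt = to_genome(ppt_local) if ppt_local else None
        ltr_seq = work[pair.five_prime[0] : pair.five_prime[1]]
        if trna_panel is not None:
            hit = find_pbs(work, pair.five_prime[1], trna_panel, ltr_seq)
            if hit:
                pbs = (to_genome(hit[0]), hit[1])
        for name, rx in PROMOTER_MOTIFS:
            for m in rx.finditer(ltr_seq):
                promoter.append((name, m.start()))

    orfs_genome = []
    for orf in orfs_local:
        g = to_genome((region_off + orf.start, region_off + orf.end))
        orf_strand = orf.strand if strand == "+" else ("-" if orf.strand == "+" else "+")
        orfs_genome.append(Orf(g[0], g[1], orf_strand, orf.protein))

    best_hit = max(loc.hits, key=lambda h: h.score) if loc.hits else None
    return ElementAnnotation(
        seq_id=genome.id,
        element=to_genome(element_local) if element_local else None,
        strand=strand,
        ltr_pair=LTRPair(to_genome(pair.three_prime) if strand == "-" else to_genome(pair.five_prime),
                         to_genome(pair.five_prime) if strand == "-" else to_genome(pair.three_prime),
                         pair.identity, pair.ends_canonical) if pair else None,
        ltr_identity=ltr_ident,
        tsd=tsd,
        orfs=orfs_genome,
        domains=all_domains,
        domain_order=order,
        cchc_present=cchc,
        ppt=ppt,
        pbs=pbs,
        promoter_boxes=promoter,
        classification=classification,
        partial=pair is None,
        anchor=loc.anchor,
        label=best_hit.label if best_hit else None,
        rt_int_protein=best_hit.translation if best_hit else "",
    )


def annotation_features(ann: ElementAnnotation) -> list[Feature]:
    """Flatten an annotation into GFF3-ready features."""
    feats: list[Feature] = []
    if ann.element:
        attrs = {"classification": ann.classification,
                 "partial": "1" if ann.partial else "0"}
        if ann.label:
            attrs["clade"] = ann.label
        if ann.tsd:
            attrs["tsd"] = ann.tsd
        feats.append(Feature(ann.seq_id, ann.element[0], ann.element[1],
                             ann.strand, "LTR_retrotransposon", attrs))
    if ann.ltr_pair:
        for which, iv in (("5'", ann.ltr_pair.five_prime),
                          ("3'", ann.ltr_pair.three_prime)):
            feats.append(Feature(ann.seq_id, iv[0], iv[1], ann.strand,
                                 "long_terminal_repeat", {"which": which}))
    if ann.tsd and ann.element:
        k = len(ann.tsd)
        s, e = ann.element
        feats.append(Feature(ann.seq_id, s - k, s, ".",
                             "target_site_duplication", {"tsd": ann.tsd}))
        feats.append(Feature(ann.seq_id, e, e + k, ".",
                             "target_site_duplication", {"tsd": ann.tsd}))
    for orf in ann.orfs:
        feats.append(Feature(ann.seq_id, orf.start, orf.end, orf.strand, "ORF",
                             {"aa_length": str(len(orf.protein))}))
    if ann.ppt:
        feats.append(Feature(ann.seq_id, ann.ppt[0], ann.ppt[1], ann.strand,
                             "RR_tract", {}))
    if ann.pbs:
        feats.append(Feature(ann.seq_id, ann.pbs[0][0], ann.pbs[0][1],
                             ann.strand, "primer_binding_site",
                             {"mechanism": ann.pbs[1]}))
    return feats


def reconstruct_from_partials(fragments: list[str], min_overlap: int = 200,
                              min_identity: float = 0.95) -> list[str]:
    """Greedy reconstruction of full-length sequences from partial copies.

    Same-family partial sequences sharing a suffix-prefix overlap of at
    least ``min_overlap`` nt at >= ``min_identity`` identity are merged
    (longest overlap first) until no further merge is possible.  Returns
    the remaining contigs, longest first.
    """
    contigs = sorted((f for f in fragments if f), key=len, reverse=True)

    def best_overlap(a: str, b: str) -> int:
        """Longest suffix(a)/prefix(b) overlap at sufficient identity.

        Columnwise (Hamming) identity: an overlap is a positional match
        between copies differing by substitutions; indel-tolerant scoring
        would mistake shifted placements for slightly longer overlaps.
        """
        limit = min(len(a), len(b))
        for n in range(limit, min_overlap - 1, -1):
            tail, head = a[-n:], b[:n]
            matches = sum(x == y for x, y in zip(tail, head))
            if matches / n >= min_identity:
                return n
        return 0

    merged = True
    while merged and len(contigs) > 1:
        merged = False
        best = (0, None, None, False)
        for i in range(len(contigs)):
            for j in range(len(contigs)):
                if i == j:
                    continue
                n = best_overlap(contigs[i], contigs[j])
                if n > best[0]:
                    best = (n, i, j, False)
        n, i, j, _ = best
        if n:
            contigs[i] = contigs[i] + contigs[j][n:]
            del contigs[j]
            contigs.sort(key=len, reverse=True)
            merged = True
    return contigs


def default_domain_profiles() -> dict[str, ProfileModel]:
    """Profiles for PR, RT, RH, Int, CHD and dUTPase from the seed library."""
    from .search import build_profile
    from .synthetic import domain_seed_alignments

    return {name: build_profile(aln)
            for name, aln in domain_seed_alignments().items()}


def gyrt1_ty3a_pair() -> PrimerPair:
    """The degenerate GyRT1 / ty3-A (3' core) primer pair, ~320 bp apart."""
    from ._domains import GYRT1, TY3A_CORE

    return PrimerPair(forward=GYRT1, reverse=TY3A_CORE, product_range=(250, 400))
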