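"""Synthetic genomes with planted LTR retroelements and known ground truth.

The generator emulates the study conditions of a genome-mining survey:
an i.i.d. background genome, families of Gypsy-like LTR retroelements with
the canonical anatomy (TG...CA long terminal repeats, 4-6 bp target-site
duplications, gag/pol ORFs carrying PR-RT-RH-Int-CHD, a CCHC zinc-knuckle
in Gag, a polypurine tract ahead of the 3'LTR, a degenerate-primer cassette
inside RT), 90-100% within-family identity, and amino-acid pairs diverged
under a Poisson substitution model at stated rates and times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _domains as lib
from .io import Feature, SequenceRecord, AMINO_ACID, NUCLEOTIDE, IUPAC_EXPAND, reverse_complement

PURINES = frozenset("AG")


def iupac_match(seq: str, pattern: str) -> bool:
    """True iff every position of ``seq`` is compatible with the IUPAC pattern."""
    if len(seq) != len(pattern):
        return False
    return all(s in IUPAC_EXPAND[p] for s, p in zip(seq, pattern))


# ---------------------------------------------------------------------------
# Templates and truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElementTemplate:
    """Blueprint of one full-length element."""

    ltr_length: int = 440
    tsd_length: int = 5
    orf_layout: str = "two"  # "two" (gag + pol) or "single" (gag-pol fusion)
    domain_order: tuple[str, ...] = lib.DEFAULT_DOMAIN_ORDER
    has_cchc: bool = True
    has_pbs: bool = False
    has_ppt: bool = True
    primer_cassette: bool = True

    def __post_init__(self) -> None:
        if self.ltr_length < 100:
            raise ValueError("ltr_length must be >= 100")
        if not 4 <= self.tsd_length <= 6:
            raise ValueError("tsd_length must be in 4..6")
        if self.orf_layout not in {"two", "single"}:
            raise ValueError(f"unknown orf_layout {self.orf_layout!r}")
        unknown = set(self.domain_order) - set(lib.DOMAIN_AA)
        if unknown:
            raise ValueError(f"unknown domains {sorted(unknown)}")
        if "CHD" in self.domain_order and "Int" in self.domain_order:
            if self.domain_order.index("CHD") < self.domain_order.index("Int"):
                raise ValueError("chromovirus templates carry CHD after Int")
        if not 4400 <= self.total_length <= 13500:
            raise ValueError(
                f"element length {self.total_length} outside 4.4-13.5 kb"
            )

    @property
    def pol_length_aa(self) -> int:
        return len(lib.pol_consensus(self.domain_order)[0])

    @property
    def total_length(self) -> int:
        gag_nt = 3 * _GAG_LEN + 3
        pol_nt = 3 * self.pol_length_aa + 3
        if self.orf_layout == "single":
            coding = gag_nt - 3 + pol_nt - 3 + 3  # fused, one stop
            spacers = _LEADER_LEN + _POST_POL_LEN + _INTER_ORF_LEN
        else:
            coding = gag_nt + pol_nt
            spacers = _LEADER_LEN + _INTER_ORF_LEN + _POST_POL_LEN
        return 2 * self.ltr_length + spacers + coding


# Internal geometry (nt).  With the default template this yields a 5704 bp
# element: 2x440 LTR + 60 leader + 972 gag + 45 spacer + 3717 pol + 30 tail.
_GAG_LEN = 323          # aa, incl. leading Met
_LEADER_LEN = 60
_INTER_ORF_LEN = 45
_POST_POL_LEN = 30      # 16 spacer + 12 nt PPT + 2 nt gap
_PPT = "AGGGGAAAGGGA"   # 12 nt, all purines
_CCHC_OFFSET = 60       # motif position within Gag


@dataclass
class ElementTruth:
    """Ground truth for one built element, in element-local coordinates."""

    length: int
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    orfs: list[tuple[int, int, str]]          # (start, end, name); end excl. stop
    domains: list[tuple[str, int, int]]       # nt coords within element
    cassette: tuple[int, int] | None          # fwd site start, rev site start
    cchc_nt: tuple[int, int] | None
    ppt: tuple[int, int] | None
    pbs: tuple[int, int] | None


@dataclass(frozen=True)
class FamilySpec:
    """One planted family: a template plus population parameters.

    ``within_divergence`` is the expected pairwise nucleotide divergence
    between copies (each copy diverges from the family master at half that
    rate).  ``consensus_divergence`` is the amino-acid divergence of this
    family's proteins from the shared consensus library, which keeps
    between-family identity far below the 90% family threshold while the
    RT-Int region stays findable by one shared profile.
    """

    name: str
    template: ElementTemplate = field(default_factory=ElementTemplate)
    copy_number: int = 5
    within_divergence: float = 0.03
    decay_fraction: float = 0.0
    consensus_divergence: float = 0.30

    def __post_init__(self) -> None:
        if not 0 <= self.within_divergence <= 0.10:
            raise ValueError("within_divergence must be in [0, 0.10]")
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")
        if not 0 <= self.decay_fraction < 1:
            raise ValueError("decay_fraction must be in [0, 1)")


@dataclass
class PlantedCopy:
    """Ground truth for one planted copy, in genome coordinates."""

    copy_id: str
    family: str
    start: int
    end: int
    strand: str
    intact: bool
    truncated_end: str | None   # "5'" or "3'" for decayed copies
    tsd: str | None
    cassette_intact: bool
    features: list[Feature]
    element_truth: ElementTruth


# ---------------------------------------------------------------------------
# Element construction
# ---------------------------------------------------------------------------

def _build_ltr(template: ElementTemplate, rng: np.random.Generator) -> str:
    ltr = ["ACGT"[i] for i in rng.integers(0, 4, template.ltr_length)]
    ltr[0:2] = "TG"
    ltr[-2:] = "CA"
    # Promoter boxes inside the LTR.
    ltr[20:26] = "TATAAA"
    ltr[50:54] = "CAAT"
    return "".join(ltr)


def _family_gag(rng: np.random.Generator, has_cchc: bool) -> str:
    gag = list("M" + lib.random_protein(rng, _GAG_LEN - 1))
    if has_cchc:
        motif = list(lib.random_protein(rng, 14))
        motif[0] = motif[3] = motif[13] = "C"
        motif[8] = "H"
        gag[_CCHC_OFFSET : _CCHC_OFFSET + 14] = motif
    return "".join(gag)


def _family_pol(template: ElementTemplate, rng: np.random.Generator,
                consensus_divergence: float) -> tuple[str, dict[str, tuple[int, int]]]:
    aa, intervals = lib.pol_consensus(template.domain_order)
    protected = {0}  # initiator Met
    if "RT" in template.domain_order:
        rt0 = intervals["RT"][0]
        protected.update(rt0 + c for c in lib.RT_FIXED_CODONS)
    aa = lib.mutate_protein(aa, consensus_divergence, rng,
                            protected=frozenset(protected))
    return aa, intervals


def _encode_pol(aa: str, intervals: dict[str, tuple[int, int]],
                template: ElementTemplate, rng: np.random.Generator) -> str:
    fixed = {}
    if template.primer_cassette and "RT" in intervals:
        rt0 = intervals["RT"][0]
        fixed = {rt0 + c: nt for c, nt in lib.RT_FIXED_CODONS.items()}
    return lib.encode_protein(aa, rng, fixed_codons=fixed)


def build_element(template: ElementTemplate, rng_seed,
                  consensus_divergence: float = 0.0) -> tuple[str, ElementTruth]:
    """Build one full-length element and its local ground truth.

    ``rng_seed`` may be an int or a ``numpy.random.Generator``.
    """
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator) else rng_seed

    ltr = _build_ltr(template, rng)
    gag_aa = _family_gag(rng, template.has_cchc)
    pol_aa, dom_intervals = _family_pol(template, rng, consensus_divergence)

    gag_cds = lib.encode_protein(gag_aa, rng)
    pol_cds = _encode_pol(pol_aa, dom_intervals, template, rng)

    leader = ["ACGT"[i] for i in rng.integers(0, 4, _LEADER_LEN)]
    pbs = None
    if template.has_pbs:
        trna = lib.TRNA_PANEL["tRNA-Met"]
        probe = reverse_complement(trna[-15:])
        leader[3 : 3 + 15] = probe
        pbs = (template.ltr_length + 3, template.ltr_length + 18)
    else:
        # SM-Tcn1-like: a conserved thymine-rich stretch instead of a PBS.
        tr = ["T" if rng.random() < 0.7 else "ACG"[rng.integers(0, 3)]
              for _ in range(20)]
        leader[3:23] = tr
    leader = "".join(leader)

    spacer = "".join("ACGT"[i] for i in rng.integers(0, 4, _INTER_ORF_LEN))
    tail = list("ACGT"[i] for i in rng.integers(0, 4, _POST_POL_LEN))
    ppt = None
    if template.has_ppt:
        tail[-14:-2] = _PPT

    stop1 = "TAA"
    stop2 = "TGA"
    if template.orf_layout == "single":
        coding = gag_cds + pol_cds[3:] + stop2  # fused gag-pol, drop pol's Met
        parts = [ltr, leader, coding, spacer, "".join(tail), ltr]
        orf_defs = [("gag-pol", len(ltr) + len(leader), len(coding) - 3)]
        pol_cds_off = len(ltr) + len(leader) + len(gag_cds) - 3
    else:
        parts = [ltr, leader, gag_cds + stop1, spacer, pol_cds + stop2,
                 "".join(tail), ltr]
        gag_off = len(ltr) + len(leader)
        pol_off = gag_off + len(gag_cds) + 3 + len(spacer)
        orf_defs = [("gag", gag_off, len(gag_cds)), ("pol", pol_off, len(pol_cds))]
        pol_cds_off = pol_off

    seq = "".join(parts)
    length = len(seq)

    if template.has_ppt:
        ppt_start = length - len(ltr) - 14
        ppt = (ppt_start, ppt_start + 12)

    domains = [
        (name, pol_cds_off + 3 * a, pol_cds_off + 3 * b)
        for name, (a, b) in sorted(dom_intervals.items(), key=lambda kv: kv[1])
    ]
    cassette = None
    if template.primer_cassette and "RT" in dom_intervals:
        rt_nt = pol_cds_off + 3 * dom_intervals["RT"][0]
        cassette = (rt_nt + lib.CASSETTE_FWD_NT, rt_nt + lib.CASSETTE_REV_NT)

    cchc_nt = None
    if template.has_cchc:
        gag_nt_off = orf_defs[0][1]
        cchc_nt = (gag_nt_off + 3 * _CCHC_OFFSET, gag_nt_off + 3 * (_CCHC_OFFSET + 14))

    truth = ElementTruth(
        length=length,
        ltr5=(0, len(ltr)),
        ltr3=(length - len(ltr), length),
        orfs=[(off, off + ln, name) for name, off, ln in orf_defs],
        domains=domains,
        cassette=cassette,
        cchc_nt=cchc_nt,
        ppt=ppt,
        pbs=pbs,
    )
    return seq, truth


def mutate_nucleotides(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    out = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        base = out[i].decode()
        alternatives = "ACGT".replace(base, "")
        out[i] = alternatives[rng.integers(0, 3)].encode()
    return out.tobytes().decode()


def _cassette_intact(copy_seq: str, fwd: int, rev: int) -> bool:
    if fwd < 0 or rev + len(lib.TY3A_SITE_RC) > len(copy_seq):
        return False
    fwd_ok = iupac_match(copy_seq[fwd : fwd + len(lib.GYRT1)], lib.GYRT1)
    rev_ok = iupac_match(
        copy_seq[rev : rev + len(lib.TY3A_SITE_RC)],
        reverse_complement(lib.TY3A_CORE),
    )
    return fwd_ok and rev_ok


def _mirror(iv: tuple[int, int], length: int) -> tuple[int, int]:
    return (length - iv[1], length - iv[0])


def plant_elements(background_length: int, gc: float,
                   family_specs: list[FamilySpec], rng_seed,
                   seq_id: str = "chr1",
                   random_strand: bool = True) -> tuple[SequenceRecord, list[PlantedCopy]]:
    """Plant element copies into an i.i.d. background genome.

    Returns the genome record and per-copy ground truth.  Decayed copies are
    truncated at a random end (losing 30-70% of their length) and carry no
    target-site duplication; intact insertions are flanked by identical
    ``tsd_length`` bp duplications.
    """
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator) else rng_seed

    probs = [(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2]  # A, T, G, C
    bg = "".join(np.array(list("ATGC"))[
        rng.choice(4, size=background_length, p=probs)])

    # Build masters and copies first so we know total inserted length.
    copies: list[dict] = []
    for spec in family_specs:
        master, truth = build_element(spec.template, rng,
                                      consensus_divergence=spec.consensus_divergence)
        n_decayed = int(round(spec.decay_fraction * spec.copy_number))
        decayed = set(rng.choice(spec.copy_number, size=n_decayed, replace=False)) \
            if n_decayed else set()
        for i in range(spec.copy_number):
            cseq = mutate_nucleotides(master, spec.within_divergence / 2, rng)
            trunc_end = None
            offset = 0  # nt of the full element removed from the 5' side
            if i in decayed:
                frac = rng.uniform(0.3, 0.7)
                cut = int(frac * len(cseq))
                if rng.random() < 0.5:
                    trunc_end = "5'"
                    offset = cut
                    cseq = cseq[cut:]
                else:
                    trunc_end = "3'"
                    cseq = cseq[: len(cseq) - cut]
            strand = "-" if (random_strand and rng.random() < 0.5) else "+"
            copies.append(dict(spec=spec, seq=cseq, truth=truth, strand=strand,
                               trunc_end=trunc_end, offset=offset,
                               index=i))

    total_insert = sum(len(c["seq"]) + c["spec"].template.tsd_length for c in copies)
    margin = 2000
    if background_length < total_insert + margin * (len(copies) + 1):
        raise ValueError(
            f"background of {background_length} bp too small for "
            f"{len(copies)} copies ({total_insert} bp plus margins)"
        )

    # Choose well-separated insertion points in background coordinates.
    for _ in range(100):
        points = np.sort(rng.integers(margin, background_length - margin,
                                      size=len(copies)))
        if len(points) < 2 or np.min(np.diff(points)) >= margin:
            break
    else:
        raise ValueError("could not place copies without overlap")
    order = rng.permutation(len(copies))

    pieces: list[str] = []
    truths: list[PlantedCopy] = []
    prev = 0
    for point, ci in zip(points, order):
        c = copies[ci]
        spec: FamilySpec = c["spec"]
        k = spec.template.tsd_length if c["trunc_end"] is None else 0
        tsd = bg[point : point + k] if k else None
        inserted = c["seq"] if c["strand"] == "+" else reverse_complement(c["seq"])

        pieces.append(bg[prev:point + k])
        start = sum(len(p) for p in pieces)  # genome coord of element start
        pieces.append(inserted)
        prev = point  # background resumes at the duplicated site
        end = start + len(inserted)

        truths.append(_copy_truth(c, spec, seq_id, start, end, tsd))

    pieces.append(bg[prev:])
    genome = SequenceRecord(id=seq_id, residues="".join(pieces),
                            alphabet=NUCLEOTIDE)
    truths.sort(key=lambda t: t.start)
    return genome, truths


def _copy_truth(c: dict, spec: FamilySpec, seq_id: str,
                start: int, end: int, tsd: str | None) -> PlantedCopy:
    truth: ElementTruth = c["truth"]
    strand = c["strand"]
    copy_len = end - start
    full_len = truth.length
    offset = c["offset"]  # removed from element 5' side
    copy_id = f"{spec.name}_c{c['index']}"

    def to_copy(iv: tuple[int, int]) -> tuple[int, int] | None:
        a, b = iv[0] - offset, iv[1] - offset
        if a < 0 or b > copy_len:
            return None
        if strand == "-":
            a, b = _mirror((a, b), copy_len)
        return (start + a, start + b)

    features = [Feature(seq_id, start, end, strand, "LTR_retrotransposon",
                        {"ID": copy_id, "family": spec.name,
                         "intact": "0" if c["trunc_end"] else "1"})]
    for name, iv in (("5'", truth.ltr5), ("3'", truth.ltr3)):
        g = to_copy(iv)
        if g:
            features.append(Feature(seq_id, g[0], g[1], strand,
                                    "long_terminal_repeat",
                                    {"Parent": copy_id, "which": name}))
    if tsd:
        k = len(tsd)
        features.append(Feature(seq_id, start - k, start, ".",
                                "target_site_duplication",
                                {"Parent": copy_id, "tsd": tsd}))
        features.append(Feature(seq_id, end, end + k, ".",
                                "target_site_duplication",
                                {"Parent": copy_id, "tsd": tsd}))
    for a, b, name in truth.orfs:
        g = to_copy((a, b))
        if g:
            features.append(Feature(seq_id, g[0], g[1], strand, "ORF",
                                    {"Parent": copy_id, "name": name}))
    for name, a, b in truth.domains:
        g = to_copy((a, b))
        if g:
            features.append(Feature(seq_id, g[0], g[1], strand, "protein_domain",
                                    {"Parent": copy_id, "name": name}))

    cassette_ok = False
    if truth.cassette is not None:
        fwd, rev = truth.cassette[0] - offset, truth.cassette[1] - offset
        cassette_ok = _cassette_intact(c["seq"], fwd, rev)

    return PlantedCopy(
        copy_id=copy_id, family=spec.name, start=start, end=end, strand=strand,
        intact=c["trunc_end"] is None, truncated_end=c["trunc_end"],
        tsd=tsd, cassette_intact=cassette_ok, features=features,
        element_truth=truth,
    )


# ---------------------------------------------------------------------------
# Protein pairs under the Poisson model
# ---------------------------------------------------------------------------

def evolve_protein_pair(length_aa: int, rate_r: float, time_T_myr: float,
                        rng_seed) -> tuple[SequenceRecord, SequenceRecord, float]:
    """Diverge a protein pair for 2*T at rate ``rate_r`` (subs/site/year).

    Each site of the second sequence differs from the first independently
    with probability 1 - exp(-d), d = 2 * r * T; the replacement residue is
    uniform over the 19 alternatives.  Returns (seq1, seq2, true_d).
    """
    if length_aa < 50:
        raise ValueError("length_aa must be >= 50")
    if rate_r < 0 or time_T_myr <= 0:
        raise ValueError("need rate_r >= 0 and time_T_myr > 0")
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator) else rng_seed
    d = 2.0 * rate_r * time_T_myr * 1e6
    p = 1.0 - math.exp(-d)
    s1 = lib.random_protein(rng, length_aa)
    s2 = list(s1)
    for i in np.flatnonzero(rng.random(length_aa) < p):
        s2[i] = lib.AA20.replace(s2[i], "")[rng.integers(0, 19)]
    rec1 = SequenceRecord("seq1", s1, AMINO_ACID)
    rec2 = SequenceRecord("seq2", "".join(s2), AMINO_ACID)
    return rec1, rec2, d


# ---------------------------------------------------------------------------
# Seed alignments, panels and the standard demo scene
# ---------------------------------------------------------------------------

def rt_int_seed_alignment(n: int = 8, divergence: float = 0.15,
                          rng_seed=20100408) -> list[SequenceRecord]:
    """Gap-free seed alignment of RT..partial-Int fragments for profiles."""
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator) else rng_seed
    frag = lib.RT_INT_FRAGMENT
    return [
        SequenceRecord(f"seed{i}", lib.mutate_protein(frag, divergence, rng),
                       AMINO_ACID)
        for i in range(n)
    ]


def reference_panel(clades: tuple[str, ...] = ("Tcn1", "Tcn2", "Pyggy", "Pyret", "Maggy"),
                    divergence: float = 0.30, rng_seed=5704) -> list[SequenceRecord]:
    """Clade-labelled RT-Int reference sequences for hit verification."""
    rng = np.random.default_rng(rng_seed)
    return [
        SequenceRecord(clade, lib.mutate_protein(lib.RT_INT_FRAGMENT, divergence, rng),
                       AMINO_ACID, description="synthetic reference")
        for clade in clades
    ]


def domain_seed_alignments(n: int = 6, divergence: float = 0.12,
                           rng_seed=440) -> dict[str, list[SequenceRecord]]:
    """Per-domain gap-free seed alignments (PR, RT, RH, Int, CHD, dUTPase)."""
    rng = np.random.default_rng(rng_seed)
    out = {}
    for name, cons in lib.DOMAIN_AA.items():
        out[name] = [
            SequenceRecord(f"{name}{i}", lib.mutate_protein(cons, divergence, rng),
                           AMINO_ACID)
            for i in range(n)
        ]
    return out


def trna_panel() -> list[SequenceRecord]:
    return [SequenceRecord(name, seq, NUCLEOTIDE)
            for name, seq in lib.TRNA_PANEL.items()]


def demo_family_specs(n_families: int = 5, copy_number: int = 6,
                      within_divergence: float = 0.03,
                      decay_fraction: float = 0.2) -> list[FamilySpec]:
    """The standard synthetic survey scene: 5 families x 6 copies."""
    return [
        FamilySpec(name=f"fam{i+1}", template=ElementTemplate(),
                   copy_number=copy_number,
                   within_divergence=within_divergence,
                   decay_fraction=decay_fraction)
        for i in range(n_families)
    ]


def demo_scene(rng_seed, background_length: int = 2_000_000, gc: float = 0.5,
               **spec_kwargs) -> tuple[SequenceRecord, list[PlantedCopy]]:
    """Build the standard 2 Mb demo genome with 5 planted families."""
    return plant_elements(background_length, gc,
                          demo_family_specs(**spec_kwargs), rng_seed)
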