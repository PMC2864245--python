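"""Synthetic consensus library for the element generator and domain profiles.

Every sequence here is synthetic: a deterministic pseudo-random stand-in for
the conserved protein domains of Gypsy LTR retrotransposons (PR, RT, RH, Int,
CHD, dUTPase), generated once from a fixed internal seed so that the planted
elements, the search profiles and the reference panel all share one coherent
"ancestral" sequence space.  The reverse-transcriptase coding sequence
carries a degenerate-primer cassette: one exact expansion of the GyRT1
forward primer and, 303 nt downstream, the reverse complement of an exact
expansion of the ty3-A 3'-terminal core, so that in-silico PCR on intact
copies yields a 320 bp product (forward-primer start to reverse-site end).
"""

from __future__ import annotations

import numpy as np

from .io import reverse_complement

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# Degenerate primers targeting the conserved RT core.
GYRT1 = "MRNATGTGYGTNGAYTAYMG"
TY3A_FULL = "AATTCGCTGCCGCTAAGATNARNADRTCRTC"
# The 5' tail of ty3-A is a cloning adapter and never anneals genomically;
# only the 3'-terminal 17 nt core is matched.
TY3A_CORE = TY3A_FULL[-17:]  # AAGATNARNADRTCRTC

# Concrete expansions planted in the RT coding strand.
GYRT1_SITE = "AGAATGTGCGTAGATTACAG"
TY3A_CORE_SITE = "AAGATAAGAAGGTCGTC"
TY3A_SITE_RC = reverse_complement(TY3A_CORE_SITE)

# Cassette geometry inside the RT coding sequence (nt, codon-frame 0).
CASSETTE_FWD_NT = 90                      # GyRT1 site start
CASSETTE_REV_NT = CASSETTE_FWD_NT + 303   # RC(ty3-A core) site start
PCR_PRODUCT_LEN = 320                     # fwd start .. rev-site end

RT_CDS_LEN = 900  # 300 codons

_CODON_TABLE = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"],
    "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
}
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(c for cs in _CODON_TABLE.values() for c in cs)
_TRANSLATE = {c: aa for aa, cs in _CODON_TABLE.items() for c in cs}
_TRANSLATE.update({s: "*" for s in _STOPS})


def translate_cds(cds: str) -> str:
    return "".join(_TRANSLATE[cds[i : i + 3]] for i in range(0, len(cds) - 2, 3))


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AA20[i] for i in rng.integers(0, 20, size=length))


def encode_protein(aa: str, rng: np.random.Generator,
                   fixed_codons: dict[int, str] | None = None) -> str:
    """Reverse-translate, drawing synonymous codons at random.

    ``fixed_codons`` pins whole codons (by codon index) to given nucleotides,
    used to keep the primer cassette bit-identical across families.
    """
    out = []
    for i, a in enumerate(aa):
        if fixed_codons and i in fixed_codons:
            out.append(fixed_codons[i])
        else:
            codons = _CODON_TABLE[a]
            out.append(codons[rng.integers(0, len(codons))])
    return "".join(out)


def mutate_protein(aa: str, rate: float, rng: np.random.Generator,
                   protected: frozenset[int] = frozenset()) -> str:
    """Substitute each site independently with probability ``rate``."""
    if rate <= 0:
        return aa
    out = list(aa)
    hits = np.flatnonzero(rng.random(len(aa)) < rate)
    for i in hits:
        if i in protected:
            continue
        alternatives = AA20.replace(out[i], "")
        out[i] = alternatives[rng.integers(0, 19)]
    return "".join(out)


def _build_rt_cds(rng: np.random.Generator) -> str:
    codons = [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), RT_CDS_LEN // 3)]
    cds = list("".join(codons))
    cds[CASSETTE_FWD_NT : CASSETTE_FWD_NT + len(GYRT1_SITE)] = GYRT1_SITE
    cds[CASSETTE_REV_NT : CASSETTE_REV_NT + len(TY3A_SITE_RC)] = TY3A_SITE_RC
    cds = "".join(cds)
    # Splicing may create in-frame stops at cassette junction codons; repair
    # by swapping the free third base (never inside the fixed windows).
    fixed = set(range(CASSETTE_FWD_NT, CASSETTE_FWD_NT + len(GYRT1_SITE)))
    fixed |= set(range(CASSETTE_REV_NT, CASSETTE_REV_NT + len(TY3A_SITE_RC)))
    out = list(cds)
    for c in range(0, RT_CDS_LEN, 3):
        while "".join(out[c : c + 3]) in _STOPS:
            for pos in (c + 2, c + 1, c):
                if pos not in fixed:
                    choices = [b for b in "ACGT" if b != out[pos]]
                    out[pos] = choices[rng.integers(0, 3)]
                    break
            else:  # pragma: no cover - cassette windows contain no stops
                raise AssertionError("unfixable stop codon in cassette")
    return "".join(out)


# ---------------------------------------------------------------------------
# Library construction (fixed internal seed; import-time, ~milliseconds).
# ---------------------------------------------------------------------------

_rng = np.random.default_rng(797801)

RT_CDS = _build_rt_cds(_rng)
RT_AA = translate_cds(RT_CDS)
assert "*" not in RT_AA

# Codon indices whose nucleotides are pinned to RT_CDS in every family
# (codons overlapping the two primer sites).
RT_FIXED_CODONS = {
    i: RT_CDS[3 * i : 3 * i + 3]
    for i in sorted(
        set(range(CASSETTE_FWD_NT // 3, (CASSETTE_FWD_NT + len(GYRT1_SITE) + 2) // 3))
        | set(range(CASSETTE_REV_NT // 3, (CASSETTE_REV_NT + len(TY3A_SITE_RC) + 2) // 3))
    )
}

DOMAIN_AA = {
    "PR": random_protein(_rng, 110),
    "RT": RT_AA,
    "RH": random_protein(_rng, 130),
    "Int": random_protein(_rng, 250),
    "CHD": random_protein(_rng, 60),
    "dUTPase": random_protein(_rng, 140),
}

# Conserved linkers of the polyprotein scaffold (part of the consensus so
# that the RT..Int search fragment is contiguous).
LINKERS = {
    "lead": random_protein(_rng, 40),
    ("PR", "RT"): random_protein(_rng, 60),
    ("RT", "RH"): random_protein(_rng, 50),
    ("RH", "Int"): random_protein(_rng, 60),
    ("Int", "CHD"): random_protein(_rng, 40),
    "tail": random_protein(_rng, 137),
    "generic": random_protein(_rng, 20),
}

# Synthetic tRNA panel (3' termini are what PBS detection matches).
TRNA_PANEL = {
    f"tRNA-{name}": "".join("ACGT"[i] for i in _rng.integers(0, 4, 72))
    for name in ("Met", "Lys", "Arg", "Ser")
}

del _rng


def pol_layout(domain_order: tuple[str, ...]) -> list[tuple[str | None, str]]:
    """Assemble the polyprotein as (domain_name_or_None, aa_segment) parts.

    The default chromovirus order PR-RT-RH-Int-CHD totals 1238 aa.
    """
    parts: list[tuple[str | None, str]] = [(None, "M"), (None, LINKERS["lead"])]
    for i, dom in enumerate(domain_order):
        parts.append((dom, DOMAIN_AA[dom]))
        if i < len(domain_order) - 1:
            key = (dom, domain_order[i + 1])
            parts.append((None, LINKERS.get(key, LINKERS["generic"])))
    parts.append((None, LINKERS["tail"]))
    return parts


def pol_consensus(domain_order: tuple[str, ...]) -> tuple[str, dict[str, tuple[int, int]]]:
    """Polyprotein consensus and per-domain aa intervals."""
    aa = []
    intervals: dict[str, tuple[int, int]] = {}
    pos = 0
    for dom, seg in pol_layout(domain_order):
        if dom is not None:
            intervals[dom] = (pos, pos + len(seg))
        aa.append(seg)
        pos += len(seg)
    return "".join(aa), intervals


DEFAULT_DOMAIN_ORDER = ("PR", "RT", "RH", "Int", "CHD")
POL_AA, POL_DOMAIN_INTERVALS = pol_consensus(DEFAULT_DOMAIN_ORDER)
assert len(POL_AA) == 1238

# The RT .. partial-Int fragment used for mining profiles, family clustering
# and the reference panel (660 aa: RT through the first 120 aa of Int).
RT_INT_START = POL_DOMAIN_INTERVALS["RT"][0]
RT_INT_END = POL_DOMAIN_INTERVALS["Int"][0] + 120
RT_INT_FRAGMENT = POL_AA[RT_INT_START:RT_INT_END]

# Pol aa positions that must never mutate (primer-cassette codons).
POL_PROTECTED = frozenset(RT_INT_START + c for c in RT_FIXED_CODONS)
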