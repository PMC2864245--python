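"""Profile search for RT..partial-Int coding regions in genomic sequence.

Six-frame translation feeds a position-specific scoring model (PSSM with
affine gap penalties, scored in bits against a uniform 1/20 background);
the glocal Viterbi — profile global, sequence local — reports every
non-overlapping segment above a bit threshold.  Hits are then verified by
local alignment (BLOSUM62, gap 11/1) against a labelled reference panel and
merged into loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from Bio.Align import PairwiseAligner, substitution_matrices
from numba import njit

from .io import SequenceRecord, AMINO_ACID, NUCLEOTIDE, reverse_complement
from ._domains import AA20

_AA_INDEX = {a: i for i, a in enumerate(AA20)}
_UNKNOWN = 20  # 'X', '*', anything non-standard
_UNKNOWN_SCORE = -8.0  # bits; discourages crossing stops/ambiguity


@dataclass
class TranslatedFrame:
    """One reading frame of a nucleotide sequence with its coordinate map."""

    source_id: str
    frame: int  # +1,+2,+3,-1,-2,-3
    aa_sequence: str
    source_length: int

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"

    @property
    def offset(self) -> int:
        return abs(self.frame) - 1

    def aa_to_nt(self, aa_start: int, aa_end: int) -> tuple[int, int]:
        """Map an aa interval to a source-nucleotide interval (0-based)."""
        a = self.offset + 3 * aa_start
        b = self.offset + 3 * aa_end
        if self.frame > 0:
            return a, b
        return self.source_length - b, self.source_length - a


def six_frame_translate(record: SequenceRecord) -> list[TranslatedFrame]:
    """Translate a nucleotide record in all six frames (standard code).

    Stop codons are emitted as '*'; ambiguity codons translate to 'X'
    unless every IUPAC expansion agrees on one residue.
    """
    if record.alphabet != NUCLEOTIDE:
        raise ValueError("six_frame_translate requires nucleotide input")
    if len(record) < 3:
        raise ValueError("sequence shorter than one codon")
    frames = []
    rc = reverse_complement(record.residues)
    for strand_seq, sign in ((record.residues, 1), (rc, -1)):
        for off in range(3):
            sub = strand_seq[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            aa = str(Seq(sub).translate()) if sub else ""
            frames.append(
                TranslatedFrame(record.id, sign * (off + 1), aa, len(record))
            )
    return frames


@dataclass
class ProfileModel:
    """Per-column emission log-odds (bits) with affine gap penalties."""

    log_odds: np.ndarray  # (ncolumns, 21); column 20 scores unknown residues
    gap_open: float = 12.0
    gap_extend: float = 0.25   # deletion extend: skipping profile columns
    ins_extend: float = 4.0    # insertion extend: skipping sequence residues
    threshold: float = 25.0
    consensus: str = ""

    @property
    def ncolumns(self) -> int:
        return self.log_odds.shape[0]


def build_profile(seed_alignment: list[SequenceRecord], pseudocount: float = 0.5,
                  gap_open: float = 12.0, gap_extend: float = 0.25,
                  ins_extend: float = 4.0,
                  threshold: float | None = None) -> ProfileModel:
    """Build a PSSM from an aligned FASTA of >= 2 equal-length sequences.

    Match columns are those with < 50% gap characters; emissions are
    (count + pseudocount) / (total + 20 * pseudocount), converted to
    log2 odds against a uniform 1/20 background.

    The default bit threshold scales with profile length (0.15 bits per
    match column, floor 25): genuine homologs score >= 1 bit per column
    even at deep divergence, while empirical scrambled-sequence maxima
    stay far below this line (see the calibration test suite).
    """
    if len(seed_alignment) < 2:
        raise ValueError("seed alignment needs >= 2 sequences")
    lengths = {len(r.residues) for r in seed_alignment}
    if len(lengths) != 1:
        raise ValueError("ragged seed alignment (unequal sequence lengths)")
    ncols_in = lengths.pop()
    nseq = len(seed_alignment)
    rows = [r.residues for r in seed_alignment]

    cols = []
    for c in range(ncols_in):
        col = [row[c] for row in rows]
        gaps = sum(ch in "-." for ch in col)
        if gaps * 2 < nseq:
            cols.append(col)

    log_odds = np.empty((len(cols), 21), dtype=np.float64)
    consensus = []
    for i, col in enumerate(cols):
        counts = np.zeros(20)
        for ch in col:
            idx = _AA_INDEX.get(ch)
            if idx is not None:
                counts[idx] += 1
        total = counts.sum()
        probs = (counts + pseudocount) / (total + 20 * pseudocount)
        with np.errstate(divide="ignore"):  # -inf is fine at pseudocount 0
            log_odds[i, :20] = np.log2(probs * 20.0)
        log_odds[i, 20] = _UNKNOWN_SCORE
        consensus.append(AA20[int(np.argmax(counts))])

    if threshold is None:
        threshold = max(25.0, 0.15 * len(cols))
    return ProfileModel(log_odds=log_odds, gap_open=gap_open,
                        gap_extend=gap_extend, ins_extend=ins_extend,
                        threshold=threshold, consensus="".join(consensus))


@dataclass
class DomainHit:
    """One profile match on a translated frame."""

    source_id: str
    frame: int
    aa_start: int
    aa_end: int
    nt_start: int
    nt_end: int
    strand: str
    score: float
    coverage: float
    translation: str
    label: str | None = None
    identity: float | None = None


def encode_protein_indices(aa: str) -> np.ndarray:
    idx = np.full(len(aa), _UNKNOWN, dtype=np.int64)
    for i, ch in enumerate(aa):
        idx[i] = _AA_INDEX.get(ch, _UNKNOWN)
    return idx


@njit(cache=True)
def _glocal_end_scores(lo, sidx, gap_open, gap_extend, ins_extend):
    """Best glocal score ending at each sequence position (profile global)."""
    N = lo.shape[0]
    L = sidx.shape[0]
    NEG = -1e30
    E = np.full(L, NEG)
    if L == 0:
        return E
    M = np.empty(L)
    D = np.empty(L)
    I = np.empty(L)
    Mp = np.empty(L)
    Dp = np.empty(L)
    Ip = np.empty(L)
    for j in range(L):
        Mp[j] = lo[0, sidx[j]]
        Dp[j] = -gap_open  # column 0 deleted, nothing consumed
        Ip[j] = NEG
    for j in range(1, L):
        a = Mp[j - 1] - gap_open
        b = Ip[j - 1] - ins_extend
        Ip[j] = a if a > b else b
    if N == 1:
        for j in range(L):
            E[j] = Mp[j]
        return E
    for i in range(1, N):
        del_prefix = -(gap_open + (i - 1) * gap_extend)
        for j in range(L):
            best = Dp[j - 1] if j > 0 else del_prefix
            if j > 0:
                if Mp[j - 1] > best:
                    best = Mp[j - 1]
                if Ip[j - 1] > best:
                    best = Ip[j - 1]
            M[j] = lo[i, sidx[j]] + best
            a = Mp[j] - gap_open
            b = Dp[j] - gap_extend
            D[j] = a if a > b else b
        I[0] = NEG
        for j in range(1, L):
            a = M[j - 1] - gap_open
            b = I[j - 1] - ins_extend
            I[j] = a if a > b else b
        Mp, M = M, Mp
        Dp, D = D, Dp
        Ip, I = I, Ip
    for j in range(L):
        E[j] = Mp[j] if Mp[j] > Dp[j] else Dp[j]
    return E


@njit(cache=True)
def _glocal_traceback(lo, sidx, gap_open, gap_extend, ins_extend):
    """Full DP with pointers on a window; returns (start, matches, score).

    The alignment must end at the window's last position (in M or D state).
    """
    N = lo.shape[0]
    L = sidx.shape[0]
    NEG = -1e30
    M = np.full((N, L), NEG)
    D = np.full((N, L), NEG)
    I = np.full((N, L), NEG)
    # pointers: 0=M,1=D,2=I; -1 = alignment start
    Mp = np.full((N, L), -1, dtype=np.int8)
    Dp = np.zeros((N, L), dtype=np.int8)
    Ip = np.zeros((N, L), dtype=np.int8)
    for j in range(L):
        M[0, j] = lo[0, sidx[j]]
        D[0, j] = -gap_open
    for j in range(1, L):
        a = M[0, j - 1] - gap_open
        b = I[0, j - 1] - ins_extend
        if a >= b:
            I[0, j] = a
            Ip[0, j] = 0
        else:
            I[0, j] = b
            Ip[0, j] = 2
    for i in range(1, N):
        del_prefix = -(gap_open + (i - 1) * gap_extend)
        for j in range(L):
            best = del_prefix
            ptr = -1
            if j > 0:
                if M[i - 1, j - 1] > best:
                    best = M[i - 1, j - 1]
                    ptr = 0
                if D[i - 1, j - 1] > best:
                    best = D[i - 1, j - 1]
                    ptr = 1
                if I[i - 1, j - 1] > best:
                    best = I[i - 1, j - 1]
                    ptr = 2
            M[i, j] = lo[i, sidx[j]] + best
            Mp[i, j] = ptr
            a = M[i - 1, j] - gap_open
            b = D[i - 1, j] - gap_extend
            if a >= b:
                D[i, j] = a
                Dp[i, j] = 0
            else:
                D[i, j] = b
                Dp[i, j] = 1
            if j > 0:
                a = M[i, j - 1] - gap_open
                b = I[i, j - 1] - ins_extend
                if a >= b:
                    I[i, j] = a
                    Ip[i, j] = 0
                else:
                    I[i, j] = b
                    Ip[i, j] = 2
    j = L - 1
    if M[N - 1, j] >= D[N - 1, j]:
        state = 0
        score = M[N - 1, j]
    else:
        state = 1
        score = D[N - 1, j]
    i = N - 1
    # Walk back, recording per-step score increments (reverse order).
    max_steps = 2 * (N + L)
    step_score = np.empty(max_steps)
    step_j = np.full(max_steps, -1, dtype=np.int64)
    step_m = np.zeros(max_steps, dtype=np.int8)
    k = 0
    while True:
        if state == 0:
            step_score[k] = lo[i, sidx[j]]
            step_j[k] = j
            step_m[k] = 1
            k += 1
            ptr = Mp[i, j]
            if ptr == -1:
                break
            i -= 1
            j -= 1
            state = ptr
        elif state == 1:
            ptr = Dp[i, j]
            step_score[k] = -gap_open if ptr == 0 else -gap_extend
            k += 1
            i -= 1
            state = ptr
            if i < 0:
                break
        else:
            ptr = Ip[i, j]
            step_score[k] = -gap_open if ptr == 0 else -ins_extend
            step_j[k] = j
            k += 1
            j -= 1
            state = ptr
            if j < 0:
                break
    # Kadane over forward step order: trim the alignment to its
    # maximal-scoring contiguous core (drops weak junk at the envelopes).
    best_sum = -1e30
    best_a = best_b = 0
    cur_sum = 0.0
    cur_a = k - 1
    for idx in range(k - 1, -1, -1):  # forward order
        if cur_sum <= 0.0:
            cur_sum = step_score[idx]
            cur_a = idx
        else:
            cur_sum += step_score[idx]
        if cur_sum > best_sum:
            best_sum = cur_sum
            best_a = cur_a
            best_b = idx
    core_start = -1
    core_end = -1
    matches = 0
    for idx in range(best_a, best_b - 1, -1):
        if step_j[idx] >= 0:
            if core_start < 0:
                core_start = step_j[idx]
            core_end = step_j[idx]
        if step_m[idx] == 1:
            matches += 1
    if core_start < 0:  # degenerate: no residue consumed in the core
        core_start = core_end = j if j >= 0 else 0
    return core_start, core_end, matches, score


def _scan_indices(sidx: np.ndarray, profile: ProfileModel,
                  ) -> list[tuple[int, int, float, float]]:
    """All non-overlapping glocal hits >= threshold, best-first.

    Greedy select-and-mask: take the best remaining end position, trace its
    alignment back, report the maximal-scoring core, then mask every end
    the accepted hit explains (one profile length of slack each side).
    Ends whose core collides with an accepted hit are trailing shoulders of
    that hit and are masked without a report.
    Returns (aa_start, aa_end, score, coverage) tuples.
    """
    if sidx.size == 0:
        return []
    lo = np.ascontiguousarray(profile.log_odds, dtype=np.float64)
    E = _glocal_end_scores(lo, sidx, profile.gap_open, profile.gap_extend,
                           profile.ins_extend)
    N = profile.ncolumns
    hits: list[tuple[int, int, float, float]] = []
    taken: list[tuple[int, int]] = []
    for _ in range(1000):  # generous cap; each round masks a wide range
        j = int(np.argmax(E))
        if E[j] < profile.threshold:
            break
        w0 = max(0, j - 2 * N - 64)
        cs, ce, matches, score = _glocal_traceback(
            lo, sidx[w0 : j + 1], profile.gap_open, profile.gap_extend,
            profile.ins_extend)
        a, b = w0 + cs, w0 + ce + 1
        if any(a < tb and ta < b for ta, tb in taken):
            E[a : j + 1] = -np.inf  # shoulder of an accepted hit
            continue
        hits.append((a, b, float(score), matches / N))
        taken.append((a, b))
        E[max(0, a - N) : min(len(E), b + N)] = -np.inf
    hits.sort(key=lambda h: -h[2])
    return hits


def scan_profile(frame: TranslatedFrame, profile: ProfileModel) -> list[DomainHit]:
    """Scan one translated frame; report non-overlapping hits best-first."""
    sidx = encode_protein_indices(frame.aa_sequence)
    out = []
    for a, b, score, cov in _scan_indices(sidx, profile):
        nt_start, nt_end = frame.aa_to_nt(a, b)
        out.append(DomainHit(
            source_id=frame.source_id, frame=frame.frame,
            aa_start=a, aa_end=b, nt_start=nt_start, nt_end=nt_end,
            strand=frame.strand, score=score, coverage=cov,
            translation=frame.aa_sequence[a:b],
        ))
    return out


def scan_protein(protein: str, profile: ProfileModel, name: str = "",
                 ) -> list[DomainHit]:
    """Scan a plain amino-acid sequence (used for per-domain annotation)."""
    sidx = encode_protein_indices(protein)
    return [
        DomainHit(source_id=name, frame=0, aa_start=a, aa_end=b,
                  nt_start=3 * a, nt_end=3 * b, strand="+", score=score,
                  coverage=cov, translation=protein[a:b])
        for a, b, score, cov in _scan_indices(sidx, profile)
    ]


# ---------------------------------------------------------------------------
# Verification against a reference panel (blastp-style)
# ---------------------------------------------------------------------------

def _local_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "local"
    return aligner


def local_identity(a: str, b: str,
                   aligner: PairwiseAligner | None = None) -> tuple[float, int]:
    """(identity, aligned_length) of the best local alignment of a vs b."""
    aligner = aligner or _local_aligner()
    a = a.replace("*", "X")
    b = b.replace("*", "X")
    try:
        aln = aligner.align(a, b)[0]
    except (IndexError, ValueError):
        return 0.0, 0
    matches = 0
    aligned = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        aligned += a1 - a0
        matches += sum(1 for x, y in zip(a[a0:a1], b[b0:b1]) if x == y)
    if aligned == 0:
        return 0.0, 0
    return matches / aligned, aligned


def verify_hits(hits: list[DomainHit], reference_panel: list[SequenceRecord],
                min_identity: float = 0.25, min_aligned: int = 100,
                ) -> list[DomainHit]:
    """Keep hits with >= min_identity over >= min_aligned aa to some panel
    member; annotate each kept hit with the best panel label."""
    if not reference_panel:
        raise ValueError("empty reference panel")
    aligner = _local_aligner()
    kept = []
    for hit in hits:
        best = (0.0, 0, None)
        for ref in reference_panel:
            ident, alen = local_identity(hit.translation, ref.residues, aligner)
            if alen >= min_aligned and ident > best[0]:
                best = (ident, alen, ref.id)
        if best[2] is not None and best[0] >= min_identity:
            hit.label = best[2]
            hit.identity = best[0]
            kept.append(hit)
    return kept


# ---------------------------------------------------------------------------
# Locus assembly
# ---------------------------------------------------------------------------

@dataclass
class SearchLocus:
    """Same-strand hits within max_gap_nt merged into one genomic locus."""

    source_id: str
    start: int
    end: int
    strand: str
    hits: list[DomainHit] = field(default_factory=list)

    @property
    def best_hit(self) -> DomainHit:
        return max(self.hits, key=lambda h: h.score)


def merge_hits(hits: list[DomainHit], max_gap_nt: int = 1000) -> list[SearchLocus]:
    """Merge same-source, same-strand hits within max_gap_nt into loci."""
    loci: list[SearchLocus] = []
    for key in sorted({(h.source_id, h.strand) for h in hits}):
        group = sorted((h for h in hits
                        if (h.source_id, h.strand) == key),
                       key=lambda h: h.nt_start)
        current: SearchLocus | None = None
        for h in group:
            if current is not None and h.nt_start - current.end <= max_gap_nt:
                current.end = max(current.end, h.nt_end)
                current.hits.append(h)
            else:
                current = SearchLocus(h.source_id, h.nt_start, h.nt_end,
                                      h.strand, [h])
                loci.append(current)
    loci.sort(key=lambda l: (l.source_id, l.start))
    return loci


def mine_genome(records: list[SequenceRecord], profile: ProfileModel,
                reference_panel: list[SequenceRecord] | None = None,
                min_identity: float = 0.25, max_gap_nt: int = 1000,
                ) -> list[SearchLocus]:
    """Six-frame translate, scan, optionally verify, and merge into loci."""
    all_hits: list[DomainHit] = []
    for rec in records:
        for frame in six_frame_translate(rec):
            all_hits.extend(scan_profile(frame, profile))
    if reference_panel is not None:
        all_hits = verify_hits(all_hits, reference_panel, min_identity)
    return merge_hits(all_hits, max_gap_nt)
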