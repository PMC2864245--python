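"""Family classification of annotated elements and genome-occupancy summaries.

Elements are grouped into families by amino-acid identity of their RT-Int
region (members of one family share >= 90% identity, different families
very little), then each family's copy number and genome fraction are
estimated by nucleotide search with the family representative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .io import SequenceRecord, reverse_complement


def _global_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def pairwise_identity(protein_a: str, protein_b: str,
                      include_gaps: bool = False,
                      aligner: PairwiseAligner | None = None) -> float:
    """Global-alignment amino-acid identity of two proteins.

    By default identity is matches / aligned columns excluding columns where
    either sequence has a gap; ``include_gaps=True`` counts gap columns as
    mismatches (both conventions occur in the literature).  Symmetric.
    """
    if not protein_a or not protein_b:
        raise ValueError("empty protein sequence")
    aligner = aligner or _global_aligner()
    a = protein_a.replace("*", "X")
    b = protein_b.replace("*", "X")
    aln = aligner.align(a, b)[0]
    matches = 0
    aligned = 0
    total_cols = 0
    prev_a = prev_b = 0
    blocks_a, blocks_b = aln.aligned
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        total_cols += max(a0 - prev_a, b0 - prev_b)  # gap columns
        prev_a, prev_b = a1, b1
        aligned += a1 - a0
        total_cols += a1 - a0
        matches += sum(1 for x, y in zip(a[a0:a1], b[b0:b1]) if x == y)
    total_cols += max(len(a) - prev_a, len(b) - prev_b)
    denom = total_cols if include_gaps else aligned
    if denom == 0:
        return 0.0
    return matches / denom


@dataclass
class Family:
    name: str
    member_ids: list[str]
    representative_id: str
    mean_within_identity: float
    copy_number: int = 0
    genome_fraction: float = 0.0


def cluster_families(elements: dict[str, str], threshold: float = 0.90,
                     include_gaps: bool = False) -> list[Family]:
    """Single-linkage clustering of elements by RT-Int amino-acid identity.

    ``elements`` maps element id -> RT-Int protein sequence.  Output is
    sorted by family size (descending) then by the lexicographically
    smallest member id; deterministic and input-order invariant.
    """
    ids = sorted(elements)
    n = len(ids)
    aligner = _global_aligner()
    ident = np.zeros((n, n))
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            ident[i, j] = ident[j, i] = pairwise_identity(
                elements[ids[i]], elements[ids[j]], include_gaps, aligner)
            if ident[i, j] >= threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    families = []
    for members in groups.values():
        member_ids = sorted(ids[i] for i in members)
        rep = max(member_ids, key=lambda mid: (len(elements[mid]), mid))
        if len(members) > 1:
            vals = [ident[i, j] for i in members for j in members if i < j]
            mean_ident = float(np.mean(vals))
        else:
            mean_ident = 1.0
        families.append(Family(name="", member_ids=member_ids,
                               representative_id=rep,
                               mean_within_identity=mean_ident))
    families.sort(key=lambda f: (-len(f.member_ids), f.member_ids[0]))
    for i, fam in enumerate(families):
        fam.name = f"F{i + 1:03d}"
    return families


# ---------------------------------------------------------------------------
# Copy number and genome fraction by nucleotide search
# ---------------------------------------------------------------------------

def _seed_hits(query: str, genome: str, k: int = 16) -> dict[int, list[int]]:
    """Genome positions of exact k-mer matches, keyed by rounded diagonal."""
    index: dict[str, list[int]] = {}
    for i in range(0, len(query) - k + 1, 4):
        index.setdefault(query[i : i + k], []).append(i)
    hits: dict[int, list[int]] = {}
    for j in range(len(genome) - k + 1):
        for i in index.get(genome[j : j + k], ()):
            hits.setdefault((j - i) // 400, []).append(j)
    return hits


def find_nucleotide_hits(query: str, genome: str, min_identity: float = 0.80,
                         min_len: int = 100, k: int = 16,
                         ) -> list[tuple[int, int, str, float]]:
    """Seed-and-extend local search of ``query`` against both genome strands.

    Returns non-overlapping (start, end, strand, identity) spans of length
    >= min_len at >= min_identity, best-length-first.
    """
    candidates: list[tuple[int, int, str, float]] = []
    L = len(genome)
    for strand, g in (("+", genome), ("-", reverse_complement(genome))):
        hits = _seed_hits(query, g, k)
        # merge adjacent diagonal bands into candidate windows
        positions = sorted(p for ps in hits.values() for p in ps)
        if not positions:
            continue
        windows: list[tuple[int, int]] = []
        w0 = w1 = positions[0]
        for p in positions[1:]:
            if p - w1 <= 1000:
                w1 = p
            else:
                windows.append((w0, w1 + k))
                w0 = w1 = p
        windows.append((w0, w1 + k))
        for a, b in windows:
            # the seed extent sits inside the true copy span; align it
            # against the representative as an infix
            res = edlib.align(g[a:b], query, mode="HW", task="distance")
            span = b - a
            if span < min_len:
                continue
            identity = 1.0 - res["editDistance"] / span
            if identity < min_identity:
                continue
            if strand == "+":
                candidates.append((a, b, "+", identity))
            else:
                candidates.append((L - b, L - a, "-", identity))
    candidates.sort(key=lambda c: -(c[1] - c[0]))
    chosen: list[tuple[int, int, str, float]] = []
    for c in candidates:
        if any(c[0] < o[1] and o[0] < c[1] for o in chosen):
            continue
        chosen.append(c)
    chosen.sort()
    return chosen


def estimate_copy_number(representative: str, genome: SequenceRecord,
                         min_identity: float = 0.80, min_len: int = 100,
                         ) -> int:
    """Count non-overlapping nucleotide hits of the representative."""
    return len(find_nucleotide_hits(representative, genome.residues,
                                    min_identity, min_len))


def genome_fraction(hit_spans: list[tuple[int, int]], genome_length: int,
                    ) -> float:
    """Fraction of the genome covered by the union of hit spans."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    spans = sorted(hit_spans)
    covered = 0
    cur_start = cur_end = None
    for a, b in spans:
        if cur_end is None or a > cur_end:
            if cur_end is not None:
                covered += cur_end - cur_start
            cur_start, cur_end = a, b
        else:
            cur_end = max(cur_end, b)
    if cur_end is not None:
        covered += cur_end - cur_start
    return covered / genome_length


def summarize_families(families: list[Family], element_seqs: dict[str, str],
                       genome: SequenceRecord,
                       min_identity: float = 0.80, min_len: int = 100,
                       ) -> list[Family]:
    """Fill in copy_number and genome_fraction for each family in place."""
    for fam in families:
        rep = element_seqs[fam.representative_id]
        hits = find_nucleotide_hits(rep, genome.residues, min_identity, min_len)
        fam.copy_number = len(hits)
        fam.genome_fraction = genome_fraction(
            [(a, b) for a, b, _, _ in hits], len(genome))
    return families
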