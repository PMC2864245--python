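"""Distance phylogenetics: progressive alignment, neighbor-joining with
bootstrap support, outgroup rooting and reference-based clade assignment.

Distances are p-distances over shared ungapped columns, optionally with the
Poisson multiple-hit correction d = -ln(1 - p).  Neighbor joining follows
the Saitou-Nei Q-criterion with lexicographic tie-breaking and negative
branch lengths clamped to zero (deficit transferred to the sister branch),
so that trees are deterministic functions of the input matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from Bio.Align import substitution_matrices

from .io import SequenceRecord, AMINO_ACID, NUCLEOTIDE

# ---------------------------------------------------------------------------
# Tree structure
# ---------------------------------------------------------------------------


@dataclass
class Node:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out = []
        for child in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class Tree:
    root: Node
    rooted: bool = False

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.root.leaves()]

    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else f"{node.support:g}"
            return f"({inner}){label}:{node.length:.6g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        label = "" if self.root.support is None else f"{self.root.support:g}"
        return f"({inner}){label};"

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        import dendropy

        dtree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)

        def convert(dnode) -> Node:
            node = Node(length=dnode.edge.length or 0.0)
            if dnode.is_leaf():
                node.name = dnode.taxon.label if dnode.taxon else dnode.label
            else:
                if dnode.label is not None:
                    try:
                        node.support = float(dnode.label)
                    except ValueError:
                        node.name = dnode.label
                node.children = [convert(c) for c in dnode.child_nodes()]
            return node

        root = convert(dtree.seed_node)
        return cls(root=root, rooted=len(root.children) == 2)

    def bipartitions(self, with_support: bool = False):
        """Non-trivial bipartitions as frozensets of one side's leaf names.

        Sides are canonicalized to exclude the lexicographically smallest
        leaf, so each internal edge maps to exactly one frozenset.
        """
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        result = {}

        def walk(node: Node) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset()
            for child in node.children:
                below |= walk(child)
            if 1 < len(below) < len(all_leaves) - 1:
                side = below if anchor not in below else all_leaves - below
                if 1 < len(side):
                    result[side] = node.support
            return below

        walk(self.root)
        return result if with_support else set(result)

    def path_distances(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf path lengths (sum of branch lengths)."""
        dists: dict[tuple[str, str], float] = {}

        def walk(node: Node) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: node.length}
            merged: dict[str, float] = {}
            groups = [walk(c) for c in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a, da in groups[gi].items():
                        for b, db in groups[gj].items():
                            key = (a, b) if a < b else (b, a)
                            dists[key] = da + db
            for g in groups:
                for name, d in g.items():
                    merged[name] = d + node.length
            return merged

        walk(self.root)
        return dists


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.all(np.isfinite(m)):
            raise ValueError("non-finite distances")
        if not np.allclose(m, m.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("nonzero diagonal")
        if np.any(m < 0):
            raise ValueError("negative distances")


def poisson_correct(p: float) -> float:
    if p >= 1 - 1e-9:
        raise ValueError(f"p-distance {p} too large for Poisson correction")
    if p < 0:
        raise ValueError("negative p-distance")
    return -math.log1p(-p)


def distance_matrix(alignment: list[SequenceRecord],
                    model: str = "poisson") -> DistanceMatrix:
    """Pairwise distances over shared ungapped columns of an alignment."""
    if model not in {"p", "poisson"}:
        raise ValueError(f"unknown model {model!r}")
    ids = [r.id for r in alignment]
    rows = np.array([list(r.residues) for r in alignment])
    gap = (rows == "-") | (rows == ".")
    n = len(ids)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~gap[i] & ~gap[j]
            total = int(shared.sum())
            if total == 0:
                raise ValueError(f"no shared columns for {ids[i]}/{ids[j]}")
            p = float((rows[i][shared] != rows[j][shared]).sum() / total)
            d = poisson_correct(p) if model == "poisson" else p
            m[i, j] = m[j, i] = d
    return DistanceMatrix(ids=ids, matrix=m)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining; deterministic, additive-exact.

    Ties in the Q-criterion break on the lexicographically smallest pair of
    cluster labels (each cluster labelled by its smallest leaf).  Negative
    branch lengths are clamped to zero with the deficit transferred to the
    sister branch.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    d = dm.matrix.astype(float).copy()
    nodes = [Node(name=name) for name in dm.ids]
    labels = list(dm.ids)
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        pairs = [
            (tuple(sorted((labels[active[i]], labels[active[j]]))), i, j)
            for i, j in zip(*np.nonzero(np.isclose(q, qmin, rtol=0, atol=1e-12)))
            if i < j
        ]
        _, i, j = min(pairs)
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = dij / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        child_i, child_j = nodes[ai], nodes[aj]
        child_i.length = li
        child_j.length = lj
        new = Node(children=[child_i, child_j])
        new_idx = len(nodes)
        nodes.append(new)
        labels.append(min(labels[ai], labels[aj]))
        newrow = np.zeros(len(nodes))
        d = np.pad(d, ((0, 1), (0, 1)))
        for kk in active:
            if kk in (ai, aj):
                continue
            dist = (d[ai, kk] + d[aj, kk] - dij) / 2
            d[new_idx, kk] = d[kk, new_idx] = max(dist, 0.0)
        active = [a for a in active if a not in (ai, aj)] + [new_idx]

    a, b, c = active
    la = (d[a, b] + d[a, c] - d[b, c]) / 2
    lb = (d[a, b] + d[b, c] - d[a, c]) / 2
    lc = (d[a, c] + d[b, c] - d[a, b]) / 2
    order = sorted([(labels[a], a, la), (labels[b], b, lb), (labels[c], c, lc)])
    children = []
    for _, idx, length in order:
        nodes[idx].length = max(length, 0.0)
        children.append(nodes[idx])
    return Tree(root=Node(children=children), rooted=False)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap(alignment: list[SequenceRecord], builder=None, n: int = 1000,
              seed: int = 0, model: str = "poisson") -> Tree:
    """Column bootstrap: resample alignment columns with replacement.

    Support on each internal node of the point-estimate tree is the
    percentage of replicates whose tree contains the same bipartition.
    """
    if builder is None:
        def builder(aln):
            return nj_tree(distance_matrix(aln, model=model))

    point = builder(alignment)
    if n == 0:
        return point
    rng = np.random.default_rng(seed)
    ncols = len(alignment[0].residues)
    rows = [r.residues for r in alignment]
    counts: dict[frozenset, int] = {bp: 0 for bp in point.bipartitions()}
    for _ in range(n):
        cols = rng.integers(0, ncols, size=ncols)
        resampled = [
            SequenceRecord(r.id, "".join(row[c] for c in cols), r.alphabet)
            for r, row in zip(alignment, rows)
        ]
        try:
            rep_tree = builder(resampled)
        except ValueError:
            continue  # degenerate resample (e.g. all-gap shared columns)
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1

    all_leaves = frozenset(point.leaf_names())
    anchor = min(all_leaves)

    def annotate(node: Node) -> frozenset:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset()
        for child in node.children:
            below |= annotate(child)
        if 1 < len(below) < len(all_leaves) - 1:
            side = below if anchor not in below else all_leaves - below
            if side in counts:
                node.support = 100.0 * counts[side] / n
        return below

    annotate(point.root)
    return point


# ---------------------------------------------------------------------------
# Rooting and clade assignment
# ---------------------------------------------------------------------------

def root_with_outgroup(tree: Tree, outgroup_ids: list[str]) -> Tree:
    """Root on the branch separating the outgroup from everything else."""
    names = set(tree.leaf_names())
    og = set(outgroup_ids)
    if not og or not og.issubset(names):
        raise ValueError("outgroup must be a non-empty subset of leaves")
    if og == names:
        raise ValueError("outgroup cannot contain all leaves")
    if len(og) > 1:
        bps = tree.bipartitions()
        all_leaves = frozenset(names)
        anchor = min(all_leaves)
        target = frozenset(og) if anchor not in og else all_leaves - og
        if len(names - og) > 1 and target not in bps:
            raise ValueError("outgroup is not monophyletic in the tree")

    import dendropy

    dtree = dendropy.Tree.get(data=tree.to_newick(), schema="newick", preserve_underscores=True)
    taxa = [t for t in dtree.taxon_namespace if t.label in og]
    if len(og) == 1:
        node = dtree.find_node_with_taxon_label(list(og)[0])
        edge = node.edge
    else:
        mrca = dtree.mrca(taxa=taxa)
        edge = mrca.edge
    length = edge.length or 0.0
    dtree.reroot_at_edge(edge, length1=length / 2, length2=length / 2,
                         update_bipartitions=False)
    rooted = Tree.from_newick(dtree.as_string(schema="newick",
                                              suppress_rooting=True))
    rooted.rooted = True
    return rooted


@dataclass
class CladeAssignment:
    query_id: str
    clade: str  # reference label or "unclassified"
    support: float | None = None


def assign_clades(tree: Tree, reference_labels: dict[str, str],
                  support_min: float = 50.0) -> list[CladeAssignment]:
    """Assign each query leaf the label of the smallest containing clade
    whose reference leaves are label-uniform and whose support passes
    ``support_min``; otherwise "unclassified"."""
    queries = [name for name in tree.leaf_names() if name not in reference_labels]
    assignments = []
    for query in queries:
        clade = "unclassified"
        support = None
        # ancestors of the query, smallest first
        path: list[Node] = []

        def find(node: Node) -> bool:
            if node.is_leaf:
                return node.name == query
            for child in node.children:
                if find(child):
                    path.append(node)
                    return True
            return False

        find(tree.root)
        for node in path:
            labels = {reference_labels[l.name] for l in node.leaves()
                      if l.name in reference_labels}
            if not labels:
                continue
            if len(labels) > 1:
                break  # larger clades can only add more labels
            if node.support is not None and node.support >= support_min:
                clade = labels.pop()
                support = node.support
                break
        assignments.append(CladeAssignment(query, clade, support))
    return assignments


# ---------------------------------------------------------------------------
# Progressive multiple alignment
# ---------------------------------------------------------------------------

@njit(cache=True)
def _nw_profile(S, gap):
    """Global DP over a precomputed column-pair score matrix.

    Returns the traceback as an array of moves (0 diag, 1 up/gap-in-B,
    2 left/gap-in-A), reversed.
    """
    n, m = S.shape
    H = np.empty((n + 1, m + 1))
    P = np.zeros((n + 1, m + 1), dtype=np.int8)
    H[0, 0] = 0.0
    for i in range(1, n + 1):
        H[i, 0] = -gap * i
        P[i, 0] = 1
    for j in range(1, m + 1):
        H[0, j] = -gap * j
        P[0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = H[i - 1, j - 1] + S[i - 1, j - 1]
            ptr = 0
            up = H[i - 1, j] - gap
            if up > best:
                best = up
                ptr = 1
            left = H[i, j - 1] - gap
            if left > best:
                best = left
                ptr = 2
            H[i, j] = best
            P[i, j] = ptr
    moves = np.empty(n + m, dtype=np.int8)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        ptr = P[i, j]
        moves[k] = ptr
        k += 1
        if ptr == 0:
            i -= 1
            j -= 1
        elif ptr == 1:
            i -= 1
        else:
            j -= 1
    return moves[:k]


_GAP_IDX = 20  # nucleotide profiles use index 4


def _profile_counts(rows: list[str], alphabet_index: dict[str, int],
                    nsym: int) -> np.ndarray:
    L = len(rows[0])
    counts = np.zeros((L, nsym + 1))
    for row in rows:
        for c, ch in enumerate(row):
            counts[c, alphabet_index.get(ch, nsym)] += 1
    return counts


def _submatrix(alphabet: str) -> tuple[np.ndarray, dict[str, int], int, float]:
    if alphabet == AMINO_ACID:
        blosum = substitution_matrices.load("BLOSUM62")
        letters = "ACDEFGHIKLMNPQRSTVWY"
        nsym = 20
        S = np.zeros((nsym + 1, nsym + 1))
        for i, a in enumerate(letters):
            for j, b in enumerate(letters):
                S[i, j] = blosum[a][b]
        gap_vs_res = -4.0
        gap = 8.0
    else:
        letters = "ACGT"
        nsym = 4
        S = np.full((nsym + 1, nsym + 1), -4.0)
        np.fill_diagonal(S, 5.0)
        gap_vs_res = -4.0
        gap = 10.0
    S[nsym, :] = gap_vs_res
    S[:, nsym] = gap_vs_res
    S[nsym, nsym] = 0.0
    index = {ch: i for i, ch in enumerate(letters)}
    return S, index, nsym, gap


def _merge_profiles(rows_a: list[str], rows_b: list[str], alphabet: str,
                    ) -> tuple[list[str], list[str]]:
    S, index, nsym, gap = _submatrix(alphabet)
    ca = _profile_counts(rows_a, index, nsym)
    cb = _profile_counts(rows_b, index, nsym)
    pair_scores = (ca @ S @ cb.T) / (len(rows_a) * len(rows_b))
    moves = _nw_profile(pair_scores, gap)
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    i = j = 0
    for mv in moves:
        if mv == 0:
            for r, row in enumerate(rows_a):
                out_a[r].append(row[i])
            for r, row in enumerate(rows_b):
                out_b[r].append(row[j])
            i += 1
            j += 1
        elif mv == 1:
            for r, row in enumerate(rows_a):
                out_a[r].append(row[i])
            for r in range(len(rows_b)):
                out_b[r].append("-")
            i += 1
        else:
            for r in range(len(rows_a)):
                out_a[r].append("-")
            for r, row in enumerate(rows_b):
                out_b[r].append(row[j])
            j += 1
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def _pairwise_pdist(a: str, b: str, alphabet: str) -> float:
    aligned_a, aligned_b = _merge_profiles([a], [b], alphabet)
    pa, pb = aligned_a[0], aligned_b[0]
    shared = [(x, y) for x, y in zip(pa, pb) if x != "-" and y != "-"]
    if not shared:
        return 1.0
    return sum(1 for x, y in shared if x != y) / len(shared)


def progressive_msa(sequences: list[SequenceRecord]) -> list[SequenceRecord]:
    """Progressive multiple alignment along an NJ guide tree.

    Pairwise p-distances from global alignments feed a neighbor-joining
    guide tree; profiles are merged at each internal node (sum-of-pairs
    column scores, linear gap penalty).  Deterministic and input-order
    invariant (all tie-breaking is on sequence ids).
    """
    if len(sequences) < 2:
        raise ValueError("need >= 2 sequences")
    alphabets = {r.alphabet for r in sequences}
    if len(alphabets) != 1:
        raise ValueError("mixed alphabets")
    alphabet = alphabets.pop()
    ids = [r.id for r in sequences]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    by_id = {r.id: r for r in sequences}
    order = sorted(ids)

    if len(sequences) == 2:
        rows_a, rows_b = _merge_profiles([by_id[order[0]].residues],
                                         [by_id[order[1]].residues], alphabet)
        aligned = {order[0]: rows_a[0], order[1]: rows_b[0]}
        return [SequenceRecord(r.id, aligned[r.id], alphabet) for r in sequences]

    n = len(order)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = _pairwise_pdist(
                by_id[order[i]].residues, by_id[order[j]].residues, alphabet)
    guide = nj_tree(DistanceMatrix(ids=order, matrix=m))

    def align_node(node: Node) -> tuple[list[str], list[str]]:
        if node.is_leaf:
            return [node.name], [by_id[node.name].residues]
        parts = [align_node(c) for c in node.children]
        names, rows = parts[0]
        for more_names, more_rows in parts[1:]:
            rows, more_rows = _merge_profiles(rows, more_rows, alphabet)
            names = names + more_names
            rows = rows + more_rows
        return names, rows

    names, rows = align_node(guide.root)
    aligned = dict(zip(names, rows))
    return [SequenceRecord(r.id, aligned[r.id], alphabet) for r in sequences]
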