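"""Independent quadratic-time alignment oracles used only by the tests."""

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM = substitution_matrices.load("BLOSUM62")


def nw_affine_score(a: str, b: str, gap_open: float = 11.0,
                    gap_extend: float = 1.0) -> float:
    """Optimal global alignment score, affine gaps (open includes first)."""
    NEG = -1e18
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _BLOSUM[a[i - 1]][b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1],
                          Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend)
    return float(max(M[n, m], X[n, m], Y[n, m]))


def sw_affine_best(a: str, b: str, gap_open: float = 11.0,
                   gap_extend: float = 1.0) -> float:
    """Optimal local alignment score, affine gaps."""
    n, m = len(a), len(b)
    NEG = -1e18
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _BLOSUM[a[i - 1]][b[j - 1]]
            M[i, j] = max(0.0, M[i - 1, j - 1] + s, X[i - 1, j - 1] + s,
                          Y[i - 1, j - 1] + s)
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend)
            best = max(best, M[i, j])
    return float(best)


def fitch_loss_count(tree, presence: dict) -> int:
    """Minimum state changes on the tree with the root forced present.

    Small-parsimony oracle for the loss-counting routine: with a presence
    root state and irreversible presence->absence interpretation, the
    change count equals the number of maximal absent subtrees.
    """
    def walk(node):
        # returns (cost_if_present, cost_if_absent)
        if node.is_leaf:
            state = presence[node.name]
            return (0 if state else 10**6, 10**6 if state else 0)
        cp = ca = 0
        for child in node.children:
            p, a = walk(child)
            cp += min(p, a + 1)   # losing on the child edge costs 1
            ca += min(a, p + 10**6)  # no regain allowed
        return cp, ca

    return walk(tree.root)[0]
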