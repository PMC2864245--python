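"""Poisson-corrected evolutionary rates and horizontal-transfer criteria.

For a pair of homologous proteins with proportion p of differing residues,
the Poisson-corrected distance is d = -ln(1 - p) and the substitution rate
r = d / 2T, with T the divergence time of the hosts' last common ancestor.
Rates are reported in units of 1e-9 substitutions/site/year.

Horizontal transfer (HT) between host lineages is assessed by three
classical criteria: phylogenetic incongruence between element and host
trees, a rate slowdown of the element relative to host genes over the same
taxon pairs, and a patchy presence/absence distribution across the host
phylogeny.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .families import pairwise_identity
from .phylo import Node, Tree

RATE_SCALE = 1e9  # report rates as r * 1e9


# ---------------------------------------------------------------------------
# Divergence times
# ---------------------------------------------------------------------------

#: Host-group divergence times (Myr) used for rate calibration.
DEFAULT_DIVERGENCE_TIMES = {
    ("Plants", "Fungi"): 1500.0,
    ("Basidiomycetes", "Ascomycetes"): 1200.0,
    ("Homobasidiomycetes", "Chytridiomycetes"): 900.0,
    ("Sordariomycetes", "Eurotiomycetes"): 540.0,
    ("Sordariomycetes", "Dothideomycetes"): 490.0,
    ("Tremellomycetes", "Agaricomycetes"): 700.0,
}


class DivergenceTimeTable:
    """Symmetric lookup of divergence times (Myr) for taxon-group pairs."""

    def __init__(self, times: dict[tuple[str, str], float] | None = None):
        self._times: dict[frozenset, float] = {}
        for (a, b), t in (times or DEFAULT_DIVERGENCE_TIMES).items():
            if t <= 0:
                raise ValueError(f"divergence time for {a}/{b} must be > 0")
            self._times[frozenset((a, b))] = float(t)

    def lookup(self, group_a: str, group_b: str) -> float:
        key = frozenset((group_a, group_b))
        if key not in self._times:
            raise KeyError(
                f"no divergence time for taxon pair {group_a}/{group_b}")
        return self._times[key]

    @classmethod
    def from_tsv(cls, path) -> "DivergenceTimeTable":
        df = pd.read_csv(path, sep="\t")
        times = {(row.group_a, row.group_b): float(row.time_myr)
                 for row in df.itertuples()}
        return cls(times)

    def to_tsv(self, path) -> None:
        rows = [{"group_a": sorted(k)[0], "group_b": sorted(k)[1],
                 "time_myr": v} for k, v in self._times.items()]
        pd.DataFrame(rows).sort_values(["group_a", "group_b"]).to_csv(
            path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Core rate arithmetic
# ---------------------------------------------------------------------------

def poisson_distance(p: float) -> float:
    """Poisson-corrected amino-acid distance d = -ln(1 - p)."""
    if p < 0:
        raise ValueError("p must be >= 0")
    if p >= 1 - 1e-9:
        raise ValueError("p >= 1: Poisson correction undefined")
    return -math.log1p(-p)


def substitution_rate(d: float, T_myr: float) -> float:
    """Substitutions per site per year: r = d / (2 T), T in Myr."""
    if T_myr <= 0:
        raise ValueError("T must be > 0")
    if d < 0:
        raise ValueError("d must be >= 0")
    return d / (2.0 * T_myr * 1e6)


@dataclass
class RateEstimate:
    id_a: str
    id_b: str
    group_a: str
    group_b: str
    aligned_length: int
    identity: float
    p: float
    d: float
    T_myr: float
    rate: float            # substitutions/site/year

    @property
    def rate_scaled(self) -> float:
        """Rate in units of 1e-9 substitutions/site/year."""
        return self.rate * RATE_SCALE


def rate_from_identity(id_a: str, id_b: str, group_a: str, group_b: str,
                       identity: float, time_table: DivergenceTimeTable,
                       aligned_length: int = 0) -> RateEstimate:
    if not 0 < identity <= 1:
        raise ValueError("identity must be in (0, 1]")
    p = 1.0 - identity
    d = poisson_distance(p)
    T = time_table.lookup(group_a, group_b)
    return RateEstimate(id_a, id_b, group_a, group_b, aligned_length,
                        identity, p, d, T, substitution_rate(d, T))


def rate_table(pairs: list[tuple[str, str, str, str]],
               sequences: dict[str, str],
               time_table: DivergenceTimeTable,
               include_gaps: bool = False) -> pd.DataFrame:
    """Per-pair identities, Poisson distances and calibrated rates.

    ``pairs`` holds (id_a, id_b, taxon_group_a, taxon_group_b); sequences
    are aligned globally and identity computed per the gap convention.
    """
    rows = []
    for id_a, id_b, group_a, group_b in pairs:
        identity = pairwise_identity(sequences[id_a], sequences[id_b],
                                     include_gaps=include_gaps)
        est = rate_from_identity(id_a, id_b, group_a, group_b, identity,
                                 time_table)
        rows.append({
            "id_a": id_a, "id_b": id_b,
            "group_a": group_a, "group_b": group_b,
            "identity_pct": 100.0 * est.identity,
            "p": est.p, "d": est.d, "T_myr": est.T_myr,
            "rate_1e9": est.rate_scaled,
        })
    return pd.DataFrame(rows)


def estimate_rate_from_pair(seq_a: str, seq_b: str, T_myr: float,
                            ) -> tuple[float, float, float]:
    """(p, d, r) for an aligned equal-length pair (gap-free comparison)."""
    if len(seq_a) != len(seq_b) or not seq_a:
        raise ValueError("sequences must be equal-length and non-empty")
    p = sum(1 for a, b in zip(seq_a, seq_b) if a != b) / len(seq_a)
    d = poisson_distance(p)
    return p, d, substitution_rate(d, T_myr)


def load_divergence_table() -> pd.DataFrame:
    """Bundled divergence table: published pairwise amino-acid identities of
    host genes (Pho88, uapA) and RT-Int element fragments, with host-group
    assignments and the originally reported rates for cross-checking."""
    from importlib.resources import files

    path = files("chromomine.data").joinpath("divergence_table.tsv")
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t", keep_default_na=False)


def recompute_reference_rates(table: pd.DataFrame | None = None,
                              time_table: DivergenceTimeTable | None = None,
                              ) -> pd.DataFrame:
    """Recompute rates from the bundled identities via d = -ln(1-p), r = d/2T.

    Rows without a listed divergence time are skipped (rate left NaN).
    """
    table = load_divergence_table() if table is None else table.copy()
    time_table = time_table or DivergenceTimeTable()
    computed = []
    for row in table.itertuples():
        if not row.group_a or not row.group_b:
            computed.append(float("nan"))
            continue
        est = rate_from_identity(row.id_a, row.id_b, row.group_a, row.group_b,
                                 row.identity_pct / 100.0, time_table,
                                 aligned_length=row.length_aa)
        computed.append(est.rate_scaled)
    table["computed_rate_1e9"] = computed
    return table


# ---------------------------------------------------------------------------
# Horizontal-transfer criteria
# ---------------------------------------------------------------------------

def slowdown_test(te_rates: list[float], gene_rates: list[float],
                  ) -> tuple[bool, float]:
    """Rate-slowdown criterion over matched taxon pairs.

    True iff every element rate lies strictly below every host-gene rate;
    the margin is min(gene) - max(te) (negative when the test fails).
    """
    if not te_rates or not gene_rates:
        raise ValueError("need non-empty rate lists")
    margin = min(gene_rates) - max(te_rates)
    return margin > 0, margin


def count_losses(presence: dict[str, bool], host_tree: Tree) -> int:
    """Independent losses required under single-origin vertical descent.

    Assuming the element entered at the root of the host tree, the minimum
    number of losses equals the number of maximal all-absent subtrees.
    """
    missing = set(host_tree.leaf_names()) - set(presence)
    if missing:
        raise KeyError(f"presence missing for leaves {sorted(missing)}")

    losses = 0

    def walk(node: Node) -> bool:
        """Returns True iff any leaf below is present; counts maximal
        absent subtrees whose parent has presence."""
        nonlocal losses
        if node.is_leaf:
            return presence[node.name]
        child_states = [walk(c) for c in node.children]
        if any(child_states):
            losses += sum(1 for s in child_states if not s)
            return True
        return False

    any_present = walk(host_tree.root)
    if not any_present:
        return 0
    return losses


def patchy_distribution_test(presence: dict[str, bool], host_tree: Tree,
                             ) -> tuple[bool, int]:
    """Patchy-distribution criterion.

    True iff the element is present in some lineage whose sister lineage
    lacks it: at least one loss is required under vertical descent and
    presence is not universal.
    """
    losses = count_losses(presence, host_tree)
    present = [l for l in host_tree.leaf_names() if presence[l]]
    patchy = bool(present) and len(present) < len(host_tree.leaf_names()) \
        and losses >= 1
    return patchy, losses


def _restricted_splits(tree: Tree, keep: frozenset) -> set[frozenset]:
    """Non-trivial splits of the tree restricted to the ``keep`` leaf set."""
    splits = set()
    for side in tree.bipartitions():
        a = frozenset(side) & keep
        b = keep - a
        if len(a) > 1 and len(b) > 1:
            splits.add(frozenset((a, b)))
    return splits


def incongruence_test(element_tree: Tree, host_tree: Tree,
                      leaf_to_host: dict[str, str], support_min: float = 50.0,
                      ) -> tuple[bool, tuple[frozenset, frozenset] | None]:
    """Phylogenetic-incongruence criterion.

    A well-supported element bipartition, mapped to host taxa, conflicts
    with the host tree iff some host split has all four intersections with
    it non-empty (the classical split-compatibility test).  Hosts appearing
    on both sides of a mapped bipartition (paralogous copies) make that
    bipartition uninformative and it is skipped.
    """
    host_leaves = frozenset(host_tree.leaf_names())
    host_splits = _restricted_splits(host_tree, host_leaves)
    for side, support in element_tree.bipartitions(with_support=True).items():
        if support is None or support < support_min:
            continue
        mapped_a = frozenset(leaf_to_host[l] for l in side
                             if l in leaf_to_host)
        other = frozenset(element_tree.leaf_names()) - side
        mapped_b = frozenset(leaf_to_host[l] for l in other
                             if l in leaf_to_host)
        overlap = mapped_a & mapped_b
        mapped_a -= overlap
        mapped_b -= overlap
        if not mapped_a or not mapped_b:
            continue
        for split in host_splits:
            h1, h2 = tuple(split)
            if (mapped_a & h1 and mapped_a & h2
                    and mapped_b & h1 and mapped_b & h2):
                return True, (mapped_a, mapped_b)
    return False, None


@dataclass
class HTReport:
    """Combined verdict over the three HT criteria for one candidate."""

    candidate: str
    incongruence: bool
    incongruence_detail: tuple | None
    slowdown: bool
    slowdown_margin: float
    patchy: bool
    losses_required: int
    verdict: str = field(init=False)

    def __post_init__(self) -> None:
        supported = self.slowdown and (self.incongruence or self.patchy)
        self.verdict = "HT-supported" if supported else "vertical-plausible"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "candidate": self.candidate,
            "incongruence": self.incongruence,
            "slowdown": self.slowdown,
            "slowdown_margin_1e9": self.slowdown_margin * RATE_SCALE,
            "patchy": self.patchy,
            "losses_required": self.losses_required,
            "verdict": self.verdict,
        }])


def ht_report(candidate: str,
              element_tree: Tree, host_tree: Tree,
              leaf_to_host: dict[str, str],
              presence: dict[str, bool],
              te_rates: list[float], gene_rates: list[float],
              support_min: float = 50.0) -> HTReport:
    """Evaluate all three HT criteria and combine them.

    The verdict is "HT-supported" iff the rate slowdown holds together with
    at least one of incongruence or patchy distribution.
    """
    incong, detail = incongruence_test(element_tree, host_tree, leaf_to_host,
                                       support_min)
    slow, margin = slowdown_test(te_rates, gene_rates)
    patchy, losses = patchy_distribution_test(presence, host_tree)
    return HTReport(candidate=candidate, incongruence=incong,
                    incongruence_detail=detail, slowdown=slow,
                    slowdown_margin=margin, patchy=patchy,
                    losses_required=losses)
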