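"""Gene-tree heterogeneity statistics.

Given a set of rooted gene trees on a common taxon set, this module measures
how much, and where, the gene trees disagree: pairwise tree distances
(Robinson-Foulds on rooted clusters, and the matching cluster distance),
binning into exact topology classes, per-clade gene support frequency (GSF)
and internode certainty "all" (ICA), and rooted-triplet tallies for taxon or
lineage trios.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .treecore import GeneTreeSet, RootedTree, TreeError


def _check_same_leaves(t1: RootedTree, t2: RootedTree) -> None:
    if t1.leaf_labels != t2.leaf_labels:
        only1 = sorted(t1.leaf_labels - t2.leaf_labels)
        only2 = sorted(t2.leaf_labels - t1.leaf_labels)
        raise TreeError(
            f"leaf sets differ: only in first {only1}, only in second {only2}"
        )


def rf_cluster_distance(t1: RootedTree, t2: RootedTree) -> int:
    """Robinson-Foulds cluster distance on rooted trees: the size of the
    symmetric difference of the two nontrivial cluster sets.  0 iff the two
    rooted topologies are identical (including polytomy structure)."""
    _check_same_leaves(t1, t2)
    return len(t1.clusters() ^ t2.clusters())


def matching_cluster_distance(t1: RootedTree, t2: RootedTree) -> int:
    """Matching cluster distance: minimum total cost over perfect matchings of
    the two cluster lists (padded with empty clusters), where pairing clusters
    A and B costs ``|A ^ B|``.  Less sensitive than RF to the displacement of
    a single taxon."""
    _check_same_leaves(t1, t2)
    c1 = [set(c) for c in t1.clusters()]
    c2 = [set(c) for c in t2.clusters()]
    m = max(len(c1), len(c2))
    if m == 0:
        return 0
    c1 += [set()] * (m - len(c1))
    c2 += [set()] * (m - len(c2))
    cost = np.empty((m, m), dtype=np.int64)
    for i, a in enumerate(c1):
        for j, b in enumerate(c2):
            cost[i, j] = len(a ^ b)
    rows, cols = linear_sum_assignment(cost)
    return int(cost[rows, cols].sum())


# ---------------------------------------------------------------------------
# topology distributions
# ---------------------------------------------------------------------------


@dataclass
class TopologyBin:
    representative: RootedTree
    count: int
    is_species_tree: bool


@dataclass
class TopologyDistribution:
    """Gene trees partitioned into exact-topology bins (pairwise RF = 0),
    sorted by descending count."""

    bins: list[TopologyBin]
    total: int

    @property
    def species_tree_rank(self) -> Optional[int]:
        """1-based rank of the species-tree bin, or None if absent."""
        for i, b in enumerate(self.bins, start=1):
            if b.is_species_tree:
                return i
        return None

    def top(self, k: int) -> list[TopologyBin]:
        return self.bins[:k]


def bin_topologies(
    gene_trees: GeneTreeSet, species_tree: Optional[RootedTree] = None
) -> TopologyDistribution:
    """Partition trees into bins of identical rooted topology (RF = 0; a
    polytomy bins only with identical polytomies) and flag the species-tree
    bin.  Ties in count are broken by first appearance, so the order is
    deterministic for a given input order."""
    counts: dict = {}
    reps: dict = {}
    order: dict = {}
    for i, tree in enumerate(gene_trees):
        key = tree.topology_key()
        if key not in counts:
            counts[key] = 0
            reps[key] = tree
            order[key] = i
        counts[key] += 1
    sp_key = species_tree.topology_key() if species_tree is not None else None
    bins = [
        TopologyBin(reps[k], c, k == sp_key)
        for k, c in sorted(
            counts.items(), key=lambda kv: (-kv[1], order[kv[0]])
        )
    ]
    return TopologyDistribution(bins, total=len(gene_trees))


def plot_topology_distribution(
    dist: TopologyDistribution, top: int = 50, ax=None, path=None
):
    """Bar plot of the ``top`` most common gene-tree topologies; the
    species-tree bin (if present) is starred."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    bins = dist.top(top)
    xs = np.arange(len(bins))
    heights = [b.count / dist.total for b in bins]
    colors = ["tab:red" if b.is_species_tree else "tab:blue" for b in bins]
    ax.bar(xs, heights, color=colors)
    for x, b in zip(xs, bins):
        if b.is_species_tree:
            ax.text(x, b.count / dist.total, "*", ha="center")
    ax.set_xlabel("topology rank")
    ax.set_ylabel("frequency")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


# ---------------------------------------------------------------------------
# per-clade support
# ---------------------------------------------------------------------------


@dataclass
class CladeSupport:
    cluster: frozenset[str]
    gsf: float  # gene support frequency, percent in [0, 100]
    ica: float  # internode certainty "all", in [-1, 1]


def gene_support_frequency(gene_trees: GeneTreeSet, cluster: Iterable[str]) -> float:
    """Percent of gene trees containing the clade."""
    cl = frozenset(cluster)
    if not cl <= gene_trees.taxon_universe:
        raise TreeError("cluster is not a subset of the taxon universe")
    if len(gene_trees) == 0:
        raise TreeError("empty gene tree set")
    n = sum(1 for t in gene_trees if cl in t.clusters())
    return 100.0 * n / len(gene_trees)


def _incompatible(a: frozenset, b: frozenset) -> bool:
    return bool(a & b) and not (a <= b) and not (b <= a)


def internode_certainty_all(
    gene_trees: GeneTreeSet,
    species_tree: RootedTree,
    freq_threshold: float = 0.05,
) -> list[CladeSupport]:
    """GSF and ICA for every internal edge (nontrivial cluster) of the
    species tree.

    For a focal cluster, the conflict set contains every observed cluster
    incompatible with it whose relative frequency is at least
    ``freq_threshold``.  The focal and conflicting frequencies are normalized
    to sum to 1 and ICA = 1 + sum(p_i * log_n(p_i)) with n the number of
    clusters considered; the sign is negated when the focal cluster is not
    the most frequent of the set.  With no qualifying conflict, ICA = 1.
    """
    if len(gene_trees) == 0:
        raise TreeError("empty gene tree set")
    total = len(gene_trees)
    observed: Counter = Counter()
    for tree in gene_trees:
        observed.update(tree.clusters())
    supports: list[CladeSupport] = []
    for focal in sorted(species_tree.clusters(), key=lambda c: (len(c), sorted(c))):
        f_focal = observed.get(focal, 0) / total
        conflicts = [
            (cl, cnt / total)
            for cl, cnt in observed.items()
            if cnt / total >= freq_threshold and _incompatible(cl, focal)
        ]
        if not conflicts:
            ica = 1.0
        else:
            freqs = np.array([f_focal] + [f for _, f in conflicts])
            probs = freqs / freqs.sum()
            n = len(probs)
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = np.where(probs > 0, probs * np.log(probs) / np.log(n), 0.0)
            ica = 1.0 + float(terms.sum())
            if f_focal < max(f for _, f in conflicts):
                ica = -ica
        supports.append(CladeSupport(focal, gsf=100.0 * f_focal, ica=ica))
    return supports


# ---------------------------------------------------------------------------
# rooted triplets
# ---------------------------------------------------------------------------


def decompose_triplets(
    tree: RootedTree, trio: Sequence[str]
) -> Optional[frozenset[str]]:
    """Resolution of the rooted tree restricted to a trio of leaves.

    Returns the cherry pair as a frozenset (e.g. ``{A, B}`` for AB|C), or
    ``None`` when the restriction is unresolved (a polytomy spans the trio).
    """
    a, b, c = trio
    leaves = tree.leaf_labels
    missing = [x for x in (a, b, c) if x not in leaves]
    if missing:
        raise TreeError(f"trio taxa not in tree: {missing}")
    cls = tree.clusters()
    for pair, out in (((a, b), c), ((a, c), b), ((b, c), a)):
        x, y = pair
        for cl in cls:
            if x in cl and y in cl and out not in cl:
                return frozenset(pair)
    return None


@dataclass
class TripletCounts:
    """Cross-gene counts of the three resolutions of a trio of taxa or
    lineages.  ``counts`` maps the cherry pair (a frozenset of two of the
    trio's names) to its count; ``unresolved`` counts genes whose modal
    outcome was unresolved; ``omitted_ties`` counts genes omitted because two
    resolutions tied for the per-gene mode."""

    trio: tuple[str, str, str]
    counts: dict
    unresolved: int = 0
    omitted_ties: int = 0

    def as_tuple(self) -> tuple[int, int, int]:
        """(n1, n2, n3) in the fixed order: trio (A, B, C) yields counts for
        AB|C, AC|B, BC|A."""
        a, b, c = self.trio
        return (
            self.counts.get(frozenset((a, b)), 0),
            self.counts.get(frozenset((a, c)), 0),
            self.counts.get(frozenset((b, c)), 0),
        )

    @property
    def total_resolved(self) -> int:
        return sum(self.as_tuple())

    @property
    def major_pair(self) -> Optional[frozenset]:
        """Cherry pair of the most frequent resolution (None on a tie)."""
        n = sorted(self.counts.items(), key=lambda kv: -kv[1])
        if not n or (len(n) > 1 and n[0][1] == n[1][1]):
            return None
        return n[0][0]

    def proportions(self) -> tuple[float, float, float]:
        """Resolution proportions among resolved genes (unresolved genes are
        excluded from the denominator and reported separately)."""
        t = self.total_resolved
        if t == 0:
            raise TreeError("no resolved genes")
        n1, n2, n3 = self.as_tuple()
        return (n1 / t, n2 / t, n3 / t)


def lineage_triplet_tally(
    gene_trees: GeneTreeSet,
    lineage_map: Mapping[str, str],
    lineages: Sequence[str],
) -> TripletCounts:
    """Per-gene modal triplet resolution for a trio of lineages, tallied
    across genes; genes with a tie for the per-gene mode are omitted.

    For each gene, every cross-lineage taxon trio (one member per lineage)
    is decomposed; the modal resolution over those trios is the gene's vote.
    Sampled trios within a gene are not independent, which is why a single
    modal vote per gene is used.
    """
    lin = tuple(lineages)
    if len(lin) != 3:
        raise TreeError("need exactly three lineages")
    members: dict[str, list[str]] = {l: [] for l in lin}
    for taxon, lineage in lineage_map.items():
        if lineage in members:
            members[lineage].append(taxon)
    for l in lin:
        if not members[l]:
            raise TreeError(f"lineage {l!r} has no member taxa")
        members[l].sort()

    pair_of = {
        frozenset((a, b)): frozenset((la, lb))
        for (la, a_list), (lb, b_list) in itertools.combinations(
            ((l, members[l]) for l in lin), 2
        )
        for a in a_list
        for b in b_list
    }

    counts: Counter = Counter()
    unresolved_genes = 0
    omitted = 0
    for tree in gene_trees:
        votes: Counter = Counter()
        n_unres = 0
        for a, b, c in itertools.product(*(members[l] for l in lin)):
            res = decompose_triplets(tree, (a, b, c))
            if res is None:
                n_unres += 1
            else:
                votes[pair_of[res]] += 1
        if not votes:
            unresolved_genes += 1
            continue
        ranked = votes.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            omitted += 1
            continue
        counts[ranked[0][0]] += 1
    return TripletCounts(
        trio=lin, counts=dict(counts), unresolved=unresolved_genes, omitted_ties=omitted
    )
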