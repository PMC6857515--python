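"""Phylogenomic subsampling with a rooted-triplet species-tree estimator.

Loci are resampled with replacement into subsets of increasing size; each
replicate is then gene-wise bootstrapped, a species tree is estimated per
bootstrap with the R* triplet consensus (modal rooted triplets assembled by
greedy BUILD), and the estimate is scored against a configurable set of
mutually exclusive topological hypotheses on lineage-collapsed trees.  The
summaries are per-replicate bootstrap percentages, per-size means, and
threshold heatmap counts.

The R* consensus is statistically consistent under the multispecies
coalescent (no three-taxon anomaly exists), so it recovers the species tree
from enough gene trees even inside the anomaly zone.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .treecore import GeneTreeSet, Node, RootedTree, TreeError

#: subset-size grid of the standard design
DEFAULT_SIZES = (50, 100, 200, 300, 400, 500, 1000, 1500, 2000, 2500, 3000)

OTHER = "other"


@dataclass(frozen=True)
class SubsampleDesign:
    """Double-resampling design: ``sizes`` loci drawn with replacement,
    ``replicates`` independent draws per size, ``bootstraps`` gene-wise
    bootstrap redraws per replicate."""

    sizes: tuple[int, ...] = DEFAULT_SIZES
    replicates: int = 10
    bootstraps: int = 200

    def __post_init__(self):
        if not self.sizes or any(
            b <= a for a, b in zip(self.sizes, self.sizes[1:])
        ):
            raise ValueError("sizes must be strictly increasing")
        if min(self.sizes) < 1 or self.replicates < 1 or self.bootstraps < 1:
            raise ValueError("sizes, replicates and bootstraps must be >= 1")

    @property
    def total_datasets(self) -> int:
        return len(self.sizes) * self.replicates

    @property
    def work_units(self) -> int:
        return sum(self.sizes) * self.replicates * self.bootstraps


@dataclass
class HypothesisSet:
    """Named topological statements on the lineage alphabet.

    Each hypothesis is a tuple of lineage-level clusters that must all be
    present in the lineage-collapsed estimate; hypotheses are checked in
    order and must be mutually exclusive on binary lineage trees.  Estimates
    matching none (or with a non-monophyletic lineage) score as "other".
    """

    hypotheses: dict  # name -> tuple of frozensets of lineage names
    order: tuple = ()

    def __post_init__(self):
        if not self.order:
            self.order = tuple(self.hypotheses)

    @property
    def names(self) -> tuple:
        return self.order + (OTHER,)

    def evaluate(self, lineage_clusters: Optional[frozenset]) -> str:
        if lineage_clusters is None:
            return OTHER
        for name in self.order:
            if all(cl in lineage_clusters for cl in self.hypotheses[name]):
                return name
        return OTHER

    @classmethod
    def rhea_default(
        cls,
        rhea: str = "rhea",
        emu_cassowary: str = "emu_cassowary",
        kiwi: str = "kiwi",
        moa_tinamou: str = "moa_tinamou",
        ostrich: str = "ostrich",
    ) -> "HypothesisSet":
        """The five alternative placements of the rheas among the major
        palaeognath lineages (configurable lineage names):

        H1 rheas sister to (emu/cassowary + kiwi); H2 rheas sister to all
        other nonostrich lineages; H3 rheas sister to moa + tinamous; H4
        rheas sister to emu/cassowary; H5 rheas sister to kiwi.
        """
        eck = frozenset((emu_cassowary, kiwi))
        return cls(
            {
                "H1": (eck, frozenset((rhea, emu_cassowary, kiwi))),
                "H2": (
                    frozenset((emu_cassowary, kiwi, moa_tinamou)),
                    frozenset((rhea, emu_cassowary, kiwi, moa_tinamou)),
                ),
                "H3": (frozenset((rhea, moa_tinamou)),),
                "H4": (frozenset((rhea, emu_cassowary)),),
                "H5": (frozenset((rhea, kiwi)),),
            }
        )

    @classmethod
    def from_yaml(cls, path) -> "HypothesisSet":
        """YAML mapping: name -> list of clusters, each a list of lineages."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        hyps = {
            name: tuple(frozenset(cl) for cl in clusters)
            for name, clusters in raw.items()
        }
        return cls(hyps)


# ---------------------------------------------------------------------------
# R* triplet consensus
# ---------------------------------------------------------------------------


def _trio_resolution_codes(
    trees: Iterable[RootedTree], taxa: Sequence[str]
) -> tuple[list[tuple], np.ndarray]:
    """Per-tree resolution code for every taxon trio.

    Codes 0/1/2 index the cherry pair within the trio's pair list
    ``((a,b),(a,c),(b,c))``; 3 marks an unresolved trio.  Uses cluster
    bitmasks, so polytomies are handled.
    """
    taxa = list(taxa)
    bit = {t: 1 << i for i, t in enumerate(taxa)}
    trios = list(itertools.combinations(taxa, 3))
    pair_masks = np.array(
        [
            (
                (bit[a] | bit[b], bit[c]),
                (bit[a] | bit[c], bit[b]),
                (bit[b] | bit[c], bit[a]),
            )
            for a, b, c in trios
        ],
        dtype=np.uint64,
    )
    trees = list(trees)
    pm = pair_masks[:, :, 0]  # (T, 3)
    om = pair_masks[:, :, 1]
    codes = np.full((len(trees), len(trios)), 3, dtype=np.int8)
    for gi, tree in enumerate(trees):
        masks = np.array(
            [sum(bit[t] for t in cl if t in bit) for cl in tree.clusters()],
            dtype=np.uint64,
        )
        if masks.size == 0:
            continue
        m = masks[:, None, None]
        hit = ((m & pm) == pm) & ((m & om) == 0)  # (M, T, 3)
        resolved = hit.any(axis=0)  # (T, 3); at most one pair per trio
        ti, pi = np.nonzero(resolved)
        codes[gi, ti] = pi
    return trios, codes


def _build(taxa: frozenset, triplets: Sequence[tuple]) -> Optional[Node]:
    """Aho BUILD construction from rooted triples (pair, out); returns None
    on incompatibility.  Underdetermined regions come out as polytomies."""
    if len(taxa) == 1:
        return Node(next(iter(taxa)))
    graph = nx.Graph()
    graph.add_nodes_from(taxa)
    for pair, out in triplets:
        if out in taxa and pair <= taxa:
            a, b = pair
            graph.add_edge(a, b)
    components = list(nx.connected_components(graph))
    if len(components) == 1:
        return None
    node = Node()
    for comp in sorted(components, key=lambda c: sorted(c)):
        child = _build(frozenset(comp), triplets)
        if child is None:
            return None
        node.add(child)
    return node


def _greedy_rstar(
    taxa: Sequence[str],
    trios: Sequence[tuple],
    counts: np.ndarray,
) -> RootedTree:
    """Assemble modal triplets (ties leave the trio unconstrained) into a
    rooted tree: sort by support margin, insert via BUILD, skip triplets
    incompatible with those already accepted."""
    candidates = []
    for ti, trio in enumerate(trios):
        c = counts[ti, :3]
        order = np.argsort(-c, kind="stable")
        if c[order[0]] == 0 or c[order[0]] == c[order[1]]:
            continue  # tie or no signal: unconstrained
        a, b, cc = trio
        pairs = ((a, b, cc), (a, cc, b), (b, cc, a))
        x, y, out = pairs[order[0]]
        margin = int(c[order[0]] - c[order[1]])
        candidates.append((margin, trio, (frozenset((x, y)), out)))
    candidates.sort(key=lambda item: (-item[0], item[1]))

    taxa_set = frozenset(taxa)
    accepted: list[tuple] = []
    for _, _, trip in candidates:
        if _build(taxa_set, accepted + [trip]) is not None:
            accepted.append(trip)
    root = _build(taxa_set, accepted)
    assert root is not None  # a compatible set always builds
    return RootedTree(root, validate=False)


def rstar_species_tree(
    gene_trees: GeneTreeSet, outgroup: Optional[str] = None
) -> RootedTree:
    """R* consensus species tree from rooted gene trees.

    The modal resolution of every taxon trio across gene trees is assembled
    by greedy BUILD; contested or underdetermined regions yield polytomies.
    If ``outgroup`` is given it is excluded from the triplet analysis and
    re-attached at the root of the estimate.
    """
    if len(gene_trees) == 0:
        raise TreeError("empty gene tree set")
    taxa = sorted(gene_trees.taxon_universe)
    if outgroup is not None:
        if outgroup not in taxa:
            raise TreeError(f"outgroup {outgroup!r} not in taxon universe")
        taxa = [t for t in taxa if t != outgroup]
    if len(taxa) < 3:
        raise TreeError("need at least three ingroup taxa")
    trios, codes = _trio_resolution_codes(gene_trees, taxa)
    counts = np.zeros((len(trios), 4), dtype=np.int64)
    for ti in range(len(trios)):
        counts[ti] = np.bincount(codes[:, ti], minlength=4)
    tree = _greedy_rstar(taxa, trios, counts)
    if outgroup is not None:
        new_root = Node()
        new_root.add(Node(outgroup))
        ingroup = tree.root
        new_root.add(ingroup)
        tree = RootedTree(new_root, validate=False)
    return tree


# ---------------------------------------------------------------------------
# lineage collapsing and hypothesis scoring
# ---------------------------------------------------------------------------


def collapse_to_lineages(
    tree: RootedTree, lineage_map: Mapping[str, str]
) -> Optional[frozenset]:
    """Lineage-level cluster set of a taxon tree, or None when any
    multi-member lineage is not monophyletic.

    Taxa absent from the lineage map (e.g. the outgroup) are pruned first.
    Only clusters that are exact unions of complete lineages survive the
    collapse.
    """
    mapped = tree.leaf_labels & set(lineage_map)
    t = tree.restrict_to(mapped)
    members: dict[str, set[str]] = {}
    for taxon in mapped:
        members.setdefault(lineage_map[taxon], set()).add(taxon)
    clusters = t.clusters()
    all_taxa = t.leaf_labels
    for lineage, mem in members.items():
        if len(mem) > 1 and mem != all_taxa and frozenset(mem) not in clusters:
            return None
    lineage_clusters = set()
    n_lineages = len(members)
    for cl in clusters:
        lins = set(lineage_map[t_] for t_ in cl)
        if all(frozenset(members[l]) <= cl for l in lins):
            if 2 <= len(lins) < n_lineages:
                lineage_clusters.add(frozenset(lins))
    return frozenset(lineage_clusters)


# ---------------------------------------------------------------------------
# the subsampling engine
# ---------------------------------------------------------------------------


@dataclass
class SubsampleResult:
    per_replicate: pd.DataFrame  # size, replicate, hypothesis, bootstrap_pct
    summary: pd.DataFrame  # size, hypothesis, mean_pct
    design: SubsampleDesign
    seed: int
    work_units: int


def run_subsample(
    gene_trees: GeneTreeSet,
    design: SubsampleDesign,
    hypotheses: HypothesisSet,
    lineage_map: Mapping[str, str],
    seed: int,
    outgroup: Optional[str] = None,
) -> SubsampleResult:
    """Double gene-level resampling with R* estimation.

    For each size x replicate, loci are drawn with replacement; each of the
    design's bootstraps redraws loci with replacement from the replicate,
    estimates a species tree with R*, collapses it to lineages and scores
    which hypothesis holds.  Reported are per-replicate bootstrap percentages
    and per-size means; the run is deterministic given the seed.
    """
    if len(gene_trees) == 0:
        raise TreeError("empty gene tree set")
    rng = np.random.default_rng(seed)
    taxa = sorted(gene_trees.taxon_universe)
    if outgroup is not None:
        taxa = [t for t in taxa if t != outgroup]
    trios, codes = _trio_resolution_codes(gene_trees, taxa)
    one_hot = np.zeros((len(gene_trees), len(trios), 4), dtype=np.int32)
    g_idx = np.arange(len(gene_trees))[:, None]
    t_idx = np.arange(len(trios))[None, :]
    one_hot[g_idx, t_idx, codes] = 1

    rows = []
    for size in design.sizes:
        for rep in range(design.replicates):
            replicate = rng.integers(len(gene_trees), size=size)
            tallies = {name: 0 for name in hypotheses.names}
            for _ in range(design.bootstraps):
                boot = replicate[rng.integers(size, size=size)]
                counts = one_hot[boot].sum(axis=0)
                est = _greedy_rstar(taxa, trios, counts)
                name = hypotheses.evaluate(
                    collapse_to_lineages(est, lineage_map)
                )
                tallies[name] += 1
            for name in hypotheses.names:
                rows.append(
                    {
                        "size": size,
                        "replicate": rep,
                        "hypothesis": name,
                        "bootstrap_pct": 100.0 * tallies[name] / design.bootstraps,
                    }
                )
    per_replicate = pd.DataFrame(rows)
    summary = (
        per_replicate.groupby(["size", "hypothesis"], sort=True)["bootstrap_pct"]
        .mean()
        .rename("mean_pct")
        .reset_index()
    )
    return SubsampleResult(
        per_replicate=per_replicate,
        summary=summary,
        design=design,
        seed=seed,
        work_units=design.work_units,
    )


def threshold_heatmap_counts(
    result: SubsampleResult, thresholds: Sequence[float] = (70.0, 90.0)
) -> pd.DataFrame:
    """Per (size, hypothesis, threshold): number of replicates whose
    bootstrap percentage meets the threshold."""
    rows = []
    grouped = result.per_replicate.groupby(["size", "hypothesis"], sort=True)
    for (size, hyp), grp in grouped:
        for thr in thresholds:
            rows.append(
                {
                    "size": size,
                    "hypothesis": hyp,
                    "threshold": thr,
                    "n_replicates": int((grp["bootstrap_pct"] >= thr).sum()),
                }
            )
    return pd.DataFrame(rows)
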