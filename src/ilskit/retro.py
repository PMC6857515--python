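"""Retroelement presence/absence analytics.

Retroelement (e.g. CR1) insertions are near-homoplasy-free characters: a
shared insertion marks a clade, and conflicting insertion patterns across a
trio of lineages measure incomplete lineage sorting (hemiplasy).  This module
classifies insertion loci against a species tree, tallies trio support,
computes the insertion significance test for the three resolutions of a trio
against a polytomy null, tests the symmetry of the two minor patterns, and
simulates hemiplasy by dropping insertions on MSC gene trees.

Matrix convention: loci x taxa with states present / absent / omitted
("omitted" marks alignment gaps spanning the insertion site); TSV symbols
are 1 / 0 / ?.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .treecore import GeneTreeSet, RootedTree, TreeError
from .coalescent import SpeciesTreeModel, simulate_gene_trees

PRESENT, ABSENT, OMITTED = 1, 0, -1
_SYMBOL_TO_CODE = {"1": PRESENT, "0": ABSENT, "?": OMITTED}
_CODE_TO_SYMBOL = {PRESENT: "1", ABSENT: "0", OMITTED: "?"}


class InsertionMatrix:
    """Loci x taxa presence/absence/omitted matrix with optional per-locus
    metadata (element subtype, orientation, ... carried for provenance)."""

    def __init__(self, data: pd.DataFrame, metadata: Optional[pd.DataFrame] = None):
        values = data.to_numpy()
        bad = ~np.isin(values, (PRESENT, ABSENT, OMITTED))
        if bad.any():
            raise ValueError("states limited to {present, absent, omitted}")
        if (values == OMITTED).all(axis=1).any():
            raise ValueError("every locus needs >= 1 non-omitted state")
        self.data = data.astype(np.int8)
        self.metadata = metadata

    @property
    def loci(self) -> list:
        return list(self.data.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)

    def state(self, locus, taxon) -> int:
        return int(self.data.at[locus, taxon])

    @classmethod
    def from_tsv(cls, path) -> "InsertionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        coded = df.map(lambda s: _SYMBOL_TO_CODE[s.strip()])
        return cls(coded)

    def to_tsv(self, path) -> None:
        out = self.data.map(lambda v: _CODE_TO_SYMBOL[int(v)])
        out.to_csv(path, sep="\t", index_label="locus")


# ---------------------------------------------------------------------------
# pattern classification
# ---------------------------------------------------------------------------

INFORMATIVE = "informative"
SYMPLESIOMORPHY = "symplesiomorphy"
AUTAPOMORPHY = "autapomorphy"
MISSING_LINEAGE = "missing-lineage-omitted"
UNINFORMATIVE = "uninformative"  # no presence among scored taxa

PATTERN_LABELS = (
    INFORMATIVE,
    SYMPLESIOMORPHY,
    AUTAPOMORPHY,
    MISSING_LINEAGE,
    UNINFORMATIVE,
)


@dataclass(frozen=True)
class PatternClass:
    locus: object
    label: str
    presence: Optional[frozenset]  # set for informative loci, else None
    scored: frozenset  # non-omitted taxa at this locus


def classify_patterns(
    matrix: InsertionMatrix, lineage_map: Mapping[str, str]
) -> list[PatternClass]:
    """Per-locus classification against the lineage map.

    A locus lacking a scored (non-omitted) taxon in any lineage is
    "missing-lineage-omitted"; presence in all scored taxa is a
    symplesiomorphy; presence in exactly one taxon is an autapomorphy;
    presence in no scored taxon is "uninformative"; anything else is
    informative, carrying its presence cluster.
    """
    unmapped = [t for t in matrix.taxa if t not in lineage_map]
    if unmapped:
        raise ValueError(f"taxa missing from lineage map: {unmapped}")
    lineages = sorted(set(lineage_map[t] for t in matrix.taxa))
    taxa = np.array(matrix.taxa)
    lineage_of = np.array([lineage_map[t] for t in matrix.taxa])
    values = matrix.data.to_numpy()

    out: list[PatternClass] = []
    for i, locus in enumerate(matrix.loci):
        row = values[i]
        scored_mask = row != OMITTED
        scored = frozenset(taxa[scored_mask])
        scored_lineages = set(lineage_of[scored_mask])
        if any(l not in scored_lineages for l in lineages):
            out.append(PatternClass(locus, MISSING_LINEAGE, None, scored))
            continue
        presence = frozenset(taxa[row == PRESENT])
        if not presence:
            out.append(PatternClass(locus, UNINFORMATIVE, None, scored))
        elif presence == scored:
            out.append(PatternClass(locus, SYMPLESIOMORPHY, None, scored))
        elif len(presence) == 1:
            out.append(PatternClass(locus, AUTAPOMORPHY, presence, scored))
        else:
            out.append(PatternClass(locus, INFORMATIVE, presence, scored))
    return out


# ---------------------------------------------------------------------------
# trio tallies and significance tests
# ---------------------------------------------------------------------------


@dataclass
class PatternTally:
    """Counts of informative insertions supporting each of the three
    resolutions of a lineage trio (A, B, C): pairs AB, AC, BC."""

    trio: tuple[str, str, str]
    counts: dict

    def as_counts(self) -> tuple[int, int, int]:
        a, b, c = self.trio
        return (
            self.counts.get(frozenset((a, b)), 0),
            self.counts.get(frozenset((a, c)), 0),
            self.counts.get(frozenset((b, c)), 0),
        )


def tally_trio_support(
    classes: Sequence[PatternClass],
    lineage_map: Mapping[str, str],
    trio: Sequence[str],
) -> PatternTally:
    """Count informative loci uniting exactly two of the three lineages.

    A locus contributes only when every trio lineage has at least one scored
    member; a lineage counts as "present" when any scored member carries the
    insertion.  Loci with zero or one present lineage, or all three present,
    are not trio-informative.
    """
    trio = tuple(trio)
    if len(trio) != 3:
        raise ValueError("need exactly three lineages")
    members: dict[str, set[str]] = {l: set() for l in trio}
    for taxon, lineage in lineage_map.items():
        if lineage in members:
            members[lineage].add(taxon)
    for l in trio:
        if not members[l]:
            raise ValueError(f"lineage {l!r} has no member taxa")

    counts: Counter = Counter()
    for pc in classes:
        if pc.label != INFORMATIVE:
            continue
        if any(not (members[l] & pc.scored) for l in trio):
            continue
        present = frozenset(l for l in trio if members[l] & pc.presence)
        if len(present) == 2:
            counts[present] += 1
    return PatternTally(trio=trio, counts=dict(counts))


@dataclass(frozen=True)
class KKSCResult:
    """Insertion significance test for one resolution of a lineage trio.

    n1 supports the tested resolution; the p-value is the exact upper tail
    P(X >= n1) with X ~ Binomial(n1+n2+n3, 1/3), i.e. the chance of at least
    n1 markers falling on one resolution under the polytomy null in which
    each insertion supports any of the three resolutions equally.
    """

    n1: int
    n2: int
    n3: int
    p: float

    @property
    def total(self) -> int:
        return self.n1 + self.n2 + self.n3


def kksc_tree_test(n1: int, n2: int, n3: int) -> KKSCResult:
    """Exact binomial-tail insertion significance test (computed in log
    space); p = 1 for an empty trio."""
    if min(n1, n2, n3) < 0:
        raise ValueError("counts must be >= 0")
    total = n1 + n2 + n3
    if total == 0:
        return KKSCResult(n1, n2, n3, 1.0)
    p = float(stats.binom.sf(n1 - 1, total, 1.0 / 3.0))
    return KKSCResult(n1, n2, n3, min(p, 1.0))


def minor_symmetry_test(n2: int, n3: int) -> float:
    """Exact two-sided binomial test of the two minor-pattern counts against
    the symmetric null p = 1/2 (symmetry is the ILS signature; asymmetry
    suggests e.g. ancestral hybridization)."""
    if n2 < 0 or n3 < 0:
        raise ValueError("counts must be >= 0")
    if n2 + n3 == 0:
        raise ValueError("no minor patterns to compare")
    return float(stats.binomtest(n2, n2 + n3, 0.5, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# species-tree consistency
# ---------------------------------------------------------------------------


@dataclass
class ConsistencyReport:
    n_informative: int
    n_consistent: int
    per_edge: dict  # full-tree cluster -> supporting insertion count
    conflicting_loci: list

    @property
    def fraction_consistent(self) -> float:
        if self.n_informative == 0:
            raise ValueError("no informative loci")
        return self.n_consistent / self.n_informative


def species_tree_consistency_report(
    classes: Sequence[PatternClass],
    species_tree: RootedTree,
    lineage_map: Optional[Mapping[str, str]] = None,
) -> ConsistencyReport:
    """Flag each informative locus consistent/conflicting with the species
    tree: consistent iff its presence set is a cluster of the species tree
    restricted to the locus's scored taxa.  Consistent loci are credited to
    the smallest full-tree cluster whose restriction matches (per-edge
    supporting counts).

    If the species tree's leaves are lineage names (requires
    ``lineage_map``), presence and scoring are first collapsed to lineages
    (a lineage is present/scored when any member is).
    """
    sp_leaves = species_tree.leaf_labels
    lineage_level = lineage_map is not None and sp_leaves <= set(
        lineage_map.values()
    )
    full_clusters = sorted(species_tree.clusters(), key=len)

    n_inf = 0
    n_cons = 0
    per_edge: Counter = Counter()
    conflicting: list = []
    for pc in classes:
        if pc.label != INFORMATIVE:
            continue
        n_inf += 1
        if lineage_level:
            presence = frozenset(lineage_map[t] for t in pc.presence)
            scored = frozenset(lineage_map[t] for t in pc.scored)
        else:
            presence = pc.presence
            scored = pc.scored
        scored = scored & sp_leaves
        presence = presence & sp_leaves
        if len(presence) < 2 or presence == scored:
            # insertion is uninformative on the species tree's taxon set
            n_cons += 1
            continue
        credited = None
        for cl in full_clusters:
            if cl & scored == presence:
                credited = cl
                break
        if credited is not None:
            n_cons += 1
            per_edge[credited] += 1
        else:
            conflicting.append(pc.locus)
    return ConsistencyReport(
        n_informative=n_inf,
        n_consistent=n_cons,
        per_edge=dict(per_edge),
        conflicting_loci=conflicting,
    )


# ---------------------------------------------------------------------------
# hemiplasy simulator
# ---------------------------------------------------------------------------


def generate_insertion_dataset(
    model: SpeciesTreeModel,
    n_loci: int,
    seed: Union[int, Sequence[int]],
    omission_rate: float = 0.0,
    stem_length: float = 1.0,
) -> tuple[InsertionMatrix, pd.DataFrame]:
    """Simulate an insertion matrix by dropping one insertion per locus on an
    MSC gene tree.

    Per locus: simulate one gene tree from the model, pick an edge with
    probability proportional to its mutational length (a stem edge of length
    ``stem_length`` above the gene root is included so symplesiomorphies can
    arise), and mark presence for all leaves descending from the insertion
    point.  ``omission_rate`` then independently rescored states as omitted
    (redrawn in the rare case a locus would lose all scored taxa).
    Deterministic given the seed.

    Returns the matrix and a truth table (locus, edge type, clade, class
    before omission noise) for generator bookkeeping.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = np.random.default_rng(seed)
    gts = simulate_gene_trees(model, n_loci, rng)
    taxa = sorted(model.taxa)
    n_taxa = len(taxa)
    tx_index = {t: i for i, t in enumerate(taxa)}

    rows = np.empty((n_loci, n_taxa), dtype=np.int8)
    truth_rows = []
    for i, tree in enumerate(gts):
        edges = []  # (node-or-None, length); None encodes the stem
        below: dict[int, frozenset] = {}
        for node in tree.root.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset((node.label,))
            else:
                below[id(node)] = frozenset().union(
                    *(below[id(c)] for c in node.children)
                )
            if node is not tree.root:
                edges.append((below[id(node)], node.length or 0.0))
        edges.append((tree.leaf_labels, float(stem_length)))  # stem -> all taxa
        weights = np.array([w for _, w in edges], dtype=float)
        if weights.sum() <= 0:
            raise ValueError("gene tree has no positive edge length")
        choice = int(rng.choice(len(edges), p=weights / weights.sum()))
        clade, _ = edges[choice]
        is_stem = choice == len(edges) - 1
        row = np.full(n_taxa, ABSENT, dtype=np.int8)
        for t in clade:
            row[tx_index[t]] = PRESENT
        if omission_rate > 0:
            while True:
                mask = rng.random(n_taxa) < omission_rate
                if not mask.all():
                    break
            row = row.copy()
            row[mask] = OMITTED
        rows[i] = row
        if is_stem or len(clade) == n_taxa:
            true_class = SYMPLESIOMORPHY
        elif len(clade) == 1:
            true_class = AUTAPOMORPHY
        else:
            true_class = INFORMATIVE
        truth_rows.append(
            {
                "locus": f"L{i:06d}",
                "edge_type": "stem" if is_stem else (
                    "terminal" if len(clade) == 1 else "internal"
                ),
                "clade": ",".join(sorted(clade)),
                "true_class": true_class,
            }
        )
    loci = [r["locus"] for r in truth_rows]
    data = pd.DataFrame(rows, index=loci, columns=taxa)
    truth = pd.DataFrame(truth_rows).set_index("locus")
    return InsertionMatrix(data, metadata=truth), truth
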