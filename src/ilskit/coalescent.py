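"""Multispecies-coalescent analytics and simulation.

A :class:`SpeciesTreeModel` is a rooted species-tree topology with, per
branch, a length tau in coalescent units (the convention used throughout is
tau = T/4Ne), a mutational length muT (expected substitutions), and the
population parameter Theta tied to the other two by Theta = muT / tau.
Terminal-branch Theta is fixed at 1 by convention; with one sampled allele
per species it has no effect on simulated topologies.

On top of the model the module provides the classic rooted-triplet
expectations (major frequency 1 - (2/3) e^{-t}), the anomaly-zone boundary
a(x) for successive internal branches and its scan over a species tree,
topology-only MSC gene-tree simulation, gene-tree/species-tree heterogeneity
ratios, and an exact goodness-of-fit test of observed triplet counts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .treecore import GeneTreeSet, Node, RootedTree, TreeError
from .heterogeneity import (
    TripletCounts,
    matching_cluster_distance,
    rf_cluster_distance,
)


# ---------------------------------------------------------------------------
# closed-form MSC quantities
# ---------------------------------------------------------------------------


def theta_from_lengths(muT: float, tau: float) -> float:
    """Theta = muT / tau (internal-branch identity tying mutational and
    coalescent lengths)."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if muT < 0:
        raise ValueError("muT must be >= 0")
    return muT / tau


@dataclass(frozen=True)
class TripletExpectation:
    """Expected rooted-triplet frequencies for internal branch length t
    (coalescent units): major = 1 - (2/3) e^{-t}, each minor = (1/3) e^{-t}."""

    t: float
    major: float
    minor: float

    def as_probs(self) -> tuple[float, float, float]:
        return (self.major, self.minor, self.minor)


def expected_triplet_probs(t: float) -> TripletExpectation:
    if t < 0:
        raise ValueError("t must be >= 0")
    e = math.exp(-t)
    return TripletExpectation(t=t, major=1.0 - (2.0 / 3.0) * e, minor=e / 3.0)


def branch_length_from_major_freq(p_major: float) -> float:
    """Invert the major-triplet formula: t = -ln(3 (1 - p) / 2)."""
    if not (1.0 / 3.0 < p_major < 1.0):
        raise ValueError("p_major must lie in (1/3, 1)")
    return -math.log(3.0 * (1.0 - p_major) / 2.0)


def a_of_x(x: float) -> float:
    """Anomaly-zone boundary for a parent internal branch of length x
    (coalescent units):

        a(x) = ln[ 2/3 + (3 e^{2x} - 2) / (18 (e^{3x} - e^{2x})) ]

    A descendant internal branch y with y < a(x) places the pair in the
    anomaly zone.  a(x) may be negative (no anomaly possible for that x); the
    formula is singular at x = 0.
    """
    if x <= 0:
        raise ValueError("x must be > 0 (formula singular at 0)")
    e2 = math.exp(2.0 * x)
    e3 = math.exp(3.0 * x)
    return math.log(2.0 / 3.0 + (3.0 * e2 - 2.0) / (18.0 * (e3 - e2)))


# ---------------------------------------------------------------------------
# species tree model
# ---------------------------------------------------------------------------


EdgeKey = Union[frozenset, str]  # internal edges keyed by cluster, terminals by taxon


class ModelError(TreeError):
    pass


class SpeciesTreeModel:
    """Rooted species tree with per-branch tau, muT and Theta.

    Parameters
    ----------
    tree:
        Rooted topology whose branch lengths are tau in coalescent units.
    mut_lengths:
        Optional mapping edge -> muT (internal edges keyed by the frozenset
        of descendant taxa, terminal edges by taxon name).  Where both tau
        and muT are available, Theta = muT / tau; otherwise Theta defaults to
        ``default_theta``.
    thetas:
        Optional explicit Theta per edge; inconsistency with muT/tau raises.
    terminal_theta:
        Theta convention for terminal branches (inert with one allele per
        species); default 1.
    root_theta:
        Theta used above the root for final coalescence; default 1.
    """

    def __init__(
        self,
        tree: RootedTree,
        mut_lengths: Optional[Mapping[EdgeKey, float]] = None,
        thetas: Optional[Mapping[EdgeKey, float]] = None,
        terminal_theta: float = 1.0,
        root_theta: float = 1.0,
        default_theta: float = 1.0,
    ):
        self.tree = tree
        self.terminal_theta = terminal_theta
        self.root_theta = root_theta
        self.default_theta = default_theta
        mut_lengths = dict(mut_lengths or {})
        thetas = dict(thetas or {})

        self.tau: dict[EdgeKey, Optional[float]] = {}
        self.mut: dict[EdgeKey, Optional[float]] = {}
        self.theta: dict[EdgeKey, float] = {}
        self._cluster_of: dict[int, frozenset] = {}

        below: dict[int, frozenset] = {}
        for node in tree.root.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset((node.label,))
            else:
                below[id(node)] = frozenset().union(
                    *(below[id(c)] for c in node.children)
                )
            self._cluster_of[id(node)] = below[id(node)]
            if node is tree.root:
                continue
            key: EdgeKey = node.label if node.is_leaf else below[id(node)]
            tau = node.length
            if tau is not None and tau < 0:
                raise ModelError(f"negative tau on edge {self._edge_name(key)}")
            mu = mut_lengths.get(key)
            self.tau[key] = tau
            if node.is_leaf:
                theta = terminal_theta
                self.mut[key] = mu if mu is not None else (
                    None if tau is None else theta * tau
                )
            else:
                if mu is not None and tau is not None:
                    if tau <= 0:
                        raise ModelError(
                            f"tau must be > 0 on internal edge {self._edge_name(key)}"
                        )
                    theta = theta_from_lengths(mu, tau)
                    given = thetas.get(key)
                    if given is not None and not math.isclose(
                        given, theta, rel_tol=1e-8
                    ):
                        raise ModelError(
                            f"inconsistent (tau, muT, Theta) on edge "
                            f"{self._edge_name(key)}: Theta = muT/tau requires "
                            f"{theta:g}, got {given:g}"
                        )
                    self.mut[key] = mu
                else:
                    theta = thetas.get(key, default_theta)
                    self.mut[key] = mu if mu is not None else (
                        None if tau is None else theta * tau
                    )
            self.theta[key] = theta

    def _edge_name(self, key: EdgeKey) -> str:
        if isinstance(key, str):
            return key
        return ",".join(sorted(key))

    @property
    def taxa(self) -> frozenset[str]:
        return self.tree.leaf_labels

    def internal_edges(self) -> list[tuple[frozenset, Optional[float]]]:
        """(cluster, tau) for each internal edge, in postorder."""
        return [
            (k, v) for k, v in self.tau.items() if not isinstance(k, str)
        ]

    def require_internal_tau(self) -> None:
        for key, tau in self.internal_edges():
            if tau is None:
                raise ModelError(f"missing tau on internal edge {self._edge_name(key)}")


# ---------------------------------------------------------------------------
# anomaly-zone scan
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnomalyPair:
    """A parent/child pair of internal species-tree edges with the anomaly
    criterion y < a(x)."""

    parent_cluster: frozenset
    child_cluster: frozenset
    x: float
    y: float
    a_x: float
    anomalous: bool


def anomaly_scan(model: SpeciesTreeModel) -> list[AnomalyPair]:
    """Evaluate y < a(x) for every (parent internal edge x, child internal
    edge y) adjacency of the species tree."""
    model.require_internal_tau()
    pairs: list[AnomalyPair] = []
    for node in model.tree.root.preorder():
        if node.is_leaf or node is model.tree.root:
            continue
        parent_cluster = model._cluster_of[id(node)]
        x = model.tau[parent_cluster]
        ax = a_of_x(x)
        for child in node.children:
            if child.is_leaf:
                continue
            child_cluster = model._cluster_of[id(child)]
            y = model.tau[child_cluster]
            pairs.append(
                AnomalyPair(
                    parent_cluster=parent_cluster,
                    child_cluster=child_cluster,
                    x=x,
                    y=y,
                    a_x=ax,
                    anomalous=y < ax,
                )
            )
    return pairs


def anomaly_fractions(models: Sequence[SpeciesTreeModel]):
    """Batch evaluation over a set of (e.g. bootstrap) species trees: the
    fraction of replicates flagging each parent/child pair.  Returns a pandas
    DataFrame with one row per pair."""
    import pandas as pd

    flagged: dict[tuple, list[int]] = {}
    for model in models:
        for pair in anomaly_scan(model):
            key = (
                ",".join(sorted(pair.parent_cluster)),
                ",".join(sorted(pair.child_cluster)),
            )
            flagged.setdefault(key, []).append(int(pair.anomalous))
    rows = [
        {
            "parent": parent,
            "child": child,
            "n_replicates": len(vals),
            "fraction_anomalous": sum(vals) / len(vals),
        }
        for (parent, child), vals in sorted(flagged.items())
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# MSC simulation (one allele per species, topology + mutational lengths)
# ---------------------------------------------------------------------------


def simulate_gene_trees(
    model: SpeciesTreeModel,
    n: int,
    seed: Union[int, Sequence[int], np.random.Generator],
    marker_class: str = "simulated",
) -> GeneTreeSet:
    """Simulate ``n`` gene trees under the multispecies coalescent.

    One lineage is sampled per extant species.  Within a species-tree branch
    of length tau (coalescent units), each pair of lineages coalesces at rate
    1 per coalescent unit; surviving lineages are passed to the ancestral
    branch, and the root branch is extended until complete coalescence (using
    ``model.root_theta``).  Output branch lengths are in mutational units:
    coalescent time within a branch is scaled by that branch's Theta
    (muT = Theta * tau).  Deterministic given the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    model.require_internal_tau()
    # species-tree postorder with per-node (tau, theta); root gets tau=inf
    sp_nodes = list(model.tree.root.postorder())
    for node in sp_nodes:
        if node is not model.tree.root:
            key = node.label if node.is_leaf else model._cluster_of[id(node)]
            if model.tau[key] is None:
                raise ModelError(
                    f"missing tau on edge {model._edge_name(key)} "
                    "(required for simulation)"
                )

    trees: list[RootedTree] = []
    for _ in range(n):
        pools: dict[int, list[tuple[Node, float]]] = {}
        root_node: Optional[Node] = None
        for node in sp_nodes:
            if node.is_leaf:
                pool = [(Node(node.label), 0.0)]
            else:
                pool = []
                for child in node.children:
                    pool.extend(pools.pop(id(child)))
            if node is model.tree.root:
                tau = math.inf
                theta = model.root_theta
            else:
                key = node.label if node.is_leaf else model._cluster_of[id(node)]
                tau = model.tau[key]
                theta = model.theta[key]
            elapsed = 0.0
            while len(pool) > 1:
                k = len(pool)
                wait = rng.exponential(1.0 / (k * (k - 1) / 2.0))
                if elapsed + wait > tau:
                    break
                elapsed += wait
                pool = [(g, acc + wait * theta) for g, acc in pool]
                i = int(rng.integers(k))
                j = int(rng.integers(k - 1))
                if j >= i:
                    j += 1
                gi, li = pool[i]
                gj, lj = pool[j]
                joint = Node()
                gi.length = li
                gj.length = lj
                joint.add(gi)
                joint.add(gj)
                pool = [p for idx, p in enumerate(pool) if idx not in (i, j)]
                pool.append((joint, 0.0))
            if math.isfinite(tau):
                remaining = tau - elapsed
                pool = [(g, acc + remaining * theta) for g, acc in pool]
                pools[id(node)] = pool
            else:
                root_node = pool[0][0]
        trees.append(RootedTree(root_node, validate=False))
    return GeneTreeSet(
        trees, taxon_universe=model.taxa, marker_class=marker_class
    )


# ---------------------------------------------------------------------------
# heterogeneity ratio
# ---------------------------------------------------------------------------


@dataclass
class HeterogeneityRatio:
    """Ratio of mean simulated to mean empirical gene-tree/species-tree
    distances: the share of observed heterogeneity attributable to coalescent
    variation.  ``defined`` is False when the empirical mean distance is 0."""

    ratio: float
    defined: bool
    metric: str
    sim_mean: float
    sim_ci: tuple[float, float]
    emp_mean: float
    emp_ci: tuple[float, float]
    n_sim: int
    n_empirical: int
    seed: Optional[int] = None


_METRICS = {"rf": rf_cluster_distance, "matching": matching_cluster_distance}


def _mean_ci(values: np.ndarray) -> tuple[float, tuple[float, float]]:
    mean = float(values.mean())
    if len(values) > 1:
        half = 1.96 * float(values.std(ddof=1)) / math.sqrt(len(values))
    else:
        half = math.nan
    return mean, (mean - half, mean + half)


def heterogeneity_ratio(
    empirical: GeneTreeSet,
    model: SpeciesTreeModel,
    n_sim: int = 10000,
    metric: str = "rf",
    seed: int = 0,
) -> HeterogeneityRatio:
    """Mean distance of simulated trees to the species-tree topology divided
    by the mean distance of empirical trees; 95% CIs on both means."""
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {sorted(_METRICS)}")
    dist = _METRICS[metric]
    sp = model.tree
    sim = simulate_gene_trees(model, n_sim, seed)
    sim_d = np.array([dist(t, sp) for t in sim], dtype=float)
    emp_d = np.array([dist(t, sp) for t in empirical], dtype=float)
    sim_mean, sim_ci = _mean_ci(sim_d)
    emp_mean, emp_ci = _mean_ci(emp_d)
    defined = emp_mean > 0
    ratio = sim_mean / emp_mean if defined else math.nan
    return HeterogeneityRatio(
        ratio=ratio,
        defined=defined,
        metric=metric,
        sim_mean=sim_mean,
        sim_ci=sim_ci,
        emp_mean=emp_mean,
        emp_ci=emp_ci,
        n_sim=n_sim,
        n_empirical=len(empirical),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# triplet goodness of fit (exact 2xk Fisher test)
# ---------------------------------------------------------------------------


def _log_table_prob(table: np.ndarray) -> float:
    """Log conditional probability of a 2xk table given its margins
    (multivariate hypergeometric)."""
    from math import lgamma

    n = table.sum()
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    lp = sum(lgamma(r + 1) for r in rows) + sum(lgamma(c + 1) for c in cols)
    lp -= lgamma(n + 1)
    lp -= sum(lgamma(x + 1) for x in table.ravel())
    return lp


def fisher_exact_2xk(
    table: Sequence[Sequence[int]],
    max_tables: int = 2_000_000,
    n_mc: int = 100_000,
    seed: int = 0,
) -> tuple[float, str]:
    """Fisher exact test for a 2 x k contingency table.

    The p-value is the total conditional probability of tables (same margins)
    no more probable than the observed one.  When the enumeration would
    exceed ``max_tables`` candidate tables the p-value is estimated by Monte
    Carlo sampling of tables with the given margins (Patefield algorithm via
    scipy), using the add-one estimator.  Returns ``(p, method)`` with method
    "exact" or "monte-carlo".
    """
    obs = np.asarray(table, dtype=np.int64)
    if obs.ndim != 2 or obs.shape[0] != 2:
        raise ValueError("table must be 2 x k")
    if (obs < 0).any():
        raise ValueError("counts must be >= 0")
    if obs.sum() == 0:
        raise ValueError("empty table")
    r1 = int(obs[0].sum())
    cols = obs.sum(axis=0)
    k = obs.shape[1]
    lp_obs = _log_table_prob(obs)
    tol = 1e-9

    n_candidates = 1
    for c in cols[:-1]:
        n_candidates *= min(r1, int(c)) + 1
    if n_candidates <= max_tables:
        # enumerate row-1 fills; margins are fixed, so
        # logP = const - sum(lgamma(cell + 1)) over cells
        from math import lgamma

        n = int(obs.sum())
        const = (
            sum(lgamma(int(r) + 1) for r in obs.sum(axis=1))
            + sum(lgamma(int(c) + 1) for c in cols)
            - lgamma(n + 1)
        )
        lg = [lgamma(i + 1) for i in range(n + 1)]
        cols_i = [int(c) for c in cols]
        total = 0.0
        threshold = lp_obs + tol
        ranges = [range(min(r1, c) + 1) for c in cols_i[:-1]]
        for combo in itertools.product(*ranges):
            last = r1 - sum(combo)
            if last < 0 or last > cols_i[-1]:
                continue
            cells = list(combo) + [last]
            lp = const - sum(
                lg[a] + lg[c - a] for a, c in zip(cells, cols_i)
            )
            if lp <= threshold:
                total += math.exp(lp)
        return min(total, 1.0), "exact"

    rng = np.random.default_rng(seed)
    sampler = stats.random_table(obs.sum(axis=1), cols)
    samples = sampler.rvs(n_mc, random_state=rng)
    hits = 0
    for s in samples:
        if _log_table_prob(np.asarray(s, dtype=np.int64)) <= lp_obs + tol:
            hits += 1
    return (hits + 1) / (n_mc + 1), "monte-carlo"


def _largest_remainder(probs: Sequence[float], total: int) -> np.ndarray:
    """Round probs*total to integers preserving the total."""
    raw = np.asarray(probs, dtype=float) * total
    base = np.floor(raw).astype(np.int64)
    short = total - int(base.sum())
    order = np.argsort(-(raw - base))
    for i in range(short):
        base[order[i]] += 1
    return base


def triplet_gof(
    observed: Union[TripletCounts, Sequence[int]],
    t: float,
    max_tables: int = 2_000_000,
    n_mc: int = 100_000,
    seed: int = 0,
) -> float:
    """Fisher exact test of observed triplet counts against the MSC
    expectation for internal branch length ``t``.

    The observed counts are ordered (major, minor, minor); expected counts
    are the expected probabilities times the observed total, rounded by the
    largest-remainder method so both rows of the 2x3 table share a margin.
    """
    if isinstance(observed, TripletCounts):
        obs = observed.as_tuple()
    else:
        obs = tuple(int(x) for x in observed)
    if len(obs) != 3 or any(x < 0 for x in obs):
        raise ValueError("observed must be three counts >= 0")
    total = sum(obs)
    if total == 0:
        raise ValueError("zero total count")
    exp = expected_triplet_probs(t)
    expected = _largest_remainder(exp.as_probs(), total)
    p, _ = fisher_exact_2xk(
        [list(obs), expected.tolist()], max_tables=max_tables, n_mc=n_mc, seed=seed
    )
    return p


def read_mut_lengths(path) -> dict[EdgeKey, float]:
    """Read a sidecar TSV of mutational branch lengths: two columns,
    ``edge`` (comma-joined descendant taxa for internal edges, a single taxon
    name for terminal edges) and ``muT``."""
    out: dict[EdgeKey, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("edge\t"):
                continue
            edge, mu = line.split("\t")
            taxa = edge.split(",")
            key: EdgeKey = taxa[0] if len(taxa) == 1 else frozenset(taxa)
            out[key] = float(mu)
    return out


def write_mut_lengths(model: SpeciesTreeModel, path) -> None:
    with open(path, "w") as fh:
        fh.write("edge\tmuT\n")
        for key, mu in sorted(
            model.mut.items(), key=lambda kv: model._edge_name(kv[0])
        ):
            if mu is None:
                continue
            fh.write(f"{model._edge_name(key)}\t{mu:.10g}\n")
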