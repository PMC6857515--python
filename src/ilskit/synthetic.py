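"""Synthetic study-scale data: species-tree scenarios, gene-tree sets with
controlled estimation error, and insertion matrices.

The default scenario is a palaeognath-like sampling of 12 ingroup species in
five major lineages (ostrich; two rheas; emu + cassowary; three kiwi; moa
plus three tinamous) with a chicken-like outgroup.  Two successive internal
branches — the stem of (rheas, (emu/cassowary, kiwi)) and the stem of
(emu/cassowary, kiwi) — are short enough that each (parent, child) pair
satisfies the anomaly-zone condition y < a(x); this placement is verified at
construction.  Branch lengths are the scenario's own desk-scale choices (and
are recorded in every manifest), not estimates of any particular empirical
tree.

Marker classes emulate three noncoding marker panels whose full-scale sizes
are 12,676 / 5,016 / 3,158 loci (CNEE-, intron- and UCE-like), scaled down by
a single factor.  Gene-tree estimation error is modelled as random NNI
perturbation, with the short-locus CNEE-like class noisiest; random taxon
deletion emulates missing data.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .treecore import (
    GeneTreeSet,
    RootedTree,
    apply_random_nni,
    parse_newick,
)
from .coalescent import (
    SpeciesTreeModel,
    anomaly_scan,
    write_mut_lengths,
)
from .retro import InsertionMatrix, generate_insertion_dataset


class ScenarioError(ValueError):
    pass


#: full-scale loci per marker class (scaled by ``ScenarioSpec.scale``)
STUDY_LOCI = {"CNEE": 12676, "intron": 5016, "UCE": 3158}

#: full-scale screened insertion loci stand-in (desk scale: scale * 13000)
STUDY_INSERTION_LOCI = 13000


@dataclass(frozen=True)
class MarkerProfile:
    """One marker class: scaled locus count plus an error model (probability
    that a locus's tree is perturbed by ``nni_moves`` random NNI moves, and a
    per-(tree, taxon) deletion rate emulating missing data)."""

    name: str
    n_loci: int
    nni_rate: float
    nni_moves: int = 1
    missing_rate: float = 0.007


#: per-class NNI error rates; the CNEE-like class is noisiest (short,
#: low-variability loci estimate gene trees least reliably)
DEFAULT_NNI_RATES = {"CNEE": 0.30, "intron": 0.08, "UCE": 0.10}

DEFAULT_LINEAGES = {
    "ostrich": "ostrich",
    "rhea_greater": "rhea",
    "rhea_lesser": "rhea",
    "emu": "emu_cassowary",
    "cassowary": "emu_cassowary",
    "kiwi_little_spotted": "kiwi",
    "kiwi_great_spotted": "kiwi",
    "kiwi_okarito": "kiwi",
    "moa": "moa_tinamou",
    "tinamou_thicket": "moa_tinamou",
    "tinamou_whitethroat": "moa_tinamou",
    "tinamou_elegant": "moa_tinamou",
    "chicken": "outgroup",
}

# tau in coalescent units; the (0.06, 0.04) and (0.04, 0.03) successive pairs
# are inside the anomaly zone (a(0.06) ~ 0.57, a(0.04) ~ 0.81)
_DEFAULT_TAU_NEWICK = (
    "(chicken:25,"
    "(ostrich:13.13,"
    "((moa:8,(tinamou_thicket:6,(tinamou_whitethroat:4,tinamou_elegant:4):2):2):5.07,"
    "((rhea_greater:6,rhea_lesser:6):7.03,"
    "((emu:5,cassowary:5):8,"
    "((kiwi_little_spotted:3,kiwi_great_spotted:3):1.5,kiwi_okarito:4.5):8.5"
    "):0.03):0.04):0.06):11.87);"
)


@dataclass
class ScenarioSpec:
    """Fully parameterized synthetic scenario."""

    tau_newick: str
    lineage_map: dict
    profiles: tuple[MarkerProfile, ...]
    n_insertions: int
    scale: float
    theta: float  # Theta on every branch (muT = theta * tau)
    stem_length: float
    omission_rate: float
    seed: int
    outgroup: str = "chicken"


@dataclass
class Scenario:
    spec: ScenarioSpec
    model: SpeciesTreeModel


_OVERRIDE_KEYS = {
    "scale",
    "tau_newick",
    "tau_overrides",
    "all_internal_tau",
    "theta",
    "stem_length",
    "omission_rate",
    "n_insertions",
    "profiles",
    "nni_rates",
    "missing_rate",
    "require_anomaly",
}


def make_scenario(
    overrides: Optional[Mapping] = None, seed: int = 0
) -> Scenario:
    """Build the default palaeognath-like scenario, optionally overridden.

    Recognised override keys: scale, tau_newick, tau_overrides (cluster
    tuple -> tau), all_internal_tau, theta, stem_length, omission_rate,
    n_insertions, profiles, nni_rates, missing_rate, require_anomaly.

    Unless branch lengths are overridden (or ``require_anomaly`` is set
    explicitly), construction verifies via a(x) that exactly the two designed
    successive short-branch pairs are anomalous.
    """
    overrides = dict(overrides or {})
    unknown = set(overrides) - _OVERRIDE_KEYS
    if unknown:
        raise ScenarioError(f"unknown override keys: {sorted(unknown)}")

    scale = float(overrides.get("scale", 0.1))
    theta = float(overrides.get("theta", 1.0))
    tau_newick = overrides.get("tau_newick", _DEFAULT_TAU_NEWICK)
    tree = parse_newick(tau_newick)

    tau_touched = "tau_newick" in overrides
    if "all_internal_tau" in overrides:
        tau_touched = True
        val = float(overrides["all_internal_tau"])
        if val < 0:
            raise ScenarioError("tau must be >= 0")
        for node in tree.root.postorder():
            if not node.is_leaf and node is not tree.root:
                node.length = val
    if "tau_overrides" in overrides:
        tau_touched = True
        wanted = {
            frozenset(k): float(v) for k, v in overrides["tau_overrides"].items()
        }
        below: dict[int, frozenset] = {}
        for node in tree.root.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset((node.label,))
            else:
                below[id(node)] = frozenset().union(
                    *(below[id(c)] for c in node.children)
                )
            key = below[id(node)]
            if key in wanted:
                node.length = wanted.pop(key)
        if wanted:
            raise ScenarioError(
                f"tau_overrides name clades absent from the tree: "
                f"{[sorted(k) for k in wanted]}"
            )
    for node in tree.root.postorder():
        if node.length is not None and node.length < 0:
            raise ScenarioError("tau must be >= 0")

    model = SpeciesTreeModel(
        tree, default_theta=theta, terminal_theta=theta, root_theta=theta
    )

    require_anomaly = overrides.get("require_anomaly")
    if require_anomaly is None:
        require_anomaly = not tau_touched
    if require_anomaly:
        flagged = [p for p in anomaly_scan(model) if p.anomalous]
        if len(flagged) != 2:
            raise ScenarioError(
                f"anomaly-zone placement violated: expected exactly 2 "
                f"anomalous parent/child pairs, found {len(flagged)}"
            )

    nni_rates = dict(DEFAULT_NNI_RATES)
    nni_rates.update(overrides.get("nni_rates", {}))
    missing_rate = float(overrides.get("missing_rate", 0.007))
    profiles = overrides.get("profiles")
    if profiles is None:
        profiles = tuple(
            MarkerProfile(
                name=name,
                n_loci=int(round(n * scale)),
                nni_rate=nni_rates[name],
                missing_rate=missing_rate,
            )
            for name, n in STUDY_LOCI.items()
        )
    n_insertions = int(
        overrides.get("n_insertions", round(STUDY_INSERTION_LOCI * scale))
    )

    spec = ScenarioSpec(
        tau_newick=tree.to_newick(precision=10),
        lineage_map=dict(DEFAULT_LINEAGES),
        profiles=tuple(profiles),
        n_insertions=n_insertions,
        scale=scale,
        theta=theta,
        stem_length=float(overrides.get("stem_length", 1.0)),
        omission_rate=float(overrides.get("omission_rate", 0.01)),
        seed=seed,
    )
    return Scenario(spec=spec, model=model)


# ---------------------------------------------------------------------------
# gene-tree sets with estimation error
# ---------------------------------------------------------------------------


def generate_gene_tree_sets(
    model: SpeciesTreeModel,
    profiles: Sequence[MarkerProfile],
    seed: int,
) -> dict:
    """Per marker class: simulate loci under the MSC, then apply the class's
    error model (random NNI with probability ``nni_rate``, random taxon
    deletion at ``missing_rate``).

    Returns ``{class name: (GeneTreeSet, manifest)}`` where the manifest is a
    truth table per locus: pre-error topology id, perturbed flag, number of
    NNI moves, deleted taxa.  Topology ids number distinct pre-error
    topologies in order of first appearance.
    """
    if not profiles:
        raise ValueError("profiles must be nonempty")
    from .coalescent import simulate_gene_trees

    out: dict = {}
    taxa = sorted(model.taxa)
    for ci, profile in enumerate(sorted(profiles, key=lambda p: p.name)):
        rng = np.random.default_rng([seed, ci])
        raw = simulate_gene_trees(model, profile.n_loci, rng, profile.name)
        topo_ids: dict = {}
        trees = []
        records = []
        for li, tree in enumerate(raw):
            key = tree.topology_key()
            tid = topo_ids.setdefault(key, len(topo_ids))
            perturbed = bool(rng.random() < profile.nni_rate)
            final = (
                apply_random_nni(tree, rng, moves=profile.nni_moves)
                if perturbed
                else tree
            )
            deleted = []
            if profile.missing_rate > 0:
                mask = rng.random(len(taxa)) < profile.missing_rate
                deleted = [t for t, m in zip(taxa, mask) if m]
                if deleted and len(deleted) < final.n_leaves:
                    final = final.prune_taxa(deleted)
            trees.append(final)
            records.append(
                {
                    "locus": f"{profile.name}_{li:06d}",
                    "topology_id": tid,
                    "perturbed": perturbed,
                    "nni_moves": profile.nni_moves if perturbed else 0,
                    "deleted_taxa": ",".join(deleted),
                }
            )
        gts = GeneTreeSet(
            trees, taxon_universe=model.taxa, marker_class=profile.name
        )
        out[profile.name] = (gts, pd.DataFrame(records).set_index("locus"))
    return out


@dataclass
class Bundle:
    scenario: Scenario
    gene_tree_sets: dict  # name -> GeneTreeSet
    manifests: dict  # name -> DataFrame
    insertions: InsertionMatrix
    insertion_truth: pd.DataFrame


def build_bundle(scenario: Scenario) -> Bundle:
    """Generate every synthetic input the analysis stages consume."""
    spec = scenario.spec
    gsets = generate_gene_tree_sets(
        scenario.model, spec.profiles, seed=spec.seed
    )
    matrix, truth = generate_insertion_dataset(
        scenario.model,
        spec.n_insertions,
        seed=[spec.seed, 991],
        omission_rate=spec.omission_rate,
        stem_length=spec.stem_length,
    )
    return Bundle(
        scenario=scenario,
        gene_tree_sets={k: v[0] for k, v in gsets.items()},
        manifests={k: v[1] for k, v in gsets.items()},
        insertions=matrix,
        insertion_truth=truth,
    )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture_bundle(bundle: Bundle, out_dir) -> dict:
    """Write the bundle as a deterministic directory of plain-text files and
    return the JSON manifest (also written as ``manifest.json``).

    Contents: species tree with tau branch lengths, muT sidecar TSV, one
    multi-tree Newick per marker class plus its truth manifest TSV, the
    insertion matrix TSV and its truth TSV, the lineage map TSV, and a
    manifest with the scenario parameters, seed and per-file sha256
    checksums.  The same seed yields a byte-identical bundle.
    """
    os.makedirs(out_dir, exist_ok=True)
    spec = bundle.scenario.spec
    files: dict[str, str] = {}

    def _path(name: str) -> str:
        files[name] = os.path.join(out_dir, name)
        return files[name]

    with open(_path("species_tree_tau.nwk"), "w") as fh:
        fh.write(spec.tau_newick + "\n")
    write_mut_lengths(bundle.scenario.model, _path("species_tree_muT.tsv"))
    with open(_path("lineages.tsv"), "w") as fh:
        fh.write("taxon\tlineage\n")
        for taxon in sorted(spec.lineage_map):
            fh.write(f"{taxon}\t{spec.lineage_map[taxon]}\n")
    for name in sorted(bundle.gene_tree_sets):
        bundle.gene_tree_sets[name].to_file(
            _path(f"genetrees_{name}.nwk"), precision=6
        )
        bundle.manifests[name].to_csv(_path(f"manifest_{name}.tsv"), sep="\t")
    bundle.insertions.to_tsv(_path("insertions.tsv"))
    bundle.insertion_truth.to_csv(_path("insertions_truth.tsv"), sep="\t")

    manifest = {
        "seed": spec.seed,
        "scale": spec.scale,
        "theta": spec.theta,
        "stem_length": spec.stem_length,
        "omission_rate": spec.omission_rate,
        "n_insertions": spec.n_insertions,
        "outgroup": spec.outgroup,
        "profiles": [
            {
                "name": p.name,
                "n_loci": p.n_loci,
                "nni_rate": p.nni_rate,
                "nni_moves": p.nni_moves,
                "missing_rate": p.missing_rate,
            }
            for p in spec.profiles
        ],
        "tau_newick": spec.tau_newick,
        "checksums": {name: _sha256(path) for name, path in sorted(files.items())},
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def validate_bundle(out_dir) -> bool:
    """Recompute the checksums recorded in ``manifest.json``."""
    with open(os.path.join(out_dir, "manifest.json")) as fh:
        manifest = json.load(fh)
    return all(
        _sha256(os.path.join(out_dir, name)) == digest
        for name, digest in manifest["checksums"].items()
    )
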