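# Methods

## Model and conventions

All analyses assume the multispecies coalescent (MSC) with one sampled
allele per species. A species tree is a rooted topology with, per branch,

* `τ` — length in coalescent units (convention τ = T/4Nₑ; only ratios of
  coalescent rates matter for topologies, so the convention does not affect
  any topological result),
* `μT` — length in expected substitutions per site (mutation rate ×
  generations),
* `Θ` — the population mutation parameter, tied to the other two by
  `Θ = μT/τ`.

`Θ = μT/τ` is adopted as the defining identity of the unit system (together
with τ = T/4Nₑ); `μT = Θ·τ` is then used to convert simulated coalescent
times to mutational branch lengths. Terminal-branch Θ is fixed at 1 by
convention: with one allele per species no coalescence can occur on a
terminal branch, so the value is inert for topologies and only scales
terminal branch lengths. Coalescence above the root uses a configurable
root Θ (default 1), the standard "root branch extended indefinitely"
convention.

Within a branch of length τ, each pair of the k lineages present coalesces
independently at rate 1 per coalescent unit (total rate k(k−1)/2);
survivors pass to the ancestral branch. The simulator is an exact
implementation of this process (exponential waiting times, uniform pair
choice), deterministic given a seed. Its oracle is the closed-form rooted
triplet distribution: major frequency `1 − (2/3)e^{−t}`, minors
`(1/3)e^{−t}` each; the test suite checks simulated frequencies against
these within three binomial standard errors at n = 10,000, and checks the
inversion `t = −ln(3(1−p)/2)` recovers branch lengths.

## Anomaly zone

For successive internal branches, parent `x` and child `y` (coalescent
units), anomalous gene trees are expected when `y < a(x)` with

    a(x) = ln[ 2/3 + (3e^{2x} − 2) / (18(e^{3x} − e^{2x})) ].

`a` is monotone decreasing, diverges as x → 0⁺, crosses zero at
x ≈ 0.2655 and tends to ln(2/3) < 0, so no anomaly is possible below a
parent branch longer than ≈ 0.2655 coalescent units. `anomaly_scan`
evaluates every parent/child adjacency of internal edges; a batch variant
reports, over a set of (bootstrap) species trees, the fraction of
replicates flagging each pair.

## Heterogeneity statistics

* **RF cluster distance**: size of the symmetric difference of the two
  rooted nontrivial cluster (clade) sets. Zero iff identical rooted
  topologies, including polytomy structure.
* **Matching cluster distance**: minimum-cost perfect matching between the
  two cluster lists (padded with empty clusters), pair cost = symmetric
  difference of leaf sets, solved with the Hungarian algorithm. Verified
  against exhaustive matching on all pairs with ≤ 6 leaves.
* **Topology binning**: trees grouped by exact cluster-set equality
  (equivalent to pairwise RF = 0). A polytomy bins only with identical
  polytomies. "Top 50" style truncation is a reporting parameter only.
* **GSF**: percent of gene trees containing a clade.
* **ICA** (internode certainty "all"): for a focal species-tree cluster,
  collect observed clusters incompatible with it at relative frequency
  ≥ `freq_threshold` (default 0.05 — the threshold is exposed because
  published usage varies), normalize focal + conflict frequencies to sum
  to 1, and compute `1 + Σ pᵢ log_n pᵢ` over the n clusters considered,
  negated when the focal cluster is not the most frequent. No qualifying
  conflict gives ICA = 1; a dominant conflict with an absent focal cluster
  gives −1.
* **Rooted triplets**: a tree restricted to a trio resolves to the pair
  whose cluster excludes the third taxon; a polytomy spanning the trio is
  unresolved. For lineage trios, every cross-lineage taxon trio votes
  within a gene, the gene contributes its modal resolution, and genes with
  tied modes are omitted (sampled trios within a gene are not independent,
  hence one vote per gene). Unresolved genes are excluded from proportion
  denominators and reported separately.

## Heterogeneity ratio

The ratio of the mean distance (RF or matching) between simulated gene
trees and the species-tree topology to the mean distance for empirical
gene trees measures the share of observed heterogeneity attributable to
coalescent variation. Both means carry normal-approximation 95% CIs. A
degenerate empirical set at distance 0 makes the ratio undefined; it is
reported as such (NaN with `defined=False`), not raised.

## Triplet goodness of fit

Observed trio counts (major, minor, minor) are compared to MSC expectations
at a given `t` with a Fisher exact test on the 2×3 table of observed versus
expected counts. Expected counts are probabilities × total, rounded by
largest remainder so both rows share the same margin (an explicit
construction choice; the rounding can shift exact p-values slightly for
small totals). The 2×k exact p-value sums conditional
multivariate-hypergeometric probabilities of tables no more probable than
the observed one; when the enumeration would exceed a size guard
(2,000,000 candidate tables by default) a Monte Carlo estimate over
Patefield-sampled tables with the same margins is used, with the add-one
estimator. The exact path is validated against R's `fisher.test` (values
frozen in the tests).

## Retroelement analytics

A locus is classified against the lineage map: lacking any scored
(non-omitted) taxon in some lineage → *missing-lineage-omitted*; presence
in all scored taxa → *symplesiomorphy*; presence in exactly one taxon →
*autapomorphy*; presence in ≥ 2 but not all scored taxa → *informative*
(with its presence cluster). Omission noise can erase all presences at a
locus; such loci get an explicit *uninformative* label so the labels always
partition the data.

A trio tally counts informative loci uniting exactly two of three lineages
(a lineage is present when any scored member carries the insertion, and a
locus participates only when all three lineages are scored — the "any
member" rule matches lineage-level reporting practice). The tree
significance test for counts (n₁, n₂, n₃), with n₁ supporting the tested
resolution, is the exact binomial tail `P(X ≥ n₁)`, `X ~ Bin(n₁+n₂+n₃, ⅓)`,
computed in log space. Only this tree test is implemented (the
polytomy/hybridization companions of the published test family are out of
scope); it is validated against exhaustive trinomial enumeration for totals
≤ 12 and satisfies `p(n₁,0,0) = 3^{−n₁}`. Minor-pattern symmetry is an
exact two-sided binomial test at p = ½.

The hemiplasy simulator drops one insertion per locus on an MSC gene tree,
choosing an edge with probability proportional to its mutational length
(plus a stem edge above the gene root, default length 1.0 μT, so
symplesiomorphies can arise); presence = leaves below the insertion.
Under this length-proportional placement the expected trio pattern weights
are (t + e^{−t}/3) : e^{−t}/3 : e^{−t}/3 — close to, but not identical
with, the triplet topology frequencies (they agree at t → 0 and t → ∞ and
differ by < 0.005 at t ≈ 0.1); the unit tests assert against this exact
expression. Minor patterns remain exactly symmetric, which is the property
the analysis relies on.

## R* consensus and subsampling

The species-tree estimator is the R* rooted-triplet consensus: the modal
resolution of every taxon trio (ties unconstrained), assembled greedily in
order of decreasing support margin via the Aho BUILD construction,
skipping triplets incompatible with those already accepted.
Underdetermined regions come out as polytomies. R* is statistically
consistent under the MSC — no three-taxon anomaly exists — which the suite
demonstrates by recovering the species tree from gene trees simulated
inside the anomaly zone, where topology-vote methods rank an anomalous
tree first.

Subsampling follows a double-resampling design: subsets of N loci drawn
with replacement (default grid 50–3000 in 11 steps, 10 replicates per
size), each bootstrapped gene-wise (default 200×); every bootstrap is
re-estimated with R*, collapsed to lineages (a non-monophyletic
multi-member lineage scores "other"), and matched against a hypothesis set
— by default the five alternative placements of the rheas, kept
configurable because hypothesis membership is a user-level modelling
choice. Reported are per-replicate bootstrap percentages, per-size means,
and counts of replicates exceeding support thresholds (70% / 90% by
default). The inner bootstrap resamples genes, not alignment sites: this
package operates on gene trees only, so site resampling has no meaning
here; the two-level design, size grid and summarization are otherwise
preserved.

## Synthetic scenario

The default scenario emulates a palaeognath-like sampling: 12 ingroup taxa
in five lineages (ostrich; 2 rheas; emu + cassowary; 3 kiwi; moa + 3
tinamous) plus a distant outgroup. Internal branch lengths are the
package's own desk-scale choices, recorded in every manifest and *not*
estimates of any empirical tree; the two successive short branches — the
stem of (rheas, (emu/cassowary, kiwi)) at τ = 0.04 below a τ = 0.06 parent,
and the (emu/cassowary, kiwi) stem at τ = 0.03 — satisfy y < a(x), and
construction verifies that exactly these two parent/child pairs are
flagged. All Θ default to 1, so μT = τ numerically; long terminal branches
make most simulated insertions recent (autapomorphic), as in real
retroelement screens.

Marker classes scale the full panel sizes 12,676 / 5,016 / 3,158 by one
factor (default 0.1). Gene-tree estimation error is modelled as a single
random NNI move applied with per-class probability (defaults 0.30 / 0.08 /
0.10 for the CNEE-, intron- and UCE-like classes: the short-locus class is
noisiest) — NNI is chosen because its topological effect is minimal and
exactly quantifiable (one cluster, RF distance 2). Missing data is
per-(tree, taxon) deletion at rate 0.007. What the generator does *not*
emulate: sequence-level variation, alignment length/quality differences,
biased (non-random) gene-tree error, and ascertainment of insertion loci;
passing tests therefore demonstrate correctness of the statistics under
the MSC with unbiased error, not robustness to systematic biases in real
data.

## Numerical choices and problem sizes

* Exact tests run in log space (`lgamma`); binomial tails via the stable
  survival function.
* Largest-remainder rounding preserves table margins in the goodness-of-fit
  test; topology-bin ties break by first appearance; greedy R* ties break
  by margin then lexicographic trio order — all outputs are deterministic
  given the input order and seed.
* Degenerate inputs are defined, not crashed on: empty trio totals give
  p = 1 in the insertion test; a zero empirical mean distance yields an
  undefined ratio; an empty filter result warns.
* Rooted-topology enumeration is guarded at 9 leaves per enumerated part
  ((2n−3)!! growth), with the estimated count named in the error.
* Default problem sizes in tests and examples (10,000–20,000 simulated
  trees for distribution-level claims, hundreds to thousands of loci for
  subsampling and insertion matrices) were chosen so that every
  distributional assertion has at least ~3σ headroom while the whole suite
  stays desk-scale.

## Known limitations

* μT values inherit the simplification that mutational branch lengths are
  estimated ignoring extra mutations from ancestral polymorphism; no
  correction is applied.
* Only one allele per species is simulated; multi-allele sampling and
  migration/hybridization are out of scope.
* The insertion test implements the tree-significance form only; the stated
  unit conventions are taken as defining (see above), so Θ values are
  interpretable only within this unit system.
* R* with greedy BUILD is a consistent but not likelihood-based estimator;
  it stands in for pseudo-likelihood/quartet methods by design.
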