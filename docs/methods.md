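# Methods

## The model

A Bayesian phylogenetic MCMC run returns a sample `T = {T1, …, Tk}` of rooted
binary tree topologies on a taxon set `X` of size `n`.  Because tree space
grows super-exponentially, even large samples miss most trees with
non-negligible posterior probability, so the raw *sample distribution*
(Monte Carlo probabilities `multiplicity / k`) is a poor estimate of the
posterior over topologies.  Conditional clade distributions (CCDs) smooth the
sample by assuming that, conditional on a clade occurring, the way it splits
is independent of the rest of the tree.

The data structure is a **CCD graph**: a rooted bipartite digraph whose
vertices are clades (subsets of `X`, stored as bit masks) and clade splits
(unordered pairs of disjoint clades partitioning their parent).  Each
non-leaf clade `C` carries a probability distribution over its child splits,
`Σ_{S∈S(C)} Pr(S|C) = 1`.  A tree `T` displayed by the graph has probability

    Pr(T) = Π_{S∈S(T)} Pr(S | parent(S)),

and these probabilities sum to one over all displayed trees.  Three
parametrizations populate the graph from sample frequencies `f(C)`, `f(S)`:

* **CCD1** (split frequencies): `Pr(S|C) = f(S) / f(C)` on the observed
  splits.  A CCD1's clade probabilities equal the Monte Carlo clade
  frequencies `f(C)/k` exactly (verified as an exact-math property test).
* **CCD0** (clade frequencies): the split set is *expanded* to every
  `{C1, C2}` with `C1`, `C2`, `C1∪C2` all observed and `C1∩C2 = ∅`, and
  probabilities are normalized so that `Pr(T) ∝ Π_{C∈C(T)} f(C)/k`.  Fewer
  parameters than CCD1, hence better small-sample behaviour but an
  asymptotic bias.
* **CCD2** (sibling-conditioned splits): an extended graph whose vertices
  are (clade, sibling-context) pairs, so `Pr(S | C, sibling)`.  More
  parameters than CCD1; with frequency estimates it displays exactly the
  sampled trees.

### CCD0 normalization

The normalization is computed with a subtree-sum recursion: `z(leaf) = 1`,
`z(C) = (f(C)/k) · Σ_{{C1,C2}∈S(C)} z(C1) z(C2)`, and
`Pr({C1,C2}|C) = z(C1) z(C2) / Σ_{S(C)} z(C1′) z(C2′)`.  Telescoping the
product along any displayed tree shows `Pr(T) = (1/z(X)) Π f(C)/k`, i.e.
exactly the clade-product model normalized to total mass one.  The sums are
accumulated in log space (`logsumexp`) so deep trees cannot underflow.
Correctness is enforced by an independent brute-force oracle: on small
graphs, enumerated probabilities are checked for constant proportionality to
`Π f(C)/k` and for unit total mass.

### Queries

All queries are dynamic programs over the graph, generic over plain and
extended (CCD2) graphs via a common vertex interface:

* tree probability: product of conditional split probabilities in log space;
  a tree using any absent split has probability exactly 0 (not an error);
* sampling: top-down draw of one split per clade (inverse-CDF per vertex,
  seeded NumPy generator — byte-identical output for identical seeds);
* tree count: `t(C) = Σ t(C1) t(C2)` with arbitrary-precision integers
  (counts overflow fixed-width integers quickly);
* entropy: `H*(C) = Σ_S −Pr(S)(log Pr(S) − H*(C1) − H*(C2))` with natural
  logarithm, so the number equivalent `Ne = exp(H)` is the effective number
  of distinct topologies;
* clade probabilities: one top-down pass distributing `p(parent)·Pr(S|parent)`
  to children; within a single tree the incoming split instances of a clade
  are disjoint events, so the sums are exact;
* enumeration (the test oracle): recursive expansion, refused above a
  configurable cap (default 10⁶ displayed trees).

## Point estimators

* **MCC**: the *sampled* tree maximizing `Π_{C∈C(T)} f(C)/k` over nontrivial
  clades (trivial clades contribute factor one).  Ties → higher
  multiplicity, then canonical clade-set order.
* **Greedy consensus**: clades accepted in decreasing frequency when nested
  with or disjoint from all accepted clades; ties → larger clade, then
  smaller bit mask.  Output may be unresolved; this is the only place
  unresolved topologies arise, and they carry splits only at binary nodes.
* **CCD-MAP** (any flavor): `Pr*(C) = max_S Pr(S|C) Pr*(C1) Pr*(C2)` in log
  space with backtracking; ties → canonical-first split.  Always fully
  resolved; its probability is verified to match `tree_probability`.
* **CCD0-MSCC**: same backbone with sums of clade credibilities,
  `S*(C) = f(C)/k + max_S (S*(C1) + S*(C2))`, nontrivial clades only
  (trivial clades add the same constant to every tree).

Canonical orderings used everywhere: a split stores the smaller bit mask
first; a clade's splits are sorted by (left bits, right bits); topologies
compare by the sorted tuple of their clade bit masks.  These replace every
"ties broken arbitrarily" in the procedure definitions so results are
reproducible across runs and platforms.

## Evaluation metrics

Against an enumerable *golden* reference distribution: MAE (mean
|p_est − p_ref| over reference-support trees, which weights high-probability
trees most), MRE over the 50%/95% credible prefix or over all reference
clades, rank of the reference's top tree in the estimate's ordering, and
replicate precision (mean absolute probability difference over the union of
two replicates' supports).  Point-estimator accuracy and precision use the
rooted Robinson–Foulds distance — half the symmetric difference of
nontrivial clade sets — and its `n−2` normalization (the fraction of true
clades an estimate got wrong).  When an estimate's support is too large to
enumerate, the top-tree rank falls back to a stated candidate pool
(reference support plus the estimate's MAP tree).

## Synthetic data: what it emulates, what it does not

There is no MCMC here.  Ground truths are synthetic CCDs built by
`random_ccd`: a leaf-prune-regraft random walk (default one move per step)
from a Yule base topology contributes the clade/split support, and each
clade's split distribution is drawn from a symmetric
Dirichlet(concentration).  The walk is essential: posterior samples
concentrate on mutually similar trees whose shared clades recombine, so the
graph displays far more trees than it was built from.  A pool of
*independent* random topologies on ≥8 taxa shares almost no clades and
degenerates to a distribution over the pool itself (Ne ≈ 2–3) — nothing
like a posterior.  At walk length 100 on 8–10 taxa the truths display
hundreds to thousands of trees with entropies around 3–6 nats, i.e.
genuinely diffuse.

Replicate "posterior" samples are i.i.d. draws from the truth, organized as
nested subsamples (the size-3 sample is a prefix of the size-10 sample,
mirroring subsampling a single chain).  This emulates a well-mixed chain;
it does **not** emulate autocorrelation, multi-modality, or burnin
contamination, so passing tests show correctness of the estimators and the
qualitative sample-size regimes, not performance on pathological real
chains.  The truth being itself clade-factorized slightly favours CCD
models over the sample distribution; that is the regime the smoothing
argument addresses, and the benchmark's golden reference is the exact
generating distribution rather than a mega-sample (which the generator makes
both exact and cheap).

## Problem sizes and numerical choices

Tests and the benchmark run at desk scale by design: oracle suites use 4–7
taxa with walk length 3–5 (enumerable graphs, ≤ a few thousand trees), and
the sample-size-regime study uses 24 seeded truths on 8–10 taxa (walk length
100, display cap 20 000) with subsamples of 3/10/30 trees — CCD0 is scored
against the raw sample distribution by MAE, and the win count is tested
against a fair coin at 95% confidence.  Probability-sum invariants are
validated to 1e−9 at construction; exact identities (clade-probability
theorem, worked-example fractions) are asserted to 1e−12; burnin defaults to
a fraction 0.1 of trees in file order, applied before multiplicity merging.

Outlier diagnostics follow the once-observed rule: a topology is reported
if it contains clades or splits seen exactly once, or if it is *isolated* —
every nontrivial clade's count equals the topology's own multiplicity (it
shares nothing with the rest) *and* it is a minority of the sample
(multiplicity ≤ k/2; without the guard a homogeneous sample would flag
itself).  Detection is advisory only; nothing is removed.

## Known limitations

* CCD parameters come from observed frequencies only; maximum-likelihood,
  regularized, or variational parameter fitting is out of scope.
* Input trees must be rooted and binary; unresolved trees appear only as
  greedy-consensus output.
* Branch lengths and divergence times are ignored throughout; annotating a
  summary topology with times is an independent downstream step.
* `expand_splits` is quadratic in the number of observed clades — fine at
  desk scale, the known hot spot for very large samples.
* Topology-level only: no unrooted-tree support and no polytomy-aware RF
  variants.
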