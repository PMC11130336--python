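# Methods

## Model

A discrete trait with observed states O (binary absent/present, or the
ternary absent/actinorhizal/rhizobial split) evolves along a rooted,
time-calibrated phylogeny under a continuous-time Markov chain on
composite states S = O × R, where R is a set of 1–5 hidden rate
classes. The generator Q is parameterized by an integer index matrix:
entry 0 marks a forbidden transition (exactly zero in Q for every
parameter vector), entry p > 0 points to free rate parameter p. Allowed
transitions are observed-state changes within a class and class changes
within an observed state, each with its own rate (fully unequal rates);
simultaneous changes of both parts are forbidden by default — the
standard hidden-rates convention — with an `allow_dual` flag for
experimentation. Rates are events per Myr with default bounds
[1e-9, 100]; on a ~100-Myr tree the lower bound is numerically
indistinguishable from zero.

Three special structures are first-class:

- a **no-gain class**: in one designated class, transitions out of the
  absent state into the present state are forbidden, modelling lineages
  with no pathway to the trait. The same biology can emerge from a free
  3-class fit whose third class becomes absorbing; both routes are
  constructible, and neither is hard-coded as "the" model.
- the **two-rate precursor model**: absent/nonprecursor ↔
  absent/precursor → present, with loss back to the precursor (4
  parameters). The present/nonprecursor composite state exists but is
  disconnected.
- the **three-state stepping-stone model**: two classes; actinorhizal
  symbiosis gained only from precursor-class absent, rhizobial symbiosis
  only from the actinorhizal state, losses back to absent within a
  class, class changes within absent. The direct absent → rhizobial
  entry is structurally zero. The published description of this model is
  verbal; the loss and class-change structure here (9 parameters) is
  this package's concrete realization of it, and the enumerated
  transition list in `build_three_state_pathway_model` is the
  authoritative definition.

## Likelihood

Felsenstein pruning over composite states. Tip vectors put 1 on every
composite state whose observed part matches the scored state; unknown
('?') tips are all-ones. Node-state constraints (e.g. "focal ancestor
trait-present, any class") zero the disallowed composite states at that
node before its message passes rootward; data rendered impossible yield
lnL = −∞ with a flag rather than an exception. Underflow is controlled
by per-node rescaling with accumulated log factors, which survives
10⁴-tip trees.

Root priors: flat over composite states (default), stationary
distribution of Q (least-squares solve, robust to reducible Q),
FitzJohn observed-conditional weighting, or a user vector. The source
analyses do not state their choice; every result records which prior
was used, and the likelihood oracle tests cover all three built-ins.
Fits to data simulated with a known root state use the matching user
prior.

**Transition probabilities.** P(t) = e^{Qt} is needed for thousands of
branch lengths per likelihood evaluation. Instead of one
scaling-and-squaring expm per edge, Q is eigendecomposed once per
evaluation and P(t) for all edges is assembled in a single batched
einsum; if the eigenvector matrix is ill-conditioned (cond > 1e10) the
code falls back to scipy's expm per distinct branch length. For the
state spaces used here (≤ 10 states) the two routes agree to ~1e-13
(asserted indirectly by the enumeration oracle tests, which use scipy
expm exclusively). Zero-length branches get an identity matrix without
an exponential. Pruning itself is batched over "levels" (nodes grouped
by height) so the per-node Python overhead is amortized; a 2,000-tip
binary-model evaluation costs ~5 ms.

## Fitting and uncertainty

Rates are optimized on the log₁₀ scale by bounded Nelder–Mead
(fatol 1e-8) from random starts drawn log-uniform over the bounds;
restart seeds derive from a master seed via a counter and every
trajectory is recorded, so "n random restarts" is exactly reproducible.
An optional `start_range` narrows the start distribution (the large
fixture fits start in [1e-5, 1] rates/Myr, where any plausible optimum
lies) without narrowing the optimization bounds. Model comparison uses
AIC = 2k − 2 lnL, best-first, ties broken toward fewer parameters.

The Δ2 confidence region follows the dentist approach: points are
sampled in log-rate space and kept iff lnL ≥ lnL_max − Δ (Δ = 2 by
default); reported are per-parameter min/max over accepted samples and
the accepted-sample covariance, whose off-diagonal structure flags
likelihood ridges. Sampling combines (a) per-axis doubling-plus-bisection
to the Δ boundary with other parameters at the MLE, and (b) Gaussian
random walks (step 0.25 in log₁₀ units) restarted from the MLE and from
each axis boundary point. For a one-parameter model the reported
interval matches a dense grid profile of the likelihood (asserted in
tests). The function refuses to run when re-evaluating the supplied
optimum does not reproduce its stated likelihood.

## Reconstruction and event counting

Marginal reconstruction is the standard up–down algorithm: outside
vectors propagate rootward-to-tipward, and the per-node posterior is the
normalized product of outside and inside vectors. Joint reconstruction
is the Pupko max-product dynamic program with back-pointers, run in log
space; the root maximization includes the root prior, and ties (within
1e-10 log units) are broken toward the lowest composite-state index and
logged. Both agree with exhaustive enumeration on small instances to
1e-8/1e-10.

Gains and losses are counted by comparing collapsed observed states at
the two ends of every edge of the joint reconstruction. These are
minimum-change counts — a state can change and revert within one edge
without leaving a nodal trace — and every summary carries that caveat.
Events are attributed to the child-side edge and, in clade tables, to
the smallest named clade containing the edge's parent node, with a
catch-all row preserving totals. Stochastic character mapping, which
would resolve within-edge histories, is out of scope.

Fitted 3-class binary models are given roles heuristically: the class
whose absent composite state has total exit rate below a threshold
(default 1e-6/Myr, configurable) is the non-precursor; of the rest, the
class with the larger gain rate is the intermediary and the other the
precursor. Non-unique assignments raise with the full rate signature.

## Rate-grid scan

"Even distribution" of gain/loss pairs is ambiguous, and rates are
scale parameters, so the default grid is 100 couples even on the log₁₀
scale over factors 1e-2..1e2 of the anchored MLE, with gain factors
ascending and loss factors descending so the loss/gain ratio sweeps
monotonically; the point nearest the MLE is replaced by the exact MLE
pair. A √n × √n factorial mode and a linear spacing are options, and
the spec used is recorded in the output. The anchor is a 1-class
2-parameter fit; each pair gets a tree log-likelihood and the focal
node's marginal observed-state probabilities.

## Synthetic data

Trees are constant-rate birth–death, grown forward from a root split
until the extant count first reaches n (then extended by one more
exponential waiting time), with extinct lineages pruned, unifurcations
suppressed and extinct-everything attempts discarded. This "stop at
first passage" conditioning is approximate — it slightly favours trees
that reach n quickly — which is irrelevant here because all downstream
analyses condition on the realized tree. Trees are optionally rescaled
to a fixed height (fixtures use 100 Myr).

Trait histories are simulated exactly: along each edge, exponential
waiting times from the current composite state's total exit rate,
destination by relative rates, with the full event chain retained. The
mean event count matches the matrix-method expectation
∫ occupancy(t)·exit-rates dt (tested to 3 standard errors), and
endpoint pattern frequencies match pruning probabilities.

The flagship fixture emulates the statistical structure of a
nitrogen-fixing-clade-like history: 1,000 tips, height 100 Myr, a
3-class binary no-gain-class model, the precursor class seeded at the
internal node whose clade is closest to half the tips, and the
absorbing non-precursor everywhere else (so outgroup tips stay absent).
The default rates encode the qualitative ordering inferred for RNS:
gain from the intermediary 0.02/Myr; precursor → intermediary 10×
slower (0.002); loss 150× slower than gain (1.33e-4); precursor loses
lability to non-precursor twice as fast as it gains it (0.004); the
intermediary returns to the precursor as fast as it gains the trait
(0.02). The absolute scale was set by a flux argument: with ~6,000 Myr
of ingroup branch length, ~12 expected precursor → intermediary entries
and a ~50% chance of gaining before reverting yield a handful of
independent gains per history — the multiple-gain regime the method
must resolve. Histories with fewer than 2 true gains are regenerated
with an incremented seed (count logged). A configurable fraction of
tips can be masked to unknown. All randomness flows from one master
seed via named substreams (tree / history / mask).

What the fixtures do **not** emulate: genus-level collapsing of tips,
non-random (clade-correlated) missingness, phylogenetic error, or
diversification–trait interactions. Passing tests therefore demonstrate
correctness of the inference machinery under the model class, not
robustness to tree error or biased sampling.

## Problem sizes and test design

Enumeration oracles run on ≤ 6-tip trees with ≤ 6 composite states,
where exhaustive sums and argmaxes are exact and fast. Rate-recovery
calibration uses 2,000-tip trees (20 replicates) with generating rates
gain 0.005, loss 0.002 /Myr and the matching known-root prior; the
generating pair is expected inside the dentist-style Δ2 parameter
ranges in ≥ 80% of replicates. (The likelihood-ratio statistic itself
is slightly over-dispersed relative to its asymptotic χ² at this tree
scale — a known finite-information effect on phylogenies — so the
per-parameter ranges, not the raw likelihood inequality, are the
reported uncertainty summary.) Multiple-gain
detectability uses 10 default fixtures with moderate optimization
effort (4 restarts, capped evaluations — far below the 100 restarts a
production analysis would use, but enough that detection failures are
not dominated by unconverged fits).

A genuine failure mode worth knowing about: on simulated histories
where gains are so numerous that the trait saturates most of the
ingroup, the globally best-fitting solution under a flat root prior can
be the inverted scenario — an ancestrally present trait with many
losses — in which case the joint reconstruction honestly counts zero
gains. This is the single-origin/many-loss rival hypothesis itself, and
distinguishing the two on real data is precisely a model-comparison and
fixed-ancestor question (the ΔAIC machinery here exists for that
purpose); the detectability check simply accepts that a small fraction
of extreme simulated histories resolve that way.

## Known limitations

- Joint reconstruction reports one optimum; near-ties are logged but
  alternative co-optimal histories are not enumerated.
- Minimum-change event counts understate true event numbers on long
  edges in high-rate regimes (by design; flagged in every summary).
- AIC on a single tree has no replicate-based error bar; the Δ2 region
  quantifies rate uncertainty only, under the chosen model.
- No AICc correction is applied (the effective sample size of
  phylogenetically correlated tips is not well defined); the `aicc`
  field currently mirrors `aic` and is reported for interface
  completeness only.
- The no-gain-class and free-absorbing routes to the same biology are
  not distinguished automatically; choosing between them is left to
  model comparison by the user.
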