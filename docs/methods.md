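# Methods

## Propagation model

The package models a signaling network as a simple signed digraph: one link
per ordered (source, target) pair, signed +1 (activation) or −1
(inhibition). Node activity is multiplicative in its regulators' activities
and its own basal activity; taking logarithms gives the linear update

    x(t+1) = α W x(t) + (1 − α) b

with `x` log-activity, `b` log basal activity and `α ∈ (0, 1)` the damping
hyperparameter balancing incoming signal flow against basal activity.
Sustained input stimulation is encoded as `b = +1` at the stimulated node,
inhibitory perturbation as `b = −1`; stimulation is assumed constant in
time, so it lives entirely in `b`. All computation stays in log-space —
callers who want raw activities exponentiate themselves.

The steady state `x_s = (1 − α)(I − α W)⁻¹ b` is computed by a linear solve
(never an explicit inverse) and is independent of the initial state. The
iterative mode starts from `x(1) = b` and stops when the step norm (L2 by
default; L1/L∞ configurable) drops below `tol`. A positive spectral margin
`1 − α·ρ(W)` certifies both convergence of the iteration and invertibility
of `I − α W`.

Assumptions worth keeping in mind: linearity (no saturation, no logic
gates), time-invariant stimulation, a single weight per ordered node pair,
and signs that are correct in the curated topology. The method predicts
*directions* of change between two conditions, not magnitudes.

## Link-weight normalization

`W = D_in^{-1/2} A D_out^{-1/2}`, where `D_in`/`D_out` are diagonal
matrices of in-/out-degrees (row/column sums of |A|). Every link weight
then satisfies `|W_ij|·sqrt(d_in(i)·d_out(j)) = 1` exactly, so `|w| ≤ 1`
with equality iff both incident degrees are 1 — effectively all links
become decay type (|w| < 1), which is what keeps the propagation stable
without any kinetic information. Zero-degree diagonal entries would be
singular under the inverse square root; their contribution is defined as 0,
which is safe because a link implies both incident degrees ≥ 1.
Normalization is not idempotent, so weight matrices carry a `normalized`
flag and re-normalizing one is an error; recompute from the adjacency
matrix instead.

Weight classification: decay `|w| < 1`, amplification `|w| > 1`, and the
boundary `|w| = 1` gets its own "unit" kind rather than being forced into
either class. Post-normalization weight multipliers (positive factors on
named links) support what-if adjustment of selected flows; sign changes are
deliberately not expressible there — they belong to topology randomization.

## Conditions, DAC and scoring

A condition is a stimulus set (basal +1 each) and a perturbation set (−1
each); all panel perturbations are inhibitory, matching the evaluation
datasets this workflow was designed around (an optional signed extension
exists for activating perturbations). The control for a condition defaults
to "same stimuli, no perturbations", so the fold change
`x_fold = x(cond) − x(control)` isolates the perturbation's net effect; an
explicit control can override this per panel. When several inputs are
stimulated together each contributes +1 (magnitude interactions are not
modeled).

The DAC is `sign(x_fold)` with an exact-zero threshold by default
(`zero_tol` configurable for noisy data). Accuracy per condition is the
fraction of readouts whose predicted sign matches the actual one.
Readouts whose actual entry is exactly 0 ("no change") are excluded from
the denominator by default, because the panels score direction; a strict
mode counts 0-vs-0 as a match instead. Real-valued actual panels (log2
fold changes) are signed before scoring. Conditions that fail to converge
are dropped from scoring with a logged warning rather than aborting the
whole evaluation. The headline summary is the median per-condition
accuracy, with quartiles for distribution plots.

## Randomization and weight policies

The "wrong topology" null model preserves every node's in- and out-degree:
a swap picks two links and exchanges their targets; proposals creating a
duplicate ordered pair or a new self-loop are rejected and redrawn (up to
100 retries, then the swap is skipped and counted in a warning). Sign
flips pick links with replacement, so a link flipped twice is restored; a
`distinct` option forces distinct links. Defaults: L swap events and
⌊L/2⌋ flip events for a network with L links. All randomizations are pure
functions of (network, spec, seed).

Weight policies replace the normalized weights with sampled magnitudes
(signs always from the topology): D draws |w| from (0.001, 1), D+A from
(0.001, 1000); the N(·) variants re-apply the degree normalization to the
sampled matrix, with sampled magnitudes entering the degree sums as
absolute values. Magnitudes are drawn **uniformly** over the range by
default. A log-uniform option is provided, but uniform is the default for
a substantive reason: the hallmark result of the policy comparison is that
normalization recovers the D+A arm's accuracy, and that recovery is only
possible when the sampled magnitudes are concentrated within about a
decade (as uniform draws over (0.001, 1000) are). Log-uniform magnitudes
span six decades and remain heterogeneous after normalization, so the
N(D+A) arm would stay degraded — a different experiment than the one being
emulated.

## Synthetic ground truth

Topology-only prediction can only be benchmarked against outcomes produced
by dynamics the predictor does not see. The hidden model shares the
network's topology and signs but not its magnitudes: each normalized
weight is multiplied by a lognormal factor `exp(σ·N(0,1))` with spread
σ = 1.0 by default — order-of-magnitude kinetic uncertainty, the regime
where topology is informative but not sufficient. If the jittered matrix
would lose the spectral margin, the whole matrix is rescaled uniformly to
a margin of 0.05; uniform rescaling preserves every flow direction.
Observed log fold changes get additive Gaussian noise (σ = 0.01 by
default, small measurement noise), and a detection threshold (default 2×
the noise scale) calls folds below it "no change" (0), the way panel DAC
calls threshold small fold changes. With zero noise the threshold is 0 and
unaffected readouts come out exactly 0. An optional tanh squashing of the
hidden update stresses the predictor outside the linear family.

Benchmark datasets mirror the shape of the densest published evaluation
panel: 22 nodes, 47 links, 2 inputs, 13 perturbation targets, 13 readouts,
66 conditions (all single perturbations plus sampled duals, every
condition under full input stimulation), 25% inhibitory links — a typical
fraction for curated signaling networks — and 5 sub-datasets per
replicate as a desk-scale stand-in for the published 200. Inputs are
disjoint from perturbation targets; readouts are drawn from non-input
nodes and may coincide with targets, as in the published panels. All
generators are pure functions of their spec and seed.

What passing benchmarks do and do not show: the hidden model is the same
linear log-space family as the predictor, so the benchmark isolates the
effect of *unknown magnitudes* given *correct signs and wiring*. It does
not probe nonlinear saturation (beyond the optional tanh), feedback-driven
multistability, time-dependent stimulation, or curation errors in the
signs themselves — accuracies on real panels will generally be lower than
on this synthetic family.

## Clustering and topology correlation

Accuracy matrices (readouts × conditions, entries the fraction of
sub-datasets in which the readout's direction was called correctly) are
clustered agglomeratively with Manhattan (city-block) distances via
scipy's `pdist`/`linkage`. Average linkage is used — the distance choice
is specified by the workflow being emulated, the linkage is not, and
average linkage is the least committal for non-Euclidean distances. The
topology comparison correlates the readouts' cophenetic distances (not
plotted dendrogram heights) with shortest-path distances on the
undirected, unsigned skeleton; pairs disconnected in the skeleton are
excluded, and fewer than 3 usable pairs is an error.

## Numerical choices and degenerate inputs

- Iterative convergence: L2 step norm, `tol = 1e−6`, `max_iter = 1000`;
  hitting the budget returns a flagged unconverged state instead of
  raising, so panel evaluations can skip the condition.
- Non-finite iterates raise a divergence error pointing at the spectral
  margin; the exact solver raises when `cond(I − αW) > 1e12`, at which
  point steady-state signs are numerically meaningless.
- Exact mode is the default (the steady state is the quantity of
  interest); the iterative solver doubles as an independent oracle in the
  tests.
- The acceptance benchmark runs 50 replicates of the 22-node spec; the
  test suite uses the same generator at smaller replicate counts.
- Duplicate links are an input error (one weight per ordered pair);
  self-loops are representable but never emitted by the generators.
- The |w| = 1 boundary in weight classification is reported as "unit":
  normalized weights hit it exactly when both incident degrees are 1, so
  collapsing it into "decay" or "amplification" would misdescribe the
  closed form.

## Known limitations

- Linearity: strong feedback and saturation can make true steady-state
  responses non-monotone in ways no sign-consistent linear model captures.
- The six-node demonstration network is a synthetic completion: the
  E→B and E→D links (and the downstream effect on F) are fixed by the
  worked example it reproduces, the remaining links are filler chosen so
  the stimulus reaches every node; quantitative tests avoid the filler
  links.
- Weight-policy conclusions depend on the sampling distribution (see
  above); both distributions are available for sensitivity analysis.
- The evaluation treats readouts independently; correlated measurement
  error across readouts is not modeled.
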