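# Methods

`dynhom` implements joint Bayesian inference of *primary homology
statements* and time-calibrated phylogeny for discrete morphological
data, together with the downstream analyses used to characterise an
ancestral phenotype: ancestral sequence logging at a focal node and
MORD/PCO phenetics of the reconstructed ancestors.

## The model

**Data.** A taxa-by-characters matrix of discrete states (symbols 0-9)
with missing (`?`) and inapplicable (`-`) entries and polymorphic cells
(`{01}`). Missing and inapplicable are distinct tokens in the data model
but are treated identically by the likelihood and by distances (both
become uninformative); polymorphic cells contribute partial likelihood
at each member state.

**Dynamic homology.** Where comparative anatomy admits N conflicting
primary homology statements for a set of features, the matrix carries a
*homology block*: N alternative codings ("homology alignments") of the
same character columns. An integer homology state h in {0..N-1} selects
the active coding. The likelihood bank keeps one pruning engine per
coding with cached per-state log-likelihoods and dirty flags; the
*multiplexer* passes the active state's value to the posterior, and all
states' values are refreshed at logging time so per-state mean
log-likelihoods are estimable from any trace. The chain therefore dwells
in homology states in proportion to how well their alignments fit the
tree — on a fixed tree the homology posterior is exactly the softmax of
the per-state log-likelihoods under the uniform prior over states, and
that analytic value is used to validate the sampler. Multiple
independent blocks are supported; the likelihood factorises over the
fixed partition and the blocks, so per-state values reported in traces
are the homology partition's own tree likelihoods (the fixed partition's
contribution cancels in every homology comparison).

**Substitution model.** The Mk model (symmetric k-state CTMC, uniform
stationary frequencies) with per-partition rate multipliers. Characters
are partitioned by (observed state count, homoplasy); each partition has
a rate r_p with the constraint that the character-weighted mean of rates
equals one, maintained exactly by a weight-scaled delta-exchange
operator. Rates carry normal(1, 2) priors (truncated to positive by
rejection). No gamma heterogeneity: rate variation is handled entirely
by the homoplasy partitions. By default no ascertainment correction is
applied (plain Mk); an `mkv` flag conditions on variable characters as a
sensitivity knob, since tools in this ecosystem commonly do. Characters
with fewer than two observed states are scored under the binary model;
a character with no observations contributes exactly zero
log-likelihood. The pruning pass exploits the equal-off-diagonal
structure of Mk (P v = P_diff * sum(v) + e^{-kd/(k-1)} v) and rescales
partials per node.

**Homoplasy partitioning.** Homoplasy is extra Fitch length beyond
(observed states - 1), computed on the best tree found by a seeded
implied-weights parsimony search (Goloboff fit cost sum h/(h+k),
concavity k = 10 by default; random-addition starts + SPR, 10 starts by
default, deterministic per seed). A single search is run on the matrix
containing the fixed columns plus *every* coding of every block;
variable-homology characters whose homoplasy differs between codings
take the lower value, and their observed-state count is taken from the
lower-homoplasy coding (ties resolve to the lower state index). Each
distinct homoplasy value is its own partition key (no binning) — a
binned scheme can be obtained by pre-transforming the homoplasy vector.

**Tree prior.** The sampled-ancestor birth-death process with
speciation lambda, extinction mu, fossil sampling psi, extant-sampling
probability rho (0 for all-fossil matrices) and an origin time,
conditioned on the origin. Sampled ancestors are represented as
zero-length terminal attachments: the tree stays strictly binary, the
pruning pass needs no special casing, and the density routine classifies
tips by pendant length (a zero-pendant fossil contributes psi; a pendant
fossil leaf psi p0(y)/q(y); an extant tip rho; true bifurcations lambda
q(x)). Two analytic checks pin the implementation: the psi->0 limit
equals an independently coded constant-rate birth-death density, and
jointly rescaling all times and rates changes the density by exactly the
dimensional Jacobian.

**Tip dates.** Fossil tips belong to fossil *sites*; all tips of a site
share one age parameter with a uniform prior over the site's
stratigraphic bounds. Site moves drag sampled-ancestor attachments along
with their tips and reject age-order violations.

**Clock.** Uncorrelated lognormal relaxed clock: a global rate
(lognormal prior, log-space mean -5.5, sd 2 — a real-space mean of -5.5
is impossible for a rate, so log-space is the only consistent reading)
times i.i.d. per-branch multipliers, lognormal with real-space mean one
and log-sd sigma (exponential prior with mean 1 on sigma). Continuous
multipliers are used rather than the discretised-category scheme — same
model family, simpler operators. The birth prior "real-space mean 0.14,
sd 0.9" is read as real-space mean with log-space sd, the convention of
the original software's prior specification; a flag
(`birth_sigma_real_space`) switches to the real-space-sd reading.
The origin carries a uniform prior on [0, `origin_max`] (default 1000
Ma) — the least informative proper choice; it only matters through the
constraint origin > root age.

**Constraints.** Monophyly constraints are enforced by rejection
(-inf prior on violating states), and the starting tree is built to
satisfy them (nested constraint sets are clustered smallest-first).

## MCMC

Metropolis-Hastings over (tree topology, node ages, origin, site ages,
clock rate and sd, branch multipliers, partition rates, FBD rates,
homology states). Operators: scale moves on all positive scalars; a
uniform node-age move; a root stem scaler; a sampled-ancestor-aware
Wilson-Balding move and a wide exchange (both draw their nodes uniformly
and auto-reject invalid pairs, making the node-choice kernel symmetric;
the Wilson-Balding Hastings ratio is the ratio of reattachment-interval
lengths); a reversible-jump leaf/sampled-ancestor toggle whose Jacobian
is the attachment-interval length; the weighted delta exchange on
partition rates; uniform site-age redraws; the homology flip; and joint
variants of the two tree moves that simultaneously redraw the homology
state (for correlated tree/homology space). Moves adjacent to
sampled-ancestor attachments are excluded from the fixed-dimension tree
moves so that only the dedicated jump operator changes the
sampled-ancestor configuration. Scale operators adapt toward an
acceptance rate of 0.234 during burn-in only.

The initial state counts as sample 0 (a chain of L generations sampled
every s yields L/s + 1 samples; the production settings 800M/400k give
2001, and a 10% burn-in of floor(0.1 n) = 200 leaves 1801). Runs are
deterministic per seed. An audit mode recomputes all cached likelihood
components from scratch at a fixed cadence and fails loudly on drift.

**Prior validation mode.** `sample_from_prior=True` switches the
likelihood off; `include_tree_prior=False` additionally drops the FBD
term. Marginals of the scalar parameters then equal their hyper-priors,
which is what the prior-recovery tests assert (with the FBD term
included, birth rate and site ages are legitimately coupled to the tree
and would *not* match their marginal priors — that coupling is the tree
prior doing its job, not an error).

**Diagnostics.** ESS via the autocorrelation-time estimate (arviz),
clamped to the sample count (anti-correlated traces can nominally exceed
n); constant traces report NaN. The 50% majority-rule consensus retains
clades with frequency strictly above the threshold and annotates each
with its frequency and the mean MRCA age over the trees containing it
(tip ages are averaged the same way because site moves shift them
between samples).

## Ancestors and phenetics

At every logged sample a full character-state vector is drawn at the
MRCA of the focal clade (the clade of the first monophyly constraint,
e.g. the apomorphy-defined gnathostomes in the motivating study) from
the exact conditional given tips, tree and parameters, under the
*currently active* homology alignment; the sample records h so
downstream distances use the matching coding. Characters are
conditionally independent given the tree, so per-character conditional
draws at the single focal node form a coherent joint phenotype. The
conditional combines below-partials (pruning) with an above-pass from
the root; draws at unobserved model states of near-constant characters
map to the lowest unused symbols.

Distances use MORD (mismatch count over mutually scored characters
divided by their maximum possible dissimilarity — the Gower coefficient
for unordered data). Polymorphic cells match if their state sets
intersect (uncertainty reading; a strict-mismatch switch exists).
Principal coordinates are classical metric scaling of -0.5 D^2:
all eigenvalues (including negative ones) are reported, coordinates span
the positive axes, and an optional Cailliez correction is available
(none is applied by default). Nearest-taxon queries break ties by taxon
order and flag them. The ordination subsample takes every 20th retained
ancestor and excludes non-modal homology states, reporting counts before
and after exclusion because the order of thinning versus exclusion
changes the subsample size by about one and the right reading is not
determinable.

## Synthetic data

`simulate_matrix` evolves characters down a dated tree under Mk
(uniform root states, closed-form transitions, i.i.d. missingness),
writing a truth record (tree, rates, root states, realised change
counts, masked cells) for recovery tests. `make_fig2_fixture` builds the
two-group didactic setup: groups A, B and C (C1-3), six fixed characters
and a two-character two-state homology block whose coding X scores group
C like A and coding Y like B. The strong variant's fixed characters are
[A-defining, B-defining, four congruent (B+C) characters]: the C stem
carries no defining character, so the extra changes demanded by the
losing coding fall on short branches and the winning state reaches
posterior probability >0.9 (0.92-0.96 across seeds in the design-time
power analysis at 10^5 generations). The moderate variant
[A-, B-, C-defining, three (A+C) characters] yields ~0.75-0.85 for
coding X — the C-defining character keeps the C stem long, which is
exactly what dilutes the discrimination. These fixtures emulate the
canonical illustration's *support pattern*; its literal cell values are
not reproduced.

What the fixtures do not emulate: real matrices are far larger (hundreds
of characters), riddled with inapplicable scores with hierarchical
dependencies, and their homology blocks span many characters with
heterogeneous state counts. Passing tests on the fixtures demonstrate
the machinery (likelihood, operators, homology sampling, reconstruction)
is correct at small scale, not that any particular empirical result is
reproduced; the production configuration for the full-scale analysis is
provided (`configs/full_study.yaml`) but is cluster-scale and is not
executed by the test suite.

## Numerical choices and edge cases

- Pruning partials are rescaled per internal node; log scalers
  accumulate per character.
- Parsimony treats missing/inapplicable as the full symbol alphabet and
  polymorphic cells as their literal state sets; ties in the search are
  broken first-found under the seeded order.
- Distances with zero mutually scored characters are flagged undefined;
  PCO refuses matrices containing them (callers resolve or correct).
- Zero-duration branches (sampled ancestors) yield identity transition
  matrices and contribute nothing to the likelihood.
- Degenerate inputs fail loudly: fewer than 4 taxa for tree search,
  empty state sets, ragged NEXUS rows, out-of-range homology states.

## Problem sizes used in the checks

Desk-scale throughout: oracle equivalence uses <= 6-taxon trees with
exhaustive enumeration (1,000 random instances); homology-recovery runs
use the 9-taxon fixture at 10^5 generations for 20 seeds; prior
recovery uses 6x10^4-generation parameter-only chains; the end-to-end
pipeline check runs a few thousand generations. These sizes were chosen
so the whole validation suite completes on a laptop-class single core
while every statistical check retains enough Monte-Carlo resolution for
its stated tolerance.

## Known limitations

- The search heuristic is random-addition + SPR only (no ratchet or
  TBR); adequate below ~100 taxa but not a TNT replacement.
- No analytic detailed-balance audit against closed-form clade
  probabilities of the constrained SA-FBD prior (no closed form was
  available); operator correctness rests on the prior-recovery,
  validity-audit and cache-audit tests plus end-to-end recovery.
- Consensus annotation implements mean MRCA heights only.
- Ordered characters are honoured in the data model but the likelihood
  treats all characters as unordered (the Mk model as used here).
- Single-machine, single-chain engine: independent runs are separate
  seeded invocations; no Metropolis coupling or checkpointing across
  architectures.
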