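# Methods

This note records the model, the numerical choices, and the design
decisions behind `phylokit`, in enough detail that a reader can judge
what the test suite does and does not demonstrate.

## Likelihood model

Site columns are independent draws from a reversible continuous-time
Markov chain on the state space of the partition's data type (4
nucleotides, 20 amino acids in PAML order ARNDCQEGHILKMFPSTWYV, or 2
binary states).  The rate matrix is `Q_ij = s_ij pi_j` with symmetric
exchangeabilities `s` and stationary frequencies `pi`, diagonal set so
rows sum to zero, rescaled so the expected number of substitutions per
unit branch length is one.  Detailed balance (`pi_i Q_ij = pi_j Q_ji`)
holds by construction, so `diag(sqrt(pi)) Q diag(1/sqrt(pi))` is
symmetric; its eigendecomposition (scipy `eigh`) gives real eigenvalues
and the stable transition-probability form `P(t) = U exp(Lambda t) U^-1`,
clamped to [0, 1] against rounding.

**DNA rate linkage.**  A linkage is a set partition of the six
exchangeability slots (AC, AG, AT, CG, CT, GT), one free rate per class,
with the class containing GT pinned to rate 1 (the conventional GTR
normalisation).  Enumerating all set partitions in restricted-growth
order yields the 203 reversible DNA sub-models; named shortcuts map JC/
F81 to the 1-class and K80/HKY to the transition/transversion 2-class
linkage.

**Amino-acid catalog.**  Eighteen empirical models are registered
(DAYHOFF, DCMUT, JTT, MTREV, WAG, RTREV, CPREV, VT, BLOSUM62, MTMAM, LG,
MTART, MTZOA, PMB, HIVB, HIVW, JTTDCMUT, FLU), storing the published
exchangeabilities and model frequencies; frequencies may be overridden by
empirical counts or ML estimation.  One entry is an exception: the `PMB`
slot holds a synthetic stand-in (the Blosum62 rate model under the PMB
name — both derive from the Blocks database) rather than the published
Probability Matrix from Blocks values.  It is flagged
`SYNTHETIC_MODELS`/`is_synthetic` so callers can warn; every structural
invariant (reversibility, normalisation) holds for it, but analyses that
specifically need the published PMB matrix should not rely on this entry.

**Rate heterogeneity.**  The discrete-Gamma model uses `c` equiprobable
categories (default 4) with mean-of-category rates computed through the
incomplete-gamma identity and renormalised to exact unit mean; means are
preferred over medians because they preserve the unit-mean property
without ad-hoc scaling.  The deviation of all category rates from 1
shrinks as `~1.27/sqrt(alpha)`, which is the attainable "no
heterogeneity" limit the tests assert.  The per-site-rate (PSR) model
hard-assigns each site pattern to one of `c` free rates; after
reassignment the rates are renormalised to weighted mean one and the
branch lengths absorb the factor (`r -> r/m`, `t -> t m`), which keeps
the renormalisation likelihood-neutral so reassignment can only improve
the likelihood.  With several partitions sharing branch lengths the
length rescaling is skipped (it would perturb the other partitions), so
there the renormalisation is only approximately neutral.  PSR cannot be
combined with the ascertainment correction.

## Trees, views, and traversals

Trees are unrooted and bifurcating, stored as triple-linked
half-edge records: an inner node is a cycle of three records, `back`
crosses an edge, and both records of an edge carry the same length and a
stable edge id (ids survive any rearrangement in which the edge
survives, which lets transition-matrix caches be keyed by id + length).
Newick input accepts rooted files (the root is collapsed, child edge
lengths summed) and quoted labels; missing lengths default to 0.1;
lengths are clamped to [1e-8, 100] with a warning.  Output is canonical
(trifurcation at the inner node next to the alphabetically smallest
taxon, children ordered by smallest descendant label, 17 significant
digits) so textual equality is topological identity.

Each inner node owns exactly one CLV per partition, plus an
*orientation*: the record the CLV points along.  A traversal descriptor
toward a virtual-root edge lists, in post-order, the nodes whose
orientation disagrees with the direction the root induces (all `n-2`
nodes for a full traversal).  Any operation that changes what a stored
CLV summarises — a branch-length change, a rearrangement — unsets the
orientations of exactly the nodes whose CLV region contains a touched
edge, found by walking outward from that edge; the next partial
traversal then recomputes precisely the stale set.  Moves (NNI, SPR,
TBR) store enough prior state to undo exactly: topology, lengths, and
edge ids are restored bit-for-bit, and orientation flags are restored up
to the same invalidation rule, so a partial evaluation after
apply-then-undo reproduces the pre-move likelihood without a full
recomputation.

Random topologies are generated by sequential random-edge addition
(uniform over labelled unrooted topologies) with i.i.d. exponential
branch lengths, mean 0.1.  This distribution is a package choice, made
once and recorded here.

## Numerical scaling

After each CLV update, any pattern whose maximum entry falls below
`2^-256` is multiplied by `2^256` and the event is counted; the counts
accumulate up the tree and are added back (times `256 ln 2`) at the
root.  The per-site mode keeps one counter per (node, partition,
pattern); the per-node mode keeps a single accumulated scaler per (node,
partition) — exact when all patterns at a node scale together, with an
automatic local fall-back to per-site counters when only some do, so
correctness never depends on the mode.  The threshold/multiplier pair
(2^-256, 2^256) is chosen so that products of two just-above-threshold
child CLVs stay far from the denormal range.  An unscaled mode exists
for testing only; on a ~700-taxon chain it underflows to an exact zero
site likelihood, which the engine reports as an error naming the pattern
and partition rather than propagating `-inf`.

## Ascertainment correction

For partitions flagged `+ASC` (variable-sites-only data), one dummy
constant pattern per state rides along every CLV computation with weight
zero; at the root their likelihoods sum to `V = Pr(constant)` and each
observed site's log-likelihood gets `-log(1 - V)`.  Input columns that
*could* be constant (some state compatible with every tip, ambiguity
included) are rejected, matching the model's definition.  If `V`
approaches 1 (within 1e-6 — effectively a star tree with near-zero
branches) the correction is meaningless and a degenerate-regime error is
raised; the 1e-6 margin exists because branch clamping at 1e-8 keeps `V`
strictly below 1 even in the limit the error is meant to catch.

## Optimisation

With the virtual root on the edge being optimised, the site likelihood is
`L_s(t) = sum_j w_j sum_k a_sjk exp(lambda_k r_j t)` where the sumtable
`a` is built once from the two endpoint CLVs transformed into the
eigenbasis.  Newton-Raphson iterates on the analytic first/second
derivatives of log L (ascertainment term included, since `V(t)` has the
same exponential-mixture form); iterates that leave [1e-8, 100] or meet
non-negative curvature fall back to bounded Brent.  Brent searches over
positive quantities (branch lengths, alpha) run in log space: a linear
bounded search over [1e-8, 100] starts its golden-section probes on the
flat large-value plateau and converges there, which is a real failure
mode, not a hypothetical.  A candidate is accepted only if it does not
decrease the objective by more than 1e-9, so every optimiser is
monotone.

The round-robin driver optimises branches (smoothing passes over edges
in depth-first order, so consecutive roots are adjacent and partial
traversals short), then per partition: linked rates (coordinate-wise
Brent in log space, reference class fixed), Gamma shape or a PSR round
(rate Brent + reassignment), and ML frequencies (coordinate-wise Brent
in log-ratio coordinates with a 1e-6 floor).  Defaults: logL tolerance
0.1, Newton tolerance 1e-8 (max 32 iterations), Brent tolerance 1e-6,
alpha in [0.02, 100], rates in [1e-4, 1e4], at most 32 smoothing passes
and 50 rounds.  These are package choices; they are not taken from any
external source.  Branch lengths are linked across partitions (one
length per edge).  Model-parameter changes are detected by versioning
(substitution-model version + current category rates) and force a full
traversal and a transition-matrix cache flush, mirroring the CLV
validity rule.

## Parsimony and search

Fitch parsimony runs on per-pattern state-set bitmasks (ambiguity codes
set several bits, gaps all bits); the score is root-invariant.  Patterns
that cost the same on every topology — all tips unambiguous and at most
one state occurring more than once — are scored once as a constant
offset, so stepwise addition and move ranking only recurse over
parsimony-informative patterns; reported scores always include the
offset.  The randomized stepwise-addition starting tree shuffles taxa by
seed and inserts each on the edge minimising the Fitch score, ties going
to the lowest edge id, so a seed fully determines the tree.

The hill-climbing search enumerates NNI (both alternatives per internal
edge) or SPR candidates (regraft targets within an edge-step radius,
default 10, of the pruning point; the gap edge is excluded since it
recreates the topology), ranks them by the Fitch score of the rearranged
tree, evaluates the best 25% (at least 5) by likelihood using partial
traversals plus local branch-length optimisation of the three edges at
the junction, accepts the best strictly improving move, then smooths all
branches.  TBR moves (bisect an internal edge, reconnect one target per
component) are provided with the same exact-undo contract and radius
semantics; the search driver itself uses NNI/SPR.  Edge-step distance
from the pruning point is the radius definition used throughout.

## Simulator

The simulator draws the root state from `pi`, a category per site (equal
weights for Gamma; recorded for introspection), and children by
row-sampling `P(r_j t)` down each branch — exactly the process the
likelihood assumes, with states only (no indels; gaps can be masked
afterwards).  A single seed drives tree, parameters and sequences
through independent spawned streams, so fixtures are stable under
partial re-runs.  What passing recovery tests show is therefore internal
consistency: estimates converge to generating values *when the model is
correctly specified*.  They do not show robustness to model violation,
alignment error, selection, or non-reversible processes — none of which
the generator emulates.

## Problem sizes in the tests

Unit tests use 4-10 taxa and tens of sites, where exhaustive
enumeration over all inner-node state assignments (the likelihood
oracle) and Sankoff dynamic programming (the parsimony oracle) are
feasible; the oracle-equivalence suite runs 500 such instances at 1e-10
agreement.  Recovery checks fit 12-taxon, 20,000-site simulations (five
seeds; Gamma shape 0.5 recovered within [0.4, 0.6], a planted AG rate 4
within [3.2, 4.8]); search checks recover 8-taxon generating topologies
from random starts at 10,000 sites (five seeds).  The deep-chain scaling
demonstration uses a 700-taxon caterpillar, comfortably past the depth
where unscaled products underflow.  These sizes were chosen to make the
Monte-Carlo bands tight enough to be meaningful while keeping the default
run of the whole suite in the minutes range on one core.

## Known limitations

- Branch lengths are linked across partitions; per-partition lengths and
  among-partition rate multipliers are out of scope, as are
  time-heterogeneous models, codon models, and an invariant-sites
  category.
- Joint (max-path) ancestral reconstruction is not implemented; only
  marginal posteriors are.
- The PSR model's likelihood is a profile (hard assignment), so its
  optimum is not comparable across different category counts.
- The search is a single-path hill climb; it inherits the usual local
  optima of greedy tree search and is not a replacement for multi-start
  or bootstrap workflows.
- Single precision, vectorised kernels, and shared-memory/MPI
  parallelism are out of scope; `--threads` is accepted for interface
  compatibility and ignored beyond 1.
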