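# Methods

This note records the model, the numerical procedures, the choices made
where the design was genuinely open, and what the test suite does and
does not establish.

## The circuit model

A circuit is a directed graph of transcription-factor regulations, each
labeled activation or inhibition.  Protein levels are dimensionless
concentrations obeying

    dX_i/dt = G_i · Π_{j→i} F_ji(X_j) − k_i · X_i,

with one multiplicative factor per incoming link (regulators are assumed
independent; competitive or cooperative multivalent schemes are out of
scope).  The single-link response is the shifted Hill function

    H_S(X; X0, n, λ) = λ + (1 − λ) / (1 + (X/X0)^n),

a Hill response rescaled to the dynamic range between 1 (regulator
absent) and λ (regulator saturating).

**Activation convention.**  `G_i` is the maximum production rate,
defined as the rate with all activators (and no inhibitor) bound.  An
activating factor must therefore saturate at 1, not at λ: we use
`F = H_S/λ ∈ [1/λ, 1]` for activation and `F = H_S ∈ [λ, 1]` for
inhibition.  Both are implemented as one affine form
`F = a + b/(1 + (X/X0)^n)` with per-edge constants, which is also what
the compiled integrator consumes.  With the unnormalized alternative
(`F = H_S ∈ [1, λ]`), an activated gene's level scales with λ·G/k, the
ensemble's expression distributions spread over ~4 extra decades, and
the coupled-toggle-switch ensembles lose the cluster structure described
below; the normalized convention is also the only one consistent with
the stated meaning of G.

## Randomization and the half-functional rule

Parameters are drawn independently per model:

| parameter | law | default range | why |
|---|---|---|---|
| production G | uniform | [1, 100] | two decades of expression scale |
| degradation k | uniform | [0.1, 1] | protein lifetimes 1–10 time units |
| Hill n | uniform integer | {1..6} | realistic binding cooperativity |
| fold change λ (act.) | uniform | [1, 100] | up to 100-fold response |
| fold change λ (inh.) | 1/U[1, 100] | [0.01, 1] | reciprocal law, so inhibition strength mirrors activation |
| threshold X0 | uniform | [0.02·M, 1.98·M] | half-functional rule (below) |

A link is *functional* in a model when the regulator's level crosses the
threshold (equivalently, its shifted-Hill factor deviates from 1 by more
than half its maximum deviation).  The half-functional rule asks that
each link be functional in roughly half the models.  Since the threshold
is drawn uniformly from an interval symmetric about M, the rule holds
exactly when M is the median of the regulator's level distribution.

That distribution is itself shaped by regulation, so the per-gene
medians are estimated by a self-consistent Monte Carlo (default 10,000
samples, 10 iterations, seeded): every gene starts with level samples
G/k; each iteration rebuilds each gene's sample as G/k times, per
incoming link, a shifted-Hill factor evaluated at a regulator level
resampled (with permutation) from the previous iteration against a
threshold drawn around the regulator's current median, with n and λ
freshly drawn.  Iteration matters: evaluating the factor at a random
level against a random threshold makes it effectively bimodal (≈λ or
≈1, the link is either engaged or not), which is what actual ensembles
do, whereas a uniformly random occupancy (a factor ~ U[λ, 1]) biases
medians upward and roughly halves the multistability of coupled
circuits.  For an unregulated gene the estimate reduces to the median
of G/k (≈ 92 for the default ranges).  Ranges are rounded to 6
significant digits when built, so `circuit.prs` round-trips exactly.

## Steady-state enumeration

Each model is integrated from `num_init_conds` initial conditions drawn
log-uniformly between the extreme steady-level bounds per gene
(G/k times the product of minimal incoming factors up to G/k itself).
The solver is fixed-step Euler (dt = 0.01) or classical Runge–Kutta
(dt = 0.1, the default); time is discretized in windows of 50 units, and
a trajectory is converged when its largest per-gene |Δ log2 level| over
one window falls below 10⁻³.  Runs exhausting 200 windows — limit
cycles, or divergent overshoots, which are clipped into [0, 10¹⁵] rather
than allowed to produce NaNs — are counted as non-converged and
excluded.  Levels are floored at 10⁻¹⁰ before any log transform.

Distinct stable states are selected by a greedy first-come scan:
a converged endpoint is kept iff its Euclidean distance in log2 space to
every previously kept state exceeds 1.0.  The tolerance sits orders of
magnitude above numerical scatter (≤ ~10⁻² log2 after convergence) and
well below genuine attractor separations in toggle-switch circuits
(several log2 units); measured state counts are insensitive to the
tolerance across 0.03–1.0.

The integrator is a numba-compiled kernel that advances all starts of
one model simultaneously (genes × trajectories layout, SIMD-friendly
inner loops, integer Hill powers unrolled) and compacts converged
trajectories out of the active set each window.  Endpoints were
cross-checked against scipy's adaptive `solve_ivp` on the same
right-hand side.

Per-model random streams are derived as `default_rng([master_seed,
stream, model_index])`, so results are independent of execution order,
and a perturbed ensemble run under the same master seed re-draws
identical parameters except for the perturbed entries (degenerate
ranges still consume one draw to keep the streams aligned).

## Perturbations

Knockout pins a gene's production range to [0, 0] (its level is exactly
0; outgoing regulations sit at F(0) = 1 for inhibition targets of the
shifted-Hill form — i.e. effectively removed); over-expression and
knockdown scale the production range by a factor (defaults 10 and 0.1);
link removal deletes the edge and its three parameters.  Threshold
ranges are deliberately *not* re-estimated, implementing the perturbation
as a treatment applied to the same ensemble (paired comparison).

## Ensemble analysis

Pooled stable states (log2 levels) are z-scored per gene; a zero-variance
gene (e.g. a knockout) is an error — knockout data are normalized with
the reference statistics instead, which pins the gene at its fixed
"zero expression" z-coordinate, and are projected onto the reference
principal components after that substitution.  PCA signs follow the
convention that each component's largest-|loading| entry is positive.

Gene states are major clusters of average-linkage hierarchical
clustering on Euclidean distances.  The number of major clusters
(fraction ≥ cutoff, default 5%) is read off by persistence: the tree is
cut into k clusters for every k = 2..⌈1/cutoff⌉ and the major count
observed for the most granularities wins, ties toward fewer clusters;
labels come from the coarsest cut realizing it.  A single "best" cut is
ill-posed here — maximizing the count over all heights systematically
over-reports by promoting merged rare patterns past the cutoff — while
the persistence count is stable across seeds and matches the count of
discrete expression patterns (sign of A_i − B_i per motif) exceeding the
cutoff.  Cuts into more than 1/cutoff clusters cannot be dominated by
major clusters, which bounds the search without a tuning knob.

Convergence diagnostics compare replicate runs by the Bhattacharyya
distance `D_B(p,q) = −ln Σ√(p q)` (symmetric, 0 iff p = q; disjoint
supports are capped at 700 ≈ −ln of the smallest positive double; the
Kullback–Leibler divergence is available as an alternative metric).  The
dissimilarity at a setting is the mean pairwise D_B between its
replicates and the reference replicates at the largest setting (10 each
by default); for state counts the distributions are over the number of
stable states per model, for expressions they are per-gene histograms of
log2 levels on 50 equal-width bins spanning the pooled reference range
(values outside are clipped into the edge bins so supports always
match).  The minimal sufficient setting is the first grid point whose
step to the next decreases the dissimilarity by less than a threshold
(default 5·10⁻⁴); a never-converging grid returns "not reached" (None).

Parameter differentiation between two gene states compares, per
parameter, the models contributing states to each cluster
(Mann–Whitney U, standardized mean difference, Benjamini–Hochberg
adjustment across parameters); groups under 5 models are flagged.

## Coupled-toggle-switch generators

`generate_cts("I", n)` builds n mutual-inhibition motifs (A_i ⊣ B_i,
B_i ⊣ A_i) coupled by unidirectional activations running in *opposite*
directions along the two sides: A_i → A_{i+1} and B_{i+1} → B_i.  The
anti-parallel wiring is what makes the two chain roots (A1, B_n) the
most and least critical genes in an asymmetric, mirrored order, and its
robust expression patterns are the n+1 "domain wall" states (A-dominant
prefix, B-dominant suffix) plus the rarer off-cascade patterns.  With
parallel chains the circuit would be exactly symmetric under A↔B
relabeling and gene importance could not be ordered oppositely on the
two sides.  `generate_cts("II", n)` uses mutual activations between
consecutive same-side genes.

## What the tests establish

The suite verifies closed-form identities of the building blocks,
cross-checks the integrator against an independent adaptive integrator,
validates the half-functional rule on a single-link circuit (functional
fraction 0.5 ± 0.1 over 5000 models), and reproduces ensemble-level
behavior of CTS-I5 at desk scale (500–2000 models × 200 starts): mean
stable states per model in [2.2, 2.7], maximum multistability ≥ 5, six
major gene states across seeds, convergence-diagnostic decrease with
ensemble size, and the A1-vs-A5 knockout asymmetry.  Full-scale ensembles
(10,000 models × 1000 starts) are not run in CI; nothing here validates
the generators against experimental expression data — the synthetic
ensembles state what the model implies about a topology, not what cells
do.

## Known limitations

Only stable fixed points are characterized; limit cycles are merely
counted as non-converged starts.  Only transcription-factor regulation
is modeled.  The multivalent product rule ignores competition for
binding sites.  Threshold self-consistency is a median-level
approximation, not a full fixed-point of the ensemble distribution.
Fixed-step integration can misassign basins for stiff models (attractor
identity is unaffected: fixed points of the stepping map coincide with
those of the ODE, and states are polished by the convergence criterion).
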