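# Methods

This note documents the models, numerical choices and open design
decisions behind `iecflow`, and what the synthetic-data tests do and do not
establish about real data.

## Conventions and data model

All square matrices follow one orientation: **rows index targets, columns
index sources**, so `W[i, j]` is the influence of region *j* on region *i*
and a region's weighted in-degree is its row sum. Much of the
graphical-model literature uses the transpose; every estimator here emits
the row=target convention and `register_external_ec(transposed=True)`
converts files written the other way. Region order is taken from file
order and every cross-object operation demands identical ordered label
sequences — silent reindexing is a misalignment bug waiting to happen, so
it is refused outright.

EC and ground-truth matrices carry a structural zero diagonal. SLN-like
(laminar tracer) matrices may contain NaN for unmeasured pairs; those
entries are skipped, never imputed.

## Effective-connectivity estimators

**VAR (ridge).** Lag-1 autoregression x(t+1) = A x(t) + c, solved in
closed form by the normal equations with an L2 penalty λ on the diagonal
(default λ = 0.01, tunable; `gp_maximize` can drive a λ grid search).
Predictors and responses are centred by their own means, which is exactly
equivalent to fitting the intercept and — unlike centring by one global
mean — preserves exact identification on noise-free data. Signs are
preserved: the signed coefficients are what the downstream
hierarchy/flow analyses consume. Lag orders above 1 are representable in
configuration but deliberately untested territory; at typical fMRI
sampling rates higher lags add parameters faster than information.

**Pairwise conditional Granger (MVGC).** For each ordered pair, an F test
of the full model (target's own lag + source lag) against the restricted
model (own lag only); the edge weight is the F statistic, zeroed at
p ≥ α. Collinear designs (e.g. duplicated signals) fall back to
minimum-norm least squares, yield no likelihood improvement and therefore
no edge — degenerate inputs produce empty rows rather than exceptions.
This estimator is implemented for completeness but flagged as excluded
from integration defaults: its estimates are the least robust of the
family to haemodynamic confounds.

**DirectLiNGAM.** Causal order by repeatedly extracting the most exogenous
variable; exogeneity is scored with the entropy-based pairwise likelihood
ratio (maximum-entropy approximation of differential entropy with the
log-cosh and Gaussian-derivative moments). A true root has no positive
entries in its row of the pairwise matrix, so the root score accumulates
squared positive parts. After ordering, connection coefficients come from
regressing each variable on its predecessors on the original scale.
Identifiability requires non-Gaussian disturbances; on jointly Gaussian
data direction assignment degrades to chance, and a test asserts exactly
that rather than hiding it.

**Skewness-orientation graph.** Adjacency from partial correlation given
all remaining regions (|pcorr| above a threshold *and* significant by the
Fisher z test), orientation by the conditional-correlation rule: compare
corr(x, y | x > 0) with corr(x, y | y > 0); the conditioning variable of
the larger is the source. Negatively skewed regions are flipped to
positive skew before orientation, so the rule's positive-skew premise is
met regardless of sign conventions in the input. The full constraint-based
adjacency search of the original two-step algorithm is replaced by
thresholded partial correlation for tractability; fidelity to the original
tool is explicitly not claimed, and externally computed matrices can be
injected instead.

**Patel's τ.** Each region is mapped to a graded activation level: a
linear ramp from its q-quantile (default 0.75) to its 99th percentile,
clipped to [0, 1]. Joint activation is the mean elementwise minimum
(graded conjunction), and

    τ = (P(x|y) − P(y|x)) / max(P(x|y), P(y|x)) ∈ [−1, 1],

with τ > 0 stored as an X → Y edge. A hard cut at each region's own
quantile would force identical marginal activation probabilities and make
the asymmetry identically zero — the graded formulation is what gives the
statistic content. τ's premise is that *sources activate more broadly than
their targets*: in linear models whose source is right-skewed the premise
fails and τ anti-orients, which is a property of the measure, not a bug;
the shared orientation fixture therefore uses a left-skewed source (see
below).

**Subsampling ensemble.** Graphical estimators (LiNGAM, skew, and any
registered custom estimator) can be rerun on random timepoint subsamples
of size ⌈T/2⌉ drawn without replacement (default 100 draws), averaging
signed edge indicators into weights in [−1, 1] that read as signed edge
frequencies. Random subsampling destroys temporal order, which is
acceptable exactly because these estimators treat samples as i.i.d.;
dynamical estimators always see the full ordered series and are refused by
the ensemble. Up to 20% of subsample fits may fail (singular draws) before
the ensemble aborts with diagnostics.

## Integration

Estimates are standardized by the SD of their off-diagonal entries, with
no centring: raw estimator scales differ by orders of magnitude (F
statistics vs regression coefficients vs bounded τ), and without
harmonization the weights β would be uninterpretable, while centring would
destroy the sign/zero semantics the profiling stage needs. β is bounded to
[0, 1]: a negative weight would silently invert an estimator's
excitatory/suppressive semantics.

The objective is either the Pearson correlation between the integrated
matrix and a target (off-diagonal entries only; NaN target entries
skipped; an optional log10 transform of positive target entries is exposed
because tracer-style weights are heavy-tailed) or the composite simulation
fit described below. Optimization uses a Gaussian-process surrogate
(Matérn 5/2, expected-improvement acquisition over random candidate sets)
over the box; the contract — verified by test — is a best value within 1%
of a 10,000-point random search on 3-dimensional problems. The optimizer
runs `n_restarts` times (default 50) with distinct seeds and reports the
per-restart optima plus their elementwise median; the median, not the
mean, is also how training-session βs are aggregated before being applied
to held-out sessions in `crossval_integration`.

For the composite-fit objective each candidate β is scored with a fixed
simulation seed, so the surrogate sees a deterministic function (variance
reduction); a final fit may then be re-estimated on fresh seeds.

## Hopf (Stuart-Landau) simulator

Each region is a Stuart-Landau oscillator near its bifurcation:
a = −0.01 (stable focus excited by noise), intrinsic frequency ω per
region (defaults in the 0.04–0.07 Hz band typical of resting-state BOLD,
or estimated from data by Welch periodogram peak), diffusive coupling
G·Σⱼ C_ij (x_j − x_i), additive Gaussian noise of amplitude ε = 0.02
scaled by √dt, Euler–Maruyama integration at dt = 0.1.

Two sign conventions in circulation differ on the coupling difference
(x_j − x_i vs x_i − x_j) and the rotation term; this implementation
defaults to the diffusive (x_j − x_i) coupling and the standard normal
form rotation (−ωy, +ωx), with both switchable (`coupling_sign`,
`rotation_sign`) for sensitivity checks. Independent noise streams drive
the x and y components.

Model time is mapped to seconds with dt = 0.1 s, and output is decimated
to a sampling interval of 0.72 s by default (a typical fMRI repetition
time; the stride is rounded to an integer number of integration steps, so
the effective interval is 0.7 s and is recorded on the output object).
Burn-in defaults to 20% of all integrated steps and is discarded before
decimation. With ε = 0 and G = 0 the integrator reproduces the analytic
radius dynamics to first order in dt (halving dt halves the error — a
test pins this), and the limit-cycle radius √a is recovered to 1e-3.
Trajectories are bit-reproducible under a fixed seed. When a candidate EC
drives the simulation it is SD-standardized first and G defaults to 1.

## Validation metrics

Static FC is the region-by-region Pearson matrix. FCD uses sliding
windows (default 30 samples, step 3 — conventional values; the windowing
is configurable and tests that need integer-cycle windows say so
explicitly): each window's FC is vectorized and the FCD matrix is the
correlation between window pairs, whose upper triangle forms the FCD
distribution. The composite score is `fit = r − KS` with KS the
two-sample sup-distance between pooled FCD distributions; a self-fit is
exactly 1 − 0. Note KS on finite FCD samples is quantized at ~1/(number
of window pairs), which bounds how exactly affine invariance can hold.

The time-delay projection finds, per region pair, the extremum of the
lagged cross-covariance within ±max_lag samples (default 10), refines it
by parabolic interpolation, censors extrema pinned at the window edge,
and reports each region's row mean (positive = the region tends to lead).
The pairwise lag matrix is antisymmetric by construction.

F1 directionality binarizes the estimate by keeping its top `sparsity`
fraction of |weights| (15% and 30% are the conventional operating points)
and the truth by its nonzero entries — tract-tracing semantics, where an
absent projection is a structural zero — and scores directed edge labels.

## Synthetic networks

The SC generator emulates three hallmarks of empirical structural
connectomes, chosen a priori as the features that matter for
topology-preservation statistics:

1. **Spatial embedding** — regions live in a unit square and connection
   scores decay with distance (length scale 0.25), the exponential
   distance rule in miniature;
2. **Hubs** — each region draws a log-normal attractiveness (sd = 1.0)
   multiplying the pair score, producing the broad degree distributions of
   rich-club connectomes;
3. **Heavy-tailed weights** — log-normal with σ = 2 by default (spanning
   roughly four orders of magnitude, as streamline-count and tracer
   weight distributions do), or Pareto with a chosen tail index; weights
   are rank-matched to the connection score, so short hub-hub links are
   strongest. The weight multiset is exactly the requested distribution,
   which is what makes the tail-index recovery test a clean
   generator/estimator consistency check.

A maximum-score spanning tree guarantees connectedness at the exact
requested edge count. These choices matter: binary degree sequences are
*exactly* invariant under the directed rewiring below, so the pre/post
correlation of weighted clustering is driven by degree- and
weight-heterogeneity; a homogeneous random graph would understate it
badly and misrepresent what rewiring does to an empirical connectome.

**Directed rewiring** performs the standard degree-preserving swap
(a→b, c→d ⇒ a→d, c→b; weights travel with their source stub), rejecting
self-loops and duplicates, until the requested fraction of edges (default
20%) has been reassigned — each accepted swap reassigns two edges. Weak
connectedness is checked every 10 accepted swaps with batch rollback
(per-swap checking would be O(E) each). Out-strengths are exactly
preserved by construction; in-strengths and clustering are preserved only
statistically, which is precisely what the acceptance quantities measure.
The rewiring operates on weighted edges (the weights are needed downstream
as Hopf couplings); rewiring a binarized copy first would be the
alternative reading.

**Planted hierarchies** place edge weights β_i − β_j + noise on a random
connected skeleton (both orientations included; full density = all ordered
pairs), with the planted levels attached as metadata for recovery tests.

## Hierarchy and signal flow

After retaining the top 15% of |weights| (ties at the cutoff are all
kept — determinism beats hitting the nominal count exactly; the retained
count is logged), each retained edge j → i contributes the linear
equation EC_ij = β_i − β_j with an identity link. The p × n incidence
system is solved by minimum-norm least squares. Levels are identifiable
only up to a constant per connected component of the retained graph, so
each component is anchored to mean zero and the component labels are
reported; levels are never comparable across components and regions
outside any retained edge get NaN. Useful exact properties (all tested):
adding a constant to planted levels leaves estimates unchanged, scaling
scales them, and transposing the input negates them. Signed edges
genuinely matter: flipping the sign of a region's incoming weights moves
the solution, which is the operational content of profiling positive and
negative connections separately.

For flow analysis the EC is rescaled to `EC/(λmax + c) − I` with c = 1,
where λmax is the **largest real part** among eigenvalues — for signed
matrices this is the only reading under which the result is provably
Hurwitz-stable (every eigenvalue's real part becomes negative); a
spectral-radius variant is available in configuration. Signal flow is the
time-integral of the impulse response of x′ = EC·x: analytically
−EC⁻¹x(0), or A⁻¹(e^{AT} − I)x(0) for finite horizons (the two agree in
the long-horizon limit and against dense ODE integration to 1e-5 — both
tested). A seeded module splits unit mass uniformly over its regions;
per-region seeding is also available. Module-level flows keep positive
and negative streams separate, because their scientific readings differ
(amplifying vs suppressive influence).

State contrasts z-score the per-module outflow differences across modules
— separately per signed stream, since the positive and negative streams
are reported separately — and flag |z| ≥ 1.645 (one-tailed level) and
|z| ≥ 1.96 (two-tailed level). With sample z-scoring at ~27 modules the
empirical flag rate under a Gaussian null sits slightly below the nominal
rate; the calibration test allows for that.

## Connectome profiling

Weighted in-/out-strengths are plain row/column sums. The
positive/negative ratio formulas use the matrix dimension N as the
denominator — the indicator-sum formulation reproduced exactly, even
though N−1 (excluding the structural-zero diagonal) would be the more
natural choice; fidelity to the published formula wins and a hand-worked
toy pins the behaviour. The tail index is a Hill estimator over the top
10% order statistics of positive weights (the estimator choice is the
package's; values below 2 flag heavy tails). FF/FB profiling thresholds
an SLN-like matrix at 0.5 (feedforward above, feedback below, exact ties
dropped, NaN skipped) and reports the signed-EC proportions per class.

## What the synthetic tests do and do not show

The planted-network studies establish *internal validity*: estimators
recover what the generative model plants, integration does not lose to
its best ingredient out of sample, the hierarchy solver inverts its own
forward model under noise, and the simulator/metric stack is
self-consistent. They do not establish that BOLD data satisfy any
estimator's assumptions: haemodynamic convolution, measurement noise
spectra, spatial leakage and non-stationarity are all absent from the
generator. Orientation fixtures are deliberately favourable — e.g. the
shared two-node fixture uses a left-skewed source because Patel's τ
identifies sources by activation prevalence and anti-orients right-skewed
linear sources; on near-Gaussian oscillator output the graphical
estimators' orientation signal is weak, which is visible in the planted
whole-network study's modest absolute correlations. The integration
property claimed (and tested) is relative, not absolute.

## Problem sizes and seeds

The end-to-end integration study runs 10 training + 10 test sessions of
100 regions and 1200 timepoints with 5 optimizer restarts per training
session; the rewiring study uses 10 realizations of 100 regions; estimator
orientation uses 100 replicates at n = 5000. Every stochastic operation
takes an explicit seed, and fixed seeds give bit-identical results on a
fixed library stack.
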