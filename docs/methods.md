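# Methods

`pdpmanifold` implements two connected pieces of machinery: a balanced
spiking network model of zebrafish pDp (the teleost homolog of piriform
cortex) that stores odor memories as E/I assemblies, and the
population-geometry analytics — distance matrices and manifold capacity —
used to quantify how such memories reshape odor representations.  This
note records the models, the parameter choices, and the numerical
decisions, in enough detail to reproduce or challenge them.

## 1. Neural manifolds

A *manifold* is the point cloud of population activity vectors evoked by
one odor, pooled over trials and time bins inside an analysis window.  For
imaging-like data at 7.5 Hz with 3 trials, the standard window is 24
frames starting 1 s after response onset, giving 72 points per manifold.
(3 s at 7.5 Hz would give 22.5 frames; the 24-frame reading is adopted so
the point count comes out at the canonical 72.)  For simulated spiking
data the window is 2 s of 100 ms bins over 4 trials (80 points), pooling
all excitatory neurons.

## 2. Distances between manifolds

* **dE** — Euclidean distance between manifold centers (Hz).  Symmetric;
  sensitive to both the angle and the amplitude of the mean patterns.
* **dM** — mean Mahalanobis distance from each point of a *sample*
  manifold X to the distribution of a *reference* manifold Y:
  `mean_x sqrt((x-mu_Y)' S_Y^{-1} (x-mu_Y))` with `S_Y` the unbiased
  sample covariance of Y.  Directional (rows of a matrix are samples,
  columns references); dimensionless; invariant under joint invertible
  affine maps and under uniform scaling of all data, whereas dE scales
  linearly — the pair therefore separates displacement from reshaping.

The square root sits inside the per-point term (the standard definition);
a config flag could flip this but the default follows the standard form.

Because covariance inversion needs more points than dimensions, matrices
are computed on random subsets of 70 neurons, repeated 50 times (the same
subset for all odor pairs within a repeat, so matrices stay comparable),
and averaged.  Neurons with zero variance across all manifolds are
excluded from the subsampling pool: they carry no distance information
and make `S_Y` exactly singular.  A ridge `delta * mean(diag(S_Y)) * I`
conditions the inverse; the default `delta = 1e-6` suits dense
imaging-like data (72 points vs 70 dimensions is barely invertible), while
sparse spiking data at 80 points vs 70 dimensions uses `delta = 1e-2` in
the worked analyses — Poisson count covariances estimated at that ratio
are otherwise dominated by their smallest eigenvalues.  Diagonal dM
entries use the full distribution without leave-one-out and are therefore
biased low; they are reported but never interpreted.

The label-shuffle null pools the two point clouds, re-splits them into two
equal halves at random (an odd pooled count drops one point), and repeats
50 times.  Shuffling destroys all between-manifold structure while
preserving the marginal point distribution.

## 3. Manifold capacity

Capacity `alpha` measures how many manifolds per ambient dimension remain
linearly separable under random binary labels — the degree of
"untangledness" of a representation.  It is computed as the inverse of a
Gaussian average of a projection quadratic program: for `T ~ N(0, I_N)`,

```
F(T) = min_V ||V - T||^2   subject to   y_mu * V.x >= 0
                                        for every point x of manifold mu,
alpha = ( E_{T,y}[F(T)] / P )^(-1) .
```

Manifolds enter as their finite point sets (convex-hull representation).
Preprocessing subtracts the grand mean of the manifold centers (global
centering) and appends a constant bias coordinate so the separating
hyperplane can carry an offset; both are on by default.

**Solving the QP.**  The feasible set is a polyhedral cone, so the
minimizer is the Euclidean projection of T onto that cone.  By Moreau
decomposition the projection reduces to nonnegative least squares over
the polar cone spanned by the signed points; this NNLS problem is solved
exactly with the Lawson–Hanson algorithm (`scipy.optimize.nnls`).  Since
F(T) depends on T only through its component in the span of the data
points, the Gaussian average is evaluated in that subspace — an exact
reformulation that reduces a 700-dimensional draw to at most
(number of points) dimensions.  Constraint rows are normalized to unit
length for conditioning (the cone, and hence F, is unchanged).

**Label average.**  For P = 2 the two non-trivial dichotomies are related
by the V -> -V symmetry of the Gaussian measure, so the fixed labeling
(+1, -1) equals their average.  For P > 2 a uniform random dichotomy is
drawn per Gaussian sample.

**Monte Carlo.**  Default 200 Gaussian samples; the standard error of
`alpha` comes from batch means (10 batches) through the delta method.
Subsampling follows the source protocol: 700 neurons and 140 patterns per
manifold for imaging-like data (patterns must stay below neurons so a
separator exists), repeated 50 times per odor pair and averaged; pattern
subsampling is uniform over (trial, time-bin) points without replacement.

**Anchor points and effective measures.**  The dual NNLS weights identify,
per manifold and per draw, the convex combination of points active in the
program — the anchor point.  The five effective geometric measures are
computed from the anchor distribution with the following
operationalisation (the exact closed forms of the originating theory are
not restated here; the implementation is pinned by limit cases instead):

* *radius* — root-mean-square anchor displacement from the manifold
  center, normalized by the center length (centered frame);
* *dimension* — participation ratio of the anchor-displacement
  second-moment spectrum;
* *center alignment* — cosine similarity of the raw (pre-centering)
  manifold centers.  With P = 2 the centered centers are exactly
  antiparallel, so alignment is only meaningful on the raw centers;
* *axes alignment* — mean absolute cosine between the two manifolds'
  anchor displacements at the same draw;
* *center-axes alignment* — mean absolute cosine between one manifold's
  anchor displacement and the other's raw center, symmetrized.

Pinned limits: point manifolds give radius 0 and dimension 0; identical
centers give center alignment 1; orthogonal-center isotropic d-balls of
radius r recover radius ~ r, dimension ~ d, center alignment ~ 0; point
manifolds in general position give `alpha ~ 2` (Cover's counting
theorem); pooling two manifolds of M patterns each and relabeling at
random drives `alpha` to the Cover limit `2/M` (for M = 140:
0.0143, printed as 0.014).

## 4. Spiking network model of pDp

1000 excitatory (E) and 250 inhibitory (I) adaptive leaky
integrate-and-fire neurons with conductance synapses, driven by 1500
olfactory-bulb (OB) mitral cells modeled as inhomogeneous Poisson sources
(6 Hz baseline).  Membrane dynamics, adaptation (E cells only) and
exponentially decaying conductances follow the standard conductance-based
LIF formulation; integration is exponential-Euler for conductance and
adaptation decay and forward Euler for the membrane, dt = 0.1 ms (halving
dt changes population rates by < 2%, which is the guard test for the
scheme).

Connectivity is Bernoulli per ordered pair with probability `p_XY` and
uniform weight `w_XY`; the four published weight settings (A–D, in pS)
ship as presets.  The remaining parameters are **package defaults, chosen
once and frozen** (the source model's values are external to this
package); they were calibrated so that the preset-A network is nearly
silent at rest, responds to odor input at ~0.5–1 Hz population rate with
tuned cells at 3–5 Hz, is inhibition-stabilized, and decays within
~100 ms of input offset (no persistent activity):

| parameter | E | I |
|---|---|---|
| C (pF) | 120 | 100 |
| g_rest (nS) | 2.5 | 4 |
| E_rest, V_reset (mV) | −66 | −66 |
| V_th (mV) | −50 | −52 |
| refractory (ms) | 5 | 2 |

Adaptation: a = 0.5 nS, b = 10 pA, tau_ad = 200 ms.  Reversals: 0 mV
(exc), −70 mV (inh).  Synaptic time constants: 20 ms (recurrent exc),
10 ms (inh), 10 ms (OB).  Connection probabilities: E→E 0.05, I→E 0.08,
OB→E 0.04, E→I 0.06, OB→I 0.10, I→I 0.10.  Odor input raises 150 mitral
cells by 30 Hz and suppresses 75 by 6 Hz (to 0 Hz), with shared up/down
cells across odors realizing the target pattern correlations (see §6).

**E/I assemblies.**  A memory for an odor is stored structurally: the 100
E neurons with the most inputs from that odor's up-modulated mitral cells
form the E-assembly (ties resolve to the lower index), and the 25 I
neurons with the most inputs from the E-assembly form the I-assembly.
Connection counts within the E-assembly and between the E- and I-assembly
(both directions) are multiplied by the enhancement factor (default 4;
larger factors are inhibition-dominated at these densities and *reduce*
assembly rates).  To keep the total count per projection exactly
constant, an equal number of edges from non-assembly neurons onto
assembly neurons is removed at random — the incoming-boundary reading of
"between non-assembly and assembly neurons", which also conserves each
assembly neuron's in-degree and avoids a global activity drop that would
otherwise confound every distance comparison.

In this regime the assembly produces a modest (~+15%) amplification of
assembly-neuron rates for the stored odor with essentially unchanged
non-assembly rates, the balanced-network phenotype.  Consequences at the
manifold level, measured against a matched no-assembly network: dE from
learned odors to others increases more than the background; capacity
rises with lower effective radius.  The *directional* dM selectivity and
the dimension decrease are at the edge of detectability at the
two-instantiation scale used in the tests: the balance that suppresses
attractor dynamics also suppresses the coherent along-assembly
variability that carries those signatures, and a stronger-adaptation
variant that produces them inverts the radius/dimension signs instead.
This trade-off is a genuine property of the juvenile-scale model at these
weights, not a tolerance choice, and the corresponding assertions are
left as implemented.

## 5. Statistics

Naive-vs-trained comparisons use the two-sided Mann–Whitney U test (exact
null when both n <= 8 without ties, tie-corrected normal approximation
otherwise).  Multi-group comparisons use Kruskal–Wallis followed by
Dunn's z against the control group only, with the tie correction
`sum(t^3 - t) / (12 (N-1))` in the rank variance and Bonferroni
adjustment over the contrasts with the control (adjusted P =
min(1, raw * k)).  All tests are two-sided (sidedness is not specified by
the protocol; two-sided is the conservative choice).  Stars: ns >= 0.05,
* < 0.05, ** < 0.01, *** < 0.001.  Correlations are ordinary least
squares of y on x; the slope, R², slope P, and Pearson r =
sign(slope)·sqrt(R²) are reported together with the Pearson-test P (the
two P values coincide for simple regression, and both are emitted because
the reporting convention is ambiguous).

The behavioral discrimination score is `sum_trials(zeta+ - zeta-) /
n_days`, where zeta are per-trial appetitive scores for the rewarded
(CS+) and unrewarded (CS−) odor.  The video-based zeta computation is out
of scope; a small synthetic generator with a configurable CS+/CS− offset
stands in for it so the correlation stage can be exercised.

## 6. Synthetic data generator

The generator emulates the *structure* of the imaging data — it is the
package's stand-in for raw recordings, not a model of calcium indicator
dynamics or spike-inference noise.

* **Panel**: six odors, two classes of three (A = amino-acid-like with
  CS+/CS−/AA3 roles, B = bile-acid-like); 3 trials; 7.5 Hz.
* **Mitral patterns**: per-odor up/down cell sets whose rate-vector
  Pearson correlations hit a target matrix (default: 0.3 within class, 0
  across) by sharing a computed number of cells between correlated odors;
  shared blocks are disjoint across pairs so realized correlations are
  exact up to integer rounding (a residual shared block also appears for
  target 0, compensating the slight anticorrelation that strictly
  disjoint sets would have through the common mean offset).  Negative
  targets are rejected.  Default modulation: +30 Hz on 150 cells, −6 Hz
  on 75 cells, baseline 6 Hz.
* **Response time course**: zero before onset, then a unit-peak
  alpha-function transient (peak time = decay constant, default 0.5 s)
  riding on a saturating plateau (default fraction 0.4, rise 0.1 s).
* **Manifold geometry**: each odor's center is a sparse nonnegative
  vector (default support 12% of the population, lognormal amplitudes,
  norm 30 Hz) with exact pairwise cosines realized by shared support
  blocks whose amplitude mass is fixed to the shared fraction.  Points
  are `baseline + profile(t) * (center + trial_offset + bin_noise)`
  clipped at zero; trial offsets and per-bin draws have separate scales
  (defaults 0.6 and 1.0 Hz per neuron) so across-trial and within-trial
  spread are independently controllable, and the noise covariance can be
  elongated along a direction (default: the center direction).
* **"Trained" regime**: the CS+ and CS− centers and covariances are
  amplified along the amplification direction (default: the own-center
  direction, gain 1.5); AA3 receives half the effect (generalization
  factor 0.5 — partial generalization is observed but no factor is
  printed, so 0.5 is the package's choice).
* Zero-clipping slightly biases realized covariances and cosines when
  means sit near zero; parameter-recovery tests therefore use a positive
  baseline, and near-zero-mean configurations are excluded from recovery
  claims.  Identical seeds give bit-identical tensors.

Because no quantitative naive-regime manifold parameters are published,
the defaults above were calibrated once so that capacity on synthetic
naive data lands in a plausible range (~0.1 at the 700/140 protocol);
this calibration is exploratory, not a claim about real tissue.

## 7. Problem sizes in the shipped tests and analyses

The test suite and the acceptance script run everything at desk scale:
two network instantiations of preset A (the source protocol uses four
weight settings x two instantiations), 4 trials x 2 s per odor, 25–50
subsampling repeats for distances, 4–20 repeats x 80–200 Gaussian samples
for capacity, and 20 generator seeds for parameter recovery.  These sizes
are the package's reproducibility compromise; all protocols scale up by
configuration.

## 8. Known limitations

* The effective-measure formulas are an anchor-based operationalisation
  pinned by limit cases, not a re-derivation of the originating theory's
  closed forms; absolute values of the alignment measures should be
  compared only within this package.
* The dM estimator at 80 points vs 70 dimensions depends visibly on the
  ridge; comparisons are meaningful at fixed ridge only.
* The spiking model reproduces the balanced-regime phenotype and the
  sign-level distance/capacity effects described in §4, with the
  documented exceptions; it is calibrated at juvenile scale for preset A
  and is not a fit to any recorded dataset.
* Synthetic data contain no indicator dynamics, no inference noise, no
  slow drift, and no neuron identity across virtual fish; passing tests
  demonstrate correctness of the analytics on data with the configured
  statistical structure, not performance on real recordings.
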