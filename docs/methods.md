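# Methods

## Problem

Double electron-electron resonance (DEER/PELDOR) measures the dipolar
coupling between pairs of nitroxide spin labels attached to engineered
cysteines, encoding the inter-label distance distribution in a
time-domain echo decay. Interpreting those decays as backbone restraints
is confounded by the label's own flexibility: a rotamer ensemble several
Angstrom wide sits between the measured distance and the residue one
cares about. When many label pairs share common sites, however, the
network of decays over-determines the label positions — the same
multilateration principle used in satellite positioning. `deerlaterate`
refines, for every labeled residue, a weighted cloud of coarse-grained
label positions ("pseudo-rotamers") against all raw decays
simultaneously, then exports refined distance distributions, confidence
bands, and a distribution-overlap score usable as a restraint for
ranking candidate structural models.

Fitting happens in the time domain on purpose: transforming decays into
distance distributions first (Tikhonov regularization, Gaussian
mixtures, neural networks) bakes that method's assumptions and artifacts
into the restraints. Here the only transformations applied to the data
are phase correction, normalization, and an optional tail truncation.

## Forward model

For a label pair (u, v) with candidate positions and weights, the
distance distribution is the weighted histogram of all pairwise
candidate distances on a uniform grid (default 0.5 A bins over
10-100 A). Backbone heterogeneity broadens it: each residue contributes
an RMSF inferred from the crystallographic isotropic B-factor of its CA
atom,

    RMSF_u = sqrt(3 B_u / (8 pi^2)),     RMSF_uv = sqrt(RMSF_u^2 + RMSF_v^2),

and the distribution is convolved with a Gaussian of width RMSF_uv
(implemented as a column-normalized discrete kernel, so probability mass
is conserved exactly). B-factors are deliberately not rescaled between
structures; resolution differences may reflect genuine disorder
differences.

The intramolecular form factor is the powder average of the dipolar
oscillation over the angle x between the inter-spin vector and the
field,

    K(r, t) = ∫_0^{π/2} sin x · cos((1 − 3cos²x) ω_dd(r) t) dx,
    ω_dd(r) = μ0 μB² g² / (4π ħ r³)  ≈ 2π · 52.04 MHz at r = 1 nm,

evaluated in closed form via Fresnel integrals (a fixed-order trapezoid
quadrature is available through `n_quad`; the closed form matches a
100 001-point quadrature to machine precision, while low fixed orders
under-resolve the oscillations at large ω t). Distances below 15 A are
excluded from the form factor and the surviving mass renormalized —
such components barely modulate the observable decay, and
renormalization keeps V_intra(0) = 1. The observed decay adds a
stretched-exponential intermolecular background with modulation depth
lambda:

    V_sim(t) = exp(−(k t)^(d/3)) · (1 − λ (1 − V_intra(t))).

The background dimensionality d is fixed at 3 for soluble proteins and
may float in [2.0, 3.5] for membrane proteins, where excluded volume
flattens the spin bath. Background parameters are fit per trace by a
coarse grid (λ in 0.05-0.6, log-spaced k) followed by
Levenberg-Marquardt in smoothly bounded (logit/log) coordinates.

## Likelihood, noise, and model selection

With traces i = 1..N and per-trace noise s.d. σ_i estimated from the
phase-corrected imaginary channel, the log-likelihood of a coordinate
model θ is the noise-normalized sum of squared residuals,

    ln L(θ) = −(n_total/2) · ln( (1/n_total) Σ_i Σ_t ((V_exp − V_sim)/σ_i)² ),

with the mean floored at 1e-12 to keep a perfect fit finite. Noise
normalization matters: without it the optimizer over-fits noisy traces
and under-fits clean ones. Model complexity is scored by the
small-sample-corrected Akaike criterion,

    AICc = −2 ln L + 2K + 2K(K+1)/(n_total − K − 1),

where K counts every rotamer with nonzero weight plus the background
parameters (2 per trace with d fixed, 3 when free). AICc embodies the
physical prior that flash-freezing leaves few rotamers contributing to
the signal: among equally good fits, the sparsest ensemble wins.

## Annealing

Each replica starts from one randomly chosen rotamer per residue at
weight 1. A trial perturbs one uniformly chosen rotamer weight by a
uniform draw in [−m, m] (m starts at 0.1), clipped at zero, re-drawn if
it would zero out a residue entirely; affected traces get their
histograms updated incrementally and their backgrounds re-fit by two
warm-started damped Gauss-Newton iterations. Moves are accepted by the
Metropolis rule on −lnL at temperature kT, which starts each round at
1.5 and decays hyperbolically to 1% of that value across the round's
schedule of 2500 trials per trace. A round aborts after 500 consecutive
trials that fail to improve on the best SSR sampled so far; a round
with no such improvement at all shrinks m tenfold, and the replica
concludes once m reaches 1e-4 (a max_rounds cap of 300 guards against
non-termination, since a round with even one improvement never shrinks
m). Rounds restart from the best-sampled state, and the replica's
result is that best state — aborted rounds end at high temperature, so
the final wandered state would systematically discard the converged
solution.

Two deterministic conclusion steps follow: a strict-descent polish
(greedy passes at m = 0.1, 0.01, 0.001 with the same abort rule) and an
AICc-guided pruning sweep that zeroes any rotamer whose removal lowers
the AICc. Desk-scale runs use 10-20 replicas rather than the thousand
of a production run, and with so few replicas the selection by AICc is
easily scrambled by residual weight dust from the stochastic phase;
pruning implements the same parsimony objective the criterion already
encodes. Backgrounds are fully re-fit (grid + Gauss-Newton) at every
round boundary and at conclusion. For the free-d policy, d stays fixed
at 3.0 during the first round and floats in [2.0, 3.5] afterwards;
releasing it immediately collapses d to its lower bound early and traps
the fit.

Replicas are embarrassingly independent (seeds base + index) and ranked
by AICc; confidence bands on each pair's distribution are the per-bin
2.5th/97.5th percentiles over the five lowest-AICc models, with the
per-bin mean as the central estimate. Held-out pairs are predicted by
the same broadened-distribution path without ever touching their traces.

The inner loop is jit-compiled (numba). All stochasticity flows from
explicit integer seeds; two replicas with equal seeds are bit-identical.

## Overlap restraint score

Agreement between a simulated and an experimental (or reference)
distribution on a shared grid is scored per pair as −ln Σ_j p_sim,j
p_exp,j, summed over pairs; lower is better. A vanishing overlap gives
ln 0, capped at 87.0 — the magnitude of the log of the smallest normal
single-precision float — so one disjoint pair cannot dominate a score
sum to infinity. Distributions on different grids are linearly resampled
onto the experimental grid and renormalized.

## Synthetic data

The fixture generator builds an ideal alpha-helix (rise 1.5 A,
100°/residue, CA radius 2.3 A) with N/CA/CB/C/O atoms at standard bond
lengths and a configurable B-factor profile, writes it as a PDB,
generates clash-filtered candidate clouds, plants one ground-truth
rotamer per labeled site, and synthesizes each pair's decay through the
full forward chain before adding i.i.d. Gaussian noise to the real
channel and pure noise of the same amplitude to the imaginary channel
(mirroring the imaginary channel's role as a noise proxy). Traces are
written in the plain-text dialect the reader accepts (ns time column),
and every fixture is a pure function of its seed.

The canonical recovery benchmark uses 6 labeled sites on a 40-residue
helix, 10 pairs with every site restrained by at least three of them,
2.0 µs traces at 16 ns steps, noise s.d. 0.01, modulation depths of
0.25-0.40, background rates 0.1-0.3 µs⁻¹ at d = 3, and a constant
B-factor of 26.32 A² (1.0 A RMSF per residue). Planted rotamers are
drawn so all pair distances land in 18-70 A. Its clouds carry 12
candidates per site (4-5 A apart) rather than the 50 of the default
generator: pairwise distances determine a constellation only up to
rigid motion, and diagnostic runs with dense clouds recover all pair
distances to ~0.2 A while absolute centroids drift several Angstrom
along that degeneracy. A planted-recovery benchmark is only well posed
when the decoys are distinguishable by the data; with real rotamer
libraries the same anchoring is supplied by the library's compactness.

What passing recovery does and does not show: the benchmark
demonstrates that the optimizer finds planted, identifiable solutions
under realistic noise and background nuisance parameters. It does not
emulate orientation selection, multi-spin effects, non-ideal excitation,
or label ensembles broader than one rotamer, and absolute-position
accuracy on real proteins is bounded by the faithfulness of the rotamer
library, not by this test.

## Numerical choices and edge cases

- Time is microseconds internally; files store nanoseconds. Distances
  are Angstrom except inside the kernel (nm).
- Trace normalization divides by the maximum of the real channel. On a
  noisy trace the max overshoots the true amplitude by roughly
  σ·E[max of n standard normals] (about 2.5% at σ = 0.01, n = 126); no
  model with V_sim(0) = 1 can absorb that scale, which sets a floor on
  attainable fit quality that all candidate models share.
- Noise estimation: the phase angle minimizing the imaginary channel's
  RMS has a closed form (smallest eigenvector of the 2x2 second-moment
  matrix); the estimate is the mean-subtracted s.d. of the rotated
  imaginary channel and is invariant under global phase rotation.
  Noiseless imaginary channels are rejected rather than defaulted.
- Tail truncation drops points with t > t_max − cut (default 500 ns).
- Histogram binning assigns each distance to the nearest bin center,
  clipped to the grid, so no probability is silently lost.
- In-engine background refits clamp k ≥ 1e-6 µs⁻¹ (the d < 3 derivative
  of the background is singular at k = 0); the module-level fitter uses
  a log parametrization and can reach arbitrarily small k.
- Weight moves clip at zero exactly, so pruned rotamers have weight 0.0
  and K is well defined without a threshold.
- A residue always keeps at least one active rotamer; moves that would
  empty a residue are re-drawn.

## Limitations

- Single-centroid pseudo-rotamers ignore rotamer-rotamer exclusion and
  any coupling between label conformations.
- The stretched-exponential background is phenomenological; strongly
  structured intermolecular contributions (e.g., nanodisc crowding) are
  outside its reach.
- No attempt is made to guarantee the global optimum; the replica
  ensemble plus AICc ranking is the sole defense, and production use
  should run hundreds to a thousand replicas.
- Confidence bands summarize variation across the top replicas; they are
  not posterior credible intervals.
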