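# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `morphorates`. Everything stated here is computed by
the test suite or by `scripts/acceptance.py`; nothing is quoted from
external data.

## Elliptic Fourier analysis

A closed outline is treated as a polygon parameterized by cumulative
chord length `t` with perimeter `T`. The coordinate functions are
expanded in harmonics; because `x(t)`, `y(t)` are piecewise linear, the
Fourier integrals have an exact closed form obtained by integration by
parts:

    a_n = T/(2 pi^2 n^2) * sum_p (dx_p/dt_p) (cos phi_p - cos phi_{p-1})

(analogously `b_n` with sines, and `c_n, d_n` for `y`), with
`phi_p = 2 pi n t_p / T`. The DC terms are the exact means of the
piecewise-linear coordinate functions. No resampling is applied:
the closed form is exact for polygonal input, and outlines are used at
their native point count. Traversal is standardized to
counterclockwise (reversing the vertex order when the signed area is
negative) so that handedness is consistent across specimens.

**Normalization.** The first-harmonic ellipse has semi-major magnitude
`E`, starting-point phase `theta` and orientation `psi`, obtained from
the standard half-angle formula with an explicit quarter-turn
correction when the formula's branch lands on the semi-minor axis.
`size` mode divides all harmonics by `E` and zeroes the DC terms
(scale + translation invariance); `full` mode additionally conjugates
each harmonic matrix by the rotation `psi` and phase `n*theta`,
resolving the residual half-turn ambiguity by requiring the normalized
first-harmonic `a_1 > 0`. The default is `size`, keeping all `4 N_h`
coefficients per outline (80 at the default `N_h = 20`); full
normalization would pin three of them and is available for sensitivity
analyses. Degenerate first harmonics (`E < 1e-12`) raise an error.

**A property worth knowing.** Chord-length EFA is a statement about a
curve parameterized by its own arc length. The first harmonic of an
eccentric ellipse sampled this way is *not* `(a, 0, 0, b)`: for a 3:1
ellipse it is approximately `(2.62, 0, 0, 1.10)`, with the remaining
energy pushed into odd harmonics (even harmonics vanish by the
ellipse's two-fold symmetry). The test suite asserts the true
invariants (axis alignment, vanishing even harmonics, reconstruction
convergence) rather than the naive identification.

## Phylogenetic machinery

All comparative statistics use the Brownian-motion covariance `C` of
shared root-to-MRCA path lengths. The inverse symmetric square root
`P = V diag(w^-1/2) V'` is computed by eigendecomposition rather than
Cholesky so the whitened residuals `U = P (Y - 1 E(Y)')` are
rotation-consistent across trait blocks; eigenvalues below
`1e-12 * max(w)` raise an error carrying the condition number. The
phylogenetic mean is the GLS estimator `E(Y) = (1'C^-1 1)^-1 1'C^-1 Y`.
Trees are not forced ultrametric; a warning is emitted when tip depths
differ by more than 0.1% because the rate and signal statistics
interpret `C` as proportional to time.

Ancestral states for a univariate trait are the GLS (maximum
likelihood) estimates `a_v = mu + c_v' C^-1 (y - mu)` with `c_v` the
node-tip shared path lengths, and variance
`sigma^2 (t_v - c_v'C^-1 c_v + (1 - 1'C^-1 c_v)^2 / (1'C^-1 1))`,
`sigma^2` estimated by GLS with `N - 1` denominator. The root estimate
equals the phylogenetic mean by construction; tips carry zero variance.
Traitgrams are the per-edge `(time, value)` segments of these
estimates.

BM simulation walks the tree root-to-tips with increments
`N(0, branch_length * R)`; the rate matrix may be scalar, diagonal or
full SPD (Cholesky factor computed once). One seed governs a top-level
call; replicate simulations share a single generator stream so results
are reproducible and vectorizable.

## Estimators and tests

**K_mult.** Implemented exactly as the distance-based generalization
of Blomberg's K (see `signal.py` docstring for the formula); with
`p = 1` it reduces algebraically to univariate K, which the tests
verify against an independently coded GLS oracle at 1e-10. Under BM on
a 33-tip unit-depth tree its mean over 200 simulations lies in
[0.9, 1.1]. Significance: whole rows of Y are permuted across tips
(preserving within-species covariance among coefficients), p-value
convention `(b+1)/(m+1)` so the floor at 1000 permutations is 0.001.

**Rates.** `sigma^2 = sum_i ||U_i||^2 / (N p)` per block. The division
by `p` makes `sigma^2` estimate the per-dimension BM rate directly and
makes blocks of unequal dimensionality comparable; when every block has
the same `p` (the standard 80), ratios are unaffected, and
`dim_normalize=False` restores division by `N` alone. The estimator
carries the usual `(N-1)/N` finite-sample factor (mean recovery within
10% is Monte-Carlo-tested), which cancels from all ratios. The global
test simulates all blocks jointly under a single pooled per-dimension
rate — the null hypothesis is exactly rate equality, and the pooled
value only sets a scale that cancels from R — and compares null R to
observed R with `(b+1)/(m+1)`. Pairwise post hoc p-values are computed
from the same simulations without multiplicity adjustment. Bootstrap
CIs resample specimens within species with replacement and recompute
species means and `sigma^2`; percentile intervals at 95%.

**pPLS.** SVD of the whitened cross-block covariance; the statistic is
the absolute correlation of the first latent score pair. The
permutation test shuffles *whitened* rows of the second block: whitened
rows are exchangeable under the BM null, which keeps the test size at
alpha (measured 0.04-0.07 at alpha = 0.05 over 200 replicates).
Shuffling raw rows instead leaves the phylogenetic structure intact in
the unpermuted block and inflates the type-I error to ~0.35-0.4; this
choice is therefore load-bearing, not cosmetic. Sign convention: the
left vector's largest-magnitude element is positive.

**Specimen statistics.** The ICC uses the one-way ANOVA estimator with
the unbalanced-design constant
`n0 = (N - sum n_i^2 / N)/(k - 1)`; estimates are clamped to [0, 1]
(repeatability is reported on that scale). SE and CI come from a
parametric bootstrap of the fitted variance components; the p-value
from permuting values across groups. The shape-effects models use
sequential (type-I) sums of squares via OLS, complete cases only, with
effects ordered species, sex (when present), size — with 157 specimens
of 33 species and one covariate the denominator df is 123, dropping to
122 when one specimen lacks a size measurement. The variance-ratio
test doubles the smaller F tail (capped at 1), so `F = 2.28` at
df (32, 32) gives p = 0.0225, printed as 0.02.

## Synthetic data

The generator emulates the study design the package targets: a Yule
tree rescaled to unit depth (33 species by default), four trait blocks
of 80 coefficients with per-dimension BM rates (1.99, 0.73, 0.36,
0.24), a uniform per-dimension correlation rho = 0.67 between the
paired columns of the two genital blocks (the simplest SPD construction
with one interpretable knob), and isotropic within-species Gaussian
noise. The noise sd defaults to 0.5, chosen so that per-dimension
among-species repeatability for the fastest block is about
1.99/(1.99 + 0.25) ~ 0.89, matching the magnitude of repeatabilities
reported for real outline data. Trait sizes are lognormal and
independent of shape, mirroring the isometry assumption behind size
normalization.

**Outline synthesis.** Rendering a coefficient vector and re-extracting
it is *not* the identity: extraction reparameterizes the curve by chord
length, and the extracted coefficients always satisfy arc-length
consistency constraints that an arbitrary vector violates (the
render-extract Jacobian has ~8 near-null directions). Three design
choices make the round trip exact to < 1e-6 anyway:

1. planted deviations fill harmonics 2..(p/4 + 1) around a fixed
   first-harmonic carrier ellipse (semi-minor 0.9), so size
   normalization — which pins the first harmonic — cannot erase
   planted variance;
2. amplitudes are tapered as `scale / n^2` (real outline spectra decay
   with harmonic number), which keeps the reparameterization feedback
   contractive;
3. the embedded vector is projected onto the curve's own arc-length
   parameterization (dense FFT reparameterization) before use, i.e.
   the generator only ever emits vectors from the class that real
   digitized outlines occupy.

`synthesize_outlines` then refines the rendering coefficients by
fixed-point iteration until the re-extracted, size-normalized
coefficients match the request (converges to ~2e-7 at 1024 points; for
vectors outside the realizable class it stops at the closest attainable
match). The embedding is inverted by `recover_shape_deviations`, which
subtracts the carrier's own arc-length signature and undoes the taper.
The net embed-render-extract-recover map is a fixed near-identity
linear distortion applied identically to every specimen and block, so
planted *ratios* survive: at study-realistic amplitudes a planted
variance contrast is recovered within a few percent, and the full
outline pipeline recovers a planted 2.7x rate contrast with mean
estimates within ~5% over replicates.

What the synthetic data do not emulate: non-isotropic within-species
error, digitization artifacts (pixelation, smoothing, landmark drift),
allometry, non-BM evolutionary processes, and phylogenetic uncertainty.
Passing tests demonstrate correctness of the estimators under the BM
generating model at study dimensions, not robustness to those
real-data complications.

## Problem sizes and randomness

Monte-Carlo checks use 200 replicates for calibration and type-I
bands, 100 replicates for planted-effect recovery at the full study
dimensions (N = 33, p = 80 per block), and 199 permutation/simulation
draws per replicate (p-value floor 0.005); the acceptance script uses
the same sizes and finishes in a few minutes on one CPU. Every
stochastic routine takes one seed; the pipeline derives per-stage
streams from its single seed via `SeedSequence.spawn`, and identical
configuration + seed reproduces outputs byte-for-byte.

## Known limitations

- Open curves are out of scope; outlines must be closed and simple
  (self-intersection only triggers a warning in area computation).
- The rate and signal statistics assume time-proportional covariance;
  non-ultrametric trees are accepted with a warning but the statistics
  lose their calibration.
- `sigma^2` comparisons assume isotropic within-block rates; the
  pooled-rate null matches the reference methodology but is parametric
  (simulation-based), not a permutation test.
- The variance-ratio F test on PC1 scores does not control for
  phylogeny (a phylogenetically corrected version is not defined for
  this statistic); it should be read as a descriptive contrast.
- Full (rotation/start-point) normalization has a documented reflection
  convention; mirrored outlines are not identified with their
  reflections.
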