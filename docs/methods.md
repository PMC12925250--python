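# Methods

This note records the model assumptions, the numerical choices, and the
design decisions behind `spaco`, in enough detail that a maintainer can
tell which behaviours are contracts and which are implementation
convenience.

## Conventions that the math depends on

**Population variance everywhere.** "Centred and scaled" always means
mean 0 and *population* variance 1 (divide by n, not n−1). This is not a
stylistic choice: the identity `xᵀLx = 1 + I(x)` requires `(1/n)xᵀx = 1`
exactly, and the whitened matrix must satisfy `(1/n)XᵀX = I` so that
every unit combination of its columns is a unit-variance pattern and the
eigenvalues of `XᵀLX` equal `1 + I` of the corresponding pattern.

**W is scale-free.** Moran's I and Geary's C divide by `|W|`, so only the
relative weights matter. The identity `I + C = 1` holds exactly whenever
the symmetric W has constant row sums (the usual statement is for
row-stochastic W; dividing each entry of a constant-row-sum W by the row
sum is a no-op for both statistics). The package exercises this identity
on a torus lattice, where every spot has exactly 8 neighbours; on a
bordered lattice it holds only approximately, which is why no test asserts
it there.

**L is structural.** The operator is kept as `(1/n)·identity +
(1/|W|)·sparse` and applied through matrix–vector products; it is never
densified except inside small-n test oracles (`MoranOperator.dense`
refuses n > 1000). I and C are computed directly from W, not through L,
to avoid subtracting the `1/n` term back out.

## Weight matrices

- **Grid kernel (default).** The lattice unit is the smallest pairwise
  spot distance; spots within 1.5 units are neighbours with weight 1.
  On a square lattice this is the 8-neighbourhood (diagonals at √2); on a
  hexagonal Visium layout it yields the 6 natural neighbours. Border
  spots simply have fewer neighbours. A distance rule rather than a
  literal "8 nearest" keeps corner spots from reaching across the tissue.
- **kNN kernel.** Directed unit edges to the N nearest neighbours,
  symmetrized as `(W̃ + W̃ᵀ)/2`, entries in {0, ½, 1}. Ties at equal
  distance keep the smaller row index — determinism is worth more than
  any pretence of fairness at measure-zero configurations. Note that kNN
  forces every spot, including corners, to have N out-neighbours, so its
  support matches the grid kernel only away from lattice borders.
- **Gaussian kernel.** Per-spot widths σᵢ are bisected so that the
  perplexity (2^entropy) of the normalized weight row hits a target P,
  with |Perp − P| < 1e−5 within 200 iterations. If a spot's N neighbours
  are exactly equidistant the perplexity is constant in σ and the target
  is unattainable; the uniform (maximum-entropy) row is returned, since
  it is the only possible weight assignment for that geometry. Genuine
  non-convergence raises with a diagnostic. The unit-weight kernels are
  the defaults; the Gaussian variant exists for irregular spot layouts.

A test-only torus option wraps lattice distances so that a doubly
stochastic W exists for the exact-identity tests.

## Preprocessing

Whitening uses the SVD `X = USVᵀ` of the z-scored matrix and returns
`√n·U_q`, which satisfies the two contracts downstream math needs: zero
column means and identity population covariance. Components with singular
value below `1e−10·σ_max` are treated as numerical rank deficiency and
excluded before the variance threshold is applied; `q` is then the
smallest number of components with cumulative variance ≥ 95% (the
threshold is exposed). The gene-space rotation is stored so that component
loadings can be pulled back to genes. All non-constant genes participate;
constant genes are dropped with a warning and resurface as NA rows in the
SVG table rather than disappearing.

Normalization proper is out of scope: the package expects a
variance-stabilized matrix and offers only an explicit, warning-emitting
library-size + log1p helper for quick experiments.

## Component selection

The permutation null draws R spot permutations of the whitened matrix and
records the largest eigenvalue of each permuted `X̃ᵀLX̃`; W and L stay
fixed, and the whitened matrix is not re-whitened (spot permutation leaves
the covariance untouched, so re-whitening would be a no-op up to
rotation). The threshold is the order statistic of rank
`⌈(R+1)(1−γ)⌉`, not an interpolated quantile: the ceiling guarantees
`P(μ > l) ≤ γ` for the empirical null, which is the direction the
family-wise error guarantee needs. R defaults to 1000 and is refused
below 100, where the 5% quantile of a max-statistic is too unstable to
mean anything. A seed is mandatory in the API; the CLI logs it.
`k = 0` is a legal outcome; the SVG test and the denoiser refuse to run
on such a model with a clear message, because both are defined relative
to a non-empty spatial subspace.

Eigenproblems are always solved in the q×q whitened space (q is at most a
few hundred); the n×n operator enters only through quadratic forms.
Component signs are fixed by making the largest-magnitude loading
positive.

## The SVG null and its tail

The mixture weights `cᵢ` are the eigenvalues of the k×k matrix
`(S_kᵀL)(LS_k)`, mathematically equal to the non-zero eigenvalues of the
n×n `Σ = LᵀS_kS_kᵀL`; both routes are computed in the test suite and must
agree to 1e−8. Negative eigenvalues beyond −1e−10 are a contract
violation; smaller ones are numerical noise and are clipped to zero.

Tail probabilities `P(Σcᵢχ²(1) ≥ t)` are computed by Ruben's expansion:
with β = min cᵢ the mixture distribution is an infinite convex combination
of central χ² distributions with k, k+2, … degrees of freedom, scaled by
β, whose coefficients follow a two-term recursion through the power sums
of `1 − β/cᵢ`. The series has non-negative coefficients summing to one,
so its truncation error is bounded by the unassigned mass; iteration
stops once that mass is at machine precision *and* the terms have entered
their decreasing phase with the last term below 1e−14 of the accumulated
sum, which keeps the result accurate in relative terms deep in the tail
(validated against 50-digit high-precision inversion of the
characteristic function down to p ≈ 1e−44). Coefficients below 1e−10 of
the largest are discarded first; they contribute nothing to the
distribution but can stall the series. If the series still fails to
converge (pathological coefficient spread), the code falls back to
adaptive-quadrature inversion of the characteristic function (Imhof's
formula) for moderate tails and to the Liu–Tang–Zhang moment-matching
noncentral-χ² approximation for far tails. P-values are floored at
1e−300. A vectorized variant shares the series coefficients across all
genes of a table, which is what makes 10⁵-gene calibration runs cheap.

Genes are tested on their centred, population-scaled patterns — the same
convention used in fitting — although the null is stated for i.i.d.
N(0, 1) spots without that conditioning. The discrepancy is O(1/n); the
calibration test therefore runs at slide scale (52×52 = 2704 spots,
matching a typical Visium capture area of ~2700 spots), where the
p-values of 10⁵ null genes are uniform with KS < 0.006 and the p < 0.01
tail frequency within [0.007, 0.013]. On very small lattices (n in the
dozens) a slight conservatism of the same order should be expected.
Multiplicity adjustment is Benjamini–Hochberg by default, Bonferroni on
request.

## Resampling

Coverage-adjusted local resampling redraws each spot's value from a
uniformly chosen donor within radius r (independently per gene by
default; a per-spot shared-donor mode exists) and then rescales each row
by original-total / resampled-total, so per-spot coverage is conserved
exactly and spots with a zero resampled total keep their zeros. Values
stay continuous; re-rounding to integers would break exact conservation
for no downstream benefit. The adjustment matters: unadjusted resampling
manufactures anticorrelation with the coverage pattern, which is itself
spatially structured, and would turn negative controls into positives.

Twin negative controls resample a single gene with r = ∞. A per-row
rescale is the identity map for a single gene (the row total *is* the
gene), so twins instead scale each donated value by the recipient/donor
coverage ratio computed from the full matrix — the same adjustment
expressed at single-gene granularity. The twin of a strongly spatial gene
lands inside the Moran permutation-null band, which the tests check.

## Synthetic data

The generator emulates a gridded slide: unit-spaced lattice, a small
number of latent smooth fields (Gaussian-filtered white noise), spatial
genes mixing a latent with gene-specific white noise, pure-noise genes,
and per-gene Poisson counts with rate `coverage_mean · softplus(x) /
mean(softplus(x))` (mild coverage heterogeneity). Defaults — 12×12
lattice, 30 spatial + 470 noise genes, 3 latent programs, smoothness 3
grid units (domains spanning about a quarter of the slide, the scale of
anatomical zones), signal fraction 0.8 (strong markers, gene-level
Moran's I ≈ 0.7), mean coverage 50 — were chosen once to represent a
small slide with clearly detectable regional structure. A `gaussian`
count model emits standardized values directly for experiments whose null
must be exactly i.i.d. normal spots.

What the generator does *not* emulate: hexagonal Visium geometry (beyond
the distance-threshold neighbour rule), mean–variance relationships of
real UMI data, segmentation artefacts, and histology covariates. Passing
tests therefore demonstrate the mathematics and the statistical
guarantees under the stated model, not performance on any particular
tissue.

Worth knowing: the default 12×12 regime is deliberately hard for
selection. Whitening 500 genes on 144 spots retains ~120 components, and
the largest permuted eigenvalue of a near-square whitened matrix is
large, so the FWER threshold sits near Moran's I ≈ 0.95 and only strong
latent structure clears it. That is the honest cost of family-wise error
control at small n, and it is why weak-signal simulations on tiny grids
select k = 0.

## Experiment sizes

The statistical suites use: 500 null datasets × 500 permutations for the
family-wise error rate; 10⁵ genes on a 52×52 lattice for calibration;
10⁷ Monte-Carlo draws for the tail oracle; 50 replicates on a 20×20
lattice with resampling radius 2 (the ~8%-of-slide-width noise level,
scaled down from a full slide) for the denoising property. These sizes
give Monte-Carlo standard errors comfortably below the asserted margins.

## Known limitations

- Single slide only; no joint multi-slide decomposition.
- The permutation test runs on all spots by default. A `subsample`
  argument exists as an explicitly-labelled, uncalibrated speed heuristic
  for very large slides (it restricts every draw to a random spot subset
  and warns); thresholds derived from it carry no family-wise error
  guarantee, and nothing in the package uses it implicitly.
- Moran's I of an eigen-pattern can in principle exceed 1 for extreme
  weight spectra; no clipping is applied.
- p-values below 1e−300 are reported as 1e−300.
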