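# spaco — spatial component analysis for spatial transcriptomics

Spatially resolved transcriptomics measures a full expression profile at
every spot of a tissue slide. Neighbouring spots are biologically similar,
so the interesting structure in such data is *spatial*: genes whose
expression forms smooth tissue patterns, and low-dimensional feature
spaces that preserve those patterns. `spaco` implements spatial component
analysis, a spectral method that does three things in one framework,
without any tuning parameters:

1. **Dimension reduction** — find linear combinations of genes (spatial
   components, "SpaCs") whose spot patterns maximize Moran's I, the
   classical measure of spatial autocorrelation.
2. **Feature selection** — a calibrated per-gene test for spatially
   variable genes (SVGs) against an exact weighted-χ² null.
3. **Denoising** — an orthogonal projection that cleans the patterns of
   genes identified as spatial.

It is aimed at analysts of 10x Visium and similar gridded spatial omics
data who want a statistically principled alternative to PCA-based
preprocessing and to heuristic SVG rankings.

## The model

Spot proximity is encoded in a sparse symmetric weight matrix
`W` (unit weights between the N = 8 nearest lattice neighbours by
default), with total weight `|W| = Σᵢⱼ wᵢⱼ`. For a pattern `x ∈ ℝⁿ`
centred to mean 0 and scaled to population variance 1,

```
I(x) = (1/|W|) Σᵢⱼ wᵢⱼ xᵢ xⱼ          (Moran's I)
C(x) = (1/2|W|) Σᵢⱼ wᵢⱼ (xᵢ − xⱼ)²    (Geary's C)
```

The operator `L = (1/n)E + (1/|W|)W` turns Moran's I into a squared
length: `‖x‖²_L = xᵀLx = 1 + I(x)`. After gene-wise z-scoring and PCA
whitening (keeping the fewest components with ≥ 95% of the variance), any
unit combination `u` of whitened columns gives a unit-variance pattern
`Xu`, so the eigenvectors `u₁, u₂, …` of `XᵀLX` (eigenvalues
`λᵢ = 1 + I(Xuᵢ)`, decreasing) are exactly the Moran-optimal components,
and by Courant–Fischer the span of the first `k` patterns maximizes the
*worst* Moran's I over all k-dimensional pattern subspaces.

`k` is chosen by a permutation test: permuting spots destroys spatial
structure but preserves covariance, so the largest eigenvalue `μ` of the
spot-permuted problem is a simultaneous null for every component.
Thresholding the observed eigenvalues at the conservative empirical
`(1−γ)` quantile of R permutation draws controls the family-wise error
rate at `γ` (default 0.05).

With `sᵢ = Xuᵢ/√λᵢ` (L-orthonormal patterns, `S_k = [s₁…s_k]`), the
SVG statistic of a centred, scaled gene pattern `x` is

```
t = ‖P(x)‖²_L = Σᵢ≤k (sᵢᵀLx)² = xᵀΣx,   Σ = LᵀS_kS_kᵀL,
```

which under the i.i.d. normal null follows `Σᵢ cᵢ χ²(1)` with `cᵢ` the
eigenvalues of the k×k matrix `(S_kᵀL)(LS_k)`. Tail probabilities are
computed exactly by Ruben's series of central χ² tails; p-values are
Benjamini–Hochberg adjusted. The projection `P` is also the denoiser:
applied to a significantly spatial gene it strips non-spatial variation.

## Worked example

```bash
spaco simulate --out demo --rows 14 --cols 14 --spatial-genes 25 \
    --noise-genes 75 --seed 1
spaco fit --matrix demo --coords demo/coordinates.tsv --log-normalize \
    --out demo_model --seed 7 --permutations 200
spaco test --matrix demo --coords demo/coordinates.tsv --log-normalize \
    --model demo_model --out demo_svg.tsv
spaco denoise --matrix demo --coords demo/coordinates.tsv --log-normalize \
    --model demo_model --out demo_denoised.tsv
```

The `fit` step prints

```
selected k=3 of q=66 spatial components (threshold 1.5749 at FWER 0.05)
```

meaning 66 whitened dimensions were searched, three spatial components had
eigenvalues above the permutation threshold 1.5749 (patterns with Moran's
I above ≈ 0.57), and everything else is indistinguishable from spatially
permuted noise. The `test` step prints

```
26 significant gene(s) at adjusted alpha=0.05
```

and writes a table of per-gene statistics, raw and adjusted p-values; on
this simulation the 26 calls comprise 25 of the 25 planted spatial genes
(the top of the table is `svg0024` at an adjusted p of about 1e-35) plus
one borderline noise gene. `demo_denoised.tsv` contains the projected
(denoised) patterns of the significant genes only — projections of
non-spatial genes look spatial by construction and are refused unless you
pass `--all-genes`.

The same pipeline is available as a library:

```python
import spaco
X, coords, truth = spaco.simulate_dataset(spaco.SyntheticSpec(seed=1))
model, L, Xw = spaco.fit_pipeline(spaco.log_normalize(X), coords, seed=7)
table = spaco.test_genes(spaco.z_transform(spaco.log_normalize(X)), model, L)
```

Real data enter through `spaco.io.read_matrix` (MatrixMarket triplet
directory or TSV) and `spaco.io.read_coordinates` (simple 3-column tables
or the 10x Visium `tissue_positions.csv` dialect; out-of-tissue spots are
dropped and spots are joined to the matrix by barcode, never by file
order). The matrix is assumed normalized upstream (e.g. SCTransform); the
built-in `--log-normalize` is a convenience for quick looks, never applied
silently.

## Scope notes

Multi-slide joint fitting, SCTransform itself, clustering of the reduced
space, and comparisons with external SVG callers are out of scope.
Unadjusted (non-coverage-preserving) resampling is deliberately not
offered as a negative control: resampled patterns anticorrelate with the
spot-coverage pattern, which is itself biologically structured.
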