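# trilomorph

Outline geometric morphometrics and disparity analysis for trilobite
cephala.

Trilobite head shields (cephala) carry much of the group's morphological
disparity, and their 2D outline is one of the few characters comparable
across every trilobite order. `trilomorph` implements the full analysis
chain for digitized cephalic outlines:

1. **Digitized curves → closed outlines.** Each specimen is recorded as two
   open curves anchored at the genal-spine tips (tpsDIG2 convention): an
   anterior curve from the left tip around the front to the right tip, and
   a posterior curve back again. Each is resampled to 64 equally spaced
   semilandmarks and the pair is assembled into a closed, positively wound
   128-point outline.
2. **Elliptic Fourier analysis (EFA).** The closed contour (x(t), y(t)) is
   decomposed into per-harmonic quadruples (a_n, b_n, c_n, d_n),

   x(t) = A₀ + Σₙ aₙ cos(2πnt/T) + bₙ sin(2πnt/T),
   y(t) = C₀ + Σₙ cₙ cos(2πnt/T) + dₙ sin(2πnt/T),

   with exact piecewise-linear integrals over the arc-length
   parameterization. The harmonic count N is chosen as the smallest N whose
   mean cumulative power Pₙ = (aₙ² + bₙ² + cₙ² + dₙ²)/2 reaches 99.9%.
   Coefficients are normalized for size, rotation and starting point via
   the first-harmonic ellipse.
3. **Morphospace.** Covariance PCA of the normalized coefficient matrix;
   the first two components are retained for all downstream analytics.
4. **Group statistics.** Convex-hull areas, centroid distances, mean
   shapes, sum-of-variances (SoV) and sum-of-ranges (SoR) disparity with
   bootstrap support, one-way MANOVA (Pillai's trace) with pairwise tests
   under Bonferroni correction (α / C(g,2)), LDA leave-one-out
   cross-validation tables, and k-means scans with elbow selection —
   per taxonomic order, per geological period, and per order-within-period
   on a single shared morphospace.
5. **Synthetic data.** A seven-parameter cephalon generator (width, axial
   length ratio, genal-spine length/base/angle, marginal brim, anterior
   roundness) produces group-structured datasets with known ground truth,
   including a 983-specimen, 12-order × 6-period study-scale preset.

## Worked example

```python
from trilomorph import pipeline

cfg = pipeline.RunConfig(preset="five_morphogroups", seed=42,
                         bootstrap_replicates=200)
res = pipeline.run_pipeline(cfg)

print(f"harmonics retained (99.9% power): {res.n_harmonics}")
vf = res.model.variance_fractions
print(f"PC1 {vf[0]:.1%}, PC2 {vf[1]:.1%}")
```

prints, for the six-group preset (240 specimens realizing five
morphogroups — a brimmed long-spined harpid analogue, a narrow-spined
trinucleid analogue, a short lichid analogue, and three near-identical
central groups):

```
harmonics retained (99.9% power): 7
PC1 65.0%, PC2 24.4%
```

The group statistics recover the built-in structure: the harpid analogue's
centroid sits at least 0.246 PC units from every other group (the three
central groups are within 0.07 of each other), order identity is highly
significant overall (MANOVA F = 65.84, p = 8.6e-83), and the leave-one-out
LDA classifies 82% of harpid-analogue specimens correctly while the
near-identical central groups are mutually confusable. Per-group disparity
(SoV 0.010–0.016, SoR 0.59–0.75) is tabulated with bootstrap quantiles in
`res.tables["disparity_order"]`.

The same analysis runs from the shell on files:

```
trilomorph simulate --preset study_mimic --seed 1 --out-dir data/
trilomorph full --tps data/outlines.tps --metadata data/metadata.csv \
    --seed 1 --out-dir results/
```

`full` writes every result table as CSV plus a JSON manifest recording the
config, seed, selected harmonic count and retained variance fractions.
Real datasets digitized with tpsDIG2 (two curves per specimen) and a
metadata CSV with columns `id,species,order,period` are read the same way;
a column-mapping option adapts other table layouts.

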