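# Methods

## Outline model and assembly

A specimen enters the pipeline as two open digitized curves meeting at the
genal-spine tips (or, for spineless cephala, the posterolateral corners):
anterior (left tip → front → right tip) and posterior (right tip → rear →
left tip). Both are resampled to 64 semilandmarks at equal arc length by
piecewise-linear interpolation — no spline smoothing, so the resampler is
exactly idempotent up to the O(h²) chord/arc discrepancy and preserves
endpoints to machine precision.

Joining two 64-point curves that share both endpoints yields 126 distinct
points, while the digitization protocol counts 128 semilandmarks (each
curve's endpoints counted in both curves). We resolve this by merging each
duplicated junction pair into its average and resampling the merged closed
contour at equal arc length to exactly 128 points, anchored at the left
junction. This keeps the protocol's 128-point count, guarantees strictly equal
spacing around the whole outline (which the per-curve protocol only
approximates), and records both junction positions as anchor indices.
Winding is forced positive (counter-clockwise in y-up coordinates)
regardless of digitization direction. A junction gap larger than a
configurable fraction (default 1%) of the outline diameter is an assembly
error reporting the measured gap.

## Elliptic Fourier analysis

Coefficients are the exact integrals of the piecewise-linear contour
(Kuhl–Giardina form), not an FFT approximation: for each harmonic n,

aₙ = T/(2n²π²) Σᵢ (Δxᵢ/Δtᵢ)(cos φᵢ − cos φᵢ₋₁),   φᵢ = 2πn tᵢ/T,

and likewise bₙ (sine), cₙ, dₙ (y-series); A₀, C₀ are the exact arc-length
means. The parameterization is arc length by default. A `uniform` option
assigns each vertex an equal parameter step instead; the two coincide
exactly for equally spaced semilandmarks (i.e. for everything the pipeline
assembles), but the uniform option lets curves that carry their own
parameterization — e.g. an ellipse sampled evenly in its angular parameter,
for which the first harmonic is the exact closed form — be decomposed in
that parameter. Note that the arc-length EFA of an eccentric ellipse is
*not* a single harmonic (the 2:1 ellipse gives a first-harmonic ellipse of
≈1.83 × 1.07): the textbook "first harmonic = best-fitting ellipse"
statement is a property of the natural parameterization.

Reconstruction (`efa_inverse`) synthesizes at equally spaced parameter
values. Truncation error is monotonically nonincreasing in N; at the
Nyquist limit (N = K/2) the residual is the spectral tail of the
piecewise-linear interpolant — ~1e-7 relative for a smooth densely sampled
curve, ~1e-4 for a 128-vertex polygon (every vertex is a kink).

### Normalization

Size, rotation and starting point are standardized through the
first-harmonic ellipse: the parameter origin is shifted onto the semi-major
axis (phase θ), the shape is rotated so that axis lies along +x (angle ψ),
and all harmonics are divided by the semi-major length. DC terms are
zeroed; the divisor, rotation and shift are stored in a normalization
record, and a flag path (`pipeline.RunConfig.n_harmonics` + skipping
normalization via the `process --no-normalize` CLI route) supports
sensitivity checks without it.

The remaining 180° ambiguity (either end of the major axis) must be
resolved by a rule that is *continuous in shape*: any rule keyed to the
sign of a near-zero coefficient splits a cloud of similar specimens into
two antipodal clusters and wrecks every downstream group statistic (we
observed LDA diagonals collapse to ~0 under a lexicographic rule). We use
the skewness of the synthesized outline's y coordinate (falling back to x,
then to a lexicographic comparison for doubly symmetric shapes): skewness
negates under a half turn, and cephalon-like shapes — dome forward, spines
rearward — keep it stably nonzero. Reflection is deliberately not
standardized: cephala are digitized in consistent anatomical orientation.

Harmonic selection computes each specimen's cumulative power fraction over
64 harmonics (un-normalized coefficients) and takes the smallest N whose
mean across specimens reaches the threshold (default 99.9%).

## Morphospace

PCA is an eigendecomposition of the coefficient covariance matrix (no
correlation scaling — coefficient columns share units, and rescaling would
amplify noise-dominated high harmonics), with a deterministic sign rule
(largest-magnitude loading positive per axis) so scores are
bit-reproducible. Two components are retained for all downstream analytics
(hulls, centroids, disparity, MANOVA, LDA, k-means); the retained count is
configurable for sensitivity analyses. Convex hulls come from
scipy.spatial; groups with fewer than three distinct non-collinear points
are reported with zero hull area and flagged, never dropped.

## Disparity and tests

SoV is the sum of per-dimension sample variances (n−1 denominator), SoR
the sum of per-dimension ranges, both on retained-PC scores. Bootstrap
resamples each group with replacement at its observed size (no
rarefaction), 500 replicates by default, one seeded generator threaded
through every stochastic step; bootstrap SoR is inherently ≤ observed SoR.
Pairwise disparity comparisons are Welch t-tests between bootstrap
distributions (the groups' bootstrap spreads differ by construction) at a
Bonferroni-corrected α = 0.05 / C(g, 2). Location differences are tested
with one-way MANOVA, Pillai's trace by default (most robust to covariance
heterogeneity; Wilks' lambda via flag), using the standard approximate-F
transforms; the implementation is closed-form SSCP algebra, cross-checked
against statsmodels in the test suite, and its type-I error calibrates to
0.05 within ±0.02 over 1000 null simulations.

## Classification and clustering

The LDA cross-validation table is leave-one-out: each specimen is
predicted by a pooled-covariance Gaussian LDA fit on all the others, with
priors proportional to group size (uniform-priors flag available), and
proportions are tabulated true × predicted. Under label permutation the
mean weighted diagonal approaches Σ(n_g/n)², the proportional-prior chance
rate.

K-means scans k = 1..10 (25 restarts per k, seeded) and selects k by the
largest second difference of the within-cluster sum of squares, ties
toward smaller k; a manual override reproduces visually chosen elbows.
Per-period scans run on that period's rows of the *global* PCA scores —
never a refit — so per-period clusters are positioned in the common
morphospace. Cluster mean shapes are coefficient-wise means synthesized
back to outlines.

## Synthetic cephalon generator

The generator is a deliberately low-dimensional (seven-parameter)
abstraction, not an anatomical model: an anterior superellipse dome of
height L·W through the posterior corners (exponent blended by roundness r),
an optional posterolateral brim flare (maximal at the dome shoulders,
magnitude b·W), two triangular genal spines (length s·W, base w·W,
direction θ from straight posterior toward lateral), and a straight
posterior margin. Specimens are emitted as the two digitization curves,
radially jittered (Gaussian, sd as a fraction of W, endpoints fixed),
resampled and assembled through the standard pipeline — synthetic data
exercise exactly the code path real digitizations take. Draws whose jitter
self-intersects are rejected (cap 100 attempts); population parameters are
truncated-Gaussian within documented valid ranges.

Defaults of the study-scale preset: 983 specimens over 12 orders and 6
periods with strongly unequal group sizes (three orders under 40
specimens), per-order stratigraphic ranges (Redlichiida Cambrian-only;
only Proetida and Aulacopleurida reach the Carboniferous, only Proetida
the Permian), order mean shapes keyed to the qualitative contrasts of real
cephala (a long, brimmed, broad-spined harpid analogue; a narrow-spined
trinucleid analogue; short lichid/odontopleurid analogues; an
aulacopleurid–olenid–redlichiid morphogroup; a central
asaphid–corynexochid–phacopid–proetid–unassigned morphogroup), and
within-group spreads chosen once so that group-level SoV (~0.01–0.05), SoR
(~0.6–1.8) and hull areas (~0.03–0.5) have the order of magnitude typical
of digitized cephalic-outline datasets. Per-order counts are proportional
placeholders; radial jitter (0.004·W) stands in for digitization and
preservation noise.

What the generator does *not* emulate: real digitization error structure
(correlated along the outline, heavier near reconstructed librigenae),
taphonomic deformation, ontogenetic variation, within-order taxonomic
substructure, and the high-frequency outline detail of real cephala (real
datasets need more harmonics at 99.9% power than the ~6 the smooth
synthetic shapes require). Passing tests therefore demonstrate that the
machinery recovers known structure under controlled conditions, not that
any particular empirical dataset will behave identically.

## Numerical choices and degenerate inputs

Equal-arc-length targets are linear-interpolated on the cumulative chord
length; zero-length curves raise. Hull area of <3 distinct or collinear
points is 0 by convention. MANOVA requires each group n ≥ p+1 and LDA
n ≥ p+1 per group (errors name the offending group). The elbow rule needs
at least three scanned k values; otherwise the smallest k is returned.
Eigenvalues are clipped at zero before forming variance fractions. TPS
output uses shortest round-trip float representation, so
write → read → write is byte-idempotent, and result tables contain no
timestamps, so a rerun with the same seed and config is byte-identical.

## Known limitations

- First-harmonic normalization is unstable for shapes whose first
  harmonic is nearly circular; the skewness tie-break removes the discrete
  flip but the continuous orientation instability is intrinsic to the
  convention.
- The LDA table uses proportional priors, so rare groups are penalized —
  intended, as it models prediction of an unknown find from a realistic
  sampling, but it makes diagonals sample-size dependent.
- Bootstrap SoR is downward-biased (resampling cannot exceed the observed
  range); comparisons between groups of very different n inherit some of
  that bias.
- The elbow rule prefers conservative (small) k when WCSS decays smoothly;
  the manual override exists because visually chosen elbows on real data
  are often larger.
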