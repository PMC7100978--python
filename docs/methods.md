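# Methods

`mosaiq` quantifies genetic mosaics in confocal images of epithelial
tissues (the motivating system is the *Drosophila* larval eye disc): it
segments nuclei, removes spectral crosstalk between fluorescence channels,
and assigns each nucleus a clonal-marker gene dosage in {0, 1, 2} without
any training labels.  A growth simulator generates ground-truth mosaics so
the whole pipeline can be benchmarked quantitatively.

## Segmentation

The nuclear-stain channel is normalized by its maximum (making the result
invariant to bit depth and global gain), contrast-equalized by CLAHE
(clip 0.01, tile 64 px), Gaussian-smoothed (sigma 2 px) and Otsu
thresholded.  Watershed seeds are the local maxima of the Euclidean
distance transform of the foreground mask (minimum separation 5 px);
watershed on the negated distance transform, restricted to the mask,
yields one segment per nucleus.  Segments below 10 px are treated as
speckle and dropped.  All five parameters are exposed in
`SegmentationParams`; the defaults suit nuclei of roughly 8–15 px radius.
Mean pixel intensity per segment and channel is the per-nucleus
measurement; any external segmentation tool can substitute for this stage
by writing the same measurement table.

## Bleedthrough correction

The background intensity of a target channel is modelled as a linear
superposition of the other channels plus an offset,
`B = sum_k alpha_k F_k + beta`.  Coefficients are estimated from
background pixels only: the foreground mask is dilated (3x3 disk) until
its per-iteration growth falls below 1% (at most 20 iterations), the
remaining pixels are resampled so the source-channel intensity histogram
is approximately uniform over 10 equal-width bins (default 100 000 draws,
seeded) — background intensities are heavily right-skewed and would
otherwise dominate the fit at low intensities — and a gamma-family GLM
with identity link is fitted to the resampled pixels (IRLS via
statsmodels, ordinary least squares as fallback on pathological
backgrounds).  Per-nucleus correction subtracts the predicted background
from the measured mean.  Corrected values may be negative and are kept:
clipping here would bias downstream group comparisons; the annotation
stage handles positivity explicitly.

## Clone annotation

Let `x_i` be the (corrected) clonal-marker level of cell `i` and
`X_i = ln x_i` (values at or below a floor of 1% of the positive median
are clipped to that floor before the log).

1. **Correlation length.** The radial correlation function
   `psi(delta) = <(X_i - mu)(X_j - mu)> / var(X)` is estimated over 200
   equal-count separation bins (pairs capped at 5·10^5 by seeded
   subsampling) and smoothed with a 5-bin moving average.  The decay
   length is the 1/rate of a least-squares exponential fit, bounded by
   the span of observed separations; a bound-saturated fit (flat,
   structureless curve) falls back to the first 1/e crossing.  The bin
   count sets the shortest resolvable scale — the first-bin distance
   quantile — and 200 bins are needed to resolve correlation lengths near
   the cell spacing, where small clones live.
2. **Context.** `Y_i` is the mean of `X` over all cells within the decay
   length of cell `i` (excluding `i`; isolated cells fall back to their
   own value).  The radius is floored at twice the median
   nearest-neighbor spacing: a sub-spacing radius would leave every cell
   neighborless, collapse `Y` onto `X`, and let the diagonal-covariance
   mixture degenerate on the `X = Y` line.
3. **Mixture.** For K = 3…8 a K-component bivariate normal mixture with
   diagonal covariances is fitted to `(X, Y)` by EM (k-means
   initialization, 5 jittered restarts, 500 iterations max, tolerance
   1e-6 on the log-likelihood, seeded).  A run in which a component's
   effective count drops below two observations is discarded as
   degenerate (a likelihood spike on a single point); component variances
   are floored at 1e-6 of the overall variance so genuinely tight
   components survive.  Restarts stay in the k-means basin deliberately:
   on high-ambiguity data, wider random restarts reach higher-likelihood
   optima that tile the density without tracking dosage structure.  The
   model minimizing `BIC = ln(N) q_K - 2 ln L`, with `q_K = 5K - 1` free
   parameters for the diagonal bivariate model, is selected.
4. **Component → dosage map.** The component means `e^mu` (X axis) are
   clustered into three groups by 1-D k-means *weighted by the mixture
   weights*; groups in ascending order map to dosages 0, 1, 2.  Weighting
   matters: an unweighted clustering can absorb a heavy central component
   into the low-expression group when a few light components sit below
   it, mislabeling the bulk of the tissue.  The label count is
   configurable (2 for binary mutant/non-mutant mosaics).
5. **Cell graph.** Delaunay edges over the centroids, dropping edges above
   the 95th length percentile, weighted by expression similarity
   `w_ij = exp(-|X_i - X_j| / <|dX|>)`.
6. **Communities.** Infomap partitions the weighted graph; coarser levels
   are built by re-running Infomap on the quotient graph of communities
   (aggregated weights), with a greedy strongest-pair merge whenever it
   stops coarsening.  The chosen level is the coarsest whose mean
   community spatial extent (twice the RMS distance to the community
   centroid) stays below the correlation length.  The community mean of
   `X` replaces the radius-based context at application time; if the
   partition degenerates to singletons, the radius-based context is kept.
7. **Diffusion.** Component posteriors `p(k | X_i, Y_i^c)` diffuse across
   the graph through the Katz-style linear system
   `p_hat = (I - alpha W)^{-1} (1 - alpha) p`, solved by sparse LU and
   renormalized per cell (the linear map does not preserve
   row-stochasticity; the argmax is unaffected but confidences need a
   probability scale).  The attenuation defaults to `0.9 / rho(W)`, which
   guarantees invertibility.
8. **Labels and fallback.** Each cell gets `f(argmax_k p_hat)` with
   confidence equal to the diffused posterior mass of the winning dosage.
   Labels with confidence below 0.80 are replaced by the marginal
   classifier — `f(argmax_k p(k|X))` using the X-axis marginal of each
   component, ties toward the lower component index — which protects
   cells whose spatial context is uninformative (small or fragmented
   clones).

One model is trained per image by default, matching the per-replicate
training used in the benchmark; pooled training across images is possible
by concatenating tables.

## Curation and statistics

Clone borders are cells with at least one Delaunay neighbor (same
edge-length filter as the cell graph) of different dosage; they are
excluded from expression comparisons by default since border cells are
exposed to non-autonomous signals from the adjacent clone.  A polygonal
region of interest (even-odd rule, boundary inside) and an x-axis window
restrict comparisons to cells of comparable developmental context.
Dosage groups are compared by two-sided Mann-Whitney U (exact null for
group sizes up to 20 without ties, normal approximation with tie
correction otherwise); the reported U is the min-orientation statistic.

## Growth simulator

A culture grows from one heterozygous cell by synchronous stochastic
division (probability 0.2 per cell per round).  Mitotic recombination
(probability 0.2 per division of a dosage-1 parent) produces daughter
dosages (2, 0) instead of (1, 1); dosage-0/2 lineages are sealed.  The
recombination window opens when the population first reaches
`recombination_start_size` (default 16) and lasts
`recombination_duration` generations (default 4); growth stops when the
population exceeds `final_size` (default 2048).  These defaults mirror
the benchmark conditions; the window parameters are the handle on clone
number and size (later onsets give more, smaller clones).

After each round, positions relax on a spring network over the Delaunay
triangulation: edges of hull-adjacent sliver triangles (any interior
angle above 150°) are removed, the rest length is the median edge length,
same-dosage springs are 10% stiffer (keeping clonal siblings cohesive),
and positions update force-directed for 50 damped iterations — enough to
keep the nearest-neighbor distance coefficient of variation below 0.5
(approximately uniform density) at every population size we simulate.

Fluorescence is sampled per cell as `ln x ~ N(mu_n, sigma_alpha^2)` with
`mu_n = ln 2^(n-1)`: the mean doubles per gene copy, and `sigma_alpha`
(default 0.25, a mid-range ambiguity) controls the overlap between dosage
distributions.  An optional dosage-independent control reporter can be
co-sampled with an injected linear crosstalk coefficient to exercise the
bleedthrough stage end to end.  Cultures can be rendered as two-channel
images of uniform-radius disks (stain uniform, marker shaded by level,
optional Gaussian read noise) to exercise segmentation.

## What the simulator does and does not emulate

It reproduces the features the annotation algorithm relies on: clonal
spatial cohesion, tunable clone size/number, dosage-conditioned lognormal
expression, roughly uniform cell density, and linear spectral crosstalk.
It does not model 3-D tissue structure, cell death, size/shape variation
of nuclei, spatially varying background, autofluorescence, or optical
blur between neighboring nuclei.  Passing benchmarks therefore bound
performance under idealized geometry and noise; on real images,
segmentation error and structured background add error sources the
benchmark does not measure.

## Benchmark

Performance is scored by the mean absolute error over the ordered dosage
labels (a 0↔2 confusion costs twice an off-by-one) and by accuracy, for
both the full annotator and the marginal classifier, with a freshly
trained model per replicate and borders not excluded (a lower bound on
curated performance).  The desk-scale grid is 4 recombination-window
levels × 4 ambiguities × 10 replicates at 2048 cells; clone size is
reported as the realized mean cells per clone.  Tests use smaller
cultures (512–2048 cells) and fewer replicates per condition, chosen so
each property is measured at the smallest size where it is stable.

## Numerical choices and edge cases

- Constant images raise a degenerate-threshold error; constant expression
  fields raise a zero-variance error.
- EM ties and posterior argmax ties break toward the lower component
  index for reproducibility.
- Diffusion refuses attenuation values with `alpha * rho(W) >= 1`.
- All stochastic steps (pair subsampling, resampling, EM restarts,
  Infomap, simulation) consume explicit seeds; a culture grown twice from
  the same seed is bitwise identical.

## Known limitations

At high fluorescence ambiguity (sigma_alpha around 0.5 and above) the
mixture likelihood no longer identifies the dosage partition reliably:
EM solutions that tile the nearly unimodal density can beat mode-aligned
solutions in likelihood, and occasional replicates are annotated largely
wrong even with the safeguards above.  This tracks the method's published
operating envelope — annotation is meant for experiments designed to
produce large clones with moderate ambiguity — but it means per-replicate
results in the hardest benchmark corner have heavy-tailed error.
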