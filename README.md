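# mosaiq

Quantitative analysis of genetic mosaics in confocal images of epithelial
tissues, built around the *Drosophila* imaginal disc workflow: mitotic
recombination produces clones carrying 0, 1 or 2 copies of a fluorescently
tagged clonal marker, and the question is whether a reporter of interest
differs between those clones.  Answering it quantitatively requires
segmenting nuclei, correcting spectral bleedthrough between channels,
labeling every nucleus with its marker gene dosage, and comparing curated
groups statistically.  `mosaiq` automates all four steps and ships a
ground-truth simulator to benchmark them.

## The annotation model

For each nucleus, let `x` be its (bleedthrough-corrected) clonal-marker
level and `X = ln x`.  Expression within a dosage class is lognormal, so
the tissue-wide distribution is a mixture of normals in `X`.  Because the
three classes overlap, `mosaiq` augments `X` with a spatial context
`Y` — the mean of `X` over the cell's neighborhood, with the neighborhood
radius estimated from the exponential decay length of the radial
correlation function `psi(delta)` — and fits K-component diagonal
bivariate normal mixtures

    p(X, Y) = sum_k  lambda_k N(X, Y | mu_k, sigma2_k),      K = 3 ... 8

by EM, selecting K with `BIC = ln(N) q_K − 2 ln L`.  Components map onto
dosages {0, 1, 2} by weighted 1-D k-means of their linear means `e^mu`.
At application time the context is recomputed over Infomap communities of
a Delaunay cell graph whose edges are weighted by expression similarity
`w_ij = exp(−|X_i − X_j| / ⟨|ΔX|⟩)`, and the component posteriors diffuse
across that graph through a Katz-style system
`p̂ = (I − αW)⁻¹(1 − α) p` before each cell takes the most probable
dosage.  Labels with confidence below 0.8 fall back to a marginal
classifier that uses `X` alone.  Bleedthrough coefficients come from a
gamma GLM (identity link) fitted to resampled background pixels; group
comparisons use the two-sided Mann-Whitney U test after excluding clone
borders.  See `docs/methods.md` for the full account.

## Worked example

Simulate a mosaic culture, synthesize fluorescence, annotate it, and
compare the marker between homozygous clones:

```python
import mosaiq as mq

params = mq.GrowthParams(final_size=1024, recombination_start_size=16)
culture = mq.grow_culture(params, seed=7)
table = mq.synthesize_measurements(
    culture, mq.FluorescenceParams(sigma_alpha=0.2), seed=8
)
labeled, result = mq.annotate_detailed(
    table, mq.AnnotationConfig(marker_channel=1, seed=0)
)
scores = mq.score_labels(labeled)
print(f"cells: {len(labeled)}  clones: {mq.mean_clone_size(culture):.0f} cells/clone")
print(f"mixture: K={result.model.K} (BIC {result.model.bic:.0f}), "
      f"dosage map {result.model.dosage_map.tolist()}")
print(f"accuracy vs ground truth: {scores['accuracy']:.1%}  MAE: {scores['mae']:.4f}")

flagged = mq.flag_borders_table(labeled)
print(mq.compare_clones(flagged, 1, 0, 2, exclude_borders=True))
```

prints

```
cells: 1168  clones: 167 cells/clone
mixture: K=4 (BIC -1960), dosage map [2, 1, 0, 1]
accuracy vs ground truth: 98.0%  MAE: 0.0197
dosage 0 (n=11) vs dosage 2 (n=17): U=0.0, p=9.31e-08
```

The mixture found four components; two of them (the dosage map's two 1s)
jointly model the heterozygous class.  98% of 1168 nuclei get the correct
gene dosage, and the marker level differs decisively between the
homozygous-null and homozygous-wildtype clones once border cells are
excluded.

The same stages are available from the shell for data organized as
`experiment/disc_<i>/layer_<j>/`:

```sh
mosaiq simulate --final-size 2048 --sigma-alpha 0.25 --out culture/
mosaiq segment  <layer_dir> --stain-channel 0
mosaiq correct  <layer_dir> --target 2 --sources 1
mosaiq annotate <layer_dir> --marker-channel 1
mosaiq curate   <layer_dir> --exclude-borders
mosaiq compare  <experiment_dir> --channel 2 --groups 0,2
mosaiq benchmark --grid small --replicates 10 --out results.csv
```

Measurement tables are plain CSV with columns `cell_id, x, y, ch<i>, ...`,
so output from any external segmentation tool drops into the downstream
stages unchanged.

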