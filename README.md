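# matfet

Maternal vs fetal origin assignment for single cells at the placental
maternal–fetal interface, from sparse scRNA-seq SNV observations.

## The problem

Tissue sampled across the maternal–fetal interface (fetal side FS, middle
Mid_S, maternal side Mat_S) is a mixture of two genomes: maternal (decidual)
cells and fetal (trophoblast-derived) cells. The fetus carries paternal
alleles the mother lacks, so the sparse single-nucleotide variants visible in
each cell's reads identify its genome of origin — if the noise, sparsity and
thresholds are handled carefully. `matfet` implements that assignment as a
reusable, fully tested pipeline, together with the variant hard filters,
single-cell QC fences and expression-prevalence rules of the surrounding
workflow, and a synthetic trio/cell simulator so every stage can be verified
without any sequencing data.

## The classifier

For each cell, and each fetal SNP reference panel *p* (consensus genotypes
built from umbilical-cord data or any fetal genotype source), the
**difference ratio** is

&nbsp;&nbsp;&nbsp;&nbsp;TstX<sub>cell,p</sub> = (# covered panel sites whose
observed allele disagrees with the panel) / (# covered panel sites).

Training cells with known origin (e.g. from an external genetic
demultiplexer) give two class summaries in this feature space — fetal
centroid/covariance (μ₁, S₁) from the fetal rows, maternal (μ₂, S₂) from the
maternal rows (column means and sample covariances). Each cell is scored by
the ratio of squared Mahalanobis distances

&nbsp;&nbsp;&nbsp;&nbsp;Ratio = D²(TstX; μ₂, S₂) / D²(TstX; μ₁, S₁),

oriented so fetal cells land on the low end, and thresholded by two
discriminant cuts chosen on a candidate grid to maximise training accuracy
(ties broken by Youden's J): Ratio below the fetal cut ⇒ fetal, above the
maternal cut ⇒ maternal, otherwise — or with too few covered sites — unknown.

Also included, with comparisons exactly as printed (strict `<` / `>`,
missing annotations never fire):

* hard-filter profiles `wgs_site` (QD < 2.0 ‖ MQ < 40.0 ‖ FS > 200.0 ‖
  SOR > 10.0 ‖ MQRankSum < −12.5 ‖ ReadPosRankSum < −8.0) and `cell_snv`
  (DP < 6 ‖ QD < 2.0 ‖ MQ < 40.0 ‖ FS > 60.0 ‖ SOR > 3.0 ‖ the same
  rank-sum cuts) plus a 35-bp / 3-SNP cluster window;
* expression QC: genes in < 0.1% of cells removed; cells with < 800
  detected genes or > 10% mitochondrial counts removed; per-library Tukey
  fences (1.5 × IQR) on detected genes flag potential doublets;
* highly-expressed genes (prevalence > 20%, CV < 1, mean > 0), one-vs-rest
  Wilcoxon rank-sum markers (BH-adjusted p < 0.05, log fold change > 0.25),
  and ligand–receptor calls at > 40% prevalence in each of two *distinct*
  cell types.

## Worked example

```python
from matfet import (simulate_trio_genotypes, simulate_cell_allele_counts,
                    panels_from_cord_cells, compute_difference_ratios,
                    CellOriginModel, evaluate_calls)

trio = simulate_trio_genotypes(n_sites=5000, informative_fraction=0.3, seed=11)
cord = {f"cord{k}": simulate_cell_allele_counts(
            trio, 300, fetal_fraction=1.0,
            sites_per_cell={"dist": "negbin", "mean": 150, "dispersion": 30},
            error_rate=0.01, seed=100 + k)
        for k in range(3)}
reference = panels_from_cord_cells(cord, min_support=3)

obs = simulate_cell_allele_counts(trio, 600, fetal_fraction=0.5,
                                  error_rate=0.01, seed=7)
drm = compute_difference_ratios(obs, reference, min_sites=10)

model = CellOriginModel(drm, obs.truth.iloc[:300])   # train on half
res = model.fit()
print(res.summary())
calls = res.predict(drm).iloc[300:]                  # classify the rest
print(evaluate_calls(calls, obs.truth.iloc[300:]))
```

The summary reports three panel features, orientation `inverted` (the raw
distance ratio puts fetal cells high, so the reciprocal is used), fetal and
maternal centroids near 0.15 and 0.61, and coincident discriminant cuts at
0.7086 with training sensitivity 0.978 / specificity 0.994 / accuracy 0.986.
On the held-out 300 cells this run prints

```
{'n': 300, 'n_called': 284, 'unknown_fraction': 0.053,
 'sensitivity': 0.958, 'specificity': 0.993, 'accuracy': 0.975, ...}
```

i.e. 284 cells receive a confident call, 97.5% of them correct, with 5.3%
left unknown — cells whose ratio falls between the cuts or that cover fewer
than 10 reference sites.

The same run is available end to end from the shell:

```bash
matfet run --seed 11 --out-dir demo_run      # writes calls, model, manifest
matfet simulate trio --n-sites 5000 --out trio.vcf
matfet filter-variants --vcf calls.vcf --out filtered.vcf --profile cell_snv
```

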