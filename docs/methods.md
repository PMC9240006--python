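# Methods

## Scope and model

`matfet` assigns single cells of a mixed maternal–fetal tissue to their
genome of origin from sparse per-cell SNV observations. The classifier is a
two-class Gaussian summary in *difference-ratio* space with a
Mahalanobis-distance-ratio decision statistic and empirically calibrated
three-way thresholds. Around it sit the standard workflow stages it assumes:
rule-based variant hard filtering, scRNA-seq quality control, and
expression-prevalence analyses. A synthetic-data module generates every
input the analysis consumes, so the package is testable end to end with no
sequencing data.

## Difference-ratio features

For each cell and each fetal reference panel, the feature is the fraction of
the cell's covered panel sites whose observed allele disagrees with the
panel. Two disagreement definitions are implemented (`mode=` in
`compute_difference_ratios`):

* **alt_support** (default): a covered site is discordant when the observed
  allele fails to support the panel's variant call — differs from the panel
  ALT where the panel carries the ALT, and from REF at a hom-ref site. This
  is the definition under which maternal cells, which lack the
  fetus-specific ALT at informative sites, accumulate discordance against a
  *fetal* reference. It is the package default because it is the only
  definition that gives the classifier signal in this direction: under
  biallelic Mendelian inheritance, a site where the fetus carries an allele
  the mother lacks forces the mother homozygous-REF and the fetus
  heterozygous, so the mother's REF allele is always *present* in the fetal
  genotype pair and presence-based discordance at exactly the informative
  sites is identically zero.
* **allele_presence**: discordant when the observed allele is absent from
  the panel's diploid genotype pair. Useful for genotype-level audits (an
  error-free fetal cell scores exactly 0 against its own full genotype); not
  the default for the reason above.

Features default to one column per reference panel — the panel multiplicity
(three umbilical-cord references in the motivating design) is the natural
multivariate structure for the column-mean/covariance estimates — with a
per-chromosome alternative (`features="chrom"`).

## The origin model

Training cells with external origin labels give
μ₁ = colMeans, S₁ = sample covariance of the fetal rows of the feature
matrix, and μ₂, S₂ of the maternal rows. A cell x is scored by

    Ratio(x) = D²(x; μ₂, S₂) / D²(x; μ₁, S₁),

the ratio of squared Mahalanobis distances. Squared distances are the
default convention; the ratio of squares is a monotone transform of the
ratio of plain distances and the cuts are calibrated on the same scale, so
calls are identical either way (`squared=False` is available, and a test
asserts call-for-call identity).

**Orientation.** Written as above, cells far from the maternal class — fetal
cells — get *large* ratios, while the three-way decision rule calls *small*
ratios fetal. The fit resolves this empirically: if the median raw ratio of
labelled fetal cells exceeds the maternal median, the reciprocal is used and
the model records `orientation="inverted"`. Both the formula and the rule
are thereby preserved, and the flag makes the applied reading auditable.

**Regularisation.** Class covariances get a ridge of 1e−6 · trace(S)/dim by
default — panels built from the same fetal genome are nearly collinear, so
the raw covariances are close to singular; the ridge is small enough to
leave well-conditioned problems untouched (the Mahalanobis oracle check
passes at 1e−10 relative tolerance with ridge 0). A zero ridge with a
zero-variance feature is refused with a training error.

**Thresholds.** Candidate cuts default to the percentile grid of the
training ratios. At each cut the two-way rule (below ⇒ fetal) is tabulated
into sensitivity, specificity and accuracy with fetal as the positive class.
The selection criterion is maximum accuracy with ties broken by Youden's J
(`criterion="youden"` swaps the order). Ranking is done on integer confusion
counts — accuracy orders as TP+TN and Youden's J as TP·N + TN·P for fixed
class sizes — so selection is exactly reproducible and float ties cannot
reorder candidates. The fetal cut is the smallest optimal cut, the maternal
cut the largest; consequently fetal_cut ≤ maternal_cut always, the band
between them is called unknown, and the full metrics table is kept on the
results object for audit.

**Calls.** Oriented ratio < fetal cut ⇒ fetal; > maternal cut ⇒ maternal;
otherwise unknown. Cells in which no feature reaches `min_sites` (default
10) covered sites are unknown regardless of ratio. A denominator below 1e−12
caps the ratio at `cap` (default 1e6). Evaluation treats fetal as positive,
excludes unknown calls from sensitivity/specificity/accuracy, and reports
the unknown fraction separately — the three-way rule otherwise leaves
accuracy undefined; both choices are configurable in reporting terms since
the confusion table is returned whole.

## Variant hard filters

Two built-in profiles encode the printed filtration expressions: `wgs_site`
(QD < 2.0, MQ < 40.0, FS > 200.0, SOR > 10.0, MQRankSum < −12.5,
ReadPosRankSum < −8.0) and `cell_snv` (DP < 6 plus QD/MQ as above,
FS > 60.0, SOR > 3.0, the same rank-sum cuts, and a 35-bp/3-SNP cluster
window). Semantics follow the tool those expressions are written for: OR of
single predicates, strict comparisons exactly as printed (QD = 2.0 and
DP = 6 pass), and a missing annotation never fires — the only reading that
keeps records lacking rank-sum annotations usable. DP is read from the
site-level depth field (configurable in the record construction), since the
expression is applied in a single per-cell filtration step. The cluster
window flags a variant iff it belongs to ≥ 3 variants spanning ≤ 35 bp
(max − min + 1) on one chromosome, computed by an O(n) sliding window over
sorted positions and verified against an O(n²) all-windows brute force;
unsorted input is an error, never silently re-sorted. Failing VCF records
are tagged in FILTER, not deleted (`--drop-failing` opts out).

## Expression QC and prevalence rules

All comparisons are strict as stated: genes detected in < 0.1% of cells are
removed (a gene at exactly 0.1% stays); cells with < 800 detected genes or a
mitochondrial count fraction > 10% are removed (800 genes and exactly 10%
stay); per library, detected-gene counts outside Tukey fences
(quartiles ± 1.5 × IQR, linear-interpolation quartiles) are removed, with
high-side outliers labelled potential doublets. The declared order is gene
prevalence → cell QC → fences; the QC report records shapes, thresholds,
per-reason removals at every step. Filters are idempotent.

Normalisation for CV/mean and markers is counts-per-10k + log1p, recorded in
every report. Highly-expressed genes require prevalence > 20%, CV < 1
(sd/mean of normalised expression, sample sd) and mean > 0; zero-mean genes
are excluded arithmetically, never by a division error. Markers use a
two-sided one-vs-rest Mann–Whitney U per gene with Benjamini–Hochberg
adjustment across genes within each group; the fold change is
ln(mean_in + 1) − ln(mean_out + 1) on normalised expression (pseudocount 1,
natural log — the marker-finder convention; the 0.25 cut's log base is not
otherwise determined). Constant genes get p = 1 by convention.
Ligand–receptor pairs are called for every ordered pair of distinct cell
types when ligand and receptor each exceed 40% prevalence in their
respective type; same-type pairs are never emitted; pair genes missing from
the matrix are skipped with a warning.

## Synthetic data: what it emulates, and what it does not

The trio generator flags each site informative with probability
`informative_fraction`; informative sites are built mother 0/0 with a
paternally transmitted ALT (fetus 0/1) — the only biallelic configuration in
which the fetus carries an allele the mother lacks. Other sites draw the
mother from Hardy–Weinberg proportions at the site's minor-allele frequency
(default U(0.1, 0.5), a common-SNP panel range) with the paternal
transmission constrained so the fetal pair stays within the maternal allele
set. Every trio is Mendelian-consistent by construction and checked
site-by-site in tests.

Cell observations model per-cell variant calling: a cell covers a
negative-binomial number of sites (default mean 30, dispersion 30), each
covered site has depth 1 + Poisson(mean_depth − 1) reads drawn from the
individual's allele dosage with symmetric per-read error flips (default 1%),
and the recorded allele is ALT iff at least one read supports the ALT. With
error 0 the observation is provably one of the individual's own alleles.
Cord-style reference panels are deeper draws of the same process
(3 panels × 300 fetal cells × ~150 sites by default); their consensus caller
uses asymmetric evidence thresholds (ALT present above 20% ALT observations,
REF present above 8% REF observations) because variant-supporting reporting
depletes REF observations at heterozygous sites.

Not emulated: doublets, ambient RNA, allele-specific expression, mapping
bias, linkage between sites, and any read-level realism (no FASTQ, no
alignment). Passing tests therefore demonstrate the statistical machinery is
correct under the stated generative assumptions, not that real placental
data meets those assumptions; per-cell coverage and SNV density in
particular are parameters, not facts.

The variant-record generator draws every annotation below, at and above its
profile threshold (plus missing values) so both sides of every boundary are
exercised; the expression generator gives exact control of per-cell detected
genes and mitochondrial fractions so planted QC violators are recoverable by
construction.

## Numerical and reproducibility choices

* All generators are deterministic given their seed; the pipeline fans one
  top-level seed out per stage via SeedSequence keyed on a stable digest of
  the stage name, so stages re-run in isolation.
* Mahalanobis quadratic forms are computed by linear solve (no explicit
  inverse), clipped at 0 against round-off; singular ridged covariances
  raise with a diagnostic rather than returning garbage.
* Low-coverage cells are flagged, never dropped, in the feature matrix;
  NaN features (no covered site in a panel) are treated as 0 at model time.
* Reference-panel consensus ties (no strict majority) exclude the site.
* The run manifest records SHA-256 digests of every stage output; two runs
  with the same config are byte-identical (asserted in tests).

## Problem sizes

The reference experiment used throughout tests and the acceptance script —
a 5,000-site trio, 30% informative sites, three cord panels, 600 balanced
cells at ~30 covered sites and 1% error, trained on 300 cells and evaluated
on the held-out 300 — was chosen as the smallest configuration in which all
pipeline stages operate in their intended regime; it completes in seconds.

## Known limitations

* With a single informative-site direction, classifier power depends on the
  alt_support difference definition; allele_presence mode on the same data
  separates only through natural mother-het/fetus-hom sites and is weaker.
* Thresholds are selected on the training grid; ratios outside the observed
  training range are classified by the nearest cut, which is conservative.
* The consensus caller assumes biallelic sites and the variant-supporting
  observation convention; genotype calls from other observation models
  should be supplied via `build_fetal_reference` directly.
* Sections are modelled independently (per-section models and cuts); the
  pooled alternative is a deliberate non-default.
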