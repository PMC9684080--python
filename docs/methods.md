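# Methods

`scaakit` implements the bespoke computational stages of a multi-region,
single-gland multi-omic analysis of colorectal tumours: purity estimation
from ATAC reads, low-pass copy-number fitting, copy-number-aware detection
of somatic chromatin accessibility alterations (SCAAs), TF-binding-site
footprint analysis, and region-stratified mutational-signature activity
estimation. All stages are exercised on a synthetic gland-cohort generator
with fully known ground truth; this note records the models, the defaults
and why, and what the synthetic data do and do not establish.

## Purity from ATAC allele counts (`scaakit.purity`)

At a clonal somatic SNV with multiplicity `m` (mutated copies per tumour
cell) and tumour copy number `c`, a read from a sample of purity `rho`
carries the alternative allele with probability

    p(rho) = rho * m / (rho * c + 2 - 2 * rho),

the `2 - 2 rho` term being the two reference copies of the contaminating
normal cells. The per-sample purity minimizes the summed binomial negative
log likelihood of the observed alt counts over sites. We use an exhaustive
grid (default step 0.001) rather than a derivative-based optimizer: with
few informative sites the likelihood can be almost flat near 0, and the
grid guarantees the global optimum to step resolution. Ties break toward
smaller `rho`. A 95% interval is read off the profile likelihood at the
chi-square(1) half-width 1.92; the interval is our addition (point
estimates would suffice for the downstream purity > 0.4 gate).

Defaults: sites with depth < 5 are excluded (ATAC coverage at a single SNV
is low and shallow sites carry almost no information; the floor is
configurable); sites with `c = 0` (homozygous deletions) are excluded and
counted, since `p` is undefined there at `rho = 1`.

## Low-pass copy number (`scaakit.cna`)

Per-sample 500-kb binned log2 coverage ratios are median-centred and then
segmented jointly across all samples of a patient: breakpoints are shared,
per-sample means are free. We minimize summed squared error plus a penalty
per breakpoint (default 10), computed by exact dynamic programming per
contig up to 300 bins and greedy binary segmentation beyond. Because the
penalty should not depend on the data scale, each sample is standardized
by a robust noise SD estimated from successive bin differences
(`1.4826 * median|diff| / sqrt(2)`) before the cost is evaluated — jumps
are sparse, so successive differences reflect noise, not copy-number
steps. On noise-free data the noise estimate collapses and any true jump
is recovered exactly.

Segment means `r` are inverted to continuous copy number with the
standard sequencing-data mixture relation (gamma = 1):

    n_cont = (2^r * (2(1-rho) + rho * psi_t) - 2(1-rho)) / rho,

where the integer tumour ploidy `psi_t` is a required input (from paired
deep WGS in real use; ground truth in simulations). The purity grid runs
from 0.1 to 1 in steps of 0.01; the goodness of fit at each `rho` is the
bin-length-weighted squared distance of `n_cont` to the nearest
non-negative integer. The chosen purity is the best strict local minimum
(ties toward higher purity, avoiding degenerate sub-clonal
interpretations at `rho/k`); with no local minimum — e.g. a flat diploid
genome — purity defaults to 1. Negative integer states are clamped to 0.

One numerical addition: median-centring leaves a small systematic offset
whenever the gained and lost genome fractions are unbalanced (the median
bin then sits off-centre within the neutral noise mass). `fit_purity`
therefore profiles out a re-centring offset within ±0.08 log2 units
(step 0.005) jointly with the purity. Without it, purity estimates carry
a bias of several grid steps on realistic aneuploid genomes.

## SCAA detection (`scaakit.scaa`)

Fragments are reduced to Tn5 cut sites by shifting forward read starts by
−4 and reverse read starts by +5 — note this follows the source
convention used throughout this pipeline, which is the mirror image of
the more common +4/−5 convention; the two differ only by a 1-bp offset in
opposite directions. Fragments ≤ 100 bp are nucleosome-free, 180–620 bp
nucleosome-associated; sizes in between join neither track.

Per-region peak calls (an input boundary — peak calling itself is
external) are filtered at q < 0.1%, enrichment > 4, top 20,000, then
merged iteratively: the most significant remaining peak absorbs every
overlapping call and stands as the representative, until no overlaps
remain. This is *not* transitive overlap clustering: in an A–B–C chain
where only B overlaps both, the far end survives as its own
representative. Retained peaks are those supported by more than 2 tumour
regions or by the panel of normals. "Promoter" means TSS distance
≤ 1,000 bp for the recurrence analysis; general annotation uses
±3,000 bp; both are named constants.

Counts are normalized with TMM size factors (pseudo-count 0.5 for zeros;
reference sample = upper quartile closest to the mean upper quartile;
factors include the library-size component and are normalized to
geometric mean 1). This is a simplification of the singleton-pairing TMM
variant with the same invariances.

The per-peak test is a negative-binomial GLM with log link, fixed global
dispersion, and offset = size factor × copy-number adjustment

    (2(1-rho) + pi*rho) / (2(1-rho) + psi*rho),

comparing each patient's glands (purity > 0.4, ≥ 2 glands) against the
pooled normals by likelihood-ratio test. The GLM is implemented in-house
(IRLS; a Newton solver on the group-wise score equations for the
two-group case), with the global dispersion estimated by maximizing the
profile likelihood across peaks. Exact numerical agreement with any
published count-model package is a non-goal; calibration is the contract
(type-I error at p ≤ 0.01 is measured at ≈ 0.010–0.013 on 2,000 null
peaks). Note that with a fixed dispersion the likelihood is not
scale-free: rescaling all offsets leaves (lfc, p) unchanged, but doubling
counts and offsets together preserves only the fold change — the larger
counts genuinely carry more information.

Recurrence: significant (p ≤ 0.01) same-direction calls in at least
`ceil(min_frac × n_cases)` patients (default 20%). The printed "4 of 26"
threshold corresponds to `min_frac = 4/26`; `ceil(0.2 × 26)` would be 6 —
both behaviours are reachable through `min_frac`.

Subclonality: nested NB models `~purity + region` vs `~purity` with
same-region glands as biological replicates (≥ 2 regions with ≥ 2
samples, else untestable), BH correction across tested events, direction
agreement with the bulk-level call, and — for gains — a called peak
within 500 bp. The affected-region pattern is read off the sum-centred
region coefficients split at the midpoint of their range; for the planted
3-fold two-of-four-region effects this recovers the exact pattern in
> 95% of replicates.

Expression association uses the same NB machinery: altered vs non-altered
patient groups (normals their own level), library-size offsets, Wald
contrast, one-sided for promoters in the direction of the accessibility
change, BH across genes. Expressed-gene filtering keeps genes with ≥ 10
TPM in ≥ 5% of tumour samples and then removes genes whose log expression
falls significantly with purity (negative slope, FDR < 0.05, patient as a
fixed covariate) — those track normal contamination, not tumour biology.

## TF footprints (`scaakit.footprint`)

For each TF, insertions (both cut sites of every fragment) within ±1 kb
of the motif centres are tabulated into a 5-bp insertion-size ×
1-bp distance matrix, with distances flipped for minus-strand sites (the
orientation convention is ours; it keeps asymmetric footprints
coherent). Each size row is divided by the genome-wide count of
insertions of that size, and the per-row mean over the 750–1,000-bp
flanks is subtracted, so a signal-free matrix is ≈ 0 everywhere. The
differential signal of a sample against the read-weighted pooled normal
matrix is the sum over the central block (sizes 25–120 bp, distances
within ±100 bp).

Signals are regressed on `tsse * tsse_nf + purity:patient` (or
`purity:region`), weighted by the square root of the read count; the
purity-interaction coefficients are the per-patient TF summaries, their
WLS t-statistics the significance. The 150 TFs most frequently
significant are clustered (Euclidean, complete linkage).

Site bookkeeping: strata are TSS-distance classes (proximal ≤ 2 kb,
close ≤ 10 kb, distal) crossed with peak overlap; same-TF sites closer
than 1 kb are removed (homotypic clusters would let one locus drive a
TF's genome-wide signal).

## Mutational signatures (`scaakit.signatures`)

Exposures of fixed 96-channel signatures are fitted to
frequency-normalized catalogues by non-negative L1-regularized least
squares (coordinate descent; default λ = 0.025), reported normalized to
sum 1. Patient clustering applies k-means (default k = 6; the analysis
also supports 5 — the appropriate number is data-dependent) to the rows
of the 1 − cosine exposure similarity matrix.

Region-stratified activities are estimated by repeated jackknife
sampling: 100 iterations, each aggregating a random 90% of a cluster's
samples per region class, normalizing the catalogue for the region's
trinucleotide content relative to the genome (channel ×
freq_genome/freq_region), fitting exposures, and dividing
exposure × catalogue size by the region length. Means and 2.5/97.5
percentiles are reported; clusters under 3 samples (or explicitly
excluded, mirroring the exclusion of outlier clusters) are skipped.
Because the L1 penalty on frequency-scale catalogues shrinks minor
exposures — which biases between-region activity ratios upward by
~20% — the jackknife uses a relaxed-LASSO scheme: λ selects the
signature support, an unpenalized non-negative refit quantifies it. A
planted 3-fold enrichment is then recovered at ≈ 3.0.

## Cohort statistics (`scaakit.stats`)

Fisher exact tests are two-sided (sum of hypergeometric probabilities of
tables no more probable than observed). MSI is called when more than 30%
of microsatellites are mutated (strict inequality at the boundary — the
critical value itself classifies as MSS; a separate figure-caption
convention of ">25%" exists, and the threshold is an argument); a
clinical override flag covers low-purity cases.

The adenoma/carcinoma burden comparison subsamples each carcinoma's reads
without replacement (multivariate hypergeometric over its peak counts
plus a residual class, preserving per-peak proportions in expectation)
down to the mean adenoma read total, recounts detected SCAAs per lesion
(count ≥ 10), and applies Welch two-sided t-tests separately to gains
and losses; carcinomas already below the target are used unsubsampled
and tallied. Degenerate comparisons (zero variance in both groups) return
p = 1 when the means agree.

Heritability: pairwise Euclidean SCAA distances are regressed on a
same-region indicator plus TSS-enrichment and read-count differences.
Pairwise distances are not independent, so the p-value for the
same-region term comes from permuting region labels (999 by default,
Mantel-style) — a parametric ANOVA p would be anticalibrated here. The
genetic–epigenetic association is the partial Pearson correlation of the
two distance vectors controlling for purity differences, also with a
Mantel permutation p. Identical profiles everywhere yield an untestable
(NA) result.

## Synthetic cohort (`scaakit.synthetic`)

The generator emulates the study design — per patient, four tumour
regions (A–D) and a distant normal region (E), each with several glands —
on a fabricated genome of five 10-Mb contigs with a TSS every 100 kb and
uniform trinucleotide content. One global seed fans out to fixed
per-stage child seeds (counter-based spawn keys), so any stage can be
re-run independently and reproducibly.

Conditions and defaults:

- **Purity**: tumour glands uniform over `purity_range` (default
  0.3–0.95; the within-tumour distribution is a modelling convenience),
  normals exactly 0.
- **Allele counts**: depth Poisson(30)/site, alt counts binomial with the
  purity model above; site contexts (m, c) ∈ {(1,2), (1,3), (2,4)} at
  70/20/10%.
- **Peak counts**: NB with dispersion 0.05 (biological CV ≈ 22% between
  replicate glands), per-peak baselines lognormal(log 50, 0.6), per-sample
  size factors lognormal(0, 0.2). Planted gains multiply the mean by 3,
  losses by 1/3, only in affected regions of carrier patients, on top of
  the copy-number mixture factor. Half of planted SCAAs recur in ~30% of
  patients; a configurable fraction is subclonal (confined to a random
  strict subset of regions).
- **Copy number**: segment-constant truth shared across a patient's
  samples; an aberrant segment (4–12 bins, state ploidy −1/+1/+2 at
  40/40/20%) on 95% of contigs — MSS colorectal cancers are highly
  aneuploid — while keeping the majority of bins at ploidy so that
  median-centring stays a near no-op.
- **Fragments**: insertion sizes mix a sub-100-bp open component
  (60 + Exp(18) bp, mode ≈ 60) with nucleosomal Gaussians at 200 and
  400 bp (60/30/10) — a qualitative match to nucleosomal periodicity, not
  a claim of fidelity. Each TF site receives uniform background fragments
  plus centre-focused open fragments whose rate scales as
  `1 + (effect − 1) × purity`; a genome-wide distal pool (default
  150 fragments/site/sample) dominates the insertion-size histogram, as
  background does in a real library. Without that pool the row
  normalization is distorted by the signal itself and the purity response
  turns sublinear.
- **Low-pass bins**: exact mixture log-ratios plus Gaussian noise
  (default SD 0.05), median-centred with the applied median recorded.
- **Mutation catalogues**: multinomial draws from exposure-weighted
  signature mixtures, channel probabilities re-weighted by region vs
  genome trinucleotide content. Signature profiles are synthetic sparse
  random probability vectors (20-channel support), not any published
  catalogue.

What passing tests show — and don't. The generator realizes exactly the
model each estimator assumes (binomial allele sampling, NB counts with a
single dispersion, shared breakpoints, linear-in-purity footprint
effects). Recovery and calibration on these data demonstrate the
estimators are correct and well calibrated under their own assumptions at
desk scale; they do not demonstrate robustness to mappability and GC
artefacts, peak-calling errors, purity mis-estimation feeding the CN
offsets, inter-patient dispersion differences, or any other violation
present in real sequencing data. Problem sizes in the acceptance runs
(e.g. 2,000 peaks, 50 single-patient cohorts, 150 sites/TF, 10^5-mutation
catalogues) were chosen so the full suite completes on a laptop-class
machine while leaving Monte-Carlo error well below the tolerance bands.

## Known limitations

- Ploidy `psi_t` is an input, never estimated; grossly wrong ploidy
  shifts all integer states (real pipelines occasionally need manual
  override, which the API exposes as the caller's choice of `psi_t`).
- The purity/region subclonality test treats region as fixed effects;
  with a single gland per region it is declared untestable rather than
  attempted.
- The NB GLM uses one global dispersion; peak-specific dispersion
  (e.g. promoter vs enhancer classes fitted separately) is supported only
  by running the caller per class.
- The Fisher, k-means, WLS and hierarchical-clustering steps delegate to
  scipy/sklearn/statsmodels; their numerical behaviour is theirs.
- No read-level realism: no FASTQ, mappability, GC bias or duplicate
  structure is simulated.
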