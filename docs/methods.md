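# Methods

This note records the models, conventions and design choices behind
`dimspipe`, in the order data flows through the pipeline.

## Spectral front end

**Signal model.** An FT-ICR transient is modelled as a sum of
exponentially decaying cosines plus white Gaussian noise; each ion
contributes at its cyclotron frequency. One replicate is acquired as
seven SIM windows (100 Da wide, 30 Da overlaps, 70–590 Da). Transients
from repeated scans of one window are averaged pointwise, Hanning
apodised, zero-filled once (length exactly doubled) and Fourier
transformed; only the positive-frequency magnitude half-spectrum is kept.

**Noise and peak picking.** The noise scale is `median(magnitude)/ln 2`.
For Rayleigh-distributed noise magnitudes (the FFT of white noise) the
median is σ·√(2 ln 2), so this is a fixed monotone rescaling of σ that
is immune to any realistic number of large signal bins. Peaks are local
maxima; a peak is flagged real only when magnitude/noise is *strictly*
greater than 3.5 (a peak at exactly 3.5 is rejected). Sub-flag maxima are
retained with flag 0 so thresholding stays auditable. Peak frequencies
are refined by three-point parabolic interpolation of the log-magnitude,
which is near-exact for the Gaussian-like main lobe of a Hanning-windowed
sinusoid; at the default 0.4 s / 4 MHz simulation scale this yields
~0.01 ppm mass errors, far inside the 2 ppm recall criterion.

**Calibration.** The two-term FT-ICR relation is implemented as
`m/z = A/f + B/f²`: A is set by the magnetic field and B absorbs
space-charge effects, so m/z must *decrease* with frequency — an
inverse-frequency form. (A literal product form `A·f + B·f²` would make
m/z increase with f and is dimensionally inconsistent with a
field-dependent A; the inverse form is the standard two-parameter FTMS
calibration.) Internal calibration matches flagged peaks to a calibrant
list within 6.5 ppm (using the external calibration for the provisional
mass axis) and solves the linear least-squares problem in (1/f, 1/f²)
with column scaling; two matched calibrants determine (A, B) exactly, and
fewer than two raises a typed error so the caller falls back to the
window's external calibration, recording `source="external"`.

**Stitching.** Each window contributes its exclusive region plus half of
each shared overlap — the splice sits at the overlap midpoint, where both
windows are furthest from their (least accurate) edges. Residual
duplicates within the ppm tolerance across a splice are merged keeping
the higher-SNR peak. The published workflow's exact overlap rule is not
specified at this level; the midpoint rule is this package's documented
convention, and stitching is invariant to window processing order.

## Synthetic data

The generator emulates the benchmark design: `make_design()` defaults to
8 batches × (1 blank + 5 QCs bracketing 4 blocks of 5 biological
samples), triplicate injections, 20 biological repeat groups (10 cow, 10
sheep) measured once per batch in a fixed order — 208 injections. QC
counts below 2 per batch are rejected because batch correction needs
anchors at both batch ends. Blank and equilibration-QC counts are free
parameters rather than hard-coded totals.

Intensities are fully multiplicative:
`x = base(group, feature) · class_effect · drift(batch, feature, t) ·
dilution(sample) · lognormal_noise`. Key defaults, chosen once to match
the study conditions the pipeline is validated under:

| parameter | default | meaning |
|---|---|---|
| `n_features` | 500 | features before filtering |
| `base_log10_mean/sd` | 6.0 / 0.8 | lognormal feature intensity scale |
| `noise_cv` | 0.16 | replicate-level CV; after triplicate averaging the matrix-level within-batch QC RSD sits at ~8–11% |
| `drift_linear/curv` | 0.10 / 0.05 | smooth within-batch drift (log scale), shared shape per batch with per-feature sensitivity ~N(1, 0.3) |
| `batch_sd` | 0.18 | batch-to-batch level shifts; with the drift terms this inflates the pooled QC RSD to ~19% |
| `dilution_sd` | 0.15 | lognormal dilution spread, biological injections only (QCs come from one pool) |
| `n_contaminants` | 30 | features present in blanks at biological-level intensity |
| `missing_mid_log10/scale` | 4.5 / 0.4 | logistic missingness: a replicate measurement is lost with probability decreasing in log10 intensity, centred ~1.5 decades below the median feature |

The matrix cell applies the replicate consensus (≥ 2 of 3 detected, mean
over detected); the full replicate layer, drift factors, dilutions and
contaminant set are returned as ground truth. `write_spl_directory`
materialises per-replicate peak lists with sub-ppm m/z jitter so
cross-replicate clustering is exercised realistically.

**What the generator does not emulate:** isotope patterns, chemical
noise libraries, ion suppression, space-charge frequency shifts,
correlated (structured) missingness, or heavy-tailed intensity noise.
Passing tests therefore demonstrate algorithmic correctness under the
stated statistical model, not instrument-level realism.

## Filters

All filters are idempotent, never increase sample or feature counts, and
log every removal into the matrix's append-only history.

* **Electrospray check:** a sample fails when any replicate's per-scan
  TIC trace contains ≥ 3 consecutive scans at zero (configurable run
  length and ε); one failing replicate removes the whole sample.
* **TIC filter:** per-sample 7-value median-TIC profiles (one per SIM
  window, replicates averaged) are mean-centred and decomposed by PCA;
  samples with |PC2| above mean + 2 SD are flagged. This is an automated
  stand-in for a visual PC2-based outlier call; the threshold is
  configurable.
* **Replicate filter:** flagged peaks only; single-linkage gap clustering
  of the pooled m/z axis (break where the gap exceeds the ppm tolerance);
  clusters spanning ≥ 2 distinct replicates emit the mean m/z and the
  mean intensity *over detected replicates* (absences are not zeros).
* **Alignment:** the same gap clustering across all samples; the feature
  m/z is the intensity-weighted cluster mean; a sample contributing
  several peaks to one cluster contributes its most intense one; cluster
  spans > 3× tolerance warn.
* **Blank filter:** median across blanks vs median across biologicals
  (missing excluded); removal when blank ≥ ⅓ × biological, inclusive.
  Medians are this package's choice — the summary statistic is not fixed
  by the workflow description; medians are robust and symmetric between
  the two sides.
* **Sample filter:** presence is counted over biological samples only
  (QC presence is reported but not used), inclusive at the threshold
  (16/20 = 80% is retained).
* **Missing-value filter:** per-sample missing % over QC + biological
  samples; removal strictly above mean + 2 SD (n−1 SD); applied once,
  after which the pipeline repeats the blank and sample filters. To make
  that repeat possible the pipeline's first blank-filter pass retains the
  blank rows and only the second pass drops them.

## Normalisation and correction

**PQN** uses the QC median spectrum as reference — QCs are the designated
stable material in this design, so the reference is not perturbed by
class differences. Each sample is divided by the median of its
per-feature quotients over co-observed features; missing stays missing.
Note the estimated factor is the product of true dilution with the
sample's median biological deviation from the reference; dilution
*recovery* is therefore validated on simulations with the biological
spread switched off.

**QC-RSC.** Consecutive same-batch QCs are collapsed to the first before
fitting (they would otherwise over-weight the batch ends). Per feature
and batch, candidate trends of increasing flexibility — constant
(median), straight line, cubic smoothing splines at two smoothing levels
— are fitted to the *log* QC intensities versus run order (log-scale
fitting keeps the back-transformed trend strictly positive) and scored by
leave-one-out cross-validation; the smoothest candidate within one
standard error of the best CV score wins. The one-SE tie-break is what
keeps the correction a no-op on drift-free data: with only ~5 QCs per
batch, plain CV minimisation would let an interpolating cubic chase noise
on a sizeable fraction of features. Splines require ≥ 5 QC values (so LOO
leaves ≥ 4); batches with ≥ 4 but < 5 use constant/linear only; batches
with 1–3 QC values fall back to constant median scaling
(`fallback-median`); features with no QC data anywhere are left unchanged
(`uncorrectable`). Correction divides by the trend (evaluated at each
sample's run order, clipped to the QC-anchored range) and rescales to the
batch QC median (MPA); batches are then aligned by scaling each so its
corrected QC median equals the overall corrected QC median.

**Spectral cleaning.** Rule 1 (batch inconsistency): QC intensities are
divided by their batch's biological median and compared across batches by
Kruskal–Wallis at α = 1e-4; this exposes features whose correction is
untrustworthy (e.g. undetected in one batch's QCs: the correction then
rescales that batch's biologicals instead, and the QC/biological ratio
reveals it even though QC levels were forced equal). Rule 2 (QC bias):
Wilcoxon signed-rank of QC intensities against the overall biological
median at α = 1e-14 (normal approximation — the exact distribution cannot
reach such p-values at realistic QC counts). Rule 3: pooled QC RSD > 20%.
Rules run 1→2→3 and only the first trigger is recorded; degenerate inputs
(zero variance, all ties) retain the feature. Two statistical facts shape
the validation design: (i) the Kruskal–Wallis statistic for a single
deviant batch is bounded by its perfect-separation value, which only
clears the 1e-4 critical level with around a dozen QCs per batch — with
the study-like 5 QCs × 8 batches, rule 1 can only fire when several
batches mutually separate; (ii) dividing by a *sampled* batch biological
median shifts a whole QC group coherently, so null-level type-I control
requires many more biologicals than QCs per batch (the validation uses
400 vs 12). Because rules 1–2 can remove a feature from anywhere in the
RSD distribution, the post-cleaning median QC RSD may move by one
order-statistic gap in either direction; only rule 3 removals push it
systematically down.

**KNN imputation** standardises features (observed mean 0, SD 1), then
imputes each missing cell as the distance-weighted mean of the k = 5
nearest samples (Euclidean over co-observed features) that observed the
feature, via scikit-learn's nan-Euclidean KNN imputer, and returns to the
original scale. Observed cells are never modified; results are clipped
into the positive domain against float round-off.

**glog** applies `y = ln((x + √(x² + λ))/2)` cellwise (exactly `ln x` at
λ = 0). When λ is not fixed by the user it is chosen by grid search
(25 log-spaced points spanning the squared QC-mean range) minimising the
absolute Spearman correlation between per-feature QC standard deviation
and mean — a variance-stabilised transform makes spread independent of
level. Transformed values may be non-positive; the glog matrix is the one
container exempt from the positivity invariant.

## Quality metrics

RSD = 100 · s/mean with the n−1 standard deviation; features with < 3
observations in the relevant subset are excluded from medians. The
pooled median RSD over QCs uses all QCs together (not a
median-of-batch-medians). Biological-repeat RSD is computed per repeat
group over its surviving measurements (with n reported), then summarised
by the per-group median and the mean over groups. PCA mean-centres
without unit-variance scaling (glog already stabilised variance) and
fixes signs so each component's largest-magnitude loading is positive.

## Pipeline and problem sizes

The pipeline is a pure function of (input, config, seed); every stage
writes text artifacts sufficient to resume, and reruns are byte-identical
at the declared precision (m/z to 6 decimals, intensities to 6
significant figures). The validation experiments run at desk scale chosen
for statistical adequacy: the full-study simulation uses the default
8 × 25 design at 300–500 features; the front-end check uses 70 peaks
across seven 0.4 s / 4 MHz windows; cleaning error rates use 2000
features; oracle equivalence uses 100 random instances per filter.

## Known limitations

* Rule 1/2 constructions are documented stand-ins: the original
  description fixes the tests and α levels but not the exact input
  construction.
* The spline smoothing grid (two levels, scaled to the linear-fit
  residual) is deliberately coarse; with ~5 QCs per batch a finer grid is
  not identifiable.
* The TIC filter automates a judgement originally made visually; its
  mean + 2 SD rule on |PC2| is a convention.
* `process` at the CLI validates stitched peak lists; full
  transient-level processing is exposed through the library
  (`process_replicate`), since transient containers are in-memory arrays
  produced by the simulator rather than an on-disk instrument format.
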