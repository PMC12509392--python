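# Methods

This note documents the statistical models, defaults and design choices
behind `tmtquant`, and what the synthetic benchmarks do and do not
demonstrate about real data.

## Measurement model and synthetic data

A TMTpro 16-plex experiment measures sixteen samples in one run; each
identified spectrum (PSM) carries sixteen reporter-ion intensities. The
generator (`tmtquant.simulate`) models, per PSM of protein *g* and
peptide *p*:

1. true channel signal = 2^(per-sample true log2 abundance) × a
   log-normal peptide ionization factor (σ = 1.0 on the natural-log
   scale, constant across channels within a PSM, so within-spectrum
   reporter ratios are abundance-driven) × multiplicative log-normal
   reporter noise (default CV 0.10, independent per channel, median 1 so
   log2 values are unbiased);
2. isotope-impurity mixing: observed = M·signal, where column *j* of the
   16×16 matrix M distributes true channel *j*'s signal across observed
   channels. The built-in representative matrix uses constant
   vendor-style levels (−2: 0.1%, −1: 0.7%, +1: 3.0%, +2: 0.3%); a 1 Da
   shift moves signal two positions in the interleaved N/C channel list,
   and mass shifts that leave the 16-channel window are lost (columns
   sum to < 1);
3. co-isolation interference: with fraction *f* ~ Beta(2, 8) (mean 0.2),
   the observed vector is blended as (1−f)·mixed + f·total(mixed)·b,
   where b is the experiment-average relative channel composition —
   the simplest model in which co-isolated "average" peptides compress
   reporter ratios toward 1, the known effect of co-isolation;
4. missingness: each reporter is dropped with probability 0.1,
   completely at random by default; an optional left-censoring mode
   scales the drop probability by within-PSM intensity rank while
   preserving the marginal rate. The mechanism of missingness in real
   TMT data is not well identified, so MCAR is the neutral default.

Protein abundances are log-normal (log2 mean 20, SD 2.5, arbitrary
intensity units). A configurable fraction of proteins (default 10%) is
differentially abundant between cohorts at ±2 log2 units, split half
up / half down (an odd count ties to the up-shift). PSM counts per
protein are shifted Poisson, 1 + Poisson(11) (mean 12): per-protein
spectral-count distributions in deep TMT experiments are overdispersed
and right-skewed, and a shifted Poisson is the simplest shape that
guarantees at least one PSM while keeping the mean configurable. The
default study design mirrors the target cohort structure: 8 young
(channels 126–130N) and 8 old samples, 3/8 vs 4/8 female, hypertension
present only in the old cohort (4/8).

A second generator, `simulate_protein_matrix`, skips the PSM layer and
draws protein-level log2 values with per-protein error variances from a
scaled inverse-chi-square prior (d₀ = 4, s₀² = 0.05 by default). This is
exactly the generative regime the moderated t-statistic assumes, so it is
the reference for null-calibration and hyperparameter-recovery studies at
large protein counts, where simulating hundreds of thousands of PSMs
would add nothing to what is being tested.

What the generator does **not** emulate: peptide-level identification
errors, intensity-dependent (heteroscedastic-in-mean) noise, retention-
time or fractionation structure, shared-peptide ambiguity beyond chance
sequence collisions, and batch effects (the target design is a single
16-plex run). Passing benchmarks therefore demonstrate correctness of
the computations under the stated measurement model, not robustness to
every artifact of real acquisitions.

## PSM processing rules

- **Impurity correction** solves M·x = observed per PSM (LU
  factorization, one factorization per matrix). Negative solution
  components are clipped to 0; zero intensities are later coerced to
  missing, since a zero reporter is indistinguishable from not-detected.
  By default only fully observed PSMs are corrected and incomplete ones
  pass through; an optional mode solves the observed-channel subsystem.
  Correction is applied before the interference filter; under the model
  here the two steps do not interact, as filtering only drops rows.
- **Interference filter**: PSMs with interference strictly greater than
  0.5 are excluded ("exceeding" the 50% maximum); the boundary value is
  retained. Threshold configurable.
- **Rollup** sums corrected intensities over each protein's PSMs.
  Peptide sequences observed under more than one accession are excluded
  with a warning — razor-protein assignment is a database-search concern,
  out of scope here. A protein/channel cell with no contributing
  intensity is missing.
- **Group-missingness filter**: a protein is removed when either cohort
  is missing ≥ 50% of its values (the inclusive reading of "missing half
  were removed"; an exclusive switch is provided). No imputation is ever
  performed.
- **Normalization**: log2 then per-sample median subtraction, making
  every column's median of present values exactly zero.

## iBAQ

The theoretical-peptide denominator counts distinct peptides of 6–30
residues from a fully cleaved (0 missed cleavages) tryptic digest —
the convention of the original iBAQ definition; both the window and the
missed-cleavage count are configurable since conventions vary. Cleavage
is C-terminal to K/R unless followed by proline; a C-terminal K/R is not
treated as a site (the cut would split off an empty fragment and
duplicate missed-cleavage variants). The numerator sums a protein's
corrected, pre-normalization reporter intensities over all channels:
iBAQ here describes overall abundance in the experiment, not a
per-channel quantity.

## Moderated differential expression

Per protein, OLS of log2 expression on intercept + cohort + sex +
hypertension, fitted on the protein's present samples (consistent with
no imputation); proteins whose reduced design is rank-deficient are
reported untestable rather than silently dropped. Fitting is vectorized
by missingness pattern. Note the hypertension covariate is partially
confounded with cohort when, as in the default design, no young patient
is hypertensive; the design stays full rank, and its condition number is
reported as a diagnostic.

Hyperparameters (d₀, s₀²) are estimated once across all testable
proteins — the prior is assay-wide — by moment matching of log s²
against its theoretical scaled log-chi-square distribution
(digamma/trigamma inversion, Newton's method for the trigamma inverse).
Degenerate inputs: exactly equal variances return d₀ = ∞ with the common
value as s₀² (the sampling model cannot hold, so no log-bias correction
is applied); all-zero variances (noise-free data) return d₀ = ∞ with a
vanishing prior, which preserves fold changes while null statistics
collapse to t = 0; fewer than 10 usable variances raise an error
instructing a fallback to ordinary t-tests.

The moderated p-value uses d + d₀ total degrees of freedom (normal when
d₀ = ∞). FDR adjustment is tail-area: Storey-type q-values with π̂₀
estimated as the average of #{p > λ}/((1−λ)m) over λ ∈ {0.2, …, 0.8},
capped to [0, 1]; plain BH (π̂₀ = 1) is also provided and is the
automatic choice below 200 testable proteins, where the π̂₀ estimator is
too variable. Significance: adjusted p < 0.05, configurable.

## Descriptive summaries

PCA uses complete-case proteins (dropped ones reported), per-protein
centering, and unit scaling by default — mixed molecule classes sit on
different variance scales; scaling is configurable since either
convention is defensible. Scores are U·S and loadings the orthonormal
right singular vectors. The heatmap takes the 50 smallest adjusted
p-values (ties by |logFC| then accession), Z-scores each row with the
sample (n−1) standard deviation, and orders rows and columns by
agglomerative clustering with Euclidean distance and average linkage
(both configurable; distances are pairwise-complete under missingness).
Box-plot summaries use linear-interpolation quartiles.

## Clinical table

Fisher's exact two-sided p sums the hypergeometric probabilities of all
tables with the observed margins whose probability is at most the
observed table's, with a 1 + 1e-7 relative tolerance guarding
floating-point equality at symmetric tables; degenerate margins give
p = 1. Continuous characteristics default to the exact Wilcoxon rank-sum
test (enumeration for combined n ≤ 20 without ties, tie-corrected normal
approximation otherwise); Welch's t is available, and the method used is
annotated per row. Percentages are rounded half-up to integers.

## Benchmark problem sizes

The validation suite uses 20,000 proteins for null calibration and
hyperparameter recovery (protein-level generator), and 20 replicates of
400 proteins through the full PSM pipeline for the power/false-discovery
and effect-recovery benchmarks. The recovery benchmarks set co-isolation
interference to zero: residual interference below the 50% filter
compresses fold changes toward zero by design of the measurement model,
and the pipeline — like the standard TMT workflow it implements —
filters rather than corrects that bias, so unbiased effect recovery is
only a meaningful expectation without it. Accuracy under interference is
instead covered by the sign/direction and calibration checks.

## Known limitations

- Shared peptides are discarded, so proteins quantified mainly by shared
  sequence are under-represented; razor assignment is out of scope.
- The interference fraction is taken as given per PSM; no signal
  decontamination is attempted beyond filtering.
- The tail-area FDR uses a λ-average π̂₀ without spline smoothing; for
  very small protein counts the BH fallback applies.
- iBAQ values are on arbitrary intensity scales; no spike-in calibration
  to absolute copy numbers is provided.
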