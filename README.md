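# tmtquant

A tested, reusable pipeline for quantitative analysis of TMTpro 16-plex
isobaric-labelling proteomics, built for laser-capture-microdissected
FFPE tissue studies that compare two small clinical cohorts (for example,
young versus old kidney tubulointerstitium, 8 patients per group, all
sixteen samples multiplexed in a single MS run).

It is aimed at proteomics analysts who have a PSM-level reporter-ion
table (a MaxQuant-evidence-like export) and want the downstream
quantitation done reproducibly: isotope-impurity correction, isolation-
interference filtering, protein rollup, normalization, iBAQ abundance
estimation, moderated differential expression with false-discovery-rate
control, and the descriptive summaries that typically accompany such a
study. A ground-truthed synthetic-data generator makes every stage
testable without any raw mass-spectrometry data.

## What it computes

**PSM processing.** Observed reporter intensities are a linear mixture of
the true channel signals caused by reagent isotope impurities; the
pipeline solves the 16×16 mixing system per PSM (negative solutions are
clipped to zero). PSMs whose precursor isolation window contained more
than 50% foreign ion current are discarded (a PSM at exactly 50% is
retained). Protein × channel intensities are the sum of corrected
reporter intensities over each protein's unique-peptide PSMs; proteins
missing at least half their values in either cohort are removed, with no
imputation; values are log2-transformed and each sample column is median-
centred.

**iBAQ.** Protein abundance is estimated as the summed peptide intensity
divided by the number of theoretical tryptic peptides of 6–30 residues
from an in-silico digest (cleavage after K/R, blocked by proline).

**Differential expression.** Per protein, log2 expression is regressed on
an intercept, the cohort indicator and clinical covariates (sex,
hypertension). Residual variances are shrunk toward an assay-wide prior
estimated by empirical Bayes: with prior degrees of freedom d₀ and prior
variance s₀², the posterior variance is

    s̃² = (d₀·s₀² + d·s²) / (d₀ + d)

and the moderated statistic t = logFC / √(s̃²·v) is referred to a
t-distribution with d + d₀ degrees of freedom. P-values receive a
tail-area false discovery rate correction (Storey-type q-values, i.e.
π̂₀-scaled Benjamini–Hochberg with monotonization; plain BH is the
conservative default below 200 proteins). Significance is declared at
adjusted p < 0.05.

**Summaries.** PCA biplot tables (sample scores plus top-10 protein
loadings), a Z-scored heatmap of the top-50 DE proteins with hierarchical
row/column ordering, per-protein group box-plot statistics, annotation
set-overlap/coverage counts, and a clinical characteristics table with
Fisher's exact tests (exhaustive hypergeometric enumeration) and
rank-sum tests.

## Worked example

Simulate a 500-protein study (8 young vs 8 old samples, 10% of proteins
shifted ±2 log2 units in the old cohort), then quantify and test:

```sh
printf 'n_proteins = 500\nseed = 11\n' > sim.cfg
tmtquant simulate --config sim.cfg --seed 11 --outdir sim
tmtquant quantify --psms sim/psms.tsv --design sim/design.tsv \
    --impurity sim/impurity.tsv --out-matrix matrix.tsv --out-report filters.tsv
tmtquant de --matrix matrix.tsv --design sim/design.tsv --out de.tsv
tmtquant ibaq --psms sim/psms.tsv --fasta sim/proteins.fasta \
    --impurity sim/impurity.tsv --out ibaq.tsv
```

prints

```
wrote 5806 PSMs for 500 proteins to sim
quantified 500 proteins x 16 samples
54 significant proteins (25 up, 29 down) of 500 tested; FDR method: tail_area
median log10 iBAQ: 7.27 over 500 proteins
```

Of the 50 truly differential proteins, 54 are called significant at
q < 0.05 — essentially all true positives plus a handful of false calls
whose rate the q-value threshold controls; the up/down split mirrors the
simulated half-up/half-down design. The filter report (`filters.tsv`)
shows 122 of 5,806 PSMs removed for exceeding 50% isolation interference
and no protein lost to the group-missingness rule at the default 10%
missing-value rate. `de.tsv` contains per-protein log2 fold changes
(old relative to young), moderated t-statistics, raw and adjusted
p-values — the coordinates of a volcano plot.

From Python the same pipeline is three calls:

```python
import tmtquant as tq

cfg = tq.SimulationConfig(n_proteins=500, seed=11)
db, design, truth, psms = tq.simulate_study(cfg)
matrix, reports = tq.process_psm_table(psms, tq.ImpurityMatrix.default(), design)
result, report = tq.run_de(matrix, design)
```

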