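# Methods

`kinoviab` implements a framework for predicting drug-induced cancer cell
viability from multi-dose kinome-inhibition profiles and baseline omics,
together with a synthetic-data generator that reproduces the structure of
the real resources so every stage can be tested with known ground truth.

## The modeling problem

A kinobead/MS competition assay profiles each small-molecule kinase
inhibitor against a panel of proteins at several concentrations.  The
readout per (compound, protein, concentration) is a *relative intensity*:
about 1 when the protein is unaffected, near 0 when it is fully competed
away (inhibited), occasionally above 1 (apparent increased capture).  A
pooled viability screen provides per-(cell line, compound) dose-response
curves as four-parameter log-logistic (LL.4) fits.  Baseline omics
(expression as log2(TPM+1), copy number, proteomics, CRISPR-KO dependency
scores) characterize each untreated cell line.  The model learns

    viability(cell line, compound, concentration)
        ~ f(inhibition state of the compound at that concentration,
            baseline omics of the cell line)

with viability on a 0–1 scale (0 = complete death, 1 = no effect; fitted
curves may legitimately exceed 1).

## Pipeline stages

1. **Preprocessing** (`preprocess`).  Sparse inhibition records are
   densified with a default intensity of 1 for every (compound, protein)
   pair the assay did not report.  Isolated single-concentration gaps in
   reported series are filled with the mean of the two flanking doses
   (boundary gaps copy the nearest neighbor; two adjacent gaps violate the
   isolated-gap premise and raise).  Finally intensities are truncated at a
   global high percentile (default 99.99) of the dense tensor, pooled over
   all compounds, doses and proteins; the quantile uses linear
   interpolation between order statistics and the threshold is logged.
   The threshold is computed *after* densification; because default-1 cells
   dominate the tensor, this choice affects the value only in pathological
   cases, and the percentile is configurable.
   Omics columns get class prefixes (`act_`, `exp_`, `cnv_`, `prot_`,
   `dep_`) so features derived from the same gene in different assays stay
   distinct.  Missing proteomics readings are imputed to the per-protein
   observed minimum minus one (sample) standard deviation; columns with
   fewer than two observations are dropped.  Cell lines with residual
   missing entries are removed.

2. **Viability imputation** (`viability`).  The LL.4 curve
   `f(x) = c + (d-c) / (1 + exp(b (ln x - ln e)))` is evaluated at the
   8-point assay grid (3 nM, 10 nM, 30 nM, 100 nM, 300 nM, 1 uM, 3 uM,
   30 uM).  Natural log is used throughout; the curve is invariant to the
   log base given a matching slope.  Parameter sets whose curve value at
   the top grid dose exceeds the value at the bottom dose imply enhanced
   growth with increasing concentration and are filtered out; for monotone
   LL.4 curves the endpoint comparison is equivalent to a full
   monotonicity check.  Imputed values are *not* clipped by default (the
   observed distribution extends beyond 1); an optional `clip_max`
   reproduces a bounded scale and its state is logged.

3. **Feature screening** (`features`).  The design matrix has one row per
   (cell line, compound, concentration); inhibition columns vary only with
   (compound, concentration) and omics columns only with cell line.  Each
   feature's Pearson correlation with imputed viability is computed;
   features are selected in descending |r| order (a signed mode is
   available), with lexicographic tie-breaks so selection is a total,
   deterministic order and every top-k1 list is a prefix of every top-k2
   list (k1 < k2).  Zero-variance features are assigned r = 0 and flagged
   rather than dropped, keeping the ranking a permutation.  log10(dose) is
   appended to the design matrix as a covariate whenever inhibition
   features are in play and does not count toward the feature budget k;
   models built from dose-invariant classes alone (e.g. expression-only
   ablations) exclude it, so their score reflects what baseline omics can
   do without any dose information.

4. **Modeling** (`modeling`).  Cross-validation is grouped: all eight
   doses of a (cell line, compound) combination travel together, so no
   dose-response curve is split between training and test.  Folds are a
   random balanced partition of combinations (sizes differ by at most
   one).  Feature screening is recomputed inside every training fold
   before fitting.  Families: a dose-only baseline (training-set mean
   viability per concentration), ordinary least squares, random forest
   (default 500 trees, 22 predictors per split falling back to
   floor(sqrt(p)) when 22 exceeds the feature count, minimal node size 5),
   and gradient boosting.  R^2 is the squared Pearson correlation of
   out-of-fold predictions with observations by default; the
   coefficient-of-determination convention is available behind a flag and
   every metrics file records which was used.  Variable importance is
   impurity-based by default with permutation importance as an option;
   features are tagged dark kinase / light kinase / non-kinase via the
   annotation table (unannotated proteins default to non-kinase with a
   warning) or "expression".  The default sweep grid is:
   trees {500, 1000, 1500, 2000}, predictors per split {11, 22, 33, 44},
   minimal node size {3, 5, 10}.

5. **Enrichment** (`enrichment`).  The interaction network is filtered to
   confidence strictly above 0.7.  For a query gene set (the selected
   expression genes) versus the inhibition-panel proteins, two statistics
   are computed: how many query genes touch at least one panel protein,
   and the mean number of panel interactors per query gene (zeros
   included).  Significance comes from uniform without-replacement
   resampling of same-size gene sets (default 10,000 draws); the reported
   percentile is (#draws strictly below + half the ties) / draws x 100.
   The half-tie convention keeps percentiles centered on degenerate
   networks (all-zero nulls score 50, not 0 or 100).

6. **Prediction and validation** (`predict`).  The final model is fit on
   the full table (screening on all rows, top-k selection).  Predictions
   cover every (cell line, compound) pair with expression and an
   inhibition profile but no viability screen, at all grid doses; the
   prediction grid plus the tested mask partitions the full cartesian
   space.  Laboratory plates are normalized row-wise to the mean of their
   DMSO-only controls (replicates averaged after normalization; rows with
   non-positive control means are flagged invalid), then any plate row
   with a normalized value >= 120% of DMSO is removed entirely.
   Normalization strictly precedes QC.  Predicted and measured records are
   joined on (cell line, compound, concentration) and scored by
   R^2 / RMSE; the same comparison serves the replication experiment with
   imputed viabilities in place of predictions.

## The synthetic-data generator

The generator (`synthetic`) defines the study conditions; its defaults are
fixed and are what the tests and the acceptance script run against.

**Mechanism.**  Each compound gets `targets_per_compound` target proteins
with log-uniform potencies k in [10 nM, 3 uM]; target intensity decays as
`1 / (1 + exp(slope (ln x - ln k)))` with one Hill slope (1.5) shared
across the dataset.  Each compound also gets `n_driver_genes` driver
genes, disjoint across compounds; each driver loads on a per-(line,
compound) latent factor (effect 1.2, residual SD 0.4) on top of a
log2(TPM+1)-scale background (mean 3, SD 1, clipped at 0).  Sensitivity is
`s(l, j) = logistic(offset_j + 0.6 * latent(l, j))` with per-compound
offsets drawn N(0, 1): compound identity dominates viability variance and
expression modulates it per line, matching the variance structure of the
emulated screens, where inhibition profiles carry most of the predictive
power and expression adds a smaller per-line refinement.  True viability
is `V = 1 - s (1 - min_target intensity)`; with a shared slope, the
minimum over targets is exactly the most potent target's curve, so V is
an exact LL.4 curve (upper asymptote 1, lower asymptote 1-s, inflection
at the best potency).  LL.4 parameters are refit to V plus Gaussian noise
(SD 0.05) by multi-start nonlinear least squares on log-concentration
(starts around slope 1, asymptotes at the response extremes, inflection at
the geometric-median dose); failed fits are logged and dropped.

**Anomalies.**  A per-interior-cell probability `gap_rate` (default 0.02,
matching the ~1.8% single-concentration gaps in the real profiles)
withholds isolated values, never two adjacent.  A probability
`outlier_rate` (default 0.001) inflates a recorded intensity by a factor
in [3.5, 6].  A fraction `growth_fraction` (default 0.02) of combos gets a
deliberately increasing parameter set to exercise the growth filter.  The
interaction network places background edges with probability p0 (default
0.02) and driver-target edges with probability p0 x enrichment strength
(default 5); confidences are uniform [0.4, 1].  A kinase annotation table
labels each panel protein light kinase / dark kinase / non-kinase
(roughly half non-kinases, as in kinobead pulldowns).

**Defaults.**  40 cell lines x 30 compounds x 8 doses, 80 proteins, 200
genes, 3 targets and 3 drivers per compound, seed-controlled throughout;
identical config and seed give byte-identical outputs.

**What the generator does not emulate.**  Marginal distributions beyond
scale and sparsity; correlated omics blocks (CNV/proteomics/dependency are
signal-free noise matrices apart from planted proteomics missingness and
incomplete dependency lines); assay-specific artifacts such as plate
spatial bias; the actual curve-fitting pipeline of the viability screen
(the generator's fit is a stand-in).  Passing tests therefore demonstrate
that the pipeline's arithmetic and learning machinery recover planted
structure under realistic sparsity and noise — not that the models would
reach any particular accuracy on the real resources.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` run the full study conditions
(40 x 30 x 8) for fold-integrity, signal-recovery and importance checks,
with 150-tree forests (R^2 plateaus well below that count, as the
tree-count sweep itself shows); the tree-count sweep {500, 1000, 1500,
2000} runs at a reduced 16 x 12 scale with 5 folds and k = 100.
Enrichment calibration uses 200 repeats of 1,000 draws on an
Erdos-Renyi network, comparing the null mean to the closed form
`set_size * (1 - (1-p)^T)` with the network-level binomial variance folded
into the tolerance.  Exact-arithmetic operations (densification, gap
filling, truncation, selection, plate normalization) are checked against
independent brute-force scans, and the LL.4 evaluator against an
independently coded formula at 1e-10 over 10,000 random draws.

Ties in the max-variance dose pick go to the lower concentration; ties in
feature ranking break lexicographically; the truncation quantile uses
linear interpolation; concentration matching in densification requires
exact membership of the dose grid after float canonicalization (no
tolerance window).

## Known limitations

- In-fold selection with k far above the number of informative features
  fills the tail of each fold's list with rank-noise among near-zero
  correlations, so the all-fold selection overlap on synthetic data is
  dominated by that tail (the informative head is stable).
- The endpoint-based growth filter can remove noisy near-flat curves whose
  fitted parameters tilt slightly upward; with fit noise the removed set
  is therefore a superset of the planted growth combos (they coincide
  exactly when the generator's noise is zero).
- `DoseOnlyBaseline` refuses to extrapolate to concentrations absent from
  training; grouped folds keep whole curves together, so every grid dose
  is always represented in training and this never triggers in the
  pipeline.
- Gradient boosting uses histogram-based trees with their library
  defaults; it is provided for family comparison, not tuned.
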