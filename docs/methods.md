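# Methods

This note documents the models behind `iphdnet`, the defaults that matter,
the synthetic benchmark design, and the numerical choices a user relying on
the outputs should know about.

## Data model and preprocessing

Assay data enter as GCT 1.3 matrices (analytes × samples, log2 units) with
typed sample metadata (cell line, perturbagen, dose, time point, replicate,
vehicle-control flag). Missing cells — sentinel `-666` (LINCS convention)
or `NA` — become explicit missing flags.

- **Imputation** is correlation k-nearest-analyte averaging (default
  `k = 5`): for an analyte with holes, the k most Pearson-correlated
  analytes on shared observed samples donate their observed values at the
  missing column, combined with similarity weights shifted to `(0, 1]` so
  anti-correlated neighbors never carry negative weight. The procedure is
  deterministic and never alters an observed value. It assumes analytes
  are missing at random and that correlated analytes exist; an analyte with
  no observed values at all is an error, and a column no neighbor observed
  falls back to the analyte's own mean.
- **Replicate collapsing** takes the median within each (cell line,
  perturbagen, dose, time point) group — robust to single-plate outliers.
- **Fold change** is the difference of log2 values: treatment column minus
  the mean of vehicle-control columns matched within (cell line, time
  point). Dose is ignored for control matching because the vehicle has
  none. Input declared linear-scale is log2-transformed first with a floor
  at `1e-6`. Controls are removed from the output, so a fold-change matrix
  contains treatments only.

## Histone signatures (consensus NMF)

Signed fold changes cannot enter NMF directly. The matrix is split into
stacked positive and negative parts (`max(V,0)` over `max(−V,0)`), which
preserves elevation and reduction as separate non-negative features and
keeps sparsity — the alternative, shifting the whole matrix positive,
inflates baseline loadings and was rejected.

Factorisation uses multiplicative Frobenius updates (tolerance `1e-6`, at
most 2000 iterations) from seeded uniform random initialisations, 30
restarts by default; the restart with the lowest reconstruction error is
kept. Treatment co-membership (argmax row of `H`) across restarts
accumulates into a consensus matrix; its cophenetic correlation — the
agreement between consensus distances `1 − C` and the average-linkage
dendrogram built from them — measures how reproducible a clustering at
rank k is.

**Rank selection** maximises the cophenetic correlation over a rank range
(default 2–8). Ties within `1e-9` resolve toward the *larger* rank: on
clean data, any rank that merely merges true modules is also perfectly
reproducible (cophenetic exactly 1), so the finest perfectly-stable rank
is the informative one. A degenerate consensus with zero spread in its
distances is defined as cophenetic 1.

Module assignment: each drug goes to the argmax row of its `H` column;
each histone to the module with the largest combined loading (positive +
negative part rows of `W`); exact ties break toward the lowest module
index. Drug–histone edges exist only within a module, weighted by
`(W_pos[h,m] + W_neg[h,m]) · H[m,d]`, signed by the fold change (zero fold
change ⇒ no edge). The default weight cutoff is the 25th percentile of
nonzero same-module products — data-adaptive so edge density does not
depend on the scale of the factorisation — and is configurable, as the
appropriate pruning level is ultimately a display/interpretation choice.

## Phosphoprotein → histone PLSR

With ~31 treatments and ~96 phosphopeptide predictors the regression is
n ≪ p, so each histone code is modelled by partial least squares
regression (NIPALS) on all phosphoproteins jointly. Both blocks are
column-standardized internally; coefficients are reported back on the
original scale so they are comparable to fold changes. Constant predictors
are dropped with a warning and given zero coefficients.

**Component count** is chosen by deterministic cross-validated PRESS
(round-robin folds over sorted sample ids; leave-one-out by default,
capped at 10 components for assay-scale data). PRESS flattens into a
plateau once the informative components are in, and a strict argmin
wanders along that plateau; the selector therefore returns the smallest
count within 5% of the achievable PRESS reduction relative to an
intercept-only baseline (`rel_tol = 0` restores the plain argmin). When no
component count beats the baseline — pure-noise responses — the
one-component model is returned.

**Coefficient significance.** PLSR has no closed-form coefficient
variance, so inference is a nonparametric bootstrap over sample rows
(default 1000 draws, 2000 in the calibration benchmarks): `se` is the
bootstrap standard deviation, `t = B/se`, and the two-sided p-value uses a
t reference with `n − a − 1` degrees of freedom for `a` components (the
latent-variable convention; a plain normal reference is a one-line swap).
A degenerate coefficient with zero bootstrap variance gets `p = 1` with a
warning — conservative by design. Edges retain coefficients with raw
`p < α` (default `1e-4`); a Benjamini–Hochberg column is emitted for
reference but deliberately not used for retention, keeping the network
definition a fixed raw-p threshold.

Calibration caveat: within one dataset the coefficient p-values are
mutually correlated (they share the fitted component directions), so the
fraction below 0.05 in a single null dataset is itself a noisy quantity.
The calibration benchmarks therefore pool p-values over 40+ independent
null datasets; pooled, the null fraction sits near 0.05 and the pooled
distribution is close to uniform (KS ≈ 0.03–0.05).

## Network assembly and queries

The drug–histone and histone–phosphoprotein layers merge on exact
histone-code strings (e.g. `H3K27me3K36me3`); a preflight warning lists
histones present in only one layer, because silent id drift would
fragment the network. The tripartite constraint — no intra-layer and no
drug–phosphoprotein edges — is validated on every construction. Edge
weights keep their native per-layer scales (NMF coefficient product vs
|B|); optional min–max rescaling to [0, 1] exists for display exports.
Exports are SIF, GraphML and an edge TSV whose read-back reproduces the
network exactly; node ids are namespaced by layer (`drug:`, `histone:`,
`phospho:`) to prevent collisions.

## Concordance statistics

- **Rand index**: plain RI (fraction of item pairs on which two
  partitions agree), computed by contingency-table pair counting; an
  adjusted (chance-corrected) variant is available behind a flag. Module
  labels are arbitrary, so partition comparisons always go through RI,
  never raw labels.
- **Interval correlation**: for each drug, the per-analyte change vector
  `value(t_end) − value(t_start)` (replicates averaged); reported r is the
  Pearson correlation between the two drugs' change vectors. The phrase
  "correlation of two drug responses over an interval" admits a
  within-drug reading (one drug's profile at t_start vs t_end); that
  variant is provided as `within_drug_interval_correlation`.
- **Paired regression**: OLS of one drug's fold changes on the other's,
  per-analyte pairing, at a fixed time point.

## Over-representation analysis and MCN

Enrichment is an exact hypergeometric upper tail `P(X ≥ overlap)` against
user-supplied GMT libraries within an explicit universe (library sets are
intersected with the universe first; the universe choice dominates ORA
p-values and is therefore never implicit), with Benjamini–Hochberg
q-values over the tested terms. This is a deliberate offline replacement
for web enrichment services; rank-based combined scores are not
replicated.

MCN reconstruction expands seed phosphoproteins to their first-level PPI
neighborhood (seeds ∪ direct partners, keeping partner–partner edges) at a
configurable STRING combined-score cutoff (default 700, "high
confidence" — the appropriate cutoff is dataset-dependent and nothing in
the method fixes it). Proteins are partitioned by time-point membership;
the Venn region `{3, 6, 24}` is the "remained enriched throughout" set.
The networks are mechanistic in the sense of time-annotated interaction
context; no causal edge orientation is inferred.

## Synthetic benchmark design

`simulate_gcp_p100` emulates the assay geometry: 60 histone marks (24 h),
96 phosphopeptides (3/6/24 h), 31 drugs, DMSO controls, 2 replicates,
log2 baselines ~N(8, 1). Drugs and histones are partitioned into k = 4
balanced modules; every within-module (drug, histone) pair carries a
fold-change signal of ±1.5 log2 units with independent N(0, 0.3) noise
per measured cell. The response direction is drawn once per (module,
histone) — all drugs of a module move a given mark the same way — because
a signature *is* a coherent response pattern: fully independent per-pair
signs would make each planted module rank-2 under positive/negative
stacking and the true rank unrecoverable in principle. Early time points
carry 40%/70% of the 24 h response. The phospho block is the minimum-norm
preimage of the histone signal through a planted sparse coefficient map
`B0` (5% density, magnitudes 0.5–1.5, random signs, resampled to full
column rank), so `P100_fc @ B0 ≈ GCP_fc` holds exactly at 24 h before
noise. `simulate_plsr_system` is the decoupled variant (X ~ N(0,1),
Y = XB0 + noise, noise SD 0.5) used for coefficient-recovery
benchmarks. Both are byte-identical under a fixed seed.

What passing these benchmarks does **not** show: real GCP/P100 data have
unbalanced signature sizes, analyte-correlated (not i.i.d.) noise, plate
and batch effects, dose–response structure and missing-not-at-random
holes; module boundaries in real data are soft. Recovery rates measured
here are upper bounds on what the same settings achieve on real assays.

## Problem sizes used in the shipped benchmarks

Rank-selection recovery uses the full fixture (60×31, ranks 2–8, 30
restarts, 10 seeds). Bootstrap calibration pools 40 null datasets of
n = 40, p = 10, q = 5 with 2000 bootstrap draws each. Edge recovery uses
the full 96 × 60 map at n = 60 with 5-fold CV component selection and
1000 bootstrap draws. Oracle checks (Rand index, hypergeometric vs Fisher)
use 200 and 100 random configurations respectively.

## Known limitations

- The bootstrap t-test treats the selected component count as fixed;
  selection uncertainty is not propagated.
- Cophenetic rank selection assumes hard module structure; overlapping
  signatures inflate the selected rank.
- The correlation-kNN imputer is O(analytes²) per matrix — fine at assay
  scale (≲10³ analytes), not intended for transcriptome-wide input.
- `neighborhood` scans the edge set per query; the networks here are
  small (10²–10³ edges), so no adjacency index is kept.
- GCT support is the 1.3 text format only; binary GCTX is out of scope.
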