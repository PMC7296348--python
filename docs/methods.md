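# Methods

This note documents the models, procedures, numerical choices and known
limitations behind `cortexfate`, in the order the pipeline runs them.

## Normalization of panel counts

The chain follows the standard nCounter workflow. Per sample *s*:

1. background `b_s` = geometric mean of the 8 negative control probes,
   subtracted from every other probe and clamped at 0. If every negative
   probe is zero the background is 0; otherwise zero counts are replaced
   by 1 before the log so the geometric mean stays defined while
   preserving "low".
2. positive-control factor `p_s = R_pos / g_s` where `g_s` is the sample's
   geometric mean over the 6 positive probes (after background
   subtraction) and `R_pos` is the geometric mean of the `g_s` across the
   dataset being normalized. Applied multiplicatively to all probes.
3. housekeeping factor `h_s`, same construction over the 7 housekeeping
   genes on the positive-normalized values, applied next. The ordering
   (positive before housekeeping) follows the convention of the assay
   vendor's software.
4. samples with `p_s` or `h_s` outside `[0.25, 4]`, or with a control
   geometric mean of exactly 0 after clamping, are flagged and removed,
   and steps 1–3 are recomputed once on the survivors. We deliberately do
   **not** iterate to a fixed point: outlier removal is a one-shot QC
   decision, and iterating could cascade removals on small datasets.
   Factors that drift out of range in the re-pass are kept (and visible
   in the QC table).

**Exact invariances.** Multiplying every count of one sample by `c > 0` is
absorbed by the positive-control factor *except* for the dataset
reference, which shifts by exactly `c^(1/n)` (it is a geometric mean over
`n` samples). The output is therefore unchanged up to that single global
factor, and within-sample relative expression is exactly unchanged; the
test suite asserts this corrected exact form at `rtol = 1e-12`. A literal
"output unchanged" invariance would require a reference independent of
the scaled sample (e.g. leave-one-out), which contradicts the
dataset-geometric-mean reference the method prescribes.

Expression filtering keeps genes **strictly above** 30 normalized counts
in at least one sample (a gene peaking at exactly 30 is dropped). The log
transform is `log2(max(x, 1))`: clamping at 1 maps everything at or below
background to 0 while keeping the transform monotone above it.

**Codeset merging.** For each gene shared by two codesets, the scale
factor is the geometric mean over bridge samples (≥ 2, typically 5) of the
ratio of their expression in codeset 1 vs codeset 2. A stabilizing
`eps = 0.5` is added to both sides of a ratio only when one side is zero;
this keeps the merge *exact* whenever codeset 2 is an exact per-gene
rescaling of codeset 1 on positive bridge values (a blanket additive eps
would bias every factor).

## Variation analysis

PCA is computed by SVD of the gene-centered log2 matrix — no
unit-variance scaling, since log2 already stabilizes variance and scaling
would inflate low-variance genes. Loading signs are fixed by requiring the
largest-magnitude entry of each component to be positive, making outputs
reproducible. Per-component contributor selection z-scores the loadings
across genes (sample standard deviation) and labels genes with |z| > 2.

Sample clustering uses `d(x, y) = 1 − Pearson(x, y)` over genes with
complete linkage; the distance is invariant to per-sample affine
transforms. Cluster labels at each cut are renumbered by decreasing size
(ties broken by first sample position) so they are stable across runs.
The linkage method is configurable; complete linkage is the default of
the heatmap tooling this analysis style is usually run with.

Early→late analysis correlates late-stage marker expression with
early-stage expression of every gene across paired differentiations, with
an optional |r| > 0.75 reporting filter. The correlation-of-correlations
summary compares, over all ordered gene pairs, the cross-time correlation
with the within-early-dataset correlation; identical matrices give r = 1
and permuted pairings center on 0.

## Threshold classifier and line-bias statistics

The five-class decision tree is evaluated in fixed order — caudal calls
take precedence, so a FOXG1/DLX5-low sample is caudal even when NKX2-1 is
high. Comparisons are strict `<` for "low" and `>=` for "high"; the
fitted cutoffs are midpoints between adjacent training values, so the
choice of strictness cannot change a training call.

`fit_thresholds` reproduces the published analysis logic: cutoffs are
first-class configuration, with fitting as the re-derivation path.
Candidate cutoffs are midpoints between adjacent distinct training values
plus one sentinel on each side; the (FOXG1, DLX5) pair is fitted jointly
to separate caudalized outcomes from the rest, then (NKX2-1, PAX6) on the
predicted-rostral remainder under strict three-class agreement
(highly/partially ventralized vs dorsalized). Ties in agreement are
broken by the larger minimum margin to training values, then by the
lexicographically smallest pair — deterministic and matched by an
independently coded brute-force oracle in the tests. Very-low (highly
caudal) cutoffs are fitted only when highly-caudal training examples
exist; otherwise they default to 2 log2 units below the low cutoffs. When
training data are not separable the best-agreement cutoffs are returned
with a warning listing the misclassified pairs. In agreement reporting, a
predicted partially-ventralized sample counts as consistent with a
dorsalized late outcome (at the late stage, partially ventralized
cultures do not separate from dorsalized ones).

Per-line summaries include lines with at least 2 differentiations. The
line-bias interval is the Newcombe hybrid score construction: Wilson 95%
intervals `(l1, u1)`, `(l2, u2)` for the line proportion `p1` and the
comparison proportion `p2` combine as
`(d − sqrt((p1−l1)² + (u2−p2)²), d + sqrt((u1−p1)² + (p2−l2)²))`,
`d = p1 − p2`. The comparison group **excludes the line under test**,
making the two proportions independent as the construction assumes. A
plain Wald difference was rejected as inconsistent with the Wilson-based
description of the method. Genotype-level frequencies average each line's
frequency vector with equal weight (so a 26-differentiation line counts
once), including genotypes with ≥ 3 lines.

## Atlas mapping

Energies are transformed as `log2(energy + 1)` before regression; raw
residual units would depend on the energy scale. For each ordered region
pair (A, B), OLS of A on B across genes; a gene is selective for A iff
its internally studentized residual (`r_i / (s·sqrt(1−h_i))`) exceeds 2 in
the comparison with **every** other retained region (the conjunctive
reading of "each pairwise comparison"). Regions with no selective genes
are removed *simultaneously* and the analysis repeats; this terminates in
at most `n_regions` rounds and is order-independent. If fewer than two
regions survive, the procedure errors. A perfect fit (duplicated regions)
yields all-zero residuals rather than a division by zero, so duplicated
regions prune each other.

Mapping scores are Spearman correlations (midrank ties) between a
sample's expression and each region's energies over the union of
selective genes present in the panel (≥ 5 required), z-normalized per
sample across regions (population SD, so each row has mean 0, variance
1). Scores are invariant to any strictly monotone per-sample transform of
expression. A constant expression vector leaves that sample's scores
missing, with a warning.

## Group statistics

Welch tests are unpaired, two-sided, without equal-variance assumption
(Welch–Satterthwaite df). Degenerate cases follow explicit conventions:
both groups constant and equal → t = 0, p = 1 (logged); constant but
different → p = 0 limit. One-way ANOVA is computed from explicit sums of
squares with (k−1, N−k) df. One-sample t tests (default mu = 0) serve
paired treated-minus-control log2 fold changes, FDR-corrected across
genes. FDR is Benjamini–Hochberg step-up with monotonicity enforcement,
input order preserved. FDR families are explicit in each caller: per-gene
families within a pooling window for time courses, per-contrast gene
families for treatments. Time-course comparisons first average replicate
samples of the same differentiation (by induction number), pool into the
named windows ~17.5 = [17, 18] dpi and ~35 = [30, 39] dpi, and skip (with
a warning) any window where a group has fewer than 2 differentiations.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with every latent variable recorded as ground truth.

* **Study design.** 27 PSC lines, 149 differentiations with a realistic
  per-line spread (2–26), most lines dorsal-prone, three partially and
  four highly ventral-prone, one partially and one highly caudal-prone
  line (the latter standing in for a line that consistently caudalizes).
* **Latent signaling.** Each differentiation draws
  `(wnt, hh) ~ N(line mean, 0.25²)`. The line means are fixed constants
  in the roster.
* **Fate link.** Region scores
  `cortex = 1.2 + wnt − hh`, `LGE = 0.3 + 0.6(hh − wnt)`,
  `MGE = 1.5·hh − wnt − 0.3`, `mid/hindbrain = 3(wnt − 1.8)`,
  `hypothalamus = −1.8` pass through a softmax into Dirichlet
  concentrations (kappa = 150). Higher Wnt favors cortex and, at high
  levels, mid/hindbrain; higher Hedgehog favors MGE/LGE; low Wnt favors
  MGE — the simplest monotone link consistent with the qualitative
  signaling model. The magnitudes are calibration constants of the
  simulation, not biological claims.
* **Ground-truth labels** come from fixed proportion thresholds: MGE in
  (0.15, 0.4] → partially, > 0.4 → highly ventralized; mid/hindbrain in
  (0.25, 0.45] → partially, > 0.45 → highly caudalized; else dorsalized.
  The MGE thresholds follow the generator's documented convention; the
  caudal thresholds are placed so the label boundary coincides with an
  expression gap the marker classifier can resolve. Arbitrary but fixed.
* **Expression.** Expected expression is the proportion-weighted mixture
  of five regional programs (markers ≥ 8-fold enriched in their home
  program, validated at generation; FOXG1 high in all forebrain
  programs); signaling readouts scale as `base · 2^(coef · activity)`
  (GAS1 with negative coefficient). A block of neutral genes
  (adhesion/guidance/Notch) is expressed independently of regional
  identity, diluting the axis signal the way real codesets' non-regional
  probes do. Counts are negative-binomial (size 60 endogenous, 200
  controls) around lane-scaled means (log-normal lane factor, sd 0.15),
  with 8 negative probes (mean 4), a 6-step positive ladder and 7
  housekeeping genes.
* **Time courses** share one neutral latent trajectory across groups
  before the divergence day (default 17 dpi) and follow line-specific
  means afterwards; `divergence_dpi = inf` yields an exact null.
* **Treatments** shift the latent activity of the treated arm before the
  mixture draw; control and treated arms share per-differentiation seed
  streams, so zero magnitude gives byte-identical datasets and the paired
  contrast isolates the effect.
* **Atlas fixture.** A shared log-normal baseline across regions with a
  60-fold boost for each gene of the 27-gene / 5-region selective
  partition, 140 correlated background genes and 0.3 log2 noise —
  constructed so the selective-gene procedure recovers the partition
  exactly (verified across seeds).

All generators are pure functions of (config, seed) via
`numpy.random.default_rng` seed sequences.

**What the simulation does not model:** colony/spatial effects,
single-cell heterogeneity, probe-specific chemistry (binding-density
artifacts), RNA-quality gradients, operator effects, and real biological
coupling between proliferation and patterning. Passing tests demonstrate
that the pipeline's inferences are correct *under the stated generative
assumptions*; they do not certify performance on real panel data.

## Problem sizes and calibration checks

The default suite and acceptance script run the 149-differentiation
cohort end-to-end, 50 random training sets for the threshold-fitting
oracle, 1,000 random marker vectors for the classifier truth table, 20
random profile sets for the selective-gene oracle, 2,000 replicates of
the Newcombe null (line n = 26 vs cohort n = 123 at p = 0.58, matching
the cohort's scale), and 10,000 replicates each for the Welch
(N(0,1) vs N(0,4), n = 10/10) and ANOVA (3 × n = 10) type-I simulations.
These sizes give Monte-Carlo standard errors comfortably below the ±1
percentage-point bands the calibration tests assert.

## Known limitations

* The nSolver MultiRLF merge algorithm is proprietary; the
  geometric-mean-of-ratios reconstruction is standard but not guaranteed
  bit-identical to vendor output.
* Cluster identities (EC/LC-style names) are label-compatible, not
  guaranteed identical to any particular published cut, since the
  original linkage and cut heights are not fully specified.
* The classifier's published numeric cutoffs are not available; fitted
  cutoffs reproduce the procedure, not the exact printed dashed lines.
* Reproducing the published headline numbers requires the study's
  deposited normalized expression tables and atlas exports; without those
  files the pipeline validates against its own ground-truthed simulation.
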