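# Methods

This note documents the models and procedures implemented in `sumosite`,
the parameters that matter, the choices made where the design was open,
and what the bundled synthetic data can and cannot demonstrate.

## Window extraction and the consensus motif

Candidate sites are all lysines of a protein, each represented by its
7-residue window: upstream slots `w-_1, w-_2, w-_3` and downstream slots
`w+_1, w+_2, w+_3`, numbered so that `w-_3` and `w+_1` are adjacent to the
central K. Lysines closer than three residues to a terminus are **kept**,
with the missing slots marked padded; padded slots contribute zeros to all
positional features. Discarding them would silently change dataset counts,
and the neutral-zero convention is harmless under min–max scaling.

The consensus predicate is `w-_3 ∈ {I,V,L,M,A,P}` and `w+_2 ∈ {D,E}`,
identical to the baseline scanner's pattern `[IVLMAP]K.[DE]`. The Ψ set is
fixed to those six residues for both; each lysine is judged on its own
context (lookahead-style scanning), so overlapping motifs are all
reported. Ambiguity codes (X, B, Z, U) are legal in sequences but never
satisfy any character class and carry zero hydrophilicity/volume.
Coordinates are 1-based in every file and report.

## Feature encoding

137 features per site: 120 positional one-hot indicators, 6 per-slot
Hopp–Woods hydrophilicity values, `Consensus`, `wDE`, `wK`, `Flexible`,
`DisorderReal`, `DisorderBinary`, `TerminalBinary`, `SignedLength`,
`BeforeVol`, `AfterVol`, `Difference` — 126 binary, 11 real. The split is
asserted at module load.

Numerical conventions, chosen where reasonable alternatives exist and
exposed in the API:

* `DisorderBinary` uses an **inclusive** 0.5 cutoff (tendency == 0.5 maps
  to 1); the cutoff is a function argument.
* The terminal region test is an exact fractional comparison
  (`position ≤ 0.1·L` or `position > 0.9·L`), no rounding.
* All 137 features pass through the same min–max scaler; binary columns
  that contain both values are unchanged by it. Constant training columns
  map to 0. Test data scaled with training parameters is **not clamped**,
  so out-of-range values fall outside [0, 1] — the usual semantics of
  sparse-format SVM scaling.
* The Hopp–Woods and Kharakoz tables are shipped as versioned TSV data
  files with citations in their headers.

Flexibility and disorder are consumed from annotation TSVs rather than
computed: the original predictors (FlexPred for conformational
flexibility, IUPred for disorder tendency) are external tools outside this
package's scope. A null provider (all zeros) lets the pipeline run without
them, which doubles as the "without flexibility & disorder" ablation; the
config toggles `use_flexibility` / `use_disorder` drop the corresponding
columns instead (134 features when both are off).

## ReliefF feature selection

Merit of a feature is the expected weighted difference of feature mismatch
between an instance's k nearest misses and k nearest hits. Parameters:
k = 10 neighbours, every instance sampled, Manhattan distance on scaled
features, exponential rank weighting `exp(-(rank/σ)²)` with σ = 2
normalized to sum to one within each neighbour group — i.e. a
distance-weighted variant of the standard ReliefF update. Ties in merit
break by canonical feature order, making the ranking deterministic and
invariant to instance order.

The wrapper evaluates top-c feature subsets by 10-fold cross-validated
MCC at a fixed (C, γ) — the grid-search optimum is not re-tuned per count,
a deliberate tractability trade-off (re-tuning could shift the optimum for
small counts). Equal MCC prefers fewer features. A stride parameter
coarsens the count sweep when 137 nested fits are too expensive.

## Weighted RBF-SVM

scikit-learn's `SVC` (libsvm) with per-class penalties `weight·C`;
weights default to negative:positive = 1:5, read as up-weighting the
minority positive class to counteract the ≈1:20 imbalance without
resampling (the orientation is configurable). The hyperparameter grid is
C ∈ 2⁻⁵..2¹⁵, γ ∈ 2⁻¹⁵..2³ in exponent steps of 1; when the argmax lands
on a border, that axis is extended one step at a time, never more than 5
exponent steps past the original margin. The grid objective is stratified
10-fold cross-validated MCC (the selection criterion used elsewhere in the
pipeline; the choice is an argument). Solver settings (shrinking,
tolerance, cache) stay at library defaults and are recorded in the saved
model bundle's metadata.

Predictions act on raw decision values only — no probability calibration.
Named thresholds low/medium/high = −0.5/0/0.5; any numeric cutoff is
accepted, so operating points like −0.4 are expressible. Sensitivity is
non-increasing and specificity non-decreasing in the threshold.

## Statistical screening

Three strategies: positive vs negative windows, consensus-positive vs
non-consensus-positive, consensus-negative vs non-consensus-negative.
Binary features get a Pearson chi-square test of independence (df = 1);
Yates' continuity correction applies iff some **observed** cell is < 5 —
the rule is read literally on observed counts, not expected ones (an
expected-count convention would be a one-line change and is noted in the
code). Features constant across both groups are reported as explicit
"untestable" rows. Real features get a two-tailed Mann–Whitney U with
midranks for ties, oriented to the positive group, so
PS = U/(n₁n₂) estimates P(positive value > negative value). The z
statistic is `(U − n₁n₂/2)/√(n₁n₂(n₁+n₂+1)/12)` with **no tie
correction** by default (a tie-corrected variant sits behind a flag), and
the p-value is the two-tailed normal approximation rather than an exact
permutation p. Benjamini–Hochberg adjustment is applied within each
strategy's family of (testable) tests — one family per strategy, 137
tests each — and significance is flagged at α = 0.05.

## Evaluation

Acc, Sp, Sn and MCC from confusion counts, with 0/0 ratios and a zero MCC
denominator resolving to 0. Cross-validation is **stratified**: with ~4%
positives, plain random folds can lack positives entirely. This is a
design choice, and a documented deviation risk when comparing against
results obtained with unstratified folds. It is repeated 25 times by
default with fresh
partitions, averaged over folds then repeats, with standard deviations
retained. Self-consistency trains and evaluates on the same data to
measure fitting capacity. ROC curves come from a threshold sweep with
trapezoidal AUC; across repeats, TPR is vertically averaged on a fixed
101-point FPR grid and AUC is taken from the averaged curve. Report tables
round to 2 decimals; full precision is kept in the objects.

## Synthetic data: what it emulates, and what it does not

The generator plants, per site class, the reported marginal structure:

| quantity | positive | negative |
|---|---|---|
| class mix (cons-pos/noncons-pos/cons-neg/noncons-neg) | 3.23 / 1.09 % | 3.39 / 92.29 % |
| Glu at `w+_2` | 0.81 | 0.07 |
| Asp at `w+_2` | 0.08 | 0.05 |
| extra Lys at `w+_2` / `w-_3` | 0.01 / 0.03 | 0.09 / 0.09 |
| Arg at `w+_2` / `w-_3` | 0.01 / 0.01 | 0.06 / 0.07 |
| His at `w+_2` | 0.002 | 0.03 |
| Pro at `w+_3` | 0.19 | 0.06 |
| Ψ total at `w-_3` | 0.80 (I/V-heavy) | background |
| flexible central K | 0.57 | 0.44 |
| disordered central K (binary) | 0.59 | 0.39 |

Effects are planted independently per position given the class — the
simplest model consistent with reported marginal proportions. The positive
Ψ block is split I .35 / V .27 / L .16 / M .08 / A .09 / P .05 of its 0.80
total, reflecting the strong isoleucine/valine preference positive-site
logos and the top-ranked positional indicators show; without it,
consensus positives would be statistically exchangeable with consensus
negatives, which real data contradicts. Windows are drawn from these
distributions and rejection-sampled so consensus classes satisfy the
motif predicate and non-consensus classes fail it; conditioning slightly
shifts realized marginals (Glu at `w+_2` in positives realizes near
0.75–0.85 rather than exactly 0.81). Disorder tendencies are drawn from
Beta(2, 1.5) rescaled to [0.5, 1] for disordered residues and Beta(1.5, 2)
rescaled to [0, 0.5) otherwise, so the binary exceedance matches the class
probability exactly. Protein lengths are uniform on 100–600 so the
terminal-region features take both values; backgrounds are uniform over
the 20 residues; all labeled windows are interior (no padded labeled
sites) and non-overlapping.

Not modeled: realistic proteome composition, higher-order positional
correlations, paralog structure, the joint distribution of features in
non-consensus positives (unknown; the generator plants the same positive
profile and conditions on motif failure), and PTM cross-talk such as the
acetylation–sumoylation switch. Consequently, passing tests demonstrate
that the pipeline recovers structure of the planted kind at realistic
effect sizes and imbalance — not that the classifier attains any
particular performance on real proteins.

## Problem sizes and defaults used in checks

End-to-end checks and `scripts/acceptance.py` run the generator at its
defaults — 2,600 labeled windows (~4% positive) across 260 proteins — with
the grid search over the full exponent ranges at stride 2 scored by 5-fold
CV, 5-fold cross-validation with 5 repeats, and the feature-count sweep at
stride 20. Stride-1 grids and 25 repeats are the library defaults and
change probe-run results only marginally (the stride-2 and stride-1 grids
chose the same optimum on probe data).

## Known limitations

* Published performance on the original curated dataset (CV MCC 0.66,
  Sn 73%, Sp 98%, Acc 97%, AUC 0.91, the 93-feature optimum and the
  reported merit values) depends on that external dataset plus external
  FlexPred/IUPred annotations; none of it is bundled, so those exact
  numbers are out of reach here. The README describes how to plug in a
  real dataset and annotation TSVs to attempt full reproduction.
* The ReliefF neighbour count and sampling size of the original
  feature-selection run are not certain; the implementation adopts the
  common defaults (k = 10, all instances) plus distance weighting.
* Whether the original cross-validation was stratified is unknown;
  stratification is used here for the reasons above.
* The Kharakoz volume table is transcribed from secondary literature; its
  exact values only enter as monotone per-residue weights in three
  min–max-scaled features.
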