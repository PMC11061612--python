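# Methods

This note documents the models and procedures implemented in
`comboscreen`, the defaults chosen where the design was genuinely open,
and what the synthetic-data validation does and does not establish.

## Dose-response model

Single-agent responses on the growth-inhibition scale are modelled with a
two-parameter logistic with asymptotes fixed at 0 and 1:

    f(d) = 1 / (1 + (IC50 / d)^s)

* `IC50` (concentration units) — position; `s` (dimensionless) — shape.
* Fitting clips observed inhibition into [0, 1] (probability semantics),
  minimizes squared error in (log IC50, log s), and restarts from a
  coarse vectorized grid over 25 log-spaced IC50 candidates × 7 slopes
  before one local refinement — a cheap guard against the multiple local
  minima that flat or non-monotone curves induce. Slope is bounded to
  [0.05, 20].
* Single-agent **Emax** is the fitted value at the highest screened dose,
  not the raw top-dose well.
* IC50 estimates outside the tested 1,000-fold range are flagged
  censored (`left`/`right`) rather than trusted as extrapolations; a fit
  that fails outright reports the observed top-dose value as Emax with
  `converged=False`.

Fits are per experiment (one drug, one cell line, one plate). A pooled
mixed-effects formulation across the screen could shrink noisy fits but
would couple all experiments; the per-experiment fit keeps the extracted
quantities (Emax at top dose, IC50) identical in definition and every
experiment independent.

Normalization maps raw signal linearly so the DMSO negative-control mean
is 0 and the blank (cell-free) mean is 1. Values are deliberately *not*
clipped at normalization time: inhibitions slightly outside [0, 1] carry
information about noise and control placement; clipping happens only
where a probability reading is required (fitting and synergy excess).

## Synergy scores

With marginals `E_A(i)`, `E_B(j)` and combination wells `E_AB(i, j)` all
clipped to [0, 1]:

* Bliss excess: `E_AB − (E_A + E_B − E_A·E_B)`.
* HSA excess: `E_AB − max(E_A, E_B)`.
* **Matrix score** = mean excess over all wells. The alternative
  "highest single well" reading is exposed via `matrix_aggregate="max"`,
  but the mean is primary: only a mean can go negative while a window is
  positive, the signature of localized synergy.
* **Window score** = max over all contiguous 3×3 windows of the
  within-window mean; on 7×7 there are 25 windows, on a 5×5 trimmed
  matrix 9. Argmax ties break row-major (smallest row, then column),
  and window means are computed directly per window so exact ties stay
  exact.
* Combo Emax = second-highest well, so one outlier well cannot set the
  maximum-effect estimate.

Per-well Bliss excess never exceeds HSA excess (Bliss expectation
dominates the larger marginal), so Bliss matrix/window scores are
bounded by their HSA counterparts; this ordering is property-tested.

## Plate QC

CV, NC0/NC1 ratio and Z-factor use sample (n−1) standard deviations.
Defaults: CV < 0.18 (the screen-specific 0.17985 is accepted via
config), ratio in [0.8, 1.2], Z ≥ 0.3 with a relaxed 0.2 for flagged
hard-to-assay lines; the Z gate applies only to positive controls the
line responds to (NC1/PC mean ratio ≥ 4) and is skipped, not failed,
otherwise. "Significant inconsistency" between replicates has no
standard numeric definition; it is implemented as a stand-in rule —
replicate range at a dose point > τ (default τ = 0.3 inhibition units),
a drug failing when ≥ 2 dose points in one line or ≥ 2 lines are
flagged — chosen because it is simple, monotone and unit-consistent.

## Prioritization

Activity: combo Emax > 0.5 **and** HSA > 0.1, both strict. The HSA
*matrix* score feeds the call by default (`hsa_column` switches to the
window score; which variant the original workflow used is not
documentable, so both are first-class). Responder percentages are
reported to one decimal, round-half-up (3/7 → 42.9). The specificity
score uses the number of cancer types the combination was actually
tested in, not a fixed panel-wide count, so half-panel combinations are
not penalized. The breadth filter drops combinations sensitive
(≥ 10% responders) in ≥ 50% of their tested types; the three filters are
pure row predicates and commute, which is asserted by permutation
testing.

## Biomarker ANOVA

Each (feature × metric × combination × subgroup) test is the F-test of
the binary feature in an OLS model of the response. Pan-cancer runs add
cancer-type dummy covariates (flag `pan_cancer_covariate`, default on
pan-cancer, off in subgroups, where tissue is constant or the subgroup
*is* the context); the feature term is then a partial F-test computed by
Frisch–Waugh residualization, which reduces exactly to one-way ANOVA
(F = t², pooled variance) when no covariates are present — both
identities are tested against scipy/statsmodels. Glass deltas are
|mean difference| / per-group SD for both groups; groups below 3 lines
skip the test with a reason rather than reporting p = 1. BH FDR is
computed within each (subgroup × metric) family, the granularity at
which the per-analysis results are interpreted. Expression is binarized
within the analysis panel at |Z| ≥ 2 into `GENE_up` / `GENE_down`
features, so basket and pan-cancer binarizations can legitimately
disagree. Cancer-type subgroups require ≥ 20 cell lines.

Emergent flagging: a significant combination-metric association is
emergent iff the same feature, same subgroup, same combination is
significant for neither single-agent Emax. Matching is within-subgroup;
matching against significance in *any* subgroup would be stricter and is
not what "excluding monotherapy-driven markers" implies here. Emergent
biomarkers are partitioned at the (feature, combination, subgroup) level
into Bliss-only / both / combo-Emax-only; the three classes are disjoint
and sum to the emergent total by construction.

## Pathway enrichment

Per mechanism category: Es = nc/Nc observed versus Er = nb/Nc where nb
is the mean category count when the n active labels are redistributed
uniformly at random over all combination–cell-line pairs (10 replicates
by default, configurable). This permutation reading of "enrichment by
random" conserves the total active count in every replicate; an
alternative reading (resampling category labels) would not. The
empirical p (fraction of replicates reaching the observed count) is an
extension beyond the binary Es > Er verdict and is labelled as such.
Counting by combination instead of by pair is available via `unit=`.

## Synthetic screen generator

The generator emulates: 7-point log-equispaced dose ladders spanning a
1,000-fold range (top dose 10 concentration units); per (drug, line)
logistic curves with log10 IC50 ~ Normal(log10 top dose, 0.8) and slope
~ Uniform(1, 2.5), giving the wide single-agent Emax spectrum a
pan-cancer panel shows; Bliss-additive combination baselines; localized
synergy as a 3×3 window of wells boosted by 0.3 (defaults) in a
configurable fraction of pairs; i.i.d. Gaussian well noise on the
inhibition scale (default SD 0.05, a free parameter since the real
well-level noise magnitude is not published), not clipped, so QC and
normalization see realistic out-of-range values; per-plate Gaussian
control populations (155 + 155 negative, 16 + 16 positive, 28 blank
wells) whose means/SDs are set so plate statistics sit near typical
screen medians (CV ≈ 0.12, Z ≈ 0.5, NC ratio ≈ 1); and a Bernoulli(0.3)
binary feature matrix.

Planted biomarker effects are additive shifts on the inhibition scale
for feature-positive lines: single-agent effects shift one drug's
response truth (and propagate into its combinations through the Bliss
baseline — the monotherapy-driven case), emergent effects shift only one
combination's wells, leaving both monotherapies untouched.

Window placement: combination inhibition is capped at 1, so a boost
planted where the Bliss baseline is saturated leaves no trace in the
data and cannot act as ground truth. Planted windows are therefore drawn
uniformly among locations where at least half the boost is expressible
on average; when no location qualifies (both drugs near-maximally active)
the pair is recorded as having no window. Under these conditions the
window argmax of the Bliss excess localizes the planted window in ≈ 98%
of pairs at boost 0.3 / noise 0.05.

Randomness: one global seed expands into fixed per-entity substreams
keyed by (seed, stream tag, entity indices), so adding cell lines or
combinations never perturbs existing data and all outputs are
byte-reproducible.

What the generator does *not* emulate — and hence what passing recovery
tests cannot show about real screens: plate spatial/edge artifacts,
pharmacokinetic or mechanistic dose–response shapes beyond the 2-parameter
logistic, Loewe-type dose-additivity, correlated noise between wells,
cell-line lineage structure in the feature matrix, or linkage
disequilibrium between molecular features.

## Problem sizes and numerical choices

The bundled validation runs at desk scale by design: default screens of
80 lines × 6 combinations; null ANOVA calibration over 20 seeded
screens of 60 × 3 (≈ 3,600 tests pooled, checked with a one-sided exact
binomial test against the nominal 0.001 rate, since a point assertion on
a Monte-Carlo rate would be ill-posed); window recovery over ~200 pairs;
emergent-biomarker sensitivity over 5 screens of 150 lines with two
planted effects each (0.25 inhibition-scale shifts, i.e. 5× well noise —
a strong but realistic synergy biomarker). Degenerate inputs are
contracts, not silent NaNs: zero-mean CV, equal control means, windows
outside the grid, non-binary MOBEM values, unlabeled cell lines and
missing control classes all raise typed errors.

## Known limitations

* Per-experiment logistic fits have no cross-experiment shrinkage; very
  flat curves yield censored, low-information IC50s (flagged, not
  hidden).
* The replicate-inconsistency rule is a declared stand-in (see above).
* ANOVA assumes homoscedastic residuals within a test; with binarized
  metrics bounded in [0, 1] this is approximate near the boundaries.
* The enrichment null conditions on the observed number of active pairs
  only; it does not preserve per-combination activity correlation within
  a category.
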