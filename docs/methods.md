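# Methods

`dynatrauma` implements a stratified analysis of trauma-induced systemic
inflammation: blunt-trauma patients are split at an admission arterial base
deficit (BD) of 4 mEq/L, and the two strata are compared on clinical
outcomes (2×2 contingency statistics), circulating mediator trajectories
(two-way ANOVA and AUC fold changes), and time-windowed correlation
networks (Dynamic Network Analysis, DyNA). Because no patient-level biobank
is bundled, a synthetic cohort generator reproduces the statistical
structure the analysis assumes and provides planted ground truth for
network recovery.

## Cohort model

Each patient belongs to one of two strata. Admission BD is drawn from a
stratum-conditional truncated normal — BD < 4: mean 1.7, SD 0.84, truncated
above at 4 mEq/L; BD ≥ 4: mean 6.7, SD 3.67, truncated below at 4 — so the
stratum label and the BD value are always consistent. The SDs are the SEMs
of the two stratum means (0.1 and 0.4 at n = 70 and 84) scaled back to
per-patient SDs. Other clinical covariates (age, ISS, GCS, admission
SBP/HR, ICU/hospital length of stay, ventilator days, daily organ
dysfunction scores, transfusion and surgery indicators, disposition) are
drawn from normals/Bernoullis calibrated to the stratum-level mean ± SEM
summaries and proportions of the source cohort; they exist so the
stratification and reporting code has realistic input, not as a mechanistic
model of trauma physiology.

Mediator concentrations are log10-normal:

    log10 C_imt = mu[m, g(i), t] + sigma_m * z_imt

with a per-mediator baseline, an early-peak-then-decay time profile, and a
stratum offset equal to log10 of the target fold elevation. Cytokine panel
data are strongly right-skewed, which motivates the log-normal form; the
distributional family is a modelling choice of this package, not an
empirical fact about any particular assay. Default folds for the elevated
mediators follow the published AUC fold ranking (IL-1RA 3.1 down to TNF-α
1.2) and the baselines put group-mean concentrations on the published
0–24 h AUC scale (AUC/24 h, corrected for the lognormal mean factor
exp((ln10·σ)²/2) ≈ 1.53 at the default σ = 0.4 log10 units).

Within a *planted block* — a (stratum, time-window, mediator-subset, ρ)
tuple — the residuals z of the block mediators at any draw inside the
window are equicorrelated: z = √ρ·u + √(1−ρ)·e with a shared u per draw.
Outside blocks residuals are independent. The default configuration plants
one block of 10 mediators at ρ = 0.85 in the BD ≥ 4 stratum during the
0–8 h and 8–16 h windows only, which is the condition the network-recovery
tests exercise. Scheduled draws are dropped whole-panel with probability
`missing_prob` (default 0.1); the random stream is consumed regardless so
missingness never reshuffles later patients' values. Values below the
per-mediator LOD are replaced by LOD/2 and flagged censored (the
conventional multiplex substitution); the default LOD of 1 pg/mL censors
essentially nothing under the default means.

The nominal draw grid is 4, 12, 20 h (one draw per 8 h window of the first
day) and then 48…168 h daily. The within-24 h times are a design choice —
only "three draws in the first 24 h" is specified by the emulated protocol —
placed so each DyNA window contains exactly one draw per patient.

What the generator does **not** emulate: within-patient autocorrelation
across days, assay batch effects, informative missingness (sicker patients
missing draws), or any mechanistic coupling between mediators and organ
dysfunction. Passing recovery tests therefore demonstrates correctness of
the analysis code under the stated statistical model, not clinical validity
on real biobank data.

## Stratification and clinical statistics

Exclusions use strict thresholds: ethanol > 10 ng/dL (documented alcohol
intoxication) or prehospital fluids > 2 L are removed; boundary values are
retained, missing values raise rather than pass silently. Stratification is
BD ≥ 4 versus BD < 4 (cutoff inclusive above). Shock Index is HR/SBP with
hypovolemic shock flagged strictly above 1.

The relative risk on a 2×2 table (a,b exposed event/non-event; c,d
unexposed) is (a/(a+b)) / (c/(c+d)) with the Katz log-method CI

    exp( ln RR ± z_{1−α/2} · sqrt(1/a − 1/(a+b) + 1/c − 1/(c+d)) ).

The Katz method is the default because it reproduces the published interval
[1.056, 2.033] exactly from the printed surgical-intervention counts. Zero
event counts raise with a pointer to an explicit continuity correction
(add 0.5 to every cell) rather than applying one silently. The Pearson
chi-square is uncorrected by default (a Yates flag exists): the uncorrected
statistic is consistent with the published p ≈ 0.02 for 51/84 vs 29/70.
Fisher's exact test is two-sided by probability-mass summation. The
Mann–Whitney U test is exact by enumeration when n1+n2 ≤ 12 and the pooled
sample is tie-free, otherwise a normal approximation with midrank tie
correction. No time-to-event model is provided: the reported "risk" claims
are risk ratios from 2×2 tables, and no hazard machinery is warranted by
them.

## Trajectories

Raw draw times map to the nominal grid by half-open bins
[edge_i, edge_{i+1}); duplicate draws of one mediator in one bin are
averaged; draws at/after 192 h are dropped with a logged count. Group×time
effects are tested per mediator by fixed-effects two-way ANOVA on
log10-transformed concentrations (raw scale available): Type III sums of
squares with sum-to-zero contrasts via an OLS decomposition, so unbalanced
stratum sizes are handled and the balanced case reduces to the classical
partition. There is deliberately no subject random effect — the emulated
analysis treats all observations as exchangeable within cells — and a
mixed model would give different (generally more conservative) group
p-values on real repeated-measures data. No multiplicity correction is
applied across the 22 mediators by default; a Benjamini–Hochberg adjustment
can be applied to the returned p-values by the caller.

The AUC of a group-mean trajectory is the trapezoidal integral of the cell
means over the stated interval (pg/mL integrated over hours; reported under
the conventional "pg·h/L" label of the emulated tables despite the apparent
unit mismatch, which we document rather than rescale). Trapezoids are the
default because the units imply time integration; a sum-of-means
alternative is exposed (`method="sum"`) for sensitivity checks. Missing
interior cells are spanned by the trapezoid; nothing is extrapolated beyond
the first/last observed point. Fold change is AUC(BD≥4)/AUC(BD<4),
restricted to mediators with ANOVA group-effect p < α (the group effect,
not the interaction, is the default inclusion rule; the emulated tables'
precise rule is not stated), sorted descending with ties broken by name.

## DyNA

For each stratum and each adjacent 8 h window of the first day (0–8, 8–16,
16–24 h), each patient contributes the mean of their log10 concentrations
inside the window (one value per patient avoids mixing within- and
between-patient variation; pooling raw samples is the untestable
alternative). Pearson correlation on these per-patient values is the
default (Spearman via flag). A mediator pair forms an edge when r ≥ 0.7,
reading the threshold literally as signed positive co-variation; an
absolute-value mode exists because negative correlations are otherwise
ignored. Pairs with fewer than `min_pairs = 8` complete patient pairs never
form edges — a floor against spurious small-overlap correlations.

Network density is

    density = E·N / (N(N−1)/2) = 2E/(N−1),

with N the number of *connected* nodes (degree ≥ 1) by default, matching
the metric's intent of accounting for the size of the active network;
`node_rule="all"` uses the full panel instead. Density is 0 for empty
networks, and equals N on complete graphs by construction. No statistical
test is attached to density differences (none is defined for the emulated
metric).

## Numerical and design notes

- All randomness flows through one `numpy.random.Generator` owned by the
  run; identical config + seed give identical tables, and CSV floats are
  written at %.6g so manifests hash identically across reruns.
- Degenerate inputs raise early with the offending field or cell named:
  constant ANOVA data, empty design cells, zero-variance correlation
  columns (missing r + warning), zero RR event counts, sbp ≤ 0.
- Test and acceptance problem sizes: network recovery runs at the study's
  own 70/84 patients; ANOVA calibration uses 1,000 null datasets at
  20/group × 3 time points; the density identity is checked on 1,000
  random graphs.

## Known limitations

Fixed-effects ANOVA on repeated measures, no partial-correlation or
directed network inference, no survival analysis, no multivariable
adjustment, and the synthetic-data caveats above. The published network
figures and density curves depend on the undeposited patient data and are
represented here only by planted-structure recovery properties.
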