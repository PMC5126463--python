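# dynatrauma

Analysis of post-trauma systemic inflammation stratified by admission
arterial **base deficit (BD)** — the amount of base (mEq/L) needed to
titrate whole blood back to normal pH, an early marker of metabolic
acidosis and hypoperfusion after injury. Blunt-trauma patients are split at
BD = 4 mEq/L (BD < 4 vs BD ≥ 4), and the package asks how the two strata
differ in clinical course and in the dynamics of their circulating
inflammatory response, measured as a 22-analyte cytokine/chemokine panel
(pg/mL) sampled three times in the first 24 h and daily through day 7.

It is aimed at systems-immunology and trauma-research groups who have
long-format multiplex immunoassay data plus a per-patient clinical table,
or who want a reproducible, seeded simulator of such a cohort.

Four components, organised as model/results objects:

- **Synthetic cohort** (`generate_cohort`, `SimulationConfig`):
  seed-reproducible two-stratum cohorts with log10-normal mediator
  concentrations, plantable within-window correlation blocks, LOD
  censoring, and missing draws.
- **Stratification & clinical statistics** (`apply_exclusions`,
  `stratify_by_bd`, `ContingencyTable2x2`): exclusion rules (ethanol
  > 10 ng/dL, prehospital fluids > 2 L), the BD split, Shock Index
  (HR/SBP, shock if > 1), and 2×2 statistics — relative risk
  RR = (a/(a+b))/(c/(c+d)) with the Katz log CI
  exp(ln RR ± z·√(1/a − 1/(a+b) + 1/c − 1/(c+d))), chi-square, Fisher
  exact, Mann–Whitney U, mean ± SEM summaries.
- **Trajectories** (`TrajectoryAnalysis`): half-open time-binning onto a
  nominal grid, per-mediator two-way group×time ANOVA (Type III,
  sum-to-zero contrasts, log10 scale), trapezoidal AUC of the group-mean
  trajectory, and the fold-change ranking AUC(BD≥4)/AUC(BD<4) restricted
  to mediators with a significant group effect.
- **DyNA** (`DynamicNetworkAnalysis`): per-stratum correlation networks in
  adjacent 8 h windows (0–8, 8–16, 16–24 h) of per-patient window-mean
  log10 concentrations, edges where r ≥ 0.7, and the density metric
  density = E·N / (N(N−1)/2) = 2E/(N−1) over the connected nodes.

A `click` CLI (`dynatrauma simulate|stratify|trajectories|dyna|report|all`)
drives the pipeline end to end and writes CSV tables, GraphML networks and
a hash manifest.

## Worked example

```python
import dynatrauma as dt

# published surgical-intervention counts: 51/84 (BD>=4) vs 29/70 (BD<4)
rr = dt.ContingencyTable2x2(51, 33, 29, 41).relative_risk()
print(f"RR = {rr.rr:.2f}, 95% CI [{rr.ci_low:.3f}, {rr.ci_high:.3f}]")

cfg = dt.default_config(seed=1)                 # 70 vs 84 patients, 22 mediators
patients, samples = dt.generate_cohort(cfg)
groups = patients.set_index("patient_id")["group"]

print(dt.dyna_run(samples, groups).summary())
traj = dt.TrajectoryAnalysis(samples, groups, interval=(4.0, 20.0)).fit()
print(traj.summary())
```

prints

```
RR = 1.47, 95% CI [1.056, 2.033]
Dynamic network analysis (r >= 0.7, pearson, node rule: connected)
 group window  edges  nodes density
BD_GE4   0-8h     45     10   10.00
BD_GE4  8-16h     45     10   10.00
BD_GE4 16-24h      0      0    0.00
BD_LT4   0-8h      0      0    0.00
BD_LT4  8-16h      0      0    0.00
BD_LT4 16-24h      0      0    0.00
Trajectory analysis (group x time ANOVA + AUC fold ranking)
  interval: 4-20 h, transform: log10, alpha: 0.05
  mediators analysed: 22; significant group effect: 14

mediator  auc_BD_GE4  auc_BD_LT4 fold_change  p_anova
  IL-1RA 2558.797219  933.368839         2.7 4.73e-74
    IL-7  234.124000  114.622940         2.0  8.6e-42
    IL-8  234.235503  117.556270         2.0 2.34e-37
    ...
```

The relative risk of requiring surgery within 24 h is 1.47 (≈1.5) with the
95% CI [1.056, 2.033]: an elevated admission BD is associated with a ~50%
higher risk of urgent operative management. In the simulated cohort, the
ρ = 0.85 correlation block planted among 10 mediators in the BD ≥ 4 stratum
during the first two 8 h windows is recovered as exactly its 45 pairwise
edges (density 10 = the complete-graph value 2E/(N−1)), while the BD < 4
stratum and the 16–24 h window stay empty — the qualitative signature of a
denser early inflammatory network in the high-BD stratum that dissolves by
24 h. The fold-change table ranks the planted elevations (IL-1RA top) with
their ANOVA group-effect p-values.

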