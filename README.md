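# betaglut

Kinetic modelling of glucose transport and phosphorylation in the human
pancreatic β-cell, in health and Type 2 diabetes (T2D).

β-cells sense blood glucose by taking it up through the facilitative
transporters GLUT-1 (Km ≈ 3 mM) and GLUT-2 (Km ≈ 17 mM) and phosphorylating
it with glucokinase (GK), the pathway's normal pacemaker. In T2D the
membrane residency of both transporters collapses (to ~14% and ~5% of
normal), and below a critical expression level *transport*, not GK, becomes
rate-limiting for glucose-6-phosphate (G6P) production — a metabolic
"tipping point" that disables glucose sensing. This package implements:

- the **reduced model**: bidirectional Michaelis–Menten transport plus Hill
  GK kinetics,

  dGᵢ/dt ∝ Σₜ εₜ·Vₜ·[Gₒ/(Kₜ+Gₒ) − Gᵢ/(Kₜ+Gᵢ)] − V_GK·Gᵢʰ/(S₀.₅ʰ+Gᵢʰ),

  with S₀.₅ = 8 mM, h = 1.7, and εₜ the membrane-expression fraction of
  transporter t relative to healthy;
- **calibration** of the unprinted maximum rates from steady-state anchors
  (see below), with an explicit residual report for redundant anchors;
- the **threshold analysis**: steady-state GK-rate surface over
  (ε₁, ε₂), the critical iso-rate contour, and classification of scenarios
  as phosphorylation- vs transport-limited;
- the **regulatory network**: HNF1A/FOXA2 expression and nuclear
  translocation, two-layer transcription (promoter binding + HNF1A-driven
  histone acetylation) of *GLUT1*, *GLUT2* and *MGAT4A*, GNT-4A-dependent
  N-glycosylation, and lectin-mediated membrane retention with glycan
  competition — all feed-forward into the reduced model;
- local **sensitivity analysis** ranking therapeutic control points by the
  normalized coefficient S = (RNA/v_GK)·∂v_GK/∂RNA;
- **synthetic uptake assays** (lognormal multiplicative noise) and a
  least-squares harness that recovers (ε₁, ε₂) from them.

## Worked example

```python
from betaglut import calibrate_reduced, solve_steady_state, find_threshold_epsilon2

cal = calibrate_reduced()
print(cal.vmax_gk, cal.vmax_normal_glut1, cal.vmax_normal_glut2)
# 0.16963187685913642 0.4671039977183136 1.5876927470017133

params = cal.to_reduced_params()          # healthy: epsilon1 = epsilon2 = 1
healthy = solve_steady_state(params, 16.8)
print(healthy.glucose_in, healthy.gk_rate)
# 13.0 0.11795753389847644

t2d = solve_steady_state(params.with_epsilons(0.14, 0.05), 16.8)
print(t2d.glucose_in, t2d.gk_rate)
# 4.1270664821798855 0.041568363326994116

print(find_threshold_epsilon2(params, 16.8, critical_rate=0.07))
# 0.200000022568121
```

Calibration reconstructs the three maximum rates (nmol/min/10⁵ cells) from
printed steady-state anchors: a cell with 20% GLUT-2 and no GLUT-1 at
16.8 mM extracellular glucose sits at 6.5 mM intracellular glucose with a
GK rate of 0.07, and a healthy cell sits at 13.0 mM. At stimulatory glucose
the healthy cell phosphorylates at ~0.118 (prints as 0.12) — GK-limited —
while the T2D cell (14%/5% expression) reaches only ~0.042, well below the
0.07 critical rate: transport-limited. The critical GLUT-2 fraction in the
absence of GLUT-1 is exactly 20% of normal.

The numbered drivers under `analysis/` walk the full study: calibration,
the postprandial 2.8 → 16.8 mM excursion, the threshold scan, regulatory
perturbations (nuclear exclusion, glycan competitors), control-point
sensitivity, and parameter recovery; each writes TSV tables under
`results/`. A `betaglut` CLI exposes the same operations
(`betaglut calibrate`, `simulate`, `steady`, `threshold`, `sensitivity`,
`generate-data`, `recover`).

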