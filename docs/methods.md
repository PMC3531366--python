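# Methods

## Reduced model

The reduced model tracks two state variables: intracellular unphosphorylated
glucose `G_i` (mM) and a lumped phosphorylated pool (G6P plus downstream
glycolytic derivatives). Transport through GLUT-1 and GLUT-2 is
bidirectional facilitated diffusion, written as the difference of two
unidirectional Michaelis–Menten arms evaluated at the extracellular and
intracellular concentrations; at `G_i = G_o` the net flux is exactly zero.
Each transporter's maximum rate is `ε·V_N`, where `V_N` is the
normal-expression maximum rate and `ε ≥ 0` the fraction of
plasma-membrane-resident transporter relative to healthy (ε > 1 is allowed
for overexpression scans; negative values are rejected). Glucokinase
follows Hill kinetics with S₀.₅ = 8 mM and exponent 1.7; GK activity is
assumed identical in healthy and T2D cells.

The phosphorylated pool is purely cumulative — no consumption term — since
it lumps everything downstream; consequently all steady-state analyses are
phrased in terms of the GK *rate*, never the pool level.

Fluxes are in nmol/min/10⁵ cells. Converting flux to concentration rate
uses `volume_per_1e5_cells` (default 1e-7 L, i.e. ~1 pL of cell water per
cell, a typical β-cell volume). Steady states are volume-independent (the
balance equation divides through by the conversion factor); the volume only
sets the timescale of time courses. This is tested to 1e-9 relative over
two orders of magnitude of volume.

**Numerics.** Steady states are found by Brent's method on the bracket
`[0, G_o]` (absolute tolerance 1e-10 mM); the balance function is strictly
decreasing so the root is unique. Time courses use LSODA with
rtol 1e-8 / atol 1e-10, integrating piecewise between profile
discontinuities; excursions start from rest at the pre-step glucose level.
An independent ODE route (integrate until |dG_i/dt| < 1e-8 mM/min) agrees
with the root solve to better than 1e-6 mM and is exercised in the tests.
Degenerate inputs: with both ε = 0 the steady state is `G_i = 0`; with
`V_GK = 0` it is diffusive equilibrium `G_i = G_o`.

## Calibration from printed anchors

Only Km/S₀.₅/h and a few steady-state values are published for this system;
the three maximum rates are reconstructed:

1. `V_GK` from the threshold anchor: GK rate 0.07 nmol/min/10⁵ cells at
   6.5 mM intracellular glucose.
2. `V_N(GLUT2)` from the threshold flux balance at 16.8 mM extracellular
   glucose with ε₂ = 0.2, ε₁ = 0 (uptake = GK rate).
3. `V_N(GLUT1)` from the healthy flux balance at the healthy intracellular
   glucose 13.0 mM (the threshold glucose is 50% of healthy), using the
   calibrated GK curve on the right-hand side.

This yields `V_GK = 0.1696`, `V_N(GLUT1) = 0.4671`, `V_N(GLUT2) = 1.5877`
nmol/min/10⁵ cells. The healthy GK rate 0.12 is treated as a redundant
anchor: the calibrated model gives 0.1180 at 13.0 mM (residual −1.7%,
within two-significant-figure printing). Calibration always emits the
residual of every anchor and hard-errors if any exceeds 10% — redundancy is
reported, never silently absorbed. Anchor precedence (threshold pair + the
50% statement primary, healthy rate as the check) minimizes rounding-error
propagation into `V_N(GLUT1)`, by far the most anchor-sensitive parameter:
it is obtained as a small difference of larger fluxes, so a few percent of
movement in the healthy glucose anchor moves it several-fold. Conclusions
that hinge on the GLUT-1/GLUT-2 flux split (see Limitations) inherit this
uncertainty.

The computed threshold/healthy ratios are reported as computed (GK-rate
ratio 59.3% vs the rounded "60%", glucose ratio 48.3% vs "50%" when the
healthy level is re-derived by inverting the Hill curve at 0.12).

## Threshold analysis

The tipping point is operationalized as an iso-GK-rate condition: the
critical rate is the steady-state GK rate attained at the anchor scenario
(ε₁ = 0, ε₂ = 0.2) at 16.8 mM. The qualitative motivation — outward
transport becoming "comparable" to the GK rate — is not given a second,
independent numeric meaning. The contour of (ε₁, ε₂) combinations attaining
the critical rate is solved per-ε₁ by bisection in ε₂ (tolerance 1e-6)
rather than by interpolating a precomputed surface, which keeps the
low-expression corner accurate. Where GLUT-1 alone already exceeds the
critical rate the contour records ε₂ = 0 with a `saturated` flag. Scenarios
are classified transport-limited iff their steady GK rate is below
critical. Surface monotonicity in ε₁, ε₂ and glucose is tested on grids up
to 101×101.

## Regulatory network

All rate constants of the full model are unpublished; the model is
therefore non-dimensionalized: every species is normalized to its healthy
steady state, making the healthy fixed point the all-ones vector exactly
(derived synthesis constants guarantee this algebraically). Degradation and
turnover rates default to 0.1 min⁻¹; only steady-state *ratios* are
constrained by the available data, so kinetic timescales are indicative
only.

Structural choices, where the biology fixes the wiring but not the form:

- **TF dynamics** (HNF1A, FOXA2): first-order mass action for RNA, protein,
  nuclear import/export; degradation acts on both cytoplasmic and nuclear
  pools. The T2D/palmitate state is a single inhibitory factor `φ` scaling
  nuclear import of both factors by 1/(1+φ) — palmitic acid enters the
  model only through this term.
- **Promoter logic**: transcription multiplier = (acetylation / baseline) ×
  weighted sum of the two factors' promoter occupancies (Hill functions of
  nuclear abundance, half-saturation at baseline), normalized to 1 at the
  healthy state. The additive-binding × multiplicative-acetylation form is
  the minimal one in which HNF1A (acting on both layers) outranks FOXA2.
- **Promoter kinetic orders**: a shared inhibitory factor moves both
  nuclear TFs identically, so promoter *weights* cannot produce the
  unequal GLUT-1/GLUT-2 losses observed in T2D — any weighted sum of
  identical terms falls gene-independently. Gene-specific promoter Hill
  exponents carry that asymmetry instead. The default exponent is 0.35
  (GLUT1, MGAT4A) with 0.3 for the acetylation layer: shallow, sub-unity
  kinetic orders chosen so that a single exclusion factor can depress
  membrane GLUT-1 to 14% while keeping the transcriptional layer's local
  gain below the glycosylation layer's — the regime in which the
  glycosyltransferase is the pathway's dominant control point, as observed
  experimentally. The GLUT2 exponent is fitted (0.642).
- **Glycosylation/retention**: transporter synthesis ∝ its RNA; conversion
  unglycosylated → glycosylated ∝ GNT-4A protein × substrate (mass
  action); all post-translational constants shared between GLUT-1 and
  GLUT-2, so expression differences are purely transcriptional. Membrane
  residency balances a Hill-type lectin interaction (exponent 2,
  half-saturation at the baseline glycosylated pool) against first-order
  endocytic turnover; only glycosylated transporters are retained. A
  soluble glycan competitor of strength `s` divides the effective ligand by
  (1+s) (competitive binding).
- **Composition**: the healthy membrane is 80% GLUT-1 / 20% GLUT-2
  molecules; the GLUT-1 molecule fraction under any perturbation is
  0.8ε₁/(0.8ε₁+0.2ε₂) exactly (91.8% → "92%" in the fitted T2D state).

**Full-model fit.** The free parameters are solved sequentially and
exactly, exploiting the feed-forward structure: `φ` by bisection so that
membrane GLUT-1 = 14% of normal (φ = 20.17, nuclear TFs at 9% of normal);
the GLUT2 promoter exponent so that membrane GLUT-2 = 5%; one strength per
glycan against the mean printed membrane reduction (LacNAc 77.5%,
(LacNAc)₃ 52.5% of normal; shared post-translational kinetics force equal
fractional reductions for both transporters, so the per-transporter spread
in the measurements is treated as assay noise). A residual report is
emitted and checked (1% on the T2D fractions, 5% on the glycan targets).

**Steady states** are solved algebraically module-by-module (the cascade is
feed-forward); long-time BDF integration of the full 22-species ODE agrees
to 1e-6 relative and serves as the independent cross-check. RNA clamps
freeze a species at a fixed abundance (derivative zeroed); an
ε-override bypasses the network for imposed-expression experiments. A
transcribed but functionless control RNA (`CTRL`) is included as a
negative control for sensitivity analyses.

## Sensitivity analysis

Normalized coefficients S = (RNA/v_GK)·∂v_GK/∂RNA are estimated by central
differences: the RNA is clamped at (1 ± δ)·its steady abundance in the
T2D-perturbed state (clamping, rather than scaling transcription, matches
normalization by RNA abundance itself), the downstream steady state is
re-solved, and the GK-rate difference is normalized. Default δ = 0.01;
halving the step changes coefficients by < 1% and one-sided differences
agree to first order (tested). Coefficients are evaluated at 2.8 and
16.8 mM plasma glucose in the T2D state.

With the fitted defaults the hierarchy is MGAT4A > HNF1A > FOXA2 at both
glucose levels (glycosylation is the top control point; HNF1A outranks
FOXA2 through its extra acetylation role), and GLUT2 > GLUT1 at 16.8 mM.

## Synthetic data and parameter recovery

The generator emulates steady-state uptake assays: for each scenario
(ε₁, ε₂) and glucose level it draws `n` replicates of the model's steady
net uptake times a mean-one lognormal deviate (σ² = ln(1+CV²)); the
expected measurement equals the model truth. Default CV 0.1, replicate
defaults n = 3 for demonstration and n = 20 for recovery studies; a single
seeded generator makes datasets bit-reproducible. What this emulates — and
what it does not: real uptake assays carry donor-to-donor heterogeneity,
shared-batch correlations and possible additive background, none of which
are modelled; passing recovery tests therefore demonstrates correctness of
the inference machinery under the stated noise model, not robustness to
real-assay systematics.

Recovery fits (ε₁, ε₂) by bounded nonlinear least squares on log-uptake
residuals (noise is multiplicative), with standard errors from the
Gauss–Newton covariance σ̂²(JᵀJ)⁻¹. The mean-one lognormal induces a
−σ²/2 bias in log space (~0.5% at CV 0.1), negligible against the standard
errors and left uncorrected. Four starting points are tried and the lowest
cost kept: when one transporter carries a small flux share the bounded
landscape can hold a second basin. ε₁ and ε₂ are separable only because
the Km values differ; designs should span both regimes (≲3 mM and
≳17 mM) — the Fisher-information condition number is reported and a
single-level design triggers a confounding warning. For the healthy
scenario ε₁ remains weakly identified even with three levels (GLUT-1
carries ~14% of healthy uptake), which shows up as a large reported SE
rather than as a biased point estimate. Coverage of the ±2 SE interval at
CV 0.1, n = 20, levels {2.8, 10, 16.8} is ~98% over seeded repeats.

## Known limitations

- Everything downstream of G6P (insulin granule exocytosis, fatty-acid
  oxidation, FFA-receptor signalling) is out of scope; the G6P pool is
  cumulative by construction.
- The model is deterministic and represents an average cell; β-cell
  population heterogeneity and intrinsic noise are not modelled.
- Kinetic timescales of the regulatory network are nominal (0.1 min⁻¹
  turnover); only steady-state ratios are data-constrained.
- `V_N(GLUT1)` is weakly identified by the available anchors. Downstream,
  the GLUT-1/GLUT-2 flux split in the T2D state at *low* glucose is
  sensitive to it: with the anchored value GLUT-1 carries ~66% of T2D
  uptake at 2.8 mM, so the transporter-gene sensitivity ordering
  (GLUT2 > GLUT1) holds at stimulatory glucose but inverts at 2.8 mM, and
  S(GLUT1) is slightly larger at 2.8 than at 16.8 mM. A smaller GLUT-1
  maximum rate — equally compatible with the rounded anchors — would
  restore the ordering at both levels. The test suite asserts the orderings
  at both levels as stated conditions; the 2.8 mM transporter-gene
  assertions fail under this calibration and are documented here rather
  than weakened.
- Hill coefficients and half-saturations of TF–promoter and lectin binding
  are assumptions (documented above), not measured values; the sensitivity
  *hierarchy* among TFs and MGAT4A is robust to them in the fitted regime,
  but magnitudes are not.
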