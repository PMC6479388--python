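# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of pbpkit. It is written for users who need to know
what the package computes and why, and what a passing test suite does and
does not demonstrate about real data.

## Bioanalytical calibration and QC statistics

The calibration model is the quadratic `y = a·x² + b·x + c` relating the
analyte/internal-standard peak-area ratio to nominal concentration, fitted
by weighted least squares with weights 1/x². This weighting is the correct
generalized-least-squares choice when assay error is multiplicative
(constant CV), which is the standard behaviour of LC-MS/MS peak-area
ratios; the synthetic response generator produces exactly this error
structure. The quadratic term absorbs detector saturation and matrix
effects at the top of the range.

Curve quality is summarized by the weighted R² and its square root r; both
are exposed because reporting conventions differ on which is quoted
(r ≥ 0.99 is the acceptance gate). Inverse prediction solves the quadratic
with the cancellation-safe form of the root formula (important because the
fitted `a` of near-linear data is a tiny non-zero number); the root inside
the validated range [LLOQ, ULOQ] = [1.01, 2200] ng/mL wins, results
outside the range are flagged BLQ/ALQ, and if both roots are in range the
one nearer the range midpoint is taken with a warning.

QC statistics follow bioanalytical convention: %Acc = 100·mean/nominal,
%CV = 100·sd/mean with the sample (n−1) standard deviation, both gated at
±25%. With a single replicate %CV is reported as NaN (undefined) and the
pass flag considers accuracy only.

## In vitro ADME reduction

Substrate depletion is modelled as mono-exponential: the rate constant k
is the negative slope of an ordinary least-squares regression of
ln(remaining %) on time, pooling all replicate points into one regression
(using all information rather than averaging time points first). Then
T½ = 0.693/k and Cl_int,in vitro = (0.693/T½)/C_protein = k/C_protein in
mL/min/mg. The constant 0.693 (rather than ln 2 to full precision) is
used as conventionally printed; the 2×10⁻⁴ relative difference is
irrelevant at assay precision. A fitted k at or below 10⁻¹² /min is
reported as a stable compound (Cl_int = 0). When the assay is run at
several microsomal protein concentrations (0.5–2 mg/mL), each level is
reduced separately and the arithmetic mean is reported.

Note on design power: with samples at 0, 15, 30 and 60 min in triplicate
and 10% multiplicative noise, the regression recovers k with a median
error under 5% only when the incubation window spans roughly two or more
depletion half-lives; for very stable compounds the design itself, not
the estimator, limits precision.

The unbound fraction in plasma is the buffer/plasma concentration ratio of
an equilibrium dialysis pair, reported in percent; pairs at multiple
plasma concentrations are averaged (the pooling rule used when binding is
concentration-independent, as it is for tozadenant at 0.1 and 1 µg/mL:
26.63% rat, 26.72% human).

## IVIVE

Whole-body intrinsic clearance:

    Cl_int [mL/min/kg] = Cl_int,in vitro × mppgl × liver mass

with microsomal protein content (mppgl) 44.8 (rat) and 48.8 (human) mg per
g liver and liver masses 40 and 25.7 g per kg body weight. Hepatic
clearance uses the well-stirred model in its plain form,

    Cl_H = Q·Cl_int / (Q + Cl_int),

with hepatic blood flows Q = 55.2 (rat) and 20.7 (human) mL/min/kg. Many
well-stirred formulations insert an unbound-fraction term fu_b·Cl_int;
the plain form is the default here for consistency with the clearance
chain this package reproduces (0.0021 → 3.76 → 3.52 mL/min/kg rat;
0.0008 → 1.00 → 0.95 human), and the extended fu_b = fup/Rbp variant is
available through optional arguments. The PBPK simulator's hepatic
elimination term follows the same default (see below) so that simulated
low-extraction hepatic clearance equals the IVIVE value.

## Species physiology

Fourteen compartments: arterial and venous blood, lung (in series between
them at cardiac output), and adipose, muscle, liver, spleen, gut, heart,
brain, kidney, skin, bone+marrow, and rest-of-body in parallel. Gut and
spleen drain through the portal vein into the liver; the hepatic artery
carries the balance of total hepatic flow. Volumes (L/kg) and regional
flows (mL/min/kg) are standard reference-compendium values for a 0.3 kg
rat and a 70 kg human, adjusted at the fraction-of-a-percent level so
that two identities hold exactly: Σ venous returns = cardiac output
(296 rat, 80 human mL/min/kg), and hepatic artery + gut + spleen = total
hepatic flow (55.2 / 20.7 mL/min/kg). GFR (5.2 rat, 1.8 human mL/min/kg)
is carried for the renal clearance default. Every constant can be
overridden through the plain-text physiology document.

## Tissue partitioning (Kp)

Tissue:plasma partition coefficients come from the Poulin–Theil
tissue-composition method: each tissue is a mixture of water, neutral
lipid and phospholipid; neutral lipid partitions like octanol
(P = 10^logD at pH 7.4), phospholipid like a 30:70 octanol:water mixture,
and for adipose the vegetable-oil:water coefficient
log D_vo:w = 1.115·logD − 1.35 replaces P. Tissue binding is tied to
plasma binding through fu_t = 1/(1 + 0.5·(1−fup)/fup), with adipose
assumed non-binding. Ionization uses Henderson–Hasselbalch; because the
reported pKa values are structure predictions without assigned types,
values below 7 are treated as basic and above 7 as acidic — for
tozadenant (pKa 3.28, 4.7, 10.81) this makes the molecule effectively
neutral at pH 7.4, logD ≈ logP = 1.96. The method is pluggable
(`predict_kp(..., method=...)`; `"unity"` sets all Kp = 1 for limit
checks) and the choice is recorded in output metadata.

## PBPK simulator

States are drug amounts (ng), which makes mass conservation exact by
construction: every transport term appears with opposite signs in its
source and destination rows of the (constant) coefficient matrix, so
column sums vanish and dose minus (system + eliminated + unabsorbed) is
zero to integrator tolerance. A perfusion-limited tissue obeys
V·dC/dt = Q·(C_art − C·Rbp/Kp), leaving in venous equilibrium with tissue.
Plasma concentration is reported as venous blood concentration / Rbp.

Elimination:

* **Hepatic** — rate = Cl_int,hep·BW·C_liver·Rbp/Kp_liver, i.e. the
  scaled intrinsic clearance acting on the liver-outflow blood
  concentration. In the high-flow limit this reproduces Cl_H of the
  plain well-stirred model exactly. The unbound-driven variant
  (multiplying by fup) is available via `unbound_hepatic=True`.
* **Renal** — rate = Cl_renal·BW·C_art, a clearance on the kidney inflow
  blood concentration (switchable to the plasma-side concentration).
  The default value is the filtration clearance fup × GFR.

Oral dosing uses a gut-lumen depot with first-order transfer: a fraction
fa of depot transfer (rate constant ka) enters the portal stream upstream
of the liver (so first-pass extraction emerges mechanistically), and
(1−fa) is tracked as never absorbed. Defaults for tozadenant:
**fa = 0.74** (the observed rat bioavailability 69.43% divided by the
hepatic availability 1 − 3.54/55.2) and **ka = 0.13 /min** (reproducing
the observed rat oral Tmax of ~22.5 min under the calibrated rat
disposition).

Integration is LSODA with analytic (constant) Jacobian, rtol 10⁻⁸ and
atol 10⁻³ ng, on a 1-minute output grid (capped at ~4000 points), which
keeps NCA discretization error well under 1%. Reported concentrations are
clipped at zero (solver noise in deep tails); amount states are left raw
so mass-balance checks see the true solver error. The system is linear,
so dose linearity holds to ~10⁻⁷ and superposition can be used freely.

## Non-compartmental analysis

Cmax/Tmax are taken from observed points. The terminal rate constant λz
is fitted by log-linear regression over the best of all windows of ≥3
consecutive points ending at the last positive concentration and starting
strictly after Tmax, ranked by adjusted R² (rounded to 4 decimals) with
ties going to the longer window — the best-fit convention of commercial
NCA software. On dense simulated grids candidate window starts are
thinned to ≤40 evenly spaced positions (a pure cost control; the search
is exhaustive on experimental grids).

AUC uses the lin-up/log-down trapezoid by default. The rationale: on the
sparse 12-point study design (terminal samples 120/240/360/480 min with a
~80–140 min half-life) the plain linear trapezoid overestimates the
terminal AUC by ~3%, biasing clearance low by the same amount, whereas
the log-down rule is exact for mono-exponential decay between samples.
The plain linear rule remains available (`auc_method="linear"`), and the
two converge at order 2 as the grid refines.

For an IV bolus whose record starts after dosing (or has a zero pre-dose
sample at t = 0), C(0) is back-extrapolated from the log-linear fit of
the first two positive points. The same convention is applied to
*simulated* bolus profiles: the t = 0 state — the full dose sitting
unmixed in the venous compartment — is excluded before NCA, because no
sampled study observes it and including it inflates the trapezoidal AUC
substantially.

Derived parameters: AUC∞ = AUC_last + C_last/λz, t½ = ln2/λz,
Cl = Dose/AUC∞ (CL/F for oral), Vz = Cl/λz, and
Vss = Dose·AUMC∞/AUC∞² for IV bolus. Bioavailability uses
F = (D_iv/D_po)·(AUC_po/AUC_iv)·100, with a helper that averages
per-dose-group F values arithmetically; computed from group-mean AUC_last
values the two rat dose groups give 72.9% and 64.8%, mean 68.9%, within
1% of the reported animal-level average of 69.43%.

## Model calibration (rat)

Three parameters are calibrated on the rat IV 1 mg/kg data: renal
clearance (bounds 0–50 mL/min/kg, start fup×GFR = 1.38) and
multiplicative adjustments to the predicted liver and kidney Kp (bounds
0.1–50, start 1), the liver/kidney choice mirroring the practice of
assigning unexplained clearance and distribution volume to the
eliminating organs. The objective is log-scale moment matching,

    (ln Cl_sim − ln Cl_obs)² + (ln Vss_sim − ln Vd_obs)²,

optionally plus the mean squared log-concentration profile residual when
an observed profile is supplied. Moment matching is the default because
the calibration inputs are the published summary parameters
(Cl 14.36 mL/min/kg, Vd 1.63 L/kg); the profile mode exists for synthetic
and user data. The printed Vd is matched against simulated Vss (the
printed value is inconsistent with Vz = Cl·t½/ln2 from the same table, so
it is treated as a steady-state volume; both are reported by the NCA).

The search is bounded Nelder–Mead on [cl_renal, log₁₀ multipliers] with a
generously scaled initial simplex (the default 5% perturbation cannot
escape the IVIVE starting point), accepted at objective < 10⁻⁴. With
summary targets only, the problem is underdetermined — the two Kp
multipliers trade off along a nearly flat valley — and the optimizer
returns one point on the optimal manifold, deterministically. When a
profile is supplied, a bounded trust-region least-squares polish on the
log-concentration residuals follows the simplex stage (run from both the
incumbent and the starting point); the derivative-based step resolves the
flat valley that a simplex cannot, and on noiseless synthetic problems
recovers all three generating parameters essentially exactly. Parameter
identifiability requires sampling the first minutes post-dose: the kidney
distribution transient has a time constant of ~2 min, so the synthetic
recovery experiment samples every 15 s over the first 10 min; from a
design whose first sample is at 2 min the kidney multiplier is
practically unidentifiable.

Calibrated values for tozadenant: cl_renal ≈ 13.0 mL/min/kg,
Kp_liver ×3.9, Kp_kidney ×0.30, reproducing the target Cl and Vss to
numerical precision. The large renal term reflects that the microsomal
assay underpredicts rat in vivo clearance ~4-fold for this compound.

## Validation and fold errors

Fold error is predicted/observed (a signed direction: 0.7 means
underprediction), "within two-fold" meaning 0.5 ≤ fold ≤ 2. Predicted NCA
parameters for the rat validation groups are computed on the study
sampling grid (2–480 min) interpolated from the dense simulation, so Tmax
resolution and trapezoid discretization match the conventions under which
the observed parameters were derived. The calibrated model validates
within two-fold on every metric of both oral groups and on IV 5 mg/kg
AUC, Tmax and t½; the IV 5 mg/kg Cmax (fold 0.45) misses because the
observed rat Cmax is supra-proportional in dose (7820 vs 5×1119 ng/mL),
which no dose-linear model can reproduce.

## Human scale-up

The human model is rebuilt from human inputs: Kp recomputed from human
tissue composition, hepatic Cl_int from human IVIVE
(0.0008 → 1.00 mL/min/kg), and renal clearance from an explicit
interspecies rule. Defaults and rationale:

* **Kp carry-over: none.** The rat liver/kidney multipliers are an
  empirical correction absorbing rat-specific disposition and are only
  weakly identified between the two organs; transferring a fitted
  partition multiplier across species has no physiological basis, and
  doing so multiplicatively inflates the human distribution volume (and
  halves Cmax) for no mechanistic reason. The multiplicative rule is
  implemented as an option (`kp_carryover="multiplicative"`).
* **Renal scaling: "gfr"** — human Cl_renal = fup × GFR_human
  ≈ 0.48 mL/min/kg, the standard filtration-limited default. The rat
  extra clearance is treated as species-specific metabolic
  underprediction, not a transferable renal process (tozadenant is not
  reported to be renally excreted). Alternatives: kidney-blood-flow
  scaling, per-kg allometry ((BW_h/BW_r)^−0.25), and direct carry-over.
* **Absorption**: fa is carried unchanged; ka is slowed by the rat:human
  small-intestinal transit-time ratio (≈88/199 min, factor 0.44).

Simulating 240 mg oral in a 70 kg human over 48 h gives
AUC_last 29.3 µg·h/mL (observed 35.0, fold 0.84), Cmax 2.65 µg/mL
(observed 1.74, fold 1.52) and t½ 17.4 h (observed 15, fold 1.16) — all
within the two-fold band considered acceptable for prospective human PK
prediction. Tmax is predicted at 0.27 h against an observed 4 h: a single
first-order rate constant cannot represent the dissolution- and
transit-limited absorption of a 240 mg dose of a compound with 0.28 mg/mL
solubility (dose number ≈ 3.4); mechanistic gut absorption models handle
this and are out of scope here. The human AUC prediction is insensitive
to ka across more than an order of magnitude, so this limitation is
confined to the absorption-phase shape (Tmax, and Cmax to a lesser
degree).

## Synthetic-data generators

All generators are pure functions of a seeded configuration
(`GeneratorConfig`): identical seeds reproduce datasets exactly. The noise
model is multiplicative log-normal with mean 1 (σ² = ln(1+CV²)),
the standard bioanalytical error structure. Defaults mirror the study
designs: PK sampling at 0–480 min, depletion triplicates at 0/15/30/60
min, dialysis at 0.1 and 1 µg/mL, LLOQ censoring at 1.01 ng/mL. The
generators emulate the *statistical* structure of the assays — they do
not simulate chromatographic signals, matrix effects, between-animal
variability in disposition parameters, or model misspecification (the
generating model is the analysis model). Passing recovery tests therefore
demonstrate estimator correctness and pipeline wiring, not robustness to
real-data pathologies.

## Numerical conventions and degenerate inputs

Internal units: minutes, mL, ng, per kg body weight; human outputs are
converted to hours and µg at the reporting boundary only. Zero dose
returns an identically zero profile with mass balance defined as 1. A
depletion fit with k ≤ 10⁻¹² is "stable". Profiles with no estimable
terminal phase return AUC_last with λz-dependent fields NaN and a flag.
All-equal calibration concentrations raise an error rather than silently
degenerating. Loosening the ODE tolerances degrades the mass-balance
residual, which is the intended tolerance-violation diagnostic.

## Known limitations

* Linear kinetics throughout: no saturable metabolism, transport or
  binding; the observed rat supra-proportionality at 5 mg/kg is outside
  the model class.
* First-order absorption only (no dissolution, transit or regional
  permeability); human Tmax is systematically early for
  solubility-limited doses.
* Perfusion-limited tissues only; no permeability-limited compartments,
  enterohepatic recirculation, or metabolite kinetics.
* The liver/kidney Kp calibration is a two-target, three-parameter
  problem: reported multipliers are one point on an optimal manifold
  unless a profile with early sampling is supplied.
* Single "typical" physiologies per species; no variability or special
  populations.
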