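# Methods

`pahmix` implements a three-stage quantitative chain for assessing
competitive metabolism of polycyclic aromatic hydrocarbons (PAHs):
in vitro kinetics → competitive-inhibition constants → whole-body
pharmacokinetic (PBPK) consequences. This note records the models, the
defaults and why, the numerical choices, and the limits of what the test
suite demonstrates.

## 1. Initial rates from substrate depletion

A microsomal depletion assay measures substrate concentration S(t) (µM) at
a handful of time points in replicate. The initial disappearance rate is
obtained by least-squares fitting S(t) = S₀·e^(−kt) on the raw
concentration scale (additive measurement noise; all replicates pooled into
one regression per course), then converting

    v = k·S₀ / c_protein    (nmol/min/mg; µM ≡ nmol/mL, so volume cancels)

with assay defaults of 0.5 mL incubations at 2.0 mg microsomal protein/mL.
Uncertainty comes from a nonparametric bootstrap: replicate measurements
are resampled with replacement within each time point, the regression is
repeated, and the 2.5/97.5 percentile interval is reported (default
n = 1000, seeded).

**Estimator bias under substantial depletion.** k·S₀ equals the true
initial rate v(S₀) only in the limit of small fractional depletion, or when
metabolism is genuinely first-order (S ≪ Km) so the course is exactly
exponential. With the shipped kinetic parameters and realistic 0–30/0–60
min windows, low-concentration courses deplete by >90% and the exponential
regression underestimates initial rates at saturating concentrations by up
to ~20% (the bias falls roughly linearly with window length: ~4% at 10 min,
~0.04% at 0.1 min for a DBC-like assay). The generator→fitter round-trip
tests therefore run in the short-window limit (0–0.01 min), where the
estimator is unbiased to ≤4×10⁻⁴; the end-to-end demo pipeline, which
keeps the realistic windows, inherits the bias and can shift BIC model
selection and Ki recovery accordingly. This is a property of the
initial-rate estimator itself, not of the optimizer.

**Bootstrap coverage.** With triplicate measurements, within-time-point
resampling draws from only three values, which is known to understate
variance; measured empirical coverage of the 95% rate interval is ~80–85%
rather than nominal. The parametric bootstrap below shows the same
small-sample percentile-interval undercoverage (measured ~87–94% per
parameter at 5% noise, n = 36). The intervals are reported as percentile
intervals without small-sample correction; treat them as approximate.

## 2. Baseline rate laws, likelihood, and BIC

Three candidate laws describe the uninhibited rate v(S):

    MM            v = Vmax·S/(Km+S)
    MM-clearance  v = Vmax₁·S/(Km₁+S) + Clint₂·S
    double MM     v = Vmax₁·S/(Km₁+S) + Vmax₂·S/(Km₂+S),  Km₂ > Km₁

The second and third describe a high-affinity/low-capacity enzyme working
alongside a low-affinity/high-capacity one (non-saturating and saturating,
respectively). Errors are i.i.d. additive Gaussian with common unknown σ on
the rate scale; profiling σ makes the ML point estimate identical to
unweighted least squares (asserted to 10⁻⁸ against an independent joint
likelihood optimization). The log-likelihood keeps its 2π terms and BIC
counts σ as a parameter:

    BIC = −2·logL + (p+1)·ln n

Only BIC differences matter for selection; ties (|ΔBIC| < 10⁻⁹) go to the
form with fewer parameters, ordered MM < MM-clearance < double MM.

Optimization is over log-parameters (strict positivity) with bounds
[10⁻⁹, 10³] in native units and coordinate-wise multistart: eight
log-spaced multipliers per parameter around a data-driven start. Double-MM
label switching is removed by relabeling so phase 1 is always the low-Km
phase. Noiseless self-generated data are recovered to ≤10⁻⁴ relative for
all three forms. The first-phase intrinsic clearance is Clint₁ = Vmax₁/Km₁
in mL/min/mg microsomal protein (some published tables print this as
"mL/min"; dimensional analysis of Vmax/Km fixes the per-mg basis used
here).

Parameter intervals use a parametric bootstrap: rates are redrawn from
Normal(fitted value, σ̂) truncated at zero (negative draws clipped to 0),
the model is refit from the fitted point, and percentile intervals are
taken (default n = 1000, seeded). σ̂ is the ML estimate √(RSS/n), floored
at 10⁻¹² so noiseless fits keep finite likelihoods.

## 3. Competitive inhibition

With the MM-clearance baseline fixed, an inhibitor at concentration I can
compete with either phase:

    phase 1:  v = Vmax₁·S/(Km₁·(1+I/Ki)+S) + Clint₂·S
    phase 2:  v = Vmax₁·S/(Km₁+S) + Clint₂·S/(1+I/Ki)

Only Ki (and σ) are estimated — the baseline parameters stay fixed, because
a single nominal substrate concentration cannot identify them jointly. If
the data contain no I = 0 observation, the baseline model prediction at the
assay's substrate concentration anchors the fit. The two placements are
compared by BIC exactly as above; flat rate–inhibitor profiles drive Ki to
its upper bound (10³ µM) and are flagged "no inhibition detected". The
inhibitor concentration is treated as constant at its nominal value for the
whole incubation (apparent-Ki framing; inhibitor depletion is out of
scope).

A defined mixture is treated as one lumped inhibitor at its total molar
concentration. The shipped Supermix-10 composition carries molar ratios
normalized to 2-methylnaphthalene; molar fractions are ratios over their
sum (Σ = 51.27). Recomputing the retene fraction gives 7.43/51.27 = 0.145 →
0.14 at two decimals, whereas the source table prints 0.15; the
recomputed value is used and the discrepancy simply noted. Per-component
inhibition constants are an explicit non-goal.

## 4. PBPK interaction model

A flow-limited, venous-equilibrium compartment model (gut lumen, liver,
fat, richly perfused, slowly perfused, blood) is run for two compounds
simultaneously. For tissue T: dA_T/dt = Q_T·(C_art − A_T/(V_T·P_T)); the
gut lumen empties into the liver by first-order absorption (ka); hepatic
metabolism of each parent uses the phase-1 competitive law driven by the
venous-equilibrated liver concentration C_vl = C_liver/P_liver, with the
partner compound as inhibitor. Metabolism is the sole elimination route and
its products accumulate in a terminal sink state, so mass conservation is
exact up to solver error (measured residual ≤10⁻¹¹ of dose across the full
dose grid). No plasma-protein-binding term is applied (none is available).

In vitro→in vivo scaling (IVIVE) multiplies microsomal Vmax₁ and Clint₂ by
30 mg microsomal protein per g liver and the liver mass (73 kg × 2.6% =
1898 g by default): Vmax in vivo = 358.7 nmol/min for the default BaP
parameters. Internal units are nmol/L/h; per-minute in vitro terms are
converted once at scaling.

**Default fixture.** The source human models for these compounds do not
publish their full parameter sets, so the module is parameter-file driven
and ships a documented reference fixture: 73 kg; cardiac output 5.2 L/min;
volume fractions liver 2.6%, fat 21%, richly perfused 5%, slowly perfused
54.5% (so perfused tissue plus blood is 91% of body weight), blood 7.9%;
flow fractions 25/5/45/25%; ka 0.5 h⁻¹; tissue:blood partition
coefficients liver 10, fat 200, richly 10, slowly 4 — deliberate
placeholders for highly lipophilic PAHs, identical for both compounds. All
shipped checks are either parameter-independent (conservation, limits,
ratio properties) or pinned to this fixture; absolute published
concentration curves and ratio maxima are not reproduction targets.

**Scenarios and the AUC-ratio metric.** Each co-exposure is simulated twice
— competitive metabolism on (measured Ki) and off (Ki = 10⁹⁹ µM) — and the
per-compound ratio of blood-concentration AUCs is reported; 1 means no
interaction. The dose grid spans 16 log-spaced oral doses from 0.1 ng to
10¹⁴ ng (100 kg) per compound, 256 combinations. With the shipped fixture,
ratios stay within 10⁻³ of 1 at trace doses and only depart from 1 when the
inhibitor dose reaches the ~100 mg scale, consistent with the
dose-additivity assumption of the Relative Potency Factor approach at
typical human exposures; at the very top substrate doses self-saturation
outcompetes the inhibitor and ratios return to ≈1.

**Numerics.** LSODA with rtol 10⁻⁸/atol 10⁻¹² nmol by default (grid runs
use 10⁻⁷/10⁻¹⁰; halving tolerances changes AUCs by <10⁻⁴). The horizon
doubles from 240 h until the blood concentration of every dosed compound
falls below 10⁻⁶ of its running peak, capped at 10⁶ h for the absurd top
doses. AUC is an integrated auxiliary state (solver-grid independent;
agrees with trapezoids on a dense grid to <0.1%); Cmax/Tmax are read off
the sampled series, so Tmax resolution equals the output sampling step.
The right-hand side is verified against an independent fixed-step explicit
Euler integration to 10⁻⁶ relative.

## 5. Synthetic data

The generator emulates the depletion assays: it integrates
dS/dt = −v(S; I)·c_protein with a fixed-step RK4 scheme (independent of the
solver used anywhere in the fitting chain), samples the design's time
points, and adds independent Gaussian noise with SD = cv·S₀ per
measurement, clipped at zero — the simplest structure consistent with HPLC
quantitation near a fixed limit of quantification (~0.0015 µM); sub-LOQ
values are reported as-is, not censored. Controls (inactivated microsomes)
hold S₀. Everything is deterministic given a seed. Default designs mirror
the assays: BaP-like 0.05–2.5 µM over 0–30 min, DBC-like 0.025–1 µM over
0–60 min, inhibitor levels 0.1–10 µM (0.1–30 µM for mixtures), triplicate,
cv = 0.05 (a test convenience — the true replicate noise of the source
assays is unknown).

What passing tests show: the estimators recover their own generating
process (exactly without noise, with ≥90% BIC selection accuracy at 5%
noise) and the PBPK model obeys conservation and limiting behavior. What
they do not show: recovery of any real assay's values; real HPLC noise is
not purely additive-Gaussian, real inhibitors deplete during incubation,
and inter-donor microsome variability is not modeled.

## 6. Problem sizes and pipeline defaults

Model-recovery studies use 100 seeds (12 substrate levels or 5 inhibitor
levels, triplicate); bootstrap defaults are n = 1000 in the library and
n = 200 in the demo pipeline; the full 16×16 dose grid is 512 ODE
simulations. The `run-all` demo uses a 4×4 grid by default (`grid: full`
in the master config enables 16×16). All stage seeds derive from one master
seed via `SeedSequence` spawning, so reruns with the same config are
byte-identical.

## 7. Known limitations

- Percentile bootstrap intervals undercover at triplicate sample sizes
  (§1); no BCa or t-interval correction is applied.
- The exponential-regression initial-rate estimator is biased under
  substantial depletion (§1); analyses of strongly depleting courses
  should shorten windows or expect compressed high-concentration rates.
- Parent compounds only: metabolite disposition, metabolite-mediated
  inhibition, and enzyme induction are out of scope; metabolism is a
  terminal sink.
- The PBPK fixture's partition coefficients and ka are placeholders;
  absolute AUCs/Cmax are fixture-dependent, and only ratio and
  conservation properties are asserted.
- Mixtures are lumped single inhibitors; no per-component Ki or
  per-component PBPK sub-models.
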