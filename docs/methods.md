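# Methods

## Model structure

The simulator couples two layers through a shared 41-component state.

**Whole-body layer (14 ODEs, minutes).**  Glucose masses (mg) move from
hunger-driven intake into the stomach (`b9·H`), to the intestine (`b8·S`),
and into plasma scaled by the absorbed fraction `f` and the distribution
volume `v` (dL), so that mass/`v` is a concentration in mg/dL.  Plasma
glucose is cleared by an insulin-independent route (`b1·G`, brain and other
non-insulin-dependent tissues) and an insulin-dependent route (`b3·I·G`,
muscle and adipose).  Muscle glucose entry is structurally tied to 10% of
the insulin-dependent disposal: its rate is `0.1·v·f·b3·G·I·e`, which
divided by `v·f` times `b3·I·G` gives exactly 10% when the insulin
effectiveness `e` equals 1.  The liver holds a glucose pool `C` produced at
a basal rate `b23`, suppressed by insulin (`b25·I·e`) and glucose
(`b22·G`), stimulated by glucagon (`b21·E`), and secreted at `b5·C`.
Glucagon itself is secreted at a basal rate plus a term
`c1/(c2 + I·e)·(Ge − G)·u(Ge − G)` gated by a right-continuous unit step
(`u(0) = 1`) below the glucose threshold `Ge`; above threshold glucagon
relaxes exponentially to `c0/c3` at rate `c3`.  Insulin secretion has a
direct glucose route (`b4·G`) and an incretin-amplified route (`c·W·G`);
incretins track intestinal glucose.  Ghrelin secretion is exponentially
suppressed by stomach content (`exp(−l·S)`) and insulin (`exp(−m·I)`);
leptin tracks adipose glucose mass scaled by total fat mass.  The hunger
signal `H` — the amount of glucose the body asks for — is driven by
ghrelin, divided down by leptin (`1/(b18·Y + 1)`), exponentially gated by
insulin (`exp(−r·I)`), and drained by eating (`b9·H`) and by elevated
glucose (`b19·G·H`).  The "I(t)e" products are read as multiplicative
insulin effectiveness `e·I`, applied uniformly in the glucagon, liver and
muscle equations; `e = 1` in NGR and `e < 1` in T2DM.

**Interstitial coupling.**  Only the plasma excess above basal transfers to
the interstitium: `dINS_A/dt = −p2U·INS_A + p2U·max(I − Ib, 0)` and
analogously for `Gt_A` with rates `q1`, `q2`.  The drives are floored at
zero so a plasma dip below basal cannot pull the deviations negative.

**Cellular layer (27 ODEs, arbitrary units).**  Pure mass-action kinetics
over ten conserved interconversion cycles: the insulin receptor 5-cycle
(binding of INS_A, autophosphorylation, internalization, X_P-assisted
dephosphorylation, recycling), the IRS1 4-cycle (tyrosine and serine-307
phosphoforms, with mTORC1a feedback scaled by `kfb` on the serine route),
the feedback protein X, the PKB 4-cycle (T308/S473), mTORC1 and mTORC2
activation pairs, AS160, GLUT4 cytosol/membrane, and the terminal S6K and
S6 pairs.  Glucose uptake into adipose tissue is the sum of two saturating
routes, insulin-regulated GLUT4m and constitutive GLUT1 (held constant),
each Michaelis–Menten in interstitial glucose.  Two transcription
corrections are applied relative to the as-circulated equation set: the
IRS1 tyrosine-phosphorylation drive is the internalized receptor IRi_YP in
both IRS1 balances (restoring IRS1 conservation; the membrane-receptor
variant is available behind `irs1_printed_variant` for comparison), and
the inactive-mTORC1 balance is read as d(mTORC1)/dt (its printed label
duplicates the active form but its right-hand side is the exact negative
of the activation equation).

## Parameter provenance and derivation

No authoritative numeric table ships with the model, so the defaults in
`data/defaults.yaml` are the package's own calibration, produced by the
parameter workflow the package also exposes:

1. **Anchored rates.**  Fasting levels (G 90 mg/dL, I 10 µU/mL, glucagon
   70 pg/mL, leptin 10 ng/mL, ghrelin 800 pg/mL) and turnover rates are set
   to literature-standard orders of magnitude, then jointly adjusted (see
   step 3).
2. **Steady-state derivation.**  Eight parameters are never stored but
   derived in closed form by imposing a fasting steady state at t = 0:
   `c3 = c0/E0` (the NGR and T2DM fasting glucose both sit above `Ge`, so
   the gated branch is off), `b5` from the liver balance, `b13` from
   leptin, `b12` from ghrelin, `b17` from hunger, `b27` from muscle, and
   `{b4, c}` jointly from the insulin balance with an incretin fraction
   ρ = 0.5 (the two secretion routes cannot be separated by one fasting
   constraint; ρ splits basal insulin turnover between them and is
   configurable).  The derivation order c3 → b5 → b13 → b12 → b17 → b27 →
   {b4, c} avoids circular dependencies, and every derived value is
   substituted back; residuals are ~1e-16, far below the 1e-10 contract.
3. **Dynamics calibration.**  The free loop rates were tuned so the closed
   loop self-sustains distinct meals inside the physiological bands.
   Linear stability analysis of the interior ("grazing") equilibrium shows
   the oscillation is a Hopf-type instability of the intake → digestion →
   insulin → appetite-suppression loop: it requires a sharp insulin gate on
   hunger (`r` of order 1 mL/µU, so the drive is effectively binary around
   basal insulin), strong insulin-dependent disposal (`b3`), and fast
   incretin/insulin turnover relative to digestion.  Because every
   whole-body flux is linear in exactly one rate constant, scaling all rate
   constants by a common factor is an exact time dilation; a factor 0.4
   stretches the limit-cycle period to ≈318 min, i.e. three meals per 1000
   minutes with ~55-min gastric emptying and ~5-h ghrelin recovery.  The
   calibrated cycle corresponds to frequent small meals (~8 g glucose
   equivalent per episode after the first): the oscillation amplitude is a
   property of the limit cycle, and per-meal glucose is on the low side of
   physiology — a known limitation, not a tuning target.
4. **T2DM preset as a diff.**  T2DM overrides NGR entry by entry: `e` 0.5,
   fat mass 30 kg, basal G/I 140 mg/dL / 15 µU/mL, hepatic basal
   production `b23` raised so fasting hyperglycemia is self-consistent
   (the hallmark of excessive endogenous glucose output), per-condition
   estimates of `b3` and `r`, receptor and GLUT4 totals reduced to 55% and
   50%, and mTORC1 feedback `kfb` reduced five-fold.  The derived
   parameters are recomputed from the T2DM fasting state, which is how the
   reduced secretory capacity `b4` emerges rather than being imposed.

**Cellular parameterization.**  Amounts are in arbitrary units with every
protein total set to 100 a.u. in NGR.  Rate constants were chosen for
minute-scale kinetics with a clear insulin dose response: basal membrane
GLUT4 ≈ 18% of the pool, rising to ≈ 60% under sustained interstitial
insulin.  The fasting cellular state is not stored either: the preset
builder relaxes the cascade to its unstimulated (INS_A = 0) steady state
by long-time integration (BDF, rtol 1e-10), so fasting initial values are
always consistent with the rate constants in use.  The absolute scale
linking GLUT4m (a.u.) to mg/min of uptake is carried entirely by `k8`.

## Numerical choices

* **Integrator.**  Stiff multistep BDF (`scipy.integrate.solve_ivp`),
  rtol 1e-6, atol 1e-9 by default, dense 1-min output grid.  The exact
  Heaviside glucagon gate is handled by event location on `Ge − G` with an
  integrator restart at each crossing, so the discontinuity never sits
  inside a solver step; a smooth tanh gate (configurable steepness) is
  available as an alternative.  (Under the calibrated presets fasting
  glucose stays above `Ge`, so the gate stays off in unclamped runs.)
* **Non-negativity.**  Rate laws are evaluated on the clipped state
  `max(y, 0)` because implicit solvers legitimately probe slightly
  out-of-domain trial states; the raw pre-clipping minimum of every
  component is recorded in trajectory metadata, and output values in
  (−1e-9, 0) are clipped to zero.  Structurally, every component except
  liver glucose `C` has a non-negative derivative on its zero boundary;
  `C` can transiently be driven down by strong insulin/glucose suppression
  and is kept positive by calibration (the suppression terms never exceed
  basal-plus-glucagon production in the visited region).
* **Conservation.**  The ten cellular totals are linear invariants of the
  mass-action network; BDF preserves them to Newton-solve accuracy
  (relative drift ~1e-10 over 1000 min at default tolerances), which the
  simulator records per run.
* **Meal detection.**  Prominence-based peak detection on one column
  (default stomach glucose S, fraction 0.2 of the column's range; the
  hunger signal H is an accepted alternative).  On the calibrated NGR run
  S and plasma glucose G both give three peaks; H gives two because the
  fasting initial condition starts at the hunger maximum, so the first
  episode is a boundary maximum rather than an interior peak.
* **Sensitivity analysis.**  Normalized local coefficients
  `(p/X)·∂X/∂p` by central differences with relative step δ = 0.01,
  second-order accurate away from gate switchings; samples within one
  output step of a switching are masked, as are samples where the baseline
  passes within 0.1% of zero (normalizing there divides solver noise by a
  vanishing baseline).  A variance-based global method is out of scope.
  Perturbations are applied to the final parameter values without
  re-running the steady-state derivation: the analysis probes the model as
  simulated, not the derivation pipeline.
* **Feasibility search.**  `constrained_estimate` is a seeded,
  derivative-free (Nelder–Mead with restarts, log-space) minimization of a
  pure penalty: integrated relative band violation after a transient, with
  a large constant for integration failure.  Zero penalty is the
  feasibility notion used throughout ("no discontinuities or unrealistic
  values"); a feasible starting point is returned unchanged.

## What the fixtures emulate

The synthetic fixtures (`fixtures_and_io.generate_fixture`) produce traces
with analytically known ground truth: Gaussian-bump meal profiles for peak
detection (specs whose bumps merge are rejected rather than mislabeled),
monotone traces (zero peaks), and rectangular band-violation windows for
the range validator.  They exercise event detection and validation logic
only — they carry no hormonal dynamics, so passing fixture tests says
nothing about physiological realism; that burden falls on the closed-loop
property tests (meal count, band compliance, conservation, T2DM
contrasts).

## Known limitations

* Parameter values are a self-consistent calibration, not a fit to
  subject-level data; per-meal glucose is small and the insulin-independent
  disposal share is below the physiological fraction.
* No circadian variation by design; the subject eats whenever the loop
  says so, day and night.
* The five S6/S6K regulatory extensions of the source signaling model are
  excluded; S6K/S6 are terminal read-outs here.
* Exogenous interventions (meals as inputs, insulin dosing, exercise) are
  not modeled; the loop is strictly self-feeding.
* Leptin dynamics are heavily dampened (by construction), so the model
  cannot reproduce long-term energy-balance adaptation.
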