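# Methods

This note documents the models, the numerical choices and the synthetic-data
design behind `moafit`, and what the validation experiments do and do not
demonstrate.

## Assay geometry and units

Everything internal is molar, seconds and kelvin; readers convert declared
nM/µM/minute/Celsius columns at the boundary.  The default assay geometry
follows a TR-FRET probe-competition platform: kinetic competition plates use
a 5-step tenfold competitor dilution from 2.5 µM plus a zero-competitor
well, 600 s traces at 10 s intervals, probe at 15 nM; equilibrium plates use
a 12-step 3.5-fold dilution from 20 µM with probe at 1.5 nM and target at
0.1 nM; probe titrations use eight twofold dilutions from 10 nM with a 240 s
association phase and a ~40 min chase.  Temperature studies run at 5, 15,
25, 30 and 37 °C.  Washout profiles use incubation times 0.5, 1, 2, 4, 24,
48 and 72 h with 72 h as the full-exposure reference.  The default probe is
assigned k1 = 1e6 M⁻¹s⁻¹ and k2 = 1.1e-3 s⁻¹, i.e. a 1.1 nM kinetic K_D
split into plausible rate constants; both are configurable.

## Kinetic models

The 1:1 association/chase model and the Motulsky–Mahan competitive model
are implemented as closed forms and as ODE integrations (`solve_ivp`,
LSODA, rtol 1e-10).  The closed form is used for fitting; the ODE route
generates synthetic data and serves as the independent oracle, so a
transcription error in either would surface as a recovery failure.  The
repeated-root case KF = KS of the biexponential is evaluated by its analytic
limit

    Y → Bmax·k1·L·[ k4/K²·(1 − e^(−Kt)) − t·e^(−Kt)·(k4 − K)/K ]

switched on when |KF − KS| < 1e-9·(KF + KS); continuity across the switch is
tested.  The chase phase is treated as irreversible (no probe rebinding)
because chase concentrations are ≥100-fold over the probe.

Global fits share one parameter set across a trace family, weight all
points equally, and are solved by Levenberg–Marquardt (lmfit) with
multi-start initial guesses; rate-like and affinity-like parameters are
fitted as log10 values, which enforces positivity and conditions problems
that span decades.  Standard errors on log-fitted parameters are mapped back
by the delta method.  A fitted k4 with k4 × (trace duration) < 0.1 carries
essentially no dissociation information; such fits keep their kon but flag
koff unreliable ("elusive equilibrium"), and `koff_from_equilibrium`
provides the kon × K_D(eq) fallback with provenance recorded.  A kinetic
scenario with K_D far inside the tight-binding regime of the equilibrium
assay (K_i ≲ target concentration) inflates the Cheng–Prusoff K_i and hence
the fallback koff — this is a property of ligand depletion, not of the
fitter, and is why the depletion diagnostic exists.

## Equilibrium models

Plate normalization maps the neutral-control mean to 0% and the
inhibitor-control mean to 100% (displacement convention), reports the
Z'-factor, and excludes masked wells; it is affine-invariant by
construction.  The 4PL is fitted with the Hill slope free but bounded to
[0.3, 5] (fixable to 1 by config); a falling curve is canonicalized by
swapping asymptotes and reporting a signed Hill slope so Top ≥ Bottom always
holds.  A curve spanning less than 30% of the assay window returns a
"potency not determinable" flag instead of an extrapolated IC50.  The
allosteric affinity-shift model is fitted globally across modulator
concentrations with Top/Bottom/Hill/EC50/K_B/α shared; α statistically
indistinguishable from 1 (two standard errors) raises a no-shift flag.
Saturation fits raise a ligand-depletion diagnostic when the fitted K_D is
within tenfold of the stated protein concentration; the fit is reported,
flagged, never refused.

## Thermodynamics

Linear van't Hoff and Eyring analyses are ordinary least squares on the
printed basis functions; the heat-capacity ("integrated"/"nonlinear") forms
are linear in (ΔH, ΔS, ΔCp) given their basis functions and are solved by
linear least squares for robustness, retaining the conventional "nonlinear"
label in reporting.  Per-point uncertainties, when present, enter as
1/variance weights on the log scale (delta method).  Second-order on-rates
enter the Eyring expression as pure numbers on the 1 M standard-state scale;
the convention is recorded in the output because absolute ΔS‡(on) depends on
it.  Both linear and ΔCp models are always reported side by side — the
package never auto-selects between them, since their transition-state
signatures can differ substantially.  Signatures at temperature T propagate
ΔCp: ΔH(T) = ΔH° + ΔCp(T − T°), ΔS(T) = ΔS° + ΔCp·ln(T/T°); the driver tag
is the more favorable of ΔH and −TΔS, and the optimization-plot zone flag
(−TΔS < ΔH) agrees with it by construction.

## Cellular washout

Potency is normalized as P(t) = IC50(t_ref)/IC50(t) ∈ [0, 1] (a
pIC50-difference mode is available); P(t_ref) = 1 by construction.  The
one-phase decay Y = plateau + (Y0 − plateau)·e^(−ln2·x/t½) is fitted with
the decay variable x = t_ref − t, the washout lead time: potency is full at
complete exposure and decays as incubation shortens, so a *large* t½ means a
persistent compound — the semantics in which washout half-lives are usually
discussed.  (Fitting the same form on raw incubation time is available as a
config alternative but inverts that reading.)  A series whose usable span is
below 0.05 is flat and returns a not-determinable flag rather than an
infinite t½.  AUC is the trapezoid on the linear time axis over the observed
span only; undeterminable points are bridged linearly and flagged.  The t½
of profiles much slower than the 72 h design span is poorly identified (the
plateau and half-life become collinear); the recovery study therefore uses a
24 h half-life scenario, squarely inside the design window.

## Synthetic panels and what they show

`generate_panel` draws kon log-uniform over 1e4–1e7 M⁻¹s⁻¹ and residence
time log-uniform over 5 s–1 h, the spans reported for this target class;
K_D = koff/kon is consistent row-wise by construction.  The
allosteric-modulator condition divides koff by a log-uniform 5–30× slowdown
(bracketing the observed ~27-fold probe effect); the mutant condition
divides kon by 3–30× (association impairment; a koff-mechanism switch is
provided).  Activation enthalpies and heat capacities are drawn per phase
and the entropies solved so the 25 °C rates are reproduced exactly, making
the kinetic and thermodynamic ground truths mutually consistent.  The
cellular coupling t½(cell) = 150 h × (RT/1 h) is a deliberate, monotone
modelling choice — strong enough that a 30 min residence time retains >50%
potency at the shortest exposure; its *strength* is not a measured quantity,
so recovery of the koff-versus-AUC association demonstrates that the
pipeline detects such a relationship when present, not that cells behave
this way.  Noise defaults are 1% multiplicative CV for TR-FRET signals and
5% for cellular potencies; generators are pure functions of (seed, design)
and emit bit-identical output on rerun.

What the recovery tests do not show: the simulator omits plate-position
effects, signal drift, injector dead time (configurable but defaulting to
0 s), probe depletion during kinetics, and compound-specific artefacts
(aggregation, fluorescence interference); real-data error will be larger
than the recovery medians reported here.

## Numerical details

CSV writers use `%.17g` and readers round-trip floats exactly.  The
equilibrium competition simulator solves the exact three-species mass
balance by a bracketed scalar root (free-target equation, `brentq`,
rtol 1e-14) rather than any IC50 shortcut, so the Cheng–Prusoff
approximation error is observable downstream.  Spearman correlation is
computed explicitly as average ranks followed by Pearson, pairwise-complete
with a minimum of 3 pairs per cell; constant columns yield NaN.  Fold-change
labels round to the nearest integer fold.  All validation experiments run in
seconds to a few minutes on one CPU at the problem sizes stated above
(50-seed recovery studies, 30-compound panels).
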