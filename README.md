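# moafit

Mode-of-action profiling of reversible inhibitors from plate-reader data:
equilibrium and kinetic probe-competition fitting, binding thermodynamics,
cellular washout pharmacodynamics, and the derived metrics used to rank
compounds in lead optimization.

## The problem

High-throughput binding assays for targets such as the PRC2/EZH2 histone
methyltransferase read out a fluorescent tracer ("probe") that competes with
unlabeled test compounds for one site.  Endpoint displacement curves give
equilibrium affinities; time-resolved traces give association and
dissociation rates; repeating either assay across temperatures gives binding
thermodynamics; and cellular washout experiments test whether slow
dissociation translates into persistent pharmacology.  `moafit` implements
the full analysis chain behind such a platform, plus seeded synthetic-assay
generators so every stage is verifiable by parameter recovery — no
proprietary plate data required.

## Models at the core

**Competitive binding kinetics** (kPCA).  With probe L (rates k1, k2) and
competitor I (rates k3 = kon, k4 = koff) in excess over the target, the
tracer-bound signal is the Motulsky–Mahan biexponential.  Writing
KA = k1·L + k2, KB = k3·I + k4, S = √((KA−KB)² + 4·k1·k3·L·I),
KF,KS = (KA + KB ± S)/2 and Q = Bmax·k1·L/(KF−KS):

    Y(t) = Q·[ k4(KF−KS)/(KF·KS) + (k4−KF)/KF·e^(−KF·t) − (k4−KS)/KS·e^(−KS·t) ]

A global fit across a competitor dilution series yields kon, koff, the
kinetic K_D = koff/kon and the target residence time RT = 1/koff.  The
implementation is checked against numerical integration of the underlying
ODE system, including the repeated-root limit KF → KS.

**Equilibrium competition** (ePCA).  Normalized displacement curves are
fitted with the four-parameter logistic and converted to K_i via
Cheng–Prusoff, K_i = IC50/(1 + [L]/K_D).  Probe saturation families measured
against an allosteric modulator B are fitted globally to the affinity-shift
model EC50·Antag(B) with Antag = (1 + B/K_B)/(1 + α·B/K_B).

**Thermodynamics.**  ln K_A regressed on 1/T (van't Hoff) and
ln(k·h/(k_B·T)) on 1/T (Eyring), in linear form and with the heat-capacity
term ΔCp/R·[(T−T°)/T − ln(T/T°)] at T° = 298.15 K.  The two descriptions are
mutually consistent: ΔH° = ΔH‡(on) − ΔH‡(off), and likewise for ΔS° and ΔCp.

**Cellular washout.**  Per-incubation-time IC50s are normalized to the
full-exposure reference, fitted to a one-phase decay in the washout lead
time for t½, and integrated (trapezoid) for the AUC — the efficacy measure
that tracks residence time when binding kinetics drive cellular persistence.

## Worked example

`examples/02_competition_kinetics.py` simulates two compounds, fits the
competition traces and prints:

```
fast binder : kon 9.800e+04  koff 9.792e-03  RT 102 s  flagged=False
slow binder : kon 9.972e+03  fitted koff unreliable=True (k4 x 600 s < 0.1)
  fallback  : koff = kon x Ki = 1.070e-05 s^-1 (true 1e-05; source=equilibrium_product)
```

The fast binder's rates (true kon 1e5 M⁻¹s⁻¹, koff 1e-2 s⁻¹) come back
within 2% at 1% signal noise.  The slow binder dissociates too slowly for a
600 s trace, so its fitted koff is flagged unreliable; the recommended
fallback — multiplying the well-determined kon by the equilibrium K_i —
recovers the true off-rate within 7%, with the provenance recorded.  The
other examples cover probe characterization, allosteric modulation,
thermodynamic signatures and the washout-versus-koff correlation.

A thin CLI mirrors the library for shell use:

```bash
moa simulate --what kpca --n 5 --seed 17 --out sim/
moa fit-kpca --traces sim/kpca_traces.csv --k1 1e6 --k2 1.1e-3 --out kinetics.csv
```

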