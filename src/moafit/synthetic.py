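"""Seeded generators emulating the probe-competition profiling assays.

Every assay stage has a generator that draws ground-truth parameters and
produces the same data structures the fitting functions consume, so the whole
pipeline can be validated by parameter recovery without any external data:

* :func:`generate_panel` — a ground-truth compound panel (kon, koff per
  protein/modulator condition, activation thermodynamics per phase, cellular
  coupling, heavy atoms).
* :func:`simulate_probe_traces` — 1:1 probe association/chase titrations.
* :func:`simulate_kpca_plate` — kinetic competition traces, integrated from
  the coupled ODE system (never the closed form, so closed-form
  transcription errors are detectable by fitting).
* :func:`simulate_epca_plate` — equilibrium competition plates from the
  exact three-species mass-balance solution (not the Cheng-Prusoff
  approximation, so the approximation error is measurable downstream).
* :func:`simulate_temperature_series` — rates/affinities across the assay
  temperatures from each compound's activation parameters.
* :func:`simulate_washout` — per-incubation-time cellular potencies whose
  decay rate is coupled to the true residence time.

All generators are pure functions of (seed, design): identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cellular import WashoutSeries
from .equilibrium import NormalizedCurve, logistic4
from .kinetics import KineticTrace, ProbeKinetics, competition_ode_signal, probe_ode_signal
from .thermo import (
    H_PLANCK,
    K_BOLTZMANN,
    R_GAS,
    T_REF,
    TemperatureSeries,
    eyring_rate,
)

__all__ = [
    "NoiseModel",
    "KpcaDesign",
    "EpcaDesign",
    "ProbeDesign",
    "WashoutDesign",
    "TruePanel",
    "DEFAULT_PROBE",
    "ASSAY_TEMPERATURES_K",
    "generate_panel",
    "simulate_probe_traces",
    "simulate_kpca_plate",
    "simulate_epca_plate",
    "simulate_temperature_series",
    "simulate_washout",
    "simulate_washout_plates",
    "equilibrium_bound_fraction",
    "cellular_half_life_h",
    "NOISELESS",
]

#: assay temperatures (5, 15, 25, 30, 37 °C in kelvin)
ASSAY_TEMPERATURES_K = (278.15, 288.15, 298.15, 303.15, 310.15)

#: fluorescent probe defaults: 1.1 nM affinity split into plausible rates
DEFAULT_PROBE = ProbeKinetics(k1=1.0e6, k2=1.1e-3, bmax=1.0, protein_id="wt")

_SCAFFOLDS = ("indole", "indazole", "substituted_benzyl",
              "dihydroisoquinolinone", "scaffold_I", "scaffold_II")


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative CV + additive SD noise with random well failures."""

    cv: float = 0.01
    additive_sd: float = 0.0
    masked_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.cv < 0 or self.additive_sd < 0 or not 0 <= self.masked_prob < 1:
            raise ValueError("invalid noise model")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = values * (1.0 + self.cv * rng.standard_normal(values.shape))
        if self.additive_sd > 0:
            out = out + self.additive_sd * rng.standard_normal(values.shape)
        return out


NOISELESS = NoiseModel(cv=0.0, additive_sd=0.0, masked_prob=0.0)


@dataclass(frozen=True)
class KpcaDesign:
    """Kinetic competition plate: 5-step tenfold dilution from 2.5 µM plus a
    zero-competitor well, 600 s traces at 10 s intervals."""

    competitor_top: float = 2.5e-6
    n_dilutions: int = 5
    dilution_factor: float = 10.0
    duration_s: float = 600.0
    interval_s: float = 10.0
    probe_conc: float = 1.5e-8

    def competitor_concs(self) -> np.ndarray:
        concs = self.competitor_top / self.dilution_factor ** np.arange(self.n_dilutions)
        return np.concatenate([[0.0], concs[::-1]])

    def times(self) -> np.ndarray:
        return np.arange(0.0, self.duration_s + 0.5 * self.interval_s, self.interval_s)


@dataclass(frozen=True)
class EpcaDesign:
    """Equilibrium competition plate: 12-step 3.5-fold dilution from 20 µM,
    low protein to keep ligand depletion mild."""

    dose_top: float = 20e-6
    n_steps: int = 12
    dilution_factor: float = 3.5
    probe_conc: float = 1.5e-9
    protein_conc: float = 1.0e-10
    probe_kd: float = 1.1e-9

    def doses(self) -> np.ndarray:
        return np.sort(self.dose_top / self.dilution_factor ** np.arange(self.n_steps))


@dataclass(frozen=True)
class ProbeDesign:
    """Probe kinetic titration: twofold dilution from 10 nM, 240 s
    association then chase with excess unlabeled ligand."""

    probe_top: float = 1.0e-8
    n_concs: int = 8
    dilution_factor: float = 2.0
    assoc_duration_s: float = 240.0
    assoc_interval_s: float = 10.0
    chase_duration_s: float = 2400.0
    chase_interval_s: float = 15.0

    def probe_concs(self) -> np.ndarray:
        return np.sort(self.probe_top / self.dilution_factor ** np.arange(self.n_concs))

    def times(self) -> np.ndarray:
        assoc = np.arange(0.0, self.assoc_duration_s, self.assoc_interval_s)
        chase = np.arange(
            self.assoc_duration_s,
            self.assoc_duration_s + self.chase_duration_s + 0.5 * self.chase_interval_s,
            self.chase_interval_s,
        )
        return np.concatenate([assoc, chase])


@dataclass(frozen=True)
class WashoutDesign:
    """Washout time design (hours) with its full-exposure reference."""

    times: tuple = (0.5, 1.0, 2.0, 4.0, 24.0, 48.0, 72.0)
    reference_time: float = 72.0
    floor_potency: float = 0.03  # extrapolated potency at zero exposure


@dataclass
class TruePanel:
    """Ground-truth parameter set for a simulated compound panel.

    ``table`` has one row per compound with rate constants for the wild-type
    protein, the modulator (activator-peptide) condition and the
    association-impaired mutant, activation thermodynamics per phase, the
    cellular washout coupling and molecular metadata.  KD = koff/kon is
    consistent row-wise by construction.
    """

    table: pd.DataFrame
    seed: int
    config: dict = field(default_factory=dict)


def generate_panel(
    n_compounds: int,
    seed: int,
    kon_range: tuple[float, float] = (1e4, 1e7),
    residence_range_s: tuple[float, float] = (5.0, 3600.0),
    modulator_slowdown: tuple[float, float] = (5.0, 30.0),
    mutant_kon_impairment: tuple[float, float] = (3.0, 30.0),
    mutant_mechanism: str = "kon",
) -> TruePanel:
    """Draw a ground-truth compound panel.

    kon is log-uniform over ``kon_range`` (M^-1 s^-1) and residence time
    log-uniform over ``residence_range_s`` (so koff spans fast binders to
    nearly irreversible ones), matching the spans observed for the target
    class.  The modulator condition divides koff by a drawn slowdown factor
    (allosteric activation prolongs residence); the mutant divides kon
    (association impairment) or, with ``mutant_mechanism="koff"``,
    multiplies koff.  Activation enthalpies/heat capacities are drawn per
    phase and the matching entropies solved so the 25 °C rates are exactly
    reproduced.
    """
    if n_compounds < 1:
        raise ValueError("need n_compounds >= 1")
    for lo, hi in (kon_range, residence_range_s, modulator_slowdown, mutant_kon_impairment):
        if not 0 < lo <= hi:
            raise ValueError("ranges must be positive with lo <= hi")
    if mutant_mechanism not in ("kon", "koff"):
        raise ValueError("mutant_mechanism must be 'kon' or 'koff'")
    rng = np.random.default_rng(seed)
    n = n_compounds

    def log_uniform(lo, hi, size):
        return np.exp(rng.uniform(math.log(lo), math.log(hi), size))

    kon = log_uniform(*kon_range, n)
    rt = log_uniform(*residence_range_s, n)
    koff = 1.0 / rt
    slowdown = log_uniform(*modulator_slowdown, n)
    impair = log_uniform(*mutant_kon_impairment, n)

    # activation thermodynamics; entropies anchored so rates at 25 °C match
    dh_on = rng.uniform(20e3, 70e3, n)
    dcp_on = rng.uniform(-3000.0, -500.0, n)
    dh_off = rng.uniform(40e3, 90e3, n)
    dcp_off = rng.uniform(-500.0, 0.0, n)

    def ds_for(k, dh):
        # from ln k = ln(kB T/h) - dH/(RT) + dS/R at T_REF
        return R_GAS * (np.log(k * H_PLANCK / (K_BOLTZMANN * T_REF))
                        + dh / (R_GAS * T_REF))

    table = pd.DataFrame(
        {
            "compound_id": [f"C{i + 1:03d}" for i in range(n)],
            "scaffold_class": rng.choice(_SCAFFOLDS, n),
            "heavy_atoms": rng.integers(28, 45, n),
            "kon_wt": kon,
            "koff_wt": koff,
            "modulator_slowdown": slowdown,
            "kon_mod": kon,
            "koff_mod": koff / slowdown,
            "mutant_impairment": impair,
            "kon_mut": kon / impair if mutant_mechanism == "kon" else kon,
            "koff_mut": koff if mutant_mechanism == "kon" else koff * impair,
            "dh_act_on": dh_on,
            "ds_act_on": ds_for(kon, dh_on),
            "dcp_act_on": dcp_on,
            "dh_act_off": dh_off,
            "ds_act_off": ds_for(koff, dh_off),
            "dcp_act_off": dcp_off,
        }
    ).set_index("compound_id", drop=False)
    table["kd_wt"] = table["koff_wt"] / table["kon_wt"]
    return TruePanel(
        table=table,
        seed=seed,
        config={
            "kon_range": kon_range,
            "residence_range_s": residence_range_s,
            "modulator_slowdown": modulator_slowdown,
            "mutant_kon_impairment": mutant_kon_impairment,
            "mutant_mechanism": mutant_mechanism,
        },
    )


def simulate_probe_traces(
    probe: ProbeKinetics = DEFAULT_PROBE,
    design: ProbeDesign = ProbeDesign(),
    noise: NoiseModel = NOISELESS,
    seed: int = 0,
) -> list[KineticTrace]:
    """Probe titration traces (association then chase) from the 1:1 ODE."""
    rng = np.random.default_rng(seed)
    t = design.times()
    t0 = design.assoc_duration_s
    traces = []
    for L in design.probe_concs():
        y = probe_ode_signal(t, L, probe.k1, probe.k2, probe.bmax, t0=t0)
        traces.append(
            KineticTrace(
                time=t, signal=noise.apply(y, rng), probe_conc=float(L),
                chase_time=t0, protein_id=probe.protein_id, condition=probe.condition,
            )
        )
    return traces


def simulate_kpca_plate(
    kon: float,
    koff: float,
    probe: ProbeKinetics = DEFAULT_PROBE,
    design: KpcaDesign = KpcaDesign(),
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    compound_id: str = "",
) -> list[KineticTrace]:
    """Kinetic competition traces for one compound, from the coupled ODE.

    Includes the mandatory zero-competitor well.  Masked wells (noise
    ``masked_prob``) are dropped from the returned family.
    """
    rng = np.random.default_rng(seed)
    t = design.times()
    L = design.probe_conc
    traces = []
    for I in design.competitor_concs():
        if I == 0:
            y = probe_ode_signal(t, L, probe.k1, probe.k2, probe.bmax)
        else:
            y = competition_ode_signal(t, L, float(I), probe.k1, probe.k2,
                                       kon, koff, probe.bmax)
        masked = noise.masked_prob > 0 and rng.random() < noise.masked_prob
        if masked:
            continue
        traces.append(
            KineticTrace(
                time=t, signal=noise.apply(y, rng), probe_conc=L,
                competitor_conc=float(I), compound_id=compound_id,
                protein_id=probe.protein_id, condition=probe.condition,
            )
        )
    return traces


def equilibrium_bound_fraction(
    r_tot: float, l_tot: float, i_tot: float, kd_l: float, kd_i: float
) -> float:
    """Exact probe-bound target concentration at three-species equilibrium.

    Solves the mass-balance system for free target R in [0, Rtot]
    (monotone scalar root), with free ligands L = Ltot/(1 + R/KdL) and
    I = Itot/(1 + R/KdI); returns [RL].  No excess-ligand approximation is
    made, so ligand depletion is represented faithfully.
    """

    def f(r):
        lf = l_tot / (1.0 + r / kd_l)
        if_ = i_tot / (1.0 + r / kd_i) if i_tot > 0 else 0.0
        return r * (1.0 + lf / kd_l + if_ / kd_i) - r_tot

    if r_tot == 0:
        return 0.0
    r_free = brentq(f, 0.0, r_tot, xtol=1e-18, rtol=1e-14)
    l_free = l_tot / (1.0 + r_free / kd_l)
    return r_free * l_free / kd_l


def simulate_epca_plate(
    ki: float,
    design: EpcaDesign = EpcaDesign(),
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    compound_id: str = "",
) -> NormalizedCurve:
    """Equilibrium competition curve for one compound (exact mass balance).

    Signal is proportional to probe-bound target; responses are normalized so
    the zero-competitor equilibrium reads 0% and complete displacement 100%.
    Noise acts on the signal scale before normalization.  Masked doses are
    dropped.
    """
    rng = np.random.default_rng(seed)
    doses = design.doses()
    rl0 = equilibrium_bound_fraction(
        design.protein_conc, design.probe_conc, 0.0, design.probe_kd, ki
    )
    keep, resp = [], []
    for d in doses:
        if noise.masked_prob > 0 and rng.random() < noise.masked_prob:
            continue
        rl = equilibrium_bound_fraction(
            design.protein_conc, design.probe_conc, float(d), design.probe_kd, ki
        )
        sig = float(noise.apply(np.array([rl / rl0]), rng)[0])
        keep.append(float(d))
        resp.append(100.0 * (1.0 - sig))
    return NormalizedCurve(
        doses=np.array(keep), response=np.array(resp), compound_id=compound_id,
        meta={"true_ki": ki, "probe_conc": design.probe_conc,
              "probe_kd": design.probe_kd, "protein_conc": design.protein_conc},
    )


def simulate_temperature_series(
    panel: TruePanel,
    temperatures=ASSAY_TEMPERATURES_K,
    noise: NoiseModel = NOISELESS,
    seed: int = 0,
) -> dict[str, dict[str, TemperatureSeries]]:
    """Rate and affinity series across temperatures for every panel compound.

    kon(T) and koff(T) follow each compound's activation parameters through
    the Eyring relation; the KA series is derived as kon/koff, so the
    transition-state and equilibrium descriptions are mutually consistent by
    construction.
    """
    rng = np.random.default_rng(seed)
    T = np.asarray(temperatures, dtype=float)
    out: dict[str, dict[str, TemperatureSeries]] = {}
    for cid, row in panel.table.iterrows():
        kon = eyring_rate(T, row["dh_act_on"], row["ds_act_on"], row["dcp_act_on"])
        koff = eyring_rate(T, row["dh_act_off"], row["ds_act_off"], row["dcp_act_off"])
        kon_n = noise.apply(kon, rng)
        koff_n = noise.apply(koff, rng)
        out[str(cid)] = {
            "kon": TemperatureSeries(T, kon_n, kind="kon", compound_id=str(cid)),
            "koff": TemperatureSeries(T, koff_n, kind="koff", compound_id=str(cid)),
            "KA": TemperatureSeries(T, kon_n / koff_n, kind="KA", compound_id=str(cid)),
        }
    return out


def cellular_half_life_h(residence_time_s: float, scale_h: float = 150.0,
                         power: float = 1.0) -> float:
    """Designed coupling between residence time and cellular washout t1/2.

    A monotone power law t_half = scale * (RT/1 h)^power; the default maps a
    30 min residence time to a 75 h cellular half-life, so such compounds
    retain more than half their potency even at the shortest exposure of the
    washout design (the qualitative slow-binder behaviour the cellular assay
    is meant to expose).
    """
    return scale_h * (residence_time_s / 3600.0) ** power


def simulate_washout(
    panel: TruePanel,
    design: WashoutDesign = WashoutDesign(),
    noise: NoiseModel = NoiseModel(cv=0.05),
    seed: int = 0,
    coupling_scale_h: float = 150.0,
    coupling_power: float = 1.0,
) -> dict[str, WashoutSeries]:
    """Per-compound normalized washout potency series coupled to koff.

    The noiseless profile is the one-phase form in the washout lead time
    u = t_ref - t:  P = floor + (1 - floor)*exp(-ln2 * u/t_half_cell) with
    t_half_cell from :func:`cellular_half_life_h` — potency is full at the
    reference exposure and decays toward the floor as incubation shortens,
    faster for fast-dissociating compounds.  Multiplicative noise (default
    5% CV) acts on the per-time IC50 and the series is renormalized to its
    reference time, so P(t_ref) = 1 exactly.  Masked time points become NaN
    gaps.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(design.times, dtype=float)
    out: dict[str, WashoutSeries] = {}
    for cid, row in panel.table.iterrows():
        th = cellular_half_life_h(1.0 / row["koff_wt"], coupling_scale_h, coupling_power)
        u = design.reference_time - t
        p = design.floor_potency + (1.0 - design.floor_potency) * np.exp(
            -math.log(2.0) * u / th)
        ic50 = 1.0 / p  # reference IC50 of 1 in arbitrary units
        ic50 = ic50 * (1.0 + noise.cv * rng.standard_normal(ic50.shape))
        if noise.masked_prob > 0:
            gaps = rng.random(t.shape) < noise.masked_prob
            gaps[np.isclose(t, design.reference_time)] = False
            ic50[gaps] = np.nan
        ref = ic50[np.isclose(t, design.reference_time)][0]
        out[str(cid)] = WashoutSeries(
            times=t, potency=ref / ic50, reference_time=design.reference_time,
            compound_id=str(cid),
        )
    return out


def simulate_washout_plates(
    panel: TruePanel,
    design: WashoutDesign = WashoutDesign(),
    noise: NoiseModel = NoiseModel(cv=0.05),
    seed: int = 0,
    reference_ic50: float = 1e-7,
    hill: float = 1.0,
    coupling_scale_h: float = 150.0,
    coupling_power: float = 1.0,
) -> dict[str, dict[float, NormalizedCurve]]:
    """Full-resolution washout data: one dose-response curve per time point.

    Uses the cellular 10-dose threefold design (12.4 µM down to 0.63 nM).
    The per-time IC50 follows the same koff-coupled decay as
    :func:`simulate_washout`; responses get multiplicative noise.  Feeding
    these through ``fit_logistic4`` and :func:`moafit.cellular.washout_series`
    exercises the complete cellular stage end to end.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(design.times, dtype=float)
    doses = np.sort(12.4e-6 / 3.0 ** np.arange(10))
    out: dict[str, dict[float, NormalizedCurve]] = {}
    for cid, row in panel.table.iterrows():
        th = cellular_half_life_h(1.0 / row["koff_wt"], coupling_scale_h, coupling_power)
        u = design.reference_time - t
        p = design.floor_potency + (1.0 - design.floor_potency) * np.exp(
            -math.log(2.0) * u / th)
        curves: dict[float, NormalizedCurve] = {}
        for ti, pi in zip(t, p):
            ic50_t = reference_ic50 / pi
            resp = logistic4(doses, ic50_t, hill, 100.0, 0.0)
            resp = resp * (1.0 + noise.cv * rng.standard_normal(resp.shape))
            curves[float(ti)] = NormalizedCurve(
                doses=doses, response=resp, compound_id=str(cid),
                meta={"incubation_time_h": float(ti), "true_ic50": ic50_t},
            )
        out[str(cid)] = curves
    return out
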