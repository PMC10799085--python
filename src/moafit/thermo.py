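"""Equilibrium and transition-state thermodynamics of binding.

Temperature series of equilibrium association constants KA = 1/KD = kon/koff
are analysed with the van't Hoff equation,

    ln KA = dS°/R - dH°/(R*T)                       (linear form)
    ln KA = -dH°(T°)/(R*T) + dS°(T°)/R
            + dCp/R * [(T - T°)/T - ln(T/T°)]       (integrated form)

and temperature series of rate constants with the Eyring equation,

    ln(k*h/(kB*T)) = dS‡/R - dH‡/(R*T)              (linear form)

plus the analogous heat-capacity form for dCp‡.  Both heat-capacity forms are
linear in (dH, dS, dCp) given their basis functions and are solved by
(optionally weighted) linear least squares; following common usage they are
still reported as the "nonlinear"/"integrated" model.  Second-order on-rates
(M^-1 s^-1) enter the Eyring expression as pure numbers on the 1 M
standard-state scale, which fixes the absolute dS‡ convention (recorded in
the output).

Free energies are in J/mol, entropies and heat capacities in J/mol/K;
temperatures are kelvin everywhere (convert Celsius at the reader boundary).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "R_GAS",
    "H_PLANCK",
    "K_BOLTZMANN",
    "T_REF",
    "TemperatureSeries",
    "EquilibriumThermo",
    "TransitionThermo",
    "ThermoSignature",
    "vant_hoff_linear",
    "vant_hoff_integrated",
    "eyring_linear",
    "eyring_nonlinear",
    "eyring_rate",
    "vant_hoff_ka",
    "thermo_signature",
    "optimization_plot_table",
]

R_GAS = 8.314  # J mol^-1 K^-1
H_PLANCK = 6.626e-34  # J s
K_BOLTZMANN = 1.381e-23  # J K^-1
T_REF = 298.15  # K

_MIN_KELVIN = 150.0  # anything below this is almost certainly Celsius


def _curvature(T, t_ref=T_REF):
    """Heat-capacity basis function (T - T°)/T - ln(T/T°); zero at T = T°."""
    T = np.asarray(T, dtype=float)
    return (T - t_ref) / T - np.log(T / t_ref)


@dataclass
class TemperatureSeries:
    """Values of one thermodynamic observable across temperatures.

    ``kind`` is "KA" (equilibrium association constant, M^-1), "kon"
    (M^-1 s^-1) or "koff" (s^-1).  Optional per-point standard deviations
    enable 1/variance-weighted regression on the log scale.
    """

    temperature: np.ndarray  # kelvin
    values: np.ndarray
    kind: str = "KA"
    sd: np.ndarray | None = None
    compound_id: str = ""
    protein_id: str = ""

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.temperature.shape != self.values.shape:
            raise ValueError("temperature and values must have equal length")
        if np.any(self.temperature < _MIN_KELVIN):
            raise ValueError(
                "temperatures must be kelvin (found values < 150 K; convert "
                "Celsius at the reader boundary)"
            )
        if np.any(self.values <= 0):
            raise ValueError("equilibrium/rate constants must be positive")
        if self.kind not in ("KA", "kon", "koff"):
            raise ValueError(f"unknown series kind {self.kind!r}")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if np.any(self.sd < 0):
                raise ValueError("standard deviations must be non-negative")

    def n_distinct(self) -> int:
        return len(np.unique(self.temperature))


@dataclass
class EquilibriumThermo:
    """Equilibrium binding thermodynamics at the reference temperature."""

    dh: float  # J/mol
    ds: float  # J/mol/K
    dcp: float  # J/mol/K (0 for the linear model)
    model: str  # "linear" | "integrated"
    t_ref: float = T_REF
    rss: float = float("nan")
    stderr: dict = field(default_factory=dict)
    compound_id: str = ""

    @property
    def dg_ref(self) -> float:
        """dG° = dH° - T°*dS° at the reference temperature (J/mol)."""
        return self.dh - self.t_ref * self.ds


@dataclass
class TransitionThermo:
    """Activation thermodynamics of one kinetic phase at T°."""

    dh: float  # dH‡, J/mol
    ds: float  # dS‡, J/mol/K
    dcp: float  # dCp‡, J/mol/K
    phase: str  # "association" | "dissociation"
    model: str  # "linear" | "nonlinear"
    standard_state: str = "1 M"  # convention for second-order on-rates
    t_ref: float = T_REF
    rss: float = float("nan")
    stderr: dict = field(default_factory=dict)
    compound_id: str = ""

    @property
    def dg_ref(self) -> float:
        return self.dh - self.t_ref * self.ds


@dataclass
class ThermoSignature:
    """(dG, dH, -T*dS) bar values at one temperature, with a driver tag."""

    dg: float
    dh: float
    minus_tds: float
    temperature: float
    driver: str  # "enthalpy_driven" | "entropy_driven" | "balanced" | "unfavorable"


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray | None):
    """Weighted linear least squares; returns (beta, rss, stderr)."""
    if w is not None:
        sw = np.sqrt(w)
        Xw, yw = X * sw[:, None], y * sw
    else:
        Xw, yw = X, y
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    dof = len(y) - X.shape[1]
    stderr = np.full(X.shape[1], np.nan)
    if dof > 0:
        try:
            cov = np.linalg.inv(Xw.T @ Xw) * (rss / dof)
            stderr = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:  # pragma: no cover
            pass
    return beta, rss, stderr


def _log_weights(series: TemperatureSeries) -> np.ndarray | None:
    # var(ln v) ~= (sd/v)^2 by the delta method
    if series.sd is None or np.any(series.sd == 0):
        return None
    return (series.values / series.sd) ** 2


def vant_hoff_linear(series: TemperatureSeries) -> EquilibriumThermo:
    """Linear van't Hoff fit: OLS of ln KA on 1/T.

    dH° = -slope*R and dS° = intercept*R; dCp is fixed at zero.
    """
    if series.kind != "KA":
        raise ValueError("van't Hoff analysis needs a KA series")
    if series.n_distinct() < 3:
        raise ValueError("need >= 3 distinct temperatures")
    T = series.temperature
    y = np.log(series.values)
    X = np.column_stack([1.0 / T, np.ones_like(T)])
    beta, rss, se = _wls(X, y, _log_weights(series))
    return EquilibriumThermo(
        dh=-beta[0] * R_GAS,
        ds=beta[1] * R_GAS,
        dcp=0.0,
        model="linear",
        rss=rss,
        stderr={"dh": se[0] * R_GAS, "ds": se[1] * R_GAS},
        compound_id=series.compound_id,
    )


def vant_hoff_integrated(series: TemperatureSeries) -> EquilibriumThermo:
    """Integrated (heat-capacity) van't Hoff fit.

    ln KA = -dH°(T°)/(R*T) + dS°(T°)/R + dCp/R*[(T - T°)/T - ln(T/T°)];
    linear in (dH°, dS°, dCp) and solved by least squares on exactly the
    printed basis functions.
    """
    if series.kind != "KA":
        raise ValueError("van't Hoff analysis needs a KA series")
    if series.n_distinct() < 4:
        raise ValueError("need >= 4 distinct temperatures for a dCp fit")
    T = series.temperature
    y = np.log(series.values)
    X = np.column_stack([-1.0 / (R_GAS * T), np.full_like(T, 1.0 / R_GAS),
                         _curvature(T) / R_GAS])
    beta, rss, se = _wls(X, y, _log_weights(series))
    return EquilibriumThermo(
        dh=beta[0], ds=beta[1], dcp=beta[2],
        model="integrated",
        rss=rss,
        stderr={"dh": se[0], "ds": se[1], "dcp": se[2]},
        compound_id=series.compound_id,
    )


def _eyring_y(series: TemperatureSeries) -> np.ndarray:
    return np.log(series.values * H_PLANCK / (K_BOLTZMANN * series.temperature))


def _phase_of(series: TemperatureSeries, phase: str | None) -> str:
    if phase is not None:
        return phase
    return {"kon": "association", "koff": "dissociation"}.get(series.kind, "association")


def eyring_linear(series: TemperatureSeries, phase: str | None = None) -> TransitionThermo:
    """Linear Eyring fit: OLS of ln(k*h/(kB*T)) on 1/T.

    dH‡ = -slope*R, dS‡ = intercept*R.  ``phase`` defaults from the series
    kind (kon -> association, koff -> dissociation).
    """
    if series.kind == "KA":
        raise ValueError("Eyring analysis needs a rate-constant series")
    if series.n_distinct() < 3:
        raise ValueError("need >= 3 distinct temperatures")
    T = series.temperature
    y = _eyring_y(series)
    X = np.column_stack([1.0 / T, np.ones_like(T)])
    beta, rss, se = _wls(X, y, _log_weights(series))
    return TransitionThermo(
        dh=-beta[0] * R_GAS, ds=beta[1] * R_GAS, dcp=0.0,
        phase=_phase_of(series, phase), model="linear",
        rss=rss, stderr={"dh": se[0] * R_GAS, "ds": se[1] * R_GAS},
        compound_id=series.compound_id,
    )


def eyring_nonlinear(series: TemperatureSeries, phase: str | None = None) -> TransitionThermo:
    """Heat-capacity Eyring fit returning (dH‡(T°), dS‡(T°), dCp‡)."""
    if series.kind == "KA":
        raise ValueError("Eyring analysis needs a rate-constant series")
    if series.n_distinct() < 4:
        raise ValueError("need >= 4 distinct temperatures for a dCp fit")
    T = series.temperature
    y = _eyring_y(series)
    X = np.column_stack([-1.0 / (R_GAS * T), np.full_like(T, 1.0 / R_GAS),
                         _curvature(T) / R_GAS])
    beta, rss, se = _wls(X, y, _log_weights(series))
    return TransitionThermo(
        dh=beta[0], ds=beta[1], dcp=beta[2],
        phase=_phase_of(series, phase), model="nonlinear",
        rss=rss, stderr={"dh": se[0], "ds": se[1], "dcp": se[2]},
        compound_id=series.compound_id,
    )


def eyring_rate(T, dh, ds, dcp=0.0, t_ref=T_REF):
    """Rate constant implied by activation parameters (inverse of the fits).

    k(T) = (kB*T/h) * exp(-dH‡(T°)/(R*T) + dS‡(T°)/R + dCp‡/R*[(T-T°)/T - ln(T/T°)])
    """
    T = np.asarray(T, dtype=float)
    lnk = (-dh / (R_GAS * T) + ds / R_GAS + dcp / R_GAS * _curvature(T, t_ref)
           + np.log(K_BOLTZMANN * T / H_PLANCK))
    return np.exp(lnk)


def vant_hoff_ka(T, dh, ds, dcp=0.0, t_ref=T_REF):
    """Equilibrium KA implied by (dH°, dS°, dCp) — generator-side inverse."""
    T = np.asarray(T, dtype=float)
    return np.exp(-dh / (R_GAS * T) + ds / R_GAS + dcp / R_GAS * _curvature(T, t_ref))


def thermo_signature(thermo, T: float = T_REF) -> ThermoSignature:
    """(dG, dH, -T*dS) decomposition at temperature T with a driver tag.

    A non-zero dCp propagates the reference-temperature values:
    dH(T) = dH° + dCp*(T - T°) and dS(T) = dS° + dCp*ln(T/T°).  The driver is
    the more favorable (more negative) of dH and -T*dS; if neither is
    favorable the tag is "unfavorable", if they tie "balanced".
    """
    dh = thermo.dh + thermo.dcp * (T - thermo.t_ref)
    ds = thermo.ds + thermo.dcp * math.log(T / thermo.t_ref)
    minus_tds = -T * ds
    dg = dh + minus_tds
    if dh < 0 and dh < minus_tds:
        driver = "enthalpy_driven"
    elif minus_tds < 0 and minus_tds < dh:
        driver = "entropy_driven"
    elif dh < 0 and dh == minus_tds:
        driver = "balanced"
    else:
        driver = "unfavorable"
    return ThermoSignature(dg=dg, dh=dh, minus_tds=minus_tds, temperature=T, driver=driver)


def optimization_plot_table(
    panel: dict[str, EquilibriumThermo], T: float = T_REF
) -> pd.DataFrame:
    """Coordinates for a thermodynamic optimization plot (dH vs -T*dS plane).

    Each compound contributes one point; constant-dG isolines are the
    anti-diagonals dH + (-T*dS) = dG.  The ``entropy_dominant`` flag marks
    points whose entropy term is the more favorable axis (the zone advanced
    compounds tend to enter); it agrees with the :func:`thermo_signature`
    driver tag by construction.
    """
    if not panel:
        raise ValueError("empty panel")
    rows = []
    for compound_id, th in panel.items():
        sig = thermo_signature(th, T)
        rows.append(
            {
                "compound_id": compound_id,
                "dh": sig.dh,
                "minus_tds": sig.minus_tds,
                "dg": sig.dg,
                "entropy_dominant": sig.minus_tds < sig.dh,
                "driver": sig.driver,
            }
        )
    return pd.DataFrame(rows)
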