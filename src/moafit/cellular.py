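"""Cellular washout pharmacodynamics and ancillary cell-level readouts.

In a washout experiment, cells see the compound for a limited incubation
time before the medium is replaced; a dose-response curve per incubation
time yields IC50(t).  Potency is normalized to the full-exposure reference,
P(t) = IC50(t_ref)/IC50(t) in [0, 1] with P(t_ref) = 1 by construction, so
the profile is scale-free: P decays as exposure is shortened.  Two summary
statistics describe the profile — the washout half-life from a one-phase
exponential model along the incubation-time axis, and the area under the
potency-versus-time curve (trapezoidal, no extrapolation beyond the observed
span).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import lmfit
import numpy as np

from .equilibrium import DoseResponseFit, NormalizedCurve, fit_logistic4
from .kinetics import _multistart

__all__ = [
    "WashoutSeries",
    "WashoutSummary",
    "PermeabilityResult",
    "washout_series",
    "fit_one_phase_decay",
    "washout_auc",
    "efflux_ratio",
]


@dataclass
class WashoutSeries:
    """Normalized cellular potency per incubation time for one compound.

    Times are hours, sorted ascending; undeterminable time points are NaN
    gaps.  ``mode`` records the y-variable: "ic50_ratio"
    (IC50(t_ref)/IC50(t)) or "pic50_diff" (pIC50(t) - pIC50(t_ref)).
    """

    times: np.ndarray  # hours
    potency: np.ndarray  # normalized, NaN = not determinable
    reference_time: float
    mode: str = "ic50_ratio"
    pic50: np.ndarray | None = None
    compound_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.potency = np.asarray(self.potency, dtype=float)
        if self.times.shape != self.potency.shape:
            raise ValueError("times and potency must have equal length")
        if np.any(self.times <= 0):
            raise ValueError("incubation times must be positive")
        order = np.argsort(self.times, kind="stable")
        self.times = self.times[order]
        self.potency = self.potency[order]
        if self.pic50 is not None:
            self.pic50 = np.asarray(self.pic50, dtype=float)[order]
        if not np.any(np.isclose(self.times, self.reference_time)):
            raise ValueError("reference_time must be one of the incubation times")

    def usable(self) -> tuple[np.ndarray, np.ndarray]:
        ok = np.isfinite(self.potency)
        return self.times[ok], self.potency[ok]


@dataclass
class WashoutSummary:
    """Washout half-life, plateau and AUC for one compound."""

    t_half: float  # hours
    plateau: float
    y0: float = float("nan")
    auc: float = float("nan")
    t_half_determinable: bool = True
    gaps_bridged: bool = False
    rss: float = float("nan")
    compound_id: str = ""


@dataclass
class PermeabilityResult:
    """Bidirectional apparent permeability and the derived efflux ratio."""

    papp_ab: float  # cm/s, apical -> basolateral
    papp_ba: float  # cm/s, basolateral -> apical

    @property
    def efflux_ratio(self) -> float:
        """Papp(B->A) / Papp(A->B); > 1 suggests active efflux."""
        return self.papp_ba / self.papp_ab


def washout_series(
    per_time_curves: dict[float, NormalizedCurve | DoseResponseFit],
    reference_time: float,
    mode: str = "ic50_ratio",
    compound_id: str = "",
    **fit_kwargs,
) -> WashoutSeries:
    """Per-incubation-time dose-response fits -> normalized potency series.

    Curves are fitted with the 4PL model (already-fitted results are accepted
    as-is); times whose potency is flagged not determinable become NaN gaps.
    The reference-time curve must be fittable, otherwise the whole series is
    undefined.
    """
    if reference_time not in per_time_curves:
        raise ValueError("reference_time has no curve")
    fits: dict[float, DoseResponseFit] = {}
    for t, curve in per_time_curves.items():
        fits[t] = curve if isinstance(curve, DoseResponseFit) else fit_logistic4(curve, **fit_kwargs)
    ref = fits[reference_time]
    if not ref.determinable:
        raise ValueError("reference-time curve is not determinable")
    times = np.array(sorted(fits), dtype=float)
    potency = np.empty_like(times)
    pic50 = np.empty_like(times)
    for i, t in enumerate(times):
        f = fits[t]
        if not f.determinable:
            potency[i] = np.nan
            pic50[i] = np.nan
        elif mode == "ic50_ratio":
            potency[i] = ref.ic50 / f.ic50
            pic50[i] = f.pic50
        elif mode == "pic50_diff":
            potency[i] = f.pic50 - ref.pic50
            pic50[i] = f.pic50
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return WashoutSeries(
        times=times, potency=potency, reference_time=reference_time,
        mode=mode, pic50=pic50, compound_id=compound_id,
    )


def fit_one_phase_decay(
    series: WashoutSeries,
    convention: str = "washout_lead",
    flat_span: float = 0.05,
    n_starts: int = 4,
) -> WashoutSummary:
    """One-phase exponential model of the washout profile.

    Fits Y(x) = plateau + (Y0 - plateau)*exp(-ln2 * x / t_half).  With the
    default ``"washout_lead"`` convention the decay variable is
    x = t_ref - t, the time the compound is absent before the endpoint:
    potency is Y0 (~1) at full exposure and decays toward the plateau as the
    incubation is shortened, so a *large* t_half means the effect persists
    at brief exposures.  ``"incubation_time"`` fits the same form along the
    raw time axis instead.  A series whose usable span is below
    ``flat_span`` carries no rate information and is reported as not
    determinable (flagged) rather than as an infinite half-life.
    """
    t, y = series.usable()
    if len(t) < 4:
        raise ValueError("need >= 4 usable time points")
    if float(y.max() - y.min()) < flat_span:
        return WashoutSummary(
            t_half=float("nan"), plateau=float(np.mean(y)),
            t_half_determinable=False, compound_id=series.compound_id,
        )
    if convention == "washout_lead":
        x = series.reference_time - t
        y0_guess, plateau_guess = float(y[-1]), float(y[0])
    elif convention == "incubation_time":
        x = t
        y0_guess, plateau_guess = float(y[0]), float(y[-1])
    else:
        raise ValueError(f"unknown convention {convention!r}")

    def residual(p):
        th = 10.0 ** p["log_t_half"]
        return p["plateau"] + (p["y0"] - p["plateau"]) * np.exp(
            -math.log(2.0) * x / th
        ) - y

    xpos = x[x > 0]
    lo, hi = math.log10(xpos.min() / 4.0), math.log10(xpos.max() * 4.0)
    starts = []
    for lth in np.linspace(lo, hi, n_starts):
        p = lmfit.Parameters()
        p.add("plateau", value=plateau_guess)
        p.add("y0", value=y0_guess)
        p.add("log_t_half", value=float(lth), min=lo - 2, max=hi + 2)
        starts.append(p)
    res = _multistart(residual, starts)
    return WashoutSummary(
        t_half=10.0 ** res.params["log_t_half"].value,
        plateau=float(res.params["plateau"].value),
        y0=float(res.params["y0"].value),
        t_half_determinable=True,
        rss=float(res.chisqr),
        compound_id=series.compound_id,
    )


def washout_auc(series: WashoutSeries) -> float:
    """Trapezoidal area under the potency-versus-incubation-time curve.

    Integrated on the linear time axis over the observed span only; NaN gaps
    are bridged linearly (equivalent to dropping them from the trapezoid).
    Units: normalized potency x hours.
    """
    t, y = series.usable()
    if len(t) < 2:
        raise ValueError("need >= 2 usable time points for an AUC")
    return float(np.trapezoid(y, t))


def efflux_ratio(papp_ab: float, papp_ba: float) -> PermeabilityResult:
    """Bidirectional permeability -> efflux ratio Papp(B->A)/Papp(A->B)."""
    if not (papp_ab > 0 and papp_ba > 0):
        raise ValueError("permeabilities must be positive")
    return PermeabilityResult(papp_ab=papp_ab, papp_ba=papp_ba)
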