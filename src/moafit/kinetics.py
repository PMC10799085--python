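"""Time-domain binding models for probe-competition kinetics.

A fluorescent tracer (the "probe") and an unlabeled competitor bind a single
site on the target under pseudo-first-order conditions (both ligands in large
excess over binding sites, so their free concentrations stay constant).  The
probe alone follows simple 1:1 association/chase kinetics; with a competitor
present the tracer occupancy follows the Motulsky & Mahan closed-form solution
of the coupled two-ligand rate equations.  Fitting those traces yields the
competitor's association rate kon (k3), dissociation rate koff (k4), the
kinetic dissociation constant KD = koff/kon and the target residence time
RT = 1/koff.

Rate-constant naming follows the competition-kinetics convention:
k1/k2 are the probe's on/off rates, k3/k4 the competitor's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import lmfit
import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "KineticTrace",
    "ProbeKinetics",
    "CompoundKinetics",
    "assoc_dissoc_model",
    "motulsky_mahan_signal",
    "competition_ode_signal",
    "probe_ode_signal",
    "single_trace_kobs",
    "fit_probe_kinetics",
    "fit_kpca",
    "koff_from_equilibrium",
    "rapid_table",
]

# relative root separation below which the repeated-root limit form is used
_DEGENERATE_TOL = 1e-9


@dataclass
class KineticTrace:
    """One well's blank-subtracted TR-FRET signal versus time.

    Concentrations are molar, time in seconds, temperature in kelvin.
    ``chase_time`` marks the start of the dissociation ("chase") phase where
    an excess of unlabeled ligand blocks probe re-association.
    """

    time: np.ndarray
    signal: np.ndarray
    probe_conc: float
    competitor_conc: float = 0.0
    modulator_conc: float = 0.0
    temperature: float = 298.15
    chase_time: float | None = None
    compound_id: str = ""
    protein_id: str = ""
    condition: str = ""
    well: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.signal.shape:
            raise ValueError("time and signal must be 1-D arrays of equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.probe_conc < 0 or self.competitor_conc < 0 or self.modulator_conc < 0:
            raise ValueError("concentrations must be non-negative")
        if self.chase_time is not None and not (
            self.time.min() < self.chase_time < self.time.max()
        ):
            raise ValueError("chase_time must lie strictly inside the time range")

    @property
    def duration(self) -> float:
        return float(self.time.max() - self.time.min())


@dataclass
class ProbeKinetics:
    """Globally fitted 1:1 rate constants of the fluorescent probe."""

    k1: float  # association rate, M^-1 s^-1
    k2: float  # dissociation rate, s^-1
    bmax: float  # signal amplitude at full saturation
    k1_stderr: float = float("nan")
    k2_stderr: float = float("nan")
    bmax_stderr: float = float("nan")
    rss: float = float("nan")
    kobs_per_trace: dict[float, float] = field(default_factory=dict)
    k2_wide_interval: bool = False
    protein_id: str = ""
    condition: str = ""

    @property
    def kd(self) -> float:
        """Kinetic dissociation constant k2/k1 (molar)."""
        return self.k2 / self.k1


@dataclass
class CompoundKinetics:
    """Fitted competitor rate constants and derived kinetic quantities."""

    kon: float  # k3, M^-1 s^-1
    koff: float  # k4, s^-1
    kon_stderr: float = float("nan")
    koff_stderr: float = float("nan")
    bmax: float = float("nan")
    rss: float = float("nan")
    koff_source: str = "fitted"  # "fitted" | "equilibrium_product"
    elusive_equilibrium: bool = False
    koff_unreliable: bool = False
    compound_id: str = ""
    protein_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if self.kon <= 0 or self.koff <= 0:
            raise ValueError("kon and koff must be positive")

    @property
    def kd(self) -> float:
        return self.koff / self.kon

    @property
    def residence_time(self) -> float:
        """Target residence time 1/koff in seconds."""
        return 1.0 / self.koff


def _check_positive(**params: float) -> None:
    for name, value in params.items():
        if not value > 0:
            raise ValueError(f"{name} must be positive, got {value}")


def assoc_dissoc_model(t, L, k1, k2, bmax, t0=None):
    """1:1 probe association followed by an irreversible chase.

    Before the chase time ``t0`` the bound signal rises as
    Y = Eq*(1 - exp(-kobs*t)) with kobs = k1*L + k2 and the equilibrium
    plateau Eq = bmax*L/(L + KD), KD = k2/k1.  From ``t0`` on, excess
    unlabeled ligand prevents re-association and the signal decays as
    Y(t0)*exp(-k2*(t - t0)).  The curve is continuous at t0.
    """
    _check_positive(k1=k1, k2=k2, bmax=bmax)
    if L < 0:
        raise ValueError("probe concentration must be non-negative")
    t = np.asarray(t, dtype=float)
    if L == 0:
        return np.zeros_like(t)
    kobs = k1 * L + k2
    eq = bmax * L / (L + k2 / k1)
    y = eq * (1.0 - np.exp(-kobs * t))
    if t0 is not None:
        y_t0 = eq * (1.0 - math.exp(-kobs * t0))
        chase = t >= t0
        y = np.where(chase, y_t0 * np.exp(-k2 * (t - t0)), y)
    return y


def _mm_degenerate(t, L, k1, k4, bmax, kk):
    # analytic limit of the biexponential as KF -> KS = kk (repeated root)
    expk = np.exp(-kk * t)
    core = k4 / kk**2 * (1.0 - expk) - t * expk * (k4 - kk) / kk
    return bmax * k1 * L * core


def motulsky_mahan_signal(t, L, I, k1, k2, k3, k4, bmax):
    """Closed-form tracer occupancy signal under competitive binding kinetics.

    Tracer (probe) at constant free concentration ``L`` with rates k1/k2 and
    competitor at constant ``I`` with rates k3/k4 start binding a free target
    at t = 0.  With KA = k1*L + k2, KB = k3*I + k4 and
    S = sqrt((KA - KB)^2 + 4*k1*k3*L*I) the tracer-bound signal is the
    biexponential with eigenvalues KF = (KA + KB + S)/2, KS = (KA + KB - S)/2:

        Y(t) = Q * [ k4*(KF - KS)/(KF*KS)
                     + (k4 - KF)/KF * exp(-KF*t)
                     - (k4 - KS)/KS * exp(-KS*t) ],   Q = bmax*k1*L/(KF - KS)

    With I = 0 this reduces exactly to 1:1 association with
    kobs = k1*L + k2.  A repeated root KF = KS is evaluated by its analytic
    limit when |KF - KS| < 1e-9*(KF + KS).
    """
    _check_positive(k1=k1, k2=k2, k3=k3, k4=k4, bmax=bmax)
    if L < 0 or I < 0:
        raise ValueError("concentrations must be non-negative")
    t = np.asarray(t, dtype=float)
    if L == 0:
        return np.zeros_like(t)
    ka = k1 * L + k2
    kb = k3 * I + k4
    s = math.sqrt((ka - kb) ** 2 + 4.0 * k1 * k3 * L * I)
    kf = 0.5 * (ka + kb + s)
    ks = 0.5 * (ka + kb - s)
    if kf - ks < _DEGENERATE_TOL * (kf + ks):
        return _mm_degenerate(t, L, k1, k4, bmax, 0.5 * (kf + ks))
    q = bmax * k1 * L / (kf - ks)
    y = q * (
        k4 * (kf - ks) / (kf * ks)
        + (k4 - kf) / kf * np.exp(-kf * t)
        - (k4 - ks) / ks * np.exp(-ks * t)
    )
    return y


def competition_ode_signal(t, L, I, k1, k2, k3, k4, bmax, rtol=1e-10, atol=1e-13):
    """Numerical reference for :func:`motulsky_mahan_signal`.

    Integrates the coupled occupancy fractions

        dRL/dt = k1*L*(1 - RL - RI) - k2*RL
        dRI/dt = k3*I*(1 - RL - RI) - k4*RI

    from an empty target and returns bmax*RL(t).  Used by the synthetic-data
    generators (so fitting is never tested against its own closed form) and by
    the oracle-equivalence tests.
    """
    t = np.asarray(t, dtype=float)

    def rhs(_t, y):
        rl, ri = y
        free = 1.0 - rl - ri
        return [k1 * L * free - k2 * rl, k3 * I * free - k4 * ri]

    t0 = min(0.0, float(t.min()))
    sol = solve_ivp(
        rhs,
        (t0, float(t.max())),
        [0.0, 0.0],
        t_eval=t,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:  # pragma: no cover - LSODA is robust on this system
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return bmax * sol.y[0]


def probe_ode_signal(t, L, k1, k2, bmax, t0=None, rtol=1e-10, atol=1e-13):
    """ODE reference for :func:`assoc_dissoc_model` (irreversible chase)."""
    t = np.asarray(t, dtype=float)

    # association: dRL = k1 L (1-RL) - k2 RL ; chase: dRL = -k2 RL
    # integrated in two segments so the chase discontinuity is exact
    def assoc(_tt, y):
        return [k1 * L * (1.0 - y[0]) - k2 * y[0]]

    def chase(_tt, y):
        return [-k2 * y[0]]

    t_end = float(t.max())
    if t0 is None or t0 >= t_end:
        sol = solve_ivp(assoc, (0.0, t_end), [0.0], t_eval=t,
                        method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        return bmax * sol.y[0]

    pre, post = t[t < t0], t[t >= t0]
    sol1 = solve_ivp(assoc, (0.0, float(t0)), [0.0],
                     t_eval=np.append(pre, t0), method="LSODA",
                     rtol=rtol, atol=atol)
    sol2 = solve_ivp(chase, (float(t0), t_end), [sol1.y[0][-1]],
                     t_eval=post, method="LSODA", rtol=rtol, atol=atol)
    if not (sol1.success and sol2.success):  # pragma: no cover
        raise RuntimeError("ODE integration failed")
    return bmax * np.concatenate([sol1.y[0][:-1], sol2.y[0]])


def _multistart(residual, param_sets):
    best = None
    for params in param_sets:
        try:
            res = lmfit.minimize(residual, params, method="leastsq")
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("all fit starts failed")
    return best


def _log_stderr(param) -> float:
    # delta method: parameter fitted as log10(p); se(p) = ln(10) * p * se(log10 p)
    if param.stderr is None:
        return float("nan")
    return math.log(10.0) * (10.0 ** param.value) * param.stderr


def single_trace_kobs(trace: KineticTrace) -> float:
    """Observed rate of a single association phase (diagnostic).

    Fits the pre-chase portion to A*(1 - exp(-kobs*t)); a regression of kobs
    on probe concentration has slope k1 and intercept k2.
    """
    mask = (
        trace.time < trace.chase_time if trace.chase_time is not None
        else np.ones_like(trace.time, bool)
    )
    t, y = trace.time[mask], trace.signal[mask]

    def residual(p):
        return p["amp"] * (1.0 - np.exp(-(10.0 ** p["log_kobs"]) * t)) - y

    ymax = max(float(y.max()), 1e-12)
    half = t[np.searchsorted(y, 0.5 * ymax)] if np.any(y >= 0.5 * ymax) else t[-1]
    guess = math.log10(max(math.log(2.0) / max(half, t[1]), 1e-6))
    starts = []
    for dg in (-0.5, 0.0, 0.5):
        p = lmfit.Parameters()
        p.add("amp", value=ymax, min=0.0)
        p.add("log_kobs", value=guess + dg, min=-8, max=3)
        starts.append(p)
    res = _multistart(residual, starts)
    return float(10.0 ** res.params["log_kobs"].value)


def fit_probe_kinetics(
    traces: list[KineticTrace],
    n_starts: int = 3,
    with_kobs_diagnostics: bool = False,
) -> ProbeKinetics:
    """Global 1:1 association/chase fit across a probe titration family.

    A single (k1, k2, bmax) triple is shared by all traces; each trace
    contributes its own probe concentration and chase time.  Traces must come
    from one protein/condition/temperature.  Raises a wide-interval warning
    flag on k2 when the recorded dissociation phase is shorter than 0.5/k2.
    """
    traces = [tr for tr in traces if tr.probe_conc > 0]
    if len(traces) < 4:
        raise ValueError("need >= 4 traces with non-zero probe concentration")
    if len({(tr.protein_id, tr.condition) for tr in traces}) > 1:
        raise ValueError("traces must share protein and condition")

    def residual(p):
        k1, k2 = 10.0 ** p["log_k1"], 10.0 ** p["log_k2"]
        out = [
            assoc_dissoc_model(tr.time, tr.probe_conc, k1, k2, p["bmax"], tr.chase_time)
            - tr.signal
            for tr in traces
        ]
        return np.concatenate(out)

    # initial guesses from the highest-concentration trace
    top = max(traces, key=lambda tr: tr.probe_conc)
    ymax = max(float(top.signal.max()), 1e-12)
    k2_guess = 1e-3
    if top.chase_time is not None:
        chase = top.time >= top.chase_time
        yc = top.signal[chase]
        tc = top.time[chase] - top.chase_time
        pos = yc > 0.05 * ymax
        if pos.sum() >= 3:
            slope = np.polyfit(tc[pos], np.log(yc[pos]), 1)[0]
            if slope < 0:
                k2_guess = -slope
    kobs_guess = single_trace_kobs(top)
    k1_guess = max((kobs_guess - k2_guess) / top.probe_conc, 1e2)

    starts = []
    factors = np.logspace(-1, 1, n_starts) if n_starts > 1 else [1.0]
    for f in factors:
        p = lmfit.Parameters()
        p.add("log_k1", value=math.log10(k1_guess * f), min=0, max=12)
        p.add("log_k2", value=math.log10(k2_guess), min=-8, max=2)
        p.add("bmax", value=ymax * 1.2, min=0.0)
        starts.append(p)
    res = _multistart(residual, starts)
    k1 = 10.0 ** res.params["log_k1"].value
    k2 = 10.0 ** res.params["log_k2"].value
    dissoc_len = max(
        (tr.duration - tr.chase_time for tr in traces if tr.chase_time is not None),
        default=0.0,
    )
    kobs = (
        {tr.probe_conc: single_trace_kobs(tr) for tr in traces}
        if with_kobs_diagnostics
        else {}
    )
    return ProbeKinetics(
        k1=k1,
        k2=k2,
        bmax=float(res.params["bmax"].value),
        k1_stderr=_log_stderr(res.params["log_k1"]),
        k2_stderr=_log_stderr(res.params["log_k2"]),
        bmax_stderr=res.params["bmax"].stderr or float("nan"),
        rss=float(res.chisqr),
        kobs_per_trace=kobs,
        k2_wide_interval=bool(dissoc_len > 0 and dissoc_len < 0.5 / k2),
        protein_id=traces[0].protein_id,
        condition=traces[0].condition,
    )


def fit_kpca(
    traces: list[KineticTrace],
    probe: ProbeKinetics,
    fix_bmax: float | None = None,
    elusive_threshold: float = 0.1,
) -> CompoundKinetics:
    """Global Motulsky–Mahan fit of a kinetic probe-competition family.

    The probe rates (k1, k2) are fixed from :func:`fit_probe_kinetics`; a
    single (k3, k4) pair is fitted across all competitor concentrations with
    a shared signal amplitude (fitted, or fixed via ``fix_bmax``).  When the
    fitted k4 times the acquisition window is below ``elusive_threshold`` the
    dissociation rate is uninformative within the trace duration and the
    result carries ``elusive_equilibrium``/``koff_unreliable`` flags — the
    recommended fallback is :func:`koff_from_equilibrium`.
    """
    if not traces:
        raise ValueError("no traces supplied")
    if all(tr.competitor_conc == 0 for tr in traces):
        raise ValueError("no competition information: all competitor concentrations are zero")
    n_conc = len({tr.competitor_conc for tr in traces if tr.competitor_conc > 0})
    if n_conc < 2:
        raise ValueError("need >= 2 non-zero competitor concentrations for a global fit")

    k1, k2 = probe.k1, probe.k2
    duration = max(tr.duration for tr in traces)
    top = max(tr.signal.max() for tr in traces)
    bmax_guess = fix_bmax if fix_bmax is not None else float(top) * 1.2

    def residual(p):
        k3, k4 = 10.0 ** p["log_k3"], 10.0 ** p["log_k4"]
        bm = p["bmax"].value
        out = [
            motulsky_mahan_signal(
                tr.time, tr.probe_conc, tr.competitor_conc, k1, k2, k3, k4, bm
            )
            - tr.signal
            for tr in traces
        ]
        return np.concatenate(out)

    starts = []
    for lk3 in (4.0, 5.5, 7.0):
        for lk4 in (math.log10(0.5 / duration), math.log10(5.0 / duration)):
            p = lmfit.Parameters()
            p.add("log_k3", value=lk3, min=0, max=12)
            p.add("log_k4", value=lk4, min=-9, max=2)
            p.add("bmax", value=bmax_guess, min=0.0, vary=fix_bmax is None)
            starts.append(p)
    res = _multistart(residual, starts)
    k3 = 10.0 ** res.params["log_k3"].value
    k4 = 10.0 ** res.params["log_k4"].value
    elusive = bool(k4 * duration < elusive_threshold)
    return CompoundKinetics(
        kon=k3,
        koff=k4,
        kon_stderr=_log_stderr(res.params["log_k3"]),
        koff_stderr=_log_stderr(res.params["log_k4"]),
        bmax=float(res.params["bmax"].value),
        rss=float(res.chisqr),
        koff_source="fitted",
        elusive_equilibrium=elusive,
        koff_unreliable=elusive,
        compound_id=traces[0].compound_id,
        protein_id=traces[0].protein_id,
        condition=traces[0].condition,
    )


def koff_from_equilibrium(
    kon: float,
    kd_eq: float,
    template: CompoundKinetics | None = None,
) -> CompoundKinetics:
    """Dissociation rate from the product of kon and the equilibrium KD.

    For slow binders whose dissociation is invisible within the acquisition
    window, koff = kon x KD_eq (KD_eq typically the Ki from the equilibrium
    competition assay).  Provenance is recorded as ``equilibrium_product``.
    """
    _check_positive(kon=kon, kd_eq=kd_eq)
    base = template if template is not None else CompoundKinetics(kon=kon, koff=1.0)
    return replace(
        base,
        kon=kon,
        koff=kon * kd_eq,
        koff_stderr=float("nan"),
        koff_source="equilibrium_product",
        koff_unreliable=False,
    )


def rapid_table(panel: list[CompoundKinetics]):
    """Rate-plot (isoaffinity diagonal) coordinates for a compound panel.

    One row per compound x protein x condition with log10 kon, log10 koff and
    the isoaffinity value log10 KD = log10 koff - log10 kon.  Points of equal
    KD lie on a slope-1 diagonal in the (log kon, log koff) plane.
    """
    import pandas as pd

    if not panel:
        raise ValueError("empty panel")
    rows = [
        {
            "compound_id": ck.compound_id,
            "protein_id": ck.protein_id,
            "condition": ck.condition,
            "log10_kon": math.log10(ck.kon),
            "log10_koff": math.log10(ck.koff),
            "log10_kd": math.log10(ck.koff) - math.log10(ck.kon),
            "residence_time_s": ck.residence_time,
            "koff_source": ck.koff_source,
            "koff_unreliable": ck.koff_unreliable,
        }
        for ck in panel
    ]
    return pd.DataFrame(rows)
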