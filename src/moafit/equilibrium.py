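"""Equilibrium binding and dose-response models.

Covers the endpoint side of the probe-competition platform: plate
normalization against neutral/inhibitor controls, 1:1 saturation binding of
the fluorescent probe, four-parameter logistic (4PL) dose-response fitting,
the allosteric affinity-shift model for a modulator acting at a distinct
site, and the Cheng-Prusoff conversion of competition IC50s into Ki values.

Responses are expressed throughout as % displacement/inhibition: 0% at the
vehicle (neutral) control, 100% at the full-block (inhibitor) control, so
displacement curves rise with dose.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd

from .kinetics import _log_stderr, _multistart

__all__ = [
    "NormalizedCurve",
    "SaturationFit",
    "DoseResponseFit",
    "AllostericFit",
    "normalize_plate",
    "normalize_plate_all",
    "fit_saturation",
    "fit_logistic4",
    "fit_allosteric_shift",
    "cheng_prusoff",
    "ki_to_ic50",
    "logistic4",
    "allosteric_antag",
]


@dataclass
class NormalizedCurve:
    """Control-normalized dose-response points for one compound.

    All replicate points are kept (doses may repeat); fits consume them
    simultaneously rather than pre-averaging.
    """

    doses: np.ndarray  # molar, sorted ascending
    response: np.ndarray  # % displacement
    neutral_mean: float = float("nan")
    neutral_sd: float = float("nan")
    inhibitor_mean: float = float("nan")
    inhibitor_sd: float = float("nan")
    z_factor: float = float("nan")
    compound_id: str = ""
    modulator_conc: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.doses.shape != self.response.shape:
            raise ValueError("doses and response must have equal length")
        if np.any(self.doses <= 0):
            raise ValueError("doses must be strictly positive")
        order = np.argsort(self.doses, kind="stable")
        self.doses = self.doses[order]
        self.response = self.response[order]
        if not np.all(np.isfinite(self.response)):
            raise ValueError("response values must be finite")
        if np.isfinite(self.z_factor) and self.z_factor > 1:
            raise ValueError("Z'-factor cannot exceed 1")


@dataclass
class SaturationFit:
    """1:1 specific-binding fit Y = Bmax*X/(KD + X)."""

    bmax: float
    kd: float  # molar
    bmax_stderr: float
    kd_stderr: float
    rss: float
    ligand_depletion: bool = False


@dataclass
class DoseResponseFit:
    """Four-parameter logistic fit of a normalized displacement curve."""

    ic50: float  # molar
    hill: float
    top: float
    bottom: float
    ic50_stderr: float = float("nan")
    hill_stderr: float = float("nan")
    rss: float = float("nan")
    converged: bool = True
    determinable: bool = True

    def __post_init__(self) -> None:
        if self.determinable and not self.ic50 > 0:
            raise ValueError("IC50 must be positive")
        if self.top < self.bottom:
            raise ValueError("Top must be >= Bottom")

    @property
    def pic50(self) -> float:
        return -math.log10(self.ic50) if self.determinable else float("nan")


@dataclass
class AllostericFit:
    """Global allosteric affinity-shift fit across a modulator series.

    ``kb`` is the modulator's binding constant at its own (allosteric) site
    and ``alpha`` the ternary-complex cooperativity factor: the apparent
    potency at modulator concentration B is EC50 * Antag(B) with
    Antag = (1 + B/KB)/(1 + alpha*B/KB); alpha > 1 means the modulator
    increases the probe's apparent affinity (limiting shift 1/alpha).
    """

    ec50: float  # molar, probe potency at B = 0
    kb: float  # molar
    alpha: float
    hill: float
    top: float
    bottom: float
    ec50_stderr: float = float("nan")
    kb_stderr: float = float("nan")
    alpha_stderr: float = float("nan")
    rss: float = float("nan")
    no_shift_detected: bool = False

    def apparent_ec50(self, B: float) -> float:
        return self.ec50 * allosteric_antag(B, self.kb, self.alpha)


def logistic4(x, ic50, hill, top, bottom):
    """Rising 4PL: Y = Bottom + (Top - Bottom)/(1 + (IC50/X)^Hill)."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ic50 / x) ** hill)


def allosteric_antag(B, kb, alpha):
    """Apparent-potency shift factor Antag = (1 + B/KB)/(1 + alpha*B/KB)."""
    return (1.0 + B / kb) / (1.0 + alpha * B / kb)


def _control_stats(values: np.ndarray) -> tuple[float, float]:
    return float(np.mean(values)), float(np.std(values, ddof=1))


def normalize_plate(
    plate: pd.DataFrame,
    compound_id: str | None = None,
    neutral_role: str = "neutral_control",
    inhibitor_role: str = "inhibitor_control",
) -> NormalizedCurve:
    """Normalize one compound's raw signals against plate controls.

    response = 100 * (neutral_mean - signal) / (neutral_mean - inhibitor_mean)

    so vehicle wells score 0% and full-block wells 100%.  The plate table
    needs columns ``role``, ``dose_M``, ``signal`` and optionally
    ``compound_id``, ``masked``, ``modulator_conc_M``.  Masked wells are
    excluded.  The Z'-factor 1 - 3*(SD_n + SD_i)/|mean_n - mean_i| is
    reported as a plate-quality diagnostic.
    """
    df = plate.copy()
    if "masked" in df.columns:
        df = df[df["masked"].fillna(0).astype(int) == 0]
    neutral = df[df["role"] == neutral_role]["signal"].to_numpy(float)
    inhibitor = df[df["role"] == inhibitor_role]["signal"].to_numpy(float)
    if len(neutral) < 2:
        raise ValueError(f"need >= 2 wells with role '{neutral_role}'")
    if len(inhibitor) < 2:
        raise ValueError(f"need >= 2 wells with role '{inhibitor_role}'")
    n_mean, n_sd = _control_stats(neutral)
    i_mean, i_sd = _control_stats(inhibitor)
    window = n_mean - i_mean
    if window == 0:
        raise ZeroDivisionError(
            "normalization undefined: neutral and inhibitor control means are identical"
        )
    z_factor = 1.0 - 3.0 * (n_sd + i_sd) / abs(window)

    samples = df[df["role"] == "sample"]
    if compound_id is None:
        ids = samples["compound_id"].unique() if "compound_id" in samples else [""]
        if len(ids) != 1:
            raise ValueError(
                f"plate holds {len(ids)} compounds; pass compound_id or use "
                "normalize_plate_all"
            )
        compound_id = str(ids[0])
    elif "compound_id" in samples.columns:
        samples = samples[samples["compound_id"] == compound_id]
    if samples.empty:
        raise ValueError(f"no sample wells for compound {compound_id!r}")
    response = 100.0 * (n_mean - samples["signal"].to_numpy(float)) / window
    mod = 0.0
    if "modulator_conc_M" in samples.columns:
        mods = samples["modulator_conc_M"].fillna(0.0).unique()
        if len(mods) == 1:
            mod = float(mods[0])
    return NormalizedCurve(
        doses=samples["dose_M"].to_numpy(float),
        response=response,
        neutral_mean=n_mean,
        neutral_sd=n_sd,
        inhibitor_mean=i_mean,
        inhibitor_sd=i_sd,
        z_factor=z_factor,
        compound_id=compound_id,
        modulator_conc=mod,
    )


def normalize_plate_all(plate: pd.DataFrame, **kwargs) -> dict[str, NormalizedCurve]:
    """Normalize every compound on a multi-compound plate."""
    ids = plate.loc[plate["role"] == "sample", "compound_id"].unique()
    return {str(c): normalize_plate(plate, compound_id=str(c), **kwargs) for c in ids}


def fit_saturation(
    conc,
    signal,
    protein_conc: float | None = None,
    n_starts: int = 5,
) -> SaturationFit:
    """Least-squares 1:1 saturation binding fit (Y = Bmax*X/(KD + X)).

    Multi-start over log-spaced KD guesses spanning the titration range; KD is
    fitted on a log scale so decade-spanning affinities are well conditioned.
    Raises a ligand-depletion flag when the fitted KD is within tenfold of the
    stated protein concentration (the fit is then reported but suspect).
    """
    conc = np.asarray(conc, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if len(np.unique(conc[conc > 0])) < 4:
        raise ValueError("need >= 4 distinct non-zero concentrations")
    noise_floor = 0.05 * float(np.max(np.abs(signal)))
    if np.any(signal < -3 * noise_floor):
        warnings.warn("negative signals beyond the noise floor", UserWarning)

    def residual(p):
        kd = 10.0 ** p["log_kd"]
        return p["bmax"] * conc / (kd + conc) - signal

    pos = conc[conc > 0]
    lo, hi = math.log10(pos.min() / 10.0), math.log10(pos.max() * 10.0)
    starts = []
    for lkd in np.linspace(lo, hi, n_starts):
        p = lmfit.Parameters()
        p.add("bmax", value=float(np.max(signal)), min=0.0)
        p.add("log_kd", value=float(lkd), min=lo - 3, max=hi + 3)
        starts.append(p)
    res = _multistart(residual, starts)
    kd = 10.0 ** res.params["log_kd"].value
    return SaturationFit(
        bmax=float(res.params["bmax"].value),
        kd=kd,
        bmax_stderr=res.params["bmax"].stderr or float("nan"),
        kd_stderr=_log_stderr(res.params["log_kd"]),
        rss=float(res.chisqr),
        ligand_depletion=bool(protein_conc is not None and kd < 10.0 * protein_conc),
    )


def fit_logistic4(
    curve: NormalizedCurve,
    fix_top: float | None = None,
    fix_bottom: float | None = None,
    fix_hill: float | None = None,
    window: float = 100.0,
    min_span_fraction: float = 0.3,
    n_starts: int = 5,
) -> DoseResponseFit:
    """Four-parameter logistic fit of one normalized displacement curve.

    The Hill slope is free but bounded to [0.3, 5] unless fixed.  When the
    observed response spans less than ``min_span_fraction`` of the assay
    window the potency is reported as not determinable (NaN IC50 with a flag)
    rather than as an extrapolated number.
    """
    x, y = curve.doses, curve.response
    if len(np.unique(x)) < 5:
        raise ValueError("need >= 5 distinct doses")
    span = float(y.max() - y.min())
    if span < min_span_fraction * window:
        return DoseResponseFit(
            ic50=float("nan"), hill=float("nan"),
            top=float(y.max()), bottom=float(y.min()),
            converged=False, determinable=False,
        )

    def residual(p):
        return logistic4(x, 10.0 ** p["log_ic50"], p["hill"], p["top"], p["bottom"]) - y

    lo, hi = math.log10(x.min()), math.log10(x.max())
    starts = []
    for lic in np.linspace(lo, hi, n_starts):
        p = lmfit.Parameters()
        p.add("log_ic50", value=float(lic), min=lo - 4, max=hi + 4)
        p.add("hill", value=fix_hill if fix_hill is not None else 1.0,
              min=0.3, max=5.0, vary=fix_hill is None)
        p.add("top", value=fix_top if fix_top is not None else float(y.max()),
              vary=fix_top is None)
        p.add("bottom", value=fix_bottom if fix_bottom is not None else float(y.min()),
              vary=fix_bottom is None)
        starts.append(p)
    res = _multistart(residual, starts)
    top, bottom = float(res.params["top"].value), float(res.params["bottom"].value)
    hill = float(res.params["hill"].value)
    if top < bottom:
        # falling-curve convention: swap asymptotes, report a signed Hill slope
        top, bottom, hill = bottom, top, -hill
    return DoseResponseFit(
        ic50=10.0 ** res.params["log_ic50"].value,
        hill=hill,
        top=top,
        bottom=bottom,
        ic50_stderr=_log_stderr(res.params["log_ic50"]),
        hill_stderr=res.params["hill"].stderr or float("nan"),
        rss=float(res.chisqr),
        converged=bool(res.success),
    )


def fit_allosteric_shift(
    curves: list[NormalizedCurve],
    fix_hill: float | None = None,
    n_starts: int = 5,
) -> AllostericFit:
    """Global allosteric affinity-shift fit over a modulator concentration family.

    Each curve carries its modulator concentration B (one of them must be
    B = 0); Top, Bottom, Hill, EC50, KB and alpha are shared across the
    family and the B-dependence enters only through
    Antag(B) = (1 + B/KB)/(1 + alpha*B/KB).  With B = 0 the model reduces
    exactly to the plain 4PL.  When alpha is statistically indistinguishable
    from 1 (within two standard errors) a ``no_shift_detected`` flag is set
    alongside the estimates.
    """
    if len(curves) < 3:
        raise ValueError("need >= 3 modulator concentrations")
    if not any(c.modulator_conc == 0 for c in curves):
        raise ValueError("family must include a B = 0 curve")

    def residual(p):
        ec50 = 10.0 ** p["log_ec50"]
        kb = 10.0 ** p["log_kb"]
        alpha = 10.0 ** p["log_alpha"]
        out = []
        for c in curves:
            antag = allosteric_antag(c.modulator_conc, kb, alpha)
            out.append(
                logistic4(c.doses, ec50 * antag, p["hill"], p["top"], p["bottom"])
                - c.response
            )
        return np.concatenate(out)

    all_y = np.concatenate([c.response for c in curves])
    base = min(curves, key=lambda c: c.modulator_conc)
    lo, hi = math.log10(base.doses.min()), math.log10(base.doses.max())
    b_pos = [c.modulator_conc for c in curves if c.modulator_conc > 0]
    starts = []
    for lkb in np.linspace(math.log10(min(b_pos) / 3), math.log10(max(b_pos) * 3), n_starts):
        p = lmfit.Parameters()
        p.add("log_ec50", value=0.5 * (lo + hi), min=lo - 4, max=hi + 4)
        p.add("log_kb", value=float(lkb), min=lkb - 4, max=lkb + 4)
        p.add("log_alpha", value=0.3, min=-3, max=3)
        p.add("hill", value=fix_hill if fix_hill is not None else 1.0,
              min=0.3, max=5.0, vary=fix_hill is None)
        p.add("top", value=float(all_y.max()))
        p.add("bottom", value=float(all_y.min()))
        starts.append(p)
    res = _multistart(residual, starts)
    alpha = 10.0 ** res.params["log_alpha"].value
    alpha_se = _log_stderr(res.params["log_alpha"])
    no_shift = bool(np.isfinite(alpha_se) and abs(alpha - 1.0) < 2.0 * alpha_se)
    return AllostericFit(
        ec50=10.0 ** res.params["log_ec50"].value,
        kb=10.0 ** res.params["log_kb"].value,
        alpha=alpha,
        hill=float(res.params["hill"].value),
        top=float(res.params["top"].value),
        bottom=float(res.params["bottom"].value),
        ec50_stderr=_log_stderr(res.params["log_ec50"]),
        kb_stderr=_log_stderr(res.params["log_kb"]),
        alpha_stderr=alpha_se,
        rss=float(res.chisqr),
        no_shift_detected=no_shift,
    )


def cheng_prusoff(ic50: float, probe_conc: float, probe_kd: float) -> float:
    """Competition IC50 -> Ki: Ki = IC50 / (1 + [L]/KD).

    [L] is the tracer concentration and KD its affinity; for a competitive
    mechanism without ligand depletion this is exact.
    """
    for name, v in {"ic50": ic50, "probe_conc": probe_conc, "probe_kd": probe_kd}.items():
        if not v > 0:
            raise ValueError(f"{name} must be positive")
    return ic50 / (1.0 + probe_conc / probe_kd)


def ki_to_ic50(ki: float, probe_conc: float, probe_kd: float) -> float:
    """Inverse Cheng-Prusoff: IC50 = Ki * (1 + [L]/KD)."""
    for name, v in {"ki": ki, "probe_conc": probe_conc, "probe_kd": probe_kd}.items():
        if not v > 0:
            raise ValueError(f"{name} must be positive")
    return ki * (1.0 + probe_conc / probe_kd)
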