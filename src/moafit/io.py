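"""CSV readers/writers, run configuration and the pipeline orchestrator.

All interchange is long-format CSV (plate readers export delimited text).
Internally everything is molar, seconds and kelvin; other units are
converted at the reader boundary via a per-column unit declaration.
Concentration zero is encoded as a literal 0, never as a blank, so designed
zero-competitor wells are distinguishable from missing data.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cellular, equilibrium, kinetics, metrics, thermo

log = logging.getLogger("moafit")

__all__ = [
    "RunConfig",
    "TRACE_COLUMNS",
    "PLATE_COLUMNS",
    "THERMO_COLUMNS",
    "WASHOUT_COLUMNS",
    "read_traces",
    "write_traces",
    "read_plates",
    "read_thermo",
    "read_washout",
    "read_params",
    "write_result_table",
    "run_pipeline",
]

TRACE_COLUMNS = [
    "well", "time_s", "signal", "probe_conc_M", "competitor_conc_M",
    "modulator_conc_M", "temperature_K", "phase", "compound_id", "protein_id",
]
PLATE_COLUMNS = ["well", "role", "compound_id", "dose_M", "signal"]
THERMO_COLUMNS = ["compound_id", "protein_id", "temperature_K", "quantity", "value"]
WASHOUT_COLUMNS = ["compound_id", "incubation_time_h", "dose_M", "response_pct"]

_UNIT_FACTORS = {
    "M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9, "pM": 1e-12,
    "s": 1.0, "min": 60.0, "h": 3600.0,
}


@dataclass
class RunConfig:
    """Serializable options for a pipeline run; every field has a default."""

    seed: int = 0
    output_dir: str = "results"
    reference_washout_time_h: float = 72.0
    washout_mode: str = "ic50_ratio"
    fix_hill: float | None = None
    n_starts: int = 5
    thermo_model: str = "both"  # "linear" | "integrated" | "both"
    units: dict = field(default_factory=dict)  # column -> unit symbol
    inputs: dict = field(default_factory=dict)  # stage -> csv path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in required
             and c not in ("masked", "sd", "condition", "row", "col",
                           "modulator_conc_M", "protein_id", "incubation_time_h")]
    if extra:
        log.warning("%s: ignoring unknown column(s) %s", path, extra)


def _convert_units(df: pd.DataFrame, units: dict | None) -> pd.DataFrame:
    if not units:
        return df
    df = df.copy()
    for col, unit in units.items():
        if col not in df.columns:
            continue
        if unit not in _UNIT_FACTORS:
            raise ValueError(f"unknown unit {unit!r} for column {col!r}")
        df[col] = df[col].astype(float) * _UNIT_FACTORS[unit]
    return df


def read_traces(path: str | Path, units: dict | None = None) -> list[kinetics.KineticTrace]:
    """Read a kinetic trace table into per-well :class:`KineticTrace` objects.

    Wells are grouped by the ``well`` column; a ``phase`` column with values
    assoc/dissoc marks the chase boundary (first dissoc time).  Validation
    errors name the offending row.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TRACE_COLUMNS, path)
    df = _convert_units(df, units)
    neg = df.index[df["time_s"] < 0]
    if len(neg):
        raise ValueError(f"{path}: negative time_s at row {neg[0]}")
    traces = []
    for well, grp in df.groupby("well", sort=True):
        grp = grp.sort_values("time_s")
        chase = grp.loc[grp["phase"] == "dissoc", "time_s"]
        traces.append(
            kinetics.KineticTrace(
                time=grp["time_s"].to_numpy(float),
                signal=grp["signal"].to_numpy(float),
                probe_conc=float(grp["probe_conc_M"].iloc[0]),
                competitor_conc=float(grp["competitor_conc_M"].iloc[0]),
                modulator_conc=float(grp.get("modulator_conc_M", pd.Series([0.0])).iloc[0]),
                temperature=float(grp["temperature_K"].iloc[0]),
                chase_time=float(chase.iloc[0]) if len(chase) else None,
                compound_id=str(grp["compound_id"].iloc[0]),
                protein_id=str(grp["protein_id"].iloc[0]),
                well=str(well),
            )
        )
    return traces


def write_traces(traces: list[kinetics.KineticTrace], path: str | Path) -> None:
    """Write traces in the same schema :func:`read_traces` consumes."""
    rows = []
    for i, tr in enumerate(traces):
        well = tr.well or f"W{i + 1:03d}"
        for t, y in zip(tr.time, tr.signal):
            rows.append(
                {
                    "well": well, "time_s": t, "signal": y,
                    "probe_conc_M": tr.probe_conc,
                    "competitor_conc_M": tr.competitor_conc,
                    "modulator_conc_M": tr.modulator_conc,
                    "temperature_K": tr.temperature,
                    "phase": "dissoc" if (tr.chase_time is not None and t >= tr.chase_time)
                             else "assoc",
                    "compound_id": tr.compound_id, "protein_id": tr.protein_id,
                }
            )
    # %.17g keeps every float bit-exact through the text round trip
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_plates(path: str | Path, units: dict | None = None) -> pd.DataFrame:
    """Read and validate an endpoint plate table (one or more compounds)."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, PLATE_COLUMNS, path)
    df = _convert_units(df, units)
    bad = df.index[(df["role"] == "sample") & ~(df["dose_M"] > 0)]
    if len(bad):
        raise ValueError(f"{path}: non-positive dose_M in sample well at row {bad[0]}")
    return df


def read_thermo(path: str | Path, units: dict | None = None) -> dict:
    """Read a thermo table into {(compound, quantity): TemperatureSeries}."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, THERMO_COLUMNS, path)
    df = _convert_units(df, units)
    out = {}
    for (cid, quantity), grp in df.groupby(["compound_id", "quantity"], sort=True):
        if quantity not in ("KA", "kon", "koff"):
            raise ValueError(f"{path}: unknown quantity {quantity!r} for {cid}")
        out[(str(cid), str(quantity))] = thermo.TemperatureSeries(
            temperature=grp["temperature_K"].to_numpy(float),
            values=grp["value"].to_numpy(float),
            kind=str(quantity),
            sd=grp["sd"].to_numpy(float) if "sd" in grp and grp["sd"].notna().all() else None,
            compound_id=str(cid),
        )
    return out


def read_washout(path: str | Path, units: dict | None = None) -> dict:
    """Read washout dose-response data into {compound: {time_h: curve}}."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, WASHOUT_COLUMNS, path)
    df = _convert_units(df, units)
    if "masked" in df.columns:
        df = df[df["masked"].fillna(0).astype(int) == 0]
    out: dict[str, dict[float, equilibrium.NormalizedCurve]] = {}
    for (cid, t), grp in df.groupby(["compound_id", "incubation_time_h"], sort=True):
        out.setdefault(str(cid), {})[float(t)] = equilibrium.NormalizedCurve(
            doses=grp["dose_M"].to_numpy(float),
            response=grp["response_pct"].to_numpy(float),
            compound_id=str(cid),
        )
    return out


def read_params(path: str | Path) -> pd.DataFrame:
    """Read a tidy (compound_id, parameter, value) table, wide-pivoted."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["compound_id", "parameter", "value"], path)
    return df.pivot_table(index="compound_id", columns="parameter",
                          values="value", aggfunc="first")


def write_result_table(rows: list[dict], path: str | Path) -> pd.DataFrame:
    """Write tidy results, stable-sorted for diff-ability, and return them."""
    df = pd.DataFrame(rows)
    sort_cols = [c for c in ("compound_id", "protein_id", "condition", "parameter")
                 if c in df.columns]
    if sort_cols:
        df = df.sort_values(sort_cols, kind="stable").reset_index(drop=True)
    df.to_csv(path, index=False, float_format="%.17g")
    return df


def _probe_stage(cfg, rows, state):
    traces = read_traces(cfg.inputs["probe_traces"], cfg.units)
    probe = kinetics.fit_probe_kinetics(traces)
    state["probe"] = probe
    for name, value, sd in (
        ("k1", probe.k1, probe.k1_stderr),
        ("k2", probe.k2, probe.k2_stderr),
        ("KD_kin", probe.kd, float("nan")),
    ):
        rows.append({"stage": "probe", "compound_id": "probe",
                     "protein_id": probe.protein_id, "condition": probe.condition,
                     "parameter": name, "value": value, "sd": sd, "flag": ""})


def _kpca_stage(cfg, rows, state):
    probe = state.get("probe")
    if probe is None:
        raise RuntimeError("kPCA requires the probe stage")
    traces = read_traces(cfg.inputs["kpca_traces"], cfg.units)
    by_compound: dict[str, list] = {}
    for tr in traces:
        by_compound.setdefault(tr.compound_id, []).append(tr)
    panel = []
    for cid, fam in sorted(by_compound.items()):
        ck = kinetics.fit_kpca(fam, probe)
        panel.append(ck)
        flag = "koff_unreliable" if ck.koff_unreliable else ""
        for name, value, sd in (("kon", ck.kon, ck.kon_stderr),
                                ("koff", ck.koff, ck.koff_stderr),
                                ("residence_time_s", ck.residence_time, float("nan"))):
            rows.append({"stage": "kpca", "compound_id": cid,
                         "protein_id": ck.protein_id, "condition": ck.condition,
                         "parameter": name, "value": value, "sd": sd, "flag": flag})
    state["kinetics"] = panel


def _epca_stage(cfg, rows, state):
    plate = read_plates(cfg.inputs["epca_plates"], cfg.units)
    curves = equilibrium.normalize_plate_all(plate)
    meta = cfg.inputs.get("epca_probe", {"probe_conc_M": 1.5e-9, "probe_kd_M": 1.1e-9})
    for cid, curve in sorted(curves.items()):
        fit = equilibrium.fit_logistic4(curve, fix_hill=cfg.fix_hill)
        flag = "" if fit.determinable else "potency_not_determinable"
        ki = (equilibrium.cheng_prusoff(fit.ic50, meta["probe_conc_M"], meta["probe_kd_M"])
              if fit.determinable else float("nan"))
        for name, value in (("IC50", fit.ic50), ("pIC50", fit.pic50), ("Ki", ki)):
            rows.append({"stage": "epca", "compound_id": cid, "protein_id": "",
                         "condition": "", "parameter": name, "value": value,
                         "sd": float("nan"), "flag": flag})


def _thermo_stage(cfg, rows, state):
    series = read_thermo(cfg.inputs["thermo"], cfg.units)
    models = ("linear", "integrated") if cfg.thermo_model == "both" else (cfg.thermo_model,)
    for (cid, quantity), s in sorted(series.items()):
        for model in models:
            if quantity == "KA":
                fit = (thermo.vant_hoff_linear(s) if model == "linear"
                       else thermo.vant_hoff_integrated(s))
            else:
                fit = (thermo.eyring_linear(s) if model == "linear"
                       else thermo.eyring_nonlinear(s))
            for name, value in (("dH", fit.dh), ("dS", fit.ds),
                                ("dCp", fit.dcp), ("dG_ref", fit.dg_ref)):
                rows.append({"stage": "thermo", "compound_id": cid, "protein_id": "",
                             "condition": f"{quantity}/{model}", "parameter": name,
                             "value": value, "sd": float("nan"), "flag": ""})


def _washout_stage(cfg, rows, state):
    data = read_washout(cfg.inputs["washout"], cfg.units)
    for cid, curves in sorted(data.items()):
        series = cellular.washout_series(
            curves, cfg.reference_washout_time_h, mode=cfg.washout_mode,
            compound_id=cid, fix_hill=cfg.fix_hill,
        )
        summary = cellular.fit_one_phase_decay(series)
        auc = cellular.washout_auc(series)
        flag = "" if summary.t_half_determinable else "t_half_not_determinable"
        rows.append({"stage": "washout", "compound_id": cid, "protein_id": "",
                     "condition": "", "parameter": "t_half_h", "value": summary.t_half,
                     "sd": float("nan"), "flag": flag})
        rows.append({"stage": "washout", "compound_id": cid, "protein_id": "",
                     "condition": "", "parameter": "auc", "value": auc,
                     "sd": float("nan"), "flag": ""})


def _correlation_stage(cfg, rows, state):
    df = pd.DataFrame(rows)
    if df.empty:
        raise RuntimeError("no upstream results to correlate")
    wide = df.pivot_table(index="compound_id", columns="parameter",
                          values="value", aggfunc="first")
    wide = wide.drop(index=[i for i in ("probe",) if i in wide.index])
    cm = metrics.correlation_matrix(wide, method="spearman")
    state["correlation"] = cm
    for a in cm.matrix.index:
        for b in cm.matrix.columns:
            rows.append({"stage": "correlation", "compound_id": "", "protein_id": "",
                         "condition": f"{a}|{b}", "parameter": "spearman_rho",
                         "value": cm.matrix.loc[a, b],
                         "sd": float("nan"), "flag": ""})


_STAGES = [
    ("probe", "probe_traces", _probe_stage),
    ("kpca", "kpca_traces", _kpca_stage),
    ("epca", "epca_plates", _epca_stage),
    ("thermo", "thermo", _thermo_stage),
    ("washout", "washout", _washout_stage),
]


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Run every stage whose inputs are configured, in dependency order.

    Stage failures are isolated: the failing stage is skipped with a logged
    reason (recorded in the result table) and downstream stages that do not
    depend on it still run.  The result is a tidy table with stage
    provenance and the config digest, written to ``<output_dir>/results.csv``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows: list[dict] = []
    state: dict = {}
    ran_any = False
    for stage, input_key, fn in _STAGES:
        if input_key not in config.inputs:
            continue
        ran_any = True
        try:
            fn(config, rows, state)
            log.info("stage %s complete", stage)
        except Exception as exc:
            log.warning("stage %s skipped: %s", stage, exc)
            rows.append({"stage": stage, "compound_id": "", "protein_id": "",
                         "condition": "", "parameter": "stage_skipped",
                         "value": float("nan"), "sd": float("nan"), "flag": str(exc)})
    if not ran_any:
        raise ValueError("no stage inputs configured")
    if sum(1 for r in rows if r["parameter"] not in ("stage_skipped",)) > 0:
        try:
            _correlation_stage(config, rows, state)
        except Exception as exc:
            log.warning("correlation skipped: %s", exc)
    digest = config.digest()
    for r in rows:
        r["config_digest"] = digest
    return write_result_table(rows, outdir / "results.csv")
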