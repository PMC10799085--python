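"""Compound-level efficiency metrics and cross-parameter correlation.

Efficiency metrics normalize a potency-like quantity by molecular size
(heavy-atom count HA): ligand efficiency LE = 1.4*pIC50/HA (kcal/mol per
heavy atom, with 1.4 kcal/mol per log unit at ~298 K), kinetic efficiency
KE = residence time/HA (s per heavy atom) and enthalpic efficiency
EE = dH/HA.  The correlation matrix across fitted parameters uses
pairwise-complete observations and average-rank Spearman coefficients,
implemented as explicit rank-then-Pearson so tie handling is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "CompoundRecord",
    "EfficiencyMetrics",
    "CorrelationMatrix",
    "FoldChange",
    "ligand_efficiency",
    "kinetic_efficiency",
    "enthalpic_efficiency",
    "efficiency_table",
    "radar_table",
    "max_preincubation_shift",
    "correlation_matrix",
    "fold_change",
]


@dataclass(frozen=True)
class CompoundRecord:
    """Static metadata for one compound."""

    compound_id: str
    heavy_atoms: int
    scaffold_class: str = ""
    salt_form: bool = False

    def __post_init__(self) -> None:
        if self.heavy_atoms < 1:
            raise ValueError("heavy-atom count must be >= 1")


@dataclass
class EfficiencyMetrics:
    """Size-normalized efficiency metrics for one compound (NaN = undefined)."""

    compound_id: str
    le: float = float("nan")  # kcal/mol per heavy atom
    ke: float = float("nan")  # s per heavy atom
    ee: float = float("nan")  # J/mol per heavy atom
    ke_unreliable: bool = False


@dataclass
class CorrelationMatrix:
    """Pairwise-complete correlation coefficients between parameters."""

    matrix: pd.DataFrame
    n: pd.DataFrame  # complete observations per pair
    method: str


@dataclass(frozen=True)
class FoldChange:
    """Ratio of two positive quantities with the conventional fold label."""

    ratio: float
    label: str


def _check_ha(heavy_atoms: int) -> None:
    if heavy_atoms < 1:
        raise ValueError("heavy-atom count must be >= 1")


def ligand_efficiency(p_value: float, heavy_atoms: int) -> float:
    """LE = 1.4 * pIC50 (or pKi) / HA, in kcal/mol per heavy atom."""
    _check_ha(heavy_atoms)
    if p_value is None or not np.isfinite(p_value):
        return float("nan")
    return 1.4 * p_value / heavy_atoms


def kinetic_efficiency(residence_time_s: float, heavy_atoms: int) -> float:
    """KE = residence time / HA, in seconds per heavy atom."""
    _check_ha(heavy_atoms)
    if residence_time_s is None or not np.isfinite(residence_time_s):
        return float("nan")
    return residence_time_s / heavy_atoms


def enthalpic_efficiency(dh: float, heavy_atoms: int) -> float:
    """EE = binding enthalpy / HA, in J/mol per heavy atom."""
    _check_ha(heavy_atoms)
    if dh is None or not np.isfinite(dh):
        return float("nan")
    return dh / heavy_atoms


def efficiency_table(records: dict[str, CompoundRecord], params: pd.DataFrame) -> pd.DataFrame:
    """Per-compound efficiency metrics from a tidy parameter table.

    ``params`` is indexed by compound_id with any of the columns ``pic50``
    (or ``pki``), ``residence_time_s``, ``dh``, ``koff_unreliable``.
    """
    rows = []
    for cid, rec in records.items():
        row = params.loc[cid] if cid in params.index else pd.Series(dtype=float)
        p = row.get("pic50", row.get("pki", float("nan")))
        rows.append(
            {
                "compound_id": cid,
                "le": ligand_efficiency(p, rec.heavy_atoms),
                "ke": kinetic_efficiency(row.get("residence_time_s", float("nan")),
                                         rec.heavy_atoms),
                "ee": enthalpic_efficiency(row.get("dh", float("nan")), rec.heavy_atoms),
                "ke_unreliable": bool(row.get("koff_unreliable", False)),
            }
        )
    return pd.DataFrame(rows).set_index("compound_id")


def radar_table(metrics: pd.DataFrame) -> pd.DataFrame:
    """Normalize each metric column to the panel maximum magnitude.

    The best compound on each axis maps to 1.0 (radar-plot convention);
    normalization is idempotent.  Magnitudes are used so that favorable
    negative enthalpies rank by size.
    """
    out = metrics.select_dtypes(include=[np.number]).abs()
    maxima = out.max(axis=0)
    return out / maxima.replace(0, np.nan)


def max_preincubation_shift(pic50_by_time: dict[float, float]) -> float:
    """Maximum pIC50 gain over the no-pre-incubation baseline.

    ``pic50_by_time`` maps pre-incubation time (minutes) to pIC50; time 0
    must be present.  Returns max over t > 0 of pIC50(t) - pIC50(0), which
    may be negative and is reported as-is (short pre-incubations sometimes
    shift more than long ones).  NaN when no later time is fittable.
    """
    if 0 not in pic50_by_time and 0.0 not in pic50_by_time:
        raise ValueError("baseline pIC50 at time 0 is required")
    base = pic50_by_time.get(0, pic50_by_time.get(0.0))
    if base is None or not np.isfinite(base):
        raise ValueError("baseline pIC50 at time 0 is required")
    later = [v for t, v in pic50_by_time.items() if t > 0 and np.isfinite(v)]
    if not later:
        return float("nan")
    return max(later) - base


def _rank_then_pearson(x: np.ndarray, y: np.ndarray) -> float:
    rx, ry = rankdata(x, method="average"), rankdata(y, method="average")
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def correlation_matrix(
    table: pd.DataFrame,
    method: str = "spearman",
    min_pairs: int = 3,
    listwise: bool = False,
) -> CorrelationMatrix:
    """Pairwise-complete correlation matrix over a compounds x parameters table.

    Spearman coefficients use average ranks for ties, computed explicitly as
    rank-then-Pearson.  Cells with fewer than ``min_pairs`` complete pairs,
    or with a constant column, are NaN.  ``listwise=True`` first drops every
    row with any missing value.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    df = table.select_dtypes(include=[np.number])
    if listwise:
        df = df.dropna(axis=0, how="any")
    cols = list(df.columns)
    k = len(cols)
    mat = np.full((k, k), np.nan)
    npairs = np.zeros((k, k), dtype=int)
    corr = _rank_then_pearson if method == "spearman" else _pearson
    for i in range(k):
        for j in range(i, k):
            xy = df[[cols[i], cols[j]]].dropna()
            npairs[i, j] = npairs[j, i] = len(xy)
            if len(xy) < min_pairs:
                continue
            x, y = xy.iloc[:, 0].to_numpy(float), xy.iloc[:, 1].to_numpy(float)
            if i == j:
                mat[i, i] = 1.0 if not np.all(x == x[0]) else np.nan
            else:
                mat[i, j] = mat[j, i] = corr(x, y)
    return CorrelationMatrix(
        matrix=pd.DataFrame(mat, index=cols, columns=cols),
        n=pd.DataFrame(npairs, index=cols, columns=cols),
        method=method,
    )


_FOLD_WORDS = {
    1: "onefold", 2: "twofold", 3: "threefold", 4: "fourfold", 5: "fivefold",
    6: "sixfold", 7: "sevenfold", 8: "eightfold", 9: "ninefold", 10: "tenfold",
}


def fold_change(value_a: float, value_b: float) -> FoldChange:
    """Ratio a/b with a nearest-integer fold label (e.g. 4.2 -> "fourfold")."""
    if not (value_a > 0 and value_b > 0):
        raise ValueError("fold change needs positive values")
    ratio = value_a / value_b
    n = max(round(ratio), 1)
    label = _FOLD_WORDS.get(n, f"{n}-fold")
    return FoldChange(ratio=ratio, label=label)
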