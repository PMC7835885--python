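"""Data processing ahead of network inference.

Biomarker panels carry asymmetric, heavy-tailed marginals, so location and
dispersion are summarized robustly: each variable is centered on its median
and scaled by its range (median-range normalization). Gross outliers are
screened per variable with a robust-fit, FDR-controlled procedure (ROUT at
rate Q); normality is screened with Shapiro–Wilk to justify rank-based
correlation downstream; and the standard clinically derived indices (MAP,
BMI, HOMA, Castelli ratios, differential leukocyte proportions, ...) can be
appended from their parent variables.

Flagged outliers become missing *cells*, never dropped subjects, so pairwise
correlations keep every untouched observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable


@dataclass
class NormalizationParams:
    """Per-variable median / max / min, sufficient to invert the transform."""

    table: pd.DataFrame  # index = variable, columns = median, max, min

    def invert(self, normalized: pd.DataFrame) -> pd.DataFrame:
        t = self.table
        return normalized * (t["max"] - t["min"]) + t["median"]


@dataclass
class RoutConfig:
    """Q is the target maximum false-discovery rate of outlier calls."""

    q: float = 0.01

    def __post_init__(self):
        if not 0.0 < self.q <= 1.0:
            raise ValueError("Q must be in (0, 1]")


@dataclass
class ScreenReport:
    """Outcome of an outlier and/or normality screen."""

    flagged: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["subject", "variable", "value", "p_value"]
        )
    )
    shapiro: Optional[pd.DataFrame] = None  # variable, n, W, p, testable
    skipped: List[str] = field(default_factory=list)
    action: str = "kept"


def normalize_median_range(table: CohortTable) -> tuple:
    """x_i = (V_i - median) / (max - min), per variable.

    Missing entries propagate; ranks (hence Spearman correlations) are
    unchanged. Constant variables have no defined normalization and raise.
    """
    values = table.values
    med = values.median(axis=0, skipna=True)
    vmax = values.max(axis=0, skipna=True)
    vmin = values.min(axis=0, skipna=True)
    span = vmax - vmin
    constant = span[(span == 0) | span.isna()].index.tolist()
    if constant:
        raise ValueError(f"constant variable(s), normalization undefined: {constant}")
    normalized = (values - med) / span
    params = NormalizationParams(
        pd.DataFrame({"median": med, "max": vmax, "min": vmin})
    )
    return CohortTable(normalized, table.meta.copy()), params


def _bh_reject(pvals: np.ndarray, q: float) -> np.ndarray:
    """Benjamini–Hochberg rejection mask at level q."""
    n = pvals.size
    order = np.argsort(pvals)
    ranked = pvals[order]
    thresh = q * (np.arange(1, n + 1)) / n
    below = ranked <= thresh
    mask = np.zeros(n, dtype=bool)
    if below.any():
        kmax = np.max(np.flatnonzero(below))
        mask[order[: kmax + 1]] = True
    return mask


def rout_screen(table: CohortTable, cfg: RoutConfig | float = 0.01) -> tuple:
    """ROUT-style robust outlier screen per variable at FDR level Q.

    Per column: robust location = median; robust scale (RSDR) = 68.27th
    percentile of absolute residuals with an n/(n-1) small-sample correction;
    residual/RSDR referred to a t distribution with n-1 df for a two-sided
    p-value; Benjamini–Hochberg control at Q flags the outliers. Flagged
    cells are set to missing. Columns with < 10 observations or zero robust
    scale are skipped and listed in the report.
    """
    if not isinstance(cfg, RoutConfig):
        cfg = RoutConfig(float(cfg))
    values = table.values.copy()
    records = []
    skipped = []
    for col in values.columns:
        x = values[col].dropna()
        n = len(x)
        if n < 10:
            skipped.append(col)
            continue
        resid = x - x.median()
        rsdr = np.percentile(np.abs(resid), 68.27) * n / (n - 1)
        if rsdr == 0:
            skipped.append(col)
            continue
        t = (resid / rsdr).to_numpy()
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
        mask = _bh_reject(p, cfg.q)
        for subject, val, pv in zip(x.index[mask], x[mask], p[mask]):
            values.loc[subject, col] = np.nan
            records.append(
                {"subject": subject, "variable": col, "value": val, "p_value": pv}
            )
    report = ScreenReport(
        flagged=pd.DataFrame(
            records, columns=["subject", "variable", "value", "p_value"]
        ),
        skipped=skipped,
        action="removed" if records else "kept",
    )
    return CohortTable(values, table.meta.copy()), report


def shapiro_screen(table: CohortTable) -> ScreenReport:
    """Shapiro–Wilk W and p per variable; no data modification.

    Variables with fewer than 3 observations are marked untestable. The
    report motivates rank-based correlation; nothing is removed.
    """
    rows = []
    for col in table.values.columns:
        x = table.values[col].dropna().to_numpy()
        n = x.size
        if n < 3 or np.ptp(x) == 0:
            rows.append({"variable": col, "n": n, "W": np.nan, "p": np.nan, "testable": False})
            continue
        res = stats.shapiro(x)
        rows.append(
            {"variable": col, "n": n, "W": float(res.statistic), "p": float(res.pvalue), "testable": True}
        )
    return ScreenReport(shapiro=pd.DataFrame(rows), action="kept")


# Derived clinical indices: name -> (parent short names, function, id, units).
# Glucose enters the HOMA formulas in mmol/L (mg/dL / 18.016); insulin in
# mIU/L. 'Lean' (bioimpedance fat-free mass) backs the fat-free mass
# proportion. Heights are measured in cm and converted to meters where needed.
_GLUC_MGDL_PER_MMOL = 18.016

_DERIVED = {
    "MAP": (("SBP", "DBP"), lambda d: (d["SBP"] + 2 * d["DBP"]) / 3.0, 101, "mmHg"),
    "BMI": (("Wt", "Ht"), lambda d: d["Wt"] / (d["Ht"] / 100.0) ** 2, 102, "kg/m^2"),
    "BFp": (("BF", "Wt"), lambda d: 100.0 * d["BF"] / d["Wt"], 103, "%"),
    "FFMp": (("Lean", "Wt"), lambda d: 100.0 * d["Lean"] / d["Wt"], 104, "%"),
    "SMMp": (("SMM", "Wt"), lambda d: 100.0 * d["SMM"] / d["Wt"], 107, "%"),
    "TBWp": (("TBW", "Wt"), lambda d: 100.0 * d["TBW"] / d["Wt"], 108, "%"),
    "ECWp": (("ECW", "TBW"), lambda d: 100.0 * d["ECW"] / d["TBW"], 109, "%"),
    "ICWp": (("ICW", "TBW"), lambda d: 100.0 * d["ICW"] / d["TBW"], 110, "%"),
    "Neup": (("Neut", "Leuk"), lambda d: 100.0 * d["Neut"] / d["Leuk"], 111, "%"),
    "Lymp": (("Lymph", "Leuk"), lambda d: 100.0 * d["Lymph"] / d["Leuk"], 112, "%"),
    "Monop": (("Mono", "Leuk"), lambda d: 100.0 * d["Mono"] / d["Leuk"], 113, "%"),
    "Eosp": (("Eos", "Leuk"), lambda d: 100.0 * d["Eos"] / d["Leuk"], 114, "%"),
    "Basop": (("Baso", "Leuk"), lambda d: 100.0 * d["Baso"] / d["Leuk"], 115, "%"),
    "Cast1": (("Chol", "HDL"), lambda d: d["Chol"] / d["HDL"], 116, "ratio"),
    "Cast2": (("LDL", "HDL"), lambda d: d["LDL"] / d["HDL"], 117, "ratio"),
    "HOMA-IR": (
        ("Gluc", "Ins"),
        lambda d: (d["Gluc"] / _GLUC_MGDL_PER_MMOL) * d["Ins"] / 22.5,
        118,
        "mmol/L * mIU/L",
    ),
    "HOMA-B": (
        ("Gluc", "Ins"),
        lambda d: 20.0 * d["Ins"] / (d["Gluc"] / _GLUC_MGDL_PER_MMOL - 3.5),
        119,
        "mIU/L / (mmol/L)",
    ),
    "BUN": (("Urea",), lambda d: d["Urea"] / 2.14, 120, "mg/dL"),
    "rel": (("FEV1", "FVC"), lambda d: d["FEV1"] / d["FVC"], 123, "ratio"),
}

DERIVED_VARIABLES = tuple(_DERIVED)


def derive_variables(table: CohortTable, requested: Sequence[str]) -> CohortTable:
    """Append requested derived variables; parents are never mutated.

    A missing parent value, a zero denominator, or a nonpositive HOMA-beta
    denominator yields a missing derived cell. Unknown names and absent
    parent columns raise.
    """
    unknown = [r for r in requested if r not in _DERIVED]
    if unknown:
        raise ValueError(f"unknown derived variable(s): {unknown}")
    values = table.values.copy()
    meta_rows = []
    for name in requested:
        parents, fn, vid, units = _DERIVED[name]
        missing = [p for p in parents if p not in values.columns]
        if missing:
            raise ValueError(f"derived {name!r} requires missing parent(s): {missing}")
        with np.errstate(divide="ignore", invalid="ignore"):
            col = fn(values)
        col = col.replace([np.inf, -np.inf], np.nan)
        if name == "HOMA-B":
            denom = values["Gluc"] / _GLUC_MGDL_PER_MMOL - 3.5
            col = col.mask(denom <= 0)
        values[name] = col
        meta_rows.append(
            {"id": vid, "short_name": name, "category": "Derived", "units": units}
        )
    meta = pd.concat([table.meta, pd.DataFrame(meta_rows)], ignore_index=True)
    if meta["id"].duplicated().any():
        # keep ids unique if the cohort already uses the 100+ range
        dup = meta["id"].duplicated(keep="first")
        meta.loc[dup, "id"] = meta["id"].max() + np.arange(1, dup.sum() + 1)
    return CohortTable(values, meta)
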