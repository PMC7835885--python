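"""Synthetic biomarker cohorts with planted correlation blocks.

Real biomarker panels show asymmetric, leptokurtic marginals and a
block-structured inter-variable correlation reflecting functional systems
(body size, immune cells, lipids, ...). The generator emulates exactly that:
a Gaussian copula whose latent correlation matrix is block-constant
(``within_rho`` inside each planted block, ``between_rho`` across blocks),
pushed through lognormal / gamma / normal marginals by probability-integral
transform. The Gaussian copula gives a closed-form population Spearman,
rho_S = (6/pi) * asin(rho_latent / 2), which downstream tests lean on.

Rare gross outliers (transcription/measurement errors) are injected after the
marginal transform as multiples of the column IQR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .communities import Partition


@dataclass(frozen=True)
class BlockSpec:
    """One planted functional cluster of variables."""

    label: str
    size: int
    within_rho: float

    def __post_init__(self):
        if self.size < 1:
            raise ValueError(f"block {self.label!r}: size must be >= 1")
        if not 0.0 <= self.within_rho < 1.0:
            raise ValueError(f"block {self.label!r}: within_rho must be in [0, 1)")


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for one synthetic cohort.

    ``marginal_params`` optionally gives per-variable (shape, scale) pairs for
    the chosen family; defaults are lognormal(sigma=0.6), gamma(k=3, theta=1),
    normal(0, 1). ``outlier_magnitude`` is in multiples of the column IQR.
    """

    n_subjects: int
    blocks: Sequence[BlockSpec]
    between_rho: float = 0.0
    marginal_family: str = "lognormal"
    marginal_params: Optional[Sequence[tuple]] = None
    outlier_rate: float = 0.0
    outlier_magnitude: float = 5.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if not self.blocks:
            raise ValueError("at least one block required")
        if not 0.0 <= self.between_rho < 1.0:
            raise ValueError("between_rho must be in [0, 1)")
        min_within = min(b.within_rho for b in self.blocks)
        if self.between_rho > 0 and self.between_rho >= min_within:
            raise ValueError("between_rho must be smaller than every within_rho")
        if self.marginal_family not in ("lognormal", "gamma", "normal"):
            raise ValueError(f"unknown marginal family {self.marginal_family!r}")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def n_variables(self) -> int:
        return sum(b.size for b in self.blocks)

    def latent_correlation(self) -> np.ndarray:
        """Block-constant latent Gaussian correlation matrix."""
        p = self.n_variables
        R = np.full((p, p), self.between_rho)
        start = 0
        for b in self.blocks:
            R[start : start + b.size, start : start + b.size] = b.within_rho
            start += b.size
        np.fill_diagonal(R, 1.0)
        return R


@dataclass
class CohortTable:
    """Subjects x variables biomarker table with per-variable metadata.

    ``values``: DataFrame, one row per subject, columns = variable short
    names, NaN for missing entries. ``meta``: DataFrame with columns
    id, short_name, category, units (ids unique).
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        if self.values.shape[1] != len(self.meta):
            raise ValueError("column count does not match metadata length")
        if self.meta["id"].duplicated().any():
            raise ValueError("variable ids must be unique")
        if list(self.values.columns) != list(self.meta["short_name"]):
            raise ValueError("values columns must equal meta short_name order")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def variables(self) -> List[str]:
        return list(self.values.columns)

    def copy(self) -> "CohortTable":
        return CohortTable(self.values.copy(), self.meta.copy())

    def to_csv(self, values_path, meta_path) -> None:
        self.values.to_csv(values_path, index_label="subject")
        self.meta.to_csv(meta_path, index=False)

    @classmethod
    def from_csv(cls, values_path, meta_path=None) -> "CohortTable":
        values = pd.read_csv(values_path, index_col="subject")
        if meta_path is not None:
            meta = pd.read_csv(meta_path)
        else:
            meta = pd.DataFrame(
                {
                    "id": np.arange(1, values.shape[1] + 1),
                    "short_name": values.columns,
                    "category": "unknown",
                    "units": "a.u.",
                }
            )
        return cls(values, meta)


def spearman_of_latent(rho_latent: float) -> float:
    """Population Spearman correlation implied by a Gaussian copula."""
    return 6.0 / np.pi * np.arcsin(rho_latent / 2.0)


_DEFAULT_PARAMS = {"lognormal": (0.6, 1.0), "gamma": (3.0, 1.0), "normal": (0.0, 1.0)}


def _marginal_ppf(family: str, shape: float, scale: float, u: np.ndarray) -> np.ndarray:
    if family == "lognormal":
        return stats.lognorm.ppf(u, s=shape, scale=scale)
    if family == "gamma":
        return stats.gamma.ppf(u, a=shape, scale=scale)
    return stats.norm.ppf(u, loc=shape, scale=scale)


def generate_cohort(spec: CohortSpec) -> tuple:
    """Draw one cohort; returns (CohortTable, planted Partition).

    Values come from a latent multivariate normal with the block-constant
    correlation of ``spec``, mapped to uniforms by the normal CDF and then to
    the requested marginals by their quantile functions. Fully reproducible
    from ``spec.seed``.
    """
    R = spec.latent_correlation()
    eig = np.linalg.eigvalsh(R)
    if eig[0] <= 1e-12:
        raise ValueError(
            f"latent correlation matrix is not positive definite "
            f"(smallest eigenvalue {eig[0]:.3e})"
        )
    if spec.outlier_rate > 0 and spec.n_subjects < 10:
        warnings.warn("outlier injection with fewer than 10 subjects is unreliable")
    p = spec.n_variables
    rng = np.random.default_rng(spec.seed)
    L = np.linalg.cholesky(R)
    z = rng.standard_normal((spec.n_subjects, p)) @ L.T
    u = stats.norm.cdf(z)
    params = spec.marginal_params
    if params is None:
        params = [_DEFAULT_PARAMS[spec.marginal_family]] * p
    if len(params) != p:
        raise ValueError("marginal_params length must equal number of variables")
    X = np.column_stack(
        [
            _marginal_ppf(spec.marginal_family, sh, sc, u[:, j])
            for j, (sh, sc) in enumerate(params)
        ]
    )
    names, categories, membership = [], [], {}
    planted_groups = []
    for bi, b in enumerate(spec.blocks, start=1):
        group = []
        for k in range(1, b.size + 1):
            name = f"{b.label}_{k}"
            names.append(name)
            categories.append(b.label)
            group.append(name)
        planted_groups.append(group)
    values = pd.DataFrame(X, columns=names, index=pd.RangeIndex(1, spec.n_subjects + 1, name="subject"))
    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values = values.mask(mask)
    meta = pd.DataFrame(
        {
            "id": np.arange(1, p + 1),
            "short_name": names,
            "category": categories,
            "units": "a.u.",
        }
    )
    table = CohortTable(values, meta)
    if spec.outlier_rate > 0:
        table, _ = inject_outliers(
            table,
            rate=spec.outlier_rate,
            magnitude=spec.outlier_magnitude,
            seed=int(rng.integers(2**31 - 1)),
        )
    for label, group in enumerate(planted_groups, start=1):
        for name in group:
            membership[name] = label
    planted = Partition(membership, None, "planted", spec.seed)
    return table, planted


def inject_outliers(
    table: CohortTable, rate: float, magnitude: float, seed: int | None = None
) -> tuple:
    """Displace a Bernoulli(rate) subset of cells by magnitude x column IQR.

    The displacement sign is random per cell. Columns with zero IQR are
    skipped and reported in the log. Returns (new table, log DataFrame with
    columns subject, variable, original, displaced).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    values = table.values.copy()
    records = []
    skipped = []
    if rate > 0:
        for col in values.columns:
            x = values[col]
            finite = x.dropna()
            if finite.empty:
                skipped.append(col)
                continue
            iqr = float(finite.quantile(0.75) - finite.quantile(0.25))
            if iqr == 0:
                skipped.append(col)
                continue
            hit = rng.random(len(x)) < rate
            hit &= x.notna().to_numpy()
            signs = rng.choice([-1.0, 1.0], size=len(x))
            for pos in np.flatnonzero(hit):
                subject = x.index[pos]
                orig = x.iloc[pos]
                new = orig + signs[pos] * magnitude * iqr
                values.loc[subject, col] = new
                records.append(
                    {"subject": subject, "variable": col, "original": orig, "displaced": new}
                )
    log = pd.DataFrame(records, columns=["subject", "variable", "original", "displaced"])
    log.attrs["skipped_columns"] = skipped
    return CohortTable(values, table.meta.copy()), log
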