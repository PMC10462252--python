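"""Metabolite preprocessing.

Raw relative abundances are log-transformed toward normality, remaining
outliers are winsorized at mean ± 3 SD, and two branches diverge: the
network branch regresses out batch, age, sex and BMI and learns the
graph on the residuals, while the survival branch z-scores the columns
so Cox coefficients are per-SD log hazard ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PLATFORMS = ("AAA", "BONS", "lipid")


@dataclass(frozen=True)
class MetaboliteMatrix:
    """Samples × metabolites table with platform-block and exogeneity
    annotations and a record of the transforms applied, in order."""

    data: pd.DataFrame
    platform: dict = field(default_factory=dict)
    exogenous: frozenset = frozenset()
    transforms: tuple = ()

    def __post_init__(self):
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicated sample identifier {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicated metabolite identifier {dup!r}")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def metabolite_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def with_data(self, data: pd.DataFrame, transform: str) -> "MetaboliteMatrix":
        return replace(self, data=data,
                       transforms=self.transforms + (transform,))

    def platform_columns(self, label: str) -> list:
        return [m for m in self.data.columns if self.platform.get(m) == label]


def log_transform(m: MetaboliteMatrix) -> MetaboliteMatrix:
    """Natural log, elementwise.  Raises on nonpositive abundances,
    naming the offending metabolite and sample."""
    bad = m.data <= 0
    if bad.to_numpy().any():
        col = m.data.columns[bad.any(axis=0)][0]
        row = m.data.index[bad[col]][0]
        raise ValueError(
            f"nonpositive value for metabolite {col!r} in sample {row!r}; "
            "log transform requires positive relative abundances")
    return m.with_data(np.log(m.data), "log")


def winsorize(m: MetaboliteMatrix, k: float = 3.0) -> MetaboliteMatrix:
    """Shrink values beyond mean ± k·SD to the cutoff, per column.

    Mean and SD are computed once from the input column; zero-variance
    columns are left unchanged with a logged warning.
    """
    if k <= 0:
        raise ValueError(f"winsorization cutoff must be positive, got {k}")
    out = m.data.copy()
    mu = out.mean(axis=0)
    sd = out.std(axis=0, ddof=1)
    flat = sd[sd == 0].index
    for col in flat:
        logger.warning("zero-variance column %r left unchanged by "
                       "winsorization", col)
    lo, hi = mu - k * sd, mu + k * sd
    lo[flat], hi[flat] = -np.inf, np.inf
    out = out.clip(lower=lo, upper=hi, axis=1)
    return m.with_data(out, f"winsorize(k={k:g})")


def _design_matrix(covariates: pd.DataFrame,
                   which: Sequence[str]) -> np.ndarray:
    parts = [np.ones((len(covariates), 1))]
    for name in which:
        col = covariates[name]
        if col.dtype == object or str(col.dtype) == "category" \
                or name == "batch":
            dummies = pd.get_dummies(col, prefix=name, drop_first=True)
            parts.append(dummies.to_numpy(dtype=float))
        else:
            parts.append(col.to_numpy(dtype=float)[:, None])
    return np.hstack(parts)


def residualize(m: MetaboliteMatrix, covariates: pd.DataFrame,
                which: Sequence[str] = ("batch", "age", "sex", "bmi"),
                ) -> MetaboliteMatrix:
    """Replace each column by its OLS residuals on an intercept plus the
    named covariates (batch entered as indicator contrasts)."""
    missing = [c for c in which if c not in covariates.columns]
    if missing:
        raise KeyError(f"covariates not found: {missing}")
    cov = covariates.loc[m.data.index]
    if cov.isna().to_numpy().any():
        raise ValueError("covariates contain missing values")
    X = _design_matrix(cov, which)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariate design matrix")
    Y = m.data.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = pd.DataFrame(resid, index=m.data.index, columns=m.data.columns)
    return m.with_data(out, f"residualize({','.join(which)})")


def standardize(m: MetaboliteMatrix) -> MetaboliteMatrix:
    """Z-score each column (mean 0, SD 1), so downstream Cox effect
    sizes are per-SD log hazard ratios."""
    sd = m.data.std(axis=0, ddof=1)
    if (sd == 0).any():
        col = sd[sd == 0].index[0]
        raise ValueError(f"zero-variance column {col!r} cannot be "
                         "standardized")
    out = (m.data - m.data.mean(axis=0)) / sd
    return m.with_data(out, "standardize")


def drop_incomplete(m: MetaboliteMatrix) -> MetaboliteMatrix:
    """Complete-case filter: drop samples with any missing metabolite,
    logging the count removed."""
    mask = m.data.notna().all(axis=1)
    n_drop = int((~mask).sum())
    if n_drop:
        logger.info("complete-case filter removed %d of %d samples",
                    n_drop, len(m.data))
    return m.with_data(m.data.loc[mask], f"complete_case(-{n_drop})")
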