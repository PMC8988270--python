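"""Covariate adjustment: remove linear age and sex effects from item scores.

Each item is regressed on intercept + age + sex by ordinary least squares and
the residuals are carried forward as the network input. By default each group
is residualized within its own rows (``scope="per_group"``); ``"pooled"``
fits one regression across the full sample, which is the relevant scope when
comparing per-group residual means descriptively.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EstimationError
from .io import CohortTable

logger = logging.getLogger(__name__)


@dataclass
class ResidualMatrix:
    """Item scores with linear age/sex effects removed; group labels carried."""

    values: np.ndarray
    group: np.ndarray
    item_names: list
    scope: str = "per_group"

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def for_group(self, g) -> "ResidualMatrix":
        mask = self.group == g
        return ResidualMatrix(self.values[mask], self.group[mask], self.item_names, self.scope)

    def group_means(self) -> pd.DataFrame:
        """Descriptive per-group residual means (one row per group)."""
        df = pd.DataFrame(self.values, columns=self.item_names)
        df["group"] = self.group
        return df.groupby("group", sort=False).mean()


def _ols_residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _design(age: np.ndarray, sex: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(age)]
    for name, v in (("age", age), ("sex", sex.astype(float))):
        if np.ptp(v) == 0:
            logger.info("residualize: covariate %r is constant; dropped from design", name)
        else:
            cols.append(v)
    return np.column_stack(cols)


def residualize_items(cohort: CohortTable, scope: str = "per_group") -> ResidualMatrix:
    """OLS-residualize every item on intercept + age + sex.

    Constant covariates are dropped from the design (the residual then
    reduces to the deviation from the item mean). Raises
    :class:`EstimationError` when a regression sample is smaller than its
    design's column count.
    """
    if scope not in ("per_group", "pooled"):
        raise ValueError("scope must be 'per_group' or 'pooled'")
    values = np.empty(cohort.items.shape, dtype=float)
    blocks = (
        [np.flatnonzero(cohort.group == g) for g in cohort.groups]
        if scope == "per_group"
        else [np.arange(cohort.n)]
    )
    for idx in blocks:
        X = _design(cohort.age[idx], cohort.sex[idx])
        if len(idx) < X.shape[1] + 1:
            raise EstimationError(
                f"residualization sample of {len(idx)} rows is too small for "
                f"a {X.shape[1]}-column design"
            )
        values[idx] = _ols_residuals(cohort.items[idx].astype(float), X)
    return ResidualMatrix(values, cohort.group.copy(), list(cohort.item_names), scope)
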