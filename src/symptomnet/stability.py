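"""Bootstrap accuracy and stability diagnostics.

Edge-weight accuracy: nonparametric row bootstrap (resample participants
with replacement, re-estimate the network) with percentile confidence
intervals per edge; an edge whose CI excludes zero is read as sufficiently
strong. A parametric bootstrap is deliberately not offered — LASSO
regularization biases it.

Centrality stability: case-dropping subset bootstrap — re-estimate on
subsamples with a growing proportion of participants dropped and correlate
the subset centralities with the full-sample ones. The CS-coefficient is
the largest drop proportion at which at least ``prob`` of the subsample
correlations stay at or above ``cor_floor``; values above 0.25 are
conventionally read as stable.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centrality import MEASURES, betweenness, closeness, strength
from .errors import EstimationError
from .ggm import estimate_network
from .residualize import ResidualMatrix

logger = logging.getLogger(__name__)

DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.05, 0.751, 0.05), 2))


def _values(resid) -> np.ndarray:
    return resid.values if isinstance(resid, ResidualMatrix) else np.asarray(resid, dtype=float)


@dataclass
class EdgeBootstrapResult:
    """Per-edge sample estimates, bootstrap means and percentile CIs,
    ordered by sample edge weight descending."""

    table: pd.DataFrame
    B: int
    seed: object
    ci_levels: tuple
    n_redrawn: int = 0


def bootstrap_edges(
    resid,
    B: int = 2500,
    seed=None,
    estimator: dict | None = None,
    ci_levels: tuple = (2.5, 97.5),
) -> EdgeBootstrapResult:
    """Nonparametric bootstrap CIs for every edge weight.

    Resamples the n rows with replacement ``B`` times, re-estimating the
    full network each time. Replicates whose estimation fails (e.g. a
    zero-variance resample) are redrawn and counted.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    est = estimator or {}
    X = _values(resid)
    n, p = X.shape
    net = estimate_network(X, **est)
    iu = np.triu_indices(p, k=1)

    rng = np.random.default_rng(seed)
    boot = np.empty((B, len(iu[0])))
    redrawn = 0
    done = 0
    while done < B:
        rows = rng.integers(0, n, size=n)
        try:
            bnet = estimate_network(X[rows], **est)
        except EstimationError:
            redrawn += 1
            if redrawn > 10 * B:
                raise
            continue
        boot[done] = bnet.W[iu]
        done += 1
    if redrawn:
        logger.info("bootstrap_edges: redrew %d failed replicate(s)", redrawn)

    lo, hi = np.percentile(boot, ci_levels, axis=0)
    df = pd.DataFrame({
        "item_i": iu[0] + 1,
        "item_j": iu[1] + 1,
        "sample_weight": net.W[iu],
        "boot_mean": boot.mean(axis=0),
        "ci_lower": lo,
        "ci_upper": hi,
    })
    df["excludes_zero"] = (df["ci_lower"] > 0) | (df["ci_upper"] < 0)
    df = df.sort_values("sample_weight", ascending=False, kind="mergesort").reset_index(drop=True)
    return EdgeBootstrapResult(table=df, B=B, seed=seed, ci_levels=tuple(ci_levels),
                               n_redrawn=redrawn)


def _centrality_vectors(W) -> dict:
    return {
        "strength": strength(W),
        "closeness": closeness(W),
        "betweenness": betweenness(W),
    }


def _pearson_or_nan(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class CaseDropResult:
    """Case-dropping bootstrap correlations per drop proportion and measure."""

    correlations: pd.DataFrame  # columns: proportion, measure, replicate, correlation
    proportions: tuple
    B: int
    seed: object
    full_centralities: pd.DataFrame = field(default=None, repr=False)
    n_undefined: int = 0


def case_dropping(
    resid,
    proportions=DEFAULT_DROP_GRID,
    B: int = 1000,
    seed=None,
    estimator: dict | None = None,
) -> CaseDropResult:
    """Correlate subset centralities with full-sample centralities.

    For each drop proportion q, draws ``B`` subsamples of size
    ``ceil((1-q)*n)`` without replacement, re-estimates the network and
    correlates each centrality measure with its full-sample counterpart.
    Constant centrality vectors make the correlation undefined; those
    replicates are recorded as missing and counted.
    """
    est = estimator or {}
    X = _values(resid)
    n, p = X.shape
    props = tuple(sorted(float(q) for q in proportions))
    if any(not 0 <= q < 1 for q in props):
        raise ValueError("drop proportions must lie in [0, 1)")
    for q in props:
        if int(np.ceil((1 - q) * n)) < p + 2:
            raise ValueError(f"drop proportion {q} leaves fewer than p+2 rows")

    full = _centrality_vectors(estimate_network(X, **est).W)
    rng = np.random.default_rng(seed)
    rows = []
    n_undef = 0
    for q in props:
        m = int(np.ceil((1 - q) * n))
        for b in range(B):
            keep = rng.choice(n, size=m, replace=False)
            try:
                sub = _centrality_vectors(estimate_network(X[keep], **est).W)
            except EstimationError:
                sub = None
            for meas in MEASURES:
                r = np.nan if sub is None else _pearson_or_nan(full[meas], sub[meas])
                if np.isnan(r):
                    n_undef += 1
                rows.append({"proportion": q, "measure": meas,
                             "replicate": b, "correlation": r})
    df = pd.DataFrame(rows)
    full_df = pd.DataFrame(full)
    return CaseDropResult(correlations=df, proportions=props, B=B, seed=seed,
                          full_centralities=full_df, n_undefined=n_undef)


def cs_coefficient(
    result: CaseDropResult,
    cor_floor: float = 0.7,
    prob: float = 0.95,
) -> dict:
    """Correlation-stability coefficient per centrality measure.

    The largest tested drop proportion q at which at least ``prob`` of that
    q's defined bootstrap correlations are >= ``cor_floor``; 0 if no tested
    proportion qualifies. Undefined correlations are excluded from the
    denominator (a proportion with no defined correlation cannot qualify).
    """
    out = {}
    df = result.correlations
    for meas in MEASURES:
        cs = 0.0
        for q in result.proportions:
            r = df.loc[(df["measure"] == meas) & (df["proportion"] == q), "correlation"]
            r = r.dropna()
            if len(r) and (r >= cor_floor).mean() >= prob:
                cs = max(cs, q)
        out[meas] = cs
    return out
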