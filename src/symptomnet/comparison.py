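"""Between-group network comparisons.

Two families of tests:

* chi-square tests on the ratio of nonzero edges (out of the p(p-1)/2
  possible pairs) between two groups' estimated networks, Holm-corrected
  across the pairs compared;
* the permutation Network Comparison Test (NCT): participants are pooled
  and repeatedly reassigned to pseudo-groups of the original sizes, both
  networks are re-estimated each time, and the observed global-strength
  difference and structure statistic (maximum absolute difference in any
  edge weight) are referred to their permutation distributions.

Each of the two NCT indicators is Holm-corrected as its own family across
the group pairs tested.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from statsmodels.stats.multitest import multipletests

from .errors import EstimationError
from .ggm import estimate_network
from .residualize import ResidualMatrix

logger = logging.getLogger(__name__)


def global_strength(W) -> float:
    """Sum of absolute edge weights over pairs i < j."""
    A = np.asarray(W.W if hasattr(W, "W") else W, dtype=float)
    iu = np.triu_indices(A.shape[0], k=1)
    return float(np.abs(A[iu]).sum())


def structure_statistic(WA, WB) -> float:
    """Maximum absolute difference in any single edge weight."""
    A = np.asarray(WA.W if hasattr(WA, "W") else WA, dtype=float)
    B = np.asarray(WB.W if hasattr(WB, "W") else WB, dtype=float)
    return float(np.abs(A - B).max())


def holm(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def edge_ratio_chi2(nonzero_a: int, nonzero_b: int, possible: int):
    """Pearson chi-square (no continuity correction) on the 2x2 table
    [(nonzero_a, zero_a), (nonzero_b, zero_b)].

    Returns ``(statistic, p, degenerate)``; a table with an all-zero row or
    column is degenerate and reported as statistic 0, p = 1.
    """
    table = np.array([
        [nonzero_a, possible - nonzero_a],
        [nonzero_b, possible - nonzero_b],
    ])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0, True
    stat, p, _, _ = chi2_contingency(table, correction=False)
    return float(stat), float(p), False


@dataclass
class EdgeCountTestResult:
    """Pairwise nonzero-edge-ratio chi-square tests with Holm correction."""

    table: pd.DataFrame
    possible_edges: int


def edge_count_test(networks: dict, pairs=None) -> EdgeCountTestResult:
    """Chi-square test of nonzero-edge ratios for every pair of groups.

    ``networks`` maps group label to an estimated network; all must share
    the same p. Holm correction is applied across the pairs tested.
    """
    groups = list(networks)
    if len(groups) < 2:
        raise ValueError("need at least two networks to compare")
    p_nodes = {g: networks[g].p for g in groups}
    if len(set(p_nodes.values())) != 1:
        raise ValueError(f"networks have differing node counts: {p_nodes}")
    possible = next(iter(p_nodes.values())) * (next(iter(p_nodes.values())) - 1) // 2
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    rows = []
    for a, b in pairs:
        na, nb = networks[a].nonzero_edge_count, networks[b].nonzero_edge_count
        stat, praw, degen = edge_ratio_chi2(na, nb, possible)
        rows.append({"group_a": a, "group_b": b, "nonzero_a": na, "nonzero_b": nb,
                     "chi2": stat, "p_raw": praw, "degenerate": degen})
    df = pd.DataFrame(rows)
    df["p_holm"] = holm(df["p_raw"].to_numpy())
    return EdgeCountTestResult(table=df, possible_edges=possible)


@dataclass
class NCTResult:
    """Permutation comparison of two groups' networks."""

    group_a: str
    group_b: str
    strength_a: float
    strength_b: float
    strength_diff: float
    structure_stat: float
    p_strength: float
    p_structure: float
    n_permutations: int
    seed: object
    n_redrawn: int = 0


def _values(resid) -> np.ndarray:
    return resid.values if isinstance(resid, ResidualMatrix) else np.asarray(resid, dtype=float)


def nct(
    resid_a,
    resid_b,
    B: int = 5000,
    seed=None,
    estimator: dict | None = None,
    group_a: str = "A",
    group_b: str = "B",
) -> NCTResult:
    """Network Comparison Test between two residualized samples.

    Rows are pooled (in a canonical sort order, making the p-values exactly
    invariant to swapping the two inputs) and reassigned without replacement
    to pseudo-groups of the original sizes ``B`` times; both networks are
    re-estimated with the full penalty-path procedure on each reassignment.
    p-values use the add-one convention ``(1 + #{perm >= obs}) / (B + 1)``
    and therefore never equal 0. A permutation whose estimation fails is
    redrawn and the redraw count is logged.
    """
    if B < 1:
        raise ValueError("need at least one permutation")
    est = estimator or {}
    XA, XB = _values(resid_a), _values(resid_b)
    if XA.shape[1] != XB.shape[1]:
        raise ValueError("groups have differing item counts")

    net_a = estimate_network(XA, **est)
    net_b = estimate_network(XB, **est)
    s_a, s_b = global_strength(net_a), global_strength(net_b)
    obs_strength = abs(s_a - s_b)
    obs_structure = structure_statistic(net_a, net_b)

    pooled = np.vstack([XA, XB])
    pooled = pooled[np.lexsort(pooled.T[::-1])]
    n_small, n_large = sorted([XA.shape[0], XB.shape[0]])
    n = n_small + n_large

    rng = np.random.default_rng(seed)
    ge_strength = 0
    ge_structure = 0
    redrawn = 0
    done = 0
    while done < B:
        idx = rng.permutation(n)
        try:
            net1 = estimate_network(pooled[idx[:n_small]], **est)
            net2 = estimate_network(pooled[idx[n_small:]], **est)
        except EstimationError:
            redrawn += 1
            if redrawn > 10 * B:
                raise
            continue
        if abs(global_strength(net1) - global_strength(net2)) >= obs_strength:
            ge_strength += 1
        if structure_statistic(net1, net2) >= obs_structure:
            ge_structure += 1
        done += 1
    if redrawn:
        logger.info("nct: redrew %d failed permutation(s)", redrawn)
    return NCTResult(
        group_a=group_a, group_b=group_b,
        strength_a=s_a, strength_b=s_b,
        strength_diff=obs_strength, structure_stat=obs_structure,
        p_strength=(1 + ge_strength) / (B + 1),
        p_structure=(1 + ge_structure) / (B + 1),
        n_permutations=B, seed=seed, n_redrawn=redrawn,
    )


def nct_all(
    resid: ResidualMatrix,
    B: int = 5000,
    seed=None,
    estimator: dict | None = None,
    pairs=None,
) -> pd.DataFrame:
    """Run the NCT for every pair of groups in a residual matrix.

    The global-strength p-values and the structure p-values are
    Holm-corrected as two separate families.
    """
    groups = list(pd.unique(resid.group))
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in pairs:
        res = nct(
            resid.for_group(a), resid.for_group(b), B=B,
            seed=int(rng.integers(0, 2**31 - 1)),
            estimator=estimator, group_a=a, group_b=b,
        )
        rows.append(vars(res))
    df = pd.DataFrame(rows)
    df["p_strength_holm"] = holm(df["p_strength"].to_numpy())
    df["p_structure_holm"] = holm(df["p_structure"].to_numpy())
    return df
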