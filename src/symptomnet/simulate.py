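"""Synthetic cohorts with known conditional-independence structure.

Ordinal item scores are produced by thresholding a latent multivariate
Gaussian whose precision matrix encodes a known sparse partial-correlation
network (a Gaussian-copula-style mechanism). Group severity differences,
and linear age/sex effects, act as shifts on the latent scale, so that
linear residualization downstream approximately removes them. The
generator's only contract is that the true conditional-independence
structure is known; it does not claim to match published questionnaire
norms.

The default four-group preset mirrors the study conditions this package
was built to analyse: two clinical groups (current and remitted
depression) sharing one dense network but differing in severity, a sparse
subthreshold-depression group, and an empty healthy-control group, with
group sizes 294 / 118 / 184 / 257.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GenerationError
from .io import CohortTable

__all__ = [
    "TruePrecisionModel",
    "GroupArchetype",
    "DiscretizationRule",
    "make_precision_model",
    "sample_group",
    "four_group_fixture",
    "DEFAULT_ARCHETYPES",
    "DEFAULT_GROUP_SIZES",
]

#: Default four-group sample sizes (clinical cohorts are small;
#: remitted patients are hardest to recruit).
DEFAULT_GROUP_SIZES = {"CD": 294, "RD": 118, "SD": 184, "HC": 257}


@dataclass(frozen=True)
class TruePrecisionModel:
    """Ground-truth precision matrix and its implied partial correlations."""

    precision: np.ndarray
    true_partials: np.ndarray
    edge_set: frozenset
    density: float

    @property
    def p(self) -> int:
        return self.precision.shape[0]

    @property
    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.precision)


@dataclass(frozen=True)
class DiscretizationRule:
    """Monotone mapping from a latent continuous value to scores {0,1,2,3}.

    Default thresholds (-0.5, 0.5, 1.5) on a unit-variance latent scale give
    right-skewed item distributions typical of community samples.
    """

    thresholds: tuple = (-0.5, 0.5, 1.5)

    def __post_init__(self):
        t = np.asarray(self.thresholds, dtype=float)
        if t.ndim != 1 or len(t) != 3 or not np.all(np.diff(t) > 0):
            raise ValueError("thresholds must be 3 strictly increasing cut points")

    def apply(self, latent: np.ndarray) -> np.ndarray:
        return np.searchsorted(np.asarray(self.thresholds), latent, side="right").astype(np.int64)


@dataclass(frozen=True)
class GroupArchetype:
    """Generative settings for one group.

    ``mean_shift`` is a per-item (or scalar) latent mean offset encoding
    symptom severity; ``age_effect`` and ``sex_effect`` are linear
    coefficients on the latent scale (per year of centred age, and for
    sex = 1 vs 0).
    """

    name: str
    density: float
    weight_range: tuple
    n: int
    mean_shift: float = 0.0
    age_effect: float = 0.01
    sex_effect: float = 0.15
    age_mean: float = 45.0
    age_sd: float = 15.0
    sex_prob: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("density must lie in [0, 1]")
        lo, hi = self.weight_range
        if self.density > 0 and not 0.0 < lo <= hi < 1.0:
            raise ValueError("weight_range must satisfy 0 < lo <= hi < 1")


def partials_to_precision(partials: np.ndarray) -> np.ndarray:
    """Unit-diagonal precision matrix implied by a partial-correlation matrix."""
    K = -np.asarray(partials, dtype=float).copy()
    np.fill_diagonal(K, 1.0)
    return K


def precision_to_partials(precision: np.ndarray) -> np.ndarray:
    """partial(i,j) = -K_ij / sqrt(K_ii * K_jj), zero diagonal."""
    K = np.asarray(precision, dtype=float)
    d = np.sqrt(np.diag(K))
    P = -K / np.outer(d, d)
    np.fill_diagonal(P, 0.0)
    return P


def make_precision_model(
    p: int,
    density: float,
    weight_range: tuple = (0.1, 0.3),
    seed=None,
    positive_prob: float = 0.5,
    scale_factor: float = 0.98,
    max_scale_iter: int = 2000,
) -> TruePrecisionModel:
    """Draw a random sparse partial-correlation structure.

    ``floor(density * p(p-1)/2)`` node pairs become edges; their partial
    correlations are drawn uniformly in ``weight_range``, each sign positive
    with probability ``positive_prob`` (0.5 by default; set 1.0 for the
    all-positive connectivity typical of estimated symptom networks —
    note dense all-positive structures force heavy shrinkage to stay
    positive-definite). If the implied precision is not
    positive-definite, all off-diagonal entries are scaled by ``scale_factor``
    repeatedly — preserving the edge pattern, shrinking magnitudes — and the
    true partials are recomputed from the adjusted precision. The default
    factor 0.98 stops close to the positive-definiteness boundary, so dense
    structures keep a strong general-factor-like marginal correlation
    pattern, as real questionnaire data show.
    """
    rng = np.random.default_rng(seed)
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    n_edges = int(np.floor(density * len(pairs)))
    idx = rng.choice(len(pairs), size=n_edges, replace=False) if n_edges else []
    edge_set = frozenset(pairs[k] for k in np.sort(np.asarray(idx, dtype=int)))

    lo, hi = weight_range
    P = np.zeros((p, p))
    for (i, j) in edge_set:
        w = rng.uniform(lo, hi)
        if rng.random() >= positive_prob:
            w = -w
        P[i, j] = P[j, i] = w

    K = partials_to_precision(P)
    for _ in range(max_scale_iter):
        if np.linalg.eigvalsh(K).min() > 1e-6:
            break
        off = K - np.diag(np.diag(K))
        K = np.diag(np.diag(K)) + scale_factor * off
    else:
        raise GenerationError(
            "could not reach positive-definiteness; use smaller edge weights"
        )
    true_partials = precision_to_partials(K)
    return TruePrecisionModel(
        precision=K,
        true_partials=true_partials,
        edge_set=edge_set,
        density=len(edge_set) / len(pairs) if pairs else 0.0,
    )


def sample_group(
    model: TruePrecisionModel,
    archetype: GroupArchetype,
    rule: DiscretizationRule = DiscretizationRule(),
    seed=None,
) -> CohortTable:
    """Sample one group's cohort from the latent-Gaussian model.

    Latent vectors are drawn from N(0, precision^-1), standardized to unit
    marginal variance (partial correlations are scale-invariant), shifted by
    ``mean_shift + age_effect*(age - mean age) + sex_effect*sex``, and
    discretized by ``rule``. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    n, p = archetype.n, model.p
    age = rng.normal(archetype.age_mean, archetype.age_sd, size=n)
    sex = (rng.random(n) < archetype.sex_prob).astype(np.int64)

    cov = model.covariance
    scale = np.sqrt(np.diag(cov))
    L = np.linalg.cholesky(cov)
    latent = (rng.standard_normal((n, p)) @ L.T) / scale

    shift = (
        np.broadcast_to(np.asarray(archetype.mean_shift, dtype=float), (p,))
        + np.outer(age - archetype.age_mean, np.full(p, archetype.age_effect))
        + np.outer(sex, np.full(p, archetype.sex_effect))
    )
    items = rule.apply(latent + shift)
    return CohortTable(
        items=items, age=age, sex=sex,
        group=np.full(n, archetype.name, dtype=object),
    )


#: Default four-group study conditions. CD and RD share one dense structure
#: (the "trace" scenario: same network, different severity); SD is sparse;
#: HC has no edges. Densities echo the reported per-group edge counts
#: (119 and 20 of 210 pairs; HC near-empty).
DEFAULT_ARCHETYPES = {
    "CD": GroupArchetype("CD", density=119 / 210, weight_range=(0.10, 0.40),
                         n=DEFAULT_GROUP_SIZES["CD"], mean_shift=1.0),
    "RD": GroupArchetype("RD", density=119 / 210, weight_range=(0.10, 0.40),
                         n=DEFAULT_GROUP_SIZES["RD"], mean_shift=0.0),
    "SD": GroupArchetype("SD", density=20 / 210, weight_range=(0.25, 0.45),
                         n=DEFAULT_GROUP_SIZES["SD"], mean_shift=0.4),
    "HC": GroupArchetype("HC", density=0.0, weight_range=(0.0, 0.0),
                         n=DEFAULT_GROUP_SIZES["HC"], mean_shift=0.0),
}


def four_group_fixture(
    seed=None,
    p: int = 21,
    archetypes: dict | None = None,
    rule: DiscretizationRule = DiscretizationRule(),
):
    """Generate the default four-group cohort preset.

    Returns ``(cohorts, models)``: dicts keyed by group label. CD and RD are
    sampled from the *same* precision model, so their true edge sets are
    identical by construction; HC's edge set is empty.
    """
    arch = dict(archetypes or DEFAULT_ARCHETYPES)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=8)

    dense = make_precision_model(p, arch["CD"].density, arch["CD"].weight_range, seed=seeds[0])
    sparse = make_precision_model(p, arch["SD"].density, arch["SD"].weight_range, seed=seeds[1])
    empty = make_precision_model(p, 0.0, (0.1, 0.1), seed=seeds[2])
    models = {"CD": dense, "RD": dense, "SD": sparse, "HC": empty}

    cohorts = {
        g: sample_group(models[g], arch[g], rule, seed=seeds[3 + k])
        for k, g in enumerate(["CD", "RD", "SD", "HC"])
    }
    return cohorts, models


def concat_cohorts(cohorts: dict) -> CohortTable:
    """Stack per-group cohorts into one table (order: dict iteration order)."""
    tables = list(cohorts.values())
    return CohortTable(
        items=np.vstack([t.items for t in tables]),
        age=np.concatenate([t.age for t in tables]),
        sex=np.concatenate([t.sex for t in tables]),
        group=np.concatenate([t.group for t in tables]),
        item_names=list(tables[0].item_names),
    )
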