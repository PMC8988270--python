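"""Cohort data model and tabular input/output.

A cohort is one row per participant: ``p`` ordinal item scores (0-3 each,
21 items by default, mirroring a BDI-II-style questionnaire), the covariates
age (years) and sex (binary), and a group label (e.g. CD / RD / SD / HC).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

ITEM_MIN = 0
ITEM_MAX = 3

#: Documented labelling constants from the study design; the pipeline never
#: applies them — group membership is input metadata.
HAMD17_CURRENT_DEPRESSION_MIN = 8
SUBTHRESHOLD_BDI_MIN = 13
HEALTHY_CONTROL_BDI_MAX = 10


@dataclass(frozen=True)
class ItemMetadata:
    """Label and symptom category for one questionnaire item (1-based id)."""

    item_id: int
    label: str
    category: str


def load_item_metadata() -> list[ItemMetadata]:
    """Load the bundled 21-item label/category table.

    Categories are the three-factor grouping used for node colouring:
    ``negative_attitude``, ``performance_difficulty``, ``somatic_elements``.
    """
    ref = resources.files("symptomnet.data").joinpath("bdi_items.yaml")
    raw = yaml.safe_load(ref.read_text())
    meta = [ItemMetadata(d["id"], d["label"], d["category"]) for d in raw["items"]]
    cats = {m.category for m in meta}
    expected = {"negative_attitude", "performance_difficulty", "somatic_elements"}
    if cats != expected or len(meta) != 21:
        raise ValidationError("bundled item metadata is corrupt")
    return meta


@dataclass
class CohortTable:
    """Participants x (items + age + sex + group).

    Attributes
    ----------
    items : (n, p) int array of item scores, each in {0, 1, 2, 3}.
    age : (n,) float array, years.
    sex : (n,) int array, coded 0/1.
    group : (n,) array of group labels.
    """

    items: np.ndarray
    age: np.ndarray
    sex: np.ndarray
    group: np.ndarray
    item_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.items = np.asarray(self.items)
        self.age = np.asarray(self.age, dtype=float)
        self.sex = np.asarray(self.sex)
        self.group = np.asarray(self.group)
        n = self.items.shape[0]
        if not (len(self.age) == len(self.sex) == len(self.group) == n):
            raise ValidationError("items, age, sex and group must have equal length")
        if not np.issubdtype(self.items.dtype, np.number):
            raise ValidationError("item scores must be numeric")
        bad = (self.items < ITEM_MIN) | (self.items > ITEM_MAX) | (self.items % 1 != 0)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"item score out of range {{0..3}} at row {r}, item {c + 1} "
                f"(value {self.items[r, c]!r})"
            )
        self.items = self.items.astype(np.int64)
        if not np.isin(self.sex, [0, 1]).all():
            raise ValidationError("sex must be coded 0/1")
        self.sex = self.sex.astype(np.int64)
        if not self.item_names:
            self.item_names = [f"item{j + 1}" for j in range(self.items.shape[1])]

    @property
    def n(self) -> int:
        return self.items.shape[0]

    @property
    def p(self) -> int:
        return self.items.shape[1]

    @property
    def groups(self) -> list:
        """Group labels in order of first appearance."""
        return list(pd.unique(self.group))

    def subset(self, mask: np.ndarray) -> "CohortTable":
        mask = np.asarray(mask)
        return CohortTable(
            self.items[mask], self.age[mask], self.sex[mask], self.group[mask],
            list(self.item_names),
        )

    def by_group(self) -> dict:
        return {g: self.subset(self.group == g) for g in self.groups}

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.items, columns=self.item_names)
        df["age"] = self.age
        df["sex"] = self.sex
        df["group"] = self.group
        return df


DEFAULT_SCHEMA: Mapping[str, object] = {
    "age": "age",
    "sex": "sex",
    "group": "group",
    # "items" may be a list of column names; None means autodetect "item*".
    "items": None,
}


def _resolve_schema(df: pd.DataFrame, schema: Mapping[str, object] | None) -> dict:
    merged = dict(DEFAULT_SCHEMA)
    if schema:
        merged.update(schema)
    if merged["items"] is None:
        merged["items"] = [c for c in df.columns if str(c).startswith("item")]
        if not merged["items"]:
            raise SchemaError("no item columns found (expected names starting with 'item')")
    missing = [c for c in list(merged["items"]) + [merged["age"], merged["sex"], merged["group"]]
               if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    return merged


def read_cohort_csv(path, schema: Mapping[str, object] | None = None) -> CohortTable:
    """Read and validate a cohort CSV.

    Rows with any missing mapped value are dropped listwise and the count is
    logged. A two-level ``sex`` column of any dtype is accepted and mapped to
    {0, 1} by sorted level order (mapping logged).
    """
    df = pd.read_csv(path)
    sch = _resolve_schema(df, schema)
    cols = list(sch["items"]) + [sch["age"], sch["sex"], sch["group"]]
    use = df[cols]
    keep = use.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("read_cohort_csv: dropped %d row(s) with missing values (listwise)", n_dropped)
    use = use.loc[keep]

    sex_raw = use[sch["sex"]]
    levels = sorted(pd.unique(sex_raw))
    if len(levels) > 2:
        raise ValidationError(f"sex column has {len(levels)} levels; expected at most 2")
    if set(levels) <= {0, 1}:
        sex = sex_raw.to_numpy()
    else:
        mapping = {lv: i for i, lv in enumerate(levels)}
        logger.info("read_cohort_csv: sex levels mapped %s", mapping)
        sex = sex_raw.map(mapping).to_numpy()

    items = use[list(sch["items"])].to_numpy()
    bad = (items < ITEM_MIN) | (items > ITEM_MAX) | (items % 1 != 0)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValidationError(
            f"item score out of range {{0..3}}: row {use.index[r]}, "
            f"column {sch['items'][c]!r} (value {items[r, c]!r})"
        )
    return CohortTable(
        items=items,
        age=use[sch["age"]].to_numpy(dtype=float),
        sex=sex,
        group=use[sch["group"]].to_numpy(),
        item_names=[str(c) for c in sch["items"]],
    )


def write_edge_list(network, path, include_zeros: bool = False) -> None:
    """Serialize a network's edge weights to CSV (columns item_i, item_j, weight).

    Items are 1-based and only pairs i < j are written; zero-weight pairs are
    included only when ``include_zeros`` is set.
    """
    W = np.asarray(network.W if hasattr(network, "W") else network)
    p = W.shape[0]
    rows = []
    for i in range(p):
        for j in range(i + 1, p):
            if include_zeros or W[i, j] != 0.0:
                rows.append((i + 1, j + 1, W[i, j]))
    pd.DataFrame(rows, columns=["item_i", "item_j", "weight"]).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_edge_list(path, p: int) -> np.ndarray:
    """Read an edge-list CSV back into a dense symmetric p x p weight matrix."""
    df = pd.read_csv(path)
    W = np.zeros((p, p))
    for i, j, w in df[["item_i", "item_j", "weight"]].itertuples(index=False):
        W[int(i) - 1, int(j) - 1] = w
        W[int(j) - 1, int(i) - 1] = w
    return W
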