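"""Ordinal response data with group labels and two kinds of missingness.

A :class:`ResponseMatrix` holds a persons x items integer matrix of ordered
categories ``0..m_i`` together with a per-person group label.  Two kinds of
missing cells are distinguished:

* *incidental* — ordinary nonresponse (empty cell in the CSV);
* *structural* — created by design when an item is resolved into
  group-specific copies: every group except the designated one is
  structurally missing on that copy.

CSV layout (one row per person)::

    person_id,group,headache,stomach_ache,...
    p0001,boys,2,0,...
    p0002,girls_period,1,,...

An empty field is incidental missing.  Structural missingness only arises
in-memory through item resolution and is not round-tripped through CSV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ItemSpec", "ResponseMatrix", "read_responses", "write_responses"]


class DataValidationError(ValueError):
    """Raised for malformed response data."""


@dataclass(frozen=True)
class ItemSpec:
    """Identity and category range of one item column."""

    item_id: str
    m: int
    group_tag: str | None = None  # set on resolved (group-specific) copies

    def __post_init__(self) -> None:
        if self.m < 1:
            raise DataValidationError(f"item {self.item_id!r}: m must be >= 1")


class ResponseMatrix:
    """Persons x items ordinal responses with group labels.

    Parameters
    ----------
    responses : (n_persons, n_items) int array
        Category scores; entries at missing cells are ignored (use 0).
    observed : bool array, same shape
        True where a response was actually given.
    structural : bool array, same shape
        True where the cell is missing *by design* (resolved items).
        Must be False wherever ``observed`` is True.
    items : list of ItemSpec
    group : sequence of str, length n_persons
    person_id : sequence of str, length n_persons
    """

    def __init__(self, responses, observed, structural, items, group, person_id=None):
        self.responses = np.asarray(responses, dtype=np.int16)
        self.observed = np.asarray(observed, dtype=bool)
        self.structural = np.asarray(structural, dtype=bool)
        self.items = list(items)
        self.group = np.asarray(group, dtype=object)
        n, k = self.responses.shape
        if person_id is None:
            person_id = [f"p{i + 1:05d}" for i in range(n)]
        self.person_id = np.asarray(person_id, dtype=object)
        self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_observed(cls, responses, items, group, person_id=None, observed=None):
        """Build a matrix with no structural missingness."""
        responses = np.asarray(responses)
        if observed is None:
            observed = np.ones(responses.shape, dtype=bool)
        structural = np.zeros(responses.shape, dtype=bool)
        return cls(responses, observed, structural, items, group, person_id)

    def _validate(self) -> None:
        n, k = self.responses.shape
        if self.observed.shape != (n, k) or self.structural.shape != (n, k):
            raise DataValidationError("mask shapes do not match responses")
        if len(self.items) != k:
            raise DataValidationError(
                f"{len(self.items)} item specs for {k} response columns"
            )
        if len(self.group) != n or len(self.person_id) != n:
            raise DataValidationError("group/person_id length mismatch")
        if np.any(self.observed & self.structural):
            raise DataValidationError("a cell cannot be both observed and structural")
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise DataValidationError("duplicate item ids")
        if len(set(self.person_id)) != n:
            raise DataValidationError("duplicate person ids")
        for j, spec in enumerate(self.items):
            col = self.responses[:, j]
            obs = self.observed[:, j]
            if obs.any():
                bad = obs & ((col < 0) | (col > spec.m))
                if bad.any():
                    v = np.argmax(bad)
                    raise DataValidationError(
                        f"item {spec.item_id!r}: response {col[v]} at person "
                        f"{self.person_id[v]!r} outside 0..{spec.m}"
                    )
        # structural missingness is only legal on group-specific items,
        # exactly off the designated group
        for j, spec in enumerate(self.items):
            struct = self.structural[:, j]
            if spec.group_tag is None:
                if struct.any():
                    raise DataValidationError(
                        f"common item {spec.item_id!r} has structural missingness"
                    )
            else:
                in_group = self.group == spec.group_tag
                if np.any(struct & in_group):
                    raise DataValidationError(
                        f"resolved item {spec.item_id!r}: structural missingness "
                        f"inside its designated group {spec.group_tag!r}"
                    )

    # -- basic properties --------------------------------------------------

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def groups(self) -> list[str]:
        """Group levels in order of first appearance."""
        return list(pd.unique(self.group))

    def item_index(self, item_id: str) -> int:
        try:
            return self.item_ids.index(item_id)
        except ValueError:
            raise KeyError(f"no item {item_id!r}") from None

    def copy(self) -> "ResponseMatrix":
        return ResponseMatrix(
            self.responses.copy(),
            self.observed.copy(),
            self.structural.copy(),
            list(self.items),
            self.group.copy(),
            self.person_id.copy(),
        )

    def take_persons(self, index) -> "ResponseMatrix":
        """Row-subset by integer index array."""
        index = np.asarray(index)
        return ResponseMatrix(
            self.responses[index],
            self.observed[index],
            self.structural[index],
            list(self.items),
            self.group[index],
            self.person_id[index],
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ResponseMatrix({self.n_persons} persons x {self.n_items} items, "
            f"groups={self.groups})"
        )


def write_responses(data: ResponseMatrix, path) -> None:
    """Write a response matrix as CSV; missing cells become empty fields."""
    cols = {"person_id": data.person_id, "group": data.group}
    for j, spec in enumerate(data.items):
        col = data.responses[:, j].astype(float)
        col[~data.observed[:, j]] = np.nan
        cols[spec.item_id] = col
    df = pd.DataFrame(cols)
    for spec in data.items:
        df[spec.item_id] = df[spec.item_id].astype("Int64")
    df.to_csv(path, index=False)


def read_responses(path, schema: dict[str, int] | None = None) -> ResponseMatrix:
    """Read a response matrix from CSV.

    Parameters
    ----------
    path : str or Path
        Delimited file with header row; must contain ``person_id`` and
        ``group`` columns, all remaining columns are items.
    schema : dict, optional
        ``{item_id: m}`` declaring the maximum category per item.  Items
        absent from the schema get ``m`` inferred from the observed maximum.

    Raises
    ------
    DataValidationError
        On a missing group column, duplicate person ids, unparseable cells,
        or responses outside the declared range, naming row and column.
    """
    df = pd.read_csv(path, dtype={"person_id": str, "group": str})
    for required in ("person_id", "group"):
        if required not in df.columns:
            raise DataValidationError(f"missing required column {required!r}")
    item_cols = [c for c in df.columns if c not in ("person_id", "group")]
    if not item_cols:
        raise DataValidationError("no item columns found")
    n = len(df)
    responses = np.zeros((n, len(item_cols)), dtype=np.int16)
    observed = np.zeros((n, len(item_cols)), dtype=bool)
    items = []
    for j, col in enumerate(item_cols):
        raw = df[col]
        vals = pd.to_numeric(raw, errors="coerce")
        bad = vals.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            r = int(np.argmax(bad.to_numpy()))
            raise DataValidationError(
                f"unparseable cell {raw.iloc[r]!r} at row {r + 2}, column {col!r}"
            )
        obs = vals.notna().to_numpy()
        v = vals.to_numpy(dtype=float)
        if obs.any() and np.any(v[obs] != np.floor(v[obs])):
            r = int(np.argmax(obs & (v != np.floor(v))))
            raise DataValidationError(
                f"non-integer response {v[r]} at row {r + 2}, column {col!r}"
            )
        m = (schema or {}).get(col)
        if m is None:
            m = int(np.nanmax(v)) if obs.any() else 1
            m = max(m, 1)
        if obs.any():
            vo = v[obs]
            if vo.min() < 0 or vo.max() > m:
                r = int(np.argmax(obs & ((v < 0) | (v > m))))
                raise DataValidationError(
                    f"response {int(v[r])} outside 0..{m} at row {r + 2}, "
                    f"column {col!r}"
                )
        responses[obs, j] = v[obs].astype(np.int16)
        observed[:, j] = obs
        items.append(ItemSpec(col, int(m)))
    return ResponseMatrix.from_observed(
        responses, items, df["group"].to_numpy(dtype=object),
        df["person_id"].to_numpy(dtype=object), observed=observed,
    )
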