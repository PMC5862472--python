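"""Item banks, response matrices, and category recoding.

The data model mirrors the generalized partial credit model (GPCM)
parameterization: each item has a slope (discrimination) ``a`` and ordered
step difficulties ``b_1..b_m`` in logits; an item with ``n_categories = m+1``
is scored 0..m, where 0 conventionally denotes the lowest performance level
("total assistance" on a caregiver-report self-care scale).

Files are flat, diff-friendly text: one CSV row per item for banks (step
difficulties semicolon-joined), respondents-as-rows CSV for response
matrices with empty cells for missing responses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: Internal sentinel for a missing response. CSV files use an empty cell.
MISSING: int = -1

#: Reserved (non-item) column names in response-matrix CSV files.
_RESERVED_COLUMNS = ("respondent_id", "group", "age")


class SchemaError(ValueError):
    """A file or in-memory object violates the documented schema."""


@dataclass(eq=True, frozen=True)
class ItemParameters:
    """One GPCM item.

    ``step_difficulties`` may be ``None`` for an item whose categories were
    recoded and which awaits re-calibration; all likelihood computations
    require calibrated items.
    """

    item_id: str
    slope: float
    step_difficulties: tuple[float, ...] | None
    n_categories: int
    group_specific: str | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.item_id:
            raise SchemaError("item_id must be a non-empty string")
        if not np.isfinite(self.slope) or self.slope <= 0:
            raise SchemaError(f"item {self.item_id!r}: slope must be positive, got {self.slope}")
        if not 2 <= self.n_categories <= 4:
            raise SchemaError(
                f"item {self.item_id!r}: n_categories must be in [2, 4], got {self.n_categories}"
            )
        if self.step_difficulties is not None:
            steps = tuple(float(b) for b in self.step_difficulties)
            object.__setattr__(self, "step_difficulties", steps)
            if len(steps) != self.n_categories - 1:
                raise SchemaError(
                    f"item {self.item_id!r}: expected {self.n_categories - 1} step "
                    f"difficulties, got {len(steps)}"
                )
            if not all(np.isfinite(steps)):
                raise SchemaError(f"item {self.item_id!r}: non-finite step difficulty")

    @property
    def max_category(self) -> int:
        return self.n_categories - 1

    @property
    def calibrated(self) -> bool:
        return self.step_difficulties is not None


@dataclass(eq=False)
class ItemBank:
    """Ordered collection of items with unique ids."""

    items: list[ItemParameters]
    name: str = "bank"

    def __post_init__(self) -> None:
        if not self.items:
            raise SchemaError("item bank must contain at least one item")
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate item ids: {dupes}")
        self._index: dict[str, int] = {iid: pos for pos, iid in enumerate(ids)}

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[ItemParameters]:
        return iter(self.items)

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._index

    def __getitem__(self, item_id: str) -> ItemParameters:
        try:
            return self.items[self._index[item_id]]
        except KeyError:
            raise KeyError(f"unknown item id {item_id!r}") from None

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def position(self, item_id: str) -> int:
        if item_id not in self._index:
            raise KeyError(f"unknown item id {item_id!r}")
        return self._index[item_id]

    def subset(self, item_ids: Sequence[str], name: str | None = None) -> "ItemBank":
        return ItemBank([self[iid] for iid in item_ids], name=name or self.name)


@dataclass(eq=False)
class ResponseMatrix:
    """Respondents x items integer category data with optional metadata.

    ``values`` holds category indices (0-based) with :data:`MISSING` for
    missing cells. ``groups`` is a per-respondent label (e.g. gender) used by
    DIF scans; ``ages`` is the respondent age in years.
    """

    respondent_ids: list[str]
    item_ids: list[str]
    values: np.ndarray
    groups: list[str] | None = None
    ages: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        n, k = self.values.shape
        if len(self.respondent_ids) != n:
            raise SchemaError("respondent_ids length does not match value rows")
        if len(self.item_ids) != k:
            raise SchemaError("item_ids length does not match value columns")
        for label, ids in (("respondent", self.respondent_ids), ("item", self.item_ids)):
            if len(set(ids)) != len(ids):
                raise SchemaError(f"duplicate {label} ids")
        if np.any((self.values < 0) & (self.values != MISSING)):
            raise SchemaError("negative response value that is not the missing sentinel")
        if self.groups is not None and len(self.groups) != n:
            raise SchemaError("groups length does not match respondents")
        if self.ages is not None:
            self.ages = np.asarray(self.ages, dtype=float)
            if self.ages.shape != (n,):
                raise SchemaError("ages length does not match respondents")
        self._col: dict[str, int] = {iid: j for j, iid in enumerate(self.item_ids)}

    @property
    def n_respondents(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def column(self, item_id: str) -> np.ndarray:
        try:
            return self.values[:, self._col[item_id]]
        except KeyError:
            raise KeyError(f"unknown item id {item_id!r}") from None

    def observed_mask(self) -> np.ndarray:
        return self.values != MISSING

    def subset_items(self, item_ids: Sequence[str]) -> "ResponseMatrix":
        cols = [self._col[iid] for iid in item_ids]
        return ResponseMatrix(
            respondent_ids=list(self.respondent_ids),
            item_ids=list(item_ids),
            values=self.values[:, cols].copy(),
            groups=list(self.groups) if self.groups is not None else None,
            ages=self.ages.copy() if self.ages is not None else None,
        )

    def aligned_to(self, bank: ItemBank) -> np.ndarray:
        """Response array in bank item order; MISSING for items absent here."""
        n = self.n_respondents
        out = np.full((n, len(bank)), MISSING, dtype=np.int64)
        for j, iid in enumerate(bank.item_ids):
            if iid in self._col:
                out[:, j] = self.values[:, self._col[iid]]
        return out

    def validate_against(self, bank: ItemBank) -> None:
        """Raise with respondent/item coordinates on out-of-range values."""
        for iid in self.item_ids:
            if iid not in bank:
                continue
            col = self.column(iid)
            bad = np.nonzero((col != MISSING) & (col > bank[iid].max_category))[0]
            if bad.size:
                rid = self.respondent_ids[bad[0]]
                raise SchemaError(
                    f"response {col[bad[0]]} out of range for item {iid!r} "
                    f"(max category {bank[iid].max_category}) at respondent {rid!r}"
                )


@dataclass(frozen=True)
class RecodeMap:
    """Order-preserving surjection of old category indices onto fewer new ones."""

    item_id: str
    mapping: Mapping[int, int]

    def __post_init__(self) -> None:
        keys = sorted(self.mapping)
        m_old = max(keys)
        if keys != list(range(m_old + 1)):
            raise SchemaError(f"recode for {self.item_id!r}: keys must be contiguous 0..m_old")
        vals = [self.mapping[k] for k in keys]
        if vals[0] != 0:
            raise SchemaError(f"recode for {self.item_id!r}: mapping(0) must be 0")
        if any(b - a not in (0, 1) for a, b in zip(vals, vals[1:])):
            raise SchemaError(
                f"recode for {self.item_id!r}: mapping must be non-decreasing and "
                "onto contiguous new indices"
            )
        if vals[-1] >= m_old:
            raise SchemaError(f"recode for {self.item_id!r}: must reduce the category count")

    @property
    def n_old(self) -> int:
        return len(self.mapping)

    @property
    def n_new(self) -> int:
        return max(self.mapping.values()) + 1

    def as_array(self) -> np.ndarray:
        return np.array([self.mapping[k] for k in range(self.n_old)], dtype=np.int64)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_BANK_COLUMNS = ["item_id", "slope", "steps", "n_categories", "group_specific", "label"]


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    return "json" if path.suffix.lower() == ".json" else "csv"


def _item_to_record(it: ItemParameters) -> dict:
    return {
        "item_id": it.item_id,
        "slope": it.slope,
        "steps": ";".join(repr(b) for b in it.step_difficulties)
        if it.step_difficulties is not None
        else "",
        "n_categories": it.n_categories,
        "group_specific": it.group_specific or "",
        "label": it.label or "",
    }


def _record_to_item(rec: Mapping, row: int) -> ItemParameters:
    for col in ("item_id", "slope", "steps", "n_categories"):
        if col not in rec:
            raise SchemaError(f"bank row {row}: missing column {col!r}")
    steps_raw = rec["steps"]
    if steps_raw is None or (isinstance(steps_raw, float) and np.isnan(steps_raw)):
        steps_raw = ""
    steps_raw = str(steps_raw).strip()
    try:
        steps = tuple(float(s) for s in steps_raw.split(";")) if steps_raw else None
    except ValueError as exc:
        raise SchemaError(f"bank row {row}, field 'steps': {exc}") from None
    try:
        slope = float(rec["slope"])
        n_cat = int(rec["n_categories"])
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"bank row {row}: {exc}") from None

    def _opt(key: str) -> str | None:
        val = rec.get(key)
        if val is None or (isinstance(val, float) and np.isnan(val)):
            return None
        val = str(val).strip()
        return val or None

    try:
        return ItemParameters(
            item_id=str(rec["item_id"]),
            slope=slope,
            step_difficulties=steps,
            n_categories=n_cat,
            group_specific=_opt("group_specific"),
            label=_opt("label"),
        )
    except SchemaError as exc:
        raise SchemaError(f"bank row {row}: {exc}") from None


def read_bank(path: str | Path, format: str | None = None) -> ItemBank:
    """Read an item bank from CSV or JSON (format inferred from the suffix)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        payload = json.loads(path.read_text())
        items = [_item_to_params_json(rec, i) for i, rec in enumerate(payload.get("items", []))]
        return ItemBank(items, name=payload.get("name", path.stem))
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ("item_id", "slope", "steps", "n_categories") if c not in frame.columns]
    if missing:
        raise SchemaError(f"bank file {path.name}: missing columns {missing}")
    items = [_record_to_item(rec, i) for i, rec in enumerate(frame.to_dict("records"))]
    return ItemBank(items, name=path.stem)


def _item_to_params_json(rec: Mapping, row: int) -> ItemParameters:
    rec = dict(rec)
    steps = rec.get("step_difficulties")
    rec["steps"] = ";".join(repr(float(b)) for b in steps) if steps else ""
    return _record_to_item(rec, row)


def write_bank(bank: ItemBank, path: str | Path, format: str | None = None) -> None:
    """Write an item bank; :func:`read_bank` reproduces it field for field."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        payload = {
            "name": bank.name,
            "items": [
                {
                    "item_id": it.item_id,
                    "slope": it.slope,
                    "step_difficulties": list(it.step_difficulties)
                    if it.step_difficulties is not None
                    else None,
                    "n_categories": it.n_categories,
                    "group_specific": it.group_specific,
                    "label": it.label,
                }
                for it in bank
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
        return
    frame = pd.DataFrame([_item_to_record(it) for it in bank], columns=_BANK_COLUMNS)
    frame.to_csv(path, index=False)


def read_responses(path: str | Path, bank: ItemBank | None = None) -> ResponseMatrix:
    """Read a respondents-as-rows response CSV.

    Columns ``respondent_id`` (first), optional ``group`` and ``age``, then
    one column per item. Empty cells are missing responses. If ``bank`` is
    given, category values are range-checked against it.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "respondent_id" not in frame.columns:
        raise SchemaError(f"response file {path.name}: missing 'respondent_id' column")
    item_cols = [c for c in frame.columns if c not in _RESERVED_COLUMNS]
    if not item_cols:
        raise SchemaError(f"response file {path.name}: no item columns")
    n = len(frame)
    values = np.full((n, len(item_cols)), MISSING, dtype=np.int64)
    for j, col in enumerate(item_cols):
        raw = frame[col].to_numpy()
        for i, cell in enumerate(raw):
            cell = str(cell).strip()
            if not cell:
                continue
            try:
                values[i, j] = int(cell)
            except ValueError:
                raise SchemaError(
                    f"response file {path.name}: non-integer value {cell!r} for "
                    f"respondent {frame['respondent_id'][i]!r}, item {col!r}"
                ) from None
    groups = list(frame["group"]) if "group" in frame.columns else None
    ages = None
    if "age" in frame.columns:
        ages = np.array([float(a) if str(a).strip() else np.nan for a in frame["age"]])
    rm = ResponseMatrix(
        respondent_ids=[str(r) for r in frame["respondent_id"]],
        item_ids=item_cols,
        values=values,
        groups=groups,
        ages=ages,
    )
    if bank is not None:
        rm.validate_against(bank)
    return rm


def write_responses(rm: ResponseMatrix, path: str | Path) -> None:
    path = Path(path)
    data: dict[str, list] = {"respondent_id": list(rm.respondent_ids)}
    if rm.groups is not None:
        data["group"] = list(rm.groups)
    if rm.ages is not None:
        data["age"] = ["" if np.isnan(a) else repr(float(a)) for a in rm.ages]
    for j, iid in enumerate(rm.item_ids):
        col = rm.values[:, j]
        data[iid] = ["" if v == MISSING else str(int(v)) for v in col]
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Recoding and descriptive rates
# ---------------------------------------------------------------------------


def apply_recode(
    bank: ItemBank, rm: ResponseMatrix, maps: Sequence[RecodeMap]
) -> tuple[ItemBank, ResponseMatrix]:
    """Collapse response categories of selected items.

    The recoded items' step difficulties are cleared (marked uncalibrated,
    pending a re-fit); other items and all non-targeted responses are
    untouched. Respondent and item counts never change.
    """
    by_item = {}
    for m in maps:
        if m.item_id in by_item:
            raise SchemaError(f"duplicate recode map for item {m.item_id!r}")
        if m.item_id not in bank:
            raise KeyError(f"recode targets unknown item {m.item_id!r}")
        by_item[m.item_id] = m
    new_items = []
    for it in bank:
        m = by_item.get(it.item_id)
        if m is None:
            new_items.append(it)
            continue
        if m.n_old != it.n_categories:
            raise SchemaError(
                f"recode for {it.item_id!r} covers {m.n_old} categories but the "
                f"item has {it.n_categories}"
            )
        new_items.append(
            replace(it, step_difficulties=None, n_categories=m.n_new)
        )
    new_values = rm.values.copy()
    for iid, m in by_item.items():
        if iid not in rm._col:
            continue
        j = rm._col[iid]
        arr = m.as_array()
        col = new_values[:, j]
        obs = col != MISSING
        if np.any(col[obs] >= m.n_old):
            raise SchemaError(f"responses for {iid!r} exceed the recode map domain")
        col[obs] = arr[col[obs]]
    new_rm = ResponseMatrix(
        respondent_ids=list(rm.respondent_ids),
        item_ids=list(rm.item_ids),
        values=new_values,
        groups=list(rm.groups) if rm.groups is not None else None,
        ages=rm.ages.copy() if rm.ages is not None else None,
    )
    return ItemBank(new_items, name=bank.name), new_rm


def category_response_rates(rm: ResponseMatrix) -> tuple[np.ndarray, pd.DataFrame]:
    """Observed per-category proportions, pooled over items and per item.

    Returns ``(pooled, per_item)``: pooled proportions over all non-missing
    cells (summing to 1) and a DataFrame of per-item proportions indexed by
    item id.
    """
    obs = rm.observed_mask()
    if not obs.any():
        raise SchemaError("all responses missing; no rates to compute")
    max_cat = int(rm.values[obs].max())
    pooled = np.bincount(rm.values[obs].ravel(), minlength=max_cat + 1).astype(float)
    pooled /= pooled.sum()
    rows = {}
    for j, iid in enumerate(rm.item_ids):
        col = rm.values[:, j]
        colobs = col != MISSING
        if colobs.any():
            counts = np.bincount(col[colobs], minlength=max_cat + 1).astype(float)
            rows[iid] = counts / counts.sum()
        else:
            rows[iid] = np.full(max_cat + 1, np.nan)
    per_item = pd.DataFrame.from_dict(rows, orient="index", columns=range(max_cat + 1))
    return pooled, per_item
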