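"""Response-table data model, I/O, response normalisation and accuracy
aggregation.

The canonical in-memory container is a pandas :class:`~pandas.DataFrame`
("response table") with one row per trial and the fixed column order
:data:`COLUMNS`.  :class:`ResponseRecord` is the row-level dataclass; every
public operation accepts either a record list or a table.

A trial records who responded (``rater_id``, ``rater_kind``), when
(``session``, ``block``, ``trial_index``), under which viewing condition
(``presentation``, ``image_condition``), to which stimulus (``stimulus_id``,
``true_category``), and what they answered (``response_label`` as typed or
emitted, ``response_category`` after mapping onto the experiment's category
set).  Free-naming answers that map to no category carry the sentinel
:data:`UNKNOWN`, which participates in agreement analysis as a category of
its own.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dataclass_fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import IntegrityError, SchemaError

__all__ = [
    "COLUMNS",
    "UNKNOWN",
    "RATER_KINDS",
    "SESSIONS",
    "PRESENTATIONS",
    "IMAGE_CONDITIONS",
    "ResponseRecord",
    "records_to_table",
    "table_to_records",
    "validate_table",
    "read_responses",
    "read_response_table",
    "write_responses",
    "read_synonym_map",
    "normalize_free_response",
    "normalize_table",
    "compute_accuracy",
    "split_halves",
    "as_table",
]

#: Canonical CSV / table column order.
COLUMNS = [
    "rater_id",
    "rater_kind",
    "session",
    "presentation",
    "image_condition",
    "block",
    "trial_index",
    "stimulus_id",
    "true_category",
    "response_label",
    "response_category",
]

#: Sentinel category for free-naming answers outside the category set.
UNKNOWN = "UNKNOWN"

RATER_KINDS = frozenset({"human", "model"})
SESSIONS = frozenset({"test", "retest"})
PRESENTATIONS = frozenset({"ms50", "ms200", "self_paced", "none"})
IMAGE_CONDITIONS = frozenset({"isolated", "full", "none"})

#: Columns that jointly identify one trial of one rater.
TRIAL_KEY = ["rater_id", "session", "presentation", "image_condition", "stimulus_id"]


@dataclass(frozen=True)
class ResponseRecord:
    """One trial outcome."""

    rater_id: str
    rater_kind: str
    session: str
    presentation: str
    image_condition: str
    block: int
    trial_index: int
    stimulus_id: str
    true_category: str
    response_label: str
    response_category: str

    def __post_init__(self) -> None:
        if self.rater_kind not in RATER_KINDS:
            raise IntegrityError(f"unknown rater_kind {self.rater_kind!r}")
        if self.session not in SESSIONS:
            raise IntegrityError(f"unknown session {self.session!r}")
        if self.presentation not in PRESENTATIONS:
            raise IntegrityError(f"unknown presentation {self.presentation!r}")
        if self.image_condition not in IMAGE_CONDITIONS:
            raise IntegrityError(f"unknown image_condition {self.image_condition!r}")
        if self.block < 1 or self.trial_index < 1:
            raise IntegrityError("block and trial_index must be positive")


assert [f.name for f in dataclass_fields(ResponseRecord)] == COLUMNS


def records_to_table(records: Iterable[ResponseRecord]) -> pd.DataFrame:
    """Convert a record iterable to the canonical response table."""
    rows = [
        (
            r.rater_id, r.rater_kind, r.session, r.presentation, r.image_condition,
            r.block, r.trial_index, r.stimulus_id, r.true_category,
            r.response_label, r.response_category,
        )
        for r in records
    ]
    df = pd.DataFrame(rows, columns=COLUMNS)
    if df.empty:
        df = _empty_table()
    return df


def table_to_records(table: pd.DataFrame) -> list[ResponseRecord]:
    """Convert a response table to a list of :class:`ResponseRecord`."""
    _require_columns(table)
    return [
        ResponseRecord(
            rater_id=str(row.rater_id),
            rater_kind=str(row.rater_kind),
            session=str(row.session),
            presentation=str(row.presentation),
            image_condition=str(row.image_condition),
            block=int(row.block),
            trial_index=int(row.trial_index),
            stimulus_id=str(row.stimulus_id),
            true_category=str(row.true_category),
            response_label=str(row.response_label),
            response_category=str(row.response_category),
        )
        for row in table.itertuples(index=False)
    ]


def as_table(records: "pd.DataFrame | Iterable[ResponseRecord]") -> pd.DataFrame:
    """Coerce either accepted response representation to a table."""
    if isinstance(records, pd.DataFrame):
        _require_columns(records)
        return records
    return records_to_table(records)


def _empty_table() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in COLUMNS})
    df["block"] = df["block"].astype(int)
    df["trial_index"] = df["trial_index"].astype(int)
    return df


def _require_columns(table: pd.DataFrame) -> None:
    missing = [c for c in COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"response table is missing columns: {missing}")


def validate_table(table: pd.DataFrame, category_set: Sequence[str]) -> None:
    """Validate a response table against the experiment's category set.

    Raises :class:`IntegrityError` naming offending CSV line numbers
    (header = line 1, first data row = line 2).
    """
    _require_columns(table)
    categories = set(category_set)
    problems: list[str] = []

    def lines(mask: pd.Series) -> str:
        idx = (np.flatnonzero(mask.to_numpy()) + 2).tolist()
        shown = ", ".join(map(str, idx[:10]))
        more = f" (+{len(idx) - 10} more)" if len(idx) > 10 else ""
        return shown + more

    for col, allowed in (
        ("rater_kind", RATER_KINDS),
        ("session", SESSIONS),
        ("presentation", PRESENTATIONS),
        ("image_condition", IMAGE_CONDITIONS),
    ):
        bad = ~table[col].isin(allowed)
        if bad.any():
            problems.append(f"invalid {col} value(s) at line(s) {lines(bad)}")

    bad_true = ~table["true_category"].isin(categories)
    if bad_true.any():
        problems.append(
            "true_category outside the category set at line(s) " + lines(bad_true)
        )
    bad_resp = ~table["response_category"].isin(categories | {UNKNOWN})
    if bad_resp.any():
        problems.append(
            "response_category outside the category set (and not UNKNOWN) "
            "at line(s) " + lines(bad_resp)
        )
    for col in ("block", "trial_index"):
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = vals.isna() | (vals < 1)
        if bad.any():
            problems.append(f"non-positive or non-integer {col} at line(s) {lines(bad)}")

    dup = table.duplicated(subset=TRIAL_KEY, keep=False)
    if dup.any():
        problems.append(
            "duplicate (rater, session, presentation, image_condition, stimulus) "
            "key at line(s) " + lines(dup)
        )

    if problems:
        raise IntegrityError("; ".join(problems))


def read_response_table(path: "str | Path", category_set: Sequence[str]) -> pd.DataFrame:
    """Read and validate a response CSV into the canonical table."""
    path = Path(path)
    df = pd.read_csv(path, dtype={c: str for c in COLUMNS if c not in ("block", "trial_index")})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    df = df[COLUMNS]
    validate_table(df, category_set)
    df["block"] = df["block"].astype(int)
    df["trial_index"] = df["trial_index"].astype(int)
    return df


def read_responses(path: "str | Path", category_set: Sequence[str]) -> list[ResponseRecord]:
    """Read a response CSV as a list of :class:`ResponseRecord`."""
    return table_to_records(read_response_table(path, category_set))


def write_responses(
    records: "pd.DataFrame | Iterable[ResponseRecord]", path: "str | Path"
) -> Path:
    """Write responses to UTF-8 CSV in the canonical column order."""
    path = Path(path)
    table = as_table(records)
    table.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
    return path


def read_synonym_map(path: "str | Path") -> dict[str, str]:
    """Read a two-column (alias, category) CSV into a synonym mapping."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: synonym map needs two columns (alias, category)")
    alias_col, cat_col = df.columns[:2]
    return dict(zip(df[alias_col].astype(str), df[cat_col].astype(str)))


def _canonical_lookup(category_set: Sequence[str]) -> dict[str, str]:
    return {c.strip().casefold(): c for c in category_set}


def normalize_free_response(
    raw: str,
    synonym_map: Mapping[str, str],
    category_set: Sequence[str],
) -> str:
    """Map a free-naming answer onto the category set, else :data:`UNKNOWN`.

    Matching is case- and surrounding-whitespace-insensitive.  An exact
    category match wins over the synonym map; synonym-map values must lie in
    the category set.  Total and deterministic: never raises on input text.
    """
    canon = _canonical_lookup(category_set)
    lowered_map: dict[str, str] = {}
    for alias, target in synonym_map.items():
        target_canon = canon.get(str(target).strip().casefold())
        if target_canon is None:
            raise IntegrityError(
                f"synonym map target {target!r} is not in the category set"
            )
        lowered_map[str(alias).strip().casefold()] = target_canon
    key = str(raw).strip().casefold()
    if key in canon:
        return canon[key]
    if key in lowered_map:
        return lowered_map[key]
    return UNKNOWN


def normalize_table(
    table: pd.DataFrame,
    synonym_map: Mapping[str, str],
    category_set: Sequence[str],
) -> pd.DataFrame:
    """Return a copy with ``response_category`` recomputed from
    ``response_label`` via :func:`normalize_free_response`."""
    out = table.copy()
    labels = out["response_label"].astype(str)
    cache: dict[str, str] = {}
    out["response_category"] = [
        cache.setdefault(s, normalize_free_response(s, synonym_map, category_set))
        for s in labels
    ]
    return out


DEFAULT_ACCURACY_KEYS = [
    "rater_id",
    "session",
    "presentation",
    "image_condition",
    "true_category",
]


def compute_accuracy(
    records: "pd.DataFrame | Iterable[ResponseRecord]",
    group_by: "Sequence[str] | None" = None,
    categories: "Sequence[str] | None" = None,
) -> pd.DataFrame:
    """Aggregate correct/total counts and proportions.

    Parameters
    ----------
    records
        Response table or record list; must be non-empty.
    group_by
        Grouping columns; defaults to rater x session x condition x category.
    categories
        Optional full category list.  When given and ``true_category`` is a
        grouping key, missing (rater-condition, category) cells are emitted
        with ``n_trials = 0`` and ``proportion`` NaN rather than dropped.

    Returns
    -------
    DataFrame with the grouping columns (``true_category`` renamed to
    ``category``), ``n_correct``, ``n_trials`` and ``proportion``.
    Proportions are exact count ratios; no rounding is applied.
    """
    table = as_table(records)
    if table.empty:
        raise IntegrityError("compute_accuracy requires a non-empty response table")
    keys = list(group_by) if group_by is not None else list(DEFAULT_ACCURACY_KEYS)
    work = table.copy()
    work["_correct"] = (work["response_category"] == work["true_category"]).astype(int)
    grouped = work.groupby(keys, observed=True, sort=True)["_correct"].agg(
        n_correct="sum", n_trials="count"
    )
    if categories is not None and "true_category" in keys:
        other = [k for k in keys if k != "true_category"]
        if other:
            combos = work[other].drop_duplicates()
            full = combos.merge(pd.DataFrame({"true_category": list(categories)}), how="cross")
            full_index = pd.MultiIndex.from_frame(full[keys])
        else:
            full_index = pd.Index(list(categories), name="true_category")
        grouped = grouped.reindex(full_index, fill_value=0)
    out = grouped.reset_index()
    with np.errstate(invalid="ignore", divide="ignore"):
        out["proportion"] = np.where(
            out["n_trials"] > 0, out["n_correct"] / out["n_trials"], np.nan
        )
    out = out.rename(columns={"true_category": "category"})
    return out


def split_halves(
    records: "pd.DataFrame | Iterable[ResponseRecord]",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split repeated stimulus presentations into first/second occurrence sets.

    Within each (rater, session, image_condition, stimulus) group the trial
    with the smaller ``trial_index`` goes to the first set.  The presentation
    duration is deliberately not part of the key: in a counterbalanced
    two-duration design the two occurrences of one image differ in duration,
    and the carryover question is about exposure order.  Stimuli seen only
    once go entirely to the first set; three or more occurrences raise
    :class:`IntegrityError`.
    """
    table = as_table(records)
    key = ["rater_id", "session", "image_condition", "stimulus_id"]
    ordered = table.sort_values(key + ["trial_index"], kind="mergesort")
    occurrence = ordered.groupby(key, sort=False).cumcount()
    if (occurrence > 1).any():
        bad = ordered.loc[occurrence > 1, "stimulus_id"].unique()[:5].tolist()
        raise IntegrityError(
            f"stimuli presented more than twice per rater/condition: {bad}"
        )
    first = ordered[occurrence == 0]
    second = ordered[occurrence == 1]
    return (
        first.sort_index().reset_index(drop=True),
        second.sort_index().reset_index(drop=True),
    )
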