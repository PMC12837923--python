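"""Ordinal discretisation of per-category accuracies.

A rater's per-category accuracy profile is reduced to a qualitative
triangular matrix: for every ordered category pair (i, j) with i > j the
cell holds one of three relations — the row category performed worse
(``<``), better (``>``) or approximately equally (``=``) relative to the
column category.  The k(k-1)/2 cells in fixed row-major order form a
string signature, giving each rater a discrete "pattern" that can be
counted across a cohort, compared between sessions, and matched between a
model and the human modal pattern.

Two equality criteria are provided:

* ``threshold`` — cells are EQUIV iff |p_i - p_j| <= tau (default
  tau = 0.1, i.e. 3 images out of 30).  Equality is decided before sign.
* ``ci_overlap`` — cells are EQUIV iff the two Wilson score intervals for
  the binomial proportions overlap.

Signatures are read over the configured category order and are not
canonicalised under category permutation: the order is part of the frame
of reference, exactly as in a published triangular-matrix figure.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, ConfigurationError

__all__ = [
    "LESS",
    "GREATER",
    "EQUIV",
    "DiscretisationCriterion",
    "OrdinalPattern",
    "discretise",
    "discretise_accuracy_table",
    "pattern_signature",
    "signature_to_pattern",
    "pattern_frequencies",
    "modal_pattern",
    "session_consistency",
    "match_model_to_human",
]

LESS = "<"
GREATER = ">"
EQUIV = "="
_RELATIONS = (LESS, GREATER, EQUIV)


@dataclass(frozen=True)
class DiscretisationCriterion:
    """How two binomial proportions are declared approximately equal."""

    mode: str = "threshold"
    tolerance: float = 0.1
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.mode not in ("threshold", "ci_overlap"):
            raise ConfigurationError(f"unknown criterion mode {self.mode!r}")
        if not (0.0 <= self.tolerance <= 1.0):
            raise ConfigurationError("tolerance must lie in [0, 1]")
        if not (0.0 < self.ci_level < 1.0):
            raise ConfigurationError("ci_level must lie in (0, 1)")


@dataclass(frozen=True)
class OrdinalPattern:
    """Strictly-lower-triangular relation matrix over an ordered category list.

    ``cells[m]`` is the relation for pair (i, j), i > j, enumerated
    row-major: (1,0), (2,0), (2,1), (3,0), ...  Cell (i, j) reads "category
    i versus category j"; the implied reverse relation is its inverse
    (LESS <-> GREATER, EQUIV <-> EQUIV).
    """

    categories: tuple[str, ...]
    cells: tuple[str, ...]

    def __post_init__(self) -> None:
        k = len(self.categories)
        expected = k * (k - 1) // 2
        if len(self.cells) != expected:
            raise ConfigurationError(
                f"{k} categories need {expected} cells, got {len(self.cells)}"
            )
        bad = [c for c in self.cells if c not in _RELATIONS]
        if bad:
            raise ConfigurationError(f"invalid relation symbols: {bad[:3]}")

    @property
    def signature(self) -> str:
        return "".join(self.cells)

    def relation(self, i: int, j: int) -> str:
        """Relation of category index ``i`` versus ``j`` (any i != j)."""
        if i == j:
            raise ValueError("no self-relation")
        if i > j:
            return self.cells[i * (i - 1) // 2 + j]
        inverse = {LESS: GREATER, GREATER: LESS, EQUIV: EQUIV}
        return inverse[self.cells[j * (j - 1) // 2 + i]]


def _pair_indices(k: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(1, k) for j in range(i)]


def discretise(
    counts: "Sequence[tuple[int, int]] | Mapping[str, tuple[int, int]]",
    criterion: DiscretisationCriterion = DiscretisationCriterion(),
    categories: "Sequence[str] | None" = None,
) -> OrdinalPattern:
    """Discretise per-category (n_correct, n_trials) pairs into a pattern.

    ``counts`` is either a sequence ordered like ``categories`` or a mapping
    keyed by category.  Every category needs at least one trial.  In
    threshold mode a pair is EQUIV iff the absolute proportion difference is
    within the band (inclusive), *before* any sign comparison; in
    ci_overlap mode iff the two Wilson score intervals intersect.
    """
    if isinstance(counts, Mapping):
        if categories is None:
            categories = tuple(counts.keys())
        pairs = [counts[c] for c in categories]
    else:
        pairs = list(counts)
        if categories is None:
            categories = tuple(f"C{i + 1}" for i in range(len(pairs)))
    cats = tuple(categories)
    if len(cats) < 2:
        raise ConfigurationError("need at least two categories")
    if len(pairs) != len(cats):
        raise AlignmentError("counts and category list have different lengths")
    n_correct = np.array([c for c, _ in pairs], dtype=float)
    n_trials = np.array([n for _, n in pairs], dtype=float)
    if np.any(n_trials <= 0):
        zero = [cats[i] for i in np.flatnonzero(n_trials <= 0)]
        raise ConfigurationError(f"zero-trial category/ies: {zero}")
    if np.any(n_correct < 0) or np.any(n_correct > n_trials):
        raise ConfigurationError("n_correct must lie in [0, n_trials]")
    p = n_correct / n_trials

    if criterion.mode == "ci_overlap":
        from statsmodels.stats.proportion import proportion_confint

        lo, hi = proportion_confint(
            n_correct, n_trials, alpha=1 - criterion.ci_level, method="wilson"
        )
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)

    ii, jj = np.tril_indices(len(cats), k=-1)  # row-major (1,0),(2,0),(2,1),...
    if criterion.mode == "threshold":
        equal = np.abs(p[ii] - p[jj]) <= criterion.tolerance + 1e-15
    else:
        equal = (lo[ii] <= hi[jj] + 1e-15) & (lo[jj] <= hi[ii] + 1e-15)
    cells = np.where(equal, EQUIV, np.where(p[ii] < p[jj], LESS, GREATER))
    return OrdinalPattern(categories=cats, cells=tuple(cells.tolist()))


def discretise_accuracy_table(
    accuracy: pd.DataFrame,
    categories: Sequence[str],
    criterion: DiscretisationCriterion = DiscretisationCriterion(),
    group_cols: Sequence[str] = ("rater_id", "session"),
) -> pd.DataFrame:
    """Discretise an accuracy table into one pattern per rater group.

    ``accuracy`` is a table with columns ``category``, ``n_correct``,
    ``n_trials`` plus the ``group_cols``.  Returns one row per group with
    the pattern object and its signature.
    """
    keys = [c for c in group_cols if c in accuracy.columns]
    rows = []
    for key, grp in accuracy.groupby(keys, observed=True, sort=True):
        counts = {
            r.category: (int(r.n_correct), int(r.n_trials))
            for r in grp.itertuples(index=False)
        }
        missing = [c for c in categories if c not in counts]
        if missing:
            raise AlignmentError(f"group {key!r} lacks categories {missing}")
        pat = discretise(counts, criterion, categories=categories)
        key_tuple = key if isinstance(key, tuple) else (key,)
        rows.append((*key_tuple, pat, pat.signature))
    return pd.DataFrame(rows, columns=list(keys) + ["pattern", "signature"])


def pattern_signature(pattern: OrdinalPattern) -> str:
    """Canonical row-major string encoding of a pattern's cells."""
    return pattern.signature


def signature_to_pattern(signature: str, categories: Sequence[str]) -> OrdinalPattern:
    """Inverse of :func:`pattern_signature` for a given category order."""
    return OrdinalPattern(categories=tuple(categories), cells=tuple(signature))


def _check_shared_order(patterns: Sequence[OrdinalPattern]) -> tuple[str, ...]:
    orders = {p.categories for p in patterns}
    if len(orders) != 1:
        raise AlignmentError("patterns use different category orders")
    return next(iter(orders))


def pattern_frequencies(patterns: Sequence[OrdinalPattern]) -> pd.DataFrame:
    """Ranked table of unique signatures: count desc, ties lexicographic."""
    pats = list(patterns)
    if not pats:
        raise ConfigurationError("no patterns supplied")
    _check_shared_order(pats)
    tally = Counter(p.signature for p in pats)
    rows = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    out = pd.DataFrame(rows, columns=["signature", "count"])
    out["proportion"] = out["count"] / len(pats)
    return out


def modal_pattern(
    patterns: Sequence[OrdinalPattern],
) -> tuple[list[OrdinalPattern], float]:
    """Most frequent pattern(s) and the cohort proportion carrying them.

    All tied top signatures are returned, in lexicographic order.
    """
    pats = list(patterns)
    if not pats:
        raise ConfigurationError("no patterns supplied")
    cats = _check_shared_order(pats)
    freq = pattern_frequencies(pats)
    top = int(freq["count"].iloc[0])
    winners = sorted(freq.loc[freq["count"] == top, "signature"])
    proportion = top / len(pats)
    return [signature_to_pattern(s, cats) for s in winners], proportion


def session_consistency(
    test_patterns: Mapping[str, OrdinalPattern],
    retest_patterns: Mapping[str, OrdinalPattern],
) -> tuple[float, pd.Series, list[str]]:
    """Fraction of participants whose signature is identical across sessions.

    Returns ``(proportion, per_participant_indicator, exclusions)``;
    participants present in only one session land in ``exclusions``.
    """
    shared = sorted(set(test_patterns) & set(retest_patterns))
    exclusions = sorted(
        (set(test_patterns) | set(retest_patterns)) - set(shared)
    )
    if not shared:
        raise AlignmentError("no participant appears in both sessions")
    _check_shared_order(
        [test_patterns[r] for r in shared] + [retest_patterns[r] for r in shared]
    )
    indicator = pd.Series(
        {r: test_patterns[r].signature == retest_patterns[r].signature for r in shared},
        name="consistent",
    )
    return float(indicator.mean()), indicator, exclusions


def match_model_to_human(
    model_pattern: OrdinalPattern,
    human_patterns: Sequence[OrdinalPattern],
) -> dict:
    """Match a model's pattern against a human cohort's patterns.

    Returns a dict with:

    * ``exact_match_to_modal`` — signature identical to the (first, in
      lexicographic tie order) human modal signature;
    * ``cell_overlap_with_modal`` — fraction of the k(k-1)/2 cells agreeing
      with that modal signature;
    * ``rank_of_model_signature`` — 1-based rank of the model's signature in
      the human frequency table, or None if absent.
    """
    pats = list(human_patterns)
    if not pats:
        raise ConfigurationError("no human patterns supplied")
    cats = _check_shared_order(pats)
    if model_pattern.categories != cats:
        raise AlignmentError("model pattern uses a different category order")
    winners, modal_prop = modal_pattern(pats)
    modal_sig = winners[0].signature
    model_sig = model_pattern.signature
    overlap = float(np.mean([a == b for a, b in zip(model_sig, modal_sig)]))
    freq = pattern_frequencies(pats)
    where = freq.index[freq["signature"] == model_sig]
    rank = int(where[0]) + 1 if len(where) else None
    return {
        "exact_match_to_modal": model_sig == modal_sig,
        "cell_overlap_with_modal": overlap,
        "rank_of_model_signature": rank,
        "modal_signature": modal_sig,
        "modal_proportion": modal_prop,
        "model_signature": model_sig,
    }
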