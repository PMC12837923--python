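"""Chance-corrected trial-by-trial agreement.

Implements unweighted Cohen's kappa between two aligned label sequences,
with the Fleiss-Cohen-Everitt large-sample standard error and a Wald
confidence interval, plus the Landis-Koch qualitative bands, pairwise
agreement matrices, and per-participant test-retest (intra-rater)
reliability.

kappa = (p_o - p_e) / (1 - p_e), where p_o is the observed proportion of
agreeing trials and p_e the agreement expected from the two raters'
marginal label frequencies.  The label universe is the union of labels
observed in either sequence; the UNKNOWN sentinel is a first-class label,
so open-vocabulary (free-naming) raters remain comparable with fixed-
vocabulary ones.

Degenerate marginals are resolved explicitly: two constant, identical
sequences give kappa = 1 (flagged), two constant but different sequences
give kappa = 0 (flagged); both are 0/0-adjacent corners of the formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
import pandas as pd

from .exceptions import AlignmentError

__all__ = [
    "KappaResult",
    "cohen_kappa",
    "kappa_band",
    "pairwise_agreement_matrix",
    "kappa_matrix_values",
    "pooled_pairwise_kappa",
    "intra_rater_reliability",
    "align_rater_sequences",
]

_ESTIMATOR = "unweighted kappa; Fleiss-Cohen-Everitt SE; Wald CI"


@dataclass(frozen=True)
class KappaResult:
    """Chance-corrected agreement estimate with uncertainty and band."""

    kappa: float
    observed_agreement: float
    expected_agreement: float
    n_items: int
    standard_error: float
    ci_low: float
    ci_high: float
    ci_level: float = 0.95
    band: str = ""
    degenerate_marginals: bool = False
    method: str = _ESTIMATOR


def kappa_band(kappa: float) -> str:
    """Landis-Koch qualitative interpretation of a kappa value."""
    if not np.isfinite(kappa) or kappa < -1 - 1e-9 or kappa > 1 + 1e-9:
        raise ValueError(f"kappa {kappa!r} outside [-1, 1]")
    eps = 1e-9  # float noise in the estimate must not flip a band
    if kappa <= 0 + eps:
        return "no"
    if kappa <= 0.20 + eps:
        return "slight"
    if kappa <= 0.40 + eps:
        return "fair"
    if kappa <= 0.60 + eps:
        return "moderate"
    if kappa <= 0.80 + eps:
        return "substantial"
    return "almost_perfect"


def _contingency(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, list]:
    labels = sorted(set(a.tolist()) | set(b.tolist()), key=str)
    index = {lab: i for i, lab in enumerate(labels)}
    k = len(labels)
    ai = np.fromiter((index[x] for x in a), dtype=np.intp, count=len(a))
    bi = np.fromiter((index[x] for x in b), dtype=np.intp, count=len(b))
    counts = np.zeros((k, k))
    np.add.at(counts, (ai, bi), 1.0)
    return counts, labels


def _kappa_from_counts(counts: np.ndarray, ci_level: float) -> KappaResult:
    from scipy.stats import norm

    n = counts.sum()
    p = counts / n
    row_counts = counts.sum(axis=1)
    col_counts = counts.sum(axis=0)
    # compute p_o/p_e from count sums so exact cases stay exact in floats
    po = float(np.trace(counts) / n)
    pe = float((row_counts @ col_counts) / (n * n))
    row = row_counts / n
    col = col_counts / n
    degenerate = bool(np.any(row >= 1.0) or np.any(col >= 1.0))

    if pe >= 1.0 - 1e-15:
        kappa = 1.0 if po >= 1.0 - 1e-15 else 0.0
        return KappaResult(
            kappa=kappa, observed_agreement=po, expected_agreement=pe,
            n_items=int(n), standard_error=0.0, ci_low=kappa, ci_high=kappa,
            ci_level=ci_level, band=kappa_band(kappa), degenerate_marginals=True,
        )
    kappa = (po - pe) / (1.0 - pe)

    # Fleiss, Cohen & Everitt large-sample variance of the kappa estimate.
    diag = np.diag(p)
    a_term = float(
        np.sum(diag * ((1 - pe) - (row + col) * (1 - po)) ** 2)
    )
    weights = (col[:, None] + row[None, :]) ** 2  # cell (i, j): (p_.i + p_j.)^2
    b_all = float(np.sum(p * weights))
    b_diag = float(np.sum(diag * (col + row) ** 2))
    b_term = (1 - po) ** 2 * (b_all - b_diag)
    c_term = (po * pe - 2 * pe + po) ** 2
    var = max((a_term + b_term - c_term) / (n * (1 - pe) ** 4), 0.0)
    se = float(np.sqrt(var))
    z = norm.ppf(0.5 + ci_level / 2.0)
    lo = max(kappa - z * se, -1.0)
    hi = min(kappa + z * se, 1.0)
    return KappaResult(
        kappa=float(kappa), observed_agreement=po, expected_agreement=pe,
        n_items=int(n), standard_error=se,
        ci_low=min(lo, kappa), ci_high=max(hi, kappa), ci_level=ci_level,
        band=kappa_band(float(kappa)), degenerate_marginals=degenerate,
    )


def cohen_kappa(
    responses_a: Sequence[Hashable],
    responses_b: Sequence[Hashable],
    ci_level: float = 0.95,
) -> KappaResult:
    """Unweighted Cohen's kappa between two aligned label sequences.

    The sequences must be the same length (>= 2) and aligned item by item
    (same stimulus order); misalignment is the caller's responsibility to
    prevent, typically via :func:`align_rater_sequences`.
    """
    a = np.asarray(list(responses_a), dtype=object)
    b = np.asarray(list(responses_b), dtype=object)
    if len(a) != len(b):
        raise AlignmentError(f"sequence lengths differ: {len(a)} vs {len(b)}")
    if len(a) < 2:
        raise AlignmentError("kappa needs at least two aligned items")
    counts, _ = _contingency(a, b)
    return _kappa_from_counts(counts, ci_level)


def align_rater_sequences(
    table: pd.DataFrame,
    rater_ids: "Sequence[str] | None" = None,
    session: "str | None" = "test",
) -> pd.DataFrame:
    """Pivot a response table to a (stimulus x rater) label matrix.

    Restricts to one session if ``session`` is given.  Raises
    :class:`AlignmentError` when raters do not share an identical stimulus
    set (the aligned frame would contain holes).
    """
    df = table if session is None else table[table["session"] == session]
    if rater_ids is not None:
        df = df[df["rater_id"].isin(list(rater_ids))]
    if df.empty:
        raise AlignmentError("no responses to align")
    wide = df.pivot_table(
        index="stimulus_id", columns="rater_id", values="response_category",
        aggfunc="first",
    )
    if wide.isna().any().any():
        missing = wide.columns[wide.isna().any()].tolist()[:5]
        raise AlignmentError(f"raters with incomplete stimulus coverage: {missing}")
    return wide


def pairwise_agreement_matrix(
    raters: Sequence[tuple[str, Sequence[Hashable]]],
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Symmetric matrix of :class:`KappaResult` for every rater pair.

    Diagonal entries compare a rater with themselves (kappa = 1).  All
    sequences must be aligned on the same stimulus set and equal length.
    """
    ids = [rid for rid, _ in raters]
    if len(set(ids)) != len(ids):
        raise AlignmentError("duplicate rater ids")
    lengths = {len(seq) for _, seq in raters}
    if len(lengths) > 1:
        raise AlignmentError(f"sequences have differing lengths: {sorted(lengths)}")
    mat = pd.DataFrame(index=ids, columns=ids, dtype=object)
    for i, (rid_a, seq_a) in enumerate(raters):
        for rid_b, seq_b in raters[i:]:
            res = cohen_kappa(seq_a, seq_b, ci_level=ci_level)
            mat.loc[rid_a, rid_b] = res
            mat.loc[rid_b, rid_a] = res
    return mat


def _code_matrix(wide: pd.DataFrame) -> tuple[np.ndarray, int]:
    labels = sorted(pd.unique(wide.to_numpy().ravel()).tolist(), key=str)
    index = {lab: i for i, lab in enumerate(labels)}
    codes = wide.apply(lambda col: col.map(index)).to_numpy().T  # raters x items
    return codes.astype(np.intp), len(labels)


def kappa_matrix_values(wide: pd.DataFrame) -> pd.DataFrame:
    """Vectorised pairwise kappa point estimates.

    ``wide`` is a (stimulus x rater) label frame as produced by
    :func:`align_rater_sequences`.  Returns a float rater x rater matrix;
    equivalent to calling :func:`cohen_kappa` per pair but fast enough for
    hundreds of raters.
    """
    codes, n_labels = _code_matrix(wide)
    n_raters, n_items = codes.shape
    agree = np.zeros((n_raters, n_raters))
    marg = np.zeros((n_raters, n_labels))
    for lab in range(n_labels):
        ind = (codes == lab).astype(float)
        agree += ind @ ind.T
        marg[:, lab] = ind.sum(axis=1)
    po = agree / n_items
    pe = (marg @ marg.T) / (n_items**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        kap = (po - pe) / (1.0 - pe)
    kap[pe >= 1.0 - 1e-15] = np.where(
        po[pe >= 1.0 - 1e-15] >= 1.0 - 1e-15, 1.0, 0.0
    )
    np.fill_diagonal(kap, 1.0)
    return pd.DataFrame(kap, index=wide.columns, columns=wide.columns)


def pooled_pairwise_kappa(wide: pd.DataFrame, ci_level: float = 0.95) -> KappaResult:
    """Kappa over the pooled trials of all unordered rater pairs.

    Builds the summed two-rater contingency table over every pair (i < j)
    and every stimulus, then applies the standard kappa formula.  Because
    pairs are unordered, each pair contributes its table symmetrised (the
    result is invariant to rater ordering).  This is one of the two
    cohort-level summaries emitted for inter-rater agreement (the other
    being the distribution of per-pair values).
    """
    codes, n_labels = _code_matrix(wide)
    n_raters, n_items = codes.shape
    if n_raters < 2:
        raise AlignmentError("pooled pairwise kappa needs at least two raters")
    counts = np.zeros((n_labels, n_labels))
    for t in range(n_items):
        c = np.bincount(codes[:, t], minlength=n_labels).astype(float)
        counts += np.outer(c, c)
        counts[np.diag_indices(n_labels)] -= c
    counts /= 2.0  # unordered pairs
    return _kappa_from_counts(counts, ci_level)


def intra_rater_reliability(
    test_records: pd.DataFrame,
    retest_records: pd.DataFrame,
    ci_level: float = 0.95,
) -> tuple[pd.DataFrame, float, list[str]]:
    """Per-participant test-retest kappa and the cohort median.

    Responses are aligned by stimulus within each participant.  Participants
    missing a session, or with mismatched stimulus sets, are returned in the
    exclusions list rather than silently dropped.

    Returns ``(per_participant, median_kappa, exclusions)`` where
    ``per_participant`` has one row per retained participant with kappa,
    SE, CI bounds, band and item count.
    """
    from .records import as_table

    test = as_table(test_records)
    retest = as_table(retest_records)
    raters = sorted(set(test["rater_id"]) | set(retest["rater_id"]))
    rows = []
    exclusions: list[str] = []
    t_groups = dict(tuple(test.groupby("rater_id", sort=False)))
    r_groups = dict(tuple(retest.groupby("rater_id", sort=False)))
    for rid in raters:
        t = t_groups.get(rid)
        r = r_groups.get(rid)
        if t is None or r is None:
            exclusions.append(rid)
            continue
        t_seq = t.set_index("stimulus_id")["response_category"]
        r_seq = r.set_index("stimulus_id")["response_category"]
        if set(t_seq.index) != set(r_seq.index):
            exclusions.append(rid)
            continue
        r_seq = r_seq.reindex(t_seq.index)
        res = cohen_kappa(t_seq.to_numpy(), r_seq.to_numpy(), ci_level=ci_level)
        rows.append(
            (rid, res.kappa, res.standard_error, res.ci_low, res.ci_high,
             res.band, res.n_items, res.degenerate_marginals)
        )
    per_participant = pd.DataFrame(
        rows,
        columns=["rater_id", "kappa", "standard_error", "ci_low", "ci_high",
                 "band", "n_items", "degenerate_marginals"],
    )
    median = float(per_participant["kappa"].median()) if len(per_participant) else float("nan")
    return per_participant, median, exclusions
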