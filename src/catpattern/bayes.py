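"""JZS (Jeffreys-Zellner-Siow) default Bayes-factor t-tests.

The alternative hypothesis places a Cauchy(0, r) prior on the standardised
effect size delta; the null fixes delta = 0.  The Bayes factor BF10 is the
ratio of marginal likelihoods of the observed t statistic, computed as the
one-dimensional JZS integral over the prior-variance multiplier g
(equivalent to integrating the noncentral-t likelihood over the Cauchy
effect-size prior):

    BF10 = integral over g of (1+Ng)^(-1/2)
           * [ (1 + t^2/((1+Ng) nu)) / (1 + t^2/nu) ]^(-(nu+1)/2)
           * InvGamma(g; 1/2, r^2/2) dg

where nu is the degrees of freedom and N the effective sample size (n for
one-sample/paired designs, n1*n2/(n1+n2) for two-sample).  The integrand is
a likelihood *ratio*, evaluated by adaptive quadrature over log g with
log-space shifting, so arbitrarily large |t| and nu cannot overflow.  BF10
depends on the data only through t, so it is invariant to rescaling the
inputs.

The default prior scale r = sqrt(2)/2 ~ 0.707 is the conventional "medium"
default of the Bayesian t-test family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, ConfigurationError

__all__ = [
    "DEFAULT_PRIOR_SCALE",
    "BayesFactorResult",
    "jzs_bf_from_t",
    "jzs_bf_paired",
    "jzs_bf_one_sample",
    "jzs_bf_two_sample",
    "bf_evidence_label",
    "compare_accuracies",
]

DEFAULT_PRIOR_SCALE = math.sqrt(2.0) / 2.0


@dataclass(frozen=True)
class BayesFactorResult:
    """A JZS Bayes factor with its provenance."""

    bf10: float
    t_statistic: float
    n1: int
    n2: "int | None"
    prior_scale: float
    log_marginal_alt: float
    log_marginal_null: float
    grade: str
    marks: str

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


def bf_evidence_label(bf10: float) -> tuple[str, str]:
    """Evidence grade and significance marks for a Bayes factor.

    Marks follow the BF > 3 / 10 / 100 convention ("*", "**", "***");
    grades follow Jeffreys-style bands, symmetric around BF = 1 (e.g.
    1/10 < BF < 1/3 is moderate evidence for the null, 1/3 < BF < 1
    anecdotal evidence for no effect, BF = 1 inconclusive).
    """
    if math.isnan(bf10) or bf10 <= 0:
        raise ValueError(f"bf10 must be a positive number, got {bf10!r}")
    marks = "***" if bf10 > 100 else "**" if bf10 > 10 else "*" if bf10 > 3 else ""
    if bf10 == 1.0:
        return "inconclusive", marks
    if bf10 > 1:
        if bf10 <= 3:
            grade = "anecdotal_h1"
        elif bf10 <= 10:
            grade = "moderate_h1"
        elif bf10 <= 30:
            grade = "strong_h1"
        elif bf10 <= 100:
            grade = "very_strong_h1"
        else:
            grade = "extreme_h1"
    else:
        inv = 1.0 / bf10
        if inv <= 3:
            grade = "anecdotal_h0"
        elif inv <= 10:
            grade = "moderate_h0"
        elif inv <= 30:
            grade = "strong_h0"
        elif inv <= 100:
            grade = "very_strong_h0"
        else:
            grade = "extreme_h0"
    return grade, marks


def _log_bf10(t: float, df: float, n_eff: float, r: float) -> float:
    """Log Bayes factor via the JZS integral over the prior-variance
    multiplier g (Cauchy-on-delta marginalised analytically to an
    inverse-gamma(1/2, r^2/2) mixing density).

    The integrand is the *ratio* of alternative to null likelihoods, so the
    computation stays bounded in log space for arbitrarily large |t| and
    df.  Quadrature runs over z = log g (an unbounded smooth transform),
    split at a grid-located mode.
    """
    from scipy import integrate

    t2 = t * t
    log_null_term = (df + 1) / 2.0 * math.log1p(t2 / df)
    log_prior_const = math.log(r) - 0.5 * math.log(2.0 * math.pi)

    def log_integrand(z: float) -> float:
        if abs(z) > 700.0:  # beyond float exp range: zero mass either way
            return -math.inf
        g = math.exp(z)
        log_ratio = (
            -0.5 * math.log1p(n_eff * g)
            + log_null_term
            - (df + 1) / 2.0 * math.log1p(t2 / ((1.0 + n_eff * g) * df))
        )
        # inverse-gamma(1/2, r^2/2) prior density in g, times Jacobian g
        log_prior = log_prior_const - 1.5 * z - r * r / (2.0 * g)
        return log_ratio + log_prior + z

    zs = np.linspace(-40.0, 40.0, 161)
    vals = np.array([log_integrand(z) for z in zs])
    peak = float(zs[int(np.argmax(vals))])
    shift = float(vals.max())

    def integrand(z: float) -> float:
        return math.exp(log_integrand(z) - shift)

    left, _ = integrate.quad(
        integrand, -np.inf, peak, epsabs=1e-12, epsrel=1e-10, limit=300
    )
    right, _ = integrate.quad(
        integrand, peak, np.inf, epsabs=1e-12, epsrel=1e-10, limit=300
    )
    return shift + math.log(left + right)


def jzs_bf_from_t(
    t: float,
    n1: int,
    n2: "int | None" = None,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
) -> BayesFactorResult:
    """Bayes factor from a t statistic and sample size(s).

    ``n2 = None`` means a one-sample/paired design (nu = n1 - 1, N = n1);
    otherwise an independent two-sample design (nu = n1 + n2 - 2,
    N = n1 n2 / (n1 + n2)).
    """
    from scipy import stats

    if not math.isfinite(t):
        raise ValueError("t statistic must be finite")
    if prior_scale <= 0:
        raise ValueError("prior_scale must be positive")
    if n2 is None:
        if n1 < 2:
            raise ValueError("one-sample design needs n >= 2")
        df, n_eff = n1 - 1, float(n1)
    else:
        if n1 < 2 or n2 < 2:
            raise ValueError("two-sample design needs n1, n2 >= 2")
        df, n_eff = n1 + n2 - 2, n1 * n2 / (n1 + n2)
    log_bf = _log_bf10(float(t), float(df), n_eff, float(prior_scale))
    log_m0 = float(stats.t.logpdf(t, df))
    log_m1 = log_bf + log_m0
    with np.errstate(over="ignore"):
        bf10 = float(np.exp(log_bf))  # overflows to inf; log marginals stay exact
    grade, marks = bf_evidence_label(bf10)
    return BayesFactorResult(
        bf10=bf10, t_statistic=float(t), n1=int(n1),
        n2=None if n2 is None else int(n2), prior_scale=float(prior_scale),
        log_marginal_alt=log_m1, log_marginal_null=log_m0,
        grade=grade, marks=marks,
    )


def _check_finite(x: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")


def jzs_bf_paired(
    differences: Sequence[float],
    prior_scale: float = DEFAULT_PRIOR_SCALE,
) -> BayesFactorResult:
    """Paired-samples JZS Bayes factor from per-unit differences."""
    d = np.asarray(list(differences), dtype=float)
    if d.size < 2:
        raise ValueError("paired test needs at least two differences")
    _check_finite(d, "differences")
    sd = float(d.std(ddof=1))
    mean = float(d.mean())
    if sd == 0.0:
        if mean != 0.0:
            raise ValueError(
                "all differences identical and nonzero: t is unbounded"
            )
        t = 0.0
    else:
        t = mean / (sd / math.sqrt(d.size))
    return jzs_bf_from_t(t, n1=d.size, prior_scale=prior_scale)


def jzs_bf_one_sample(
    x: Sequence[float],
    mu0: float = 0.0,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
) -> BayesFactorResult:
    """One-sample JZS Bayes factor against a known constant ``mu0``."""
    arr = np.asarray(list(x), dtype=float)
    return jzs_bf_paired(arr - mu0, prior_scale=prior_scale)


def jzs_bf_two_sample(
    x: Sequence[float],
    y: Sequence[float],
    prior_scale: float = DEFAULT_PRIOR_SCALE,
) -> BayesFactorResult:
    """Independent two-sample JZS Bayes factor (pooled-variance t)."""
    a = np.asarray(list(x), dtype=float)
    b = np.asarray(list(y), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("two-sample test needs n1, n2 >= 2")
    _check_finite(a, "x")
    _check_finite(b, "y")
    n1, n2 = a.size, b.size
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    denom = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = float(a.mean() - b.mean())
    if denom == 0.0:
        if diff != 0.0:
            raise ValueError("zero pooled variance with unequal means: t unbounded")
        t = 0.0
    else:
        t = diff / denom
    return jzs_bf_from_t(t, n1=n1, n2=n2, prior_scale=prior_scale)


def compare_accuracies(
    human_table: pd.DataFrame,
    model_table: pd.DataFrame,
    scope: str = "category",
    test: str = "one_sample",
    prior_scale: float = DEFAULT_PRIOR_SCALE,
) -> pd.DataFrame:
    """Bayes-factor comparison of human and model accuracies.

    ``human_table`` and ``model_table`` are accuracy tables (one row per
    rater x condition x category, as produced by
    :func:`catpattern.records.compute_accuracy`).  With
    ``test='one_sample'`` the model's accuracy is treated as a known
    constant and participant-level accuracies are tested against it; with
    ``test='two_sample'`` model raters form a second sample (requires at
    least two model raters per cell).

    ``scope='category'`` yields one row per model x condition x category;
    ``scope='overall'`` aggregates counts over categories first.  Each row
    records t, BF10, the evidence grade/marks, the direction of the numeric
    difference, and which test variant was used.
    """
    if scope not in ("category", "overall"):
        raise ConfigurationError(f"unknown scope {scope!r}")
    if test not in ("one_sample", "two_sample"):
        raise ConfigurationError(f"unknown test {test!r}")

    cond_cols = [
        c for c in ("presentation", "image_condition")
        if c in human_table.columns and c in model_table.columns
    ]
    cell_cols = cond_cols + (["category"] if scope == "category" else [])

    def collapse(table: pd.DataFrame) -> pd.DataFrame:
        keys = ["rater_id"] + cell_cols
        agg = table.groupby(keys, observed=True, sort=True)[
            ["n_correct", "n_trials"]
        ].sum().reset_index()
        agg["proportion"] = agg["n_correct"] / agg["n_trials"]
        return agg

    humans = collapse(human_table)
    models = collapse(model_table)

    if scope == "category":
        h_cats = set(humans["category"])
        m_cats = set(models["category"])
        if h_cats != m_cats:
            raise AlignmentError(
                f"category sets differ: only-human={sorted(h_cats - m_cats)}, "
                f"only-model={sorted(m_cats - h_cats)}"
            )

    rows = []
    for model_id, m_rows in models.groupby("rater_id", sort=True):
        cells = m_rows[cell_cols].drop_duplicates() if cell_cols else pd.DataFrame([{}])
        for _, cell in cells.iterrows():
            h_mask = pd.Series(True, index=humans.index)
            m_mask = pd.Series(True, index=models.index)
            for c in cell_cols:
                h_mask &= humans[c] == cell[c]
                m_mask &= models[c] == cell[c]
            h_vals = humans.loc[h_mask, "proportion"].to_numpy()
            if h_vals.size == 0:
                raise AlignmentError(f"no human data for cell {dict(cell)}")
            if test == "one_sample":
                m_val = float(
                    models.loc[m_mask & (models["rater_id"] == model_id), "proportion"].iloc[0]
                )
                res = jzs_bf_one_sample(h_vals, mu0=m_val, prior_scale=prior_scale)
            else:
                m_vals = models.loc[m_mask, "proportion"].to_numpy()
                if m_vals.size < 2:
                    raise ConfigurationError(
                        "two_sample comparison needs at least two model raters"
                    )
                m_val = float(m_vals.mean())
                res = jzs_bf_two_sample(h_vals, m_vals, prior_scale=prior_scale)
            direction = (
                "human_higher" if h_vals.mean() > m_val
                else "model_higher" if h_vals.mean() < m_val
                else "equal"
            )
            row = {c: cell[c] for c in cell_cols}
            row.update(
                model_id=model_id, n_humans=int(h_vals.size),
                human_mean=float(h_vals.mean()), model_value=m_val,
                direction=direction, t_statistic=res.t_statistic,
                bf10=res.bf10, grade=res.grade, marks=res.marks,
                test=test, prior_scale=prior_scale,
            )
            rows.append(row)
    out = pd.DataFrame(rows)
    front = ["model_id"] + cell_cols
    return out[front + [c for c in out.columns if c not in front]]
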