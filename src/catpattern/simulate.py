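"""Synthetic experiment schedules and cohorts.

This module replaces non-public human data with cohorts of known
ground-truth structure.  A :class:`DesignSpec` describes the trial schedule
(categories, images per category, presentation durations, blocks,
counterbalancing); a :class:`CohortSpec` describes the population
(latent subgroups with per-category accuracy profiles, a confusion kernel
for wrong answers, and a test-retest stability mechanism).

The generator is purely statistical: a participant answers each trial
correctly with probability equal to their profile entry for the stimulus
category, and otherwise emits a wrong label drawn from the category's
confusion kernel.  It emulates the input *structure* of a two-session
brief-presentation categorisation study — it does not model perception
(masking dynamics, per-image difficulty, fatigue).

Everything is a pure function of the specs: the same seed yields a
byte-identical table.  Per-participant random substreams are derived by
stable hashing of the rater id, so cohorts are reproducible regardless of
generation order.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .records import COLUMNS, UNKNOWN

__all__ = [
    "DEFAULT_CATEGORIES",
    "TWO_DURATION_CATEGORIES",
    "DesignSpec",
    "Subgroup",
    "CohortSpec",
    "make_counterbalanced_design",
    "generate_cohort",
    "generate_model_rater",
    "plant_modal_scenario",
    "default_retest_design",
    "default_two_duration_design",
    "default_cohort_spec",
]

#: Nine-category stimulus set of the two-session retest study, ordered
#: hard -> moderate -> easy.
DEFAULT_CATEGORIES = (
    "Plate", "Vase", "Basket", "TV", "Helmet", "Mug", "Banana", "Match", "Plunger",
)

#: Ten-category set of the two-duration forced-choice study.
TWO_DURATION_CATEGORIES = (
    "Plate", "Vase", "Basket", "TV", "Doormat", "Helmet", "Mug",
    "Drill", "Plunger", "Safety pin",
)


def _stimulus_ids(category: str, n: int) -> list[str]:
    stem = category.lower().replace(" ", "_")
    return [f"{stem}_{i:03d}" for i in range(1, n + 1)]


@dataclass(frozen=True)
class DesignSpec:
    """Trial-schedule description for one session."""

    categories: tuple[str, ...]
    n_images_per_category: int
    presentations: tuple[str, ...] = ("ms50",)
    n_blocks: int = 6
    counterbalance: bool = False
    image_condition: str = "full"
    seed: int = 0

    def validate(self) -> None:
        if len(self.categories) < 2:
            raise ConfigurationError("need at least two categories")
        if len(set(self.categories)) != len(self.categories):
            raise ConfigurationError("duplicate category labels")
        if self.n_images_per_category < 1 or self.n_blocks < 1:
            raise ConfigurationError("counts must be positive")
        if self.counterbalance:
            if len(self.presentations) != 2:
                raise ConfigurationError(
                    "counterbalancing needs exactly two presentation durations"
                )
            if len(self.categories) % 2:
                raise ConfigurationError(
                    "counterbalancing needs an even number of categories"
                )
            if self.n_blocks % 2:
                raise ConfigurationError("counterbalancing needs an even block count")

    @property
    def n_trials(self) -> int:
        return len(self.categories) * self.n_images_per_category * len(self.presentations)


@dataclass(frozen=True)
class Subgroup:
    """A latent cohort subgroup: mixture weight + per-category accuracy."""

    weight: float
    accuracy_profile: Mapping[str, float]
    note: str = ""


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a synthetic human cohort.

    ``session_stability`` is the probability that a participant keeps their
    test-session accuracy profile at retest; otherwise each category's
    accuracy is independently perturbed on the logit scale with SD
    ``profile_jitter``.  ``carryover_boost`` adds a fixed accuracy increment
    to the second within-session occurrence of a stimulus (0 = no carryover,
    the default study assumption).
    """

    n_participants: int
    categories: tuple[str, ...] = DEFAULT_CATEGORIES
    n_images_per_category: int = 30
    subgroups: tuple[Subgroup, ...] = ()
    confusion_kernel: "Mapping[str, Mapping[str, float]] | None" = None
    session_stability: float = 0.6
    profile_jitter: float = 4.0
    sessions: tuple[str, ...] = ("test", "retest")
    carryover_boost: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be positive")
        if not self.subgroups:
            raise ConfigurationError("at least one subgroup is required")
        total = float(sum(g.weight for g in self.subgroups))
        if abs(total - 1.0) > 1e-12:
            raise ConfigurationError(f"subgroup weights sum to {total!r}, not 1")
        for g in self.subgroups:
            if not (0.0 <= g.weight <= 1.0):
                raise ConfigurationError("subgroup weight outside [0, 1]")
            for cat in self.categories:
                p = g.accuracy_profile.get(cat)
                if p is None:
                    raise ConfigurationError(f"profile missing category {cat!r}")
                if not (0.0 <= p <= 1.0):
                    raise ConfigurationError(f"accuracy for {cat!r} outside [0, 1]")
        if not (0.0 <= self.session_stability <= 1.0):
            raise ConfigurationError("session_stability outside [0, 1]")
        if self.profile_jitter < 0:
            raise ConfigurationError("profile_jitter must be nonnegative")
        if self.confusion_kernel is not None:
            for cat in self.categories:
                row = self.confusion_kernel.get(cat)
                if row is None:
                    raise ConfigurationError(f"confusion kernel missing row {cat!r}")
                if abs(sum(row.values()) - 1.0) > 1e-9:
                    raise ConfigurationError(f"confusion row {cat!r} does not sum to 1")
                if row.get(cat, 0.0) > 0:
                    raise ConfigurationError(
                        f"confusion row {cat!r} puts mass on the correct label"
                    )


# ---------------------------------------------------------------------------
# Schedules


def make_counterbalanced_design(spec: DesignSpec) -> pd.DataFrame:
    """Build one session's ordered trial schedule.

    Returns a DataFrame with columns ``block``, ``trial_index``,
    ``stimulus_id``, ``true_category``, ``presentation``.  Every image occurs
    exactly once per presentation duration.  With ``counterbalance`` on, each
    category is bound to one duration in the first half of the blocks and to
    the other in the second half; trial order is randomised within each half
    by the spec seed.  Block sizes differ by at most one trial.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    cats = spec.categories
    stim = {c: _stimulus_ids(c, spec.n_images_per_category) for c in cats}

    def rows_for(assignment: Mapping[str, str]) -> pd.DataFrame:
        recs = [
            (s, c, assignment[c])
            for c in cats
            for s in stim[c]
        ]
        df = pd.DataFrame(recs, columns=["stimulus_id", "true_category", "presentation"])
        return df.iloc[rng.permutation(len(df))].reset_index(drop=True)

    if spec.counterbalance:
        half = len(cats) // 2
        a, b = spec.presentations
        first_map = {c: (a if i < half else b) for i, c in enumerate(cats)}
        second_map = {c: (b if i < half else a) for i, c in enumerate(cats)}
        halves = [(rows_for(first_map), 0), (rows_for(second_map), spec.n_blocks // 2)]
        parts = []
        for df, block_offset in halves:
            chunks = np.array_split(np.arange(len(df)), spec.n_blocks // 2)
            for j, chunk in enumerate(chunks):
                piece = df.iloc[chunk].copy()
                piece["block"] = block_offset + j + 1
                parts.append(piece)
        out = pd.concat(parts, ignore_index=True)
    else:
        recs = [
            (s, c, p)
            for p in spec.presentations
            for c in cats
            for s in stim[c]
        ]
        df = pd.DataFrame(recs, columns=["stimulus_id", "true_category", "presentation"])
        df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
        chunks = np.array_split(np.arange(len(df)), spec.n_blocks)
        parts = []
        for j, chunk in enumerate(chunks):
            piece = df.iloc[chunk].copy()
            piece["block"] = j + 1
            parts.append(piece)
        out = pd.concat(parts, ignore_index=True)

    out["trial_index"] = np.arange(1, len(out) + 1)
    return out[["block", "trial_index", "stimulus_id", "true_category", "presentation"]]


# ---------------------------------------------------------------------------
# Response simulation


def _kernel_matrix(
    spec_kernel: "Mapping[str, Mapping[str, float]] | None",
    categories: Sequence[str],
) -> tuple[list[str], np.ndarray]:
    """Build the (category x response-label) wrong-answer distribution.

    Default: uniform over the other categories.  The label universe extends
    to :data:`UNKNOWN` only if some kernel row gives it mass (free naming).
    """
    cats = list(categories)
    if spec_kernel is None:
        labels = cats
        k = len(cats)
        mat = np.full((k, k), 1.0 / (k - 1))
        np.fill_diagonal(mat, 0.0)
        return labels, mat
    extra = sorted(
        {lab for row in spec_kernel.values() for lab in row} - set(cats)
    )
    for lab in extra:
        if lab != UNKNOWN:
            raise ConfigurationError(
                f"confusion kernel label {lab!r} outside the category set"
            )
    labels = cats + extra
    mat = np.zeros((len(cats), len(labels)))
    col = {lab: i for i, lab in enumerate(labels)}
    for i, cat in enumerate(cats):
        for lab, p in spec_kernel[cat].items():
            mat[i, col[lab]] = p
    return labels, mat


def _simulate_session(
    schedule: pd.DataFrame,
    profile: np.ndarray,
    labels: list[str],
    kernel: np.ndarray,
    cat_index: Mapping[str, int],
    rng: np.random.Generator,
    carryover_boost: float,
) -> np.ndarray:
    """Return the response-label index for each schedule row."""
    cat_idx = schedule["true_category"].map(cat_index).to_numpy()
    p = profile[cat_idx].copy()
    if carryover_boost:
        occurrence = schedule.groupby("stimulus_id", sort=False).cumcount().to_numpy()
        p = np.clip(p + carryover_boost * (occurrence > 0), 0.0, 1.0)
    correct = rng.random(len(p)) < p
    resp = cat_idx.copy()  # correct answers: label index == category index
    wrong = np.flatnonzero(~correct)
    if wrong.size:
        cum = np.cumsum(kernel[cat_idx[wrong]], axis=1)
        u = rng.random(wrong.size)
        resp[wrong] = (u[:, None] > cum).sum(axis=1)
    return resp


def _participant_rng(seed: int, rater_id: str) -> np.random.Generator:
    digest = hashlib.blake2b(rater_id.encode("utf-8"), digest_size=4).digest()
    sub = int.from_bytes(digest, "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([seed, sub]))


def _logit_jitter(profile: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    eps = 1e-4
    clipped = np.clip(profile, eps, 1 - eps)
    logit = np.log(clipped / (1 - clipped))
    jittered = logit + rng.normal(0.0, sd, size=profile.shape)
    return 1.0 / (1.0 + np.exp(-jittered))


def generate_cohort(spec: CohortSpec, design: DesignSpec) -> pd.DataFrame:
    """Generate a full synthetic cohort response table.

    Each participant is assigned a subgroup by mixture weight and answers
    both sessions of the schedule.  All participants see the same two
    session schedules (test order and an independently shuffled retest
    order), mirroring a fixed-block online deployment.
    """
    spec.validate()
    if tuple(design.categories) != tuple(spec.categories):
        raise ConfigurationError("design and cohort category sets differ")
    schedules = {
        session: make_counterbalanced_design(replace(design, seed=design.seed + offset))
        for offset, session in enumerate(spec.sessions)
    }
    labels, kernel = _kernel_matrix(spec.confusion_kernel, spec.categories)
    cat_index = {c: i for i, c in enumerate(spec.categories)}
    label_arr = np.asarray(labels, dtype=object)

    master = np.random.default_rng(np.random.SeedSequence([spec.seed, 11]))
    weights = np.array([g.weight for g in spec.subgroups])
    weights = weights / weights.sum()
    width = max(3, len(str(spec.n_participants)))
    rater_ids = [f"p{i:0{width}d}" for i in range(1, spec.n_participants + 1)]
    assignments = master.choice(len(spec.subgroups), size=spec.n_participants, p=weights)

    profiles = np.array(
        [[g.accuracy_profile[c] for c in spec.categories] for g in spec.subgroups]
    )

    parts: list[pd.DataFrame] = []
    for rater_id, g_idx in zip(rater_ids, assignments):
        rng = _participant_rng(spec.seed, rater_id)
        test_profile = profiles[g_idx]
        session_profiles = {}
        for session in spec.sessions:
            if session == "retest" and rng.random() >= spec.session_stability:
                session_profiles[session] = _logit_jitter(
                    test_profile, spec.profile_jitter, rng
                )
            else:
                session_profiles[session] = test_profile
        for session in spec.sessions:
            sched = schedules[session]
            resp_idx = _simulate_session(
                sched, session_profiles[session], labels, kernel, cat_index,
                rng, spec.carryover_boost,
            )
            resp = label_arr[resp_idx]
            parts.append(
                pd.DataFrame(
                    {
                        "rater_id": rater_id,
                        "rater_kind": "human",
                        "session": session,
                        "presentation": sched["presentation"].to_numpy(),
                        "image_condition": design.image_condition,
                        "block": sched["block"].to_numpy(),
                        "trial_index": sched["trial_index"].to_numpy(),
                        "stimulus_id": sched["stimulus_id"].to_numpy(),
                        "true_category": sched["true_category"].to_numpy(),
                        "response_label": resp,
                        "response_category": resp,
                    }
                )
            )
    return pd.concat(parts, ignore_index=True)[COLUMNS]


def generate_model_rater(
    rater_id: str,
    accuracy_profile: Mapping[str, float],
    confusion_kernel: "Mapping[str, Mapping[str, float]] | None",
    design: DesignSpec,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a deterministic-architecture rater (a stand-in for a network's
    responses): one response per scheduled stimulus, single test session."""
    design.validate()
    for cat in design.categories:
        p = accuracy_profile.get(cat)
        if p is None or not (0.0 <= p <= 1.0):
            raise ConfigurationError(f"invalid accuracy for category {cat!r}")
    sched = make_counterbalanced_design(design)
    labels, kernel = _kernel_matrix(confusion_kernel, design.categories)
    cat_index = {c: i for i, c in enumerate(design.categories)}
    profile = np.array([accuracy_profile[c] for c in design.categories])
    rng = _participant_rng(seed, rater_id)
    resp_idx = _simulate_session(sched, profile, labels, kernel, cat_index, rng, 0.0)
    resp = np.asarray(labels, dtype=object)[resp_idx]
    return pd.DataFrame(
        {
            "rater_id": rater_id,
            "rater_kind": "model",
            "session": "test",
            "presentation": sched["presentation"].to_numpy(),
            "image_condition": design.image_condition,
            "block": sched["block"].to_numpy(),
            "trial_index": sched["trial_index"].to_numpy(),
            "stimulus_id": sched["stimulus_id"].to_numpy(),
            "true_category": sched["true_category"].to_numpy(),
            "response_label": resp,
            "response_category": resp,
        }
    )[COLUMNS]


# ---------------------------------------------------------------------------
# Scenario builders


def plant_modal_scenario(
    n_participants: int,
    modal_weight: float,
    n_variant_subgroups: int,
    seed: int = 0,
    categories: Sequence[str] = DEFAULT_CATEGORIES,
    flat_accuracy: float = 0.99,
    variant_separation: float = 0.45,
    session_stability: float = 0.6,
    profile_jitter: float = 6.0,
) -> CohortSpec:
    """Cohort spec with a planted flat-profile modal subgroup.

    One subgroup carries a flat (all categories equal) accuracy profile at
    mixture weight ``modal_weight``; the remaining weight is split evenly
    over variant subgroups whose profiles depress distinct category subsets
    by ``variant_separation``.  The flat level sits near ceiling and the
    separation is large relative to the discretisation band, so that with 30
    trials per category the planted subgroup structure is recoverable from
    sampled proportions rather than swamped by binomial noise.  The retest
    jitter SD defaults to 6 on the logit scale so that a perturbed profile
    almost surely changes its signature — the condition under which observed
    cross-session consistency tracks the planted stability (see the methods
    note for both identifiability arguments).
    """
    if not (0.0 < modal_weight < 1.0):
        raise ConfigurationError("modal_weight must lie strictly inside (0, 1)")
    if n_variant_subgroups < 1:
        raise ConfigurationError("need at least one variant subgroup")
    cats = tuple(categories)
    flat = {c: flat_accuracy for c in cats}
    low = max(flat_accuracy - variant_separation, 0.0)
    subsets = itertools.chain.from_iterable(
        itertools.combinations(range(len(cats)), r) for r in range(1, len(cats) + 1)
    )
    variants = []
    share = (1.0 - modal_weight) / n_variant_subgroups
    for subset, _ in zip(subsets, range(n_variant_subgroups)):
        profile = dict(flat)
        for i in subset:
            profile[cats[i]] = low
        variants.append(
            Subgroup(weight=share, accuracy_profile=profile,
                     note=f"low:{','.join(cats[i] for i in subset)}")
        )
    groups = (Subgroup(weight=modal_weight, accuracy_profile=flat, note="flat"),) + tuple(variants)
    # Absorb float rounding into the first variant so weights sum to 1 exactly.
    total = sum(g.weight for g in groups)
    if groups[1:] and total != 1.0:
        g1 = groups[1]
        groups = (groups[0], replace(g1, weight=g1.weight + (1.0 - total))) + groups[2:]
    return CohortSpec(
        n_participants=n_participants,
        categories=cats,
        subgroups=groups,
        session_stability=session_stability,
        profile_jitter=profile_jitter,
        seed=seed,
    )


def default_retest_design(seed: int = 0) -> DesignSpec:
    """Nine categories x 30 images, 50 ms, six blocks of 45 per session."""
    return DesignSpec(
        categories=DEFAULT_CATEGORIES,
        n_images_per_category=30,
        presentations=("ms50",),
        n_blocks=6,
        counterbalance=False,
        image_condition="full",
        seed=seed,
    )


def default_two_duration_design(seed: int = 0) -> DesignSpec:
    """Ten categories x 60 images at 50 ms and 200 ms, counterbalanced over
    eight blocks (1200 trials, 150 per block)."""
    return DesignSpec(
        categories=TWO_DURATION_CATEGORIES,
        n_images_per_category=60,
        presentations=("ms50", "ms200"),
        n_blocks=8,
        counterbalance=True,
        image_condition="full",
        seed=seed,
    )


def default_cohort_spec(n_participants: int = 398, seed: int = 0) -> CohortSpec:
    """Study-mirroring cohort: ~86% mean accuracy, weakest on Helmet (~74%),
    a dominant broadly-even subgroup plus three structured minorities."""
    base = {
        "Plate": 0.84, "Vase": 0.82, "Basket": 0.83,
        "TV": 0.88, "Helmet": 0.78, "Mug": 0.87,
        "Banana": 0.93, "Match": 0.92, "Plunger": 0.91,
    }
    helmet_weak = dict(base, Helmet=0.60)
    hard_weak = dict(base, Plate=0.69, Vase=0.67, Basket=0.68)
    strong = {c: min(p + 0.06, 0.98) for c, p in base.items()}
    return CohortSpec(
        n_participants=n_participants,
        categories=DEFAULT_CATEGORIES,
        n_images_per_category=30,
        subgroups=(
            Subgroup(0.60, base, "broadly even"),
            Subgroup(0.20, helmet_weak, "helmet-weak"),
            Subgroup(0.10, hard_weak, "hard-category-weak"),
            Subgroup(0.10, strong, "high performers"),
        ),
        session_stability=0.6,
        profile_jitter=4.0,
        seed=seed,
    )
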