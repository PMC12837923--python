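"""End-to-end analysis orchestration.

``run_retest_analysis`` drives the whole pipeline for a two-session
(test/retest) categorisation study under a single configuration: simulate
or load response tables, aggregate accuracies, measure intra-rater
reliability and inter-rater agreement, run human-vs-model Bayes-factor
comparisons, and reduce per-participant accuracy profiles to ordinal
patterns.  Outputs are plain CSV/JSON files plus a manifest sufficient to
reproduce the run bit-for-bit (the manifest deliberately records no wall
time, so reruns with one seed are byte-identical).

Only test-session data feed the human-machine comparisons; the retest
session is used for reliability and pattern-consistency analyses alone.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .agreement import (
    align_rater_sequences,
    intra_rater_reliability,
    kappa_matrix_values,
    pooled_pairwise_kappa,
)
from .bayes import DEFAULT_PRIOR_SCALE, compare_accuracies, jzs_bf_paired
from .exceptions import ConfigurationError, IntegrityError
from .patterns import (
    DiscretisationCriterion,
    discretise_accuracy_table,
    match_model_to_human,
    modal_pattern,
    pattern_frequencies,
    session_consistency,
)
from .records import compute_accuracy, read_response_table, split_halves, write_responses
from .simulate import (
    CohortSpec,
    DesignSpec,
    Subgroup,
    default_cohort_spec,
    default_retest_design,
    generate_cohort,
    generate_model_rater,
)

__all__ = [
    "AnalysisConfig",
    "default_model_profiles",
    "default_config",
    "run_retest_analysis",
    "run_carryover_check",
]

log = logging.getLogger("catpattern")


def default_model_profiles() -> dict[str, dict[str, float]]:
    """Synthetic stand-ins for two model families' accuracy structure:
    a flat high-accuracy multimodal-style rater and a convnet-style rater
    that is strong on easy categories and weak on hard ones."""
    flat = {c: 0.92 for c in default_retest_design().categories}
    convnet = {
        "Plate": 0.55, "Vase": 0.58, "Basket": 0.60,
        "TV": 0.85, "Helmet": 0.82, "Mug": 0.84,
        "Banana": 0.95, "Match": 0.95, "Plunger": 0.95,
    }
    return {"multimodal_zero_shot": flat, "convnet_baseline": convnet}


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration for one full pipeline run.

    Exactly one of (``human_input``, ``cohort``) must be set: response
    tables are either loaded from CSV or generated.  Model raters likewise
    come from ``model_inputs`` CSVs or are simulated from
    ``model_profiles``.
    """

    seed: int = 0
    categories: tuple[str, ...] = default_retest_design().categories
    cohort: "CohortSpec | None" = None
    design: "DesignSpec | None" = None
    model_profiles: "Mapping[str, Mapping[str, float]] | None" = None
    human_input: "str | None" = None
    model_inputs: tuple[str, ...] = ()
    criterion: DiscretisationCriterion = DiscretisationCriterion()
    prior_scale: float = DEFAULT_PRIOR_SCALE
    ci_level: float = 0.95
    run_agreement: bool = True
    run_bayes: bool = True
    run_patterns: bool = True
    run_carryover: bool = False

    def validate(self) -> None:
        if (self.cohort is None) == (self.human_input is None):
            raise ConfigurationError(
                "exactly one of a cohort spec or a human input path is required"
            )
        if self.cohort is not None and self.design is None:
            raise ConfigurationError("a design spec is required with a cohort spec")


def default_config(seed: int = 0, n_participants: int = 398) -> AnalysisConfig:
    """Study-mirroring synthetic configuration (398 participants, two
    sessions, nine categories, 50 ms, two synthetic model raters)."""
    return AnalysisConfig(
        seed=seed,
        cohort=default_cohort_spec(n_participants=n_participants, seed=seed),
        design=default_retest_design(seed=seed),
        model_profiles=default_model_profiles(),
    )


def config_from_mapping(cfg: Mapping[str, Any]) -> AnalysisConfig:
    """Build an :class:`AnalysisConfig` from a YAML/JSON-style mapping."""
    seed = int(cfg.get("seed", 0))
    categories = tuple(cfg.get("categories", default_retest_design().categories))
    design = None
    if "design" in cfg or "cohort" in cfg:
        d = dict(cfg.get("design", {}))
        design = DesignSpec(
            categories=categories,
            n_images_per_category=int(d.get("n_images_per_category", 30)),
            presentations=tuple(d.get("presentations", ("ms50",))),
            n_blocks=int(d.get("n_blocks", 6)),
            counterbalance=bool(d.get("counterbalance", False)),
            image_condition=str(d.get("image_condition", "full")),
            seed=int(d.get("seed", seed)),
        )
    cohort = None
    if "cohort" in cfg:
        c = dict(cfg["cohort"])
        if "subgroups" in c:
            subgroups = tuple(
                Subgroup(
                    weight=float(g["weight"]),
                    accuracy_profile=dict(g["accuracy_profile"]),
                    note=str(g.get("note", "")),
                )
                for g in c["subgroups"]
            )
        else:
            subgroups = default_cohort_spec().subgroups
        cohort = CohortSpec(
            n_participants=int(c.get("n_participants", 398)),
            categories=categories,
            n_images_per_category=int(c.get("n_images_per_category", 30)),
            subgroups=subgroups,
            confusion_kernel=c.get("confusion_kernel"),
            session_stability=float(c.get("session_stability", 0.6)),
            profile_jitter=float(c.get("profile_jitter", 4.0)),
            sessions=tuple(c.get("sessions", ("test", "retest"))),
            carryover_boost=float(c.get("carryover_boost", 0.0)),
            seed=int(c.get("seed", seed)),
        )
    crit = dict(cfg.get("criterion", {}))
    criterion = DiscretisationCriterion(
        mode=str(crit.get("mode", "threshold")),
        tolerance=float(crit.get("tolerance", 0.1)),
        ci_level=float(crit.get("ci_level", 0.95)),
    )
    toggles = dict(cfg.get("analyses", {}))
    models_cfg = cfg.get("models")
    model_profiles = None
    if models_cfg is not None:
        model_profiles = {
            m["rater_id"]: dict(m["accuracy_profile"]) for m in models_cfg
        }
    elif "inputs" not in cfg:
        model_profiles = default_model_profiles()
    inputs = dict(cfg.get("inputs", {}))
    return AnalysisConfig(
        seed=seed,
        categories=categories,
        cohort=cohort,
        design=design,
        model_profiles=model_profiles,
        human_input=inputs.get("humans"),
        model_inputs=tuple(inputs.get("models", ())),
        criterion=criterion,
        prior_scale=float(cfg.get("prior_scale", DEFAULT_PRIOR_SCALE)),
        ci_level=float(cfg.get("ci_level", 0.95)),
        run_agreement=bool(toggles.get("agreement", True)),
        run_bayes=bool(toggles.get("bayes", True)),
        run_patterns=bool(toggles.get("patterns", True)),
        run_carryover=bool(toggles.get("carryover", False)),
    )


def config_from_yaml(path: "str | Path") -> AnalysisConfig:
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        return config_from_mapping(yaml.safe_load(fh) or {})


class _Stage:
    """Context manager logging a stage name and wall time to stderr."""

    def __init__(self, name: str) -> None:
        self.name = name

    def __enter__(self) -> "_Stage":
        log.info("stage %s: start", self.name)
        self._t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb) -> None:
        dt = time.perf_counter() - self._t0
        if exc_type is None:
            log.info("stage %s: done in %.2fs", self.name, dt)
        else:
            log.error("stage %s: FAILED (%s)", self.name, exc)


def _json_dump(obj: Any, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")


def run_carryover_check(
    records: pd.DataFrame,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
) -> pd.DataFrame:
    """Per-duration paired Bayes factor for first- vs second-half accuracy.

    Requires each stimulus to be presented exactly twice per rater within a
    session (a counterbalanced repeated-presentation design).  For every
    presentation duration, each participant's overall accuracy is computed
    separately over first and second stimulus occurrences and the paired
    differences are tested with the JZS Bayes factor.
    """
    first, second = split_halves(records)
    if second.empty:
        raise IntegrityError(
            "carryover check needs two presentations of each stimulus"
        )
    out_rows = []
    acc_first = compute_accuracy(first, group_by=["rater_id", "presentation"])
    acc_second = compute_accuracy(second, group_by=["rater_id", "presentation"])
    merged = acc_first.merge(
        acc_second, on=["rater_id", "presentation"], suffixes=("_first", "_second")
    )
    for pres, grp in merged.groupby("presentation", sort=True):
        diffs = (grp["proportion_second"] - grp["proportion_first"]).to_numpy()
        res = jzs_bf_paired(diffs, prior_scale=prior_scale)
        out_rows.append(
            {
                "presentation": pres,
                "n_participants": len(grp),
                "mean_first": float(grp["proportion_first"].mean()),
                "mean_second": float(grp["proportion_second"].mean()),
                "t_statistic": res.t_statistic,
                "bf10": res.bf10,
                "grade": res.grade,
                "marks": res.marks,
                "prior_scale": prior_scale,
            }
        )
    return pd.DataFrame(out_rows)


def _load_or_generate(config: AnalysisConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (human response table, model response table)."""
    if config.cohort is not None:
        humans = generate_cohort(config.cohort, config.design)
    else:
        humans = read_response_table(config.human_input, config.categories)
    model_parts: list[pd.DataFrame] = []
    for path in config.model_inputs:
        model_parts.append(read_response_table(path, config.categories))
    if config.model_profiles:
        design = config.design if config.design is not None else default_retest_design(config.seed)
        for rid, profile in config.model_profiles.items():
            model_parts.append(
                generate_model_rater(rid, profile, None, design, seed=config.seed)
            )
    models = (
        pd.concat(model_parts, ignore_index=True) if model_parts
        else humans.iloc[0:0]
    )
    return humans, models


def run_retest_analysis(config: AnalysisConfig, out_dir: "str | Path") -> dict[str, Path]:
    """Run the full pipeline; returns a name -> path map of the bundle."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Path] = {}
    report: dict[str, Any] = {}

    with _Stage("data"):
        humans, models = _load_or_generate(config)
        test = humans[humans["session"] == "test"]
        retest = humans[humans["session"] == "retest"]
        bundle["responses_humans"] = write_responses(humans, out / "responses_humans.csv")
        if not models.empty:
            bundle["responses_models"] = write_responses(models, out / "responses_models.csv")

    with _Stage("accuracy"):
        acc_humans = compute_accuracy(humans, categories=config.categories)
        acc_humans.to_csv(out / "accuracy_humans.csv", index=False)
        bundle["accuracy_humans"] = out / "accuracy_humans.csv"
        report["human_mean_test_accuracy"] = float(
            test["response_category"].eq(test["true_category"]).mean()
        )
        if not retest.empty:
            report["human_mean_retest_accuracy"] = float(
                retest["response_category"].eq(retest["true_category"]).mean()
            )
        if not models.empty:
            acc_models = compute_accuracy(models, categories=config.categories)
            acc_models.to_csv(out / "accuracy_models.csv", index=False)
            bundle["accuracy_models"] = out / "accuracy_models.csv"

    if not retest.empty:
        with _Stage("reliability"):
            per_participant, median_kappa, excluded = intra_rater_reliability(
                test, retest, ci_level=config.ci_level
            )
            per_participant.to_csv(out / "reliability.csv", index=False)
            bundle["reliability"] = out / "reliability.csv"
            report["intra_rater_median_kappa"] = median_kappa
            report["reliability_exclusions"] = excluded

    if config.run_agreement:
        with _Stage("agreement"):
            wide_h = align_rater_sequences(test, session="test")
            frames = [wide_h]
            if not models.empty:
                wide_m = align_rater_sequences(models, session="test")
                frames.append(wide_m)
            wide_all = pd.concat(frames, axis=1)
            if wide_all.isna().any().any():
                raise IntegrityError("human and model stimulus sets differ")
            kmat = kappa_matrix_values(wide_all)
            human_ids = list(wide_h.columns)
            hh = kmat.loc[human_ids, human_ids].to_numpy()
            iu = np.triu_indices(len(human_ids), k=1)
            pair_vals = hh[iu]
            pooled = pooled_pairwise_kappa(wide_h, ci_level=config.ci_level)
            summary_rows = [
                {
                    "comparison": "human_vs_human",
                    "summary": "per_pair_median", "kappa": float(np.median(pair_vals)),
                    "n_pairs": int(pair_vals.size),
                },
                {
                    "comparison": "human_vs_human",
                    "summary": "per_pair_mean", "kappa": float(np.mean(pair_vals)),
                    "n_pairs": int(pair_vals.size),
                },
                {
                    "comparison": "human_vs_human",
                    "summary": "pooled_trials", "kappa": pooled.kappa,
                    "n_pairs": int(pair_vals.size),
                },
            ]
            model_ids = [c for c in wide_all.columns if c not in human_ids]
            for mid in model_ids:
                vals = kmat.loc[human_ids, mid].to_numpy()
                summary_rows.append(
                    {
                        "comparison": f"human_vs_{mid}",
                        "summary": "per_pair_median", "kappa": float(np.median(vals)),
                        "n_pairs": int(vals.size),
                    }
                )
            pd.DataFrame(summary_rows).to_csv(out / "agreement_summary.csv", index=False)
            bundle["agreement_summary"] = out / "agreement_summary.csv"
            report["human_human_median_kappa"] = float(np.median(pair_vals))
            if model_ids:
                kmat.loc[model_ids, model_ids].to_csv(out / "agreement_models_matrix.csv")
                bundle["agreement_models_matrix"] = out / "agreement_models_matrix.csv"

    if config.run_bayes and not models.empty:
        with _Stage("bayes"):
            acc_h_test = compute_accuracy(test, categories=config.categories)
            acc_m = compute_accuracy(models, categories=config.categories)
            per_cat = compare_accuracies(
                acc_h_test, acc_m, scope="category",
                test="one_sample", prior_scale=config.prior_scale,
            )
            overall = compare_accuracies(
                acc_h_test, acc_m, scope="overall",
                test="one_sample", prior_scale=config.prior_scale,
            )
            overall.insert(1, "category", "OVERALL")
            bf_table = pd.concat([overall, per_cat], ignore_index=True)
            bf_table.to_csv(out / "bayes_comparisons.csv", index=False)
            bundle["bayes_comparisons"] = out / "bayes_comparisons.csv"

    if config.run_patterns:
        with _Stage("patterns"):
            acc_sessions = compute_accuracy(
                humans,
                group_by=["rater_id", "session", "true_category"],
                categories=config.categories,
            )
            pats = discretise_accuracy_table(
                acc_sessions, config.categories, config.criterion,
                group_cols=("rater_id", "session"),
            )
            pats[["rater_id", "session", "signature"]].to_csv(
                out / "patterns_signatures.csv", index=False
            )
            bundle["patterns_signatures"] = out / "patterns_signatures.csv"
            pattern_report: dict[str, Any] = {
                "criterion": asdict(config.criterion),
            }
            session_pats: dict[str, dict] = {}
            for session in humans["session"].unique():
                sub = pats[pats["session"] == session]
                session_pats[session] = dict(zip(sub["rater_id"], sub["pattern"]))
                freq = pattern_frequencies(list(sub["pattern"]))
                freq.to_csv(out / f"patterns_frequencies_{session}.csv", index=False)
                bundle[f"patterns_frequencies_{session}"] = (
                    out / f"patterns_frequencies_{session}.csv"
                )
                winners, prop = modal_pattern(list(sub["pattern"]))
                pattern_report[f"{session}_modal_signatures"] = [
                    w.signature for w in winners
                ]
                pattern_report[f"{session}_modal_proportion"] = prop
                pattern_report[f"{session}_n_unique_patterns"] = int(len(freq))
            if {"test", "retest"} <= set(session_pats):
                prop, indicator, excl = session_consistency(
                    session_pats["test"], session_pats["retest"]
                )
                pattern_report["session_consistency"] = prop
                pattern_report["session_consistency_exclusions"] = excl
            if not models.empty:
                acc_m_cat = compute_accuracy(
                    models,
                    group_by=["rater_id", "true_category"],
                    categories=config.categories,
                )
                model_pats = discretise_accuracy_table(
                    acc_m_cat, config.categories, config.criterion,
                    group_cols=("rater_id",),
                )
                matches = {}
                for row in model_pats.itertuples(index=False):
                    matches[row.rater_id] = match_model_to_human(
                        row.pattern, list(session_pats.get("test", {}).values())
                    )
                pattern_report["model_matches"] = matches
            _json_dump(pattern_report, out / "patterns_report.json")
            bundle["patterns_report"] = out / "patterns_report.json"
            report["test_modal_proportion"] = pattern_report.get("test_modal_proportion")
            report["session_consistency"] = pattern_report.get("session_consistency")

    if config.run_carryover:
        with _Stage("carryover"):
            carry = run_carryover_check(test, prior_scale=config.prior_scale)
            carry.to_csv(out / "carryover.csv", index=False)
            bundle["carryover"] = out / "carryover.csv"

    with _Stage("manifest"):
        manifest = {
            "package": "catpattern",
            "version": __version__,
            "seed": config.seed,
            "categories": list(config.categories),
            "criterion": asdict(config.criterion),
            "prior_scale": config.prior_scale,
            "ci_level": config.ci_level,
            "n_participants": (
                config.cohort.n_participants if config.cohort is not None else None
            ),
            "session_stability": (
                config.cohort.session_stability if config.cohort is not None else None
            ),
            "analyses": {
                "agreement": config.run_agreement,
                "bayes": config.run_bayes,
                "patterns": config.run_patterns,
                "carryover": config.run_carryover,
            },
            "outputs": sorted(str(p.name) for p in bundle.values()),
        }
        _json_dump(manifest, out / "manifest.json")
        bundle["manifest"] = out / "manifest.json"
        _json_dump(report, out / "report.json")
        bundle["report"] = out / "report.json"
    return bundle
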