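import sys
from pathlib import Path

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


CATEGORIES9 = (
    "Plate", "Vase", "Basket", "TV", "Helmet", "Mug", "Banana", "Match", "Plunger",
)


@pytest.fixture(scope="session")
def categories9():
    return CATEGORIES9


@pytest.fixture
def tiny_table():
    """Two raters x one session x three stimuli, hand-checkable."""
    rows = []
    answers = {
        "r1": ["Plate", "Vase", "Vase"],
        "r2": ["Plate", "Plate", "Basket"],
    }
    truths = ["Plate", "Vase", "Basket"]
    stims = ["plate_001", "vase_001", "basket_001"]
    for rid, resp in answers.items():
        for i, (stim, truth, r) in enumerate(zip(stims, truths, resp), start=1):
            rows.append(
                dict(
                    rater_id=rid, rater_kind="human", session="test",
                    presentation="ms50", image_condition="full",
                    block=1, trial_index=i, stimulus_id=stim,
                    true_category=truth, response_label=r, response_category=r,
                )
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-participant two-session cohort on a reduced design (shared
    across tests; generation is deterministic)."""
    from catpattern.simulate import (
        CohortSpec, DesignSpec, Subgroup, generate_cohort,
    )

    cats = CATEGORIES9
    design = DesignSpec(
        categories=cats, n_images_per_category=10,
        presentations=("ms50",), n_blocks=2, seed=7,
    )
    base = {c: 0.85 for c in cats}
    weak = dict(base, Helmet=0.5)
    spec = CohortSpec(
        n_participants=12, categories=cats, n_images_per_category=10,
        subgroups=(Subgroup(0.7, base), Subgroup(0.3, weak)),
        session_stability=0.8, seed=7,
    )
    return generate_cohort(spec, design), design
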