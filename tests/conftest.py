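import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from focalstage import synthetic as syn

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_sim() -> syn.SyntheticCohort:
    """The default 900-participant synthetic cohort (seed 42)."""
    return syn.generate_cohort(syn.GeneratorConfig())


@pytest.fixture(scope="session")
def default_staged(default_sim) -> syn.StagedCohort:
    """The default cohort run through the full staging pipeline."""
    return syn.stage_generated_cohort(default_sim)


@pytest.fixture(scope="session")
def focal_enriched_staged() -> syn.StagedCohort:
    """A 600-subject all-focal cohort staged with default-population cutoffs.

    Every subject carries planted focal involvement (no global positives),
    giving ~600 eligible subjects for involvement-frequency checks.
    """
    cfg = syn.GeneratorConfig(
        n_participants=600,
        seed=42,
        g_plus_prob={"CU": 0.0, "aMCI": 0.0, "dementia": 0.0},
        focal_prob_given_gneg={"CU": 1.0, "aMCI": 1.0, "dementia": 1.0},
    )
    sim = syn.generate_cohort(cfg)
    reference = syn.make_cu_reference(syn.GeneratorConfig(seed=42))
    return syn.stage_generated_cohort(sim, cu_reference=reference)
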