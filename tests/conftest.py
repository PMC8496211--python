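import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracle.py importable

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_profile():
    """One calibrated 30-state toy profile shared across tests."""
    from orthohunt.fixtures import make_toy_profile

    return make_toy_profile(30, seed=7, name="toy30")


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """A 3-profile x 2-proteome planted fixture plus one full pipeline run."""
    from orthohunt import RunConfig, run_pipeline
    from orthohunt.fixtures import FixtureScenario, build_fixture

    root = tmp_path_factory.mktemp("small_run")
    scenario = FixtureScenario.cycle(n_profiles=3, n_proteomes=2, seed=11)
    fixture = build_fixture(scenario, root / "fixture")
    config = RunConfig(
        hmm_list_path=fixture.hmm_list,
        fasta_list_path=fixture.fasta_list,
        output_dir=root / "out",
    )
    summary = run_pipeline(config)
    return scenario, fixture, config, summary
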