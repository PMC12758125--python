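import hypothesis
import pytest

from ciswas.synthetic_cohort import scenario_config, simulate_scenario

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def shared_bundle():
    """One shared-causal scenario reused by smoke/integration tests."""
    cfg = scenario_config("shared_causal", seed=20_240_601,
                          n_individuals=8000, n_pqtl=3000, n_variants=60,
                          n_causal=3)
    return simulate_scenario(cfg)


@pytest.fixture(scope="session")
def mediated_bundle():
    cfg = scenario_config("mediated", seed=20_240_602, n_individuals=12_000,
                          n_pqtl=4000, n_mediator=8000, n_variants=60,
                          n_causal=3, ld_decay=0.2)
    return simulate_scenario(cfg, fit=False)
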