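import pytest

from pahmsc import (
    HEAD_TO_HEAD_COMPARISONS,
    PRIMARY_COMPARISONS,
    SimulationConfig,
    generate_expression,
    quantile_normalize,
    run_comparison,
)


@pytest.fixture(scope="session")
def study_config():
    """Strong-effect study at the default study scale."""
    return SimulationConfig(n_genes=1000, effect_size=2.0, noise_sd=0.3,
                            seed=5)


@pytest.fixture(scope="session")
def study(study_config):
    """(normalized matrix, truth) for the shared synthetic study."""
    matrix, truth = generate_expression(study_config)
    return quantile_normalize(matrix), truth


@pytest.fixture(scope="session")
def fitted(study):
    """All six comparisons (four primary + two head-to-head) fitted."""
    matrix, _ = study
    out = {}
    for spec in PRIMARY_COMPARISONS + HEAD_TO_HEAD_COMPARISONS:
        out[spec.name] = run_comparison(matrix, spec, seed=5)
    return out
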