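import numpy as np
import pytest

from dhqtl import default_config, simulate_study

SMALL_CHROMS = (("C1", 60.0, 7), ("C2", 80.0, 9))


@pytest.fixture(scope="session")
def study157():
    """Full-size study: 157 lines, 241 markers, line-level phenotypes."""
    return simulate_study(
        default_config(n_lines=157, n_reps=1, plants_per_line_rep=1, seed=42)
    )


@pytest.fixture(scope="session")
def small_study():
    """Two small chromosomes, one major gene, replicated phenotypes."""
    return simulate_study(
        default_config(
            n_lines=60,
            n_reps=2,
            plants_per_line_rep=2,
            chromosomes=SMALL_CHROMS,
            major_genes=(("C1", 30.0, 8.0),),
            epistasis=(),
            polygene_variance=4.0,
            env_variance=9.0,
            seed=11,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
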