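import numpy as np
import pytest

from biokey import signal_model as sm

# the 5x5 worked-example reduced matrix whose COO listing is
# {(2,2,1),(1,3,2),(2,3,2),(3,3,2),(1,4,2),(2,4,2),(1,5,1),(2,5,1)}
WORKED_EXAMPLE_RM = np.array(
    [
        [0, 0, 2, 2, 1],
        [0, 1, 2, 2, 1],
        [0, 0, 2, 0, 0],
        [0, 0, 0, 0, 0],
        [0, 0, 0, 0, 0],
    ]
)

WORKED_EXAMPLE_TRIPLES = {
    (2, 2, 1),
    (1, 3, 2),
    (2, 3, 2),
    (3, 3, 2),
    (1, 4, 2),
    (2, 4, 2),
    (1, 5, 1),
    (2, 5, 1),
}


@pytest.fixture(scope="session")
def small_cohort():
    """Six-individual paired ECG/SpO2 cohort, 10 s sessions at 100 Hz."""
    return sm.simulate_cohort(
        n_individuals=6, sessions_per_individual=2, duration_s=10.0, seed=7
    )


@pytest.fixture(scope="session")
def one_individual():
    rng = np.random.default_rng(11)
    return sm.draw_individual(rng)
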