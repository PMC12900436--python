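import numpy as np
import pytest

import crnlogit as cl


@pytest.fixture(scope="session")
def birth_death_net():
    """Toy network 0 -> A at rate 10, A -> 0 at rate 1*x.

    The embedded chain has P(death | x) = x / (10 + x): an exact logistic
    law with slope 1 and intercept log(1/10) on log x.  The stationary count
    is ~Poisson(10), so zero-count states are essentially never visited and
    the zero-floor choice is immaterial.
    """
    return cl.build_network({
        "species": ["A"],
        "reactions": ["0 -> A @ 10", "A -> 0 @ 1"],
        "initial_state": [10],
    })


@pytest.fixture(scope="session")
def birth_death_events(birth_death_net):
    """~10^4 pooled events from the toy birth/death chain."""
    return cl.simulate_ensemble(birth_death_net, t_max=60.0, n_traj=10,
                                seed=42, max_events=200_000)


@pytest.fixture(scope="session")
def catalytic_toy():
    """Fully positive three-species toy with a catalytic conversion.

    0 -> A @ 5, 0 -> B @ 5 with first-order decay of all species, and
    A + B -> A + C @ 0.002 x_A x_B: A raises the conversion propensity
    without net change (a catalyst, invisible to stoichiometry).  Counts
    hover at A ~ 50, B ~ 25, C ~ 25, so reactions fire at strictly positive
    counts and all six jump vectors are distinct.
    """
    return cl.build_network({
        "species": ["A", "B", "C"],
        "reactions": [
            "0 -> A @ 5",
            "0 -> B @ 5",
            "A -> 0 @ 0.1",
            "B -> 0 @ 0.1",
            "C -> 0 @ 0.1",
            "A + B -> A + C @ 0.002",
        ],
        "initial_state": [50, 25, 25],
    })


@pytest.fixture(scope="session")
def catalytic_events(catalytic_toy):
    return cl.simulate_ensemble(catalytic_toy, t_max=120.0, n_traj=10,
                                seed=7, max_events=200_000)
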