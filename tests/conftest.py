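import numpy as np
import pytest

from photonfret import (
    CompositeGenerator,
    PhotophysicsSpec,
    SystemKinetics,
    build_composite_generator,
    efficiency_to_fret_rate,
)

# The pedagogical two-state composite used throughout: excitation 10 ms^-1,
# system rates 2 and 1 ms^-1, donor/acceptor relaxation 277000/285000 ms^-1,
# FRET rates 70000 and 2500000 ms^-1 (efficiencies ~0.2 and ~0.9).
WORKED_EXAMPLE_MATRIX = np.array(
    [
        [-12.0, 10.0, 0.0, 2.0, 0.0, 0.0],
        [277000.0, -347002.0, 70000.0, 0.0, 2.0, 0.0],
        [285000.0, 0.0, -285002.0, 0.0, 0.0, 2.0],
        [1.0, 0.0, 0.0, -11.0, 10.0, 0.0],
        [0.0, 1.0, 0.0, 277000.0, -2777001.0, 2500000.0],
        [0.0, 0.0, 1.0, 285000.0, 0.0, -285001.0],
    ]
)


@pytest.fixture
def worked_example_gen() -> CompositeGenerator:
    system = SystemKinetics([[0.0, 2.0], [1.0, 0.0]])
    photo = PhotophysicsSpec(
        excitation_rate=10.0,
        donor_relax_rate=277000.0,
        acceptor_relax_rate=285000.0,
        fret_rates=(70000.0, 2500000.0),
    )
    return build_composite_generator(system, photo)


@pytest.fixture
def worked_example_exact_gen() -> CompositeGenerator:
    """Worked example with unrounded relaxation rates (3.6 / 3.5 ns lifetimes).

    The printed matrix rounds the relaxation rates to 277000 / 285000 ms^-1;
    the example's likelihood value (3.06) corresponds to the exact rates.
    """
    system = SystemKinetics([[0.0, 2.0], [1.0, 0.0]])
    photo = PhotophysicsSpec(
        excitation_rate=10.0,
        donor_relax_rate=1e6 / 3.6,
        acceptor_relax_rate=1e6 / 3.5,
        fret_rates=(70000.0, 2500000.0),
    )
    return build_composite_generator(system, photo)


@pytest.fixture
def benchmark_gen() -> CompositeGenerator:
    """Two-state benchmark: escape rates 1 and 2 ms^-1, efficiencies 0.09/0.29."""
    ld = 277000.0
    system = SystemKinetics([[0.0, 1.0], [2.0, 0.0]])
    photo = PhotophysicsSpec(
        excitation_rate=10.0,
        donor_relax_rate=ld,
        acceptor_relax_rate=285000.0,
        fret_rates=tuple(efficiency_to_fret_rate(e, ld) for e in (0.09, 0.29)),
    )
    return build_composite_generator(system, photo)


@pytest.fixture
def single_fluorophore_gen() -> CompositeGenerator:
    """Toy two-superstate composite: ground <-> excited donor, one channel."""
    matrix = np.array([[-1.0, 1.0], [10.0, -10.0]])
    masks = np.zeros((1, 2, 2), dtype=bool)
    masks[0, 1, 0] = True
    exc = np.zeros((2, 2), dtype=bool)
    exc[0, 1] = True
    return CompositeGenerator(
        matrix=matrix,
        radiative_masks=masks,
        excitation_mask=exc,
        channel_names=("donor",),
        n_system_states=1,
        n_photo_states=2,
    )
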