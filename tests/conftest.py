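import numpy as np
import pytest

from fluxcut import (
    FluxRegion,
    InterventionSpec,
    MetabolicNetwork,
    fig2_bundle,
    fig4_bundle,
)


@pytest.fixture(scope="session")
def fig2():
    return fig2_bundle()


@pytest.fixture(scope="session")
def fig4():
    return fig4_bundle()


@pytest.fixture()
def chain3():
    """up -> A -> B -> out, uptake capped at 10; all unit stoichiometry."""
    stoich = np.array([
        [1.0, -1.0, 0.0],
        [0.0, 1.0, -1.0],
    ])
    net = MetabolicNetwork(
        stoich,
        np.zeros(3),
        np.array([10.0, np.inf, np.inf]),
        ["up", "mid", "out"],
        ["A", "B"],
    )
    spec = InterventionSpec({r: "deletable" for r in net.reaction_ids},
                            {r: 1.0 for r in net.reaction_ids})
    target = FluxRegion("target", np.array([[0.0, 0.0, -1.0]]), np.array([-1.0]),
                        label="product")
    return net, spec, target
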