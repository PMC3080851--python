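import numpy as np
import pytest

from parenchyma.lattice import apply_prestrain, build_cubic_network
from parenchyma.mechanics import BoundaryCondition, ConstitutiveParams, \
    EquilibriumCriteria, equilibrate


@pytest.fixture(scope="session")
def params():
    return ConstitutiveParams()


@pytest.fixture()
def cubic2():
    """Intact 2x2x2 cubic block, as built (no pre-strain)."""
    return build_cubic_network(2)


@pytest.fixture()
def cubic2_eq():
    """Pre-strained, equilibrated 2x2x2 block."""
    net = build_cubic_network(2)
    apply_prestrain(net, 1.2)
    equilibrate(net)
    return net


@pytest.fixture()
def cubic4_eq():
    net = build_cubic_network(4)
    apply_prestrain(net, 1.2)
    equilibrate(net)
    return net


@pytest.fixture()
def damaged2():
    """2x2x2 block with two internal walls removed, re-equilibrated."""
    from parenchyma.destruction import remove_faces
    net = build_cubic_network(2)
    apply_prestrain(net, 1.2)
    equilibrate(net)
    internal = [f.id for f in net.faces if not f.is_boundary]
    remove_faces(net, internal[:2])
    equilibrate(net)
    return net
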