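import numpy as np
import pytest

from colloidkit.shell import ShellGeometry, build_goldberg_shell
from colloidkit.topology import Topology, default_charge_distribution


@pytest.fixture(scope="session")
def gp32():
    """Default 380-atom shell (built once per session)."""
    return build_goldberg_shell(3, 2, 1.42)


@pytest.fixture(scope="session")
def gp11():
    """Small 60-atom shell for cheap oracle comparisons."""
    return build_goldberg_shell(1, 1, 1.42)


@pytest.fixture(scope="session")
def charge_dist():
    return default_charge_distribution()


@pytest.fixture()
def two_point_geometry():
    """Degenerate 2-atom 'shell' for hand-computable dipole checks."""
    pos = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
    return ShellGeometry(
        surface_positions=pos,
        central_position=pos.mean(axis=0),
        bond_length=10.0,
        goldberg_indices=(1, 0),
    )


def make_topology(geometry, charges, **kw) -> Topology:
    return Topology(geometry=geometry, surface_charges=np.asarray(charges, float), **kw)
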