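import numpy as np
import pytest

import memelast as m


@pytest.fixture(scope="session")
def ff():
    return m.ForceFieldParams()


@pytest.fixture(scope="session")
def small_bilayer():
    """4x4 fluid bilayer + solvent; straight chains, freshly built."""
    return m.build_bilayer(4, 4, "fluid", seed=1)


@pytest.fixture(scope="session")
def tiny_lipid_box(ff):
    """Three lipids, no solvent, roomy box — cheap exact-energy oracle system."""
    cfg = m.build_bilayer(2, 2, "fluid", seed=0, solvent_density=0.0)
    keep = cfg.molecules[:3]
    idx = np.concatenate(keep)
    remap = {int(o): i for i, o in enumerate(idx)}
    return m.Configuration(
        positions=cfg.positions[idx].copy(),
        kinds=cfg.kinds[idx].copy(),
        molecules=[[remap[int(b)] for b in mol] for mol in keep],
        box=cfg.box.copy(),
    )


@pytest.fixture(scope="session")
def tri_network():
    return m.make_triangular_network(8, stiffness=100.0)
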