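"""Shared fixtures: small synthetic structures and assemblies.

Everything is generated at test time; no binary fixtures exist.  Scales
are kept small (hundreds of pseudo-atoms, coarse solvent grids) so the
full suite runs in minutes on one CPU.
"""

import numpy as np
import pytest

from oligostate.structure import (RigidTransform, StructureModel,
                                  build_assembly)
from oligostate.synthetic import ToyStructureSpec, make_toy_structure


def toy_model(n: int = 4, coords=None, chains=None, masses=None,
              resnames=None, atoms=None, resnums=None) -> StructureModel:
    """Hand-rolled minimal structure for geometric unit tests."""
    if coords is None:
        coords = np.arange(n * 3, dtype=float).reshape(n, 3)
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if chains is None:
        chains = ["A"] * n
    if resnums is None:
        resnums = np.arange(1, n + 1)
    return StructureModel(
        np.array(chains, dtype=object),
        np.array(resnums, dtype=int),
        np.array(resnames if resnames is not None else ["ALA"] * n, dtype=object),
        np.array(atoms if atoms is not None else ["CA"] * n, dtype=object),
        coords,
        np.array(masses if masses is not None else [110.0] * n, dtype=float),
        np.array(["X"] * n, dtype=object),
    )


@pytest.fixture(scope="session")
def sphere_dimer():
    """Symmetric two-chain sphere-shell dimer with linkable sites."""
    spec = ToyStructureSpec(n_chains=2, atoms_per_chain=100,
                            shape="sphere-shell",
                            labeled_sites=(1, 25, 50, 75, 100),
                            seed=2, radius=10.0, separation=24.0)
    model, truth = make_toy_structure(spec)
    return model, truth


@pytest.fixture(scope="session")
def sphere_dimer_assembly(sphere_dimer):
    model, _ = sphere_dimer
    return build_assembly(model, [RigidTransform.identity()], "dimer")


@pytest.fixture(scope="session")
def two_lobe_dimer_assembly():
    spec = ToyStructureSpec(n_chains=2, atoms_per_chain=120,
                            shape="two-lobe", seed=2,
                            radius=10.0, separation=24.0)
    model, _ = make_toy_structure(spec)
    return build_assembly(model, [RigidTransform.identity()], "dimer")


def random_rigid(rng) -> RigidTransform:
    from scipy.spatial.transform import Rotation
    return RigidTransform(Rotation.random(random_state=rng).as_matrix(),
                          rng.uniform(-50, 50, 3))
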