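import numpy as np
import pytest

from memtrap.io_formats import StructureModel
from memtrap.synthetic_data import SimSpec


@pytest.fixture()
def sim_spec() -> SimSpec:
    """Default study-condition simulation spec with a fixed seed."""
    return SimSpec(seed=1234)


def bead_model(
    xyz, radii=None, groups=None, residue_index=None
) -> StructureModel:
    """Small helper to build ad-hoc bead structures for SASA tests."""
    xyz = np.asarray(xyz, dtype=float)
    n = len(xyz)
    if radii is None:
        radii = np.full(n, 0.2)
    if groups is None:
        groups = ["peptide"] * n
    if residue_index is None:
        residue_index = np.arange(1, n + 1)
    return StructureModel(
        atom_name=["X"] * n,
        residue_index=np.asarray(residue_index),
        residue_name=["XXX"] * n,
        chain_id=["A"] * n,
        xyz=xyz,
        vdw_radius=np.asarray(radii, dtype=float),
        group=list(groups),
    )
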