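import numpy as np
import pytest

import frustevo as fv
from frustevo.structure import Chain, Residue, StructureModel


@pytest.fixture
def em():
    return fv.EnergyModel(seed=11)


@pytest.fixture
def identity_em():
    """e(a, b) = -1 iff a == b, else 0 — closed-form friendly."""
    pot = np.where(np.eye(20, dtype=bool), -1.0, 0.0)
    return fv.EnergyModel(pair_potential=pot, seed=11)


@pytest.fixture
def small_structure():
    return fv.make_structure(40, seed=5)


def manual_model(spec, structure_id="manual"):
    """Build a StructureModel from {chain_id: [(resnum, aa, site_xyz), ...]}.

    The site coordinate is written as both CA and (for non-Gly) CB so the
    representative-site convention lands exactly on it.
    """
    chains = []
    for cid, residues in spec.items():
        rs = []
        for num, aa, xyz in residues:
            xyz = np.asarray(xyz, dtype=float)
            atoms = {"CA": xyz} if aa == "G" else {"CA": xyz, "CB": xyz}
            rs.append(Residue(num, aa, atoms))
        chains.append(Chain(cid, rs))
    return StructureModel(structure_id, chains, 1)
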