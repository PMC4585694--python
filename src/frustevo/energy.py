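"""Residue-pair contact potentials and the energy-model container.

The energy of one residue is the sum of pair energies over its contact-map
neighbors (inter-chain contacts included).  The default potential is a
20x20 symmetric matrix generated from a stated formula rather than fitted
data:

    e(a, b) = -lambda * (h_a + h_b) + mu * |h_a - h_b| + gamma * q_a * q_b

with h the Kyte-Doolittle hydropathy and q the net side-chain charge at
neutral pH (D, E = -1; K, R = +1).  The additive term is the dominant
component of statistical contact matrices; the hydropathy-mismatch term
penalizes hydrophobic-polar contacts (the segregation that drives burial),
and the charge product penalizes like charges and rewards salt bridges.
The mismatch term matters structurally: a potential that is affine in the
candidate identity's features would make the decoy Z-score independent of
which uncharged neighbors a residue has (all candidate energies would
shift and scale together), whereas the |h_a - h_b| kinks tie a residue's
preferred identity to its actual environment.  Any 20x20 symmetric matrix
can be substituted via a whitespace-delimited file with a one-letter
header row and column.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .structure import STANDARD_AA

AA_INDEX = {a: i for i, a in enumerate(STANDARD_AA)}

KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}
CHARGE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0}


def default_pair_potential(
    hydro_scale: float = 0.1,
    mismatch_scale: float = 0.05,
    charge_scale: float = 1.0,
) -> np.ndarray:
    """Hydropathy + hydropathy-mismatch + charge contact potential
    (indexed by ``STANDARD_AA`` order; lower = more stabilizing)."""
    h = np.array([KYTE_DOOLITTLE[a] for a in STANDARD_AA])
    q = np.array([CHARGE.get(a, 0.0) for a in STANDARD_AA])
    e = (
        -hydro_scale * (h[:, None] + h[None, :])
        + mismatch_scale * np.abs(h[:, None] - h[None, :])
        + charge_scale * np.outer(q, q)
    )
    return e


def read_pair_potential(path: str | Path) -> np.ndarray:
    """Read a 20x20 matrix file with one-letter header row and column."""
    lines = [ln.split() for ln in Path(path).read_text().splitlines() if ln.strip()]
    header = lines[0]
    if len(header) != 20 or sorted(header) != sorted(STANDARD_AA):
        raise ValueError("matrix header must list the 20 standard one-letter codes")
    mat = np.zeros((20, 20))
    for row in lines[1:]:
        a = row[0]
        for b, val in zip(header, row[1:]):
            mat[AA_INDEX[a], AA_INDEX[b]] = float(val)
    if not np.allclose(mat, mat.T):
        raise ValueError("pair potential must be symmetric")
    return mat


def write_pair_potential(mat: np.ndarray, path: str | Path) -> None:
    lines = [" ".join(STANDARD_AA)]
    for i, a in enumerate(STANDARD_AA):
        lines.append(a + " " + " ".join(f"{mat[i, j]:.6f}" for j in range(20)))
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class EnergyModel:
    """Everything needed to score a residue.

    ``decoy_policy`` selects how mutational-decoy identities are drawn:
    ``"composition"`` draws from the multiset of identities present in the
    analyzed model; ``"uniform20"`` draws uniformly over the 20 codes.
    """

    pair_potential: np.ndarray = field(default_factory=default_pair_potential)
    contact_cutoff_A: float = 6.5
    min_seq_sep: int = 2
    decoy_policy: str = "composition"
    n_decoys: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        self.pair_potential = np.asarray(self.pair_potential, dtype=float)
        if self.pair_potential.shape != (20, 20):
            raise ValueError("pair_potential must be 20x20")
        if not np.allclose(self.pair_potential, self.pair_potential.T):
            raise ValueError("pair_potential must be symmetric")
        if self.n_decoys < 1:
            raise ValueError("n_decoys must be >= 1")
        if self.decoy_policy not in ("composition", "uniform20"):
            raise ValueError(f"unknown decoy_policy {self.decoy_policy!r}")

    def pair_energy(self, a: str, b: str) -> float:
        return float(self.pair_potential[AA_INDEX[a], AA_INDEX[b]])

    def residue_rng(self, chain_id: str, resnum: int) -> np.random.Generator:
        """Per-residue RNG stream keyed by (global seed, chain id, residue number).

        Adding or removing residues elsewhere never shifts another residue's
        decoy draws; the stream is independent of bound/unbound context so an
        interface-free target cannot perturb it.
        """
        stream = zlib.crc32(f"{chain_id}/{resnum}".encode())
        return np.random.default_rng([int(self.seed), stream])

    def with_seed(self, seed: int) -> "EnergyModel":
        return replace(self, seed=seed)
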