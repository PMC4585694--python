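"""Cleaned protein structure models and residue contact maps.

Reads PDB files into a minimal coarse-grained representation: chains of
residues, each residue carrying its heavy atoms and a single representative
interaction site (Cβ, falling back to Cα for glycine or when Cβ is missing).
Cleaning removes hydrogens, waters, ions and other hetero groups, keeps the
first model of multi-model (NMR) entries by default, maps selenomethionine
to Met, and drops residues with any other nonstandard code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from scipy.spatial.distance import cdist

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


class StructureError(ValueError):
    """Unreadable or unusable structure input."""


class EmptyStructureError(StructureError):
    """No standard amino-acid residues survived cleaning."""


@dataclass
class Residue:
    """One amino acid: author residue number, one-letter code, heavy atoms."""

    number: int
    aa: str
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def site(self) -> np.ndarray:
        """Representative interaction site: Cβ, or Cα for Gly / missing Cβ."""
        if self.aa != "G" and "CB" in self.atoms:
            return self.atoms["CB"]
        return self.atoms["CA"]


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class StructureModel:
    """A cleaned polymer structure (one or more chains, one model)."""

    id: str
    chains: list[Chain] = field(default_factory=list)
    source_model_index: int = 1

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.id!r}")

    def iter_residues(self) -> Iterator[tuple[str, int, Residue]]:
        """Yield (chain_id, within-chain index, residue) in model order."""
        for c in self.chains:
            for k, r in enumerate(c.residues):
                yield c.chain_id, k, r

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    def labels(self) -> list[tuple[str, int]]:
        """(chain_id, author residue number) per residue, in model order."""
        return [(cid, r.number) for cid, _, r in self.iter_residues()]

    def sites(self) -> np.ndarray:
        return np.array([r.site for _, _, r in self.iter_residues()], dtype=float)

    def sequence(self) -> str:
        return "".join(r.aa for _, _, r in self.iter_residues())

    def copy(self) -> "StructureModel":
        chains = [
            Chain(c.chain_id, [Residue(r.number, r.aa, dict(r.atoms)) for r in c.residues])
            for c in self.chains
        ]
        return StructureModel(self.id, chains, self.source_model_index)


@dataclass
class ContactMap:
    """Symmetric residue-residue contacts over a structure's site coordinates.

    ``pairs`` holds (i, j) with i < j, indices into the flattened residue
    order of the structure the map was built from.  Within-chain pairs with
    index separation < ``min_seq_sep`` are excluded; inter-chain pairs are
    never filtered by separation.
    """

    pairs: set[tuple[int, int]]
    cutoff_A: float
    min_seq_sep: int
    labels: list[tuple[str, int]]

    def neighbors(self, i: int) -> list[int]:
        out = [b for a, b in self.pairs if a == i] + [a for a, b in self.pairs if b == i]
        return sorted(out)

    def neighbor_lists(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.labels]
        for a, b in self.pairs:
            adj[a].append(b)
            adj[b].append(a)
        return [sorted(v) for v in adj]


def _pick_altloc(atom):
    """Highest-occupancy alternate location; ties broken by altloc label order."""
    if not atom.is_disordered():
        return atom
    children = sorted(
        atom.disordered_get_list(),
        key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
    )
    return children[0]


def load_structure(
    path: str | Path,
    model_policy: str = "first",
    model_index: int = 1,
) -> StructureModel:
    """Read and clean a PDB file.

    Hydrogens, waters, ions and other hetero groups are dropped; MSE is
    mapped to Met before the 20-code filter; residues with any other
    nonstandard code are dropped with a warning.  ``model_policy`` is
    ``"first"`` (keep model 1, the default for multi-model NMR entries) or
    ``"index"`` (keep the 1-based ``model_index``).
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        pdb = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # noqa: BLE001 - normalise parser failures
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc

    models = list(pdb.get_models())
    if not models:
        raise StructureError(f"no models in {path}")
    if model_policy == "first":
        kept_index = 1
    elif model_policy == "index":
        if not 1 <= model_index <= len(models):
            raise StructureError(
                f"model index {model_index} out of range 1..{len(models)}"
            )
        kept_index = model_index
    else:
        raise ValueError(f"unknown model_policy {model_policy!r}")
    model = models[kept_index - 1]

    chains: list[Chain] = []
    for ch in model:
        residues: list[Residue] = []
        last_number = None
        for res in ch:
            hetflag, resseq, _icode = res.get_id()
            resname = res.get_resname().strip()
            if resname == "MSE":
                resname = "MET"
            elif hetflag.strip():
                continue  # water, ions, ligands
            if resname not in THREE_TO_ONE:
                warnings.warn(
                    f"{path.name}: dropping nonstandard residue {resname} "
                    f"{ch.id}{resseq}"
                )
                continue
            atoms: dict[str, np.ndarray] = {}
            for atom in res:
                a = _pick_altloc(atom)
                if (a.element or "").strip().upper() in ("H", "D"):
                    continue
                atoms[a.get_name()] = np.asarray(a.get_coord(), dtype=float)
            if "CA" not in atoms:
                warnings.warn(f"{path.name}: dropping residue {ch.id}{resseq} (no CA)")
                continue
            if last_number is not None and resseq <= last_number:
                warnings.warn(
                    f"{path.name}: dropping residue {ch.id}{resseq} "
                    "(non-increasing author numbering after cleaning)"
                )
                continue
            residues.append(Residue(resseq, THREE_TO_ONE[resname], atoms))
            last_number = resseq
        if residues:
            chains.append(Chain(ch.id, residues))

    if not chains:
        raise EmptyStructureError(f"no standard amino-acid residues in {path}")
    return StructureModel(path.stem, chains, kept_index)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a StructureModel as a minimal single-model PDB file.

    Used by the synthetic-data generators and tests; atoms are written in
    stored order with occupancy 1.00.
    """
    lines: list[str] = []
    serial = 1
    for chain in model.chains:
        for res in chain.residues:
            res3 = ONE_TO_THREE[res.aa]
            for name, xyz in res.atoms.items():
                pad_name = f" {name:<3s}" if len(name) < 4 else name
                lines.append(
                    f"ATOM  {serial:5d} {pad_name}{'':1s}{res3:>3s} "
                    f"{chain.chain_id}{res.number:4d}{'':1s}   "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {name[0]:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def extract_chains(s: StructureModel, keep: Iterable[str]) -> StructureModel:
    """Restrict a model to the chains in ``keep``; coordinates untouched."""
    keep = set(keep)
    unknown = keep - set(s.chain_ids)
    if not keep:
        raise ValueError("keep must be a nonempty set of chain ids")
    if unknown:
        raise KeyError(f"unknown chain id(s) {sorted(unknown)} in {s.id!r}")
    sub = s.copy()
    sub.chains = [c for c in sub.chains if c.chain_id in keep]
    return sub


def contact_map(
    s: StructureModel, cutoff_A: float = 6.5, min_seq_sep: int = 2
) -> ContactMap:
    """All residue pairs whose sites lie within ``cutoff_A``.

    Within a chain, pairs closer than ``min_seq_sep`` in sequence-index
    separation are excluded (the default 2 drops i, i±1); inter-chain pairs
    are kept at any separation.
    """
    if cutoff_A <= 0:
        raise ValueError("cutoff_A must be positive")
    if min_seq_sep < 1:
        raise ValueError("min_seq_sep must be >= 1")
    entries = list(s.iter_residues())
    if not entries:
        return ContactMap(set(), cutoff_A, min_seq_sep, [])
    sites = np.array([r.site for _, _, r in entries])
    chain_of = np.array([s.chain_ids.index(cid) for cid, _, _ in entries])
    pos = np.array([k for _, k, _ in entries])
    d = cdist(sites, sites)
    pairs: set[tuple[int, int]] = set()
    n = len(entries)
    ii, jj = np.triu_indices(n, k=1)
    close = d[ii, jj] <= cutoff_A
    same = chain_of[ii] == chain_of[jj]
    sep_ok = np.abs(pos[ii] - pos[jj]) >= min_seq_sep
    keep = close & (~same | sep_ok)
    for a, b in zip(ii[keep], jj[keep]):
        pairs.add((int(a), int(b)))
    return ContactMap(pairs, cutoff_A, min_seq_sep, s.labels())


def sequence_of(chain: Chain) -> str:
    """One-letter sequence of a chain in residue order."""
    return "".join(r.aa for r in chain.residues)
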