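"""Ground-truth-labeled synthetic structures, complexes and alignments.

Every pipeline stage can be exercised without downloads:

* :func:`make_structure` builds a compact single-chain model whose Calpha
  trace follows a helix wound along a circular arc (a solenoid), giving a
  dense, deterministic contact graph without physical simulation — the
  frustration machinery needs only a contact graph, not realistic geometry.
* :func:`design_sequence` plants ground-truth frustration: at MF-designed
  positions the identity minimizing the residue's native contact energy is
  chosen, at HF-designed positions the maximizing one, elsewhere random.
* :func:`make_complex` adds a target chain placed so its residues contact
  exactly the requested receptor interface positions.
* :func:`simulate_msa` evolves a root sequence down a known tree under
  uniform replacement (Jukes-Cantor-style over 20 letters) with per-column
  rate classes, yielding known conserved / non-conserved columns.

All generators are seed-deterministic and emit standard formats (PDB,
FASTA, Newick, TSV).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .conservation import MSA, PhyloTree
from .energy import AA_INDEX, EnergyModel
from .structure import STANDARD_AA, Chain, ContactMap, Residue, StructureModel, contact_map


class GeneratorError(RuntimeError):
    pass


# --- structures --------------------------------------------------------------

_TUBE_RADIUS = 2.3      # Calpha helix radius, A
_SITE_OFFSET = 1.5      # Cbeta placed this far beyond Calpha from the tube axis
_POLOIDAL_STEP = math.radians(100.0)  # helix twist per residue
_ARC_PER_RESIDUE = 4.2  # toroidal arc advance per residue, A (winding spacing)


def _solenoid_coords(length: int) -> tuple[np.ndarray, np.ndarray]:
    """Calpha and Cbeta coordinates of the solenoid backbone template."""
    per_turn = 2 * math.pi / _POLOIDAL_STEP  # residues per poloidal turn (3.6)
    ring_radius = max(6.0, 0.24 * length)
    ca = np.empty((length, 3))
    cb = np.empty((length, 3))
    dphi = _ARC_PER_RESIDUE / (per_turn * ring_radius)
    for t in range(length):
        phi = t * dphi
        theta = t * _POLOIDAL_STEP
        u = np.array([math.cos(phi), math.sin(phi), 0.0])
        z = np.array([0.0, 0.0, 1.0])
        center = ring_radius * u
        direction = math.cos(theta) * u + math.sin(theta) * z
        ca[t] = center + _TUBE_RADIUS * direction
        cb[t] = center + (_TUBE_RADIUS + _SITE_OFFSET) * direction
    return ca, cb


def make_structure(
    length: int,
    seed: int,
    chain_id: str = "A",
    sequence: str | None = None,
    structure_id: str = "synthetic",
) -> StructureModel:
    """Compact deterministic single-chain model with a random (or given) sequence.

    Same seed -> bit-identical coordinates and sequence; a different seed
    changes the sequence but not the backbone template.
    """
    if length < 5:
        raise ValueError("length must be >= 5")
    if sequence is not None and len(sequence) != length:
        raise ValueError("sequence length mismatch")
    rng = np.random.default_rng([int(seed), 0x51])
    if sequence is None:
        sequence = "".join(STANDARD_AA[i] for i in rng.integers(0, 20, size=length))
    ca, cb = _solenoid_coords(length)
    ca, cb = np.round(ca, 3), np.round(cb, 3)  # match PDB precision for round-trips
    residues = [
        Residue(t + 1, sequence[t], {"CA": ca[t], "CB": cb[t]})
        for t in range(length)
    ]
    return StructureModel(structure_id, [Chain(chain_id, residues)], 1)


def design_sequence(
    structure: StructureModel,
    designed: dict[int, str],
    em: EnergyModel,
    seed: int,
    max_sweeps: int = 10,
    background: str = "random",
) -> tuple[str, bool]:
    """Plant frustration ground truth by local identity optimization.

    ``designed`` maps residue positions (author numbering of the single
    chain) to "MF" or "HF".  MF positions receive the identity minimizing
    their native contact energy given current neighbors, HF positions the
    maximizing identity; other positions keep a seed-random identity
    (``background="random"``) or the structure's current sequence
    (``background="keep"``).  Sweeps in fixed position order repeat until
    stable or ``max_sweeps``.  Returns (sequence, converged).
    """
    if len(structure.chains) != 1:
        raise ValueError("design_sequence expects a single-chain structure")
    chain = structure.chains[0]
    numbers = [r.number for r in chain.residues]
    idx_of = {num: i for i, num in enumerate(numbers)}
    for pos, state in designed.items():
        if pos not in idx_of:
            raise ValueError(f"designed position {pos} not in structure")
        if state not in ("MF", "HF"):
            raise ValueError(f"designed state must be MF or HF, got {state!r}")

    rng = np.random.default_rng([int(seed), 0xD5])
    if background == "keep":
        codes = np.array([AA_INDEX[r.aa] for r in chain.residues])
    else:
        codes = rng.integers(0, 20, size=len(chain.residues))
    cm = contact_map(structure, em.contact_cutoff_A, em.min_seq_sep)
    adj = cm.neighbor_lists()

    order = sorted(designed)
    converged = False
    for _ in range(max_sweeps):
        changed = False
        for pos in order:
            i = idx_of[pos]
            if not adj[i]:
                continue
            cand = em.pair_potential[:, codes[adj[i]]].sum(axis=1)
            best = int(np.argmin(cand) if designed[pos] == "MF" else np.argmax(cand))
            if codes[i] != best:
                codes[i] = best
                changed = True
        if not changed:
            converged = True
            break
    sequence = "".join(STANDARD_AA[c] for c in codes)
    for r, aa in zip(chain.residues, sequence):
        r.aa = aa
    return sequence, converged


def verify_design(
    structure: StructureModel, designed: dict[int, str], em: EnergyModel
) -> dict[int, bool]:
    """Re-verify local optimality of designed positions.

    True when no single-identity change lowers (MF) / raises (HF) the
    position's native contact energy.  Designed positions that contact each
    other can oscillate during sweeps and fail this check; choosing
    mutually non-adjacent positions guarantees convergence in one sweep.
    """
    chain = structure.chains[0]
    codes = np.array([AA_INDEX[r.aa] for r in chain.residues])
    idx_of = {r.number: i for i, r in enumerate(chain.residues)}
    cm = contact_map(structure, em.contact_cutoff_A, em.min_seq_sep)
    adj = cm.neighbor_lists()
    out = {}
    for pos, state in designed.items():
        i = idx_of[pos]
        if not adj[i]:
            out[pos] = False
            continue
        cand = em.pair_potential[:, codes[adj[i]]].sum(axis=1)
        native = cand[codes[i]]
        out[pos] = bool(
            native <= cand.min() + 1e-12 if state == "MF" else native >= cand.max() - 1e-12
        )
    return out


# --- complexes ---------------------------------------------------------------

def make_complex(
    receptor: StructureModel,
    interface_positions: list[int],
    seed: int,
    target_chain_id: str = "B",
    target_sequence: str | None = None,
    em: EnergyModel | None = None,
) -> StructureModel:
    """Two-chain complex whose inter-chain contact set is exactly the interface.

    One target residue is placed outside each requested receptor position's
    site (within the contact cutoff of that site only); with an empty
    interface the target is a short segment 120 A away.  Raises
    GeneratorError when no placement satisfies the exact-contact-set
    contract.
    """
    if len(receptor.chains) != 1:
        raise ValueError("receptor must be single-chain")
    em = em or EnergyModel()
    cutoff = em.contact_cutoff_A
    chain = receptor.chains[0]
    idx_of = {r.number: i for i, r in enumerate(chain.residues)}
    for pos in interface_positions:
        if pos not in idx_of:
            raise ValueError(f"interface position {pos} not in receptor")

    rng = np.random.default_rng([int(seed), 0xC0])
    sites = np.array([r.site for r in chain.residues])
    centroid = sites.mean(axis=0)

    n_target = max(len(interface_positions), 3)
    if target_sequence is None:
        target_sequence = "".join(
            STANDARD_AA[i] for i in rng.integers(0, 20, size=n_target)
        )
    elif len(target_sequence) < len(interface_positions):
        raise ValueError("target_sequence shorter than interface")

    target_sites: list[np.ndarray] = []
    placed_dirs: list[np.ndarray] = []
    for pos in interface_positions:
        site = sites[idx_of[pos]]
        # local outward normal: away from the nearby residue cloud
        near = sites[np.linalg.norm(sites - site, axis=1) < 10.0]
        base_dir = site - near.mean(axis=0)
        norm = np.linalg.norm(base_dir)
        base_dir = base_dir / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
        placed = None
        for attempt in range(300):
            if attempt == 0:
                direction = base_dir
            elif attempt < 150:
                jitter = rng.normal(scale=0.4, size=3)
                direction = base_dir + jitter
                direction /= np.linalg.norm(direction)
            else:
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
            for dist in (5.5, 5.0, 6.0, 4.5, 6.3, 4.0):
                cand = site + dist * direction
                d_all = np.linalg.norm(sites - cand, axis=1)
                # guard band keeps the decision stable under the 0.001 A
                # coordinate rounding of the PDB writer
                others_clear = np.all(np.delete(d_all, idx_of[pos]) > cutoff + 0.01)
                if d_all[idx_of[pos]] <= cutoff - 0.01 and others_clear:
                    placed = cand
                    break
            if placed is not None:
                break
        if placed is None:
            raise GeneratorError(
                f"cannot place target residue against receptor position {pos}"
            )
        target_sites.append(placed)
        placed_dirs.append(direction)

    # pad the target chain to n_target residues with far-away spacers
    far = centroid + np.array([120.0, 0.0, 0.0])
    k = 0
    while len(target_sites) < n_target:
        target_sites.append(far + np.array([0.0, 8.0 * k, 0.0]))
        placed_dirs.append(np.array([1.0, 0.0, 0.0]))
        k += 1

    residues = []
    for t, (site, direction) in enumerate(zip(target_sites, placed_dirs)):
        aa = target_sequence[t]
        # the representative site (CB, or CA for Gly) must land on the
        # computed contact point
        if aa == "G":
            atoms = {"CA": np.round(site, 3)}
        else:
            atoms = {"CA": np.round(site + 1.5 * direction, 3),
                     "CB": np.round(site, 3)}
        residues.append(Residue(t + 1, aa, atoms))

    cx = receptor.copy()
    cx.id = f"{receptor.id}_complex"
    cx.chains.append(Chain(target_chain_id, residues))

    cm = contact_map(cx, cutoff, em.min_seq_sep)
    inter = interchain_contacts(cx, cm, chain.chain_id, target_chain_id)
    expected = {idx_of[p] for p in interface_positions}
    if {i for i, _ in inter} != expected:
        raise GeneratorError(
            f"interface mismatch: wanted receptor indices {sorted(expected)}, "
            f"got {sorted({i for i, _ in inter})}"
        )
    return cx


def interchain_contacts(
    cx: StructureModel, cm: ContactMap, chain_a: str, chain_b: str
) -> set[tuple[int, int]]:
    """(within-chain-A index, within-chain-B index) pairs in contact."""
    labels = cm.labels
    chain_of = [cid for cid, _ in labels]
    # within-chain running index
    within: list[int] = []
    counters: dict[str, int] = {}
    for cid, _ in labels:
        counters[cid] = counters.get(cid, -1) + 1
        within.append(counters[cid])
    out = set()
    for a, b in cm.pairs:
        ca, cb = chain_of[a], chain_of[b]
        if {ca, cb} == {chain_a, chain_b}:
            if ca == chain_a:
                out.add((within[a], within[b]))
            else:
                out.add((within[b], within[a]))
    return out


def make_null_complex(receptor: StructureModel, target_chain_id: str = "B") -> StructureModel:
    """Receptor plus a far-away copy of itself: zero inter-chain contacts and
    a target composition exactly proportional to the receptor's, so bound and
    unbound rescoring agree bit-for-bit under either decoy policy."""
    if len(receptor.chains) != 1:
        raise ValueError("receptor must be single-chain")
    cx = receptor.copy()
    cx.id = f"{receptor.id}_null"
    shift = np.array([200.0, 0.0, 0.0])
    ghost = [
        Residue(r.number, r.aa, {k: np.round(v + shift, 3) for k, v in r.atoms.items()})
        for r in receptor.chains[0].residues
    ]
    cx.chains.append(Chain(target_chain_id, ghost))
    return cx


# --- alignments --------------------------------------------------------------

RATE_CLASSES = {"invariant": 0.0, "slow": 0.3, "fast": 2.0}


@dataclass
class _Node:
    name: str | None = None
    length: float = 0.0
    children: list["_Node"] = field(default_factory=list)

    def newick(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}):{self.length:.6f}"


def random_tree(n_leaves: int, rng: np.random.Generator,
                branch_low: float = 0.05, branch_high: float = 0.25) -> _Node:
    """Random bifurcating tree over leaves s1..sN by successive random joins."""
    nodes = [_Node(name=f"s{i + 1}", length=float(rng.uniform(branch_low, branch_high)))
             for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = _Node(length=float(rng.uniform(branch_low, branch_high)),
                       children=[left, right])
        nodes.append(parent)
    root = nodes[0]
    root.length = 0.0
    return root


@dataclass
class SimulatedMSA:
    msa: MSA
    tree: PhyloTree
    newick: str
    column_classes: list[str]  # rate class per column
    root_sequence: str


def simulate_msa(
    n_leaves: int,
    column_classes: list[str],
    seed: int,
    root_sequence: str | None = None,
    include_root_as: str | None = "ref",
    tree: _Node | None = None,
) -> SimulatedMSA:
    """Evolve a root sequence down a known tree; no indels.

    Substitution model: along a branch of length t, a column of rate r
    experiences Poisson(r*t) replacement events, each drawing uniformly
    from the 20 amino acids (so the column stays put with probability
    exp(-r*t) + (1-exp(-r*t))/20).  Invariant columns never change.

    ``include_root_as`` grafts an extra zero-length leaf at the root
    carrying the unmutated root sequence, giving the alignment an exact
    reference record; pass None to omit it.
    """
    for c in column_classes:
        if c not in RATE_CLASSES:
            raise ValueError(f"unknown rate class {c!r}")
    rng = np.random.default_rng([int(seed), 0x35A])
    n_cols = len(column_classes)
    if root_sequence is None:
        root_sequence = "".join(STANDARD_AA[i] for i in rng.integers(0, 20, size=n_cols))
    if len(root_sequence) != n_cols:
        raise ValueError("root_sequence length must equal number of columns")
    rates = np.array([RATE_CLASSES[c] for c in column_classes])

    if tree is None:
        tree = random_tree(n_leaves, rng)
    if include_root_as is not None:
        tree = _Node(length=0.0,
                     children=[tree, _Node(name=include_root_as, length=0.0)])
        tree.children[0].length = max(tree.children[0].length, 1e-6)

    root_codes = np.array([AA_INDEX[a] for a in root_sequence])
    records: list[tuple[str, str]] = []

    def evolve(node: _Node, codes: np.ndarray) -> None:
        if node.length > 0:
            n_events = rng.poisson(rates * node.length)
            hit = n_events > 0
            if hit.any():
                codes = codes.copy()
                codes[hit] = rng.integers(0, 20, size=int(hit.sum()))
        if not node.children:
            records.append((node.name, "".join(STANDARD_AA[c] for c in codes)))
        for child in node.children:
            evolve(child, codes)

    evolve(tree, root_codes)
    ids = [r[0] for r in records]
    seqs = [r[1] for r in records]
    ref_id = include_root_as if include_root_as is not None else ids[0]
    msa = MSA(ids, seqs, reference_id=ref_id)
    newick = tree.newick() + ";"
    return SimulatedMSA(
        msa=msa,
        tree=PhyloTree.from_newick(newick),
        newick=newick,
        column_classes=list(column_classes),
        root_sequence=root_sequence,
    )
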