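"""Evolutionary-trace-style conservation ranks from an MSA and a tree.

The rank of an alignment column follows the real-valued evolutionary-trace
construction: the phylogenetic tree is cut just below its n-1 highest
internal nodes to partition the leaves into n groups, for every level
n = 1..N-1; the column's score is

    rho_i = 1 + sum_{n=1}^{N-1} (1/n) * sum_{g in groups(n)} H_g(i)

where H_g(i) is the Shannon entropy (natural log) of the amino-acid
frequencies at column i within group g, gaps excluded (an all-gap group
contributes 0).  Invariant columns score exactly 1; lower scores mean
earlier fixation in the tree, i.e. stronger conservation.  A column is
conserved (C) when rho is strictly below the cutoff (default 5) and
non-conserved (NC) otherwise.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .structure import STANDARD_AA

GAP_CHARS = "-."
_LETTER_CODE = {a: i for i, a in enumerate(STANDARD_AA)}
_GAP_CODE = 20


class ConservationError(ValueError):
    pass


@dataclass
class MSA:
    """An aligned sequence set with a designated reference record."""

    ids: list[str]
    seqs: list[str]
    reference_id: str

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ConservationError("ids and seqs length mismatch")
        if len({len(s) for s in self.seqs}) > 1:
            raise ConservationError("aligned sequences must have equal length")
        if self.reference_id not in self.ids:
            raise ConservationError(f"reference {self.reference_id!r} not in MSA")

    @property
    def n_records(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    @property
    def reference_seq(self) -> str:
        return self.seqs[self.ids.index(self.reference_id)]

    def encoded(self) -> np.ndarray:
        """(records, columns) int array: 0..19 amino acids, 20 gap."""
        out = np.empty((self.n_records, self.n_columns), dtype=np.int8)
        for r, seq in enumerate(self.seqs):
            for c, ch in enumerate(seq.upper()):
                if ch in _LETTER_CODE:
                    out[r, c] = _LETTER_CODE[ch]
                elif ch in GAP_CHARS:
                    out[r, c] = _GAP_CODE
                else:
                    raise ConservationError(
                        f"record {self.ids[r]!r}: unsupported symbol {ch!r}"
                    )
        return out

    @classmethod
    def from_file(
        cls, path: str | Path, reference_id: str | None = None, fmt: str | None = None
    ) -> "MSA":
        """Read a FASTA or Clustal alignment; default reference = first record."""
        from Bio import AlignIO

        path = Path(path)
        if fmt is None:
            head = path.read_text().lstrip()[:7].upper()
            fmt = "clustal" if head.startswith("CLUSTAL") else "fasta"
        aln = AlignIO.read(str(path), fmt)
        ids = [rec.id for rec in aln]
        seqs = [str(rec.seq) for rec in aln]
        return cls(ids, seqs, reference_id or ids[0])

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rid, seq in zip(self.ids, self.seqs):
                fh.write(f">{rid}\n{seq}\n")


def filter_sequences(
    raw: list[tuple[str, str]], reference: str, min_len_frac: float = 0.8
) -> list[tuple[str, str]]:
    """Homolog-set filter applied before alignment-based analysis.

    Drops sequences identical to the reference and sequences whose ungapped
    length is below ``min_len_frac`` times the reference's ungapped length;
    the reference itself is retained exactly once.
    """
    if not (0 < min_len_frac <= 1):
        raise ValueError("min_len_frac must be in (0, 1]")
    ref = _ungap(reference)
    if not ref:
        raise ValueError("reference sequence is empty")
    min_len = min_len_frac * len(ref)
    kept: list[tuple[str, str]] = []
    reference_kept = False
    for rid, seq in raw:
        s = _ungap(seq)
        if s == ref:
            if not reference_kept:
                kept.append((rid, seq))
                reference_kept = True
            continue
        if len(s) < min_len:
            continue
        kept.append((rid, seq))
    if not kept:
        raise ConservationError("no sequences survive filtering")
    return kept


def _ungap(seq: str) -> str:
    return "".join(ch for ch in seq if ch not in GAP_CHARS)


# --- tree handling -----------------------------------------------------------


@dataclass
class PhyloTree:
    """Rooted tree wrapper exposing heights and level partitions.

    Node height is the maximum branch-length path to any descendant leaf
    (negative branch lengths are clamped to zero, missing lengths count as
    one), so heights are weakly decreasing from root to leaves.
    """

    clade: object  # Bio.Phylo root clade

    def __post_init__(self) -> None:
        self._heights: dict[int, float] = {}
        self._preorder: dict[int, int] = {}
        self._compute_heights(self.clade)
        for idx, node in enumerate(self._walk_preorder(self.clade)):
            self._preorder[id(node)] = idx

    def _compute_heights(self, node) -> float:
        kids = getattr(node, "clades", [])
        if not kids:
            h = 0.0
        else:
            h = max(
                max(0.0, k.branch_length if k.branch_length is not None else 1.0)
                + self._compute_heights(k)
                for k in kids
            )
        self._heights[id(node)] = h
        return h

    def _walk_preorder(self, node):
        yield node
        for k in getattr(node, "clades", []):
            yield from self._walk_preorder(k)

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self._walk_preorder(self.clade) if not getattr(n, "clades", [])]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def height(self, node) -> float:
        """Max branch-length path from ``node`` to a descendant leaf."""
        return self._heights[id(node)]

    @property
    def root_height(self) -> float:
        return self._heights[id(self.clade)]

    def internal_nodes_by_height(self) -> list[object]:
        """Internal nodes, highest first; ties broken by preorder index."""
        internals = [n for n in self._walk_preorder(self.clade) if getattr(n, "clades", [])]
        return sorted(internals, key=lambda n: (-self._heights[id(n)], self._preorder[id(n)]))

    def leaves_under(self, node) -> list[str]:
        return [n.name for n in self._walk_preorder(node) if not getattr(n, "clades", [])]

    @classmethod
    def from_newick(cls, text_or_path: str | Path) -> "PhyloTree":
        from Bio import Phylo

        text = str(text_or_path)
        if "(" in text or ";" in text:  # newick literal, not a path
            tree = Phylo.read(io.StringIO(text), "newick")
        else:
            tree = Phylo.read(text, "newick")
        return cls(tree.root)

    def to_newick(self, path: str | Path) -> None:
        from Bio import Phylo
        from Bio.Phylo import BaseTree

        Phylo.write(BaseTree.Tree(root=self.clade, rooted=True), str(path), "newick")


def p_distance(a: str, b: str) -> float:
    """Fraction of mismatches over columns where both sequences are ungapped."""
    comparable = mismatch = 0
    for x, y in zip(a, b):
        if x in GAP_CHARS or y in GAP_CHARS:
            continue
        comparable += 1
        if x != y:
            mismatch += 1
    return mismatch / comparable if comparable else 1.0


def build_tree(msa: MSA) -> PhyloTree:
    """Neighbor-joining on p-distances, midpoint-rooted; deterministic.

    External trees (Newick) can be supplied instead via
    ``PhyloTree.from_newick`` — see :func:`validate_tree`.
    """
    if msa.n_records < 2:
        raise ConservationError("at least 2 records required to build a tree")
    if msa.n_records == 2:
        d = p_distance(msa.seqs[0], msa.seqs[1])
        nwk = f"({msa.ids[0]}:{d / 2:.8f},{msa.ids[1]}:{d / 2:.8f}):0;"
        return PhyloTree.from_newick(nwk)

    from Bio.Phylo.TreeConstruction import DistanceMatrix, DistanceTreeConstructor

    names = list(msa.ids)
    matrix = [
        [p_distance(msa.seqs[i], msa.seqs[j]) for j in range(i + 1)]
        for i in range(len(names))
    ]
    tree = DistanceTreeConstructor().nj(DistanceMatrix(names, matrix))
    for clade in tree.find_clades():
        if clade.branch_length is not None and clade.branch_length < 0:
            clade.branch_length = 0.0
        if clade.clades:
            clade.name = None  # drop NJ's Inner## labels
    tree.root_at_midpoint()
    return PhyloTree(tree.root)


def validate_tree(tree: PhyloTree, msa: MSA) -> None:
    if sorted(tree.leaf_names) != sorted(msa.ids):
        raise ConservationError("tree leaf set does not match MSA record ids")


def level_partitions(tree: PhyloTree) -> list[list[list[str]]]:
    """Leaf partitions for levels n = 1..N-1.

    Level n cuts the tree at the n-1 highest internal nodes (root first,
    descending height, ties by preorder index); groups are the maximal
    subtrees hanging below the cut.  Partitions are nested.
    """
    internals = tree.internal_nodes_by_height()
    n_leaves = tree.n_leaves
    partitions: list[list[list[str]]] = []
    for n in range(1, n_leaves):
        cut = {id(node) for node in internals[: n - 1]}
        if not cut:
            partitions.append([list(tree.leaf_names)])
            continue
        groups: list[list[str]] = []

        def collect(node):
            if id(node) in cut:
                for k in node.clades:
                    collect(k)
            else:
                groups.append(tree.leaves_under(node))

        collect(tree.clade)
        partitions.append(groups)
    return partitions


# --- rvET scores -------------------------------------------------------------


@dataclass
class ConservationProfile:
    """Per reference-position rvET score and C/NC state."""

    table: pd.DataFrame  # columns: position, ref_aa, column_index, rvet, state
    cutoff: float = 5.0

    def rvet(self, position: int) -> float:
        row = self.table[self.table.position == position]
        if row.empty:
            raise KeyError(f"no reference position {position}")
        return float(row.rvet.iloc[0])

    def state(self, position: int) -> str:
        row = self.table[self.table.position == position]
        if row.empty:
            raise KeyError(f"no reference position {position}")
        return str(row.state.iloc[0])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path: str | Path, cutoff: float = 5.0) -> "ConservationProfile":
        return cls(pd.read_csv(path, sep="\t"), cutoff)


def conservation_state(rho: float, cutoff: float = 5.0) -> str:
    """C when rho is strictly below the cutoff, otherwise NC."""
    return "C" if rho < cutoff else "NC"


def column_scores(msa: MSA, tree: PhyloTree) -> np.ndarray:
    """rvET score for every MSA column (including reference-gap columns)."""
    validate_tree(tree, msa)
    enc = msa.encoded()
    row_of = {rid: i for i, rid in enumerate(msa.ids)}
    n_cols = msa.n_columns
    scores = np.ones(n_cols)
    for n, groups in enumerate(level_partitions(tree), start=1):
        level_sum = np.zeros(n_cols)
        for group in groups:
            rows = enc[[row_of[g] for g in group], :]
            counts = np.zeros((21, n_cols))
            for code in range(21):
                counts[code] = (rows == code).sum(axis=0)
            aa_counts = counts[:20]
            totals = aa_counts.sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                freqs = np.where(totals > 0, aa_counts / np.maximum(totals, 1), 0.0)
                ent = -np.where(freqs > 0, freqs * np.log(freqs), 0.0).sum(axis=0)
            ent[totals == 0] = 0.0  # all-gap group contributes nothing
            level_sum += ent
        scores += level_sum / n
    return scores


def rvet_scores(msa: MSA, tree: PhyloTree, cutoff: float = 5.0) -> ConservationProfile:
    """Conservation profile over the reference's ungapped positions.

    Columns where the reference is gapped are dropped; positions are
    1-based indices into the reference's ungapped sequence.
    """
    scores = column_scores(msa, tree)
    ref = msa.reference_seq
    rows = []
    pos = 0
    for col, ch in enumerate(ref):
        if ch in GAP_CHARS:
            continue
        pos += 1
        rho = float(scores[col])
        rows.append((pos, ch.upper(), col, rho, conservation_state(rho, cutoff)))
    table = pd.DataFrame(rows, columns=["position", "ref_aa", "column_index", "rvet", "state"])
    return ConservationProfile(table=table, cutoff=cutoff)


def distribution_cutoff(scores: np.ndarray) -> float:
    """Two-cluster split of a score distribution, for cutoff selection.

    One-dimensional two-means: returns the midpoint between the two cluster
    centers, iterated to convergence from the extremes.  Used when a fixed
    cutoff is not appropriate (e.g. simulated alignments), mirroring
    distribution-based cutoff choice on real homolog sets.
    """
    s = np.sort(np.asarray(scores, dtype=float))
    if s.size < 2 or s[0] == s[-1]:
        return float(s[0]) if s.size else 1.0
    lo, hi = float(s[0]), float(s[-1])
    for _ in range(100):
        mid = (lo + hi) / 2
        left = s[s <= mid]
        right = s[s > mid]
        if left.size == 0 or right.size == 0:
            break
        new_lo, new_hi = float(left.mean()), float(right.mean())
        if new_lo == lo and new_hi == hi:
            break
        lo, hi = new_lo, new_hi
    return (lo + hi) / 2
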