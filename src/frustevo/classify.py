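"""Six-class residue tables: frustration state x conservation state.

Joins per-complex frustration profiles (mapped onto a common reference
sequence) with a single conservation profile, yielding the six-class
assignment {MF, HF, N} x {C, NC} per residue per complex, ensemble counts
("minimally frustrated in 53 out of 58 complexes"-style), per-complex class
fractions, and the 2-D rvET-vs-SRLF map data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .conservation import ConservationProfile
from .frustration import FrustrationProfile

SIX_CLASSES = ["(MF, C)", "(HF, C)", "(HF, NC)", "(MF, NC)", "(N, C)", "(N, NC)"]


def six_class(srlf_state: str, cons_state: str) -> str:
    """Pair a frustration state with a conservation state into a class label."""
    if srlf_state not in ("MF", "HF", "N"):
        raise ValueError(f"unknown frustration state {srlf_state!r}")
    if cons_state not in ("C", "NC"):
        raise ValueError(f"unknown conservation state {cons_state!r}")
    return f"({srlf_state}, {cons_state})"


def map_to_reference(
    chain_seq: str, reference: str, min_identity: float = 0.6
) -> dict[int, int]:
    """Map 1-based chain positions to 1-based reference positions.

    Global alignment with match +1, mismatch 0, gap -1 per symbol plus an
    infinitesimal gap-opening surcharge, and a deterministic traceback that
    prefers reference-gap runs over diagonal moves.  Both choices matter on
    EF-hand-style sequences: with mismatches costing 0 and heavy internal
    repeats, scattered alignments tie the contiguous one under purely
    linear gaps, and even run-count ties remain (a tail can match an
    equivalent motif of a later repeat); the opening surcharge plus the
    trailing-gap-first traceback make truncated chains map as a single
    contiguous offset block.  If the aligned identity over the chain falls
    below ``min_identity`` a warning is issued and the mapping is empty.
    """
    if not chain_seq or not reference:
        raise ValueError("both sequences must be nonempty")
    mapping, matches = _affine_block_align(chain_seq, reference)
    identity = matches / len(chain_seq)
    if identity < min_identity:
        warnings.warn(
            f"chain-to-reference identity {identity:.2f} below floor "
            f"{min_identity:.2f}; returning empty mapping"
        )
        return {}
    return dict(sorted(mapping.items()))


_NEG = -1e18


def _affine_block_align(chain_seq: str, reference: str) -> tuple[dict[int, int], int]:
    """Gotoh global alignment returning (chain->reference mapping, matches).

    Scores: match 1, mismatch 0, gap open -(1 + 1e-6), gap extend -1.
    Traceback preference: reference-gap (X) > diagonal (M) > chain-gap (Y).
    """
    n, m = len(chain_seq), len(reference)
    go, ge = 1.0 + 1e-6, 1.0
    ref = np.frombuffer(reference.encode(), dtype=np.uint8)
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in chain: reference consumed
    Y = np.full((n + 1, m + 1), _NEG)  # gap in reference: chain consumed
    M[0, 0] = 0.0
    X[0, 1:] = -go - ge * np.arange(m)
    Y[1:, 0] = -go - ge * np.arange(n)
    for i in range(1, n + 1):
        sub = (ref == ord(chain_seq[i - 1])).astype(float)
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = prev_best[:-1] + sub
        Y[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], X[i - 1, 1:]) - go, Y[i - 1, 1:] - ge
        )
        Y[i, 0] = -go - ge * (i - 1)
        row_m, row_y, row_x = M[i], Y[i], X[i]
        acc = _NEG
        for j in range(1, m + 1):
            acc = max(max(row_m[j - 1], row_y[j - 1]) - go, acc - ge)
            row_x[j] = acc
    mapping: dict[int, int] = {}
    matches = 0
    i, j = n, m
    # equality up to 1e-9: float rounding is ~1e-12 per cell while the
    # gap-opening surcharge that the tie-break relies on is 1e-6
    eq = lambda a, b: abs(a - b) < 1e-9  # noqa: E731
    scores = {"X": X[n, m], "M": M[n, m], "Y": Y[n, m]}
    state = max(("X", "M", "Y"), key=lambda s: (scores[s], s == "X", s == "M"))
    while i > 0 or j > 0:
        if state == "M":
            sub = 1.0 if chain_seq[i - 1] == reference[j - 1] else 0.0
            if sub:
                matches += 1
            mapping[i] = j
            target = M[i, j] - sub
            i, j = i - 1, j - 1
            for s, mat in (("X", X), ("M", M), ("Y", Y)):
                if eq(mat[i, j], target):
                    state = s
                    break
        elif state == "X":  # reference consumed against a chain gap
            if eq(X[i, j], X[i, j - 1] - ge):
                j -= 1  # extend the run (prefers the longest, leftmost-opened run)
            else:
                target = X[i, j] + go
                j -= 1
                state = "M" if eq(M[i, j], target) else "Y"
        else:  # Y: chain consumed against a reference gap
            if eq(Y[i, j], Y[i - 1, j] - ge):
                i -= 1
            else:
                target = Y[i, j] + go
                i -= 1
                state = "X" if eq(X[i, j], target) else "M"
    return dict(sorted(mapping.items())), matches


@dataclass
class ComplexEntry:
    """One complex's contribution to the ensemble table."""

    complex_id: str
    profile: FrustrationProfile
    chain_id: str  # receptor chain carrying the reference protein
    mapping: Mapping[int, int]  # chain 1-based position -> reference position


@dataclass
class ResidueClassTable:
    """Joined six-class assignments: per-position ensemble summary plus
    the per-(complex, residue) long table and per-complex class fractions."""

    per_position: pd.DataFrame
    per_complex: pd.DataFrame
    fractions: pd.DataFrame
    unmapped: pd.DataFrame


def _modal_state(states: Sequence[str]) -> str:
    """Modal frustration state; ties resolve to neutral."""
    counts = pd.Series(states).value_counts()
    top = counts.max()
    winners = sorted(counts[counts == top].index)
    return winners[0] if len(winners) == 1 else "N"


def aggregate(
    entries: Iterable[ComplexEntry], cons: ConservationProfile
) -> ResidueClassTable:
    """Build the ensemble six-class table across complexes.

    Conservation is computed once for the reference and shared by every
    complex.  Residues that do not map to the reference are tallied in
    ``unmapped`` rather than silently dropped.
    """
    entries = list(entries)
    if not entries:
        raise ValueError("at least one complex entry is required")
    cons_by_pos = cons.table.set_index("position")

    long_rows = []
    unmapped_rows = []
    for e in entries:
        chain_rows = e.profile.table[e.profile.table.chain == e.chain_id]
        for k, row in enumerate(chain_rows.itertuples(), start=1):
            ref_pos = e.mapping.get(k)
            if ref_pos is None or ref_pos not in cons_by_pos.index:
                unmapped_rows.append((e.complex_id, e.chain_id, row.resnum, row.aa))
                continue
            crow = cons_by_pos.loc[ref_pos]
            long_rows.append(
                (e.complex_id, ref_pos, row.aa, float(row.srlf), row.state,
                 float(crow.rvet), crow.state, six_class(row.state, crow.state))
            )
    per_complex = pd.DataFrame(
        long_rows,
        columns=["complex", "position", "aa", "srlf", "state_frust",
                 "rvet", "state_cons", "class"],
    )
    unmapped = pd.DataFrame(
        unmapped_rows, columns=["complex", "chain", "resnum", "aa"]
    )

    pos_rows = []
    for pos, grp in per_complex.groupby("position"):
        counts = grp.state_frust.value_counts()
        consensus = _modal_state(list(grp.state_frust))
        crow = cons_by_pos.loc[pos]
        pos_rows.append(
            (pos, crow.ref_aa, float(crow.rvet), crow.state,
             int(counts.get("MF", 0)), int(counts.get("N", 0)),
             int(counts.get("HF", 0)), int(len(grp)), consensus,
             six_class(consensus, crow.state))
        )
    per_position = pd.DataFrame(
        pos_rows,
        columns=["position", "aa", "rvet", "state_cons", "n_MF", "n_N", "n_HF",
                 "n_total", "consensus", "consensus_class"],
    ).sort_values("position").reset_index(drop=True)

    frac_rows = []
    for cid, grp in per_complex.groupby("complex"):
        frac = grp["class"].value_counts(normalize=True)
        frac_rows.append([cid] + [float(frac.get(c, 0.0)) for c in SIX_CLASSES])
    pooled = per_complex["class"].value_counts(normalize=True)
    frac_rows.append(["pooled"] + [float(pooled.get(c, 0.0)) for c in SIX_CLASSES])
    fractions = pd.DataFrame(frac_rows, columns=["complex"] + SIX_CLASSES)

    return ResidueClassTable(
        per_position=per_position,
        per_complex=per_complex,
        fractions=fractions,
        unmapped=unmapped,
    )


def two_d_map(table: ResidueClassTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scatter points (rvet, srlf per residue per complex) and region counts.

    The six regions are exactly the six classes, so region counts agree
    with the class tallies by construction.
    """
    points = table.per_complex[["complex", "position", "rvet", "srlf", "class"]].copy()
    counts = points["class"].value_counts()
    regions = pd.DataFrame(
        {"class": SIX_CLASSES, "count": [int(counts.get(c, 0)) for c in SIX_CLASSES]}
    )
    return points, regions


def residue_report(table: ResidueClassTable, positions: Sequence[int]) -> pd.DataFrame:
    """Restrict the ensemble table to selected reference positions
    (e.g. the Met set or the Leu set)."""
    known = set(table.per_position.position)
    unknown = [p for p in positions if p not in known]
    if unknown:
        raise KeyError(f"unknown reference position(s) {unknown}")
    sub = table.per_position[table.per_position.position.isin(positions)]
    return sub.reset_index(drop=True)
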