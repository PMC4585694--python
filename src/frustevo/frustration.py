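"""Single-residue-level frustration (SRLF) via mutational decoys.

Each residue's native contact energy is compared, as a Z-score, to the
energies obtained when only that residue's amino-acid identity is replaced
by randomly drawn alternatives (geometry and all neighbor identities fixed).
A residue is minimally frustrated (MF) when its SRLF index is > 1 — the
native identity is markedly more stabilizing than random alternatives —
highly frustrated (HF) when it is < -1, and neutral (N) in between, with
the boundary values classified neutral.  Residues whose decoy energies have
zero spread (e.g. no contacts) are flagged degenerate, given SRLF 0 and
classified neutral.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .energy import AA_INDEX, EnergyModel
from .structure import (
    STANDARD_AA,
    ContactMap,
    StructureModel,
    contact_map,
    extract_chains,
)

PROFILE_COLUMNS = [
    "chain", "resnum", "aa", "E_native", "decoy_mean", "decoy_sd",
    "srlf", "state", "degenerate", "context",
]


def classify_srlf(srlf: float, degenerate: bool = False) -> str:
    """MF for srlf > 1, HF for srlf < -1, otherwise N (boundaries neutral)."""
    if degenerate:
        return "N"
    if srlf > 1.0:
        return "MF"
    if srlf < -1.0:
        return "HF"
    return "N"


@dataclass
class FrustrationProfile:
    """Per-residue SRLF indices and MF/N/HF states for one structure."""

    table: pd.DataFrame
    context: str = "bound"

    def srlf(self, chain: str, resnum: int) -> float:
        row = self.table[(self.table.chain == chain) & (self.table.resnum == resnum)]
        if row.empty:
            raise KeyError(f"no residue {chain}/{resnum} in profile")
        return float(row.srlf.iloc[0])

    def state(self, chain: str, resnum: int) -> str:
        row = self.table[(self.table.chain == chain) & (self.table.resnum == resnum)]
        if row.empty:
            raise KeyError(f"no residue {chain}/{resnum} in profile")
        return str(row.state.iloc[0])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FrustrationProfile":
        table = pd.read_csv(path, sep="\t")
        ctx = table["context"].iloc[0] if len(table) else "bound"
        return cls(table=table, context=str(ctx))


def _aa_codes(s: StructureModel) -> np.ndarray:
    return np.array([AA_INDEX[r.aa] for _, _, r in s.iter_residues()], dtype=int)


def _composition_weights(s: StructureModel) -> np.ndarray:
    counts = np.bincount(_aa_codes(s), minlength=20).astype(float)
    return counts / counts.sum()


def _decoy_weights(s: StructureModel, em: EnergyModel) -> np.ndarray:
    if em.decoy_policy == "uniform20":
        return np.full(20, 1.0 / 20.0)
    return _composition_weights(s)


def _candidate_energies(
    aa_codes: np.ndarray, neighbors: Sequence[int], em: EnergyModel
) -> np.ndarray:
    """Energy of residue i for each of the 20 candidate identities.

    Neighbor identities stay native; with no neighbors all candidates score 0.
    """
    if not neighbors:
        return np.zeros(20)
    return em.pair_potential[:, aa_codes[list(neighbors)]].sum(axis=1)


def native_residue_energy(
    s: StructureModel, cm: ContactMap, em: EnergyModel, i: int
) -> float:
    """Sum of pair energies over residue i's contacts (inter-chain included)."""
    aa_codes = _aa_codes(s)
    adj = cm.neighbor_lists()
    return float(_candidate_energies(aa_codes, adj[i], em)[aa_codes[i]])


def mutational_decoy_energies(
    s: StructureModel,
    cm: ContactMap,
    em: EnergyModel,
    i: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Energies of N single-residue mutational decoys at position i.

    Each decoy replaces only residue i's identity with a draw per the
    energy model's decoy policy; geometry and neighbors are unchanged.
    """
    aa_codes = _aa_codes(s)
    adj = cm.neighbor_lists()
    cand = _candidate_energies(aa_codes, adj[i], em)
    weights = _decoy_weights(s, em)
    if rng is None:
        cid, resnum = cm.labels[i]
        rng = em.residue_rng(cid, resnum)
    draws = rng.choice(20, size=em.n_decoys, p=weights)
    return cand[draws]


def srlf_index(e_native: float, decoy_energies: Sequence[float]) -> float:
    """Z-score of the native energy against the decoy energies.

    Positive when the native identity is more stabilizing (lower energy)
    than the decoy mean; population standard deviation; zero spread maps
    to srlf 0 (degenerate).
    """
    decoys = np.asarray(decoy_energies, dtype=float)
    if decoys.size == 0:
        raise ValueError("at least one decoy energy is required")
    sd = float(decoys.std())
    if sd == 0.0:
        return 0.0
    return float((decoys.mean() - e_native) / sd)


def srlf_exhaustive(
    s: StructureModel, cm: ContactMap, em: EnergyModel, i: int
) -> float:
    """Deterministic SRLF: enumerate all 20 identities with their policy weights."""
    z, *_ = _exhaustive_stats(s, cm, em, i)
    return z


def _exhaustive_stats(s, cm, em, i):
    aa_codes = _aa_codes(s)
    adj = cm.neighbor_lists()
    cand = _candidate_energies(aa_codes, adj[i], em)
    w = _decoy_weights(s, em)
    e_native = float(cand[aa_codes[i]])
    mean = float(w @ cand)
    var = float(w @ (cand - mean) ** 2)
    sd = np.sqrt(var)
    if sd == 0.0:
        return 0.0, e_native, mean, 0.0, True
    return float((mean - e_native) / sd), e_native, mean, float(sd), False


def frustration_profile(
    s: StructureModel,
    em: EnergyModel,
    exact: bool = False,
    context: str = "bound",
    cm: ContactMap | None = None,
) -> FrustrationProfile:
    """SRLF index and MF/N/HF state for every residue of a cleaned model.

    ``exact=True`` replaces Monte-Carlo decoy sampling with the closed-form
    enumeration over the 20 candidate identities (same decoy-policy weights).
    """
    if cm is None:
        cm = contact_map(s, em.contact_cutoff_A, em.min_seq_sep)
    aa_codes = _aa_codes(s)
    adj = cm.neighbor_lists()
    weights = _decoy_weights(s, em)
    rows = []
    for i, (cid, _, res) in enumerate(s.iter_residues()):
        cand = _candidate_energies(aa_codes, adj[i], em)
        e_native = float(cand[aa_codes[i]])
        if exact:
            mean = float(weights @ cand)
            sd = float(np.sqrt(weights @ (cand - mean) ** 2))
        else:
            rng = em.residue_rng(cid, res.number)
            decoys = cand[rng.choice(20, size=em.n_decoys, p=weights)]
            mean = float(decoys.mean())
            sd = float(decoys.std())
        degenerate = sd == 0.0
        z = 0.0 if degenerate else (mean - e_native) / sd
        rows.append(
            (cid, res.number, res.aa, e_native, mean, sd, z,
             classify_srlf(z, degenerate), degenerate, context)
        )
    table = pd.DataFrame(rows, columns=PROFILE_COLUMNS)
    return FrustrationProfile(table=table, context=context)


def unbound_profile(
    complex_model: StructureModel,
    receptor_chains: Iterable[str],
    em: EnergyModel,
    exact: bool = False,
) -> FrustrationProfile:
    """Rescore the receptor after removing the target chains.

    Any bound-vs-unbound SRLF difference is then attributable to contacts
    (and, under the composition policy, sequence composition) contributed
    by the removed target.
    """
    receptor = extract_chains(complex_model, receptor_chains)
    return frustration_profile(receptor, em, exact=exact, context="unbound")


def delta_frustration(
    bound: FrustrationProfile, unbound: FrustrationProfile
) -> pd.DataFrame:
    """Per-residue bound-minus-unbound SRLF change with transition labels.

    The bound profile may contain target-chain rows; the table is restricted
    to the unbound (receptor) residue set, which must be fully present.
    """
    key = ["chain", "resnum"]
    merged = unbound.table[key + ["aa", "srlf", "state"]].merge(
        bound.table[key + ["srlf", "state"]],
        on=key,
        how="left",
        suffixes=("_unbound", "_bound"),
    )
    if merged.srlf_bound.isna().any():
        missing = merged[merged.srlf_bound.isna()][key].values.tolist()
        raise ValueError(f"receptor residues missing from bound profile: {missing}")
    merged["delta_srlf"] = merged.srlf_bound - merged.srlf_unbound
    merged["transition"] = merged.state_unbound + "->" + merged.state_bound
    return merged[
        ["chain", "resnum", "aa", "srlf_bound", "srlf_unbound", "delta_srlf",
         "state_bound", "state_unbound", "transition"]
    ]


@dataclass
class VariantResult:
    chain: str
    position: int
    wt_aa: str
    new_aa: str
    srlf_wt: float
    srlf_mut: float
    state_wt: str
    state_mut: str
    fold_change: float | None  # |srlf_mut| / |srlf_wt|; None when srlf_wt == 0


def variant_scan(
    s: StructureModel,
    em: EnergyModel,
    position: int,
    new_aa: str,
    chain: str | None = None,
    exact: bool = False,
) -> VariantResult:
    """Fixed-backbone rescoring of a point variant.

    Only the residue's identity is replaced (coordinates untouched); SRLF is
    recomputed with the same per-residue seed policy, so an identity
    mutation reproduces the wild-type score exactly.
    """
    if new_aa not in STANDARD_AA:
        raise ValueError(f"nonstandard amino acid {new_aa!r}")
    if chain is None:
        if len(s.chains) != 1:
            raise ValueError("chain must be given for multi-chain structures")
        chain = s.chains[0].chain_id
    target = None
    for cid, _, res in s.iter_residues():
        if cid == chain and res.number == position:
            target = res
            break
    if target is None:
        raise KeyError(f"no residue {chain}/{position}")

    mutant = s.copy()
    for cid, _, res in mutant.iter_residues():
        if cid == chain and res.number == position:
            res.aa = new_aa

    wt_prof = frustration_profile(s, em, exact=exact)
    mut_prof = frustration_profile(mutant, em, exact=exact)
    z_wt = wt_prof.srlf(chain, position)
    z_mut = mut_prof.srlf(chain, position)
    fold = abs(z_mut) / abs(z_wt) if z_wt != 0.0 else None
    return VariantResult(
        chain=chain,
        position=position,
        wt_aa=target.aa,
        new_aa=new_aa,
        srlf_wt=z_wt,
        srlf_mut=z_mut,
        state_wt=classify_srlf(z_wt),
        state_mut=classify_srlf(z_mut),
        fold_change=fold,
    )
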