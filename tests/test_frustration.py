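"""SRLF decoy machinery: energies, Z-scores, profiles, deltas, variants."""

import numpy as np
import pandas as pd
import pytest

import frustevo as fv
from frustevo.energy import AA_INDEX
from frustevo.frustration import classify_srlf

from conftest import manual_model


def _toy_pair(aa_a="A", aa_b="A"):
    """Two single-residue chains 5 A apart: exactly one (inter-chain) contact."""
    return manual_model({"A": [(1, aa_a, (0, 0, 0))], "B": [(1, aa_b, (5, 0, 0))]})


# --- native energies ---------------------------------------------------------

def test_native_energy_zero_without_contacts(em):
    m = manual_model({"A": [(1, "A", (0, 0, 0)), (2, "L", (50, 0, 0)), (3, "V", (99, 0, 0))]})
    cm = fv.contact_map(m)
    assert fv.native_residue_energy(m, cm, em, 0) == 0.0


def test_native_energy_single_contact_identity_matrix(identity_em):
    m = _toy_pair("A", "A")
    cm = fv.contact_map(m)
    assert fv.native_residue_energy(m, cm, identity_em, 0) == -1.0
    m2 = _toy_pair("A", "L")
    assert fv.native_residue_energy(m2, fv.contact_map(m2), identity_em, 0) == 0.0


def test_native_energy_matches_double_loop_oracle(em):
    s = fv.make_structure(40, seed=13)
    cm = fv.contact_map(s)
    residues = [r for _, _, r in s.iter_residues()]
    for i in range(40):
        expected = 0.0
        for a, b in cm.pairs:
            if i in (a, b):
                j = b if a == i else a
                expected += em.pair_energy(residues[i].aa, residues[j].aa)
        assert fv.native_residue_energy(s, cm, em, i) == pytest.approx(expected)


# --- decoys ------------------------------------------------------------------

def test_decoys_with_identical_rows_equal_native():
    pot = np.ones((20, 20)) * -0.3
    em = fv.EnergyModel(pair_potential=pot, seed=4)
    s = fv.make_structure(20, seed=4)
    cm = fv.contact_map(s)
    e0 = fv.native_residue_energy(s, cm, em, 8)
    decoys = fv.mutational_decoy_energies(s, cm, em, 8)
    assert np.all(decoys == e0)


def test_homopolymer_composition_decoys_are_degenerate(identity_em):
    s = fv.make_structure(20, seed=4, sequence="A" * 20)
    cm = fv.contact_map(s)
    e0 = fv.native_residue_energy(s, cm, identity_em, 10)
    decoys = fv.mutational_decoy_energies(s, cm, identity_em, 10)
    assert np.all(decoys == e0)
    assert fv.srlf_exhaustive(s, cm, identity_em, 10) == 0.0


# --- Z-scores ----------------------------------------------------------------

def test_srlf_index_hand_arithmetic():
    assert fv.srlf_index(-1.0, [0.0, 2.0]) == pytest.approx(2.0)
    assert fv.srlf_index(1.0, [0.0, 2.0]) == pytest.approx(0.0)
    assert fv.srlf_index(5.0, [5.0, 5.0]) == 0.0  # zero spread -> degenerate 0
    with pytest.raises(ValueError):
        fv.srlf_index(0.0, [])


def test_srlf_exhaustive_single_contact_closed_form():
    """Uniform-over-20 decoys, identity matrix, same-type partner:
    mean -0.05, population sd sqrt(0.05*0.95), z ~ 4.359."""
    pot = np.where(np.eye(20, dtype=bool), -1.0, 0.0)
    em = fv.EnergyModel(pair_potential=pot, decoy_policy="uniform20", seed=1)
    m = _toy_pair("A", "A")
    cm = fv.contact_map(m)
    expected = (-0.05 - (-1.0)) / np.sqrt(0.05 * 0.95)
    assert fv.srlf_exhaustive(m, cm, em, 0) == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(4.3589, abs=1e-4)


@pytest.mark.parametrize("policy", ["composition", "uniform20"])
def test_sampled_srlf_converges_to_exhaustive(policy):
    em = fv.EnergyModel(seed=6, n_decoys=5000, decoy_policy=policy)
    s = fv.make_structure(30, seed=6)
    cm = fv.contact_map(s)
    for i in range(30):
        z_ex = fv.srlf_exhaustive(s, cm, em, i)
        decoys = fv.mutational_decoy_energies(s, cm, em, i)
        z_mc = fv.srlf_index(fv.native_residue_energy(s, cm, em, i), decoys)
        assert abs(z_mc - z_ex) < 0.1


def test_sampled_mean_within_three_standard_errors(em):
    s = fv.make_structure(30, seed=8)
    cm = fv.contact_map(s)
    em_big = fv.EnergyModel(seed=8, n_decoys=100_000)
    for i in (0, 7, 19):
        decoys = fv.mutational_decoy_energies(s, cm, em_big, i)
        from frustevo.frustration import _exhaustive_stats
        _, _, mean, sd, degenerate = _exhaustive_stats(s, cm, em_big, i)
        if degenerate:
            continue
        se = sd / np.sqrt(len(decoys))
        assert abs(decoys.mean() - mean) < 3 * se + 1e-12


# --- profiles and classification --------------------------------------------

def test_classification_cutoffs_strict():
    assert classify_srlf(1.5) == "MF"
    assert classify_srlf(-1.2) == "HF"
    assert classify_srlf(0.3) == "N"
    assert classify_srlf(1.0) == "N"
    assert classify_srlf(-1.0) == "N"
    assert classify_srlf(0.0, degenerate=True) == "N"


def test_profile_invariants(em, small_structure):
    prof = fv.frustration_profile(small_structure, em)
    t = prof.table
    assert len(t) == small_structure.n_residues
    # classification partition: states recompute exactly from srlf
    for row in t.itertuples():
        assert row.state == classify_srlf(row.srlf, row.degenerate)
    assert t.loc[t.degenerate, "srlf"].eq(0.0).all()


def test_seed_determinism(em, small_structure):
    a = fv.frustration_profile(small_structure, em)
    b = fv.frustration_profile(small_structure, em)
    pd.testing.assert_frame_equal(a.table, b.table)
    # different seed -> different draws somewhere
    c = fv.frustration_profile(small_structure, em.with_seed(999))
    assert not np.allclose(a.table.srlf, c.table.srlf)


def test_rigid_motion_invariance(em, small_structure):
    moved = small_structure.copy()
    theta = 0.7
    rot = np.array([
        [np.cos(theta), -np.sin(theta), 0.0],
        [np.sin(theta), np.cos(theta), 0.0],
        [0.0, 0.0, 1.0],
    ])
    shift = np.array([11.0, -3.0, 42.0])
    for _, _, r in moved.iter_residues():
        r.atoms = {k: rot @ v + shift for k, v in r.atoms.items()}
    a = fv.frustration_profile(small_structure, em)
    b = fv.frustration_profile(moved, em)
    assert np.allclose(a.table.srlf, b.table.srlf)


def test_chain_rename_invariance_exact_mode(em):
    s = fv.make_structure(25, seed=2, chain_id="A")
    renamed = s.copy()
    renamed.chains[0].chain_id = "Q"
    a = fv.frustration_profile(s, em, exact=True)
    b = fv.frustration_profile(renamed, em, exact=True)
    assert np.allclose(a.table.srlf, b.table.srlf)


def test_monotonicity_more_favorable_native_never_lowers_srlf():
    """Strictly lowering all of residue i's native contact energies can only
    raise (never lower) its exhaustive SRLF."""
    rng = np.random.default_rng(0)
    checked = 0
    for _ in range(60):
        s = fv.make_structure(25, seed=int(rng.integers(1e6)))
        m = rng.normal(size=(20, 20))
        em = fv.EnergyModel(pair_potential=np.round((m + m.T) / 2, 3), seed=1)
        cm = fv.contact_map(s)
        i = int(rng.integers(25))
        nb = cm.neighbor_lists()[i]
        if not nb:
            continue
        checked += 1
        residues = [r for _, _, r in s.iter_residues()]
        z0 = fv.srlf_exhaustive(s, cm, em, i)
        pot2 = em.pair_potential.copy()
        ai = AA_INDEX[residues[i].aa]
        for j in nb:
            aj = AA_INDEX[residues[j].aa]
            pot2[ai, aj] -= 0.7
            if ai != aj:
                pot2[aj, ai] -= 0.7
        z1 = fv.srlf_exhaustive(s, cm, fv.EnergyModel(pair_potential=pot2, seed=1), i)
        assert z1 >= z0 - 1e-9
    assert checked > 30


# --- bound / unbound ---------------------------------------------------------

@pytest.mark.parametrize("policy", ["composition", "uniform20"])
def test_interface_free_target_leaves_profile_bitwise_identical(policy):
    receptor = fv.make_structure(30, seed=21)
    cx = fv.make_null_complex(receptor)
    em = fv.EnergyModel(seed=21, decoy_policy=policy)
    bound = fv.frustration_profile(cx, em)
    unbound = fv.unbound_profile(cx, {"A"}, em)
    b = bound.table[bound.table.chain == "A"].reset_index(drop=True)
    u = unbound.table.reset_index(drop=True)
    for col in ("E_native", "decoy_mean", "decoy_sd", "srlf"):
        assert (b[col].to_numpy() == u[col].to_numpy()).all()
    assert (b.state == u.state).all()


def test_single_interface_contact_changes_only_that_native_energy():
    receptor = fv.make_structure(30, seed=22)
    em = fv.EnergyModel(seed=22, decoy_policy="uniform20")
    cx = fv.make_complex(receptor, [14], seed=22, em=em)
    bound = fv.frustration_profile(cx, em)
    unbound = fv.unbound_profile(cx, {"A"}, em)
    b = bound.table[bound.table.chain == "A"].set_index("resnum")
    u = unbound.table.set_index("resnum")
    diff = (b.E_native - u.E_native).abs()
    changed = set(diff[diff > 1e-12].index)
    assert changed <= {14}


def test_unbound_with_all_chains_equals_bound(em):
    receptor = fv.make_structure(20, seed=23)
    cx = fv.make_complex(receptor, [8], seed=23)
    a = fv.frustration_profile(cx, em)
    b = fv.unbound_profile(cx, set(cx.chain_ids), em)
    assert np.allclose(a.table.srlf, b.table.srlf)


def test_delta_frustration_labels(em):
    receptor = fv.make_structure(20, seed=24)
    cx = fv.make_null_complex(receptor)
    bound = fv.frustration_profile(cx, em)
    unbound = fv.unbound_profile(cx, {"A"}, em)
    delta = fv.delta_frustration(bound, unbound)
    assert np.allclose(delta.delta_srlf, 0.0)
    assert (delta.transition == delta.state_unbound + "->" + delta.state_bound).all()
    # residue-set mismatch errors
    short = fv.frustration_profile(fv.make_structure(10, seed=24), em)
    with pytest.raises(ValueError):
        fv.delta_frustration(short, unbound)


def test_favorable_interchain_contact_raises_srlf():
    """Constructed sign check: under an identity-matrix potential a
    same-type target partner stabilizes only the native identity, so the
    interface residue's SRLF must rise upon binding."""
    pot = np.where(np.eye(20, dtype=bool), -1.0, 0.0)
    em = fv.EnergyModel(pair_potential=pot, seed=25, decoy_policy="uniform20")
    receptor = fv.make_structure(30, seed=25)
    native = receptor.chain("A").residues[10].aa  # position 11
    cx = fv.make_complex(receptor, [11], seed=25, target_sequence=native * 3, em=em)
    bound = fv.frustration_profile(cx, em, exact=True)
    unbound = fv.unbound_profile(cx, {"A"}, em, exact=True)
    delta = fv.delta_frustration(bound, unbound)
    row = delta[delta.resnum == 11].iloc[0]
    assert row.delta_srlf > 0


# --- variants ----------------------------------------------------------------

def test_identity_mutation_is_a_fixed_point(em, small_structure):
    native = small_structure.chains[0].residues[5]
    res = fv.variant_scan(small_structure, em, native.number, native.aa)
    assert res.srlf_mut == res.srlf_wt
    assert res.fold_change in (1.0, None)


def test_variant_nonstandard_aa_rejected(em, small_structure):
    with pytest.raises(ValueError):
        fv.variant_scan(small_structure, em, 5, "X")


def test_variant_with_degenerate_matrix_unchanged(small_structure):
    pot = np.full((20, 20), -0.5)
    em = fv.EnergyModel(pair_potential=pot, seed=3)
    res = fv.variant_scan(small_structure, em, 7, "W")
    assert res.srlf_mut == pytest.approx(res.srlf_wt)


def test_designed_hf_residue_flips_to_mf_on_optimal_mutation():
    em = fv.EnergyModel(seed=31)
    s = fv.make_structure(40, seed=31)
    seq, converged = fv.design_sequence(s, {15: "HF"}, em, seed=31)
    assert converged
    cm = fv.contact_map(s)
    # the energy-optimal identity at position 15 given its neighbors
    codes = [AA_INDEX[r.aa] for r in s.chains[0].residues]
    nb = cm.neighbor_lists()[14]
    cand = em.pair_potential[:, np.array(codes)[nb]].sum(axis=1)
    best = fv.structure.STANDARD_AA[int(np.argmin(cand))]
    res = fv.variant_scan(s, em, 15, best, exact=True)
    assert res.state_wt == "HF"
    assert res.state_mut == "MF"
    assert res.fold_change is not None


def test_pair_potential_file_round_trip(tmp_path):
    mat = fv.default_pair_potential()
    path = tmp_path / "potential.mat"
    fv.write_pair_potential(mat, path)
    back = fv.read_pair_potential(path)
    assert np.allclose(back, mat)
    # asymmetric files are rejected
    bad = mat.copy()
    bad[0, 1] += 1.0
    fv.write_pair_potential(bad, path)
    with pytest.raises(ValueError):
        fv.read_pair_potential(path)
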