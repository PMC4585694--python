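"""rvET conservation ranks: filtering, trees, level partitions, scores."""

import math

import numpy as np
import pytest

import frustevo as fv
from frustevo.conservation import (
    ConservationError,
    column_scores,
    distribution_cutoff,
    p_distance,
    validate_tree,
)


# --- homolog-set filtering ---------------------------------------------------

class TestFilterSequences:
    REF = fv.load_cam_sequence()  # 148 residues

    def test_short_sequences_dropped(self):
        raw = [("ref", self.REF), ("short", "A" * 110), ("long", "A" * 148)]
        kept = fv.filter_sequences(raw, self.REF, min_len_frac=0.8)
        ids = [r[0] for r in kept]
        assert "short" not in ids  # 110 < 0.8 * 148 = 118.4
        assert "long" in ids

    def test_identical_to_reference_dropped_reference_kept_once(self):
        raw = [("ref", self.REF), ("dup", self.REF), ("var", "W" + self.REF[1:])]
        kept = fv.filter_sequences(raw, self.REF)
        seqs = [s for _, s in kept]
        assert seqs.count(self.REF) == 1
        assert ("var", "W" + self.REF[1:]) in kept

    def test_single_substitution_kept(self):
        cand = self.REF[:-1] + ("A" if self.REF[-1] != "A" else "G")
        kept = fv.filter_sequences([("x", cand)], self.REF)
        assert kept == [("x", cand)]

    def test_empty_survivor_set_is_error(self):
        with pytest.raises(ConservationError):
            fv.filter_sequences([("tiny", "AAA")], self.REF)


# --- trees -------------------------------------------------------------------

def test_two_sequence_tree_is_a_cherry_at_half_distance():
    msa = fv.MSA(["a", "b"], ["AAAA", "AATT"], "a")
    tree = fv.build_tree(msa)
    assert sorted(tree.leaf_names) == ["a", "b"]
    assert tree.root_height == pytest.approx(p_distance("AAAA", "AATT") / 2)


def test_block_structured_distances_give_sister_cherries():
    # two tight pairs: (a1, a2) and (b1, b2)
    seqs = {
        "a1": "AAAAAAAAAA",
        "a2": "AAAAAAAAAC",
        "b1": "WWWWWWWWWW",
        "b2": "WWWWWWWWWC",
    }
    msa = fv.MSA(list(seqs), list(seqs.values()), "a1")
    tree = fv.build_tree(msa)
    parts = fv.level_partitions(tree)
    level2 = sorted(sorted(g) for g in parts[1])
    assert level2 == [["a1", "a2"], ["b1", "b2"]]


def test_external_newick_passthrough_and_validation():
    tree = fv.PhyloTree.from_newick("((a:1,b:1):1,(c:1,d:1):1):0;")
    msa = fv.MSA(["a", "b", "c", "d"], ["AA", "AC", "CA", "CC"], "a")
    validate_tree(tree, msa)  # no error
    bad = fv.MSA(["a", "b", "c", "x"], ["AA", "AC", "CA", "CC"], "a")
    with pytest.raises(ConservationError):
        validate_tree(tree, bad)


def test_build_tree_needs_two_records():
    with pytest.raises(ConservationError):
        fv.build_tree(fv.MSA(["a"], ["AA"], "a"))


# --- level partitions --------------------------------------------------------

def test_level_partitions_two_leaves():
    tree = fv.PhyloTree.from_newick("(a:1,b:1):0;")
    parts = fv.level_partitions(tree)
    assert len(parts) == 1
    assert sorted(parts[0][0]) == ["a", "b"]


def test_level_partitions_balanced_four_leaves():
    tree = fv.PhyloTree.from_newick("((a:1,b:1):2,(c:1,d:1):2):0;")
    parts = fv.level_partitions(tree)
    assert [len(g) for g in (parts[0], parts[1], parts[2])] == [1, 2, 3]
    level2 = sorted(sorted(g) for g in parts[1])
    assert level2 == [["a", "b"], ["c", "d"]]


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_level_partitions_properties_random_trees(seed):
    """Partitions are nested refinements, have n groups at level n, split in
    descending-height order, and every group is a clade."""
    rng = np.random.default_rng(seed)
    from frustevo.synthetic import random_tree

    node = random_tree(8, rng)
    tree = fv.PhyloTree.from_newick(node.newick() + ";")
    parts = fv.level_partitions(tree)
    assert len(parts) == 7
    clades = {frozenset(tree.leaves_under(n)) for n in tree._walk_preorder(tree.clade)}
    prev = None
    for n, groups in enumerate(parts, start=1):
        assert len(groups) == n
        leaves = sorted(x for g in groups for x in g)
        assert leaves == sorted(tree.leaf_names)
        for g in groups:
            assert frozenset(g) in clades
        if prev is not None:
            # nested: every new group fits inside exactly one previous group
            for g in groups:
                assert sum(1 for p in prev if set(g) <= set(p)) == 1
        prev = groups
    # the split order follows weakly decreasing node heights
    internals = tree.internal_nodes_by_height()
    heights = [tree.height(x) for x in internals]
    assert heights == sorted(heights, reverse=True)


# --- rvET scores -------------------------------------------------------------

def test_invariant_column_scores_exactly_one():
    msa = fv.MSA(["a", "b", "c", "d"], ["AW", "AW", "AW", "AW"], "a")
    tree = fv.PhyloTree.from_newick("((a:1,b:1):1,(c:1,d:1):1):0;")
    prof = fv.rvet_scores(msa, tree)
    assert (prof.table.rvet == 1.0).all()
    assert (prof.table.state == "C").all()


def test_two_sequence_mismatch_column_is_one_plus_ln2():
    msa = fv.MSA(["a", "b"], ["AY", "AW"], "a")
    tree = fv.build_tree(msa)
    prof = fv.rvet_scores(msa, tree)
    assert prof.rvet(1) == pytest.approx(1.0, abs=1e-12)
    assert prof.rvet(2) == pytest.approx(1.0 + math.log(2), abs=1e-12)


def test_rvet_matches_hand_computed_oracle():
    """Independent recomputation from explicit partitions and frequency
    tables on a fixed 4-leaf tree."""
    seqs = {"a": "AAWC", "b": "AAYC", "c": "AWYD", "d": "AWWE"}
    msa = fv.MSA(list(seqs), list(seqs.values()), "a")
    tree = fv.PhyloTree.from_newick("((a:1,b:1):3,(c:1,d:1):3):0;")
    # heights: root 4, cherry-ab 1, cherry-cd 1 (preorder: ab before cd)
    partitions = [
        [["a", "b", "c", "d"]],
        [["a", "b"], ["c", "d"]],
        [["a"], ["b"], ["c", "d"]],  # height tie broken by preorder: ab splits first
    ]

    def entropy(column_letters):
        freqs = {}
        for ch in column_letters:
            freqs[ch] = freqs.get(ch, 0) + 1
        total = sum(freqs.values())
        return -sum(c / total * math.log(c / total) for c in freqs.values())

    expected = []
    for col in range(4):
        rho = 1.0
        for n, groups in enumerate(partitions, start=1):
            rho += sum(entropy([seqs[g][col] for g in grp]) for grp in groups) / n
        expected.append(rho)
    got = column_scores(msa, tree)
    assert np.allclose(got, expected, atol=1e-12)


def test_rvet_invariant_to_record_order_and_relabeling():
    rng = np.random.default_rng(5)
    from frustevo.synthetic import random_tree

    sim = fv.simulate_msa(8, ["fast"] * 6 + ["invariant"] * 2, seed=5)
    base = column_scores(sim.msa, sim.tree)
    # reorder records
    order = rng.permutation(sim.msa.n_records)
    msa2 = fv.MSA(
        [sim.msa.ids[i] for i in order],
        [sim.msa.seqs[i] for i in order],
        sim.msa.reference_id,
    )
    assert np.allclose(column_scores(msa2, sim.tree), base)
    # consistent relabeling of MSA ids and tree leaves
    rename = {rid: f"x_{rid}" for rid in sim.msa.ids}
    msa3 = fv.MSA([rename[r] for r in sim.msa.ids], sim.msa.seqs, rename[sim.msa.reference_id])
    newick3 = sim.newick
    for old, new in sorted(rename.items(), key=lambda kv: -len(kv[0])):
        newick3 = newick3.replace(old + ":", new + ":")
    tree3 = fv.PhyloTree.from_newick(newick3)
    assert np.allclose(column_scores(msa3, tree3), base)


def test_reference_gap_columns_dropped_and_gaps_excluded_from_frequencies():
    msa = fv.MSA(
        ["r", "s", "t"],
        ["A-W", "AC-", "ACW"],
        "r",
    )
    tree = fv.PhyloTree.from_newick("((r:1,s:1):1,t:1):0;")
    prof = fv.rvet_scores(msa, tree)
    # reference has a gap in column 2 -> only positions 1 and 2 (cols 0, 2)
    assert list(prof.table.position) == [1, 2]
    assert list(prof.table.column_index) == [0, 2]
    # column 2 has letters W, -, W -> gap excluded, invariant among non-gaps
    assert prof.rvet(2) == pytest.approx(1.0)


def test_conservation_state_strict_cutoff():
    assert fv.conservation_state(2.3) == "C"
    assert fv.conservation_state(7.0) == "NC"
    assert fv.conservation_state(5.0) == "NC"
    assert fv.conservation_state(4.999) == "C"


def test_maximal_diversity_column_has_maximal_score():
    # one invariant column, one fully diverse column
    ids = [f"s{i}" for i in range(4)]
    msa = fv.MSA(ids, ["AW", "AY", "AC", "AD"], "s0")
    tree = fv.build_tree(msa)
    scores = column_scores(msa, tree)
    assert scores[1] == max(scores)
    assert scores[0] == pytest.approx(1.0)


def test_distribution_cutoff_splits_two_clusters():
    scores = np.array([1.0] * 10 + [9.0, 10.0, 11.0, 12.0])
    cut = distribution_cutoff(scores)
    assert 1.0 < cut < 9.0


def test_msa_file_round_trip(tmp_path):
    sim = fv.simulate_msa(6, ["fast"] * 5, seed=3)
    path = tmp_path / "aln.fasta"
    sim.msa.to_fasta(path)
    back = fv.MSA.from_file(path, reference_id="ref")
    assert back.ids == sim.msa.ids
    assert back.seqs == sim.msa.seqs
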