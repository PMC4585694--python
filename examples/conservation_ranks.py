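"""Rank alignment columns by evolutionary-trace conservation.

Simulates 24 homologs down a known tree with 30% invariant and 70% fast
columns, computes per-column rvET scores, and shows that invariant columns
score exactly 1 (perfectly conserved) while fast columns score higher.
"""

import numpy as np

import frustevo as fv

rng = np.random.default_rng(7)
classes = ["invariant" if rng.random() < 0.3 else "fast" for _ in range(40)]
sim = fv.simulate_msa(24, classes, seed=7)

profile = fv.rvet_scores(sim.msa, sim.tree, cutoff=5.0)
table = profile.table.assign(true_class=classes)
print(table.head(12).to_string(index=False))

inv = table[table.true_class == "invariant"].rvet
fast = table[table.true_class == "fast"].rvet
print(f"\ninvariant columns: rvET all exactly 1.0 -> {set(inv)}")
print(f"fast columns: rvET {fast.min():.2f} .. {fast.max():.2f}")
print(
    "\nLower rvET = fixed earlier in the tree = more conserved. A column is\n"
    "called conserved (C) when rvET < 5; the invariant/fast separation here\n"
    "is what lets the six-class join recover designed conservation labels."
)
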