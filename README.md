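# frustevo

Per-residue **energetic frustration** joined with **evolutionary
conservation** for protein complexes.

Proteins that bind many different partners — calmodulin (CaM) is the
canonical case, with its 148 residues, four EF-hands and a Met-rich
target-binding surface — balance two pressures: residues that fold and
stabilize the scaffold, and residues kept energetically "uncomfortable"
because that discomfort is what binding and regulation exploit.  `frustevo`
quantifies both axes per residue and crosses them:

* **Frustration (SRLF index).**  A residue's native contact energy
  `E_i = Σ_{j∈contacts(i)} ε(a_i, a_j)` is compared to the energies of *N*
  mutational decoys in which only that residue's amino-acid identity is
  randomized (geometry and neighbors fixed).  The single-residue-level
  frustration index is the Z-score

  `SRLF_i = (⟨E_decoy⟩ − E_i) / σ_decoy`

  with states **MF** (minimally frustrated, SRLF > 1), **HF** (highly
  frustrated, SRLF < −1) and **N** (neutral) — strict inequalities, so ±1
  is neutral.  Decoy identities are drawn from the analyzed model's
  composition (or uniformly over the 20 amino acids), and a closed-form
  enumeration over all 20 identities is available as an exact mode.

* **Conservation (rvET score).**  Given an MSA and a phylogenetic tree,
  cutting the tree below its n−1 highest nodes partitions the leaves into
  n groups; the real-valued evolutionary-trace rank of column *i* is

  `ρ_i = 1 + Σ_{n=1}^{N−1} (1/n) Σ_{g} H_g(i)`

  where `H_g(i)` is the Shannon entropy of the column within group *g*
  (gaps excluded).  Invariant columns score exactly 1; a column is
  conserved (**C**) when ρ < 5, else non-conserved (**NC**).

* **Six-class join.**  Each residue, in each complex, lands in one of
  {MF, HF, N} × {C, NC}.  The package aggregates across complex ensembles
  ("minimally frustrated in 53 out of 58 complexes"-style counts),
  computes bound-vs-unbound delta frustration by removing target chains,
  and rescans point variants on a fixed backbone.

A synthetic-data module generates structures with controllable contact
maps, sequences *designed* to be minimally/highly frustrated at chosen
positions, complexes with exact interfaces, and MSAs evolved down known
trees with known conserved columns — so every stage is testable with
ground truth and no downloads.

## Worked example

```python
import frustevo as fv

structure = fv.make_structure(50, seed=11)      # compact synthetic 50-mer
em = fv.EnergyModel(seed=11)                    # 6.5 A contacts, 2000 decoys
profile = fv.frustration_profile(structure, em)
print(profile.table.head(3).to_string(index=False))
```

prints

```
chain  resnum aa  E_native  decoy_mean  decoy_sd      srlf state  degenerate context
    A       1  P     0.355    0.102540  0.679084 -0.371766     N       False   bound
    A       2  R     1.240    0.179305  0.676087 -1.568873    HF       False   bound
    A       3  Q     1.435    0.175295  1.023673 -1.230573    HF       False   bound
```

Residue 2 (Arg) is highly frustrated: its native energy (1.24) is about
1.6 decoy standard deviations *worse* than the average random identity at
that position.  Random sequences are mostly neutral (33 of 50 here), as
expected.

A designed variant scan (`examples/variant_rescoring.py`) shows the other
direction — replacing a designed-worst identity with the optimal one:

```
wild type R15: SRLF -1.53 (HF)
variant  I15: SRLF +1.61 (MF)
fold change |SRLF_mut| / |SRLF_wt| = 1.05
```

The `examples/` directory has one short script per capability
(frustration profiles, bound/unbound deltas, conservation ranks, the
six-class ensemble benchmark, variant rescoring); each prints its numbers
with a line on what they mean.  A thin CLI mirrors the library:
`frustevo frustration|conserve|classify|variant|simulate --help`.

The 148-residue mature human calmodulin sequence ships as a fixture
(`frustevo.load_cam_sequence()`), with its nine Met (36, 51, 71, 72, 76,
109, 124, 144, 145) and nine Leu (4, 18, 32, 39, 48, 69, 105, 112, 116)
focus positions.

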