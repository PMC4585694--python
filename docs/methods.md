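# Methods

This note records the models, parameter choices and numerical conventions
behind `frustevo`, and what the synthetic benchmarks do and do not show.

## Structure model

PDB files are reduced to chains of standard amino acids.  Hydrogens and
hetero groups (waters, ions, ligands) are removed; selenomethionine (MSE)
is mapped to Met before the 20-code filter; residues with any other
nonstandard code are dropped with a warning.  Multi-model (NMR) entries
keep model 1 by default — the "best representative conformer" flag is not
machine-readable across files, so the first model is the deterministic
choice, with an explicit model-index override.  Alternate locations keep
the highest-occupancy atom, ties broken by altloc label order.  Author
residue numbering is preserved everywhere; internal indices are 0-based.

Each residue is represented by one interaction site: Cβ, falling back to
Cα for glycine or when Cβ is missing — the standard coarse-grained
convention.  Two residues are in contact when their sites lie within
**6.5 Å**; within a chain, pairs separated by fewer than **2** sequence
positions (i, i±1) are excluded, while inter-chain pairs are never
filtered by separation.  Both values are configurable; the defaults are
common contact-potential practice.

## Energy model

The default pair potential is generated from a stated formula rather than
a fitted table:

    ε(a, b) = −0.1·(h_a + h_b) + 0.05·|h_a − h_b| + 1.0·q_a·q_b

with `h` the Kyte–Doolittle hydropathy and `q` the net side-chain charge
(D, E = −1; K, R = +1).  The additive hydropathy term is the dominant
component of statistical contact matrices; the mismatch term penalizes
hydrophobic–polar contacts (the segregation behind burial); the charge
product penalizes like charges and rewards salt bridges.  The mismatch
term is structurally necessary, not cosmetic: under any potential that is
affine in the candidate identity's features, all 20 candidate energies at
a position shift and scale together when an uncharged neighbor is added,
so the frustration Z-score would be blind to most of a residue's
environment.  The |Δh| kinks break that degeneracy.

Units are arbitrary (the Z-score is scale-free).  Any 20×20 symmetric
matrix can be substituted via a whitespace-delimited file with one-letter
header row and column, so knowledge-based matrices can be dropped in.
Because this potential is not the all-atom transferable force field used
by frustration web servers, absolute SRLF values on real PDB entries are
comparable in rank and class, not in raw value.

## Frustration (SRLF)

For residue *i*, the native energy is the sum of pair energies over its
contacts, including inter-chain contacts in complexes.  Mutational decoys
replace **only** residue *i*'s identity; neighbors and geometry are fixed.
Decoy identities are drawn either from the composition of the analyzed
model (the complex for bound runs, the receptor alone for unbound runs —
the default, reading "randomly selecting identities in the native state"
literally) or uniformly over the 20 amino acids (`uniform20`).

SRLF is the Z-score `(⟨E_decoy⟩ − E_i)/σ`, with population σ.  σ = 0
(no contacts, or a single-identity composition) yields SRLF 0, state
neutral, and a degenerate flag rather than an error, so ensemble runs
never crash.  Classification uses strict inequalities: MF iff SRLF > 1,
HF iff SRLF < −1, neutral otherwise (±1 exactly is neutral).

**Decoy count** defaults to N = 2000.  The Monte-Carlo standard error of
the Z estimate is ≈ √((1 + z²/2)/N) ≈ 0.03 at N = 2000 — an order of
magnitude below the unit-width classification bands.  An exact mode
enumerates the ≤ 20 candidate identities with their policy weights in
closed form and is used as the test oracle; sampled and exact scores agree
within 0.1 at N = 5000 in the acceptance checks.

**Reproducibility.**  Each residue has its own RNG stream derived from
(global seed, chain id, residue number), so adding or removing residues
never shifts another residue's draws, bound and unbound runs share
streams, and identical inputs + seed give byte-identical outputs.  The
stream keying means sampled scores are invariant under rigid motions but
only distributionally invariant under chain renaming; the exact mode is
invariant under both.

**Bound vs unbound.**  `unbound_profile` removes the target chains and
rescores; `delta_frustration` reports per-residue ΔSRLF = bound − unbound
with transition labels (e.g. `N->MF`).  A target with no receptor contacts
leaves profiles bit-identical when the decoy composition is unchanged —
exactly true under `uniform20`, and under the composition policy whenever
the target's composition is proportional to the receptor's (the packaged
null-complex generator uses a displaced copy of the receptor for this
reason).  A contact-free target whose composition differs can still shift
SRLF slightly through the decoy weights; that is a property of the
composition policy, not a bug.

**Variant rescoring** replaces one residue's identity on a fixed backbone
and recomputes SRLF with the same seed policy, reporting the fold change
|SRLF_mut|/|SRLF_wt| (undefined when SRLF_wt = 0).  This deliberately
substitutes relabeling for homology modeling: no side-chain rebuild, no
backbone relaxation.

## Conservation (rvET)

Sequence filtering drops exact duplicates of the reference and sequences
shorter than 0.8× the reference's ungapped length (both configurable),
keeping the reference once.

Trees are built by neighbor joining on p-distances (mismatch fraction over
mutually ungapped columns), with negative NJ branch lengths clamped to
zero and midpoint rooting; external Newick trees are accepted instead and
validated against the MSA.  Node height is the maximum branch-length path
to a descendant leaf, so heights decrease from root to leaves.  Level *n*
cuts the tree at the n−1 highest internal nodes (ties broken by preorder
index), giving nested partitions with *n* groups on binary trees.

The rank of column *i* is `ρ_i = 1 + Σ_{n=1}^{N−1} (1/n) Σ_g H_g(i)` with
natural-log Shannon entropies over amino-acid frequencies within each
group; gaps are excluded from the frequencies and an all-gap group
contributes 0.  Invariant columns score exactly 1.  Columns where the
reference is gapped are dropped; profiles are indexed by 1-based reference
positions.  This weighting is one concrete instantiation of the
real-valued evolutionary-trace family; published variants differ in
weighting details, so ranks are comparable within this package rather than
against a specific server.  Conservation states use a strict cutoff:
C iff ρ < 5.  The 5 default suits homolog sets of a few hundred sequences;
for simulated alignments the cutoff is instead chosen from the score
distribution by a two-cluster (1-D two-means) split, mirroring
distribution-based cutoff selection on real data.

## Six-class join

Chains are mapped onto the reference by global alignment (match +1,
mismatch 0, gap −1 per symbol) with an infinitesimal gap-opening surcharge
and a traceback preferring reference-gap runs over diagonal moves.  Both
tie-breaks matter on EF-hand-family sequences: internal repeats make
scattered alignments exactly co-optimal with the contiguous one, and the
chosen preferences guarantee truncated chains map as single offset blocks.
Mappings below 60% identity are rejected (warning + empty mapping);
unmapped residues are tallied separately, never silently dropped.

Conservation is computed once per reference and shared by all complexes.
Per complex, each mapped residue gets the class (frustration state,
conservation state); the ensemble table reports per-position counts
(n_MF/n_N/n_HF out of n_total), a consensus class (modal frustration
state, ties → neutral — the raw counts are always reported alongside,
since a consensus rule is a summarization choice), per-complex class
fractions, and 2-D map data (rvET vs SRLF points plus region counts; both
per-complex points and per-position summaries are available since either
view of the scatter is legitimate).

## Synthetic data

`make_structure` places Cα on a solenoid — a helix (2.3 Å tube radius,
100°/residue twist) wound along a circular arc (ring radius
max(6, 0.24·length) Å, 4.2 Å of arc per residue) — with Cβ 1.5 Å further
from the tube axis.  The geometry was chosen so that ≥ 80% of residues
have ≥ 2 contacts at default cutoffs for all lengths ≥ 5, with no
non-neighbor pair closer than ~3 Å.  It is a fixed deterministic curve,
not a physical simulation: the frustration machinery needs only a contact
graph.  Coordinates are rounded to 0.001 Å so structures round-trip
through PDB exactly.

`design_sequence` plants ground truth: MF-designed positions get the
identity minimizing their native energy given current neighbors (which is
also the Z-maximizing identity, since the decoy distribution does not
depend on the native choice), HF-designed the maximizing identity, other
positions a seed-random background (or the existing sequence on request).
Sweeps repeat until stable; designed positions that contact each other can
oscillate between jointly inconsistent optima, so convergence is flagged
and a verification helper re-checks local optimality per position.

`make_complex` places one target residue outside each requested receptor
position — within the contact cutoff of that site and clear of all others
by a 0.01 Å guard band against coordinate rounding — searching local
surface normals, then random directions, and failing loudly if the
position is buried.  The resulting inter-chain contact set equals the
requested interface exactly.  `make_null_complex` appends a displaced copy
of the receptor: zero contacts and proportional composition, the exact
interface-null control.

`simulate_msa` evolves a root sequence down a random bifurcating tree
(uniform branch lengths 0.05–0.25) or a supplied one.  Per column, a rate
class (invariant 0, slow 0.3, fast 2.0 substitutions per unit branch
length) drives Poisson replacement events, each drawing uniformly from the
20 letters — so a column survives a branch of length t unchanged with
probability e^(−rt) + (1 − e^(−rt))/20, giving closed-form saturation
checks.  No indels are simulated (gap handling is tested on hand-built
gapped fixtures); a zero-length leaf carrying the unmutated root sequence
is grafted at the root so the alignment contains an exact reference.

## The recovery benchmark

The end-to-end benchmark miniaturizes a multi-complex study: one
60-residue receptor with 6 MF- and 6 HF-designed positions, 58 complexes
with random 2–4-residue interfaces placed away from the designed
positions, and a 32-leaf simulated homolog set with 30% invariant / 70%
fast columns rooted at the receptor's sequence.  Designed positions are
chosen mutually non-adjacent in the contact graph (so each label is
independently optimizable and the design sweep provably converges) and are
verified: a position only counts as ground truth if its best (worst)
identity clears the ±1 cutoff with a 0.15 margin — about three combined
standard errors of decoy sampling plus the composition shift a small
target induces.  At some positions no identity is classifiable as MF or
HF; counting such a position as "designed" would assert a label that is
not true, so the benchmark replaces it (reshuffling selection and, if
needed, the background sequence).  The conservation cutoff is chosen from
the simulated score distribution by the two-means split.

Reported metrics: the fraction of designed (position, complex) pairs
whose six-class label matches the designed one, and the Mann–Whitney AUC
of rvET ranking invariant vs fast columns.  Across wide seed scans the
benchmark recovers ≥ 99% of designed labels with AUC 1.0 and runs in a
couple of seconds on one CPU.

**What this does and does not show.**  Passing demonstrates that the
decoy Z-score machinery, the tree-partition entropy ranks, and the
six-class bookkeeping are internally correct and recover planted signal
through the entire pipeline.  It does not validate the energy function
against experimental stabilities, simulate indels, alignment error, or
phylogenetic uncertainty, and synthetic geometry is not protein geometry —
conclusions about real complexes inherit the usual caveats of contact
potentials and single-tree evolutionary-trace ranks.

## Numerical conventions

Z-scores use the population standard deviation of the decoy set.
Boundary values classify conservatively (±1 → neutral; ρ = cutoff → NC).
Degenerate residues are flagged, never dropped.  All RNG streams derive
from explicit integer seeds via numpy's Generator seeding; no global RNG
state is used.  Alignment traceback equality comparisons use a 1e-9
tolerance, three orders of magnitude below the 1e-6 gap-opening surcharge
they must distinguish.  TSV outputs are written with six decimal places,
which is what makes repeat runs byte-identical.
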