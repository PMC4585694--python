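"""Attribute frustration changes to a binding partner.

Builds a receptor-target complex whose target touches exactly two receptor
residues, scores the receptor bound and unbound, and prints the per-residue
SRLF change: only the interface residues can move.
"""

import frustevo as fv

receptor = fv.make_structure(40, seed=21)
complex_model = fv.make_complex(receptor, interface_positions=[12, 27], seed=21)
em = fv.EnergyModel(seed=21)

bound = fv.frustration_profile(complex_model, em)
unbound = fv.unbound_profile(complex_model, {"A"}, em)
delta = fv.delta_frustration(bound, unbound)

moved = delta[delta.delta_srlf.abs() > 1e-9]
print(moved.to_string(index=False))
print(
    "\ndelta_srlf = SRLF(bound) - SRLF(unbound). Positive: the target's\n"
    "contact stabilizes that residue's native identity upon binding.\n"
    "Residues 12 and 27 are the designed interface; under the composition\n"
    "decoy policy the target's residues also shift decoy weights slightly,\n"
    "so small nonzero deltas can appear elsewhere."
)
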