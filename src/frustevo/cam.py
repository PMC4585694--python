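"""Packaged calmodulin reference: the 148-residue mature human sequence.

Calmodulin (CaM) is the canonical multi-specific Ca2+ sensor: four EF-hand
motifs in two lobes, a flexible central linker, and an unusually
methionine-rich surface that lets it engage hundreds of different targets.
The nine Met and nine Leu positions below are the standard focus sets for
per-residue analyses of its binding promiscuity.
"""

from __future__ import annotations

from importlib import resources

MET_POSITIONS = (36, 51, 71, 72, 76, 109, 124, 144, 145)
LEU_POSITIONS = (4, 18, 32, 39, 48, 69, 105, 112, 116)


def load_cam_sequence() -> str:
    """The mature human CaM sequence (1-based positions match author numbering)."""
    text = (resources.files("frustevo.data") / "calmodulin_human.fasta").read_text()
    return "".join(ln.strip() for ln in text.splitlines() if not ln.startswith(">"))


def composition_percent(sequence: str, aa: str) -> float:
    """Percentage of the sequence made up of amino acid ``aa``."""
    if not sequence:
        raise ValueError("empty sequence")
    return 100.0 * sequence.count(aa) / len(sequence)
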