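"""Sequence-level statistics for keratin chains.

Small helpers for the counts that matter to disulfide-free dimer
modelling: cysteine content (epithelial keratins carry few cysteines, so
non-covalent contacts dominate) and the net side-chain formal charge of a
region at neutral pH (histidine neutral), which controls the electrostatic
anchoring of the head domain onto the rod.
"""

from __future__ import annotations

__all__ = ["count_residues", "net_sidechain_charge"]

# side-chain formal charges at pH 7 with neutral histidine
_CHARGE = {"K": +1, "R": +1, "D": -1, "E": -1, "H": 0}


def count_residues(sequence: str, residue: str) -> int:
    """Occurrences of a one-letter residue code in a sequence."""
    return sequence.upper().count(residue.upper())


def net_sidechain_charge(sequence: str, start: int = 1,
                         end: int | None = None) -> int:
    """Net side-chain formal charge of sequence[start..end] (1-based,
    inclusive) at neutral pH, histidine neutral."""
    seq = sequence.upper()
    if end is None:
        end = len(seq)
    region = seq[start - 1:end]
    return sum(_CHARGE.get(aa, 0) for aa in region)
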