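"""Average (not monoisotopic) peptide masses, matching the mass scale of the
2-DE / MALDI screening window (28-40 kD for the gliadin peaks)."""
from __future__ import annotations

from pyteomics import mass as _pmass

from .errors import InputError
from .records import AMINO_ACIDS, ProteinRecord

WATER_DA = _pmass.calculate_mass(formula="H2O", average=True)

AVERAGE_RESIDUE_MASS_DA = {
    aa: _pmass.calculate_mass(sequence=aa, average=True) - WATER_DA
    for aa in sorted(AMINO_ACIDS)
}


def peptide_mass(sequence: str) -> float:
    """Average mass in Da of a peptide: residue masses plus one water."""
    if not sequence:
        raise InputError("cannot compute the mass of an empty peptide")
    try:
        return sum(AVERAGE_RESIDUE_MASS_DA[aa] for aa in sequence) + WATER_DA
    except KeyError as exc:
        raise InputError(f"unknown residue {exc.args[0]!r}") from None


def mature_mass(protein: ProteinRecord | str) -> float:
    """Average mass in Da of a mature gliadin chain."""
    if isinstance(protein, ProteinRecord):
        if protein.form != "mature":
            raise InputError("mature_mass expects the mature form")
        return peptide_mass(protein.sequence)
    return peptide_mass(protein)
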