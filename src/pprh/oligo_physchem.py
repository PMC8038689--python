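"""Oligo physicochemistry: MW, GC, melting temperature, dose arithmetic.

Molecular weights use the linear single-stranded anhydrous free-acid
convention common among oligo vendors: the sum of per-nucleotide
monomer masses minus a single terminal correction of 61.96 Da
(replacing one phosphate with the 5'-OH). Tm uses deliberately simple
closed forms (Wallace rule for short oligos, a GC/length formula
otherwise) — a QC aid, not a hybridization model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

from .sequence_model import SequenceError, reverse_complement

__all__ = [
    "PhyschemConstants",
    "OligoReport",
    "molecular_weight",
    "molarity",
    "gc_content",
    "melting_temperature",
    "oligo_report",
]

_DEFAULT_MONOMER_MASS = MappingProxyType(
    {"A": 313.21, "T": 304.2, "C": 289.18, "G": 329.21}
)


@dataclass(frozen=True)
class PhyschemConstants:
    """Monomer masses (Da) and terminal correction for ssDNA MW."""

    monomer_mass: Mapping[str, float] = field(
        default_factory=lambda: _DEFAULT_MONOMER_MASS
    )
    terminal_correction: float = 61.96

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.monomer_mass.values()):
            raise ValueError("monomer masses must be positive")


DEFAULT_CONSTANTS = PhyschemConstants()


def molecular_weight(seq: str, constants: PhyschemConstants = DEFAULT_CONSTANTS) -> float:
    """Anhydrous ssDNA molecular weight in Da."""
    seq = seq.upper()
    total = 0.0
    for i, ch in enumerate(seq):
        if ch not in constants.monomer_mass:
            raise SequenceError(
                f"cannot compute MW: non-concrete base {ch!r} at position {i}"
            )
        total += constants.monomer_mass[ch]
    if not seq:
        raise SequenceError("empty sequence")
    return total - constants.terminal_correction


def molarity(mass_ug: float, mw: float, volume_ml: float) -> float:
    """Concentration in nM of ``mass_ug`` µg of an oligo of ``mw`` Da in ``volume_ml`` mL.

    nM = µg / (Da) / mL * 1e6. Returned unrounded; round only at display.
    """
    if mass_ug <= 0 or mw <= 0 or volume_ml <= 0:
        raise ValueError("mass, MW and volume must all be positive")
    return mass_ug / mw / volume_ml * 1e6


def gc_content(seq: str) -> float:
    """Fraction of G+C bases."""
    seq = seq.upper()
    if not seq:
        raise SequenceError("empty sequence")
    return sum(c in "GC" for c in seq) / len(seq)


def melting_temperature(seq: str) -> tuple[float, str]:
    """Approximate Tm in °C and the method tag used.

    Wallace rule 2(A+T) + 4(G+C) below 14 nt; otherwise
    64.9 + 41*(G+C - 16.4)/length.
    """
    seq = seq.upper()
    if not seq:
        raise SequenceError("empty sequence")
    gc = sum(c in "GC" for c in seq)
    at = sum(c in "AT" for c in seq)
    if len(seq) < 14:
        return 2.0 * at + 4.0 * gc, "wallace"
    return 64.9 + 41.0 * (gc - 16.4) / len(seq), "gc_length"


@dataclass(frozen=True)
class OligoReport:
    """Physchem summary for one oligo."""

    seq: str
    length: int
    gc_fraction: float
    mw: float
    tm: float
    method_tags: tuple[str, ...]


def oligo_report(seq: str, constants: PhyschemConstants = DEFAULT_CONSTANTS) -> OligoReport:
    seq = seq.upper()
    tm, tm_method = melting_temperature(seq)
    return OligoReport(
        seq=seq,
        length=len(seq),
        gc_fraction=gc_content(seq),
        mw=molecular_weight(seq, constants),
        tm=tm,
        method_tags=("mw:anhydrous_ssDNA", f"tm:{tm_method}"),
    )
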