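"""Solute registry.

Molar masses are in kg mol-1 (SI), i.e. 0.11912 kg mol-1 for l-threonine
(C4H9NO3) and 0.17617 kg mol-1 for glycyl-l-threonine (C6H12N2O4).
"""

from dataclasses import dataclass
from enum import Enum


class SoluteKind(str, Enum):
    amino_acid = "amino_acid"
    dipeptide = "dipeptide"
    other = "other"


@dataclass(frozen=True)
class SoluteSpec:
    name: str
    molar_mass: float  # kg mol-1
    kind: SoluteKind = SoluteKind.other

    def __post_init__(self):
        if not self.name:
            raise ValueError("solute name must be non-empty")
        if not self.molar_mass > 0:
            raise ValueError(f"molar_mass must be positive, got {self.molar_mass}")


SOLUTES = {
    "l-threonine": SoluteSpec("l-threonine", 0.11912, SoluteKind.amino_acid),
    "glycyl-l-threonine": SoluteSpec("glycyl-l-threonine", 0.17617, SoluteKind.dipeptide),
}


def solute_registry(extra=None):
    """Default registry, optionally extended/overridden by an iterable of SoluteSpec."""
    registry = dict(SOLUTES)
    for spec in extra or ():
        registry[spec.name] = spec
    return registry
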