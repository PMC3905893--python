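"""Molar extinction coefficients at 260 nm, with analog scaling.

Natural-sequence coefficients use the standard nearest-neighbor model,

    eps(strand) = sum_i eps_NN(b_i, b_i+1) - sum_interior eps_mono(b_i),

with the classic dinucleotide/mononucleotide values (M^-1 cm^-1).  For
sequences containing base analogs, whose nearest-neighbor parameters are
unknown, the coefficient is estimated by composition scaling: the
nearest-neighbor value of the natural parent sequence is multiplied by the
ratio of summed individual (mononucleotide) coefficients of the modified
vs. natural sequence.  With ~25% modified residues this perturbative
estimate stays close to unity.
"""
from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["SequenceComposition", "nn_extinction", "scaled_extinction",
           "MONO_EPSILON", "NN_EPSILON"]

#: Mononucleotide extinction coefficients at 260 nm (M^-1 cm^-1).
MONO_EPSILON = {"A": 15400.0, "C": 7400.0, "G": 11500.0, "T": 8700.0}

#: Nearest-neighbor dinucleotide coefficients at 260 nm (M^-1 cm^-1, per dimer).
NN_EPSILON = {
    "AA": 27400.0, "AC": 21200.0, "AG": 25000.0, "AT": 22800.0,
    "CA": 21200.0, "CC": 14600.0, "CG": 18000.0, "CT": 15200.0,
    "GA": 25200.0, "GC": 17600.0, "GG": 21600.0, "GT": 20000.0,
    "TA": 23400.0, "TC": 16200.0, "TG": 19000.0, "TT": 16800.0,
}


@dataclass(frozen=True)
class SequenceComposition:
    """A natural parent strand plus analog substitutions.

    ``analog_positions`` maps 0-based positions to analog identifiers
    (e.g. ``"2"``-``"9"``); ``analog_epsilon`` maps each identifier to its
    individual extinction coefficient, which must be supplied by the user
    (analog coefficients are compound-specific).
    """

    sequence: str
    analog_positions: dict = field(default_factory=dict)
    analog_epsilon: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if len(seq) < 2:
            raise ValueError("sequence must have at least 2 residues")
        bad = set(seq) - set("ACGT")
        if bad:
            raise ValueError(f"sequence letters outside ACGT: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)
        for pos in self.analog_positions:
            if not 0 <= pos < len(seq):
                raise ValueError(f"analog position {pos} outside sequence")
        for pos, analog in self.analog_positions.items():
            if analog not in self.analog_epsilon:
                raise KeyError(
                    f"no individual extinction coefficient supplied for analog "
                    f"{analog!r} (position {pos})"
                )
            if not self.analog_epsilon[analog] > 0:
                raise ValueError(f"epsilon for analog {analog!r} must be positive")


def nn_extinction(sequence: str) -> float:
    """Nearest-neighbor extinction coefficient of a natural strand (M^-1 cm^-1)."""
    seq = sequence.upper()
    if len(seq) < 2:
        raise ValueError("need at least a dinucleotide")
    eps = sum(NN_EPSILON[seq[i:i + 2]] for i in range(len(seq) - 1))
    eps -= sum(MONO_EPSILON[b] for b in seq[1:-1])
    return float(eps)


def scaled_extinction(comp: SequenceComposition) -> float:
    """Extinction coefficient of an analog-containing strand (M^-1 cm^-1).

    eps = eps_NN(natural parent) * sum(eps_individual, modified strand)
                                 / sum(eps_individual, natural strand).
    """
    natural = nn_extinction(comp.sequence)
    mono_natural = sum(MONO_EPSILON[b] for b in comp.sequence)
    mono_modified = 0.0
    for i, b in enumerate(comp.sequence):
        if i in comp.analog_positions:
            mono_modified += comp.analog_epsilon[comp.analog_positions[i]]
        else:
            mono_modified += MONO_EPSILON[b]
    return float(natural * mono_modified / mono_natural)
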