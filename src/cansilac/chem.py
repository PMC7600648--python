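"""Elemental and residue mass bookkeeping.

Monoisotopic masses of peptides and of the three arginine label states
(light Arg, SILAC heavy ``13C6,15N4``-Arg, and canavanine) underpin the
whole analysis: the Arg-to-canavanine substitution shifts a peptide by
+1.9793 Da, which nearly coincides with the +2.0066 Da spacing between
the third and first isotopologues of the unmodified peptide.  The 27.3 mDa
gap between the two is the analytical conflict the heavy-Arg labeling
design works around.

The four atomic masses that enter that arithmetic (1H, 12C, 13C, 16O)
are fixed at the 4-decimal values 1.0078, 12, 13.0033 and 15.9949 so the
diagnostic constants reproduce the printed arithmetic exactly; the
remaining isotopes carry full-precision CIAAW 2019 values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = [
    "ELEMENT_MASSES",
    "PROTON_MASS",
    "WATER_MASS",
    "RESIDUE_COMPOSITIONS",
    "CANAVANINE",
    "HEAVY_ARG",
    "STANDARD_RESIDUES",
    "ModificationDelta",
    "residue_mass",
    "composition_mass",
    "peptide_monoisotopic_mass",
    "diagnostic_deltas",
    "mz_from_mass",
    "HEAVY_ARG_SHIFT",
    "CANAVANINE_SHIFT",
]

# Isotope label -> exact mass in Da.  1H/12C/13C/16O truncated to the
# 4-decimal values used in the diagnostic-delta arithmetic; the rest are
# CIAAW 2019 monoisotopic masses.
ELEMENT_MASSES: dict[str, float] = {
    "1H": 1.0078,
    "2H": 2.0141018,
    "12C": 12.0,
    "13C": 13.0033,
    "14N": 14.0030740,
    "15N": 15.0001089,
    "16O": 15.9949,
    "32S": 31.9720712,
}

#: Mass of a proton (charging constant for ESI positive mode), Da.
PROTON_MASS = 1.00728

# Internal one-character symbols for the two non-standard residues.
# PSM tables never contain them; they exist so that mass computations can
# address a specific label state of an Arg position.
CANAVANINE = "c"
HEAVY_ARG = "h"

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


def _comp(C=0, H=0, N=0, O=0, S=0, C13=0, N15=0) -> dict[str, int]:
    out: dict[str, int] = {}
    for label, n in (
        ("12C", C), ("1H", H), ("14N", N), ("16O", O), ("32S", S),
        ("13C", C13), ("15N", N15),
    ):
        if n:
            out[label] = n
    return out


# In-chain (residue) elemental compositions of the 20 standard amino
# acids, plus canavanine and heavy Arg.
RESIDUE_COMPOSITIONS: dict[str, dict[str, int]] = {
    "G": _comp(C=2, H=3, N=1, O=1),
    "A": _comp(C=3, H=5, N=1, O=1),
    "S": _comp(C=3, H=5, N=1, O=2),
    "P": _comp(C=5, H=7, N=1, O=1),
    "V": _comp(C=5, H=9, N=1, O=1),
    "T": _comp(C=4, H=7, N=1, O=2),
    "C": _comp(C=3, H=5, N=1, O=1, S=1),
    "L": _comp(C=6, H=11, N=1, O=1),
    "I": _comp(C=6, H=11, N=1, O=1),
    "N": _comp(C=4, H=6, N=2, O=2),
    "D": _comp(C=4, H=5, N=1, O=3),
    "Q": _comp(C=5, H=8, N=2, O=2),
    "K": _comp(C=6, H=12, N=2, O=1),
    "E": _comp(C=5, H=7, N=1, O=3),
    "M": _comp(C=5, H=9, N=1, O=1, S=1),
    "H": _comp(C=6, H=7, N=3, O=1),
    "F": _comp(C=9, H=9, N=1, O=1),
    "R": _comp(C=6, H=12, N=4, O=1),
    "Y": _comp(C=9, H=9, N=1, O=2),
    "W": _comp(C=11, H=10, N=2, O=1),
    # canavanine: Arg with one CH2 of the side chain replaced by O
    CANAVANINE: _comp(C=5, H=10, N=4, O=2),
    # heavy Arg: 13C6,15N4-arginine
    HEAVY_ARG: _comp(H=12, O=1, C13=6, N15=4),
}


@dataclass(frozen=True)
class ModificationDelta:
    """A named mass shift applied to a target residue."""

    name: str
    mass_shift: float
    target: str


def composition_mass(composition: Mapping[str, int]) -> float:
    """Sum exact isotope masses over an elemental composition."""
    total = 0.0
    for label, count in composition.items():
        if label not in ELEMENT_MASSES:
            raise KeyError(f"unknown isotope label: {label!r}")
        if count < 0:
            raise ValueError(f"negative count for {label!r}")
        total += ELEMENT_MASSES[label] * count
    return total


def residue_mass(residue: str) -> float:
    """Monoisotopic in-chain mass of a residue symbol.

    Accepts the 20 standard one-letter codes plus the internal canavanine
    and heavy-Arg symbols.
    """
    try:
        comp = RESIDUE_COMPOSITIONS[residue]
    except KeyError:
        raise KeyError(f"unknown residue symbol: {residue!r}") from None
    return composition_mass(comp)


#: Monoisotopic mass of H2O, Da.
WATER_MASS = 2 * ELEMENT_MASSES["1H"] + ELEMENT_MASSES["16O"]

#: Mass shift of replacing one light Arg by heavy Arg, Da (rounds to +10).
HEAVY_ARG_SHIFT = residue_mass(HEAVY_ARG) - residue_mass("R")

#: Mass shift of replacing one light Arg by canavanine, Da.
CANAVANINE_SHIFT = residue_mass(CANAVANINE) - residue_mass("R")

_STATE_SYMBOL = {"L": "R", "H": HEAVY_ARG, "CAV": CANAVANINE}


def peptide_monoisotopic_mass(
    sequence: str, site_states: Sequence[str] | None = None
) -> float:
    """Neutral monoisotopic mass of a peptide.

    Parameters
    ----------
    sequence
        Uppercase residue string using standard one-letter codes.
    site_states
        Optional label states over the Arg positions of ``sequence`` in
        order, each one of ``"H"``, ``"L"``, ``"CAV"``.  When omitted,
        every Arg is light.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    arg_positions = [i for i, aa in enumerate(sequence) if aa == "R"]
    states = list(site_states) if site_states is not None else ["L"] * len(arg_positions)
    if len(states) != len(arg_positions):
        raise ValueError(
            f"site_states has length {len(states)} but sequence has "
            f"{len(arg_positions)} Arg positions"
        )
    effective = list(sequence)
    for pos, state in zip(arg_positions, states):
        try:
            effective[pos] = _STATE_SYMBOL[state]
        except KeyError:
            raise ValueError(f"unknown label state: {state!r}") from None
    return sum(residue_mass(aa) for aa in effective) + WATER_MASS


def diagnostic_deltas() -> dict[str, float]:
    """The three mass constants at the core of the labeling design.

    Returns a dict with

    ``can_shift``
        Arg -> canavanine substitution shift, ``16O - 12C - 2*1H``
        (+1.9793 Da).
    ``isotope_pair``
        Spacing between the third and first isotopologues of a peptide,
        ``2 * (13C - 12C)`` (+2.0066 Da).
    ``conflict_gap``
        Their difference (27.3 mDa) — the separation an instrument would
        need to resolve a canavanine variant from the A+2 isotopologue of
        the unmodified peptide.
    """
    m = ELEMENT_MASSES
    can_shift = m["16O"] - m["12C"] - 2 * m["1H"]
    isotope_pair = 2 * (m["13C"] - m["12C"])
    return {
        "can_shift": can_shift,
        "isotope_pair": isotope_pair,
        "conflict_gap": isotope_pair - can_shift,
    }


def mz_from_mass(neutral_mass: float, charge: int) -> float:
    """m/z of an ion given neutral monoisotopic mass and positive charge."""
    if charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    return (neutral_mass + charge * PROTON_MASS) / charge
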