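"""Monoisotopic mass arithmetic for CHO molecules and their [M-H]- anions."""

from __future__ import annotations

# CODATA / AME monoisotopic masses (Da)
MASS_C = 12.0
MASS_H = 1.00782503207
MASS_O = 15.99491461956
MASS_ELECTRON = 0.00054857990907


def neutral_mass(c: int, h: int, o: int) -> float:
    """Monoisotopic mass of the neutral CcHhOo molecule."""
    if c < 0 or h < 0 or o < 0:
        raise ValueError("element counts must be nonnegative")
    return c * MASS_C + h * MASS_H + o * MASS_O


def anion_mz(c: int, h: int, o: int) -> float:
    """Theoretical m/z of the deprotonated [M-H]- anion.

    The electron gained on deprotonation is included: at 3 ppm below
    m/z 200 the ~0.5 mDa electron mass is not negligible.
    """
    if h < 1:
        raise ValueError("need at least one hydrogen to deprotonate")
    return neutral_mass(c, h, o) - MASS_H + MASS_ELECTRON


def dbe(c: int, h: int) -> float:
    """Double-bond equivalents (rings + double bonds) of a neutral CcHhOo."""
    return c - h / 2.0 + 1.0


def z_number(c: int, h: int) -> float:
    """Hydrogen deficiency Z in the CnH(2n+Z)O2 convention: Z = 2(1 - DBE)."""
    return 2.0 * (1.0 - dbe(c, h))
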