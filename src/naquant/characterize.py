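"""CHO molecular-formula assignment for ESI(-) peaks and class summaries.

Deprotonated [M-H]- ions are matched against neutral CcHhOo candidates by
exhaustive enumeration over carbon and oxygen counts, solving the hydrogen
count from the observed mass. Assignments report the neutral formula, ppm
error, double-bond equivalents, the Ox heteroatom class and the Z number of
the CnH(2n+Z)O2 convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import MASS_C, MASS_ELECTRON, MASS_H, MASS_O, anion_mz
from .spectra_io import Spectrum


@dataclass(frozen=True)
class FormulaAssignment:
    observed_mz: float
    formula: tuple[int, int, int]  # neutral (c, h, o)
    theoretical_mz: float
    ppm_error: float
    dbe: int
    class_label: str
    z_number: int


def assign_formula(
    mz: float,
    tolerance_ppm: float = 3.0,
    c_range: tuple[int, int] = (1, 40),
    o_range: tuple[int, int] = (1, 6),
    dbe_range: tuple[int, int] = (0, 15),
) -> list[FormulaAssignment]:
    """Candidate neutral CHO formulas for one [M-H]- peak, best ppm first.

    For each (c, o) the hydrogen count is solved from the mass; only even h
    (integer DBE for a CHO neutral), h >= 1 and DBE inside ``dbe_range``
    survive. An empty list (no candidate) is not an error.
    """
    if not 0 < mz < 2000:
        raise ValueError("mz must be in (0, 2000)")
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be > 0")
    out: list[FormulaAssignment] = []
    for c in range(c_range[0], c_range[1] + 1):
        for o in range(o_range[0], o_range[1] + 1):
            h_exact = (mz - c * MASS_C - o * MASS_O + MASS_H - MASS_ELECTRON) / MASS_H
            h = int(round(h_exact))
            if h < 1:
                continue
            if h % 2:  # odd h -> half-integer DBE for the neutral
                continue
            d = c - h // 2 + 1
            if not dbe_range[0] <= d <= dbe_range[1]:
                continue
            theo = anion_mz(c, h, o)
            ppm = (mz - theo) / theo * 1e6
            if abs(ppm) <= tolerance_ppm:
                out.append(
                    FormulaAssignment(
                        observed_mz=mz,
                        formula=(c, h, o),
                        theoretical_mz=theo,
                        ppm_error=ppm,
                        dbe=d,
                        class_label=f"O{o}",
                        z_number=2 * (1 - d),
                    )
                )
    out.sort(key=lambda a: abs(a.ppm_error))
    return out


def assign_spectrum(
    spectrum: Spectrum,
    tolerance_ppm: float = 3.0,
    c_range: tuple[int, int] = (1, 40),
    o_range: tuple[int, int] = (1, 6),
    dbe_range: tuple[int, int] = (0, 15),
) -> pd.DataFrame:
    """Best assignment per peak; unassignable peaks are omitted."""
    rows = []
    for m, inten in zip(spectrum.mz, spectrum.intensity):
        hits = assign_formula(float(m), tolerance_ppm, c_range, o_range, dbe_range)
        if not hits:
            continue
        best = hits[0]
        c, h, o = best.formula
        rows.append(
            {
                "observed_mz": best.observed_mz,
                "intensity": float(inten),
                "c": c,
                "h": h,
                "o": o,
                "formula": f"C{c}H{h}O{o}",
                "theoretical_mz": best.theoretical_mz,
                "ppm_error": best.ppm_error,
                "dbe": best.dbe,
                "class_label": best.class_label,
                "z_number": best.z_number,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "observed_mz", "intensity", "c", "h", "o", "formula",
            "theoretical_mz", "ppm_error", "dbe", "class_label", "z_number",
        ],
    )


def class_distribution(
    assignments: list[FormulaAssignment] | pd.DataFrame,
    intensities: np.ndarray | None = None,
) -> pd.Series:
    """Relative abundance (%) of summed assigned intensity per Ox class."""
    df = _as_frame(assignments, intensities)
    if df.empty:
        raise ValueError("need at least one assignment")
    totals = df.groupby("class_label")["intensity"].sum()
    return (100.0 * totals / totals.sum()).sort_index()


def dbe_carbon_matrix(
    assignments: list[FormulaAssignment] | pd.DataFrame,
    intensities: np.ndarray | None = None,
    class_filter: str | None = None,
) -> pd.DataFrame:
    """DBE x carbon-number matrix of summed intensity, as % of the total.

    ``class_filter`` restricts to one Ox class (e.g. "O2") before
    normalizing.
    """
    df = _as_frame(assignments, intensities)
    if class_filter is not None:
        df = df[df["class_label"] == class_filter]
    if df.empty:
        raise ValueError("no assignments after class filter")
    pivot = df.pivot_table(
        index="dbe", columns="c", values="intensity", aggfunc="sum", fill_value=0.0
    )
    return 100.0 * pivot / pivot.to_numpy().sum()


def _as_frame(assignments, intensities) -> pd.DataFrame:
    if isinstance(assignments, pd.DataFrame):
        return assignments
    if intensities is None:
        raise ValueError("intensities required with a list of assignments")
    rows = [
        {
            "class_label": a.class_label,
            "dbe": a.dbe,
            "c": a.formula[0],
            "intensity": float(i),
        }
        for a, i in zip(assignments, intensities)
    ]
    return pd.DataFrame(rows, columns=["class_label", "dbe", "c", "intensity"])
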