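"""Simulated produced-water spectra with known concentration structure.

The simulator emits direct-infusion ESI(-) centroid peak lists for mixtures
of the ten carboxylic-acid calibration standards, with configurable mass
error, intensity noise, chemical baseline and (in real-sample mode) dense
interferent peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .chem import anion_mz
from .spectra_io import Spectrum

#: default total-NA concentration levels (mg/L), three replicates each
DEFAULT_LEVELS = (
    0.50, 4.10, 7.68, 11.27, 14.86, 18.45,
    22.05, 25.63, 29.23, 32.82, 36.41, 40.00,
)
DEFAULT_REPLICATES = 3


@dataclass(frozen=True)
class StandardCompound:
    """One calibration standard: neutral CHO formula and its anion mass."""

    name: str
    formula: tuple[int, int, int]  # (c, h, o)
    response_factor: float  # counts per mg/L

    def __post_init__(self) -> None:
        if self.response_factor <= 0:
            raise ValueError("response_factor must be positive")

    @property
    def mz_anion(self) -> float:
        return anion_mz(*self.formula)

    @property
    def molecular_weight(self) -> float:
        c, h, o = self.formula
        return 12.011 * c + 1.008 * h + 15.999 * o


# Distinct response factors stand in for real ESI ionization-efficiency
# differences between acids; values are arbitrary but fixed.
_PANEL: tuple[tuple[str, tuple[int, int, int], float], ...] = (
    ("cyclopentanecarboxylic acid", (6, 10, 2), 1200.0),
    ("benzoic acid", (7, 6, 2), 800.0),
    ("cyclohexanebutyric acid", (10, 18, 2), 1500.0),
    ("1-naphthoic acid", (11, 8, 2), 600.0),
    ("9-anthracenecarboxylic acid", (15, 10, 2), 400.0),
    ("pentadecanoic acid", (15, 30, 2), 2000.0),
    ("decanoic acid", (10, 20, 2), 1700.0),
    ("3,5-dimethyladamantane-1-carboxylic acid", (13, 20, 2), 900.0),
    ("3,5-dimethyladamantane-1-acetic acid", (14, 22, 2), 1100.0),
    ("2-methyloctadecanoic acid", (19, 38, 2), 1300.0),
)


def standard_panel() -> list[StandardCompound]:
    """The ten carboxylic-acid calibration standards."""
    return [StandardCompound(n, f, rf) for n, f, rf in _PANEL]


@dataclass(frozen=True)
class SimulationParams:
    """Noise / nuisance structure of the simulated instrument.

    ``share`` controls how the total NA concentration is split across the
    ten standards: ``equal_mass`` gives each a tenth of the total mass
    concentration; ``equimolar`` splits moles equally, i.e. mass shares
    proportional to molecular weight.
    """

    seed: int
    sigma_ppm: float = 1.0
    intensity_cv: float = 0.05
    n_baseline_peaks: int = 50
    baseline_intensity_scale: float = 2000.0
    n_interferents: int = 200
    mz_min: float = 100.0
    mz_max: float = 400.0
    share: str = "equal_mass"

    def __post_init__(self) -> None:
        for name in ("sigma_ppm", "intensity_cv", "baseline_intensity_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_baseline_peaks < 0 or self.n_interferents < 0:
            raise ValueError("peak counts must be nonnegative")
        if self.share not in ("equal_mass", "equimolar"):
            raise ValueError("share must be 'equal_mass' or 'equimolar'")


def make_design(
    levels: list[float] | tuple[float, ...] | None = None,
    replicates: int = DEFAULT_REPLICATES,
) -> pd.DataFrame:
    """Concentration design: one row per (level, replicate) sample.

    Defaults to the 12 standard levels x 3 replicates = 36 samples.
    """
    if levels is None:
        levels = DEFAULT_LEVELS
    levels = list(levels)
    if not levels:
        raise ValueError("levels must be nonempty")
    if any(c < 0 for c in levels):
        raise ValueError("concentrations must be nonnegative")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rows = [
        {
            "sample_id": f"L{i + 1:02d}R{r + 1}",
            "level_index": i,
            "replicate": r + 1,
            "concentration": float(c),
        }
        for i, c in enumerate(levels)
        for r in range(replicates)
    ]
    return pd.DataFrame(rows)


def _per_compound_concentrations(total: float, params: SimulationParams) -> np.ndarray:
    panel = standard_panel()
    if params.share == "equal_mass":
        shares = np.full(len(panel), 1.0 / len(panel))
    else:  # equimolar: equal moles -> mass proportional to MW
        mw = np.asarray([s.molecular_weight for s in panel])
        shares = mw / mw.sum()
    return total * shares


def simulate_spectrum(
    concentration: float,
    params: SimulationParams,
    mode: str = "standard_mix",
    sample_id: str = "sim",
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """One simulated centroid spectrum at a total NA concentration (mg/L).

    Standard peaks appear at ``mz_anion * (1 + e/1e6)`` with
    ``e ~ N(0, sigma_ppm)`` and intensity
    ``response_factor * c_i * max(0, 1 + N(0, intensity_cv))``.
    Baseline peaks sit at uniform random m/z; ``real_sample`` mode adds
    ``n_interferents`` further peaks excluding +-5 mTh around the standards.
    """
    if concentration < 0:
        raise ValueError("concentration must be nonnegative")
    if mode not in ("standard_mix", "real_sample"):
        raise ValueError("mode must be 'standard_mix' or 'real_sample'")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    panel = standard_panel()
    conc_i = _per_compound_concentrations(concentration, params)
    mzs: list[float] = []
    intens: list[float] = []
    for compound, c_i in zip(panel, conc_i):
        e = rng.normal(0.0, params.sigma_ppm) if params.sigma_ppm > 0 else 0.0
        noise = rng.normal(0.0, params.intensity_cv) if params.intensity_cv > 0 else 0.0
        mzs.append(compound.mz_anion * (1.0 + e / 1e6))
        intens.append(compound.response_factor * c_i * max(0.0, 1.0 + noise))
    for _ in range(params.n_baseline_peaks):
        mzs.append(rng.uniform(params.mz_min, params.mz_max))
        intens.append(params.baseline_intensity_scale * rng.exponential())
    if mode == "real_sample":
        standards_mz = np.asarray([s.mz_anion for s in panel])
        n_added = 0
        while n_added < params.n_interferents:
            m = rng.uniform(params.mz_min, params.mz_max)
            if np.min(np.abs(standards_mz - m)) <= 0.005:
                continue
            mzs.append(m)
            intens.append(params.baseline_intensity_scale * 10.0 * rng.exponential())
            n_added += 1
    return Spectrum(sample_id, np.asarray(mzs), np.asarray(intens))


def simulate_dataset(
    design: pd.DataFrame,
    params: SimulationParams,
    mode: str = "standard_mix",
) -> tuple[list[Spectrum], np.ndarray]:
    """One spectrum per design row, each from its own seed substream.

    Returns the spectra and the matching concentration vector y.
    """
    seeds = np.random.SeedSequence(params.seed).spawn(len(design))
    spectra = []
    for ss, row in zip(seeds, design.itertuples(index=False)):
        spectra.append(
            simulate_spectrum(
                row.concentration,
                params,
                mode=mode,
                sample_id=str(row.sample_id),
                rng=np.random.default_rng(ss),
            )
        )
    y = design["concentration"].to_numpy(dtype=np.float64)
    return spectra, y


def noiseless(params: SimulationParams) -> SimulationParams:
    """Copy of params with every stochastic term switched off."""
    return replace(
        params, sigma_ppm=0.0, intensity_cv=0.0, n_baseline_peaks=0, n_interferents=0
    )
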