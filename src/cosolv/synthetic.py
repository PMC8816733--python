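"""Seeded generators for synthetic inputs with realistic statistical structure.

Three generators cover the pipeline's inputs:

* solubility datasets drawn from a known cosolvency model with multiplicative
  (log-normal) noise — solubility is strictly positive and the evaluation
  metric is a relative deviation, so noise belongs on the log scale;
* powder diffractograms as Gaussian crystalline peaks over a broad amorphous
  halo with additive detector noise;
* HPLC detector areas from a known calibration line.

Every generator is a pure function of (specification, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence

import numpy as np

from .cosolvency import (
    JouybanAcreeParams,
    ModifiedWilsonParams,
    ja_predict,
    wilson_predict,
)
from .data_model import ETHANOL_WATER, SolubilityDataset, SolubilityRecord, SolventSystem
from .exceptions import DomainError, ValidationError
from .quantitation import CalibrationCurve

__all__ = [
    "SyntheticSpec",
    "generate_solubility_dataset",
    "generate_diffractogram",
    "gaussian_peak_area",
    "generate_hplc_areas",
    "DEFAULT_F1_GRID",
    "DEFAULT_TEMPERATURES",
]

#: Default measurement design: 11 volume fractions at two temperatures,
#: mirroring the packaged study dataset.
DEFAULT_F1_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 2))
DEFAULT_TEMPERATURES = (298.15, 310.15)


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth for a synthetic solubility dataset.

    ``anchors`` maps temperature (K) to the true neat-solvent solubilities
    (C1 in pure cosolvent, C2 in pure water, mol/L); ``noise_sd`` is the
    standard deviation of Gaussian noise on ln C.
    """

    model: JouybanAcreeParams | ModifiedWilsonParams
    anchors: Mapping[float, tuple[float, float]]
    f1_grid: tuple[float, ...] = DEFAULT_F1_GRID
    noise_sd: float = 0.05
    seed: int = 0
    n_replicates: int = 3
    system: SolventSystem = ETHANOL_WATER

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        grid = tuple(float(f) for f in self.f1_grid)
        if any(not 0.0 <= f <= 1.0 for f in grid):
            raise ValidationError("f1 grid outside [0, 1]")
        if 0.0 not in grid or 1.0 not in grid:
            raise ValidationError("f1 grid must include both neat solvents (0 and 1)")
        object.__setattr__(self, "f1_grid", grid)

    def true_solubility(self, f1: float, T: float) -> float:
        """Noise-free model value at (f1, T)."""
        C1, C2 = self.anchors[T]
        if isinstance(self.model, ModifiedWilsonParams):
            return float(wilson_predict(self.model, C1, C2, f1))
        return float(ja_predict(self.model, C1, C2, f1, T))


def generate_solubility_dataset(spec: SyntheticSpec) -> SolubilityDataset:
    """Draw a noisy dataset from the spec's generating model.

    The recorded solubility at each (f1, T) is a single log-normal draw
    around the model mean (so its relative error has standard deviation
    ``noise_sd``); the sd column is the sample standard deviation of
    ``n_replicates`` further replicate draws, mimicking a triplicate assay.
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    for T in sorted(spec.anchors):
        for f1 in spec.f1_grid:
            mean_ln = np.log(spec.true_solubility(f1, T))
            c = float(np.exp(mean_ln + spec.noise_sd * rng.standard_normal()))
            reps = np.exp(mean_ln + spec.noise_sd * rng.standard_normal(spec.n_replicates))
            records.append(
                SolubilityRecord(
                    f1=f1, T=T, C=c,
                    sd=float(np.std(reps, ddof=1)) if spec.n_replicates > 1 else 0.0,
                )
            )
    return SolubilityDataset(
        system=spec.system,
        records=tuple(records),
        solute_name="synthetic solute",
    )


def gaussian_peak_area(height: float, width: float) -> float:
    """Analytic area of a Gaussian peak with the given height and sigma-width."""
    return float(height * width * np.sqrt(2.0 * np.pi))


def generate_diffractogram(
    crystalline_peaks: Sequence[tuple[float, float, float]],
    halo: tuple[float, float, float],
    noise_sd: float = 0.0,
    seed: int = 0,
    two_theta_range: tuple[float, float] = (5.0, 50.0),
    step: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a powder diffractogram on a regular 2-theta grid.

    ``crystalline_peaks`` is a list of (position deg, height, sigma deg)
    Gaussians; ``halo`` is a single broad (center, height, sigma) Gaussian
    for the amorphous background.  Additive Gaussian detector noise with
    standard deviation ``noise_sd`` is applied pointwise.
    """
    lo, hi = two_theta_range
    for pos, _, _ in crystalline_peaks:
        if not lo <= pos <= hi:
            raise DomainError(f"peak position {pos} outside scan range [{lo}, {hi}]")
    tt = np.arange(lo, hi + step / 2, step)
    y = np.zeros_like(tt)
    for pos, height, width in crystalline_peaks:
        y += height * np.exp(-0.5 * ((tt - pos) / width) ** 2)
    c0, h0, w0 = halo
    y += h0 * np.exp(-0.5 * ((tt - c0) / w0) ** 2)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=tt.shape)
    return tt, y


def generate_hplc_areas(
    curve: CalibrationCurve,
    concentrations,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Detector areas for the given concentrations (mg/L) from a calibration line."""
    c = np.asarray(concentrations, dtype=float)
    if np.any(c < 0):
        raise DomainError("concentrations must be non-negative")
    areas = curve.slope * c + curve.intercept
    if noise_sd > 0:
        areas = areas + np.random.default_rng(seed).normal(0.0, noise_sd, size=c.shape)
    return areas
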