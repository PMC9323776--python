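"""Seedable synthetic data with the statistical structure the pipeline assumes.

The study deposited neither raw spectra nor raw tensile curves, so every
pipeline stage is exercised on simulated inputs:

* component profiles — uniform draws over the observed content ranges,
  rejection-resampled so cellulose + hemicellulose + lignin <= 100%;
* NIR spectra — Beer–Lambert mixtures of three pure-component band models
  (sums of Gaussian bands) plus a linear baseline, multiplicative scatter and
  additive noise;
* tensile compliance points — dL/F = (L0/A)/E + Cs + noise over a gauge-length
  design of 3 lengths x 15 replicates;
* grey systems — reference series forward-generated to satisfy the GM(1,N)
  difference equation exactly for known coefficients, with optional noise.

All generators are pure functions of (config, seed): one global seed expands
into fixed per-generator substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .chemometrics import SpectraMatrix
from .mechanics import CompliancePoint
from .grey import ago, initialize

__all__ = [
    "GaussianBand",
    "DEFAULT_BANDS",
    "MixtureSimConfig",
    "TensileSimConfig",
    "GreySimConfig",
    "SimulatedSpectra",
    "simulate_components",
    "simulate_spectra",
    "simulate_tensile",
    "simulate_grey_system",
]

# Fixed substream tags so each generator draws from an independent stream of
# the same global seed.
_STREAMS = {"components": 11, "spectra": 12, "tensile": 13, "grey": 14}


def _rng(seed: int | None, stream: str) -> np.random.Generator:
    if seed is None:
        return np.random.default_rng()
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass(frozen=True)
class GaussianBand:
    """One Gaussian absorption band of a pure component."""

    center: float  # cm^-1
    width: float  # cm^-1 (standard deviation)
    intensity: float  # AU per % content

    def __post_init__(self):
        if self.width <= 0 or self.intensity < 0:
            raise ValueError("band width must be > 0 and intensity >= 0")


# Synthetic pure-component band sets. Centers sit in the 4,000–9,000 cm^-1
# overtone/combination region with deliberate overlap between components so
# the mixture problem is neither trivial nor degenerate; they are not
# spectroscopic band assignments for real lignocellulose.
DEFAULT_BANDS: dict[str, tuple[GaussianBand, ...]] = {
    "cellulose": (
        GaussianBand(4280, 60, 0.006),
        GaussianBand(4740, 80, 0.005),
        GaussianBand(5200, 110, 0.007),
        GaussianBand(5800, 90, 0.004),
        GaussianBand(6290, 120, 0.005),
        GaussianBand(6720, 100, 0.003),
    ),
    "hemicellulose": (
        GaussianBand(4390, 70, 0.005),
        GaussianBand(4890, 90, 0.006),
        GaussianBand(5180, 100, 0.004),
        GaussianBand(5930, 110, 0.005),
        GaussianBand(6450, 130, 0.004),
    ),
    "lignin": (
        GaussianBand(4180, 60, 0.004),
        GaussianBand(4680, 90, 0.005),
        GaussianBand(5230, 120, 0.005),
        GaussianBand(5980, 100, 0.006),
        GaussianBand(6880, 140, 0.004),
        GaussianBand(8200, 160, 0.002),
    ),
}

#: Observed content extremes (% by mass) across the 26 study samples.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "cellulose": (7.93, 80.58),
    "hemicellulose": (10.33, 20.96),
    "lignin": (3.94, 76.97),
}


@dataclass
class MixtureSimConfig:
    """Conditions for component-profile and NIR-spectrum simulation."""

    n_samples: int = 26
    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    #: Accepted window for cellulose + hemicellulose + lignin (% of dry mass).
    #: The three structural polymers dominate dry lignocellulose, so their sum
    #: closes near 100%; draws outside the window are rejected. The upper
    #: bound also enforces the physical sum <= 100 constraint.
    total_range: tuple[float, float] = (85.0, 100.0)
    bands: dict[str, tuple[GaussianBand, ...]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    baseline_offset: tuple[float, float] = (0.0, 0.1)  # AU
    baseline_slope: tuple[float, float] = (-0.05, 0.05)  # AU across the grid
    scatter: tuple[float, float] = (-0.15, 0.15)  # multiplicative, fraction
    noise_sd: float = 0.002  # AU
    grid_start: float = 4000.0  # cm^-1
    grid_stop: float = 12000.0  # cm^-1
    grid_step: float = 4.0  # cm^-1

    def grid(self) -> np.ndarray:
        return np.arange(self.grid_start, self.grid_stop + self.grid_step / 2, self.grid_step)


def simulate_components(
    config: MixtureSimConfig | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Uniform component draws within ranges, resampled into the closure window.

    Each component is drawn uniformly within its range; a draw is kept only
    when the three contents sum to at most 100% and at least the lower closure
    bound (``config.total_range``).
    """
    config = config or MixtureSimConfig()
    names = list(config.ranges)
    lo_total, hi_total = config.total_range
    hi_total = min(hi_total, 100.0)
    min_sum = sum(lo for lo, _ in config.ranges.values())
    max_sum = sum(hi for _, hi in config.ranges.values())
    if min_sum > hi_total or max_sum < lo_total:
        raise ValueError(
            f"infeasible ranges: achievable totals [{min_sum:.2f}, {max_sum:.2f}]% "
            f"cannot meet the closure window [{lo_total}, {hi_total}]%"
        )
    rng = _rng(seed, "components")
    rows = np.empty((config.n_samples, len(names)))
    for i in range(config.n_samples):
        while True:
            draw = np.array(
                [rng.uniform(*config.ranges[name]) for name in names]
            )
            if lo_total <= draw.sum() <= hi_total:
                rows[i] = draw
                break
    df = pd.DataFrame(rows, columns=names)
    df.insert(0, "sample_id", np.arange(1, config.n_samples + 1))
    return df.set_index("sample_id")


def _pure_spectrum(bands: Sequence[GaussianBand], grid: np.ndarray) -> np.ndarray:
    out = np.zeros_like(grid)
    for band in bands:
        out += band.intensity * np.exp(-0.5 * ((grid - band.center) / band.width) ** 2)
    return out


@dataclass
class SimulatedSpectra:
    """Simulated absorbance matrix with the component table that produced it."""

    grid: np.ndarray
    absorbance: np.ndarray  # (n, p)
    components: pd.DataFrame

    def matrix(self, component: str) -> SpectraMatrix:
        """View as a calibration matrix with one component as the reference."""
        return SpectraMatrix(
            self.grid,
            self.absorbance,
            self.components[component].to_numpy(),
            sample_ids=self.components.index.to_numpy(),
        )


def simulate_spectra(
    components: pd.DataFrame,
    config: MixtureSimConfig | None = None,
    seed: int | None = None,
) -> SimulatedSpectra:
    """Beer–Lambert mixture spectra for a component table.

    absorbance = (1 + scatter) * sum_i content_i * pure_i(nu)
                 + baseline + iid Gaussian noise
    """
    config = config or MixtureSimConfig()
    rng = _rng(seed, "spectra")
    grid = config.grid()
    names = [c for c in components.columns if c in config.bands]
    if not names:
        raise ValueError("component table shares no column with the band sets")
    for name in names:
        if not config.bands[name]:
            raise ValueError(f"empty band set for component {name!r}")
    pures = np.stack([_pure_spectrum(config.bands[n], grid) for n in names])
    signal = components[names].to_numpy() @ pures  # (n, p)
    n = signal.shape[0]
    scatter = rng.uniform(*config.scatter, size=(n, 1))
    offset = rng.uniform(*config.baseline_offset, size=(n, 1))
    slope = rng.uniform(*config.baseline_slope, size=(n, 1))
    t = (grid - grid[0]) / (grid[-1] - grid[0])
    baseline = offset + slope * t
    noise = rng.normal(0.0, config.noise_sd, size=signal.shape)
    return SimulatedSpectra(grid, (1.0 + scatter) * signal + baseline + noise, components)


@dataclass
class TensileSimConfig:
    """Single-fiber tensile test design: 3 gauge lengths x 15 replicates."""

    true_e: float = 1500.0  # MPa
    true_cs: float = 0.2  # mm/N
    gauge_lengths: tuple[float, ...] = (20.0, 30.0, 40.0)  # mm
    n_per_length: int = 15
    area_mean: float = 0.1  # mm^2
    area_sd: float = 0.02  # mm^2
    noise_sd: float = 0.01  # mm/N on dL/F

    def __post_init__(self):
        if self.true_e <= 0 or any(g <= 0 for g in self.gauge_lengths):
            raise ValueError("true_e and gauge lengths must be positive")


def simulate_tensile(
    config: TensileSimConfig | None = None, seed: int | None = None
) -> list[CompliancePoint]:
    """Compliance points consistent with dL/F = (L0/A)/E + Cs + noise."""
    config = config or TensileSimConfig()
    rng = _rng(seed, "tensile")
    points = []
    for l0 in config.gauge_lengths:
        for _ in range(config.n_per_length):
            area = 0.0
            while area < 1e-4:  # redraw non-physical (near-zero) areas
                area = rng.normal(config.area_mean, config.area_sd)
            x = l0 / area
            y = x / config.true_e + config.true_cs + rng.normal(0.0, config.noise_sd)
            points.append(CompliancePoint(x, y))
    return points


@dataclass
class GreySimConfig:
    """Exactly-consistent grey system with known coefficients."""

    n: int = 15
    a: float = 0.3
    b: tuple[float, ...] = (0.5, -0.3, 0.8)
    comparative_range: tuple[float, float] = (0.5, 2.0)
    reference_first: float = 1000.0  # scale of the raw reference series
    noise_sd: float = 0.0  # on the raw reference, relative to reference_first

    def __post_init__(self):
        if abs(1.0 + self.a / 2.0) < 1e-12:
            raise ValueError("1 + a/2 = 0: forward recursion undefined")
        if self.n < len(self.b) + 2:
            raise ValueError("n too small to identify the coefficients")


def simulate_grey_system(
    config: GreySimConfig | None = None,
    seed: int | None = None,
    comparatives: Sequence[Sequence[float]] | None = None,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Forward-generate (comparatives, reference) satisfying the grey equation.

    With Z1 the consecutive-pair mean of the reference AGO, each k >= 2 obeys
        X0(0)(k) = [sum_i b_i X_i(1)(k) − a X0(1)(k−1)] / (1 + a/2)
    exactly at zero noise. Gaussian noise (sd ``noise_sd * reference_first``)
    is then added to the raw reference at k >= 2.
    """
    config = config or GreySimConfig()
    rng = _rng(seed, "grey")
    m = len(config.b)
    if comparatives is None:
        comparatives = [
            rng.uniform(*config.comparative_range, size=config.n) for _ in range(m)
        ]
    comps = [np.asarray(c, dtype=float) for c in comparatives]
    if len(comps) != m or any(c.size != config.n for c in comps):
        raise ValueError("comparatives must match len(b) series of length n")
    comp_ago = np.column_stack([ago(initialize(c)) for c in comps])
    b = np.asarray(config.b, dtype=float)
    x0 = np.empty(config.n)
    x0[0] = 1.0
    cum = 1.0
    for k in range(1, config.n):
        x0[k] = (b @ comp_ago[k] - config.a * cum) / (1.0 + config.a / 2.0)
        cum += x0[k]
    reference = x0 * config.reference_first
    if config.noise_sd > 0:
        reference[1:] += rng.normal(
            0.0, config.noise_sd * config.reference_first, size=config.n - 1
        )
    return comps, reference
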