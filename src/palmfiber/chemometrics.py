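"""NIR calibration: spectral preprocessing, PLS regression, validation.

The calibration protocol predicts a component content (% by mass of
cellulose, hemicellulose or lignin) from an NIR absorbance spectrum on a
4,000–12,000 cm⁻¹ grid:

* preprocessing — any ordered combination of unit-vector normalization,
  Savitzky–Golay first derivative with respect to wavenumber, and SNV
  (standard normal variate: per-spectrum standardization);
* calibration — single-response PLS (NIPALS, mean-centred, unscaled
  predictors) with a chosen number of latent factors;
* assessment — RMSEC/Rc² on the training fit and RMSEP/Rcv² from
  leave-one-out cross-validation;
* external validation — absolute errors on held-out samples plus a paired
  two-tailed t-test of predicted vs measured (critical value 4.303 at
  α = 0.05 with df = 2, i.e. three validation samples).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from sklearn.cross_decomposition import PLSRegression

__all__ = [
    "T_CRITICAL_3",
    "Spectrum",
    "SpectraMatrix",
    "PreprocessStep",
    "PreprocessChain",
    "CalibrationStats",
    "ExternalValidation",
    "NIRCalibration",
    "NIRCalibrationResults",
    "vector_normalize",
    "sg_first_derivative",
    "snv",
    "fit_pls",
    "cross_validate",
    "select_factors",
    "external_validate",
    "paired_t_test",
]

#: Two-tailed critical value of Student's t at alpha = 0.05 with df = 2.
T_CRITICAL_3 = 4.303


@dataclass(frozen=True)
class Spectrum:
    """One absorbance spectrum on a strictly ascending wavenumber grid."""

    grid: np.ndarray  # cm^-1
    absorbance: np.ndarray  # AU

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=float)
        absorbance = np.asarray(self.absorbance, dtype=float)
        if grid.shape != absorbance.shape:
            raise ValueError("grid and absorbance must have the same length")
        if grid.size >= 2 and np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly ascending")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "absorbance", absorbance)


@dataclass
class SpectraMatrix:
    """n spectra on a shared grid plus per-sample reference contents (%)."""

    grid: np.ndarray  # (p,)
    absorbance: np.ndarray  # (n, p)
    reference: np.ndarray  # (n,)
    sample_ids: np.ndarray | None = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.reference = np.asarray(self.reference, dtype=float)
        n, p = self.absorbance.shape
        if self.grid.size != p or self.reference.size != n:
            raise ValueError("inconsistent shapes")
        if self.sample_ids is None:
            self.sample_ids = np.arange(1, n + 1)
        self.sample_ids = np.asarray(self.sample_ids)

    def subset(self, idx) -> "SpectraMatrix":
        return SpectraMatrix(
            self.grid, self.absorbance[idx], self.reference[idx], self.sample_ids[idx]
        )

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]


# ---------------------------------------------------------------------------
# preprocessing


def vector_normalize(absorbance: np.ndarray) -> np.ndarray:
    """Scale each spectrum (row) to unit Euclidean norm."""
    a = np.atleast_2d(np.asarray(absorbance, dtype=float))
    norms = np.linalg.norm(a, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("all-zero spectrum cannot be normalized")
    out = a / norms
    return out[0] if np.ndim(absorbance) == 1 else out


def sg_first_derivative(
    absorbance: np.ndarray, grid: np.ndarray, window: int = 15, polyorder: int = 2
) -> np.ndarray:
    """Savitzky–Golay first derivative with respect to the grid coordinate.

    Requires an odd ``window`` larger than ``polyorder`` and no longer than
    the spectrum, and a uniformly spaced grid.
    """
    grid = np.asarray(grid, dtype=float)
    a = np.asarray(absorbance, dtype=float)
    p = a.shape[-1]
    if window % 2 == 0 or window <= polyorder or window > p:
        raise ValueError(
            f"window must be odd, > polyorder and <= {p}; got window={window}, "
            f"polyorder={polyorder}"
        )
    steps = np.diff(grid)
    if not np.allclose(steps, steps[0]):
        raise ValueError("Savitzky–Golay derivative requires a uniform grid")
    return savgol_filter(
        a, window_length=window, polyorder=polyorder, deriv=1, delta=steps[0], axis=-1
    )


def snv(absorbance: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum mean 0, standard deviation 1."""
    a = np.atleast_2d(np.asarray(absorbance, dtype=float))
    sd = a.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant spectrum: SNV undefined")
    out = (a - a.mean(axis=1, keepdims=True)) / sd
    return out[0] if np.ndim(absorbance) == 1 else out


@dataclass(frozen=True)
class PreprocessStep:
    name: str  # vector_normalize | sg_first_derivative | snv
    params: dict = field(default_factory=dict)


class PreprocessChain:
    """Ordered preprocessing steps applied per spectrum (no cross-sample state)."""

    KNOWN = ("vector_normalize", "sg_first_derivative", "snv")

    def __init__(self, steps: Sequence[PreprocessStep | str] = ()):
        self.steps = [
            s if isinstance(s, PreprocessStep) else PreprocessStep(s) for s in steps
        ]
        for s in self.steps:
            if s.name not in self.KNOWN:
                raise ValueError(f"unknown preprocessing step {s.name!r}")

    @classmethod
    def default(cls) -> "PreprocessChain":
        """Normalization → first derivative → SNV, in that order."""
        return cls(
            [
                PreprocessStep("vector_normalize"),
                PreprocessStep("sg_first_derivative", {"window": 15, "polyorder": 2}),
                PreprocessStep("snv"),
            ]
        )

    def apply(self, absorbance: np.ndarray, grid: np.ndarray) -> np.ndarray:
        out = np.asarray(absorbance, dtype=float)
        for step in self.steps:
            if step.name == "vector_normalize":
                out = vector_normalize(out)
            elif step.name == "sg_first_derivative":
                out = sg_first_derivative(out, grid, **step.params)
            elif step.name == "snv":
                out = snv(out)
        return out

    def describe(self) -> list[dict]:
        return [{"step": s.name, **s.params} for s in self.steps]


# ---------------------------------------------------------------------------
# PLS calibration


@dataclass(frozen=True)
class CalibrationStats:
    """Calibration (RMSEC, Rc²) and cross-validation (RMSEP, Rcv²) figures."""

    rmsec: float
    r2c: float
    rmsep: float
    r2cv: float


class NIRCalibration:
    """PLS calibration model for one component content.

    Parameters
    ----------
    data
        Calibration spectra with the target component as ``reference``.
    chain
        Preprocessing chain (default: normalization → derivative → SNV).
    n_factors
        Number of PLS latent variables.
    """

    def __init__(
        self,
        data: SpectraMatrix,
        chain: PreprocessChain | None = None,
        n_factors: int = 5,
    ):
        if n_factors < 1:
            raise ValueError("n_factors must be >= 1")
        if data.n_samples < n_factors + 1:
            raise ValueError(
                f"{data.n_samples} samples cannot support {n_factors} factors"
            )
        self.data = data
        self.chain = chain if chain is not None else PreprocessChain.default()
        self.n_factors = n_factors

    def fit(self) -> "NIRCalibrationResults":
        X = self.chain.apply(self.data.absorbance, self.data.grid)
        y = self.data.reference
        pls = PLSRegression(n_components=self.n_factors, scale=False)
        pls.fit(X, y)
        return NIRCalibrationResults(self, pls)


class NIRCalibrationResults:
    """Fitted PLS calibration: predictions, statistics, external validation."""

    def __init__(self, model: NIRCalibration, pls: PLSRegression):
        self.model = model
        self._pls = pls
        fitted = self.predict_matrix(model.data)
        y = model.data.reference
        self.rmsec = float(np.sqrt(np.mean((fitted - y) ** 2)))
        self.r2c = _r2(y, fitted)

    @property
    def regression_vector(self) -> np.ndarray:
        return self._pls.coef_.ravel()

    def predict_matrix(self, data: SpectraMatrix) -> np.ndarray:
        X = self.model.chain.apply(data.absorbance, data.grid)
        return self._pls.predict(X).ravel()

    def summary(self) -> str:
        return (
            f"PLS calibration ({self.model.n_factors} factors, "
            f"{self.model.data.n_samples} samples)\n"
            f"  chain  {' -> '.join(s.name for s in self.model.chain.steps) or 'none'}\n"
            f"  RMSEC  {self.rmsec:.4g}\n"
            f"  Rc²    {self.r2c:.4f}"
        )


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination; can be negative, never clamped."""
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return 1.0 - ss_res / ss_tot


def fit_pls(
    data: SpectraMatrix, chain: PreprocessChain | None = None, n_factors: int = 5
) -> NIRCalibrationResults:
    """Functional shortcut for ``NIRCalibration(...).fit()``."""
    return NIRCalibration(data, chain, n_factors).fit()


def cross_validate(
    data: SpectraMatrix,
    chain: PreprocessChain | None = None,
    n_factors: int = 5,
    scheme: str = "loo",
    n_folds: int | None = None,
    seed: int | None = None,
) -> CalibrationStats:
    """RMSEC/Rc² from the full fit plus RMSEP/Rcv² from cross-validation.

    ``scheme`` is ``"loo"`` (leave-one-out, default) or ``"kfold"`` with
    ``n_folds`` and a ``seed`` controlling the shuffle. The whole pipeline —
    preprocessing and PLS centring included — is refit inside every fold.
    """
    full = fit_pls(data, chain, n_factors)
    n = data.n_samples
    if scheme == "loo":
        folds = [[i] for i in range(n)]
    elif scheme == "kfold":
        if n_folds is None or n_folds < 2 or n - n // n_folds < 2:
            raise ValueError("k-fold scheme needs 2 <= n_folds with >= 2 train samples")
        order = np.random.default_rng(seed).permutation(n)
        folds = [list(order[i::n_folds]) for i in range(n_folds)]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    preds = np.empty(n)
    for fold in folds:
        train = np.setdiff1d(np.arange(n), fold)
        res = fit_pls(data.subset(train), chain, n_factors)
        preds[fold] = res.predict_matrix(data.subset(fold))
    y = data.reference
    rmsep = float(np.sqrt(np.mean((preds - y) ** 2)))
    return CalibrationStats(full.rmsec, full.r2c, rmsep, _r2(y, preds))


def select_factors(
    data: SpectraMatrix, chain: PreprocessChain | None = None, max_factors: int = 10
) -> int:
    """Factor count minimizing cross-validated RMSEP; ties go to fewer factors.

    Ties are judged at a 1e-6 relative tolerance so float-level jitter on an
    already-exhausted fit never buys an extra latent variable.
    """
    if max_factors < 1:
        raise ValueError("max_factors must be >= 1")
    rmseps = [
        cross_validate(data, chain, k).rmsep for k in range(1, max_factors + 1)
    ]
    best = min(rmseps)
    for k, rmsep in enumerate(rmseps, start=1):
        if rmsep <= best * (1 + 1e-6) + 1e-12:
            return k
    return max_factors


# ---------------------------------------------------------------------------
# external validation


def paired_t_test(
    measured: Sequence[float], predicted: Sequence[float]
) -> tuple[float, int]:
    """|t| of the paired two-tailed t-test and its degrees of freedom.

    t = mean(d) / (sd(d)/sqrt(n)) with d = predicted − measured and the
    n−1-denominator sample standard deviation. A zero-spread, nonzero-mean
    difference yields t = inf.
    """
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.size != p.size or m.size < 2:
        raise ValueError("need >= 2 paired observations")
    d = p - m
    sd = d.std(ddof=1)
    if sd == 0:
        return (0.0 if d.mean() == 0 else math.inf), m.size - 1
    return abs(float(d.mean() / (sd / math.sqrt(d.size)))), m.size - 1


@dataclass
class ExternalValidation:
    """Per-sample errors plus the paired t-test verdict."""

    measured: np.ndarray
    predicted: np.ndarray
    abs_error: np.ndarray
    t_abs: float
    df: int
    t_critical: float
    significant: bool

    @classmethod
    def from_pairs(
        cls,
        measured: Sequence[float],
        predicted: Sequence[float],
        t_critical: float = T_CRITICAL_3,
    ) -> "ExternalValidation":
        m = np.asarray(measured, dtype=float)
        p = np.asarray(predicted, dtype=float)
        t_abs, df = paired_t_test(m, p)
        return cls(m, p, np.abs(m - p), t_abs, df, t_critical, t_abs > t_critical)

    def to_dict(self) -> dict:
        return {
            "measured": self.measured.tolist(),
            "predicted": self.predicted.tolist(),
            "abs_error": self.abs_error.tolist(),
            "t_abs": self.t_abs,
            "df": self.df,
            "t_critical": self.t_critical,
            "significant": self.significant,
        }


def external_validate(
    results: NIRCalibrationResults,
    validation: SpectraMatrix,
    t_critical: float = T_CRITICAL_3,
) -> ExternalValidation:
    """Predict held-out spectra and test predicted vs measured contents."""
    if validation.n_samples < 2:
        raise ValueError("external validation needs >= 2 samples")
    predicted = results.predict_matrix(validation)
    return ExternalValidation.from_pairs(
        validation.reference, predicted, t_critical=t_critical
    )
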