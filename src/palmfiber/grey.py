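"""Multivariate grey model GM(1,N): sequence operators, estimation, prediction.

Grey-system modelling relates a reference series X0 to m comparative (driver)
series X1..Xm observed at the same indices k = 1..n, with n small. The chain:

1. *Initialization*: every series is divided by its first element, so each
   starts at exactly 1 and all series are dimensionless,
       X(0)(k) = X(m)(k) / X(m)(1).
2. *AGO* (one-time accumulated generating operation): the running cumulative
   sum X(1)(k) = sum_{j<=k} X(0)(j), which smooths sample-to-sample noise.
3. *Mean-generating sequence* of the reference AGO,
       Z1(k) = 0.5 (X0(1)(k-1) + X0(1)(k)),   k = 2..n
   (consecutive-pair averages; defined from k = 2).
4. The grey difference equation
       X0(0)(k) = b1 X1(1)(k) + ... + bm Xm(1)(k) − a Z1(k)
   is solved for (a, b1..bm) by least squares over k = 2..n: response
   Y = X0(0)(k), design rows (−Z1(k), X1(1)(k), ..., Xm(1)(k)).

``a`` is the development coefficient; each ``b_i`` is the grey action
quantity of driver i — positive values mark promoters of the reference
series, negative values inhibitors.

:class:`GreyModel` / :class:`GreyResults` wrap the chain statsmodels-style;
the individual operators are exposed for direct use and for reproducing
printed intermediate tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GreyCoefficients",
    "GreyModel",
    "GreyResults",
    "RankError",
    "initialize",
    "ago",
    "inverse_ago",
    "mean_sequence",
    "build_design",
    "estimate",
    "predict",
    "error_analysis",
]


class RankError(np.linalg.LinAlgError):
    """Design matrix is rank-deficient or under-determined."""


def initialize(values: Sequence[float]) -> np.ndarray:
    """Divide a series by its first element (first element becomes exactly 1)."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("series must be a non-empty 1-D sequence")
    if v[0] == 0:
        raise ValueError("first element is zero; initialization undefined")
    out = v / v[0]
    out[0] = 1.0
    return out


def ago(values: Sequence[float]) -> np.ndarray:
    """One-time accumulated generating operation (running cumulative sum)."""
    return np.cumsum(np.asarray(values, dtype=float))


def inverse_ago(values: Sequence[float]) -> np.ndarray:
    """First-difference inverse of :func:`ago`; exact round trip."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return v.copy()
    return np.concatenate(([v[0]], np.diff(v)))


def mean_sequence(ago_values: Sequence[float]) -> np.ndarray:
    """Consecutive-pair means Z1(k) = 0.5 (X(1)(k-1) + X(1)(k)), k = 2..n."""
    v = np.asarray(ago_values, dtype=float)
    if v.size < 2:
        raise ValueError("mean-generating sequence needs at least 2 AGO values")
    return 0.5 * (v[1:] + v[:-1])


@dataclass(frozen=True)
class GreyCoefficients:
    """Development coefficient ``a`` and grey action quantities ``b``."""

    a: float
    b: np.ndarray

    def signs(self) -> list[str]:
        """Classify each driver as 'promoter' (b_i > 0) or 'inhibitor'."""
        return ["promoter" if bi > 0 else "inhibitor" for bi in self.b]


def build_design(
    reference: Sequence[float], comparatives: Sequence[Sequence[float]]
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix B and response Y of the grey difference equation.

    Rows cover k = 2..n. The first column is −Z1(k) so the solved vector is
    (a, b1..bm) with the conventional signs; remaining columns are the AGO
    values of each comparative series at k.
    """
    ref0 = initialize(reference)
    n = ref0.size
    comps = [initialize(c) for c in comparatives]
    if any(c.size != n for c in comps):
        raise ValueError("all series must have the same length")
    n_params = 1 + len(comps)
    if n - 1 < n_params:
        raise RankError(
            f"{n - 1} equations cannot identify {n_params} parameters"
        )
    z = mean_sequence(ago(ref0))
    cols = [-z] + [ago(c)[1:] for c in comps]
    return np.column_stack(cols), ref0[1:]


def estimate(design: np.ndarray, response: np.ndarray) -> GreyCoefficients:
    """Least-squares solution of B θ = Y with θ = (a, b1..bm).

    Solved by a numerically stable least-squares routine; equivalent to the
    normal-equations formula (BᵀB)⁻¹BᵀY on well-conditioned designs.
    """
    design = np.asarray(design, dtype=float)
    response = np.asarray(response, dtype=float)
    if design.shape[0] < design.shape[1]:
        raise RankError("under-determined system")
    theta, _, rank, sv = np.linalg.lstsq(design, response, rcond=None)
    if rank < design.shape[1]:
        cond = sv[0] / sv[-1] if sv[-1] > 0 else np.inf
        raise RankError(f"rank-deficient design (rank {rank}, cond {cond:.3g})")
    return GreyCoefficients(a=float(theta[0]), b=theta[1:])


def predict(
    coeffs: GreyCoefficients, ago_values: Sequence[float], z: float
) -> float:
    """One-step value of the grey equation: Σ b_i X_i(1)(k) − a Z1(k)."""
    ago_values = np.asarray(ago_values, dtype=float)
    if ago_values.size != coeffs.b.size:
        raise ValueError(
            f"{ago_values.size} AGO values for {coeffs.b.size} coefficients"
        )
    return float(coeffs.b @ ago_values - coeffs.a * z)


def error_analysis(
    coeffs: GreyCoefficients,
    comparative_ago: np.ndarray,
    z: Sequence[float],
    actual: Sequence[float],
) -> pd.DataFrame:
    """Per-k predicted vs actual values and relative errors.

    Parameters
    ----------
    comparative_ago
        Array of shape (n-1, m): AGO values of each comparative series at
        k = 2..n (these may come from printed tables or be recomputed).
    z
        Mean-generating values at k = 2..n.
    actual
        Initialized reference values at k = 2..n.

    Returns a frame indexed by k with columns predicted, actual,
    relative_error; the arithmetic mean of the relative errors is stored in
    ``df.attrs["average_relative_error"]``.
    """
    comparative_ago = np.atleast_2d(np.asarray(comparative_ago, dtype=float))
    z = np.asarray(z, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if np.any(actual == 0):
        raise ZeroDivisionError("actual value is zero; relative error undefined")
    pred = comparative_ago @ coeffs.b - coeffs.a * z
    rel = np.abs(pred - actual) / np.abs(actual)
    df = pd.DataFrame(
        {"predicted": pred, "actual": actual, "relative_error": rel},
        index=pd.RangeIndex(2, 2 + len(z), name="k"),
    )
    df.attrs["average_relative_error"] = float(rel.mean())
    return df


class GreyModel:
    """GM(1,N) model of a reference series driven by comparative series.

    Parameters
    ----------
    reference
        The dependent series (e.g. per-sample Young's modulus), k = 1..n.
    comparatives
        The driver series (e.g. cellulose, hemicellulose, lignin contents),
        each of length n.
    labels
        Optional names for the comparative series.
    """

    def __init__(
        self,
        reference: Sequence[float],
        comparatives: Sequence[Sequence[float]],
        labels: Sequence[str] | None = None,
    ):
        self.reference = np.asarray(reference, dtype=float)
        self.comparatives = [np.asarray(c, dtype=float) for c in comparatives]
        if labels is None:
            labels = [f"x{i + 1}" for i in range(len(self.comparatives))]
        if len(labels) != len(self.comparatives):
            raise ValueError("one label per comparative series")
        self.labels = list(labels)
        # Validates lengths/identifiability eagerly.
        self._design, self._response = build_design(self.reference, self.comparatives)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, reference: str, comparatives: Sequence[str]
    ) -> "GreyModel":
        return cls(
            df[reference].to_numpy(),
            [df[c].to_numpy() for c in comparatives],
            labels=list(comparatives),
        )

    def fit(self) -> "GreyResults":
        coeffs = estimate(self._design, self._response)
        return GreyResults(self, coeffs)


class GreyResults:
    """Fitted GM(1,N): coefficients, per-k errors, and a summary table."""

    def __init__(self, model: GreyModel, coeffs: GreyCoefficients):
        self.model = model
        self.coeffs = coeffs
        ago_cols = np.column_stack(
            [ago(initialize(c))[1:] for c in model.comparatives]
        )
        z = mean_sequence(ago(initialize(model.reference)))
        self.report = error_analysis(coeffs, ago_cols, z, model._response)

    @property
    def a(self) -> float:
        return self.coeffs.a

    @property
    def b(self) -> np.ndarray:
        return self.coeffs.b

    @property
    def average_relative_error(self) -> float:
        return self.report.attrs["average_relative_error"]

    def predicted_reference(self) -> np.ndarray:
        """Fitted reference values back on the original scale (k = 2..n)."""
        return self.report["predicted"].to_numpy() * self.model.reference[0]

    def summary(self) -> str:
        lines = [
            f"GM(1,{1 + len(self.model.comparatives)}) fit over n = "
            f"{self.model.reference.size} observations",
            f"  development coefficient a  {self.a: .4f}",
        ]
        for label, bi, sign in zip(self.model.labels, self.b, self.coeffs.signs()):
            lines.append(f"  b[{label}]  {bi: .4f}  ({sign})")
        lines.append(
            f"  average relative error     {self.average_relative_error:.4f}"
        )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": dict(zip(self.model.labels, map(float, self.b))),
            "signs": dict(zip(self.model.labels, self.coeffs.signs())),
            "average_relative_error": self.average_relative_error,
        }
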