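"""Cubic B-spline bases with second-difference roughness penalties.

Shared machinery for the penalized-spline relative-hazard model and the
penalized-spline granule-onset (binomial) model: basis construction with
interior knots at covariate quantiles, the P-spline difference penalty on
the coefficients, and effective degrees of freedom for AIC smoothing
selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineBasis", "second_difference_penalty", "default_lambda_grid"]

DEGREE = 3


def second_difference_penalty(n_coef: int) -> np.ndarray:
    """Penalty matrix D'D for second-order differences of the coefficients."""
    if n_coef < 3:
        raise ValueError("need at least 3 coefficients for a 2nd-order penalty")
    D = np.diff(np.eye(n_coef), n=2, axis=0)
    return D.T @ D


def default_lambda_grid(n: int = 30, lo: float = 1e-3, hi: float = 1e5) -> np.ndarray:
    return np.geomspace(lo, hi, n)


@dataclass
class SplineBasis:
    """Clamped cubic B-spline basis over a covariate's observed range."""

    knots: np.ndarray  # full knot vector, clamped
    x_min: float
    x_max: float

    @classmethod
    def from_data(cls, x: np.ndarray, n_interior: int = 8) -> "SplineBasis":
        x = np.asarray(x, dtype=float)
        if np.ptp(x) == 0:
            raise ValueError("no variation: covariate is constant")
        x_min, x_max = float(x.min()), float(x.max())
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, qs)
        # de-duplicate coincident quantiles (discrete covariates)
        interior = np.unique(
            np.clip(interior, x_min + 1e-12, x_max - 1e-12)
        )
        knots = np.concatenate(
            [[x_min] * (DEGREE + 1), interior, [x_max] * (DEGREE + 1)]
        )
        return cls(knots=knots, x_min=x_min, x_max=x_max)

    @property
    def n_basis(self) -> int:
        return len(self.knots) - DEGREE - 1

    def design_matrix(self, x: np.ndarray) -> np.ndarray:
        """Full basis matrix; rows sum to one inside the data range."""
        x = np.clip(np.asarray(x, dtype=float), self.x_min, self.x_max)
        return BSpline.design_matrix(x, self.knots, DEGREE).toarray()

    def reduced_design(self, x: np.ndarray) -> np.ndarray:
        """Basis with the last column dropped.

        Because the full basis rows sum to one, the full design is confounded
        with any intercept (and with the baseline hazard in a Cox model).
        Pinning the last coefficient to zero removes that null direction; the
        fitted curve is identified up to an additive constant, which callers
        re-centre for reporting.
        """
        return self.design_matrix(x)[:, :-1]

    def reduced_penalty(self) -> np.ndarray:
        P = second_difference_penalty(self.n_basis)
        return P[:-1, :-1]
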