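"""Closed-form expectation of the crude change-score regression slope.

For standardized variables, the expected regression coefficient of the
difference Y2 - Y1 on X1 is

    E(beta_{X1, Y2-Y1}) = (r_{X1,Y2} - r_{X1,Y1}) / (2 (1 - r_{Y1,Y2}))

so the coefficient is negative exactly when the concurrent correlation
r_{X1,Y1} exceeds the cross-lagged correlation r_{X1,Y2} — the mechanism
by which imperfect reliability and shared occasion states produce
artifactual "decreasing" effects in difference-score analyses.  The
denominator ``2 (1 - r_{Y1,Y2})`` is the variance of the change score for
standardized repeated measures, so the expectation lives on that scale;
rescaling to other standardizations multiplies it by a positive factor
and leaves the sign unchanged.  The artifact grows (more negative) as the
retest correlation r_{Y1,Y2} rises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class CorrelationTriple:
    """The three correlations entering the expectation."""

    r_x1y2: float
    r_x1y1: float
    r_y1y2: float

    def __post_init__(self) -> None:
        for name in ("r_x1y2", "r_x1y1", "r_y1y2"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} is not a correlation")

    def correlation_matrix(self, r_x1_completion: float | None = None) -> np.ndarray:
        """3x3 correlation matrix of (X1, Y1, Y2).

        All three pairwise entries are fixed by the triple itself, so the
        matrix is fully determined; the optional argument is accepted for
        symmetry with partially specified uses and must be None.
        """
        if r_x1_completion is not None:
            raise ValueError("the (X1, Y1, Y2) correlation matrix has no free entry")
        return np.array([
            [1.0, self.r_x1y1, self.r_x1y2],
            [self.r_x1y1, 1.0, self.r_y1y2],
            [self.r_x1y2, self.r_y1y2, 1.0]])

    def is_psd(self, tol: float = 1e-10) -> bool:
        return bool(np.linalg.eigvalsh(self.correlation_matrix()).min() >= -tol)


def expected_change_beta(triple: CorrelationTriple) -> float:
    """Expected slope of (Y2 - Y1) on X1 for standardized variables."""
    if triple.r_y1y2 >= 1.0:
        raise ValueError("r_y1y2 = 1 makes the difference score degenerate "
                         "(zero variance); the expectation is undefined")
    return (triple.r_x1y2 - triple.r_x1y1) / (2.0 * (1.0 - triple.r_y1y2))


def simulate_change_beta(triple: CorrelationTriple, n: int = 1_000_000,
                         seed: int = 0) -> float:
    """Brute-force oracle for the closed form, from trivariate-normal draws.

    The expectation equals ``cov(X1, Y2 - Y1) / var(Y2 - Y1)`` for
    standardized X1, Y1, Y2 — the OLS coefficient pairing X1 with the
    change score on the change-score-variance scale (for standardized
    scores, ``var(Y2 - Y1) = 2 (1 - r_{Y1,Y2})``).  Any other scaling of
    the crude change regression differs only by a positive factor, so the
    sign law is shared by all of them.
    """
    R = triple.correlation_matrix()
    if not triple.is_psd():
        raise ValueError("correlation triple is not positive semidefinite")
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal(np.zeros(3), R, size=n, method="svd")
    x1, y1, y2 = z[:, 0], z[:, 1], z[:, 2]
    d = y2 - y1
    return float(np.cov(x1, d, ddof=1)[0, 1] / np.var(d, ddof=1))
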