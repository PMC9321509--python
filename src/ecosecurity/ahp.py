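"""Analytic Hierarchy Process: weights and Saaty consistency diagnostics.

A pairwise comparison matrix A holds judgements a_ij on Saaty's 1-9 scale
with a_ji = 1/a_ij.  Criterion weights are the normalized principal
eigenvector of A; judgement coherence is measured by

    CI = (lambda_max - n) / (n - 1),      CR = CI / RI(n)

where RI(n) is the random consistency index for matrix order n.  A weight
vector is considered sensible when CR < 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np

__all__ = [
    "PairwiseMatrix",
    "AhpResult",
    "ri_lookup",
    "principal_eigen",
    "consistency",
    "parse_matrix",
]

#: Saaty's random consistency index for orders 1..10
RANDOM_INDEX = (0.0, 0.0, 0.58, 0.90, 1.12, 1.24, 1.32, 1.41, 1.45, 1.49)

RECIPROCAL_RTOL = 1e-6


@dataclass(frozen=True)
class PairwiseMatrix:
    """A positive reciprocal comparison matrix (order 1-10)."""

    entries: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", a)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("comparison matrix must be square")
        if not np.all(a > 0):
            raise ValueError("comparison matrix entries must be positive")
        if not np.allclose(np.diag(a), 1.0, rtol=RECIPROCAL_RTOL):
            raise ValueError("diagonal entries must all be 1")
        if not np.allclose(a * a.T, 1.0, rtol=RECIPROCAL_RTOL):
            raise ValueError("matrix is not reciprocal (a_ji != 1/a_ij)")

    @property
    def n(self) -> int:
        return self.entries.shape[0]

    @classmethod
    def from_weights(cls, weights) -> "PairwiseMatrix":
        """The perfectly consistent matrix with entries w_i / w_j."""
        w = np.asarray(weights, dtype=float)
        return cls(np.outer(w, 1.0 / w))


@dataclass(frozen=True)
class AhpResult:
    lambda_max: float
    weights: np.ndarray
    ci: float
    cr: float

    @property
    def consistent(self) -> bool:
        return self.cr < 0.1


def ri_lookup(n: int) -> float:
    """Random consistency index RI for matrix order n in 1..10."""
    if not 1 <= n <= 10:
        raise ValueError(f"RI is tabulated for orders 1-10, got {n}")
    return RANDOM_INDEX[n - 1]


def principal_eigen(
    matrix: PairwiseMatrix,
    rtol: float = 1e-10,
    max_iter: int = 10_000,
) -> tuple[float, np.ndarray]:
    """Dominant eigenvalue and normalized principal eigenvector.

    Power iteration from the uniform vector; for a positive matrix the
    Perron root is simple, so the iteration converges deterministically.
    """
    a = matrix.entries
    n = matrix.n
    w = np.full(n, 1.0 / n)
    lam = float(n)
    for _ in range(max_iter):
        y = a @ w
        lam_new = float(y.sum())
        y /= lam_new
        if np.allclose(y, w, rtol=rtol, atol=rtol) and abs(lam_new - lam) <= rtol * lam:
            w, lam = y, lam_new
            break
        w, lam = y, lam_new
    # Rayleigh-style estimate: with w normalized to sum 1, sum(Aw) -> lambda
    lam = float((a @ w).sum() / w.sum())
    return lam, w / w.sum()


def consistency(matrix: PairwiseMatrix) -> AhpResult:
    """Full AHP diagnostics: lambda_max, weights, CI, CR.

    CI is defined as 0 for orders 1 and 2 (any reciprocal 2x2 is perfectly
    consistent), and CR is 0 whenever RI(n) = 0.
    """
    n = matrix.n
    ri = ri_lookup(n)
    lam, w = principal_eigen(matrix)
    ci = 0.0 if n <= 2 else (lam - n) / (n - 1)
    cr = 0.0 if ri == 0 else ci / ri
    return AhpResult(lambda_max=lam, weights=w, ci=ci, cr=cr)


def parse_matrix(text: str | Path) -> PairwiseMatrix:
    """Parse a matrix from text: n rows of n entries, fractions accepted.

    Entries like ``1/6`` are parsed as exact rationals before conversion so
    the reciprocal invariant holds to machine precision.
    """
    if isinstance(text, Path):
        text = text.read_text()
    rows = []
    for line in text.strip().splitlines():
        tokens = line.split()
        if not tokens or tokens[0].startswith("#"):
            continue
        rows.append([float(Fraction(t)) for t in tokens])
    if not rows:
        raise ValueError("empty matrix text")
    return PairwiseMatrix(np.array(rows))


def geometric_mean_weights(matrix: PairwiseMatrix) -> np.ndarray:
    """Row-geometric-mean weights (diagnostic alternative to the eigenvector)."""
    g = np.exp(np.log(matrix.entries).mean(axis=1))
    return g / g.sum()
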