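"""The kinship transformation K* = wK + alpha*11' + beta*I and its diagnostics.

``w`` rescales the matrix (and with it the genetic variance it implies),
``alpha`` re-bases every element and ``beta`` re-bases the diagonal only.
The same transformation is applied to K or to K⁻¹; it is a probe of how the
element distribution drives the heritability estimate and the spread of
breeding values, not a tuning device.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .relmat import RelationshipMatrix

__all__ = [
    "TransformSpec",
    "SQSDecomposition",
    "ConditionReport",
    "transform_matrix",
    "sqs_decompose",
    "condition_report",
    "paper_grid",
]


@dataclass(frozen=True)
class TransformSpec:
    """Coefficients of ``w*K + alpha*11' + beta*I``."""

    w: float = 1.0
    alpha: float = 0.0
    beta: float = 0.0

    def __post_init__(self):
        if self.w <= 0:
            raise ValueError("scale factor w must be positive")

    @property
    def is_identity(self) -> bool:
        return self.w == 1.0 and self.alpha == 0.0 and self.beta == 0.0


@dataclass
class SQSDecomposition:
    """K = S Q S with S = diag(sqrt(diag(K))) and Q the correlation matrix."""

    S: np.ndarray
    Q: np.ndarray

    def reassemble(self) -> np.ndarray:
        return self.S[:, None] * self.Q * self.S[None, :]


@dataclass
class ConditionReport:
    """Numerical-condition diagnostics of a symmetric matrix.

    Eigenvalue extremes are the direct indicators; a failed Cholesky
    factorization flags loss of positive definiteness.
    """

    smallest_eigenvalue: float
    largest_eigenvalue: float
    condition_number: float
    positive_definite: bool


def transform_matrix(K: RelationshipMatrix, spec: TransformSpec) -> RelationshipMatrix:
    """Return ``w*K + alpha*11' + beta*I`` as a new matrix of kind 'custom'.

    The input is never mutated and the kind tag is reset so downstream code
    cannot assume pedigree/genomic semantics for a transformed matrix.
    """
    n = len(K)
    out = spec.w * K.values + spec.alpha
    out[np.diag_indices(n)] += spec.beta
    return RelationshipMatrix(list(K.ids), out, kind="custom")


def sqs_decompose(K: RelationshipMatrix) -> SQSDecomposition:
    """Split K into standard deviations S and correlations Q (K = SQS)."""
    v = np.diag(K.values)
    if np.any(v <= 0):
        raise ValueError("SQS decomposition requires a strictly positive diagonal")
    S = np.sqrt(v)
    Q = K.values / np.outer(S, S)
    np.fill_diagonal(Q, 1.0)
    return SQSDecomposition(S=S, Q=Q)


def condition_report(K: RelationshipMatrix) -> ConditionReport:
    """Eigenvalue extremes, condition number and a PD flag; never raises."""
    eig = scipy.linalg.eigh(K.values, eigvals_only=True)
    lo, hi = float(eig[0]), float(eig[-1])
    cond = np.inf if lo <= 0 else hi / lo
    try:
        scipy.linalg.cho_factor(K.values)
        pd = True
    except (np.linalg.LinAlgError, ValueError):
        pd = False
    return ConditionReport(
        smallest_eigenvalue=lo,
        largest_eigenvalue=hi,
        condition_number=cond,
        positive_definite=pd,
    )


def paper_grid(kind: str = "G") -> list[TransformSpec]:
    """The w/alpha/beta study grid: w in {0.9, 1, 1.1}, alpha, beta in {-0.05, 0, 0.05}.

    For a pedigree matrix (kind 'A' or 'A_inv') two regions are excluded:
    alpha = -0.05 (negative off-diagonals) and (alpha = 0, beta = -0.05)
    (diagonals below 1).
    """
    ws = (0.9, 1.0, 1.1)
    shifts = (-0.05, 0.0, 0.05)
    specs = []
    pedigree_like = kind.startswith("A")
    for w, a, b in itertools.product(ws, shifts, shifts):
        if pedigree_like and a == -0.05:
            continue
        if pedigree_like and a == 0.0 and b == -0.05:
            continue
        specs.append(TransformSpec(w, a, b))
    return specs
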