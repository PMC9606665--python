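"""Distributional diagnostics of relationship matrices and EBV comparisons.

Off-diagonal statistics count each unordered pair once (upper triangle) and
standard deviations are sample sds (ddof = 1).  ``D = mu(diag) - mu(offdiag)``
is the distribution parameter that governs the base-population genetic
variance implied by a relationship matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import EbvResult, PhenotypeTable
from .relmat import AlignmentError, RelationshipMatrix

__all__ = [
    "ElementSummary",
    "EbvComparison",
    "element_summary",
    "ebv_compare",
    "discard_extreme_rows",
]


@dataclass
class ElementSummary:
    """Moments and extremes of the diagonal and off-diagonal elements."""

    mu_diag: float
    sd_diag: float
    min_diag: float
    max_diag: float
    mu_offdiag: float
    sd_offdiag: float
    min_offdiag: float
    max_offdiag: float
    D: float
    band: tuple[float, float]
    band_fraction: float


@dataclass
class EbvComparison:
    """Pearson correlation and slope of comparison EBVs regressed on reference."""

    pearson_r: float
    slope: float
    mean_reference: float
    sd_reference: float
    mean_comparison: float
    sd_comparison: float


def _offdiag(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if x.size > 1 else 0.0


def element_summary(
    K: RelationshipMatrix | np.ndarray, band: tuple[float, float] = (-0.02, 0.02)
) -> ElementSummary:
    """Summarize diag and offdiag element distributions of a square matrix.

    ``band_fraction`` is the share of off-diagonal elements strictly inside
    the open interval ``band`` (default (−0.02, 0.02), the concentration
    band used for inverse matrices).
    """
    values = K.values if isinstance(K, RelationshipMatrix) else np.asarray(K)
    diag = np.diag(values)
    off = _offdiag(values)
    lo, hi = band
    frac = float(np.mean((off > lo) & (off < hi))) if off.size else 1.0
    return ElementSummary(
        mu_diag=float(diag.mean()),
        sd_diag=_sd(diag),
        min_diag=float(diag.min()),
        max_diag=float(diag.max()),
        mu_offdiag=float(off.mean()) if off.size else 0.0,
        sd_offdiag=_sd(off),
        min_offdiag=float(off.min()) if off.size else 0.0,
        max_offdiag=float(off.max()) if off.size else 0.0,
        D=float(diag.mean()) - (float(off.mean()) if off.size else 0.0),
        band=(lo, hi),
        band_fraction=frac,
    )


def ebv_compare(reference: EbvResult, comparison: EbvResult) -> EbvComparison:
    """Correlation and regression of comparison EBVs on reference EBVs.

    The slope is of the comparison set regressed on the reference set:
    slope > 1 means the comparison EBVs are more dispersed (inflated)
    relative to the reference.
    """
    if list(reference.ids) != list(comparison.ids):
        raise AlignmentError("EBV sets must cover the same ids in the same order")
    x = np.asarray(reference.ebv, dtype=float)
    y = np.asarray(comparison.ebv, dtype=float)
    sx, sy = _sd(x), _sd(y)
    if sx == 0 or sy == 0:
        raise ValueError("EBV comparison undefined: a set has zero variance")
    cov = float(np.cov(x, y, ddof=1)[0, 1])
    return EbvComparison(
        pearson_r=cov / (sx * sy),
        slope=cov / (sx * sx),
        mean_reference=float(x.mean()),
        sd_reference=sx,
        mean_comparison=float(y.mean()),
        sd_comparison=sy,
    )


def discard_extreme_rows(
    K_inv: RelationshipMatrix,
    phen: PhenotypeTable,
    diag_gt: float | None = None,
    offdiag_lt: float | None = None,
) -> tuple[RelationshipMatrix, PhenotypeTable, list[str]]:
    """Drop rows/columns with extreme elements, and their phenotypes.

    A row/column is removed when its diagonal exceeds ``diag_gt`` or when it
    participates in any off-diagonal element below ``offdiag_lt``.  Both
    criteria are evaluated in one pass on the original matrix.  Returns the
    reduced matrix, reduced phenotypes and the list of removed ids.
    """
    values = K_inv.values
    n = len(K_inv)
    drop = np.zeros(n, dtype=bool)
    if diag_gt is not None:
        drop |= np.diag(values) > diag_gt
    if offdiag_lt is not None:
        off = values.copy()
        np.fill_diagonal(off, np.inf)
        drop |= (off < offdiag_lt).any(axis=1)
    if drop.all():
        raise ValueError("extreme-element thresholds would remove every row")
    removed = [K_inv.ids[i] for i in np.nonzero(drop)[0]]
    keep_ids = [K_inv.ids[i] for i in np.nonzero(~drop)[0]]
    reduced = K_inv.submatrix(keep_ids)
    removed_set = set(removed)
    mask = [i not in removed_set for i in phen.ids]
    reduced_phen = PhenotypeTable(
        ids=[i for i, m in zip(phen.ids, mask) if m],
        y=phen.y[np.asarray(mask, dtype=bool)],
    )
    return reduced, reduced_phen, removed
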