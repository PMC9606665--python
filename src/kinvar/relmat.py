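"""Pedigree, genomic and hybrid relationship matrices and their inverses.

The numerator relationship matrix **A** is built by the tabular method from
an ordered pedigree, and its inverse directly by Henderson's rules with
Mendelian-sampling variances that account for parental inbreeding.  The
genomic matrix **G** follows VanRaden's first method,
``G = WW' / (2 * sum p_l (1 - p_l))`` with ``W`` the column-centred marker
coding, optionally blended with the pedigree matrix for invertibility.  The
single-step hybrid inverse ``H^-1`` is assembled as ``A^-1`` plus the
genotyped-block correction ``G^-1 - A22^-1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.linalg

__all__ = [
    "Pedigree",
    "GenotypeMatrix",
    "RelationshipMatrix",
    "PedigreeError",
    "SingularMatrixError",
    "AlignmentError",
    "compute_inbreeding",
    "build_A",
    "build_A_inverse",
    "build_G_vanraden1",
    "blend_G_A",
    "build_H_inverse",
    "invert_matrix",
]

UNKNOWN = -1  # internal index code for an unknown parent


class PedigreeError(ValueError):
    """Structurally invalid pedigree (duplicate ids, bad ordering, cycles)."""


class SingularMatrixError(np.linalg.LinAlgError):
    """Matrix is singular or not positive definite where PD is required."""

    def __init__(self, msg: str, smallest_eigenvalue: float | None = None):
        super().__init__(msg)
        self.smallest_eigenvalue = smallest_eigenvalue


class AlignmentError(KeyError):
    """Identifier sets of two objects do not match as required."""


def _as_str_ids(ids: Iterable) -> list[str]:
    return [str(i) for i in ids]


@dataclass(frozen=True)
class Pedigree:
    """Topologically ordered pedigree: parents appear before offspring.

    ``sire_idx``/``dam_idx`` hold positions into ``ids`` (−1 = unknown).
    """

    ids: tuple[str, ...]
    sire_idx: np.ndarray
    dam_idx: np.ndarray

    def __post_init__(self):
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise PedigreeError("duplicate individual ids in pedigree")
        for name, arr in (("sire", self.sire_idx), ("dam", self.dam_idx)):
            if arr.shape != (n,):
                raise PedigreeError(f"{name} index has wrong length")
            bad = (arr >= np.arange(n)) & (arr != UNKNOWN)
            if bad.any():
                k = int(np.nonzero(bad)[0][0])
                raise PedigreeError(
                    f"{name} of individual {self.ids[k]!r} does not precede it: "
                    "pedigree must list parents before offspring"
                )

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_records(
        cls, records: Sequence[tuple[object, object, object]]
    ) -> "Pedigree":
        """Build from (id, sire, dam) triplets; 0, '', '0' or None = unknown."""
        ids = _as_str_ids(r[0] for r in records)
        pos = {i: k for k, i in enumerate(ids)}
        if len(pos) != len(ids):
            raise PedigreeError("duplicate individual ids in pedigree")

        def parent(x) -> int:
            if x is None or str(x) in ("", "0", "nan", "NA"):
                return UNKNOWN
            key = str(x)
            if key not in pos:
                raise PedigreeError(f"parent {key!r} never appears as an individual")
            return pos[key]

        sire = np.array([parent(r[1]) for r in records], dtype=np.int64)
        dam = np.array([parent(r[2]) for r in records], dtype=np.int64)
        return cls(tuple(ids), sire, dam)

    def records(self) -> list[tuple[str, str, str]]:
        """Return (id, sire, dam) triplets with '0' for unknown parents."""
        out = []
        for k, i in enumerate(self.ids):
            s = "0" if self.sire_idx[k] == UNKNOWN else self.ids[self.sire_idx[k]]
            d = "0" if self.dam_idx[k] == UNKNOWN else self.ids[self.dam_idx[k]]
            out.append((i, s, d))
        return out


@dataclass
class GenotypeMatrix:
    """Individuals × markers allele-dosage matrix with allele frequencies.

    ``coding`` is ``"dosage"`` for the usual 0/1/2 count of the reference
    allele, or ``"binary"`` for fully inbred 0/1 lines (mapped to −1/+1 in
    the centred coding).  ``allele_freqs`` defaults to the observed
    frequencies of the dosages; pass an array to override with base-population
    frequencies.
    """

    ids: list[str]
    markers: list[str]
    dosages: np.ndarray
    coding: str = "dosage"
    allele_freqs: np.ndarray | None = None

    def __post_init__(self):
        self.ids = _as_str_ids(self.ids)
        self.dosages = np.asarray(self.dosages)
        n, m = self.dosages.shape
        if n != len(self.ids) or m != len(self.markers):
            raise ValueError("dosage matrix shape does not match ids/markers")
        hi = 1 if self.coding == "binary" else 2
        if self.dosages.min(initial=0) < 0 or self.dosages.max(initial=0) > hi:
            raise ValueError(f"dosages outside 0..{hi} for coding {self.coding!r}")
        if self.allele_freqs is None:
            denom = 1.0 if self.coding == "binary" else 2.0
            self.allele_freqs = self.dosages.mean(axis=0) / denom
        else:
            self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
            if self.allele_freqs.shape != (m,):
                raise ValueError("allele_freqs length does not match markers")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def filter_maf(self, threshold: float = 0.02) -> "GenotypeMatrix":
        """Drop markers with minor allele frequency below ``threshold``."""
        p = self.allele_freqs
        keep = np.minimum(p, 1 - p) >= threshold
        return GenotypeMatrix(
            ids=self.ids,
            markers=[m for m, k in zip(self.markers, keep) if k],
            dosages=self.dosages[:, keep],
            coding=self.coding,
            allele_freqs=p[keep],
        )

    def centered_coding(self) -> np.ndarray:
        """Column-centred marker matrix W with entries M_il − 2 p_l + 1.

        M is the symmetric −1/0/+1 genotype code: dosage 0/1/2 maps to
        −1/0/+1 and binary 0/1 maps to −1/+1.
        """
        if self.coding == "binary":
            M = 2.0 * self.dosages - 1.0
        else:
            M = self.dosages - 1.0
        return M - (2.0 * self.allele_freqs - 1.0)

    def subset(self, ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {i: k for k, i in enumerate(self.ids)}
        try:
            idx = [pos[str(i)] for i in ids]
        except KeyError as e:
            raise AlignmentError(f"id {e.args[0]!r} not genotyped") from None
        return GenotypeMatrix(
            ids=list(ids),
            markers=self.markers,
            dosages=self.dosages[idx],
            coding=self.coding,
            allele_freqs=self.allele_freqs,
        )


@dataclass
class RelationshipMatrix:
    """Dense symmetric relationship matrix (or inverse) with an id index."""

    ids: list[str]
    values: np.ndarray
    kind: str = "custom"

    _KINDS = {"A", "G", "H", "A_inv", "G_inv", "H_inv", "custom"}

    def __post_init__(self):
        self.ids = _as_str_ids(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match number of ids")
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("matrix is not symmetric")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def is_inverse(self) -> bool:
        return self.kind.endswith("_inv")

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        pos = {i: k for k, i in enumerate(self.ids)}
        try:
            return np.array([pos[str(i)] for i in ids], dtype=np.int64)
        except KeyError as e:
            raise AlignmentError(f"id {e.args[0]!r} not in matrix index") from None

    def submatrix(self, ids: Sequence[str], kind: str | None = None) -> "RelationshipMatrix":
        idx = self.index_of(ids)
        return RelationshipMatrix(
            ids=[str(i) for i in ids],
            values=self.values[np.ix_(idx, idx)].copy(),
            kind=kind or self.kind,
        )


# ---------------------------------------------------------------------------
# Pedigree-based matrices


def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Row of individual i is the half-sum of its parents' rows;
    ``A_ii = 1 + a(sire_i, dam_i) / 2`` so the diagonal is 1 + inbreeding.
    """
    n = len(ped)
    A = np.zeros((n, n))
    s, d = ped.sire_idx, ped.dam_idx
    for i in range(n):
        row = np.zeros(i)
        if s[i] != UNKNOWN:
            row += 0.5 * A[s[i], :i]
        if d[i] != UNKNOWN:
            row += 0.5 * A[d[i], :i]
        A[i, :i] = row
        A[:i, i] = row
        f = 0.5 * A[s[i], d[i]] if (s[i] != UNKNOWN and d[i] != UNKNOWN) else 0.0
        A[i, i] = 1.0 + f
    return RelationshipMatrix(list(ped.ids), A, kind="A")


def compute_inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F_i = a(sire_i, dam_i)/2 (0 if a parent is unknown)."""
    return np.diag(build_A(ped).values) - 1.0


def _mendelian_variances(ped: Pedigree, F: np.ndarray) -> np.ndarray:
    """Within-family (Mendelian sampling) variances per individual."""
    s, d = ped.sire_idx, ped.dam_idx
    Fs = np.where(s != UNKNOWN, F[s], np.nan)
    Fd = np.where(d != UNKNOWN, F[d], np.nan)
    both = (s != UNKNOWN) & (d != UNKNOWN)
    one = (s != UNKNOWN) ^ (d != UNKNOWN)
    Fp = np.where(s != UNKNOWN, Fs, Fd)
    dvar = np.ones(len(ped))
    dvar[both] = 0.5 - 0.25 * (Fs[both] + Fd[both])
    dvar[one] = 0.75 - 0.25 * Fp[one]
    return dvar


def build_A_inverse(ped: Pedigree, use_inbreeding: bool = True) -> RelationshipMatrix:
    """Direct A⁻¹ by Henderson's rules.

    Each trio (i, sire, dam) contributes b = 1/d_i to the diagonal of i,
    −b/2 to the individual–parent cells and b/4 to the parent–parent cells,
    with d_i the Mendelian-sampling variance.  With ``use_inbreeding`` the
    d_i account for parental inbreeding and the result equals the dense
    inverse of the tabular A; without, inbreeding is ignored (a known bias
    source kept for comparison).
    """
    n = len(ped)
    F = compute_inbreeding(ped) if use_inbreeding else np.zeros(n)
    dvar = _mendelian_variances(ped, F)
    Ainv = np.zeros((n, n))
    s, d = ped.sire_idx, ped.dam_idx
    for i in range(n):
        b = 1.0 / dvar[i]
        Ainv[i, i] += b
        parents = [p for p in (s[i], d[i]) if p != UNKNOWN]
        for p in parents:
            Ainv[i, p] -= b / 2
            Ainv[p, i] -= b / 2
            Ainv[p, p] += b / 4
        if len(parents) == 2:
            p, q = parents
            Ainv[p, q] += b / 4
            Ainv[q, p] += b / 4
    return RelationshipMatrix(list(ped.ids), Ainv, kind="A_inv")


# ---------------------------------------------------------------------------
# Genomic and hybrid matrices


def build_G_vanraden1(geno: GenotypeMatrix) -> RelationshipMatrix:
    """Genomic relationship matrix, VanRaden method 1.

    ``G = W W' / (2 * sum_l p_l (1 - p_l))`` with W the centred −1/0/+1
    coding.  Raises when every marker is monomorphic (zero denominator).
    """
    p = geno.allele_freqs
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ZeroDivisionError(
            "all markers are monomorphic: G denominator 2*sum p(1-p) is zero"
        )
    W = geno.centered_coding()
    G = (W @ W.T) / denom
    G = 0.5 * (G + G.T)
    return RelationshipMatrix(list(geno.ids), G, kind="G")


def blend_G_A(
    G: RelationshipMatrix, A_sub: RelationshipMatrix, weight: float = 0.95
) -> RelationshipMatrix:
    """Weighted blend ``weight*G + (1-weight)*A`` on a common id set."""
    if G.ids != A_sub.ids:
        raise AlignmentError("G and A submatrix must share ids in the same order")
    return RelationshipMatrix(
        list(G.ids), weight * G.values + (1.0 - weight) * A_sub.values, kind="G"
    )


def invert_matrix(K: RelationshipMatrix, rcond: float = 1e-10) -> RelationshipMatrix:
    """Dense inverse of a symmetric positive-definite relationship matrix.

    Raises :class:`SingularMatrixError` when the factorization fails
    (indefinite matrix) or the estimated reciprocal condition number falls
    below ``rcond`` (numerically singular, e.g. dominated by a rank-one
    component).  The error reports the smallest eigenvalue as a diagnostic.
    """

    def _singular_error() -> SingularMatrixError:
        smallest = float(scipy.linalg.eigh(K.values, eigvals_only=True)[0])
        return SingularMatrixError(
            f"matrix of kind {K.kind!r} is singular or not positive definite "
            f"(smallest eigenvalue {smallest:.3e})",
            smallest_eigenvalue=smallest,
        )

    try:
        c, low = scipy.linalg.cho_factor(K.values)
    except np.linalg.LinAlgError:
        raise _singular_error() from None
    anorm = float(np.linalg.norm(K.values, 1))
    rcond_est, info = scipy.linalg.lapack.dpocon(c, anorm, uplo=b"L" if low else b"U")
    if info != 0 or rcond_est < rcond:
        raise _singular_error()
    inv = scipy.linalg.cho_solve((c, low), np.eye(len(K)))
    inv = 0.5 * (inv + inv.T)
    kind_map = {"A": "A_inv", "G": "G_inv", "H": "H_inv",
                "A_inv": "A", "G_inv": "G", "H_inv": "H"}
    inverse_kind = kind_map.get(K.kind, "custom")
    return RelationshipMatrix(list(K.ids), inv, kind=inverse_kind)


def build_H_inverse(
    A_inv: RelationshipMatrix,
    G_blend: RelationshipMatrix,
    A22: RelationshipMatrix,
    genotyped_ids: Sequence[str],
) -> RelationshipMatrix:
    """Single-step hybrid inverse: A⁻¹ plus (G⁻¹ − A22⁻¹) on the genotyped block.

    ``G_blend`` and ``A22`` must be indexed by ``genotyped_ids`` (a subset of
    the A⁻¹ index).  Plain construction, no relative weighting of the blocks.
    """
    gids = _as_str_ids(genotyped_ids)
    if list(G_blend.ids) != gids or list(A22.ids) != gids:
        raise AlignmentError("G_blend and A22 must be indexed by genotyped_ids")
    idx = A_inv.index_of(gids)
    H = A_inv.values.copy()
    if gids:
        Ginv = invert_matrix(G_blend).values
        A22inv = invert_matrix(A22).values
        H[np.ix_(idx, idx)] += Ginv - A22inv
    return RelationshipMatrix(list(A_inv.ids), H, kind="H_inv")
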