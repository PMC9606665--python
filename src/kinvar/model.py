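"""Single-trait animal model: REML variance components and BLUP breeding values.

Model: ``y = 1*mu + Z u + e`` with ``u ~ N(0, K sigma2_g)`` and
``e ~ N(0, I sigma2_e)``.  The only fixed effect is the overall mean, so the
mixed-model coefficient matrix is nonsingular without constraints.

REML is solved exactly for this one-random-effect model: on the phenotyped
subset the marginal covariance is ``sigma2_g * (K_obs + lambda I)`` with
``lambda = sigma2_e / sigma2_g``, so after an eigendecomposition of K_obs the
restricted log-likelihood is a smooth function of the single ratio and is
maximized by bounded scalar search, with the genetic variance profiled out in
closed form.  Individuals without phenotypes stay in the equations; their
breeding values flow through K⁻¹.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg
import scipy.optimize

from .relmat import AlignmentError, RelationshipMatrix, SingularMatrixError

__all__ = [
    "PhenotypeTable",
    "VarianceComponents",
    "EbvResult",
    "MixedModelSystem",
    "build_mme",
    "solve_mme",
    "reml_estimate",
]

# bounds of the scalar REML search, in log10(lambda); lambda = 1e-6..1e6
# corresponds to h2 in (1e-6, 1 - 1e-6) for practical purposes
_LOG_LAMBDA_BOUNDS = (-6.0, 6.0)


@dataclass
class PhenotypeTable:
    """Observed trait records; individuals without a record are simply absent."""

    ids: list[str]
    y: np.ndarray

    def __post_init__(self):
        self.ids = [str(i) for i in self.ids]
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (len(self.ids),):
            raise ValueError("phenotype vector length does not match ids")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("repeated records per individual are not supported")
        if np.isnan(self.y).any():
            raise ValueError("missing phenotypes must be dropped, not NaN-coded")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class VarianceComponents:
    """Genetic and residual variances with derived heritability and ratio."""

    sigma2_g: float
    sigma2_e: float
    n_iter: int = 0
    converged: bool = True
    loglik: float = np.nan

    def __post_init__(self):
        if self.sigma2_g < 0 or self.sigma2_e < 0:
            raise ValueError("variance components must be non-negative")

    @property
    def h2(self) -> float:
        return self.sigma2_g / (self.sigma2_g + self.sigma2_e)

    @property
    def lam(self) -> float:
        """Shrinkage ratio lambda = sigma2_e / sigma2_g = (1 - h2) / h2."""
        return self.sigma2_e / self.sigma2_g

    @classmethod
    def from_h2(cls, h2: float, var_phenotypic: float = 1.0) -> "VarianceComponents":
        if not 0 < h2 < 1:
            raise ValueError("h2 must be in (0, 1)")
        return cls(sigma2_g=h2 * var_phenotypic, sigma2_e=(1 - h2) * var_phenotypic)


@dataclass
class EbvResult:
    """Solutions of the mixed model equations."""

    ids: list[str]
    fixed_solutions: np.ndarray
    ebv: np.ndarray
    lhs_summary: dict = field(default_factory=dict)


@dataclass
class MixedModelSystem:
    """Assembled dense MME: LHS [[X'X, X'Z], [Z'X, Z'Z + K^-1 lambda]]."""

    lhs: np.ndarray
    rhs: np.ndarray
    ids: list[str]
    n_fixed: int = 1


def _incidence(K_ids: Sequence[str], phen: PhenotypeTable) -> np.ndarray:
    pos = {i: k for k, i in enumerate(K_ids)}
    try:
        cols = [pos[i] for i in phen.ids]
    except KeyError as e:
        raise AlignmentError(
            f"phenotyped id {e.args[0]!r} absent from relationship matrix"
        ) from None
    Z = np.zeros((len(phen), len(K_ids)))
    Z[np.arange(len(phen)), cols] = 1.0
    return Z


def build_mme(
    K_inv: RelationshipMatrix, phen: PhenotypeTable, lam: float
) -> MixedModelSystem:
    """Assemble the mean + breeding-value mixed model equations for given K⁻¹."""
    if lam <= 0:
        raise ValueError("variance ratio lambda must be positive")
    if len(phen) == 0:
        raise ValueError("no phenotype records: nothing to assemble")
    Z = _incidence(K_inv.ids, phen)
    X = np.ones((len(phen), 1))
    q = len(K_inv)
    lhs = np.empty((1 + q, 1 + q))
    lhs[:1, :1] = X.T @ X
    lhs[:1, 1:] = X.T @ Z
    lhs[1:, :1] = lhs[:1, 1:].T
    lhs[1:, 1:] = Z.T @ Z + K_inv.values * lam
    rhs = np.concatenate([X.T @ phen.y, Z.T @ phen.y])
    return MixedModelSystem(lhs=lhs, rhs=rhs, ids=list(K_inv.ids))


def solve_mme(system: MixedModelSystem) -> EbvResult:
    """Solve the MME directly (dense); generalized solve as fallback.

    Raises when even the least-squares solution leaves a large residual
    (inconsistent / numerically broken system).
    """
    try:
        sol = scipy.linalg.solve(system.lhs, system.rhs, assume_a="sym")
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgWarning):
        sol = None
    resid_scale = max(1.0, float(np.linalg.norm(system.rhs)))
    if sol is None or not np.isfinite(sol).all() or (
        np.linalg.norm(system.lhs @ sol - system.rhs) / resid_scale > 1e-8
    ):
        sol, *_ = scipy.linalg.lstsq(system.lhs, system.rhs)
        resid = np.linalg.norm(system.lhs @ sol - system.rhs) / resid_scale
        if resid > 1e-6:
            raise SingularMatrixError(
                f"mixed model equations are singular (relative residual {resid:.2e})"
            )
    nf = system.n_fixed
    return EbvResult(
        ids=list(system.ids),
        fixed_solutions=sol[:nf],
        ebv=sol[nf:],
        lhs_summary={"n_equations": system.lhs.shape[0]},
    )


def _restricted_neg_loglik(
    log_lam: float, d: np.ndarray, zeta: np.ndarray, xi: np.ndarray
) -> tuple[float, float]:
    """−2·REML log-likelihood (up to a constant) and the profiled sigma2_g.

    ``d`` are eigenvalues of K on the phenotyped subset, ``zeta``/``xi`` the
    rotated phenotype and intercept columns.
    """
    lam = 10.0**log_lam
    w = d + lam
    xtvx = float(np.sum(xi * xi / w))
    beta = float(np.sum(xi * zeta / w)) / xtvx
    r = zeta - beta * xi
    quad = float(np.sum(r * r / w))
    n, p = len(d), 1
    sigma2_g = quad / (n - p)
    m2ll = (
        (n - p) * np.log(sigma2_g)
        + float(np.sum(np.log(w)))
        + np.log(xtvx)
        + (n - p)
    )
    return m2ll, sigma2_g


def _neg_loglik_gradient(
    log_lam: float, d: np.ndarray, zeta: np.ndarray, xi: np.ndarray
) -> float:
    """d(−2·REML log-likelihood)/d lambda of the profiled likelihood.

    The genetic variance and the mean are profiled out; by the envelope
    theorem only the explicit lambda dependence contributes.
    """
    lam = 10.0**log_lam
    w = d + lam
    xtvx = float(np.sum(xi * xi / w))
    beta = float(np.sum(xi * zeta / w)) / xtvx
    r = zeta - beta * xi
    quad = float(np.sum(r * r / w))
    n, p = len(d), 1
    return (
        -(n - p) * float(np.sum(r * r / w**2)) / quad
        + float(np.sum(1.0 / w))
        - float(np.sum(xi * xi / w**2)) / xtvx
    )


def reml_estimate(
    K: RelationshipMatrix,
    phen: PhenotypeTable,
    init: VarianceComponents | None = None,
    tol: float = 1e-12,
    max_iter: int = 500,
) -> VarianceComponents:
    """REML estimates of (sigma2_g, sigma2_e) for the animal model.

    ``K`` is the relationship matrix itself (not its inverse); only its
    phenotyped-subset block enters the restricted likelihood.  ``init`` is
    accepted for interface compatibility but the scalar search does not need
    a starting value.  Boundary optima are clamped with a warning.
    """
    if len(phen) < 3:
        raise ValueError("REML needs at least 3 phenotype records")
    if np.var(phen.y) == 0:
        raise ValueError("phenotypic variance is zero")
    if K.is_inverse:
        raise ValueError("reml_estimate expects K, not an inverse matrix")
    idx = K.index_of(phen.ids)
    Kobs = K.values[np.ix_(idx, idx)]
    d, U = scipy.linalg.eigh(Kobs)
    if d[0] < -1e-8 * max(1.0, d[-1]):
        raise SingularMatrixError(
            f"K is not positive semi-definite on the phenotyped subset "
            f"(smallest eigenvalue {d[0]:.3e})",
            smallest_eigenvalue=float(d[0]),
        )
    d = np.clip(d, 0.0, None)
    zeta = U.T @ phen.y
    xi = U.T @ np.ones(len(phen))

    # The restricted likelihood is maximized where the gradient of the
    # profiled -2*loglik crosses zero from below; root-finding on the
    # analytic gradient locates lambda to near machine precision, which a
    # function-value search cannot.
    lo, hi = _LOG_LAMBDA_BOUNDS
    grid = np.linspace(lo, hi, 49)
    grads = np.array([_neg_loglik_gradient(t, d, zeta, xi) for t in grid])
    sign_change = np.nonzero((grads[:-1] < 0) & (grads[1:] >= 0))[0]
    nfev = len(grid)
    at_bound = False
    if sign_change.size == 0:
        # monotone gradient: optimum sits at a parameter boundary
        log_lam = lo if grads[0] > 0 else hi
        at_bound = True
    else:
        if sign_change.size > 1:
            # rare multimodality: keep the bracket with the lowest -2*loglik
            vals = [
                _restricted_neg_loglik(grid[k], d, zeta, xi)[0] for k in sign_change
            ]
            k = sign_change[int(np.argmin(vals))]
        else:
            k = sign_change[0]
        sol = scipy.optimize.root_scalar(
            _neg_loglik_gradient,
            args=(d, zeta, xi),
            bracket=(grid[k], grid[k + 1]),
            method="brentq",
            xtol=tol,
            maxiter=max_iter,
        )
        log_lam = float(sol.root)
        nfev += sol.function_calls
    m2ll, sigma2_g = _restricted_neg_loglik(log_lam, d, zeta, xi)
    lam = 10.0**log_lam
    if at_bound:
        warnings.warn(
            "REML optimum at the parameter boundary; variance estimate clamped",
            RuntimeWarning,
            stacklevel=2,
        )
    return VarianceComponents(
        sigma2_g=sigma2_g,
        sigma2_e=lam * sigma2_g,
        n_iter=int(nfev),
        converged=not at_bound,
        loglik=-0.5 * m2ll,
    )
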