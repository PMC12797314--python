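"""Penalized-likelihood engine behind the vital-rate regressions.

Fits generalized linear models whose linear predictor combines unpenalized
fixed effects (intercept + size), an optional ridge-penalized spline block
(a P-spline in its mixed-model reparametrization) and intercept-only
random-effect blocks (individual / year / plot).  All penalized blocks are
treated uniformly: block coefficients ``u_k`` carry the quadratic penalty
``u_k'u_k / sigma_k^2`` and the variance parameters ``sigma_k^2`` are
estimated by maximizing a Laplace approximation to the marginal likelihood
(exact for Gaussian responses, where it is ordinary maximum likelihood).

The model AIC is computed on this marginal scale with one parameter per
variance/smoothing component, which makes linear, smooth and mixed
candidates for the same response directly comparable.  With no penalized
blocks the fit and its AIC coincide with the ordinary GLM ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.interpolate import BSpline
from scipy.optimize import minimize
from scipy.sparse.linalg import splu
from scipy.special import expit, gammaln

__all__ = [
    "FitError",
    "SeparationError",
    "PenalizedFit",
    "SplineBasis",
    "fit_penalized_glm",
    "get_family",
    "make_spline_basis",
    "group_design",
]

_ETA_MAX = 35.0  # |linear predictor| beyond this signals divergence/separation


class FitError(RuntimeError):
    """A vital-rate model could not be fitted."""


class SeparationError(FitError):
    """Complete separation (or likelihood divergence) in a binary fit."""


# ---------------------------------------------------------------------------
# Exponential families (canonical links throughout)
# ---------------------------------------------------------------------------


class _Binomial:
    name = "binomial"
    has_dispersion = False

    @staticmethod
    def check(y: np.ndarray, label: str) -> None:
        if not np.all((y == 0.0) | (y == 1.0)):
            raise FitError(f"{label}: binomial family requires a 0/1 response")
        if np.all(y == y[0]):
            raise SeparationError(
                f"complete separation in {label}: all responses equal {int(y[0])}"
            )

    @staticmethod
    def mean(eta: np.ndarray) -> np.ndarray:
        return expit(eta)

    @staticmethod
    def irls(y: np.ndarray, eta: np.ndarray):
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        return w, eta + (y - mu) / w

    @staticmethod
    def loglik(y: np.ndarray, eta: np.ndarray, phi: float = 1.0) -> float:
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


class _Poisson:
    name = "poisson"
    has_dispersion = False

    @staticmethod
    def check(y: np.ndarray, label: str) -> None:
        if np.any(y < 0) or np.any(y != np.floor(y)):
            raise FitError(f"{label}: Poisson family requires nonnegative counts")

    @staticmethod
    def mean(eta: np.ndarray) -> np.ndarray:
        return np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))

    @classmethod
    def irls(cls, y: np.ndarray, eta: np.ndarray):
        mu = cls.mean(eta)
        w = np.clip(mu, 1e-10, None)
        return w, eta + (y - mu) / w

    @classmethod
    def loglik(cls, y: np.ndarray, eta: np.ndarray, phi: float = 1.0) -> float:
        mu = cls.mean(eta)
        return float(np.sum(y * np.clip(eta, -_ETA_MAX, _ETA_MAX) - mu - gammaln(y + 1.0)))


class _TruncatedPoisson:
    """Zero-truncated Poisson (support 1, 2, ...) with a log link on the rate.

    Used for flower counts of reproducing individuals: the reproduction
    probability is modelled separately, so the count model never sees zeros.
    ``mean`` returns the truncated mean mu/(1-exp(-mu)), i.e. the expected
    number of structures among reproducers, which is the response-scale
    quantity the projection kernel consumes.
    """

    name = "truncated_poisson"
    has_dispersion = False

    @staticmethod
    def check(y: np.ndarray, label: str) -> None:
        if np.any(y < 1) or np.any(y != np.floor(y)):
            raise FitError(
                f"{label}: zero-truncated Poisson requires integer counts >= 1"
            )

    @staticmethod
    def mean(eta: np.ndarray) -> np.ndarray:
        mu = np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))
        denom = np.clip(-np.expm1(-mu), 1e-12, None)
        return mu / denom

    @classmethod
    def irls(cls, y: np.ndarray, eta: np.ndarray):
        mu = np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))
        q = np.exp(-mu)
        denom = np.clip(1.0 - q, 1e-12, None)
        m = mu / denom
        dm_dmu = (denom - mu * q) / denom**2
        w = np.clip(mu * dm_dmu, 1e-10, None)
        return w, eta + (y - m) / w

    @staticmethod
    def loglik(y: np.ndarray, eta: np.ndarray, phi: float = 1.0) -> float:
        eta = np.clip(eta, -_ETA_MAX, _ETA_MAX)
        mu = np.exp(eta)
        denom = np.clip(-np.expm1(-mu), 1e-300, None)
        return float(np.sum(y * eta - mu - np.log(denom) - gammaln(y + 1.0)))


class _Gaussian:
    name = "gaussian"
    has_dispersion = True

    @staticmethod
    def check(y: np.ndarray, label: str) -> None:
        if not np.all(np.isfinite(y)):
            raise FitError(f"{label}: non-finite Gaussian response")

    @staticmethod
    def mean(eta: np.ndarray) -> np.ndarray:
        return eta

    @staticmethod
    def irls(y: np.ndarray, eta: np.ndarray):
        return np.ones_like(y), y

    @staticmethod
    def loglik(y: np.ndarray, eta: np.ndarray, phi: float = 1.0) -> float:
        rss = float(np.sum((y - eta) ** 2))
        n = y.size
        return -0.5 * (rss / phi + n * np.log(2.0 * np.pi * phi))


_FAMILIES = {
    "binomial": _Binomial,
    "poisson": _Poisson,
    "truncated_poisson": _TruncatedPoisson,
    "gaussian": _Gaussian,
}


def get_family(name: str):
    try:
        return _FAMILIES[name]
    except KeyError:
        raise FitError(f"unknown family {name!r}") from None


# ---------------------------------------------------------------------------
# Spline basis (P-spline, mixed-model reparametrization)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplineBasis:
    """Cubic B-spline basis with a second-order difference penalty.

    The basis is reparametrized so that its penalty null space (the linear
    trend) lives in the unpenalized fixed effects; the remaining ``nbasis-2``
    directions form a single ridge-penalized block whose variance acts as the
    inverse smoothing parameter.  Evaluation clamps sizes to the training
    range, i.e. the smooth deviation is extended as a constant beyond it.
    """

    knots: np.ndarray
    degree: int
    xmin: float
    xmax: float
    transform: np.ndarray  # nbasis x (nbasis - 2)

    @property
    def nbasis(self) -> int:
        return len(self.knots) - self.degree - 1

    def design(self, x: np.ndarray) -> sp.csr_matrix:
        xc = np.clip(np.asarray(x, dtype=float), self.xmin, self.xmax)
        b = BSpline.design_matrix(xc, self.knots, self.degree)
        return sp.csr_matrix(b @ self.transform)


def make_spline_basis(xmin: float, xmax: float, nbasis: int = 10, degree: int = 3) -> SplineBasis:
    if xmax <= xmin:
        raise FitError("spline basis requires xmax > xmin")
    inner = np.linspace(xmin, xmax, nbasis - degree + 1)
    knots = np.r_[np.full(degree, xmin), inner, np.full(degree, xmax)]
    d2 = np.diff(np.eye(nbasis), n=2, axis=0)  # (nbasis-2) x nbasis
    transform = d2.T @ np.linalg.inv(d2 @ d2.T)
    return SplineBasis(knots=knots, degree=degree, xmin=float(xmin), xmax=float(xmax), transform=transform)


def group_design(labels) -> tuple[sp.csr_matrix, np.ndarray]:
    """Indicator matrix (n x n_levels) for an intercept-only grouping."""
    levels, inverse = np.unique(np.asarray(labels), return_inverse=True)
    n = len(inverse)
    z = sp.csr_matrix(
        (np.ones(n), (np.arange(n), inverse)), shape=(n, len(levels))
    )
    return z, levels


# ---------------------------------------------------------------------------
# Core fit
# ---------------------------------------------------------------------------


@dataclass
class PenalizedFit:
    beta: np.ndarray
    block_names: list[str]
    block_coefs: dict[str, np.ndarray]
    sigma2: dict[str, float]
    phi: float
    loglik: float
    aic: float
    n_obs: int
    n_params: int
    converged: bool
    outer_nfev: int = 0
    trail: list = field(default_factory=list, repr=False)


def _logdet_spd(a: sp.spmatrix) -> float:
    """log-determinant of a sparse symmetric positive-definite matrix."""
    if a.shape[0] == 0:
        return 0.0
    if a.shape[0] <= 200:
        sign, logdet = np.linalg.slogdet(a.toarray())
        if sign <= 0:
            raise FitError("non-positive-definite penalized Hessian")
        return float(logdet)
    lu = splu(
        a.tocsc(),
        permc_spec="MMD_AT_PLUS_A",
        diag_pivot_thresh=0.0,
        options=dict(SymmetricMode=True),
    )
    diag = lu.U.diagonal()
    if np.any(diag <= 0):
        # pivoting may flip signs pairwise; fall back on |diag| which is
        # correct for an SPD matrix up to permutation parity
        return float(np.sum(np.log(np.abs(diag))))
    return float(np.sum(np.log(diag)))


def fit_penalized_glm(
    y,
    X,
    blocks,
    family_name: str,
    *,
    label: str = "model",
    max_pirls: int = 60,
    outer_maxfev: int = 400,
    s2_init: dict | None = None,
) -> PenalizedFit:
    """Fit a GLM with ridge-penalized coefficient blocks.

    Parameters
    ----------
    y : array (n,)
        Response on the family's natural scale.
    X : array (n, p)
        Unpenalized fixed-effect design.
    blocks : list of (name, Z)
        Penalized blocks; ``Z`` is the (n, q_k) design of block ``k``.
    family_name : str
        One of ``binomial``, ``poisson``, ``truncated_poisson``, ``gaussian``.
    """
    fam = get_family(family_name)
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if y.size != n:
        raise FitError(f"{label}: response/design length mismatch")
    fam.check(y, label)

    names = [nm for nm, _ in blocks]
    zmats = [sp.csr_matrix(z) for _, z in blocks]
    qs = [z.shape[1] for z in zmats]
    K = len(blocks)
    q = int(sum(qs))
    m = p + q

    # One large intercept-only grouping (e.g. 'individual') makes the normal
    # equations an arrow matrix: its Gram block is diagonal, so it can be
    # eliminated by a Schur complement against the small dense remainder.
    def _is_indicator(z: sp.csr_matrix) -> bool:
        return (
            z.nnz == z.shape[0]
            and np.all(np.diff(z.indptr) == 1)
            and np.all(z.data == 1.0)
        )

    big = None
    cand = [i for i in range(K) if qs[i] > 60 and _is_indicator(zmats[i])]
    if cand:
        largest = max(cand, key=lambda i: qs[i])
        if p + q - qs[largest] <= 300:
            big = largest
    small_idx = [i for i in range(K) if i != big]

    if big is None and m > 400:
        mode = "sparse"
    elif big is None:
        mode = "dense"
    else:
        mode = "schur"

    # internal coefficient layout: [X | small blocks (original order) | big]
    order = small_idx + ([big] if big is not None else [])
    new_offsets = {}
    pos = p
    for i in order:
        new_offsets[i] = slice(pos, pos + qs[i])
        pos += qs[i]
    block_slices = [new_offsets[i] for i in range(K)]  # original order -> slice

    if mode == "sparse":
        C = sp.hstack([sp.csr_matrix(X)] + [zmats[i] for i in order], format="csr")
        CT = C.T.tocsr()
    else:
        Cs = np.hstack([X] + [zmats[i].toarray() for i in small_idx]) if small_idx else X
        ms = Cs.shape[1]
        if big is not None:
            Zb = zmats[big]
            ZbT = Zb.T.tocsr()
            gidx = Zb.indices.astype(np.intp)
            qb = qs[big]

    def penalty_diag(s2: np.ndarray) -> np.ndarray:
        d = np.zeros(m)
        for i, s in enumerate(s2):
            d[block_slices[i]] = 1.0 / s
        return d

    gaussian = fam.name == "gaussian"
    warm = {"coef": np.zeros(m)}

    def eta_of(coef: np.ndarray) -> np.ndarray:
        if mode == "sparse":
            return C @ coef
        eta = Cs @ coef[:ms]
        if mode == "schur":
            eta = eta + coef[ms:][gidx]
        return eta

    def solve_system(wp: np.ndarray, target: np.ndarray, pen: np.ndarray) -> np.ndarray:
        """Solve (C'WC + diag(pen)) coef = C'W target in the internal layout."""
        if mode == "sparse":
            A = (CT @ C.multiply(wp[:, None])) + sp.diags(pen)
            rhs = CT @ (wp * target)
            return splu(A.tocsc()).solve(rhs)
        wt = wp * target
        Ass = (Cs * wp[:, None]).T @ Cs + np.diag(pen[:ms])
        rhs_s = Cs.T @ wt
        if mode == "dense":
            try:
                return np.linalg.solve(Ass, rhs_s)
            except np.linalg.LinAlgError as exc:
                raise FitError(f"singular system in {label}: {exc}") from None
        d = np.bincount(gidx, weights=wp, minlength=qb) + pen[ms]
        B = ZbT @ (Cs * wp[:, None])  # qb x ms
        rhs_b = np.bincount(gidx, weights=wt, minlength=qb)
        dinv = 1.0 / d
        schur = Ass - B.T @ (B * dinv[:, None])
        rhs_sch = rhs_s - B.T @ (dinv * rhs_b)
        try:
            x_s = np.linalg.solve(schur, rhs_sch)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"singular system in {label}: {exc}") from None
        x_b = dinv * (rhs_b - B @ x_s)
        return np.r_[x_s, x_b]

    def logdet_u(wp: np.ndarray, pen: np.ndarray) -> float:
        """log det of the penalized-coordinate block of the Hessian."""
        if q == 0:
            return 0.0
        if mode == "sparse":
            Zall = C[:, p:]
            Hu = (Zall.T @ Zall.multiply(wp[:, None])).tocsc() + sp.diags(pen[p:])
            return _logdet_spd(Hu)
        if mode == "dense":
            U = Cs[:, p:]
            Hu = (U * wp[:, None]).T @ U + np.diag(pen[p:ms])
            sign, ld = np.linalg.slogdet(Hu)
            if sign <= 0:
                raise FitError(f"non-positive-definite penalized Hessian in {label}")
            return float(ld)
        d = np.bincount(gidx, weights=wp, minlength=qb) + pen[ms]
        U = Cs[:, p:]
        if U.shape[1] == 0:
            return float(np.sum(np.log(d)))
        Hss = (U * wp[:, None]).T @ U + np.diag(pen[p:ms])
        Bu = ZbT @ (U * wp[:, None])  # qb x (ms - p)
        schur = Hss - Bu.T @ (Bu / d[:, None])
        sign, ld = np.linalg.slogdet(schur)
        if sign <= 0:
            raise FitError(f"non-positive-definite penalized Hessian in {label}")
        return float(np.sum(np.log(d))) + float(ld)

    def pirls(s2: np.ndarray, phi: float, coef0: np.ndarray):
        pen = penalty_diag(s2)
        coef = coef0.copy()

        def pll(cf: np.ndarray) -> float:
            return fam.loglik(y, eta_of(cf), phi) - 0.5 * float(np.sum(pen * cf**2))

        current = pll(coef)
        n_iter = 1 if gaussian else max_pirls
        for _ in range(n_iter):
            eta = eta_of(coef)
            if not gaussian and np.max(np.abs(eta)) > _ETA_MAX + 20:
                raise SeparationError(f"likelihood divergence in {label}")
            w, z = fam.irls(y, eta)
            new = solve_system(w / phi, z, pen)
            if gaussian:
                coef = new
                current = pll(coef)
                break
            # step-halving towards the IRLS update
            step = new - coef
            t = 1.0
            for _half in range(12):
                cand = coef + t * step
                val = pll(cand)
                if np.isfinite(val) and val >= current - 1e-10:
                    break
                t *= 0.5
            else:
                cand, val = coef, current
            moved = float(np.max(np.abs(cand - coef)))
            coef, current = cand, val
            if moved <= 1e-9 * (1.0 + float(np.max(np.abs(coef)))):
                break
        if not np.isfinite(current):
            raise FitError(f"non-finite likelihood in {label}")
        return coef, current

    def laplace(s2: np.ndarray, phi: float, coef: np.ndarray) -> float:
        eta = eta_of(coef)
        ll = fam.loglik(y, eta, phi)
        if q == 0:
            return ll
        w, _ = fam.irls(y, eta)
        pen = penalty_diag(s2)
        upart = coef[p:]
        pen_term = 0.5 * float(np.sum(pen[p:] * upart**2))
        logsig = 0.5 * float(sum(qk * np.log(s) for qk, s in zip(qs, s2)))
        return ll - pen_term - logsig - 0.5 * logdet_u(w / phi, pen)

    K = len(blocks)
    n_var = K + (1 if gaussian else 0)

    if n_var == 0:
        coef, _ = pirls(np.empty(0), 1.0, warm["coef"])
        ll = laplace(np.empty(0), 1.0, coef)
        nfev = 0
        s2_hat = np.empty(0)
        phi_hat = 1.0
    elif gaussian and K == 0:
        # ordinary least squares with ML dispersion
        coef, _ = pirls(np.empty(0), 1.0, warm["coef"])
        resid = y - eta_of(coef)
        phi_hat = max(float(np.mean(resid**2)), 1e-12)
        ll = fam.loglik(y, eta_of(coef), phi_hat)
        s2_hat = np.empty(0)
        nfev = 0
    else:
        inits = s2_init or {}
        x0 = np.log(np.array([np.clip(inits.get(nm, 0.05), 1e-4, 1e4) for nm in names]))
        if gaussian:
            phi0 = max(float(np.var(y)), 1e-8)
            x0 = np.r_[x0, np.log(phi0)]

        def neg_marginal(x: np.ndarray) -> float:
            s2 = np.clip(np.exp(x[:K]), 1e-8, 1e6)
            phi = float(np.clip(np.exp(x[K]), 1e-10, 1e8)) if gaussian else 1.0
            try:
                coef, _ = pirls(s2, phi, warm["coef"])
            except SeparationError:
                raise
            except FitError:
                return 1e12
            warm["coef"] = coef
            val = laplace(s2, phi, coef)
            if not np.isfinite(val):
                return 1e12
            return -val

        res = minimize(
            neg_marginal,
            x0,
            method="Nelder-Mead",
            options=dict(xatol=0.08, fatol=0.02, maxfev=outer_maxfev),
        )
        nfev = int(res.nfev)
        xopt = res.x
        s2_hat = np.clip(np.exp(xopt[:K]), 1e-8, 1e6)
        phi_hat = float(np.clip(np.exp(xopt[K]), 1e-10, 1e8)) if gaussian else 1.0
        coef, _ = pirls(s2_hat, phi_hat, warm["coef"])
        ll = laplace(s2_hat, phi_hat, coef)

    if not np.isfinite(ll):
        raise FitError(f"non-finite likelihood in {label}")

    n_params = p + n_var
    aic = -2.0 * ll + 2.0 * n_params
    return PenalizedFit(
        beta=coef[:p].copy(),
        block_names=names,
        block_coefs={nm: coef[sl].copy() for nm, sl in zip(names, block_slices)},
        sigma2={nm: float(s) for nm, s in zip(names, s2_hat)},
        phi=float(phi_hat),
        loglik=float(ll),
        aic=float(aic),
        n_obs=n,
        n_params=n_params,
        converged=True,
        outer_nfev=nfev,
    )
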