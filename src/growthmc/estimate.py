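"""Maximum-likelihood estimation of the three-level growth model.

The marginal model for the stacked outcomes of group ``j`` is

    y_j ~ N(X_j gamma, V_j),
    V_j = Z3_j G3 Z3_j' + blockdiag_i(Z2 G2 Z2') + sigma2_e I,

with fixed-effect design columns ``(1, z, x, t, t*z, t*x)``, level-3
random design ``(1, x, t, t*x)`` and level-2 random design ``(1, t)``.
The fixed effects are concentrated out by generalized least squares, and
the profiled log-likelihood is maximized over the variance parameters on
the *unconstrained* variance scale: negative variance estimates are
reachable and are classified as inadmissible rather than prevented,
mirroring the admissibility accounting of standard ML software.

Likelihood evaluations exploit the structure of the model: the level-2
plus residual block ``B = sigma2_e I + Z2 G2 Z2'`` is one T x T matrix
shared by every individual, and the group-level random effects enter
through a rank-4 update handled with the Woodbury identity and the
matrix determinant lemma.  Per-dataset sufficient statistics are
precomputed once, after which an evaluation costs a few small batched
tensor contractions regardless of the number of observations.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy import stats as sps

from .design import (
    FIXED_EFFECT_NAMES,
    VARIANCE_NAMES,
    DesignError,
    VarianceComponents,
)
from .simulate import LongDataset

__all__ = [
    "ModelSpec",
    "FitOptions",
    "FitResult",
    "ConvergenceStatus",
    "build_group_covariance",
    "profile_loglik",
    "fit_ml",
    "classify_convergence",
]

_LOG_2PI = float(np.log(2.0 * np.pi))
_Z_975 = 1.959964  # standard-normal 97.5% quantile

#: Extra parameter names when covariances are freed.
_L2_COV_NAMES = ("sigma_r01",)
_L3_COV_NAMES = (
    "sigma_u00_01",
    "sigma_u00_10",
    "sigma_u00_11",
    "sigma_u01_10",
    "sigma_u01_11",
    "sigma_u10_11",
)
_L3_COV_IDX = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@dataclass(frozen=True)
class ModelSpec:
    """Structure of the fitted model.

    Both random-effect covariance matrices are diagonal by default,
    matching the zero-covariance generating model; either can be freed.
    """

    level2_covariance: str = "diagonal"
    level3_covariance: str = "diagonal"

    def __post_init__(self) -> None:
        for v in (self.level2_covariance, self.level3_covariance):
            if v not in ("diagonal", "free"):
                raise DesignError("covariance structure must be 'diagonal' or 'free'")

    @property
    def parameter_names(self) -> tuple[str, ...]:
        names = list(VARIANCE_NAMES)
        if self.level2_covariance == "free":
            names += list(_L2_COV_NAMES)
        if self.level3_covariance == "free":
            names += list(_L3_COV_NAMES)
        return tuple(names)

    def n_parameters(self) -> int:
        return len(self.parameter_names)

    def unpack(self, theta: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        """theta -> (sigma2_e, G2 (2x2), G3 (4x4))."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_parameters(),):
            raise DesignError(
                f"theta must have length {self.n_parameters()} for this ModelSpec"
            )
        sigma2_e = theta[0]
        G2 = np.diag(theta[1:3])
        G3 = np.diag(theta[3:7])
        k = 7
        if self.level2_covariance == "free":
            G2[0, 1] = G2[1, 0] = theta[k]
            k += 1
        if self.level3_covariance == "free":
            for (a, b), v in zip(_L3_COV_IDX, theta[k:]):
                G3[a, b] = G3[b, a] = v
        return float(sigma2_e), G2, G3

    def pack(self, vc: VarianceComponents) -> np.ndarray:
        theta = [getattr(vc, n) for n in VARIANCE_NAMES]
        if self.level2_covariance == "free":
            theta.append(vc.sigma_r01)
        if self.level3_covariance == "free":
            theta += [vc.sigma_u_offdiag] * 6
        return np.asarray(theta, dtype=float)


@dataclass(frozen=True)
class FitOptions:
    """Optimizer and numerical-differentiation controls."""

    tol: float = 1e-6            # relative log-likelihood change at convergence
    max_iter: int = 500
    grad_step: float = 1e-5      # relative central-difference step (gradient)
    hess_step: float = 1e-3      # relative central-difference step (Hessian)
    start_floor: float = 1e-4    # lower floor for moment-based starting variances
    compute_hessian: bool = True


class ConvergenceStatus(enum.Enum):
    CONVERGED = "converged"
    INADMISSIBLE = "inadmissible"
    FAILED = "failed"


@dataclass
class FitResult:
    """Estimates, standard errors and inference for one fitted dataset."""

    estimates: dict[str, float]
    std_errors: dict[str, float]
    p_values: dict[str, float]
    conf_ints: dict[str, tuple[float, float]]
    loglik: float
    converged: bool
    admissible: bool
    optimizer_status: str
    n_iter: int
    n_obs: int
    n_groups: int
    parameter_names: tuple[str, ...] = ()
    condition_label: str = ""
    replication: int = -1
    seed: int | None = None

    @property
    def fixed_effects(self) -> dict[str, float]:
        return {n: self.estimates[n] for n in FIXED_EFFECT_NAMES}

    @property
    def variance_components(self) -> dict[str, float]:
        return {n: self.estimates[n] for n in VARIANCE_NAMES}

    def to_record(self) -> dict[str, float]:
        """Flat key-value record suitable for CSV/JSON serialization."""
        rec: dict[str, float] = {
            "condition": self.condition_label,
            "replication": self.replication,
            "seed": self.seed,
            "loglik": self.loglik,
            "converged": self.converged,
            "admissible": self.admissible,
            "status": self.optimizer_status,
            "n_iter": self.n_iter,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
        }
        for name, est in self.estimates.items():
            rec[f"est_{name}"] = est
            rec[f"se_{name}"] = self.std_errors.get(name, np.nan)
            rec[f"p_{name}"] = self.p_values.get(name, np.nan)
            lo, hi = self.conf_ints.get(name, (np.nan, np.nan))
            rec[f"lo_{name}"] = lo
            rec[f"hi_{name}"] = hi
        return rec


def classify_convergence(fit: FitResult) -> ConvergenceStatus:
    """Mplus-style accounting: converged / inadmissible / failed.

    A replication counts as converged only if the optimizer succeeded,
    the information matrix was invertible, and no variance estimate is
    negative.  Optimizer success with a negative variance is
    inadmissible; anything else (including a singular information
    matrix) is a failure.
    """
    if not fit.converged:
        return ConvergenceStatus.FAILED
    if not fit.admissible:
        return ConvergenceStatus.INADMISSIBLE
    return ConvergenceStatus.CONVERGED


# ---------------------------------------------------------------------------
# covariance assembly (direct form, used for small problems and testing)
# ---------------------------------------------------------------------------

def build_group_covariance(
    theta: np.ndarray | VarianceComponents,
    x: np.ndarray,
    n_timepoints: int,
    spec: ModelSpec | None = None,
) -> np.ndarray:
    """Marginal covariance of one group's stacked observations.

    ``x`` holds the individual-level covariate value of each of the
    group's individuals; rows are ordered individual-major, occasion
    0..T-1 within individual.
    """
    spec = spec or ModelSpec()
    if isinstance(theta, VarianceComponents):
        theta = spec.pack(theta)
    sigma2_e, G2, G3 = spec.unpack(theta)
    x = np.asarray(x, dtype=float)
    T = n_timepoints
    t = np.arange(T, dtype=float)
    Z2 = np.column_stack([np.ones(T), t])
    n = x.size
    # level-3 design: one row per observation, columns (1, x, t, x*t)
    Z3 = np.empty((n * T, 4))
    for i, xi in enumerate(x):
        Z3[i * T:(i + 1) * T, 0] = 1.0
        Z3[i * T:(i + 1) * T, 1] = xi
        Z3[i * T:(i + 1) * T, 2] = t
        Z3[i * T:(i + 1) * T, 3] = xi * t
    V = Z3 @ G3 @ Z3.T
    B2 = Z2 @ G2 @ Z2.T
    for i in range(n):
        sl = slice(i * T, (i + 1) * T)
        V[sl, sl] += B2
    V[np.diag_indices_from(V)] += sigma2_e
    return 0.5 * (V + V.T)


# ---------------------------------------------------------------------------
# sufficient statistics and the fast profiled likelihood
# ---------------------------------------------------------------------------

@dataclass
class _Stats:
    """Per-dataset sufficient statistics for likelihood evaluation."""

    T: int
    J: int
    n_obs: int
    Z2: np.ndarray       # (T, 2) level-2 design, shared by all individuals
    C: np.ndarray        # (J, T, T, 7, 7) sum_i W_i[a,:] x W_i[b,:]
    D: np.ndarray        # (J, 2, T, 7) sum_i x_i^p W_i
    xm: np.ndarray       # (J, 3) sums of x^0, x^1, x^2 over individuals
    y_ind: np.ndarray    # (N_ind, T) outcomes per individual (for starts)
    x_ind: np.ndarray    # (N_ind,)
    z_ind: np.ndarray    # (N_ind,)
    group_of_ind: np.ndarray  # (N_ind,)


def _prepare_stats(dataset: LongDataset) -> _Stats:
    dataset.validate()
    df = dataset.data.sort_values(
        ["group_id", "individual_id", "time"], kind="mergesort"
    )
    T = dataset.n_timepoints
    y = df["y"].to_numpy(float)
    x = df["x"].to_numpy(float)
    z = df["z"].to_numpy(float)
    t = df["time"].to_numpy(float)
    gid = df["group_id"].to_numpy()

    n_obs = y.size
    n_ind = n_obs // T
    X = np.column_stack([np.ones(n_obs), z, x, t, t * z, t * x])
    W = np.concatenate([X, y[:, None]], axis=1).reshape(n_ind, T, 7)

    x_ind = x.reshape(n_ind, T)[:, 0]
    z_ind = z.reshape(n_ind, T)[:, 0]
    gid_ind = gid.reshape(n_ind, T)[:, 0]
    # individuals are sorted by group; locate group boundaries
    starts = np.flatnonzero(np.r_[True, gid_ind[1:] != gid_ind[:-1]])
    group_of_ind = np.cumsum(np.r_[False, gid_ind[1:] != gid_ind[:-1]])
    J = starts.size

    WW = np.einsum("iak,ibl->iabkl", W, W)
    C = np.add.reduceat(WW, starts, axis=0)
    Dp = np.stack([W, W * x_ind[:, None, None]], axis=1)
    D = np.add.reduceat(Dp, starts, axis=0)
    counts = np.diff(np.r_[starts, n_ind]).astype(float)
    sx = np.add.reduceat(x_ind, starts)
    sxx = np.add.reduceat(x_ind**2, starts)
    xm = np.column_stack([counts, sx, sxx])

    Z2 = np.column_stack([np.ones(T), np.arange(T, dtype=float)])
    return _Stats(
        T=T, J=J, n_obs=n_obs, Z2=Z2, C=C, D=D, xm=xm,
        y_ind=y.reshape(n_ind, T), x_ind=x_ind, z_ind=z_ind,
        group_of_ind=group_of_ind,
    )


def _profile_eval(stats: _Stats, sigma2_e: float, G2: np.ndarray, G3: np.ndarray):
    """Profiled likelihood pieces at one variance-parameter point.

    Returns ``(loglik, gamma_hat, XtVinvX)`` or ``None`` when the
    implied covariance is not positive definite (infeasible point).
    """
    T, J = stats.T, stats.J
    B = sigma2_e * np.eye(T) + stats.Z2 @ G2 @ stats.Z2.T
    try:
        cB = np.linalg.cholesky(B)
    except np.linalg.LinAlgError:
        return None
    logdetB = 2.0 * float(np.sum(np.log(np.diag(cB))))
    Binv = sla.cho_solve((cB, True), np.eye(T), check_finite=False)

    M = stats.Z2.T @ Binv @ stats.Z2          # (2, 2)
    P = stats.Z2.T @ Binv                     # (2, T)

    T1 = np.einsum("ab,jabkl->jkl", Binv, stats.C)      # (J, 7, 7)
    Q = np.einsum("ca,jpal->jpcl", P, stats.D)          # (J, 2, 2, 7)
    U = np.empty((J, 4, 7))
    U[:, 0] = Q[:, 0, 0]   # 1        -> u00
    U[:, 1] = Q[:, 1, 0]   # x        -> u01
    U[:, 2] = Q[:, 0, 1]   # t        -> u10
    U[:, 3] = Q[:, 1, 1]   # x*t      -> u11

    Nj = np.empty((J, 2, 2))
    Nj[:, 0, 0] = stats.xm[:, 0]
    Nj[:, 0, 1] = Nj[:, 1, 0] = stats.xm[:, 1]
    Nj[:, 1, 1] = stats.xm[:, 2]
    S = np.einsum("cd,jef->jcedf", M, Nj).reshape(J, 4, 4)

    G3S = np.matmul(G3, S)
    # V_j is PD iff B is PD and every eigenvalue of G3 S_j exceeds -1
    # (they are real: G3 S_j shares its nonzero spectrum with a
    # symmetric congruence of G3).  When G3 is PSD this holds trivially.
    diag3 = np.diag(G3)
    psd_fast = np.all(diag3 >= 0.0) and np.allclose(G3, np.diag(diag3))
    if not psd_fast:
        # a margin keeps iterates strictly inside the PD region; the
        # likelihood diverges at the boundary and its numerical
        # derivatives are meaningless in the last few ulps before it
        eig = np.linalg.eigvals(G3S)
        if np.any(eig.real <= -1.0 + 1e-6):
            return None
    F = np.eye(4)[None, :, :] + G3S
    sign, logdetF = np.linalg.slogdet(F)
    if np.any(sign <= 0.0):
        return None

    G3U = np.matmul(G3, U)
    K = np.linalg.solve(F, G3U)
    corr = np.einsum("jak,jal->jkl", U, K)
    Gtot = (T1 - corr).sum(axis=0)
    Gtot = 0.5 * (Gtot + Gtot.T)

    XtVX = Gtot[:6, :6]
    XtVy = Gtot[:6, 6]
    ytVy = Gtot[6, 6]
    try:
        cX = sla.cho_factor(XtVX, check_finite=False)
    except (np.linalg.LinAlgError, sla.LinAlgError):
        return None
    gamma = sla.cho_solve(cX, XtVy, check_finite=False)
    quad = ytVy - 2.0 * gamma @ XtVy + gamma @ XtVX @ gamma

    logdetV = float((stats.xm[:, 0] * logdetB).sum() + logdetF.sum())
    ll = -0.5 * (stats.n_obs * _LOG_2PI + logdetV + quad)
    return float(ll), gamma, XtVX


def profile_loglik(
    theta: np.ndarray | VarianceComponents,
    dataset: LongDataset,
    spec: ModelSpec | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Profiled marginal log-likelihood at variance parameters ``theta``.

    Returns ``(loglik, gls_fixed_effects, gls_cov_of_fixed)`` where the
    fixed effects are the GLS solution at ``theta`` and their covariance
    is ``(sum_j X_j' V_j^-1 X_j)^-1``.  Raises :class:`DesignError` when
    the covariance implied by ``theta`` is not positive definite.
    """
    spec = spec or ModelSpec()
    if isinstance(theta, VarianceComponents):
        theta = spec.pack(theta)
    sigma2_e, G2, G3 = spec.unpack(np.asarray(theta, dtype=float))
    stats = _prepare_stats(dataset)
    out = _profile_eval(stats, sigma2_e, G2, G3)
    if out is None:
        raise DesignError("covariance not positive definite at theta")
    ll, gamma, XtVX = out
    cov = np.linalg.inv(XtVX)
    return ll, gamma, cov


# ---------------------------------------------------------------------------
# starting values
# ---------------------------------------------------------------------------

def _moment_start(stats: _Stats, spec: ModelSpec, floor: float) -> np.ndarray:
    """Moment-based starting values on the variance scale.

    Per-individual OLS growth lines give level-1 residual variance and
    noisy intercept/slope measurements; their within- and between-group
    moments, corrected for OLS sampling noise, seed the level-2 and
    level-3 variances.  Group-level covariate-slope variances start at
    a small positive constant.
    """
    T = stats.T
    Z2 = stats.Z2
    A = np.linalg.solve(Z2.T @ Z2, Z2.T)          # (2, T) OLS operator
    b = stats.y_ind @ A.T                          # (N_ind, 2) intercept, slope
    resid = stats.y_ind - b @ Z2.T
    dof = stats.y_ind.shape[0] * (T - 2)
    sigma2_e0 = max(float((resid**2).sum()) / max(dof, 1), floor)
    # sampling variance of the OLS intercept/slope at sigma2_e0
    cmat = sigma2_e0 * np.linalg.inv(Z2.T @ Z2)
    # remove fixed covariate effects from the growth coefficients
    Xb = np.column_stack([np.ones(b.shape[0]), stats.z_ind, stats.x_ind])
    coef, *_ = np.linalg.lstsq(Xb, b, rcond=None)
    bres = b - Xb @ coef

    start = np.full(spec.n_parameters(), 0.0)
    start[0] = sigma2_e0
    g = stats.group_of_ind
    for k in range(2):                             # 0: intercept, 1: slope
        v = bres[:, k]
        means = np.bincount(g, weights=v) / np.bincount(g)
        within = v - means[g]
        n_ind, J = v.size, means.size
        w_var = float((within**2).sum()) / max(n_ind - J, 1)
        level2 = max(w_var - cmat[k, k], floor)
        nbar = n_ind / J
        b_var = float(np.var(means, ddof=1)) if J > 1 else 0.0
        level3 = max(b_var - w_var / nbar, floor)
        start[1 + k] = level2                      # sigma2_r0 / sigma2_r1
        start[3 + 2 * k] = level3                  # sigma2_u00 / sigma2_u10
    start[4] = start[6] = max(0.05, floor)         # sigma2_u01 / sigma2_u11
    return start


# ---------------------------------------------------------------------------
# quasi-Newton optimizer with monotone backtracking line search
# ---------------------------------------------------------------------------

@dataclass
class _OptResult:
    x: np.ndarray
    f: float
    n_iter: int
    success: bool
    message: str


def _num_grad(fun, x, f0, rel_step):
    g = np.empty_like(x)
    for k in range(x.size):
        h = rel_step * (abs(x[k]) + 0.1)
        xp = x.copy(); xp[k] += h
        xm = x.copy(); xm[k] -= h
        fp, fm = fun(xp), fun(xm)
        if np.isfinite(fp) and np.isfinite(fm):
            g[k] = (fp - fm) / (2.0 * h)
        elif np.isfinite(fp):
            g[k] = (fp - f0) / h
        elif np.isfinite(fm):
            g[k] = (f0 - fm) / h
        else:
            g[k] = 0.0
    return g


def _minimize_qn(fun, x0, *, tol, max_iter, grad_step):
    """BFGS with Armijo backtracking; infeasible points are rejected.

    Accepted iterates never increase the objective, and convergence is
    declared after two consecutive accepted steps whose relative
    objective change falls below ``tol``.
    """
    x = np.asarray(x0, dtype=float)
    f = fun(x)
    if not np.isfinite(f):
        return _OptResult(x, np.inf, 0, False, "infeasible starting point")
    g = _num_grad(fun, x, f, grad_step)
    H = np.eye(x.size)
    small_count = 0
    for it in range(1, max_iter + 1):
        p = -H @ g
        gp = float(g @ p)
        if not np.isfinite(gp) or gp >= 0.0:
            H = np.eye(x.size)
            p = -g
            gp = float(g @ p)
            if gp >= 0.0:
                return _OptResult(x, f, it, True, "gradient vanished")
        def backtrack(direction, slope):
            alpha = 1.0
            for _ in range(60):
                f_try = fun(x + alpha * direction)
                if np.isfinite(f_try) and f_try <= f + 1e-4 * alpha * slope:
                    return alpha, f_try
                alpha *= 0.5
            return None, None

        alpha, f_new = backtrack(p, gp)
        if alpha is None and not np.array_equal(p, -g):
            # quasi-Newton direction failed: restart from steepest descent
            H = np.eye(x.size)
            p = -g
            gp = float(g @ p)
            alpha, f_new = backtrack(p, gp)
        if alpha is None:
            # no descent possible along the gradient: at the noise floor
            return _OptResult(x, f, it, True, "converged (line search floor)")
        x_new = x + alpha * p
        g_new = _num_grad(fun, x_new, f_new, grad_step)
        s = x_new - x
        yv = g_new - g
        sy = float(s @ yv)
        if sy > 1e-10 * float(np.linalg.norm(s) * np.linalg.norm(yv) + 1e-300):
            rho = 1.0 / sy
            I = np.eye(x.size)
            V = I - rho * np.outer(s, yv)
            H = V @ H @ V.T + rho * np.outer(s, s)
        df = f - f_new
        x, f, g = x_new, f_new, g_new
        if df <= tol * (1.0 + abs(f)):
            small_count += 1
            if small_count >= 2:
                return _OptResult(x, f, it, True, "converged")
        else:
            small_count = 0
    return _OptResult(x, f, max_iter, False, "maximum iterations reached")


# ---------------------------------------------------------------------------
# observed information
# ---------------------------------------------------------------------------

def _numerical_hessian(fun, x, rel_step):
    """Central-difference Hessian; shrinks steps that hit infeasibility.

    Returns ``None`` when finite evaluations cannot be obtained.
    """
    k = x.size
    h = rel_step * (np.abs(x) + 0.1)
    f0 = fun(x)
    if not np.isfinite(f0):
        return None

    def eval_shift(*shifts):
        xp = x.copy()
        for idx, step in shifts:
            xp[idx] += step
        return fun(xp)

    # per-coordinate steps small enough to stay feasible
    for i in range(k):
        for _ in range(4):
            if np.isfinite(eval_shift((i, h[i]))) and np.isfinite(
                eval_shift((i, -h[i]))
            ):
                break
            h[i] /= 5.0
        else:
            return None

    H = np.empty((k, k))
    for i in range(k):
        fp = eval_shift((i, h[i]))
        fm = eval_shift((i, -h[i]))
        H[i, i] = (fp - 2.0 * f0 + fm) / h[i] ** 2
        for j in range(i + 1, k):
            fpp = eval_shift((i, h[i]), (j, h[j]))
            fpm = eval_shift((i, h[i]), (j, -h[j]))
            fmp = eval_shift((i, -h[i]), (j, h[j]))
            fmm = eval_shift((i, -h[i]), (j, -h[j]))
            if not all(np.isfinite(v) for v in (fpp, fpm, fmp, fmm)):
                return None
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


# ---------------------------------------------------------------------------
# the full fit
# ---------------------------------------------------------------------------

def _failed_result(names, n_obs, n_groups, message, dataset=None) -> FitResult:
    nan = float("nan")
    all_names = tuple(FIXED_EFFECT_NAMES) + tuple(names)
    return FitResult(
        estimates={n: nan for n in all_names},
        std_errors={n: nan for n in all_names},
        p_values={n: nan for n in all_names},
        conf_ints={n: (nan, nan) for n in all_names},
        loglik=nan,
        converged=False,
        admissible=False,
        optimizer_status=message,
        n_iter=0,
        n_obs=n_obs,
        n_groups=n_groups,
        parameter_names=all_names,
        condition_label=getattr(dataset, "condition_label", ""),
        replication=getattr(dataset, "replication", -1),
        seed=getattr(dataset, "seed", None),
    )


def fit_ml(
    dataset: LongDataset,
    spec: ModelSpec | None = None,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit the three-level growth model by maximum likelihood.

    Maximizes the profiled log-likelihood over the variance parameters
    from moment-based starting values.  Fixed-effect standard errors
    come from the GLS covariance at the optimum; variance-parameter
    standard errors from the inverse of a central-difference observed
    information of the profiled log-likelihood.  Wald z-statistics use
    the standard-normal reference and 95% confidence intervals are
    symmetric on the estimation scale for every parameter.

    Data-driven failures (too few groups, constant outcome, optimizer
    breakdown) yield a :class:`FitResult` with ``converged=False``;
    exceptions are reserved for malformed inputs.
    """
    spec = spec or ModelSpec()
    options = options or FitOptions()
    names = spec.parameter_names

    try:
        stats = _prepare_stats(dataset)
    except DesignError:
        raise
    n_obs, J = getattr(stats, "n_obs", 0), getattr(stats, "J", 0)
    if J < 2:
        return _failed_result(names, n_obs, J, "fewer than 2 groups", dataset)
    if float(np.var(stats.y_ind)) == 0.0:
        return _failed_result(names, n_obs, J, "constant outcome", dataset)

    def objective(theta):
        sigma2_e, G2, G3 = spec.unpack(theta)
        out = _profile_eval(stats, sigma2_e, G2, G3)
        if out is None:
            return np.inf
        return -out[0]

    x0 = _moment_start(stats, spec, options.start_floor)
    opt = _minimize_qn(
        objective,
        x0,
        tol=options.tol,
        max_iter=options.max_iter,
        grad_step=options.grad_step,
    )

    theta_hat = opt.x
    sigma2_e, G2, G3 = spec.unpack(theta_hat)
    out = _profile_eval(stats, sigma2_e, G2, G3)
    if out is None or not np.isfinite(opt.f):
        return _failed_result(names, n_obs, J, opt.message, dataset)
    ll, gamma, XtVX = out

    try:
        cov_gamma = np.linalg.inv(XtVX)
        fixed_ok = bool(np.all(np.diag(cov_gamma) > 0.0))
    except np.linalg.LinAlgError:
        cov_gamma = np.full((6, 6), np.nan)
        fixed_ok = False

    info_ok = True
    theta_se = np.full(theta_hat.size, np.nan)
    if options.compute_hessian:
        H = _numerical_hessian(objective, theta_hat, options.hess_step)
        if H is None:
            info_ok = False
        else:
            try:
                cH = sla.cho_factor(0.5 * (H + H.T), check_finite=False)
                cov_theta = sla.cho_solve(cH, np.eye(theta_hat.size))
                diag = np.diag(cov_theta)
                if np.any(diag <= 0.0):
                    info_ok = False
                else:
                    theta_se = np.sqrt(diag)
            except (np.linalg.LinAlgError, sla.LinAlgError):
                info_ok = False

    estimates: dict[str, float] = {}
    std_errors: dict[str, float] = {}
    for i, n in enumerate(FIXED_EFFECT_NAMES):
        estimates[n] = float(gamma[i])
        std_errors[n] = float(np.sqrt(cov_gamma[i, i])) if fixed_ok else np.nan
    for i, n in enumerate(names):
        estimates[n] = float(theta_hat[i])
        std_errors[n] = float(theta_se[i])

    p_values: dict[str, float] = {}
    conf_ints: dict[str, tuple[float, float]] = {}
    for n, est in estimates.items():
        se = std_errors[n]
        if np.isfinite(se) and se > 0.0:
            zstat = est / se
            p_values[n] = float(2.0 * sps.norm.sf(abs(zstat)))
            conf_ints[n] = (est - _Z_975 * se, est + _Z_975 * se)
        else:
            p_values[n] = np.nan
            conf_ints[n] = (np.nan, np.nan)

    converged = bool(opt.success and info_ok and fixed_ok)
    admissible = bool(all(estimates[n] >= 0.0 for n in VARIANCE_NAMES))
    return FitResult(
        estimates=estimates,
        std_errors=std_errors,
        p_values=p_values,
        conf_ints=conf_ints,
        loglik=float(ll),
        converged=converged,
        admissible=admissible,
        optimizer_status=opt.message,
        n_iter=opt.n_iter,
        n_obs=n_obs,
        n_groups=J,
        parameter_names=tuple(FIXED_EFFECT_NAMES) + tuple(names),
        condition_label=dataset.condition_label,
        replication=dataset.replication,
        seed=dataset.seed,
    )
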