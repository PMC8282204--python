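"""Brute-force reference computations used only by the test suite.

These deliberately share no code with the estimation path: the dense
likelihood enumerates every random-effect contribution pair by pair and
feeds the full N x N covariance to a stock multivariate-normal density,
and the moment decomposition is a plain ANOVA-style estimator.  They
are slow and size-guarded on purpose.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .design import DesignError, FixedEffects, VarianceComponents
from .simulate import LongDataset

__all__ = ["dense_loglik", "moment_decomposition"]

_MAX_DENSE_OBS = 500


def dense_loglik(
    dataset: LongDataset,
    fixed: FixedEffects | np.ndarray,
    vc: VarianceComponents,
) -> float:
    """Multivariate-normal log-density of the full stacked outcome.

    The mean is ``X gamma`` at the supplied fixed effects and the
    covariance is assembled entry by entry from the random-effect
    structure (no blocking, profiling or factorization shortcuts).
    Refuses datasets with more than 500 observations.
    """
    df = dataset.data.sort_values(
        ["group_id", "individual_id", "time"], kind="mergesort"
    )
    n = len(df)
    if n > _MAX_DENSE_OBS:
        raise DesignError(f"dense oracle limited to {_MAX_DENSE_OBS} observations")

    g = df["group_id"].to_numpy()
    ind = df["individual_id"].to_numpy()
    t = df["time"].to_numpy(float)
    x = df["x"].to_numpy(float)
    z = df["z"].to_numpy(float)
    y = df["y"].to_numpy(float)

    if isinstance(fixed, FixedEffects):
        gamma = np.asarray(fixed.as_tuple())
    else:
        gamma = np.asarray(fixed, dtype=float)
    X = np.column_stack([np.ones(n), z, x, t, t * z, t * x])
    mean = X @ gamma

    G3 = np.full((4, 4), vc.sigma_u_offdiag)
    np.fill_diagonal(
        G3, [vc.sigma2_u00, vc.sigma2_u01, vc.sigma2_u10, vc.sigma2_u11]
    )
    G2 = np.array([[vc.sigma2_r0, vc.sigma_r01], [vc.sigma_r01, vc.sigma2_r1]])

    V = np.zeros((n, n))
    for a in range(n):
        za = np.array([1.0, x[a], t[a], x[a] * t[a]])
        wa = np.array([1.0, t[a]])
        for b in range(n):
            cov = 0.0
            if g[a] == g[b]:
                zb = np.array([1.0, x[b], t[b], x[b] * t[b]])
                cov += za @ G3 @ zb
                if ind[a] == ind[b]:
                    wb = np.array([1.0, t[b]])
                    cov += wa @ G2 @ wb
                    if t[a] == t[b]:
                        cov += vc.sigma2_e
            V[a, b] = cov
    return float(
        sps.multivariate_normal.logpdf(y, mean=mean, cov=V, allow_singular=True)
    )


def moment_decomposition(dataset: LongDataset) -> tuple[float, float, float]:
    """ANOVA-style estimates of the intercept-pathway variances.

    Removes the fixed covariate effects by pooled OLS, fits each
    individual's growth line, and splits the intercept variation into
    within-individual (level 1), between-individual-within-group
    (level 2) and between-group (level 3) parts using mean squares.
    Returns ``(level1, level2, level3)`` variance estimates.
    """
    df = dataset.data.sort_values(
        ["group_id", "individual_id", "time"], kind="mergesort"
    )
    T = dataset.n_timepoints
    t = df["time"].to_numpy(float)
    x = df["x"].to_numpy(float)
    z = df["z"].to_numpy(float)
    y = df["y"].to_numpy(float)
    g = df["group_id"].to_numpy()

    X = np.column_stack([np.ones(len(df)), z, x, t, t * z, t * x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    e = (y - X @ beta).reshape(-1, T)

    n_ind = e.shape[0]
    g_ind = g.reshape(-1, T)[:, 0]
    groups, g_idx = np.unique(g_ind, return_inverse=True)
    J = groups.size
    if J < 2 or n_ind < 2 * J:
        raise DesignError("need >= 2 groups and >= 2 individuals per group")

    tt = np.arange(T, dtype=float)
    Z2 = np.column_stack([np.ones(T), tt])
    A = np.linalg.solve(Z2.T @ Z2, Z2.T)
    b = e @ A.T                                   # per-individual lines
    resid = e - b @ Z2.T
    sigma2_e = float((resid**2).sum()) / (n_ind * (T - 2))

    # intercepts carry OLS noise c0 * sigma2_e
    c0 = sigma2_e * np.linalg.inv(Z2.T @ Z2)[0, 0]
    b0 = b[:, 0]
    counts = np.bincount(g_idx).astype(float)
    means = np.bincount(g_idx, weights=b0) / counts
    within = b0 - means[g_idx]
    ms_within = float((within**2).sum()) / (n_ind - J)
    sigma2_r0 = ms_within - c0
    grand = float(b0.mean())
    ms_between = float((counts * (means - grand) ** 2).sum()) / (J - 1)
    # E[ms_between] ~ n0 * sigma2_u00 + (sigma2_r0 + c0) with
    # n0 the ANOVA effective group size
    n0 = (counts.sum() - (counts**2).sum() / counts.sum()) / (J - 1)
    sigma2_u00 = (ms_between - ms_within) / n0
    return sigma2_e, sigma2_r0, sigma2_u00
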