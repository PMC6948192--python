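"""Maximum-entropy solver for linear inverse problems with positivity.

Solves problems of the form: among all non-negative amplitude vectors p with
model y_hat = A @ p fitting the data to a target reduced chi-square, pick the
one closest to a prior m by the generalized (Skilling) entropy

    S(p) = sum_i [ p_i - m_i - p_i * ln(p_i / m_i) ]

which is maximal (0) at p = m and requires no normalization of p.  The
stationarity condition of S - lambda * chi2/2 is the multiplicative fixed
point p_i = m_i * exp(-lambda * g_i) with g = d(chi2/2)/dp; the solver
iterates this update with log-space damping at fixed lambda and bisects
lambda on the chi-square constraint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MaxEntResult", "maxent_fit", "MaxEntError"]


class MaxEntError(RuntimeError):
    """Raised when the maximum-entropy iteration fails to converge."""

    def __init__(self, message: str, chi2: float | None = None):
        super().__init__(message)
        self.chi2 = chi2


@dataclass
class MaxEntResult:
    p: np.ndarray
    chi2: float
    lam: float
    n_iter: int
    entropy: float


_EXP_CLIP = 200.0


def _entropy(p: np.ndarray, m: np.ndarray) -> float:
    ratio = np.where(p > 0, p / m, 1.0)
    return float(np.sum(p - m - p * np.log(ratio)))


def _solve_at_lambda(
    A: np.ndarray,
    y: np.ndarray,
    w2: np.ndarray,
    m: np.ndarray,
    lam: float,
    p0: np.ndarray,
    max_iter: int,
    rtol: float,
) -> tuple[np.ndarray, float, int]:
    """Minimize lam*chi2/2 - S at fixed lambda.  w2 = 1/(N*sigma^2).

    The Lagrangian is convex in p; it is minimized over u = ln p (which
    keeps p positive) by L-BFGS with the analytic gradient
    grad_u = p * (lam * d(chi2/2)/dp + ln(p/m)).
    """
    from scipy.optimize import minimize

    logm = np.log(m)
    AtW = (A * w2[:, None]).T  # A^T diag(w2)

    def objective(u: np.ndarray):
        p = np.exp(u)
        resid = y - A @ p
        chi2_half = 0.5 * float(np.sum(w2 * resid**2))
        # generalized entropy S = sum(p - m - p ln(p/m))
        s = float(np.sum(p - m - p * (u - logm)))
        g_p = -(AtW @ resid)  # d(chi2/2)/dp
        grad_u = p * (lam * g_p + (u - logm))
        return lam * chi2_half - s, grad_u

    u0 = np.clip(np.log(np.maximum(p0, 1e-300)), logm - _EXP_CLIP, logm + _EXP_CLIP)
    bounds = [(lm - _EXP_CLIP, lm + _EXP_CLIP) for lm in logm]
    res = minimize(objective, u0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": max_iter, "ftol": rtol * 1e-3,
                            "gtol": 1e-12})
    p = np.exp(res.x)
    resid = y - A @ p
    chi2 = float(np.sum(w2 * resid**2))
    return p, chi2, int(res.nit)


def maxent_fit(
    A: np.ndarray,
    y: np.ndarray,
    sigma: np.ndarray | None,
    prior: np.ndarray,
    chi2_target: float | None = 1.0,
    max_iter: int = 10_000,
    rtol: float = 1e-6,
    lam_tol: float = 1e-3,
) -> MaxEntResult:
    """Fit y ~ A @ p by maximum entropy relative to ``prior``.

    Parameters
    ----------
    A : (n_obs, n_par) design matrix
    y : observations
    sigma : per-point errors; ``None`` means unit weights (chi2 then carries
        the squared data units)
    prior : positive prior amplitudes m (sets the scale of the solution)
    chi2_target : reduced chi-square at which to stop regularizing.  ``None``
        tightens the fit until the residual RMS stops improving (used for
        error estimation on data without trusted sigmas).

    Returns
    -------
    MaxEntResult with the amplitude vector, achieved reduced chi-square,
    final lambda, iteration count and entropy.
    """
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float)
    n_obs = y.size
    if sigma is None:
        w2 = np.full(n_obs, 1.0 / n_obs)
    else:
        sigma = np.asarray(sigma, dtype=float)
        w2 = 1.0 / (n_obs * sigma**2)
    m = np.asarray(prior, dtype=float).copy()
    if np.any(m <= 0):
        raise ValueError("prior must be strictly positive")

    # chi2 of the prior itself; lambda=0 returns the prior.
    resid0 = y - A @ m
    chi2_prior = float(np.sum(w2 * resid0**2))

    if chi2_target is not None and chi2_prior <= chi2_target:
        return MaxEntResult(m.copy(), chi2_prior, 0.0, 0, 0.0)

    # Scale-aware initial lambda: lambda * |g| should perturb log p by O(1).
    g0 = np.abs((A * w2[:, None]).T @ resid0)
    gmax = float(np.max(g0)) if np.max(g0) > 0 else 1.0
    lam = 0.1 / gmax

    p = m.copy()
    chi2 = chi2_prior
    total_iter = 0

    if chi2_target is None:
        # Tighten until the residual RMS plateaus (relative change < 0.5%).
        prev_rms = np.sqrt(chi2)
        for _ in range(60):
            lam *= 2.0
            p_try, chi2_try, it = _solve_at_lambda(A, y, w2, m, lam, p, max_iter, rtol)
            total_iter += it
            rms = np.sqrt(chi2_try)
            p, chi2 = p_try, chi2_try
            if prev_rms > 0 and (prev_rms - rms) / prev_rms < 5e-3:
                break
            prev_rms = rms
        return MaxEntResult(p, chi2, lam, total_iter, _entropy(p, m))

    # Grow lambda until the constraint is met, then bisect.
    lam_lo, lam_hi = 0.0, None
    p_lo = m.copy()
    for _ in range(60):
        p_try, chi2_try, it = _solve_at_lambda(A, y, w2, m, lam, p, max_iter, rtol)
        total_iter += it
        if chi2_try <= chi2_target:
            lam_hi, p_hi, chi2_hi = lam, p_try, chi2_try
            break
        lam_lo, p_lo, chi2_lo = lam, p_try, chi2_try
        p = p_try
        lam *= 4.0
    else:
        raise MaxEntError(
            f"chi2 target {chi2_target:.4g} unreachable; best achieved "
            f"{chi2_try:.4g}", chi2=chi2_try,
        )

    # Bisection on lambda for |chi2 - target|/target < lam_tol.
    for _ in range(100):
        if abs(chi2_hi - chi2_target) / chi2_target < lam_tol:
            break
        lam_mid = 0.5 * (lam_lo + lam_hi)
        p_mid, chi2_mid, it = _solve_at_lambda(A, y, w2, m, lam_mid, p_hi, max_iter, rtol)
        total_iter += it
        if chi2_mid <= chi2_target:
            lam_hi, p_hi, chi2_hi = lam_mid, p_mid, chi2_mid
        else:
            lam_lo, p_lo = lam_mid, p_mid
    return MaxEntResult(p_hi, chi2_hi, lam_hi, total_iter, _entropy(p_hi, m))
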