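"""SEC-SAXS frame-series decomposition and error estimation.

During size-exclusion chromatography every exposure frame is a linear
mixture of protein and buffer scattering whose proportions vary across the
elution peak.  ``svd_reconstruct`` recovers the pure protein component by
singular value decomposition of the peak + buffer frame submatrix followed
by a linear combination of the significant components chosen so that the
low-q Guinier region of the combination is maximally linear (SVD-LC).

``estimate_errors`` assigns per-point errors to a reconstructed profile as
the root-mean-square deviation of the residuals of a maximum-entropy P(r)
fit, which sidesteps error propagation through the SVD.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import minimize_scalar

from .basic import invert_pr_mem
from .profile import FrameSeries, RegionSpec, SaxsProfile

__all__ = ["svd_reconstruct", "select_rank", "estimate_errors"]


def _lag1_autocorr(v: np.ndarray) -> float:
    v = v - v.mean()
    denom = float(np.dot(v, v))
    if denom == 0:
        return 0.0
    return float(np.dot(v[:-1], v[1:]) / denom)


def select_rank(
    singular_values: np.ndarray,
    right_vectors: np.ndarray,
    sv_frac: float = 0.05,
    ac_min: float = 0.5,
) -> int:
    """Number of significant SVD components.

    A component is significant when its singular value exceeds ``sv_frac``
    of the largest AND its right singular vector (the q-space shape) has a
    lag-1 autocorrelation above ``ac_min`` — noise components decorrelate
    point to point while physical spectra are smooth in q.
    """
    s = np.asarray(singular_values, dtype=float)
    keep = 0
    for k in range(s.size):
        if s[k] < sv_frac * s[0]:
            break
        if _lag1_autocorr(right_vectors[k]) < ac_min:
            break
        keep += 1
    return max(keep, 1)


def _guinier_window_cost(q: np.ndarray, I: np.ndarray, n_window: int) -> float:
    from ._linearity import guinier_linearity_cost

    return guinier_linearity_cost(q, I, fixed_window=n_window)


def svd_reconstruct(
    series: FrameSeries,
    regions: RegionSpec,
    rank: int | str = "auto",
    n_window: int = 30,
) -> SaxsProfile:
    """Reconstruct the protein scattering profile by SVD-LC.

    Parameters
    ----------
    series : FrameSeries
    regions : RegionSpec
        Frame indices of the elution main peak and of a buffer region.
    rank : int or "auto"
        Number of SVD components to retain; "auto" applies
        :func:`select_rank`.
    n_window : int
        Number of low-q points over which Guinier linearity is optimized.

    Returns
    -------
    SaxsProfile scaled to the protein amplitude of the strongest peak frame
    (no sigma; see :func:`estimate_errors`).
    """
    regions.validate(series.n_frames)
    sel = list(regions.peak_frames) + list(regions.buffer_frames)
    M = series.frames[sel]  # (n_sel, n_q)
    U, s, Vt = np.linalg.svd(M, full_matrices=False)

    if rank == "auto":
        r = select_rank(s, Vt)
    else:
        r = int(rank)
        if r < 1 or r > len(sel):
            raise ValueError(f"rank must be in [1, {len(sel)}]")
    if s[0] == 0 or (r > 1 and s[r - 1] < 1e-12 * s[0]):
        warnings.warn("frame submatrix is rank deficient; reducing rank")
        r = max(1, int(np.sum(s > 1e-12 * s[0])))

    V = Vt[:r]  # (r, n_q) orthonormal q-space components
    q = series.q

    # Initial direction: projection of (mean peak - mean buffer) onto span(V).
    diff = series.frames[list(regions.peak_frames)].mean(axis=0) - \
        series.frames[list(regions.buffer_frames)].mean(axis=0)
    c0 = V @ diff
    norm0 = np.linalg.norm(c0)
    if norm0 == 0:
        c0 = np.eye(r)[0]
    else:
        c0 = c0 / norm0

    # Freeze the Guinier window from the plain buffer-subtracted estimate so
    # every candidate direction is judged over the same q points.
    from ._linearity import guinier_window

    I_init = c0 @ V
    if I_init[:10].sum() < 0:
        I_init = -I_init
    n_window = guinier_window(q, I_init, n_start=min(n_window, q.size))

    # Noise floor of the linearity objective: the sub-rank residual of the
    # selected frames estimates the per-point noise; the candidate profile
    # averages n_sel frames, and the objective is a mean squared ln-residual.
    resid_frames = M - (U[:, :r] * s[:r]) @ V
    sigma_pt = np.sqrt(np.mean(resid_frames**2, axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = sigma_pt[:n_window] / np.maximum(np.abs(I_init[:n_window]), 1e-300)
    cost_floor = float(np.mean(rel**2)) * r / len(sel)

    def direction_cost(c_: np.ndarray) -> float:
        nrm = np.linalg.norm(c_)
        if nrm == 0:
            return 1e9
        I = (c_ / nrm) @ V
        if I[:n_window].sum() < 0:
            I = -I
        return _guinier_window_cost(q, I, n_window)

    if r == 1:
        c = c0
    else:
        if r == 2:
            perp = np.array([-c0[1], c0[0]])

            def at(theta: float) -> np.ndarray:
                return np.cos(theta) * c0 + np.sin(theta) * perp
        else:
            from scipy.optimize import minimize as _minimize

            res = _minimize(direction_cost, c0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12,
                                     "maxiter": 5000})
            c_opt = res.x / np.linalg.norm(res.x)
            # reduce to one angle: rotate from c0 toward the optimum
            perp = c_opt - np.dot(c_opt, c0) * c0
            nperp = np.linalg.norm(perp)
            if nperp < 1e-15:
                perp = None
            else:
                perp = perp / nperp

            def at(theta: float) -> np.ndarray:
                if perp is None:
                    return c0
                return np.cos(theta) * c0 + np.sin(theta) * perp

        def cost_theta(theta: float) -> float:
            return direction_cost(at(theta))

        thetas = np.linspace(-np.pi / 2, np.pi / 2, 361)
        costs = np.array([cost_theta(t) for t in thetas])
        ig = int(np.argmin(costs))
        res = minimize_scalar(
            cost_theta,
            bounds=(thetas[max(ig - 1, 0)], thetas[min(ig + 1, len(thetas) - 1)]),
            method="bounded", options={"xatol": 1e-12})
        theta_g = float(res.x)
        cost_min = float(res.fun)
        # parabolic-vertex polish: the cost is locally quadratic in theta,
        # so a few vertex steps refine the minimizer to near machine precision
        for h in (1e-5, 1e-7, 1e-9):
            c0_, cm, cp_ = (cost_theta(theta_g), cost_theta(theta_g - h),
                            cost_theta(theta_g + h))
            denom = cp_ - 2.0 * c0_ + cm
            if denom <= 0:
                continue
            step = -h * (cp_ - cm) / (2.0 * denom)
            if abs(step) < 2.0 * h and cost_theta(theta_g + step) <= c0_:
                theta_g += step
        cost_min = cost_theta(theta_g)

        # Among directions whose objective is within the noise floor of the
        # minimum, prefer the one closest to the plain-subtraction direction
        # (theta = 0): the subtraction direction is statistically unbiased,
        # while the raw minimizer can trade buffer admixture against the
        # intrinsic low-q curvature of a non-Gaussian particle.
        theta_hat = theta_g
        if cost_floor > 0 and theta_g != 0.0:
            if cost_theta(0.0) <= cost_min + cost_floor:
                theta_hat = 0.0
            else:
                # bisect for the admissible boundary nearest theta = 0
                target = cost_min + cost_floor
                a, b = 0.0, theta_g
                for _ in range(60):
                    mid = 0.5 * (a + b)
                    if cost_theta(mid) <= target:
                        b = mid
                    else:
                        a = mid
                theta_hat = b
        c = at(theta_hat)

    I_dir = c @ V
    if I_dir[:n_window].sum() < 0:
        I_dir = -I_dir

    # Scale to the protein amplitude of the strongest peak frame: project
    # buffer-subtracted peak frames onto the protein direction.  (A joint
    # two-basis fit is unstable when the found direction is nearly
    # collinear with the buffer, e.g. on protein-free series.)
    buf_mean = series.frames[list(regions.buffer_frames)].mean(axis=0)
    peak = series.frames[list(regions.peak_frames)] - buf_mean
    amps = peak @ I_dir / float(I_dir @ I_dir)
    a_max = float(np.max(amps))
    return SaxsProfile(q, a_max * I_dir, label="SVD-LC reconstruction")


def estimate_errors(
    profile: SaxsProfile,
    dmax_hint: float,
    n_bins: int | None = None,
) -> SaxsProfile:
    """Assign per-point errors as the RMSD of maximum-entropy fit residuals.

    A P(r) model is fitted to the profile on a 1 Angstrom grid extending
    ~15% beyond ``dmax_hint`` and tightened until the residual RMS plateaus;
    sigma is the constant residual RMSD (or, with ``n_bins``, the RMSD per
    contiguous q bin).
    """
    if dmax_hint <= 0:
        raise ValueError("dmax_hint must be positive")
    pr = invert_pr_mem(
        SaxsProfile(profile.q, profile.intensity, label=profile.label),
        dmax_hint,
        chi2_target=None,
        grid_margin=1.15,
    )
    from .basic import _pr_design

    r, A = _pr_design(profile.q, pr.dmax)
    resid = profile.intensity - A @ pr.p
    if n_bins:
        edges = np.array_split(np.arange(profile.q.size), n_bins)
        sigma = np.empty_like(profile.intensity)
        for block in edges:
            sigma[block] = np.sqrt(np.mean(resid[block] ** 2))
    else:
        sigma = np.full_like(profile.intensity, np.sqrt(np.mean(resid**2)))
    sigma = np.maximum(sigma, 1e-12 * np.max(np.abs(profile.intensity)))
    return profile.with_sigma(sigma)
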