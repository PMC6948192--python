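"""Basic SAXS analyses: Guinier fits, dimensionless Kratky transform,
maximum-dimension estimation and P(r) inversion by maximum entropy.

The pair-distance distribution P(r) is obtained by inverting the discretized
transform

    I(q) = 4 pi * sum_r P(r) * sin(q r) / (q r) * dr

on a real-space grid of 1 Angstrom spacing, selecting among all P >= 0 that
fit the data to a target reduced chi-square the one of maximum informational
entropy relative to a sine prior m(r) ~ sin(pi r / dmax) on 0..pi radians.
The sine prior vanishes at both ends of the support, which encodes the
physical expectation that P(r) decays to zero at r = 0 and r = D_max without
imposing it as a hard constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mem import MaxEntError, maxent_fit
from .profile import SaxsProfile

__all__ = [
    "GuinierResult",
    "GuinierError",
    "PofR",
    "guinier_fit",
    "kratky_dimensionless",
    "estimate_dmax",
    "invert_pr_mem",
    "DmaxScanError",
]


class GuinierError(RuntimeError):
    pass


class DmaxScanError(RuntimeError):
    def __init__(self, message: str, trace: np.ndarray | None = None):
        super().__init__(message)
        self.trace = trace


@dataclass
class GuinierResult:
    """Result of a Guinier fit: R_G, I(0) and the fit window used."""

    rg: float
    i0: float
    q_first: float
    q_last: float
    srg_limit: float
    residual_rms: float
    n_points: int

    @property
    def q_rg_max(self) -> float:
        return self.q_last * self.rg


@dataclass
class PofR:
    """Pair-distance distribution on a 1 Angstrom grid with derived moments.

    rg is computed from the second moment, rg^2 = sum(p r^2 dr) / (2 sum(p dr)),
    and i0 from the zeroth moment, i0 = 4 pi sum(p dr).
    """

    r: np.ndarray
    p: np.ndarray
    dmax: float
    chi2: float
    rg: float = field(init=False)
    i0: float = field(init=False)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        dr = 1.0
        total = float(np.sum(self.p) * dr)
        if total <= 0:
            raise ValueError("P(r) has no mass")
        self.rg = float(np.sqrt(np.sum(self.p * self.r**2) * dr / (2.0 * total)))
        self.i0 = float(4.0 * np.pi * total)

    def normalized(self) -> np.ndarray:
        return self.p / np.sum(self.p)


def _weighted_linefit(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    W = np.sqrt(w)
    Xm = np.column_stack([x * W, W])
    coef, *_ = np.linalg.lstsq(Xm, y * W, rcond=None)
    resid = y - (coef[0] * x + coef[1])
    return coef[0], coef[1], resid


def guinier_fit(
    profile: SaxsProfile,
    srg_limit: float = 1.3,
    q_first: float | None = None,
    reject_outliers: bool = True,
) -> GuinierResult:
    """Weighted linear fit of ln I vs q^2 over the Guinier region.

    The upper window limit is chosen self-consistently so that
    q_last * R_G <= srg_limit.  At most 3 low-q points with studentized
    residuals beyond 4 sigma are discarded when ``reject_outliers``.
    """
    q, I = profile.q, profile.intensity
    mask = I > 0
    if q_first is not None:
        mask &= q >= q_first
    if mask.sum() < 5:
        raise GuinierError("fewer than 5 usable points for a Guinier fit")

    qv, Iv = q[mask], I[mask]
    if profile.has_sigma:
        sv = profile.sigma[mask]
        w_all = (Iv / sv) ** 2  # weights on ln I
        w_all = np.where(np.isfinite(w_all) & (w_all > 0), w_all, 1.0)
    else:
        w_all = np.ones_like(qv)

    # Self-consistent window: iterate q_last <= srg_limit / rg.
    n = min(max(10, 5), qv.size)
    rg = None
    for _ in range(100):
        x = qv[:n] ** 2
        y = np.log(Iv[:n])
        slope, intercept, resid = _weighted_linefit(x, y, w_all[:n])
        if slope >= 0:
            raise GuinierError("no negative Guinier slope found (rising profile)")
        rg_new = float(np.sqrt(-3.0 * slope))
        n_new = int(np.searchsorted(qv, srg_limit / rg_new, side="right"))
        n_new = max(n_new, 5)
        n_new = min(n_new, qv.size)
        if n_new == n and rg is not None and abs(rg_new - rg) / rg < 1e-10:
            break
        rg, n = rg_new, n_new
    rg = rg_new

    drop: list[int] = []
    if reject_outliers and n > 7:
        x = qv[:n] ** 2
        y = np.log(Iv[:n])
        slope, intercept, resid = _weighted_linefit(x, y, w_all[:n])
        s = np.std(resid, ddof=2)
        if s > 0:
            order = np.argsort(-np.abs(resid))
            for i in order:
                if len(drop) >= 3:
                    break
                if abs(resid[i]) > 4.0 * s:
                    drop.append(int(i))
        if drop:
            keep = np.setdiff1d(np.arange(n), drop)
            x, y, ww = x[keep], y[keep], w_all[:n][keep]
            slope, intercept, resid = _weighted_linefit(x, y, ww)
            if slope >= 0:
                raise GuinierError("no negative Guinier slope after outlier rejection")
            rg = float(np.sqrt(-3.0 * slope))

    x = qv[:n] ** 2
    y = np.log(Iv[:n])
    if drop:
        keep = np.setdiff1d(np.arange(n), drop)
    else:
        keep = np.arange(n)
    slope, intercept, resid = _weighted_linefit(x[keep], y[keep], w_all[:n][keep])
    rg = float(np.sqrt(-3.0 * slope))
    return GuinierResult(
        rg=rg,
        i0=float(np.exp(intercept)),
        q_first=float(qv[keep[0]]),
        q_last=float(qv[keep[-1]]),
        srg_limit=srg_limit,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_points=int(keep.size),
    )


def kratky_dimensionless(profile: SaxsProfile, g: GuinierResult) -> tuple[np.ndarray, np.ndarray]:
    """Dimensionless Kratky transform: (q R_G)^2 I(q)/I(0) against q R_G.

    For a globular particle obeying the Guinier law the curve peaks at
    q R_G = sqrt(3) with height 3/e; elongation and flexibility shift and
    raise the maximum.
    """
    if g.i0 <= 0:
        raise ValueError("I(0) must be positive")
    x = profile.q * g.rg
    y = x**2 * profile.intensity / g.i0
    return x, y


def _pr_design(q: np.ndarray, dmax: float) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix of the discretized sine transform on the 1 A r grid."""
    r = np.arange(1.0, np.floor(dmax) + 0.5, 1.0)
    qr = np.outer(q, r)
    with np.errstate(invalid="ignore", divide="ignore"):
        sinc = np.where(qr > 0, np.sin(qr) / qr, 1.0)
    return r, 4.0 * np.pi * sinc  # dr = 1


def invert_pr_mem(
    profile: SaxsProfile,
    dmax: float,
    chi2_target: float | None = 1.0,
    grid_margin: float = 1.0,
) -> PofR:
    """Invert I(q) to P(r) by maximum entropy with a sine prior.

    ``grid_margin`` > 1 extends the r grid beyond dmax (the prior still
    vanishes at the grid end), which is useful when dmax is only a hint.
    Raises MaxEntError when the chi-square target cannot be reached.
    """
    if dmax <= 0:
        raise ValueError("dmax must be positive")
    span = dmax * grid_margin
    r, A = _pr_design(profile.q, span)
    prior = np.sin(np.pi * r / span)
    prior = np.maximum(prior, 1e-6 * prior.max())
    # Scale the prior so its forward model matches the data magnitude.
    yhat = A @ prior
    scale = float(np.dot(profile.intensity, yhat) / np.dot(yhat, yhat))
    prior *= max(scale, 1e-12)

    sigma = profile.sigma if profile.has_sigma else None
    res = maxent_fit(A, profile.intensity, sigma, prior, chi2_target=chi2_target)
    return PofR(r=r, p=res.p, dmax=float(span), chi2=res.chi2)


def _tail_is_clean(p: np.ndarray, frac: float = 0.01, level: float = 1e-3) -> bool:
    """True when < ``frac`` of the P(r) mass lies beyond the last crossing
    of the ``level``*max(p) threshold (no oscillating tail)."""
    thr = level * p.max()
    above = p > thr
    sign_change = np.nonzero(above[:-1] != above[1:])[0]
    if sign_change.size == 0:
        return True
    last = sign_change[-1] + 1
    return float(p[last:].sum()) < frac * float(p.sum())


def estimate_dmax(
    profile: SaxsProfile,
    scan: np.ndarray | tuple[float, float, float],
    chi2_slack: float = 0.05,
) -> float:
    """Scan candidate maximum dimensions and return the plateau onset.

    For each D_max candidate the P(r) fit is run to its tightest chi-square;
    the returned value is the smallest candidate whose chi-square is within
    ``chi2_slack`` of the plateau minimum and whose P(r) has a clean tail.
    Raises DmaxScanError (carrying the chi-square trace) when the scan shows
    no plateau.
    """
    if isinstance(scan, tuple):
        scan = np.arange(*scan, dtype=float)
    scan = np.asarray(scan, dtype=float)
    if scan.size < 3:
        raise ValueError("scan must contain at least 3 candidate values")

    chi2s = np.full(scan.size, np.inf)
    tails = np.zeros(scan.size, dtype=bool)
    for i, dm in enumerate(scan):
        try:
            pr = invert_pr_mem(profile, dm, chi2_target=None)
        except MaxEntError as err:
            chi2s[i] = err.chi2 if err.chi2 is not None else np.inf
            continue
        chi2s[i] = pr.chi2
        tails[i] = _tail_is_clean(pr.p)

    finite = np.isfinite(chi2s)
    if not finite.any():
        raise DmaxScanError("no candidate D_max admitted a P(r) fit", trace=chi2s)
    best = float(np.min(chi2s[finite]))
    # Plateau must be established inside the scan, not at its upper edge only.
    ok = finite & (chi2s <= best * (1.0 + chi2_slack)) & tails
    if not ok.any() or (ok.sum() == 1 and np.nonzero(ok)[0][0] == scan.size - 1):
        raise DmaxScanError(
            "chi2(D_max) shows no plateau inside the scan range", trace=chi2s
        )
    return float(scan[np.nonzero(ok)[0][0]])
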