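"""Multi-state ensemble selection and maximum-entropy weighting.

A flexible dimer in solution contributes a population-weighted average of
conformer profiles to the measured scattering.  Two complementary fits over
a conformer pool are provided:

* **Minimal ensembles** (ES-k): the best-fitting k-member weighted subset
  for k = 1..kmax, found exhaustively on small pools and by a deterministic
  beam search on large ones.  ES1 is the single best model, ES6 the
  six-state ensemble.
* **MEM weights**: a weight per pool model maximizing informational entropy
  relative to the uniform (unbiased) prior subject to a chi-square
  constraint, conventionally terminated at the chi-square achieved by the
  best six-state ensemble to avoid over-fitting.

The user-facing entry point is :class:`EnsembleModel`, which follows the
model/fit/results pattern: construct from a data profile and a pool, call
``fit``/``fit_mem``, and read estimates off the returned results objects.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .conformers import ModelPool, classify_conformer
from .debye import FitScore
from .profile import SaxsProfile

__all__ = [
    "WeightedEnsemble",
    "MemWeights",
    "fit_weights",
    "search_minimal_ensemble",
    "mem_weights",
    "rg_summary",
    "EnsembleModel",
    "MinimalEnsembleResults",
    "MemResults",
]

EXHAUSTIVE_POOL_LIMIT = 50
EXHAUSTIVE_K_LIMIT = 3
BEAM_WIDTH = 100


@dataclass
class WeightedEnsemble:
    """A k-state ensemble: pool indices, fractional weights and fit score."""

    member_indices: tuple[int, ...]
    weights: np.ndarray
    score: FitScore

    def __post_init__(self) -> None:
        self.member_indices = tuple(int(i) for i in self.member_indices)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.member_indices) != self.weights.size:
            raise ValueError("indices and weights must match")
        if np.any(self.weights < -1e-12):
            raise ValueError("weights must be non-negative")
        s = self.weights.sum()
        if not np.isclose(s, 1.0, atol=1e-6):
            raise ValueError("weights must sum to 1")

    @property
    def k(self) -> int:
        return len(self.member_indices)


@dataclass
class MemWeights:
    """Maximum-entropy weight distribution over a full pool."""

    weights: np.ndarray
    chi2_target: float
    chi2_achieved: float
    entropy: float
    scale: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < -1e-12):
            raise ValueError("weights must be non-negative")
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-6):
            raise ValueError("weights must sum to 1")


def _prepare(data: SaxsProfile, profiles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if not data.has_sigma:
        raise ValueError("data must carry error estimates")
    P = np.atleast_2d(np.asarray(profiles, dtype=float))
    if P.shape[1] != data.q.size:
        raise ValueError("component profiles must share the data q grid")
    w = 1.0 / data.sigma
    return P * w, data.intensity * w


def _nnls_subset(Aw: np.ndarray, yw: np.ndarray, idx: tuple[int, ...]):
    """Non-negative LS of the data on the selected components.  Returns
    (amplitudes, chi2) with chi2 divided by the point count."""
    A = Aw[list(idx)].T
    amps, rnorm = nnls(A, yw)
    chi2 = rnorm**2 / yw.size
    return amps, chi2


def fit_weights(
    member_profiles: np.ndarray,
    data: SaxsProfile,
    member_indices: tuple[int, ...] | None = None,
) -> WeightedEnsemble:
    """Non-negative weights plus a global scale minimizing chi-square.

    The unnormalized non-negative amplitudes a_i absorb the global scale
    c = sum(a); fractions are w_i = a_i / c.  Identical duplicate members
    make the split degenerate; the mass is then assigned to the lowest pool
    index for reproducibility (with a warning).
    """
    Aw, yw = _prepare(data, member_profiles)
    n = Aw.shape[0]
    idx = tuple(range(n)) if member_indices is None else tuple(member_indices)
    amps, chi2 = _nnls_subset(Aw, yw, tuple(range(n)))
    total = amps.sum()
    if total <= 0:
        raise ValueError("no member received positive weight (all-zero fit)")

    # collapse exact duplicates onto the lowest index (reproducible split)
    _, inverse = np.unique(Aw, axis=0, return_inverse=True)
    for group in np.unique(inverse):
        dup = np.nonzero(inverse == group)[0]
        if dup.size > 1:
            warnings.warn(
                f"duplicate members {[idx[i] for i in dup]}: weight assigned "
                "to the lowest index")
            amps[dup[0]] += amps[dup[1:]].sum()
            amps[dup[1:]] = 0.0
    fractions = amps / amps.sum()
    return WeightedEnsemble(
        member_indices=idx,
        weights=fractions,
        score=FitScore(chi2=chi2, scale=float(total)),
    )


def _beam_search(Aw: np.ndarray, yw: np.ndarray, kmax: int,
                 beam_width: int) -> dict[int, tuple[tuple[int, ...], np.ndarray, float]]:
    """Deterministic beam search over subsets with NNLS refit per candidate.

    Every beam member of size k-1 is extended with every pool model, so the
    best (k-1)-subset plus any extra member is always examined, which makes
    chi2(k) non-increasing in k by construction.
    """
    n = Aw.shape[0]
    # k = 1: score all singletons
    singles = []
    for i in range(n):
        amps, chi2 = _nnls_subset(Aw, yw, (i,))
        singles.append((chi2, (i,), amps))
    singles.sort(key=lambda t: (t[0], t[1]))
    best: dict[int, tuple[tuple[int, ...], np.ndarray, float]] = {}
    best[1] = (singles[0][1], singles[0][2], singles[0][0])
    beam = [(c, s) for c, s, _ in singles[:beam_width]]

    for k in range(2, kmax + 1):
        seen: set[tuple[int, ...]] = set()
        scored: list[tuple[float, tuple[int, ...], np.ndarray]] = []
        for _, subset in beam:
            for j in range(n):
                if j in subset:
                    continue
                cand = tuple(sorted(subset + (j,)))
                if cand in seen:
                    continue
                seen.add(cand)
                amps, chi2 = _nnls_subset(Aw, yw, cand)
                scored.append((chi2, cand, amps))
        if not scored:
            break
        scored.sort(key=lambda t: (t[0], t[1]))
        best[k] = (scored[0][1], scored[0][2], scored[0][0])
        beam = [(c, s) for c, s, _ in scored[:beam_width]]
    return best


def _exhaustive(Aw: np.ndarray, yw: np.ndarray, kmax: int):
    n = Aw.shape[0]
    best: dict[int, tuple[tuple[int, ...], np.ndarray, float]] = {}
    for k in range(1, kmax + 1):
        top: tuple[float, tuple[int, ...], np.ndarray] | None = None
        for cand in itertools.combinations(range(n), k):
            amps, chi2 = _nnls_subset(Aw, yw, cand)
            if top is None or chi2 < top[0] - 1e-15:
                top = (chi2, cand, amps)
        best[k] = (top[1], top[2], top[0])
    return best


def search_minimal_ensemble(
    pool: ModelPool,
    data: SaxsProfile,
    kmax: int = 6,
    beam_width: int = BEAM_WIDTH,
    force: str | None = None,
) -> dict[int, WeightedEnsemble]:
    """Best-fitting ensemble for each state count k = 1..kmax.

    Exhaustive enumeration for pools of at most 50 models with k <= 3;
    deterministic beam search (default width 100) otherwise.  ``force`` can
    pin "exhaustive" or "beam".  chi2(k) is non-increasing in k.
    """
    if pool.component_profiles is None:
        raise ValueError("pool has no component profiles; call compute_profiles")
    n = len(pool)
    if kmax > n:
        warnings.warn(f"kmax {kmax} exceeds pool size {n}; clipping")
        kmax = n
    Aw, yw = _prepare(data, pool.component_profiles)
    method = force or ("exhaustive" if n <= EXHAUSTIVE_POOL_LIMIT
                       and kmax <= EXHAUSTIVE_K_LIMIT else "beam")
    raw = (_exhaustive if method == "exhaustive" else
           lambda a, y, k: _beam_search(a, y, k, beam_width))(Aw, yw, kmax)

    out: dict[int, WeightedEnsemble] = {}
    for k, (subset, amps, chi2) in raw.items():
        keep = amps > 0
        if not keep.any():
            continue
        total = amps.sum()
        out[k] = WeightedEnsemble(
            member_indices=subset,
            weights=amps / total,
            score=FitScore(chi2=float(chi2), scale=float(total)),
        )
    return out


def _mem_chi2_and_grad(a: np.ndarray, Aw: np.ndarray, yw: np.ndarray):
    model = Aw.T @ a
    resid = yw - model
    n = yw.size
    chi2 = float(resid @ resid) / n
    grad = -(Aw @ resid) / n  # d(chi2/2)/da * 2 ... (factor folded below)
    return chi2, grad


def mem_weights(
    pool: ModelPool,
    data: SaxsProfile,
    chi2_target: float,
    rtol: float = 1e-3,
    max_outer: int = 200,
    max_inner: int = 4000,
) -> MemWeights:
    """Maximum-entropy weights over the whole pool at a chi-square target.

    Maximizes S = -sum_i w_i ln(w_i M) (M = pool size, uniform prior)
    subject to chi2(w) <= chi2_target, sum w = 1, w >= 0, with the global
    intensity scale refit inside every chi-square evaluation.  Solved by
    exponentiated-gradient fixed-point iteration at fixed Lagrange
    multiplier with bisection on the multiplier.

    Raises ValueError when the target lies below the best chi-square
    achievable over the weight simplex (the NNLS solution).
    """
    if pool.component_profiles is None:
        raise ValueError("pool has no component profiles; call compute_profiles")
    Aw, yw = _prepare(data, pool.component_profiles)
    M = Aw.shape[0]

    amps, chi2_best = _nnls_subset(Aw, yw, tuple(range(M)))
    if chi2_target < chi2_best * (1.0 - 1e-6):
        raise ValueError(
            f"chi2 target {chi2_target:.4g} infeasible; best achievable "
            f"{chi2_best:.4g}")

    def scale_refit(w: np.ndarray) -> float:
        model = Aw.T @ w
        denom = float(model @ model)
        return float(model @ yw) / denom if denom > 0 else 1.0

    def chi2_of(w: np.ndarray) -> float:
        c = scale_refit(w)
        resid = yw - c * (Aw.T @ w)
        return float(resid @ resid) / yw.size

    uniform = np.full(M, 1.0 / M)
    chi2_uniform = chi2_of(uniform)
    if chi2_uniform <= chi2_target:
        return MemWeights(
            weights=uniform, chi2_target=chi2_target,
            chi2_achieved=chi2_uniform, entropy=float(np.log(M)),
            scale=scale_refit(uniform))

    from scipy.optimize import minimize
    from scipy.special import logsumexp

    def solve_at(lam: float, w0: np.ndarray) -> np.ndarray:
        """Minimize lam*chi2/2 - S over the simplex via softmax coordinates.

        The objective is convex in w; the softmax map keeps the iterate in
        the open simplex and the shift invariance of softmax removes the
        sum constraint.  The gradient treats the refit scale as fixed at
        its per-evaluation optimum (envelope theorem)."""

        def objective(u: np.ndarray):
            logw = u - logsumexp(u)
            w = np.exp(logw)
            c = scale_refit(w)
            resid = yw - c * (Aw.T @ w)
            chi2_half = 0.5 * float(resid @ resid) / yw.size
            neg_s = float(np.sum(w * (logw + np.log(M))))
            g_w = -c * (Aw @ resid) / yw.size + (logw + np.log(M) + 1.0) / lam
            grad_w = lam * g_w
            # chain rule through softmax: J^T v = w*(v - w.v)
            grad_u = w * (grad_w - float(w @ grad_w))
            return lam * chi2_half + neg_s, grad_u

        u0 = np.log(np.maximum(w0, 1e-300))
        res = minimize(objective, u0, jac=True, method="L-BFGS-B",
                       options={"maxiter": max_inner, "ftol": 1e-14,
                                "gtol": 1e-12})
        logw = res.x - logsumexp(res.x)
        return np.exp(logw)

    # grow lambda until feasible, then bisect
    g0 = np.abs(Aw @ (yw - scale_refit(uniform) * (Aw.T @ uniform))) / yw.size
    lam = 0.1 / max(float(g0.max()), 1e-300)
    lam_lo, lam_hi = 0.0, None
    w = uniform
    for _ in range(80):
        w_try = solve_at(lam, w)
        c2 = chi2_of(w_try)
        if c2 <= chi2_target:
            lam_hi, w_hi, c2_hi = lam, w_try, c2
            break
        lam_lo, w = lam, w_try
        lam *= 3.0
    else:
        raise ValueError(
            f"MEM iteration could not reach chi2 target {chi2_target:.4g} "
            f"(achieved {c2:.4g})")

    for _ in range(max_outer):
        if abs(c2_hi - chi2_target) / chi2_target < rtol:
            break
        mid = 0.5 * (lam_lo + lam_hi)
        w_mid = solve_at(mid, w_hi)
        c2_mid = chi2_of(w_mid)
        if c2_mid <= chi2_target:
            lam_hi, w_hi, c2_hi = mid, w_mid, c2_mid
        else:
            lam_lo = mid

    entropy = float(-np.sum(w_hi * np.log(np.maximum(w_hi * M, 1e-300))))
    return MemWeights(
        weights=w_hi, chi2_target=chi2_target, chi2_achieved=c2_hi,
        entropy=entropy, scale=scale_refit(w_hi))


def rg_summary(
    weights: np.ndarray,
    rgs: np.ndarray,
    bins: int = 25,
    pool_rgs: np.ndarray | None = None,
) -> dict:
    """Fraction-weighted R_G statistics of a weighted ensemble.

    Returns the fraction-weighted mean R_G, a fraction-weighted histogram
    (masses summing to 1) and compact/intermediate/extended percentages
    relative to ``pool_rgs`` (default: ``rgs`` itself).
    """
    weights = np.asarray(weights, dtype=float)
    rgs = np.asarray(rgs, dtype=float)
    if weights.shape != rgs.shape:
        raise ValueError("weights and rgs must have the same length")
    if not np.isclose(weights.sum(), 1.0, atol=1e-6):
        raise ValueError("weights must sum to 1")
    ref = rgs if pool_rgs is None else np.asarray(pool_rgs, dtype=float)
    mean_rg = float(np.sum(weights * rgs))
    hist, edges = np.histogram(rgs, bins=bins, weights=weights)
    cats = {"compact": 0.0, "intermediate": 0.0, "extended": 0.0}
    for w, r in zip(weights, rgs):
        cats[classify_conformer(r, ref)] += float(w)
    return {
        "mean_rg": mean_rg,
        "hist": hist,
        "bin_edges": edges,
        "percent": {k: 100.0 * v for k, v in cats.items()},
    }


# ---------------------------------------------------------------------------
# model / fit / results facade
# ---------------------------------------------------------------------------

@dataclass
class MinimalEnsembleResults:
    """Results of a minimal-ensemble search: the best ES-k per k."""

    model: "EnsembleModel"
    ensembles: dict[int, WeightedEnsemble]

    def chi2_path(self) -> dict[int, float]:
        return {k: e.score.chi2 for k, e in sorted(self.ensembles.items())}

    def ensemble(self, k: int) -> WeightedEnsemble:
        return self.ensembles[k]

    def rg_summary(self, k: int, **kw) -> dict:
        e = self.ensembles[k]
        rgs = self.model.pool.rgs[list(e.member_indices)]
        return rg_summary(e.weights, rgs, pool_rgs=self.model.pool.rgs, **kw)

    def summary(self) -> str:
        lines = ["Minimal ensemble search", "=" * 47,
                 f"{'k':>3} {'chi2':>10} {'scale':>10}  members (weight %)"]
        for k, e in sorted(self.ensembles.items()):
            members = ", ".join(
                f"{i}({100 * w:.0f}%)" for i, w in
                zip(e.member_indices, e.weights) if w > 0)
            lines.append(f"{k:>3} {e.score.chi2:>10.4g} {e.score.scale:>10.4g}  {members}")
        return "\n".join(lines)


@dataclass
class MemResults:
    """Results of a MEM fit over the full pool."""

    model: "EnsembleModel"
    mem: MemWeights

    @property
    def weights(self) -> np.ndarray:
        return self.mem.weights

    def rg_summary(self, **kw) -> dict:
        return rg_summary(self.mem.weights, self.model.pool.rgs, **kw)

    def summary(self) -> str:
        s = self.rg_summary()
        pct = s["percent"]
        return "\n".join([
            "Maximum-entropy ensemble weights",
            "=" * 47,
            f"pool size            {len(self.model.pool)}",
            f"chi2 target          {self.mem.chi2_target:.4g}",
            f"chi2 achieved        {self.mem.chi2_achieved:.4g}",
            f"entropy (nats)       {self.mem.entropy:.4g} (max {np.log(len(self.model.pool)):.4g})",
            f"weighted mean R_G    {s['mean_rg']:.2f} A",
            f"compact              {pct['compact']:.1f}%",
            f"intermediate         {pct['intermediate']:.1f}%",
            f"extended             {pct['extended']:.1f}%",
        ])


class EnsembleModel:
    """Ensemble analysis of a scattering profile over a conformer pool.

    Parameters
    ----------
    data : SaxsProfile
        Experimental (or reconstructed) profile with error estimates.
    pool : ModelPool
        Conformer pool; component profiles are computed on ``data.q`` if
        not already cached on a matching grid.
    """

    def __init__(self, data: SaxsProfile, pool: ModelPool):
        if not data.has_sigma:
            raise ValueError("data must carry error estimates")
        self.data = data
        self.pool = pool
        if (pool.component_profiles is None or pool.q is None
                or pool.q.shape != data.q.shape
                or not np.allclose(pool.q, data.q)):
            pool.compute_profiles(data.q)

    def fit(self, kmax: int = 6, **kw) -> MinimalEnsembleResults:
        """Minimal-ensemble search up to ``kmax`` states."""
        ens = search_minimal_ensemble(self.pool, self.data, kmax=kmax, **kw)
        return MinimalEnsembleResults(model=self, ensembles=ens)

    def fit_mem(
        self,
        chi2_target: float | None = None,
        target_from_k: int | None = None,
        minimal: MinimalEnsembleResults | None = None,
        **kw,
    ) -> MemResults:
        """MEM weighting of the full pool.

        The chi-square target is given directly or taken from the ES-k
        chi-square of a minimal-ensemble fit (run here when not supplied);
        the conventional choice is ``target_from_k=6``.
        """
        if chi2_target is None:
            k = 6 if target_from_k is None else target_from_k
            if minimal is None:
                minimal = self.fit(kmax=k)
            chi2_target = minimal.ensembles[max(minimal.ensembles)].score.chi2
        mem = mem_weights(self.pool, self.data, chi2_target, **kw)
        return MemResults(model=self, mem=mem)
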