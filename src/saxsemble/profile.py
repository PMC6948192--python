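"""One-dimensional scattering profiles and SEC elution frame series.

A :class:`SaxsProfile` holds a single buffer-subtracted (or raw) scattering
curve I(q) with optional per-point errors; a :class:`FrameSeries` holds the
matrix of elution-frame profiles collected during a size-exclusion
chromatography run, all on one shared q grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SaxsProfile",
    "FrameSeries",
    "RegionSpec",
    "read_profile",
    "write_profile",
    "read_frame_series",
    "write_frame_series",
    "average_frames",
    "subtract_buffer",
]

_COMMENT_CHARS = ("#", ";")


@dataclass
class SaxsProfile:
    """Scattering profile I(q) with optional per-point errors.

    Parameters
    ----------
    q : array
        Scattering vector magnitudes in 1/Angstrom, strictly increasing, > 0.
    intensity : array
        Intensities in arbitrary units, same length as ``q``.
    sigma : array, optional
        Per-point error estimates (same units as intensity, all > 0), or
        ``None`` when errors have not been estimated yet.
    label : str
        Free-text metadata.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        self._validate()

    def _validate(self) -> None:
        if self.q.ndim != 1 or self.q.size == 0:
            raise ValueError("q must be a non-empty 1-D array")
        if self.intensity.shape != self.q.shape:
            raise ValueError("intensity and q must have the same length")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if self.q[0] <= 0:
            raise ValueError("all q must be positive")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")
        if self.sigma is not None:
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma and q must have the same length")
            if np.any(self.sigma <= 0) or not np.all(np.isfinite(self.sigma)):
                raise ValueError("sigma must be positive and finite")

    def __len__(self) -> int:
        return self.q.size

    @property
    def has_sigma(self) -> bool:
        return self.sigma is not None

    def with_sigma(self, sigma: np.ndarray) -> "SaxsProfile":
        return replace(self, sigma=np.asarray(sigma, dtype=float))

    def scaled(self, factor: float) -> "SaxsProfile":
        sig = None if self.sigma is None else self.sigma * abs(factor)
        return replace(self, intensity=self.intensity * factor, sigma=sig)


@dataclass
class FrameSeries:
    """Matrix of elution-frame intensities on a common q grid."""

    q: np.ndarray
    frames: np.ndarray  # (n_frames, n_q)
    frame_ids: list[str] = field(default_factory=list)
    exposure: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.frames = np.atleast_2d(np.asarray(self.frames, dtype=float))
        if self.frames.shape[1] != self.q.size:
            raise ValueError("frames must share the q grid")
        if self.frames.shape[0] < 2:
            raise ValueError("a frame series needs at least 2 frames")
        if not self.frame_ids:
            self.frame_ids = [f"frame{i:04d}" for i in range(self.n_frames)]
        if len(self.frame_ids) != self.n_frames:
            raise ValueError("frame_ids length must match frame count")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def profile(self, i: int) -> SaxsProfile:
        return SaxsProfile(self.q, self.frames[i], label=self.frame_ids[i])


@dataclass(frozen=True)
class RegionSpec:
    """Index sets marking the elution main peak and a buffer region."""

    peak_frames: tuple[int, ...]
    buffer_frames: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "peak_frames", tuple(self.peak_frames))
        object.__setattr__(self, "buffer_frames", tuple(self.buffer_frames))
        if not self.peak_frames or not self.buffer_frames:
            raise ValueError("peak and buffer regions must be non-empty")
        if set(self.peak_frames) & set(self.buffer_frames):
            raise ValueError("peak and buffer regions must be disjoint")

    def validate(self, n_frames: int) -> None:
        for i in self.peak_frames + self.buffer_frames:
            if not 0 <= i < n_frames:
                raise IndexError(f"frame index {i} out of range [0, {n_frames})")


def _parse_columns(path: Path) -> np.ndarray:
    rows = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith(_COMMENT_CHARS):
            continue
        parts = line.replace(",", " ").split()
        try:
            rows.append([float(x) for x in parts])
        except ValueError:
            continue  # header / trailer text lines tolerated
    if not rows:
        raise ValueError(f"{path}: no numeric data found")
    ncol = min(len(r) for r in rows)
    if ncol < 2:
        raise ValueError(f"{path}: need at least 2 columns (q, I)")
    return np.array([r[:ncol] for r in rows], dtype=float)


def read_profile(path: str | Path) -> SaxsProfile:
    """Read a 2- or 3-column ASCII profile (q, I[, sigma]).

    Lines starting with '#' or ';' and non-numeric header lines are skipped.
    """
    path = Path(path)
    data = _parse_columns(path)
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return SaxsProfile(data[:, 0], data[:, 1], sigma=sigma, label=path.stem)


def write_profile(path: str | Path, profile: SaxsProfile) -> None:
    """Write a profile as 3-column (or 2-column when sigma absent) ASCII."""
    path = Path(path)
    with path.open("w") as fh:
        if profile.label:
            fh.write(f"# {profile.label}\n")
        fh.write("# q(1/A)  I(q)" + ("  sigma\n" if profile.has_sigma else "\n"))
        for i in range(len(profile)):
            if profile.has_sigma:
                fh.write(
                    f"{profile.q[i]:.9e} {profile.intensity[i]:.9e} "
                    f"{profile.sigma[i]:.9e}\n"
                )
            else:
                fh.write(f"{profile.q[i]:.9e} {profile.intensity[i]:.9e}\n")


def read_frame_series(source: str | Path) -> FrameSeries:
    """Read a frame series from a directory of .dat files (filename order)
    or a single matrix file whose header row carries the q grid."""
    source = Path(source)
    if source.is_dir():
        files = sorted(source.glob("*.dat"))
        if len(files) < 2:
            raise ValueError(f"{source}: need at least 2 .dat frames")
        profiles = [read_profile(f) for f in files]
        q = profiles[0].q
        for p in profiles[1:]:
            if p.q.shape != q.shape or not np.allclose(p.q, q):
                raise ValueError("frames do not share a common q grid")
        return FrameSeries(
            q,
            np.vstack([p.intensity for p in profiles]),
            frame_ids=[f.stem for f in files],
        )
    data = np.loadtxt(source, comments=list(_COMMENT_CHARS))
    return FrameSeries(data[0], data[1:])


def write_frame_series(path: str | Path, series: FrameSeries) -> None:
    """Write a series as a matrix file: first row q, then one row per frame."""
    np.savetxt(path, np.vstack([series.q, series.frames]), fmt="%.9e",
               header="row 1: q grid (1/A); following rows: frame intensities")


def average_frames(series: FrameSeries, idx: Sequence[int] | Iterable[int]) -> SaxsProfile:
    """Pointwise mean of the selected frames.

    sigma is the standard error of the mean per q point (0 when a single
    frame is selected or frames are identical).
    """
    idx = list(idx)
    if not idx:
        raise ValueError("idx must be non-empty")
    sub = series.frames[idx]
    mean = sub.mean(axis=0)
    if len(idx) > 1:
        sem = sub.std(axis=0, ddof=1) / np.sqrt(len(idx))
    else:
        sem = np.zeros_like(mean)
    prof = SaxsProfile(series.q, mean, label=f"mean of {len(idx)} frames")
    prof.sigma = sem  # may contain zeros; treated as provisional errors
    return prof


def subtract_buffer(
    sample: SaxsProfile,
    buffer: SaxsProfile,
    auto_scale: bool = False,
) -> SaxsProfile:
    """Buffer subtraction I_out = I_sample - k * I_buffer.

    With ``auto_scale`` the scaling constant k is chosen to minimize the
    squared residuals of a Guinier-region straight-line fit (ln I vs q^2)
    of the subtracted profile: a coarse k grid followed by golden-section
    refinement. Errors are propagated in quadrature.
    """
    if sample.q.shape != buffer.q.shape or not np.allclose(sample.q, buffer.q):
        raise ValueError("sample and buffer must share the q grid")

    if auto_scale:
        from ._linearity import guinier_linearity_cost, guinier_window

        n_fix = guinier_window(sample.q, sample.intensity - buffer.intensity)

        def cost(k: float) -> float:
            return guinier_linearity_cost(
                sample.q, sample.intensity - k * buffer.intensity,
                fixed_window=n_fix)

        ks = np.linspace(0.5, 1.5, 101)
        costs = [cost(k) for k in ks]
        i0 = int(np.argmin(costs))
        lo = ks[max(i0 - 1, 0)]
        hi = ks[min(i0 + 1, len(ks) - 1)]
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(cost, bracket=None, bounds=(lo, hi), method="bounded")
        k = float(res.x)
    else:
        k = 1.0

    out = sample.intensity - k * buffer.intensity
    sigma = None
    if sample.has_sigma and buffer.has_sigma:
        sigma = np.sqrt(sample.sigma**2 + (k * buffer.sigma) ** 2)
        sigma = np.maximum(sigma, np.finfo(float).tiny)
    prof = SaxsProfile(sample.q, out, label=f"{sample.label} - {k:.4g}*buffer")
    prof.sigma = sigma
    prof.buffer_scale = k  # type: ignore[attr-defined]
    return prof
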