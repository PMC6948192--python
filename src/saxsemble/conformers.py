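"""Coarse-grained conformer pools for two-armed dimers with flexible linkers.

The dimer architecture mirrored here is a central rigid dimerization rod
(a coiled-coil stand-in built from two straight bead strands in parallel or
antiparallel orientation) connected through flexible linkers to two rigid
"arm" segments (the autoinhibited core stand-ins).  Two alternative arm
templates, A and B, represent the two hinge conformations of the core, and
dimers combine them as AA, BB or AB.  Conformational diversity comes from
self-avoiding linker walks and the resulting arm placements.

Coarse-graining: one bead per residue at 3.8 Angstrom virtual bond length,
uniform bead radius 1.9 Angstrom, clash distance 3.0 Angstrom between
non-bonded beads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist, pdist

__all__ = [
    "BeadModel",
    "ModelPool",
    "PoolSpec",
    "PoolGenerationError",
    "model_rg",
    "sample_linker_pool",
    "classify_conformer",
    "make_arm_template",
    "write_bead_pdb",
    "read_bead_pdb",
]

BOND_LENGTH = 3.8
CLASH_DISTANCE = 3.0
DEFAULT_BEAD_RADIUS = 1.9
RETRY_CAP = 100


class PoolGenerationError(RuntimeError):
    def __init__(self, message: str, acceptance_rate: float):
        super().__init__(f"{message} (acceptance rate {acceptance_rate:.3f})")
        self.acceptance_rate = acceptance_rate


@dataclass
class BeadModel:
    """One coarse-grained conformer: bead coordinates plus segment labels."""

    coords: np.ndarray  # (N, 3) Angstrom
    bead_radius: float = DEFAULT_BEAD_RADIUS
    segment_labels: list[str] = field(default_factory=list)
    topology_tag: str = "antiparallel"
    conformer_tag: str = "AA"

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if not self.segment_labels:
            self.segment_labels = ["body"] * len(self.coords)
        if len(self.segment_labels) != len(self.coords):
            raise ValueError("segment_labels must match bead count")

    def __len__(self) -> int:
        return len(self.coords)

    def min_nonbonded_distance(self) -> float:
        """Minimum pairwise distance excluding bonded (consecutive same-
        segment) bead pairs."""
        n = len(self)
        if n < 2:
            return np.inf
        d = pdist(self.coords)
        # mask out bonded neighbors
        idx = 0
        best = np.inf
        labels = self.segment_labels
        for i in range(n - 1):
            row = d[idx: idx + n - 1 - i]
            start = 0
            if labels[i] == labels[i + 1]:
                start = 1  # skip bonded neighbor
            if row[start:].size:
                best = min(best, row[start:].min())
            idx += n - 1 - i
        return float(best)


def model_rg(m: BeadModel | np.ndarray) -> float:
    """Radius of gyration: RMS distance of beads from their centroid
    (unit masses)."""
    coords = m.coords if isinstance(m, BeadModel) else np.atleast_2d(np.asarray(m, float))
    if len(coords) == 0:
        raise ValueError("empty model")
    c = coords - coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(c**2, axis=1))))


@dataclass
class ModelPool:
    """A pool of conformers with cached R_G values and, once computed,
    component scattering profiles on a stated q grid."""

    models: list[BeadModel]
    rgs: np.ndarray = None  # type: ignore[assignment]
    component_profiles: np.ndarray | None = None  # (n_models, n_q)
    q: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.rgs is None:
            self.rgs = np.array([model_rg(m) for m in self.models])
        self.rgs = np.asarray(self.rgs, dtype=float)
        if self.rgs.size != len(self.models):
            raise ValueError("rgs length must match model count")
        if self.component_profiles is not None:
            self.component_profiles = np.atleast_2d(
                np.asarray(self.component_profiles, dtype=float))
            if self.component_profiles.shape[0] != len(self.models):
                raise ValueError("component_profiles rows must match model count")

    def __len__(self) -> int:
        return len(self.models)

    def compute_profiles(self, q: np.ndarray) -> np.ndarray:
        from .debye import debye_profile

        q = np.asarray(q, dtype=float)
        self.component_profiles = np.vstack(
            [debye_profile(m, q) for m in self.models])
        self.q = q
        return self.component_profiles


@dataclass
class PoolSpec:
    """Recipe for a conformer pool.

    arm templates are (N, 3) coordinate arrays whose first bead is the
    linker attachment point; ``rod_length`` is the rod span in Angstrom;
    ``linker_residues`` the flexible linker length in residues (one bead
    each); mixes are fractions by tag.
    """

    arm_template_a: np.ndarray
    arm_template_b: np.ndarray
    linker_residues: int = 8
    rod_length: float = 54.0
    rod_separation: float = 5.0
    conformer_mix: dict = field(
        default_factory=lambda: {"AA": 1 / 3, "BB": 1 / 3, "AB": 1 / 3})
    topology_mix: dict = field(
        default_factory=lambda: {"antiparallel": 0.5, "parallel": 0.5})

    def __post_init__(self) -> None:
        self.arm_template_a = np.atleast_2d(np.asarray(self.arm_template_a, float))
        self.arm_template_b = np.atleast_2d(np.asarray(self.arm_template_b, float))
        if self.linker_residues < 0:
            raise ValueError("linker length must be >= 0")


def make_arm_template(kind: str = "A", radius: float = 14.0,
                      spacing: float = BOND_LENGTH) -> np.ndarray:
    """Deterministic rigid arm templates on a cubic lattice.

    "A" is a roughly spherical blob of the given radius; "B" is a prolate
    (2:1 elongated) blob of equal volume — two distinguishable hinge
    conformations of the same core.
    """
    pts = []
    if kind.upper() == "A":
        ax = np.array([radius, radius, radius])
    elif kind.upper() == "B":
        ax = np.array([radius * 1.6, radius * 0.79, radius * 0.79])
    else:
        raise ValueError("kind must be 'A' or 'B'")
    grid = [np.arange(-a, a + spacing / 2, spacing) for a in ax]
    for x in grid[0]:
        for y in grid[1]:
            for z in grid[2]:
                if (x / ax[0]) ** 2 + (y / ax[1]) ** 2 + (z / ax[2]) ** 2 <= 1.0:
                    pts.append((x, y, z))
    coords = np.array(pts)
    # first bead = attachment point: the lattice point of minimal z, then x, y
    order = np.lexsort((coords[:, 1], coords[:, 0], coords[:, 2]))
    coords = coords[order]
    return coords - coords[0]


def _build_rod(spec: PoolSpec, topology: str) -> tuple[np.ndarray, list[np.ndarray]]:
    """Two straight bead strands along z.  Returns (coords, [attach points]).

    Antiparallel strands place the two linker exits at opposite rod ends;
    parallel strands place both exits at the same end.
    """
    n = max(int(round(spec.rod_length / BOND_LENGTH)) + 1, 2)
    z = np.linspace(0.0, spec.rod_length, n)
    off = spec.rod_separation / 2.0
    s1 = np.column_stack([np.full(n, -off), np.zeros(n), z])
    if topology == "antiparallel":
        s2 = np.column_stack([np.full(n, off), np.zeros(n), z[::-1]])
        attach = [s1[-1], s2[-1]]  # strand C-termini: top and bottom
    elif topology == "parallel":
        s2 = np.column_stack([np.full(n, off), np.zeros(n), z])
        attach = [s1[-1], s2[-1]]  # both at the top
    else:
        raise ValueError(f"unknown topology {topology!r}")
    return np.vstack([s1, s2]), attach


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    u1, u2, u3 = rng.random(3)
    qw = np.sqrt(1 - u1) * np.sin(2 * np.pi * u2)
    qx = np.sqrt(1 - u1) * np.cos(2 * np.pi * u2)
    qy = np.sqrt(u1) * np.sin(2 * np.pi * u3)
    qz = np.sqrt(u1) * np.cos(2 * np.pi * u3)
    q = np.array([qw, qx, qy, qz])
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _grow_linker(
    start: np.ndarray,
    n_steps: int,
    occupied: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray | None:
    """Self-avoiding random walk of 3.8 A steps; None on dead end."""
    walk = [start]
    for _ in range(n_steps):
        placed = False
        for _attempt in range(30):
            v = rng.normal(size=3)
            v *= BOND_LENGTH / np.linalg.norm(v)
            cand = walk[-1] + v
            prev = np.vstack([occupied] + [w[None, :] for w in walk[:-1]])
            if cdist(cand[None, :], prev).min() >= CLASH_DISTANCE:
                walk.append(cand)
                placed = True
                break
        if not placed:
            return None
    return np.vstack(walk[1:]) if n_steps > 0 else np.empty((0, 3))


def _allocate(mix: dict, n: int) -> list[str]:
    """Largest-remainder allocation of n items to tags by fractional mix."""
    tags = sorted(mix)
    fracs = np.array([mix[t] for t in tags], dtype=float)
    fracs = fracs / fracs.sum()
    counts = np.floor(fracs * n).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(fracs * n - counts))
    for i in range(rem):
        counts[order[i % len(tags)]] += 1
    out: list[str] = []
    for t, c in zip(tags, counts):
        out.extend([t] * c)
    return out


def _align_rotation(v: np.ndarray) -> np.ndarray:
    """Rotation taking the +z axis onto the unit vector v."""
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(z, v))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(z, v)
    s = np.linalg.norm(axis)
    axis = axis / s
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def _cone_direction(axis: np.ndarray, max_angle: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Uniform random unit vector within ``max_angle`` (rad) of ``axis``."""
    cosa = rng.uniform(np.cos(max_angle), 1.0)
    sina = np.sqrt(1.0 - cosa**2)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    local = np.array([sina * np.cos(phi), sina * np.sin(phi), cosa])
    return _align_rotation(axis / np.linalg.norm(axis)) @ local


def _build_model(
    spec: PoolSpec,
    topology: str,
    conformer: str,
    rng: np.random.Generator,
) -> BeadModel | None:
    rod, attach = _build_rod(spec, topology)
    arm_by_letter = {"A": spec.arm_template_a, "B": spec.arm_template_b}
    letters = {"AA": "AA", "BB": "BB", "AB": "AB"}[conformer]

    coords = [rod]
    labels = ["rod"] * len(rod)
    occupied = rod
    rod_center = rod.mean(axis=0)
    for arm_i, (letter, anchor) in enumerate(zip(letters, attach)):
        walk = _grow_linker(anchor, spec.linker_residues, occupied, rng)
        if walk is None:
            return None
        end = walk[-1] if len(walk) else anchor
        template = arm_by_letter[letter]
        if spec.linker_residues > 0:
            # Orient the arm's long axis within a 90-degree cone of the
            # outward direction (away from the body) with a free spin, so
            # orientations vary while most placements stay clash-free.
            outward = end - (rod_center if np.allclose(end, anchor) else anchor)
            nrm = np.linalg.norm(outward)
            outward = outward / nrm if nrm > 0 else np.array([0.0, 0.0, 1.0])
            v = _cone_direction(outward, np.pi / 6, rng)
            spin = rng.uniform(0.0, 2.0 * np.pi)
            Rspin = np.array([[np.cos(spin), -np.sin(spin), 0],
                              [np.sin(spin), np.cos(spin), 0],
                              [0, 0, 1.0]])
            R = _align_rotation(v) @ Rspin
            arm = (template @ R.T) + end + v * BOND_LENGTH
        else:
            # rigid placement: continue straight along the rod axis
            if topology == "antiparallel" and arm_i == 1:
                # template extends toward +z; flip it to grow downward
                flipped = template * np.array([1.0, -1.0, -1.0])
                arm = flipped + end + np.array([0.0, 0.0, -BOND_LENGTH])
            else:
                arm = template + end + np.array([0.0, 0.0, BOND_LENGTH])
        body = np.vstack([occupied] + ([walk] if len(walk) else []))
        if len(arm) and cdist(arm, body).min() < CLASH_DISTANCE:
            return None
        if len(walk):
            coords.append(walk)
            labels += [f"linker{arm_i + 1}"] * len(walk)
        coords.append(arm)
        labels += [f"arm{arm_i + 1}"] * len(arm)
        occupied = np.vstack(coords)
    return BeadModel(np.vstack(coords), segment_labels=labels,
                     topology_tag=topology, conformer_tag=conformer)


def sample_linker_pool(spec: PoolSpec, n: int, seed: int) -> ModelPool:
    """Sample ``n`` clash-free conformers reproducibly from ``seed``.

    Pool composition follows the requested conformer and topology mixes to
    within rounding (largest-remainder allocation).  Raises
    :class:`PoolGenerationError` when the retry cap is exhausted.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    conformers = _allocate(spec.conformer_mix, n)
    topologies = _allocate(spec.topology_mix, n)
    rng.shuffle(topologies)  # decorrelate the two tag sequences

    models: list[BeadModel] = []
    attempts = 0
    for conf, topo in zip(conformers, topologies):
        for trial in range(RETRY_CAP):
            attempts += 1
            m = _build_model(spec, topo, conf, rng)
            if m is not None:
                models.append(m)
                break
        else:
            raise PoolGenerationError(
                "linker growth exhausted retry cap",
                acceptance_rate=len(models) / max(attempts, 1),
            )
    return ModelPool(models=models, seed=seed)


def classify_conformer(rg: float, pool_rgs: np.ndarray) -> str:
    """Label an R_G as compact / intermediate / extended relative to a pool.

    Thresholds sit at the pool mean -/+ 0.5 standard deviations: "compact"
    is well below the pool mean, "extended" well above, "intermediate" near.
    """
    pool_rgs = np.asarray(pool_rgs, dtype=float)
    if pool_rgs.size == 0:
        raise ValueError("pool_rgs must be non-empty")
    mu, sd = pool_rgs.mean(), pool_rgs.std()
    if rg < mu - 0.5 * sd:
        return "compact"
    if rg > mu + 0.5 * sd:
        return "extended"
    return "intermediate"


_SEGMENT_CHAINS = {"rod": "R", "linker1": "L", "linker2": "M",
                   "arm1": "A", "arm2": "B", "body": "X"}


def write_bead_pdb(path: str | Path, m: BeadModel) -> None:
    """Write a bead model as a Calpha-only PDB (one CA per bead; segment
    encoded in the chain ID)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = len(m)
    arr = struc.AtomArray(n)
    arr.coord = m.coords.astype(np.float32)
    arr.atom_name = np.array(["CA"] * n)
    arr.res_name = np.array(["GLY"] * n)
    arr.element = np.array(["C"] * n)
    arr.res_id = np.arange(1, n + 1)
    arr.chain_id = np.array(
        [_SEGMENT_CHAINS.get(lbl, "X") for lbl in m.segment_labels])
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def read_bead_pdb(path: str | Path) -> BeadModel:
    from biotite.structure.io.pdb import PDBFile

    arr = PDBFile.read(str(path)).get_structure(model=1)
    arr = arr[arr.atom_name == "CA"]
    rev = {v: k for k, v in _SEGMENT_CHAINS.items()}
    labels = [rev.get(str(c), "body") for c in arr.chain_id]
    return BeadModel(np.asarray(arr.coord, dtype=float), segment_labels=labels)
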