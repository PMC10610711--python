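"""Synthetic trajectories and scenes with exact ground truth.

Every analysis stage in this package (Einstein diffusion, Fickian-window
detection, hydrogen-bond census, periodic clustering, density maps) is
validated against inputs whose answer is known by construction:

* random walkers with a prescribed diffusion coefficient (free Brownian,
  ballistic, or sphere-confined motion), returned both wrapped and as the
  continuous ground-truth path;
* single-frame scenes with planted water clusters of prescribed sizes,
  optionally straddling a periodic boundary, together with the true
  partition;
* single-frame scenes realizing requested donor–H···acceptor geometries
  exactly, for exercising the distance/angle hydrogen-bond criteria.

Walkers are rigid ideal waters (O–H 0.9572 Å, H–O–H 104.52°) translated
with the walker; internal motion is irrelevant to all analyses here, and
exact variance bookkeeping beats physical realism for an oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .trajio import (
    ATOMIC_MASSES,
    Box,
    Topology,
    Trajectory,
    water_topology,
    wrap_coords,
)

__all__ = [
    "SyntheticSpec",
    "ClusterScene",
    "HBondScene",
    "gen_walkers",
    "gen_cluster_scene",
    "gen_hbond_scene",
    "measure_hbond_geometry",
    "M2S_PER_A2PS",
    "WATER_OH",
    "WATER_ANGLE_DEG",
]

#: Unit conversion: 1 Å²/ps = 1e-8 m²/s.
M2S_PER_A2PS = 1e-8

WATER_OH = 0.9572       # Å, rigid O-H bond
WATER_ANGLE_DEG = 104.52


def _water_site_offsets() -> np.ndarray:
    """O, H, H site positions relative to the molecular center of mass."""
    half = math.radians(WATER_ANGLE_DEG) / 2
    o = np.zeros(3)
    h1 = WATER_OH * np.array([math.sin(half), 0.0, math.cos(half)])
    h2 = WATER_OH * np.array([-math.sin(half), 0.0, math.cos(half)])
    sites = np.stack([o, h1, h2])
    masses = np.array([ATOMIC_MASSES["O"], ATOMIC_MASSES["H"], ATOMIC_MASSES["H"]])
    com = (masses[:, None] * sites).sum(0) / masses.sum()
    return sites - com


_WATER_OFFSETS = _water_site_offsets()


def _as_box(box) -> Box:
    if isinstance(box, Box):
        return box
    if np.isscalar(box):
        return Box.cubic(float(box))
    return Box(np.asarray(box, float))


# --------------------------------------------------------------------------
# walkers
# --------------------------------------------------------------------------

@dataclass
class SyntheticSpec:
    """Recipe for an ensemble of water-like walkers.

    ``d_true`` is in m²/s (brownian/confined step variance 2·D·dt per
    axis after conversion to Å²/ps), ``speed`` in Å/ps (ballistic),
    ``cavity_radius`` in Å (confined).  ``dt`` defaults to a 5 ps
    recording interval.
    """

    mode: str = "brownian"
    n_molecules: int = 100
    n_frames: int = 100
    dt: float = 5.0
    d_true: float = 1e-12
    speed: float = 0.1
    cavity_radius: float = 5.0
    box: Box | float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("brownian", "ballistic", "confined"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.d_true < 0:
            raise ValueError("d_true must be non-negative")
        if self.mode == "confined" and self.cavity_radius <= 0:
            raise ValueError("cavity_radius must be positive for confined mode")
        self.box = _as_box(self.box)


def _com_paths(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    n_t, n_m = spec.n_frames, spec.n_molecules
    lengths = spec.box.lengths
    starts = rng.uniform(0.0, lengths, size=(n_m, 3))
    if spec.mode == "ballistic":
        v = rng.normal(size=(n_m, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        t = np.arange(n_t) * spec.dt
        return starts[None] + spec.speed * v[None] * t[:, None, None]

    d_aps = spec.d_true / M2S_PER_A2PS  # m²/s -> Å²/ps
    sigma = math.sqrt(2.0 * d_aps * spec.dt)
    if sigma > lengths.min() / 4:
        raise ValueError(
            f"per-axis step sd {sigma:.3g} Å exceeds L/4 = {lengths.min() / 4:.3g} Å; "
            "unwrapping would be ambiguous — enlarge the box or shorten dt"
        )
    steps = rng.normal(0.0, sigma, size=(n_t - 1, n_m, 3)) if sigma > 0 else np.zeros((n_t - 1, n_m, 3))
    if spec.mode == "brownian":
        out = np.empty((n_t, n_m, 3))
        out[0] = starts
        np.cumsum(steps, axis=0, out=out[1:])
        out[1:] += starts
        return out

    # confined: Brownian steps with specular (radial mirror) reflection at a
    # sphere of cavity_radius centred on each walker's start position
    r = spec.cavity_radius
    out = np.empty((n_t, n_m, 3))
    out[0] = starts
    pos = starts.copy()
    for t in range(1, n_t):
        pos = pos + steps[t - 1]
        delta = pos - starts
        for _ in range(64):
            dist = np.linalg.norm(delta, axis=1)
            outside = dist > r
            if not outside.any():
                break
            scale = (2.0 * r - dist[outside]) / dist[outside]
            delta[outside] *= scale[:, None]
        pos = starts + delta
        out[t] = pos
    return out


def gen_walkers(spec: SyntheticSpec) -> tuple[Trajectory, Trajectory, Topology]:
    """Generate (wrapped trajectory, continuous ground truth, topology).

    Bit-identical output for identical spec + seed.  Brownian steps are
    Gaussian with per-axis variance 2·D·dt; the continuous trajectory is
    the exact path before box wrapping, so it serves as the unwrap and
    MSD oracle.
    """
    rng = np.random.default_rng(spec.seed)
    com = _com_paths(spec, rng)  # (frames, molecules, 3)
    n_t, n_m = com.shape[:2]
    coords = (com[:, :, None, :] + _WATER_OFFSETS[None, None]).reshape(n_t, n_m * 3, 3)
    times = np.arange(n_t) * spec.dt
    boxes = np.broadcast_to(spec.box.lengths, (n_t, 3)).copy()
    continuous = Trajectory(times, coords, boxes, wrapped=False)
    wrapped = Trajectory(times.copy(), wrap_coords(coords, spec.box), boxes.copy(), wrapped=True)
    return wrapped, continuous, water_topology(n_m)


# --------------------------------------------------------------------------
# planted cluster scenes
# --------------------------------------------------------------------------

@dataclass
class ClusterScene:
    """Planted water clusters: each cluster is connected at ``cutoff``
    (O···O linkage) and distinct clusters are separated by more than
    ``min_gap`` under the minimum image convention."""

    planted_sizes: list[int] = field(default_factory=lambda: [5, 3, 1])
    cutoff: float = 3.5
    min_gap: float = 7.0
    span_boundary: bool = False
    box: Box | float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.planted_sizes or any(s < 1 for s in self.planted_sizes):
            raise ValueError("planted_sizes must be positive")
        if self.min_gap <= self.cutoff:
            raise ValueError("min_gap must exceed cutoff")
        self.box = _as_box(self.box)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _grow_cluster(rng: np.random.Generator, size: int, cutoff: float) -> np.ndarray:
    """Connected point set: every member within cutoff of another member."""
    min_pair = min(2.3, 0.7 * cutoff)
    lo, hi = min_pair, 0.95 * cutoff
    pts = [np.zeros(3)]
    for _ in range(size - 1):
        for _attempt in range(500):
            base = pts[rng.integers(len(pts))]
            p = base + _random_unit(rng) * rng.uniform(lo, hi)
            if all(np.linalg.norm(p - q) >= min_pair for q in pts[: len(pts)] if q is not base):
                pts.append(p)
                break
        else:
            raise RuntimeError(f"could not grow a connected cluster of size {size}")
    pts = np.array(pts)
    return pts - pts.mean(axis=0)


def gen_cluster_scene(scene: ClusterScene) -> tuple[Trajectory, Topology, list[np.ndarray]]:
    """Generate (single-frame wrapped trajectory, topology, true partition).

    The partition is a list of molecule-id arrays, one per planted
    cluster in the order of ``planted_sizes``.  If ``span_boundary``,
    the whole scene is translated so the largest cluster straddles a
    box face before wrapping.
    """
    rng = np.random.default_rng(scene.seed)
    lengths = scene.box.lengths
    shapes = [_grow_cluster(rng, s, scene.cutoff) for s in scene.planted_sizes]
    radii = [float(np.linalg.norm(p, axis=1).max()) if len(p) > 1 else 0.0 for p in shapes]
    margin = 0.5
    for rad in radii:
        if 2 * rad + scene.min_gap + margin >= lengths.min():
            raise RuntimeError(
                "planted cluster too large for the box at the requested gap; use a larger box"
            )
    centers: list[np.ndarray] = []
    for i, rad in enumerate(radii):
        for _attempt in range(2000):
            c = rng.uniform(0.0, lengths)
            ok = True
            for j, cj in enumerate(centers):
                d = c - cj
                d -= lengths * np.floor(d / lengths + 0.5)
                if np.linalg.norm(d) < radii[j] + rad + scene.min_gap + margin:
                    ok = False
                    break
            if ok:
                centers.append(c)
                break
        else:
            raise RuntimeError("could not place planted clusters; use a larger box")

    oxygens = np.concatenate([c + p for c, p in zip(centers, shapes)])
    if scene.span_boundary:
        largest = int(np.argmax(scene.planted_sizes))
        # put the largest cluster's centre on the box origin so it wraps
        # across the faces
        oxygens = oxygens - centers[largest]
    # O sits exactly on the planted point; hydrogens ride along rigidly
    coords = (oxygens[:, None, :] + (_WATER_OFFSETS - _WATER_OFFSETS[0])[None]).reshape(-1, 3)
    n_mol = len(oxygens)
    times = np.zeros(1)
    boxes = lengths.reshape(1, 3)
    traj = Trajectory(times, wrap_coords(coords.reshape(1, -1, 3), scene.box), boxes, wrapped=True)
    topo = water_topology(n_mol)
    partition = []
    start = 0
    for s in scene.planted_sizes:
        partition.append(np.arange(start, start + s))
        start += s
    return traj, topo, partition


# --------------------------------------------------------------------------
# planted hydrogen-bond scenes
# --------------------------------------------------------------------------

@dataclass
class HBondScene:
    """Requested D–H···A geometries: each entry is
    (H···A distance Å, donor angle °, acceptor angle °, donor species,
    acceptor species), species in {"water", "polymer"}."""

    triplets: list[tuple[float, float, float, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.triplets:
            raise ValueError("triplet list must be nonempty")
        for t in self.triplets:
            d, da, aa = t[0], t[1], t[2]
            if d <= 0:
                raise ValueError("H···A distance must be positive")
            if not (0.0 <= da <= 180.0 and 0.0 <= aa <= 180.0):
                raise ValueError("angles must lie in [0°, 180°]")
            if t[3] not in ("water", "polymer") or t[4] not in ("water", "polymer"):
                raise ValueError("species must be water or polymer")


def _cone_directions(axis: np.ndarray, angle_deg: float, n: int = 72) -> np.ndarray:
    """Unit vectors making ``angle_deg`` with ``axis``, sampled in azimuth."""
    axis = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    theta = math.radians(angle_deg)
    phis = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
    return (
        math.cos(theta) * axis[None]
        + math.sin(theta) * (np.cos(phis)[:, None] * e1[None] + np.sin(phis)[:, None] * e2[None])
    )


def _best_cone_point(
    origin: np.ndarray, axis: np.ndarray, angle_deg: float, length: float, avoid: np.ndarray
) -> np.ndarray:
    """Point at ``length`` on the cone around ``axis`` maximising the
    minimum distance to the ``avoid`` coordinates."""
    cands = origin[None] + length * _cone_directions(axis, angle_deg)
    dists = np.linalg.norm(cands[:, None, :] - avoid[None], axis=2).min(axis=1)
    return cands[int(np.argmax(dists))]


def _build_triplet(
    dist: float, donor_angle: float, acceptor_angle: float, donor_sp: str, acceptor_sp: str
) -> tuple[np.ndarray, list[str], list[str], list[tuple[int, int]], int, int, int]:
    """Local coordinates for one D–H···A–X construction.

    Returns (coords, elements, frags, bonds, donor_idx, hydrogen_idx,
    acceptor_idx); ``frags`` marks each atom "d" (donor fragment) or
    "a" (acceptor fragment).
    """
    alpha = math.radians(donor_angle)
    beta = math.radians(acceptor_angle)
    h = np.zeros(3)
    a = np.array([dist, 0.0, 0.0])
    d = WATER_OH * np.array([math.cos(alpha), math.sin(alpha), 0.0])

    coords: list[np.ndarray] = [d, h, a]
    elements = ["O", "H", "O"]
    frags = ["d", "d", "a"]
    bonds = [(0, 1)]
    d_idx, h_idx, a_idx = 0, 1, 2

    # acceptor-side neighbour X realising the requested acceptor angle,
    # measured at A against the A->H direction (-x)
    if acceptor_sp == "polymer":
        x = a + 1.23 * np.array([-math.cos(beta), math.sin(beta), 0.0])  # carbonyl C=O
        coords.append(x)
        elements.append("C")
        frags.append("a")
        bonds.append((a_idx, 3))
    else:
        x = a + WATER_OH * np.array([-math.cos(beta), math.sin(beta), 0.0])
        coords.append(x)
        elements.append("H")
        frags.append("a")
        bonds.append((a_idx, 3))
        # second water hydrogen, azimuth-optimised away from the donor side
        h2a = _best_cone_point(a, (x - a), WATER_ANGLE_DEG, WATER_OH, np.array([d, h]))
        coords.append(h2a)
        elements.append("H")
        frags.append("a")
        bonds.append((a_idx, 4))

    # donor-side completion
    avoid = np.array(coords[2:])  # acceptor-fragment atoms
    if donor_sp == "water":
        h2 = _best_cone_point(d, (h - d), WATER_ANGLE_DEG, WATER_OH, avoid)
        coords.append(h2)
        elements.append("H")
    else:
        c = _best_cone_point(d, (h - d), 108.5, 1.43, avoid)
        coords.append(c)
        elements.append("C")
    frags.append("d")
    bonds.append((d_idx, len(coords) - 1))

    arr = np.array(coords)
    dmat = np.linalg.norm(arr[:, None] - arr[None], axis=2)
    np.fill_diagonal(dmat, np.inf)
    if dmat.min() < 0.5:
        raise ValueError(
            f"unrealizable geometry (atoms {dmat.min():.2f} Å apart) for "
            f"triplet d={dist}, donor={donor_angle}°, acceptor={acceptor_angle}°"
        )
    return arr, elements, frags, bonds, d_idx, h_idx, a_idx


def gen_hbond_scene(scene: HBondScene) -> tuple[Trajectory, Topology]:
    """Realize each requested geometry exactly in one frame.

    Triplets are laid out on a 50 Å grid so no unintended inter-triplet
    contacts arise.  The donor and acceptor of every triplet belong to
    different molecules; only the planted hydrogen is donor-flagged and
    only the planted acceptor is acceptor-flagged, so the detected
    census equals the requested list under criteria the geometries pass.
    Water fragments are full (O, H, H) molecules.
    """
    spacing = 50.0
    n = len(scene.triplets)
    side = max(1, math.ceil(n ** (1 / 3)))
    lengths = np.full(3, spacing * side)
    all_coords: list[np.ndarray] = []
    elements: list[str] = []
    masses: list[float] = []
    molecule_ids: list[int] = []
    species: list[str] = []
    bonds: list[tuple[int, int]] = []
    donor_h: list[bool] = []
    acceptor: list[bool] = []
    mol = 0
    for k, (dist, da, aa, dsp, asp) in enumerate(scene.triplets):
        coords, elems, frags, local_bonds, d_idx, h_idx, a_idx = _build_triplet(dist, da, aa, dsp, asp)
        gi, gj, gk = k % side, (k // side) % side, k // side**2
        offset = np.array([gi, gj, gk]) * spacing + spacing / 2
        base = len(elements)
        for idx, (p, e, frag) in enumerate(zip(coords, elems, frags)):
            all_coords.append(p + offset)
            elements.append(e)
            masses.append(ATOMIC_MASSES[e])
            molecule_ids.append(mol + (1 if frag == "a" else 0))
            species.append(asp if frag == "a" else dsp)
            donor_h.append(idx == h_idx)
            acceptor.append(idx == a_idx)
        bonds.extend((base + x, base + y) for x, y in local_bonds)
        mol += 2
    coords = np.array(all_coords).reshape(1, -1, 3)
    topo = Topology(elements, masses, molecule_ids, species, bonds, donor_h, acceptor)
    traj = Trajectory(np.zeros(1), wrap_coords(coords, Box(lengths)), lengths.reshape(1, 3), wrapped=True)
    return traj, topo


def measure_hbond_geometry(
    coords: np.ndarray,
    topology: Topology,
    donor: int,
    hydrogen: int,
    acceptor: int,
    box: Box | None = None,
) -> tuple[float, float, float | None]:
    """(H···A distance, donor angle at H, acceptor angle at A vs its first
    bonded neighbour; None if the acceptor has no neighbour).  Minimum
    image convention applies when a box is given."""

    def disp(i: int, j: int) -> np.ndarray:
        d = coords[j] - coords[i]
        if box is not None:
            d = d - box.lengths * np.floor(d / box.lengths + 0.5)
        return d

    ha = disp(hydrogen, acceptor)
    hd = disp(hydrogen, donor)
    dist = float(np.linalg.norm(ha))
    donor_angle = math.degrees(
        math.acos(np.clip(hd @ ha / (np.linalg.norm(hd) * dist), -1.0, 1.0))
    )
    nbrs = topology.adjacency[acceptor]
    if len(nbrs) == 0:
        return dist, donor_angle, None
    ah = disp(acceptor, hydrogen)
    ax = disp(acceptor, int(nbrs[0]))
    acc_angle = math.degrees(
        math.acos(np.clip(ah @ ax / (np.linalg.norm(ah) * np.linalg.norm(ax)), -1.0, 1.0))
    )
    return dist, donor_angle, acc_angle
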