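"""Geometric hydrogen-bond detection and class decomposition.

A hydrogen bond is a donor–hydrogen···acceptor contact with

* H···A minimum-image distance strictly below 2.8 Å,
* donor angle ∠(D–H···A), measured at the hydrogen, of at least 120°,
* acceptor angle ∠(H···A–X) of at least 90° for every heavy neighbour X
  of the acceptor (an acceptor with no heavy neighbour — a bare ion, or
  a water oxygen whose neighbours are hydrogens — passes vacuously).

Donors are N/O heavy atoms carrying a flagged hydrogen; acceptors are
flagged N/O atoms.  Bonds are classified water–water (ww),
polymer–polymer (pp) or polymer–water (pw) from the species of the
donor and acceptor molecules; filler counts as polymer.  The census
satisfies the decomposition N_total = N_ww + N_pp + N_pw identically,
and the pw count may equivalently be obtained by difference
(:func:`pw_by_difference`).

Intra-molecular contacts are excluded for water and allowed for polymer
when donor and acceptor are more than three covalent bonds apart
(crosslinked chains can fold back onto themselves).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .trajio import Box, Topology, Trajectory, TopologyError, wrap_coords

__all__ = [
    "HBondCriteria",
    "HBond",
    "HBondCounts",
    "detect_hbonds",
    "classify",
    "pw_by_difference",
    "hbond_profile",
]

CLASSES = ("ww", "pp", "pw")

# Threshold comparisons are resolved at this numerical resolution so that
# geometries constructed to sit exactly on a threshold behave as the
# definition states (distance strictly below, angles inclusive) regardless
# of rounding introduced by scene placement and wrapping.
_DIST_RESOLUTION = 1e-9  # Å
_ANGLE_RESOLUTION = 1e-7  # degrees


@dataclass(frozen=True)
class HBondCriteria:
    """Distance/angle thresholds.  The distance bound is strict (<);
    both angle bounds are inclusive (>=)."""

    max_ha: float = 2.8           # Å
    min_donor_angle: float = 120.0    # degrees, at the hydrogen
    min_acceptor_angle: float = 90.0  # degrees, at the acceptor

    def __post_init__(self) -> None:
        if self.max_ha <= 0:
            raise ValueError("max_ha must be positive")
        for a in (self.min_donor_angle, self.min_acceptor_angle):
            if not 0.0 <= a <= 180.0:
                raise ValueError("angle thresholds must lie in [0°, 180°]")


@dataclass(frozen=True)
class HBond:
    donor: int
    hydrogen: int
    acceptor: int
    frame: int
    cls: str  # ww | pp | pw


@dataclass
class HBondCounts:
    """Per-frame class counts; n_total == n_ww + n_pp + n_pw per frame."""

    frames: np.ndarray
    times: np.ndarray
    n_ww: np.ndarray
    n_pp: np.ndarray
    n_pw: np.ndarray

    @property
    def n_total(self) -> np.ndarray:
        return self.n_ww + self.n_pp + self.n_pw

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frames,
                "time_ps": self.times,
                "n_ww": self.n_ww,
                "n_pp": self.n_pp,
                "n_pw": self.n_pw,
                "n_total": self.n_total,
            }
        )

    def summary(self) -> pd.DataFrame:
        """Mean ± sd per class, laid out one interaction type per row."""
        rows = []
        for label, series in (
            ("Water-Water", self.n_ww),
            ("Polymer-Polymer", self.n_pp),
            ("Total", self.n_total),
            ("Polymer-Water", self.n_pw),
        ):
            rows.append(
                {
                    "interaction": label,
                    "mean": float(np.mean(series)),
                    "sd": float(np.std(series, ddof=0)),
                }
            )
        return pd.DataFrame(rows)


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    c = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _class_of(topology: Topology, donor: int, acceptor: int) -> str:
    ds = "water" if topology.species[donor] == "water" else "polymer"
    as_ = "water" if topology.species[acceptor] == "water" else "polymer"
    if ds == "water" and as_ == "water":
        return "ww"
    if ds == "polymer" and as_ == "polymer":
        return "pp"
    return "pw"


def detect_hbonds(
    coords: np.ndarray,
    topology: Topology,
    box: Box,
    criteria: HBondCriteria | None = None,
    frame: int = 0,
) -> list[HBond]:
    """All (D, H, A) triplets passing the geometric criteria in one frame.

    Coordinates are wrapped into the box internally; all distances and
    angle vectors use the minimum image convention.  Candidate H···A
    pairs come from a periodic k-d tree at the distance cutoff, then
    every test is applied exactly, so the result matches a brute-force
    triple loop.
    """
    criteria = criteria or HBondCriteria()
    lengths = box.lengths
    pos = wrap_coords(np.asarray(coords, float), box)
    hydrogens = np.flatnonzero(topology.donor_h)
    acceptors = np.flatnonzero(topology.acceptor)
    out: list[HBond] = []
    if len(hydrogens) == 0 or len(acceptors) == 0:
        return out
    for h in hydrogens:
        if len(topology.heavy_neighbors(h)) == 0:
            raise TopologyError(f"donor hydrogen {h} has no bonded heavy atom")
    # nudge exactly-on-boundary coordinates inside for the periodic tree
    tree = cKDTree(np.minimum(pos[acceptors], np.nextafter(lengths, 0.0)), boxsize=lengths)
    hpos = np.minimum(pos[hydrogens], np.nextafter(lengths, 0.0))
    neighbor_lists = tree.query_ball_point(hpos, r=criteria.max_ha)
    for hi, neigh in zip(hydrogens, neighbor_lists):
        if not neigh:
            continue
        d = topology.donor_of(hi)
        for a in (int(acceptors[k]) for k in sorted(neigh)):
            if a == d or a == hi:
                continue
            ha = pos[a] - pos[hi]
            ha -= lengths * np.floor(ha / lengths + 0.5)
            dist = float(np.linalg.norm(ha))
            if not dist < criteria.max_ha - _DIST_RESOLUTION:
                continue
            same_mol = topology.molecule_ids[d] == topology.molecule_ids[a]
            if same_mol:
                if topology.species[d] == "water":
                    continue
                if topology.bond_path_within(d, a, 3):
                    continue
            hd = pos[d] - pos[hi]
            hd -= lengths * np.floor(hd / lengths + 0.5)
            if _angle_deg(hd, ha) < criteria.min_donor_angle - _ANGLE_RESOLUTION:
                continue
            ok = True
            for x in topology.heavy_neighbors(a):
                ax = pos[x] - pos[a]
                ax -= lengths * np.floor(ax / lengths + 0.5)
                if _angle_deg(-ha, ax) < criteria.min_acceptor_angle - _ANGLE_RESOLUTION:
                    ok = False
                    break
            if ok:
                out.append(HBond(int(d), int(hi), int(a), frame, _class_of(topology, d, a)))
    return out


def classify(
    hbonds: Sequence[HBond],
    topology: Topology,
    frames: Sequence[int] | None = None,
    times: Sequence[float] | None = None,
) -> HBondCounts:
    """Aggregate detected bonds into per-frame class counts.

    ``frames`` fixes the frame axis (frames with no bonds count zero);
    by default the frames present in ``hbonds`` are used."""
    if frames is None:
        frames = sorted({b.frame for b in hbonds}) or [0]
    frames = np.asarray(list(frames), int)
    times = np.asarray(list(times), float) if times is not None else frames.astype(float)
    index = {f: i for i, f in enumerate(frames)}
    counts = {c: np.zeros(len(frames), int) for c in CLASSES}
    for b in hbonds:
        cls = b.cls or _class_of(topology, b.donor, b.acceptor)
        counts[cls][index[b.frame]] += 1
    return HBondCounts(frames, times, counts["ww"], counts["pp"], counts["pw"])


def pw_by_difference(n_total: int, n_pp: int, n_ww: int) -> int:
    """Polymer–water bond count by difference from the total:
    N_pw = N_total − N_pp − N_ww."""
    result = int(n_total) - int(n_pp) - int(n_ww)
    if result < 0:
        raise ValueError(
            f"inconsistent counts: total {n_total} < pp {n_pp} + ww {n_ww}"
        )
    return result


def hbond_profile(
    traj: Trajectory,
    topology: Topology,
    criteria: HBondCriteria | None = None,
    stride: int = 1,
) -> HBondCounts:
    """Per-frame hydrogen-bond class counts at the given frame stride."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    frames = list(range(0, traj.n_frames, stride))
    bonds: list[HBond] = []
    for f in frames:
        bonds.extend(detect_hbonds(traj.coords[f], topology, traj.box(f), criteria, frame=f))
    return classify(bonds, topology, frames=frames, times=traj.times[frames])
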