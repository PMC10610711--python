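"""Time-averaged density projections of a molecular selection.

The 3D distribution of (typically) water centers of mass is flattened
onto one or two box axes and averaged over frames, giving a number or
mass density per bin (count·Å⁻¹ for 1D, count·Å⁻²·frame-averaged for
2D; amu instead of count in mass mode).  A uniformly penetrated matrix
yields a flat map; channelling or pocketing shows up as hot bins, which
the coefficient-of-variation summary turns into a scalar.

Bin widths are adjusted so an integer number of half-open bins exactly
tiles the box edge; in number mode the identity
Σ values × bin measure = mean selected count per frame holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajio import Topology, Trajectory, wrap_coords
from .msd import molecule_com

__all__ = ["DensityMap", "project_density", "uniformity_cv"]

AXIS_NAMES = "xyz"


@dataclass
class DensityMap:
    """Frame-averaged projected density on a regular grid."""

    axes: tuple[int, ...]
    bin_edges: list[np.ndarray]  # Å, one array per projected axis
    values: np.ndarray           # density per bin (count or amu per Å^k)
    mode: str                    # number | mass
    n_frames: int

    @property
    def bin_measure(self) -> float:
        """Bin length (1D) or area (2D) in Å^k."""
        return float(np.prod([e[1] - e[0] for e in self.bin_edges]))

    def to_frame(self) -> pd.DataFrame:
        if len(self.axes) == 1:
            e = self.bin_edges[0]
            return pd.DataFrame(
                {f"{AXIS_NAMES[self.axes[0]]}_edge": e[:-1], "value": self.values}
            )
        ex, ey = self.bin_edges
        xx, yy = np.meshgrid(ex[:-1], ey[:-1], indexing="ij")
        return pd.DataFrame(
            {
                f"{AXIS_NAMES[self.axes[0]]}_edge": xx.ravel(),
                f"{AXIS_NAMES[self.axes[1]]}_edge": yy.ravel(),
                "value": self.values.ravel(),
            }
        )


def project_density(
    traj: Trajectory,
    topology: Topology,
    species: str = "water",
    axes: tuple[int, ...] = (0, 1),
    bin_width: float = 1.0,
    mode: str = "number",
) -> DensityMap:
    """Bin molecular centers of mass on one or two axes, averaged over frames.

    The trajectory must be wrapped (or wrappable: coordinates are folded
    into the frame-0 box).  ``mode="mass"`` weights each molecule by its
    mass in amu.  Half-open bins [edge, edge + width).
    """
    if mode not in ("number", "mass"):
        raise ValueError("mode must be 'number' or 'mass'")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    axes = tuple(int(a) for a in (axes if np.iterable(axes) else (axes,)))
    if not axes or len(axes) > 2 or len(set(axes)) != len(axes) or any(a not in (0, 1, 2) for a in axes):
        raise ValueError("axes must be one or two distinct axes out of (0, 1, 2)")
    lengths = traj.boxes[0]
    if bin_width > lengths.min():
        raise ValueError(f"bin_width {bin_width} Å exceeds the smallest box edge {lengths.min()} Å")
    _, groups = topology.molecules(species)
    if not groups:
        raise ValueError(f"no {species!r} molecules in the topology")
    com = wrap_coords(molecule_com(traj, topology, groups), lengths)
    weights = None
    if mode == "mass":
        weights = np.array([topology.masses[g].sum() for g in groups])

    nbins = [max(1, int(round(lengths[a] / bin_width))) for a in axes]
    edges = [np.linspace(0.0, lengths[a], nb + 1) for a, nb in zip(axes, nbins)]
    accum = np.zeros(nbins)
    for f in range(traj.n_frames):
        sample = com[f][:, list(axes)]
        w = weights if weights is not None else None
        hist, _ = np.histogramdd(sample, bins=edges, weights=w)
        accum += hist
    measure = float(np.prod([e[1] - e[0] for e in edges]))
    values = accum / traj.n_frames / measure
    return DensityMap(axes=axes, bin_edges=edges, values=values, mode=mode, n_frames=traj.n_frames)


def uniformity_cv(dmap: DensityMap) -> float:
    """Coefficient of variation (population sd / mean) of the bin values:
    0 for a perfectly uniform map, √(k−1) when all weight sits in one of
    k bins."""
    vals = np.asarray(dmap.values, float).ravel()
    if vals.size == 0:
        raise ValueError("empty density map")
    mean = vals.mean()
    if mean == 0:
        raise ValueError("zero-mean density map: coefficient of variation undefined")
    return float(vals.std(ddof=0) / mean)
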