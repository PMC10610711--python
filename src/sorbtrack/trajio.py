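"""Trajectory and topology I/O with periodic-boundary primitives.

Internal units are Å for coordinates and ps for time throughout the
package.  Only orthorhombic simulation cells are supported: the minimum
image convention is then exact and cheap (component-wise), which every
downstream analysis (MSD unwrapping, hydrogen-bond distances, cluster
linkage, density binning) relies on.

Supported on-disk formats
-------------------------
* multi-frame XYZ whose comment line carries ``Lattice="Lx Ly Lz"``
  (or the 9-number row-major diagonal variant) and optionally
  ``Time=<ps>``;
* multi-model PDB with CRYST1 (read and written through MDAnalysis);
* GRO frames (nm, converted to Å), optionally concatenated into a
  multi-frame file, with ``t= <ps>`` honoured on the title line.

Topologies travel as a JSON (or CSV) sidecar annotating each atom with
element, mass, molecule id, species tag (water / polymer / filler),
covalent bonds and hydrogen-bond donor/acceptor roles.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Box",
    "Topology",
    "Trajectory",
    "TrajectoryFormatError",
    "TopologyError",
    "minimum_image_displacement",
    "wrap_coords",
    "wrap",
    "unwrap",
    "select",
    "read_trajectory",
    "write_trajectory",
    "load_topology",
    "save_topology",
    "water_topology",
    "topology_from_resnames",
]

SPECIES_TAGS = ("water", "polymer", "filler")

#: Standard atomic masses (amu) for the builders.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "Si": 28.086, "P": 30.974, "S": 32.06, "Cl": 35.45,
}

#: Residue names recognised as water by the convenience builders.
WATER_RESNAMES = frozenset({"HOH", "SOL", "WAT", "TIP3", "SPC", "T3P"})


class TrajectoryFormatError(ValueError):
    """Raised for malformed or unsupported trajectory files."""


class TopologyError(ValueError):
    """Raised for inconsistent topology annotations."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Box:
    """Orthorhombic periodic cell, edge lengths in Å."""

    lengths: np.ndarray

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=float).reshape(3)
        if not np.all(np.isfinite(lengths)) or np.any(lengths <= 0):
            raise ValueError(f"box edge lengths must be positive and finite, got {lengths}")
        object.__setattr__(self, "lengths", lengths)

    @classmethod
    def cubic(cls, length: float) -> "Box":
        return cls(np.full(3, float(length)))

    @property
    def volume(self) -> float:
        return float(np.prod(self.lengths))


class Topology:
    """Per-atom annotations driving selections and hydrogen-bond roles.

    Parameters
    ----------
    elements : element symbols, one per atom.
    masses : atomic masses in amu, strictly positive.
    molecule_ids : integer molecule labels partitioning the atoms.
    species : per-atom tag, one of ``water``, ``polymer``, ``filler``.
    bonds : iterable of (i, j) covalent bonds, 0-based atom indices.
    donor_h : boolean flags on hydrogens that can donate a hydrogen
        bond (must be bonded to exactly one heavy atom, their donor).
    acceptor : boolean flags on N/O atoms that can accept.
    """

    def __init__(
        self,
        elements: Sequence[str],
        masses: Sequence[float],
        molecule_ids: Sequence[int],
        species: Sequence[str],
        bonds: Iterable[tuple[int, int]] = (),
        donor_h: Sequence[bool] | None = None,
        acceptor: Sequence[bool] | None = None,
        validate: bool = True,
    ) -> None:
        self.elements = np.asarray(elements, dtype=object)
        self.masses = np.asarray(masses, dtype=float)
        self.molecule_ids = np.asarray(molecule_ids, dtype=int)
        self.species = np.asarray(species, dtype=object)
        self.bonds = [tuple(sorted((int(i), int(j)))) for i, j in bonds]
        n = self.n_atoms
        self.donor_h = (
            np.zeros(n, dtype=bool) if donor_h is None else np.asarray(donor_h, dtype=bool)
        )
        self.acceptor = (
            np.zeros(n, dtype=bool) if acceptor is None else np.asarray(acceptor, dtype=bool)
        )
        if validate:
            self._validate()

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def _validate(self) -> None:
        n = self.n_atoms
        for arr, name in (
            (self.masses, "masses"),
            (self.molecule_ids, "molecule_ids"),
            (self.species, "species"),
            (self.donor_h, "donor_h"),
            (self.acceptor, "acceptor"),
        ):
            if len(arr) != n:
                raise TopologyError(f"{name} has length {len(arr)}, expected {n}")
        if np.any(self.masses <= 0):
            raise TopologyError("all masses must be strictly positive")
        bad = set(self.species) - set(SPECIES_TAGS)
        if bad:
            raise TopologyError(f"unknown species tags {sorted(bad)}; allowed: {SPECIES_TAGS}")
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise TopologyError(f"invalid bond ({i}, {j})")
        # donor-flagged hydrogens carry exactly one bonded heavy atom
        for h in np.flatnonzero(self.donor_h):
            if self.elements[h] != "H":
                raise TopologyError(f"donor_h flag on non-hydrogen atom {h} ({self.elements[h]})")
            heavies = self.heavy_neighbors(h)
            if len(heavies) != 1:
                raise TopologyError(
                    f"donor hydrogen {h} must have exactly one bonded heavy atom, has {len(heavies)}"
                )
        # every water molecule is an O + 2 H triad
        for mol in np.unique(self.molecule_ids[self.species == "water"]):
            atoms = np.flatnonzero(self.molecule_ids == mol)
            elems = sorted(self.elements[atoms])
            if elems != ["H", "H", "O"]:
                raise TopologyError(f"water molecule {mol} is not an (O, H, H) triad: {elems}")

    @cached_property
    def adjacency(self) -> list[np.ndarray]:
        adj: list[list[int]] = [[] for _ in range(self.n_atoms)]
        for i, j in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        return [np.array(sorted(a), dtype=int) for a in adj]

    def neighbors(self, i: int) -> np.ndarray:
        return self.adjacency[i]

    def heavy_neighbors(self, i: int) -> np.ndarray:
        nb = self.adjacency[i]
        return nb[[self.elements[j] != "H" for j in nb]] if len(nb) else nb

    def donor_of(self, h: int) -> int:
        """The heavy atom a donor hydrogen is covalently bonded to."""
        heavies = self.heavy_neighbors(h)
        if len(heavies) != 1:
            raise TopologyError(f"hydrogen {h} has {len(heavies)} bonded heavy atoms")
        return int(heavies[0])

    def bond_path_within(self, i: int, j: int, max_bonds: int) -> bool:
        """True if j is reachable from i in at most ``max_bonds`` covalent bonds."""
        if i == j:
            return True
        frontier = {i}
        seen = {i}
        for _ in range(max_bonds):
            nxt: set[int] = set()
            for a in frontier:
                for b in self.adjacency[a]:
                    if b == j:
                        return True
                    if b not in seen:
                        seen.add(b)
                        nxt.add(b)
            frontier = nxt
            if not frontier:
                break
        return False

    def molecules(self, species: str | None = None) -> tuple[np.ndarray, list[np.ndarray]]:
        """Molecule ids and their atom-index groups, ascending by id."""
        mask = np.ones(self.n_atoms, bool) if species is None else (self.species == species)
        ids = np.unique(self.molecule_ids[mask])
        groups = [np.flatnonzero(self.molecule_ids == m) for m in ids]
        return ids, groups

    def water_oxygens(self) -> tuple[np.ndarray, np.ndarray]:
        """(molecule ids, O atom index) for every water molecule."""
        ids, groups = self.molecules("water")
        oxy = np.array(
            [g[np.flatnonzero(self.elements[g] == "O")[0]] for g in groups], dtype=int
        ) if len(ids) else np.empty(0, dtype=int)
        return ids, oxy


@dataclass
class Trajectory:
    """Uniformly sampled trajectory: times (ps), coords (frames × atoms × 3, Å),
    a per-frame orthorhombic box, and a flag recording whether coordinates
    are wrapped into [0, L)."""

    times: np.ndarray
    coords: np.ndarray
    boxes: np.ndarray  # (n_frames, 3) edge lengths, Å
    wrapped: bool = True

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).reshape(-1)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (frames, atoms, 3), got {self.coords.shape}")
        if self.coords.shape[0] != len(self.times):
            raise ValueError("times and coords disagree on the frame count")
        if len(self.times) < 1:
            raise ValueError("need at least one frame")
        boxes = np.asarray(self.boxes, dtype=float)
        if boxes.ndim == 1:
            boxes = np.broadcast_to(boxes.reshape(1, 3), (self.n_frames, 3)).copy()
        if boxes.shape != (self.n_frames, 3):
            raise ValueError(f"boxes must be (frames, 3), got {boxes.shape}")
        if np.any(boxes <= 0):
            raise ValueError("box edge lengths must be positive")
        self.boxes = boxes
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if len(self.times) > 1:
            dts = np.diff(self.times)
            if np.any(dts <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
                raise TrajectoryFormatError("non-uniform time spacing between frames")
        if self.wrapped and not _in_box(self.coords, self.boxes):
            raise ValueError(
                "wrapped=True but coordinates fall outside [0, L); wrap first or pass wrapped=False"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def dt(self) -> float:
        if self.n_frames < 2:
            raise ValueError("dt undefined for a single-frame trajectory")
        return float(self.times[1] - self.times[0])

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])

    def box(self, frame: int = 0) -> Box:
        return Box(self.boxes[frame])


def _in_box(coords: np.ndarray, boxes: np.ndarray) -> bool:
    return bool(np.all(coords >= 0) and np.all(coords < boxes[:, None, :]))


# --------------------------------------------------------------------------
# periodic-boundary primitives
# --------------------------------------------------------------------------

def minimum_image_displacement(a: np.ndarray, b: np.ndarray, box: Box) -> np.ndarray:
    """Displacement ``b - a`` shifted by integer box multiples so each
    component lies in [-L/2, L/2).  Broadcasts over leading dimensions."""
    length = box.lengths if isinstance(box, Box) else np.asarray(box, float)
    d = np.asarray(b, float) - np.asarray(a, float)
    return d - length * np.floor(d / length + 0.5)


def wrap_coords(coords: np.ndarray, box: Box | np.ndarray) -> np.ndarray:
    """Wrap coordinates into [0, L) per axis."""
    length = box.lengths if isinstance(box, Box) else np.asarray(box, float)
    x = np.asarray(coords, float)
    return x - length * np.floor(x / length)


def wrap(traj: Trajectory) -> Trajectory:
    """Return a wrapped copy of the trajectory (coordinates folded into the box)."""
    coords = traj.coords - traj.boxes[:, None, :] * np.floor(
        traj.coords / traj.boxes[:, None, :]
    )
    return Trajectory(traj.times.copy(), coords, traj.boxes.copy(), wrapped=True)

def unwrap(traj: Trajectory) -> Trajectory:
    """Reconstruct continuous per-atom paths from a wrapped trajectory.

    Frame 0 is left unchanged; each subsequent position is the wrapped
    position plus an integer number of box lengths chosen so successive
    displacements equal the minimum-image displacement of the wrapped
    input.  Valid only when true frame-to-frame motion stays below L/2
    per axis; a step hitting that bound triggers a warning naming the
    atom and frame (the unwrap is then ambiguous).
    """
    if not traj.wrapped:
        raise ValueError("trajectory is already unwrapped")
    boxes = traj.boxes
    coords = traj.coords
    out = np.empty_like(coords)
    out[0] = coords[0]
    # cumulative integer image counts, so floating error does not accumulate
    images = np.zeros_like(coords[0])
    for t in range(1, traj.n_frames):
        length = boxes[t]
        raw = coords[t] - coords[t - 1]
        shift = np.floor(raw / length + 0.5)
        images -= shift
        out[t] = coords[t] + images * length
        step = raw - shift * length
        bad = np.abs(step) >= length / 2 * (1 - 1e-12)
        if np.any(bad):
            atom = int(np.flatnonzero(bad.any(axis=1))[0])
            warnings.warn(
                f"ambiguous unwrap: atom {atom} moved >= L/2 between frames {t-1} and {t}",
                RuntimeWarning,
                stacklevel=2,
            )
    return Trajectory(traj.times.copy(), out, boxes.copy(), wrapped=False)


def select(topology: Topology, species: str) -> np.ndarray:
    """Atom indices carrying the given species tag, ascending."""
    if species not in SPECIES_TAGS:
        raise ValueError(f"unknown species {species!r}; allowed: {SPECIES_TAGS}")
    idx = np.flatnonzero(topology.species == species)
    if idx.size == 0:
        warnings.warn(f"selection {species!r} is empty", RuntimeWarning, stacklevel=2)
    return idx


# --------------------------------------------------------------------------
# trajectory readers / writers
# --------------------------------------------------------------------------

def _make_traj(times: np.ndarray, coords: np.ndarray, boxes: np.ndarray) -> Trajectory:
    # readers cannot know the wrap convention of the producer; record what holds
    return Trajectory(times, coords, boxes, wrapped=_in_box(coords, boxes))


_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_TIME_RE = re.compile(r"Time=([-+0-9.eE]+)")
_GRO_TIME_RE = re.compile(r"\bt=\s*([-+0-9.eE]+)")


def _parse_lattice(comment: str, frame: int) -> np.ndarray:
    m = _LATTICE_RE.search(comment)
    if not m:
        raise TrajectoryFormatError(f"frame {frame}: missing Lattice=\"...\" box metadata")
    vals = np.array([float(v) for v in m.group(1).split()])
    if vals.size == 3:
        return vals
    if vals.size == 9:
        mat = vals.reshape(3, 3)
        if np.any(mat - np.diag(np.diag(mat)) != 0):
            raise TrajectoryFormatError(
                f"frame {frame}: triclinic lattice not supported (orthorhombic only)"
            )
        return np.diag(mat)
    raise TrajectoryFormatError(f"frame {frame}: Lattice must have 3 or 9 numbers")


def _finalize_times(times: list[float | None], n_frames: int, dt: float | None) -> np.ndarray:
    if all(t is not None for t in times) and n_frames > 0:
        return np.asarray(times, float)
    if dt is None:
        if n_frames == 1:
            return np.zeros(1)
        raise TrajectoryFormatError(
            "no per-frame time metadata found; pass dt= (ps between frames)"
        )
    return np.arange(n_frames, dtype=float) * float(dt)


def _read_xyz(path: Path, dt: float | None) -> Trajectory:
    frames, boxes, times = [], [], []
    n_ref = None
    with open(path) as fh:
        frame = 0
        while True:
            header = fh.readline()
            if not header.strip():
                break
            try:
                n = int(header)
            except ValueError as exc:
                raise TrajectoryFormatError(f"frame {frame}: bad atom-count line {header!r}") from exc
            if n_ref is None:
                n_ref = n
            elif n != n_ref:
                raise TrajectoryFormatError(
                    f"frame {frame}: atom count changed from {n_ref} to {n}"
                )
            comment = fh.readline()
            boxes.append(_parse_lattice(comment, frame))
            m = _TIME_RE.search(comment)
            times.append(float(m.group(1)) if m else None)
            xyz = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                xyz[i] = [float(v) for v in parts[1:4]]
            frames.append(xyz)
            frame += 1
    if not frames:
        raise TrajectoryFormatError(f"{path}: no frames found")
    coords = np.stack(frames)
    return _make_traj(_finalize_times(times, len(frames), dt), coords, np.stack(boxes))


def _write_xyz(traj: Trajectory, path: Path, topology: Topology | None) -> None:
    elems = topology.elements if topology is not None else ["X"] * traj.n_atoms
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            lx, ly, lz = traj.boxes[f]
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f'Lattice="{lx:.8f} {ly:.8f} {lz:.8f}" Time={traj.times[f]:.6f}\n')
            for e, (x, y, z) in zip(elems, traj.coords[f]):
                fh.write(f"{e} {x:.8f} {y:.8f} {z:.8f}\n")


def _read_gro(path: Path, dt: float | None) -> Trajectory:
    frames, boxes, times = [], [], []
    n_ref = None
    with open(path) as fh:
        frame = 0
        while True:
            title = fh.readline()
            if not title.strip():
                break
            m = _GRO_TIME_RE.search(title)
            times.append(float(m.group(1)) if m else None)
            n = int(fh.readline())
            if n_ref is None:
                n_ref = n
            elif n != n_ref:
                raise TrajectoryFormatError(f"frame {frame}: atom count changed from {n_ref} to {n}")
            xyz = np.empty((n, 3))
            for i in range(n):
                line = fh.readline()
                # fixed columns: positions occupy 20:44 in nm
                xyz[i] = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
            box_parts = fh.readline().split()
            if len(box_parts) < 3:
                raise TrajectoryFormatError(f"frame {frame}: missing GRO box line")
            if len(box_parts) > 3 and any(float(v) != 0.0 for v in box_parts[3:]):
                raise TrajectoryFormatError(
                    f"frame {frame}: triclinic GRO box not supported (orthorhombic only)"
                )
            boxes.append(np.array([float(v) for v in box_parts[:3]]) * 10.0)
            frames.append(xyz * 10.0)  # nm -> Å
            frame += 1
    if not frames:
        raise TrajectoryFormatError(f"{path}: no frames found")
    return _make_traj(_finalize_times(times, len(frames), dt), np.stack(frames), np.stack(boxes))


def _write_gro(traj: Trajectory, path: Path, topology: Topology | None) -> None:
    elems = topology.elements if topology is not None else ["X"] * traj.n_atoms
    mols = (
        topology.molecule_ids if topology is not None else np.zeros(traj.n_atoms, int)
    )
    resnames = (
        np.where(topology.species == "water", "SOL", "RES")
        if topology is not None
        else np.array(["RES"] * traj.n_atoms)
    )
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"sorbtrack frame {f} t= {traj.times[f]:.4f}\n{traj.n_atoms}\n")
            for i in range(traj.n_atoms):
                x, y, z = traj.coords[f, i] / 10.0  # Å -> nm
                fh.write(
                    f"{int(mols[i]) % 100000:5d}{resnames[i]:<5s}{str(elems[i]):>5s}"
                    f"{(i + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            lx, ly, lz = traj.boxes[f] / 10.0
            fh.write(f"{lx:10.5f}{ly:10.5f}{lz:10.5f}\n")


def _scan_cryst1(path: Path) -> list[np.ndarray]:
    """All CRYST1 records in file order as (a, b, c, alpha, beta, gamma)."""
    records = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                records.append(
                    np.array(
                        [line[6:15], line[15:24], line[24:33], line[33:40], line[40:47], line[47:54]],
                        dtype=float,
                    )
                )
    return records


def _read_pdb(path: Path, dt: float | None) -> Trajectory:
    import MDAnalysis as mda

    crysts = _scan_cryst1(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        frames, boxes = [], []
        for frame, ts in enumerate(u.trajectory):
            if ts.dimensions is not None and np.any(ts.dimensions[:3] > 0):
                dims = np.asarray(ts.dimensions, dtype=float)
            elif len(crysts) == 1:
                # single CRYST1 applying to the whole (NVT) trajectory;
                # MDAnalysis only attaches per-MODEL records
                dims = crysts[0]
            elif frame < len(crysts):
                dims = crysts[frame]
            else:
                raise TrajectoryFormatError(f"frame {frame}: missing CRYST1 box metadata")
            if not np.allclose(dims[3:], 90.0):
                raise TrajectoryFormatError(
                    f"frame {frame}: triclinic cell not supported (orthorhombic only)"
                )
            boxes.append(dims[:3].copy())
            frames.append(ts.positions.astype(float).copy())
    coords = np.stack(frames)
    times = _finalize_times([None] * len(frames), len(frames), dt)
    return _make_traj(times, coords, np.stack(boxes))


def _write_pdb(traj: Trajectory, path: Path, topology: Topology | None) -> None:
    import MDAnalysis as mda

    n = traj.n_atoms
    if topology is not None:
        mol_ids = topology.molecule_ids
        _, res_index = np.unique(mol_ids, return_inverse=True)
        n_res = res_index.max() + 1
        resnames = []
        for m in np.unique(mol_ids):
            sp = topology.species[np.flatnonzero(mol_ids == m)[0]]
            resnames.append("HOH" if sp == "water" else "RES")
        names = [str(e) for e in topology.elements]
        elements = names
    else:
        res_index = np.zeros(n, int)
        n_res = 1
        resnames = ["RES"]
        names = elements = ["X"] * n
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n, n_residues=n_res, atom_resindex=res_index, trajectory=True
        )
        u.add_TopologyAttr("names", names)
        u.add_TopologyAttr("elements", elements)
        u.add_TopologyAttr("resnames", resnames)
        u.add_TopologyAttr("resids", list(range(1, n_res + 1)))
        with mda.Writer(str(path), n, multiframe=True) as writer:
            for f in range(traj.n_frames):
                u.atoms.positions = traj.coords[f]
                u.dimensions = [*traj.boxes[f], 90.0, 90.0, 90.0]
                writer.write(u.atoms)


_READERS = {"xyz": _read_xyz, "gro": _read_gro, "pdb": _read_pdb}
_WRITERS = {"xyz": _write_xyz, "gro": _write_gro, "pdb": _write_pdb}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
    else:
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in _READERS:
        raise TrajectoryFormatError(f"unsupported trajectory format {fmt!r}")
    return fmt


def read_trajectory(path: str | Path, format: str | None = None, dt: float | None = None) -> Trajectory:
    """Read a trajectory, converting units to Å/ps.

    ``dt`` (ps between frames) is required when the format carries no
    per-frame time metadata (PDB always; XYZ/GRO without Time=/t=).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return _READERS[_infer_format(path, format)](path, dt)


def write_trajectory(
    traj: Trajectory,
    path: str | Path,
    format: str | None = None,
    topology: Topology | None = None,
) -> Path:
    path = Path(path)
    _WRITERS[_infer_format(path, format)](traj, path, topology)
    return path


# --------------------------------------------------------------------------
# topology sidecars and builders
# --------------------------------------------------------------------------

def save_topology(topology: Topology, path: str | Path) -> Path:
    """Write a topology sidecar; JSON for ``.json``, CSV otherwise."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "atoms": [
                {
                    "element": str(topology.elements[i]),
                    "mass": float(topology.masses[i]),
                    "molecule_id": int(topology.molecule_ids[i]),
                    "species": str(topology.species[i]),
                    "donor_h": bool(topology.donor_h[i]),
                    "acceptor": bool(topology.acceptor[i]),
                }
                for i in range(topology.n_atoms)
            ],
            "bonds": [[int(i), int(j)] for i, j in topology.bonds],
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        partners: list[list[int]] = [[] for _ in range(topology.n_atoms)]
        for i, j in topology.bonds:
            partners[i].append(j)
            partners[j].append(i)
        df = pd.DataFrame(
            {
                "element": topology.elements,
                "mass": topology.masses,
                "molecule_id": topology.molecule_ids,
                "species": topology.species,
                "donor_h": topology.donor_h.astype(int),
                "acceptor": topology.acceptor.astype(int),
                "bonded_to": [";".join(map(str, sorted(p))) for p in partners],
            }
        )
        df.to_csv(path, index_label="index")
    return path


def load_topology(path: str | Path) -> Topology:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        atoms = payload["atoms"]
        return Topology(
            elements=[a["element"] for a in atoms],
            masses=[a["mass"] for a in atoms],
            molecule_ids=[a["molecule_id"] for a in atoms],
            species=[a["species"] for a in atoms],
            bonds=[tuple(b) for b in payload.get("bonds", [])],
            donor_h=[a.get("donor_h", False) for a in atoms],
            acceptor=[a.get("acceptor", False) for a in atoms],
        )
    df = pd.read_csv(path, index_col="index", keep_default_na=False)
    bonds = set()
    for i, cell in zip(df.index, df["bonded_to"].astype(str)):
        for j in filter(None, cell.split(";")):
            bonds.add(tuple(sorted((int(i), int(j)))))
    return Topology(
        elements=df["element"].tolist(),
        masses=df["mass"].to_numpy(),
        molecule_ids=df["molecule_id"].to_numpy(),
        species=df["species"].tolist(),
        bonds=sorted(bonds),
        donor_h=df["donor_h"].to_numpy().astype(bool),
        acceptor=df["acceptor"].to_numpy().astype(bool),
    )


def water_topology(n_waters: int, first_molecule_id: int = 0) -> Topology:
    """Topology for ``n_waters`` rigid waters laid out as O, H, H triads,
    with all hydrogens donor-flagged and all oxygens acceptor-flagged."""
    if n_waters < 0:
        raise ValueError("n_waters must be non-negative")
    elements = ["O", "H", "H"] * n_waters
    masses = [ATOMIC_MASSES["O"], ATOMIC_MASSES["H"], ATOMIC_MASSES["H"]] * n_waters
    molecule_ids = np.repeat(np.arange(n_waters) + first_molecule_id, 3)
    bonds = []
    donor_h = []
    acceptor = []
    for w in range(n_waters):
        o = 3 * w
        bonds += [(o, o + 1), (o, o + 2)]
        acceptor += [True, False, False]
        donor_h += [False, True, True]
    return Topology(elements, masses, molecule_ids, ["water"] * (3 * n_waters), bonds, donor_h, acceptor)


def topology_from_resnames(
    resnames: Sequence[str],
    elements: Sequence[str],
    molecule_ids: Sequence[int],
    bonds: Iterable[tuple[int, int]] = (),
    filler_resnames: Iterable[str] = (),
) -> Topology:
    """Derive a topology from residue names: residues named HOH/SOL/WAT/...
    become water (with O-H bonds and donor/acceptor flags inferred),
    ``filler_resnames`` become filler, everything else polymer."""
    resnames = np.asarray(resnames, dtype=object)
    elements = np.asarray(elements, dtype=object)
    molecule_ids = np.asarray(molecule_ids, dtype=int)
    filler = {r.upper() for r in filler_resnames}
    species = []
    for r in resnames:
        r_up = str(r).upper()
        if r_up in WATER_RESNAMES:
            species.append("water")
        elif r_up in filler:
            species.append("filler")
        else:
            species.append("polymer")
    species = np.asarray(species, dtype=object)
    masses = np.array([ATOMIC_MASSES.get(str(e), 12.0) for e in elements])
    bonds = {tuple(sorted((int(i), int(j)))) for i, j in bonds}
    donor_h = np.zeros(len(elements), bool)
    acceptor = np.zeros(len(elements), bool)
    for mol in np.unique(molecule_ids[species == "water"]):
        atoms = np.flatnonzero(molecule_ids == mol)
        o = atoms[np.flatnonzero(elements[atoms] == "O")[0]]
        acceptor[o] = True
        for h in atoms[elements[atoms] == "H"]:
            bonds.add(tuple(sorted((int(o), int(h)))))
            donor_h[h] = True
    return Topology(elements, masses, molecule_ids, species, sorted(bonds), donor_h, acceptor)
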