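import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from sorbtrack import (
    Box,
    Trajectory,
    minimum_image_displacement,
    read_trajectory,
    select,
    unwrap,
    wrap,
    write_trajectory,
)
from sorbtrack.msd import compute_msd
from sorbtrack.trajio import (
    Topology,
    TopologyError,
    TrajectoryFormatError,
    load_topology,
    save_topology,
    topology_from_resnames,
    water_topology,
    wrap_coords,
)

from oracles import min_image_27


# ----------------------------------------------------------------- parsing

def test_xyz_parse_two_frames(tmp_path):
    text = (
        "3\n"
        'Lattice="30 30 30" Time=0.0\n'
        "O 1.0 2.0 3.0\nH 1.5 2.0 3.0\nH 0.5 2.0 3.0\n"
        "3\n"
        'Lattice="30 30 30" Time=5.0\n'
        "O 1.1 2.0 3.0\nH 1.6 2.0 3.0\nH 0.6 2.0 3.0\n"
    )
    p = tmp_path / "t.xyz"
    p.write_text(text)
    traj = read_trajectory(p)
    assert traj.n_frames == 2 and traj.n_atoms == 3
    assert np.allclose(traj.boxes, 30.0)
    assert traj.dt == 5.0
    assert traj.coords[0, 0, 0] == 1.0


def test_gro_nm_to_angstrom(tmp_path):
    text = (
        "frame t= 0.0\n1\n"
        "    1SOL     O    1   1.500   0.200   0.300\n"
        "   3.00000   3.00000   3.00000\n"
    )
    p = tmp_path / "t.gro"
    p.write_text(text)
    traj = read_trajectory(p)
    assert traj.coords[0, 0, 0] == pytest.approx(15.0)
    assert np.allclose(traj.boxes[0], 30.0)


@pytest.mark.parametrize("fmt,tol", [("xyz", 1e-7), ("gro", 1.1e-2), ("pdb", 2e-3)])
def test_roundtrip_to_printed_precision(small_brownian, tmp_path, fmt, tol):
    _, wrapped, _, topo = small_brownian
    p = tmp_path / f"rt.{fmt}"
    write_trajectory(wrapped, p, topology=topo)
    back = read_trajectory(p, dt=5.0)
    assert back.n_frames == wrapped.n_frames
    assert np.abs(back.coords - wrapped.coords).max() < tol
    assert np.allclose(back.boxes, wrapped.boxes, atol=1e-2)


def test_missing_lattice_is_hard_error(tmp_path):
    p = tmp_path / "bad.xyz"
    p.write_text("1\nno box here\nO 1 2 3\n")
    with pytest.raises(TrajectoryFormatError, match="frame 0"):
        read_trajectory(p)


def test_triclinic_lattice_rejected(tmp_path):
    p = tmp_path / "tri.xyz"
    p.write_text('1\nLattice="30 0 0 5 30 0 0 0 30"\nO 1 2 3\n')
    with pytest.raises(TrajectoryFormatError, match="triclinic"):
        read_trajectory(p)


def test_atom_count_change_rejected(tmp_path):
    p = tmp_path / "n.xyz"
    p.write_text(
        '2\nLattice="30 30 30" Time=0\nO 1 2 3\nH 2 2 3\n'
        '1\nLattice="30 30 30" Time=5\nO 1 2 3\n'
    )
    with pytest.raises(TrajectoryFormatError, match="atom count"):
        read_trajectory(p)


def test_nonuniform_times_rejected(tmp_path):
    p = tmp_path / "t.xyz"
    p.write_text(
        '1\nLattice="30 30 30" Time=0\nO 1 2 3\n'
        '1\nLattice="30 30 30" Time=5\nO 1 2 3\n'
        '1\nLattice="30 30 30" Time=20\nO 1 2 3\n'
    )
    with pytest.raises(TrajectoryFormatError, match="non-uniform"):
        read_trajectory(p)


# ------------------------------------------------------ minimum image / wrap

def test_minimum_image_wraparound_case():
    box = Box.cubic(10.0)
    d = minimum_image_displacement(np.array([1.0, 0, 0]), np.array([9.0, 0, 0]), box)
    assert np.allclose(d, [-2.0, 0, 0])
    assert np.linalg.norm(d) == pytest.approx(2.0)


def test_minimum_image_identity():
    a = np.array([3.0, 4.0, 5.0])
    assert np.allclose(minimum_image_displacement(a, a, Box.cubic(12.0)), 0.0)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    a=hst.tuples(*[hst.floats(0, 25) for _ in range(3)]),
    b=hst.tuples(*[hst.floats(0, 25) for _ in range(3)]),
    lengths=hst.tuples(*[hst.floats(5, 25) for _ in range(3)]),
)
def test_minimum_image_matches_27_image_bruteforce(a, b, lengths):
    a, b, lengths = np.array(a), np.array(b), np.array(lengths)
    a, b = wrap_coords(a, lengths), wrap_coords(b, lengths)
    d = minimum_image_displacement(a, b, Box(lengths))
    ref = min_image_27(a, b, lengths)
    assert np.linalg.norm(d) == pytest.approx(np.linalg.norm(ref), abs=1e-9)
    # global bound on the minimum-image norm
    assert np.linalg.norm(d) <= np.sqrt(3) / 2 * lengths.max() + 1e-12


def test_unwrap_single_crossing():
    times = [0.0, 1.0]
    coords = np.array([[[9.8, 5, 5]], [[0.3, 5, 5]]])
    traj = Trajectory(times, coords, np.array([10.0, 10, 10]), wrapped=True)
    u = unwrap(traj)
    assert u.coords[1, 0, 0] == pytest.approx(10.3)


def test_wrap_unwrap_inverse(small_brownian):
    _, wrapped, _, _ = small_brownian
    rewrapped = wrap(unwrap(wrapped))
    assert np.allclose(rewrapped.coords, wrapped.coords, atol=1e-8)


def test_msd_invariant_under_wrap_unwrap(small_brownian):
    """Unwrapping the wrapped trajectory reproduces the ground-truth MSD."""
    _, wrapped, continuous, topo = small_brownian
    a = compute_msd(unwrap(wrapped), topo, max_lag=100.0)
    b = compute_msd(continuous, topo, max_lag=100.0)
    assert np.allclose(a.values, b.values, rtol=1e-9, atol=1e-9)


def test_unwrap_warns_on_ambiguous_step():
    coords = np.array([[[0.1, 5, 5]], [[5.1, 5, 5]]])  # step of exactly L/2
    traj = Trajectory([0.0, 1.0], coords, np.array([10.0, 10, 10]), wrapped=True)
    with pytest.warns(RuntimeWarning, match="ambiguous unwrap"):
        unwrap(traj)


def test_wrapped_flag_requires_in_box_coords():
    with pytest.raises(ValueError, match="wrapped"):
        Trajectory([0.0], np.array([[[12.0, 0, 0]]]), np.array([10.0, 10, 10]), wrapped=True)


# --------------------------------------------------------------- selections

def test_select_counts_and_partition():
    topo = water_topology(3)
    assert len(select(topo, "water")) == 9
    with pytest.warns(RuntimeWarning, match="empty"):
        assert len(select(topo, "filler")) == 0
    with pytest.warns(RuntimeWarning):
        all_idx = np.concatenate([select(topo, s) for s in ("water", "polymer", "filler")])
    assert sorted(all_idx) == list(range(topo.n_atoms))


def test_topology_roundtrip(tmp_path, small_brownian):
    _, _, _, topo = small_brownian
    for name in ("topo.json", "topo.csv"):
        p = tmp_path / name
        save_topology(topo, p)
        back = load_topology(p)
        assert list(back.elements) == list(topo.elements)
        assert np.allclose(back.masses, topo.masses)
        assert sorted(back.bonds) == sorted(topo.bonds)
        assert np.array_equal(back.donor_h, topo.donor_h)
        assert np.array_equal(back.acceptor, topo.acceptor)


def test_topology_from_resnames_flags_water():
    topo = topology_from_resnames(
        resnames=["SOL", "SOL", "SOL", "RES"],
        elements=["O", "H", "H", "C"],
        molecule_ids=[0, 0, 0, 1],
    )
    assert list(topo.species) == ["water", "water", "water", "polymer"]
    assert topo.acceptor[0] and topo.donor_h[1] and topo.donor_h[2]
    assert (0, 1) in topo.bonds and (0, 2) in topo.bonds


def test_invalid_topologies_rejected():
    with pytest.raises(TopologyError, match="water molecule"):
        Topology(["O", "H"], [16.0, 1.0], [0, 0], ["water", "water"], [(0, 1)])
    with pytest.raises(TopologyError, match="masses"):
        Topology(["O"], [0.0], [0], ["polymer"])
    with pytest.raises(TopologyError, match="donor"):
        Topology(["H"], [1.0], [0], ["polymer"], donor_h=[True])
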