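import math

import numpy as np
import pytest

from sorbtrack import (
    HBondCriteria,
    HBondScene,
    detect_hbonds,
    gen_hbond_scene,
    hbond_profile,
    pw_by_difference,
)
from sorbtrack.hbond import classify
from sorbtrack.trajio import Box, Topology, TopologyError, Trajectory, water_topology

from conftest import random_hbond_topology
from oracles import brute_hbonds


def _scene_bonds(triplets, criteria=None):
    traj, topo = gen_hbond_scene(HBondScene(triplets=list(triplets)))
    return detect_hbonds(traj.coords[0], topo, traj.box(0), criteria), traj, topo


# ------------------------------------------------------------- boundaries

@pytest.mark.parametrize(
    "triplet,expected",
    [
        ((2.7, 180.0, 120.0, "water", "polymer"), 1),  # all criteria met
        ((2.8, 180.0, 180.0, "water", "polymer"), 0),  # distance bound is strict
        ((2.5, 119.0, 120.0, "water", "polymer"), 0),  # donor angle below threshold
        ((2.5, 120.0, 90.0, "polymer", "polymer"), 1),  # both angle bounds inclusive
        ((2.5, 150.0, 89.0, "water", "polymer"), 0),   # acceptor angle below threshold
        ((2.7999, 120.0, 90.0, "water", "polymer"), 1),  # just inside every bound
    ],
)
def test_criteria_boundaries(triplet, expected):
    bonds, _, _ = _scene_bonds([triplet])
    assert len(bonds) == expected


def test_water_acceptor_angle_is_vacuous():
    # water oxygens have no heavy neighbour, so the acceptor-angle test
    # cannot fail for them
    bonds, _, _ = _scene_bonds([(2.5, 150.0, 45.0, "polymer", "water")])
    assert len(bonds) == 1


def test_water_dimer_yields_one_bond_no_mirror():
    """Ideal donated hydrogen gives exactly one bond, never a reversed duplicate."""
    half = math.radians(104.52) / 2
    r = 0.9572
    donor_o = np.array([5.0, 5.0, 5.0])
    h1 = donor_o + [r, 0.0, 0.0]                       # donated, points at acceptor
    h2 = donor_o + r * np.array([math.cos(math.radians(104.52)), math.sin(math.radians(104.52)), 0])
    acc_o = donor_o + [2.9, 0.0, 0.0]
    h3 = acc_o + r * np.array([math.cos(half), math.sin(half), 0.0])
    h4 = acc_o + r * np.array([math.cos(half), -math.sin(half), 0.0])
    coords = np.array([donor_o, h1, h2, acc_o, h3, h4])
    topo = water_topology(2)
    bonds = detect_hbonds(coords, topo, Box.cubic(30.0))
    assert len(bonds) == 1
    b = bonds[0]
    assert (b.donor, b.hydrogen, b.acceptor) == (0, 1, 3)
    assert b.cls == "ww"


def test_intramolecular_water_excluded_polymer_beyond_3_bonds_allowed():
    # chain C0-O1-H2 ... C3-C4-C5-O6 (acceptor): donor O1 to acceptor O6 is
    # 5 bonds away -> allowed; a 3-bond-near acceptor O7 on C3 is excluded
    elements = ["C", "O", "H", "C", "C", "C", "O", "O"]
    masses = [12.011, 15.999, 1.008, 12.011, 12.011, 12.011, 15.999, 15.999]
    bonds = [(0, 1), (1, 2), (0, 3), (3, 4), (4, 5), (5, 6), (3, 7)]
    topo = Topology(
        elements, masses, [0] * 8, ["polymer"] * 8, bonds,
        donor_h=[False, False, True] + [False] * 5,
        acceptor=[False, True] + [False] * 4 + [True, True],
    )
    # geometry: both candidate acceptors at a perfect H-bond position
    # (distance 2.0 Å from H, donor and acceptor angles passing)
    coords = np.array([
        [4.0, 5.0, 5.0],   # C0
        [5.0, 5.0, 5.0],   # O1 donor
        [5.96, 5.0, 5.0],  # H2 donated
        [5.96, 9.0, 5.0],  # C3 (heavy neighbour of O7, straight behind it)
        [10.0, 9.0, 5.0],  # C4
        [9.2, 6.5, 5.0],   # C5 (heavy neighbour of O6, obtuse to H)
        [7.96, 5.0, 5.0],  # O6 far along chain (5 bonds) at 2.0 Å from H
        [5.96, 7.0, 5.0],  # O7 near in chain (3 bonds), 2.0 Å from H
    ])
    found = detect_hbonds(coords, topo, Box.cubic(30.0))
    acceptors = {b.acceptor for b in found}
    assert 6 in acceptors  # > 3 bonds apart: allowed
    assert 7 not in acceptors  # <= 3 bonds apart: excluded


def test_hydrogen_without_heavy_neighbor_is_topology_defect():
    topo = Topology(
        ["O", "H"], [15.999, 1.008], [0, 1], ["polymer", "polymer"],
        bonds=[], donor_h=[False, True], acceptor=[True, False], validate=False,
    )
    coords = np.array([[5.0, 5, 5], [7.0, 5, 5]])
    with pytest.raises(TopologyError, match="no bonded heavy"):
        detect_hbonds(coords, topo, Box.cubic(20.0))


# --------------------------------------------------------- oracle equivalence

def test_detector_matches_bruteforce_triple_loop_on_random_scenes():
    rng = np.random.default_rng(99)
    for _ in range(200):
        topo = random_hbond_topology(
            rng,
            n_waters=int(rng.integers(2, 9)),
            n_carbonyls=int(rng.integers(0, 5)),
            n_hydroxyls=int(rng.integers(0, 5)),
        )
        assert topo.n_atoms <= 60
        L = float(rng.uniform(8.0, 16.0))
        coords = rng.uniform(0, L, size=(topo.n_atoms, 3))
        box = Box.cubic(L)
        ours = {(b.donor, b.hydrogen, b.acceptor) for b in detect_hbonds(coords, topo, box)}
        ref = brute_hbonds(coords, topo, box.lengths)
        assert ours == ref


def test_loosening_any_threshold_never_decreases_count():
    rng = np.random.default_rng(3)
    topo = random_hbond_topology(rng, n_waters=8, n_carbonyls=4, n_hydroxyls=4)
    L = 14.0
    coords = rng.uniform(0, L, size=(topo.n_atoms, 3))
    box = Box.cubic(L)
    base = HBondCriteria()
    n_base = len(detect_hbonds(coords, topo, box, base))
    for loosened in (
        HBondCriteria(max_ha=3.4),
        HBondCriteria(min_donor_angle=100.0),
        HBondCriteria(min_acceptor_angle=60.0),
        HBondCriteria(max_ha=3.4, min_donor_angle=90.0, min_acceptor_angle=0.0),
    ):
        assert len(detect_hbonds(coords, topo, box, loosened)) >= n_base


# ---------------------------------------------------------- classification

def test_classify_counts_planted_classes():
    triplets = (
        [(2.0, 175.0, 150.0, "water", "water")] * 2
        + [(2.2, 170.0, 140.0, "polymer", "polymer")]
        + [(2.4, 165.0, 130.0, "water", "polymer")] * 3
    )
    bonds, _, topo = _scene_bonds(triplets)
    counts = classify(bonds, topo)
    assert counts.n_ww[0] == 2 and counts.n_pp[0] == 1 and counts.n_pw[0] == 3
    assert counts.n_total[0] == 6


def test_pw_by_difference_values_and_errors():
    assert pw_by_difference(666, 251, 78) == 337
    assert pw_by_difference(674, 257, 80) == 337
    assert pw_by_difference(0, 0, 0) == 0
    with pytest.raises(ValueError, match="inconsistent"):
        pw_by_difference(5, 4, 3)


def test_eq3_difference_equals_direct_classification_every_frame(small_brownian):
    _, wrapped, _, topo = small_brownian
    counts = hbond_profile(wrapped, topo, stride=10)
    for i in range(len(counts.frames)):
        assert pw_by_difference(int(counts.n_total[i]), int(counts.n_pp[i]), int(counts.n_ww[i])) == counts.n_pw[i]


# ---------------------------------------------------------------- profiles

def test_static_scene_constant_profile():
    traj, topo = gen_hbond_scene(HBondScene(triplets=[(2.0, 175.0, 150.0, "water", "water")]))
    frames = np.repeat(traj.coords, 5, axis=0)
    traj5 = Trajectory(np.arange(5.0), frames, np.repeat(traj.boxes, 5, axis=0), wrapped=True)
    counts = hbond_profile(traj5, topo)
    assert np.all(counts.n_total == 1)
    assert counts.summary().query("interaction == 'Total'")["sd"].item() == 0.0


def test_two_frame_toggle_profile():
    topo = water_topology(2)
    near = np.array(
        [[5.0, 5, 5], [5.96, 5, 5], [4.76, 5.93, 5], [7.9, 5, 5], [8.5, 5.7, 5], [8.5, 4.3, 5]]
    )
    far = near.copy()
    far[3:] += [10.0, 0, 0]  # acceptor water moved out of range
    coords = np.stack([far, near])
    traj = Trajectory([0.0, 1.0], coords, np.full(3, 30.0), wrapped=True)
    counts = hbond_profile(traj, topo)
    assert list(counts.n_total) == [0, 1]
    assert counts.summary().query("interaction == 'Total'")["mean"].item() == 0.5


def test_scheduled_bond_series_matches_schedule():
    topo = water_topology(2)
    base = np.array(
        [[5.0, 5, 5], [5.96, 5, 5], [4.76, 5.93, 5], [7.9, 5, 5], [8.5, 5.7, 5], [8.5, 4.3, 5]]
    )
    schedule = [1, 0, 1, 1, 0, 0, 1]
    frames = []
    for on in schedule:
        f = base.copy()
        if not on:
            f[3:] += [12.0, 0, 0]
        frames.append(f)
    traj = Trajectory(np.arange(float(len(schedule))), np.stack(frames), np.full(3, 30.0), wrapped=True)
    counts = hbond_profile(traj, topo)
    assert list(counts.n_total) == schedule
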