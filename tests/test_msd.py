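import numpy as np
import pytest

from sorbtrack import (
    SyntheticSpec,
    compute_msd,
    detect_linear_window,
    fit_diffusion,
    gen_walkers,
    loglog_slope,
)
from sorbtrack.msd import (
    M2S_PER_A2PS,
    MSDCurve,
    NoLinearWindowError,
    block_stderr,
    estimate_diffusion,
)
from sorbtrack.trajio import Trajectory, water_topology

from oracles import brute_msd


def _single_molecule_traj(positions, dt=1.0, box=1000.0):
    """One 'molecule' per coordinate path; masses irrelevant (single site)."""
    pos = np.asarray(positions, float)  # (T, M, 3)
    T = pos.shape[0]
    return Trajectory(np.arange(T) * dt, pos, np.full(3, box), wrapped=False)


def test_static_trajectory_has_zero_msd():
    pos = np.tile(np.array([[1.0, 2.0, 3.0]]), (8, 1, 1))
    traj = _single_molecule_traj(pos)
    curve = compute_msd(traj, groups=[np.array([0])])
    assert np.allclose(curve.values, 0.0)


def test_constant_velocity_closed_form():
    v = np.array([0.3, -0.1, 0.2])
    t = np.arange(20)[:, None, None]
    traj = _single_molecule_traj(5.0 + v * t, dt=1.0)
    curve = compute_msd(traj, groups=[np.array([0])])
    expected = (np.linalg.norm(v) * curve.lags) ** 2
    assert np.allclose(curve.values, expected, rtol=1e-10)


@pytest.mark.parametrize("stride", [1, 2, 3])
@pytest.mark.parametrize("shape", [(6, 2), (50, 10)])
def test_fast_msd_equals_bruteforce_double_loop(stride, shape):
    T, M = shape
    rng = np.random.default_rng(T * 10 + stride)
    pos = rng.normal(scale=3.0, size=(T, M, 3)).cumsum(axis=0)
    traj = _single_molecule_traj(pos, dt=2.0)
    max_frames = T - 1
    curve = compute_msd(traj, groups=[np.array([m]) for m in range(M)], origin_stride=stride)
    ref_vals, ref_counts = brute_msd(pos, max_frames, stride=stride)
    assert np.allclose(curve.values, ref_vals, rtol=1e-10, atol=1e-10)
    assert np.array_equal(curve.n_samples, ref_counts)


def test_msd_cross_checked_against_mdanalysis():
    """Independent route: MDAnalysis EinsteinMSD on the same coordinates."""
    import MDAnalysis as mda
    from MDAnalysis.analysis import msd as mda_msd

    rng = np.random.default_rng(5)
    pos = rng.normal(scale=2.0, size=(40, 6, 3)).cumsum(axis=0)
    traj = _single_molecule_traj(pos, dt=1.0)
    curve = compute_msd(traj, groups=[np.array([m]) for m in range(6)])

    u = mda.Universe.empty(6, trajectory=True)
    u.load_new(pos.astype(np.float32), format="memory", dt=1.0)
    analysis = mda_msd.EinsteinMSD(u, select="all", msd_type="xyz", fft=False)
    analysis.run()
    ref = analysis.results.timeseries  # lag 0 included
    assert np.allclose(curve.values, ref[1:], rtol=1e-5, atol=1e-4)


def test_wrapped_trajectory_is_hard_error(small_brownian):
    _, wrapped, _, topo = small_brownian
    with pytest.raises(ValueError, match="unwrap"):
        compute_msd(wrapped, topo)


def test_n_samples_non_increasing(small_brownian):
    _, _, continuous, topo = small_brownian
    curve = compute_msd(continuous, topo)
    assert np.all(np.diff(curve.n_samples) <= 0)


# ----------------------------------------------------------- log-log slopes

def _curve_from_fn(fn, lags):
    lags = np.asarray(lags, float)
    return MSDCurve(lags, fn(lags), np.full(len(lags), 100))


def test_loglog_slope_of_pure_power_laws():
    lags = np.arange(1.0, 200.0)
    lin = _curve_from_fn(lambda t: 6 * 1e-3 * t, lags)
    bal = _curve_from_fn(lambda t: 0.04 * t**2, lags)
    assert np.allclose(loglog_slope(lin), 1.0, atol=1e-6)
    assert np.allclose(loglog_slope(bal), 2.0, atol=1e-6)


def test_loglog_slope_transitions_at_crossover():
    lags = np.arange(10.0, 4000.0, 10.0)
    cross = 2000.0
    curve = _curve_from_fn(lambda t: np.where(t <= cross, 6e-3 * t, 6e-3 * cross), lags)
    slopes = loglog_slope(curve)
    assert slopes[5] == pytest.approx(1.0, abs=1e-6)
    assert abs(slopes[-5]) < 1e-6


def test_detect_window_full_range_for_power_law():
    lags = np.arange(5.0, 500.0, 5.0)
    curve = _curve_from_fn(lambda t: 0.01 * t, lags)
    t0, t1 = detect_linear_window(curve)
    assert t0 == lags[0] and t1 == lags[-1]


def test_detect_window_finds_crossover_near_2ns():
    lags = np.arange(10.0, 4000.0, 10.0)
    curve = _curve_from_fn(lambda t: np.where(t <= 2000.0, 6e-3 * t, 12.0), lags)
    t0, t1 = detect_linear_window(curve)
    assert 1600.0 <= t1 <= 2400.0


def test_detect_window_rejects_ballistic():
    lags = np.arange(5.0, 500.0, 5.0)
    curve = _curve_from_fn(lambda t: 0.01 * t**2, lags)
    with pytest.raises(NoLinearWindowError):
        detect_linear_window(curve)


def test_detect_window_excludes_early_ballistic_regime():
    # ballistic up to 50 ps, then diffusive
    lags = np.arange(1.0, 400.0)
    tc = 50.0
    curve = _curve_from_fn(lambda t: np.where(t <= tc, 0.006 * t**2, 0.006 * tc * t), lags)
    t0, t1 = detect_linear_window(curve)
    assert t0 > tc


# ------------------------------------------------------------- Einstein fit

def test_fit_unit_bookkeeping():
    lags = np.arange(5.0, 500.0, 5.0)
    curve = _curve_from_fn(lambda t: 6 * 1e-4 * t, lags)
    est = fit_diffusion(curve, (lags[0], lags[-1]), n_molecules=10)
    assert est.d == pytest.approx(1.0e-12, rel=1e-9)
    assert est.slope == pytest.approx(6e-4, rel=1e-9)
    assert est.r_squared == pytest.approx(1.0)


def test_fit_rejects_negative_slope():
    lags = np.arange(1.0, 50.0)
    curve = MSDCurve(lags, 100.0 - lags, np.full(len(lags), 10))
    with pytest.raises(ValueError, match="non-diffusive"):
        fit_diffusion(curve, (1.0, 49.0), n_molecules=5)


def test_fit_window_needs_five_points():
    lags = np.arange(1.0, 50.0)
    curve = _curve_from_fn(lambda t: t, lags)
    with pytest.raises(ValueError, match="5"):
        fit_diffusion(curve, (1.0, 3.0), n_molecules=5)


def test_diffusion_recovery_moderate_ensemble():
    d_true = 1e-9
    spec = SyntheticSpec(mode="brownian", n_molecules=300, n_frames=800, d_true=d_true, box=30.0, seed=23)
    _, continuous, topo = gen_walkers(spec)
    est, _ = estimate_diffusion(continuous, topo)
    assert abs(est.d - d_true) / d_true < 0.05


# ------------------------------------------------------------- block stderr

def test_block_stderr_zero_for_identical_deterministic_molecules():
    v = np.array([0.1, 0.0, 0.0])
    t = np.arange(60)[:, None, None]
    pos = np.tile((5.0 + v * t), (1, 12, 1))
    topo = water_topology(12)
    coords = np.repeat(pos, 3, axis=1)  # all three water sites on the walker point
    traj = Trajectory(np.arange(60.0), coords, np.full(3, 1e6), wrapped=False)
    se = block_stderr(traj, topo, window=(5.0, 50.0), n_blocks=4)
    assert se == pytest.approx(0.0, abs=1e-20)


def test_block_stderr_shrinks_with_molecule_count():
    def run(n, seed):
        spec = SyntheticSpec(mode="brownian", n_molecules=n, n_frames=300, d_true=1e-9, box=30.0, seed=seed)
        _, cont, topo = gen_walkers(spec)
        return block_stderr(cont, topo, window=(5.0, 150.0), n_blocks=5)

    # a 5-block stderr is itself noisy; average over seeds before comparing
    se_small = np.mean([run(100, s) for s in (31, 32, 33, 34, 35)])
    se_big = np.mean([run(400, s) for s in (31, 32, 33, 34, 35)])
    assert se_big < se_small
    # expect roughly a factor 2 (1/sqrt(4)); allow a generous band
    assert 1.3 < se_small / se_big < 3.0


def test_block_stderr_within_3x_of_independent_rerun_spread():
    window = (5.0, 100.0)

    def one_run(seed):
        spec = SyntheticSpec(mode="brownian", n_molecules=60, n_frames=200, d_true=1e-9, box=30.0, seed=seed)
        _, cont, topo = gen_walkers(spec)
        return estimate_diffusion(cont, topo, window=window, max_lag=window[1])[0].d

    spread = np.std([one_run(s) for s in range(100, 120)], ddof=1)
    spec = SyntheticSpec(mode="brownian", n_molecules=60, n_frames=200, d_true=1e-9, box=30.0, seed=100)
    _, cont, topo = gen_walkers(spec)
    se = block_stderr(cont, topo, window=window, n_blocks=5)
    assert spread / 3 < se < spread * 3


def test_block_stderr_requires_enough_molecules():
    spec = SyntheticSpec(mode="brownian", n_molecules=6, n_frames=50, d_true=1e-9, box=30.0, seed=1)
    _, cont, topo = gen_walkers(spec)
    with pytest.raises(ValueError, match="blocks"):
        block_stderr(cont, topo, window=(5.0, 25.0), n_blocks=5)
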