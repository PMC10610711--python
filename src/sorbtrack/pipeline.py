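"""Config-driven orchestration of the analysis stages.

A single YAML/JSON run configuration names the inputs (a trajectory +
topology on disk, or an inline synthetic-walker recipe), switches the
stages on or off, and surfaces every parameter the analyses expose
(MSD max lag and origin stride, slope band, hydrogen-bond thresholds,
cluster cutoff, density binning, block count).  ``run_pipeline`` writes
per-stage CSV/JSON artifacts, a checksummed manifest, and a summary
report; identical config + inputs + seed give byte-identical output.

Also hosts the equilibration drift check used on scalar time series
(potential/kinetic energy, density): the least-squares slope over the
tail of the series, passed when the accumulated drift over the tail is
within 1% of the tail mean.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import clusters as clusters_mod
from . import densproj as densproj_mod
from . import hbond as hbond_mod
from . import msd as msd_mod
from . import synthgen, trajio

__all__ = [
    "ScalarSeries",
    "DriftResult",
    "RunConfig",
    "equilibration_drift",
    "run_pipeline",
]

log = logging.getLogger("sorbtrack.pipeline")


@dataclass
class ScalarSeries:
    """A labelled scalar time series (e.g. potential energy in kcal/mol)."""

    times: np.ndarray  # ps
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class DriftResult:
    slope_per_ns: float
    drift_over_tail: float
    tail_mean: float
    relative_drift: float | None
    passed: bool

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def equilibration_drift(
    series: ScalarSeries,
    tail_fraction: float = 0.5,
    rel_tol: float = 0.01,
    abs_tol: float | None = None,
) -> DriftResult:
    """Drift statistic over the tail of a scalar series.

    Least-squares slope over the last ``tail_fraction`` of the series;
    the check passes when |slope × tail span| <= ``rel_tol`` × |tail
    mean|.  For a (near-)zero-mean series the relative criterion is
    replaced by the absolute threshold ``abs_tol``, which must then be
    provided.
    """
    if not 0 < tail_fraction <= 1:
        raise ValueError("tail_fraction must lie in (0, 1]")
    n = len(series.values)
    if n < 10:
        raise ValueError("need at least 10 samples for a drift estimate")
    start = n - max(2, int(round(tail_fraction * n)))
    t = series.times[start:]
    v = series.values[start:]
    res = stats.linregress(t, v)
    span = float(t[-1] - t[0])
    drift = float(res.slope * span)
    mean = float(v.mean())
    if abs(mean) > 1e-12 * max(1.0, float(np.abs(v).max())):
        rel = abs(drift) / abs(mean)
        passed = rel <= rel_tol
    else:
        if abs_tol is None:
            raise ValueError("zero-mean series: provide abs_tol for the drift criterion")
        rel = None
        passed = abs(drift) <= abs_tol
    return DriftResult(
        slope_per_ns=float(res.slope * 1000.0),  # per ps -> per ns
        drift_over_tail=drift,
        tail_mean=mean,
        relative_drift=rel,
        passed=bool(passed),
    )


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

def _default_stages() -> dict:
    return {
        "msd": {"enabled": True},
        "hbond": {"enabled": True},
        "clusters": {"enabled": True},
        "density": {"enabled": True},
        "equilibration": {"enabled": False},
    }


@dataclass
class RunConfig:
    """Everything a pipeline run needs; every analysis parameter the
    underlying modules expose is settable here."""

    output_dir: str = "sorbtrack_out"
    seed: int = 0
    trajectory: dict | None = None  # {path, format, dt, topology}
    synthetic: dict | None = None   # SyntheticSpec fields
    stages: dict = field(default_factory=_default_stages)

    def __post_init__(self) -> None:
        if (self.trajectory is None) == (self.synthetic is None):
            raise ValueError("configure exactly one of 'trajectory' or 'synthetic'")
        base = _default_stages()
        for name, cfg in (self.stages or {}).items():
            if name not in base:
                raise ValueError(f"unknown stage {name!r}")
            base[name].update(cfg or {})
        self.stages = base
        if self.trajectory is not None:
            for key in ("path", "topology"):
                if key not in self.trajectory:
                    raise ValueError(f"trajectory config needs {key!r}")
                if not Path(self.trajectory[key]).exists():
                    raise FileNotFoundError(self.trajectory[key])

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _json_default(o: Any):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True, default=_json_default) + "\n")


def _load_inputs(config: RunConfig) -> tuple[trajio.Trajectory, trajio.Topology]:
    if config.synthetic is not None:
        spec_kwargs = dict(config.synthetic)
        spec_kwargs.setdefault("seed", config.seed)
        spec = synthgen.SyntheticSpec(**spec_kwargs)
        wrapped, _continuous, topo = synthgen.gen_walkers(spec)
        return wrapped, topo
    tcfg = config.trajectory
    traj = trajio.read_trajectory(tcfg["path"], format=tcfg.get("format"), dt=tcfg.get("dt"))
    topo = trajio.load_topology(tcfg["topology"])
    return traj, topo


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and write artifacts + manifest.

    Stage failures are recorded in the report under ``errors``;
    independent stages still run.  Returns the report dict (also
    written to ``report.json``)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"stages": {}, "errors": {}, "timing_s": {}}
    artifacts: list[Path] = []

    traj, topo = _load_inputs(config)
    report["input"] = {
        "n_frames": traj.n_frames,
        "n_atoms": topo.n_atoms,
        "source": "synthetic" if config.synthetic is not None else config.trajectory["path"],
    }

    def run_stage(name, fn):
        cfg = config.stages[name]
        if not cfg.get("enabled", True):
            log.info("stage %s disabled", name)
            return
        t0 = time.perf_counter()
        try:
            fn(cfg)
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            log.error("stage %s failed: %s", name, exc)
            report["errors"][name] = f"{type(exc).__name__}: {exc}"
        report["timing_s"][name] = round(time.perf_counter() - t0, 4)

    def stage_msd(cfg):
        work = traj if not traj.wrapped else trajio.unwrap(traj)
        est, curve = msd_mod.estimate_diffusion(
            work,
            topo,
            species=cfg.get("species", "water"),
            max_lag=cfg.get("max_lag"),
            origin_stride=cfg.get("origin_stride", 1),
            window=tuple(cfg["window"]) if cfg.get("window") else None,
            slope_band=tuple(cfg.get("slope_band", (0.9, 1.1))),
            min_span_decades=cfg.get("min_span_decades", 0.5),
            n_blocks=cfg.get("n_blocks", 5),
        )
        curve_path = outdir / "msd_curve.csv"
        curve.to_frame().to_csv(curve_path, index=False)
        slopes = msd_mod.loglog_slope(curve)
        slope_path = outdir / "loglog_slope.csv"
        pd.DataFrame({"lag_ps": curve.lags, "loglog_slope": slopes}).to_csv(slope_path, index=False)
        dpath = outdir / "diffusion.json"
        _write_json(est.to_dict(), dpath)
        artifacts.extend([curve_path, slope_path, dpath])
        report["stages"]["msd"] = est.to_dict()

    def stage_hbond(cfg):
        criteria = hbond_mod.HBondCriteria(
            max_ha=cfg.get("max_ha", 2.8),
            min_donor_angle=cfg.get("min_donor_angle", 120.0),
            min_acceptor_angle=cfg.get("min_acceptor_angle", 90.0),
        )
        counts = hbond_mod.hbond_profile(traj, topo, criteria, stride=cfg.get("stride", 1))
        ppath = outdir / "hbond_profile.csv"
        counts.to_frame().to_csv(ppath, index=False)
        spath = outdir / "hbond_summary.json"
        summary = counts.summary().to_dict(orient="records")
        _write_json({"criteria": dataclasses.asdict(criteria), "summary": summary}, spath)
        artifacts.extend([ppath, spath])
        report["stages"]["hbond"] = summary

    def stage_clusters(cfg):
        series = clusters_mod.cluster_series(
            traj, topo, cutoff=cfg.get("cutoff", 3.5), stride=cfg.get("stride", 1)
        )
        cpath = outdir / "cluster_series.csv"
        series.table.to_csv(cpath, index=False)
        artifacts.append(cpath)
        report["stages"]["clusters"] = series.summary()

    def stage_density(cfg):
        dmap = densproj_mod.project_density(
            traj,
            topo,
            species=cfg.get("species", "water"),
            axes=tuple(cfg.get("axes", (0, 1))),
            bin_width=cfg.get("bin_width", 1.0),
            mode=cfg.get("mode", "number"),
        )
        gpath = outdir / "density_map.csv"
        dmap.to_frame().to_csv(gpath, index=False)
        mpath = outdir / "density_matrix.txt"
        np.savetxt(mpath, np.atleast_2d(dmap.values), fmt="%.8e")
        artifacts.extend([gpath, mpath])
        report["stages"]["density"] = {
            "uniformity_cv": densproj_mod.uniformity_cv(dmap),
            "n_bins": list(dmap.values.shape),
            "mode": dmap.mode,
        }

    def stage_equilibration(cfg):
        path = cfg.get("series_csv")
        if not path:
            raise ValueError("equilibration stage needs series_csv (columns: time_ps,value)")
        df = pd.read_csv(path)
        series = ScalarSeries(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), label=str(df.columns[1]))
        drift = equilibration_drift(
            series,
            tail_fraction=cfg.get("tail_fraction", 0.5),
            rel_tol=cfg.get("rel_tol", 0.01),
            abs_tol=cfg.get("abs_tol"),
        )
        epath = outdir / "equilibration.json"
        _write_json(drift.to_dict(), epath)
        artifacts.append(epath)
        report["stages"]["equilibration"] = drift.to_dict()

    run_stage("equilibration", stage_equilibration)
    run_stage("msd", stage_msd)
    run_stage("hbond", stage_hbond)
    run_stage("clusters", stage_clusters)
    run_stage("density", stage_density)

    report_path = outdir / "report.json"
    # timings are logged and returned but kept out of the artifact so that
    # identical config + inputs + seed give byte-identical output files
    _write_json({k: v for k, v in report.items() if k != "timing_s"}, report_path)
    artifacts.append(report_path)

    import sorbtrack

    config_payload = dataclasses.asdict(config)
    # the hash identifies the analysis parameters, not the output location
    hashed = {k: v for k, v in config_payload.items() if k != "output_dir"}
    manifest = {
        "config": config_payload,
        "config_sha256": hashlib.sha256(
            json.dumps(hashed, sort_keys=True, default=_json_default).encode()
        ).hexdigest(),
        "seed": config.seed,
        "sorbtrack_version": sorbtrack.__version__,
        "numpy_version": np.__version__,
        "outputs": {p.name: _sha256(p) for p in sorted(set(artifacts))},
    }
    _write_json(manifest, outdir / "manifest.json")
    return report
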