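"""Experiment orchestration: sweeps of growth runs over stress grids,
growth laws and realizations, with reproducible on-disk results.

A sweep cell is one (stress value, realization) pair for one growth law
and noise level.  Each run executes the standard pipeline: generate a
hierarchical network, optimize thicknesses to the force-model fixed
point, apply frozen thickness noise, compute the reference box (and the
reference stress eta0), then grow to area doubling under the external
stress.  A manifest records the configuration hash, package version,
per-run seeds and completeness, so a rerun with the same configuration
is bit-identical (timestamps live only in the manifest metadata).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from . import __version__
from .generate import (
    apply_thickness_noise,
    generate_reference_network,
    optimize_thickness,
)
from .mechanics import (
    GrowthLaw,
    GrowthStalledError,
    SimulationConfig,
    Trajectory,
    compute_reference_dims,
    run_simulation,
)
from .io import write_snapshot
from .texture import summarize_realizations, tensor_field, trajectory_q, extract_areoles

__all__ = ["ExperimentConfig", "run_experiment", "run_pipeline"]


@dataclass
class ExperimentConfig:
    """Fully serializable description of a sweep.

    ``stress_values`` are in units of the turgor pressure and applied
    along ``stress_axis`` ("x" or "y").  Seeds for each run derive
    deterministically from ``seed`` and the cell indices.
    """

    n_areoles: int = 60
    areole_size: float = 6.0
    beta: float = 0.25
    law_kind: str = "threshold"
    eta_star: float = 1.0
    noise_r: float = 0.4
    stress_axis: str = "x"
    stress_values: tuple = (0.0, 1.0, 2.0)
    n_realizations: int = 40
    dt: float = 1e-5
    stop_area_ratio: float = 2.0
    minimizer_tol: float = 1e-8
    thickness_tol: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stress_axis not in ("x", "y"):
            raise ValueError("stress_axis must be 'x' or 'y'")
        self.stress_values = tuple(float(s) for s in self.stress_values)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _run_seed(base: int, cell: int, rep: int) -> int:
    ss = np.random.SeedSequence(entropy=base, spawn_key=(cell, rep))
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(
    config: ExperimentConfig, stress: float, seed: int, snapshot_every: int = 0
) -> Trajectory:
    """One full run: generate -> optimize thickness -> noise ->
    reference dims -> grow to area doubling under the external stress."""
    net = generate_reference_network(
        config.n_areoles,
        seed,
        {"areole_size": config.areole_size, "beta": config.beta},
    )
    net = optimize_thickness(net, tol=config.thickness_tol)
    if config.noise_r > 0:
        net = apply_thickness_noise(net, config.noise_r, seed + 1)
    net = compute_reference_dims(net, tol=config.minimizer_tol)
    sigma = stress * net.P_tur
    if config.stress_axis == "x":
        net.sigma_xx = sigma
    else:
        net.sigma_yy = sigma
    law = GrowthLaw(kind=config.law_kind, eta_star=config.eta_star)
    sim = SimulationConfig(
        dt=config.dt,
        stop_area_ratio=config.stop_area_ratio,
        minimizer_tol=config.minimizer_tol,
        snapshot_every=snapshot_every,
        seed=seed,
    )
    return run_simulation(net, law, sim)


def run_experiment(
    config: ExperimentConfig, out_dir: Union[str, Path]
) -> Path:
    """Execute a sweep and write its results directory.

    Per run: initial and final snapshots, a diagnostics CSV, and a
    per-areole descriptor CSV (texture descriptors of the final state
    merged with the non-affinity indices).  Per experiment: the summary
    tables of :func:`summarize_realizations` and ``manifest.json``.
    Individual run failures (e.g. stalled growth above the yield
    threshold) are logged in the manifest and skipped.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "code_version": __version__,
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "runs": [],
    }
    pools: dict[str, list[Trajectory]] = {}
    for cell, stress in enumerate(config.stress_values):
        label = f"sigma_{config.stress_axis}={stress:g}"
        pools[label] = []
        for rep in range(config.n_realizations):
            seed = _run_seed(config.seed, cell, rep)
            run_id = f"{label}_rep{rep}"
            rec = {"run": run_id, "stress": stress, "seed": seed, "status": "ok"}
            try:
                traj = run_pipeline(config, stress, seed)
            except GrowthStalledError as e:
                rec["status"] = "stalled"
                rec["message"] = str(e)
                manifest["runs"].append(rec)
                continue
            except Exception as e:  # e.g. embedding entangled under high stress
                rec["status"] = "failed"
                rec["message"] = f"{type(e).__name__}: {e}"
                manifest["runs"].append(rec)
                continue
            pools[label].append(traj)
            rdir = out / run_id
            rdir.mkdir(exist_ok=True)
            write_snapshot(traj.initial, rdir / "initial.json")
            write_snapshot(traj.final, rdir / "final.json")
            traj.diagnostics_table().to_csv(rdir / "diagnostics.csv", index=False)
            desc = tensor_field(extract_areoles(traj.final))
            desc = desc.merge(trajectory_q(traj), on="areole_id")
            desc.to_csv(rdir / "descriptors.csv", index=False)
            manifest["runs"].append(rec)
    completed = {k: v for k, v in pools.items() if v}
    if completed:
        tables = summarize_realizations(completed)
        for name, df in tables.items():
            df.to_csv(out / f"summary_{name}.csv", index=False)
    manifest["n_completed"] = sum(len(v) for v in pools.values())
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
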