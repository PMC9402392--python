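"""Reduced-unit Langevin (stochastic leapfrog) dynamics in the NVT ensemble.

Temperature is entered on the conventional reduced scale where
k_B = 0.008314 (so T = 100 means k_B T = 0.8314 ε).  The integrator is
the BAOAB splitting of Langevin dynamics: with friction γ = 0 and the
noise switched off it reduces to velocity Verlet and conserves energy
(NVE mode).  All beads have unit mass by default; masses only set the
time scale of a Cα model.  Trajectories are exactly reproducible from
their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import _kernels
from .sbm_builder import COMPONENT_NAMES, SBMTopology

__all__ = [
    "KB",
    "IntegratorParams",
    "Trajectory",
    "run_dynamics",
    "instantaneous_temperature",
    "maxwell_boltzmann_velocities",
    "write_trajectory",
    "read_trajectory",
    "write_energy_log",
]

KB = 0.008314  # reduced Boltzmann constant (ε per reduced kelvin)

ENERGY_COLUMNS = ("step",) + COMPONENT_NAMES + ("potential", "kinetic",
                                                "temperature")


@dataclass
class IntegratorParams:
    n_steps: int
    dt: float = 0.0005
    temperature: float = 100.0  # reduced kelvin; k_B T = 0.8314 ε at default
    friction: float = 1.0  # γ, reduced time⁻¹
    mass: float = 1.0
    save_every: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.temperature <= 0 or self.mass <= 0:
            raise ValueError("dt, temperature and mass must be positive")
        if self.friction < 0:
            raise ValueError("friction must be >= 0")
        if self.save_every < 1:
            raise ValueError("save_every must be >= 1")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")

    @property
    def kbt(self) -> float:
        return KB * self.temperature


@dataclass
class Trajectory:
    steps: np.ndarray  # (F,) integer step index of each saved frame
    frames: np.ndarray  # (F, n, 3) bead coordinates, nm
    energies: dict[str, np.ndarray]  # per-frame components, KE, temperature
    params: IntegratorParams
    seed: int
    velocities_final: np.ndarray | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.steps)


def maxwell_boltzmann_velocities(n: int, temperature: float, mass: float,
                                 rng: np.random.Generator) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(KB * temperature / mass), size=(n, 3))


def instantaneous_temperature(velocities: np.ndarray, mass: float = 1.0) -> float:
    """2·KE / (3N·k_B) in reduced kelvin."""
    v = np.asarray(velocities, dtype=float)
    ke = 0.5 * mass * float(np.sum(v * v))
    return 2.0 * ke / (3.0 * len(v) * KB)


def run_dynamics(
    top: SBMTopology,
    coords0: np.ndarray,
    p: IntegratorParams,
    velocities0: np.ndarray | None = None,
    nve: bool = False,
) -> Trajectory:
    """Propagate Langevin dynamics and return the saved trajectory.

    Frames (and the energy log) are stored at step 0 and every
    ``save_every`` steps thereafter.  With ``nve=True`` (or friction 0)
    the thermostat is off and total energy is conserved.  Identical
    inputs and seed produce bit-identical trajectories.
    """
    coords = np.ascontiguousarray(coords0, dtype=float).copy()
    if coords.shape != (top.n_beads, 3):
        raise ValueError(f"coords0 shape {coords.shape} != ({top.n_beads}, 3)")
    if not np.isfinite(coords).all():
        raise ValueError("non-finite initial coordinate")
    rng = np.random.Generator(np.random.PCG64(p.seed))
    if velocities0 is None:
        velocities = maxwell_boltzmann_velocities(top.n_beads, p.temperature,
                                                  p.mass, rng)
    else:
        velocities = np.ascontiguousarray(velocities0, dtype=float).copy()
    gamma = 0.0 if nve else p.friction

    arrays = top.kernel_arrays()
    comps, _ = _kernels.energy_forces(coords, **arrays)
    if not np.isfinite(comps).all():
        raise RuntimeError("non-finite initial energy")

    n_saves = p.n_steps // p.save_every
    steps = [0]
    frames = [coords.copy()]
    log: list[np.ndarray] = [_log_row(0, comps, velocities, p)]

    empty_noise = np.zeros((0, top.n_beads, 3))
    step = 0
    for _ in range(n_saves):
        chunk = p.save_every
        noise = (rng.standard_normal((chunk, top.n_beads, 3))
                 if gamma > 0 else empty_noise)
        comps, _ = _kernels.integrate_chunk(
            coords, velocities, chunk, p.dt, gamma, p.kbt, p.mass, noise,
            **arrays,
        )
        step += chunk
        total = comps.sum()
        if not np.isfinite(total) or abs(total) > 1e6:
            raise RuntimeError(f"energy divergence at step {step}: E={total}")
        steps.append(step)
        frames.append(coords.copy())
        log.append(_log_row(step, comps, velocities, p))

    remainder = p.n_steps - n_saves * p.save_every
    if remainder > 0:  # trailing steps are integrated but not saved
        noise = (rng.standard_normal((remainder, top.n_beads, 3))
                 if gamma > 0 else empty_noise)
        _kernels.integrate_chunk(
            coords, velocities, remainder, p.dt, gamma, p.kbt, p.mass, noise,
            **arrays,
        )

    energies = {name: np.array([row[k] for row in log])
                for k, name in enumerate(ENERGY_COLUMNS)}
    return Trajectory(np.array(steps, dtype=np.int64), np.array(frames),
                      energies, replace(p), p.seed,
                      velocities_final=velocities)


def _log_row(step: int, comps: np.ndarray, velocities: np.ndarray,
             p: IntegratorParams) -> np.ndarray:
    ke = 0.5 * p.mass * float(np.sum(velocities ** 2))
    temp = instantaneous_temperature(velocities, p.mass)
    return np.array([step, *comps, comps.sum(), ke, temp])


# -- trajectory I/O --

def write_trajectory(traj: Trajectory, path: str | Path,
                     format: str = "binary_standard") -> None:
    """Write frames as XTC (``binary_standard``) or multi-model PDB."""
    path = Path(path)
    if format == "binary_standard":
        import mdtraj.formats as fmts

        with fmts.XTCTrajectoryFile(str(path), "w") as fh:
            fh.write(traj.frames.astype(np.float32),
                     time=traj.steps.astype(float),
                     step=traj.steps)
    elif format == "multi_model_pdb":
        with open(path, "w") as fh:
            for m, (step, frame) in enumerate(zip(traj.steps, traj.frames), 1):
                fh.write(f"MODEL     {m:4d}\n")
                fh.write(f"REMARK 250 STEP {int(step)}\n")
                for k, (x, y, z) in enumerate(frame * 10.0, 1):
                    fh.write(
                        f"ATOM  {k:5d}  CA  GLY A{k % 10000:4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                    )
                fh.write("ENDMDL\n")
            fh.write("END\n")
    else:
        raise ValueError(f"unknown trajectory format {format!r}")


def read_trajectory(path: str | Path,
                    format: str = "binary_standard") -> tuple[np.ndarray, np.ndarray]:
    """Read frames back; returns (steps, coords(F, n, 3) in nm)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "binary_standard":
        import mdtraj.formats as fmts

        with fmts.XTCTrajectoryFile(str(path), "r") as fh:
            coords, _, steps, _ = fh.read()
        if coords.size == 0:
            raise IOError(f"empty or truncated trajectory: {path}")
        return steps.astype(np.int64), coords.astype(float)
    if format == "multi_model_pdb":
        steps_list: list[int] = []
        frames: list[list[list[float]]] = []
        current: list[list[float]] | None = None
        for line in path.read_text().splitlines():
            if line.startswith("MODEL"):
                current = []
            elif line.startswith("REMARK 250 STEP"):
                steps_list.append(int(line.split()[-1]))
            elif line.startswith("ATOM") and current is not None:
                current.append([float(line[30:38]), float(line[38:46]),
                                float(line[46:54])])
            elif line.startswith("ENDMDL"):
                if current is None:
                    raise IOError(f"truncated trajectory: {path}")
                frames.append(current)
                current = None
        if not frames:
            raise IOError(f"no frames in {path}")
        if not steps_list:
            steps_list = list(range(len(frames)))
        return (np.array(steps_list, dtype=np.int64),
                np.array(frames, dtype=float) / 10.0)
    raise ValueError(f"unknown trajectory format {format!r}")


def write_energy_log(traj: Trajectory, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame({k: traj.energies[k] for k in ENERGY_COLUMNS}).to_csv(
        path, sep="\t", index=False, float_format="%.8g"
    )
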