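"""Molecular dynamics: velocity Verlet, Langevin NVT, harmonic biases, minimization.

Units: positions Å, time fs, energies eV, masses amu. The integrator is
plain velocity Verlet in the NVE ensemble and the BAOAB splitting of
Langevin dynamics in NVT (the friction γ sets the thermostat coupling).
Initial velocities are Maxwell–Boltzmann with the net linear momentum
removed. A model blow-up (non-finite or absurdly large force) aborts the
episode and returns the partial trajectory flagged unstable — this is the
stability signal the active-learning loop consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .core import Configuration
from .potentials import Potential
from .units import AMU_A2_FS2_TO_EV, KB

FORCE_BLOWUP = 1e3  # eV Å⁻¹; any larger component aborts the episode


@dataclass
class MDParams:
    """Integration parameters; defaults mirror the 0.5 fs production timestep."""

    dt: float = 0.5                # fs
    temperature: float = 300.0     # K
    ensemble: str = "NVT"
    friction: float = 0.02         # fs⁻¹, Langevin
    duration: float = 1000.0       # fs
    rng_seed: int = 0
    stride: int = 10               # store every stride-th frame

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")
        if self.ensemble not in ("NVE", "NVT"):
            raise ValueError("ensemble must be NVE or NVT")
        n = self.duration / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration must be a multiple of dt")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


class Coordinate:
    """Scalar function of the positions with a gradient — the bias target."""

    def value(self, positions: np.ndarray) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def gradient(self, positions: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class DistanceCoordinate(Coordinate):
    """Interatomic distance |r_j − r_i| (no minimum imaging — bonded pairs)."""

    def __init__(self, i: int, j: int):
        self.i, self.j = int(i), int(j)

    def value(self, positions: np.ndarray) -> float:
        return float(np.linalg.norm(positions[self.j] - positions[self.i]))

    def gradient(self, positions: np.ndarray) -> np.ndarray:
        g = np.zeros_like(positions)
        vec = positions[self.j] - positions[self.i]
        r = np.linalg.norm(vec)
        u = vec / r
        g[self.j] = u
        g[self.i] = -u
        return g


class MeanDistanceCoordinate(Coordinate):
    """ξ = (r₁ + r₂)/2 over two atom pairs — the cycloaddition reaction coordinate."""

    def __init__(self, pair1: tuple[int, int], pair2: tuple[int, int]):
        self.d1 = DistanceCoordinate(*pair1)
        self.d2 = DistanceCoordinate(*pair2)

    def value(self, positions: np.ndarray) -> float:
        return 0.5 * (self.d1.value(positions) + self.d2.value(positions))

    def gradient(self, positions: np.ndarray) -> np.ndarray:
        return 0.5 * (self.d1.gradient(positions) + self.d2.gradient(positions))


@dataclass
class HarmonicBias:
    """½ k (ξ − center)² restraint on a scalar coordinate."""

    coordinate: Coordinate
    center: float
    k: float  # eV Å⁻²

    def energy_forces(self, positions: np.ndarray) -> tuple[float, np.ndarray]:
        xi = self.coordinate.value(positions)
        delta = xi - self.center
        e = 0.5 * self.k * delta**2
        f = -self.k * delta * self.coordinate.gradient(positions)
        return e, f

    def value(self, positions: np.ndarray) -> float:
        return self.coordinate.value(positions)


@dataclass
class SteeredBias:
    """Harmonic bias whose centre ramps linearly in time (steered MD).

    The centre moves from ``center_start`` to ``center_end`` over
    ``ramp_time`` fs and then holds — the restraint that drags a reaction
    coordinate over barriers a fixed spring of the same stiffness could not
    cross on the simulation timescale.
    """

    coordinate: Coordinate
    center_start: float
    center_end: float
    ramp_time: float
    k: float  # eV Å⁻²

    def __post_init__(self):
        self._center = self.center_start

    def set_time(self, t_fs: float) -> None:
        f = min(max(t_fs / self.ramp_time, 0.0), 1.0) if self.ramp_time > 0 else 1.0
        self._center = self.center_start + f * (self.center_end - self.center_start)

    def energy_forces(self, positions: np.ndarray) -> tuple[float, np.ndarray]:
        xi = self.coordinate.value(positions)
        delta = xi - self._center
        e = 0.5 * self.k * delta**2
        f = -self.k * delta * self.coordinate.gradient(positions)
        return e, f

    def value(self, positions: np.ndarray) -> float:
        return self.coordinate.value(positions)


@dataclass
class Trajectory:
    """MD output: stored frames plus per-step scalar records."""

    frames: list = field(default_factory=list)           # Configuration, at stride
    frame_times: np.ndarray | None = None                # fs
    times: np.ndarray | None = None                      # fs, every step
    potential_energies: np.ndarray | None = None         # eV, every step
    kinetic_energies: np.ndarray | None = None           # eV, every step
    bias_energies: np.ndarray | None = None              # eV, every step
    traces: dict = field(default_factory=dict)           # name -> per-step series
    unstable: bool = False
    final: Configuration | None = None

    def temperatures(self, n_dof: int) -> np.ndarray:
        return 2.0 * self.kinetic_energies / (n_dof * KB)

    def write_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            names = sorted(self.traces)
            writer.writerow(["time_fs", "potential_eV", "kinetic_eV", "bias_eV"] + names)
            for i, t in enumerate(self.times):
                writer.writerow(
                    [t, self.potential_energies[i], self.kinetic_energies[i],
                     self.bias_energies[i]] + [self.traces[n][i] for n in names]
                )


def init_velocities(
    config: Configuration,
    temperature: float,
    rng_seed: int,
    frozen_atoms: Sequence[int] = (),
) -> np.ndarray:
    """Maxwell–Boltzmann velocities (Å/fs) with net linear momentum removed."""
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    m = config.masses()
    v = np.zeros((config.n_atoms, 3))
    if temperature > 0:
        rng = np.random.default_rng(rng_seed)
        sigma = np.sqrt(KB * temperature / (m * AMU_A2_FS2_TO_EV))
        v = rng.normal(size=(config.n_atoms, 3)) * sigma[:, None]
    frozen = np.zeros(config.n_atoms, dtype=bool)
    frozen[list(frozen_atoms)] = True
    free = ~frozen
    if free.any() and temperature > 0:
        p = (m[free, None] * v[free]).sum(axis=0)
        v[free] -= p / m[free].sum()
    v[frozen] = 0.0
    return v


def kinetic_energy(v: np.ndarray, m: np.ndarray) -> float:
    return float(0.5 * AMU_A2_FS2_TO_EV * np.sum(m[:, None] * v**2))


def run_md(
    config: Configuration,
    potential: Potential,
    params: MDParams,
    biases: Sequence[HarmonicBias] = (),
    frozen_atoms: Sequence[int] = (),
    velocities: np.ndarray | None = None,
    trace_fns: dict[str, Callable[[np.ndarray], float]] | None = None,
    stop_fn: Callable[[np.ndarray, int], bool] | None = None,
) -> Trajectory:
    """Propagate MD, returning the trajectory (partial and flagged on blow-up).

    ``trace_fns`` are scalar observables recorded every step (e.g. bond
    distances); ``stop_fn`` ends the run early when it returns True (e.g. on
    reaching product). Frozen atoms are excluded from integration entirely.
    """
    m = config.masses()
    pos = config.positions.copy()
    frozen = np.zeros(config.n_atoms, dtype=bool)
    frozen[list(frozen_atoms)] = True
    free = ~frozen
    n_free = int(free.sum())
    if velocities is None:
        v = init_velocities(config, params.temperature, params.rng_seed, frozen_atoms)
    else:
        v = velocities.copy()
        v[frozen] = 0.0

    work = config.copy()
    trace_fns = trace_fns or {}
    rng = np.random.default_rng(params.rng_seed + 1)

    def eval_forces(x, t_fs):
        work.positions = x
        e_pot, f = potential.evaluate(work)
        e_bias = 0.0
        for bias in biases:
            if hasattr(bias, "set_time"):
                bias.set_time(t_fs)
            eb, fb = bias.energy_forces(x)
            e_bias += eb
            f = f + fb
        return e_pot, e_bias, f

    traj = Trajectory(traces={name: [] for name in trace_fns})
    times, e_pots, e_kins, e_biases = [], [], [], []

    e_pot, e_bias, f = eval_forces(pos, 0.0)
    if not np.all(np.isfinite(f)):
        traj.unstable = True
        traj.final = work.copy()
        _finalize(traj, times, e_pots, e_kins, e_biases)
        return traj

    inv_mc = 1.0 / (m * AMU_A2_FS2_TO_EV)
    if params.ensemble == "NVT":
        c1 = np.exp(-params.friction * params.dt)
        c2 = np.sqrt(max(0.0, 1.0 - c1**2))
        sigma_v = np.sqrt(KB * params.temperature * inv_mc)

    def record(step):
        times.append(step * params.dt)
        e_kins.append(kinetic_energy(v, m))
        e_pots.append(e_pot)
        e_biases.append(e_bias)
        for name, fn in trace_fns.items():
            traj.traces[name].append(fn(pos))
        if step % params.stride == 0:
            snap = work.copy()
            snap.positions = pos.copy()
            snap.provenance = dict(config.provenance, md_time_fs=step * params.dt)
            traj.frames.append(snap)

    record(0)
    half_dt = 0.5 * params.dt
    for step in range(1, params.n_steps + 1):
        v[free] += half_dt * f[free] * inv_mc[free, None]          # B
        pos[free] += half_dt * v[free]                             # A
        if params.ensemble == "NVT":                               # O
            noise = rng.normal(size=(config.n_atoms, 3))
            v[free] = c1 * v[free] + c2 * sigma_v[free, None] * noise[free]
        pos[free] += half_dt * v[free]                             # A
        e_pot, e_bias, f = eval_forces(pos, step * params.dt)
        if not np.all(np.isfinite(f)) or np.abs(f[free]).max() > FORCE_BLOWUP:
            traj.unstable = True
            break
        v[free] += half_dt * f[free] * inv_mc[free, None]          # B
        record(step)
        if stop_fn is not None and stop_fn(pos, step):
            break

    traj.final = work.copy()
    traj.final.positions = pos.copy()
    traj.velocities = v.copy()
    _finalize(traj, times, e_pots, e_kins, e_biases)
    return traj


def _finalize(traj, times, e_pots, e_kins, e_biases):
    traj.times = np.asarray(times)
    traj.potential_energies = np.asarray(e_pots)
    traj.kinetic_energies = np.asarray(e_kins)
    traj.bias_energies = np.asarray(e_biases)
    traj.frame_times = np.asarray([f.provenance.get("md_time_fs", 0.0) for f in traj.frames])
    for name in traj.traces:
        traj.traces[name] = np.asarray(traj.traces[name])


def minimize(
    config: Configuration,
    potential: Potential,
    biases: Sequence[HarmonicBias] = (),
    frozen_atoms: Sequence[int] = (),
    f_tol: float = 1e-3,
    max_steps: int = 500,
) -> tuple[Configuration, bool]:
    """Quasi-Newton (L-BFGS) minimization with optional restraints and frozen atoms.

    Converged when the largest free-atom force component falls below
    ``f_tol`` (eV Å⁻¹). Returns (relaxed configuration, converged flag).
    """
    frozen = np.zeros(config.n_atoms, dtype=bool)
    frozen[list(frozen_atoms)] = True
    free = np.nonzero(~frozen)[0]
    work = config.copy()
    pos_full = config.positions.copy()

    def objective(x_free):
        pos = pos_full.copy()
        pos[free] = x_free.reshape(-1, 3)
        work.positions = pos
        e, forces = potential.evaluate(work)
        for bias in biases:
            eb, fb = bias.energy_forces(pos)
            e += eb
            forces = forces + fb
        return e, -forces[free].ravel()

    res = _scipy_minimize(
        objective,
        pos_full[free].ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_steps, "gtol": f_tol * 0.1, "ftol": 1e-12},
    )
    pos = pos_full.copy()
    pos[free] = res.x.reshape(-1, 3)
    out = config.copy()
    out.positions = pos
    _, g = objective(res.x)
    converged = bool(np.abs(g).max() < f_tol) if len(g) else True
    return out, converged
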