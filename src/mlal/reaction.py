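"""Reaction-dynamics analysis: scans, umbrella sampling, trajectory ensembles, solvent structure.

The reaction coordinate for the model cycloaddition is ξ = (r₁ + r₂)/2, the
mean of the two forming-bond distances; Δr = |r₂ − r₁| measures the
asynchronicity. A state is product when both bonds are below 1.6 Å and
reactant when both exceed 3.0 Å. The time gap Δt between the two bond
formations separates concerted (< 60 fs) from stepwise trajectories.

Free energies along ξ are reconstructed from overlapping harmonic umbrella
windows with the weighted histogram analysis method (WHAM); profiles are
reported in kcal mol⁻¹, shifted so the minimum is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import Configuration, ConfigurationSet, detect_molecules
from .dynamics import (
    HarmonicBias,
    MDParams,
    MeanDistanceCoordinate,
    Trajectory,
    minimize,
    run_md,
)
from .potentials import Potential
from .units import EV_TO_KCAL_PER_MOL, KB

PRODUCT_DISTANCE = 1.6     # Å; both forming bonds below → product
REACTANT_DISTANCE = 3.0    # Å; both forming bonds above → reactant
CONCERTED_GAP_FS = 60.0    # fs; time-gap criterion for concertedness


@dataclass
class ReactionCoordinate:
    """ξ = (r₁ + r₂)/2 over the two forming-bond atom pairs."""

    pair1: tuple[int, int]
    pair2: tuple[int, int]

    def __post_init__(self):
        self._coord = MeanDistanceCoordinate(self.pair1, self.pair2)

    def r1(self, config_or_pos) -> float:
        pos = getattr(config_or_pos, "positions", config_or_pos)
        return float(np.linalg.norm(pos[self.pair1[1]] - pos[self.pair1[0]]))

    def r2(self, config_or_pos) -> float:
        pos = getattr(config_or_pos, "positions", config_or_pos)
        return float(np.linalg.norm(pos[self.pair2[1]] - pos[self.pair2[0]]))

    def xi(self, config_or_pos) -> float:
        return 0.5 * (self.r1(config_or_pos) + self.r2(config_or_pos))

    def delta_r(self, config_or_pos) -> float:
        """Asynchronicity Δr = |r₂ − r₁| (Å)."""
        return abs(self.r2(config_or_pos) - self.r1(config_or_pos))

    def coordinate(self) -> MeanDistanceCoordinate:
        return self._coord


def classify_state(r1: float, r2: float) -> str:
    """product | reactant | ongoing from the two forming-bond distances."""
    if r1 <= 0 or r2 <= 0:
        raise ValueError("distances must be positive")
    if r1 < PRODUCT_DISTANCE and r2 < PRODUCT_DISTANCE:
        return "product"
    if r1 > REACTANT_DISTANCE and r2 > REACTANT_DISTANCE:
        return "reactant"
    return "ongoing"


# ---------------------------------------------------------------------------
# relaxed 2D scan
# ---------------------------------------------------------------------------

@dataclass
class Scan2D:
    r1_grid: np.ndarray
    r2_grid: np.ndarray
    energies: np.ndarray          # eV, restraint-corrected
    converged: np.ndarray         # bool per grid point


def relaxed_scan_2d(
    potential: Potential,
    start: Configuration,
    rc: ReactionCoordinate,
    r1_grid: Sequence[float],
    r2_grid: Sequence[float],
    restraint_k: float = 40.0,
    frozen_atoms: Sequence[int] = (),
    f_tol: float = 1e-3,
) -> Scan2D:
    """Relaxed potential-energy surface over a grid of (r₁, r₂) targets.

    At each grid point the structure is minimized under stiff harmonic
    restraints holding r₁ and r₂; the reported energy has the residual
    restraint energy removed. Neighbouring points are warm-started along
    each r₁ row. Non-converged cells are flagged and the scan continues.
    """
    from .dynamics import DistanceCoordinate

    r1_grid = np.asarray(r1_grid, float)
    r2_grid = np.asarray(r2_grid, float)
    if len(r1_grid) > 1 and not (np.all(np.diff(r1_grid) > 0) or np.all(np.diff(r1_grid) < 0)):
        raise ValueError("r1_grid must be monotone")
    if len(r2_grid) > 1 and not (np.all(np.diff(r2_grid) > 0) or np.all(np.diff(r2_grid) < 0)):
        raise ValueError("r2_grid must be monotone")
    energies = np.full((len(r1_grid), len(r2_grid)), np.nan)
    converged = np.zeros((len(r1_grid), len(r2_grid)), dtype=bool)
    c1 = DistanceCoordinate(*rc.pair1)
    c2 = DistanceCoordinate(*rc.pair2)

    row_start = start.copy()
    for i, r1 in enumerate(r1_grid):
        current = row_start.copy()
        for j, r2 in enumerate(r2_grid):
            biases = [HarmonicBias(c1, r1, restraint_k), HarmonicBias(c2, r2, restraint_k)]
            relaxed, ok = minimize(current, potential, biases=biases,
                                   frozen_atoms=frozen_atoms, f_tol=f_tol)
            e, _ = potential.evaluate(relaxed)
            energies[i, j] = e
            converged[i, j] = ok
            current = relaxed           # warm start along the row
            if j == 0:
                row_start = relaxed     # warm start the next row
    return Scan2D(r1_grid=r1_grid, r2_grid=r2_grid, energies=energies, converged=converged)


# ---------------------------------------------------------------------------
# umbrella sampling + WHAM
# ---------------------------------------------------------------------------

@dataclass
class UmbrellaWindow:
    center: float                  # Å
    k: float                       # eV Å⁻²
    xi_series: np.ndarray          # sampled after burn-in
    temperature: float             # K


@dataclass
class FESResult:
    xi: np.ndarray                 # grid (bin centres), Å
    free_energy: np.ndarray        # kcal/mol, min-shifted to 0
    barrier: float                 # ΔG‡ kcal/mol (TS maximum − reactant basin)
    ts_xi: float
    reactant_xi: float
    product_xi: float
    window_offsets: np.ndarray     # converged WHAM free energies per window, eV


def default_window_spec(
    wide_range: tuple[float, float] = (1.55, 4.0),
    narrow_range: tuple[float, float] = (1.7, 2.5),
    k_wide: float = 10.0,
    k_narrow: float = 20.0,
    n_each: int = 15,
) -> list[tuple[float, float]]:
    """The production window layout: n_each windows equally spaced over the
    wide range (spring ``k_wide``) plus n_each more over the narrow range
    around the barrier (spring ``k_narrow``); 30 windows in total by
    default. Per-window overrides are plain (center, k) entries."""
    wide = [(c, k_wide) for c in np.linspace(*wide_range, n_each)]
    narrow = [(c, k_narrow) for c in np.linspace(*narrow_range, n_each)]
    return sorted(wide + narrow)


def run_umbrella(
    potential: Potential,
    rc: ReactionCoordinate,
    window_spec: Sequence[tuple[float, float]],
    md: MDParams,
    start: Configuration,
    burn_in_fraction: float = 0.1,
    steer_time_fs: float = 200.0,
) -> list[UmbrellaWindow]:
    """Biased NVT sampling in harmonic windows along ξ.

    Windows are visited in order of their centre, warm-started from the
    previous window's final frame; the first window is seeded by steered MD
    that drags ξ from the start structure to the window centre. The first
    ``burn_in_fraction`` of each window's samples is discarded. Windows with
    no histogram overlap with any neighbour raise an error naming the gap.
    """
    spec = sorted((float(c), float(k)) for c, k in window_spec)
    coord = rc.coordinate()
    # steer from the start structure to the first window centre
    current = start.copy()
    xi0 = rc.xi(current)
    n_steer = max(2, int(round(steer_time_fs / md.dt)))
    steer_md = MDParams(dt=md.dt, temperature=md.temperature, ensemble="NVT",
                        friction=md.friction, duration=n_steer * md.dt,
                        rng_seed=md.rng_seed + 17, stride=10**9)
    centers = np.linspace(xi0, spec[0][0], 5)[1:]
    for c in centers:
        traj = run_md(current, potential, steer_md,
                      biases=[HarmonicBias(coord, c, max(spec[0][1], 5.0))])
        if traj.unstable:
            raise RuntimeError("steered seeding became unstable")
        current = traj.final

    windows: list[UmbrellaWindow] = []
    for w_index, (center, k) in enumerate(spec):
        bias = HarmonicBias(coord, center, k)
        wmd = MDParams(dt=md.dt, temperature=md.temperature, ensemble="NVT",
                       friction=md.friction, duration=md.duration,
                       rng_seed=md.rng_seed + 1000 + w_index, stride=10**9)
        traj = run_md(current, potential, wmd, biases=[bias],
                      trace_fns={"xi": lambda pos: coord.value(pos)})
        if traj.unstable:
            raise RuntimeError(f"window at ξ={center:.3f} Å became unstable")
        xi = traj.traces["xi"]
        skip = int(burn_in_fraction * len(xi))
        windows.append(UmbrellaWindow(center=center, k=k, xi_series=xi[skip:],
                                      temperature=md.temperature))
        current = traj.final
    _check_overlap(windows)
    return windows


def _check_overlap(windows: list[UmbrellaWindow], n_bins: int = 100) -> None:
    if len(windows) < 2:
        return
    lo = min(w.xi_series.min() for w in windows)
    hi = max(w.xi_series.max() for w in windows)
    edges = np.linspace(lo, hi, n_bins + 1)
    hists = [np.histogram(w.xi_series, bins=edges)[0] > 0 for w in windows]
    order = np.argsort([w.center for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        if not np.any(hists[a] & hists[b]):
            raise ValueError(
                f"umbrella windows at ξ={windows[a].center:.3f} and "
                f"ξ={windows[b].center:.3f} Å have no histogram overlap — "
                "add a window or stiffen the springs"
            )


def reconstruct_fes(
    windows: Sequence[UmbrellaWindow],
    n_bins: int = 120,
    tol: float = 1e-7,
    max_iter: int = 100000,
) -> FESResult:
    """WHAM reconstruction of the free-energy profile from umbrella windows.

    Self-consistent iteration on the window free energies f_i to tolerance
    ``tol`` (eV); the profile is min-shifted and reported in kcal mol⁻¹ with
    the barrier measured from the reactant (large-ξ) basin to the highest
    intervening maximum.
    """
    if len(windows) == 0:
        raise ValueError("no umbrella windows")
    T = windows[0].temperature
    beta = 1.0 / (KB * T)
    lo = min(w.xi_series.min() for w in windows)
    hi = max(w.xi_series.max() for w in windows)
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    counts = np.stack([np.histogram(w.xi_series, bins=edges)[0] for w in windows])
    n_i = counts.sum(axis=1).astype(float)        # samples per window
    total = counts.sum(axis=0).astype(float)      # samples per bin
    bias = np.stack([0.5 * w.k * (centers - w.center) ** 2 for w in windows])  # (W, B)
    boltz = np.exp(-beta * bias)

    f = np.zeros(len(windows))
    for iteration in range(max_iter):
        denom = (n_i[:, None] * np.exp(beta * f)[:, None] * boltz).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            rho = np.where(total > 0, total / denom, 0.0)
        z = (boltz * rho[None, :]).sum(axis=1)
        f_new = -np.log(z) / beta
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"WHAM failed to converge in {max_iter} iterations (residual {delta:.2e} eV)"
        )

    mask = rho > 0
    F = np.full_like(rho, np.nan)
    F[mask] = -np.log(rho[mask]) / beta
    F -= np.nanmin(F)
    F_kcal = F * EV_TO_KCAL_PER_MOL

    xi, F_valid = centers[mask], F_kcal[mask]
    barrier, ts_xi, reactant_xi, product_xi = _barrier_analysis(xi, F_valid)
    return FESResult(
        xi=xi, free_energy=F_valid, barrier=barrier, ts_xi=ts_xi,
        reactant_xi=reactant_xi, product_xi=product_xi, window_offsets=f,
    )


def _barrier_analysis(xi: np.ndarray, F: np.ndarray):
    """Locate basins and the barrier: reactant is the large-ξ basin."""
    interior = np.arange(1, len(F) - 1)
    minima = [i for i in interior if F[i] <= F[i - 1] and F[i] <= F[i + 1]]
    if not minima:
        minima = [int(np.argmin(F))]
    reactant_i = max(minima)           # largest-ξ local minimum
    product_i = min(minima)
    if reactant_i == product_i:
        product_i = int(np.argmin(F))
    lo, hi = sorted((product_i, reactant_i))
    if hi > lo:
        ts_rel = int(np.argmax(F[lo : hi + 1]))
        ts_i = lo + ts_rel
    else:
        ts_i = int(np.argmax(F))
    barrier = float(F[ts_i] - F[reactant_i])
    return barrier, float(xi[ts_i]), float(xi[reactant_i]), float(xi[product_i])


def write_fes(result: FESResult, path) -> None:
    """Two-column text: ξ (Å), F (kcal/mol)."""
    np.savetxt(path, np.column_stack([result.xi, result.free_energy]),
               header="xi_A  free_energy_kcal_per_mol")


# ---------------------------------------------------------------------------
# downhill / uphill trajectory ensembles
# ---------------------------------------------------------------------------

@dataclass
class DownhillOutcome:
    """Terminal state and bond-formation timing of one trajectory."""

    terminal: str                  # product | reactant | timeout
    t_r1: float | None             # fs, first downward crossing of 1.6 Å
    t_r2: float | None
    time_gap: float | None         # fs, |t(r2) − t(r1)|; None unless product
    concerted: bool | None         # time gap < 60 fs
    final_xi: float


def formation_times(times: np.ndarray, r1: np.ndarray, r2: np.ndarray):
    """First downward crossings of the product distance for each bond."""
    out = []
    for series in (r1, r2):
        below = series < PRODUCT_DISTANCE
        idx = np.nonzero(below)[0]
        out.append(float(times[idx[0]]) if len(idx) else None)
    return tuple(out)


def classify_trajectory(
    times: np.ndarray, r1: np.ndarray, r2: np.ndarray,
    terminal_states: tuple = ("product", "reactant"),
) -> DownhillOutcome:
    """Outcome record from the r₁(t), r₂(t) series of one trajectory.

    ``terminal_states`` lists the states that end a trajectory: both basins
    for downhill runs, only the product for uphill runs (which start in the
    reactant basin).
    """
    state = "ongoing"
    for i in range(len(times)):
        state = classify_state(r1[i], r2[i])
        if state in terminal_states:
            times, r1, r2 = times[: i + 1], r1[: i + 1], r2[: i + 1]
            break
    terminal = state if state in terminal_states else "timeout"
    t1, t2 = formation_times(times, r1, r2)
    gap = None
    concerted = None
    if terminal == "product" and t1 is not None and t2 is not None:
        gap = abs(t2 - t1)
        concerted = gap < CONCERTED_GAP_FS
    return DownhillOutcome(
        terminal=terminal, t_r1=t1, t_r2=t2, time_gap=gap, concerted=concerted,
        final_xi=0.5 * (r1[-1] + r2[-1]),
    )


@dataclass
class EnsembleSummary:
    outcomes: list
    n_product: int
    n_reactant: int
    n_timeout: int
    mean_time_gap: float | None    # fs, product trajectories only
    fraction_concerted: float | None

    @classmethod
    def from_outcomes(cls, outcomes: list) -> "EnsembleSummary":
        gaps = [o.time_gap for o in outcomes if o.time_gap is not None]
        conc = [o.concerted for o in outcomes if o.concerted is not None]
        return cls(
            outcomes=outcomes,
            n_product=sum(o.terminal == "product" for o in outcomes),
            n_reactant=sum(o.terminal == "reactant" for o in outcomes),
            n_timeout=sum(o.terminal == "timeout" for o in outcomes),
            mean_time_gap=float(np.mean(gaps)) if gaps else None,
            fraction_concerted=float(np.mean(conc)) if conc else None,
        )

    def write_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["terminal", "t_r1_fs", "t_r2_fs", "time_gap_fs", "concerted"])
            for o in self.outcomes:
                writer.writerow([o.terminal, o.t_r1, o.t_r2, o.time_gap, o.concerted])


def _run_outcome_trajectory(
    config: Configuration,
    potential: Potential,
    rc: ReactionCoordinate,
    md: MDParams,
    max_time: float,
    biases=(),
    terminal_states: tuple = ("product", "reactant"),
) -> tuple[DownhillOutcome, Trajectory]:
    params = MDParams(dt=md.dt, temperature=md.temperature, ensemble=md.ensemble,
                      friction=md.friction, duration=np.ceil(max_time / md.dt) * md.dt,
                      rng_seed=md.rng_seed, stride=md.stride)

    def stop(pos, step):
        return classify_state(rc.r1(pos), rc.r2(pos)) in terminal_states

    traj = run_md(
        config, potential, params, biases=biases,
        trace_fns={"r1": rc.r1, "r2": rc.r2, "xi": rc.xi},
        stop_fn=stop,
    )
    outcome = classify_trajectory(traj.times, traj.traces["r1"], traj.traces["r2"],
                                  terminal_states=terminal_states)
    return outcome, traj


def downhill_ensemble(
    ts_pool: ConfigurationSet,
    potential: Potential,
    rc: ReactionCoordinate,
    md: MDParams,
    max_time: float = 2000.0,
    keep_trajectories: bool = False,
) -> EnsembleSummary:
    """Unbiased trajectories from transition-state structures until commitment.

    Each trajectory runs until product (both bonds < 1.6 Å) or reactant
    (both > 3.0 Å) forms, or ``max_time`` (2 ps) elapses (timeout, excluded
    from time-gap statistics). Velocities are Maxwell–Boltzmann, seeded per
    pool member.
    """
    outcomes = []
    trajectories = []
    for i, ts in enumerate(ts_pool):
        mdi = MDParams(dt=md.dt, temperature=md.temperature, ensemble=md.ensemble,
                       friction=md.friction, duration=md.duration,
                       rng_seed=md.rng_seed + i, stride=md.stride)
        outcome, traj = _run_outcome_trajectory(ts, potential, rc, mdi, max_time)
        outcomes.append(outcome)
        if keep_trajectories:
            trajectories.append(traj)
    summary = EnsembleSummary.from_outcomes(outcomes)
    if keep_trajectories:
        summary.trajectories = trajectories
    return summary


def prepare_rs_pool(
    reactant: Configuration,
    potential: Potential,
    rc: ReactionCoordinate,
    md: MDParams,
    restraint_centers: tuple[float, float] = (3.5, 3.5),
    restraint_k: float = 2.0,
    n_snapshots: int = 5,
    interval_fs: float = 250.0,
) -> ConfigurationSet:
    """Reactant-state pool from restrained equilibration.

    The forming bonds are restrained inside the reactant range
    ([3.0, 5.0] Å); snapshots are collected every ``interval_fs``.
    """
    from .dynamics import DistanceCoordinate

    for c in restraint_centers:
        if not 3.0 <= c <= 5.0:
            raise ValueError(
                f"reactant restraint centre {c} Å outside the reactant range [3.0, 5.0] Å"
            )
    biases = [
        HarmonicBias(DistanceCoordinate(*rc.pair1), restraint_centers[0], restraint_k),
        HarmonicBias(DistanceCoordinate(*rc.pair2), restraint_centers[1], restraint_k),
    ]
    params = MDParams(dt=md.dt, temperature=md.temperature, ensemble="NVT",
                      friction=md.friction,
                      duration=np.ceil(n_snapshots * interval_fs / md.dt) * md.dt,
                      rng_seed=md.rng_seed, stride=max(1, int(interval_fs / md.dt)))
    traj = run_md(reactant, potential, params, biases=biases)
    if traj.unstable:
        raise RuntimeError("reactant-pool equilibration became unstable")
    pool = ConfigurationSet(traj.frames[1 : n_snapshots + 1], name="rs_pool")
    return pool


def prepare_ts_pool(
    ts_guess: Configuration,
    potential: Potential,
    rc: ReactionCoordinate,
    md: MDParams,
    ts_distances: tuple[float, float],
    restraint_k: float = 40.0,
    n_snapshots: int = 4,
    interval_fs: float = 500.0,
    solute_atoms: Sequence[int] = (0, 1, 2, 3),
) -> ConfigurationSet:
    """Solvent-perturbed transition-state pool.

    The solute geometry is frozen while the solvent equilibrates; snapshots
    taken at fixed intervals are then re-optimized with the solvent frozen
    and harmonic restraints holding the forming bonds at their TS values —
    each pool member carries a solvent environment consistent with the TS.
    """
    from .dynamics import DistanceCoordinate

    solute = list(solute_atoms)
    params = MDParams(dt=md.dt, temperature=md.temperature, ensemble="NVT",
                      friction=md.friction,
                      duration=np.ceil(n_snapshots * interval_fs / md.dt) * md.dt,
                      rng_seed=md.rng_seed, stride=max(1, int(interval_fs / md.dt)))
    traj = run_md(ts_guess, potential, params, frozen_atoms=solute)
    if traj.unstable:
        raise RuntimeError("frozen-solute equilibration became unstable")
    snapshots = traj.frames[1 : n_snapshots + 1]
    solvent_atoms = [i for i in range(ts_guess.n_atoms) if i not in solute]
    biases = [
        HarmonicBias(DistanceCoordinate(*rc.pair1), ts_distances[0], restraint_k),
        HarmonicBias(DistanceCoordinate(*rc.pair2), ts_distances[1], restraint_k),
    ]
    pool = ConfigurationSet(name="ts_pool")
    for snap in snapshots:
        relaxed, _ = minimize(snap, potential, biases=biases,
                              frozen_atoms=solvent_atoms, f_tol=1e-3)
        pool.append(relaxed)
    return pool


def uphill_ensemble(
    rs_pool: ConfigurationSet,
    potential: Potential,
    rc: ReactionCoordinate,
    md: MDParams,
    bias_k: float = 0.4,
    bias_center: float = 1.5,
    max_time: float = 3000.0,
    keep_trajectories: bool = False,
) -> EnsembleSummary:
    """Bias-driven trajectories from reactant structures over the barrier.

    Each forming bond carries its own weak harmonic potential
    (0.4 eV Å⁻² by default) centred at the product distance, mirroring the
    per-bond restraints used to prepare the reactant pool; the pair of
    springs lowers the effective barrier to a few k_BT so thermal motion
    carries the system over. Each trajectory runs until the product forms
    or ``max_time`` (3 ps) elapses. Per-frame ξ, r₁, r₂ traces are retained
    so solvent observables can be resolved along the reaction.
    """
    from .dynamics import DistanceCoordinate

    outcomes = []
    trajectories = []
    for i, rs in enumerate(rs_pool):
        mdi = MDParams(dt=md.dt, temperature=md.temperature, ensemble=md.ensemble,
                       friction=md.friction, duration=md.duration,
                       rng_seed=md.rng_seed + i, stride=md.stride)
        biases = []
        if bias_k > 0:
            biases = [
                HarmonicBias(DistanceCoordinate(*rc.pair1), bias_center, bias_k),
                HarmonicBias(DistanceCoordinate(*rc.pair2), bias_center, bias_k),
            ]
        outcome, traj = _run_outcome_trajectory(
            rs, potential, rc, mdi, max_time, biases=biases,
            terminal_states=("product",),
        )
        outcomes.append(outcome)
        if keep_trajectories:
            trajectories.append(traj)
    summary = EnsembleSummary.from_outcomes(outcomes)
    if keep_trajectories:
        summary.trajectories = trajectories
    return summary


# ---------------------------------------------------------------------------
# solvent structure: RDF and hydrogen bonds
# ---------------------------------------------------------------------------

@dataclass
class RDFResult:
    r: np.ndarray        # bin centres, Å
    g: np.ndarray        # pair distribution
    coordination: np.ndarray  # running coordination number n(r)


def rdf(
    traj_or_frames,
    species_pair: tuple[str, str],
    r_max: float,
    n_bins: int = 100,
) -> RDFResult:
    """Radial distribution function g(r) under periodic boundary conditions.

    Minimum-image distances; normalized by the ideal-gas pair density, so
    g → 1 at large r for a homogeneous fluid. ``r_max`` must not exceed half
    the shortest box length.
    """
    frames = traj_or_frames.frames if isinstance(traj_or_frames, Trajectory) else list(traj_or_frames)
    if not frames:
        raise ValueError("no frames")
    first = frames[0]
    if not first.periodic or first.cell is None:
        raise ValueError("RDF requires periodic frames with a cell")
    box = np.diag(first.cell)
    if r_max > box.min() / 2 + 1e-9:
        raise ValueError(
            f"r_max {r_max} Å exceeds half the shortest box length ({box.min()/2:.2f} Å)"
        )
    sa, sb = species_pair
    edges = np.linspace(0.0, r_max, n_bins + 1)
    hist = np.zeros(n_bins)
    volume = float(np.prod(box))
    n_a = n_b = 0
    for frame in frames:
        species = np.array(frame.species)
        ia = np.nonzero(species == sa)[0]
        ib = np.nonzero(species == sb)[0]
        n_a, n_b = len(ia), len(ib)
        d = frame.positions[ib][None, :, :] - frame.positions[ia][:, None, :]
        d -= box * np.round(d / box)
        r = np.linalg.norm(d, axis=-1).ravel()
        if sa == sb:
            r = r[r > 1e-9]  # drop self-pairs
        hist += np.histogram(r[r < r_max], bins=edges)[0]
    hist /= len(frames)
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    rho_b = n_b / volume
    with np.errstate(divide="ignore", invalid="ignore"):
        g = hist / (n_a * rho_b * shell)
    coordination = np.cumsum(hist) / n_a
    return RDFResult(r=centers, g=g, coordination=coordination)


@dataclass
class HBCriterion:
    """Geometric hydrogen-bond definition.

    A donor–H…acceptor triple counts as hydrogen bonded when the heavy-atom
    (donor–acceptor) distance is below ``distance_cutoff`` and the
    donor–H–acceptor angle exceeds ``angle_cutoff_deg``.
    """

    distance_cutoff: float = 3.5       # Å
    angle_cutoff_deg: float = 140.0    # degrees

    def __post_init__(self):
        if self.distance_cutoff <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 90.0 < self.angle_cutoff_deg <= 180.0:
            raise ValueError("angle cutoff must lie in (90°, 180°]")


def find_hbonds(config: Configuration, criterion: HBCriterion) -> list[tuple[int, int, int]]:
    """(donor O, H, acceptor O) triples satisfying the geometric criterion.

    Donors are oxygens with covalently bound hydrogens; every oxygen is a
    potential acceptor. Minimum-image convention under periodicity.
    """
    species = np.array(config.species)
    o_idx = np.nonzero(species == "O")[0]
    if len(o_idx) < 2:
        return []
    molecules = detect_molecules(config)
    mol_of = np.empty(config.n_atoms, dtype=int)
    for m, atoms in enumerate(molecules):
        for a in atoms:
            mol_of[a] = m
    box = np.diag(config.cell) if config.periodic else None

    def mi(v):
        return v - box * np.round(v / box) if box is not None else v

    # hydrogens bound to each oxygen, by molecule membership + distance
    bonds = []
    cos_cut = np.cos(np.deg2rad(criterion.angle_cutoff_deg))
    for od in o_idx:
        hs = [a for a in molecules[mol_of[od]]
              if config.species[a] == "H"
              and np.linalg.norm(mi(config.positions[a] - config.positions[od])) < 1.3]
        for oa in o_idx:
            if oa == od or mol_of[oa] == mol_of[od]:
                continue
            d_oo = mi(config.positions[oa] - config.positions[od])
            if np.linalg.norm(d_oo) >= criterion.distance_cutoff:
                continue
            for h in hs:
                v_hd = mi(config.positions[od] - config.positions[h])
                v_ha = mi(config.positions[oa] - config.positions[h])
                cos_t = np.dot(v_hd, v_ha) / (np.linalg.norm(v_hd) * np.linalg.norm(v_ha))
                # donor-H-acceptor angle > cutoff  ⇔  cos(angle) < cos(cutoff)
                if cos_t < cos_cut:
                    bonds.append((int(od), int(h), int(oa)))
    return bonds


def count_hbs_by_distance(
    frames,
    criterion: HBCriterion,
    solute_atoms: Sequence[int],
    shell_edges: Sequence[float],
) -> tuple[np.ndarray, np.ndarray]:
    """Mean hydrogen bonds per solvent molecule versus distance from the solute.

    For every frame, each solvent molecule's hydrogen-bond count (donor or
    acceptor) is binned by its oxygen's distance from the solute centre of
    mass; the far-field bin estimates the bulk value. Empty bins are NaN.
    """
    frames = frames.frames if isinstance(frames, Trajectory) else list(frames)
    if not frames:
        raise ValueError("no frames")
    edges = np.asarray(shell_edges, float)
    sums = np.zeros(len(edges) - 1)
    counts = np.zeros(len(edges) - 1)
    solute = list(solute_atoms)
    for frame in frames:
        from .units import mass_of

        bonds = find_hbonds(frame, criterion)
        participation: dict[int, int] = {}
        for od, h, oa in bonds:
            participation[od] = participation.get(od, 0) + 1
            participation[oa] = participation.get(oa, 0) + 1
        if solute:
            masses = np.array([mass_of(frame.species[i]) for i in solute])
            com = (masses[:, None] * frame.positions[solute]).sum(axis=0) / masses.sum()
        else:
            com = frame.positions.mean(axis=0)
        species = np.array(frame.species)
        o_idx = [i for i in np.nonzero(species == "O")[0] if i not in solute]
        for o in o_idx:
            v = frame.positions[o] - com
            if frame.periodic:
                box = np.diag(frame.cell)
                v -= box * np.round(v / box)
            dist = np.linalg.norm(v)
            b = np.searchsorted(edges, dist) - 1
            if 0 <= b < len(sums):
                sums[b] += participation.get(int(o), 0)
                counts[b] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, mean
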