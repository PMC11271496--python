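"""Synthetic study systems: water clusters and boxes, the model cycloaddition dimer.

These builders define the desk-scale study conditions: a 27-molecule water
cluster (the selector-comparison system), a periodic water box at liquid
density, and the four-atom two-bond reactive solute, optionally solvated.
All builders are deterministic given their seed.
"""

from __future__ import annotations

import numpy as np

from .core import Configuration

WATER_OH = 0.96        # Å
WATER_ANGLE = 104.5    # degrees
LIQUID_WATER_DENSITY = 0.0334  # molecules / Å³ at ambient conditions


def water_geometry() -> np.ndarray:
    """One water molecule (O, H, H) at its toy-model equilibrium geometry."""
    half = np.deg2rad(WATER_ANGLE) / 2.0
    return np.array(
        [
            [0.0, 0.0, 0.0],
            [WATER_OH * np.sin(half), WATER_OH * np.cos(half), 0.0],
            [-WATER_OH * np.sin(half), WATER_OH * np.cos(half), 0.0],
        ]
    )


def make_water_molecule() -> Configuration:
    return Configuration(species=["O", "H", "H"], positions=water_geometry())


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _lattice_waters(sites: np.ndarray, rng: np.random.Generator, jitter: float):
    mol = water_geometry()
    mol = mol - mol.mean(axis=0)
    species, positions = [], []
    for site in sites:
        rot = _random_rotation(rng)
        centre = site + rng.uniform(-jitter, jitter, size=3)
        positions.append(mol @ rot.T + centre)
        species.extend(["O", "H", "H"])
    return species, np.vstack(positions)


def make_water_cluster(n_molecules: int = 27, rng_seed: int = 0, spacing: float = 3.1,
                       jitter: float = 0.15) -> Configuration:
    """Water cluster on a jittered cubic lattice with random orientations.

    27 molecules on a 3×3×3 lattice is the default selector-comparison
    system. The raw lattice structure is strained; equilibrate with the
    reference potential before using it as a thermal starting point.
    """
    rng = np.random.default_rng(rng_seed)
    n_side = int(np.ceil(n_molecules ** (1.0 / 3.0)))
    sites = np.array(
        [[i, j, k] for i in range(n_side) for j in range(n_side) for k in range(n_side)],
        dtype=float,
    )[:n_molecules] * spacing
    species, positions = _lattice_waters(sites, rng, jitter)
    return Configuration(
        species=species, positions=positions,
        provenance={"system": f"water_cluster_{n_molecules}"},
    )


def make_water_box(n_molecules: int = 64, rng_seed: int = 0,
                   density: float = LIQUID_WATER_DENSITY) -> Configuration:
    """Periodic cubic water box at the given number density.

    64 molecules give a 12.4 Å box — the smallest size whose half-box
    exceeds the toy potential's 6 Å nonbonded cutoff.
    """
    n_side = int(round(n_molecules ** (1.0 / 3.0)))
    if n_side**3 != n_molecules:
        raise ValueError("n_molecules must be a perfect cube for the lattice start")
    L = (n_molecules / density) ** (1.0 / 3.0)
    rng = np.random.default_rng(rng_seed)
    a = L / n_side
    sites = (
        np.array(
            [[i, j, k] for i in range(n_side) for j in range(n_side) for k in range(n_side)],
            dtype=float,
        )
        + 0.5
    ) * a
    species, positions = _lattice_waters(sites, rng, jitter=0.1)
    return Configuration(
        species=species, positions=positions, cell=np.eye(3) * L, periodic=True,
        provenance={"system": f"water_box_{n_molecules}", "box_A": L},
    )


def make_reactive_dimer(r1: float = 3.2, r2: float = 3.2, bond: float = 1.4) -> Configuration:
    """The four-atom two-bond solute at given forming-bond distances.

    Atoms 0–1 are one fragment, 2–3 the other; the forming bonds are
    (0, 2) and (1, 3). Both fragment bonds are placed exactly at their rest
    length, so the geometry realizes (r₁, r₂) with zero internal strain.
    Defaults start in the reactant basin.
    """
    a1 = np.array([0.0, 0.0, 0.0])
    a2 = np.array([bond, 0.0, 0.0])
    b1 = np.array([0.0, r1, 0.0])
    # b2: distance `bond` from b1 and r2 from a2 — in-plane circle intersection
    d_vec = a2 - b1
    D = np.linalg.norm(d_vec)
    if not abs(r2 - bond) <= D <= r2 + bond:
        raise ValueError(f"no planar geometry realizes r1={r1}, r2={r2} with bond={bond}")
    a = (bond**2 - r2**2 + D**2) / (2.0 * D)
    h = np.sqrt(max(bond**2 - a**2, 0.0))
    along = d_vec / D
    perp = np.array([-along[1], along[0], 0.0])
    cand = [b1 + a * along + h * perp, b1 + a * along - h * perp]
    b2 = max(cand, key=lambda p: p[1])  # keep the fragments on opposite sides
    positions = np.stack([a1, a2, b1, b2])
    return Configuration(
        species=["C", "C", "C", "C"], positions=positions,
        provenance={"system": "reactive_dimer", "r1": r1, "r2": r2},
    )


def solvate_reactive_dimer(
    solute: Configuration, n_waters: int = 20, rng_seed: int = 0,
    spacing: float = 3.1, min_dist: float = 2.5,
) -> Configuration:
    """Surround the reactive solute with toy-water molecules on nearby lattice sites."""
    rng = np.random.default_rng(rng_seed)
    n_side = int(np.ceil(((n_waters * 3) ** (1.0 / 3.0)))) + 2
    centre = solute.positions.mean(axis=0)
    offsets = np.arange(n_side) - (n_side - 1) / 2.0
    sites = np.array([[i, j, k] for i in offsets for j in offsets for k in offsets]) * spacing
    sites = sites + centre
    d = np.linalg.norm(sites[:, None, :] - solute.positions[None, :, :], axis=-1).min(axis=1)
    order = np.argsort(np.linalg.norm(sites - centre, axis=1), kind="stable")
    good = [s for s in order if d[s] > min_dist][:n_waters]
    if len(good) < n_waters:
        raise ValueError("could not place the requested number of solvent molecules")
    species, positions = _lattice_waters(sites[good], rng, jitter=0.1)
    return Configuration(
        species=list(solute.species) + species,
        positions=np.vstack([solute.positions, positions]),
        provenance=dict(solute.provenance, n_waters=n_waters),
    )


def equilibrated_water_cluster(
    n_molecules: int,
    potential,
    rng_seed: int = 0,
    equilibration_fs: float = 500.0,
    temperature: float = 300.0,
) -> Configuration:
    """Lattice water cluster relaxed and thermalized with the given potential."""
    from .dynamics import MDParams, minimize, run_md

    raw = make_water_cluster(n_molecules, rng_seed=rng_seed)
    relaxed, _ = minimize(raw, potential, f_tol=5e-2, max_steps=200)
    params = MDParams(
        dt=0.5, temperature=temperature, ensemble="NVT",
        duration=equilibration_fs, rng_seed=rng_seed, stride=10**9,
    )
    traj = run_md(relaxed, potential, params)
    if traj.unstable:
        raise RuntimeError("equilibration became unstable")
    out = traj.final
    out.provenance = dict(raw.provenance, equilibrated_fs=equilibration_fs,
                          temperature_K=temperature)
    return out


def cluster_initial_snapshots(
    n_molecules: int,
    potential,
    n_snapshots: int = 15,
    rng_seed: int = 0,
    temperature: float = 300.0,
    interval_fs: float = 50.0,
) -> "ConfigurationSet":
    """Initial training data for condensed-phase AL: equilibrated cluster snapshots.

    Mirrors the condensed-phase initialization, where initial configurations
    are solvent-cluster structures rather than random displacements of a
    single geometry: the reference potential equilibrates the cluster and
    snapshots are collected at fixed intervals.
    """
    from .core import ConfigurationSet
    from .dynamics import MDParams, run_md

    eq = equilibrated_water_cluster(
        n_molecules, potential, rng_seed=rng_seed, equilibration_fs=300.0,
        temperature=temperature,
    )
    stride = max(1, int(interval_fs / 0.5))
    params = MDParams(
        dt=0.5, temperature=temperature, ensemble="NVT",
        duration=n_snapshots * interval_fs, rng_seed=rng_seed + 1, stride=stride,
    )
    traj = run_md(eq, potential, params)
    frames = traj.frames[1 : n_snapshots + 1]
    out = ConfigurationSet(name=f"cluster_{n_molecules}_initial")
    for i, f in enumerate(frames):
        c = f.stripped()
        c.provenance = {"origin": "initial", "index": i}
        out.append(c)
    out.log.append(
        f"cluster_initial_snapshots(n={n_molecules}, count={n_snapshots}, seed={rng_seed})"
    )
    return out
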