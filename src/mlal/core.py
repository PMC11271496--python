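"""Atomic configurations, extended-XYZ I/O, initial-data generation and cluster carving.

A :class:`Configuration` is one atomic structure: element symbols, Cartesian
coordinates (Å), an optional orthorhombic cell, and optional energy (eV) /
per-atom force (eV Å⁻¹) labels tagged with the backend that produced them.
A :class:`ConfigurationSet` is an ordered, append-only collection of them —
the training set of an active-learning run.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .units import BOND_SCALE, covalent_radius_of, mass_of


class ExtxyzParseError(ValueError):
    """Raised when an extended-XYZ file cannot be parsed; names the frame index."""


@dataclass
class Configuration:
    """One atomic structure with optional energy/force labels and provenance tags.

    Parameters
    ----------
    species
        Per-atom element symbols, length N.
    positions
        (N, 3) Cartesian coordinates in Å.
    cell
        Optional 3×3 lattice vectors (Å). Only orthorhombic (diagonal) cells
        are supported by the periodic machinery in this package.
    periodic
        Whether minimum-image conventions apply.
    energy, forces
        Optional labels; both must come from the same backend
        (``label_source``) — mixing reference and MLP labels on one record
        is rejected.
    provenance
        Free-form tags (subset label, AL iteration index, selector name).
    """

    species: list[str]
    positions: np.ndarray
    cell: np.ndarray | None = None
    periodic: bool = False
    energy: float | None = None
    forces: np.ndarray | None = None
    label_source: str | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.species = [str(s) for s in self.species]
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        n = len(self.species)
        if self.positions.shape != (n, 3):
            raise ValueError(
                f"species ({n}) and positions ({self.positions.shape[0]}) disagree"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=float).reshape(-1, 3)
            if self.forces.shape != (n, 3):
                raise ValueError("forces must have one 3-vector per atom")
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=float).reshape(3, 3)
            if self.periodic and abs(np.linalg.det(self.cell)) < 1e-10:
                raise ValueError("periodic configuration with singular cell")
        if self.periodic and self.cell is None:
            raise ValueError("periodic configuration requires a cell")
        if (self.energy is not None or self.forces is not None) and not self.label_source:
            self.label_source = "unknown"

    # -- convenience -------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.species)

    def masses(self) -> np.ndarray:
        return np.array([mass_of(s) for s in self.species])

    def copy(self) -> "Configuration":
        return Configuration(
            species=list(self.species),
            positions=self.positions.copy(),
            cell=None if self.cell is None else self.cell.copy(),
            periodic=self.periodic,
            energy=self.energy,
            forces=None if self.forces is None else self.forces.copy(),
            label_source=self.label_source,
            provenance=dict(self.provenance),
        )

    def with_labels(
        self, energy: float, forces: np.ndarray | None, source: str
    ) -> "Configuration":
        """Return a copy carrying energy/forces from a single backend."""
        out = self.copy()
        out.energy = float(energy)
        out.forces = None if forces is None else np.asarray(forces, float).copy()
        out.label_source = source
        return out

    def stripped(self) -> "Configuration":
        """Copy without labels (used before relabelling with a new backend)."""
        out = self.copy()
        out.energy = None
        out.forces = None
        out.label_source = None
        return out


class ConfigurationSet:
    """Ordered, append-only collection of configurations with a creation log."""

    def __init__(self, configs: Iterable[Configuration] = (), name: str = ""):
        self._configs: list[Configuration] = list(configs)
        self.name = name
        self.log: list[str] = []

    def append(self, config: Configuration, note: str = "") -> None:
        self._configs.append(config)
        if note:
            self.log.append(note)

    def extend(self, configs: Iterable[Configuration], note: str = "") -> None:
        for c in configs:
            self._configs.append(c)
        if note:
            self.log.append(note)

    def __len__(self) -> int:
        return len(self._configs)

    def __iter__(self) -> Iterator[Configuration]:
        return iter(self._configs)

    def __getitem__(self, i):
        if isinstance(i, slice):
            out = ConfigurationSet(self._configs[i], name=self.name)
            return out
        return self._configs[i]

    def energies(self) -> np.ndarray:
        es = [c.energy for c in self._configs]
        if any(e is None for e in es):
            missing = [i for i, e in enumerate(es) if e is None]
            raise ValueError(f"configurations without energy labels at indices {missing}")
        return np.array(es, dtype=float)

    def split(self, fraction: float, rng_seed: int) -> tuple["ConfigurationSet", "ConfigurationSet"]:
        """Deterministic shuffled split: (first ``fraction``, remainder)."""
        rng = np.random.default_rng(rng_seed)
        idx = rng.permutation(len(self._configs))
        k = int(round(fraction * len(self._configs)))
        a = ConfigurationSet([self._configs[i] for i in idx[:k]], name=f"{self.name}/a")
        b = ConfigurationSet([self._configs[i] for i in idx[k:]], name=f"{self.name}/b")
        return a, b


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------

_KV_RE = re.compile(r'(\S+?)=(".*?"|\S+)')


def _format_comment(config: Configuration) -> str:
    props = "species:S:1:pos:R:3"
    if config.forces is not None:
        props += ":forces:R:3"
    parts = [f"Properties={props}"]
    if config.cell is not None:
        flat = " ".join(f"{x:.10f}" for x in config.cell.ravel())
        parts.insert(0, f'Lattice="{flat}"')
    if config.energy is not None:
        parts.append(f"energy={config.energy:.10f}")
    if config.label_source:
        parts.append(f"label_source={config.label_source}")
    pbc = "T T T" if config.periodic else "F F F"
    parts.append(f'pbc="{pbc}"')
    return " ".join(parts)


def write_extxyz(configs, path) -> None:
    """Write configurations to an extended-XYZ file.

    Accepts a single :class:`Configuration`, a :class:`ConfigurationSet`, or
    any iterable of configurations.
    """
    if isinstance(configs, Configuration):
        configs = [configs]
    with open(path, "w") as fh:
        for config in configs:
            fh.write(f"{config.n_atoms}\n")
            fh.write(_format_comment(config) + "\n")
            for i, s in enumerate(config.species):
                x, y, z = config.positions[i]
                line = f"{s} {x:.10f} {y:.10f} {z:.10f}"
                if config.forces is not None:
                    fx, fy, fz = config.forces[i]
                    line += f" {fx:.10f} {fy:.10f} {fz:.10f}"
                fh.write(line + "\n")


def _parse_comment(comment: str) -> dict:
    out = {}
    for key, val in _KV_RE.findall(comment):
        if val.startswith('"') and val.endswith('"'):
            val = val[1:-1]
        out[key] = val
    return out


def read_extxyz(path) -> ConfigurationSet:
    """Read an extended-XYZ file into a :class:`ConfigurationSet`.

    Understands ``Lattice``, ``Properties`` (species/pos and optional
    per-atom forces), ``energy``, ``label_source`` and ``pbc`` keys.
    Raises :class:`ExtxyzParseError` naming the frame index on malformed input.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    configs = ConfigurationSet(name=str(path))
    i = 0
    frame = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ExtxyzParseError(
                f"frame {frame}: expected atom count, got {lines[i]!r}"
            ) from None
        if i + 1 + n >= len(lines) + 1 and i + 1 + n > len(lines):
            raise ExtxyzParseError(f"frame {frame}: declares {n} atoms but file ends early")
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        meta = _parse_comment(comment)
        props = meta.get("Properties", "species:S:1:pos:R:3")
        fields = props.split(":")
        cols = []
        j = 0
        while j < len(fields):
            cols.append((fields[j], fields[j + 1], int(fields[j + 2])))
            j += 3
        has_forces = any(name == "forces" for name, _, _ in cols)
        n_cols = sum(width for _, _, width in cols)

        species, positions, forces = [], [], []
        for k in range(n):
            idx = i + 2 + k
            if idx >= len(lines):
                raise ExtxyzParseError(f"frame {frame}: declares {n} atoms, file truncated")
            tok = lines[idx].split()
            if len(tok) < n_cols:
                raise ExtxyzParseError(
                    f"frame {frame}: atom line {k} has {len(tok)} columns, expected {n_cols}"
                )
            col = 0
            for name, _, width in cols:
                vals = tok[col : col + width]
                if name == "species":
                    species.append(vals[0])
                elif name == "pos":
                    positions.append([float(v) for v in vals])
                elif name == "forces":
                    forces.append([float(v) for v in vals])
                col += width
        # guard against a frame that declared too few atoms: next line should be
        # a bare integer (next frame header) or EOF
        nxt = i + 2 + n
        if nxt < len(lines) and lines[nxt].strip():
            try:
                int(lines[nxt].strip())
            except ValueError:
                raise ExtxyzParseError(
                    f"frame {frame}: declared {n} atoms but more atom lines follow"
                ) from None

        cell = None
        if "Lattice" in meta:
            cell = np.array([float(v) for v in meta["Lattice"].split()]).reshape(3, 3)
        periodic = "T" in meta.get("pbc", "F F F")
        energy = float(meta["energy"]) if "energy" in meta else None
        configs.append(
            Configuration(
                species=species,
                positions=np.array(positions),
                cell=cell,
                periodic=periodic,
                energy=energy,
                forces=np.array(forces) if has_forces else None,
                label_source=meta.get("label_source"),
            )
        )
        i = nxt
        frame += 1
    return configs


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def minimum_image_displacements(positions: np.ndarray, cell: np.ndarray) -> np.ndarray:
    """All-pairs displacement vectors r_j − r_i under the minimum-image convention.

    Only orthorhombic (diagonal) cells are supported.
    """
    box = np.diag(cell)
    if not np.allclose(cell, np.diag(box)):
        raise ValueError("only orthorhombic cells are supported")
    d = positions[None, :, :] - positions[:, None, :]
    d -= box * np.round(d / box)
    return d


def pair_displacements(config: Configuration) -> np.ndarray:
    """(N, N, 3) displacement vectors, minimum-image if periodic."""
    if config.periodic:
        return minimum_image_displacements(config.positions, config.cell)
    return config.positions[None, :, :] - config.positions[:, None, :]


def detect_molecules(config: Configuration) -> list[list[int]]:
    """Group atoms into molecules by a covalent-radius bond cutoff.

    Two atoms are bonded when their (minimum-image) distance is below
    ``BOND_SCALE`` × the sum of their covalent radii. Returns connected
    components as sorted index lists, ordered by their smallest member.
    """
    n = config.n_atoms
    d = np.linalg.norm(pair_displacements(config), axis=-1)
    radii = np.array([covalent_radius_of(s) for s in config.species])
    cut = BOND_SCALE * (radii[:, None] + radii[None, :])
    bonded = (d < cut) & ~np.eye(n, dtype=bool)
    # BFS over the bond graph
    seen = np.zeros(n, dtype=bool)
    molecules = []
    for start in range(n):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            a = stack.pop()
            comp.append(a)
            for b in np.nonzero(bonded[a])[0]:
                if not seen[b]:
                    seen[b] = True
                    stack.append(int(b))
        molecules.append(sorted(comp))
    return molecules


# ---------------------------------------------------------------------------
# initial-data generation and cluster carving
# ---------------------------------------------------------------------------

def random_displace(
    seed_config: Configuration,
    max_disp: float,
    count: int,
    rng_seed: int,
) -> ConfigurationSet:
    """Generate initial configurations by random displacement of the coordinates.

    Each Cartesian component of every atom is displaced i.i.d. uniformly on
    [−max_disp, +max_disp]. Deterministic given ``rng_seed``; outputs carry
    the provenance tag ``origin="initial"``.
    """
    if count <= 0:
        raise ValueError("count must be positive")
    if max_disp < 0:
        raise ValueError("max_disp must be non-negative")
    rng = np.random.default_rng(rng_seed)
    out = ConfigurationSet(name="initial")
    for i in range(count):
        disp = rng.uniform(-max_disp, max_disp, size=seed_config.positions.shape)
        c = seed_config.stripped()
        c.positions = c.positions + disp
        c.provenance = {"origin": "initial", "index": i}
        out.append(c)
    out.log.append(f"random_displace(max_disp={max_disp}, count={count}, rng_seed={rng_seed})")
    return out


def carve_cluster(
    snapshot: Configuration,
    solute_atom_indices: Sequence[int],
    r_cluster: float,
    r_cut: float,
) -> Configuration:
    """Carve a non-periodic solute + solvent-shell cluster from a snapshot.

    The solvent shell must be at least as wide as the descriptor cutoff
    (``r_cluster ≥ r_cut``) so that no atom in the MLP's environment sees an
    artificial vacuum interface. Solvent molecules are included whole whenever
    any of their atoms lies within ``r_cluster`` of any solute atom; under
    periodicity each molecule is first shifted to its minimum image relative
    to the solute.
    """
    if r_cluster < r_cut:
        raise ValueError(
            f"r_cluster ({r_cluster} Å) must be no less than the descriptor "
            f"cut-off radius r_cut ({r_cut} Å): a thinner solvent shell creates "
            "artificial forces at the cluster-vacuum interface"
        )
    solute = sorted(set(int(i) for i in solute_atom_indices))
    if not solute or min(solute) < 0 or max(solute) >= snapshot.n_atoms:
        raise IndexError("solute atom indices out of range")

    molecules = detect_molecules(snapshot)
    solute_set = set(solute)
    # molecules fully/partially in the solute index set belong to the solute
    solvent_mols = [m for m in molecules if not solute_set.intersection(m)]

    pos = snapshot.positions
    solute_pos = pos[solute]
    box = np.diag(snapshot.cell) if snapshot.periodic else None

    kept_species = [snapshot.species[i] for i in solute]
    kept_pos = [solute_pos]
    for mol in solvent_mols:
        mol_pos = pos[mol].copy()
        if box is not None:
            # shift the whole molecule by the lattice translation that brings
            # its first atom closest to the solute centroid, keeping it intact
            centroid = solute_pos.mean(axis=0)
            shift = -box * np.round((mol_pos[0] - centroid) / box)
            mol_pos = mol_pos + shift
        d = np.linalg.norm(mol_pos[:, None, :] - solute_pos[None, :, :], axis=-1)
        if d.min() <= r_cluster:
            kept_species.extend(snapshot.species[i] for i in mol)
            kept_pos.append(mol_pos)

    return Configuration(
        species=kept_species,
        positions=np.vstack(kept_pos),
        cell=None,
        periodic=False,
        provenance={"origin": "carve_cluster", "r_cluster": r_cluster, "r_cut": r_cut},
    )
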