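"""Potential backends: the contract, analytic reference potentials, and the SOAP-KRR MLP.

Anything that maps a :class:`~mlal.core.Configuration` to an energy (eV) and
per-atom forces (eV Å⁻¹) is a potential. Two analytic potentials act as the
ground-truth reference in place of an external quantum-chemistry backend:

* :class:`ToyWaterPotential` — flexible point-charge water (harmonic O–H
  bonds and H–O–H angles, O–O Lennard-Jones, smoothly switched Coulomb),
  parameterized so the liquid O–O RDF peaks near 2.8 Å.
* :class:`TwoBondReactivePotential` — a four-atom model cycloaddition in
  which two forming bonds r₁, r₂ each move on an asymmetric double well
  (reactant minimum at large r, product at short r) with a harmonic
  coupling that controls synchronicity; optionally solvated in toy water.

:class:`SoapKrrMlp` is the internal trainable machine-learning potential:
ridge regression over SOAP power-spectrum features fitted to energies and
forces (linear extensive features by default, with per-atom sparse-kernel
and global dual-kernel variants), forces from analytic descriptor
gradients.

External quantum-chemistry backends are represented only by this contract —
see :class:`ExternalBackendStub`.
"""

from __future__ import annotations

import json
from abc import ABC, abstractmethod
from dataclasses import dataclass

import numpy as np

from .core import Configuration, ConfigurationSet
from .descriptors import SoapCalculator, SoapParams
from .mathutils import smoothstep_down
from .units import COULOMB_EV_A, EV_TO_KCAL_PER_MOL


class ReferenceFailure(RuntimeError):
    """The reference backend cannot label a structure (the SCF-failure analogue)."""


class Potential(ABC):
    """The potential contract: energy plus per-atom forces for a configuration."""

    label: str = "potential"
    r_cut: float = 5.0

    @abstractmethod
    def evaluate(self, config: Configuration) -> tuple[float, np.ndarray]:
        """Return (energy eV, forces (N,3) eV Å⁻¹)."""

    def label_config(self, config: Configuration) -> Configuration:
        """Return a copy of ``config`` labeled with this backend's energy/forces."""
        e, f = self.evaluate(config)
        return config.with_labels(e, f, source=self.label)


def evaluate(potential: Potential, config: Configuration) -> tuple[float, np.ndarray]:
    """Functional form of the contract (delegates to ``potential.evaluate``)."""
    return potential.evaluate(config)


def numerical_forces(potential: Potential, config: Configuration, h: float = 1e-4) -> np.ndarray:
    """Central finite-difference forces; the oracle for force consistency."""
    pos0 = config.positions
    f = np.zeros_like(pos0)
    work = config.copy()
    for a in range(config.n_atoms):
        for d in range(3):
            work.positions = pos0.copy()
            work.positions[a, d] += h
            ep = potential.evaluate(work)[0]
            work.positions[a, d] -= 2 * h
            em = potential.evaluate(work)[0]
            f[a, d] = -(ep - em) / (2 * h)
    return f


# ---------------------------------------------------------------------------
# pairwise building blocks
# ---------------------------------------------------------------------------

def _displacements(config: Configuration) -> np.ndarray:
    if config.periodic:
        box = np.diag(config.cell)
        if not np.allclose(config.cell, np.diag(box)):
            raise ValueError("only orthorhombic cells are supported")
        d = config.positions[None, :, :] - config.positions[:, None, :]
        d -= box * np.round(d / box)
        return d
    return config.positions[None, :, :] - config.positions[:, None, :]


@dataclass
class ToyWaterPotential(Potential):
    """Flexible point-charge water model (analytic reference in place of DFT).

    Intramolecular terms are harmonic (O–H stretch and H–O–H bend at the
    water equilibrium geometry); intermolecular interactions are TIP3P-like
    O–O Lennard-Jones plus point-charge Coulomb, both multiplied by a C²
    switching function that vanishes at ``r_c`` so the potential is smooth
    everywhere sampled. Hydrogens are assigned to their nearest oxygen at
    every call; the assignment is stable for intact water molecules.
    """

    k_bond: float = 45.0        # eV Å⁻²
    r0: float = 0.96            # Å
    k_angle: float = 3.5        # eV rad⁻²
    theta0_deg: float = 104.5
    lj_epsilon: float = 0.0066  # eV
    lj_sigma: float = 3.1507    # Å
    q_O: float = -0.834
    q_H: float = 0.417
    r_c: float = 6.0            # nonbonded cutoff Å
    switch_width: float = 1.0
    # labeling-validity limit: like an SCF, the reference refuses structures
    # distorted beyond its domain (an assigned O-H bond stretched past this)
    label_bond_limit: float = 1.8

    label: str = "toy_water"
    r_cut: float = 6.0

    def label_config(self, config: Configuration) -> Configuration:
        d = _displacements(config)
        o_idx, h_idx, owner, _, _ = self._topology(config, d)
        r = np.linalg.norm(d[h_idx, owner], axis=1)
        if len(r) and r.max() > self.label_bond_limit:
            raise ReferenceFailure(
                f"O-H bond stretched to {r.max():.2f} Å exceeds the reference "
                f"validity limit ({self.label_bond_limit} Å)"
            )
        return super().label_config(config)

    def _topology(self, config: Configuration, d: np.ndarray):
        species = np.array(config.species)
        o_idx = np.nonzero(species == "O")[0]
        h_idx = np.nonzero(species == "H")[0]
        if len(o_idx) + len(h_idx) != config.n_atoms:
            bad = sorted(set(config.species) - {"O", "H"})
            raise ValueError(f"toy water supports O/H only, got {bad}")
        if len(h_idx) != 2 * len(o_idx):
            raise ValueError("toy water requires two hydrogens per oxygen")
        r_ho = np.linalg.norm(d[h_idx[:, None], o_idx[None, :]], axis=-1)
        owner = o_idx[np.argmin(r_ho, axis=1)]
        mol_id = np.empty(config.n_atoms, dtype=int)
        for m, o in enumerate(o_idx):
            mol_id[o] = m
        mol_id[h_idx] = mol_id[owner]
        # hydrogens bound to each oxygen (normally two; distorted structures
        # may assign one or three — the potential stays defined and finite)
        h_of = {int(o): [] for o in o_idx}
        for h, o in zip(h_idx, owner):
            h_of[int(o)].append(int(h))
        return o_idx, h_idx, owner, mol_id, h_of

    def evaluate(self, config: Configuration) -> tuple[float, np.ndarray]:
        n = config.n_atoms
        d = _displacements(config)  # d[i,j] = r_j - r_i
        if config.periodic:
            box = np.diag(config.cell)
            if self.r_c > box.min() / 2 + 1e-9:
                raise ValueError(
                    f"nonbonded cutoff {self.r_c} Å exceeds half the box ({box.min()/2:.2f} Å)"
                )
        o_idx, h_idx, owner, mol_id, h_of = self._topology(config, d)
        energy = 0.0
        forces = np.zeros((n, 3))

        # O-H bonds
        vec = d[h_idx, owner]  # r_O - r_H
        r = np.linalg.norm(vec, axis=1)
        energy += 0.5 * self.k_bond * np.sum((r - self.r0) ** 2)
        fpair = (self.k_bond * (r - self.r0) / r)[:, None] * vec  # force on H
        np.add.at(forces, h_idx, fpair)
        np.add.at(forces, owner, -fpair)

        # H-O-H angles (every pair of hydrogens bound to the same oxygen)
        from itertools import combinations

        theta0 = np.deg2rad(self.theta0_deg)
        angle_triples = [
            (o, h1, h2) for o, hs in h_of.items() for h1, h2 in combinations(hs, 2)
        ]
        for o, h1, h2 in angle_triples:
            u, v = d[o, h1], d[o, h2]
            ru, rv = np.linalg.norm(u), np.linalg.norm(v)
            cos_t = np.clip(np.dot(u, v) / (ru * rv), -1.0, 1.0)
            theta = np.arccos(cos_t)
            sin_t = max(np.sqrt(1.0 - cos_t**2), 1e-8)
            energy += 0.5 * self.k_angle * (theta - theta0) ** 2
            dE = self.k_angle * (theta - theta0)
            dcos_du = v / (ru * rv) - cos_t * u / ru**2
            dcos_dv = u / (ru * rv) - cos_t * v / rv**2
            f1 = dE / sin_t * dcos_du   # force on h1 = -dE/dr_h1; dθ/dcos = -1/sinθ
            f2 = dE / sin_t * dcos_dv
            forces[h1] += f1
            forces[h2] += f2
            forces[o] -= f1 + f2

        # intermolecular nonbonded (switched Coulomb everywhere, LJ on O-O)
        iu, ju = np.triu_indices(n, k=1)
        inter = mol_id[iu] != mol_id[ju]
        iu, ju = iu[inter], ju[inter]
        vec = d[iu, ju]
        r = np.linalg.norm(vec, axis=1)
        close = r < self.r_c
        iu, ju, vec, r = iu[close], ju[close], vec[close], r[close]
        s, ds = smoothstep_down(r, self.r_c - self.switch_width, self.r_c)

        charges = np.where(np.array(config.species) == "O", self.q_O, self.q_H)
        qq = COULOMB_EV_A * charges[iu] * charges[ju]
        e_c = qq / r
        de_c = -qq / r**2
        both_o = (np.array(config.species)[iu] == "O") & (np.array(config.species)[ju] == "O")
        x6 = np.zeros_like(r)
        e_lj = np.zeros_like(r)
        de_lj = np.zeros_like(r)
        if np.any(both_o):
            ro = r[both_o]
            x6 = (self.lj_sigma / ro) ** 6
            e_lj_o = 4.0 * self.lj_epsilon * (x6**2 - x6)
            de_lj_o = 4.0 * self.lj_epsilon * (-12.0 * x6**2 + 6.0 * x6) / ro
            e_lj[both_o] = e_lj_o
            de_lj[both_o] = de_lj_o
        e_pair = (e_c + e_lj) * s
        de_pair = (de_c + de_lj) * s + (e_c + e_lj) * ds
        energy += float(np.sum(e_pair))
        fpair = (de_pair / r)[:, None] * vec  # force on j is -dE/dr_j = -de * rhat
        np.add.at(forces, ju, -fpair)
        np.add.at(forces, iu, fpair)
        return float(energy), forces


@dataclass
class TwoBondReactivePotential(Potential):
    """Model cycloaddition: two forming bonds on coupled asymmetric double wells.

    Atoms 0–3 form two fragments (0–1 and 2–3, harmonic bonds); the forming
    bonds are r₁ = |r₀ − r₂| and r₂ = |r₁ − r₃| by default. Each forming bond
    carries V(r) = h·(x²−1)² + tilt·x with x = (r − r_m)/b, giving a reactant
    minimum near r_m + b and a (lower, for tilt < 0) product minimum near
    r_m − b, with barrier ≈ h − |tilt|. A term g·(r₁−r₂)² couples the two
    bonds and controls how synchronously they form. Any atoms beyond the
    first four must be toy-water solvent; solute–solvent interactions are a
    switched Lennard-Jones on the solute carbons.
    """

    pair1: tuple[int, int] = (0, 2)
    pair2: tuple[int, int] = (1, 3)
    bonds: tuple = ((0, 1), (2, 3))
    k_bond: float = 25.0
    r0_bond: float = 1.4
    barrier: float = 0.6        # h, eV
    tilt: float = 0.15          # eV (positive → exothermic, product well deeper)
    r_m: float = 2.325          # Å, double-well midpoint
    b: float = 0.875            # Å, double-well half-width
    coupling: float = 0.05      # g, eV Å⁻²
    solvent_lj_epsilon: float = 0.004
    solvent_lj_sigma: float = 3.2

    label: str = "two_bond_reactive"
    r_cut: float = 6.0

    def __post_init__(self):
        self._water = ToyWaterPotential()

    def label_config(self, config: Configuration) -> Configuration:
        if config.n_atoms > 4:
            solvent = Configuration(
                species=config.species[4:], positions=config.positions[4:],
                cell=config.cell, periodic=config.periodic,
            )
            self._water.label_config(solvent)  # validity check on the solvent
        for i, j in self.bonds:
            r = float(np.linalg.norm(config.positions[j] - config.positions[i]))
            if r > 2.5 * self.r0_bond:
                raise ReferenceFailure(
                    f"fragment bond {i}-{j} stretched to {r:.2f} Å — outside the "
                    "reference validity domain"
                )
        return super().label_config(config)

    def double_well(self, r: float) -> float:
        x = (r - self.r_m) / self.b
        return self.barrier * (x**2 - 1.0) ** 2 + self.tilt * x

    def _dw_deriv(self, r: float) -> float:
        x = (r - self.r_m) / self.b
        return (4.0 * self.barrier * x * (x**2 - 1.0) + self.tilt) / self.b

    def constrained_energy(self, r1: float, r2: float) -> float:
        """Analytic minimum energy at fixed (r₁, r₂): the relaxed-scan oracle.

        With the fragment bonds at their rest length and no other solute
        terms, the constrained PES is exactly the sum of the two double
        wells plus the coupling.
        """
        return self.double_well(r1) + self.double_well(r2) + self.coupling * (r1 - r2) ** 2

    def reactant_minimum(self) -> float:
        """Location of the reactant (large-r) well of one forming bond."""
        from scipy.optimize import minimize_scalar
        res = minimize_scalar(self.double_well, bounds=(self.r_m, self.r_m + 2 * self.b),
                              method="bounded")
        return float(res.x)

    def product_minimum(self) -> float:
        from scipy.optimize import minimize_scalar
        res = minimize_scalar(self.double_well, bounds=(self.r_m - 2 * self.b, self.r_m),
                              method="bounded")
        return float(res.x)

    def evaluate(self, config: Configuration) -> tuple[float, np.ndarray]:
        n = config.n_atoms
        if n < 4:
            raise ValueError("reactive system needs at least the four solute atoms")
        pos = config.positions
        energy = 0.0
        forces = np.zeros((n, 3))

        def add_pair(i, j, de, r, vec):
            f = (de / r) * vec  # dE/dr * rhat acting on j
            forces[j] -= f
            forces[i] += f

        # fragment bonds
        for i, j in self.bonds:
            vec = pos[j] - pos[i]
            r = np.linalg.norm(vec)
            energy += 0.5 * self.k_bond * (r - self.r0_bond) ** 2
            add_pair(i, j, self.k_bond * (r - self.r0_bond), r, vec)

        # forming bonds on double wells + coupling
        (a1, b1), (a2, b2) = self.pair1, self.pair2
        v1 = pos[b1] - pos[a1]
        v2 = pos[b2] - pos[a2]
        r1, r2 = np.linalg.norm(v1), np.linalg.norm(v2)
        energy += self.double_well(r1) + self.double_well(r2)
        energy += self.coupling * (r1 - r2) ** 2
        de1 = self._dw_deriv(r1) + 2.0 * self.coupling * (r1 - r2)
        de2 = self._dw_deriv(r2) - 2.0 * self.coupling * (r1 - r2)
        add_pair(a1, b1, de1, r1, v1)
        add_pair(a2, b2, de2, r2, v2)

        if n > 4:
            solvent = Configuration(
                species=config.species[4:], positions=pos[4:],
                cell=config.cell, periodic=config.periodic,
            )
            e_w, f_w = self._water.evaluate(solvent)
            energy += e_w
            forces[4:] += f_w
            # solute-solvent switched LJ (solute atoms vs all solvent atoms)
            d = pos[4:][None, :, :] - pos[:4][:, None, :]
            if config.periodic:
                box = np.diag(config.cell)
                d -= box * np.round(d / box)
            r = np.linalg.norm(d, axis=-1)
            mask = r < self._water.r_c
            ii, jj = np.nonzero(mask)
            rr = r[ii, jj]
            vec = d[ii, jj]
            s, ds = smoothstep_down(rr, self._water.r_c - 1.0, self._water.r_c)
            x6 = (self.solvent_lj_sigma / rr) ** 6
            e_lj = 4.0 * self.solvent_lj_epsilon * (x6**2 - x6)
            de_lj = 4.0 * self.solvent_lj_epsilon * (-12.0 * x6**2 + 6.0 * x6) / rr
            energy += float(np.sum(e_lj * s))
            de = de_lj * s + e_lj * ds
            f = (de / rr)[:, None] * vec
            np.add.at(forces, 4 + jj, -f)
            np.add.at(forces, ii, f)

        return float(energy), forces


@dataclass
class HarmonicDimerPotential(Potential):
    """Two atoms on a single harmonic bond — closed-form test system."""

    k: float = 5.0
    r0: float = 1.0
    label: str = "harmonic_dimer"
    r_cut: float = 5.0

    def evaluate(self, config: Configuration) -> tuple[float, np.ndarray]:
        vec = config.positions[1] - config.positions[0]
        r = np.linalg.norm(vec)
        e = 0.5 * self.k * (r - self.r0) ** 2
        f = np.zeros((config.n_atoms, 3))
        fd = -self.k * (r - self.r0) / r * vec
        f[1] = fd
        f[0] = -fd
        return float(e), f


@dataclass
class DoubleWellDimerPotential(Potential):
    """Two atoms whose distance moves on an asymmetric double well.

    The free-energy profile along r has the closed form
    F(r) = U(r) − 2 k_B T ln r (up to a constant), which serves as the
    quadrature oracle for umbrella-sampling reconstruction.
    """

    barrier: float = 0.3   # eV
    tilt: float = -0.05    # eV
    r_m: float = 2.0       # Å
    b: float = 0.5         # Å
    label: str = "double_well_dimer"
    r_cut: float = 5.0

    def distance_energy(self, r) -> np.ndarray:
        x = (np.asarray(r, float) - self.r_m) / self.b
        return self.barrier * (x**2 - 1.0) ** 2 + self.tilt * x

    def evaluate(self, config: Configuration) -> tuple[float, np.ndarray]:
        vec = config.positions[1] - config.positions[0]
        r = np.linalg.norm(vec)
        x = (r - self.r_m) / self.b
        e = self.barrier * (x**2 - 1.0) ** 2 + self.tilt * x
        de = (4.0 * self.barrier * x * (x**2 - 1.0) + self.tilt) / self.b
        f = np.zeros((config.n_atoms, 3))
        fd = -de / r * vec
        f[1] = fd
        f[0] = -fd
        return float(e), f


class ExternalBackendStub(Potential):
    """Adapter point for external quantum-chemistry backends.

    The package never manages quantum-chemistry processes; an integration
    wraps its single-point driver in this interface (energy in eV, forces in
    eV Å⁻¹) and everything else — selectors, the AL loop, the analysis stack
    — works unchanged.
    """

    label = "external"

    def __init__(self, single_point_fn=None, label: str = "external", r_cut: float = 5.0):
        self._fn = single_point_fn
        self.label = label
        self.r_cut = r_cut

    def evaluate(self, config: Configuration) -> tuple[float, np.ndarray]:
        if self._fn is None:
            raise NotImplementedError(
                "no external backend attached; provide single_point_fn(config) -> (energy, forces)"
            )
        e, f = self._fn(config)
        return float(e), np.asarray(f, float).reshape(-1, 3)


# ---------------------------------------------------------------------------
# the internal trainable MLP
# ---------------------------------------------------------------------------

class _NormalEquations:
    """Incrementally accumulated weighted least-squares normal equations."""

    def __init__(self, n_features: int):
        self.AtA = np.zeros((n_features, n_features))
        self.Atb = np.zeros(n_features)
        self.n_rows = 0

    def add(self, A: np.ndarray, b: np.ndarray, weight: float = 1.0) -> None:
        A = np.atleast_2d(A)
        b = np.atleast_1d(b)
        w2 = weight * weight
        self.AtA += w2 * (A.T @ A)
        self.Atb += w2 * (A.T @ b)
        self.n_rows += len(b)

    def solve(self, lam_rel: float) -> np.ndarray:
        n = len(self.Atb)
        scale = np.trace(self.AtA) / n
        if scale <= 0:
            raise ValueError("no data accumulated")
        return np.linalg.solve(self.AtA + lam_rel * scale * np.eye(n), self.Atb)


class SoapKrrMlp(Potential):
    """Trainable MLP over global SOAP power spectra — the internal stand-in
    for an externally trained model inside the AL loop.

    Three regression modes:

    * ``mode="linear"`` (default): ridge regression on the *summed* (extensive)
      power spectrum plus per-species composition columns, fitted to total
      energies and, when available, per-atom forces. Linear-in-features with
      force labels is the same inductive bias as linear atomic cluster
      expansion models and reaches chemical accuracy with tens of labelled
      configurations; energies alone cannot (a configuration contributes one
      energy equation but 3N force equations).
    * ``mode="local"``: sparse kernel regression on *per-atom* environments
      (the construction behind Gaussian approximation potentials): the total
      energy is a sum of atomic energies ε(p̂ᵢ) = Σ_m α_m |p̂ᵢ·q̂_m|^ζ over a
      set of representative environments q̂_m picked by farthest-point
      sampling; fitted to energies and forces. The nonlinear local form is
      markedly more accurate than the linear one at equal data.
    * ``mode="kernel"``: dual kernel ridge regression |p·q|^ζ over the
      unit-normalized global descriptors, energies only — the similarity
      kernel reused as a regressor; retained for small interpolation tasks.

    Forces come from the analytic descriptor gradient in adjoint form
    (``force_method="analytic"``) or from central finite differences of the
    predicted energy (``force_method="fd"``, step ``h``, O(6N) descriptor
    evaluations per call) — the independent cross-check.
    """

    label = "soap_krr_mlp"

    def __init__(
        self,
        soap: SoapParams,
        lam: float = 1e-11,
        zeta: int = 4,
        h: float = 1e-3,
        force_method: str = "analytic",
        mode: str = "linear",
        use_forces: bool = True,
        energy_weight: float = 10.0,
        n_sparse: int = 120,
        local_kernel: str = "se",
        length_scale: float | None = None,
    ):
        if zeta < 1 or int(zeta) != zeta:
            raise ValueError("zeta must be a positive integer")
        if force_method not in ("analytic", "fd"):
            raise ValueError("force_method must be 'analytic' or 'fd'")
        if mode not in ("linear", "kernel", "local"):
            raise ValueError("mode must be 'linear', 'kernel' or 'local'")
        # one SoapParams, or several for a multi-scale (multi-channel) model:
        # e.g. a sharp short-range channel resolving covalent bonds plus a
        # smooth long-range channel for nonbonded structure
        channels = tuple(soap) if isinstance(soap, (tuple, list)) else (soap,)
        if mode in ("kernel", "local") and len(channels) != 1:
            raise ValueError(f"mode {mode!r} supports a single descriptor channel")
        self.soap = channels[0] if len(channels) == 1 else channels
        self.channels = channels
        self.lam = float(lam)
        self.zeta = int(zeta)
        self.h = float(h)
        self.force_method = force_method
        self.mode = mode
        self.use_forces = bool(use_forces)
        self.energy_weight = float(energy_weight)
        self.r_cut = max(c.r_cut for c in channels)
        self._calcs = tuple(SoapCalculator.get(c) for c in channels)
        self._calc = self._calcs[0]
        # kernel mode state
        self.X: np.ndarray | None = None
        self.alpha: np.ndarray | None = None
        self.shift: float = 0.0
        # linear / local mode state
        self.weights: np.ndarray | None = None
        self.n_sparse = int(n_sparse)
        if local_kernel not in ("se", "poly"):
            raise ValueError("local_kernel must be 'se' or 'poly'")
        self.local_kernel = local_kernel
        self.length_scale = length_scale  # SE kernel width; auto if None
        self.Q: np.ndarray | None = None  # (M, D) representative environments

    # -- feature rows (linear mode) ----------------------------------------

    @property
    def n_design_features(self) -> int:
        if self.mode == "local":
            if self.Q is None:
                raise RuntimeError("sparse environments not selected yet")
            return len(self.Q) + self._calc.n_species
        return sum(c.n_features for c in self._calcs) + self._calc.n_species

    # backwards-friendly alias
    n_linear_features = n_design_features

    # -- sparse environment selection (local mode) -------------------------

    @staticmethod
    def _farthest_point_sample(X: np.ndarray, m: int) -> np.ndarray:
        """Greedy k-centre selection: deterministic, starts from row 0."""
        n = len(X)
        if n <= m:
            return np.arange(n)
        chosen = [0]
        d = np.linalg.norm(X - X[0], axis=1)
        for _ in range(1, m):
            nxt = int(np.argmax(d))
            chosen.append(nxt)
            d = np.minimum(d, np.linalg.norm(X - X[nxt], axis=1))
        return np.array(chosen)

    def ensure_sparse(self, train_set: ConfigurationSet) -> None:
        """Pick the representative atomic environments once (local mode only).

        The sparse set is frozen for the lifetime of the model so that
        design rows accumulated incrementally stay consistent.
        """
        if self.mode != "local" or self.Q is not None:
            return
        envs = []
        for config in train_set:
            _, cache = self._calc.descriptor(config)
            P = cache["p_atoms"]
            if self.local_kernel == "poly":
                P = P / np.linalg.norm(P, axis=1)[:, None]
            envs.append(P)
        E = np.vstack(envs)
        self.Q = E[self._farthest_point_sample(E, self.n_sparse)]
        if self.local_kernel == "se" and self.length_scale is None:
            # median heuristic over the sparse-point pairwise distances
            d = np.linalg.norm(self.Q[:, None, :] - self.Q[None, :, :], axis=-1)
            self.length_scale = float(np.median(d[np.triu_indices_from(d, k=1)]))

    def _local_kernels(self, cache):
        """Per-atom kernel matrix k (N, M) and the adjoint weights builder.

        Returns (k, make_W) where make_W(coeff) maps per-(atom, sparse)
        coefficients (N, M) — e.g. α broadcast or row selectors — to the
        per-atom adjoint weight array (N, D) for position gradients.
        """
        P = cache["p_atoms"]
        if self.local_kernel == "se":
            theta2 = self.length_scale**2
            d2 = (
                np.sum(P**2, axis=1)[:, None]
                - 2.0 * P @ self.Q.T
                + np.sum(self.Q**2, axis=1)[None, :]
            )
            k = np.exp(-0.5 * np.maximum(d2, 0.0) / theta2)

            def make_W(coeff):
                # ∂k_im/∂p_i = -k_im (p_i − q_m)/θ²
                B = coeff * k / theta2
                return B @ self.Q - B.sum(axis=1)[:, None] * P

            return k, make_W
        norms = np.linalg.norm(P, axis=1)
        Phat = P / norms[:, None]
        d = Phat @ self.Q.T
        k = np.abs(d) ** self.zeta

        def make_W(coeff):
            pref = coeff * self.zeta * np.abs(d) ** (self.zeta - 1) * np.sign(d)
            W = pref @ self.Q - (pref * d).sum(axis=1)[:, None] * Phat
            return W / norms[:, None]

        return k, make_W

    def _composition(self, config: Configuration) -> np.ndarray:
        counts = np.zeros(self._calc.n_species)
        for s in config.species:
            counts[self._calc._spec_index[s]] += 1
        return counts

    def rows_for(self, config: Configuration):
        """(energy feature row, energy, force design block, force targets).

        The force block is None when force training is off or the
        configuration carries no force labels. Rows depend only on the
        descriptor (and, in local mode, the frozen sparse set); callers
        retraining incrementally should cache them per configuration.
        """
        want_jac = self.use_forces and config.forces is not None
        if self.mode == "local":
            _, cache = self._calc.descriptor(config, want_grad_cache=want_jac)
            return self._rows_local(config, cache, want_jac)
        phis, jacs = [], []
        for calc in self._calcs:
            _, cache = calc.descriptor(config, want_grad_cache=want_jac)
            phis.append(calc.raw_sum(cache))
            if want_jac:
                J = calc.feature_jacobian(cache)  # (F, N, 3)
                jacs.append(-J.reshape(J.shape[0], -1).T)
        x_e = np.concatenate(phis + [self._composition(config)])
        if not want_jac:
            return x_e, config.energy, None, None
        A_f = np.concatenate(
            jacs + [np.zeros((3 * config.n_atoms, self._calc.n_species))], axis=1,
        )
        return x_e, config.energy, A_f, config.forces.ravel()

    def _rows_local(self, config: Configuration, cache, want_jac: bool):
        if self.Q is None:
            raise RuntimeError("call ensure_sparse/fit before building local rows")
        k, make_W = self._local_kernels(cache)
        x_e = np.concatenate([k.sum(axis=0), self._composition(config)])
        if not want_jac:
            return x_e, config.energy, None, None
        n_atoms = config.n_atoms
        A_f = np.zeros((3 * n_atoms, len(self.Q) + self._calc.n_species))
        coeff = np.zeros_like(k)
        for m in range(len(self.Q)):
            coeff[:] = 0.0
            coeff[:, m] = 1.0
            W = make_W(coeff)
            grad = self._calc.position_gradient_peratom(cache, W)  # (N, 3)
            A_f[:, m] = -grad.ravel()
        return x_e, config.energy, A_f, config.forces.ravel()

    def add_rows(self, neq: "_NormalEquations", rows) -> None:
        """Accumulate one configuration's rows into running normal equations."""
        x_e, e, A_f, f = rows
        if e is None:
            raise ValueError("every training configuration needs a reference energy")
        neq.add(x_e, np.array([e]), weight=self.energy_weight)
        if A_f is not None:
            neq.add(A_f, f)

    def fit_neq(self, neq: "_NormalEquations") -> "SoapKrrMlp":
        """Solve accumulated normal equations (incremental retraining path)."""
        self.weights = neq.solve(self.lam)
        return self

    def fit_rows(self, rows) -> "SoapKrrMlp":
        """Train the linear model from cached feature rows."""
        neq = _NormalEquations(self.n_linear_features)
        n_energy = 0
        for row in rows:
            self.add_rows(neq, row)
            n_energy += 1
        if n_energy == 0:
            raise ValueError("empty training set")
        return self.fit_neq(neq)

    # -- training ----------------------------------------------------------

    def fit(self, train_set: ConfigurationSet, descriptors: np.ndarray | None = None) -> "SoapKrrMlp":
        """Train on a labeled configuration set (reference energies required)."""
        if len(train_set) == 0:
            raise ValueError("empty training set")
        missing = [i for i, c in enumerate(train_set) if c.energy is None]
        if missing:
            raise ValueError(f"configurations without reference energies: {missing}")
        if self.mode in ("linear", "local"):
            self.ensure_sparse(train_set)
            return self.fit_rows([self.rows_for(c) for c in train_set])
        if descriptors is None:
            descriptors = np.stack([self._calc.descriptor(c)[0] for c in train_set])
        X = np.asarray(descriptors, float)
        y = train_set.energies()
        self.shift = float(y.mean())
        K = np.abs(X @ X.T) ** self.zeta
        K[np.diag_indices_from(K)] += self.lam
        try:
            self.alpha = np.linalg.solve(K, y - self.shift)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "singular kernel system — duplicate descriptors with λ=0? "
                "increase the ridge parameter lam"
            ) from None
        self.X = X
        return self

    @property
    def trained(self) -> bool:
        if self.mode == "kernel":
            return self.alpha is not None
        return self.weights is not None

    # -- prediction --------------------------------------------------------

    def _require_trained(self):
        if not self.trained:
            raise RuntimeError("model is not trained")

    def predict_energy(self, config: Configuration) -> float:
        self._require_trained()
        if self.mode == "kernel":
            p0, _ = self._calc.descriptor(config)
            k = np.abs(self.X @ p0) ** self.zeta
            return float(k @ self.alpha + self.shift)
        if self.mode == "local":
            _, cache = self._calc.descriptor(config, want_grad_cache=False)
            k, _ = self._local_kernels(cache)
            x_e = np.concatenate([k.sum(axis=0), self._composition(config)])
        else:
            phis = []
            for calc in self._calcs:
                _, cache = calc.descriptor(config, want_grad_cache=False)
                phis.append(calc.raw_sum(cache))
            x_e = np.concatenate(phis + [self._composition(config)])
        return float(x_e @ self.weights)

    def evaluate(self, config: Configuration) -> tuple[float, np.ndarray]:
        self._require_trained()
        if self.force_method == "fd":
            return self.predict_energy(config), numerical_forces(
                _EnergyOnly(self), config, h=self.h
            )
        if self.mode == "linear":
            e = 0.0
            grad = np.zeros((config.n_atoms, 3))
            offset = 0
            for calc in self._calcs:
                _, cache = calc.descriptor(config, want_grad_cache=True)
                phi = calc.raw_sum(cache)
                w_ch = self.weights[offset : offset + calc.n_features]
                e += float(phi @ w_ch)
                grad += calc.position_gradient(cache, w_ch, normalized=False)
                offset += calc.n_features
            e += float(self._composition(config) @ self.weights[offset:])
            return e, -grad
        p0, cache = self._calc.descriptor(config, want_grad_cache=True)
        if self.mode == "local":
            k, make_W = self._local_kernels(cache)
            m_feat = len(self.Q)
            e = float(k.sum(axis=0) @ self.weights[:m_feat]
                      + self._composition(config) @ self.weights[m_feat:])
            # per-atom adjoint: W_i = Σ_m α_m ∂k_im/∂p_i
            W = make_W(np.broadcast_to(self.weights[None, :m_feat], k.shape))
            grad = self._calc.position_gradient_peratom(cache, W)
            return e, -grad
        d = self.X @ p0
        k = np.abs(d) ** self.zeta
        e = float(k @ self.alpha + self.shift)
        # ∂E/∂p0 = ζ Σ_i α_i |d_i|^{ζ-1} sign(d_i) X_i
        w = (self.zeta * self.alpha * np.abs(d) ** (self.zeta - 1) * np.sign(d)) @ self.X
        grad = self._calc.position_gradient(cache, w)
        return e, -grad

    # -- serialization -----------------------------------------------------

    def save(self, path) -> None:
        """JSON header + binary weight block (.npz)."""
        self._require_trained()
        def soap_dict(s):
            return {
                "r_cut": s.r_cut,
                "n_max": s.n_max,
                "l_max": s.l_max,
                "sigma_atom": s.sigma_atom,
                "species": list(s.species),
                "average": s.average,
                "radial_power": s.radial_power,
                "radial_width_factor": s.radial_width_factor,
            }

        header = {
            "soap_channels": [soap_dict(s) for s in self.channels],
            "soap_hash": "+".join(s.params_hash() for s in self.channels),
            "lam": self.lam,
            "zeta": self.zeta,
            "h": self.h,
            "shift": self.shift,
            "force_method": self.force_method,
            "mode": self.mode,
            "use_forces": self.use_forces,
            "energy_weight": self.energy_weight,
            "n_sparse": self.n_sparse,
            "local_kernel": self.local_kernel,
            "length_scale": self.length_scale,
        }
        blobs = {"header": np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)}
        if self.mode == "kernel":
            blobs["X"] = self.X
            blobs["alpha"] = self.alpha
        else:
            blobs["weights"] = self.weights
            if self.mode == "local":
                blobs["Q"] = self.Q
        np.savez(path, **blobs)

    @classmethod
    def load(cls, path, expected_soap: SoapParams | None = None) -> "SoapKrrMlp":
        data = np.load(path if str(path).endswith(".npz") else f"{path}.npz")
        header = json.loads(bytes(data["header"]).decode())
        channels = tuple(
            SoapParams(species=tuple(d.pop("species")), **d)
            for d in header["soap_channels"]
        )
        soap = channels if len(channels) > 1 else channels[0]
        if expected_soap is not None and expected_soap.params_hash() != header["soap_hash"]:
            raise ValueError(
                "model was trained with different SOAP parameters "
                f"(hash {header['soap_hash']} ≠ {expected_soap.params_hash()})"
            )
        model = cls(
            soap, lam=header["lam"], zeta=header["zeta"], h=header["h"],
            force_method=header["force_method"], mode=header["mode"],
            use_forces=header["use_forces"], energy_weight=header["energy_weight"],
            n_sparse=header.get("n_sparse", 120),
            local_kernel=header.get("local_kernel", "se"),
            length_scale=header.get("length_scale"),
        )
        if model.mode == "kernel":
            model.X = data["X"]
            model.alpha = data["alpha"]
            model.shift = header["shift"]
        else:
            model.weights = data["weights"]
            if model.mode == "local":
                model.Q = data["Q"]
        return model


class _EnergyOnly(Potential):
    """Wraps an MLP so numerical_forces only triggers energy evaluations."""

    label = "energy_only"

    def __init__(self, mlp: SoapKrrMlp):
        self._mlp = mlp

    def evaluate(self, config):
        return self._mlp.predict_energy(config), None


def train_krr(
    train_set: ConfigurationSet,
    soap: SoapParams,
    lam: float = 1e-8,
    zeta: int = 4,
    **kwargs,
) -> SoapKrrMlp:
    """Train the internal SOAP-KRR MLP on a reference-labeled set."""
    return SoapKrrMlp(soap, lam=lam, zeta=zeta, **kwargs).fit(train_set)


def predict(model: SoapKrrMlp, config: Configuration) -> tuple[float, np.ndarray]:
    """Predict energy and forces with a trained MLP."""
    return model.evaluate(config)


def mad_metrics(
    model: Potential,
    reference: Potential,
    eval_set: ConfigurationSet,
) -> tuple[float, float]:
    """Mean absolute deviation of energies and force components vs the reference.

    Returns (MAD_energy in kcal mol⁻¹ per configuration,
    MAD_forces in kcal mol⁻¹ Å⁻¹ per force component).
    """
    if len(eval_set) == 0:
        raise ValueError("empty evaluation set")
    de, df = [], []
    for config in eval_set:
        em, fm = model.evaluate(config)
        er, fr = reference.evaluate(config)
        de.append(abs(em - er))
        if fm is not None and fr is not None:
            df.append(np.abs(fm - fr).ravel())
    mad_e = float(np.mean(de)) * EV_TO_KCAL_PER_MOL
    mad_f = float(np.mean(np.concatenate(df))) * EV_TO_KCAL_PER_MOL if df else float("nan")
    return mad_e, mad_f
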