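"""Global SOAP descriptors and the sharpened dot-product similarity kernel.

The Smooth Overlap of Atomic Positions (SOAP) descriptor expands the
Gaussian-smeared neighbour density of every atom in radial basis functions
g_n(r) and spherical harmonics Y_lm, and collects the rotationally invariant
power spectrum p_{ss'nn'l} = Σ_m c^s_{nlm} c^{s'*}_{n'lm}. Here the per-atom
power spectra are averaged over the configuration and unit-normalized,
giving one global vector **p** per structure. Two structures are compared
with the kernel |**p**·**p**'|^ζ, where the positive integer ζ sharpens the
kernel's sensitivity to changes in atomic positions.

Implementation notes
--------------------
* The radial integrals I_nl(r_j) = 4π ∫ g_n(r) e^{-(r²+r_j²)/2σ²} i_l(r r_j/σ²) r² dr
  are evaluated with the exponentially scaled Bessel function
  ĩ_l(x) = e^{-x} i_l(x) (no overflow) on a Gauss–Legendre grid, then stored
  as cubic splines of the neighbour distance — descriptor evaluation per
  pair is a spline lookup, not a quadrature.
* A C² polynomial switching function takes the neighbour weight smoothly to
  zero at r_cut so that MLP energies built on these descriptors are smooth
  enough for energy-conserving MD.
* Gradients are provided in adjoint form: given ∂E/∂**p** the calculator
  returns ∂E/∂positions directly, which is what a kernel model needs for
  forces. A fixed internal "generic" rotation removes the spherical-polar
  coordinate singularity for bonds exactly parallel to the z axis; it is
  invisible in the descriptor values because SOAP is rotation invariant.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.special import ive, roots_legendre

from .core import Configuration
from .mathutils import smoothstep_down


@dataclass(frozen=True)
class SoapParams:
    """Hyperparameters of the SOAP descriptor.

    Defaults follow common SOAP practice for molecular systems: a 5 Å
    environment cutoff, six radial functions, l up to 4 and a 0.5 Å atomic
    Gaussian width.
    """

    r_cut: float = 5.0
    n_max: int = 6
    l_max: int = 4
    sigma_atom: float = 0.5
    species: tuple[str, ...] = ("H", "O")
    average: bool = True
    # radial-basis layout: centres at r_cut·(i/(n_max−1))^radial_power, so a
    # power > 1 concentrates resolution at bonding distances; widths are
    # radial_width_factor × the local centre spacing
    radial_power: float = 1.0
    radial_width_factor: float = 1.0

    def __post_init__(self):
        if self.r_cut <= 0:
            raise ValueError("r_cut must be positive")
        if self.n_max < 1 or self.l_max < 0:
            raise ValueError("n_max must be ≥1 and l_max ≥0")
        if not self.species:
            raise ValueError("species list must be non-empty")
        if self.radial_power <= 0 or self.radial_width_factor <= 0:
            raise ValueError("radial_power and radial_width_factor must be positive")
        object.__setattr__(self, "species", tuple(sorted(self.species)))

    def params_hash(self) -> str:
        payload = json.dumps(
            {
                "r_cut": self.r_cut,
                "n_max": self.n_max,
                "l_max": self.l_max,
                "sigma_atom": self.sigma_atom,
                "species": list(self.species),
                "average": self.average,
                "radial_power": self.radial_power,
                "radial_width_factor": self.radial_width_factor,
            },
            sort_keys=True,
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:16]


@dataclass
class DescriptorVector:
    """Unit-normalized global SOAP vector of one configuration."""

    values: np.ndarray
    source: Configuration | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        n = np.linalg.norm(self.values)
        if not np.isfinite(n) or abs(n - 1.0) > 1e-10:
            raise ValueError(f"descriptor vector must be unit-normalized (norm={n})")

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.values))

    def __len__(self) -> int:
        return len(self.values)


# fixed generic rotation (about an irrational axis by an irrational angle):
# keeps axis-aligned bonds away from the spherical-polar poles.
def _generic_rotation() -> np.ndarray:
    axis = np.array([1.0, np.sqrt(2.0), np.sqrt(3.0)])
    axis /= np.linalg.norm(axis)
    angle = 0.5 * (np.sqrt(5.0) - 1.0)  # ≈ 0.618 rad
    kx, ky, kz = axis
    K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


_R0 = _generic_rotation()


def _scaled_spherical_in(l: int, x: np.ndarray) -> np.ndarray:
    """e^{-x} i_l(x), stable for large x; correct x→0 limit (δ_{l0})."""
    x = np.maximum(x, 1e-10)
    return np.sqrt(np.pi / (2.0 * x)) * ive(l + 0.5, x)


class SoapCalculator:
    """Evaluates global SOAP descriptors (and adjoint gradients) for one parameter set."""

    _cache: dict = {}

    def __init__(self, params: SoapParams):
        self.params = params
        self.n_species = len(params.species)
        self._spec_index = {s: i for i, s in enumerate(params.species)}
        l_max, n_max = params.l_max, params.n_max
        # (l, m≥0) channel bookkeeping
        self.l_of_lm = np.concatenate(
            [np.full(l + 1, l, dtype=int) for l in range(l_max + 1)]
        )
        self.m_of_lm = np.concatenate(
            [np.arange(l + 1, dtype=int) for l in range(l_max + 1)]
        )
        self.n_lm = len(self.l_of_lm)
        # m-degeneracy weight in the power-spectrum sum: 1 for m=0, 2 for m>0
        self.w_lm = np.where(self.m_of_lm == 0, 1.0, 2.0)
        self._build_radial_splines()
        self.n_channels = self.n_species * n_max  # combined (species, n) index
        self.n_features = self.n_channels**2 * (l_max + 1)

    @classmethod
    def get(cls, params: SoapParams) -> "SoapCalculator":
        key = params.params_hash()
        if key not in cls._cache:
            cls._cache[key] = cls(params)
        return cls._cache[key]

    # -- radial machinery --------------------------------------------------

    def _build_radial_splines(self) -> None:
        p = self.params
        sigma2 = p.sigma_atom**2
        n_max, l_max = p.n_max, p.l_max
        # Gaussian radial basis; centres follow a power grid in [0, r_cut]
        if n_max > 1:
            centres = p.r_cut * (np.arange(n_max) / (n_max - 1)) ** p.radial_power
            spacing = np.gradient(centres)
            widths = p.radial_width_factor * spacing
        else:
            centres = np.array([0.0])
            widths = np.array([p.r_cut / 2.0])
        # quadrature over the density support
        xq, wq = roots_legendre(160)
        r_hi = p.r_cut + 4.0 * p.sigma_atom
        rq = 0.5 * r_hi * (xq + 1.0)
        wq = 0.5 * r_hi * wq
        g = np.exp(-0.5 * ((rq[None, :] - centres[:, None]) / widths[:, None]) ** 2)  # (n, Q)

        grid = np.linspace(0.0, p.r_cut, 420)
        # I[j, n, l] for neighbour distance grid[j]
        I = np.empty((len(grid), n_max, l_max + 1))
        for l in range(l_max + 1):
            x = np.outer(grid, rq) / sigma2  # (G, Q)
            il = _scaled_spherical_in(l, x)
            gauss = np.exp(-0.5 * (rq[None, :] - grid[:, None]) ** 2 / sigma2)
            kernel_q = il * gauss * rq[None, :] ** 2 * wq[None, :]  # (G, Q)
            I[:, :, l] = 4.0 * np.pi * kernel_q @ g.T
        # fold in the cutoff switching function
        s, _ = smoothstep_down(grid, p.r_cut - 1.0, p.r_cut)
        I *= s[:, None, None]
        flat = I.reshape(len(grid), -1)
        self._rad_spline = CubicSpline(grid, flat, axis=0)
        self._rad_spline_d = self._rad_spline.derivative()
        self._rad_at_zero = flat[0].reshape(n_max, l_max + 1)

    def _radial(self, r: np.ndarray, want_grad: bool = False):
        p = self.params
        R = self._rad_spline(r).reshape(len(r), p.n_max, p.l_max + 1)
        if not want_grad:
            return R, None
        dR = self._rad_spline_d(r).reshape(len(r), p.n_max, p.l_max + 1)
        return R, dR

    # -- neighbour list ----------------------------------------------------

    def _pairs(self, config: Configuration):
        """Directed pairs (i ← j) within r_cut, minimum images expanded under PBC."""
        p = self.params
        pos = config.positions @ _R0.T
        if config.periodic:
            box = np.diag(config.cell)
            if not np.allclose(config.cell, np.diag(box)):
                raise ValueError("periodic SOAP supports orthorhombic cells only")
            reps = np.ceil(p.r_cut / box).astype(int)
            shifts = np.array(
                [
                    [a, b, c]
                    for a in range(-reps[0], reps[0] + 1)
                    for b in range(-reps[1], reps[1] + 1)
                    for c in range(-reps[2], reps[2] + 1)
                ],
                dtype=float,
            ) * box
            # rotate lattice shifts into the internal frame
            shifts = shifts @ _R0.T
        else:
            shifts = np.zeros((1, 3))
        i_list, j_list, v_list = [], [], []
        for shift in shifts:
            d = pos[None, :, :] + shift - pos[:, None, :]
            r2 = np.einsum("ijk,ijk->ij", d, d)
            mask = (r2 < p.r_cut**2) & (r2 > 1e-16)
            ii, jj = np.nonzero(mask)
            i_list.append(ii)
            j_list.append(jj)
            v_list.append(d[ii, jj])
        return np.concatenate(i_list), np.concatenate(j_list), np.concatenate(v_list)

    # -- angular machinery -------------------------------------------------

    def _angular(self, ct: np.ndarray, st: np.ndarray, want_grad: bool):
        """Fully normalized associated Legendre tables by stable recursion.

        Returns (P̃_lm, dP̃_lm/dθ, P̃_lm/sinθ) for m ≥ 0, each (n_pairs, n_lm).
        The last two are None unless gradients are requested; all three are
        pole-safe (the m ≥ 1 columns of P̃/sinθ follow their own recursion and
        never divide by sinθ).
        """
        l_max = self.params.l_max
        n_pairs = len(ct)
        M = self.n_lm
        Pt = np.zeros((n_pairs, M))
        dPt = np.zeros((n_pairs, M)) if want_grad else None
        Qt = np.zeros((n_pairs, M)) if want_grad else None

        def k_of(l, m):
            return l * (l + 1) // 2 + m

        pmm = np.full(n_pairs, np.sqrt(1.0 / (4.0 * np.pi)))
        dpmm = np.zeros(n_pairs)
        qmm = np.zeros(n_pairs)
        pmm_prev = pmm
        for m in range(l_max + 1):
            if m > 0:
                f = -np.sqrt((2 * m + 1) / (2.0 * m))
                qmm = f * pmm_prev  # P̃_mm / sinθ, smooth for m ≥ 1
            Pt[:, k_of(m, m)] = pmm
            if want_grad:
                dPt[:, k_of(m, m)] = dpmm
                if m > 0:
                    Qt[:, k_of(m, m)] = qmm
            if m + 1 <= l_max:
                f1 = np.sqrt(2.0 * m + 3.0)
                pl1, pl2 = f1 * ct * pmm, pmm
                Pt[:, k_of(m + 1, m)] = pl1
                if want_grad:
                    dpl1, dpl2 = f1 * (-st * pmm + ct * dpmm), dpmm
                    ql1, ql2 = f1 * ct * qmm, qmm
                    dPt[:, k_of(m + 1, m)] = dpl1
                    Qt[:, k_of(m + 1, m)] = ql1
                for l in range(m + 2, l_max + 1):
                    a = np.sqrt((4.0 * l * l - 1.0) / (l * l - m * m))
                    b = np.sqrt(((l - 1) ** 2 - m * m) / (4.0 * (l - 1) ** 2 - 1.0))
                    pl = a * (ct * pl1 - b * pl2)
                    Pt[:, k_of(l, m)] = pl
                    if want_grad:
                        dpl = a * (-st * pl1 + ct * dpl1 - b * dpl2)
                        ql = a * (ct * ql1 - b * ql2)
                        dPt[:, k_of(l, m)] = dpl
                        Qt[:, k_of(l, m)] = ql
                        dpl2, dpl1 = dpl1, dpl
                        ql2, ql1 = ql1, ql
                    pl2, pl1 = pl1, pl
            pmm_prev = pmm
            f = -np.sqrt((2 * (m + 1) + 1) / (2.0 * (m + 1)))
            dpmm = f * (ct * pmm + st * dpmm)
            pmm = f * st * pmm
        return Pt, dPt, Qt

    # -- forward -----------------------------------------------------------

    def descriptor(self, config: Configuration, want_grad_cache: bool = False):
        """Global normalized power-spectrum vector; optionally a gradient cache."""
        p = self.params
        for s in set(config.species):
            if s not in self._spec_index:
                raise ValueError(
                    f"element {s!r} not covered by SoapParams.species {p.species}"
                )
        n_atoms = config.n_atoms
        S, n_max, l_max = self.n_species, p.n_max, p.l_max
        M = self.n_lm
        A = self.n_channels

        i_idx, j_idx, vec = self._pairs(config)
        n_pairs = len(i_idx)
        r = np.linalg.norm(vec, axis=1)
        R, dR = self._radial(r, want_grad=want_grad_cache)
        ct = np.clip(vec[:, 2] / r, -1.0, 1.0)
        st = np.maximum(np.sqrt(1.0 - ct * ct), 1e-12)
        eiphi = (vec[:, 0] + 1j * vec[:, 1]) / (r * st)
        Pt, dPt, Qt = self._angular(ct, st, want_grad_cache)
        # e^{imφ} powers, mapped onto the (l, m) channel layout
        ph = np.empty((n_pairs, l_max + 1), dtype=complex)
        ph[:, 0] = 1.0
        for m in range(1, l_max + 1):
            ph[:, m] = ph[:, m - 1] * eiphi
        ph_lm = ph[:, self.m_of_lm]
        Yc = Pt * np.conj(ph_lm)  # conj(Y_lm) per pair

        spec_of = np.array([self._spec_index[s] for s in config.species])
        target = i_idx * S + spec_of[j_idx]  # combined (atom, species) row

        # c[i, s, n, lm] = Σ_pairs R_{nl} · conj(Y_lm)  (bincount scatter)
        R_lm = R[:, :, self.l_of_lm]  # (P, n_max, M)
        contrib = R_lm * Yc[:, None, :]
        block = n_max * M
        flat_len = n_atoms * S * block
        if n_pairs:
            idx2 = (target * block)[:, None] + np.arange(block)[None, :]
            c = np.bincount(
                idx2.ravel(), weights=contrib.real.reshape(n_pairs, -1).ravel(),
                minlength=flat_len,
            ).astype(complex)
            c += 1j * np.bincount(
                idx2.ravel(), weights=contrib.imag.reshape(n_pairs, -1).ravel(),
                minlength=flat_len,
            )
        else:
            c = np.zeros(flat_len, dtype=complex)
        c = c.reshape(n_atoms, S, n_max, M)
        # self-density of the central atom: isotropic, l=0 only
        y00 = 1.0 / np.sqrt(4.0 * np.pi)
        c[np.arange(n_atoms), spec_of, :, 0] += self._rad_at_zero[:, 0] * y00

        cc = c.reshape(n_atoms, A, M)
        cw = cc * self.w_lm[None, None, :]
        # per-atom power spectra, l-resolved (batched matmul over m)
        p_atoms = np.empty((n_atoms, A, A, l_max + 1))
        for l in range(l_max + 1):
            sel = self.l_of_lm == l
            p_atoms[..., l] = np.matmul(
                cw[:, :, sel], np.conj(cc[:, :, sel]).transpose(0, 2, 1)
            ).real
        p_atoms = p_atoms.reshape(n_atoms, -1)
        P_raw = p_atoms.mean(axis=0)
        norm = np.linalg.norm(P_raw)
        if norm < 1e-300:
            raise ValueError("zero descriptor (empty environment)")
        p0 = P_raw / norm

        if not want_grad_cache:
            return p0, {"p0": p0, "norm": norm, "n_atoms": n_atoms,
                        "p_atoms": p_atoms}
        cache = {
            "p_atoms": p_atoms,
            "i_idx": i_idx,
            "j_idx": j_idx,
            "vec": vec,
            "r": r,
            "ct": ct,
            "st": st,
            "eiphi": eiphi,
            "R_lm": R_lm,
            "dR_lm": dR[:, :, self.l_of_lm],
            "Yc": Yc,
            "dYc": dPt * np.conj(ph_lm),
            # conj(i m Y / sinθ): the azimuthal gradient factor, pole-safe
            "mYs_c": -1j * self.m_of_lm[None, :] * Qt * np.conj(ph_lm),
            "cc": cc,
            "spec_of": spec_of,
            "p0": p0,
            "norm": norm,
            "n_atoms": n_atoms,
        }
        return p0, cache

    # -- adjoint gradient --------------------------------------------------

    def raw_sum(self, cache: dict) -> np.ndarray:
        """Summed (extensive, unnormalized) power spectrum from a forward cache."""
        return cache["p0"] * (cache["norm"] * cache["n_atoms"])

    def position_gradient(self, cache: dict, w: np.ndarray, normalized: bool = True) -> np.ndarray:
        """∂(w·p)/∂positions for the configuration behind ``cache``.

        With ``normalized=True`` (default) ``p`` is the unit-normalized
        atom-averaged descriptor (the chain rule through the normalization
        and the average is applied here); with ``normalized=False`` ``p`` is
        the raw summed power spectrum — the feature vector of the linear
        energy model.
        """
        p = self.params
        A, l_max, M = self.n_channels, p.l_max, self.n_lm
        n_atoms = cache["n_atoms"]
        p0, norm = cache["p0"], cache["norm"]
        w = np.asarray(w, dtype=float).ravel()
        if normalized:
            # through unit normalization: P_raw → p0
            w_P = (w - np.dot(w, p0) * p0) / norm
            scale = 1.0 / n_atoms
        else:
            w_P = w
            scale = 1.0
        W = w_P.reshape(A, A, l_max + 1)
        W_sym = 0.5 * (W + W.transpose(1, 0, 2)) * scale
        cc = cache["cc"]
        # G[i, b, lm] = ∂E/∂conj(c)[i, b, lm] = 2 w_m Σ_a W_sym[a,b,l] c[i,a,lm]
        G = np.empty_like(cc)
        for l in range(l_max + 1):
            sel = self.l_of_lm == l
            G[:, :, sel] = np.matmul(2.0 * W_sym[:, :, l][None, :, :], cc[:, :, sel])
        G *= self.w_lm[None, None, :]

        return self._pair_contract(cache, G)

    def _pair_contract(self, cache: dict, G: np.ndarray) -> np.ndarray:
        """Contract an adjoint G = ∂E/∂conj(c) with the per-pair derivatives."""
        p = self.params
        M = self.n_lm
        n_atoms = cache["n_atoms"]
        i_idx, j_idx = cache["i_idx"], cache["j_idx"]
        r, vec = cache["r"], cache["vec"]
        Yc, dYc, mYs_c = cache["Yc"], cache["dYc"], cache["mYs_c"]
        R_lm, dR_lm = cache["R_lm"], cache["dR_lm"]
        spec_of = cache["spec_of"]
        n_max = p.n_max

        # gather the adjoint for each pair's target channel block (s_j fixed)
        Gpc = np.conj(G.reshape(n_atoms, self.n_species, n_max, M)[i_idx, spec_of[j_idx]])
        # radial and angular contractions, m-resolved then paired with Y tables
        V = np.einsum("pnm,pnm->pm", Gpc, dR_lm)
        U = np.einsum("pnm,pnm->pm", Gpc, R_lm)
        a_r = np.einsum("pm,pm->p", V, Yc).real
        a_t = np.einsum("pm,pm->p", U, dYc).real / r
        a_p = np.einsum("pm,pm->p", U, mYs_c).real / r

        ct, st, eiphi = cache["ct"], cache["st"], cache["eiphi"]
        cos_p, sin_p = eiphi.real, eiphi.imag
        rhat = vec / r[:, None]
        that = np.stack([ct * cos_p, ct * sin_p, -st], axis=1)
        phat = np.stack([-sin_p, cos_p, np.zeros_like(sin_p)], axis=1)
        dpair = a_r[:, None] * rhat + a_t[:, None] * that + a_p[:, None] * phat

        grad = np.empty((n_atoms, 3))
        for d in range(3):
            grad[:, d] = np.bincount(j_idx, weights=dpair[:, d], minlength=n_atoms)
            grad[:, d] -= np.bincount(i_idx, weights=dpair[:, d], minlength=n_atoms)
        # rotate back out of the internal generic frame
        return grad @ _R0


    def position_gradient_peratom(self, cache: dict, W: np.ndarray) -> np.ndarray:
        """∂(Σ_i W_i·p_i)/∂positions with a separate weight vector per atom.

        ``W`` is (n_atoms, n_features) in the space of *raw per-atom* power
        spectra p_i — the adjoint a local (per-environment) energy model
        needs for forces. Returns (n_atoms, 3).
        """
        p = self.params
        A, l_max, M = self.n_channels, p.l_max, self.n_lm
        n_atoms = cache["n_atoms"]
        W = np.asarray(W, float).reshape(n_atoms, A, A, l_max + 1)
        W_sym = 0.5 * (W + W.transpose(0, 2, 1, 3))
        cc = cache["cc"]
        G = np.empty_like(cc)
        for l in range(l_max + 1):
            sel = self.l_of_lm == l
            G[:, :, sel] = np.einsum("iab,iam->ibm", 2.0 * W_sym[..., l], cc[:, :, sel])
        G *= self.w_lm[None, None, :]
        return self._pair_contract(cache, G)

    def feature_jacobian(self, cache: dict) -> np.ndarray:
        """Analytic Jacobian of the summed power spectrum w.r.t. positions.

        Returns (n_features, n_atoms, 3). Used to build force rows when the
        linear energy model is trained on forces; computed once per training
        configuration and cached by the caller.
        """
        p = self.params
        A, n_max, l_max, M = self.n_channels, p.n_max, p.l_max, self.n_lm
        S = self.n_species
        n_atoms = cache["n_atoms"]
        L = l_max + 1
        i_idx, j_idx = cache["i_idx"], cache["j_idx"]
        n_pairs = len(i_idx)
        J = np.zeros((A, A, L, n_atoms, 3))
        if n_pairs:
            r, vec = cache["r"], cache["vec"]
            ct, st, eiphi = cache["ct"], cache["st"], cache["eiphi"]
            cos_p, sin_p = eiphi.real, eiphi.imag
            rhat = vec / r[:, None]
            that = np.stack([ct * cos_p, ct * sin_p, -st], axis=1)
            phat = np.stack([-sin_p, cos_p, np.zeros_like(sin_p)], axis=1)
            Yc, dYc, mYs_c = cache["Yc"], cache["dYc"], cache["mYs_c"]
            R_lm, dR_lm = cache["R_lm"], cache["dR_lm"]
            # per-pair derivative of the c-contribution w.r.t. x_j: (P, n, M, 3);
            # angular terms carry the 1/r factor of ∇ on the unit sphere
            ang = (
                dYc[:, :, None] * that[:, None, :] + mYs_c[:, :, None] * phat[:, None, :]
            ) / r[:, None, None]
            Tp = (
                dR_lm[:, :, :, None] * (Yc[:, :, None] * rhat[:, None, :])[:, None, :, :]
                + R_lm[:, :, :, None] * ang[:, None, :, :]
            )
            cpair = cache["cc"][i_idx]  # (P, A, M)
            CW = self.w_lm[None, None, :] * np.conj(cpair)
            # M1[p, a, n, l, d] = Σ_{m∈l} Re(CW[p,a,m] Tp[p,n,m,d])
            M1 = np.empty((n_pairs, A, n_max, L, 3))
            for l in range(L):
                sel = self.l_of_lm == l
                M1[:, :, :, l, :] = np.einsum(
                    "pam,pnmd->pand", CW[:, :, sel], Tp[:, :, sel, :]
                ).real
            spec_j = cache["spec_of"][j_idx]
            for s in range(S):
                mask = spec_j == s
                if not np.any(mask):
                    continue
                Ms = M1[mask]
                acc = np.zeros((n_atoms, A, n_max, L, 3))
                np.add.at(acc, j_idx[mask], Ms)
                np.add.at(acc, i_idx[mask], -Ms)
                block = np.moveaxis(acc, 0, 3)  # (A, n_max, L, n_atoms, 3)
                cols = slice(s * n_max, (s + 1) * n_max)
                J[:, cols] += block
                J[cols, :] += block.transpose(1, 0, 2, 3, 4)
            # rotate back out of the internal generic frame
            J = J @ _R0
        return J.reshape(self.n_features, n_atoms, 3)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def compute_soap(config: Configuration, params: SoapParams) -> DescriptorVector:
    """Global SOAP descriptor of a configuration: averaged, unit-normalized.

    Deterministic and invariant to rigid translation/rotation and to atom
    reordering within a species.
    """
    calc = SoapCalculator.get(params)
    values, _ = calc.descriptor(config)
    return DescriptorVector(values=values, source=config)


def _vals(p) -> np.ndarray:
    return p.values if isinstance(p, DescriptorVector) else np.asarray(p, float).ravel()


def kernel(p: "DescriptorVector | np.ndarray", q, zeta: int) -> float:
    """Similarity kernel |p·q|^ζ between two unit-normalized descriptors."""
    if zeta < 1 or int(zeta) != zeta:
        raise ValueError("zeta must be a positive integer")
    pv, qv = _vals(p), _vals(q)
    if pv.shape != qv.shape:
        raise ValueError(f"descriptor length mismatch: {pv.shape} vs {qv.shape}")
    return float(np.abs(np.dot(pv, qv)) ** zeta)


def similarity_vector(p0, training: Sequence, zeta: int) -> np.ndarray:
    """Kernel similarities of a new structure against every training member.

    The selector cannot run before initial data exists, so an empty training
    set is an error.
    """
    if len(training) == 0:
        raise ValueError("similarity vector undefined for an empty training set")
    p0v = _vals(p0)
    X = np.stack([_vals(t) for t in training])
    if X.shape[1] != p0v.shape[0]:
        raise ValueError("descriptor length mismatch between candidate and training set")
    return np.abs(X @ p0v) ** zeta


# ---------------------------------------------------------------------------
# descriptor-matrix caching
# ---------------------------------------------------------------------------

def save_descriptor_matrix(path, params: SoapParams, matrix: np.ndarray) -> None:
    """Cache a descriptor matrix keyed by a hash of the SOAP parameters."""
    np.savez(path, matrix=np.asarray(matrix), params_hash=params.params_hash())


def load_descriptor_matrix(path, params: SoapParams) -> np.ndarray:
    """Load a cached descriptor matrix, refusing a mismatched parameter hash."""
    data = np.load(path if str(path).endswith(".npz") else f"{path}.npz", allow_pickle=False)
    stored = str(data["params_hash"])
    if stored != params.params_hash():
        raise ValueError(
            f"descriptor cache was built with different SOAP parameters "
            f"(hash {stored} ≠ {params.params_hash()})"
        )
    return data["matrix"]
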