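"""Reaction classification, scans, umbrella sampling/WHAM, RDF and hydrogen bonds."""

import numpy as np
import pytest

from mlal.core import Configuration
from mlal.dynamics import MDParams
from mlal.potentials import DoubleWellDimerPotential, HarmonicDimerPotential
from mlal.reaction import (
    HBCriterion,
    ReactionCoordinate,
    UmbrellaWindow,
    classify_state,
    classify_trajectory,
    count_hbs_by_distance,
    find_hbonds,
    prepare_rs_pool,
    rdf,
    reconstruct_fes,
    relaxed_scan_2d,
    run_umbrella,
)
from mlal.systems import make_reactive_dimer, make_water_molecule
from mlal.units import EV_TO_KCAL_PER_MOL, KB


class TestClassifyState:
    @pytest.mark.parametrize(
        "r1, r2, state",
        [
            (1.5, 1.55, "product"),
            (3.2, 3.5, "reactant"),
            (1.5, 2.5, "ongoing"),
            (1.7, 1.5, "ongoing"),
            (2.9, 3.5, "ongoing"),
        ],
    )
    def test_thresholds(self, r1, r2, state):
        assert classify_state(r1, r2) == state

    def test_invalid_distances(self):
        with pytest.raises(ValueError):
            classify_state(-1.0, 2.0)


class TestTrajectoryClassification:
    def test_synthetic_product_trajectory_time_gap(self):
        # r1 crosses 1.6 Å at 100 fs, r2 at 150 fs → Δt = 50 fs, concerted
        times = np.arange(0.0, 400.0, 0.5)
        r1 = np.where(times < 100.0, 2.5, 1.4)
        r2 = np.where(times < 150.0, 2.5, 1.4)
        outcome = classify_trajectory(times, r1, r2)
        assert outcome.terminal == "product"
        assert outcome.t_r1 == pytest.approx(100.0)
        assert outcome.t_r2 == pytest.approx(150.0)
        assert outcome.time_gap == pytest.approx(50.0)
        assert outcome.concerted is True

    def test_stepwise_gap_above_criterion(self):
        times = np.arange(0.0, 600.0, 0.5)
        r1 = np.where(times < 50.0, 2.5, 1.4)
        r2 = np.where(times < 200.0, 2.5, 1.4)
        outcome = classify_trajectory(times, r1, r2)
        assert outcome.time_gap == pytest.approx(150.0)
        assert outcome.concerted is False

    def test_reactant_and_timeout(self):
        times = np.arange(0.0, 100.0, 0.5)
        far = np.full_like(times, 3.5)
        assert classify_trajectory(times, far, far).terminal == "reactant"
        mid = np.full_like(times, 2.2)
        out = classify_trajectory(times, mid, mid)
        assert out.terminal == "timeout"
        assert out.time_gap is None

    def test_gap_symmetric_under_pair_relabelling(self):
        times = np.arange(0.0, 400.0, 0.5)
        r1 = np.where(times < 100.0, 2.5, 1.4)
        r2 = np.where(times < 150.0, 2.5, 1.4)
        a = classify_trajectory(times, r1, r2)
        b = classify_trajectory(times, r2, r1)
        assert a.time_gap == b.time_gap
        assert a.terminal == b.terminal


class TestReactionCoordinate:
    def test_xi_and_delta_r(self):
        config = make_reactive_dimer(2.0, 3.0)
        rc = ReactionCoordinate(pair1=(0, 2), pair2=(1, 3))
        assert rc.r1(config) == pytest.approx(2.0)
        assert rc.r2(config) == pytest.approx(3.0)
        assert rc.xi(config) == pytest.approx(2.5)
        assert rc.delta_r(config) == pytest.approx(1.0)


class TestRelaxedScan:
    def test_grid_matches_analytic_constrained_surface(self, reactive_pot):
        rc = ReactionCoordinate(pair1=(0, 2), pair2=(1, 3))
        start = make_reactive_dimer(2.4, 2.4)
        r_grid = np.linspace(1.7, 3.0, 4)
        scan = relaxed_scan_2d(reactive_pot, start, rc, r_grid, r_grid,
                               restraint_k=2000.0, f_tol=1e-4)
        for i, r1 in enumerate(r_grid):
            for j, r2 in enumerate(r_grid):
                assert scan.energies[i, j] == pytest.approx(
                    reactive_pot.constrained_energy(r1, r2), abs=0.01
                )

    def test_single_point_grid_is_plain_restrained_minimum(self, reactive_pot):
        rc = ReactionCoordinate(pair1=(0, 2), pair2=(1, 3))
        start = make_reactive_dimer(2.2, 2.2)
        scan = relaxed_scan_2d(reactive_pot, start, rc, [2.2], [2.2], restraint_k=200.0)
        assert scan.energies.shape == (1, 1)
        assert scan.energies[0, 0] == pytest.approx(
            reactive_pot.constrained_energy(2.2, 2.2), abs=0.01
        )

    def test_reversed_grid_gives_same_surface(self, reactive_pot):
        rc = ReactionCoordinate(pair1=(0, 2), pair2=(1, 3))
        start = make_reactive_dimer(2.4, 2.4)
        grid = np.linspace(1.8, 2.9, 3)
        a = relaxed_scan_2d(reactive_pot, start, rc, grid, grid, restraint_k=200.0)
        b = relaxed_scan_2d(reactive_pot, start, rc, grid[::-1], grid[::-1],
                            restraint_k=200.0)
        np.testing.assert_allclose(a.energies, b.energies[::-1, ::-1], atol=0.02)

    def test_non_monotone_grid_rejected(self, reactive_pot):
        rc = ReactionCoordinate(pair1=(0, 2), pair2=(1, 3))
        with pytest.raises(ValueError, match="monotone"):
            relaxed_scan_2d(reactive_pot, make_reactive_dimer(), rc, [2.0, 1.5, 2.5], [2.0])


class TestUmbrella:
    def test_single_stiff_window_variance_matches_gaussian_closed_form(self):
        # harmonic distance potential + stiff harmonic bias → Gaussian ξ with
        # variance k_BT/(k_bias + κ)
        kappa, k_bias, T = 2.0, 20.0, 300.0
        pot = HarmonicDimerPotential(k=kappa, r0=2.0)
        rc = ReactionCoordinate(pair1=(0, 1), pair2=(0, 1))
        start = Configuration(species=["O", "O"], positions=[[0, 0, 0], [2.0, 0, 0]])
        md = MDParams(dt=0.5, temperature=T, ensemble="NVT", friction=0.05,
                      duration=8000.0, rng_seed=13)
        windows = run_umbrella(pot, rc, [(2.0, k_bias)], md, start, steer_time_fs=50.0)
        var = np.var(windows[0].xi_series)
        expected = KB * T / (k_bias + kappa)
        assert var == pytest.approx(expected, rel=0.25)

    def test_disjoint_windows_raise_overlap_error(self):
        w1 = UmbrellaWindow(center=1.0, k=10.0, xi_series=np.random.default_rng(0).normal(1.0, 0.01, 500), temperature=300.0)
        w2 = UmbrellaWindow(center=3.0, k=10.0, xi_series=np.random.default_rng(1).normal(3.0, 0.01, 500), temperature=300.0)
        from mlal.reaction import _check_overlap

        with pytest.raises(ValueError, match="overlap"):
            _check_overlap([w1, w2])


class TestWham:
    def test_flat_potential_gives_flat_profile(self):
        rng = np.random.default_rng(3)
        # unbiased uniform sampling of ξ on [0, 1] — the free energy is flat
        window = UmbrellaWindow(center=0.5, k=0.0, xi_series=rng.uniform(0, 1, 200000),
                                temperature=300.0)
        result = reconstruct_fes([window], n_bins=20)
        assert np.nanmax(result.free_energy) < 0.5 * KB * 300.0 * EV_TO_KCAL_PER_MOL

    def test_two_gaussian_windows_recover_harmonic_well(self):
        # two overlapping biased windows on a harmonic ξ-potential: WHAM must
        # reproduce the analytic quadratic profile
        rng = np.random.default_rng(4)
        kappa, T = 4.0, 300.0
        beta = 1.0 / (KB * T)
        windows = []
        for center, k in [(0.0, 4.0), (0.25, 4.0)]:
            # biased distribution is Gaussian around the compromise position
            keff = kappa + k
            mean = k * center / keff
            xi = rng.normal(mean, np.sqrt(1 / (beta * keff)), 400000)
            windows.append(UmbrellaWindow(center=center, k=k, xi_series=xi, temperature=T))
        result = reconstruct_fes(windows, n_bins=60)
        # compare shapes on the well-sampled region; the overall offset is
        # arbitrary in a free-energy profile
        mask = (result.xi > -0.1) & (result.xi < 0.35)
        expected = 0.5 * kappa * result.xi[mask] ** 2 * EV_TO_KCAL_PER_MOL
        diff = result.free_energy[mask] - expected
        assert np.ptp(diff) < 0.3  # kcal/mol


class TestRsPool:
    def test_restraint_centres_validated(self, reactive_pot):
        rc = ReactionCoordinate(pair1=(0, 2), pair2=(1, 3))
        md = MDParams(dt=0.5, temperature=300.0, duration=10.0, rng_seed=0)
        with pytest.raises(ValueError, match="\\[3.0, 5.0\\]"):
            prepare_rs_pool(make_reactive_dimer(), reactive_pot, rc, md,
                            restraint_centers=(2.0, 3.5))


class TestRdf:
    def test_two_atoms_single_populated_bin(self):
        config = Configuration(
            species=["O", "O"], positions=[[0, 0, 0], [3.0, 0, 0]],
            cell=np.eye(3) * 10.0, periodic=True,
        )
        result = rdf([config], ("O", "O"), r_max=5.0, n_bins=50)
        populated = np.nonzero(result.g > 0)[0]
        assert len(populated) == 1
        assert result.r[populated[0]] == pytest.approx(3.0, abs=0.1)

    def test_ideal_gas_is_uniform(self):
        rng = np.random.default_rng(5)
        L = 20.0
        frames = [
            Configuration(species=["Ar"] * 400, positions=rng.uniform(0, L, (400, 3)),
                          cell=np.eye(3) * L, periodic=True)
            for _ in range(8)
        ]
        result = rdf(frames, ("Ar", "Ar"), r_max=8.0, n_bins=40)
        assert np.nanmean(result.g[5:]) == pytest.approx(1.0, abs=0.05)

    def test_simple_cubic_crystal_coordination_number(self):
        a, n_side = 3.0, 4
        positions = np.array(
            [[i, j, k] for i in range(n_side) for j in range(n_side) for k in range(n_side)],
            float,
        ) * a
        config = Configuration(species=["O"] * len(positions), positions=positions,
                               cell=np.eye(3) * (n_side * a), periodic=True)
        result = rdf([config], ("O", "O"), r_max=a * 1.3, n_bins=60)
        # first shell of a simple cubic lattice: exactly 6 neighbours
        assert result.coordination[-1] == pytest.approx(6.0, abs=1e-9)

    def test_r_max_beyond_half_box_rejected(self):
        config = Configuration(species=["O"], positions=np.zeros((1, 3)),
                               cell=np.eye(3) * 8.0, periodic=True)
        with pytest.raises(ValueError, match="half"):
            rdf([config], ("O", "O"), r_max=5.0)

    def test_nonperiodic_frames_rejected(self, water_molecule):
        with pytest.raises(ValueError, match="periodic"):
            rdf([water_molecule], ("O", "O"), r_max=3.0)


class TestHydrogenBonds:
    def test_isolated_water_has_none(self, water_molecule):
        assert find_hbonds(water_molecule, HBCriterion()) == []

    def test_ideal_dimer_has_exactly_one(self):
        # donor O-H pointing straight at the acceptor O, 2.9 Å O-O
        donor = make_water_molecule()
        acceptor = make_water_molecule()
        # rotate donor so one O-H points along +x, then place acceptor O there
        d_oh = donor.positions[1] - donor.positions[0]
        d_oh /= np.linalg.norm(d_oh)
        shift = donor.positions[0] + d_oh * 2.9
        acc_pos = acceptor.positions - acceptor.positions[0] + shift
        config = Configuration(
            species=donor.species + acceptor.species,
            positions=np.vstack([donor.positions, acc_pos]),
        )
        bonds = find_hbonds(config, HBCriterion())
        assert len(bonds) == 1
        od, h, oa = bonds[0]
        assert (od, oa) == (0, 3)

    def test_participation_counts_by_shell(self):
        donor = make_water_molecule()
        d_oh = donor.positions[1] - donor.positions[0]
        d_oh /= np.linalg.norm(d_oh)
        shift = donor.positions[0] + d_oh * 2.9
        acceptor = make_water_molecule()
        acc_pos = acceptor.positions - acceptor.positions[0] + shift
        config = Configuration(
            species=donor.species + acceptor.species,
            positions=np.vstack([donor.positions, acc_pos]),
        )
        centers, mean = count_hbs_by_distance(
            [config], HBCriterion(), solute_atoms=[], shell_edges=[0.0, 5.0, 10.0],
        )
        # both molecules participate in the single hydrogen bond
        assert mean[0] == pytest.approx(1.0)
        assert np.isnan(mean[1])


class TestDoubleWellOracle:
    def test_distance_energy_profile_shape(self):
        pot = DoubleWellDimerPotential()
        r = np.linspace(1.2, 2.8, 200)
        U = pot.distance_energy(r)
        assert U[0] > U.min() and U[-1] > U.min()
        mid = pot.distance_energy(pot.r_m)
        assert mid > pot.distance_energy(pot.r_m - pot.b)
        assert mid > pot.distance_energy(pot.r_m + pot.b)
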