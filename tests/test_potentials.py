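"""Analytic reference potentials and the trainable SOAP MLP."""

import numpy as np
import pytest

from mlal.core import Configuration, ConfigurationSet
from mlal.descriptors import SoapParams
from mlal.potentials import (
    HarmonicDimerPotential,
    Potential,
    ReferenceFailure,
    SoapKrrMlp,
    mad_metrics,
    numerical_forces,
    predict,
    train_krr,
)
from mlal.systems import make_reactive_dimer, solvate_reactive_dimer
from mlal.units import EV_TO_KCAL_PER_MOL


class TestToyWater:
    def test_equilibrium_monomer_is_stationary(self, water_pot, water_molecule):
        e, f = water_pot.evaluate(water_molecule)
        assert e == pytest.approx(0.0, abs=1e-12)
        assert np.abs(f).max() < 1e-8

    def test_rigid_translation_invariance(self, water_pot, raw_cluster8):
        e1, _ = water_pot.evaluate(raw_cluster8)
        moved = raw_cluster8.copy()
        moved.positions = moved.positions + np.array([3.0, -2.0, 7.0])
        e2, _ = water_pot.evaluate(moved)
        assert e1 == pytest.approx(e2, abs=1e-10)

    def test_rigid_rotation_invariance(self, water_pot, raw_cluster8):
        ang = 0.9
        R = np.array(
            [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]]
        )
        e1, _ = water_pot.evaluate(raw_cluster8)
        rotated = raw_cluster8.copy()
        rotated.positions = rotated.positions @ R.T
        e2, _ = water_pot.evaluate(rotated)
        assert e1 == pytest.approx(e2, abs=1e-10)

    def test_unsupported_species_rejected(self, water_pot):
        bad = Configuration(species=["C", "H", "H"], positions=np.eye(3))
        with pytest.raises(ValueError, match="C"):
            water_pot.evaluate(bad)

    def test_label_refuses_dissociated_structures(self, water_pot, water_molecule):
        broken = water_molecule.copy()
        broken.positions[1] += np.array([5.0, 0.0, 0.0])
        with pytest.raises(ReferenceFailure, match="validity"):
            water_pot.label_config(broken)


class TestForceConsistency:
    """Forces must be the exact negative gradient of the energy."""

    def test_toy_water_cluster(self, water_pot, raw_cluster8):
        _, f = water_pot.evaluate(raw_cluster8)
        fn = numerical_forces(water_pot, raw_cluster8, h=1e-4)
        np.testing.assert_allclose(f, fn, atol=1e-6)
        assert np.abs(f.sum(axis=0)).max() < 1e-8  # no net force

    def test_reactive_dimer(self, reactive_pot):
        config = make_reactive_dimer(2.6, 3.1)
        _, f = reactive_pot.evaluate(config)
        fn = numerical_forces(reactive_pot, config, h=1e-4)
        np.testing.assert_allclose(f, fn, atol=1e-6)
        assert np.abs(f.sum(axis=0)).max() < 1e-8

    def test_solvated_reactive_system(self, reactive_pot):
        config = solvate_reactive_dimer(make_reactive_dimer(2.8, 2.8), n_waters=6, rng_seed=1)
        _, f = reactive_pot.evaluate(config)
        fn = numerical_forces(reactive_pot, config, h=1e-4)
        np.testing.assert_allclose(f, fn, atol=1e-6)


class TestTwoBondReactive:
    def test_double_well_has_two_minima(self, reactive_pot):
        rp, rr = reactive_pot.product_minimum(), reactive_pot.reactant_minimum()
        assert rp < reactive_pot.r_m < rr
        mid = reactive_pot.double_well(reactive_pot.r_m)
        assert reactive_pot.double_well(rp) < mid
        assert reactive_pot.double_well(rr) < mid
        # positive tilt makes the product the deeper well (exothermic)
        assert reactive_pot.double_well(rp) < reactive_pot.double_well(rr)

    def test_constrained_scan_matches_analytic_sections(self, reactive_pot):
        # with fragment bonds at rest length the constrained energy is the
        # sum of the double wells plus the coupling term, exactly
        for r1, r2 in [(1.5, 1.5), (2.0, 3.0), (3.2, 3.2)]:
            expected = (
                reactive_pot.double_well(r1)
                + reactive_pot.double_well(r2)
                + reactive_pot.coupling * (r1 - r2) ** 2
            )
            assert reactive_pot.constrained_energy(r1, r2) == pytest.approx(expected)

    def test_evaluate_at_rest_geometry_matches_constrained_energy(self, reactive_pot):
        config = make_reactive_dimer(2.5, 2.9, bond=reactive_pot.r0_bond)
        e, _ = reactive_pot.evaluate(config)
        assert e == pytest.approx(reactive_pot.constrained_energy(2.5, 2.9), abs=1e-8)


class TestSoapKrrKernelMode:
    """The dual-kernel regressor on normalized global descriptors."""

    def _labeled(self, water_pot, configs):
        return ConfigurationSet([water_pot.label_config(c) for c in configs])

    def test_single_point_interpolation(self, water_pot, soap_small, water_molecule):
        train = self._labeled(water_pot, [water_molecule])
        model = train_krr(train, soap_small, lam=1e-10, zeta=4, mode="kernel",
                          use_forces=False)
        e, _ = predict(model, water_molecule)
        assert e == pytest.approx(train[0].energy, abs=1e-6)

    def test_duplicate_rows_stay_finite_with_ridge(self, water_pot, soap_small, water_molecule):
        train = self._labeled(water_pot, [water_molecule, water_molecule.copy()])
        model = train_krr(train, soap_small, lam=1e-6, zeta=4, mode="kernel",
                          use_forces=False)
        assert np.all(np.isfinite(model.alpha))

    def test_missing_energies_listed(self, soap_small, water_molecule):
        train = ConfigurationSet([water_molecule])
        with pytest.raises(ValueError, match="without reference energies"):
            SoapKrrMlp(soap_small, mode="kernel").fit(train)

    def test_untrained_model_refuses_prediction(self, soap_small, water_molecule):
        model = SoapKrrMlp(soap_small, mode="kernel")
        with pytest.raises(RuntimeError, match="not trained"):
            model.predict_energy(water_molecule)


class TestSoapKrrLinearMode:
    """The force-trained linear model used inside the AL loop."""

    @pytest.fixture(scope="class")
    def model(self, water_pot, thermal_frames8):
        soap = SoapParams(r_cut=6.0, sigma_atom=0.3, n_max=6, l_max=3)
        return SoapKrrMlp(soap, lam=1e-11).fit(thermal_frames8)

    def test_training_set_well_reproduced(self, model, water_pot, thermal_frames8):
        errors = [
            abs(model.predict_energy(c) - c.energy) for c in thermal_frames8
        ]
        assert np.mean(errors) * EV_TO_KCAL_PER_MOL < 1.0

    def test_translation_invariant_prediction(self, model, thermal_frames8):
        config = thermal_frames8[0]
        moved = config.copy()
        moved.positions = moved.positions + 4.2
        assert model.predict_energy(moved) == pytest.approx(
            model.predict_energy(config), abs=1e-8
        )

    def test_permutation_invariant_prediction(self, model, thermal_frames8):
        config = thermal_frames8[0]
        perm = list(range(config.n_atoms))
        perm[1], perm[2] = perm[2], perm[1]  # swap two hydrogens of one water
        swapped = Configuration(
            species=[config.species[i] for i in perm], positions=config.positions[perm]
        )
        assert model.predict_energy(swapped) == pytest.approx(
            model.predict_energy(config), abs=1e-8
        )

    def test_analytic_forces_match_fd_oracle(self, model, thermal_frames8):
        config = thermal_frames8[0].stripped()
        _, f_analytic = model.evaluate(config)
        model_fd = SoapKrrMlp(model.soap, lam=model.lam, force_method="fd", h=1e-3)
        model_fd.weights = model.weights
        _, f_fd = model_fd.evaluate(config)
        np.testing.assert_allclose(f_analytic, f_fd, atol=1e-4)

    def test_fd_error_shrinks_quadratically(self, model, thermal_frames8):
        # central differences converge O(h²) toward the analytic forces
        config = thermal_frames8[1].stripped()
        _, f_exact = model.evaluate(config)
        errs = []
        for h in (4e-3, 2e-3):
            fd = SoapKrrMlp(model.soap, lam=model.lam, force_method="fd", h=h)
            fd.weights = model.weights
            _, f_h = fd.evaluate(config)
            errs.append(np.abs(f_h - f_exact).max())
        assert errs[1] < errs[0]

    def test_serialization_round_trip(self, model, thermal_frames8, tmp_path):
        path = tmp_path / "model.npz"
        model.save(path)
        back = SoapKrrMlp.load(path)
        config = thermal_frames8[2].stripped()
        assert back.predict_energy(config) == pytest.approx(
            model.predict_energy(config), abs=1e-12
        )
        with pytest.raises(ValueError, match="different SOAP"):
            SoapKrrMlp.load(path, expected_soap=SoapParams(r_cut=4.5))


class TestLearningCurve:
    def test_more_data_reduces_heldout_error(self, water_pot, thermal_frames8, cluster8):
        """Held-out energy error decreases (on average) with training size."""
        from mlal.dynamics import MDParams, run_md

        soap = SoapParams(r_cut=6.0, sigma_atom=0.3, n_max=6, l_max=3)
        traj = run_md(
            cluster8, water_pot,
            MDParams(dt=0.5, temperature=300.0, duration=150.0, rng_seed=77, stride=15),
        )
        held = ConfigurationSet([f.stripped() for f in traj.frames[1:]])
        mads = []
        for size in (3, len(thermal_frames8)):
            model = SoapKrrMlp(soap, lam=1e-11).fit(thermal_frames8[:size])
            mad_e, _ = mad_metrics(model, water_pot, held)
            mads.append(mad_e)
        assert mads[-1] < mads[0]


class TestMadMetrics:
    def test_identity_model_scores_zero(self, water_pot, thermal_frames8):
        mad_e, mad_f = mad_metrics(water_pot, water_pot, thermal_frames8[:3])
        assert mad_e == 0.0
        assert mad_f == 0.0

    def test_constant_energy_offset(self, water_pot, thermal_frames8):
        class Offset(Potential):
            label = "offset"

            def evaluate(self, config):
                e, f = water_pot.evaluate(config)
                return e + 1.0 / EV_TO_KCAL_PER_MOL, f

        mad_e, mad_f = mad_metrics(Offset(), water_pot, thermal_frames8[:3])
        assert mad_e == pytest.approx(1.0, rel=1e-9)
        assert mad_f == 0.0

    def test_matches_hand_rolled_means(self, water_pot, thermal_frames8):
        eval_set = thermal_frames8[:3]

        class Skewed(Potential):
            label = "skewed"

            def evaluate(self, config):
                e, f = water_pot.evaluate(config)
                return e + 0.01 * config.n_atoms, f + 0.002

        de = [0.01 * c.n_atoms for c in eval_set]
        mad_e, mad_f = mad_metrics(Skewed(), water_pot, eval_set)
        assert mad_e == pytest.approx(np.mean(de) * EV_TO_KCAL_PER_MOL, rel=1e-9)
        assert mad_f == pytest.approx(0.002 * EV_TO_KCAL_PER_MOL, rel=1e-9)

    def test_empty_set_rejected(self, water_pot):
        with pytest.raises(ValueError, match="empty"):
            mad_metrics(water_pot, water_pot, ConfigurationSet([]))


def test_harmonic_dimer_closed_form():
    pot = HarmonicDimerPotential(k=3.0, r0=1.2)
    config = Configuration(species=["O", "O"], positions=[[0, 0, 0], [1.5, 0, 0]])
    e, f = pot.evaluate(config)
    assert e == pytest.approx(0.5 * 3.0 * 0.3**2)
    np.testing.assert_allclose(f, numerical_forces(pot, config), atol=1e-7)


class TestLocalAndMultiChannelModes:
    def test_local_mode_forces_match_fd(self, water_pot, thermal_frames8):
        soap = SoapParams(r_cut=4.5, sigma_atom=0.3, n_max=4, l_max=2)
        model = SoapKrrMlp(soap, lam=1e-10, mode="local", n_sparse=25)
        model.fit(thermal_frames8[:6])
        config = thermal_frames8[6].stripped()
        _, f = model.evaluate(config)
        fd = numerical_forces(_EnergyOnlyWrapper(model), config, h=1e-3)
        np.testing.assert_allclose(f, fd, atol=1e-4)

    def test_local_rows_consistent_with_prediction(self, water_pot, thermal_frames8):
        soap = SoapParams(r_cut=4.5, sigma_atom=0.3, n_max=4, l_max=2)
        model = SoapKrrMlp(soap, lam=1e-10, mode="local", n_sparse=20)
        model.fit(thermal_frames8[:5])
        config = thermal_frames8[0]
        _, _, A_f, _ = model.rows_for(config)
        f_rows = (A_f @ model.weights).reshape(-1, 3)
        _, f_pred = model.evaluate(config.stripped())
        np.testing.assert_allclose(f_rows, f_pred, atol=1e-10)

    def test_two_channel_linear_model(self, water_pot, thermal_frames8):
        channels = (
            SoapParams(r_cut=2.3, sigma_atom=0.15, n_max=4, l_max=2),
            SoapParams(r_cut=5.0, sigma_atom=0.4, n_max=4, l_max=2),
        )
        model = SoapKrrMlp(channels, lam=1e-11, mode="linear")
        model.fit(thermal_frames8[:8])
        config = thermal_frames8[8].stripped()
        e1 = model.predict_energy(config)
        e2, f = model.evaluate(config)
        assert e1 == pytest.approx(e2, abs=1e-10)
        fd = numerical_forces(_EnergyOnlyWrapper(model), config, h=1e-3)
        np.testing.assert_allclose(f, fd, atol=1e-4)

    def test_channel_serialization_round_trip(self, water_pot, thermal_frames8, tmp_path):
        channels = (
            SoapParams(r_cut=2.3, sigma_atom=0.15, n_max=3, l_max=2),
            SoapParams(r_cut=5.0, sigma_atom=0.4, n_max=3, l_max=2),
        )
        model = SoapKrrMlp(channels, lam=1e-11).fit(thermal_frames8[:5])
        model.save(tmp_path / "m.npz")
        back = SoapKrrMlp.load(tmp_path / "m.npz")
        c = thermal_frames8[5].stripped()
        assert back.predict_energy(c) == pytest.approx(model.predict_energy(c), abs=1e-12)


class _EnergyOnlyWrapper(Potential):
    label = "energy_only_wrapper"

    def __init__(self, model):
        self._model = model

    def evaluate(self, config):
        return self._model.predict_energy(config), None
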