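"""Soft-core scaling, λ-gradients, ABF accumulation and cycle assembly."""

import numpy as np
import pytest

from lambdabf.alchemical import (AbfAccumulator, FreeEnergyProfile,
                                 IncompleteSamplingError, LambdaState,
                                 SoftcoreParams, assemble_abfe,
                                 integrate_profile, lambda_gradient,
                                 run_lambda_abf, scaled_nonbonded_energy)
from lambdabf.systems import (LangevinSettings, ParticleSystem,
                              potential_energy)
from lambdabf.units import COULOMB


def ideal_gas_ligand():
    """A ligand bead with no charges and no LJ next to a frozen host."""
    return ParticleSystem(
        positions=np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]]),
        masses=np.array([20.0, 20.0]),
        charges=np.zeros(2),
        lj_epsilon=np.zeros(2),
        lj_sigma=np.full(2, 3.0),
        roles=np.asarray(["host", "ligand"], dtype=object),
        frozen=np.array([True, False]),
    )


class TestSoftcoreEnergy:
    def test_fully_coupled_endpoint_identity(self, two_particle):
        system, _ = two_particle
        e = scaled_nonbonded_energy(system, 1.0, 1.0)
        assert e == pytest.approx(potential_energy(system), abs=1e-12)

    def test_fully_decoupled_endpoint(self, host_guest):
        system, _ = host_guest
        e = scaled_nonbonded_energy(system, 0.0, 0.0)
        # nonbonded energy with the ligand-environment terms deleted:
        # environment alone plus the ligand alone
        from lambdabf.systems import (ligand_only_system,
                                      nonbonded_energy_forces)
        idx = np.where(~system.ligand)[0]
        remap = {int(o): n for n, o in enumerate(idx)}
        env_excl = {frozenset((remap[i], remap[j]))
                    for pair in system.exclusions
                    for i, j in [tuple(pair)]
                    if i in remap and j in remap}
        env_only = ParticleSystem(
            positions=system.positions[idx], masses=system.masses[idx],
            charges=system.charges[idx], lj_epsilon=system.lj_epsilon[idx],
            lj_sigma=system.lj_sigma[idx], roles=system.roles[idx],
            exclusions=env_excl, dielectric=system.dielectric)
        lig_only = ligand_only_system(system)
        expected = (nonbonded_energy_forces(env_only)[0]
                    + nonbonded_energy_forces(lig_only)[0])
        assert e == pytest.approx(expected, rel=1e-12)

    def test_finite_at_particle_overlap(self, two_particle):
        system, _ = two_particle
        pos = system.positions.copy()
        pos[1] = pos[0]                       # exact overlap
        e = scaled_nonbonded_energy(system, 0.5, 0.0, positions=pos)
        assert np.isfinite(e)

    def test_lambda_outside_unit_interval_rejected(self, two_particle):
        system, _ = two_particle
        with pytest.raises(ValueError):
            scaled_nonbonded_energy(system, 1.2, 0.0)
        with pytest.raises(ValueError):
            scaled_nonbonded_energy(system, 0.0, -0.1)


class TestLambdaGradient:
    @pytest.mark.parametrize("leg,lambdas", [
        ("ELE", (1.0, 0.35)), ("ELE", (1.0, 0.9)),
        ("VDW", (0.35, 0.0)), ("VDW", (0.75, 0.0)),
    ])
    def test_matches_finite_difference(self, two_particle, leg, lambdas):
        system, _ = two_particle
        rng = np.random.default_rng(7)
        lv, le = lambdas
        h = 1e-5
        for _ in range(3):
            pos = system.positions.copy()
            pos[1] += rng.normal(0, 0.6, 3)
            if leg == "ELE":
                fd = (scaled_nonbonded_energy(system, lv, le + h,
                                              positions=pos)
                      - scaled_nonbonded_energy(system, lv, le - h,
                                                positions=pos)) / (2 * h)
            else:
                fd = (scaled_nonbonded_energy(system, lv + h, le,
                                              positions=pos)
                      - scaled_nonbonded_energy(system, lv - h, le,
                                                positions=pos)) / (2 * h)
            grad = lambda_gradient(system, lv, le, leg, positions=pos)
            assert grad == pytest.approx(fd, rel=1e-4)

    def test_zero_for_ideal_gas_ligand(self):
        system = ideal_gas_ligand()
        for lam in (0.0, 0.3, 1.0):
            assert lambda_gradient(system, 1.0, lam, "ELE") == 0.0
            assert lambda_gradient(system, lam, 0.0, "VDW") == 0.0

    def test_ele_gradient_at_full_coupling_is_coulomb_energy(
            self, two_particle):
        system, _ = two_particle
        grad = lambda_gradient(system, 1.0, 1.0, "ELE")
        r = np.linalg.norm(system.positions[1] - system.positions[0])
        coulomb = (COULOMB / system.dielectric
                   * system.charges[0] * system.charges[1] / r)
        assert grad == pytest.approx(coulomb, rel=1e-12)

    def test_invalid_leg_rejected(self, two_particle):
        system, _ = two_particle
        with pytest.raises(ValueError):
            lambda_gradient(system, 1.0, 1.0, "BOTH")


class TestSoftcoreParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            SoftcoreParams(alpha=-0.1)
        with pytest.raises(ValueError):
            SoftcoreParams(vdw_power=0)


class TestIntegrateProfile:
    def _profile(self, mean_force, direction="couple"):
        n = len(mean_force)
        return FreeEnergyProfile(
            lambda_centers=(np.arange(n) + 0.5) / n,
            mean_force=np.asarray(mean_force, dtype=float),
            counts=np.ones(n), n_walkers=1, leg="VDW", phase="complex",
            temperature=300.0, direction=direction)

    def test_constant_mean_force(self):
        g = 2.7
        assert integrate_profile(self._profile([g] * 50)) == pytest.approx(g)

    def test_linear_mean_force_integrates_to_half_slope(self):
        a = 4.0
        centers = (np.arange(100) + 0.5) / 100
        prof = self._profile(a * centers)
        assert integrate_profile(prof) == pytest.approx(a / 2, abs=a / 200)

    def test_direction_flips_sign_exactly(self):
        mf = np.random.default_rng(1).normal(0, 1, 40)
        up = integrate_profile(self._profile(mf))
        down = integrate_profile(self._profile(mf, direction="decouple"))
        assert up == -down

    def test_unvisited_bins_raise_with_bin_list(self):
        prof = self._profile([1.0] * 10)
        prof.counts[3] = 0
        with pytest.raises(IncompleteSamplingError, match="3"):
            integrate_profile(prof)

    def test_free_energy_starts_at_zero(self):
        prof = self._profile([1.0] * 10)
        assert prof.free_energy[0] == pytest.approx(0.05)  # A at first center
        # extrapolating half a bin back recovers A(0) = 0
        assert prof.free_energy[0] - prof.mean_force[0] * 0.05 == 0.0


class TestRunLambdaAbf:
    def test_null_decoupling_for_ideal_gas_ligand(self):
        system = ideal_gas_ligand()
        abf = AbfAccumulator(n_bins=20, n_full=100)
        st = LangevinSettings(temperature=300.0, friction=5.0, timestep=2.0,
                              n_steps=15000, seed=1, save_stride=10)
        prof = run_lambda_abf(system, "VDW", 2, st, abf)
        assert integrate_profile(prof) == pytest.approx(0.0, abs=0.05)

    def test_walker_count_invariance_at_fixed_total_steps(self, two_particle):
        from lambdabf.systems import FlatBottomDistanceRestraint
        system, _ = two_particle
        fb = FlatBottomDistanceRestraint(1, system.positions[0], r0=5.0,
                                         k=10.0)
        results = []
        for n_walkers, steps in ((2, 30000), (4, 15000)):
            abf = AbfAccumulator(n_bins=40, n_full=200)
            st = LangevinSettings(temperature=300.0, friction=5.0,
                                  timestep=2.0, n_steps=steps, seed=5,
                                  save_stride=10)
            prof = run_lambda_abf(system, "ELE", n_walkers, st, abf,
                                  restraints=[fb])
            results.append(integrate_profile(prof))
        assert results[0] == pytest.approx(results[1], abs=0.15)

    def test_profile_roundtrip_through_columnar_file(self, tmp_path):
        system = ideal_gas_ligand()
        abf = AbfAccumulator(n_bins=10, n_full=50)
        st = LangevinSettings(n_steps=3000, friction=5.0, timestep=2.0,
                              seed=2, save_stride=10)
        prof = run_lambda_abf(system, "ELE", 1, st, abf)
        path = tmp_path / "profile.txt"
        prof.write_columns(path)
        back = FreeEnergyProfile.read_columns(path)
        assert back.leg == "ELE" and back.direction == "decouple"
        assert np.allclose(back.mean_force, prof.mean_force)
        assert integrate_profile(back) == pytest.approx(
            integrate_profile(prof))


class TestAssemble:
    def test_zero_components_zero_total(self):
        res = assemble_abfe({"ELE": 0.0, "VDW": 0.0},
                            {"ELE": 0.0, "VDW": 0.0}, 0.0, 0.0)
        assert res.delta_g_raw == 0.0

    def test_components_sum_to_total_exactly(self):
        res = assemble_abfe({"ELE": 13.5, "VDW": -0.5},
                            {"ELE": 0.2, "VDW": 0.1},
                            dbc_release=2.6, standard_state=5.3)
        assert res.audit_sum() == res.delta_g_raw
        assert res.delta_g_raw == pytest.approx(
            (0.2 + 0.1) - (13.5 - 0.5) - 2.6 + 5.3)

    def test_mixed_temperatures_rejected(self):
        with pytest.raises(ValueError):
            assemble_abfe({"ELE": 0.0}, {"ELE": 0.0}, 0.0, 0.0,
                          temperature=300.0,
                          leg_temperatures={"complex_ELE": 310.0})

    def test_replica_statistics_via_affinity_module(self):
        from lambdabf.affinity import replica_stats
        mean, sem = replica_stats([-16.9, -17.1, -17.3])
        assert mean == pytest.approx(-17.1)
        assert sem == pytest.approx(0.2 / np.sqrt(3), abs=1e-6)


class TestRestraintTransparency:
    def test_light_positional_restraints_leave_bound_state_unchanged(
            self, host_guest):
        # k = 1 kcal/mol/Å² tethers on ion beads must not perturb the
        # fully-coupled bound-state DBC distribution (KS test)
        from scipy.stats import ks_2samp

        from lambdabf.restraints import DbcDefinition, DbcRestraint
        from lambdabf.systems import PositionalRestraint, run_langevin
        system, ref = host_guest
        dbc = DbcDefinition.from_system(system, ref, r0=10.0, k=0.0)
        restraint = DbcRestraint(dbc)
        ions = np.where(system.mask("ion"))[0]
        samples = {}
        # independent replicas (one final-frame sample each), so the KS
        # test sees uncorrelated draws from the bound-state distribution
        for label, atts in (("free", []),
                            ("tethered", [PositionalRestraint(
                                ions, ref[ions], k=1.0)])):
            vals = []
            for rep in range(30):
                st = LangevinSettings(temperature=300.0, friction=5.0,
                                      timestep=1.5, n_steps=4000,
                                      seed=1000 + rep, save_stride=4000)
                traj = run_langevin(system, st, attachments=atts)
                vals.append(restraint.value(traj.positions[-1]))
            samples[label] = np.asarray(vals)
        stat = ks_2samp(samples["free"], samples["tethered"])
        assert stat.pvalue > 0.01
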