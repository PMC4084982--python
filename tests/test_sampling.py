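import numpy as np
import pytest

from ribofit import units
from ribofit.density import EMFitParams
from ribofit.sampling import (COMHarmonic, FlatBottomDistance, HarmonicBond,
                              PositionalHarmonic, RMSDRestraint, SimState,
                              SoftRepulsion, ToyPotential, WindowProtocol,
                              adapt_w_em, minimize, remove_rigid_motion,
                              run_dynamics, run_window, thermal_velocities,
                              total_energy_forces)


def dimer(separation=2.4, k=5.0, r0=2.0):
    pot = ToyPotential(bonds=[HarmonicBond(0, 1, k, r0)])
    coords = np.array([[0.0, 0.0, 0.0], [separation, 0.0, 0.0]])
    masses = np.array([12.0, 12.0])
    return pot, coords, masses


def numerical_forces(coords, potential, restraints=(), h=1e-6):
    out = np.zeros_like(coords)
    for i in range(coords.shape[0]):
        for a in range(3):
            cp = coords.copy()
            cp[i, a] += h
            cm = coords.copy()
            cm[i, a] -= h
            ep, _ = total_energy_forces(cp, potential, restraints)
            em, _ = total_energy_forces(cm, potential, restraints)
            out[i, a] = -(ep - em) / (2 * h)
    return out


class TestPotentialTerms:
    @pytest.mark.parametrize("potential,coords", [
        (ToyPotential(bonds=[HarmonicBond(0, 1, 5.0, 2.0)]),
         np.array([[0.0, 0, 0], [2.7, 0.4, -0.2]])),
        (ToyPotential(repulsions=[SoftRepulsion(0, 1, 0.5, 2.5)]),
         np.array([[0.0, 0, 0], [2.1, 0.3, 0.1]])),
    ])
    def test_forces_match_numerical_gradient(self, potential, coords):
        _, f = potential.energy_forces(coords)
        fn = numerical_forces(coords, potential)
        assert np.allclose(f, fn, rtol=1e-6, atol=1e-7)

    @pytest.mark.parametrize("restraint", [
        COMHarmonic([0, 1], np.array([12.0, 24.0]), [0.3, -0.2, 0.5], 1.0,
                    "k_dr2"),
        COMHarmonic([0, 1], np.array([12.0, 24.0]), [0.3, -0.2, 0.5], 1.44,
                    "half_k_dr2"),
        PositionalHarmonic([0, 2], np.array([[0.1, 0, 0], [1, 1, 1]]), 2.0),
        FlatBottomDistance(0, 2, 1.2, 3.0, tol=0.1),
        RMSDRestraint([0, 1, 2], np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]]),
                      2.0, limit=0.5),
    ])
    def test_restraint_forces_match_numerical_gradient(self, restraint):
        rng = np.random.default_rng(3)
        coords = rng.normal(0, 1.5, size=(3, 3))
        _, f = restraint.energy_forces(coords)
        fn = numerical_forces(coords, ToyPotential(), (restraint,))
        assert np.allclose(f, fn, rtol=1e-5, atol=1e-6)


class TestRestraintDeadZones:
    def test_flat_bottom_zero_inside_tolerance(self):
        r = FlatBottomDistance(0, 1, 2.0, 10.0, tol=0.1)
        for d in (1.905, 2.0, 2.095):
            e, f = r.energy_forces(np.array([[0.0, 0, 0], [d, 0, 0]]))
            assert e == 0.0
            assert np.all(f == 0.0)
        e, _ = r.energy_forces(np.array([[0.0, 0, 0], [2.2, 0, 0]]))
        assert e > 0

    def test_rmsd_cap_zero_below_limit(self):
        ref = np.zeros((4, 3))
        r = RMSDRestraint([0, 1, 2, 3], ref, 5.0, limit=1.0)
        coords = np.full((4, 3), 0.5)  # rmsd ~0.87 < 1
        e, f = r.energy_forces(coords)
        assert e == 0.0 and np.all(f == 0.0)
        coords = np.full((4, 3), 0.7)  # rmsd ~1.21 > 1
        e, _ = r.energy_forces(coords)
        assert e > 0


class TestLangevin:
    def test_energy_conservation_in_symplectic_limit(self):
        pot, coords, masses = dimer()
        st = SimState(coords, np.zeros((2, 3)))
        rng = np.random.default_rng(0)
        energies = []
        x = st
        for _ in range(10):
            x = run_dynamics(x, masses, pot, (), 1000, 0.0005, 300.0, 0.0,
                             rng)
            epot, _ = total_energy_forces(x.coords, pot, ())
            ekin = (0.5 * (masses[:, None] * x.velocities ** 2).sum()
                    / units.FORCE_TO_AMU_A_PS2)
            energies.append(epot + ekin)
        energies = np.array(energies)
        drift = (energies.max() - energies.min()) / abs(energies.mean())
        assert drift < 1e-4

    def test_equipartition_in_com_harmonic(self):
        # V = k |dr|^2 with k = 1 -> per-axis variance kT / (2k)
        masses = np.array([12.0])
        pot = ToyPotential()
        restraint = COMHarmonic([0], masses, np.zeros(3), 1.0, "k_dr2")
        st = SimState(np.zeros((1, 3)),
                      thermal_velocities(masses, 300.0,
                                         np.random.default_rng(1)))
        xs = []

        def cb(step, x, v):
            if step % 5 == 0:
                xs.append(x[0].copy())

        run_dynamics(st, masses, pot, (restraint,), 60000, 0.01, 300.0, 5.0,
                     np.random.default_rng(2), callback=cb)
        var = np.array(xs).var(axis=0)
        expected = units.thermal_energy(300.0) / 2.0
        assert np.allclose(var, expected, rtol=0.05)

    def test_same_seed_reproduces_trajectory(self):
        pot, coords, masses = dimer()
        out = []
        for _ in range(2):
            st = SimState(coords.copy(), np.zeros((2, 3)))
            x = run_dynamics(st, masses, pot, (), 200, 0.005, 300.0, 5.0,
                             np.random.default_rng(77))
            out.append(x.coords)
        assert np.array_equal(out[0], out[1])

    def test_rigid_drift_removal_keeps_frame(self):
        pot, coords, masses = dimer()
        ref = coords.copy()
        st = SimState(coords.copy(),
                      thermal_velocities(masses, 300.0,
                                         np.random.default_rng(0)))
        x = run_dynamics(st, masses, pot, (), 2000, 0.005, 300.0, 5.0,
                         np.random.default_rng(1), rigid_reference=ref,
                         rigid_stride=10)
        com_drift = np.linalg.norm(
            (masses[:, None] * (x.coords - ref)).sum(0) / masses.sum())
        assert com_drift < 0.5

    def test_remove_rigid_motion_restores_reference_frame(self):
        rng = np.random.default_rng(5)
        ref = rng.normal(size=(10, 3))
        from scipy.spatial.transform import Rotation
        R = Rotation.from_euler("z", 17, degrees=True).as_matrix()
        moved = ref @ R.T + np.array([2.0, -1.0, 3.0])
        vel = rng.normal(size=(10, 3))
        back, _ = remove_rigid_motion(moved, vel, ref, np.ones(10))
        assert np.allclose(back, ref, atol=1e-8)


class TestMinimize:
    def test_stretched_dimer_relaxes_to_rest_length(self):
        pot, coords, masses = dimer(separation=3.5)
        x, e, converged = minimize(coords, pot, max_steps=2000)
        assert np.linalg.norm(x[1] - x[0]) == pytest.approx(2.0, abs=1e-4)

    def test_energy_non_increasing(self):
        pot, coords, _ = dimer(separation=3.5)
        energies = []
        x = coords
        for _ in range(10):
            x, e, _ = minimize(x, pot, max_steps=5)
            energies.append(e)
        assert np.all(np.diff(energies) <= 1e-12)

    def test_terminates_at_tolerance_or_max_steps(self):
        pot, coords, _ = dimer(separation=2.001)
        x, e, converged = minimize(coords, pot, max_steps=5000, gtol=1e-6)
        _, f = total_energy_forces(x, pot, ())
        assert converged and np.abs(f).max() < 1e-6


class TestAdaptWEm:
    def test_shift_above_cap_halves(self):
        assert adapt_w_em(0.7, 4e-5, cap=0.6) == pytest.approx(2e-5)

    def test_small_shift_doubles_with_clip(self):
        assert adapt_w_em(0.1, 8e-5, cap=0.6) == pytest.approx(1e-4)
        assert adapt_w_em(0.1, 1e-4, cap=0.6) == pytest.approx(1e-4)

    def test_mid_band_unchanged(self):
        assert adapt_w_em(0.45, 5e-5, cap=0.6) == pytest.approx(5e-5)


@pytest.fixture(scope="module")
def window_setup():
    from ribofit import synthetic
    spec = synthetic.ToyRibosomeSpec(n_large=40, n_small=28, n_head=14,
                                     n_trna=6, seed=5)
    toy = synthetic.make_toy_ribosome(spec)
    maps = synthetic.make_state_maps(toy.endpoints, resolution=10.0,
                                     spacing=2.0)
    groups = {n: g for n, g in toy.umbrella_groups.items()
              if not n.startswith("tRNA")}
    return toy, maps, groups


class TestRunWindow:
    protocol = WindowProtocol(em_steps=60, equil_steps=60, sample_steps=400,
                              dt=0.01, friction=2.0, em_friction=15.0,
                              sample_stride=3, w_em_bounds=(0.01, 1.0),
                              max_retries=6)

    def run_windows(self, toy, maps, groups, n, w_em, seed=0):
        rng = np.random.default_rng(seed)
        st = SimState(toy.model.coords.copy(),
                      thermal_velocities(toy.model.masses, 300.0, rng))
        recs = []
        for wi in range(n):
            rec = run_window(toy.model, st, toy.potential, groups,
                             maps["PRE"], EMFitParams(10.0, 4, w_em),
                             self.protocol, rng, index=wi)
            st = rec.restart_state
            recs.append(rec)
        return recs

    def test_neighboring_windows_overlap(self, window_setup):
        toy, maps, groups = window_setup
        recs = self.run_windows(toy, maps, groups, 3, w_em=0.2)
        assert len(recs) == 3
        for a, b in zip(recs, recs[1:]):
            # per-group histogram overlap along each group's center shift
            overlaps = []
            for g in range(a.bias_centers.shape[0]):
                d = b.bias_centers[g] - a.bias_centers[g]
                u = d / max(np.linalg.norm(d), 1e-12)
                xa = a.samples[:, g, :] @ u
                xb = b.samples[:, g, :] @ u
                lo, hi = min(xa.min(), xb.min()), max(xa.max(), xb.max())
                bins = np.linspace(lo, hi + 1e-12, 21)
                ha, _ = np.histogram(xa, bins=bins)
                hb, _ = np.histogram(xb, bins=bins)
                overlaps.append(np.minimum(ha / len(xa),
                                           hb / len(xb)).sum())
            assert np.mean(overlaps) > 0.05

    def test_zero_weight_leaves_centers_stationary(self, window_setup):
        toy, maps, groups = window_setup
        recs = self.run_windows(toy, maps, groups, 2, w_em=0.0, seed=4)
        shift = np.linalg.norm(recs[1].bias_centers - recs[0].bias_centers,
                               axis=1)
        # no driving force: only thermal diffusion of the group COMs over
        # one unrestrained fitting phase (~3 sigma bound)
        assert shift.max() < 1.5

    def test_displacement_cap_honored(self, window_setup):
        toy, maps, groups = window_setup
        recs = self.run_windows(toy, maps, groups, 3, w_em=0.5, seed=11)
        for rec in recs:
            assert rec.fitting_shift.max() <= self.protocol.displacement_cap

    def test_bias_energies_recomputable_from_samples(self, window_setup):
        toy, maps, groups = window_setup
        rec = self.run_windows(toy, maps, groups, 1, w_em=0.1, seed=2)[0]
        stored = rec.bias_energies()
        d2 = ((rec.samples - rec.bias_centers[None]) ** 2).sum(axis=2)
        manual = (d2 * rec.bias_k[None, :]).sum(axis=1)
        assert np.allclose(stored, manual, rtol=1e-12)
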