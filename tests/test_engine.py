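"""Brownian-dynamics engine: displacement statistics, forces, overlap
detection, propagation invariants and diffusion estimation."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad

from nanorelease.builder import build_topology
from nanorelease.engine import (
    BrownianEngine,
    bond_forces,
    detect_overlap,
    estimate_diffusion,
    forced_displacement,
    free_displacement,
    step,
)
from nanorelease.kinetics import stokes_einstein
from nanorelease.model import (
    MONOMER,
    SOLUTE,
    BeadSystem,
    NetworkTopology,
    RNGStream,
    SimulationParams,
)


def _free_solutes(n, d0=0.571, radius=1e-6, spread=1000.0, seed=3):
    """n far-apart solutes that never collide: ideal Brownian walkers."""
    gen = np.random.Generator(np.random.PCG64(seed))
    pos = gen.uniform(-spread, spread, (n, 3))
    return BeadSystem(
        pos, np.full(n, radius), np.full(n, SOLUTE), np.full(n, d0)
    )


class TestDisplacements:
    def test_zero_diffusion_gives_zero_vector(self, rng):
        assert np.all(free_displacement(0.0, 3e-3, rng) == 0.0)

    def test_component_statistics(self, rng):
        d0, dt, n = 0.571, 3e-3, 100_000
        draws = np.array([free_displacement(d0, dt, rng) for _ in range(n // 100)])
        # vectorised equivalent for the bulk of the sample
        draws = np.vstack([draws, math.sqrt(2 * d0 * dt) * rng.standard_normal((n, 3))])
        sd_expected = math.sqrt(2 * d0 * dt)  # 0.0585 nm
        assert sd_expected == pytest.approx(0.0585, abs=2e-4)
        se = sd_expected / math.sqrt(len(draws))
        assert abs(draws[:, 0].mean()) < 4 * se
        assert draws.std(ddof=1, axis=0) == pytest.approx(sd_expected, rel=0.02)

    def test_forced_reduces_to_free_for_zero_force(self):
        a = free_displacement(0.5, 3e-3, RNGStream(77))
        b = forced_displacement(0.5, np.zeros(3), 3e-3, RNGStream(77))
        assert np.allclose(a, b)

    def test_drift_term(self):
        rng = RNGStream(8)
        d0, dt, F = 0.5, 3e-3, np.array([2.0, 0.0, 0.0])
        n = 1_000_000
        disp = (
            math.sqrt(2 * d0 * dt) * rng.standard_normal((n, 3))
            + d0 * F[None, :] * dt
        )
        se = math.sqrt(2 * d0 * dt) / math.sqrt(n)
        assert disp[:, 0].mean() == pytest.approx(0.003, abs=4 * se)
        assert abs(disp[:, 1].mean()) < 4 * se

    def test_fluctuation_dissipation_ratio(self):
        """<dx>/Var(dx) = F / (2 kBT): the drift and diffusion terms of the
        overdamped displacement share one mobility."""
        rng = RNGStream(9)
        d0, dt, fx = 0.4, 3e-3, 5.0
        draws = np.array(
            [forced_displacement(d0, [fx, 0, 0], dt, rng) for _ in range(20_000)]
        )
        ratio = draws[:, 0].mean() / draws[:, 0].var(ddof=1)
        assert ratio == pytest.approx(fx / 2.0, rel=0.1)


class TestBondForces:
    def _pair(self, distance):
        pos = np.array([[0.0, 0, 0], [distance, 0, 0]])
        system = BeadSystem(
            pos, np.full(2, 0.325), np.full(2, MONOMER), np.full(2, 0.66)
        )
        topo = NetworkTopology(
            np.array([[0, 1]]), ke=98.88, r0=0.65, chain_count=1,
            crosslinker_indices=np.array([], dtype=int),
        )
        return system, topo

    def test_zero_at_rest_length(self):
        f = bond_forces(*self._pair(0.65))
        assert np.allclose(f, 0.0)

    def test_stretched_pair_attracts(self):
        f = bond_forces(*self._pair(0.75))
        # magnitude ke * 0.1 = 9.888 kBT/nm, antiparallel
        assert np.linalg.norm(f[0]) == pytest.approx(9.888, abs=1e-3)
        assert np.allclose(f[0], -f[1])
        assert f[0][0] > 0  # bead 0 pulled towards bead 1

    def test_coincident_beads_raise(self):
        with pytest.raises(ValueError):
            bond_forces(*self._pair(0.0))

    @given(seed=st.integers(0, 10_000))
    def test_net_force_vanishes(self, seed):
        gen = np.random.Generator(np.random.PCG64(seed))
        topo, system = build_topology(4, 4, 4, 2.25)
        system.positions += 0.1 * gen.standard_normal(system.positions.shape)
        f = bond_forces(system, topo)
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-9)


class TestDetectOverlap:
    def test_single_bead_never_overlaps(self):
        s = _free_solutes(1, radius=0.5)
        assert detect_overlap(s, 0, s.positions[0] + 1.0) is False

    def test_contact_threshold(self):
        pos = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        s = BeadSystem(pos, np.full(2, 0.325), np.full(2, SOLUTE), np.full(2, 0.5))
        assert detect_overlap(s, 0, [4.36, 0, 0]) is True  # 0.64 < 0.65
        assert detect_overlap(s, 0, [4.34, 0, 0]) is False  # 0.66 > 0.65
        assert detect_overlap(s, 0, [4.36, 0, 0], exempt={1}) is False

    def test_matches_brute_force_oracle(self):
        gen = np.random.Generator(np.random.PCG64(21))
        n = 1000
        pos = gen.uniform(-6, 6, (n, 3))
        radii = gen.uniform(0.2, 0.6, n)
        s = BeadSystem(pos, radii, np.full(n, SOLUTE), np.full(n, 0.5))
        for _ in range(300):
            i = int(gen.integers(n))
            trial = pos[i] + gen.normal(0, 1.0, 3)
            d = np.linalg.norm(pos - trial, axis=1)
            d[i] = np.inf
            brute = bool(np.any(d < radii + radii[i]))
            assert detect_overlap(s, i, trial) == brute


class TestPropagation:
    def test_single_free_solute_accepts_everything(self):
        s = _free_solutes(1)
        params = SimulationParams(mode="rigid", seed=4)
        eng = BrownianEngine(s, None, params, total_time_ns=3.0)
        eng.advance(1000)
        assert eng.acceptance_rate == 1.0

    @pytest.mark.parametrize("diameter", [0.75, 1.75])
    def test_free_diffusion_recovers_stokes_einstein(self, diameter):
        """MSD slope / 6 of non-interacting solutes must match the
        Einstein-Stokes D0 within 3 standard errors."""
        d0 = stokes_einstein(diameter / 2)
        n_walkers, n_steps, dt = 200, 2000, 3e-3
        s = _free_solutes(n_walkers, d0=d0, seed=int(diameter * 100))
        eng = BrownianEngine(
            s, None, SimulationParams(mode="rigid", seed=5),
            total_time_ns=n_steps * dt,
        )
        traj, times = [s.positions.copy()], [0.0]
        for k in range(20):
            eng.advance(n_steps // 20)
            traj.append(eng.system.positions.copy())
            times.append(eng.steps_done * dt)
        d_est, r2 = estimate_diffusion(
            np.array(traj), np.array(times), full=True
        )
        # SE of the MSD-slope estimate from independent walkers
        se = d0 * math.sqrt(2.0 / n_walkers)
        assert abs(d_est - d0) < 3 * se
        assert r2 > 0.99

    def test_rigid_network_is_bit_frozen(self, small_gel):
        topo, gel = small_gel
        from nanorelease.model import LoadingSpec
        from nanorelease.release import load_solutes

        loaded = load_solutes(gel, LoadingSpec(n_drug=20, solute_diameter=1.0,
                                               R_max=6.0), RNGStream(6))
        eng = BrownianEngine(
            loaded, topo, SimulationParams(mode="rigid", seed=7),
            total_time_ns=1.0,
        )
        before = loaded.positions[loaded.network_mask].copy()
        eng.advance(2000)
        after = eng.system.positions[eng.system.network_mask]
        assert np.array_equal(before, after)

    def test_identical_seeds_identical_trajectories(self, small_gel):
        topo, gel = small_gel
        params = SimulationParams(mode="flexible", seed=99)
        runs = []
        for _ in range(2):
            eng = BrownianEngine(gel, topo, params, total_time_ns=0.1)
            eng.advance(500)
            runs.append(eng.system.positions.copy())
        assert np.array_equal(runs[0], runs[1])

    def test_no_overlaps_during_propagation(self, small_gel):
        topo, gel = small_gel
        eng = BrownianEngine(
            gel, topo, SimulationParams(mode="flexible", seed=13),
            total_time_ns=0.5,
        )
        eng.advance(2000, check_every=10)
        assert eng.overlap_violations == 0

    def test_solute_in_rigid_gel_is_subdiffusive(self, reference_gel):
        """Obstruction by the network must reduce the MSD slope below the
        free-diffusion value 6 D0 t.  (Needs the full-size gel: in a tiny
        gel the solutes escape into free solvent before the obstructed
        regime is visible.)"""
        topo, gel = reference_gel
        from nanorelease.model import LoadingSpec
        from nanorelease.release import load_solutes

        d0 = stokes_einstein(0.875)
        loaded = load_solutes(
            gel, LoadingSpec(n_drug=40, solute_diameter=1.75, R_max=8.0),
            RNGStream(14),
        )
        dt, n_steps = 3e-3, 3000
        eng = BrownianEngine(
            loaded, topo, SimulationParams(mode="rigid", seed=15),
            total_time_ns=n_steps * dt,
        )
        sol = loaded.solute_mask
        traj, times = [loaded.positions[sol].copy()], [0.0]
        for _ in range(10):
            eng.advance(n_steps // 10)
            traj.append(eng.system.positions[sol].copy())
            times.append(eng.steps_done * dt)
        d_est = estimate_diffusion(np.array(traj), np.array(times))
        assert d_est < 0.8 * d0

    def test_step_functional_interface(self, rng):
        s = _free_solutes(3)
        params = SimulationParams(mode="rigid", seed=1)
        out = step(s, None, params, rng)
        assert out.n_beads == 3
        assert not np.array_equal(out.positions, s.positions)
        assert np.array_equal(s.radii, out.radii)

    def test_bond_length_follows_restricted_boltzmann(self):
        """Flexible network alone: bond lengths sample the Boltzmann
        distribution of the harmonic bond restricted to non-overlapping
        separations r >= r0, p(r) ~ r^2 exp(-ke (r-r0)^2 / 2)."""
        topo, system = build_topology(1, 1, 2, 2.25)
        eng = BrownianEngine(
            system, topo, SimulationParams(mode="flexible", seed=30),
            total_time_ns=3.0,
        )
        eng.advance(5000)  # relax the stretched initial bonds
        samples = []
        for _ in range(400):
            eng.advance(50)
            pos = eng.system.positions
            for a, b in topo.bonds:
                samples.append(np.linalg.norm(pos[a] - pos[b]))
        samples = np.array(samples)

        ke, r0 = topo.ke, topo.r0
        w = lambda r: r**2 * math.exp(-0.5 * ke * (r - r0) ** 2)
        z, _ = quad(w, r0, r0 + 1.0)
        mean, _ = quad(lambda r: r * w(r) / z, r0, r0 + 1.0)
        ex2, _ = quad(lambda r: r**2 * w(r) / z, r0, r0 + 1.0)
        var = ex2 - mean**2
        assert samples.min() >= r0
        assert samples.mean() == pytest.approx(mean, rel=0.05)
        assert samples.var() == pytest.approx(var, rel=0.35)


class TestEstimateDiffusion:
    def test_immobile_particle(self):
        traj = np.zeros((10, 3))
        assert estimate_diffusion(traj, np.arange(10.0)) == 0.0

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            estimate_diffusion(np.zeros((1, 3)), np.array([0.0]))

    def test_known_diffusion_recovered(self):
        gen = np.random.Generator(np.random.PCG64(2))
        d, dt, n_steps, n_walkers = 0.3, 0.01, 1000, 200
        steps = math.sqrt(2 * d * dt) * gen.standard_normal(
            (n_steps, n_walkers, 3)
        )
        traj = np.concatenate(
            [np.zeros((1, n_walkers, 3)), np.cumsum(steps, axis=0)]
        )
        times = np.arange(n_steps + 1) * dt
        assert estimate_diffusion(traj, times) == pytest.approx(d, rel=0.05)

    def test_ballistic_input_flagged_by_r2(self):
        t = np.linspace(0, 10, 50)
        traj = np.outer(t, [1.0, 0, 0])  # x = v t, MSD quadratic
        d, r2 = estimate_diffusion(traj, t, full=True)
        gen = np.random.Generator(np.random.PCG64(4))
        walk = np.cumsum(gen.standard_normal((50, 400, 3)), axis=0) * 0.1
        _, r2_diff = estimate_diffusion(walk, t, full=True)
        assert r2 < r2_diff  # the quadratic MSD fits a line worse
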