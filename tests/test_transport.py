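"""Lagrangian tracker: sampling, forces, integrators, analytic benchmarks."""

import math

import numpy as np
import pytest

from aerodose.flow import AirProperties, SteadyFlow
from aerodose.geometry import bend_fixture, single_tube, upper_airway_surrogate
from aerodose.transport import (
    ParticleSourceConfig,
    ParticleState,
    SimulationConfig,
    advance_particle,
    brownian_kick,
    cunningham_factor,
    diffusion_coefficient,
    drag_coefficient,
    drag_factor,
    sample_particle_sizes,
    simulate_deposition,
)

AIR = AirProperties(viscosity=1.81e-5, temperature=293.0)


def _drag_only(**kw):
    forces = {"drag": True, "gravity": False, "brownian": False}
    forces.update(kw)
    return SimulationConfig(forces=forces)


class TestSampler:
    def test_geometric_moments_recovered(self):
        src = ParticleSourceConfig(median_um=0.42, gsd=3.5)
        d = sample_particle_sizes(200_000, src, seed_or_rng=1) * 1e6
        gm = math.exp(np.mean(np.log(d)))
        gsd = math.exp(np.std(np.log(d)))
        assert gm == pytest.approx(0.42, rel=0.01)
        assert gsd == pytest.approx(3.5, rel=0.01)

    def test_degenerate_gsd_collapses_to_median(self):
        src = ParticleSourceConfig(median_um=0.42, gsd=1.0 + 1e-9)
        d = sample_particle_sizes(1000, src, seed_or_rng=0) * 1e6
        assert np.allclose(d, 0.42, rtol=1e-6)

    def test_invalid_gsd_rejected(self):
        with pytest.raises(ValueError):
            ParticleSourceConfig(gsd=0.9)

    def test_truncation_and_determinism(self):
        src = ParticleSourceConfig(truncation_um=(0.1, 10.0))
        a = sample_particle_sizes(5000, src, seed_or_rng=3) * 1e6
        b = sample_particle_sizes(5000, src, seed_or_rng=3) * 1e6
        assert np.array_equal(a, b)
        assert a.min() >= 0.1 and a.max() <= 10.0


class TestDrag:
    def test_stokes_limit(self):
        re = np.array([1e-8, 1e-6, 1e-4])
        assert np.allclose(drag_coefficient(re) * re, 24.0, rtol=1e-3)
        assert np.allclose(drag_factor(re), 1.0, atol=1e-3)

    def test_intermediate_value(self):
        assert drag_coefficient(1.0) == pytest.approx(24.0 * 1.15, rel=1e-12)

    def test_plateau(self):
        assert drag_coefficient(2000.0) == 0.44
        assert drag_coefficient(1e6) == 0.44

    def test_negative_reynolds_rejected(self):
        with pytest.raises(ValueError):
            drag_coefficient(-1.0)

    def test_cunningham_factor_grows_for_small_particles(self):
        assert cunningham_factor(10e-6) == pytest.approx(1.0, abs=0.05)
        assert cunningham_factor(100e-9) > 2.0


class TestBrownian:
    def test_zero_temperature_gives_zero_force(self, rng):
        cold = AirProperties(temperature=1e-300)
        f = brownian_kick(1e-6, cold, 1e-4, rng)
        assert np.allclose(f, 0.0, atol=1e-20)

    def test_einstein_diffusivity(self):
        d = diffusion_coefficient(1e-6, AIR)
        assert d == pytest.approx(2.37e-11, rel=0.01)

    def test_free_particle_msd_matches_2dt(self, rng):
        """Per-axis MSD of 1e4 free Brownian particles equals 2 D t within 5%."""
        n, d_p, dt, steps = 10_000, 1e-6, 1e-3, 150
        gamma = 3 * math.pi * AIR.viscosity * d_p
        diff = AIR.k_b * AIR.temperature / gamma
        m = math.pi / 6 * d_p**3 * 1000.0
        tau = 1000.0 * d_p**2 / (18 * AIR.viscosity)
        x = np.zeros((n, 3))
        v = np.zeros((n, 3))
        amp = math.sqrt(2 * AIR.k_b * AIR.temperature * gamma / dt)
        e = math.exp(-dt / tau)
        for _ in range(steps):
            a = amp * rng.standard_normal((n, 3)) / m
            ueff = tau * a
            x = x + ueff * dt + (v - ueff) * tau * (1 - e)
            v = ueff + (v - ueff) * e
        msd = (x**2).mean(axis=0)
        assert np.allclose(msd, 2 * diff * steps * dt, rtol=0.05)


class TestAdvanceParticle:
    def test_ballistic_motion_without_forces(self):
        cfg = SimulationConfig(forces={"drag": False, "gravity": False, "brownian": False})
        st = ParticleState(position=[0, 0, 0], velocity=[1.0, 2.0, -1.0], diameter=1e-6)
        new = advance_particle(st, np.zeros(3), AIR, cfg, 0.5)
        assert np.allclose(new.position, [0.5, 1.0, -0.5])
        assert np.allclose(new.velocity, st.velocity)

    def test_stokes_terminal_velocity(self):
        """10 um, 1000 kg/m^3 particle settles at 3.01 mm/s within 1%."""
        cfg = SimulationConfig(forces={"drag": True, "gravity": True, "brownian": False})
        st = ParticleState(position=np.zeros(3), velocity=np.zeros(3),
                           diameter=10e-6, density=1000.0)
        for _ in range(100):
            st = advance_particle(st, np.zeros(3), AIR, cfg, 2e-4)
        assert st.velocity[2] == pytest.approx(-3.01e-3, rel=0.01)

    def test_velocity_relaxation_closed_form(self):
        """Relaxation to a slow uniform flow follows 1 - exp(-t/tau) within 0.1%."""
        cfg = _drag_only()
        d_p, rho = 2e-6, 1000.0
        tau = rho * d_p**2 / (18 * AIR.viscosity)
        u = np.array([0.001, 0.0, 0.0])  # Re << 1 so Stokes drag is exact
        st = ParticleState(position=np.zeros(3), velocity=np.zeros(3),
                           diameter=d_p, density=rho)
        t = 0.0
        for _ in range(30):
            st = advance_particle(st, u, AIR, cfg, tau / 10)
            t += tau / 10
            expected = u[0] * (1 - math.exp(-t / tau))
            assert st.velocity[0] == pytest.approx(expected, rel=1e-3)

    def test_wall_contact_sticks(self):
        tube = single_tube(diameter=10.0, length=100.0, direction=(1, 0, 0))
        seg = tube.root
        cfg = SimulationConfig(forces={"drag": False, "gravity": False, "brownian": False})
        st = ParticleState(position=[0.01, 0.0, 0.0], velocity=[0.0, 1.0, 0.0],
                           diameter=5e-6)
        new = advance_particle(st, np.zeros(3), AIR, cfg, 0.01, segment=seg)
        assert new.status == "stuck"
        assert np.hypot(new.position[1], new.position[2]) == pytest.approx(5e-3, rel=1e-9)

    def test_nan_state_aborts(self):
        cfg = _drag_only()
        st = ParticleState(position=[np.nan, 0, 0], velocity=np.zeros(3), diameter=1e-6)
        with pytest.raises(FloatingPointError):
            advance_particle(st, np.zeros(3), AIR, cfg, 1e-3)


def _tube_run(d_um, R_m, L_m, U_ms, n, seed, forces, t_mult=4.0, air=AIR,
              direction=(1, 0, 0), brownian_fraction=30.0):
    tree = single_tube(diameter=2 * R_m * 1e3, length=L_m * 1e3, direction=direction)
    q_lpm = U_ms * math.pi * R_m**2 / (1e-3 / 60.0)
    cfg = SimulationConfig(n_particles=n, particle_density=1000.0, forces=forces,
                           t_end=L_m / U_ms * t_mult, seed=seed,
                           brownian_step_fraction=brownian_fraction)
    src = ParticleSourceConfig(kind="uniform", median_um=d_um)
    res = simulate_deposition(tree, SteadyFlow(q_lpm=q_lpm), src, cfg, air=air)
    c = res.counts
    return c["stuck"] / max(c["stuck"] + c["escaped"], 1), res


class TestSimulateDeposition:
    def test_particle_number_conservation(self, mm_tree):
        from aerodose.flow import BreathingPattern

        cfg = SimulationConfig(n_particles=800, seed=2)
        res = simulate_deposition(mm_tree, BreathingPattern(), ParticleSourceConfig(), cfg)
        c = res.counts
        assert sum(c.values()) == res.n_injected == 800
        # mass conservation: status masses partition the injected mass
        d_m = res.records["d_p"].to_numpy() * 1e-6
        m = math.pi / 6 * d_m**3 * res.records["rho_p"].to_numpy()
        total = sum(m[res.records["status"] == s].sum() for s in
                    ("airborne", "stuck", "escaped", "exhaled"))
        assert total == pytest.approx(m.sum(), rel=1e-12)

    def test_fixed_seed_reproducible(self, mm_tree):
        from aerodose.flow import BreathingPattern

        cfg = SimulationConfig(n_particles=400, seed=7)
        a = simulate_deposition(mm_tree, BreathingPattern(), ParticleSourceConfig(), cfg)
        b = simulate_deposition(mm_tree, BreathingPattern(), ParticleSourceConfig(), cfg)
        assert a.records.equals(b.records)

    def test_gormley_kennedy_diffusion_deposition(self):
        """Diffusive tube deposition matches the Graetz-series penetration."""

        def gk_efficiency(mu):
            if mu < 0.009:
                p = 1 - 5.50 * mu ** (2 / 3) + 3.77 * mu
            else:
                p = (0.81905 * math.exp(-11.489 * mu)
                     + 0.09753 * math.exp(-70.07 * mu)
                     + 0.0325 * math.exp(-179.0 * mu))
            return 1 - p

        R, L, d_p = 1e-3, 0.1, 50e-9  # 50 nm particles, diffusion dominated
        diff = diffusion_coefficient(d_p, AirProperties())
        forces = {"drag": True, "gravity": False, "brownian": True}
        for mu, n in ((3e-3, 4000), (2e-2, 3000)):
            U = diff * L / mu / (math.pi * R**2)
            eff, _ = _tube_run(d_p * 1e6, R, L, U, n, seed=2, forces=forces,
                               t_mult=3.0, air=AirProperties())
            assert eff == pytest.approx(gk_efficiency(mu), rel=0.10)

    def test_laminar_sedimentation_deposition(self):
        """Horizontal-tube settling matches a ballistic quadrature oracle."""
        R, L, U, d_um = 2e-3, 0.1, 0.3, 10.0
        v_s = 1000.0 * (d_um * 1e-6) ** 2 * 9.81 / (18 * AIR.viscosity)

        def oracle(ngrid=60, dt=2e-4):
            dep = tot = 0.0
            for ix in range(ngrid):
                for iy in range(ngrid):
                    y0 = (ix + 0.5) / ngrid * 2 * R - R
                    z0 = (iy + 0.5) / ngrid * 2 * R - R
                    if y0 * y0 + z0 * z0 >= R * R:
                        continue
                    w = 1 - (y0 * y0 + z0 * z0) / R**2  # local flux weight
                    x, z, hit = 0.0, z0, False
                    while x < L:
                        r2 = y0 * y0 + z * z
                        if r2 >= R * R:
                            hit = True
                            break
                        x += 2 * U * (1 - r2 / R**2) * dt
                        z -= v_s * dt
                    dep += w * hit
                    tot += w
            return dep / tot

        forces = {"drag": True, "gravity": True, "brownian": False}
        eff, _ = _tube_run(d_um, R, L, U, 4000, seed=3, forces=forces)
        assert eff == pytest.approx(oracle(), rel=0.10)

    def test_impaction_monotone_in_impaction_parameter(self):
        """Deposition on a fixed bend is non-decreasing in d_p^2 Q for d_p >= 5 um."""
        tree = bend_fixture(diameter=6.0, leg_length=30.0)
        effs = []
        for d_um in (5.0, 7.0, 10.0, 14.0):
            cfg = SimulationConfig(n_particles=2500, particle_density=1000.0,
                                   forces={"drag": True, "gravity": False, "brownian": False},
                                   t_end=0.1, seed=5)
            src = ParticleSourceConfig(kind="uniform", median_um=d_um)
            res = simulate_deposition(tree, SteadyFlow(q_lpm=30.0), src, cfg)
            c = res.counts
            effs.append(c["stuck"] / (c["stuck"] + c["escaped"]))
        assert all(b >= a - 0.01 for a, b in zip(effs, effs[1:]))

    def test_substep_halving_changes_ndf_below_one_percent(self):
        """Deterministic impaction run: halving the sub-step moves nDF < 1%."""
        tree = bend_fixture(diameter=6.0, leg_length=30.0)
        out = []
        for frac in (20, 40):
            cfg = SimulationConfig(n_particles=3000, particle_density=1000.0,
                                   transit_fraction=frac,
                                   forces={"drag": True, "gravity": True, "brownian": False},
                                   t_end=0.1, seed=6)
            src = ParticleSourceConfig(kind="uniform", median_um=10.0)
            res = simulate_deposition(tree, SteadyFlow(q_lpm=60.0), src, cfg)
            out.append(res.counts["stuck"] / res.n_injected)
        assert abs(out[1] - out[0]) < 0.01

    def test_upper_airway_surrogate_filters_coarse_particles(self):
        """UA-1 at 90 L/min captures >90% of 10 um particles."""
        cfg = SimulationConfig(n_particles=4000, particle_density=1000.0,
                               forces={"drag": True, "gravity": True, "brownian": False},
                               t_end=0.2, seed=1)
        src = ParticleSourceConfig(kind="uniform", median_um=10.0)
        res = simulate_deposition(upper_airway_surrogate(), SteadyFlow(q_lpm=90.0), src, cfg)
        assert res.deposited_fraction() > 0.90

    def test_exhalation_through_inlet(self, small_symmetric_tree):
        """Submicron particles still airborne at flow reversal leave as exhaled."""
        from aerodose.flow import BreathingPattern

        cfg = SimulationConfig(n_particles=500, seed=8,
                               forces={"drag": True, "gravity": False, "brownian": False})
        src = ParticleSourceConfig(kind="uniform", median_um=0.5)
        res = simulate_deposition(small_symmetric_tree, BreathingPattern(), src, cfg)
        assert res.counts["exhaled"] > 0
        # at most a handful of slow near-wall stragglers may remain airborne
        assert res.counts["airborne"] <= 0.01 * res.n_injected
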