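import numpy as np
import pytest

from crowdlens.composition import SpeciesSpec, lens_composition, to_reduced_units
from crowdlens.engine import (
    SimConfig,
    SimState,
    compress_to_phi,
    equilibrate,
    initial_state,
    predict_pair_collision,
    resolve_collision,
    run,
    run_reference,
    sample_frames,
    thermostat_event,
)


@pytest.fixture(scope="module")
def mono():
    return to_reduced_units([SpeciesSpec("alpha", 18.6, 1.13e-18)])


class TestPredictPairCollision:
    def test_head_on_analytic(self):
        t = predict_pair_collision(
            (0, 0, 0), (1, 0, 0), 1.0, (3, 0, 0), (-1, 0, 0), 1.0, 100.0
        )
        assert t == pytest.approx(1.0, abs=1e-12)

    def test_receding_pair_none(self):
        t = predict_pair_collision(
            (0, 0, 0), (-1, 0, 0), 1.0, (3, 0, 0), (1, 0, 0), 1.0, 100.0
        )
        assert t is None

    def test_offset_pair_vs_time_marching_oracle(self):
        r1, v1 = np.array([0.0, 0, 0]), np.array([1.0, 0, 0])
        r2, v2 = np.array([3.0, 0.5, 0]), np.array([-1.0, 0, 0])
        t = predict_pair_collision(r1, v1, 1.0, r2, v2, 1.0, 100.0)
        # brute-force time marching with step 1e-6
        step = 1e-6
        tau = 0.0
        while tau < 5.0:
            d = np.linalg.norm((r2 + v2 * tau) - (r1 + v1 * tau))
            if d <= 1.0:
                break
            tau += step
        assert t == pytest.approx(tau, abs=1e-5)

    def test_periodic_image_contact(self):
        # minimum image is through the boundary: gap 1, closing speed 2
        t = predict_pair_collision(
            (1.0, 5, 5), (-1, 0, 0), 1.0, (9.0, 5, 5), (1, 0, 0), 1.0, 10.0
        )
        assert t == pytest.approx(0.5, abs=1e-12)

    def test_overlapping_input_rejected(self):
        with pytest.raises(ValueError):
            predict_pair_collision(
                (0, 0, 0), (0, 0, 0), 1.0, (0.5, 0, 0), (0, 0, 0), 1.0, 100.0
            )


class TestResolveCollision:
    def test_elastic_equal_mass_swap(self):
        v1, v2 = resolve_collision(
            (1.0, 0, 0), (-1.0, 0, 0), 1.0, 1.0, (1.0, 0, 0), restitution=1.0
        )
        assert v1 == pytest.approx([-1.0, 0, 0])
        assert v2 == pytest.approx([1.0, 0, 0])

    def test_perfectly_inelastic_symmetric(self):
        v1, v2 = resolve_collision(
            (1.0, 0, 0), (-1.0, 0, 0), 1.0, 1.0, (1.0, 0, 0), restitution=1e-12
        )
        assert v1 == pytest.approx([0.0, 0, 0], abs=1e-9)
        assert v2 == pytest.approx([0.0, 0, 0], abs=1e-9)

    def test_alpha_beta_masses_conservation_closed_form(self):
        m1, m2 = 1.0, 0.26
        v1, v2 = resolve_collision((1.0, 0, 0), (0.0, 0, 0), m1, m2, (1.0, 0, 0))
        # two-body closed form for a 1-D elastic collision
        u1 = (m1 - m2) / (m1 + m2) * 1.0
        u2 = 2 * m1 / (m1 + m2) * 1.0
        assert v1[0] == pytest.approx(u1, abs=1e-12)
        assert v2[0] == pytest.approx(u2, abs=1e-12)
        # momentum and energy conserved exactly
        assert m1 * v1[0] + m2 * v2[0] == pytest.approx(m1 * 1.0, abs=1e-12)
        assert m1 * v1 @ v1 + m2 * v2 @ v2 == pytest.approx(m1, abs=1e-12)

    def test_receding_pair_rejected(self):
        with pytest.raises(ValueError):
            resolve_collision((-1.0, 0, 0), (1.0, 0, 0), 1.0, 1.0, (1.0, 0, 0))


class TestThermostatEvent:
    def _state(self, n=4):
        return SimState(
            positions=np.zeros((n, 3)),
            velocities=np.ones((n, 3)),
            diameters=np.full(n, 0.1),
            masses=np.full(n, 2.0),
            species_id=np.zeros(n, dtype=int),
            box_edge=10.0,
        )

    def test_zero_temperature_limit(self):
        st = self._state()
        thermostat_event(st, 1, 0.0, np.random.default_rng(0))
        assert st.velocities[1] == pytest.approx([0, 0, 0])

    def test_position_unchanged_and_others_untouched(self):
        st = self._state()
        pos_before = st.positions.copy()
        thermostat_event(st, 2, 1.0, np.random.default_rng(0))
        assert np.array_equal(st.positions, pos_before)
        assert np.array_equal(st.velocities[[0, 1, 3]], np.ones((3, 3)))

    def test_maxwell_variance(self):
        st = self._state(1)
        rng = np.random.default_rng(42)
        draws = np.array([
            thermostat_event(st, 0, 1.0, rng).velocities[0].copy()
            for _ in range(100_000 // 3)
        ])
        var = draws.var(axis=0)
        se = (1.0 / 2.0) * np.sqrt(2.0 / len(draws))  # var of N(0, T/m), m=2
        assert var == pytest.approx(np.full(3, 0.5), abs=3 * se + 1e-3)


class TestCompression:
    def test_noop_at_target(self, mono):
        cfg = SimConfig(n_particles=100, species_set=mono, target_phi=0.2, seed=3)
        st = initial_state(cfg, phi_init=0.2)
        pos = st.positions.copy()
        compress_to_phi(st, cfg)
        assert np.array_equal(st.positions, pos)

    def test_monodisperse_to_phi04_postconditions(self, mono):
        cfg = SimConfig(n_particles=500, species_set=mono, target_phi=0.4, seed=7)
        st = initial_state(cfg)
        compress_to_phi(st, cfg)
        assert st.packing_fraction() == pytest.approx(0.4, abs=1e-4)
        assert st.max_overlap() <= 1e-9

    def test_species_ratios_preserved(self, mono):
        cfg = SimConfig(
            n_particles=1000, species_set=lens_composition(), target_phi=0.3, seed=5
        )
        st = initial_state(cfg)
        compress_to_phi(st, cfg)
        d = st.diameters
        sid = st.species_id
        ratios = [np.unique(d[sid == k])[0] for k in range(3)]
        assert ratios[1] / ratios[0] == pytest.approx(11.7 / 18.6, rel=1e-12)
        assert ratios[2] / ratios[0] == pytest.approx(3.56 / 18.6, rel=1e-12)


class TestRun:
    def test_cell_engine_matches_brute_force_oracle(self, mono):
        cfg = SimConfig(
            n_particles=20, species_set=mono, target_phi=0.2, seed=11,
            thermostat_rate=0.0,
        )
        st = initial_state(cfg, phi_init=0.2)
        ref_state = st.copy()
        res = run(st, cfg, n_collisions=200, record_events=400, thermostat=False)
        _, ref_events = run_reference(ref_state, 200)
        assert len(res.events) == 200
        assert len(ref_events) == 200
        assert np.array_equal(res.events.first, ref_events.first)
        assert np.array_equal(res.events.second, ref_events.second)
        # hard-sphere dynamics is chaotic: last-bit arithmetic differences
        # between the two independent implementations amplify exponentially,
        # so the time tolerance is tight early and bounded late
        assert res.events.times[:100] == pytest.approx(ref_events.times[:100], abs=1e-8)
        assert res.events.times == pytest.approx(ref_events.times, abs=1e-6)

    def test_event_times_non_decreasing(self, mono):
        cfg = SimConfig(n_particles=50, species_set=mono, target_phi=0.3, seed=13)
        st = initial_state(cfg, phi_init=0.3)
        res = run(st, cfg, n_collisions=2000, record_events=2000, thermostat=False)
        assert (np.diff(res.events.times) >= 0).all()

    def test_zero_velocity_state_static(self, mono):
        cfg = SimConfig(
            n_particles=50, species_set=mono, target_phi=0.2, seed=17,
            thermostat_rate=0.0,
        )
        st = initial_state(cfg, phi_init=0.2)
        st.velocities[:] = 0.0
        pos = st.positions.copy()
        res = run(st, cfg, duration=5.0, record_events=10, thermostat=False)
        assert len(res.events) == 0
        assert st.positions == pytest.approx(pos)

    def test_elastic_conservation_over_1e4_events(self, mono):
        cfg = SimConfig(
            n_particles=300, species_set=mono, target_phi=0.3, seed=19,
            thermostat_rate=0.0,
        )
        st = initial_state(cfg, phi_init=0.3)
        p0 = st.total_momentum()
        e0 = st.kinetic_energy()
        run(st, cfg, n_collisions=10_000, thermostat=False)
        assert np.abs(st.total_momentum() - p0).max() < 1e-10
        assert abs(st.kinetic_energy() - e0) / e0 < 1e-9

    def test_polydisperse_conservation(self):
        cfg = SimConfig(
            n_particles=400, species_set=lens_composition(), target_phi=0.25,
            seed=23, thermostat_rate=0.0,
        )
        st = initial_state(cfg, phi_init=0.25)
        p0 = st.total_momentum()
        e0 = st.kinetic_energy()
        run(st, cfg, n_collisions=10_000, thermostat=False)
        assert np.abs(st.total_momentum() - p0).max() < 1e-10
        assert abs(st.kinetic_energy() - e0) / e0 < 1e-9

    def test_inelastic_dissipates_energy(self, mono):
        cfg = SimConfig(
            n_particles=200, species_set=mono, target_phi=0.3, seed=29,
            restitution=0.9, thermostat_rate=0.0,
        )
        st = initial_state(cfg, phi_init=0.3)
        e0 = st.kinetic_energy()
        run(st, cfg, n_collisions=2000, thermostat=False)
        assert st.kinetic_energy() < 0.9 * e0

    def test_thermostat_temperature_convergence(self, mono):
        cfg = SimConfig(
            n_particles=500, species_set=mono, target_phi=0.3, seed=31,
            thermostat_rate=0.5,
        )
        st = initial_state(cfg, phi_init=0.3)
        st.velocities *= np.sqrt(1.3)  # start hot
        equilibrate(st, cfg)
        # time-averaged kinetic temperature over the production window
        frames = sample_frames(st, cfg, n_frames=30)
        temps = [
            (st.masses[:, None] * frames.velocities[f] ** 2).sum() / (3 * st.n)
            for f in range(frames.n_frames)
        ]
        assert np.mean(temps) == pytest.approx(1.0, abs=0.02)

    def test_no_overlap_at_every_sampled_frame(self):
        from crowdlens.engine._kernels import max_overlap

        cfg = SimConfig(
            n_particles=300, species_set=lens_composition(), target_phi=0.35, seed=37
        )
        st = initial_state(cfg)
        compress_to_phi(st, cfg)
        frames = sample_frames(st, cfg, n_frames=10)
        for f in range(frames.n_frames):
            ov = max_overlap(frames.positions[f], frames.diameters[f], frames.box_edge)
            assert ov <= 1e-9

    def test_seed_reproducibility(self, mono):
        def one():
            cfg = SimConfig(n_particles=100, species_set=mono, target_phi=0.3, seed=41)
            st = initial_state(cfg)
            compress_to_phi(st, cfg)
            run(st, cfg, n_collisions=1000)
            return st.positions.copy()

        assert np.array_equal(one(), one())


class TestEquationOfState:
    def test_carnahan_starling_phi_030(self, mono):
        cfg = SimConfig(n_particles=2000, species_set=mono, target_phi=0.30, seed=2)
        st = initial_state(cfg)
        compress_to_phi(st, cfg)
        equilibrate(st, cfg)
        prod = run(st, cfg, n_collisions=200 * st.n, thermostat=False)
        z = prod.compressibility_factor()
        phi = 0.30
        z_cs = (1 + phi + phi**2 - phi**3) / (1 - phi) ** 3
        assert z == pytest.approx(z_cs, rel=0.03)
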