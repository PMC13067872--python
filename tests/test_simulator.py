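"""Force rules, binding registry dynamics, and the Langevin integrator."""

import numpy as np
import pytest

from revlink.model import ModelParameters, SystemTopology
from revlink.simulate import (
    BindingRegistry,
    SlabProtocolSpec,
    build_system,
    compute_forces,
    initialize_positions,
    run_bulk_simulation,
    run_slab_protocol,
    update_bindings,
)


def dimer_topology(L=20.0):
    """One single-monomer A-chain + one single-monomer B-chain."""
    return SystemTopology(NA=1, NB=1, a_positions=(0,), b_pattern=(1,),
                          nA=1, nB=1, box=(L, L, L))


def place(state, coords):
    state.positions[:] = np.asarray(coords, dtype=float)


class TestForceRules:
    def test_registered_pair_feels_binding_attraction(self, params):
        # isolated registered pair at r = 0.25 sigma: |F| = 12 pi kBT/sigma
        topo = dimer_topology()
        state = build_system(topo)
        place(state, [[10, 10, 10], [10.25, 10, 10]])
        state.partner[:] = [1, 0]
        f, _ = compute_forces(state, params)
        assert f[0, 0] == pytest.approx(12 * np.pi, rel=1e-10)
        assert f[1, 0] == pytest.approx(-12 * np.pi, rel=1e-10)

    def test_free_pair_also_feels_binding_not_wca(self, params):
        # the attraction must precede registration for binding to occur
        topo = dimer_topology()
        state = build_system(topo)
        place(state, [[10, 10, 10], [10.25, 10, 10]])
        f, _ = compute_forces(state, params)
        assert f[0, 0] == pytest.approx(12 * np.pi, rel=1e-10)
        # beyond the binding range the free pair does not interact at all
        place(state, [[10, 10, 10], [11.0, 10, 10]])
        f, _ = compute_forces(state, params)
        assert np.allclose(f, 0.0)

    def test_third_party_sees_wca(self, params):
        # free A vs a B bound elsewhere at r = sigma: repulsive WCA (|F|=24)
        topo = SystemTopology(NA=1, NB=2, a_positions=(0,), b_pattern=(1, 1),
                              nA=2, nB=1, box=(20.0, 20.0, 20.0))
        state = build_system(topo)
        # monomers: A0, A1, B0, B1 (one B-chain of two crosslinkables)
        place(state, [[10, 10, 10], [10.2, 14, 10], [11, 10, 10], [10.9, 14, 10]])
        state.partner[1] = 3
        state.partner[3] = 1
        f, _ = compute_forces(state, params)
        # A0 (free) vs B0 (free): binding pair at r=1 -> zero force
        # swap: bind B0 to A1 instead so A0 faces a bound third party
        state.partner[:] = -1
        state.partner[1] = 2
        state.partner[2] = 1
        f, _ = compute_forces(state, params)
        assert f[0, 0] == pytest.approx(-24.0, rel=1e-10)  # pushed away from B0

    def test_newtons_third_law(self, params, rng):
        topo = SystemTopology.preset(NA=7, nA=8, nB=2, box=(10.0, 10.0, 10.0))
        state = build_system(topo)
        initialize_positions(state, topo, np.random.default_rng(4), params.r0)
        update_bindings(state, params)
        f, _ = compute_forces(state, params)
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-9)

    def test_forces_match_energy_gradient(self, params):
        # one short chain: bonds + angles + WCA, against central differences
        topo = SystemTopology.preset(NA=7, nA=1, nB=0, box=(30.0, 30.0, 30.0))
        state = build_system(topo)
        rng = np.random.default_rng(2)
        initialize_positions(state, topo, rng, params.r0, min_dist=0.95)
        f, _ = compute_forces(state, params)
        h = 1e-6
        for i in range(7):
            for d in range(3):
                orig = state.positions[i, d]
                state.positions[i, d] = orig + h
                _, e_up = compute_forces(state, params)
                state.positions[i, d] = orig - h
                _, e_dn = compute_forces(state, params)
                state.positions[i, d] = orig
                num = -(e_up - e_dn) / (2 * h)
                assert f[i, d] == pytest.approx(num, rel=1e-5, abs=1e-4)


class TestBindingRegistry:
    def test_greedy_nearest_wins(self, params):
        # one free A between two free Bs at 0.2 and 0.4 binds the nearer
        topo = SystemTopology(NA=1, NB=1, a_positions=(0,), b_pattern=(1,),
                              nA=1, nB=2, box=(20.0, 20.0, 20.0))
        state = build_system(topo)
        place(state, [[10, 10, 10], [10.2, 10, 10], [9.6, 10, 10]])
        update_bindings(state, params)
        assert state.partner[0] == 1
        assert state.partner[1] == 0
        assert state.partner[2] == -1

    def test_stretched_pair_breaks(self, params):
        topo = dimer_topology()
        state = build_system(topo)
        place(state, [[10, 10, 10], [10.6, 10, 10]])
        state.partner[:] = [1, 0]
        update_bindings(state, params)
        assert np.all(state.partner == -1)

    def test_one_to_one_saturation_random_audit(self, params):
        # random crosslinker clouds: after the update no monomer has two
        # partners, all pairs are A-B, and all pairs are within r_bind
        rng = np.random.default_rng(9)
        for _ in range(200):
            nA, nB = rng.integers(2, 12, size=2)
            topo = SystemTopology(NA=1, NB=1, a_positions=(0,),
                                  b_pattern=(1,), nA=int(nA), nB=int(nB),
                                  box=(4.0, 4.0, 4.0))
            state = build_system(topo)
            state.positions[:] = rng.random((nA + nB, 3)) * 4.0
            update_bindings(state, params)
            reg = BindingRegistry.from_array(state.partner)
            reg.validate(state.link_type, state.positions, state.box,
                         params.r_bind)

    def test_registry_class_enforces_saturation(self):
        reg = BindingRegistry()
        reg.add(0, 5)
        with pytest.raises(ValueError):
            reg.add(0, 6)
        assert reg.partner_of(5) == 0
        assert len(reg) == 1


class TestIntegrator:
    def test_same_seed_identical_trajectory(self, params, small_mixture):
        t1 = run_bulk_simulation(params, small_mixture, 20.0, seed=77,
                                 frame_interval=5.0)
        t2 = run_bulk_simulation(params, small_mixture, 20.0, seed=77,
                                 frame_interval=5.0)
        for a, b in zip(t1.frames, t2.frames):
            assert np.array_equal(a.positions, b.positions)
            assert a.pairs == b.pairs

    def test_nve_energy_conservation(self, params):
        # gamma = 0 and no noise: bonded dimer drifts < 1e-4 kBT per 1e4 steps
        topo = SystemTopology(NA=2, NB=1, a_positions=(0,), b_pattern=(0,),
                              nA=1, nB=0, box=(20.0, 20.0, 20.0))
        nve = params.replace(gamma=0.0, eps_sp=0.0)
        state = build_system(topo)
        place(state, [[10, 10, 10], [10 + params.r0 + 0.05, 10, 10]])
        state.velocities[:] = [[0.05, 0.02, 0.0], [-0.05, -0.02, 0.0]]
        traj = run_bulk_simulation(nve, topo, duration=50.0, seed=1,
                                   frame_interval=0.5, state=state)
        e = np.array([f.kinetic_energy + f.potential_energy
                      for f in traj.frames])
        assert np.max(np.abs(e - e[0])) < 1e-4

    def test_free_particle_diffusion(self, params):
        # Einstein relation: <dr^2> = 6 (kBT/gamma) t for t >> m/gamma
        topo = SystemTopology(NA=1, NB=1, a_positions=(0,), b_pattern=(0,),
                              nA=1, nB=0, box=(50.0, 50.0, 50.0))
        msds = []
        t_lag = 20.0
        for seed in range(40):
            traj = run_bulk_simulation(params, topo, duration=2 * t_lag,
                                       seed=seed, frame_interval=t_lag)
            disp = traj.frames[1].unwrapped[0] - traj.frames[0].unwrapped[0]
            msds.append((disp ** 2).sum())
        expected = 6.0 * params.kBT / params.gamma * t_lag
        mean = np.mean(msds)
        se = np.std(msds, ddof=1) / np.sqrt(len(msds))
        assert abs(mean - expected) < 3.5 * se + 0.05 * expected

    def test_equipartition(self, params, small_mixture):
        traj = run_bulk_simulation(params, small_mixture, duration=100.0,
                                   seed=3, frame_interval=2.0,
                                   equilibration=20.0)
        n = small_mixture.n_monomers
        ke = np.mean([f.kinetic_energy for f in traj.frames]) / n
        assert ke == pytest.approx(1.5 * params.kBT, rel=0.02)

    def test_empty_topology(self, params):
        topo = SystemTopology(NA=1, NB=1, a_positions=(0,), b_pattern=(1,),
                              nA=0, nB=0, box=(10.0, 10.0, 10.0))
        traj = run_bulk_simulation(params, topo, duration=1.0, seed=0)
        assert traj.frames == []

    def test_no_binding_without_attraction(self, params, small_mixture):
        # eps_sp = 0 switches the binding machinery off entirely
        p0 = params.replace(eps_sp=0.0)
        traj = run_bulk_simulation(p0, small_mixture, duration=20.0, seed=5,
                                   frame_interval=5.0)
        assert all(len(f.pairs) == 0 for f in traj.frames)


class TestSlabProtocol:
    def test_reduced_slab_run_geometry(self, params):
        spec = SlabProtocolSpec.reduced(initial_box=8.0, factor=3.0,
                                        pre_run=5.0, equilibration=5.0,
                                        production=10.0, n_frames=4)
        topo = SystemTopology.preset(NA=7, nA=6, nB=1, box=(8.0, 8.0, 8.0))
        traj = run_slab_protocol(spec, params, topo, seed=12)
        assert len(traj.frames) == spec.n_frames
        assert traj.topology.box[1] == pytest.approx(24.0)
        assert traj.topology.box[0] == pytest.approx(8.0)
        # particle count conserved
        assert all(len(f.positions) == topo.n_monomers for f in traj.frames)
        # bond lengths stay physical after the extension
        from revlink.analysis import monomer_chain_map
        cid = monomer_chain_map(traj.topology)
        u = traj.frames[-1].unwrapped
        for c in np.unique(cid):
            r = u[cid == c]
            bl = np.linalg.norm(np.diff(r, axis=0), axis=1)
            assert np.all(bl < 2.0)

    def test_box_must_match_spec(self, params):
        spec = SlabProtocolSpec.reduced(initial_box=10.0)
        topo = SystemTopology.preset(NA=7, nA=2, nB=1, box=(12.0, 12.0, 12.0))
        with pytest.raises(ValueError, match="cubic initial box"):
            run_slab_protocol(spec, params, topo, seed=0)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SlabProtocolSpec(initial_box=30.0, final_length=10.0)
        with pytest.raises(ValueError):
            SlabProtocolSpec(pre_run=-1.0)
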