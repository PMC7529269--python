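import numpy as np
import pytest

import cardiorom as cr
from cardiorom.fom import (
    ConductivityModel,
    GaussianStimulus,
    IndicatorStimulus,
    MonodomainFOM,
    SnapshotSet,
    State,
    solve_fom,
)
from cardiorom.grids import Grid2D, TimeGrid
from cardiorom.ionic import IonicParams

from oracles import dense_q1_operators, dense_semi_implicit_step

ION = IonicParams(K=8.0, a=0.01, b=0.15, eps0=0.002, c1=0.2, c2=0.3)


def _isotropic(sigma=1.0, modulation=None):
    return ConductivityModel(sigma_l=sigma, sigma_t=sigma,
                             f0=np.array([1.0, 0.0]), modulation=modulation)


class TestConductivityModel:
    def test_rejects_bad_fibers(self):
        with pytest.raises(ValueError):
            ConductivityModel(sigma_l=2.0, sigma_t=1.0, f0=np.array([1.0, 1.0]))

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            ConductivityModel(sigma_l=1.0, sigma_t=0.0)

    def test_element_tensor_structure(self):
        g = Grid2D(3, 3, 1.0, 1.0)
        cm = ConductivityModel(sigma_l=2.0, sigma_t=0.5,
                               f0=np.array([0.0, 1.0]))
        D = cm.element_tensors(g)
        expect = np.array([[0.5, 0.0], [0.0, 2.0]])
        assert np.allclose(D, expect[None])

    def test_modulation_bounds(self):
        with pytest.raises(ValueError):
            ConductivityModel(sigma_l=1.0, sigma_t=1.0,
                              modulation=np.zeros(9))


class TestRestState:
    def test_zero_data_zero_forcing_stays_exactly_zero(self):
        g = Grid2D(6, 6, 1.0, 1.0)
        fom = MonodomainFOM(g, _isotropic(), ION, [])
        state = State(u=np.zeros(36), w=np.zeros(36))
        for _ in range(20):
            state = fom.step(state, 0.01)
        assert np.all(state.u == 0.0)
        assert np.all(state.w == 0.0)

    def test_zero_stimulus_trajectory_identically_zero(self, tiny_scenario):
        sc = tiny_scenario
        fom = MonodomainFOM(sc.grid, sc.conductivity_builder([5, 5], sc.grid),
                            sc.ionic_builder([5, 5]), stimuli=[])
        tg = TimeGrid(dt=0.1 / 12.9, T_ms=5.0, n_snapshots=5)
        res = fom.solve(tg)
        assert np.all(res["U"] == 0.0)


class TestSemiImplicitStep:
    def test_uniform_state_reduces_to_scalar_update(self):
        # constant u, w and spatially uniform stimulus: the stiffness term
        # vanishes and every node follows the hand scalar formula
        g = Grid2D(2, 2, 1.0, 1.0)
        stim = IndicatorStimulus(region=lambda xy: np.ones(len(xy), bool),
                                 amplitude=3.0, t_on_ms=0.0, t_off_ms=100.0)
        fom = MonodomainFOM(g, _isotropic(), ION, [stim])
        u0, w0, dt = 0.4, 0.2, 0.01
        state = fom.step(State(u=np.full(4, u0), w=np.full(4, w0)), dt)
        g_val = (ION.eps0 + ION.c1 * w0 / (ION.c2 + u0)) * (
            -w0 - ION.K * u0 * (u0 - ION.b - 1.0)
        )
        w1 = w0 + dt * g_val
        iion = ION.K * u0 * (u0 - ION.a) * (u0 - 1.0) + u0 * w1
        u1 = u0 - dt * iion + dt * 3.0
        assert np.allclose(state.w, w1, rtol=1e-14)
        assert np.allclose(state.u, u1, rtol=1e-12)

    @pytest.mark.parametrize("shape", [(3, 3), (4, 5), (5, 5)])
    def test_matches_dense_reference_step(self, shape, rng):
        nx, ny = shape
        Lx, Ly = 1.0, 1.3
        mod = 0.3 + 0.7 * rng.random(nx * ny)
        rho = rng.random(nx * ny)
        cm = ConductivityModel(sigma_l=2.0, sigma_t=1.0,
                               f0=np.array([1.0, 0.0]), modulation=mod)
        g = Grid2D(nx, ny, Lx, Ly)
        stim = GaussianStimulus(C=5.0, beta_cm2=0.3, center=(0.2, 0.2),
                                t_on_ms=0.0, t_off_ms=10.0)
        fom = MonodomainFOM(g, cm, ION, [stim], ionic_scaling=rho)
        u0 = rng.random(nx * ny)
        w0 = rng.random(nx * ny)
        dt = 0.01
        out = fom.step(State(u=u0.copy(), w=w0.copy(), t=0.0), dt)

        # independent dense path
        conn = g.elements()
        centers = g.coords()[conn].mean(axis=1)
        mod_e = mod[conn].mean(axis=1)
        base = np.array([[2.0, 0.0], [0.0, 1.0]])

        def tensor(cx, cy):
            k = np.argmin((centers[:, 0] - cx) ** 2 + (centers[:, 1] - cy) ** 2)
            return mod_e[k] * base

        M, A = dense_q1_operators(nx, ny, Lx, Ly, tensor)
        iapp = stim.profile(g.coords())
        u_ref, w_ref = dense_semi_implicit_step(u0, w0, M, A, ION, dt,
                                                iapp=iapp, rho=rho)
        assert np.allclose(out.w, w_ref, rtol=1e-12, atol=1e-14)
        assert np.allclose(out.u, u_ref, rtol=1e-12, atol=1e-12)


class TestReflectionSymmetry:
    def test_mirror_stimulus_isotropic_diffusion(self):
        n = 17
        g = Grid2D(n, n, 2.0, 2.0)
        stim = GaussianStimulus(C=20.0, beta_cm2=0.05, center=(1.0, 0.5),
                                t_on_ms=0.0, t_off_ms=2.0)
        fom = MonodomainFOM(g, _isotropic(0.05), ION, [stim])
        tg = TimeGrid(dt=0.2 / 12.9, T_ms=20.0, n_snapshots=4)
        res = fom.solve(tg)
        u = res["U"][:, -1].reshape(n, n)
        assert np.abs(u - u[:, ::-1]).max() < 1e-8
        assert u.max() > 0.1  # the wave actually developed


class TestSolveFom:
    def test_rejects_mu_outside_box(self, tiny_scenario):
        with pytest.raises(ValueError):
            solve_fom(tiny_scenario, [0.0, 0.0])

    def test_snapshot_labels_and_physio_bounds(self, tiny_scenario):
        sc = tiny_scenario
        snaps = solve_fom(sc, [5.0, 5.0], probes=np.array([[1.0, 1.0]]))
        assert snaps.S.shape == (sc.grid.n_nodes, 20)
        assert snaps.n_times == 20
        assert np.allclose(snaps.params, [5.0, 5.0])
        assert snaps.F is not None and snaps.F.shape == snaps.S.shape
        # dimensional potential after the stimulus transient: resting at
        # -80 mV, peak below +30 mV
        t_ms = snaps.times * 12.9
        late = snaps.S[:, t_ms > 5.0]
        u_mv = 100 * late - 80
        assert -80.5 < u_mv.min() < -79.0
        assert 0.0 < u_mv.max() < 30.0
        assert "probe_traces" in snaps.meta

    def test_nan_guard_triggers(self):
        g = Grid2D(4, 4, 1.0, 1.0)
        stim = IndicatorStimulus(region=lambda xy: np.ones(len(xy), bool),
                                 amplitude=1e150, t_on_ms=0.0,
                                 t_off_ms=1000.0)
        fom = MonodomainFOM(g, _isotropic(), ION, [stim])
        tg = TimeGrid(dt=0.5, T_ms=1300.0, n_snapshots=10)
        with pytest.raises(FloatingPointError):
            fom.solve(tg)


class TestSnapshotSet:
    def test_label_consistency_enforced(self):
        with pytest.raises(ValueError):
            SnapshotSet(S=np.zeros((4, 3)), times=np.zeros(3),
                        params=np.zeros((3, 1)), mu_list=np.zeros((2, 1)),
                        n_times=2)

    def test_concatenate_blocks(self):
        def make(mu):
            return SnapshotSet(S=np.full((4, 2), mu), times=np.array([0.1, 0.2]),
                               params=np.full((2, 1), mu),
                               mu_list=np.array([[mu]]), n_times=2)

        cat = SnapshotSet.concatenate([make(1.0), make(2.0)])
        assert cat.S.shape == (4, 4)
        assert np.allclose(cat.block(1), 2.0)
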