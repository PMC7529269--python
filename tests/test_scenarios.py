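import numpy as np
import pytest

from cardiorom.scenarios import (
    PRESETS,
    build_test1,
    build_test2,
    build_test4,
    get_scenario,
    ischemic_modulation,
    make_parameter_grid,
    ParameterGrid,
)


class TestIschemicModulation:
    def test_scar_center_floors_at_sigma0(self):
        rho, sigma = ischemic_modulation(np.array([5.0, 5.0]), (5.0, 5.0))
        assert rho == 0.0
        assert sigma == pytest.approx(1e-4)

    def test_healthy_tissue_limit(self):
        rho, sigma = ischemic_modulation(np.array([100.0, 100.0]), (5.0, 5.0))
        assert rho == pytest.approx(1.0)
        assert sigma == pytest.approx(1.0)

    def test_hand_value_one_cm_from_center(self):
        rho, _ = ischemic_modulation(np.array([6.0, 5.0]), (5.0, 5.0),
                                     alpha=7.0)
        assert rho == pytest.approx(1.0 - np.exp(-1.0 / 98.0), rel=1e-12)

    def test_ranges(self, rng):
        pts = rng.uniform(0, 10, size=(100, 2))
        rho, sigma = ischemic_modulation(pts, (5.0, 5.0))
        assert np.all((rho >= 0) & (rho < 1))
        assert np.all((sigma >= 1e-4) & (sigma <= 1))


class TestIschemicSlabPreset:
    def test_frozen_constants(self):
        sc = build_test1()
        assert sc.grid.n_nodes == 64 * 64
        assert sc.grid.Lx == sc.grid.Ly == 10.0
        assert sc.time.dt == pytest.approx(0.1 / 12.9)
        assert sc.time.T_ms == 400.0
        assert sc.time.n_snapshots == 1000
        assert np.allclose(sc.param_box, [[3.5, 6.5], [3.5, 6.5]])
        ion = sc.ionic_builder([5, 5])
        assert (ion.K, ion.a, ion.b, ion.eps0, ion.c1, ion.c2) == (
            8.0, 0.01, 0.15, 0.002, 0.2, 0.3)
        cond = sc.conductivity_builder(np.array([5.0, 5.0]), sc.grid)
        assert cond.sigma_l == pytest.approx(12.9 * 0.2)
        assert cond.sigma_t == pytest.approx(12.9 * 0.1)

    def test_parameter_lattices(self):
        sc = build_test1()
        assert sc.train_params.shape == (49, 2)
        assert np.allclose(sc.train_params[0], [3.5, 3.5])
        assert np.allclose(sc.train_params[-1], [6.5, 6.5])
        assert sc.test_params.shape == (36, 2)
        assert np.allclose(sc.test_params[0], [3.75, 3.75])

    def test_stimulus_window_and_amplitude(self):
        sc = build_test1()
        stim = sc.stimulus_builder([5, 5])[0]
        prof = stim.profile(np.array([[0.0, 0.0]]))
        assert prof[0] == pytest.approx(100.0)
        assert stim.is_active(1.0)
        assert not stim.is_active(3.0)


class TestReentryPreset:
    def test_frozen_constants(self):
        sc = build_test2("full")
        assert sc.grid.n_nodes == 256 * 256
        assert sc.grid.Lx == 2.0
        assert sc.time.dt == pytest.approx(0.2 / 12.9)
        assert sc.time.t_start_ms == 95.0
        assert sc.time.n_snapshots == 400
        ion = sc.ionic_builder([0.9])
        assert (ion.K, ion.a, ion.b, ion.eps0, ion.c1, ion.c2) == (
            8.0, 0.1, 0.1, 0.01, 0.14, 0.3)
        cond = sc.conductivity_builder(np.array([0.9]), sc.grid)
        assert cond.sigma_l == pytest.approx(2e-3)
        assert cond.sigma_t == pytest.approx(3.1e-4)

    def test_parameter_spaces_and_grids(self):
        full = build_test2("full")
        assert np.allclose(full.param_box, [[0.5, 1.1]])
        assert full.train_params.shape == (13, 1)
        assert full.test_params.shape == (12, 1)
        # test points are midpoints of consecutive training points
        mids = 0.5 * (full.train_params[:-1] + full.train_params[1:])
        assert np.allclose(full.test_params, mids)
        reentry = build_test2("reentry_only")
        assert np.allclose(reentry.param_box, [[0.8, 1.1]])

    def test_s1_s2_protocol_activity(self):
        sc = build_test2("full")
        mu = 0.9
        s1, s2 = sc.stimulus_builder([mu])
        # S1: bottom strip, [0, 5] ms
        assert s1.profile(np.array([[1.0, 0.05]]))[0] == 1.0
        assert s1.profile(np.array([[1.0, 0.5]]))[0] == 0.0
        assert s1.is_active(3.0) and not s1.is_active(6.0)
        # S2: disk of radius 0.2 at (1, mu), [70, 75] ms
        assert s2.profile(np.array([[1.0, mu]]))[0] == 1.0
        assert s2.profile(np.array([[1.0, mu + 0.3]]))[0] == 0.0
        assert s2.is_active(72.0) and not s2.is_active(60.0)


class TestRestitutionPreset:
    def test_training_lattice_as_printed(self):
        sc = build_test4()
        assert sc.train_params.shape == (125, 3)
        assert np.allclose(sc.train_params[0],
                           [12.9 * 0.06, 12.9 * 0.03, 0.15])
        assert np.allclose(sc.train_params[-1],
                           [12.9 * 0.2, 12.9 * 0.1, 0.25])
        assert sc.test_params.shape == (16, 3)
        assert np.allclose(sc.test_params[0],
                           [12.9 * 0.0775, 12.9 * 0.0387, 0.1625])

    def test_isotropic_when_conductivities_equal(self):
        sc = build_test4()
        g = sc.grid
        mu = np.array([1.5, 1.5, 0.2])
        D = sc.conductivity_builder(mu, g).element_tensors(g)
        assert np.allclose(D, 1.5 * np.eye(2)[None])

    def test_tensor_exact_when_mu1_below_mu2(self):
        sc = build_test4()
        g = sc.grid
        m1, m2 = 0.9, 1.2
        D = sc.conductivity_builder(np.array([m1, m2, 0.2]),
                                    g).element_tensors(g)
        expect = m2 * np.eye(2) + (m1 - m2) * np.outer([1, 0], [1, 0])
        assert np.allclose(D, expect[None])

    def test_mu3_replaces_restitution_coefficient(self):
        sc = build_test4()
        ion = sc.ionic_builder(np.array([1.0, 0.9, 0.2]))
        assert ion.c1 == 0.2  # same g as the ischemic preset at c1=0.2
        assert ion.eps0 == 0.002 and ion.c2 == 0.3


class TestParameterGrids:
    def test_lattice_single_point(self):
        pts = make_parameter_grid(np.array([[0.0, 1.0]]),
                                  {"kind": "lattice", "starts": [0.25],
                                   "steps": [0.0], "counts": [1]})
        assert np.allclose(pts, [[0.25]])

    def test_outside_box_rejected(self):
        with pytest.raises(ValueError):
            make_parameter_grid(np.array([[0.0, 1.0]]),
                                {"kind": "lattice", "starts": [0.5],
                                 "steps": [1.0], "counts": [2]})

    def test_seeded_sampling_deterministic(self):
        box = np.array([[0.0, 1.0], [2.0, 3.0]])
        spec = {"kind": "random", "n": 5, "seed": 42}
        a = make_parameter_grid(box, spec)
        b = make_parameter_grid(box, spec)
        assert np.array_equal(a, b)

    def test_train_test_overlap_rejected(self):
        with pytest.raises(ValueError):
            ParameterGrid(train=np.array([[1.0]]), test=np.array([[1.0]]))


class TestPresets:
    def test_registry_and_unknown_name(self):
        for name in ("test1", "test1-mini", "test2-full", "test2-reentry",
                     "test2-mini", "test4", "test4-mini"):
            assert name in PRESETS
        with pytest.raises(KeyError):
            get_scenario("nope")

    def test_mini_variant_scales(self):
        sc = get_scenario("test1-mini")
        assert sc.grid.n_nodes == 32 * 32
        assert sc.time.n_snapshots == 200
        assert sc.train_params.shape == (9, 2)
        assert sc.test_params.shape == (4, 2)

    def test_config_round_trip(self):
        sc = get_scenario("test1-mini", T_ms=100.0)
        cfg = sc.to_config()
        sc2 = get_scenario(cfg["preset"], **cfg["overrides"])
        assert sc2.time.T_ms == 100.0
        assert sc2.to_config() == cfg

    def test_contains(self):
        sc = get_scenario("test1-mini")
        assert sc.contains([5.0, 5.0])
        assert not sc.contains([2.0, 5.0])
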