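import numpy as np
import pytest

from dmrsmicro.forward import astrosticks_signal
from dmrsmicro.morphometric import (
    PARAM_NAMES,
    CellGraph,
    Dictionary,
    MorphometricParams,
    MorphometricRegressor,
    build_dictionary,
    generate_cell_graph,
    load_dictionary,
    predict_morphometry,
    save_dictionary,
    simulate_walkers,
    train_regressor,
)


def single_segment_graph(length, direction=(0.0, 0.0, 1.0)):
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    return CellGraph(
        nodes=np.array([-0.5 * length * d, 0.5 * length * d]),
        seg_node_a=np.array([0]), seg_node_b=np.array([1]),
        seg_length=np.array([float(length)]), seg_dir=d[None, :],
        generation=np.array([0]),
    )


class TestCellGraphGeneration:
    def test_same_seed_identical_graph(self):
        p = MorphometricParams(0.5, 4.0, 30.0, 2.0, 5.0)
        g1 = generate_cell_graph(p, seed=9)
        g2 = generate_cell_graph(p, seed=9)
        np.testing.assert_array_equal(g1.nodes, g2.nodes)
        np.testing.assert_array_equal(g1.seg_length, g2.seg_length)

    def test_binary_tree_structure(self):
        p = MorphometricParams(0.5, 3.0, 40.0, 2.0, 5.0)
        g = generate_cell_graph(p, seed=0)
        # acyclic connected tree: n_nodes = n_segments + 1
        assert len(g.nodes) == g.n_segments + 1
        assert np.all(g.seg_length > 0.5)
        # segment end positions consistent with node positions
        np.testing.assert_allclose(
            g.nodes[g.seg_node_b],
            g.seg_start + g.seg_length[:, None] * g.seg_dir,
            atol=1e-9,
        )

    def test_generation_count_governs_depth(self):
        # with a tight spread around N_branch = 2, most cells have 2
        # bifurcations per root-to-tip path (7 segments)
        p = MorphometricParams(0.5, 2.0, 50.0, 2.0, 5.0)
        depths = []
        for seed in range(30):
            g = generate_cell_graph(p, seed=seed)
            depths.append(g.generation.max())
        # truncation at >= 1 generation holds everywhere
        assert min(depths) >= 1
        # the mean realized depth tracks the requested mean within 2 SE
        se = 2.0 / np.sqrt(len(depths))
        assert abs(np.mean(depths) - 2.0) <= 3.0 * se + 1.0

    def test_segment_length_statistics_track_parameters(self):
        p = MorphometricParams(0.5, 6.0, 30.0, 2.0, 5.0)
        lengths = np.concatenate(
            [generate_cell_graph(p, seed=s).seg_length for s in range(20)]
        )
        se = 5.0 / np.sqrt(len(lengths))
        assert abs(np.mean(lengths) - 30.0) <= 3 * se

    def test_segment_cap_marks_truncation(self):
        p = MorphometricParams(0.5, 20.0, 10.0, 2.0, 5.0)
        g = generate_cell_graph(p, seed=1, max_segments=255)
        assert g.truncated
        assert g.n_segments <= 255

    def test_out_of_bounds_params_rejected(self):
        with pytest.raises(ValueError):
            MorphometricParams(0.05, 4.0, 30.0, 2.0, 5.0)
        with pytest.raises(ValueError):
            MorphometricParams(0.5, 4.0, 300.0, 2.0, 5.0)


class TestWalkerSimulation:
    def test_stick_limit_matches_astrosticks_two_point_adc(self, schemes):
        """A single very long segment is a stick: the powder two-point ADC
        must reproduce the analytical astrosticks value within MC error."""
        g = single_segment_graph(5000.0)
        res = simulate_walkers(g, 0.5, [schemes[100.0]], n_walkers=20000, seed=3)
        b0, b1 = schemes[100.0].b_pair
        expected = -np.log(
            astrosticks_signal(0.5, b1) / astrosticks_signal(0.5, b0)
        ) / (b1 - b0)
        assert res[100.0]["adc"] == pytest.approx(expected, rel=0.05)

    def test_short_segment_restricted_limit(self, schemes):
        """On an isolated 10 µm segment the ADC falls with diffusion time
        toward the fully restricted regime where displacement saturates."""
        g = single_segment_graph(10.0)
        sch = [schemes[t] for t in (100.0, 500.0, 1000.0)]
        res = simulate_walkers(g, 0.5, sch, n_walkers=20000, dt=0.05, seed=4)
        adcs = [res[t]["adc"] for t in (100.0, 500.0, 1000.0)]
        assert adcs[0] > adcs[1] > adcs[2]
        # narrow-pulse restricted oracle: var of the along-stick displacement
        # saturates at L²/6; powder-averaging over orientations gives a
        # further factor ~1/3 at small attenuation
        t_d = schemes[1000.0].t_d
        approx = 10.0**2 / 6.0 / (2.0 * t_d) / 3.0
        assert adcs[2] == pytest.approx(approx, rel=0.35)

    def test_monte_carlo_error_scales_inverse_sqrt(self, schemes):
        g = single_segment_graph(30.0)
        small, large = [], []
        for seed in range(12):
            small.append(
                simulate_walkers(g, 0.5, [schemes[500.0]], n_walkers=500, seed=seed)[500.0]["adc"]
            )
            large.append(
                simulate_walkers(g, 0.5, [schemes[500.0]], n_walkers=4000, seed=seed)[500.0]["adc"]
            )
        ratio = np.std(small) / np.std(large)
        expected = np.sqrt(4000 / 500)
        assert ratio == pytest.approx(expected, rel=0.6)

    def test_step_stability_guard(self, schemes):
        g = single_segment_graph(1.0)  # rms step at dt=0.5 exceeds L/5
        with pytest.raises(ValueError, match="step"):
            simulate_walkers(g, 0.5, [schemes[100.0]], n_walkers=100, seed=0)

    def test_adc_nonincreasing_in_diffusion_time_on_branched_graph(self, schemes):
        p = MorphometricParams(0.5, 4.0, 15.0, 2.0, 5.0)
        g = generate_cell_graph(p, seed=2, min_segment=2.5)
        sch = [schemes[t] for t in (100.0, 500.0, 750.0, 1000.0)]
        res = simulate_walkers(g, 0.5, sch, n_walkers=8000, dt=0.0625, seed=2)
        adcs = np.array([res[t]["adc"] for t in (100.0, 500.0, 750.0, 1000.0)])
        assert np.all(np.diff(adcs) <= 0.003)  # MC-noise tolerance


class TestDictionary:
    def test_single_entry_has_all_mixing_times(self, schemes):
        params = np.array([[0.5, 3.0, 20.0, 2.0, 5.0]])
        d = build_dictionary(params, n_walkers=1000, seed=0)
        assert d.n_entries == 1
        assert d.adcs.shape == (1, 4)
        assert np.all(np.isfinite(d.adcs))

    def test_interpolated_tm750_between_simulated_neighbors(self, small_dictionary):
        t_d = small_dictionary.t_d
        i750 = int(np.argmin(np.abs(t_d - 754.25)))
        i500 = int(np.argmin(np.abs(t_d - 504.25)))
        i1000 = int(np.argmin(np.abs(t_d - 1004.25)))
        lo = np.minimum(small_dictionary.adcs[:, i500], small_dictionary.adcs[:, i1000])
        hi = np.maximum(small_dictionary.adcs[:, i500], small_dictionary.adcs[:, i1000])
        assert np.all(small_dictionary.adcs[:, i750] >= lo - 1e-12)
        assert np.all(small_dictionary.adcs[:, i750] <= hi + 1e-12)

    def test_rebuild_is_bit_identical(self):
        params = np.array([[0.4, 3.0, 25.0, 2.5, 6.0], [0.7, 5.0, 12.0, 2.2, 8.0]])
        d1 = build_dictionary(params, n_walkers=800, seed=5)
        d2 = build_dictionary(params, n_walkers=800, seed=5)
        np.testing.assert_array_equal(d1.adcs, d2.adcs)

    def test_hdf5_roundtrip(self, small_dictionary, tmp_path):
        path = str(tmp_path / "dict.h5")
        save_dictionary(path, small_dictionary)
        back = load_dictionary(path)
        np.testing.assert_array_equal(back.adcs, small_dictionary.adcs)
        np.testing.assert_array_equal(back.params, small_dictionary.params)


class TestRegressor:
    def test_default_hyperparameters(self):
        reg = MorphometricRegressor()
        assert reg.n_trees == 200
        assert reg.max_depth == 20

    def test_training_entry_predicted_within_oob_band(self, small_dictionary):
        reg = train_regressor(small_dictionary)
        pred = reg.predict(small_dictionary.adcs[:5])
        err = (pred - small_dictionary.params[:5]) ** 2
        # memorization: training-entry error well inside the OOB error band
        assert np.all(err.mean(axis=0) <= 4.0 * reg.oob_mse_ + 1e-12)

    def test_predictions_respect_bounds(self, small_dictionary):
        reg = train_regressor(small_dictionary)
        rng = np.random.default_rng(0)
        noisy = small_dictionary.adcs + rng.normal(0, 0.05, small_dictionary.adcs.shape)
        pred = reg.predict(noisy)
        assert np.all(pred[:, 2] >= 5.0) and np.all(pred[:, 2] <= 100.0)
        assert np.all(pred[:, 0] >= 0.1) and np.all(pred[:, 0] <= 1.0)

    def test_wrong_grid_rejected(self, small_dictionary):
        reg = train_regressor(small_dictionary)
        with pytest.raises(ValueError):
            reg.predict(small_dictionary.adcs[0], t_d=np.array([1.0, 2.0, 3.0, 4.0]))
        with pytest.raises(ValueError):
            reg.predict(np.ones(3))

    def test_missing_value_imputed_and_flagged(self, small_dictionary):
        reg = train_regressor(small_dictionary)
        vec = small_dictionary.adcs[0].copy()
        vec[1] = np.nan
        params = predict_morphometry(reg, vec)
        assert reg.imputed_[0]
        assert isinstance(params, MorphometricParams)

    def test_too_small_dictionary_rejected(self, small_dictionary):
        tiny = Dictionary(
            params=small_dictionary.params[:10],
            adcs=small_dictionary.adcs[:10],
            t_d=small_dictionary.t_d,
        )
        with pytest.raises(ValueError):
            train_regressor(tiny)

    def test_param_names_order(self):
        assert PARAM_NAMES == ("D_intra", "N_branch", "L_segment", "SDN_branch", "SDL_segment")
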