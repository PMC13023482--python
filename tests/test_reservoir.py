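"""LIF dynamics, STDP rule, and cube training."""

import numpy as np
import pytest
import scipy.sparse as sp

from braincube.core import SpikeRaster
from braincube.reservoir import (
    LIFConfig,
    STDPParams,
    simulate,
    stdp_delta,
    train_cube,
)
from braincube.template import BrainTemplate, CubeModel, InputMapping


def _micro_cube(weights, signs=None):
    """Cube with explicit dense weights (tiny hand-built circuits)."""
    n = weights.shape[0]
    coords = np.zeros((n, 3))
    coords[:, 0] = np.arange(n)
    labels = np.array(["OTHER"] * n, dtype=object)
    signs = np.ones(n) if signs is None else np.asarray(signs)
    return CubeModel(BrainTemplate(coords, labels), sp.csr_matrix(weights), signs)


def _mapping(channels, neurons):
    return InputMapping(np.asarray(neurons), [f"in{i}" for i in range(channels)],
                        ["OTHER"] * channels)


class TestSTDPDelta:
    def test_hand_evaluated_branches(self):
        p = STDPParams(A_plus=0.01, A_minus=0.02, tau_plus=2.0, tau_minus=3.0)
        # pre just before post: approaches +A_plus
        assert abs(stdp_delta(9.999, 10.0, p) - 0.01 * np.exp(-0.001 / 2.0)) < 1e-15
        # pre lagging post by exactly tau_minus: -A_minus * e^-1
        assert abs(stdp_delta(13.0, 10.0, p) - (-0.02 * np.exp(-1.0))) < 1e-15
        # coincidence convention: +A_plus
        assert stdp_delta(5.0, 5.0, p) == p.A_plus
        # hand value: pre 2 steps before post
        assert abs(stdp_delta(8.0, 10.0, p) - 0.01 * np.exp(-1.0)) < 1e-15

    def test_decay_to_zero_both_sides(self):
        p = STDPParams()
        assert abs(stdp_delta(0.0, 1e6, p)) < 1e-300
        assert abs(stdp_delta(1e6, 0.0, p)) < 1e-300

    def test_non_finite_times_rejected(self):
        with pytest.raises(ValueError):
            stdp_delta(np.nan, 0.0, STDPParams())


class TestSimulate:
    def test_zero_input_is_quiescent(self):
        cube = _micro_cube(np.array([[0.0, 0.3], [0.0, 0.0]]))
        before = cube.weights.toarray().copy()
        raster = SpikeRaster(np.zeros((1, 20), dtype=int), "ternary")
        act = simulate(cube, raster, _mapping(1, [0]), mode="train")
        assert act.raster.spikes.sum() == 0
        np.testing.assert_array_equal(cube.weights.toarray(), before)

    @pytest.mark.parametrize("refractory", [0, 1, 3])
    def test_driven_neuron_fires_at_refractory_limited_rate(self, refractory):
        """Closed form: a neuron driven supra-threshold every step fires with
        period refractory + 1 (verified against a brute-force scalar LIF)."""
        cube = _micro_cube(np.zeros((2, 2)))
        lif = LIFConfig(threshold=0.5, input_gain=0.6, refractory_steps=refractory)
        T = 20
        raster = SpikeRaster(np.ones((1, T), dtype=int), "ternary")
        act = simulate(cube, raster, _mapping(1, [0]), mode="recall", lif=lif)
        spikes = act.raster.spikes[0]
        # brute-force one-neuron oracle
        v, ref, expected = 0.0, 0, []
        for t in range(T):
            v = lif.leak_decay * v + 0.6
            if ref > 0:
                v = 0.0
                ref -= 1
                expected.append(0)
            elif v >= 0.5:
                expected.append(1)
                v = 0.0
                ref = refractory
            else:
                expected.append(0)
        np.testing.assert_array_equal(spikes, expected)
        assert spikes.sum() == len([e for e in expected if e])
        # period check
        fire_times = np.flatnonzero(spikes)
        if len(fire_times) > 1:
            assert np.all(np.diff(fire_times) == refractory + 1)

    def test_negative_input_spikes_inject_negative_current(self):
        cube = _micro_cube(np.zeros((1, 1)))
        raster = SpikeRaster(-np.ones((1, 10), dtype=int), "ternary")
        act = simulate(cube, raster, _mapping(1, [0]), mode="recall")
        assert act.raster.spikes.sum() == 0

    def test_recall_is_deterministic_and_frozen(self, tiny_dataset):
        rng = np.random.default_rng(0)
        n = 30
        W = sp.random(n, n, density=0.2, random_state=1, data_rvs=lambda k: rng.uniform(0.2, 0.6, k)).tolil()
        W.setdiag(0)
        cube = _micro_cube(W.tocsr().toarray())
        spikes = (rng.random((5, 40)) < 0.3).astype(int)
        raster = SpikeRaster(spikes, "ternary")
        mapping = _mapping(5, [0, 1, 2, 3, 4])
        before = cube.weights.toarray().copy()
        a = simulate(cube, raster, mapping, mode="recall")
        b = simulate(cube, raster, mapping, mode="recall")
        np.testing.assert_array_equal(a.raster.spikes, b.raster.spikes)
        np.testing.assert_array_equal(cube.weights.toarray(), before)

    def test_nan_potential_reports_step(self):
        cube = _micro_cube(np.array([[0.0, np.inf], [0.0, 0.0]]))
        raster = SpikeRaster(np.ones((1, 5), dtype=int), "ternary")
        with pytest.raises(FloatingPointError, match="step"):
            simulate(cube, raster, _mapping(1, [0]), mode="recall")

    def test_mapping_channel_mismatch_rejected(self):
        cube = _micro_cube(np.zeros((2, 2)))
        raster = SpikeRaster(np.ones((2, 5), dtype=int), "ternary")
        with pytest.raises(ValueError, match="channels"):
            simulate(cube, raster, _mapping(1, [0]), mode="recall")


class TestSTDPLearning:
    def _two_neuron(self, w=0.3):
        return _micro_cube(np.array([[0.0, w], [0.0, 0.0]]))

    def test_pre_before_post_potentiates(self):
        """Drive neuron 0 then neuron 1 one step later: the 0->1 weight
        grows (LTP branch)."""
        cube = self._two_neuron()
        spikes = np.zeros((2, 30), dtype=int)
        spikes[0, ::4] = 1
        spikes[1, 1::4] = 1
        raster = SpikeRaster(spikes, "ternary")
        simulate(cube, raster, _mapping(2, [0, 1]), mode="train",
                 lif=LIFConfig(input_gain=0.6))
        assert cube.weights[0, 1] > 0.3

    def test_post_before_pre_depresses(self):
        cube = self._two_neuron()
        spikes = np.zeros((2, 30), dtype=int)
        spikes[1, ::4] = 1
        spikes[0, 1::4] = 1
        raster = SpikeRaster(spikes, "ternary")
        simulate(cube, raster, _mapping(2, [0, 1]), mode="train",
                 lif=LIFConfig(input_gain=0.6))
        assert cube.weights[0, 1] < 0.3

    def test_sign_class_and_clip_preserved(self, small_cube, tiny_dataset):
        from braincube.encoding import SFConfig, sf_encode
        from braincube.features import synchronise
        from braincube.template import tonotopic_map, topographic_map, concat_mappings

        cube = CubeModel(small_cube.template, small_cube.weights.copy(),
                         small_cube.neuron_sign)
        mapping = concat_mappings(tonotopic_map(cube.template, 40),
                                  topographic_map(cube.template))
        rasters = []
        for audio, visual, _ in tiny_dataset[:3]:
            series = synchronise(audio, visual)
            rasters.append(sf_encode(series, SFConfig(theta_rule="k_times_sd", k=0.5))[0])
        before = cube.weights.copy()
        stdp = STDPParams(w_max=1.0)
        train_cube(cube, rasters, mapping, stdp=stdp)
        after = cube.weights
        # learning occurred
        assert np.abs((after - before).toarray()).max() > 0
        # sparsity pattern unchanged
        np.testing.assert_array_equal((after != 0).toarray() | (before != 0).toarray(),
                                      (before != 0).toarray())
        # sign class per pre-synaptic neuron, magnitude clip
        arr = after.toarray()
        assert np.abs(arr).max() <= stdp.w_max + 1e-12
        for i in range(cube.n_neurons):
            if cube.neuron_sign[i] > 0:
                assert arr[i].min() >= 0
            else:
                assert arr[i].max() <= 0

    def test_empty_dataset_rejected(self, small_cube):
        with pytest.raises(ValueError):
            train_cube(small_cube, [], _mapping(1, [0]))


def test_lif_config_validation():
    with pytest.raises(ValueError):
        LIFConfig(leak_decay=0.0)
    with pytest.raises(ValueError):
        LIFConfig(threshold=0.0, reset_potential=0.0)
    with pytest.raises(ValueError):
        STDPParams(A_plus=0.0)
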