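"""Tests for the windowed LSTM decoder: input combos, window assembly,
gradients, training behavior and forearm-angle estimation."""

import numpy as np
import pytest

from synspace import (
    ScenarioSpec,
    TrainedDecoder,
    build_windows,
    estimate_forearm,
    extract,
    predict,
    scenario_grid,
    select_inputs,
    train,
)
from synspace.decoder import WindowedDataset, _LSTMNetwork, make_target_sequences
from synspace.preprocessing import fit_normalization
from synspace._common import FOREARM_IDX


class TestSelectInputs:
    @pytest.mark.parametrize(
        "combo,expected",
        [
            (2, ("SH_y", "SH_z")),
            (3, ("SH_x", "SH_y", "SH_z")),
            (4, ("SH_y", "SH_z", "dSH_y", "dSH_z")),
            (6, ("SH_x", "SH_y", "SH_z", "dSH_x", "dSH_y", "dSH_z")),
        ],
    )
    def test_published_combinations(self, combo, expected):
        assert select_inputs(combo) == expected

    def test_three_adds_internal_external_rotation(self):
        assert set(select_inputs(3)) - set(select_inputs(2)) == {"SH_x"}

    def test_invalid_combo_rejected(self):
        with pytest.raises(ValueError):
            select_inputs(5)

    def test_full_grid_has_36_scenarios(self):
        grid = scenario_grid()
        assert len(grid) == 36
        assert len(set(grid)) == 36


class TestBuildWindows:
    def test_window_counts(self):
        for T, expected in [(10, 1), (150, 141)]:
            ds = build_windows(
                [np.zeros((T, 3))], [np.zeros((T, 2))], window=10
            )
            assert ds.n_examples == expected

    def test_windows_never_cross_movement_boundaries(self):
        """Brute-force enumeration: every window's content comes from a
        single movement."""
        rng = np.random.default_rng(0)
        movements = [rng.normal(size=(t, 2)) for t in (25, 14, 31)]
        targets = [m[:, :1] for m in movements]
        ds = build_windows(movements, targets, window=10)
        expected = []
        for m in movements:
            for i in range(m.shape[0] - 9):
                expected.append(m[i : i + 10])
        assert ds.n_examples == len(expected)
        for got, want in zip(ds.inputs, expected):
            assert np.array_equal(got, want)

    def test_target_aligned_to_window_end(self):
        feats = np.arange(20, dtype=float).reshape(20, 1)
        ds = build_windows([feats], [feats.copy()], window=10)
        assert np.array_equal(ds.targets[:, 0], feats[9:, 0])

    def test_short_movements_skipped_and_empty_rejected(self):
        ds = build_windows(
            [np.zeros((4, 2)), np.zeros((12, 2))],
            [np.zeros((4, 1)), np.zeros((12, 1))],
            window=10,
        )
        assert ds.n_examples == 3
        with pytest.raises(ValueError, match="shorter than the window"):
            build_windows([np.zeros((4, 2))], [np.zeros((4, 1))], window=10)


class TestLSTMGradients:
    def test_backprop_matches_numeric_gradient(self):
        """Analytic BPTT gradients agree with central finite differences
        on a tiny two-layer network."""
        rng = np.random.default_rng(11)
        net = _LSTMNetwork(
            n_features=3, n_hidden=4, n_layers=2, n_outputs=2, dropout=0.0, rng=rng
        )
        x = rng.normal(size=(5, 6, 3))
        y = rng.normal(size=(5, 2))

        def loss():
            return float(np.mean((net.forward(x, train=True, rng=rng) - y) ** 2))

        pred = net.forward(x, train=True, rng=rng)
        grads = net.backward(2.0 * (pred - y) / (pred - y).size)
        params = net.params
        eps = 1e-6
        for p, g in zip(params, grads):
            flat = p.ravel()
            for idx in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                original = flat[idx]
                flat[idx] = original + eps
                up = loss()
                flat[idx] = original - eps
                down = loss()
                flat[idx] = original
                numeric = (up - down) / (2 * eps)
                assert g.ravel()[idx] == pytest.approx(numeric, abs=1e-6, rel=1e-4)


def _toy_dataset(rng, n=200, window=10, n_features=3, n_outputs=2, zero=False):
    feats = rng.normal(size=(n + window - 1, n_features))
    if zero:
        targets = np.zeros((n + window - 1, n_outputs))
    else:
        mix = rng.normal(size=(n_features, n_outputs))
        targets = feats @ mix * 0.3
    return build_windows([feats], [targets], window)


def _scenario(**kw):
    base = dict(
        methodology="direct",
        n_hidden_layers=1,
        input_combo=3,
        hidden_units=8,
        epochs=15,
        learning_rate=0.02,
        early_stopping_patience=0,
        seed=3,
    )
    base.update(kw)
    return ScenarioSpec(**base)


class TestTraining:
    def test_zero_targets_learned(self, rng):
        ds = _toy_dataset(rng, zero=True)
        decoder = train(ds, _scenario())
        pred = decoder.network.forward(ds.inputs, train=False)
        assert np.mean(pred**2) < 1e-4

    def test_same_seed_reproduces_final_loss(self, rng):
        ds = _toy_dataset(rng)
        a = train(ds, _scenario())
        b = train(ds, _scenario())
        assert abs(a.final_loss - b.final_loss) < 1e-6
        assert a.final_loss == b.final_loss  # fully deterministic backend

    def test_loss_decreases_on_learnable_mapping(self, rng):
        ds = _toy_dataset(rng)
        decoder = train(ds, _scenario(epochs=25))
        losses = decoder.history["train_loss"]
        assert losses[-1] < 0.2 * losses[0]

    def test_output_dimension_contract(self, rng):
        """two_synergy trains 2 outputs, one_synergy 1, direct 2."""
        for methodology, n_out in [("two_synergy", 2), ("one_synergy", 1), ("direct", 2)]:
            ds = _toy_dataset(rng, n=40, n_outputs=n_out)
            decoder = train(ds, _scenario(methodology=methodology, epochs=1))
            pred = predict(decoder, [np.zeros((12, 3))])
            assert pred[0].shape == (3, n_out)
        with pytest.raises(ValueError, match="outputs"):
            train(_toy_dataset(rng, n=30, n_outputs=1), _scenario(epochs=1))


class TestPredict:
    def test_deterministic_and_shaped(self, rng):
        ds = _toy_dataset(rng, n=60)
        decoder = train(ds, _scenario(epochs=2))
        feats = [rng.normal(size=(30, 3)), rng.normal(size=(15, 3))]
        a = predict(decoder, feats)
        b = predict(decoder, feats)
        assert [p.shape for p in a] == [(21, 2), (6, 2)]
        for pa, pb in zip(a, b):
            assert np.array_equal(pa, pb)

    def test_feature_count_mismatch_rejected(self, rng):
        ds = _toy_dataset(rng, n=30)
        decoder = train(ds, _scenario(epochs=1))
        with pytest.raises(ValueError, match="channels"):
            predict(decoder, [np.zeros((20, 5))])

    def test_overfit_run_predicts_training_targets(self, rng):
        ds = _toy_dataset(rng, n=150)
        decoder = train(ds, _scenario(epochs=40))
        pred = decoder.network.forward(ds.inputs, train=False)
        train_rmse = np.sqrt(np.mean((pred - ds.targets) ** 2))
        assert train_rmse <= np.sqrt(decoder.final_loss) * 1.5 + 1e-6


class _StubNetwork:
    """Replays precomputed outputs; stands in for a perfectly trained
    network when testing the reconstruction arithmetic in isolation."""

    def __init__(self, outputs):
        self._outputs = list(outputs)

    def forward(self, x, train=False, rng=None):
        return self._outputs.pop(0)


class TestEstimateForearm:
    def _records_and_trial(self, rng):
        angles = rng.uniform(-40, 70, size=(5, 60))
        return fit_normalization([angles]), angles

    def test_direct_with_perfect_outputs_recovers_truth(self, rng):
        record, angles = self._records_and_trial(rng)
        window = 10
        normalized = record.apply(angles)
        truth_windows = normalized[FOREARM_IDX, window - 1 :].T
        decoder = TrainedDecoder(
            scenario=_scenario(methodology="direct", epochs=1, input_combo=2),
            network=_StubNetwork([truth_windows]),
            history={"train_loss": [0.0]},
            angle_record=record,
        )
        feats = [normalized[1:3].T]  # SH_y, SH_z
        out = estimate_forearm(decoder, feats)
        assert np.allclose(out[0], angles[FOREARM_IDX, window - 1 :].T, atol=1e-9)

    def test_two_synergy_with_true_activations_matches_truncation(self, rng):
        """Feeding the true activation signals through the synergy
        matrix reproduces the forearm channels up to the 2-component
        truncation error; exactly, on a rank-2 source."""
        w = np.linalg.qr(rng.normal(size=(5, 2)))[0]
        latent = rng.normal(size=(2, 80))
        normalized = np.tanh(w @ latent * 0.4)  # keep inside [-1, 1]
        record = fit_normalization([np.vstack([normalized * 30 + 5])])
        source = record.apply(normalized * 30 + 5)
        decomp = extract(source)
        window = 10
        cp = decomp.activations[:2, window - 1 :].T
        decoder = TrainedDecoder(
            scenario=_scenario(methodology="two_synergy", epochs=1, input_combo=2),
            network=_StubNetwork([cp]),
            history={"train_loss": [0.0]},
            angle_record=record,
            decomposition=decomp,
        )
        out = estimate_forearm(decoder, [source[1:3].T])
        truncated = (
            decomp.channel_means[:, None] + decomp.loadings[:, :2] @ decomp.activations[:2]
        )
        expected = record.invert(truncated[FOREARM_IDX], rows=FOREARM_IDX).T[window - 1 :]
        assert np.allclose(out[0], expected, atol=1e-9)
        full_error = np.max(np.abs(truncated - source))
        actual = record.invert(source[FOREARM_IDX], rows=FOREARM_IDX).T[window - 1 :]
        scale = np.max(record.maxs - record.mins) / 2
        assert np.max(np.abs(out[0] - actual)) <= full_error * scale + 1e-9

    def test_missing_synergy_rejected(self, rng):
        decoder = TrainedDecoder(
            scenario=_scenario(methodology="two_synergy", epochs=1, input_combo=2),
            network=_StubNetwork([]),
            history={"train_loss": [0.0]},
            angle_record=fit_normalization([rng.normal(size=(5, 30))]),
        )
        with pytest.raises(ValueError, match="synergy"):
            estimate_forearm(decoder, [np.zeros((20, 2))])


class TestTrueBasisReconstruction:
    def test_true_basis_matches_estimated_w_within_ten_percent(self):
        """Substituting the generator's true basis (mapped to normalized
        space) for the estimated synergy matrix at reconstruction
        changes the validation RMSE by at most 10% plus the estimated
        route's error, across 5 seeds."""
        from synspace.experiment import build_subject_artifacts, train_scenario
        from synspace.evaluation import evaluate_decoder
        from synspace.synergy import SynergyDecomposition
        from synspace.synthetic_motion import generate_cohort
        from tests.conftest import small_experiment_config
        from dataclasses import replace as dc_replace

        worse = 0
        for seed in range(5):
            config = small_experiment_config(
                cohort=dict(seed=seed), epochs=8, hidden_units=12, master_seed=seed
            )
            truth, training, validation = generate_cohort(config.cohort)[0]
            art = build_subject_artifacts(truth, training, validation, config)
            decoder = train_scenario(art, config.scenario("two_synergy", 2, 6, seed))
            estimated = evaluate_decoder(decoder, art.data).pooled_rmse

            scale = 2.0 / (art.angle_record.maxs - art.angle_record.mins)
            q, _ = np.linalg.qr(truth.true_basis * scale[:, None])
            # orient the true-basis columns like the estimated loadings
            for k in range(2):
                if q[:, k] @ art.decomp_full.loadings[:, k] < 0:
                    q[:, k] = -q[:, k]
            true_decomp = SynergyDecomposition(
                loadings=q,
                activations=np.zeros((2, 1)),
                channel_means=art.decomp_full.channel_means,
                variance_fraction=np.array([0.8, 0.2]),
                n_retained=2,
            )
            substituted = dc_replace(art.data, decomp_full=true_decomp)
            with_truth = evaluate_decoder(decoder, substituted).pooled_rmse
            worse += with_truth > estimated * 1.1
        assert worse <= 2  # majority of seeds within the 10% band


class TestTargetSequences:
    def test_direct_targets_are_normalized_forearm(self, rng):
        from synspace.preprocessing import MotionTrial

        angles = rng.uniform(-30, 50, size=(5, 40))
        trial = MotionTrial("t", 0, angles, 120.0)
        record = fit_normalization([trial])
        targets = make_target_sequences([trial], "direct", record)
        assert np.allclose(targets[0], record.apply(angles)[FOREARM_IDX].T)

    def test_synergy_targets_are_projections(self, rng):
        from synspace.preprocessing import MotionTrial
        from synspace.synergy import project

        angles = rng.uniform(-30, 50, size=(5, 40))
        trial = MotionTrial("t", 0, angles, 120.0)
        record = fit_normalization([trial])
        decomp = extract(record.apply(angles))
        targets = make_target_sequences([trial], "two_synergy", record, decomp)
        expected = project(record.apply(angles), decomp, 2).T
        assert np.allclose(targets[0], expected)
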