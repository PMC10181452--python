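"""Windowed recurrent regression of activation signals from shoulder input.

A stacked long short-term-memory (LSTM) network, implemented directly in
NumPy (forward pass, backpropagation through time, Adam, inverted
dropout between layers), maps windows of the ten previous time steps of
normalized shoulder kinematics to either synergy activation signals
(synergy-space methodologies) or normalized forearm angles (direct
estimation).  The implementation is deliberately dependency-free and
fully deterministic under a seed: identical seeds give bit-identical
training runs on one thread.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np

from ._common import CHANNELS, FOREARM_IDX, VELOCITY_CHANNELS
from .preprocessing import MotionTrial, NormalizationRecord, angular_velocities
from .synergy import SynergyDecomposition, project

__all__ = [
    "METHODOLOGIES",
    "ScenarioSpec",
    "WindowedDataset",
    "TrainedDecoder",
    "TrainingError",
    "select_inputs",
    "build_windows",
    "make_feature_sequences",
    "make_target_sequences",
    "train",
    "predict",
    "estimate_forearm",
    "scenario_grid",
]

METHODOLOGIES = ("two_synergy", "one_synergy", "direct")

_INPUT_COMBOS: dict[int, tuple[str, ...]] = {
    2: ("SH_y", "SH_z"),
    3: ("SH_x", "SH_y", "SH_z"),
    4: ("SH_y", "SH_z", "dSH_y", "dSH_z"),
    6: ("SH_x", "SH_y", "SH_z", "dSH_x", "dSH_y", "dSH_z"),
}

_N_OUTPUTS = {"two_synergy": 2, "one_synergy": 1, "direct": 2}


class TrainingError(RuntimeError):
    """Raised when the loss becomes non-finite; carries the history."""

    def __init__(self, message: str, history: list[float]):
        super().__init__(message)
        self.history = history


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the methodology x depth x input-combination grid."""

    methodology: str
    n_hidden_layers: int = 2
    input_combo: int = 6
    window: int = 10
    hidden_units: int = 64
    dropout: float = 0.10
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 0.005
    early_stopping_patience: int = 10
    validation_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.methodology not in METHODOLOGIES:
            raise ValueError(f"unknown methodology {self.methodology!r}")
        if self.n_hidden_layers not in (1, 2, 3):
            raise ValueError("n_hidden_layers must be 1, 2 or 3")
        if self.input_combo not in _INPUT_COMBOS:
            raise ValueError(f"input_combo must be one of {sorted(_INPUT_COMBOS)}")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.window < 1:
            raise ValueError("window must be positive")

    @property
    def n_outputs(self) -> int:
        return _N_OUTPUTS[self.methodology]

    @property
    def input_channels(self) -> tuple[str, ...]:
        return _INPUT_COMBOS[self.input_combo]


def select_inputs(combo: int) -> tuple[str, ...]:
    """Ordered input channel names for a given input-count scenario."""
    try:
        return _INPUT_COMBOS[combo]
    except KeyError:
        raise ValueError(
            f"input combo must be one of {sorted(_INPUT_COMBOS)}, got {combo}"
        ) from None


@dataclass
class WindowedDataset:
    """Sliding-window supervised examples that never span a movement
    boundary: example i of a movement covers samples [i, i + window) and
    its target is the sample at the window's final time step."""

    inputs: np.ndarray   # (n_examples, window, n_features)
    targets: np.ndarray  # (n_examples, n_outputs)
    movement_slices: list[slice] = field(default_factory=list)

    @property
    def n_examples(self) -> int:
        return self.inputs.shape[0]


def build_windows(
    features: list[np.ndarray], targets: list[np.ndarray], window: int
) -> WindowedDataset:
    """Assemble windows per movement from time-aligned (T_i, F) feature
    and (T_i, O) target sequences.  Movements shorter than the window
    contribute nothing; an entirely empty result is an error."""
    if len(features) != len(targets):
        raise ValueError("features and targets must pair up per movement")
    xs, ys, slices = [], [], []
    cursor = 0
    for f, t in zip(features, targets):
        f = np.asarray(f, float)
        t = np.asarray(t, float)
        if f.shape[0] != t.shape[0]:
            raise ValueError("feature/target sequences must be time-aligned")
        T = f.shape[0]
        if T < window:
            continue
        n = T - window + 1
        idx = np.arange(window)[None, :] + np.arange(n)[:, None]
        xs.append(f[idx])
        ys.append(t[window - 1 :])
        slices.append(slice(cursor, cursor + n))
        cursor += n
    if not xs:
        raise ValueError(f"all movements are shorter than the window ({window})")
    return WindowedDataset(
        inputs=np.concatenate(xs, axis=0),
        targets=np.concatenate(ys, axis=0),
        movement_slices=slices,
    )


def make_feature_sequences(
    trials: list[MotionTrial],
    combo: int,
    angle_record: NormalizationRecord,
    velocity_record: NormalizationRecord | None = None,
) -> list[np.ndarray]:
    """Normalized (T, F) input sequences for each filtered trial.

    Angle channels come from ``angle_record``; velocity channels (dSH_*)
    are central-difference shoulder velocities normalized with their own
    record, which is required whenever the combo includes them.
    """
    names = select_inputs(combo)
    needs_velocity = any(n in VELOCITY_CHANNELS for n in names)
    if needs_velocity and velocity_record is None:
        raise ValueError(f"input combo {combo} needs a velocity normalization record")
    out = []
    for trial in trials:
        normalized = angle_record.apply(trial.angles)
        rows = []
        vel = None
        for name in names:
            if name in CHANNELS:
                rows.append(normalized[CHANNELS.index(name)])
            else:
                if vel is None:
                    vel = velocity_record.apply(angular_velocities(trial))
                rows.append(vel[VELOCITY_CHANNELS.index(name)])
        out.append(np.vstack(rows).T)
    return out


def make_target_sequences(
    trials: list[MotionTrial],
    methodology: str,
    angle_record: NormalizationRecord,
    decomposition: SynergyDecomposition | None = None,
) -> list[np.ndarray]:
    """(T, O) training targets per trial for the given methodology.

    Synergy methodologies project each normalized trial through the
    stored decomposition (full five-channel for two synergies,
    forearm-only for one synergy); direct estimation uses the normalized
    forearm channels themselves.
    """
    if methodology not in METHODOLOGIES:
        raise ValueError(f"unknown methodology {methodology!r}")
    out = []
    for trial in trials:
        normalized = angle_record.apply(trial.angles)
        if methodology == "direct":
            out.append(normalized[FOREARM_IDX].T)
            continue
        if decomposition is None:
            raise ValueError(f"{methodology} targets need a synergy decomposition")
        if methodology == "two_synergy":
            out.append(project(normalized, decomposition, 2).T)
        else:  # one_synergy: decomposition of the two forearm channels only
            out.append(project(normalized[FOREARM_IDX], decomposition, 1).T)
    return out


# ---------------------------------------------------------------------------
# NumPy LSTM
# ---------------------------------------------------------------------------


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class _LSTMLayer:
    """Single LSTM layer with gate order (input, forget, cell, output)."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        H = n_hidden
        limit = np.sqrt(6.0 / (n_in + 4 * H))
        self.wx = rng.uniform(-limit, limit, size=(n_in, 4 * H))
        self.wh = rng.uniform(-limit, limit, size=(H, 4 * H))
        self.b = np.zeros(4 * H)
        self.b[H : 2 * H] = 1.0  # forget-gate bias init
        self.n_hidden = H

    @property
    def params(self) -> list[np.ndarray]:
        return [self.wx, self.wh, self.b]

    def forward(self, x: np.ndarray, train: bool = False):
        """x: (B, T, F) -> outputs (B, T, H); caches activations if train."""
        B, T, _ = x.shape
        H = self.n_hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.empty((B, T, H))
        cache = [] if train else None
        for t in range(T):
            z = x[:, t] @ self.wx + h @ self.wh + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_prev = c
            c = f * c_prev + i * g
            tanh_c = np.tanh(c)
            h_prev = h
            h = o * tanh_c
            hs[:, t] = h
            if train:
                cache.append((x[:, t], h_prev, c_prev, i, f, g, o, tanh_c))
        self._cache = cache
        return hs

    def backward(self, dhs: np.ndarray):
        """dhs: (B, T, H) gradient on the outputs; returns (dx, grads)."""
        cache = self._cache
        B, T, H = dhs.shape
        dwx = np.zeros_like(self.wx)
        dwh = np.zeros_like(self.wh)
        db = np.zeros_like(self.b)
        dx = np.empty((B, T, self.wx.shape[0]))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tanh_c = cache[t]
            dh = dhs[:, t] + dh_next
            do = dh * tanh_c
            dc = dc_next + dh * o * (1.0 - tanh_c**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dwx += x_t.T @ dz
            dwh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ self.wx.T
            dh_next = dz @ self.wh.T
            dc_next = dc * f
        self._cache = None
        return dx, [dwx, dwh, db]


class _LSTMNetwork:
    """Stacked LSTM layers with a linear head on the final hidden state."""

    def __init__(
        self,
        n_features: int,
        n_hidden: int,
        n_layers: int,
        n_outputs: int,
        dropout: float,
        rng: np.random.Generator,
    ):
        self.layers = []
        n_in = n_features
        for _ in range(n_layers):
            self.layers.append(_LSTMLayer(n_in, n_hidden, rng))
            n_in = n_hidden
        limit = np.sqrt(6.0 / (n_hidden + n_outputs))
        self.wo = rng.uniform(-limit, limit, size=(n_hidden, n_outputs))
        self.bo = np.zeros(n_outputs)
        self.dropout = dropout

    @property
    def params(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        out.extend([self.wo, self.bo])
        return out

    def forward(
        self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        h = x
        self._masks = []
        for layer in self.layers:
            h = layer.forward(h, train=train)
            if train and self.dropout > 0:
                mask = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
                h = h * mask
                self._masks.append(mask)
            else:
                self._masks.append(None)
        self._h_last = h[:, -1]
        return self._h_last @ self.wo + self.bo

    def backward(self, dy: np.ndarray) -> list[np.ndarray]:
        """dy: (B, O) gradient of the loss w.r.t. the output."""
        dwo = self._h_last.T @ dy
        dbo = dy.sum(axis=0)
        B, O = dy.shape
        grads_rev = [dwo, dbo]
        dh_seq = None
        dh_last = dy @ self.wo.T
        for layer, mask in zip(reversed(self.layers), reversed(self._masks)):
            T = len(layer._cache)
            H = layer.n_hidden
            if dh_seq is None:
                dh_seq = np.zeros((B, T, H))
                dh_seq[:, -1] = dh_last
            if mask is not None:
                dh_seq = dh_seq * mask
            dh_seq, layer_grads = layer.backward(dh_seq)
            grads_rev = layer_grads + grads_rev
        return grads_rev


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g**2
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class TrainedDecoder:
    """A trained scenario: network state plus the artifacts needed to
    turn its outputs back into forearm angles."""

    scenario: ScenarioSpec
    network: _LSTMNetwork
    history: dict[str, list[float]]
    angle_record: NormalizationRecord | None = None
    velocity_record: NormalizationRecord | None = None
    decomposition: SynergyDecomposition | None = None

    @property
    def final_loss(self) -> float:
        return self.history["train_loss"][-1]


def train(dataset: WindowedDataset, scenario: ScenarioSpec, **artifacts) -> TrainedDecoder:
    """Train the scenario's network on a windowed dataset by Adam on MSE.

    A seeded 10% split of the windows is held out for early stopping
    (restoring nothing: the state at the best epoch is kept by patience
    accounting on the validation loss).  Raises :class:`TrainingError`
    with the loss history attached if the loss becomes non-finite.
    """
    if dataset.n_examples == 0:
        raise ValueError("empty dataset")
    if dataset.targets.shape[1] != scenario.n_outputs:
        raise ValueError(
            f"{scenario.methodology} expects {scenario.n_outputs} outputs, "
            f"dataset has {dataset.targets.shape[1]}"
        )
    rng = np.random.default_rng(scenario.seed)
    net = _LSTMNetwork(
        n_features=dataset.inputs.shape[2],
        n_hidden=scenario.hidden_units,
        n_layers=scenario.n_hidden_layers,
        n_outputs=scenario.n_outputs,
        dropout=scenario.dropout,
        rng=rng,
    )
    n = dataset.n_examples
    order = rng.permutation(n)
    n_val = int(round(scenario.validation_fraction * n))
    use_early_stop = n_val >= 1 and scenario.early_stopping_patience > 0
    val_idx, train_idx = order[:n_val], order[n_val:]
    if train_idx.size == 0:
        train_idx, val_idx = order, order[:0]
        use_early_stop = False
    x_train, y_train = dataset.inputs[train_idx], dataset.targets[train_idx]
    x_val, y_val = dataset.inputs[val_idx], dataset.targets[val_idx]

    optimizer = _Adam(net.params, scenario.learning_rate)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state = None
    patience_left = scenario.early_stopping_patience

    for epoch in range(scenario.epochs):
        perm = rng.permutation(train_idx.size)
        epoch_loss = 0.0
        for start in range(0, perm.size, scenario.batch_size):
            batch = perm[start : start + scenario.batch_size]
            xb, yb = x_train[batch], y_train[batch]
            pred = net.forward(xb, train=True, rng=rng)
            err = pred - yb
            loss = float(np.mean(err**2))
            epoch_loss += loss * batch.size
            grads = net.backward(2.0 * err / err.size)
            optimizer.step(net.params, grads)
        epoch_loss /= train_idx.size
        history["train_loss"].append(epoch_loss)
        if not np.isfinite(epoch_loss):
            raise TrainingError(
                f"training diverged at epoch {epoch}", history["train_loss"]
            )
        if use_early_stop:
            val_pred = net.forward(x_val, train=False)
            val_loss = float(np.mean((val_pred - y_val) ** 2))
            history["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_state = [p.copy() for p in net.params]
                patience_left = scenario.early_stopping_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
    if best_state is not None:
        for p, saved in zip(net.params, best_state):
            p[...] = saved
    return TrainedDecoder(
        scenario=scenario, network=net, history=history, **artifacts
    )


def predict(decoder: TrainedDecoder, features: list[np.ndarray]) -> list[np.ndarray]:
    """Per-movement output sequences, one vector per window end.

    Each (T, F) feature sequence yields a (T - window + 1, O) output
    array; inference applies no dropout and is deterministic.
    """
    window = decoder.scenario.window
    expected = len(decoder.scenario.input_channels)
    out = []
    for f in features:
        f = np.asarray(f, float)
        if f.shape[1] != expected:
            raise ValueError(
                f"feature sequence has {f.shape[1]} channels, expected {expected}"
            )
        if f.shape[0] < window:
            out.append(np.empty((0, decoder.scenario.n_outputs)))
            continue
        n = f.shape[0] - window + 1
        idx = np.arange(window)[None, :] + np.arange(n)[:, None]
        out.append(decoder.network.forward(f[idx], train=False))
    return out


def estimate_forearm(
    decoder: TrainedDecoder,
    features: list[np.ndarray],
    decomposition: SynergyDecomposition | None = None,
    angle_record: NormalizationRecord | None = None,
) -> list[np.ndarray]:
    """Forearm angle trajectories in degrees, one (n, 2) array per
    movement, aligned to the window-end time stamps.

    Synergy methodologies reconstruct through the (possibly substituted)
    synergy matrix before denormalizing; direct estimation denormalizes
    the network outputs.  ``decomposition`` and ``angle_record`` default
    to the artifacts attached at training time, and are the hooks for
    cross-subject transfer where the target subject's decomposition and
    records are substituted.
    """
    scenario = decoder.scenario
    record = angle_record if angle_record is not None else decoder.angle_record
    if record is None:
        raise ValueError("an angle normalization record is required")
    if scenario.methodology != "direct":
        decomp = decomposition if decomposition is not None else decoder.decomposition
        if decomp is None:
            raise ValueError(
                f"{scenario.methodology} estimation needs a synergy decomposition"
            )
    outputs = predict(decoder, features)
    results = []
    for cp in outputs:
        if scenario.methodology == "direct":
            normalized_fa = cp.T
        elif scenario.methodology == "two_synergy":
            w = decomp.loadings[:, :2]
            recon = decomp.channel_means[:, None] + w @ cp.T
            normalized_fa = recon[FOREARM_IDX]
        else:  # one_synergy: forearm-only decomposition (2 channels)
            w = decomp.loadings[:, :1]
            normalized_fa = decomp.channel_means[:, None] + w @ cp.T
        results.append(record.invert(normalized_fa, rows=FOREARM_IDX).T)
    return results


def scenario_grid(
    window: int = 10, seed: int = 0, **overrides
) -> list[ScenarioSpec]:
    """The full 3 methodologies x 3 depths x 4 input-combos = 36 grid."""
    return [
        ScenarioSpec(
            methodology=m,
            n_hidden_layers=layers,
            input_combo=combo,
            window=window,
            seed=seed,
            **overrides,
        )
        for m, layers, combo in product(METHODOLOGIES, (1, 2, 3), (2, 3, 4, 6))
    ]
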