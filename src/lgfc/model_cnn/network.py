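"""The four-branch classifier: GloCNN, LocCNN, FC and SS branches with a
concatenation head.

Branch layout (defaults follow the best validated hyper-parameters:
kernel-G n x 40, kernel-L n x 30, Dense-G 64, Dense-L 32, Dense-FC 32,
Dense-SS 32; n is the alphabet height, 4 for RNA and 7 for protein):

* GloCNN: per molecule 2 x (conv -> batch norm -> ReLU -> max pool) ->
  dropout -> dense; RNA and protein maps concatenated -> dense to 64;
* LocCNN: the multi-channel analogue on the windowed tensors -> 32;
* FC: A1 and A2 each through two dense layers, concatenated -> dense to 32;
* SS: B1 and B2 each through two dense layers, concatenated -> two dense
  layers to 32;
* head: concat(64+32+32+32) -> dense -> dense(1) -> sigmoid.

Kernel widths are clamped to the current feature-map length and pooling is
skipped when a map is shorter than the pool size, so the same config builds
for any input geometry.  The handcrafted/structure inputs are z-scored with
statistics fit on the training split (stored with the model).

Inputs are a dict of float arrays keyed ``glo_rna`` (B,4,L), ``glo_prot``
(B,7,L), ``loc_rna`` (B,C*4,w), ``loc_prot`` (B,C*7,w), ``a1``, ``a2``,
``b1``, ``b2`` (B,d).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from lgfc.model_cnn.layers import (
    Adam,
    BatchNorm,
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    Layer,
    MaxPool1D,
    ReLU,
    Sequential,
    bce_loss,
    sigmoid,
)

BRANCHES = ("glo", "loc", "fc", "ss")

_BRANCH_INPUTS = {
    "glo": ("glo_rna", "glo_prot"),
    "loc": ("loc_rna", "loc_prot"),
    "fc": ("a1", "a2"),
    "ss": ("b1", "b2"),
}
_STANDARDIZED_KEYS = ("a1", "a2", "b1", "b2")


@dataclass(frozen=True)
class ModelConfig:
    """Hyper-parameters of the four-branch classifier (all config-exposed)."""

    branches: tuple[str, ...] = BRANCHES
    kernel_g: int = 40
    kernel_l: int = 30
    n_filters: int = 16
    dense_g: int = 64
    dense_l: int = 32
    dense_fc: int = 32
    dense_ss: int = 32
    fc_hidden: tuple[int, int] = (128, 64)
    ss_hidden: int = 32
    head_hidden: int = 64
    dropout: float = 0.25
    lr: float = 1e-3
    batch_size: int = 64
    epochs: int = 50
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.branches:
            raise ValueError("at least one branch required")
        unknown = set(self.branches) - set(BRANCHES)
        if unknown:
            raise ValueError(f"unknown branches {sorted(unknown)}")
        if min(self.kernel_g, self.kernel_l, self.n_filters, self.dense_g,
               self.dense_l, self.dense_fc, self.dense_ss) < 1:
            raise ValueError("kernel widths, filter and dense sizes must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")


def ablate(config: ModelConfig, branches_subset: Sequence[str]) -> ModelConfig:
    """Restrict a config to a subset of branches (same head)."""
    subset = tuple(b for b in BRANCHES if b in set(branches_subset))
    if not subset:
        raise ValueError("branch subset must be non-empty")
    return replace(config, branches=subset)


def input_spec_from(inputs: Mapping[str, np.ndarray]) -> dict[str, tuple[int, ...]]:
    """Per-input shapes without the batch axis."""
    return {k: tuple(v.shape[1:]) for k, v in inputs.items()}


class _TwoTower(Layer):
    """Two per-molecule towers whose outputs are concatenated into a merge block."""

    def __init__(self, tower_a: Sequential, tower_b: Sequential, merge: Sequential,
                 keys: tuple[str, str]):
        self.tower_a, self.tower_b, self.merge = tower_a, tower_b, merge
        self.keys = keys

    def forward_pair(self, inputs: Mapping[str, np.ndarray], train: bool) -> np.ndarray:
        za = self.tower_a.forward(inputs[self.keys[0]], train)
        zb = self.tower_b.forward(inputs[self.keys[1]], train)
        self._wa = za.shape[1]
        return self.merge.forward(np.concatenate([za, zb], axis=1), train)

    def backward(self, grad: np.ndarray) -> None:
        g = self.merge.backward(grad)
        self.tower_a.backward(g[:, : self._wa])
        self.tower_b.backward(g[:, self._wa :])

    def params(self):
        return self.tower_a.params() + self.tower_b.params() + self.merge.params()

    @property
    def out_dim(self) -> int:
        return self.merge.out_dim


def _conv_tower(n_channels: int, length: int, width: int, config: ModelConfig,
                dense_out: int, rng: np.random.Generator) -> tuple[Sequential, int]:
    """Two conv blocks -> flatten -> dropout -> dense; returns (block, out_dim)."""
    layers: list[Layer] = []
    c, L = n_channels, length
    for _ in range(2):
        k = min(width, L)
        layers += [Conv1D(c, config.n_filters, k, rng), BatchNorm(config.n_filters), ReLU()]
        c, L = config.n_filters, L - k + 1
        if L >= 2:
            layers.append(MaxPool1D(2))
            L //= 2
    layers += [Flatten(), Dropout(config.dropout, rng), Dense(c * L, dense_out, rng), ReLU()]
    return Sequential(*layers), dense_out


def _dense_tower(n_in: int, hidden: Sequence[int], rng: np.random.Generator) -> Sequential:
    layers: list[Layer] = []
    d = n_in
    for h in hidden:
        layers += [Dense(d, h, rng), ReLU()]
        d = h
    return Sequential(*layers)


class FourBranchModel:
    """Weights + config + input spec; supports training, prediction, persistence."""

    def __init__(self, config: ModelConfig, input_spec: Mapping[str, tuple[int, ...]]):
        self.config = config
        self.input_spec = dict(input_spec)
        missing = {
            key for b in config.branches for key in _BRANCH_INPUTS[b]
        } - set(self.input_spec)
        if missing:
            raise ValueError(f"input_spec lacks shapes for {sorted(missing)}")
        rng = np.random.default_rng(config.seed)
        self.branches: dict[str, _TwoTower] = {}
        for name in config.branches:
            self.branches[name] = self._build_branch(name, rng)
        head_in = sum(b.out_dim for b in self.branches.values())
        self.head = Sequential(
            Dropout(config.dropout, rng),
            Dense(head_in, config.head_hidden, rng),
            ReLU(),
            Dense(config.head_hidden, 1, rng),
        )
        self.scalers: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self.history: list[dict] = []

    # -- construction ------------------------------------------------------

    def _build_branch(self, name: str, rng: np.random.Generator) -> _TwoTower:
        cfg = self.config
        ka, kb = _BRANCH_INPUTS[name]
        if name == "glo":
            ta, _ = _conv_tower(*self.input_spec[ka], cfg.kernel_g, cfg, cfg.dense_g, rng)
            tb, _ = _conv_tower(*self.input_spec[kb], cfg.kernel_g, cfg, cfg.dense_g, rng)
            merge = Sequential(Dense(2 * cfg.dense_g, cfg.dense_g, rng), ReLU())
        elif name == "loc":
            ta, _ = _conv_tower(*self.input_spec[ka], cfg.kernel_l, cfg, cfg.dense_l, rng)
            tb, _ = _conv_tower(*self.input_spec[kb], cfg.kernel_l, cfg, cfg.dense_l, rng)
            merge = Sequential(Dense(2 * cfg.dense_l, cfg.dense_l, rng), ReLU())
        elif name == "fc":
            ta = _dense_tower(self.input_spec[ka][0], cfg.fc_hidden, rng)
            tb = _dense_tower(self.input_spec[kb][0], cfg.fc_hidden, rng)
            merge = Sequential(Dense(2 * cfg.fc_hidden[-1], cfg.dense_fc, rng), ReLU())
        else:  # ss
            ta = _dense_tower(self.input_spec[ka][0], (cfg.ss_hidden, cfg.ss_hidden), rng)
            tb = _dense_tower(self.input_spec[kb][0], (cfg.ss_hidden, cfg.ss_hidden), rng)
            merge = Sequential(
                Dense(2 * cfg.ss_hidden, cfg.dense_ss, rng), ReLU(),
                Dense(cfg.dense_ss, cfg.dense_ss, rng), ReLU(),
            )
        return _TwoTower(ta, tb, merge, (ka, kb))

    # -- forward/backward --------------------------------------------------

    def _transform(self, inputs: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
        out = {}
        for k, v in inputs.items():
            v = np.asarray(v, dtype=np.float32)
            if k in self.scalers:
                mean, std = self.scalers[k]
                v = (v - mean) / std
            out[k] = v
        return out

    def forward_logits(self, inputs: Mapping[str, np.ndarray], train: bool) -> np.ndarray:
        outs = [self.branches[b].forward_pair(inputs, train) for b in self.config.branches]
        self._widths = [o.shape[1] for o in outs]
        return self.head.forward(np.concatenate(outs, axis=1), train)

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.head.backward(dlogits)
        off = 0
        for b, w in zip(self.config.branches, self._widths):
            self.branches[b].backward(g[:, off : off + w])
            off += w

    def params(self):
        out = []
        for b in self.config.branches:
            out.extend(self.branches[b].params())
        out.extend(self.head.params())
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.params())

    # -- state (de)serialization ------------------------------------------

    def _layers(self) -> list[Layer]:
        blocks: list[Sequential] = []
        for b in self.config.branches:
            tw = self.branches[b]
            blocks += [tw.tower_a, tw.tower_b, tw.merge]
        blocks.append(self.head)
        return [layer for blk in blocks for layer in blk.layers]

    def state_arrays(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self._layers()):
            for j, (p, _) in enumerate(layer.params()):
                state[f"layer{i}.param{j}"] = p
            if isinstance(layer, BatchNorm):
                state[f"layer{i}.running_mean"] = layer.running_mean
                state[f"layer{i}.running_var"] = layer.running_var
        for k, (mean, std) in self.scalers.items():
            state[f"scaler.{k}.mean"] = mean
            state[f"scaler.{k}.std"] = std
        return state

    def load_state(self, state: Mapping[str, np.ndarray]) -> None:
        for i, layer in enumerate(self._layers()):
            for j, (p, _) in enumerate(layer.params()):
                p[...] = state[f"layer{i}.param{j}"]
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = state[f"layer{i}.running_mean"]
                layer.running_var[...] = state[f"layer{i}.running_var"]
        scaler_keys = {k.split(".")[1] for k in state if k.startswith("scaler.")}
        self.scalers = {
            k: (np.asarray(state[f"scaler.{k}.mean"]), np.asarray(state[f"scaler.{k}.std"]))
            for k in scaler_keys
        }

    def save(self, directory: str | Path) -> None:
        """Persist weights (array archive) plus a JSON config sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(directory / "weights.npz", **self.state_arrays())
        meta = {
            "config": {**asdict(self.config), "branches": list(self.config.branches),
                        "fc_hidden": list(self.config.fc_hidden)},
            "input_spec": {k: list(v) for k, v in self.input_spec.items()},
            "history": self.history,
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "FourBranchModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        cfg_d = meta["config"]
        cfg_d["branches"] = tuple(cfg_d["branches"])
        cfg_d["fc_hidden"] = tuple(cfg_d["fc_hidden"])
        config = ModelConfig(**cfg_d)
        model = cls(config, {k: tuple(v) for k, v in meta["input_spec"].items()})
        with np.load(directory / "weights.npz") as npz:
            model.load_state(dict(npz))
        model.history = meta["history"]
        return model


def build_model(config: ModelConfig, input_spec: Mapping[str, tuple[int, ...]]) -> FourBranchModel:
    """Construct an untrained four-branch model for the given input shapes."""
    return FourBranchModel(config, input_spec)


def _required_inputs(model: FourBranchModel, inputs: Mapping[str, np.ndarray]) -> dict:
    needed = {k for b in model.config.branches for k in _BRANCH_INPUTS[b]}
    missing = needed - set(inputs)
    if missing:
        raise ValueError(f"missing model inputs: {sorted(missing)}")
    for k in sorted(needed):
        expect = model.input_spec[k]
        got = tuple(np.shape(inputs[k]))[1:]
        if got != tuple(expect):
            raise ValueError(f"input {k!r}: expected trailing shape {expect}, got {got}")
    return {k: inputs[k] for k in needed}


def train(
    model: FourBranchModel,
    train_set: tuple[Mapping[str, np.ndarray], np.ndarray],
    valid_set: tuple[Mapping[str, np.ndarray], np.ndarray],
    config: ModelConfig | None = None,
) -> FourBranchModel:
    """Binary cross-entropy training with Adam and early stopping.

    ``train_set``/``valid_set`` are ``(inputs, labels)``.  The handcrafted
    and structure inputs are z-scored on the training split.  The weights of
    the best validation-loss epoch are restored.  Deterministic for a fixed
    config seed.
    """
    cfg = config or model.config
    X_tr, y_tr = train_set
    X_va, y_va = valid_set
    y_tr = np.asarray(y_tr, dtype=np.float32).reshape(-1)
    y_va = np.asarray(y_va, dtype=np.float32).reshape(-1)
    if y_tr.size == 0 or y_va.size == 0:
        raise ValueError("empty training or validation split")

    X_tr = _required_inputs(model, X_tr)
    X_va = _required_inputs(model, X_va)

    # fit standardizers on train for vector inputs
    for key in _STANDARDIZED_KEYS:
        if key in X_tr:
            arr = np.asarray(X_tr[key], dtype=np.float64)
            mean = arr.mean(axis=0)
            std = arr.std(axis=0)
            std[std < 1e-8] = 1.0
            model.scalers[key] = (mean.astype(np.float32), std.astype(np.float32))
    X_tr = model._transform(X_tr)
    X_va = model._transform(X_va)

    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.params(), lr=cfg.lr)
    n = y_tr.size
    best_val = np.inf
    best_state = None
    best_epoch = -1
    model.history = []

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            if idx.size < 2:
                continue  # batch norm needs >= 2 samples
            batch = {k: v[idx] for k, v in X_tr.items()}
            yb = y_tr[idx]
            logits = model.forward_logits(batch, train=True)
            probs = sigmoid(logits[:, 0])
            losses.append(bce_loss(probs, yb))
            dlogits = ((probs - yb) / idx.size).astype(np.float32).reshape(-1, 1)
            model.backward(dlogits)
            opt.step()
        val_probs = predict(model, X_va, _already_transformed=True)
        val_loss = bce_loss(val_probs, y_va)
        model.history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_loss": val_loss}
        )
        if val_loss < best_val - 1e-5:
            best_val = val_loss
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}
            best_epoch = epoch
        elif epoch - best_epoch >= cfg.patience:
            break

    if best_state is not None:
        model.load_state(best_state)
    return model


def predict(
    model: FourBranchModel,
    inputs: Mapping[str, np.ndarray],
    batch_size: int = 256,
    _already_transformed: bool = False,
) -> np.ndarray:
    """Interaction probabilities in [0, 1], one per pair, batch order kept."""
    X = _required_inputs(model, inputs)
    if not _already_transformed:
        X = model._transform(X)
    n = next(iter(X.values())).shape[0]
    out = np.empty(n, dtype=np.float32)
    for start in range(0, n, batch_size):
        batch = {k: np.asarray(v[start : start + batch_size], dtype=np.float32)
                 for k, v in X.items()}
        logits = model.forward_logits(batch, train=False)
        out[start : start + batch_size] = sigmoid(logits[:, 0])
    return out
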