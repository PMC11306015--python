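"""Yield models: three stacked-LSTM architectures over multi-modal tensors.

The module follows the Model/Results convention: a model object is built
from the observed yields and a dict of :class:`ModalityTensor` inputs, its
``fit()`` runs Adam on MSE with early stopping and returns a
:class:`YieldResults` carrying the fitted parameters, training history,
predictions and (where the architecture has one) attention weights.

Architectures
-------------
``VanillaLSTMModel``
    early fusion: per-date concatenation of all modality features into one
    sequence, a stacked LSTM, and a linear head on the final hidden state.
``AttentionLSTMModel``
    the same encoder plus additive (Bahdanau-style) attention decomposed per
    (date, feature) pair, with an optional mid-season gate restricting the
    attention support to a date subset.
``MultimodalFusionModel``
    one attention branch per remote-sensing modality (each concatenated with
    the weather features along its own date axis), late fusion of the branch
    context vectors through two sigmoid dense layers, and gradient-blended
    branch losses.

Targets are min-max scaled to [0, 1] from the training split (the sigmoid
fusion head requires it); predictions are returned in original units.
Modality features are standardized per feature per date from the training
split; weather, constant across plots, is standardized per feature over the
flattened (plot, date) axis so it acts as a seasonal clock.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, SchemaError
from .nn import Adam, AdditiveAttention, Dense, StackedLSTM, Tensor, concat

__all__ = [
    "ModalityTensor",
    "ModelConfig",
    "AttentionWeights",
    "YieldResults",
    "VanillaLSTMModel",
    "AttentionLSTMModel",
    "MultimodalFusionModel",
    "lstm_parameter_count",
]

RS_MODALITIES = ("hyperspectral", "lidar")


@dataclass
class ModalityTensor:
    """plots x dates x features array for one modality."""

    values: np.ndarray
    dates: np.ndarray
    feature_names: tuple
    modality: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.dates = np.asarray(self.dates)
        self.feature_names = tuple(self.feature_names)
        if self.values.ndim != 3:
            raise SchemaError("modality tensor must be plots x dates x features")
        if self.values.shape[1] != self.dates.size:
            raise SchemaError("date axis does not match date labels")
        if self.values.shape[2] != len(self.feature_names):
            raise SchemaError("feature axis does not match feature names")

    @property
    def n_plots(self) -> int:
        return self.values.shape[0]

    @property
    def n_dates(self) -> int:
        return self.values.shape[1]

    def subset_dates(self, idx) -> "ModalityTensor":
        idx = np.asarray(idx, dtype=int)
        return ModalityTensor(
            self.values[:, idx, :], self.dates[idx], self.feature_names, self.modality
        )

    def subset_plots(self, idx) -> "ModalityTensor":
        return ModalityTensor(
            self.values[np.asarray(idx)], self.dates, self.feature_names, self.modality
        )


@dataclass
class ModelConfig:
    """Training and architecture hyperparameters (defaults used throughout)."""

    n_lstm_layers: int = 2
    units_per_layer: int = 32
    dropout: float = 0.2
    learning_rate: float = 0.001
    max_epochs: int = 200
    patience: int = 25
    batch_size: int = 64
    seed: int = 0
    gate_dates: tuple | None = None
    blend_weights: tuple | str = (1.0, 0.1, 0.1)
    blend_update_every: int = 10
    attention_dim: int = 16
    context_dim: int = 16
    fusion_hidden: int = 16
    query: str = "learned"  # or "final_state"
    restore_best: bool = True  # restore the best-validation snapshot after fit

    def __post_init__(self):
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must lie in [0, 1)")
        if self.learning_rate < 0:
            raise ConfigurationError("learning rate must be >= 0")


@dataclass
class AttentionWeights:
    """Per-plot nonnegative (date, feature) weights summing to 1."""

    weights: np.ndarray  # plots x dates x features
    dates: np.ndarray
    feature_names: tuple
    modality: str = "fused"

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise DomainError("attention weights must be nonnegative")
        sums = self.weights.reshape(self.weights.shape[0], -1).sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise DomainError("attention weights must sum to 1 per plot")


def lstm_parameter_count(n_in: int, n_units: int, n_layers: int) -> int:
    """Closed-form stacked-LSTM parameter count: sum of 4*(u*(u+i)+u)."""
    total = 0
    for k in range(n_layers):
        i = n_in if k == 0 else n_units
        total += 4 * (n_units * (n_units + i) + n_units)
    return total


# ---------------------------------------------------------------------------
# standardization & fusion helpers

@dataclass
class _Standardizer:
    mean: np.ndarray
    sd: np.ndarray

    def apply(self, values: np.ndarray) -> np.ndarray:
        return (values - self.mean) / self.sd


def fit_standardizer(tensor: ModalityTensor, train_idx) -> _Standardizer:
    v = tensor.values[np.asarray(train_idx)]
    if tensor.modality == "weather":
        mean = v.mean(axis=(0, 1), keepdims=True)[0]
        sd = v.std(axis=(0, 1), keepdims=True)[0]
    else:
        mean = v.mean(axis=0)
        sd = v.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return _Standardizer(mean, sd)


def merge_early_fusion(tensors: dict) -> ModalityTensor:
    """Concatenate modalities along the feature axis on a shared date axis.

    Modalities with identical date labels concatenate directly; otherwise the
    union of dates forms the time axis and a modality's missing dates are
    zero-filled (the post-standardization mean).
    """
    mods = sorted(tensors, key=lambda m: (m not in RS_MODALITIES, m))
    date_sets = [tuple(np.asarray(tensors[m].dates).tolist()) for m in mods]
    union = np.array(sorted(set(d for ds in date_sets for d in ds)))
    n = tensors[mods[0]].n_plots
    blocks, names = [], []
    for m in mods:
        t = tensors[m]
        block = np.zeros((n, union.size, t.values.shape[2]))
        pos = {d: k for k, d in enumerate(union.tolist())}
        for j, d in enumerate(np.asarray(t.dates).tolist()):
            block[:, pos[d], :] = t.values[:, j, :]
        blocks.append(block)
        names.extend(f"{m}:{f}" for f in t.feature_names)
    return ModalityTensor(np.concatenate(blocks, axis=2), union, tuple(names), "fused")


def _gate_mask(dates: np.ndarray, gate_dates) -> np.ndarray | None:
    if gate_dates is None:
        return None
    labels = list(np.asarray(dates).tolist())
    missing = [d for d in gate_dates if d not in labels]
    if missing:
        raise ConfigurationError(f"gate dates {missing} not among date labels")
    gate = set(gate_dates)
    return np.array([d in gate for d in labels], dtype=float)


# ---------------------------------------------------------------------------
# results object

class YieldResults:
    """Fitted-model container: parameters, history, predictions, attention."""

    def __init__(self, model, history: pd.DataFrame, best_epoch: int):
        self.model = model
        self.history = history
        self.best_epoch = best_epoch

    # delegated API ---------------------------------------------------------
    def predict(self, tensors: dict | None = None, plot_idx=None) -> np.ndarray:
        """Predicted yields in original units."""
        return self.model._predict(tensors=tensors, plot_idx=plot_idx)

    def attention(self, tensors: dict | None = None, plot_idx=None):
        """Attention weight maps (dict keyed by branch for the fusion model)."""
        return self.model._attention(tensors=tensors, plot_idx=plot_idx)

    @property
    def best_val_loss(self) -> float:
        return float(self.history["val_loss"].iloc[self.best_epoch])

    def save(self, path) -> None:
        """Checkpoint: NPZ parameter arrays plus a JSON sidecar.

        The sidecar records the architecture, config, target scaling and
        feature schema; `load_results` rebuilds the model and restores the
        parameters.
        """
        import dataclasses
        import json
        from pathlib import Path

        m = self.model
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "parameters.npz",
                 **{f"p{k}": p.data for k, p in enumerate(m._params)})
        sidecar = {
            "architecture": m.arch,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in dataclasses.asdict(m.config).items()},
            "y_min": m._y_min,
            "y_max": m._y_max,
            "feature_schema": {k: list(v) for k, v in m._feature_schema.items()},
            "standardizers": {
                k: {"mean": s.mean.tolist(), "sd": s.sd.tolist()}
                for k, s in m._standardizers.items()
            },
            "best_epoch": self.best_epoch,
        }
        (path / "checkpoint.json").write_text(json.dumps(sidecar, indent=2))
        self.history.to_csv(path / "history.csv", index=False)

    def summary(self) -> str:
        m = self.model
        lines = [
            f"{type(m).__name__} results",
            "=" * 40,
            f"architecture:      {m.arch}",
            f"parameters:        {m.n_parameters()}",
            f"epochs run:        {len(self.history)}",
            f"best epoch:        {self.best_epoch}",
            f"best val MSE:      {self.best_val_loss:.6f} (scaled units)",
            f"train plots:       {len(m._train_idx)}",
            f"validation plots:  {len(m._val_idx)}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# model base

def load_results(path, y, tensors) -> "YieldResults":
    """Rebuild a fitted model from a checkpoint directory.

    `y` and `tensors` must describe the same plots the model was trained on
    (they define shapes; parameters and scaling come from the checkpoint).
    """
    import json
    from pathlib import Path

    path = Path(path)
    sidecar = json.loads((path / "checkpoint.json").read_text())
    cfg_kwargs = dict(sidecar["config"])
    if isinstance(cfg_kwargs.get("blend_weights"), list):
        cfg_kwargs["blend_weights"] = tuple(cfg_kwargs["blend_weights"])
    if isinstance(cfg_kwargs.get("gate_dates"), list):
        cfg_kwargs["gate_dates"] = tuple(cfg_kwargs["gate_dates"])
    config = ModelConfig(**cfg_kwargs)
    cls = {m.arch: m for m in
           (VanillaLSTMModel, AttentionLSTMModel, MultimodalFusionModel)}[
        sidecar["architecture"]
    ]
    model = cls(y, tensors, config)
    model._y_min = sidecar["y_min"]
    model._y_max = sidecar["y_max"]
    model._feature_schema = {
        k: tuple(v) for k, v in sidecar["feature_schema"].items()
    }
    model._standardizers = {
        k: _Standardizer(np.asarray(s["mean"]), np.asarray(s["sd"]))
        for k, s in sidecar["standardizers"].items()
    }
    model._train_idx = np.array([], dtype=int)
    model._val_idx = np.array([], dtype=int)
    model._build(np.random.default_rng(config.seed))
    arrays = np.load(path / "parameters.npz")
    for k, p in enumerate(model._params):
        p.data = arrays[f"p{k}"]
    model._fitted = True
    history = pd.read_csv(path / "history.csv")
    return YieldResults(model, history, int(sidecar["best_epoch"]))


class _YieldModelBase:
    arch = "base"

    def __init__(self, y: np.ndarray, tensors: dict, config: ModelConfig | None = None):
        self.y = np.asarray(y, dtype=float).ravel()
        self.tensors = dict(tensors)
        self.config = config if config is not None else ModelConfig()
        n_plots = {m: t.n_plots for m, t in self.tensors.items()}
        if len(set(n_plots.values())) != 1 or self.y.size not in set(n_plots.values()):
            raise SchemaError(f"inconsistent plot counts: y={self.y.size}, {n_plots}")
        self._fitted = False

    # -- subclass hooks ----------------------------------------------------
    def _build(self, rng):
        raise NotImplementedError

    def _forward(self, inputs, training=False, rng=None):
        raise NotImplementedError

    def _prepare_inputs(self, tensors: dict) -> dict:
        raise NotImplementedError

    # -- shared machinery --------------------------------------------------
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self._params)

    def _scale_y(self, values):
        lo, hi = self._y_min, self._y_max
        return (values - lo) / (hi - lo)

    def _unscale_y(self, scaled):
        return scaled * (self._y_max - self._y_min) + self._y_min

    def _standardized(self, tensors: dict) -> dict:
        out = {}
        for m, std in self._standardizers.items():
            if m not in tensors:
                raise ConfigurationError(f"missing modality {m!r}")
            t = tensors[m]
            if tuple(t.feature_names) != self._feature_schema[m]:
                raise SchemaError(f"feature names of {m!r} differ from training")
            out[m] = ModalityTensor(
                std.apply(t.values), t.dates, t.feature_names, t.modality
            )
        return out

    def _snapshot(self):
        return [p.data.copy() for p in self._params]

    def _restore(self, snap):
        for p, s in zip(self._params, snap):
            p.data = s.copy()

    def fit(self, train_idx, val_idx) -> YieldResults:
        """Train with Adam on MSE; early-stop on validation MSE."""
        cfg = self.config
        train_idx = np.asarray(train_idx, dtype=int)
        val_idx = np.asarray(val_idx, dtype=int)
        if val_idx.size == 0:
            raise ConfigurationError("empty validation split")
        if np.intersect1d(train_idx, val_idx).size:
            raise ConfigurationError("train/validation splits overlap")

        self._train_idx, self._val_idx = train_idx, val_idx
        self._y_min = float(self.y[train_idx].min())
        self._y_max = float(self.y[train_idx].max())
        if self._y_max == self._y_min:
            raise DomainError("training yields are constant; cannot scale")
        self._standardizers = {
            m: fit_standardizer(t, train_idx) for m, t in self.tensors.items()
        }
        self._feature_schema = {
            m: tuple(t.feature_names) for m, t in self.tensors.items()
        }

        rng = np.random.default_rng(cfg.seed)
        self._build(rng)
        inputs = self._prepare_inputs(self._standardized(self.tensors))
        tr_in = {k: v[train_idx] for k, v in inputs.items()}
        va_in = {k: v[val_idx] for k, v in inputs.items()}
        y_tr = self._scale_y(self.y[train_idx])[:, None]
        y_va = self._scale_y(self.y[val_idx])[:, None]

        opt = Adam(self._params, lr=cfg.learning_rate)
        drop_rng = np.random.default_rng(cfg.seed + 1)
        best_loss, best_epoch, best_snap = np.inf, -1, self._snapshot()
        rows = []
        n_train = train_idx.size
        bs = min(cfg.batch_size, n_train)
        for epoch in range(cfg.max_epochs):
            perm = drop_rng.permutation(n_train)
            batch_rows = []
            for lo in range(0, n_train, bs):
                sel = perm[lo : lo + bs]
                b_in = {k: v[sel] for k, v in tr_in.items()}
                loss, extras = self._loss(b_in, y_tr[sel], training=True, rng=drop_rng)
                if not np.isfinite(loss.data):
                    raise RuntimeError(f"non-finite training loss at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                batch_rows.append({"train_loss": float(loss.data),
                                   **{f"train_{k}": v for k, v in extras.items()}})
            val_loss, val_extras = self._loss(va_in, y_va, training=False)
            row = {"epoch": epoch, "val_loss": float(val_loss.data)}
            for key in batch_rows[0]:
                row[key] = float(np.mean([r[key] for r in batch_rows]))
            row.update({f"val_{k}": v for k, v in val_extras.items()})
            rows.append(row)
            if float(val_loss.data) < best_loss - 1e-12:
                best_loss, best_epoch = float(val_loss.data), epoch
                best_snap = self._snapshot()
            elif epoch - best_epoch >= cfg.patience:
                break
            self._post_epoch(epoch, rows)
        if cfg.restore_best:
            self._restore(best_snap)
        self._fitted = True
        return YieldResults(self, pd.DataFrame(rows), best_epoch)

    def _post_epoch(self, epoch, rows):
        pass

    def _loss(self, inputs, y_scaled, training=False, rng=None):
        pred = self._forward(inputs, training=training, rng=rng)
        err = pred - Tensor(y_scaled)
        return (err * err).mean(), {}

    def _predict(self, tensors=None, plot_idx=None) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("model is not fitted")
        tensors = self.tensors if tensors is None else tensors
        inputs = self._prepare_inputs(self._standardized(tensors))
        if plot_idx is not None:
            inputs = {k: v[np.asarray(plot_idx)] for k, v in inputs.items()}
        pred = self._forward(inputs, training=False)
        return self._unscale_y(pred.data.ravel())

    def _attention(self, tensors=None, plot_idx=None):
        raise ConfigurationError(f"{self.arch} model exposes no attention weights")


# ---------------------------------------------------------------------------
# architectures

class VanillaLSTMModel(_YieldModelBase):
    """Early-fusion stacked LSTM with a linear head on the last hidden state."""

    arch = "vanilla"

    def _build(self, rng):
        merged = merge_early_fusion(self.tensors)
        self._merged_names = merged.feature_names
        self._merged_dates = merged.dates
        cfg = self.config
        self.lstm = StackedLSTM(
            rng, len(merged.feature_names), cfg.units_per_layer,
            cfg.n_lstm_layers, cfg.dropout,
        )
        self.head = Dense(rng, cfg.units_per_layer, 1)
        self._params = self.lstm.parameters() + self.head.parameters()

    def _prepare_inputs(self, tensors):
        return {"x": merge_early_fusion(tensors).values}

    def _forward(self, inputs, training=False, rng=None):
        hidden = self.lstm(Tensor(inputs["x"]), training=training, rng=rng)
        return self.head(hidden[-1])


class AttentionLSTMModel(_YieldModelBase):
    """Early-fusion stacked LSTM with additive (date, feature) attention."""

    arch = "attention"

    def _build(self, rng):
        merged = merge_early_fusion(self.tensors)
        self._merged_names = merged.feature_names
        self._merged_dates = merged.dates
        cfg = self.config
        n_feat = len(merged.feature_names)
        self.lstm = StackedLSTM(
            rng, n_feat, cfg.units_per_layer, cfg.n_lstm_layers, cfg.dropout
        )
        self.attn = AdditiveAttention(
            rng, cfg.units_per_layer, n_feat, merged.n_dates,
            cfg.attention_dim, cfg.context_dim,
            final_state_query=cfg.query == "final_state",
        )
        self.head = Dense(rng, cfg.context_dim, 1)
        self._gate = _gate_mask(merged.dates, cfg.gate_dates)
        self._params = (
            self.lstm.parameters() + self.attn.parameters() + self.head.parameters()
        )

    def _prepare_inputs(self, tensors):
        return {"x": merge_early_fusion(tensors).values}

    def _encode(self, inputs, training=False, rng=None):
        x = Tensor(inputs["x"])
        hidden = self.lstm(x, training=training, rng=rng)
        ctx, alpha = self.attn(hidden, x, gate_mask=self._gate)
        return ctx, alpha

    def _forward(self, inputs, training=False, rng=None):
        ctx, _ = self._encode(inputs, training=training, rng=rng)
        return self.head(ctx)

    def _attention(self, tensors=None, plot_idx=None) -> AttentionWeights:
        if not self._fitted:
            raise RuntimeError("model is not fitted")
        tensors = self.tensors if tensors is None else tensors
        inputs = self._prepare_inputs(self._standardized(tensors))
        if plot_idx is not None:
            inputs = {k: v[np.asarray(plot_idx)] for k, v in inputs.items()}
        _, alpha = self._encode(inputs, training=False)
        return AttentionWeights(
            alpha.data, self._merged_dates, self._merged_names, "fused"
        )


class MultimodalFusionModel(_YieldModelBase):
    """Two attention branches (modality + weather) with late sigmoid fusion.

    Total loss = w_f * L_fusion + w_1 * L_hyperspectral + w_2 * L_lidar where
    the branch weights either come from the config or are re-estimated every
    `blend_update_every` epochs from overfitting/gain ratios ("auto").
    """

    arch = "multimodal"

    def __init__(self, y, tensors, config=None):
        super().__init__(y, tensors, config)
        missing = [m for m in RS_MODALITIES if m not in self.tensors]
        if missing:
            raise ConfigurationError(f"missing remote-sensing modality {missing}")

    def _branch_tensors(self, tensors, modality):
        t = tensors[modality]
        parts = {modality: t}
        if "weather" in tensors:
            w = tensors["weather"]
            labels = list(np.asarray(w.dates).tolist())
            idx = [labels.index(d) for d in np.asarray(t.dates).tolist()]
            parts["weather"] = w.subset_dates(idx)
        return parts

    def _build(self, rng):
        cfg = self.config
        self.branches = {}
        self._params = []
        for m in RS_MODALITIES:
            parts = self._branch_tensors(self.tensors, m)
            merged = merge_early_fusion(parts)
            n_feat = len(merged.feature_names)
            lstm = StackedLSTM(
                rng, n_feat, cfg.units_per_layer, cfg.n_lstm_layers, cfg.dropout
            )
            attn = AdditiveAttention(
                rng, cfg.units_per_layer, n_feat, merged.n_dates,
                cfg.attention_dim, cfg.context_dim,
                final_state_query=cfg.query == "final_state",
            )
            aux = Dense(rng, cfg.context_dim, 1)
            self.branches[m] = {
                "lstm": lstm, "attn": attn, "aux": aux,
                "names": merged.feature_names, "dates": merged.dates,
                "gate": _gate_mask(merged.dates, cfg.gate_dates),
            }
            self._params += lstm.parameters() + attn.parameters() + aux.parameters()
        self.fuse1 = Dense(rng, 2 * cfg.context_dim, cfg.fusion_hidden, "sigmoid")
        self.fuse2 = Dense(rng, cfg.fusion_hidden, 1, "sigmoid")
        self._params += self.fuse1.parameters() + self.fuse2.parameters()
        if cfg.blend_weights == "auto":
            self._blend = np.array([1.0, 0.3, 0.3])
        else:
            self._blend = np.asarray(cfg.blend_weights, dtype=float)

    def _prepare_inputs(self, tensors):
        out = {}
        for m in RS_MODALITIES:
            out[m] = merge_early_fusion(self._branch_tensors(tensors, m)).values
        return out

    def _branch_forward(self, m, x_np, training=False, rng=None):
        br = self.branches[m]
        x = Tensor(x_np)
        hidden = br["lstm"](x, training=training, rng=rng)
        ctx, alpha = br["attn"](hidden, x, gate_mask=br["gate"])
        return ctx, alpha, br["aux"](ctx)

    def _forward(self, inputs, training=False, rng=None):
        contexts = []
        self._aux_preds = {}
        for m in RS_MODALITIES:
            ctx, _, aux = self._branch_forward(m, inputs[m], training, rng)
            contexts.append(ctx)
            self._aux_preds[m] = aux
        fused = concat(contexts, axis=1)
        return self.fuse2(self.fuse1(fused))

    def _loss(self, inputs, y_scaled, training=False, rng=None):
        pred = self._forward(inputs, training=training, rng=rng)
        target = Tensor(y_scaled)
        err = pred - target
        fusion_loss = (err * err).mean()
        w_f, w_1, w_2 = self._blend
        total = fusion_loss * float(w_f)
        extras = {"fusion_loss": float(fusion_loss.data)}
        for w, m in zip((w_1, w_2), RS_MODALITIES):
            aux_err = self._aux_preds[m] - target
            aux_loss = (aux_err * aux_err).mean()
            extras[f"{m}_loss"] = float(aux_loss.data)
            if w != 0.0:
                total = total + aux_loss * float(w)
        return total, extras

    def _post_epoch(self, epoch, rows):
        cfg = self.config
        if cfg.blend_weights != "auto" or epoch == 0:
            return
        k = cfg.blend_update_every
        if (epoch + 1) % k:
            return
        # overfitting-ratio reweighting: branches that still generalize get
        # more loss weight; a crude stand-in for full gradient blending
        new = []
        for m in RS_MODALITIES:
            now, prev = rows[-1], rows[max(0, len(rows) - 1 - k)]
            overfit = now[f"val_{m}_loss"] - now[f"train_{m}_loss"]
            gain = prev[f"val_{m}_loss"] - now[f"val_{m}_loss"]
            new.append(max(gain, 1e-6) / (overfit**2 + 1e-6))
        new = 0.6 * np.asarray(new) / np.sum(new)
        self._blend = np.array([1.0, new[0], new[1]])

    def _attention(self, tensors=None, plot_idx=None) -> dict:
        if not self._fitted:
            raise RuntimeError("model is not fitted")
        tensors = self.tensors if tensors is None else tensors
        inputs = self._prepare_inputs(self._standardized(tensors))
        if plot_idx is not None:
            inputs = {k: v[np.asarray(plot_idx)] for k, v in inputs.items()}
        out = {}
        for m in RS_MODALITIES:
            _, alpha, _ = self._branch_forward(m, inputs[m], training=False)
            br = self.branches[m]
            out[m] = AttentionWeights(alpha.data, br["dates"], br["names"], m)
        return out
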