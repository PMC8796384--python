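"""The regression model: architecture variants, training, prediction.

Four variants share one architecture — two convolution layers, span pooling,
three dense layers, batch normalization after every convolution and dense
layer — and differ only in convolution kind and whether the training/test
inputs are augmented with all cyclic rotation/translation replicas:

================  ============  ============
variant           convolution   augmentation
================  ============  ============
baseline          ordinary      no
cyclicconv        circular      no
augmented         ordinary      yes
cyclicconv_augmented  circular  yes
================  ============  ============

Training minimizes mean squared error on the clamped %PPB labels.  At
prediction time the replica predictions are averaged first and the mean is
then clamped to [50, 95].
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .dataset import clamp_ppb
from .featmap import MAX_LENGTH, FeatureMap, augment
from .nn import (
    Adam,
    BatchNorm,
    Conv1dSame,
    Dense,
    Network,
    ReLU,
    SpanAvgPool,
    SpanMaxPool,
)

__all__ = ["VARIANTS", "ModelConfig", "PredictionResult", "build_model", "train",
           "predict", "grid_search", "save_checkpoint", "load_checkpoint"]

#: variant -> (cyclic convolution?, augmentation?)
VARIANTS = {
    "baseline": (False, False),
    "cyclicconv": (True, False),
    "augmented": (False, True),
    "cyclicconv_augmented": (True, True),
}


@dataclass
class ModelConfig:
    variant: str = "augmented"
    n_descriptors: int = 3
    max_length: int = MAX_LENGTH
    conv_channels: tuple[int, ...] = (32, 64)
    kernel_size: int = 3
    fc_widths: tuple[int, ...] = (64, 16)
    pooling: str = "max"  # "max" | "avg"
    lr: float = 1e-3
    epochs: int = 300
    batch_size: int = 128
    patience: int = 30
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; choose from {sorted(VARIANTS)}"
            )
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        if self.pooling not in ("max", "avg"):
            raise ValueError("pooling must be 'max' or 'avg'")
        if self.n_descriptors < 1 or not self.conv_channels or not self.fc_widths:
            raise ValueError("inconsistent model shape configuration")

    @property
    def cyclic(self) -> bool:
        return VARIANTS[self.variant][0]

    @property
    def augmented(self) -> bool:
        return VARIANTS[self.variant][1]


@dataclass
class PredictionResult:
    """Replica-averaged, clamped prediction for one peptide."""

    peptide_id: str
    replica_predictions: list[float]
    y_hat_raw: float
    y_hat: float


def build_model(config: ModelConfig) -> Network:
    """Construct the network for a config; parameter init is seeded."""
    rng = np.random.default_rng(config.seed)
    layers = []
    c_in = config.n_descriptors
    for c_out in config.conv_channels:
        layers += [
            Conv1dSame(c_in, c_out, config.kernel_size, cyclic=config.cyclic, rng=rng),
            BatchNorm(c_out),
            ReLU(),
        ]
        c_in = c_out
    layers.append(SpanMaxPool() if config.pooling == "max" else SpanAvgPool())
    f_in = c_in
    for width in config.fc_widths:
        layers += [Dense(f_in, width, rng), BatchNorm(width), ReLU()]
        f_in = width
    layers.append(Dense(f_in, 1, rng))
    return Network(layers)


def _stack(maps: list[FeatureMap]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([m.values for m in maps])
    spans = np.array([[m.start, m.n] for m in maps], dtype=np.intp)
    return x, spans


def _expand(maps, labels, augmented: bool):
    if not augmented:
        return list(maps), np.asarray(labels, dtype=float)
    out_maps, out_labels = [], []
    for m, y in zip(maps, labels):
        reps = augment(m)
        out_maps.extend(reps)
        out_labels.extend([y] * len(reps))
    return out_maps, np.asarray(out_labels, dtype=float)


def train(
    model: Network,
    maps: list[FeatureMap],
    labels,
    config: ModelConfig,
) -> dict:
    """Fit the model by Adam on mean squared error over clamped labels.

    Peptides (not replicas) are split into train/validation; if augmentation
    is on every replica of a training peptide is a training sample.  The
    parameter state with the best validation loss is restored at the end.
    Returns a history dict with per-epoch train/validation loss.
    """
    labels = np.asarray(labels, dtype=float)
    if len(maps) != len(labels):
        raise ValueError("maps and labels differ in length")
    rng = np.random.default_rng(config.seed + 1)

    n_pep = len(maps)
    n_val = int(round(config.val_fraction * n_pep)) if n_pep > 2 else 0
    perm = rng.permutation(n_pep)
    val_idx, trn_idx = perm[:n_val], perm[n_val:]
    trn_maps, trn_y = _expand([maps[i] for i in trn_idx], labels[trn_idx], config.augmented)
    if n_val:
        val_maps, val_y = _expand([maps[i] for i in val_idx], labels[val_idx], config.augmented)
        xv, sv = _stack(val_maps)

    x, spans = _stack(trn_maps)
    y = trn_y
    # start the output at the mean label so the optimizer fits structure, not
    # the ~70 %PPB offset, from the first epoch
    final = model.layers[-1]
    if isinstance(final, Dense) and config.lr > 0:
        final.b[...] = float(y.mean())
    optim = Adam(model.parameters(), lr=config.lr)
    history = {"epoch": [], "train_loss": [], "val_loss": []}
    best_loss, best_state, since_best = np.inf, model.get_state(), 0

    n_samples = x.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n_samples)
        total = 0.0
        for lo in range(0, n_samples, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            xb, sb, yb = x[idx], spans[idx], y[idx]
            pred = model.forward(xb, sb, train=True)[:, 0]
            err = pred - yb
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch rows {idx[:5]}..., "
                    f"pred range [{np.nanmin(pred)}, {np.nanmax(pred)}]"
                )
            model.zero_grad()
            model.backward((2.0 * err / len(idx))[:, None])
            optim.step(model.gradients())
            total += loss * len(idx)
        train_loss = total / n_samples

        if n_val:
            vp = _forward_batched(model, xv, sv, config.batch_size)
            val_loss = float(np.mean((vp - val_y) ** 2))
        else:
            val_loss = train_loss
        history["epoch"].append(epoch)
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)

        if val_loss < best_loss - 1e-12:
            best_loss, best_state, since_best = val_loss, model.get_state(), 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    model.set_state(best_state)
    history["best_val_loss"] = best_loss
    return history


def _forward_batched(model: Network, x, spans, batch_size: int) -> np.ndarray:
    preds = []
    for lo in range(0, x.shape[0], batch_size):
        preds.append(
            model.forward(x[lo : lo + batch_size], spans[lo : lo + batch_size], train=False)[:, 0]
        )
    return np.concatenate(preds)


def predict(model: Network, fmap: FeatureMap, augment_input: bool = True,
            batch_size: int = 512) -> PredictionResult:
    """Replica-averaged clamped prediction for one peptide.

    With augmentation the full replica set is forwarded in eval mode, the
    raw predictions averaged, and the mean clamped to [50, 95]; otherwise a
    single forward pass is clamped.
    """
    maps = augment(fmap) if augment_input else [fmap]
    x, spans = _stack(maps)
    expected = model.layers[0].c_in
    if x.shape[1] != expected or x.shape[2] != MAX_LENGTH:
        raise ValueError(
            f"shape mismatch: map is D={x.shape[1]}, L={x.shape[2]}; model expects "
            f"D={expected}, L={MAX_LENGTH}"
        )
    preds = _forward_batched(model, x, spans, batch_size)
    # sort before averaging so the mean is independent of replica enumeration
    # order (exact rotation invariance, not just up to float summation order)
    raw = float(np.mean(np.sort(preds)))
    return PredictionResult(
        peptide_id=fmap.peptide_id,
        replica_predictions=[float(p) for p in preds],
        y_hat_raw=raw,
        y_hat=float(clamp_ppb(np.clip(raw, 0.0, 100.0))),
    )


def grid_search(
    maps: list[FeatureMap],
    labels,
    base_config: ModelConfig,
    param_grid: dict[str, list],
) -> tuple[ModelConfig, list[dict]]:
    """Exhaustive configuration search by best validation loss.

    ``param_grid`` maps ModelConfig field names to candidate values; every
    combination is trained from scratch (same seed) and the config with the
    lowest best-validation loss is returned together with the full trace.
    """
    from dataclasses import replace as _replace
    from itertools import product

    names = list(param_grid)
    trace = []
    best_cfg, best_loss = None, np.inf
    for combo in product(*(param_grid[n] for n in names)):
        cfg = _replace(base_config, **dict(zip(names, combo)))
        model = build_model(cfg)
        history = train(model, maps, labels, cfg)
        loss = history["best_val_loss"]
        trace.append({**dict(zip(names, combo)), "best_val_loss": loss})
        if loss < best_loss:
            best_cfg, best_loss = cfg, loss
    return best_cfg, trace


def save_checkpoint(path: str | Path, model: Network, config: ModelConfig,
                    extra: dict | None = None) -> None:
    """Write weights (npz) plus a JSON sidecar with the model config."""
    path = Path(path)
    state = model.get_state()
    np.savez(path.with_suffix(".npz"), *state)
    cfg = asdict(config)
    cfg["conv_channels"] = list(config.conv_channels)
    cfg["fc_widths"] = list(config.fc_widths)
    payload = {"config": cfg, "n_arrays": len(state), **(extra or {})}
    path.with_suffix(".json").write_text(json.dumps(payload, indent=2))


def load_checkpoint(path: str | Path) -> tuple[Network, ModelConfig, dict]:
    path = Path(path)
    payload = json.loads(path.with_suffix(".json").read_text())
    cfg_d = dict(payload["config"])
    cfg_d["conv_channels"] = tuple(cfg_d["conv_channels"])
    cfg_d["fc_widths"] = tuple(cfg_d["fc_widths"])
    config = ModelConfig(**cfg_d)
    model = build_model(config)
    with np.load(path.with_suffix(".npz")) as data:
        state = [data[k] for k in data.files]
    model.set_state(state)
    return model, config, payload
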