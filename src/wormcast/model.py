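"""Bimodal sequence-regression model for lifespan forecasting.

The predictor consumes the assay so far — one synthetic-domain frame per day
(movement information) and the live-count series — and regresses the live
count for every remaining day of the assay.

Architecture: a small convolutional encoder turns each frame into an
embedding; an LSTM summarizes the embedding sequence (the CNN-LSTM branch);
a second LSTM summarizes the count series; the final hidden states are
concatenated and a fully connected head outputs a ``max_days``-long count
vector on an absolute-day axis. Ablation variants drop one branch
(``counts_only``, ``images_only``) or replace frames with sorted per-day
coordinate matrices (``bimodal_coords``).

Counts are scaled by 1/16 (the maximum worms per plate) and pixel values to
[0, 1] at ingestion; training minimizes mean squared error over the
supervised (future-day) label region with plain SGD, per the reference
hyperparameters (100 epochs, learning rate 0.001, batch size 16).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn
from .dataset import MAX_WORMS, ModelSample
from .render import ImageSpec

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "LossRecord",
    "TrainingDivergedError",
    "LifespanPredictor",
    "build_model",
    "train",
    "predict_plate",
    "postprocess_prediction",
    "save_checkpoint",
    "load_checkpoint",
]

MODES = ("bimodal_images", "images_only", "counts_only", "bimodal_coords")


class TrainingDivergedError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    mode: str = "bimodal_images"
    image_spec: ImageSpec = field(default_factory=ImageSpec)
    max_days: int = 120
    max_worms: int = MAX_WORMS
    conv_channels: tuple[int, ...] = (8, 16, 32)
    image_rnn_width: int = 64
    count_rnn_width: int = 32
    head_hidden: int = 64

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.max_days < 2 or self.max_worms < 1:
            raise ValueError("max_days and max_worms must be positive")


@dataclass(frozen=True)
class TrainConfig:
    """Reference training hyperparameters: SGD, MSE, 100 epochs, lr 1e-3,
    batch 16. ``momentum`` defaults to 0 (plain SGD); scaled-down runs may
    raise it so short trainings converge."""

    epochs: int = 100
    learning_rate: float = 0.001
    batch_size: int = 16
    momentum: float = 0.0
    seed: int = 0


@dataclass
class LossRecord:
    """Per-epoch training/validation MSE, in squared worms."""

    train_mse: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"epoch": np.arange(1, len(self.train_mse) + 1),
             "train_mse": self.train_mse, "val_mse": self.val_mse}
        )


# -- batch assembly ----------------------------------------------------------


def assemble_batch(samples: Sequence[ModelSample], config: ModelConfig) -> dict:
    """Front-pad a list of samples into dense arrays with validity masks.

    The prefixes are aligned at their final (current) day, so the recurrent
    state at the last timestep always corresponds to day k.
    """
    b = len(samples)
    t = max(s.k + 1 for s in samples)
    side = config.image_spec.side
    need_frames = config.mode in ("bimodal_images", "images_only")
    need_coords = config.mode == "bimodal_coords"

    counts = np.zeros((b, t))
    mask = np.zeros((b, t))
    frames = np.zeros((b, t, side, side)) if need_frames else None
    coords = np.zeros((b, t, MAX_WORMS, 2)) if need_coords else None
    labels = np.zeros((b, config.max_days))
    label_mask = np.zeros((b, config.max_days))
    initial = np.zeros(b)

    for i, s in enumerate(samples):
        n = s.k + 1
        counts[i, t - n :] = s.count_prefix / config.max_worms
        mask[i, t - n :] = 1.0
        if need_frames:
            if s.frame_prefix is None:
                raise ValueError(f"mode {config.mode!r} needs samples with frames")
            if s.frame_prefix.frames.shape[1] != side:
                raise ValueError("frame size does not match the model's image_spec")
            frames[i, t - n :] = s.frame_prefix.frames / 255.0
        if need_coords:
            if s.coord_prefix is None:
                raise ValueError("bimodal_coords mode needs samples with coord_prefix")
            coords[i, t - n :] = s.coord_prefix / side
        labels[i] = s.label / config.max_worms
        label_mask[i, s.k + 1 :] = 1.0
        initial[i] = s.count_prefix[0]

    return {"counts": counts, "mask": mask, "frames": frames, "coords": coords,
            "labels": labels, "label_mask": label_mask, "initial": initial}


# -- the predictor -----------------------------------------------------------


class LifespanPredictor(nn.Module):
    """Maps a masked assay prefix to a future live-count vector."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        head_in = 0
        if config.mode in ("bimodal_images", "images_only"):
            channels = (1,) + tuple(config.conv_channels)
            self.convs = [nn.Conv2d(channels[i], channels[i + 1], rng)
                          for i in range(len(channels) - 1)]
            self.image_rnn = nn.LSTMCell(config.conv_channels[-1],
                                         config.image_rnn_width, rng)
            head_in += config.image_rnn_width
        if config.mode == "bimodal_coords":
            self.coord_embed = nn.Linear(MAX_WORMS * 2, config.conv_channels[-1], rng)
            self.image_rnn = nn.LSTMCell(config.conv_channels[-1],
                                         config.image_rnn_width, rng)
            head_in += config.image_rnn_width
        if config.mode in ("bimodal_images", "counts_only", "bimodal_coords"):
            self.count_rnn = nn.LSTMCell(1, config.count_rnn_width, rng)
            head_in += config.count_rnn_width
        self.head1 = nn.Linear(head_in, config.head_hidden, rng)
        self.head2 = nn.Linear(config.head_hidden, config.max_days, rng)

    # forward returns scaled counts (worms / max_worms)
    def forward(self, batch: dict) -> nn.Tensor:
        cfg = self.config
        mask = batch["mask"]
        b, t = mask.shape
        features: list[nn.Tensor] = []

        if cfg.mode in ("bimodal_images", "images_only"):
            frames = batch["frames"]
            side = frames.shape[2]
            # encode only the valid (unpadded) frames, then scatter back
            valid = np.nonzero(mask.reshape(-1) > 0)[0]
            x = nn.Tensor(frames.reshape(b * t, 1, side, side)[valid])
            for conv in self.convs:
                x = conv(x).relu()
            emb_valid = x.mean(axis=(2, 3))  # (n_valid, C)
            emb = nn.scatter_rows(emb_valid, valid, b * t)
            emb = emb.reshape(b, t, cfg.conv_channels[-1])
            xs = [emb[:, step, :] for step in range(t)]
            features.append(self.image_rnn.run(xs, mask))
        if cfg.mode == "bimodal_coords":
            coords = batch["coords"].reshape(b, t, MAX_WORMS * 2)
            xs = [self.coord_embed(nn.Tensor(coords[:, step, :])).relu()
                  for step in range(t)]
            features.append(self.image_rnn.run(xs, mask))
        if cfg.mode in ("bimodal_images", "counts_only", "bimodal_coords"):
            counts = batch["counts"]
            xs = [nn.Tensor(counts[:, step : step + 1]) for step in range(t)]
            features.append(self.count_rnn.run(xs, mask))

        h = features[0] if len(features) == 1 else nn.concat(features, axis=1)
        return self.head2(self.head1(h).relu())

    def predict(self, samples: Sequence[ModelSample]) -> np.ndarray:
        """Raw (pre-post-processing) predictions in worms, clipped at 0."""
        batch = assemble_batch(samples, self.config)
        out = self.forward(batch).data * self.config.max_worms
        return np.maximum(out, 0.0)


def build_model(config: ModelConfig, seed: int = 0) -> LifespanPredictor:
    """Construct a predictor with seeded parameter initialization."""
    return LifespanPredictor(config, seed=seed)


# -- training ----------------------------------------------------------------


def _masked_mse(pred: nn.Tensor, labels: np.ndarray, label_mask: np.ndarray) -> nn.Tensor:
    diff = pred - nn.Tensor(labels)
    sq = diff * diff * nn.Tensor(label_mask)
    return sq.sum() * (1.0 / label_mask.sum())


def _eval_mse(predictor: LifespanPredictor, samples: Sequence[ModelSample],
              batch_size: int) -> float:
    total, weight = 0.0, 0.0
    for lo in range(0, len(samples), batch_size):
        chunk = samples[lo : lo + batch_size]
        batch = assemble_batch(chunk, predictor.config)
        pred = predictor.forward(batch)
        w = batch["label_mask"].sum()
        total += float(_masked_mse(pred, batch["labels"], batch["label_mask"]).data) * w
        weight += w
    return total / weight


def train(
    predictor: LifespanPredictor,
    train_samples: Sequence[ModelSample],
    val_samples: Sequence[ModelSample],
    config: TrainConfig,
) -> tuple[LifespanPredictor, LossRecord]:
    """SGD training with masked-MSE loss and best-validation checkpointing.

    Returns the predictor restored to its best validation epoch (or the last
    epoch when no validation samples are given) and the per-epoch loss
    record in squared worms.
    """
    if not train_samples:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(config.seed)
    opt = nn.SGD(predictor.parameters(), lr=config.learning_rate,
                 momentum=config.momentum)
    record = LossRecord()
    scale2 = predictor.config.max_worms ** 2
    best_val, best_state = np.inf, None

    order = np.arange(len(train_samples))
    for epoch in range(config.epochs):
        rng.shuffle(order)
        epoch_total, epoch_weight = 0.0, 0.0
        for lo in range(0, len(order), config.batch_size):
            chunk = [train_samples[i] for i in order[lo : lo + config.batch_size]]
            batch = assemble_batch(chunk, predictor.config)
            pred = predictor.forward(batch)
            loss = _masked_mse(pred, batch["labels"], batch["label_mask"])
            if not np.isfinite(loss.data):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch + 1}; reduce the learning "
                    f"rate (current {config.learning_rate})"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            w = batch["label_mask"].sum()
            epoch_total += float(loss.data) * w
            epoch_weight += w
        record.train_mse.append(epoch_total / epoch_weight * scale2)
        if val_samples:
            val = _eval_mse(predictor, val_samples, config.batch_size) * scale2
            record.val_mse.append(val)
            if val < best_val:
                best_val, best_state = val, predictor.state()
        else:
            record.val_mse.append(float("nan"))
    if best_state is not None:
        predictor.load_state(best_state)
    return predictor, record


# -- inference ---------------------------------------------------------------


def postprocess_prediction(
    raw_future: np.ndarray, observed: np.ndarray, max_days: int
) -> np.ndarray:
    """Merge an observed prefix with a raw prediction into a valid curve.

    Days 0..k keep the observed counts; later days take the raw prediction
    clipped to [0, initial] and forced non-increasing by a running minimum
    seeded at the last observed count.
    """
    observed = np.asarray(observed, dtype=float)
    k = len(observed) - 1
    initial = observed[0]
    out = np.zeros(max_days)
    out[: k + 1] = observed
    future = np.clip(raw_future[k + 1 : max_days], 0.0, initial)
    out[k + 1 :] = np.minimum.accumulate(np.concatenate([[observed[-1]], future]))[1:]
    return out


def save_checkpoint(predictor: LifespanPredictor, path) -> None:
    """Serialize config + parameters to an .npz checkpoint."""
    import json
    from dataclasses import asdict

    cfg = asdict(predictor.config)
    cfg["image_spec"] = asdict(predictor.config.image_spec)
    arrays = {f"param_{i}": p for i, p in enumerate(predictor.state())}
    np.savez(path, config=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> LifespanPredictor:
    import json

    with np.load(path) as data:
        cfg = json.loads(bytes(data["config"]).decode())
        cfg["image_spec"] = ImageSpec(**cfg["image_spec"])
        cfg["conv_channels"] = tuple(cfg["conv_channels"])
        config = ModelConfig(**cfg)
        predictor = LifespanPredictor(config, seed=0)
        n = len(predictor.parameters())
        predictor.load_state([data[f"param_{i}"] for i in range(n)])
    return predictor


def predict_plate(
    predictor: LifespanPredictor,
    count_prefix: np.ndarray,
    frame_prefix=None,
    coord_prefix: np.ndarray | None = None,
) -> np.ndarray:
    """Predict one plate's full curve (length ``max_days``) from its prefix.

    The returned vector holds the observed counts through day k and the
    post-processed (clipped, non-increasing) predicted counts afterwards.
    """
    count_prefix = np.asarray(count_prefix, dtype=float)
    if count_prefix.ndim != 1 or len(count_prefix) < 1:
        raise ValueError("count_prefix must be a non-empty 1-D array")
    if count_prefix.min() >= count_prefix[0]:
        import warnings

        warnings.warn(
            "prefix shows no death yet; predictions before the first drop day "
            "are outside the model's training regime",
            stacklevel=2,
        )
    k = len(count_prefix) - 1
    sample = ModelSample(
        count_prefix=count_prefix,
        frame_prefix=frame_prefix,
        label=np.zeros(predictor.config.max_days),
        k=k,
        plate_id=-1,
        coord_prefix=coord_prefix,
    )
    raw = predictor.predict([sample])[0]
    return postprocess_prediction(raw, count_prefix, predictor.config.max_days)
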