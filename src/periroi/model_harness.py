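"""Transfer-learning style classification harness.

Assembles :class:`~periroi.roi_extract.Extraction` samples into a dataset,
augments, trains a binary classifier, and emits per-case scores. The
harness is backbone-agnostic:

``small_cnn`` (alias ``small_cnn_test``)
    A compact two-block convolutional network implemented in pure NumPy
    (see :mod:`periroi._nn`), trained end-to-end. Deterministic per seed on
    CPU and fast enough that the full configuration grid runs at desk scale.
``resnet50_imagenet``
    ImageNet-pretrained ResNet-50 with the final layer replaced by a
    1-logit head, for full-scale runs. Requires ``torch``/``torchvision``
    (imported lazily; installing the ``periroi[torch]`` extra).

Leakage guards: per-channel standardization statistics are computed on the
train cohort only and frozen into the model; validation cohorts never
influence them, and no augmentation is applied at inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

from . import _nn
from .io_volumes import CaseRecord
from .roi_extract import Extraction, RoiSpec

__all__ = [
    "TrainConfig",
    "ScoreSet",
    "RoiDataset",
    "build_dataset",
    "augment",
    "train_classifier",
    "predict",
    "run_grid",
]

BACKBONES = ("small_cnn", "small_cnn_test", "resnet50_imagenet")


@dataclass
class TrainConfig:
    backbone: str = "small_cnn"
    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 1e-4
    weight_decay: float = 0.0
    random_crop: bool = True
    hflip: bool = True
    vflip: bool = True
    seed: int = 0
    class_weighting: str = "none"  # {"none", "inverse_prevalence"}
    early_stop_patience: int = 8
    early_stop_min_delta: float = 1e-4
    hidden_channels: tuple[int, int] = (8, 16)

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.backbone not in BACKBONES:
            raise ValueError(f"backbone must be one of {BACKBONES}")
        if self.class_weighting not in ("none", "inverse_prevalence"):
            raise ValueError("class_weighting must be 'none' or 'inverse_prevalence'")


@dataclass
class ScoreSet:
    """Per-case probability scores for one cohort under one grid cell."""

    scores: dict[str, float]
    labels: dict[str, int]
    cohort: str
    spec: RoiSpec

    def __post_init__(self) -> None:
        for cid, s in self.scores.items():
            if not np.isfinite(s) or not (0.0 <= s <= 1.0):
                raise ValueError(f"score for {cid} outside [0,1]: {s}")
        if set(self.scores) != set(self.labels):
            raise ValueError("scores and labels must cover the same cases")

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        ids = sorted(self.scores)
        return (
            np.array([self.scores[i] for i in ids]),
            np.array([self.labels[i] for i in ids]),
        )


def _spec_key(spec: RoiSpec):
    return tuple(getattr(spec, f.name) for f in fields(RoiSpec))


@dataclass
class RoiDataset:
    """Stacked samples in deterministic (sorted case_id) order."""

    X: np.ndarray  # (N, C, ...) float64
    y: np.ndarray  # (N,)
    case_ids: list[str]
    cohorts: list[str]
    spec: RoiSpec
    channel_mean: Optional[np.ndarray] = None  # frozen train-cohort statistics
    channel_sd: Optional[np.ndarray] = None

    def subset(self, cohort: str) -> "RoiDataset":
        idx = [i for i, c in enumerate(self.cohorts) if c == cohort]
        if not idx:
            raise ValueError(f"no cases in cohort {cohort!r}")
        return RoiDataset(
            X=self.X[idx],
            y=self.y[idx],
            case_ids=[self.case_ids[i] for i in idx],
            cohorts=[cohort] * len(idx),
            spec=self.spec,
            channel_mean=self.channel_mean,
            channel_sd=self.channel_sd,
        )

    def standardized(self) -> np.ndarray:
        if self.channel_mean is None:
            return self.X
        shape = (1, -1) + (1,) * (self.X.ndim - 2)
        return (self.X - self.channel_mean.reshape(shape)) / self.channel_sd.reshape(shape)


def build_dataset(
    manifest: Sequence[CaseRecord], extractions: Mapping[str, Extraction]
) -> RoiDataset:
    """Assemble extractions for every manifest case into one dataset.

    All extractions must share a single RoiSpec. Per-channel mean/sd are
    computed over the train cohort only and frozen on the dataset, so
    validation cohorts reuse the train statistics.
    """
    records = sorted(manifest, key=lambda r: r.case_id)
    missing = [r.case_id for r in records if r.case_id not in extractions]
    if missing:
        raise ValueError(f"missing extraction(s) for case(s): {', '.join(missing)}")
    specs = {_spec_key(extractions[r.case_id].spec) for r in records}
    if len(specs) > 1:
        raise ValueError("extractions mix multiple RoiSpecs; one spec per dataset")
    X = np.stack([extractions[r.case_id].sample for r in records]).astype(np.float64)
    y = np.array([r.label for r in records], dtype=np.int64)
    cohorts = [r.cohort for r in records]
    ds = RoiDataset(
        X=X,
        y=y,
        case_ids=[r.case_id for r in records],
        cohorts=cohorts,
        spec=extractions[records[0].case_id].spec,
    )
    train_idx = [i for i, c in enumerate(cohorts) if c == "train"]
    stat_idx = train_idx if train_idx else list(range(len(records)))
    axes = (0,) + tuple(range(2, X.ndim))
    ds.channel_mean = X[stat_idx].mean(axis=axes)
    sd = X[stat_idx].std(axis=axes)
    ds.channel_sd = np.where(sd > 0, sd, 1.0)
    return ds


# -- augmentation -----------------------------------------------------------

def _random_crop_resize(sample: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random 90%-side crop, resized back to the input shape (per channel)."""
    spatial = sample.shape[1:]
    crop = [max(1, int(round(0.9 * s))) for s in spatial]
    starts = [rng.integers(0, s - c + 1) for s, c in zip(spatial, crop)]
    sl = (slice(None),) + tuple(slice(a, a + c) for a, c in zip(starts, crop))
    cropped = sample[sl]
    out = np.empty_like(sample)
    for ch in range(sample.shape[0]):
        out[ch] = _sk_resize(
            cropped[ch], spatial, order=1, preserve_range=True,
            anti_aliasing=False, mode="edge",
        )
    return out


def augment(sample: np.ndarray, config: TrainConfig, seed: int) -> np.ndarray:
    """Seeded random augmentation: 90% crop + resize, horizontal and vertical
    flips (each with probability 1/2 when enabled). For 3D patches the flips
    apply along every spatial axis. Output shape equals input shape; with all
    toggles off this is the identity."""
    rng = np.random.default_rng(seed)
    out = sample
    if config.random_crop:
        out = _random_crop_resize(out, rng)
    flip_axes = range(1, out.ndim)
    toggles = [config.vflip, config.hflip] if out.ndim == 3 else [config.vflip] * (
        out.ndim - 2
    ) + [config.hflip]
    for ax, enabled in zip(flip_axes, toggles):
        if enabled and rng.random() < 0.5:
            out = np.flip(out, axis=ax)
    return np.ascontiguousarray(out)


# -- backbones --------------------------------------------------------------

def _even_floor(n: int) -> int:
    return n if n % 2 == 0 else n - 1


class SmallCnnModel:
    """Compact CNN: two conv(3)+ReLU+pool blocks, global average pooling,
    linear 1-logit head. Works on (C, H, W) and (C, D, H, W) samples."""

    def __init__(self, in_shape: tuple[int, ...], config: TrainConfig, rng):
        ndim = len(in_shape) - 1
        c_in = in_shape[0]
        c1, c2 = config.hidden_channels
        # spatial sizes must survive two factor-2 pools
        self.crop_to = tuple(max(4, (s // 4) * 4) for s in in_shape[1:])
        self.net = _nn.Sequential(
            [
                _nn.Conv(c_in, c1, 3, ndim, rng),
                _nn.ReLU(),
                _nn.AvgPool2(),
                _nn.Conv(c1, c2, 3, ndim, rng),
                _nn.ReLU(),
                _nn.AvgPool2(),
                _nn.GlobalAvgPool(),
                _nn.Linear(c2, 1, rng),
            ]
        )

    def _fit_input(self, X: np.ndarray) -> np.ndarray:
        sl = (slice(None), slice(None)) + tuple(slice(0, c) for c in self.crop_to)
        return X[sl]

    def logits(self, X: np.ndarray) -> np.ndarray:
        return self.net.forward(self._fit_input(X))[:, 0]


@dataclass
class TrainedModel:
    backbone: object
    config: TrainConfig
    spec: RoiSpec
    channel_mean: np.ndarray
    channel_sd: np.ndarray
    history: list[float] = field(default_factory=list)

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        shape = (1, -1) + (1,) * (X.ndim - 2)
        return (X - self.channel_mean.reshape(shape)) / self.channel_sd.reshape(shape)


def train_classifier(dataset: RoiDataset, config: TrainConfig) -> TrainedModel:
    """Fine-tune a binary classifier on the dataset's train cohort.

    Seeded end-to-end: weight init, shuffling and augmentation all derive
    from ``config.seed``. Training stops early when the epoch loss has not
    improved by ``early_stop_min_delta`` for ``early_stop_patience`` epochs.
    """
    if config.backbone == "resnet50_imagenet":
        raise ImportError(
            "the resnet50_imagenet backbone requires torch/torchvision "
            "(install the periroi[torch] extra); use the small_cnn backbone "
            "for dependency-free runs"
        )
    train = dataset.subset("train")
    n_pos = int(train.y.sum())
    n_neg = len(train.y) - n_pos
    if n_pos < 2 or n_neg < 2:
        raise ValueError(
            f"need >= 2 cases per class in the train split (got {n_pos} pos / {n_neg} neg)"
        )
    ss = np.random.SeedSequence(config.seed)
    init_ss, shuffle_ss, aug_ss = ss.spawn(3)
    rng_init = np.random.default_rng(init_ss)
    model = SmallCnnModel(train.X.shape[1:], config, rng_init)
    opt = _nn.Adam(
        model.net.params(), lr=config.learning_rate, weight_decay=config.weight_decay
    )
    X = train.standardized()
    y = train.y.astype(np.float64)
    if config.class_weighting == "inverse_prevalence":
        w_pos = len(y) / (2.0 * n_pos)
        w_neg = len(y) / (2.0 * n_neg)
        weights = np.where(y == 1, w_pos, w_neg)
    else:
        weights = np.ones_like(y)

    shuffle_rng = np.random.default_rng(shuffle_ss)
    aug_rng = np.random.default_rng(aug_ss)
    history: list[float] = []
    best = np.inf
    stall = 0
    n = len(y)
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = np.stack(
                [
                    augment(X[i], config, int(aug_rng.integers(0, 2**31 - 1)))
                    for i in idx
                ]
            )
            model.net.zero_grad()
            logits = model.net.forward(model._fit_input(batch))
            loss, dlogits = _nn.bce_with_logits(logits[:, 0], y[idx], weights[idx])
            model.net.backward(dlogits[:, np.newaxis])
            opt.step(model.net.grads())
            epoch_loss += loss * len(idx)
        epoch_loss /= n
        history.append(epoch_loss)
        if epoch_loss < best - config.early_stop_min_delta:
            best = epoch_loss
            stall = 0
        else:
            stall += 1
            if config.early_stop_patience and stall >= config.early_stop_patience:
                break

    return TrainedModel(
        backbone=model,
        config=config,
        spec=dataset.spec,
        channel_mean=dataset.channel_mean.copy(),
        channel_sd=dataset.channel_sd.copy(),
        history=history,
    )


def predict(model: TrainedModel, dataset: RoiDataset, cohort: Optional[str] = None) -> ScoreSet:
    """Sigmoid scores for a dataset (or one cohort of it); no augmentation."""
    if _spec_key(model.spec) != _spec_key(dataset.spec):
        raise ValueError("dataset RoiSpec does not match the model's RoiSpec")
    ds = dataset.subset(cohort) if cohort is not None else dataset
    X = model._standardize(ds.X)
    scores: dict[str, float] = {}
    bs = max(1, model.config.batch_size)
    for start in range(0, len(ds.case_ids), bs):
        logits = model.backbone.logits(X[start : start + bs])
        probs = _nn.sigmoid(logits)
        for cid, p in zip(ds.case_ids[start : start + bs], probs):
            scores[cid] = float(p)
    labels = {cid: int(lab) for cid, lab in zip(ds.case_ids, ds.y)}
    return ScoreSet(scores=scores, labels=labels, cohort=cohort or "all", spec=ds.spec)


def run_grid(
    manifest: Sequence[CaseRecord],
    extractions_by_cell: Mapping[tuple, Mapping[str, Extraction]],
    config: TrainConfig,
    cohorts: Sequence[str] = ("train", "val1", "val2"),
) -> dict[tuple, dict[str, ScoreSet]]:
    """Train one model per grid cell and score every requested cohort.

    ``extractions_by_cell`` maps ``(mode, radius_mm, scenario)`` to per-case
    extractions. Per-cell seeds are derived from the base seed and the cell's
    position in sorted order, so partial grids reproduce full-grid cells.
    """
    present = {r.cohort for r in manifest}
    results: dict[tuple, dict[str, ScoreSet]] = {}
    for i, cell in enumerate(sorted(extractions_by_cell, key=str)):
        cell_config = replace(config, seed=config.seed + 1000 * i)
        ds = build_dataset(manifest, extractions_by_cell[cell])
        model = train_classifier(ds, cell_config)
        results[cell] = {
            c: predict(model, ds, cohort=c) for c in cohorts if c in present
        }
    return results
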