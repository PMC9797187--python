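"""Probe-head training over a frozen representation, and simulated responders.

The probing protocol: render word stimuli whose hues are drawn from K
narrow training bands, push them through a *frozen* feature extractor,
train a fresh softmax readout (the probe head) on the features, then
classify freshly rendered stimuli at every step of the hue spectrum.
Repeating this while the training bands shift around the circle yields
the row stacks analyzed in :mod:`huecat.borders`.

Because the question is about the representation and not the optimizer,
the probe head is deliberately minimal: a single affine layer trained
with cross-entropy by minibatch SGD on standardized features, keeping
the per-epoch checkpoint with the best validation accuracy.

Two simulated responders bracket the hypotheses: a *categorical*
responder with planted borders (labels follow the planted category of
each hue, so borders are invariant to band shifts) and a *continuous*
responder (labels follow the nearest band center, so borders track the
bands).  Both support label noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import stimuli
from .borders import row_modes
from .colorspace import HueBandSet, bin_centers, circular_distance, make_uniform_bands

__all__ = [
    "FeatureExtractor",
    "ForegroundMeanColor",
    "DownsampleExtractor",
    "FrozenConvExtractor",
    "TrainConfig",
    "EvalGrid",
    "ProbeHead",
    "train_probe_head",
    "ClassificationRow",
    "evaluate_spectrum",
    "invariant_plan",
    "run_invariant_experiment",
    "ResponderModel",
    "category_of",
    "simulate_row",
    "make_scratch_category_backbone",
    "TrainingError",
]


class TrainingError(RuntimeError):
    """Raised when a training run fails (non-finite loss, missed criterion)."""


class FeatureExtractor:
    """Deterministic map from uint8 rasters to fixed-length feature vectors."""

    name: str = "base"
    dim: int = 0

    def extract(self, images: np.ndarray) -> np.ndarray:
        """``(N, H, W, 3) uint8 -> (N, D) float32``."""
        raise NotImplementedError

    def __call__(self, image: np.ndarray) -> np.ndarray:
        return self.extract(np.asarray(image)[None])[0]


class ForegroundMeanColor(FeatureExtractor):
    """Mean RGB of non-background pixels (D = 3).

    The background is estimated per image as the per-channel median (the
    dominant flat fill in all stimulus families); foreground pixels are
    those deviating from it in any channel.  An analytic stand-in for a
    purely chromatic representation.
    """

    name = "fg-mean-rgb"
    dim = 3

    def __init__(self, threshold: int = 8):
        self.threshold = threshold

    def extract(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images)
        out = np.empty((len(images), 3), dtype=np.float32)
        for i, img in enumerate(images):
            bg = np.median(img.reshape(-1, 3), axis=0)
            mask = np.any(
                np.abs(img.astype(np.int16) - bg.astype(np.int16)) > self.threshold,
                axis=-1,
            )
            if mask.any():
                out[i] = img[mask].mean(axis=0) / 255.0
            else:
                out[i] = bg / 255.0
        return out


class DownsampleExtractor(FeatureExtractor):
    """Normalized image mean-pooled to a coarse grid (shape + color)."""

    def __init__(self, pool: int = 14, size: int = stimuli.RASTER_SIZE):
        if size % pool:
            raise ValueError("pool must divide the raster size")
        self.pool = pool
        self.grid = size // pool
        self.dim = self.grid * self.grid * 3
        self.name = f"downsample-{self.grid}x{self.grid}"

    def extract(self, images: np.ndarray, chunk: int = 64) -> np.ndarray:
        images = np.asarray(images)
        n = len(images)
        g, p = self.grid, self.pool
        mean = np.float32(stimuli.IMAGENET_MEAN)
        sd = np.float32(stimuli.IMAGENET_SD)
        out = np.empty((n, self.dim), dtype=np.float32)
        size = g * p
        for start in range(0, n, chunk):
            block = images[start : start + chunk]
            m = len(block)
            # two-stage integer pooling keeps the reductions contiguous
            rows = block.reshape(m, g, p, size * 3).sum(axis=2, dtype=np.uint32)
            pooled = rows.reshape(m, g, g, p, 3).sum(axis=3, dtype=np.uint32)
            pooled = pooled.astype(np.float32) / np.float32(p * p * 255.0)
            out[start : start + chunk] = ((pooled - mean) / sd).reshape(m, self.dim)
        return out


class FrozenConvExtractor(FeatureExtractor):
    """Penultimate activations of a frozen trained convolutional network.

    The network applies a 1x1 convolution (shared per-pixel affine map,
    3 -> C channels) with ReLU over a coarsely pooled grid, global max
    pooling, and a dense ReLU layer; that dense hidden layer is the
    penultimate layer exposed here.
    """

    def __init__(self, base: "DownsampleExtractor", w1: np.ndarray, b1: np.ndarray,
                 w2: np.ndarray, b2: np.ndarray, name: str = "scratch-conv"):
        self.base = base
        self.w1 = w1
        self.b1 = b1
        self.w2 = w2
        self.b2 = b2
        self.dim = w2.shape[1]
        self.name = name

    def extract(self, images: np.ndarray) -> np.ndarray:
        x = self.base.extract(images).reshape(len(images), -1, 3)
        pooled = np.maximum(x @ self.w1 + self.b1, 0.0).max(axis=1)
        return np.maximum(pooled @ self.w2 + self.b2, 0.0)


@dataclass(frozen=True)
class TrainConfig:
    n_train_per_class: int = 500
    n_val_per_class: int = 50
    epochs: int = 5
    batch_size: int = 64
    learning_rate: float = 0.2
    seed: int = 0

    def __post_init__(self):
        for name in ("n_train_per_class", "n_val_per_class", "epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class EvalGrid:
    n_bins: int = 100
    samples_per_bin: int = 60

    def __post_init__(self):
        if self.n_bins <= 0 or self.samples_per_bin <= 0:
            raise ValueError("grid sizes must be positive")


@dataclass
class ProbeHead:
    """Affine softmax readout on standardized features."""

    weights: np.ndarray  # (D, K)
    bias: np.ndarray  # (K,)
    feat_mean: np.ndarray
    feat_sd: np.ndarray
    trained: bool = False
    val_accuracy: float = 0.0
    val_history: tuple = ()

    @property
    def n_classes(self) -> int:
        return int(self.weights.shape[1])

    def scores(self, feats: np.ndarray) -> np.ndarray:
        z = (np.asarray(feats) - self.feat_mean) / self.feat_sd
        return z @ self.weights + self.bias

    def predict(self, feats: np.ndarray) -> np.ndarray:
        if not self.trained:
            raise RuntimeError("probe head has not been trained")
        return np.argmax(self.scores(feats), axis=-1)


def _softmax_sgd(x, y, xv, yv, k, epochs, batch, lr, rng):
    """Minibatch SGD on softmax cross-entropy, checkpointing on val accuracy."""
    n, d = x.shape
    w = rng.normal(0.0, 0.01, size=(d, k))
    b = np.zeros(k)
    best = (-1.0, w.copy(), b.copy())
    history = []
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            z = x[idx] @ w + b
            z -= z.max(axis=1, keepdims=True)
            p = np.exp(z)
            p /= p.sum(axis=1, keepdims=True)
            p[np.arange(len(idx)), y[idx]] -= 1.0
            if not np.all(np.isfinite(p)):
                raise TrainingError("non-finite loss gradient during probe training")
            g = x[idx].T @ p / len(idx)
            w -= lr * g
            b -= lr * p.mean(axis=0)
        acc = float(np.mean(np.argmax(xv @ w + b, axis=1) == yv))
        history.append(acc)
        if acc > best[0]:
            best = (acc, w.copy(), b.copy())
    return best[1], best[2], best[0], tuple(history)


def _render_band_batch(bands, n_per_class, cfg_stim, rng, stimulus_fn):
    imgs, labels = [], []
    for cls, band in enumerate(bands.bands):
        for _ in range(n_per_class):
            hue = float(band.sample(rng))
            imgs.append(stimulus_fn(hue, cfg_stim, rng))
            labels.append(cls)
    return np.stack(imgs), np.array(labels)


def train_probe_head(
    extractor: FeatureExtractor,
    bands: HueBandSet,
    cfg: TrainConfig | None = None,
    rng: np.random.Generator | None = None,
    stimulus_fn=None,
    stimulus_cfg: stimuli.WordStimulusConfig | None = None,
) -> ProbeHead:
    """Train a fresh readout on word stimuli sampled from the training bands.

    The extractor stays frozen; only the affine readout is fit.  The
    per-epoch checkpoint with the best validation accuracy is returned.
    """
    cfg = cfg or TrainConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    stimulus_fn = stimulus_fn or (lambda hue, c, r: stimuli.render_word_stimulus(hue, c, r))
    stimulus_cfg = stimulus_cfg or stimuli.WordStimulusConfig()
    k = bands.n_classes
    xtr_img, ytr = _render_band_batch(bands, cfg.n_train_per_class, stimulus_cfg, rng, stimulus_fn)
    xva_img, yva = _render_band_batch(bands, cfg.n_val_per_class, stimulus_cfg, rng, stimulus_fn)
    xtr = extractor.extract(xtr_img)
    xva = extractor.extract(xva_img)
    mean = xtr.mean(axis=0)
    sd = xtr.std(axis=0) + 1e-6
    w, b, acc, history = _softmax_sgd(
        (xtr - mean) / sd, ytr, (xva - mean) / sd, yva,
        k, cfg.epochs, cfg.batch_size, cfg.learning_rate, rng,
    )
    return ProbeHead(weights=w, bias=b, feat_mean=mean, feat_sd=sd,
                     trained=True, val_accuracy=acc, val_history=history)


@dataclass
class ClassificationRow:
    """Per-bin sample predictions from one spectrum evaluation, plus the mode row."""

    samples: np.ndarray  # (n_bins, samples_per_bin) class labels
    meta: dict = field(default_factory=dict)
    mode_row: np.ndarray = field(init=False)

    def __post_init__(self):
        self.samples = np.asarray(self.samples)
        self.mode_row = row_modes(self.samples)

    @property
    def n_bins(self) -> int:
        return int(self.samples.shape[0])


def evaluate_spectrum(
    head: ProbeHead,
    extractor: FeatureExtractor,
    grid: EvalGrid | None = None,
    rng: np.random.Generator | None = None,
    stimulus_fn=None,
    stimulus_cfg: stimuli.WordStimulusConfig | None = None,
    meta: dict | None = None,
) -> ClassificationRow:
    """Classify freshly rendered stimuli at every spectrum bin center."""
    grid = grid or EvalGrid()
    rng = rng if rng is not None else np.random.default_rng()
    stimulus_fn = stimulus_fn or (lambda hue, c, r: stimuli.render_word_stimulus(hue, c, r))
    stimulus_cfg = stimulus_cfg or stimuli.WordStimulusConfig()
    if not head.trained:
        raise RuntimeError("probe head has not been trained")
    centers = bin_centers(grid.n_bins)
    samples = np.empty((grid.n_bins, grid.samples_per_bin), dtype=np.int16)
    for b, hue in enumerate(centers):
        imgs = np.stack([
            stimulus_fn(float(hue), stimulus_cfg, rng)
            for _ in range(grid.samples_per_bin)
        ])
        samples[b] = head.predict(extractor.extract(imgs))
    return ClassificationRow(samples=samples, meta=dict(meta or {}))


def invariant_plan(class_counts=(4, 5, 6, 7, 8, 9), n_shifts: int = 150):
    """The (K, shift) design grid of the invariant-border experiment.

    Shift i spans the full circle: ``shift = i / n_shifts``.
    """
    return [
        (int(k), i, i / n_shifts)
        for k in class_counts
        for i in range(n_shifts)
    ]


def run_invariant_experiment(
    extractor: FeatureExtractor,
    class_counts=(4, 5, 6, 7, 8, 9),
    n_shifts: int = 150,
    cfg: TrainConfig | None = None,
    grid: EvalGrid | None = None,
    seed: int = 0,
    stimulus_fn=None,
    responder: "ResponderModel | None" = None,
    progress: bool = False,
) -> list:
    """Train and evaluate one probe per (class count, band shift) cell.

    With ``responder`` given, training and evaluation are replaced by the
    simulated responder (no rendering).  Failed trainings are logged in
    the row's place as ``None`` and excluded; callers may count them.
    """
    cfg = cfg or TrainConfig()
    grid = grid or EvalGrid()
    plan = invariant_plan(class_counts, n_shifts)
    rows = []
    iterator = plan
    if progress:
        try:
            from tqdm import tqdm

            iterator = tqdm(plan)
        except ImportError:
            pass
    for k, i, shift in iterator:
        bands = make_uniform_bands(k, shift)
        rng = np.random.default_rng(np.random.SeedSequence([seed, k, i]))
        meta = {"n_classes": k, "shift_index": i, "shift": shift}
        try:
            if responder is not None:
                row = simulate_row(responder, bands, grid, rng)
                row.meta.update(meta)
            else:
                head = train_probe_head(extractor, bands, cfg, rng, stimulus_fn)
                row = evaluate_spectrum(head, extractor, grid, rng, stimulus_fn, meta=meta)
        except TrainingError:
            rows.append(None)
            continue
        rows.append(row)
    return rows


@dataclass(frozen=True)
class ResponderModel:
    """Analytic stand-in for a trained network.

    ``categorical`` responders carry planted circular borders: every hue
    is labeled by the class associated with its planted category, so the
    mode-row transitions sit at the planted borders regardless of band
    shift.  ``continuous`` responders label each hue with the circularly
    nearest band center, so transitions track the bands.  Each sample
    label is flipped to a uniformly random other class with probability
    ``label_noise``.
    """

    kind: str  # "categorical" | "continuous"
    borders: np.ndarray | None = None
    label_noise: float = 0.0

    def __post_init__(self):
        if self.kind not in ("categorical", "continuous"):
            raise ValueError(f"unknown responder kind {self.kind!r}")
        if not 0 <= self.label_noise < 1:
            raise ValueError("label_noise must lie in [0, 1)")
        if self.kind == "categorical":
            if self.borders is None:
                raise ValueError("categorical responder requires planted borders")
            object.__setattr__(
                self, "borders", np.sort(np.asarray(self.borders, dtype=float) % 1.0)
            )


def category_of(h, borders: np.ndarray) -> np.ndarray:
    """Index of the planted category containing hue(s) ``h``.

    Category ``i`` spans ``[borders[i], borders[i+1])`` circularly.
    """
    borders = np.asarray(borders)
    idx = np.searchsorted(borders, np.asarray(h, dtype=float) % 1.0, side="right") - 1
    return idx % len(borders)


def _categorical_class_map(bands: HueBandSet, borders: np.ndarray) -> np.ndarray:
    """Class label for each planted category (ties/empties by nearest band center)."""
    n_cat = len(borders)
    centers = bands.centers
    center_cat = category_of(centers, borders)
    cat_mid = np.array([
        (borders[i] + 0.5 * ((borders[(i + 1) % n_cat] - borders[i]) % 1.0)) % 1.0
        for i in range(n_cat)
    ])
    mapping = np.empty(n_cat, dtype=int)
    for cat in range(n_cat):
        inside = np.nonzero(center_cat == cat)[0]
        pool = inside if len(inside) else np.arange(len(centers))
        d = circular_distance(centers[pool], cat_mid[cat])
        mapping[cat] = int(pool[np.argmin(d)])
    return mapping


def simulate_row(
    model: ResponderModel,
    bands: HueBandSet,
    grid: EvalGrid | None = None,
    rng: np.random.Generator | None = None,
) -> ClassificationRow:
    """Produce a classification row directly from a responder (no rendering)."""
    grid = grid or EvalGrid()
    rng = rng if rng is not None else np.random.default_rng()
    centers = bin_centers(grid.n_bins)
    if model.kind == "continuous":
        d = circular_distance(centers[:, None], bands.centers[None, :])
        clean = np.argmin(d, axis=1)
    else:
        mapping = _categorical_class_map(bands, model.borders)
        clean = mapping[category_of(centers, model.borders)]
    samples = np.repeat(clean[:, None], grid.samples_per_bin, axis=1).astype(np.int16)
    if model.label_noise > 0:
        k = bands.n_classes
        flip = rng.random(samples.shape) < model.label_noise
        offsets = rng.integers(1, k, size=samples.shape)
        samples = np.where(flip, (samples + offsets) % k, samples).astype(np.int16)
    return ClassificationRow(
        samples=samples,
        meta={"responder": model.kind, "n_classes": bands.n_classes,
              "shift": getattr(bands, "shift", None)},
    )


def make_scratch_category_backbone(
    planted_borders,
    seed: int = 0,
    n_channels: int = 32,
    hidden_dim: int = 16,
    pool: int = 8,
    n_train_per_class: int = 300,
    n_val_per_class: int = 40,
    n_epochs: int = 100,
    learning_rate: float = 0.05,
    lr_decay: float = 0.98,
    label_smoothing: float = 0.1,
    weight_decay: float = 3e-3,
    batch_size: int = 64,
    val_criterion: float = 0.95,
    stimulus_cfg: stimuli.WordStimulusConfig | None = None,
) -> FrozenConvExtractor:
    """Train a small convolutional network from scratch on planted categories.

    The network -- a 1x1 convolution (3 -> ``n_channels``) with ReLU over
    a coarsely pooled grid, global max pooling, a dense ReLU layer of
    ``hidden_dim`` units and a dense softmax output -- is trained
    end-to-end to classify word stimuli whose hues are uniform over the
    spectrum and whose labels are the planted categories, until
    validation accuracy reaches ``val_criterion``.  The trunk up to the
    dense hidden layer is then frozen and exposed as a feature
    extractor, playing the role of a representation with genuinely
    categorical color structure.
    """
    borders = np.sort(np.asarray(planted_borders, dtype=float) % 1.0)
    n_cat = len(borders)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBACB]))
    base = DownsampleExtractor(pool=pool)
    stimulus_cfg = stimulus_cfg or stimuli.WordStimulusConfig()

    def batch(n_per_class):
        imgs, labels = [], []
        for cat in range(n_cat):
            left = borders[cat]
            span = (borders[(cat + 1) % n_cat] - left) % 1.0
            hues = (left + rng.uniform(0, span, size=n_per_class)) % 1.0
            for h in hues:
                imgs.append(stimuli.render_word_stimulus(float(h), stimulus_cfg, rng))
                labels.append(cat)
        feats = base.extract(np.stack(imgs)).reshape(-1, base.grid * base.grid, 3)
        return feats, np.array(labels)

    xtr, ytr = batch(n_train_per_class)
    xva, yva = batch(n_val_per_class)
    w1 = rng.normal(0.0, np.sqrt(2.0 / 3.0), size=(3, n_channels))
    b1 = np.zeros(n_channels)
    w2 = rng.normal(0.0, np.sqrt(2.0 / n_channels), size=(n_channels, hidden_dim))
    b2 = np.zeros(hidden_dim)
    w3 = rng.normal(0.0, 0.01, size=(hidden_dim, n_cat))
    b3 = np.zeros(n_cat)
    params = (w1, b1, w2, b2, w3, b3)
    vel = [np.zeros_like(a) for a in params]
    momentum = 0.9

    def forward_val():
        h = np.maximum(xva @ w1 + b1, 0.0).max(axis=1)
        q = np.maximum(h @ w2 + b2, 0.0)
        return float(np.mean(np.argmax(q @ w3 + b3, axis=1) == yva))

    # soft targets: label smoothing tightens within-category feature
    # clusters, which is what makes the frozen representation categorical
    targets = np.full((len(ytr), n_cat), label_smoothing / (n_cat - 1))
    targets[np.arange(len(ytr)), ytr] = 1.0 - label_smoothing
    best_acc = 0.0
    for epoch in range(n_epochs):
        lr = learning_rate * lr_decay**epoch
        order = rng.permutation(len(xtr))
        for start in range(0, len(xtr), batch_size):
            idx = order[start : start + batch_size]
            x = xtr[idx]  # (B, P, 3)
            h = np.maximum(x @ w1 + b1, 0.0)  # (B, P, C)
            am = h.argmax(axis=1)  # (B, C) winning positions
            m = np.take_along_axis(h, am[:, None, :], axis=1)[:, 0, :]
            q = np.maximum(m @ w2 + b2, 0.0)  # (B, H) penultimate
            z = q @ w3 + b3
            z -= z.max(axis=1, keepdims=True)
            p = np.exp(z)
            p /= p.sum(axis=1, keepdims=True)
            if not np.all(np.isfinite(p)):
                raise TrainingError("non-finite loss during backbone training")
            p -= targets[idx]
            gq = (p @ w3.T) * (q > 0)
            gm = (gq @ w2.T) * (m > 0)  # gradient reaches only the argmax pixel
            x_at = np.take_along_axis(x, am[:, :, None], axis=1)  # (B, C, 3)
            grads = (
                np.einsum("bci,bc->ic", x_at, gm) / len(idx),
                gm.mean(axis=0),
                m.T @ gq / len(idx) + weight_decay * w2,
                gq.mean(axis=0),
                q.T @ p / len(idx) + weight_decay * w3,
                p.mean(axis=0),
            )
            for a, v, g in zip(params, vel, grads):
                v *= momentum
                v -= lr * g
                a += v
        best_acc = max(best_acc, forward_val())
    if best_acc < val_criterion:
        raise TrainingError(
            f"scratch backbone reached {best_acc:.3f} validation accuracy "
            f"(< {val_criterion}) within {n_epochs} epochs"
        )
    return FrozenConvExtractor(
        base, w1, b1, w2, b2, name=f"scratch-conv-{n_channels}x{hidden_dim}"
    )
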