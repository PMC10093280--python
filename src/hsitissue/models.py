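"""The two 3D-CNN patch classifiers and their training loop.

Two architectures classify 5 x 5 x 92 reflectance patches into
cancerous vs non-malignant:

* ``inception3d`` — one inception block: parallel 3D convolutions with
  kernel sizes 1, 3 and 5 under 'same' padding, channel concatenation,
  dropout, and a single sigmoid unit on the flattened features.
* ``rs3d`` — a remote-sensing-style stack: a 3D convolution, a stride-2
  3D convolution (downsampling convolutions replace pooling), then 1D
  spectral convolutions with stride 2, and exactly one fully-connected
  output layer.

The published description fixes the layer structure and the total
trainable-parameter budgets (393,633 for the inception network, 27,156 for
the RS network) but not the per-layer filter counts.  The widths below were
calibrated once to reproduce those totals exactly (choosing, among all
exact solutions, the one with the most balanced widths) and are frozen
here; ``width_scale`` shrinks them proportionally for CPU-scale runs, in
which case the parameter totals no longer apply.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .containers import AnnotationMask, InvalidInputError, ProbabilityMap, SpectralCube
from .preprocess import PATCH_SIZE, SampleSet, WeightTable, per_sample_weights

INCEPTION = "inception3d"
RS = "rs3d"

#: Frozen full-profile widths (see module docstring).
INCEPTION_BRANCH_FILTERS = {1: 62, 3: 39, 5: 66}
RS_FILTERS = (33, 24, 27, 31)

TABLE_PARAM_COUNTS = {INCEPTION: 393_633, RS: 27_156}


class ConfigurationError(ValueError):
    """The architecture plan cannot meet its parameter-count contract."""


@dataclass(frozen=True)
class ArchitectureSpec:
    """A buildable architecture description.

    ``width_scale`` < 1 shrinks every filter count proportionally (minimum
    one filter per layer) for desk-scale training; the full profile is
    ``width_scale == 1``.
    """

    name: str
    input_shape: tuple[int, int, int, int] = (5, 5, 92, 1)
    branch_kernel_sizes: tuple[int, ...] = (1, 3, 5)
    dropout_rate: float = 0.1
    width_scale: float = 1.0
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in (INCEPTION, RS):
            raise ConfigurationError(f"unknown architecture {self.name!r}")
        if not (0.0 < self.width_scale <= 1.0):
            raise ConfigurationError("width_scale must be in (0, 1]")

    @property
    def is_full_profile(self) -> bool:
        return self.width_scale == 1.0


@dataclass
class TrainingConfig:
    """Optimization hyperparameters (defaults are the study settings)."""

    epochs: int = 40
    batch_size: int = 100
    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.99
    use_class_weights: bool = True
    use_sample_weights: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.learning_rate) <= 0 or self.epochs < 0:
            raise ConfigurationError("hyperparameters must be positive")


def _scaled(width: int, scale: float) -> int:
    return max(1, round(width * scale))


def build_model(spec: ArchitectureSpec) -> nn.Network:
    """Construct an untrained classifier for the given architecture spec.

    At full profile the trainable-parameter total is checked against the
    published budget and a :class:`ConfigurationError` naming the achieved
    count is raised on mismatch.
    """
    ss = np.random.SeedSequence(entropy=spec.init_seed)
    init_rng = np.random.default_rng(ss.spawn(1)[0])
    d1, d2, d3, cin = spec.input_shape
    s = spec.width_scale

    if spec.name == INCEPTION:
        branches = []
        n_filters = 0
        for k in spec.branch_kernel_sizes:
            f = _scaled(INCEPTION_BRANCH_FILTERS[k], s)
            n_filters += f
            branches.append(nn.Sequential([
                nn.Conv3D(cin, f, (k, k, k), padding="same", rng=init_rng),
                nn.ReLU(),
            ]))
        body = nn.Sequential([
            nn.Branches(branches),
            nn.Dropout(spec.dropout_rate),
            nn.Flatten(),
            nn.Dense(d1 * d2 * d3 * n_filters, 1, rng=init_rng),
        ])
    else:  # RS
        f1, f2, f3, f4 = (_scaled(f, s) for f in RS_FILTERS)
        # spectral sizes: d3 -> d3-2 -> valid/2 -> valid/2 -> valid/2
        b1 = d3 - 2
        b2 = (b1 - 3) // 2 + 1
        b3 = (b2 - 3) // 2 + 1
        b4 = (b3 - 3) // 2 + 1  # (5,5,92): 90 -> 44 -> 21 -> 10
        body = nn.Sequential([
            nn.Conv3D(cin, f1, (3, 3, 3), rng=init_rng),
            nn.ReLU(),
            nn.Conv3D(f1, f2, (3, 3, 3), stride=(1, 1, 2), rng=init_rng),
            nn.ReLU(),
            nn.Conv3D(f2, f3, (1, 1, 3), stride=(1, 1, 2), rng=init_rng),
            nn.ReLU(),
            nn.Conv3D(f3, f4, (1, 1, 3), stride=(1, 1, 2), rng=init_rng),
            nn.ReLU(),
            nn.Dropout(spec.dropout_rate),
            nn.Flatten(),
            nn.Dense(b4 * f4, 1, rng=init_rng),
        ])

    model = nn.Network(body, ss.spawn(2)[1])
    model.spec = spec
    if spec.is_full_profile and spec.input_shape == (5, 5, 92, 1):
        achieved = count_trainable_parameters(model)
        expected = TABLE_PARAM_COUNTS[spec.name]
        if achieved != expected:
            raise ConfigurationError(
                f"{spec.name} full profile has {achieved} parameters, "
                f"expected {expected}")
    return model


def count_trainable_parameters(model: nn.Network) -> int:
    """Exact number of independently trainable scalars (weights + biases)."""
    return int(sum(p.value.size for p in model.params()))


def train_classifier(model: nn.Network, train: SampleSet, val: SampleSet,
                     cfg: TrainingConfig, weights: WeightTable | None = None
                     ) -> tuple[nn.Network, list[dict]]:
    """Train in place with weighted binary cross-entropy and Adam.

    Per-sample weights come from the class-weight table (or the
    per-(class, patient) table when ``use_sample_weights``); weights must
    have been computed on the training set only.  Returns the model and a
    per-epoch history of train/validation loss.  Fully deterministic given
    ``cfg.seed``.
    """
    if len(train) == 0:
        raise InvalidInputError("empty training set")
    if len(np.unique(train.labels)) < 2:
        raise InvalidInputError("training set contains a single class")

    if weights is not None and (cfg.use_class_weights or cfg.use_sample_weights):
        w_train = per_sample_weights(train, weights, cfg.use_sample_weights)
        w_val = None
        if len(val) and not cfg.use_sample_weights:
            w_val = per_sample_weights(val, weights, False)
    else:
        w_train = np.ones(len(train))
        w_val = None

    opt = nn.Adam(model.params(), learning_rate=cfg.learning_rate,
                  beta1=cfg.beta1, beta2=cfg.beta2)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed))
    x_train = train.patches.astype(np.float64)[..., None]
    y_train = train.labels.astype(np.float64)

    history: list[dict] = []
    for epoch in range(cfg.epochs):
        perm = shuffle_rng.permutation(len(train))
        losses = []
        for i in range(0, len(perm), cfg.batch_size):
            idx = perm[i:i + cfg.batch_size]
            logits = model.forward_logits(x_train[idx], train=True)
            loss, dlogit = nn.weighted_bce_with_logits(
                logits, y_train[idx], w_train[idx])
            model.backward(dlogit)
            opt.step()
            losses.append(loss)
        record = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if len(val):
            val_logits = model.forward_logits(
                val.patches.astype(np.float64)[..., None], train=False)
            val_loss, _ = nn.weighted_bce_with_logits(
                val_logits, val.labels.astype(np.float64), w_val)
            record["val_loss"] = val_loss
        history.append(record)
    return model, history


def predict_probability_map(model: nn.Network, cube: SpectralCube,
                            mask: AnnotationMask,
                            batch_pixels: int = 2048) -> ProbabilityMap:
    """Full-image probability map from a trained patch classifier.

    Every pixel is predicted (borders via reflect padding); the validity
    mask marks the class-labeled pixels used for metrics.  The cube must be
    preprocessed identically to the training data.
    """
    d1, d2, d3, _ = model.spec.input_shape
    if cube.n_bands != d3:
        raise InvalidInputError(
            f"cube has {cube.n_bands} bands, model expects {d3}")
    h, w = cube.shape[:2]
    half = PATCH_SIZE // 2
    padded = np.pad(cube.values, ((half, half), (half, half), (0, 0)),
                    mode="reflect")
    windows = np.lib.stride_tricks.sliding_window_view(
        padded, (PATCH_SIZE, PATCH_SIZE), axis=(0, 1))
    flat = windows.reshape(h * w, cube.n_bands, PATCH_SIZE, PATCH_SIZE)
    probs = np.empty(h * w)
    for i in range(0, h * w, batch_pixels):
        patches = np.moveaxis(flat[i:i + batch_pixels], 1, 3)
        probs[i:i + batch_pixels] = model.predict_proba(patches)
    return ProbabilityMap(probs=probs.reshape(h, w),
                          valid=mask.class_pixels())
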