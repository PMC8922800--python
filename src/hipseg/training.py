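"""Losses and the independent-training-then-assembly regime.

The segmentation loss is the weighted combination

    L = a * diceLoss + b * crossEntropy

where the Dice term favours overall shape integrity and the pixel-wise
cross-entropy preserves pixels at the bone edge; ``a`` and ``b`` are
hyper-parameters (both 1 by default).  The main femur net carries one output
head per stacked decoder; intermediate supervision sums the combined loss over
heads with per-head weights (default (0.5, 1.0): the final decoder dominates,
the intermediate one keeps gradients flowing to the early stack).

The three networks are trained independently and only assembled for testing.
While training the main net, the ground-truth bone mask — not the upward
net's prediction — supplies the fusion input, and only slices flagged
femur-positive in the ground truth are fed to it; at test time the upward
net's predicted bone map takes over (see :mod:`hipseg.inference`).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import engine as eg
from . import models
from .preprocess import (
    BONE_WINDOW,
    FEMUR_WINDOW,
    apply_window,
    resize_slice,
    split_and_flip,
)

_EPS = 1e-6
STAGES = ("upward", "main", "classifier")


@dataclasses.dataclass
class LossWeights:
    """Weights of the combined loss and of the per-decoder supervision heads."""

    a: float = 1.0
    b: float = 1.0
    head_weights: tuple = (0.5, 1.0)
    pos_weight: float = 1.0

    def __post_init__(self):
        if self.a < 0 or self.b < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.a + self.b == 0:
            raise ValueError("at least one of a, b must be positive")


@dataclasses.dataclass
class TrainConfig:
    epochs: int = 8
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0
    stage: str | None = None

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")


# ---------------------------------------------------------------------------
# losses (array API; the training loop uses the equivalent autodiff ops)
# ---------------------------------------------------------------------------

def dice_loss(pred_probs, target) -> float:
    """1 - soft Dice overlap; 0 for a perfect prediction, 1 for a total miss."""
    p = np.asarray(pred_probs, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs target {t.shape}")
    num = 2.0 * (p * t).sum() + _EPS
    den = p.sum() + t.sum() + _EPS
    return float(1.0 - num / den)


def cross_entropy_loss(pred_probs, target, pos_weight: float = 1.0) -> float:
    """Mean pixel-wise binary cross-entropy on probabilities."""
    p = np.clip(np.asarray(pred_probs, dtype=np.float64), _EPS, 1.0 - _EPS)
    t = np.asarray(target, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs target {t.shape}")
    return float(-(pos_weight * t * np.log(p) + (1.0 - t) * np.log(1.0 - p)).mean())


def combined_loss(pred_probs, target, w: LossWeights) -> float:
    """a * diceLoss + b * crossEntropy; linear in (a, b)."""
    return w.a * dice_loss(pred_probs, target) + w.b * cross_entropy_loss(
        pred_probs, target, w.pos_weight
    )


def supervised_loss(head_outputs, target, w: LossWeights) -> float:
    """Intermediate supervision: head-weighted sum of combined losses."""
    heads = list(head_outputs)
    if len(heads) != len(w.head_weights):
        raise ValueError(
            f"{len(heads)} heads but {len(w.head_weights)} head weights"
        )
    return float(
        sum(hw * combined_loss(h, target, w) for hw, h in zip(w.head_weights, heads))
    )


def _combined_loss_t(pred: eg.Tensor, target, w: LossWeights) -> eg.Tensor:
    loss = None
    if w.a:
        loss = w.a * eg.soft_dice_loss(pred, target)
    if w.b:
        ce = w.b * eg.bce_loss(pred, target, w.pos_weight)
        loss = ce if loss is None else loss + ce
    return loss


# ---------------------------------------------------------------------------
# slice dataset
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class HalfSample:
    """One mirrored half-slice with everything any stage needs."""

    bone_image: np.ndarray     # bone-window normalised image
    femur_image: np.ndarray    # femur-window normalised image
    bone_mask: np.ndarray      # ground-truth bone (femur + pelvis)
    femur_mask: np.ndarray     # ground-truth femur
    has_femur: bool


def make_half_dataset(cases, in_rows: int, in_cols: int,
                      bone_window=BONE_WINDOW, femur_window=FEMUR_WINDOW,
                      slice_step: int = 1):
    """Turn (CtVolume, LabelVolume) pairs into mirrored half-slice samples.

    Each axial slice is resized to ``in_rows x 2*in_cols``, windowed twice,
    split down the middle with the right half mirrored — so the augmentation
    doubles the dataset cardinality, two halves per slice.  ``slice_step``
    keeps every k-th axial slice, a problem-size control for CPU training.
    """
    if slice_step < 1:
        raise ValueError("slice_step must be >= 1")
    case_index = -1
    samples = []
    for ct, lab in cases:
        case_index += 1
        if ct.shape != lab.shape:
            raise ValueError(f"image {ct.shape} and labels {lab.shape} differ")
        hu = ct.hu()
        # stagger the subsampling phase across cases so every slice position
        # (boundary slices included) is represented somewhere in the dataset
        for k in range(case_index % slice_step, ct.shape[2], slice_step):
            hu_k = resize_slice(hu[:, :, k], (in_rows, 2 * in_cols))
            lab_k = resize_slice(lab.labels[:, :, k], (in_rows, 2 * in_cols), is_label=True)
            bone = apply_window(hu_k, bone_window)
            femur = apply_window(hu_k, femur_window)
            for half in zip(
                split_and_flip(bone), split_and_flip(femur), split_and_flip(lab_k)
            ):
                b, f, l = half
                samples.append(
                    HalfSample(
                        bone_image=b,
                        femur_image=f,
                        bone_mask=(l > 0).astype(np.float32),
                        femur_mask=(l == 1).astype(np.float32),
                        has_femur=bool((l == 1).any()),
                    )
                )
    return samples


def _stack(images):
    return np.stack(images).astype(np.float32)[:, None, :, :]


def _batches(n, batch_size, rng):
    perm = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield perm[i : i + batch_size]


# ---------------------------------------------------------------------------
# stage training
# ---------------------------------------------------------------------------

def train_stage(
    stage: str,
    samples,
    cfg: TrainConfig,
    net_cfg: models.NetworkConfig | None = None,
    weights: LossWeights | None = None,
):
    """Train one module on half-slice samples.

    Returns ``(NetworkHandle, per-epoch mean loss list)``.  With a fixed seed,
    dataset and single-threaded execution the loss trajectory is reproducible.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    samples = list(samples)
    if not samples:
        raise ValueError("training dataset is empty")
    net_cfg = net_cfg or models.NetworkConfig()
    w = weights or LossWeights(
        head_weights=tuple([0.5] * (net_cfg.stack_count - 1) + [1.0])
    )
    rng = np.random.default_rng(cfg.seed)

    if stage == "upward":
        handle = models.build_upward_unet(
            dataclasses.replace(net_cfg, seed=cfg.seed)
        )
        x = _stack([s.bone_image for s in samples])
        y = _stack([s.bone_mask for s in samples])

        def loss_of(idx):
            pred, _ = handle(eg.Tensor(x[idx]))
            return _combined_loss_t(pred, y[idx], w)

    elif stage == "main":
        samples = [s for s in samples if s.has_femur]
        if not samples:
            raise ValueError(
                "main-stage training needs femur-positive slices; none in dataset"
            )
        handle = models.build_main_hourglass(
            dataclasses.replace(net_cfg, seed=cfg.seed)
        )
        x = _stack([s.femur_image for s in samples])
        fusion = _stack([s.bone_mask for s in samples])  # benchmark bone labels
        y = _stack([s.femur_mask for s in samples])

        def loss_of(idx):
            heads = handle(eg.Tensor(x[idx]), eg.Tensor(fusion[idx]))
            loss = None
            for hw, h in zip(w.head_weights, heads):
                term = hw * _combined_loss_t(h, y[idx], w)
                loss = term if loss is None else loss + term
            return loss

    else:  # classifier
        handle = models.build_layer_classifier(
            dataclasses.replace(net_cfg, seed=cfg.seed)
        )
        x = _stack([s.bone_image for s in samples])
        y = np.array([[float(s.has_femur)] for s in samples], dtype=np.float32)

        def loss_of(idx):
            conf = handle(eg.Tensor(x[idx]))
            return eg.bce_loss(conf, y[idx], w.pos_weight)

    opt = eg.Adam(handle.module.parameters(), lr=cfg.learning_rate)
    history = []
    n = len(samples)
    for _ in range(cfg.epochs):
        losses = []
        for idx in _batches(n, cfg.batch_size, rng):
            opt.zero_grad()
            loss = loss_of(idx)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
    return handle, history


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Pipeline:
    """The three trained modules assembled for testing.  At test time the
    upward net's predicted bone map replaces the ground-truth fusion input."""

    upward: models.NetworkHandle
    main: models.NetworkHandle
    classifier: models.NetworkHandle

    def __post_init__(self):
        roles = (self.upward.role, self.main.role, self.classifier.role)
        if roles != (models.ROLE_UPWARD, models.ROLE_MAIN, models.ROLE_CLASSIFIER):
            raise ValueError(f"handles passed in wrong roles: {roles}")
        dims = {
            (h.config.in_rows, h.config.in_cols)
            for h in (self.upward, self.main, self.classifier)
        }
        if len(dims) != 1:
            raise ValueError(f"spatial configs differ across modules: {sorted(dims)}")
        if self.main.config.fusion_channels != 1:
            raise ValueError(
                "assembly fuses the upward net's bone probability map, so the "
                "main net must expect 1 fusion channel"
            )

    @property
    def in_rows(self):
        return self.upward.config.in_rows

    @property
    def in_cols(self):
        return self.upward.config.in_cols


def assemble(upward, main, classifier) -> Pipeline:
    return Pipeline(upward, main, classifier)


def train_all(cases, cfg: TrainConfig, net_cfg: models.NetworkConfig | None = None,
              weights: LossWeights | None = None):
    """Train the three stages independently on the same cases and assemble.

    Returns ``(Pipeline, {stage: loss history})``."""
    net_cfg = net_cfg or models.NetworkConfig()
    samples = make_half_dataset(cases, net_cfg.in_rows, net_cfg.in_cols)
    handles, histories = {}, {}
    for stage in STAGES:
        handles[stage], histories[stage] = train_stage(
            stage, samples, dataclasses.replace(cfg, stage=stage), net_cfg, weights
        )
    return assemble(handles["upward"], handles["main"], handles["classifier"]), histories
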