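"""Training procedure for the two-head segmentation model.

Mini-batches are drawn (without replacement per epoch) from an eligible pool
that initially contains only slices with calcified lesions; after every
epoch the pool is expanded with calcium-free slices the current model
misclassifies (hard negatives), where "misclassifies" means the full second
stage — thresholding at p_calc > 0.5 plus connected components and the HU
restriction — yields at least one lesion.  The loss is Dice loss on the
binary calcium head plus cross-entropy on the vessel head, the latter
evaluated only on true-calcium pixels (vessel identity is undefined
elsewhere).  Optimization is Adam with two learning-rate groups: 1e-3 for
randomly initialized weights, 1e-4 for pretrained encoder weights, a linear
warmup (5k iterations) followed by cosine annealing (300k iterations), the
pretrained group's schedule delayed by 10k iterations, and L2 regularization
1e-4 on all parameters.  ``scale_factor`` shrinks every iteration count
proportionally for CPU-scale runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _nn
from ._nn import Tensor, constant, sum_all, log, mul
from .network import SegModel
from .phantom import PhantomGroundTruth
from .ct_io import CTVolume, PreprocessConfig, preprocess_slice
from .scoring import ScoringConfig, extract_lesions

__all__ = [
    "TrainingConfig",
    "TrainingDivergedError",
    "SliceSample",
    "SliceDataset",
    "SamplerState",
    "build_slice_dataset",
    "lr_schedule",
    "pretrained_lr",
    "sample_minibatch",
    "composite_loss",
    "expand_hard_negatives",
    "Adam",
    "train",
    "training_dice",
    "hard_dice",
]


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite."""


@dataclass(frozen=True)
class TrainingConfig:
    batch_size: int = 64
    lr_new: float = 1e-3
    lr_pretrained: float = 1e-4
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    warmup_iters: int = 5_000
    anneal_iters: int = 300_000
    pretrained_delay_iters: int = 10_000
    weight_decay: float = 1e-4
    scale_factor: float = 1.0
    total_iters: int | None = None   # default: scaled warmup + anneal
    dice_smooth: float = 1.0
    seed: int = 0
    checkpoint_every: int | None = None
    checkpoint_dir: str | None = None

    def __post_init__(self):
        if self.warmup_iters >= self.anneal_iters:
            raise ValueError("warmup_iters must be below anneal_iters")
        if min(self.lr_new, self.lr_pretrained, self.scale_factor) <= 0:
            raise ValueError("rates and scale_factor must be positive")

    def _scaled(self, n: int) -> int:
        return max(1, int(round(n * self.scale_factor)))

    @property
    def warmup_scaled(self) -> int:
        return self._scaled(self.warmup_iters)

    @property
    def anneal_scaled(self) -> int:
        return self._scaled(self.anneal_iters)

    @property
    def delay_scaled(self) -> int:
        return max(0, int(round(self.pretrained_delay_iters
                                * self.scale_factor)))

    @property
    def n_iterations(self) -> int:
        if self.total_iters is not None:
            return self.total_iters
        return self.warmup_scaled + self.anneal_scaled


def lr_schedule(iteration: int, base_lr: float, cfg: TrainingConfig) -> float:
    """Linear ramp 0 -> base_lr over the warmup, then half-cosine decay
    base_lr -> 0 over the annealing window, 0 afterwards."""
    if iteration < 0:
        raise ValueError("iteration must be non-negative")
    w, a = cfg.warmup_scaled, cfg.anneal_scaled
    if iteration <= w:
        return base_lr * iteration / w
    if iteration >= w + a:
        return 0.0
    return base_lr * 0.5 * (1.0 + np.cos(np.pi * (iteration - w) / a))


def pretrained_lr(iteration: int, base_lr: float,
                  cfg: TrainingConfig) -> float:
    """The same schedule evaluated at (iteration - delay), clamped at 0 — a
    pure time shift for the pretrained parameter group."""
    return lr_schedule(max(0, iteration - cfg.delay_scaled), base_lr, cfg)


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------

@dataclass
class SliceSample:
    """One training slice: normalized model input plus ground truth."""

    image: np.ndarray         # (H, W) preprocessed (clipped, [-1, 1])
    hu: np.ndarray            # (H, W) raw HU at the same resolution
    calc_mask: np.ndarray     # (H, W) bool, true calcium
    vessel_map: np.ndarray    # (H, W) int, 0 none / 1..4 = LCA..RCA
    exam_id: str = ""
    slice_index: int = 0

    @property
    def has_calcium(self) -> bool:
        return bool(self.calc_mask.any())


@dataclass
class SliceDataset:
    samples: list[SliceSample]
    pixel_area_mm2: float

    def __len__(self):
        return len(self.samples)

    def lesion_indices(self) -> list[int]:
        return [i for i, s in enumerate(self.samples) if s.has_calcium]

    def negative_indices(self) -> list[int]:
        return [i for i, s in enumerate(self.samples) if not s.has_calcium]


def build_slice_dataset(pairs: list[tuple[CTVolume, PhantomGroundTruth]],
                        prep: PreprocessConfig | None = None) -> SliceDataset:
    """Flatten phantom exams into per-slice training samples.

    Vessel territory labels 1–4 become the vessel map; the non-coronary
    distractor label contributes neither calcium mask nor vessel identity
    (the model must learn to ignore it via low p_calc).
    """
    if not pairs:
        raise ValueError("at least one exam is required")
    size = pairs[0][0].slices.shape[1]
    prep = prep or PreprocessConfig(target_size=size)
    samples = []
    for vol, gt in pairs:
        for si in range(vol.n_slices):
            img, _ = preprocess_slice(vol.slices[si], prep)
            lab = gt.label_volume[si]
            samples.append(SliceSample(
                image=img, hu=vol.slices[si],
                calc_mask=(lab >= 1) & (lab <= 4),
                vessel_map=np.where(lab <= 4, lab, 0).astype(np.int64),
                exam_id=vol.source_id, slice_index=si))
    return SliceDataset(samples, pairs[0][0].pixel_area_mm2)


# ---------------------------------------------------------------------------
# sampling and hard negatives
# ---------------------------------------------------------------------------

@dataclass
class SamplerState:
    """Epoch-wise shuffled traversal of the eligible pool."""

    pool: set
    rng: np.random.Generator
    order: list = field(default_factory=list)
    cursor: int = 0

    @classmethod
    def initial(cls, dataset: SliceDataset, seed: int) -> "SamplerState":
        pool = set(dataset.lesion_indices())
        if not pool:
            raise ValueError("dataset has no lesion-bearing slices")
        return cls(pool=pool, rng=np.random.default_rng(seed))

    def _refill(self):
        self.order = sorted(self.pool)
        self.rng.shuffle(self.order)
        self.cursor = 0


def sample_minibatch(dataset: SliceDataset, cfg: TrainingConfig,
                     state: SamplerState):
    """Next mini-batch of eligible slice indices.

    Draws without replacement within an epoch; the final batch of an epoch
    may be short.  Returns ``(samples, indices, epoch_ended)``.
    """
    if not state.pool:
        raise ValueError("eligible pool is empty")
    if state.cursor >= len(state.order):
        state._refill()
    end = min(state.cursor + cfg.batch_size, len(state.order))
    idx = state.order[state.cursor:end]
    state.cursor = end
    epoch_ended = state.cursor >= len(state.order)
    return [dataset.samples[i] for i in idx], idx, epoch_ended


def expand_hard_negatives(model: SegModel, dataset: SliceDataset,
                          state: SamplerState,
                          scoring_cfg: ScoringConfig = ScoringConfig()
                          ) -> SamplerState:
    """Add misclassified calcium-free slices to the eligible pool.

    A negative slice is misclassified when the full second stage (p_calc
    threshold, 8-connected components, HU > 130 restriction, minimum area)
    still yields at least one lesion on it.  The pool only ever grows and
    re-adding is a no-op, so repeated calls are idempotent.
    """
    for i in dataset.negative_indices():
        if i in state.pool:
            continue
        s = dataset.samples[i]
        pc, _ = model.predict_slice(s.image)
        mask = pc > scoring_cfg.calc_prob_threshold
        lesions = extract_lesions(mask[None], s.hu[None],
                                  dataset.pixel_area_mm2, scoring_cfg)
        if any(l.agatston(scoring_cfg) > 0 for l in lesions):
            state.pool.add(i)
    return state


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def composite_loss(p_calc: Tensor, p_vessel: Tensor,
                   calc_masks: np.ndarray, vessel_maps: np.ndarray,
                   dice_smooth: float = 1.0):
    """Dice loss (binary head) + masked cross-entropy (vessel head).

    The cross-entropy averages over true-calcium pixels only; an
    all-background batch contributes zero vessel loss and the Dice smoothing
    constant keeps the ratio finite.  Returns (total, dice_loss, ce_loss)
    as autograd tensors.
    """
    m = constant(np.asarray(calc_masks, dtype=np.float64)[:, None])
    inter = sum_all(mul(p_calc, m))
    denom = sum_all(p_calc) + sum_all(m)
    dice_loss = 1.0 - (2.0 * inter + dice_smooth) / (denom + dice_smooth)

    onehot = np.stack([(vessel_maps == k + 1) for k in range(4)],
                      axis=1).astype(np.float64)
    n_pix = onehot.sum()
    if n_pix > 0:
        ce = (-1.0 / n_pix) * sum_all(
            mul(log(p_vessel + 1e-12), constant(onehot)))
    else:
        ce = constant(0.0)
    return dice_loss + ce, dice_loss, ce


def hard_dice(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Dice overlap of two binary masks (1.0 when both are empty)."""
    pred_mask = np.asarray(pred_mask, dtype=bool)
    true_mask = np.asarray(true_mask, dtype=bool)
    denom = pred_mask.sum() + true_mask.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(pred_mask, true_mask).sum() / denom


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with per-parameter-group learning rates and L2 regularization
    (the penalty gradient is added to the raw gradient, matching a weight
    decay applied to all learnable parameters)."""

    def __init__(self, params: dict, pretrained_names: set | None = None,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.pretrained = pretrained_names or set()
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self, lr_new: float, lr_pre: float, weight_decay: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, p in self.params.items():
            g = (p.grad if p.grad is not None else np.zeros_like(p.data))
            g = g + weight_decay * p.data
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            mhat = self.m[name] / (1 - b1 ** self.t)
            vhat = self.v[name] / (1 - b2 ** self.t)
            lr = lr_pre if name in self.pretrained else lr_new
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def train(model: SegModel, dataset: SliceDataset, cfg: TrainingConfig,
          scoring_cfg: ScoringConfig = ScoringConfig()):
    """Run the full procedure; returns ``(model, trace)``.

    ``trace`` has one record per iteration with the per-group learning rates
    and the loss components; its length equals the iteration count.  With
    ``total_iters=0`` the model is returned untouched.  Non-finite loss
    aborts with :class:`TrainingDivergedError`.
    """
    n_iter = cfg.n_iterations
    trace: list[dict] = []
    if n_iter == 0:
        return model, trace
    state = SamplerState.initial(dataset, cfg.seed)
    params = model.parameters()
    pretrained = (set(model.encoder_parameters())
                  if model.cfg.use_pretrained_encoder else set())
    opt = Adam(params, pretrained, cfg.adam_beta1, cfg.adam_beta2)

    for it in range(n_iter):
        batch, _, epoch_ended = sample_minibatch(dataset, cfg, state)
        x = np.stack([s.image for s in batch])[:, None]
        masks = np.stack([s.calc_mask for s in batch])
        vessels = np.stack([s.vessel_map for s in batch])
        pc, pv = model.forward(x)
        loss, dice_l, ce_l = composite_loss(pc, pv, masks, vessels,
                                            cfg.dice_smooth)
        if not np.isfinite(loss.data):
            raise TrainingDivergedError(
                f"non-finite loss at iteration {it}: {loss.data}")
        model.zero_grad()
        loss.backward()
        lr_n = lr_schedule(it, cfg.lr_new, cfg)
        lr_p = pretrained_lr(it, cfg.lr_pretrained, cfg)
        opt.step(lr_n, lr_p, cfg.weight_decay)
        trace.append({"iteration": it, "lr_new": lr_n, "lr_pretrained": lr_p,
                      "dice_loss": float(dice_l.data),
                      "ce_loss": float(ce_l.data),
                      "loss": float(loss.data)})
        if epoch_ended:
            expand_hard_negatives(model, dataset, state, scoring_cfg)
        if (cfg.checkpoint_every and cfg.checkpoint_dir
                and (it + 1) % cfg.checkpoint_every == 0):
            from .network import save_model
            Path(cfg.checkpoint_dir).mkdir(parents=True, exist_ok=True)
            save_model(model,
                       Path(cfg.checkpoint_dir) / f"ckpt_{it + 1:06d}.npz")
    return model, trace


def training_dice(model: SegModel, dataset: SliceDataset,
                  threshold: float = 0.5) -> float:
    """Hard Dice of the thresholded calcium head over the whole dataset."""
    preds, trues = [], []
    for s in dataset.samples:
        pc, _ = model.predict_slice(s.image)
        preds.append(pc > threshold)
        trues.append(s.calc_mask)
    return hard_dice(np.stack(preds), np.stack(trues))
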