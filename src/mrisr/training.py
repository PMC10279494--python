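"""Training loop: Xavier initialization, Adam updates, validation, selection.

One iteration samples a mini-batch of augmented LR/HR patch pairs, runs the
forward pass, evaluates the composite loss, and takes one Adam step on all
model parameters.  Defaults follow the published protocol: batch size 16,
24 x 24 LR patches, initial learning rate 1e-3, loss weights alpha = 0.3 and
beta = 0.1.  Every ``val_every`` iterations the model is scored
(PSNR/SSIM/RMSE) on the validation split and the parameters with the best
validation PSNR are kept; the returned model carries that checkpoint.

Everything is reproducible from ``TrainConfig.seed`` on a single worker: the
batch sampler, patch offsets, augmentation coins and the default perceptual
extractor are all seeded, and there is no hidden global random state.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import asdict, dataclass, field, fields
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .autodiff import Tensor
from .data import PairedSample, augment, extract_patch_pair
from .losses import LossWeights, RandomConvExtractor, composite_loss
from .metrics import MetricsRecord, evaluate_set
from .network import SRNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "SRDataset",
    "Adam",
    "TrainingDiverged",
    "xavier_init",
    "train",
    "evaluate_model",
]


@dataclass
class TrainConfig:
    """Optimization hyper-parameters (defaults follow the study protocol)."""

    batch_size: int = 16
    lr_patch: int = 24
    learning_rate: float = 1e-3
    alpha: float = 0.3
    beta: float = 0.1
    max_iters: int = 200
    val_every: int = 50
    seed: int = 0
    mode: str = "bd"
    scale: int = 2
    pixel_kind: str = "l1"
    # canonical Adam moment constants
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    # optional step decay; 0 disables (constant rate, the default protocol)
    lr_decay_every: int = 0
    lr_decay_factor: float = 0.5
    log_every: int = 0

    def validate(self) -> None:
        if self.batch_size < 1 or self.lr_patch < 1:
            raise ValueError("batch_size and lr_patch must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("loss weights must be non-negative")
        if self.max_iters < 0 or self.val_every < 1:
            raise ValueError("max_iters must be >= 0 and val_every >= 1")
        if self.mode.lower() not in ("bd", "td"):
            raise ValueError(f"mode must be 'bd' or 'td', got {self.mode!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        names = {f.name for f in fields(cls)}
        cfg = cls(**{k: v for k, v in d.items() if k in names})
        cfg.validate()
        return cfg


@dataclass
class SRDataset:
    """Train/val/test splits of full-image LR/HR pairs."""

    train: List[PairedSample]
    val: List[PairedSample] = field(default_factory=list)
    test: List[PairedSample] = field(default_factory=list)


@dataclass
class TrainHistory:
    """Per-iteration loss breakdown and periodic validation metrics."""

    losses: List[dict] = field(default_factory=list)
    validations: List[Tuple[int, MetricsRecord]] = field(default_factory=list)
    best_iteration: int = 0
    best_psnr: float = float("-inf")

    def totals(self) -> np.ndarray:
        return np.array([rec["total"] for rec in self.losses])


class TrainingDiverged(RuntimeError):
    """Raised when the loss turns non-finite; carries a diagnostic state dump."""

    def __init__(self, iteration: int, diagnostics: dict):
        self.iteration = iteration
        self.diagnostics = diagnostics
        super().__init__(
            f"non-finite loss at iteration {iteration}: {diagnostics.get('loss_parts')}"
        )


class Adam(object):
    """Standard Adam with bias-corrected first/second moments."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            p.data = p.data - self.lr * (self.m[i] / c1) / (np.sqrt(self.v[i] / c2) + self.eps)


def xavier_init(model: SRNetwork, seed: int) -> SRNetwork:
    """Re-draw all parameters: Xavier-uniform convolution weights, zero
    biases, configured PReLU slopes, unit/zero LayerNorm affine."""
    model.init_params(np.random.default_rng(seed))
    return model


def _sample_batch(
    pairs: Sequence[PairedSample], cfg: TrainConfig, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    lrs, hrs = [], []
    for _ in range(cfg.batch_size):
        src = pairs[int(rng.integers(len(pairs)))]
        patch = extract_patch_pair(src, cfg.lr_patch, seed=int(rng.integers(2 ** 31)))
        patch = augment(patch, seed=int(rng.integers(2 ** 31)))
        lrs.append(patch.lr)
        hrs.append(patch.hr)
    return np.stack(lrs)[:, None], np.stack(hrs)[:, None]


def evaluate_model(
    model: SRNetwork, pairs: Sequence[PairedSample], ssim_mode: str = "windowed"
) -> MetricsRecord:
    """Super-resolve every LR member and score against the HR ground truth."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("evaluate_model requires a non-empty pair set")
    return evaluate_set(
        [(p.hr, model.predict(p.lr)) for p in pairs], ssim_mode=ssim_mode
    )


def train(
    model: SRNetwork,
    dataset: SRDataset,
    cfg: TrainConfig,
    extractor=None,
) -> Tuple[SRNetwork, TrainHistory]:
    """Optimize the model against the composite loss; return the
    best-validation-PSNR checkpoint and the full history.

    ``extractor`` overrides the perceptual-loss feature extractor (default:
    a fixed seeded random-convolution stack).  With ``max_iters = 0`` the
    model is returned untouched.
    """
    cfg.validate()
    if not dataset.train:
        raise ValueError("training split is empty")
    rng = np.random.default_rng(cfg.seed)
    weights = LossWeights(
        alpha=cfg.alpha,
        beta=cfg.beta,
        pixel_kind=cfg.pixel_kind,
        extractor=extractor if extractor is not None else RandomConvExtractor(seed=0),
    )
    opt = Adam(model.parameters(), cfg.learning_rate,
               cfg.adam_beta1, cfg.adam_beta2, cfg.adam_eps)
    history = TrainHistory()
    best_params: Optional[List[np.ndarray]] = None

    for it in range(1, cfg.max_iters + 1):
        if cfg.lr_decay_every and it > 1 and (it - 1) % cfg.lr_decay_every == 0:
            opt.lr *= cfg.lr_decay_factor
        lr_batch, hr_batch = _sample_batch(dataset.train, cfg, rng)
        sr = model.forward(Tensor(lr_batch))
        total, parts = composite_loss(sr, hr_batch, weights)
        if not np.isfinite(parts["total"]):
            raise TrainingDiverged(
                it,
                {
                    "loss_parts": parts,
                    "recent_totals": [rec["total"] for rec in history.losses[-10:]],
                    "param_norms": {
                        name: float(np.abs(p.data).max())
                        for name, p in model.named_parameters()
                    },
                },
            )
        model.zero_grad()
        total.backward()
        opt.step()
        history.losses.append({"iteration": it, **parts})
        if cfg.log_every and it % cfg.log_every == 0:
            logger.info(
                "iter=%d total=%.6f pixel=%.6f perceptual=%.6f edge=%.6f",
                it, parts["total"], parts["pixel"], parts["perceptual"], parts["edge"],
            )

        run_validation = dataset.val and (it % cfg.val_every == 0 or it == cfg.max_iters)
        if run_validation:
            record = evaluate_model(model, dataset.val)
            history.validations.append((it, record))
            if cfg.log_every:
                logger.info("iter=%d val_psnr=%.4f val_ssim=%.5f val_rmse=%.5f",
                            it, record.psnr, record.ssim, record.rmse)
            if record.psnr > history.best_psnr:
                history.best_psnr = record.psnr
                history.best_iteration = it
                best_params = [p.data.copy() for p in model.parameters()]

    if best_params is not None:
        for p, data in zip(model.parameters(), best_params):
            p.data = data
    return model, history
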