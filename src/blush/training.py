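"""Training of the denoiser on half-map pairs with the recycling loss.

The loss over a minibatch of ``b`` half-map pairs is

    L = 1/(2b) * sum_i sum_{k in {0,1}} || ybar_i^(k) - f(R_r[f, y_i^(k)]) ||^2

where ``R_r`` recycles the denoiser ``r`` times (inference mode, no
gradient) before the single differentiated application, and ``||.||^2``
sums squared voxel differences over the patch.  Since every pair
contributes both half-directions, this equals the mean per-example summed
squared error, which is how it is computed here.

Examples are constructed on the fly each step (fresh augmentation draws),
optimized with Adam under a cosine learning-rate schedule.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .augment import AugmentationPolicy, HalfMapPair, TrainingExample, build_example
from .denoiser import DenoiserModel, DenoiserConfig, build_model, recycle_batch, save_checkpoint
from .nn import Adam, Tensor, sub, square, tsum

__all__ = ["TrainingConfig", "TrainingResult", "compute_loss", "train"]


@dataclass
class TrainingConfig:
    """Optimization hyperparameters.  ``batch_pairs`` is the number of
    half-map pairs per step; each contributes both half-directions, so the
    loss sums over twice as many patches."""

    batch_pairs: int = 8
    steps: int = 200
    learning_rate: float = 3e-3
    min_lr_fraction: float = 0.05
    seed: int = 0
    checkpoint_every: int = 0  # 0 = only final
    checkpoint_dir: str | None = None

    def __post_init__(self) -> None:
        if self.batch_pairs < 1 or self.steps < 1:
            raise ValueError("batch_pairs and steps must be >= 1")


@dataclass
class TrainingResult:
    model: DenoiserModel
    loss_trace: list[float]

    def loss_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(["step", "loss"])
        for i, v in enumerate(self.loss_trace):
            w.writerow([i, f"{v:.8g}"])
        return buf.getvalue()


def compute_loss(model: DenoiserModel, batch: list[TrainingExample],
                 rng: np.random.Generator | None = None,
                 train: bool = False) -> Tensor:
    """Recycling loss over a batch of examples (both half-directions of each
    pair are expected to appear in ``batch``).

    Returns a scalar Tensor; call ``.backward()`` on it for gradients.
    Recycled passes run in inference mode and are not differentiated.
    """
    if not batch:
        raise ValueError("empty batch")
    shape = batch[0].y.shape
    for ex in batch:
        if ex.y.shape != shape or ex.y_bar.shape != shape:
            raise ValueError("inconsistent patch shapes in batch")
    dt = model.config.dtype
    ys = np.stack([ex.y for ex in batch]).astype(dt)[:, None]
    ybars = np.stack([ex.y_bar for ex in batch]).astype(dt)[:, None]
    rs = np.array([ex.r for ex in batch])
    recycled = recycle_batch(model, ys, rs)
    pred = model.forward(Tensor(recycled), train=train, rng=rng)
    diff = sub(pred, Tensor(ybars))
    total = tsum(square(diff))
    scale = Tensor(np.asarray(1.0 / len(batch), dtype=dt))
    from .nn import mul

    return mul(total, scale)


def train(corpus: list[HalfMapPair], cfg: TrainingConfig,
          policy: AugmentationPolicy,
          model_config: DenoiserConfig | None = None,
          model: DenoiserModel | None = None) -> TrainingResult:
    """Minimize the recycling loss over a corpus of half-map pairs.

    Per step: sample ``batch_pairs`` pairs (with replacement), build both
    half-direction examples per pair with fresh augmentation draws, take one
    Adam step with dropout active in the differentiated pass.  The loss
    trace is deterministic under a fixed seed and thread configuration.
    Divergence (non-finite loss) aborts, returning the trace up to the last
    good step and leaving the model at its last finite state.
    """
    if not corpus:
        raise ValueError("corpus is empty")
    rng = np.random.default_rng(cfg.seed)
    if model is None:
        if model_config is None:
            model_config = DenoiserConfig()
        model = build_model(model_config, rng)
    model.train(True)
    opt = Adam(model.parameters(), lr=cfg.learning_rate,
               total_steps=cfg.steps, min_lr_fraction=cfg.min_lr_fraction)
    trace: list[float] = []
    ckpt_dir = Path(cfg.checkpoint_dir) if cfg.checkpoint_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)
    last_params = {k: p.data.copy() for k, p in model.params.items()}
    for step in range(cfg.steps):
        idx = rng.integers(0, len(corpus), size=cfg.batch_pairs)
        batch = []
        for i in idx:
            for k in (0, 1):
                batch.append(build_example(corpus[int(i)], k, rng, policy))
        loss = compute_loss(model, batch, rng=rng, train=True)
        value = float(loss.data)
        if not np.isfinite(value):
            for key, p in model.params.items():  # roll back to last good step
                p.data = last_params[key]
            model.eval()
            raise FloatingPointError(
                f"loss diverged to {value} at step {step}; "
                "model restored to the previous step"
            )
        last_params = {k: p.data.copy() for k, p in model.params.items()}
        trace.append(value)
        opt.zero_grad()
        loss.backward()
        opt.step()
        if ckpt_dir and cfg.checkpoint_every and \
                (step + 1) % cfg.checkpoint_every == 0:
            save_checkpoint(model, ckpt_dir / f"step{step + 1:06d}.npz")
    model.eval()
    if ckpt_dir:
        save_checkpoint(model, ckpt_dir / "final.npz")
    return TrainingResult(model=model, loss_trace=trace)
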