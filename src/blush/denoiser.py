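"""The residual volumetric U-net denoiser and its whole-volume inference.

The network computes ``f(v) = v + g(v)`` where ``g`` is a U-net trunk:
encoder blocks (3x3x3 convolution, instance normalization, SiLU) each
followed by 2x average-pool downsampling, a bottleneck convolution block,
and decoder blocks (2x nearest upsampling, skip concatenation, convolution,
normalization, SiLU, channel dropout).  The final trunk convolution is
zero-initialized, so a freshly built model is exactly the identity map —
the natural starting point for residual learning.

Recycling (``recycle``) feeds the denoiser its own output ``r`` times in
inference mode before the differentiated pass, teaching it to suppress
artifacts amplified by repeated application across refinement iterations.

The reference full-size configuration (depth 5, channel ladder 26..416)
lands near 13 million parameters; toy configurations used throughout the
tests are a few thousand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .nn import Tensor
from .volume_io import Volume, tile_volume, stitch_patches

__all__ = [
    "DenoiserConfig",
    "DenoiserModel",
    "build_model",
    "recycle",
    "denoise_volume",
    "save_checkpoint",
    "load_checkpoint",
    "parameter_count",
]

CHECKPOINT_FORMAT_VERSION = 1


@dataclass
class DenoiserConfig:
    """Architecture hyperparameters.

    ``base_channels`` is the encoder channel ladder, one entry per level;
    its length is the depth.  Input patch edges must be divisible by
    ``2 ** depth``.
    """

    base_channels: tuple[int, ...] = (26, 52, 104, 208, 416)
    dropout_rate: float = 0.5
    norm_kind: str = "instance"  # "instance" | "none"
    kernel: int = 3
    dtype: str = "float32"

    def __post_init__(self) -> None:
        self.base_channels = tuple(int(c) for c in self.base_channels)
        if len(self.base_channels) < 1 or min(self.base_channels) < 1:
            raise ValueError("need at least one positive channel width")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.norm_kind not in ("instance", "none"):
            raise ValueError(f"unknown norm_kind {self.norm_kind!r}")
        if self.kernel % 2 == 0:
            raise ValueError("kernel must be odd")

    @property
    def depth(self) -> int:
        return len(self.base_channels)

    def validate_edge(self, edge: int) -> None:
        if edge % (2**self.depth) != 0:
            raise ValueError(
                f"patch edge {edge} not divisible by 2^depth = {2**self.depth}"
            )


def _he_init(rng: np.random.Generator, shape: tuple, dtype) -> np.ndarray:
    fan_in = int(np.prod(shape[1:]))
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(dtype)


class DenoiserModel:
    """Residual U-net with named parameters and explicit train/infer modes."""

    def __init__(self, config: DenoiserConfig, rng: np.random.Generator):
        self.config = config
        self.training_mode = False
        dt = np.dtype(config.dtype)
        k = config.kernel
        ch = config.base_channels
        depth = config.depth
        self.params: dict[str, Tensor] = {}

        def conv_param(name: str, cin: int, cout: int, zero: bool = False):
            shape = (cout, cin, k, k, k)
            w = np.zeros(shape, dtype=dt) if zero else _he_init(rng, shape, dt)
            self.params[f"{name}.w"] = Tensor(w, requires_grad=True)
            self.params[f"{name}.b"] = Tensor(np.zeros(cout, dtype=dt),
                                              requires_grad=True)

        def norm_param(name: str, c: int):
            if config.norm_kind == "instance":
                self.params[f"{name}.gamma"] = Tensor(np.ones(c, dtype=dt),
                                                      requires_grad=True)
                self.params[f"{name}.beta"] = Tensor(np.zeros(c, dtype=dt),
                                                     requires_grad=True)

        cin = 1
        for i, c in enumerate(ch):
            conv_param(f"enc{i}", cin, c)
            norm_param(f"enc{i}.norm", c)
            cin = c
        conv_param("mid", ch[-1], ch[-1])
        norm_param("mid.norm", ch[-1])
        cur = ch[-1]
        for i in reversed(range(depth)):
            cout = ch[i - 1] if i > 0 else ch[0]
            conv_param(f"dec{i}", cur + ch[i], cout)
            norm_param(f"dec{i}.norm", cout)
            cur = cout
        conv_param("final", cur, 1, zero=True)

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def train(self, mode: bool = True) -> "DenoiserModel":
        self.training_mode = mode
        return self

    def eval(self) -> "DenoiserModel":
        return self.train(False)

    # -- forward ------------------------------------------------------------

    def _block(self, x: Tensor, name: str, train: bool,
               rng: np.random.Generator | None,
               with_dropout: bool) -> Tensor:
        h = nn.conv3d(x, self.params[f"{name}.w"], self.params[f"{name}.b"])
        if self.config.norm_kind == "instance":
            h = nn.instance_norm3d(h, self.params[f"{name}.norm.gamma"],
                                   self.params[f"{name}.norm.beta"])
        h = nn.silu(h)
        if with_dropout and train and self.config.dropout_rate > 0:
            if rng is None:
                raise ValueError("training-mode forward needs an rng for dropout")
            h = nn.dropout(h, self.config.dropout_rate, rng, train=True)
        return h

    def forward(self, x: Tensor, train: bool | None = None,
                rng: np.random.Generator | None = None) -> Tensor:
        """``f(x) = x + trunk(x)``; input shape (B, 1, D, H, W)."""
        if train is None:
            train = self.training_mode
        if x.data.ndim != 5 or x.data.shape[1] != 1:
            raise ValueError(f"expected (B, 1, D, H, W), got {x.data.shape}")
        self.config.validate_edge(x.data.shape[2])
        skips = []
        h = x
        for i in range(self.config.depth):
            h = self._block(h, f"enc{i}", train, rng, with_dropout=False)
            skips.append(h)
            h = nn.avg_pool3d(h)
        h = self._block(h, "mid", train, rng, with_dropout=False)
        for i in reversed(range(self.config.depth)):
            h = nn.upsample_nearest3d(h)
            h = nn.concat(h, skips[i], axis=1)
            h = self._block(h, f"dec{i}", train, rng, with_dropout=True)
        residual = nn.conv3d(h, self.params["final.w"], self.params["final.b"])
        return nn.add(x, residual)

    def apply(self, patch: np.ndarray) -> np.ndarray:
        """Inference on a bare 3D array (no graph, dropout off)."""
        x = Tensor(patch[None, None].astype(self.config.dtype))
        return self.forward(x, train=False).data[0, 0]


def build_model(config: DenoiserConfig,
                rng: np.random.Generator | None = None) -> DenoiserModel:
    """Construct a denoiser; the zero-initialized final convolution makes
    the fresh model the exact identity map."""
    if rng is None:
        rng = np.random.default_rng(0)
    return DenoiserModel(config, rng)


def parameter_count(config: DenoiserConfig) -> int:
    """Closed-form parameter count for a configuration (weights + biases +
    normalization affines), without building the network."""
    k3 = config.kernel**3
    ch = config.base_channels
    depth = config.depth
    norm = 2 if config.norm_kind == "instance" else 0
    total = 0
    cin = 1
    for c in ch:
        total += k3 * cin * c + c + norm * c
        cin = c
    total += k3 * ch[-1] * ch[-1] + ch[-1] + norm * ch[-1]
    cur = ch[-1]
    for i in reversed(range(depth)):
        cout = ch[i - 1] if i > 0 else ch[0]
        total += k3 * (cur + ch[i]) * cout + cout + norm * cout
        cur = cout
    total += k3 * cur * 1 + 1
    return total


def recycle(model: DenoiserModel, y: np.ndarray, r: int) -> np.ndarray:
    """Apply the denoiser to its own output ``r`` times, starting from ``y``.

    ``r = 0`` returns ``y`` unchanged.  The recycled passes run in inference
    mode and no gradient flows through them; the training loss applies the
    network once more to the result.
    """
    if not 0 <= r <= 5:
        raise ValueError(f"recycle count must be in [0, 5], got {r}")
    out = np.asarray(y)
    for _ in range(r):
        if out.ndim == 3:
            out = model.apply(out)
        else:
            out = model.forward(Tensor(out), train=False).data
    return out


def recycle_batch(model: DenoiserModel, batch: np.ndarray,
                  rs: np.ndarray) -> np.ndarray:
    """Vectorized recycling of a (B, 1, D, H, W) batch with per-example
    recycle counts: examples still needing passes are run together."""
    out = np.array(batch, copy=True)
    rs = np.asarray(rs)
    for step in range(int(rs.max()) if len(rs) else 0):
        active = rs > step
        if not np.any(active):
            break
        sub = Tensor(out[active])
        out[active] = model.forward(sub, train=False).data
    return out


def denoise_volume(model: DenoiserModel, v: Volume, patch_edge: int = 64,
                   overlap: int = 32) -> Volume:
    """Denoise a whole volume by overlapping patches.

    Each patch is standardized, passed through the network once, then
    de-standardized with its own pre-filter mean/std; patches are recombined
    with partition-of-unity raised-cosine blending.  Zero-variance patches
    pass through unchanged.
    """
    patch_edge = min(patch_edge, v.n)
    overlap = min(overlap, patch_edge - 1) if patch_edge > 1 else 0
    model.config.validate_edge(patch_edge)
    grid = tile_volume(v.n, patch_edge, overlap)
    out_patches = []
    for idx in range(grid.n_patches):
        patch = grid.extract(v.grid, idx).astype(np.float64)
        mu = float(patch.mean())
        sd = float(patch.std())
        if sd < 1e-9:
            out_patches.append(patch)
            continue
        z = (patch - mu) / sd
        dz = model.apply(z)
        out_patches.append(dz.astype(np.float64) * sd + mu)
    return stitch_patches(out_patches, grid, v.voxel_size, v.origin)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: DenoiserModel, path) -> None:
    """Single-archive checkpoint: parameters + embedded config + version."""
    meta = {"format_version": CHECKPOINT_FORMAT_VERSION,
            "config": asdict(model.config)}
    arrays = {k.replace(".", "__"): p.data for k, p in model.params.items()}
    np.savez_compressed(str(path), __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> DenoiserModel:
    with np.load(str(path)) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(
                f"unsupported checkpoint format {meta.get('format_version')}"
            )
        cfg_d = meta["config"]
        cfg_d["base_channels"] = tuple(cfg_d["base_channels"])
        config = DenoiserConfig(**cfg_d)
        model = build_model(config)
        for key, p in model.params.items():
            p.data = np.array(z[key.replace(".", "__")])
    return model
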