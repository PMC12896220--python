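"""The GLNet classifier: embedding, four global-and-local blocks, head.

The network embeds the encoded survey factors into ``embed_dim`` deep
features (default 128), then applies four global-and-local blocks (GLBs).
Each GLB runs a selective state-space scan over the feature sequence
(global context), a kernel-3 1-D convolution (local context), a leaky-ReLU,
a fully connected resize, and batch normalization.  The first two blocks
double the width, the last two halve it, and a residual connection joins
the two places where the width matches, forming a U-shaped structure:

    input_dim -> 128 -> 256 -> 512 -> 256 -> 128 -> 2

A linear two-class head with softmax produces the depression probability.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .encoding import EncodedDataset
from .nn import BatchNorm, Conv1dSame, Layer, LeakyReLU, Linear, SSMScan


@dataclass(frozen=True)
class GLNetConfig:
    input_dim: int
    embed_dim: int = 128
    ssm_state_dim: int = 16
    conv_kernel: int = 3
    leaky_slope: float = 0.01
    head_classes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embed_dim % 4 != 0:
            raise ValueError("embed_dim must be divisible by 4 "
                             "(two doublings and two halvings must return to it)")
        if self.conv_kernel % 2 == 0:
            raise ValueError("conv_kernel must be odd")
        if self.input_dim < 1:
            raise ValueError("input_dim must be positive")


class GLBlock(Layer):
    """SSM scan -> conv1d -> leaky-ReLU -> linear resize -> batch norm."""

    def __init__(self, dim_in: int, direction: str, cfg: GLNetConfig,
                 rng: np.random.Generator) -> None:
        super().__init__()
        if direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if direction == "down" and dim_in % 2:
            raise ValueError("down block needs even input dim")
        self.direction = direction
        self.dim_in = dim_in
        self.dim_out = dim_in * 2 if direction == "up" else dim_in // 2
        self.ssm = SSMScan(cfg.ssm_state_dim, rng)
        self.conv = Conv1dSame(cfg.conv_kernel, rng)
        self.act = LeakyReLU(cfg.leaky_slope)
        self.fc = Linear(dim_in, self.dim_out, rng)
        self.bn = BatchNorm(self.dim_out)
        self._subs = {"ssm": self.ssm, "conv": self.conv,
                      "fc": self.fc, "bn": self.bn}

    def forward(self, x: np.ndarray, train: bool, cache: bool = True) -> np.ndarray:
        if x.shape[1] != self.dim_in:
            raise ValueError(f"expected width {self.dim_in}, got {x.shape[1]}")
        z = self.ssm.forward(x, train, cache=cache)
        z = self.conv.forward(z, train)
        z = self.act.forward(z, train)
        z = self.fc.forward(z, train)
        return self.bn.forward(z, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dz = self.bn.backward(dy)
        dz = self.fc.backward(dz)
        dz = self.act.backward(dz)
        dz = self.conv.backward(dz)
        return self.ssm.backward(dz)

    def zero_grad(self) -> None:
        for sub in self._subs.values():
            sub.zero_grad()


class GLNetModel:
    """Parameter container plus forward/backward for the full network."""

    def __init__(self, config: GLNetConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.embed_dim
        self.embed = Linear(config.input_dim, d, rng)
        self.blocks = [
            GLBlock(d, "up", config, rng),
            GLBlock(2 * d, "up", config, rng),
            GLBlock(4 * d, "down", config, rng),
            GLBlock(2 * d, "down", config, rng),
        ]
        self.head = Linear(d, config.head_classes, rng)
        self._modules: dict[str, Layer] = {"embed": self.embed, "head": self.head}
        for i, b in enumerate(self.blocks):
            for sub_name, sub in b._subs.items():
                self._modules[f"blocks.{i}.{sub_name}"] = sub

    # -- parameter access --------------------------------------------------
    def named_parameters(self) -> dict[str, np.ndarray]:
        return {f"{m}.{k}": v for m, mod in self._modules.items()
                for k, v in mod.params.items()}

    def named_grads(self) -> dict[str, np.ndarray]:
        return {f"{m}.{k}": v for m, mod in self._modules.items()
                for k, v in mod.grads.items()}

    def named_buffers(self) -> dict[str, np.ndarray]:
        return {f"{m}.{k}": v for m, mod in self._modules.items()
                for k, v in mod.buffers.items()}

    def n_parameters(self) -> int:
        return sum(v.size for v in self.named_parameters().values())

    def zero_grad(self) -> None:
        for mod in self._modules.values():
            mod.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {f"param:{k}": v.copy() for k, v in self.named_parameters().items()}
        d.update({f"buffer:{k}": v.copy() for k, v in self.named_buffers().items()})
        return d

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params, buffers = self.named_parameters(), self.named_buffers()
        for key, val in state.items():
            kind, name = key.split(":", 1)
            target = params if kind == "param" else buffers
            if name not in target:
                raise KeyError(f"unknown state entry {key!r}")
            target[name][...] = val

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False,
                cache: bool = True) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if x.shape[1] != self.config.input_dim:
            raise ValueError(
                f"input width {x.shape[1]} != configured {self.config.input_dim}")
        z0 = self.embed.forward(x, train)
        z1 = self.blocks[0].forward(z0, train, cache)    # embed_dim -> 2d
        z2 = self.blocks[1].forward(z1, train, cache)    # 2d -> 4d
        z3 = self.blocks[2].forward(z2, train, cache)    # 4d -> 2d
        z4 = self.blocks[3].forward(z3 + z1, train, cache)  # residual at width 2d
        return self.head.forward(z4, train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dz4 = self.head.backward(dlogits)
        dsum = self.blocks[3].backward(dz4)
        dz3 = dsum
        dz1_skip = dsum
        dz2 = self.blocks[2].backward(dz3)
        dz1 = self.blocks[1].backward(dz2) + dz1_skip
        dz0 = self.blocks[0].backward(dz1)
        return self.embed.backward(dz0)


def init_model(config: GLNetConfig) -> GLNetModel:
    """Build a freshly initialized model; bit-identical for equal seeds."""
    return GLNetModel(config)


def ssm_scan(sequence: np.ndarray, params: SSMScan) -> np.ndarray:
    """Run the selective scan over one sequence (L,) or a batch (n, L)."""
    seq = np.asarray(sequence, dtype=np.float64)
    if seq.size == 0:
        raise ValueError("empty sequence")
    if seq.ndim == 1:
        return params.forward(seq[None, :], train=False)[0]
    return params.forward(seq, train=False)


def glb_forward(features: np.ndarray, block: GLBlock) -> np.ndarray:
    """Inference-mode forward through one global-and-local block."""
    feats = np.atleast_2d(np.asarray(features, dtype=np.float64))
    out = block.forward(feats, train=False)
    return out[0] if np.asarray(features).ndim == 1 else out


def glnet_forward(x: np.ndarray | EncodedDataset, model: GLNetModel,
                  mode: str = "eval") -> np.ndarray:
    """Class logits for row(s) ``x``; warns when inputs are unstandardized."""
    if mode not in ("train", "eval"):
        raise ValueError("mode must be 'train' or 'eval'")
    if isinstance(x, EncodedDataset):
        if not x.standardized:
            warnings.warn("model expects standardized inputs", stacklevel=2)
        x = x.matrix
    return model.forward(x, train=(mode == "train"))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def predict_proba(x: np.ndarray | EncodedDataset, model: GLNetModel) -> np.ndarray:
    """P(depressed) — softmax probability of class 1, eval mode."""
    return softmax(glnet_forward(x, model, mode="eval"))[:, 1]


def predict_proba_batched(x: np.ndarray, model: GLNetModel,
                          chunk: int = 1024) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    out = np.empty(x.shape[0])
    for i in range(0, x.shape[0], chunk):
        logits = model.forward(x[i:i + chunk], train=False, cache=False)
        out[i:i + chunk] = softmax(logits)[:, 1]
    return out


# ---------------------------------------------------------------------------
# Checkpoint: single text-header + raw-bytes file, deterministic on disk
# ---------------------------------------------------------------------------

_MAGIC = b"GLNETCKPT1\n"


def save_checkpoint(model: GLNetModel, path: str | Path,
                    extra: dict | None = None) -> None:
    state = model.state_dict()
    names = sorted(state)
    header = {
        "config": asdict(model.config),
        "extra": extra or {},
        "arrays": [
            {"name": n, "dtype": str(state[n].dtype), "shape": list(state[n].shape)}
            for n in names
        ],
    }
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(json.dumps(header, sort_keys=True).encode() + b"\n")
        for n in names:
            fh.write(np.ascontiguousarray(state[n]).tobytes())


def load_checkpoint(path: str | Path) -> tuple[GLNetModel, dict]:
    with open(path, "rb") as fh:
        if fh.read(len(_MAGIC)) != _MAGIC:
            raise ValueError(f"{path}: not a GLNet checkpoint")
        header = json.loads(fh.readline().decode())
        model = GLNetModel(GLNetConfig(**header["config"]))
        state = {}
        for meta in header["arrays"]:
            count = int(np.prod(meta["shape"], dtype=np.int64))
            arr = np.frombuffer(
                fh.read(count * np.dtype(meta["dtype"]).itemsize),
                dtype=meta["dtype"], count=count,
            ).reshape(meta["shape"]).copy()
            state[meta["name"]] = arr
        model.load_state_dict(state)
    return model, header["extra"]
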