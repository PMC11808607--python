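"""PortNet model construction, forward/backward, and parameter accounting.

The network family: a 3x3 convolutional stem, then residual blocks whose main
path is a depthwise separable convolution (3x3 depthwise -> BN -> ReLU -> 1x1
pointwise -> BN) and whose skip path is either a 1x1 projection convolution
(+BN) or the identity, joined by element-wise addition, ReLU, and an SE
channel gate; finally global average pooling and an affine softmax classifier.

Two independent parameter-counting routes are provided:
``count_params_closed_form`` (pure arithmetic on the block table) and
``introspect_params`` (enumeration of the built model's trainable arrays).
They must agree block by block; the reference table totals 2,621,827.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .config import ArchitectureConfig, BlockSpec, ConfigurationError

__all__ = [
    "PortNet",
    "ParamReport",
    "build_model",
    "count_params_closed_form",
    "introspect_params",
    "se_gate",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ParamReport:
    """Per-block and total trainable-parameter counts."""

    per_block: list[tuple[int, int]]
    total: int

    def table(self) -> str:
        lines = [f"{'block':>5}  {'params':>10}"]
        lines += [f"{i:>5}  {n:>10,}" for i, n in self.per_block]
        lines.append(f"{'total':>5}  {self.total:>10,}")
        return "\n".join(lines)


class _Stem(nn.Layer):
    def __init__(self, spec: BlockSpec, rng: np.random.Generator) -> None:
        self.conv = nn.Conv2d(spec.in_channels, spec.out_channels, 3,
                              stride=spec.stride, padding=1, rng=rng)
        self.bn = nn.BatchNorm2d(spec.out_channels)
        self.relu = nn.ReLU()

    def params(self):
        return self.conv.params() + self.bn.params()

    def forward(self, x, train=True):
        return self.relu.forward(self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, dout):
        return self.conv.backward(self.bn.backward(self.relu.backward(dout)))


class _ResidualBlock(nn.Layer):
    """Depthwise-separable main path + 1x1-projection or identity skip + SE."""

    def __init__(self, spec: BlockSpec, rng: np.random.Generator) -> None:
        ci, co = spec.in_channels, spec.out_channels
        self.projecting = spec.kind == "proj_block"
        self.dw = nn.DepthwiseConv2d(ci, 3, stride=spec.stride, padding=1, rng=rng)
        self.bn1 = nn.BatchNorm2d(ci)
        self.relu1 = nn.ReLU()
        self.pw = nn.Conv2d(ci, co, 1, rng=rng)
        self.bn2 = nn.BatchNorm2d(co)
        if self.projecting:
            self.skip_conv = nn.Conv2d(ci, co, 1, stride=spec.stride, rng=rng)
            self.skip_bn = nn.BatchNorm2d(co)
        self.relu_out = nn.ReLU()
        self.se = nn.SEGate(co, spec.se_hidden, rng=rng)

    def params(self):
        ps = (self.dw.params() + self.bn1.params() + self.pw.params() + self.bn2.params())
        if self.projecting:
            ps += self.skip_conv.params() + self.skip_bn.params()
        return ps + self.se.params()

    def forward(self, x, train=True):
        main = self.bn2.forward(self.pw.forward(
            self.relu1.forward(self.bn1.forward(self.dw.forward(x, train), train), train),
            train), train)
        if self.projecting:
            skip = self.skip_bn.forward(self.skip_conv.forward(x, train), train)
        else:
            skip = x
        return self.se.forward(self.relu_out.forward(main + skip, train), train)

    def backward(self, dout):
        dsum = self.relu_out.backward(self.se.backward(dout))
        dmain = self.dw.backward(self.bn1.backward(self.relu1.backward(
            self.pw.backward(self.bn2.backward(dsum)))))
        if self.projecting:
            dskip = self.skip_conv.backward(self.skip_bn.backward(dsum))
        else:
            dskip = dsum
        return dmain + dskip


class _Head(nn.Layer):
    def __init__(self, spec: BlockSpec, rng: np.random.Generator) -> None:
        self.pool = nn.GlobalAvgPool()
        self.fc = nn.Linear(spec.in_channels, spec.out_channels, rng=rng)

    def params(self):
        return self.fc.params()

    def forward(self, x, train=True):
        return self.fc.forward(self.pool.forward(x, train), train)

    def backward(self, dout):
        return self.pool.backward(self.fc.backward(dout))


class PortNet:
    """A built network: ordered layer blocks with forward/backward passes.

    ``forward`` returns pre-softmax logits; use :meth:`predict_proba` for
    softmax posteriors. ``backward`` propagates a logit gradient through every
    block, accumulating parameter gradients, and can record the gradient that
    arrives at any intermediate block output (used for Grad-CAM).
    """

    def __init__(self, config: ArchitectureConfig, seed: int = 0) -> None:
        config.validate()
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.blocks: list[nn.Layer] = []
        for spec in config.blocks:
            if spec.kind == "stem":
                self.blocks.append(_Stem(spec, rng))
            elif spec.kind in ("proj_block", "id_block"):
                self.blocks.append(_ResidualBlock(spec, rng))
            else:
                self.blocks.append(_Head(spec, rng))
        self._block_outputs: list[np.ndarray] | None = None

    # --- parameters --------------------------------------------------------

    def params(self) -> list[nn.Param]:
        out = []
        for b in self.blocks:
            out.extend(b.params())
        return out

    def num_params(self) -> int:
        return sum(p.size for p in self.params())

    # --- passes ------------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False,
                record: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != self.config.blocks[0].in_channels:
            raise ValueError(f"expected (n, 3, H, W) input, got {x.shape}")
        outputs = []
        for b in self.blocks:
            x = b.forward(x, train)
            if record:
                outputs.append(x)
        self._block_outputs = outputs if record else None
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.softmax(self.forward(x, train=False))

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Argmax class ids; ties broken toward the lowest class index."""
        return self.predict_proba(x).argmax(axis=1)

    def backward(self, dlogits: np.ndarray,
                 capture_block: int | None = None) -> np.ndarray | None:
        """Backpropagate ``dlogits``; optionally return the gradient at the
        output of block ``capture_block`` (non-negative index)."""
        captured = None
        d = dlogits
        for i in range(len(self.blocks) - 1, -1, -1):
            if capture_block is not None and i == capture_block:
                captured = d
            d = self.blocks[i].backward(d)
        return captured if capture_block is not None else d

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def batchnorm_layers(self) -> list[nn.BatchNorm2d]:
        out = []
        for b in self.blocks:
            out.extend(_batchnorms(b))
        return out

    def recalibrate_bn(self, x: np.ndarray, batch_size: int = 64) -> None:
        """Re-estimate BN running statistics with frozen weights.

        Short training schedules leave the cumulative running statistics
        polluted by early batches seen under very different weights; one
        forward sweep over the (training) data with the final weights resets
        them. No parameters change.
        """
        for bn in self.batchnorm_layers():
            bn.num_batches = 0
            bn.running_mean[...] = 0.0
            bn.running_var[...] = 1.0
        for i in range(0, len(x), batch_size):
            self.forward(x[i:i + batch_size], train=True)


def build_model(config: ArchitectureConfig, seed: int = 0) -> PortNet:
    """Instantiate a PortNet from its block table with seeded initialization."""
    return PortNet(config, seed)


def _se_params(c: int, h: int) -> int:
    # C->h affine with bias, h->C affine with bias
    return c * h + h + h * c + c


def count_params_closed_form(config: ArchitectureConfig) -> ParamReport:
    """Closed-form trainable-parameter count from the block table alone.

    Per the normative wiring: convolutions bias-free, each followed by batch
    norm (2 trainable values per channel); SE affine maps and the classifier
    carry biases. Independent of input resolution.
    """
    config.validate()
    per_block = []
    for i, b in enumerate(config.blocks):
        ci, co, h = b.in_channels, b.out_channels, b.se_hidden
        if b.kind == "stem":
            n = 9 * ci * co + 2 * co
        elif b.kind == "proj_block":
            n = (9 * ci + 2 * ci            # depthwise + BN
                 + ci * co + 2 * co         # pointwise + BN
                 + ci * co + 2 * co         # 1x1 projection skip + BN
                 + _se_params(co, h))
        elif b.kind == "id_block":
            n = 9 * ci + 2 * ci + ci * co + 2 * co + _se_params(co, h)
        else:  # head
            n = ci * co + co
        per_block.append((i, n))
    return ParamReport(per_block=per_block, total=sum(n for _, n in per_block))


def introspect_params(model: PortNet) -> ParamReport:
    """Count trainable parameters by enumerating the built model's arrays."""
    per_block = [(i, sum(p.size for p in b.params()))
                 for i, b in enumerate(model.blocks)]
    return ParamReport(per_block=per_block, total=sum(n for _, n in per_block))


def se_gate(features: np.ndarray, gate: nn.SEGate) -> np.ndarray:
    """Apply an SE gate to a feature batch (n, C, H, W)."""
    return gate.forward(np.ascontiguousarray(features, dtype=np.float32), train=False)


# --- checkpoints -----------------------------------------------------------

def save_checkpoint(model: PortNet, path) -> None:
    """Serialize parameters + BN running stats + config to a .npz archive."""
    arrays: dict[str, np.ndarray] = {}
    for i, b in enumerate(model.blocks):
        for j, p in enumerate(b.params()):
            arrays[f"b{i:02d}.p{j:02d}"] = p.value
        for j, bn in enumerate(_batchnorms(b)):
            arrays[f"b{i:02d}.rm{j}"] = bn.running_mean
            arrays[f"b{i:02d}.rv{j}"] = bn.running_var
            arrays[f"b{i:02d}.nb{j}"] = np.array([bn.num_batches])
    arrays["__config__"] = np.frombuffer(
        model.config.to_yaml().encode(), dtype=np.uint8)
    arrays["__seed__"] = np.array([model.seed])
    np.savez(path, **arrays)


def load_checkpoint(path) -> PortNet:
    with np.load(path) as data:
        cfg = ArchitectureConfig.from_yaml(bytes(data["__config__"]).decode())
        model = PortNet(cfg, seed=int(data["__seed__"][0]))
        for i, b in enumerate(model.blocks):
            for j, p in enumerate(b.params()):
                p.value[...] = data[f"b{i:02d}.p{j:02d}"]
            for j, bn in enumerate(_batchnorms(b)):
                bn.running_mean[...] = data[f"b{i:02d}.rm{j}"]
                bn.running_var[...] = data[f"b{i:02d}.rv{j}"]
                bn.num_batches = int(data[f"b{i:02d}.nb{j}"][0])
    return model


def _batchnorms(block: nn.Layer) -> list[nn.BatchNorm2d]:
    if isinstance(block, _Stem):
        return [block.bn]
    if isinstance(block, _ResidualBlock):
        bns = [block.bn1, block.bn2]
        if block.projecting:
            bns.append(block.skip_bn)
        return bns
    return []
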