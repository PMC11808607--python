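"""Declarative architecture configuration for PortNet.

A network is described by an ordered table of :class:`BlockSpec` rows — a
convolutional stem, a sequence of depthwise-separable residual blocks with
squeeze-and-excitation (SE) gating, and a global-average-pool + softmax head.
The table fully determines both the forward semantics and the exact trainable
parameter count, so configurations can be audited arithmetically before any
weights are allocated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

__all__ = [
    "BlockSpec",
    "ArchitectureConfig",
    "ConfigurationError",
    "portnet_reference",
    "toy_config",
]


class ConfigurationError(ValueError):
    """Raised when an architecture table violates its invariants."""


VALID_KINDS = ("stem", "proj_block", "id_block", "head")


@dataclass(frozen=True)
class BlockSpec:
    """One row of the layer table.

    kind
        ``stem`` (3x3 standard conv + BN + ReLU), ``proj_block`` (depthwise
        separable main path with a 1x1-convolution projection skip),
        ``id_block`` (same main path, identity skip) or ``head`` (global
        average pool + affine classifier).
    se_hidden
        Hidden width of the SE bottleneck; required for residual blocks,
        absent for stem and head.
    """

    kind: str
    in_channels: int
    out_channels: int
    stride: int = 1
    se_hidden: int | None = None

    def validate(self, index: int) -> None:
        if self.kind not in VALID_KINDS:
            raise ConfigurationError(f"block {index}: unknown kind {self.kind!r}")
        if self.in_channels < 1 or self.out_channels < 1:
            raise ConfigurationError(f"block {index}: channel widths must be positive")
        if self.kind in ("stem", "proj_block", "id_block") and self.stride not in (1, 2):
            raise ConfigurationError(f"block {index}: stride must be 1 or 2")
        if self.kind == "id_block":
            if self.in_channels != self.out_channels:
                raise ConfigurationError(
                    f"block {index}: id_block requires in_channels == out_channels "
                    f"({self.in_channels} != {self.out_channels})")
            if self.stride != 1:
                raise ConfigurationError(f"block {index}: id_block requires stride 1")
        if self.kind == "proj_block":
            if self.in_channels == self.out_channels and self.stride != 2:
                raise ConfigurationError(
                    f"block {index}: proj_block requires a channel change or stride 2")
        if self.kind in ("proj_block", "id_block"):
            if self.se_hidden is None or self.se_hidden < 1:
                raise ConfigurationError(f"block {index}: residual blocks need se_hidden >= 1")
        elif self.se_hidden is not None:
            raise ConfigurationError(f"block {index}: {self.kind} takes no se_hidden")


@dataclass
class ArchitectureConfig:
    """Ordered block table plus classifier width and input resolution."""

    blocks: list[BlockSpec]
    num_classes: int = 3
    input_size: int = 224
    name: str = "custom"

    def validate(self) -> None:
        if len(self.blocks) < 3:
            raise ConfigurationError("need at least stem, one block, and head")
        if self.blocks[0].kind != "stem":
            raise ConfigurationError("block 0: first block must be the stem")
        if self.blocks[-1].kind != "head":
            raise ConfigurationError(f"block {len(self.blocks) - 1}: last block must be the head")
        if any(b.kind in ("stem", "head") for b in self.blocks[1:-1]):
            raise ConfigurationError("stem/head may only appear at the ends of the table")
        if self.num_classes < 2:
            raise ConfigurationError("num_classes must be >= 2")
        for i, b in enumerate(self.blocks):
            b.validate(i)
            if i > 0 and b.in_channels != self.blocks[i - 1].out_channels:
                raise ConfigurationError(
                    f"block {i}: in_channels {b.in_channels} does not chain from "
                    f"previous out_channels {self.blocks[i - 1].out_channels}")
        if self.blocks[-1].out_channels != self.num_classes:
            raise ConfigurationError("head out_channels must equal num_classes")
        if self.input_size % self.total_stride != 0:
            raise ConfigurationError(
                f"input_size {self.input_size} not divisible by total stride {self.total_stride}")

    @property
    def total_stride(self) -> int:
        s = 1
        for b in self.blocks[:-1]:
            s *= b.stride
        return s

    # --- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        rows = []
        for b in self.blocks:
            row = {"kind": b.kind, "in_channels": b.in_channels,
                   "out_channels": b.out_channels}
            if b.kind != "head":
                row["stride"] = b.stride
            if b.se_hidden is not None:
                row["se_hidden"] = b.se_hidden
            rows.append(row)
        return {"name": self.name, "num_classes": self.num_classes,
                "input_size": self.input_size, "blocks": rows}

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureConfig":
        blocks = [BlockSpec(kind=r["kind"], in_channels=r["in_channels"],
                            out_channels=r["out_channels"], stride=r.get("stride", 1),
                            se_hidden=r.get("se_hidden"))
                  for r in d["blocks"]]
        cfg = cls(blocks=blocks, num_classes=d.get("num_classes", 3),
                  input_size=d.get("input_size", 224), name=d.get("name", "custom"))
        cfg.validate()
        return cfg

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ArchitectureConfig":
        try:
            with open(source) as fh:
                d = yaml.safe_load(fh)
        except (OSError, TypeError):
            d = yaml.safe_load(source)
        return cls.from_dict(d)


# 13-row reference table; total trainable parameters 2,621,827 with 3 classes.
_REFERENCE_ROWS = [
    ("stem", 3, 24, 2, None),
    ("proj_block", 24, 48, 2, 6),
    ("proj_block", 48, 96, 2, 12),
    ("id_block", 96, 96, 1, 6),
    ("id_block", 96, 96, 1, 7),
    ("proj_block", 96, 192, 2, 33),
    ("id_block", 192, 192, 1, 24),
    ("id_block", 192, 192, 1, 24),
    ("proj_block", 192, 384, 2, 48),
    ("proj_block", 384, 768, 1, 96),
    ("id_block", 768, 768, 1, 96),
    ("id_block", 768, 768, 1, 96),
    ("head", 768, 3, 1, None),
]


def portnet_reference(num_classes: int = 3, input_size: int = 224) -> ArchitectureConfig:
    """The reference PortNet layer table ("portnet-ref").

    Stride schedule 2,2,2,-,-,2,-,-,2,1,-,- gives a 32x total downsampling
    (7x7 pre-pool map at 224 input, 3x3 at 96). The SE hidden widths are
    normative; changing any width or bias convention changes the parameter
    budget.
    """
    blocks = [BlockSpec(k, ci, co if k != "head" else num_classes, s, h)
              for k, ci, co, s, h in _REFERENCE_ROWS]
    cfg = ArchitectureConfig(blocks=blocks, num_classes=num_classes,
                             input_size=input_size, name="portnet-ref")
    cfg.validate()
    return cfg


def toy_config(num_classes: int = 3, input_size: int = 96, width: int = 16) -> ArchitectureConfig:
    """A small 5-block variant (8x total stride) for fast tests and CAM demos.

    The shallower stride schedule keeps the pre-pool feature map at
    input_size / 8, which gives class-activation maps useful spatial
    resolution on small images.
    """
    w = width
    blocks = [
        BlockSpec("stem", 3, w, 2),
        BlockSpec("proj_block", w, 2 * w, 2, se_hidden=max(1, w // 4)),
        BlockSpec("id_block", 2 * w, 2 * w, 1, se_hidden=max(1, w // 4)),
        BlockSpec("proj_block", 2 * w, 4 * w, 2, se_hidden=max(1, w // 2)),
        BlockSpec("head", 4 * w, num_classes),
    ]
    cfg = ArchitectureConfig(blocks=blocks, num_classes=num_classes,
                             input_size=input_size, name="portnet-toy")
    cfg.validate()
    return cfg
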