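"""Seeded generator of 3-class histology-like test images.

Real lung histopathology slides are not redistributable with the package, so
tests and demos run on generated RGB images whose three classes are separable
by construction through object morphology and palette, mimicking the coarse
statistical structure of the task (many small dark nuclei vs. few large round
structures vs. elongated overlapping ridges on a textured background). The
generator is bit-reproducible from its seed and returns per-image foreground
masks, which ground-truth the class-activation localization checks.

No attempt is made at photorealism: what matters for testing is that (a) the
classes are learnable by a small CNN in a few epochs and (b) the evidence is
spatially confined to the rendered objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import LabeledDataset

__all__ = ["ClassRecipe", "SyntheticSpec", "generate", "write_image_folder"]


@dataclass
class ClassRecipe:
    """Morphology of one synthetic class.

    ``mean_count`` objects (Poisson, floored at 1) are rendered as rotated
    ellipses with major-axis radius N(radius_mean, radius_sd) (floored at
    1.5 px) and axis ratio (minor/major) uniform in ``axis_ratio_range``.
    ``palette`` is the base object color, jittered per object.
    """

    name: str
    mean_count: float
    radius_mean: float
    radius_sd: float
    axis_ratio_range: tuple[float, float]
    palette: tuple[int, int, int]
    color_jitter: float = 0.08


def default_recipes() -> list[ClassRecipe]:
    return [
        ClassRecipe("adenocarcinoma_like", mean_count=28, radius_mean=4.5,
                    radius_sd=1.0, axis_ratio_range=(0.35, 0.6),
                    palette=(132, 60, 150)),
        ClassRecipe("benign_like", mean_count=5, radius_mean=15.0,
                    radius_sd=2.5, axis_ratio_range=(0.85, 1.0),
                    palette=(226, 150, 170)),
        ClassRecipe("squamous_like", mean_count=14, radius_mean=13.0,
                    radius_sd=2.0, axis_ratio_range=(0.12, 0.25),
                    palette=(90, 120, 185)),
    ]


@dataclass
class SyntheticSpec:
    """Generation settings: class balance, image size, seed, background."""

    n_per_class: int = 10
    size: int = 96
    seed: int = 0
    recipes: list[ClassRecipe] = field(default_factory=default_recipes)
    background: tuple[int, int, int] = (235, 228, 238)
    noise_sd: float = 6.0

    def validate(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.size < 16:
            raise ValueError("size must be >= 16")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        palettes = {r.palette for r in self.recipes}
        if len(palettes) != len(self.recipes):
            raise ValueError("class palettes must be distinct")
        for r in self.recipes:
            if r.mean_count <= 0:
                raise ValueError(f"{r.name}: mean_count must be positive")
            if r.radius_mean <= 1.0:
                raise ValueError(f"{r.name}: radius_mean must exceed 1 pixel")


def _render_ellipse(img: np.ndarray, mask: np.ndarray, cy: float, cx: float,
                    a: float, b: float, theta: float, color: np.ndarray) -> None:
    """Alpha-composite one anti-aliased rotated ellipse in place."""
    size = img.shape[0]
    r = int(np.ceil(a)) + 2
    y0, y1 = max(0, int(cy) - r), min(size, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(size, int(cx) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    # ~1 px soft edge measured along the minor axis
    cov = np.clip(0.5 - (rho - 1.0) * b, 0.0, 1.0)
    patch = img[y0:y1, x0:x1]
    patch += cov[..., None] * (color - patch)
    mask[y0:y1, x0:x1] |= cov > 0.5


def generate(spec: SyntheticSpec | None = None) -> tuple[LabeledDataset, list[np.ndarray]]:
    """Generate the labeled image set and per-image foreground masks.

    Images are uint8 HxWx3; masks are boolean HxW, true exactly where a
    rendered object covers the pixel (coverage > 0.5). The draw order is
    fixed, so identical specs give byte-identical output.
    """
    spec = spec or SyntheticSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    size = spec.size
    items: list[tuple[object, int]] = []
    masks: list[np.ndarray] = []
    for label, recipe in enumerate(spec.recipes):
        for _ in range(spec.n_per_class):
            img = np.empty((size, size, 3), dtype=np.float64)
            img[...] = np.array(spec.background, dtype=np.float64)
            mask = np.zeros((size, size), dtype=bool)
            count = max(1, rng.poisson(recipe.mean_count))
            for _obj in range(count):
                a = max(1.5, rng.normal(recipe.radius_mean, recipe.radius_sd))
                ratio = rng.uniform(*recipe.axis_ratio_range)
                b = max(1.0, a * ratio)
                cy, cx = rng.uniform(0, size, size=2)
                theta = rng.uniform(0, np.pi)
                jitter = 1.0 + recipe.color_jitter * rng.uniform(-1, 1, size=3)
                color = np.clip(np.array(recipe.palette) * jitter, 0, 255)
                _render_ellipse(img, mask, cy, cx, a, b, theta, color)
            if spec.noise_sd > 0:
                img += rng.normal(0.0, spec.noise_sd, size=img.shape)
            items.append((np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8), label))
            masks.append(mask)
    ds = LabeledDataset(items, [r.name for r in spec.recipes])
    return ds, masks


def write_image_folder(out_dir, spec: SyntheticSpec | None = None) -> Path:
    """Materialize a generated set as PNGs: ``images/<class>/`` plus a
    ``masks/<class>/`` mirror and a manifest CSV. Returns the images root
    (suitable for :func:`portnet.data.load_image_folder`)."""
    from PIL import Image

    spec = spec or SyntheticSpec()
    ds, masks = generate(spec)
    out = Path(out_dir)
    rows = []
    for i, (img, label) in enumerate(ds.items):
        cname = ds.class_names[label]
        cdir = out / "images" / cname
        mdir = out / "masks" / cname
        cdir.mkdir(parents=True, exist_ok=True)
        mdir.mkdir(parents=True, exist_ok=True)
        fname = f"{cname}_{i:04d}.png"
        Image.fromarray(img).save(cdir / fname)
        Image.fromarray((masks[i] * 255).astype(np.uint8)).save(mdir / fname)
        rows.append((str(cdir / fname), label))
    with open(out / "manifest.csv", "w") as fh:
        fh.write("path,label\n")
        fh.writelines(f"{p},{lab}\n" for p, lab in rows)
    return out / "images"
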