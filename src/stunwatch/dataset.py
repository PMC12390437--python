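"""Dataset split and image amplification with box co-transformation.

The training corpus is split 3:1:1 into train / test / validation: the
train share is floor(0.6·n), the remainder is split evenly between test and
validation with an odd leftover going to test (so 1024 images yield
614 / 205 / 205).  The shuffle is seeded and reproducible.

Three amplification operators expand the training set, each co-transforming
the bounding-box annotations and never touching class labels:

* horizontal flip (mirror; lets the model learn reversed postures, e.g. a
  convulsing bird facing the other way),
* uniform up-scaling by 10% (birds vary in body size at line entry),
* HSV colour dithering (random hue/saturation/value offsets; lighting and
  plumage-tone variation).

Images are numpy arrays (H × W × 3, uint8 or float in [0, 1]); boxes are
center-format with continuous coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage import color as skcolor
from skimage.transform import resize as sk_resize

from .datamodel import BoundingBox

__all__ = [
    "SplitResult",
    "AmplifyConfig",
    "split_dataset",
    "split_sizes",
    "horizontal_flip",
    "scale_up",
    "hsv_dither",
    "amplify",
]


@dataclass(frozen=True)
class SplitResult:
    """Disjoint, exhaustive index partition of a dataset."""

    train: list[int]
    test: list[int]
    validation: list[int]
    seed: int

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train), len(self.test), len(self.validation))


def split_sizes(n: int) -> tuple[int, int, int]:
    """Partition sizes for the 3:1:1 split of ``n`` items.

    train = floor(0.6 n); the remainder is split evenly between test and
    validation, odd leftover to test.
    """
    if n < 5:
        raise ValueError(f"need at least 5 items for a 3:1:1 split, got {n}")
    n_train = int(np.floor(0.6 * n))
    rest = n - n_train
    n_val = rest // 2
    n_test = rest - n_val  # odd leftover goes to test
    return n_train, n_test, n_val


def split_dataset(n: int, seed: int) -> SplitResult:
    """Seeded random 3:1:1 split of indices 0..n-1."""
    n_train, n_test, n_val = split_sizes(n)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return SplitResult(
        train=perm[:n_train].tolist(),
        test=perm[n_train:n_train + n_test].tolist(),
        validation=perm[n_train + n_test:].tolist(),
        seed=seed,
    )


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim not in (2, 3):
        raise ValueError("image must be H×W or H×W×C")
    return image


def _check_in_bounds(boxes: Sequence[BoundingBox], width: int, height: int) -> None:
    for b in boxes:
        if b.x1 < 0 or b.y1 < 0 or b.x2 > width or b.y2 > height:
            raise ValueError(
                f"box {b} exceeds the {width}×{height} image bounds"
            )


def horizontal_flip(
    image: np.ndarray, boxes: Sequence[BoundingBox]
) -> tuple[np.ndarray, list[BoundingBox]]:
    """Mirror the image left-right; box centers map cx → W − cx.

    Applying the flip twice restores the original image and boxes.
    """
    image = _check_image(image)
    height, width = image.shape[:2]
    _check_in_bounds(boxes, width, height)
    flipped = image[:, ::-1].copy()
    new_boxes = [BoundingBox(width - b.cx, b.cy, b.w, b.h) for b in boxes]
    return flipped, new_boxes


def scale_up(
    image: np.ndarray, boxes: Sequence[BoundingBox], factor: float = 1.10
) -> tuple[np.ndarray, list[BoundingBox]]:
    """Resample the image by ``factor`` (default +10%) and scale boxes with it.

    Box centers and sizes are multiplied by the same factor, so relative
    geometry is preserved exactly (continuous coordinates).
    """
    if factor <= 0:
        raise ValueError("scale factor must be > 0")
    image = _check_image(image)
    height, width = image.shape[:2]
    new_boxes = [
        BoundingBox(b.cx * factor, b.cy * factor, b.w * factor, b.h * factor)
        for b in boxes
    ]
    if factor == 1.0:
        return image.copy(), new_boxes
    out_shape = (round(height * factor), round(width * factor)) + image.shape[2:]
    scaled = sk_resize(image, out_shape, order=1, anti_aliasing=factor < 1.0,
                       preserve_range=True)
    return scaled.astype(image.dtype, copy=False), new_boxes


def hsv_dither(
    image: np.ndarray,
    magnitudes: tuple[float, float, float] = (10.0, 0.1, 0.1),
    seed: int = 0,
) -> np.ndarray:
    """Random per-image HSV offsets within ±magnitudes, seeded.

    ``magnitudes`` are (hue in degrees, saturation, value); hue offsets wrap
    around the colour circle, saturation and value are clipped to [0, 1].
    Dimensions are unchanged; zero magnitudes return the image unchanged.
    """
    dh, ds, dv = magnitudes
    if dh < 0 or ds < 0 or dv < 0:
        raise ValueError("dither magnitudes must be >= 0")
    image = _check_image(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("HSV dithering requires an RGB image (H×W×3)")
    if dh == ds == dv == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    off_h = rng.uniform(-dh, dh) / 360.0
    off_s = rng.uniform(-ds, ds)
    off_v = rng.uniform(-dv, dv)
    as_uint8 = image.dtype == np.uint8
    rgb = image.astype(float) / 255.0 if as_uint8 else image.astype(float)
    hsv = skcolor.rgb2hsv(rgb)
    hsv[..., 0] = (hsv[..., 0] + off_h) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] + off_s, 0.0, 1.0)
    hsv[..., 2] = np.clip(hsv[..., 2] + off_v, 0.0, 1.0)
    out = skcolor.hsv2rgb(hsv)
    if as_uint8:
        return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)
    return out.astype(image.dtype, copy=False)


@dataclass(frozen=True)
class AmplifyConfig:
    """Amplification settings: which variants, scale factor, dither, seed."""

    keep_originals: bool = False
    scale_factor: float = 1.10
    hsv_magnitudes: tuple[float, float, float] = (10.0, 0.1, 0.1)
    seed: int = 0
    ops: tuple[str, ...] = ("hsv", "flip", "scale")


def amplify(
    dataset: Sequence[tuple[np.ndarray, Sequence[BoundingBox]]],
    cfg: AmplifyConfig | None = None,
) -> list[tuple[np.ndarray, list[BoundingBox]]]:
    """Emit the augmented variants of every (image, boxes) pair.

    With the three default operators the output holds 3n items (4n with
    ``keep_originals``); every variant keeps exactly the boxes of its
    source, co-transformed.
    """
    cfg = cfg or AmplifyConfig()
    if not dataset:
        raise ValueError("dataset must be non-empty")
    out: list[tuple[np.ndarray, list[BoundingBox]]] = []
    for idx, (image, boxes) in enumerate(dataset):
        boxes = list(boxes)
        if cfg.keep_originals:
            out.append((np.asarray(image).copy(), list(boxes)))
        for op in cfg.ops:
            if op == "hsv":
                out.append((hsv_dither(image, cfg.hsv_magnitudes,
                                       seed=cfg.seed + idx), list(boxes)))
            elif op == "flip":
                out.append(horizontal_flip(image, boxes))
            elif op == "scale":
                out.append(scale_up(image, boxes, cfg.scale_factor))
            else:
                raise ValueError(f"unknown amplification op {op!r}")
    return out
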