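"""Radiograph preprocessing: load, resize, channel-replicate, normalize.

Images are decoded with Pillow, bilinearly resized to a square model size
(default 224), replicated from grayscale to three identical channels so they
match convolutional backbones that expect RGB input, scaled to [0, 1], and
standardised channel-wise with mean/std statistics fitted on the training
split. The fitted statistics are persisted as a small JSON sidecar so that
test-time normalization matches training exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import DegenerateInputError, VaefusionError

logger = logging.getLogger(__name__)

__all__ = ["ImageTensor", "NormalizationStats", "load_and_resize",
           "fit_normalizer", "normalize", "denormalize", "save_stats",
           "load_stats", "IMAGENET_STATS"]

DEFAULT_SIZE = 224
_STD_FLOOR = 1e-6

#: fixed constants for backbone compatibility (scope="fixed")
IMAGENET_STATS = None  # populated after the dataclass definition


@dataclass(frozen=True)
class ImageTensor:
    """A model-ready image: H x W x 3 float array plus its source path."""

    pixels: np.ndarray
    source_path: str

    def __post_init__(self):
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=np.float64))


@dataclass(frozen=True)
class NormalizationStats:
    """Per-channel mean/std; scope records whether they came from the
    training split or are fixed external constants."""

    mean: np.ndarray
    std: np.ndarray
    scope: str = "train_set"

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=np.float64))
        object.__setattr__(self, "std", np.asarray(self.std, dtype=np.float64))
        if np.any(self.std <= 0):
            raise VaefusionError("normalization std must be positive")


IMAGENET_STATS = NormalizationStats(mean=np.array([0.485, 0.456, 0.406]),
                                    std=np.array([0.229, 0.224, 0.225]),
                                    scope="fixed")


def _decode(path: Path) -> np.ndarray:
    """Decode an 8/16-bit grayscale or RGB image to a [0, 1] float array."""
    with Image.open(path) as img:
        if img.mode in ("I", "I;16", "I;16B", "I;16L"):
            arr = np.asarray(img.convert("I"), dtype=np.float64) / 65535.0
        elif img.mode == "L":
            arr = np.asarray(img, dtype=np.float64) / 255.0
        else:
            arr = np.asarray(img.convert("RGB"), dtype=np.float64) / 255.0
    return arr


def load_and_resize(path: str | Path, size: int = DEFAULT_SIZE) -> ImageTensor:
    """Load an image, bilinearly resize it to size x size, and replicate
    grayscale content to three identical channels."""
    path = Path(path)
    try:
        arr = _decode(path)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot decode image {path}: {exc}") from exc
    if arr.ndim == 2:
        channels = [arr, arr, arr]
    else:
        channels = [arr[..., i] for i in range(3)]
    resized = []
    for channel in channels:
        if channel.shape == (size, size):
            resized.append(channel.copy())
        else:
            img = Image.fromarray(channel.astype(np.float32), mode="F")
            resized.append(np.asarray(img.resize((size, size), Image.BILINEAR),
                                      dtype=np.float64))
    return ImageTensor(pixels=np.stack(resized, axis=-1), source_path=str(path))


def fit_normalizer(train_images: list[ImageTensor]) -> NormalizationStats:
    """Per-channel mean/std pooled over every pixel of the training images.

    A zero-variance channel gets its std clamped to a small floor (with a
    warning) so normalization stays defined on constant inputs.
    """
    if not train_images:
        raise DegenerateInputError("cannot fit a normalizer on zero images")
    pooled = np.concatenate([im.pixels.reshape(-1, 3) for im in train_images], axis=0)
    mean = pooled.mean(axis=0)
    std = pooled.std(axis=0)
    if np.any(std < _STD_FLOOR):
        logger.warning("zero-variance channel(s) %s: std clamped to %g",
                       np.nonzero(std < _STD_FLOOR)[0].tolist(), _STD_FLOOR)
        std = np.maximum(std, _STD_FLOOR)
    return NormalizationStats(mean=mean, std=std, scope="train_set")


def normalize(image: ImageTensor, stats: NormalizationStats) -> ImageTensor:
    return ImageTensor(pixels=(image.pixels - stats.mean) / stats.std,
                       source_path=image.source_path)


def denormalize(image: ImageTensor, stats: NormalizationStats) -> ImageTensor:
    return ImageTensor(pixels=image.pixels * stats.std + stats.mean,
                       source_path=image.source_path)


def save_stats(stats: NormalizationStats, path: str | Path) -> None:
    Path(path).write_text(json.dumps({"mean": stats.mean.tolist(),
                                      "std": stats.std.tolist(),
                                      "scope": stats.scope}, indent=2))


def load_stats(path: str | Path) -> NormalizationStats:
    payload = json.loads(Path(path).read_text())
    return NormalizationStats(mean=np.array(payload["mean"]),
                              std=np.array(payload["std"]),
                              scope=payload["scope"])
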