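"""Tile-to-vector feature extraction behind a pluggable backbone contract.

Every backbone maps an RGB tile to a 512-dimensional vector, processes tiles
independently (so batching never changes the result) and is deterministic
for a fixed backbone state. Available backbones:

* ``"texture"`` (default) — handcrafted multi-scale gradient/intensity
  statistics projected to 512 dimensions by a fixed seeded random matrix.
  Needs no pretrained weights, separates oriented from isotropic textures.
* ``"random-projection"`` — a fixed Gaussian projection of the downsampled
  grayscale tile; bit-reproducible from its seed.
* ``"cnn"`` — adapter seam for a ResNet-18-class convolutional backbone;
  requires torch and pretrained weights supplied by the user.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .classifier import ConfigurationError
from .preprocess import TileRecord, _LUMA

__all__ = ["FeatureRecord", "extract_features", "BACKBONES"]

BACKBONES = ("texture", "random-projection", "cnn")


@dataclass(frozen=True)
class FeatureRecord:
    """One tile's feature vector with slide provenance."""

    patient_id: str
    slide_id: str
    x: int
    y: int
    vector: np.ndarray  # (feature_dim,)

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=np.float64)
        if v.ndim != 1 or not np.isfinite(v).all():
            raise ValueError("feature vector must be 1-D and finite")
        object.__setattr__(self, "vector", v)


def _gray(image: np.ndarray) -> np.ndarray:
    return image[..., :3].astype(np.float64) @ _LUMA


def _downsample(gray: np.ndarray, out: int) -> np.ndarray:
    """Block-mean downsample to out x out (pads by edge replication if needed)."""
    H, W = gray.shape
    ys = (np.arange(out + 1) * H / out).round().astype(int)
    xs = (np.arange(out + 1) * W / out).round().astype(int)
    res = np.empty((out, out))
    for i in range(out):
        for j in range(out):
            block = gray[ys[i] : max(ys[i + 1], ys[i] + 1), xs[j] : max(xs[j + 1], xs[j] + 1)]
            res[i, j] = block.mean()
    return res


def _texture_stats(image: np.ndarray) -> np.ndarray:
    """Multi-scale intensity/gradient statistics of one tile."""
    gray = _gray(image)
    feats = []
    for scale in (1, 2, 4):
        g = gray[::scale, ::scale]
        gy, gx = np.gradient(g)
        mag = np.hypot(gx, gy)
        ori = np.arctan2(gy, gx)  # [-pi, pi]
        feats.extend([g.mean(), g.std(), mag.mean(), mag.std()])
        hist_i, _ = np.histogram(g, bins=8, range=(0, 255))
        feats.extend(hist_i / max(g.size, 1))
        hist_m, _ = np.histogram(mag, bins=8, range=(0, 128))
        feats.extend(hist_m / max(mag.size, 1))
        # orientation histogram weighted by magnitude: stripes concentrate,
        # blobs spread uniformly
        hist_o, _ = np.histogram(ori, bins=8, range=(-np.pi, np.pi), weights=mag)
        total = hist_o.sum()
        feats.extend(hist_o / total if total > 0 else hist_o)
        feats.append(float(hist_o.max() / total) if total > 0 else 0.0)
    for ch in range(3):
        c = image[..., ch].astype(np.float64)
        feats.extend([c.mean() / 255.0, c.std() / 255.0])
    return np.asarray(feats)


def _projection(n_in: int, n_out: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xFEA7]))
    return rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(n_in, n_out))


def extract_features(
    tiles: Sequence[TileRecord],
    backbone: str = "texture",
    feature_dim: int = 512,
    seed: int = 0,
) -> list[FeatureRecord]:
    """Map each tile to a ``feature_dim`` vector with the chosen backbone.

    Tiles are processed independently, so permuting the input permutes the
    output identically and batch grouping cannot change the vectors.
    """
    if backbone == "texture":
        raws = [_texture_stats(t.image) for t in tiles]
        if not raws:
            return []
        proj = _projection(raws[0].size, feature_dim, seed)
        vectors = [r @ proj for r in raws]
    elif backbone == "random-projection":
        side = 32
        raws = [_downsample(_gray(t.image), side).ravel() / 255.0 for t in tiles]
        proj = _projection(side * side, feature_dim, seed)
        vectors = [r @ proj for r in raws]
    elif backbone == "cnn":
        vectors = _cnn_features(tiles, feature_dim)
    else:
        raise ConfigurationError(
            f"unknown backbone {backbone!r}; available: {', '.join(BACKBONES)}"
        )
    return [
        FeatureRecord(t.patient_id, t.slide_id, t.x, t.y, v) for t, v in zip(tiles, vectors)
    ]


def _cnn_features(tiles: Sequence[TileRecord], feature_dim: int) -> list[np.ndarray]:
    try:
        import torch  # noqa: F401
        import torchvision  # noqa: F401
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ConfigurationError(
            "the 'cnn' backbone requires torch and torchvision; install them or use "
            "the 'texture' backbone"
        ) from exc
    raise NotImplementedError(
        "wire a ResNet-18-class feature extractor here (global-average-pool layer, "
        f"{feature_dim} dims); the packaged backbones cover desk-scale use"
    )  # pragma: no cover


def backbone_sidecar(backbone: str, seed: int, feature_dim: int = 512) -> str:
    """JSON sidecar describing the backbone state, stored next to feature files."""
    return json.dumps(
        {"backbone": backbone, "seed": int(seed), "feature_dim": int(feature_dim)},
        sort_keys=True,
    )
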