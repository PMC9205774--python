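"""Slide preprocessing: tessellation, edge-based QC, stain normalization, sampling.

A slide raster is cut into a non-overlapping grid of square RGB tiles
(partial edge tiles are discarded). Blurry and tissue-free tiles are removed
by a Canny-edge criterion: the tile is converted to grayscale, a binary edge
map is computed (edge pixels 255, others 0), and tiles whose mean edge value
falls below a threshold (default 4) are dropped. Retained tiles are
color-normalized (Macenko stain-vector normalization by default) and at most
``n`` tiles per patient (default 150) are sampled without replacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.feature import canny

__all__ = [
    "TileRecord",
    "StainReference",
    "tessellate",
    "edge_qc_score",
    "qc_filter",
    "fit_stain_reference",
    "normalize_stain",
    "sample_patient_tiles",
    "DEFAULT_QC_THRESHOLD",
]

#: tiles with mean edge value below this are considered blurry / tissue-free
DEFAULT_QC_THRESHOLD = 4.0

#: standard luminance weights for RGB -> grayscale
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class TileRecord:
    """One grid tile cut from a slide, with provenance and QC score."""

    patient_id: str
    slide_id: str
    x: int  # pixel offset of the tile's left edge in slide coordinates
    y: int  # pixel offset of the tile's top edge
    image: np.ndarray  # (H, W, 3) uint8
    qc_score: float | None = None
    stain_warning: bool = False

    @property
    def tile_size(self) -> int:
        return self.image.shape[0]


def tessellate(
    slide: np.ndarray, tile_size: int, patient_id: str = "", slide_id: str = ""
) -> list[TileRecord]:
    """Cut a slide into a non-overlapping grid of tile_size squares.

    Partial tiles at the right/bottom edges are discarded; each record keeps
    its 0-based (x, y) grid-aligned pixel offsets.
    """
    slide = np.asarray(slide)
    if slide.ndim != 3 or slide.shape[2] != 3:
        raise ValueError(f"slide must be an RGB (H, W, 3) raster, got shape {slide.shape}")
    if slide.size == 0:
        raise ValueError("empty slide raster")
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    H, W = slide.shape[:2]
    tiles = []
    for y in range(0, (H // tile_size) * tile_size, tile_size):
        for x in range(0, (W // tile_size) * tile_size, tile_size):
            tiles.append(
                TileRecord(patient_id, slide_id, x, y, slide[y : y + tile_size, x : x + tile_size])
            )
    return tiles


def edge_qc_score(
    image: np.ndarray, canny_low: float = 40.0, canny_high: float = 100.0, sigma: float = 1.0
) -> float:
    """Mean of the binary Canny edge map (edge pixels 255) of the gray tile.

    Constant-color tiles score exactly 0; richly textured tissue scores well
    above the default removal threshold of 4. The score depends on the tile
    only through its grayscale conversion (0.299/0.587/0.114 weights).
    """
    img = np.asarray(image)
    if img.ndim == 3:
        gray = img[..., :3].astype(np.float64) @ _LUMA
    elif img.ndim == 2:
        gray = img.astype(np.float64)
    else:
        raise ValueError(f"expected a 2-D or RGB tile, got shape {img.shape}")
    edges = canny(gray, sigma=sigma, low_threshold=canny_low, high_threshold=canny_high)
    return float(edges.mean() * 255.0)


def qc_filter(tiles: Sequence[TileRecord], threshold: float = DEFAULT_QC_THRESHOLD) -> list[TileRecord]:
    """Retain tiles whose qc_score is at or above the threshold.

    Scores are computed lazily for tiles that do not have one yet. Order is
    preserved and input records are not mutated beyond score caching.
    """
    kept = []
    for t in tiles:
        if t.qc_score is None:
            t.qc_score = edge_qc_score(t.image)
        if t.qc_score >= threshold:
            kept.append(t)
    return kept


# ---------------------------------------------------------------------------
# Macenko stain normalization


@dataclass(frozen=True)
class StainReference:
    """Target stain basis: 3x2 column stain matrix and per-stain 99th-pct concentrations."""

    stain_matrix: np.ndarray  # (3, 2), columns = H and E optical-density vectors
    max_concentration: np.ndarray  # (2,)


# widely used hematoxylin/eosin reference basis
_DEFAULT_REFERENCE = StainReference(
    stain_matrix=np.array(
        [[0.5626, 0.2159], [0.7201, 0.8012], [0.4062, 0.5581]]
    ),
    max_concentration=np.array([1.9705, 1.0308]),
)

_IO = 255.0  # transmitted-light intensity of background (white)
_BETA = 0.15  # optical-density floor below which pixels count as background
_ALPHA = 1.0  # percentile trim for robust angle extremes


def _optical_density(image: np.ndarray) -> np.ndarray:
    im = image.reshape(-1, 3).astype(np.float64)
    return -np.log((im + 1.0) / (_IO + 1.0))


def fit_stain_reference(image: np.ndarray) -> StainReference:
    """Estimate a Macenko stain basis (stain matrix + max concentrations) from a tile."""
    od = _optical_density(np.asarray(image))
    mask = (od > _BETA).any(axis=1)
    od_t = od[mask]
    if od_t.shape[0] < 16:
        raise ValueError("tile has too little stained tissue to fit a stain basis")
    _, eigvecs = np.linalg.eigh(np.cov(od_t.T))
    plane = eigvecs[:, 1:3]  # two largest eigenvectors
    # orient so projections are positive
    if plane[:, 0].sum() < 0:
        plane[:, 0] *= -1
    if plane[:, 1].sum() < 0:
        plane[:, 1] *= -1
    proj = od_t @ plane
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, [_ALPHA, 100.0 - _ALPHA])
    v1 = plane @ np.array([np.cos(lo), np.sin(lo)])
    v2 = plane @ np.array([np.cos(hi), np.sin(hi)])
    # hematoxylin first (larger red-channel OD component)
    he = np.column_stack([v1, v2] if v1[0] > v2[0] else [v2, v1])
    he /= np.linalg.norm(he, axis=0)
    conc, *_ = np.linalg.lstsq(he, od_t.T, rcond=None)
    max_c = np.percentile(conc, 99, axis=1)
    return StainReference(he, max_c)


def normalize_stain(
    image: np.ndarray, reference: StainReference | None = None
) -> tuple[np.ndarray, bool]:
    """Map a tile's stain profile onto the reference (Macenko).

    Decomposes the optical-density image into two stain concentrations,
    rescales them to the reference maxima, and reconstructs with the
    reference stain matrix. Returns ``(normalized_tile, passthrough_flag)``;
    near-white tiles with no stain signal are passed through unchanged with
    the flag set (and a warning).
    """
    if reference is None:
        reference = _DEFAULT_REFERENCE
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("normalize_stain expects an RGB tile")
    try:
        src = fit_stain_reference(img)
    except ValueError:
        warnings.warn("near-white tile without stain signal: passed through un-normalized")
        return img.copy(), True
    od = _optical_density(img)
    conc, *_ = np.linalg.lstsq(src.stain_matrix, od.T, rcond=None)
    scale = np.divide(
        reference.max_concentration, src.max_concentration,
        out=np.ones(2), where=src.max_concentration > 1e-8,
    )
    conc = conc * scale[:, None]
    od_new = (reference.stain_matrix @ conc).T
    out = (_IO + 1.0) * np.exp(-od_new) - 1.0
    return np.clip(out, 0, 255).reshape(img.shape).astype(img.dtype), False


def normalize_tiles(
    tiles: Sequence[TileRecord], reference: StainReference | None = None
) -> list[TileRecord]:
    """Stain-normalize a list of tile records (new records, inputs untouched)."""
    out = []
    for t in tiles:
        norm, flagged = normalize_stain(t.image, reference)
        out.append(
            TileRecord(t.patient_id, t.slide_id, t.x, t.y, norm, t.qc_score, stain_warning=flagged)
        )
    return out


def sample_patient_tiles(tiles: Sequence[TileRecord], n: int = 150, seed: int = 0) -> list[TileRecord]:
    """Sample up to ``n`` of one patient's tiles without replacement.

    Patients with fewer than ``n`` retained tiles keep all of them; an empty
    input yields an empty output with a warning (the patient is excluded
    downstream). Deterministic under ``seed``; original order is preserved.
    """
    if len({t.patient_id for t in tiles}) > 1:
        raise ValueError("sample_patient_tiles expects tiles from a single patient")
    if len(tiles) == 0:
        warnings.warn("patient has no QC-passed tiles and will be excluded")
        return []
    if len(tiles) <= n:
        return list(tiles)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5A3D]))
    keep = np.sort(rng.choice(len(tiles), size=n, replace=False))
    return [tiles[i] for i in keep]
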