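"""Synthetic multi-cohort, weakly labeled tile datasets with known ground truth.

The generator emulates the multi-site study setting: several cohorts of
unequal size hold patients with a binary molecular label, each patient is a
bag of tiles, and only a fraction of the tiles in a positive patient (the
*witness rate*) actually carry the class signal. Cohorts differ by a
systematic *site effect* — a cohort-specific offset applied to every tile —
standing in for staining, scanner and population shift between institutions.

Feature mode draws 512-dimensional tile vectors directly:

* background tiles:  z ~ N(0, I)
* signal tiles:      z + effect_size * u          (u: fixed unit direction)
* every tile of cohort c additionally receives  site_shift * v_c, where the
  v_c are unit directions orthogonal to u and to each other.

Because the site offsets are orthogonal to the signal direction, a
label-aware oracle is unaffected by them, but finite-sample classifiers
trained on a single cohort pick up site-specific structure and degrade on a
multi-site test pool — the mechanism that makes local models underperform
collaborative ones.

Image mode renders the same bag structure as small RGB tiles of two texture
families (isotropic blobs = signal, oriented stripes = background) plus a
configurable fraction of blank tiles per slide for the QC filter to remove,
assembled into mosaic "slides" with recorded tile coordinates.

Generation is a pure function of the configuration: the same config yields
byte-identical output, and each patient's bag depends only on its own
identity, so patient order never changes the generated multiset.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import PatientBag

__all__ = [
    "SyntheticConfig",
    "SlideImage",
    "generate_feature_cohorts",
    "generate_tile_images",
    "generate_test_pool",
    "make_partition",
    "signal_direction",
    "site_directions",
]


class SyntheticConfigError(ValueError):
    """Invalid synthetic-data configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic multi-cohort dataset.

    Defaults describe the desk-scale reference setting: three cohorts of
    100/300/150 patients (smallest != middle != largest, so the basic
    schedule's checkpoint ordering is exercised), 30% class prevalence,
    32 tiles per patient of which half carry signal in positive patients,
    a standardized signal shift of 2 and a site offset of twice that
    magnitude (4) so that single-site models measurably degrade on a
    multi-site test pool without erasing the signal.
    """

    n_cohorts: int = 3
    patients_per_cohort: tuple[int, ...] = (100, 300, 150)
    prevalence: float | tuple[float, ...] = 0.3
    tiles_per_patient: int = 32
    witness_rate: float = 0.5
    effect_size: float = 2.0
    site_shift: float = 4.0
    feature_dim: int = 512
    mode: str = "features"  # "features" | "images"
    image_size: int = 64
    blank_fraction: float = 0.1  # images mode only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cohorts < 1 or len(self.patients_per_cohort) != self.n_cohorts:
            raise SyntheticConfigError("patients_per_cohort must list one size per cohort")
        for n in self.patients_per_cohort:
            if not isinstance(n, (int, np.integer)) or n < 1:
                raise SyntheticConfigError(f"cohort sizes must be positive integers, got {n!r}")
        for p in self.prevalences():
            if not 0.0 < p < 1.0:
                raise SyntheticConfigError("prevalence must be strictly between 0 and 1")
        if not 0.0 < self.witness_rate <= 1.0:
            raise SyntheticConfigError("witness_rate must be in (0, 1]")
        if self.tiles_per_patient < 1:
            raise SyntheticConfigError("tiles_per_patient must be >= 1")
        if self.mode not in ("features", "images"):
            raise SyntheticConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "images" and self.image_size < 8:
            raise SyntheticConfigError("image_size must be >= 8 pixels")
        if not 0.0 <= self.blank_fraction < 1.0:
            raise SyntheticConfigError("blank_fraction must be in [0, 1)")

    def prevalences(self) -> tuple[float, ...]:
        if isinstance(self.prevalence, (tuple, list)):
            if len(self.prevalence) != self.n_cohorts:
                raise SyntheticConfigError("per-cohort prevalence list has wrong length")
            return tuple(float(p) for p in self.prevalence)
        return tuple(float(self.prevalence) for _ in range(self.n_cohorts))

    def cohort_ids(self) -> tuple[str, ...]:
        return tuple(f"cohort{chr(ord('A') + i)}" for i in range(self.n_cohorts))


def _rng(*keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(k) & 0x7FFFFFFF for k in keys]))


def _split_key(split: str) -> int:
    return int.from_bytes(hashlib.sha256(split.encode()).digest()[:4], "little")


def signal_direction(config: SyntheticConfig) -> np.ndarray:
    """Fixed unit vector along which signal tiles are mean-shifted."""
    v = _rng(config.seed, 0xD17).normal(size=config.feature_dim)
    return v / np.linalg.norm(v)


def site_directions(config: SyntheticConfig) -> np.ndarray:
    """Per-cohort unit offset directions, orthogonal to the signal and each other."""
    u = signal_direction(config)
    basis = [u]
    out = []
    rng = _rng(config.seed, 0x517E)
    for _ in range(config.n_cohorts):
        v = rng.normal(size=config.feature_dim)
        for b in basis:
            v -= (v @ b) * b
        v /= np.linalg.norm(v)
        basis.append(v)
        out.append(v)
    return np.stack(out)


def _cohort_labels(config: SyntheticConfig, cohort_idx: int, split: str) -> np.ndarray:
    n = config.patients_per_cohort[cohort_idx]
    n_pos = int(round(config.prevalences()[cohort_idx] * n))
    n_pos = min(max(n_pos, 1), n - 1)  # keep both classes represented
    labels = np.zeros(n, dtype=np.int64)
    pos = _rng(config.seed, _split_key(split), cohort_idx, 0x1AB).choice(n, size=n_pos, replace=False)
    labels[pos] = 1
    return labels


def _patient_tiles(
    config: SyntheticConfig, cohort_idx: int, patient_idx: int, label: int, split: str,
    u: np.ndarray, v_site: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Tile feature matrix and per-tile signal mask for one patient."""
    rng = _rng(config.seed, _split_key(split), cohort_idx, patient_idx, 0x7117)
    T = config.tiles_per_patient
    X = rng.normal(size=(T, config.feature_dim))
    is_signal = np.zeros(T, dtype=bool)
    if label == 1:
        n_sig = int(round(config.witness_rate * T))
        n_sig = max(n_sig, 1)
        sig_idx = rng.choice(T, size=n_sig, replace=False)
        is_signal[sig_idx] = True
        X[is_signal] += config.effect_size * u
    X += config.site_shift * v_site
    return X, is_signal


def generate_feature_cohorts(
    config: SyntheticConfig, split: str = "train"
) -> tuple[dict[str, list[PatientBag]], pd.DataFrame]:
    """Generate per-cohort patient bags of tile feature vectors.

    Returns ``(bags_by_cohort, manifest)``; the manifest is a tidy table
    with columns patient_id, cohort_id, label, feature_key. Labels exist at
    the patient level only. ``split`` namespaces patient identities so that
    train and test pools drawn from the same config share the signal and
    site directions but contain disjoint patients.
    """
    if config.mode != "features":
        raise SyntheticConfigError("generate_feature_cohorts requires mode='features'")
    u = signal_direction(config)
    V = site_directions(config)
    bags: dict[str, list[PatientBag]] = {}
    rows = []
    for c, cid in enumerate(config.cohort_ids()):
        labels = _cohort_labels(config, c, split)
        cohort_bags = []
        for i, lab in enumerate(labels):
            pid = f"{split}_{cid}_p{i:04d}"
            X, _ = _patient_tiles(config, c, i, int(lab), split, u, V[c])
            cohort_bags.append(PatientBag(pid, cid, int(lab), X))
            rows.append({"patient_id": pid, "cohort_id": cid, "label": int(lab), "feature_key": pid})
        bags[cid] = cohort_bags
    manifest = pd.DataFrame(rows, columns=["patient_id", "cohort_id", "label", "feature_key"])
    return bags, manifest


def generate_test_pool(
    config: SyntheticConfig, patients_per_cohort: int | Sequence[int] = 100
) -> list[PatientBag]:
    """Held-out multi-site test pool sharing the config's directions.

    Draws fresh patients (split="test") from every cohort's distribution and
    pools them, emulating external validation of all models on data that
    mixes the site effects.
    """
    if isinstance(patients_per_cohort, (int, np.integer)):
        sizes = tuple(int(patients_per_cohort) for _ in range(config.n_cohorts))
    else:
        sizes = tuple(int(n) for n in patients_per_cohort)
    cfg = replace(config, patients_per_cohort=sizes)
    bags, _ = generate_feature_cohorts(cfg, split="test")
    pool: list[PatientBag] = []
    for cid in cfg.cohort_ids():
        pool.extend(bags[cid])
    return pool


def make_partition(total_patients: int, sizes: Sequence[int], seed: int) -> list[np.ndarray]:
    """Disjoint random index sets of the requested sizes; deterministic."""
    sizes = [int(s) for s in sizes]
    if any(s < 0 for s in sizes):
        raise ValueError("sizes must be non-negative")
    if sum(sizes) > total_patients:
        raise ValueError(f"requested {sum(sizes)} patients from a pool of {total_patients}")
    perm = _rng(seed, 0x9A27).permutation(total_patients)
    out, pos = [], 0
    for s in sizes:
        out.append(np.sort(perm[pos : pos + s]))
        pos += s
    return out


# ---------------------------------------------------------------------------
# image mode


@dataclass(frozen=True)
class SlideImage:
    """One synthetic slide: a mosaic of tiles with per-tile ground truth."""

    slide_id: str
    patient_id: str
    cohort_id: str
    label: int
    image: np.ndarray  # (H, W, 3) uint8 mosaic
    tile_coords: tuple[tuple[int, int], ...]  # (x, y) top-left, grid-aligned
    tile_kinds: tuple[str, ...]  # "signal" | "background" | "blank"


def _blob_tile(rng: np.random.Generator, s: int) -> np.ndarray:
    """Isotropic blob texture (signal family)."""
    yy, xx = np.mgrid[0:s, 0:s]
    img = np.zeros((s, s), dtype=np.float64)
    for _ in range(max(3, s // 8)):
        cx, cy = rng.uniform(0, s, size=2)
        r = rng.uniform(s / 16, s / 5)
        img += np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * r * r)))
    img = (img - img.min()) / (np.ptp(img) + 1e-12)
    # hard blob contours so the edge-based QC sees genuine structure
    img = np.where(img > np.median(img), 1.0, 0.0)
    img += 0.03 * rng.normal(size=(s, s))
    rgb = np.stack([200 - 120 * img, 160 - 100 * img, 210 - 60 * img], axis=-1)
    return np.clip(rgb, 0, 255).astype(np.uint8)


def _stripe_tile(rng: np.random.Generator, s: int) -> np.ndarray:
    """Oriented stripe texture (background family)."""
    yy, xx = np.mgrid[0:s, 0:s]
    theta = rng.uniform(0, np.pi)
    freq = rng.uniform(0.2, 0.5)
    phase = rng.uniform(0, 2 * np.pi)
    img = np.where(np.sin(freq * (np.cos(theta) * xx + np.sin(theta) * yy) + phase) > 0, 1.0, 0.0)
    img += 0.03 * rng.normal(size=(s, s))
    img = np.clip(img, 0, 1)
    rgb = np.stack([230 - 80 * img, 190 - 90 * img, 200 - 40 * img], axis=-1)
    return np.clip(rgb, 0, 255).astype(np.uint8)


def _blank_tile(rng: np.random.Generator, s: int) -> np.ndarray:
    level = rng.integers(230, 256)
    return np.full((s, s, 3), level, dtype=np.uint8)


def generate_tile_images(
    config: SyntheticConfig, split: str = "train"
) -> tuple[list[SlideImage], pd.DataFrame]:
    """Render the bag structure as mosaic slides of textured tiles.

    Signal tiles are blob-textured, background tiles stripe-textured, and a
    ``blank_fraction`` of each slide's tiles are constant-color (no tissue),
    giving the Canny QC filter genuine work. Tile positions on the mosaic
    grid are recorded in the manifest.
    """
    if config.mode != "images":
        raise SyntheticConfigError("generate_tile_images requires mode='images'")
    u = signal_direction(replace(config, mode="features"))
    V = site_directions(replace(config, mode="features"))
    s = config.image_size
    T = config.tiles_per_patient
    n_blank = int(round(config.blank_fraction * T))
    cols = int(np.ceil(np.sqrt(T)))
    rows_n = int(np.ceil(T / cols))
    slides: list[SlideImage] = []
    man_rows = []
    for c, cid in enumerate(config.cohort_ids()):
        labels = _cohort_labels(config, c, split)
        for i, lab in enumerate(labels):
            pid = f"{split}_{cid}_p{i:04d}"
            slide_id = f"{pid}_s0"
            rng = _rng(config.seed, _split_key(split), c, i, 0x1316)
            _, is_signal = _patient_tiles(config, c, i, int(lab), split, u, V[c])
            kinds = ["signal" if sig else "background" for sig in is_signal]
            if n_blank:
                blank_idx = rng.choice(T, size=n_blank, replace=False)
                for j in blank_idx:
                    kinds[j] = "blank"
            mosaic = np.zeros((rows_n * s, cols * s, 3), dtype=np.uint8)
            coords = []
            for j, kind in enumerate(kinds):
                r, q = divmod(j, cols)
                x, y = q * s, r * s
                trng = _rng(config.seed, _split_key(split), c, i, j, 0x71E)
                tile = {"signal": _blob_tile, "background": _stripe_tile, "blank": _blank_tile}[kind](trng, s)
                mosaic[y : y + s, x : x + s] = tile
                coords.append((x, y))
                man_rows.append(
                    {
                        "patient_id": pid, "cohort_id": cid, "label": int(lab),
                        "slide_id": slide_id, "x": x, "y": y, "kind": kind,
                    }
                )
            slides.append(
                SlideImage(slide_id, pid, cid, int(lab), mosaic, tuple(coords), tuple(kinds))
            )
    manifest = pd.DataFrame(
        man_rows, columns=["patient_id", "cohort_id", "label", "slide_id", "x", "y", "kind"]
    )
    return slides, manifest


def save_slides(slides: Sequence[SlideImage], out_dir) -> list[str]:
    """Write slide mosaics as 8-bit RGB PNGs; returns the file paths."""
    from pathlib import Path

    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for sl in slides:
        p = out / f"{sl.slide_id}.png"
        Image.fromarray(sl.image, mode="RGB").save(p, format="PNG")
        paths.append(str(p))
    return paths
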