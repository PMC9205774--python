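"""Model examination: whole-slide prediction heatmaps and top-tile export.

Heatmaps visualize tile-level class-1 probabilities as a continuous value
over the slide with a univariate color map. Interpolation happens on the
tile-grid lattice: scored tiles anchor their grid cell exactly, gaps left
by QC-removed tiles are filled by linear interpolation from scored
neighbors, and cells outside the convex hull of scored tiles take the
nearest scored value. For micrometer-scale inspection, the N
highest-scoring tiles of the M highest-scoring patients are exported with
full provenance; a lexicographic tie rule makes the ranking total and the
output order-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import griddata

__all__ = ["HeatmapGrid", "slide_heatmap", "top_tiles", "select_median_model"]


@dataclass(frozen=True)
class HeatmapGrid:
    """Interpolated per-tile probability raster for one slide."""

    slide_id: str
    grid_scores: np.ndarray  # (rows, cols) float, NaN where nothing was scored
    raster: np.ndarray  # (rows, cols) float in [0, 1], fully filled
    tile_size: int
    colormap: str = "viridis"

    def to_rgb(self, upscale: int | None = None) -> np.ndarray:
        """Render the raster with the univariate color map as 8-bit RGB."""
        import matplotlib

        cmap = matplotlib.colormaps[self.colormap]
        img = (cmap(self.raster)[:, :, :3] * 255).astype(np.uint8)
        if upscale:
            img = np.repeat(np.repeat(img, upscale, axis=0), upscale, axis=1)
        return img

    def to_frame(self) -> pd.DataFrame:
        """Sidecar table of (x, y, score) at scored tile positions."""
        rows, cols = np.nonzero(~np.isnan(self.grid_scores))
        return pd.DataFrame(
            {
                "x": cols * self.tile_size,
                "y": rows * self.tile_size,
                "score": self.grid_scores[rows, cols],
            }
        )


def slide_heatmap(
    tile_positions: Sequence[tuple[int, int]],
    tile_scores: Sequence[float],
    slide_shape: tuple[int, int],
    tile_size: int,
    slide_id: str = "",
    colormap: str = "viridis",
) -> HeatmapGrid:
    """Build the interpolated probability raster for one slide.

    ``tile_positions`` are grid-aligned (x, y) pixel offsets; ``slide_shape``
    is (height, width) in pixels. The raster equals each tile's score
    exactly at its own cell.
    """
    scores = np.asarray(tile_scores, dtype=np.float64)
    if scores.size == 0:
        raise ValueError("cannot build a heatmap without scored tiles")
    if np.nanmin(scores) < 0 or np.nanmax(scores) > 1:
        raise ValueError("tile scores must be probabilities in [0, 1]")
    H, W = slide_shape
    rows_n, cols_n = H // tile_size, W // tile_size
    grid = np.full((rows_n, cols_n), np.nan)
    for (x, y), s in zip(tile_positions, scores):
        r, c = y // tile_size, x // tile_size
        if not (0 <= r < rows_n and 0 <= c < cols_n):
            raise ValueError(f"tile at ({x}, {y}) lies outside the slide")
        grid[r, c] = s

    known = ~np.isnan(grid)
    raster = grid.copy()
    missing = np.nonzero(~known)
    if missing[0].size:
        pts = np.column_stack(np.nonzero(known)).astype(float)
        vals = grid[known]
        want = np.column_stack(missing).astype(float)
        centered = pts - pts[0]
        collinear = np.linalg.matrix_rank(centered) < 2
        if len(vals) >= 3 and not collinear:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    lin = griddata(pts, vals, want, method="linear")
                except Exception:
                    lin = np.full(len(want), np.nan)
        elif len(vals) >= 2 and collinear:
            # scored tiles on one line: 1-D linear interpolation along it,
            # clamped to the end values beyond the scored range
            direction = centered[np.argmax(np.linalg.norm(centered, axis=1))]
            direction = direction / np.linalg.norm(direction)
            t_known = centered @ direction
            order = np.argsort(t_known)
            t_want = (want - pts[0]) @ direction
            lin = np.interp(t_want, t_known[order], vals[order])
        else:
            lin = np.full(len(want), np.nan)
        near = griddata(pts, vals, want, method="nearest")
        filled = np.where(np.isnan(lin), near, lin)
        raster[missing] = filled
    # scored cells stay bit-exact
    raster[known] = grid[known]
    return HeatmapGrid(slide_id, grid, raster, tile_size, colormap)


def top_tiles(
    patient_scores: dict[str, float],
    tile_scores: pd.DataFrame,
    M: int,
    N: int,
    class_label: int = 1,
) -> pd.DataFrame:
    """N highest-scoring tiles from each of the M highest-scoring patients.

    ``tile_scores`` needs columns patient_id, slide_id, x, y, score. Ranking
    is toward ``class_label`` (probability of class 1, or its complement for
    class 0); ties break by (patient_id, x, y) so the selection is total and
    input-order independent. With fewer than M patients, all are used.
    """
    if M < 1 or N < 1:
        raise ValueError("M and N must be >= 1")
    if class_label not in (0, 1):
        raise ValueError("class_label must be 0 or 1")
    key = (lambda s: s) if class_label == 1 else (lambda s: 1.0 - s)
    if len(patient_scores) < M:
        warnings.warn(f"only {len(patient_scores)} patients available for top-{M} selection")
    ranked_patients = sorted(
        patient_scores, key=lambda p: (-key(patient_scores[p]), p)
    )[:M]
    out = []
    for pid in ranked_patients:
        sub = tile_scores[tile_scores["patient_id"] == pid].copy()
        sub["rank_score"] = key(sub["score"].to_numpy())
        sub = sub.sort_values(
            by=["rank_score", "patient_id", "x", "y"], ascending=[False, True, True, True]
        ).head(N)
        sub["patient_score"] = patient_scores[pid]
        out.append(sub.drop(columns="rank_score"))
    return pd.concat(out, ignore_index=True) if out else tile_scores.iloc[0:0]


def select_median_model(aurocs: Sequence[float]) -> int:
    """Index of the replicate with median AUROC (unique for odd replicate counts).

    Used to pick the model examined in heatmaps and tile exports.
    """
    a = np.asarray(aurocs, dtype=np.float64)
    if a.size == 0:
        raise ValueError("no replicates")
    order = np.argsort(a, kind="stable")
    return int(order[(a.size - 1) // 2])
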