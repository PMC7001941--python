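"""Image-style quantification of simulated cell populations.

Simulated positions are rasterized to a binary frame with the same
geometry as the experimental field of view (1280 x 1080 pixels of
0.658 µm), components are labeled as a particle analyzer would, and two
observables are extracted per frame: the number of aggregates normalized
by the initial cell count, and the mean projected area.  A mean-squared-
displacement estimator of the diffusion coefficient of isolated cells is
also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .engine import AbmConfig, Trajectory
from .space import BoxSpec, min_image_vector

__all__ = [
    "FrameImage",
    "AggregateStats",
    "rasterize",
    "label_components",
    "frame_stats",
    "component_circularities",
    "trajectory_timeseries",
    "unwrap_tracks",
    "msd_diffusion",
]

#: experimental frame geometry: width x height in pixels
FRAME_WIDTH_PX = 1280
FRAME_HEIGHT_PX = 1080

_STRUCT_8 = np.ones((3, 3), dtype=bool)
_STRUCT_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class FrameImage:
    """Binary mask of one frame; ``mask[row, col]`` with row 0 at y=0."""

    mask: np.ndarray
    pixel_size: float

    @property
    def shape(self):
        return self.mask.shape


@dataclass(frozen=True)
class AggregateStats:
    """Per-frame observables; ``mean_area`` is NaN when there is nothing
    in the frame."""

    time: float
    count: int
    normalized_count: float
    mean_area_um2: float
    mean_area_px2: float


def rasterize(
    positions,
    config: AbmConfig,
    width_px: int = FRAME_WIDTH_PX,
    height_px: int = FRAME_HEIGHT_PX,
) -> FrameImage:
    """Union-of-disks binary mask of the observed viewport.

    A pixel is foreground iff its center lies within one cell radius of
    some cell center (through the periodic images).  The box side equals
    the frame width (1280 px); the viewport shows the first ``height_px``
    rows of the periodic square.
    """
    px = config.pixel_size
    L = config.box.side_length
    n_side = int(round(L / px))
    r_px = (config.cell_diameter / 2.0) / px
    full = np.zeros((n_side, n_side), dtype=bool)
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    if pos.size:
        # stamp each disk into the periodic square, then crop the viewport
        half = int(np.ceil(r_px)) + 1
        offs = np.arange(-half, half + 1)
        dx, dy = np.meshgrid(offs, offs, indexing="xy")
        for x, y in pos:
            # pixel indices whose centers may fall inside the disk
            cx, cy = x / px - 0.5, y / px - 0.5  # pixel-center coordinates
            ix = int(round(cx))
            iy = int(round(cy))
            inside = (ix + dx - cx) ** 2 + (iy + dy - cy) ** 2 <= r_px * r_px
            rows = np.mod(iy + dy[inside], n_side)
            cols = np.mod(ix + dx[inside], n_side)
            full[rows, cols] = True
    return FrameImage(mask=full[:height_px, :width_px], pixel_size=px)


def label_components(image: FrameImage, connectivity: int = 8):
    """Label foreground components (8-connectivity by default, as in the
    particle analysis of the experimental pipeline).

    Returns ``(labeled, areas)`` where ``areas`` are pixel counts per
    component, background excluded.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    struct = _STRUCT_8 if connectivity == 8 else _STRUCT_4
    labeled, n = ndimage.label(image.mask, structure=struct)
    if n == 0:
        return labeled, np.empty(0, dtype=np.intp)
    areas = np.bincount(labeled.ravel())[1:]
    return labeled, areas


def frame_stats(areas_px, n_initial: int, pixel_size: float, time: float) -> AggregateStats:
    """Aggregate count (normalized by the initial cell number) and mean
    projected area from per-component pixel counts."""
    if n_initial < 1:
        raise ValueError("n_initial must be >= 1")
    areas_px = np.asarray(areas_px)
    count = len(areas_px)
    if count == 0:
        mean_px = np.nan
    else:
        mean_px = float(areas_px.mean())
    return AggregateStats(
        time=time,
        count=count,
        normalized_count=count / n_initial,
        mean_area_um2=mean_px * pixel_size**2,
        mean_area_px2=mean_px,
    )


def save_mask_png(image: FrameImage, path) -> None:
    """Write a binary frame mask as an 8-bit PNG (foreground = 255)."""
    from PIL import Image

    Image.fromarray(image.mask.astype(np.uint8) * 255).save(path, format="PNG")


def component_circularities(image: FrameImage, min_area_px: int = 0) -> np.ndarray:
    """Circularity 4*pi*A/P^2 of each labeled component (1 for a disk,
    smaller for branched filament-like aggregates).

    ``min_area_px`` restricts the measurement to large components, e.g.
    aggregates of at least some number of cells.
    """
    from skimage.measure import regionprops

    labeled, _ = label_components(image)
    out = []
    for rp in regionprops(labeled):
        if rp.area < max(min_area_px, 1):
            continue
        if rp.perimeter > 0:
            out.append(4.0 * np.pi * rp.area / rp.perimeter**2)
    return np.asarray(out)


def trajectory_timeseries(
    traj: Trajectory,
    n_initial: int | None = None,
    connectivity: int = 8,
    min_area_px: int = 0,
) -> pd.DataFrame:
    """Rasterize-label-measure every snapshot of a trajectory.

    Returns a DataFrame with columns ``time_min, n_aggregates,
    normalized_n, mean_area_um2, mean_area_px2``.  ``min_area_px``
    optionally drops components below that pixel area before measuring.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    n0 = traj.config.n_initial if n_initial is None else n_initial
    rows = []
    for snap in traj.snapshots:
        img = rasterize(snap.positions, traj.config)
        _, areas = label_components(img, connectivity=connectivity)
        if min_area_px > 0:
            areas = areas[areas >= min_area_px]
        st = frame_stats(areas, n0, traj.config.pixel_size, snap.time)
        rows.append(
            (st.time, st.count, st.normalized_count, st.mean_area_um2, st.mean_area_px2)
        )
    return pd.DataFrame(
        rows,
        columns=["time_min", "n_aggregates", "normalized_n", "mean_area_um2", "mean_area_px2"],
    )


def unwrap_tracks(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Unwrapped per-cell tracks from a trajectory.

    Only cells present in every snapshot are tracked (daughters are
    excluded).  Positions are unwrapped by accumulating minimal-image
    displacements between consecutive snapshots, which is exact as long
    as no cell travels more than half a box side per sampling interval.

    Returns ``(times, tracks)`` with ``tracks`` of shape (n_cells,
    n_times, 2).
    """
    snaps = traj.snapshots
    common = snaps[0].ids
    for s in snaps[1:]:
        common = np.intersect1d(common, s.ids)
    times = np.array([s.time for s in snaps])
    box = traj.config.box
    n = len(common)
    tracks = np.zeros((n, len(snaps), 2))
    prev = None
    for k, s in enumerate(snaps):
        idx = np.searchsorted(s.ids, common)  # ids are sorted by construction
        cur = s.positions[idx]
        if k == 0:
            tracks[:, 0] = cur
        else:
            tracks[:, k] = tracks[:, k - 1] + min_image_vector(prev, cur, box)
        prev = cur
    return times, tracks


def msd_diffusion(times: np.ndarray, tracks: np.ndarray) -> float:
    """Diffusion coefficient from the mean squared displacement.

    MSD(t) is the squared displacement from the initial position averaged
    over cells; a least-squares line through the origin is fitted over the
    first half of the available lags and D = slope / 4 (two dimensions).
    Units: µm²/min for times in minutes.
    """
    times = np.asarray(times, dtype=float)
    if len(times) < 2:
        raise ValueError("need at least two time points")
    disp = tracks - tracks[:, :1]
    msd = np.einsum("ctk,ctk->t", disp, disp) / len(tracks)
    lag = times - times[0]
    half = max(2, len(lag) // 2)
    t_fit, m_fit = lag[1:half + 1], msd[1:half + 1]
    slope = float(np.dot(t_fit, m_fit) / np.dot(t_fit, t_fit))
    return slope / 4.0
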