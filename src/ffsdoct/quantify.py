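"""Automated counterparts of the clinical image quantifications.

Replaces the manual ImageJ workflows used on the instrument's images:
point-tool endothelial cell counting, NeuronJ nerve tracing, and manual
particle tracking — with a bandpass/peak cell counter, a ridge-filter /
skeleton length-density estimator, and nearest-neighbor particle-track
linking, respectively.  All three report intensive (area-normalized)
quantities and are used for phantom parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import sato, threshold_otsu
from skimage.morphology import skeletonize

from .errors import InvalidParameterError

__all__ = ["DensityReport", "TrackSet", "count_cells", "nerve_length_density",
           "skeleton_length_um", "track_particles"]


@dataclass(frozen=True)
class DensityReport:
    value: float
    units: str
    n_objects: int
    area_mm2: float


@dataclass
class TrackSet:
    """Linked particle tracks: each a DataFrame (frame, time_s, y_px, x_px)."""

    tracks: list[pd.DataFrame] = field(default_factory=list)

    def velocity_series(self, pixel_pitch_um: float, frame_rate_fps: float
                        ) -> pd.DataFrame:
        """Per-link velocities: time, speed (mm/s) and vertical component.

        Vertical velocity is positive upward (decreasing row index).
        """
        rows = []
        for tr in self.tracks:
            if len(tr) < 2:
                continue
            t = tr["time_s"].to_numpy()
            y = tr["y_px"].to_numpy()
            x = tr["x_px"].to_numpy()
            dt = np.diff(t)
            vy = -np.diff(y) * pixel_pitch_um / dt * 1e-3
            vx = np.diff(x) * pixel_pitch_um / dt * 1e-3
            for tm, a, b in zip(t[:-1] + dt / 2, vy, vx):
                rows.append((tm, float(np.hypot(a, b)), float(a)))
        return pd.DataFrame(rows, columns=["time_s", "speed_mm_s",
                                           "v_vertical_mm_s"])


def count_cells(image: np.ndarray, expected_cell_scale_um: float = 20.0,
                pixel_pitch_um: float = 1250.0 / 1440.0,
                threshold_rel: float = 0.1) -> DensityReport:
    """Count mosaic cells by difference-of-Gaussians bandpass + local maxima.

    The bandpass is tuned to the expected cell scale; each surviving local
    maximum (minimum separation half a cell) is one cell.  A flat or empty
    image returns a zero-count report rather than raising.
    """
    img = np.asarray(image, dtype=float)
    area = img.shape[0] * img.shape[1] * pixel_pitch_um**2 * 1e-6
    if img.size == 0 or np.ptp(img) == 0:
        return DensityReport(0.0, "cells/mm^2", 0, area)
    scale_px = expected_cell_scale_um / pixel_pitch_um
    band = ndimage.gaussian_filter(img, scale_px / 6.0) \
        - ndimage.gaussian_filter(img, scale_px / 1.5)
    min_dist = max(int(round(0.4 * scale_px)), 1)
    peaks = peak_local_max(band, min_distance=min_dist,
                           threshold_abs=threshold_rel * float(np.ptp(band)))
    n = len(peaks)
    return DensityReport(n / area, "cells/mm^2", n, area)


_N8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def skeleton_length_um(skeleton: np.ndarray, pixel_pitch_um: float,
                       resample: int = 6) -> float:
    """Length of a binary skeleton by resampled path traversal.

    The skeleton is decomposed into simple arcs between junction pixels
    (8-degree >= 3); each arc is walked pixel by pixel and measured as the
    Euclidean length of the polyline through every ``resample``-th pixel,
    which suppresses the digitization zig-zag.  Chain-code weight schemes
    (1 / sqrt(2), or Kulpa's corrected weights) bias digital straight
    lines by 5-8% at some orientations; the resampled polyline stays
    within ~1% at any angle for arcs whose radius of curvature is large
    against the resampling step.  Junction-incident steps are added with
    plain chain weights (a small fraction of the total).
    """
    sk = skeleton.astype(bool)
    if not sk.any():
        return 0.0
    degree = ndimage.convolve(sk.astype(int), np.ones((3, 3), dtype=int),
                              mode="constant") - 1
    junctions = sk & (degree >= 3)
    arcs = sk & ~junctions
    labels, n_arcs = ndimage.label(arcs, structure=np.ones((3, 3)))
    total_px = 0.0
    for i in range(1, n_arcs + 1):
        pts = [tuple(p) for p in np.argwhere(labels == i)]
        pset = set(pts)
        start = next((p for p in pts
                      if sum((p[0] + dy, p[1] + dx) in pset
                             for dy, dx in _N8) <= 1), pts[0])
        # ordered walk along the arc
        order = [start]
        pset.discard(start)
        cur = start
        while True:
            nxt = [(cur[0] + dy, cur[1] + dx) for dy, dx in _N8
                   if (cur[0] + dy, cur[1] + dx) in pset]
            if not nxt:
                break
            cur = min(nxt, key=lambda q: (q[0] - cur[0]) ** 2
                      + (q[1] - cur[1]) ** 2)
            order.append(cur)
            pset.discard(cur)
        pts_arr = np.array(order, dtype=float)
        knots = np.vstack([pts_arr[::resample], pts_arr[-1:]])
        total_px += float(np.sum(np.linalg.norm(np.diff(knots, axis=0), axis=1)))
    # steps touching junction pixels, counted once with plain chain weights
    jx = np.argwhere(junctions)
    jset = {tuple(p) for p in jx}
    on = {tuple(p) for p in np.argwhere(sk)}
    for p in jx:
        for dy, dx in _N8:
            q = (p[0] + dy, p[1] + dx)
            if q not in on:
                continue
            if q not in jset:
                total_px += np.hypot(dy, dx)          # junction-to-arc step
            elif (q[0], q[1]) > (p[0], p[1]):
                total_px += np.hypot(dy, dx)          # junction-junction, once
    return total_px * pixel_pitch_um


def nerve_length_density(image: np.ndarray,
                         thickness_range_um: tuple[float, float] = (2.0, 4.0),
                         pixel_pitch_um: float = 1250.0 / 1440.0
                         ) -> DensityReport:
    """Nerve length density (mm/mm^2) by ridge enhancement + skeletonization.

    A Sato tubeness filter at the stated nerve thickness enhances the
    curvilinear structures, Otsu thresholding segments them, and the
    skeleton length per area is reported.
    """
    img = np.asarray(image, dtype=float)
    area = img.shape[0] * img.shape[1] * pixel_pitch_um**2 * 1e-6
    if img.size == 0 or np.ptp(img) == 0:
        return DensityReport(0.0, "mm/mm^2", 0, area)
    sigmas = [t / 2.0 / pixel_pitch_um for t in thickness_range_um]
    ridges = sato(img, sigmas=np.linspace(min(sigmas), max(sigmas), 3),
                  black_ridges=False)
    mask = ridges > threshold_otsu(ridges)
    sk = skeletonize(mask)
    length_mm = skeleton_length_um(sk, pixel_pitch_um) * 1e-3
    _, n_segments = ndimage.label(sk, structure=np.ones((3, 3)))
    return DensityReport(length_mm / area, "mm/mm^2", int(n_segments), area)


def _detect_blobs(frame: np.ndarray, detect_sigma_px: float,
                  threshold_rel: float) -> np.ndarray:
    sm = ndimage.gaussian_filter(frame, detect_sigma_px)
    if np.ptp(sm) == 0:
        return np.empty((0, 2))
    return peak_local_max(sm, min_distance=max(int(2 * detect_sigma_px), 1),
                          threshold_abs=threshold_rel * float(sm.max())
                          ).astype(float)


def track_particles(frames: np.ndarray | list[np.ndarray],
                    max_link_distance_px: float = 30.0,
                    detect_sigma_px: float = 2.0,
                    threshold_rel: float = 0.2,
                    frame_rate_fps: float = 275.0,
                    start_time_s: float = 0.0) -> TrackSet:
    """Detect bright particles per frame and link them into tracks.

    Frame-to-frame linking solves the one-to-one assignment minimizing the
    total link distance (Hungarian algorithm on the distance matrix, with
    ``max_link_distance_px`` as the cost of leaving a particle unlinked).
    Purely greedy nearest-neighbor linking systematically "leapfrogs"
    between particles trailing each other along a coherent drift; the
    optimal assignment resolves those conflicts.  Unlinked particles start
    new tracks (no gap closing).
    """
    from scipy.optimize import linear_sum_assignment

    frames = np.asarray(frames, dtype=float)
    if len(frames) < 2:
        raise InvalidParameterError("need at least 2 frames")
    tracks: list[list[tuple[int, float, float, float]]] = []
    open_tracks: dict[int, tuple[float, float]] = {}

    for k, frame in enumerate(frames):
        t = start_time_s + k / frame_rate_fps
        det = _detect_blobs(frame, detect_sigma_px, threshold_rel)
        assigned: set[int] = set()
        new_open: dict[int, tuple[float, float]] = {}
        if open_tracks and len(det):
            ids = list(open_tracks)
            prev = np.array([open_tracks[i] for i in ids])
            dmat = np.linalg.norm(prev[:, None, :] - det[None, :, :], axis=2)
            p, d = dmat.shape
            # square cost matrix with an unlink alternative per row/column
            big = 1e9
            cost = np.zeros((p + d, p + d))
            cost[:p, :d] = dmat
            cost[:p, d:] = np.where(np.eye(p, dtype=bool),
                                    max_link_distance_px, big)
            cost[p:, :d] = np.where(np.eye(d, dtype=bool),
                                    max_link_distance_px, big)
            rows, cols = linear_sum_assignment(cost)
            for pi, di in zip(rows, cols):
                if pi >= p or di >= d or dmat[pi, di] > max_link_distance_px:
                    continue
                assigned.add(int(di))
                tid = ids[pi]
                tracks[tid].append((k, t, det[di, 0], det[di, 1]))
                new_open[tid] = (det[di, 0], det[di, 1])
        for di in range(len(det)):
            if di in assigned:
                continue
            tid = len(tracks)
            tracks.append([(k, t, det[di, 0], det[di, 1])])
            new_open[tid] = (det[di, 0], det[di, 1])
        open_tracks = new_open
    dfs = [pd.DataFrame(tr, columns=["frame", "time_s", "y_px", "x_px"])
           for tr in tracks]
    return TrackSet(dfs)
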