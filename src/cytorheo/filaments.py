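"""Filament contours: persistence length and length statistics.

Skeletonized filament images (1-pixel-wide, 8-connected) are traced into
ordered contours; the persistence length is estimated from the tangent-angle
cosine correlation with the 2D convention

    <cos theta(s)> = exp(-s / (2 l_P)),

appropriate for filaments confined to two dimensions before imaging (the 3D
convention differs by a factor of 2 and is switchable).  Length statistics use
the mass-weighted mean ``L_w = sum(L^2) / sum(L)`` that up-weights long
filaments, with the correspondingly weighted standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd


@dataclass
class FilamentPath:
    """Ordered 2D contour coordinates in um."""

    points: np.ndarray                  # (n, 2)
    pixel_size: float | None = None     # um / px when image-derived

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2)")
        if len(self.points) < 3:
            raise ValueError("a filament path needs at least 3 points")
        if np.any(np.all(np.diff(self.points, axis=0) == 0, axis=1)):
            raise ValueError("consecutive points must be distinct")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class PersistenceEstimate:
    l_P: float               # um
    stderr: float            # um
    fit_range: tuple[float, float]   # arc-length window, um
    n_filaments: int


@dataclass
class LengthStats:
    n: int
    L_w: float               # length-weighted mean, um
    sd_w: float              # length-weighted SD, um
    mean: float              # unweighted mean, um
    sd: float                # unweighted SD, um
    exp_rate_fit: float      # ML exponential mean parameter, um


@dataclass
class CorrelationCurve:
    """Tangent cosine correlation versus arc-length separation."""

    s: np.ndarray            # um
    corr: np.ndarray
    n_pairs: np.ndarray
    ds: float
    n_filaments: int


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
              (0, 1), (1, -1), (1, 0), (1, 1)]


def skeleton_to_paths(binary_image: np.ndarray,
                      pixel_size: float = 1.0) -> list[FilamentPath]:
    """Trace a 1-pixel-wide skeleton into simple paths.

    8-connectivity; junction pixels (3 or more skeleton neighbors) split
    paths and are never traversed, so crossing filaments do not introduce
    spurious bends.  An empty image yields an empty list.
    """
    img = np.asarray(binary_image)
    vals = np.unique(img)
    if not np.all(np.isin(vals, [0, 1])) and img.dtype != bool:
        raise ValueError("skeleton image must be binary")
    mask = img.astype(bool)
    if not mask.any():
        return []
    pixels = set(map(tuple, np.argwhere(mask)))

    def neighbors(p):
        return [(p[0] + dr, p[1] + dc) for dr, dc in _NEIGHBORS
                if (p[0] + dr, p[1] + dc) in pixels]

    degree = {p: len(neighbors(p)) for p in pixels}
    junctions = {p for p, d in degree.items() if d >= 3}
    chain_pixels = pixels - junctions

    visited: set = set()
    paths: list[FilamentPath] = []

    def walk(start, first):
        """Follow a degree-<=2 chain from start through first."""
        seq = [start, first]
        visited.add(first)
        cur, prev = first, start
        while True:
            nxt = [q for q in neighbors(cur)
                   if q != prev and q in chain_pixels and q not in visited]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            visited.add(cur)
            seq.append(cur)
        return seq

    # start from chain endpoints: chain pixels with <= 1 unvisited chain neighbor
    for p in sorted(chain_pixels):
        if p in visited:
            continue
        chain_nb = [q for q in neighbors(p) if q in chain_pixels]
        if len(chain_nb) <= 1:          # endpoint of a simple branch
            visited.add(p)
            seq = walk(p, chain_nb[0]) if chain_nb else [p]
            if len(seq) >= 3:
                pts = np.array([(c, r) for r, c in seq], float) * pixel_size
                paths.append(FilamentPath(pts, pixel_size))
    # remaining unvisited chain pixels belong to closed loops
    for p in sorted(chain_pixels):
        if p in visited:
            continue
        visited.add(p)
        nb = [q for q in neighbors(p) if q in chain_pixels and q not in visited]
        seq = walk(p, nb[0]) if nb else [p]
        if len(seq) >= 3:
            pts = np.array([(c, r) for r, c in seq], float) * pixel_size
            paths.append(FilamentPath(pts, pixel_size))
    return paths


def contour_length(path: FilamentPath | np.ndarray) -> float:
    """Sum of consecutive Euclidean distances along the contour (um)."""
    pts = path.points if isinstance(path, FilamentPath) else np.asarray(path, float)
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def resample_path(pts: np.ndarray, ds: float) -> np.ndarray:
    """Resample an ordered contour at equal arc-length steps ds."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    grid = np.arange(0.0, s[-1] + ds * 1e-9, ds)
    x = np.interp(grid, s, pts[:, 0])
    y = np.interp(grid, s, pts[:, 1])
    return np.column_stack([x, y])


def tangent_correlation(paths: Sequence[FilamentPath | np.ndarray],
                        ds: float | None = None,
                        max_s: float | None = None,
                        resample_factor: float = 5.0) -> CorrelationCurve:
    """Average tangent-angle cosine correlation across filaments.

    Tangent angles come from equal-arc-length resampled segments (default step
    5x the pixel size, suppressing pixel-lattice angle quantization; for
    synthetic contours without a pixel size, the native mean step).  The
    correlation at separation s = k*ds averages cos(theta_{i+k} - theta_i)
    over all segment pairs of all filaments; by default s is restricted to
    half the shortest usable filament.
    """
    pts_list = [p.points if isinstance(p, FilamentPath) else np.asarray(p, float)
                for p in paths]
    if not pts_list:
        raise ValueError("no filaments given")
    if ds is None:
        px = next((p.pixel_size for p in paths
                   if isinstance(p, FilamentPath) and p.pixel_size), None)
        if px is not None:
            ds = resample_factor * px
        else:
            ds = float(np.mean([
                np.mean(np.linalg.norm(np.diff(p, axis=0), axis=1))
                for p in pts_list]))

    angle_list = []
    for pts in pts_list:
        rs = resample_path(pts, ds)
        if len(rs) < 3:
            continue
        d = np.diff(rs, axis=0)
        angle_list.append(np.arctan2(d[:, 1], d[:, 0]))
    if not angle_list:
        raise ValueError("no filament is long enough for the requested step")

    if max_s is None:
        max_s = min(len(a) for a in angle_list) * ds / 2
    kmax = max(1, int(np.floor(max_s / ds)))
    kmax = min(kmax, max(len(a) for a in angle_list) - 1)
    sums = np.zeros(kmax)
    counts = np.zeros(kmax, dtype=np.int64)
    for ang in angle_list:
        for k in range(1, min(kmax, len(ang) - 1) + 1):
            dtheta = ang[k:] - ang[:-k]
            sums[k - 1] += np.sum(np.cos(dtheta))
            counts[k - 1] += len(dtheta)
    keep = counts > 0
    s = np.arange(1, kmax + 1)[keep] * ds
    return CorrelationCurve(s, sums[keep] / counts[keep], counts[keep],
                            ds, len(angle_list))


def fit_persistence(curve: CorrelationCurve,
                    fit_range: tuple[float, float] | None = None,
                    convention: Literal["2d", "3d"] = "2d",
                    ) -> PersistenceEstimate:
    """Persistence length from a weighted log-linear fit of the correlation.

    2D convention: slope of ln<cos theta> vs s equals -1/(2 l_P); the 3D
    convention equals -1/l_P.  Raises if the correlation does not decay
    (straight filaments) or is non-positive over the whole fit range.
    """
    if fit_range is None:
        fit_range = (curve.s[0], curve.s[-1])
    sel = (curve.s >= fit_range[0]) & (curve.s <= fit_range[1])
    s = curve.s[sel]
    c = curve.corr[sel]
    w = curve.n_pairs[sel].astype(float)
    pos = c > 0
    if pos.sum() < 2:
        raise ValueError("correlation non-positive over the fit range")
    if not pos.all():
        # shrink to the longest positive prefix
        first_bad = int(np.argmin(pos))
        s, c, w = s[:first_bad], c[:first_bad], w[:first_bad]
        if len(s) < 2:
            raise ValueError("correlation non-positive over the fit range")
    y = np.log(c)
    wsum = w.sum()
    sbar = np.sum(w * s) / wsum
    ybar = np.sum(w * y) / wsum
    sxx = np.sum(w * (s - sbar) ** 2)
    slope = np.sum(w * (s - sbar) * (y - ybar)) / sxx
    if slope >= -1e-12:
        raise ValueError(
            "tangent correlation does not decay; persistence length "
            "diverges (straight filaments?)")
    resid = y - (ybar + slope * (s - sbar))
    dof = max(len(s) - 2, 1)
    slope_se = np.sqrt(np.sum(w * resid ** 2) / dof / sxx)
    factor = 2.0 if convention == "2d" else 1.0
    l_p = -1.0 / (factor * slope)
    stderr = slope_se / (factor * slope ** 2)
    return PersistenceEstimate(l_P=float(l_p), stderr=float(stderr),
                               fit_range=(float(s[0]), float(s[-1])),
                               n_filaments=curve.n_filaments)


def length_statistics(lengths: Sequence[float]) -> LengthStats:
    """Length-weighted (mass-weighted) filament length statistics.

    ``L_w = sum(L^2)/sum(L)``; the weighted SD uses the same length weights:
    ``sd_w = sqrt(sum(L (L - L_w)^2) / sum(L))``.  The exponential mean is the
    maximum-likelihood fit (= sample mean).
    """
    L = np.asarray(lengths, dtype=float)
    if len(L) == 0:
        raise ValueError("empty length sample")
    if np.any(L <= 0):
        raise ValueError("filament lengths must be positive")
    lw = float(np.sum(L ** 2) / np.sum(L))
    sd_w = float(np.sqrt(np.sum(L * (L - lw) ** 2) / np.sum(L)))
    return LengthStats(n=len(L), L_w=lw, sd_w=sd_w, mean=float(np.mean(L)),
                       sd=float(np.std(L, ddof=1)) if len(L) > 1 else 0.0,
                       exp_rate_fit=float(np.mean(L)))


def read_filament_csv(path) -> list[FilamentPath]:
    """Read ordered filament coordinates (filament_id, x_um, y_um)."""
    df = pd.read_csv(path)
    for col in ("filament_id", "x_um", "y_um"):
        if col not in df.columns:
            raise ValueError(f"filament CSV missing column {col!r}")
    return [FilamentPath(g[["x_um", "y_um"]].to_numpy(float))
            for _, g in df.groupby("filament_id", sort=False)]
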