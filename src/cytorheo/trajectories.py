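"""Bead trajectories and mean squared displacements.

Video particle tracking yields per-particle time series of 2D positions.  This
module holds the validated containers (:class:`Trajectory`,
:class:`TrajectoryEnsemble`), CSV I/O, optional common-mode drift removal, and
time-averaged / ensemble MSD computation.  The MSD convention is 2D:
``msd(tau) = <dx^2 + dy^2>``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical trajectory CSV columns
CSV_COLUMNS = ("particle_id", "frame", "t_s", "x_um", "y_um")

_DT_RTOL = 1e-6


@dataclass
class Trajectory:
    """One particle's 2D track with uniformly spaced sample times (s, um)."""

    particle_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) < 2:
            raise ValueError(f"trajectory {self.particle_id!r} has < 2 samples")
        if not (np.isfinite(self.t).all() and np.isfinite(self.x).all()
                and np.isfinite(self.y).all()):
            raise ValueError(f"trajectory {self.particle_id!r} has non-finite values")
        dts = np.diff(self.t)
        if np.any(dts <= 0):
            raise ValueError(f"trajectory {self.particle_id!r}: t not strictly increasing")
        if np.ptp(dts) > _DT_RTOL * np.median(dts):
            raise ValueError(f"trajectory {self.particle_id!r}: non-uniform frame interval")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t)))

    @property
    def n_frames(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class TrajectoryEnsemble:
    """A set of trajectories sharing acquisition metadata.

    ``metadata`` keys used downstream: ``bead_diameter_um``, ``temperature_k``,
    ``fps``, ``concentration_uM``.  ``truth`` optionally records the generative
    ground truth for synthetic ensembles.
    """

    trajectories: list[Trajectory]
    metadata: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [tr.particle_id for tr in self.trajectories]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate particle_ids in ensemble")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    @property
    def dt(self) -> float:
        if not self.trajectories:
            raise ValueError("empty ensemble has no dt")
        return self.trajectories[0].dt

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for tr in self.trajectories:
            frames = np.round((tr.t - tr.t[0]) / tr.dt).astype(int)
            rows.append(pd.DataFrame({
                "particle_id": tr.particle_id, "frame": frames,
                "t_s": tr.t, "x_um": tr.x, "y_um": tr.y,
            }))
        return pd.concat(rows, ignore_index=True)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")


@dataclass
class MSDCurve:
    """Time-averaged mean squared displacement on an ascending lag grid."""

    tau: np.ndarray          # lag times, s
    msd: np.ndarray          # um^2, 2D convention
    n_obs: np.ndarray        # displacement pairs (or curves) per lag
    dim: int = 2

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_obs = np.asarray(self.n_obs)
        if np.any(self.tau <= 0):
            raise ValueError("lag times must be positive")
        if np.any(np.diff(self.tau) <= 0):
            raise ValueError("lag times must be ascending")
        if np.any(self.msd < 0):
            raise ValueError("msd must be non-negative")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"tau_s": self.tau, "msd_um2": self.msd,
                             "n_obs": self.n_obs})

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")


def read_trajectories(path, metadata: dict | None = None,
                      split_gaps: bool = True) -> TrajectoryEnsemble:
    """Read a canonical trajectory CSV into a validated ensemble.

    Rows are sorted by (particle_id, frame).  Particles whose frame sequence has
    gaps are split at each gap into contiguous segments (suffixing the id), and
    segments with fewer than 2 samples are dropped with a warning.
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {missing}")
    if len(df) == 0:
        raise ValueError(f"trajectory file {path} is empty")
    if df[["t_s", "x_um", "y_um"]].isna().any().any():
        raise ValueError("NaN coordinates in trajectory file")
    df = df.sort_values(["particle_id", "frame"], kind="stable")

    trajectories: list[Trajectory] = []
    for pid, g in df.groupby("particle_id", sort=False):
        frames = g["frame"].to_numpy()
        t, x, y = (g[c].to_numpy(float) for c in ("t_s", "x_um", "y_um"))
        if split_gaps:
            breaks = np.nonzero(np.diff(frames) != 1)[0] + 1
            segments = np.split(np.arange(len(frames)), breaks)
        else:
            segments = [np.arange(len(frames))]
        for k, seg in enumerate(segments):
            seg_id = str(pid) if len(segments) == 1 else f"{pid}_seg{k}"
            if len(seg) < 2:
                logger.warning("dropping %s: fewer than 2 samples", seg_id)
                continue
            trajectories.append(Trajectory(seg_id, t[seg], x[seg], y[seg]))
    if not trajectories:
        raise ValueError(f"no usable trajectories in {path}")
    return TrajectoryEnsemble(trajectories, metadata=dict(metadata or {}))


def drift_correct(ensemble: TrajectoryEnsemble,
                  mode: Literal["none", "common_mode_median"] = "none",
                  ) -> TrajectoryEnsemble:
    """Remove common-mode drift: subtract the cumulative per-frame median
    displacement across particles.  Requires >= 5 particles; with mode
    ``none`` the input is returned unchanged."""
    if mode == "none":
        return ensemble
    if mode != "common_mode_median":
        raise ValueError(f"unknown drift mode {mode!r}")
    if len(ensemble) < 5:
        raise ValueError(
            "common_mode_median needs >= 5 particles; use mode='none'")
    t0 = min(tr.t[0] for tr in ensemble)
    dt = ensemble.dt
    n_max = max(int(round((tr.t[-1] - t0) / dt)) for tr in ensemble) + 1
    dx = np.full((len(ensemble), n_max - 1), np.nan)
    dy = np.full((len(ensemble), n_max - 1), np.nan)
    offsets = []
    for i, tr in enumerate(ensemble):
        off = int(round((tr.t[0] - t0) / dt))
        offsets.append(off)
        dx[i, off:off + tr.n_frames - 1] = np.diff(tr.x)
        dy[i, off:off + tr.n_frames - 1] = np.diff(tr.y)
    with np.errstate(all="ignore"):
        mdx = np.nan_to_num(np.nanmedian(dx, axis=0))
        mdy = np.nan_to_num(np.nanmedian(dy, axis=0))
    cum_x = np.concatenate([[0.0], np.cumsum(mdx)])
    cum_y = np.concatenate([[0.0], np.cumsum(mdy)])
    corrected = []
    for tr, off in zip(ensemble, offsets):
        sl = slice(off, off + tr.n_frames)
        corrected.append(Trajectory(tr.particle_id, tr.t,
                                    tr.x - cum_x[sl], tr.y - cum_y[sl]))
    return TrajectoryEnsemble(corrected, metadata=dict(ensemble.metadata),
                              truth=dict(ensemble.truth))


def compute_msd(traj: Trajectory, max_lag_fraction: float = 0.25,
                n_lags: int | None = None) -> MSDCurve:
    """Time-averaged MSD with overlapping windows.

    ``msd(k*dt) = mean_i |r(t_i + k*dt) - r(t_i)|^2`` over every available
    start index i.  Lags run to ``max_lag_fraction`` of the trajectory
    duration; ``n_lags`` optionally subsamples the integer lags to an
    approximately log-spaced subset (exact values at the retained lags).
    """
    if not (0 < max_lag_fraction <= 1):
        raise ValueError("max_lag_fraction must lie in (0, 1]")
    n = traj.n_frames
    kmax = max(1, int(np.floor((n - 1) * max_lag_fraction)))
    lags = np.arange(1, kmax + 1)
    if n_lags is not None and n_lags < len(lags):
        lags = np.unique(np.round(
            np.geomspace(1, kmax, n_lags)).astype(int))
    msd = np.empty(len(lags))
    n_obs = np.empty(len(lags), dtype=int)
    for j, k in enumerate(lags):
        ddx = traj.x[k:] - traj.x[:-k]
        ddy = traj.y[k:] - traj.y[:-k]
        msd[j] = np.mean(ddx * ddx + ddy * ddy)
        n_obs[j] = n - k
    return MSDCurve(tau=lags * traj.dt, msd=msd, n_obs=n_obs)


def ensemble_msd(curves: Sequence[MSDCurve],
                 aggregate: Literal["median", "mean"] = "median",
                 n_bins: int = 60) -> MSDCurve:
    """Aggregate per-particle MSD curves lag-by-lag.

    Curves sharing a frame interval are aggregated on the union of their
    integer-lag grids (lags present in only some curves aggregate over those,
    with the reduced count recorded).  Curves with differing intervals are
    first resampled onto a common geometric lag grid.
    """
    if len(curves) == 0:
        raise ValueError("no MSD curves to aggregate")
    if aggregate not in ("median", "mean"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    base_dt = np.min([np.min(np.diff(np.concatenate([[0.0], c.tau]))) for c in curves])
    shared_dt = all(
        np.allclose(np.round(c.tau / base_dt), c.tau / base_dt, rtol=0, atol=1e-6)
        for c in curves)

    if shared_dt:
        lag_sets = [np.round(c.tau / base_dt).astype(int) for c in curves]
        all_lags = np.unique(np.concatenate(lag_sets))
        vals = np.full((len(curves), len(all_lags)), np.nan)
        pos = {int(l): j for j, l in enumerate(all_lags)}
        for i, (c, ls) in enumerate(zip(curves, lag_sets)):
            for l, m in zip(ls, c.msd):
                vals[i, pos[int(l)]] = m
        counts = np.sum(~np.isnan(vals), axis=0)
        with np.errstate(all="ignore"):
            out = (np.nanmedian(vals, axis=0) if aggregate == "median"
                   else np.nanmean(vals, axis=0))
        keep = counts >= 1
        return MSDCurve(all_lags[keep] * base_dt, out[keep], counts[keep])

    # incompatible grids: geometric binning onto a shared log-spaced grid
    tmin = min(c.tau[0] for c in curves)
    tmax = max(c.tau[-1] for c in curves)
    edges = np.geomspace(tmin * 0.999, tmax * 1.001, n_bins + 1)
    centers = np.sqrt(edges[:-1] * edges[1:])
    vals = np.full((len(curves), n_bins), np.nan)
    for i, c in enumerate(curves):
        idx = np.digitize(c.tau, edges) - 1
        for b in range(n_bins):
            sel = idx == b
            if sel.any():
                vals[i, b] = np.mean(c.msd[sel])
    counts = np.sum(~np.isnan(vals), axis=0)
    with np.errstate(all="ignore"):
        out = (np.nanmedian(vals, axis=0) if aggregate == "median"
               else np.nanmean(vals, axis=0))
    keep = counts >= 1
    return MSDCurve(centers[keep], out[keep], counts[keep])
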