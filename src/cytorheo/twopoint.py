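"""Two-particle (two-point) microrheology.

Distance-dependent displacement cross-correlations between tracer pairs probe
the medium on scales large compared to the bead, so they report bulk rather
than local viscoelasticity.  For each co-observed pair and lag the
displacements are projected onto the unit separation vector (longitudinal) and
its normal (transverse), their products are averaged into (separation, lag)
bins, and the longitudinal correlation is fitted per lag to the far-field form
``D_par(r) = A(tau) / r``.  The distinct (two-point) MSD is then
``msd2p(tau) = 2 A(tau) / a`` with a the bead radius, and feeds the same GSER
machinery as the one-point MSD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE_K
from .rheology import ViscoelasticSpectrum, gser_spectrum
from .trajectories import MSDCurve, TrajectoryEnsemble


@dataclass
class PairCorrelation:
    """Binned pair displacement correlations.

    ``D_par[i, j]`` is the longitudinal cross-correlation in separation bin i
    at lag j (um^2); cells with fewer than the minimum pair count are masked
    (NaN), never zero-filled.
    """

    r_bins: np.ndarray       # nominal bin centers, um, ascending
    tau: np.ndarray          # lags, s
    D_par: np.ndarray        # (n_bins, n_lags), um^2, NaN where masked
    D_perp: np.ndarray
    n_pairs: np.ndarray      # pair-observations per cell
    r_mean: np.ndarray | None = None   # mean observed separation per cell

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.r_bins):
            for j, t in enumerate(self.tau):
                rows.append((r, t, self.D_par[i, j], self.D_perp[i, j],
                             self.n_pairs[i, j]))
        return pd.DataFrame(rows, columns=[
            "r_um", "tau_s", "D_par_um2", "D_perp_um2", "n_pairs"])


@dataclass
class TwoPointMSD:
    """Two-point MSD with per-lag 1/r-fit diagnostics."""

    tau: np.ndarray
    msd2p: np.ndarray               # um^2
    amplitude: np.ndarray           # fitted A(tau), um^3-free (um^2 * um)
    rel_residual: np.ndarray        # median relative residual of the 1/r fit
    flagged: np.ndarray             # lags where the 1/r model is rejected

    def valid(self) -> "MSDCurve":
        """The unflagged portion as an MSDCurve for GSER."""
        keep = ~self.flagged & (self.msd2p > 0)
        if keep.sum() < 3:
            raise ValueError("fewer than 3 consistent two-point lags")
        return MSDCurve(self.tau[keep], self.msd2p[keep],
                        np.ones(keep.sum(), dtype=int))


def pair_correlation(ensemble: TrajectoryEnsemble,
                     r_bins: np.ndarray | None = None,
                     lags: Sequence[int] | None = None,
                     min_pairs: int = 50,
                     r_range: tuple[float, float] | None = None,
                     n_bins: int = 12) -> PairCorrelation:
    """Crocker-style displacement cross-correlation versus separation and lag.

    Separations are taken at the start of each lag interval and binned on a
    log-spaced grid (default: bead diameter to 1/4 of the field extent).
    Trajectories must share the frame grid; self-pairs are excluded.
    """
    trajs = ensemble.trajectories
    if len(trajs) < 2:
        raise ValueError("pair correlation needs at least 2 particles")
    dt = ensemble.dt
    n_frames = min(tr.n_frames for tr in trajs)
    X = np.stack([tr.x[:n_frames] for tr in trajs])
    Y = np.stack([tr.y[:n_frames] for tr in trajs])

    if lags is None:
        kmax = max(1, n_frames // 4)
        lags = np.unique(np.round(np.geomspace(1, kmax, 15)).astype(int))
    lags = np.asarray(lags, dtype=int)

    if r_bins is None:
        if r_range is None:
            d = ensemble.metadata.get("bead_diameter_um", 2.0)
            extent = max(np.ptp(X), np.ptp(Y))
            r_range = (d, max(extent / 4, 2 * d))
        r_edges = np.geomspace(r_range[0], r_range[1], n_bins + 1)
    else:
        r_edges = np.asarray(r_bins, dtype=float)
        n_bins = len(r_edges) - 1
    r_centers = np.sqrt(r_edges[:-1] * r_edges[1:])

    sum_par = np.zeros((n_bins, len(lags)))
    sum_perp = np.zeros((n_bins, len(lags)))
    sum_r = np.zeros((n_bins, len(lags)))
    counts = np.zeros((n_bins, len(lags)), dtype=np.int64)

    n = len(trajs)
    for i in range(n):
        for j in range(i + 1, n):
            sx = X[j] - X[i]
            sy = Y[j] - Y[i]
            r_all = np.hypot(sx, sy)
            if r_all.min() > r_edges[-1]:
                continue                       # pair never inside the window
            for li, k in enumerate(lags):
                if k >= n_frames:
                    continue
                r = r_all[:n_frames - k]
                inside = (r >= r_edges[0]) & (r <= r_edges[-1])
                if not inside.any():
                    continue
                ux = sx[:n_frames - k][inside] / r[inside]
                uy = sy[:n_frames - k][inside] / r[inside]
                dxi = (X[i, k:] - X[i, :-k])[inside]
                dyi = (Y[i, k:] - Y[i, :-k])[inside]
                dxj = (X[j, k:] - X[j, :-k])[inside]
                dyj = (Y[j, k:] - Y[j, :-k])[inside]
                par = (dxi * ux + dyi * uy) * (dxj * ux + dyj * uy)
                perp = (-dxi * uy + dyi * ux) * (-dxj * uy + dyj * ux)
                b = np.clip(np.digitize(r[inside], r_edges) - 1, 0, n_bins - 1)
                sum_par[:, li] += np.bincount(b, weights=par, minlength=n_bins)
                sum_perp[:, li] += np.bincount(b, weights=perp, minlength=n_bins)
                sum_r[:, li] += np.bincount(b, weights=r[inside], minlength=n_bins)
                counts[:, li] += np.bincount(b, minlength=n_bins)

    if counts.sum() == 0:
        raise ValueError("no pair observations inside the separation window")
    with np.errstate(invalid="ignore"):
        d_par = np.where(counts >= min_pairs, sum_par / np.maximum(counts, 1),
                         np.nan)
        d_perp = np.where(counts >= min_pairs, sum_perp / np.maximum(counts, 1),
                          np.nan)
        r_mean = np.where(counts > 0, sum_r / np.maximum(counts, 1), np.nan)
    return PairCorrelation(r_centers, lags * dt, d_par, d_perp, counts, r_mean)


def two_point_msd(corr: PairCorrelation, bead_diameter: float,
                  r_window: tuple[float, float] | None = None,
                  resid_threshold: float = 0.2) -> TwoPointMSD:
    """Fit ``D_par(r) = A(tau)/r`` per lag and extrapolate to the two-point MSD.

    The fit is weighted least squares with the per-cell pair counts as
    weights.  Lags whose median relative residual exceeds the threshold (the
    1/r model is violated, e.g. rigid common motion) are flagged; so are lags
    with fewer than two usable bins.
    """
    a = bead_diameter / 2
    if r_window is None:
        r_window = (corr.r_bins[0], corr.r_bins[-1])
    in_win = (corr.r_bins >= r_window[0]) & (corr.r_bins <= r_window[1])
    if not in_win.any():
        raise ValueError("no separation bins inside the fit window")
    n_lags = len(corr.tau)
    amp = np.full(n_lags, np.nan)
    resid = np.full(n_lags, np.nan)
    flagged = np.zeros(n_lags, dtype=bool)
    for j in range(n_lags):
        d = corr.D_par[in_win, j]
        w = corr.n_pairs[in_win, j].astype(float)
        # mean observed separation per cell avoids log-bin abscissa bias
        if corr.r_mean is not None:
            r = np.where(np.isfinite(corr.r_mean[in_win, j]),
                         corr.r_mean[in_win, j], corr.r_bins[in_win])
        else:
            r = corr.r_bins[in_win]
        ok = np.isfinite(d) & (w > 0)
        if ok.sum() < 2:
            flagged[j] = True
            continue
        d, w, r = d[ok], w[ok], r[ok]
        A = np.sum(w * d / r) / np.sum(w / r ** 2)
        amp[j] = A
        pred = A / r
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(d - pred) / np.abs(pred)
        resid[j] = float(np.median(rel))
        if not np.isfinite(resid[j]) or resid[j] > resid_threshold or A <= 0:
            flagged[j] = True
    msd2p = 2 * amp / a
    return TwoPointMSD(corr.tau, msd2p, amp, resid, flagged)


def two_point_spectrum(msd2p: TwoPointMSD, bead_diameter: float,
                       temperature: float = DEFAULT_TEMPERATURE_K,
                       **gser_kwargs) -> ViscoelasticSpectrum:
    """GSER spectrum of the two-point MSD (unflagged lags only)."""
    return gser_spectrum(msd2p.valid(), bead_diameter, temperature,
                         **gser_kwargs)
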