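"""Seeded generators for every input class the analysis pipeline consumes.

Each generator is a pure function of its spec and seed, and returns ground
truth alongside the data, so every downstream estimator has a
parameter-recovery test without any external data:

* Brownian / Kelvin-Voigt / power-law bead trajectories (1P microrheology),
* 1/r-coupled bead pairs (two-point microrheology),
* discrete 2D worm-like chains (persistence length),
* exponential filament-length ensembles,
* rendered bundle line images and aster fields (morphometry).

Media are parameterized by :class:`MediumModel`; the Kelvin-Voigt bead obeys
the overdamped harmonic Langevin equation with stiffness ``kappa = 6 pi a G0``
and drag ``gamma = 6 pi a eta`` (integrated with the exact
Ornstein-Uhlenbeck update over dt, so there is no step-size bias), and the
power-law bead is fractional Brownian motion synthesized by Davies-Harte
circulant embedding (exact increment covariance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.signal import lfilter
from scipy.special import gamma as gamma_fn

from .constants import DEFAULT_TEMPERATURE_K, thermal_energy
from .trajectories import Trajectory, TrajectoryEnsemble


# --------------------------------------------------------------------------
# medium models
# --------------------------------------------------------------------------

@dataclass
class MediumModel:
    """Parametric viscoelastic medium.

    kinds:
      * ``viscous``: G*(w) = i w eta
      * ``kelvin_voigt``: G*(w) = G0 + i w eta (elastic plateau G0)
      * ``power_law``: |G*(w)| = A w^alpha with loss angle pi*alpha/2
    """

    kind: Literal["viscous", "kelvin_voigt", "power_law"]
    G0: float = 0.0          # Pa
    eta: float = 0.0         # Pa s
    A: float = 0.0           # Pa s^alpha
    alpha: float = 1.0       # dimensionless

    def __post_init__(self) -> None:
        if self.kind in ("viscous", "kelvin_voigt") and self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.kind == "kelvin_voigt" and self.G0 < 0:
            raise ValueError("G0 must be non-negative")
        if self.kind == "power_law":
            if self.A <= 0:
                raise ValueError("power-law prefactor A must be positive")
            if not (0 < self.alpha <= 1):
                raise ValueError("alpha must lie in (0, 1]")

    def msd_2d(self, tau: np.ndarray, bead_radius_um: float,
               temperature_k: float) -> np.ndarray:
        """Closed-form ensemble 2D MSD (um^2) of an embedded bead."""
        tau = np.asarray(tau, dtype=float)
        kt = thermal_energy(temperature_k)
        a = bead_radius_um
        if self.kind == "viscous":
            d = kt / (6 * np.pi * self.eta * a)
            return 4 * d * tau
        if self.kind == "kelvin_voigt":
            if self.G0 == 0:
                d = kt / (6 * np.pi * self.eta * a)
                return 4 * d * tau
            kappa = 6 * np.pi * a * self.G0
            theta = self.G0 / self.eta
            return 4 * (kt / kappa) * (1 - np.exp(-theta * tau))
        # power law: |G*| = A w^alpha  <=>  msd_2d = C tau^alpha
        c = 2 * kt / (3 * np.pi * a * self.A * gamma_fn(1 + self.alpha))
        return c * tau ** self.alpha


@dataclass
class SyntheticSpec:
    """Acquisition + medium parameters for a simulated tracking experiment."""

    n_particles: int
    n_frames: int
    dt: float                             # s
    medium: MediumModel
    bead_diameter: float = 2.0            # um
    temperature: float = DEFAULT_TEMPERATURE_K
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.bead_diameter <= 0:
            raise ValueError("bead_diameter must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def bead_radius(self) -> float:
        return self.bead_diameter / 2


# --------------------------------------------------------------------------
# bead motion
# --------------------------------------------------------------------------

def _fgn(rng: np.random.Generator, n_series: int, n_steps: int,
         hurst2: float, scale2: float, dt: float) -> np.ndarray:
    """Fractional Gaussian noise by Davies-Harte circulant embedding.

    Returns increments with Var[sum of k increments] = scale2 * (k*dt)^hurst2,
    i.e. fBm with variance scale2 * t^(2H), 2H = hurst2.
    """
    k = np.arange(n_steps + 1, dtype=float)
    # increment autocovariance gamma(j), j = 0..n
    g = 0.5 * scale2 * dt ** hurst2 * (
        np.abs(k + 1) ** hurst2 - 2 * np.abs(k) ** hurst2
        + np.abs(k - 1) ** hurst2)
    # circulant first row of size 2n
    row = np.concatenate([g[:-1], g[-1:], g[-2:0:-1]])
    lam = np.fft.fft(row).real
    lam = np.where(lam < 0, 0.0, lam)  # clip tiny negative eigenvalues
    m = len(row)
    z = rng.standard_normal((n_series, m)) + 1j * rng.standard_normal((n_series, m))
    w = np.fft.fft(z * np.sqrt(lam / m), axis=1)
    return w[:, :n_steps].real


def simulate_bead(spec: SyntheticSpec) -> TrajectoryEnsemble:
    """Simulate independent tracer beads in the spec's medium.

    Increments are statistically stationary; the ground-truth medium is kept in
    ``ensemble.truth['medium']`` for recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    kt = thermal_energy(spec.temperature)
    a = spec.bead_radius
    n, m = spec.n_particles, spec.n_frames
    med = spec.medium

    if med.kind == "viscous" or (med.kind == "kelvin_voigt" and med.G0 == 0):
        d = kt / (6 * np.pi * med.eta * a)
        steps = rng.normal(0.0, np.sqrt(2 * d * spec.dt), size=(2, n, m - 1))
        pos = np.concatenate([np.zeros((2, n, 1)), np.cumsum(steps, axis=2)], axis=2)
    elif med.kind == "kelvin_voigt":
        kappa = 6 * np.pi * a * med.G0
        theta = med.G0 / med.eta
        var = kt / kappa                       # stationary per-axis variance
        phi = np.exp(-theta * spec.dt)
        innov = rng.normal(0.0, np.sqrt(var * (1 - phi * phi)), size=(2, n, m))
        innov[:, :, 0] = rng.normal(0.0, np.sqrt(var), size=(2, n))  # stationary start
        pos = lfilter([1.0], [1.0, -phi], innov, axis=2)
    else:  # power_law
        c2d = med.msd_2d(np.array([1.0]), a, spec.temperature)[0]
        steps = _fgn(rng, 2 * n, m - 1, med.alpha, c2d / 2, spec.dt)
        steps = steps.reshape(2, n, m - 1)
        pos = np.concatenate([np.zeros((2, n, 1)), np.cumsum(steps, axis=2)], axis=2)

    t = np.arange(m) * spec.dt
    trajectories = [
        Trajectory(f"p{i}", t, pos[0, i], pos[1, i]) for i in range(n)]
    meta = {"bead_diameter_um": spec.bead_diameter,
            "temperature_k": spec.temperature, "fps": 1 / spec.dt}
    return TrajectoryEnsemble(trajectories, metadata=meta,
                              truth={"medium": med, "spec": spec})


def simulate_bead_pairs(spec: SyntheticSpec, separations: Sequence[float],
                        coupling_amplitude: float,
                        coupling_exponent: float = 1.0,
                        rigid: bool = False,
                        pair_spacing: float | None = None,
                        ) -> TrajectoryEnsemble:
    """Simulate correlated bead pairs for the two-point estimator.

    Each pair shares a common displacement along its separation axis (x).  The
    common motion has per-axis MSD ``coupling_amplitude * tau^coupling_exponent``
    (um^2, exponent 1 = Brownian via cumulative Gaussian steps, otherwise fGn)
    and is scaled by ``1/sqrt(r)`` per pair, so the true longitudinal
    cross-correlation is ``D_rr(r, tau) = coupling_amplitude * tau^q / r``.
    With ``rigid=True`` the common motion is applied unscaled (no 1/r decay),
    the fixture for a rigid-motion consistency check.  Independent per-bead
    noise comes from the spec's medium.  Pairs are stacked far apart in y so
    cross-pair separations exceed any sensible analysis window.
    """
    separations = np.asarray(separations, dtype=float)
    if np.any(separations <= 0):
        raise ValueError("separations must be positive")
    if coupling_amplitude < 0:
        raise ValueError("coupling_amplitude must be non-negative")
    rng = np.random.default_rng(spec.seed)
    m = spec.n_frames
    n_pairs = len(separations)
    if pair_spacing is None:
        pair_spacing = 10 * float(np.max(separations))

    base = simulate_bead(SyntheticSpec(
        n_particles=2 * n_pairs, n_frames=m, dt=spec.dt, medium=spec.medium,
        bead_diameter=spec.bead_diameter, temperature=spec.temperature,
        seed=spec.seed + 1))

    if coupling_amplitude > 0:
        if coupling_exponent == 1.0:
            steps = rng.normal(0.0, np.sqrt(coupling_amplitude * spec.dt),
                               size=(n_pairs, m - 1))
        else:
            steps = _fgn(rng, n_pairs, m - 1, coupling_exponent,
                         coupling_amplitude, spec.dt)
        common = np.concatenate(
            [np.zeros((n_pairs, 1)), np.cumsum(steps, axis=1)], axis=1)
    else:
        common = np.zeros((n_pairs, m))

    t = np.arange(m) * spec.dt
    trajectories = []
    for j, r in enumerate(separations):
        scale = 1.0 if rigid else 1.0 / np.sqrt(r)
        cx = common[j] * scale
        y0 = j * pair_spacing
        for side, x0 in enumerate((0.0, r)):
            b = base.trajectories[2 * j + side]
            trajectories.append(Trajectory(
                f"pair{j}_{'ab'[side]}", t, x0 + b.x + cx, y0 + b.y))
    meta = {"bead_diameter_um": spec.bead_diameter,
            "temperature_k": spec.temperature, "fps": 1 / spec.dt}
    truth = {"coupling_amplitude": coupling_amplitude,
             "coupling_exponent": coupling_exponent, "rigid": rigid,
             "separations": separations, "medium": spec.medium,
             "D_rr": (lambda r, tau:
                      coupling_amplitude * np.asarray(tau) ** coupling_exponent
                      / (1.0 if rigid else r))}
    return TrajectoryEnsemble(trajectories, metadata=meta, truth=truth)


# --------------------------------------------------------------------------
# worm-like chains and filament lengths
# --------------------------------------------------------------------------

@dataclass
class WLCSpec:
    """Discrete 2D worm-like chain ensemble parameters (um)."""

    l_P: float              # persistence length, um
    L: float                # contour length, um
    ds: float = 0.1         # discretization step, um
    n_chains: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ds <= 0 or self.L < self.ds:
            raise ValueError("need 0 < ds <= L")
        if self.ds >= self.l_P:
            raise ValueError("discretization invalid: ds must be << l_P")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")


def simulate_wlc_2d(spec: WLCSpec) -> list[np.ndarray]:
    """Sample 2D worm-like chains as (n_points, 2) coordinate arrays.

    Successive turning angles are i.i.d. N(0, ds/l_P), which yields the 2D
    tangent correlation <cos theta(s)> = exp(-s / (2 l_P)).
    """
    rng = np.random.default_rng(spec.seed)
    n_seg = int(round(spec.L / spec.ds))
    chains = []
    for _ in range(spec.n_chains):
        turns = rng.normal(0.0, np.sqrt(spec.ds / spec.l_P), size=n_seg - 1)
        theta = np.concatenate([[rng.uniform(0, 2 * np.pi)],
                                np.cumsum(turns)])
        theta[1:] += theta[0]
        steps = spec.ds * np.column_stack([np.cos(theta), np.sin(theta)])
        pts = np.concatenate([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
        chains.append(pts)
    return chains


def sample_lengths(mean_length: float, n: int, seed: int = 0) -> np.ndarray:
    """I.i.d. exponential filament lengths (um), the roughly-exponential
    length ensembles seen for in vitro polymerized actin."""
    if mean_length <= 0:
        raise ValueError("mean_length must be positive")
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    return rng.exponential(mean_length, size=n)


# --------------------------------------------------------------------------
# rendered images
# --------------------------------------------------------------------------

@dataclass
class ImageTruth:
    """Ground truth recorded beside a rendered image."""

    pixel_size: float                      # um / px
    background: float = 0.0                # a.u.
    i_single: float = 0.0                  # single-filament peak amplitude
    multiplicities: np.ndarray | None = None
    line_positions_um: np.ndarray | None = None
    centers_um: np.ndarray | None = None   # (n, 2) aster centers (x, y)
    radii_um: np.ndarray | None = None
    total_area_um2: float = 0.0
    depletion_factor: float = 1.0
    noise: dict = field(default_factory=dict)


def render_bundle_image(multiplicities: Sequence[int], i_single: float = 1.0,
                        shape: tuple[int, int] = (256, 256),
                        pixel_size: float = 0.1, psf_sigma: float = 0.2,
                        background: float = 10.0, poisson_noise: bool = False,
                        seed: int = 0) -> tuple[np.ndarray, ImageTruth]:
    """Render parallel vertical bundle lines with Gaussian cross-sections.

    Each line's peak amplitude above background is ``multiplicity * i_single``
    (intensity linear in filament number).  Lines are spread evenly across the
    width; an error is raised if that spacing is closer than 3 psf widths
    (ambiguous, unresolvable peaks).
    """
    mult = np.asarray(multiplicities, dtype=float)
    if i_single <= 0:
        raise ValueError("i_single must be positive")
    ny, nx = shape
    width_um = nx * pixel_size
    n_lines = len(mult)
    positions = (np.arange(n_lines) + 0.5) / n_lines * width_um if n_lines else np.array([])
    # snap to pixel centers so each peak height is exactly m * i_single
    positions = (np.round(positions / pixel_size - 0.5) + 0.5) * pixel_size
    if n_lines >= 2:
        spacing = positions[1] - positions[0]
        if spacing < 3 * psf_sigma:
            raise ValueError("lines closer than 3 psf widths: peaks ambiguous")
    x = (np.arange(nx) + 0.5) * pixel_size
    profile = np.full(nx, float(background))
    for m, x0 in zip(mult, positions):
        profile += m * i_single * np.exp(-0.5 * ((x - x0) / psf_sigma) ** 2)
    img = np.tile(profile, (ny, 1))
    if poisson_noise:
        rng = np.random.default_rng(seed)
        img = rng.poisson(img).astype(float)
    truth = ImageTruth(pixel_size=pixel_size, background=background,
                       i_single=i_single, multiplicities=mult,
                       line_positions_um=positions,
                       noise={"poisson": poisson_noise, "seed": seed})
    return img, truth


def render_aster_image(n_asters: int, radius_um: float | tuple[float, float] = 1.0,
                       field_size_um: float = 51.2, pixel_size: float = 0.1,
                       background: float = 100.0, amplitude: float = 500.0,
                       depletion_factor: float = 1.0,
                       min_spacing_factor: float = 2.2,
                       noise_sigma: float = 0.0, seed: int = 0,
                       max_tries: int = 10_000) -> tuple[np.ndarray, ImageTruth]:
    """Render sparse bright aster disks on a (possibly depleted) background.

    Disk radii are fixed (scalar) or uniform in a (lo, hi) range.  Centers are
    rejection-sampled with minimum center spacing
    ``min_spacing_factor * (r_i + r_j)`` so disks and their depletion annuli
    (inner radius r, outer 2r, dimmed to ``depletion_factor * background``)
    never overlap.  Raises if the requested asters cannot be placed.
    """
    npx = int(round(field_size_um / pixel_size))
    rng = np.random.default_rng(seed)
    centers: list[np.ndarray] = []
    radii: list[float] = []
    tries = 0
    while len(centers) < n_asters:
        if tries >= max_tries:
            raise ValueError(
                f"could not place {n_asters} non-overlapping asters")
        tries += 1
        r = (float(radius_um) if np.isscalar(radius_um)
             else rng.uniform(*radius_um))
        c = rng.uniform(2.5 * r, field_size_um - 2.5 * r, size=2)
        ok = all(np.linalg.norm(c - cj) >= min_spacing_factor * (r + rj)
                 for cj, rj in zip(centers, radii))
        if ok:
            centers.append(c)
            radii.append(r)
    centers_arr = np.array(centers).reshape(-1, 2)
    radii_arr = np.array(radii)

    yy, xx = np.meshgrid((np.arange(npx) + 0.5) * pixel_size,
                         (np.arange(npx) + 0.5) * pixel_size, indexing="ij")
    img = np.full((npx, npx), float(background))
    for (cx, cy), r in zip(centers_arr, radii_arr):
        dist = np.hypot(xx - cx, yy - cy)
        img[(dist > r) & (dist <= 2 * r)] = background * depletion_factor
        img[dist <= r] = amplitude
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
        img = np.clip(img, 0.0, None)
    truth = ImageTruth(pixel_size=pixel_size, background=background,
                       centers_um=centers_arr, radii_um=radii_arr,
                       total_area_um2=float(np.sum(np.pi * radii_arr ** 2)),
                       depletion_factor=depletion_factor,
                       noise={"gaussian_sigma": noise_sigma, "seed": seed})
    return img, truth
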