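"""Viscoelastic spectra from MSDs, plateau moduli and tube-model anchors.

The MSD-to-modulus conversion is the local power-law (Mason) approximation of
the generalized Stokes-Einstein relation: at each lag the logarithmic slope
``alpha(tau) = d ln msd / d ln tau`` is estimated from a local quadratic fit,
and

    |G*(omega)| = 2 kB T / (3 pi a msd_2d(1/omega) Gamma(1 + alpha)),
    G' = |G*| cos(pi alpha / 2),   G'' = |G*| sin(pi alpha / 2),

with a the bead radius.  The ``2/(3 pi a)`` prefactor is the standard 3D GSER
``kB T / (pi a msd_3d Gamma)`` applied to a 2D-measured MSD scaled by 3/2; it
is exposed via ``msd_dim_scale`` because it rescales all moduli by a constant.

Theory anchors for entangled F-actin: the geometric mesh size
``xi = sqrt(3 / rho)`` (rho = filament length per volume at full
polymerization) and the tube-model plateau
``G0 = kB T / (xi^2 l_e)`` with entanglement length
``l_e = xi^(4/5) l_P^(1/5)``, which gives G0 proportional to c^(7/5) and to
l_P^(-1/5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gamma as gamma_fn

from .constants import (ACTIN_SUBUNITS_PER_UM, AVOGADRO,
                        DEFAULT_TEMPERATURE_K, thermal_energy)
from .trajectories import MSDCurve


@dataclass
class ViscoelasticSpectrum:
    """G'(omega), G''(omega) on an ascending angular-frequency grid (rad/s)."""

    omega: np.ndarray
    G_storage: np.ndarray    # Pa
    G_loss: np.ndarray       # Pa
    alpha_local: np.ndarray  # local log-log MSD slope at tau = 1/omega

    def __post_init__(self) -> None:
        for name in ("omega", "G_storage", "G_loss", "alpha_local"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.omega <= 0) or np.any(np.diff(self.omega) <= 0):
            raise ValueError("omega must be positive ascending")
        if np.any(self.G_loss < -1e-12):
            raise ValueError("G_loss must be non-negative")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "omega_rad_s": self.omega, "G_prime_Pa": self.G_storage,
            "G_dblprime_Pa": self.G_loss, "alpha_local": self.alpha_local})

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.9g")


@dataclass
class PlateauModulus:
    G0: float                # Pa
    omega_eval: float        # rad/s
    source: Literal["one_particle", "two_particle"] = "one_particle"


@dataclass
class NetworkTheory:
    """Tube-model quantities for an entangled semiflexible network."""

    c: float                 # actin concentration, uM
    l_P: float               # um
    xi: float                # mesh size, um
    l_e: float               # entanglement length, um
    G0_theory: float         # Pa
    subunits_per_micron: float = ACTIN_SUBUNITS_PER_UM


def gser_spectrum(msd: MSDCurve, bead_diameter: float,
                  temperature: float = DEFAULT_TEMPERATURE_K,
                  half_window: int = 3,
                  msd_dim_scale: float = 1.5) -> ViscoelasticSpectrum:
    """Convert a 2D MSD curve to G'(omega), G''(omega) by the local
    power-law GSER.

    The local slope is a quadratic fit of ln msd vs ln tau over a +/-
    ``half_window``-point window, clamped to [0, 1]; the two endpoint lags
    (where the window is one-sided) are dropped.
    """
    if bead_diameter <= 0:
        raise ValueError("bead_diameter must be positive")
    if np.any(msd.msd <= 0):
        raise ValueError("msd must be strictly positive for GSER")
    if len(msd.tau) < 3:
        raise ValueError("need at least 3 lags for a local slope")
    kt = thermal_energy(temperature)
    a = bead_diameter / 2
    lt = np.log(msd.tau)
    lm = np.log(msd.msd)
    n = len(lt)
    idx = np.arange(1, n - 1)           # drop unreliable endpoints
    alpha = np.empty(len(idx))
    smoothed = np.empty(len(idx))
    for j, i in enumerate(idx):
        lo, hi = max(0, i - half_window), min(n, i + half_window + 1)
        u = lt[lo:hi] - lt[i]
        v = lm[lo:hi]
        deg = 2 if len(u) >= 3 else 1
        coeffs = np.polyfit(u, v, deg)
        alpha[j] = coeffs[-2]           # d ln msd / d ln tau at u = 0
        smoothed[j] = coeffs[-1]
    alpha = np.clip(alpha, 0.0, 1.0)
    m_val = np.exp(smoothed)
    gmag = 2 * kt / (3 * np.pi * a * m_val * gamma_fn(1 + alpha)
                     ) * (msd_dim_scale / 1.5)
    g1 = gmag * np.cos(np.pi * alpha / 2)
    g2 = gmag * np.sin(np.pi * alpha / 2)
    omega = 1.0 / msd.tau[idx]
    order = np.argsort(omega)
    return ViscoelasticSpectrum(omega[order], g1[order], g2[order],
                                alpha[order])


def plateau_modulus(spec: ViscoelasticSpectrum, omega_eval: float = 0.1,
                    source: Literal["one_particle", "two_particle"]
                    = "one_particle") -> PlateauModulus:
    """G0 = G'(omega_eval) by log-log interpolation (no extrapolation).

    The default evaluation frequency is 0.1 rad/s, the fixed low-frequency
    readout at which the storage modulus is interpreted as the entanglement
    plateau.
    """
    if not (spec.omega[0] <= omega_eval <= spec.omega[-1]):
        raise ValueError(
            f"omega_eval={omega_eval} outside spectrum range "
            f"[{spec.omega[0]:.3g}, {spec.omega[-1]:.3g}] rad/s")
    if np.any(spec.G_storage <= 0):
        # log-log interpolation needs positive G'; fall back to linear
        g0 = float(np.interp(omega_eval, spec.omega, spec.G_storage))
    else:
        g0 = float(np.exp(np.interp(np.log(omega_eval), np.log(spec.omega),
                                    np.log(spec.G_storage))))
    return PlateauModulus(G0=g0, omega_eval=omega_eval, source=source)


def relative_moduli(G0_values: Sequence[float],
                    G0_reference: float) -> np.ndarray:
    """Relative plateau moduli G_R = G_0,i / G_0,ref."""
    if G0_reference <= 0:
        raise ValueError("reference modulus must be positive")
    return np.asarray(G0_values, dtype=float) / G0_reference


def filament_length_density(c_uM: float,
                            subunits_per_micron: float = ACTIN_SUBUNITS_PER_UM,
                            ) -> float:
    """Filament contour length per volume, um / um^3, at full polymerization."""
    if c_uM <= 0:
        raise ValueError("concentration must be positive")
    monomers_per_um3 = c_uM * 1e-6 * AVOGADRO / 1e15
    return monomers_per_um3 / subunits_per_micron


def mesh_size(c_uM: float,
              subunits_per_micron: float = ACTIN_SUBUNITS_PER_UM) -> float:
    """Geometric mesh size xi = sqrt(3 / rho) in um; xi ~ c^(-1/2)."""
    rho = filament_length_density(c_uM, subunits_per_micron)
    return float(np.sqrt(3.0 / rho))


def tube_model_G0(c_uM: float, l_P: float,
                  temperature: float = DEFAULT_TEMPERATURE_K,
                  prefactor: float = 1.0,
                  subunits_per_micron: float = ACTIN_SUBUNITS_PER_UM,
                  ) -> NetworkTheory:
    """Tube-model plateau modulus of an entangled semiflexible network.

    ``l_e = xi^(4/5) l_P^(1/5)`` and ``G0 = prefactor * kB T / (xi^2 l_e)``;
    the prefactor is an order-unity model ambiguity, default 1.
    """
    if l_P <= 0:
        raise ValueError("persistence length must be positive")
    if prefactor <= 0:
        raise ValueError("prefactor must be positive")
    xi = mesh_size(c_uM, subunits_per_micron)
    l_e = xi ** 0.8 * l_P ** 0.2
    g0 = prefactor * thermal_energy(temperature) / (xi ** 2 * l_e)
    return NetworkTheory(c=c_uM, l_P=l_P, xi=xi, l_e=l_e, G0_theory=g0,
                         subunits_per_micron=subunits_per_micron)


def powerlaw_fit(x: Sequence[float], y: Sequence[float]
                 ) -> tuple[float, float, float]:
    """Least-squares power-law exponent: slope of ln y on ln x.

    Returns (exponent, stderr, intercept) where intercept is ln of the
    prefactor.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points for a power-law fit")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires positive values")
    res = stats.linregress(np.log(x), np.log(y))
    return float(res.slope), float(res.stderr), float(res.intercept)
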