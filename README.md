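# cytorheo

Passive microrheology and network morphometry for reconstituted cytoskeletal
(actin) networks, written for biophysicists analyzing video-particle-tracking
and confocal-imaging experiments on entangled or bundled filament networks.

## What it computes

**One-particle microrheology.** From tracked bead trajectories the package
computes time-averaged mean squared displacements (2D convention,
overlapping windows) and converts them to the complex shear modulus by the
local power-law form of the generalized Stokes–Einstein relation (GSER):

```
alpha(tau) = d ln<Δr²>/d ln tau
|G*(ω)| = 2 kBT / (3π a <Δr²(1/ω)> Γ(1+α)),   G' = |G*| cos(πα/2),  G'' = |G*| sin(πα/2)
```

with `a` the bead radius. The entanglement plateau modulus `G0` is read as
`G'(ω)` at a fixed low frequency (default ω = 0.1 rad/s).

**Two-particle microrheology.** Displacement cross-correlations of bead
pairs, projected on the separation vector and binned in (separation, lag),
are fitted per lag to the far-field form `D_∥(r) = A(τ)/r`; the distinct MSD
`2A(τ)/a` probes bulk rather than local response and feeds the same GSER
machinery. Lags violating the 1/r form (e.g. common-mode drift) are flagged.

**Filaments.** Skeletonized filament images are traced into contours;
persistence length comes from the tangent cosine correlation with the 2D
convention `<cos θ(s)> = exp(−s/2l_P)`, and length ensembles are summarized
by the mass-weighted mean `L_w = ΣL²/ΣL`.

**Network images.** Bundle parameter `n_B` (filaments per bundle) from
baseline-corrected line profiles divided by the single-filament intensity; an
independent mesh-based estimate `n_B = (ξ_obs/ξ_theory)²`; aster
(actomyosin contraction focus) segmentation with size, area-fraction,
nearest-neighbor and depletion statistics.

**Theory anchors.** Mesh size `ξ = sqrt(3/ρ)` (ρ = filament length per
volume; 370 subunits/µm), entanglement length `l_e = ξ^{4/5} l_P^{1/5}` and
the tube-model plateau `G0 = kBT/(ξ² l_e)`, which scales as `c^{7/5}` and
`l_P^{−1/5}`.

**Statistics.** Wilcoxon rank-sum (exact for small tie-free samples),
significance stars, boxplot summaries, and a bundling-onset readout across
cation concentrations.

A seeded synthetic-data module generates every input class with stored ground
truth — Brownian / Kelvin–Voigt / power-law bead trajectories, 1/r-coupled
bead pairs, 2D worm-like chains, exponential length ensembles, and rendered
bundle/aster images — so every estimator has a parameter-recovery test with
no external data.

## Worked example

```python
import numpy as np
from cytorheo import (MediumModel, SyntheticSpec, simulate_bead, compute_msd,
                      ensemble_msd, gser_spectrum, plateau_modulus,
                      mesh_size, tube_model_G0)

# beads of 2 um diameter in a soft elastic network (G0 = 39 mPa), 138 fps
medium = MediumModel("kelvin_voigt", G0=0.039, eta=0.0078)
spec = SyntheticSpec(n_particles=50, n_frames=10_000, dt=1/138,
                     medium=medium, bead_diameter=2.0, seed=1)
ens = simulate_bead(spec)
msd = ensemble_msd([compute_msd(tr, n_lags=150) for tr in ens])
spectrum = gser_spectrum(msd, bead_diameter=2.0, temperature=294.0)
g0 = plateau_modulus(spectrum, omega_eval=0.1)
print(f"G0 = {g0.G0:.4f} Pa")                   # G0 = 0.0396 Pa
print(f"xi(12 uM) = {mesh_size(12.0)*1e3:.0f} nm")   # xi(12 uM) = 392 nm
print(f"tube-model G0 = {tube_model_G0(12.0, 16.0).G0_theory:.3f} Pa")
#                                                tube-model G0 = 0.032 Pa
```

The recovered plateau (0.0396 Pa) matches the simulated ground truth within
two percent; the theoretical mesh size and the tube-model plateau land at the
textbook values for a 12 µM entangled F-actin solution with a 16 µm
persistence length.

The same pipeline is available from a shell:

```bash
cytorheo simulate --kind bead --seed 1 --out traj.csv
cytorheo msd traj.csv --out msd.csv
cytorheo gser msd.csv --out spectrum.csv            # prints G0
cytorheo theory --concentration 12                  # mesh size & tube model
```

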