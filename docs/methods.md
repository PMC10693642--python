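# Methods

This note documents the models, estimators, numerical choices and
limitations behind `cytorheo`. Units are micrometres, seconds and pascals
throughout; thermal energy is carried as `kBT` in Pa·µm³, with a default
temperature of 294 K (room temperature; every function takes `temperature`
explicitly).

## One-particle microrheology

### MSD estimation

`compute_msd` is the time-averaged estimator with overlapping windows,
`msd(kΔt) = mean_i |r(t_i+kΔt) − r(t_i)|²`, in the 2D convention
(Δx² + Δy²). Overlapping windows maximize data use; the correlation between
overlapping pairs is accounted for wherever we quote sampling errors (the
effective number of independent pairs at lag k is roughly n/k). Lags are
truncated by default at 1/4 of the trajectory duration because long-lag
estimates rest on few, strongly correlated pairs and would corrupt the
low-frequency plateau readout. For long recordings an optional `n_lags`
keeps only a log-spaced subset of integer lags (the values at retained lags
are exact).

Trajectories with frame gaps are split into contiguous segments rather than
interpolated: interpolation manufactures sub-frame displacements and biases
the short-lag MSD downward. Ensemble aggregation is the per-lag **median**
across particles by default (robust to the occasional bead stuck to the
coverslip or trapped in an atypical pore); the mean is available where a
mean-based summary is wanted. Curves sharing a frame interval aggregate on
the union of their integer-lag grids, recording the per-lag curve count;
heterogeneous frame rates are first rebinned onto a geometric lag grid.

Common-mode drift removal (optional, off by default) subtracts the
cumulative per-frame median displacement across particles and requires at
least five particles, below which the median is dominated by individual
beads and the "correction" injects noise.

### GSER conversion

`gser_spectrum` implements the local power-law (Mason) approximation of the
generalized Stokes–Einstein relation. At each interior lag the logarithmic
slope α and a smoothed MSD value are taken from a quadratic fit of
ln msd vs ln τ over a ±3-point window; then

    |G*(ω)| = 2 kBT / (3π a msd(1/ω) Γ(1+α)),
    G′ = |G*| cos(πα/2),  G″ = |G*| sin(πα/2).

Numerical choices:

* α is clamped to [0, 1]. Measurement noise at the extremes of the lag range
  can push the raw slope outside the physically admissible band for a
  passive tracer, where Γ(1+α) develops artifacts.
* The two endpoint lags are dropped (one-sided slope estimates are
  unreliable).
* The `2/(3π a)` prefactor is the standard 3D relation
  `kBT/(π a msd₃D Γ)` applied to the 2D-measured MSD scaled by 3/2
  (isotropy). Because this convention rescales every modulus by a constant
  it is exposed as `msd_dim_scale`.

The plateau modulus is G′ read at a fixed low frequency by log-log
interpolation, **never** extrapolation. The default readout is
ω = 0.1 rad/s: at comparable concentrations the storage modulus is flat and
the loss modulus near its minimum there, so the reading is insensitive to
the exact frequency; `omega_eval` is a parameter throughout (0.1 Hz =
0.628 rad/s users can pass explicitly).

## Two-point microrheology

`pair_correlation` computes the Crocker-style displacement cross-correlation:
for every co-observed pair and lag, displacements are projected onto the
unit separation vector (longitudinal) and its normal (transverse), and the
products are averaged in log-spaced separation bins. Conventions:

* the separation is taken at the **start** of each lag interval, and the
  per-cell mean observed separation (not the nominal bin center) is used as
  the abscissa of later fits, removing the log-bin placement bias;
* cells with fewer than `min_pairs` (default 50) observations are masked,
  not zero-filled — two-point statistics degrade sharply at long lags and
  under-sampled cells would otherwise dominate the 1/r fit;
* the default separation window spans bead diameter to a quarter of the
  field extent.

`two_point_msd` fits `D_∥(r) = A(τ)/r` per lag by weighted least squares
(weights = pair counts) and reports `msd2p = 2A/a`. A lag is flagged when
the median relative residual of the 1/r model exceeds 20%, when fewer than
two bins survive masking, or when A ≤ 0. Rigid common motion (drift) gives
an r-independent D_∥ and is flagged by construction. The unflagged two-point
MSD feeds the same GSER code as the one-point MSD.

## Filament analysis

### Skeleton tracing

`skeleton_to_paths` walks 1-pixel-wide, 8-connected skeletons
endpoint-to-endpoint. Pixels with three or more skeleton neighbors are
junctions: they terminate paths and are never traversed, because crossing
filaments traversed as one contour would contribute spurious sharp bends
that bias the persistence length down. Closed loops are traced from an
arbitrary start. Only a simple tracer is provided — producing good
skeletons from raw fluorescence images is the job of dedicated line
detectors, whose output this module consumes.

### Persistence length

Tangent angles are measured on contours resampled at equal arc length
(default step: 5 × pixel size, which suppresses the angle quantization of
the pixel lattice; for synthetic contours the native step). The tangent
cosine correlation is averaged over all segment pairs at each separation and
all filaments, restricted by default to separations up to half the shortest
usable filament. The fit is weighted log-linear; in 2D

    <cos θ(s)> = exp(−s / (2 l_P)),

appropriate for filaments confined to two dimensions before imaging. The 3D
convention (`exp(−s/l_P)`) differs by exactly a factor 2 and is switchable
(`convention="3d"`). A non-decaying correlation (straight filaments) raises
an error rather than returning a meaninglessly large number.

### Length statistics

`L_w = ΣL²/ΣL` is the mass-weighted mean, up-weighting long filaments in
proportion to the monomer mass they carry; the weighted SD uses the same
length weights, `sd_w = sqrt(ΣL(L−L_w)²/ΣL)`. Since the weighting
convention of a quoted SD is often ambiguous, both weighted and unweighted
SDs are emitted. The exponential mean is fitted by maximum likelihood (the
sample mean).

## Network-image morphometrics

### Bundle parameter

Peaks in a line profile are detected by prominence (default: a quarter of
the dynamic range above the median). The peak support used to define
"between bundles" is the width at 10% of prominence; the baseline is the
mean intensity outside all supports, and

    n_B = (peak intensity − baseline) / I_single.

`I_single` is either supplied directly or calibrated as the median peak
height above baseline in dilute single-filament profiles. The estimator is
exactly invariant under adding a constant to the profile and linear in the
peak amplitude.

### Mesh size and the mesh-based n_B

The observed mesh size is defined as twice the mean Euclidean distance
transform over background pixels of the (Otsu-)binarized network — a
pore-radius doubling — together with the distribution of per-pore maxima.
The cross-check estimator `n_B = (ξ_obs/ξ_theory)²` follows from length
conservation: collecting n_B filaments into one cable divides the cable
length density by n_B and therefore multiplies the mesh size by sqrt(n_B).

### Asters

Segmentation is deliberately minimal and fully logged: optional median
background subtraction, Gaussian smoothing (σ in µm), global Otsu threshold,
removal of objects below a minimum area, hole filling, connected-component
labeling. No watershed splitting is applied by default — touching foci
merge — because a reproducible simple default beats an unconstrained
sophisticated one. Reported metrics: areas and equivalent diameters (both,
since "size" is ambiguous), the exact area fraction Σareas/image area,
centroid nearest-neighbor distances, and a depletion ratio — mean intensity
in the annulus between 1× and 2× each object's equivalent radius divided by
the global background (median intensity farther than 2.5 radii from every
centroid). The depletion metric is a declared proxy validated against
synthetic truth only.

## Theory anchors

With c in µM and full polymerization at 370 subunits per µm of filament
(the canonical F-actin mass per length), the filament length density is
ρ = c·N_A·10⁻²¹/370 µm⁻², the geometric mesh size ξ = sqrt(3/ρ) (392 nm at
12 µM), the entanglement length l_e = ξ^{4/5} l_P^{1/5}, and the tube-model
plateau G0 = P·kBT/(ξ² l_e). The order-unity prefactor P is a genuine model
ambiguity; it defaults to 1 (giving 32 mPa at 12 µM, l_P = 16 µm, inside
the canonical 10–100 mPa entanglement bracket) and is exposed as a
parameter. Under these closed forms G0 ∝ c^{7/5} and G0 ∝ l_P^{−1/5}
exactly.

## Group statistics

The rank-sum test uses exact null enumeration for tie-free samples with
both sizes ≤ 12 (feasible and matching typical per-group measurement
counts) and the tie-corrected normal approximation with continuity
correction otherwise; two-sided by default. Stars: *p ≤ 0.05, **p ≤ 0.01,
***p ≤ 0.001. Box summaries fix the quantile convention to linear
interpolation of order statistics so that documented examples are exact;
whiskers extend to the furthest data within 1.5 IQR of the quartiles.
The bundling onset across cation concentrations is operationalized as the
smallest concentration whose mean n_B exceeds 5× the low-concentration
baseline (mean of the first two points) — the factor is a parameter.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of (spec, seed) and stores its ground
truth beside the data.

* **Kelvin–Voigt beads** follow the overdamped harmonic Langevin equation
  with stiffness κ = 6πaG0 and drag γ = 6πaη, integrated with the **exact**
  Ornstein–Uhlenbeck update over Δt and started from the stationary
  distribution, so recovery tests carry no step-size bias. Default
  acquisition mirrors the experiments emulated: 138 fps, 2 µm beads,
  ≥ 50 particles, 10⁴ frames. In recovery tests the viscosity is tied to the
  plateau as η = G0/5 (relaxation time 0.2 s) so the MSD plateau is fully
  developed at the 0.1 rad/s readout within a 72 s record.
* **Power-law media** are fractional Brownian motion synthesized by
  circulant embedding (Davies–Harte), i.e. with exact increment covariance,
  rather than approximate spectral filtering — the closed-form MSD is what
  the oracle tests require.
* **Bead pairs** share a common displacement along the separation axis,
  scaled by 1/sqrt(r) per pair, making the true longitudinal correlation
  `A·τ^q/r` analytic; a rigid (unscaled) mode provides the drift fixture.
  Pairs are stacked far apart transversely so cross-pair separations fall
  outside the analysis window. The pair fixture uses a stiff background
  medium (G0 = 0.5 Pa): the cross-correlation estimator's noise scales with
  the square of the single-bead MSD, and a soft background at desk-scale
  sampling would need orders of magnitude more frames for the same
  precision.
* **Worm-like chains** draw i.i.d. Gaussian turning angles of variance
  ds/l_P, giving `<cos θ(s)> = exp(−s/2l_P)` by construction; defaults
  l_P = 16 µm, L = 20 µm, ds = 0.1 µm match the scale of phalloidin-labeled
  actin in 2D chambers.
* **Filament lengths** are i.i.d. exponential, the roughly exponential
  ensembles of spontaneously nucleated actin; mean length is a parameter.
* **Rendered images**: bundle lines have Gaussian cross-sections with peak
  amplitude multiplicity × I_single (snapped to pixel centers so the truth
  is exact), optional Poisson noise; aster fields are non-overlapping disks
  with a depletion annulus (1–2 radii) dimmed by a known factor and optional
  Gaussian noise.

What the generators do **not** emulate: static and dynamic tracking errors,
bead polydispersity and surface chemistry, network heterogeneity and
anelastic aging, out-of-plane filament undulations, realistic PSFs and
shot-noise statistics of confocal imaging, or filament overlap in dense
fields. Passing recovery tests therefore demonstrates estimator
correctness under the stated models, not robustness to every artifact of
real data; the explicit parameters (drift mode, masks, fit windows,
thresholds) are the knobs with which real data are handled.

## Problem sizes and determinism

Recovery tests use 50 particles × 10⁴ frames (one-particle), 60 pairs ×
6·10³ frames (two-point), 500 chains (persistence), 512-pixel rendered
images — sizes at which every estimator's sampling error is several times
smaller than the tolerance it is tested against. All randomness flows
through `numpy.random.default_rng(seed)`; identical spec + seed yields
bit-identical output, and the pipeline writes byte-identical artifacts on
re-runs.

## Known limitations

* The local power-law GSER is exact only for pure power-law MSDs; spectra
  are mildly smoothed near sharp viscoelastic transitions.
* No inverse Laplace transform with regularization is provided.
* The two-point module assumes a homogeneous isotropic medium (scalar
  response); tensorial two-point microrheology is out of scope.
* The aster depletion ratio and the bundling-onset rule are operational
  definitions chosen here; alternative definitions would shift absolute
  values while preserving comparisons made with a fixed convention.
* Skeleton junction handling discards junction pixels, shortening branches
  by up to ~2 pixels at each crossing; negligible for filaments much longer
  than the pixel size.
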