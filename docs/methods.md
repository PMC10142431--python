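# Methods

## Scope and model

This package computes Van Hove cross-correlation functions G(r, t)
between two labelled bead populations — by convention choline (NC3) as
the moving species A at time t and phosphate (PO4) as the reference
species B at time 0 — in 1D (a single axis), 2D (a plane) and 3D, for
trajectories in an orthorhombic periodic box. It then reduces a grid to
a first-peak height/position trace over lag time and estimates its
one-sided power spectrum, and separately evaluates a linearized
dipole–dipole oscillator model for the vibration frequency of an
inter-leaflet headgroup pair.

Assumptions: beads are single interaction sites (in MARTINI a headgroup
"center of mass" *is* the bead position, so no center-of-mass reduction
is performed); boxes are orthorhombic (triclinic input is rejected with
an explicit error); frame times are uniformly spaced. Units are nm, ps
and GHz throughout; readers convert on input.

## Estimator conventions

**Distances.** Per-axis minimal image into (−L/2, L/2], applied per
pair; input coordinates are never pre-wrapped, which keeps
displacement-based generators artifact-free. 1D uses the absolute
single-axis separation, 2D the in-plane Euclidean norm, 3D the full
norm. Bins are half-open [r_lo, r_hi) of uniform width dr, first edge at
0; distances at or beyond r_max are dropped. A distance falling exactly
on a bin edge is assigned by floating-point division, as in numpy's
histogramming.

**Normalization.** Exact bin measures replace the differential shell
factors: (4π/3)(r_out³−r_in³) in 3D, π(r_out²−r_in²) in 2D, dr in 1D.
This removes the O(dr) bias of dividing by 4πr²dr (or 2πr dr) at the bin
center and reduces to the differential forms as dr → 0. In 1D the
histogram of absolute separations collects both signs of the axis
difference, so the normalization includes a factor 2, making the
uncorrelated uniform baseline exactly 1 in all three modes — convenient
when 1D/2D/3D panels share one intensity scale. The literal unfolded
prefactor (baseline 2) is available via `literal_1d=True`.

**Time origins.** The definition fixes the reference particle at t = 0;
the estimator averages over origins t₀ stepped by `origin_stride`
(default every frame), the standard variance-reduction device. A stride
past the trajectory end reproduces the single-origin definition. For
NPT-style fluctuating boxes, distances use each origin's box and the
normalization uses the per-lag mean box measure (exact for constant
boxes, recorded in `norm_meta`).

**Pair scope.** `all` includes every (i, j) pair — including a lipid's
own N–P pair, which produces the short-distance intramolecular band in
z-axis maps; `intra` keeps same-molecule pairs (the self part for N–P
cross-correlation); `inter` the complement (the distinct part).

**Peak traces.** Height is the maximum of G over a distance window per
lag, position the bin center of the argmax, ties broken toward smaller
r; optional 3-point parabolic refinement interpolates both. A
fixed-shell trace "along r ≈ r₀" is the same operation with a one-bin
half-width window.

**Spectra.** Mean subtraction by default, optional Hann taper, one-sided
power normalized so a unit cosine on a bin carries its variance (1/2) in
that bin; with no taper the power sums to the series variance
(Parseval). Frequencies are reported in GHz (1 ps⁻¹ = 1000 GHz).
"Frequency band" is operationalized as the span where power exceeds a
threshold fraction (default 0.05) of the non-DC maximum, since verbal
"ranges between" statements do not define an estimator.

## Dipole–dipole oscillator model

Two headgroup dipoles p = q·l (q = 1 e, l = 0.55 nm) a distance
r = 4.5 nm apart interact with force magnitude p²/(4πε₀εz⁴).
Linearizing about z = r gives k = lin_factor · p²/(4πε₀εr⁵) and
f = √(k/m)/2π. The dielectric constant of the hydrated headgroup region
is not sharply defined; two self-consistent conventions are implemented
and exactly degenerate in f: (ε = 30, lin_factor = 4), the default,
where 4 = |d/dz z⁻⁴|·z⁵ is the full derivative factor and 30 is a
standard headgroup-region dielectric; and (ε = 7.5, lin_factor = 1), the
literal force-over-distance reading. With POPC's 760 Da both give
ω ≈ 2.0×10⁹ rad/s and f ≈ 0.32 GHz, inside the 0.05–0.5 GHz surface-
undulation band — the physical point of the model. A leapfrog
integration of m·z̈ = −k·z, with frequency read from interpolated zero
crossings, serves as an independent numerical oracle (agreement to
0.1% over a mass/distance grid). The full lipid mass is used, as an
effective headgroup mass is not better constrained.

## Synthetic generators: what they emulate, and what they do not

All generators are deterministic given their `SynthSpec` (one RNG per
trajectory; per-site substreams spawned from the seed where sites are
propagated individually), emit coordinates wrapped into [0, box), and
carry NC3/PO4 pairs at a fixed offset l = 0.55 nm where pairing is
meaningful.

- `uniform_gas`: i.i.d. uniform positions per frame; the exact null
  model for the baseline-1 normalization (pair counts are Binomial, so
  per-bin standard errors are known).
- `brownian`: independent Gaussian walkers with per-axis step variance
  2·D·Δt; self-part displacements are exactly Gaussian with variance
  2·D·t (Einstein relation), giving a folded-normal 1D Van Hove.
- `harmonic_dipoles`: a square lattice whose z coordinates follow the
  *exact discretization* of the underdamped Langevin oscillator
  (position–velocity AR(1) with the matrix exponential transition and
  the discrete-Lyapunov noise covariance), started from the stationary
  law. Stationary σ_z and the damped-cosine autocovariance
  e^(−γt/2)(cos ω′t + (γ/2ω′) sin ω′t) are exact at any time step —
  Euler integration would bias the spectral tests. Overdamped parameter
  choices are accepted but flagged in metadata.
- `toy_bilayer`: two triangular-lattice leaflets (dense-packing
  first-shell geometry of fluid membranes) with per-frame i.i.d.
  in-plane jitter. The box x/y edges are snapped to lattice-commensurate
  lengths (nx·a × ny·a·√3/2, ny even) so periodic wrapping cannot create
  spurious pair distances below the lattice constant; `n_sites` rounds
  up to complete lattices and the snapped box is recorded.

None of these have lipid–lipid interactions, water, thermostats or
realistic force fields. Passing tests therefore demonstrate that the
*estimators* are correct (counts, normalizations, distributional shapes,
spectral locations) — not that any particular bilayer exhibits
particular dynamics. Conclusions about real membranes require real MD
input (below).

## Validation conditions and numerical choices

Test problem sizes were chosen to make each check sharp yet quick: the
brute-force count-equivalence suite uses > 200 randomized instances of
≤ 10 beads × ≤ 5 frames (where exact integer equality is checkable by a
plain triple loop); the uniform-baseline check uses 200+200 beads × 50
frames with dr = 0.1 nm so every bin has a well-resolved Binomial
standard error; the diffusion check uses 220 walkers × 500 frames
(≥ 10⁵ samples per lag, Kolmogorov–Smirnov distance computed at bin
edges); spectral recovery uses 36 oscillators × 2048 frames at 32
samples per period with quality factor ω₀/γ = 320, so the oscillation
outlives the 32-period analysis window and the spectral line is narrower
than one frequency bin. All randomized tests are seeded; default grids
(dr = 0.01 nm, r_max = 2.0 nm laterally / ~0.5 nm along z) resolve the
0.45 nm first shell and the 0–0.2 nm z-band of PC headgroups.

Degenerate-input conventions: a constant grid display-normalizes to all
zeros; display normalization is monotone so peak positions are
invariant; `origin_stride` beyond the trajectory gives the literal
single-origin estimator; XYZB files print 17 significant digits so the
text round trip is float-exact.

## Analysing real MD data (optional workflow)

The MD-derived observations this toolkit is designed for — a first
coordination shell near 0.45 nm for MARTINI PC bilayers, ~2–4 ps caging
with relaxation within ~25 ps laterally, a ~1–30 GHz lateral band and a
0.05–0.5 GHz out-of-plane band — require an actual coarse-grained
simulation and are not part of the test suite. A scaled-down workflow: a
MARTINI 2.2p PC bilayer of ≥ 128 lipids per leaflet (CHARMM-GUI
assembly), NPT at 1 bar / 310 K with V-Rescale thermostatting, ≥ 6 ns of
production at 20 fs steps with frames every few ps; then
`vanhove compute --mode 2d --axis xy` and `--mode 1d --axis z` with the
default grids, `trace` over the first shell, and `spectrum`. Frame
stride sets the Nyquist limit (1000/(2·Δt_ps) GHz) and trace length the
frequency resolution.

## Known limitations

Triclinic boxes, intermediate scattering functions and reciprocal-space
S(q, ω), velocity correlations, wavelet/multitaper spectral estimation,
and fitting damped-oscillator models to spectra are out of scope. The
dipole model ignores dipole orientation tensors and many-body
electrostatics; it is a single-pair order-of-magnitude estimate. Leaflet
tags are carried by the XYZB format and the bilayer generator but
standard-format readers do not infer leaflets; users must assign them
upstream if leaflet-resolved analysis is needed.
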