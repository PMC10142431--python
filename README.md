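# vanhove

Real-space, real-time imaging of collective lipid headgroup dipole motions.

Zwitterionic phosphatidylcholine (PC) bilayers carry a large headgroup
dipole: a positive choline (NC3 bead in MARTINI coarse-graining) and a
negative phosphate (PO4) about 0.55 nm apart. Their collective motions —
picosecond "caging" in the first coordination shell, slower relaxation,
and sub-GHz out-of-plane tilting that drives membrane surface
undulations — are invisible to static structural probes. This package
images them in real space and time from coarse-grained MD trajectories
by computing Van Hove *cross*-correlation functions between the choline
and phosphate bead populations, tracking the first-shell peak through
time, and Fourier-analysing the resulting traces. It is aimed at
membrane biophysicists and MD practitioners analysing GROMACS/MARTINI
(or similar) bilayer simulations.

## The statistic

For N_A choline and N_B phosphate beads in an orthorhombic periodic box
(volume V, in-plane area S, axis length L), with minimal-image distances:

    G3D(r,t) = V / (4πr² N_A N_B) · Σᵢⱼ δ(r − |r_iᴬ(t) − r_jᴮ(0)|₃D)
    G2D(r,t) = S / (2πr  N_A N_B) · Σᵢⱼ δ(r − |r_iᴬ(t) − r_jᴮ(0)|₂D)
    G1D(r,t) = L / (2    N_A N_B) · Σᵢⱼ δ(r − |r_iᴬ(t) − r_jᴮ(0)|₁D)

G(r,t) is the probability density of finding a choline bead at distance
r and lag t from where a phosphate bead sat at t = 0; it generalizes the
pair distribution function to time and decomposes into a *self* part
(same lipid; diffusion) and a *distinct* part (different lipids;
collective structure), selectable via `pair_scope`. Numerically the
differential shell factors are replaced by exact bin measures, and the
1D normalization folds the two signs of the axis separation so that the
uncorrelated baseline is 1 in all three modes (see `docs/methods.md`).

A companion analytic model estimates the vibrational frequency of an
inter-leaflet headgroup dipole pair: p = q·l, k = 4p²/(4πε₀εr⁵),
ω = √(k/m), f = ω/2π.

The package also ships synthetic-trajectory generators (ideal gas,
Brownian walkers, a damped stochastic-oscillator lattice, a jittered
two-leaflet bilayer) whose statistics are known in closed form, so every
stage of the pipeline is testable without running MD.

## Worked example

The analytic dipole–dipole frequency for POPC (q = 1 e, l = 0.55 nm,
m = 760 Da, r = 4.5 nm, ε = 30, linearization factor 4):

```sh
$ vanhove dipole-freq --m-da 760
p     = 8.8120e-29 C*m
k     = 5.0427e-06 N/m
omega = 1.9989e+09 rad/s
f     = 0.32 GHz
```

The dipole pair behaves as a spring with k ≈ 5×10⁻⁶ N/m, giving a
0.32 GHz vibration — inside the 0.05–0.5 GHz band of membrane surface
undulations, i.e. dipole–dipole coupling is fast enough to drive them.

First-shell structure of a synthetic bilayer (triangular lattice,
a = 0.45 nm, 0.02 nm in-plane jitter):

```python
import vanhove as vh

spec = vh.SynthSpec(kind="toy_bilayer", n_sites=256, n_frames=20,
                    box=(6.0, 6.0, 10.0), frame_spacing=2.0, seed=3,
                    lattice_constant=0.45, jitter_xy=0.02)
traj = vh.generate(spec)
sel = vh.select_beads(traj, "NC3", "PO4")
grid = vh.compute_vanhove(traj, sel, "2D", "xy", r_max=1.5, dr=0.01,
                          max_lag=4.0, pair_scope="inter")
trace = vh.peak_trace(grid, 0.2, 0.7)
print(trace.positions)   # [0.445 0.455 0.445]
print(trace.heights)     # [5.21 5.07 5.20]
```

The inter-molecular 2D Van Hove peaks at r ≈ 0.45 nm — the
nearest-neighbour headgroup distance — with G ≈ 5, i.e. a five-fold
density enhancement over the uncorrelated baseline of 1, and the peak
persists over the short lags shown (caging).

The same pipeline runs from the shell
(`vanhove synth → compute → trace → spectrum → plot`); every output TSV
records the producing parameter hash and a `.prov.yaml` provenance file.

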