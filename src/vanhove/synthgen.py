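"""Synthetic trajectories with known statistical structure.

Every analysis stage in this package (pair histogramming, first-peak
tracking, spectral estimation) is validated against trajectories whose
statistics are known in closed form:

``uniform_gas``
    Independent uniform bead positions each frame — the null model whose
    Van Hove function is exactly the uncorrelated baseline.
``brownian``
    Independent Brownian walkers carrying a co-moving choline/phosphate
    (NC3/PO4) pair; per-axis displacement variance is ``2*D*t`` (Einstein
    relation), giving a folded-Gaussian self part.
``harmonic_dipoles``
    A square lattice of sites whose z coordinates follow a stochastically
    driven, damped harmonic oscillation — the synthetic analogue of two
    bilayer-leaflet headgroup dipoles vibrating along the membrane normal.
    Implemented as the exact discretization of the underdamped Langevin
    oscillator (position–velocity pair), so the stationary variance and
    autocovariance are exact at any time step, not Euler approximations.
``toy_bilayer``
    Two triangular-lattice leaflets with per-frame in-plane Gaussian
    jitter — a minimal model of the in-plane nearest-neighbour ordering
    (first coordination shell) of a fluid membrane.

Identical :class:`SynthSpec` values (including the seed) produce
bit-identical trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.linalg import expm

from .trajio import Trajectory

__all__ = [
    "SynthSpec",
    "generate",
    "gen_uniform_gas",
    "gen_brownian",
    "gen_harmonic_dipoles",
    "gen_toy_bilayer",
    "ou_oscillator_autocorrelation",
]

_KINDS = ("uniform_gas", "brownian", "harmonic_dipoles", "toy_bilayer")


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic trajectory.

    Lengths in nm, times in ps, frequencies in GHz, diffusion in nm²/ps,
    damping in 1/ps. ``np_offset`` is the fixed choline–phosphate (N–P)
    separation carried by each site (0.55 nm for a PC headgroup).
    """

    kind: str
    n_sites: int = 100
    box: tuple = (10.0, 10.0, 10.0)
    n_frames: int = 100
    frame_spacing: float = 2.0
    seed: int = 0
    # brownian
    diffusion: float = 0.05
    # harmonic_dipoles
    f0: float = 1.0
    damping: float = 0.05
    sigma_z: float = 0.1
    # toy_bilayer
    lattice_constant: float = 0.45
    jitter_xy: float = 0.02
    leaflet_separation: float = 4.0
    tilt_deg: float = 0.0
    # shared
    np_offset: float = 0.55

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.n_sites <= 0 or self.n_frames <= 0:
            raise ValueError("n_sites and n_frames must be positive")
        box = tuple(float(b) for b in self.box)
        if len(box) != 3 or any(b <= 0 for b in box):
            raise ValueError("box must be 3 positive lengths (nm)")
        object.__setattr__(self, "box", box)
        if self.frame_spacing <= 0:
            raise ValueError("frame_spacing must be positive (ps)")
        for name in ("diffusion", "f0", "damping", "sigma_z",
                     "lattice_constant", "jitter_xy", "leaflet_separation",
                     "np_offset"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def generate(spec: SynthSpec) -> Trajectory:
    """Dispatch to the generator named by ``spec.kind``."""
    return {
        "uniform_gas": gen_uniform_gas,
        "brownian": gen_brownian,
        "harmonic_dipoles": gen_harmonic_dipoles,
        "toy_bilayer": gen_toy_bilayer,
    }[spec.kind](spec)


def _times(spec):
    return np.arange(spec.n_frames, dtype=float) * spec.frame_spacing


def _boxes(spec, box=None):
    box = spec.box if box is None else box
    return np.tile(np.asarray(box, dtype=float), (spec.n_frames, 1))


def _meta(spec, **extra):
    meta = {"synth_spec": asdict(spec), "seed": spec.seed}
    meta.update(extra)
    return meta


def gen_uniform_gas(spec: SynthSpec) -> Trajectory:
    """Ideal-gas null model: fresh uniform positions every frame.

    ``n_sites`` NC3 beads and ``n_sites`` PO4 beads are drawn
    independently and uniformly in the box each frame, with no pairing and
    no temporal correlation: the Van Hove function of this trajectory is
    the flat uncorrelated baseline at every lag.
    """
    if spec.kind != "uniform_gas":
        raise ValueError("spec.kind must be 'uniform_gas'")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_sites
    box = np.asarray(spec.box)
    coords = rng.uniform(0.0, 1.0, size=(spec.n_frames, 2 * n, 3)) * box
    labels = np.asarray(["NC3"] * n + ["PO4"] * n, dtype=object)
    mols = np.arange(2 * n, dtype=int)  # unpaired: every bead its own molecule
    return Trajectory(coords=coords, times=_times(spec), boxes=_boxes(spec),
                      bead_labels=labels, molecule_ids=mols,
                      metadata=_meta(spec))


def _pair_labels(n):
    labels = np.empty(2 * n, dtype=object)
    labels[0::2] = "NC3"
    labels[1::2] = "PO4"
    mols = np.repeat(np.arange(n, dtype=int), 2)
    return labels, mols


def _assemble_pairs(site_pos, offset):
    """Interleave NC3 (site + offset) and PO4 (site) beads per site."""
    n_frames, n, _ = site_pos.shape
    coords = np.empty((n_frames, 2 * n, 3), dtype=float)
    coords[:, 0::2, :] = site_pos + offset
    coords[:, 1::2, :] = site_pos
    return coords


def gen_brownian(spec: SynthSpec) -> Trajectory:
    """Independent Brownian sites, each carrying a rigid NC3/PO4 pair.

    Per-axis increments are Gaussian with variance ``2*D*frame_spacing``
    so the mean squared displacement obeys the Einstein relation
    ``MSD(t) = 2*D*t`` per axis. The PO4 bead sits at the site position
    and the NC3 bead at a fixed offset ``(0, 0, np_offset)``.
    """
    if spec.kind != "brownian":
        raise ValueError("spec.kind must be 'brownian'")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_sites
    box = np.asarray(spec.box)
    start = rng.uniform(0.0, 1.0, size=(n, 3)) * box
    step_sigma = math.sqrt(2.0 * spec.diffusion * spec.frame_spacing)
    steps = rng.normal(0.0, 1.0, size=(spec.n_frames - 1, n, 3)) * step_sigma \
        if spec.n_frames > 1 else np.zeros((0, n, 3))
    site_pos = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)]) \
        if spec.n_frames > 1 else start[None]
    coords = _assemble_pairs(site_pos, np.array([0.0, 0.0, spec.np_offset]))
    coords %= box  # emit wrapped into [0, box)
    labels, mols = _pair_labels(n)
    return Trajectory(coords=coords, times=_times(spec), boxes=_boxes(spec),
                      bead_labels=labels, molecule_ids=mols,
                      metadata=_meta(spec))


def _ou_oscillator_transition(omega0, gamma, sigma_z, dt):
    """Exact AR(1) transition for the damped stochastic harmonic oscillator.

    State s = (z, v) with dynamics dz = v dt, dv = (-omega0^2 z - gamma v) dt
    + sigma dW, where sigma is fixed by the requested stationary standard
    deviation of z. Returns (M, L) with s' = M s + L n, n ~ N(0, I).
    """
    A = np.array([[0.0, 1.0], [-omega0 ** 2, -gamma]])
    M = expm(A * dt)
    # Stationary covariance diag(sigma_z^2, omega0^2 sigma_z^2); the process
    # noise covariance follows from the discrete Lyapunov identity.
    S = np.diag([sigma_z ** 2, (omega0 * sigma_z) ** 2])
    Q = S - M @ S @ M.T
    Q = 0.5 * (Q + Q.T)
    # guard against tiny negative eigenvalues from round-off
    w, V = np.linalg.eigh(Q)
    L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    return M, S, L


def ou_oscillator_autocorrelation(t, f0_ghz, gamma):
    """Stationary normalized autocovariance of the oscillator z coordinate.

    ``rho(t) = exp(-gamma t/2) (cos(w' t) + (gamma/(2 w')) sin(w' t))`` with
    ``w' = sqrt(w0^2 - gamma^2/4)``; ``t`` in ps, ``f0_ghz`` in GHz,
    ``gamma`` in 1/ps. Valid for the underdamped regime.
    """
    t = np.abs(np.asarray(t, dtype=float))
    omega0 = 2.0 * math.pi * f0_ghz / 1000.0  # rad/ps
    disc = omega0 ** 2 - gamma ** 2 / 4.0
    if disc <= 0:
        raise ValueError("closed-form autocovariance requires underdamping")
    wp = math.sqrt(disc)
    return np.exp(-gamma * t / 2.0) * (np.cos(wp * t)
                                       + (gamma / (2.0 * wp)) * np.sin(wp * t))


def gen_harmonic_dipoles(spec: SynthSpec) -> Trajectory:
    """Square lattice of sites oscillating along z around the box midplane.

    Each site's z coordinate follows an exactly discretized underdamped
    Ornstein–Uhlenbeck oscillator with natural frequency ``f0`` (GHz),
    damping ``damping`` (1/ps) and stationary standard deviation
    ``sigma_z`` (nm), started from its stationary distribution. NC3 beads
    ride ``np_offset`` above their PO4 partner. Per-site noise streams are
    spawned deterministically from the trajectory seed.

    Overdamped parameter choices are accepted but recorded as a warning in
    the trajectory metadata (no spectral peak is then guaranteed).
    """
    if spec.kind != "harmonic_dipoles":
        raise ValueError("spec.kind must be 'harmonic_dipoles'")
    n = spec.n_sites
    box = np.asarray(spec.box)
    omega0 = 2.0 * math.pi * spec.f0 / 1000.0  # rad/ps
    warnings = []
    if omega0 > 0 and spec.damping >= 2.0 * omega0:
        warnings.append(
            f"overdamped oscillator (damping {spec.damping} 1/ps >= "
            f"2*omega0 {2 * omega0:.4g} 1/ps): spectrum peak recovery "
            "is not guaranteed")

    nx = math.ceil(math.sqrt(n))
    ax, ay = box[0] / nx, box[1] / nx
    ix, iy = np.divmod(np.arange(n), nx)
    base = np.column_stack([(iy + 0.5) * ax, (ix + 0.5) * ay,
                            np.full(n, box[2] / 2.0)])

    if spec.sigma_z == 0.0 or omega0 == 0.0:
        z_dev = np.zeros((spec.n_frames, n))
    else:
        M, S, L = _ou_oscillator_transition(omega0, spec.damping,
                                            spec.sigma_z, spec.frame_spacing)
        streams = [np.random.default_rng(s)
                   for s in np.random.SeedSequence(spec.seed).spawn(n)]
        init = np.stack([r.standard_normal(2) for r in streams])
        states = init @ np.linalg.cholesky(S).T  # stationary start
        noise = np.stack([r.standard_normal((spec.n_frames - 1, 2))
                          for r in streams], axis=1)  # (frames-1, n, 2)
        z_dev = np.empty((spec.n_frames, n))
        z_dev[0] = states[:, 0]
        for fi in range(1, spec.n_frames):
            states = states @ M.T + noise[fi - 1] @ L.T
            z_dev[fi] = states[:, 0]

    site_pos = np.broadcast_to(base, (spec.n_frames, n, 3)).copy()
    site_pos[:, :, 2] += z_dev
    coords = _assemble_pairs(site_pos, np.array([0.0, 0.0, spec.np_offset]))
    coords %= box
    labels, mols = _pair_labels(n)
    return Trajectory(coords=coords, times=_times(spec), boxes=_boxes(spec),
                      bead_labels=labels, molecule_ids=mols,
                      metadata=_meta(spec, warnings=warnings))


def gen_toy_bilayer(spec: SynthSpec) -> Trajectory:
    """Two triangular-lattice leaflets with per-frame in-plane jitter.

    Each leaflet is a periodic triangular (hexagonal) lattice with lattice
    constant ``lattice_constant`` — the dense-packing first-shell geometry
    of a fluid membrane — so the nearest-neighbour in-plane distance is
    the lattice constant. The box x/y edges are snapped to the nearest
    lattice-commensurate lengths (``nx*a``, ``ny*a*sqrt(3)/2`` with ``ny``
    even) so periodic wrapping introduces no spurious sub-lattice
    distances; the snapped box is recorded in the output frames.
    ``n_sites`` is rounded up to fill complete lattices. Headgroup N–P
    pairs point outward along the bilayer normal, optionally tilted by
    ``tilt_deg`` toward x.
    """
    if spec.kind != "toy_bilayer":
        raise ValueError("spec.kind must be 'toy_bilayer'")
    a = spec.lattice_constant
    if a <= 0:
        raise ValueError("lattice_constant must be positive")
    if a >= min(spec.box[0], spec.box[1]):
        raise ValueError("lattice_constant must be smaller than the box edges")
    row_h = a * math.sqrt(3.0) / 2.0

    n_half = max(1, spec.n_sites // 2)
    nx = max(2, round(math.sqrt(n_half)))
    ny = max(2, math.ceil(n_half / nx))
    ny += ny % 2  # even row count keeps the triangular lattice periodic in y
    n_leaf = nx * ny
    box = (nx * a, ny * row_h, spec.box[2])
    if spec.leaflet_separation + 2 * spec.np_offset >= box[2]:
        raise ValueError("box z edge too small for leaflet separation + headgroups")

    iy, ix = np.divmod(np.arange(n_leaf), nx)
    lat = np.column_stack([(ix + 0.25 + 0.5 * (iy % 2)) * a, (iy + 0.5) * row_h])

    rng = np.random.default_rng(spec.seed)
    zmid = box[2] / 2.0
    tilt = math.radians(spec.tilt_deg)
    normal = np.array([math.sin(tilt), 0.0, math.cos(tilt)])

    n_sites = 2 * n_leaf
    site_xy = np.tile(lat, (2, 1))  # lower leaflet then upper leaflet
    site_z = np.concatenate([np.full(n_leaf, zmid - spec.leaflet_separation / 2.0),
                             np.full(n_leaf, zmid + spec.leaflet_separation / 2.0)])
    outward = np.concatenate([-np.ones(n_leaf), np.ones(n_leaf)])

    jitter = rng.normal(0.0, 1.0, size=(spec.n_frames, n_sites, 2)) * spec.jitter_xy
    site_pos = np.empty((spec.n_frames, n_sites, 3))
    site_pos[:, :, :2] = site_xy[None] + jitter
    site_pos[:, :, 2] = site_z[None]

    offsets = outward[:, None] * normal[None, :] * spec.np_offset  # (n_sites, 3)
    coords = np.empty((spec.n_frames, 2 * n_sites, 3))
    coords[:, 0::2, :] = site_pos + offsets[None]  # NC3
    coords[:, 1::2, :] = site_pos                  # PO4
    coords %= np.asarray(box)

    labels, mols = _pair_labels(n_sites)
    leaflets = np.repeat(
        np.concatenate([np.full(n_leaf, "lower", dtype=object),
                        np.full(n_leaf, "upper", dtype=object)]), 2)
    return Trajectory(coords=coords, times=_times(spec), boxes=_boxes(spec, box),
                      bead_labels=labels, molecule_ids=mols,
                      leaflet_tags=leaflets,
                      metadata=_meta(spec, snapped_box=box, n_sites_effective=n_sites))
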