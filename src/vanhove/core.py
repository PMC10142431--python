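"""1D/2D/3D Van Hove cross-correlation functions G(r, t).

The Van Hove function generalizes the pair distribution function to time:
G_AB(r, t) is the probability density of finding a particle of species A
(here the choline NC3 bead) at distance r and lag t from where a species-B
particle (the phosphate PO4 bead) sat at t = 0. It contains both a *self*
part (same molecule; encodes diffusion) and a *distinct* part (different
molecules; encodes collective structure), selectable via ``pair_scope``.

Definitions implemented, for N_A × N_B pairs in an orthorhombic periodic
box with volume V = Lx·Ly·Lz, plane area S, and axis length L::

    G3D(r,t) = V / (N_A N_B) * <sum_ij delta(r - |r_i^A(t) - r_j^B(0)|_3D)> / (4 pi r^2)
    G2D(r,t) = S / (N_A N_B) * <sum_ij delta(r - |...|_2D)> / (2 pi r)
    G1D(r,t) = L / (N_A N_B) * <sum_ij delta(r - |...|_1D)> / 2

with per-axis minimal-image distances. Numerically, the differential shell
factors 4*pi*r^2*dr and 2*pi*r*dr are replaced by exact bin measures
((4 pi/3)(r_out^3 - r_in^3), pi (r_out^2 - r_in^2)), which removes the
O(dr) bias and reduces to the differential forms as dr -> 0. In 1D the
absolute separation folds the two signs of the axis difference; the
normalization includes a factor 2 so the uncorrelated uniform baseline is
1 in all three modes (the literal unfolded prefactor, baseline 2, is
available via ``literal_1d=True``).

Lag averaging uses multiple time origins stepped by ``origin_stride``
(single-origin estimation corresponds to a stride past the end).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .trajio import Trajectory, Selection, minimal_image

__all__ = [
    "VanHoveGrid",
    "compute_vanhove",
    "uniform_baseline",
    "normalize_for_display",
    "write_grid_tsv",
    "read_grid_tsv",
]

_AXES = {"x": 0, "y": 1, "z": 2}
_PLANES = {"xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}
_MODES = ("1D", "2D", "3D")
_SCOPES = ("all", "intra", "inter")


@dataclass
class VanHoveGrid:
    """Binned G(r, t) over distance bins × lag times.

    ``values`` and ``counts`` have shape (n_lags, n_bins); ``values`` is
    recomputable from ``counts`` and ``norm_meta`` (geometric bin measure,
    N_A, N_B, origins per lag).
    """

    mode: str
    axis_or_plane: str | None
    r_edges: np.ndarray
    lags: np.ndarray
    values: np.ndarray
    counts: np.ndarray
    norm_meta: dict = field(default_factory=dict)
    pair_scope: str = "all"

    def __post_init__(self):
        self.r_edges = np.asarray(self.r_edges, dtype=float)
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if self.r_edges[0] != 0.0 or np.any(np.diff(self.r_edges) <= 0):
            raise ValueError("r_edges must start at 0 and increase strictly")
        if np.any(self.values < 0):
            raise ValueError("G values must be non-negative")

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])

    @property
    def dr(self) -> float:
        return float(self.r_edges[1] - self.r_edges[0])


def uniform_baseline(mode: str, literal_1d: bool = False) -> float:
    """Expected G for uncorrelated uniform particles under this module's
    conventions: 1.0 in every mode (2.0 for 1D under the literal unfolded
    prefactor, since each absolute separation collects both signs)."""
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    if mode == "1D" and literal_1d:
        return 2.0
    return 1.0


def _bin_measures(mode, edges):
    """Exact geometric measure of each distance bin (nm³ / nm² / nm)."""
    lo, hi = edges[:-1], edges[1:]
    if mode == "3D":
        return (4.0 * math.pi / 3.0) * (hi ** 3 - lo ** 3)
    if mode == "2D":
        return math.pi * (hi ** 2 - lo ** 2)
    return hi - lo  # 1D: bin width; sign folding handled in normalization


def _pair_indices(traj, sel, pair_scope):
    ii, jj = np.meshgrid(np.arange(sel.n_a), np.arange(sel.n_b), indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    if pair_scope == "all":
        return ii, jj
    same = (traj.molecule_ids[sel.indices_a][ii]
            == traj.molecule_ids[sel.indices_b][jj])
    if pair_scope == "intra":
        ii, jj = ii[same], jj[same]
    else:
        ii, jj = ii[~same], jj[~same]
    if ii.size == 0:
        raise ValueError(f"pair_scope={pair_scope!r} leaves no pairs")
    return ii, jj


def compute_vanhove(traj: Trajectory, sel: Selection, mode: str,
                    axis_or_plane: str | None = None, *,
                    r_max: float, dr: float, max_lag: float,
                    origin_stride: int = 1, lag_stride: int = 1,
                    pair_scope: str = "all",
                    literal_1d: bool = False) -> VanHoveGrid:
    """Accumulate the Van Hove cross-correlation G(r, t) on a (r, lag) grid.

    Parameters
    ----------
    mode : {'1D', '2D', '3D'} (case-insensitive)
    axis_or_plane : axis name for 1D ('x'|'y'|'z'), plane for 2D
        ('xy'|'xz'|'yz'); ignored for 3D.
    r_max, dr : distance grid in nm; ``r_max`` must not exceed half the
        smallest relevant box edge (minimal-image ambiguity otherwise).
        Bins are half-open ``[r_lo, r_hi)``; distances exactly at ``r_max``
        are dropped.
    max_lag : largest lag time in ps; must be a multiple of the frame
        spacing and smaller than the trajectory duration.
    origin_stride : frames between successive time origins t0 (1 = every
        frame). ``lag_stride`` thins the lag grid in frames.
    pair_scope : 'all' keeps every (i, j) pair including a lipid's own
        N–P pair, 'intra' keeps same-molecule pairs only, 'inter' the
        complement.
    literal_1d : use the unfolded 1D prefactor L/(N_A N_B) (baseline 2)
        instead of the folded L/(2 N_A N_B) (baseline 1).
    """
    mode = mode.upper()
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    if pair_scope not in _SCOPES:
        raise ValueError(f"pair_scope must be one of {_SCOPES}")
    if dr <= 0 or r_max <= dr:
        raise ValueError("need dr > 0 and r_max > dr")

    if mode == "1D":
        if axis_or_plane not in _AXES:
            raise ValueError("1D mode needs axis_or_plane in {'x','y','z'}")
        cols = (_AXES[axis_or_plane],)
    elif mode == "2D":
        if axis_or_plane not in _PLANES:
            raise ValueError("2D mode needs axis_or_plane in {'xy','xz','yz'}")
        cols = _PLANES[axis_or_plane]
    else:
        cols = (0, 1, 2)

    relevant = traj.boxes[:, list(cols)]
    if r_max > relevant.min() / 2.0 + 1e-12:
        raise ValueError(
            f"minimal-image ambiguity: r_max={r_max} nm exceeds half the "
            f"smallest relevant box edge ({relevant.min() / 2.0:.6g} nm)")

    spacing = traj.frame_spacing
    if max_lag >= traj.duration + 1e-9:
        raise ValueError(
            f"max_lag={max_lag} ps must be smaller than the trajectory "
            f"duration ({traj.duration} ps)")
    n_lag_frames = max_lag / spacing
    if abs(n_lag_frames - round(n_lag_frames)) > 1e-6 * max(n_lag_frames, 1.0):
        raise ValueError("max_lag must be a multiple of the frame spacing")
    lag_frames = np.arange(0, int(round(n_lag_frames)) + 1, int(lag_stride))
    origin_stride = int(origin_stride)
    if origin_stride < 1:
        raise ValueError("origin_stride must be >= 1")

    n_bins = int(round(r_max / dr))
    edges = np.arange(n_bins + 1, dtype=float) * dr
    measures = _bin_measures(mode, edges)

    ii, jj = _pair_indices(traj, sel, pair_scope)
    idx_a = sel.indices_a[ii]
    idx_b = sel.indices_b[jj]

    counts = np.zeros((lag_frames.size, n_bins))
    n_origins = np.zeros(lag_frames.size, dtype=int)
    geom_sum = np.zeros(lag_frames.size)  # per-origin V/S/L accumulated

    cols_arr = np.asarray(cols)
    for li, lagf in enumerate(lag_frames):
        acc = np.zeros(n_bins)
        for t0 in range(0, traj.n_frames - lagf, origin_stride):
            box = traj.boxes[t0, cols_arr]
            delta = (traj.coords[t0 + lagf][idx_a][:, cols_arr]
                     - traj.coords[t0][idx_b][:, cols_arr])
            delta = minimal_image(delta, box)
            if mode == "1D":
                dist = np.abs(delta[:, 0])
            else:
                dist = np.sqrt(np.einsum("ij,ij->i", delta, delta))
            b = np.floor(dist / dr).astype(np.intp)
            valid = b < n_bins
            acc += np.bincount(b[valid], minlength=n_bins)
            n_origins[li] += 1
            geom_sum[li] += float(np.prod(box))
        counts[li] = acc

    if np.any(n_origins == 0):
        raise ValueError("no usable time origins for the requested lags")

    fold = 1.0 if (mode != "1D" or literal_1d) else 2.0
    geom_mean = geom_sum / n_origins  # mean V/S/L over used origins, per lag
    denom = sel.n_a * sel.n_b * n_origins * fold
    values = counts * (geom_mean / denom)[:, None] / measures[None, :]

    norm_meta = {
        "geom_mean": geom_mean,
        "n_a": sel.n_a,
        "n_b": sel.n_b,
        "n_origins": n_origins,
        "fold_factor": fold,
        "bin_measures": measures,
        "box": traj.boxes[0].copy(),
        "n_pairs": int(idx_a.size),
        "literal_1d": bool(literal_1d),
    }
    return VanHoveGrid(mode=mode,
                       axis_or_plane=axis_or_plane if mode != "3D" else None,
                       r_edges=edges, lags=lag_frames * spacing,
                       values=values, counts=counts,
                       norm_meta=norm_meta, pair_scope=pair_scope)


def normalize_for_display(grid: VanHoveGrid) -> VanHoveGrid:
    """Linearly rescale G values to [0, 1] by the global min/max.

    Raw values are retained under ``norm_meta['raw_values']``. A constant
    grid maps to all zeros (documented degenerate-case convention). The
    rescaling is monotone, so peak locations are unchanged.
    """
    vmin, vmax = float(grid.values.min()), float(grid.values.max())
    meta = dict(grid.norm_meta)
    meta["raw_values"] = grid.values.copy()
    meta["display_range"] = (vmin, vmax)
    if vmax > vmin:
        scaled = (grid.values - vmin) / (vmax - vmin)
    else:
        scaled = np.zeros_like(grid.values)
    return replace(grid, values=scaled, counts=grid.counts.copy(),
                   norm_meta=meta)


# ---------------------------------------------------------------------------
# TSV serialization
# ---------------------------------------------------------------------------

def write_grid_tsv(grid: VanHoveGrid, path, extra_header: dict | None = None) -> None:
    """Serialize a grid as TSV: header comments plus r_nm, t_ps, G, counts."""
    meta = grid.norm_meta
    lines = [
        f"# mode\t{grid.mode}",
        f"# axis_or_plane\t{grid.axis_or_plane or 'none'}",
        f"# pair_scope\t{grid.pair_scope}",
        f"# dr_nm\t{grid.dr:.17g}",
        f"# n_a\t{meta.get('n_a', 'NA')}",
        f"# n_b\t{meta.get('n_b', 'NA')}",
        f"# fold_factor\t{meta.get('fold_factor', 'NA')}",
        "# n_origins\t" + ",".join(str(int(x)) for x in np.atleast_1d(
            meta.get("n_origins", []))),
        "# box_nm\t" + ",".join(f"{x:.17g}" for x in np.atleast_1d(
            meta.get("box", []))),
    ]
    for key, val in (extra_header or {}).items():
        lines.append(f"# {key}\t{val}")
    lines.append("r_nm\tt_ps\tG\tcounts")
    centers = grid.r_centers
    for li, lag in enumerate(grid.lags):
        for bi, r in enumerate(centers):
            lines.append(f"{r:.17g}\t{lag:.17g}\t{grid.values[li, bi]:.17g}\t"
                         f"{grid.counts[li, bi]:.17g}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_grid_tsv(path) -> VanHoveGrid:
    """Read a grid written by :func:`write_grid_tsv`."""
    header = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# "):
                key, _, val = line[2:].partition("\t")
                header[key] = val
            elif line and not line.startswith("r_nm"):
                rows.append([float(x) for x in line.split("\t")])
    data = np.asarray(rows)
    r = np.unique(data[:, 0])
    lags = np.unique(data[:, 1])
    dr = float(header["dr_nm"])
    values = np.zeros((lags.size, r.size))
    counts = np.zeros_like(values)
    ri = {v: i for i, v in enumerate(r)}
    li = {v: i for i, v in enumerate(lags)}
    for row in data:
        values[li[row[1]], ri[row[0]]] = row[2]
        counts[li[row[1]], ri[row[0]]] = row[3]
    edges = np.arange(r.size + 1, dtype=float) * dr
    meta = {}
    if "n_a" in header and header["n_a"] != "NA":
        meta["n_a"] = int(header["n_a"])
        meta["n_b"] = int(header["n_b"])
    if header.get("n_origins"):
        meta["n_origins"] = np.array([int(x) for x in header["n_origins"].split(",")])
    if header.get("box_nm"):
        meta["box"] = np.array([float(x) for x in header["box_nm"].split(",")])
    axis = header.get("axis_or_plane", "none")
    return VanHoveGrid(mode=header["mode"],
                       axis_or_plane=None if axis == "none" else axis,
                       r_edges=edges, lags=lags, values=values, counts=counts,
                       norm_meta=meta,
                       pair_scope=header.get("pair_scope", "all"))
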