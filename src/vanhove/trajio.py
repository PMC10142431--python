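"""Trajectory containers, I/O and periodic-geometry primitives.

Trajectories are time-ordered frames of labelled bead coordinates in an
orthorhombic periodic box. All coordinates are stored in nm and all times
in ps, regardless of the source file's convention. Standard MD formats
(GRO topology + XTC/TRR frames, multi-model PDB, DCD + topology) are read
through MDAnalysis; an internal plain-text multi-frame format ("XYZB")
additionally carries per-bead molecule ids and leaflet tags, which no
standard text format records together with the box.

XYZB layout, one block per frame::

    #frame <index> <time_ps> <Lx> <Ly> <Lz>
    <name> <mol_id> <leaflet> <x> <y> <z>
    ...

Coordinates are not pre-wrapped into the box: wrapping is applied per
pair via :func:`minimal_image` at analysis time, which avoids artifacts
for displacement-based synthetic generators.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Frame",
    "Trajectory",
    "Selection",
    "TrajectoryFormatError",
    "SelectionError",
    "minimal_image",
    "read_trajectory",
    "write_trajectory",
    "select_beads",
]

#: Angstrom per nm (MDAnalysis native length unit is Angstrom).
_A_PER_NM = 10.0

_LEAFLET_VALUES = ("upper", "lower", "none")


class TrajectoryFormatError(ValueError):
    """Raised for malformed or unsupported trajectory input."""


class SelectionError(ValueError):
    """Raised when a bead-name pattern matches nothing."""


@dataclass(frozen=True)
class Frame:
    """A single trajectory frame: time (ps), box (nm, 3), coords (nm, n×3)."""

    time: float
    box: np.ndarray
    coords: np.ndarray

    def __post_init__(self):
        box = np.asarray(self.box, dtype=float)
        coords = np.asarray(self.coords, dtype=float)
        if box.shape != (3,) or not np.all(box > 0):
            raise TrajectoryFormatError("box must be 3 strictly positive lengths (nm)")
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise TrajectoryFormatError("coords must have shape (n_beads, 3)")
        if not np.all(np.isfinite(coords)):
            raise TrajectoryFormatError("coordinates must be finite")
        object.__setattr__(self, "box", box)
        object.__setattr__(self, "coords", coords)


@dataclass
class Trajectory:
    """Time-ordered bead coordinates with per-bead metadata.

    Parameters
    ----------
    coords : (n_frames, n_beads, 3) array, nm
    times : (n_frames,) array, ps — strictly increasing, uniform spacing.
    boxes : (n_frames, 3) array, nm — orthorhombic box edges per frame.
    bead_labels : (n_beads,) array of str, e.g. ``NC3``, ``PO4``.
    molecule_ids : (n_beads,) int array grouping beads into lipids.
    leaflet_tags : optional (n_beads,) array of {'upper','lower','none'}.
    metadata : free-form provenance dictionary.
    """

    coords: np.ndarray
    times: np.ndarray
    boxes: np.ndarray
    bead_labels: np.ndarray
    molecule_ids: np.ndarray
    leaflet_tags: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        self.bead_labels = np.asarray(self.bead_labels, dtype=object)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        if self.leaflet_tags is not None:
            self.leaflet_tags = np.asarray(self.leaflet_tags, dtype=object)

        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryFormatError("coords must have shape (n_frames, n_beads, 3)")
        nf, nb, _ = self.coords.shape
        if nf == 0:
            raise TrajectoryFormatError("no frames")
        if self.times.shape != (nf,) or self.boxes.shape != (nf, 3):
            raise TrajectoryFormatError("times/boxes inconsistent with frame count")
        if not np.all(self.boxes > 0):
            raise TrajectoryFormatError("box lengths must be strictly positive")
        if not np.all(np.isfinite(self.coords)):
            raise TrajectoryFormatError("coordinates must be finite")
        for name, arr in (("bead_labels", self.bead_labels),
                          ("molecule_ids", self.molecule_ids)):
            if arr.shape != (nb,):
                raise TrajectoryFormatError(f"{name} length must equal bead count")
        if self.leaflet_tags is not None and self.leaflet_tags.shape != (nb,):
            raise TrajectoryFormatError("leaflet_tags length must equal bead count")
        if nf > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise TrajectoryFormatError("frame times must be strictly increasing")
            if np.max(np.abs(dt - dt[0])) > 1e-6 * max(abs(dt[0]), 1e-30):
                raise TrajectoryFormatError("frame spacing must be uniform")

    # -- convenience ------------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coords.shape[1]

    @property
    def frame_spacing(self) -> float:
        """Time step between consecutive frames in ps."""
        if self.n_frames < 2:
            raise TrajectoryFormatError(
                "at least 2 frames are required for any time-lag computation")
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        """Total trajectory duration in ps."""
        return float(self.times[-1] - self.times[0])

    def frame(self, i: int) -> Frame:
        return Frame(time=float(self.times[i]), box=self.boxes[i],
                     coords=self.coords[i])


@dataclass(frozen=True)
class Selection:
    """Index sets for species A (e.g. choline NC3) and B (phosphate PO4).

    A and B may overlap or be identical (auto-correlation mode).
    """

    indices_a: np.ndarray
    indices_b: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.indices_a, dtype=int)
        b = np.asarray(self.indices_b, dtype=int)
        if a.size == 0 or b.size == 0:
            raise SelectionError("selection must be non-empty")
        object.__setattr__(self, "indices_a", a)
        object.__setattr__(self, "indices_b", b)

    @property
    def n_a(self) -> int:
        return int(self.indices_a.size)

    @property
    def n_b(self) -> int:
        return int(self.indices_b.size)


def minimal_image(delta, box_len):
    """Wrap a coordinate difference into the primary image ``(-L/2, L/2]``.

    Accepts scalars or arrays (broadcasting); ``box_len`` must be positive.
    Idempotent, and ``|minimal_image(d, L)| <= L/2`` for all ``d``.
    """
    delta = np.asarray(delta, dtype=float)
    box_len = np.asarray(box_len, dtype=float)
    if np.any(box_len <= 0):
        raise ValueError("box length must be positive")
    # d - L*ceil(d/L - 1/2) maps the half-open boundary d = -L/2 to +L/2.
    out = delta - box_len * np.ceil(delta / box_len - 0.5)
    if out.ndim == 0:
        return float(out)
    return out


def select_beads(traj: Trajectory, pattern_a: str, pattern_b: str) -> Selection:
    """Select species A and B bead indices by exact name or ``fnmatch`` pattern.

    Raises :class:`SelectionError` naming the pattern when nothing matches.
    """
    labels = [str(x) for x in traj.bead_labels]

    def match(pattern):
        idx = np.array([i for i, name in enumerate(labels)
                        if fnmatch.fnmatchcase(name, pattern)], dtype=int)
        if idx.size == 0:
            raise SelectionError(f"no beads match {pattern!r}")
        return idx

    return Selection(indices_a=match(pattern_a), indices_b=match(pattern_b))


# ---------------------------------------------------------------------------
# XYZB internal text format
# ---------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory to the internal XYZB text format.

    Coordinates are printed with 17 significant digits so that the
    write→read round trip reproduces the floating-point values exactly.
    """
    path = Path(path)
    if traj.n_frames == 0:  # Trajectory forbids this, but guard the contract
        raise TrajectoryFormatError("no frames")
    leaflets = (traj.leaflet_tags if traj.leaflet_tags is not None
                else np.full(traj.n_beads, "none", dtype=object))
    lines = []
    for fi in range(traj.n_frames):
        box = traj.boxes[fi]
        lines.append(f"#frame {fi} {traj.times[fi]:.17g} "
                     f"{box[0]:.17g} {box[1]:.17g} {box[2]:.17g}")
        xyz = traj.coords[fi]
        for bi in range(traj.n_beads):
            lines.append(
                f"{traj.bead_labels[bi]} {traj.molecule_ids[bi]} {leaflets[bi]} "
                f"{xyz[bi, 0]:.17g} {xyz[bi, 1]:.17g} {xyz[bi, 2]:.17g}")
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write trajectory to {path}: {exc}") from exc


def _read_xyzb(path: Path) -> Trajectory:
    try:
        text = path.read_text()
    except OSError as exc:
        raise OSError(f"cannot read trajectory from {path}: {exc}") from exc

    times, boxes, frames_xyz = [], [], []
    labels, mols, leaflets = None, None, None
    cur_xyz = None
    cur_meta = None  # (labels, mols, leaflets) of current frame

    def close_frame():
        nonlocal cur_xyz, cur_meta, labels, mols, leaflets
        if cur_xyz is None:
            return
        if labels is None:
            labels, mols, leaflets = cur_meta
        elif list(cur_meta[0]) != list(labels):
            raise TrajectoryFormatError(
                f"{path}: bead labels differ between frames")
        if frames_xyz and len(cur_xyz) != len(frames_xyz[0]):
            raise TrajectoryFormatError(
                f"{path}: inconsistent bead counts across frames")
        frames_xyz.append(cur_xyz)
        cur_xyz, cur_meta = None, None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#frame"):
            close_frame()
            parts = line.split()
            if len(parts) != 6:
                raise TrajectoryFormatError(
                    f"{path}:{lineno}: malformed frame header")
            times.append(float(parts[2]))
            boxes.append([float(parts[3]), float(parts[4]), float(parts[5])])
            cur_xyz = []
            cur_meta = ([], [], [])
        elif line.startswith("#"):
            continue
        else:
            if cur_xyz is None:
                raise TrajectoryFormatError(
                    f"{path}:{lineno}: bead line before any #frame header")
            parts = line.split()
            if len(parts) != 6:
                raise TrajectoryFormatError(
                    f"{path}:{lineno}: expected 6 fields per bead line")
            name, mol, leaflet = parts[0], int(parts[1]), parts[2]
            if leaflet not in _LEAFLET_VALUES:
                raise TrajectoryFormatError(
                    f"{path}:{lineno}: leaflet must be one of {_LEAFLET_VALUES}")
            cur_meta[0].append(name)
            cur_meta[1].append(mol)
            cur_meta[2].append(leaflet)
            cur_xyz.append([float(parts[3]), float(parts[4]), float(parts[5])])
    close_frame()

    if not frames_xyz:
        raise TrajectoryFormatError(f"{path}: no frames")
    leaflet_arr = (None if all(x == "none" for x in leaflets)
                   else np.asarray(leaflets, dtype=object))
    return Trajectory(
        coords=np.asarray(frames_xyz, dtype=float),
        times=np.asarray(times, dtype=float),
        boxes=np.asarray(boxes, dtype=float),
        bead_labels=np.asarray(labels, dtype=object),
        molecule_ids=np.asarray(mols, dtype=int),
        leaflet_tags=leaflet_arr,
        metadata={"source": str(path), "format": "xyzb"},
    )


# ---------------------------------------------------------------------------
# Standard MD formats via MDAnalysis
# ---------------------------------------------------------------------------

def _scan_pdb_cryst1(path: Path):
    """Return the first CRYST1 record of a PDB file as MDA-style dimensions."""
    try:
        with open(path) as fh:
            for line in fh:
                if line.startswith("CRYST1"):
                    vals = [float(line[6:15]), float(line[15:24]),
                            float(line[24:33]), float(line[33:40]),
                            float(line[40:47]), float(line[47:54])]
                    return np.asarray(vals, dtype=float)
    except (OSError, ValueError):
        return None
    return None


def _read_mdanalysis(path: Path, topology, format_hint) -> Trajectory:
    import MDAnalysis as mda

    try:
        if topology is not None:
            u = mda.Universe(str(topology), str(path))
        else:
            u = mda.Universe(str(path))
    except OSError as exc:
        raise OSError(f"cannot read trajectory from {path}: {exc}") from exc
    except Exception as exc:  # MDA raises assorted parser errors
        raise TrajectoryFormatError(f"cannot parse {path}: {exc}") from exc

    atoms = u.atoms
    labels = np.asarray([str(n) for n in atoms.names], dtype=object)
    try:
        mols = np.asarray(atoms.resids, dtype=int)
    except (mda.exceptions.NoDataError, AttributeError):
        mols = np.arange(len(atoms), dtype=int)

    # Multi-model PDBs often carry a single header CRYST1 outside any MODEL
    # block, which frame-wise readers miss; scan for it as a fallback box.
    fallback_dims = None
    if path.suffix.lower() == ".pdb":
        fallback_dims = _scan_pdb_cryst1(path)

    coords, times, boxes = [], [], []
    for ts in u.trajectory:
        dims = ts.dimensions
        if dims is None or not np.all(dims[:3] > 0):
            dims = fallback_dims
        if dims is None or not np.all(dims[:3] > 0):
            raise TrajectoryFormatError(
                f"{path}: no box information in frame {ts.frame}; supply a "
                "topology or trajectory that records the periodic box")
        angles = dims[3:6]
        if not np.allclose(angles, 90.0, atol=1e-3):
            raise TrajectoryFormatError(
                f"{path}: triclinic boxes are not supported "
                f"(angles {angles}); only orthorhombic boxes are accepted")
        if ts.positions.shape[0] != len(atoms):
            raise TrajectoryFormatError(
                f"{path}: inconsistent bead counts across frames")
        coords.append(ts.positions / _A_PER_NM)
        boxes.append(np.asarray(dims[:3], dtype=float) / _A_PER_NM)
        times.append(float(ts.time))  # MDAnalysis native time unit is ps

    times = np.asarray(times, dtype=float)
    if len(times) > 1 and np.allclose(times, times[0]):
        # Some readers report no time information; fall back to frame index.
        times = np.arange(len(times), dtype=float)

    return Trajectory(
        coords=np.asarray(coords, dtype=float),
        times=times,
        boxes=np.asarray(boxes, dtype=float),
        bead_labels=labels,
        molecule_ids=mols,
        leaflet_tags=None,
        metadata={"source": str(path), "format": format_hint or path.suffix.lstrip(".")},
    )


def read_trajectory(path, topology=None, format_hint: str | None = None) -> Trajectory:
    """Read a trajectory file, converting coordinates to nm and times to ps.

    Formats: internal XYZB (``.xyzb``), GRO, multi-model PDB, and XTC/TRR/DCD
    frame files combined with a ``topology`` (GRO/PDB) that carries bead
    names and molecule ids. ``format_hint`` overrides extension sniffing
    (accepts ``"xyzb"`` or any MDAnalysis format name).
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"cannot read trajectory from {path}: file does not exist")
    fmt = (format_hint or path.suffix.lstrip(".")).lower()
    if fmt == "xyzb":
        return _read_xyzb(path)
    return _read_mdanalysis(path, topology, format_hint)
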