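import math

import numpy as np
import pytest

import vanhove as vh


@pytest.fixture
def tiny_traj():
    """4 beads (2 lipids), 2 frames, 10 nm box — hand-checkable."""
    coords = np.array([
        [[1.0, 1.0, 1.0], [1.0, 1.0, 3.0], [4.0, 4.0, 4.0], [4.0, 4.0, 6.0]],
        [[1.5, 1.0, 1.0], [1.5, 1.0, 3.0], [4.0, 4.5, 4.0], [4.0, 4.5, 6.0]],
    ])
    return vh.Trajectory(
        coords=coords,
        times=np.array([0.0, 2.0]),
        boxes=np.full((2, 3), 10.0),
        bead_labels=np.array(["NC3", "PO4", "NC3", "PO4"], dtype=object),
        molecule_ids=np.array([0, 0, 1, 1]),
    )


def brute_force_counts(traj, sel, mode, axis_or_plane, r_max, dr,
                       lag_frames, origin_stride=1, pair_scope="all"):
    """Independent pair-histogram oracle: plain triple loop, no numpy math.

    Uses its own minimal-image wrap and half-open binning; meant for tiny
    instances only.
    """
    axes = {"1D": {"x": [0], "y": [1], "z": [2]}[axis_or_plane] if mode == "1D"
            else None,
            "2D": {"xy": [0, 1], "xz": [0, 2], "yz": [1, 2]}.get(axis_or_plane)
            if mode == "2D" else None,
            "3D": [0, 1, 2]}[mode]
    n_bins = int(round(r_max / dr))
    out = np.zeros((len(lag_frames), n_bins), dtype=int)
    mols = traj.molecule_ids
    for li, lag in enumerate(lag_frames):
        for t0 in range(0, traj.n_frames - lag, origin_stride):
            for ia in sel.indices_a:
                for ib in sel.indices_b:
                    same = mols[ia] == mols[ib]
                    if pair_scope == "intra" and not same:
                        continue
                    if pair_scope == "inter" and same:
                        continue
                    sq = 0.0
                    for ax in axes:
                        d = (traj.coords[t0 + lag, ia, ax]
                             - traj.coords[t0, ib, ax])
                        L = traj.boxes[t0, ax]
                        d -= L * math.floor(d / L + 0.5)
                        sq += d * d
                    dist = math.sqrt(sq)
                    b = int(dist // dr)
                    if b < n_bins:
                        out[li, b] += 1
    return out
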