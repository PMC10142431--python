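import math

import numpy as np
import pytest
from scipy import stats

import vanhove as vh
from conftest import brute_force_counts


def _random_instance(rng):
    """Tiny random trajectory + selection + grid settings."""
    n_beads = rng.integers(2, 11)
    n_frames = rng.integers(2, 6)
    box = rng.uniform(2.0, 8.0, size=3)
    coords = rng.uniform(-1.0, 1.0, size=(n_frames, n_beads, 3)) * box * 1.5
    labels = rng.choice(["NC3", "PO4"], size=n_beads)
    if "NC3" not in labels:
        labels[0] = "NC3"
    if "PO4" not in labels:
        labels[-1] = "PO4"
    mols = rng.integers(0, max(2, n_beads // 2), size=n_beads)
    traj = vh.Trajectory(coords=coords,
                         times=np.arange(n_frames, dtype=float),
                         boxes=np.tile(box, (n_frames, 1)),
                         bead_labels=labels.astype(object),
                         molecule_ids=mols)
    return traj


class TestSinglePairClosedForms:
    def test_1d_single_pair(self):
        """1 A at z=1, 1 B at z=3, Lz=10, dr=0.1: G = 10/(2*0.1) = 50."""
        coords = np.array([[[5.0, 5.0, 1.0], [5.0, 5.0, 3.0]]])
        coords = np.repeat(coords, 2, axis=0)
        traj = vh.Trajectory(coords=coords, times=np.array([0.0, 1.0]),
                             boxes=np.full((2, 3), 10.0),
                             bead_labels=np.array(["NC3", "PO4"], dtype=object),
                             molecule_ids=np.array([0, 1]))
        sel = vh.select_beads(traj, "NC3", "PO4")
        g = vh.compute_vanhove(traj, sel, "1D", "z", r_max=5.0, dr=0.1,
                               max_lag=0.0, origin_stride=10)
        bin20 = np.flatnonzero(g.counts[0])
        assert list(bin20) == [20]  # [2.0, 2.1)
        assert g.values[0, 20] == pytest.approx(50.0)
        assert g.counts[0].sum() == 1

    def test_1d_literal_convention_doubles(self):
        coords = np.repeat(np.array([[[5.0, 5.0, 1.0], [5.0, 5.0, 3.0]]]),
                           2, axis=0)
        traj = vh.Trajectory(coords=coords, times=np.array([0.0, 1.0]),
                             boxes=np.full((2, 3), 10.0),
                             bead_labels=np.array(["NC3", "PO4"], dtype=object),
                             molecule_ids=np.array([0, 1]))
        sel = vh.select_beads(traj, "NC3", "PO4")
        g = vh.compute_vanhove(traj, sel, "1D", "z", r_max=5.0, dr=0.1,
                               max_lag=0.0, origin_stride=10, literal_1d=True)
        assert g.values[0, 20] == pytest.approx(100.0)

    def test_3d_single_pair(self):
        """Single A-B pair 0.32 nm apart, 2 nm box: G ~= 51.62 in [0.3, 0.4).

        (Mid-bin separation: a distance sitting exactly on a bin edge is
        assigned by floating-point division, as in numpy's histogram.)
        """
        coords = np.repeat(np.array([[[0.0, 0.0, 0.0], [0.32, 0.0, 0.0]]]),
                           2, axis=0)
        traj = vh.Trajectory(coords=coords, times=np.array([0.0, 1.0]),
                             boxes=np.full((2, 3), 2.0),
                             bead_labels=np.array(["PO4", "NC3"], dtype=object),
                             molecule_ids=np.array([0, 1]))
        sel = vh.select_beads(traj, "NC3", "PO4")
        g = vh.compute_vanhove(traj, sel, "3D", r_max=1.0, dr=0.1,
                               max_lag=0.0, origin_stride=10)
        expected = 8.0 / ((4 * math.pi / 3) * (0.4 ** 3 - 0.3 ** 3))
        assert g.values[0, 3] == pytest.approx(expected, rel=1e-12)
        assert g.counts[0].sum() == 1


class TestBruteForceOracle:
    """Exact count equality against a plain triple-loop pair histogram."""

    @pytest.mark.parametrize("mode, axis", [
        ("1D", "x"), ("1D", "z"), ("2D", "xy"), ("2D", "yz"), ("3D", None)])
    @pytest.mark.parametrize("pair_scope", ["all", "intra", "inter"])
    def test_counts_match_brute_force(self, mode, axis, pair_scope):
        import zlib
        rng = np.random.default_rng(
            zlib.crc32(f"{mode}/{axis}/{pair_scope}".encode()))
        checked = 0
        for _ in range(20):
            traj = _random_instance(rng)
            sel = vh.select_beads(traj, "NC3", "PO4")
            r_max = float(traj.boxes[0].min()) / 2 * 0.95
            dr = r_max / rng.integers(3, 12)
            max_lagf = int(rng.integers(0, traj.n_frames - 1))
            stride = int(rng.integers(1, 3))
            try:
                grid = vh.compute_vanhove(
                    traj, sel, mode, axis, r_max=r_max, dr=dr,
                    max_lag=float(max_lagf), origin_stride=stride,
                    pair_scope=pair_scope)
            except ValueError:
                continue  # e.g. scope leaves no pairs
            lag_frames = [int(round(l)) for l in grid.lags]
            expected = brute_force_counts(traj, sel, mode, axis,
                                          grid.r_edges[-1], dr, lag_frames,
                                          origin_stride=stride,
                                          pair_scope=pair_scope)
            np.testing.assert_array_equal(grid.counts, expected)
            checked += 1
        assert checked >= 10

    def test_autocorrelation_selection(self):
        rng = np.random.default_rng(77)
        traj = _random_instance(rng)
        sel = vh.select_beads(traj, "NC3", "NC3")
        grid = vh.compute_vanhove(traj, sel, "3D", r_max=1.0, dr=0.2,
                                  max_lag=1.0)
        expected = brute_force_counts(traj, sel, "3D", None,
                                      grid.r_edges[-1], 0.2, [0, 1])
        np.testing.assert_array_equal(grid.counts, expected)


class TestNormalization:
    def test_values_recomputable_from_counts(self):
        spec = vh.SynthSpec(kind="uniform_gas", n_sites=30, n_frames=8,
                            box=(5.0, 5.0, 5.0), frame_spacing=1.0, seed=2)
        traj = vh.generate(spec)
        sel = vh.select_beads(traj, "NC3", "PO4")
        g = vh.compute_vanhove(traj, sel, "2D", "xy", r_max=2.0, dr=0.1,
                               max_lag=3.0)
        m = g.norm_meta
        recomputed = (g.counts * (m["geom_mean"]
                                  / (m["n_a"] * m["n_b"] * m["n_origins"]
                                     * m["fold_factor"]))[:, None]
                      / m["bin_measures"][None, :])
        np.testing.assert_allclose(g.values, recomputed, rtol=1e-12)

    def test_counts_bounded_by_pair_budget(self):
        spec = vh.SynthSpec(kind="uniform_gas", n_sites=20, n_frames=6,
                            box=(5.0, 5.0, 5.0), frame_spacing=1.0, seed=2)
        traj = vh.generate(spec)
        sel = vh.select_beads(traj, "NC3", "PO4")
        g = vh.compute_vanhove(traj, sel, "3D", r_max=2.0, dr=0.1, max_lag=2.0)
        budget = sel.n_a * sel.n_b * g.norm_meta["n_origins"]
        assert np.all(g.counts.sum(axis=1) <= budget)

    @pytest.mark.parametrize("mode, expected", [
        ("1D", 1.0), ("2D", 1.0), ("3D", 1.0)])
    def test_uniform_baseline_folded(self, mode, expected):
        assert vh.uniform_baseline(mode) == expected

    def test_uniform_baseline_literal_1d(self):
        """Brute-force uniform pairs: literal prefactor gives baseline 2."""
        rng = np.random.default_rng(5)
        L, n = 10.0, 4000
        a, b = rng.uniform(0, L, n), rng.uniform(0, L, n)
        d = np.abs(vh.minimal_image(a - b, L))
        hist, edges = np.histogram(d, bins=25, range=(0, L / 2))
        g_literal = hist * L / (n * np.diff(edges))
        assert np.mean(g_literal) == pytest.approx(2.0, rel=0.1)
        assert vh.uniform_baseline("1D", literal_1d=True) == 2.0


class TestUniformGasBaseline:
    def test_mean_g_matches_baseline_all_modes(self):
        spec = vh.SynthSpec(kind="uniform_gas", n_sites=100, n_frames=20,
                            box=(6.0, 6.0, 6.0), frame_spacing=1.0, seed=10)
        traj = vh.generate(spec)
        sel = vh.select_beads(traj, "NC3", "PO4")
        for mode, axis in (("1D", "x"), ("2D", "xy"), ("3D", None)):
            g = vh.compute_vanhove(traj, sel, mode, axis, r_max=2.5, dr=0.25,
                                   max_lag=5.0)
            for li in range(g.lags.size):
                total = g.counts[li].sum()
                mean_g = np.average(g.values[li],
                                    weights=g.norm_meta["bin_measures"])
                # measure-weighted mean G estimates total/E[total]: Poisson SE
                assert abs(mean_g - 1.0) < 4.0 / math.sqrt(total)

    def test_lateral_isotropy(self):
        """1D G along x and y statistically identical for an isotropic gas."""
        spec = vh.SynthSpec(kind="uniform_gas", n_sites=150, n_frames=30,
                            box=(6.0, 6.0, 6.0), frame_spacing=1.0, seed=12)
        traj = vh.generate(spec)
        sel = vh.select_beads(traj, "NC3", "PO4")
        gx = vh.compute_vanhove(traj, sel, "1D", "x", r_max=2.5, dr=0.25,
                                max_lag=2.0)
        gy = vh.compute_vanhove(traj, sel, "1D", "y", r_max=2.5, dr=0.25,
                                max_lag=2.0)
        n = gx.counts.sum()
        se = 3.0 / math.sqrt(n / gx.counts.shape[1])
        assert np.max(np.abs(gx.values - gy.values)) < 3 * se + 0.05


class TestSelfPart:
    def test_brownian_self_part_folded_gaussian(self):
        """Intra-pair 1D G(r,t) is half-normal with variance 2*D*t."""
        D = 0.05
        spec = vh.SynthSpec(kind="brownian", n_sites=150, n_frames=200,
                            box=(30.0, 30.0, 30.0), frame_spacing=2.0,
                            seed=14, diffusion=D)
        traj = vh.generate(spec)
        sel = vh.select_beads(traj, "NC3", "NC3")
        g = vh.compute_vanhove(traj, sel, "1D", "x", r_max=15.0, dr=0.05,
                               max_lag=20.0, pair_scope="intra")
        for tlag in (2.0, 10.0, 20.0):
            li = int(np.argmin(np.abs(g.lags - tlag)))
            sigma = math.sqrt(2 * D * tlag)
            emp_cdf = np.cumsum(g.counts[li]) / g.counts[li].sum()
            th_cdf = 2 * stats.norm.cdf(g.r_edges[1:] / sigma) - 1
            assert np.max(np.abs(emp_cdf - th_cdf)) < 0.02

    def test_lag0_intra_peak_at_np_offset(self):
        """All lag-0 intra weight sits in the bin containing the N-P offset."""
        spec = vh.SynthSpec(kind="brownian", n_sites=30, n_frames=5,
                            box=(8.0, 8.0, 8.0), frame_spacing=1.0, seed=6,
                            diffusion=0.1, np_offset=0.55)
        traj = vh.generate(spec)
        sel = vh.select_beads(traj, "NC3", "PO4")
        g = vh.compute_vanhove(traj, sel, "1D", "z", r_max=2.0, dr=0.1,
                               max_lag=0.0, pair_scope="intra")
        assert g.counts[0, 5] == g.counts[0].sum()  # bin [0.5, 0.6)


class TestDisplayNormalization:
    def _grid(self):
        spec = vh.SynthSpec(kind="uniform_gas", n_sites=20, n_frames=5,
                            box=(5.0, 5.0, 5.0), frame_spacing=1.0, seed=1)
        traj = vh.generate(spec)
        sel = vh.select_beads(traj, "NC3", "PO4")
        return vh.compute_vanhove(traj, sel, "3D", r_max=2.0, dr=0.2,
                                  max_lag=2.0)

    def test_rescaled_to_unit_interval(self):
        g = self._grid()
        shown = vh.normalize_for_display(g)
        assert shown.values.min() == 0.0
        assert shown.values.max() == 1.0
        np.testing.assert_array_equal(shown.norm_meta["raw_values"], g.values)

    def test_constant_grid_maps_to_zero(self):
        g = self._grid()
        g.values[:] = 3.0
        shown = vh.normalize_for_display(g)
        assert np.all(shown.values == 0.0)

    def test_argmax_preserved(self):
        g = self._grid()
        shown = vh.normalize_for_display(g)
        assert np.argmax(shown.values) == np.argmax(g.values)


class TestPreconditions:
    def _traj(self):
        spec = vh.SynthSpec(kind="uniform_gas", n_sites=10, n_frames=5,
                            box=(4.0, 4.0, 4.0), frame_spacing=1.0, seed=0)
        return vh.generate(spec)

    def test_rmax_beyond_half_box(self):
        traj = self._traj()
        sel = vh.select_beads(traj, "NC3", "PO4")
        with pytest.raises(ValueError, match="minimal-image ambiguity"):
            vh.compute_vanhove(traj, sel, "3D", r_max=3.0, dr=0.1, max_lag=1.0)

    def test_max_lag_beyond_duration(self):
        traj = self._traj()
        sel = vh.select_beads(traj, "NC3", "PO4")
        with pytest.raises(ValueError, match="duration"):
            vh.compute_vanhove(traj, sel, "3D", r_max=1.0, dr=0.1, max_lag=10.0)

    def test_incommensurate_lag(self):
        traj = self._traj()
        sel = vh.select_beads(traj, "NC3", "PO4")
        with pytest.raises(ValueError, match="multiple"):
            vh.compute_vanhove(traj, sel, "3D", r_max=1.0, dr=0.1, max_lag=1.5)

    def test_1d_requires_axis(self):
        traj = self._traj()
        sel = vh.select_beads(traj, "NC3", "PO4")
        with pytest.raises(ValueError, match="axis"):
            vh.compute_vanhove(traj, sel, "1D", None, r_max=1.0, dr=0.1,
                               max_lag=1.0)


class TestGridTsvRoundTrip:
    def test_round_trip(self, tmp_path):
        spec = vh.SynthSpec(kind="uniform_gas", n_sites=15, n_frames=4,
                            box=(5.0, 5.0, 5.0), frame_spacing=1.0, seed=3)
        traj = vh.generate(spec)
        sel = vh.select_beads(traj, "NC3", "PO4")
        g = vh.compute_vanhove(traj, sel, "2D", "xz", r_max=2.0, dr=0.1,
                               max_lag=2.0, pair_scope="inter")
        path = tmp_path / "g.tsv"
        vh.write_grid_tsv(g, path)
        back = vh.read_grid_tsv(path)
        assert back.mode == "2D" and back.axis_or_plane == "xz"
        assert back.pair_scope == "inter"
        np.testing.assert_allclose(back.values, g.values)
        np.testing.assert_allclose(back.counts, g.counts)
        np.testing.assert_allclose(back.r_edges, g.r_edges)
        np.testing.assert_allclose(back.lags, g.lags)
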