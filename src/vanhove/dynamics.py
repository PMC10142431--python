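"""First-peak time series and power spectra of Van Hove grids.

The collective-motion analyses of this package reduce a G(r, t) grid to a
one-dimensional observable — the height (and position) of the first
coordination-shell peak as a function of lag — and then Fourier-analyse
that trace to locate the GHz-band frequencies of the underlying motion
(lateral rattling of the headgroup dipoles; slower out-of-plane
surface-undulation modes along the bilayer normal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PeakTrace", "Spectrum", "peak_trace", "power_spectrum", "band_edges"]

#: 1 ps^-1 in GHz.
GHZ_PER_INV_PS = 1000.0


@dataclass
class PeakTrace:
    """First-peak height/position versus lag over a distance window."""

    lags: np.ndarray        # ps, strictly increasing, uniform
    heights: np.ndarray     # G values, >= 0
    positions: np.ndarray   # nm, within r_window
    r_window: tuple         # (r_lo, r_hi) searched

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.heights < 0):
            raise ValueError("peak heights must be non-negative")

    @property
    def lag_spacing(self) -> float:
        return float(self.lags[1] - self.lags[0])


@dataclass
class Spectrum:
    """One-sided power spectrum: frequencies in GHz from 0 to Nyquist."""

    frequencies: np.ndarray
    power: np.ndarray
    window_name: str = "none"
    detrend_flag: bool = True

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


def peak_trace(grid, r_lo: float, r_hi: float, refine: bool = False) -> PeakTrace:
    """Track the maximum of G over the window ``[r_lo, r_hi)`` per lag.

    Height is the maximum G over the window's bins and position the bin
    center of the argmax (ties broken toward smaller r). With
    ``refine=True`` a 3-point parabolic interpolation through the argmax
    and its in-window neighbours sharpens both height and position.

    To extract a trace "along r ≈ r0" (a fixed-shell trace rather than a
    first-peak search), pass a window of one-bin half-width around r0.
    """
    centers = grid.r_centers
    mask = (centers >= r_lo) & (centers < r_hi)
    if not np.any(mask):
        raise ValueError(f"window [{r_lo}, {r_hi}) overlaps no grid bins")
    win_idx = np.flatnonzero(mask)
    sub = grid.values[:, win_idx]

    arg = np.argmax(sub, axis=1)  # first max -> smaller r on ties
    heights = sub[np.arange(sub.shape[0]), arg].astype(float)
    positions = centers[win_idx[arg]].astype(float)

    if refine:
        dr = grid.dr
        for li in range(sub.shape[0]):
            k = arg[li]
            if 0 < k < sub.shape[1] - 1:
                ym, y0, yp = sub[li, k - 1], sub[li, k], sub[li, k + 1]
                denom = ym - 2.0 * y0 + yp
                if denom < 0:  # proper maximum
                    shift = 0.5 * (ym - yp) / denom
                    positions[li] += shift * dr
                    heights[li] = y0 - 0.25 * (ym - yp) * shift

    return PeakTrace(lags=grid.lags.copy(), heights=heights,
                     positions=positions, r_window=(float(r_lo), float(r_hi)))


def _as_series(trace_or_series, spacing_ps):
    if isinstance(trace_or_series, PeakTrace):
        return trace_or_series.heights, trace_or_series.lag_spacing
    series = np.asarray(trace_or_series, dtype=float)
    if spacing_ps is None:
        raise ValueError("spacing_ps is required for a plain series")
    return series, float(spacing_ps)


def power_spectrum(trace_or_series, spacing_ps: float | None = None, *,
                   window: str = "none", detrend: bool = True) -> Spectrum:
    """One-sided power spectrum of a peak trace or plain uniform series.

    The mean is subtracted when ``detrend`` is true (default), then the
    chosen taper ({'none', 'hann'}) is applied. Normalization is such that
    a unit-amplitude cosine at an exact bin frequency concentrates its
    power (1/2) in that bin; with ``window='none'`` the one-sided power
    sums to the series variance (Parseval).
    """
    series, spacing = _as_series(trace_or_series, spacing_ps)
    n = series.size
    if n < 8:
        raise ValueError("series must have at least 8 samples")
    if not np.all(np.isfinite(series)):
        raise ValueError("series must be finite")
    if isinstance(trace_or_series, PeakTrace):
        dl = np.diff(trace_or_series.lags)
        if np.max(np.abs(dl - dl[0])) > 1e-6 * abs(dl[0]):
            raise ValueError("non-uniform lags")

    x = series - series.mean() if detrend else series.astype(float)
    if window == "hann":
        w = np.hanning(n)
    elif window == "none":
        w = np.ones(n)
    else:
        raise ValueError("window must be 'none' or 'hann'")

    X = np.fft.rfft(x * w)
    scale = np.sum(w)  # = n for the boxcar; amplitude-preserving for tapers
    power = (np.abs(X) / scale) ** 2
    power[1:] *= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0  # Nyquist bin is not duplicated
    freqs = np.fft.rfftfreq(n, d=spacing) * GHZ_PER_INV_PS
    return Spectrum(frequencies=freqs, power=power,
                    window_name=window, detrend_flag=detrend)


def band_edges(spec: Spectrum, threshold_fraction: float = 0.05):
    """Frequency band where power >= threshold_fraction × max power.

    The zero-frequency bin is excluded both from the maximum and from the
    band. Returns ``(f_lo, f_hi)`` in GHz — the lowest and highest
    frequencies meeting the threshold.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must be in (0, 1)")
    p = spec.power[1:]
    f = spec.frequencies[1:]
    pmax = p.max() if p.size else 0.0
    if pmax <= 0.0:
        raise ValueError("no band: spectrum is identically zero")
    above = np.flatnonzero(p >= threshold_fraction * pmax)
    return float(f[above[0]]), float(f[above[-1]])
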