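"""LFP-proxy spectral analysis.

The LFP proxy of a layer is its pyramidal-population rate.  Spectra are
multitaper estimates (discrete prolate spheroidal sequence tapers) restricted
to 1-250 Hz, smoothed with a short moving average and normalized to unit sum
over the analyzed band, after discarding an initial transient.  Oscillation
peaks are the largest qualifying local maximum at or above 10 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .model import RateTrace

__all__ = ["PowerSpectrum", "SpectralPeak", "compute_psd", "find_peak"]

#: Peaks below this frequency (Hz) are never reported.
MIN_PEAK_FREQ = 10.0


@dataclass
class PowerSpectrum:
    """Normalized multitaper power spectrum of a layer's LFP proxy."""

    frequencies: np.ndarray     # Hz, within the analyzed band
    power: np.ndarray           # normalized, sums to 1 over the band
    layer: str
    n_trials: int = 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frequency": self.frequencies,
            "power": self.power,
            "layer": self.layer,
            "n_trials": self.n_trials,
        })


@dataclass
class SpectralPeak:
    """Dominant oscillation peak (>= 10 Hz) of a normalized spectrum."""

    frequency: float
    power: float
    found: bool


def _taper_psd(x: np.ndarray, fs: float, nw: float, n_tapers: int) -> tuple[np.ndarray, np.ndarray]:
    n = x.size
    tapers = signal.windows.dpss(n, nw, Kmax=n_tapers)
    x = x - x.mean()
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = np.abs(np.fft.rfft(tapers * x[None, :], axis=1)) ** 2
    return freqs, spec.mean(axis=0)


def compute_psd(
    trace: RateTrace | Sequence[RateTrace],
    layer: str,
    nw: float = 3.0,
    n_tapers: int = 5,
    band: tuple[float, float] = (1.0, 250.0),
    smooth_bins: int = 5,
    discard_ms: float = 500.0,
) -> PowerSpectrum:
    """Multitaper power spectrum of the layer's pyramidal rate.

    Accepts a single trace or a sequence of trials; per-trial spectra are
    averaged before smoothing and normalization.  The first ``discard_ms`` of
    each trial are dropped as a settling transient.  Raises ``ValueError``
    when the retained segment is shorter than one second (too little
    frequency resolution for the 1-250 Hz band).
    """
    traces = [trace] if isinstance(trace, RateTrace) else list(trace)
    if not traces:
        raise ValueError("no traces supplied")
    psd_sum = None
    freqs = None
    for tr in traces:
        keep = tr.time >= discard_ms
        x = tr.layer_lfp(layer)[keep]
        dt_ms = tr.time[1] - tr.time[0]
        fs = 1000.0 / dt_ms
        if x.size * dt_ms < 1000.0:
            raise ValueError(
                f"trace segment of {x.size * dt_ms:.0f} ms after transient "
                "removal is too short; need at least 1 s")
        f, p = _taper_psd(x, fs, nw, n_tapers)
        psd_sum = p if psd_sum is None else psd_sum + p
        freqs = f
    psd = psd_sum / len(traces)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    fb, pb = freqs[in_band], psd[in_band]
    if smooth_bins > 1:
        pb = uniform_filter1d(pb, size=smooth_bins, mode="nearest")
    total = pb.sum()
    if total > 0:
        pb = pb / total
    return PowerSpectrum(frequencies=fb, power=pb, layer=layer,
                         n_trials=len(traces))


def find_peak(
    spec: PowerSpectrum,
    min_freq: float = MIN_PEAK_FREQ,
    prominence_ratio: float = 1.5,
) -> SpectralPeak:
    """Largest qualifying local maximum of the spectrum at >= ``min_freq``.

    A peak qualifies when its normalized power is at least
    ``prominence_ratio`` times the band-median power — the operational
    definition of a "visible" oscillation peak.  ``found`` is False when no
    local maximum qualifies.
    """
    f, p = spec.frequencies, spec.power
    idx, _ = signal.find_peaks(p)
    median = float(np.median(p))
    good = [i for i in idx if f[i] >= min_freq and p[i] >= prominence_ratio * median]
    if not good:
        return SpectralPeak(frequency=np.nan, power=np.nan, found=False)
    k = max(good, key=lambda i: p[i])
    return SpectralPeak(frequency=float(f[k]), power=float(p[k]), found=True)
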