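"""Log-log power-spectral slopes of trial-indexed behavioral series.

Repeated estimates (and response times) form a time series over trials.
Its periodogram, fit by ordinary least squares on log10 power versus log10
frequency, classifies the serial structure: white noise is flat (slope 0), a
random walk falls off as 1/f^2 (slope -2), and long-range-dependent human
data typically sit in between, in the 1/f band with slopes between -1.5 and
-0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SeriesSpectrum:
    frequencies: np.ndarray  # cycles per trial, DC excluded
    power: np.ndarray
    slope: float
    intercept: float

    def classify(self) -> str:
        return classify_noise(self.slope)


def power_spectrum(series, freq_band: tuple | None = None) -> SeriesSpectrum:
    """Mean-detrended periodogram with an OLS log-log slope.

    Plain periodogram over the Fourier frequencies k/N, k = 1..N/2 (no
    tapering or averaging). ``freq_band=(lo, hi)`` optionally restricts the
    frequencies entering the slope fit.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 64:
        raise ValueError("need a 1-d series of length >= 64")
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be finite")
    x = x - x.mean()
    if np.allclose(x, 0.0):
        raise ValueError("constant series has no spectrum to fit")
    n = x.size
    spec = np.abs(np.fft.rfft(x)) ** 2 / n
    freqs = np.fft.rfftfreq(n)
    freqs, spec = freqs[1:n // 2 + 1], spec[1:n // 2 + 1]
    keep = spec > 0
    if freq_band is not None:
        keep &= (freqs >= freq_band[0]) & (freqs <= freq_band[1])
    lf, lp = np.log10(freqs[keep]), np.log10(spec[keep])
    slope, intercept = np.polyfit(lf, lp, 1)
    return SeriesSpectrum(frequencies=freqs, power=spec,
                          slope=float(slope), intercept=float(intercept))


def classify_noise(slope: float) -> str:
    """Map a fitted slope onto a noise class.

    ``one_over_f`` for slopes in [-1.5, -0.5] (the long-range-dependence band
    reported for human behavioral series), ``white`` for |slope| < 0.25,
    ``random_walk`` for slopes <= -1.75, otherwise ``unclassified``.
    """
    if not np.isfinite(slope):
        raise ValueError("slope must be finite")
    if -1.5 <= slope <= -0.5:
        return "one_over_f"
    if abs(slope) < 0.25:
        return "white"
    if slope <= -1.75:
        return "random_walk"
    return "unclassified"


def spectrum_summary(spectrum: SeriesSpectrum) -> dict:
    """JSON-ready summary of a fitted spectrum."""
    return {"slope": spectrum.slope, "intercept": spectrum.intercept,
            "class": spectrum.classify()}


def spectrum_frame(spectrum: SeriesSpectrum):
    """Frequency/power table (e.g. for CSV export)."""
    import pandas as pd

    return pd.DataFrame({"frequency": spectrum.frequencies,
                         "power": spectrum.power})


def series_from_csv(path) -> np.ndarray:
    """Read a one-column series CSV (header optional)."""
    import pandas as pd

    df = pd.read_csv(path)
    return df.iloc[:, 0].to_numpy(dtype=float)
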