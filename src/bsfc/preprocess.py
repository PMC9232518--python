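"""Raw-trace conditioning: band-pass filtering, daily power
normalization against a diffuse-reflectance (spectralon) standard, and
the cumulative scattering sum.

Day-to-day variation in delivered laser power makes raw scattering
intensities incomparable across experiments. Each day the incident power
at the sample, a reduced power on a 99% spectralon standard, and the
backscattered spectralon intensity are recorded per wavelength; the
normalization factor

    Norm(lambda) = Intensity_spectralon * Power_sample / Power_spectralon

rescales each scattering channel (division) so traces from different
days share a common intensity scale. Fluorescence channels are left
untouched. The three normalized scattering channels are then summed
point-wise into a single cumulative signal, which improves SNR for peak
detection because independent channel noise partially cancels while
co-located pulses add coherently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import CHANNELS, CHANNEL_WAVELENGTH, SCATTER_CHANNELS, FilterSpec

__all__ = [
    "CalibrationRecord",
    "bandpass_filter",
    "filter_segment",
    "normalization_factor",
    "apply_normalization",
    "cumulative_scatter",
    "load_calibration",
]


@dataclass(frozen=True)
class CalibrationRecord:
    """One day's calibration for one scattering wavelength."""

    wavelength_nm: int
    power_sample_mw: float
    power_spectralon_mw: float
    intensity_spectralon: float

    def __post_init__(self) -> None:
        if self.wavelength_nm not in (405, 488, 633):
            raise ValueError(f"unknown scattering wavelength {self.wavelength_nm}")
        if min(
            self.power_sample_mw, self.power_spectralon_mw, self.intensity_spectralon
        ) <= 0:
            raise ValueError("calibration powers and intensity must be positive")


def bandpass_filter(
    x: np.ndarray, spec: FilterSpec, sample_rate_hz: float
) -> np.ndarray:
    """Zero-phase Butterworth band-pass of one channel.

    Forward-backward application (``sosfiltfilt``) doubles the effective
    filter order in magnitude but leaves peak locations unshifted.
    """
    spec.validate(sample_rate_hz)
    x = np.asarray(x, dtype=float)
    if x.size <= 3 * (2 * spec.order + 1):
        raise ValueError("segment too short for the filter order")
    sos = sps.butter(
        spec.order,
        [spec.low_hz, spec.high_hz],
        btype="bandpass",
        fs=sample_rate_hz,
        output="sos",
    )
    return sps.sosfiltfilt(sos, x)


def filter_segment(
    channels: dict[str, np.ndarray], spec: FilterSpec, sample_rate_hz: float
) -> dict[str, np.ndarray]:
    """Apply the band-pass to every channel of a segment."""
    return {
        name: bandpass_filter(sig, spec, sample_rate_hz)
        for name, sig in channels.items()
    }


def normalization_factor(cal: CalibrationRecord) -> float:
    """Daily power-normalization factor for one wavelength."""
    return (
        cal.intensity_spectralon * cal.power_sample_mw / cal.power_spectralon_mw
    )


def apply_normalization(
    channels: dict[str, np.ndarray], factors: dict[int, float]
) -> dict[str, np.ndarray]:
    """Divide each scattering channel by its daily factor.

    ``factors`` maps wavelength (nm) to Norm(lambda). Fluorescence
    channels pass through unchanged.
    """
    out: dict[str, np.ndarray] = {}
    for name, sig in channels.items():
        if name in SCATTER_CHANNELS:
            wl = CHANNEL_WAVELENGTH[name]
            if wl not in factors:
                raise KeyError(f"missing normalization factor for {wl} nm")
            if factors[wl] <= 0:
                raise ValueError(f"normalization factor for {wl} nm must be positive")
            out[name] = np.asarray(sig, dtype=float) / factors[wl]
        else:
            out[name] = np.asarray(sig, dtype=float)
    return out


def cumulative_scatter(channels: dict[str, np.ndarray]) -> np.ndarray:
    """Point-wise sum of the three (normalized) scattering channels."""
    missing = [c for c in SCATTER_CHANNELS if c not in channels]
    if missing:
        raise KeyError(f"missing scattering channels: {missing}")
    return sum(np.asarray(channels[c], dtype=float) for c in SCATTER_CHANNELS)


def load_calibration(path: str) -> dict[str, dict[int, float]]:
    """Read a calibration CSV into per-day factor maps.

    Expected columns: date, wavelength_nm, power_sample_mW,
    power_spectralon_mW, intensity_spectralon. Returns
    ``{date: {wavelength: Norm(lambda)}}``.
    """
    df = pd.read_csv(path)
    out: dict[str, dict[int, float]] = {}
    for _, row in df.iterrows():
        rec = CalibrationRecord(
            wavelength_nm=int(row["wavelength_nm"]),
            power_sample_mw=float(row["power_sample_mW"]),
            power_spectralon_mw=float(row["power_spectralon_mW"]),
            intensity_spectralon=float(row["intensity_spectralon"]),
        )
        out.setdefault(str(row["date"]), {})[rec.wavelength_nm] = (
            normalization_factor(rec)
        )
    return out
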