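"""Acquisition, filtering and model configuration objects.

These dataclasses carry the instrument and pipeline settings that every
stage shares: the digitizer rate, the microfluidic flow geometry that
links pulse width to object size, the band-pass filter design, and the
boosted-tree hyperparameters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

#: Fixed channel order used everywhere: three scattering wavelengths then
#: green (FP1) and red (FP2) fluorescence.
CHANNELS: tuple[str, ...] = ("S405", "S488", "S633", "FP1", "FP2")
SCATTER_CHANNELS: tuple[str, ...] = ("S405", "S488", "S633")

#: Wavelength (nm) associated with each scattering channel.
CHANNEL_WAVELENGTH: dict[str, int] = {"S405": 405, "S488": 488, "S633": 633}


@dataclass(frozen=True)
class AcquisitionConfig:
    """Digitizer and flow-cell settings.

    Parameters
    ----------
    sample_rate_hz
        Digitizer sampling rate (Hz).
    segment_duration_s
        Length of one processing segment in seconds. Traces are handled
        in fixed-length segments so baseline drift can be normalized per
        segment.
    flow_rate_ul_min
        Volumetric sample flow rate Q (uL/min).
    channel_area_um2
        Flow-channel cross-section A (um^2).
    slit_width_um
        Width of the illumination slit (um); an object of diameter d
        produces a pulse spanning the effective diameter d + slit.
    """

    sample_rate_hz: float = 60_000.0
    segment_duration_s: float = 90.0
    flow_rate_ul_min: float = 3.0
    channel_area_um2: float = 900.0
    slit_width_um: float = 5.0

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.channel_area_um2 <= 0:
            raise ValueError("channel_area_um2 must be positive")
        if self.slit_width_um < 0:
            raise ValueError("slit_width_um must be non-negative")
        if self.flow_rate_ul_min <= 0:
            raise ValueError("flow_rate_ul_min must be positive")

    @property
    def segment_length(self) -> int:
        """Segment length in samples (exact integer)."""
        n = self.sample_rate_hz * self.segment_duration_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                "segment_duration_s * sample_rate_hz must be an integer "
                f"number of samples, got {n}"
            )
        return int(round(n))


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass filter design: 2nd-order Butterworth, zero-phase.

    The band (50-6000 Hz by default) removes both baseline drift (DC and
    sub-50-Hz wander) and high-frequency detector noise while passing
    transit pulses, whose characteristic time scale (~0.3-0.6 ms) sits
    comfortably inside the band. Zero-phase (forward-backward)
    application preserves peak locations.
    """

    order: int = 2
    low_hz: float = 50.0
    high_hz: float = 6000.0

    def validate(self, sample_rate_hz: float) -> None:
        nyquist = sample_rate_hz / 2.0
        if not (0 < self.low_hz < self.high_hz < nyquist):
            raise ValueError(
                f"band ({self.low_hz}, {self.high_hz}) Hz must satisfy "
                f"0 < low < high < Nyquist ({nyquist} Hz)"
            )


@dataclass(frozen=True)
class BoostHyperparams:
    """Gentle-AdaBoost ensemble hyperparameters.

    ``max_splits`` caps the number of internal splits per regression
    tree, ``n_learning_cycles`` the number of boosting iterations, and
    ``learning_rate`` is the shrinkage applied to each weak learner.
    """

    n_learning_cycles: int = 84
    max_splits: int = 102
    learning_rate: float = 0.899

    def __post_init__(self) -> None:
        if self.n_learning_cycles < 1:
            raise ValueError("n_learning_cycles must be >= 1")
        if self.max_splits < 1:
            raise ValueError("max_splits must be >= 1")
        if not (0 < self.learning_rate <= 1):
            raise ValueError("learning_rate must be in (0, 1]")


def to_dict(obj: Any) -> dict:
    return dataclasses.asdict(obj)


def save_yaml(obj: Any, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(obj), fh, sort_keys=False)


def load_yaml(cls: type, path: str) -> Any:
    with open(path) as fh:
        return cls(**yaml.safe_load(fh))
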