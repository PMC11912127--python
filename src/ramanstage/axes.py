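"""Wavenumber axes for Raman spectra.

A Raman spectrum is recorded on a fixed grid of spectrometer channels; each
channel maps to a Raman shift in cm**-1. Downstream code only assumes the
mapping is strictly increasing, never that it is linear.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Bounds of the biological fingerprint region (cm**-1).
FINGERPRINT_LO = 600.0
FINGERPRINT_HI = 1800.0

#: Number of raw detector channels of the emulated spectrograph.
N_CHANNELS_DEFAULT = 1340

# Channel index anchored at 600 cm**-1 and channel step of the synthetic
# linear calibration.  With 1340 channels this places exactly 870 channels
# inside [600, 1800] cm**-1 (channels 235..1104).
_ANCHOR_CHANNEL = 235
_STEP_NUM = 1200.0
_STEP_DEN = 869.0


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly increasing channel -> Raman shift (cm**-1) mapping."""

    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("axis needs at least 2 channels")
        if not np.all(np.diff(values) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of channels with lo <= value <= hi (closed interval)."""
        return (self.values >= lo) & (self.values <= hi)

    def slice(self, lo: float, hi: float) -> "WavenumberAxis":
        mask = self.window_mask(lo, hi)
        if not mask.any():
            raise ValueError(f"no channel in [{lo}, {hi}] cm^-1")
        return WavenumberAxis(self.values[mask])

    def nearest_channel(self, wavenumber: float) -> int:
        return int(np.argmin(np.abs(self.values - wavenumber)))


def make_axis(n_channels: int = N_CHANNELS_DEFAULT) -> WavenumberAxis:
    """Linear synthetic spectrograph calibration.

    Channel ``k`` maps to ``600 + (k - 235) * 1200/869`` cm**-1, so that for
    the default 1340-channel detector exactly 870 channels fall inside the
    600-1800 cm**-1 fingerprint region (channels 235 and 1104 land on the
    bounds exactly).
    """
    if n_channels < 2:
        raise ValueError("n_channels must be >= 2")
    k = np.arange(n_channels, dtype=float)
    # (k - 235) * 1200 / 869 keeps the 600/1800 anchors exact in float64.
    values = FINGERPRINT_LO + (k - _ANCHOR_CHANNEL) * _STEP_NUM / _STEP_DEN
    return WavenumberAxis(values)
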