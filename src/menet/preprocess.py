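"""Epoch container, filtering, re-referencing, and GFP-based block selection.

The preprocessing chain mirrors the standard scalp-EEG workflow for
connectivity analysis: a broad 0.5-60 Hz zero-phase band-pass for drift and
line-noise control, conversion to the average reference, and selection of a
1-s analysis block centred on the global-field-power (GFP) maximum of each
event-locked epoch.  GFP at time t is the root mean square across the K
channels of the deviation from the instantaneous channel mean:

    GFP(t) = sqrt( sum_i (V_i(t) - V_mean(t))^2 / K )

It is reference-free, so the block choice does not depend on the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .errors import ParameterError

__all__ = [
    "EEGEpoch",
    "GFPSeries",
    "BandSpec",
    "DEFAULT_BANDS",
    "BROADBAND",
    "bandpass",
    "average_reference",
    "compute_gfp",
    "select_gfp_block",
    "peak_to_peak_reject",
]


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band [f_lo, f_hi] in Hz.

    ``f_center`` is the carrier used by the synthetic generator; it defaults
    to the band midpoint when not given explicitly.
    """

    name: str
    f_lo: float
    f_hi: float
    f_center: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ParameterError(
                f"band {self.name!r}: need 0 < f_lo < f_hi, got [{self.f_lo}, {self.f_hi}]"
            )

    @property
    def center(self) -> float:
        return self.f_center if self.f_center is not None else 0.5 * (self.f_lo + self.f_hi)


#: Canonical analysis bands: alpha 8-12, beta 12-30, gamma 30-60 Hz, with the
#: generator carriers at 10 / 20 / 40 Hz.
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("alpha", 8.0, 12.0, 10.0),
    BandSpec("beta", 12.0, 30.0, 20.0),
    BandSpec("gamma", 30.0, 60.0, 40.0),
)

#: Broadband preprocessing filter edges (Hz).
BROADBAND: tuple[float, float] = (0.5, 60.0)


@dataclass
class EEGEpoch:
    """One event-locked multichannel EEG segment.

    data is channels x samples in microvolts; ``t0`` is the start offset of
    the segment (seconds) relative to its parent recording/epoch.
    """

    data: np.ndarray
    fs: float
    channel_ids: tuple[str, ...]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ParameterError("epoch data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_ids):
            raise ParameterError(
                f"{self.data.shape[0]} rows but {len(self.channel_ids)} channel ids"
            )
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ParameterError("channel_ids must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ParameterError("epoch data contains non-finite values")
        self.channel_ids = tuple(self.channel_ids)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class GFPSeries:
    """Per-sample global field power (microvolts) of one epoch."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise ParameterError("GFP values must be nonnegative")


def _design_sos(f_lo: float, f_hi: float, fs: float, order: int):
    nyq = fs / 2.0
    if not (0 < f_lo < f_hi < nyq):
        raise ParameterError(
            f"band edges ({f_lo}, {f_hi}) must satisfy 0 < f_lo < f_hi < Nyquist ({nyq})"
        )
    return signal.butter(order, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")


def bandpass(epoch: EEGEpoch, f_lo: float, f_hi: float, order: int = 4) -> EEGEpoch:
    """Zero-phase (forward-backward) Butterworth band-pass per channel.

    Zero-phase filtering is essential here: PLV is a phase statistic and a
    causal filter would introduce frequency-dependent phase shifts.
    """
    sos = _design_sos(f_lo, f_hi, epoch.fs, order)
    out = signal.sosfiltfilt(sos, epoch.data, axis=1)
    return replace(epoch, data=out)


def average_reference(epoch: EEGEpoch) -> EEGEpoch:
    """Re-reference to the common average: subtract the instantaneous channel mean."""
    if epoch.n_channels < 2:
        raise ParameterError("average reference requires at least 2 channels")
    out = epoch.data - epoch.data.mean(axis=0, keepdims=True)
    return replace(epoch, data=out)


def compute_gfp(epoch: EEGEpoch) -> GFPSeries:
    """Global field power: population RMS of channel deviations per sample."""
    if epoch.n_channels < 2:
        raise ParameterError("GFP requires at least 2 channels")
    values = epoch.data.std(axis=0, ddof=0)
    return GFPSeries(values=values, fs=epoch.fs)


def select_gfp_block(epoch: EEGEpoch, block_dur: float = 1.0) -> EEGEpoch:
    """Cut the ``block_dur`` block whose midpoint is the GFP maximum.

    The earliest sample wins GFP ties; when the peak lies within half a block
    of an epoch edge the block is shifted minimally inward so it stays fully
    inside the epoch.  Block length is round(fs * block_dur) samples and the
    midpoint uses the floor convention for even lengths.
    """
    if block_dur <= 0:
        raise ParameterError("block_dur must be positive")
    n_block = int(round(epoch.fs * block_dur))
    if n_block > epoch.n_samples:
        raise ParameterError(
            f"epoch ({epoch.n_samples} samples) shorter than block ({n_block} samples)"
        )
    gfp = compute_gfp(epoch)
    peak = int(np.argmax(gfp.values))
    start = peak - n_block // 2
    start = min(max(start, 0), epoch.n_samples - n_block)
    out = epoch.data[:, start : start + n_block]
    return replace(epoch, data=out, t0=epoch.t0 + start / epoch.fs)


def peak_to_peak_reject(epochs: list[EEGEpoch], threshold_uv: float) -> np.ndarray:
    """Boolean keep-mask: True where every channel's peak-to-peak < threshold.

    A minimal amplitude guard for real recordings; synthetic cohorts are
    clean and pass untouched.
    """
    if threshold_uv <= 0:
        raise ParameterError("threshold must be positive")
    keep = np.empty(len(epochs), dtype=bool)
    for k, ep in enumerate(epochs):
        ptp = ep.data.max(axis=1) - ep.data.min(axis=1)
        keep[k] = bool(np.all(ptp < threshold_uv))
    return keep
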