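"""Morlet-wavelet instantaneous phase and phase-locking value (PLV) matrices.

For channels i, j and analysis window of n samples, the phase-locking value
at frequency f is the modulus of the time-averaged unit phasor of the phase
difference:

    PLV_ij(f) = | (1/n) * sum_t exp(-1i * (phi_i(f,t) - phi_j(f,t))) |

PLV is 1 when the phase difference is constant over the window and decays to
~sqrt(pi)/(2*sqrt(n)) for independent phases.  Phases come from a complex
Morlet continuous wavelet transform (7 cycles, 1-Hz frequency steps across a
band); the per-bin PLV matrices are averaged arithmetically over the band.

The Morlet convolution is implemented directly (FFT convolution with a
Gaussian-windowed complex exponential truncated at +/-3 sigma_t) so that a
1-s analysis block remains analysable at alpha frequencies, where an
untruncated 7-cycle wavelet would be longer than the block itself.  Only the
coefficient's argument is used, so wavelet amplitude normalisation is
irrelevant.  Samples within one wavelet half-support (3 sigma_t at the band's
lowest frequency) of a block edge are dropped from whole-block PLV sums;
sliding sub-windows are sliced from the parent block's transform instead, to
avoid losing most of a 400-ms window to edge trimming.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ParameterError
from .preprocess import BandSpec, EEGEpoch

__all__ = [
    "PhaseTensor",
    "ConnectivityMatrix",
    "band_frequencies",
    "wavelet_phase",
    "plv_pair",
    "band_plv",
    "band_plv_batch",
    "edge_trim_samples",
]

N_CYCLES_DEFAULT = 7.0


@dataclass
class PhaseTensor:
    """Instantaneous phase, channels x frequencies x samples, wrapped to (-pi, pi]."""

    phases: np.ndarray
    freqs: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.phases)):
            raise ParameterError("phase tensor contains non-finite values")


@dataclass
class ConnectivityMatrix:
    """Symmetric node x node PLV matrix in [0, 1] with unit diagonal."""

    values: np.ndarray
    node_ids: tuple[str, ...]
    band: BandSpec

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.node_ids):
            raise ParameterError("connectivity matrix shape does not match node ids")
        self.values = v
        self.node_ids = tuple(self.node_ids)


def band_frequencies(band: BandSpec) -> np.ndarray:
    """1-Hz frequency grid spanning the band, edges inclusive."""
    return np.arange(np.ceil(band.f_lo), np.floor(band.f_hi) + 1.0)


def _sigma_t(freq: float, n_cycles: float) -> float:
    return n_cycles / (2.0 * np.pi * freq)


def edge_trim_samples(f_min: float, fs: float, n_cycles: float = N_CYCLES_DEFAULT) -> int:
    """Edge-exclusion width in samples: one sigma_t of the slowest wavelet.

    The Gaussian envelope concentrates most contamination within +/-1 sigma_t
    of a block edge.  Trimming the full truncated support (3 sigma_t) would
    leave a 7-cycle alpha wavelet only ~0.16 s of a 1-s block, too little for
    a meaningful PLV sum, so the default drops the 1-sigma core only.
    """
    return int(np.ceil(_sigma_t(f_min, n_cycles) * fs))


def _morlet_kernel(freq: float, fs: float, n_cycles: float, max_len: int) -> np.ndarray:
    half = min(int(np.ceil(3.0 * _sigma_t(freq, n_cycles) * fs)), (max_len - 1) // 2)
    tt = np.arange(-half, half + 1) / fs
    kern = np.exp(2j * np.pi * freq * tt) * np.exp(-(tt**2) / (2 * _sigma_t(freq, n_cycles) ** 2))
    return kern


def _cwt_complex(data: np.ndarray, fs: float, freqs: np.ndarray,
                 n_cycles: float) -> np.ndarray:
    """Complex Morlet coefficients for 2-D input (signals x samples).

    Returns signals x frequencies x samples.
    """
    n_sig, n_t = data.shape
    out = np.empty((n_sig, len(freqs), n_t), dtype=np.complex128)
    for k, f in enumerate(freqs):
        kern = _morlet_kernel(float(f), fs, n_cycles, n_t)
        out[:, k, :] = signal.fftconvolve(data, kern[None, :], mode="same", axes=1)
    return out


def wavelet_phase(epoch: EEGEpoch, freqs, n_cycles: float = N_CYCLES_DEFAULT) -> PhaseTensor:
    """Instantaneous phase per channel and frequency via complex Morlet CWT.

    Exact-zero coefficients get phase 0 by convention (``np.angle(0) == 0``),
    so silent channels never produce NaN phases.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=np.float64))
    nyq = epoch.fs / 2.0
    if np.any(freqs >= nyq) or np.any(freqs <= 0):
        raise ParameterError(f"analysis frequencies must lie in (0, {nyq}) Hz")
    coeffs = _cwt_complex(epoch.data, epoch.fs, freqs, n_cycles)
    return PhaseTensor(phases=np.angle(coeffs), freqs=freqs, fs=epoch.fs)


def plv_pair(phases_i: np.ndarray, phases_j: np.ndarray) -> float:
    """PLV between two equal-length per-sample phase series at one frequency."""
    phases_i = np.asarray(phases_i, dtype=np.float64)
    phases_j = np.asarray(phases_j, dtype=np.float64)
    if phases_i.shape != phases_j.shape:
        raise ParameterError("phase series must have equal length")
    if phases_i.size < 2:
        raise ParameterError("need at least 2 samples")
    val = np.abs(np.mean(np.exp(-1j * (phases_i - phases_j))))
    return float(min(val, 1.0))


def _plv_matrix_from_phases(phases: np.ndarray) -> np.ndarray:
    """Average-over-frequency PLV matrix from a (channels, freqs, samples) array."""
    n_ch, n_f, n_t = phases.shape
    acc = np.zeros((n_ch, n_ch))
    for k in range(n_f):
        z = np.exp(1j * phases[:, k, :])
        acc += np.abs(z @ z.conj().T) / n_t
    plv = acc / n_f
    plv = 0.5 * (plv + plv.T)
    np.clip(plv, 0.0, 1.0, out=plv)
    np.fill_diagonal(plv, 1.0)
    return plv


def band_plv(epoch: EEGEpoch, band: BandSpec, n_cycles: float = N_CYCLES_DEFAULT,
             edge_trim: bool = True) -> ConnectivityMatrix:
    """PLV matrix for one band of one analysis block.

    Per 1-Hz bin the pairwise PLV is computed over the edge-trimmed block,
    then bins are averaged; the result is symmetric with unit diagonal.
    """
    freqs = band_frequencies(band)
    if freqs.size == 0 or band.f_hi >= epoch.fs / 2:
        raise ParameterError(f"band {band.name!r} outside the analysable range")
    tensor = wavelet_phase(epoch, freqs, n_cycles)
    trim = edge_trim_samples(float(freqs.min()), epoch.fs, n_cycles) if edge_trim else 0
    if epoch.n_samples - 2 * trim < 2:
        raise ParameterError(
            "block too short for edge-trimmed PLV at this band's lowest frequency"
        )
    sl = slice(trim, epoch.n_samples - trim) if trim else slice(None)
    plv = _plv_matrix_from_phases(tensor.phases[:, :, sl])
    return ConnectivityMatrix(values=plv, node_ids=epoch.channel_ids, band=band)


def band_plv_batch(epochs: list[EEGEpoch], band: BandSpec,
                   n_cycles: float = N_CYCLES_DEFAULT,
                   edge_trim: bool = True) -> list[ConnectivityMatrix]:
    """``band_plv`` over same-shape blocks, sharing one batched wavelet transform."""
    if not epochs:
        return []
    fs = epochs[0].fs
    n_t = epochs[0].n_samples
    n_ch = epochs[0].n_channels
    for ep in epochs:
        if ep.fs != fs or ep.n_samples != n_t or ep.n_channels != n_ch:
            raise ParameterError("batched blocks must share fs, channel count and length")
    freqs = band_frequencies(band)
    if freqs.size == 0 or band.f_hi >= fs / 2:
        raise ParameterError(f"band {band.name!r} outside the analysable range")
    stacked = np.concatenate([ep.data for ep in epochs], axis=0)
    coeffs = _cwt_complex(stacked, fs, freqs, n_cycles)
    trim = edge_trim_samples(float(freqs.min()), fs, n_cycles) if edge_trim else 0
    if n_t - 2 * trim < 2:
        raise ParameterError("block too short for edge-trimmed PLV")
    sl = slice(trim, n_t - trim) if trim else slice(None)
    out = []
    for k, ep in enumerate(epochs):
        phases = np.angle(coeffs[k * n_ch : (k + 1) * n_ch, :, sl])
        plv = _plv_matrix_from_phases(phases)
        out.append(ConnectivityMatrix(values=plv, node_ids=ep.channel_ids, band=band))
    return out


def windowed_band_plv(block: EEGEpoch, band: BandSpec, win: float = 0.4,
                      overlap: float = 0.5,
                      n_cycles: float = N_CYCLES_DEFAULT) -> list[ConnectivityMatrix]:
    """PLV matrices for sliding sub-windows of one analysis block.

    The wavelet transform is computed once on the parent block and sliced per
    window (no additional edge trimming inside windows), so a 400-ms window
    keeps all of its samples.
    """
    from .classify import window_bounds  # local import to avoid a cycle

    freqs = band_frequencies(band)
    if freqs.size == 0 or band.f_hi >= block.fs / 2:
        raise ParameterError(f"band {band.name!r} outside the analysable range")
    tensor = wavelet_phase(block, freqs, n_cycles)
    out = []
    for start, stop in window_bounds(block.n_samples, block.fs, win, overlap):
        plv = _plv_matrix_from_phases(tensor.phases[:, :, start:stop])
        out.append(ConnectivityMatrix(values=plv, node_ids=block.channel_ids, band=band))
    return out
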