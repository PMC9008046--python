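"""Magnitude-squared coherence between all channel pairs, reduced to one
weighted adjacency matrix per frequency band.

The estimator treats each epoch as one tapered (Hann) FFT segment: the
cross-spectral density S_xy(f) is the average over epochs of the windowed FFT
cross-products, and coherence at each frequency bin is

    COH_xy(f) = |S_xy(f)|^2 / (S_xx(f) S_yy(f)),

which lies in [0, 1] with 0 meaning no linear relationship and 1 full
coherence.  A band value is the mean of COH_xy(f) over the FFT bins falling
in the half-open interval [f_low, f_high); the DC bin is always excluded.
With the study geometry (2-s epochs at 200 Hz) the grid resolution is 0.5 Hz.

Epochs are not sub-segmented: averaging across the ten 2-s epochs supplies
the estimator's degrees of freedom, and sub-segmenting 2-s windows would
destroy delta-band resolution.  Coherence from a single segment is
identically 1 and is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import get_window

from .io import (
    BandSpec,
    DEFAULT_BANDS,
    DegenerateEstimatorError,
    DegeneratePowerError,
    EmptyBandError,
    EpochSet,
    logger,
)

__all__ = [
    "BandSpec",
    "SpectralEstimate",
    "CoherenceGraph",
    "cross_spectra",
    "coherence_spectrum",
    "band_coherence",
    "subject_connectivity",
]


@dataclass
class SpectralEstimate:
    """Epoch-averaged cross-spectral density matrix.

    ``csd`` has shape (n_channels, n_channels, n_freqs) and is Hermitian in
    its first two indices at every frequency; the diagonal holds the real,
    non-negative auto-spectra.
    """

    freqs: np.ndarray
    csd: np.ndarray
    n_epochs_used: int
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not np.allclose(self.csd, self.csd.conj().transpose(1, 0, 2)):
            raise ValueError("csd must be Hermitian in its channel indices")
        auto = np.einsum("iif->if", self.csd)
        if np.any(auto.real < -1e-12 * np.abs(auto.real).max(initial=1.0)):
            raise ValueError("auto-spectra must be non-negative")


@dataclass
class CoherenceGraph:
    """Symmetric weighted adjacency matrix of band-averaged coherences."""

    band: BandSpec
    W: np.ndarray
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.shape[0] != W.shape[1] or W.shape[0] != len(self.channel_labels):
            raise ValueError("W must be square and match channel_labels")
        if not np.allclose(W, W.T):
            raise ValueError("W must be symmetric")
        off = W[~np.eye(W.shape[0], dtype=bool)]
        if off.size and (off.min() < 0 or off.max() > 1):
            raise ValueError("off-diagonal coherences must lie in [0, 1]")
        np.fill_diagonal(W, 0.0)
        self.W = W


def cross_spectra(epochs: EpochSet, window: str = "hann") -> SpectralEstimate:
    """Estimate the cross-spectral density matrix from an :class:`EpochSet`.

    Each epoch is detrended (mean removal), tapered with ``window`` and
    transformed with a real FFT; cross-products are averaged over epochs.
    Raises :class:`DegenerateEstimatorError` for fewer than two epochs.
    """
    if epochs.n_epochs < 2:
        raise DegenerateEstimatorError(
            f"subject {epochs.subject_id!r}: coherence from "
            f"{epochs.n_epochs} epoch(s) is degenerate (identically 1)"
        )
    n = epochs.n_samples
    taper = get_window(window, n, fftbins=True)
    x = epochs.data - epochs.data.mean(axis=-1, keepdims=True)
    X = np.fft.rfft(x * taper, axis=-1)  # (E, C, F)
    # Welch scaling: density per Hz.  The constant cancels in coherence but
    # keeps auto-spectra interpretable as µV²/Hz.
    scale = 1.0 / (epochs.fs * np.sum(taper**2))
    csd = np.einsum("ecf,edf->cdf", X, X.conj()) * (scale / epochs.n_epochs)
    freqs = np.fft.rfftfreq(n, d=1.0 / epochs.fs)
    return SpectralEstimate(
        freqs=freqs,
        csd=csd,
        n_epochs_used=epochs.n_epochs,
        channel_labels=epochs.channel_labels,
    )


def coherence_spectrum(spec: SpectralEstimate) -> np.ndarray:
    """Full magnitude-squared coherence tensor (C, C, F).

    Bins where a channel has zero auto-power yield NaN; callers selecting
    bands are responsible for rejecting degenerate power there.
    """
    auto = np.real(np.einsum("iif->if", spec.csd))  # (C, F)
    denom = auto[:, None, :] * auto[None, :, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.abs(spec.csd) ** 2 / denom
    return coh


def band_bins(freqs: np.ndarray, band: BandSpec) -> np.ndarray:
    """Boolean mask of FFT bins in [f_low, f_high), DC excluded."""
    return (freqs >= band.f_low) & (freqs < band.f_high) & (freqs > 0)


def band_coherence(spec: SpectralEstimate, band: BandSpec) -> CoherenceGraph:
    """Average the coherence spectrum over one band's bins.

    Raises :class:`EmptyBandError` if no bin falls in the band and
    :class:`DegeneratePowerError` if any channel has zero power on an
    in-band bin (coherence undefined there).
    """
    mask = band_bins(spec.freqs, band)
    if not mask.any():
        df = spec.freqs[1] - spec.freqs[0] if len(spec.freqs) > 1 else float("nan")
        raise EmptyBandError(
            f"band {band.name!r} [{band.f_low}, {band.f_high}) Hz contains no "
            f"FFT bin (grid resolution {df:g} Hz)"
        )
    auto = np.real(np.einsum("iif->if", spec.csd))[:, mask]  # (C, B)
    if np.any(auto <= 0):
        bad = [spec.channel_labels[i] for i in np.where((auto <= 0).any(axis=1))[0]]
        raise DegeneratePowerError(
            f"zero power in band {band.name!r} for channel(s) {bad}; "
            "coherence undefined"
        )
    coh = coherence_spectrum(spec)[:, :, mask]
    W = coh.mean(axis=-1)
    W = np.clip((W + W.T) / 2.0, 0.0, 1.0)  # enforce symmetry against rounding
    np.fill_diagonal(W, 0.0)
    return CoherenceGraph(band=band, W=W, channel_labels=spec.channel_labels)


def subject_connectivity(
    epochs: EpochSet,
    bands: Sequence[BandSpec] = DEFAULT_BANDS,
    window: str = "hann",
) -> list[CoherenceGraph]:
    """One :class:`CoherenceGraph` per band for one subject."""
    spec = cross_spectra(epochs, window=window)
    lowest = min(b.f_low for b in bands)
    if lowest > 0 and epochs.n_samples / epochs.fs < 1.0 / lowest:
        logger.warning(
            "subject %s: %.3g-s epochs are short for the %.3g Hz band edge",
            epochs.subject_id, epochs.n_samples / epochs.fs, lowest,
        )
    return [band_coherence(spec, band) for band in bands]
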