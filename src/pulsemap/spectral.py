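"""Temporal statistics, amplitude spectra, and the sliding-window periodogram.

This module holds the frequency-domain plumbing shared by the whole package:

* :class:`DynamicSeries` — a 4D (or 3D) voxel grid sampled at a fixed
  repetition time, the in-memory form of a dynamic MR acquisition;
* :class:`Spectrum` — a one-sided complex amplitude spectrum on the DFT grid
  ``k / (N * tr)``;
* the sliding-window :class:`Periodogram` of summed pixelwise amplitude
  spectra, used to locate a temporally stationary segment of the series
  before source separation.

Spectra use an amplitude normalization (``2/N`` for interior bins, ``1/N``
for the zero and, when ``N`` is even, Nyquist bins) chosen so that a cosine
of amplitude ``A`` at an exact bin frequency shows amplitude ``A`` at that
bin.  No taper is applied before the DFT; spectral leakage is accepted and
peaks are reported at grid bins, never interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .transfer import BandSpec

__all__ = [
    "DynamicSeries",
    "Spectrum",
    "Periodogram",
    "SegmentSelection",
    "temporal_mean_std",
    "zero_mean",
    "amplitude_spectrum",
    "compute_periodogram",
    "select_segment",
    "find_band_peak",
    "write_periodogram_tsv",
]


class SeriesValidationError(ValueError):
    """Raised when a dynamic series violates a structural invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class DynamicSeries:
    """A real-valued dynamic image series with time on the last axis.

    Parameters
    ----------
    data:
        Array of shape ``spatial_shape + (n_frames,)``.  2D single-slice and
        3D volumes are both accepted; a flat ``(n_pixels, n_frames)`` matrix
        works too (its "spatial" shape is then one-dimensional).
    tr:
        Repetition time in seconds — the sampling interval of each pixel's
        time course.
    mask:
        Optional boolean array over the spatial axes restricting analysis to
        a pixel subset.  ``None`` means all pixels.
    """

    data: np.ndarray
    tr: float
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim < 2:
            raise SeriesValidationError("series needs at least (pixel, frame) axes")
        if self.n_frames < 2:
            raise SeriesValidationError("n_frames must be >= 2")
        if not self.tr > 0:
            raise SeriesValidationError("tr must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise SeriesValidationError("series values must be finite")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.spatial_shape:
                raise SeriesValidationError(
                    f"mask shape {self.mask.shape} != spatial shape {self.spatial_shape}"
                )

    # -- geometry ----------------------------------------------------------

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.data.shape[:-1]

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    @property
    def nyquist(self) -> float:
        """Half the sampling rate, ``1 / (2 * tr)``, in Hz."""
        return 1.0 / (2.0 * self.tr)

    def times(self) -> np.ndarray:
        """Frame times; frame ``k`` occurs at ``t = k * tr`` (0-based)."""
        return np.arange(self.n_frames) * self.tr

    def pixel_matrix(self) -> np.ndarray:
        """Masked pixel time courses as an ``(n_pixels, n_frames)`` matrix."""
        flat = self.data.reshape(-1, self.n_frames)
        if self.mask is None:
            return flat
        return flat[self.mask.ravel()]

    def unflatten(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter per-masked-pixel values back onto the spatial grid."""
        out = np.full(int(np.prod(self.spatial_shape)), fill, dtype=float)
        if self.mask is None:
            out[:] = values
        else:
            out[self.mask.ravel()] = values
        return out.reshape(self.spatial_shape)

    # -- I/O ---------------------------------------------------------------

    def to_nifti(self, path: str) -> None:
        """Write as NIfTI-1 with ``tr`` stored in the time-axis pixdim."""
        data = self.data
        if data.ndim == 3:  # (x, y, t) -> (x, y, 1, t) for a legal 4D NIfTI
            data = data[:, :, None, :]
        img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), np.eye(4))
        zooms = (1.0,) * (data.ndim - 1) + (float(self.tr),)
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units(xyz="mm", t="sec")
        nib.save(img, path)

    @classmethod
    def from_nifti(cls, path: str, tr: Optional[float] = None) -> "DynamicSeries":
        """Load a 4D NIfTI; ``tr`` overrides the header's time pixdim."""
        img = nib.load(path)
        data = np.asarray(img.get_fdata(), dtype=float)
        if tr is None:
            zooms = img.header.get_zooms()
            if len(zooms) < data.ndim:
                raise SeriesValidationError("no time pixdim in header; pass tr")
            tr = float(zooms[data.ndim - 1])
        if not tr > 0:
            raise SeriesValidationError(f"invalid tr {tr!r}; pass an explicit tr")
        return cls(data=data, tr=tr)


@dataclass
class Spectrum:
    """One-sided complex amplitude spectrum.

    ``values`` may be a single spectrum or an array of spectra with the
    frequency-bin axis last; ``freqs`` is the shared grid ``k/(N*tr)`` for
    ``k = 0..floor(N/2)``.
    """

    values: np.ndarray
    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.values.shape[-1] != self.freqs.shape[0]:
            raise ValueError("values/freqs bin-count mismatch")
        if self.freqs[0] != 0.0 or np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must start at 0 and be strictly increasing")

    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def df(self) -> float:
        """Frequency-grid step in Hz."""
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class Periodogram:
    """Summed pixelwise amplitude spectra versus sliding-window start frame.

    ``matrix`` is indexed ``(frequency bin, window start)``; there are
    ``n_frames - window_len + 1`` window starts.
    """

    matrix: np.ndarray
    window_len: int
    freqs: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.matrix.shape[1]


@dataclass
class SegmentSelection:
    """Result of stationary-segment selection: best start plus the full audit."""

    start: int
    scores: np.ndarray
    window_len: int


# ---------------------------------------------------------------------------
# temporal statistics
# ---------------------------------------------------------------------------


def temporal_mean_std(series: DynamicSeries) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel temporal mean and population standard deviation images.

    The population formula (divide by N) is used; for a noise-free sampled
    cosine of amplitude ``A`` spanning an integer number of cycles the std
    image equals ``A / sqrt(2)`` exactly.
    """
    mean = series.data.mean(axis=-1)
    std = series.data.std(axis=-1, ddof=0)
    return mean, std


def zero_mean(series: DynamicSeries) -> DynamicSeries:
    """Subtract each pixel's temporal mean; ``tr`` and mask are preserved."""
    data = series.data - series.data.mean(axis=-1, keepdims=True)
    return replace(series, data=data)


def is_zero_mean(series: DynamicSeries, rtol: float = 1e-9, atol: float = 1e-12) -> bool:
    """Check the zero-temporal-mean contract: |mean| <= rtol*std + atol."""
    mean = np.abs(series.data.mean(axis=-1))
    std = series.data.std(axis=-1, ddof=0)
    return bool(np.all(mean <= rtol * std + atol))


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


def _amplitude_norm(n: int) -> np.ndarray:
    """Per-bin normalization turning rFFT output into cosine amplitudes."""
    n_bins = n // 2 + 1
    norm = np.full(n_bins, 2.0 / n)
    norm[0] = 1.0 / n
    if n % 2 == 0:
        norm[-1] = 1.0 / n
    return norm


def amplitude_spectrum(signal: np.ndarray, tr: float) -> Spectrum:
    """One-sided complex spectrum of one or many time courses.

    The last axis of ``signal`` is time.  Normalization is ``2/N`` for
    interior bins and ``1/N`` for the DC and (even-``N``) Nyquist bins, so a
    cosine of amplitude ``A`` at an exact bin frequency yields ``|value| = A``
    at that bin.
    """
    signal = np.asarray(signal, dtype=float)
    n = signal.shape[-1]
    if n < 2:
        raise ValueError("signal length must be >= 2")
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal must be finite")
    if not tr > 0:
        raise ValueError("tr must be > 0")
    values = np.fft.rfft(signal, axis=-1) * _amplitude_norm(n)
    freqs = np.fft.rfftfreq(n, d=tr)
    return Spectrum(values=values, freqs=freqs)


# ---------------------------------------------------------------------------
# periodogram and segment selection
# ---------------------------------------------------------------------------


def compute_periodogram(series: DynamicSeries, window_len: int) -> Periodogram:
    """Sliding-window periodogram of summed pixelwise amplitude spectra.

    For each window start ``s`` the column is the sum over masked pixels of
    the modulus of the amplitude spectrum of frames ``s .. s+window_len-1``,
    after removing each pixel's per-window mean (which suppresses the DC row
    that would otherwise dominate).  Column count is
    ``n_frames - window_len + 1``.
    """
    if window_len < 2:
        raise ValueError("window_len must be >= 2")
    if window_len > series.n_frames:
        raise ValueError(
            f"window_len {window_len} exceeds n_frames {series.n_frames}"
        )
    pix = series.pixel_matrix()
    n_windows = series.n_frames - window_len + 1
    norm = _amplitude_norm(window_len)
    freqs = np.fft.rfftfreq(window_len, d=series.tr)
    matrix = np.empty((freqs.shape[0], n_windows))
    for s in range(n_windows):
        w = pix[:, s : s + window_len]
        w = w - w.mean(axis=1, keepdims=True)
        amp = np.abs(np.fft.rfft(w, axis=1)) * norm
        matrix[:, s] = amp.sum(axis=0)
    return Periodogram(matrix=matrix, window_len=window_len, freqs=freqs)


def _band_indices(freqs: np.ndarray, band: "BandSpec") -> np.ndarray:
    idx = np.nonzero((freqs >= band.f_low) & (freqs <= band.f_high))[0]
    if idx.size == 0:
        raise ValueError(
            f"band '{band.name}' [{band.f_low}, {band.f_high}] Hz contains no "
            f"frequency bins (grid step {freqs[1] - freqs[0]:.4g} Hz)"
        )
    return idx


def select_segment(
    pg: Periodogram,
    bands: Sequence["BandSpec"],
    neighborhood: int = 25,
) -> SegmentSelection:
    """Pick the window start with the most stationary in-band peaks.

    For each band the per-window peak bin (frequency) and peak amplitude are
    traced across window starts.  Each window's stationarity score sums, over
    bands, the variance of the peak frequency (in bin units) and the variance
    of the peak amplitude (relative to the band's mean peak amplitude) over a
    centered neighborhood of ``neighborhood`` windows, clipped at the edges.
    The start minimizing the score is returned, earliest on ties, together
    with every window's score for audit.
    """
    if not bands:
        raise ValueError("at least one band is required")
    n_windows = pg.n_windows
    half = max(neighborhood // 2, 0)
    df = float(pg.freqs[1] - pg.freqs[0]) if pg.freqs.size > 1 else 1.0
    scores = np.zeros(n_windows)
    for band in bands:
        rows = _band_indices(pg.freqs, band)
        sub = pg.matrix[rows]
        peak_rows = np.argmax(sub, axis=0)  # first max -> lowest frequency
        peak_freq = pg.freqs[rows][peak_rows]
        peak_amp = sub[peak_rows, np.arange(n_windows)]
        amp_scale = peak_amp.mean() or 1.0
        for s in range(n_windows):
            lo = max(0, s - half)
            hi = min(n_windows, s + half + 1)
            scores[s] += np.var(peak_freq[lo:hi]) / df**2
            scores[s] += np.var(peak_amp[lo:hi] / amp_scale)
    start = int(np.argmin(scores))  # argmin returns the earliest tie
    return SegmentSelection(start=start, scores=scores, window_len=pg.window_len)


def find_band_peak(spec: Spectrum, band: "BandSpec") -> tuple[float, float]:
    """Frequency and amplitude of the maximal bin within a band.

    Ties go to the lowest frequency; bins are never interpolated.
    """
    if spec.values.ndim != 1:
        raise ValueError("find_band_peak expects a single spectrum")
    idx = _band_indices(spec.freqs, band)
    amp = np.abs(spec.values[idx])
    k = idx[int(np.argmax(amp))]
    return float(spec.freqs[k]), float(np.abs(spec.values[k]))


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def write_periodogram_tsv(pg: Periodogram, path: str) -> None:
    """Export as TSV: rows are frequency bins (Hz labels), columns start frames."""
    frame = pd.DataFrame(
        pg.matrix,
        index=pd.Index([f"{f:.6g}" for f in pg.freqs], name="freq_hz"),
        columns=[str(s) for s in range(pg.n_windows)],
    )
    frame.to_csv(path, sep="\t")
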