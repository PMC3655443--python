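"""Transfer-function analysis between a reference time course and every pixel.

The core quantity is the frequency-domain transfer function

    H(f) = |H(f)| exp{i phi(f)} = Y(f) / X(f),

where X(f) is the spectrum of a reference time course (a respiratory or
cardiac source waveform) and Y(f) the spectrum of a pixel's time course.
|H(f)| is the amplitude gain and phi(f) the phase shift of the pixel's
pulsation relative to the reference; the phase converts to a temporal
phase delay

    tau_p(f) = -phi(f) / (2 pi f),

bounded to half a period either side of zero.  Band-averaged magnitude and
phase images are produced for closed physiological frequency bands
(respiratory ~0.3-0.5 Hz, cardiac ~1-1.4 Hz at TR = 0.2 s).

Numerical notes
---------------
* Division by X(f) is regularized: H = Y conj(X) / (|X|^2 + eps) with
  eps = 1e-12 * max |X|^2, because the reference spectrum is near zero
  outside its pulsation bands and a raw ratio explodes there.  In-band
  values are unaffected.
* Phase is band-averaged circularly (argument of the unit-phasor sum);
  naive averaging is wrong where phases wrap at +/-pi.
* A coherence image (magnitude-weighted phase consistency, 0-1) flags
  pixels whose band phase is uninterpretable because the reference carries
  no power there.

The impulse response h(t) underlying H(f) is never materialized: only the
frequency-domain ratio is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, NamedTuple, Optional, Sequence

import numpy as np

from .spectral import (
    DynamicSeries,
    Spectrum,
    _band_indices,
    amplitude_spectrum,
    find_band_peak,
)

if TYPE_CHECKING:  # pragma: no cover
    from .ica import ICResult

__all__ = [
    "BandSpec",
    "TransferMaps",
    "NyquistInfo",
    "transfer_function",
    "band_average",
    "phase_delay",
    "transfer_maps",
    "global_transfer",
    "nyquist_limit",
]

#: Relative regularization for the complex spectral division.
EPS_RELATIVE = 1e-12

#: |X| band peak must exceed this multiple of the median out-of-band
#: amplitude for the band's phases to be considered interpretable.
MIN_PEAK_TO_FLOOR = 10.0


@dataclass(frozen=True)
class BandSpec:
    """A closed frequency interval tagged respiratory / cardiac / other."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0.0 < self.f_low < self.f_high):
            raise ValueError(
                f"band '{self.name}': need 0 < f_low < f_high, "
                f"got [{self.f_low}, {self.f_high}]"
            )

    def validate_for_tr(self, tr: float) -> None:
        nyq = 1.0 / (2.0 * tr)
        if self.f_high >= nyq:
            raise ValueError(
                f"band '{self.name}' upper edge {self.f_high} Hz is not below "
                f"the Nyquist frequency {nyq} Hz for tr={tr}"
            )

    def contains(self, f: float) -> bool:
        return self.f_low <= f <= self.f_high


@dataclass
class TransferMaps:
    """Per-band transfer-function images against a chosen reference.

    ``magnitude`` is the band-averaged |H|, ``phase`` the circular-mean
    phase in (-pi, pi], ``delay`` the phase delay in seconds at the band's
    reference frequency (the band peak of the reference spectrum), and
    ``coherence`` a 0-1 quality weight.  Pixels outside the analysis mask
    are NaN.
    """

    band: BandSpec
    magnitude: np.ndarray
    phase: np.ndarray
    delay: np.ndarray
    reference_freq: float
    coherence: np.ndarray
    warning: Optional[str] = None


class NyquistInfo(NamedTuple):
    nyquist_hz: float
    max_heart_rate_hz: float
    max_heart_rate_bpm: float


class GlobalTransferCurve(NamedTuple):
    """Per-bin transfer function of one component against the reference."""

    component: int
    freqs: np.ndarray
    magnitude: np.ndarray
    phase: np.ndarray


# ---------------------------------------------------------------------------
# elementwise operations
# ---------------------------------------------------------------------------


def transfer_function(x_spec: Spectrum, y_spec: Spectrum) -> np.ndarray:
    """Per-bin transfer function H = Y conj(X) / (|X|^2 + eps).

    ``y_spec.values`` may hold many spectra (bins on the last axis) against
    a single reference ``x_spec``; the frequency grids must be identical.
    """
    if x_spec.freqs.shape != y_spec.freqs.shape or not np.allclose(
        x_spec.freqs, y_spec.freqs
    ):
        raise ValueError("x and y spectra are on different frequency grids")
    x = x_spec.values
    if x.ndim != 1:
        raise ValueError("reference spectrum must be one-dimensional")
    power = np.abs(x) ** 2
    eps = EPS_RELATIVE * (power.max() if power.max() > 0 else 1.0)
    return y_spec.values * np.conj(x) / (power + eps)


def _wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap into (-pi, pi]."""
    out = np.mod(np.asarray(phi, dtype=float) + np.pi, 2.0 * np.pi) - np.pi
    return np.where(out == -np.pi, np.pi, out)


def band_average(
    H: np.ndarray,
    band: BandSpec,
    freqs: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Band-averaged magnitude and circular-mean phase of H.

    Magnitude is the arithmetic mean of |H| over in-band bins; phase is the
    argument of the weighted sum of unit phasors H/|H| (zero-magnitude bins
    contribute nothing), returned in (-pi, pi].  ``weights``, if given, is a
    non-negative per-bin weight on the full frequency grid — pixelwise maps
    weight by reference power so that bins where the reference is silent
    (phase there is noise) do not dilute the circular mean.  With no weights
    this is the plain unit-phasor mean.  Works elementwise over leading axes
    of ``H`` (bins last).
    """
    idx = _band_indices(np.asarray(freqs, dtype=float), band)
    h = np.asarray(H)[..., idx]
    mag = np.abs(h)
    magnitude = mag.mean(axis=-1)
    # Bins whose |H| is negligible against the in-band maximum carry no
    # phase information (they are regularization / floating-point residue);
    # give them zero weight instead of a full unit phasor.
    tiny = 1e-9 * mag.max(axis=-1, keepdims=True)
    keep = mag > tiny
    with np.errstate(invalid="ignore", divide="ignore"):
        phasors = np.where(keep, h / np.where(keep, mag, 1.0), 0.0)
    if weights is not None:
        w = np.asarray(weights, dtype=float)[idx]
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        phasors = phasors * w
    phase = _wrap_phase(np.angle(phasors.sum(axis=-1)))
    return magnitude, phase


def phase_delay(phi, f):
    """Phase delay tau_p = -phi / (2 pi f), seconds; requires f > 0.

    For phi in (-pi, pi] the delay is bounded by half the period T = 1/f.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be > 0")
    out = -np.asarray(phi, dtype=float) / (2.0 * np.pi * f)
    return out if out.ndim else float(out)


def nyquist_limit(tr: float) -> NyquistInfo:
    """Nyquist frequency and the fastest heart rate whose second harmonic
    remains observable.

    For TR = 0.2 s the Nyquist frequency is 1/(2 TR) = 2.5 Hz, so a cardiac
    second harmonic is visible only up to a 1.25 Hz (75 bpm) heart rate;
    beyond that it aliases into the respiratory range.
    """
    if not tr > 0:
        raise ValueError("tr must be > 0")
    nyq = 1.0 / (2.0 * tr)
    return NyquistInfo(nyq, nyq / 2.0, nyq / 2.0 * 60.0)


# ---------------------------------------------------------------------------
# pixelwise maps
# ---------------------------------------------------------------------------


def _reference_band_quality(x_spec: Spectrum, band: BandSpec) -> Optional[str]:
    """Warning text if the reference has no usable in-band power."""
    idx = _band_indices(x_spec.freqs, band)
    amp = np.abs(x_spec.values)
    peak = amp[idx].max()
    out = np.delete(amp[1:], idx - 1)  # drop DC and in-band bins
    floor = np.median(out) if out.size else 0.0
    if peak <= MIN_PEAK_TO_FLOOR * floor:
        return (
            f"reference has weak power in band '{band.name}' "
            f"[{band.f_low}, {band.f_high}] Hz: peak {peak:.3g} <= "
            f"{MIN_PEAK_TO_FLOOR:g} x median out-of-band amplitude {floor:.3g}"
        )
    return None


def transfer_maps(
    series: DynamicSeries,
    reference_course: np.ndarray,
    bands: Sequence[BandSpec],
) -> list[TransferMaps]:
    """Band-averaged |H|, phase, delay and coherence images per band.

    X is the spectrum of ``reference_course``; per masked pixel Y is the
    spectrum of its (zero-mean) time course.  For each band the magnitude
    is the arithmetic mean of |H| over in-band bins, the phase the circular
    mean, the delay the band phase converted at the band peak frequency of
    |X|, and the coherence

        |sum_band H |X|^2|  /  sum_band |H| |X|^2,

    a magnitude-weighted phase-consistency score in [0, 1].
    """
    reference_course = np.asarray(reference_course, dtype=float)
    if reference_course.ndim != 1 or reference_course.size != series.n_frames:
        raise ValueError("reference length must equal the series frame count")
    for band in bands:
        band.validate_for_tr(series.tr)

    x_spec = amplitude_spectrum(
        reference_course - reference_course.mean(), series.tr
    )
    pix = series.pixel_matrix()
    pix = pix - pix.mean(axis=1, keepdims=True)
    y_spec = amplitude_spectrum(pix, series.tr)
    H = transfer_function(x_spec, y_spec)

    x_amp = np.abs(x_spec.values)
    results: list[TransferMaps] = []
    x_power = x_amp**2
    for band in bands:
        idx = _band_indices(x_spec.freqs, band)
        magnitude, phase = band_average(H, band, x_spec.freqs, weights=x_power)
        ref_freq, _ = find_band_peak(x_spec, band)
        delay = phase_delay(phase, ref_freq)

        w = x_amp[idx] ** 2
        h_band = H[:, idx]
        num = np.abs((h_band * w).sum(axis=1))
        den = (np.abs(h_band) * w).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            coherence = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)

        warning = _reference_band_quality(x_spec, band)
        if warning is not None:
            warnings.warn(warning, stacklevel=2)
        results.append(
            TransferMaps(
                band=band,
                magnitude=series.unflatten(magnitude),
                phase=series.unflatten(phase),
                delay=series.unflatten(delay),
                reference_freq=ref_freq,
                coherence=series.unflatten(coherence),
                warning=warning,
            )
        )
    return results


def global_transfer(
    res: "ICResult", reference_index: int
) -> list[GlobalTransferCurve]:
    """Phase-vs-frequency curves of every non-reference component against one
    reference component's spectrum.

    Near-constant in-band phase across bins is the signature of a genuine
    fixed temporal lag between two pulsation sources; out-of-band phases are
    noise-dominated and carry near-zero coherence.
    """
    n = len(res.courses)
    if not 0 <= reference_index < n:
        raise ValueError(f"reference_index {reference_index} out of range 0..{n - 1}")
    x_spec = res.spectra[reference_index]
    curves = []
    for k in range(n):
        if k == reference_index:
            continue
        H = transfer_function(x_spec, res.spectra[k])
        curves.append(
            GlobalTransferCurve(
                component=k,
                freqs=x_spec.freqs.copy(),
                magnitude=np.abs(H),
                phase=_wrap_phase(np.angle(H)),
            )
        )
    return curves
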