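"""Spatial independent-component decomposition of a zero-mean dynamic series.

Each acquired frame is modelled as a mixture of a few spatially independent
source images (respiratory pulsation, cardiac pulsation, residual signal):
the data matrix, pixels as samples and frames as variables, is whitened by
PCA and unmixed with FastICA (tanh contrast, symmetric decorrelation).  The
outputs are paired spatial maps and mixing time courses; the time courses
of components dominated by the respiratory or cardiac band serve as
reference waveforms for the downstream transfer-function analysis.

ICA is sign- and scale-indeterminate.  Scale is fixed by giving every time
course unit variance (the map absorbs the scale); sign is fixed by forcing
each spatial map's skewness to be non-negative — pulsation foci are sparse
bright pixels, so positive skew is the physically natural orientation — and
flipping map and course together so their product is unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .spectral import DynamicSeries, Spectrum, amplitude_spectrum, is_zero_mean
from .transfer import BandSpec

__all__ = [
    "ICResult",
    "NoReferenceError",
    "run_ica",
    "classify_components",
    "fix_sign",
]

ICA_TOL = 1e-6
ICA_MAX_ITER = 500
LABEL_THRESHOLD = 0.25  # minimum in-band energy fraction to earn a band label


class NoReferenceError(LookupError):
    """No independent component qualifies as a reference for a band."""


@dataclass
class ICResult:
    """Paired spatial maps and time courses from source separation.

    ``maps`` has shape ``(n_components, n_masked_pixels)``, ``courses``
    ``(n_components, n_frames)`` with each course zero-mean and unit
    variance.  ``spectra`` are the courses' amplitude spectra.  ``labels``
    (after classification) tag each component respiratory / cardiac /
    other, and ``references`` maps a band name to the index of its best
    component.  ``residual`` is the relative Frobenius reconstruction error
    of the data within the fitted subspace.
    """

    maps: np.ndarray
    courses: np.ndarray
    spectra: list[Spectrum]
    tr: float
    spatial_shape: tuple[int, ...]
    mask: Optional[np.ndarray] = None
    labels: Optional[list[str]] = None
    references: dict[str, int] = field(default_factory=dict)
    band_fractions: Optional[np.ndarray] = None
    residual: float = np.nan
    n_iter: int = 0

    @property
    def n_components(self) -> int:
        return self.maps.shape[0]

    def map_image(self, k: int, fill: float = np.nan) -> np.ndarray:
        """Component ``k``'s spatial map scattered onto the grid (NaN outside)."""
        out = np.full(int(np.prod(self.spatial_shape)), fill)
        if self.mask is None:
            out[:] = self.maps[k]
        else:
            out[self.mask.ravel()] = self.maps[k]
        return out.reshape(self.spatial_shape)

    def reference_index(self, band_name: str) -> int:
        if band_name not in self.references:
            raise NoReferenceError(f"no reference found for band '{band_name}'")
        return self.references[band_name]

    def reference_course(self, band_name: str) -> np.ndarray:
        return self.courses[self.reference_index(band_name)]


def run_ica(
    series: DynamicSeries, n_components: int = 4, seed: int = 0
) -> ICResult:
    """FastICA decomposition into spatially independent maps + time courses.

    The series must already be zero-temporal-mean per pixel.  The pipeline is
    center -> PCA whiten to ``n_components`` -> fixed-point iteration with
    symmetric decorrelation and the tanh contrast from a seed-determined
    random start, to tolerance 1e-6 or 500 iterations.  Non-convergence is a
    warning (with the iteration count), not an error.  Deterministic given
    ``seed``.
    """
    if not is_zero_mean(series):
        raise ValueError("run_ica requires a zero-temporal-mean series; apply zero_mean first")
    M = series.pixel_matrix()  # (n_pixels, n_frames): samples x variables
    n_pixels, n_frames = M.shape
    if not 1 <= n_components <= min(n_frames, n_pixels):
        raise ValueError(
            f"n_components {n_components} must be in 1..min(n_frames, n_pixels)"
            f" = {min(n_frames, n_pixels)}"
        )

    ica = FastICA(
        n_components=n_components,
        algorithm="parallel",
        fun="logcosh",
        whiten="unit-variance",
        tol=ICA_TOL,
        max_iter=ICA_MAX_ITER,
        random_state=np.random.RandomState(seed),
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        sources = ica.fit_transform(M)  # (n_pixels, n_components)
    for w in caught:
        if issubclass(w.category, ConvergenceWarning):
            warnings.warn(
                f"FastICA did not converge within {ica.n_iter_} iterations "
                f"(tol {ICA_TOL}); returning the last iterate",
                ConvergenceWarning,
                stacklevel=2,
            )
        else:  # pragma: no cover - pass through anything unexpected
            warnings.warn_explicit(
                w.message, w.category, w.filename, w.lineno
            )

    maps = sources.T.copy()  # (k, n_pixels)
    courses = ica.mixing_.T.copy()  # (k, n_frames)

    # Scale convention: unit-variance, zero-mean courses; maps absorb scale.
    courses -= courses.mean(axis=1, keepdims=True)
    scale = courses.std(axis=1, ddof=0)
    scale[scale == 0] = 1.0
    courses /= scale[:, None]
    maps *= scale[:, None]

    recon = maps.T @ courses + ica.mean_[None, :]
    denom = np.linalg.norm(M)
    residual = float(np.linalg.norm(M - recon) / denom) if denom > 0 else 0.0

    res = ICResult(
        maps=maps,
        courses=courses,
        spectra=[amplitude_spectrum(c, series.tr) for c in courses],
        tr=series.tr,
        spatial_shape=series.spatial_shape,
        mask=None if series.mask is None else series.mask.copy(),
        residual=residual,
        n_iter=int(ica.n_iter_),
    )
    return fix_sign(res)


def _in_band_fraction(spec: Spectrum, band: BandSpec) -> float:
    """Fraction of the course's spectral energy (DC excluded) inside a band."""
    amp = spec.amplitude()
    energy = amp[1:] ** 2
    total = energy.sum()
    if total == 0:
        return 0.0
    sel = (spec.freqs[1:] >= band.f_low) & (spec.freqs[1:] <= band.f_high)
    return float(energy[sel].sum() / total)


def classify_components(
    res: ICResult,
    resp_band: BandSpec,
    card_band: BandSpec,
    threshold: float = LABEL_THRESHOLD,
) -> ICResult:
    """Label components by dominant in-band spectral energy fraction.

    Each component gets the band (respiratory or cardiac) with the larger
    energy fraction, provided that fraction reaches ``threshold``; otherwise
    it is labelled ``other``.  Per band, the highest-fraction qualifying
    component becomes the band's reference.  A white-noise course's expected
    in-band fraction is only bandwidth/Nyquist, which for the default bands
    falls below the threshold — so pure noise yields no references.
    """
    bands = [resp_band, card_band]
    fractions = np.array(
        [[_in_band_fraction(s, b) for b in bands] for s in res.spectra]
    )
    labels: list[str] = []
    for k in range(res.n_components):
        j = int(np.argmax(fractions[k]))
        labels.append(bands[j].name if fractions[k, j] >= threshold else "other")
    references: dict[str, int] = {}
    for j, band in enumerate(bands):
        candidates = [k for k in range(res.n_components) if labels[k] == band.name]
        if candidates:
            references[band.name] = max(candidates, key=lambda k: fractions[k, j])
    return replace(
        res, labels=labels, references=references, band_fractions=fractions
    )


def fix_sign(res: ICResult) -> ICResult:
    """Resolve ICA's sign indeterminacy deterministically.

    Each component is flipped so its spatial map's skewness is >= 0; on an
    exact tie the map value of largest magnitude is made positive.  Map and
    course flip together, leaving their product (the reconstruction)
    unchanged.  The operation is idempotent and an involution with respect
    to component negation.
    """
    maps = res.maps.copy()
    courses = res.courses.copy()
    for k in range(maps.shape[0]):
        sk = stats.skew(maps[k])
        if sk < 0:
            flip = True
        elif sk > 0:
            flip = False
        else:
            extreme = maps[k][np.argmax(np.abs(maps[k]))]
            flip = extreme < 0
        if flip:
            maps[k] = -maps[k]
            courses[k] = -courses[k]
    spectra = [amplitude_spectrum(c, res.tr) for c in courses]
    return replace(res, maps=maps, courses=courses, spectra=spectra)
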