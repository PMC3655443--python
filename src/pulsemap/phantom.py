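"""Synthetic dynamic-series phantoms with known pulsation structure.

No public dynamic-MR acquisitions of intracranial pulsations exist, so every
downstream stage is validated against phantoms: compartments (pixel sets)
oscillating at a respiratory-range (~0.3-0.5 Hz) or cardiac-range
(~1-1.4 Hz) frequency with a chosen amplitude, a per-compartment temporal
delay, an optional linear frequency drift to exercise stationary-segment
selection, a constant baseline and additive Gaussian noise.

The waveform is a cosine whose delay is applied as a *time shift*,

    s(t) = A cos(2 pi f_inst (t - delay)),     f_inst = f + drift * (t - delay),

with the phase integrated over the drift, so the phase delay recovered by
the transfer-function analysis is directly comparable to the specified
``delay``.  Defaults mirror the acquisition the analysis targets: a
128 x 128 single-slice matrix, 512 frames at TR = 0.2 s, pulsation
amplitudes a few percent of baseline.

Limitations: noise is Gaussian rather than Rician (adequate for the
zero-mean fluctuation signal the analysis operates on), and no MR physics
is simulated — no T2* decay, inflow saturation, k-space or EPI artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from .spectral import DynamicSeries
from .transfer import BandSpec

__all__ = [
    "CompartmentSpec",
    "PhantomSpec",
    "PhantomSpecError",
    "AmbiguityError",
    "generate_phantom",
    "ground_truth_maps",
    "load_phantom_spec",
    "disk_mask",
    "rect_mask",
]

DEFAULT_GRID = (128, 128)
DEFAULT_N_FRAMES = 512
DEFAULT_TR = 0.2  # seconds
DEFAULT_BASELINE = 100.0  # arbitrary signal units
DEFAULT_NOISE_SD = 0.2  # SNR 10 against the default 2.0 amplitude


class PhantomSpecError(ValueError):
    """A phantom spec violates one of its invariants (named in the message)."""


class AmbiguityError(ValueError):
    """Zero or several compartment frequencies fall inside a requested band."""


def disk_mask(grid_shape: Sequence[int], center: Sequence[float], radius: float) -> np.ndarray:
    """Boolean disk (2D) or ball (3D) mask on the grid."""
    grids = np.ogrid[tuple(slice(0, n) for n in grid_shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


def rect_mask(grid_shape: Sequence[int], lo: Sequence[int], hi: Sequence[int]) -> np.ndarray:
    """Boolean axis-aligned box mask with half-open bounds [lo, hi)."""
    mask = np.zeros(tuple(grid_shape), dtype=bool)
    mask[tuple(slice(a, b) for a, b in zip(lo, hi))] = True
    return mask


@dataclass
class CompartmentSpec:
    """One oscillating pixel set.

    ``delay`` shifts the waveform in time (seconds) relative to phase zero;
    ``drift_rate`` adds a linear instantaneous-frequency drift in Hz/s;
    ``harmonic_amplitudes`` lists relative amplitudes for integer harmonics
    starting at the second (frequency 2f, 3f, ...).
    """

    mask: np.ndarray
    frequency: float
    amplitude: float
    delay: float = 0.0
    drift_rate: float = 0.0
    harmonic_amplitudes: Optional[list[float]] = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    def max_frequency(self, duration: float) -> float:
        """Highest instantaneous frequency over the scan, harmonics included."""
        f_end = self.frequency + max(self.drift_rate, 0.0) * duration
        top = max(self.frequency, f_end)
        n_harm = 1 + len(self.harmonic_amplitudes or [])
        return top * n_harm


@dataclass
class PhantomSpec:
    """Full description of a synthetic dynamic series."""

    grid_shape: tuple[int, ...] = DEFAULT_GRID
    n_frames: int = DEFAULT_N_FRAMES
    tr: float = DEFAULT_TR
    compartments: list[CompartmentSpec] = field(default_factory=list)
    noise_sd: float = DEFAULT_NOISE_SD
    baseline: float = DEFAULT_BASELINE
    seed: int = 0

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.tr)

    @property
    def duration(self) -> float:
        return self.n_frames * self.tr

    def validate(self) -> None:
        if self.n_frames < 8:
            raise PhantomSpecError("invariant violated: n_frames >= 8")
        if not self.tr > 0:
            raise PhantomSpecError("invariant violated: tr > 0")
        if self.noise_sd < 0:
            raise PhantomSpecError("invariant violated: noise_sd >= 0")
        for i, comp in enumerate(self.compartments):
            if comp.mask.shape != tuple(self.grid_shape):
                raise PhantomSpecError(
                    f"invariant violated: compartment {i} mask shape "
                    f"{comp.mask.shape} must equal grid_shape {tuple(self.grid_shape)}"
                )
            if not comp.frequency > 0:
                raise PhantomSpecError(
                    f"invariant violated: compartment {i} frequency > 0"
                )
            if comp.amplitude < 0:
                raise PhantomSpecError(
                    f"invariant violated: compartment {i} amplitude >= 0"
                )
            if comp.max_frequency(self.duration) >= self.nyquist:
                raise PhantomSpecError(
                    f"invariant violated: compartment {i} frequency (incl. drift "
                    f"and harmonics) must stay below Nyquist {self.nyquist:g} Hz"
                )


def _compartment_waveform(comp: CompartmentSpec, t: np.ndarray) -> np.ndarray:
    """Sampled waveform of one compartment at frame times ``t`` (seconds)."""
    tau = t - comp.delay
    # instantaneous frequency f + drift*tau => phase integral 2pi(f tau + drift tau^2 / 2)
    phase = 2.0 * np.pi * (comp.frequency * tau + 0.5 * comp.drift_rate * tau**2)
    wave = comp.amplitude * np.cos(phase)
    for m, rel in enumerate(comp.harmonic_amplitudes or [], start=2):
        wave = wave + comp.amplitude * rel * np.cos(m * phase)
    return wave


def generate_phantom(spec: PhantomSpec) -> DynamicSeries:
    """Render a phantom spec into a dynamic series.

    Pixel (p, t) value = baseline + sum over compartments containing p of
    the compartment waveform (+ harmonics) + N(0, noise_sd).  Overlapping
    compartments add.  Bit-identical for a fixed seed.
    """
    spec.validate()
    t = np.arange(spec.n_frames) * spec.tr
    data = np.full(tuple(spec.grid_shape) + (spec.n_frames,), float(spec.baseline))
    for comp in spec.compartments:
        data[comp.mask] += _compartment_waveform(comp, t)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)
    return DynamicSeries(data=data, tr=spec.tr)


def ground_truth_maps(
    spec: PhantomSpec, band: BandSpec
) -> tuple[np.ndarray, np.ndarray]:
    """True per-pixel oscillation amplitude and delay for the band's compartment.

    Exactly one compartment frequency must fall in the band; pixels outside
    that compartment are NaN ("absent").  Ground truth reads the spec
    directly and is independent of noise.
    """
    matches = [c for c in spec.compartments if band.contains(c.frequency)]
    if len(matches) != 1:
        raise AmbiguityError(
            f"band '{band.name}' [{band.f_low}, {band.f_high}] Hz matches "
            f"{len(matches)} compartment frequencies; need exactly 1"
        )
    comp = matches[0]
    amp = np.full(tuple(spec.grid_shape), np.nan)
    delay = np.full(tuple(spec.grid_shape), np.nan)
    amp[comp.mask] = comp.amplitude
    delay[comp.mask] = comp.delay
    return amp, delay


# ---------------------------------------------------------------------------
# YAML spec I/O
# ---------------------------------------------------------------------------


def _mask_from_dict(grid_shape: Sequence[int], region: dict) -> np.ndarray:
    kind = region.get("type")
    if kind == "disk":
        return disk_mask(grid_shape, region["center"], region["radius"])
    if kind == "rect":
        return rect_mask(grid_shape, region["lo"], region["hi"])
    if kind == "pixels":
        mask = np.zeros(tuple(grid_shape), dtype=bool)
        for idx in region["indices"]:
            mask[tuple(idx)] = True
        return mask
    raise PhantomSpecError(f"unknown region type {kind!r} (disk, rect, pixels)")


def load_phantom_spec(path: str) -> PhantomSpec:
    """Read a phantom spec from YAML (or JSON, a YAML subset).

    Compartment masks are described as regions::

        grid_shape: [64, 64]
        n_frames: 512
        tr: 0.2
        baseline: 100.0
        noise_sd: 0.2
        seed: 7
        compartments:
          - region: {type: disk, center: [20, 20], radius: 6}
            frequency: 0.42
            amplitude: 2.0
            delay: 0.0
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    grid_shape = tuple(raw.get("grid_shape", DEFAULT_GRID))
    comps = []
    for c in raw.get("compartments", []):
        comps.append(
            CompartmentSpec(
                mask=_mask_from_dict(grid_shape, c["region"]),
                frequency=float(c["frequency"]),
                amplitude=float(c["amplitude"]),
                delay=float(c.get("delay", 0.0)),
                drift_rate=float(c.get("drift_rate", 0.0)),
                harmonic_amplitudes=c.get("harmonic_amplitudes"),
            )
        )
    spec = PhantomSpec(
        grid_shape=grid_shape,
        n_frames=int(raw.get("n_frames", DEFAULT_N_FRAMES)),
        tr=float(raw.get("tr", DEFAULT_TR)),
        compartments=comps,
        noise_sd=float(raw.get("noise_sd", DEFAULT_NOISE_SD)),
        baseline=float(raw.get("baseline", DEFAULT_BASELINE)),
        seed=int(raw.get("seed", 0)),
    )
    spec.validate()
    return spec
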