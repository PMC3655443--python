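"""End-to-end orchestration, file I/O, rendering and reporting.

The pipeline runs the full protocol on a 4D dynamic series:

1. mask pixels by the temporal-std image (oscillatory flow shows up as
   flow-related enhancement there);
2. sliding-window periodogram over the full series and stationary-segment
   selection in the respiratory + cardiac bands;
3. zero-mean the selected segment;
4. spatial FastICA (4 components by default) and band classification of
   the component time courses;
5. pixelwise transfer-function maps (band-averaged |H|, phase, phase delay,
   coherence) for each band whose reference component was found.

Everything is deterministic given the configured seed.  Outputs are NIfTI-1
images (maps), CSV/TSV tables (courses, periodogram, stationarity scores),
PNG renders, and a machine-readable JSON report.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")  # headless rendering

import matplotlib.pyplot as plt
import nibabel as nib
import numpy as np
import pandas as pd
from matplotlib.colors import LinearSegmentedColormap

from .ica import ICResult, NoReferenceError, classify_components, run_ica
from .spectral import (
    DynamicSeries,
    Periodogram,
    SegmentSelection,
    compute_periodogram,
    select_segment,
    temporal_mean_std,
    write_periodogram_tsv,
    zero_mean,
)
from .transfer import BandSpec, TransferMaps, nyquist_limit, transfer_maps

logger = logging.getLogger("pulsemap")

__all__ = [
    "RunConfig",
    "PipelineResult",
    "run_pipeline",
    "run_pipeline_series",
    "render_phase_map",
    "render_periodogram",
    "phase_to_rgba",
    "DEFAULT_RESP_BAND",
    "DEFAULT_CARD_BAND",
]

# Classification bands.  The respiratory and cardiac ranges are physiological
# conventions (normal quiet breathing ~12-30 /min, heart rate ~54-84 /min);
# widths are kept narrow enough that a white-noise course's expected in-band
# energy fraction (bandwidth / Nyquist) stays below the labelling threshold.
DEFAULT_RESP_BAND = BandSpec("respiratory", 0.2, 0.5)
DEFAULT_CARD_BAND = BandSpec("cardiac", 0.9, 1.4)

#: Half-width (Hz) of the analysis band centred on a reference component's peak.
DEFAULT_BAND_HALFWIDTH = 0.05

#: Phases with coherence below this are rendered gray (uninterpretable).
DEFAULT_COHERENCE_THRESHOLD = 0.5


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    input_path: Optional[str] = None
    tr: Optional[float] = None  # override for headers without a time pixdim
    window_len: int = 300
    n_components: int = 4
    bands: Optional[list[BandSpec]] = None  # explicit analysis bands
    mask_percentile: float = 75.0  # std-image percentile defining the mask
    seed: int = 0
    out_dir: Optional[str] = None
    segment_start: Optional[int] = None  # manual override of segment selection
    resp_band: BandSpec = DEFAULT_RESP_BAND
    card_band: BandSpec = DEFAULT_CARD_BAND
    band_halfwidth: float = DEFAULT_BAND_HALFWIDTH
    coherence_threshold: float = DEFAULT_COHERENCE_THRESHOLD

    def validate(self, n_frames: int) -> None:
        if not 0 <= self.mask_percentile < 100:
            raise ValueError("mask_percentile must be in [0, 100)")
        if self.window_len > n_frames:
            raise ValueError(
                f"window_len {self.window_len} exceeds n_frames {n_frames}"
            )


@dataclass
class PipelineResult:
    """Everything a run produced, plus the JSON-ready report."""

    selection: SegmentSelection
    periodogram: Periodogram
    ic: ICResult
    maps: dict[str, TransferMaps]
    failures: dict[str, str]
    report: dict
    series: DynamicSeries  # the zero-mean selected segment

    @property
    def succeeded(self) -> bool:
        return bool(self.maps)


# ---------------------------------------------------------------------------
# core run
# ---------------------------------------------------------------------------


def _analysis_band(name: str, peak: float, halfwidth: float, nyquist: float) -> BandSpec:
    lo = max(peak - halfwidth, 1e-6)
    hi = min(peak + halfwidth, np.nextafter(nyquist, 0.0))
    return BandSpec(name, lo, hi)


def run_pipeline_series(series: DynamicSeries, cfg: RunConfig) -> PipelineResult:
    """Run the full protocol on an in-memory series (no file output)."""
    cfg.validate(series.n_frames)
    nyq = series.nyquist

    # 1. analysis mask from the temporal-std image
    _, std = temporal_mean_std(series)
    thresh = np.percentile(std, cfg.mask_percentile)
    mask = std > thresh
    if not mask.any():  # degenerate (constant) input: keep everything
        mask = np.ones_like(mask)
    series = DynamicSeries(series.data, series.tr, mask=mask)
    logger.info("mask: %d / %d pixels above the %.0fth std percentile",
                mask.sum(), mask.size, cfg.mask_percentile)

    # 2. periodogram + stationary segment
    pg = compute_periodogram(series, cfg.window_len)
    selection = select_segment(pg, [cfg.resp_band, cfg.card_band])
    start = cfg.segment_start if cfg.segment_start is not None else selection.start
    logger.info("selected segment start %d (of %d windows)", start, pg.n_windows)

    # 3. zero-mean selected segment
    segment = DynamicSeries(
        series.data[..., start : start + cfg.window_len], series.tr, mask=mask
    )
    segment = zero_mean(segment)

    # 4. ICA + classification
    ic = run_ica(segment, n_components=cfg.n_components, seed=cfg.seed)
    ic = classify_components(ic, cfg.resp_band, cfg.card_band)
    logger.info("component labels: %s", ic.labels)

    # 5. transfer maps per band
    maps: dict[str, TransferMaps] = {}
    failures: dict[str, str] = {}
    band_edges: dict[str, list[float]] = {}
    for class_band in (cfg.resp_band, cfg.card_band):
        name = class_band.name
        try:
            ref_idx = ic.reference_index(name)
        except NoReferenceError as exc:
            failures[name] = str(exc)
            logger.warning("%s", exc)
            continue
        explicit = None
        if cfg.bands:
            explicit = next((b for b in cfg.bands if b.name == name), None)
        if explicit is not None:
            band = explicit
        else:
            from .spectral import find_band_peak

            peak, _ = find_band_peak(ic.spectra[ref_idx], class_band)
            band = _analysis_band(name, peak, cfg.band_halfwidth, nyq)
        band_edges[name] = [band.f_low, band.f_high]
        (tm,) = transfer_maps(segment, ic.courses[ref_idx], [band])
        maps[name] = tm

    report = {
        "tr": series.tr,
        "n_frames": int(series.data.shape[-1]),
        "window_len": cfg.window_len,
        "segment_start": int(start),
        "segment_start_auto": int(selection.start),
        "n_components": cfg.n_components,
        "seed": cfg.seed,
        "nyquist_hz": nyquist_limit(series.tr).nyquist_hz,
        "component_labels": ic.labels,
        "references": {k: int(v) for k, v in ic.references.items()},
        "band_fractions": np.round(ic.band_fractions, 6).tolist(),
        "band_edges_hz": band_edges,
        "reference_freqs_hz": {k: m.reference_freq for k, m in maps.items()},
        "band_warnings": {
            k: m.warning for k, m in maps.items() if m.warning is not None
        },
        "failures": failures,
        "ica_residual": round(ic.residual, 6),
        "mask_pixels": int(mask.sum()),
        "time_convention": "frame k occurs at t = k * tr (0-based)",
    }
    return PipelineResult(
        selection=selection,
        periodogram=pg,
        ic=ic,
        maps=maps,
        failures=failures,
        report=report,
        series=segment,
    )


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Load the input series, run the protocol, write all artifacts."""
    if cfg.input_path is None:
        raise ValueError("cfg.input_path is required")
    series = DynamicSeries.from_nifti(cfg.input_path, tr=cfg.tr)
    result = run_pipeline_series(series, cfg)
    if cfg.out_dir is not None:
        write_results(result, cfg.out_dir, cfg)
    return result


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------


def _save_map(image: np.ndarray, tr: float, path: str) -> None:
    data = np.asarray(image, dtype=np.float64)
    if data.ndim == 2:
        data = data[:, :, None]
    img = nib.Nifti1Image(data, np.eye(4))
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, path)


def write_results(result: PipelineResult, out_dir: str, cfg: RunConfig) -> None:
    """Write report, tables, maps and renders under ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    tr = result.series.tr

    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True)
        fh.write("\n")

    # stationarity score table, for audit
    pd.DataFrame(
        {"start": np.arange(result.selection.scores.size),
         "score": result.selection.scores}
    ).to_csv(os.path.join(out_dir, "stationarity_scores.tsv"), sep="\t", index=False)

    write_periodogram_tsv(result.periodogram, os.path.join(out_dir, "periodogram.tsv"))
    render_periodogram(result.periodogram, os.path.join(out_dir, "periodogram.png"))

    # component courses + spectra
    t = np.arange(result.series.n_frames) * tr
    courses = {"time_s": t}
    for k in range(result.ic.n_components):
        courses[f"ic{k + 1}"] = result.ic.courses[k]
    pd.DataFrame(courses).to_csv(os.path.join(out_dir, "courses.csv"), index=False)
    spectra = {"freq_hz": result.ic.spectra[0].freqs}
    for k, spec in enumerate(result.ic.spectra):
        spectra[f"ic{k + 1}"] = spec.amplitude()
    pd.DataFrame(spectra).to_csv(os.path.join(out_dir, "spectra.csv"), index=False)

    for k in range(result.ic.n_components):
        _save_map(result.ic.map_image(k), tr, os.path.join(out_dir, f"ic{k + 1}_map.nii.gz"))

    for name, tm in result.maps.items():
        for kind, image in (
            ("magnitude", tm.magnitude),
            ("phase", tm.phase),
            ("delay", tm.delay),
            ("coherence", tm.coherence),
        ):
            _save_map(image, tr, os.path.join(out_dir, f"{name}_{kind}.nii.gz"))
        sidecar = {
            "band": {"name": tm.band.name, "f_low_hz": tm.band.f_low,
                     "f_high_hz": tm.band.f_high},
            "reference_freq_hz": tm.reference_freq,
            "epsilon_relative": 1e-12,
            "phase_units": "radians, (-pi, pi]",
            "delay_units": "seconds",
            "warning": tm.warning,
        }
        with open(os.path.join(out_dir, f"{name}_band.json"), "w") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True)
            fh.write("\n")
        render_phase_map(
            tm,
            os.path.join(out_dir, f"{name}_phase.png"),
            coherence_threshold=cfg.coherence_threshold,
        )
    logger.info("wrote results to %s", out_dir)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

# Cyclic 4-anchor phase colormap: 0 -> white (no delay), +pi/2 -> green
# (lagging the reference), -pi/2 -> red (leading), +/-pi -> yellow (the
# half-period / inverted-amplitude ambiguity).  Domain [-pi, pi].
PHASE_CMAP = LinearSegmentedColormap.from_list(
    "phase_delay",
    [(0.0, "#ffff00"), (0.25, "#ff0000"), (0.5, "#ffffff"),
     (0.75, "#00ff00"), (1.0, "#ffff00")],
)

_GRAY = (0.5, 0.5, 0.5, 1.0)
_BACKGROUND = (0.0, 0.0, 0.0, 1.0)


def phase_to_rgba(
    phase: np.ndarray,
    coherence: Optional[np.ndarray] = None,
    threshold: float = DEFAULT_COHERENCE_THRESHOLD,
) -> np.ndarray:
    """Map wrapped phases to RGBA with the cyclic white/green/red/yellow scheme.

    Low-coherence pixels are gray; NaN phases (outside the mask) are black.
    Invariant under phase -> phase + 2 pi.
    """
    phase = np.asarray(phase, dtype=float)
    u = np.mod(phase + np.pi, 2.0 * np.pi) / (2.0 * np.pi)  # -pi..pi -> 0..1
    rgba = PHASE_CMAP(np.where(np.isfinite(u), u, 0.0))
    if coherence is not None:
        low = np.asarray(coherence) < threshold
        rgba[low & np.isfinite(phase)] = _GRAY
    rgba[~np.isfinite(phase)] = _BACKGROUND
    return rgba


def render_phase_map(
    maps: TransferMaps,
    out_path: str,
    coherence_threshold: float = DEFAULT_COHERENCE_THRESHOLD,
) -> str:
    """Render a band's phase image to PNG with a radians + seconds colorbar."""
    phase = np.squeeze(maps.phase)
    coherence = np.squeeze(maps.coherence)
    rgba = phase_to_rgba(phase, coherence, coherence_threshold)

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.imshow(rgba, origin="lower", interpolation="nearest")
    ax.set_title(
        f"{maps.band.name} phase, f_ref = {maps.reference_freq:.3g} Hz"
    )
    ax.set_xticks([])
    ax.set_yticks([])

    sm = plt.cm.ScalarMappable(cmap=PHASE_CMAP, norm=plt.Normalize(-np.pi, np.pi))
    cbar = fig.colorbar(sm, ax=ax, fraction=0.046)
    ticks = np.array([-np.pi, -np.pi / 2, 0.0, np.pi / 2, np.pi])
    delays = -ticks / (2.0 * np.pi * maps.reference_freq)
    cbar.set_ticks(ticks)
    cbar.set_ticklabels(
        [f"{t / np.pi:+.1f}π\n({d:+.2f} s)" for t, d in zip(ticks, delays)]
    )
    cbar.set_label("phase (rad) / phase delay (s)")
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out_path


def render_periodogram(pg: Periodogram, out_path: str) -> str:
    """Render the periodogram: frequency vertical, window start horizontal."""
    fig, ax = plt.subplots(figsize=(7, 4))
    extent = (0, pg.n_windows, pg.freqs[0], pg.freqs[-1])
    im = ax.imshow(
        pg.matrix, origin="lower", aspect="auto", extent=extent, cmap="gray"
    )
    ax.set_xlabel("window start frame")
    ax.set_ylabel("frequency (Hz)")
    fig.colorbar(im, ax=ax, label="summed amplitude")
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out_path
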