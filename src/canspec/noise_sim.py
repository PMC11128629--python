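"""Synthetic MEA noise recordings with exported ground truth.

The simulator produces everything the analysis pipeline consumes, at desk
scale and with known ground truth:

1. **Cell layouts** — elliptical cell footprints rasterized onto the sensor
   grid using the physical pitch. Ellipses never overlap in continuous
   space (checked on a sub-sensor occupancy raster), but two neighbouring
   cells may share a boundary sensor's area, as confluent cultures do.
   A sensor is *labelled* as belonging to a cell when that cell covers at
   least half of it; smaller fringe coverage still contributes adhesion
   signal, area-weighted.
2. **Per-sensor PSDs** — a 1/f^α background that dominates below ~10 kHz,
   a sensor-variable white floor, and, under cells, the Johnson noise
   4·k_B·T·R_J of the cleft resistance shaped by a flat plateau over the
   analysis band with raised-cosine roll-offs one octave outside. The
   three sources add (uncorrelated-sources assumption). Optionally each
   bin is gamma-sampled to emulate the fluctuation of an averaged PSD
   estimate.
3. **Time series** — Gaussian series spectrally shaped to a target PSD,
   for end-to-end tests of the Welch estimation path.
4. **Dynamics** — proliferation (daughter footprints appear adjacent to
   parents), detachment (cells vanish with a per-hour hazard) or static
   scenarios over a 0–72 h schedule, with ground-truth covered area per
   timepoint. The bundled presets are calibrated so that the untreated
   preset doubles the covered area by 72 h and the treated preset shrinks
   it 1.8-fold.

All randomness flows through explicit integer seeds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .array_model import (
    DEFAULT_TEMPERATURE_K,
    CalibrationRecording,
    NoiseRecording,
    SensorArraySpec,
    export_map_csv,
    save_recording,
)
from .biophys import johnson_psd

__all__ = [
    "NoiseModelParams",
    "CellGeometry",
    "CellLayout",
    "DynamicsScenario",
    "build_layout",
    "build_layout_to_area",
    "band_rolloff",
    "make_freq_grid",
    "synth_psd",
    "synth_chip_pair",
    "synth_timeseries",
    "evolve_layout",
    "proliferation_preset",
    "detachment_preset",
    "write_fixture",
]

#: Sub-sensor supersampling factor used by the rasterizer (per axis).
_SS = 4

#: Default HT-29-like and fibroblast-like cell diameters (mean, sd) in µm.
HT29_DIAMETER_UM = (15.0, 3.0)
HDF_DIAMETER_UM = (40.0, 8.0)

#: HT-29 grows as multi-cell clusters on collagen; this footprint scale
#: (mean, sd, µm) models the cluster blobs the electrical image resolves.
#: Isolated 15 µm footprints span barely 2–3 sensors at ~6 µm pitch and sit
#: at the segmentation resolution limit (see docs), so covered-area studies
#: use cluster-scale footprints.
HT29_CLUSTER_DIAMETER_UM = (80.0, 20.0)

#: Default cleft-resistance distribution (mean, sd) in Ω. The mean matches
#: a plateau adhesion noise of 0.027 µV²/Hz at incubation temperature.
DEFAULT_RJ_OHM = (1.58e6, 0.25e6)


@dataclass(frozen=True)
class NoiseModelParams:
    """Parameters of the per-sensor background + adhesion noise model.

    The background amplitudes are simulator choices (the defaults put the
    1/f and white contributions at equal power at 10 kHz, so 1/f dominates
    below 10 kHz and the white floor above), not measured chip values.
    ``estimator_averages`` = k gamma-samples each PSD bin with shape k,
    emulating a k-average Welch estimate; set to 0 for the noiseless model
    PSD.
    """

    a_pink: float = 5e-11  # V²·Hz^(α-1)
    alpha: float = 1.0
    s_white: float = 5e-15  # V²/Hz
    band_lo: float = 100e3  # Hz
    band_hi: float = 450e3  # Hz
    temperature: float = DEFAULT_TEMPERATURE_K  # K
    sensor_variability: float = 0.05  # relative SD of the white floor
    estimator_averages: int = 100

    def __post_init__(self) -> None:
        if self.a_pink < 0 or self.s_white < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if not (self.band_lo < self.band_hi):
            raise ValueError("band_lo must be < band_hi")
        if not (0.5 <= self.alpha <= 2.0):
            raise ValueError("alpha must lie in [0.5, 2]")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.sensor_variability < 0:
            raise ValueError("sensor_variability must be >= 0")


@dataclass(frozen=True)
class CellGeometry:
    """One elliptical cell footprint in physical (µm) coordinates."""

    row_um: float
    col_um: float
    semi_row_um: float
    semi_col_um: float
    theta_rad: float
    r_cleft_ohm: float

    @property
    def mean_radius_um(self) -> float:
        return 0.5 * (self.semi_row_um + self.semi_col_um)


def _sensor_subgrid(spec: SensorArraySpec, rows: np.ndarray, cols: np.ndarray):
    """Physical coordinates of the _SS×_SS sub-sample points of sensors."""
    off = (np.arange(_SS) + 0.5) / _SS
    ys = (rows[:, None] + off[None, :]) * spec.pitch_row_um  # (nr, ss)
    xs = (cols[:, None] + off[None, :]) * spec.pitch_col_um
    return ys, xs


def _inside(geom: CellGeometry, y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Point-in-rotated-ellipse test on broadcastable µm coordinates."""
    dy = y - geom.row_um
    dx = x - geom.col_um
    c, s = math.cos(geom.theta_rad), math.sin(geom.theta_rad)
    u = dy * c + dx * s
    v = -dy * s + dx * c
    return (u / geom.semi_row_um) ** 2 + (v / geom.semi_col_um) ** 2 <= 1.0


def _fraction_patch(spec: SensorArraySpec, geom: CellGeometry):
    """Per-sensor coverage fraction of one cell over its bounding box.

    Returns (row0, col0, frac) where ``frac`` is the fraction of each
    sensor's area covered by the ellipse, estimated on an _SS×_SS subgrid.
    """
    r_max = max(geom.semi_row_um, geom.semi_col_um)
    row0 = max(0, int((geom.row_um - r_max) / spec.pitch_row_um) - 1)
    row1 = min(spec.n_rows, int((geom.row_um + r_max) / spec.pitch_row_um) + 2)
    col0 = max(0, int((geom.col_um - r_max) / spec.pitch_col_um) - 1)
    col1 = min(spec.n_cols, int((geom.col_um + r_max) / spec.pitch_col_um) + 2)
    rows = np.arange(row0, row1)
    cols = np.arange(col0, col1)
    ys, xs = _sensor_subgrid(spec, rows, cols)
    inside = _inside(
        geom,
        ys[:, None, :, None],  # (nr, 1, ss, 1)
        xs[None, :, None, :],  # (1, nc, 1, ss)
    )
    frac = inside.mean(axis=(2, 3))
    return row0, col0, frac


def _rasterize(spec: SensorArraySpec, cells: dict[int, CellGeometry]):
    """Compose label / fraction / resistance-weight grids from geometries.

    A sensor is labelled cell-covered when the *total* covered fraction
    reaches 0.5 (half its area under cells); the label is the cell
    contributing the largest share. For an isolated cell this reduces to
    "the cell covers at least half the sensor" — equivalently, the sensor
    centre lies (essentially) inside the footprint — while in confluent
    layouts sensors straddling two touching cells still count as covered.
    """
    best_frac = np.zeros(spec.shape, dtype=float)
    best_lab = np.zeros(spec.shape, dtype=np.int32)
    fraction = np.zeros(spec.shape, dtype=float)
    rj_weight = np.zeros(spec.shape, dtype=float)
    for lab, geom in cells.items():
        r0, c0, frac = _fraction_patch(spec, geom)
        sl = (slice(r0, r0 + frac.shape[0]), slice(c0, c0 + frac.shape[1]))
        fraction[sl] += frac
        rj_weight[sl] += frac * geom.r_cleft_ohm
        better = frac > best_frac[sl]
        best_frac[sl] = np.where(better, frac, best_frac[sl])
        best_lab[sl] = np.where(better, lab, best_lab[sl])
    np.clip(fraction, 0.0, 1.0, out=fraction)
    label = np.where(fraction >= 0.5, best_lab, 0).astype(np.int32)
    return label, fraction, rj_weight


@dataclass
class CellLayout:
    """Ground-truth cell placement on a sensor grid.

    ``label_grid`` holds 0 for bare sensors and the cell id where a cell
    covers at least half the sensor; ``fraction_grid`` the (summed, capped)
    covered-area fraction; ``rj_weight_grid`` the area-weighted cleft
    resistance Σ fraction·R_J driving the adhesion-noise term.
    """

    spec: SensorArraySpec
    cells: dict[int, CellGeometry] = field(default_factory=dict)
    label_grid: np.ndarray = field(init=False)
    fraction_grid: np.ndarray = field(init=False)
    rj_weight_grid: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if any(lab <= 0 for lab in self.cells):
            raise ValueError("cell labels must be positive integers")
        self.label_grid, self.fraction_grid, self.rj_weight_grid = _rasterize(
            self.spec, self.cells
        )

    @property
    def cell_params(self) -> dict[int, float]:
        """Per-label cleft resistance R_J (Ω)."""
        return {lab: g.r_cleft_ohm for lab, g in self.cells.items()}

    @property
    def covered_area_pct(self) -> float:
        """Ground-truth covered area: % of sensors labelled as cell."""
        return 100.0 * float(np.count_nonzero(self.label_grid)) / self.spec.n_sensors

    @property
    def n_cells(self) -> int:
        return len(self.cells)


# ---------------------------------------------------------------------------
# Layout construction
# ---------------------------------------------------------------------------

class _OccupancyRaster:
    """Sub-sensor occupancy raster used for continuous non-overlap checks."""

    def __init__(self, spec: SensorArraySpec):
        self.spec = spec
        self.mask = np.zeros((spec.n_rows * _SS, spec.n_cols * _SS), dtype=bool)
        dy = spec.pitch_row_um / _SS
        dx = spec.pitch_col_um / _SS
        self.ys = (np.arange(spec.n_rows * _SS) + 0.5) * dy
        self.xs = (np.arange(spec.n_cols * _SS) + 0.5) * dx

    def _patch_idx(self, geom: CellGeometry):
        r_max = max(geom.semi_row_um, geom.semi_col_um)
        i0 = np.searchsorted(self.ys, geom.row_um - r_max)
        i1 = np.searchsorted(self.ys, geom.row_um + r_max)
        j0 = np.searchsorted(self.xs, geom.col_um - r_max)
        j1 = np.searchsorted(self.xs, geom.col_um + r_max)
        return slice(i0, i1), slice(j0, j1)

    def _inside_patch(self, geom: CellGeometry):
        si, sj = self._patch_idx(geom)
        inside = _inside(geom, self.ys[si][:, None], self.xs[sj][None, :])
        return si, sj, inside

    def overlaps(self, geom: CellGeometry) -> bool:
        si, sj, inside = self._inside_patch(geom)
        return bool(np.any(self.mask[si, sj] & inside))

    def add(self, geom: CellGeometry) -> None:
        si, sj, inside = self._inside_patch(geom)
        self.mask[si, sj] |= inside

    def remove(self, geom: CellGeometry) -> None:
        si, sj, inside = self._inside_patch(geom)
        self.mask[si, sj] &= ~inside


def _draw_geometry(
    rng: np.random.Generator,
    row_um: float,
    col_um: float,
    diameter_dist: tuple[float, float],
    rj_dist: tuple[float, float],
    min_diameter_um: float,
) -> CellGeometry:
    d_mean, d_sd = diameter_dist
    a = max(rng.normal(d_mean, d_sd), min_diameter_um) / 2.0
    b = max(rng.normal(d_mean, d_sd), min_diameter_um) / 2.0
    rj = max(rng.normal(*rj_dist), 1e4)
    theta = rng.uniform(0.0, math.pi)
    return CellGeometry(row_um, col_um, a, b, theta, rj)


def _random_center(rng: np.random.Generator, spec: SensorArraySpec, margin_um: float):
    ext_r, ext_c = spec.extent_um
    return (
        rng.uniform(margin_um, max(ext_r - margin_um, margin_um)),
        rng.uniform(margin_um, max(ext_c - margin_um, margin_um)),
    )


def build_layout(
    spec: SensorArraySpec,
    n_cells: int,
    diameter_dist: tuple[float, float] = HT29_DIAMETER_UM,
    rj_dist: tuple[float, float] = DEFAULT_RJ_OHM,
    seed: int = 0,
    max_retries: int = 200,
) -> CellLayout:
    """Place ``n_cells`` non-overlapping elliptical footprints at random.

    Deterministic for a fixed seed. Raises ``RuntimeError`` naming the
    occupancy limit when a cell cannot be placed within ``max_retries``
    random attempts.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if diameter_dist[0] <= 0 or rj_dist[0] <= 0:
        raise ValueError("distribution means must be positive")
    rng = np.random.default_rng(seed)
    occ = _OccupancyRaster(spec)
    cells: dict[int, CellGeometry] = {}
    min_d = min(spec.pitch_row_um, spec.pitch_col_um)
    for lab in range(1, n_cells + 1):
        placed = False
        for _ in range(max_retries):
            row_um, col_um = _random_center(rng, spec, diameter_dist[0] / 2.0)
            geom = _draw_geometry(rng, row_um, col_um, diameter_dist, rj_dist, min_d)
            if not occ.overlaps(geom):
                occ.add(geom)
                cells[lab] = geom
                placed = True
                break
        if not placed:
            occupancy = 100.0 * occ.mask.mean()
            raise RuntimeError(
                f"could not place cell {lab}/{n_cells} after {max_retries} attempts; "
                f"grid occupancy {occupancy:.1f}% is at its random-packing limit"
            )
    return CellLayout(spec=spec, cells=cells)


def build_layout_to_area(
    spec: SensorArraySpec,
    target_area_pct: float,
    diameter_dist: tuple[float, float] = HT29_DIAMETER_UM,
    rj_dist: tuple[float, float] = DEFAULT_RJ_OHM,
    seed: int = 0,
    max_retries: int = 200,
) -> CellLayout:
    """Place cells until the labelled covered area reaches a target %.

    Random sequential placement jams near ~50% occupancy, so when random
    attempts are exhausted the builder falls back to scanning a jittered
    lattice of candidate centres (shuffled order), which packs ellipses
    densely enough for confluent (~60%+) layouts. Raises once neither
    strategy can add a cell.
    """
    if not (0.0 <= target_area_pct <= 100.0):
        raise ValueError("target_area_pct must be in [0, 100]")
    rng = np.random.default_rng(seed)
    occ = _OccupancyRaster(spec)
    cells: dict[int, CellGeometry] = {}
    min_d = min(spec.pitch_row_um, spec.pitch_col_um)
    target_sensors = target_area_pct / 100.0 * spec.n_sensors
    mean_cell_sensors = max(
        math.pi * (diameter_dist[0] / 2.0) ** 2 / (spec.pitch_row_um * spec.pitch_col_um), 1.0
    )
    labelled = 0.0
    lab = 0

    def area_done() -> bool:
        return labelled >= target_sensors - 0.5 * mean_cell_sensors

    def try_add(geom: CellGeometry) -> bool:
        nonlocal lab, labelled
        if occ.overlaps(geom):
            return False
        lab += 1
        occ.add(geom)
        cells[lab] = geom
        labelled += math.pi * geom.semi_row_um * geom.semi_col_um / (
            spec.pitch_row_um * spec.pitch_col_um
        )
        return True

    def lattice_fill() -> None:
        # Jittered lattice with sizes clipped to the spacing: packs well
        # past the ~50% random-sequential jamming density.
        spacing = diameter_dist[0] * 1.02
        ext_r, ext_c = spec.extent_um
        grid_r = np.arange(spacing / 2.0, ext_r - spacing / 4.0, spacing)
        grid_c = np.arange(spacing / 2.0, ext_c - spacing / 4.0, spacing)
        centers = [(r, c) for r in grid_r for c in grid_c]
        rng.shuffle(centers)
        d_hi = spacing * 0.96
        d_lo = spacing * 0.70
        for r0, c0 in centers:
            if area_done():
                return
            jr = rng.uniform(-0.02, 0.02) * spacing
            jc = rng.uniform(-0.02, 0.02) * spacing
            # Confluent cells pack to the space available: sizes are drawn
            # near the lattice pitch, not from the free-growth distribution.
            geom = _draw_geometry(
                rng, r0 + jr, c0 + jc, (d_hi * 0.95, spacing * 0.03), rj_dist, min_d
            )
            a0 = float(np.clip(2 * geom.semi_row_um, d_lo, d_hi)) / 2.0
            b0 = float(np.clip(2 * geom.semi_col_um, d_lo, d_hi)) / 2.0
            for shrink in (1.0, 0.85, 0.7):  # retry smaller if jitter collides
                if try_add(
                    CellGeometry(
                        geom.row_um, geom.col_um, a0 * shrink, b0 * shrink,
                        geom.theta_rad, geom.r_cleft_ohm,
                    )
                ):
                    break

    # Dense (confluent) targets are packed lattice-first; sparse layouts use
    # random sequential placement with the lattice as a fallback.
    if target_area_pct > 40.0:
        lattice_fill()
    while not area_done():
        placed = False
        for _ in range(max_retries):
            row_um, col_um = _random_center(rng, spec, diameter_dist[0] / 2.0)
            if try_add(_draw_geometry(rng, row_um, col_um, diameter_dist, rj_dist, min_d)):
                placed = True
                break
        if not placed:
            break
    if not area_done():
        lattice_fill()
    # In-fill: remaining pockets are filled with progressively smaller
    # cells (down to single-cell scale), as a culture approaching
    # confluence does.
    scale = 0.7
    while not area_done() and diameter_dist[0] * scale >= 15.0:
        dd = (diameter_dist[0] * scale, diameter_dist[1] * scale)
        placed = False
        for _ in range(max_retries):
            row_um, col_um = _random_center(rng, spec, dd[0] / 2.0)
            if try_add(_draw_geometry(rng, row_um, col_um, dd, rj_dist, min_d)):
                placed = True
                break
        if not placed:
            scale *= 0.7
    if not area_done():
        raise RuntimeError(
            f"target area {target_area_pct:.1f}% unreachable; packed "
            f"{100.0 * occ.mask.mean():.1f}% before exhausting lattice and in-fill"
        )
    return CellLayout(spec=spec, cells=cells)


# ---------------------------------------------------------------------------
# PSD synthesis
# ---------------------------------------------------------------------------

def make_freq_grid(f_lo: float = 1e3, f_hi: float = 450e3, n: int = 450) -> np.ndarray:
    """Linear frequency grid covering the acquisition range (1–450 kHz)."""
    return np.linspace(f_lo, f_hi, n)


def band_rolloff(freq: np.ndarray, band_lo: float, band_hi: float) -> np.ndarray:
    """Plateau shape B(f): 1 inside the band, raised-cosine to 0 one octave
    outside each edge, 0 beyond. Continuous everywhere."""
    f = np.asarray(freq, dtype=float)
    b = np.zeros_like(f)
    b[(f >= band_lo) & (f <= band_hi)] = 1.0
    lo_edge = (f >= band_lo / 2.0) & (f < band_lo)
    t = np.log2(f[lo_edge] / (band_lo / 2.0))  # 0 -> 1 across the octave
    b[lo_edge] = 0.5 * (1.0 - np.cos(math.pi * t))
    hi_edge = (f > band_hi) & (f <= band_hi * 2.0)
    t = np.log2(f[hi_edge] / band_hi)
    b[hi_edge] = 0.5 * (1.0 + np.cos(math.pi * t))
    return b


def _sensor_offsets(params: NoiseModelParams, n_sensors: int, seed) -> np.ndarray:
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, params.sensor_variability, n_sensors)
    return np.clip(eps, -0.9, None)


def synth_psd(
    layout: CellLayout,
    params: NoiseModelParams,
    freq_grid: np.ndarray,
    seed: int = 0,
    meta: dict | None = None,
    sensor_offsets: np.ndarray | None = None,
) -> NoiseRecording:
    """Synthesize per-sensor one-sided PSDs for a layout.

    Model per sensor: ``S_V(f) = A_pink/f^α + S_white·(1+ε_sensor)
    + 4·k_B·T·Σ(fraction·R_J)·B(f)``; the sum over cells encodes the
    additive, uncorrelated-sources composition. ``sensor_offsets`` lets a
    culture recording share its per-sensor background with the matching
    bare calibration (a sensor's white floor is a fixed device property).
    """
    f = np.asarray(freq_grid, dtype=float)
    if np.any(f <= 0):
        raise ValueError("freq_grid must be strictly positive")
    spec = layout.spec
    if sensor_offsets is None:
        sensor_offsets = _sensor_offsets(params, spec.n_sensors, seed)
    white = params.s_white * (1.0 + sensor_offsets)
    pink = params.a_pink / f ** params.alpha
    adhesion = johnson_psd(layout.rj_weight_grid.reshape(-1), params.temperature)
    model = (
        pink[None, :]
        + white[:, None]
        + adhesion[:, None] * band_rolloff(f, params.band_lo, params.band_hi)[None, :]
    )
    if params.estimator_averages and params.estimator_averages > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
        k = params.estimator_averages
        model = model * rng.gamma(k, 1.0 / k, size=model.shape)
    m = {"temperature_K": params.temperature, "condition": "culture"}
    m.update(meta or {})
    return NoiseRecording(spec=spec, payload_kind="psd", values=model, freq_grid=f, meta=m)


def synth_chip_pair(
    layout: CellLayout,
    params: NoiseModelParams,
    freq_grid: np.ndarray,
    seed: int = 0,
    meta: dict | None = None,
) -> tuple[NoiseRecording, CalibrationRecording]:
    """Matched (culture, bare-calibration) recordings of the same chip.

    Both share the per-sensor background offsets; estimator fluctuations
    (if enabled) are independent between the two recordings.
    """
    spec = layout.spec
    offsets = _sensor_offsets(params, spec.n_sensors, seed)
    culture = synth_psd(layout, params, freq_grid, seed=seed, meta=meta, sensor_offsets=offsets)
    bare_layout = CellLayout(spec=spec, cells={})
    bare = synth_psd(
        bare_layout,
        params,
        freq_grid,
        seed=int(seed) + 1,
        meta={"condition": "bare"},
        sensor_offsets=offsets,
    )
    calibration = CalibrationRecording(
        spec=spec,
        payload_kind="psd",
        values=bare.values,
        freq_grid=bare.freq_grid,
        meta=bare.meta,
    )
    return culture, calibration


def synth_timeseries(
    freq_grid: np.ndarray,
    psd_row: np.ndarray,
    sampling_rate: float,
    duration: float,
    seed: int = 0,
) -> np.ndarray:
    """Gaussian voltage series whose one-sided PSD matches a target.

    Spectral shaping: a white complex-Gaussian spectrum is scaled by
    sqrt(target PSD) interpolated onto the FFT bins and inverse
    transformed, so the expected Welch estimate converges to the target as
    the duration grows. The DC bin is zeroed (zero-mean series). Bins
    above the last target frequency hold the last target value; bins below
    the first hold the first.
    """
    f = np.asarray(freq_grid, dtype=float)
    p = np.asarray(psd_row, dtype=float)
    if np.any(p < 0):
        raise ValueError("target PSD must be non-negative")
    if sampling_rate / 2.0 < f.max() - 1e-9:
        raise ValueError("sampling_rate/2 must cover the target freq_grid (Nyquist violation)")
    n = int(round(duration * sampling_rate))
    if n < 2 * f.size:
        raise ValueError("duration too short: need duration*sampling_rate >= 2*len(freq_grid)")
    rng = np.random.default_rng(seed)
    fft_f = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    target = np.interp(fft_f, f, p)
    # E|X_k|^2 = S(f_k)·fs·n/2 makes the one-sided periodogram unbiased.
    sigma = np.sqrt(target * sampling_rate * n / 4.0)
    x_re = rng.normal(size=fft_f.size)
    x_im = rng.normal(size=fft_f.size)
    spectrum = sigma * (x_re + 1j * x_im)
    spectrum[0] = 0.0
    if n % 2 == 0:  # real Nyquist bin
        spectrum[-1] = np.sqrt(target[-1] * sampling_rate * n / 2.0) * x_re[-1]
    return np.fft.irfft(spectrum, n=n)


# ---------------------------------------------------------------------------
# Culture dynamics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DynamicsScenario:
    """A 0–72 h culture trajectory: proliferation, detachment or static.

    ``rate`` is a per-hour exponential rate: cell count grows as
    ``N0·e^(rate·t)`` under proliferation and each cell survives an
    interval dt with probability ``e^(-rate·dt)`` under detachment.
    """

    kind: str  # "proliferation" | "detachment" | "static"
    rate: float = 0.0
    timepoints: tuple[float, ...] = (0.0, 24.0, 48.0, 72.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("proliferation", "detachment", "static"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if any(b <= a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError("timepoints must be strictly ascending")


def proliferation_preset(seed: int = 0) -> DynamicsScenario:
    """Untreated preset: covered area doubles over 72 h (rate = ln 2 / 72)."""
    return DynamicsScenario(kind="proliferation", rate=math.log(2.0) / 72.0, seed=seed)


def detachment_preset(seed: int = 0) -> DynamicsScenario:
    """Treated preset: covered area falls 1.8-fold over 72 h
    (rate = ln 1.8 / 72)."""
    return DynamicsScenario(kind="detachment", rate=math.log(1.8) / 72.0, seed=seed)


def _place_daughter(
    rng: np.random.Generator,
    spec: SensorArraySpec,
    occ: _OccupancyRaster,
    parents: dict[int, CellGeometry],
    diameter_dist: tuple[float, float],
    rj_dist: tuple[float, float],
    max_retries: int = 600,
) -> CellGeometry | None:
    """A daughter footprint adjacent to a random parent; None on failure.

    The daughter's size and cleft resistance are drawn once, and only the
    position varies across attempts — retrying the size as well would
    select systematically smaller daughters (large ones collide more).
    """
    min_d = min(spec.pitch_row_um, spec.pitch_col_um)
    labels = list(parents)
    proto = _draw_geometry(rng, 0.0, 0.0, diameter_dist, rj_dist, min_d)
    ext_r, ext_c = spec.extent_um
    margin = 0.6 * proto.mean_radius_um  # keep most of the footprint on-grid
    for attempt in range(max_retries):
        parent = parents[labels[rng.integers(len(labels))]]
        ang = rng.uniform(0.0, 2.0 * math.pi)
        # Widen the admissible annulus as attempts fail: crowded cultures
        # spawn daughters into the nearest free pocket, not only flush
        # against the parent.
        reach = 1.4 + 1.2 * (attempt / max_retries)
        dist = (parent.mean_radius_um + proto.mean_radius_um) * rng.uniform(1.02, reach)
        row_um = parent.row_um + dist * math.sin(ang)
        col_um = parent.col_um + dist * math.cos(ang)
        if not (margin < row_um < ext_r - margin and margin < col_um < ext_c - margin):
            continue
        geom = CellGeometry(
            row_um, col_um, proto.semi_row_um, proto.semi_col_um,
            proto.theta_rad, proto.r_cleft_ohm,
        )
        if not occ.overlaps(geom):
            return geom
    return None


def evolve_layout(
    layout: CellLayout,
    scenario: DynamicsScenario,
    diameter_dist: tuple[float, float] = HT29_DIAMETER_UM,
    rj_dist: tuple[float, float] = DEFAULT_RJ_OHM,
) -> list[CellLayout]:
    """Layouts at each scenario timepoint; element 0 is the input layout.

    Proliferation only adds cells (daughters adjacent to surviving
    parents, tracking the exponential target count); detachment only
    removes them; labels of surviving cells are conserved. The returned
    trajectory is deterministic per scenario seed.
    """
    out = [layout]
    if scenario.kind == "static":
        return [layout] * len(scenario.timepoints)
    rng = np.random.default_rng(scenario.seed)
    spec = layout.spec
    occ = _OccupancyRaster(spec)
    cells = dict(layout.cells)
    for g in cells.values():
        occ.add(g)

    def footprint_area(gs) -> float:
        return sum(math.pi * g.semi_row_um * g.semi_col_um for g in gs)

    area0 = footprint_area(cells.values())
    next_label = max(cells, default=0) + 1
    t0 = scenario.timepoints[0]
    for t_prev, t in zip(scenario.timepoints, scenario.timepoints[1:]):
        dt = t - t_prev
        if scenario.kind == "detachment":
            p_detach = 1.0 - math.exp(-scenario.rate * dt)
            for lab in list(cells):
                if rng.random() < p_detach:
                    occ.remove(cells[lab])
                    del cells[lab]
        else:  # proliferation: grow footprint area along the exponential
            target_area = area0 * math.exp(scenario.rate * (t - t0))
            # As free space fragments near confluence, daughters shrink to
            # fit the remaining pockets (down to single-cell scale) the way
            # a crowding culture fills in, instead of stalling.
            scale = 1.0
            min_daughter_um = 18.0
            while footprint_area(cells.values()) < target_area and cells:
                dd = (
                    max(diameter_dist[0] * scale, min_daughter_um),
                    diameter_dist[1] * scale,
                )
                geom = _place_daughter(rng, spec, occ, cells, dd, rj_dist)
                if geom is None:
                    if dd[0] <= min_daughter_um:
                        break
                    scale *= 0.7
                    continue
                occ.add(geom)
                cells[next_label] = geom
                next_label += 1
        out.append(CellLayout(spec=spec, cells=dict(cells)))
    return out


# ---------------------------------------------------------------------------
# Fixture writer
# ---------------------------------------------------------------------------

def write_fixture(
    outdir,
    layouts: Sequence[CellLayout],
    scenario: DynamicsScenario,
    params: NoiseModelParams,
    freq_grid: np.ndarray,
    chip_id: str = "sim-chip",
    seed: int = 0,
) -> dict:
    """Emit a complete synthetic dataset for one chip.

    Writes, per timepoint, the culture recording and matching bare
    calibration (HDF5 container), the ground-truth label grid (CSV), and a
    JSON manifest with parameters, seeds and true covered areas. Returns
    the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "chip_id": chip_id,
        "seed": int(seed),
        "scenario": {
            "kind": scenario.kind,
            "rate_per_h": scenario.rate,
            "timepoints_h": list(scenario.timepoints),
            "seed": scenario.seed,
        },
        "noise_params": {
            "a_pink": params.a_pink,
            "alpha": params.alpha,
            "s_white": params.s_white,
            "band_lo": params.band_lo,
            "band_hi": params.band_hi,
            "temperature_K": params.temperature,
            "sensor_variability": params.sensor_variability,
            "estimator_averages": params.estimator_averages,
        },
        "timepoints": [],
    }
    for t, lay in zip(scenario.timepoints, layouts):
        culture, bare = synth_chip_pair(
            lay,
            params,
            freq_grid,
            seed=int(seed) + int(t),
            meta={"chip_id": chip_id, "timepoint_h": t},
        )
        c_path = outdir / f"{chip_id}_t{int(t):03d}h_culture.h5"
        b_path = outdir / f"{chip_id}_t{int(t):03d}h_bare.h5"
        l_path = outdir / f"{chip_id}_t{int(t):03d}h_labels.csv"
        save_recording(c_path, culture)
        save_recording(b_path, bare)
        export_map_csv(l_path, lay.spec, lay.label_grid.astype(float), header="row,col,label")
        manifest["timepoints"].append(
            {
                "timepoint_h": t,
                "culture": c_path.name,
                "bare": b_path.name,
                "labels": l_path.name,
                "true_area_pct": lay.covered_area_pct,
                "n_cells": lay.n_cells,
            }
        )
    with open(outdir / f"{chip_id}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
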