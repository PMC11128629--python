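"""PSD estimation, background subtraction and adhesion-noise maps.

Pipeline order: per-sensor Welch PSDs (for time-series recordings) →
bin-wise subtraction of the bare-sensor calibration, giving the cell
adhesion noise ΔS_V under the uncorrelated-sources assumption → plateau
summary over the resistive band (default 100–450 kHz) → per-sensor scalar
map at the single analysis frequency (default 300 kHz, the band middle).

Negative ΔS_V values are retained in the raw spectra — they are needed
for unbiased band means — and clamped to zero only in the imaging map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .array_model import (
    NoiseRecording,
    SensorArraySpec,
    UV2_PER_HZ,
    export_map_csv,
)

__all__ = [
    "DEFAULT_BAND",
    "DEFAULT_ANALYSIS_FREQ",
    "FLATNESS_THRESHOLD",
    "AdhesionNoiseSpectra",
    "AdhesionNoiseSpectrum",
    "PlateauSummary",
    "AdhesionNoiseMap",
    "welch_psd",
    "subtract_background",
    "plateau_summary",
    "extract_map",
]

#: Resistive-plateau band (Hz): flat ΔS_V here indicates an ohmic cleft.
DEFAULT_BAND = (100e3, 450e3)

#: Single analysis frequency (Hz), the middle of the plateau band.
DEFAULT_ANALYSIS_FREQ = 300e3

#: Max |log10 deviation| from the band mean below which a spectrum is
#: flagged as flat (resistive). Configurable; there is no field-standard
#: criterion for this.
FLATNESS_THRESHOLD = 0.15


def welch_psd(
    recording: NoiseRecording,
    segment_length: int = 4096,
    overlap_fraction: float = 0.5,
    window: str = "hann",
) -> NoiseRecording:
    """Welch one-sided PSD per sensor from a time-series recording.

    Defaults (Hann, 50% overlap, 4096-sample segments at 1 MHz) give
    ≥ 100 averages per second of data at a 244 Hz bin width — fine enough
    for the 1–450 kHz analysis range. No detrending is applied, so the
    PSD integrates to the series power (Parseval contract).
    """
    if recording.payload_kind != "timeseries":
        raise ValueError("welch_psd requires a timeseries recording")
    n = recording.values.shape[1]
    if segment_length > n:
        raise ValueError(f"segment_length {segment_length} exceeds series length {n}")
    if not (0.0 <= overlap_fraction < 1.0):
        raise ValueError("overlap_fraction must be in [0, 1)")
    freqs, psd = signal.welch(
        recording.values,
        fs=recording.sampling_rate,
        window=window,
        nperseg=segment_length,
        noverlap=int(segment_length * overlap_fraction),
        detrend=False,
        return_onesided=True,
        axis=-1,
    )
    return NoiseRecording(
        spec=recording.spec,
        payload_kind="psd",
        values=psd,
        freq_grid=freqs,
        sampling_rate=recording.sampling_rate,
        meta=dict(recording.meta),
    )


@dataclass(frozen=True)
class AdhesionNoiseSpectrum:
    """ΔS_V(f) of a single sensor (may be negative before clamping)."""

    freq_grid: np.ndarray
    delta_sv: np.ndarray
    sensor: int

    def __post_init__(self) -> None:
        if self.delta_sv.shape != self.freq_grid.shape:
            raise ValueError("delta_sv and freq_grid must be shape-consistent")


@dataclass
class AdhesionNoiseSpectra:
    """ΔS_V(f) for every sensor of a chip (n_sensors × n_freqs, V²/Hz)."""

    spec: SensorArraySpec
    freq_grid: np.ndarray
    delta: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        if self.delta.shape != (self.spec.n_sensors, self.freq_grid.size):
            raise ValueError("delta must be (n_sensors, n_freqs)")

    def sensor(self, i: int) -> AdhesionNoiseSpectrum:
        return AdhesionNoiseSpectrum(self.freq_grid, self.delta[i], i)


def subtract_background(culture: NoiseRecording, bare: NoiseRecording) -> AdhesionNoiseSpectra:
    """ΔS_V = S_V(culture) − S_V(bare), bin-wise and unclamped.

    Valid under the assumption that the cleft's thermal noise and the
    sensor's intrinsic background are uncorrelated, so their powers add.
    Exact (no estimation error) when both inputs are PSD recordings.
    """
    if culture.payload_kind != "psd" or bare.payload_kind != "psd":
        raise ValueError("subtract_background requires psd recordings")
    if culture.spec != bare.spec:
        raise ValueError("culture and bare recordings use different sensor grids")
    if culture.freq_grid.shape != bare.freq_grid.shape or not np.allclose(
        culture.freq_grid, bare.freq_grid
    ):
        raise ValueError("culture and bare recordings use different frequency grids")
    return AdhesionNoiseSpectra(
        spec=culture.spec,
        freq_grid=culture.freq_grid.copy(),
        delta=culture.values - bare.values,
        meta=dict(culture.meta),
    )


@dataclass(frozen=True)
class PlateauSummary:
    """Band mean of ΔS_V and its flatness over the resistive band."""

    band: tuple[float, float]
    mean_delta_sv: float  # V²/Hz
    flatness: float  # max |log10(ΔS_V / band mean)| over in-band bins
    resistive: bool  # flat (ohmic) per FLATNESS_THRESHOLD?


def plateau_summary(
    spectrum: AdhesionNoiseSpectrum,
    band: tuple[float, float] = DEFAULT_BAND,
    flatness_threshold: float = FLATNESS_THRESHOLD,
) -> PlateauSummary:
    """Mean and flatness of one sensor's ΔS_V over the plateau band.

    Flatness is the max absolute log10 deviation from the band mean; bins
    or means that are not positive make the flatness infinite (a negative
    or zero plateau cannot be ohmic).
    """
    lo, hi = band
    if not lo < hi:
        raise ValueError("band must satisfy lo < hi")
    sel = (spectrum.freq_grid >= lo) & (spectrum.freq_grid <= hi)
    if not np.any(sel):
        raise ValueError("no frequency bins inside the requested band")
    vals = spectrum.delta_sv[sel]
    mean = float(vals.mean())
    if mean > 0 and np.all(vals > 0):
        flatness = float(np.max(np.abs(np.log10(vals / mean))))
    else:
        flatness = float("inf")
    return PlateauSummary(
        band=(lo, hi),
        mean_delta_sv=mean,
        flatness=flatness,
        resistive=flatness <= flatness_threshold,
    )


@dataclass
class AdhesionNoiseMap:
    """Per-sensor ΔS_V at the analysis frequency.

    ``raw_values`` keeps negative excursions (used for unbiased means);
    ``values`` is clamped at zero for imaging.
    """

    spec: SensorArraySpec
    analysis_freq: float
    raw_values: np.ndarray  # (n_sensors,), V²/Hz, unclamped
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.raw_values = np.asarray(self.raw_values, dtype=float).reshape(-1)
        if self.raw_values.size != self.spec.n_sensors:
            raise ValueError("raw_values length must equal the sensor count")

    @property
    def values(self) -> np.ndarray:
        return np.maximum(self.raw_values, 0.0)

    @property
    def grid(self) -> np.ndarray:
        """Clamped map reshaped to the sensor grid."""
        return self.values.reshape(self.spec.shape)

    @property
    def raw_grid(self) -> np.ndarray:
        return self.raw_values.reshape(self.spec.shape)

    def to_csv(self, path) -> None:
        """Export in µV²/Hz as (row, col, value) CSV."""
        export_map_csv(
            path, self.spec, self.values / UV2_PER_HZ, header="row,col,value_uV2_per_Hz"
        )

    def to_tiff(self, path) -> None:
        """Export the clamped map as a 32-bit float TIFF (µV²/Hz)."""
        import tifffile

        tifffile.imwrite(path, (self.grid / UV2_PER_HZ).astype(np.float32))


def extract_map(
    spectra: AdhesionNoiseSpectra, analysis_freq: float = DEFAULT_ANALYSIS_FREQ
) -> AdhesionNoiseMap:
    """Per-sensor ΔS_V at the nearest frequency bin to ``analysis_freq``.

    Nearest-bin lookup (no interpolation) matches a discrete acquisition
    grid; when the requested frequency lies exactly between two bins the
    lower bin is used.
    """
    f = spectra.freq_grid
    if not (f[0] <= analysis_freq <= f[-1]):
        raise ValueError(
            f"analysis frequency {analysis_freq:g} Hz outside the grid [{f[0]:g}, {f[-1]:g}]"
        )
    idx = int(np.argmin(np.abs(f - analysis_freq)))  # ties -> first (lower) bin
    return AdhesionNoiseMap(
        spec=spectra.spec,
        analysis_freq=float(f[idx]),
        raw_values=spectra.delta[:, idx].copy(),
        meta=dict(spectra.meta),
    )
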