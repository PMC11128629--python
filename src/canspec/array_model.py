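"""Sensor-array geometry and recording containers.

The recording platform is a high-density CMOS microelectrode array (MEA):
a rectangular grid of capacitive, oxide-insulated field-effect recording
sites. Each site reports the extracellular voltage in the electrolyte-filled
cleft above it; the quantity analysed throughout this package is the
one-sided voltage-noise power spectral density S_V of that signal.

Conventions used by every other module:

* 0-based, row-major sensor indexing; ``row`` is the slow axis.
* Internal SI units everywhere: V²/Hz for PSDs, Hz, K, Ω. The µV²/Hz and
  MΩ presentation units appear only at CLI/export boundaries
  (1 µV²/Hz = 1e-12 V²/Hz).
* PSDs are one-sided.

The on-disk container is a small HDF5 schema (see :func:`save_recording`):
datasets ``/values`` plus either ``/freq_grid`` (PSD payload) or the
``sampling_rate``/``duration`` scalars (time-series payload), with the
array geometry and free-form metadata stored as JSON in root attributes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import h5py
import numpy as np

__all__ = [
    "UV2_PER_HZ",
    "DEFAULT_TEMPERATURE_K",
    "SensorArraySpec",
    "NoiseRecording",
    "CalibrationRecording",
    "make_array_spec",
    "sensor_index_to_grid",
    "grid_to_sensor_index",
    "save_recording",
    "load_recording",
    "export_map_csv",
]

#: Scale factor between the µV²/Hz presentation unit and the V²/Hz SI unit.
UV2_PER_HZ = 1e-12

#: Incubation temperature (37 °C) assumed when a recording's metadata does
#: not state one. Cultures are recorded at incubation temperature, and the
#: thermal-noise arithmetic is temperature-dependent.
DEFAULT_TEMPERATURE_K = 310.15


@dataclass(frozen=True)
class SensorArraySpec:
    """Geometry of the rectangular recording-site grid.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions (sensors).
    pitch_row_um, pitch_col_um
        Centre-to-centre sensor pitch along the row (slow) and column
        (fast) axes, in micrometres.
    oxide_label
        Free-text description of the top dielectric (documentation only).
    """

    n_rows: int
    n_cols: int
    pitch_row_um: float
    pitch_col_um: float
    oxide_label: str = ""

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.pitch_row_um <= 0 or self.pitch_col_um <= 0:
            raise ValueError("sensor pitches must be positive")

    @property
    def n_sensors(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def extent_um(self) -> tuple[float, float]:
        """Exact physical extent (rows-axis, cols-axis) in µm.

        Stored exactly as n·pitch; vendor datasheets round this figure, so
        presentation layers may round but the model never does.
        """
        return (self.n_rows * self.pitch_row_um, self.n_cols * self.pitch_col_um)

    @classmethod
    def canq_chip(cls) -> "SensorArraySpec":
        """Default geometry: 256 × 384 sites at 6.5 µm × 5.6 µm pitch."""
        return cls(256, 384, 6.5, 5.6, oxide_label="ALD TiO2 30 nm")

    def to_dict(self) -> dict[str, Any]:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "pitch_row_um": self.pitch_row_um,
            "pitch_col_um": self.pitch_col_um,
            "oxide_label": self.oxide_label,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SensorArraySpec":
        return cls(**d)


def make_array_spec(
    n_rows: int, n_cols: int, pitch_row_um: float, pitch_col_um: float, oxide_label: str = ""
) -> SensorArraySpec:
    """Validated constructor for :class:`SensorArraySpec`."""
    return SensorArraySpec(n_rows, n_cols, pitch_row_um, pitch_col_um, oxide_label)


def sensor_index_to_grid(i: int | np.ndarray, spec: SensorArraySpec) -> tuple:
    """Map linear sensor index -> (row, col), row-major.

    Accepts scalars or integer arrays; raises for out-of-range indices.
    """
    idx = np.asarray(i)
    if np.any(idx < 0) or np.any(idx >= spec.n_sensors):
        raise IndexError(f"sensor index out of range [0, {spec.n_sensors})")
    row, col = np.divmod(idx, spec.n_cols)
    if np.isscalar(i) or idx.ndim == 0:
        return (int(row), int(col))
    return (row, col)


def grid_to_sensor_index(row: int | np.ndarray, col: int | np.ndarray, spec: SensorArraySpec) -> int | np.ndarray:
    """Inverse of :func:`sensor_index_to_grid`."""
    r = np.asarray(row)
    c = np.asarray(col)
    if np.any(r < 0) or np.any(r >= spec.n_rows) or np.any(c < 0) or np.any(c >= spec.n_cols):
        raise IndexError("grid coordinates out of range")
    idx = r * spec.n_cols + c
    if np.isscalar(row) and np.isscalar(col):
        return int(idx)
    return idx


@dataclass
class NoiseRecording:
    """Per-sensor voltage time series or one-sided PSDs for one recording.

    ``values`` has shape ``(n_sensors, n_samples)`` for the ``timeseries``
    payload or ``(n_sensors, n_freqs)`` (one-sided PSD, V²/Hz) for ``psd``.
    ``meta`` carries chip id, timepoint (h), condition label and the
    recording temperature in K (``DEFAULT_TEMPERATURE_K`` when absent).
    """

    spec: SensorArraySpec
    payload_kind: str  # "timeseries" | "psd"
    values: np.ndarray
    sampling_rate: float | None = None
    duration: float | None = None
    freq_grid: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.spec.n_sensors:
            raise ValueError(
                f"values must be (n_sensors={self.spec.n_sensors}, n), got {self.values.shape}"
            )
        if self.payload_kind == "psd":
            if self.freq_grid is None:
                raise ValueError("psd payload requires freq_grid")
            self.freq_grid = np.asarray(self.freq_grid, dtype=float)
            if self.freq_grid.ndim != 1 or self.freq_grid.size != self.values.shape[1]:
                raise ValueError("freq_grid length must match values")
            if np.any(np.diff(self.freq_grid) <= 0):
                raise ValueError("freq_grid must be strictly increasing")
            if np.any(self.values < 0):
                raise ValueError("PSD values must be non-negative")
            if self.sampling_rate is not None and np.any(self.freq_grid > self.sampling_rate / 2):
                raise ValueError("freq_grid exceeds Nyquist frequency")
            if np.any(self.freq_grid < 0):
                raise ValueError("freq_grid must be non-negative")
        elif self.payload_kind == "timeseries":
            if self.sampling_rate is None or self.sampling_rate <= 0:
                raise ValueError("timeseries payload requires a positive sampling_rate")
            if self.duration is None:
                self.duration = self.values.shape[1] / self.sampling_rate
        else:
            raise ValueError(f"unknown payload_kind {self.payload_kind!r}")

    @property
    def temperature(self) -> float:
        return float(self.meta.get("temperature_K", DEFAULT_TEMPERATURE_K))

    @property
    def condition(self) -> str:
        return str(self.meta.get("condition", ""))


class CalibrationRecording(NoiseRecording):
    """A bare-sensor (electrolyte only, no cells) background recording."""

    def __post_init__(self) -> None:
        self.meta.setdefault("condition", "bare")
        if self.meta.get("condition") != "bare":
            raise ValueError("calibration recordings must have condition 'bare'")
        super().__post_init__()


# ---------------------------------------------------------------------------
# Container I/O
# ---------------------------------------------------------------------------

def save_recording(path, rec: NoiseRecording) -> None:
    """Write a recording to the documented HDF5 container schema."""
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=rec.values)
        f.attrs["payload_kind"] = rec.payload_kind
        f.attrs["spec_json"] = json.dumps(rec.spec.to_dict())
        f.attrs["meta_json"] = json.dumps(rec.meta)
        if rec.payload_kind == "psd":
            f.create_dataset("freq_grid", data=rec.freq_grid)
            if rec.sampling_rate is not None:
                f.attrs["sampling_rate"] = float(rec.sampling_rate)
        else:
            f.attrs["sampling_rate"] = float(rec.sampling_rate)
            f.attrs["duration"] = float(rec.duration)


def load_recording(path) -> NoiseRecording:
    """Read a recording written by :func:`save_recording`.

    A recording whose metadata condition is ``bare`` loads as a
    :class:`CalibrationRecording`.
    """
    with h5py.File(path, "r") as f:
        kind = str(f.attrs["payload_kind"])
        spec = SensorArraySpec.from_dict(json.loads(f.attrs["spec_json"]))
        meta = json.loads(f.attrs["meta_json"])
        values = f["values"][...]
        freq_grid = f["freq_grid"][...] if "freq_grid" in f else None
        sampling_rate = float(f.attrs["sampling_rate"]) if "sampling_rate" in f.attrs else None
        duration = float(f.attrs["duration"]) if "duration" in f.attrs else None
    cls = CalibrationRecording if meta.get("condition") == "bare" else NoiseRecording
    return cls(
        spec=spec,
        payload_kind=kind,
        values=values,
        sampling_rate=sampling_rate,
        duration=duration,
        freq_grid=freq_grid,
        meta=meta,
    )


def export_map_csv(path, spec: SensorArraySpec, values: np.ndarray, header: str = "row,col,value") -> None:
    """Write a per-sensor scalar map as ``row,col,value`` CSV.

    ``values`` may be flat ``(n_sensors,)`` or grid-shaped
    ``(n_rows, n_cols)``; rows are emitted in row-major sensor order.
    """
    v = np.asarray(values, dtype=float).reshape(-1)
    if v.size != spec.n_sensors:
        raise ValueError("value count does not match the sensor grid")
    rows, cols = sensor_index_to_grid(np.arange(spec.n_sensors), spec)
    table = np.column_stack([rows, cols, v])
    np.savetxt(path, table, delimiter=",", header=header, comments="", fmt=["%d", "%d", "%.10g"])
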