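"""Raw detector-frame I/O and calibration handling.

The scanner's proprietary raw dialect is out of scope; frames are stored in a
small documented binary container instead (magic ``CTRAW001``), holding one
exposure's rows x channels energy-integrated readings plus acquisition
metadata.  Calibration mimics what a data-acquisition system does: per-element
gains plus optional compression of high readings into a 16-bit integer range.
The measurement method needs the *uncalibrated* data, so the central operation
here is ``decalibrate`` -- applying the calibration inversely.

Container layout (little-endian, no padding):
  8s  magic ("CTRAW001" frames, "CTCAL001" calibration tables)
  u32 n_rows, u32 n_channels
  u8  dtype code (0 = float32, 1 = uint16 + scale/offset)
  f64 scale, f64 offset            (quantisation parameters; 1, 0 for float32)
  f64 kVp, f64 mA, f64 exposure_s
  u8  flags (bit0 phantom, bit1 blocker, bit2 calibrated)
  u64 seed
  row-major payload
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "FrameMeta", "DetectorFrame", "CalibrationTable", "RawFormatError",
    "write_frame", "read_frame", "calibrate", "decalibrate",
    "write_calibration", "read_calibration",
]

_MAGIC_FRAME = b"CTRAW001"
_MAGIC_CAL = b"CTCAL001"
_HEADER = struct.Struct("<8sIIBdddddBQ")  # 66 bytes


class RawFormatError(IOError):
    """The file is not a valid raw-frame container."""


@dataclass(frozen=True)
class FrameMeta:
    kvp: float = 0.0
    tube_current_ma: float = 0.0
    exposure_s: float = 0.0
    phantom_present: bool = False
    blocker_present: bool = False
    calibrated: bool = False
    seed: int = 0
    compensated: bool = False  # in-memory only, set by the pipeline


@dataclass(frozen=True)
class DetectorFrame:
    """One exposure's readings (n_rows x n_channels, >= 0) plus metadata."""

    readings: np.ndarray
    meta: FrameMeta

    def __post_init__(self) -> None:
        r = np.asarray(self.readings, dtype=float)
        if r.ndim != 2:
            raise ValueError("readings must be a 2-D rows x channels matrix")
        if np.any(r < 0):
            raise ValueError("negative detector readings")
        object.__setattr__(self, "readings", r)

    @property
    def shape(self) -> tuple[int, int]:
        return self.readings.shape


def _flags(meta: FrameMeta) -> int:
    return (int(meta.phantom_present) | int(meta.blocker_present) << 1
            | int(meta.calibrated) << 2)


def write_frame(frame: DetectorFrame, path: str | Path, dtype: str = "float32") -> Path:
    """Write a frame; ``dtype`` 'float32' stores readings exactly (to f32),
    'uint16' quantises them affinely into the 16-bit range."""
    path = Path(path)
    n_rows, n_ch = frame.shape
    r = frame.readings
    if dtype == "float32":
        code, scale, offset = 0, 1.0, 0.0
        payload = r.astype("<f4").tobytes()
    elif dtype == "uint16":
        code = 1
        offset = float(r.min())
        scale = float(max(r.max() - offset, 1e-300)) / 65535.0
        q = np.round((r - offset) / scale).astype("<u2")
        payload = q.tobytes()
    else:
        raise ValueError(f"unknown dtype {dtype!r}")
    m = frame.meta
    header = _HEADER.pack(_MAGIC_FRAME, n_rows, n_ch, code, scale, offset,
                          m.kvp, m.tube_current_ma, m.exposure_s, _flags(m), m.seed)
    path.write_bytes(header + payload)
    return path


def read_frame(path: str | Path) -> DetectorFrame:
    """Inverse of :func:`write_frame`."""
    blob = Path(path).read_bytes()
    if len(blob) < _HEADER.size or blob[:8] != _MAGIC_FRAME:
        raise RawFormatError(f"{path}: bad magic, not a raw frame file")
    (_, n_rows, n_ch, code, scale, offset,
     kvp, ma, exp_s, flags, seed) = _HEADER.unpack_from(blob)
    itemsize = 4 if code == 0 else 2
    expected = _HEADER.size + n_rows * n_ch * itemsize
    if len(blob) != expected:
        raise RawFormatError(
            f"{path}: truncated payload, expected {expected} bytes, got {len(blob)}"
        )
    raw = blob[_HEADER.size:]
    if code == 0:
        readings = np.frombuffer(raw, dtype="<f4").astype(float)
    elif code == 1:
        readings = np.frombuffer(raw, dtype="<u2").astype(float) * scale + offset
    else:
        raise RawFormatError(f"{path}: unknown dtype code {code}")
    meta = FrameMeta(kvp=kvp, tube_current_ma=ma, exposure_s=exp_s,
                     phantom_present=bool(flags & 1), blocker_present=bool(flags & 2),
                     calibrated=bool(flags & 4), seed=seed)
    return DetectorFrame(readings=np.clip(readings.reshape(n_rows, n_ch), 0.0, None),
                         meta=meta)


@dataclass(frozen=True)
class CalibrationTable:
    """Per-element gains (> 0) plus the compression mode the DAS applies.

    compression 'none' keeps floating readings; 'uint16' additionally maps
    readings affinely into the 16-bit integer range on disk, mirroring a DAS
    that compresses high detector values for file-size reasons.
    """

    gains: np.ndarray
    compression: str = "none"

    def __post_init__(self) -> None:
        g = np.asarray(self.gains, dtype=float)
        if np.any(g <= 0):
            raise ValueError("calibration gains must all be positive")
        if self.compression not in ("none", "uint16"):
            raise ValueError(f"unknown compression {self.compression!r}")
        object.__setattr__(self, "gains", g)

    @classmethod
    def identity(cls, n_rows: int, n_channels: int) -> "CalibrationTable":
        return cls(gains=np.ones((n_rows, n_channels)))


def calibrate(frame: DetectorFrame, table: CalibrationTable) -> DetectorFrame:
    """Apply the scanner calibration (gains) to an uncalibrated frame."""
    if frame.meta.calibrated:
        raise ValueError("frame is already calibrated")
    if frame.shape != table.gains.shape:
        raise ValueError(f"shape mismatch: frame {frame.shape} vs table {table.gains.shape}")
    return DetectorFrame(readings=frame.readings * table.gains,
                         meta=replace(frame.meta, calibrated=True))


def decalibrate(frame: DetectorFrame, table: CalibrationTable) -> DetectorFrame:
    """Invert the calibration factors to recover the untainted readings."""
    if not frame.meta.calibrated:
        raise ValueError("frame is not calibrated; nothing to invert")
    if frame.shape != table.gains.shape:
        raise ValueError(f"shape mismatch: frame {frame.shape} vs table {table.gains.shape}")
    return DetectorFrame(readings=frame.readings / table.gains,
                         meta=replace(frame.meta, calibrated=False))


def write_calibration(table: CalibrationTable, path: str | Path) -> Path:
    path = Path(path)
    n_rows, n_ch = table.gains.shape
    header = _HEADER.pack(_MAGIC_CAL, n_rows, n_ch, 0, 1.0, 0.0,
                          0.0, 0.0, 0.0, 0, 0)
    path.write_bytes(header + table.gains.astype("<f4").tobytes())
    return path


def read_calibration(path: str | Path) -> CalibrationTable:
    blob = Path(path).read_bytes()
    if len(blob) < _HEADER.size or blob[:8] != _MAGIC_CAL:
        raise RawFormatError(f"{path}: bad magic, not a calibration file")
    _, n_rows, n_ch, *_ = _HEADER.unpack_from(blob)
    gains = np.frombuffer(blob[_HEADER.size:], dtype="<f4").astype(float)
    if gains.size != n_rows * n_ch:
        raise RawFormatError(f"{path}: truncated calibration payload")
    return CalibrationTable(gains=gains.reshape(n_rows, n_ch))
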