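"""Calibrated image-sequence I/O and measurement reports.

A B-scan time series is stored on disk as a multi-page TIFF (one page per
frame) next to a small JSON sidecar holding the temporal and spatial
calibration: frame rate, lateral and axial pixel pitch, and the refractive
index of the liquid layers.  In memory the universal container is
:class:`BScanSequence`, a ``T x Z x X`` float array plus that calibration.

Summary statistics follow the mean +/- SEM convention (SEM = sample standard
deviation / sqrt(n)), and measurement rows are collected into a CSV report.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import SidecarError

#: keys that must be present in a calibration sidecar
REQUIRED_SIDECAR_KEYS = ("frame_rate", "dx_um", "dz_um", "n_liquid")


@dataclass
class BScanSequence:
    """A cross-sectional image time series with calibration.

    Parameters
    ----------
    frames:
        Intensity grid of shape ``(T, Z, X)``.  ``Z`` increases with depth
        (row 0 is the top of the image, i.e. the air side).
    dt:
        Frame interval in seconds.
    dx:
        Lateral pixel pitch in micrometres per pixel.
    dz:
        Axial pixel pitch in micrometres per pixel (image coordinates, i.e.
        optical path; divide sub-interface distances by ``n_liquid`` to get
        physical distances).
    n_liquid:
        Refractive index of the liquid layers (mucus and periciliary
        liquid), used to convert optical path length to physical depth.
    """

    frames: np.ndarray
    dt: float
    dx: float
    dz: float
    n_liquid: float = 1.33

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a T x Z x X array with T >= 1")
        if not (self.dt > 0 and self.dx > 0 and self.dz > 0):
            raise ValueError("dt, dx and dz must all be positive")
        if self.n_liquid < 1:
            raise ValueError("n_liquid must be >= 1")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite intensities")

    # -- convenience ------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def duration(self) -> float:
        """Total duration in seconds."""
        return self.n_frames * self.dt

    @property
    def frame_rate(self) -> float:
        return 1.0 / self.dt

    @property
    def nyquist(self) -> float:
        """Nyquist frequency in Hz."""
        return 0.5 / self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt

    @property
    def z_um(self) -> np.ndarray:
        """Axial pixel-centre coordinates in image micrometres."""
        return (np.arange(self.frames.shape[1]) + 0.5) * self.dz

    @property
    def x_um(self) -> np.ndarray:
        """Lateral pixel-centre coordinates in micrometres."""
        return (np.arange(self.frames.shape[2]) + 0.5) * self.dx


def save_sequence(
    seq: BScanSequence,
    stack_path: str | Path,
    sidecar_path: str | Path,
    dtype: str = "float32",
    extra_meta: Optional[dict] = None,
) -> None:
    """Write a sequence as a multi-page TIFF plus JSON calibration sidecar.

    ``dtype`` may be ``"float32"`` (default, lossless for analysis use) or
    ``"uint16"`` (intensities assumed in [0, 1], scaled by 65535 for
    interoperability with viewers that dislike float TIFFs).
    """
    stack_path = Path(stack_path)
    sidecar_path = Path(sidecar_path)
    if dtype == "float32":
        data = seq.frames.astype(np.float32)
    elif dtype == "uint16":
        data = np.clip(seq.frames, 0.0, 1.0)
        data = np.round(data * 65535.0).astype(np.uint16)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}; use 'float32' or 'uint16'")
    tifffile.imwrite(stack_path, data, photometric="minisblack")
    meta = {
        "frame_rate": 1.0 / seq.dt,
        "dx_um": seq.dx,
        "dz_um": seq.dz,
        "n_liquid": seq.n_liquid,
    }
    if extra_meta:
        meta.update(extra_meta)
    sidecar_path.write_text(json.dumps(meta, indent=2) + "\n")


def load_sequence(stack_path: str | Path, sidecar_path: str | Path) -> BScanSequence:
    """Load a multi-page TIFF stack with its calibration sidecar.

    Raises
    ------
    SidecarError
        If a required calibration key is missing (the message names the
        offending key).
    ValueError
        If the pages are ragged (tifffile refuses to stack them) or the
        stack is empty.
    """
    sidecar_path = Path(sidecar_path)
    if not sidecar_path.exists():
        raise SidecarError(f"sidecar file not found: {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in REQUIRED_SIDECAR_KEYS:
        if key not in meta:
            raise SidecarError(f"sidecar is missing required key '{key}'")
    frames = tifffile.imread(stack_path)
    frames = np.asarray(frames)
    if frames.ndim == 2:  # single-page stack: a static image, T = 1
        frames = frames[None, ...]
    if frames.ndim != 3:
        raise ValueError(f"expected a 2-D or 3-D TIFF stack, got shape {frames.shape}")
    if frames.dtype == np.uint16:
        frames = frames.astype(np.float32) / 65535.0
    else:
        frames = frames.astype(np.float32)
    return BScanSequence(
        frames=frames,
        dt=1.0 / float(meta["frame_rate"]),
        dx=float(meta["dx_um"]),
        dz=float(meta["dz_um"]),
        n_liquid=float(meta["n_liquid"]),
    )


# ---------------------------------------------------------------------------
# aggregation and reporting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AggregateResult:
    """Mean +/- SEM summary of a set of per-region or per-track values.

    ``sem`` is ``None`` when only a single value contributed (the sample
    standard deviation is undefined for n = 1).
    """

    mean: float
    sem: Optional[float]
    n: int


def aggregate(values: Iterable[float]) -> AggregateResult:
    """Arithmetic mean, standard error of the mean, and count.

    SEM uses the sample standard deviation (ddof = 1) divided by sqrt(n).
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("aggregate requires at least one value")
    n = int(vals.size)
    mean = float(vals.mean())
    if n < 2:
        return AggregateResult(mean=mean, sem=None, n=n)
    sem = float(vals.std(ddof=1) / math.sqrt(n))
    return AggregateResult(mean=mean, sem=sem, n=n)


@dataclass
class Report:
    """Tabular collection of measurement rows.

    Rows carry a metric name, a region/track identifier, a value with units,
    and a ``kind`` flag distinguishing individual values from aggregate
    (mean +/- SEM) rows, which additionally fill ``sem`` and ``n``.
    """

    rows: list = field(default_factory=list)

    COLUMNS = ("metric", "region_id", "value", "units", "kind", "sem", "n")

    def add_value(self, metric: str, region_id, value: float, units: str) -> None:
        self.rows.append(
            {
                "metric": metric,
                "region_id": region_id,
                "value": float(value),
                "units": units,
                "kind": "value",
                "sem": np.nan,
                "n": 1,
            }
        )

    def add_aggregate(self, metric: str, agg: AggregateResult, units: str) -> None:
        self.rows.append(
            {
                "metric": metric,
                "region_id": "all",
                "value": agg.mean,
                "units": units,
                "kind": "aggregate",
                "sem": np.nan if agg.sem is None else agg.sem,
                "n": agg.n,
            }
        )

    def add_note(self, metric: str, message: str) -> None:
        """Record a stage warning/error as a non-numeric row."""
        self.rows.append(
            {
                "metric": metric,
                "region_id": "note",
                "value": np.nan,
                "units": message,
                "kind": "note",
                "sem": np.nan,
                "n": 0,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=list(self.COLUMNS))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Report":
        df = pd.read_csv(path)
        rep = cls()
        rep.rows = df.to_dict("records")
        return rep

    def get(self, metric: str, kind: str = "aggregate") -> Optional[dict]:
        """Return the first row for ``metric`` of the given kind, or None."""
        for row in self.rows:
            if row["metric"] == metric and row["kind"] == kind:
                return row
        return None
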