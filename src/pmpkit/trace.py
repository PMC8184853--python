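"""Containers for whole-body fluorescence recordings.

A :class:`FluorescenceTrace` holds the uniformly sampled whole-body GCaMP
fluorescence of a single animal, optionally together with the body aspect
ratio (AR = length/width) measured on the same time grid and the tracked
centroid position used for locomotor analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FluorescenceTrace", "read_trace_tsv"]

_TIME_TOL = 1e-9


@dataclass
class FluorescenceTrace:
    """Uniformly sampled fluorescence (and AR) series for one animal.

    Parameters
    ----------
    time_s:
        Strictly increasing sample times in seconds, uniformly spaced.
    F:
        Whole-body fluorescence in arbitrary units, finite everywhere.
    AR:
        Optional dimensionless body aspect ratio on the same grid.
    x_px, y_px:
        Optional tracked centroid coordinates (image frame, pixels).
    meta:
        Free-form provenance (genotype label, seed, ...).
    """

    time_s: np.ndarray
    F: np.ndarray
    AR: np.ndarray | None = None
    x_px: np.ndarray | None = None
    y_px: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.size < 2:
            raise ValueError("trace needs at least two samples")
        if self.F.shape != self.time_s.shape:
            raise ValueError("time_s and F must have matching shapes")
        if not np.all(np.isfinite(self.F)):
            raise ValueError("F must be finite")
        dt = np.diff(self.time_s)
        if np.any(dt <= 0):
            raise ValueError("time_s must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > _TIME_TOL + 1e-6 * dt[0]:
            raise ValueError("time_s must be uniformly spaced")
        for name in ("AR", "x_px", "y_px"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.time_s.shape:
                    raise ValueError(f"{name} must match the time grid")
                setattr(self, name, v)

    @property
    def dt(self) -> float:
        return float(self.time_s[1] - self.time_s[0])

    @property
    def sampling_rate_hz(self) -> float:
        return 1.0 / self.dt

    @property
    def n(self) -> int:
        return int(self.time_s.size)

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    def index_at(self, t: float) -> int:
        """Index of the sample closest to time ``t`` (clipped to range)."""
        i = int(round((t - self.time_s[0]) * self.sampling_rate_hz))
        return min(max(i, 0), self.n - 1)

    def to_tsv(self, path: str | Path) -> None:
        """Write the trace as tab-separated text (time_s, F, AR, x, y)."""
        cols = {"time_s": self.time_s, "F": self.F}
        if self.AR is not None:
            cols["AR"] = self.AR
        if self.x_px is not None:
            cols["x_px"] = self.x_px
            cols["y_px"] = self.y_px
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
        if self.meta:
            Path(str(path) + ".meta.json").write_text(json.dumps(self.meta))

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_s": self.time_s, "F": self.F}
        if self.AR is not None:
            cols["AR"] = self.AR
        if self.x_px is not None:
            cols["x_px"] = self.x_px
            cols["y_px"] = self.y_px
        return pd.DataFrame(cols)


def read_trace_tsv(path: str | Path) -> FluorescenceTrace:
    """Read a trace written by :meth:`FluorescenceTrace.to_tsv`."""
    df = pd.read_csv(path, sep="\t")
    if "time_s" not in df or "F" not in df:
        raise ValueError(f"{path}: expected columns time_s and F")
    meta_path = Path(str(path) + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return FluorescenceTrace(
        time_s=df["time_s"].to_numpy(),
        F=df["F"].to_numpy(),
        AR=df["AR"].to_numpy() if "AR" in df else None,
        x_px=df["x_px"].to_numpy() if "x_px" in df else None,
        y_px=df["y_px"].to_numpy() if "y_px" in df else None,
        meta=meta,
    )
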