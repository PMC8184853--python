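"""Per-second larva tracking and locomotor parameters.

Frames are segmented with a global threshold (Otsu by default); the
largest connected component is taken as the larva, yielding centroid,
fitted-ellipse aspect ratio, and mean brightness.  Kinematic series
follow the arena conventions: distances in pixels, image-frame
coordinates (x right, y down), speed as the distance traveled over the
trailing 60 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "LarvaTrack",
    "segment_larva",
    "track",
    "step_distance",
    "total_distance",
    "speed",
    "distance_to_final",
]


@dataclass
class LarvaTrack:
    """Per-second centroid/AR/brightness records for one animal."""

    data: pd.DataFrame          # t_s, x_px, y_px, ar, brightness, missing
    frame_shape: tuple[int, int]

    def __post_init__(self) -> None:
        need = {"t_s", "x_px", "y_px", "ar", "brightness", "missing"}
        if not need.issubset(self.data.columns):
            raise ValueError(f"track table needs columns {sorted(need)}")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def final_centroid(self) -> tuple[float, float]:
        ok = self.data.loc[~self.data["missing"]]
        last = ok.iloc[-1]
        return float(last["x_px"]), float(last["y_px"])

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def segment_larva(
    frame: np.ndarray,
    polarity: str = "bright_on_dark",
    min_area: int = 20,
) -> dict | None:
    """Segment one grayscale frame; None when no component qualifies."""
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel image")
    if polarity == "dark_on_bright":
        img = img.max() - img
    elif polarity != "bright_on_dark":
        raise ValueError("polarity must be bright_on_dark or dark_on_bright")
    if np.ptp(img) == 0:
        return None
    # cut midway between the Otsu class means: the boundary then falls
    # at ~50% pixel coverage, which keeps the fitted axes unbiased
    otsu = threshold_otsu(img)
    m0 = img[img <= otsu].mean()
    m1 = img[img > otsu].mean()
    mask = img > 0.5 * (m0 + m1)
    lab = label(mask)
    regions = regionprops(lab, intensity_image=img)
    regions = [r for r in regions if r.area >= min_area]
    if not regions:
        return None
    r = max(regions, key=lambda r: r.area)
    cy, cx = r.centroid
    minor = r.axis_minor_length
    ar = r.axis_major_length / minor if minor > 0 else np.nan
    return {
        "x_px": float(cx),
        "y_px": float(cy),
        "ar": float(ar),
        "brightness": float(r.intensity_mean),
    }


def track(
    frames: np.ndarray,
    dt_s: float = 1.0,
    polarity: str = "bright_on_dark",
    min_area: int = 20,
) -> LarvaTrack:
    """Segment an ordered frame sequence into a per-second track.

    Missing records (no component) are bridged by linear interpolation
    and flagged; more than 50% missing is an error.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValueError("expected a (n, h, w) frame stack")
    rows = []
    for i, frame in enumerate(frames):
        rec = segment_larva(frame, polarity=polarity, min_area=min_area)
        if rec is None:
            rec = {"x_px": np.nan, "y_px": np.nan,
                   "ar": np.nan, "brightness": np.nan}
            missing = True
        else:
            missing = False
        rec["t_s"] = i * dt_s
        rec["missing"] = missing
        rows.append(rec)
    df = pd.DataFrame(rows)
    n_missing = int(df["missing"].sum())
    if n_missing > 0.5 * len(df):
        raise ValueError(f"{n_missing}/{len(df)} frames without a larva")
    for col in ("x_px", "y_px", "ar", "brightness"):
        df[col] = df[col].interpolate(limit_direction="both")
    return LarvaTrack(
        data=df[["t_s", "x_px", "y_px", "ar", "brightness", "missing"]],
        frame_shape=frames.shape[1:],
    )


def step_distance(track: LarvaTrack) -> np.ndarray:
    """Euclidean distance between consecutive positions (length n-1)."""
    if track.n < 2:
        raise ValueError("need at least two records")
    x = track.data["x_px"].to_numpy()
    y = track.data["y_px"].to_numpy()
    return np.hypot(np.diff(x), np.diff(y))


def total_distance(track: LarvaTrack) -> np.ndarray:
    """Cumulative distance traveled (length n, starts at 0)."""
    return np.concatenate(([0.0], np.cumsum(step_distance(track))))


def speed(track: LarvaTrack, window_s: float = 60.0) -> np.ndarray:
    """Distance traveled over the trailing ``window_s`` (px per window).

    NaN over the first window, where the trailing distance is undefined.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    t = track.data["t_s"].to_numpy()
    dt = t[1] - t[0] if track.n > 1 else 1.0
    w = max(1, int(round(window_s / dt)))
    steps = step_distance(track)
    csum = np.concatenate(([0.0], np.cumsum(steps)))  # csum[i] = path length to i
    out = np.full(track.n, np.nan)
    if track.n > w:
        out[w:] = csum[w:] - csum[:-w]
    return out


def distance_to_final(track: LarvaTrack) -> np.ndarray:
    """Straight-line distance from each position to the pupariation site."""
    fx, fy = track.final_centroid
    x = track.data["x_px"].to_numpy()
    y = track.data["y_px"].to_numpy()
    return np.hypot(x - fx, y - fy)
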