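"""Per-strike kinematic variables from calibrated landmark tracks.

Five variables characterize each gel-biting strike:

1. **Peak gape** (mm) — maximum distance between the upper-jaw and lower-jaw
   tip landmarks over the clip.
2. **Peak jaw protrusion** (mm) — maximum distance from the pupil center to
   the upper-jaw tip.
3. **Minimum lower jaw angle** (deg) — smallest angle at the jaw-joint
   landmark between the rays to the lower-jaw tip and to the ventral
   (opercle) landmark, restricted to the window from the 20%-of-peak-gape
   crossing to peak gape.
4. **TTPG** (ms) — time from the 20%-of-peak-gape crossing to peak gape.
   At 1100 fps the per-frame interval is 0.909 ms.
5. **Ram speed** (m/s) — displacement of the pupil over the TTPG window
   divided by TTPG; mm/ms is numerically m/s.

The 20% crossing is the *last* upward crossing of the threshold before the
peak (robust to pre-strike mouth flutter), with the crossing position
linearly interpolated between the bracketing frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_landmarks import LandmarkTrack, LandmarkError


class KinematicsError(ValueError):
    """Raised when a kinematic variable cannot be computed for a strike."""


@dataclass
class StrikeKinematics:
    strike_id: str
    peak_gape_mm: float
    peak_protrusion_mm: float
    min_jaw_angle_deg: float
    ttpg_ms: float
    ram_speed_m_s: float
    peak_gape_frame: int
    t20_frame: float
    n_valid_frames: int
    quality_flag: str = "ok"

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _require_mm(track: LandmarkTrack) -> None:
    if track.units != "mm":
        raise KinematicsError(
            f"{track.strike_id}: track must be calibrated to mm (units={track.units!r})"
        )


def landmark_distance_series(
    track: LandmarkTrack, node_a: str, node_b: str
) -> np.ndarray:
    """Per-frame Euclidean distance between two nodes; NaN where either is missing."""
    _require_mm(track)
    try:
        a = track.node_xy(node_a)
        b = track.node_xy(node_b)
    except LandmarkError as e:
        raise KinematicsError(str(e)) from None
    return np.hypot(a[:, 0] - b[:, 0], a[:, 1] - b[:, 1])


def gape_series(track: LandmarkTrack) -> np.ndarray:
    """Distance from upper-jaw tip (premaxilla) to lower-jaw tip (dentary)."""
    return landmark_distance_series(track, "upper_jaw", "lower_jaw")


def protrusion_series(track: LandmarkTrack) -> np.ndarray:
    """Distance from pupil center to upper-jaw tip."""
    return landmark_distance_series(track, "pupil", "upper_jaw")


def jaw_angle_series(track: LandmarkTrack) -> np.ndarray:
    """Interior angle (deg) at the jaw joint between lower jaw and opercle rays.

    Degenerate frames where the vertex coincides with a ray endpoint are NaN.
    """
    _require_mm(track)
    v = track.node_xy("jaw_joint")
    u = track.node_xy("lower_jaw") - v
    w = track.node_xy("opercle") - v
    nu = np.hypot(u[:, 0], u[:, 1])
    nw = np.hypot(w[:, 0], w[:, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = (u * w).sum(axis=1) / (nu * nw)
        cosang = np.clip(cosang, -1.0, 1.0)
        ang = np.degrees(np.arccos(cosang))
    ang[(nu == 0) | (nw == 0)] = np.nan
    return ang


def find_peak_gape(series: np.ndarray) -> tuple[int, float]:
    """Global maximum of a series over non-missing frames; earliest tie wins."""
    s = np.asarray(series, dtype=float)
    valid = np.isfinite(s)
    if valid.sum() < 2:
        raise KinematicsError("need at least 2 non-missing values for a peak")
    vals = s[valid]
    if np.nanmax(vals) == np.nanmin(vals):
        raise KinematicsError("constant series has no peak")
    peak = np.nanmax(s)
    frame = int(np.flatnonzero(valid & (s == peak))[0])
    return frame, float(peak)


def find_t20(series: np.ndarray, peak_frame: int) -> float:
    """Fractional frame of the last upward crossing of 0.2 x peak before the peak.

    Raises :class:`KinematicsError` if the gape never drops below the
    threshold before the peak (baseline gape too large) — TTPG is then
    undefined for the strike.
    """
    s = np.asarray(series, dtype=float)
    peak = s[peak_frame]
    if not np.isfinite(peak) or peak <= 0:
        raise KinematicsError("peak gape must be positive and observed")
    thr = 0.2 * peak
    # scan backward over observed, contiguous-in-observation pairs
    below = None
    for i in range(peak_frame - 1, -1, -1):
        if not np.isfinite(s[i]):
            continue
        if s[i] < thr:
            below = i
            break
    if below is None:
        raise KinematicsError("gape never below 20% of peak before the peak")
    # next observed frame after `below`
    j = below + 1
    while j <= peak_frame and not np.isfinite(s[j]):
        j += 1
    # linear interpolation of the crossing between the bracketing frames
    return below + (thr - s[below]) / (s[j] - s[below]) * (j - below)


def ttpg_ms(t20_frame: float, peak_frame: int, frame_rate_hz: float) -> float:
    """Elapsed time from the 20% crossing to peak gape, in milliseconds."""
    if not peak_frame > t20_frame:
        raise KinematicsError("peak frame must follow the 20% crossing")
    return (peak_frame - t20_frame) * 1000.0 / frame_rate_hz


def _interp_node(track: LandmarkTrack, node: str, t: float) -> np.ndarray:
    """Node position at a fractional frame, linearly interpolated."""
    xy = track.node_xy(node)
    lo = int(math.floor(t))
    hi = int(math.ceil(t))
    if not (np.isfinite(xy[lo]).all() and np.isfinite(xy[hi]).all()):
        raise KinematicsError(
            f"{track.strike_id}: node {node!r} missing at bracketing frames of t={t:.2f}"
        )
    if lo == hi:
        return xy[lo]
    w = t - lo
    return (1 - w) * xy[lo] + w * xy[hi]


def ram_speed(track: LandmarkTrack, t20_frame: float, peak_frame: int) -> float:
    """Pupil displacement (mm) over the TTPG window divided by TTPG (ms).

    mm/ms is numerically identical to m/s.
    """
    _require_mm(track)
    p0 = _interp_node(track, "pupil", t20_frame)
    p1 = _interp_node(track, "pupil", float(peak_frame))
    dist_mm = float(np.hypot(*(p1 - p0)))
    dt_ms = ttpg_ms(t20_frame, peak_frame, track.frame_rate_hz)
    return dist_mm / dt_ms


def extract_strike(
    track: LandmarkTrack,
    *,
    min_valid_frames: int = 10,
    median_filter: bool = False,
    window: tuple[int, int] | None = None,
) -> StrikeKinematics:
    """Compute all five kinematic variables for one strike.

    ``window`` optionally restricts the peak search to a frame range
    (gel-contact frames are not annotated, so the default spans the clip).
    ``median_filter`` applies an optional 3-frame median filter to the gape
    and protrusion series before event detection (off by default).
    """
    _require_mm(track)
    n_valid = int(track.mask.all(axis=1).sum())
    if n_valid < min_valid_frames:
        raise KinematicsError(
            f"{track.strike_id}: only {n_valid} fully observed frames (< {min_valid_frames})"
        )
    try:
        gape = gape_series(track)
        prot = protrusion_series(track)
        if median_filter:
            from scipy.ndimage import median_filter as _mf

            gape = _mf(gape, size=3, mode="nearest")
            prot = _mf(prot, size=3, mode="nearest")
        search = gape.copy()
        if window is not None:
            lo, hi = window
            out = np.ones_like(search, dtype=bool)
            out[lo:hi] = False
            search[out] = np.nan
        peak_frame, peak_gape = find_peak_gape(search)
        _, peak_prot = find_peak_gape(prot)
        t20 = find_t20(gape, peak_frame)
        ttpg = ttpg_ms(t20, peak_frame, track.frame_rate_hz)
        ram = ram_speed(track, t20, peak_frame)
        ang = jaw_angle_series(track)
        w_lo, w_hi = int(math.ceil(t20)), peak_frame
        ang_window = ang[w_lo : w_hi + 1]
        if not np.isfinite(ang_window).any():
            raise KinematicsError("jaw angle unobserved over the TTPG window")
        min_angle = float(np.nanmin(ang_window))
        quality = "ok"
        n_window = w_hi - w_lo + 1
        n_missing = int(np.sum(~track.mask.all(axis=1)[w_lo : w_hi + 1]))
        if n_window > 0 and n_missing / n_window > 0.2:
            quality = "low_quality"
    except KinematicsError as e:
        raise KinematicsError(f"{track.strike_id}: {e}") from None

    return StrikeKinematics(
        strike_id=track.strike_id,
        peak_gape_mm=peak_gape,
        peak_protrusion_mm=peak_prot,
        min_jaw_angle_deg=min_angle,
        ttpg_ms=ttpg,
        ram_speed_m_s=ram,
        peak_gape_frame=peak_frame,
        t20_frame=float(t20),
        n_valid_frames=n_valid,
        quality_flag=quality,
    )


def extract_table(tracks, **kwargs) -> "pd.DataFrame":  # noqa: F821
    """Extract kinematics for many tracks into a tidy DataFrame.

    Strikes that fail extraction are reported with an ``error`` column
    rather than silently dropped.
    """
    import pandas as pd

    rows = []
    for tr in tracks:
        try:
            rows.append({**extract_strike(tr, **kwargs).as_dict(), "error": ""})
        except KinematicsError as e:
            rows.append({"strike_id": tr.strike_id, "error": str(e)})
    return pd.DataFrame(rows)
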