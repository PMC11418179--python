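"""Reading, calibrating and gap-filling pose-estimation landmark tracks.

Strike videos are landmarked by a pose-estimation tool and exported as HDF5
files holding a coordinate array plus a node-name list.  Different exporters
store the array with different axis orders, so :func:`read_landmark_file`
resolves axes by shape rather than assuming a layout.  Five anatomical
landmarks are canonical throughout the package:

``upper_jaw``  anterior tip of the premaxilla (upper jaw)
``lower_jaw``  anterior tip of the dentary (lower jaw)
``pupil``      center of the pupil
``opercle``    posteroventral margin of the opercle
``jaw_joint``  posterior-most visible point of the lower jaw (jaw-joint proxy)

Coordinates are image coordinates (origin top-left, x rightward, y downward);
all downstream geometry uses distances and angles only, so the convention
never matters.  Missing detections are NaN in the file and become the missing
mask of the track.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

CANONICAL_NODES = ("upper_jaw", "lower_jaw", "pupil", "opercle", "jaw_joint")

#: Default free-text label aliases mapped onto the canonical five.  Users can
#: extend this via the ``aliases`` argument of :func:`read_landmark_file` or
#: the YAML config of the CLI.
DEFAULT_ALIASES: dict[str, str] = {
    "upper_jaw": "upper_jaw",
    "upperjaw": "upper_jaw",
    "premaxilla": "upper_jaw",
    "upper jaw": "upper_jaw",
    "lower_jaw": "lower_jaw",
    "lowerjaw": "lower_jaw",
    "dentary": "lower_jaw",
    "lower jaw": "lower_jaw",
    "pupil": "pupil",
    "eye": "pupil",
    "pupil_center": "pupil",
    "opercle": "opercle",
    "operculum": "opercle",
    "preopercle": "opercle",
    "jaw_joint": "jaw_joint",
    "jawjoint": "jaw_joint",
    "jaw joint": "jaw_joint",
    "articular": "jaw_joint",
}


class LandmarkError(ValueError):
    """Raised for malformed landmark files or invalid track operations."""


@dataclass
class LandmarkTrack:
    """Per-strike time series of the five canonical landmarks.

    ``coords`` has shape (frames, 5, 2); missing detections are NaN and are
    mirrored in ``mask`` (True = observed).
    """

    strike_id: str
    coords: np.ndarray
    frame_rate_hz: float
    units: str = "px"  # "px" or "mm"
    node_names: tuple[str, ...] = CANONICAL_NODES
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (5, 2):
            raise LandmarkError(
                f"{self.strike_id}: coords must be (frames, 5, 2), got {self.coords.shape}"
            )
        if self.coords.shape[0] < 2:
            raise LandmarkError(f"{self.strike_id}: need at least 2 frames")
        if tuple(self.node_names) != CANONICAL_NODES:
            raise LandmarkError(
                f"{self.strike_id}: node names must be {CANONICAL_NODES}, got {self.node_names}"
            )
        if not self.frame_rate_hz > 0:
            raise LandmarkError(f"{self.strike_id}: frame_rate_hz must be > 0")
        if self.units not in ("px", "mm"):
            raise LandmarkError(f"{self.strike_id}: units must be 'px' or 'mm'")
        observed = np.isfinite(self.coords).all(axis=2)
        if self.mask is None:
            self.mask = observed
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != observed.shape:
                raise LandmarkError(f"{self.strike_id}: mask shape mismatch")
            # masked-out entries are forced to NaN so mask and NaN agree
            self.coords = self.coords.copy()
            self.coords[~self.mask] = np.nan
        if not np.isfinite(self.coords[self.mask]).all():
            raise LandmarkError(f"{self.strike_id}: non-finite observed coordinate")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def frame_interval_ms(self) -> float:
        return 1000.0 / self.frame_rate_hz

    def node_index(self, name: str) -> int:
        try:
            return CANONICAL_NODES.index(name)
        except ValueError:
            raise LandmarkError(f"unknown node label {name!r}") from None

    def node_xy(self, name: str) -> np.ndarray:
        """(frames, 2) coordinates of one node; NaN where missing."""
        return self.coords[:, self.node_index(name), :]


@dataclass(frozen=True)
class CalibrationRecord:
    """Pixel-to-millimetre scale for one filming session (ruler image)."""

    session_id: str
    px_per_mm: float

    def __post_init__(self) -> None:
        if not self.px_per_mm > 0:
            raise LandmarkError(
                f"session {self.session_id}: px_per_mm must be > 0, got {self.px_per_mm}"
            )


def _map_node_names(raw: list[str], aliases: dict[str, str] | None) -> list[int]:
    """Return, for each canonical node, its index in the raw name list."""
    table = dict(DEFAULT_ALIASES)
    if aliases:
        table.update({k.strip().lower(): v for k, v in aliases.items()})
    mapped: dict[str, int] = {}
    for i, name in enumerate(raw):
        key = name.strip().lower()
        if key not in table:
            raise LandmarkError(f"unmapped node label {name!r}; extend the alias table")
        canon = table[key]
        if canon in mapped:
            raise LandmarkError(f"duplicate mapping for canonical node {canon!r}")
        mapped[canon] = i
    missing = [n for n in CANONICAL_NODES if n not in mapped]
    if missing:
        raise LandmarkError(f"file lacks canonical nodes: {missing}")
    return [mapped[n] for n in CANONICAL_NODES]


def _resolve_axes(shape: tuple[int, ...], n_nodes: int) -> tuple[int, int, int, int | None]:
    """Identify (frames, nodes, coords, tracks) axes of a coordinate array.

    The coordinate axis is the length-2 axis; the node axis matches the
    node-name list; with 4 dims the smaller of the remaining axes is taken as
    the track axis.  Ambiguity (e.g. two unexplained length-2 axes) is an
    error rather than a guess.
    """
    ndim = len(shape)
    if ndim not in (3, 4):
        raise LandmarkError(f"coordinate array must be 3-D or 4-D, got shape {shape}")
    axes = list(range(ndim))
    coord_candidates = [a for a in axes if shape[a] == 2]
    node_candidates = [a for a in axes if shape[a] == n_nodes]
    # prefer assignments where node and coord axes are distinct
    pairs = [(na, ca) for na in node_candidates for ca in coord_candidates if na != ca]
    if not pairs:
        raise LandmarkError(
            f"cannot resolve node axis (len {n_nodes}) and coordinate axis (len 2) in shape {shape}"
        )
    if len(pairs) > 1:
        # disambiguate: remaining axes must leave a plausible frame axis;
        # pick the assignment whose leftover axes are not length 2 or n_nodes
        def leftover_score(p):
            rest = [shape[a] for a in axes if a not in p]
            return sum(x not in (2, n_nodes) for x in rest)

        best = max(leftover_score(p) for p in pairs)
        pairs = [p for p in pairs if leftover_score(p) == best]
        if len(pairs) > 1:
            # e.g. a 2-track file: two length-2 axes.  Prefer the trailing
            # coordinate axis, the common (…, nodes, 2) export convention.
            trailing = [p for p in pairs if p[1] == ndim - 1]
            if trailing:
                pairs = trailing
            if len(pairs) > 1:
                raise LandmarkError(f"ambiguous axis layout for shape {shape}")
    node_ax, coord_ax = pairs[0]
    rest = [a for a in axes if a not in (node_ax, coord_ax)]
    if ndim == 3:
        return rest[0], node_ax, coord_ax, None
    # 4-D: track axis is the smaller remaining axis (few animals, many frames)
    track_ax, frame_ax = sorted(rest, key=lambda a: shape[a])
    return frame_ax, node_ax, coord_ax, track_ax


def read_landmark_file(
    path: str | Path,
    frame_rate_hz: float = 1100.0,
    *,
    aliases: dict[str, str] | None = None,
    cull_to_single: bool = True,
    strike_id: str | None = None,
) -> list[LandmarkTrack]:
    """Read one exported HDF5 landmark file into :class:`LandmarkTrack` s.

    Accepts the common pose-export dialect: a dataset named ``tracks`` (or
    the sole 3/4-D float dataset) with axes resolvable among
    {tracks, coords, nodes, frames}, plus a ``node_names`` string dataset.
    With ``cull_to_single`` (default), multi-track files are reduced to the
    track with the most fully observed frames, mirroring single-fish filming.
    """
    path = Path(path)
    if not path.exists():
        raise LandmarkError(f"no such file: {path}")
    with h5py.File(path, "r") as f:
        if "node_names" not in f:
            raise LandmarkError(f"{path}: missing node_names dataset")
        raw_names = [
            n.decode() if isinstance(n, bytes) else str(n) for n in f["node_names"][()]
        ]
        if "tracks" in f:
            arr = np.asarray(f["tracks"][()], dtype=float)
        else:
            cands = [
                k
                for k, v in f.items()
                if isinstance(v, h5py.Dataset) and v.ndim in (3, 4) and v.dtype.kind == "f"
            ]
            if len(cands) != 1:
                raise LandmarkError(f"{path}: cannot identify coordinate dataset")
            arr = np.asarray(f[cands[0]][()], dtype=float)
        rate = float(f.attrs.get("frame_rate_hz", frame_rate_hz))
        units = f.attrs.get("units", "px")
        units = units.decode() if isinstance(units, bytes) else str(units)
        sid_attr = f.attrs.get("strike_id")

    order = _map_node_names(raw_names, aliases)
    frame_ax, node_ax, coord_ax, track_ax = _resolve_axes(arr.shape, len(raw_names))
    if track_ax is None:
        arr = np.transpose(arr, (frame_ax, node_ax, coord_ax))[np.newaxis]
    else:
        arr = np.transpose(arr, (track_ax, frame_ax, node_ax, coord_ax))
    arr = arr[:, :, order, :]  # canonical node order

    base_id = strike_id or (
        sid_attr.decode() if isinstance(sid_attr, bytes) else sid_attr
    ) or path.stem
    n_tracks = arr.shape[0]
    if n_tracks > 1 and cull_to_single:
        valid = [int(np.isfinite(arr[t]).all(axis=(1, 2)).sum()) for t in range(n_tracks)]
        arr = arr[int(np.argmax(valid))][np.newaxis]
        n_tracks = 1
    elif n_tracks > 1:
        raise LandmarkError(
            f"{path}: {n_tracks} tracks present and cull_to_single is disabled"
        )

    tracks = []
    for t in range(n_tracks):
        sid = base_id if n_tracks == 1 else f"{base_id}_track{t}"
        tracks.append(
            LandmarkTrack(strike_id=sid, coords=arr[t], frame_rate_hz=rate, units=units)
        )
    return tracks


def write_landmark_file(track: LandmarkTrack, path: str | Path) -> None:
    """Write a track in the canonical layout (frames x nodes x 2)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("tracks", data=track.coords)
        f.create_dataset(
            "node_names", data=np.array([n.encode() for n in track.node_names])
        )
        f.attrs["frame_rate_hz"] = track.frame_rate_hz
        f.attrs["strike_id"] = track.strike_id
        f.attrs["units"] = track.units


def calibrate(track: LandmarkTrack, cal: CalibrationRecord) -> LandmarkTrack:
    """Convert a pixel-space track to millimetres using the session scale."""
    if track.units != "px":
        raise LandmarkError(f"{track.strike_id}: track already calibrated to mm")
    return replace(
        track, coords=track.coords / cal.px_per_mm, units="mm", mask=track.mask.copy()
    )


def fill_gaps(track: LandmarkTrack, max_gap_frames: int = 3) -> LandmarkTrack:
    """Linearly interpolate short missing runs per node.

    Runs longer than ``max_gap_frames``, and leading/trailing gaps (which
    have only one flanking observation), are left missing — interpolation
    never extrapolates, so no kinematic event can be fabricated at the clip
    edges.
    """
    coords = track.coords.copy()
    n = track.n_frames
    for j in range(coords.shape[1]):
        obs = track.mask[:, j]
        if obs.all() or not obs.any():
            continue
        idx = np.flatnonzero(obs)
        miss = np.flatnonzero(~obs)
        # interior gaps only, bounded length
        for k in miss:
            if k < idx[0] or k > idx[-1]:
                continue
            left = idx[idx < k][-1]
            right = idx[idx > k][0]
            if right - left - 1 <= max_gap_frames:
                w = (k - left) / (right - left)
                coords[k, j] = (1 - w) * coords[left, j] + w * coords[right, j]
    filled = LandmarkTrack(
        strike_id=track.strike_id,
        coords=coords,
        frame_rate_hz=track.frame_rate_hz,
        units=track.units,
    )
    assert n == filled.n_frames
    return filled


def read_calibration_csv(path: str | Path) -> dict[str, CalibrationRecord]:
    """Read a session calibration table (columns: session_id, px_per_mm)."""
    records: dict[str, CalibrationRecord] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            sid = row["session_id"].strip()
            if sid in records:
                raise LandmarkError(f"duplicate session_id {sid!r} in {path}")
            records[sid] = CalibrationRecord(sid, float(row["px_per_mm"]))
    return records


def track_to_frame(track: LandmarkTrack) -> "pd.DataFrame":  # noqa: F821
    """Tidy per-frame, per-node table of one track (for CSV export)."""
    import pandas as pd

    frames, nodes = np.meshgrid(
        np.arange(track.n_frames), np.arange(5), indexing="ij"
    )
    return pd.DataFrame(
        {
            "strike_id": track.strike_id,
            "frame": frames.ravel(),
            "node": np.array(track.node_names)[nodes.ravel()],
            "x": track.coords[..., 0].ravel(),
            "y": track.coords[..., 1].ravel(),
            "observed": track.mask.ravel(),
        }
    )
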