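"""Loading, rasterization and canonical alignment of retinal activity recordings.

The raw recording is a table of spike events -- ``(channel, time)`` pairs --
plus an electrode map giving each channel's position on a regular grid
(87.5 um pitch for the 1024-electrode HD-MEA configuration this package was
designed around). :func:`rasterize` bins the events into a dense ``x, y, t``
movie of per-pixel, per-frame spike counts, the common container shared with
calcium-imaging input. :func:`align` transforms a movie into the canonical
retinal orientation used throughout: temporal retina at low x, nasal at high
x, ventral at low y, dorsal at high y, optic nerve near the grid center.
"""

from __future__ import annotations

import csv as _csv
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from .errors import FormatError, GeometryError, IntegrityError, ParameterError

DEFAULT_PITCH_UM = 87.5
DEFAULT_FRAME_S = 1.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ElectrodeMap:
    """Channel-to-position lookup for a regular electrode grid.

    Parameters
    ----------
    channel : array of int
        Unique channel identifiers.
    x_um, y_um : array of float
        Electrode positions in micrometres. Positions must lie on a regular
        grid with a single pitch in both axes.
    is_reference : array of bool
        Reference electrodes are kept in the map but excluded from
        rasterization and masked in the movie.
    pitch_um : float, optional
        Grid pitch. Inferred from the positions when omitted.
    """

    channel: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    is_reference: np.ndarray
    pitch_um: float | None = None

    def __post_init__(self) -> None:
        self.channel = np.asarray(self.channel, dtype=np.int64)
        self.x_um = np.asarray(self.x_um, dtype=np.float64)
        self.y_um = np.asarray(self.y_um, dtype=np.float64)
        self.is_reference = np.asarray(self.is_reference, dtype=bool)
        n = self.channel.size
        if not (self.x_um.size == self.y_um.size == self.is_reference.size == n):
            raise IntegrityError("electrode map arrays have mismatched lengths")
        if np.unique(self.channel).size != n:
            raise IntegrityError("electrode map contains duplicate channel ids")
        if self.pitch_um is None:
            self.pitch_um = _infer_pitch(self.x_um, self.y_um)

    @property
    def n_channels(self) -> int:
        return int(self.channel.size)

    def grid_indices(self) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
        """Map electrode positions to 0-based ``(x, y)`` grid indices.

        Returns ``(xi, yi, (nx, ny))``. Raises :class:`GeometryError` if any
        position is off-lattice for the map's pitch.
        """
        p = float(self.pitch_um)
        x0, y0 = self.x_um.min(), self.y_um.min()
        fx = (self.x_um - x0) / p
        fy = (self.y_um - y0) / p
        xi = np.rint(fx).astype(np.int64)
        yi = np.rint(fy).astype(np.int64)
        if np.max(np.abs(fx - xi), initial=0.0) > 1e-6 or np.max(
            np.abs(fy - yi), initial=0.0
        ) > 1e-6:
            raise GeometryError(
                f"electrode positions do not lie on a regular grid of pitch {p} um"
            )
        shape = (int(xi.max(initial=0)) + 1, int(yi.max(initial=0)) + 1)
        return xi, yi, shape


def _infer_pitch(x_um: np.ndarray, y_um: np.ndarray) -> float:
    deltas = []
    for coords in (x_um, y_um):
        u = np.unique(coords)
        if u.size > 1:
            deltas.append(np.diff(u).min())
    if not deltas:
        # single electrode: pitch is irrelevant for indexing
        return DEFAULT_PITCH_UM
    pitch = float(min(deltas))
    if pitch <= 0:
        raise GeometryError("could not infer a positive grid pitch")
    for coords in (x_um, y_um):
        frac = (coords - coords.min()) / pitch
        if np.max(np.abs(frac - np.rint(frac)), initial=0.0) > 1e-6:
            raise GeometryError(
                "electrode positions are not on a regular grid (non-uniform pitch)"
            )
    return pitch


@dataclass
class SpikeEvents:
    """A spike-event table: every action potential as (channel, timestamp)."""

    channel: np.ndarray
    time_s: np.ndarray
    duration_s: float
    emap: ElectrodeMap

    def __post_init__(self) -> None:
        self.channel = np.asarray(self.channel, dtype=np.int64)
        self.time_s = np.asarray(self.time_s, dtype=np.float64)
        if self.channel.size != self.time_s.size:
            raise IntegrityError("channel and time arrays have different lengths")
        if self.time_s.size:
            if self.time_s.min() < 0 or self.time_s.max() > self.duration_s:
                raise IntegrityError("spike times fall outside [0, duration_s]")
            unknown = np.setdiff1d(self.channel, self.emap.channel)
            if unknown.size:
                raise IntegrityError(
                    f"events reference channels absent from the map: {unknown[:5].tolist()}"
                )

    @property
    def n_events(self) -> int:
        return int(self.time_s.size)


@dataclass
class ActivityMovie:
    """Dense ``x, y, t`` matrix of spike counts (or fluorescence) per pixel per frame."""

    data: np.ndarray
    pixel_pitch_um: float = DEFAULT_PITCH_UM
    frame_s: float = DEFAULT_FRAME_S
    valid_mask: np.ndarray | None = None
    optic_nerve_xy: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise GeometryError("movie data must be a 3-D (x, y, t) array")
        if self.data.size and self.data.min() < 0:
            raise IntegrityError("movie data must be non-negative")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.data.shape[:2], dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.data.shape[:2]:
                raise GeometryError("valid_mask shape does not match movie x,y extent")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    @property
    def recording_s(self) -> float:
        return self.n_frames * self.frame_s


@dataclass(frozen=True)
class OrientationSpec:
    """Flip/offset transform bringing a recording into canonical orientation.

    Applied as flips first (about the grid center of each axis), then integer
    pixel offsets. ``optic_nerve_xy`` records the optic-nerve center in the
    *post-alignment* frame; identifying it is up to the experimenter.
    """

    flip_x: bool = False
    flip_y: bool = False
    offset_x: int = 0
    offset_y: int = 0
    optic_nerve_xy: tuple[float, float] | None = None

    def inverse(self) -> "OrientationSpec":
        """The orientation transform that undoes this one (flip-then-offset)."""
        ox = self.offset_x if self.flip_x else -self.offset_x
        oy = self.offset_y if self.flip_y else -self.offset_y
        return OrientationSpec(self.flip_x, self.flip_y, ox, oy)

    @property
    def is_identity(self) -> bool:
        return not (self.flip_x or self.flip_y or self.offset_x or self.offset_y)


# ---------------------------------------------------------------------------
# loading / writing spike events
# ---------------------------------------------------------------------------

def load_spikes(path, fmt: str = "auto", map_path=None) -> SpikeEvents:
    """Load a spike-event table plus electrode map.

    Supported layouts: the package's generic HDF5 spike layout (``fmt="hdf5"``),
    paired CSV files (``fmt="csv"``, requires ``map_path``), and a best-effort
    adapter for Maxwell MaxOne "Record Spikes Only" files (``fmt="maxwell"``).
    """
    path = str(path)
    if fmt == "auto":
        fmt = "csv" if path.endswith(".csv") else "hdf5"
    if fmt == "hdf5":
        return _load_hdf5(path)
    if fmt == "csv":
        if map_path is None:
            raise ParameterError("CSV input requires map_path for the electrode map")
        return _load_csv(path, str(map_path))
    if fmt == "maxwell":
        return _load_maxwell(path)
    raise ParameterError(f"unknown spike format {fmt!r}")


def _require(group, name, kind="dataset"):
    if name not in group:
        raise FormatError(f"missing {kind} {name!r} in {group.file.filename}")
    return group[name]


def _load_hdf5(path: str) -> SpikeEvents:
    with h5py.File(path, "r") as f:
        time_s = np.asarray(_require(f, "spikes/time_s"))
        channel = np.asarray(_require(f, "spikes/channel"))
        emap = ElectrodeMap(
            channel=np.asarray(_require(f, "map/channel")),
            x_um=np.asarray(_require(f, "map/x_um")),
            y_um=np.asarray(_require(f, "map/y_um")),
            is_reference=np.asarray(_require(f, "map/is_reference")).astype(bool),
            pitch_um=float(f.attrs["pixel_pitch_um"]) if "pixel_pitch_um" in f.attrs else None,
        )
        duration = float(f.attrs["duration_s"]) if "duration_s" in f.attrs else (
            float(time_s.max()) if time_s.size else 0.0
        )
    return SpikeEvents(channel=channel, time_s=time_s, duration_s=duration, emap=emap)


def _read_csv_columns(path: str, required: tuple[str, ...]) -> dict[str, list[str]]:
    with open(path, newline="") as fh:
        reader = _csv.DictReader(fh)
        cols = reader.fieldnames or []
        for name in required:
            if name not in cols:
                raise FormatError(f"missing column {name!r} in {path}")
        out: dict[str, list[str]] = {name: [] for name in required}
        for row in reader:
            for name in required:
                out[name].append(row[name])
    return out

def _load_csv(events_path: str, map_path: str) -> SpikeEvents:
    ev = _read_csv_columns(events_path, ("time_s", "channel"))
    mp = _read_csv_columns(map_path, ("channel", "x_um", "y_um", "is_reference"))
    emap = ElectrodeMap(
        channel=np.array(mp["channel"], dtype=np.int64),
        x_um=np.array(mp["x_um"], dtype=np.float64),
        y_um=np.array(mp["y_um"], dtype=np.float64),
        is_reference=np.array([s.strip().lower() in ("1", "true") for s in mp["is_reference"]]),
    )
    time_s = np.array(ev["time_s"], dtype=np.float64)
    channel = np.array(ev["channel"], dtype=np.int64)
    duration = float(time_s.max()) if time_s.size else 0.0
    return SpikeEvents(channel=channel, time_s=time_s, duration_s=duration, emap=emap)


def _load_maxwell(path: str) -> SpikeEvents:
    """Adapter for Maxwell MaxOne 'Record Spikes Only' HDF5 output.

    Reads the compound ``/proc0/spikeTimes`` (or legacy ``/spikes``) dataset
    and the ``/mapping`` table; spike frame numbers are converted to seconds
    with the recorded sampling rate (20 kHz if absent).
    """
    with h5py.File(path, "r") as f:
        spikes = None
        for key in ("proc0/spikeTimes", "spikes"):
            if key in f:
                spikes = np.asarray(f[key])
                break
        if spikes is None:
            raise FormatError(f"no Maxwell spike dataset (/proc0/spikeTimes) in {path}")
        if "mapping" not in f:
            raise FormatError(f"missing dataset 'mapping' in {path}")
        mapping = np.asarray(f["mapping"])
        fs = 20000.0
        for key in ("settings/sampling", "sampling"):
            if key in f:
                fs = float(np.asarray(f[key]).ravel()[0])
                break
        names = spikes.dtype.names or ()
        if "frameno" not in names or "channel" not in names:
            raise FormatError("Maxwell spike dataset lacks 'frameno'/'channel' fields")
        frameno = spikes["frameno"].astype(np.int64)
        time_s = (frameno - frameno.min()) / fs if frameno.size else np.empty(0)
        mnames = mapping.dtype.names or ()
        for req in ("channel", "x", "y"):
            if req not in mnames:
                raise FormatError(f"Maxwell mapping lacks field {req!r}")
        is_ref = (
            mapping["electrode"] < 0 if "electrode" in mnames
            else np.zeros(mapping.shape[0], dtype=bool)
        )
        emap = ElectrodeMap(
            channel=mapping["channel"].astype(np.int64),
            x_um=mapping["x"].astype(np.float64),
            y_um=mapping["y"].astype(np.float64),
            is_reference=np.asarray(is_ref, dtype=bool),
        )
    duration = float(time_s.max()) if time_s.size else 0.0
    return SpikeEvents(
        channel=spikes["channel"].astype(np.int64), time_s=np.asarray(time_s),
        duration_s=duration, emap=emap,
    )


def write_spikes(path, spikes: SpikeEvents) -> None:
    """Write events in the generic HDF5 spike layout (round-trips with load_spikes)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("spikes/time_s", data=spikes.time_s)
        f.create_dataset("spikes/channel", data=spikes.channel)
        f.create_dataset("map/channel", data=spikes.emap.channel)
        f.create_dataset("map/x_um", data=spikes.emap.x_um)
        f.create_dataset("map/y_um", data=spikes.emap.y_um)
        f.create_dataset("map/is_reference", data=spikes.emap.is_reference.astype(np.uint8))
        f.attrs["duration_s"] = spikes.duration_s
        f.attrs["pixel_pitch_um"] = float(spikes.emap.pitch_um)


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def n_frames_for(duration_s: float, frame_s: float) -> int:
    """Frame count covering [0, duration_s] with half-open bins [t, t+frame_s)."""
    return int(np.floor(duration_s / frame_s)) + 1


def rasterize(spikes: SpikeEvents, frame_s: float = DEFAULT_FRAME_S) -> ActivityMovie:
    """Bin spike events onto the electrode grid, one frame per ``frame_s``.

    ``data[x, y, t]`` counts spikes on the electrode at grid position (x, y)
    with timestamps in the half-open bin ``[t*frame_s, (t+1)*frame_s)``.
    Reference electrodes are excluded from the counts and from ``valid_mask``;
    the total of the matrix equals the number of events on recording channels.
    """
    if frame_s <= 0:
        raise ParameterError("frame_s must be positive")
    emap = spikes.emap
    xi, yi, (nx, ny) = emap.grid_indices()
    nt = n_frames_for(spikes.duration_s, frame_s)
    data = np.zeros((nx, ny, nt), dtype=np.int32)
    valid = np.zeros((nx, ny), dtype=bool)
    rec = ~emap.is_reference
    valid[xi[rec], yi[rec]] = True

    if spikes.n_events:
        order = np.argsort(emap.channel, kind="stable")
        pos = np.searchsorted(emap.channel[order], spikes.channel)
        idx = order[pos]
        keep = ~emap.is_reference[idx]
        ex, ey = xi[idx[keep]], yi[idx[keep]]
        et = np.floor(spikes.time_s[keep] / frame_s).astype(np.int64)
        np.add.at(data, (ex, ey, et), 1)

    return ActivityMovie(
        data=data, pixel_pitch_um=float(emap.pitch_um), frame_s=frame_s, valid_mask=valid
    )


# ---------------------------------------------------------------------------
# canonical alignment
# ---------------------------------------------------------------------------

def align(movie: ActivityMovie, spec: OrientationSpec) -> ActivityMovie:
    """Apply an orientation spec (flips, then integer offsets) to a movie.

    Pure pixel permutation: values are moved, never altered, and the valid
    mask is transformed identically. An offset that would push a valid pixel
    off the grid raises :class:`GeometryError` (this guarantees that a spec
    followed by its :meth:`OrientationSpec.inverse` is the identity).
    """
    data = movie.data
    mask = movie.valid_mask
    if spec.flip_x:
        data = data[::-1, :, :]
        mask = mask[::-1, :]
    if spec.flip_y:
        data = data[:, ::-1, :]
        mask = mask[:, ::-1]

    nx, ny = mask.shape
    if spec.offset_x or spec.offset_y:
        vx, vy = np.nonzero(mask)
        if vx.size:
            nvx, nvy = vx + spec.offset_x, vy + spec.offset_y
            if nvx.min() < 0 or nvx.max() >= nx or nvy.min() < 0 or nvy.max() >= ny:
                raise GeometryError(
                    "offset would move valid pixels outside the grid; "
                    "pad the movie before aligning"
                )
        data = _shift2d(data, spec.offset_x, spec.offset_y)
        mask = _shift2d(mask[:, :, None], spec.offset_x, spec.offset_y)[:, :, 0]
    else:
        data = data.copy()
        mask = mask.copy()

    return replace(movie, data=data, valid_mask=mask, optic_nerve_xy=spec.optic_nerve_xy)


def _shift2d(arr: np.ndarray, ox: int, oy: int) -> np.ndarray:
    out = np.zeros_like(arr)
    nx, ny = arr.shape[:2]
    sx = slice(max(ox, 0), min(nx + ox, nx))
    sy = slice(max(oy, 0), min(ny + oy, ny))
    dx = slice(max(-ox, 0), min(nx - ox, nx))
    dy = slice(max(-oy, 0), min(ny - oy, ny))
    out[sx, sy] = arr[dx, dy]
    return out


# ---------------------------------------------------------------------------
# movie I/O (calcium-imaging style input)
# ---------------------------------------------------------------------------

def load_movie_tiff(
    path, pixel_pitch_um: float, frame_s: float, valid_mask=None
) -> ActivityMovie:
    """Load a multi-page TIFF stack (one page per frame) as an ActivityMovie.

    Pages are interpreted as (row=y, col=x) images and transposed into the
    package's (x, y, t) axis order.
    """
    import tifffile

    stack = tifffile.imread(str(path))
    if stack.ndim == 2:
        stack = stack[None]
    data = np.transpose(stack, (2, 1, 0))
    return ActivityMovie(
        data=data, pixel_pitch_um=pixel_pitch_um, frame_s=frame_s, valid_mask=valid_mask
    )


def write_movie_tiff(path, movie: ActivityMovie) -> None:
    import tifffile

    stack = np.transpose(movie.data, (2, 1, 0))
    tifffile.imwrite(str(path), stack)
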