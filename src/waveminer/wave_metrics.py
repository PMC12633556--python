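"""Per-wave and per-recording spatiotemporal wave properties.

Implements the full analysis suite for segmented retinal waves:

===================  =======================================================
area                 distinct x,y footprint size x pitch^2 (um^2)
duration             (t_end - t_start) x frame interval (s)
speed                mean Euclidean-distance-transform distance of newly
                     recruited (leading-edge) pixels to the previous frame's
                     footprint, per frame pair, converted to um/s
initiation site      unweighted centroid of the wave's first frame
IBI                  initiation bias index: fraction of waves initiating on
                     the nasal (high-x) half; 0.5 = unbiased
flow field           per-pixel propagation vector: summed displacement of
                     the wave's center of mass within the pixel's 3x3
                     neighborhood across consecutive frames
direction            mean flow vector, classified into 90-degree quadrants
                     centered on the four cardinal retinal axes
NBI                  nasal bias index: fraction of classified waves
                     propagating nasally; 0.25 = unbiased
LSI                  local synchrony index: wavefront activity over
                     wavefront + ahead-of-wavefront activity; 1 = perfectly
                     confined wave
frequency            per-pixel mean wave rate (waves/min per pixel) and the
                     whole-retina wave count rate
IWI                  inter-wave intervals: minutes between consecutive waves
                     crossing the same pixel, pooled over pixels
===================  =======================================================

Canonical orientation is assumed: nasal = +x, dorsal = +y.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GeometryError, UndefinedResultError
from .io_align import ActivityMovie
from .wave_segmentation import WaveLabelMatrix, WaveRecord, extract_waves

NASAL, TEMPORAL, DORSAL, VENTRAL = "nasal", "temporal", "dorsal", "ventral"
DIRECTION_CLASSES = (NASAL, TEMPORAL, DORSAL, VENTRAL)


# ---------------------------------------------------------------------------
# per-wave metrics
# ---------------------------------------------------------------------------

def wave_area(wave: WaveRecord, pitch_um: float) -> float:
    """Wave area in um^2: the x,y footprint flattened over time.

    A pixel active in many frames counts once.
    """
    if wave.n_pixels == 0:
        raise UndefinedResultError("area of an empty wave is undefined")
    return float(wave.footprint_xy().sum()) * pitch_um**2


def wave_duration(wave: WaveRecord, frame_s: float) -> float:
    """Wave duration in seconds: (t_end - t_start) * frame_s.

    By this definition a wave confined to a single frame has duration 0.
    """
    return (wave.t_end - wave.t_start) * frame_s


def wave_speed(
    wave: WaveRecord, pitch_um: float, frame_s: float, per_pair: bool = False
) -> float:
    """Wavefront speed in um/s from the Euclidean distance transform.

    For each consecutive frame pair within the wave, the leading edge is the
    set of pixels newly recruited at t+1; each is assigned its EDT distance
    to the frame-t footprint. The default pools all leading-edge distances
    across pairs before averaging; ``per_pair=True`` averages within each
    pair first and then across pairs. Returns NaN for single-frame waves
    (speed undefined) and 0 when no pair recruits new pixels.
    """
    if wave.n_frames < 2:
        return float("nan")
    fps = wave.footprints()
    dists: list[np.ndarray] = []
    for i in range(fps.shape[0] - 1):
        prev, nxt = fps[i], fps[i + 1]
        new = nxt & ~prev
        if not (prev.any() and new.any()):
            continue
        edt = ndimage.distance_transform_edt(~prev)
        dists.append(edt[new])
    if not dists:
        return 0.0
    if per_pair:
        mean_px = float(np.mean([d.mean() for d in dists]))
    else:
        mean_px = float(np.concatenate(dists).mean())
    return mean_px * pitch_um / frame_s


def initiation_site(wave: WaveRecord) -> tuple[float, float]:
    """Unweighted centroid (x, y) of the wave's first-frame footprint."""
    first = wave.pixels[wave.pixels[:, 2] == wave.t_start]
    return float(first[:, 0].mean()), float(first[:, 1].mean())


def flow_field(wave: WaveRecord) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel propagation vectors of a wave.

    For every participating pixel, the wave's footprint restricted to the
    pixel's 3x3 spatial neighborhood is reduced to its binary center of mass
    at each frame of the wave; the pixel's vector is the sum over consecutive
    frame pairs of the center-of-mass displacement. Pairs where either frame's
    neighborhood is empty contribute nothing; single-frame waves yield a zero
    field.

    Returns ``(pixels_xy, vectors)``: an (n, 2) array of the wave's distinct
    x,y pixels and the matching (n, 2) array of (vx, vy) vectors.
    """
    xy = np.unique(wave.pixels[:, :2], axis=0)
    vectors = np.zeros((xy.shape[0], 2), dtype=np.float64)
    if wave.n_frames < 2:
        return xy, vectors

    fps = wave.footprints().astype(np.float64)
    nx, ny = wave.shape[:2]
    gx = np.arange(nx, dtype=np.float64)[:, None]
    gy = np.arange(ny, dtype=np.float64)[None, :]
    kernel = np.ones((3, 3))

    # For each frame: count, sum-of-x and sum-of-y of wave pixels in the 3x3
    # window centered at every grid position (constant-zero padding).
    coms = np.full((fps.shape[0], 2, nx, ny), np.nan)
    for i, f in enumerate(fps):
        cnt = ndimage.correlate(f, kernel, mode="constant")
        sx = ndimage.correlate(f * gx, kernel, mode="constant")
        sy = ndimage.correlate(f * gy, kernel, mode="constant")
        with np.errstate(invalid="ignore", divide="ignore"):
            coms[i, 0] = np.where(cnt > 0, sx / cnt, np.nan)
            coms[i, 1] = np.where(cnt > 0, sy / cnt, np.nan)

    px, py = xy[:, 0], xy[:, 1]
    series = coms[:, :, px, py]           # (n_frames, 2, n_pixels)
    step = series[1:] - series[:-1]       # displacement per frame pair
    vectors = np.nansum(step, axis=0).T   # (n_pixels, 2); all-NaN pairs -> 0
    return xy, vectors


def classify_direction(vx: float, vy: float) -> str | None:
    """Quadrant classification of a propagation vector.

    90-degree bins centered on the cardinal axes: nasal = [-45, 45) degrees
    from +x, dorsal = [45, 135), temporal = [135, 225), ventral = [225, 315).
    Boundary angles fall counterclockwise into the next bin (half-open
    intervals). A zero vector is unclassifiable and returns None.
    """
    if vx == 0 and vy == 0:
        return None
    ang = np.degrees(np.arctan2(vy, vx))  # [-180, 180]
    if -45 <= ang < 45:
        return NASAL
    if 45 <= ang < 135:
        return DORSAL
    if -135 <= ang < -45:
        return VENTRAL
    return TEMPORAL


def propagation_direction(wave: WaveRecord) -> tuple[np.ndarray, str | None]:
    """Mean flow-field vector and its cardinal direction class.

    The propagation direction is the average of all per-pixel flow vectors;
    a zero mean vector leaves the wave unclassified (None).
    """
    _, vectors = flow_field(wave)
    mean_vec = vectors.mean(axis=0) if vectors.size else np.zeros(2)
    return mean_vec, classify_direction(float(mean_vec[0]), float(mean_vec[1]))


def local_synchrony(wave: WaveRecord, movie: ActivityMovie) -> float:
    """Local synchrony index (LSI) in [0, 1].

    Over every consecutive frame pair within the wave's duration, tabulates
    activity_wf: raw activity on the wave's leading-wavefront pixels (newly
    recruited at t+1), and activity_aheadwf: raw activity on pixels active at
    t+1 but not at t that are not part of the wave, i.e. the positive-part
    frame difference outside the wave. LSI = wf / (wf + aheadwf); 1 means no
    activity ahead of the wavefront. Raises :class:`UndefinedResultError`
    when the denominator is zero or the wave spans a single frame.
    """
    if wave.n_frames < 2:
        raise UndefinedResultError("LSI requires a wave spanning at least 2 frames")
    fps = wave.footprints()
    act_wf = 0.0
    act_ahead = 0.0
    for i in range(fps.shape[0] - 1):
        t = wave.t_start + i
        prev, nxt = fps[i], fps[i + 1]
        front = nxt & ~prev
        frame_next = movie.data[:, :, t + 1]
        act_wf += float(frame_next[front].sum())
        raw_prev = movie.data[:, :, t] > 0
        raw_next = frame_next > 0
        ahead = raw_next & ~raw_prev & ~nxt
        act_ahead += float(frame_next[ahead].sum())
    denom = act_wf + act_ahead
    if denom == 0:
        raise UndefinedResultError("no wavefront or ahead-of-wavefront activity")
    return act_wf / denom


# ---------------------------------------------------------------------------
# population metrics
# ---------------------------------------------------------------------------

def initiation_bias(init_x: np.ndarray, split_x: float) -> float:
    """Initiation bias index: fraction of waves initiating nasally (x >= split).

    Sites exactly on the split line count as nasal (deterministic tie rule).
    """
    init_x = np.asarray(init_x, dtype=float)
    if init_x.size == 0:
        raise UndefinedResultError("IBI is undefined for zero waves")
    num_n = int(np.sum(init_x >= split_x))
    return num_n / init_x.size


def nasal_bias(direction_classes) -> float:
    """Nasal bias index over classified waves: numN / (numN+numT+numV+numD)."""
    classes = [c for c in direction_classes if c in DIRECTION_CLASSES]
    if not classes:
        raise UndefinedResultError("NBI is undefined with no classified waves")
    return classes.count(NASAL) / len(classes)


def _pixel_wave_onsets(wlm: WaveLabelMatrix) -> pd.DataFrame:
    """Long table of (x, y, label, onset_frame): first frame each wave touches each pixel."""
    xs, ys, ts = np.nonzero(wlm.labels)
    if xs.size == 0:
        return pd.DataFrame(columns=["x", "y", "label", "onset"])
    labs = wlm.labels[xs, ys, ts]
    df = pd.DataFrame({"x": xs, "y": ys, "label": labs, "t": ts})
    return (
        df.groupby(["x", "y", "label"], sort=False)["t"].min()
        .rename("onset").reset_index()
    )


def wave_frequency(wlm: WaveLabelMatrix, recording_s: float | None = None) -> float:
    """Per-pixel wave frequency in waves/min.

    For every valid pixel, the number of distinct waves passing through it is
    divided by the recording length; the frequencies are averaged over
    pixels, yielding the occurrence of waves per unit space of the retina.
    Pixels no wave crosses contribute zero.
    """
    recording_s = recording_s if recording_s is not None else wlm.recording_s
    if recording_s <= 0:
        raise GeometryError("recording length must be positive")
    valid = wlm.valid_mask if wlm.valid_mask is not None else np.ones(wlm.shape[:2], bool)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise GeometryError("no valid pixels in the recording")
    onsets = _pixel_wave_onsets(wlm)
    total_crossings = len(onsets)  # one row per (pixel, wave)
    return total_crossings / n_valid / recording_s * 60.0


def total_wave_rate(wlm: WaveLabelMatrix, recording_s: float | None = None) -> float:
    """Whole-retina wave rate: total wave count / recording length, in waves/min."""
    recording_s = recording_s if recording_s is not None else wlm.recording_s
    if recording_s <= 0:
        raise GeometryError("recording length must be positive")
    return wlm.n_waves / recording_s * 60.0


def inter_wave_intervals(wlm: WaveLabelMatrix) -> np.ndarray:
    """Pooled per-pixel inter-wave intervals in minutes.

    For each pixel crossed by at least two distinct waves, the intervals
    between onset frames of consecutive waves at that pixel; pooled across
    pixels. Empty when no pixel sees two waves.
    """
    onsets = _pixel_wave_onsets(wlm)
    if onsets.empty:
        return np.empty(0)
    onsets = onsets.sort_values(["x", "y", "onset"])
    diffs = onsets.groupby(["x", "y"], sort=False)["onset"].diff().dropna().to_numpy()
    return diffs * wlm.frame_s / 60.0


# ---------------------------------------------------------------------------
# wave table and recording summary
# ---------------------------------------------------------------------------

WAVE_TABLE_COLUMNS = [
    "wave_id", "t_start_s", "t_end_s", "duration_s", "area_um2", "speed_um_s",
    "init_x", "init_y", "dir_x", "dir_y", "direction_class", "lsi", "n_pixels",
]


def analyze_waves(
    wlm: WaveLabelMatrix, movie: ActivityMovie | None = None
) -> pd.DataFrame:
    """Compute the full per-wave metric table.

    One row per wave with the columns in :data:`WAVE_TABLE_COLUMNS`. Metrics
    that are undefined for a wave (speed/LSI of a single-frame wave, LSI with
    a zero denominator or without a raw movie) are NaN.
    """
    rows = []
    for wave in extract_waves(wlm):
        ix, iy = initiation_site(wave)
        mean_vec, dclass = propagation_direction(wave)
        lsi = np.nan
        if movie is not None and wave.n_frames >= 2:
            try:
                lsi = local_synchrony(wave, movie)
            except UndefinedResultError:
                lsi = np.nan
        rows.append({
            "wave_id": wave.wave_id,
            "t_start_s": wave.t_start * wlm.frame_s,
            "t_end_s": wave.t_end * wlm.frame_s,
            "duration_s": wave_duration(wave, wlm.frame_s),
            "area_um2": wave_area(wave, wlm.pixel_pitch_um),
            "speed_um_s": wave_speed(wave, wlm.pixel_pitch_um, wlm.frame_s),
            "init_x": ix,
            "init_y": iy,
            "dir_x": mean_vec[0],
            "dir_y": mean_vec[1],
            "direction_class": dclass if dclass is not None else "",
            "lsi": lsi,
            "n_pixels": wave.n_pixels,
        })
    return pd.DataFrame(rows, columns=WAVE_TABLE_COLUMNS)


def _population_stats(table: pd.DataFrame, split_x: float) -> dict:
    out: dict = {"n_waves": int(len(table))}
    if len(table):
        out["ibi"] = initiation_bias(table["init_x"].to_numpy(), split_x)
        classes = [c for c in table["direction_class"] if c]
        out["nbi"] = nasal_bias(classes) if classes else None
        out["mean_area_um2"] = float(table["area_um2"].mean())
        out["mean_duration_s"] = float(table["duration_s"].mean())
        speeds = table["speed_um_s"].dropna()
        out["mean_speed_um_s"] = float(speeds.mean()) if len(speeds) else None
        lsis = table["lsi"].dropna()
        out["lsi_mean"] = float(lsis.mean()) if len(lsis) else None
    else:
        out.update({k: None for k in (
            "ibi", "nbi", "mean_area_um2", "mean_duration_s",
            "mean_speed_um_s", "lsi_mean",
        )})
    return out


def summarize_recording(
    wlm: WaveLabelMatrix,
    movie: ActivityMovie | None = None,
    optic_nerve_x: float | None = None,
    table: pd.DataFrame | None = None,
    per_hour: bool = False,
) -> dict:
    """Recording-level summary of wave occurrence and population biases.

    The nasal/temporal split defaults to the grid's x center (the canonical
    optic-nerve position); supply ``optic_nerve_x`` when alignment placed it
    elsewhere. With ``per_hour=True`` the population statistics are
    additionally recomputed in 1-h bins (waves assigned to the hour
    containing their first frame), mirroring long-recording analyses.
    """
    if table is None:
        table = analyze_waves(wlm, movie)
    if optic_nerve_x is None:
        if movie is not None and movie.optic_nerve_xy is not None:
            optic_nerve_x = movie.optic_nerve_xy[0]
        else:
            optic_nerve_x = (wlm.shape[0] - 1) / 2.0
    iwi = inter_wave_intervals(wlm)
    summary = {
        "recording_s": wlm.recording_s,
        "frequency_per_min": wave_frequency(wlm),
        "total_waves_per_min": total_wave_rate(wlm),
        "total_waves": wlm.n_waves,
        "iwi_minutes_mean": float(iwi.mean()) if iwi.size else None,
        "iwi_minutes_n": int(iwi.size),
        "optic_nerve_x": float(optic_nerve_x),
    }
    try:
        summary.update(_population_stats(table, optic_nerve_x))
    except UndefinedResultError:
        summary.update(_population_stats(table.iloc[0:0], optic_nerve_x))
    if per_hour:
        hours = []
        n_hours = int(np.ceil(wlm.recording_s / 3600.0))
        for h in range(n_hours):
            sel = table[(table["t_start_s"] >= h * 3600) & (table["t_start_s"] < (h + 1) * 3600)]
            span = min(3600.0, wlm.recording_s - h * 3600)
            block = {"hour": h, "waves_per_min": len(sel) / span * 60.0}
            block.update(_population_stats(sel, optic_nerve_x))
            hours.append(block)
        summary["per_hour"] = hours
    return summary
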