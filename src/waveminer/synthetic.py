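"""Synthetic retinal-wave recordings with known ground truth.

The simulator emits spike-event recordings in which propagating waves with
known origin, direction, speed and extent ride on Poisson tonic background —
the test surface for every pipeline stage in the absence of deposited raw
recordings.

Model
-----
Waves are planar activity bands (or translating discs) that move across a
regular electrode grid at a fixed speed; every member pixel fires Poisson
spikes at ``wavefront_rate_hz`` while the band covers it, and every valid
pixel fires tonic Poisson spikes at ``tonic_rate_hz`` throughout. Wave onset
times follow a renewal process with a refractory period: successive gaps are
``refractory_s + Exponential(mean = period - refractory_s)`` where ``period
= 60 / wave_rate_per_min``, so the mean inter-wave interval equals the
period exactly while waves never overlap in time — ground truth stays
unambiguous, and recovery of the generating frequency and IWI is an honest
point comparison. (Real retinal waves likewise show local refractoriness.)

Direction is drawn over the four cardinal axes (nasal = +x, temporal = -x,
dorsal = +y, ventral = -y) and the initiation site over the nasal/temporal
halves, independently, so direction- and initiation-bias estimators can be
exercised separately. ``ahead_noise_ratio`` injects extra Poisson activity
just ahead of each advancing wavefront with a known expected mass relative
to the front's, giving the local-synchrony index a closed-form expectation
of ``1 / (1 + ratio)``.

The default speed of 87.5 um/s is one pixel per 1-s frame on the 87.5-um
grid: the one discretization of a translating band for which the pooled
leading-edge EDT speed estimator is exactly unbiased (a band advancing d > 1
pixels per frame has newly recruited pixels at distances 1..d, mean
(d+1)/2). It also sits within the range reported for first-postnatal-week
waves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

from .errors import ParameterError
from .io_align import ActivityMovie, ElectrodeMap, SpikeEvents, n_frames_for
from .wave_segmentation import WaveLabelMatrix

DIRECTIONS = ("N", "T", "D", "V")
_DIR_STEP = {"N": (1, 0), "T": (-1, 0), "D": (0, 1), "V": (0, -1)}


@dataclass(frozen=True)
class SimulationParams:
    """Generating conditions for a synthetic recording.

    Grid and timing default to the HD-MEA configuration this package targets
    (32 x 32 electrodes at 87.5 um, 1-s frames); wave conditions default to
    first-postnatal-week-like values: about one wave per minute, 87.5 um/s,
    ~1.3-mm-wide bands sweeping ~1 mm, 20-Hz firing at the front over a
    0.5-Hz tonic background.
    """

    nx: int = 32
    ny: int = 32
    duration_s: float = 600.0
    frame_s: float = 1.0
    pixel_pitch_um: float = 87.5
    wave_rate_per_min: float = 1.0
    speed_um_s: float = 87.5
    profile: str = "planar"  # "planar", "fullfield" or "disc"
    band_width_px: int = 15
    band_thickness_px: int = 3
    travel_px: int = 12
    disc_radius_px: int = 4
    direction_distribution: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    initiation_p_nasal: float = 0.5
    tonic_rate_hz: float = 0.5
    wavefront_rate_hz: float = 20.0
    ahead_noise_ratio: float = 0.0
    refractory_s: float | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.direction_distribution) - 1.0) > 1e-9:
            raise ParameterError("direction_distribution must sum to 1")
        if not 0.0 <= self.initiation_p_nasal <= 1.0:
            raise ParameterError("initiation_p_nasal must be in [0, 1]")
        for name in ("wave_rate_per_min", "tonic_rate_hz", "wavefront_rate_hz",
                     "ahead_noise_ratio"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.profile not in ("planar", "fullfield", "disc"):
            raise ParameterError(f"unknown wave profile {self.profile!r}")

    @property
    def speed_px_per_frame(self) -> float:
        return self.speed_um_s / self.pixel_pitch_um * self.frame_s

    def wave_frames(self) -> int:
        """Number of frames a single wave lasts."""
        step = max(self.speed_px_per_frame, 1e-9)
        if self.profile == "fullfield":
            travel = max(self.nx, self.ny) + self.band_thickness_px
        else:
            travel = self.travel_px
        return max(int(round(travel / step)), 1)

    def effective_refractory_s(self) -> float:
        if self.refractory_s is not None:
            return self.refractory_s
        return (self.wave_frames() + 5) * self.frame_s


@dataclass
class GroundTruth:
    """True wave inventory matching a simulated recording.

    ``waves`` has one row per wave (wave_id, onset frame, direction label,
    initiation half, origin, speed, frame span, voxel count); ``labels`` is
    the true wave-ID matrix with the same shape the pipeline produces.
    """

    waves: pd.DataFrame
    labels: np.ndarray
    params: SimulationParams
    n_rejected: int = 0

    @property
    def n_waves(self) -> int:
        return int(len(self.waves))

    def label_matrix(self) -> WaveLabelMatrix:
        """The truth as a WaveLabelMatrix, for running metrics on it directly."""
        from .wave_segmentation import Connectivity

        return WaveLabelMatrix(
            labels=self.labels, n_waves=self.n_waves, connectivity=Connectivity(),
            min_pixels=0, pixel_pitch_um=self.params.pixel_pitch_um,
            frame_s=self.params.frame_s,
        )


def grid_electrode_map(params: SimulationParams) -> ElectrodeMap:
    """Full nx x ny recording-electrode map with channel = x * ny + y."""
    xs, ys = np.meshgrid(np.arange(params.nx), np.arange(params.ny), indexing="ij")
    xs, ys = xs.ravel(), ys.ravel()
    return ElectrodeMap(
        channel=xs * params.ny + ys,
        x_um=xs * params.pixel_pitch_um,
        y_um=ys * params.pixel_pitch_um,
        is_reference=np.zeros(xs.size, dtype=bool),
        pitch_um=params.pixel_pitch_um,
    )


# ---------------------------------------------------------------------------
# wave geometry
# ---------------------------------------------------------------------------

def _draw_origin(params: SimulationParams, direction: str, nasal: bool,
                 rng: np.random.Generator) -> tuple[float, float]:
    """Origin (lead position along motion axis, perpendicular center).

    Chosen so the first-frame center of mass lies in the requested
    nasal/temporal half with margin, while the band stays mostly on-grid.
    """
    nx, ny = params.nx, params.ny
    split = (nx - 1) / 2.0
    thick = params.band_thickness_px
    if params.profile == "fullfield":
        # band starts off-grid and sweeps the entire array
        n_along = nx if direction in ("N", "T") else ny
        n_perp = ny if direction in ("N", "T") else nx
        lead = 0.0 if direction in ("N", "D") else float(n_along - 1)
        return lead, n_perp / 2.0
    if direction in ("N", "T"):
        # motion along x: initiation x is set by the starting band position
        lo, hi = (int(np.ceil(split)) + 2, nx - 3) if nasal else (2, int(split) - 2)
        if lo > hi:
            raise ParameterError("grid too small for the requested wave geometry")
        com_x = rng.integers(lo, hi + 1)
        lead = com_x + (thick - 1) // 2 if direction == "N" else com_x - (thick - 1) // 2
        perp = rng.integers(3, ny - 3)
        return float(lead), float(perp)
    # motion along y: initiation x is the band's perpendicular center; the
    # margin keeps the (possibly edge-clipped) band's centroid in its half
    m = max(2, nx // 8)
    lo, hi = (int(np.ceil(split)) + m, nx - 1 - m) if nasal else (m, int(split) - m)
    if lo > hi:
        raise ParameterError("grid too small for the requested wave geometry")
    perp = rng.integers(lo, hi + 1)
    lead = rng.integers(3, ny - 3)
    return float(lead), float(perp)


def _band_voxels(params: SimulationParams, direction: str, lead0: float,
                 perp0: float, n_frames: int) -> list[np.ndarray]:
    """Per-frame (n, 2) pixel arrays of a translating band, clipped to grid."""
    nx, ny = params.nx, params.ny
    along_x = direction in ("N", "T")
    sgn = 1 if direction in ("N", "D") else -1
    step = params.speed_px_per_frame
    thick = params.band_thickness_px
    if params.profile == "fullfield":
        half_w = max(nx, ny)
    else:
        half_w = params.band_width_px // 2
    n_along = nx if along_x else ny
    n_perp = ny if along_x else nx

    frames = []
    for k in range(n_frames):
        lead = int(round(lead0 + sgn * step * k))
        if sgn > 0:
            a_lo, a_hi = lead - thick + 1, lead
        else:
            a_lo, a_hi = lead, lead + thick - 1
        a = np.arange(max(a_lo, 0), min(a_hi, n_along - 1) + 1)
        p = np.arange(max(int(perp0) - half_w, 0), min(int(perp0) + half_w, n_perp - 1) + 1)
        if a.size == 0 or p.size == 0:
            frames.append(np.empty((0, 2), dtype=np.int64))
            continue
        aa, pp = np.meshgrid(a, p, indexing="ij")
        if along_x:
            frames.append(np.column_stack([aa.ravel(), pp.ravel()]))
        else:
            frames.append(np.column_stack([pp.ravel(), aa.ravel()]))
    return frames


def _disc_voxels(params: SimulationParams, direction: str, lead0: float,
                 perp0: float, n_frames: int) -> list[np.ndarray]:
    """Per-frame pixels of a disc translating at the wave speed."""
    nx, ny = params.nx, params.ny
    dx, dy = _DIR_STEP[direction]
    step = params.speed_px_per_frame
    r = params.disc_radius_px
    if direction in ("N", "T"):
        cx0, cy0 = lead0, perp0
    else:
        cx0, cy0 = perp0, lead0
    gx, gy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    frames = []
    for k in range(n_frames):
        cx, cy = cx0 + dx * step * k, cy0 + dy * step * k
        mask = (gx - cx) ** 2 + (gy - cy) ** 2 <= r**2
        frames.append(np.column_stack(np.nonzero(mask)))
    return frames


def _front_pixels(prev: np.ndarray, cur: np.ndarray) -> np.ndarray:
    """Pixels in cur but not in prev (the newly recruited wavefront)."""
    if prev.size == 0:
        return cur
    prev_keys = {tuple(p) for p in prev}
    return np.array([p for p in cur if tuple(p) not in prev_keys], dtype=np.int64).reshape(-1, 2)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate(params: SimulationParams) -> tuple[SpikeEvents, GroundTruth]:
    """Generate a synthetic spike recording plus its ground truth.

    Fully deterministic given ``params.rng_seed``. Waves whose (safety-
    checked) space-time support would collide with an already placed wave
    are re-drawn up to a retry cap; irreducible rejections are counted in
    ``GroundTruth.n_rejected``.
    """
    rng = np.random.default_rng(params.rng_seed)
    nt = n_frames_for(params.duration_s, params.frame_s)
    nt_active = int(np.floor(params.duration_s / params.frame_s))
    labels = np.zeros((params.nx, params.ny, nt), dtype=np.int32)

    period = 60.0 / params.wave_rate_per_min if params.wave_rate_per_min > 0 else np.inf
    refr = params.effective_refractory_s()
    if np.isfinite(period) and period <= refr:
        raise ParameterError(
            f"wave period ({period:.1f}s) must exceed the refractory interval "
            f"({refr:.1f}s); lower wave_rate_per_min or shorten the waves"
        )
    n_frames_wave = params.wave_frames()

    # --- schedule wave onsets (renewal process, mean gap = period) ---
    onsets_s: list[float] = []
    if np.isfinite(period):
        t = rng.exponential(period - refr)
        while t + n_frames_wave * params.frame_s < params.duration_s:
            onsets_s.append(t)
            t += refr + rng.exponential(period - refr)

    truth_rows = []
    ev_channel: list[np.ndarray] = []
    ev_time: list[np.ndarray] = []
    occupied = np.zeros((params.nx, params.ny, nt), dtype=bool)
    n_rejected = 0
    builder = _disc_voxels if params.profile == "disc" else _band_voxels

    for wave_id, onset_s in enumerate(onsets_s, start=1):
        f0 = int(np.floor(onset_s / params.frame_s))
        placed = False
        for _attempt in range(20):
            direction = DIRECTIONS[rng.choice(4, p=params.direction_distribution)]
            nasal = rng.random() < params.initiation_p_nasal
            lead0, perp0 = _draw_origin(params, direction, nasal, rng)
            per_frame = builder(params, direction, lead0, perp0, n_frames_wave)
            # safety check (scheduling already serializes waves in time)
            collide = False
            for k, pix in enumerate(per_frame):
                f = f0 + k
                if f >= nt_active or pix.size == 0:
                    continue
                lo, hi = max(f - 2, 0), min(f + 3, nt)
                if occupied[pix[:, 0], pix[:, 1], lo:hi].any():
                    collide = True
                    break
            if not collide:
                placed = True
                break
            n_rejected += 1
        if not placed:
            continue

        n_vox = 0
        prev = np.empty((0, 2), dtype=np.int64)
        for k, pix in enumerate(per_frame):
            f = f0 + k
            if f >= nt_active or pix.size == 0:
                prev = pix
                continue
            labels[pix[:, 0], pix[:, 1], f] = wave_id
            occupied[pix[:, 0], pix[:, 1], f] = True
            n_vox += pix.shape[0]
            # spikes on member pixels
            counts = rng.poisson(params.wavefront_rate_hz * params.frame_s, pix.shape[0])
            _emit(ev_channel, ev_time, params, pix, f, counts, rng)
            # activity injected ahead of the advancing front (for LSI control)
            if params.ahead_noise_ratio > 0 and k > 0:
                front = _front_pixels(prev, pix)
                ahead = _ahead_pixels(params, front, _DIR_STEP[direction])
                if ahead.size:
                    lam = (
                        params.ahead_noise_ratio * params.wavefront_rate_hz
                        * params.frame_s * front.shape[0] / ahead.shape[0]
                    )
                    _emit(ev_channel, ev_time, params, ahead, f,
                          rng.poisson(lam, ahead.shape[0]), rng)
            prev = pix
        frames_used = [k for k, pix in enumerate(per_frame)
                       if f0 + k < nt_active and pix.size]
        if not frames_used:
            continue
        truth_rows.append({
            "wave_id": wave_id, "t_start_frame": f0 + frames_used[0],
            "t_end_frame": f0 + frames_used[-1], "direction": direction,
            "initiated_nasal": bool(nasal), "origin_lead": lead0,
            "origin_perp": perp0, "speed_um_s": params.speed_um_s,
            "n_pixels": n_vox,
        })

    # --- tonic background ---
    if params.tonic_rate_hz > 0:
        counts = rng.poisson(
            params.tonic_rate_hz * params.frame_s,
            size=(params.nx * params.ny, nt_active),
        )
        flat = counts.ravel()
        nz = np.nonzero(flat)[0]
        reps = flat[nz]
        pix_idx = nz // nt_active
        frame_idx = nz % nt_active
        ch = np.repeat(pix_idx, reps)  # channel = x * ny + y by construction
        fr = np.repeat(frame_idx, reps)
        ev_channel.append(ch)
        ev_time.append((fr + rng.random(fr.size)) * params.frame_s)

    emap = grid_electrode_map(params)
    if ev_channel:
        channel = np.concatenate(ev_channel)
        time_s = np.concatenate(ev_time)
        order = np.argsort(time_s, kind="stable")
        channel, time_s = channel[order], time_s[order]
    else:
        channel = np.empty(0, dtype=np.int64)
        time_s = np.empty(0)
    spikes = SpikeEvents(
        channel=channel, time_s=time_s, duration_s=params.duration_s, emap=emap
    )
    truth = GroundTruth(
        waves=pd.DataFrame(
            truth_rows, columns=[
                "wave_id", "t_start_frame", "t_end_frame", "direction",
                "initiated_nasal", "origin_lead", "origin_perp", "speed_um_s",
                "n_pixels",
            ],
        ),
        labels=labels, params=params, n_rejected=n_rejected,
    )
    return spikes, truth


def _emit(ev_channel, ev_time, params, pix, frame, counts, rng) -> None:
    total = int(counts.sum())
    if total == 0:
        return
    ch = np.repeat(pix[:, 0] * params.ny + pix[:, 1], counts)
    ev_channel.append(ch)
    ev_time.append((frame + rng.random(total)) * params.frame_s)


def _ahead_pixels(params, front: np.ndarray, step: tuple[int, int]) -> np.ndarray:
    """Pixels two steps ahead of the new front, clipped to the grid."""
    if front.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    ahead = front + 2 * np.array(step)
    ok = (
        (ahead[:, 0] >= 0) & (ahead[:, 0] < params.nx)
        & (ahead[:, 1] >= 0) & (ahead[:, 1] < params.ny)
    )
    return ahead[ok]


# ---------------------------------------------------------------------------
# developmental presets
# ---------------------------------------------------------------------------

#: Qualitative developmental presets. Values are illustrative of the reported
#: trends over the first two postnatal weeks — frequency and speed rise into
#: the second week, area grows then shrinks again late, duration peaks mid
#: timeline, and a nasal propagation bias appears transiently around 1.5
#: weeks — not fits to any recording.
_PRESETS: dict[str, dict] = {
    "0wk":   dict(wave_rate_per_min=0.6, speed_um_s=87.5, band_width_px=9,
                  travel_px=8, direction_distribution=(0.25, 0.25, 0.25, 0.25)),
    "0.5wk": dict(wave_rate_per_min=0.8, speed_um_s=87.5, band_width_px=13,
                  travel_px=10, direction_distribution=(0.25, 0.25, 0.25, 0.25)),
    "1wk":   dict(wave_rate_per_min=1.0, speed_um_s=131.25, band_width_px=17,
                  travel_px=14, direction_distribution=(0.25, 0.25, 0.25, 0.25)),
    "1.5wk": dict(wave_rate_per_min=1.6, speed_um_s=175.0, band_width_px=15,
                  travel_px=12, direction_distribution=(0.55, 0.15, 0.15, 0.15)),
    "2wk":   dict(wave_rate_per_min=2.0, speed_um_s=262.5, band_width_px=11,
                  travel_px=10, direction_distribution=(0.25, 0.25, 0.25, 0.25)),
}


def preset(age_group: str, **overrides) -> SimulationParams:
    """Simulation parameters qualitatively matching a developmental age group.

    ``age_group`` is one of '0wk', '0.5wk', '1wk', '1.5wk', '2wk'. Keyword
    overrides replace any field.
    """
    if age_group not in _PRESETS:
        raise ParameterError(
            f"unknown age group {age_group!r}; choose from {sorted(_PRESETS)}"
        )
    kw = dict(_PRESETS[age_group])
    kw.update(overrides)
    return SimulationParams(**kw)


# ---------------------------------------------------------------------------
# truth I/O and detection scoring
# ---------------------------------------------------------------------------

def write_truth(path, truth: GroundTruth) -> None:
    """Write ground truth to HDF5: /true_labels plus a /true_waves table."""
    with h5py.File(path, "w") as f:
        f.create_dataset("true_labels", data=truth.labels, compression="gzip")
        g = f.create_group("true_waves")
        for col in truth.waves.columns:
            data = truth.waves[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            g.create_dataset(col, data=data)
        f.attrs["rng_seed"] = truth.params.rng_seed
        f.attrs["n_rejected"] = truth.n_rejected


def match_to_truth(
    wlm: WaveLabelMatrix, truth: GroundTruth, min_cover: float = 0.5
) -> dict:
    """Score detected waves against ground truth.

    A true wave is *hit* when a single detected label covers at least
    ``min_cover`` of its voxels. Returns hit rate, per-wave best coverage,
    and the number of detected labels matched to no true wave.
    """
    coverages = []
    matched_labels: set[int] = set()
    for wave_id in truth.waves["wave_id"]:
        support = truth.labels == wave_id
        det = wlm.labels[support]
        det = det[det > 0]
        if det.size == 0:
            coverages.append(0.0)
            continue
        best = np.bincount(det).argmax()
        cover = float(np.sum(det == best)) / float(support.sum())
        coverages.append(cover)
        if cover >= min_cover:
            matched_labels.add(int(best))
    coverages_arr = np.array(coverages) if coverages else np.empty(0)
    hits = int(np.sum(coverages_arr >= min_cover))
    n_true = len(coverages)
    return {
        "n_true": n_true,
        "n_detected": wlm.n_waves,
        "hits": hits,
        "hit_rate": hits / n_true if n_true else float("nan"),
        "coverage": coverages_arr,
        "unmatched_detected": wlm.n_waves - len(matched_labels),
    }
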