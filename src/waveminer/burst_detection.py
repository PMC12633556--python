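"""Dynamic burst detection: separating phasic (wave) from tonic activity.

Retinal waves ride on top of baseline ("tonic") firing whose level varies
across pixels, across hours, and — in pharmacological experiments that raise
overall excitability — can be several-fold elevated. Segmentation therefore
runs not on raw activity but on a per-pixel *phasic mask*: frames where the
smoothed firing rate excursion above a rolling robust baseline is large and
sustained.

Per pixel, the detector

1. smooths the count rate with a short boxcar (``smoothing_s``),
2. estimates a rolling baseline (median) and dispersion (MAD, converted to a
   sigma-equivalent and floored at the Poisson standard deviation of the
   smoothed rate) over ``baseline_window_s``,
3. marks frames with smoothed rate > median + ``threshold_k``·sigma, and
4. keeps only runs of at least ``min_burst_frames`` consecutive supra-
   threshold frames.

The median/MAD pair makes the baseline insensitive to the bursts themselves
(waves occupy a small fraction of any minute-scale window), and thresholding
in units of the *local* dispersion makes detection invariant to uniform
changes in tonic rate — the property that lets the same parameters segment
waves before and after a drug raises baseline firing five-fold. The floor on
the dispersion matters at low rates, where the MAD of a discrete Poisson
count series underestimates its counting noise, and requiring
``min_burst_frames`` to exceed the smoothing window means a single outlier
count bin can never fake a burst on its own.

Because the baseline is slow by construction, it is evaluated on a coarse
stride (default a quarter window) and linearly interpolated between
evaluation points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_opening, uniform_filter1d

from .errors import ParameterError
from .io_align import ActivityMovie

#: MAD of a normal distribution is sigma / 1.4826
MAD_TO_SIGMA = 1.4826


@dataclass(frozen=True)
class BurstParams:
    """Parameters of the phasic/tonic separation.

    baseline_window_s : rolling window for the median/MAD baseline (s).
    smoothing_s       : boxcar rate-smoothing window (s).
    threshold_k       : multiplier on the baseline dispersion.
    min_burst_frames  : minimum consecutive supra-threshold frames.
    baseline_stride_s : spacing of baseline evaluation points (s);
                        default ``baseline_window_s / 4``.
    """

    baseline_window_s: float = 60.0
    smoothing_s: float = 2.0
    threshold_k: float = 4.0
    min_burst_frames: int = 3
    baseline_stride_s: float | None = None

    def __post_init__(self) -> None:
        if min(self.baseline_window_s, self.smoothing_s, self.threshold_k) <= 0:
            raise ParameterError("burst parameters must be positive")
        if self.min_burst_frames < 1:
            raise ParameterError("min_burst_frames must be >= 1")
        if self.baseline_window_s <= self.smoothing_s:
            raise ParameterError("baseline_window_s must exceed smoothing_s")
        if self.baseline_stride_s is not None and self.baseline_stride_s <= 0:
            raise ParameterError("baseline_stride_s must be positive")


@dataclass
class PhasicMovie:
    """Binary ``x, y, t`` mask of burst-classified (phasic) activity.

    Invariant: every phasic voxel had nonzero activity in the source movie.
    """

    data: np.ndarray
    pixel_pitch_um: float
    frame_s: float
    valid_mask: np.ndarray
    params: BurstParams

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


def _windowed_median(x: np.ndarray, centers: np.ndarray, half: int) -> np.ndarray:
    """Median of x[:, c-half : c+half+1] per center, window clipped at the edges."""
    nt = x.shape[1]
    out = np.empty((x.shape[0], centers.size), dtype=np.float32)
    for j, c in enumerate(centers):
        lo, hi = max(0, c - half), min(nt, c + half + 1)
        out[:, j] = np.median(x[:, lo:hi], axis=1)
    return out


def _windowed_mean(x: np.ndarray, centers: np.ndarray, half: int) -> np.ndarray:
    """Mean of x[:, c-half : c+half+1] per center, window clipped at the edges."""
    nt = x.shape[1]
    out = np.empty((x.shape[0], centers.size), dtype=np.float32)
    for j, c in enumerate(centers):
        lo, hi = max(0, c - half), min(nt, c + half + 1)
        out[:, j] = x[:, lo:hi].mean(axis=1)
    return out


def _interp_frames(values: np.ndarray, centers: np.ndarray, nt: int) -> np.ndarray:
    """Linear interpolation of per-center values onto every frame (vectorized)."""
    if centers.size == 1:
        return np.repeat(values, nt, axis=1)
    t = np.arange(nt)
    hi = np.clip(np.searchsorted(centers, t), 1, centers.size - 1)
    lo = hi - 1
    span = (centers[hi] - centers[lo]).astype(np.float32)
    w = np.clip((t - centers[lo]) / span, 0.0, 1.0).astype(np.float32)
    return values[:, lo] * (1.0 - w) + values[:, hi] * w


def filter_phasic(movie: ActivityMovie, params: BurstParams | None = None) -> PhasicMovie:
    """Classify each voxel of an activity movie as phasic (burst) or tonic.

    Returns a binary :class:`PhasicMovie` of the same geometry. Raises
    :class:`ParameterError` when the recording is shorter than the baseline
    window.
    """
    params = params or BurstParams()
    nt = movie.n_frames
    w_base = max(int(round(params.baseline_window_s / movie.frame_s)), 2)
    w_smooth = max(int(round(params.smoothing_s / movie.frame_s)), 1)
    if nt < w_base:
        raise ParameterError(
            f"recording ({nt} frames) is shorter than the baseline window "
            f"({w_base} frames); reduce baseline_window_s"
        )
    stride_s = params.baseline_stride_s or params.baseline_window_s / 4.0
    stride = max(int(round(stride_s / movie.frame_s)), 1)

    nx, ny = movie.data.shape[:2]
    raw = movie.data.reshape(nx * ny, nt)
    smoothed = uniform_filter1d(
        raw.astype(np.float32), size=w_smooth, axis=1, mode="nearest"
    )

    centers = np.arange(0, nt, stride)
    if centers[-1] != nt - 1:
        centers = np.append(centers, nt - 1)
    half = w_base // 2

    med_c = _windowed_median(smoothed, centers, half)
    med = _interp_frames(med_c, centers, nt)
    dev = np.abs(smoothed - med)
    mad = _interp_frames(_windowed_median(dev, centers, half), centers, nt)

    # Dispersion: sigma-equivalent MAD, floored at the Poisson sd of the
    # smoothed rate. The rate entering the floor is the rolling *mean* (the
    # median of a low-rate count series is 0 well before the rate is), itself
    # floored at one count per window so silent pixels get a finite threshold.
    rate = _interp_frames(_windowed_mean(smoothed, centers, half), centers, nt)
    floor_rate = np.maximum(rate, 1.0 / w_base)
    sigma = np.maximum(MAD_TO_SIGMA * mad, np.sqrt(floor_rate / w_smooth))

    supra = smoothed > med + params.threshold_k * sigma
    if params.min_burst_frames > 1:
        structure = np.ones((1, params.min_burst_frames), dtype=bool)
        supra = binary_opening(supra, structure=structure)

    phasic = supra & (raw > 0)
    phasic &= movie.valid_mask.reshape(nx * ny, 1)
    return PhasicMovie(
        data=phasic.reshape(nx, ny, nt),
        pixel_pitch_um=movie.pixel_pitch_um,
        frame_s=movie.frame_s,
        valid_mask=movie.valid_mask,
        params=params,
    )


def write_phasic(path, phasic: PhasicMovie) -> None:
    """Export the phasic mask to HDF5 (/phasic, uint8, x,y,t) with provenance attrs."""
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("phasic", data=phasic.data.astype(np.uint8), compression="gzip")
        d.attrs["pixel_pitch_um"] = phasic.pixel_pitch_um
        d.attrs["frame_s"] = phasic.frame_s
        for k in ("baseline_window_s", "smoothing_s", "threshold_k", "min_burst_frames"):
            d.attrs[k] = getattr(phasic.params, k)
        f.create_dataset("valid_mask", data=phasic.valid_mask.astype(np.uint8))
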