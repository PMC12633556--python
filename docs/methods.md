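# Methods

This note records the models, parameter choices and numerical conventions
behind `waveminer`, and what the synthetic benchmarks do and do not
demonstrate.

## Data model and conventions

A recording is either a spike-event table — `(channel, time)` pairs plus an
electrode map — or a dense movie. Rasterization bins events into
`data[x, y, t]` counts with **half-open time bins** `[t·Δt, (t+1)·Δt)`; a
spike at exactly the bin boundary belongs to the next frame, and the frame
count is `floor(duration/Δt) + 1` so the boundary spike at `t = duration`
has a frame. The default frame interval is 1 s because the speed metric is
defined between pairs of 1-s frames; the default pitch is 87.5 µm (the
1024-electrode HD-MEA configuration, 12 reference electrodes excluded from
rasterization and masked).

Pixel coordinates are 0-based grid indices with the canonical orientation
nasal = +x, dorsal = +y. Alignment is an explicit flip/offset specification
supplied by the experimenter (anatomical landmarking is interactive by
nature and out of scope); it is a pure pixel permutation, and an offset that
would push a valid pixel off the grid is an error rather than a silent crop
— this is what makes "apply spec, then its inverse" an exact identity.

## Burst detection (phasic/tonic separation)

The separation runs per pixel on the count rate smoothed with a
`smoothing_s` boxcar:

- baseline = rolling **median** over `baseline_window_s`;
- dispersion `σ = max(1.4826·MAD, sqrt(max(rate, 1/w)/w_s))`, where `rate`
  is the rolling **mean** (floored at one count per window), `w` and `w_s`
  are the baseline and smoothing windows in frames;
- a frame is supra-threshold when the smoothed rate exceeds
  `median + threshold_k·σ`, and phasic when it belongs to a run of at least
  `min_burst_frames` supra-threshold frames *and* carries nonzero raw
  activity (so the phasic mask is always a subset of the raw support).

Defaults: `baseline_window_s = 60`, `smoothing_s = 2`, `threshold_k = 4`,
`min_burst_frames = 3`. Two choices deserve justification:

- **The Poisson floor on σ.** For spike counts at sub-hertz baselines the
  MAD of the smoothed rate — and even its median — is frequently zero, which
  would let any pair of coincident spikes cross a `k·MAD` threshold. The
  dispersion is therefore floored at the Poisson standard deviation of the
  smoothed rate, estimated from the rolling mean (the median underestimates
  a skewed count distribution's location long before the rate is actually
  zero).
- **`min_burst_frames` exceeds the smoothing window.** With a 2-frame boxcar,
  one outlier count bin props up two consecutive smoothed frames; requiring
  three keeps single-bin accidents out, so a false burst needs two
  independent large excursions, which at the default threshold has
  per-frame probability of order 10⁻⁸.

The thresholds adapt to the local baseline, so a uniform five-fold increase
in tonic rate (the pharmacological scenario the detector exists for) shifts
the median and the floor together and leaves wave detection essentially
unchanged; this is verified end-to-end in the acceptance suite.

The baseline is evaluated every `baseline_stride_s` (default a quarter
window) and linearly interpolated: baselines drift over minutes, not frames,
and the stride turns an O(nt·w) rolling median over hours-long recordings
into a negligible cost. Windows shrink one-sidedly at the recording edges
rather than discarding frames. The mask is binarized for segmentation; raw
per-frame magnitudes stay in the `ActivityMovie` and are what the local
synchrony index consumes.

Known behavior at very low baselines: a ≥ 4σ run of spikes on one pixel
(e.g. four spikes in three seconds at 0.05 Hz) is, by construction, phasic —
the detector flags statistically real excursions, not only waves. Such
micro-events become 1-pixel, few-frame clusters; the isolated-pixel discard
removes the single-voxel ones and the rest are visible in the wave table as
single-pixel-footprint "waves" (an optional area/duration filter can remove
them, off by default).

## Segmentation

A wave is any maximal cluster of phasic voxels connected in x, y and t.
Default connectivity is 26-neighborhood (8-connected in-frame, and the same
3×3 spatial neighborhood across adjacent frames), because diagonal
propagation between 1-s frames is routine at second-week wave speeds;
4-connected / no-temporal-diagonal variants are available. Clusters below
`min_pixels = 2` voxels — isolated active pixels with no active neighbor —
are discarded. Labeling is `scipy.ndimage.label` followed by a deterministic
renumbering in order of each component's first voxel under a t-major, then
y, then x scan, so identical input yields an identical matrix. The contract
is the partition, which the test suite checks voxel-for-voxel against an
independent union-find implementation on seeded random movies.

## Metrics: numerical choices

- **Speed.** The leading edge between frames t and t+1 is the set of pixels
  newly recruited at t+1 (the trailing edge never enters). Distances come
  from the Euclidean distance transform of the frame-t footprint. All edge
  distances across all frame pairs are pooled before averaging (a per-pair
  mean-of-means is available as an option). Single-frame waves have no
  speed (NaN, excluded from population means); a wave that never recruits a
  new pixel has speed 0. Note a discretization property relevant to
  benchmarks: a band translating d > 1 pixels per frame yields new pixels at
  distances 1..d (pooled mean (d+1)/2), and sub-pixel advances per frame
  register distance-1 recruitments only — the estimator is exactly unbiased
  at one pixel per frame.
- **Flow field.** Centers of mass are computed on binary footprints through
  3×3 correlation sums; frames where a pixel's 3×3 window contains no wave
  pixel contribute nothing to that pixel's displacement sum.
- **Direction classes.** Quadrants are half-open 90° bins centered on the
  cardinal axes; an angle exactly on a 45° boundary falls counterclockwise
  into the next bin. A zero mean vector leaves the wave unclassified and out
  of the NBI counts.
- **IBI.** The nasal/temporal split defaults to the grid's x center (the
  canonical optic-nerve position) and can be overridden; a centroid exactly
  on the split counts as nasal (deterministic, and measure-zero for
  continuous centroids).
- **LSI.** For each frame pair inside a wave, wavefront activity is the raw
  count mass on the newly recruited wave pixels at t+1; ahead-of-wavefront
  activity is the raw count mass on pixels active at t+1 but not at t and
  *not part of the wave at t+1*. Excluding only wave-members-at-t would put
  the wavefront itself in the denominator twice, capping the index at 0.5
  for any confined wave, so the wave's t+1 membership is excluded as the
  formula's intent requires. Count-weighted (not binary) activity is used
  throughout.
- **Frequency.** The per-pixel reading — each valid pixel's distinct-wave
  count per minute, averaged over pixels — is the primary statistic
  ("occurrence of waves per unit space"); the whole-retina count rate is
  reported alongside, and per-wave versus per-recording aggregation are both
  available in the summary. Per-hour binning assigns each wave to the hour
  containing its first frame.
- **Duration** is exactly `(t_end − t_start)·Δt`: a single-frame wave has
  duration 0. No inclusive +1 is applied.

## The simulator

Synthetic recordings emulate planar (or disc) waves crossing the array over
Poisson tonic background. Defaults are the package's study conditions:
32×32 grid at 87.5 µm, 1-s frames, 1 wave/min, 87.5 µm/s, 15-pixel-wide and
3-pixel-thick bands traveling 12 pixels, 20-Hz firing on wave pixels over
0.5-Hz tonic background, isotropic directions and unbiased initiation.
Why these values: the grid is the HD-MEA configuration; about one wave per
minute and ~100 µm/s are canonical first-week figures; 87.5 µm/s is exactly
one pixel per frame, where the EDT speed estimator is unbiased (see above);
band extents give per-wave areas around 1 mm² and durations around 10 s;
20 Hz front firing against 0.5 Hz tonic reflects burst-versus-baseline rates
in the source recordings.

Wave onsets follow a renewal process: gap = refractory + Exponential(mean =
period − refractory), period = 60/rate. The mean gap equals the period
*exactly*, so frequency and inter-wave-interval recovery are point
comparisons, while the refractory interval (wave length + 5 frames by
default) serializes waves in time and keeps ground truth unambiguous — a
deliberate idealization that also mirrors the refractoriness of real retinal
waves. A safety overlap check with redraw remains for non-default
geometries. Direction (over the four cardinal axes) and initiation half are
drawn independently so the two bias estimators can be validated separately;
`ahead_noise_ratio` injects Poisson activity two pixels ahead of each
advancing front with total expected mass equal to the ratio times the
front's, giving LSI the closed-form expectation 1/(1+ratio).

Developmental presets ('0wk' … '2wk') encode only the qualitative trends —
frequency and speed rising into the second week, area growing then
shrinking, duration peaking mid-timeline, a transient nasal propagation bias
at 1.5 weeks — and are for ordering tests and demonstrations, never
quantitative benchmarks.

What the simulator does **not** emulate: curved or spiraling trajectories,
wave-to-wave interactions and spatial refractoriness, amplitude adaptation,
electrode dropout or spike-sorting artifacts, and calcium indicator
dynamics. Passing the recovery benchmarks therefore shows the estimators
are correct for translating coherent wavefronts with Poisson statistics; it
does not certify accuracy on every real recording.

## Benchmark problem sizes

The verification suite uses: 100 random 20×20×50 movies for the flood-fill
oracle; 50 seeded 16×16×150 simulations for the conservation laws; two
12 000-s, 32×32 recordings (~400 mixed-direction waves and ~200 full-field
sweeps) for parameter recovery — frequency and pooled IWI within 10 %, mean
speed within 15 %, NBI and IBI within 0.05 of their generating values; and
paired 1 800-s recordings at 1× and 5× tonic rate for noise robustness
(ground-truth hit-rate drop ≤ 0.10). The full-field scenario exists because
there every wave crosses every pixel, making the generating per-pixel
frequency and IWI analytically known; in the mixed scenario the whole-retina
rate is the analytically known quantity.

## Known limitations

- Simultaneous waves that touch in any shared frame form, by definition, a
  single connected cluster and are reported as one wave; no probabilistic
  splitting is attempted.
- The burst detector needs recordings longer than its baseline window
  (60 s by default) and flags any sustained multi-sigma excursion, wave or
  not, at very low baselines.
- Speed estimates inherit the EDT discretization bias described above for
  waves advancing far from one pixel per frame; with 1-s frames and 87.5-µm
  pitch this is accurate through the first-week speed range and compresses
  the fastest second-week waves.
- The Maxwell-native reader is a best-effort adapter for the "Record Spikes
  Only" layout; the generic HDF5/CSV layouts are the supported interchange
  formats.
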