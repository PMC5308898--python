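# Methods

## Scope and data model

`burstnet` analyzes grayscale calcium-imaging movies of spontaneously
bursting neuronal networks. A movie is a `(time, height, width)` stack of
8-bit intensities at a nominal 20 frames/s; the analysis is designed around
movies resized to 128×128 pixels, where the default ROI lattice yields 196
signals, but every stage works at any resolution that fits at least three
ROIs. All stages are deterministic; the only randomness in the package
lives in the synthetic generator and the bootstrap, both seeded.

## Trace extraction and preprocessing

**ROI lattice.** The field of view is tiled with identical oval ROIs: an
`roi_size`×`roi_size` square (default 11) whose footprint is the inscribed
ellipse (pixel centers inside `((i-c)/r)^2 + ((j-c)/r)^2 <= 1` with
`r = roi_size/2`; the center pixel is always in). Top-left corners sit at
multiples of `spacing` (default 9, so adjacent ovals overlap by 2 px) while
the square fits in the frame. Each ROI's trace is the unweighted mean
intensity over its footprint, per frame.

**Smoothing.** A centered running mean of `round(window_s * fps)` frames
(default 1 s → 21 frames after forcing the count odd). At the trace ends
the full-width window is kept but shifted to stay inside the recording
rather than shrunk: a shrinking window leaves the terminal frames nearly
unsmoothed, and those high-variance frames generated spurious
above-threshold rising edges clustered at the movie ends. The shifted
window invents no values and keeps noise suppression uniform; its one
side effect is that the first and last half-window of output frames are
constant.

**ΔF/F.** Per ROI, `(F - F0)/F0` with `F0` the trace's 10th percentile.
A low percentile is robust when transients occupy a minority of frames
(bursting duty cycles here are well under 50% of frames at the baseline
value); a non-positive `F0` is an error naming the ROI rather than a
silent NaN.

## PCA signal/noise separation

The ROI×time ΔF/F matrix is decomposed by SVD with ROIs as observations:
each ROI trace is mean-centered over time (the removed means are folded
back into the signal matrix afterwards). Eigenvalues are the squared
singular values over `T-1`. The retained component count is the
scree-plot elbow **plus two**, capped at the ROI count; the elbow is found
by the triangle method — normalize both axes of the descending spectrum to
[0, 1] and take the point of maximum perpendicular distance from the chord
joining the first and last eigenvalues. The signal matrix is the
reconstruction from the retained components, the noise matrix is the
reconstruction from the rest, so `signal + noise` equals the input to
machine precision — this identity is asserted in the tests at a relative
error of 1e-8 and holds in practice at ~1e-15. A zero-variance input
degenerates to one retained component, an all-zero noise matrix and a
logged warning.

Whether ROIs or time points are the PCA observations only matters through
the centering; the per-ROI temporal centering used here keeps each trace's
own baseline out of the decomposition and makes the reconstruction
identity hold on the raw ΔF/F input.

## Burst detection

For each ROI, rising edges of the **signal** trace are candidate bursts:
local extrema are found by first-difference sign change, plateaus broken
at their first frame (zero first differences take the sign of the next
nonzero difference), and each local minimum is paired with the next local
maximum. An edge becomes a burst when its base-to-peak amplitude exceeds
`k_sigma` (default 1.96) times the standard deviation of the same ROI's
**noise** trace, computed over the full recording. If the noise trace has
zero variance the threshold falls back to an epsilon scaled by the trace
range, with a warning.

Events whose bases lie closer than `min_separation_s` (default 0.5 s) are
merged keeping the larger amplitude; this suppresses double-counted noisy
edges within one transient and can be disabled with 0.

The burst *position* is the base frame (rising-edge start): it is the most
noise-robust landmark and matches the base-to-peak amplitude definition.
Note that positions are measured on the smoothed trace and therefore lead
the raw-trace onset by about half the smoothing window (≈0.5 s at the
defaults); the lead is common to all bursts, so interval statistics are
unaffected, and ground-truth comparisons in the tests remove it as a
fixed constant.

## Burst catalog

Events from all ROIs are merged into distinct network burst positions by
greedy clustering: pool all events sorted by position; the earliest
unassigned event seeds an entry, which absorbs every unassigned event
within ±`window_s` (default 1 s) of the seed — at most one per ROI, the
nearest to the seed winning and the earlier winning ties. The entry's
representative time is the **median** of its assigned positions: with
~200 supporting ROIs the occasional ROI whose base slips a frame would
otherwise leave sub-frame wobble on the representative time, and the
median pins it to the consensus frame. Entries supported by fewer than
`min_support` (default 4%) of the ROIs are then discarded — strictly
"fewer than", so 8 of 196 ROIs (4.08%) survive while 7 (3.57%) do not —
ids are reassigned in time order and each ROI is re-described as its
ordered sequence of surviving entries. Filtering is idempotent.

The 4% filter is what protects the catalog from the detector's residual
false positives: the retained noise components can produce occasional
above-threshold edges in single ROIs, and those never reach 4% support at
the design geometry of 196 ROIs. At much smaller ROI counts (≲25) the
filter's absolute support floor drops to one ROI and loses this
protection — small-frame analyses should treat low-support entries with
suspicion.

## Network complexity

Nodes are the cataloged bursts; for every ROI, each consecutive pair
(X, Y) of its sequence adds the directed edge X→Y, deduplicated across
ROIs. With `E` edges, the canonical score is the mean of
`E / #{nodes with outdegree ≥ 1}` and `E / #{nodes with indegree ≥ 1}` —
the average out- and in-degree over non-terminal nodes. Identical
sequences give a chain and a score of exactly 1; ROIs sharing some but
not all bursts create nodes with more than one incoming or outgoing edge
and push the score above 1; parallel fully disjoint chains still score 1.

The phrase "ratio of nodes with more than one outgoing edge" admits a
second, literal reading — the *fraction* of such nodes — which is 0
rather than 1 for a chain and is inconsistent with a baseline of 1 for
uniform activity. The degree-ratio definition above reproduces the
baseline and every qualitative property expected of the statistic and is
the canonical one here; the fraction variant is implemented behind
`variant="fraction"` for comparison. A graph with no edges has no defined
score and is reported as not computable (`score=None`), never as 0 or 1.
The score is computed once per movie.

**Group statistics.** Complexity distributions are non-normal with unequal
variances, so groups are compared with the two-sample two-sided
Kolmogorov–Smirnov test (exact p-value when the combined sample size is
≤ 25, asymptotic otherwise; the regime is reported), and summarized as
median ± bootstrap SE (SD of medians over `n_boot` seeded resamples with
replacement, default 1000). Other metrics use a two-sided Student t-test,
paired or pooled-variance unpaired.

## Burst-train and synchrony metrics

* frequency: bursts per minute, `count / duration × 60`;
* I.C.V.: sample SD (n−1) of inter-burst intervals over their mean;
  undefined (NaN) below two intervals; a train is *rhythmic* when
  I.C.V. < 0.2, with the boundary value assigned to non-rhythmic;
* amplitude C.V.: sample SD of burst amplitudes over their mean;
* synchrony: zero-lag Pearson correlation for every unordered ROI pair of
  the ΔF/F traces, summarized by the mean over valid pairs; zero-variance
  traces are excluded and counted. "Cross-correlation" is taken at zero
  lag since network bursts are near-simultaneous across the field at
  20 frames/s; a max-over-±lags variant is available via `max_lag_s`.

The pipeline reports these per ROI (cellular analysis) and for the
network-level train formed by the filtered catalog entries (network
analysis), whose per-entry amplitude is the mean of the supporting events'
amplitudes.

## Synthetic movies

Pixel intensity is
`baseline × (1 + Σ_b A_b K(t − t_b)) + N(0, noise_sd)`, clipped to
[0, 255] and quantized by round-half-up to 8 bits (more than 10% of
samples out of range logs a warning). `K` is the difference of
exponentials `exp(-t/τ_decay) − exp(-t/τ_rise)` normalized to peak 1 —
the simplest kernel with the fast-rise/slow-decay morphology the detector
assumes.

Schedules are renewal processes: inter-burst intervals are
gamma-distributed with mean `mean_period` and CV `period_jitter_cv`
(exactly periodic at CV 0), floored at `2 τ_rise` so consecutive
transients remain resolvable. The gamma family is used because it is
strictly positive: the floor is essentially never active at realistic
jitter, so the realized interval CV equals the requested one — a
truncated normal at CV 0.5 would bias the realized CV to ≈0.45. Each
schedule begins a burn-in of 1.5 periods before frame 0 and bursts up to
5 decay constants before onset are rendered: the recording therefore opens
on the decay tail of a pre-onset burst, as a camera started mid-activity
would, rather than on a cold flat baseline (whose first rising edge has
no decay-pinned base and detects with several frames of jitter).
Ground-truth schedules list only bursts at t ≥ 0.

The field is partitioned into `n_subnetworks` contiguous regions —
near-equal vertical stripes by default (trivially checkable), or a seeded
Voronoi "blobs" mode. Each subnetwork follows its own schedule with rate
`(1 − shared_fraction)/mean_period` plus a schedule with rate
`shared_fraction/mean_period` common to all subnetworks, so every
subnetwork bursts at `1/mean_period` overall while sharing the requested
fraction of its burst times. Per-burst amplitudes are gamma with mean
`amplitude_mean` and CV `amplitude_cv` (a free knob; real burst-amplitude
distributions are not calibrated). Everything is driven by seed-sequence
streams spawned from the config seed: identical configs give bit-identical
movies.

Defaults (2-minute, 128×128, 20 fps movie): `mean_period` 10 s (≈6
bursts/min, a typical slow network-bursting rate), jitter CV 0.1,
`τ_rise` 0.2 s and `τ_decay` 2 s (GCaMP-like kinetics; the slow decay
also keeps the inter-burst trace strictly decaying, which pins the
detector's base landmark), amplitude 1.0 ΔF/F with CV 0.2, baseline 80
and noise SD 1.0 on the 8-bit scale (so transients span ~80 counts
against ~1 count of pixel noise, ~0.1 counts after ROI averaging).

**What the generator does not emulate:** motion, photobleaching,
photon-statistics (signal-dependent) noise, cell-body structure within a
subnetwork, conduction delays or any biophysical network mechanism —
subnetworks are ideal synchronous units. Passing tests therefore
demonstrate the correctness and calibration of the analysis chain on
movies satisfying its assumptions, not robustness to instrumental
artifacts of real recordings.

## Validation problem sizes

The test-suite runs the full chain on movies chosen to keep the suite
fast while leaving each check well-posed: one 2-minute 128×128 movie for
detector recovery (recall, timing within ±2 frames after removing the
fixed smoothing lead, full-field support); twenty 4-minute 128×128 movies
per jitter level (CV 0 and 0.5) for interval-CV recovery within 3
standard errors; ten 2-minute 64×64 movies per condition for the
complexity contrast across 1, 2 and 4 partially shared subnetworks
(30% sharing). Timing comparisons exclude bursts within one smoothing
window (1.05 s) of the recording ends, where transients are truncated.

## Known limitations

* Reported burst positions lead the raw-trace onset by ≈ half the
  smoothing window; downstream interval statistics are unaffected.
* The support filter loses its protective effect below ~25 ROIs (see
  above).
* The complexity score is computed per movie, not per time segment;
  slow drifts in network structure within a movie are averaged.
* ROIs are a fixed lattice, not cells; cell-resolved analysis requires
  user-supplied traces fed directly into the burst/catalog stages.
* The I.C.V. boundary value 0.2 is classified non-rhythmic by convention.
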