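# burstnet

Network-activity analysis for calcium-imaging movies of bursting neuronal
networks — stem-cell-derived "circuitoid" cultures and similar preparations
whose emergent activity resembles central-pattern-generator output — plus a
ground-truthed synthetic movie generator so that every stage of the analysis
can be validated without recordings.

Given an 8-bit grayscale movie stack, the pipeline:

1. tiles the field of view with 11×11-pixel oval ROIs at 9-pixel spacing
   (196 ROIs on a 128×128 frame) and extracts mean-intensity traces;
2. smooths each trace with a 1-s running mean and converts it to ΔF/F;
3. PCA-transforms the ROI×time matrix and splits it into a *signal* matrix
   (components up to two past the scree-plot elbow) and a *noise* matrix,
   with signal + noise equal to the input;
4. calls bursts per ROI as rising edges of the signal trace whose
   base-to-peak change exceeds 1.96 × SD of the same ROI's noise trace;
5. merges burst positions from all ROIs into a catalog of distinct network
   burst positions within ±1 s windows, discards entries supported by
   fewer than 4% of the ROIs, and re-describes each ROI as its sequence of
   catalog entries;
6. builds a directed graph — nodes are cataloged bursts, with an edge
   X→Y whenever burst Y immediately followed burst X in some ROI — and
   scores the movie's **network complexity**

   ```
   out_ratio = E / |{v : outdeg(v) ≥ 1}|
   in_ratio  = E / |{v : indeg(v) ≥ 1}|
   complexity = (out_ratio + in_ratio) / 2
   ```

   which is exactly 1 when all ROIs share one burst sequence (a chain) and
   rises as ROIs share some but not all bursts (segmentation);
7. computes the burst-train metrics used alongside the score: burst
   frequency (bursts/min), rhythmicity as the interval coefficient of
   variation (I.C.V. = SD/mean of inter-burst intervals, rhythmic when
   I.C.V. < 0.2), amplitude C.V., and network synchrony as the mean
   pairwise zero-lag Pearson correlation of ΔF/F traces. Groups of movies
   are compared with a two-sample Kolmogorov–Smirnov test for complexity
   (medians ± bootstrap SE) and Student t-tests for the other metrics.

The synthetic generator renders movies with known burst schedules
(controllable period jitter: rhythmic ↔ irregular), a spatial partition
into subnetworks sharing a controllable fraction of burst times
(synchronized ↔ segmented), difference-of-exponentials calcium transients
and Gaussian sensor noise — so detector recall, timing accuracy, parameter
recovery and the complexity score's discrimination of segmentation are all
tested against ground truth.

## Worked example

```python
import burstnet as bn

for label, k in [("synchronized (k=1)", 1), ("segmented (k=4)", 4)]:
    cfg = bn.SyntheticConfig(n_frames=2400, height=64, width=64, n_subnetworks=k,
                             shared_fraction=0.3 if k > 1 else 0.0,
                             period_jitter_cv=0.1, noise_sd=0.5, seed=1)
    movie, gt = bn.render_movie(cfg)
    res = bn.analyze_movie(movie, bn.PipelineConfig(fps=cfg.fps))
    n = res.network
    print(f"{label}: {res.counts['n_rois']} ROIs, "
          f"{res.counts['n_catalog_entries']} catalog bursts, "
          f"complexity {n['complexity']:.3f}, "
          f"frequency {n['frequency_bpm']:.2f} bursts/min, "
          f"I.C.V. {n['icv']:.3f} ({'rhythmic' if n['rhythmic'] else 'non-rhythmic'}), "
          f"synchrony {n['mean_pairwise_correlation']:.3f}")
```

prints

```
synchronized (k=1): 36 ROIs, 12 catalog bursts, complexity 1.000, frequency 6.00 bursts/min, I.C.V. 0.070 (rhythmic), synchrony 1.000
segmented (k=4): 36 ROIs, 24 catalog bursts, complexity 2.043, frequency 12.00 bursts/min, I.C.V. 0.734 (non-rhythmic), synchrony 0.669
```

The fully synchronized movie is scored at the complexity baseline of 1 —
every ROI carries the same burst sequence, so the burst graph is a chain —
and is classified rhythmic (I.C.V. < 0.2). Splitting the field into four
subnetworks that share only 30% of their bursts roughly doubles the
cataloged burst count (each subnetwork contributes its own positions),
drives the complexity score and the pooled-train I.C.V. up, and pulls the
mean pairwise correlation down.

The same analyses are available from the shell:

```sh
burstnet simulate --frames 2400 --size 128 --subnetworks 2 --shared-fraction 0.3 \
                  --seed 1 --out-dir run1
burstnet analyze run1/movie.tif --out-dir run1/results
burstnet compare --metric complexity --group-a a/complexity.csv --group-b b/complexity.csv
```

`analyze` writes per-stage CSVs (ΔF/F traces, burst events, catalog,
sequences, per-ROI metrics, complexity) plus a JSON manifest with the
configuration, per-stage counts and output checksums.

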