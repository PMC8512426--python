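# glovescan

Surface extraction from 6-DoF position-sensing-glove scans.

A sensing glove fitted with electromagnetic 6-DoF trackers lets a
clinician build a 3-D model of an object — in the motivating application,
a patient's foot during ankle-foot-orthosis assessment — simply by
feeling and manipulating it.  The tracker reports every pose sample
whether or not the fingers touch the object, so the raw stream mixes
on-surface contact points with transit motion through the air and
occasional gross glitches.  `glovescan` implements the validation method
that separates the two, plus a hardware-free simulator and an evaluation
suite, so the whole method runs and is testable on a desk.

## Method

All samples are first re-expressed in the frame of a reference sensor
rigidly mounted on the scanned object (`p_obj = Rᵀ(p − t_ref)`), which
cancels rigid object motion during the scan.

Filtering is anchored on one or more *reference points* — user-chosen
origins strictly inside the object, typically obtained by averaging the
glove-sensor positions over a short time window while holding the hand
around the target.  It proceeds in two stages, always over the entire
accumulated dataset:

1. **Volume minimization.**  Directions around each reference point are
   partitioned into solid angular sectors of user-chosen size Δ (an
   equal-angle azimuth × elevation grid).  Within each sector, only the
   sample with minimal radius `r = ‖p − p_ref‖` is retained.  The
   retained set encloses the reference point in the smallest volume —
   which, for a solid object scanned from outside, is the surface.  With
   several reference points, each sample is validated by the reference
   nearest to it and the result is the union over references.
2. **Outlier rejection.**  A lone sample in a sector is retained by
   stage 1 no matter how far out it is.  Stage 2 therefore re-bins the
   selected points on a coarser grid, computes each coarse sector's mean
   radius r̄, and drops every point with `r > (1 + τ)·r̄` (default
   τ = 0.20, i.e. 20% beyond the sector mean).

The angular size Δ trades feature resolution against selectivity: small
sectors preserve detail but retain more invalid data; large sectors
reject aggressively but blur small features.

## Worked example

Simulate a 30 000-sample glove scan of the built-in foot-like phantom
(tracker-grade noise of 1.4 mm RMS, half the samples recorded in
transit, 1% gross glitches), filter with two interior reference points
at 4° resolution, and evaluate against the analytic ground truth:

```bash
glovescan pipeline --shape foot_like --n-samples 30000 --seed 42 \
    --gross-outlier-rate 0.01 --angular-resolution 4 \
    --report-out report.json
```

prints

```json
{
  "seed": 42,
  "n_raw": 30000,
  "n_selected": 5392,
  "selectivity_percent": 17.973333333333333,
  "distance": {
    "count": 5392,
    "mean_mm": 2.789325234418036,
    "median_mm": 0.6749628448923772,
    "max_mm": 97.61933563996172
  },
  "confusion": {
    "kept_surface": 4764,
    "kept_nonsurface": 628,
    "dropped_surface": 10102,
    "dropped_nonsurface": 14506,
    "kept_nonsurface_rate": 0.04149596934055769
  }
}
```

Reading: of 30 000 raw samples, 5 392 survive (18% selectivity at 4°).
The retained cloud sits on average 2.8 mm from the true surface (median
0.7 mm — the mean is dominated by a small tail of leaked off-surface
points), and only 4.1% of the truly off-surface samples leak through the
filter.  Other subcommands: `simulate`, `filter`, `evaluate`, and
`sweep` (the selectivity-vs-resolution ladder); `glovescan --help` lists
all flags.

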