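# featrack

Feature-assisted multi-object tracking for dense cell collectives.

Classical cell trackers link detections between frames by centroid
proximity, which collapses as soon as cells move further than their own
spacing between frames — the everyday regime of dense, motile bacterial
monolayers, swarming colonies and growing microcolonies.  `featrack` links
objects using *everything* a segmenter measures about them — position,
length, orientation, fluorescence intensity — combined automatically, with
no manual feature weighting, and tells you up front how reliable the
resulting tracks will be.

The statistical core models an object's movement through the
N-dimensional feature space as a Gaussian random walk,
x_{t+1} = x_t + ΔX_t with ΔX_t ~ N(μ_t, Σ_t(Δx)).  From the fitted
statistics the package derives:

* **trackability** — the identity information available per object and
  frame pair, in bits:

  r_t = ½·log₂(|Σ_t(x)|/|Σ_t(Δx)|) + (N/2)·log₂(6πe) − log₂(n_o,t)

  where Σ_t(x) is the frame-wide feature covariance (the dynamic range the
  objects occupy) and n_o,t the object count;

* **feature normalization** — candidate links are scored by the
  Mahalanobis norm of their whitened displacement, L⁻¹(Δx − μ_t), so every
  feature contributes equitable, isotropic variation;

* an **adaptive threshold** β_t, derived from a single user threshold P as
  the score radius at which the expected number of spurious competitors
  reaches P — lenient when information is plentiful, strict when it is
  scarce.

Around this core the package provides a two-stage tracker (training pass,
model-based assignment, gap bridging with interpolated entries), division
detection that assigns daughter cells to mothers with the same machinery,
a self-propelled-rod (SPR) simulator that generates ground-truthed
synthetic collectives for validation, and link-level F1 benchmarking with
threshold sweeps and feature ablations.  See `docs/methods.md` for the
model details and design choices.

## Worked example

Simulate a dense collective of 100 motile rods (packing fraction ≈ 0.25,
baseline measurement noise, one frame every 10 time units — so rods travel
roughly twice their spacing between frames), track it, and compare feature
sets:

```python
import numpy as np
from featrack import (SimConfig, simulate, TrackerConfig, track_dataset,
                      compare_links, sweep_threshold)

ds = simulate(SimConfig(n_rods=100, A=1430.0, dT=10.0, n_frames=20, seed=42))

tracks, links, report = track_dataset(ds.frames, ds.spec,
                                      TrackerConfig(P=1.0, F=0.5, max_gap=0))
print(f"tracks: {tracks.n_tracks}, accepted links: {len(links)}")
print(f"mean trackability: {np.mean(report.r):.2f} bits/object")
cmp = compare_links(links, ds.gt_links)
print(f"all features:   TP={cmp.TP} FP={cmp.FP} FN={cmp.FN} F1={cmp.f1:.3f}")

for feats in (("x", "y"), None):          # centroids only, then every feature
    sw = sweep_threshold(ds, TrackerConfig(features_used=feats, max_gap=0))
    label = "centroids" if feats else "all features"
    print(f"sweep {label:12s}: max F1 = {sw.max_f1:.3f} at P = {sw.argmax_P:g}"
          f" ({sw.best.errors} link errors)")
```

which prints:

```
tracks: 206, accepted links: 1794
mean trackability: 15.17 bits/object
all features:   TP=1476 FP=318 FN=424 F1=0.799
sweep centroids   : max F1 = 0.005 at P = 1 (3313 link errors)
sweep all features: max F1 = 0.799 at P = 1 (742 link errors)
```

Read: each object carries ~15 bits of identity information per frame pair
against the log₂(100) ≈ 6.6 bits needed to single it out, but almost none
of it lives in the centroids — position-only tracking recovers essentially
nothing (F1 = 0.005) in this fast-dense regime, while the full feature set
recovers four fifths of all links and makes 4.5-fold fewer errors.  The
trackability report (`report.r` per frame, with low-information frames
flagged) predicts this without any ground truth.

The same pipeline is scriptable from the shell:

```bash
featrack simulate --config sim.yaml --seed 1 --out data/run1
featrack track --features data/run1/features.csv --spec data/run1/spec.yaml \
               --P 0.05 --F 0.5 --use x,y,length,intensity --out out/run1
featrack sweep --dataset data/run1 --grid log:1e-4:1:13 --out sweep.csv
featrack divisions --tracks out/run1/tracks.csv --spec data/run1/spec.yaml \
                   --out lineage.csv
featrack batch --config run.yaml --out batch/ data/run1 data/run2
```

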