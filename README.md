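# wormquant

Automated *Caenorhabditis elegans* phenotyping from plate images and
videos. The package quantifies four classic phenotypes from a
dissecting-scope imaging rig (8-bit grayscale stills and short videos,
~20 µm/px):

- **lifespan** — counts *moving* (living) worms from two scans of the
  same well taken ~2 minutes apart, then turns daily counts into a
  survival curve and mean lifespan;
- **locomotion** — tracks every moving worm through a 30-s video and
  reports per-track and population mean velocity (µm/s);
- **length** — measures body length from a still image by tracing the
  medial skeleton of each worm silhouette;
- **eggs** — counts eggs on a plate with a multi-threshold detector
  that survives worm-track scars, debris, and touching egg clusters.

A fifth module, the **simulator**, generates the validation data: videos
of sinusoidal virtual worms gliding at exactly known constant speeds,
still plates of worms with analytically known arc length, egg plates
with known counts, and time-lapse pairs with known numbers of movers —
each with a ground-truth manifest, so every engine is testable against
truth known by construction.

## Methods in brief

All segmentation uses Bradley-style adaptive local-mean thresholding
(foreground iff intensity < local mean × (1 − offset)), which tolerates
shadowed plates and illumination gradients. Moving-worm counting
binarizes |scan₁ − scan₂|, flags a worm-sized region of scan 2 as
moving when enough changed pixels fall inside it, and recovers movers
hidden against large dark objects from the difference image alone.
Daily counts are made monotone with the step-wise decrease filter
(right-to-left running maximum) before survival statistics; deaths on
day *t* are count(*t*−1) − count(*t*) and mean lifespan is the
death-weighted mean death day (day 0 = first day of adulthood).

Tracking associates per-frame centroids greedily (nearest centroid,
gated by step size and relative area change); a track ends at a
collision, at the frame boundary, or at video end, and trails are
smoothed with piecewise cubic least-squares (Bezier) fits before the
mean velocity = path length / elapsed time is computed. Body length is
the arc length of the branch-free skeleton curve (a branched skeleton
means a worm touching an egg or debris and is rejected, not
mismeasured), corrected for the tip pixels lost to thinning. Egg
counting learns single-egg priors from isolated eggs (edge detection →
gap/hole filling → shape filter), binarizes the image at ≥ 10 gray
levels (default 30…230 step 10), keeps egg-shaped blobs at each level,
splits clumps by area multiples, and clusters detections across levels
so each spatial cluster seen at ≥ 3 distinct levels counts once.

See `docs/methods.md` for the full model, parameter, and limitation
notes.

## Worked example

Simulate a two-cohort video (five worms at 1 px/frame, five at
0.25 px/frame, 7 fps) and analyze it:

```sh
$ wormquant sim video --seed 11 --out demo/vid --speeds 1.0x5,0.25x5 --n-frames 140
wrote 140 frames and manifest to demo/vid
$ wormquant locomotion --video demo/vid --out demo/loco
10 tracks; mean velocity 87.5 um/s
```

All ten worms are recovered as distinct tracks. At 7 fps and 20 µm/px,
1 px/frame is 140 µm/s and 0.25 px/frame is 35 µm/s; the population
mean over the two five-worm cohorts is (140 + 35)/2 = 87.5 µm/s, which
is what the tracker reports. `demo/loco/` also holds per-track
velocities, histogram/cumulative-distribution tables, a JSON-lines
track file, and an overlay PNG.

Egg counting against a known plate:

```sh
$ wormquant sim egg-plate --seed 5 --n-eggs 30 --out demo/eggs
wrote egg plate with 30 eggs to demo/eggs
$ wormquant egg --image demo/eggs/plate.png --worms 10 --minutes 90
29 eggs
egg laying rate: 1.93 eggs/worm/hr
```

29 of the 30 rendered eggs are found (one is hidden under simulated
debris); the rate line is the 90-minute assay arithmetic for a
10-worm well. Moving-worm counting on a simulated time-lapse pair:

```sh
$ wormquant sim lifespan-pair --seed 2 --n-moving 5 --n-still 3 --out demo/pair
$ wormquant lifespan count --img1 demo/pair/scan1.png --img2 demo/pair/scan2.png
well1 day 0: 5 moving worms
```

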