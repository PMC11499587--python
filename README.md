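# plotpheno

A toolkit for plot-level phenotyping of field trials from UAV orthomosaics:

- **Synthetic field simulator** — renders axis-misaligned grids of textured
  plots with exact ground truth (plot boxes, panicle instances with angle
  classes, per-plot heading/maturity calendars), so the whole pipeline is
  testable without field imagery.
- **Grid segmentation (Plot-Seg style)** — orientation estimation from the
  excess-green index, rotation to axis alignment, 1600 px tiling with 1/4
  overlap, per-tile plot detection (pluggable; a classical
  threshold-and-morphology baseline is included), cross-tile merging of
  detections with >60% overlap, row/column grid-line fitting through the
  detected centroids, and completion of missed plots from line
  intersections with mean-size boundaries.
- **Growth staging** — assignment of acquisition days to thirds of the
  full-heading-to-maturity interval, and heading-duration (10%→80%
  heading) from heading-ratio time series.
- **Panicle quantification** — panicle counts and panicle number per unit
  area (PNpA) from detections over fixed crops, the traditional 6-plant
  sampling estimator, and the 4-class panicle-angle scheme (0°/15°/45°/90°).
- **Evaluation suite** — Euclidean distance, IoU (boxes or masks), greedy
  detection matching, precision/recall, AP/AR at fixed IoU thresholds,
  R²/RMSE/rRMSE, confusion-matrix metrics, relative-improvement
  arithmetic, Wilcoxon rank-sum sampling-stability reports, and
  grid-vs-truth agreement.
- **Flight geometry** — ground sample distance from camera specs and
  areal coverage-rate ratios from fields of view.

## CLI

```sh
plotpheno simulate --rows 4 --cols 4 --gsd 1.9 --rotation 5 --seed 1 --out runs/sim
plotpheno segment --mosaic runs/sim/mosaic.png --tile-size 1600 --overlap 0.25 \
    --merge-threshold 0.6 --out runs/seg
plotpheno stage --calendar runs/sim/calendar.csv --acq-day 98 --acq-day 104 --out stages.csv
plotpheno count --detections panicles.json --crop-px 700 --gsd 1.9 --out pnpa.csv
plotpheno evaluate --pred pred.json --truth truth.json --iou 0.5 --iou 0.75 --out metrics.json
plotpheno plan gsd --camera p1 --altitude 15
plotpheno plan coverage --fov-a 63.5 --fov-b 30.4
plotpheno run --config cfg.yaml --seed 1 --out runs/full   # simulate→segment→stage→count→evaluate
```

Annotations are exchanged as COCO instance JSON (bbox + polygon
segmentation), COCO results lists, or LabelMe JSON; calendars and tabular
outputs are plain CSV; configuration is a single YAML file
(`plotpheno.config.RunConfig`) whose defaults follow the published pipeline
values (1600 px tiles, 25% overlap, 60% merge threshold, 700/400 px crops,
1.9 mm/px).

## Layout

```
src/plotpheno/
  simulate.py   # synthetic fields + truth + truth-backed tile detector
  mosaic.py     # affine transforms, orientation, rotation, tiling
  detect.py     # detection types, baseline detector, COCO/LabelMe IO
  gridseg.py    # merge, cluster, line fit, grid completion, segment_plots
  staging.py    # heading-to-maturity thirds, heading duration
  panicles.py   # counts, PNpA, angle classes
  metrics.py    # the full evaluation suite
  flight.py     # GSD and coverage-rate arithmetic
  config.py     # YAML run configuration
  cli.py        # click CLI
```
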