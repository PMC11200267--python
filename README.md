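# tasselkit

Tassel-state assessment for large UAV maize-canopy frames.

Large UAV frames (8,192 × 5,460 px at 0.25 cm/px) cannot be fed to a
detector directly; `tasselkit` implements the full surrounding pipeline:

- **geometry** — center-anchored blocking patterns (2×2 and 3×3 overlapping,
  full non-overlapping grid), generic sliding windows, and GSD-based ground
  footprint arithmetic.
- **annotations** — YOLO TXT I/O, standardization of Tassel-N/S boxes to
  fixed squares (default 140 px), the box-size sweep harness, dataset
  statistics (area, length–width ratio, category proportions), block-level
  label cropping, and seeded 8:1:1 splits.
- **augmentation** — rotation, random cropping, brightness, shadow, and
  chromatic adjustment, all transforming boxes with the image under seeded
  randomness.
- **detector** — a pluggable detection contract: import/export of 6-column
  detection files, confidence screening, and a truth-conditioned mock
  detector with controllable miss rate, a radial miss-rate slope (a
  perspective-distortion surrogate), category confusion, jitter, and false
  positives.
- **fusion** — remapping block-local detections to frame coordinates and
  category-wise single-linkage merging of redundant objects at a 50-px
  radius (greedy variant behind a flag).
- **metrics** — IoU, greedy confidence-ordered matching, precision/recall,
  all-points-interpolated AP and mAP@0.5, plus count-level ED / ACC / MDR /
  RMSE / MAE / MPAE with their algebraic identities enforced.
- **synthetic** — deterministic schematic maize scenes (jittered 25 cm /
  60 cm plant grid, stage-dependent category mixtures, female/male row
  structure, radial elongation) and raster-free annotation fixtures.
- **pipeline / cli** — the end-to-end study: generate → block → detect →
  fuse → evaluate, per growth stage and per blocking pattern.

## CLI

```bash
tasselkit generate --out scenes/ --stage spikelet --width 2048 --height 2048 --seed 1
tasselkit block --pattern 1 --out plan/            # 8192x5460 defaults
tasselkit detect --labels scenes/spikelet_0001.txt --pattern 1 \
    --width 2048 --height 2048 --block-side 512 --overlap 100 --out dets/
tasselkit fuse --dets dets/ --out fused.csv
tasselkit evaluate --counts counts.csv
tasselkit run-all --config run.yaml --out report/ --seed 1
```

`tasselkit standardize`, `sweep`, `augment`, and `stats` cover the
annotation-side workflow. Exit codes: 0 ok, 2 config error, 3 data error.

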