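# flockkit

Group-movement analytics for multi-member GPS tracks. The package turns raw
tracks (GPX or CSV) into rest-free movement periods, re-expresses every
member's position in a path-adapted coordinate system (lateral offset from
the group's smoothed path, and along-path offset from the centroid), extracts
a catalog of individual- and group-level movement features, and evaluates how
well group-level features predict an external performance score via
leave-one-out regression with stability-assessed feature selection.

## Modules

| module | what it does |
|---|---|
| `flock.trajectory_io` | read GPX/CSV, project to UTM, spline-smooth, resample onto a uniform grid |
| `flock.utm` | WGS84 ↔ UTM conversion (Karney–Krüger series, no external geodesy dependency) |
| `flock.segmentation` | individual/group rest detection, trimmed movement periods |
| `flock.pacs` | path-adapted coordinate transform + instantaneous-heading baseline |
| `flock.kinematics` | speed/acceleration series, group spread and cross-member variance |
| `flock.spatial` | stretch index, convex hull, hull-clipped Voronoi, length/width, SEI, cross-period consistency |
| `flock.grouping` | DBSCAN/HDBSCAN frame clustering, outliers, consistency, nearest-neighbour metrics |
| `flock.leadership` | directional-correlation time delays, hierarchy graphs, HCS ratios, instability |
| `flock.regularity` | location/series entropy, rolling VAR/VARX forecast error |
| `flock.doctrine` | pace/spacing/break-regularity/column-length compliance metrics |
| `flock.synthetic` | seeded march simulator with ground truth for every feature family |
| `flock.prediction` | feature table assembly, LOO regression, Jaccard stability, residual diagnostics |

## CLI

```sh
flock simulate --seed 1 --n-members 6 --out traj.csv --truth truth.json
flock ingest   --input tracks/ --format gpx --dt 1 --out traj.csv
flock segment  --traj traj.csv --area 100 --min-dur 120 --trim 30 --out periods.json
flock pacs     --traj traj.csv --periods periods.json --out pacs.csv
flock predict  --features features.csv --scores scores.csv --out report.json
```

`flock pacs` accepts `--route route.csv` to transform against a
pre-determined path instead of the fitted centroid path. The scores CSV for
`flock predict` has columns `group_id,score`.

## Notes

- Default grid step is 1 s; spline smoothing penalties default to
  generalized cross-validation. Both are configurable.
- Rest detection uses a bounding-disc criterion (100 m² ≈ 11.28 m diameter,
  ≥ 120 s) per member; group rests require a common instant at which every
  member is resting and span earliest arrival to latest departure. Movement
  periods trim 30 s at each boundary; with no rests the span is split in half.
- Acceleration features are flagged low-confidence: consumer GPS is too
  noisy to characterize acceleration precisely.
- The feature-selection slot in `flock.prediction.loo_evaluate` is
  pluggable; the default is L1-penalized regression with inner
  cross-validation (leave-one-out for small n, which also makes selection
  invariant to row order).
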