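# somatomap

Surface-based somatotopic mapping and remapping analysis, exercised end to
end on a synthetic cortical-patch cohort. The package implements:

- **`somatomap.synthetic`** — a flat triangulated patch standing in for the
  postcentral strip, band-shaped hand/face ROIs with a border anchor,
  per-subject ground-truth Gaussian activation blobs with an upright facial
  gradient (forehead nearest the hand border), block-design time series
  (8 s blocks, 4 repeats per condition, 5 baseline blocks, 3 runs,
  TR 1.45 s), and a Table-1-style questionnaire table. The whole cohort is a
  pure function of `(CohortSpec, seed)`.
- **`somatomap.glm`** — double-gamma HRF, boxcar-convolved design matrices
  with constant/drift nuisance (optional temporal derivatives), per-vertex
  OLS, and fixed-effects averaging into `beta_mean` / `t_like` maps.
- **`somatomap.topography`** — winner-takes-all maps, triangle-edge
  connected clusters, area-weighted pooled centres of gravity, graph
  geodesic distances (Dijkstra on edge lengths) signed against the
  hand-border anchor (medial positive), and surface-coverage laterality
  `(deprived − intact)/(deprived + intact)`.
- **`somatomap.overlap`** — per-condition Jaccard similarity between winner
  maps and leave-self-out group averaging.
- **`somatomap.rsa`** — multidimensional noise normalisation (run-averaged
  residual covariance shrunk toward its diagonal with an analytic optimal
  lambda), unbiased crossnobis RDMs over all ordered run pairs (normalised
  by vertex count), scalar dissimilarity summaries and classical MDS.
- **`somatomap.phantom`** — questionnaire frequency recoding
  (`6 − table_code`), chronic PLS/PLP scores (intensity / recoded
  frequency, 1 decimal, half away from zero), PLP classification, and
  demographics; a worked-example table ships with the package
  (`load_reference_table()`).
- **`somatomap.stats` / `somatomap.pipeline` / `somatomap.cli`** —
  3-SD outlier flagging (report, never remove), permutation surrogates for
  the group × hemisphere interaction, and the end-to-end driver with TSV /
  GIFTI / NIfTI outputs, a run log and a config snapshot.

## CLI

Each stage is a subcommand taking `--config <yaml> --seed <int> --out <dir>
--verbose`; later stages run everything before them:

```bash
somatomap simulate  --seed 1 --out out/      # cohort + participants.tsv
somatomap topography --seed 1 --out out/     # WTA, distances, laterality
somatomap report    --seed 1 --out out/      # full pipeline + permutation stats
somatomap table-scores                        # score the packaged reference table
```

A config file mirrors `PipelineConfig` (see `somatomap/config.py`); omit it
to use the small default cohort. All outputs are reproducible byte-for-byte
from `(config, seed)`.

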