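# stmorph

ST-segment morphology delineation of ambulatory ECG via orthogonal
transformations.

The package builds two orthonormal bases over a 32-sample ST window
(F+40 ms to F+160 ms after each beat's fiducial point):

* **LPT** — discretized, Gram–Schmidt-orthonormalized Legendre polynomials,
  whose first three basis functions (constant, linear, quadratic) map
  directly onto the clinically meaningful ST morphology categories: level
  shift, slope change, and scooping.
* **KLT** — eigenvectors of a robust covariance matrix formed from
  interval-class means of ST pattern vectors, ordered by descending
  eigenvalue.

From preprocessed ECG it derives per-beat feature time series — heart
rate, rate-adjusted ST level and slope, nine raw and std-normalized
coefficients per transform, residual reconstruction errors, and a compound
Mahalanobis distance to the first beat — and evaluates how well episode-mean
feature vectors separate ischaemic from heart-rate-related ST episodes
under repeated stratified cross-validation.

A fully seeded synthetic ECG generator (parametric ST morphology,
triangular episodes, T-wave encroachment, axis shifts, wander, noise,
ectopic beats) makes the whole pipeline testable without any external data.

## Layout

| module | contents |
| --- | --- |
| `stmorph.basis` | Legendre recurrence, monomial matrix, weighted modified Gram–Schmidt, orthonormality diagnostics |
| `stmorph.klt` | outlier rejection, interval classes, robust covariance, eigenbasis, coefficient stds |
| `stmorph.preprocess` | 55 Hz zero-phase Butterworth, PQ-flatness isoelectric estimation, cubic-spline baseline removal, abnormal-beat exclusion |
| `stmorph.delineate` | heart rate, ST level/slope, pattern-vector extraction, projections, normalization, residuals, Mahalanobis series |
| `stmorph.synth` | synthetic beats, records, episodes and training corpora |
| `stmorph.evaluate` | episode mean features, Se/Sp/CA, classifier roster, repeated stratified CV |
| `stmorph.benchmark` | end-to-end seeded classification benchmark |
| `stmorph.io` | TSV/JSON formats, NPZ record bundle, minimal WFDB (format 16) |
| `stmorph.cli` | `stmorph` command-line interface |

All amplitudes are microvolts internally; on-disk headers record the
conventional display scale (20 units = 100 µV).

## CLI

```sh
stmorph basis --kind lpt --samples 32 --out lpt.tsv
stmorph train-klt --intervals 40 20 60 --seed 1 --out klt.json --norm-out norm.json
stmorph synth --config synth.yaml --out record.npz --episodes episodes.json
stmorph preprocess --record record.npz --out clean.npz
stmorph delineate --record clean.npz --lpt lpt.tsv --klt klt.json --norm norm.json --out features.tsv
stmorph evaluate --features features.tsv --episodes episodes.json --transform klt --subset 1-8 --classifier 3nn --out results.json
```

A `synth.yaml` mirrors `SyntheticRecordConfig`, e.g.:

```yaml
duration_s: 120.0
leads: 1
seed: 5
noise_rms: 8.0
episodes:
  - kind: ischaemic
    onset_s: 20.0
    extremum_s: 50.0
    offset_s: 80.0
    extremum_magnitude: -180.0
    affected_leads: [0]
```

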