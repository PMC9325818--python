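# Run configuration schema

Every CLI command accepts `--config FILE` (YAML). The file is validated
against this schema before any compute runs; unknown keys are rejected
with a non-zero exit. Command-line flags override config values.

```yaml
# top level
dataset: path/to/dataset.csv        # str
output_dir: runs/exp1               # str
seed: 0                             # int; fans out to per-stage seeds
split_fractions: [0.7, 0.8, 0.9]    # date-rank cut points

gcnn:
  conv_sizes: [64, 64, 64]   # three conv unit widths
  fc_size: 128               # saliency tensor / fingerprint width
  l2: 0.0005                 # weight penalty coefficient
  epochs: 50
  learning_rate: 0.001
  batch_size: 64
  head_size: 64              # classifier hidden layer width

saliency:
  k_max: 5                   # max salient neighborhoods per molecule
  top_m: 1                   # winners counted per fingerprint column
  decay: 0.8                 # highlight decay per bond
  decay_mode: multiplicative # or "additive"

clustering:
  d_c_percentile: 2.0        # DPC cutoff: percentile of positive distances
  min_points: 8              # below this, k-means (k=2) fallback
  n_bits: 2048               # fragment ECFP4 length

search:
  iterations: 10
  samples: 80                # Gaussian draws per iteration
  sigma: 0.2                 # relative perturbation width

generator:
  n: 600
  motif: "S(=O)(=O)N"
  label_noise: 0.0
  drift: 1.0
  active_fraction: 0.5
```

Dataset CSVs require the columns `id`, `smiles`, `label` (0/1), and
`date` (ISO-8601). Every command writes a `manifest.json` beside its
artifacts recording the command, package version, seed, config, and
SHA-256 checksums of its inputs; outputs are never overwritten without
`--force`.
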