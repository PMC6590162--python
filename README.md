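# hetci

Confidence intervals for the between-study variance (τ²) in
random-effects meta-analysis, built around the Q statistic:

* **Q-profile** — test inversion of the generalized Q statistic
  `Q(τ²) = Σ (yᵢ − μ̂)² / (τ² + vᵢ)` against the χ²ₖ₋₁ reference,
  with the Paule–Mandel point estimate (the root of `Q(τ²) = k − 1`).
* **GENQ** — test inversion of the exact distribution of a weighted
  Q statistic with fixed positive weights (inverse-variance or
  inverse-standard-error), a weighted sum of independent χ²(1)
  variables evaluated through Ruben/Farebrother's mixture series with
  an Imhof-integration fallback.

Both methods report an explicit interval status (`regular`,
`lower_truncated`, `null_set`); the empty interval counts as
non-covering in all coverage accounting.

The package also ships the machinery used to study these methods when
their normality/known-variance assumptions fail for log odds ratios
from 2×2 tables:

* `hetci.effects` — continuity-corrected (+0.5 to every cell) log odds
  ratios, estimated variances, zero-cell counting.
* `hetci.simulate` — binomial 2×2-table meta-analysis generator
  (θᵢ ~ N(μ, τ²), πᴱ from θᵢ and πᶜ), the (30, 50, 100, 150, 300)
  group-size pattern, estimated vs enumeration-exact variance modes,
  and an ideal-normal mode for exactness checks.
* `hetci.exact` — enumeration-exact mean and true sampling variance of
  the corrected log odds ratio over all (nᴱ+1)(nᶜ+1) tables.
* `hetci.experiments` — coverage/width experiments, zero-cell subset
  analyses, generalized-Q distribution diagnostics, coverage grids,
  bias–coverage correlation, and preset condition grids.
* `hetci.io` / `hetci.cli` — study-table I/O, YAML condition grids,
  run manifests, command-line entry points.

## CLI

```sh
# τ² CI from a study CSV (columns x_e,n_e,x_c,n_c or y,v)
hetci ci studies.csv --method qprofile --level 0.95
hetci ci studies.csv --method genq --weights se

# exact moments of the corrected log OR by full enumeration
hetci truevar --n-e 30 --n-c 30 --theta 0.5 --pi-c 0.1

# coverage experiment over a YAML grid or a named preset
hetci simulate --preset study2 --reps 200 --seed 1 --out coverage.csv
hetci simulate --config grid.yaml --seed 1 --out coverage.csv

# distribution of the generalized Q statistic at the true τ²
hetci qdist --pi-c 0.1 --k 5 --size 30 --reps 5000 --seed 1 --out q.csv

# coverage maps over preset (k, π_c) or (size, π_c) grids
hetci grid --preset heatmap_k_pi --reps 500 --seed 1 --out heatmap.csv
```

Grid configs are YAML mappings with explicit lists, e.g.

```yaml
mu: [0.0]
tau: [0.0, 0.1, 0.2, 0.3, 0.4, 0.5]
pi_c: [0.1, 0.5]
k: [5, 40, 160]
sizes: [30]        # omit to use the 30/50/100/150/300 pattern
reps: 3000
seed: 7
variance_mode: exact
```

Every results CSV is written with a `.manifest.yaml` beside it
recording seed, grid and version; outputs are bit-identical given the
same seed and are invariant to `--workers`.

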