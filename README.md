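# stromalyzer

Semi-automatic **tumor-stroma ratio (TSR)** quantification for H&E-stained
rectal-cancer histology, with the full evaluation harness used to compare
automated scoring against expert observers.

The TSR is a prognostic marker: tumors with abundant intratumoral stroma
carry a worse prognosis. Inside an expert-selected circular *hot-spot*
(1.8 mm diameter, tumor at all borders) the ratio is

```
TSR = 100% × stroma area / (tumor area + stroma area)
```

with all other tissue (lumen, necrosis, muscle, ...) excluded. Patients
are split at a cutoff — 50% by convention, or the cohort median of the
automated scores — into *stroma-low* (TSR ≤ cutoff) and *stroma-high*
(TSR > cutoff), and the groups are compared for disease-specific (DSS) and
disease-free (DFS) survival.

The package provides, for pathologists' computational collaborators and
methods researchers:

- **`fixtures`** — synthetic pseudo-histology tiles with ground-truth
  masks, circular hot-spot scenes with known true TSR, and simulated
  cohorts whose survival depends on the stroma group. Everything else is
  testable against these with no downloads.
- **`stainnorm`** — Reinhard-style LAB channel-statistics and
  Macenko-style stain-deconvolution normalization behind one interface.
- **`segmenter`** — a patch-based 9-class tissue classifier (256×256
  patches, dense maps by central-block painting), with slide-level
  cross-validated evaluation that prevents within-slide leakage.
- **`hotspot`** — mm↔pixel geometry (1.8 mm at 0.455 µm/px ≈ 4000 px),
  pixel-center circle masks, the TSR formula with class exclusion, and
  dichotomization (inclusive-low; fixed or median cutoff).
- **`concordance`** — 2×2 cross-tabulations, unweighted Cohen's kappa,
  intraclass correlation (absolute-agreement default), rank tests.
- **`survival`** — Kaplan–Meier/log-rank, 5-year rates, and uni-/multi-
  variate Cox regression with the conventional grouped covariate coding.
- **`stromalyzer`** CLI — `simulate`, `train`, `segment`, `tsr`, `agree`,
  `survival`, `run-all`.

## Worked example

Simulate a 129-patient cohort, score agreement between the visual
consensus and the automated score at the median cutoff, and test the
prognostic value:

```bash
$ stromalyzer simulate --n 129 --seed 7 --out cohort.csv
$ stromalyzer agree --cohort cohort.csv --a consensus_label --b auto_label_median
{
  "counts": [[61, 11], [4, 53]],
  "n": 129,
  "concordant": 114,
  "kappa": 0.767,
  ...
}
```

114 of 129 patients land in the same stroma group under both scorings;
kappa 0.767 is the chance-corrected agreement. Survival for the automated
grouping:

```bash
$ stromalyzer survival --cohort cohort.csv --group auto_label_median --endpoint dss
{
  "logrank_p": 0.00013,
  "five_year_rates": {"stroma-low": 70.4, "stroma-high": 40.6},
  "univariate":  {"stroma_high": {"HR": 2.481, "ci_low": 1.533, "ci_high": 4.016, "p": 0.0002}},
  ...
}
```

Stroma-high patients die of disease sooner (5-year DSS 40.6% vs 70.4%,
univariate HR 2.48) — as built into this simulated cohort's hazard model.

The imaging path, in Python:

```python
import numpy as np, stromalyzer as st
from stromalyzer.hotspot import attach_label

tile, true_tsr = st.generate_hotspot_scene(65, 512, 0.1, seed=5)  # true 65.0
model = st.train_segmenter(
    [st.generate_tile({int(c)}, 384, 0.455, seed=s * 16 + int(c))
     for s in range(2) for c in st.TISSUE_CLASSES],
    st.TrainConfig(epochs=30), seed=0)
seg = st.segment_raster(model, tile.image, spacing_um=0.455)
circle = st.circle_mask(seg.labels.shape, (256, 256), 512)
print(attach_label(st.compute_tsr(seg.labels, circle), cutoff=50))
# TsrResult(stroma_px=104172, tumor_px=59592, excluded_px=42128,
#           tsr_percent=63.61..., label='stroma-high', cutoff_used=50.0)
```

The automated TSR (63.6%) recovers the scene's true 65.0% to within two
points; the excluded pixels are the other-tissue share and background.

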