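# baldeconv

Reference-based cell-type deconvolution of DNA methylation profiles from
mixed-cell samples, built around the cell types of bronchoalveolar lavage
(BAL): alveolar macrophages, granulocytes, lymphocytes and alveolar
epithelial cells (AEC).

## The problem

Epigenome-wide association studies on mixed tissues are confounded by
cell-type composition: each cell type carries its own methylation profile,
so a shift in composition masquerades as differential methylation. The
standard remedy is reference-based deconvolution: measure beta values
(per-CpG methylation fractions, β ∈ [0, 1]) for purified constituent cell
types, find CpG probes whose methylation discriminates each type from the
rest, and estimate each mixed sample's composition from those probes.

`baldeconv` implements that workflow end to end for users with purified
reference profiles and mixed-sample arrays:

* **QC** — drop samples with mean detection p-value > 0.01, drop probes
  failing detection in any retained sample or flagged as SNP-at-CpG,
  sex-chromosome or cross-reactive, then cross-sample quantile
  normalisation.
* **Signature selection** — per cell type, equal-variance one-vs-rest
  F statistics (F = t², df 1 and n − 2) per probe; keep probes with
  p < 1 × 10⁻⁸ and take either the top 100 by |Δβ| ("any") or the top 50
  hypermethylated plus top 50 hypomethylated ("both"); the deduplicated
  union across types forms the signature matrix X (probes × cell types,
  entries are within-type mean betas).
* **Projection** — for each mixture with beta vector y over the signature
  probes, estimate proportions ŵ = argmin‖y − Xw‖² subject to w ≥ 0
  (optionally Σw ≤ 1 or Σw = 1). With a good panel the unconstrained sums
  land close to one, which doubles as a sanity check.
* **Validation** — MSE by cell type or subject (fraction² scale),
  Bland–Altman bias and limits of agreement, rescaling of flow-cytometry
  compositions over the DNA-bearing cell types, an invariant-probe check
  (probes ≥ 0.95 or ≤ 0.05 in every purified type must stay on that side in
  mixtures if no other nucleated cells are present), a pool-size versus
  variance regression, and a classical MDS diagnostic.
* **Simulation** — synthetic profiles with planted hyper/hypo signature
  probes on a bimodal background, per-individual sorted samples, DNA pools,
  Dirichlet-weighted mixtures with Beta-distributed noise, and an optional
  DNA-free (red-blood-cell-like) fraction that dilutes cytometry truth but
  not methylation — so every stage is testable with known ground truth.

## Worked example

```python
import numpy as np
from baldeconv import (generate_profiles, sample_individuals,
                       generate_mixtures, estimate_cell_counts, mse)

profiles = generate_profiles(5000, n_signature_per_type=60, delta=0.5, seed=7)
reference, sheet = sample_individuals(profiles, n_per_type=3, precision=100, seed=8)
mixtures, truth = generate_mixtures(profiles, n_mixtures=12, noise_precision=200, seed=9)

estimates, signature = estimate_cell_counts(mixtures, reference, sheet, mode="any")
print("signature probes:", len(signature.probe_ids))
print(estimates.data.head(3).round(3))
print(mse(truth.true_weights, estimates, by="cell_type").round(6))
```

Output:

```
signature probes: 387
           AlveolarMacrophage  Granulocyte  Lymphocyte    AEC
sample_id
mix1                    0.681        0.076       0.165  0.077
mix2                    0.941        0.056       0.004  0.000
mix3                    0.585        0.186       0.115  0.112
AlveolarMacrophage    0.000013
Granulocyte           0.000008
Lymphocyte            0.000017
AEC                   0.000008
```

The 387-probe signature (13 short of 4 × 100 because at this noise level a
few lymphocyte candidates miss the 10⁻⁸ significance bar — the shortfall is
logged) recovers the planted compositions with per-cell-type MSE below
2 × 10⁻⁵ on the fraction² scale, and the estimated rows sum to ≈ 1 even
though no sum constraint is imposed.

The same stages are available from the shell:

```bash
baldeconv simulate --n-probes 5000 --seed 7 --outdir demo
baldeconv qc --beta demo/reference_beta.csv --detp demo/detection_p.csv \
             --out-beta demo/qc_beta.csv --report demo/qc.json
baldeconv select-signature --reference-beta demo/reference_beta.csv \
             --sample-sheet demo/sample_sheet.csv --mode both \
             --out-signature demo/signature.csv --report demo/selection.json
baldeconv deconvolve --mixture-beta demo/mixture_beta.csv \
             --reference-beta demo/reference_beta.csv \
             --sample-sheet demo/sample_sheet.csv --out demo/proportions.csv
baldeconv validate --truth demo/truth_weights.csv \
             --estimate demo/proportions.csv --out-report demo/validation.json
baldeconv run-all --seed 7 --outdir demo_all   # all of the above, chained
```

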