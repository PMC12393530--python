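# chrompen

Polymer-physics distance penalties for chromatin interaction proxies.

## The problem

Scalable proxies of 3D genome contacts — co-accessibility scores from
scATAC-seq and deep-learning sequence models — systematically overestimate
long-range interactions: their scores barely decay with genomic distance,
while experimental Hi-C contact frequency follows the power-law decay that
polymer physics predicts.  `chrompen` corrects this bias with a penalty
derived directly from Hi-C decay data, and quantifies how well a proxy
profile matches a Hi-C reference.  It is written for regulatory-genomics
practitioners who already have a loop list (BEDPE) and a pairwise score
table (TSV) and want a transparent, physics-grounded post-processing step.

## The model

The contact probability of two loci at linear separation *s* scales as
*P*(*s*) ∝ *s*<sup>−α</sup> with α = 3ν (Flory exponent ν).  Empirical decay
curves are only piecewise linear in log-log space — different folding
regimes (packed loop-scale globules, TAD-scale collapsed globules, distal
decay) carry different exponents.  `chrompen` therefore fits a mixture

&nbsp;&nbsp;&nbsp;&nbsp;*P*(*s*) = Σᵢ πᵢ βᵢ *s*<sup>−αᵢ</sup>

by: binning contact distances, converting counts to densities, decomposing
the (log₁₀ *s*, log₁₀ density) point cloud with a 2-D Gaussian mixture
(number of regimes chosen by a parsimonious BIC rule), fitting a line per
regime (αᵢ = −slope), and refining all exponents jointly against the full
mixture curve.  Penalization multiplies each raw proxy score by *P*(*s*)
(normalized to max 1 on the fit range, so it only down-weights).
Concordance of max-1-normalized profiles over 35–500 kb is measured by
Spearman ρ, 1-D Wasserstein distance, and area-based FPR/FNR/F1
(FPR = proxy area above the reference / total proxy area; FNR = reference
area not covered / total reference area).

## Worked example

`examples/fit_decay_model.py` simulates contact sets from known ground
truth and runs the fitting pipeline end to end:

```
maize-like: generating alpha(s) = 2.34
  selected n = 1 regimes (BIC scan: [(1, -103.6), (2, -87.9), (3, -68.6), (4, -47.8), (5, -26.5)])
  regime 1: alpha = 2.341  pi = 1.000  R^2 = 0.9995

two-regime: generating alpha(s) = 6, 0.5
  selected n = 2 regimes (BIC scan: [(1, 153.4), (2, -35.1), (3, -22.9), (4, -6.0), (5, 15.3)])
  regime 1: alpha = 6.025  pi = 0.305  R^2 = 0.9989
  regime 2: alpha = 0.509  pi = 0.695  R^2 = 0.9989
  regime transition at 99.7 kb
```

The single-regime exponent is recovered at 2.341 (generating 2.34); the
two-regime mixture is recovered at (6.03, 0.51) with the regime handover
located at 99.7 kb (generating 100 kb).  `examples/compare_profiles.py`
then shows the correction effect on a flat, noisy proxy:

```
metric                   raw proxy   penalized
Spearman rho                0.1355      1.0000
Wasserstein (kb)          115.0284      0.1671
area FPR                    0.9377      0.0000
area FNR                    0.0000      0.0334
F1                          0.1173      0.9830
```

A distance-independent proxy puts ~94% of its area above the decaying
reference (FPR 0.94); after multiplying by the fitted penalty the profile
matches the reference almost exactly.

## Command line

The same pipeline is exposed as a thin CLI:

```sh
chrompen simulate --preset maize-like --n 50000 --seed 7 --out loops.bedpe
chrompen fit --bedpe loops.bedpe --min-dist 35000 --max-dist 500000 --seed 42 --out params.json
chrompen apply --scores scores.tsv --params params.json --out penalized.tsv
chrompen evaluate --proxy penalized.tsv --reference loops.bedpe --column penalized_score
```

BEDPE and score-table coordinates are 0-based half-open (BED convention);
anchor distance is midpoint-to-midpoint in bp.  Parameter files are JSON
(`{"species", "fit_range_bp", "normalization", "components": [{"pi",
"beta", "alpha"}, ...]}`) and round-trip exactly.

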