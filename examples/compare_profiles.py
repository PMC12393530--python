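"""Quantify how well raw vs penalized proxy profiles match a Hi-C reference.

Standardizes both signals into max-1-normalized profiles over 35-500 kb and
reports Spearman rho, Wasserstein distance, the area-based false
positive/negative rates, and the F1 score before and after penalization.
"""

from chrompen import (
    apply_penalty,
    compare,
    fit_decay_model,
    make_reference_profile,
    preset_config,
    simulate_contacts,
    simulate_flat_scores,
)

hic = preset_config("maize-like", n_records=50_000, seed=7)
params = fit_decay_model(simulate_contacts(hic), seed=7)
flat = simulate_flat_scores(preset_config("flat-scores", n_records=20_000, seed=9))
reference = make_reference_profile(hic, n_bins=30, range_bp=(35_000.0, 500_000.0))

raw = compare(flat, reference, n_bins=30)
pen = compare(apply_penalty(flat, params), reference, n_bins=30,
              proxy_column="penalized_score")

print(f"{'metric':<22}{'raw proxy':>12}{'penalized':>12}")
for name, r, p in [
    ("Spearman rho", raw.spearman_rho, pen.spearman_rho),
    ("Wasserstein (kb)", raw.wasserstein_kb, pen.wasserstein_kb),
    ("area FPR", raw.fpr, pen.fpr),
    ("area FNR", raw.fnr, pen.fnr),
    ("F1", raw.f1, pen.f1),
]:
    fmt = lambda v: "   undef" if v is None else f"{v:12.4f}"
    print(f"{name:<22}{fmt(r)}{fmt(p)}")

print("\nThe flat proxy's area is almost entirely excess over the decaying"
      "\nreference (FPR near 1, F1 low). After multiplying by the fitted"
      "\npenalty the profile shapes coincide: FPR collapses, rho and F1 rise.")
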