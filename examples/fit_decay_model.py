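"""Fit the multi-regime power-law decay model to simulated Hi-C contacts.

Generates contact lists from known ground truth (a single maize-like regime
and a steep/shallow two-regime mixture), runs the full fitting pipeline, and
prints the selected number of regimes, each decay exponent alpha, and the
regime transition point.
"""

from chrompen import fit_decay_model, preset_config, simulate_contacts

for preset in ("maize-like", "two-regime"):
    cfg = preset_config(preset, n_records=50_000, seed=7)
    contacts = simulate_contacts(cfg)
    params = fit_decay_model(contacts, fit_range_bp=cfg.range_bp, seed=7,
                             species_label=preset)
    gen = ", ".join(f"{c.alpha:g}" for c in cfg.components)
    print(f"\n{preset}: generating alpha(s) = {gen}")
    print(f"  selected n = {params.n_components} regimes "
          f"(BIC scan: {[(r['n'], round(r['bic'], 1)) for r in params.selection_table]})")
    for i, c in enumerate(params.components, 1):
        print(f"  regime {i}: alpha = {c.alpha:.3f}  pi = {c.pi:.3f}  R^2 = {c.r_squared:.4f}")
    for t in params.transitions_bp:
        print(f"  regime transition at {t / 1000:.1f} kb")

print("\nAlpha is the log-log slope of contact probability vs distance:"
      "\n~1 fractal globule, 1.5 random walk, ~0 collapsed globule, >3 tightly"
      "\npartitioned short-range packing. Transitions mark loop/TAD-scale handovers.")
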