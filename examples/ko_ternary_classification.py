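"""Classify KOs as core/enriched/diluted across three metagenomic libraries.

Plants a KO table with known structure, recovers the categories with
the two-fold rule, summarizes counts and abundance shares, and writes a
ternary scatter.
"""

from sipautotroph import (
    classify_ko_table,
    plot_ternary,
    simulate_ko_table,
    summarize_categories,
)

triples, truth = simulate_ko_table(
    n_core=40, n_enriched=(8, 8, 8), n_diluted=(4, 4, 4),
    fold=4.0, noise_cv=0.0, seed=5,
)
classes = classify_ko_table(triples, normalize=False)  # already per-million scale

hits = sum(c.category == truth[c.ko_id] for c in classes)
print(f"planted-category recovery: {hits}/{len(classes)}")

summary = summarize_categories(classes, triples)
print("\nper-category KO counts and per-library abundance totals:")
print(summary.to_string())
print("\n-> core KOs (spread < two-fold) dominate the shared functional")
print("   repertoire; enriched KOs are >= two-fold above both other libraries.")

ax = plot_ternary(classes, triples, labels=("65C", "45C", "30C"))
ax.figure.savefig("ko_ternary.png", dpi=150, bbox_inches="tight")
print("\nwrote ko_ternary.png (core gray, enriched filled, diluted open circles)")
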