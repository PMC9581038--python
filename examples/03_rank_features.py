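"""Rank features by information gain against the label-powerset class.

Each feature is discretized by MDL-stopped recursive splitting, then scored
as the reduction in class entropy (bits).  On data with planted glutamine /
proline / valine enrichment in multi-class epitopes, the corresponding
composition features surface at the top.
"""

import abclass

ds = abclass.generate(abclass.default_spec(scale=0.02, signal_strength=1.5,
                                           seed=11))
fm = abclass.encode_dataset(ds, "aac")
ranking = abclass.rank_features(fm, ds, class_mode="powerset")

print(f"ranked {len(ranking.entries)} composition features on {len(ds)} records")
print("top 5 by information gain (bits):")
for name, gain in abclass.top_k(ranking, 5).entries:
    print(f"  {name:<8} {gain:.4f}")
print("\nGlutamine (aac:Q) ranks near the top: it separates both the "
      "IgA-vs-IgE axis and multi-class from single-class epitopes.")
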