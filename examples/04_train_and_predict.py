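"""Train a Binary Relevance model and predict antibody classes for peptides.

Four one-vs-rest Random Forests (optionally AdaBoost-boosted) are fitted,
one per antibody class; a new peptide is pushed through all four and every
class whose positive score reaches 0.5 is called.
"""

import abclass

train = abclass.generate(abclass.default_spec(scale=0.02, signal_strength=1.5,
                                              seed=7))
fm = abclass.encode_dataset(train, "dc")
base = abclass.BaseLearnerConfig(kind="rf_adaboost", n_trees=40,
                                 n_boost_rounds=4, seed=0)
model = abclass.fit(fm, train, "binary_relevance", base, encoder="dc")
print(f"trained BR-RF-AdaBoost on {len(train)} records, "
      f"{fm.shape[1]} dipeptide features")

probes = abclass.Dataset(records=[
    abclass.EpitopeRecord("probe_igg_like", "ALSALSGALSLAGSALS", None),
    abclass.EpitopeRecord("probe_multi_like", "QPVQPVQQPVQPVQQPV", None),
])
bits, scores = abclass.predict_dataset(model, probes)
print("\nper-class calls (score >= 0.5 sets the bit):")
for rec, b, s in zip(probes.records, bits, scores):
    calls = [n for n, bit in zip(abclass.LABEL_NAMES, b) if bit] or ["none"]
    print(f"  {rec.id:<18} bits={tuple(int(x) for x in b)}  "
          f"scores={[round(float(x), 2) for x in s]}  -> {'+'.join(calls)}")
print("\nThe composition-biased probes pick up the classes whose planted "
      "residue signature they carry.")
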