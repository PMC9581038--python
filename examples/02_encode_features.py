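"""Encode peptides with the four sequence-feature encoders.

AAC (20 residue frequencies), DC (400 ordered dipeptide frequencies) and
the two pseudo amino acid composition variants, which append lambda
(type 1) or 2*lambda (type 2) sequence-order correlation terms.  Every
encoding is a partition of unity.
"""

import numpy as np

import abclass
from abclass.features import feature_names

seq = "QQPVLKACDEFG"
cfg = abclass.PseAACConfig(lam=4, w=0.05)

aac = abclass.encode_aac(seq)
dc = abclass.encode_dc(seq)
p1 = abclass.encode_pseaac1(seq, cfg)
p2 = abclass.encode_pseaac2(seq, cfg)

print(f"peptide: {seq} (length {len(seq)})")
print(f"AAC      -> {len(aac)} components, sum {aac.sum():.6f}")
nz = {n: round(float(v), 4) for n, v in zip(feature_names('aac'), aac) if v > 0}
print(f"  nonzero: {nz}")
print(f"DC       -> {len(dc)} components, sum {dc.sum():.6f}; "
      f"dc:QQ = {dict(zip(feature_names('dc'), dc))['dc:QQ']:.4f}")
print(f"PseAAC1  -> {len(p1)} components (20 + lambda), sum {p1.sum():.6f}")
print(f"  order terms theta_1..4: {np.round(p1[20:], 4)}")
print(f"PseAAC2  -> {len(p2)} components (20 + 2*lambda), sum {p2.sum():.6f}")

ds = abclass.generate(abclass.default_spec(scale=0.01, seed=3))
fm = abclass.encode_dataset(ds, "combined", cfg)
print(f"\ncombined matrix on {len(ds)} records: {fm.shape[0]} x {fm.shape[1]} "
      "(20 + 400 + 24 + 28 columns)")
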