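"""Fixed-length numeric encodings of peptide sequences.

Four encoders are provided, all emitting rows that sum to one:

* **AAC** — amino-acid composition, the 20 residue frequencies
  ``F(i) = N_i / N``;
* **DC** — dipeptide composition, the 400 ordered adjacent-pair frequencies
  ``F(i, j) = N_ij / (N - 1)`` (pair order matters: AG != GA);
* **PseAAC type 1** — parallel-correlation pseudo amino acid composition:
  the 20 residue frequencies plus lambda sequence-order correlation factors
  theta_k, each the mean over positions of the squared-difference coupling
  of residues k apart, computed on standardized hydrophobicity,
  hydrophilicity and side-chain mass scales;
* **PseAAC type 2** — amphiphilic (series-correlation) variant: 2*lambda
  per-property correlation factors tau, products of standardized
  hydrophobicity resp. hydrophilicity values of residues k apart.

Both PseAAC types are normalized so that all 20+lambda (type 1) or
20+2*lambda (type 2) components form a partition of unity with the
sequence-order terms weighted by ``w``; at ``w = 0``, or on a homopolymer
(type 1), they reduce exactly to the plain composition.

The property scales are the classic per-residue hydrophobicity
(Tanford/Chou), hydrophilicity (Hopp-Woods) and side-chain mass tables,
standardized to zero mean and unit variance over the 20 residues before use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AMINO_ACIDS, Dataset

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Ordered 400 dipeptides, row-major over the alphabet (AA, AC, ..., YY).
DIPEPTIDES = tuple(a + b for a in AMINO_ACIDS for b in AMINO_ACIDS)

# Raw per-residue scales, keyed by one-letter code order of AMINO_ACIDS.
_HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19, "G": 0.48,
    "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06, "M": 0.64, "N": -0.78,
    "P": 0.12, "Q": -0.85, "R": -2.53, "S": -0.18, "T": -0.05, "V": 1.08,
    "W": 0.81, "Y": 0.26,
}
_HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5, "G": 0.0,
    "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8, "M": -1.3, "N": 0.2,
    "P": 0.0, "Q": 0.2, "R": 3.0, "S": 0.3, "T": -0.4, "V": -1.5,
    "W": -3.4, "Y": -2.3,
}
_SIDECHAIN_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0, "G": 1.0,
    "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0, "M": 75.0, "N": 58.0,
    "P": 42.0, "Q": 72.0, "R": 101.0, "S": 31.0, "T": 45.0, "V": 43.0,
    "W": 130.0, "Y": 107.0,
}

PROPERTY_TABLES = {
    "hydrophobicity": _HYDROPHOBICITY,
    "hydrophilicity": _HYDROPHILICITY,
    "sidechain_mass": _SIDECHAIN_MASS,
}


def standardized_scale(name: str) -> np.ndarray:
    """A property scale as a length-20 vector with mean 0, population SD 1."""
    table = PROPERTY_TABLES[name]
    vals = np.array([table[aa] for aa in AMINO_ACIDS], dtype=float)
    return (vals - vals.mean()) / vals.std()  # population SD, ddof=0


@dataclass(frozen=True)
class PseAACConfig:
    """Settings for the pseudo amino acid composition encoders.

    lam
        Number of sequence-order correlation tiers (lambda).  Must stay below
        the shortest peptide it is applied to; with the 5-residue minimum the
        ceiling is 4, which is also the default.
    w
        Weight of the sequence-order terms relative to the composition terms.
        0.05 is the customary default.
    properties
        Property scales for the type-1 squared-difference coupling.  Type 2
        always uses the amphiphilic pair (hydrophobicity, hydrophilicity).
    """

    lam: int = 4
    w: float = 0.05
    properties: tuple[str, ...] = ("hydrophobicity", "hydrophilicity",
                                   "sidechain_mass")
    amphiphilic_properties: tuple[str, ...] = ("hydrophobicity", "hydrophilicity")

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lam must be non-negative")
        if self.w < 0:
            raise ValueError("w must be non-negative")
        if len(self.amphiphilic_properties) != 2:
            raise ValueError("type-2 encoding uses exactly two property scales")


def _indices(seq: str) -> np.ndarray:
    try:
        return np.array([AA_INDEX[aa] for aa in seq], dtype=int)
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r} in sequence") from exc


def encode_aac(seq: str) -> np.ndarray:
    """Amino-acid composition: 20 residue frequencies summing to 1."""
    if len(seq) == 0:
        raise ValueError("cannot encode an empty sequence")
    idx = _indices(seq)
    counts = np.bincount(idx, minlength=20).astype(float)
    return counts / len(seq)


def encode_dc(seq: str) -> np.ndarray:
    """Dipeptide composition: 400 ordered-pair frequencies summing to 1."""
    if len(seq) < 2:
        raise ValueError("dipeptide composition needs length >= 2")
    idx = _indices(seq)
    pair_idx = idx[:-1] * 20 + idx[1:]
    counts = np.bincount(pair_idx, minlength=400).astype(float)
    return counts / (len(seq) - 1)


def _correlation_factors_type1(idx: np.ndarray, cfg: PseAACConfig) -> np.ndarray:
    """theta_k, k = 1..lam: mean squared-difference coupling at lag k."""
    scales = np.stack([standardized_scale(p) for p in cfg.properties])  # (P, 20)
    vals = scales[:, idx]  # (P, N)
    thetas = np.empty(cfg.lam)
    for k in range(1, cfg.lam + 1):
        diff = vals[:, k:] - vals[:, :-k]          # (P, N-k)
        thetas[k - 1] = np.mean(diff ** 2, axis=0).mean()
    return thetas


def _correlation_factors_type2(idx: np.ndarray, cfg: PseAACConfig) -> np.ndarray:
    """tau, 2*lam factors ordered (prop1 lag1, prop2 lag1, prop1 lag2, ...)."""
    scales = np.stack([standardized_scale(p) for p in cfg.amphiphilic_properties])
    vals = scales[:, idx]  # (2, N)
    taus = np.empty(2 * cfg.lam)
    for k in range(1, cfg.lam + 1):
        prod = vals[:, k:] * vals[:, :-k]          # (2, N-k)
        taus[2 * (k - 1):2 * k] = prod.mean(axis=1)
    return taus


def _normalize_pseaac(aac: np.ndarray, order_terms: np.ndarray, w: float) -> np.ndarray:
    denom = aac.sum() + w * order_terms.sum()
    if denom <= 0:
        raise ValueError("degenerate sequence-order terms: non-positive normalizer")
    return np.concatenate([aac, w * order_terms]) / denom


def encode_pseaac1(seq: str, cfg: PseAACConfig | None = None) -> np.ndarray:
    """Type-1 (parallel-correlation) PseAAC: 20 + lambda components."""
    cfg = cfg or PseAACConfig()
    if len(seq) <= cfg.lam:
        raise ValueError(f"sequence length {len(seq)} must exceed lam={cfg.lam}")
    idx = _indices(seq)
    aac = encode_aac(seq)
    thetas = _correlation_factors_type1(idx, cfg) if cfg.lam else np.empty(0)
    return _normalize_pseaac(aac, thetas, cfg.w)


def encode_pseaac2(seq: str, cfg: PseAACConfig | None = None) -> np.ndarray:
    """Type-2 (amphiphilic, series-correlation) PseAAC: 20 + 2*lambda components."""
    cfg = cfg or PseAACConfig()
    if len(seq) <= cfg.lam:
        raise ValueError(f"sequence length {len(seq)} must exceed lam={cfg.lam}")
    idx = _indices(seq)
    aac = encode_aac(seq)
    taus = _correlation_factors_type2(idx, cfg) if cfg.lam else np.empty(0)
    return _normalize_pseaac(aac, taus, cfg.w)


def encode_combined(seq: str, cfg: PseAACConfig | None = None) -> np.ndarray:
    """Concatenation AAC | DC | PseAAC1 | PseAAC2, length 440 + 3*lambda."""
    cfg = cfg or PseAACConfig()
    return np.concatenate([
        encode_aac(seq), encode_dc(seq),
        encode_pseaac1(seq, cfg), encode_pseaac2(seq, cfg),
    ])


def feature_names(encoder: str, cfg: PseAACConfig | None = None) -> list[str]:
    """Globally unique, encoder-prefixed column names for one encoder."""
    cfg = cfg or PseAACConfig()
    if encoder == "aac":
        return [f"aac:{aa}" for aa in AMINO_ACIDS]
    if encoder == "dc":
        return [f"dc:{dp}" for dp in DIPEPTIDES]
    if encoder == "pseaac1":
        return ([f"pse1:{aa}" for aa in AMINO_ACIDS]
                + [f"pse1:theta{k}" for k in range(1, cfg.lam + 1)])
    if encoder == "pseaac2":
        names = [f"pse2:{aa}" for aa in AMINO_ACIDS]
        for k in range(1, cfg.lam + 1):
            for prop in cfg.amphiphilic_properties:
                names.append(f"pse2:tau{k}_{prop}")
        return names
    if encoder == "combined":
        return (feature_names("aac") + feature_names("dc")
                + feature_names("pseaac1", cfg) + feature_names("pseaac2", cfg))
    raise ValueError(f"unknown encoder {encoder!r}")


ENCODERS = {
    "aac": lambda seq, cfg: encode_aac(seq),
    "dc": lambda seq, cfg: encode_dc(seq),
    "pseaac1": encode_pseaac1,
    "pseaac2": encode_pseaac2,
    "combined": encode_combined,
}


def encode_dataset(ds: Dataset, encoder: str = "dc",
                   cfg: PseAACConfig | None = None) -> pd.DataFrame:
    """Encode every record of a dataset into a feature matrix.

    Returns a DataFrame with record ids as the index and encoder-prefixed
    column names; row order follows the dataset.  Deterministic.
    """
    if encoder not in ENCODERS:
        raise ValueError(f"unknown encoder {encoder!r}; choose from {sorted(ENCODERS)}")
    cfg = cfg or PseAACConfig()
    fn = ENCODERS[encoder]
    rows = np.array([fn(r.sequence, cfg) for r in ds.records], dtype=float)
    if rows.size == 0:
        rows = rows.reshape(0, len(feature_names(encoder, cfg)))
    return pd.DataFrame(rows, index=ds.ids(), columns=feature_names(encoder, cfg))
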