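"""Synthetic labelled epitope datasets with plantable compositional signal.

The generator emulates the statistical structure the classifier assumes:
eleven antibody-class label combinations with realistic entry counts,
peptide lengths uniform on 5-50, and class-dependent residue-frequency
biases.  Each label carries a characteristic compositional direction and
multi-class combinations are additionally enriched in Q, P and V and
depleted in H and C, echoing the trends seen in curated epitope data
(IgE-only and IgA-only profiles differ most visibly in E and Q).  Residues
are drawn i.i.d. from the combination's profile by default; an optional
first-order Markov mode plants label-specific dipeptide structure — a
cyclic-shift transition preference per label, plus Q-Q and P-Q enrichment
in multi-class epitopes — on a composition-flat background, so that
dipeptide features carry signal that plain composition cannot see.

These simulations reproduce compositional learnability only: no assay
noise, host effects, positional motifs beyond first order, or real epitope
biology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AMINO_ACIDS, Dataset, EpitopeRecord, LabelVector

#: Label combinations and entry counts of the full-scale study dataset
#: (order: IgG, IgE, IgA, IgM).
STUDY_COMBINATIONS: dict[LabelVector, int] = {
    (1, 0, 0, 0): 6027,   # IgG
    (0, 1, 0, 0): 1512,   # IgE
    (0, 0, 1, 0): 412,    # IgA
    (0, 0, 0, 1): 999,    # IgM
    (1, 1, 0, 0): 748,    # IgG + IgE
    (1, 0, 0, 1): 701,    # IgG + IgM
    (1, 0, 1, 0): 242,    # IgG + IgA
    (0, 1, 1, 0): 10,     # IgE + IgA
    (1, 0, 1, 1): 62,     # IgG + IgM + IgA
    (1, 1, 0, 1): 20,     # IgG + IgM + IgE
    (1, 1, 1, 0): 11,     # IgG + IgE + IgA
}

#: The highly skewed coronavirus holdout: 176 epitopes, 166 of them IgG-only.
SARS_COMBINATIONS: dict[LabelVector, int] = {
    (1, 0, 0, 0): 166,
    (0, 0, 1, 0): 4,
    (0, 0, 0, 1): 5,
    (1, 0, 0, 1): 1,
}

_AA_IDX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def _direction(enriched: str, depleted: str) -> np.ndarray:
    d = np.zeros(20)
    for aa in enriched:
        d[_AA_IDX[aa]] = 1.0
    for aa in depleted:
        d[_AA_IDX[aa]] = -1.0
    return d


#: Per-label compositional directions (log-scale tilts from uniform).
LABEL_DIRECTIONS: tuple[np.ndarray, ...] = (
    _direction("ALS", "WY"),   # IgG
    _direction("EF", "Q"),     # IgE
    _direction("QT", "E"),     # IgA
    _direction("KR", "D"),     # IgM
)

#: Extra tilt applied to combinations binding more than one antibody class.
MULTI_CLASS_DIRECTION: np.ndarray = _direction("QPV", "HC")

#: Markov-mode transition signatures.  Each label boosts the transitions
#: i -> i + shift (mod 20) for every residue i — a permutation pattern, so
#: the tilted chain stays doubly stochastic and its stationary composition
#: stays exactly uniform: the class signal lives purely in dipeptides.
LABEL_SHIFTS: tuple[int, ...] = (1, 2, 3, 4)  # IgG, IgE, IgA, IgM

#: Multi-class combinations additionally boost the Q-Q and P-Q dipeptides.
MULTI_CLASS_PAIR_SIGNATURES: tuple[str, ...] = ("QQ", "PQ")


@dataclass(frozen=True)
class SyntheticSpec:
    """A recipe for one synthetic dataset.

    combos
        Map from 4-bit label vector to (record count, residue profile); each
        profile is a probability distribution over the 20 amino acids.
    signal_strength
        Log-scale divergence of profiles from uniform; 0 means no
        compositional signal at all.
    markov
        When set, residues are drawn from a first-order chain whose
        transitions carry the label's dipeptide signatures scaled by
        ``dipeptide_signal``, over a composition-flat background.
    """

    combos: dict[LabelVector, tuple[int, np.ndarray]]
    length_range: tuple[int, int] = (5, 50)
    signal_strength: float = 1.0
    seed: int = 0
    markov: bool = False
    dipeptide_signal: float = 1.5

    def total(self) -> int:
        return sum(count for count, _ in self.combos.values())

    def validate(self) -> None:
        for combo, (count, profile) in self.combos.items():
            if count <= 0:
                raise ValueError(f"combination {combo} has count {count} <= 0")
            p = np.asarray(profile, dtype=float)
            if p.shape != (20,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"profile for {combo} is not a distribution")


def combo_direction(combo: LabelVector) -> np.ndarray:
    """Summed log-tilt direction for one label combination."""
    d = np.zeros(20)
    for bit, direction in zip(combo, LABEL_DIRECTIONS):
        if bit:
            d = d + direction
    if sum(combo) > 1:
        d = d + MULTI_CLASS_DIRECTION
    return d


def combo_profile(combo: LabelVector, signal_strength: float) -> np.ndarray:
    """Residue distribution: uniform background exponentially tilted."""
    logits = signal_strength * combo_direction(combo)
    p = np.exp(logits - logits.max())
    return p / p.sum()


def default_spec(scale: float = 1.0, signal_strength: float = 1.0,
                 seed: int = 0, markov: bool = False,
                 dipeptide_signal: float = 1.5) -> SyntheticSpec:
    """The study-shaped recipe: 11 combinations with scaled entry counts.

    Counts are ``round(scale * full count)`` with a floor of 2 so even smoke
    tests keep every combination represented (no singleton powerset class).
    In Markov mode the compositional profiles are kept uniform so that the
    class signal lives in dipeptide transitions only.
    """
    if not (0.0 < scale <= 1.0):
        raise ValueError("scale must lie in (0, 1]")
    combos = {}
    for combo, full_count in STUDY_COMBINATIONS.items():
        count = max(2, round(scale * full_count))
        profile = combo_profile(combo, 0.0 if markov else signal_strength)
        combos[combo] = (count, profile)
    return SyntheticSpec(combos=combos, signal_strength=signal_strength,
                         seed=seed, markov=markov,
                         dipeptide_signal=dipeptide_signal)


def sars_like_spec(signal_strength: float = 1.0, seed: int = 0) -> SyntheticSpec:
    """A deliberately skewed holdout: 176 records, >94% IgG-only."""
    combos = {
        combo: (count, combo_profile(combo, signal_strength))
        for combo, count in SARS_COMBINATIONS.items()
    }
    return SyntheticSpec(combos=combos, signal_strength=signal_strength, seed=seed)


def _transition_matrix(combo: LabelVector, profile: np.ndarray,
                       dipeptide_signal: float) -> np.ndarray:
    """Row-stochastic 20x20 chain: background profile boosted on signatures."""
    boost = np.zeros((20, 20))
    idx = np.arange(20)
    for bit, shift in zip(combo, LABEL_SHIFTS):
        if bit:
            boost[idx, (idx + shift) % 20] += 1.0
    if sum(combo) > 1:
        for pair in MULTI_CLASS_PAIR_SIGNATURES:
            boost[_AA_IDX[pair[0]], _AA_IDX[pair[1]]] += 1.0
    trans = profile[None, :] * np.exp(dipeptide_signal * boost)
    return trans / trans.sum(axis=1, keepdims=True)


def _draw_sequence(rng: np.random.Generator, length: int, profile: np.ndarray,
                   trans: np.ndarray | None) -> str:
    if trans is None:
        idx = rng.choice(20, size=length, p=profile)
    else:
        idx = np.empty(length, dtype=int)
        idx[0] = rng.choice(20, p=profile)
        for t in range(1, length):
            idx[t] = rng.choice(20, p=trans[idx[t - 1]])
    return "".join(AMINO_ACIDS[i] for i in idx)


def generate(spec: SyntheticSpec) -> Dataset:
    """Draw a dataset from a spec; deterministic given ``spec.seed``.

    Every generated record satisfies the epitope-record invariants, so the
    output round-trips through the readers unchanged.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    records: list[EpitopeRecord] = []
    for combo in sorted(spec.combos):  # fixed combo order for determinism
        count, profile = spec.combos[combo]
        profile = np.asarray(profile, dtype=float)
        trans = (_transition_matrix(combo, profile, spec.dipeptide_signal)
                 if spec.markov else None)
        tag = "".join(map(str, combo))
        for i in range(count):
            length = int(rng.integers(lo, hi + 1))
            seq = _draw_sequence(rng, length, profile, trans)
            records.append(EpitopeRecord(id=f"syn_{tag}_{i:05d}",
                                         sequence=seq, labels=combo))
    return Dataset(records=records)
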