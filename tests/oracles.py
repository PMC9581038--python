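"""Independent brute-force reference implementations used only by tests.

Everything here is written in plain loops over dicts/lists, deliberately
sharing no code with the package: the raw property tables are re-declared,
standardization is redone with the statistics module, and the metrics are
per-definition recomputations.  These are the oracles the fast vectorized
implementations are checked against.
"""

from __future__ import annotations

import math
from statistics import pstdev, mean

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

RAW_SCALES = {
    "hydrophobicity": {
        "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19, "G": 0.48,
        "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06, "M": 0.64, "N": -0.78,
        "P": 0.12, "Q": -0.85, "R": -2.53, "S": -0.18, "T": -0.05, "V": 1.08,
        "W": 0.81, "Y": 0.26,
    },
    "hydrophilicity": {
        "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5, "G": 0.0,
        "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8, "M": -1.3, "N": 0.2,
        "P": 0.0, "Q": 0.2, "R": 3.0, "S": 0.3, "T": -0.4, "V": -1.5,
        "W": -3.4, "Y": -2.3,
    },
    "sidechain_mass": {
        "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0, "G": 1.0,
        "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0, "M": 75.0, "N": 58.0,
        "P": 42.0, "Q": 72.0, "R": 101.0, "S": 31.0, "T": 45.0, "V": 43.0,
        "W": 130.0, "Y": 107.0,
    },
}


def _standardize(table: dict[str, float]) -> dict[str, float]:
    vals = [table[aa] for aa in ALPHABET]
    mu, sd = mean(vals), pstdev(vals)
    return {aa: (table[aa] - mu) / sd for aa in ALPHABET}


def oracle_aac(seq: str) -> list[float]:
    return [sum(1 for c in seq if c == aa) / len(seq) for aa in ALPHABET]


def oracle_dc(seq: str) -> list[float]:
    out = []
    for a in ALPHABET:
        for b in ALPHABET:
            n = sum(1 for i in range(len(seq) - 1)
                    if seq[i] == a and seq[i + 1] == b)
            out.append(n / (len(seq) - 1))
    return out


def oracle_pseaac1(seq: str, lam: int, w: float,
                   properties=("hydrophobicity", "hydrophilicity",
                               "sidechain_mass")) -> list[float]:
    scales = [_standardize(RAW_SCALES[p]) for p in properties]
    thetas = []
    for k in range(1, lam + 1):
        couplings = []
        for t in range(len(seq) - k):
            a, b = seq[t], seq[t + k]
            couplings.append(mean((s[b] - s[a]) ** 2 for s in scales))
        thetas.append(mean(couplings))
    f = oracle_aac(seq)
    denom = sum(f) + w * sum(thetas)
    return [x / denom for x in f] + [w * th / denom for th in thetas]


def oracle_pseaac2(seq: str, lam: int, w: float,
                   properties=("hydrophobicity", "hydrophilicity")) -> list[float]:
    scales = [_standardize(RAW_SCALES[p]) for p in properties]
    taus = []
    for k in range(1, lam + 1):
        for s in scales:
            taus.append(mean(s[seq[t]] * s[seq[t + k]]
                             for t in range(len(seq) - k)))
    f = oracle_aac(seq)
    denom = sum(f) + w * sum(taus)
    return [x / denom for x in f] + [w * tau / denom for tau in taus]


def oracle_combined(seq: str, lam: int, w: float) -> list[float]:
    return (oracle_aac(seq) + oracle_dc(seq)
            + oracle_pseaac1(seq, lam, w) + oracle_pseaac2(seq, lam, w))


# ---------------------------------------------------------------------------
# metrics


def oracle_metrics(y_true, y_pred) -> dict[str, float]:
    """Hamming Loss and the six macro/micro P/R/F1 values, by definition."""
    n, q = len(y_true), len(y_true[0])
    hl = sum(sum(1 for j in range(q) if y_true[i][j] != y_pred[i][j]) / q
             for i in range(n)) / n
    tp = [0] * q
    fp = [0] * q
    fn = [0] * q
    for i in range(n):
        for j in range(q):
            if y_true[i][j] == 1 and y_pred[i][j] == 1:
                tp[j] += 1
            elif y_true[i][j] == 0 and y_pred[i][j] == 1:
                fp[j] += 1
            elif y_true[i][j] == 1 and y_pred[i][j] == 0:
                fn[j] += 1

    def div(a, b):
        return a / b if b else 0.0

    p_j = [div(tp[j], tp[j] + fp[j]) for j in range(q)]
    r_j = [div(tp[j], tp[j] + fn[j]) for j in range(q)]
    f_j = [div(2 * p_j[j] * r_j[j], p_j[j] + r_j[j]) for j in range(q)]
    p_micro = div(sum(tp), sum(tp) + sum(fp))
    r_micro = div(sum(tp), sum(tp) + sum(fn))
    return {
        "hamming_loss": hl,
        "p_macro": mean(p_j), "r_macro": mean(r_j), "f1_macro": mean(f_j),
        "p_micro": p_micro, "r_micro": r_micro,
        "f1_micro": div(2 * p_micro * r_micro, p_micro + r_micro),
    }


# ---------------------------------------------------------------------------
# boosting


class ReferenceAdaBoost:
    """Hand-rolled binary AdaBoost (targets in {-1, +1}) over any base factory.

    Implements the textbook loop: fit on the weighted distribution, weight
    the learner by 0.5*ln((1-err)/err), reweight examples towards mistakes,
    renormalize; stop early on a perfect or no-better-than-chance round.
    Exposes the per-round example-weight history for invariant checks.
    """

    def __init__(self, base_factory, n_rounds: int):
        self.base_factory = base_factory
        self.n_rounds = n_rounds
        self.learners: list = []
        self.alphas: list[float] = []
        self.weight_history: list[list[float]] = []

    def fit(self, X, y):
        m = len(y)
        d = [1.0 / m] * m
        for t in range(self.n_rounds):
            learner = self.base_factory(t)
            learner.fit(X, y, sample_weight=d)
            pred = learner.predict(X)
            err = sum(w for w, yi, pi in zip(d, y, pred) if yi != pi)
            if err >= 0.5:
                break
            if err <= 0:
                self.learners.append(learner)
                self.alphas.append(1.0)
                break
            alpha = 0.5 * math.log((1 - err) / err)
            self.learners.append(learner)
            self.alphas.append(alpha)
            d = [w * math.exp(-alpha * yi * pi)
                 for w, yi, pi in zip(d, y, pred)]
            z = sum(d)
            d = [w / z for w in d]
            self.weight_history.append(list(d))
        return self

    def decision(self, X):
        agg = [0.0] * len(X)
        for alpha, learner in zip(self.alphas, self.learners):
            for i, p in enumerate(learner.predict(X)):
                agg[i] += alpha * p
        return agg

    def predict(self, X):
        return [1 if s >= 0 else -1 for s in self.decision(X)]

    def training_error(self, X, y):
        pred = self.predict(X)
        return sum(1 for yi, pi in zip(y, pred) if yi != pi) / len(y)
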