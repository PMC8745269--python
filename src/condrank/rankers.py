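"""Condition-ranking strategies.

Three rankers share one output contract — a total order over enumerable
condition combinations:

* :class:`LikelihoodRankingModel` — a feed-forward network (one ReLU hidden
  layer, sigmoid outputs, one per condition bit) trained with multi-label
  binary cross-entropy.  For a query reaction it predicts per-bit
  probabilities, and every condition combination is scored by the likelihood

      L = -(1/6) * [ln q_T + ln q_P + ln q_cat + ln q_acid + ln q_base + ln q_poison]

  the negative log of the geometric mean of the six component probabilities,
  where q for a selected temperature/pressure/catalyst bin is the predicted
  probability of that bit and each additive contributes its Bernoulli
  probability (P if the combination selects the additive, 1 - P otherwise).
  Combinations are ranked ascending in L: lower L = higher confidence, and
  exp(-L) in (0, 1] is reported as a confidence score.

* ranking kNN — returns the condition combinations of the k training
  reactions nearest in descriptor (PCA) space, in ascending distance order,
  keeping only the nearest occurrence of a duplicated combination.

* null model — the training set's combinations sorted by descending
  frequency, identical for every query; the negative control.

The network is trained with Adam (lr 0.001, multiplied by 0.99 after each
epoch) for 200 epochs by default, matching a single hidden layer of 2000
units.  Desk-scale workflows shrink both.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .conditions import BINS, ConditionCombination, ConditionVocabulary

EPS = 1e-9  # probability clip before taking logs


@dataclass
class LRMConfig:
    hidden_size: int = 2000
    epochs: int = 200
    learning_rate: float = 1e-3
    lr_decay: float = 0.99  # multiplicative, applied after every epoch
    batch_size: int = 32
    seed: int = 42


@dataclass
class RankedConditions:
    """Combinations in rank order (best first) with their scores.

    For the likelihood model scores are L values sorted ascending; for kNN
    they are Euclidean distances; for the null model, negative frequencies.
    """

    combinations: list[ConditionCombination]
    scores: np.ndarray

    def __len__(self) -> int:
        return len(self.combinations)

    def top(self, k: int) -> list[ConditionCombination]:
        return self.combinations[:k]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class LikelihoodRankingModel:
    """input -> hidden (ReLU) -> condition bits (sigmoid), trained with BCE."""

    def __init__(self, input_dim: int, output_dim: int, config: LRMConfig | None = None):
        self.config = config or LRMConfig()
        self.input_dim = input_dim
        self.output_dim = output_dim
        rng = np.random.default_rng(self.config.seed)
        h = self.config.hidden_size
        # He init for the ReLU layer, Glorot for the sigmoid head
        self.W1 = rng.normal(0.0, np.sqrt(2.0 / input_dim), (input_dim, h))
        self.b1 = np.zeros(h)
        self.W2 = rng.normal(0.0, np.sqrt(1.0 / h), (h, output_dim))
        self.b2 = np.zeros(output_dim)
        self.loss_history: list[float] = []

    # --- training ---------------------------------------------------------

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "LikelihoodRankingModel":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
            raise ValueError(f"misaligned shapes X{X.shape} Y{Y.shape}")
        if X.shape[1] != self.input_dim or Y.shape[1] != self.output_dim:
            raise ValueError(
                f"expected X(*, {self.input_dim}) and Y(*, {self.output_dim}), "
                f"got X{X.shape} Y{Y.shape}"
            )
        cfg = self.config
        rng = np.random.default_rng(cfg.seed + 1)
        params = [self.W1, self.b1, self.W2, self.b2]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        lr = cfg.learning_rate
        step = 0
        n = X.shape[0]
        batch = min(cfg.batch_size, n)
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch):
                idx = order[start:start + batch]
                xb, yb = X[idx], Y[idx]
                # forward
                z1 = xb @ self.W1 + self.b1
                a1 = np.maximum(z1, 0.0)
                p = _sigmoid(a1 @ self.W2 + self.b2)
                pc = np.clip(p, EPS, 1.0 - EPS)
                epoch_loss -= float(
                    np.sum(yb * np.log(pc) + (1.0 - yb) * np.log(1.0 - pc))
                )
                # backward (BCE + sigmoid -> p - y)
                dz2 = (p - yb) / len(idx)
                grads = [
                    xb.T @ ((dz2 @ self.W2.T) * (z1 > 0)),
                    np.sum((dz2 @ self.W2.T) * (z1 > 0), axis=0),
                    a1.T @ dz2,
                    np.sum(dz2, axis=0),
                ]
                step += 1
                for p_, g, m_, v_ in zip(params, grads, m, v):
                    m_ *= beta1
                    m_ += (1 - beta1) * g
                    v_ *= beta2
                    v_ += (1 - beta2) * g * g
                    mhat = m_ / (1 - beta1 ** step)
                    vhat = v_ / (1 - beta2 ** step)
                    p_ -= lr * mhat / (np.sqrt(vhat) + eps)
            self.loss_history.append(epoch_loss / n)
            lr *= cfg.lr_decay
        return self

    # --- inference --------------------------------------------------------

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        a1 = np.maximum(X @ self.W1 + self.b1, 0.0)
        return _sigmoid(a1 @ self.W2 + self.b2)

    # --- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        np.savez(
            path, W1=self.W1, b1=self.b1, W2=self.W2, b2=self.b2,
            config=np.array([
                self.config.hidden_size, self.config.epochs,
                self.config.learning_rate, self.config.lr_decay,
                self.config.batch_size, self.config.seed,
            ]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "LikelihoodRankingModel":
        data = np.load(path)
        c = data["config"]
        cfg = LRMConfig(int(c[0]), int(c[1]), float(c[2]), float(c[3]),
                        int(c[4]), int(c[5]))
        model = cls(data["W1"].shape[0], data["W2"].shape[1], cfg)
        model.W1, model.b1 = data["W1"], data["b1"]
        model.W2, model.b2 = data["W2"], data["b2"]
        return model


# --- likelihood scoring ----------------------------------------------------

def component_probabilities(
    probs: np.ndarray, c: ConditionCombination, vocab: ConditionVocabulary
) -> np.ndarray:
    """The six per-component probabilities q selected by a combination."""
    p = np.asarray(probs, dtype=float)
    if p.shape != (vocab.n_bits,):
        raise ValueError(f"expected {vocab.n_bits} probabilities, got {p.shape}")
    q = np.array([
        p[BINS.index(c.temperature_bin)],
        p[3 + BINS.index(c.pressure_bin)],
        p[9 + c.catalyst],
        p[6] if c.acid else 1.0 - p[6],
        p[7] if c.base else 1.0 - p[7],
        p[8] if c.poison else 1.0 - p[8],
    ])
    return q


def score_combination(
    probs: np.ndarray, c: ConditionCombination, vocab: ConditionVocabulary
) -> float:
    """Likelihood L = -mean(log q) over the six component probabilities."""
    q = np.clip(component_probabilities(probs, c, vocab), EPS, 1.0)
    return float(-np.mean(np.log(q)))


def _combo_arrays(combos: list[ConditionCombination]) -> dict[str, np.ndarray]:
    return {
        "t": np.array([BINS.index(c.temperature_bin) for c in combos]),
        "p": np.array([3 + BINS.index(c.pressure_bin) for c in combos]),
        "cat": np.array([9 + c.catalyst for c in combos]),
        "acid": np.array([c.acid for c in combos], dtype=bool),
        "base": np.array([c.base for c in combos], dtype=bool),
        "poison": np.array([c.poison for c in combos], dtype=bool),
    }


def score_all(
    probs: np.ndarray,
    combos: list[ConditionCombination],
    vocab: ConditionVocabulary,
) -> np.ndarray:
    """Vectorized L for every combination (same value as score_combination)."""
    p = np.asarray(probs, dtype=float)
    a = _combo_arrays(combos)
    logs = np.log(np.clip(p, EPS, 1.0))
    log1m = np.log(np.clip(1.0 - p, EPS, 1.0))
    total = logs[a["t"]] + logs[a["p"]] + logs[a["cat"]]
    for flag, bit in (("acid", 6), ("base", 7), ("poison", 8)):
        total += np.where(a[flag], logs[bit], log1m[bit])
    return -total / 6.0


def rank_probabilities(
    probs: np.ndarray,
    combos: list[ConditionCombination],
    vocab: ConditionVocabulary,
) -> RankedConditions:
    """Rank combinations ascending in L; ties broken by bit-vector order.

    ``combos`` are expected in the deterministic order produced by
    :func:`condrank.conditions.enumerate_combinations` (bit-vector order), so
    a stable argsort realizes the tie-break.
    """
    L = score_all(probs, combos, vocab)
    order = np.argsort(L, kind="stable")
    return RankedConditions([combos[i] for i in order], L[order])


def rank_lrm(
    model: LikelihoodRankingModel,
    x: np.ndarray,
    combos: list[ConditionCombination],
    vocab: ConditionVocabulary,
) -> RankedConditions:
    probs = model.predict_proba(x)[0]
    return rank_probabilities(probs, combos, vocab)


# --- ranking kNN ------------------------------------------------------------

@dataclass
class KNNIndex:
    """Training descriptors (PCA space) aligned with their conditions."""

    X: np.ndarray
    conditions: list[ConditionCombination]
    k: int = 10
    _nn: NearestNeighbors = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.conditions):
            raise ValueError("descriptor matrix rows must align with conditions")
        if self.X.shape[0] == 0:
            raise ValueError("empty kNN index")
        self._nn = NearestNeighbors(metric="euclidean").fit(self.X)


def rank_knn(index: KNNIndex, x: np.ndarray) -> RankedConditions:
    """Conditions of the k nearest training reactions, nearest first; when a
    combination recurs at a farther neighbor, the farther occurrence is
    dropped."""
    k = index.k
    if k > index.X.shape[0]:
        warnings.warn(
            f"k={k} exceeds training size {index.X.shape[0]}; truncating",
            stacklevel=2,
        )
        k = index.X.shape[0]
    dist, idx = index._nn.kneighbors(np.atleast_2d(x), n_neighbors=k)
    seen: set[ConditionCombination] = set()
    combos, scores = [], []
    for d, i in zip(dist[0], idx[0]):
        c = index.conditions[int(i)]
        if c in seen:
            continue
        seen.add(c)
        combos.append(c)
        scores.append(float(d))
    return RankedConditions(combos, np.array(scores))


# --- null model -------------------------------------------------------------

def rank_null(
    training_conditions: list[ConditionCombination],
    vocab: ConditionVocabulary,
) -> RankedConditions:
    """Unique training combinations by descending frequency (ties: bit-vector
    order); the same list is returned regardless of the query reaction."""
    if not training_conditions:
        raise ValueError("null model needs a non-empty training condition list")
    freq = Counter(training_conditions)
    combos = sorted(freq, key=lambda c: (-freq[c], c.bits_key(vocab)))
    return RankedConditions(combos, np.array([-freq[c] for c in combos], dtype=float))
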