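"""Linear-chain CRF: scoring, partition function, gradients, Viterbi decoding.

The chain score of a label sequence ``y`` for a sentence of length ``n`` is

    Score(X, y) = sum_{i=1..n} P[i, y_i] + sum_{i=0..n} T[y_i, y_{i+1}]

with ``y_0 = start`` and ``y_{n+1} = stop``: two augmented states carry the
boundary transition scores, so the transition matrix has shape
``(k+2, k+2)`` for ``k`` labels.  ``P`` is the emission matrix produced by the
encoder's linear projection.

Structurally invalid transitions (into ``start``, out of ``stop``, and —
when BIO constraints are enabled — ``I-X`` after anything other than
``B-X``/``I-X``, including the sentence start) are clamped to a large
negative sentinel rather than ``-inf`` so every quantity stays finite and
differentiable; the sentinel is far below any reachable score, so such
transitions never appear in decoded output.

All partition arithmetic is done in log-space with max-shifting, so scores
up to ``±1e3`` per term cause no overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .corpus import BioTag

__all__ = [
    "NEG_INF",
    "LabelSet",
    "build_constraint_mask",
    "effective_transitions",
    "crf_score",
    "crf_log_partition",
    "crf_nll",
    "crf_nll_grad",
    "viterbi_decode",
    "DecodeError",
]

#: Finite stand-in for -infinity inside masked transition entries.
NEG_INF = -1.0e4

def _has_valid_path(n: int, labelset: LabelSet, mask: np.ndarray | None) -> bool:
    """Boolean forward reachability over the constraint mask."""
    if mask is None:
        return True
    k = labelset.k
    reach = mask[labelset.start_state, :k].copy()
    for _ in range(n - 1):
        reach = (reach[:, None] & mask[:k, :k]).any(axis=0)
    return bool((reach & mask[:k, labelset.stop_state]).any())


class DecodeError(RuntimeError):
    """Raised when no constraint-valid label path exists."""


@dataclass(frozen=True)
class LabelSet:
    """Ordered BIO label inventory plus the two augmented boundary states.

    ``start_state`` and ``stop_state`` index rows/columns ``k`` and ``k+1``
    of the augmented transition matrix.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if "O" not in self.labels:
            raise ValueError("label set must contain O")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels")
        for lab in self.labels:
            tag = BioTag.parse(lab)  # validates prefix syntax
            if tag.prefix == "I" and f"B-{tag.entity_type}" not in self.labels:
                raise ValueError(f"I label {lab} without matching B label")

    @classmethod
    def from_labels(cls, labels: list[str] | tuple[str, ...]) -> "LabelSet":
        return cls(tuple(labels))

    @property
    def k(self) -> int:
        return len(self.labels)

    @property
    def k_augmented(self) -> int:
        return self.k + 2

    @property
    def start_state(self) -> int:
        return self.k

    @property
    def stop_state(self) -> int:
        return self.k + 1

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def tags(self, indices: list[int] | np.ndarray) -> list[BioTag]:
        return [BioTag.parse(self.labels[int(i)]) for i in indices]


def build_constraint_mask(
    labelset: LabelSet, bio_constraints: bool = True
) -> np.ndarray:
    """Boolean ``(k+2, k+2)`` matrix of structurally allowed transitions.

    Always disallowed: transitions into ``start`` and out of ``stop``.
    With ``bio_constraints``: ``start -> I-X`` for any X, and ``a -> I-X``
    unless ``a`` is ``B-X`` or ``I-X`` of the same type.
    """
    k = labelset.k
    kk = labelset.k_augmented
    start, stop = labelset.start_state, labelset.stop_state
    mask = np.ones((kk, kk), dtype=bool)
    mask[:, start] = False
    mask[stop, :] = False
    mask[start, stop] = False  # empty sentences do not occur
    if bio_constraints:
        parsed = [BioTag.parse(lab) for lab in labelset.labels]
        for b, tag_b in enumerate(parsed):
            if tag_b.prefix != "I":
                continue
            mask[start, b] = False
            for a, tag_a in enumerate(parsed):
                if tag_a.prefix == "O" or tag_a.entity_type != tag_b.entity_type:
                    mask[a, b] = False
    return mask


def effective_transitions(T: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    """Transition scores with masked entries replaced by the sentinel."""
    if mask is None:
        return T
    return np.where(mask, T, NEG_INF)


def _check_shapes(P: np.ndarray, T: np.ndarray, labelset: LabelSet) -> None:
    if P.ndim != 2 or P.shape[1] != labelset.k:
        raise ValueError(f"emission matrix must be (n, {labelset.k}), got {P.shape}")
    if T.shape != (labelset.k_augmented, labelset.k_augmented):
        raise ValueError(
            f"transition matrix must be {(labelset.k_augmented,) * 2}, got {T.shape}"
        )


def crf_score(
    P: np.ndarray,
    T: np.ndarray,
    y: list[int] | np.ndarray,
    labelset: LabelSet,
    mask: np.ndarray | None = None,
) -> float:
    """Exact chain score of label sequence ``y``: n emission + n+1 transition terms."""
    _check_shapes(P, T, labelset)
    y = np.asarray(y, dtype=np.int64)
    n = P.shape[0]
    if y.shape != (n,):
        raise ValueError(f"label sequence length {y.shape} != sentence length {n}")
    if y.min() < 0 or y.max() >= labelset.k:
        raise IndexError("label index out of range")
    Te = effective_transitions(T, mask)
    score = float(P[np.arange(n), y].sum())
    score += float(Te[labelset.start_state, y[0]])
    score += float(Te[y[:-1], y[1:]].sum())
    score += float(Te[y[-1], labelset.stop_state])
    return score


def _forward_alphas(
    P: np.ndarray, Te: np.ndarray, labelset: LabelSet
) -> np.ndarray:
    n, k = P.shape
    alphas = np.empty((n, k))
    alphas[0] = Te[labelset.start_state, :k] + P[0]
    inner = Te[:k, :k]
    for t in range(1, n):
        alphas[t] = logsumexp(alphas[t - 1][:, None] + inner, axis=0) + P[t]
    return alphas


def crf_log_partition(
    P: np.ndarray,
    T: np.ndarray,
    labelset: LabelSet,
    mask: np.ndarray | None = None,
) -> float:
    """Log of the sum over all label sequences of ``exp(crf_score)``.

    Computed by the forward recursion in log-space.  Raises
    :class:`DecodeError` when every path crosses a masked transition.
    """
    _check_shapes(P, T, labelset)
    if not _has_valid_path(P.shape[0], labelset, mask):
        raise DecodeError("no constraint-valid label path exists")
    Te = effective_transitions(T, mask)
    alphas = _forward_alphas(P, Te, labelset)
    return float(logsumexp(alphas[-1] + Te[: labelset.k, labelset.stop_state]))


def crf_nll(
    P: np.ndarray,
    T: np.ndarray,
    y: list[int] | np.ndarray,
    labelset: LabelSet,
    mask: np.ndarray | None = None,
) -> float:
    """Negative log-likelihood ``log Z - Score(X, y)``; non-negative."""
    return crf_log_partition(P, T, labelset, mask) - crf_score(P, T, y, labelset, mask)


def crf_nll_grad(
    P: np.ndarray,
    T: np.ndarray,
    y: list[int] | np.ndarray,
    labelset: LabelSet,
    mask: np.ndarray | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """NLL plus analytic gradients w.r.t. emissions and transitions.

    Uses forward-backward marginals: ``dNLL/dP[t,j]`` is the posterior
    probability of label ``j`` at position ``t`` minus the gold indicator;
    ``dNLL/dT[a,b]`` is the expected transition count minus the observed
    count.  Masked transition entries receive zero gradient (the sentinel is
    a constant, not the parameter).
    """
    _check_shapes(P, T, labelset)
    y = np.asarray(y, dtype=np.int64)
    n, k = P.shape
    start, stop = labelset.start_state, labelset.stop_state
    if not _has_valid_path(n, labelset, mask):
        raise DecodeError("no constraint-valid label path exists")
    Te = effective_transitions(T, mask)
    inner = Te[:k, :k]

    alphas = _forward_alphas(P, Te, labelset)
    betas = np.empty((n, k))
    betas[-1] = Te[:k, stop]
    for t in range(n - 2, -1, -1):
        betas[t] = logsumexp(inner + (P[t + 1] + betas[t + 1])[None, :], axis=1)
    log_z = float(logsumexp(alphas[-1] + betas[-1]))

    # Unary marginals -> emission gradient.
    unary = np.exp(alphas + betas - log_z)
    dP = unary.copy()
    dP[np.arange(n), y] -= 1.0

    # Pairwise marginals -> transition gradient.
    dT = np.zeros_like(T)
    dT[start, :k] = np.exp(Te[start, :k] + P[0] + betas[0] - log_z)
    dT[:k, stop] = np.exp(alphas[-1] + Te[:k, stop] - log_z)
    for t in range(n - 1):
        dT[:k, :k] += np.exp(
            alphas[t][:, None] + inner + (P[t + 1] + betas[t + 1])[None, :] - log_z
        )
    dT[start, y[0]] -= 1.0
    dT[y[-1], stop] -= 1.0
    np.subtract.at(dT, (y[:-1], y[1:]), 1.0)
    if mask is not None:
        dT[~mask] = 0.0

    nll = log_z - crf_score(P, T, y, labelset, mask)
    return nll, dP, dT


def viterbi_decode(
    P: np.ndarray,
    T: np.ndarray,
    labelset: LabelSet,
    mask: np.ndarray | None = None,
) -> tuple[list[int], float]:
    """Highest-scoring label sequence and its score.

    Ties are broken deterministically by taking the lowest label index at
    every backpointer and at the final state.
    """
    _check_shapes(P, T, labelset)
    n, k = P.shape
    start, stop = labelset.start_state, labelset.stop_state
    Te = effective_transitions(T, mask)
    inner = Te[:k, :k]

    if not _has_valid_path(n, labelset, mask):
        raise DecodeError("no constraint-valid label path exists")
    delta = Te[start, :k] + P[0]
    backptr = np.empty((n, k), dtype=np.int64)
    for t in range(1, n):
        cand = delta[:, None] + inner  # (prev, next)
        backptr[t] = np.argmax(cand, axis=0)
        delta = cand[backptr[t], np.arange(k)] + P[t]
    final = delta + Te[:k, stop]
    best_last = int(np.argmax(final))
    best_score = float(final[best_last])

    path = [best_last]
    for t in range(n - 1, 0, -1):
        path.append(int(backptr[t, path[-1]]))
    path.reverse()
    return path, best_score
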