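"""Independent brute-force oracles used across the test suite.

Everything here enumerates, sums term-by-term, or applies a textbook formula
directly; nothing imports the recursions it is used to check.
"""

from __future__ import annotations

import itertools

import numpy as np

from bionerkit.corpus import BioTag, EntitySpan
from bionerkit.crf import NEG_INF, LabelSet


def all_sequences(n: int, k: int):
    return itertools.product(range(k), repeat=n)


def path_score_termwise(
    P: np.ndarray,
    T: np.ndarray,
    y,
    labelset: LabelSet,
    mask: np.ndarray | None = None,
) -> float:
    """Sum the n emission terms and n+1 transition terms one by one."""
    Te = T.copy()
    if mask is not None:
        Te = np.where(mask, Te, NEG_INF)
    augmented = [labelset.start_state, *y, labelset.stop_state]
    total = 0.0
    for i, lab in enumerate(y):
        total += P[i, lab]
    for a, b in zip(augmented[:-1], augmented[1:]):
        total += Te[a, b]
    return total


def exhaustive_max(P, T, labelset, mask=None):
    """(best sequence, best score) by enumerating every label sequence."""
    n, k = P.shape
    best, best_y = -np.inf, None
    for y in all_sequences(n, k):
        s = path_score_termwise(P, T, y, labelset, mask)
        if s > best:
            best, best_y = s, list(y)
    return best_y, best


def exhaustive_log_partition(P, T, labelset, mask=None) -> float:
    """log-sum-exp over every label sequence's score, via a shifted sum."""
    n, k = P.shape
    scores = np.array(
        [path_score_termwise(P, T, y, labelset, mask) for y in all_sequences(n, k)]
    )
    m = scores.max()
    return float(m + np.log(np.exp(scores - m).sum()))


def segment_runs(tag_strings: list[str]) -> list[EntitySpan]:
    """Brute-force B-then-I run segmentation on string tags (strict reading)."""
    spans = []
    i, n = 0, len(tag_strings)
    while i < n:
        if tag_strings[i].startswith("B-"):
            etype = tag_strings[i][2:]
            j = i + 1
            while j < n and tag_strings[j] == f"I-{etype}":
                j += 1
            spans.append(EntitySpan(i, j, etype))
            i = j
        else:
            i += 1
    return spans


def prf_formulas(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Scalar precision/recall/F1 with the zero-denominator-is-zero convention."""
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def count_matches_setwise(gold, pred) -> tuple[int, int, int]:
    """tp/fp/fn by set intersection over (start, end, type) triples."""
    gs = {(s.start, s.end, s.entity_type) for s in gold}
    ps = {(s.start, s.end, s.entity_type) for s in pred}
    tp = len(gs & ps)
    return tp, len(ps) - tp, len(gs) - tp


def random_instance(rng: np.random.Generator, n: int, k: int, labelset: LabelSet):
    """A random emission/transition pair on the augmented state space."""
    P = rng.normal(0.0, 2.0, size=(n, k))
    T = rng.normal(0.0, 1.0, size=(labelset.k_augmented, labelset.k_augmented))
    return P, T


def bio_labelset(k: int) -> LabelSet:
    """A BIO label inventory of size k: O plus alternating B-/I- types."""
    labels = ["O"]
    t = 0
    while len(labels) < k:
        labels.append(f"B-T{t}")
        if len(labels) < k:
            labels.append(f"I-T{t}")
        t += 1
    return LabelSet.from_labels(labels)
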