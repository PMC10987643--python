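"""Linear-chain CRF against exhaustive enumeration and numerical gradients."""

import numpy as np
import pytest

from bionerkit.crf import (
    DecodeError,
    LabelSet,
    build_constraint_mask,
    crf_log_partition,
    crf_nll,
    crf_nll_grad,
    crf_score,
    viterbi_decode,
)
from bionerkit.corpus import BioTag, validate_bio

from .oracles import (
    all_sequences,
    bio_labelset,
    exhaustive_log_partition,
    exhaustive_max,
    path_score_termwise,
    random_instance,
)


@pytest.fixture
def ls3():
    return LabelSet.from_labels(["O", "B-Disease", "I-Disease"])


class TestScore:
    def test_zero_transitions(self, ls3):
        P = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        T = np.zeros((5, 5))
        assert crf_score(P, T, [0, 1], ls3) == pytest.approx(2.0)

    def test_single_boundary_perturbation(self, ls3):
        P = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        T = np.zeros((5, 5))
        T[ls3.start_state, 0] = 0.5
        assert crf_score(P, T, [0, 1], ls3) == pytest.approx(2.5)

    def test_matches_termwise_oracle(self):
        rng = np.random.default_rng(11)
        ls = bio_labelset(4)
        for _ in range(100):
            n = int(rng.integers(1, 7))
            P, T = random_instance(rng, n, ls.k, ls)
            y = rng.integers(0, ls.k, size=n)
            expected = path_score_termwise(P, T, list(y), ls)
            assert crf_score(P, T, y, ls) == pytest.approx(expected, rel=1e-12)

    def test_label_out_of_range(self, ls3):
        with pytest.raises(IndexError):
            crf_score(np.zeros((2, 3)), np.zeros((5, 5)), [0, 3], ls3)


class TestLogPartition:
    def test_single_label_single_path(self):
        ls = LabelSet.from_labels(["O"])
        rng = np.random.default_rng(0)
        P = rng.normal(size=(4, 1))
        T = rng.normal(size=(3, 3))
        expected = P.sum() + T[ls.start_state, 0] + 3 * T[0, 0] + T[0, ls.stop_state]
        assert crf_log_partition(P, T, ls) == pytest.approx(float(expected))

    def test_uniform_scores_count_paths(self):
        ls = LabelSet.from_labels(["O", "B-X"])
        P = np.zeros((3, 2))
        T = np.zeros((4, 4))
        assert crf_log_partition(P, T, ls) == pytest.approx(3 * np.log(2.0))

    def test_matches_enumeration(self):
        rng = np.random.default_rng(5)
        ls = bio_labelset(4)
        P, T = random_instance(rng, 5, 4, ls)
        expected = exhaustive_log_partition(P, T, ls)
        assert crf_log_partition(P, T, ls) == pytest.approx(expected, rel=1e-10)

    def test_large_scores_stable(self, ls3):
        P = np.full((6, 3), 1.0e3)
        T = np.zeros((5, 5))
        lz = crf_log_partition(P, T, ls3)
        assert np.isfinite(lz)
        assert lz == pytest.approx(6e3 + 6 * np.log(3.0))


class TestNll:
    def test_single_path_zero_loss(self):
        ls = LabelSet.from_labels(["O"])
        P = np.random.default_rng(1).normal(size=(3, 1))
        T = np.zeros((3, 3))
        assert crf_nll(P, T, [0, 0, 0], ls) == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative_and_matches_enumerated_posterior(self):
        rng = np.random.default_rng(7)
        ls = bio_labelset(3)
        for _ in range(20):
            n = int(rng.integers(1, 6))
            P, T = random_instance(rng, n, 3, ls)
            y = list(rng.integers(0, 3, size=n))
            nll = crf_nll(P, T, y, ls)
            assert nll >= -1e-12
            scores = np.array(
                [path_score_termwise(P, T, s, ls) for s in all_sequences(n, 3)]
            )
            probs = np.exp(scores - scores.max())
            probs /= probs.sum()
            idx = sum(lab * 3 ** (n - 1 - i) for i, lab in enumerate(y))
            assert np.exp(-nll) == pytest.approx(probs[idx], rel=1e-8)

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(13)
        ls = bio_labelset(3)
        P, T = random_instance(rng, 4, 3, ls)
        total = sum(
            np.exp(
                crf_score(P, T, list(y), ls) - crf_log_partition(P, T, ls)
            )
            for y in all_sequences(4, 3)
        )
        assert total == pytest.approx(1.0, rel=1e-10)


class TestGradients:
    @pytest.mark.parametrize("use_mask", [False, True])
    def test_central_difference(self, use_mask):
        rng = np.random.default_rng(21)
        ls = bio_labelset(4)
        mask = build_constraint_mask(ls) if use_mask else None
        eps = 1e-6
        for _ in range(10):
            n = int(rng.integers(2, 6))
            P, T = random_instance(rng, n, 4, ls)
            y = [0] * n  # all-O: always constraint-valid
            nll, dP, dT = crf_nll_grad(P, T, y, ls, mask)
            assert nll >= 0.0
            for _ in range(6):
                i, j = rng.integers(0, n), rng.integers(0, 4)
                Pp, Pm = P.copy(), P.copy()
                Pp[i, j] += eps
                Pm[i, j] -= eps
                num = (
                    crf_nll(Pp, T, y, ls, mask) - crf_nll(Pm, T, y, ls, mask)
                ) / (2 * eps)
                assert dP[i, j] == pytest.approx(num, rel=1e-4, abs=1e-7)
            for _ in range(6):
                a, b = rng.integers(0, ls.k_augmented, size=2)
                Tp, Tm = T.copy(), T.copy()
                Tp[a, b] += eps
                Tm[a, b] -= eps
                num = (
                    crf_nll(P, Tp, y, ls, mask) - crf_nll(P, Tm, y, ls, mask)
                ) / (2 * eps)
                assert dT[a, b] == pytest.approx(num, rel=1e-4, abs=1e-7)


class TestViterbi:
    def test_zero_transition_reduces_to_argmax(self, ls3):
        rng = np.random.default_rng(3)
        P = rng.normal(size=(5, 3))
        T = np.zeros((5, 5))
        path, score = viterbi_decode(P, T, ls3)
        assert path == list(P.argmax(axis=1))
        assert score == pytest.approx(P.max(axis=1).sum())

    def test_matches_exhaustive_max(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            k = int(rng.integers(1, 6))
            ls = bio_labelset(k)
            n = int(rng.integers(1, 7))
            P, T = random_instance(rng, n, k, ls)
            path, score = viterbi_decode(P, T, ls)
            best_y, best = exhaustive_max(P, T, ls)
            assert score == pytest.approx(best, rel=1e-10)
            assert score == pytest.approx(
                crf_score(P, T, path, ls), rel=1e-12
            )

    def test_constraint_mask_blocks_forbidden_bigram(self):
        ls = LabelSet.from_labels(["O", "B-X", "I-X"])
        mask = build_constraint_mask(ls)
        # Emissions overwhelmingly prefer O then I-X, which the mask forbids.
        P = np.array([[10.0, -10.0, -10.0], [-10.0, -10.0, 10.0]])
        T = np.zeros((5, 5))
        path, score = viterbi_decode(P, T, ls, mask)
        tags = ls.tags(path)
        assert validate_bio(tags) == []
        best_y, best = exhaustive_max(P, T, ls, mask)
        assert score == pytest.approx(best)

    def test_no_valid_path_raises(self):
        ls = LabelSet.from_labels(["O", "B-X", "I-X"])
        mask = build_constraint_mask(ls)
        mask[ls.start_state, :] = False  # nothing can start the sentence
        with pytest.raises(DecodeError):
            viterbi_decode(np.zeros((2, 3)), np.zeros((5, 5)), ls, mask)

    def test_monotonicity_in_decoded_emissions(self):
        rng = np.random.default_rng(29)
        ls = bio_labelset(3)
        P, T = random_instance(rng, 4, 3, ls)
        path, score = viterbi_decode(P, T, ls)
        P2 = P.copy()
        P2[2, path[2]] += 0.7
        _, score2 = viterbi_decode(P2, T, ls)
        assert score2 >= score


class TestConstraintMask:
    def test_rule_table_oracle(self):
        ls = LabelSet.from_labels(["O", "B-D", "I-D", "B-C", "I-C"])
        mask = build_constraint_mask(ls)
        start, stop = ls.start_state, ls.stop_state
        names = list(ls.labels) + ["<start>", "<stop>"]
        for a in range(ls.k_augmented):
            for b in range(ls.k_augmented):
                na, nb = names[a], names[b]
                allowed = True
                if nb == "<start>" or na == "<stop>":
                    allowed = False
                elif na == "<start>" and nb == "<stop>":
                    allowed = False
                elif nb.startswith("I-"):
                    t = nb[2:]
                    allowed = na in (f"B-{t}", f"I-{t}")
                assert mask[a, b] == allowed, (na, nb)

    def test_start_to_inside_masked(self):
        ls = LabelSet.from_labels(["O", "B-D", "I-D"])
        mask = build_constraint_mask(ls)
        assert not mask[ls.start_state, ls.index("I-D")]
        assert not mask[ls.index("O"), ls.index("I-D")]
        assert mask[ls.index("B-D"), ls.index("I-D")]
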