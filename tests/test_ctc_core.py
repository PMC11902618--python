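"""CTC loss and decoders against exhaustive enumeration oracles."""

import itertools

import numpy as np
import pytest

from mealvoice.ctc_core import (
    BeamConfig,
    Posteriorgram,
    best_path_decode,
    ctc_nll,
    ctc_posteriors,
    peaks_to_events,
    prefix_beam_search,
)
from mealvoice.labels import Vocabulary

from conftest import random_posteriorgram


def collapse(path, blank=0):
    """CTC collapse rule: merge repeats, then drop blanks."""
    out = []
    prev = None
    for v in path:
        if v != prev and v != blank:
            out.append(v)
        prev = v
    return tuple(out)


def brute_force_nll(logp, target):
    """Sum of path probabilities over every alignment collapsing to target."""
    T, V = logp.shape
    total = -np.inf
    for path in itertools.product(range(V), repeat=T):
        if collapse(path) == tuple(target):
            total = np.logaddexp(total, sum(logp[t, v] for t, v in enumerate(path)))
    return -total


def brute_force_best_labeling(logp):
    """Exhaustive max-total-probability labeling over all label sequences."""
    T, V = logp.shape
    scores = {}
    for path in itertools.product(range(V), repeat=T):
        lab = collapse(path)
        p = sum(logp[t, v] for t, v in enumerate(path))
        scores[lab] = np.logaddexp(scores.get(lab, -np.inf), p)
    return max(scores.items(), key=lambda kv: kv[1])


class TestCtcNll:
    def test_single_frame_closed_form(self):
        logp = np.log(np.array([[0.3, 0.7]]))
        assert ctc_nll(Posteriorgram(logp), [1]) == pytest.approx(-np.log(0.7))

    def test_empty_target_all_blank_path(self, rng):
        logp = random_posteriorgram(rng, 5, 3)
        assert ctc_nll(Posteriorgram(logp), []) == pytest.approx(-logp[:, 0].sum())

    def test_matches_exhaustive_enumeration(self, rng):
        # 3-frame / 2-label instance against full path enumeration
        logp = random_posteriorgram(rng, 3, 3)
        expected = brute_force_nll(logp, [1, 2])
        assert ctc_nll(Posteriorgram(logp), [1, 2]) == pytest.approx(expected, abs=1e-8)

    def test_oracle_equivalence_random_instances(self, rng):
        for _ in range(60):
            T = int(rng.integers(1, 7))
            V = int(rng.integers(2, 5))
            L = int(rng.integers(0, 4))
            target = list(rng.integers(1, V, size=L))
            logp = random_posteriorgram(rng, T, V)
            got = ctc_nll(Posteriorgram(logp), target)
            want = brute_force_nll(logp, target)
            if np.isinf(want):
                assert np.isinf(got)
            else:
                assert got == pytest.approx(want, abs=1e-8)

    def test_unalignable_target_signals_infinity(self, rng):
        logp = random_posteriorgram(rng, 2, 3)
        assert np.isinf(ctc_nll(Posteriorgram(logp), [1, 1, 2]))

    def test_loss_decreases_when_target_probability_rises(self, rng):
        logp = random_posteriorgram(rng, 4, 3)
        base = ctc_nll(Posteriorgram(logp), [1])
        boosted = logp.copy()
        boosted[2, 1] += 0.5  # raise a target-consistent probability
        boosted -= np.log(np.exp(boosted).sum(axis=1, keepdims=True))
        # renormalization shifts others down; loss must not increase
        assert ctc_nll(Posteriorgram(boosted), [1]) <= base + 1e-12

    def test_gradient_matches_finite_differences(self, rng):
        logits = rng.normal(0, 1, size=(4, 3))
        target = [1, 2]

        def loss(z):
            lp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
            nll, _ = ctc_posteriors(lp, target)
            return nll

        lp = logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))
        _, gamma = ctc_posteriors(lp, target)
        analytic = np.exp(lp) - gamma
        eps = 1e-6
        for t in range(4):
            for v in range(3):
                z = logits.copy()
                z[t, v] += eps
                up = loss(z)
                z[t, v] -= 2 * eps
                dn = loss(z)
                num = (up - dn) / (2 * eps)
                assert num == pytest.approx(analytic[t, v], abs=1e-5)


class TestBestPathDecode:
    def make_post(self, argmax_ids, V=3):
        T = len(argmax_ids)
        logp = np.full((T, V), np.log(0.1 / (V - 1)))
        for t, v in enumerate(argmax_ids):
            logp[t] = np.log((1 - 0.9) / (V - 1))
            logp[t, v] = np.log(0.9)
        return Posteriorgram(logp)

    def test_collapse_rule(self, small_vocab):
        post = self.make_post([0, 1, 1, 0, 1])
        dec = best_path_decode(post, small_vocab)
        assert dec.symbols() == ["a", "a"]
        assert dec.frame_times == [0.02 * 1, 0.02 * 4]

    def test_all_blank_empty(self, small_vocab):
        dec = best_path_decode(self.make_post([0, 0, 0]), small_vocab)
        assert dec.symbols() == []

    def test_repeat_collapse_with_blank_separator(self, small_vocab):
        post = self.make_post([3, 3, 0, 3], V=5)
        dec = best_path_decode(post, small_vocab)
        assert dec.symbols() == ["#", "#"]
        assert dec.frame_times == [0.0, 0.02 * 3]


class TestPrefixBeamSearch:
    def test_single_frame_matches_closed_form(self, rng, small_vocab):
        logp = random_posteriorgram(rng, 1, 5)
        dec = prefix_beam_search(
            Posteriorgram(logp), small_vocab,
            BeamConfig(beam_width=1000, logp_prune=None, token_logp_min=None),
        )
        best_lab, best_score = brute_force_best_labeling(logp)
        assert tuple(small_vocab.index(s) for s in dec.symbols()) == best_lab
        assert dec.score == pytest.approx(best_score, abs=1e-9)

    def test_saturating_beam_equals_brute_force(self, rng):
        vocab = Vocabulary(["_", "a", "b"])
        for _ in range(30):
            logp = random_posteriorgram(rng, 4, 3)
            dec = prefix_beam_search(
                Posteriorgram(logp), vocab,
                BeamConfig(beam_width=10000, logp_prune=None, token_logp_min=None),
            )
            lab, score = brute_force_best_labeling(logp)
            assert tuple(vocab.index(s) for s in dec.symbols()) == lab
            assert dec.score == pytest.approx(score, abs=1e-8)

    def test_score_monotone_in_beam_width(self, rng, small_vocab):
        logp = random_posteriorgram(rng, 6, 5)
        scores = []
        for width in (1, 2, 5, 20, 100):
            dec = prefix_beam_search(
                Posteriorgram(logp), small_vocab,
                BeamConfig(beam_width=width, logp_prune=None, token_logp_min=None),
            )
            scores.append(dec.score)
        assert all(b >= a - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_certainty_pruning_degenerates_on_diffuse_posteriors(self, small_vocab):
        # uniform rows: no token reaches log-probability 0, nothing expands
        T, V = 4, 5
        logp = np.full((T, V), -np.log(V))
        dec = prefix_beam_search(
            Posteriorgram(logp), small_vocab,
            BeamConfig(beam_width=10, logp_prune=None, token_logp_min=0.0),
        )
        assert dec.symbols() == []


class TestPeaksToEvents:
    def test_frame_time_arithmetic(self, small_vocab):
        from mealvoice.ctc_core import DecodedSeq

        dec = DecodedSeq(
            [small_vocab.tokens[i] for i in (1, 3, 2, 4)],
            [2 * 0.02, 10 * 0.02, 30 * 0.02, 200 * 0.02],
            0.0,
        )
        events = peaks_to_events(dec)
        assert events == [
            ("chew", pytest.approx(0.20), pytest.approx(0.22)),
            ("swallow", pytest.approx(4.00), pytest.approx(4.02)),
        ]

    def test_no_event_tokens(self, small_vocab):
        from mealvoice.ctc_core import DecodedSeq

        dec = DecodedSeq([small_vocab.tokens[1]], [0.0], 0.0)
        assert peaks_to_events(dec) == []

    def test_adjacent_chews_stay_distinct(self, small_vocab):
        from mealvoice.ctc_core import DecodedSeq

        dec = DecodedSeq(
            [small_vocab.tokens[3], small_vocab.tokens[3]], [0.20, 0.24], 0.0
        )
        assert len(peaks_to_events(dec)) == 2
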