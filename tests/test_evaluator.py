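"""CER, allowance-window event matching, and F1 arithmetic."""

import numpy as np
import pytest

from mealvoice.evaluator import (
    AllowanceConfig,
    EventMatchResult,
    character_error_rate,
    f1_scores,
    match_events,
)
from mealvoice.labels import StrongLabelTrack, make_token


def dp_edit_distance(a, b):
    """Classic Wagner-Fischer dynamic program (independent oracle)."""
    m, n = len(a), len(b)
    d = np.zeros((m + 1, n + 1), dtype=int)
    d[:, 0] = np.arange(m + 1)
    d[0, :] = np.arange(n + 1)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            d[i, j] = min(
                d[i - 1, j] + 1,
                d[i, j - 1] + 1,
                d[i - 1, j - 1] + (a[i - 1] != b[j - 1]),
            )
    return int(d[m, n])


def track(entries):
    return StrongLabelTrack([(s, e, make_token(sym)) for s, e, sym in entries])


class TestCharacterErrorRate:
    def test_identity_zero(self):
        assert character_error_rate("abc", "abc") == 0.0

    def test_all_deletions(self):
        assert character_error_rate("abc", "") == 1.0

    def test_kitten_sitting(self):
        assert character_error_rate("kitten", "sitting") == pytest.approx(3 / 6)

    def test_empty_reference_raises(self):
        with pytest.raises(ValueError):
            character_error_rate("", "abc")

    def test_event_tokens_stripped(self):
        assert character_error_rate("a#b$c", "abc") == 0.0

    def test_matches_dp_oracle_on_random_pairs(self, rng):
        alphabet = "abcdefg"
        for _ in range(100):
            ref = "".join(rng.choice(list(alphabet), size=rng.integers(1, 10)))
            hyp = "".join(rng.choice(list(alphabet), size=rng.integers(0, 10)))
            want = dp_edit_distance(ref, hyp) / len(ref)
            assert character_error_rate(ref, hyp) == pytest.approx(want)

    def test_triangle_style_bound(self, rng):
        alphabet = "abcd"
        for _ in range(50):
            a, b, c = (
                "".join(rng.choice(list(alphabet), size=rng.integers(1, 8)))
                for _ in range(3)
            )
            lhs = character_error_rate(a, c) * len(a)
            rhs = character_error_rate(a, b) * len(a) + dp_edit_distance(b, c)
            assert lhs <= rhs + 1e-9


class TestMatchEvents:
    def test_direct_overlap_tp(self):
        r = match_events([("chew", 1.00, 1.02)], track([(1.01, 1.30, "#")]))
        assert (r.tp["chew"], r.fp["chew"], r.fn["chew"]) == (1, 0, 0)

    def test_swallow_collar_expansion(self):
        # expanded start 1.00 - 0.01 = 0.99; prediction ending 1.005 overlaps
        r = match_events([("swallow", 0.985, 1.005)], track([(1.00, 1.20, "$")]))
        assert r.tp["swallow"] == 1

    def test_outside_collar_is_fp_and_fn(self):
        r = match_events([("swallow", 0.90, 0.92)], track([(1.00, 1.20, "$")]))
        assert (r.tp["swallow"], r.fp["swallow"], r.fn["swallow"]) == (0, 1, 1)

    def test_one_to_one_consumption(self):
        r = match_events(
            [("chew", 1.05, 1.07), ("chew", 1.10, 1.12)], track([(1.00, 1.30, "#")])
        )
        assert (r.tp["chew"], r.fp["chew"], r.fn["chew"]) == (1, 1, 0)

    def test_class_mismatch_not_matched(self):
        r = match_events([("chew", 1.05, 1.07)], track([(1.00, 1.30, "$")]))
        assert r.fp["chew"] == 1
        assert r.fn["swallow"] == 1

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            match_events([("cough", 0.0, 0.02)], track([]))

    def test_shift_invariance(self, rng):
        entries = [(0.5, 0.7, "#"), (1.5, 1.9, "$"), (2.5, 2.6, "#")]
        preds = [("chew", 0.55, 0.57), ("swallow", 1.6, 1.62), ("chew", 3.5, 3.52)]
        base = match_events(preds, track(entries))
        d = 7.25
        shifted = match_events(
            [(k, a + d, b + d) for k, a, b in preds],
            track([(s + d, e + d, sym) for s, e, sym in entries]),
        )
        assert base.tp == shifted.tp and base.fp == shifted.fp and base.fn == shifted.fn

    def test_count_conservation_identities(self, rng):
        for _ in range(200):
            n_truth = int(rng.integers(0, 6))
            n_pred = int(rng.integers(0, 6))
            entries = []
            t = 0.0
            for _ in range(n_truth):
                t += rng.uniform(0.3, 1.0)
                entries.append((t, t + rng.uniform(0.05, 0.3), "#"))
            preds = sorted(
                [("chew", float(x), float(x) + 0.02) for x in rng.uniform(0, t + 1, n_pred)],
                key=lambda p: p[1],
            )
            r = match_events(preds, track(entries))
            assert r.tp["chew"] + r.fn["chew"] == n_truth
            assert r.tp["chew"] + r.fp["chew"] == n_pred

    def test_f1_monotone_in_allowance(self, rng):
        entries = [(1.0, 1.1, "#"), (2.0, 2.1, "#"), (3.0, 3.4, "$")]
        preds = [("chew", 0.95, 0.97), ("chew", 2.14, 2.16), ("swallow", 3.42, 3.44)]
        last = -1.0
        for allow in np.linspace(0.0, 0.2, 11):
            cfg = AllowanceConfig(chew_allowance_s=allow, swallow_allowance_s=allow)
            scores = f1_scores(match_events(preds, track(entries), cfg))
            f1 = scores["chew"]["f1"] + scores["swallow"]["f1"]
            assert f1 >= last - 1e-12
            last = f1


class TestF1Scores:
    def test_perfect(self):
        r = EventMatchResult()
        r.tp["chew"] = 10
        assert f1_scores(r)["chew"]["f1"] == 1.0

    def test_degenerate_zero(self):
        r = EventMatchResult()
        r.fn["swallow"] = 3
        assert f1_scores(r)["swallow"]["f1"] == 0.0

    def test_formula(self):
        r = EventMatchResult()
        r.tp["chew"], r.fp["chew"], r.fn["chew"] = 8, 2, 4
        s = f1_scores(r)["chew"]
        assert s["precision"] == pytest.approx(0.8)
        assert s["recall"] == pytest.approx(2 / 3)
        assert s["f1"] == pytest.approx(2 * 0.8 * (2 / 3) / (0.8 + 2 / 3))
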