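"""Synthetic mixture generation: padding, concatenation, corpus balance."""

import numpy as np
import pytest

from mealvoice.audio_io import AudioClip
from mealvoice.labels import (
    StrongLabelTrack,
    WeakLabelSeq,
    make_token,
)
from mealvoice.synthesis import (
    SourceItem,
    assemble_mixture,
    build_corpus,
    pad_to_fixed,
)

RATE = 1000  # toy rate keeps fixtures tiny


def speech_item(text, dur_s, seed=0):
    rng = np.random.default_rng(seed)
    clip = AudioClip(rng.normal(0, 0.2, int(dur_s * RATE)), RATE, f"sp:{text}:{seed}")
    weak = WeakLabelSeq([make_token(c) for c in text])
    return SourceItem(clip=clip, weak=weak, domain="speech")


def eating_item(dur_s, events, seed=0):
    rng = np.random.default_rng(seed)
    clip = AudioClip(rng.normal(0, 0.2, int(dur_s * RATE)), RATE, f"eat:{seed}")
    track = StrongLabelTrack([(s, e, make_token(sym)) for s, e, sym in events])
    weak = WeakLabelSeq([make_token(sym) for _, _, sym in events])
    return SourceItem(clip=clip, weak=weak, domain="eating", strong=track)


class TestPadToFixed:
    def test_full_length_item_no_padding(self):
        item = speech_item("ab", 10.0)
        ex = pad_to_fixed(item, seed=1)
        assert ex.clip.n_samples == 10 * RATE
        assert ex.segments[0].placed_offset_s == 0.0
        np.testing.assert_array_equal(ex.clip.mono(), item.clip.mono())

    def test_noise_split_sample_count(self):
        item = speech_item("ab", 8.0)
        ex = pad_to_fixed(item, seed=2)
        assert ex.clip.n_samples == 10 * RATE
        off = int(ex.segments[0].placed_offset_s * RATE)
        # the item is embedded bit-exactly; noise fills exactly 2 s
        np.testing.assert_array_equal(
            ex.clip.mono()[off : off + item.clip.n_samples], item.clip.mono()
        )
        assert (10 * RATE - item.clip.n_samples) == 2 * RATE

    def test_strong_labels_shifted_by_offset(self):
        item = eating_item(8.0, [(1.0, 1.2, "#")], seed=3)
        ex = pad_to_fixed(item, seed=3)
        off = ex.segments[0].placed_offset_s
        s, e, tok = ex.strong.entries[0]
        assert s == pytest.approx(1.0 + off)
        assert e == pytest.approx(1.2 + off)
        assert tok.symbol == "#"

    def test_oversized_item_rejected(self):
        with pytest.raises(ValueError):
            pad_to_fixed(speech_item("a", 10.0), target_dur_s=5.0)


class TestAssembleMixture:
    def test_single_full_item_degenerate(self):
        item = speech_item("ab", 10.0)
        ex = assemble_mixture([item], seed=4)
        np.testing.assert_array_equal(ex.clip.mono(), item.clip.mono())

    def test_speech_then_eating_concatenation(self):
        sp = speech_item("abc", 3.0, seed=5)
        eat = eating_item(4.0, [(0.5, 0.6, "#"), (1.5, 1.6, "#"), (2.5, 2.9, "$")], seed=6)
        ex = assemble_mixture([sp, eat], seed=7)
        assert ex.weak.symbols() == ["a", "b", "c", "#", "#", "$"]
        assert ex.clip.n_samples == 10 * RATE
        # three noise gaps total exactly 3 s
        gaps_s = 10.0 - 3.0 - 4.0
        assert gaps_s == pytest.approx(3.0)
        # both sources embedded bit-exactly at their offsets
        for item, seg in zip([sp, eat], ex.segments):
            off = int(seg.placed_offset_s * RATE)
            np.testing.assert_array_equal(
                ex.clip.mono()[off : off + item.clip.n_samples], item.clip.mono()
            )

    def test_space_token_between_speech_items(self):
        a = speech_item("ab", 3.0, seed=8)
        b = speech_item("cd", 3.0, seed=9)
        ex = assemble_mixture([a, b], seed=10)
        assert ex.weak.symbols() == ["a", "b", " ", "c", "d"]

    def test_overlong_items_rejected(self):
        with pytest.raises(ValueError):
            assemble_mixture([speech_item("a", 6.0), speech_item("b", 6.0)], seed=1)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            assemble_mixture([], seed=1)


class TestBuildCorpus:
    def make_pools(self, n_per_domain=7, dur=5.0):
        speech = [speech_item("abc"[: (i % 3) + 1], dur, seed=100 + i) for i in range(n_per_domain)]
        eating = [
            eating_item(dur, [(0.5, 0.6, "#"), (2.0, 2.4, "$")], seed=200 + i)
            for i in range(n_per_domain)
        ]
        return speech, eating

    def test_threshold_items_single_segment_padded(self):
        speech = [speech_item("ab", 8.0, seed=1)]
        eating = [eating_item(8.0, [(1.0, 1.1, "#")], seed=2)]
        train, val, _ = build_corpus(speech, eating, seed=3)
        examples = train + val
        assert len(examples) == 2
        assert all(len(ex.segments) == 1 for ex in examples)

    def test_balance_within_ten_percent(self):
        speech, eating = self.make_pools()
        _, _, balance = build_corpus(speech, eating, seed=5)
        total = balance.speech_dur_s + balance.eating_dur_s
        assert abs(balance.speech_dur_s - balance.eating_dur_s) / total <= 0.1

    def test_deterministic_manifests(self):
        speech, eating = self.make_pools()
        a = build_corpus(speech, eating, seed=9)
        b = build_corpus(speech, eating, seed=9)
        ma = [ex.manifest() for ex in a[0] + a[1]]
        mb = [ex.manifest() for ex in b[0] + b[1]]
        assert ma == mb

    def test_exact_duration_and_label_order_invariants(self):
        speech, eating = self.make_pools(5)
        train, val, _ = build_corpus(speech, eating, seed=11)
        for ex in train + val:
            assert ex.clip.n_samples == 10 * RATE
            # weak tokens equal concatenation over segments in offset order
            offsets = [g.placed_offset_s for g in ex.segments]
            assert offsets == sorted(offsets)
            # eating strong labels fall inside the example
            for s, e, _ in ex.strong.entries:
                assert 0 <= s < e <= 10.0 + 1e-9

    def test_every_source_consumed(self):
        speech, eating = self.make_pools(4)
        train, val, _ = build_corpus(speech, eating, seed=13)
        used = {g.source_id for ex in train + val for g in ex.segments}
        for it in speech + eating:
            assert it.clip.source_id in used

    def test_split_ratio(self):
        speech, eating = self.make_pools(10, dur=8.0)
        train, val, _ = build_corpus(speech, eating, seed=17)
        n = len(train) + len(val)
        assert abs(len(train) - round(0.9 * n)) <= 1

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            build_corpus([], [eating_item(5.0, [(0.5, 0.6, "#")])], seed=1)
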