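"""Synthetic mixed-corpus generation.

Real meals interleave talking and eating, but no public corpus records both.
The generator builds fixed-length (10 s) training examples from separate
speech and eating pools:

* clips of 7–10 s are padded to exactly 10 s with white noise split across
  both ends;
* clips under 7 s are concatenated with a partner whose domain is chosen to
  keep the cumulative speech/eating duration ratio balanced, further clips
  are appended while they fit, and white noise fills the gaps before,
  between and after the clips.

Weak labels are the ordered concatenation of the source sequences; strong
labels (eating events) are offset-shifted into mixture time. Every example
records per-segment provenance so embedding can be verified bit-exactly.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .audio_io import AudioClip
from .labels import (
    SPACE,
    StrongLabelTrack,
    WeakLabelSeq,
    shift_track,
    weak_from_strong,
)


@dataclass
class SourceItem:
    """A preprocessed mono source clip with its labels.

    ``strong`` is present for eating items (timed events) and absent for
    speech items, whose transcript lives in ``weak`` only.
    """

    clip: AudioClip
    weak: WeakLabelSeq
    domain: str  # "speech" | "eating"
    strong: StrongLabelTrack | None = None

    def __post_init__(self) -> None:
        if self.domain not in ("speech", "eating"):
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.clip.n_channels != 1:
            raise ValueError("source items must be mono")
        if self.duration_s > 10.0 + 1e-9:
            raise ValueError("items longer than 10 s are excluded upstream")

    @property
    def duration_s(self) -> float:
        return self.clip.duration_s


@dataclass
class Segment:
    """Provenance of one source placement inside a mixture."""

    source_id: str
    domain: str
    placed_offset_s: float
    source_dur_s: float


@dataclass
class SyntheticExample:
    """A fixed-length mixture with weak/strong labels and provenance."""

    clip: AudioClip
    weak: WeakLabelSeq
    strong: StrongLabelTrack
    segments: list[Segment]
    rng_seed: int

    def manifest(self) -> dict:
        return {
            "clip_id": self.weak.clip_id,
            "rng_seed": self.rng_seed,
            "duration_s": self.clip.duration_s,
            "weak": self.weak.symbols(),
            "strong": [[s, e, t.symbol] for s, e, t in self.strong.entries],
            "segments": [
                [g.source_id, g.domain, g.placed_offset_s, g.source_dur_s]
                for g in self.segments
            ],
        }


@dataclass
class BalanceState:
    """Cumulative seconds of material per domain, against a target ratio."""

    speech_dur_s: float = 0.0
    eating_dur_s: float = 0.0
    target_ratio: float = 1.0

    def add(self, domain: str, dur_s: float) -> None:
        if domain == "speech":
            self.speech_dur_s += dur_s
        else:
            self.eating_dur_s += dur_s

    def deficit_domain(self) -> str:
        """The domain whose cumulative duration trails the target ratio."""
        # target_ratio = desired speech/eating
        if self.speech_dur_s < self.target_ratio * self.eating_dur_s:
            return "speech"
        return "eating"


def _noise(rng: np.random.Generator, n: int, level: float) -> np.ndarray:
    return rng.normal(0.0, level, size=n)


def _noise_level(items: list[SourceItem], noise_snr_db: float) -> float:
    """Noise sigma: pool-median RMS reduced by ``noise_snr_db`` decibels."""
    rms = [
        float(np.sqrt(np.mean(np.square(it.clip.mono()))))
        for it in items
        if it.clip.n_samples > 0
    ]
    median = float(np.median([r for r in rms if r > 0] or [1.0]))
    return median * 10.0 ** (-noise_snr_db / 20.0)


def _place(
    items: list[SourceItem],
    offsets_samples: list[int],
    target_dur_s: float,
    rate: int,
    noise_sigma: float,
    rng: np.random.Generator,
    seed: int,
    clip_id: str,
) -> SyntheticExample:
    """Assemble the mixture waveform and labels from placed items."""
    n_total = int(round(target_dur_s * rate))
    out = _noise(rng, n_total, noise_sigma)
    weak_tokens = []
    strong_entries = []
    segments = []
    prev_domain: str | None = None
    for item, off in zip(items, offsets_samples):
        n = item.clip.n_samples
        out[off : off + n] = item.clip.mono()
        if prev_domain == "speech" and item.domain == "speech":
            weak_tokens.append(SPACE)  # delimit concatenated utterances
        weak_tokens.extend(item.weak.tokens)
        if item.strong is not None:
            shifted = shift_track(item.strong, off / rate)
            strong_entries.extend(shifted.entries)
        segments.append(
            Segment(item.clip.source_id, item.domain, off / rate, item.duration_s)
        )
        prev_domain = item.domain
    clip = AudioClip(out, rate, source_id=clip_id)
    return SyntheticExample(
        clip=clip,
        weak=WeakLabelSeq(weak_tokens, clip_id=clip_id),
        strong=StrongLabelTrack(strong_entries, clip_id=clip_id),
        segments=segments,
        rng_seed=seed,
    )


def pad_to_fixed(
    item: SourceItem,
    target_dur_s: float = 10.0,
    noise_sigma: float = 1e-3,
    seed: int = 0,
    clip_id: str | None = None,
) -> SyntheticExample:
    """Pad one item to ``target_dur_s`` with white noise split across both ends.

    The left/right split is drawn uniformly so events land at varied
    positions within the fixed window.
    """
    rate = item.clip.sample_rate
    n_total = int(round(target_dur_s * rate))
    n_item = item.clip.n_samples
    if n_item > n_total:
        raise ValueError("item longer than the target duration")
    rng = np.random.default_rng(seed)
    offset = int(rng.integers(0, n_total - n_item + 1))
    return _place(
        [item],
        [offset],
        target_dur_s,
        rate,
        noise_sigma,
        rng,
        seed,
        clip_id or f"{item.clip.source_id}:pad",
    )


def assemble_mixture(
    items: list[SourceItem],
    target_dur_s: float = 10.0,
    noise_sigma: float = 1e-3,
    seed: int = 0,
    clip_id: str | None = None,
) -> SyntheticExample:
    """Concatenate items in order with white-noise gaps before/between/after."""
    if not items:
        raise ValueError("assemble_mixture needs at least one item")
    rate = items[0].clip.sample_rate
    if any(it.clip.sample_rate != rate for it in items):
        raise ValueError("all items must share one sample rate")
    n_total = int(round(target_dur_s * rate))
    lengths = [it.clip.n_samples for it in items]
    slack = n_total - sum(lengths)
    if slack < 0:
        raise ValueError("item durations exceed the target duration")
    rng = np.random.default_rng(seed)
    # Split the slack over len(items)+1 gaps uniformly at random.
    cuts = np.sort(rng.integers(0, slack + 1, size=len(items))) if slack else np.zeros(len(items), dtype=int)
    gaps = np.diff(np.concatenate([[0], cuts, [slack]]))
    offsets = []
    pos = 0
    for gap, n in zip(gaps[:-1], lengths):
        pos += int(gap)
        offsets.append(pos)
        pos += n
    return _place(
        items,
        offsets,
        target_dur_s,
        rate,
        noise_sigma,
        rng,
        seed,
        clip_id or "mix:" + "+".join(it.clip.source_id for it in items),
    )


def build_corpus(
    speech_items: list[SourceItem],
    eating_items: list[SourceItem],
    target_dur_s: float = 10.0,
    pad_threshold_s: float = 7.0,
    target_ratio: float = 1.0,
    noise_snr_db: float = 30.0,
    seed: int = 0,
    val_ratio: float = 0.1,
) -> tuple[list[SyntheticExample], list[SyntheticExample], BalanceState]:
    """Generate the synthetic corpus and split it 9:1 into train/validation.

    Every source item is consumed at least once. Items of at least
    ``pad_threshold_s`` go through the padding path; shorter items are
    concatenated with a partner chosen from the domain that reduces the
    cumulative speech/eating imbalance, then further random items are
    appended while they fit.
    """
    if not speech_items or not eating_items:
        raise ValueError("both source pools must be non-empty")
    rng = np.random.default_rng(seed)
    noise_sigma = _noise_level(speech_items + eating_items, noise_snr_db)
    balance = BalanceState(target_ratio=target_ratio)
    pools = {"speech": list(speech_items), "eating": list(eating_items)}
    # unconsumed primaries per domain, in seeded random order
    queues = {
        "speech": [speech_items[i] for i in rng.permutation(len(speech_items))],
        "eating": [eating_items[i] for i in rng.permutation(len(eating_items))],
    }
    examples: list[SyntheticExample] = []

    def draw_partner(domain: str, max_dur: float) -> SourceItem | None:
        """A pool item of ``domain`` fitting ``max_dur``; among fits, prefer
        the duration closest to the current domain deficit (reduces
        |speech_dur - eating_dur| the most without overshoot)."""
        fits = [it for it in pools[domain] if it.duration_s <= max_dur + 1e-9]
        if not fits:
            return None
        trail = abs(balance.speech_dur_s - balance.target_ratio * balance.eating_dur_s)
        best = min(fits, key=lambda it: abs(it.duration_s - trail))
        return best

    while queues["speech"] or queues["eating"]:
        # draw the next primary from the domain trailing the target ratio
        domain = balance.deficit_domain()
        if not queues[domain]:
            domain = "speech" if domain == "eating" else "eating"
        item = queues[domain].pop()
        ex_seed = int(rng.integers(0, 2 ** 31 - 1))
        clip_id = f"syn{len(examples):05d}"
        if item.duration_s >= pad_threshold_s:
            ex = pad_to_fixed(item, target_dur_s, noise_sigma, ex_seed, clip_id)
            balance.add(domain, item.duration_s)
        else:
            placed = [item]
            balance.add(domain, item.duration_s)
            room = target_dur_s - item.duration_s
            partner_domain = balance.deficit_domain()
            partner = draw_partner(partner_domain, room) or draw_partner(
                "speech" if partner_domain == "eating" else "eating", room
            )
            if partner is not None:
                placed.append(partner)
                balance.add(partner.domain, partner.duration_s)
                room -= partner.duration_s
            # fill remaining room with random extra clips while they fit
            while True:
                extra_domain = balance.deficit_domain()
                extra = draw_partner(extra_domain, room)
                if extra is None:
                    break
                placed.append(extra)
                balance.add(extra.domain, extra.duration_s)
                room -= extra.duration_s
            ex = assemble_mixture(placed, target_dur_s, noise_sigma, ex_seed, clip_id)
        examples.append(ex)

    # balancing pass: top up the trailing domain with reused source clips
    # (same-domain mixtures are a permitted outcome) until the corpus-level
    # duration ratio is comfortably inside tolerance
    for _ in range(len(examples)):
        total = balance.speech_dur_s + balance.eating_dur_s
        if total == 0 or abs(balance.speech_dur_s - balance.eating_dur_s) / total <= 0.05:
            break
        domain = balance.deficit_domain()
        gap = abs(balance.speech_dur_s - balance.target_ratio * balance.eating_dur_s)
        placed = []
        room = target_dur_s
        while room > 0 and gap > 0:
            extra = draw_partner(domain, min(room, gap + min(
                it.duration_s for it in pools[domain]
            )))
            if extra is None:
                break
            placed.append(extra)
            balance.add(domain, extra.duration_s)
            room -= extra.duration_s
            gap -= extra.duration_s
        if not placed:
            break
        ex_seed = int(rng.integers(0, 2 ** 31 - 1))
        examples.append(
            assemble_mixture(
                placed, target_dur_s, noise_sigma, ex_seed, f"syn{len(examples):05d}"
            )
        )

    n_val = max(1, int(round(len(examples) * val_ratio))) if len(examples) > 1 else 0
    perm = rng.permutation(len(examples))
    val = [examples[i] for i in perm[:n_val]]
    train = [examples[i] for i in perm[n_val:]]
    return train, val, balance


def write_corpus(examples: list[SyntheticExample], out_dir: str | os.PathLike) -> None:
    """Write WAV + TSV strong track + weak text + JSON manifest per example."""
    from .audio_io import write_wav
    from .labels import write_track

    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    manifest = []
    for ex in examples:
        base = os.path.join(out_dir, ex.weak.clip_id)
        write_wav(base + ".wav", ex.clip, dtype="float32")
        write_track(ex.strong, base + ".tsv")
        with open(base + ".weak.txt", "w", encoding="utf-8") as fh:
            fh.write("".join(ex.weak.symbols()) + "\n")
        manifest.append(ex.manifest())
    with open(os.path.join(out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, ensure_ascii=False)
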