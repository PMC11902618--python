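"""Connectionist temporal classification: loss, decoding, event extraction.

CTC aligns a T-frame posteriorgram with a shorter label sequence by summing
over all monotonic frame-to-label alignments, using a blank symbol to absorb
unlabeled frames and to separate repeated labels. Trained CTC models emit
each label as a sharp peak of 1–4 frames, so decoded event tokens are turned
into single-frame intervals for overlap-based scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .labels import Token, WeakLabelSeq

NEG_INF = -np.inf


@dataclass
class Posteriorgram:
    """Per-frame token log-probabilities at a 20 ms stride.

    ``logp`` has shape [T frames, V tokens]; each row log-sum-exps to 0.
    Token index 0 is the blank.
    """

    logp: np.ndarray
    frame_stride_s: float = 0.02
    clip_id: str = ""

    def __post_init__(self) -> None:
        self.logp = np.asarray(self.logp, dtype=np.float64)
        if self.logp.ndim != 2:
            raise ValueError("logp must be [T, V]")

    @property
    def n_frames(self) -> int:
        return self.logp.shape[0]

    @property
    def n_tokens(self) -> int:
        return self.logp.shape[1]


@dataclass
class BeamConfig:
    """Prefix beam-search settings.

    ``logp_prune`` drops beams trailing the best by more than its magnitude;
    ``token_logp_min`` expands only tokens whose frame log-probability is at
    least the threshold; ``history_prune`` merges beams sharing a collapsed
    prefix. No language model is integrated.
    """

    beam_width: int = 100
    logp_prune: float | None = -12.0
    token_logp_min: float | None = -1.2
    history_prune: bool = True
    use_lm: bool = False

    def __post_init__(self) -> None:
        if self.beam_width < 1:
            raise ValueError("beam_width must be >= 1")
        for thr in (self.logp_prune, self.token_logp_min):
            if thr is not None and thr > 0:
                raise ValueError("prune thresholds must be <= 0")
        if self.use_lm:
            raise NotImplementedError("language-model fusion is not implemented")


@dataclass
class DecodedSeq:
    """A collapsed (blank-free) label sequence with per-token emission times."""

    tokens: list[Token]
    frame_times: list[float]
    score: float
    frame_stride_s: float = 0.02

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.frame_times):
            raise ValueError("tokens and frame_times must align")

    def symbols(self) -> list[str]:
        return [t.symbol for t in self.tokens]

    def text(self) -> str:
        return "".join(self.symbols())


def _extended_targets(target: list[int], blank: int) -> np.ndarray:
    ext = np.full(2 * len(target) + 1, blank, dtype=np.int64)
    ext[1::2] = target
    return ext


def _min_frames(target: list[int]) -> int:
    """Minimum T that can align the target: |y| plus a blank per repeat."""
    repeats = sum(1 for a, b in zip(target, target[1:]) if a == b)
    return len(target) + repeats


def _forward_alphas(logp: np.ndarray, ext: np.ndarray, blank: int) -> np.ndarray:
    """Log-space alpha recursion; alpha[t, s] includes the emission at t."""
    T = logp.shape[0]
    S = len(ext)
    alpha = np.full((T, S), NEG_INF)
    alpha[0, 0] = logp[0, ext[0]]
    if S > 1:
        alpha[0, 1] = logp[0, ext[1]]
    # skip transition s-2 -> s allowed when ext[s] is non-blank and != ext[s-2]
    can_skip = np.zeros(S, dtype=bool)
    if S > 2:
        can_skip[2:] = (ext[2:] != blank) & (ext[2:] != ext[:-2])
    for t in range(1, T):
        prev = alpha[t - 1]
        stay = prev
        step = np.full(S, NEG_INF)
        step[1:] = prev[:-1]
        skip = np.full(S, NEG_INF)
        if S > 2:
            skip[2:] = prev[:-2]
        skip = np.where(can_skip, skip, NEG_INF)
        stacked = np.stack([stay, step, skip])
        m = stacked.max(axis=0)
        with np.errstate(invalid="ignore"):
            tot = np.where(
                np.isneginf(m),
                NEG_INF,
                m + np.log(np.exp(stacked - m).sum(axis=0)),
            )
        alpha[t] = tot + logp[t, ext]
    return alpha


def ctc_nll(post: Posteriorgram, target: WeakLabelSeq | list[int], vocab=None) -> float:
    """Negative log-likelihood of the target under the posteriorgram.

    Computed by the forward algorithm over all valid alignments. Returns
    ``inf`` when the target cannot be aligned in the available frames (an
    unalignable-target signal, distinct from numeric overflow).
    """
    if isinstance(target, WeakLabelSeq):
        if vocab is None:
            raise ValueError("a vocabulary is required to encode a WeakLabelSeq")
        ids = vocab.encode(target)
    else:
        ids = list(target)
    logp = post.logp
    if _min_frames(ids) > logp.shape[0]:
        return float("inf")
    ext = _extended_targets(ids, blank=0)
    alpha = _forward_alphas(logp, ext, blank=0)
    tail = alpha[-1, -1]
    if len(ext) > 1:
        tail = np.logaddexp(tail, alpha[-1, -2])
    return float(-tail)


def ctc_posteriors(logp: np.ndarray, target: list[int], blank: int = 0) -> tuple[float, np.ndarray]:
    """Forward-backward pass: (nll, per-frame alignment posterior over tokens).

    The returned ``gamma`` has the shape of ``logp``; each row sums to 1 over
    tokens. The training gradient with respect to pre-softmax logits is
    ``softmax(logits) - gamma``.
    """
    T, V = logp.shape
    if _min_frames(target) > T:
        return float("inf"), np.zeros_like(logp)
    ext = _extended_targets(target, blank)
    S = len(ext)
    alpha = _forward_alphas(logp, ext, blank)
    # beta via the forward recursion on the time-reversed problem
    beta_rev = _forward_alphas(logp[::-1], ext[::-1], blank)
    beta = beta_rev[::-1, ::-1]
    log_z = alpha[-1, -1] if S == 1 else np.logaddexp(alpha[-1, -1], alpha[-1, -2])
    # alpha and beta both include the frame-t emission: subtract it once
    with np.errstate(invalid="ignore"):
        occ = alpha + beta - logp[:, ext] - log_z
    occ = np.exp(np.where(np.isnan(occ), NEG_INF, occ))
    gamma = np.zeros((T, V))
    for s in range(S):
        gamma[:, ext[s]] += occ[:, s]
    return float(-log_z), gamma


def best_path_decode(post: Posteriorgram, vocab) -> DecodedSeq:
    """Greedy decode: per-frame argmax, collapse repeats, drop blanks.

    Emission time of a token is the first frame of its argmax run. Argmax
    ties break toward the lowest token index (blank first) for determinism.
    """
    ids = np.argmax(post.logp, axis=1)
    tokens: list[Token] = []
    times: list[float] = []
    score = float(np.max(post.logp, axis=1).sum())
    prev = -1
    for t, v in enumerate(ids):
        if v != prev and v != 0:
            tokens.append(vocab.tokens[v])
            times.append(t * post.frame_stride_s)
        prev = v
    return DecodedSeq(tokens, times, score, post.frame_stride_s)


def prefix_beam_search(post: Posteriorgram, vocab, cfg: BeamConfig | None = None) -> DecodedSeq:
    """Prefix beam search over collapsed label sequences.

    Beams are scored by total probability over all alignments mapping to the
    prefix (blank and non-blank endings tracked separately). With pruning
    disabled and a saturating beam this returns the exact maximum-probability
    labeling.
    """
    cfg = cfg or BeamConfig()
    logp = post.logp
    T, V = logp.shape
    # prefix -> [p_blank, p_nonblank] in log space, plus emission frames
    beams: dict[tuple[int, ...], list] = {(): [0.0, NEG_INF, []]}
    for t in range(T):
        frame = logp[t]
        candidates = (
            [v for v in range(1, V) if frame[v] >= cfg.token_logp_min]
            if cfg.token_logp_min is not None
            else list(range(1, V))
        )
        nxt: dict[tuple[int, ...], list] = {}

        def bucket(prefix: tuple[int, ...]) -> list:
            entry = nxt.get(prefix)
            if entry is None:
                entry = [NEG_INF, NEG_INF, None]
                nxt[prefix] = entry
            return entry

        for prefix, (pb, pnb, times) in beams.items():
            total = np.logaddexp(pb, pnb)
            # blank extension keeps the prefix
            entry = bucket(prefix)
            entry[0] = np.logaddexp(entry[0], total + frame[0])
            if entry[2] is None:
                entry[2] = times
            last = prefix[-1] if prefix else None
            for v in candidates:
                p_tok = frame[v]
                if v == last:
                    # repeating the last token without a blank stays collapsed
                    entry = bucket(prefix)
                    entry[1] = np.logaddexp(entry[1], pnb + p_tok)
                    if entry[2] is None:
                        entry[2] = times
                    new_mass = pb + p_tok  # emission after a blank extends
                else:
                    new_mass = total + p_tok
                new_prefix = prefix + (v,)
                entry = bucket(new_prefix)
                entry[1] = np.logaddexp(entry[1], new_mass)
                if entry[2] is None:
                    entry[2] = times + [t]
        scored = sorted(
            nxt.items(),
            key=lambda kv: (-np.logaddexp(kv[1][0], kv[1][1]), kv[0]),
        )
        if cfg.logp_prune is not None and scored:
            best = np.logaddexp(scored[0][1][0], scored[0][1][1])
            scored = [
                kv
                for kv in scored
                if np.logaddexp(kv[1][0], kv[1][1]) >= best + cfg.logp_prune
            ]
        beams = dict(scored[: cfg.beam_width])
    best_prefix, (pb, pnb, times) = max(
        beams.items(), key=lambda kv: (np.logaddexp(kv[1][0], kv[1][1]), kv[0])
    )
    return DecodedSeq(
        [vocab.tokens[v] for v in best_prefix],
        [t * post.frame_stride_s for t in times],
        float(np.logaddexp(pb, pnb)),
        post.frame_stride_s,
    )


def peaks_to_events(
    dec: DecodedSeq, classes: tuple[str, ...] = ("chew", "swallow")
) -> list[tuple[str, float, float]]:
    """Turn decoded event tokens into single-frame intervals.

    Each chew/swallow token becomes ``(class, onset, onset + frame)``;
    character and space tokens are ignored. Adjacent event tokens stay
    distinct events (no merging).
    """
    events = []
    for tok, t in zip(dec.tokens, dec.frame_times):
        if tok.kind in classes:
            events.append((tok.kind, t, t + dec.frame_stride_s))
    return events
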