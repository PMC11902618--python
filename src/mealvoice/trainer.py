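"""Two-stage fine-tuning orchestration and the comparative protocols.

Speech recognition needs fine-grained linguistic representations; eating
event detection is a far simpler task. Training both at once tends to
degrade one or the other, so the two-stage recipe first adapts the model to
speech, then fine-tunes on a second corpus (eating-only, speech+eating, or
the synthetic mixtures). Seven comparative protocols cover the design space:

===  ==============================  =========================
id   stage-1 corpus                  stage-2 corpus
===  ==============================  =========================
A1   speech                          -
A2   eating                          -
B1   speech + eating (pooled)        -
B2   synthetic mixtures              -
C1   speech                          eating
C2   speech                          speech + eating (pooled)
C3   speech                          synthetic mixtures
===  ==============================  =========================

Optimization uses two parameter groups: an adaptive-delta method (lr 1.0,
rho 0.95, eps 1e-8) for the head and an adaptive-moment method (lr 1e-4)
for the encoder, each annealed (x0.8 / x0.9) whenever the relative
validation-loss improvement falls below 0.25%. The best checkpoint is the
epoch with minimum validation loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _nn
from .ctc_core import ctc_posteriors
from .labels import WeakLabelSeq


@dataclass
class OptimGroupConfig:
    """Per-group optimizer settings and the shared annealing rule.

    Defaults are the full-scale recipe: adaptive-delta (lr 1.0, rho 0.95,
    eps 1e-8) on the head, adaptive-moment (lr 1e-4) on the encoder.
    ``head_optimizer`` may be set to ``"adam"`` for small surrogate runs,
    where the adaptive-delta accumulators would need far more steps than a
    desk-scale corpus provides; the annealing schedule applies per group
    either way.
    """

    head_optimizer: str = "adadelta"
    head_lr: float = 1.0
    head_rho: float = 0.95
    head_eps: float = 1e-8
    encoder_lr: float = 1e-4
    anneal_factor_head: float = 0.8
    anneal_factor_encoder: float = 0.9
    improvement_threshold: float = 0.0025
    clip_norm: float | None = 5.0  # global gradient-norm clip per group

    def __post_init__(self) -> None:
        if self.head_optimizer not in ("adadelta", "adam"):
            raise ValueError("head_optimizer must be 'adadelta' or 'adam'")
        if not (0 < self.anneal_factor_head < 1 and 0 < self.anneal_factor_encoder < 1):
            raise ValueError("anneal factors must lie in (0, 1)")
        if self.improvement_threshold <= 0:
            raise ValueError("improvement threshold must be positive")

    def make_head_optimizer(self):
        if self.head_optimizer == "adadelta":
            return _nn.AdaDelta(lr=self.head_lr, rho=self.head_rho, eps=self.head_eps)
        return _nn.Adam(lr=self.head_lr)


_PROTOCOL_TABLE = {
    "A1": ("speech", None),
    "A2": ("eating", None),
    "B1": ("speech+eating", None),
    "B2": ("synthetic", None),
    "C1": ("speech", "eating"),
    "C2": ("speech", "speech+eating"),
    "C3": ("speech", "synthetic"),
}


@dataclass
class Protocol:
    """One comparative training protocol (A/B single-stage, C two-stage)."""

    id: str
    stage1_data: str = ""
    stage2_data: str | None = None

    def __post_init__(self) -> None:
        if self.id not in _PROTOCOL_TABLE:
            raise ValueError(f"unknown protocol {self.id!r}")
        default1, default2 = _PROTOCOL_TABLE[self.id]
        if not self.stage1_data:
            self.stage1_data = default1
        if self.stage2_data is None:
            self.stage2_data = default2
        if self.id.startswith(("A", "B")) and self.stage2_data is not None:
            raise ValueError("A/B protocols have no second stage")
        if self.id.startswith("C") and self.stage2_data is None:
            raise ValueError("C protocols require a stage-2 corpus")


def _clip(grads: list[np.ndarray], max_norm: float | None) -> list[np.ndarray]:
    """Scale the gradient group so its global L2 norm is at most max_norm."""
    if max_norm is None:
        return grads
    total = float(np.sqrt(sum(float(np.sum(g * g)) for g in grads)))
    if total <= max_norm or total == 0.0:
        return grads
    scale = max_norm / total
    return [g * scale for g in grads]


def split_train_val(corpus: list, ratio: float = 0.9, seed: int = 0) -> tuple[list, list]:
    """Disjoint 9:1 (by default) split; |train| = round(ratio * N)."""
    n = len(corpus)
    if n < 2:
        raise ValueError("corpus must contain at least 2 examples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(ratio * n))
    n_train = min(max(n_train, 1), n - 1)
    train = [corpus[i] for i in perm[:n_train]]
    val = [corpus[i] for i in perm[n_train:]]
    return train, val


def _encode_targets(model, pairs):
    out = []
    for x, y in pairs:
        symbols = y.symbols() if isinstance(y, WeakLabelSeq) else list(y)
        missing = [s for s in symbols if s not in model.vocab_]
        if missing:
            raise ValueError(
                f"model vocabulary does not cover the targets: {sorted(set(missing))}"
            )
        out.append((x, [model.vocab_.index(s) for s in symbols]))
    return out


def _eval_loss(model, pairs) -> float:
    """Mean CTC NLL in evaluation mode (dropout off, BN running stats)."""
    losses = []
    for x, ids in pairs:
        post = model.forward_logprobs(x)
        nll, _ = ctc_posteriors(post.logp, ids)
        if np.isfinite(nll):
            losses.append(nll)
    return float(np.mean(losses)) if losses else float("inf")


def train_stage(
    model,
    train: list,
    val: list,
    optim: OptimGroupConfig | None = None,
    epochs: int = 30,
    seed: int = 0,
    plateau_abort: tuple[int, float] | None = None,
) -> tuple[object, list[dict]]:
    """Train the model on (input, weak-label) pairs; return best checkpoint.

    Validation loss is computed each epoch; when its relative improvement
    over the previous epoch is below the threshold, both group learning
    rates are annealed by their factors. The returned model carries the
    parameters of the minimum-validation-loss epoch, and the history lists
    per-epoch train/val losses and per-group learning rates.
    """
    optim = optim or OptimGroupConfig()
    if not model.is_built():
        model.build()
    train = _encode_targets(model, train)
    val = _encode_targets(model, val)

    head_opt = optim.make_head_optimizer()
    enc_opt = _nn.Adam(lr=optim.encoder_lr)
    rng = np.random.default_rng(seed)
    batch_size = getattr(model, "batch_size", 8)
    frozen = model.encoder_config_.frozen_frontend

    history: list[dict] = []
    best_val = float("inf")
    best_state: dict | None = None
    prev_val: float | None = None

    def snapshot() -> dict:
        front, rest = model.parameter_partition()
        state = {k: v.copy() for k, v in {**front, **rest}.items()}
        state.update({f"bn::{k}": v.copy() for k, v in model.head_.bn_state().items()})
        return state

    def restore(state: dict) -> None:
        front, rest = model.parameter_partition()
        for k, v in {**front, **rest}.items():
            v[...] = state[k]
        for k, v in model.head_.bn_state().items():
            v[...] = state[f"bn::{k}"]

    for epoch in range(1, epochs + 1):
        order = rng.permutation(len(train))
        epoch_losses = []
        for b0 in range(0, len(order), batch_size):
            batch = [train[i] for i in order[b0 : b0 + batch_size]]
            waves = [model._as_wave(x)[0] for x, _ in batch]
            H, lengths = model.encoder_.forward_batch(waves, training=True)
            z = model.head_.forward(H, training=True, rng=rng)
            logp = _nn.log_softmax(z)
            grad_z = np.zeros_like(z)
            pos = 0
            n_used = 0
            batch_loss = 0.0
            for (x, ids), T in zip(batch, lengths):
                lp = logp[pos : pos + T]
                nll, gamma = ctc_posteriors(lp, ids)
                if np.isfinite(nll):
                    grad_z[pos : pos + T] = np.exp(lp) - gamma
                    batch_loss += nll
                    n_used += 1
                pos += T
            if n_used == 0:
                continue
            batch_loss /= n_used
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    f"NaN loss in epoch {epoch}, batch starting at index {b0}"
                )
            grad_z /= n_used
            dH = model.head_.backward(grad_z)
            hp = model.head_.params()
            hg = model.head_.grads()
            head_opt.step(
                [hp[k] for k in hp], _clip([hg[k] for k in hp], optim.clip_norm)
            )
            if not frozen:
                model.encoder_.backward(dH)
                ep = model.encoder_.params()
                eg = model.encoder_.grads()
                enc_opt.step(
                    [ep[k] for k in ep], _clip([eg[k] for k in ep], optim.clip_norm)
                )
            epoch_losses.append(batch_loss)

        # recalibrate batch-norm running stats on the training set so
        # evaluation mode matches training-mode behavior (small batches
        # leave momentum-averaged stats far from population moments)
        calib_waves = [model._as_wave(x)[0] for x, _ in train]
        H_cal, _ = model.encoder_.forward_batch(calib_waves, training=False)
        model.head_.calibrate_batchnorm(H_cal)

        val_loss = _eval_loss(model, val)
        if prev_val is not None:
            rel = (prev_val - val_loss) / abs(prev_val) if prev_val != 0 else 0.0
            if rel < optim.improvement_threshold:
                head_opt.lr *= optim.anneal_factor_head
                enc_opt.lr *= optim.anneal_factor_encoder
        prev_val = val_loss
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)) if epoch_losses else float("nan"),
                "val_loss": val_loss,
                "lr_head": head_opt.lr,
                "lr_encoder": enc_opt.lr,
            }
        )
        if val_loss < best_val:
            best_val = val_loss
            best_state = snapshot()
        if (
            plateau_abort is not None
            and epoch == plateau_abort[0]
            and best_val > plateau_abort[1] * history[0]["val_loss"]
        ):
            break  # stuck on the initial plateau; caller may restart

    if best_state is not None:
        restore(best_state)
    return model, history


def run_annealing_schedule(
    val_losses: list[float], optim: OptimGroupConfig | None = None
) -> list[tuple[float, float]]:
    """Learning rates after each epoch for a scripted val-loss sequence.

    Pure arithmetic mirror of the schedule in :func:`train_stage`, exposed
    so the annealing rule can be checked in closed form.
    """
    optim = optim or OptimGroupConfig()
    lr_h, lr_e = optim.head_lr, optim.encoder_lr
    out = []
    prev = None
    for v in val_losses:
        if prev is not None:
            rel = (prev - v) / abs(prev) if prev != 0 else 0.0
            if rel < optim.improvement_threshold:
                lr_h *= optim.anneal_factor_head
                lr_e *= optim.anneal_factor_encoder
        prev = v
        out.append((lr_h, lr_e))
    return out


def run_protocol(
    protocol: Protocol | str,
    corpora: dict[str, list],
    seed: int = 0,
    model_params: dict | None = None,
    optim: OptimGroupConfig | None = None,
    epochs: int = 30,
    stage2_epochs: int | None = None,
    speech_test=None,
    eating_test=None,
    allowance=None,
):
    """Execute one protocol end to end and evaluate it.

    ``corpora`` maps corpus names (``speech``, ``eating``, ``synthetic``,
    ``speech+eating``) to lists of (input, WeakLabelSeq) pairs. Stage-1
    vocabulary is derived from the stage-1 corpus targets; stage-2 extends
    it with the chew/swallow event tokens before resuming from the stage-1
    best checkpoint. Returns (model, report dict, histories).
    """
    from .labels import BLANK_SYMBOL
    from .model import CTCRecognizer

    if isinstance(protocol, str):
        protocol = Protocol(protocol)
    for name in [protocol.stage1_data] + (
        [protocol.stage2_data] if protocol.stage2_data else []
    ):
        if name not in corpora:
            raise ValueError(f"protocol {protocol.id} requires corpus {name!r}")

    def corpus_symbols(pairs):
        syms = set()
        for _, y in pairs:
            syms.update(t.symbol for t in y)
        return syms

    stage1 = corpora[protocol.stage1_data]
    vocab = [BLANK_SYMBOL] + sorted(corpus_symbols(stage1))
    params = dict(model_params or {})
    params.setdefault("seed", seed)
    model = CTCRecognizer(vocab_symbols=vocab, **params).build()

    train1, val1 = split_train_val(stage1, seed=seed)
    model, hist1 = train_stage(model, train1, val1, optim, epochs=epochs, seed=seed)
    histories = {"stage1": hist1}

    if protocol.stage2_data is not None:
        frame_rate_before = model.encoder_.hop
        vocab_before = model.vocab_.symbols
        stage2 = corpora[protocol.stage2_data]
        new_syms = sorted(corpus_symbols(stage2) - set(model.vocab_.symbols))
        model.extend_vocab(new_syms, seed=seed)
        assert model.encoder_.hop == frame_rate_before, "frame rate must survive resume"
        assert model.vocab_.symbols[: len(vocab_before)] == vocab_before, (
            "stage-1 vocabulary must be preserved on resume"
        )
        train2, val2 = split_train_val(stage2, seed=seed + 1)
        model, hist2 = train_stage(
            model,
            train2,
            val2,
            optim,
            epochs=stage2_epochs if stage2_epochs is not None else epochs,
            seed=seed + 1,
        )
        histories["stage2"] = hist2

    report = None
    if speech_test is not None or eating_test is not None:
        from .evaluator import AllowanceConfig, evaluate_run

        report = evaluate_run(
            model,
            speech_test=speech_test,
            eating_test=eating_test,
            cfg=allowance or AllowanceConfig(),
        )
    return model, report, histories
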