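"""The recognition network: frame encoder plus fully connected CTC head.

The full-scale system puts a self-supervised waveform encoder (wav2vec 2.0
family, feature extractor frozen) under a 4-layer fully connected head of
width 1024 with leaky-rectifier activations, batch normalization and dropout
0.15, emitting per-frame log-probabilities over the token vocabulary at a
20 ms stride. Here the encoder seam is pluggable: the shipped surrogate is a
CPU-sized learnable filterbank front end (windowed sinusoid projections,
log-energy, context stacking, one hidden projection) that preserves the
frame rate and the frozen-front-end semantics; an external pretrained
encoder can be attached through the same interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import _nn
from .audio_io import AudioClip
from .ctc_core import Posteriorgram
from .labels import Vocabulary

CHECKPOINT_VERSION = 1


@dataclass
class EncoderConfig:
    """Frame-encoder settings; the 20 ms stride is fixed by the evaluator."""

    kind: str = "surrogate"  # or "pretrained-ssl-adapter"
    frame_stride_s: float = 0.02
    feature_dim: int = 64
    n_filters: int = 32
    context: int = 2  # frames of context stacked on each side
    frozen_frontend: bool = True
    fmin_hz: float = 120.0

    def __post_init__(self) -> None:
        if abs(self.frame_stride_s - 0.02) > 1e-12:
            raise ValueError("frame stride must be 0.02 s (evaluation assumes it)")
        if self.kind not in ("surrogate", "pretrained-ssl-adapter"):
            raise ValueError(f"unknown encoder kind {self.kind!r}")


@dataclass
class HeadConfig:
    """Fully connected head settings (defaults match the full-scale model)."""

    n_layers: int = 4
    width: int = 1024
    dropout_p: float = 0.15
    vocab_size: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.n_layers < 1:
            raise ValueError("need at least one FC layer")


class SurrogateEncoder:
    """Learnable filterbank front end emitting one feature row per 20 ms.

    A frame of 2x the hop is projected onto windowed cosine/sine pairs at
    log-spaced center frequencies; log magnitude-energy gives phase-invariant
    features, followed by a per-channel affine, +/-``context`` frame
    stacking, and one leaky-rectified projection to ``feature_dim``.
    """

    def __init__(self, cfg: EncoderConfig, sample_rate: int, rng: np.random.Generator):
        self.cfg = cfg
        self.sample_rate = int(sample_rate)
        self.hop = int(round(cfg.frame_stride_s * sample_rate))
        self.win = 2 * self.hop
        K = cfg.n_filters
        fmax = 0.45 * sample_rate
        freqs = np.geomspace(cfg.fmin_hz, fmax, K)
        t = np.arange(self.win) / sample_rate
        window = np.hanning(self.win)
        self.C = (window[:, None] * np.cos(2 * np.pi * freqs[None, :] * t[:, None]))
        self.S = (window[:, None] * np.sin(2 * np.pi * freqs[None, :] * t[:, None]))
        self.gain = np.ones(K)
        self.bias = np.zeros(K)
        d_ctx = (2 * cfg.context + 1) * K
        self.proj = _nn.Linear(d_ctx, cfg.feature_dim, rng)
        self._eps = 1e-8
        self._cache: list | None = None
        self._grads: dict[str, np.ndarray] = {}

    # -- shape helpers -------------------------------------------------
    def n_frames(self, n_samples: int) -> int:
        return max(1, n_samples // self.hop)

    def _frame(self, wave: np.ndarray) -> np.ndarray:
        T = self.n_frames(len(wave))
        need = (T - 1) * self.hop + self.win
        padded = np.pad(wave, (0, max(0, need - len(wave))))
        idx = np.arange(self.win)[None, :] + self.hop * np.arange(T)[:, None]
        return padded[idx]

    def _stack_context(self, A: np.ndarray) -> np.ndarray:
        c = self.cfg.context
        T = A.shape[0]
        cols = []
        for d in range(-c, c + 1):
            shifted = np.zeros_like(A)
            if d < 0:
                shifted[-d:] = A[:T + d]
            elif d > 0:
                shifted[: T - d] = A[d:]
            else:
                shifted = A
            cols.append(shifted)
        return np.concatenate(cols, axis=1)

    def _unstack_context(self, dZ: np.ndarray) -> np.ndarray:
        c = self.cfg.context
        K = self.cfg.n_filters
        T = dZ.shape[0]
        dA = np.zeros((T, K))
        for j, d in enumerate(range(-c, c + 1)):
            block = dZ[:, j * K : (j + 1) * K]
            if d < 0:
                dA[: T + d] += block[-d:]
            elif d > 0:
                dA[d:] += block[: T - d]
            else:
                dA += block
        return dA

    def forward(self, wave: np.ndarray, training: bool = False) -> np.ndarray:
        H, _ = self.forward_batch([wave], training)
        return H

    def forward_batch(
        self, waves: list[np.ndarray], training: bool = False
    ) -> tuple[np.ndarray, list[int]]:
        """Pooled forward over a batch: rows of all clips' frames stacked.

        Context stacking never crosses clip boundaries. Returns the pooled
        feature matrix and per-clip frame counts for un-pooling.
        """
        Xs, Zs = [], []
        lengths = []
        UVs = []
        for wave in waves:
            X = self._frame(np.asarray(wave, dtype=np.float64))
            U = X @ self.C
            V = X @ self.S
            E2 = U * U + V * V + self._eps
            L = 0.5 * np.log(E2)
            A = self.gain * L + self.bias
            Zs.append(self._stack_context(A))
            Xs.append(X)
            UVs.append((U, V, E2, L))
            lengths.append(X.shape[0])
        Z = np.concatenate(Zs, axis=0)
        H0 = self.proj.forward(Z, training)
        H = _nn.leaky_relu(H0)
        if training:
            self._cache = [Xs, UVs, lengths, H0]
        return H, lengths

    def backward(self, dH: np.ndarray) -> None:
        """Accumulate gradients for the frontend parameters (unfrozen path)."""
        Xs, UVs, lengths, H0 = self._cache
        dH0 = _nn.leaky_relu_grad(H0, dH)
        dZ = self.proj.backward(dH0)
        gC = np.zeros_like(self.C)
        gS = np.zeros_like(self.S)
        ggain = np.zeros_like(self.gain)
        gbias = np.zeros_like(self.bias)
        pos = 0
        for X, (U, V, E2, L), T in zip(Xs, UVs, lengths):
            dA = self._unstack_context(dZ[pos : pos + T])
            pos += T
            ggain += (dA * L).sum(axis=0)
            gbias += dA.sum(axis=0)
            dL = dA * self.gain
            dE2 = 0.5 * dL / E2
            gC += X.T @ (2 * U * dE2)
            gS += X.T @ (2 * V * dE2)
        self._grads = {"C": gC, "S": gS, "gain": ggain, "bias": gbias}

    def params(self) -> dict[str, np.ndarray]:
        out = {"C": self.C, "S": self.S, "gain": self.gain, "bias": self.bias}
        out.update({f"proj.{k}": v for k, v in self.proj.params().items()})
        return out

    def grads(self) -> dict[str, np.ndarray]:
        out = {k: self._grads.get(k, np.zeros_like(v)) for k, v in
               [("C", self.C), ("S", self.S), ("gain", self.gain), ("bias", self.bias)]}
        out.update({f"proj.{k}": v for k, v in self.proj.grads().items()})
        return out

    def zero_grads(self) -> None:
        self._grads = {}
        self.proj.gW = np.zeros_like(self.proj.W)
        self.proj.gb = np.zeros_like(self.proj.b)


class FCHead:
    """FC blocks (linear, batch-norm, leaky rectifier, dropout) + projection."""

    def __init__(self, d_in: int, cfg: HeadConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.blocks = []
        d = d_in
        for _ in range(cfg.n_layers):
            self.blocks.append(
                {
                    "lin": _nn.Linear(d, cfg.width, rng),
                    "bn": _nn.BatchNorm(cfg.width),
                    "drop": _nn.Dropout(cfg.dropout_p),
                }
            )
            d = cfg.width
        self.out = _nn.Linear(d, cfg.vocab_size, rng)
        # damped output projection: untrained posteriors near-uniform (row
        # entropy >= 0.9 log V) while keeping enough asymmetry to break the
        # all-blank plateau quickly
        self.out.W *= 0.3
        self._pre: list[np.ndarray] = []

    def forward(self, H: np.ndarray, training: bool, rng: np.random.Generator | None = None) -> np.ndarray:
        self._pre = []
        x = H
        for blk in self.blocks:
            x = blk["lin"].forward(x, training)
            x = blk["bn"].forward(x, training)
            if training:
                self._pre.append(x)
            x = _nn.leaky_relu(x)
            x = blk["drop"].forward(x, training, rng)
        return self.out.forward(x, training)

    def backward(self, dz: np.ndarray) -> np.ndarray:
        dx = self.out.backward(dz)
        for blk, pre in zip(reversed(self.blocks), reversed(self._pre)):
            dx = blk["drop"].backward(dx)
            dx = _nn.leaky_relu_grad(pre, dx)
            dx = blk["bn"].backward(dx)
            dx = blk["lin"].backward(dx)
        return dx

    def params(self) -> dict[str, np.ndarray]:
        out = {}
        for i, blk in enumerate(self.blocks):
            out.update({f"fc{i}.{k}": v for k, v in blk["lin"].params().items()})
            out.update({f"bn{i}.{k}": v for k, v in blk["bn"].params().items()})
        out.update({f"out.{k}": v for k, v in self.out.params().items()})
        return out

    def grads(self) -> dict[str, np.ndarray]:
        out = {}
        for i, blk in enumerate(self.blocks):
            out.update({f"fc{i}.{k}": v for k, v in blk["lin"].grads().items()})
            out.update({f"bn{i}.{k}": v for k, v in blk["bn"].grads().items()})
        out.update({f"out.{k}": v for k, v in self.out.grads().items()})
        return out

    def bn_state(self) -> dict[str, np.ndarray]:
        out = {}
        for i, blk in enumerate(self.blocks):
            out.update({f"bn{i}.{k}": v for k, v in blk["bn"].state().items()})
        return out

    def calibrate_batchnorm(self, H: np.ndarray) -> None:
        """Set running statistics to exact population moments over ``H``.

        Small-batch training leaves the momentum-averaged running stats far
        from the population statistics, so evaluation-mode outputs drift
        from training-mode outputs; recalibrating on the training set after
        each epoch removes the mismatch.
        """
        x = H
        for blk in self.blocks:
            x = blk["lin"].forward(x, False)
            bn = blk["bn"]
            bn.run_mean = x.mean(axis=0)
            bn.run_var = x.var(axis=0)
            x = _nn.leaky_relu(bn.forward(x, False))


try:  # sklearn provides get_params/set_params and pipeline compatibility
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore[no-redef]
        pass


class CTCRecognizer(BaseEstimator):
    """Sequence recognizer mapping waveforms to token sequences via CTC.

    Follows the scikit-learn estimator protocol: hyperparameters are
    constructor arguments, :meth:`fit` trains on lists of waveforms/clips
    ``X`` and weak label sequences ``y``, fitted state lives in
    trailing-underscore attributes, and :meth:`predict` returns decoded
    token sequences.

    Parameters
    ----------
    vocab_symbols : list of str
        Token inventory, first entry must be the blank ``_``.
    sample_rate : int
        Expected waveform rate (16 kHz full scale; 4 kHz allowed for toys).
    n_layers, width, dropout_p : head architecture (defaults full-scale).
    feature_dim, n_filters, context, frozen_frontend : surrogate encoder.
    epochs, batch_size : training loop defaults used by :meth:`fit`.
    seed : master seed for initialization, batching, and dropout.
    """

    def __init__(
        self,
        vocab_symbols: list[str] | None = None,
        sample_rate: int = 16000,
        n_layers: int = 4,
        width: int = 1024,
        dropout_p: float = 0.15,
        feature_dim: int = 64,
        n_filters: int = 32,
        context: int = 2,
        frozen_frontend: bool = True,
        fmin_hz: float = 120.0,
        epochs: int = 30,
        batch_size: int = 8,
        seed: int = 0,
    ):
        self.vocab_symbols = vocab_symbols
        self.sample_rate = sample_rate
        self.n_layers = n_layers
        self.width = width
        self.dropout_p = dropout_p
        self.feature_dim = feature_dim
        self.n_filters = n_filters
        self.context = context
        self.frozen_frontend = frozen_frontend
        self.fmin_hz = fmin_hz
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed

    # -- construction --------------------------------------------------
    def build(self) -> "CTCRecognizer":
        """Initialize network weights (idempotent only by re-initializing)."""
        if not self.vocab_symbols:
            raise ValueError("vocab_symbols is required")
        self.vocab_ = Vocabulary(self.vocab_symbols)
        rng = np.random.default_rng(self.seed)
        enc_cfg = EncoderConfig(
            feature_dim=self.feature_dim,
            n_filters=self.n_filters,
            context=self.context,
            frozen_frontend=self.frozen_frontend,
            fmin_hz=self.fmin_hz,
        )
        head_cfg = HeadConfig(
            n_layers=self.n_layers,
            width=self.width,
            dropout_p=self.dropout_p,
            vocab_size=len(self.vocab_),
        )
        self.encoder_ = SurrogateEncoder(enc_cfg, self.sample_rate, rng)
        self.head_ = FCHead(self.feature_dim, head_cfg, rng)
        self.encoder_config_ = enc_cfg
        self.head_config_ = head_cfg
        return self

    def is_built(self) -> bool:
        return hasattr(self, "head_")

    # -- inference -----------------------------------------------------
    def _as_wave(self, x) -> tuple[np.ndarray, str]:
        if isinstance(x, AudioClip):
            if x.n_channels != 1:
                raise ValueError("model input must be mono")
            if x.sample_rate != self.sample_rate:
                raise ValueError(
                    f"clip rate {x.sample_rate} != model rate {self.sample_rate}"
                )
            return x.mono(), x.source_id
        return np.asarray(x, dtype=np.float64), ""

    def forward_logprobs(self, x) -> Posteriorgram:
        """Evaluation-mode forward pass to a normalized posteriorgram."""
        wave, clip_id = self._as_wave(x)
        H = self.encoder_.forward(wave, training=False)
        z = self.head_.forward(H, training=False)
        return Posteriorgram(_nn.log_softmax(z), 0.02, clip_id)

    def predict(self, X) -> list[list[str]]:
        """Best-path decode each input; returns token-symbol lists."""
        from .ctc_core import best_path_decode

        return [
            best_path_decode(self.forward_logprobs(x), self.vocab_).symbols()
            for x in X
        ]

    # -- training ------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        """Train with the two-group schedule; see trainer.train_stage."""
        from .trainer import OptimGroupConfig, split_train_val, train_stage

        if not self.is_built():
            self.build()
        pairs = list(zip(X, y))
        if X_val is None:
            train, val = split_train_val(pairs, seed=self.seed)
        else:
            train, val = pairs, list(zip(X_val, y_val))
        _, history = train_stage(
            self, train, val, OptimGroupConfig(), epochs=self.epochs, seed=self.seed
        )
        self.history_ = history
        return self

    # -- parameter partition and vocab growth ---------------------------
    def parameter_partition(self) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
        """(frontend params, remaining params); disjoint exact cover."""
        front = {f"encoder.{k}": v for k, v in self.encoder_.params().items()}
        rest = {f"head.{k}": v for k, v in self.head_.params().items()}
        return front, rest

    def extend_vocab(self, new_symbols: list[str], init_scale: float = 1e-2, seed: int = 0) -> None:
        """Grow the output layer for stage-2 tokens; existing rows preserved.

        New output columns start at small random values so the stage-1
        distribution is barely disturbed at the start of fine-tuning.
        """
        old = self.vocab_
        grown = old.extend(new_symbols)
        n_new = len(grown) - len(old)
        if n_new == 0:
            return
        rng = np.random.default_rng(seed)
        out = self.head_.out
        out.W = np.concatenate(
            [out.W, rng.normal(0, init_scale, size=(out.W.shape[0], n_new))], axis=1
        )
        # negative bias: new tokens start at low probability so the stage-1
        # output distribution is barely disturbed, yet reachable within a
        # short fine-tuning budget
        out.b = np.concatenate([out.b, np.full(n_new, -2.0)])
        out.gW = np.zeros_like(out.W)
        out.gb = np.zeros_like(out.b)
        self.vocab_ = grown
        self.vocab_symbols = grown.symbols
        self.head_config_.vocab_size = len(grown)

    # -- persistence ----------------------------------------------------
    def save(self, path: str) -> None:
        """Single-file checkpoint: config + weights + vocab + version."""
        front, rest = self.parameter_partition()
        arrays = {**front, **rest}
        arrays.update({f"head.{k}": v for k, v in self.head_.bn_state().items()})
        config = {
            "version": CHECKPOINT_VERSION,
            "params": self.get_params(deep=False),
        }
        np.savez(path, __config__=np.frombuffer(
            json.dumps(config).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str) -> "CTCRecognizer":
        data = np.load(path if str(path).endswith(".npz") else str(path) + ".npz")
        config = json.loads(bytes(data["__config__"]).decode())
        if config.get("version") != CHECKPOINT_VERSION:
            raise ValueError("unsupported checkpoint version")
        model = cls(**config["params"]).build()
        front, rest = model.parameter_partition()
        all_params = {**front, **rest}
        all_params.update(
            {f"head.{k}": v for k, v in model.head_.bn_state().items()}
        )
        for name, arr in all_params.items():
            arr[...] = data[name]
        return model


def forward_logprobs(model: CTCRecognizer, clip) -> Posteriorgram:
    """Module-level convenience wrapper over the estimator method."""
    return model.forward_logprobs(clip)


def trainable_parameter_partition(model: CTCRecognizer):
    """(frontend params, rest params); frontend is the frozen set when
    ``frozen_frontend`` is active."""
    return model.parameter_partition()
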