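"""LSTM with additive attention for streaming emotion classification.

The classifier consumes the per-segment sequence of spectral frames
x_1..x_n and applies a single LSTM layer:

    i_t = sigmoid(Wxi x_t + Whi h_{t-1} + bi)        input gate
    o_t = sigmoid(Wxo x_t + Who h_{t-1} + bo)        output gate
    f_t = sigmoid(Wxf x_t + Whf h_{t-1} + bf)        forget gate
    g_t = tanh   (Wxc x_t + Whc h_{t-1} + bc)        candidate cell
    C_t = f_t * C_{t-1} + i_t * g_t
    h_t = o_t * tanh(C_t)

followed by additive attention over the hidden sequence X = [h_1..h_n]:

    A = softmax(w^T X)   (weights in [0,1], summing to 1)
    Z = X A^T            (attention context)

Because recent frames carry the newest emotional state, the learned
scoring vector w lets the model up-weight the end of the window.  The
context Z is fused with the final hidden state h_n (concatenation by
default, or a learned convex gate), passed through dropout (training
only) and a dense softmax layer.

Everything is plain float64 NumPy.  Gradients are analytic
(backpropagation through time), optimization is Adam, and all
randomness flows from a single seeded Generator, so identical
configurations give bit-identical training histories.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import h5py
import numpy as np
from sklearn.model_selection import train_test_split

from .features import STFTConfig, SpectralFeatureTensor, featurize_segment
from .windowing import SegmentSet

FUSION_MODES = ("concat", "gated_sum")


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class LSTMParams:
    """The twelve learned blocks of a single LSTM layer."""

    Wxi: np.ndarray; Whi: np.ndarray; bi: np.ndarray
    Wxo: np.ndarray; Who: np.ndarray; bo: np.ndarray
    Wxf: np.ndarray; Whf: np.ndarray; bf: np.ndarray
    Wxc: np.ndarray; Whc: np.ndarray; bc: np.ndarray

    def __post_init__(self) -> None:
        d, m = self.Wxi.shape
        for name in ("Wxi", "Wxo", "Wxf", "Wxc"):
            if getattr(self, name).shape != (d, m):
                raise ValueError(f"{name} must be {d}x{m}")
        for name in ("Whi", "Who", "Whf", "Whc"):
            if getattr(self, name).shape != (d, d):
                raise ValueError(f"{name} must be {d}x{d}")
        for name in ("bi", "bo", "bf", "bc"):
            if getattr(self, name).shape != (d,):
                raise ValueError(f"{name} must have length {d}")
        for name in self.block_names():
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in {name}")

    @staticmethod
    def block_names() -> tuple[str, ...]:
        return ("Wxi", "Whi", "bi", "Wxo", "Who", "bo",
                "Wxf", "Whf", "bf", "Wxc", "Whc", "bc")

    @property
    def hidden_dim(self) -> int:
        return self.Wxi.shape[0]

    @property
    def input_dim(self) -> int:
        return self.Wxi.shape[1]


@dataclass
class HiddenState:
    h: np.ndarray
    C: np.ndarray


@dataclass
class AttentionParams:
    w: np.ndarray  # length-d scoring vector

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.w)):
            raise ValueError("non-finite attention parameters")


@dataclass
class ClassifierParams:
    fusion_mode: str
    W_out: np.ndarray  # n_classes x fused_dim
    b_out: np.ndarray  # n_classes
    gate_raw: float = 0.0  # gated_sum: lambda = sigmoid(gate_raw) in (0,1)

    def __post_init__(self) -> None:
        if self.fusion_mode not in FUSION_MODES:
            raise ValueError(f"unknown fusion mode {self.fusion_mode!r}")

    @property
    def gate(self) -> float:
        return float(_sigmoid(np.array(self.gate_raw)))


@dataclass
class ModelParams:
    """All learned parameters plus the metadata needed at inference."""

    lstm: LSTMParams
    attention: AttentionParams
    classifier: ClassifierParams
    class_alphabet: list[str]
    stft_config: dict | None = None
    feature_mean: np.ndarray | None = None
    feature_std: np.ndarray | None = None

    @property
    def hidden_dim(self) -> int:
        return self.lstm.hidden_dim

    @property
    def input_dim(self) -> int:
        return self.lstm.input_dim


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 0.001
    dropout_rate: float = 0.5
    max_epochs: int = 500
    patience: int = 50
    min_delta: float = 0.0001
    batch_size: int = 64
    seed: int = 0
    validation_fraction: float = 0.2
    hidden_dim: int = 128
    fusion_mode: str = "concat"
    #: z-score each feature using training-split statistics; the learned
    #: statistics are stored in the model and re-applied at inference
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if not (0 < self.validation_fraction < 1):
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.fusion_mode not in FUSION_MODES:
            raise ValueError(f"unknown fusion mode {self.fusion_mode!r}")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def init_params(input_dim: int, hidden_dim: int, n_classes: int,
                fusion_mode: str, rng: np.random.Generator
                ) -> tuple[LSTMParams, AttentionParams, ClassifierParams]:
    """Uniform(-k, k) initialization with k = 1/sqrt(hidden_dim)."""
    k = 1.0 / np.sqrt(hidden_dim)
    d, m = hidden_dim, input_dim

    def u(*shape):
        return rng.uniform(-k, k, size=shape)

    lstm = LSTMParams(
        Wxi=u(d, m), Whi=u(d, d), bi=u(d),
        Wxo=u(d, m), Who=u(d, d), bo=u(d),
        Wxf=u(d, m), Whf=u(d, d), bf=u(d),
        Wxc=u(d, m), Whc=u(d, d), bc=u(d),
    )
    att = AttentionParams(w=u(d))
    fused = 2 * d if fusion_mode == "concat" else d
    clf = ClassifierParams(fusion_mode=fusion_mode,
                           W_out=u(n_classes, fused), b_out=u(n_classes))
    return lstm, att, clf


# ---------------------------------------------------------------------------
# forward operations (single-instance public API)
# ---------------------------------------------------------------------------

def lstm_step(x_t: np.ndarray, prev: HiddenState, p: LSTMParams) -> HiddenState:
    """One LSTM cell update (all gates elementwise)."""
    x_t = np.asarray(x_t, dtype=np.float64)
    if x_t.shape != (p.input_dim,):
        raise ValueError(
            f"input of length {x_t.shape} does not match input_dim {p.input_dim}"
        )
    i = _sigmoid(p.Wxi @ x_t + p.Whi @ prev.h + p.bi)
    o = _sigmoid(p.Wxo @ x_t + p.Who @ prev.h + p.bo)
    f = _sigmoid(p.Wxf @ x_t + p.Whf @ prev.h + p.bf)
    g = np.tanh(p.Wxc @ x_t + p.Whc @ prev.h + p.bc)
    C = f * prev.C + i * g
    h = o * np.tanh(C)
    return HiddenState(h=h, C=C)


def lstm_sequence(frames: SpectralFeatureTensor | np.ndarray,
                  p: LSTMParams) -> np.ndarray:
    """Hidden-state matrix X (d x n): column t is h_t, zero initial state."""
    xs = frames.frames if isinstance(frames, SpectralFeatureTensor) else np.asarray(frames)
    if xs.ndim != 2 or xs.shape[0] < 1:
        raise ValueError("lstm_sequence needs at least one frame")
    state = HiddenState(h=np.zeros(p.hidden_dim), C=np.zeros(p.hidden_dim))
    cols = []
    for t in range(xs.shape[0]):
        state = lstm_step(xs[t], state, p)
        cols.append(state.h)
    return np.stack(cols, axis=1)


def additive_attention(X: np.ndarray, a: AttentionParams
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Attention weights A = softmax(w^T X) and context Z = X A^T."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be a d x n matrix with n >= 1")
    A = _softmax(a.w @ X)
    Z = X @ A
    return A, Z


def fuse_and_classify(Z: np.ndarray, h_n: np.ndarray,
                      c: ClassifierParams) -> np.ndarray:
    """Fuse attention context with the final hidden state, then softmax."""
    if c.fusion_mode == "concat":
        fused = np.concatenate([Z, h_n])
    else:
        lam = c.gate
        fused = lam * Z + (1.0 - lam) * h_n
    if c.W_out.shape[1] != fused.shape[0]:
        raise ValueError(
            f"classifier expects fused dim {c.W_out.shape[1]}, got {fused.shape[0]}"
        )
    return _softmax(c.W_out @ fused + c.b_out)


def forward(model: ModelParams, frames: np.ndarray) -> np.ndarray:
    """Class probabilities for one frame sequence (n x input_dim)."""
    x = np.asarray(frames, dtype=np.float64)
    if model.feature_mean is not None:
        x = (x - model.feature_mean) / model.feature_std
    X = lstm_sequence(x, model.lstm)
    _, Z = additive_attention(X, model.attention)
    return fuse_and_classify(Z, X[:, -1], model.classifier)


# ---------------------------------------------------------------------------
# batched forward/backward for training
# ---------------------------------------------------------------------------

def _forward_batch(xs, lstm, att, clf, dropout_mask=None):
    """Batched forward pass; returns probabilities and a cache for BPTT.

    xs: (B, n, input_dim).
    """
    B, n, _ = xs.shape
    d = lstm.hidden_dim
    h = np.zeros((B, d))
    C = np.zeros((B, d))
    steps = []
    Hs = np.empty((B, n, d))
    for t in range(n):
        x = xs[:, t, :]
        i = _sigmoid(x @ lstm.Wxi.T + h @ lstm.Whi.T + lstm.bi)
        o = _sigmoid(x @ lstm.Wxo.T + h @ lstm.Who.T + lstm.bo)
        f = _sigmoid(x @ lstm.Wxf.T + h @ lstm.Whf.T + lstm.bf)
        g = np.tanh(x @ lstm.Wxc.T + h @ lstm.Whc.T + lstm.bc)
        C_new = f * C + i * g
        tC = np.tanh(C_new)
        h_new = o * tC
        steps.append((x, h, C, i, o, f, g, tC))
        h, C = h_new, C_new
        Hs[:, t, :] = h
    s = Hs @ att.w
    A = _softmax(s, axis=1)
    Z = np.einsum("bn,bnd->bd", A, Hs)
    if clf.fusion_mode == "concat":
        fused = np.concatenate([Z, h], axis=1)
    else:
        lam = clf.gate
        fused = lam * Z + (1.0 - lam) * h
    dropped = fused if dropout_mask is None else fused * dropout_mask
    logits = dropped @ clf.W_out.T + clf.b_out
    probs = _softmax(logits, axis=1)
    cache = dict(xs=xs, steps=steps, Hs=Hs, A=A, Z=Z, h_n=h, fused=fused,
                 dropped=dropped, probs=probs, dropout_mask=dropout_mask,
                 lstm=lstm, att=att, clf=clf)
    return probs, cache


def _backward_batch(cache, y_onehot):
    """Gradients of mean cross-entropy w.r.t. every parameter block."""
    lstm, att, clf = cache["lstm"], cache["att"], cache["clf"]
    xs, Hs, A, Z = cache["xs"], cache["Hs"], cache["A"], cache["Z"]
    B, n, d = Hs.shape
    grads = {name: np.zeros_like(getattr(lstm, name))
             for name in LSTMParams.block_names()}
    dlogits = (cache["probs"] - y_onehot) / B
    grads["W_out"] = dlogits.T @ cache["dropped"]
    grads["b_out"] = dlogits.sum(axis=0)
    dfused = dlogits @ clf.W_out
    if cache["dropout_mask"] is not None:
        dfused = dfused * cache["dropout_mask"]
    if clf.fusion_mode == "concat":
        dZ = dfused[:, :d]
        dh_last = dfused[:, d:]
    else:
        lam = clf.gate
        dZ = lam * dfused
        dh_last = (1.0 - lam) * dfused
        grads["gate_raw"] = float(
            np.sum(dfused * (Z - cache["h_n"])) * lam * (1.0 - lam))
    # attention backward
    dA = np.einsum("bd,bnd->bn", dZ, Hs)
    dH = A[:, :, None] * dZ[:, None, :]
    ds = A * (dA - np.sum(A * dA, axis=1, keepdims=True))
    grads["w"] = np.einsum("bn,bnd->d", ds, Hs)
    dH += ds[:, :, None] * att.w[None, None, :]
    # BPTT
    dh_next = np.zeros((B, d))
    dC_next = np.zeros((B, d))
    for t in range(n - 1, -1, -1):
        x, h_prev, C_prev, i, o, f, g, tC = cache["steps"][t]
        dh = dH[:, t, :] + dh_next
        if t == n - 1:
            dh = dh + dh_last
        do = dh * tC
        dC = dh * o * (1.0 - tC ** 2) + dC_next
        di = dC * g
        dg = dC * i
        df = dC * C_prev
        dC_next = dC * f
        dzi = di * i * (1.0 - i)
        dzo = do * o * (1.0 - o)
        dzf = df * f * (1.0 - f)
        dzc = dg * (1.0 - g ** 2)
        for dz, wx, wh, b in ((dzi, "Wxi", "Whi", "bi"),
                              (dzo, "Wxo", "Who", "bo"),
                              (dzf, "Wxf", "Whf", "bf"),
                              (dzc, "Wxc", "Whc", "bc")):
            grads[wx] += dz.T @ x
            grads[wh] += dz.T @ h_prev
            grads[b] += dz.sum(axis=0)
        dh_next = (dzi @ lstm.Whi + dzo @ lstm.Who
                   + dzf @ lstm.Whf + dzc @ lstm.Whc)
    return grads


def _param_dict(lstm, att, clf):
    d = {name: getattr(lstm, name) for name in LSTMParams.block_names()}
    d["w"] = att.w
    d["W_out"] = clf.W_out
    d["b_out"] = clf.b_out
    return d


class _Adam:
    def __init__(self, params: dict, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, p in params.items():
            g = grads.get(k)
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * np.square(g)
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _stack_dataset(dataset):
    if isinstance(dataset, tuple) and len(dataset) == 2:
        xs, labels = np.asarray(dataset[0], dtype=np.float64), list(dataset[1])
    else:
        tensors = list(dataset)
        if any(t.label is None for t in tensors):
            raise ValueError("every feature tensor must carry a label")
        xs = np.stack([t.frames for t in tensors]).astype(np.float64)
        labels = [t.label for t in tensors]
    alphabet = sorted(set(labels))
    y = np.array([alphabet.index(lab) for lab in labels])
    return xs, y, alphabet


def _evaluate(xs, y, lstm, att, clf, n_classes, batch_size=256):
    losses, correct = 0.0, 0
    for i0 in range(0, len(y), batch_size):
        xb, yb = xs[i0:i0 + batch_size], y[i0:i0 + batch_size]
        probs, _ = _forward_batch(xb, lstm, att, clf)
        losses += -np.sum(np.log(probs[np.arange(len(yb)), yb] + 1e-300))
        correct += int(np.sum(probs.argmax(axis=1) == yb))
    return losses / len(y), correct / len(y)


def train(dataset, cfg: TrainConfig | None = None,
          stft_config: STFTConfig | None = None
          ) -> tuple[ModelParams, dict]:
    """Fit the classifier with Adam, early stopping on the validation set.

    ``dataset`` is a collection of labeled :class:`SpectralFeatureTensor`
    (or a ``(array, labels)`` pair with array shaped N x n_frames x dim).
    The data are split into train/validation stratified by class; two
    early-stopping monitors run side by side -- validation accuracy
    failing to improve by ``min_delta``, and validation loss failing to
    decrease -- and either one ends training after ``patience`` stalled
    epochs.  The parameters returned are those of the best
    validation-accuracy epoch.
    """
    cfg = cfg or TrainConfig()
    xs, y, alphabet = _stack_dataset(dataset)
    if len(alphabet) < 2:
        raise ValueError("training requires at least two classes")
    rng = np.random.default_rng(cfg.seed)
    idx_train, idx_val = train_test_split(
        np.arange(len(y)), test_size=cfg.validation_fraction,
        stratify=y, random_state=cfg.seed % (2 ** 31))
    x_tr, y_tr = xs[idx_train], y[idx_train]
    x_va, y_va = xs[idx_val], y[idx_val]

    mean = std = None
    if cfg.normalize:
        mean = x_tr.mean(axis=(0, 1))
        std = x_tr.std(axis=(0, 1)) + 1e-8
        x_tr = (x_tr - mean) / std
        x_va = (x_va - mean) / std

    n_classes = len(alphabet)
    lstm, att, clf = init_params(xs.shape[2], cfg.hidden_dim, n_classes,
                                 cfg.fusion_mode, rng)
    params = _param_dict(lstm, att, clf)
    opt = _Adam(params, cfg.learning_rate)
    eye = np.eye(n_classes)

    history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    best_acc, best_loss = -np.inf, np.inf
    best_state = None
    best_epoch = 0
    stall_acc = stall_loss = 0
    fused_dim = clf.W_out.shape[1]

    for epoch in range(1, cfg.max_epochs + 1):
        perm = rng.permutation(len(y_tr))
        for i0 in range(0, len(perm), cfg.batch_size):
            sel = perm[i0:i0 + cfg.batch_size]
            xb, yb = x_tr[sel], y_tr[sel]
            mask = None
            if cfg.dropout_rate > 0:
                keep = 1.0 - cfg.dropout_rate
                mask = (rng.random((len(sel), fused_dim)) < keep) / keep
            _, cache = _forward_batch(xb, lstm, att, clf, dropout_mask=mask)
            grads = _backward_batch(cache, eye[yb])
            opt.step(params, grads)
            if "gate_raw" in grads:
                clf.gate_raw -= cfg.learning_rate * grads["gate_raw"]
        tr_loss, tr_acc = _evaluate(x_tr, y_tr, lstm, att, clf, n_classes)
        va_loss, va_acc = _evaluate(x_va, y_va, lstm, att, clf, n_classes)
        history["train_loss"].append(tr_loss)
        history["train_acc"].append(tr_acc)
        history["val_loss"].append(va_loss)
        history["val_acc"].append(va_acc)

        if va_acc >= best_acc + cfg.min_delta:
            stall_acc = 0
        else:
            stall_acc += 1
        if va_acc > best_acc or best_state is None:
            best_state = (copy.deepcopy(lstm), copy.deepcopy(att),
                          copy.deepcopy(clf))
            best_epoch = epoch
            best_acc = va_acc
        if va_loss < best_loss:
            best_loss = va_loss
            stall_loss = 0
        else:
            stall_loss += 1
        if stall_acc > cfg.patience or stall_loss > cfg.patience:
            break

    history["best_epoch"] = best_epoch
    history["stopped_epoch"] = epoch
    lstm, att, clf = best_state
    model = ModelParams(
        lstm=lstm, attention=att, classifier=clf, class_alphabet=alphabet,
        stft_config=(stft_config.to_dict() if stft_config is not None else None),
        feature_mean=mean, feature_std=std,
    )
    return model, history


# ---------------------------------------------------------------------------
# streaming prediction
# ---------------------------------------------------------------------------

def _resolve_stft_config(model: ModelParams,
                         stft_config: STFTConfig | None) -> STFTConfig:
    if model.stft_config is not None:
        trained = STFTConfig(**model.stft_config)
        if stft_config is not None and stft_config != trained:
            raise ValueError(
                "feature settings differ from the ones the model was "
                "trained with")
        return trained
    return stft_config or STFTConfig()


def classify_segments(segments: SegmentSet, model: ModelParams,
                      stft_config: STFTConfig | None = None) -> np.ndarray:
    """Class probabilities for a (not necessarily time-ordered) segment set."""
    cfg = _resolve_stft_config(model, stft_config)
    seg_list = list(segments)
    if not seg_list:
        raise ValueError("no segments to predict on")
    fs = segments.sampling_rate_hz
    xs = np.stack([featurize_segment(s, fs, cfg).frames for s in seg_list])
    if model.feature_mean is not None:
        xs = (xs - model.feature_mean) / model.feature_std
    probs_all = []
    for i0 in range(0, len(seg_list), 256):
        probs, _ = _forward_batch(xs[i0:i0 + 256], model.lstm,
                                  model.attention, model.classifier)
        probs_all.append(probs)
    return np.concatenate(probs_all, axis=0)


def predict_labels(segments: SegmentSet, model: ModelParams,
                   stft_config: STFTConfig | None = None) -> list[str]:
    """Argmax labels for a segment set (ties to the lowest class index)."""
    probs = classify_segments(segments, model, stft_config)
    return [model.class_alphabet[i] for i in probs.argmax(axis=1)]


def predict_stream(segments: SegmentSet | list, model: ModelParams,
                   stft_config: STFTConfig | None = None):
    """Time-stamped class probabilities, one per segment.

    Each prediction is stamped with the segment's end time, the earliest
    moment it could causally exist.  The feature settings must match the
    ones the model was trained with.
    """
    from .evaluation import PredictionStream

    if not isinstance(segments, SegmentSet):
        raise ValueError("predict_stream needs a SegmentSet with a sampling rate")
    probs = classify_segments(segments, model, stft_config)
    return PredictionStream(
        end_times_s=np.array([s.end_s for s in segments]),
        probabilities=probs,
        class_alphabet=list(model.class_alphabet),
    )


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_model(path, model: ModelParams) -> None:
    """Single-HDF5-file checkpoint, one dataset per parameter block."""
    with h5py.File(path, "w") as f:
        g = f.create_group("lstm")
        for name in LSTMParams.block_names():
            g.create_dataset(name, data=getattr(model.lstm, name))
        f.create_dataset("attention/w", data=model.attention.w)
        f.create_dataset("classifier/W_out", data=model.classifier.W_out)
        f.create_dataset("classifier/b_out", data=model.classifier.b_out)
        if model.feature_mean is not None:
            f.create_dataset("feature_mean", data=model.feature_mean)
            f.create_dataset("feature_std", data=model.feature_std)
        f.attrs["config"] = json.dumps({
            "class_alphabet": model.class_alphabet,
            "fusion_mode": model.classifier.fusion_mode,
            "gate_raw": model.classifier.gate_raw,
            "stft_config": model.stft_config,
        })


def load_model(path) -> ModelParams:
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["config"])
        lstm = LSTMParams(**{name: f["lstm"][name][()]
                             for name in LSTMParams.block_names()})
        att = AttentionParams(w=f["attention/w"][()])
        clf = ClassifierParams(fusion_mode=meta["fusion_mode"],
                               W_out=f["classifier/W_out"][()],
                               b_out=f["classifier/b_out"][()],
                               gate_raw=meta["gate_raw"])
        mean = f["feature_mean"][()] if "feature_mean" in f else None
        std = f["feature_std"][()] if "feature_std" in f else None
    return ModelParams(lstm=lstm, attention=att, classifier=clf,
                       class_alphabet=list(meta["class_alphabet"]),
                       stft_config=meta["stft_config"],
                       feature_mean=mean, feature_std=std)
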