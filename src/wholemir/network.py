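"""Deep feed-forward site classifier with autoencoder-pretrained features.

Architecture: 280 one-hot inputs -> eight dense ReLU hidden layers
(default widths 400, 250, 150, 80, 40, 40, 20, 10) -> two softmax outputs
(o0 = negative class, o1 = positive class).  The first hidden layer is
wider than the input (over-completion: room to expand the representation
before compressing); layers 1-5 form the encoder half of a stacked
autoencoder and can be pretrained in isolation to reconstruct the encoded
transcripts before supervised training.

Training uses inverted dropout (default rate 0.2), the Adam optimizer and
mini-batches; the epoch with the best validation loss supplies the final
weights.  Two loss configurations are exposed, cross-entropy (``XENT``)
and negative log-likelihood (``NLL``); with softmax outputs and one-hot
targets the two are analytically identical, and both are kept as distinct
configuration values purely so either convention can be named in configs
and compared like-for-like.

Everything is implemented directly on NumPy: the model is a few dense
matrix products, so a tensor framework would add dependency weight without
adding capability, and single-threaded NumPy keeps training bit-for-bit
reproducible from the configured seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .encode import ENCODING_VERSION, EncodedPair, PAIR_DIM
from .errors import ValidationError

_UNKNOWN = 0  # class code for grey-area calls


@dataclass(frozen=True)
class NetworkSpec:
    """Hyperparameters of the site classifier."""

    input_dim: int = PAIR_DIM
    hidden_sizes: tuple[int, ...] = (400, 250, 150, 80, 40, 40, 20, 10)
    pretrain_depth: int = 5
    dropout: float = 0.2
    max_epochs: int = 500
    loss: str = "XENT"
    seed: int = 0
    learning_rate: float = 1e-3
    batch_size: int = 128

    def validate(self) -> None:
        if not self.hidden_sizes:
            raise ValidationError("at least one hidden layer required")
        if self.hidden_sizes[0] <= self.input_dim:
            raise ValidationError(
                f"first hidden layer ({self.hidden_sizes[0]}) must exceed the input "
                f"dimension ({self.input_dim}): the representation is over-complete"
            )
        if not (1 <= self.pretrain_depth <= len(self.hidden_sizes)):
            raise ValidationError("pretrain_depth must index into hidden_sizes")
        if not (0.0 <= self.dropout < 1.0):
            raise ValidationError("dropout must be in [0, 1)")
        if self.loss not in ("XENT", "NLL"):
            raise ValidationError(f"loss must be XENT or NLL, got {self.loss!r}")
        if self.max_epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValidationError("max_epochs, batch_size, learning_rate must be positive")


@dataclass(frozen=True)
class SiteOutput:
    """Softmax outputs for one site and the thresholded class call."""

    o0: float
    o1: float
    cls: int  # 1 positive, -1 negative, 0 unknown (grey area)

    @property
    def score(self) -> float:
        return self.o1 - self.o0


def classify_output(o0: float, o1: float, K: float = 0.0) -> int:
    """Turn the two softmax outputs into a class via the grey-area margin.

    Returns 1 if ``o1 - o0 >= K``, -1 if ``o1 - o0 <= -K`` and 0 (unknown)
    inside the open interval.  With ``K = 0`` this reduces to the plain
    sign rule, with ties (o1 - o0 = 0) classified negative.
    """
    if K < 0:
        raise ValidationError("grey-area margin K must be >= 0")
    if not (0.0 <= o0 <= 1.0 and 0.0 <= o1 <= 1.0) or abs(o0 + o1 - 1.0) > 1e-6:
        raise ValidationError("o0 and o1 must be complementary probabilities")
    score = o1 - o0
    if score <= -K:
        return -1
    if score >= K:
        return 1
    return _UNKNOWN


# --------------------------------------------------------------------------
# numerical core


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _he_init(rng: np.random.Generator, sizes: list[int]):
    W = [
        rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
        for i in range(len(sizes) - 1)
    ]
    b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
    return W, b


class _Adam:
    """Plain Adam over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _forward_hidden(X, W, b, n_hidden, dropout=0.0, rng=None):
    """ReLU pass through the hidden stack; returns activations and masks."""
    acts = [X]
    masks = []
    A = X
    for layer in range(n_hidden):
        A = _relu(A @ W[layer] + b[layer])
        if dropout > 0.0 and rng is not None:
            mask = (rng.random(A.shape) >= dropout) / (1.0 - dropout)
            A = A * mask
            masks.append(mask)
        else:
            masks.append(None)
        acts.append(A)
    return acts, masks


def _backward_hidden(W, acts, masks, delta):
    """Backprop ``delta`` (gradient at the top hidden output) to all layers."""
    gW = [None] * len(acts[:-1])
    gb = [None] * len(acts[:-1])
    for layer in range(len(gW) - 1, -1, -1):
        if masks[layer] is not None:
            delta = delta * masks[layer]
        delta = delta * (acts[layer + 1] > 0)  # after-mask sign equals pre-mask sign
        gW[layer] = acts[layer].T @ delta
        gb[layer] = delta.sum(axis=0)
        if layer > 0:
            delta = delta @ W[layer].T
        else:
            delta = delta @ W[0].T
    return gW, gb, delta


class SiteClassifier:
    """The deep feed-forward classifier (hidden stack + 2-unit softmax)."""

    def __init__(self, spec: NetworkSpec):
        spec.validate()
        self.spec = spec
        sizes = [spec.input_dim, *spec.hidden_sizes, 2]
        rng = np.random.default_rng(spec.seed)
        self.W, self.b = _he_init(rng, sizes)
        self.trained = False
        self.encoding_version = ENCODING_VERSION

    # -- inference ---------------------------------------------------------

    def _logits(self, X: np.ndarray, dropout: float = 0.0, rng=None):
        n_hidden = len(self.spec.hidden_sizes)
        acts, masks = _forward_hidden(X, self.W, self.b, n_hidden, dropout, rng)
        logits = acts[-1] @ self.W[-1] + self.b[-1]
        return logits, acts, masks

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        logits, _, _ = self._logits(X)
        return _softmax(logits)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write weights (.npz) plus a JSON sidecar with spec + encoding."""
        path = Path(path)
        arrays = {}
        for i, (w, bb) in enumerate(zip(self.W, self.b)):
            arrays[f"W{i}"] = w
            arrays[f"b{i}"] = bb
        np.savez(path, **arrays)
        meta = {
            "spec": asdict(self.spec),
            "encoding_version": self.encoding_version,
            "trained": self.trained,
            "n_layers": len(self.W),
        }
        Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SiteClassifier":
        path = Path(path)
        meta = json.loads(Path(str(path) + ".meta.json").read_text())
        if meta["encoding_version"] != ENCODING_VERSION:
            raise ValidationError(
                f"model was trained under encoding {meta['encoding_version']!r}; "
                f"this build encodes {ENCODING_VERSION!r} — refusing to score"
            )
        spec_d = meta["spec"]
        spec_d["hidden_sizes"] = tuple(spec_d["hidden_sizes"])
        model = cls(NetworkSpec(**spec_d))
        data = np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz")
        for i in range(meta["n_layers"]):
            model.W[i] = data[f"W{i}"]
            model.b[i] = data[f"b{i}"]
        model.trained = meta["trained"]
        return model


def build_model(spec: NetworkSpec) -> SiteClassifier:
    """Construct the classifier with deterministic seed-derived weights."""
    return SiteClassifier(spec)


# --------------------------------------------------------------------------
# supervised training


def _to_targets(y: np.ndarray) -> np.ndarray:
    """Map {+1, -1} labels to softmax class indices (o1 = positive)."""
    y = np.asarray(y)
    if not set(np.unique(y)) <= {-1, 1}:
        raise ValidationError("labels must be +1 / -1")
    return (y == 1).astype(int)


def _mean_nll(probs: np.ndarray, targets: np.ndarray) -> float:
    return float(-np.log(np.clip(probs[np.arange(len(targets)), targets], 1e-12, None)).mean())


def _loss_value(loss: str, probs: np.ndarray, targets: np.ndarray) -> float:
    if loss == "XENT":
        # cross-entropy against one-hot targets
        onehot = np.zeros_like(probs)
        onehot[np.arange(len(targets)), targets] = 1.0
        return float(-(onehot * np.log(np.clip(probs, 1e-12, None))).sum(axis=1).mean())
    # NLL of the observed class under the log-softmax — identical for one-hot
    return _mean_nll(probs, targets)


def train_classifier(
    model: SiteClassifier,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_valid: np.ndarray,
    y_valid: np.ndarray,
    spec: NetworkSpec | None = None,
    patience: int | None = None,
) -> dict:
    """Supervised training with dropout; keeps the best-validation epoch.

    ``y`` labels are +1/-1.  Returns a history dict with per-epoch train and
    validation loss and the selected epoch.  Deterministic given (seed,
    data, spec) on one thread.  ``patience`` optionally stops early after
    that many epochs without validation improvement.
    """
    spec = spec or model.spec
    X_train = np.asarray(X_train, dtype=float)
    X_valid = np.asarray(X_valid, dtype=float)
    t_train = _to_targets(y_train)
    t_valid = _to_targets(y_valid)
    if len(set(t_train.tolist())) < 2:
        raise ValidationError("training set must contain both classes")

    params = model.W + model.b
    opt = _Adam(params, spec.learning_rate)
    shuffle_rng = np.random.default_rng([spec.seed, 1])
    drop_rng = np.random.default_rng([spec.seed, 2])
    n = len(X_train)
    history = {"train_loss": [], "valid_loss": []}
    best = (np.inf, None, None)  # (valid loss, epoch, weights)
    stale = 0

    for epoch in range(spec.max_epochs):
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, spec.batch_size):
            idx = order[lo:lo + spec.batch_size]
            Xb, tb = X_train[idx], t_train[idx]
            logits, acts, masks = model._logits(Xb, spec.dropout, drop_rng)
            probs = _softmax(logits)
            epoch_loss += _loss_value(spec.loss, probs, tb) * len(idx)
            # gradient of mean CE/NLL wrt logits
            dlogits = probs.copy()
            dlogits[np.arange(len(tb)), tb] -= 1.0
            dlogits /= len(idx)
            gW_out = acts[-1].T @ dlogits
            gb_out = dlogits.sum(axis=0)
            delta = dlogits @ model.W[-1].T
            gW, gb, _ = _backward_hidden(model.W, acts, masks, delta)
            grads = gW + [gW_out] + gb + [gb_out]
            opt.step(params, grads)
        history["train_loss"].append(epoch_loss / n)

        v_probs = model.predict_proba(X_valid)
        v_loss = _loss_value(spec.loss, v_probs, t_valid)
        history["valid_loss"].append(v_loss)
        if v_loss < best[0]:  # strict: ties keep the earliest epoch
            best = (v_loss, epoch, ([w.copy() for w in model.W], [bb.copy() for bb in model.b]))
            stale = 0
        else:
            stale += 1
            if patience is not None and stale >= patience:
                break

    if best[2] is not None:
        model.W, model.b = best[2]
    history["best_epoch"] = best[1]
    history["best_valid_loss"] = best[0]
    model.trained = True
    return history


def predict_site(model: SiteClassifier, x: EncodedPair | np.ndarray, K: float = 0.0) -> SiteOutput:
    """Score one encoded pair and apply the grey-area rule."""
    if not model.trained:
        raise ValidationError("model has not been trained")
    vec = x.combined if isinstance(x, EncodedPair) else np.asarray(x)
    probs = model.predict_proba(vec[None, :] if vec.ndim == 1 else vec)[0]
    o0, o1 = float(probs[0]), float(probs[1])
    return SiteOutput(o0=o0, o1=o1, cls=classify_output(o0, o1, K))


# --------------------------------------------------------------------------
# autoencoder pretraining


def _block_targets(X: np.ndarray) -> np.ndarray:
    """Categorical target per 4-bit slot: 0..3 for U,G,C,A order; 4 = empty."""
    blocks = X.reshape(len(X), -1, 4)
    empty = blocks.sum(axis=2) == 0
    t = blocks.argmax(axis=2)
    t[empty] = 4
    return t


def reconstruction_relative_error(logits: np.ndarray, targets: np.ndarray) -> float:
    """Fraction of nucleotide slots decoded to the wrong symbol.

    The natural reconstruction error for categorical sequence data: each
    4-bit slot is decoded by argmax over the 5 symbol classes (A/C/G/U/empty)
    and compared with the input symbol.
    """
    pred = logits.argmax(axis=2)
    return float((pred != targets).mean())


def pretrain_autoencoder(
    model: SiteClassifier,
    X: np.ndarray,
    max_epochs: int = 150,
    target_error: float = 0.05,
    holdout_fraction: float = 0.1,
    learning_rate: float | None = None,
    batch_size: int | None = None,
) -> dict:
    """Pretrain encoder layers 1..pretrain_depth as a stacked autoencoder.

    The encoder (the classifier's first ``pretrain_depth`` hidden layers) is
    trained jointly with a mirrored ReLU decoder to reconstruct the one-hot
    input, read out as a 5-way softmax per nucleotide slot.  Training stops
    once the held-out reconstruction relative error (fraction of wrongly
    decoded slots) drops below ``target_error``, or at the epoch cap — in
    which case the weights reached are kept and a warning is recorded in
    the returned history.  Encoder weights are then transferred into the
    classifier in place.
    """
    spec = model.spec
    X = np.asarray(X, dtype=float)
    if len(X) < 2:
        raise ValidationError("pretraining needs at least two samples")
    lr = learning_rate if learning_rate is not None else spec.learning_rate
    bs = batch_size if batch_size is not None else spec.batch_size

    depth = spec.pretrain_depth
    enc_sizes = [spec.input_dim, *spec.hidden_sizes[:depth]]
    n_blocks = spec.input_dim // 4
    dec_sizes = [*enc_sizes[::-1][:-1], n_blocks * 5]  # mirrored, categorical head

    rng = np.random.default_rng([spec.seed, 3])
    We = [w.copy() for w in model.W[:depth]]
    be = [b.copy() for b in model.b[:depth]]
    Wd, bd = _he_init(rng, dec_sizes)

    split_rng = np.random.default_rng([spec.seed, 4])
    order = split_rng.permutation(len(X))
    n_hold = max(1, int(round(holdout_fraction * len(X))))
    hold, train = order[:n_hold], order[n_hold:]
    if len(train) == 0:
        train = hold
    Xtr, Xho = X[train], X[hold]
    t_tr, t_ho = _block_targets(Xtr), _block_targets(Xho)

    params = We + Wd + be + bd
    opt = _Adam(params, lr)
    shuffle_rng = np.random.default_rng([spec.seed, 5])
    history = {"holdout_error": [], "holdout_mse": [], "converged": False}

    def _ae_logits(Xb):
        acts_e, _ = _forward_hidden(Xb, We, be, depth)
        acts_d, _ = _forward_hidden(acts_e[-1], Wd, bd, len(Wd) - 1)
        logits = acts_d[-1] @ Wd[-1] + bd[-1]
        return logits.reshape(len(Xb), n_blocks, 5), acts_e, acts_d

    for epoch in range(max_epochs):
        order = shuffle_rng.permutation(len(Xtr))
        for lo in range(0, len(Xtr), bs):
            idx = order[lo:lo + bs]
            Xb, tb = Xtr[idx], t_tr[idx]
            logits, acts_e, acts_d = _ae_logits(Xb)
            probs = _softmax(logits)
            dlogits = probs
            dlogits[np.arange(len(tb))[:, None], np.arange(n_blocks)[None, :], tb] -= 1.0
            dlogits = dlogits.reshape(len(Xb), -1) / len(Xb)
            gWd_out = acts_d[-1].T @ dlogits
            gbd_out = dlogits.sum(axis=0)
            delta = dlogits @ Wd[-1].T
            masks_d = [None] * (len(Wd) - 1)
            gWd, gbd, delta = _backward_hidden(Wd[:-1], acts_d, masks_d, delta)
            masks_e = [None] * depth
            gWe, gbe, _ = _backward_hidden(We, acts_e, masks_e, delta)
            grads = gWe + gWd + [gWd_out] + gbe + gbd + [gbd_out]
            opt.step(We + Wd[:-1] + [Wd[-1]] + be + bd[:-1] + [bd[-1]], grads)

        logits_ho, _, _ = _ae_logits(Xho)
        err = reconstruction_relative_error(logits_ho, t_ho)
        history["holdout_error"].append(err)
        # companion diagnostic: per-input-unit squared reconstruction error,
        # reading the expected bit values off the per-slot distributions
        probs_ho = _softmax(logits_ho)
        xhat = probs_ho[:, :, :4].reshape(len(Xho), -1)
        history["holdout_mse"].append(float(((Xho - xhat) ** 2).mean()))
        if err < target_error:
            history["converged"] = True
            break

    if not history["converged"]:
        import warnings

        warnings.warn(
            f"autoencoder pretraining stopped at the epoch cap with held-out "
            f"relative error {history['holdout_error'][-1]:.3f} >= {target_error}; "
            "keeping the weights reached",
            stacklevel=2,
        )
    for i in range(depth):
        model.W[i] = We[i]
        model.b[i] = be[i]
    history["final_error"] = history["holdout_error"][-1]
    history["final_mse"] = history["holdout_mse"][-1]
    return history
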