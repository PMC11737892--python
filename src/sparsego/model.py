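"""The knowledge-masked sparse neural network.

Architecture (bottom to top): a gene input layer, a transcription-factor
layer, a GO-term layer, and an output layer (one node per cell type, or a
single linear node in regression mode).  Each hidden connection matrix is
elementwise-multiplied by a binary knowledge mask, so only edges supported
by GO annotation or TF-target evidence can carry signal.  Genes reach the
GO layer both directly (gene->GO annotation edges) and through the TF layer
(gene->TF target edges, TF->GO edges).

Training minimizes cross-entropy (classification) or mean squared error
(regression) with Adam at a fixed learning rate of 0.001 by default.
Gradients at mask-zero positions are multiplied by the mask every step and
weights are re-zeroed after each update, so masked entries are exactly 0 at
all times — an invariant the test suite asserts as exact equality.

Everything here is plain NumPy with hand-written gradients; the network is
small enough (a few hundred genes by a few dozen terms) that this is both
fast and fully deterministic given a seed.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp

from .expression import ExpressionMatrix
from .knowledge import MaskSet, load_masks, save_masks

MODEL_FORMAT = "sparsego-model"
MODEL_VERSION = 1


@dataclass
class TrainingConfig:
    """Optimization hyper-parameters.

    ``validation_fraction`` of cells (deterministically chosen by ``seed``)
    is held out for early stopping; set it to 0 to disable both.
    """

    learning_rate: float = 0.001
    optimizer: str = "adam"
    max_epochs: int = 1000
    batch_size: int = 64
    seed: int = 0
    early_stop_patience: int = 50
    weight_decay: float | None = None  # None -> per-mode default
    mode: str = "classification"
    validation_fraction: float = 0.1
    shuffle: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.mode not in ("classification", "regression"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0.0 <= self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in [0, 1)")
        if self.weight_decay is not None and self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")

    @property
    def resolved_weight_decay(self) -> float:
        """L2 strength actually used: 1e-3 for classification, 0.1 for
        regression (MSE on a [0, 1] target needs much stronger shrinkage
        than cross-entropy to generalize), unless set explicitly."""
        if self.weight_decay is not None:
            return self.weight_decay
        return 1e-3 if self.mode == "classification" else 0.1


@dataclass
class PredictionResult:
    probabilities: np.ndarray
    predicted_label: list[str]
    max_probability: np.ndarray
    novelty_flag: np.ndarray
    novelty_threshold: float
    cell_ids: list[str] | None = None

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "predicted_label": self.predicted_label,
                "max_probability": self.max_probability,
                "novelty_flag": self.novelty_flag,
            }
        )
        if self.cell_ids is not None:
            df.insert(0, "cell_id", self.cell_ids)
        return df


def _activation(name: str) -> tuple[Callable, Callable]:
    if name == "relu":
        return (lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(float))
    if name == "tanh":
        return (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2)
    if name == "identity":
        return (lambda z: z, lambda z: np.ones_like(z))
    raise ValueError(f"unknown activation {name!r}")


class SparseGOModel:
    """Masked-weight network with gene, TF, GO and output layers."""

    _WEIGHTS = ("W_gene_tf", "W_gene_go", "W_tf_go", "W_go_out")
    _BIASES = ("b_tf", "b_go", "b_out")

    def __init__(
        self,
        masks: MaskSet,
        labels: Sequence[str] | None,
        mode: str = "classification",
        activation: str = "tanh",
        use_direct_gene_go: bool = True,
    ) -> None:
        if mode not in ("classification", "regression"):
            raise ValueError(f"unknown mode {mode!r}")
        if mode == "classification":
            if not labels:
                raise ValueError("classification mode requires a non-empty label list")
            self.label_map = list(labels)
            if len(set(self.label_map)) != len(self.label_map):
                raise ValueError("duplicate labels")
        else:
            self.label_map = None
        self.masks = masks
        self.mode = mode
        self.activation = activation
        self.use_direct_gene_go = use_direct_gene_go
        _activation(activation)  # validate early

        n_out = len(self.label_map) if self.label_map is not None else 1
        G, T, K = len(masks.genes), len(masks.tfs), len(masks.go_terms)
        self.W_gene_tf = np.zeros((G, T))
        self.W_gene_go = np.zeros((G, K))
        self.W_tf_go = np.zeros((T, K))
        self.W_go_out = np.zeros((K, n_out))
        self.b_tf = np.zeros(T)
        self.b_go = np.zeros(K)
        self.b_out = np.zeros(n_out)

    # -- structural properties -------------------------------------------

    @property
    def n_outputs(self) -> int:
        return self.W_go_out.shape[1]

    def _mask_for(self, name: str) -> np.ndarray | None:
        if name == "W_gene_tf":
            return self.masks.M_gene_tf
        if name == "W_gene_go":
            m = self.masks.M_gene_go
            return m if self.use_direct_gene_go else np.zeros_like(m)
        if name == "W_tf_go":
            return self.masks.M_tf_go
        return None  # dense output head

    def apply_masks(self) -> None:
        # in place: the optimizer holds references to these arrays
        for name in self._WEIGHTS:
            m = self._mask_for(name)
            if m is not None:
                getattr(self, name)[...] *= m

    def initialize(self, seed: int) -> "SparseGOModel":
        """He-scaled random init at mask-one positions; deterministic per seed.

        Scaling uses the full layer fan-in rather than each column's mask
        count: masked columns then start with small pre-activations close to
        the ReLU threshold, which avoids permanently dead knowledge nodes
        (inputs are non-negative, so a node starting strongly negative could
        never recover).
        """
        rng = np.random.default_rng(seed)
        for name in self._WEIGHTS:
            w = getattr(self, name)
            fan_in = max(w.shape[0], 1)
            setattr(self, name, rng.standard_normal(w.shape) * np.sqrt(2.0 / fan_in))
        self.apply_masks()
        return self

    def count_parameters(self) -> tuple[int, int]:
        """(sparse trainable count, dense all-ones equivalent), biases included."""
        sparse = dense = 0
        for name in self._WEIGHTS:
            w = getattr(self, name)
            m = self._mask_for(name)
            dense += w.size
            sparse += w.size if m is None else int(m.sum())
        n_bias = sum(getattr(self, b).size for b in self._BIASES)
        return sparse + n_bias, dense + n_bias

    # -- forward ----------------------------------------------------------

    def forward(self, X: np.ndarray, cache: bool = False):
        """Batch forward pass; returns probabilities (classification) or
        scores (regression); with ``cache=True`` returns the layer dict."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.masks.genes):
            raise ValueError(
                f"input has {X.shape[1]} genes, model expects {len(self.masks.genes)}"
            )
        act, _ = _activation(self.activation)
        Z1 = X @ self.W_gene_tf + self.b_tf
        H1 = act(Z1)
        Z2 = X @ self.W_gene_go + H1 @ self.W_tf_go + self.b_go
        H2 = act(Z2)
        logits = H2 @ self.W_go_out + self.b_out
        out = {"X": X, "Z1": Z1, "H1": H1, "Z2": Z2, "H2": H2, "logits": logits}
        if self.mode == "classification":
            out["probs"] = _softmax(logits)
        if cache:
            return out
        return out["probs"] if self.mode == "classification" else logits[:, 0]

    def logits(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X, cache=True)["logits"]

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        manifest = {
            "format": MODEL_FORMAT,
            "version": MODEL_VERSION,
            "mode": self.mode,
            "activation": self.activation,
            "use_direct_gene_go": self.use_direct_gene_go,
            "label_map": self.label_map,
            "n_outputs": self.n_outputs,
        }
        with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
            zf.writestr("manifest.json", json.dumps(manifest, indent=1))
            buf = io.BytesIO()
            _save_masks_bytes(self.masks, buf)
            zf.writestr("masks.zip", buf.getvalue())
            for name in self._WEIGHTS:
                zf.writestr(f"{name}.mtx", _mm_bytes(sp.coo_matrix(getattr(self, name))))
            for name in self._BIASES:
                zf.writestr(
                    f"{name}.mtx", _mm_bytes(sp.coo_matrix(getattr(self, name)[None, :]))
                )

    @classmethod
    def load(cls, path: str | Path) -> "SparseGOModel":
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            if manifest.get("format") != MODEL_FORMAT:
                raise ValueError("not a sparsego model archive")
            if manifest.get("version") != MODEL_VERSION:
                raise ValueError(
                    f"model archive version {manifest.get('version')} "
                    f"not supported (expected {MODEL_VERSION})"
                )
            if "mode" not in manifest:
                raise ValueError("model manifest missing 'mode'")
            masks = _load_masks_bytes(zf.read("masks.zip"))
            model = cls(
                masks,
                labels=manifest["label_map"],
                mode=manifest["mode"],
                activation=manifest["activation"],
                use_direct_gene_go=manifest["use_direct_gene_go"],
            )
            for name in cls._WEIGHTS:
                w = _mm_read(zf.read(f"{name}.mtx"), getattr(model, name).shape)
                setattr(model, name, w)
            for name in cls._BIASES:
                b = _mm_read(zf.read(f"{name}.mtx"), (1, getattr(model, name).size))
                setattr(model, name, b[0])
        return model


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _log_softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=1, keepdims=True))


def _mm_bytes(m) -> bytes:
    buf = io.BytesIO()
    scipy.io.mmwrite(buf, m, precision=17)
    return buf.getvalue()


def _mm_read(data: bytes, shape) -> np.ndarray:
    m = scipy.io.mmread(io.BytesIO(data))
    return np.asarray(sp.coo_matrix(m, shape=shape).todense())


def _save_masks_bytes(masks: MaskSet, buf) -> None:
    import tempfile, os

    with tempfile.NamedTemporaryFile(suffix=".zip", delete=False) as tmp:
        name = tmp.name
    try:
        save_masks(masks, name)
        with open(name, "rb") as fh:
            buf.write(fh.read())
    finally:
        os.unlink(name)


def _load_masks_bytes(data: bytes) -> MaskSet:
    import tempfile, os

    with tempfile.NamedTemporaryFile(suffix=".zip", delete=False) as tmp:
        tmp.write(data)
        name = tmp.name
    try:
        return load_masks(name)
    finally:
        os.unlink(name)


# -- construction / training ---------------------------------------------


def init_model(
    masks: MaskSet,
    labels: Sequence[str] | None,
    mode: str = "classification",
    seed: int = 0,
    activation: str = "tanh",
    use_direct_gene_go: bool = True,
) -> SparseGOModel:
    """Build and randomly initialize a masked network."""
    model = SparseGOModel(
        masks, labels, mode=mode, activation=activation,
        use_direct_gene_go=use_direct_gene_go,
    )
    return model.initialize(seed)


class _Adam:
    """Standard Adam with bias correction, one slot per parameter array."""

    def __init__(self, shapes: dict[str, tuple], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _batch_gradients(model: SparseGOModel, X: np.ndarray, y: np.ndarray):
    """Loss and gradients for one minibatch; gradients are already masked."""
    _, dact = _activation(model.activation)
    c = model.forward(X, cache=True)
    n = X.shape[0]
    if model.mode == "classification":
        logp = _log_softmax(c["logits"])
        loss = -logp[np.arange(n), y].mean()
        dlogits = c["probs"].copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
    else:
        resid = c["logits"][:, 0] - y
        loss = float(np.mean(resid ** 2))
        dlogits = (2.0 * resid / n)[:, None]

    grads: dict[str, np.ndarray] = {}
    grads["W_go_out"] = c["H2"].T @ dlogits
    grads["b_out"] = dlogits.sum(axis=0)
    dH2 = dlogits @ model.W_go_out.T
    dZ2 = dH2 * dact(c["Z2"])
    grads["W_gene_go"] = c["X"].T @ dZ2
    grads["W_tf_go"] = c["H1"].T @ dZ2
    grads["b_go"] = dZ2.sum(axis=0)
    dH1 = dZ2 @ model.W_tf_go.T
    dZ1 = dH1 * dact(c["Z1"])
    grads["W_gene_tf"] = c["X"].T @ dZ1
    grads["b_tf"] = dZ1.sum(axis=0)

    for name in model._WEIGHTS:
        m = model._mask_for(name)
        if m is not None:
            grads[name] = grads[name] * m
    return float(loss), grads


def _encode_labels(model: SparseGOModel, y: Sequence) -> np.ndarray:
    index = {lab: i for i, lab in enumerate(model.label_map)}
    try:
        return np.array([index[v] for v in y], dtype=int)
    except KeyError as exc:
        raise ValueError(f"label {exc.args[0]!r} not in the model's label map") from None


def train(
    model: SparseGOModel,
    X: ExpressionMatrix | np.ndarray,
    y: Sequence,
    config: TrainingConfig | None = None,
) -> dict:
    """Fit the masked network in place; returns loss traces.

    Returns a dict with ``loss`` (mean train loss per epoch), ``val_loss``
    (per epoch, empty when validation is disabled) and ``epochs_run``.
    Weights at mask-zero positions are exactly 0 after every update.
    """
    config = config or TrainingConfig(mode=model.mode)
    if config.mode != model.mode:
        raise ValueError(f"config mode {config.mode!r} != model mode {model.mode!r}")
    Xv = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    if Xv.shape[0] != len(y):
        raise ValueError("number of labels does not match number of cells")
    if model.mode == "classification":
        yv = _encode_labels(model, y)
    else:
        yv = np.asarray(y, dtype=float)

    rng = np.random.default_rng(config.seed)
    n = Xv.shape[0]
    perm = rng.permutation(n)
    n_val = int(round(config.validation_fraction * n))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if train_idx.size == 0:
        raise ValueError("no training cells left after validation split")

    params = {k: getattr(model, k) for k in model._WEIGHTS + model._BIASES}
    opt = _Adam({k: p.shape for k, p in params.items()}, lr=config.learning_rate)
    weight_decay = config.resolved_weight_decay

    history: dict = {"loss": [], "val_loss": [], "epochs_run": 0}
    best_val = np.inf
    best_state = None
    patience_left = config.early_stop_patience

    for epoch in range(config.max_epochs):
        order = rng.permutation(train_idx) if config.shuffle else train_idx
        epoch_losses = []
        for start in range(0, order.size, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, grads = _batch_gradients(model, Xv[idx], yv[idx])
            if weight_decay:
                for name in model._WEIGHTS:
                    g = grads[name] + weight_decay * params[name]
                    m = model._mask_for(name)
                    grads[name] = g if m is None else g * m
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss}; "
                    "check input normalization and learning rate"
                )
            epoch_losses.append(loss)
            opt.step(params, grads)
            model.apply_masks()  # keep masked entries exactly zero
        history["loss"].append(float(np.mean(epoch_losses)))
        history["epochs_run"] = epoch + 1

        if n_val:
            vloss, _ = _batch_gradients(model, Xv[val_idx], yv[val_idx])
            history["val_loss"].append(vloss)
            if vloss < best_val - 1e-12:
                best_val = vloss
                best_state = {k: p.copy() for k, p in params.items()}
                patience_left = config.early_stop_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break

    if best_state is not None:
        for k, v in best_state.items():
            getattr(model, k)[...] = v
        model.apply_masks()
    return history


def predict(
    model: SparseGOModel,
    X: ExpressionMatrix | np.ndarray,
    novelty_threshold: float = 0.95,
) -> PredictionResult:
    """Class probabilities, argmax labels (lowest index wins ties) and the
    open-set novelty flag: a cell whose maximum probability falls below the
    cutoff (0.95 by default) is marked as a putative novel cell type."""
    if model.mode != "classification":
        raise ValueError("model is in regression mode: use predict_score")
    cell_ids = X.cell_ids if isinstance(X, ExpressionMatrix) else None
    Xv = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    probs = model.forward(Xv)
    best = probs.argmax(axis=1)
    max_p = probs[np.arange(probs.shape[0]), best]
    return PredictionResult(
        probabilities=probs,
        predicted_label=[model.label_map[i] for i in best],
        max_probability=max_p,
        novelty_flag=max_p < novelty_threshold,
        novelty_threshold=novelty_threshold,
        cell_ids=cell_ids,
    )


def predict_score(model: SparseGOModel, X: ExpressionMatrix | np.ndarray) -> np.ndarray:
    """Continuous per-cell score from a regression-mode model."""
    if model.mode != "regression":
        raise ValueError("model is in classification mode: use predict")
    Xv = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    return model.forward(Xv)


def count_parameters(model: SparseGOModel) -> tuple[int, int]:
    return model.count_parameters()


def save_model(model: SparseGOModel, path: str | Path) -> None:
    model.save(path)


def load_model(path: str | Path) -> SparseGOModel:
    return SparseGOModel.load(path)
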