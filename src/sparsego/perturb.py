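"""In-silico gene perturbation screening and de-novo TF-target inference.

A perturbation scales a single gene's (normalized) expression: x0.5 for
inhibition, x2 for activation.  ``screen_genes`` applies each perturbation
to every cell of a source class and counts the fraction of cells whose
predicted label flips to a target class — genes with a high shift fraction
are candidate drivers of the state transition.

``infer_de_novo_tf_targets`` embeds TF expression into a low-dimensional
latent space with a small encoder, projects the latent code back onto the
full expression space with a decoder (trained to reconstruct expression),
then perturbs each TF's input and scores every gene by the mean absolute
fluctuation of its decoded expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .expression import ExpressionMatrix
from .model import SparseGOModel, _Adam, predict

DEFAULT_FACTORS = {"inhibit": 0.5, "activate": 2.0}


@dataclass
class PerturbationResult:
    gene: str
    direction: str
    scale_factor: float
    shift_fraction: float
    n_cells: int


@dataclass
class TFTargetScore:
    tf: str
    target_gene: str
    score: float


def perturb_expression(
    x: np.ndarray,
    gene: str,
    direction: str,
    gene_names: Sequence[str],
    factor: float | None = None,
) -> np.ndarray:
    """Return a copy of ``x`` with the named gene's expression scaled.

    Inhibition scales by 0.5, activation by 2 (override with ``factor``).
    All other entries are bit-identical to the input.
    """
    if direction not in DEFAULT_FACTORS:
        raise ValueError(f"unknown direction {direction!r}")
    try:
        j = list(gene_names).index(gene)
    except ValueError:
        raise KeyError(f"gene {gene!r} not in vocabulary") from None
    f = DEFAULT_FACTORS[direction] if factor is None else factor
    out = np.array(x, dtype=float, copy=True)
    out[..., j] = out[..., j] * f
    return out


def screen_genes(
    model: SparseGOModel,
    X_source: ExpressionMatrix | np.ndarray,
    source_label: str,
    target_label: str,
    min_shift_fraction: float = 0.0,
    directions: Sequence[str] = ("inhibit", "activate"),
    factors: dict[str, float] | None = None,
    criterion: str = "argmax",
    probability_delta: float = 0.05,
) -> list[PerturbationResult]:
    """Single-gene perturbation screen for source -> target state shifts.

    For every gene and direction the source cells are re-predicted on the
    perturbed matrix; ``shift_fraction`` is the fraction whose argmax label
    becomes the target class (``criterion="argmax"``), or whose target-class
    probability rises by more than ``probability_delta``
    (``criterion="soft"``).  Results with shift_fraction >=
    ``min_shift_fraction`` are returned sorted by shift fraction descending,
    then gene name, then direction.
    """
    if model.mode != "classification":
        raise ValueError("perturbation screening requires a classification model")
    for lab in (source_label, target_label):
        if lab not in model.label_map:
            raise ValueError(f"label {lab!r} not in model label map")
    if criterion not in ("argmax", "soft"):
        raise ValueError(f"unknown criterion {criterion!r}")
    factors = {**DEFAULT_FACTORS, **(factors or {})}

    Xv = X_source.values if isinstance(X_source, ExpressionMatrix) else np.atleast_2d(
        np.asarray(X_source, dtype=float)
    )
    base = predict(model, Xv)
    keep = np.array([lab == source_label for lab in base.predicted_label])
    if not keep.any():
        raise ValueError(f"no cells predicted as source class {source_label!r}")
    Xs = Xv[keep]
    n = Xs.shape[0]
    t = model.label_map.index(target_label)
    base_probs = model.forward(Xs)

    results: list[PerturbationResult] = []
    for j, gene in enumerate(model.masks.genes):
        for direction in directions:
            f = factors[direction]
            Xp = Xs.copy()
            Xp[:, j] *= f
            probs = model.forward(Xp)
            if criterion == "argmax":
                shifted = probs.argmax(axis=1) == t
            else:
                shifted = (probs[:, t] - base_probs[:, t]) > probability_delta
            frac = float(shifted.mean())
            if frac >= min_shift_fraction:
                results.append(
                    PerturbationResult(gene, direction, f, frac, n)
                )
    results.sort(key=lambda r: (-r.shift_fraction, r.gene, r.direction))
    return results


def infer_de_novo_tf_targets(
    expression: ExpressionMatrix,
    tf_list: Sequence[str],
    latent_dim: int = 8,
    seed: int = 0,
    perturb_factor: float = 2.0,
    epochs: int = 500,
    learning_rate: float = 0.001,
    batch_size: int = 64,
    score_quantile: float = 0.95,
) -> list[TFTargetScore]:
    """Latent-space TF perturbation for de-novo TF-target inference.

    A single-hidden-layer network (relu encoder of size ``latent_dim``,
    linear decoder) is trained with Adam to reconstruct the full expression
    matrix from the TF columns alone.  Each TF's input column is then scaled
    by ``perturb_factor`` and the mean absolute change of every decoded gene
    is its regulatory score.  Pairs scoring above the ``score_quantile``
    quantile of all (TF, gene) scores are returned, sorted descending; set
    ``score_quantile=0`` to return every pair.
    """
    tf_list = list(tf_list)
    if latent_dim < 1:
        raise ValueError("latent_dim must be >= 1")
    missing = [t for t in tf_list if t not in expression.gene_names]
    if missing:
        raise KeyError(f"TFs absent from expression: {missing[:5]}")
    if expression.n_cells < latent_dim:
        raise ValueError("fewer cells than latent dimensions")

    X = expression.values
    tf_idx = [expression.gene_names.index(t) for t in tf_list]
    T = X[:, tf_idx]  # cells x TFs
    n, g = X.shape

    rng = np.random.default_rng(seed)
    params = {
        "W1": rng.standard_normal((len(tf_list), latent_dim)) * np.sqrt(2.0 / max(len(tf_list), 1)),
        "b1": np.zeros(latent_dim),
        "W2": rng.standard_normal((latent_dim, g)) * np.sqrt(2.0 / latent_dim),
        "b2": np.zeros(g),
    }
    opt = _Adam({k: p.shape for k, p in params.items()}, lr=learning_rate)

    def decode(tin: np.ndarray) -> np.ndarray:
        z = tin @ params["W1"] + params["b1"]
        return np.maximum(z, 0.0) @ params["W2"] + params["b2"]

    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            tb, xb = T[idx], X[idx]
            z = tb @ params["W1"] + params["b1"]
            h = np.maximum(z, 0.0)
            xhat = h @ params["W2"] + params["b2"]
            resid = (xhat - xb) / idx.size
            grads = {
                "W2": h.T @ (2 * resid),
                "b2": (2 * resid).sum(axis=0),
            }
            dh = (2 * resid) @ params["W2"].T
            dz = dh * (z > 0)
            grads["W1"] = tb.T @ dz
            grads["b1"] = dz.sum(axis=0)
            opt.step(params, grads)

    baseline = decode(T)
    scores = np.zeros((len(tf_list), g))
    for i in range(len(tf_list)):
        Tp = T.copy()
        Tp[:, i] *= perturb_factor
        scores[i] = np.abs(decode(Tp) - baseline).mean(axis=0)

    cutoff = np.quantile(scores, score_quantile) if score_quantile > 0 else -np.inf
    out = [
        TFTargetScore(tf_list[i], expression.gene_names[j], float(scores[i, j]))
        for i in range(len(tf_list))
        for j in range(g)
        if scores[i, j] >= cutoff
    ]
    out.sort(key=lambda r: (-r.score, r.tf, r.target_gene))
    return out
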