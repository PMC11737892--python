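"""Model interpretation: attribution and weight tracing.

Gene importance follows the reference-activation idea: every neuron's
activation is compared against its activation on a reference input (all
zeros by default, or the mean expression profile), and the activation
differences are propagated back to the gene layer with the rescale rule —
for each nonlinearity the multiplier is Delta(output)/Delta(input).  For
such multipliers the contributions are complete: summed over genes they
equal the target logit difference f(x) - f(reference) exactly (biases
cancel in the deltas), which the test suite asserts.

GO-term and TF contributions are obtained by tracing trained weights toward
an output node: the magnitude of a GO node's output weight (optionally
scaled by its mean activation over supplied cells), and for a TF the
mask-supported |W_tf_go| . |W_go_out| path strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expression import ExpressionMatrix
from .model import SparseGOModel


@dataclass
class AttributionReport:
    target_label: str
    gene_scores: dict[str, float] = field(default_factory=dict)
    go_scores: dict[str, float] = field(default_factory=dict)
    tf_scores: dict[str, float] = field(default_factory=dict)
    reference_description: str = ""

    def top_genes(self, n: int = 10) -> list[str]:
        return sorted(self.gene_scores, key=lambda g: -self.gene_scores[g])[:n]

    def to_frame(self, which: str = "gene"):
        import pandas as pd

        scores = getattr(self, f"{which}_scores")
        df = pd.DataFrame(
            {which: list(scores), "score": list(scores.values())}
        ).sort_values("score", ascending=False, kind="stable")
        df["rank"] = np.arange(1, len(df) + 1)
        return df.reset_index(drop=True)


def _target_index(model: SparseGOModel, target_label: str) -> int:
    if model.mode != "classification" or model.label_map is None:
        raise ValueError("attribution requires a classification model")
    try:
        return model.label_map.index(target_label)
    except ValueError:
        raise ValueError(f"target_label {target_label!r} not in label map") from None


def _multiplier(h: np.ndarray, h_ref: np.ndarray, z: np.ndarray, z_ref: np.ndarray) -> np.ndarray:
    """Rescale-rule multiplier Delta(h)/Delta(z); 0 where Delta(z) vanishes
    (there Delta(h) vanishes too for any 1-Lipschitz activation)."""
    dz = z - z_ref
    dh = h - h_ref
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(np.abs(dz) > 1e-12, dh / np.where(dz == 0, 1.0, dz), 0.0)
    return m


def rescale_contributions(
    model: SparseGOModel,
    X: np.ndarray,
    target_index: int,
    reference: np.ndarray,
) -> np.ndarray:
    """Per-cell, per-gene contributions to the target logit relative to the
    reference input.  Rows sum to logit(x) - logit(reference)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ref = np.asarray(reference, dtype=float).reshape(1, -1)
    cx = model.forward(X, cache=True)
    cr = model.forward(ref, cache=True)

    m_tf = _multiplier(cx["H1"], cr["H1"], cx["Z1"], cr["Z1"])
    m_go = _multiplier(cx["H2"], cr["H2"], cx["Z2"], cr["Z2"])
    dx = X - ref

    d_hgo = model.W_go_out[:, target_index][None, :]  # 1 x |GO|
    d_zgo = m_go * d_hgo
    direct = dx * (d_zgo @ model.W_gene_go.T)
    d_htf = d_zgo @ model.W_tf_go.T
    d_ztf = m_tf * d_htf
    via_tf = dx * (d_ztf @ model.W_gene_tf.T)
    return direct + via_tf


def gene_importance(
    model: SparseGOModel,
    X: ExpressionMatrix | np.ndarray,
    target_label: str,
    reference: str = "zeros",
) -> AttributionReport:
    """Average rescale-rule gene contributions over cells of the target class.

    ``reference`` is either ``"zeros"`` (silent cell) or ``"mean"`` (the mean
    expression profile of X).  Cells are assigned to the target class by the
    model's own argmax prediction.
    """
    t = _target_index(model, target_label)
    Xv = X.values if isinstance(X, ExpressionMatrix) else np.atleast_2d(np.asarray(X, dtype=float))
    if Xv.shape[0] == 0:
        raise ValueError("X is empty")
    if reference == "zeros":
        ref = np.zeros(Xv.shape[1])
    elif reference == "mean":
        ref = Xv.mean(axis=0)
    else:
        raise ValueError(f"unknown reference {reference!r}")

    probs = model.forward(Xv)
    members = np.flatnonzero(probs.argmax(axis=1) == t)
    if members.size == 0:
        raise ValueError(f"no cells predicted as {target_label!r}")
    contrib = rescale_contributions(model, Xv[members], t, ref)
    mean_contrib = contrib.mean(axis=0)
    return AttributionReport(
        target_label=target_label,
        gene_scores=dict(zip(model.masks.genes, mean_contrib.tolist())),
        reference_description=f"{reference} reference, {members.size} cells",
    )


def go_contributions(
    model: SparseGOModel,
    target_label: str,
    aggregation: str | None = None,
    X: ExpressionMatrix | np.ndarray | None = None,
) -> AttributionReport:
    """Per-GO-term contribution to an output node by weight tracing.

    ``weight`` mode scores |W_go_out[g, target]|; ``weight_times_activation``
    additionally scales by the magnitude of the mean GO-node activation over
    the supplied cells (pass cells of the target class — activations are
    signed, so averaging over a mixture of classes cancels the signal).
    Default: activation-scaled when cells are given, plain weights otherwise.
    Scores are returned sorted descending (ties in vocabulary order).
    """
    t = _target_index(model, target_label)
    if aggregation is None:
        aggregation = "weight" if X is None else "weight_times_activation"
    w = np.abs(model.W_go_out[:, t])
    if aggregation == "weight":
        scores = w
        desc = "weight tracing"
    elif aggregation == "weight_times_activation":
        if X is None:
            raise ValueError("weight_times_activation requires cells X")
        Xv = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
        h_go = model.forward(Xv, cache=True)["H2"]
        scores = w * np.abs(h_go.mean(axis=0))
        desc = "weight x |mean activation|"
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    order = np.argsort(-scores, kind="stable")
    go = model.masks.go_terms
    return AttributionReport(
        target_label=target_label,
        go_scores={go[j]: float(scores[j]) for j in order},
        reference_description=desc,
    )


def tf_contributions(model: SparseGOModel, target_label: str) -> AttributionReport:
    """TF contribution = sum over GO nodes of |W_tf_go| . |W_go_out[., target]|
    along mask-supported paths (masked weights are exactly zero, so only
    knowledge-supported paths contribute)."""
    t = _target_index(model, target_label)
    path = np.abs(model.W_tf_go) @ np.abs(model.W_go_out[:, t])
    order = np.argsort(-path, kind="stable")
    tfs = model.masks.tfs
    return AttributionReport(
        target_label=target_label,
        tf_scores={tfs[k]: float(path[k]) for k in order},
        reference_description="two-layer weight tracing",
    )
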