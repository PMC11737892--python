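"""Synthetic knowledge graphs and expression matrices with planted structure.

The generator emulates the ingredients the masked network consumes: a gene
vocabulary, GO-term memberships, TF regulons, and log-normalizable
negative-binomial counts.  Each cell type is tied to a disjoint set of
marker genes, and those markers form the membership of one designated GO
term and the regulon of one designated TF, so attribution and perturbation
analyses have an unambiguous ground truth to recover.

Counts are gamma-Poisson (negative binomial) with a per-gene mean of
``baseline_mean``, multiplied by ``exp(effect_size)`` for the cell type's
marker genes.  A continuous variant draws a latent score s ~ U(0, 1) per
cell and scales an "up-program" gene set by ``exp(effect_size * s)`` and a
"down-program" by ``exp(-effect_size * s)``, mimicking a graded cell state
such as a senescence score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .expression import ExpressionMatrix, log_normalize
from .knowledge import AnnotationRecord, AnnotationTable, TFTargetTable

# re-exported under the conventional name used elsewhere in the package
lognormalize = log_normalize


@dataclass
class SyntheticScenario:
    """Sizes, effect sizes and noise levels of a planted-structure dataset."""

    n_genes: int = 500
    n_tfs: int = 25
    n_terms: int = 40
    genes_per_term: int = 10
    targets_per_tf: int = 10
    n_cell_types: int = 5
    n_cells_per_type: int = 200
    marker_genes_per_type: int = 10
    effect_size: float = 2.0  # log-scale mean shift of marker genes
    dispersion: float = 0.5  # NB overdispersion; 0 = Poisson
    baseline_mean: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_genes", "n_tfs", "n_terms", "genes_per_term", "targets_per_tf",
            "n_cell_types", "n_cells_per_type", "marker_genes_per_type",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.dispersion < 0 or self.baseline_mean <= 0:
            raise ValueError("dispersion must be >= 0 and baseline_mean > 0")

    @property
    def gene_names(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    @property
    def type_labels(self) -> list[str]:
        return [f"type{k}" for k in range(self.n_cell_types)]


def make_knowledge(
    scenario: SyntheticScenario,
) -> tuple[AnnotationTable, TFTargetTable, dict]:
    """Random gene<->GO and TF<->target graphs with planted class structure.

    The first ``n_cell_types`` GO terms and TFs are the planted ones: term k's
    membership is exactly the markers of cell type k (padded with random genes
    if ``genes_per_term`` exceeds the marker count) plus the planted TF's own
    gene, and TF k's regulon is exactly those markers.  Remaining terms/TFs
    get uniformly random memberships at the requested sizes.
    """
    sc = scenario
    if sc.genes_per_term > sc.n_genes or sc.targets_per_tf > sc.n_genes:
        raise ValueError("term/regulon size exceeds the gene vocabulary")
    n_marked = sc.n_cell_types * sc.marker_genes_per_type
    if sc.n_tfs + n_marked > sc.n_genes:
        raise ValueError(
            "gene vocabulary too small for disjoint TF genes and type markers"
        )
    if sc.n_cell_types > min(sc.n_terms, sc.n_tfs):
        raise ValueError("need at least one GO term and one TF per cell type")

    rng = np.random.default_rng([sc.seed, 0])
    genes = sc.gene_names
    tf_genes = genes[: sc.n_tfs]  # TF genes are part of the vocabulary
    non_tf = np.array(genes[sc.n_tfs :])
    marker_pool = rng.choice(non_tf, size=n_marked, replace=False)
    markers = {
        lab: sorted(marker_pool[k * sc.marker_genes_per_type : (k + 1) * sc.marker_genes_per_type])
        for k, lab in enumerate(sc.type_labels)
    }

    term_ids = [f"GO:{j + 1:07d}" for j in range(sc.n_terms)]
    pairs: set[tuple[str, str]] = set()
    records: list[AnnotationRecord] = []

    def _annotate(gene: str, term: str) -> None:
        if (gene, term) not in pairs:
            pairs.add((gene, term))
            records.append(AnnotationRecord(gene, term))

    planted: dict = {"types": {}}
    for k, lab in enumerate(sc.type_labels):
        term, tf = term_ids[k], tf_genes[k]
        members = list(markers[lab])
        if sc.genes_per_term > len(members):
            pad_pool = [g for g in genes if g not in members and g not in tf_genes]
            members += list(
                rng.choice(pad_pool, size=sc.genes_per_term - len(members), replace=False)
            )
        for g in members[: max(sc.genes_per_term, len(markers[lab]))]:
            _annotate(g, term)
        _annotate(tf, term)  # TF->GO wiring inherits the TF gene's annotations
        planted["types"][lab] = {"markers": markers[lab], "go_term": term, "tf": tf}

    for term in term_ids[sc.n_cell_types :]:
        for g in rng.choice(genes, size=sc.genes_per_term, replace=False):
            _annotate(g, term)

    tf_records: set[tuple[str, str]] = set()
    for k, lab in enumerate(sc.type_labels):
        for g in markers[lab]:
            tf_records.add((tf_genes[k], g))
    for tf in tf_genes[sc.n_cell_types :]:
        for g in rng.choice(genes, size=sc.targets_per_tf, replace=False):
            tf_records.add((tf, g))

    return (
        AnnotationTable(records),
        TFTargetTable(sorted(tf_records)),
        planted,
    )


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with Var = mean + dispersion * mean^2."""
    if dispersion == 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def simulate_cells(
    scenario: SyntheticScenario, knowledge: dict
) -> tuple[np.ndarray, list[str]]:
    """Negative-binomial counts with type-specific marker up-shifts.

    ``knowledge`` is the planted-truth dict from :func:`make_knowledge`.
    Returns an integer (n_cell_types * n_cells_per_type) x n_genes matrix and
    the per-cell type labels.
    """
    sc = scenario
    rng = np.random.default_rng([sc.seed, 1])
    gene_index = {g: i for i, g in enumerate(sc.gene_names)}
    blocks, labels = [], []
    for lab in sc.type_labels:
        mean = np.full(sc.n_genes, sc.baseline_mean)
        for g in knowledge["types"][lab]["markers"]:
            mean[gene_index[g]] *= np.exp(sc.effect_size)
        mean_matrix = np.tile(mean, (sc.n_cells_per_type, 1))
        blocks.append(_nb_counts(rng, mean_matrix, sc.dispersion))
        labels += [lab] * sc.n_cells_per_type
    return np.vstack(blocks), labels


def simulate_continuous(
    scenario: SyntheticScenario,
    knowledge: dict,
    n_cells: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Counts driven by a continuous latent score s ~ U(0, 1) per cell.

    Graded transcriptional states in real data (senescence scores, cell-cycle
    phase, differentiation stage) engage programs of dozens of genes spread
    over several functional modules, so the up- and down-programs here span
    multiple planted marker modules: the up-program is the markers of the
    first ceil(n_cell_types / 2) types (mean scaled by exp(effect_size * s))
    and the down-program is the markers of the remaining types (scaled by
    exp(-effect_size * s)).  Returns (counts, scores).
    """
    sc = scenario
    if sc.n_cell_types < 2:
        raise ValueError("continuous simulation needs two planted programs")
    rng = np.random.default_rng([sc.seed, 2])
    gene_index = {g: i for i, g in enumerate(sc.gene_names)}
    n_up_types = (sc.n_cell_types + 1) // 2
    up = [
        gene_index[g]
        for lab in sc.type_labels[:n_up_types]
        for g in knowledge["types"][lab]["markers"]
    ]
    down = [
        gene_index[g]
        for lab in sc.type_labels[n_up_types:]
        for g in knowledge["types"][lab]["markers"]
    ]
    scores = rng.uniform(0.0, 1.0, size=n_cells)
    mean = np.full((n_cells, sc.n_genes), sc.baseline_mean)
    mean[:, up] *= np.exp(sc.effect_size * scores)[:, None]
    mean[:, down] *= np.exp(-sc.effect_size * scores)[:, None]
    return _nb_counts(rng, mean, sc.dispersion), scores
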