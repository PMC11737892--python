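"""Shared fixtures: planted-structure datasets and trained models.

Everything is generated programmatically and deterministically; training
the session-scoped models takes a few tens of seconds total and they are
shared by the unit, property and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import sparsego as sg


@pytest.fixture(scope="session")
def default_scenario() -> sg.SyntheticScenario:
    """The reference study conditions: 5 types x 200 cells, 500 genes,
    marker effect size 2 on the log scale, NB dispersion 0.5."""
    return sg.SyntheticScenario()


@pytest.fixture(scope="session")
def default_data(default_scenario):
    sc = default_scenario
    ann, tft, truth = sg.make_knowledge(sc)
    masks = sg.align_masks(sg.build_masks(ann, tft, sc.gene_names), sc.gene_names)
    counts, labels = sg.simulate_cells(sc, truth)
    expr = sg.lognormalize(counts, gene_names=sc.gene_names)
    labels = np.array(labels)
    rng = np.random.default_rng(0)
    perm = rng.permutation(expr.n_cells)
    n_test = expr.n_cells // 5
    return {
        "scenario": sc,
        "annotations": ann,
        "tf_targets": tft,
        "truth": truth,
        "masks": masks,
        "expr": expr,
        "labels": labels,
        "test_idx": perm[:n_test],
        "train_idx": perm[n_test:],
    }


@pytest.fixture(scope="session")
def trained_classifier(default_data):
    d = default_data
    model = sg.init_model(d["masks"], sorted(set(d["labels"])), seed=0)
    history = sg.train(
        model,
        d["expr"].values[d["train_idx"]],
        d["labels"][d["train_idx"]],
        sg.TrainingConfig(seed=0),
    )
    return model, history


@pytest.fixture(scope="session")
def small_data():
    """A fast 3-type scenario for unit tests that need a trained model but
    not the full study conditions."""
    sc = sg.SyntheticScenario(
        n_genes=80, n_tfs=8, n_terms=10, genes_per_term=6, targets_per_tf=6,
        n_cell_types=3, n_cells_per_type=60, marker_genes_per_type=4, seed=2,
    )
    ann, tft, truth = sg.make_knowledge(sc)
    masks = sg.align_masks(
        sg.build_masks(ann, tft, sc.gene_names, min_term_size=2), sc.gene_names
    )
    counts, labels = sg.simulate_cells(sc, truth)
    expr = sg.lognormalize(counts, gene_names=sc.gene_names)
    return {
        "scenario": sc,
        "truth": truth,
        "masks": masks,
        "expr": expr,
        "labels": np.array(labels),
    }


@pytest.fixture(scope="session")
def small_classifier(small_data):
    d = small_data
    model = sg.init_model(d["masks"], sorted(set(d["labels"])), seed=0)
    sg.train(
        model, d["expr"].values, d["labels"],
        sg.TrainingConfig(seed=0, max_epochs=300, early_stop_patience=30),
    )
    return model
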