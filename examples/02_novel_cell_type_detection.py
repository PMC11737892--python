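"""Open-set detection of a never-seen cell type.

Trains on 4 of 5 synthetic types and applies the 0.95 maximum-probability
cutoff: cells of the held-out type should fall below the cutoff (flagged
novel) while known-type cells stay confidently above it.
"""

import numpy as np

import sparsego as sg

scenario = sg.SyntheticScenario(seed=0)
annotations, tf_targets, truth = sg.make_knowledge(scenario)
masks = sg.align_masks(
    sg.build_masks(annotations, tf_targets, scenario.gene_names),
    scenario.gene_names,
)
counts, labels = sg.simulate_cells(scenario, truth)
expr = sg.lognormalize(counts, gene_names=scenario.gene_names)
labels = np.array(labels)

held_out = "type4"
known = np.flatnonzero(labels != held_out)
novel = np.flatnonzero(labels == held_out)
rng = np.random.default_rng(0)
rng.shuffle(known)
test_known, train_known = known[:160], known[160:]

model = sg.init_model(masks, sorted(set(labels[train_known])), seed=0)
sg.train(model, expr.values[train_known], labels[train_known], sg.TrainingConfig(seed=0))

res_novel = sg.predict(model, expr.values[novel], novelty_threshold=0.95)
res_known = sg.predict(model, expr.values[test_known], novelty_threshold=0.95)
print(f"held-out type '{held_out}' flagged novel: {res_novel.novelty_flag.mean():.1%}")
print(f"known-type test cells flagged novel:     {res_known.novelty_flag.mean():.1%}")
print("(the first should be high, the second low)")
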