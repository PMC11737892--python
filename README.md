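# sparsego

Biologically informed sparse neural networks for interpretable cell status
annotation from single-cell expression data.

## The problem

Cell type annotation from scRNA-seq is usually done either by marker lists
or by black-box classifiers.  `sparsego` takes a third route: a neural
network whose hidden nodes *are* biological entities.  The first hidden
layer has one node per transcription factor (TF), the second one node per
Gene Ontology (GO) term, and the connections between layers exist only
where prior knowledge supports them — a gene connects to a GO node only if
it is annotated with that term, and to a TF node only if it is a known
target of that TF.  Formally, each hidden linear layer carries a binary
mask `M` with

    M[i, j] = 1  iff  gene i is annotated with GO term j  (else 0)

and the effective weights are `W ⊙ M`, so knowledge-unsupported weights are
exactly zero at initialization and after every training step.  This prunes
the parameter count by one to two orders of magnitude, reduces overfitting
on small training sets, and makes the trained weights directly readable:
tracing `|W_go_out[:, c]|` ranks the GO terms driving cell type `c`, and a
DeepLIFT-style rescale-rule attribution (activation differences against a
reference input, backpropagated to the gene layer) ranks genes.

The model is trained with Adam (learning rate 0.001) on the cross-entropy
loss `Loss = −Σ_i z_i log(q_i)` for classification, or mean squared error
with a single linear output for continuous cell states (e.g. senescence-like
scores).  On top of the classifier the package provides:

* **open-set prediction** — cells whose maximum class probability falls
  below a cutoff (0.95 by default) are flagged as putative novel cell types;
* **in-silico perturbation screening** — each gene is inhibited (×0.5) or
  activated (×2) per cell and genes are ranked by the fraction of cells
  whose predicted state flips;
* **de-novo TF–target inference** — TF expression is embedded into a latent
  space, decoded back to the full expression space, and each TF is perturbed
  to score candidate target genes by their decoded fluctuation;
* **a synthetic-data generator** with planted marker/GO/TF structure, so
  every capability can be validated against a known ground truth;
* **first-principles metrics** (accuracy, precision/recall/F1, ROC/AUC,
  confusion matrices).

Everything is plain NumPy with hand-written gradients; the networks are
small (hundreds of genes by tens of terms) and train in seconds on a laptop
CPU, fully deterministically given a seed.

## Worked example

```bash
python examples/01_annotate_cell_types.py
```

builds a 5-type synthetic dataset (200 cells per type, 500 genes, planted
10-gene marker programs), compiles GO/TF masks, trains the masked classifier
and prints:

```
trained 890 epochs, final loss 0.0059
parameters: 944 masked vs 33770 dense (2.8% of a fully connected net)
held-out accuracy: 1.000
held-out macro-F1: 1.000
```

The parameter line shows the knowledge pruning (~3% of a dense network);
the accuracy/F1 lines show the planted cell identities are recovered on
held-out cells.  The other examples exercise one capability each — novelty
detection (`02`), attribution (`03`), perturbation screening (`04`),
regression (`05`), de-novo TF targets (`06`) — and print both the model's
output and the planted truth it should match.  For shell-based workflows
the same steps are available as a thin CLI
(`sparsego simulate|build-masks|train|predict|interpret|perturb|infer-tf-targets|evaluate`);
every run writes a `run_manifest.json` with the resolved configuration and
input checksums.

## Layout

```
src/sparsego/
  knowledge.py    GAF / TSV parsers, mask compilation and alignment
  expression.py   ExpressionMatrix container, log-normalization
  model.py        masked network, Adam training, open-set prediction, persistence
  interpret.py    rescale-rule attribution, GO/TF weight tracing
  perturb.py      perturbation screen, de-novo TF-target inference
  metrics.py      accuracy / F1 / ROC-AUC / confusion from first principles
  simulate.py     planted-structure synthetic data generator
  io.py, cli.py   MTX / CSV readers-writers, thin command line
docs/methods.md   model, assumptions, parameter choices, limitations
examples/         one short narrative script per capability
```
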