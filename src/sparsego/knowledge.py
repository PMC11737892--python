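"""Parsing of GO annotation and TF-target knowledge, and mask compilation.

The network prunes its connectivity with binary masks derived from two
knowledge sources:

* gene -> GO term annotations (GAF 2.x files or a minimal two-column TSV),
* TF -> target-gene tables (e.g. DAP-seq peaks annotated to transcription
  start sites by an external tool, exported as a two-column TSV).

``build_masks`` compiles these into a :class:`MaskSet` of aligned 0/1
connectivity matrices: an entry ``M_gene_go[i, j]`` is 1 exactly when gene
``i`` is annotated with GO term ``j``, and analogously for the TF layers.
"""

from __future__ import annotations

import json
import re
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp

GO_ID_PATTERN = re.compile(r"^GO:\d{7}$")

_ASPECTS = {"P": "BP", "F": "MF", "C": "CC"}


@dataclass(frozen=True)
class AnnotationRecord:
    gene_id: str
    go_term_id: str
    aspect: str = "unknown"


@dataclass
class AnnotationTable:
    """Deduplicated gene -> GO term annotations."""

    records: list[AnnotationRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def pairs(self) -> set[tuple[str, str]]:
        return {(r.gene_id, r.go_term_id) for r in self.records}


@dataclass
class TFTargetTable:
    """Deduplicated TF gene -> target gene edges (self-targets retained)."""

    records: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class MaskSet:
    """Aligned vocabularies plus the binary connectivity matrices.

    ``M_gene_go`` is |genes| x |go_terms|, ``M_gene_tf`` is |genes| x |tfs|
    (entry 1 iff the gene is a *target* of the TF), ``M_tf_go`` is
    |tfs| x |go_terms| (by default a TF node inherits the GO annotations of
    its own gene; pass ``tf_go_wiring="dense"`` to ``build_masks`` for
    all-ones wiring).
    """

    genes: list[str]
    tfs: list[str]
    go_terms: list[str]
    M_gene_go: np.ndarray
    M_gene_tf: np.ndarray
    M_tf_go: np.ndarray
    min_term_size: int = 1
    max_term_size: int = 10**9

    def __post_init__(self) -> None:
        self.M_gene_go = np.asarray(self.M_gene_go, dtype=np.float64)
        self.M_gene_tf = np.asarray(self.M_gene_tf, dtype=np.float64)
        self.M_tf_go = np.asarray(self.M_tf_go, dtype=np.float64)
        if self.M_gene_go.shape != (len(self.genes), len(self.go_terms)):
            raise ValueError("M_gene_go shape does not match vocabularies")
        if self.M_gene_tf.shape != (len(self.genes), len(self.tfs)):
            raise ValueError("M_gene_tf shape does not match vocabularies")
        if self.M_tf_go.shape != (len(self.tfs), len(self.go_terms)):
            raise ValueError("M_tf_go shape does not match vocabularies")
        for m in (self.M_gene_go, self.M_gene_tf, self.M_tf_go):
            if m.size and not np.isin(m, (0.0, 1.0)).all():
                raise ValueError("mask entries must be 0 or 1")

    @property
    def nnz(self) -> tuple[int, int, int]:
        return (
            int(self.M_gene_go.sum()),
            int(self.M_gene_tf.sum()),
            int(self.M_tf_go.sum()),
        )


def _open_text(path: str | Path):
    import gzip

    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def load_go_annotations(path: str | Path, format: str = "tsv2col") -> AnnotationTable:
    """Read gene -> GO annotations from a GAF 2.x or two-column TSV file.

    GAF dialect: lines starting with ``!`` are comments; only the gene symbol
    (column 3), GO id (column 5) and aspect (column 9) are read, and records
    whose qualifier (column 4) contains ``NOT`` are skipped.  GO ids must
    match ``GO:#######``; malformed ids are skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format not in ("gaf", "tsv2col"):
        raise ValueError(f"unknown format {format!r}")

    seen: set[tuple[str, str]] = set()
    records: list[AnnotationRecord] = []
    n_bad = 0
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            cols = line.split("\t")
            if format == "gaf":
                if len(cols) < 9:
                    n_bad += 1
                    continue
                gene, qualifier, go_id, aspect_code = cols[2], cols[3], cols[4], cols[8]
                if "NOT" in qualifier.split("|"):
                    continue
                aspect = _ASPECTS.get(aspect_code, "unknown")
            else:
                if len(cols) < 2:
                    n_bad += 1
                    continue
                gene, go_id = cols[0], cols[1]
                aspect = "unknown"
            if not gene or not GO_ID_PATTERN.match(go_id):
                n_bad += 1
                continue
            key = (gene, go_id)
            if key in seen:
                continue
            seen.add(key)
            records.append(AnnotationRecord(gene, go_id, aspect))
    if n_bad:
        warnings.warn(f"skipped {n_bad} malformed annotation line(s) in {path}")
    if not records:
        raise ValueError("no annotations parsed")
    return AnnotationTable(records)


def load_tf_targets(path: str | Path) -> TFTargetTable:
    """Read a header-less two-column ``tf<TAB>target`` TSV (deduplicated)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    seen: set[tuple[str, str]] = set()
    records: list[tuple[str, str]] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 2 or not cols[0] or not cols[1]:
                continue
            key = (cols[0], cols[1])
            if key in seen:
                continue
            seen.add(key)
            records.append(key)
    if not records:
        raise ValueError(f"no TF-target records parsed from {path}")
    return TFTargetTable(records)


def build_masks(
    annotations: AnnotationTable,
    tf_targets: TFTargetTable,
    gene_vocab: Sequence[str],
    min_term_size: int = 5,
    max_term_size: int = 500,
    tf_go_wiring: str = "inherit",
) -> MaskSet:
    """Compile knowledge tables into aligned binary connectivity masks.

    GO terms are kept when their membership *within gene_vocab* has size in
    ``[min_term_size, max_term_size]``; TFs are kept when their gene appears
    in ``gene_vocab``.  Genes absent from all knowledge remain all-zero rows.
    """
    gene_vocab = list(gene_vocab)
    if not gene_vocab:
        raise ValueError("gene_vocab must be non-empty")
    if len(set(gene_vocab)) != len(gene_vocab):
        raise ValueError("gene_vocab contains duplicates")
    if not (1 <= min_term_size <= max_term_size):
        raise ValueError("require 1 <= min_term_size <= max_term_size")
    if tf_go_wiring not in ("inherit", "dense"):
        raise ValueError(f"unknown tf_go_wiring {tf_go_wiring!r}")

    gene_index = {g: i for i, g in enumerate(gene_vocab)}

    term_members: dict[str, set[str]] = {}
    for rec in annotations.records:
        if rec.gene_id in gene_index:
            term_members.setdefault(rec.go_term_id, set()).add(rec.gene_id)
    go_terms = sorted(
        t for t, members in term_members.items()
        if min_term_size <= len(members) <= max_term_size
    )
    if not go_terms:
        raise ValueError("knowledge too sparse for vocabulary: zero surviving GO terms")
    term_index = {t: j for j, t in enumerate(go_terms)}

    tfs = sorted({tf for tf, _ in tf_targets.records if tf in gene_index})
    tf_index = {t: k for k, t in enumerate(tfs)}

    M_gene_go = np.zeros((len(gene_vocab), len(go_terms)))
    for term, members in term_members.items():
        j = term_index.get(term)
        if j is None:
            continue
        for g in members:
            M_gene_go[gene_index[g], j] = 1.0

    M_gene_tf = np.zeros((len(gene_vocab), len(tfs)))
    for tf, target in tf_targets.records:
        k = tf_index.get(tf)
        if k is not None and target in gene_index:
            M_gene_tf[gene_index[target], k] = 1.0

    if tf_go_wiring == "dense":
        M_tf_go = np.ones((len(tfs), len(go_terms)))
    else:
        M_tf_go = np.zeros((len(tfs), len(go_terms)))
        for tf, k in tf_index.items():
            M_tf_go[k, :] = M_gene_go[gene_index[tf], :]

    return MaskSet(
        genes=gene_vocab,
        tfs=tfs,
        go_terms=go_terms,
        M_gene_go=M_gene_go,
        M_gene_tf=M_gene_tf,
        M_tf_go=M_tf_go,
        min_term_size=min_term_size,
        max_term_size=max_term_size,
    )


def align_masks(masks: MaskSet, expression_genes: Sequence[str]) -> MaskSet:
    """Restrict/reorder mask rows to an expression vocabulary.

    The returned gene rows follow ``expression_genes`` order (restricted to
    genes the masks know about).  GO columns left with no member and TF
    columns left with no target are dropped.  Idempotent for a fixed
    vocabulary.
    """
    expression_genes = list(expression_genes)
    if not expression_genes:
        raise ValueError("expression_genes must be non-empty")
    known = {g: i for i, g in enumerate(masks.genes)}
    kept = [g for g in expression_genes if g in known]
    if not kept:
        raise ValueError("no overlap between mask genes and expression genes")
    coverage = len(kept) / len(expression_genes)
    if coverage < 1.0:
        warnings.warn(
            f"expression vocabulary coverage {coverage:.1%}: "
            f"{len(expression_genes) - len(kept)} gene(s) absent from masks"
        )
    rows = [known[g] for g in kept]
    M_gene_go = masks.M_gene_go[rows, :]
    M_gene_tf = masks.M_gene_tf[rows, :]

    keep_terms = np.flatnonzero(M_gene_go.sum(axis=0) >= 1)
    keep_tfs = np.flatnonzero(M_gene_tf.sum(axis=0) >= 1)
    return MaskSet(
        genes=kept,
        tfs=[masks.tfs[k] for k in keep_tfs],
        go_terms=[masks.go_terms[j] for j in keep_terms],
        M_gene_go=M_gene_go[:, keep_terms],
        M_gene_tf=M_gene_tf[:, keep_tfs],
        M_tf_go=masks.M_tf_go[np.ix_(keep_tfs, keep_terms)],
        min_term_size=masks.min_term_size,
        max_term_size=masks.max_term_size,
    )


_MASK_FILES = {
    "M_gene_go": "gene_go.mtx",
    "M_gene_tf": "gene_tf.mtx",
    "M_tf_go": "tf_go.mtx",
}


def save_masks(masks: MaskSet, path: str | Path) -> None:
    """Serialize a MaskSet to a zip of coordinate-format matrices,
    one-id-per-line vocabulary files and a JSON manifest."""
    import hashlib
    import io

    path = Path(path)
    manifest = {
        "format": "sparsego-maskset",
        "version": 1,
        "min_term_size": masks.min_term_size,
        "max_term_size": masks.max_term_size,
        "shapes": {
            "M_gene_go": list(masks.M_gene_go.shape),
            "M_gene_tf": list(masks.M_gene_tf.shape),
            "M_tf_go": list(masks.M_tf_go.shape),
        },
        "checksums": {},
    }
    payload: dict[str, bytes] = {}
    for attr, fname in _MASK_FILES.items():
        buf = io.BytesIO()
        scipy.io.mmwrite(buf, sp.coo_matrix(getattr(masks, attr)))
        payload[fname] = buf.getvalue()
    payload["genes.txt"] = ("\n".join(masks.genes) + "\n").encode()
    payload["tfs.txt"] = ("\n".join(masks.tfs) + ("\n" if masks.tfs else "")).encode()
    payload["go_terms.txt"] = ("\n".join(masks.go_terms) + "\n").encode()
    for fname, data in payload.items():
        manifest["checksums"][fname] = hashlib.sha256(data).hexdigest()
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=1))
        for fname, data in payload.items():
            zf.writestr(fname, data)


def load_masks(path: str | Path) -> MaskSet:
    import io

    with zipfile.ZipFile(path) as zf:
        manifest = json.loads(zf.read("manifest.json"))
        if manifest.get("format") != "sparsego-maskset":
            raise ValueError("not a sparsego mask archive")
        mats = {}
        for attr, fname in _MASK_FILES.items():
            m = scipy.io.mmread(io.BytesIO(zf.read(fname)))
            mats[attr] = np.asarray(sp.coo_matrix(m, shape=manifest["shapes"][attr]).todense())

        def _vocab(fname: str) -> list[str]:
            text = zf.read(fname).decode()
            return [line for line in text.splitlines() if line]

        return MaskSet(
            genes=_vocab("genes.txt"),
            tfs=_vocab("tfs.txt"),
            go_terms=_vocab("go_terms.txt"),
            min_term_size=manifest["min_term_size"],
            max_term_size=manifest["max_term_size"],
            **mats,
        )
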