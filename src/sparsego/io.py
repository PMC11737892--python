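"""Expression file readers and writers.

Supported layouts:

* ``mtx_dir`` — a directory holding ``matrix.mtx(.gz)``,
  ``features.tsv(.gz)`` and ``barcodes.tsv(.gz)`` in the 10x triplet
  convention (features file column 1 = id, column 2 = symbol; the symbol is
  used when present).  The standard orientation is genes_by_cells.
* ``dense_csv`` — CSV/TSV with cells in rows and a header of gene names;
  a leading ``cell_id`` column is used as cell identifiers when present.

Gzip is handled transparently by file extension.  Duplicate gene names are
suffixed ``.1``, ``.2``, ... deterministically.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .expression import ExpressionMatrix


def _find(directory: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(f"{stem}(.gz) not found in {directory}")


def _read_lines(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def dedupe_names(names: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for n in names:
        if n in seen:
            seen[n] += 1
            out.append(f"{n}.{seen[n]}")
        else:
            seen[n] = 0
            out.append(n)
    return out


def read_expression(
    path: str | Path,
    layout: str = "mtx_dir",
    orientation: str = "genes_by_cells",
) -> ExpressionMatrix:
    """Read an expression matrix; always returns cells x genes values."""
    path = Path(path)
    if orientation not in ("cells_by_genes", "genes_by_cells"):
        raise ValueError(f"unknown orientation {orientation!r}")

    if layout == "mtx_dir":
        mat = sp.coo_matrix(scipy.io.mmread(_find(path, "matrix.mtx"))).toarray()
        feature_lines = _read_lines(_find(path, "features.tsv"))
        barcodes = _read_lines(_find(path, "barcodes.tsv"))
        names = []
        for line in feature_lines:
            cols = line.split("\t")
            names.append(cols[1] if len(cols) > 1 and cols[1] else cols[0])
        if orientation == "genes_by_cells":
            mat = mat.T
        if mat.shape != (len(barcodes), len(names)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match "
                f"{len(barcodes)} barcodes x {len(names)} features"
            )
        return ExpressionMatrix(mat, dedupe_names(names), barcodes)

    if layout == "dense_csv":
        sep = "\t" if path.name.replace(".gz", "").endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(path, sep=sep)
        has_index = str(df.columns[0]) in ("cell_id", "barcode", "gene_id", "Unnamed: 0", "")
        index = df.iloc[:, 0].astype(str).tolist() if has_index else []
        if has_index:
            df = df.iloc[:, 1:]
        values = df.to_numpy(dtype=float)
        header = [str(c) for c in df.columns]
        if orientation == "genes_by_cells":
            # rows = genes (ids in the index column), header = cell ids
            values = values.T
            cell_ids = header
            names = index or [f"g{i}" for i in range(values.shape[1])]
        else:
            cell_ids = index
            names = header
        return ExpressionMatrix(values, dedupe_names(names), cell_ids)

    raise ValueError(f"unknown layout {layout!r}")


def write_expression(
    expr: ExpressionMatrix,
    path: str | Path,
    layout: str = "mtx_dir",
    orientation: str = "genes_by_cells",
) -> None:
    """Write an expression matrix in the chosen layout.

    Integer-valued matrices are written with an integer MTX field so count
    data round-trips exactly; floats are written at full precision.
    """
    path = Path(path)
    if layout == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        values = expr.values.T if orientation == "genes_by_cells" else expr.values
        is_int = np.all(values == np.round(values))
        mat = sp.coo_matrix(values.astype(np.int64) if is_int else values)
        scipy.io.mmwrite(path / "matrix.mtx", mat, field="integer" if is_int else "real",
                         precision=17)
        with open(path / "features.tsv", "w") as fh:
            for g in expr.gene_names:
                fh.write(f"{g}\t{g}\tGene Expression\n")
        with open(path / "barcodes.tsv", "w") as fh:
            fh.write("\n".join(expr.cell_ids) + "\n")
        return
    if layout == "dense_csv":
        sep = "\t" if path.name.replace(".gz", "").endswith((".tsv", ".txt")) else ","
        if orientation == "genes_by_cells":
            df = pd.DataFrame(expr.values.T, columns=expr.cell_ids)
            df.insert(0, "gene_id", expr.gene_names)
        else:
            df = pd.DataFrame(expr.values, columns=expr.gene_names)
            df.insert(0, "cell_id", expr.cell_ids)
        df.to_csv(path, sep=sep, index=False, float_format="%.10g")
        return
    raise ValueError(f"unknown layout {layout!r}")


def read_labels(path: str | Path) -> list[str]:
    """One label per line, or barcode<TAB>label; returns labels in file order."""
    lines = _read_lines(Path(path))
    labels = []
    for line in lines:
        cols = line.split("\t")
        labels.append(cols[-1])
    return labels


def write_labels(labels: list[str], path: str | Path, cell_ids: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        if cell_ids is None:
            fh.write("\n".join(labels) + "\n")
        else:
            for c, lab in zip(cell_ids, labels):
                fh.write(f"{c}\t{lab}\n")
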