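"""Reading and writing the MTX-triplet + CSV interchange convention.

A count directory holds ``matrix.mtx`` (genes x cells, MatrixMarket),
``features.tsv``, ``barcodes.tsv`` and optionally ``metadata.csv`` (first
column = barcode). HTO directories use the same triplet with hashtags in
place of genes.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from timedrift.containers import CountMatrix, HtoMatrix


def write_counts(m: CountMatrix, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    scipy.io.mmwrite(os.path.join(out_dir, "matrix.mtx"), sp.coo_matrix(m.counts))
    pd.Series(m.gene_names).to_csv(
        os.path.join(out_dir, "features.tsv"), sep="\t", index=False, header=False
    )
    pd.Series(m.barcodes).to_csv(
        os.path.join(out_dir, "barcodes.tsv"), sep="\t", index=False, header=False
    )
    meta = m.cell_meta.copy()
    meta.index.name = "barcode"
    meta.to_csv(os.path.join(out_dir, "metadata.csv"))


def read_counts(in_dir: str) -> CountMatrix:
    counts = sp.csr_matrix(scipy.io.mmread(os.path.join(in_dir, "matrix.mtx")))
    genes = pd.read_csv(
        os.path.join(in_dir, "features.tsv"), sep="\t", header=None
    ).iloc[:, 0]
    barcodes = pd.read_csv(
        os.path.join(in_dir, "barcodes.tsv"), sep="\t", header=None
    ).iloc[:, 0]
    meta_path = os.path.join(in_dir, "metadata.csv")
    if os.path.exists(meta_path):
        meta = pd.read_csv(meta_path, index_col=0)
        meta = meta.loc[barcodes.values]
    else:
        meta = pd.DataFrame(index=pd.Index(barcodes.values, name="barcode"))
    return CountMatrix(counts, pd.Index(genes.values), meta)


def write_hto(m: HtoMatrix, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    scipy.io.mmwrite(os.path.join(out_dir, "matrix.mtx"), sp.coo_matrix(m.counts))
    pd.Series(m.hto_names).to_csv(
        os.path.join(out_dir, "features.tsv"), sep="\t", index=False, header=False
    )
    pd.Series(m.barcode_ids).to_csv(
        os.path.join(out_dir, "barcodes.tsv"), sep="\t", index=False, header=False
    )


def read_hto(path: str) -> HtoMatrix:
    """Read an HTO matrix from a triplet directory or a CSV file.

    The CSV layout is hashtags in rows (first column = hashtag name) and
    barcodes in columns.
    """
    if os.path.isdir(path):
        counts = np.asarray(
            scipy.io.mmread(os.path.join(path, "matrix.mtx")).todense()
        )
        htos = pd.read_csv(
            os.path.join(path, "features.tsv"), sep="\t", header=None
        ).iloc[:, 0]
        barcodes = pd.read_csv(
            os.path.join(path, "barcodes.tsv"), sep="\t", header=None
        ).iloc[:, 0]
        return HtoMatrix(counts, pd.Index(htos.values), pd.Index(barcodes.values))
    df = pd.read_csv(path, index_col=0)
    return HtoMatrix(df.values, pd.Index(df.index), pd.Index(df.columns))


def read_gene_sets(path: str) -> dict[str, list[str]]:
    """Read gene sets from GMT (term, description, genes...) or two-column TSV
    (term <tab> gene, one pair per line)."""
    sets: dict[str, list[str]] = {}
    if path.endswith(".gmt"):
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or not parts[0]:
                    continue
                sets[parts[0]] = [g for g in parts[2:] if g]
        return sets
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    for term, group in df.groupby(0):
        sets[str(term)] = [str(g) for g in group[1]]
    return sets
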