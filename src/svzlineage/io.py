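"""Readers and writers for the plain-text formats the pipeline exchanges.

Count matrices use the CellRanger triplet layout (``matrix.mtx`` in Matrix
Market integer format with ``barcodes.tsv`` / ``features.tsv`` sidecars);
gene sets use GMT; everything else is CSV/TSV through pandas.
"""

from __future__ import annotations

import os
from typing import Dict, List

import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .types import CountMatrix


def write_10x(cm: CountMatrix, outdir: str) -> None:
    """Write a CountMatrix as matrix.mtx + barcodes.tsv + features.tsv.

    The Matrix Market file is genes x cells (CellRanger orientation).
    """
    os.makedirs(outdir, exist_ok=True)
    sio.mmwrite(
        os.path.join(outdir, "matrix.mtx"),
        sp.coo_matrix(cm.counts.T),
        field="integer",
    )
    cm.cell_meta.to_csv(
        os.path.join(outdir, "barcodes.tsv"), sep="\t", header=True, index=True
    )
    cm.gene_meta.to_csv(
        os.path.join(outdir, "features.tsv"), sep="\t", header=True, index=True
    )


def read_10x(indir: str) -> CountMatrix:
    mat = sio.mmread(os.path.join(indir, "matrix.mtx")).T.tocsr()
    cells = pd.read_csv(os.path.join(indir, "barcodes.tsv"), sep="\t", index_col=0)
    genes = pd.read_csv(os.path.join(indir, "features.tsv"), sep="\t", index_col=0)
    return CountMatrix(mat.astype(int), cells, genes)


def write_gmt(sets: Dict[str, List[str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def read_gmt(path: str) -> Dict[str, List[str]]:
    out: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            out[parts[0]] = [g for g in parts[2:] if g]
    return out
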