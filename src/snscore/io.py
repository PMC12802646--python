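"""Readers and writers for count matrices, score tables and run manifests.

Two matrix conventions are auto-detected: a 10x-style directory
(``matrix.mtx`` gene-major triplets, ``features.tsv`` with the symbol in
column 2, ``barcodes.tsv``) and a dense CSV with cells in rows and a header
row of gene symbols.  In-memory orientation is always cells-by-genes.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .preprocess import CountMatrix
from .synthetic import SimTruth

__all__ = [
    "read_counts",
    "read_10x_dir",
    "read_dense_csv",
    "write_10x_dir",
    "write_dense_csv",
    "write_truth_tsv",
    "read_truth_tsv",
    "write_score_table",
    "write_manifest",
]


def read_10x_dir(path: str | Path) -> CountMatrix:
    """Read a 10x-convention directory (gene-major .mtx is transposed)."""
    path = Path(path)
    mtx = sparse.csr_matrix(spio.mmread(path / "matrix.mtx")).T
    features = pd.read_csv(path / "features.tsv", sep="\t", header=None)
    symbol_col = 1 if features.shape[1] > 1 else 0
    genes = features.iloc[:, symbol_col].astype(str).to_numpy()
    barcodes = pd.read_csv(
        path / "barcodes.tsv", sep="\t", header=None
    ).iloc[:, 0].astype(str).to_numpy()
    counts = np.asarray(mtx.todense())
    return CountMatrix(counts, barcodes, genes)


def read_dense_csv(path: str | Path) -> CountMatrix:
    """Read a dense cells x genes CSV with a gene header and cell index."""
    df = pd.read_csv(path, index_col=0)
    return CountMatrix(
        df.to_numpy(), df.index.astype(str).to_numpy(),
        df.columns.astype(str).to_numpy(),
    )


def read_counts(path: str | Path) -> CountMatrix:
    """Auto-detect and read either supported matrix format."""
    path = Path(path)
    if path.is_dir():
        if not (path / "matrix.mtx").exists():
            raise FileNotFoundError(f"no matrix.mtx in directory {path}")
        return read_10x_dir(path)
    if path.suffix.lower() == ".csv":
        return read_dense_csv(path)
    raise ValueError(f"unsupported input {path}; expected a 10x directory "
                     "or a dense .csv")


def write_10x_dir(counts: CountMatrix, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(
        str(path / "matrix.mtx"),
        sparse.coo_matrix(counts.counts.T.astype(int)),
        field="integer",
    )
    with open(path / "features.tsv", "w") as fh:
        for g in counts.gene_ids:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(path / "barcodes.tsv", "w") as fh:
        for c in counts.cell_ids:
            fh.write(f"{c}\n")


def write_dense_csv(counts: CountMatrix, path: str | Path) -> None:
    pd.DataFrame(
        counts.counts.astype(int),
        index=counts.cell_ids, columns=counts.gene_ids,
    ).to_csv(path)


def write_truth_tsv(truth: SimTruth, cell_ids, path: str | Path) -> None:
    df = pd.DataFrame({"cell_id": cell_ids, "label": truth.labels})
    if truth.region is not None:
        df["region"] = truth.region
    if truth.coordinates is not None:
        df["x"] = truth.coordinates[:, 0]
        df["y"] = truth.coordinates[:, 1]
    df.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_score_table(result, path: str | Path) -> None:
    """Score TSV: cell_id, score, uncertainty, call, neuron, flipped."""
    n = len(result.score)
    df = pd.DataFrame({
        "cell_id": result.cell_ids if result.cell_ids is not None
        else [f"cell{i}" for i in range(n)],
        "score": result.score,
        "uncertainty": result.uncertainty if result.uncertainty is not None
        else np.full(n, np.nan),
        "call": (
            np.where(result.call, "senescent", "non-senescent")
            if result.call is not None else np.full(n, "NA")
        ),
        "neuron_index": result.neuron_index,
        "orientation_flipped": result.orientation_flipped,
    })
    df.to_csv(path, sep="\t", index=False)


def write_manifest(path: str | Path, seed: int, params: dict) -> None:
    """JSON run manifest with seed, parameters and a config hash."""
    from . import __version__

    payload = {
        "package": "snscore",
        "version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "parameters": params,
    }
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()
    payload["config_hash"] = digest
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
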