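"""Community-matrix transforms and dissimilarities.

Aligned bin tables (samples x T-RF bins of relative peak areas) are
prepared for ordination: Wisconsin double standardization followed by
Bray–Curtis dissimilarities, the combination conventionally fed to NMDS.
Ordination itself (metaMDS, envfit) is delegated to standard tools; this
module writes their exact inputs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = ["wisconsin", "bray_curtis", "combine_genes"]


def wisconsin(M: pd.DataFrame) -> pd.DataFrame:
    """Wisconsin double standardization.

    Each value is divided by its column (species) maximum, then each row
    (sample) by its row sum; output rows sum to 1. Raises on all-zero
    columns, naming the offending bins.
    """
    M = M.astype(float)
    if (M.values < 0).any():
        raise ValueError("community matrix must be non-negative")
    colmax = M.max(axis=0)
    dead = colmax[colmax == 0]
    if len(dead):
        raise ValueError(f"all-zero bins cannot be standardized: {list(dead.index)}")
    out = M / colmax
    rowsum = out.sum(axis=1)
    if (rowsum == 0).any():
        raise ValueError("all-zero samples cannot be standardized")
    return out.div(rowsum, axis=0)


def bray_curtis(M: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray–Curtis dissimilarities between samples.

    d(x, y) = sum|x_i - y_i| / sum(x_i + y_i); symmetric with zero
    diagonal, values in [0, 1]. Pairs of all-zero samples are undefined
    (NaN) and flagged with a warning.
    """
    X = M.astype(float).values
    if (X < 0).any():
        raise ValueError("community matrix must be non-negative")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        D = squareform(pdist(X, metric="braycurtis"))
    np.fill_diagonal(D, 0.0)
    if np.isnan(D).any():
        warnings.warn("Bray–Curtis undefined (NaN) for pairs of all-zero samples")
    return pd.DataFrame(D, index=M.index, columns=M.index)


def combine_genes(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-gene bin tables into one collective matrix.

    Columns get gene-prefixed ids; all tables must cover the same
    samples (row order of the first table is used).
    """
    if not tables:
        raise ValueError("no tables to combine")
    genes = list(tables)
    index = tables[genes[0]].index
    parts = []
    for gene in genes:
        t = tables[gene]
        if set(t.index) != set(index):
            raise ValueError(f"sample mismatch in gene table {gene!r}")
        t = t.loc[index]
        t = t.rename(columns={c: f"{gene}_{c}" for c in t.columns})
        parts.append(t)
    return pd.concat(parts, axis=1)
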