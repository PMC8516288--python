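"""Expression-table preprocessing: aggregation, filtering, normalization,
clustering.

The raw input is a transcript-level FPKM table over the experimental time
points plus one asynchronous sample.  Transcripts are summed per gene, lowly
expressed genes (asynchronous FPKM below a threshold) are removed, and rows
are z-scored before deconvolution.  Deconvolved profiles are mapped back to
the linear scale, stabilized with an adaptive per-column pseudocount (the
5th percentile of strictly positive values), log2-normalized against a
10^6-scaled column total, and double-centered so every row and column mean
is zero -- the representation consumed by the TF-activity regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "ClusterAssignment",
    "aggregate_and_filter",
    "zscore_rows",
    "unzscore_rows",
    "lognorm_transform",
    "cluster_rows",
]


@dataclass
class ClusterAssignment:
    """Cluster labels and a display ordering for the rows of a table."""

    row_ids: list
    labels: pd.Series  # row id -> cluster label (0..k-1)
    ordering: np.ndarray  # permutation of row positions for display
    k: int


def aggregate_and_filter(
    transcripts: pd.DataFrame,
    tx2gene: Optional[Mapping[str, str]] = None,
    async_col: str = "async",
    min_fpkm: float = 36.0,
) -> pd.DataFrame:
    """Sum transcript rows per gene and drop lowly expressed genes.

    Genes whose asynchronous-sample FPKM is strictly below ``min_fpkm`` are
    removed (strict inequality: a gene at exactly the threshold is kept).
    With no transcript-to-gene map the rows are taken to be genes already.
    """
    if async_col not in transcripts.columns:
        raise ValueError(f"missing asynchronous column {async_col!r}")
    if tx2gene:
        genes = transcripts.index.to_series().map(dict(tx2gene))
        if genes.isna().any():
            missing = list(transcripts.index[genes.isna()][:5])
            raise ValueError(f"transcripts without gene mapping, e.g. {missing}")
        table = transcripts.groupby(genes.values).sum()
        table.index.name = transcripts.index.name
    else:
        table = transcripts.copy()
    return table.loc[table[async_col] >= min_fpkm]


def zscore_rows(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Standardize each row to mean 0, SD 1 (population SD).

    Returns the transformed table and the per-row means and SDs needed to
    invert the transform later.  Constant rows (zero SD) are dropped with a
    warning.
    """
    mu = table.mean(axis=1)
    sigma = table.std(axis=1, ddof=0)
    constant = sigma == 0
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} constant rows (zero variance)",
            stacklevel=2,
        )
        table = table.loc[~constant]
        mu = mu.loc[~constant]
        sigma = sigma.loc[~constant]
    z = table.sub(mu, axis=0).div(sigma, axis=0)
    return z, mu, sigma


def unzscore_rows(z: pd.DataFrame, mu: pd.Series, sigma: pd.Series) -> pd.DataFrame:
    """Invert :func:`zscore_rows` using the stored per-row mean and SD."""
    return z.mul(sigma.loc[z.index], axis=0).add(mu.loc[z.index], axis=0)


def lognorm_transform(
    values: pd.DataFrame,
    mu: Optional[pd.Series] = None,
    sigma: Optional[pd.Series] = None,
    scale: float = 1e6,
) -> pd.DataFrame:
    """Adaptive-pseudocount log2 normalization followed by double centering.

    If ``mu``/``sigma`` are given the input is first mapped back to the
    linear scale (inverting an earlier row z-score).  Then, per column, the
    5th percentile of the strictly positive values is added as a pseudocount,
    values are normalized by the column total times ``scale`` and
    log2-transformed, and finally the table is double-centered
    (``e = e_hat - row_mean - col_mean + grand_mean``) so every row and
    column mean is zero.
    """
    linear = values
    if mu is not None and sigma is not None:
        linear = unzscore_rows(values, mu, sigma)
    linear = linear.astype(float).copy()

    for col in linear.columns:
        v = linear[col].to_numpy()
        pos = v[v > 0]
        if pos.size == 0:
            raise ValueError(f"column {col!r} has no positive values")
        pc = np.percentile(pos, 5)
        v = v + pc
        # entries still nonpositive after the shift (strongly negative
        # deconvolution artefacts) are floored at the pseudocount
        v[v <= 0] = pc
        linear[col] = v

    ehat = np.log2(scale * linear / linear.sum(axis=0))
    row_mean = ehat.mean(axis=1)
    col_mean = ehat.mean(axis=0)
    grand = float(ehat.values.mean())
    return ehat.sub(row_mean, axis=0).sub(col_mean, axis=1) + grand


def cluster_rows(
    table: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    n_init: int = 50,
) -> ClusterAssignment:
    """K-means clustering of row profiles with a display ordering.

    Clusters are renumbered by the peak time (argmax) of their mean profile
    so earlier-peaking clusters come first; within a cluster rows are sorted
    by Euclidean distance to the cluster mean.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > table.shape[0]:
        raise ValueError("more clusters than rows")
    X = table.to_numpy(dtype=float)
    if k == 1:
        raw = np.zeros(X.shape[0], dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        raw = km.fit_predict(X)

    # order clusters by the argmax of the mean profile, ties by cluster id
    peak = {}
    for c in range(k):
        profile = X[raw == c].mean(axis=0)
        peak[c] = (int(np.argmax(profile)), c)
    new_of_old = {c: i for i, (c) in enumerate(sorted(range(k), key=lambda c: peak[c]))}
    labels = np.array([new_of_old[c] for c in raw])

    order: list[int] = []
    for c in range(k):
        members = np.flatnonzero(labels == c)
        centre = X[members].mean(axis=0)
        dist = np.linalg.norm(X[members] - centre, axis=1)
        order.extend(members[np.argsort(dist, kind="stable")])

    return ClusterAssignment(
        row_ids=list(table.index),
        labels=pd.Series(labels, index=table.index, name="cluster"),
        ordering=np.asarray(order, dtype=int),
        k=k,
    )
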