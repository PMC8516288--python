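"""Inference of time-dependent TF motif activities from promoter site counts.

The centered log-expression of gene g at pseudotime tau is modelled as a
linear combination of motif activities weighted by promoter binding-site
counts, ``e_gtau = sum_f N_gf A_ftau``.  The site matrix N is column-centered
(each motif column sums to zero over genes), which makes the fitted
activities zero-mean and invariant to adding a constant to any expression
column.  Activities are obtained per pseudotime column by ridge regression
with one shared penalty; the penalty weight is chosen by an 80/20
cross-validation over genes at the minimum held-out mean squared error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "SiteMatrix",
    "ActivityTable",
    "FitDiagnostics",
    "build_site_matrix",
    "fit_activities",
    "cross_validate",
    "classify_activities",
    "activity_expression_xcorr",
]


@dataclass
class SiteMatrix:
    """Genes-by-motifs binding-site counts around promoters.

    ``counts`` holds the raw nonnegative counts; the column-centered form
    used by the regression is derived on demand.  ``motif_to_tfs`` maps a
    motif to the (possibly several) TF gene names sharing it.
    """

    counts: pd.DataFrame
    motif_to_tfs: Optional[Mapping[str, Sequence[str]]] = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("site counts must be nonnegative")

    @property
    def centered(self) -> pd.DataFrame:
        return self.counts - self.counts.mean(axis=0)

    @property
    def gene_ids(self) -> list:
        return list(self.counts.index)

    @property
    def motif_ids(self) -> list:
        return list(self.counts.columns)


@dataclass
class ActivityTable:
    """Motif-by-pseudotime activities with optional dynamics annotation."""

    activities: pd.DataFrame  # motifs x pseudotime
    cluster: Optional[pd.Series] = None  # mitotic-active | early-g1-active | steady
    peak_time: Optional[pd.Series] = None
    ordering: Optional[np.ndarray] = None

    @property
    def motif_ids(self) -> list:
        return list(self.activities.index)

    @property
    def grid(self) -> np.ndarray:
        return np.asarray(self.activities.columns, dtype=float)

    @property
    def sigma_f(self) -> pd.Series:
        """Per-motif activity amplitude, the root sum of squares over the grid."""
        return np.sqrt((self.activities**2).sum(axis=1))


@dataclass
class FitDiagnostics:
    lambda_grid: np.ndarray
    mse_train: np.ndarray
    mse_test: np.ndarray
    explained_variance: np.ndarray  # held-out EV = 1 - residual fraction
    residual_fraction: np.ndarray
    chosen_lambda: float
    split_seed: int


def build_site_matrix(
    tfbs: pd.DataFrame,
    tss: pd.DataFrame,
    window: int = 500,
    expressed_genes: Optional[Sequence[str]] = None,
    motif_to_tfs: Optional[Mapping[str, Sequence[str]]] = None,
) -> SiteMatrix:
    """Count binding sites within ``+/- window`` bp of each gene's TSS.

    ``tfbs`` is BED-like (columns chrom, start, end, motif; 0-based
    half-open) and a site is assigned by its midpoint ``floor((start+end)/2)``
    falling in the closed interval ``[tss - window, tss + window]``.  ``tss``
    needs columns gene, chrom, tss (and optionally strand).  Sites on
    chromosomes absent from the annotation are skipped with a warning.  When
    ``expressed_genes`` and ``motif_to_tfs`` are both given, motifs whose
    TFs are all absent from the expressed list are dropped.
    """
    genes = list(tss["gene"])
    motifs = sorted(tfbs["motif"].unique())
    counts = pd.DataFrame(0, index=genes, columns=motifs, dtype=int)

    by_chrom = {c: g for c, g in tss.groupby("chrom")}
    unknown = set()
    for rec in tfbs.itertuples(index=False):
        ann = by_chrom.get(rec.chrom)
        if ann is None:
            unknown.add(rec.chrom)
            continue
        mid = (int(rec.start) + int(rec.end)) // 2
        hit = ann.loc[(ann["tss"] - mid).abs() <= window, "gene"]
        for g in hit:
            counts.loc[g, rec.motif] += 1
    if unknown:
        warnings.warn(
            f"skipped sites on chromosomes absent from the TSS annotation: "
            f"{sorted(unknown)}",
            stacklevel=2,
        )

    if expressed_genes is not None and motif_to_tfs is not None:
        expressed = set(expressed_genes)
        keep = [
            m
            for m in counts.columns
            if any(tf in expressed for tf in motif_to_tfs.get(m, ()))
        ]
        counts = counts[keep]

    return SiteMatrix(counts=counts, motif_to_tfs=motif_to_tfs)


def _aligned_design(e: pd.DataFrame, sites: SiteMatrix, center: bool = True) -> np.ndarray:
    design = sites.centered if center else sites.counts
    if list(e.index) != sites.gene_ids:
        if set(e.index) != set(sites.gene_ids):
            raise ValueError("gene sets of expression and site matrix differ")
        design = design.loc[e.index]
    return design.to_numpy(dtype=float)


def fit_activities(
    e: pd.DataFrame,
    sites: SiteMatrix,
    lam: float,
    center: bool = True,
) -> ActivityTable:
    """Ridge solution A = (N'N + lam I)^-1 N' e, shared across all columns.

    ``e`` is the centered log-expression (genes x pseudotime); the centered
    site matrix is aligned to its gene order (pass ``center=False`` to use
    the raw counts as the design).  A single Cholesky factorization of the
    penalized normal matrix is reused for every pseudotime column.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    N = _aligned_design(e, sites, center=center)
    G = N.T @ N + lam * np.eye(N.shape[1])
    try:
        c = cho_factor(G)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "normal matrix singular; use lambda > 0 for a rank-deficient design"
        ) from exc
    A = cho_solve(c, N.T @ e.to_numpy(dtype=float))
    frame = pd.DataFrame(A, index=sites.motif_ids, columns=e.columns)
    return ActivityTable(activities=frame)


def cross_validate(
    e: pd.DataFrame,
    sites: SiteMatrix,
    lambda_grid: Sequence[float],
    test_fraction: float = 0.2,
    seed: int = 0,
) -> FitDiagnostics:
    """Choose the ridge penalty by held-out MSE over a gene split.

    Genes are split (1 - test_fraction)/test_fraction at the given seed;
    activities are fitted on the training genes only and evaluated on the
    held-out genes.  The explained variance is reported as
    ``1 - sum(e - e_fit)^2 / sum(e - row_mean)^2`` on the test genes, and
    the raw residual fraction is also kept.  The chosen lambda minimizes
    the test MSE.
    """
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("lambda grid is empty")
    if e.shape[0] < 10:
        raise ValueError("need at least 10 genes for cross-validation")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(e.shape[0])
    n_test = max(1, int(round(test_fraction * e.shape[0])))
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    e_train, e_test = e.iloc[train_idx], e.iloc[test_idx]

    N_all = _aligned_design(e, sites)
    N_train, N_test = N_all[train_idx], N_all[test_idx]
    Y_train = e_train.to_numpy(dtype=float)
    Y_test = e_test.to_numpy(dtype=float)
    ss_test = float(np.sum((Y_test - Y_test.mean(axis=1, keepdims=True)) ** 2))

    mse_tr, mse_te, resid_frac = [], [], []
    G0 = N_train.T @ N_train
    B = N_train.T @ Y_train
    for lam in lambda_grid:
        A = cho_solve(cho_factor(G0 + lam * np.eye(G0.shape[0])), B)
        r_tr = Y_train - N_train @ A
        r_te = Y_test - N_test @ A
        mse_tr.append(float(np.mean(r_tr**2)))
        mse_te.append(float(np.mean(r_te**2)))
        resid_frac.append(float(np.sum(r_te**2)) / ss_test)

    mse_te = np.asarray(mse_te)
    chosen = float(lambda_grid[int(np.argmin(mse_te))])
    resid_frac = np.asarray(resid_frac)
    return FitDiagnostics(
        lambda_grid=lambda_grid,
        mse_train=np.asarray(mse_tr),
        mse_test=mse_te,
        explained_variance=1.0 - resid_frac,
        residual_fraction=resid_frac,
        chosen_lambda=chosen,
        split_seed=seed,
    )


def classify_activities(
    table: ActivityTable,
    tau_mit: float,
    sd_threshold: float = 0.07,
) -> ActivityTable:
    """Label motif dynamics as mitotic-active, early-G1-active or steady.

    A motif is steady when its amplitude (root sum of squared activities)
    does not exceed ``sd_threshold``; otherwise it is mitotic-active when
    its activity peaks strictly before ``tau_mit`` and early-G1-active
    otherwise.  A display ordering sorts clusters mitotic < early-G1 <
    steady and, within each cluster, by the time of the first maximum.
    """
    A = table.activities
    grid = table.grid
    sigma = table.sigma_f
    peak_idx = A.to_numpy().argmax(axis=1)
    peak_time = pd.Series(grid[peak_idx], index=A.index, name="peak_time")

    labels = np.where(
        sigma <= sd_threshold,
        "steady",
        np.where(peak_time < tau_mit, "mitotic-active", "early-g1-active"),
    )
    cluster = pd.Series(labels, index=A.index, name="cluster")

    rank = {"mitotic-active": 0, "early-g1-active": 1, "steady": 2}
    order = sorted(
        range(A.shape[0]),
        key=lambda i: (rank[cluster.iloc[i]], peak_time.iloc[i], A.index[i]),
    )
    return ActivityTable(
        activities=A,
        cluster=cluster,
        peak_time=peak_time,
        ordering=np.asarray(order, dtype=int),
    )


def activity_expression_xcorr(
    activity: Sequence[float],
    expression: Sequence[float],
    max_lag: int,
) -> tuple[float, Optional[int], str]:
    """Maximum cross-correlation between a TF's activity and its expression.

    Pearson correlation is evaluated at integer lags 0..max_lag with the
    activity lagging the expression; returns the signed correlation at the
    lag maximizing its absolute value, the lag, and the regulatory mode
    (activator for positive, repressor for negative correlation).  Constant
    series give an undefined correlation.
    """
    a = np.asarray(activity, dtype=float)
    x = np.asarray(expression, dtype=float)
    if a.shape != x.shape:
        raise ValueError("series must share the same grid")
    if max_lag >= a.size:
        raise ValueError("max_lag must be smaller than the series length")
    if np.ptp(a) == 0 or np.ptp(x) == 0:
        return float("nan"), None, "undefined"

    best = (0.0, 0)
    for lag in range(max_lag + 1):
        a_seg = a[lag:]
        x_seg = x[: a.size - lag]
        if np.ptp(a_seg) == 0 or np.ptp(x_seg) == 0:
            continue
        r = float(np.corrcoef(a_seg, x_seg)[0, 1])
        if abs(r) > abs(best[0]):
            best = (r, lag)
    corr, lag = best
    mode = "activator" if corr > 0 else "repressor"
    return corr, lag, mode
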