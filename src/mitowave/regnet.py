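"""TF importance ranking, core regulatory network, and bookmarking scores.

A motif's importance is measured by how much the explained variance of the
activity model drops when the motif is removed and the remaining activities
are refitted: the score is the ratio of the reduced to the full explained
variance, so smaller scores mark more influential regulators.  The core
regulatory network connects the top-ranked motifs with a directed edge
f -> f' whenever the promoter of f's target TF gene f' carries at least one
binding site for motif f.  Promoter-level scores summarize the mitotic
behaviour of a gene's regulators: the mitotic binding score (MBS) is the
site-count-weighted mean of the regulators' mitotic bound fractions, and
the mitotic activity score (MAS) is the site-count-weighted sum of their
mean activities during mitosis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .activity import ActivityTable, SiteMatrix, _aligned_design

__all__ = [
    "ImportanceRanking",
    "CoreNetwork",
    "importance_scores",
    "select_core",
    "build_crn",
    "random_network_baseline",
    "mitotic_binding_score",
    "mitotic_activity_score",
    "peak_to_gene",
    "group_expression_contrast",
]


@dataclass
class ImportanceRanking:
    """Per-motif leave-one-out explained-variance ratios, ascending =
    most important first."""

    table: pd.DataFrame  # columns: ev_reduced, score; index: motif, sorted
    ev_full: float

    @property
    def motif_ids(self) -> list:
        return list(self.table.index)


@dataclass
class CoreNetwork:
    graph: nx.DiGraph
    edge_count: int
    random_baseline: Optional[tuple[float, float]] = None  # (mean, sd)

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)


def _explained_variance(Y: np.ndarray, Y_fit: np.ndarray) -> float:
    ss_res = float(np.sum((Y - Y_fit) ** 2))
    ss_tot = float(np.sum((Y - Y.mean(axis=1, keepdims=True)) ** 2))
    return 1.0 - ss_res / ss_tot


def _ridge_fit(N: np.ndarray, Y: np.ndarray, lam: float) -> np.ndarray:
    G = N.T @ N + lam * np.eye(N.shape[1])
    return cho_solve(cho_factor(G), N.T @ Y)


def importance_scores(
    e: pd.DataFrame,
    sites: SiteMatrix,
    lam: float,
) -> ImportanceRanking:
    """Leave-one-motif-out importance ranking.

    For every motif the activities are refitted (same penalty) with that
    motif's column removed, and the reduced explained variance EV_f is
    compared with the full-model EV.  The score EV_f / EV is sorted
    ascending: the stronger the drop, the more the motif matters.
    """
    N = _aligned_design(e, sites)
    Y = e.to_numpy(dtype=float)
    if N.shape[1] < 2:
        raise ValueError("need at least two motifs to rank by removal")
    ev_full = _explained_variance(Y, N @ _ridge_fit(N, Y, lam))

    rows = []
    for j, motif in enumerate(sites.motif_ids):
        N_red = np.delete(N, j, axis=1)
        ev_red = _explained_variance(Y, N_red @ _ridge_fit(N_red, Y, lam))
        rows.append({"motif": motif, "ev_reduced": ev_red, "score": ev_red / ev_full})
    table = (
        pd.DataFrame(rows)
        .set_index("motif")
        .sort_values(["score", "motif"], kind="stable")
    )
    return ImportanceRanking(table=table, ev_full=ev_full)


def select_core(ranking: ImportanceRanking, fraction: float = 0.05) -> list:
    """Top motifs by importance: the first floor(fraction * n) of the ranking.

    Ties at the cutoff are already broken lexically by motif id in the
    ranking itself, making the selection deterministic.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    n_sel = math.floor(fraction * ranking.table.shape[0])
    return list(ranking.table.index[:n_sel])


def _count_edges(
    nodes: Sequence[str],
    counts: pd.DataFrame,
    motif_to_gene: Mapping[str, str],
) -> list[tuple[str, str]]:
    edges = []
    for target in nodes:
        gene = motif_to_gene.get(target)
        if gene is None or gene not in counts.index:
            continue
        row = counts.loc[gene]
        for source in nodes:
            if source in row.index and row[source] > 0:
                edges.append((source, target))
    return edges


def build_crn(
    nodes: Sequence[str],
    sites: SiteMatrix,
    motif_to_gene: Mapping[str, str],
    clusters: Optional[pd.Series] = None,
) -> CoreNetwork:
    """Directed network among the selected motifs.

    Edge f -> f' exists when the promoter of the gene encoding f' carries at
    least one raw binding site for motif f; self-loops are allowed.  Motifs
    without a mappable TF gene keep their node but receive no incoming
    edges (with a warning).
    """
    g = nx.DiGraph()
    for m in nodes:
        attrs = {}
        if clusters is not None and m in clusters.index:
            attrs["cluster"] = clusters[m]
        g.add_node(m, **attrs)
        if motif_to_gene.get(m) is None or motif_to_gene[m] not in sites.counts.index:
            warnings.warn(f"motif {m!r} has no mappable TF gene", stacklevel=2)
    for u, v in _count_edges(list(nodes), sites.counts, motif_to_gene):
        g.add_edge(u, v)
    return CoreNetwork(graph=g, edge_count=g.number_of_edges())


def random_network_baseline(
    sites: SiteMatrix,
    motif_to_gene: Mapping[str, str],
    n_nodes: int,
    n_draws: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean and SD of the edge count over random same-size motif sets."""
    motifs = sites.motif_ids
    if n_nodes > len(motifs):
        raise ValueError("n_nodes exceeds the number of motifs")
    rng = np.random.default_rng(seed)
    counts = []
    for _ in range(n_draws):
        chosen = [motifs[i] for i in rng.choice(len(motifs), n_nodes, replace=False)]
        counts.append(len(_count_edges(chosen, sites.counts, motif_to_gene)))
    counts = np.asarray(counts, dtype=float)
    return float(counts.mean()), float(counts.std(ddof=0))


def mitotic_binding_score(
    sites: SiteMatrix,
    mbf: pd.Series,
    decile: float = 0.10,
) -> pd.DataFrame:
    """Mitotic binding score per gene: the MBF of its regulators, weighted by
    site counts.

    ``MBS_g = sum_f MBF_f N_gf / sum_f N_gf`` with both sums over the motifs
    that have an annotated mitotic bound fraction.  Genes without any such
    site (zero denominator) are removed.  Returns a frame with the score,
    the total raw site count over all motifs, and top/bottom-decile group
    labels ('high' / 'low' / 'mid').
    """
    if mbf.empty:
        raise ValueError("MBF table is empty")
    known = [m for m in sites.motif_ids if m in mbf.index]
    if not known:
        raise ValueError("no motif in the site matrix has an MBF annotation")
    counts = sites.counts
    sub = counts[known].to_numpy(dtype=float)
    weights = mbf.loc[known].to_numpy(dtype=float)
    den = sub.sum(axis=1)
    num = sub @ weights
    keep = den > 0
    mbs = pd.Series(num[keep] / den[keep], index=counts.index[keep], name="mbs")
    out = pd.DataFrame(
        {
            "mbs": mbs,
            "total_sites": counts.loc[mbs.index].sum(axis=1),
        }
    )
    out["group"] = _decile_groups(out["mbs"], decile)
    return out


def mitotic_activity_score(
    sites: SiteMatrix,
    activities: ActivityTable,
    tau_mit: float,
    decile: float = 0.10,
) -> pd.DataFrame:
    """Mitotic activity score per gene.

    ``MAS_g = sum_f N_gf * Abar_f`` where ``Abar_f`` is the motif's mean
    activity over pseudotime bins before ``tau_mit``.  The site-count
    weighted *sum* couples promoter strength (many sites) with regulator
    mitotic activity; genes are grouped into top/bottom deciles.
    """
    grid = activities.grid
    mit = grid < tau_mit
    abar = activities.activities.loc[:, activities.activities.columns[mit]].mean(axis=1)
    common = [m for m in sites.motif_ids if m in abar.index]
    mas = sites.counts[common].to_numpy(dtype=float) @ abar.loc[common].to_numpy()
    out = pd.DataFrame(
        {
            "mas": pd.Series(mas, index=sites.counts.index),
            "total_sites": sites.counts.sum(axis=1),
        }
    )
    out["group"] = _decile_groups(out["mas"], decile)
    return out


def _decile_groups(score: pd.Series, decile: float) -> pd.Series:
    lo = score.quantile(decile)
    hi = score.quantile(1 - decile)
    return pd.Series(
        np.where(score >= hi, "high", np.where(score <= lo, "low", "mid")),
        index=score.index,
        name="group",
    )


def peak_to_gene(
    peaks: pd.DataFrame,
    tss: pd.DataFrame,
    expressed: Optional[Sequence[str]] = None,
) -> list:
    """Nearest expressed gene for each peak.

    ``peaks`` is BED-like (chrom, start, end; 0-based half-open); the
    reference point is the peak midpoint ``floor((start + end) / 2)`` and
    the assigned gene minimizes ``|tss - midpoint|`` among expressed genes
    on the same chromosome.  Equidistant ties go to the TSS at the smaller
    genomic coordinate.  Peaks on chromosomes without an expressed TSS are
    skipped with a warning; duplicate assignments are collapsed keeping the
    first occurrence.
    """
    ann = tss
    if expressed is not None:
        ann = tss.loc[tss["gene"].isin(set(expressed))]
    by_chrom = {c: g.sort_values(["tss", "gene"]) for c, g in ann.groupby("chrom")}

    out: list = []
    skipped = set()
    for rec in peaks.itertuples(index=False):
        genes = by_chrom.get(rec.chrom)
        if genes is None or genes.empty:
            skipped.add(rec.chrom)
            continue
        mid = (int(rec.start) + int(rec.end)) // 2
        dist = (genes["tss"] - mid).abs()
        best = dist.min()
        # candidates at the minimal distance; tie -> smaller TSS coordinate
        winner = genes.loc[dist == best].iloc[0]["gene"]
        if winner not in out:
            out.append(winner)
    if skipped:
        warnings.warn(
            f"peaks skipped on chromosomes without expressed TSS: {sorted(skipped)}",
            stacklevel=2,
        )
    return out


def group_expression_contrast(
    table: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    normalize: bool = False,
) -> dict[str, pd.DataFrame]:
    """Mean +/- SEM expression profile per gene group.

    ``table`` is genes x pseudotime (linear or normalized scale).  With
    ``normalize=True`` the adaptive-pseudocount log2 normalization and
    double centering are applied first.  Returns, per group, a frame with
    'mean' and 'sem' rows over the pseudotime columns.
    """
    if normalize:
        from .preprocess import lognorm_transform

        table = lognorm_transform(table)
    out = {}
    for name, members in groups.items():
        members = [g for g in members if g in table.index]
        if not members:
            raise ValueError(f"group {name!r} is empty")
        sub = table.loc[members]
        mean = sub.mean(axis=0)
        sem = sub.std(axis=0, ddof=1) / np.sqrt(len(members)) if len(members) > 1 else mean * 0.0
        out[name] = pd.DataFrame({"mean": mean, "sem": sem}).T
    return out
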