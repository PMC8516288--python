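"""Synthetic-data generator with known ground truth for the whole pipeline.

Emulates a nocodazole-release nascent-RNA time course: binomially sampled
mitotic-fraction counts under the lag model, smooth wave-shaped motif
activities over pseudotime, a sparse nonnegative promoter site matrix,
log-scale expression generated by the linear activity model plus Gaussian
noise, and observed bulk samples produced by the exact forward mixture used
by the deconvolution design (so recovery tests are self-consistent).

All randomness flows from the single ``seed`` in :class:`SimulationConfig`;
each operation derives an independent stream from it, so the same config
always yields the same truth regardless of call order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .activity import ActivityTable, SiteMatrix
from .deconvolution import (
    INTERPHASE,
    DeconvolutionDesign,
    MixtureFractions,
    PseudotimeGrid,
    build_design,
)
from .lag import LagParams, MitoticCountData, mitotic_fraction

__all__ = ["SimulationConfig", "SyntheticTruth", "simulate_mitotic_counts",
           "simulate_site_matrix", "simulate_activities",
           "simulate_expression_and_observe"]

# per-operation stream tags so every generator draws from an independent,
# seed-reproducible stream
_TAG_COUNTS, _TAG_SITES, _TAG_ACT, _TAG_EXPR = 11, 13, 17, 19

LIBRARY_SIZE = 1e6  # per-pseudotime linear-scale column total


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    Defaults mirror the experimental design: expression sampled at 0, 40,
    80, 105 and 165 minutes after block release plus an asynchronous
    sample; mitotic cells counted at those times plus 300 min; a log-normal
    lag with tau_mit = 67 min, mu = 3.4, sigma = 0.7; and contamination
    fractions pi_M = 0.23, pi_I = 0.075.
    """

    n_genes: int = 300
    n_tfs: int = 25
    time_points: tuple = (0.0, 40.0, 80.0, 105.0, 165.0)
    count_time_points: tuple = (0.0, 40.0, 80.0, 105.0, 165.0, 300.0)
    n_cells_per_timepoint: int = 200
    grid_step: float = 1.0
    grid_max: float = 165.0
    true_lag: LagParams = field(default_factory=lambda: LagParams(67.0, 3.4, 0.7))
    mixture: MixtureFractions = field(default_factory=MixtureFractions)
    noise_sd: float = 0.1
    site_density: float = 0.1
    activity_amplitude: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_tfs", "n_cells_per_timepoint"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        tp = np.asarray(self.time_points, dtype=float)
        if tp[0] != 0 or np.any(np.diff(tp) <= 0):
            raise ValueError("time_points must be strictly increasing from 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not (0 <= self.site_density <= 1):
            raise ValueError("site_density must lie in [0, 1]")

    @property
    def grid(self) -> PseudotimeGrid:
        return PseudotimeGrid(step=self.grid_step, max=self.grid_max)

    @property
    def gene_ids(self) -> list:
        width = len(str(self.n_genes))
        return [f"g{i:0{width}d}" for i in range(self.n_genes)]

    @property
    def motif_ids(self) -> list:
        width = len(str(self.n_tfs))
        return [f"M{i:0{width}d}" for i in range(self.n_tfs)]

    def to_json(self, path) -> None:
        data = asdict(self)
        Path(path).write_text(json.dumps(data, indent=2, default=list))


@dataclass
class SyntheticTruth:
    """Ground truth plus the observations derived from it."""

    config: SimulationConfig
    true_activities: ActivityTable
    true_site_matrix: SiteMatrix
    true_expression: pd.DataFrame  # genes x grid, nonnegative linear scale
    true_log_expression: pd.DataFrame  # genes x grid, centered-model scale
    interphase_expression: pd.Series
    observed_expression: pd.DataFrame  # genes x (time points + async)
    mitotic_counts: MitoticCountData
    design: DeconvolutionDesign

    def write_tsvs(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.mitotic_counts.to_tsv(d / "mitotic_counts.tsv")
        self.observed_expression.to_csv(d / "observed_expression.tsv", sep="\t")
        self.true_expression.to_csv(d / "true_expression.tsv", sep="\t")
        self.true_site_matrix.counts.to_csv(d / "site_matrix.tsv", sep="\t")
        self.true_activities.activities.to_csv(d / "true_activities.tsv", sep="\t")
        self.config.to_json(d / "config.json")


def _rng(config: SimulationConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([tag, config.seed]))


def simulate_mitotic_counts(config: SimulationConfig) -> MitoticCountData:
    """Binomial mitotic/total counts at each count time point under the lag
    model: n_mit ~ Binomial(n_tot, q(t))."""
    rng = _rng(config, _TAG_COUNTS)
    t = np.asarray(config.count_time_points, dtype=float)
    q = mitotic_fraction(t, config.true_lag)
    n_tot = np.full(t.size, config.n_cells_per_timepoint, dtype=int)
    n_mit = rng.binomial(n_tot, q)
    return MitoticCountData(t, n_mit, n_tot)


def simulate_site_matrix(
    config: SimulationConfig, ensure_targets: bool = True
) -> SiteMatrix:
    """Sparse nonnegative promoter site counts.

    Each (gene, motif) entry is nonzero with probability ``site_density``;
    nonzero counts are 1 plus a small Poisson excess.  With
    ``ensure_targets`` every motif is guaranteed at least one target gene;
    without it an all-zero matrix is flagged as degenerate.  Motif ``M<i>``
    is mapped to TF gene ``g<i>`` (the first ``n_tfs`` genes encode the TFs
    themselves), which downstream network code uses.
    """
    rng = _rng(config, _TAG_SITES)
    shape = (config.n_genes, config.n_tfs)
    mask = rng.random(shape) < config.site_density
    counts = mask * (1 + rng.poisson(0.7, size=shape))
    if ensure_targets:
        for j in np.flatnonzero(counts.sum(axis=0) == 0):
            counts[rng.integers(config.n_genes), j] = 1
    elif counts.sum() == 0:
        warnings.warn("degenerate site matrix: all entries are zero", stacklevel=2)
    genes, motifs = config.gene_ids, config.motif_ids
    motif_to_tfs = {m: [genes[i]] for i, m in enumerate(motifs) if i < config.n_genes}
    return SiteMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=motifs),
        motif_to_tfs=motif_to_tfs,
    )


def simulate_activities(
    config: SimulationConfig,
    amplitudes: Optional[Sequence[float]] = None,
    peak_fraction_max: float = 0.8,
) -> ActivityTable:
    """Smooth wave-shaped motif activities over the pseudotime grid.

    Each motif gets one Gaussian bump with peak time uniform on
    ``[0, peak_fraction_max * grid_max]`` (covering waves both before and
    after ``tau_mit``), width uniform on 30-80 min (matching the breadth of
    observed reactivation waves over the sampled window), and amplitude
    ``activity_amplitude`` scaled by a uniform factor.  Rows are
    mean-centered over the grid, matching the zero-mean convention of the
    inference model.
    """
    rng = _rng(config, _TAG_ACT)
    grid = config.grid.points
    peaks = rng.uniform(0.0, peak_fraction_max * config.grid_max, config.n_tfs)
    widths = rng.uniform(30.0, 80.0, config.n_tfs)
    if amplitudes is None:
        amps = config.activity_amplitude * rng.uniform(0.5, 1.5, config.n_tfs)
    else:
        amps = np.asarray(amplitudes, dtype=float)
        if amps.size != config.n_tfs:
            raise ValueError("amplitudes must have one entry per TF")
    A = amps[:, None] * np.exp(
        -((grid[None, :] - peaks[:, None]) ** 2) / (2 * widths[:, None] ** 2)
    )
    A = A - A.mean(axis=1, keepdims=True)
    frame = pd.DataFrame(A, index=config.motif_ids, columns=grid)
    peak_time = pd.Series(peaks, index=config.motif_ids, name="peak_time")
    return ActivityTable(activities=frame, peak_time=peak_time)


def simulate_expression_and_observe(
    config: SimulationConfig,
    sites: Optional[SiteMatrix] = None,
    activities: Optional[ActivityTable] = None,
) -> SyntheticTruth:
    """Generate expression from the linear model and observe it through the
    population mixture.

    Log-scale pseudotime expression is ``e = N_centered A + noise``; it is
    mapped to the nonnegative linear scale by ``2**e`` with each pseudotime
    column rescaled to a fixed library size of 10^6 (so the downstream log2
    normalization round-trips).  The interphase level is the per-gene mean
    over the last 20% of the grid.  Observations are computed exactly as
    ``r_g = M E_g`` with the same design matrix the deconvolution uses:
    experimental samples mix the lag-distributed cycling population with
    arrested (tau = 0) and interphase contamination, and the asynchronous
    sample averages the mitotic bins and the interphase level.
    """
    if sites is None:
        sites = simulate_site_matrix(config)
    if activities is None:
        activities = simulate_activities(config)
    A = activities.activities.to_numpy(dtype=float)
    N = sites.centered.to_numpy(dtype=float)
    if N.shape[1] != A.shape[0]:
        raise ValueError(
            f"site matrix has {N.shape[1]} motifs but activities have {A.shape[0]}"
        )

    rng = _rng(config, _TAG_EXPR)
    e = N @ A
    if config.noise_sd > 0:
        e = e + rng.normal(0.0, config.noise_sd, size=e.shape)

    E = np.power(2.0, e)
    E *= LIBRARY_SIZE / E.sum(axis=0, keepdims=True)

    grid = config.grid.points
    tail = grid >= 0.8 * config.grid_max
    e_interphase = E[:, tail].mean(axis=1)

    design = build_design(config.true_lag, config.mixture, config.grid,
                          config.time_points)
    states = np.hstack([E, e_interphase[:, None]])
    r = states @ design.M.T

    genes = sites.gene_ids
    observed = pd.DataFrame(r, index=genes, columns=design.obs_labels)
    return SyntheticTruth(
        config=config,
        true_activities=activities,
        true_site_matrix=sites,
        true_expression=pd.DataFrame(E, index=genes, columns=grid),
        true_log_expression=pd.DataFrame(e, index=genes, columns=grid),
        interphase_expression=pd.Series(e_interphase, index=genes, name=INTERPHASE),
        observed_expression=observed,
        mitotic_counts=simulate_mitotic_counts(config),
        design=design,
    )
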