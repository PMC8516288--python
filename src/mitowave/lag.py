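"""Stochastic lag-time model for mitotic-arrest release.

After a nocodazole block is washed out, each cell waits a random lag time
``eta`` before it restarts cell-cycle progression.  The lag is modelled as
log-normal with location ``mu`` and scale ``sigma`` (both on the log-minute
scale).  A cell observed at experimental time ``t`` has internal cell-cycle
pseudotime ``tau = t - eta`` (clamped at 0 while the lag has not elapsed),
and needs an average time ``tau_mit`` to complete mitosis once progression
restarts.  The expected fraction of cells still in mitosis at time ``t`` is
therefore the complementary log-normal CDF evaluated at ``t - tau_mit``,
which is fitted to mitotic/total cell counts by binomial maximum likelihood.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import erf

__all__ = [
    "LagParams",
    "MitoticCountData",
    "LagFitResult",
    "lag_density",
    "mitotic_fraction",
    "binomial_log_likelihood",
    "fit_lag_model",
    "pseudotime_distribution",
]

_Q_CLAMP = 1e-12  # keeps log q and log(1-q) finite at the q in {0, 1} branches


@dataclass(frozen=True)
class LagParams:
    """Parameters of the desynchronization model.

    tau_mit : average time (minutes) a cell needs to complete mitosis once
        its lag has elapsed.
    mu, sigma : location and scale of the log-normal lag-time distribution
        (log-minutes).  The median lag is ``exp(mu)``.
    """

    tau_mit: float
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not (self.tau_mit > 0):
            raise ValueError(f"tau_mit must be positive, got {self.tau_mit}")
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    @property
    def median_lag(self) -> float:
        """Median of the log-normal lag distribution, in minutes."""
        return math.exp(self.mu)


@dataclass
class MitoticCountData:
    """Mitotic vs total cell counts at each experimental time point."""

    time_points: np.ndarray
    n_mit: np.ndarray
    n_tot: np.ndarray

    def __post_init__(self) -> None:
        self.time_points = np.asarray(self.time_points, dtype=float)
        self.n_mit = np.asarray(self.n_mit, dtype=int)
        self.n_tot = np.asarray(self.n_tot, dtype=int)
        if not (self.time_points.shape == self.n_mit.shape == self.n_tot.shape):
            raise ValueError("time_points, n_mit and n_tot must have equal length")
        if np.any(self.time_points < 0):
            raise ValueError("time points must be nonnegative")
        if np.any(self.n_mit < 0) or np.any(self.n_mit > self.n_tot):
            raise ValueError("counts must satisfy 0 <= n_mit <= n_tot")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.time_points, "n_mit": self.n_mit, "n_tot": self.n_tot}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MitoticCountData":
        df = pd.read_csv(path, sep="\t")
        return cls(df["t"].values, df["n_mit"].values, df["n_tot"].values)


@dataclass
class LagFitResult:
    params: LagParams
    log_likelihood: float
    converged: bool
    identifiable: bool = True
    uncertainties: Optional[dict] = field(default=None)


def lag_density(tau, t: float, params: LagParams):
    """Probability density over pseudotime ``tau`` for cells observed at ``t``.

    The density of ``tau`` equals the log-normal density of the lag
    ``eta = t - tau``; it is zero for ``tau >= t`` (the lag cannot be
    negative or zero-length in the continuous model).
    """
    if t < 0:
        raise ValueError("experimental time t must be nonnegative")
    tau = np.asarray(tau, dtype=float)
    eta = t - tau
    out = np.zeros_like(eta)
    pos = eta > 0
    e = eta[pos]
    out[pos] = np.exp(-((np.log(e) - params.mu) ** 2) / (2 * params.sigma**2)) / (
        np.sqrt(2 * np.pi) * params.sigma * e
    )
    return out if out.ndim else float(out)


def _lag_sf(eta, params: LagParams):
    """P(lag >= eta): complementary CDF of the log-normal lag."""
    eta = np.asarray(eta, dtype=float)
    out = np.ones_like(eta)
    pos = eta > 0
    z = (np.log(eta[pos]) - params.mu) / (math.sqrt(2.0) * params.sigma)
    out[pos] = 0.5 - 0.5 * erf(z)
    return out if out.ndim else float(out)


def mitotic_fraction(t, params: LagParams):
    """Expected fraction q(t) of cells still in mitosis at experimental time t.

    Equals 1 while ``t <= tau_mit`` and the complementary log-normal CDF of
    the lag evaluated at ``t - tau_mit`` afterwards.
    """
    t = np.asarray(t, dtype=float)
    q = _lag_sf(t - params.tau_mit, params)
    return q


def binomial_log_likelihood(params: LagParams, counts: MitoticCountData) -> float:
    """Binomial log-likelihood of the mitotic counts under q(t)."""
    q = np.clip(mitotic_fraction(counts.time_points, params), _Q_CLAMP, 1 - _Q_CLAMP)
    return float(
        np.sum(counts.n_mit * np.log(q))
        + np.sum((counts.n_tot - counts.n_mit) * np.log(1 - q))
    )


def _pack(params: LagParams) -> np.ndarray:
    # log transform on tau_mit and sigma enforces positivity during the search
    return np.array([math.log(params.tau_mit), params.mu, math.log(params.sigma)])


def _unpack(x: np.ndarray) -> LagParams:
    return LagParams(tau_mit=math.exp(x[0]), mu=x[1], sigma=math.exp(x[2]))


def fit_lag_model(
    counts: MitoticCountData,
    init: Optional[LagParams] = None,
    n_bootstrap: int = 0,
    seed: Optional[int] = None,
    max_iter: int = 10_000,
) -> LagFitResult:
    """Maximum-likelihood fit of the lag model to mitotic-fraction counts.

    Uses a derivative-free Nelder-Mead simplex search on transformed
    parameters (log tau_mit, mu, log sigma).  Standard errors, when
    requested, come from a parametric bootstrap: counts are resampled
    binomially at the fitted q(t) and refit ``n_bootstrap`` times.
    """
    if np.count_nonzero(counts.n_tot > 0) < 3:
        raise ValueError("need at least 3 time points with n_tot > 0")
    if init is None:
        init = LagParams(tau_mit=50.0, mu=3.0, sigma=1.0)

    def neg_ll(x):
        return -binomial_log_likelihood(_unpack(x), counts)

    res = minimize(
        neg_ll,
        _pack(init),
        method="Nelder-Mead",
        options={"maxiter": max_iter, "xatol": 1e-8, "fatol": 1e-10},
    )
    params = _unpack(res.x)
    ll = -float(res.fun)

    identifiable = True
    if np.all(counts.n_mit == counts.n_tot):
        # likelihood is flat for any tau_mit beyond the last observation
        identifiable = False
        t_max = float(counts.time_points.max())
        if params.tau_mit < t_max:
            params = LagParams(tau_mit=t_max, mu=params.mu, sigma=params.sigma)
            ll = binomial_log_likelihood(params, counts)
        warnings.warn(
            "all cells mitotic at every time point: tau_mit is only bounded "
            "below by the last time point",
            stacklevel=2,
        )

    uncertainties = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        q_hat = np.clip(
            mitotic_fraction(counts.time_points, params), 0.0, 1.0
        )
        draws = []
        for _ in range(n_bootstrap):
            n_mit_b = rng.binomial(counts.n_tot, q_hat)
            boot = MitoticCountData(counts.time_points, n_mit_b, counts.n_tot)
            r = fit_lag_model(boot, init=params, n_bootstrap=0)
            draws.append([r.params.tau_mit, r.params.mu, r.params.sigma])
        sd = np.std(np.array(draws), axis=0, ddof=1)
        uncertainties = {"tau_mit": sd[0], "mu": sd[1], "sigma": sd[2]}

    return LagFitResult(
        params=params,
        log_likelihood=ll,
        converged=bool(res.success),
        identifiable=identifiable,
        uncertainties=uncertainties,
    )


def pseudotime_distribution(
    t: float, grid: Sequence[float], params: LagParams
) -> np.ndarray:
    """Discrete distribution of pseudotime over ``grid`` for cells at time t.

    ``grid`` is a uniform array of bin centres starting at 0.  Bin ``tau_j``
    collects the probability that the lag falls in the interval
    ``(t - tau_j - dt/2, t - tau_j + dt/2]``, computed from CDF differences
    of the log-normal lag so that narrow distributions are handled exactly.
    All mass for lags that have not yet elapsed (``eta >= t``, i.e. the cell
    is still held at pseudotime 0) is lumped into the first bin.  The row
    sums to 1.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    grid = np.asarray(grid, dtype=float)
    if grid.size < 1 or grid[0] != 0:
        raise ValueError("grid must start at 0")
    row = np.zeros(grid.size)
    if t <= 0:
        row[0] = 1.0
        return row
    dt = grid[1] - grid[0] if grid.size > 1 else 1.0
    if dt <= 0:
        raise ValueError("grid step must be positive")
    # bin tau_j <-> lag eta in (t - tau_j - dt/2, t - tau_j + dt/2];
    # mass from survival-function differences (sf(eta<=0) = 1)
    sf_lo = _lag_sf(t - (grid + dt / 2.0), params)
    sf_hi = _lag_sf(t - (grid - dt / 2.0), params)
    mass = sf_lo - sf_hi
    # the first bin absorbs every lag that has not elapsed (eta >= t - dt/2)
    mass[0] = _lag_sf(t - dt / 2.0, params)
    row = np.clip(mass, 0.0, None)
    s = row.sum()
    if s <= 0:
        row[0] = 1.0
        return row
    return row / s
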