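"""Pseudotime deconvolution of bulk expression from desynchronized populations.

Each observed sample is modelled as a convex mixture of three cell
populations: cycling cells spread over cell-cycle pseudotime according to
the lag model (fraction ``pi_C``), cells that never exited mitotic arrest
and sit at pseudotime 0 (``pi_M``), and cells that escaped the block and
stayed in interphase (``pi_I``).  An extra asynchronous sample averages
mitotic expression (weight ``f_mit = tau_mit / T_C``) and the interphase
level (``f_I = 1 - f_mit``).  Stacking these mixtures gives a row-stochastic
design matrix ``M`` so that observations satisfy ``r_g = M E_g`` where the
state vector ``E_g`` holds per-pseudotime-bin expression plus one interphase
slot.  The inverse problem is solved in closed form per gene with a
first-difference smoothness penalty, and the penalty weight is selected by
AIC/BIC with effective degrees of freedom given by the hat-matrix trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .lag import LagParams, pseudotime_distribution

__all__ = [
    "MixtureFractions",
    "PseudotimeGrid",
    "DeconvolutionDesign",
    "DeconvolvedExpression",
    "build_design",
    "smoothing_penalty",
    "deconvolve",
    "effective_dof",
    "select_lambda",
]

INTERPHASE = "interphase"


@dataclass(frozen=True)
class MixtureFractions:
    """Population composition of the synchronized samples.

    pi_C : fraction of cells that re-enter the cell cycle.
    pi_M : fraction that never exited mitotic arrest (held at pseudotime 0).
    pi_I : fraction that escaped the block and stayed in interphase.
    T_C  : full cell-cycle duration in minutes (default 24 h).
    """

    pi_C: float = 0.695
    pi_M: float = 0.23
    pi_I: float = 0.075
    T_C: float = 1440.0

    def __post_init__(self) -> None:
        if min(self.pi_C, self.pi_M, self.pi_I) < 0:
            raise ValueError("mixture fractions must be nonnegative")
        if abs(self.pi_C + self.pi_M + self.pi_I - 1.0) > 1e-9:
            raise ValueError("pi_C + pi_M + pi_I must equal 1")
        if self.T_C <= 0:
            raise ValueError("T_C must be positive")

    def f_mit(self, tau_mit: float) -> float:
        """Fraction of the cycle an asynchronous cell spends in mitosis."""
        return tau_mit / self.T_C

    def f_interphase(self, tau_mit: float) -> float:
        return 1.0 - self.f_mit(tau_mit)


@dataclass(frozen=True)
class PseudotimeGrid:
    """Uniform pseudotime grid from 0 to ``max`` with step ``step`` (minutes)."""

    step: float = 1.0
    max: float = 165.0

    def __post_init__(self) -> None:
        if self.step <= 0 or self.max <= 0:
            raise ValueError("grid step and max must be positive")
        n = self.max / self.step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("grid step must divide grid max")

    @property
    def points(self) -> np.ndarray:
        return np.arange(0.0, self.max + self.step / 2.0, self.step)

    @property
    def n_bins(self) -> int:
        return int(round(self.max / self.step)) + 1


@dataclass
class DeconvolutionDesign:
    """Observation-by-state mixture matrices mapping pseudotime expression
    (plus an interphase slot) to the measured samples."""

    grid: PseudotimeGrid
    sample_times: np.ndarray
    lag: LagParams
    mixture: MixtureFractions
    M_C: np.ndarray
    M_M: np.ndarray
    M_I: np.ndarray

    @property
    def M(self) -> np.ndarray:
        return self.M_C + self.M_M + self.M_I

    @property
    def n_obs(self) -> int:
        return self.M_C.shape[0]

    @property
    def n_states(self) -> int:
        return self.M_C.shape[1]

    @property
    def state_labels(self) -> list:
        return [float(t) for t in self.grid.points] + [INTERPHASE]

    @property
    def obs_labels(self) -> list:
        return [float(t) for t in self.sample_times] + ["async"]


@dataclass
class DeconvolvedExpression:
    genes: list
    E: pd.DataFrame  # genes x (grid bins + interphase)
    lambda_used: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def grid_part(self) -> pd.DataFrame:
        return self.E.iloc[:, :-1]

    @property
    def interphase(self) -> pd.Series:
        return self.E.iloc[:, -1]


def build_design(
    lag: LagParams,
    mixture: MixtureFractions,
    grid: PseudotimeGrid,
    sample_times: Sequence[float],
) -> DeconvolutionDesign:
    """Assemble the three-population mixture matrix M = M_C + M_M + M_I.

    Rows are the experimental samples followed by the asynchronous sample;
    columns are the pseudotime bins followed by the interphase slot.  M_C
    carries the lag-model pseudotime distribution scaled by pi_C; M_M puts
    pi_M on the tau=0 bin of every experimental row; M_I puts pi_I on the
    interphase slot and holds the asynchronous row, which averages the
    mitotic bins (total weight f_mit) and the interphase slot (f_I).
    Every row of M sums to 1.
    """
    sample_times = np.asarray(sample_times, dtype=float)
    if grid.max < sample_times.max():
        raise ValueError("grid max must cover the largest sample time")
    if lag.tau_mit >= grid.max:
        raise ValueError("tau_mit must lie inside the pseudotime grid")

    n_obs = sample_times.size + 1
    n_states = grid.n_bins + 1
    M_C = np.zeros((n_obs, n_states))
    M_M = np.zeros((n_obs, n_states))
    M_I = np.zeros((n_obs, n_states))

    pts = grid.points
    for i, t in enumerate(sample_times):
        M_C[i, :-1] = mixture.pi_C * pseudotime_distribution(t, pts, lag)
        M_M[i, 0] = mixture.pi_M
        M_I[i, -1] = mixture.pi_I

    mit_bins = pts < lag.tau_mit
    f_mit = mixture.f_mit(lag.tau_mit)
    M_I[-1, :-1][mit_bins] = f_mit / mit_bins.sum()
    M_I[-1, -1] = mixture.f_interphase(lag.tau_mit)

    return DeconvolutionDesign(
        grid=grid,
        sample_times=sample_times,
        lag=lag,
        mixture=mixture,
        M_C=M_C,
        M_M=M_M,
        M_I=M_I,
    )


def smoothing_penalty(n_states: int) -> np.ndarray:
    """First-difference smoothness penalty K = D1' D1 over the pseudotime bins.

    ``n_states`` counts the grid bins plus the interphase slot; the
    interphase slot is excluded from differencing (no smoothness tie between
    the end of the grid and the interphase level).
    """
    if n_states < 2:
        raise ValueError("need at least two states")
    n_grid = n_states - 1
    K = np.zeros((n_states, n_states))
    if n_grid >= 2:
        d1 = np.diff(np.eye(n_grid), axis=0)
        K[:n_grid, :n_grid] = d1.T @ d1
    return K


def _system_matrix(design: DeconvolutionDesign, lam: float, ridge_eps: float):
    M = design.M
    Q = M.T @ M
    K = smoothing_penalty(design.n_states)
    return Q + lam * K + ridge_eps * lam * np.eye(design.n_states), M


def deconvolve(
    observed: pd.DataFrame,
    design: DeconvolutionDesign,
    lam: float,
    ridge_eps: float = 1e-6,
) -> DeconvolvedExpression:
    """Closed-form smooth-ridge deconvolution E* = (Q + lam*K)^-1 M' r per gene.

    ``observed`` is genes x samples with columns ordered as the design rows
    (experimental times then the asynchronous sample).  A single Cholesky
    factorization is shared across genes.  Negative estimates are allowed
    (the solution is unconstrained) but their count is reported.  A tiny
    pure-ridge term ``ridge_eps * lam`` on the diagonal guards against a
    residual null space; set ``ridge_eps=0`` for the pure smoothness penalty.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    R = np.asarray(observed, dtype=float)
    if R.shape[1] != design.n_obs:
        raise ValueError(
            f"observed has {R.shape[1]} columns but design expects {design.n_obs}"
        )
    A, M = _system_matrix(design, lam, ridge_eps)
    try:
        c = cho_factor(A)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises its own
        raise np.linalg.LinAlgError(
            "system singular; use lambda > 0 for an underdetermined design"
        ) from exc
    E = cho_solve(c, M.T @ R.T).T  # genes x states
    genes = list(observed.index)
    frame = pd.DataFrame(E, index=genes, columns=design.state_labels)
    resid = R - E @ M.T
    diagnostics = {
        "n_negative": int((E < 0).sum()),
        "chi2": float(np.sum(resid**2)),
    }
    return DeconvolvedExpression(
        genes=genes, E=frame, lambda_used=float(lam), diagnostics=diagnostics
    )


def effective_dof(
    design: DeconvolutionDesign, lam: float, ridge_eps: float = 1e-6
) -> float:
    """Effective degrees of freedom D = Tr(M (Q + lam*K)^-1 M')."""
    A, M = _system_matrix(design, lam, ridge_eps)
    c = cho_factor(A)
    return float(np.trace(M @ cho_solve(c, M.T)))


def select_lambda(
    observed: pd.DataFrame,
    design: DeconvolutionDesign,
    lambda_grid: Sequence[float],
    ridge_eps: float = 1e-6,
) -> tuple[pd.DataFrame, float]:
    """Sweep the penalty weight and pick the BIC minimizer.

    For each lambda computes chi2 = sum_g |r_g - M E*_g|^2, the effective
    degrees of freedom D, AIC = N_E*chi2 + 2*N_G*D and
    BIC = N_E*chi2 + 2*N_G*D*log(N_E), where N_E is the number of
    observation rows and N_G the number of genes.  Returns the diagnostics
    table and the argmin-BIC lambda.
    """
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("lambda grid is empty")
    n_e = design.n_obs
    n_g = observed.shape[0]
    rows = []
    for lam in lambda_grid:
        fit = deconvolve(observed, design, lam, ridge_eps=ridge_eps)
        chi2 = fit.diagnostics["chi2"]
        D = effective_dof(design, lam, ridge_eps=ridge_eps)
        rows.append(
            {
                "lambda": lam,
                "chi2": chi2,
                "dof": D,
                "aic": n_e * chi2 + 2 * n_g * D,
                "bic": n_e * chi2 + 2 * n_g * D * np.log(n_e),
            }
        )
    table = pd.DataFrame(rows)
    best = float(table.loc[table["bic"].idxmin(), "lambda"])
    return table, best
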