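"""Exact transient and steady-state quantal-content (QC) statistics.

For a deterministic AP train the number of docked SVs just before the i-th
stimulus is Binomial(M, p_i) and the QC is Binomial(M, p_i * p_r,i), where
the per-site occupancy probability p_i obeys the recursion

    p_{i+1} = p_i (1 - p_r,i)(1 - p_u,i) + (1 - p_i (1 - p_r,i)) p_d,i .

Everything in this module follows from that recursion: per-stimulus mean QC
``M * p_i * p_r,i``, per-stimulus Fano factor ``1 - p_i * p_r,i``, the
closed-form solution for constant parameters, the steady-state occupancy,
Fano factor and lag-l autocorrelation of the QC sequence, and the evoked
amplitude statistics when quantal size itself fluctuates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .params import QuantalSizeModel, Schedule, SynapseParams

__all__ = [
    "OccupancySeries",
    "SteadyStateStats",
    "occupancy_recursion",
    "occupancy_closed_form",
    "qc_pmf",
    "steady_state_occupancy",
    "steady_state_fano",
    "steady_state_corr",
    "rho_argmin_pr",
    "normalized_depression",
    "fano_lower_bounds",
    "evoked_stats",
    "steady_state_stats",
]

RHO_GLOBAL_MIN = -0.125  # attained at pr = pd = 0.5, pu = 0


@dataclass(frozen=True)
class OccupancySeries:
    """Per-stimulus occupancy probabilities and derived QC moments."""

    p: np.ndarray          # occupancy probability just before each stimulus
    mean_qc: np.ndarray    # M * p_i * p_r,i
    fano: np.ndarray       # 1 - p_i * p_r,i
    M: int

    def __len__(self) -> int:
        return len(self.p)


@dataclass(frozen=True)
class SteadyStateStats:
    """Steady-state occupancy, QC Fano factor and lag-1 correlation."""

    p_bar: float
    ff: float
    rho: float
    rho_ell: Optional[np.ndarray] = None


def occupancy_recursion(params: SynapseParams, n_stimuli: int) -> OccupancySeries:
    """Iterate the occupancy recursion for stimuli 1..n_stimuli.

    Returns the occupancy probability before each AP together with the
    derived mean QC and per-stimulus Fano factor. Works for arbitrary
    time-varying schedules.
    """
    if n_stimuli < 1:
        raise ValueError(f"n_stimuli must be >= 1, got {n_stimuli}")
    pr = params.pr.values(n_stimuli)
    pu = params.pu.values(n_stimuli)
    pd = params.pd.values(n_stimuli)
    p = np.empty(n_stimuli)
    p[0] = params.p1
    for i in range(n_stimuli - 1):
        survived = p[i] * (1.0 - pr[i])
        p[i + 1] = survived * (1.0 - pu[i]) + (1.0 - survived) * pd[i]
    mean_qc = params.M * p * pr
    fano = 1.0 - p * pr
    return OccupancySeries(p=p, mean_qc=mean_qc, fano=fano, M=params.M)


def _denominator(pr: float, pu: float, pd: float) -> float:
    den = pd + pu + pr * (1.0 - pd - pu)
    if den <= 0.0:
        raise ValueError(
            "degenerate parameters: pd + pu + pr*(1-pd-pu) = "
            f"{den} at (pr={pr}, pu={pu}, pd={pd})"
        )
    return den


def occupancy_closed_form(p1: float, pr: float, pu: float, pd: float, i: int) -> float:
    """Closed-form occupancy before stimulus ``i`` for constant parameters.

    Equivalent to iterating the recursion; the occupancy relaxes
    geometrically from ``p1`` to its fixed point with per-step factor
    ``lam = (1 - pr)(1 - pd - pu)``.
    """
    if i < 1:
        raise ValueError(f"stimulus index must be >= 1, got {i}")
    den = _denominator(pr, pu, pd)
    lam = (1.0 - pr) * (1.0 - pd - pu)
    return (pd + lam ** (i - 1) * (-pd + p1 * den)) / den


def qc_pmf(params: SynapseParams, i: int) -> np.ndarray:
    """Exact QC distribution at stimulus ``i``: Binomial(M, p_i * p_r,i).

    Returns the pmf over {0, ..., M}. Uses scipy's log-space binomial pmf,
    stable up to M of order 1e4.
    """
    series = occupancy_recursion(params, i)
    succ = series.p[i - 1] * params.pr(i)
    return sps.binom.pmf(np.arange(params.M + 1), params.M, succ)


def steady_state_occupancy(pr: float, pu: float = 0.0, pd: float = 0.0) -> float:
    """Fixed point of the occupancy recursion, pbar = pd / (pd + pu + pr(1-pd-pu)).

    With full initial occupancy and constant release probability this is also
    the normalized synaptic depression.
    """
    return pd / _denominator(pr, pu, pd)


def steady_state_fano(pr: float, pu: float = 0.0, pd: float = 0.0) -> float:
    """Steady-state QC Fano factor, FF = 1 - pbar * pr.

    Expanded form: (pd + pr + pu(1-pr) - 2 pr pd) / (pd + pr + pu(1-pr) - pr pd).
    Symmetric under pr <-> pd when pu = 0; 1 - FF lower-bounds both pr and pd.
    """
    return 1.0 - steady_state_occupancy(pr, pu, pd) * pr


def steady_state_corr(pr: float, pu: float = 0.0, pd: float = 0.0, lag: int = 1) -> float:
    """Steady-state Pearson correlation between QCs ``lag`` stimuli apart.

    Lag 1 has the exact closed form

        rho = -pd (1-pr) pr (1-pd-pu) / (pr + pd + pu(1-pr) - 2 pd pr) <= 0.

    For lag > 1 the per-site occupancy chain relaxes geometrically with
    factor ``lam = (1-pr)(1-pu-pd)``, giving ``rho_lag = rho_1 * lam**(lag-1)``
    (a derived form, cross-checked against Monte-Carlo simulation in the
    test suite).
    """
    if lag < 1:
        raise ValueError(f"lag must be >= 1, got {lag}")
    _denominator(pr, pu, pd)
    den = pr + pd + pu * (1.0 - pr) - 2.0 * pd * pr
    if den == 0.0:
        raise ValueError(
            f"degenerate correlation denominator at (pr={pr}, pu={pu}, pd={pd})"
        )
    rho1 = -pd * (1.0 - pr) * pr * (1.0 - pd - pu) / den
    if lag == 1:
        return rho1
    lam = (1.0 - pr) * (1.0 - pu - pd)
    return rho1 * lam ** (lag - 1)


def rho_argmin_pr(pd: float) -> float:
    """Release probability minimizing the lag-1 correlation at fixed ``pd``.

    Setting the derivative of the lag-1 correlation (pu = 0) with respect to
    pr to zero gives ``(2 pd - 1) pr**2 - 2 pd pr + pd = 0``, whose root in
    the unit interval simplifies to

        pr* = sqrt(pd) / (sqrt(pd) + sqrt(1 - pd)).

    The global minimum rho = -0.125 sits at pr = pd = 0.5.
    """
    if not (0.0 < pd < 1.0):
        raise ValueError(f"pd must be in the open interval (0, 1), got {pd}")
    root = np.sqrt(pd)
    return root / (root + np.sqrt(1.0 - pd))


def normalized_depression(params: SynapseParams) -> float:
    """Steady-state mean QC divided by first-stimulus mean QC.

    Equals the steady-state occupancy pbar when p1 = 1 and the release
    probability is constant. Steady state is evaluated on the schedule tail
    values.
    """
    first = params.p1 * params.pr(1)
    if first <= 0.0:
        raise ValueError("first-stimulus mean QC is zero; depression undefined")
    pr, pu, pd = params.tail_probs()
    return steady_state_occupancy(pr, pu, pd) * pr / first


def fano_lower_bounds(ff: float) -> tuple:
    """Lower bounds (pr_min, pd_min) implied by a steady-state Fano factor.

    With pu = 0 every (pr, pd) pair consistent with the observed FF satisfies
    pr >= 1 - FF and pd >= 1 - FF.
    """
    if not (0.0 <= ff <= 1.0):
        raise ValueError(f"Fano factor must lie in [0, 1], got {ff}")
    return 1.0 - ff, 1.0 - ff


def evoked_stats(ss: SteadyStateStats, q: QuantalSizeModel) -> tuple:
    """Steady-state evoked-amplitude Fano factor and lag-1 correlation.

    The evoked amplitude is a compound sum of QC independent quantal sizes,
    so by the law of total variance/covariance

        FF_e  = <c> * (FF + CV_q**2)
        rho_e = rho * FF / (FF + CV_q**2).

    Reduces to (FF, rho) at <c> = 1, CV_q = 0; cross-checked against
    simulated amplitude traces in the test suite.
    """
    denom = ss.ff + q.cv_q ** 2
    ff_e = q.c_mean * denom
    rho_e = ss.rho * ss.ff / denom if denom > 0 else 0.0
    return ff_e, rho_e


def steady_state_stats(
    pr: float, pu: float = 0.0, pd: float = 0.0, lags: Optional[Sequence[int]] = None
) -> SteadyStateStats:
    """Bundle pbar, FF, rho (and optional lag-l correlations) for constant tails."""
    rho_ell = None
    if lags is not None:
        rho_ell = np.array([steady_state_corr(pr, pu, pd, lag=l) for l in lags])
    return SteadyStateStats(
        p_bar=steady_state_occupancy(pr, pu, pd),
        ff=steady_state_fano(pr, pu, pd),
        rho=steady_state_corr(pr, pu, pd, lag=1),
        rho_ell=rho_ell,
    )
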