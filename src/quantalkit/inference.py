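"""Estimators recovering synaptic parameters from quantal-content traces.

The estimators are sklearn-style (``fit`` + trailing-underscore attributes)
and cover the full inference toolbox for the docking-site model:

* :func:`empirical_stats` — steady-state Fano factor and lag-1 correlation
  of an observed QC trace with bootstrap confidence intervals;
* :class:`MomentEstimator` / :func:`solve_moments` — joint inversion of the
  steady-state Fano-factor and correlation formulas for (p_r, p_d), with the
  swap-symmetric double root disambiguated by the observed normalized
  depression;
* :class:`TransientLSEstimator` / :func:`fit_transient_ls` — least-squares
  fit of the closed-form depression curve to a normalized mean-QC trace;
* :class:`EQEstimator` / :func:`eq_method` — the classical
  Elmqvist–Quastel pool-size extrapolation from the first few stimuli
  (biased low when replenishment is present);
* :class:`RefillScheduleEstimator` / :func:`fit_time_varying_refill` —
  time-varying refilling schedule, by least squares on the mean trace or by
  maximum likelihood on evoked amplitudes with quantal-size noise;
* :func:`feasible_region` — parameter-space mask consistent with bounds on
  FF, rho and normalized depression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats as sps
from sklearn.base import BaseEstimator

from . import core_stats
from .params import QuantalSizeModel, Schedule, SynapseParams
from .simulator import QCTrace

__all__ = [
    "EmpiricalStats",
    "InferenceResult",
    "empirical_stats",
    "solve_moments",
    "fit_transient_ls",
    "eq_method",
    "fit_time_varying_refill",
    "feasible_region",
    "MomentEstimator",
    "TransientLSEstimator",
    "EQEstimator",
    "RefillScheduleEstimator",
]


@dataclass(frozen=True)
class EmpiricalStats:
    """Point estimates and 95% bootstrap CIs of steady-state QC statistics."""

    mean_qc: float
    ff: float
    rho: float
    ci: dict
    burn_in: int
    n_boot: int
    seed: int
    n_used: int
    rho_ell: Optional[np.ndarray] = None


@dataclass
class InferenceResult:
    """Parameter estimates with alternative roots and diagnostics."""

    method: str
    estimates: dict
    roots: list = field(default_factory=list)
    ci: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    @property
    def pr(self) -> Optional[float]:
        return self.estimates.get("pr")

    @property
    def pd(self) -> Optional[float]:
        return self.estimates.get("pd")


def _as_qc(trace) -> np.ndarray:
    if isinstance(trace, QCTrace):
        return trace.qc
    return np.asarray(trace, dtype=float)


def empirical_stats(
    trace,
    burn_in: int = 10,
    n_boot: int = 1000,
    seed: int = 0,
    lags: Optional[Sequence[int]] = None,
) -> EmpiricalStats:
    """Steady-state mean QC, Fano factor and lag-1 correlation of a trace.

    Statistics are computed on stimuli ``burn_in .. end`` (1-based,
    inclusive), the window the recordings use once the initial depression has
    settled. FF bootstraps single QC values; rho bootstraps consecutive
    (qc_i, qc_{i+1}) pairs so the lag-1 structure being estimated survives
    resampling. CIs are 2.5/97.5 percentiles.
    """
    qc = _as_qc(trace)
    if burn_in < 1:
        raise ValueError(f"burn_in must be >= 1, got {burn_in}")
    if len(qc) <= burn_in + 1:
        raise ValueError(
            f"trace length {len(qc)} too short for burn_in {burn_in}"
        )
    window = qc[burn_in - 1:]
    mean = window.mean()
    if mean == 0.0:
        raise ValueError("mean QC over the window is zero; Fano factor undefined")
    if window.std() == 0.0:
        raise ValueError("constant QC trace; correlation undefined")
    ff = window.var(ddof=1) / mean
    pairs = np.column_stack([window[:-1], window[1:]])
    rho = _pearson(pairs[:, 0], pairs[:, 1])
    rho_ell = None
    if lags is not None:
        rho_ell = np.array(
            [_pearson(window[:-l], window[l:]) for l in lags]
        )

    rng = np.random.default_rng(seed)
    n = len(window)
    ff_boot = np.empty(n_boot)
    rho_boot = np.empty(n_boot)
    mean_boot = np.empty(n_boot)
    for b in range(n_boot):
        resampled = window[rng.integers(0, n, n)]
        mean_boot[b] = resampled.mean()
        ff_boot[b] = resampled.var(ddof=1) / resampled.mean()
        pick = pairs[rng.integers(0, len(pairs), len(pairs))]
        rho_boot[b] = _pearson(pick[:, 0], pick[:, 1])
    ci = {
        "mean_qc": tuple(np.percentile(mean_boot, [2.5, 97.5])),
        "ff": tuple(np.percentile(ff_boot, [2.5, 97.5])),
        "rho": tuple(np.percentile(rho_boot, [2.5, 97.5])),
    }
    return EmpiricalStats(
        mean_qc=float(mean), ff=float(ff), rho=float(rho), ci=ci,
        burn_in=burn_in, n_boot=n_boot, seed=seed, n_used=n, rho_ell=rho_ell,
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return np.nan
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


# ---------------------------------------------------------------------------
# Joint (FF, rho) moment inversion
# ---------------------------------------------------------------------------

def solve_moments(
    ff_obs: float,
    rho_obs: float,
    pu_fixed: float = 0.0,
    depression_obs: Optional[float] = None,
) -> InferenceResult:
    """All (p_r, p_d) roots of {FF = ff_obs, rho = rho_obs} at fixed p_u.

    For ``pu_fixed = 0`` the system reduces analytically: with
    ``s = pr + pd`` and ``q = pr * pd``,

        q = 1 - FF + rho * FF,     s = q (2 - FF) / (1 - FF),

    and (pr, pd) are the two roots of ``x**2 - s x + q = 0`` — a
    swap-symmetric pair, since FF and rho are symmetric in (pr, pd) when
    there is no undocking. For ``pu_fixed > 0`` a deterministic multi-start
    root search solves the full system. When ``depression_obs`` is given the
    root whose predicted normalized depression (pbar, assuming full initial
    occupancy and constant release probability) is closest is selected;
    otherwise the high-pr root comes first.
    """
    if not (0.0 < ff_obs < 1.0):
        raise ValueError(f"ff_obs must be in (0, 1), got {ff_obs}")
    if rho_obs > 0.0:
        raise ValueError(f"rho_obs must be <= 0, got {rho_obs}")
    if pu_fixed == 0.0 and rho_obs < core_stats.RHO_GLOBAL_MIN:
        raise ValueError(
            f"rho_obs = {rho_obs} below the global minimum "
            f"{core_stats.RHO_GLOBAL_MIN} attainable with pu = 0"
        )

    if pu_fixed == 0.0:
        roots = _solve_moments_pu0(ff_obs, rho_obs)
    else:
        roots = _solve_moments_numeric(ff_obs, rho_obs, pu_fixed)
    if not roots:
        raise ValueError(
            f"no (pr, pd) root in the open unit square for FF={ff_obs}, "
            f"rho={rho_obs}, pu={pu_fixed}"
        )

    roots.sort(key=lambda r: -r[0])  # high-pr root first by default
    depressions = [
        core_stats.steady_state_occupancy(pr, pu_fixed, pd) for pr, pd in roots
    ]
    selected = 0
    if depression_obs is not None:
        selected = int(np.argmin([abs(d - depression_obs) for d in depressions]))
    pr_hat, pd_hat = roots[selected]
    return InferenceResult(
        method="moments",
        estimates={"pr": pr_hat, "pd": pd_hat, "pu": pu_fixed},
        roots=[tuple(r) for r in roots],
        diagnostics={
            "selected_root": selected,
            "depression_per_root": depressions,
            "depression_obs": depression_obs,
        },
    )


def _solve_moments_pu0(ff: float, rho: float) -> list:
    q = 1.0 - ff + rho * ff
    s = q * (2.0 - ff) / (1.0 - ff)
    disc = s * s - 4.0 * q
    if q <= 0.0 or disc < 0.0:
        return []
    root = np.sqrt(disc)
    x1, x2 = (s + root) / 2.0, (s - root) / 2.0
    if not (0.0 < x2 <= x1 < 1.0):
        return []
    if x1 == x2:
        return [(x1, x2)]
    return [(x1, x2), (x2, x1)]


def _solve_moments_numeric(ff: float, rho: float, pu: float) -> list:
    def residuals(x):
        pr, pd = x
        pr = min(max(pr, 1e-9), 1 - 1e-9)
        pd = min(max(pd, 1e-9), 1 - 1e-9)
        return [
            core_stats.steady_state_fano(pr, pu, pd) - ff,
            core_stats.steady_state_corr(pr, pu, pd) - rho,
        ]

    found = []
    starts = [(a, b) for a in np.arange(0.05, 1.0, 0.1) for b in np.arange(0.05, 1.0, 0.1)]
    for start in starts:
        sol = optimize.least_squares(
            residuals, start, bounds=([1e-6, 1e-6], [1 - 1e-6, 1 - 1e-6]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        if not sol.success or np.linalg.norm(sol.fun) > 1e-10:
            continue
        pr, pd = sol.x
        if not (1e-5 < pr < 1 - 1e-5 and 1e-5 < pd < 1 - 1e-5):
            continue
        if any(abs(pr - r[0]) < 1e-6 and abs(pd - r[1]) < 1e-6 for r in found):
            continue
        found.append((float(pr), float(pd)))
    return found


# ---------------------------------------------------------------------------
# Transient least-squares fit (constant pr, pd)
# ---------------------------------------------------------------------------

def _depression_curve(pr: float, pd: float, n: int) -> np.ndarray:
    """Normalized mean-QC curve for constant (pr, pd), pu=0, full initial occupancy."""
    den = pd + pr * (1.0 - pd)
    i = np.arange(1, n + 1)
    lam = (1.0 - pr) * (1.0 - pd)
    return (pd + lam ** (i - 1) * (den - pd)) / den


def fit_transient_ls(mean_trace) -> InferenceResult:
    """Least-squares (pr, pd) fit of the normalized depression curve.

    ``mean_trace`` must be normalized to its first stimulus (element 1 == 1).
    A deterministic grid of starts feeds a bounded least-squares solver; the
    best residual wins.
    """
    data = _as_qc(mean_trace)
    if abs(data[0] - 1.0) > 1e-9:
        raise ValueError(
            "mean_trace must be normalized to the first stimulus "
            f"(got first element {data[0]})"
        )
    n = len(data)

    def residuals(x):
        return _depression_curve(x[0], x[1], n) - data

    best = None
    for start in [(a, b) for a in (0.1, 0.3, 0.5, 0.7, 0.9)
                  for b in (0.1, 0.3, 0.5, 0.7, 0.9)]:
        sol = optimize.least_squares(
            residuals, start, bounds=([1e-9, 1e-9], [1 - 1e-9, 1.0]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    pr_hat, pd_hat = float(best.x[0]), float(best.x[1])
    return InferenceResult(
        method="ls_transient",
        estimates={"pr": pr_hat, "pd": pd_hat},
        diagnostics={
            "residual_norm": float(np.sqrt(2 * best.cost)),
            "converged": bool(best.success),
            "p_bar": pd_hat / (pd_hat + pr_hat * (1 - pd_hat)),
        },
    )


# ---------------------------------------------------------------------------
# Elmqvist–Quastel estimator
# ---------------------------------------------------------------------------

def eq_method(qc_head, k: int = 3) -> InferenceResult:
    """Classical pool-size extrapolation from the first ``k`` stimuli.

    Regresses QC_i on the cumulative QC released before stimulus i and
    extrapolates to the x-intercept, which estimates the initial releasable
    pool under the assumption of no replenishment during the first stimuli;
    the release probability estimate is QC_1 / pool. When replenishment is
    in fact present the pool is overestimated and pr is biased low.
    """
    qc = _as_qc(qc_head)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if len(qc) < k:
        raise ValueError(f"need at least k={k} QC values, got {len(qc)}")
    y = qc[:k]
    x = np.concatenate([[0.0], np.cumsum(y)[:-1]])
    slope, intercept = np.polyfit(x, y, 1)
    if slope >= 0.0:
        raise ValueError(
            "EQ method inapplicable: QC does not decrease with cumulative "
            f"release (slope {slope:.4g} >= 0)"
        )
    pool = float(-intercept / slope)
    pr_hat = float(y[0] / pool)
    return InferenceResult(
        method="eq",
        estimates={"pool": pool, "pr": pr_hat},
        diagnostics={"slope": float(slope), "intercept": float(intercept), "k": k},
    )


# ---------------------------------------------------------------------------
# Time-varying refilling schedule (LS and MLE)
# ---------------------------------------------------------------------------

def _schedule_curve(theta: np.ndarray, pr: float, n: int) -> np.ndarray:
    """Normalized mean QC under refilling schedule theta = (pd_1..pd_k, tail)."""
    params = SynapseParams(
        M=1, p1=1.0, pr=pr,
        pd=Schedule(tuple(theta[:-1]), theta[-1], "pd"),
        pu=0.0,
    )
    series = core_stats.occupancy_recursion(params, n)
    return series.p  # p1 = 1, constant pr -> normalized mean QC = p_i


def fit_time_varying_refill(
    trace,
    pr_fixed: float,
    n_transient: int = 5,
    mode: str = "ls",
    M: Optional[int] = None,
    quantal: Optional[QuantalSizeModel] = None,
) -> InferenceResult:
    """Fit per-stimulus refilling probabilities (first ``n_transient`` free,
    then a constant tail) at a fixed release probability.

    ``mode='ls'`` minimizes the squared error between the model's normalized
    mean QC and the trace normalized to its first stimulus. ``mode='mle'``
    maximizes the compound binomial–Gaussian likelihood of evoked
    amplitudes: each amplitude's marginal density sums Binomial(b; M,
    p_i * pr) against a Gaussian with mean b*c_mean and variance
    b*(cv_q*c_mean)**2, which accounts for quantal-size fluctuations
    explicitly. MLE requires ``M``, ``quantal`` and a trace carrying
    amplitudes.
    """
    if not (0.0 < pr_fixed <= 1.0):
        raise ValueError(f"pr_fixed must be in (0, 1], got {pr_fixed}")
    if mode == "ls":
        return _fit_schedule_ls(trace, pr_fixed, n_transient)
    if mode == "mle":
        return _fit_schedule_mle(trace, pr_fixed, n_transient, M, quantal)
    raise ValueError(f"unknown mode {mode!r}")


def _fit_schedule_ls(trace, pr: float, k: int) -> InferenceResult:
    data = _as_qc(trace)
    if data[0] <= 0:
        raise ValueError("first-stimulus QC must be positive for normalization")
    data = data / data[0]
    n = len(data)

    def residuals(theta):
        return _schedule_curve(theta, pr, n) - data

    best = None
    for start_val in (0.3, 0.5, 0.8):
        sol = optimize.least_squares(
            residuals, np.full(k + 1, start_val),
            bounds=(np.zeros(k + 1), np.ones(k + 1)),
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    theta = best.x
    return InferenceResult(
        method="time_varying_ls",
        estimates={
            "pd_schedule": [float(v) for v in theta[:-1]],
            "pd_tail": float(theta[-1]),
            "pr": pr,
        },
        diagnostics={
            "residual_norm": float(np.sqrt(2 * best.cost)),
            "converged": bool(best.success),
        },
    )


def _fit_schedule_mle(
    trace, pr: float, k: int, M: Optional[int], quantal: Optional[QuantalSizeModel]
) -> InferenceResult:
    if not isinstance(trace, QCTrace) or trace.amplitude is None:
        raise ValueError("MLE mode requires a QCTrace with evoked amplitudes")
    if quantal is None:
        raise ValueError("MLE mode requires a QuantalSizeModel")
    amp = trace.amplitude
    n = len(amp)
    if M is None:
        # scale from the steady-state mean QC implied by the amplitudes
        qc_proxy = amp / quantal.c_mean
        stats0 = empirical_stats(qc_proxy, burn_in=min(10, n // 10 + 1), n_boot=50)
        root = solve_moments(min(max(stats0.ff, 1e-3), 1 - 1e-3), min(stats0.rho, 0.0))
        M = int(round(stats0.mean_qc / (
            core_stats.steady_state_occupancy(root.pr, 0.0, root.pd) * root.pr)))
    b = np.arange(M + 1)
    sd = quantal.c_sd * np.sqrt(np.maximum(b, 1))
    # Gaussian density of each amplitude under each possible QC b >= 1;
    # b = 0 is a point mass at amplitude exactly zero. Parameter-independent,
    # so computed once.
    G = np.zeros((n, M + 1))
    G[:, 1:] = sps.norm.pdf(
        amp[:, None], loc=b[1:] * quantal.c_mean, scale=sd[1:]
    )
    G[:, 0] = (amp == 0.0).astype(float)

    def negloglik(theta):
        succ = _schedule_curve(theta, pr, n) * pr
        vals, inv = np.unique(np.round(succ, 12), return_inverse=True)
        pmf = sps.binom.pmf(b[None, :], M, vals[:, None])
        lik = np.einsum("ij,ij->i", pmf[inv], G)
        return -np.sum(np.log(np.maximum(lik, 1e-300)))

    start = np.full(k + 1, 0.5)
    sol = optimize.minimize(
        negloglik, start, method="L-BFGS-B",
        bounds=[(1e-4, 1 - 1e-4)] * (k + 1),
        options={"maxiter": 500},
    )
    theta = sol.x
    return InferenceResult(
        method="mle",
        estimates={
            "pd_schedule": [float(v) for v in theta[:-1]],
            "pd_tail": float(theta[-1]),
            "pr": pr,
            "M": int(M),
        },
        diagnostics={
            "neg_loglik": float(sol.fun),
            "converged": bool(sol.success),
            "message": str(sol.message),
        },
    )


# ---------------------------------------------------------------------------
# Feasible-region mask
# ---------------------------------------------------------------------------

def feasible_region(
    ff_max: Optional[float] = None,
    rho_min: Optional[float] = None,
    depression_range: Optional[Tuple[float, float]] = None,
    resolution: float = 0.005,
):
    """Mask of the (pr, pd) unit square consistent with observed bounds.

    Evaluates the steady-state Fano factor, lag-1 correlation and
    normalized depression (pu = 0) on a regular grid and intersects the
    constraints ``FF <= ff_max``, ``rho >= rho_min`` and
    ``depression_range[0] <= pbar <= depression_range[1]``. Returns
    ``(mask, pr_values, pd_values)`` with mask indexed [pr, pd].
    """
    if not (0.0 < resolution < 0.5):
        raise ValueError(f"resolution must be in (0, 0.5), got {resolution}")
    vals = np.arange(resolution, 1.0, resolution)
    if len(vals) == 0:
        raise ValueError("empty grid")
    pr = vals[:, None]
    pd = vals[None, :]
    den = pd + pr * (1.0 - pd)
    pbar = pd / den
    ff = 1.0 - pbar * pr
    rho = pd * pr * (1.0 - pr) * (1.0 - pd) / (2.0 * pd * pr - pr - pd)
    mask = np.ones(ff.shape, dtype=bool)
    if ff_max is not None:
        mask &= ff <= ff_max
    if rho_min is not None:
        mask &= rho >= rho_min
    if depression_range is not None:
        lo, hi = depression_range
        mask &= (pbar >= lo) & (pbar <= hi)
    return mask, vals.copy(), vals.copy()


# ---------------------------------------------------------------------------
# sklearn-style estimator classes
# ---------------------------------------------------------------------------

class MomentEstimator(BaseEstimator):
    """Recover (p_r, p_d) from a QC trace via steady-state moment inversion.

    ``fit`` computes the empirical Fano factor and lag-1 correlation over the
    steady-state window, then solves the closed-form moment equations. The
    observed normalized depression (steady-state mean over first-stimulus QC)
    disambiguates the symmetric double root unless ``use_depression=False``.
    """

    def __init__(self, pu: float = 0.0, burn_in: int = 10, n_boot: int = 1000,
                 use_depression: bool = True, seed: int = 0):
        self.pu = pu
        self.burn_in = burn_in
        self.n_boot = n_boot
        self.use_depression = use_depression
        self.seed = seed

    def fit(self, trace, y=None):
        qc = _as_qc(trace)
        self.stats_ = empirical_stats(
            qc, burn_in=self.burn_in, n_boot=self.n_boot, seed=self.seed
        )
        depression = None
        if self.use_depression and qc[0] > 0:
            depression = self.stats_.mean_qc / qc[0]
        self.result_ = solve_moments(
            self.stats_.ff, min(self.stats_.rho, 0.0),
            pu_fixed=self.pu, depression_obs=depression,
        )
        self.pr_ = self.result_.pr
        self.pd_ = self.result_.pd
        self.roots_ = self.result_.roots
        return self


class TransientLSEstimator(BaseEstimator):
    """Fit constant (p_r, p_d) to the normalized mean-QC depression curve."""

    def __init__(self, normalize: bool = True):
        self.normalize = normalize

    def fit(self, mean_trace, y=None):
        data = _as_qc(mean_trace)
        if self.normalize:
            if data[0] <= 0:
                raise ValueError("cannot normalize: first element <= 0")
            data = data / data[0]
        self.result_ = fit_transient_ls(data)
        self.pr_ = self.result_.pr
        self.pd_ = self.result_.pd
        return self


class EQEstimator(BaseEstimator):
    """Elmqvist–Quastel pool/release-probability estimator from early stimuli."""

    def __init__(self, k: int = 3):
        self.k = k

    def fit(self, trace, y=None):
        self.result_ = eq_method(_as_qc(trace), k=self.k)
        self.pool_ = self.result_.estimates["pool"]
        self.pr_ = self.result_.estimates["pr"]
        return self


class RefillScheduleEstimator(BaseEstimator):
    """Time-varying refilling-probability schedule at fixed release probability."""

    def __init__(self, pr_fixed: float = 0.93, n_transient: int = 5,
                 mode: str = "ls", M: Optional[int] = None,
                 quantal: Optional[QuantalSizeModel] = None):
        self.pr_fixed = pr_fixed
        self.n_transient = n_transient
        self.mode = mode
        self.M = M
        self.quantal = quantal

    def fit(self, trace, y=None):
        self.result_ = fit_time_varying_refill(
            trace, pr_fixed=self.pr_fixed, n_transient=self.n_transient,
            mode=self.mode, M=self.M, quantal=self.quantal,
        )
        self.pd_schedule_ = self.result_.estimates["pd_schedule"]
        self.pd_tail_ = self.result_.estimates["pd_tail"]
        return self
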