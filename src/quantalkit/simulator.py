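"""Seeded Monte-Carlo simulation of the docking-site model.

Two regimes are covered:

* deterministic AP trains, where the exact binomial theory of
  :mod:`quantalkit.core_stats` applies and the simulator serves as its
  empirical cross-check;
* random i.i.d. inter-stimulus intervals, where per-interval refilling and
  undocking probabilities are recomputed from continuous-time site kinetics
  for each sampled interval and the QC is no longer binomial (its Fano
  factor can exceed one).

The site-level Bernoulli simulation is the reference implementation — it is
the literal model, one coin per site per event. Because sites are identical
and independent, an aggregated path drawing binomials on occupied/empty
counts is distributionally equivalent and much faster; the test suite proves
the equivalence and either can be selected via ``method=``.

Event order within one stimulus cycle: fusion at the AP, then undocking of
surviving docked SVs, then refilling of sites that were empty after fusion.
A site makes at most one transition per interval — a site emptied by fusion
may refill before the next AP, but a site that undocks may not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .kinetics import SiteRates, rates_to_probs
from .params import QuantalSizeModel, Schedule, SynapseParams

__all__ = [
    "QCTrace",
    "IntervalModel",
    "simulate_trial",
    "simulate_ensemble",
    "simulate_random_train",
    "add_quantal_noise",
]


@dataclass
class QCTrace:
    """A sequence of per-stimulus quantal contents, optionally with amplitudes.

    Experimental QCs are amplitude ratios and therefore real-valued;
    simulated QCs are integer counts stored as floats in the same container.
    """

    qc: np.ndarray
    amplitude: Optional[np.ndarray] = None
    stimulus_times: Optional[np.ndarray] = None
    recording_id: Optional[str] = None

    def __post_init__(self):
        self.qc = np.asarray(self.qc, dtype=float)
        if self.qc.ndim != 1 or len(self.qc) == 0:
            raise ValueError("qc must be a non-empty 1-D sequence")
        if np.any(self.qc < 0) or not np.all(np.isfinite(self.qc)):
            raise ValueError("qc values must be finite and non-negative")
        if self.amplitude is not None:
            self.amplitude = np.asarray(self.amplitude, dtype=float)
            if self.amplitude.shape != self.qc.shape:
                raise ValueError("amplitude length must match qc length")
        if self.stimulus_times is not None:
            self.stimulus_times = np.asarray(self.stimulus_times, dtype=float)
            if self.stimulus_times.shape != self.qc.shape:
                raise ValueError("stimulus_times length must match qc length")
            if np.any(np.diff(self.stimulus_times) <= 0):
                raise ValueError("stimulus_times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.qc)


@dataclass(frozen=True)
class IntervalModel:
    """Inter-stimulus interval model: fixed, exponential or gamma.

    ``fixed`` uses ``dt`` seconds between APs. ``exponential`` draws i.i.d.
    intervals with the given ``mean``; ``gamma`` with ``shape`` and ``scale``.
    """

    kind: str = "fixed"
    dt: float = 0.02
    mean: Optional[float] = None
    shape: Optional[float] = None
    scale: Optional[float] = None

    def __post_init__(self):
        if self.kind not in ("fixed", "exponential", "gamma"):
            raise ValueError(f"unknown interval model kind {self.kind!r}")
        if self.kind == "fixed" and self.dt <= 0:
            raise ValueError("fixed interval dt must be > 0")
        if self.kind == "exponential" and (self.mean is None or self.mean <= 0):
            raise ValueError("exponential interval model requires mean > 0")
        if self.kind == "gamma" and (
            self.shape is None or self.scale is None or self.shape <= 0 or self.scale <= 0
        ):
            raise ValueError("gamma interval model requires shape > 0 and scale > 0")

    @property
    def is_random(self) -> bool:
        return self.kind != "fixed"

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(n, self.dt)
        if self.kind == "exponential":
            out = rng.exponential(self.mean, size=n)
        else:
            out = rng.gamma(self.shape, self.scale, size=n)
        if np.any(out <= 0):
            raise ValueError("sampled inter-stimulus interval <= 0")
        return out


def _advance_counts(
    rng: np.random.Generator, n, M: int, pr: float, pu: float, pd: float
):
    """One stimulus cycle on docked counts (scalar or vector ``n``).

    Returns (qc, next_n). Aggregated binomial form of the per-site rules.
    """
    qc = rng.binomial(n, pr)
    remaining = n - qc
    undocked = rng.binomial(remaining, pu) if pu > 0 else 0
    refilled = rng.binomial(M - remaining, pd)
    return qc, remaining - undocked + refilled


def simulate_trial(
    params: SynapseParams,
    n_stimuli: int,
    seed: int,
    method: str = "site",
    return_counts: bool = False,
):
    """Simulate one AP train; identical seed gives an identical trace.

    ``method='site'`` flips one coin per site per event (reference
    implementation); ``method='aggregate'`` draws the distributionally
    equivalent binomial counts.
    """
    if n_stimuli < 1:
        raise ValueError(f"n_stimuli must be >= 1, got {n_stimuli}")
    if method not in ("site", "aggregate"):
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    M = params.M
    pr = params.pr.values(n_stimuli)
    pu = params.pu.values(n_stimuli)
    pd = params.pd.values(n_stimuli)
    qc = np.empty(n_stimuli, dtype=np.int64)
    counts = np.empty(n_stimuli, dtype=np.int64)

    if method == "site":
        state = rng.random(M) < params.p1
        for i in range(n_stimuli):
            counts[i] = state.sum()
            released = state & (rng.random(M) < pr[i])
            qc[i] = released.sum()
            occupied = state & ~released
            undock = occupied & (rng.random(M) < pu[i])
            refill = ~occupied & (rng.random(M) < pd[i])
            state = (occupied & ~undock) | refill
    else:
        n = rng.binomial(M, params.p1)
        for i in range(n_stimuli):
            counts[i] = n
            qc[i], n = _advance_counts(rng, n, M, pr[i], pu[i], pd[i])

    trace = QCTrace(qc=qc.astype(float))
    if return_counts:
        return trace, counts
    return trace


def simulate_ensemble(
    params: SynapseParams, n_stimuli: int, n_trials: int, seed: int
):
    """Vectorized ensemble of independent trials (aggregated path).

    Returns ``(qc, counts)`` integer arrays of shape (n_trials, n_stimuli).
    Used for empirical per-stimulus distributions at large trial counts.
    """
    rng = np.random.default_rng(seed)
    M = params.M
    pr = params.pr.values(n_stimuli)
    pu = params.pu.values(n_stimuli)
    pd = params.pd.values(n_stimuli)
    n = rng.binomial(M, params.p1, size=n_trials)
    qc = np.empty((n_trials, n_stimuli), dtype=np.int64)
    counts = np.empty((n_trials, n_stimuli), dtype=np.int64)
    for i in range(n_stimuli):
        counts[:, i] = n
        qc[:, i], n = _advance_counts(rng, n, M, pr[i], pu[i], pd[i])
    return qc, counts


def simulate_random_train(
    M: int,
    p1: float,
    pr,
    rates: SiteRates,
    interval_model: IntervalModel,
    n_stimuli: int,
    seed: int,
) -> QCTrace:
    """Simulate an AP train with i.i.d. random inter-stimulus intervals.

    The kinetic rates are the primitives here: each sampled interval length
    is converted to per-interval refilling/undocking probabilities, so
    interval variability propagates into occupancy variability and the QC
    Fano factor may exceed one.
    """
    if not interval_model.is_random:
        raise ValueError(
            "interval_model must be random; use simulate_trial for fixed trains"
        )
    if n_stimuli < 1:
        raise ValueError(f"n_stimuli must be >= 1, got {n_stimuli}")
    pr = Schedule.from_value(pr, "pr")
    rng = np.random.default_rng(seed)
    intervals = interval_model.sample(rng, n_stimuli - 1)
    times = np.concatenate([[0.0], np.cumsum(intervals)])
    n = rng.binomial(M, p1)
    qc = np.empty(n_stimuli, dtype=np.int64)
    for i in range(n_stimuli):
        qc[i] = rng.binomial(n, pr(i + 1))
        if i < n_stimuli - 1:
            pd_i, pu_i = rates_to_probs(rates, intervals[i])
            remaining = n - qc[i]
            undocked = rng.binomial(remaining, pu_i) if pu_i > 0 else 0
            n = remaining - undocked + rng.binomial(M - remaining, pd_i)
    return QCTrace(qc=qc.astype(float), stimulus_times=times)


def add_quantal_noise(trace: QCTrace, q: QuantalSizeModel, seed: int) -> QCTrace:
    """Attach evoked amplitudes: each released quantum contributes an
    independent Gaussian amplitude with mean ``c_mean`` and SD
    ``cv_q * c_mean``, clipped at zero (physically non-negative; the clipped
    mass is negligible for cv_q <= 0.5).
    """
    qc_int = trace.qc
    if np.any(qc_int != np.round(qc_int)):
        raise ValueError("quantal noise applies to integer (simulated) QCs only")
    qc_int = qc_int.astype(np.int64)
    rng = np.random.default_rng(seed)
    total = int(qc_int.sum())
    draws = rng.normal(q.c_mean, q.c_sd, size=total) if q.cv_q > 0 else np.full(
        total, q.c_mean
    )
    np.maximum(draws, 0.0, out=draws)
    bounds = np.concatenate([[0], np.cumsum(qc_int)])
    sums = np.add.reduceat(
        np.concatenate([draws, [0.0]]), bounds[:-1]
    )
    sums[qc_int == 0] = 0.0
    return QCTrace(
        qc=trace.qc.copy(),
        amplitude=sums,
        stimulus_times=None if trace.stimulus_times is None else trace.stimulus_times.copy(),
        recording_id=trace.recording_id,
    )
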