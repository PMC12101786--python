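"""Model parameters for the stochastic docking-site description of a synapse.

The synapse is modelled as ``M`` identical, independent docking sites. Each
site is either empty or occupied by a release-ready synaptic vesicle (SV).
Three per-stimulus probabilities drive the dynamics:

* release probability ``p_r,i`` — a docked SV fuses upon the i-th action
  potential (AP),
* refilling probability ``p_d,i`` — an empty site is reoccupied between
  APs i and i+1,
* undocking probability ``p_u,i`` — an occupied site empties between APs
  (transient docking / spontaneous release).

All three may vary arbitrarily with the stimulus number, which is what lets
the model express facilitation, depression and transient replenishment
regimes within one framework.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

__all__ = ["Schedule", "SynapseParams", "QuantalSizeModel"]


ScheduleLike = Union[float, Sequence[float], "Schedule"]


@dataclass(frozen=True)
class Schedule:
    """A per-stimulus probability schedule: explicit prefix, then constant tail.

    ``Schedule([0.92, 0.73], tail=0.51)`` evaluates to 0.92 at stimulus 1,
    0.73 at stimulus 2 and 0.51 at every later stimulus. A bare constant is
    a schedule with an empty prefix. Stimulus indices are 1-based throughout.
    """

    prefix: tuple = ()
    tail: float = 0.0
    name: str = "schedule"

    def __post_init__(self):
        object.__setattr__(self, "prefix", tuple(float(v) for v in self.prefix))
        object.__setattr__(self, "tail", float(self.tail))
        for idx, v in enumerate(self.prefix, start=1):
            _check_prob(v, f"{self.name}[{idx}]")
        _check_prob(self.tail, f"{self.name} tail")

    @classmethod
    def from_value(cls, value: ScheduleLike, name: str = "schedule") -> "Schedule":
        """Coerce a constant, a sequence (last value becomes the tail), or a
        Schedule into a Schedule."""
        if isinstance(value, Schedule):
            return cls(value.prefix, value.tail, name)
        if np.isscalar(value):
            return cls((), float(value), name)
        seq = [float(v) for v in np.asarray(value, dtype=float).ravel()]
        if not seq:
            raise ValueError(f"{name}: empty schedule sequence")
        return cls(tuple(seq[:-1]), seq[-1], name)

    def __call__(self, i: int) -> float:
        """Value at stimulus ``i`` (1-based)."""
        if i < 1:
            raise ValueError(f"stimulus index must be >= 1, got {i}")
        if i <= len(self.prefix):
            return self.prefix[i - 1]
        return self.tail

    def values(self, n: int) -> np.ndarray:
        """Vector of values for stimuli 1..n."""
        out = np.full(n, self.tail)
        k = min(n, len(self.prefix))
        out[:k] = self.prefix[:k]
        return out

    @property
    def is_constant(self) -> bool:
        return all(v == self.tail for v in self.prefix)


def _check_prob(value: float, name: str) -> float:
    value = float(value)
    if not np.isfinite(value) or not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be a probability in [0, 1], got {value}")
    return value


@dataclass(frozen=True)
class SynapseParams:
    """Full generative specification of the docking-site model.

    Parameters
    ----------
    M : int
        Number of docking sites (>= 1).
    p1 : float
        Probability that a site is occupied when the first AP arrives.
    pr, pd, pu : float, sequence or Schedule
        Release / refilling / undocking probability schedules. Constants,
        sequences (last entry repeated forever) and `Schedule` objects are
        accepted.
    """

    M: int = 100
    p1: float = 1.0
    pr: Schedule = field(default_factory=lambda: Schedule((), 0.5, "pr"))
    pd: Schedule = field(default_factory=lambda: Schedule((), 0.5, "pd"))
    pu: Schedule = field(default_factory=lambda: Schedule((), 0.0, "pu"))

    def __post_init__(self):
        if int(self.M) != self.M or self.M < 1:
            raise ValueError(f"M must be a positive integer, got {self.M}")
        object.__setattr__(self, "M", int(self.M))
        _check_prob(self.p1, "p1")
        object.__setattr__(self, "pr", Schedule.from_value(self.pr, "pr"))
        object.__setattr__(self, "pd", Schedule.from_value(self.pd, "pd"))
        object.__setattr__(self, "pu", Schedule.from_value(self.pu, "pu"))

    @property
    def is_constant(self) -> bool:
        """True when all three schedules are constant across stimuli."""
        return self.pr.is_constant and self.pd.is_constant and self.pu.is_constant

    def tail_probs(self) -> tuple:
        """Constant tail values (pr, pu, pd) used for steady-state formulas."""
        return self.pr.tail, self.pu.tail, self.pd.tail


@dataclass(frozen=True)
class QuantalSizeModel:
    """Postsynaptic amplitude contributed by a single vesicle.

    ``c_mean`` is the mean quantal size (pA for the auditory-brainstem
    recordings this package emulates, where spontaneous PSCs average about
    22 pA) and ``cv_q`` its coefficient of variation.
    """

    c_mean: float = 22.0
    cv_q: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.c_mean) or self.c_mean <= 0:
            raise ValueError(f"c_mean must be > 0, got {self.c_mean}")
        if not np.isfinite(self.cv_q) or self.cv_q < 0:
            raise ValueError(f"cv_q must be >= 0, got {self.cv_q}")

    @property
    def c_sd(self) -> float:
        return self.cv_q * self.c_mean
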