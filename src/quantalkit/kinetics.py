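"""Mapping between continuous-time docking kinetics and per-interval probabilities.

Between two APs separated by ``dt`` seconds, a single docking site behaves as
a two-state continuous-time Markov chain: an empty site docks an SV with rate
``k_d`` (per second) and an occupied site loses its SV with rate ``k_u``.
Integrating the chain over the interval gives the per-interval refilling and
undocking probabilities

    p_d = k_d / (k_d + k_u) * (1 - exp(-(k_d + k_u) dt))
    p_u = k_u / (k_d + k_u) * (1 - exp(-(k_d + k_u) dt))

which reduce to ``p_d = 1 - exp(-k_d dt)``, ``p_u = 0`` when ``k_u = 0``.
Because the probabilities depend on ``dt`` they change with stimulation
frequency; the inverse map recovers rates from probabilities estimated at a
known inter-stimulus interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SiteRates", "rates_to_probs", "probs_to_rates"]


@dataclass(frozen=True)
class SiteRates:
    """Per-site docking rate ``k_d`` and undocking rate ``k_u`` (per second)."""

    k_d: float
    k_u: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.k_d) or self.k_d < 0:
            raise ValueError(f"k_d must be >= 0, got {self.k_d}")
        if not np.isfinite(self.k_u) or self.k_u < 0:
            raise ValueError(f"k_u must be >= 0, got {self.k_u}")


def rates_to_probs(rates: SiteRates, dt: float) -> tuple:
    """Per-interval (p_d, p_u) for a site with the given rates over ``dt`` seconds."""
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    total = rates.k_d + rates.k_u
    if total == 0.0:
        return 0.0, 0.0
    mix = 1.0 - np.exp(-total * dt)
    return rates.k_d / total * mix, rates.k_u / total * mix


def probs_to_rates(pd: float, pu: float, dt: float) -> SiteRates:
    """Exact inverse of :func:`rates_to_probs`.

    Requires ``pd + pu < 1``: finite rates cannot fully mix the two-state
    chain within a finite interval.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if pd < 0 or pu < 0:
        raise ValueError("probabilities must be non-negative")
    if pd + pu >= 1.0:
        raise ValueError(
            f"pd + pu = {pd + pu} >= 1: no finite rates reproduce these "
            "probabilities over a finite interval"
        )
    if pd == 0.0 and pu == 0.0:
        return SiteRates(0.0, 0.0)
    total = -np.log(1.0 - pd - pu) / dt
    frac = pd / (pd + pu)
    return SiteRates(k_d=total * frac, k_u=total * (1.0 - frac))
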