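"""Synthetic QC traces emulating the study conditions of the auditory case.

Named presets reproduce the parameter regimes this package is built around:

* ``mntb_lso`` — the inferred model of the inhibitory MNTB-LSO synapse
  under a 50-Hz, 3000-stimulus challenge: high constant release probability
  (p_r = 0.93), a refilling probability that starts near one and settles to
  0.51 within six stimuli, no undocking, full initial occupancy, and
  Gaussian quantal sizes with a 22 pA mean. Its steady-state theory gives
  FF ~ 0.51 and rho ~ -0.033.
* ``fig2_blue / fig2_orange / fig2_gray`` — depression at constant low
  release probability (p_r = 0.15) with decreasing refilling probability
  (p_d = 0.3 / 0.15 / 0.05) on M = 200 sites.
* ``fig2_yellow`` — facilitation-then-depression: release probability
  ramping 0.15 -> 0.3 over the first four stimuli with p_d = 0.02.
* ``fig3_low`` — the low-probability regime (p_r = 0.15, p_d = 0.05):
  Fano factor near one throughout.
* ``fig3_high`` — high release probability (p_r = 0.9) with a time-varying
  refilling schedule solved so the mean QC exactly tracks ``fig3_low``;
  the Fano factor instead starts low and rises.
* ``fig3_sites`` — p_r = p_d = 0.9 with a small pool matched to the same
  first-stimulus mean: Fano factor low throughout. (The scenario this
  stands for attributes the shared mean depression to a shrinking number
  of docking sites, which a fixed-M model does not reproduce; only the
  fluctuation profile is emulated.)

What these fixtures do not emulate about real recordings: slow drifts in
recording quality, amplitude measurement error beyond quantal-size
variability, and stimulation artifacts.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from . import core_stats
from .params import QuantalSizeModel, Schedule, SynapseParams
from .simulator import QCTrace, add_quantal_noise, simulate_trial

__all__ = ["generate_fixture", "mntb_lso_params", "list_scenarios"]

# Refilling schedule inferred for the MNTB-LSO case: transient values for the
# first five stimuli, then a constant tail.
MNTB_LSO_PD_SCHEDULE = (0.92, 0.73, 0.66, 0.53, 0.12)
MNTB_LSO_PD_TAIL = 0.51
MNTB_LSO_PR = 0.93
MNTB_LSO_C_MEAN = 22.0
MNTB_LSO_CV_Q = 0.3
MNTB_LSO_N_STIMULI = 3000  # 50 Hz for one minute


def mntb_lso_params(M: int = 100) -> SynapseParams:
    """Ground-truth parameters of the MNTB-LSO preset."""
    return SynapseParams(
        M=M, p1=1.0, pr=MNTB_LSO_PR,
        pd=Schedule(MNTB_LSO_PD_SCHEDULE, MNTB_LSO_PD_TAIL, "pd"),
        pu=0.0,
    )


def _fig2_params(color: str) -> SynapseParams:
    pd = {"blue": 0.3, "orange": 0.15, "gray": 0.05, "yellow": 0.02}[color]
    if color == "yellow":
        pr = Schedule((0.15, 0.2, 0.25), 0.3, "pr")
    else:
        pr = 0.15
    return SynapseParams(M=200, p1=1.0, pr=pr, pd=pd, pu=0.0)


def _fig3_high_params(n_stimuli: int) -> SynapseParams:
    """High-pr regime whose mean QC tracks the low-probability regime.

    The refilling schedule is obtained by inverting the occupancy recursion
    against the target occupancy trajectory of (pr=0.15, pd=0.05) rescaled
    to the smaller pool that matches the first-stimulus mean.
    """
    low = SynapseParams(M=200, p1=1.0, pr=0.15, pd=0.05, pu=0.0)
    target_mean = core_stats.occupancy_recursion(low, n_stimuli).mean_qc
    pr_high = 0.9
    M_high = int(round(target_mean[0] / pr_high))
    p = target_mean / (M_high * pr_high)
    p = np.minimum(p, 1.0)
    pd_sched = []
    for i in range(n_stimuli - 1):
        survived = p[i] * (1.0 - pr_high)
        pd_i = (p[i + 1] - survived) / (1.0 - survived)
        pd_sched.append(min(max(pd_i, 0.0), 1.0))
    tail = pd_sched[-1] if pd_sched else 0.0
    return SynapseParams(
        M=M_high, p1=1.0, pr=pr_high,
        pd=Schedule(tuple(pd_sched), tail, "pd"), pu=0.0,
    )


def list_scenarios() -> list:
    return [
        "mntb_lso", "fig2_blue", "fig2_orange", "fig2_gray", "fig2_yellow",
        "fig3_low", "fig3_high", "fig3_sites",
    ]


def generate_fixture(
    scenario: str,
    seed: int,
    n_stimuli: Optional[int] = None,
    M: Optional[int] = None,
) -> Tuple[QCTrace, SynapseParams, dict]:
    """Simulate a named preset; returns (trace, ground-truth params, extras).

    ``extras`` carries the quantal-size model when the preset attaches evoked
    amplitudes, so parameter-recovery tests know the full generative truth.
    Identical seeds give identical fixtures.
    """
    extras: dict = {}
    if scenario == "mntb_lso":
        n = n_stimuli or MNTB_LSO_N_STIMULI
        params = mntb_lso_params(M or 100)
        trace = simulate_trial(params, n, seed=seed, method="aggregate")
        q = QuantalSizeModel(c_mean=MNTB_LSO_C_MEAN, cv_q=MNTB_LSO_CV_Q)
        trace = add_quantal_noise(trace, q, seed=seed + 1)
        trace.stimulus_times = np.arange(n) * 0.02
        trace.recording_id = f"mntb_lso_seed{seed}"
        extras["quantal"] = q
    elif scenario.startswith("fig2_"):
        n = n_stimuli or 30
        params = _fig2_params(scenario.removeprefix("fig2_"))
        trace = simulate_trial(params, n, seed=seed, method="aggregate")
        trace.recording_id = f"{scenario}_seed{seed}"
    elif scenario == "fig3_low":
        n = n_stimuli or 30
        params = SynapseParams(M=200, p1=1.0, pr=0.15, pd=0.05, pu=0.0)
        trace = simulate_trial(params, n, seed=seed, method="aggregate")
        trace.recording_id = f"{scenario}_seed{seed}"
    elif scenario == "fig3_high":
        n = n_stimuli or 30
        params = _fig3_high_params(n)
        trace = simulate_trial(params, n, seed=seed, method="aggregate")
        trace.recording_id = f"{scenario}_seed{seed}"
    elif scenario == "fig3_sites":
        n = n_stimuli or 30
        params = SynapseParams(M=M or 33, p1=1.0, pr=0.9, pd=0.9, pu=0.0)
        trace = simulate_trial(params, n, seed=seed, method="aggregate")
        trace.recording_id = f"{scenario}_seed{seed}"
    else:
        raise ValueError(
            f"unknown scenario {scenario!r}; available: {list_scenarios()}"
        )
    return trace, params, extras
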