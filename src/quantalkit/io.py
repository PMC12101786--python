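"""Reading and writing QC trace files and run configurations.

Traces travel as tidy tables with columns ``recording_id``,
``stimulus_index`` (1-based, contiguous), ``qc`` and optionally
``amplitude_pA``. CSV is the native format; spreadsheets (.xlsx) are
ingested in either the same tidy layout or a one-column-per-recording
layout, auto-detected from the header.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import yaml

from .params import QuantalSizeModel, Schedule, SynapseParams
from .simulator import IntervalModel, QCTrace

__all__ = ["read_trace", "write_trace", "RunConfig"]

_REQUIRED = ["recording_id", "stimulus_index", "qc"]


def _traces_from_tidy(df: pd.DataFrame, source: str) -> List[QCTrace]:
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing required columns {missing}")
    qc_numeric = pd.to_numeric(df["qc"], errors="coerce")
    bad = df.index[qc_numeric.isna() & df["qc"].notna()]
    if len(bad):
        raise ValueError(f"{source}: non-numeric qc value at row {bad[0] + 2}")
    df = df.assign(qc=qc_numeric).dropna(subset=["qc"])
    traces = []
    for rid, group in df.groupby("recording_id", sort=False):
        idx = group["stimulus_index"].to_numpy()
        expected = np.arange(1, len(idx) + 1)
        if not np.array_equal(idx, expected):
            gap = int(expected[idx != expected][0]) if len(idx) == len(expected) else len(idx)
            raise ValueError(
                f"{source}: recording {rid!r} has non-contiguous stimulus_index "
                f"(first problem near stimulus {gap})"
            )
        amp = None
        if "amplitude_pA" in group.columns and group["amplitude_pA"].notna().all():
            amp = group["amplitude_pA"].to_numpy(dtype=float)
        traces.append(
            QCTrace(qc=group["qc"].to_numpy(dtype=float), amplitude=amp,
                    recording_id=str(rid))
        )
    if not traces:
        raise ValueError(f"{source}: no recordings found")
    return traces


def _traces_from_wide(df: pd.DataFrame, source: str) -> List[QCTrace]:
    traces = []
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce").dropna().to_numpy(dtype=float)
        if len(vals) == 0:
            continue
        traces.append(QCTrace(qc=vals, recording_id=str(col)))
    if not traces:
        raise ValueError(f"{source}: no numeric columns found")
    return traces


def read_trace(path, format: Optional[str] = None) -> List[QCTrace]:
    """Read one QCTrace per recording from a CSV or spreadsheet file.

    ``format`` may be ``'csv'`` or ``'xlsx'``; inferred from the suffix when
    omitted. Spreadsheets may use either the tidy layout or one column of QC
    values per recording (header = recording id), auto-detected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("xlsx" if path.suffix.lower() in (".xlsx", ".xlsm") else "csv")
    if fmt == "csv":
        df = pd.read_csv(path)
    elif fmt == "xlsx":
        df = pd.read_excel(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if all(c in df.columns for c in _REQUIRED):
        return _traces_from_tidy(df, str(path))
    if fmt == "xlsx":
        return _traces_from_wide(df, str(path))
    raise ValueError(
        f"{path}: expected columns {_REQUIRED} (+ optional amplitude_pA)"
    )


def write_trace(traces, path) -> None:
    """Write traces as a tidy CSV with 12 significant digits."""
    if isinstance(traces, QCTrace):
        traces = [traces]
    frames = []
    for k, tr in enumerate(traces):
        rid = tr.recording_id if tr.recording_id is not None else f"rec{k + 1}"
        frame = {
            "recording_id": rid,
            "stimulus_index": np.arange(1, len(tr) + 1),
            "qc": tr.qc,
        }
        if tr.amplitude is not None:
            frame["amplitude_pA"] = tr.amplitude
        frames.append(pd.DataFrame(frame))
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.12g"
    )


@dataclasses.dataclass
class RunConfig:
    """Validated simulation/analysis configuration (YAML round-trippable).

    Schedules accept a scalar or a list whose last entry repeats forever.
    Every stochastic step is governed by the single explicit ``seed``.
    """

    M: int = 100
    p1: float = 1.0
    pr: object = 0.5
    pd: object = 0.5
    pu: object = 0.0
    n_stimuli: int = 3000
    seed: int = 0
    burn_in: int = 10
    n_boot: int = 1000
    c_mean: Optional[float] = None
    cv_q: float = 0.0
    interval: Optional[dict] = None
    schema: str = "quantalkit/run-config/1"

    def synapse_params(self) -> SynapseParams:
        return SynapseParams(M=self.M, p1=self.p1, pr=self.pr, pd=self.pd, pu=self.pu)

    def quantal_model(self) -> Optional[QuantalSizeModel]:
        if self.c_mean is None:
            return None
        return QuantalSizeModel(c_mean=self.c_mean, cv_q=self.cv_q)

    def interval_model(self) -> Optional[IntervalModel]:
        if self.interval is None:
            return None
        return IntervalModel(**self.interval)

    def validate(self) -> "RunConfig":
        self.synapse_params()
        self.quantal_model()
        self.interval_model()
        if self.n_stimuli < 1:
            raise ValueError("n_stimuli must be >= 1")
        if self.seed is None:
            raise ValueError("an explicit seed is required")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.schema != cls.schema:
            raise ValueError(
                f"{path}: unsupported schema {cfg.schema!r}"
            )
        return cfg.validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
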