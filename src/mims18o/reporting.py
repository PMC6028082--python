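"""Trace I/O, run reports, and small auxiliary statistics.

Traces travel as plain CSV with header ``time_s,alpha18_co2`` (no community
standard exists for membrane-inlet MS progress curves); extra columns are
tolerated and preserved in the trace metadata.  Pipeline runs are summarised
in a :class:`PipelineReport` that serializes losslessly to JSON so a run can
be reproduced bit-for-bit from its own record.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .exchange import Trace

__all__ = [
    "PipelineReport",
    "tumor_volume",
    "compare_groups",
    "GroupComparison",
    "read_trace",
    "write_trace",
]

TRACE_COLUMNS = ("time_s", "alpha18_co2")


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Ellipsoid-approximation xenograft tumor volume, 0.5 * L * W^2 (mm^3).

    Length is the longer caliper measurement; if width exceeds length the
    arguments are swapped with a warning rather than silently producing an
    inflated volume.
    """
    if length_mm < 0 or width_mm < 0:
        raise ValueError("caliper measurements must be non-negative")
    if width_mm > length_mm:
        warnings.warn(
            "width exceeds length; swapping arguments", UserWarning, stacklevel=2
        )
        length_mm, width_mm = width_mm, length_mm
    return 0.5 * length_mm * width_mm**2


@dataclass(frozen=True)
class GroupComparison:
    t_statistic: float
    p_value: float
    significant: bool
    n_a: int
    n_b: int
    equal_var: bool


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    equal_var: bool = True,
    alpha: float = 0.05,
) -> GroupComparison:
    """Two-sample Student's t test, two-tailed.

    Equal-variance form by default (Welch behind ``equal_var=False``).  Two
    zero-variance groups with equal means return t = 0, p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return GroupComparison(0.0, 1.0, False, len(a), len(b), equal_var)
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(
        t_statistic=float(t),
        p_value=float(p),
        significant=bool(p < alpha),
        n_a=len(a),
        n_b=len(b),
        equal_var=equal_var,
    )


def write_trace(trace: Trace, path: Union[str, Path]) -> None:
    """Write a trace as CSV (``time_s,alpha18_co2``), 12 significant digits."""
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.times, "alpha18_co2": trace.alpha})
    df.to_csv(path, index=False, float_format="%.12g")


def read_trace(path: Union[str, Path]) -> Trace:
    """Read a trace CSV, validating values and naming offending lines.

    The first two columns must be ``time_s`` and ``alpha18_co2``; extra
    columns are kept in ``trace.metadata["extra_columns"]``.  Non-monotone
    times and atom fractions outside [0, 1] are rejected with the 1-based
    file line number (header is line 1).
    """
    path = Path(path)
    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols[:2] != list(TRACE_COLUMNS):
        raise ValueError(
            f"{path}: expected header starting with "
            f"{','.join(TRACE_COLUMNS)!r}, found {','.join(cols)!r}"
        )
    times = df["time_s"].to_numpy(dtype=float)
    alpha = df["alpha18_co2"].to_numpy(dtype=float)
    for i, a in enumerate(alpha):
        if not (0.0 <= a <= 1.0) or math.isnan(a):
            raise ValueError(
                f"{path}, line {i + 2}: atom fraction {a} outside [0, 1]"
            )
    bad = np.nonzero(np.diff(times) <= 0)[0]
    if len(bad):
        raise ValueError(
            f"{path}, line {bad[0] + 3}: time {times[bad[0] + 1]} does not "
            f"increase past {times[bad[0]]}"
        )
    metadata = {"source": str(path)}
    extras = cols[2:]
    if extras:
        metadata["extra_columns"] = {c: df[c].tolist() for c in extras}
    return Trace(times=times, alpha=alpha, metadata=metadata)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


@dataclass
class PipelineReport:
    """Self-describing record of one pipeline run."""

    inputs: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)
    provenance: list = field(default_factory=list)
    version: str = __version__

    def add_stage(self, name: str, result) -> None:
        self.stages[name] = _jsonable(result)

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        payload = json.dumps(_jsonable(dataclasses.asdict(self)), indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "PipelineReport":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        raw = json.loads(text)
        return cls(
            inputs=raw.get("inputs", {}),
            stages=raw.get("stages", {}),
            provenance=raw.get("provenance", []),
            version=raw.get("version", __version__),
        )
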