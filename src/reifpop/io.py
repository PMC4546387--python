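"""Plain-text readers and writers for traces, parameters and cohorts.

Traces are CSV with a header row ``t_ms,I_pA,V_mV`` (either channel may be
absent) preceded by optional ``# key=value`` metadata lines (``dt_ms`` and
``seed`` among them).  The time column must be uniform; voltages round-trip
to 1e-4 mV.  Parameter sets and cohorts are JSON carrying the
``reif_params_v1`` schema version.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core_model import EIFParams, PARAMS_VERSION, rEIFParams
from .simulator import Trace

__all__ = [
    "read_trace",
    "write_trace",
    "read_params",
    "write_params",
    "read_cohort",
    "write_cohort",
    "TraceFormatError",
]

COHORT_VERSION = "reif_cohort_v1"


class TraceFormatError(ValueError):
    """A trace file violates the columnar text format."""


def write_trace(trace: Trace, path: Union[str, Path]) -> None:
    """Write a trace as '#'-prefixed metadata plus CSV columns."""
    path = Path(path)
    n = len(trace)
    # per-column precision: absolute for t (uniform grid) and V (1e-4 mV
    # round-trip contract), significant digits for I
    cols = {
        "t_ms": pd.Series(np.arange(n) * trace.dt).map("{:.6f}".format)
    }
    if trace.I is not None:
        cols["I_pA"] = pd.Series(trace.I).map("{:.6g}".format)
    if trace.V is not None:
        cols["V_mV"] = pd.Series(trace.V).map("{:.4f}".format)
    with path.open("w") as fh:
        fh.write(f"# dt_ms={trace.dt!r}\n")
        for k, v in trace.metadata.items():
            if isinstance(v, (str, int, float, bool)):
                fh.write(f"# {k}={v}\n")
        pd.DataFrame(cols).to_csv(fh, index=False)


def read_trace(path: Union[str, Path]) -> Trace:
    """Read a trace file; validates header and time-base uniformity."""
    path = Path(path)
    meta: dict = {}
    with path.open() as fh:
        pos = fh.tell()
        for line in iter(fh.readline, ""):
            if not line.startswith("#"):
                fh.seek(pos)
                break
            body = line[1:].strip()
            if "=" in body:
                k, _, v = body.partition("=")
                meta[k.strip()] = v.strip()
            pos = fh.tell()
        df = pd.read_csv(fh)
    if "t_ms" not in df.columns:
        raise TraceFormatError(f"{path}: missing required column 't_ms'")
    known = {"t_ms", "I_pA", "V_mV"}
    unknown = set(df.columns) - known
    if unknown:
        raise TraceFormatError(
            f"{path}: unrecognised columns {sorted(unknown)} "
            "(expected t_ms, I_pA, V_mV; units are part of the name)"
        )
    if "I_pA" not in df.columns and "V_mV" not in df.columns:
        raise TraceFormatError(f"{path}: need at least one of I_pA, V_mV")
    t = df["t_ms"].to_numpy(dtype=float)
    if len(t) < 2:
        raise TraceFormatError(f"{path}: need at least two samples")
    dt_col = np.diff(t)
    dt = float(meta["dt_ms"]) if "dt_ms" in meta else float(np.median(dt_col))
    bad = np.nonzero(np.abs(dt_col - dt) > 1e-6 * max(dt, 1.0))[0]
    if bad.size:
        raise TraceFormatError(
            f"{path}: non-uniform time base at data line {bad[0] + 2} "
            f"(dt {dt_col[bad[0]]:.9g} vs declared {dt:.9g})"
        )
    metadata = {k: v for k, v in meta.items() if k != "dt_ms"}
    return Trace(
        dt=dt,
        I=df["I_pA"].to_numpy(dtype=float) if "I_pA" in df.columns else None,
        V=df["V_mV"].to_numpy(dtype=float) if "V_mV" in df.columns else None,
        metadata=metadata,
    )


def write_params(params: Union[EIFParams, rEIFParams], path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=2) + "\n")


def read_params(path: Union[str, Path]) -> Union[EIFParams, rEIFParams]:
    d = json.loads(Path(path).read_text())
    if d.get("version") != PARAMS_VERSION:
        raise ValueError(f"{path}: unsupported parameter schema {d.get('version')!r}")
    if "g1" in d:
        return rEIFParams.from_dict(d)
    return EIFParams.from_dict(d)


def write_cohort(
    cells: list,
    path: Union[str, Path],
    class_name: str = "",
    seed: Optional[int] = None,
) -> None:
    """Write a generated cohort (EIF or rEIF parameter sets) as JSON."""
    payload = {
        "version": COHORT_VERSION,
        "class_name": class_name,
        "seed": seed,
        "cells": [c.to_dict() for c in cells],
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_cohort(path: Union[str, Path]) -> list:
    d = json.loads(Path(path).read_text())
    if d.get("version") != COHORT_VERSION:
        raise ValueError(f"{path}: unsupported cohort schema {d.get('version')!r}")
    out = []
    for cd in d["cells"]:
        if cd.get("version") != PARAMS_VERSION:
            raise ValueError(f"{path}: cell with bad schema version")
        out.append(rEIFParams.from_dict(cd) if "g1" in cd else EIFParams.from_dict(cd))
    return out
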