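"""Result serialisation: CSV time series (lossless round-trip) and JSON summaries.

The time-series CSV has one header row and a fixed column order::

    t, g_level_true, mmse, p_H1..p_Hm, tilt_true, tilt_perceived,
    a_true_{x,y,z}, a_perceived_{x,y,z}, omega_true_{x,y,z},
    omega_perceived_{x,y,z}

Floats are written at full (repr) precision.  Metadata, the hypothesis grid
and the summary record travel in ``#``-prefixed JSON comment lines before the
header, so a written file reads back into a field-identical
:class:`~vestadapt.simulate.SimResult`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import SimResult


def _columns(m: int) -> list[str]:
    cols = ["t", "g_level_true", "mmse"]
    cols += [f"p_H{j + 1}" for j in range(m)]
    cols += ["tilt_true", "tilt_perceived"]
    for name in ("a_true", "a_perceived", "omega_true", "omega_perceived"):
        cols += [f"{name}_{ax}" for ax in "xyz"]
    return cols


def write_timeseries(result: SimResult, path: str | Path) -> Path:
    """Write the per-step record to CSV (full float precision)."""
    path = Path(path)
    m = len(result.hypotheses)
    data = np.column_stack(
        [
            result.t,
            result.g_level_true,
            result.mmse,
            result.posterior,
            result.tilt_true,
            result.tilt_perceived,
            result.a_true,
            result.a_perceived,
            result.omega_true,
            result.omega_perceived,
        ]
    ) if len(result.t) else np.empty((0, 3 + m + 2 + 12))
    frame = pd.DataFrame(data, columns=_columns(m))
    header_meta = {
        "metadata": result.metadata,
        "hypotheses": [float(h) for h in result.hypotheses],
        "summary": result.summary,
    }
    with path.open("w") as fh:
        fh.write("# " + json.dumps(header_meta, sort_keys=True) + "\n")
        frame.to_csv(fh, index=False, float_format="%.17g")
    return path


def read_timeseries(path: str | Path) -> SimResult:
    """Read a CSV written by :func:`write_timeseries` back into a SimResult."""
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        if not first.startswith("# "):
            raise ValueError(f"{path}: missing metadata header line")
        meta = json.loads(first[2:])
        frame = pd.read_csv(fh, float_precision="round_trip")
    hypotheses = np.asarray(meta["hypotheses"], dtype=float)
    m = len(hypotheses)
    expected = _columns(m)
    if list(frame.columns) != expected:
        raise ValueError(f"{path}: unexpected column layout")
    get = lambda names: frame[names].to_numpy(dtype=float)
    return SimResult(
        metadata=meta["metadata"],
        t=get(["t"])[:, 0],
        g_level_true=get(["g_level_true"])[:, 0],
        mmse=get(["mmse"])[:, 0],
        posterior=get([f"p_H{j + 1}" for j in range(m)]),
        hypotheses=hypotheses,
        tilt_true=get(["tilt_true"])[:, 0],
        tilt_perceived=get(["tilt_perceived"])[:, 0],
        a_true=get([f"a_true_{ax}" for ax in "xyz"]),
        a_perceived=get([f"a_perceived_{ax}" for ax in "xyz"]),
        omega_true=get([f"omega_true_{ax}" for ax in "xyz"]),
        omega_perceived=get([f"omega_perceived_{ax}" for ax in "xyz"]),
        summary=meta["summary"],
    )


def write_summary(result: SimResult, path: str | Path) -> Path:
    """Write the flat summary-metrics record as JSON."""
    import math

    path = Path(path)
    payload = dict(result.summary)
    payload["config_hash"] = result.metadata.get("config_hash")
    clean = {
        k: ("inf" if isinstance(v, float) and math.isinf(v) else v) for k, v in payload.items()
    }
    path.write_text(json.dumps(clean, indent=2, sort_keys=True, default=_json_default) + "\n")
    return path


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {obj!r}")
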