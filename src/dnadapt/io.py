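"""Plain-text file contracts shared by the pipeline stages.

Condition-response sets, voltage recordings and model predictions are
written as tab-separated tables with a small ``# key=value`` header
(sampling rate, onset, units); parameters and fit results are flat JSON.
All sample indices are 0-based; windows are given in seconds.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .dn_model import CategoryScaling, DNParams
from .model_fitting import ConditionResponseSet
from .broadband import VoltageRecording

__all__ = [
    "write_responses", "read_responses", "write_voltage", "read_voltage",
    "write_params", "read_params", "write_matrix", "read_matrix",
]


def _write_header(fh, meta: dict) -> None:
    for k, v in meta.items():
        fh.write(f"# {k}={v}\n")


def _read_header(path: Path) -> dict:
    meta = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            k, _, v = line[1:].strip().partition("=")
            meta[k.strip()] = v.strip()
    return meta


def write_responses(data: ConditionResponseSet, path: str | Path) -> None:
    """One row per condition: kind, level, category, then samples."""
    path = Path(path)
    rows = []
    for (kind, level, cat), tc in sorted(data.responses.items()):
        rows.append({"kind": kind, "level": level, "category": cat,
                     **{f"s{i}": v for i, v in enumerate(tc)}})
    df = pd.DataFrame(rows)
    with path.open("w") as fh:
        _write_header(fh, {"fs": data.fs, "onset_s": data.onset_s,
                           "electrode_id": data.electrode_id,
                           "area": data.area or ""})
        df.to_csv(fh, sep="\t", index=False)


def read_responses(path: str | Path) -> ConditionResponseSet:
    path = Path(path)
    meta = _read_header(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    sample_cols = [c for c in df.columns if c.startswith("s")
                   and c[1:].isdigit()]
    sample_cols.sort(key=lambda c: int(c[1:]))
    responses = {}
    for _, row in df.iterrows():
        key = (row["kind"], int(row["level"]), row["category"])
        responses[key] = row[sample_cols].to_numpy(dtype=float)
    return ConditionResponseSet(
        fs=float(meta["fs"]), onset_s=float(meta["onset_s"]),
        responses=responses, electrode_id=meta.get("electrode_id", "e0"),
        area=meta.get("area") or None)


def write_voltage(rec: VoltageRecording, path: str | Path) -> None:
    """Channels x samples matrix with fs header and group sidecar column."""
    path = Path(path)
    with path.open("w") as fh:
        _write_header(fh, {"fs": rec.fs})
        df = pd.DataFrame(rec.data)
        df.insert(0, "group", list(rec.groups))
        df.to_csv(fh, sep="\t", index=False)


def read_voltage(path: str | Path) -> VoltageRecording:
    path = Path(path)
    meta = _read_header(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    groups = df.pop("group").tolist()
    return VoltageRecording(float(meta["fs"]), df.to_numpy(dtype=float),
                            groups)


def write_matrix(values: np.ndarray, fs: float, path: str | Path,
                 columns: Optional[list[str]] = None) -> None:
    """Time x condition matrix with an fs header line."""
    path = Path(path)
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    df = pd.DataFrame(arr.T, columns=columns)
    with path.open("w") as fh:
        _write_header(fh, {"fs": fs})
        df.to_csv(fh, sep="\t", index=False)


def read_matrix(path: str | Path) -> tuple[np.ndarray, float]:
    path = Path(path)
    meta = _read_header(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    return df.to_numpy(dtype=float).T, float(meta["fs"])


def write_params(params: DNParams, path: str | Path,
                 scalings: Optional[CategoryScaling] = None,
                 extra: Optional[dict] = None) -> None:
    """Flat JSON: {tau1, tau2, n, sigma, shift, scale, sf_bodies, ...}."""
    d = params.to_dict()
    if scalings is not None:
        d.update({f"sf_{c}": scalings[c] for c in scalings.sf})
    if extra:
        d.update(extra)
    Path(path).write_text(json.dumps(d, indent=2))


def read_params(path: str | Path
                ) -> tuple[DNParams, Optional[CategoryScaling]]:
    d = json.loads(Path(path).read_text())
    params = DNParams(**{k: d[k] for k in
                         ("tau1", "tau2", "n", "sigma", "shift", "scale")})
    sf = {k[3:]: v for k, v in d.items() if k.startswith("sf_")}
    return params, (CategoryScaling(sf) if sf else None)
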