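"""Readers and writers for the tabular artifacts.

Count matrices are features-by-samples tables (first column = feature
identifier) in TSV (native) or CSV.  Output files carry a provenance
header as ``#`` comment lines (tool version, configuration hash, seed)
so that re-runs with identical configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .params import BNBParams, BZINBParams

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_count_pair",
    "write_count_pair",
    "read_params_json",
    "write_params_json",
    "provenance_header",
]

ORIENTATIONS = ("features_by_samples", "samples_by_features")


def _sep_for(path: Path, text: str) -> str:
    if path.suffix.lower() == ".csv":
        return ","
    if path.suffix.lower() in (".tsv", ".tab", ".txt"):
        return "\t"
    return "\t" if "\t" in text.splitlines()[0] else ","


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    body = "\n".join(
        ln for ln in path.read_text().splitlines() if not ln.startswith("#")
    )
    if not body.strip():
        raise ValueError(f"{path}: file is empty")
    from io import StringIO

    try:
        return pd.read_csv(StringIO(body), sep=_sep_for(path, body), index_col=0)
    except Exception as exc:  # surface file context
        raise ValueError(f"{path}: malformed table ({exc})") from exc


def read_count_matrix(path, orientation: str = "features_by_samples") -> pd.DataFrame:
    """Integer-validated count matrix; duplicate identifiers and
    non-integer cells are rejected with row/column context."""
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    df = _read_table(path)
    if orientation == "samples_by_features":
        df = df.T
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate feature identifier {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample identifier {dup!r}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = df.map(lambda v: not isinstance(v, (int, float, np.number)))
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric entry at feature {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    frac = arr != np.floor(arr)
    if frac.any() or (arr < 0).any():
        r, c = np.argwhere(frac | (arr < 0))[0]
        raise ValueError(
            f"{path}: entry {arr[r, c]!r} at feature {df.index[r]!r}, "
            f"sample {df.columns[c]!r} is not a non-negative integer"
        )
    return df.astype(np.int64)


def provenance_header(seed: Optional[int] = None, config: Optional[dict] = None) -> str:
    cfg = json.dumps(config or {}, sort_keys=True)
    digest = hashlib.sha256(cfg.encode()).hexdigest()[:12]
    lines = [f"# bzinbnet v{__version__}", f"# config_hash={digest}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    return "\n".join(lines) + "\n"


def write_count_matrix(df: pd.DataFrame, path, seed=None, config=None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(provenance_header(seed, config))
        df.to_csv(fh, sep="\t")


def write_count_pair(y1, y2, path, seed=None, config=None,
                     names=("y1", "y2")) -> None:
    df = pd.DataFrame({names[0]: y1, names[1]: y2})
    df.index.name = "sample"
    write_count_matrix(df, path, seed=seed, config=config)


def read_count_pair(path):
    df = _read_table(Path(path))
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected exactly two count columns")
    return df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy()


def write_params_json(params, path, extra: Optional[dict] = None) -> None:
    d = params.to_dict() if hasattr(params, "to_dict") else dict(params)
    if extra:
        d.update(extra)
    Path(path).write_text(json.dumps(d, indent=1, sort_keys=True) + "\n")


def read_params_json(path):
    d = json.loads(Path(path).read_text())
    if "pi1" in d:
        return BZINBParams.from_dict(d)
    return BNBParams(d["alpha0"], d["alpha1"], d["alpha2"], d["beta1"], d["beta2"])
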