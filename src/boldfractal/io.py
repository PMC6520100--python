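"""NIfTI and table input/output with provenance headers."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


def config_hash(settings: dict) -> str:
    """Stable short hash of a settings mapping, recorded in every output."""
    payload = json.dumps(settings, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def save_volume(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Tab-separated table with ``# key: value`` header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="nan")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["nan"])


def write_matrix(weights: np.ndarray, path: str | Path, meta: dict | None = None) -> None:
    """Square weight matrix as delimited text, full double precision so the
    read/write round trip is bit-stable."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        np.savetxt(fh, weights, fmt="%.17g", delimiter="\t")


def read_matrix(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, comments="#", delimiter="\t")
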