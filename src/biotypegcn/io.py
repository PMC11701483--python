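"""Readers, writers, checksums and seed management.

All tables are comma-separated UTF-8 text with LF line endings and explicit
headers; matrices additionally ship in an ``.npz`` container that records
shape and dtype. Every writer emits a ``<file>.sha256`` sidecar and every
reader verifies it when present, so truncated or edited files fail loudly
rather than misparse.
"""

from __future__ import annotations

import hashlib
import json
import pathlib

import numpy as np
import pandas as pd
import yaml

from .exceptions import ChecksumError, DataShapeError
from .fnc import edge_names
from .synthetic import CohortSpec

#: Stage names in pipeline order; each stage draws its own child seed.
STAGES = (
    "simulate",
    "features",
    "graph",
    "fit",
    "evaluate",
    "project",
    "discriminate",
    "treat",
)


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage child seed: SeedSequence(global_seed, spawn_key=stage index).

    Stages are therefore independently reproducible from the one global
    seed; returned values stay below 2**31.
    """
    if stage not in STAGES:
        raise DataShapeError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence(entropy=int(global_seed), spawn_key=(STAGES.index(stage),))
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: pathlib.Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_sidecar(path: pathlib.Path) -> None:
    path.with_name(path.name + ".sha256").write_text(_sha256(path) + "\n")


def _verify_sidecar(path: pathlib.Path) -> None:
    sidecar = path.with_name(path.name + ".sha256")
    if sidecar.exists():
        expected = sidecar.read_text().strip()
        actual = _sha256(path)
        if actual != expected:
            raise ChecksumError(f"{path} failed checksum verification")


def write_table(df: pd.DataFrame, path) -> pathlib.Path:
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # %.17g round-trips IEEE doubles exactly through text
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.17g")
    _write_sidecar(path)
    return path


def read_table(path, expected_columns=None) -> pd.DataFrame:
    path = pathlib.Path(path)
    _verify_sidecar(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if expected_columns is not None:
        missing = [c for c in expected_columns if c not in df.columns]
        if missing:
            raise DataShapeError(f"{path} missing columns {missing}")
        df = df[list(expected_columns)]  # realign by header names
    return df


def write_matrix(matrix: np.ndarray, path) -> pathlib.Path:
    """Binary container with shape and dtype metadata plus checksum sidecar."""
    path = pathlib.Path(path).with_suffix(".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix = np.asarray(matrix)
    np.savez(path, data=matrix, shape=np.asarray(matrix.shape), dtype=str(matrix.dtype))
    _write_sidecar(path)
    return path


def read_matrix(path) -> np.ndarray:
    path = pathlib.Path(path)
    _verify_sidecar(path)
    with np.load(path, allow_pickle=False) as z:
        data = z["data"]
        if tuple(z["shape"]) != data.shape:
            raise DataShapeError(f"{path}: shape metadata mismatch")
    return data


def write_fnc_table(fnc: np.ndarray, ids, path) -> pathlib.Path:
    """Subjects-by-edges feature table with canonical edge-name header."""
    fnc = np.asarray(fnc)
    c = int(round((1 + np.sqrt(1 + 8 * fnc.shape[1])) / 2))
    df = pd.DataFrame(fnc, columns=edge_names(c))
    df.insert(0, "id", list(ids))
    return write_table(df, path)


def read_fnc_table(path) -> tuple[list[str], np.ndarray]:
    df = read_table(path)
    ids = df["id"].astype(str).tolist()
    return ids, df.drop(columns="id").to_numpy(dtype=float)


def write_manifest(spec: CohortSpec, seed: int, path) -> pathlib.Path:
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"spec": spec.to_dict(), "seed": int(seed)}
    path.write_text(yaml.safe_dump(payload, sort_keys=True))
    _write_sidecar(path)
    return path


def read_manifest(path) -> dict:
    path = pathlib.Path(path)
    _verify_sidecar(path)
    return yaml.safe_load(path.read_text())


def write_edge_list(a: np.ndarray, path) -> pathlib.Path:
    """Weighted edge list (u, v, weight) for the population graph."""
    iu = np.triu_indices_from(a, k=1)
    nz = a[iu] > 0
    df = pd.DataFrame({"u": iu[0][nz], "v": iu[1][nz], "weight": a[iu][nz]})
    return write_table(df, path)


def read_edge_list(path, n_nodes: int) -> np.ndarray:
    df = read_table(path, expected_columns=("u", "v", "weight"))
    a = np.zeros((n_nodes, n_nodes))
    a[df["u"], df["v"]] = df["weight"]
    return a + a.T


def write_json(obj, path) -> pathlib.Path:
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, default=_jsonify) + "\n")
    _write_sidecar(path)
    return path


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
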