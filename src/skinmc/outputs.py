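"""Output writers: delimited-text matrices, JSON summaries, manifests.

Matrices are written as comma-separated text, one row per fixed z, one
column per y, with a header comment recording the cell size and origin so
the file is self-describing.  Every write_outputs call produces a
manifest listing the files with content hashes, which makes seeded reruns
verifiable byte-for-byte.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd


def get_logger(out_dir: Path | None = None, level: str = "INFO") -> logging.Logger:
    logger = logging.getLogger("skinmc")
    logger.setLevel(level.upper())
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        sh = logging.StreamHandler()
        sh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(sh)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        log_path = out_dir / "run.log"
        if not any(getattr(h, "baseFilename", None) == str(log_path)
                   for h in logger.handlers):
            fh = logging.FileHandler(log_path)
            fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
            logger.addHandler(fh)
    return logger


def write_matrix(path: Path, array: np.ndarray, meta: dict | None = None) -> None:
    header_lines = []
    for key, val in (meta or {}).items():
        header_lines.append(f"# {key}={val}")
    header_lines.append("# rows: fixed z (downward), columns: y")
    with open(path, "w") as fh:
        fh.write("\n".join(header_lines) + "\n")
        np.savetxt(fh, np.atleast_2d(array), fmt="%.8e", delimiter=",")


def read_matrix(path: Path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", comments="#")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(bundle: dict, out_dir) -> dict:
    """Write a result bundle and return the manifest.

    Bundle values are dispatched by type: ndarray -> CSV matrix (value may
    also be a (array, meta) tuple), DataFrame -> CSV table, dict -> JSON.
    """
    if not bundle:
        raise ValueError("empty result bundle")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, value in bundle.items():
        meta = None
        if isinstance(value, tuple) and len(value) == 2 and isinstance(value[0], np.ndarray):
            value, meta = value
        if isinstance(value, np.ndarray):
            path = out_dir / f"{name}.csv"
            write_matrix(path, value, meta)
        elif isinstance(value, pd.DataFrame):
            path = out_dir / f"{name}.csv"
            value.to_csv(path, index=False)
        elif isinstance(value, dict):
            path = out_dir / f"{name}.json"
            path.write_text(json.dumps(value, indent=2, sort_keys=True, default=float))
        elif isinstance(value, str):
            path = out_dir / name
            path.write_text(value)
        else:
            raise TypeError(f"cannot serialize bundle entry {name!r} of type {type(value)}")
        written.append(path)
    manifest = {p.name: {"sha256": _sha256(p), "bytes": p.stat().st_size} for p in written}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
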