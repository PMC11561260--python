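"""Small shared helpers: atomic writes, checksums, manifests, seed fan-out."""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from pathlib import Path
from typing import Any

import numpy as np


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def atomic_write_bytes(path: str | Path, data: bytes) -> None:
    """Write via a temp file in the same directory plus rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_text(path: str | Path, text: str) -> None:
    atomic_write_bytes(path, text.encode("utf-8"))


def write_manifest(directory: str | Path, files: list[str | Path],
                   meta: dict[str, Any] | None = None,
                   name: str = "manifest.json") -> Path:
    """Record paths, sizes and checksums of the files a run produced."""
    directory = Path(directory)
    entries = {}
    for f in files:
        f = Path(f)
        entries[f.name] = {
            "path": str(f),
            "bytes": f.stat().st_size,
            "sha256": sha256_file(f),
        }
    payload = {"files": entries, "meta": meta or {}}
    out = directory / name
    atomic_write_text(out, json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
    return out


def derive_seed(global_seed: int, stage: str) -> int:
    """Fan a global seed out to a per-stage seed (< 2**31).

    Each pipeline stage gets an independent, reproducible stream keyed by its
    name, so a stage can be rerun in isolation with the same randomness.
    """
    stage_key = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
    ss = np.random.SeedSequence(entropy=int(global_seed), spawn_key=(stage_key,))
    return int(ss.generate_state(1)[0] % (2 ** 31))
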