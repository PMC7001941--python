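"""Run manifests: enough metadata to reproduce a run bit-exactly."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

__all__ = ["write_manifest", "sha256_file"]


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_manifest(out_dir, config, seed, outputs, started, command: str) -> Path:
    """Write ``manifest.json`` atomically (write then rename) into
    ``out_dir``, inventorying the produced files with SHA-256 checksums."""
    from . import __version__

    out_dir = Path(out_dir)
    manifest = {
        "command": command,
        "software_version": __version__,
        "seed": seed,
        "config": _jsonable(config),
        "started": started,
        "finished": datetime.now(timezone.utc).isoformat(),
        "outputs": {
            str(Path(p).name): sha256_file(p) for p in outputs if Path(p).exists()
        },
    }
    tmp = out_dir / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    final = out_dir / "manifest.json"
    tmp.replace(final)
    return final
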