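"""Run manifests: enough metadata to re-execute a run bit-identically."""

from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_path: str | Path,
    command: str,
    parameters: dict,
    input_paths: dict[str, str | Path] | None = None,
) -> dict:
    """Write a JSON manifest recording command, parameters (including all
    seeds), input digests, library version, and a timestamp."""
    from . import __version__

    inputs = {
        name: {"path": str(p), "sha256": _sha256(Path(p))}
        for name, p in (input_paths or {}).items()
    }
    manifest = {
        "command": command,
        "parameters": parameters,
        "inputs": inputs,
        "clue_version": __version__,
        "python": platform.python_version(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    out_path = Path(out_path)
    out_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
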