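"""Run manifests: a reproducibility record written next to every result."""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def input_hashes(inputs: dict[str, str | Path]) -> dict[str, str]:
    """Content hashes of input files; directories hash their sorted files."""
    out: dict[str, str] = {}
    for name, p in inputs.items():
        p = Path(p)
        if p.is_dir():
            h = hashlib.sha256()
            for f in sorted(p.rglob("*")):
                if f.is_file():
                    h.update(f.name.encode())
                    h.update(_sha256_file(f).encode())
            out[name] = h.hexdigest()
        elif p.is_file():
            out[name] = _sha256_file(p)
    return out


def write_manifest(
    out_dir: str | Path,
    command: str,
    config: dict,
    inputs: dict[str, str | Path] | None = None,
    filename: str = "run_manifest.json",
) -> Path:
    """Write a manifest capturing the command, config snapshot, and inputs.

    Results stay byte-stable across reruns; only the manifest carries the
    timestamp.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "toolkit": "simfish",
        "version": __version__,
        "command": command,
        "config": config,
        "inputs": input_hashes(inputs or {}),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / filename
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
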