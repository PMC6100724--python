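"""Run provenance: command line, config snapshot, input checksums, seed."""

from __future__ import annotations

import hashlib
import json
import sys
from datetime import datetime, timezone
from pathlib import Path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(out_dir: str | Path, params: dict,
                     inputs: list[str | Path] = (), seed: int | None = None) -> Path:
    """Write the single provenance record for an output directory."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "command": sys.argv,
        "params": {k: str(v) if isinstance(v, Path) else v for k, v in params.items()},
        "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).is_file()},
        "seed": seed,
        "version": __version__,
        "python": sys.version.split()[0],
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(record, indent=2) + "\n")
    return path
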