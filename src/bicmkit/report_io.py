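"""Serialization of result objects to JSON and flat TSV.

Every result type in the package exposes ``to_dict()``; the writer wraps
that payload with provenance metadata (package version, optional input
checksum and seed) and emits either nested JSON or a flattened TSV with one
``key<TAB>value`` row per scalar leaf.  JSON reports round-trip through
:func:`read_report`.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Any

__all__ = ["write_report", "read_report", "file_checksum"]


def file_checksum(path: str | Path) -> str:
    """SHA-256 hex digest of a file's bytes."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj: Any) -> Any:
    import numpy as np

    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        obj = float(obj)
    if isinstance(obj, float):
        if math.isnan(obj):
            return None
        if math.isinf(obj):
            return "inf" if obj > 0 else "-inf"
    return obj


def _flatten(obj: Any, prefix: str = "") -> list[tuple[str, Any]]:
    if isinstance(obj, dict):
        out: list[tuple[str, Any]] = []
        for k, v in obj.items():
            key = f"{prefix}.{k}" if prefix else str(k)
            out.extend(_flatten(v, key))
        return out
    if isinstance(obj, list):
        out = []
        for i, v in enumerate(obj):
            out.extend(_flatten(v, f"{prefix}[{i}]"))
        return out
    return [(prefix, obj)]


def write_report(
    obj: Any,
    path: str | Path,
    fmt: str = "json",
    *,
    input_checksum: str | None = None,
    seed: int | None = None,
) -> None:
    """Serialize a result object (anything with ``to_dict``) to disk.

    Floating values are written at full ``repr`` precision; JSON output is
    nested under a ``"result"`` key next to provenance metadata, TSV output
    is a flat two-column table.
    """
    from bicmkit import __version__

    if hasattr(obj, "to_dict"):
        payload = obj.to_dict()
    elif isinstance(obj, dict):
        payload = obj
    else:
        raise TypeError(
            f"cannot serialize object of type {type(obj).__name__}: "
            "expected a package result type or a dict"
        )
    meta: dict[str, Any] = {
        "package": "bicmkit",
        "version": __version__,
        "type": type(obj).__name__,
    }
    if input_checksum is not None:
        meta["input_checksum"] = input_checksum
    if seed is not None:
        meta["seed"] = seed
    document = {"meta": meta, "result": _jsonable(payload)}
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(document, indent=2) + "\n")
    elif fmt == "tsv":
        lines = ["key\tvalue"]
        for key, value in _flatten(document):
            lines.append(f"{key}\t{value!r}" if isinstance(value, str) else f"{key}\t{value}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def read_report(path: str | Path) -> dict:
    """Load a JSON report written by :func:`write_report`."""
    with open(path) as fh:
        return json.load(fh)
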