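"""Small shared helpers: canonical JSON, hashing, deterministic seeds."""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from typing import Any


def parse_date(value: Any) -> dt.date:
    """Coerce an ISO-8601 string (or date) to a ``datetime.date``."""
    if isinstance(value, dt.date) and not isinstance(value, dt.datetime):
        return value
    return dt.date.fromisoformat(str(value).strip())


def canonical_json(obj: Any) -> str:
    """Deterministic JSON: sorted keys, compact separators, UTF-8 safe."""
    return json.dumps(obj, sort_keys=True, separators=(",", ":"), ensure_ascii=False)


def sha256_hex(data: bytes | str) -> str:
    if isinstance(data, str):
        data = data.encode("utf-8")
    return hashlib.sha256(data).hexdigest()


def stable_seed(*parts: Any) -> int:
    """Derive a reproducible 31-bit seed from arbitrary labelled parts.

    Avoids Python's randomized ``hash``; the same parts always give the
    same seed on every platform and run.
    """
    digest = hashlib.sha256("|".join(str(p) for p in parts).encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
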