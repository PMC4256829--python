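"""Small shared helpers."""

from __future__ import annotations

import hashlib
from decimal import ROUND_HALF_UP, Decimal


def round_half_away(value: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (unlike Python's banker's round)."""
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP) if value >= 0 \
        else -((-Decimal(repr(value))).quantize(q, rounding=ROUND_HALF_UP))
    return float(d)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
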