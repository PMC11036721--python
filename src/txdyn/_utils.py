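"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero, as printed tables conventionally do.

    Python's built-in round() is banker's rounding; reported percentages here
    follow the half-up convention (e.g. 0.125 -> 0.13 at 2 digits).
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


PATTERN_ALPHABET = frozenset("UDM")


def validate_pattern(pattern: str, k: int, name: str = "pattern") -> None:
    """Raise ValueError unless *pattern* is a length-k string over {U, D, M}."""
    if len(pattern) != k:
        raise ValueError(f"{name}: expected length {k}, got {len(pattern)} ({pattern!r})")
    bad = set(pattern) - PATTERN_ALPHABET
    if bad:
        raise ValueError(f"{name}: illegal symbols {sorted(bad)} in {pattern!r}; alphabet is U/D/M")
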