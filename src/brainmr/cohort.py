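"""Sample-characteristics arithmetic for cohort description tables."""

from __future__ import annotations

__all__ = ["percent"]


def percent(count: int, total: int, ndigits: int = 1) -> float:
    """``count`` as a percentage of ``total``, rounded for table display."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    return round(100.0 * count / total, ndigits)
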