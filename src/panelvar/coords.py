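"""Coordinate-frame conversions.

VCF and GFF3 use 1-based inclusive coordinates; bedGraph, BED and BEDPE use
0-based half-open intervals. Every transform between the two frames in this
package goes through these four functions so the convention lives in one place.
"""


def one_to_zero(pos: int) -> int:
    """1-based position -> 0-based index."""
    return pos - 1


def zero_to_one(idx: int) -> int:
    """0-based index -> 1-based position."""
    return idx + 1


def interval_one_to_zero(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive interval -> 0-based half-open."""
    return start - 1, end


def interval_zero_to_one(start: int, end: int) -> tuple[int, int]:
    """0-based half-open interval -> 1-based inclusive."""
    return start + 1, end
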