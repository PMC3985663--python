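"""Converters between genomic and L1-internal coordinates.

Genomic positions are 0-based; L1-internal positions are 1-based on the
sense strand of the element, so that position 1 is the first base of the
5' UTR regardless of which genomic strand the integrant occupies.

For a plus-strand integrant at ``[start, end)``::

    l1_coord = genomic_pos - start + 1
    genomic_pos = start + l1_coord - 1

For a minus-strand integrant the element's sense strand reads right to
left on the genome::

    l1_coord = end - genomic_pos
    genomic_pos = end - l1_coord
"""

from __future__ import annotations

from .models import L1Integrant


def genomic_to_l1(pos: int, l1: L1Integrant) -> int:
    """Map a 0-based genomic base position to a 1-based L1 sense coordinate."""
    if not (l1.start <= pos < l1.end):
        raise ValueError(f"position {pos} outside L1 {l1.l1_id} [{l1.start},{l1.end})")
    if l1.strand == "+":
        return pos - l1.start + 1
    return l1.end - pos


def l1_to_genomic(coord: int, l1: L1Integrant) -> int:
    """Map a 1-based L1 sense coordinate to a 0-based genomic base position."""
    if not (1 <= coord <= l1.length):
        raise ValueError(f"L1 coordinate {coord} outside [1,{l1.length}]")
    if l1.strand == "+":
        return l1.start + coord - 1
    return l1.end - coord
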