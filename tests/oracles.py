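"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own scanning/enumeration code
paths: the motif oracle expands every gap-length combination into a
concrete regular expression, and the CDN oracle canonicalizes by unordered
multiset of (base, donor) units.
"""

from collections import Counter
from itertools import product
import re


def regex_scan_oracle(sequence: str, pattern) -> set[tuple[tuple[int, int], ...]]:
    """All anchor placements via exhaustive regex enumeration."""
    elements = pattern.elements
    gap_ranges = [
        range(e.min_len, e.max_len + 1) for e in elements if e.kind == "gap"
    ]
    placements: set[tuple[tuple[int, int], ...]] = set()
    for combo in product(*gap_ranges):
        gaps = iter(combo)
        parts, anchor_offsets, total = [], [], 0
        for el in elements:
            if el.kind == "gap":
                length = next(gaps)
                parts.append(".{%d}" % length)
                total += length
            else:
                chars = (
                    el.residue if el.kind == "fixed" else "".join(sorted(el.members))
                )
                parts.append("[" + re.escape(chars) + "]")
                anchor_offsets.append(total)
                total += 1
        rx = re.compile("".join(parts))
        for start in range(len(sequence) - total + 1):
            if rx.fullmatch(sequence, start, start + total):
                placements.add(
                    tuple((start + o, start + o + 1) for o in anchor_offsets)
                )
    return placements


def cdn_enumeration_oracle(bases) -> set[frozenset]:
    """Distinct cyclic dinucleotides as unordered unit multisets."""
    units = [(b, d) for b in bases for d in (2, 3)]
    return {
        frozenset(Counter((u, v)).items()) for u in units for v in units
    }
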