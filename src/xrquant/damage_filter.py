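"""Select reads bearing the excision-repair damage signature.

The dual incision of nucleotide excision repair releases the lesion inside
the excised oligomer at a stereotyped distance from the 3' cut: UV
photoproducts form at adjacent pyrimidines, so a genuine excision product
carries a pyrimidine dinucleotide close to its 3' terminus.  The filter
keeps reads with a dipyrimidine whose bases both lie between the 4th and
10th positions counted from the 3' end.

Offsets are 1-based from the 3' terminus (offset 1 = 3'-terminal base); the
verdict is computed on the read-oriented sequence, never the reference
slice, and depends only on the 3'-terminal window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import AlignedRead

PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class DipyrimidineWindow:
    """1-based 3'-offset window both dinucleotide bases must fall in."""

    lo_offset: int = 4
    hi_offset: int = 10

    def __post_init__(self) -> None:
        if not (1 <= self.lo_offset < self.hi_offset):
            raise ValueError(
                f"window requires 1 <= lo < hi, got "
                f"[{self.lo_offset},{self.hi_offset}]")


DEFAULT_WINDOW = DipyrimidineWindow()


def has_dipyrimidine_3prime(sequence: str,
                            window: DipyrimidineWindow = DEFAULT_WINDOW,
                            require_both: bool = True) -> bool:
    """True iff a pyrimidine dinucleotide sits in the 3'-end window.

    With ``require_both`` (default) both bases of the pair must lie at
    3'-offsets within [lo, hi]; the pair whose 3' base is at offset p then
    occupies offsets p and p+1, p in [lo, hi-1].  With
    ``require_both=False`` only the pair's 3' base must fall in the window
    (the alternative reading of "dipyrimidine between the 4th and 10th
    position").  Any N inside the window makes the verdict False.
    """
    n = len(sequence)
    if n < window.hi_offset:
        raise ValueError(
            f"sequence length {n} shorter than window hi offset "
            f"{window.hi_offset}")
    hi_pair = window.hi_offset - 1 if require_both else window.hi_offset
    for p in range(window.lo_offset, hi_pair + 1):
        # base at 3'-offset j is sequence[n - j]
        if sequence[n - p] in PYRIMIDINES and sequence[n - p - 1] in PYRIMIDINES:
            return True
    return False


def filter_damage(reads: Sequence[AlignedRead],
                  window: DipyrimidineWindow = DEFAULT_WINDOW,
                  require_both: bool = True,
                  ) -> tuple[list[AlignedRead], dict[str, int]]:
    """Keep exactly the reads whose sequence passes the dipyrimidine test."""
    kept = [r for r in reads
            if has_dipyrimidine_3prime(r.sequence, window, require_both)]
    return kept, {"kept": len(kept), "dropped": len(reads) - len(kept)}
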