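"""Kissing-loop complex detection.

Two hairpins whose unpaired loop bases are complementary can anneal into
an intramolecular kissing complex; in LA genomes a 4-bp loop-loop duplex
(5'-AAUU/3'-UUAA) links the 5'-extra stem loop to its canonical copy.
"""

from __future__ import annotations

from dataclasses import dataclass

from .energy import PAIRS
from .fold import to_rna

_WC = {"AU", "UA", "CG", "GC"}


@dataclass(frozen=True)
class KissingComplex:
    loop_a: str
    loop_b: str
    n_pairs: int
    offset_a: int  # 0-based start of the duplex within loop_a (5'->3')
    offset_b: int  # 0-based start within loop_b of the base pairing the duplex's last a-base

    def __post_init__(self) -> None:
        if self.n_pairs > min(len(self.loop_a), len(self.loop_b)):
            raise ValueError("more pairs than loop bases")

    @property
    def paired_offsets(self) -> tuple[tuple[int, int], ...]:
        """(pos_in_a, pos_in_b) for each annealed pair, antiparallel."""
        return tuple(
            (self.offset_a + k, self.offset_b + self.n_pairs - 1 - k)
            for k in range(self.n_pairs)
        )


def kissing_pairs(loop_a: str, loop_b: str, allow_gu: bool = False) -> KissingComplex:
    """Best contiguous antiparallel duplex between two loop sequences.

    Pairing is Watson-Crick (GU optional, off by default): base a[i] pairs
    b[j] with j descending as i ascends. Symmetric in its arguments.
    """
    a, b = to_rna(loop_a), to_rna(loop_b)
    if not a or not b:
        raise ValueError("both loops must be non-empty")
    ok = PAIRS if allow_gu else _WC
    best = (0, 0, 0)  # (n_pairs, start_a, start_b_of_last)
    # Antiparallel alignment: compare a against reversed b at every offset.
    br = b[::-1]
    for shift in range(-(len(br) - 1), len(a)):
        run, run_start = 0, None
        for i in range(len(a)):
            j = i - shift  # index into reversed b
            if 0 <= j < len(br) and a[i] + br[j] in ok:
                if run == 0:
                    run_start = i
                run += 1
                if run > best[0]:
                    jb = len(b) - 1 - (i - shift)  # original index in b of a[i]'s partner
                    best = (run, run_start, jb)
            else:
                run = 0
    n, sa, sb = best
    return KissingComplex(loop_a=a, loop_b=b, n_pairs=n, offset_a=sa, offset_b=sb)
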