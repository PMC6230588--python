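"""Recombination signal sequence (RSS) detection.

Every recombinable TRB gene element is flanked by a recombination signal:
a conserved heptamer, a spacer of 12 or 23 nucleotides, and a conserved
nonamer.  V genes carry a 23-spacer RSS 3' of the coding region, J genes a
12-spacer RSS 5' of it, and D genes both (12-spacer 5', 23-spacer 3').

Signals are scored as separate exact (Hamming) match counts of the heptamer
and nonamer against the consensus; no position-weight matrix is used.  The
consensus is written in the coding-flank convention: ``CACAGTG`` reading
away from the coding region.  On the opposite flank (5' of J and D genes)
the signal appears reverse-complemented on the forward strand, which is
what ``orientation="reverse"`` scans for.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, List

HEPTAMER = "CACAGTG"
NONAMER = "ACAAAAACC"

_COMP = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

VALID_SPACERS = (12, 23)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes tolerated)."""
    return seq.translate(_COMP)[::-1]


def _check_alphabet(seq: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in "ACGTNRYSWKMBDHV":
            raise ValueError(f"invalid nucleotide {ch!r} at position {i}")


def hamming_matches(window: str, consensus: str) -> int:
    """Number of positions of *window* identical to *consensus*."""
    return sum(1 for a, b in zip(window, consensus) if a == b)


@dataclass(frozen=True)
class RecombinationSignal:
    """A heptamer + spacer + nonamer hit on a contig.

    ``heptamer_start`` is the 0-based offset of the heptamer element on the
    forward strand of the contig (for reverse-orientation signals this is
    the start of the reverse-complemented heptamer 7-mer).
    """

    heptamer_start: int
    spacer_len: int
    heptamer_matches: int
    nonamer_matches: int
    orientation: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        if self.spacer_len not in VALID_SPACERS:
            raise ValueError(f"spacer_len must be 12 or 23, got {self.spacer_len}")
        if not (0 <= self.heptamer_matches <= 7):
            raise ValueError("heptamer_matches out of range 0-7")
        if not (0 <= self.nonamer_matches <= 9):
            raise ValueError("nonamer_matches out of range 0-9")

    @property
    def heptamer_end(self) -> int:
        return self.heptamer_start + 7

    @property
    def nonamer_start(self) -> int:
        if self.orientation == "forward":
            return self.heptamer_end + self.spacer_len
        return self.heptamer_start - self.spacer_len - 9

    @property
    def span(self) -> tuple:
        """Half-open interval covered by the whole signal on the contig."""
        if self.orientation == "forward":
            return (self.heptamer_start, self.heptamer_end + self.spacer_len + 9)
        return (self.nonamer_start, self.heptamer_end)

    @property
    def is_perfect(self) -> bool:
        return self.heptamer_matches == 7 and self.nonamer_matches == 9


def scan_rss(
    contig: str,
    spacer_len: int,
    min_heptamer_matches: int = 6,
    min_nonamer_matches: int = 7,
    orientation: str = "forward",
) -> List[RecombinationSignal]:
    """Exhaustively scan *contig* for recombination signals.

    Every window whose heptamer and nonamer Hamming match counts against the
    consensus reach the given minima is reported, sorted by position.

    ``orientation="forward"`` looks for ``HEPTAMER + spacer + NONAMER``
    (the 3'-flank layout); ``orientation="reverse"`` looks for
    ``revcomp(NONAMER) + spacer + revcomp(HEPTAMER)`` (the 5'-flank layout
    as it reads on the forward strand).
    """
    if spacer_len not in VALID_SPACERS:
        raise ValueError(f"spacer_len must be 12 or 23, got {spacer_len}")
    if orientation not in ("forward", "reverse"):
        raise ValueError(f"orientation must be 'forward' or 'reverse', got {orientation!r}")
    if not contig:
        raise ValueError("empty contig")
    contig = contig.upper()
    _check_alphabet(contig)
    total = 7 + spacer_len + 9
    if len(contig) < total:
        return []

    hits: List[RecombinationSignal] = []
    if orientation == "forward":
        for i in range(len(contig) - total + 1):
            hm = hamming_matches(contig[i : i + 7], HEPTAMER)
            if hm < min_heptamer_matches:
                continue
            j = i + 7 + spacer_len
            nm = hamming_matches(contig[j : j + 9], NONAMER)
            if nm >= min_nonamer_matches:
                hits.append(
                    RecombinationSignal(i, spacer_len, hm, nm, "forward")
                )
    else:
        rc_hept = revcomp(HEPTAMER)
        rc_nona = revcomp(NONAMER)
        for i in range(len(contig) - total + 1):
            # window: rc(nonamer) at i, spacer, rc(heptamer)
            nm = hamming_matches(contig[i : i + 9], rc_nona)
            if nm < min_nonamer_matches:
                continue
            h = i + 9 + spacer_len
            hm = hamming_matches(contig[h : h + 7], rc_hept)
            if hm >= min_heptamer_matches:
                hits.append(
                    RecombinationSignal(h, spacer_len, hm, nm, "reverse")
                )
    hits.sort(key=lambda s: s.heptamer_start)
    return hits


def scan_rss_with_tolerance(
    contig: str,
    spacer_len: int,
    tolerance: int = 0,
    min_heptamer_matches: int = 6,
    min_nonamer_matches: int = 7,
    orientation: str = "forward",
) -> List[tuple]:
    """Scan allowing the spacer to deviate by up to *tolerance* nt.

    Natural spacers occasionally run one base long or short; hits found at
    a non-canonical spacer are reported as raw tuples
    ``(heptamer_start, spacer_used, heptamer_matches, nonamer_matches,
    orientation)`` because :class:`RecombinationSignal` only admits the
    canonical 12/23 spacers.
    """
    out = []
    for delta in range(-tolerance, tolerance + 1):
        sp = spacer_len + delta
        if sp < 1:
            continue
        if sp in VALID_SPACERS:
            for h in scan_rss(contig, sp, min_heptamer_matches,
                              min_nonamer_matches, orientation):
                out.append((h.heptamer_start, sp, h.heptamer_matches,
                            h.nonamer_matches, orientation))
        else:
            out.extend(
                _scan_raw(contig, sp, min_heptamer_matches,
                          min_nonamer_matches, orientation)
            )
    out.sort()
    return out


def _scan_raw(contig: str, spacer: int, min_h: int, min_n: int,
              orientation: str) -> Iterator[tuple]:
    contig = contig.upper()
    total = 7 + spacer + 9
    if orientation == "forward":
        for i in range(max(0, len(contig) - total + 1)):
            hm = hamming_matches(contig[i : i + 7], HEPTAMER)
            nm = hamming_matches(contig[i + 7 + spacer : i + 16 + spacer], NONAMER)
            if hm >= min_h and nm >= min_n:
                yield (i, spacer, hm, nm, orientation)
    else:
        rc_h, rc_n = revcomp(HEPTAMER), revcomp(NONAMER)
        for i in range(max(0, len(contig) - total + 1)):
            nm = hamming_matches(contig[i : i + 9], rc_n)
            hm = hamming_matches(contig[i + 9 + spacer : i + 16 + spacer], rc_h)
            if hm >= min_h and nm >= min_n:
                yield (i + 9 + spacer, spacer, hm, nm, orientation)
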