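"""Frame/CDR assignment and canonical-position alignment for VH-like domains.

Two routes produce a :class:`RegionMap`:

* an imported numbering table (e.g. produced externally by an HMM-based
  numbering tool), where CDRs are the residues whose Chothia scheme numbers
  fall inside the configured boundary set; or
* an anchor-motif heuristic keyed on the two conserved cysteines, the
  CDR1-closing tryptophan and the C-terminal W-G-x-G motif.

Canonical alignment places every residue of a numberable sequence into a
fixed 126-slot layout, which with a 21-letter alphabet (20 amino acids + gap)
yields the 126 x 21 = 2,646-dimensional one-hot embedding used for
repertoire clustering.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

GAP = "-"
N_CANONICAL_POSITIONS = 126


class UnnumberableSequenceError(ValueError):
    """Anchor motifs not found and no numbering table supplied."""


@dataclass(frozen=True)
class RegionBoundaries:
    """Chothia heavy-chain CDR definitions plus heuristic anchor offsets.

    ``cdr1/cdr2/cdr3`` are inclusive scheme-number ranges (Chothia heavy
    chain: 26-32, 52-56, 95-102). The remaining fields parameterize the
    anchor heuristic used when no numbering table is available.
    """

    cdr1: tuple[int, int] = (26, 32)
    cdr2: tuple[int, int] = (52, 56)
    cdr3: tuple[int, int] = (95, 102)
    first_cys_window: tuple[int, int] = (15, 30)  # 0-based index window, inclusive
    cdr1_offset_from_cys: int = 4
    cdr2_offset_from_w: int = 19
    cdr2_length: int = 5
    cdr3_offset_from_cys: int = 3


DEFAULT_BOUNDARIES = RegionBoundaries()


@dataclass(frozen=True)
class RegionMap:
    """Half-open 0-based CDR intervals; the frame is their complement."""

    cdr1: tuple[int, int]
    cdr2: tuple[int, int]
    cdr3: tuple[int, int]

    def validate(self, n: int) -> None:
        ivs = [self.cdr1, self.cdr2, self.cdr3]
        prev_end = 0
        for name, (s, e) in zip(("cdr1", "cdr2", "cdr3"), ivs):
            if not (0 <= s < e <= n):
                raise ValueError(f"{name} interval {s, e} invalid for length {n}")
            if s < prev_end:
                raise ValueError(f"{name} overlaps or precedes the previous CDR")
            prev_end = e

    def frame_indices(self, n: int) -> list[int]:
        in_cdr = set()
        for s, e in (self.cdr1, self.cdr2, self.cdr3):
            in_cdr.update(range(s, e))
        return [i for i in range(n) if i not in in_cdr]

    def cdr_indices(self) -> dict[str, range]:
        return {"cdr1": range(*self.cdr1), "cdr2": range(*self.cdr2),
                "cdr3": range(*self.cdr3)}

    @property
    def cdr3_length(self) -> int:
        return self.cdr3[1] - self.cdr3[0]


# ---------------------------------------------------------------------------
# numbering tables

def read_numbering_table(text: str) -> list[tuple[int, int, str]]:
    """Parse a two-column table: residue index, scheme number (+ optional insertion letter).

    Returns a list of (residue_index, scheme_number, insertion_letter) sorted
    by residue index.
    """
    rows = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"numbering table line {lineno}: expected 2 columns")
        idx = int(parts[0])
        m = re.fullmatch(r"(\d+)([A-Za-z]?)", parts[1])
        if not m:
            raise ValueError(f"numbering table line {lineno}: bad scheme number {parts[1]!r}")
        rows.append((idx, int(m.group(1)), m.group(2).upper()))
    rows.sort()
    return rows


def _regions_from_table(sequence: str, numbering, boundaries: RegionBoundaries) -> RegionMap:
    scheme = {idx: num for idx, num, _ in numbering}
    intervals = []
    for lo, hi in (boundaries.cdr1, boundaries.cdr2, boundaries.cdr3):
        hits = [i for i in range(len(sequence)) if lo <= scheme.get(i, -1) <= hi]
        if not hits:
            raise UnnumberableSequenceError(
                f"no residues with scheme numbers in [{lo}, {hi}]")
        intervals.append((min(hits), max(hits) + 1))
    rm = RegionMap(*intervals)
    rm.validate(len(sequence))
    return rm


# ---------------------------------------------------------------------------
# anchor heuristic

def _regions_from_heuristic(sequence: str, boundaries: RegionBoundaries) -> RegionMap:
    b = boundaries
    n = len(sequence)
    lo, hi = b.first_cys_window
    cys1 = sequence.find("C", lo, hi + 1)
    if cys1 < 0:
        raise UnnumberableSequenceError(
            f"unnumberable sequence: no conserved Cys in positions {lo}-{hi}")
    c1s = cys1 + b.cdr1_offset_from_cys
    w1 = sequence.find("W", c1s + 1)
    if w1 < 0:
        raise UnnumberableSequenceError("unnumberable sequence: no CDR1-closing Trp")
    c1e = w1
    c2s = w1 + b.cdr2_offset_from_w
    c2e = c2s + b.cdr2_length
    if c2e >= n:
        raise UnnumberableSequenceError("unnumberable sequence: CDR2 window beyond chain end")
    cys2 = sequence.find("C", c2e)
    if cys2 < 0:
        raise UnnumberableSequenceError("unnumberable sequence: no second conserved Cys")
    c3s = cys2 + b.cdr3_offset_from_cys
    m = re.compile("WG.G").search(sequence, c3s + 1)
    if not m:
        raise UnnumberableSequenceError("unnumberable sequence: no C-terminal W-G-x-G motif")
    c3e = m.start()
    rm = RegionMap((c1s, c1e), (c2s, c2e), (c3s, c3e))
    rm.validate(n)
    return rm


def assign_regions(sequence: str, numbering=None,
                   boundaries: RegionBoundaries = DEFAULT_BOUNDARIES) -> RegionMap:
    """Assign CDR1-3 intervals (and implicitly the frame) to a sequence.

    With a numbering table the configured Chothia boundary set is looked up
    directly; otherwise the anchor-motif heuristic is used.
    """
    if not 70 <= len(sequence) <= 140:
        raise ValueError(f"sequence length {len(sequence)} outside [70, 140]")
    if numbering is not None:
        return _regions_from_table(sequence, numbering, boundaries)
    return _regions_from_heuristic(sequence, boundaries)


# ---------------------------------------------------------------------------
# canonical alignment

@dataclass(frozen=True)
class CanonicalLayout:
    """Slot capacities for the seven segments (frames and CDRs); sums to 126.

    Frame 1 is right-aligned in its block (N-terminal truncations are
    common); the other frame segments are left-aligned; CDRs fill from both
    ends toward the middle, mirroring how numbering schemes place loop
    insertions. Segment overflow is collapsed (dropped from the alignment,
    never from the model input) from the far edge of frames and from the
    middle of CDRs.
    """

    f1: int = 25
    cdr1: int = 9
    f2: int = 19
    cdr2: int = 8
    f3: int = 34
    cdr3: int = 16
    f4: int = 15

    def total(self) -> int:
        return self.f1 + self.cdr1 + self.f2 + self.cdr2 + self.f3 + self.cdr3 + self.f4


DEFAULT_LAYOUT = CanonicalLayout()
assert DEFAULT_LAYOUT.total() == N_CANONICAL_POSITIONS


@dataclass
class CanonicalAlignment:
    """A sequence placed onto the fixed canonical positions."""

    positions: list[str]                 # length 126; GAP where unoccupied
    source_sequence_map: list[int | None]  # canonical slot -> source index
    collapsed: list[int] = field(default_factory=list)  # source indices dropped

    def __post_init__(self) -> None:
        if len(self.positions) != N_CANONICAL_POSITIONS:
            raise ValueError("canonical alignment must have exactly 126 positions")

    def aligned_subsequence(self) -> str:
        return "".join(c for c in self.positions if c != GAP)


def _place_frame(indices: list[int], cap: int, right_align: bool) -> tuple[list[int | None], list[int]]:
    if len(indices) > cap:
        dropped = indices[:-cap] if right_align else indices[cap:]
        kept = indices[-cap:] if right_align else indices[:cap]
    else:
        dropped, kept = [], indices
    slots: list[int | None] = [None] * cap
    offset = cap - len(kept) if right_align else 0
    for j, src in enumerate(kept):
        slots[offset + j] = src
    return slots, dropped


def _place_cdr(indices: list[int], cap: int) -> tuple[list[int | None], list[int]]:
    if len(indices) > cap:
        n_front = (cap + 1) // 2
        n_back = cap - n_front
        dropped = indices[n_front:len(indices) - n_back]
        front, back = indices[:n_front], indices[len(indices) - n_back:]
    else:
        dropped = []
        n_front = (len(indices) + 1) // 2
        front, back = indices[:n_front], indices[n_front:]
    slots: list[int | None] = [None] * cap
    for j, src in enumerate(front):
        slots[j] = src
    for j, src in enumerate(reversed(back)):
        slots[cap - 1 - j] = src
    return slots, dropped


def canonical_align(sequence: str, numbering=None,
                    boundaries: RegionBoundaries = DEFAULT_BOUNDARIES,
                    layout: CanonicalLayout = DEFAULT_LAYOUT) -> CanonicalAlignment:
    """Place a numberable sequence onto the 126 canonical positions."""
    rm = assign_regions(sequence, numbering=numbering, boundaries=boundaries)
    n = len(sequence)
    segments = [
        (list(range(0, rm.cdr1[0])), layout.f1, "f1"),
        (list(range(*rm.cdr1)), layout.cdr1, "cdr1"),
        (list(range(rm.cdr1[1], rm.cdr2[0])), layout.f2, "f2"),
        (list(range(*rm.cdr2)), layout.cdr2, "cdr2"),
        (list(range(rm.cdr2[1], rm.cdr3[0])), layout.f3, "f3"),
        (list(range(*rm.cdr3)), layout.cdr3, "cdr3"),
        (list(range(rm.cdr3[1], n)), layout.f4, "f4"),
    ]
    source_map: list[int | None] = []
    collapsed: list[int] = []
    for indices, cap, name in segments:
        if name in ("cdr1", "cdr2", "cdr3"):
            slots, dropped = _place_cdr(indices, cap)
        else:
            slots, dropped = _place_frame(indices, cap, right_align=(name == "f1"))
        if dropped:
            logger.info("canonical_align: %d residues of %s collapsed out of the "
                        "alignment", len(dropped), name)
        source_map.extend(slots)
        collapsed.extend(dropped)
    positions = [sequence[i] if i is not None else GAP for i in source_map]
    return CanonicalAlignment(positions, source_map, collapsed)
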