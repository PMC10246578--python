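"""96-well plate layout with two-channel color balancing.

Two-channel Illumina instruments image each cycle in two channels: A lights
both, C lights channel 1, T lights channel 2, and G is dark.  A pooled set
of indexes must produce signal in both channels at every index cycle, or
base calling fails.  Plates are laid out so that every aligned group of
four wells along a row (columns 1–4, 5–8, 9–12) is balanced on its own,
letting users pool as few as four consecutive wells without checking
balance themselves.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import Iterator, Sequence

ROWS = "ABCDEFGH"
COLUMNS = tuple(range(1, 13))

#: All 96 well names in row-major order (A1..A12, B1..H12).
WELLS: tuple[str, ...] = tuple(f"{r}{c}" for r in ROWS for c in COLUMNS)

QUARTETS_PER_PLATE = 24
PLATE_SIZE = 96

# two-channel signal model: A = both, C = ch1, T = ch2, G = dark
_CHANNELS = {
    "A": frozenset({"ch1", "ch2"}),
    "C": frozenset({"ch1"}),
    "T": frozenset({"ch2"}),
    "G": frozenset(),
}
_BOTH = frozenset({"ch1", "ch2"})


class LayoutError(RuntimeError):
    """Raised when no color-balanced arrangement can be found."""


def base_channels(base: str) -> frozenset[str]:
    """Channels lit by one base under two-channel chemistry."""
    try:
        return _CHANNELS[base]
    except KeyError:
        raise ValueError(f"invalid base {base!r}") from None


def is_color_balanced(group: Sequence[str]) -> bool:
    """True iff at every position the group lights both channels.

    This guarantees signal in each channel and rules out all-dark (all-G)
    cycles for any pool containing the whole group.
    """
    if not group:
        raise ValueError("empty group")
    k = len(group[0])
    if any(len(s) != k for s in group):
        raise ValueError("group members must share one length")
    for pos in range(k):
        lit: set[str] = set()
        for s in group:
            lit |= _CHANNELS[s[pos]]
        if lit != _BOTH:
            return False
    return True


@dataclass
class PlateLayout:
    """A full 96-well assignment of index sequences.

    ``assignments`` maps canonical well names ("A1".."H12") to sequences;
    downstream primer assembly enriches wells to full primer records.
    """

    plate_id: str
    assignments: dict[str, str] = field(default_factory=dict)

    def indexes_row_major(self) -> list[str]:
        return [self.assignments[w] for w in WELLS]

    def quartets(self) -> Iterator[tuple[tuple[str, ...], tuple[str, ...]]]:
        """Yield (wells, sequences) for the 24 aligned row quartets."""
        for start in range(0, PLATE_SIZE, 4):
            wells = WELLS[start : start + 4]
            yield wells, tuple(self.assignments[w] for w in wells)

    def to_matrix_csv(self, path) -> None:
        """Debug export: 8×12 matrix of index sequences."""
        import pandas as pd

        data = {
            c: [self.assignments[f"{r}{c}"] for r in ROWS] for c in COLUMNS
        }
        pd.DataFrame(data, index=list(ROWS)).to_csv(path, index_label="row")


def audit_plate(layout: PlateLayout) -> None:
    """Raise LayoutError unless all 96 wells are assigned and every aligned
    quartet is color balanced."""
    missing = [w for w in WELLS if w not in layout.assignments]
    if missing:
        raise LayoutError(f"plate {layout.plate_id}: unassigned wells {missing[:5]}...")
    for wells, seqs in layout.quartets():
        if not is_color_balanced(seqs):
            raise LayoutError(
                f"plate {layout.plate_id}: quartet {wells[0]}-{wells[-1]} not color balanced"
            )


def _find_quartet(remaining: list[str], visit_cap: int = 8000) -> set[int] | None:
    """Find positions of four mutually color-balanced members of
    ``remaining``: scan triples in list order, then search exhaustively for
    a fourth member that balances the group.  Bounded backtracking."""
    n = len(remaining)
    visits = 0
    for combo3 in itertools.combinations(range(min(n, 40)), 3):
        trip = [remaining[i] for i in combo3]
        taken = set(combo3)
        for j in range(n):
            if j in taken:
                continue
            visits += 1
            if is_color_balanced(trip + [remaining[j]]):
                return taken | {j}
        if visits > visit_cap:
            return None
    return None


def arrange_plate(
    indexes: Sequence[str],
    plate_id: str,
    seed: int | None = None,
    max_restarts: int = 200,
) -> PlateLayout:
    """Place 96 indexes on a plate so every aligned row quartet is balanced.

    Greedy with bounded backtracking: quartets are filled one at a time
    from a shuffled pool; a dead end reshuffles and restarts (deterministic
    under ``seed``).  Exactly 96 indexes are consumed; supplying a surplus
    makes dead ends rarer.
    """
    pool = list(indexes)
    if len(pool) < PLATE_SIZE:
        raise ValueError(f"need >= {PLATE_SIZE} indexes, got {len(pool)}")
    if len(set(pool)) != len(pool):
        raise ValueError("duplicate indexes supplied")
    rng = random.Random(seed)
    for _attempt in range(max_restarts):
        order = rng.sample(pool, len(pool))
        remaining = order[:]
        chosen: list[str] = []
        ok = True
        for _q in range(QUARTETS_PER_PLATE):
            hit = _find_quartet(remaining)
            if hit is None:
                ok = False
                break
            # preserve list order within the quartet for determinism
            chosen.extend(remaining[i] for i in sorted(hit))
            remaining = [x for i, x in enumerate(remaining) if i not in hit]
        if ok:
            layout = PlateLayout(plate_id, dict(zip(WELLS, chosen)))
            audit_plate(layout)
            return layout
    raise LayoutError(
        f"no color-balanced arrangement found for plate {plate_id} after "
        f"{max_restarts} restarts; supply a larger candidate surplus"
    )
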