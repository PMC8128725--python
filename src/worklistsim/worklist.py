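"""Pending-exam worklist with stable priority ordering and aging promotion.

The worklist is the queue of acquired-but-unreported exams.  Three
ordering rules are supported:

* FIFO append (acquisition order);
* stable priority insertion — a new exam goes behind every exam of equal
  or higher urgency and ahead of strictly less urgent ones;
* maximum-waiting-time promotion — any exam waiting longer than ``t_max``
  is lifted into a dedicated tier (rank 0) ahead of all unpromoted work,
  bounding the starvation caused by false-negative predictions.

Priority rank 1 is the most urgent finding tier, rank K+1 the "normal"
tier, rank 0 the promoted tier.  Within a tier, order is always
first-in-first-out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from bisect import insort

__all__ = ["WorklistItem", "Worklist", "PROMOTED_RANK"]

PROMOTED_RANK = 0


@dataclass
class WorklistItem:
    exam_id: int
    acquisition_time: float  # minutes
    priority_rank: int
    promoted: bool = False


@dataclass
class Worklist:
    """Priority-ordered pending exams, stable (FIFO) within each rank."""

    _entries: list[tuple[int, int, WorklistItem]] = field(default_factory=list)
    _ids: set = field(default_factory=set)
    _seq: int = 0

    def __len__(self) -> int:
        return len(self._entries)

    def items(self) -> list[WorklistItem]:
        """Current queue contents in pop order (does not consume)."""
        return [item for _, _, item in self._entries]

    def _add(self, item: WorklistItem) -> None:
        if item.exam_id in self._ids:
            raise ValueError(f"duplicate exam_id {item.exam_id!r}")
        if item.promoted and item.priority_rank != PROMOTED_RANK:
            raise ValueError("promoted items must carry the promoted rank")
        insort(self._entries, (item.priority_rank, self._seq, item))
        self._ids.add(item.exam_id)
        self._seq += 1

    def insert(self, item: WorklistItem) -> None:
        """Stable priority insertion.

        The item lands after all items of equal-or-lower rank value
        (equal or higher urgency) and before strictly larger ranks;
        existing relative order is untouched.
        """
        self._add(item)

    def fifo_insert(self, item: WorklistItem) -> None:
        """Append in acquisition order, ignoring the item's urgency."""
        if item.exam_id in self._ids:
            raise ValueError(f"duplicate exam_id {item.exam_id!r}")
        tail_rank = self._entries[-1][0] if self._entries else 0
        # A monotone rank key makes appending a degenerate stable insert.
        insort(self._entries, (max(tail_rank, 0), self._seq, item))
        self._ids.add(item.exam_id)
        self._seq += 1

    def pop_head(self) -> WorklistItem:
        """Remove and return the head of the queue."""
        if not self._entries:
            raise IndexError("empty worklist")
        _, _, item = self._entries.pop(0)
        self._ids.discard(item.exam_id)
        return item

    def promote_overdue(self, now: float, t_max: float) -> int:
        """Lift every exam waiting longer than ``t_max`` to the front.

        Promoted exams get rank 0 and are ordered among themselves by
        acquisition time (oldest first), ahead of all unpromoted exams.
        Idempotent for a fixed ``now``.  Returns the number of exams
        newly promoted.
        """
        if t_max <= 0:
            raise ValueError("t_max must be positive")
        overdue = [
            (rank, seq, item)
            for rank, seq, item in self._entries
            if not item.promoted and (now - item.acquisition_time) > t_max
        ]
        if not overdue:
            return 0
        overdue_ids = {item.exam_id for _, _, item in overdue}
        keep = [e for e in self._entries if e[2].exam_id not in overdue_ids]
        promoted_existing = [e for e in keep if e[2].promoted]
        rest = [e for e in keep if not e[2].promoted]
        for _, _, item in overdue:
            item.promoted = True
            item.priority_rank = PROMOTED_RANK
        merged = promoted_existing + [
            (PROMOTED_RANK, -1, item) for _, _, item in overdue
        ]
        # Promoted tier ordered by acquisition time, oldest first; ties
        # resolved by original queue position for determinism.
        merged.sort(key=lambda e: (e[2].acquisition_time, e[1]))
        self._entries = [
            (PROMOTED_RANK, i - len(merged), item)
            for i, (_, _, item) in enumerate(merged)
        ] + rest
        return len(overdue)
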