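"""Worklist engine against a brute-force stable-sort reference."""

from itertools import permutations

import numpy as np
import pytest

from worklistsim.worklist import PROMOTED_RANK, Worklist, WorklistItem


class ReferenceWorklist:
    """Oracle: re-sorts the full pending set with a stable sort per step.

    Promoted items sort by acquisition time (oldest first) ahead of
    everything; within a rank, insertion order is preserved because
    Python's sort is stable over the insertion-ordered list.
    """

    def __init__(self):
        self.pending = []  # (insertion_idx, rank, acq, promoted)
        self.counter = 0

    def insert(self, exam_id, rank, acq):
        self.pending.append({"id": exam_id, "rank": rank, "acq": acq, "promoted": False})

    def _sorted(self):
        return sorted(
            self.pending,
            key=lambda e: (0, e["acq"]) if e["promoted"] else (1, e["rank"]),
        )

    def pop_head(self):
        head = self._sorted()[0]
        self.pending.remove(head)
        return head

    def promote_overdue(self, now, t_max):
        for e in self.pending:
            if now - e["acq"] > t_max:
                e["promoted"] = True
                e["rank"] = PROMOTED_RANK


class TestInsert:
    def test_singleton(self):
        wl = Worklist()
        wl.insert(WorklistItem(1, 0.0, 3))
        assert [i.exam_id for i in wl.items()] == [1]

    def test_between_ranks(self):
        wl = Worklist()
        wl.insert(WorklistItem("A", 0.0, 2))
        wl.insert(WorklistItem("B", 1.0, 5))
        wl.insert(WorklistItem("C", 2.0, 3))
        assert [i.exam_id for i in wl.items()] == ["A", "C", "B"]

    def test_duplicate_id_rejected(self):
        wl = Worklist()
        wl.insert(WorklistItem(1, 0.0, 3))
        with pytest.raises(ValueError, match="duplicate"):
            wl.insert(WorklistItem(1, 1.0, 4))

    def test_matches_stable_sort_of_insertion_sequence(self):
        rng = np.random.default_rng(0)
        wl = Worklist()
        seq = []
        for i in range(50):
            rank = int(rng.integers(1, 10))
            wl.insert(WorklistItem(i, float(i), rank))
            seq.append((rank, i))
        expected = [i for _, i in sorted(seq, key=lambda x: x[0])]  # stable
        assert [i.exam_id for i in wl.items()] == expected


class TestPopHead:
    def test_pops_in_order(self):
        wl = Worklist()
        wl.insert(WorklistItem("A", 0.0, 1))
        wl.insert(WorklistItem("B", 1.0, 2))
        assert wl.pop_head().exam_id == "A"
        assert [i.exam_id for i in wl.items()] == ["B"]
        assert wl.pop_head().exam_id == "B"
        with pytest.raises(IndexError):
            wl.pop_head()

    def test_nondecreasing_rank_fifo_within_rank(self):
        rng = np.random.default_rng(1)
        wl = Worklist()
        for i in range(50):
            wl.insert(WorklistItem(i, float(i), int(rng.integers(1, 5))))
        popped = [wl.pop_head() for _ in range(50)]
        ranks = [p.priority_rank for p in popped]
        assert ranks == sorted(ranks)
        for r in set(ranks):
            ids = [p.exam_id for p in popped if p.priority_rank == r]
            assert ids == sorted(ids)  # FIFO within a tier


class TestFifoInsert:
    def test_acquisition_order(self):
        wl = Worklist()
        for i in range(100):
            wl.fifo_insert(WorklistItem(i, float(i), 1 + i % 7))
        assert [wl.pop_head().exam_id for _ in range(100)] == list(range(100))

    def test_equals_priority_insert_for_uniform_rank(self):
        a, b = Worklist(), Worklist()
        for i in range(20):
            a.fifo_insert(WorklistItem(i, float(i), 4))
            b.insert(WorklistItem(i, float(i), 4))
        assert [x.exam_id for x in a.items()] == [x.exam_id for x in b.items()]

    def test_duplicate_id_rejected(self):
        wl = Worklist()
        wl.fifo_insert(WorklistItem(1, 0.0, 1))
        with pytest.raises(ValueError, match="duplicate"):
            wl.fifo_insert(WorklistItem(1, 1.0, 1))


class TestPromoteOverdue:
    def test_nothing_overdue_is_noop(self):
        wl = Worklist()
        wl.insert(WorklistItem("A", 0.0, 2))
        before = [i.exam_id for i in wl.items()]
        assert wl.promote_overdue(now=100.0, t_max=360.0) == 0
        assert [i.exam_id for i in wl.items()] == before

    def test_overdue_item_jumps_the_queue(self):
        wl = Worklist()
        wl.insert(WorklistItem("A", 0.0, 6))
        wl.insert(WorklistItem("B", 390.0, 1))
        assert wl.promote_overdue(now=400.0, t_max=360.0) == 1
        items = wl.items()
        assert [i.exam_id for i in items] == ["A", "B"]
        assert items[0].promoted and items[0].priority_rank == PROMOTED_RANK
        assert not items[1].promoted

    def test_idempotent_for_fixed_now(self):
        wl = Worklist()
        for i in range(10):
            wl.insert(WorklistItem(i, float(i * 50), 1 + i % 4))
        wl.promote_overdue(now=500.0, t_max=120.0)
        snapshot = [(i.exam_id, i.priority_rank, i.promoted) for i in wl.items()]
        assert wl.promote_overdue(now=500.0, t_max=120.0) == 0
        assert snapshot == [(i.exam_id, i.priority_rank, i.promoted) for i in wl.items()]

    def test_promoted_tier_ordered_by_acquisition(self):
        rng = np.random.default_rng(2)
        wl = Worklist()
        acq = rng.permutation(20) * 30.0
        for i in range(20):
            wl.insert(WorklistItem(i, float(acq[i]), int(rng.integers(1, 9))))
        wl.promote_overdue(now=400.0, t_max=150.0)
        items = wl.items()
        promoted = [i for i in items if i.promoted]
        rest = [i for i in items if not i.promoted]
        # promotion safety: promoted block strictly precedes the rest
        assert items[: len(promoted)] == promoted
        acqs = [i.acquisition_time for i in promoted]
        assert acqs == sorted(acqs)
        assert all(400.0 - i.acquisition_time > 150.0 for i in promoted)
        assert all(400.0 - i.acquisition_time <= 150.0 for i in rest)
        ranks = [i.priority_rank for i in rest]
        assert ranks == sorted(ranks)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            Worklist().promote_overdue(now=10.0, t_max=0.0)


class TestOracleEquivalence:
    def test_exhaustive_equal_priority_permutations(self):
        # stability over all arrival orders of 5 equal-priority exams
        for perm in permutations(range(5)):
            wl = Worklist()
            for i in perm:
                wl.insert(WorklistItem(i, float(i), 3))
            assert [wl.pop_head().exam_id for _ in range(5)] == list(perm)

    def test_random_interleaving_matches_reference(self):
        rng = np.random.default_rng(3)
        wl, ref = Worklist(), ReferenceWorklist()
        next_id = 0
        clock = 0.0
        for _ in range(2000):
            clock += float(rng.exponential(5.0))
            u = rng.random()
            if u < 0.5 or len(wl) == 0:
                rank = int(rng.integers(1, 10))
                wl.insert(WorklistItem(next_id, clock, rank))
                ref.insert(next_id, rank, clock)
                next_id += 1
            elif u < 0.8:
                assert wl.pop_head().exam_id == ref.pop_head()["id"]
            else:
                wl.promote_overdue(clock, 60.0)
                ref.promote_overdue(clock, 60.0)
                got = [(i.exam_id, i.promoted) for i in wl.items()]
                want = [(e["id"], e["promoted"]) for e in ref._sorted()]
                assert got == want
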