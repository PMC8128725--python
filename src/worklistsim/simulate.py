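"""Event-driven Monte Carlo simulation of the reporting worklist.

Each simulated day is an independent 24-hour replication: an X-ray
machine generates exams whose inter-arrival gaps follow the hour-of-day
arrival distribution; each exam receives ground-truth findings from the
prevalence catalog and, under AI-prioritized strategies, stochastic
predictions from the classifier's operating point; a single virtual
radiologist finalizes reports at gaps drawn from the hour-of-day
reporting distribution, always taking the current head of the worklist.
Arrivals stop at minute 1440 and the backlog drains to zero before the
next day begins, so days are exchangeable replications.

Four strategies are available:

* ``fifo``    — acquisition order (the conventional workflow baseline);
* ``prio``    — stable priority insertion on the *predicted* urgency rank;
* ``prio_maxwait`` — ``prio`` plus promotion of any exam waiting longer
  than ``t_max`` minutes (bounds false-negative starvation);
* ``perfect`` — priority insertion on the *true* rank (error-free
  classifier; the upper bound on prioritization benefit).

Four named random streams (arrival, labels, classifier, service) are
seeded independently so that competing strategies can consume identical
randomness — common random numbers — which makes paired strategy
contrasts sharp.  The classifier stream is only consumed by the
prediction-based strategies; all other streams are consumed identically,
so arrival times, true labels, and report completion times coincide
across strategies run with the same seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import inf

import numpy as np
import pandas as pd

from .catalog import FindingCatalog, sample_labels, urgency_rank_vector
from .classifier import OperatingPoint, sample_prediction
from .timing import TimeOfDayHistogram, sample_delta
from .worklist import Worklist, WorklistItem

__all__ = [
    "STRATEGIES",
    "DAY_MINUTES",
    "StreamSeeds",
    "SimulationConfig",
    "ExamRecord",
    "run_day",
    "run_simulation",
    "records_to_dataframe",
    "write_event_log",
]

STRATEGIES = ("fifo", "prio", "prio_maxwait", "perfect")
DAY_MINUTES = 1440.0
_SEED_MASK = 0x7FFFFFFF  # keep derived seeds in signed-int32 range


@dataclass(frozen=True)
class StreamSeeds:
    """Independent seeds for the four named random streams."""

    arrival: int
    labels: int
    classifier: int
    service: int

    @classmethod
    def from_master(cls, master: int) -> "StreamSeeds":
        """Expand one master seed into the four stream seeds.

        Uses numpy's SeedSequence state expansion, masked into the
        signed 32-bit range, so the whole experiment is reproducible
        from a single integer.
        """
        state = np.random.SeedSequence(master).generate_state(4)
        return cls(*(int(s) & _SEED_MASK for s in state))

    def day_rng(self, stream: str, day_index: int) -> np.random.Generator:
        """Per-day substream: deterministic in (stream seed, day index)."""
        seed = getattr(self, stream)
        return np.random.default_rng(np.random.SeedSequence([seed, day_index]))


@dataclass(slots=True)
class ExamRecord:
    """Lifecycle of one simulated exam."""

    exam_id: int
    day_index: int
    acquisition_time: float
    true_labels: np.ndarray
    predicted_labels: np.ndarray | None
    assigned_rank: int
    promoted: bool
    report_time: float
    rtat: float


@dataclass
class SimulationConfig:
    strategy: str
    n_days: int
    catalog: FindingCatalog
    arrival_hist: TimeOfDayHistogram
    reporting_hist: TimeOfDayHistogram
    operating_point: OperatingPoint | None = None
    t_max: float | None = None
    master_seed: int | None = None
    seeds: StreamSeeds | None = None

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(
                f"unknown strategy {self.strategy!r}; choose from {STRATEGIES}"
            )
        if self.n_days < 1:
            raise ValueError("n_days must be at least 1")
        if self.strategy in ("prio", "prio_maxwait") and self.operating_point is None:
            raise ValueError(f"strategy {self.strategy!r} requires operating_point")
        if self.strategy == "prio_maxwait":
            if self.t_max is None:
                raise ValueError("strategy 'prio_maxwait' requires t_max")
            if self.t_max <= 0:
                raise ValueError("t_max must be positive")
        if self.seeds is None:
            if self.master_seed is None:
                raise ValueError("provide either seeds or master_seed")
            self.seeds = StreamSeeds.from_master(self.master_seed)


def _generate_arrivals(
    hist: TimeOfDayHistogram, rng: np.random.Generator
) -> np.ndarray:
    """Arrival times (minutes) of one day: cumulative sampled gaps < 1440."""
    times: list[float] = []
    t = 0.0
    while True:
        t += sample_delta(hist, t, rng)
        if t >= DAY_MINUTES:
            break
        times.append(t)
    return np.asarray(times)


def run_day(
    config: SimulationConfig, day_index: int, seeds: StreamSeeds | None = None
) -> list[ExamRecord]:
    """Simulate one independent day and return its exam records.

    Arrivals are generated until minute 1440; service continues past
    midnight until the worklist is empty, so every arrival is reported
    within its own day cycle.  A report completion always removes the
    worklist head at the moment of completion.  When a completion finds
    the list empty the radiologist idles; the next completion is
    scheduled one fresh reporting gap after the next arrival.
    """
    seeds = seeds if seeds is not None else config.seeds
    strategy = config.strategy
    catalog = config.catalog

    arrival_rng = seeds.day_rng("arrival", day_index)
    label_rng = seeds.day_rng("labels", day_index)
    service_rng = seeds.day_rng("service", day_index)

    times = _generate_arrivals(config.arrival_hist, arrival_rng)
    n = times.shape[0]
    true_labels = sample_labels(catalog, label_rng, size=n)

    predicted: np.ndarray | None = None
    if strategy in ("prio", "prio_maxwait"):
        classifier_rng = seeds.day_rng("classifier", day_index)
        predicted = sample_prediction(true_labels, config.operating_point, classifier_rng)
        ranks = urgency_rank_vector(predicted, catalog)
    elif strategy == "perfect":
        ranks = urgency_rank_vector(true_labels, catalog) if n else np.empty(0, int)
    else:  # fifo is rank-blind; record the uniform lowest tier
        ranks = np.full(n, catalog.normal_rank, dtype=int)

    use_fifo = strategy == "fifo"
    promote = strategy == "prio_maxwait"
    t_max = config.t_max
    rep_hist = config.reporting_hist

    wl = Worklist()
    records: list[ExamRecord | None] = [None] * n
    id_base = day_index * 1_000_000
    i = 0
    next_completion: float | None = None

    while i < n or next_completion is not None:
        ta = times[i] if i < n else inf
        tc = next_completion if next_completion is not None else inf
        if ta < tc:  # ties: finalize the pending report before the new arrival
            clock = float(ta)
            item = WorklistItem(
                exam_id=i, acquisition_time=clock, priority_rank=int(ranks[i])
            )
            (wl.fifo_insert if use_fifo else wl.insert)(item)
            i += 1
            if promote:
                wl.promote_overdue(clock, t_max)
            if next_completion is None:
                next_completion = clock + sample_delta(rep_hist, clock, service_rng)
        else:
            clock = float(tc)
            if promote:
                wl.promote_overdue(clock, t_max)
            done = wl.pop_head()
            j = done.exam_id
            records[j] = ExamRecord(
                exam_id=id_base + j,
                day_index=day_index,
                acquisition_time=done.acquisition_time,
                true_labels=true_labels[j],
                predicted_labels=None if predicted is None else predicted[j],
                assigned_rank=int(ranks[j]),
                promoted=done.promoted,
                report_time=clock,
                rtat=clock - done.acquisition_time,
            )
            if len(wl) > 0:
                next_completion = clock + sample_delta(rep_hist, clock, service_rng)
            else:
                next_completion = None

    assert all(r is not None for r in records), "arrival/report conservation broken"
    return records  # type: ignore[return-value]


def run_simulation(config: SimulationConfig) -> list[ExamRecord]:
    """Simulate ``config.n_days`` independent days and concatenate records.

    Per-day substreams are derived deterministically from the named
    stream seeds, so the output is reproducible bit-for-bit and equals
    the concatenation of the corresponding single-day runs.
    """
    records: list[ExamRecord] = []
    for day in range(config.n_days):
        records.extend(run_day(config, day))
    return records


def records_to_dataframe(
    records: list[ExamRecord], catalog: FindingCatalog
) -> pd.DataFrame:
    """Flatten exam records into the event-log table.

    Label vectors are serialized as semicolon-joined finding names; times
    are decimal minutes.
    """
    names = np.array(catalog.names)

    def join(labels: np.ndarray | None) -> str:
        if labels is None:
            return ""
        return ";".join(names[np.asarray(labels, dtype=bool)])

    return pd.DataFrame(
        {
            "day": [r.day_index for r in records],
            "exam_id": [r.exam_id for r in records],
            "acq_min": [round(r.acquisition_time, 3) for r in records],
            "report_min": [round(r.report_time, 3) for r in records],
            "rtat_min": [round(r.rtat, 3) for r in records],
            "rank": [r.assigned_rank for r in records],
            "promoted": [r.promoted for r in records],
            "true_labels": [join(r.true_labels) for r in records],
            "pred_labels": [join(r.predicted_labels) for r in records],
        }
    )


def write_event_log(records, catalog: FindingCatalog, path) -> None:
    records_to_dataframe(records, catalog).to_csv(path, index=False)
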