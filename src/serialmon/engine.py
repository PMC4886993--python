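"""Master/worker streaming engine with stale-event skipping and fault tolerance.

The pipeline contract mirrors the layered monitor design: workers *extract*
the needed properties from each event and *process* them into a flat
key-value frame result; the master *collects* frame results one at a time,
holds all cross-event state, and broadcasts aggregate snapshots to any
attached viewers.  The engine here runs the roles as threads inside one
process under a message-passing contract (results travel over a queue, the
master holds rank 0's role), which keeps the semantics — per-event dispatch,
corrupt-event skipping, drop-oldest backlogs, worker-crash survival —
identical to a multi-node deployment while remaining testable without a
launcher.

Guarantees, for every run:

* conservation: fetched = processed + skipped(corrupt) + dropped(stale)
  (+ lost-in-crash when a worker dies with events still queued);
* with unbounded backlog and healthy workers, the multiset of frame
  results equals a serial reference run's;
* a crashed worker never deadlocks the run — the master detects dead
  workers by liveness polling and finishes with the survivors' results;
* broadcast never blocks the master (see :mod:`serialmon.broadcast`).
"""

from __future__ import annotations

import queue
import threading
import time
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Iterator, Sequence

import numpy as np

from .broadcast import Publisher
from .sources import Event, ExtractedData, SkipEvent

__all__ = [
    "PipelineDefinition",
    "RunReport",
    "WorkerStats",
    "select_next_event",
    "run_monitor",
    "serial_reference",
    "canonical_result",
]

FrameResult = dict  # flat key-value record, self-contained and serializable
CollectedData = dict


@dataclass(frozen=True)
class PipelineDefinition:
    """The three user-supplied stages of a monitor.

    ``extract_fn`` and ``process_fn`` run on workers and must be pure
    per-event functions; ``collect_fn`` runs on the master and is the only
    holder of cross-event state.  ``collect_fn`` returns an aggregate
    snapshot to broadcast, or None to stay silent for this event.
    """

    extract_fn: Callable[[Event], ExtractedData]
    process_fn: Callable[[ExtractedData], FrameResult]
    collect_fn: Callable[[FrameResult], CollectedData | None]


@dataclass
class WorkerStats:
    fetched: int = 0
    processed: int = 0
    skipped: int = 0
    dropped: int = 0
    finished: bool = False
    crashed: bool = False
    feeder_thread: Any = None  # joined by the master for exact accounting
    #: (selected arrival_index, newest arrival_index pushed at selection time)
    selection_log: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class RunReport:
    """Terminal accounting of one monitor run."""

    fetched: int = 0
    processed: int = 0
    skipped: int = 0
    dropped: int = 0
    lost_in_crash: int = 0
    collect_calls: int = 0
    broadcasts: int = 0
    workers_crashed: int = 0
    worker_stats: list[WorkerStats] = field(default_factory=list)

    @property
    def conserved(self) -> bool:
        return (self.fetched
                == self.processed + self.skipped + self.dropped
                + self.lost_in_crash)


def select_next_event(
    pending: Sequence[Event], capacity: int
) -> tuple[Event | None, list[Event]]:
    """Drop-oldest selection: keep the newest ``capacity`` pending events.

    Returns the event to process next (the oldest *retained* one, so order
    is preserved within the capacity window) and the list of dropped stale
    events.  An empty backlog returns (None, []) — the caller waits.
    """
    if capacity < 1:
        raise ValueError("capacity must be >= 1")
    pending = list(pending)
    if not pending:
        return None, []
    dropped = pending[:-capacity] if len(pending) > capacity else []
    return pending[-capacity:][0], dropped


class _Backlog:
    """Thread-safe drop-oldest event buffer feeding one worker."""

    def __init__(self, capacity: int | None) -> None:
        self._items: list[Event] = []
        self._capacity = capacity
        self._cond = threading.Condition()
        self._closed = False
        self.newest_pushed = -1
        self.n_dropped = 0

    def push(self, event: Event) -> None:
        with self._cond:
            self._items.append(event)
            self.newest_pushed = max(self.newest_pushed, event.arrival_index)
            if self._capacity is not None and len(self._items) > self._capacity:
                overflow = len(self._items) - self._capacity
                self.n_dropped += overflow
                del self._items[:overflow]
            self._cond.notify()

    def close(self) -> None:
        with self._cond:
            self._closed = True
            self._cond.notify_all()

    def pop(self, timeout: float = 0.2) -> tuple[Event | None, int, bool]:
        """Next event (oldest retained), newest index seen, and closed flag."""
        with self._cond:
            if not self._items and not self._closed:
                self._cond.wait(timeout)
            if self._items:
                return self._items.pop(0), self.newest_pushed, False
            return None, self.newest_pushed, self._closed


class _WorkerCrashed(Exception):
    """Injected abrupt worker death (fault-tolerance testing)."""


def _worker_loop(
    wid: int,
    events: Iterator[Event],
    pipeline: PipelineDefinition,
    results_q: queue.Queue,
    stats: WorkerStats,
    backlog_capacity: int | None,
    source_interval_s: float,
    crash_after: int | None,
) -> None:
    buffered = backlog_capacity is not None or source_interval_s > 0

    def handle(event: Event) -> None:
        if crash_after is not None and stats.processed >= crash_after:
            raise _WorkerCrashed
        try:
            extracted = pipeline.extract_fn(event)
        except SkipEvent:
            stats.skipped += 1
            return
        result = pipeline.process_fn(extracted)
        stats.processed += 1
        results_q.put(("result", wid, result))

    try:
        if not buffered:
            for event in events:
                stats.fetched += 1
                handle(event)
        else:
            backlog = _Backlog(backlog_capacity)

            def feed() -> None:
                for event in events:
                    stats.fetched += 1
                    backlog.push(event)
                    if source_interval_s > 0:
                        time.sleep(source_interval_s)
                backlog.close()

            feeder = threading.Thread(target=feed, daemon=True,
                                      name=f"worker{wid}-feeder")
            stats.feeder_thread = feeder
            feeder.start()
            while True:
                event, newest, closed = backlog.pop()
                if event is None:
                    if closed:
                        break
                    continue
                stats.selection_log.append((event.arrival_index, newest))
                handle(event)
            stats.dropped = backlog.n_dropped
            feeder.join()
        stats.finished = True
    except _WorkerCrashed:
        stats.crashed = True  # abrupt exit: no farewell message, state dropped


def run_monitor(
    source: Callable[[int, int], Iterator[Event]],
    pipeline: PipelineDefinition,
    n_workers: int = 1,
    *,
    backlog_capacity: int | None = None,
    source_interval_s: float = 0.0,
    publisher: Publisher | None = None,
    crash_plan: dict[int, int] | None = None,
    poll_s: float = 0.05,
) -> RunReport:
    """Run a pipeline over a source with ``n_workers`` worker threads.

    ``backlog_capacity`` of None means unbounded FIFO processing (every
    fetched event is examined); an integer enables the drop-oldest stale
    policy with that per-worker depth.  ``source_interval_s`` paces event
    arrival to emulate a live data stream.  ``crash_plan`` maps worker id
    to the number of events after which that worker dies abruptly — the
    run must still complete on the survivors.
    """
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    crash_plan = crash_plan or {}
    results_q: queue.Queue = queue.Queue()
    stats = [WorkerStats() for _ in range(n_workers)]
    threads = []
    for wid in range(n_workers):
        t = threading.Thread(
            target=_worker_loop,
            args=(wid, source(wid, n_workers), pipeline, results_q,
                  stats[wid], backlog_capacity, source_interval_s,
                  crash_plan.get(wid)),
            name=f"worker{wid}",
            daemon=True,
        )
        threads.append(t)
        t.start()

    report = RunReport(worker_stats=stats)
    while True:
        try:
            _, _wid, result = results_q.get(timeout=poll_s)
        except queue.Empty:
            if all(not t.is_alive() for t in threads):
                if results_q.empty():
                    break
            continue
        report.collect_calls += 1
        collected = pipeline.collect_fn(result)
        if collected is not None:
            report.broadcasts += 1
            if publisher is not None:
                publisher.publish(collected)

    for t in threads:
        t.join(timeout=5.0)
    for s in stats:
        if s.feeder_thread is not None:
            s.feeder_thread.join(timeout=5.0)
    for s in stats:
        report.fetched += s.fetched
        report.processed += s.processed
        report.skipped += s.skipped
        report.dropped += s.dropped
        if s.crashed:
            report.workers_crashed += 1
    report.lost_in_crash = (report.fetched - report.processed
                            - report.skipped - report.dropped)
    return report


def serial_reference(
    source: Callable[[int, int], Iterator[Event]],
    pipeline: PipelineDefinition,
) -> tuple[list[FrameResult], RunReport]:
    """Single-threaded reference run: the oracle the engine must match.

    Processes every event of ``source(0, 1)`` in order with no backlog and
    no parallelism, returning the full list of frame results.
    """
    results: list[FrameResult] = []
    report = RunReport(worker_stats=[WorkerStats()])
    s = report.worker_stats[0]
    for event in source(0, 1):
        s.fetched += 1
        report.fetched += 1
        try:
            extracted = pipeline.extract_fn(event)
        except SkipEvent:
            s.skipped += 1
            report.skipped += 1
            continue
        result = pipeline.process_fn(extracted)
        s.processed += 1
        report.processed += 1
        results.append(result)
        report.collect_calls += 1
        pipeline.collect_fn(result)
    s.finished = True
    return results, report


def canonical_result(result: FrameResult) -> tuple:
    """A hashable canonical form of a frame result, for multiset comparison."""
    items = []
    for key in sorted(result):
        value = result[key]
        if isinstance(value, np.ndarray):
            items.append((key, value.dtype.str, value.shape, value.tobytes()))
        elif isinstance(value, (list, tuple)):
            items.append((key, tuple(np.asarray(value).ravel().tolist())))
        else:
            items.append((key, value))
    return tuple(items)
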