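"""Pipelined batch-workflow timing model for a set of needle-core biopsies.

All biopsies are stained and rinsed simultaneously, loaded once, then imaged
sequentially; processing of each biopsy starts the moment its imaging ends
(queueing FIFO if worker slots are limited) and a single reader diagnoses
the datasets in order as they become available.  All event times are minutes
from batch start.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["StageTiming", "BiopsyEvents", "Schedule", "build_schedule",
           "turnaround_summary", "load_timing"]


@dataclass(frozen=True)
class StageTiming:
    """Durations of each workflow stage.

    ``process_workers`` of ``None`` means unbounded concurrency (every
    dataset is processed the instant its imaging finishes).
    """

    stain_min: float = 5.0
    rinse_min: float = 1.5  # 3 rinses x 30 s
    load_min: float = 3.0   # assumption: loading time is not published
    image_min_per_biopsy: float = 2.0
    process_min_per_biopsy: float = 8.0
    diagnose_sec_per_biopsy: float = 35.0
    process_workers: int | None = None

    def __post_init__(self) -> None:
        durations = (self.stain_min, self.rinse_min, self.load_min,
                     self.image_min_per_biopsy, self.process_min_per_biopsy,
                     self.diagnose_sec_per_biopsy)
        if any(d < 0 for d in durations):
            raise ValueError("stage durations must be non-negative")
        if self.process_workers is not None and self.process_workers < 1:
            raise ValueError("process_workers must be positive or None")

    @property
    def preimaging_min(self) -> float:
        """Serial stain + rinse + load offset before imaging starts."""
        return self.stain_min + self.rinse_min + self.load_min

    @property
    def diagnose_min_per_biopsy(self) -> float:
        return self.diagnose_sec_per_biopsy / 60.0


@dataclass(frozen=True)
class BiopsyEvents:
    """Event times (minutes from batch start) for one biopsy."""

    image_start: float
    image_end: float
    process_start: float
    process_end: float
    diagnose_start: float
    diagnose_end: float


@dataclass
class Schedule:
    """Per-biopsy event times plus batch totals."""

    events: list[BiopsyEvents]
    timing: StageTiming
    last_dataset_ready: float
    total_turnaround: float

    @property
    def n_biopsies(self) -> int:
        return len(self.events)


def build_schedule(n_biopsies: int, timing: StageTiming = StageTiming()
                   ) -> Schedule:
    """Compute the deterministic pipelined schedule for ``n_biopsies``.

    Imaging slots are sequential and contiguous starting after the shared
    stain/rinse/load offset; processing starts when imaging of that biopsy
    ends (FIFO queueing onto ``process_workers`` slots when limited); the
    single reader diagnoses dataset ``i`` at
    ``max(process_end(i), diagnose_end(i-1))``.
    """
    if n_biopsies < 1:
        raise ValueError("need at least one biopsy")
    t = timing
    offset = t.preimaging_min

    image_start = [offset + i * t.image_min_per_biopsy
                   for i in range(n_biopsies)]
    image_end = [s + t.image_min_per_biopsy for s in image_start]

    process_start: list[float] = []
    process_end: list[float] = []
    if t.process_workers is None:
        for i in range(n_biopsies):
            process_start.append(image_end[i])
            process_end.append(image_end[i] + t.process_min_per_biopsy)
    else:
        # FIFO onto a min-heap of worker free times
        free = [0.0] * t.process_workers
        heapq.heapify(free)
        for i in range(n_biopsies):
            avail = heapq.heappop(free)
            start = max(image_end[i], avail)
            end = start + t.process_min_per_biopsy
            process_start.append(start)
            process_end.append(end)
            heapq.heappush(free, end)

    diagnose_start: list[float] = []
    diagnose_end: list[float] = []
    prev_end = 0.0
    for i in range(n_biopsies):
        start = max(process_end[i], prev_end)
        end = start + t.diagnose_min_per_biopsy
        diagnose_start.append(start)
        diagnose_end.append(end)
        prev_end = end

    events = [
        BiopsyEvents(image_start[i], image_end[i], process_start[i],
                     process_end[i], diagnose_start[i], diagnose_end[i])
        for i in range(n_biopsies)
    ]
    return Schedule(
        events=events,
        timing=timing,
        last_dataset_ready=max(process_end),
        total_turnaround=diagnose_end[-1],
    )


def turnaround_summary(schedule: Schedule) -> dict:
    """Summarise a schedule: totals, critical-path shares, reader idle gaps.

    ``stage_shares`` decomposes the span from batch start to the last
    dataset: the serial pre-imaging offset, the sequential imaging block,
    and the processing tail that extends past the final imaging slot.
    ``idle_gaps`` lists, per biopsy, how long the reader waited between
    finishing the previous diagnosis and starting this one.
    """
    t = schedule.timing
    ev = schedule.events
    n = schedule.n_biopsies
    imaging_total = ev[-1].image_end - ev[0].image_start
    processing_tail = schedule.last_dataset_ready - ev[-1].image_end
    diagnosis_tail = schedule.total_turnaround - schedule.last_dataset_ready
    gaps = []
    prev = 0.0
    for e in ev:
        gaps.append(e.diagnose_start - prev if prev > 0 else 0.0)
        prev = e.diagnose_end
    return {
        "n_biopsies": n,
        "total_turnaround_min": schedule.total_turnaround,
        "last_dataset_ready_min": schedule.last_dataset_ready,
        "stage_shares_min": {
            "preimaging": t.preimaging_min,
            "imaging": imaging_total,
            "processing_tail": processing_tail,
            "diagnosis_tail": diagnosis_tail,
        },
        "idle_gaps_min": gaps,
    }


def load_timing(path: str | Path) -> StageTiming:
    """Read a :class:`StageTiming` from a YAML mapping."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return StageTiming(**data)
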