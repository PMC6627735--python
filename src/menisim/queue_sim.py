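"""Arrival processes and the first-come-first-served allograft queue.

Patients join the transplant waiting list with exponential interarrival
times (mean 1 week). Donor menisci arrive with mixed-exponential
interarrivals: each gap is exponential with a mean freshly drawn from
Uniform(1, 5) weeks, reflecting the erratic supply of musculoskeletal
donors. Donors are matched first-come-first-served to the longest-waiting
patient; a patient who waits 104 weeks (2 years) without a graft leaves the
queue for total knee arthroplasty.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QueueOutcome",
    "QueueDisposition",
    "sample_patient_arrivals",
    "sample_donor_arrivals",
    "run_allocation",
    "dispositions_to_frame",
]


class QueueOutcome(str, Enum):
    """How a patient left the waiting queue."""

    TRANSPLANTED = "transplanted"
    TIMED_OUT = "timed_out"


@dataclass(frozen=True)
class QueueDisposition:
    """Resolution of one patient's stay on the waiting list.

    ``event_week`` is the transplantation week for ``TRANSPLANTED`` or
    exactly ``arrival_week + threshold`` for ``TIMED_OUT``;
    ``waiting_weeks`` is their difference.
    """

    patient: int
    arrival_week: float
    outcome: QueueOutcome
    event_week: float

    @property
    def waiting_weeks(self) -> float:
        return self.event_week - self.arrival_week


def sample_patient_arrivals(
    n_patients: int, mean_interarrival: float, rng: np.random.Generator
) -> np.ndarray:
    """Arrival times (weeks) of ``n_patients`` with exponential interarrivals."""
    if n_patients < 0:
        raise ValueError("n_patients must be non-negative")
    if mean_interarrival <= 0:
        raise ValueError("mean interarrival time must be positive")
    return np.cumsum(rng.exponential(mean_interarrival, size=n_patients))


def sample_donor_arrivals(
    horizon: float,
    rng: np.random.Generator,
    mean_range: tuple[float, float] = (1.0, 5.0),
    *,
    resample_mean_per_gap: bool = True,
) -> np.ndarray:
    """Donor arrival times (weeks) up to ``horizon``.

    Each interarrival is exponential with mean drawn from
    ``Uniform(mean_range)``. With ``resample_mean_per_gap`` (default) a
    fresh mean is drawn for every gap; otherwise one mean is drawn for the
    whole stream, a coarser reading of the same mixed-exponential process.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    lo, hi = mean_range
    if not 0 < lo <= hi:
        raise ValueError(f"invalid donor mean range {mean_range}")
    times: list[float] = []
    t = 0.0
    mean = rng.uniform(lo, hi)
    while True:
        if resample_mean_per_gap and times:
            mean = rng.uniform(lo, hi)
        t += rng.exponential(mean)
        if t > horizon:
            break
        times.append(t)
        if not resample_mean_per_gap:
            continue
        mean = rng.uniform(lo, hi)
    return np.asarray(times)


def run_allocation(
    patients: Sequence[float] | np.ndarray,
    donors: Sequence[float] | np.ndarray,
    threshold: float,
) -> list[QueueDisposition]:
    """Resolve the FCFS allograft queue.

    Donors are assigned in time order to the longest-waiting patient present
    at the donor's arrival; a donor finding the queue empty is discarded
    (menisci are patient-matched on arrival, not banked). A patient whose
    waiting time reaches ``threshold`` before a donor is removed with
    outcome ``TIMED_OUT`` at exactly ``arrival + threshold``; if a donor
    arrives at that same instant the timeout wins. Every patient receives
    exactly one disposition, returned in patient order.
    """
    if threshold <= 0:
        raise ValueError("waiting-time threshold must be positive")
    arrivals = np.asarray(patients, dtype=float)
    dispositions: list[QueueDisposition | None] = [None] * len(arrivals)
    waiting: deque[int] = deque()
    next_patient = 0

    def time_out(idx: int) -> None:
        dispositions[idx] = QueueDisposition(
            patient=idx,
            arrival_week=arrivals[idx],
            outcome=QueueOutcome.TIMED_OUT,
            event_week=arrivals[idx] + threshold,
        )

    for donor_time in np.asarray(donors, dtype=float):
        while next_patient < len(arrivals) and arrivals[next_patient] <= donor_time:
            waiting.append(next_patient)
            next_patient += 1
        # Timeout check precedes assignment when both fall at the same instant.
        while waiting and arrivals[waiting[0]] + threshold <= donor_time:
            time_out(waiting.popleft())
        if waiting:
            idx = waiting.popleft()
            dispositions[idx] = QueueDisposition(
                patient=idx,
                arrival_week=arrivals[idx],
                outcome=QueueOutcome.TRANSPLANTED,
                event_week=donor_time,
            )
    # No donors left: everyone still waiting (or yet to arrive) times out.
    for idx in list(waiting) + list(range(next_patient, len(arrivals))):
        time_out(idx)
    return [d for d in dispositions if d is not None]


def dispositions_to_frame(dispositions: Iterable[QueueDisposition]) -> pd.DataFrame:
    """Tidy table of queue dispositions (one row per patient)."""
    return pd.DataFrame(
        [
            {
                "patient_id": d.patient,
                "arrival_week": d.arrival_week,
                "outcome": d.outcome.value,
                "event_week": d.event_week,
                "waiting_weeks": d.waiting_weeks,
            }
            for d in dispositions
        ]
    )
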