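"""Post-transplant Markov trajectories and their exact analytic oracle.

Every transplanted patient starts in NI and makes one transition per annual
check. Entries into the intermediate states R and RO are counted; on what
would be the third entry (cap 2, configurable) the patient is instead
forced straight to the absorbing TKA state -- repeated interventions on the
same meniscus are taken to have exhausted its repair potential.

``tka_probability_by_cycle`` computes the exact distribution of absorption
times by augmenting the chain with the entry count, which the Monte-Carlo
path sampler must reproduce; it is the validation oracle for the whole
progression model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model_core import INTERMEDIATE_STATES, HealthState, TransitionMatrix

__all__ = [
    "Trajectory",
    "step_state",
    "simulate_post_transplant",
    "tka_probability_by_cycle",
    "trajectories_to_frame",
]


@dataclass(frozen=True)
class Trajectory:
    """One patient's annual-cycle state path after transplantation.

    ``states[k]`` is the state at cycle ``k`` (years after surgery);
    ``states[0]`` is always NI. The path stops at the first TKA entry or at
    the simulated horizon. ``forced_tka`` records whether TKA was imposed by
    the intermediate-entry cap rather than sampled.
    """

    states: tuple[HealthState, ...]
    intermediate_entries: int
    forced_tka: bool

    def __post_init__(self) -> None:
        if not self.states or self.states[0] != HealthState.NI:
            raise ValueError("a trajectory starts at NI (cycle 0)")

    @property
    def n_cycles(self) -> int:
        return len(self.states) - 1

    @property
    def reached_tka(self) -> bool:
        return self.states[-1] == HealthState.TKA

    @property
    def tka_cycle(self) -> int | None:
        """Cycle index of the TKA entry, or None if never absorbed."""
        return len(self.states) - 1 if self.reached_tka else None


def step_state(
    current: HealthState, matrix: TransitionMatrix, rng: np.random.Generator
) -> HealthState:
    """Sample the next annual state from ``current``'s transition row."""
    if current == HealthState.TKA:
        raise ValueError("TKA is absorbing: no transition to sample")
    return _inverse_cdf_step(matrix.row(current), rng.random())


def _inverse_cdf_step(row: np.ndarray, u: float) -> HealthState:
    # Inverse-CDF sampling in the fixed state order (NI, R, RO, TKA).  A
    # shared uniform then couples matrices monotonically in the quality
    # factor, which common-random-number scenario comparisons rely on.
    return HealthState(int(np.searchsorted(np.cumsum(row), u, side="right")))


def _is_new_entry(
    current: HealthState, dest: HealthState, r_to_ro_new_entry: bool
) -> bool:
    if dest not in INTERMEDIATE_STATES:
        return False
    if current not in INTERMEDIATE_STATES:
        return True
    return r_to_ro_new_entry


def simulate_post_transplant(
    matrix: TransitionMatrix,
    n_cycles: int,
    max_intermediate_entries: int = 2,
    rng: np.random.Generator | None = None,
    *,
    uniforms: Sequence[float] | None = None,
    r_to_ro_new_entry: bool = True,
) -> Trajectory:
    """Simulate one patient's post-transplant path for ``n_cycles`` years.

    Each sampled transition into R or RO increments the intermediate-entry
    count (an R→RO move counts as a new entry by default; set
    ``r_to_ro_new_entry=False`` to treat it as one continuing episode).
    When a sampled move would be entry number ``max_intermediate_entries+1``
    the destination is replaced by TKA and ``forced_tka`` is set. The path
    stops at TKA.

    Randomness comes from ``rng`` or, for common-random-number coupling,
    from an explicit ``uniforms`` sequence (one draw per cycle).
    """
    if n_cycles < 0:
        raise ValueError("n_cycles must be non-negative")
    if max_intermediate_entries < 0:
        raise ValueError("max_intermediate_entries must be non-negative")
    if (rng is None) == (uniforms is None):
        raise ValueError("provide exactly one of rng or uniforms")
    cum = np.cumsum(matrix.probs, axis=1)
    states = [HealthState.NI]
    entries = 0
    forced = False
    current = HealthState.NI
    for k in range(n_cycles):
        u = float(uniforms[k]) if uniforms is not None else rng.random()
        dest = HealthState(int(np.searchsorted(cum[int(current)], u, side="right")))
        if _is_new_entry(current, dest, r_to_ro_new_entry):
            entries += 1
            if entries > max_intermediate_entries:
                dest = HealthState.TKA
                forced = True
        states.append(dest)
        current = dest
        if current == HealthState.TKA:
            break
    return Trajectory(tuple(states), entries, forced)


def tka_probability_by_cycle(
    matrix: TransitionMatrix,
    n_cycles: int,
    max_intermediate_entries: int | None = 2,
    *,
    r_to_ro_new_entry: bool = True,
) -> np.ndarray:
    """Exact P(absorbed in TKA by cycle k), k = 0..n_cycles.

    Built from the entry-count-augmented chain with states
    ``(health state, intermediate entries used)`` in which the
    ``(cap+1)``-th intermediate entry is redirected to TKA. Passing
    ``max_intermediate_entries=None`` disables the cap, giving the plain
    absorption probability of the unaugmented chain.
    """
    if n_cycles < 0:
        raise ValueError("n_cycles must be non-negative")
    kernel, start, tka_index = _augmented_kernel(
        matrix, max_intermediate_entries, r_to_ro_new_entry
    )
    probs = np.empty(n_cycles + 1)
    v = start
    probs[0] = v[tka_index]
    for k in range(1, n_cycles + 1):
        v = v @ kernel
        probs[k] = v[tka_index]
    return probs


def _augmented_kernel(
    matrix: TransitionMatrix,
    cap: int | None,
    r_to_ro_new_entry: bool,
) -> tuple[np.ndarray, np.ndarray, int]:
    transient = (HealthState.NI, HealthState.R, HealthState.RO)
    if cap is None:
        # Plain chain: augmentation unnecessary.
        kernel = np.asarray(matrix.probs)
        start = np.zeros(4)
        start[HealthState.NI] = 1.0
        return kernel, start, int(HealthState.TKA)
    n_levels = cap + 1

    def index(state: HealthState, entries: int) -> int:
        return entries * len(transient) + int(state)

    tka_index = n_levels * len(transient)
    kernel = np.zeros((tka_index + 1, tka_index + 1))
    kernel[tka_index, tka_index] = 1.0
    for entries in range(n_levels):
        for state in transient:
            src = index(state, entries)
            for dest in HealthState:
                if dest == HealthState.WAITING:
                    continue
                p = matrix.probs[int(state), int(dest)]
                if p == 0.0:
                    continue
                if dest == HealthState.TKA:
                    kernel[src, tka_index] += p
                elif _is_new_entry(state, dest, r_to_ro_new_entry):
                    if entries + 1 > cap:
                        kernel[src, tka_index] += p
                    else:
                        kernel[src, index(dest, entries + 1)] += p
                else:
                    kernel[src, index(dest, entries)] += p
    start = np.zeros(tka_index + 1)
    start[index(HealthState.NI, 0)] = 1.0
    return kernel, start, tka_index


def trajectories_to_frame(
    trajectories: Iterable[Trajectory], patient_ids: Iterable[int] | None = None
) -> pd.DataFrame:
    """Tidy long-format table: patient_id, cycle, state, entries_used, forced_tka."""
    rows = []
    trajectories = list(trajectories)
    ids = list(patient_ids) if patient_ids is not None else range(len(trajectories))
    for pid, traj in zip(ids, trajectories, strict=True):
        for cycle, state in enumerate(traj.states):
            rows.append(
                {
                    "patient_id": pid,
                    "cycle": cycle,
                    "state": state.name,
                    "entries_used": traj.intermediate_entries,
                    "forced_tka": traj.forced_tka,
                }
            )
    return pd.DataFrame(rows)
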