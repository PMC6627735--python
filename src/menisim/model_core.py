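"""Health states, annual transition kernels, and implant-quality scenarios.

The post-transplant course of a meniscus-transplant patient is modelled as a
discrete-time Markov chain over four states -- no issue (NI), repair (R),
reoperation (RO) and total knee arthroplasty (TKA) -- with one transition per
annual check-up. TKA is absorbing. The quality of a 3D-printed implant is
encoded by a single multiplicative factor applied to every transition into
R, RO or TKA (the complement is routed back to NI), yielding eight named
sensitivity scenarios around the allograft-derived baseline matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum, IntEnum
from typing import Iterable

import numpy as np

__all__ = [
    "HealthState",
    "INTERMEDIATE_STATES",
    "STATE_ORDER",
    "TransitionMatrix",
    "ScenarioFactors",
    "Scenario",
    "SCENARIO_FACTORS",
    "InfeasibleFactorError",
    "build_traditional_matrix",
    "scale_transition_matrix",
    "combined_factor",
    "scenario_matrix",
]

#: Fixed ordering of the post-transplant states in every matrix and export.
STATE_ORDER: tuple[str, ...] = ("NI", "R", "RO", "TKA")

#: Tolerance for row-stochasticity checks on construction.
ROW_SUM_TOL = 1e-9


class HealthState(IntEnum):
    """Patient state in the transplantation pathway.

    ``WAITING`` occurs only before transplantation (traditional paradigm);
    the remaining four states index the rows/columns of a
    :class:`TransitionMatrix`. ``TKA`` is absorbing.
    """

    WAITING = -1
    NI = 0
    R = 1
    RO = 2
    TKA = 3


#: The "intermediate" states whose repeat entries are capped.
INTERMEDIATE_STATES = frozenset({HealthState.R, HealthState.RO})


class InfeasibleFactorError(ValueError):
    """Raised when a quality factor would push a row's off-NI mass above 1."""


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic annual transition kernel over (NI, R, RO, TKA).

    Parameters
    ----------
    probs
        4x4 array of transition probabilities, rows indexed by the current
        state and columns by the next state in :data:`STATE_ORDER`.

    Raises
    ------
    ValueError
        If the array is not 4x4, has entries outside [0, 1], has a row not
        summing to 1 within ``ROW_SUM_TOL``, or does not keep TKA absorbing.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.probs, dtype=float)
        if arr.shape != (4, 4):
            raise ValueError(f"transition matrix must be 4x4, got {arr.shape}")
        if np.any(arr < -ROW_SUM_TOL) or np.any(arr > 1 + ROW_SUM_TOL):
            raise ValueError("transition probabilities must lie in [0, 1]")
        row_sums = arr.sum(axis=1)
        if np.any(np.abs(row_sums - 1.0) > ROW_SUM_TOL):
            raise ValueError(f"rows must sum to 1, got sums {row_sums}")
        tka = arr[HealthState.TKA]
        if not np.array_equal(tka, [0.0, 0.0, 0.0, 1.0]):
            raise ValueError("TKA row must be (0, 0, 0, 1): TKA is absorbing")
        arr = arr.copy()
        arr.flags.writeable = False
        object.__setattr__(self, "probs", arr)

    def row(self, state: HealthState) -> np.ndarray:
        """Return the outgoing probability row of ``state``."""
        if state == HealthState.WAITING:
            raise ValueError("WAITING is not a Markov-chain state")
        return self.probs[int(state)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TransitionMatrix):
            return NotImplemented
        return np.array_equal(self.probs, other.probs)

    def __hash__(self) -> int:  # frozen dataclass with array payload
        return hash(self.probs.tobytes())

    # -- serialization -------------------------------------------------

    def to_json(self) -> str:
        """Serialize as ``{"states": [...], "rows": [[...], ...]}``."""
        return json.dumps({"states": list(STATE_ORDER), "rows": self.probs.tolist()})

    @classmethod
    def from_json(cls, payload: str) -> "TransitionMatrix":
        obj = json.loads(payload)
        if tuple(obj.get("states", ())) != STATE_ORDER:
            raise ValueError(f"state order must be {STATE_ORDER}")
        return cls(np.asarray(obj["rows"], dtype=float))


@dataclass(frozen=True)
class ScenarioFactors:
    """Quality factors of a 3D-printed implant along the three axes.

    ``mechanical``, ``shape`` and ``biocompatibility`` each scale the
    probabilities of entering R, RO or TKA relative to an allograft;
    ``combined`` is their product.
    """

    mechanical: float
    shape: float
    biocompatibility: float

    def __post_init__(self) -> None:
        for name in ("mechanical", "shape", "biocompatibility"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} factor must be positive")

    @property
    def combined(self) -> float:
        return combined_factor(self.mechanical, self.shape, self.biocompatibility)


class Scenario(str, Enum):
    """Named implant-quality scenarios for the sensitivity analysis.

    ``ORIGINAL`` means the printed implant behaves exactly like an
    allograft (factor 1); S1/S2 vary mechanical performance, S3/S4 shape
    fidelity, S5/S6 biocompatibility, and S7/S8 combine the three bad
    (resp. good) cases multiplicatively.
    """

    ORIGINAL = "original"
    S1 = "s1"  # bad mechanical performance
    S2 = "s2"  # good mechanical performance
    S3 = "s3"  # bad shape fidelity
    S4 = "s4"  # good shape fidelity
    S5 = "s5"  # bad biocompatibility
    S6 = "s6"  # good biocompatibility
    S7 = "s7"  # worst case: all three bad
    S8 = "s8"  # best case: all three good


def combined_factor(mechanical: float, shape: float, biocompatibility: float) -> float:
    """Product of the three quality factors.

    All inputs must be positive; raises ``ValueError`` otherwise.
    """
    for name, value in (
        ("mechanical", mechanical),
        ("shape", shape),
        ("biocompatibility", biocompatibility),
    ):
        if value <= 0:
            raise ValueError(f"{name} factor must be positive, got {value}")
    return mechanical * shape * biocompatibility


#: Scalar R/RO/TKA scaling factor of each scenario.
SCENARIO_FACTORS: dict[Scenario, float] = {
    Scenario.ORIGINAL: 1.0,
    Scenario.S1: 1.50,
    Scenario.S2: 0.50,
    Scenario.S3: 0.95,
    Scenario.S4: 0.90,
    Scenario.S5: 1.43,
    Scenario.S6: 1.11,
    Scenario.S7: combined_factor(1.50, 0.95, 1.43),  # 2.03775
    Scenario.S8: combined_factor(0.50, 0.90, 1.11),  # 0.4995
}


def build_traditional_matrix() -> TransitionMatrix:
    """Annual transition matrix of traditional allograft transplantation.

    From NI a patient stays issue-free with probability 0.82, needs a
    meniscal repair with 0.04, a reoperation with 0.12, and progresses to
    TKA with 0.02 per year. A repair succeeds (back to NI) with 0.80 and
    escalates to reoperation with 0.20; a reoperation always succeeds.
    """
    return TransitionMatrix(
        np.array(
            [
                [0.82, 0.04, 0.12, 0.02],  # NI
                [0.80, 0.00, 0.20, 0.00],  # R
                [1.00, 0.00, 0.00, 0.00],  # RO
                [0.00, 0.00, 0.00, 1.00],  # TKA (absorbing)
            ]
        )
    )


def scale_transition_matrix(base: TransitionMatrix, factor: float) -> TransitionMatrix:
    """Scale every transition into R, RO or TKA by ``factor``.

    In each non-absorbing row the entries into R, RO and TKA are multiplied
    by ``factor`` and the NI entry is reset to the complement, so the result
    stays row-stochastic. The TKA row is untouched.

    Raises
    ------
    InfeasibleFactorError
        If the scaled off-NI mass of any row would exceed 1 (the scenario
        definition would not be a probability distribution; it is rejected
        rather than clipped).
    ValueError
        If ``factor`` is not positive.
    """
    if factor <= 0:
        raise ValueError(f"scaling factor must be positive, got {factor}")
    if factor == 1.0:
        return TransitionMatrix(base.probs)
    arr = np.array(base.probs, copy=True)
    off = slice(HealthState.R, HealthState.TKA + 1)  # columns R, RO, TKA
    for row in (HealthState.NI, HealthState.R, HealthState.RO):
        scaled = arr[row, off] * factor
        mass = scaled.sum()
        if mass > 1 + ROW_SUM_TOL:
            raise InfeasibleFactorError(
                f"factor {factor} gives off-NI mass {mass:.6f} > 1 in row "
                f"{STATE_ORDER[row]}"
            )
        arr[row, off] = scaled
        arr[row, HealthState.NI] = 1.0 - min(mass, 1.0)
    return TransitionMatrix(arr)


def scenario_matrix(scenario: Scenario | str) -> TransitionMatrix:
    """Transition matrix of a named implant-quality scenario."""
    key = Scenario(scenario)
    return scale_transition_matrix(build_traditional_matrix(), SCENARIO_FACTORS[key])
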