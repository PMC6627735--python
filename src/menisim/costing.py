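"""Cost accounting for both transplantation paradigms.

Traditional paradigm, per patient:
    cost = waiting cost + transplantation cost + post-transplantation cost
(the evaluation cost is negligible and set to zero). Waiting cost accrues
at $30 per completed week on the queue; the transplantation procedure
(allograft, surgery, therapy) costs $8875; each post-transplant annual
state charges its per-event treatment cost (NI $0, R $2760, RO $1770,
TKA $14167).

3DP-enabled paradigm: identical except there is no waiting cost (the
implant is printed on demand) and the transplantation costs $7249 --
the $4750 allograft inside the $8875 procedure is replaced by a $3124
3D-printed implant, itemized in :func:`default_implant_bom`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .model_core import HealthState
from .progression import Trajectory
from .queue_sim import QueueDisposition, QueueOutcome

__all__ = [
    "CostTable",
    "BomItem",
    "ImplantBillOfMaterials",
    "MENISCUS_ALLOGRAFT_COST",
    "TRADITIONAL_TRANSPLANT_COST",
    "default_implant_bom",
    "implant_cost",
    "transplantation_cost_3dp",
    "accrue_patient_cost",
]

#: Allograft component of the traditional transplantation cost (USD).
MENISCUS_ALLOGRAFT_COST = 4750.0

#: Traditional transplantation procedure cost (allograft + surgery + therapy).
TRADITIONAL_TRANSPLANT_COST = 8875.0


@dataclass(frozen=True)
class CostTable:
    """Per-event and per-week costs (USD) used by the simulation."""

    no_issue: float = 0.0
    repair: float = 2760.0
    reoperation: float = 1770.0
    tka: float = 14167.0
    waiting_per_week: float = 30.0
    transplantation: float = TRADITIONAL_TRANSPLANT_COST

    def __post_init__(self) -> None:
        for name in (
            "no_issue",
            "repair",
            "reoperation",
            "tka",
            "waiting_per_week",
            "transplantation",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"cost {name} must be non-negative")

    def state_cost(self, state: HealthState) -> float:
        """Treatment cost charged on entering ``state`` at an annual check."""
        return {
            HealthState.NI: self.no_issue,
            HealthState.R: self.repair,
            HealthState.RO: self.reoperation,
            HealthState.TKA: self.tka,
        }[state]

    @classmethod
    def traditional(cls) -> "CostTable":
        return cls()

    @classmethod
    def three_dp(cls, implant: float | None = None) -> "CostTable":
        """Cost table of the 3DP paradigm (no waiting, cheaper procedure)."""
        if implant is None:
            implant = implant_cost(default_implant_bom())
        return cls(
            waiting_per_week=0.0,
            transplantation=transplantation_cost_3dp(
                TRADITIONAL_TRANSPLANT_COST, MENISCUS_ALLOGRAFT_COST, implant
            ),
        )


@dataclass(frozen=True)
class BomItem:
    name: str
    amount: str
    cost: float


@dataclass(frozen=True)
class ImplantBillOfMaterials:
    """Itemized component costs of one 3D-printed meniscus implant."""

    items: tuple[BomItem, ...]


def default_implant_bom() -> ImplantBillOfMaterials:
    """Bill of materials of one printed meniscus: cells, biomaterials,
    growth factor, printing consumables and overhead ($3124 total)."""
    return ImplantBillOfMaterials(
        (
            BomItem("stem cells", "", 1000.0),
            BomItem("cell culture", "500 mL", 213.0),
            BomItem("human collagen-II", "22.5 mL", 805.5),
            BomItem("alginate", "5 g", 0.7),
            BomItem("polycaprolactone (PCL)", "1 g", 0.4),
            BomItem("TGF-beta I", "0.1 mg", 1076.5),
            BomItem("ABS", "63.5 g", 0.8),
            BomItem("acetone", "10 mL", 0.1),
            BomItem("others (container, machine, electricity, labor)", "", 27.0),
        )
    )


def implant_cost(bom: ImplantBillOfMaterials) -> float:
    """Total cost of the implant: sum of its bill-of-materials items."""
    for item in bom.items:
        if item.cost < 0:
            raise ValueError(f"negative cost for BOM item {item.name!r}")
    return math.fsum(item.cost for item in bom.items)


def transplantation_cost_3dp(
    traditional_transplant: float, allograft: float, implant: float
) -> float:
    """3DP procedure cost: the allograft inside the traditional procedure
    cost is replaced by the printed implant."""
    if min(traditional_transplant, allograft, implant) < 0:
        raise ValueError("costs must be non-negative")
    if allograft > traditional_transplant:
        raise ValueError("allograft cost cannot exceed the procedure cost")
    return traditional_transplant - allograft + implant


def accrue_patient_cost(
    disposition: QueueDisposition,
    trajectory: Trajectory | None,
    costs: CostTable,
    horizon: float,
    weeks_per_year: float = 52.0,
) -> list[tuple[float, float]]:
    """Cost events ``(week, USD)`` of one patient, clipped to the horizon.

    Emits: the weekly waiting charge for every completed week on the queue
    (timed-out patients are charged the full threshold); the transplantation
    cost at the transplant week; the per-state treatment cost at each annual
    check of the post-transplant trajectory (NI charges nothing, TKA is
    charged once -- it is absorbing); and, for timed-out patients, a single
    TKA cost at the timeout week with no transplantation cost. Events
    falling after ``horizon`` are dropped.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if trajectory is not None and disposition.outcome != QueueOutcome.TRANSPLANTED:
        raise ValueError("a timed-out patient has no post-transplant trajectory")
    events: list[tuple[float, float]] = []
    if costs.waiting_per_week > 0:
        completed = int(math.floor(disposition.waiting_weeks + 1e-9))
        for week_on_queue in range(1, completed + 1):
            events.append((disposition.arrival_week + week_on_queue, costs.waiting_per_week))
    if disposition.outcome == QueueOutcome.TIMED_OUT:
        events.append((disposition.event_week, costs.tka))
    else:
        events.append((disposition.event_week, costs.transplantation))
        if trajectory is not None:
            for cycle, state in enumerate(trajectory.states):
                if cycle == 0:
                    continue  # cycle 0 is the surgery itself (state NI)
                cost = costs.state_cost(state)
                if cost > 0:
                    events.append((disposition.event_week + weeks_per_year * cycle, cost))
    return [(week, usd) for week, usd in events if week <= horizon]
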