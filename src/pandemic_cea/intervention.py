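"""Intervention outcomes: cases averted, QALYs gained, net savings, CE class.

A mitigation strategy reaches a fraction (``coverage``) of ALL adults affected
by the condition during the pandemic — pre-existing and pandemic-attributable
cases alike — and removes the condition in ``efficacy`` of participants. One
averted case avoids both the short-term and the long-term per-episode
consequences (long-term discounted as in the burden model). Intervention
costs are charged entirely in year one, undiscounted.

Averted costs do not all materialise at once: an accrual schedule phases the
short- and long-term averted costs over 1-, 3- and 10-year horizons (defaults
60/90/95% of short-term and 0/20/50% of long-term costs incurred by those
horizons; the lifetime horizon accrues everything). Net savings at a horizon
are the accrued averted costs minus the full intervention cost.

An intervention whose lifetime savings exceed its cost while gaining QALYs is
*dominant* versus doing nothing; otherwise the net cost per QALY gained (an
incremental cost-effectiveness ratio, ICER) is reported.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .model_core import BurdenResult, ConditionParams

__all__ = [
    "DEFAULT_ACCRUAL_ENTRIES",
    "InterventionParams",
    "AccrualSchedule",
    "CEClassification",
    "InterventionResult",
    "compute_intervention",
    "classify_cost_effectiveness",
    "stroke_reach_adjustment",
]

DEFAULT_ACCRUAL_ENTRIES: dict[str, tuple[float, float]] = {
    "year1": (0.60, 0.00),
    "year3": (0.90, 0.20),
    "year10": (0.95, 0.50),
    "lifetime": (1.00, 1.00),
}


@dataclass
class InterventionParams:
    """One mitigation strategy.

    ``coverage`` is the fraction of all affected adults reached (default 20%);
    ``efficacy`` is the relative reduction in the condition among participants;
    ``cost_per_participant`` is in 2020 USD, charged once in year one.
    """

    name: str
    efficacy: float
    cost_per_participant: float
    coverage: float = 0.20
    cost_timing: str = "year_one_undiscounted"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 < self.coverage <= 1.0:
            raise ValueError(f"{self.name}: coverage must be in (0, 1], got {self.coverage}")
        if not 0.0 <= self.efficacy <= 1.0:
            raise ValueError(f"{self.name}: efficacy must be in [0, 1], got {self.efficacy}")
        if self.cost_per_participant < 0:
            raise ValueError(f"{self.name}: cost_per_participant must be >= 0")


@dataclass
class AccrualSchedule:
    """Ordered horizons -> (fraction of short-term, fraction of long-term)
    averted costs incurred by that horizon. Fractions must be nondecreasing in
    horizon order and the final ``lifetime`` entry must be (1, 1).
    """

    entries: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ACCRUAL_ENTRIES)
    )

    def __post_init__(self) -> None:
        self.entries = {k: (float(v[0]), float(v[1])) for k, v in self.entries.items()}
        self.validate()

    @classmethod
    def default(cls) -> "AccrualSchedule":
        return cls(dict(DEFAULT_ACCRUAL_ENTRIES))

    def validate(self) -> None:
        if "lifetime" not in self.entries:
            raise ValueError("accrual schedule must include a 'lifetime' entry")
        if list(self.entries)[-1] != "lifetime":
            raise ValueError("'lifetime' must be the last schedule entry")
        if self.entries["lifetime"] != (1.0, 1.0):
            raise ValueError(
                f"lifetime accrual must be (1, 1), got {self.entries['lifetime']}"
            )
        prev = (0.0, 0.0)
        for label, (fs, fl) in self.entries.items():
            if not (0.0 <= fs <= 1.0 and 0.0 <= fl <= 1.0):
                raise ValueError(f"schedule entry {label}: fractions must be in [0, 1]")
            if fs < prev[0] or fl < prev[1]:
                raise ValueError(
                    f"schedule entry {label}: accrual fractions must be nondecreasing "
                    f"across horizons ({prev} -> ({fs}, {fl}))"
                )
            prev = (fs, fl)

    @property
    def horizons(self) -> list[str]:
        return list(self.entries)

    def net_savings(self, averted_short: float, averted_long: float, cost: float) -> dict[str, float]:
        """Net savings at every horizon for given averted costs and intervention cost."""
        return {
            h: fs * averted_short + fl * averted_long - cost
            for h, (fs, fl) in self.entries.items()
        }


@dataclass
class CEClassification:
    """Lifetime cost-effectiveness versus doing nothing."""

    kind: str  # "dominant" | "icer" | "undefined"
    icer: float | None = None  # net cost per QALY gained, when kind == "icer"

    def __str__(self) -> str:
        if self.kind == "dominant":
            return "dominant"
        if self.kind == "icer":
            return f"ICER ${self.icer:,.0f}/QALY"
        return "undefined (no QALYs gained)"

    def to_dict(self) -> dict:
        return {"kind": self.kind, "icer": self.icer}

    @classmethod
    def from_dict(cls, d: dict) -> "CEClassification":
        return cls(**d)


@dataclass
class InterventionResult:
    """Computed outcomes of one intervention at a given population scale."""

    intervention: str
    condition: str
    participants: float
    cases_averted: float
    qalys_gained_short: float
    qalys_gained_long_discounted: float
    qalys_gained_total: float
    averted_cost_short: float
    averted_cost_long_discounted: float
    intervention_cost_total: float
    net_savings_by_horizon: dict[str, float]
    ce_class: CEClassification

    def to_dict(self) -> dict:
        return {
            "intervention": self.intervention,
            "condition": self.condition,
            "participants": self.participants,
            "cases_averted": self.cases_averted,
            "qalys_gained_short": self.qalys_gained_short,
            "qalys_gained_long_discounted": self.qalys_gained_long_discounted,
            "qalys_gained_total": self.qalys_gained_total,
            "averted_cost_short": self.averted_cost_short,
            "averted_cost_long_discounted": self.averted_cost_long_discounted,
            "intervention_cost_total": self.intervention_cost_total,
            "net_savings_by_horizon": dict(self.net_savings_by_horizon),
            "ce_class": self.ce_class.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InterventionResult":
        d = dict(d)
        d["ce_class"] = CEClassification.from_dict(d["ce_class"])
        return cls(**d)


def classify_cost_effectiveness(
    lifetime_net_savings: float, qalys_gained: float
) -> CEClassification:
    """Dominance/ICER classification versus doing nothing.

    Positive lifetime net savings with QALYs gained -> dominant; net cost with
    QALYs gained -> ICER (net cost per QALY); zero QALYs gained -> undefined.
    """
    if qalys_gained < 0:
        raise ValueError(f"qalys_gained must be >= 0, got {qalys_gained}")
    if qalys_gained == 0:
        return CEClassification("undefined")
    if lifetime_net_savings > 0:
        return CEClassification("dominant")
    return CEClassification("icer", icer=-lifetime_net_savings / qalys_gained)


def compute_intervention(
    cond: ConditionParams,
    burden: BurdenResult,
    interv: InterventionParams,
    schedule: AccrualSchedule | None = None,
) -> InterventionResult:
    """Run the intervention-outcomes section of the model.

    ``burden`` must have been computed from ``cond`` at the same population
    scale; the eligible pool is the TOTAL affected population (not just
    pandemic-attributable cases).
    """
    if schedule is None:
        schedule = AccrualSchedule.default()
    schedule.validate()

    participants = burden.total_affected * interv.coverage
    cases_averted = participants * interv.efficacy

    sev_q = cond.severity_multiplier
    sev_c = cond.severity_multiplier if cond.severity_applies_to_costs else 1.0
    pv = cond.long_term_discount_factor

    q_short = cases_averted * cond.short_term.qaly_loss_per_episode * sev_q
    q_long = cases_averted * cond.long_term.qaly_loss_per_episode * sev_q * pv
    a_short = cases_averted * cond.short_term.cost_per_episode * sev_c
    a_long = cases_averted * cond.long_term.cost_per_episode * sev_c * pv

    cost_total = participants * interv.cost_per_participant
    net = schedule.net_savings(a_short, a_long, cost_total)
    ce = classify_cost_effectiveness(net["lifetime"], q_short + q_long)

    return InterventionResult(
        intervention=interv.name,
        condition=cond.name,
        participants=participants,
        cases_averted=cases_averted,
        qalys_gained_short=q_short,
        qalys_gained_long_discounted=q_long,
        qalys_gained_total=q_short + q_long,
        averted_cost_short=a_short,
        averted_cost_long_discounted=a_long,
        intervention_cost_total=cost_total,
        net_savings_by_horizon=net,
        ce_class=ce,
    )


def stroke_reach_adjustment(
    at_risk_pool: float,
    total_campaign_cost: float,
    *,
    efficacy: float,
    name: str = "public awareness campaign",
) -> InterventionParams:
    """Population-wide campaign parameters: 100% reach of the at-risk pool,
    with the fixed campaign cost spread as a per-person cost.
    """
    if at_risk_pool <= 0:
        raise ValueError(f"at_risk_pool must be > 0, got {at_risk_pool}")
    if total_campaign_cost < 0:
        raise ValueError("total_campaign_cost must be >= 0")
    return InterventionParams(
        name=name,
        coverage=1.0,
        efficacy=efficacy,
        cost_per_participant=total_campaign_cost / at_risk_pool,
    )
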