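"""Excess-burden model for pandemic-exacerbated health conditions.

Each condition is described by its pre-pandemic adult prevalence, the relative
risk (RR) of the condition during the pandemic, and per-episode consequences
split into a short-term and a long-term component. The model computes, for a
population of ``n_adults``:

* total prevalence during the pandemic (baseline x RR) and excess prevalence
  (baseline x (RR - 1));
* excess QALYs lost, short-term plus long-term, the long-term component
  discounted to present value at an annual rate (default 3%) over a mean lag
  (default 10 years);
* excess societal costs (direct medical + non-medical), same structure.

QALY losses per episode may be given directly or assembled from morbidity
(health-state utility decrement x duration) and mortality (case fatality x
QALYs lost per death). A severity multiplier scales health outcomes only
(e.g. 0.25 for acute pandemic-related homelessness, whose consequences are
assumed much milder than chronic homelessness); it does not touch costs
unless explicitly requested.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

__all__ = [
    "DEFAULT_DISCOUNT_RATE",
    "DEFAULT_LONG_TERM_LAG_YEARS",
    "EpisodeImpact",
    "HealthOutcomeComponents",
    "ConditionParams",
    "PopulationScale",
    "BurdenResult",
    "qaly_loss_from_components",
    "discount",
    "excess_prevalence",
    "compute_added_burden",
]

DEFAULT_DISCOUNT_RATE = 0.03
DEFAULT_LONG_TERM_LAG_YEARS = 10.0


@dataclass
class EpisodeImpact:
    """Per-episode societal cost (2020 USD) and QALY loss of one component
    (short-term or long-term) of a condition. Values are undiscounted;
    discounting of the long-term component happens in the burden computation.
    """

    cost_per_episode: float
    qaly_loss_per_episode: float

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.cost_per_episode < 0:
            raise ValueError(f"cost_per_episode must be >= 0, got {self.cost_per_episode}")
        if self.qaly_loss_per_episode < 0:
            raise ValueError(
                f"qaly_loss_per_episode must be >= 0, got {self.qaly_loss_per_episode}"
            )


@dataclass
class HealthOutcomeComponents:
    """Morbidity/mortality decomposition of a per-episode QALY loss.

    Morbidity contributes ``utility_decrement x duration_years``; mortality
    contributes ``case_fatality x qalys_lost_per_death``.
    """

    utility_decrement: float
    duration_years: float
    case_fatality: float
    qalys_lost_per_death: float

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 <= self.utility_decrement <= 1.0:
            raise ValueError(f"utility_decrement must be in [0, 1], got {self.utility_decrement}")
        if not 0.0 <= self.case_fatality <= 1.0:
            raise ValueError(f"case_fatality must be in [0, 1], got {self.case_fatality}")
        if self.duration_years < 0:
            raise ValueError(f"duration_years must be >= 0, got {self.duration_years}")
        if self.qalys_lost_per_death < 0:
            raise ValueError(f"qalys_lost_per_death must be >= 0, got {self.qalys_lost_per_death}")

    def qaly_loss(self) -> float:
        return qaly_loss_from_components(self)

    def to_episode_impact(self, cost_per_episode: float) -> EpisodeImpact:
        return EpisodeImpact(cost_per_episode, self.qaly_loss())


def qaly_loss_from_components(c: HealthOutcomeComponents) -> float:
    """Collapse a morbidity/mortality decomposition into QALYs lost per episode.

    Returns ``utility_decrement * duration_years
    + case_fatality * qalys_lost_per_death``.
    """
    c.validate()
    return c.utility_decrement * c.duration_years + c.case_fatality * c.qalys_lost_per_death


@dataclass
class ConditionParams:
    """One pandemic-exacerbated health condition.

    Parameters
    ----------
    name
        Condition label.
    baseline_prevalence
        Pre-pandemic adult prevalence, in (0, 1).
    rr_pandemic
        Relative risk of the condition during the pandemic (> 0).
    rr_range
        (low, high) uncertainty range bracketing ``rr_pandemic``.
    short_term, long_term
        Per-episode consequences. The long-term component is assumed to occur
        after ``long_term_lag_years`` and is discounted at ``discount_rate``.
    severity_multiplier
        Scalar in (0, 1] applied to QALY losses (health outcomes) only;
        applied to costs as well only if ``severity_applies_to_costs``.
    """

    name: str
    baseline_prevalence: float
    rr_pandemic: float
    rr_range: tuple[float, float]
    short_term: EpisodeImpact
    long_term: EpisodeImpact
    severity_multiplier: float = 1.0
    long_term_lag_years: float = DEFAULT_LONG_TERM_LAG_YEARS
    discount_rate: float = DEFAULT_DISCOUNT_RATE
    severity_applies_to_costs: bool = False

    def __post_init__(self) -> None:
        self.rr_range = (float(self.rr_range[0]), float(self.rr_range[1]))
        self.validate()

    def validate(self) -> None:
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValueError(
                f"{self.name}: baseline_prevalence must be in (0, 1), "
                f"got {self.baseline_prevalence}"
            )
        if self.rr_pandemic <= 0:
            raise ValueError(f"{self.name}: rr_pandemic must be > 0, got {self.rr_pandemic}")
        low, high = self.rr_range
        if not low <= self.rr_pandemic <= high:
            raise ValueError(
                f"{self.name}: rr_range {self.rr_range} must bracket rr_pandemic "
                f"{self.rr_pandemic}"
            )
        if not 0.0 < self.severity_multiplier <= 1.0:
            raise ValueError(
                f"{self.name}: severity_multiplier must be in (0, 1], "
                f"got {self.severity_multiplier}"
            )
        if self.long_term_lag_years < 0:
            raise ValueError(f"{self.name}: long_term_lag_years must be >= 0")
        if self.discount_rate < 0:
            raise ValueError(f"{self.name}: discount_rate must be >= 0")
        self.short_term.validate()
        self.long_term.validate()

    @property
    def long_term_discount_factor(self) -> float:
        """Present-value factor for the long-term component."""
        return 1.0 / (1.0 + self.discount_rate) ** self.long_term_lag_years


@dataclass
class PopulationScale:
    """Reporting denominator for absolute outputs (default: one million adults)."""

    n_adults: int = 1_000_000
    reporting_unit: str = "per million adults"

    def __post_init__(self) -> None:
        if self.n_adults <= 0:
            raise ValueError(f"n_adults must be > 0, got {self.n_adults}")


@dataclass
class BurdenResult:
    """Excess burden attributable to the pandemic, at a given population scale."""

    condition: str
    total_affected: float
    excess_affected: float
    excess_qalys_short: float
    excess_qalys_long_discounted: float
    excess_cost_short: float
    excess_cost_long_discounted: float
    per_capita_qalys: float
    per_capita_cost: float

    @property
    def excess_qalys_total(self) -> float:
        return self.excess_qalys_short + self.excess_qalys_long_discounted

    @property
    def excess_cost_total(self) -> float:
        return self.excess_cost_short + self.excess_cost_long_discounted

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "total_affected": self.total_affected,
            "excess_affected": self.excess_affected,
            "excess_qalys_short": self.excess_qalys_short,
            "excess_qalys_long_discounted": self.excess_qalys_long_discounted,
            "excess_cost_short": self.excess_cost_short,
            "excess_cost_long_discounted": self.excess_cost_long_discounted,
            "per_capita_qalys": self.per_capita_qalys,
            "per_capita_cost": self.per_capita_cost,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BurdenResult":
        return cls(**d)


def discount(value: float, rate: float, years: float) -> float:
    """Present value of ``value`` incurred ``years`` from now at annual ``rate``."""
    if years < 0:
        raise ValueError(f"years must be >= 0, got {years}")
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    return value / (1.0 + rate) ** years


def excess_prevalence(baseline: float, rr: float) -> tuple[float, float]:
    """Total and excess prevalence during the pandemic.

    ``total = baseline * rr``; ``excess = baseline * (rr - 1)``, floored at
    zero (with a warning) when rr < 1 — the framework models conditions the
    pandemic made more common, not protective effects.
    """
    if not 0.0 < baseline < 1.0:
        raise ValueError(f"baseline prevalence must be in (0, 1), got {baseline}")
    if rr <= 0:
        raise ValueError(f"relative risk must be > 0, got {rr}")
    total = baseline * rr
    if total > 1.0:
        raise ValueError(
            f"implausible total prevalence {total:.4g} > 1 (baseline {baseline}, rr {rr})"
        )
    if rr < 1.0:
        warnings.warn(
            f"rr {rr} < 1 implies the pandemic reduced prevalence; "
            "excess burden floored at zero",
            UserWarning,
            stacklevel=2,
        )
        return total, 0.0
    return total, baseline * (rr - 1.0)


def compute_added_burden(
    cond: ConditionParams, scale: PopulationScale | None = None
) -> BurdenResult:
    """Excess cases, QALYs lost and societal costs attributable to the pandemic.

    Long-term QALYs and costs are discounted once at the mean lag. The
    severity multiplier scales QALY losses; costs are scaled only when
    ``cond.severity_applies_to_costs`` is set.
    """
    if scale is None:
        scale = PopulationScale()
    total_prev, excess_prev = excess_prevalence(cond.baseline_prevalence, cond.rr_pandemic)
    n = scale.n_adults
    total_affected = total_prev * n
    excess_affected = excess_prev * n

    sev_q = cond.severity_multiplier
    sev_c = cond.severity_multiplier if cond.severity_applies_to_costs else 1.0
    pv = cond.long_term_discount_factor

    qalys_short = excess_affected * cond.short_term.qaly_loss_per_episode * sev_q
    qalys_long = excess_affected * cond.long_term.qaly_loss_per_episode * sev_q * pv
    cost_short = excess_affected * cond.short_term.cost_per_episode * sev_c
    cost_long = excess_affected * cond.long_term.cost_per_episode * sev_c * pv

    return BurdenResult(
        condition=cond.name,
        total_affected=total_affected,
        excess_affected=excess_affected,
        excess_qalys_short=qalys_short,
        excess_qalys_long_discounted=qalys_long,
        excess_cost_short=cost_short,
        excess_cost_long_discounted=cost_long,
        per_capita_qalys=(qalys_short + qalys_long) / n,
        per_capita_cost=(cost_short + cost_long) / n,
    )
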