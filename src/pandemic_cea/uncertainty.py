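"""Probabilistic and deterministic sensitivity analysis.

The probabilistic sensitivity analysis (PSA) propagates parameter uncertainty
through the full pipeline (burden -> intervention) by Monte Carlo: each draw
jointly resamples every listed parameter independently, reruns the model end
to end, and the collected outputs are summarised by their mean and an
empirical 95% prediction interval (2.5th/97.5th percentiles, linear/type-7
interpolation).

Distribution families follow standard health-economics PSA conventions:
relative risks are lognormal matched to a published 95% range, probabilities
(prevalence, coverage, efficacy) beta, costs gamma — each family's two
parameters are solved so the distribution's 2.5/97.5% quantiles equal the
given bounds. Point, uniform and (modified-)PERT families are also available.
Sampled values outside a target parameter's domain are resampled and counted;
draws yielding an invalid model state (e.g. total prevalence > 1) are rejected
and redrawn, with an error if rejections dominate.

The one-way deterministic sensitivity analysis (DSA) sweeps a single
parameter over stated values with everything else at base case.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .calibration import CalibratedScenario, run_scenario
from .intervention import AccrualSchedule
from .model_core import PopulationScale

__all__ = [
    "FAMILIES",
    "ParameterDistribution",
    "PSAConfig",
    "PSAResult",
    "sample_distribution",
    "run_psa",
    "one_way_dsa",
    "default_distributions",
    "lognormal_from_ci",
    "beta_from_ci",
    "gamma_from_ci",
    "get_param",
    "set_param",
]

FAMILIES = (
    "point",
    "uniform",
    "pert",
    "lognormal-from-95CI",
    "beta-from-95CI",
    "gamma-from-95CI",
)

_Z95 = stats.norm.ppf(0.975)  # 1.959964...


# ---------------------------------------------------------------------------
# quantile matching: solve family parameters from a 95% interval
# ---------------------------------------------------------------------------

def lognormal_from_ci(low: float, high: float) -> tuple[float, float]:
    """(mu, sigma) of the log scale whose 2.5/97.5% quantiles are (low, high).

    The implied median is the geometric mean of the bounds.
    """
    if not 0 < low < high:
        raise ValueError(f"lognormal CI bounds must satisfy 0 < low < high, got ({low}, {high})")
    sigma = (np.log(high) - np.log(low)) / (2.0 * _Z95)
    mu = 0.5 * (np.log(low) + np.log(high))
    return float(mu), float(sigma)


def beta_from_ci(low: float, high: float) -> tuple[float, float]:
    """(a, b) of a beta distribution whose 2.5/97.5% quantiles are (low, high)."""
    if not 0.0 <= low < high <= 1.0:
        raise ValueError(f"beta CI bounds must satisfy 0 <= low < high <= 1, got ({low}, {high})")
    m0 = 0.5 * (low + high)
    sd0 = max((high - low) / (2.0 * _Z95), 1e-6)
    k0 = max(m0 * (1 - m0) / sd0**2 - 1.0, 2.0)

    def resid(x):
        m, k = 1.0 / (1.0 + np.exp(-x[0])), np.exp(x[1])
        a, b = m * k, (1.0 - m) * k
        return [stats.beta.ppf(0.025, a, b) - low, stats.beta.ppf(0.975, a, b) - high]

    x0 = [np.log(m0 / (1 - m0)), np.log(k0)]
    sol = optimize.fsolve(resid, x0, full_output=True)
    x, info, ier, _ = sol
    if ier != 1 or max(abs(np.asarray(info["fvec"]))) > 1e-6:
        raise ValueError(f"could not match beta quantiles to ({low}, {high})")
    m, k = 1.0 / (1.0 + np.exp(-x[0])), np.exp(x[1])
    return float(m * k), float((1.0 - m) * k)


def gamma_from_ci(low: float, high: float) -> tuple[float, float]:
    """(shape, scale) of a gamma distribution whose 2.5/97.5% quantiles are (low, high)."""
    if not 0 < low < high:
        raise ValueError(f"gamma CI bounds must satisfy 0 < low < high, got ({low}, {high})")
    m0 = 0.5 * (low + high)
    sd0 = (high - low) / (2.0 * _Z95)
    a0, s0 = (m0 / sd0) ** 2, sd0**2 / m0

    def resid(x):
        a, s = np.exp(x)
        return [stats.gamma.ppf(0.025, a, scale=s) - low, stats.gamma.ppf(0.975, a, scale=s) - high]

    sol = optimize.fsolve(resid, [np.log(a0), np.log(s0)], full_output=True)
    x, info, ier, _ = sol
    if ier != 1 or max(abs(np.asarray(info["fvec"]))) > 1e-6 * max(1.0, high):
        raise ValueError(f"could not match gamma quantiles to ({low}, {high})")
    a, s = np.exp(x)
    return float(a), float(s)


# ---------------------------------------------------------------------------
# distributions
# ---------------------------------------------------------------------------

@dataclass
class ParameterDistribution:
    """Sampling rule for one model parameter.

    ``target_parameter`` is a dotted path into the scenario, rooted at
    ``condition`` or ``intervention`` (e.g. ``condition.rr_pandemic``,
    ``intervention.efficacy``, ``condition.short_term.cost_per_episode``).
    """

    target_parameter: str
    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown distribution family {self.family!r}; one of {FAMILIES}")
        required = {
            "point": {"value"},
            "uniform": {"low", "high"},
            "pert": {"low", "mode", "high"},
            "lognormal-from-95CI": {"low", "high"},
            "beta-from-95CI": {"low", "high"},
            "gamma-from-95CI": {"low", "high"},
        }[self.family]
        missing = required - set(self.params)
        if missing:
            raise ValueError(f"{self.target_parameter}: family {self.family} needs {sorted(missing)}")
        root = self.target_parameter.split(".")[0]
        if root not in ("condition", "intervention"):
            raise ValueError(
                f"target_parameter must be rooted at 'condition' or 'intervention', "
                f"got {self.target_parameter!r}"
            )


def sample_distribution(d: ParameterDistribution, rng: np.random.Generator, size=None):
    """Draw from ``d`` (scalar when ``size`` is None, else an array)."""
    p = d.params
    if d.family == "point":
        v = p["value"]
        return float(v) if size is None else np.full(size, float(v))
    if d.family == "uniform":
        if p["low"] > p["high"]:
            raise ValueError(f"{d.target_parameter}: uniform low > high")
        return rng.uniform(p["low"], p["high"], size=size)
    if d.family == "pert":
        low, mode, high = p["low"], p["mode"], p["high"]
        if not low <= mode <= high:
            raise ValueError(f"{d.target_parameter}: PERT needs low <= mode <= high")
        if low == high:
            return float(low) if size is None else np.full(size, float(low))
        lam = p.get("lambda", 4.0)
        a = 1.0 + lam * (mode - low) / (high - low)
        b = 1.0 + lam * (high - mode) / (high - low)
        return low + rng.beta(a, b, size=size) * (high - low)
    if d.family == "lognormal-from-95CI":
        mu, sigma = lognormal_from_ci(p["low"], p["high"])
        return rng.lognormal(mu, sigma, size=size)
    if d.family == "beta-from-95CI":
        a, b = beta_from_ci(p["low"], p["high"])
        return rng.beta(a, b, size=size)
    if d.family == "gamma-from-95CI":
        a, s = gamma_from_ci(p["low"], p["high"])
        return rng.gamma(a, scale=s, size=size)
    raise AssertionError("unreachable")


# domain of each settable parameter, keyed by the path's final attribute:
# (low, high, low_open) — draws outside are resampled
_DOMAINS = {
    "baseline_prevalence": (0.0, 1.0, True),
    "efficacy": (0.0, 1.0, False),
    "coverage": (0.0, 1.0, True),
    "severity_multiplier": (0.0, 1.0, True),
    "utility_decrement": (0.0, 1.0, False),
    "case_fatality": (0.0, 1.0, False),
    "rr_pandemic": (0.0, np.inf, True),
    "cost_per_episode": (0.0, np.inf, False),
    "qaly_loss_per_episode": (0.0, np.inf, False),
    "cost_per_participant": (0.0, np.inf, False),
    "discount_rate": (0.0, np.inf, False),
    "long_term_lag_years": (0.0, np.inf, False),
}


def _in_domain(path: str, value: float) -> bool:
    leaf = path.split(".")[-1]
    low, high, low_open = _DOMAINS.get(leaf, (-np.inf, np.inf, False))
    if low_open and value <= low:
        return False
    if not low_open and value < low:
        return False
    return value <= high


def get_param(scenario: CalibratedScenario, path: str) -> float:
    obj: object = scenario
    for seg in path.split("."):
        if not hasattr(obj, seg):
            raise AttributeError(f"cannot resolve parameter path {path!r} (at {seg!r})")
        obj = getattr(obj, seg)
    return obj  # type: ignore[return-value]


def set_param(scenario: CalibratedScenario, path: str, value: float) -> None:
    """Set a parameter by dotted path, then revalidate the touched object.

    Setting ``rr_pandemic`` outside the stored uncertainty range widens the
    range to cover it — the range is metadata, not a constraint during
    sensitivity analysis.
    """
    segs = path.split(".")
    obj: object = scenario
    for seg in segs[:-1]:
        if not hasattr(obj, seg):
            raise AttributeError(f"cannot resolve parameter path {path!r} (at {seg!r})")
        obj = getattr(obj, seg)
    leaf = segs[-1]
    if not hasattr(obj, leaf):
        raise AttributeError(f"cannot resolve parameter path {path!r} (at {leaf!r})")
    setattr(obj, leaf, float(value))
    if leaf == "rr_pandemic":
        low, high = scenario.condition.rr_range
        scenario.condition.rr_range = (min(low, value), max(high, value))
    root = scenario.condition if segs[0] == "condition" else scenario.intervention
    root.validate()


def default_distributions(scenario: CalibratedScenario) -> list[ParameterDistribution]:
    """Default PSA set: relative risk lognormal on the scenario's stated range."""
    low, high = scenario.condition.rr_range
    return [
        ParameterDistribution(
            "condition.rr_pandemic", "lognormal-from-95CI", {"low": low, "high": high}
        )
    ]


# ---------------------------------------------------------------------------
# PSA
# ---------------------------------------------------------------------------

@dataclass
class PSAConfig:
    distributions: list[ParameterDistribution]
    n_draws: int = 10_000
    seed: int = 0
    percentiles: tuple[float, float] = (2.5, 97.5)
    keep_draws: bool = False

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError(f"n_draws must be >= 1, got {self.n_draws}")
        lo, hi = self.percentiles
        if not 0 <= lo < hi <= 100:
            raise ValueError(f"percentiles must satisfy 0 <= lo < hi <= 100, got {self.percentiles}")


@dataclass
class PSAResult:
    """Per-output mean and prediction-interval bounds over the draw set."""

    summaries: dict[str, dict[str, float]]  # output -> {mean, lower, upper}
    n_draws: int
    seed: int
    percentiles: tuple[float, float]
    n_rejected: int = 0
    n_truncated: int = 0
    draws: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "summaries": {k: dict(v) for k, v in self.summaries.items()},
            "n_draws": self.n_draws,
            "seed": self.seed,
            "percentiles": list(self.percentiles),
            "n_rejected": self.n_rejected,
            "n_truncated": self.n_truncated,
        }


def _scenario_outputs(scenario, scale, schedule) -> dict[str, float]:
    _, result = run_scenario(scenario, scale=scale, schedule=schedule)
    out = {"qalys_gained_total": result.qalys_gained_total}
    for h, v in result.net_savings_by_horizon.items():
        out[f"net_savings_{h}"] = v
    return out


def run_psa(
    scenario: CalibratedScenario,
    cfg: PSAConfig,
    scale: PopulationScale | None = None,
    schedule: AccrualSchedule | None = None,
) -> PSAResult:
    """Monte-Carlo PSA over the full burden -> intervention pipeline.

    Each draw jointly resamples all configured parameters (independently),
    reruns the model, and contributes one value per output. Identical seed and
    config give bit-identical summaries.
    """
    if schedule is None:
        schedule = AccrualSchedule.default()
    rng = np.random.default_rng(cfg.seed)
    rows: list[dict[str, float]] = []
    n_rejected = 0
    n_truncated = 0
    max_attempts = max(20 * cfg.n_draws, 1000)
    attempts = 0
    while len(rows) < cfg.n_draws:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"PSA rejection rate too high: {n_rejected} rejections in {attempts - 1} attempts"
            )
        sampled: dict[str, float] = {}
        ok = True
        for d in cfg.distributions:
            v = sample_distribution(d, rng)
            tries = 0
            while not _in_domain(d.target_parameter, v):
                n_truncated += 1
                tries += 1
                if tries > 1000:
                    raise RuntimeError(
                        f"{d.target_parameter}: sampler cannot produce in-domain values"
                    )
                v = sample_distribution(d, rng)
            sampled[d.target_parameter] = float(v)
        draw = copy.deepcopy(scenario)
        try:
            for path, v in sampled.items():
                set_param(draw, path, v)
            outputs = _scenario_outputs(draw, scale, schedule)
        except ValueError as exc:
            n_rejected += 1
            if n_rejected > attempts / 2 and attempts >= 20:
                raise RuntimeError(
                    f"PSA rejection rate exceeds 50% ({n_rejected}/{attempts}); "
                    "check distributions against parameter domains"
                ) from exc
            continue
        rows.append({**{f"param:{k}": v for k, v in sampled.items()}, **outputs})

    frame = pd.DataFrame(rows)
    out_cols = [c for c in frame.columns if not c.startswith("param:")]
    lo, hi = cfg.percentiles
    summaries = {
        c: {
            "mean": float(frame[c].mean()),
            "lower": float(np.percentile(frame[c].to_numpy(), lo)),
            "upper": float(np.percentile(frame[c].to_numpy(), hi)),
        }
        for c in out_cols
    }
    return PSAResult(
        summaries=summaries,
        n_draws=cfg.n_draws,
        seed=cfg.seed,
        percentiles=cfg.percentiles,
        n_rejected=n_rejected,
        n_truncated=n_truncated,
        draws=frame if cfg.keep_draws else None,
    )


# ---------------------------------------------------------------------------
# one-way DSA
# ---------------------------------------------------------------------------

def one_way_dsa(
    scenario: CalibratedScenario,
    parameter_path: str,
    values: list[float],
    scale: PopulationScale | None = None,
    schedule: AccrualSchedule | None = None,
) -> pd.DataFrame:
    """Deterministic rerun per value of one parameter, all else at base case.

    Returns one row per value: QALYs gained, net savings by horizon, CE class.
    """
    get_param(scenario, parameter_path)  # fail fast on unresolvable paths
    if schedule is None:
        schedule = AccrualSchedule.default()
    rows = []
    for v in values:
        run = copy.deepcopy(scenario)
        set_param(run, parameter_path, v)
        _, result = run_scenario(run, scale=scale, schedule=schedule)
        row = {"value": float(v), "qalys_gained_total": result.qalys_gained_total}
        for h, s in result.net_savings_by_horizon.items():
            row[f"net_savings_{h}"] = s
        row["ce_class"] = str(result.ce_class)
        rows.append(row)
    return pd.DataFrame(rows)
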