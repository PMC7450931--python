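"""Markov cohort model of CKD progression and cost-effectiveness analysis.

A discrete-time cohort model tracks the fraction of a patient cohort across
CKD stages (3, 4, 5/dialysis), post-complication states (stroke, acute
myocardial infarction, congestive heart failure) and death.  A care-program
strategy modifies per-cycle transition probabilities (relative risks on
stage progression and on complication incidence) for a limited effect
duration and charges an annual program cost to living patients.  The engine
accrues discounted lifetime costs (Baht) and quality-adjusted life years,
computes the incremental cost-effectiveness ratio (ICER) between two
strategies, and runs threshold, scenario and one-way sensitivity analyses.

Conventions (replication-critical, documented in the methods note):
cycle length one year; accrual at the start of each cycle with an optional
half-cycle correction; a relative risk on a transition moves the freed
probability mass into the stay-in-state probability; the lifetime horizon
stops when the cohort reaches age 100 or living occupancy falls below 1e-6.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError

__all__ = [
    "MarkovSpec",
    "StrategyConfig",
    "CohortTrace",
    "CeaResult",
    "IcerResult",
    "apply_strategy",
    "run_cohort",
    "accumulate",
    "run_cea",
    "icer",
    "threshold_analysis",
    "scenario_analysis",
    "one_way_analysis",
    "psa",
    "load_markov_spec",
    "default_markov_spec",
    "null_strategy",
]

_MASS_TOL = 1e-10
_ROW_TOL = 1e-12
_LIVING_EPS = 1e-6
_MAX_AGE = 100.0


@dataclass(frozen=True)
class MarkovSpec:
    """State space, transition structure and economic parameters.

    ``transitions`` is an S x S per-cycle probability matrix (rows sum to 1;
    the dead state is absorbing).  ``state_costs`` are Baht per cycle of
    occupancy (outpatient + inpatient); ``event_costs`` are one-off Baht
    charges at incident entry into the named (complication) states;
    ``utilities`` are QALY weights per state in [0, 1] with dead exactly 0.
    """

    states: tuple[str, ...]
    transitions: np.ndarray
    state_costs: np.ndarray
    utilities: np.ndarray
    event_costs: dict = field(default_factory=dict)
    event_states: tuple[str, ...] = ()
    dead_state: str = "dead"
    stage_edges: dict = field(
        default_factory=lambda: {"stage3_to_4": ("CKD3", "CKD4"), "stage4_to_5": ("CKD4", "CKD5")}
    )
    discount_rate: float = 0.03
    cycle_length: float = 1.0
    start_distribution: np.ndarray | None = None
    start_age: float = 60.0
    horizon: float | str = "lifetime"
    half_cycle_correction: bool = False

    def __post_init__(self):
        S = len(self.states)
        T = np.asarray(self.transitions, dtype=float)
        if T.shape != (S, S):
            raise ValidationError(f"transitions: expected {S}x{S} matrix, got {T.shape}")
        if np.any(T < -1e-15) or np.any(T > 1 + 1e-15):
            raise ValidationError("transitions: probabilities must lie in [0, 1]")
        if np.any(np.abs(T.sum(axis=1) - 1.0) > _ROW_TOL):
            raise ValidationError("transitions: every row must sum to 1 within 1e-12")
        if self.dead_state not in self.states:
            raise ValidationError(f"dead_state: {self.dead_state!r} not in states")
        d = self.states.index(self.dead_state)
        if not (T[d, d] == 1.0 and np.all(T[d, np.arange(S) != d] == 0.0)):
            raise ValidationError("transitions: dead state must be absorbing")
        u = np.asarray(self.utilities, dtype=float)
        if u.shape != (S,) or np.any(u < 0) or np.any(u > 1):
            raise ValidationError("utilities: need one weight per state in [0, 1]")
        if u[d] != 0.0:
            raise ValidationError("utilities: dead state utility must be exactly 0")
        c = np.asarray(self.state_costs, dtype=float)
        if c.shape != (S,):
            raise ValidationError("state_costs: need one cost per state")
        if self.discount_rate < 0:
            raise ValidationError(f"discount_rate: must be >= 0, got {self.discount_rate}")
        if self.cycle_length <= 0:
            raise ValidationError(f"cycle_length: must be > 0, got {self.cycle_length}")
        sd = self.start_distribution
        sd = np.zeros(S) if sd is None else np.asarray(sd, dtype=float)
        if self.start_distribution is None:
            sd[0] = 1.0
        if sd.shape != (S,) or np.any(sd < 0) or abs(sd.sum() - 1.0) > 1e-9:
            raise ValidationError("start_distribution: must be a probability vector over states")
        for s in self.event_states:
            if s not in self.states:
                raise ValidationError(f"event_states: {s!r} not in states")
        for s in self.event_costs:
            if s not in self.states:
                raise ValidationError(f"event_costs: {s!r} not in states")
        object.__setattr__(self, "transitions", T)
        object.__setattr__(self, "utilities", u)
        object.__setattr__(self, "state_costs", c)
        object.__setattr__(self, "start_distribution", sd)

    def index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise ValidationError(f"state: unknown state {state!r}")


@dataclass(frozen=True)
class StrategyConfig:
    """A care strategy: program cost plus relative risks on progression.

    Defaults encode the comprehensive-care program assessment: 1,000 Baht
    per patient per year, stage 3→4 progression slowed by 20% (rr 0.8),
    stage 4→5 by 25% (rr 0.75), complication incidence reduced by 20%
    (rr 0.8), all effects persisting for the first five years.
    """

    name: str = "comprehensive-care"
    annual_program_cost: float = 1000.0
    rr_stage3_to_4: float = 0.8
    rr_stage4_to_5: float = 0.75
    rr_complications: float = 0.8
    effect_duration: float = 5.0

    def __post_init__(self):
        for name in ("rr_stage3_to_4", "rr_stage4_to_5", "rr_complications"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValidationError(f"{name}: multiplier must be in (0, 1], got {v}")
        if self.effect_duration < 0:
            raise ValidationError(f"effect_duration: must be >= 0, got {self.effect_duration}")
        if self.annual_program_cost < 0:
            raise ValidationError(
                f"annual_program_cost: must be >= 0, got {self.annual_program_cost}"
            )


def null_strategy(name: str = "conventional-care") -> StrategyConfig:
    """Comparator strategy: no program cost, no effect on transitions."""
    return StrategyConfig(
        name=name,
        annual_program_cost=0.0,
        rr_stage3_to_4=1.0,
        rr_stage4_to_5=1.0,
        rr_complications=1.0,
        effect_duration=0.0,
    )


def apply_strategy(
    spec: MarkovSpec, strategy: StrategyConfig | None, cycle_index: int
) -> np.ndarray:
    """Effective transition matrix for one cycle under a strategy.

    Within the effect duration, each targeted off-diagonal probability is
    multiplied by its relative risk and the freed mass is added to the
    stay-in-state probability; afterwards the base matrix applies.
    """
    T = spec.transitions
    if strategy is None:
        return T
    if cycle_index * spec.cycle_length >= strategy.effect_duration:
        return T
    T = T.copy()
    edges: list[tuple[int, int, float]] = []
    for key, rr in (
        ("stage3_to_4", strategy.rr_stage3_to_4),
        ("stage4_to_5", strategy.rr_stage4_to_5),
    ):
        if key in spec.stage_edges and rr != 1.0:
            a, b = spec.stage_edges[key]
            edges.append((spec.index(a), spec.index(b), rr))
    if strategy.rr_complications != 1.0:
        ev = {spec.index(s) for s in spec.event_states}
        for i in range(len(spec.states)):
            if i in ev or spec.states[i] == spec.dead_state:
                continue
            for j in ev:
                if T[i, j] > 0:
                    edges.append((i, j, strategy.rr_complications))
    for i, j, rr in edges:
        freed = T[i, j] * (1.0 - rr)
        T[i, j] -= freed
        T[i, i] += freed
        if T[i, i] > 1.0 + 1e-12 or T[i, j] < -1e-15:
            raise ValidationError(
                f"transitions: strategy modification drove row {spec.states[i]} out of [0, 1]"
            )
    return T


@dataclass
class CohortTrace:
    """State occupancy per cycle: row t is the start-of-cycle-t distribution."""

    states: tuple[str, ...]
    occupancy: np.ndarray  # (n_cycles + 1, S)
    matrices: list[np.ndarray]  # effective matrix used in each cycle

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(self.states))
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        return df


def run_cohort(spec: MarkovSpec, strategy: StrategyConfig | None = None) -> CohortTrace:
    """Propagate the start distribution through the (strategy-modified) chain.

    Mass is conserved each cycle.  A "lifetime" horizon stops when the
    cohort reaches age 100 or the living occupancy drops below 1e-6;
    a numeric horizon (years) stops after that many years.
    """
    d = spec.index(spec.dead_state)
    if spec.horizon == "lifetime":
        max_cycles = int(math.ceil((_MAX_AGE - spec.start_age) / spec.cycle_length))
    else:
        max_cycles = int(round(float(spec.horizon) / spec.cycle_length))
    max_cycles = max(max_cycles, 1)

    occ = [spec.start_distribution.copy()]
    mats = []
    for t in range(max_cycles):
        if spec.horizon == "lifetime" and 1.0 - occ[-1][d] < _LIVING_EPS:
            break
        M = apply_strategy(spec, strategy, t)
        nxt = occ[-1] @ M
        if abs(nxt.sum() - 1.0) > _MASS_TOL:
            raise ValidationError("transitions: occupancy mass not conserved")
        occ.append(nxt)
        mats.append(M)
    return CohortTrace(states=spec.states, occupancy=np.array(occ), matrices=mats)


def accumulate(
    trace: CohortTrace, spec: MarkovSpec, strategy: StrategyConfig | None = None
) -> tuple[float, float]:
    """Discounted total cost (Baht) and QALYs for a cohort trace.

    Per cycle t: state costs weighted by occupancy, plus the program cost
    charged to living states while the strategy is funded, plus one-off
    event costs on incident transitions into complication states; QALYs are
    occupancy-weighted utilities times cycle length.  Both streams are
    discounted by (1 + r)^(-t * cycle_length) at start-of-cycle accrual
    (mid-cycle when the half-cycle correction is enabled).
    """
    if trace.occupancy.shape[1] != len(spec.states):
        raise ValidationError("trace: state dimension does not match spec")
    d = spec.index(spec.dead_state)
    ev_idx = {spec.index(s): spec.event_costs.get(s, 0.0) for s in spec.event_states}
    cl = spec.cycle_length
    total_cost = 0.0
    total_qaly = 0.0
    for t in range(trace.n_cycles):
        occ = trace.occupancy[t]
        occ_acc = 0.5 * (occ + trace.occupancy[t + 1]) if spec.half_cycle_correction else occ
        df = (1.0 + spec.discount_rate) ** (-(t + (0.5 if spec.half_cycle_correction else 0.0)) * cl)
        cost = float(occ_acc @ spec.state_costs) * cl
        if strategy is not None and t * cl < strategy.effect_duration:
            living = 1.0 - occ_acc[d]
            cost += strategy.annual_program_cost * living * cl
        M = trace.matrices[t]
        for j, ec in ev_idx.items():
            if ec:
                incident = sum(occ[i] * M[i, j] for i in range(len(spec.states)) if i != j)
                cost += incident * ec
        total_cost += cost * df
        total_qaly += float(occ_acc @ spec.utilities) * cl * df
    return total_cost, total_qaly


@dataclass
class IcerResult:
    delta_cost: float
    delta_qalys: float
    icer: float | None
    label: str  # "icer", "dominant", "dominated", "undefined"


def icer(
    cost_intervention: float,
    qalys_intervention: float,
    cost_comparator: float,
    qalys_comparator: float,
) -> IcerResult:
    """Incremental cost-effectiveness ratio on unrounded totals.

    "dominant" when the intervention is cheaper and more effective,
    "dominated" when costlier and less effective, undefined when the QALY
    difference is zero.
    """
    dc = cost_intervention - cost_comparator
    de = qalys_intervention - qalys_comparator
    if de == 0.0:
        return IcerResult(dc, de, None, "undefined")
    if dc < 0 and de > 0:
        return IcerResult(dc, de, dc / de, "dominant")
    if dc > 0 and de < 0:
        return IcerResult(dc, de, dc / de, "dominated")
    return IcerResult(dc, de, dc / de, "icer")


@dataclass
class CeaResult:
    """Per-strategy discounted totals plus the incremental comparison."""

    intervention: str
    comparator: str
    cost_intervention: float
    qalys_intervention: float
    cost_comparator: float
    qalys_comparator: float
    incremental: IcerResult

    def as_dict(self) -> dict:
        return {
            "intervention": self.intervention,
            "comparator": self.comparator,
            "cost_intervention_baht": self.cost_intervention,
            "qalys_intervention": self.qalys_intervention,
            "cost_comparator_baht": self.cost_comparator,
            "qalys_comparator": self.qalys_comparator,
            "delta_cost_baht": self.incremental.delta_cost,
            "delta_qalys": self.incremental.delta_qalys,
            "icer_baht_per_qaly": self.incremental.icer,
            "label": self.incremental.label,
        }


def run_cea(
    spec: MarkovSpec,
    intervention: StrategyConfig,
    comparator: StrategyConfig | None = None,
) -> CeaResult:
    """Evaluate both strategies on the same spec and compare them."""
    comparator = comparator or null_strategy()
    ci, qi = accumulate(run_cohort(spec, intervention), spec, intervention)
    cc, qc = accumulate(run_cohort(spec, comparator), spec, comparator)
    return CeaResult(
        intervention=intervention.name,
        comparator=comparator.name,
        cost_intervention=ci,
        qalys_intervention=qi,
        cost_comparator=cc,
        qalys_comparator=qc,
        incremental=icer(ci, qi, cc, qc),
    )


def threshold_analysis(
    spec: MarkovSpec,
    strategy: StrategyConfig,
    cost_grid: Sequence[float],
    threshold: float,
    comparator: StrategyConfig | None = None,
) -> tuple[pd.DataFrame, float | None]:
    """ICER across a grid of annual program costs.

    Returns the per-grid-point table and the largest grid cost whose ICER
    stays at or below the willingness-to-pay threshold (None if none does).
    The ICER is non-decreasing in the annual program cost, all else fixed.
    """
    if len(cost_grid) == 0:
        raise ValidationError("cost_grid: must be non-empty")
    rows = []
    best = None
    for cost in cost_grid:
        res = run_cea(spec, replace(strategy, annual_program_cost=float(cost)), comparator)
        inc = res.incremental
        rows.append(
            {
                "annual_program_cost": float(cost),
                "delta_cost_baht": inc.delta_cost,
                "delta_qalys": inc.delta_qalys,
                "icer_baht_per_qaly": inc.icer,
                "label": inc.label,
            }
        )
        cost_effective = inc.label == "dominant" or (
            inc.icer is not None and inc.delta_qalys > 0 and inc.icer <= threshold
        )
        if cost_effective and (best is None or cost > best):
            best = float(cost)
    return pd.DataFrame(rows), best


_STRATEGY_FIELDS = {f.name for f in dataclasses.fields(StrategyConfig)}
_SPEC_SCALARS = {"discount_rate", "start_age", "half_cycle_correction"}


def _apply_overrides(
    spec: MarkovSpec, strategy: StrategyConfig, overrides: dict
) -> tuple[MarkovSpec, StrategyConfig]:
    for key, value in overrides.items():
        if key in _STRATEGY_FIELDS:
            strategy = replace(strategy, **{key: value})
        elif key in _SPEC_SCALARS:
            spec = replace(spec, **{key: value})
        elif key.startswith("state_cost:") or key.startswith("utility:"):
            kind, state = key.split(":", 1)
            idx = spec.index(state)
            arr = (spec.state_costs if kind == "state_cost" else spec.utilities).copy()
            arr[idx] = value
            spec = replace(spec, **{"state_costs" if kind == "state_cost" else "utilities": arr})
        elif key.startswith("event_cost:"):
            state = key.split(":", 1)[1]
            if state not in spec.event_costs:
                raise ValidationError(f"overrides: unknown event-cost state {state!r}")
            costs = dict(spec.event_costs)
            costs[state] = value
            spec = replace(spec, event_costs=costs)
        else:
            raise ValidationError(f"overrides: unknown parameter {key!r}")
    return spec, strategy


def scenario_analysis(
    spec: MarkovSpec,
    strategy: StrategyConfig,
    scenarios: dict[str, dict],
    comparator: StrategyConfig | None = None,
) -> pd.DataFrame:
    """One CEA per named scenario of parameter overrides.

    Override keys may name StrategyConfig fields, spec scalars
    (``discount_rate``, ``start_age``, ``half_cycle_correction``) or
    per-state economics (``state_cost:<state>``, ``utility:<state>``,
    ``event_cost:<state>``).  An empty override dict reproduces the base case.
    """
    rows = []
    for name, overrides in scenarios.items():
        s_spec, s_strategy = _apply_overrides(spec, strategy, overrides)
        res = run_cea(s_spec, s_strategy, comparator)
        rows.append({"scenario": name, **res.as_dict()})
    return pd.DataFrame(rows)


def one_way_analysis(
    spec: MarkovSpec,
    strategy: StrategyConfig,
    rel: float = 0.2,
    comparator: StrategyConfig | None = None,
) -> pd.DataFrame:
    """Tornado-style one-way sensitivity on each cost parameter (default ±20%).

    Rows are ordered by the width of the ICER swing, widest first.
    """
    params: dict[str, float] = {"annual_program_cost": strategy.annual_program_cost}
    for s, c in zip(spec.states, spec.state_costs):
        if c:
            params[f"state_cost:{s}"] = float(c)
    for s, c in spec.event_costs.items():
        if c:
            params[f"event_cost:{s}"] = float(c)
    rows = []
    for key, base_value in params.items():
        icers = []
        for mult in (1.0 - rel, 1.0 + rel):
            sc_spec, sc_strategy = _apply_overrides(spec, strategy, {key: base_value * mult})
            icers.append(run_cea(sc_spec, sc_strategy, comparator).incremental.icer)
        lo, hi = icers
        rows.append(
            {
                "parameter": key,
                "base_value": base_value,
                "icer_low": lo,
                "icer_high": hi,
                "swing": abs((hi if hi is not None else np.nan) - (lo if lo is not None else np.nan)),
            }
        )
    return pd.DataFrame(rows).sort_values("swing", ascending=False, ignore_index=True)


def psa(
    spec: MarkovSpec,
    strategy: StrategyConfig,
    sampler,
    n: int,
    seed: int = 0,
    comparator: StrategyConfig | None = None,
) -> pd.DataFrame:
    """Probabilistic sensitivity hook: user-supplied override sampler.

    ``sampler(rng)`` must return an override dict (same keys as
    :func:`scenario_analysis`).  The distributions are entirely the
    caller's; nothing here is calibrated to patient-level data.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n):
        s_spec, s_strategy = _apply_overrides(spec, strategy, sampler(rng))
        res = run_cea(s_spec, s_strategy, comparator)
        rows.append({"draw": k, **res.as_dict()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Parameter file IO
# ---------------------------------------------------------------------------


def _spec_from_dict(raw: dict) -> MarkovSpec:
    try:
        states = tuple(raw["states"])
        trans = raw["transitions"]
        costs = raw["costs"]
        utils = raw["utilities"]
        settings = raw.get("settings", {})
    except KeyError as e:
        raise ValidationError(f"params: missing section {e.args[0]!r}")
    S = len(states)
    T = np.zeros((S, S))
    for i, s in enumerate(states):
        row = trans.get(s)
        if row is None:
            raise ValidationError(f"transitions: missing row for state {s!r}")
        for dst, p in row.items():
            if dst not in states:
                raise ValidationError(f"transitions: unknown destination {dst!r}")
            T[i, states.index(dst)] = float(p)
        # any unassigned residual is the stay probability
        resid = 1.0 - T[i].sum() + T[i, i]
        if row.get(s) is None:
            if resid < -1e-9:
                raise ValidationError(f"transitions: row {s!r} exceeds probability 1")
            T[i, i] = max(resid, 0.0)
    return MarkovSpec(
        states=states,
        transitions=T,
        state_costs=np.array([float(costs["state"].get(s, 0.0)) for s in states]),
        utilities=np.array([float(utils.get(s, 0.0)) for s in states]),
        event_costs={k: float(v) for k, v in costs.get("event", {}).items()},
        event_states=tuple(raw.get("event_states", ())),
        dead_state=raw.get("dead_state", "dead"),
        stage_edges={k: tuple(v) for k, v in raw.get("stage_edges", {}).items()}
        or MarkovSpec.__dataclass_fields__["stage_edges"].default_factory(),
        discount_rate=float(settings.get("discount_rate", 0.03)),
        cycle_length=float(settings.get("cycle_length", 1.0)),
        start_distribution=np.array(
            [float(raw.get("start_distribution", {}).get(s, 0.0)) for s in states]
        )
        if raw.get("start_distribution")
        else None,
        start_age=float(settings.get("start_age", 60.0)),
        horizon=settings.get("horizon", "lifetime"),
        half_cycle_correction=bool(settings.get("half_cycle_correction", False)),
    )


def strategy_from_dict(raw: dict) -> StrategyConfig:
    unknown = set(raw) - _STRATEGY_FIELDS
    if unknown:
        raise ValidationError(f"strategy: unknown field(s) {sorted(unknown)}")
    return StrategyConfig(**raw)


def load_markov_spec(path) -> tuple[MarkovSpec, StrategyConfig]:
    """Load a YAML parameter file with sections states/transitions/costs/
    utilities/strategy/settings; returns the spec and the strategy."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    spec = _spec_from_dict(raw)
    strategy = strategy_from_dict(raw.get("strategy", {}))
    return spec, strategy


def default_markov_spec() -> tuple[MarkovSpec, StrategyConfig]:
    """The packaged synthetic CKD parameter set (see the data file header)."""
    with resources.files("ckdcare.data").joinpath("markov_params_synthetic.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    return _spec_from_dict(raw), strategy_from_dict(raw.get("strategy", {}))
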