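"""Individual-level microsimulation oracle and random-input generator.

The cohort engine tracks expected fractions; this module simulates the
same process child by child, drawing each chance node — cavity onset,
treatment allocation, restoration success — explicitly per cycle.  The
per-child means of any quantity are unbiased estimates of the cohort
model's expectations, which makes the microsimulation an independent
cross-check of every cohort-level result (occupancy, discounted cost,
each effectiveness measure).

`random_parameter_set` draws structurally valid parameter registries for
property testing: probabilities in range, treatment mix below one, a
protective relative risk, positive costs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .economics import EFFECTIVENESS_MODES, RewardSchedule
from .markov import HealthState, TransitionModel
from .parameters import ParameterSet, ParameterValue

__all__ = [
    "IndividualPath",
    "MicrosimPaths",
    "MicrosimSummary",
    "simulate_individuals",
    "summarize",
    "random_parameter_set",
    "write_paths",
]

# treatment outcome codes stored per (child, cycle)
_T_NONE = 0
_T_GIC_SUCCESS = 1
_T_GIC_FAILURE = 2
_T_HALL_SUCCESS = 3
_T_HALL_FAILURE = 4
_T_EXTRACTION = 5

_EVENT_NAMES = {
    _T_GIC_SUCCESS: "gic_success",
    _T_GIC_FAILURE: "gic_failure",
    _T_HALL_SUCCESS: "hall_success",
    _T_HALL_FAILURE: "hall_failure",
    _T_EXTRACTION: "extraction",
}


@dataclass(frozen=True)
class IndividualPath:
    """One child's state sequence and event log.

    ``states`` has length ``n_cycles + 1`` (entry state first); ``events``
    lists ``(cycle, event)`` pairs with event one of ``new_cavity``,
    ``gic_success``, ``gic_failure``, ``hall_success``, ``hall_failure``,
    ``extraction``.
    """

    child_id: int
    states: tuple[HealthState, ...]
    events: tuple[tuple[int, str], ...]


@dataclass(frozen=True)
class MicrosimPaths:
    """Vectorised container for all simulated paths.

    ``states[i, t]`` is child ``i``'s state at the end of cycle ``t``;
    ``new_cavity[i, t-1]`` and ``treatment[i, t-1]`` record what happened
    to the child during cycle ``t``.
    """

    model: TransitionModel
    seed: int
    states: np.ndarray
    new_cavity: np.ndarray
    treatment: np.ndarray

    @property
    def n_children(self) -> int:
        return self.states.shape[0]

    @property
    def n_cycles(self) -> int:
        return self.states.shape[1] - 1

    def __len__(self) -> int:
        return self.n_children

    def path(self, child_id: int) -> IndividualPath:
        events = []
        for t in range(1, self.n_cycles + 1):
            if self.new_cavity[child_id, t - 1]:
                events.append((t, "new_cavity"))
            code = int(self.treatment[child_id, t - 1])
            if code != _T_NONE:
                events.append((t, _EVENT_NAMES[code]))
        return IndividualPath(
            child_id=child_id,
            states=tuple(HealthState(int(s)) for s in self.states[child_id]),
            events=tuple(events),
        )

    def __iter__(self) -> Iterator[IndividualPath]:
        return (self.path(i) for i in range(self.n_children))


@dataclass(frozen=True)
class MicrosimSummary:
    """Per-child means over a simulated population."""

    n_children: int
    end_state_proportions: np.ndarray
    ever_cavity_fraction: float
    mean_discounted_cost: float
    mean_effectiveness: Mapping[str, float]


def simulate_individuals(
    model: TransitionModel, n: int, n_cycles: int, seed: int
) -> MicrosimPaths:
    """Simulate ``n`` children for ``n_cycles`` six-month cycles.

    Every child enters caries-free.  Within each cycle, a caries-free
    child may develop a cavity; a child with a cavity at cycle start is
    allocated a treatment (glass ionomer, Hall crown, or extraction) and
    its success resolved; a treated-history child may relapse.  All draws
    come from one seeded generator, so runs are exactly reproducible.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if n_cycles < 0:
        raise ValueError("n_cycles must be non-negative")
    rng = np.random.default_rng(seed)
    m = model.matrix
    p_nc = m[HealthState.NO_CAVITY, HealthState.CAVITY]
    p_prev = m[HealthState.PREVIOUS_CAVITY, HealthState.CAVITY]

    states = np.zeros((n, n_cycles + 1), dtype=np.int8)
    new_cavity = np.zeros((n, n_cycles), dtype=bool)
    treatment = np.zeros((n, n_cycles), dtype=np.int8)

    for t in range(1, n_cycles + 1):
        current = states[:, t - 1]
        nxt = current.copy()

        in_nc = current == HealthState.NO_CAVITY
        if in_nc.any():
            onset = rng.random(int(in_nc.sum())) < p_nc
            idx = np.nonzero(in_nc)[0][onset]
            nxt[idx] = HealthState.CAVITY
            new_cavity[idx, t - 1] = True

        in_pc = current == HealthState.PREVIOUS_CAVITY
        if in_pc.any():
            relapse = rng.random(int(in_pc.sum())) < p_prev
            idx = np.nonzero(in_pc)[0][relapse]
            nxt[idx] = HealthState.CAVITY
            new_cavity[idx, t - 1] = True

        in_c = np.nonzero(current == HealthState.CAVITY)[0]
        if in_c.size:
            u = rng.random(in_c.size)
            gic = u < model.q_gic
            hall = (~gic) & (u < model.q_gic + model.q_hall)
            ext = ~(gic | hall)
            success = np.empty(in_c.size, dtype=bool)
            success[gic] = rng.random(int(gic.sum())) < model.s_gic
            success[hall] = rng.random(int(hall.sum())) < model.s_hall
            success[ext] = True
            codes = np.where(
                ext,
                _T_EXTRACTION,
                np.where(
                    gic,
                    np.where(success, _T_GIC_SUCCESS, _T_GIC_FAILURE),
                    np.where(success, _T_HALL_SUCCESS, _T_HALL_FAILURE),
                ),
            )
            treatment[in_c, t - 1] = codes
            nxt[in_c[success]] = HealthState.PREVIOUS_CAVITY
            nxt[in_c[~success]] = HealthState.CAVITY
        states[:, t] = nxt

    return MicrosimPaths(
        model=model,
        seed=seed,
        states=states,
        new_cavity=new_cavity,
        treatment=treatment,
    )


def summarize(
    paths: MicrosimPaths,
    schedule: RewardSchedule,
    annual_rate: float = 0.05,
    cycle_length_years: float = 0.5,
    state_timing: str = "start",
) -> MicrosimSummary:
    """Per-child mean cost and effectiveness with the cohort conventions.

    Uses the same reward placement as the cohort engine — state cost read
    from the start-of-cycle state (configurable), treatment costs in the
    cycle they occur, varnish cost every cycle on the fv arm, everything
    discounted at the cycle-end factor — so means are directly comparable
    with `accumulate_costs` / `accumulate_effectiveness`.
    """
    if state_timing not in ("start", "end"):
        raise ValueError("state_timing must be 'start' or 'end'")
    n, n_cycles = paths.n_children, paths.n_cycles
    states = paths.states
    t = np.arange(1, n_cycles + 1)
    disc = (1.0 + annual_rate) ** (-t * cycle_length_years)

    end_props = np.array(
        [(states[:, -1] == s).mean() for s in HealthState]
    )
    ever_cavity = (states == HealthState.CAVITY).any(axis=1)

    state_costs = np.array([schedule.state_cost_per_cycle[s] for s in HealthState])
    occ_states = states[:, :-1] if state_timing == "start" else states[:, 1:]
    per_cycle_cost = state_costs[occ_states]
    event_cost_by_code = np.zeros(6)
    event_cost_by_code[[_T_GIC_SUCCESS, _T_GIC_FAILURE]] = schedule.event_costs["gic"]
    event_cost_by_code[[_T_HALL_SUCCESS, _T_HALL_FAILURE]] = schedule.event_costs["hall"]
    event_cost_by_code[_T_EXTRACTION] = schedule.event_costs["ext"]
    per_cycle_cost = per_cycle_cost + event_cost_by_code[paths.treatment]
    if paths.model.arm == "fv":
        per_cycle_cost = per_cycle_cost + schedule.fv_cost_per_cycle
    cost_per_child = per_cycle_cost @ disc

    end_states = states[:, 1:]
    eff = {
        "ever_cavity_avoided": float((~ever_cavity).mean()),
        "cavity_free_time": float(
            ((end_states == HealthState.NO_CAVITY) @ disc).mean() * cycle_length_years
        ),
        "expected_cavities": float((paths.new_cavity @ disc).mean()),
        "daly": float(
            ((end_states == HealthState.CAVITY) @ disc).mean()
            * cycle_length_years
            * schedule.daly_weight_per_year
        ),
    }
    assert set(eff) == set(EFFECTIVENESS_MODES)
    return MicrosimSummary(
        n_children=n,
        end_state_proportions=end_props,
        ever_cavity_fraction=float(ever_cavity.mean()),
        mean_discounted_cost=float(cost_per_child.mean()),
        mean_effectiveness=eff,
    )


def random_parameter_set(seed: int) -> ParameterSet:
    """Draw a structurally valid random parameter registry.

    Probabilities are uniform over plausible caries-model ranges with the
    treatment mix kept below one, the relative risk is protective
    (``(0.5, 1.0]``), and costs are positive.  Bounds are set to ±10%
    around each draw (clipped to the role's admissible range) so the
    registry passes every validation the packaged table passes.
    """
    rng = np.random.default_rng(seed)

    def u(lo: float, hi: float) -> float:
        return float(rng.uniform(lo, hi))

    probs = {
        "p_nocav_cavity": u(0.01, 0.25),
        "q_gic": u(0.4, 0.9),
        "q_hall": u(0.0, 0.05),
        "s_gic": u(0.3, 0.95),
        "s_hall": u(0.5, 0.99),
        "p_prev_cavity": u(0.05, 0.6),
    }
    eff_rr = u(0.5, 1.0)
    costs = {
        "c_routine": u(50.0, 250.0),
        "c_gic": u(80.0, 400.0),
        "c_hall": u(100.0, 500.0),
        "c_ext": u(80.0, 400.0),
        "c_fv": u(30.0, 150.0),
    }

    values = []
    for pid, p in probs.items():
        values.append(
            ParameterValue(
                id=pid,
                role="probability",
                arm="both" if pid.startswith(("q_", "s_")) else "standard",
                baseline=p,
                low=max(0.0, 0.9 * p),
                high=min(1.0, 1.1 * p),
                distribution="beta",
                note="randomly generated",
            )
        )
    values.append(
        ParameterValue(
            id="eff_rr",
            role="relative-risk",
            arm="fv",
            baseline=eff_rr,
            low=0.9 * eff_rr,
            high=min(1.0, 1.1 * eff_rr),
            distribution="lognormal",
            note="randomly generated",
        )
    )
    for pid, c in costs.items():
        values.append(
            ParameterValue(
                id=pid,
                role="cost",
                arm="fv" if pid == "c_fv" else "both",
                baseline=c,
                low=0.8 * c,
                high=1.2 * c,
                distribution="gamma",
                note="randomly generated",
            )
        )
    for pid, role, v in (
        ("daly_weight", "disability-weight", 0.01),
        ("discount_rate_annual", "rate", 0.05),
        ("n_cycles", "count", 8),
        ("cycle_length_years", "rate", 0.5),
        ("wtp_daly", "cost", 40000.0),
        ("wtp_cavity", "cost", 60.0),
    ):
        values.append(
            ParameterValue(
                id=pid,
                role=role,
                arm="both",
                baseline=float(v),
                low=float(v),
                high=float(v),
                distribution="fixed",
                note="model constant",
            )
        )
    return ParameterSet(values)


def write_paths(paths: MicrosimPaths, path: str | Path) -> None:
    """Export paths as long CSV: ``child_id,cycle,state,event``."""
    records = []
    for p in paths:
        events = dict()
        for cycle, ev in p.events:
            events.setdefault(cycle, []).append(ev)
        for t, state in enumerate(p.states):
            records.append(
                {
                    "child_id": p.child_id,
                    "cycle": t,
                    "state": state.name,
                    "event": ";".join(events.get(t, [])),
                }
            )
    pd.DataFrame.from_records(records).to_csv(path, index=False)
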