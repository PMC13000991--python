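"""Three-state Markov cohort engine for early-childhood caries.

States are NO_CAVITY (caries-free), CAVITY (at least one untreated
cavitated lesion), and PREVIOUS_CAVITY (treated history, no active
lesion).  Each cycle is six months.  A child in CAVITY at the start of a
cycle is treated during that cycle — restored with glass ionomer cement,
crowned with the Hall technique, or extracted — and ends the cycle in
PREVIOUS_CAVITY on treatment success (extraction always succeeds) or back
in CAVITY on restoration failure.  There is no direct edge from NO_CAVITY
to PREVIOUS_CAVITY, no remission without treatment, and no mortality or
dropout.  The fluoride-varnish arm differs only in the relative-risk-scaled
progression and failure probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .parameters import DerivationError, ParameterSet, derive_fv_probabilities

__all__ = [
    "HealthState",
    "TransitionModel",
    "CohortTrajectory",
    "ModelConstructionError",
    "build_transition_model",
    "propagate",
    "ever_cavity_probability",
    "write_trajectory",
]

_ROW_TOL = 1e-12


class ModelConstructionError(ValueError):
    """A transition matrix entry fell outside [0, 1] or rows don't close."""


class HealthState(IntEnum):
    """The three caries states tracked per six-month cycle."""

    NO_CAVITY = 0
    CAVITY = 1
    PREVIOUS_CAVITY = 2


@dataclass(frozen=True)
class TransitionModel:
    """Per-arm transition matrix plus the treatment mix behind it.

    The matrix rows follow :class:`HealthState` order.  The treatment mix
    and success probabilities are retained so downstream accounting can
    attribute expected treatment events, which the collapsed matrix alone
    cannot separate.
    """

    arm: str
    matrix: np.ndarray
    q_gic: float
    q_hall: float
    q_ext: float
    s_gic: float
    s_hall: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ModelConstructionError(f"matrix must be 3x3, got {m.shape}")
        if (m < -_ROW_TOL).any() or (m > 1 + _ROW_TOL).any():
            raise ModelConstructionError("matrix entries must lie in [0, 1]")
        rows = m.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=_ROW_TOL, rtol=0):
            raise ModelConstructionError(f"matrix rows must sum to 1, got {rows}")
        if m[HealthState.NO_CAVITY, HealthState.PREVIOUS_CAVITY] != 0.0:
            raise ModelConstructionError(
                "no direct transition from NO_CAVITY to PREVIOUS_CAVITY"
            )
        object.__setattr__(self, "matrix", m)

    @property
    def p_progress(self) -> float:
        """Per-cycle probability of a caries-free child developing a cavity."""
        return float(self.matrix[HealthState.NO_CAVITY, HealthState.CAVITY])


@dataclass(frozen=True)
class CohortTrajectory:
    """Cohort occupancy and expected event counts over the horizon.

    ``occupancy`` has shape ``(n_cycles + 1, 3)``; row ``t`` is the state
    distribution at the end of cycle ``t`` (row 0 is model entry).  Event
    arrays have length ``n_cycles``; entry ``t-1`` refers to cycle ``t``.
    ``new_cavity_inflow`` counts mass entering CAVITY from the two
    non-cavitated states (restoration failures keep a child in CAVITY and
    are not new entries).
    """

    occupancy: np.ndarray
    new_cavity_inflow: np.ndarray
    gic_events: np.ndarray
    hall_events: np.ndarray
    ext_events: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def end_occupancy(self) -> np.ndarray:
        return self.occupancy[-1]

    def state_series(self, state: HealthState) -> np.ndarray:
        """Occupancy of ``state`` at every cycle end, cycle 0 first."""
        return self.occupancy[:, int(state)]


def build_transition_model(
    params: ParameterSet,
    arm: str,
    overrides: Mapping[str, float] | None = None,
) -> TransitionModel:
    """Assemble the per-cycle transition matrix for one strategy arm.

    Parameters
    ----------
    params
        Validated parameter registry.
    arm
        ``"standard"`` or ``"fv"``.
    overrides
        Optional ``{parameter id: value}`` replacements applied before
        assembly.  Base ids (``p_nocav_cavity`` ...) override the
        standard-care inputs; ``fv_``-prefixed ids override the derived
        fluoride-varnish probabilities directly, which is how one-way
        sensitivity analysis applies the published bounds for those rows.
    """
    if arm not in ("standard", "fv"):
        raise ValueError(f"arm must be 'standard' or 'fv', got {arm!r}")
    ov = dict(overrides or {})

    def base(pid: str, value: float) -> float:
        return ov.get(pid, value)

    q_gic = base("q_gic", params.q_gic)
    q_hall = base("q_hall", params.q_hall)
    q_ext = 1.0 - q_gic - q_hall
    if q_ext < -_ROW_TOL:
        raise ModelConstructionError("treatment mix q_gic + q_hall exceeds 1")
    q_ext = max(0.0, q_ext)
    s_gic = base("s_gic", params.s_gic)
    s_hall = base("s_hall", params.s_hall)
    f_gic = 1.0 - s_gic
    f_hall = 1.0 - s_hall
    p_nc = base("p_nocav_cavity", params.p_nocav_cavity)
    p_prev = base("p_prev_cavity", params.p_prev_cavity)

    if arm == "fv":
        rr = base("eff_rr", params.eff_rr)
        if rr <= 0:
            raise DerivationError(f"relative risk must be positive, got {rr}")
        p_nc = ov.get("fv_p_nocav_cavity", p_nc * rr)
        f_gic = ov.get("fv_f_gic", f_gic * rr)
        f_hall = ov.get("fv_f_hall", f_hall * rr)
        p_prev = ov.get("fv_p_prev_cavity", p_prev * rr)

    for name, p in (
        ("p_nocav_cavity", p_nc),
        ("f_gic", f_gic),
        ("f_hall", f_hall),
        ("p_prev_cavity", p_prev),
    ):
        if not (0.0 <= p <= 1.0):
            raise ModelConstructionError(f"{arm} arm: {name} = {p} outside [0, 1]")

    # Treated-cavity resolution within the cycle: stay on failure,
    # move to PREVIOUS_CAVITY on success (extraction always succeeds).
    stay_cavity = q_gic * f_gic + q_hall * f_hall
    to_previous = q_gic * (1.0 - f_gic) + q_hall * (1.0 - f_hall) + q_ext
    matrix = np.array(
        [
            [1.0 - p_nc, p_nc, 0.0],
            [0.0, stay_cavity, to_previous],
            [0.0, p_prev, 1.0 - p_prev],
        ]
    )
    # Retain the arm-effective success probabilities (failure complements
    # after any relative-risk scaling) so event attribution matches the
    # collapsed matrix.
    return TransitionModel(
        arm=arm,
        matrix=matrix,
        q_gic=q_gic,
        q_hall=q_hall,
        q_ext=q_ext,
        s_gic=1.0 - f_gic,
        s_hall=1.0 - f_hall,
    )


def propagate(
    model: TransitionModel,
    n_cycles: int,
    init: np.ndarray | None = None,
) -> CohortTrajectory:
    """Propagate a cohort distribution through ``n_cycles`` cycles.

    ``init`` defaults to the whole cohort entering caries-free.  Expected
    treatment events in cycle ``t`` are attributed from the CAVITY
    occupancy at the start of that cycle times the treatment mix.
    """
    if n_cycles < 0:
        raise ValueError("n_cycles must be non-negative")
    if init is None:
        init = np.array([1.0, 0.0, 0.0])
    init = np.asarray(init, dtype=float)
    if init.shape != (3,) or (init < 0).any() or abs(init.sum() - 1.0) > 1e-10:
        raise ValueError("init must be a probability distribution over 3 states")

    m = model.matrix
    occ = np.empty((n_cycles + 1, 3))
    occ[0] = init
    inflow = np.empty(n_cycles)
    gic = np.empty(n_cycles)
    hall = np.empty(n_cycles)
    ext = np.empty(n_cycles)
    for t in range(1, n_cycles + 1):
        start = occ[t - 1]
        occ[t] = start @ m
        inflow[t - 1] = (
            start[HealthState.NO_CAVITY] * m[HealthState.NO_CAVITY, HealthState.CAVITY]
            + start[HealthState.PREVIOUS_CAVITY]
            * m[HealthState.PREVIOUS_CAVITY, HealthState.CAVITY]
        )
        in_cavity = start[HealthState.CAVITY]
        gic[t - 1] = in_cavity * model.q_gic
        hall[t - 1] = in_cavity * model.q_hall
        ext[t - 1] = in_cavity * model.q_ext
    return CohortTrajectory(
        occupancy=occ,
        new_cavity_inflow=inflow,
        gic_events=gic,
        hall_events=hall,
        ext_events=ext,
    )


def ever_cavity_probability(p_nc: float, n_cycles: int) -> float:
    """Probability a child entering caries-free ever develops a cavity.

    With no inflow back into NO_CAVITY this is ``1 - (1 - p_nc)**n``.
    """
    if not (0.0 <= p_nc <= 1.0):
        raise ValueError(f"p_nc must lie in [0, 1], got {p_nc}")
    if n_cycles < 0:
        raise ValueError("n_cycles must be non-negative")
    return 1.0 - (1.0 - p_nc) ** n_cycles


def write_trajectory(traj: CohortTrajectory, path: str | Path) -> None:
    """Write a trajectory as long-format CSV, one row per cycle and state."""
    records = []
    for t in range(traj.n_cycles + 1):
        for state in HealthState:
            records.append(
                {
                    "cycle": t,
                    "state": state.name,
                    "occupancy": traj.occupancy[t, int(state)],
                    "new_cavity_inflow": traj.new_cavity_inflow[t - 1] if t else 0.0,
                    "gic_events": traj.gic_events[t - 1] if t else 0.0,
                    "hall_events": traj.hall_events[t - 1] if t else 0.0,
                    "ext_events": traj.ext_events[t - 1] if t else 0.0,
                }
            )
    pd.DataFrame.from_records(records).to_csv(path, index=False)
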