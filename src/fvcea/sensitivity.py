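"""Deterministic and probabilistic sensitivity analysis.

One-way (tornado) analysis re-runs the full two-arm comparison with a
single parameter pushed to each of its published bounds.  Probabilistic
analysis samples all uncertain parameters jointly — beta for
probabilities (method of moments from the mean and 95% CI), gamma for
costs (coefficient of variation fixed at 20%), lognormal for the varnish
relative risk (median at the point estimate, log-scale spread from the
CI) — rebuilds both arms per iteration, and summarises the incremental
cost/effect cloud as cost-effectiveness acceptability curves.

Sampling is independent across parameters; the fluoride-varnish arm's
probabilities are re-derived from each iteration's sampled standard-care
probabilities and relative risk, and chance-node complements are closed
after sampling so every node remains a distribution.  Draws that violate
joint constraints (treatment mix exceeding one, a relative-risk product
above one) are rejected and redrawn, preserving the fitted shapes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .economics import EFFECTIVENESS_MODES, CEAResult, run_cea
from .parameters import FV_DERIVED_IDS, ParameterSet, ParameterValue

__all__ = [
    "DistributionFitError",
    "DistributionSpec",
    "TornadoEntry",
    "PSASampleSet",
    "CEACCurve",
    "fit_beta_from_mean_ci",
    "fit_gamma_cv20",
    "fit_lognormal_rr",
    "fit_parameter",
    "one_way_dsa",
    "tornado",
    "run_psa",
    "ceac",
    "default_wtp_grid",
    "write_tornado",
    "write_psa_samples",
    "write_ceac",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile
_BETA_CAP = 1e9  # shape cap above which the fit degenerates to a point mass
_MAX_REJECT = 1000


class DistributionFitError(ValueError):
    """The requested family cannot match the stated mean and spread."""


@dataclass(frozen=True)
class DistributionSpec:
    """A fitted sampling distribution for one parameter.

    ``family`` is ``beta``, ``gamma``, ``lognormal`` or ``fixed``;
    ``shape`` holds the family-specific parameters (``alpha``/``beta``,
    ``shape``/``scale``, ``mu``/``sigma``, or ``value``).
    """

    family: str
    shape: Mapping[str, float]
    source_mean: float
    source_low: float
    source_high: float

    def sample(self, rng: np.random.Generator, size: int | None = None):
        if self.family == "beta":
            return rng.beta(self.shape["alpha"], self.shape["beta"], size=size)
        if self.family == "gamma":
            return rng.gamma(self.shape["shape"], self.shape["scale"], size=size)
        if self.family == "lognormal":
            return rng.lognormal(self.shape["mu"], self.shape["sigma"], size=size)
        if self.family == "fixed":
            v = self.shape["value"]
            return v if size is None else np.full(size, v)
        raise ValueError(f"unknown family {self.family!r}")


@dataclass(frozen=True)
class TornadoEntry:
    """One bar of the tornado: ICER at each bound of a single parameter."""

    parameter_id: str
    icer_low: float
    icer_high: float
    increases_icer: bool | None

    @property
    def width(self) -> float:
        if math.isnan(self.icer_low) or math.isnan(self.icer_high):
            return math.nan
        return abs(self.icer_high - self.icer_low)


@dataclass(frozen=True)
class PSASampleSet:
    """Monte-Carlo draws with their incremental outcomes.

    ``samples`` holds one row per iteration: the sampled parameter values
    and the incremental cost and incremental effectiveness for each
    requested outcome (columns ``d_cost`` and ``d_effect_<mode>``).
    """

    seed: int
    n_iter: int
    modes: tuple[str, ...]
    samples: pd.DataFrame
    n_rejections: int

    def d_cost(self) -> np.ndarray:
        return self.samples["d_cost"].to_numpy()

    def d_effect(self, mode: str) -> np.ndarray:
        return self.samples[f"d_effect_{mode}"].to_numpy()


@dataclass(frozen=True)
class CEACCurve:
    """Acceptance probability as a function of willingness to pay."""

    mode: str
    wtp: np.ndarray
    probability: np.ndarray

    def crossing(self, level: float = 0.5) -> float:
        """Smallest grid WTP at which the probability reaches ``level``."""
        above = np.nonzero(self.probability >= level)[0]
        return float(self.wtp[above[0]]) if above.size else math.nan


# ---------------------------------------------------------------------------
# distribution fitting


def fit_beta_from_mean_ci(mean: float, low: float, high: float) -> DistributionSpec:
    """Method-of-moments beta fit from a mean and its 95% interval.

    The standard deviation is read off the interval width,
    ``s = (high - low) / (2 * 1.96)``, then ``alpha = mean * k`` and
    ``beta = (1 - mean) * k`` with ``k = mean (1 - mean) / s^2 - 1``.
    Degenerate spreads (``low == high`` or shapes beyond a cap) collapse
    to a point mass at the mean.
    """
    if not (0.0 < mean < 1.0):
        raise DistributionFitError(f"beta mean must lie in (0, 1), got {mean}")
    if low > high:
        raise DistributionFitError(f"bounds out of order: ({low}, {high})")
    s = (high - low) / (2.0 * _Z95)
    if s == 0.0:
        return DistributionSpec("fixed", {"value": mean}, mean, low, high)
    var = s * s
    if var >= mean * (1.0 - mean):
        raise DistributionFitError(
            f"variance {var} too large for a beta with mean {mean}"
        )
    k = mean * (1.0 - mean) / var - 1.0
    alpha, beta = mean * k, (1.0 - mean) * k
    if alpha > _BETA_CAP or beta > _BETA_CAP:
        return DistributionSpec("fixed", {"value": mean}, mean, low, high)
    return DistributionSpec("beta", {"alpha": alpha, "beta": beta}, mean, low, high)


def fit_gamma_cv20(mean: float) -> DistributionSpec:
    """Gamma fit with the standard deviation set to 20% of the mean.

    The coefficient of variation fixes ``shape = (1 / 0.2)^2 = 25``;
    ``scale = mean / 25`` then reproduces the mean exactly.
    """
    if mean <= 0:
        raise DistributionFitError(f"gamma mean must be positive, got {mean}")
    shape = 25.0
    return DistributionSpec(
        "gamma",
        {"shape": shape, "scale": mean / shape},
        mean,
        0.8 * mean,
        1.2 * mean,
    )


def fit_lognormal_rr(rr: float, low: float, high: float) -> DistributionSpec:
    """Lognormal fit for a relative risk with a 95% confidence interval.

    The median is pinned at the point estimate (``mu = ln rr``) and the
    log-scale spread comes from the CI,
    ``sigma = (ln high - ln low) / (2 * 1.96)``.  A zero-width interval
    collapses to a point mass.
    """
    if low <= 0 or high <= 0 or rr <= 0:
        raise DistributionFitError("relative risk and bounds must be positive")
    if not (low <= rr <= high):
        raise DistributionFitError(f"bounds must bracket the estimate: {low} {rr} {high}")
    if low == high:
        return DistributionSpec("fixed", {"value": rr}, rr, low, high)
    sigma = (math.log(high) - math.log(low)) / (2.0 * _Z95)
    return DistributionSpec(
        "lognormal", {"mu": math.log(rr), "sigma": sigma}, rr, low, high
    )


def fit_parameter(pv: ParameterValue) -> DistributionSpec:
    """Fit the declared family of one registered parameter."""
    if pv.distribution == "fixed" or pv.low == pv.high:
        return DistributionSpec("fixed", {"value": pv.baseline}, pv.baseline, pv.low, pv.high)
    if pv.distribution == "beta":
        return fit_beta_from_mean_ci(pv.baseline, pv.low, pv.high)
    if pv.distribution == "gamma":
        return fit_gamma_cv20(pv.baseline)
    if pv.distribution == "lognormal":
        return fit_lognormal_rr(pv.baseline, pv.low, pv.high)
    raise DistributionFitError(f"{pv.id}: unknown distribution {pv.distribution!r}")


# ---------------------------------------------------------------------------
# deterministic (one-way) sensitivity analysis


def one_way_dsa(
    params: ParameterSet,
    mode: str,
    varied_id: str,
    state_timing: str = "start",
) -> TornadoEntry:
    """Recompute the ICER with one parameter at each of its bounds.

    All other parameters stay at baseline.  ``fv_``-prefixed ids replace
    the derived fluoride-varnish probability directly, using the published
    bounds for those rows.
    """
    pv = params.value(varied_id)
    icers = {}
    for bound_name, bound in (("low", pv.low), ("high", pv.high)):
        result = run_cea(
            params, mode, overrides={varied_id: bound}, state_timing=state_timing
        )
        icers[bound_name] = result.icer
    direction: bool | None
    if math.isnan(icers["low"]) or math.isnan(icers["high"]):
        direction = None
    else:
        direction = icers["high"] > icers["low"]
    return TornadoEntry(
        parameter_id=varied_id,
        icer_low=icers["low"],
        icer_high=icers["high"],
        increases_icer=direction,
    )


def tornado(
    params: ParameterSet,
    mode: str = "ever_cavity_avoided",
    varied_ids: Sequence[str] | None = None,
    state_timing: str = "start",
) -> list[TornadoEntry]:
    """One-way analysis over every uncertain parameter, widest bar first.

    By default only independent inputs are varied: the fluoride-varnish
    arm's derived probabilities are relative-risk expressions (their
    published bounds are the products of the relative risk with the base
    parameters' bounds), so they co-vary with their inputs rather than
    forming bars of their own.  Pass ``varied_ids`` explicitly to vary a
    derived row at its published bounds.
    """
    if varied_ids is None:
        varied_ids = [
            pid
            for pid in params.ids()
            if params.value(pid).distribution != "fixed"
            and pid not in FV_DERIVED_IDS
        ]
    entries = [one_way_dsa(params, mode, pid, state_timing) for pid in varied_ids]
    return sorted(
        entries,
        key=lambda e: -1.0 if math.isnan(e.width) else e.width,
        reverse=True,
    )


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis

#: Parameters sampled in the PSA.  The fluoride-varnish probabilities are
#: derived per iteration from these, not sampled separately.
PSA_SAMPLED_IDS = (
    "p_nocav_cavity",
    "q_gic",
    "q_hall",
    "s_gic",
    "s_hall",
    "p_prev_cavity",
    "eff_rr",
    "c_routine",
    "c_gic",
    "c_hall",
    "c_ext",
    "c_fv",
)


def _draw_iteration(
    specs: Mapping[str, DistributionSpec], rng: np.random.Generator
) -> tuple[dict[str, float], int]:
    """One joint parameter draw with rejection of invalid combinations."""
    rejections = 0
    for _ in range(_MAX_REJECT):
        draw = {pid: float(spec.sample(rng)) for pid, spec in specs.items()}
        rr = draw["eff_rr"]
        if draw["q_gic"] + draw["q_hall"] > 1.0:
            rejections += 1
            continue
        fv_products = (
            draw["p_nocav_cavity"] * rr,
            (1.0 - draw["s_gic"]) * rr,
            (1.0 - draw["s_hall"]) * rr,
            draw["p_prev_cavity"] * rr,
        )
        if any(p > 1.0 for p in fv_products):
            rejections += 1
            continue
        return draw, rejections
    raise RuntimeError("rejection sampling failed to find a valid parameter draw")


def run_psa(
    params: ParameterSet,
    n_iter: int = 1000,
    seed: int = 0,
    modes: Sequence[str] = ("ever_cavity_avoided", "daly"),
    state_timing: str = "start",
) -> PSASampleSet:
    """Monte-Carlo probabilistic sensitivity analysis.

    Each iteration draws every uncertain parameter from its fitted
    distribution (independently, with rejection of jointly invalid draws),
    re-derives the varnish arm, runs the full two-arm comparison for each
    requested outcome, and records the incremental cost and effect.
    Iteration ``k`` uses its own deterministic substream of ``seed``, so
    runs are exactly reproducible and any iteration can be replayed alone.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")
    for mode in modes:
        if mode not in EFFECTIVENESS_MODES:
            raise ValueError(f"unknown effectiveness mode {mode!r}")
    specs = {pid: fit_parameter(params.value(pid)) for pid in PSA_SAMPLED_IDS}
    records = []
    total_rejections = 0
    for k in range(n_iter):
        rng = np.random.default_rng([seed, k])
        draw, rej = _draw_iteration(specs, rng)
        total_rejections += rej
        row: dict[str, float] = {"iteration": k, **draw}
        for i, mode in enumerate(modes):
            result = run_cea(params, mode, overrides=draw, state_timing=state_timing)
            if i == 0:
                row["d_cost"] = result.incr_cost
            row[f"d_effect_{mode}"] = result.incr_effect
        records.append(row)
    frame = pd.DataFrame.from_records(records)
    return PSASampleSet(
        seed=seed,
        n_iter=n_iter,
        modes=tuple(modes),
        samples=frame,
        n_rejections=total_rejections,
    )


def default_wtp_grid(icer: float, n_steps: int = 200) -> np.ndarray:
    """Grid from 0 to twice the deterministic ICER, inclusive."""
    if not math.isfinite(icer) or icer <= 0:
        raise ValueError(f"need a positive finite ICER to scale the grid, got {icer}")
    return np.linspace(0.0, 2.0 * icer, n_steps + 1)


def ceac(
    samples: PSASampleSet, wtp_grid: np.ndarray, mode: str | None = None
) -> CEACCurve:
    """Cost-effectiveness acceptability curve from PSA samples.

    At each willingness-to-pay value the curve reports the fraction of
    iterations whose net monetary benefit ``wtp * dE - dC`` is
    non-negative.
    """
    wtp = np.asarray(wtp_grid, dtype=float)
    if wtp.size == 0:
        raise ValueError("WTP grid must be non-empty")
    if mode is None:
        mode = samples.modes[0]
    d_cost = samples.d_cost()
    d_eff = samples.d_effect(mode)
    nmb = wtp[:, None] * d_eff[None, :] - d_cost[None, :]
    probability = (nmb >= 0).mean(axis=1)
    return CEACCurve(mode=mode, wtp=wtp, probability=probability)


# ---------------------------------------------------------------------------
# writers


def write_tornado(entries: Sequence[TornadoEntry], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "parameter": e.parameter_id,
                "icer_low": e.icer_low,
                "icer_high": e.icer_high,
                "width": e.width,
                "increases_icer": e.increases_icer,
            }
            for e in entries
        ]
    ).to_csv(path, index=False)


def write_psa_samples(samples: PSASampleSet, path: str | Path) -> None:
    samples.samples.to_csv(path, index=False)


def write_ceac(curves: Sequence[CEACCurve], path: str | Path) -> None:
    frames = [
        pd.DataFrame({"outcome": c.mode, "wtp": c.wtp, "probability": c.probability})
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
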