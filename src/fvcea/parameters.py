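"""Parameter registry for the fluoride-varnish cost-effectiveness model.

The model is driven entirely by a small table of published quantities:
six-month transition probabilities for the caries process in the primary
dentition, the treatment mix a cavitated child receives (glass ionomer
cement, Hall-technique crown, or extraction) with per-cycle success
probabilities, procedure and visit costs in 2022 Brazilian Reais, the
pooled relative risk of fluoride varnish, and the model constants
(discount rate, horizon, cycle length, DALY disability weight,
willingness-to-pay thresholds).

The default table ships with the package as a CSV file; user-supplied
files with the same schema are accepted.  The fluoride-varnish arm's
progression and failure probabilities are derived from the standard-care
arm by multiplying with the relative risk; branch probabilities left
unstated in the source table are closed so every chance node sums to one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "ParameterError",
    "ParameterLoadError",
    "ParameterValidationError",
    "DerivationError",
    "ParameterValue",
    "ParameterSet",
    "FvProbabilities",
    "load_parameter_table",
    "write_parameter_table",
    "default_parameter_path",
    "derive_fv_probabilities",
    "close_complements",
]

ROLES = frozenset(
    {"probability", "cost", "relative-risk", "disability-weight", "rate", "count"}
)
ARMS = frozenset({"standard", "fv", "both"})
DISTRIBUTIONS = frozenset({"beta", "gamma", "lognormal", "fixed"})

#: Parameter ids that must be present in every parameter file.
REQUIRED_IDS = (
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
    "daly_weight",
    "discount_rate_annual",
    "n_cycles",
    "cycle_length_years",
    "wtp_daly",
    "wtp_cavity",
)

#: Derived fluoride-varnish probabilities; optional in user files.  When
#: present they carry the published one-way sensitivity bounds, which are
#: not exact baseline-times-bound products of the underlying parameters.
FV_DERIVED_IDS = (
    "fv_p_nocav_cavity",
    "fv_f_gic",
    "fv_f_hall",
    "fv_p_prev_cavity",
)

_CSV_COLUMNS = ["id", "role", "arm", "baseline", "low", "high", "distribution", "note"]

_SUM_TOL = 1e-12


class ParameterError(ValueError):
    """Base class for parameter-file and parameter-value problems."""


class ParameterLoadError(ParameterError):
    """A parameter file is missing, malformed, or lacks a required id."""


class ParameterValidationError(ParameterError):
    """A parameter value violates its role-specific bounds or ordering."""


class DerivationError(ParameterError):
    """A derived quantity (relative-risk product, complement) is invalid."""


@dataclass(frozen=True)
class ParameterValue:
    """One registered model quantity with its uncertainty bounds.

    ``low`` and ``high`` are the 95% confidence bounds where the source
    reports one, or the one-way sensitivity limits otherwise; for fixed
    quantities they equal the baseline.
    """

    id: str
    role: str
    arm: str
    baseline: float
    low: float
    high: float
    distribution: str
    note: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ParameterValidationError(
                f"{self.id}: unknown role {self.role!r}"
            )
        if self.arm not in ARMS:
            raise ParameterValidationError(f"{self.id}: unknown arm {self.arm!r}")
        if self.distribution not in DISTRIBUTIONS:
            raise ParameterValidationError(
                f"{self.id}: unknown distribution {self.distribution!r}"
            )
        if not (self.low <= self.baseline <= self.high):
            raise ParameterValidationError(
                f"{self.id}: bounds must satisfy low <= baseline <= high, "
                f"got ({self.low}, {self.baseline}, {self.high})"
            )
        if self.role == "probability":
            if not (0.0 <= self.low and self.high <= 1.0):
                raise ParameterValidationError(
                    f"{self.id}: probability bounds must lie in [0, 1], "
                    f"got ({self.low}, {self.high})"
                )
        elif self.role == "cost":
            if self.low < 0.0:
                raise ParameterValidationError(
                    f"{self.id}: cost must be non-negative, got low={self.low}"
                )
        elif self.role == "relative-risk":
            if self.low <= 0.0:
                raise ParameterValidationError(
                    f"{self.id}: relative risk must be positive, got low={self.low}"
                )
        elif self.role == "disability-weight":
            if not (0.0 <= self.low and self.high <= 1.0):
                raise ParameterValidationError(
                    f"{self.id}: disability weight must lie in [0, 1]"
                )


@dataclass(frozen=True)
class FvProbabilities:
    """Fluoride-varnish arm probabilities derived via the relative risk.

    Progression and restoration-failure probabilities are the standard-care
    values multiplied by the relative risk; the treatment-mix probabilities
    are carried over unchanged because the varnish modifies caries activity,
    not the choice of treatment once a cavity exists.
    """

    p_nocav_cavity: float
    f_gic: float
    f_hall: float
    p_prev_cavity: float
    q_gic: float
    q_hall: float
    q_ext: float


class ParameterSet:
    """Validated registry of every model parameter.

    Provides attribute access to baseline values (``params.p_nocav_cavity``),
    the closed complements (``q_ext``, ``f_gic``, ``f_hall``), and the full
    :class:`ParameterValue` records via :meth:`value`.
    """

    def __init__(self, values: Iterable[ParameterValue]):
        registry: dict[str, ParameterValue] = {}
        for v in values:
            if v.id in registry:
                raise ParameterLoadError(f"duplicate parameter id {v.id!r}")
            registry[v.id] = v
        missing = [pid for pid in REQUIRED_IDS if pid not in registry]
        if missing:
            raise ParameterLoadError(
                "parameter file is missing required id(s): " + ", ".join(missing)
            )
        self._registry = registry
        # Treatment mix must leave room for the extraction complement.
        close_complements(
            {"q_gic": registry["q_gic"].baseline, "q_hall": registry["q_hall"].baseline},
            node="treatment mix",
        )
        if registry["n_cycles"].baseline != int(registry["n_cycles"].baseline):
            raise ParameterValidationError("n_cycles must be an integer")
        if registry["cycle_length_years"].baseline <= 0:
            raise ParameterValidationError("cycle_length_years must be positive")
        if registry["discount_rate_annual"].baseline <= -1:
            raise ParameterValidationError("discount_rate_annual must exceed -1")

    # -- access ---------------------------------------------------------

    def value(self, pid: str) -> ParameterValue:
        """Return the full record for ``pid`` (baseline, bounds, family)."""
        try:
            return self._registry[pid]
        except KeyError:
            raise ParameterLoadError(f"unknown parameter id {pid!r}") from None

    def ids(self) -> tuple[str, ...]:
        return tuple(self._registry)

    def __contains__(self, pid: str) -> bool:
        return pid in self._registry

    def __getattr__(self, name: str) -> float:
        registry = object.__getattribute__(self, "_registry")
        if name in registry:
            return registry[name].baseline
        raise AttributeError(name)

    # -- closed complements --------------------------------------------

    @property
    def q_ext(self) -> float:
        """Extraction share of the treatment mix (closed complement)."""
        closed = close_complements(
            {"q_gic": self.q_gic, "q_hall": self.q_hall}, node="treatment mix"
        )
        return closed["#"]

    @property
    def f_gic(self) -> float:
        """Glass-ionomer failure probability, complement of success."""
        return close_complements({"s_gic": self.s_gic}, node="glass ionomer")["#"]

    @property
    def f_hall(self) -> float:
        """Hall-technique failure probability, complement of success."""
        return close_complements({"s_hall": self.s_hall}, node="Hall technique")["#"]

    @property
    def horizon_years(self) -> float:
        return self.n_cycles * self.cycle_length_years

    # -- modification ---------------------------------------------------

    def with_value(self, pid: str, baseline: float) -> "ParameterSet":
        """Return a copy with ``pid``'s baseline replaced (bounds widened
        to admit the new value, so one-way sensitivity runs validate)."""
        v = self.value(pid)
        new = replace(
            v,
            baseline=baseline,
            low=min(v.low, baseline),
            high=max(v.high, baseline),
        )
        values = [new if x.id == pid else x for x in self._registry.values()]
        return ParameterSet(values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": v.id,
                    "role": v.role,
                    "arm": v.arm,
                    "baseline": v.baseline,
                    "low": v.low,
                    "high": v.high,
                    "distribution": v.distribution,
                    "note": v.note,
                }
                for v in self._registry.values()
            ],
            columns=_CSV_COLUMNS,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParameterSet):
            return NotImplemented
        return self._registry == other._registry

    def __repr__(self) -> str:
        return f"ParameterSet({len(self._registry)} parameters)"


def default_parameter_path() -> Path:
    """Path of the packaged default parameter table."""
    return Path(resources.files("fvcea").joinpath("data/table1_parameters.csv"))


def load_parameter_table(path: str | Path | None = None) -> ParameterSet:
    """Read a parameter CSV and return a validated :class:`ParameterSet`.

    Parameters
    ----------
    path
        CSV file with header ``id,role,arm,baseline,low,high,distribution,note``.
        ``None`` loads the packaged default table.
    """
    if path is None:
        path = default_parameter_path()
    path = Path(path)
    if not path.exists():
        raise ParameterLoadError(f"parameter file not found: {path}")
    try:
        frame = pd.read_csv(path, dtype={"note": str}, keep_default_na=False)
    except Exception as exc:  # malformed CSV
        raise ParameterLoadError(f"cannot parse parameter file {path}: {exc}") from exc
    missing_cols = [c for c in _CSV_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ParameterLoadError(
            f"parameter file {path} lacks column(s): {', '.join(missing_cols)}"
        )
    values = []
    for row in frame.itertuples(index=False):
        values.append(
            ParameterValue(
                id=str(row.id),
                role=str(row.role),
                arm=str(row.arm),
                baseline=float(row.baseline),
                low=float(row.low),
                high=float(row.high),
                distribution=str(row.distribution),
                note=str(row.note),
            )
        )
    return ParameterSet(values)


def write_parameter_table(params: ParameterSet, path: str | Path) -> None:
    """Write ``params`` to CSV in the same dialect the loader reads."""
    params.to_frame().to_csv(path, index=False)


def close_complements(
    stated: Mapping[str, float], node: str = "chance node"
) -> dict[str, float]:
    """Complete a chance node whose unstated branch is a complement.

    ``stated`` maps branch names to probabilities; the returned dict adds a
    ``"#"`` entry holding ``1 - sum(stated)`` so the node sums to one, the
    convention the source table uses for branches it leaves implicit.

    Raises :class:`DerivationError` if the stated branches already exceed 1.
    """
    total = math.fsum(stated.values())
    for name, p in stated.items():
        if not (0.0 <= p <= 1.0):
            raise DerivationError(f"{node}: branch {name!r} = {p} outside [0, 1]")
    if total > 1.0 + _SUM_TOL:
        raise DerivationError(
            f"{node}: stated branch probabilities sum to {total} > 1"
        )
    closed = dict(stated)
    closed["#"] = max(0.0, 1.0 - total)
    return closed


def derive_fv_probabilities(
    params: ParameterSet, eff_rr: float | None = None
) -> FvProbabilities:
    """Derive the fluoride-varnish arm's probabilities from standard care.

    The relative risk multiplies exactly the four probabilities the source
    scales: progression no-cavity to cavity, glass-ionomer failure,
    Hall-technique failure, and relapse from previous-cavity.  The
    treatment mix is unchanged.

    Raises :class:`DerivationError` if any product exceeds 1.
    """
    rr = params.eff_rr if eff_rr is None else eff_rr
    if rr <= 0:
        raise DerivationError(f"relative risk must be positive, got {rr}")
    scaled = {
        "p_nocav_cavity": params.p_nocav_cavity * rr,
        "f_gic": params.f_gic * rr,
        "f_hall": params.f_hall * rr,
        "p_prev_cavity": params.p_prev_cavity * rr,
    }
    for name, p in scaled.items():
        if p > 1.0:
            raise DerivationError(
                f"relative-risk product {name} = {p} exceeds 1"
            )
    return FvProbabilities(
        **scaled,
        q_gic=params.q_gic,
        q_hall=params.q_hall,
        q_ext=params.q_ext,
    )
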