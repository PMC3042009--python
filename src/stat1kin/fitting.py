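"""Multi-dose parameter estimation by SEM-weighted least squares.

The cost is the classic chi-square over all observables k and time points l,

    chi2(theta) = sum_k sum_l ((y_exp - y_mod) / sigma_exp)**2,

where each dose is simulated with its own local parameters plus the shared
global ones, and model series are mapped to the data conventions of
:mod:`stat1kin.observables` (blot series scaled by a WB gain, mRNA series
normalized to their time average, RSNC compared directly).

Optimization is a hybrid: seeded simulated-annealing chains explore the
(log-transformed) parameter box globally, and the best point is refined with
a bounded trust-region least-squares search.  Free immunoblot scaling
factors are conditionally linear in the residuals and are therefore profiled
analytically at every cost evaluation (weighted least-squares closed form,
clipped to their bounds) instead of being carried in the search vector;
fixing a scaling factor (as the plateau sweep does) bypasses the profiling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import observables as obs
from .model import (
    DELAY_PARAMETERS,
    INITIAL_CONDITION_PARAMETERS,
    RATE_PARAMETERS,
    IntegrationError,
    KineticParameters,
    ModelDomainError,
    Trajectory,
    simulate,
)

__all__ = [
    "Dataset",
    "ParamSpec",
    "ParameterSpace",
    "OptimizerSettings",
    "FitResult",
    "ConfigurationError",
    "chi_squared",
    "fit",
    "hybrid_minimize",
    "PENALTY_COST",
]

logger = logging.getLogger(__name__)

#: Large-but-finite cost returned when a simulation fails inside the search,
#: so stochastic optimization can continue past pathological parameter draws.
PENALTY_COST = 1e12

#: Integration tolerance used inside the fit (within the <= 1e-8 contract).
FIT_RTOL = 1e-8
FIT_ATOL = 1e-11

MODEL_PARAMETER_NAMES = (
    RATE_PARAMETERS
    + DELAY_PARAMETERS
    + INITIAL_CONDITION_PARAMETERS
    + ("I_total", "n_chain")
)
SCALING_PARAMETER_NAMES = tuple(
    sorted(set(obs.BLOT_SCALING.values()))
)


class ConfigurationError(ValueError):
    """Raised for inconsistent dataset / parameter-space configuration."""


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------

DATASET_COLUMNS = ("observable", "dose_ng_ml", "time_min", "mean", "sem")


@dataclass
class Dataset:
    """Per-observable, per-dose time series with mean and SEM.

    ``frame`` columns: observable, dose_ng_ml, time_min, mean, sem.
    SEM must be strictly positive for every row (a zero SEM is rejected
    rather than floored, so noise floors are an explicit upstream choice).
    """

    frame: pd.DataFrame
    provenance: str = "experimental"
    seed: int | None = None

    def __post_init__(self):
        df = self.frame
        missing = [c for c in DATASET_COLUMNS if c not in df.columns]
        if missing:
            raise ConfigurationError(f"dataset is missing columns {missing}")
        if len(df) == 0:
            raise ConfigurationError("dataset is empty")
        bad_sem = df.index[~(df["sem"] > 0)].tolist()
        if bad_sem:
            raise ConfigurationError(
                f"rows {bad_sem[:5]} have non-positive SEM; state a noise floor "
                "explicitly upstream"
            )
        unknown = set(df["observable"]) - set(obs.OBSERVABLE_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown observables {sorted(unknown)}")
        dup = df.duplicated(subset=["observable", "dose_ng_ml", "time_min"])
        if dup.any():
            raise ConfigurationError(
                f"duplicate (observable, dose, time) rows at index {df.index[dup].tolist()[:5]}"
            )
        self.frame = df.reset_index(drop=True)

    @property
    def doses(self) -> tuple[float, ...]:
        return tuple(sorted(self.frame["dose_ng_ml"].unique()))

    @property
    def n_data(self) -> int:
        return len(self.frame)

    def series(self):
        """Iterate (observable, dose, sub-frame sorted by time)."""
        for (name, dose), grp in self.frame.groupby(
            ["observable", "dose_ng_ml"], sort=True
        ):
            yield name, float(dose), grp.sort_values("time_min")

    @classmethod
    def from_csv(cls, path, provenance: str = "experimental") -> "Dataset":
        return cls(pd.read_csv(path, comment="#"), provenance=provenance)

    def to_csv(self, path, header_comment: str | None = None):
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.frame.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Parameter space
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParamSpec:
    """Search-space description of one parameter."""

    name: str
    lower: float = np.nan
    upper: float = np.nan
    scale: str = "log"          # log | linear
    scope: str = "global"       # global | local (per dose)
    fixed: bool = False
    value: float | None = None  # required when fixed

    def __post_init__(self):
        if self.scale not in ("log", "linear"):
            raise ConfigurationError(f"{self.name}: unknown scale {self.scale!r}")
        if self.scope not in ("global", "local"):
            raise ConfigurationError(f"{self.name}: unknown scope {self.scope!r}")
        if self.fixed:
            if self.value is None:
                raise ConfigurationError(f"{self.name}: fixed without a value")
            return
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ConfigurationError(f"{self.name}: free parameter needs finite bounds")
        if not self.lower < self.upper:
            raise ConfigurationError(f"{self.name}: lower must be < upper")
        if self.scale == "log" and self.lower <= 0:
            raise ConfigurationError(
                f"{self.name}: log-scale bounds must be positive"
            )

    def transform(self, v):
        return np.log10(v) if self.scale == "log" else v

    def untransform(self, u):
        return 10.0 ** u if self.scale == "log" else u


class ParameterSpace:
    """Named collection of :class:`ParamSpec` plus base parameter values.

    ``base`` supplies values for model parameters not listed in the space.
    Scaling-factor specs (``WB_*``) define bounds/fixing for the blot gains;
    free gains are profiled inside the cost rather than searched.
    """

    def __init__(self, specs: Sequence[ParamSpec], base: KineticParameters):
        self.specs: dict[str, ParamSpec] = {}
        for spec in specs:
            if spec.name in self.specs:
                raise ConfigurationError(f"duplicate parameter {spec.name!r}")
            valid = MODEL_PARAMETER_NAMES + SCALING_PARAMETER_NAMES
            if spec.name not in valid:
                raise ConfigurationError(f"unknown parameter name {spec.name!r}")
            self.specs[spec.name] = spec
        self.base = base

    # -- search-vector layout ------------------------------------------------

    def search_entries(self, doses: Sequence[float]) -> list[tuple[str, ParamSpec]]:
        """Ordered (theta key, spec) pairs making up the search vector.

        Scaling factors are excluded (profiled); local parameters contribute
        one entry per dose, keyed ``name@dose``.
        """
        entries = []
        for name, spec in self.specs.items():
            if spec.fixed or name in SCALING_PARAMETER_NAMES:
                continue
            if spec.scope == "global":
                entries.append((name, spec))
            else:
                for d in sorted(doses):
                    entries.append((f"{name}@{d:g}", spec))
        return entries

    def bounds_vectors(self, doses) -> tuple[np.ndarray, np.ndarray]:
        entries = self.search_entries(doses)
        lo = np.array([s.transform(s.lower) for _, s in entries])
        hi = np.array([s.transform(s.upper) for _, s in entries])
        return lo, hi

    def decode(self, x: np.ndarray, doses) -> dict[str, float]:
        entries = self.search_entries(doses)
        if len(x) != len(entries):
            raise ConfigurationError(
                f"vector length {len(x)} != search dimension {len(entries)}"
            )
        return {key: float(s.untransform(xi)) for (key, s), xi in zip(entries, x)}

    def encode(self, theta: Mapping[str, float], doses) -> np.ndarray:
        entries = self.search_entries(doses)
        try:
            return np.array([s.transform(theta[key]) for key, s in entries])
        except KeyError as exc:
            raise ConfigurationError(f"theta is missing entry {exc}") from None

    # -- parameter assembly ---------------------------------------------------

    def _lookup(self, theta: Mapping[str, float], name: str, dose: float):
        spec = self.specs.get(name)
        if spec is not None and not spec.fixed and spec.scope == "local":
            key = f"{name}@{dose:g}"
            if key in theta:
                return theta[key]
        if name in theta:
            return theta[name]
        if spec is not None and spec.fixed:
            return spec.value
        return None

    def kinetic_parameters(
        self, theta: Mapping[str, float], dose: float
    ) -> KineticParameters:
        """Assemble the kinetic parameters effective at one dose."""
        values = self.base.to_dict()
        for name in MODEL_PARAMETER_NAMES:
            v = self._lookup(theta, name, dose)
            if v is not None:
                values[name] = v
        return KineticParameters.from_dict(values)

    def gain_bounds(self, name: str) -> tuple[float, float]:
        spec = self.specs.get(name)
        if spec is None or spec.fixed:
            return (0.0, np.inf)
        return (spec.lower, spec.upper)

    def fixed_gain(self, name: str) -> float | None:
        spec = self.specs.get(name)
        if spec is not None and spec.fixed:
            return spec.value
        return None

    def gain_scope(self, name: str) -> str:
        spec = self.specs.get(name)
        return spec.scope if spec is not None else "local"

    def with_fixed(self, name: str, value: float) -> "ParameterSpace":
        """Copy of the space with one parameter fixed at a value."""
        specs = []
        found = False
        for n, s in self.specs.items():
            if n == name:
                specs.append(replace(s, fixed=True, value=value))
                found = True
            else:
                specs.append(s)
        if not found:
            specs.append(ParamSpec(name, fixed=True, value=value))
        return ParameterSpace(specs, self.base)


# ---------------------------------------------------------------------------
# Prediction and cost
# ---------------------------------------------------------------------------


def _simulate_doses(
    theta: Mapping[str, float],
    dataset: Dataset,
    space: ParameterSpace,
    rtol: float,
    atol: float,
) -> dict[float, Trajectory]:
    trajs = {}
    for dose in dataset.doses:
        params = space.kinetic_parameters(theta, dose)
        times = np.unique(
            dataset.frame.loc[dataset.frame["dose_ng_ml"] == dose, "time_min"]
        )
        if times[0] != 0:
            times = np.insert(times, 0, 0.0)
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            trajs[dose] = simulate(params, dose, times, rtol=rtol, atol=atol)
    return trajs


def _values_at(traj: Trajectory, name: str, times: np.ndarray) -> np.ndarray:
    combo = obs.species_combination(name, traj)
    idx = np.searchsorted(traj.times, times)
    if np.any(idx >= traj.times.size) or np.any(
        np.abs(traj.times[np.minimum(idx, traj.times.size - 1)] - times) > 1e-9
    ):
        raise ConfigurationError("data times missing from simulated trajectory")
    return combo[idx]


def predict(
    theta: Mapping[str, float],
    dataset: Dataset,
    space: ParameterSpace,
    *,
    rtol: float = FIT_RTOL,
    atol: float = FIT_ATOL,
) -> pd.DataFrame:
    """Model predictions aligned to the dataset rows.

    Returns the dataset frame with added ``prediction`` and ``gain`` columns.
    Blot gains come from theta if present, else from a fixed spec, else from
    the analytic weighted-least-squares profile (respecting the gain's scope:
    per-dose series when local, pooled across doses when global).
    """
    trajs = _simulate_doses(theta, dataset, space, rtol, atol)

    rows = []
    for name, dose, grp in dataset.series():
        times = grp["time_min"].to_numpy(dtype=float)
        combo = _values_at(trajs[dose], name, times)
        rows.append((name, dose, grp, combo))

    # group blot series for gain determination
    out = dataset.frame.copy()
    out["prediction"] = np.nan
    out["gain"] = np.nan
    groups: dict[tuple, list] = {}
    for name, dose, grp, combo in rows:
        gain_name = obs.BLOT_SCALING.get(name)
        if gain_name is None:
            # mRNA: normalize model series to its own time average; RSNC: direct
            if name in ("SOCS1_mRNA", "STAT1_mRNA"):
                mean = combo.mean()
                pred = combo / mean if mean > 0 else combo
            else:
                pred = combo
            out.loc[grp.index, "prediction"] = pred
            continue
        key = (
            (gain_name,)
            if space.gain_scope(gain_name) == "global"
            else (gain_name, dose)
        )
        groups.setdefault(key, []).append((name, dose, grp, combo))

    for key, members in groups.items():
        gain_name = key[0]
        explicit = None
        for _, dose, _, _ in members:
            for k in (f"{gain_name}@{dose:g}", gain_name):
                if k in theta:
                    explicit = theta[k]
                    break
        if explicit is None:
            explicit = space.fixed_gain(gain_name)
        if explicit is not None:
            gain = float(explicit)
        else:
            num = 0.0
            den = 0.0
            for _, _, grp, combo in members:
                w = 1.0 / grp["sem"].to_numpy() ** 2
                num += float(np.sum(w * grp["mean"].to_numpy() * combo))
                den += float(np.sum(w * combo**2))
            if den <= 0 or num <= 0:
                gain = 1.0
            else:
                lo, hi = space.gain_bounds(gain_name)
                gain = float(np.clip(num / den, lo, hi))
        for _, _, grp, combo in members:
            out.loc[grp.index, "prediction"] = gain * combo
            out.loc[grp.index, "gain"] = gain
    return out


def residual_vector(theta, dataset, space, **kw) -> np.ndarray:
    pred = predict(theta, dataset, space, **kw)
    return ((pred["mean"] - pred["prediction"]) / pred["sem"]).to_numpy()


def chi_squared(
    theta: Mapping[str, float],
    dataset: Dataset,
    space: ParameterSpace,
    *,
    rtol: float = FIT_RTOL,
    atol: float = FIT_ATOL,
) -> float:
    """SEM-weighted sum of squared residuals over all observables and times.

    Simulation failures return :data:`PENALTY_COST` (logged) so that
    stochastic search can continue.
    """
    try:
        r = residual_vector(theta, dataset, space, rtol=rtol, atol=atol)
    except (IntegrationError, ModelDomainError) as exc:
        logger.warning("simulation failed during cost evaluation: %s", exc)
        return PENALTY_COST
    return float(np.dot(r, r))


# ---------------------------------------------------------------------------
# Hybrid optimizer
# ---------------------------------------------------------------------------


@dataclass
class OptimizerSettings:
    """Budget and schedule of the hybrid simulated-annealing + local search."""

    sa_iterations: int = 2000
    sa_initial_temperature: float = 50.0
    sa_cooling_rate: float = 0.97
    sa_step_scale: float = 0.15   # proposal sd as a fraction of the box width
    local_max_iterations: int = 40
    local_tolerance: float = 1e-8
    n_restarts: int = 5
    seed: int = 0

    def __post_init__(self):
        if not (
            self.sa_iterations > 0
            and self.sa_initial_temperature > 0
            and 0 < self.sa_cooling_rate < 1
            and self.sa_step_scale > 0
            and self.local_max_iterations > 0
            and self.local_tolerance > 0
            and self.n_restarts > 0
        ):
            raise ConfigurationError("optimizer settings must be positive "
                                     "(cooling rate in (0,1))")


def _reflect(x, lo, hi):
    """Reflect proposals back into the box."""
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return lo + y


def _anneal(cost, x0, lo, hi, settings, rng, trace, best):
    """One simulated-annealing chain; updates the global best and trace."""
    x = x0.copy()
    c = cost(x)
    if c < best[1]:
        best[0], best[1] = x.copy(), c
    T = settings.sa_initial_temperature
    width = hi - lo
    d = x.size
    for _ in range(settings.sa_iterations):
        sigma = settings.sa_step_scale * max(T / settings.sa_initial_temperature, 1e-2) ** 0.5
        step = np.zeros(d)
        # perturb a small random subset of coordinates
        k = min(d, max(1, rng.poisson(3)))
        idx = rng.choice(d, size=k, replace=False)
        step[idx] = rng.normal(0.0, sigma, size=k) * width[idx]
        x_new = _reflect(x + step, lo, hi)
        c_new = cost(x_new)
        if c_new < c or rng.random() < np.exp(-(c_new - c) / T):
            x, c = x_new, c_new
            if c < best[1]:
                best[0], best[1] = x.copy(), c
        T *= settings.sa_cooling_rate
        trace.append(best[1])
    return x, c


def hybrid_minimize(
    cost: Callable[[np.ndarray], float],
    lower: np.ndarray,
    upper: np.ndarray,
    settings: OptimizerSettings,
    residual: Callable[[np.ndarray], np.ndarray] | None = None,
    x0: np.ndarray | None = None,
):
    """Seeded SA restarts followed by bounded trust-region refinement.

    Returns ``(x_best, cost_best, trace)`` where ``trace`` is the best-so-far
    cost after every SA iteration (non-increasing by construction).
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    d = lower.size
    rng = np.random.default_rng(settings.seed)
    trace: list[float] = []
    best: list = [None, np.inf]

    for restart in range(settings.n_restarts):
        if restart == 0 and x0 is not None:
            start = np.clip(x0, lower, upper)
        elif restart == 0:
            start = 0.5 * (lower + upper)
        else:
            start = rng.uniform(lower, upper)
        logger.info("SA restart %d/%d starting", restart + 1, settings.n_restarts)
        _anneal(cost, start, lower, upper, settings, rng, trace, best)
        logger.info(
            "SA restart %d/%d done, best cost %.6g", restart + 1,
            settings.n_restarts, best[1],
        )

    x_best, c_best = best[0], best[1]
    if residual is not None and c_best < PENALTY_COST:
        try:
            res = least_squares(
                residual,
                x_best,
                bounds=(lower, upper),
                method="trf",
                xtol=settings.local_tolerance,
                ftol=settings.local_tolerance,
                gtol=settings.local_tolerance,
                max_nfev=settings.local_max_iterations,
            )
            c_local = float(2 * res.cost)  # least_squares cost = 0.5 * chi2
            if c_local <= c_best:
                x_best, c_best = res.x, c_local
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("local refinement failed: %s", exc)
        trace.append(c_best)
    return x_best, c_best, np.asarray(trace)


# ---------------------------------------------------------------------------
# Fit driver
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Optimized parameters with cost, predictions and optimizer trace."""

    theta: dict[str, float]
    chi2: float
    n_data: int
    predictions: pd.DataFrame
    trace: np.ndarray
    settings: OptimizerSettings
    seed: int
    trajectories: dict[float, Trajectory] = field(default_factory=dict)

    def report(self) -> dict:
        return {
            "theta_hat": self.theta,
            "chi2": self.chi2,
            "n_data": self.n_data,
            "chi2_per_point": self.chi2 / self.n_data,
            "seed": self.seed,
            "settings": self.settings.__dict__,
        }


def fit(
    dataset: Dataset,
    space: ParameterSpace,
    settings: OptimizerSettings | None = None,
    *,
    x0: np.ndarray | None = None,
    local_only: bool = False,
) -> FitResult:
    """Estimate parameters for a multi-dose dataset with the hybrid optimizer.

    With ``local_only`` the simulated-annealing phase is skipped and the
    bounded trust-region refinement runs directly from ``x0`` (used for
    continuation along the plateau sweep).
    """
    if settings is None:
        settings = OptimizerSettings()
    doses = dataset.doses
    entries = space.search_entries(doses)
    if not entries:
        raise ConfigurationError("parameter space has no free parameters")
    lo, hi = space.bounds_vectors(doses)

    def cost(x):
        return chi_squared(space.decode(x, doses), dataset, space)

    def residual(x):
        try:
            return residual_vector(space.decode(x, doses), dataset, space)
        except (IntegrationError, ModelDomainError):
            return np.full(dataset.n_data, np.sqrt(PENALTY_COST / dataset.n_data))

    if local_only:
        if x0 is None:
            raise ConfigurationError("local_only refinement requires x0")
        sa_free = replace(settings, n_restarts=1, sa_iterations=1)
        x_best, c_best, trace = hybrid_minimize(
            cost, lo, hi, sa_free, residual=residual, x0=np.asarray(x0, dtype=float)
        )
    else:
        x_best, c_best, trace = hybrid_minimize(
            cost, lo, hi, settings, residual=residual, x0=x0
        )
    theta = space.decode(x_best, doses)
    pred = predict(theta, dataset, space)
    # expose the profiled / fixed gains in theta_hat
    for (name, dose), grp in pred.groupby(["observable", "dose_ng_ml"], sort=True):
        gain_name = obs.BLOT_SCALING.get(name)
        if gain_name is None:
            continue
        gain = float(grp["gain"].iloc[0])
        key = (
            gain_name
            if space.gain_scope(gain_name) == "global"
            else f"{gain_name}@{float(dose):g}"
        )
        theta[key] = gain
    trajs = {}
    for dose in doses:
        params = space.kinetic_parameters(theta, dose)
        tmax = float(dataset.frame["time_min"].max())
        times = np.unique(np.concatenate([np.linspace(0, tmax, 241),
                                          dataset.frame["time_min"].unique()]))
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            trajs[dose] = simulate(params, dose, times, rtol=FIT_RTOL, atol=FIT_ATOL)
    return FitResult(
        theta=theta,
        chi2=c_best,
        n_data=dataset.n_data,
        predictions=pred,
        trace=trace,
        settings=settings,
        seed=settings.seed,
        trajectories=trajs,
    )
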