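"""Macroscopic population reduction: logistic growth, sigmoid fits, hazard process.

The agent simulation's per-state cell counts saturate in time; this module
provides (i) the logistic model dN/dt = r N (1 - N/K) and its closed-form
solution, (ii) least-squares fitting of several sigmoid families to count
series with R^2 and leave-p-out cross-validation, and (iii) the equivalent
stochastic pure-birth process in which the waiting time to the next division
is exponential with hazard h(N) = r N (1 - N/K) (Gillespie construction).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DegenerateFitError, FitError, InvalidParameterError, InvalidStateError

__all__ = [
    "PopulationSeries",
    "SigmoidFit",
    "LogisticModel",
    "SIGMOID_FAMILIES",
    "logistic_solution",
    "fit_sigmoid",
    "compare_sigmoid_fits",
    "hazard_rate",
    "simulate_birth_process",
    "total_living_asymptote",
]


@dataclass(frozen=True)
class LogisticModel:
    """Logistic growth parameters: carrying capacity K, rate r, start N0."""

    carrying_capacity: float
    growth_rate: float
    initial_population: float = 1.0

    def __post_init__(self):
        if not self.carrying_capacity >= self.initial_population >= 1:
            raise InvalidParameterError("require K >= N0 >= 1")
        if self.growth_rate <= 0:
            raise InvalidParameterError("growth rate must be positive")


@dataclass(frozen=True)
class SigmoidFit:
    """Fitted sigmoid: asymptote A, rate k, midpoint/shape t0, and goodness."""

    asymptote: float
    rate: float
    midpoint: float
    r_squared: float
    family: str = "logistic"
    cv_score: float | None = None

    def __post_init__(self):
        if self.asymptote <= 0:
            raise InvalidParameterError("asymptote must be positive")
        if self.r_squared > 1:
            raise InvalidParameterError("R^2 cannot exceed 1")

    def __call__(self, t):
        return SIGMOID_FAMILIES[self.family](np.asarray(t, dtype=float),
                                             self.asymptote, self.rate, self.midpoint)


def _logistic(t, a, k, t0):
    return a / (1.0 + np.exp(np.clip(-k * (t - t0), -700, 700)))


def _gompertz(t, a, k, t0):
    return a * np.exp(-np.exp(np.clip(-k * (t - t0), -700, 700)))


def _hill(t, a, k, t0):
    t = np.maximum(t, 0.0)
    t0 = max(t0, 1e-12)
    return a * t ** k / (t0 ** k + t ** k)


def _chapman(t, a, k, t0):
    # Chapman-Richards with shape exponent t0
    return a * (1.0 - np.exp(-k * np.maximum(t, 0.0))) ** max(t0, 1e-12)


def _boltzmann(t, a, k, t0):
    # Boltzmann sigmoid with zero lower asymptote == logistic parameterization
    return a / (1.0 + np.exp(np.clip((t0 - t) * k, -700, 700)))


SIGMOID_FAMILIES = {
    "logistic": _logistic,
    "gompertz": _gompertz,
    "hill": _hill,
    "chapman": _chapman,
    "boltzmann": _boltzmann,
}


def logistic_solution(model: LogisticModel, t):
    """Closed-form logistic trajectory, overflow-safe for large r t.

    N(t) = K N0 e^{rt} / (K + N0 (e^{rt} - 1)), evaluated as
    K / (1 + (K/N0 - 1) e^{-rt}).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("t must be >= 0")
    k, r, n0 = model.carrying_capacity, model.growth_rate, model.initial_population
    out = k / (1.0 + (k / n0 - 1.0) * np.exp(np.clip(-r * t, -700, 700)))
    return float(out) if out.ndim == 0 else out


def _initial_guess(t: np.ndarray, y: np.ndarray) -> dict:
    a0 = float(y.max()) * 1.02
    half = a0 / 2.0
    above = np.flatnonzero(y >= half)
    t0 = float(t[above[0]]) if len(above) else float(np.median(t))
    # rate from the central slope: dy/dt at half-max = a k / 4 for a logistic
    slope = float(np.max(np.gradient(y, t)))
    k0 = max(4.0 * slope / a0, 1e-6) if slope > 0 else 1e-3
    return {"a": a0, "k": k0, "t0": t0}


def fit_sigmoid(t, counts, family: str = "logistic", p_out: int | None = None,
                max_cv_splits: int = 50) -> SigmoidFit:
    """Least-squares fit of a sigmoid family to one state's count series.

    Initialization: A from the max count, t0 from the half-max time, k from
    the central slope.  ``p_out`` enables leave-p-out cross-validation; the
    CV score is the mean squared prediction error over (at most
    ``max_cv_splits``) held-out subsets.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(counts, dtype=float)
    if len(t) < 4:
        raise DegenerateFitError("need at least 4 points")
    if np.ptp(y) == 0:
        raise DegenerateFitError("constant series cannot constrain a sigmoid")
    if family not in SIGMOID_FAMILIES:
        raise InvalidParameterError(f"unknown sigmoid family {family!r}")
    fun = SIGMOID_FAMILIES[family]
    init = _initial_guess(t, y)
    if family == "hill":
        init = {"a": init["a"], "k": 4.0, "t0": max(init["t0"], 1e-6)}
    elif family == "chapman":
        init = {"a": init["a"], "k": init["k"], "t0": 2.0}
    p0 = [init["a"], init["k"], init["t0"]]
    try:
        popt, _ = curve_fit(fun, t, y, p0=p0, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"{family} fit failed to converge: {exc}", init=init) from exc
    resid = y - fun(t, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
    cv = None
    if p_out:
        cv = _leave_p_out_score(fun, t, y, popt, p_out, max_cv_splits)
    return SigmoidFit(float(popt[0]), float(popt[1]), float(popt[2]), r2,
                      family=family, cv_score=cv)


def _leave_p_out_score(fun, t, y, p0, p, max_splits) -> float:
    n = len(t)
    combos = itertools.combinations(range(n), p)
    errors = []
    for held in itertools.islice(combos, max_splits):
        held = np.asarray(held)
        mask = np.ones(n, dtype=bool)
        mask[held] = False
        try:
            popt, _ = curve_fit(fun, t[mask], y[mask], p0=p0, maxfev=5000)
        except (RuntimeError, ValueError):
            continue
        errors.append(np.mean((y[held] - fun(t[held], *popt)) ** 2))
    return float(np.mean(errors)) if errors else float("nan")


def compare_sigmoid_fits(t, counts, families=None, p_out: int | None = None):
    """Fit several sigmoid families and rank them by R^2 (descending).

    Families that fail to converge are reported with their error and ranked
    last.  Returns a list of (family, SigmoidFit | FitError).
    """
    families = families or list(SIGMOID_FAMILIES)
    results = []
    for fam in families:
        try:
            results.append((fam, fit_sigmoid(t, counts, family=fam, p_out=p_out)))
        except (FitError, DegenerateFitError) as exc:
            results.append((fam, exc))
    def sort_key(item):
        fit = item[1]
        return -fit.r_squared if isinstance(fit, SigmoidFit) else np.inf
    return sorted(results, key=sort_key)


def hazard_rate(n, model: LogisticModel):
    """Birth hazard h(N) = r N (1 - N/K), events per unit time."""
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr < 0) or np.any(n_arr > model.carrying_capacity):
        raise InvalidStateError("population must lie in [0, K]")
    out = model.growth_rate * n_arr * (1.0 - n_arr / model.carrying_capacity)
    return float(out) if out.ndim == 0 else out


def simulate_birth_process(model: LogisticModel, rng, t_max: float = np.inf,
                           printed_waiting_map: bool = False):
    """Stochastic pure-birth trajectory under the logistic hazard.

    Waiting times between births are exponential with rate h(N) (Gillespie);
    the population increments by one per event until K or ``t_max``.
    ``printed_waiting_map`` switches to the deterministic map dt = e^{h(N)}
    (provided for comparison only; it is not a waiting-time distribution).

    Returns (times, populations) arrays including the initial state.
    """
    n = float(model.initial_population)
    t = 0.0
    times = [0.0]
    pops = [n]
    k = model.carrying_capacity
    while n < k and t < t_max:
        h = hazard_rate(min(n, k), model)
        if h <= 0:
            break
        if printed_waiting_map:
            dt = float(np.exp(h))
        else:
            dt = rng.exponential(1.0 / h)
        t += dt
        if t > t_max:
            break
        n += 1.0
        times.append(t)
        pops.append(n)
    return np.asarray(times), np.asarray(pops)


def total_living_asymptote(fit_q: SigmoidFit | float, fit_p: SigmoidFit | float) -> float:
    """Total living population: sum of the quiescent and proliferating asymptotes."""
    a_q = fit_q.asymptote if isinstance(fit_q, SigmoidFit) else float(fit_q)
    a_p = fit_p.asymptote if isinstance(fit_p, SigmoidFit) else float(fit_p)
    if a_q < 0 or a_p < 0:
        raise InvalidParameterError("asymptotes must be non-negative")
    return a_q + a_p


class PopulationSeries:
    """Per-iteration counts of proliferating, quiescent and necrotic cells."""

    COLUMNS = ("iteration", "proliferating", "quiescent", "necrotic")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise InvalidParameterError(f"population series missing columns {missing}")
        if (frame[list(self.COLUMNS[1:])].to_numpy() < 0).any():
            raise InvalidParameterError("counts must be non-negative")
        if not np.all(np.diff(frame["iteration"].to_numpy()) > 0):
            raise InvalidParameterError("iterations must be strictly increasing")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: list[dict]) -> "PopulationSeries":
        return cls(pd.DataFrame.from_records(records, columns=list(cls.COLUMNS)))

    @property
    def living(self) -> np.ndarray:
        return (self.frame["proliferating"] + self.frame["quiescent"]).to_numpy()

    def counts(self, state_name: str) -> np.ndarray:
        return self.frame[state_name].to_numpy()

    @property
    def iterations(self) -> np.ndarray:
        return self.frame["iteration"].to_numpy()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PopulationSeries":
        return cls(pd.read_csv(path))
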