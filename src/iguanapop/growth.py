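"""Discrete-time logistic dynamics of a harvested population.

The population model is a logistic surplus-production update on an annual
(survey-to-survey) time step, with ``K`` the carrying capacity (abundance
above which density dependence drives decline), ``r_max`` the maximum
intrinsic growth rate at low density, and ``H_t = h_t * N_t`` the number of
animals removed during interval ``[t, t+1)``.  Harvest may be specified as a
rate ``h_t`` or as a total count.

Two harvest orderings are provided behind the ``timing`` flag:

``"escapement"`` (package default)
    Removals are taken from the surveyed abundance before the next breeding
    season; the escapement ``S_t = N_t - H_t`` then grows logistically:

        N_{t+1} = max(0, [S_t + r_max * S_t * (1 - S_t / K)] * exp(eps_t)).

    This matches a quota set each August from the August survey and
    harvested before the next August survey: sustained rates above
    ``r_max / (1 + r_max)`` drive the population to extinction.

``"simultaneous"``
    The classical Schaefer discretisation with removals and growth acting
    within the same interval:

        N_{t+1} = max(0, [N_t + r_max * N_t * (1 - N_t / K) - H_t] * exp(eps_t)).

    Any rate below 1 leaves the positive equilibrium ``K * (1 - h / r_max)``;
    this ordering carries the textbook sustained-yield identities.

In both, ``eps_t ~ Normal(0, sigma_proc^2)`` is multiplicative lognormal
process noise.  Closed-form derived quantities of the logistic model live
here too: the maximum sustained harvest rate ``h_msy = r_max / 2`` and the
low-density doubling time ``ln(2) / r_max`` (reported in months).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GrowthParams",
    "PopulationState",
    "HarvestSchedule",
    "Trajectory",
    "DEFAULT_TIMING",
    "det_step",
    "logistic_step",
    "simulate_trajectory",
    "h_msy",
    "doubling_time_months",
    "harvest_needed",
    "equilibrium_abundance",
]

#: Harvest ordering used throughout the package unless overridden.
DEFAULT_TIMING = "escapement"
_TIMINGS = ("escapement", "simultaneous")


def _require_finite(name: str, value: float) -> float:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return float(value)


@dataclass(frozen=True)
class GrowthParams:
    """Biological parameters of the logistic model.

    Parameters
    ----------
    K : float
        Carrying capacity, individuals.  Must be > 0.
    r_max : float
        Maximum intrinsic growth rate, per year.  Must be > 0.
    sigma_proc : float, default 0.0
        Standard deviation of the multiplicative process noise on the
        natural-log scale (dimensionless).  Must be >= 0.
    """

    K: float
    r_max: float
    sigma_proc: float = 0.0

    def __post_init__(self) -> None:
        for name in ("K", "r_max", "sigma_proc"):
            _require_finite(name, getattr(self, name))
        if self.K <= 0:
            raise ValueError(f"K must be > 0, got {self.K}")
        if self.r_max <= 0:
            raise ValueError(f"r_max must be > 0, got {self.r_max}")
        if self.sigma_proc < 0:
            raise ValueError(f"sigma_proc must be >= 0, got {self.sigma_proc}")

    @property
    def h_msy(self) -> float:
        return h_msy(self.r_max)


@dataclass(frozen=True)
class PopulationState:
    """True abundance at one survey epoch (0 = first survey year)."""

    time_index: int
    N: float

    def __post_init__(self) -> None:
        if self.time_index < 0:
            raise ValueError(f"time_index must be >= 0, got {self.time_index}")
        if not (math.isfinite(self.N) and self.N >= 0):
            raise ValueError(f"N must be finite and >= 0, got {self.N}")


class HarvestSchedule:
    """Per-interval harvest, each interval carrying either a rate or a total.

    A rate ``h`` in [0, 1) removes ``h * N_t`` animals; a total removes a
    fixed count (capped at what the population plus its growth can supply).
    Zero-harvest intervals are rates of 0.
    """

    def __init__(self, entries: Sequence[tuple[str, float]]):
        parsed: list[tuple[str, float]] = []
        for i, (kind, value) in enumerate(entries):
            value = _require_finite(f"harvest[{i}]", value)
            if kind == "rate":
                if not 0.0 <= value < 1.0:
                    raise ValueError(
                        f"harvest rate at interval {i} must be in [0, 1), got {value}"
                    )
            elif kind == "total":
                if value < 0:
                    raise ValueError(
                        f"harvest total at interval {i} must be >= 0, got {value}"
                    )
            else:
                raise ValueError(f"unknown harvest kind {kind!r} at interval {i}")
            parsed.append((kind, value))
        self._entries = tuple(parsed)

    @classmethod
    def from_rates(cls, rates: Sequence[float]) -> "HarvestSchedule":
        return cls([("rate", r) for r in rates])

    @classmethod
    def from_totals(cls, totals: Sequence[float]) -> "HarvestSchedule":
        return cls([("total", h) for h in totals])

    @classmethod
    def no_harvest(cls, n_intervals: int) -> "HarvestSchedule":
        return cls.from_rates([0.0] * n_intervals)

    @property
    def entries(self) -> tuple[tuple[str, float], ...]:
        return self._entries

    @property
    def all_rates(self) -> bool:
        return all(kind == "rate" for kind, _ in self._entries)

    def rates(self) -> np.ndarray:
        """Rates as an array; raises if any interval is total-specified."""
        if not self.all_rates:
            raise ValueError("schedule contains total-specified intervals")
        return np.array([v for _, v in self._entries], dtype=float)

    def __len__(self) -> int:
        return len(self._entries)

    def __getitem__(self, i: int) -> tuple[str, float]:
        return self._entries[i]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, HarvestSchedule) and self._entries == other._entries

    def __repr__(self) -> str:
        return f"HarvestSchedule({list(self._entries)!r})"


@dataclass(frozen=True)
class Trajectory:
    """An ordered latent-abundance path with its generating ingredients."""

    states: tuple[PopulationState, ...]
    params: GrowthParams
    schedule: HarvestSchedule
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.states) != len(self.schedule) + 1:
            raise ValueError(
                f"trajectory length {len(self.states)} does not match "
                f"schedule length {len(self.schedule)} + 1"
            )
        indices = [s.time_index for s in self.states]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValueError("time_index must be strictly increasing")

    @property
    def abundances(self) -> np.ndarray:
        return np.array([s.N for s in self.states], dtype=float)

    def __len__(self) -> int:
        return len(self.states)


def det_step(N, K, r_max, kind: str, value: float, timing: str = DEFAULT_TIMING):
    """Deterministic one-interval prediction, before the floor at zero.

    Vectorised over ``N`` (and broadcastable ``K``, ``r_max``); used by the
    sampler and the projector, where the sign of the raw prediction matters
    (a non-positive prediction has no lognormal successor).
    """
    if timing not in _TIMINGS:
        raise ValueError(f"timing must be one of {_TIMINGS}, got {timing!r}")
    if timing == "escapement":
        if kind == "rate":
            S = N * (1.0 - value)
        else:
            S = np.maximum(N - value, 0.0)
        return S + r_max * S * (1.0 - S / K)
    growth = r_max * N * (1.0 - N / K)
    if kind == "rate":
        return N + growth - value * N
    supply = np.maximum(N + growth, 0.0)
    return N + growth - np.minimum(value, supply)


def logistic_step(
    N: float,
    params: GrowthParams,
    *,
    harvest_rate: float | None = None,
    harvest_total: float | None = None,
    noise: float | None = None,
    timing: str = DEFAULT_TIMING,
) -> float:
    """Advance abundance one interval under logistic growth with removals.

    With the default ``timing="escapement"`` the harvest ``H = harvest_rate
    * N`` (or ``min(harvest_total, N)``) is removed first and the escapement
    grows logistically; ``timing="simultaneous"`` computes the classical
    ``max(0, (N + r_max*N*(1 - N/K) - H) * exp(noise))`` with the total-form
    harvest capped at ``N`` plus growth.  Deterministic when ``noise`` is
    None (treated as 0).  The floor at zero means over-harvest drives the
    population extinct rather than erroring — the correct biological reading
    of removing more animals than exist.
    """
    N = _require_finite("N", N)
    if N < 0:
        raise ValueError(f"N must be >= 0, got {N}")
    if harvest_rate is not None and harvest_total is not None:
        raise ValueError("specify harvest_rate or harvest_total, not both")
    if harvest_rate is not None:
        harvest_rate = _require_finite("harvest_rate", harvest_rate)
        if not 0.0 <= harvest_rate < 1.0:
            raise ValueError(f"harvest_rate must be in [0, 1), got {harvest_rate}")
        kind, value = "rate", harvest_rate
    elif harvest_total is not None:
        harvest_total = _require_finite("harvest_total", harvest_total)
        if harvest_total < 0:
            raise ValueError(f"harvest_total must be >= 0, got {harvest_total}")
        kind, value = "total", harvest_total
    else:
        kind, value = "rate", 0.0
    pred = float(det_step(N, params.K, params.r_max, kind, value, timing))
    factor = 1.0 if noise is None else math.exp(_require_finite("noise", noise))
    return max(0.0, pred * factor)


def equilibrium_abundance(
    params: GrowthParams, h: float, timing: str = DEFAULT_TIMING
) -> float:
    """Positive fixed point of the deterministic harvested map, 0 if none.

    ``K * (1 - h / r_max)`` for the simultaneous ordering (positive for
    ``h < r_max``); ``K * (r_max*(1-h) - h) / (r_max*(1-h)^2)`` for the
    escapement ordering (positive for ``h < r_max / (1 + r_max)``).
    """
    if not 0.0 <= h < 1.0:
        raise ValueError(f"h must be in [0, 1), got {h}")
    r, K = params.r_max, params.K
    if timing == "simultaneous":
        return max(0.0, K * (1.0 - h / r))
    if timing == "escapement":
        return max(0.0, K * (r * (1.0 - h) - h) / (r * (1.0 - h) ** 2))
    raise ValueError(f"timing must be one of {_TIMINGS}, got {timing!r}")


def simulate_trajectory(
    N0: float,
    params: GrowthParams,
    schedule: HarvestSchedule,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    timing: str = DEFAULT_TIMING,
) -> Trajectory:
    """Iterate :func:`logistic_step` over a harvest schedule.

    Process noise ``eps_t ~ Normal(0, sigma_proc^2)`` on the log scale is
    drawn when a ``seed`` or ``rng`` is supplied and ``sigma_proc > 0``;
    otherwise the deterministic skeleton is returned.  Fixed seeds give
    bit-identical trajectories on one platform.
    """
    if len(schedule) == 0:
        raise ValueError("schedule must be non-empty")
    if rng is None and seed is not None:
        rng = np.random.default_rng(seed)
    stochastic = rng is not None and params.sigma_proc > 0
    states = [PopulationState(0, float(N0))]
    N = float(N0)
    for t, (kind, value) in enumerate(schedule.entries):
        eps = float(rng.normal(0.0, params.sigma_proc)) if stochastic else None
        if kind == "rate":
            N = logistic_step(N, params, harvest_rate=value, noise=eps, timing=timing)
        else:
            N = logistic_step(N, params, harvest_total=value, noise=eps, timing=timing)
        states.append(PopulationState(t + 1, N))
    return Trajectory(tuple(states), params, schedule, seed)


def h_msy(r_max: float) -> float:
    """Maximum sustained harvest rate of the logistic model, ``r_max / 2``."""
    r_max = _require_finite("r_max", r_max)
    if r_max <= 0:
        raise ValueError(f"r_max must be > 0, got {r_max}")
    return r_max / 2.0


def doubling_time_months(r_max: float) -> float:
    """Low-density doubling time in months, ``ln(2) / r_max * 12``."""
    r_max = _require_finite("r_max", r_max)
    if r_max <= 0:
        raise ValueError(f"r_max must be > 0, got {r_max}")
    return math.log(2.0) / r_max * 12.0


def harvest_needed(N: float, target_rate: float) -> int:
    """Minimum whole-animal harvest achieving a target rate on abundance N.

    Uses the ceiling so the realised rate is at least the target, matching
    management recommendations phrased as strict "more than" counts.
    """
    N = _require_finite("N", N)
    if N < 0:
        raise ValueError(f"N must be >= 0, got {N}")
    target_rate = _require_finite("target_rate", target_rate)
    if not 0.0 <= target_rate < 1.0:
        raise ValueError(f"target_rate must be in [0, 1), got {target_rate}")
    return int(math.ceil(N * target_rate))
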