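"""Bayesian fitting of the state-space logistic model to survey series.

The observation layer is lognormal: the survey-based estimate ``y_t`` is
treated as a draw with median equal to the latent abundance ``N_t`` and a
log-scale SD fixed from the survey's own precision,
``tau_t = sqrt(ln(1 + CV_t^2))`` with ``CV_t = SE_t / y_t``.  The process
layer places Normal(0, sigma_proc^2) deviations on the log of the
deterministic surplus-production prediction (see :mod:`iguanapop.growth`).
Priors are uniform on ``K``, ``r_max`` and ``sigma_proc``, and lognormal on
the initial abundance, centred on the first survey estimate with its own
survey CV.

Sampling is by adaptive random-walk Metropolis-within-Gibbs over the scalar
blocks ``(K, r_max, sigma_proc, ln N_0, ..., ln N_{T-1})``.  Proposal scales
adapt toward a 44% acceptance rate during burn-in only and are frozen
afterwards, keeping the retained chain Markovian.  Proposals outside prior
support are rejected outright so the uniform priors stay exact.  All chains
advance in lock-step as vectorised numpy operations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .growth import DEFAULT_TIMING, GrowthParams, HarvestSchedule, det_step, h_msy

__all__ = [
    "SurveySeries",
    "PriorSpec",
    "PosteriorSample",
    "MCMCResult",
    "MCMCDiagnosticError",
    "observation_loglik",
    "process_loglik",
    "log_posterior",
    "run_mcmc",
    "summarize_posterior",
]

_LOG_2PI = math.log(2.0 * math.pi)


class MCMCDiagnosticError(RuntimeError):
    """Raised when the sampler finishes in a state its output cannot be trusted."""


@dataclass(frozen=True)
class SurveySeries:
    """Annual survey-based abundance estimates with standard errors.

    ``cv`` and ``log_sd`` are derived: ``cv = se/mean`` and
    ``log_sd = sqrt(ln(1 + cv^2))``, the SD of ``ln(estimate)`` under the
    lognormal convention the survey CIs use.
    """

    years: tuple[int, ...]
    means: tuple[float, ...]
    ses: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.years)
        if not (len(self.means) == len(self.ses) == n):
            raise ValueError("years, means and ses must have equal length")
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ValueError("years must be strictly increasing")
        for y, m, s in zip(self.years, self.means, self.ses):
            if not (math.isfinite(m) and m > 0):
                raise ValueError(f"survey mean for year {y} must be > 0, got {m}")
            if not (math.isfinite(s) and s > 0):
                raise ValueError(f"survey SE for year {y} must be > 0, got {s}")

    @classmethod
    def from_arrays(cls, years, means, ses) -> "SurveySeries":
        return cls(
            tuple(int(y) for y in years),
            tuple(float(m) for m in means),
            tuple(float(s) for s in ses),
        )

    @property
    def n_surveys(self) -> int:
        return len(self.years)

    @property
    def cv(self) -> np.ndarray:
        return np.asarray(self.ses) / np.asarray(self.means)

    @property
    def log_sd(self) -> np.ndarray:
        return np.sqrt(np.log1p(self.cv**2))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "mean": self.means, "se": self.ses})


@dataclass(frozen=True)
class PriorSpec:
    """Prior distributions for the state-space fit.

    ``K``, ``r_max`` and ``sigma_proc`` are uniform over the given bounds.
    The initial latent abundance is lognormal with median ``n0_center`` and
    log-scale SD ``n0_log_sd``; both default to the first survey's estimate
    and log-SD when left as None.
    """

    k_bounds: tuple[float, float] = (900_000.0, 2_000_000.0)
    r_max_bounds: tuple[float, float] = (0.500, 2.000)
    sigma_bounds: tuple[float, float] = (0.01, 1.0)
    n0_center: float | None = None
    n0_log_sd: float | None = None

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("k_bounds", self.k_bounds),
            ("r_max_bounds", self.r_max_bounds),
            ("sigma_bounds", self.sigma_bounds),
        ):
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"{name} must satisfy lower < upper, got ({lo}, {hi})")
        if self.k_bounds[0] <= 0 or self.r_max_bounds[0] <= 0:
            raise ValueError("K and r_max lower bounds must be > 0")
        if self.sigma_bounds[0] < 0:
            raise ValueError("sigma_proc lower bound must be >= 0")
        if self.n0_center is not None and self.n0_center <= 0:
            raise ValueError("n0_center must be > 0")
        if self.n0_log_sd is not None and self.n0_log_sd <= 0:
            raise ValueError("n0_log_sd must be > 0")

    def resolve_n0(self, data: SurveySeries) -> tuple[float, float]:
        center = self.n0_center if self.n0_center is not None else data.means[0]
        log_sd = self.n0_log_sd if self.n0_log_sd is not None else float(data.log_sd[0])
        return float(center), float(log_sd)


@dataclass(frozen=True)
class PosteriorSample:
    """One MCMC draw: parameters plus the latent log-abundance path."""

    K: float
    r_max: float
    sigma_proc: float
    log_n: tuple[float, ...]
    chain: int = 0
    iteration: int = 0

    @property
    def params(self) -> GrowthParams:
        return GrowthParams(self.K, self.r_max, self.sigma_proc)

    @property
    def latent_n(self) -> np.ndarray:
        return np.exp(np.asarray(self.log_n))


def observation_loglik(sample: PosteriorSample, data: SurveySeries) -> float:
    """Lognormal log-density of the observed estimates given the latent states.

    The latent state is the median of the observation distribution and the
    log-scale SD is fixed from each survey's SE via its CV.
    """
    x = np.asarray(sample.log_n, dtype=float)
    if x.shape != (data.n_surveys,):
        raise ValueError(
            f"sample carries {x.size} latent states for {data.n_surveys} surveys"
        )
    y = np.asarray(data.means)
    tau = data.log_sd
    z = (np.log(y) - x) / tau
    return float(np.sum(-np.log(y) - np.log(tau) - 0.5 * _LOG_2PI - 0.5 * z**2))


def process_loglik(
    sample: PosteriorSample,
    schedule: HarvestSchedule,
    timing: str = DEFAULT_TIMING,
) -> float:
    """Normal log-density of log-scale process deviations along the path.

    Returns ``-inf`` when any deterministic prediction is non-positive (the
    latent successor would lie outside the lognormal support) or when
    ``sigma_proc`` is zero and a deviation is non-zero.
    """
    x = np.asarray(sample.log_n, dtype=float)
    if x.size != len(schedule) + 1:
        raise ValueError(
            f"sample carries {x.size} latent states for {len(schedule)} intervals"
        )
    sigma = sample.sigma_proc
    total = 0.0
    for t, (kind, value) in enumerate(schedule.entries):
        pred = float(
            det_step(math.exp(x[t]), sample.K, sample.r_max, kind, value, timing)
        )
        if pred <= 0:
            return -math.inf
        dev = x[t + 1] - math.log(pred)
        if sigma == 0.0:
            if dev != 0.0:
                return -math.inf
            continue
        total += -math.log(sigma) - 0.5 * _LOG_2PI - 0.5 * (dev / sigma) ** 2
    return total


def log_posterior(
    sample: PosteriorSample,
    data: SurveySeries,
    schedule: HarvestSchedule,
    priors: PriorSpec,
    timing: str = DEFAULT_TIMING,
) -> float:
    """Unnormalised log posterior density of one draw.

    Uniform priors contribute their (constant) log-density inside support and
    ``-inf`` outside; the initial-abundance prior is evaluated as a Normal on
    ``ln N_0``.
    """
    if not (priors.k_bounds[0] <= sample.K <= priors.k_bounds[1]):
        return -math.inf
    if not (priors.r_max_bounds[0] <= sample.r_max <= priors.r_max_bounds[1]):
        return -math.inf
    if not (priors.sigma_bounds[0] <= sample.sigma_proc <= priors.sigma_bounds[1]):
        return -math.inf
    lp = -math.log(priors.k_bounds[1] - priors.k_bounds[0])
    lp += -math.log(priors.r_max_bounds[1] - priors.r_max_bounds[0])
    lp += -math.log(priors.sigma_bounds[1] - priors.sigma_bounds[0])
    center, log_sd = priors.resolve_n0(data)
    z0 = (sample.log_n[0] - math.log(center)) / log_sd
    lp += -math.log(log_sd) - 0.5 * _LOG_2PI - 0.5 * z0**2
    lp += observation_loglik(sample, data)
    lp += process_loglik(sample, schedule, timing)
    return lp


@dataclass
class MCMCResult:
    """Retained draws from all chains, with sampler metadata.

    Parameter arrays have shape ``(n_chains, n_kept)``; the latent path array
    has shape ``(n_chains, n_kept, n_surveys)``.
    """

    K: np.ndarray
    r_max: np.ndarray
    sigma_proc: np.ndarray
    log_n: np.ndarray
    years: tuple[int, ...]
    seed: int
    acceptance: dict[str, np.ndarray]
    priors: PriorSpec
    schedule: HarvestSchedule
    timing: str = DEFAULT_TIMING

    @property
    def n_chains(self) -> int:
        return self.K.shape[0]

    @property
    def n_kept(self) -> int:
        return self.K.shape[1]

    @property
    def n_draws(self) -> int:
        return self.K.size

    def samples(self) -> list[PosteriorSample]:
        """All retained draws as :class:`PosteriorSample` objects."""
        out = []
        for c in range(self.n_chains):
            for i in range(self.n_kept):
                out.append(
                    PosteriorSample(
                        float(self.K[c, i]),
                        float(self.r_max[c, i]),
                        float(self.sigma_proc[c, i]),
                        tuple(self.log_n[c, i]),
                        chain=c,
                        iteration=i,
                    )
                )
        return out

    def to_frame(self) -> pd.DataFrame:
        """Flat table: one row per draw, parameters plus latent abundances."""
        n = self.n_kept
        frames = {
            "chain": np.repeat(np.arange(self.n_chains), n),
            "draw": np.tile(np.arange(n), self.n_chains),
            "K": self.K.ravel(),
            "r_max": self.r_max.ravel(),
            "sigma_proc": self.sigma_proc.ravel(),
            "h_msy": self.r_max.ravel() / 2.0,
        }
        for j, year in enumerate(self.years):
            frames[f"N_{year}"] = np.exp(self.log_n[:, :, j]).ravel()
        return pd.DataFrame(frames)

    def _scalar_draws(self, name: str) -> np.ndarray:
        if name == "h_msy":
            return self.r_max / 2.0
        if name in ("K", "r_max", "sigma_proc"):
            return getattr(self, name)
        if name.startswith("N_"):
            year = int(name[2:])
            j = self.years.index(year)
            return np.exp(self.log_n[:, :, j])
        raise KeyError(name)

    def rhat(self, name: str) -> float:
        """Split-chain potential scale reduction factor (rank-normalised)."""
        import arviz as az

        return float(az.rhat(self._scalar_draws(name)))

    def ess(self, name: str) -> float:
        import arviz as az

        return float(az.ess(self._scalar_draws(name)))

    @property
    def terminal_log_n(self) -> np.ndarray:
        """Latent log-abundance at the final survey, one value per draw."""
        return self.log_n[:, :, -1].ravel()


def _propose_start(
    rng: np.random.Generator,
    priors: PriorSpec,
    data: SurveySeries,
    schedule: HarvestSchedule,
    timing: str,
) -> tuple[float, float, float, np.ndarray]:
    log_means = np.log(np.asarray(data.means))
    for _ in range(1000):
        K = rng.uniform(*priors.k_bounds)
        r = rng.uniform(*priors.r_max_bounds)
        sig = rng.uniform(*priors.sigma_bounds)
        x = log_means + rng.normal(0.0, 0.1, size=log_means.size)
        sample = PosteriorSample(K, r, sig, tuple(x))
        if math.isfinite(log_posterior(sample, data, schedule, priors, timing)):
            return K, r, sig, x
    raise MCMCDiagnosticError(
        "could not find a finite-posterior starting point from the priors; "
        "check that the harvest schedule is compatible with the survey series"
    )


def run_mcmc(
    data: SurveySeries,
    schedule: HarvestSchedule,
    priors: PriorSpec | None = None,
    n_chains: int = 4,
    n_iter: int = 50_000,
    n_burn: int = 25_000,
    seed: int = 0,
    thin: int = 1,
    timing: str = DEFAULT_TIMING,
) -> MCMCResult:
    """Sample the joint posterior of ``(K, r_max, sigma_proc, {ln N_t})``.

    ``n_iter`` counts total iterations per chain; the first ``n_burn`` are
    discarded (proposal adaptation happens only there).  Starting points are
    overdispersed draws from the priors.  The full run is reproducible from
    ``seed``.

    Raises
    ------
    ValueError
        For fewer than 3 surveys, a schedule not covering every interval, or
        inconsistent iteration counts.
    MCMCDiagnosticError
        If any proposal block accepts nothing after the adaptation window,
        which indicates the step scales are badly sized for the posterior.
    """
    if priors is None:
        priors = PriorSpec()
    if data.n_surveys < 3:
        raise ValueError("at least 3 surveys are required for fitting")
    if len(schedule) != data.n_surveys - 1:
        raise ValueError(
            f"schedule has {len(schedule)} intervals but the series needs "
            f"{data.n_surveys - 1}"
        )
    if not (n_iter > n_burn >= 0):
        raise ValueError("need n_iter > n_burn >= 0")
    if n_chains < 2:
        raise ValueError("n_chains must be >= 2 for convergence diagnostics")

    T = data.n_surveys
    C = n_chains
    rng = np.random.default_rng(seed)

    log_y = np.log(np.asarray(data.means))
    tau = data.log_sd
    inv2tau2 = 0.5 / tau**2
    n0_center, n0_log_sd = priors.resolve_n0(data)
    mu0, inv2sd0 = math.log(n0_center), 0.5 / n0_log_sd**2
    kinds = [kind for kind, _ in schedule.entries]
    values = np.array([v for _, v in schedule.entries])
    k_lo, k_hi = priors.k_bounds
    r_lo, r_hi = priors.r_max_bounds
    s_lo, s_hi = priors.sigma_bounds

    K = np.empty(C)
    r = np.empty(C)
    sig = np.empty(C)
    x = np.empty((C, T))
    for c in range(C):
        K[c], r[c], sig[c], x[c] = _propose_start(rng, priors, data, schedule, timing)

    def log_pred_all(Kv, rv, xv):
        """log of deterministic predictions for every interval; nan where <= 0."""
        N = np.exp(xv[:, :-1])
        out = np.empty_like(N)
        for t in range(T - 1):
            pred = det_step(N[:, t], Kv, rv, kinds[t], values[t], timing)
            with np.errstate(divide="ignore", invalid="ignore"):
                out[:, t] = np.where(pred > 0, np.log(np.maximum(pred, 1e-300)), np.nan)
        return out

    def proc_quad(lp, xv, sv):
        """Process-layer log-density up to the sigma normalisation constant."""
        dev = xv[:, 1:] - lp
        q = -np.sum(dev**2, axis=1) / (2.0 * sv**2)
        return np.where(np.isnan(lp).any(axis=1), -np.inf, q)

    lp_cur = log_pred_all(K, r, x)

    # one proposal scale per scalar block per chain, adapted during burn-in
    n_blocks = 3 + T
    scales = np.empty((n_blocks, C))
    scales[0] = 0.1 * (k_hi - k_lo)
    scales[1] = 0.1 * (r_hi - r_lo)
    scales[2] = 0.1 * (s_hi - s_lo)
    scales[3:] = 0.3
    acc_batch = np.zeros((n_blocks, C))
    acc_post = np.zeros((n_blocks, C))
    batch_len = 50
    batch_count = 0

    n_kept = (n_iter - n_burn + thin - 1) // thin
    out_K = np.empty((C, n_kept))
    out_r = np.empty((C, n_kept))
    out_s = np.empty((C, n_kept))
    out_x = np.empty((C, n_kept, T))
    kept = 0

    log_u = None  # filled per-iteration chunk below
    for it in range(n_iter):
        adapting = it < n_burn
        # --- K block ---
        Kp = K + rng.normal(0.0, scales[0])
        ok = (Kp >= k_lo) & (Kp <= k_hi)
        lp_prop = log_pred_all(np.where(ok, Kp, K), r, x)
        delta = proc_quad(lp_prop, x, sig) - proc_quad(lp_cur, x, sig)
        accept = ok & (np.log(rng.random(C)) < delta)
        K = np.where(accept, Kp, K)
        lp_cur = np.where(accept[:, None], lp_prop, lp_cur)
        acc_batch[0] += accept
        if not adapting:
            acc_post[0] += accept

        # --- r_max block ---
        rp = r + rng.normal(0.0, scales[1])
        ok = (rp >= r_lo) & (rp <= r_hi)
        lp_prop = log_pred_all(K, np.where(ok, rp, r), x)
        delta = proc_quad(lp_prop, x, sig) - proc_quad(lp_cur, x, sig)
        accept = ok & (np.log(rng.random(C)) < delta)
        r = np.where(accept, rp, r)
        lp_cur = np.where(accept[:, None], lp_prop, lp_cur)
        acc_batch[1] += accept
        if not adapting:
            acc_post[1] += accept

        # --- sigma block (predictions unchanged; only the normal scale moves) ---
        sp = sig + rng.normal(0.0, scales[2])
        ok = (sp >= s_lo) & (sp <= s_hi)
        sse = np.sum((x[:, 1:] - lp_cur) ** 2, axis=1)
        sp_safe = np.where(ok, sp, sig)
        delta = (T - 1) * (np.log(sig) - np.log(sp_safe)) - 0.5 * sse * (
            1.0 / sp_safe**2 - 1.0 / sig**2
        )
        accept = ok & (np.log(rng.random(C)) < delta)
        sig = np.where(accept, sp, sig)
        acc_batch[2] += accept
        if not adapting:
            acc_post[2] += accept

        # --- latent-state blocks ---
        steps = rng.normal(0.0, 1.0, size=(T, C)) * scales[3:]
        log_us = np.log(rng.random((T, C)))
        inv2s2 = 0.5 / sig**2
        for t in range(T):
            xp = x[:, t] + steps[t]
            delta = inv2tau2[t] * ((log_y[t] - x[:, t]) ** 2 - (log_y[t] - xp) ** 2)
            if t == 0:
                delta += inv2sd0 * ((x[:, 0] - mu0) ** 2 - (xp - mu0) ** 2)
            if t > 0:
                lp_prev = lp_cur[:, t - 1]
                delta += inv2s2 * ((x[:, t] - lp_prev) ** 2 - (xp - lp_prev) ** 2)
            if t < T - 1:
                pred = det_step(np.exp(xp), K, r, kinds[t], values[t], timing)
                with np.errstate(divide="ignore", invalid="ignore"):
                    lp_new = np.where(
                        pred > 0, np.log(np.maximum(pred, 1e-300)), np.nan
                    )
                old_term = inv2s2 * (x[:, t + 1] - lp_cur[:, t]) ** 2
                new_term = inv2s2 * (x[:, t + 1] - lp_new) ** 2
                delta = delta + old_term - np.where(np.isnan(lp_new), np.inf, new_term)
            accept = log_us[t] < delta
            x[:, t] = np.where(accept, xp, x[:, t])
            if t < T - 1:
                lp_cur[:, t] = np.where(accept, lp_new, lp_cur[:, t])
            acc_batch[3 + t] += accept
            if not adapting:
                acc_post[3 + t] += accept

        if adapting and (it + 1) % batch_len == 0:
            batch_count += 1
            rate = acc_batch / batch_len
            step = min(0.05, 1.0 / math.sqrt(batch_count))
            scales *= np.exp(np.where(rate > 0.44, step, -step))
            acc_batch[:] = 0.0

        if not adapting and (it - n_burn) % thin == 0:
            out_K[:, kept] = K
            out_r[:, kept] = r
            out_s[:, kept] = sig
            out_x[:, kept] = x
            kept += 1

    post_iters = n_iter - n_burn
    if post_iters > 0 and np.any(acc_post.sum(axis=1) == 0):
        dead = [i for i in range(n_blocks) if acc_post[i].sum() == 0]
        raise MCMCDiagnosticError(
            f"proposal blocks {dead} accepted nothing after the adaptation "
            "window; widen or narrow the step scales, or check the data"
        )

    acceptance = {
        "K": acc_post[0] / max(post_iters, 1),
        "r_max": acc_post[1] / max(post_iters, 1),
        "sigma_proc": acc_post[2] / max(post_iters, 1),
        "latent": acc_post[3:] / max(post_iters, 1),
    }
    return MCMCResult(
        K=out_K[:, :kept],
        r_max=out_r[:, :kept],
        sigma_proc=out_s[:, :kept],
        log_n=out_x[:, :kept],
        years=tuple(data.years),
        seed=seed,
        acceptance=acceptance,
        priors=priors,
        schedule=schedule,
        timing=timing,
    )


def summarize_posterior(
    result: MCMCResult,
    quantities: Sequence[str] = ("K", "r_max", "sigma_proc", "h_msy"),
) -> pd.DataFrame:
    """Posterior summary table: mean, SD, median, 2.5/97.5th percentiles.

    Derived quantities (``h_msy``) are transformed draw-by-draw before
    summarising, never by transforming the summaries.  Effective sample size
    and the split-chain convergence statistic are appended per quantity.
    """
    if result.n_draws == 0:
        raise ValueError("no retained draws to summarize")
    if result.n_draws < 1000:
        raise ValueError(
            f"need >= 1000 retained draws for stable summaries, have {result.n_draws}"
        )
    rows = []
    for name in quantities:
        draws = result._scalar_draws(name)
        flat = draws.ravel()
        rows.append(
            {
                "quantity": name,
                "mean": float(np.mean(flat)),
                "sd": float(np.std(flat, ddof=1)),
                "median": float(np.median(flat)),
                "q2_5": float(np.percentile(flat, 2.5)),
                "q97_5": float(np.percentile(flat, 97.5)),
                "ess": result.ess(name),
                "rhat": result.rhat(name),
            }
        )
    return pd.DataFrame(rows).set_index("quantity")
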