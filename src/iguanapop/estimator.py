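"""Scikit-learn-style front end to the state-space logistic fit.

:class:`StateSpaceLogistic` packages priors and sampler settings as
estimator parameters, exposes the fit through trailing-underscore
attributes, and offers ``predict`` (posterior-mean latent abundance for the
fitted years) and ``project`` (scenario forecasting).  It composes with
sklearn's ``get_params`` / ``set_params`` / ``clone`` machinery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .growth import HarvestSchedule
from .inference import PriorSpec, SurveySeries, run_mcmc, summarize_posterior
from .projection import ScenarioBand, ScenarioProjection, project

__all__ = ["StateSpaceLogistic"]


class StateSpaceLogistic(BaseEstimator):
    """Bayesian state-space logistic population model with harvest.

    Parameters
    ----------
    k_bounds, r_max_bounds, sigma_bounds : tuple of float
        Uniform prior bounds for carrying capacity (individuals), maximum
        intrinsic growth rate (per year) and log-scale process SD.
    n_chains, n_iter, n_burn, thin : int
        MCMC settings; ``n_iter`` counts total iterations per chain.
    random_state : int
        Seed for the whole sampling run.
    timing : {"escapement", "simultaneous"}
        Harvest ordering of the population update (removals before growth,
        or the classical simultaneous Schaefer form).

    Attributes
    ----------
    posterior_ : pandas.DataFrame
        One row per retained draw (K, r_max, sigma_proc, h_msy, latent
        abundances per survey year).
    summary_ : pandas.DataFrame
        Posterior mean/SD/median/percentiles plus ESS and split-chain
        statistic per quantity.
    result_ : MCMCResult
        The raw chain container (arrays per chain).
    years_ : tuple of int
        Survey years the model was fitted to.
    """

    def __init__(
        self,
        k_bounds: tuple[float, float] = (900_000.0, 2_000_000.0),
        r_max_bounds: tuple[float, float] = (0.500, 2.000),
        sigma_bounds: tuple[float, float] = (0.01, 1.0),
        n_chains: int = 4,
        n_iter: int = 50_000,
        n_burn: int = 25_000,
        thin: int = 1,
        random_state: int = 0,
        timing: str = "escapement",
    ):
        self.k_bounds = k_bounds
        self.r_max_bounds = r_max_bounds
        self.sigma_bounds = sigma_bounds
        self.n_chains = n_chains
        self.n_iter = n_iter
        self.n_burn = n_burn
        self.thin = thin
        self.random_state = random_state
        self.timing = timing

    def _priors(self) -> PriorSpec:
        return PriorSpec(
            k_bounds=tuple(self.k_bounds),
            r_max_bounds=tuple(self.r_max_bounds),
            sigma_bounds=tuple(self.sigma_bounds),
        )

    def fit(self, X, y=None, *, harvest=None) -> "StateSpaceLogistic":
        """Fit to a survey series.

        ``X`` is a :class:`SurveySeries` or a DataFrame with columns
        ``year, mean, se``; ``harvest`` is a :class:`HarvestSchedule` or a
        sequence of per-interval rates (defaults to no harvest).
        """
        if isinstance(X, SurveySeries):
            data = X
        else:
            frame = pd.DataFrame(X)
            data = SurveySeries.from_arrays(frame["year"], frame["mean"], frame["se"])
        if harvest is None:
            harvest = HarvestSchedule.no_harvest(data.n_surveys - 1)
        elif not isinstance(harvest, HarvestSchedule):
            harvest = HarvestSchedule.from_rates(harvest)
        self.result_ = run_mcmc(
            data,
            harvest,
            priors=self._priors(),
            n_chains=self.n_chains,
            n_iter=self.n_iter,
            n_burn=self.n_burn,
            seed=self.random_state,
            thin=self.thin,
            timing=self.timing,
        )
        self.posterior_ = self.result_.to_frame()
        self.summary_ = summarize_posterior(self.result_)
        self.years_ = self.result_.years
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "result_"):
            raise AttributeError("this StateSpaceLogistic instance is not fitted yet")

    def predict(self, X=None) -> np.ndarray:
        """Posterior-mean latent abundance at each fitted survey year."""
        self._check_fitted()
        return np.exp(self.result_.log_n).mean(axis=(0, 1))

    def project(
        self,
        scenario: ScenarioBand,
        seed: int | None = None,
        n_draws: int | None = None,
        process_noise: bool = True,
    ) -> ScenarioProjection:
        """Forward Monte Carlo projection under a harvest-rate band."""
        self._check_fitted()
        if seed is None:
            seed = self.random_state + 1
        return project(
            self.result_, scenario, seed=seed, n_draws=n_draws, process_noise=process_noise
        )
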