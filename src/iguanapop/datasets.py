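"""Packaged Grand Cayman green iguana survey data and study constants.

The islandwide August 2014-2021 post-reproduction survey series (means,
bootstrapped SEs and lognormal 95% CIs from the published distance-sampling
analysis) ships as a small CSV, together with the published annual harvest
rates and the six harvest-rate scenario bands used for projection.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .growth import HarvestSchedule
from .inference import SurveySeries
from .projection import ScenarioBand

__all__ = [
    "load_surveys",
    "load_harvest",
    "default_bands",
    "PRIOR_K",
    "PRIOR_R_MAX",
    "PRIOR_SIGMA_PROC",
    "HARVEST_RATES",
    "HARVEST_RATE_2018_ALT",
]

#: Uniform prior bounds used in the published fit (individuals; per year).
PRIOR_K = (900_000.0, 2_000_000.0)
PRIOR_R_MAX = (0.500, 2.000)
#: Log-scale process-SD prior; the publication leaves it unstated, this is
#: the package default (see docs/methods.md).
PRIOR_SIGMA_PROC = (0.01, 1.0)

#: Published annual harvest rates per inter-survey interval.  The cull began
#: in October 2018, so the four 2014->2018 intervals are zero.  Two printed
#: rates touch the 2018->2019 interval (0.629 Oct 2018-Jul 2019, 0.568 in
#: August 2019); 0.629 is the default, 0.568 the recorded alternative.
HARVEST_RATES: dict[str, float] = {
    "2014-2015": 0.0,
    "2015-2016": 0.0,
    "2016-2017": 0.0,
    "2017-2018": 0.0,
    "2018-2019": 0.629,
    "2019-2020": 0.374,
    "2020-2021": 0.082,
}
HARVEST_RATE_2018_ALT = 0.568


def _data_path(name: str):
    return resources.files("iguanapop.data").joinpath(name)


def load_surveys() -> SurveySeries:
    """The packaged 2014-2021 survey series (8 annual estimates)."""
    from .io import read_surveys

    with resources.as_file(_data_path("table1.csv")) as path:
        return read_surveys(path)


def load_harvest(alt_2018_rate: bool = False) -> HarvestSchedule:
    """The 7-interval harvest-rate schedule matching the packaged surveys."""
    rates = list(HARVEST_RATES.values())
    if alt_2018_rate:
        rates[4] = HARVEST_RATE_2018_ALT
    return HarvestSchedule.from_rates(rates)


def default_bands(horizon: int = 9) -> list[ScenarioBand]:
    """The six uniform harvest-rate scenario bands of the published study.

    The default 9-year horizon spans August 2022-2030 when projection starts
    from the August 2021 state.
    """
    limits = [
        (0.001, 0.100),
        (0.101, 0.300),
        (0.301, 0.500),
        (0.501, 0.700),
        (0.701, 0.900),
        (0.001, 0.900),
    ]
    return [
        ScenarioBand(label=f"{lo:.3f}-{hi:.3f}", lower=lo, upper=hi, horizon=horizon)
        for lo, hi in limits
    ]


def surveys_frame() -> pd.DataFrame:
    """The raw packaged table as a DataFrame (year, mean, se, ci columns)."""
    with resources.as_file(_data_path("table1.csv")) as path:
        return pd.read_csv(path, thousands=",")
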