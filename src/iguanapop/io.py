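"""Readers, writers, run configuration, and reporting-convention utilities.

Survey and harvest data travel as plain CSV with explicit headers; thousands
separators are tolerated on input because published tables print them.
Run configuration is YAML (or JSON) validated against the same bounds as the
prior and scenario types, with unknown keys rejected.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .growth import HarvestSchedule
from .inference import PriorSpec, SurveySeries
from .projection import ScenarioBand

__all__ = [
    "read_surveys",
    "write_surveys",
    "read_harvest",
    "write_harvest",
    "lognormal_ci",
    "RunConfig",
    "write_study",
    "read_study",
]


def read_surveys(path) -> SurveySeries:
    """Read a survey series CSV with columns ``year,mean,se`` (extras ignored).

    Validation failures name the offending CSV row (1-based, excluding the
    header).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, thousands=",", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no data (empty file)") from None
    for col in ("year", "mean", "se"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    years, means, ses = [], [], []
    seen: dict[int, int] = {}
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        try:
            year = int(getattr(rec, "year"))
            mean = float(getattr(rec, "mean"))
            se = float(getattr(rec, "se"))
        except (TypeError, ValueError) as err:
            raise ValueError(f"{path}: row {i}: unparseable value ({err})") from None
        if year in seen:
            raise ValueError(f"{path}: row {i}: duplicate year {year} (also row {seen[year]})")
        seen[year] = i
        if not (math.isfinite(mean) and mean > 0):
            raise ValueError(f"{path}: row {i}: mean for year {year} must be > 0, got {mean}")
        if not (math.isfinite(se) and se > 0):
            raise ValueError(f"{path}: row {i}: SE for year {year} must be > 0, got {se}")
        years.append(year)
        means.append(mean)
        ses.append(se)
    order = np.argsort(years)
    if not np.array_equal(order, np.arange(len(years))):
        raise ValueError(f"{path}: years must be strictly increasing")
    return SurveySeries.from_arrays(years, means, ses)


def write_surveys(series: SurveySeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_harvest(path) -> HarvestSchedule:
    """Read a harvest CSV with columns ``interval,kind,value``.

    ``kind`` is ``rate`` or ``total``; intervals are kept in file order.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, thousands=",", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no data (empty file)") from None
    for col in ("kind", "value"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    entries = []
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        kind = str(getattr(rec, "kind")).strip()
        try:
            value = float(getattr(rec, "value"))
        except (TypeError, ValueError) as err:
            raise ValueError(f"{path}: row {i}: unparseable value ({err})") from None
        try:
            HarvestSchedule([(kind, value)])
        except ValueError as err:
            raise ValueError(f"{path}: row {i}: {err}") from None
        entries.append((kind, value))
    if not entries:
        raise ValueError(f"{path}: no data rows")
    return HarvestSchedule(entries)


def write_harvest(schedule: HarvestSchedule, path, labels=None) -> None:
    rows = []
    for i, (kind, value) in enumerate(schedule.entries):
        label = labels[i] if labels is not None else i
        rows.append({"interval": label, "kind": kind, "value": value})
    pd.DataFrame(rows).to_csv(path, index=False)


def lognormal_ci(mean: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Lognormal confidence interval for a positive estimate.

    ``C = exp(z * sqrt(ln(1 + (se/mean)^2)))`` with ``z`` the standard-normal
    quantile for the confidence level; returns ``(mean / C, mean * C)``, so
    the bounds multiply back to ``mean**2`` exactly.
    """
    if not (math.isfinite(mean) and mean > 0):
        raise ValueError(f"mean must be > 0, got {mean}")
    if not (math.isfinite(se) and se > 0):
        raise ValueError(f"se must be > 0, got {se}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    z = stats.norm.ppf(0.5 + level / 2.0)
    C = math.exp(z * math.sqrt(math.log1p((se / mean) ** 2)))
    return mean / C, mean * C


_CONFIG_KEYS = {
    "surveys",
    "harvest",
    "priors",
    "mcmc",
    "timing",
    "scenarios",
    "output_dir",
    "report",
}
_PRIOR_KEYS = {"k_bounds", "r_max_bounds", "sigma_bounds", "n0_center", "n0_log_sd"}
_MCMC_KEYS = {"n_chains", "n_iter", "n_burn", "seed", "thin"}
_SCENARIO_KEYS = {"label", "lower", "upper", "horizon", "no_harvest", "mode"}
_REPORT_KEYS = {"plots", "n_projection_draws"}


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration for the command-line workflow."""

    surveys: str | None = None
    harvest: str | None = None
    timing: str = "escapement"
    priors: PriorSpec = field(default_factory=PriorSpec)
    n_chains: int = 4
    n_iter: int = 50_000
    n_burn: int = 25_000
    seed: int = 0
    thin: int = 1
    scenarios: tuple[ScenarioBand, ...] = ()
    output_dir: str = "."
    plots: bool = False
    n_projection_draws: int | None = None

    def __post_init__(self) -> None:
        if not (self.n_iter > self.n_burn >= 0):
            raise ValueError("need n_iter > n_burn >= 0")
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.timing not in ("escapement", "simultaneous"):
            raise ValueError(f"unknown timing {self.timing!r}")

    @classmethod
    def from_mapping(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")

        def _sub(section, allowed):
            block = raw.get(section) or {}
            bad = set(block) - allowed
            if bad:
                raise ValueError(f"unknown keys in {section!r}: {sorted(bad)}")
            return block

        prior_block = _sub("priors", _PRIOR_KEYS)
        for key in ("k_bounds", "r_max_bounds", "sigma_bounds"):
            if key in prior_block:
                prior_block[key] = tuple(prior_block[key])
        priors = PriorSpec(**prior_block)
        mcmc = _sub("mcmc", _MCMC_KEYS)
        report = _sub("report", _REPORT_KEYS)
        bands = []
        for i, entry in enumerate(raw.get("scenarios") or []):
            bad = set(entry) - _SCENARIO_KEYS
            if bad:
                raise ValueError(f"unknown keys in scenarios[{i}]: {sorted(bad)}")
            entry = dict(entry)
            entry.setdefault("label", f"{entry.get('lower', 0)}-{entry.get('upper', 0)}")
            bands.append(ScenarioBand(**entry))
        return cls(
            surveys=raw.get("surveys"),
            harvest=raw.get("harvest"),
            timing=raw.get("timing", "escapement"),
            priors=priors,
            scenarios=tuple(bands),
            output_dir=raw.get("output_dir", "."),
            plots=bool(report.get("plots", False)),
            n_projection_draws=report.get("n_projection_draws"),
            **mcmc,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_mapping(raw)

    def echo(self) -> dict:
        out = dataclasses.asdict(self)
        out["priors"] = dataclasses.asdict(self.priors)
        out["scenarios"] = [dataclasses.asdict(b) for b in self.scenarios]
        return out


def write_study(study, directory) -> None:
    """Write a synthetic study as surveys.csv + harvest.csv + truth.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_surveys(study.surveys, directory / "surveys.csv")
    write_harvest(study.schedule, directory / "harvest.csv")
    truth = dict(study.truth)
    truth["seed"] = study.seed
    truth["cv_design"] = list(study.cv_design)
    truth["latent"] = study.trajectory.abundances.tolist()
    (directory / "truth.json").write_text(json.dumps(truth, indent=2))


def read_study(directory) -> tuple[SurveySeries, HarvestSchedule, dict]:
    """Read back the (surveys, harvest, truth) triple written by write_study."""
    directory = Path(directory)
    surveys = read_surveys(directory / "surveys.csv")
    harvest = read_harvest(directory / "harvest.csv")
    truth = json.loads((directory / "truth.json").read_text())
    return surveys, harvest, truth
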