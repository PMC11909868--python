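"""Model-input registry: base values, sensitivity ranges, and PSA distributions.

Every input of the diagnostic decision model is described by a
:class:`ParameterSpec` holding its base-case value, the [low, high] interval
used in one-way sensitivity analysis, and the distribution sampled in
probabilistic sensitivity analysis (PSA).  Distributions are specified the way
health-economic sources usually report them — a lognormal by its (mean,
median), a beta by its (mean, SD) or by an explicit (alpha, beta) shape pair —
and the closed-form inversions to internal shape parameters live here.

A :class:`ParameterRegistry` validates the full set of inputs and realizes
concrete :class:`ParameterSet` objects: the base-case point, the
distribution-mean point, or an independent Monte Carlo draw.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

import numpy as np
import yaml

__all__ = [
    "ConfigError",
    "DistributionSpec",
    "ParameterSpec",
    "ParameterSet",
    "ParameterRegistry",
    "solve_lognormal",
    "solve_beta_mean_sd",
    "load_registry",
    "default_registry",
    "default_config_text",
]


class ConfigError(ValueError):
    """A model-input configuration is missing, inconsistent, or unsolvable."""


def solve_lognormal(mean: float, median: float) -> tuple[float, float]:
    """Invert a lognormal's (mean, median) to the underlying normal (mu, sigma).

    For ``X ~ LogNormal(mu, sigma)``: ``median = exp(mu)`` and
    ``mean = exp(mu + sigma^2/2)``, so ``mu = ln(median)`` and
    ``sigma = sqrt(2 ln(mean/median))``.  This is the unique two-parameter
    solution; ``mean == median`` degenerates to a point mass (sigma = 0).

    Raises
    ------
    ConfigError
        If either input is non-positive, or ``mean < median`` (a lognormal's
        mean never falls below its median).
    """
    if mean <= 0 or median <= 0:
        raise ConfigError(
            f"lognormal(mean={mean}, median={median}): inputs must be positive"
        )
    if mean < median:
        raise ConfigError(
            f"lognormal(mean={mean}, median={median}): mean must be >= median"
        )
    mu = math.log(median)
    sigma = math.sqrt(2.0 * math.log(mean / median))
    return mu, sigma


def solve_beta_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments (alpha, beta) for a beta with the given mean and SD.

    With ``nu = mean(1-mean)/sd^2 - 1``: ``alpha = mean*nu``,
    ``beta = (1-mean)*nu``.  Requires ``0 < mean < 1`` and
    ``sd^2 < mean(1-mean)`` (otherwise no beta distribution exists).
    """
    if not 0.0 < mean < 1.0:
        raise ConfigError(f"beta(mean={mean}, sd={sd}): mean must be in (0, 1)")
    if sd <= 0:
        raise ConfigError(f"beta(mean={mean}, sd={sd}): sd must be positive")
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise ConfigError(
            f"beta(mean={mean}, sd={sd}): sd^2 must be < mean*(1-mean)"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


@dataclass(frozen=True)
class DistributionSpec:
    """A PSA sampling distribution in the parameterization its source reports.

    Parameters
    ----------
    family : {"lognormal", "beta", "normal", "fixed"}
    parameterization : {"mean_median", "mean_sd", "shape_pair", "point"}
    given : mapping
        The 1-2 named summaries, e.g. ``{"mean": 5000, "median": 4900}`` or
        ``{"alpha": 27, "beta": 7}``.
    support : (low, high)
        Closed interval used for validation and (for the normal family)
        truncation by resampling.
    """

    family: str
    parameterization: str
    given: Mapping[str, float]
    support: tuple[float, float] = (-math.inf, math.inf)

    _FAMILIES = ("lognormal", "beta", "normal", "fixed")

    def __post_init__(self) -> None:
        if self.family not in self._FAMILIES:
            raise ConfigError(f"unknown distribution family {self.family!r}")
        # Solve eagerly so a bad spec fails at construction, not at sampling.
        object.__setattr__(self, "_shape", self._solve())

    def _solve(self) -> tuple[float, ...]:
        g = self.given
        if self.family == "lognormal":
            if self.parameterization != "mean_median":
                raise ConfigError(
                    f"lognormal supports mean_median only, got {self.parameterization!r}"
                )
            return solve_lognormal(g["mean"], g["median"])
        if self.family == "beta":
            if self.parameterization == "mean_sd":
                return solve_beta_mean_sd(g["mean"], g["sd"])
            if self.parameterization == "shape_pair":
                a, b = float(g["alpha"]), float(g["beta"])
                if a <= 0 or b <= 0:
                    raise ConfigError(f"beta shape pair must be positive, got ({a}, {b})")
                return a, b
            raise ConfigError(f"beta does not support {self.parameterization!r}")
        if self.family == "normal":
            if self.parameterization != "mean_sd":
                raise ConfigError(f"normal supports mean_sd only")
            if g["sd"] < 0:
                raise ConfigError("normal sd must be >= 0")
            return float(g["mean"]), float(g["sd"])
        # fixed
        if self.parameterization != "point":
            raise ConfigError("fixed distribution must use the point parameterization")
        return (float(g["value"]),)

    @property
    def shape(self) -> tuple[float, ...]:
        """Solved internal shape parameters (mu/sigma, alpha/beta, mean/sd, or value)."""
        return self._shape  # type: ignore[attr-defined]

    def mean(self) -> float:
        """Analytic mean of the distribution.

        For the truncated normal the untruncated mean is returned; with the
        default inputs the truncation point sits 3 SD below the mean and the
        bias is < 1e-4 of the SD.
        """
        if self.family == "lognormal":
            mu, sigma = self.shape
            return math.exp(mu + 0.5 * sigma * sigma)
        if self.family == "beta":
            a, b = self.shape
            return a / (a + b)
        if self.family == "normal":
            return self.shape[0]
        return self.shape[0]

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw from the distribution; the normal family resamples values
        outside ``support`` (a negative quality-of-life decrement is
        meaningless)."""
        if self.family == "lognormal":
            mu, sigma = self.shape
            return rng.lognormal(mu, sigma, size)
        if self.family == "beta":
            a, b = self.shape
            return rng.beta(a, b, size)
        if self.family == "normal":
            m, s = self.shape
            lo, hi = self.support
            x = np.atleast_1d(rng.normal(m, s, size if size is not None else 1))
            bad = (x < lo) | (x > hi)
            while bad.any():
                x[bad] = rng.normal(m, s, int(bad.sum()))
                bad = (x < lo) | (x > hi)
            return x if size is not None else float(x[0])
        v = self.shape[0]
        return np.full(size, v) if size is not None else v


@dataclass(frozen=True)
class ParameterSpec:
    """One model-input row: base value, sensitivity range, PSA distribution."""

    name: str
    base_value: float
    range_low: float
    range_high: float
    distribution: DistributionSpec
    psa_fixed: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if not self.range_low <= self.base_value <= self.range_high:
            raise ConfigError(
                f"{self.name}: base value {self.base_value} outside sensitivity "
                f"range [{self.range_low}, {self.range_high}]"
            )


@dataclass(frozen=True)
class ParameterSet:
    """One concrete assignment of every model symbol.

    Costs are lifetime 2022 US dollars; ``q_*`` are lifetime QALYs by terminal
    classification state; ``u_*`` are QALY decrements.  ``treat_cost_multiplier``
    and ``p_inconclusive_treat`` are scenario knobs (not Table-style inputs):
    they default to the base analysis and are set per scenario run.
    """

    c_algo: float
    c_classifier: float
    c_bronch: float
    c_slb: float
    c_symptom: float
    c_treat: float
    p_referral: float
    sens_algo: float
    spec_algo: float
    sens_gc: float
    spec_gc: float
    p_biopsy_death: float
    sens_biopsy: float
    spec_biopsy: float
    p_fp_benefit_test: float
    p_fp_benefit_treatall: float
    prevalence: float
    u_biopsy: float
    q_tp: float
    q_fp: float
    q_tn: float
    q_fn: float
    u_complication: float
    treat_cost_multiplier: float = 1.0
    p_inconclusive_treat: float = 0.0

    _PROBS = (
        "p_referral", "sens_algo", "spec_algo", "sens_gc", "spec_gc",
        "p_biopsy_death", "sens_biopsy", "spec_biopsy", "p_fp_benefit_test",
        "p_fp_benefit_treatall", "prevalence", "p_inconclusive_treat",
    )
    _COSTS = ("c_algo", "c_classifier", "c_bronch", "c_slb", "c_symptom", "c_treat")

    def __post_init__(self) -> None:
        for name in self._PROBS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} is not a probability in [0, 1]")
        for name in self._COSTS:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be a nonnegative cost")
        for name in ("q_tp", "q_fp", "q_tn", "q_fn"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be a nonnegative QALY total")
        if self.treat_cost_multiplier < 0:
            raise ConfigError("treat_cost_multiplier must be nonnegative")

    def replace(self, **changes) -> "ParameterSet":
        return dataclasses.replace(self, **changes)


#: Registry field names (everything in ParameterSet except scenario knobs).
SYMBOLS: tuple[str, ...] = tuple(
    f.name
    for f in dataclasses.fields(ParameterSet)
    if f.name not in ("treat_cost_multiplier", "p_inconclusive_treat")
)


class ParameterRegistry:
    """Validated, ordered collection of :class:`ParameterSpec` rows."""

    def __init__(self, specs: list[ParameterSpec]):
        self._specs: dict[str, ParameterSpec] = {}
        for s in specs:
            if s.name in self._specs:
                raise ConfigError(f"duplicate parameter {s.name!r}")
            if s.name not in SYMBOLS:
                raise ConfigError(f"unknown parameter {s.name!r}")
            self._specs[s.name] = s
        missing = [name for name in SYMBOLS if name not in self._specs]
        if missing:
            raise ConfigError(f"missing parameter(s): {', '.join(missing)}")

    def __getitem__(self, name: str) -> ParameterSpec:
        return self._specs[name]

    def __iter__(self) -> Iterator[ParameterSpec]:
        return iter(self._specs.values())

    def __len__(self) -> int:
        return len(self._specs)

    def names(self) -> tuple[str, ...]:
        return tuple(self._specs)

    def realize(
        self, mode: str = "base", rng: np.random.Generator | None = None
    ) -> ParameterSet:
        """Produce one concrete :class:`ParameterSet`.

        mode="base"
            Every symbol at its base-case value.
        mode="distribution_mean"
            Every non-fixed symbol at its PSA distribution's analytic mean
            (e.g. a Beta(27, 7) input realizes as 27/34, not its base value);
            fixed rows at their base value.
        mode="sample"
            An independent Monte Carlo draw from every non-fixed distribution;
            requires ``rng``; fixed rows stay at base.
        """
        if mode == "base":
            values = {s.name: s.base_value for s in self}
        elif mode == "distribution_mean":
            values = {
                s.name: s.base_value if s.psa_fixed else s.distribution.mean()
                for s in self
            }
        elif mode == "sample":
            if rng is None:
                raise ConfigError("mode='sample' requires an rng")
            values = {
                s.name: s.base_value if s.psa_fixed else float(s.distribution.sample(rng))
                for s in self
            }
        else:
            raise ConfigError(f"unknown realization mode {mode!r}")
        return ParameterSet(**values)


def _spec_from_entry(entry: Mapping) -> ParameterSpec:
    try:
        name = entry["name"]
    except (KeyError, TypeError):
        raise ConfigError("parameter entry without a 'name'") from None
    try:
        dist_cfg = dict(entry["dist"])
        family = dist_cfg.pop("family")
        parameterization = dist_cfg.pop("parameterization")
        base = float(entry["base"])
        low = float(entry["low"])
        high = float(entry["high"])
    except KeyError as exc:
        raise ConfigError(f"{name}: missing field {exc}") from None
    support = (-math.inf, math.inf)
    if family == "beta":
        support = (0.0, 1.0)
    elif family == "normal":
        support = (max(0.0, low), math.inf)
    try:
        dist = DistributionSpec(family, parameterization, dist_cfg, support)
    except ConfigError as exc:
        raise ConfigError(f"{name}: {exc}") from None
    try:
        return ParameterSpec(
            name=name,
            base_value=base,
            range_low=low,
            range_high=high,
            distribution=dist,
            psa_fixed=bool(entry.get("psa_fixed", False)),
            label=entry.get("label", ""),
        )
    except ConfigError:
        raise


def load_registry(config) -> ParameterRegistry:
    """Build a registry from a config mapping, YAML/JSON text, or file path."""
    if isinstance(config, ParameterRegistry):
        return config
    if isinstance(config, (str, bytes)):
        import os

        if isinstance(config, str) and (
            os.path.exists(config) or config.endswith((".yaml", ".yml", ".json"))
        ):
            if not os.path.exists(config):
                raise ConfigError(f"config file not found: {config}")
            with open(config) as fh:
                config = yaml.safe_load(fh)
        else:
            config = yaml.safe_load(config)
    if not isinstance(config, Mapping) or "parameters" not in config:
        raise ConfigError("config must be a mapping with a 'parameters' list")
    specs = [_spec_from_entry(e) for e in config["parameters"]]
    return ParameterRegistry(specs)


def default_config_text() -> str:
    """The packaged model-input transcription, verbatim YAML."""
    return (
        resources.files("ipfcea").joinpath("data/default_config.yaml").read_text()
    )


def default_registry() -> ParameterRegistry:
    """Registry built from the packaged default inputs."""
    return load_registry(yaml.safe_load(default_config_text()))
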