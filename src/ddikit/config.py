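"""Scenario and run configuration.

A :class:`ScenarioConfig` fully determines a synthetic hospitalization
data set: together with its seed it is a reproducible recipe, and two
generations from the same config are byte-identical. Defaults emulate
the structure of a national hospital discharge database partitioned
into 705 small residential regions, with diagnostic diversity decaying
log-logistically in travel time and rare-disease rates declining
log-linearly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple

import numpy as np
import yaml

from .decay import LogLogisticParams
from .errors import ConfigurationError

#: number of disease groups in the rare-disease nomenclature emulated here
DEFAULT_N_GROUPS = 35


def _default_group_slopes() -> np.ndarray:
    # 33 groups with a genuine travel-time decline, 2 null groups
    slopes = np.full(DEFAULT_N_GROUPS, -0.012)
    slopes[-2:] = 0.0
    return slopes


def _default_group_rates() -> np.ndarray:
    return np.full(DEFAULT_N_GROUPS, 10.0)


@dataclass
class ScenarioConfig:
    """Generating parameters of a synthetic hospitalization scenario.

    Attributes
    ----------
    n_regions : residential regions (default 705).
    travel_time_range : (min, max) minutes; travel times are uniform on
        this interval. Equal endpoints give a degenerate point mass.
    pop_median, pop_sigma : log-normal population law per region
        (median persons, log-scale SD).
    hospitalization_rate : inpatient cases per person over the study
        window.
    vocab_size : number of distinct ICD-10-like codes K.
    diag_count_p : success probability of the geometric law for the
        total codes per case (1 + geometric failures, capped at 51);
        the default 0.27 targets median 3 with IQR (1, 5).
    ddi_curve : true log-logistic decay of regional DDI vs travel time.
    group_baseline_rates : per-group rare-disease hospitalization rate
        at travel time 0, cases per 10,000 persons per window.
    group_slopes : per-group log-linear travel-time slope, per minute.
    rd_code_fraction : fraction of the vocabulary reserved for
        rare-disease-associated codes (excluded from background coding,
        injected at the group rates).
    mapping_multiplicity : fraction of rare-disease ICD codes mapped to
        two ORPHAcodes instead of one (many-to-many structure).
    seed : RNG seed; all stage substreams derive from it.
    """

    n_regions: int = 705
    travel_time_range: Tuple[float, float] = (0.0, 120.0)
    pop_median: float = 5000.0
    pop_sigma: float = 0.5
    hospitalization_rate: float = 0.75
    vocab_size: int = 2000
    diag_count_p: float = 0.27
    ddi_curve: LogLogisticParams = field(
        default_factory=lambda: LogLogisticParams(
            ddi_low=4.0, ddi_up=6.9, tau=0.1, t_half=41.0
        )
    )
    group_baseline_rates: np.ndarray = field(default_factory=_default_group_rates)
    group_slopes: np.ndarray = field(default_factory=_default_group_slopes)
    rd_code_fraction: float = 0.087
    mapping_multiplicity: float = 0.2
    seed: int = 0

    def __post_init__(self):
        self.group_baseline_rates = np.asarray(self.group_baseline_rates, dtype=float)
        self.group_slopes = np.asarray(self.group_slopes, dtype=float)
        self.validate()

    @property
    def n_groups(self) -> int:
        return len(self.group_baseline_rates)

    @property
    def n_rd_codes(self) -> int:
        return int(round(self.rd_code_fraction * self.vocab_size))

    def validate(self) -> None:
        lo, hi = self.travel_time_range
        if self.n_regions < 1:
            raise ConfigurationError("n_regions must be >= 1")
        if lo > hi or lo < 0:
            raise ConfigurationError(
                f"invalid travel_time_range {self.travel_time_range}"
            )
        if not 0 < self.diag_count_p < 1:
            raise ConfigurationError("diag_count_p must be in (0, 1)")
        if self.pop_median <= 0 or self.pop_sigma < 0:
            raise ConfigurationError("population law requires median > 0, sigma >= 0")
        if self.hospitalization_rate < 0:
            raise ConfigurationError("hospitalization_rate must be >= 0")
        c = self.ddi_curve
        if not (c.ddi_up > c.ddi_low >= 0):
            raise ConfigurationError("need ddi_up > ddi_low >= 0")
        if c.tau <= 0:
            raise ConfigurationError("tau must be > 0")
        if not 0 < self.rd_code_fraction < 1:
            raise ConfigurationError("rd_code_fraction must be in (0, 1)")
        if len(self.group_slopes) != len(self.group_baseline_rates):
            raise ConfigurationError("group rate/slope arrays must align")
        if np.any(self.group_baseline_rates <= 0):
            raise ConfigurationError("group baseline rates must be positive")
        if self.n_rd_codes < self.n_groups:
            raise ConfigurationError(
                f"{self.n_rd_codes} flagged codes cannot cover {self.n_groups} groups"
            )
        if self.ddi_curve.ddi_up >= np.log(self.vocab_size - self.n_rd_codes):
            raise ConfigurationError(
                "ddi_up must lie below ln(background vocabulary size)"
            )

    # -- flat (de)serialization ------------------------------------------

    def to_flat_dict(self) -> dict:
        d = {
            "n_regions": self.n_regions,
            "travel_time_min": float(self.travel_time_range[0]),
            "travel_time_max": float(self.travel_time_range[1]),
            "pop_median": self.pop_median,
            "pop_sigma": self.pop_sigma,
            "hospitalization_rate": self.hospitalization_rate,
            "vocab_size": self.vocab_size,
            "diag_count_p": self.diag_count_p,
            "ddi_low": self.ddi_curve.ddi_low,
            "ddi_up": self.ddi_curve.ddi_up,
            "tau": self.ddi_curve.tau,
            "t_half": self.ddi_curve.t_half,
            "group_baseline_rates": [float(x) for x in self.group_baseline_rates],
            "group_slopes": [float(x) for x in self.group_slopes],
            "rd_code_fraction": self.rd_code_fraction,
            "mapping_multiplicity": self.mapping_multiplicity,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_flat_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        kwargs = {}
        for key in (
            "n_regions", "pop_median", "pop_sigma", "hospitalization_rate",
            "vocab_size", "diag_count_p", "rd_code_fraction",
            "mapping_multiplicity", "seed",
        ):
            if key in d:
                kwargs[key] = d[key]
        if "travel_time_min" in d or "travel_time_max" in d:
            kwargs["travel_time_range"] = (
                float(d.get("travel_time_min", 0.0)),
                float(d.get("travel_time_max", 120.0)),
            )
        if any(k in d for k in ("ddi_low", "ddi_up", "tau", "t_half")):
            kwargs["ddi_curve"] = LogLogisticParams(
                ddi_low=float(d.get("ddi_low", 4.0)),
                ddi_up=float(d.get("ddi_up", 6.9)),
                tau=float(d.get("tau", 0.1)),
                t_half=float(d.get("t_half", 41.0)),
            )
        if "group_baseline_rates" in d:
            kwargs["group_baseline_rates"] = np.asarray(d["group_baseline_rates"], float)
        if "group_slopes" in d:
            kwargs["group_slopes"] = np.asarray(d["group_slopes"], float)
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_flat_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_flat_dict(yaml.safe_load(fh))


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Exactly one of ``scenario`` (simulate inputs) or ``input_dir``
    (read previously written tables) must be supplied.
    """

    outdir: str = "ddikit_run"
    scenario: Optional[ScenarioConfig] = None
    input_dir: Optional[str] = None
    min_cases: int = 1
    weight_by_cases: bool = False
    bootstrap: int = 0
    alpha: float = 0.05
    seed: int = 0
    make_plots: bool = True

    def __post_init__(self):
        if (self.scenario is None) == (self.input_dir is None):
            raise ConfigurationError(
                "exactly one of scenario / input_dir must be supplied"
            )
        if not 0 <= self.alpha <= 1:
            raise ConfigurationError("alpha must be in [0, 1]")
        if self.min_cases < 1:
            raise ConfigurationError("min_cases must be >= 1")
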