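"""Screen configuration.

A single :class:`ScreenConfig` document drives every stage of the pipeline:
library composition, the concentration grid, plate geometry, the noise model,
curve-classification thresholds, decision-tree windows, and SOM settings.
Configs round-trip through YAML so a run is fully described by one file plus
one seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

TRUTH_CLASSES = (
    "full_agonist",
    "partial_agonist",
    "antagonist",
    "cytotoxic_only",
    "autofluorescent",
    "inactive",
    "selective_modulator",
)

#: default class mixture (fraction of the library per ground-truth class)
DEFAULT_MIXTURE = {
    "full_agonist": 0.08,
    "partial_agonist": 0.05,
    "antagonist": 0.05,
    "cytotoxic_only": 0.05,
    "autofluorescent": 0.02,
    "selective_modulator": 0.02,
    "inactive": 0.73,
}


class ConfigurationError(ValueError):
    """Raised when a ScreenConfig fails validation."""


@dataclass
class NoiseModel:
    """Noise applied to raw plate signals.

    multiplicative_sd: log-normal well noise (sd of log signal, ~CV).
    plate_sd: per-plate multiplicative random effect.
    additive_sd: additive Gaussian noise in raw signal units.
    """

    multiplicative_sd: float = 0.07
    plate_sd: float = 0.03
    additive_sd: float = 1.0

    @property
    def percent_sd(self) -> float:
        """Approximate noise sd on the normalized percent-activity scale."""
        return 100.0 * (self.multiplicative_sd**2 + self.plate_sd**2) ** 0.5


@dataclass
class ClassifyConfig:
    """Thresholds for grading fitted curves into curve classes."""

    r2_complete: float = 0.9      # minimum r2 for class 1.x
    r2_min: float = 0.6           # below this (with response) -> class 3
    efficacy_split: float = 80.0  # .1 vs .2 split, percent of control max
    min_response: float = 20.0    # floor on the significant-response threshold
    noise_multiplier: float = 3.0
    asymptote_tol: float = 0.1    # fraction of span for "asymptote reached"


@dataclass
class CallConfig:
    """Windows for the counter-screen demotion rules."""

    cytotox_ac50_window: float = 3.0    # viability/antagonist AC50 ratio window
    viability_loss_pct: float = 50.0    # loss at/below the antagonist AC50
    autofluor_sd_multiplier: float = 3.0


@dataclass
class SomConfig:
    rows: int | None = None  # None -> auto from library size
    cols: int | None = None
    epochs: int = 24
    sigma_end: float = 0.5
    compounds_per_cluster: float = 13.0  # sets auto grid density
    enrichment_p: float = 0.01
    metric: str = "euclidean"  # assignment distance; also: hamming, tanimoto


@dataclass
class ScreenConfig:
    """Full description of one in-silico qHTS screen."""

    n_compounds: int = 1000
    seed: int = 0
    mixture: dict = field(default_factory=lambda: dict(DEFAULT_MIXTURE))

    # concentration grid: 15-point geometric series, 1.1 nM to 92 uM
    n_concentrations: int = 15
    c_min: float = 1.1e-9
    c_max: float = 9.2e-5

    n_runs: int = 3
    n_duplicates: int = 88

    plate_rows: int = 32
    plate_cols: int = 48

    noise: NoiseModel = field(default_factory=NoiseModel)

    fingerprint_bits: int = 512
    fingerprint_density: float = 0.3
    bit_flip_rate: float = 0.05
    family_size_mean: float = 12.0
    planted_agonist_family: int = 30
    planted_confound_family: int = 30

    # fraction of the maximal (EC100) agonist response used to pre-stimulate
    # antagonist-mode wells (~EC80)
    stimulation_fraction: float = 0.8

    binding_coverage: float = 0.3

    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    call: CallConfig = field(default_factory=CallConfig)
    som: SomConfig = field(default_factory=SomConfig)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_compounds < 1:
            raise ConfigurationError("n_compounds must be positive")
        if self.n_concentrations < 4:
            raise ConfigurationError("need at least 4 concentration points")
        if not (0 < self.c_min < self.c_max):
            raise ConfigurationError("require 0 < c_min < c_max")
        unknown = set(self.mixture) - set(TRUTH_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown truth classes in mixture: {sorted(unknown)}")
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"mixture proportions sum to {total}, expected 1")
        if any(p < 0 for p in self.mixture.values()):
            raise ConfigurationError("mixture proportions must be non-negative")
        if self.n_duplicates > self.n_compounds:
            raise ConfigurationError("more duplicate controls than compounds")
        if not 0 < self.stimulation_fraction < 1:
            raise ConfigurationError("stimulation_fraction must be in (0, 1)")

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ScreenConfig":
        data = dict(data)
        for key, sub in (
            ("noise", NoiseModel),
            ("classify", ClassifyConfig),
            ("call", CallConfig),
            ("som", SomConfig),
        ):
            if key in data and isinstance(data[key], dict):
                data[key] = sub(**data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the configuration (used in run manifests)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()
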