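"""Model configuration: every constant and mode switch of the simulator.

The configuration is a flat, validated dataclass.  Defaults reproduce the
baseline model world: a 5x5 grid of demes at carrying capacity K = 160,
females laying R = 8 eggs on a discrete timeline, three evolving traits
(remating interval tau, sperm number s, sperm mortality rate mu) each
encoded by 20 continuous-allele loci, 1000 biallelic deleterious loci
causing inbreeding depression in sperm number, and 1000 neutral loci whose
continuous alleles track identity by descent.

Each field carries a provenance note: ``published`` for values stated in
the source model description, ``default`` for values this implementation
had to choose (documented in docs/methods.md) — see :data:`PROVENANCE`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

MODES = ("evolving_polyandry", "fixed_monandry", "no_sperm_competition")
DEPRESSION_TARGETS = ("s", "mu", "rho0", "none")

# Provenance of each default: "published" values are stated in the model
# description this package implements; "default" values are implementation
# choices (the published parameter table is not available in full).
PROVENANCE = {
    "grid_size": "published", "carrying_capacity": "published",
    "eggs_per_female": "published", "mutation_rate": "published",
    "n_trait_loci": "published", "n_deleterious_loci": "published",
    "n_neutral_loci": "published", "neutral_allele_bound": "published",
    "selection_coefficient": "published (sweep axis)",
    "dominance": "published", "dispersal_probability": "published (sweep axis)",
    "dispersal_mean_distance": "published", "omega2_female": "published",
    "omega2_male": "published", "tau_min": "published", "tau_max": "published",
    "s_min": "published", "mu_min": "published",
    "fertilization_efficiency": "default", "sperm_cost_beta": "default",
    "rho0": "default (cost threshold of the initial population)",
    "tau_init_mean": "default", "s_init_mean": "default",
    "mu_init_mean": "default", "init_allele_sd_scale": "default",
    "mutation_sd_scale": "default", "trade_off": "published",
    "sperm_cost_linear": "default (alternative reading, off)",
    "depression_target": "published", "mode": "published (experiment axis)",
    "generations": "published", "replicates": "published",
    "record_every": "default", "correlation_window": "default",
    "master_seed": "default",
}


@dataclass
class ModelConfig:
    # --- genetic architecture ---
    n_trait_loci: int = 20
    n_deleterious_loci: int = 1000
    n_neutral_loci: int = 1000
    mutation_rate: float = 0.001          # per allele per generation
    neutral_allele_bound: float = 1000.0  # neutral alleles ~ U[-bound, bound]
    # initial trait means (genotypic scale); per-allele init mean = mean/40
    tau_init_mean: float = 1.0
    s_init_mean: float = 100.0
    mu_init_mean: float = 0.5
    # sd of initial alleles and of mutational perturbations, as a fraction of
    # the per-allele initial mean (per-allele mean = trait mean / 40).
    # Scale 1.0 gives each trait a genotypic CV of ~16% — enough standing and
    # mutational variance for the mating system to respond to selection on
    # simulated timescales (see docs/methods.md).
    init_allele_sd_scale: float = 1.0
    mutation_sd_scale: float = 1.0
    # --- inbreeding depression ---
    selection_coefficient: float = 0.02   # S, homozygous effect
    dominance: float = 0.0                # h
    depression_target: str = "s"          # s | mu | rho0 | none
    # --- phenotypic bounds ---
    tau_min: float = 0.01
    tau_max: float = 1.0
    s_min: float = 1.0
    mu_min: float = 1e-10
    # --- reproduction and costs ---
    eggs_per_female: int = 8              # R
    fertilization_efficiency: float = 0.01  # r, per viable sperm
    omega2_female: float = 1.28e5         # strength of the polyandry cost
    omega2_male: float = 1.0              # strength of the sperm-investment cost
    sperm_cost_beta: float = 0.5          # beta in rho = s^beta / mu
    rho0: float | None = None             # cost-free resource; None -> s_init^beta/mu_init
    trade_off: bool = True                # s-mu trade-off on (off: rho = s^beta)
    sperm_cost_linear: bool = False       # alternative reading rho = beta*s/mu
    # --- landscape ---
    grid_size: int = 5
    carrying_capacity: int = 160          # K per deme
    dispersal_probability: float = 0.01   # d
    dispersal_mean_distance: float = 1.5  # cells, exponential kernel
    # --- experiment ---
    mode: str = "evolving_polyandry"
    generations: int = 10_000
    replicates: int = 50
    record_every: int = 10
    correlation_window: int = 50          # generations pooled for the H_i-siring correlation
    master_seed: int = 1

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Raise ``ConfigError`` on any out-of-range or inconsistent field."""
        def check(cond: bool, msg: str) -> None:
            if not cond:
                raise ConfigError(msg)

        check(self.n_trait_loci >= 1, "n_trait_loci must be >= 1")
        check(self.n_deleterious_loci >= 1, "n_deleterious_loci must be >= 1")
        check(self.n_neutral_loci >= 1, "n_neutral_loci must be >= 1")
        check(0.0 <= self.mutation_rate <= 1.0,
              f"mutation_rate must be in [0, 1], got {self.mutation_rate}")
        check(0.0 <= self.selection_coefficient <= 1.0,
              f"selection_coefficient must be in [0, 1], got {self.selection_coefficient}")
        check(0.0 <= self.dominance <= 1.0,
              f"dominance must be in [0, 1], got {self.dominance}")
        check(self.depression_target in DEPRESSION_TARGETS,
              f"depression_target must be one of {DEPRESSION_TARGETS}, "
              f"got {self.depression_target!r}")
        check(self.mode in MODES, f"mode must be one of {MODES}, got {self.mode!r}")
        check(0.0 < self.tau_min <= self.tau_max <= 1.0,
              "require 0 < tau_min <= tau_max <= 1")
        check(self.s_min >= 1.0, "s_min must be >= 1")
        check(self.mu_min > 0.0, "mu_min must be > 0")
        check(self.eggs_per_female >= 1, "eggs_per_female must be a positive integer")
        check(self.fertilization_efficiency > 0, "fertilization_efficiency must be > 0")
        check(self.omega2_female > 0, "omega2_female must be > 0")
        check(self.omega2_male > 0, "omega2_male must be > 0")
        check(self.sperm_cost_beta > 0, "sperm_cost_beta must be > 0")
        check(self.rho0 is None or self.rho0 > 0, "rho0 must be > 0")
        check(self.grid_size >= 1, "grid_size must be >= 1")
        check(self.carrying_capacity >= 2, "carrying_capacity must be >= 2")
        check(0.0 <= self.dispersal_probability <= 1.0,
              f"dispersal_probability must be in [0, 1], got {self.dispersal_probability}")
        check(self.dispersal_mean_distance > 0, "dispersal_mean_distance must be > 0")
        check(self.generations >= 1, "generations must be >= 1")
        check(self.replicates >= 1, "replicates must be >= 1")
        check(self.record_every >= 1, "record_every must be >= 1")
        check(self.correlation_window >= 1, "correlation_window must be >= 1")
        check(0 <= self.master_seed < 2**31, "master_seed must be in [0, 2^31)")
        check(self.tau_init_mean > 0 and self.s_init_mean > 0 and self.mu_init_mean > 0,
              "initial trait means must be > 0")

    # ------------------------------------------------------------------
    # Derived quantities
    @property
    def effective_rho0(self) -> float:
        """Cost-free resource budget; defaults to the investment of the
        initial population mean male (s_init, mu_init) so founders pay no
        survival cost for their sperm."""
        if self.rho0 is not None:
            return self.rho0
        from . import mating
        return mating.sperm_investment(
            self.s_init_mean, self.mu_init_mean, self.sperm_cost_beta,
            trade_off=self.trade_off, linear=self.sperm_cost_linear)

    def trait_init_means(self):
        return (self.tau_init_mean, self.s_init_mean, self.mu_init_mean)

    def allele_init_means(self):
        """Per-allele initial means: trait mean split over the 2*n_loci alleles."""
        n = 2 * self.n_trait_loci
        return tuple(m / n for m in self.trait_init_means())

    def allele_init_sds(self):
        return tuple(m * self.init_allele_sd_scale for m in self.allele_init_means())

    def mutation_sds(self):
        """Sd of the zero-mean normal perturbation added to a mutated trait allele."""
        return tuple(m * self.mutation_sd_scale for m in self.allele_init_means())

    # ------------------------------------------------------------------
    # Serialization
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, source) -> "ModelConfig":
        """Load from a YAML path, file object, or string. An empty document
        yields the all-defaults configuration."""
        if hasattr(source, "read"):
            text = source.read()
        else:
            try:
                with open(source) as fh:
                    text = fh.read()
            except (OSError, ValueError):
                text = str(source)
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError("configuration document must be a mapping")
        return cls.from_dict(data)

    def replace(self, **kwargs) -> "ModelConfig":
        return dataclasses.replace(self, **kwargs)


class ConfigError(ValueError):
    """A configuration field violated its schema."""


def parse_override(text: str):
    """Parse a ``key=value`` command-line override with YAML value typing."""
    if "=" not in text:
        raise ConfigError(f"override {text!r} is not of the form key=value")
    key, raw = text.split("=", 1)
    return key.strip(), yaml.safe_load(raw)
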