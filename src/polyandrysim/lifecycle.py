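"""Landscape, generation loop, dispersal and density regulation.

The world is a 5x5 grid of demes, each with carrying capacity K.  One
generation runs, in sequence: reproduction (mating, fertilization, birth),
adult death (generations are nonoverlapping), natal dispersal of the
offspring, and density-dependent survival.  Observer statistics are sampled
during reproduction, before density regulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import genetics, mating, observers
from .config import ModelConfig
from .genetics import Population


@dataclass
class Landscape:
    """Square grid of unit cells; deme index = gy * size + gx."""

    size: int = 5
    carrying_capacity: int = 160
    dispersal_probability: float = 0.01
    dispersal_mean_distance: float = 1.5

    @property
    def n_demes(self) -> int:
        return self.size * self.size

    @classmethod
    def from_config(cls, config: ModelConfig) -> "Landscape":
        return cls(size=config.grid_size,
                   carrying_capacity=config.carrying_capacity,
                   dispersal_probability=config.dispersal_probability,
                   dispersal_mean_distance=config.dispersal_mean_distance)


@dataclass
class SimulationState:
    generation: int
    pop: Population
    config: ModelConfig
    next_id: int
    status: str = "running"          # running | extinct
    skipped_matings: int = 0


# ----------------------------------------------------------------------

def initialize_population(config: ModelConfig, rng: np.random.Generator) -> SimulationState:
    """Seed every deme with K individuals at a 1:1 sex ratio.

    Founders carry unique continuous neutral alleles (H_p ~ 0), no
    deleterious mutations, and trait alleles from the configured initial
    normal distributions.
    """
    land = Landscape.from_config(config)
    K = config.carrying_capacity
    n = land.n_demes * K
    trait, dele, neutral = genetics.founder_genomes(n, config, rng)
    female = np.zeros(n, dtype=bool)
    deme = np.repeat(np.arange(land.n_demes), K)
    for g in range(land.n_demes):
        rows = np.where(deme == g)[0]
        female[rng.permutation(rows)[: K // 2]] = True
    pop = Population(
        ids=np.arange(n, dtype=np.int64), female=female, trait=trait,
        deleterious=dele, neutral=neutral, deme=deme, natal_deme=deme.copy(),
        dam_id=np.full(n, -1, dtype=np.int64),
        sire_id=np.full(n, -1, dtype=np.int64))
    return SimulationState(generation=0, pop=pop, config=config, next_id=n)


# ----------------------------------------------------------------------
# Dispersal

def draw_dispersal_distances(n: int, rng: np.random.Generator,
                             mean: float = 1.5) -> np.ndarray:
    """The dispersal kernel's distance component: exponential, mean 1.5 cells."""
    return rng.exponential(mean, size=n)


def draw_dispersal_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.uniform(0.0, 2.0 * np.pi, size=n)


def disperse(deme: np.ndarray, landscape: Landscape,
             rng: np.random.Generator) -> np.ndarray:
    """Each individual disperses with probability d from its natal cell
    center; (distance, direction) pairs are redrawn until the landing point
    falls on the grid.  Landing in the natal cell still counts as dispersal.
    Returns the new deme index array."""
    n = len(deme)
    out = deme.copy()
    moving = np.where(rng.random(n) < landscape.dispersal_probability)[0]
    if moving.size == 0:
        return out
    size = landscape.size
    gx = deme[moving] % size
    gy = deme[moving] // size
    cx, cy = gx + 0.5, gy + 0.5
    pending = np.arange(moving.size)
    nx = np.empty(moving.size)
    ny = np.empty(moving.size)
    while pending.size:
        dist = draw_dispersal_distances(pending.size, rng,
                                        landscape.dispersal_mean_distance)
        ang = draw_dispersal_directions(pending.size, rng)
        px = cx[pending] + dist * np.cos(ang)
        py = cy[pending] + dist * np.sin(ang)
        ok = (px >= 0) & (px < size) & (py >= 0) & (py < size)
        nx[pending[ok]] = px[ok]
        ny[pending[ok]] = py[ok]
        pending = pending[~ok]
    out[moving] = np.floor(ny).astype(np.int64) * size + np.floor(nx).astype(np.int64)
    return out


# ----------------------------------------------------------------------
# Density regulation

def density_regulate(deme: np.ndarray, K: int, n_demes: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Independent survival with probability min(K/N, 1), N the deme census.
    Returns a boolean keep mask (expected survivors = min(N, K))."""
    census = np.bincount(deme, minlength=n_demes)
    p = np.minimum(K / np.maximum(census, 1), 1.0)
    return rng.random(len(deme)) < p[deme]


# ----------------------------------------------------------------------
# One generation

def step_generation(state: SimulationState, rng: np.random.Generator,
                    collect_corr: bool = False,
                    collect_pairs: bool = False) -> tuple[SimulationState, dict]:
    """Advance one generation and return ``(new_state, record)``.

    ``record`` is the observer output (see :mod:`polyandrysim.observers`);
    ``collect_corr`` adds per-deme male (H_i, offspring-count) arrays for
    the homozygosity-siring correlation, ``collect_pairs`` adds
    father-offspring H_i pairs for the heritability-of-homozygosity slope.
    """
    cfg = state.config
    pop = state.pop
    land = Landscape.from_config(cfg)
    R = cfg.eggs_per_female

    if pop.size == 0 or (~pop.female).sum() == 0 or pop.female.sum() == 0:
        state.status = "extinct"
        return state, observers.empty_record(state.generation)

    phen = genetics.express_phenotypes(pop, cfg)
    nu_f = mating.female_viability(phen.tau, R, cfg.omega2_female)
    nu_m = mating.male_viability(phen.rho, phen.rho0, cfg.omega2_male)

    params = mating.ReproductionParams(
        R=R, r=cfg.fertilization_efficiency, omega2_f=cfg.omega2_female,
        omega2_m=cfg.omega2_male, mode=cfg.mode)
    phase = mating.run_reproductive_phase(
        pop.female, pop.deme, phen.tau, phen.s, phen.mu, nu_f, nu_m,
        params, rng)

    # ---- observers (before dispersal and density regulation) -----------
    record = observers.observe_generation(
        state.generation, pop, phen, nu_f, nu_m, phase, cfg,
        collect_corr=collect_corr, collect_pairs=collect_pairs)

    # ---- offspring birth, adult death, dispersal, regulation ------------
    # Dispersal and density regulation are independent of offspring
    # genotype, so they are decided first and meiosis + mutation run only
    # for the survivors — statistically identical to building every
    # conceived offspring's genome, but much cheaper.  When the
    # father-offspring homozygosity pairs are requested, genomes of all
    # conceived offspring are materialised instead.
    n_off = phase.dam_idx.size
    if n_off == 0:
        state.status = "extinct"
        return state, record
    sex = rng.random(n_off) < 0.5
    natal = pop.deme[phase.dam_idx]
    new_deme = disperse(natal, land, rng)
    keep = density_regulate(new_deme, land.carrying_capacity, land.n_demes, rng)
    ids = np.arange(state.next_id, state.next_id + n_off, dtype=np.int64)

    build = np.ones(n_off, dtype=bool) if collect_pairs else keep
    rows = np.where(build)[0]
    trait, dele, neutral = genetics.inherit(pop, phase.dam_idx[rows],
                                            phase.sire_idx[rows], rng)
    trait, dele, neutral = genetics.mutate_offspring(trait, dele, neutral,
                                                     cfg, rng)
    if collect_pairs:
        record["father_offspring_pairs"] = (
            genetics.neutral_homozygosity(pop.neutral)[phase.sire_idx],
            genetics.neutral_homozygosity(neutral))
        surv = keep  # all rows built; subset down to survivors
    else:
        surv = np.ones(rows.size, dtype=bool)
    survivors = Population(
        ids=ids[rows][surv], female=sex[rows][surv],
        trait=trait[surv], deleterious=dele[surv], neutral=neutral[surv],
        deme=new_deme[rows][surv], natal_deme=natal[rows][surv],
        dam_id=pop.ids[phase.dam_idx[rows][surv]],
        sire_id=pop.ids[phase.sire_idx[rows][surv]])

    new_state = SimulationState(
        generation=state.generation + 1, pop=survivors, config=cfg,
        next_id=state.next_id + n_off,
        skipped_matings=phase.skipped_matings)
    if survivors.size == 0:
        new_state.status = "extinct"
    return new_state, record


# ----------------------------------------------------------------------

def run_replicate(config: ModelConfig, seed_or_rng,
                  progress: bool = False) -> "observers.ReplicateResult":
    """Run one replicate for ``config.generations`` generations.

    The homozygosity-siring correlation inputs are accumulated over the
    final ``correlation_window`` generations; father-offspring H_i pairs are
    taken at the final generation.  Returns a
    :class:`polyandrysim.observers.ReplicateResult`.
    """
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    state = initialize_population(config, rng)
    G = config.generations
    window_start = max(G - config.correlation_window, 0)
    records = []
    corr_records: dict[int, list] = {}
    pairs = None
    for g in range(G):
        in_window = g >= window_start
        final = g == G - 1
        state, rec = step_generation(state, rng, collect_corr=in_window,
                                     collect_pairs=final)
        if in_window and "corr_inputs" in rec:
            for deme_g, arrs in rec.pop("corr_inputs").items():
                corr_records.setdefault(deme_g, []).append(arrs)
        if final and "father_offspring_pairs" in rec:
            pairs = rec.pop("father_offspring_pairs")
        if g % config.record_every == 0 or final:
            records.append(rec)
        if state.status == "extinct":
            break
    return observers.ReplicateResult(
        records=records, corr_records=corr_records,
        father_offspring_pairs=pairs, status=state.status,
        generations_run=state.generation)
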