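"""Genomes, inheritance, mutation, phenotype expression and homozygosity.

The simulator is array-based: a :class:`Population` holds one numpy array
per genome class with the individual as the leading axis, so every genetic
operation (meiosis, mutation, homozygosity counting) is vectorised over the
whole population.

Genome classes
--------------
trait
    shape ``(n, 3, L_t, 2)`` float; three quantitative traits — remating
    interval tau, sperm number s, sperm mortality rate mu — each encoded by
    ``L_t`` (default 20) unlinked additive loci with continuous alleles.
    The genotypic value of a trait is the plain sum of its 2*L_t alleles.
deleterious
    shape ``(n, L_d, 2)`` bool; True marks a deleterious allele.  Loci
    homozygous (Theta) and heterozygous (theta) for deleterious mutations
    depress male sperm traits multiplicatively.
neutral
    shape ``(n, L_n, 2)`` float; alleles initialised and re-mutated from
    U[-1000, 1000].  Two equal alleles at a locus are identical by descent
    (identity by state under continuous redraws has negligible probability),
    so the fraction of homozygous loci H_i is a realized-inbreeding proxy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ModelConfig

# Trait indices within the trait-genome axis.
TAU, SPERM, MORT = 0, 1, 2
TRAIT_NAMES = ("tau", "s", "mu")


@dataclass
class Population:
    """Structure-of-arrays container for one generation of individuals."""

    ids: np.ndarray        # (n,) int64, globally unique
    female: np.ndarray     # (n,) bool
    trait: np.ndarray      # (n, 3, L_t, 2) float64
    deleterious: np.ndarray  # (n, L_d, 2) bool
    neutral: np.ndarray    # (n, L_n, 2) float64
    deme: np.ndarray       # (n,) int, current deme index
    natal_deme: np.ndarray  # (n,) int
    dam_id: np.ndarray     # (n,) int64, -1 for founders
    sire_id: np.ndarray    # (n,) int64, -1 for founders

    @property
    def size(self) -> int:
        return len(self.ids)

    def subset(self, idx) -> "Population":
        return Population(
            ids=self.ids[idx], female=self.female[idx], trait=self.trait[idx],
            deleterious=self.deleterious[idx], neutral=self.neutral[idx],
            deme=self.deme[idx], natal_deme=self.natal_deme[idx],
            dam_id=self.dam_id[idx], sire_id=self.sire_id[idx])


@dataclass
class Phenotypes:
    """Expressed (sex-limited) phenotypes plus the genotypic values they
    derive from.  ``rho`` and ``rho0`` are per-male cost quantities computed
    from pre-depression values, so inbreeding depression never alters a
    male's investment or survival for a given genotype."""

    g_tau: np.ndarray
    g_s: np.ndarray
    g_mu: np.ndarray
    tau: np.ndarray   # females: clamped remating interval
    s: np.ndarray     # males: sperm number after depression + clamp
    mu: np.ndarray    # males: sperm mortality rate after depression + clamp
    rho: np.ndarray   # males: resources invested in sperm (pre-depression)
    rho0: np.ndarray  # per-male cost-free resource (depressed in the rho0 variant)


# ----------------------------------------------------------------------
# Elementary operations

def genotypic_value(trait_genome: np.ndarray, trait: int | str) -> np.ndarray:
    """Sum of a trait's 2*L allelic values (purely additive, no dominance).

    ``trait_genome`` may be a single genome ``(3, L, 2)`` or a population
    batch ``(n, 3, L, 2)``; ``trait`` is an index or one of ``tau|s|mu``.
    """
    if isinstance(trait, str):
        try:
            trait = TRAIT_NAMES.index(trait)
        except ValueError:
            raise KeyError(f"unknown trait {trait!r}; expected one of {TRAIT_NAMES}")
    if not 0 <= int(trait) < 3:
        raise KeyError(f"unknown trait index {trait}")
    return trait_genome[..., trait, :, :].sum(axis=(-2, -1))


def apply_inbreeding_depression(g, S: float, h: float, Theta, theta):
    """Multiplicative depression ``g * (1-S)^Theta * (1-h*S)^theta``.

    Theta and theta are the counts of loci homozygous and heterozygous for
    deleterious mutations; every mutation acts independently.
    """
    if not 0.0 <= S <= 1.0:
        raise ValueError(f"S must be in [0, 1], got {S}")
    if not 0.0 <= h <= 1.0:
        raise ValueError(f"h must be in [0, 1], got {h}")
    return g * (1.0 - S) ** np.asarray(Theta) * (1.0 - h * S) ** np.asarray(theta)


def count_deleterious(deleterious: np.ndarray):
    """Return ``(Theta, theta)``: loci with two vs exactly one deleterious allele."""
    a = deleterious[..., 0]
    b = deleterious[..., 1]
    Theta = (a & b).sum(axis=-1)
    theta = (a ^ b).sum(axis=-1)
    return Theta, theta


def neutral_homozygosity(neutral: np.ndarray) -> np.ndarray:
    """H_i: fraction of neutral loci whose two alleles are exactly equal.

    Exact floating-point equality is intended: neutral alleles are only ever
    copied or redrawn from a continuous distribution, never transformed, so
    equality means identity by descent.
    """
    return (neutral[..., 0] == neutral[..., 1]).mean(axis=-1)


# ----------------------------------------------------------------------
# Phenotype expression

def express_phenotypes(pop: Population, config: ModelConfig) -> Phenotypes:
    """Compute genotypic values and sex-limited phenotypes for a population.

    Inbreeding depression applies to the configured target (default: sperm
    number), then bounds are enforced: tau in [0.01, 1], s >= 1, mu >= 1e-10.
    Clamping happens after depression — the bounds are phenotypic.  Male
    investment ``rho`` always derives from the pre-depression (bounded)
    genotypic values.
    """
    g_tau = genotypic_value(pop.trait, TAU)
    g_s = genotypic_value(pop.trait, SPERM)
    g_mu = genotypic_value(pop.trait, MORT)

    S, h = config.selection_coefficient, config.dominance
    Theta, theta = count_deleterious(pop.deleterious)
    dep = (1.0 - S) ** Theta * (1.0 - h * S) ** theta

    tau = np.clip(g_tau, config.tau_min, config.tau_max)
    if config.mode == "fixed_monandry":
        tau = np.full_like(tau, config.tau_max)

    s_pre = np.maximum(g_s, config.s_min)
    mu_pre = np.maximum(g_mu, config.mu_min)

    from . import mating  # local import to avoid a cycle
    rho = mating.sperm_investment(
        s_pre, mu_pre, config.sperm_cost_beta,
        trade_off=config.trade_off, linear=config.sperm_cost_linear)
    rho0 = np.full(pop.size, config.effective_rho0)

    target = config.depression_target
    if target == "s":
        s = np.maximum(g_s * dep, config.s_min)
        mu = mu_pre
    elif target == "mu":
        # depression increases the mortality rate
        s = s_pre
        mu = np.maximum(g_mu / np.maximum(dep, 1e-300), config.mu_min)
    elif target == "rho0":
        s = s_pre
        mu = mu_pre
        rho0 = rho0 * dep
    else:  # "none"
        s = s_pre
        mu = mu_pre

    return Phenotypes(g_tau=g_tau, g_s=g_s, g_mu=g_mu,
                      tau=tau, s=s, mu=mu, rho=rho, rho0=rho0)


# ----------------------------------------------------------------------
# Mutation

def _mutation_positions(n_alleles: int, rate: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Flat indices of mutated alleles.  Exactly equivalent to independent
    per-allele Bernoulli(rate) trials: the hit count is Binomial(n, rate)
    and positions are uniform without replacement (rejection-sampled,
    cheap because the rate is small)."""
    k = int(rng.binomial(n_alleles, rate))
    if k == 0:
        return np.empty(0, dtype=np.int64)
    if k > n_alleles // 20:
        # dense regime: rejection sampling degenerates, permute instead
        return np.sort(rng.permutation(n_alleles)[:k])
    pos = np.unique(rng.integers(0, n_alleles, k))
    while pos.size < k:
        extra = rng.integers(0, n_alleles, k - pos.size)
        pos = np.unique(np.concatenate([pos, extra]))
    return pos


def mutate_trait(trait: np.ndarray, config: ModelConfig, rng: np.random.Generator,
                 rate: float | None = None) -> np.ndarray:
    """Per-allele Bernoulli mutation; hits receive a zero-mean normal deviate
    (bidirectional). Returns a mutated copy."""
    rate = config.mutation_rate if rate is None else rate
    out = trait.copy()
    if rate <= 0:
        return out
    flat = out.reshape(-1)
    pos = _mutation_positions(flat.size, rate, rng)
    if pos.size:
        block = trait.shape[-2] * trait.shape[-1]  # alleles per trait block
        trait_idx = (pos // block) % 3
        sds = np.asarray(config.mutation_sds())
        flat[pos] += rng.normal(0.0, sds[trait_idx])
    return out


def mutate_deleterious(deleterious: np.ndarray, config: ModelConfig,
                       rng: np.random.Generator,
                       rate: float | None = None) -> np.ndarray:
    """Bidirectional state flip: wild-type -> deleterious and back."""
    rate = config.mutation_rate if rate is None else rate
    out = deleterious.copy()
    if rate <= 0:
        return out
    flat = out.reshape(-1)
    pos = _mutation_positions(flat.size, rate, rng)
    if pos.size:
        flat[pos] = ~flat[pos]
    return out


def mutate_neutral(neutral: np.ndarray, config: ModelConfig,
                   rng: np.random.Generator,
                   rate: float | None = None) -> np.ndarray:
    """Mutated neutral alleles are redrawn from U[-bound, bound]."""
    rate = config.mutation_rate if rate is None else rate
    out = neutral.copy()
    if rate <= 0:
        return out
    flat = out.reshape(-1)
    pos = _mutation_positions(flat.size, rate, rng)
    if pos.size:
        flat[pos] = draw_neutral_alleles(pos.size, config, rng)
    return out


def draw_neutral_alleles(n: int, config: ModelConfig,
                         rng: np.random.Generator) -> np.ndarray:
    """Sampler behind both neutral initialisation and the mutation redraw."""
    b = config.neutral_allele_bound
    return rng.uniform(-b, b, size=n)


# ----------------------------------------------------------------------
# Inheritance

def _gametes(parental: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One uniformly chosen allele per locus from each parent's pair,
    independent across loci (all loci unlinked).  ``parental`` has allele
    pairs on the last axis; the result drops that axis."""
    pick_second = rng.integers(0, 2, size=parental.shape[:-1], dtype=bool)
    return np.where(pick_second, parental[..., 1], parental[..., 0])


def inherit(pop: Population, dam_idx: np.ndarray, sire_idx: np.ndarray,
            rng: np.random.Generator):
    """Meiosis for a batch of offspring: maternal gamete + paternal gamete
    at every locus of every genome class.  Mutation is applied separately
    (see :func:`mutate_offspring`).  Returns ``(trait, deleterious, neutral)``
    arrays with the maternal allele at index 0 and paternal at index 1.
    """
    dam_idx = np.asarray(dam_idx)
    sire_idx = np.asarray(sire_idx)
    out = []
    for arr in (pop.trait, pop.deleterious, pop.neutral):
        mat = _gametes(arr[dam_idx], rng)
        pat = _gametes(arr[sire_idx], rng)
        out.append(np.stack([mat, pat], axis=-1))
    return tuple(out)


def mutate_offspring(trait, deleterious, neutral, config: ModelConfig,
                     rng: np.random.Generator):
    return (mutate_trait(trait, config, rng),
            mutate_deleterious(deleterious, config, rng),
            mutate_neutral(neutral, config, rng))


# ----------------------------------------------------------------------
# Founders

def founder_genomes(n: int, config: ModelConfig, rng: np.random.Generator):
    """Founder genomes: trait alleles ~ Normal(trait_mean/2L, sd), no
    deleterious mutations, neutral alleles i.i.d. U[-1000, 1000] (every
    founder allele unique with probability one -> initial H_p ~ 0)."""
    L = config.n_trait_loci
    means = np.asarray(config.allele_init_means())
    sds = np.asarray(config.allele_init_sds())
    trait = rng.normal(means[None, :, None, None],
                       sds[None, :, None, None],
                       size=(n, 3, L, 2))
    deleterious = np.zeros((n, config.n_deleterious_loci, 2), dtype=bool)
    neutral = draw_neutral_alleles(
        n * config.n_neutral_loci * 2, config, rng).reshape(
        n, config.n_neutral_loci, 2)
    return trait, deleterious, neutral
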