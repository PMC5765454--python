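"""Deterministic small populations backing unit tests, plus a plain-text
genome dump format.

Dump format: one row per allele, tab-separated, columns in this order:
``individual_id  genome_class  locus  allele_index  value`` where
``genome_class`` is one of ``trait_tau | trait_s | trait_mu | deleterious |
neutral`` and ``allele_index`` is 0 (maternal) or 1 (paternal).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import genetics
from .config import ModelConfig
from .genetics import Population

FIXTURE_KINDS = ("founders", "pedigree_sibs", "constructed_homozygosity",
                 "two_male_raffle")

GENOME_CLASSES = ("trait_tau", "trait_s", "trait_mu", "deleterious", "neutral")


def _founder_pop(n: int, config: ModelConfig, rng: np.random.Generator,
                 start_id: int = 0) -> Population:
    trait, dele, neutral = genetics.founder_genomes(n, config, rng)
    female = np.zeros(n, dtype=bool)
    female[: n // 2] = True
    zeros = np.zeros(n, dtype=np.int64)
    return Population(
        ids=np.arange(start_id, start_id + n, dtype=np.int64), female=female,
        trait=trait, deleterious=dele, neutral=neutral, deme=zeros,
        natal_deme=zeros.copy(),
        dam_id=np.full(n, -1, np.int64), sire_id=np.full(n, -1, np.int64))


def _offspring_of(pop: Population, dam_row: int, sire_row: int, n: int,
                  config: ModelConfig, rng: np.random.Generator,
                  female=None, mutate: bool = False) -> Population:
    dam = np.full(n, dam_row)
    sire = np.full(n, sire_row)
    trait, dele, neutral = genetics.inherit(pop, dam, sire, rng)
    if mutate:
        trait, dele, neutral = genetics.mutate_offspring(trait, dele, neutral,
                                                         config, rng)
    if female is None:
        female = rng.random(n) < 0.5
    zeros = np.zeros(n, dtype=np.int64)
    return Population(
        ids=np.arange(n, dtype=np.int64), female=np.asarray(female, bool),
        trait=trait, deleterious=dele, neutral=neutral, deme=zeros,
        natal_deme=zeros.copy(),
        dam_id=pop.ids[dam], sire_id=pop.ids[sire])


def generate_fixture(kind: str, rng: np.random.Generator,
                     config: ModelConfig | None = None):
    """Build one of the deterministic test populations.

    founders
        20 unrelated founders in one deme (H_p ~ 0).
    pedigree_sibs
        dict with a founder pair, two full sibs, and ``n_offspring = 200``
        full-sib-incest offspring whose expected H_i is 0.25.
    constructed_homozygosity
        a founder population whose first individual has exactly 250
        homozygous neutral loci (H_i = 0.25).
    two_male_raffle
        dict of sperm packets with viable sperm 30 and 10 at the
        fertilization time (raffle probabilities 0.75 / 0.25).
    """
    config = config or ModelConfig()
    if kind == "founders":
        return _founder_pop(20, config, rng)
    if kind == "pedigree_sibs":
        founders = _founder_pop(2, config, rng)
        founders.female[:] = [True, False]
        sibs = _offspring_of(founders, 0, 1, 2, config, rng,
                             female=[True, False])
        sibs.ids += founders.size
        offspring = _offspring_of(sibs, 0, 1, 200, config, rng)
        return {"founders": founders, "sibs": sibs, "offspring": offspring}
    if kind == "constructed_homozygosity":
        pop = _founder_pop(4, config, rng)
        pop.neutral[0, :250, 1] = pop.neutral[0, :250, 0]
        # remaining loci of individual 0 keep distinct continuous alleles
        return pop
    if kind == "two_male_raffle":
        return {"sires": np.array([101, 102]),
                "s": np.array([30.0, 10.0]),
                "mu": np.array([1e-10, 1e-10]),
                "t_mating": np.array([0.0, 0.0]),
                "t_fertilization": 1.0}
    raise ValueError(f"unknown fixture kind {kind!r}; "
                     f"expected one of {FIXTURE_KINDS}")


# ----------------------------------------------------------------------
# Genome dump

def dump_genomes(pop: Population, path) -> None:
    """Write every allele of every individual as one tabular row."""
    rows = []
    for i in range(pop.size):
        ind = int(pop.ids[i])
        for t, name in enumerate(("trait_tau", "trait_s", "trait_mu")):
            for locus in range(pop.trait.shape[2]):
                for a in range(2):
                    rows.append((ind, name, locus, a,
                                 pop.trait[i, t, locus, a]))
        for locus in range(pop.deleterious.shape[1]):
            for a in range(2):
                rows.append((ind, "deleterious", locus, a,
                             float(pop.deleterious[i, locus, a])))
        for locus in range(pop.neutral.shape[1]):
            for a in range(2):
                rows.append((ind, "neutral", locus, a,
                             pop.neutral[i, locus, a]))
    df = pd.DataFrame(rows, columns=["individual_id", "genome_class",
                                     "locus", "allele_index", "value"])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def load_genomes(path, config: ModelConfig | None = None) -> Population:
    """Reconstruct a Population's genomes from a dump (sexes default male;
    pedigree and location metadata are not part of the dump)."""
    config = config or ModelConfig()
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    ids = np.sort(df["individual_id"].unique())
    n = len(ids)
    row_of = {v: i for i, v in enumerate(ids)}
    trait = np.zeros((n, 3, config.n_trait_loci, 2))
    dele = np.zeros((n, config.n_deleterious_loci, 2), dtype=bool)
    neutral = np.zeros((n, config.n_neutral_loci, 2))
    class_to_trait = {"trait_tau": 0, "trait_s": 1, "trait_mu": 2}
    ridx = df["individual_id"].map(row_of).to_numpy()
    locus = df["locus"].to_numpy()
    aidx = df["allele_index"].to_numpy()
    value = df["value"].to_numpy()
    gclass = df["genome_class"].to_numpy()
    for name, t in class_to_trait.items():
        sel = gclass == name
        trait[ridx[sel], t, locus[sel], aidx[sel]] = value[sel]
    sel = gclass == "deleterious"
    dele[ridx[sel], locus[sel], aidx[sel]] = value[sel] > 0.5
    sel = gclass == "neutral"
    neutral[ridx[sel], locus[sel], aidx[sel]] = value[sel]
    zeros = np.zeros(n, dtype=np.int64)
    return Population(
        ids=ids.astype(np.int64), female=np.zeros(n, dtype=bool),
        trait=trait, deleterious=dele, neutral=neutral, deme=zeros,
        natal_deme=zeros.copy(), dam_id=np.full(n, -1, np.int64),
        sire_id=np.full(n, -1, np.int64))
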