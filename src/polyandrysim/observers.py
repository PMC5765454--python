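"""Summary statistics and per-generation observer records.

Everything here is a pure read of simulation state.  The quantities are the
ones the model's experiments report: population-wide neutral homozygosity
H_p, sex-specific reproductive-success variances V_f and V_m and the
effective population size N_ev = 8N/(V_m + V_f + 4) they imply, mean female
fertility before density regulation, the monandrous-female fertilization
diagnostic, deleterious-mutation purging metrics, the within-deme
correlation between male homozygosity and siring success, and the
father-offspring regression of homozygosity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import genetics
from .config import ModelConfig

log = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# Elementary statistics

def population_homozygosity(H_i: np.ndarray) -> float:
    """H_p: mean individual neutral homozygosity across all subpopulations."""
    H_i = np.asarray(H_i, dtype=float)
    if H_i.size == 0:
        log.warning("H_p undefined for an empty population")
        return float("nan")
    return float(H_i.mean())


def effective_size(N: int, V_m: float, V_f: float) -> float:
    """N_ev = 8N / (V_m + V_f + 4): effective size attributable to the
    variances in sex-specific reproductive success."""
    if N <= 0:
        raise ValueError("N must be positive")
    return 8.0 * N / (V_m + V_f + 4.0)


def reproductive_success_variances(female_counts: np.ndarray,
                                   male_counts: np.ndarray) -> tuple[float, float]:
    """Population (divide-by-n) variances of per-adult offspring counts,
    pooled over demes; adults with zero offspring are included."""
    V_f = float(np.var(female_counts)) if len(female_counts) else float("nan")
    V_m = float(np.var(male_counts)) if len(male_counts) else float("nan")
    return V_f, V_m


def mean_female_fertility(female_counts: np.ndarray) -> float:
    """Mean offspring conceived per female, before density regulation;
    females that died mid-phase or never conceived count as zero."""
    counts = np.asarray(female_counts, dtype=float)
    return float(counts.mean()) if counts.size else float("nan")


def monandry_phi_diagnostic(s: np.ndarray, mu: np.ndarray, r: float,
                            R: int) -> float:
    """Mean fertilization probability a hypothetical once-mated female would
    have: for each male, average over egg times t = 1..R of
    Phi(s*exp(-mu*t)) with a single mating at t = 0."""
    s = np.atleast_1d(np.asarray(s, dtype=float))
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    if s.size == 0:
        return float("nan")
    t = np.arange(1, R + 1, dtype=float)
    zeta = s[:, None] * np.exp(-mu[:, None] * t[None, :])
    phi = -np.expm1(-r * zeta)
    return float(phi.mean())


def purging_metrics(deleterious: np.ndarray) -> tuple[float, float, float]:
    """(deleterious allele frequency, mean Theta, mean theta) over the
    population's 2 * L_d allele slots per individual."""
    Theta, theta = genetics.count_deleterious(deleterious)
    L = deleterious.shape[-2]
    freq = float((2 * Theta + theta).mean() / (2 * L))
    return freq, float(Theta.mean()), float(theta.mean())


def homozygosity_success_correlation(corr_records: dict) -> float:
    """Fig-style summary: Pearson correlation between male H_i and number
    of offspring sired, computed within each deme pooling a window of
    generations, then averaged over demes.  Demes where the correlation is
    undefined (no variation in either variable) are excluded."""
    per_deme = []
    for deme, chunks in corr_records.items():
        H = np.concatenate([c[0] for c in chunks])
        n_off = np.concatenate([c[1] for c in chunks])
        if len(H) < 2 or H.std() == 0 or n_off.std() == 0:
            log.debug("deme %s excluded from H_i-siring correlation", deme)
            continue
        per_deme.append(float(np.corrcoef(H, n_off)[0, 1]))
    if not per_deme:
        return float("nan")
    return float(np.mean(per_deme))


def father_offspring_regression(father_H: np.ndarray,
                                offspring_H: np.ndarray) -> float:
    """OLS slope of offspring H_i on father H_i across all offspring.
    Heritability of homozygosity: a positive slope lets paternity skew
    toward outbred males propagate into lower offspring homozygosity."""
    fh = np.asarray(father_H, dtype=float)
    oh = np.asarray(offspring_H, dtype=float)
    if fh.size < 2 or np.var(fh) == 0:
        log.warning("father-offspring regression undefined "
                    "(n=%d, var=%s)", fh.size, np.var(fh) if fh.size else "na")
        return float("nan")
    return float(np.cov(fh, oh, ddof=0)[0, 1] / np.var(fh))


# ----------------------------------------------------------------------
# Per-generation record assembly

POOLED_COLUMNS = [
    "generation", "N", "n_females", "n_males", "mean_tau", "mean_mating_rate",
    "mean_s", "mean_g_s", "mean_mu", "mean_g_mu", "mean_nu_f", "mean_nu_m",
    "H_p", "V_f", "V_m", "N_ev", "mean_female_fertility", "phi_monandry",
    "deleterious_freq", "mean_Theta", "mean_theta", "n_offspring",
]


def empty_record(generation: int) -> dict:
    rec = {c: float("nan") for c in POOLED_COLUMNS}
    rec["generation"] = generation
    rec["N"] = 0
    rec["n_offspring"] = 0
    return rec


def observe_generation(generation: int, pop, phen, nu_f, nu_m, phase,
                       config: ModelConfig, collect_corr: bool = False,
                       collect_pairs: bool = False) -> dict:
    """Assemble the observer record for one generation.

    Fertility and the success variances are sampled at conception, i.e.
    before offspring dispersal and density regulation.
    """
    fem = pop.female
    males = ~fem
    n = pop.size
    counts = np.bincount(phase.dam_idx, minlength=n) if phase.dam_idx.size \
        else np.zeros(n, dtype=np.int64)
    counts = counts + (np.bincount(phase.sire_idx, minlength=n)
                       if phase.sire_idx.size else 0)
    # each offspring contributes once to its dam and once to its sire;
    # dams are always female and sires male, so the split below is exact
    female_counts = counts[fem]
    male_counts = counts[males]

    H_i = genetics.neutral_homozygosity(pop.neutral)
    V_f, V_m = reproductive_success_variances(female_counts, male_counts)
    R = config.eggs_per_female

    rec = {
        "generation": generation,
        "N": int(n),
        "n_females": int(fem.sum()),
        "n_males": int(males.sum()),
        "mean_tau": float(phen.tau[fem].mean()) if fem.any() else float("nan"),
        "mean_mating_rate": float((1.0 / phen.tau[fem]).mean()) if fem.any() else float("nan"),
        "mean_s": float(phen.s[males].mean()) if males.any() else float("nan"),
        "mean_g_s": float(phen.g_s[males].mean()) if males.any() else float("nan"),
        "mean_mu": float(phen.mu[males].mean()) if males.any() else float("nan"),
        "mean_g_mu": float(phen.g_mu[males].mean()) if males.any() else float("nan"),
        "mean_nu_f": float(nu_f[fem].mean()) if fem.any() else float("nan"),
        "mean_nu_m": float(nu_m[males].mean()) if males.any() else float("nan"),
        "H_p": population_homozygosity(H_i),
        "V_f": V_f,
        "V_m": V_m,
        "N_ev": effective_size(n, V_m, V_f) if n > 0 else float("nan"),
        "mean_female_fertility": mean_female_fertility(female_counts),
        "phi_monandry": monandry_phi_diagnostic(
            phen.s[males], phen.mu[males], config.fertilization_efficiency, R),
        "n_offspring": int(phase.dam_idx.size),
    }
    freq, mTheta, mtheta = purging_metrics(pop.deleterious)
    rec["deleterious_freq"] = freq
    rec["mean_Theta"] = mTheta
    rec["mean_theta"] = mtheta

    # per-deme means for the tidy output
    demes = np.arange(config.grid_size ** 2)
    per_deme = {"deme": demes}
    for name, vals, mask in (("mean_tau", phen.tau, fem),
                             ("mean_s", phen.s, males),
                             ("mean_mu", phen.mu, males),
                             ("H_p", H_i, np.ones(n, bool)),
                             ("mean_female_fertility", counts.astype(float), fem)):
        col = np.full(len(demes), np.nan)
        for g in demes:
            sel = mask & (pop.deme == g)
            if sel.any():
                col[g] = vals[sel].mean()
        per_deme[name] = col
    rec["per_deme"] = per_deme

    if collect_corr:
        corr_inputs = {}
        male_H = H_i[males]
        male_deme = pop.deme[males]
        mc = counts[males]
        for g in np.unique(male_deme):
            sel = male_deme == g
            corr_inputs[int(g)] = (male_H[sel], mc[sel])
        rec["corr_inputs"] = corr_inputs
    return rec


# ----------------------------------------------------------------------
# Replicate-level containers and writers

@dataclass
class ReplicateResult:
    records: list
    corr_records: dict
    father_offspring_pairs: tuple | None
    status: str
    generations_run: int

    def frame(self) -> pd.DataFrame:
        """Tidy per-generation table: one pooled row per recorded
        generation plus one row per deme (subset of columns)."""
        rows = []
        for rec in self.records:
            pooled = {k: v for k, v in rec.items()
                      if k in POOLED_COLUMNS}
            pooled["deme"] = "pooled"
            rows.append(pooled)
            pd_block = rec.get("per_deme")
            if pd_block is not None:
                for i, g in enumerate(pd_block["deme"]):
                    row = {"generation": rec["generation"], "deme": str(int(g))}
                    for k, col in pd_block.items():
                        if k != "deme":
                            row[k] = col[i]
                    rows.append(row)
        df = pd.DataFrame(rows)
        cols = ["generation", "deme"] + [c for c in POOLED_COLUMNS
                                         if c != "generation"]
        return df.reindex(columns=[c for c in cols if c in df.columns])

    def summary(self) -> dict:
        """Final-generation pooled values plus the windowed correlation and
        the father-offspring homozygosity slope."""
        final = self.records[-1] if self.records else empty_record(-1)
        out = {k: v for k, v in final.items() if k in POOLED_COLUMNS}
        out["homozygosity_siring_correlation"] = \
            homozygosity_success_correlation(self.corr_records)
        if self.father_offspring_pairs is not None:
            out["father_offspring_slope"] = father_offspring_regression(
                *self.father_offspring_pairs)
        else:
            out["father_offspring_slope"] = float("nan")
        out["status"] = self.status
        out["generations_run"] = self.generations_run
        return out


def write_records(path, result: ReplicateResult, config: ModelConfig) -> None:
    """Write the tidy per-generation table as TSV, with the effective
    configuration echoed verbatim in '#' header lines."""
    df = result.frame()
    with open(path, "w") as fh:
        for line in config.to_yaml().rstrip().splitlines():
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="nan")


def summarize_replicates(summaries: list[dict]) -> pd.DataFrame:
    """Across-replicate mean and SD of every numeric summary quantity
    (the 'final generation, averaged across replicates' reporting style)."""
    df = pd.DataFrame(summaries)
    num = df.select_dtypes(include=[np.number])
    out = pd.DataFrame({"mean": num.mean(), "sd": num.std(ddof=1)})
    out.index.name = "statistic"
    return out
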