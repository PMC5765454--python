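"""The within-generation reproduction process.

Each female lays R eggs fertilized at the discrete times t = 1..R.  She
mates once at t = 0 and thereafter deterministically every tau time units
with males drawn uniformly from the live males of her deme.  Every mating
stores a sperm packet that decays exponentially at the male's sperm
mortality rate; at each fertilization event all stored packets compete.

Model equations
---------------
* viable sperm of a packet at time t:      zeta = s_i * exp(-mu_i (t - t_i))
* fair-raffle paternity:                   P(sire = i) = zeta_i / sum_j zeta_j
* sperm-limited fertilization:             Phi = 1 - exp(-r * Z_t)
* female viability (cost of mating):       nu_f = exp(-(R/tau - R)^2 / (2 w2_f))
* male viability (cost of sperm):          nu_m = exp(-(rho - rho0)^2 / (2 w2_m)) for rho > rho0, else 1
* sperm resource trade-off:                rho = s^beta / mu
* survival through the phase:              psi(t) = nu^(t/R), realised as a
  Bernoulli trial with probability nu^(1/R) after each fertilization event.

Sperm is never depleted by fertilization; only decay reduces a packet.  A
dead male's stored packets stay competitive (sperm storage is physically
decoupled from his survival), but he receives no further matings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Relative guard against floating-point representation error in k*tau <= t
# comparisons (e.g. 8/0.1 evaluating just below 80).
_EPS = 1e-12


# ----------------------------------------------------------------------
# Schedules

def _kmax(t: float, tau) -> np.ndarray:
    """Largest integer k with k*tau <= t, robust to representation error."""
    return np.floor(np.asarray(t) / np.asarray(tau) * (1.0 + _EPS) + _EPS).astype(np.int64)


def build_mating_schedule(tau: float, R: int) -> np.ndarray:
    """Deterministic mating times {k*tau : k = 0..floor(R/tau)}.

    The schedule always begins at t = 0 and has floor(R/tau) + 1 entries;
    matings with time in (t-1, t] (plus the initial t = 0 mating for t = 1)
    occur before the fertilization event at integer time t.
    """
    if not (0.0 < tau <= 1.0):
        raise ValueError(f"tau out of bounds: {tau}")
    k = np.arange(_kmax(R, tau) + 1)
    return k * tau


def matings_before_event(tau, t: int):
    """Per-female mating indices k scheduled in the interval before event t.

    Returns ``(k_lo, k_hi)`` (inclusive) arrays; event 1 includes the
    initial mating at t = 0.
    """
    tau = np.asarray(tau, dtype=float)
    k_hi = _kmax(t, tau)
    k_lo = np.zeros_like(k_hi) if t == 1 else _kmax(t - 1, tau) + 1
    return k_lo, k_hi


# ----------------------------------------------------------------------
# Packet arithmetic

def viable_sperm(s, mu, t_mating, t):
    """zeta = s * exp(-mu * (t - t_mating)); requires t >= t_mating."""
    dt = np.asarray(t, dtype=float) - np.asarray(t_mating, dtype=float)
    if np.any(dt < -1e-9):
        raise ValueError("fertilization before mating time: scheduling bug")
    return np.asarray(s, dtype=float) * np.exp(-np.asarray(mu, dtype=float) * np.maximum(dt, 0.0))


def raffle_probabilities(zetas) -> np.ndarray:
    """Fair-raffle weights: each packet's share of the total viable sperm."""
    z = np.asarray(zetas, dtype=float)
    total = z.sum()
    if total <= 0:
        raise ValueError("raffle called with no viable sperm")
    return z / total


def raffle_paternity(sires, zetas, rng: np.random.Generator):
    """Draw the sire of one egg: categorical over packets with probability
    proportional to viable sperm.  Packets of the same male are distinct
    entries, so his probabilities add."""
    p = raffle_probabilities(zetas)
    return np.asarray(sires)[rng.choice(len(p), p=p)]


def fertilization_probability(Z, r: float):
    """Phi = 1 - exp(-r Z): sperm-limited fertilization, monotone in Z."""
    return -np.expm1(-r * np.asarray(Z, dtype=float))


# ----------------------------------------------------------------------
# Costs and survival

def sperm_investment(g_s, mu, beta: float, trade_off: bool = True,
                     linear: bool = False):
    """Resources a male allocates to sperm, from pre-depression values.

    Default reading: rho = s^beta / mu (trade-off between number and
    longevity).  ``linear=True`` selects the alternative reading
    rho = (beta*s)/mu; ``trade_off=False`` removes mu (rho = s^beta),
    for the variant model without a sperm-longevity trait.
    """
    g_s = np.asarray(g_s, dtype=float)
    base = beta * g_s if linear else g_s ** beta
    if not trade_off:
        return base
    return base / np.asarray(mu, dtype=float)


def male_viability(rho, rho0, omega2_m: float):
    """nu = exp(-(rho - rho0)^2 / (2 w2_m)) above the cost-free budget, 1 below."""
    rho = np.asarray(rho, dtype=float)
    rho0 = np.asarray(rho0, dtype=float)
    excess = np.maximum(rho - rho0, 0.0)
    return np.exp(-excess**2 / (2.0 * omega2_m))


def female_viability(tau, R: int, omega2_f: float):
    """nu = exp(-(R/tau - R)^2 / (2 w2_f)); monandry (tau = 1) costs nothing."""
    m = np.asarray(R, dtype=float) / np.asarray(tau, dtype=float)
    return np.exp(-(m - R) ** 2 / (2.0 * omega2_f))


def survival_through_phase(nu, t, R: int):
    """Cumulative survival to time t: psi = nu^(t/R)."""
    return np.asarray(nu, dtype=float) ** (np.asarray(t, dtype=float) / R)


# ----------------------------------------------------------------------
# The reproductive phase

@dataclass
class ReproductionParams:
    R: int = 8
    r: float = 0.01
    omega2_f: float = 1.28e5
    omega2_m: float = 1.0
    mode: str = "evolving_polyandry"


@dataclass
class PhaseResult:
    """Outcome of one subpopulation-timeline reproduction phase."""

    dam_idx: np.ndarray    # per conceived offspring, row index of the mother
    sire_idx: np.ndarray   # row index of the father
    egg_time: np.ndarray   # fertilization event (1..R) of each offspring
    alive: np.ndarray      # (n,) adults alive after the final survival trial
    skipped_matings: int   # matings skipped because no live male was available
    egg_log: list | None = None  # optional (t, female, Z, fertilized, sire) rows


def run_reproductive_phase(female: np.ndarray, deme: np.ndarray,
                           tau: np.ndarray, s: np.ndarray, mu: np.ndarray,
                           nu_f: np.ndarray, nu_m: np.ndarray,
                           params: ReproductionParams,
                           rng: np.random.Generator,
                           log_eggs: bool = False) -> PhaseResult:
    """Simulate the shared discrete timeline t = 1..R for all demes at once.

    Per step: (1) scheduled matings in (t-1, t] occur (the t = 0 mating is
    bundled into step 1), each drawing a male uniformly with replacement
    from the live males of the female's deme; (2) each live female's egg is
    fertilized with probability Phi(Z_t) and a sire assigned by fair raffle
    over her stored packets; (3) survival trials with probability nu^(1/R)
    hit every live adult.  Dead females lay no further eggs; dead males get
    no new matings but their stored sperm stays in play.  After t = R all
    adults are past reproduction (nonoverlapping generations).

    ``female``, ``deme`` and the phenotype arrays are per-individual rows;
    phenotypes of the other sex are ignored.  In ``no_sperm_competition``
    mode a single male is designated per egg interval and paternity is
    forced to him, removing raffle competition without changing the
    female's number of matings or costs.
    """
    n = len(female)
    R = params.R
    no_comp = params.mode == "no_sperm_competition"

    fem_rows = np.where(female)[0]
    alive = np.ones(n, dtype=bool)
    p_event = np.empty(n)
    p_event[female] = nu_f[female] ** (1.0 / R)
    p_event[~female] = nu_m[~female] ** (1.0 / R)

    # per-deme male row lists
    demes = np.unique(deme)
    males_of = {g: np.where(~female & (deme == g))[0] for g in demes}

    # packet store (grown per step, concatenated views kept current)
    pk_fem: list[np.ndarray] = []    # mother row of the packet
    pk_sire: list[np.ndarray] = []
    pk_time: list[np.ndarray] = []
    cat = {"fem": np.empty(0, np.int64), "sire": np.empty(0, np.int64),
           "time": np.empty(0, float), "s": np.empty(0, float),
           "mu": np.empty(0, float)}

    designated = np.full(n, -1, dtype=np.int64)  # per-female male, no_comp mode
    dams, sires, times = [], [], []
    skipped = 0
    egg_log = [] if log_eggs else None
    tau_f = tau[fem_rows]

    for t in range(1, R + 1):
        # ---- 1. matings scheduled in this interval ----------------------
        live_f = fem_rows[alive[fem_rows]]
        if live_f.size:
            k_lo, k_hi = matings_before_event(tau[live_f], t)
            counts = np.maximum(k_hi - k_lo + 1, 0)
            total = int(counts.sum())
        else:
            counts = np.empty(0, np.int64)
            total = 0
        if total:
            rep_f = np.repeat(live_f, counts)
            # mating index k within each female's schedule
            starts = np.repeat(np.cumsum(counts) - counts, counts)
            k = np.arange(total) - starts + np.repeat(k_lo, counts)
            m_times = k * tau[rep_f]
            mates = np.full(total, -1, dtype=np.int64)
            if no_comp:
                # one designated male per female for this whole egg interval
                for g in demes:
                    pool = males_of[g]
                    pool = pool[alive[pool]]
                    sel_f = live_f[(deme[live_f] == g)]
                    if pool.size == 0 or sel_f.size == 0:
                        continue
                    designated[sel_f] = pool[rng.integers(0, pool.size, sel_f.size)]
                mates = designated[rep_f]
                # a stale designated male (no live male to redraw) may have
                # died: he keeps paternity of stored sperm but mates no more
                stale = (mates >= 0) & ~alive[np.maximum(mates, 0)]
                mates[stale] = -1
            else:
                for g in demes:
                    sel = deme[rep_f] == g
                    if not sel.any():
                        continue
                    pool = males_of[g]
                    pool = pool[alive[pool]]
                    if pool.size == 0:
                        continue
                    mates[sel] = pool[rng.integers(0, pool.size, int(sel.sum()))]
            ok = mates >= 0
            skipped += int((~ok).sum())
            if ok.any():
                pk_fem.append(rep_f[ok])
                pk_sire.append(mates[ok])
                pk_time.append(m_times[ok])
                cat = {
                    "fem": np.concatenate(pk_fem),
                    "sire": np.concatenate(pk_sire),
                    "time": np.concatenate(pk_time),
                }
                cat["s"] = s[cat["sire"]]
                cat["mu"] = mu[cat["sire"]]

        # ---- 2. fertilization -------------------------------------------
        live_f = fem_rows[alive[fem_rows]]
        if live_f.size and cat["fem"].size:
            zeta = cat["s"] * np.exp(-cat["mu"] * (t - cat["time"]))
            Z = np.zeros(n)
            np.add.at(Z, cat["fem"], zeta)
            phi = fertilization_probability(Z[live_f], params.r)
            fert = rng.random(live_f.size) < phi
            mothers = live_f[fert]
            if mothers.size:
                if no_comp:
                    egg_sires = designated[mothers]
                    valid = egg_sires >= 0
                    mothers, egg_sires = mothers[valid], egg_sires[valid]
                else:
                    # Gumbel-max categorical draw per female over her packets
                    with np.errstate(divide="ignore"):
                        score = np.log(zeta) - np.log(-np.log(
                            rng.random(zeta.size)))
                    best = np.full(n, -np.inf)
                    np.maximum.at(best, cat["fem"], score)
                    win = np.where(score == best[cat["fem"]])[0]
                    # first winner per female (exact ties have measure zero)
                    uniq_f, first = np.unique(cat["fem"][win], return_index=True)
                    sire_of = np.full(n, -1, dtype=np.int64)
                    sire_of[uniq_f] = cat["sire"][win[first]]
                    egg_sires = sire_of[mothers]
                    valid = egg_sires >= 0
                    mothers, egg_sires = mothers[valid], egg_sires[valid]
                dams.append(mothers)
                sires.append(egg_sires)
                times.append(np.full(mothers.size, t))
            if log_eggs:
                sire_col = np.full(live_f.size, -1, dtype=np.int64)
                if mothers.size:
                    pos = {m: s_ for m, s_ in zip(mothers, egg_sires)}
                    for i, f in enumerate(live_f):
                        sire_col[i] = pos.get(f, -1)
                for i, f in enumerate(live_f):
                    egg_log.append((t, int(f), float(Z[f]), bool(fert[i]),
                                    int(sire_col[i])))
        elif log_eggs and live_f.size:
            for f in live_f:
                egg_log.append((t, int(f), 0.0, False, -1))

        # ---- 3. survival trials -----------------------------------------
        live = np.where(alive)[0]
        alive[live] &= rng.random(live.size) < p_event[live]

    empty = np.empty(0, dtype=np.int64)
    return PhaseResult(
        dam_idx=np.concatenate(dams) if dams else empty,
        sire_idx=np.concatenate(sires) if sires else empty,
        egg_time=np.concatenate(times) if times else empty,
        alive=alive, skipped_matings=skipped, egg_log=egg_log)
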