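# Methods

`polyandrysim` is a genetically explicit, individual-based, forward-in-time
simulator of the coevolution of female multiple mating (polyandry) and male
sperm traits in a spatially structured population in which inbreeding — and
inbreeding depression in sperm traits — emerges from the population's own
mating and dispersal dynamics.

## The model

**World.** A 5×5 grid of demes (subpopulations), each with carrying
capacity `K` (default 160). Generations are nonoverlapping. Each
generation runs, in order: reproduction (mating, fertilization, birth),
adult death, offspring dispersal, density-dependent survival.

**Genetic architecture.** Every individual is diploid and carries three
genome classes, all with unlinked loci and free recombination:

* *Trait loci.* Three quantitative traits — female remating interval τ
  (bounded to [0.01, 1]), male sperm number *s* (≥ 1) and male sperm
  mortality rate μ (≥ 10⁻¹⁰) — each encoded by 20 loci with continuous
  alleles. A genotypic value is the plain sum of its 40 alleles; expression
  is sex-limited with no environmental variance.
* *Deleterious loci.* 1000 biallelic loci (wild-type/deleterious); all
  individuals start mutation-free. A male homozygous at Θ loci and
  heterozygous at θ loci expresses sperm number
  `s = g_s (1−S)^Θ (1−hS)^θ` (default target; variants put the depression
  on μ, multiplicatively increasing it, or on the male's cost-free resource
  ρ₀). Dominance is `h = 0` by default, so only homozygotes are affected —
  inbreeding exposes the load.
* *Neutral loci.* 1000 loci whose alleles are drawn (and re-mutated) from
  U[−1000, 1000]. Two equal alleles are identical by descent for all
  practical purposes, so an individual's homozygous fraction H_i is a
  realized-inbreeding proxy, and its population mean H_p tracks
  population-wide inbreeding independently of the selected loci.

All alleles mutate at 0.001/allele/generation: trait alleles receive a
zero-mean normal perturbation, deleterious alleles flip state in either
direction, neutral alleles are redrawn.

**Reproduction.** Each female lays `R = 8` eggs, fertilized at discrete
times t = 1…R. She mates once at t = 0 and then deterministically every τ
time units (⌊R/τ⌋ + 1 matings in total), each time with a male drawn
uniformly with replacement from the live males of her deme. A mating
stores a sperm packet that decays as ζ = s·e^(−μ(t−t_mating)). An egg is
fertilized with probability Φ = 1 − e^(−rZ) where Z is the female's total
viable stored sperm (sperm limitation), and paternity follows a fair
raffle: each packet wins in proportion to its ζ. Mating is costly for
females (viability ν_f = e^(−(R/τ−R)²/2ω²_f), ω²_f = 1.28×10⁵) and sperm
investment ρ = s^β/μ beyond a free budget ρ₀ is costly for males
(ν_m = e^(−(ρ−ρ₀)²/2ω²_m) above ρ₀, ω²_m = 1). Survival is applied as a
Bernoulli trial with probability ν^(1/R) after every fertilization event,
so cumulative survival to the end of the phase equals ν. Investment ρ is
always computed from pre-depression values: an inbred male pays the same
cost as an outbred male of equal genotype.

**Dispersal and regulation.** Offspring disperse with probability `d`;
displacement is exponential (mean 1.5 cells) in a uniform random
direction, redrawn until the destination lies on the grid. Each individual
then survives density regulation with probability min(K/N, 1), N the local
census.

**Observers.** Per generation the simulator reports trait means (τ, 1/τ,
s, g_s, μ), viabilities, H_p, female fertility before regulation, the
sex-specific reproductive-success variances V_f and V_m (population
variance over all adults, zero counts included) and the effective size
N_ev = 8N/(V_m+V_f+4), the deleterious allele frequency and Θ/θ means, and
a diagnostic Φ̄_mon — the fertilization probability a hypothetical
once-mated (t = 0) female would have, averaged over egg times and males.
Windowed statistics: the within-deme Pearson correlation between male H_i
and offspring sired (pooled over a configurable trailing window, default
50 generations, averaged over demes) and the OLS slope of offspring H_i on
father H_i at the final generation.

## Experiment modes

* `evolving_polyandry` — the full model.
* `fixed_monandry` — female phenotype forced to τ = 1 (which also removes
  the mating cost); isolates the feedback of the mating system on
  homozygosity.
* `no_sperm_competition` — one male is designated per egg interval and
  all of that interval's matings and the egg's paternity go to him;
  females mate just as often and pay the same costs, but raffle
  competition among males is removed.

## Choices where the design was open

* **Fertilization efficiency r = 0.01.** Gives a once-mated female of the
  founder-mean male (s = 100, μ = 0.5) per-egg Φ ≈ 0.63 at one time unit of
  decay: sperm limitation is real but not absolute.
* **Sperm cost β = 0.5, ρ₀ = s₀^β/μ₀ = 20.** The founder population sits
  exactly at the cost threshold and pays no male viability cost. The
  alternative typographic reading of the investment function,
  ρ = (β·s)/μ, is available via `sperm_cost_linear`.
* **Trait-allele variance.** Initial alleles are Normal(m/40, m/40) for a
  trait with initial mean m (τ: 1, s: 100, μ: 0.5), and mutational
  perturbations have the same sd (per-allele CV = 1, genotypic CV ≈ 16%).
  This is the one free parameter that controls evolvability of the mating
  system. With substantially smaller variance (e.g. a CV scale of 0.2) the
  remating interval cannot respond on simulated timescales: strong
  inbreeding depression then drives fertility collapse and extinction
  before polyandry can evolve, contradicting the qualitative dynamics this
  model exists to produce. Both scales are configurable
  (`init_allele_sd_scale`, `mutation_sd_scale`).
* **Sperm accounting.** Fertilization does not deplete stored sperm; only
  exponential decay reduces a packet. Packets of the same male from
  repeated matings stay separate (their raffle weights add). A dead male's
  stored sperm remains competitive; he simply receives no new matings.
* **Density regulation is local**: N in min(K/N, 1) is the deme census —
  a per-cell carrying capacity is meaningless otherwise.
* **Dispersal that lands in the natal cell still counts as dispersal**;
  only off-grid landings are resampled.
* **Tie-breaking and numerics.** Mating-schedule comparisons k·τ ≤ t use a
  10⁻¹² relative guard against floating-point representation error (8/0.1
  evaluating just below 80). The raffle uses a Gumbel-max categorical
  draw; exact score ties have probability zero. Neutral-locus homozygosity
  intentionally uses exact floating-point equality: alleles are only ever
  copied or redrawn, never transformed.
* **Depression-on-μ variant** uses g_μ/((1−S)^Θ(1−hS)^θ) (depression
  *increases* the mortality rate); **depression-on-ρ₀** multiplies the
  male's free budget by the depression factor.

## Performance and statistical shortcuts (all exactly equivalent)

* Per-allele Bernoulli mutation is realised as a Binomial(n, rate) hit
  count plus uniform positions without replacement.
* Dispersal and density regulation are independent of offspring genotype,
  so they are decided before meiosis and genomes are built only for
  surviving offspring — except at the final generation, when all conceived
  offspring are materialised for the father–offspring regression.
* Observer statistics are sampled at conception (before regulation), as
  the reported fertility and success variances require.

## What the scaled-down acceptance world does and does not establish

Full-scale experiments (K = 160, 10,000 generations, 50 replicates) are
cluster-scale. The test suite instead reruns the model in a scaled world —
K = 100, 700 generations, 3 replicates, 250 neutral loci (observational
only; the deleterious architecture is untouched) — and asserts *orderings*
of across-replicate means: polyandry (1/τ) higher at S = 0.03 than S = 0;
Φ̄_mon lower; female fertility higher with sperm competition than without
at S = 0.03; H_p under evolving polyandry not above fixed monandry; the
male homozygosity–siring correlation more negative under depression.
Because small demes inbreed much faster than the published world, strong-
depression cells can go extinct mid-run; comparisons are therefore made at
the latest generation recorded in all replicates of the cells being
compared. A green ordering shows the mechanism operates with the right
sign at desk scale; it does not reproduce equilibrium magnitudes, and the
H_p contrast in particular is a small effect that sits near the resolution
limit of three replicates.

The synthetic founder world emulates an outbred, mutation-free,
demographically saturated population; it does not emulate standing
deleterious variation, linkage, environmental variance, or mate choice —
so no test here speaks to those.

## Known limitations

* No linkage, pleiotropy, dominance at trait loci, or inbreeding
  depression in offspring viability (all deliberately outside the model).
* The correlation/regression observers need within-deme variation; demes
  with none are excluded (logged at debug level), and tiny populations can
  leave them undefined (NaN).
* Extreme polyandry (τ near 0.01) makes the packet store large; the
  engine remains exact but slows roughly linearly in packets per female.
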