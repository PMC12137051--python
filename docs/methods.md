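# Methods

## Model structure and assumptions

`virunet` implements a discrete-generation, individual-based SI
metapopulation. Hosts and parasites are asexual and haploid with
non-overlapping generations; parasites are obligately host-borne (they
disperse only inside hosts and leave no environmental propagule pool);
transmission and competition are strictly local to a patch. Host traits
are fixed — only parasite virulence evolves — so the model applies to
systems in which parasites evolve much faster than their hosts.
Riverine flow directionality is not modelled: river-like networks are
undirected spanning trees.

Virulence v ∈ (0, 1] acts on host fecundity: an infected host produces
(1 − v) times the offspring of a susceptible one. Its only benefit to
the parasite is increased transmission through the trade-off
β(v) = β_max v^s (saturating for s < 1, linear at s = 1, accelerating
for s > 1).

### Life-cycle order and stochastic realization

Each generation applies dispersal → reproduction → transmission →
(optional) genotype shuffle, in that order; the state after transmission
is the next generation's starting state.

- **Dispersal.** Each individual leaves with probability d and, if it
  leaves, moves to a uniformly chosen neighbor (a disperser never stays
  home; d is the leaving probability). Susceptible movement is realized
  per patch as a Binomial(S_x, d) emigrant count multinomially split
  over neighbors; infected hosts are moved individually so genotypes
  travel with them. Both are distributionally identical to per-individual
  Bernoulli moves.
- **Reproduction.** The per-parent offspring rate in patch x is
  f_x = λ₀ / (1 + α N_x) for susceptible and (1 − v_i) f_x for infected
  parent i (each parent's own virulence). The realized newborn count is
  one Poisson draw per patch with rate f_x (S_x + Σ_i (1 − v_i)). By
  Poisson additivity this equals, in distribution, independent
  per-parent draws; because all offspring are born susceptible and
  inherit nothing from the parent host, parent identity is irrelevant
  and a single draw is exact, not an approximation.
- **Transmission.** Each infected parent i contributes force
  φ_i = a β(v_i) / (1 + a N_x(t+1)) toward the newborn cohort
  N_x(t+1). A newborn escapes infection with probability exp(−Σφ_i);
  infected counts are Binomial(N_x(t+1), 1 − e^(−Σφ)). The infecting
  strain is a competitive lottery with probability φ_i / Σφ ("many can
  find a host, one infects"). Summing forces inside one exponential
  makes the monomorphic expectation reduce exactly to the
  Nicholson–Bailey type II form. The alternative (sequential strain
  attacks) was rejected because it is order-dependent and has no
  closed-form monomorphic limit.
- **Mutation** applies to each newly transmitted genotype. Virulence:
  with probability m_v, logit(v) is perturbed by Normal(0, σ_v); v is
  clamped to [10⁻⁶, 1 − 10⁻⁶] before the logit so the transform is
  always finite (fixed-virulence runs bypass mutation and may sit at
  v = 1 exactly). Neutral locus: with probability m_n (default = m_v),
  the allele is replaced by a never-before-used identifier
  (infinite-allele model), so allelic identity implies common descent.
- **Shuffle** (kin-structure control): after transmission, the multiset
  of parasite genotypes is randomly permuted across all infected host
  slots landscape-wide. Per-patch S and I counts are bit-identical
  before and after; only genotype location changes.

### Parameters

| name | meaning | default | notes |
|---|---|---|---|
| λ₀ | host intrinsic growth rate | 4 | focal scenario |
| α | intraspecific competition (per ind.) | 0.01 | K ≈ (λ₀−1)/α = 300 per patch |
| β_max | maximum transmission rate | 8 | focal scenario |
| s | trade-off shape | 0.5 | saturating |
| a | parasite searching efficiency | 0.01 | type II functional response |
| d | natal dispersal probability | 0.5 | swept in experiments |
| m_v | virulence mutation prob. per transmission | 0.01 | see below |
| σ_v | mutation-effect SD (logit scale) | 0.2 | see below |
| m_n | neutral mutation probability | = m_v | same rate as the trait |
| T | generations | 2500 | evolutionary equilibrium horizon |

The focal demographic/epidemiological parameters put the system in a
strongly oscillatory host–parasite regime with frequent local parasite
extinctions; this host limitation is what gives kin selection its
purchase. The mutation parameters m_v = 0.01 and σ_v = 0.2 are package
defaults of a plausible magnitude for trait-evolution individual-based
models; they control the *speed* of virulence evolution (equilibria are
approached, at the focal parameters, on a ~2,500-generation horizon)
much more than its endpoint.

### Initialization

Every patch starts at the host Beverton–Holt equilibrium
round((λ₀ − 1)/α) with a configurable fraction (default 10%) of hosts
infected. Initial virulence is v₀ = 0.5 in evolving runs (the fixed
value in ecological runs). All initial neutral alleles are distinct
(maximal diversity), so any relatedness observed later was generated by
the extinction–recolonization and transmission dynamics, not seeded in.

## Landscapes

- **RGG (terrestrial-like).** n points uniform on the unit square;
  pairs within radius r are neighbors. Disconnected draws are discarded
  and all coordinates redrawn with a fresh sub-seed (whole-network
  rejection, not local repair). At the defaults (n = 100, r = 0.15) the
  accepted-realization grand mean degree is ≈ 6.1.
- **OCN (river-like).** A drainage-direction spanning tree on an
  un-aggregated grid (default 10×10, fixed outlet at the corner cell),
  relaxed by Metropolis annealing of E = Σ_i A_i^γ, where A_i is the
  drainage area (cells draining through i, itself included) and γ = 0.5.
  Proposals re-point one non-outlet cell to a different lattice neighbor
  (8-neighbor directions, standard for drainage grids) and are rejected
  if they would create a cycle. Temperature starts at the standard
  deviation of ΔE over a 100-proposal pilot and decays geometrically to
  10⁻³ of that over the run; the default budget is 50·(grid side)²
  proposals, which on the 10×10 grid reliably drops the energy well
  below the random-tree starting point (the annealing internals shape
  dendritic realism only — *any* iteration count yields a spanning tree
  with exactly n − 1 edges, hence mean degree 1.98 for n = 100).
- **Controls.** `circular` is a ring lattice (every degree 2k; k = 1
  matches the OCN mean degree with a perfectly homogeneous
  distribution); `spiky` is a cycle of hubs each carrying pendant
  degree-1 leaves (OCN-like mean degree with an OCN-like leaf-heavy
  degree distribution). Both follow the verbal construction of
  degree-matched controls; their parameters are exposed so alternative
  recipes can be matched exactly.

## Statistics

- **Relatedness** R_x = Σ_k p²_{k,x} (identity-in-state probability of
  two draws with replacement). Over a window it is computed per time
  point and averaged over the parasite-occupied time points; patches
  never occupied in the window yield a missing value and are excluded
  from landscape averages (an occupancy-weighted variant is available
  behind a flag). Empty-patch time points contribute missing, never 0
  or 1.
- **Evolved virulence**: median v over all infected hosts landscape-wide
  at the final step; extinct runs yield missing. Both conventions for
  aggregating extinct replicates (exclude vs. impute-missing) are
  supported by `persisted_only`, since medians-with-missing have no
  unique convention.
- **Local parasite extinction**: the fraction of a trailing window
  (default 100 generations) during which a patch holds no parasite;
  prevalence and host densities are time averages over the same window.
- **Degree stratification**: medians and inter-quartile ranges per patch
  degree over pooled patches and replicates; degree classes 1 vs. 5
  contrast headwaters with hubs.

## Experiment orchestration

A design is the full factorial of landscape kinds × landscape
replicates × dispersal values × treatments (evolving / shuffled / fixed,
the latter crossed with a virulence grid v = 0.8, 0.82, …, 1.0). Every
cell's seed is derived by hashing the design key (master seed, kind,
replicate, dispersal, treatment, fixed v) through `SeedSequence`, so
cells are order-independent, parallel-safe, and individually
reproducible bit-for-bit; landscape replicates are likewise seeded per
(kind, replicate) and shared across treatments. Cell failures are
flagged in the summary table rather than aborting a sweep. Each run uses
five named RNG streams (dispersal, reproduction, transmission, mutation,
shuffle) spawned from the cell seed, so refactoring one process leaves
the others' draws untouched.

## Problem sizes

Production-scale presets (1,000 landscape realizations per kind,
T = 2,500) are provided as configuration; the package's own test suite
and worked examples run desk-scale versions — typically 3–10 landscape
replicates per kind, T = 400–1,000, and a 6-point dispersal grid —
which already reproduce the qualitative patterns (river-like unimodal
virulence with a higher peak; terrestrial-like saturating increase;
relatedness decreasing with patch degree at low dispersal). The
dispersal grid for gradient sweeps defaults to
{0.01, 0.05, 0.1, 0.2, 0.3, 0.5, 0.7, 1.0}.

## Numerical and design notes

- Whole-landscape state is stored flat (per-patch susceptible counts
  plus one row per infected host), making a generation a handful of
  vectorized numpy operations; the per-patch operations in the public
  API wrap the same code paths.
- Strain lottery sampling uses a within-segment inverse-CDF search on
  the per-parent force cumsum; the per-patch total force is derived from
  the same cumsum so the lottery and the escape probability are
  numerically consistent.
- Ties/degenerate inputs: an empty landscape is absorbing; a globally
  extinct parasite cannot reappear; λ₀ = 0 empties the landscape in one
  generation; runs always continue to T with extinction times flagged.
- `T = 0` returns the initial state; `d = 0` disables movement exactly;
  `d = 1` forces every individual to move.

## Known limitations

- The synthetic landscapes emulate the *topology* of terrestrial and
  riverine systems, not their geometry beyond it: no directional river
  flow, no patch-size or habitat-quality variation, no distance-weighted
  dispersal within the neighbor set. Conclusions from passing tests
  concern topology-mediated effects only.
- Host evolution (dispersal, resistance), overlapping generations,
  environmental parasite reservoirs, and mortality virulence are out of
  scope by design.
- The OCN annealer is a generic drainage-energy minimizer; it does not
  reproduce any particular hydrological package's realization
  statistics beyond the spanning-tree degree structure and a
  substantially lowered drainage energy.
- At desk-scale horizons (T ≈ 1,000) slow late-stage selection (the
  trade-off flattens as v → 1) means evolving runs can still be creeping
  upward; endpoint medians at T = 1,000 are systematically a little
  below their T = 2,500 equilibria. The shuffled-treatment median, for
  example, reaches ≈ 0.99 only on the longer horizon.
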