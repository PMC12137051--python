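"""Individual-based host-parasite metapopulation dynamics.

The model is a discrete-generation susceptible-infected (SI)
metapopulation.  Hosts are asexual and haploid; parasites are vertically
carried by dispersing hosts and transmitted locally to newborn hosts.
Each generation runs, in order:

1. **Dispersal** — every individual independently leaves its natal patch
   with probability ``d`` and moves to a uniformly chosen neighbor patch.
2. **Reproduction** — Beverton-Holt density regulation: a susceptible
   parent in patch x contributes Poisson(lambda0 / (1 + alpha * N_x))
   offspring; an infected parent carrying virulence v contributes
   Poisson((1 - v) * lambda0 / (1 + alpha * N_x)) — fecundity virulence.
   All offspring are born susceptible and the parental generation dies.
3. **Transmission** — propagules released from the dead infected parents
   attack the newborn cohort following a Nicholson-Bailey model with a
   type II functional response: with per-strain force
   ``phi_g = a * beta(v_g) * I_g / (1 + a * N_new)``, each newborn escapes
   infection with probability ``exp(-sum_g phi_g)``; an infected newborn's
   strain is a competitive lottery proportional to ``phi_g``.  The
   transmission rate trades off with virulence, ``beta(v) = beta_max *
   v**s``.  New infections then mutate: virulence on the logit scale
   (probability ``m_v``, Normal(0, sigma_v) effects) and a neutral marker
   locus under an infinite-allele scheme (probability ``m_n``).
4. **Shuffle** (optional) — parasite genotypes are permuted across all
   infected hosts landscape-wide, destroying kin structure while leaving
   every patch's susceptible and infected counts untouched.

States are stored in flat arrays (per-patch susceptible counts plus one
row per infected host) so a full generation is a handful of vectorized
numpy operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.special import expit, logit

from .landscapes import LandscapeGraph

__all__ = [
    "ModelParams",
    "InitSpec",
    "ParasiteGenotype",
    "PatchState",
    "MetapopState",
    "RngStreams",
    "SimulationResult",
    "transmission_rate",
    "disperse",
    "reproduce",
    "transmit",
    "mutate_virulence",
    "mutate_neutral",
    "shuffle_parasites",
    "step",
    "run",
]

_V_EPS = 1e-6  # clamp for the logit transform of virulence


# ---------------------------------------------------------------------------
# Parameters and state containers
# ---------------------------------------------------------------------------


@dataclass
class ModelParams:
    """Demographic, epidemiological and mutational parameters.

    Defaults are the focal scenario: host intrinsic growth rate
    ``lambda0 = 4``, intraspecific competition ``alpha = 0.01`` (carrying
    capacity ~300 hosts per patch), maximum transmission ``beta_max = 8``
    with a saturating trade-off ``s = 0.5``, and parasite searching
    efficiency ``a = 0.01``.
    """

    lambda0: float = 4.0  # host intrinsic growth rate (offspring/parent)
    alpha: float = 0.01  # intraspecific competition (per individual)
    beta_max: float = 8.0  # maximum transmission rate
    s: float = 0.5  # trade-off shape (saturating < 1 < accelerating)
    a: float = 0.01  # parasite searching efficiency
    d: float = 0.5  # natal dispersal probability
    m_v: float = 0.01  # virulence mutation probability per transmission
    sigma_v: float = 0.2  # mutation-effect SD on the logit scale
    m_n: float | None = None  # neutral-locus mutation probability (= m_v)
    T: int = 2500  # generations
    virulence_mode: str = "evolving"  # or "fixed"
    fixed_v: float = 0.94  # virulence used when fixed
    shuffle: bool = False  # break kin structure post-transmission

    @property
    def neutral_mutation_rate(self) -> float:
        return self.m_v if self.m_n is None else self.m_n

    def validate(self) -> None:
        if self.lambda0 < 0:
            raise ValueError("lambda0 must be >= 0")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.beta_max < 0:
            raise ValueError("beta_max must be >= 0")
        if self.s <= 0:
            raise ValueError("s must be > 0")
        if self.a <= 0:
            raise ValueError("a must be > 0")
        if not 0.0 <= self.d <= 1.0:
            raise ValueError("d must lie in [0, 1]")
        for name in ("m_v", "neutral_mutation_rate"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.sigma_v <= 0:
            raise ValueError("sigma_v must be > 0")
        if self.T < 0:
            raise ValueError("T must be >= 0")
        if self.virulence_mode not in ("evolving", "fixed"):
            raise ValueError("virulence_mode must be 'evolving' or 'fixed'")
        if not 0.0 < self.fixed_v <= 1.0:
            raise ValueError("fixed_v must lie in (0, 1]")


@dataclass
class InitSpec:
    """Initial conditions.

    Every patch starts at the host Beverton-Holt equilibrium
    ``round((lambda0 - 1) / alpha)`` and a fraction ``infected_fraction``
    of those hosts carry a parasite.  Initial virulence is ``v0`` in
    evolving runs (``fixed_v`` in fixed runs); initial neutral alleles are
    all distinct so any later relatedness is generated by the dynamics,
    not the initializer.
    """

    infected_fraction: float = 0.1
    v0: float = 0.5

    def validate(self) -> None:
        if not 0.0 <= self.infected_fraction <= 1.0:
            raise ValueError("infected_fraction must lie in [0, 1]")
        if not 0.0 < self.v0 <= 1.0:
            raise ValueError("v0 must lie in (0, 1]")


class ParasiteGenotype(NamedTuple):
    """Heritable parasite genome: virulence v in (0, 1] and a neutral
    allele identifier (infinite-allele model)."""

    v: float
    neutral_allele: int


@dataclass
class PatchState:
    """One patch: a susceptible count and one genotype per infected host."""

    susceptibles: int
    infected: list[ParasiteGenotype] = field(default_factory=list)

    @property
    def n_infected(self) -> int:
        return len(self.infected)

    @property
    def n_total(self) -> int:
        return self.susceptibles + len(self.infected)


@dataclass
class MetapopState:
    """Whole-landscape state in flat-array form.

    ``S[x]`` is the susceptible count of patch x; infected hosts are rows
    of the parallel arrays (``inf_patch``, ``inf_v``, ``inf_allele``).
    """

    S: np.ndarray
    inf_patch: np.ndarray
    inf_v: np.ndarray
    inf_allele: np.ndarray
    t: int = 0
    next_allele: int = 0

    @property
    def n_patches(self) -> int:
        return len(self.S)

    @property
    def I(self) -> np.ndarray:
        return np.bincount(self.inf_patch, minlength=self.n_patches).astype(np.int64)

    @property
    def n_infected(self) -> int:
        return len(self.inf_patch)

    @property
    def patches(self) -> list[PatchState]:
        out = [PatchState(int(s)) for s in self.S]
        for p, v, a in zip(self.inf_patch, self.inf_v, self.inf_allele):
            out[int(p)].infected.append(ParasiteGenotype(float(v), int(a)))
        return out

    @classmethod
    def from_patches(
        cls, patches: Sequence[PatchState], t: int = 0, next_allele: int | None = None
    ) -> "MetapopState":
        S = np.array([p.susceptibles for p in patches], dtype=np.int64)
        rows = [
            (x, g.v, g.neutral_allele)
            for x, p in enumerate(patches)
            for g in p.infected
        ]
        if rows:
            px, pv, pa = zip(*rows)
        else:
            px, pv, pa = (), (), ()
        if next_allele is None:
            next_allele = (max(pa) + 1) if pa else 0
        return cls(
            S=S,
            inf_patch=np.array(px, dtype=np.int64),
            inf_v=np.array(pv, dtype=np.float64),
            inf_allele=np.array(pa, dtype=np.int64),
            t=t,
            next_allele=int(next_allele),
        )

    def copy(self) -> "MetapopState":
        return MetapopState(
            S=self.S.copy(),
            inf_patch=self.inf_patch.copy(),
            inf_v=self.inf_v.copy(),
            inf_allele=self.inf_allele.copy(),
            t=self.t,
            next_allele=self.next_allele,
        )


@dataclass
class RngStreams:
    """Named, independent random streams (one per life-cycle process) so
    that refactoring one process never perturbs the draws of another."""

    dispersal: np.random.Generator
    reproduction: np.random.Generator
    transmission: np.random.Generator
    mutation: np.random.Generator
    shuffle: np.random.Generator

    @classmethod
    def from_seed(cls, seed) -> "RngStreams":
        children = np.random.SeedSequence(seed).spawn(5)
        return cls(*(np.random.default_rng(c) for c in children))


# ---------------------------------------------------------------------------
# Life-cycle primitives
# ---------------------------------------------------------------------------


def transmission_rate(v, params: ModelParams):
    """Virulence-transmission trade-off beta(v) = beta_max * v**s."""
    v = np.asarray(v, dtype=float)
    if np.any(v < 0) or np.any(v > 1):
        raise ValueError("virulence must lie in [0, 1]")
    out = params.beta_max * v ** params.s
    return float(out) if out.ndim == 0 else out


def _disperse_susceptibles(S, d, indptr, indices, rng) -> np.ndarray:
    """Move Binomial(S_x, d) susceptibles out of each patch, each to a
    uniformly chosen neighbor; returns the new count vector."""
    n = len(S)
    movers = rng.binomial(S, d) if d > 0 else np.zeros(n, dtype=np.int64)
    new_S = S - movers
    for x in range(n):
        m = int(movers[x])
        if m == 0:
            continue
        nbr = indices[indptr[x] : indptr[x + 1]]
        if len(nbr) == 0:
            raise ValueError(f"patch {x} has no neighbors")
        counts = rng.multinomial(m, np.full(len(nbr), 1.0 / len(nbr)))
        np.add.at(new_S, nbr, counts)
    return new_S


def _disperse_infected(inf_patch, d, indptr, indices, rng) -> np.ndarray:
    """Per-individual dispersal of infected hosts (genotypes ride along)."""
    m = len(inf_patch)
    if m == 0 or d == 0:
        return inf_patch.copy()
    move = rng.random(m) < d
    new_patch = inf_patch.copy()
    src = inf_patch[move]
    deg = indptr[src + 1] - indptr[src]
    if np.any(deg == 0):
        bad = src[deg == 0][0]
        raise ValueError(f"patch {bad} has no neighbors")
    pick = rng.integers(0, deg)
    new_patch[move] = indices[indptr[src] + pick]
    return new_patch


def disperse(
    state: MetapopState, g: LandscapeGraph, d: float, rng: np.random.Generator
) -> MetapopState:
    """Natal dispersal: each individual leaves with probability ``d`` to a
    uniformly chosen neighbor patch.  Totals of S and I are conserved."""
    if len(state.S) != g.n_patches:
        raise ValueError("state and landscape disagree on patch count")
    if not 0.0 <= d <= 1.0:
        raise ValueError("d must lie in [0, 1]")
    indptr, indices = g.neighbors()
    new = state.copy()
    new.S = _disperse_susceptibles(state.S, d, indptr, indices, rng)
    new.inf_patch = _disperse_infected(state.inf_patch, d, indptr, indices, rng)
    return new


def _offspring_counts(S, inf_patch, inf_v, params: ModelParams, rng) -> np.ndarray:
    """Poisson newborn count per patch under Beverton-Holt regulation with
    per-parent fecundity rates (infected parents contribute 1 - v each).

    One Poisson draw per patch with the summed per-parent rate; by Poisson
    additivity this is distributed identically to independent per-parent
    draws, and offspring carry nothing from their parent.
    """
    n = len(S)
    I_load = np.bincount(inf_patch, weights=1.0 - inf_v, minlength=n)
    N = S + np.bincount(inf_patch, minlength=n)
    fec = params.lambda0 / (1.0 + params.alpha * N)
    return rng.poisson(fec * (S + I_load)).astype(np.int64)


def reproduce(patch: PatchState, params: ModelParams, rng) -> int:
    """Newborn count (all susceptible) for one patch; the caller discards
    the parental generation."""
    inf_v = np.array([g.v for g in patch.infected], dtype=float)
    inf_patch = np.zeros(len(inf_v), dtype=np.int64)
    S = np.array([patch.susceptibles], dtype=np.int64)
    return int(_offspring_counts(S, inf_patch, inf_v, params, rng)[0])


def _transmit_all(
    inf_patch, inf_v, inf_allele, newborns, params: ModelParams, rng
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nicholson-Bailey attack of parental propagules on the newborn cohort.

    Returns (patch, v, allele) arrays for the newly infected hosts; the
    genotypes are verbatim parental copies (mutation is applied later).
    """
    n = len(newborns)
    m = len(inf_patch)
    if m == 0 or newborns.sum() == 0:
        e = np.empty(0, dtype=np.int64)
        return e, np.empty(0, dtype=np.float64), e.copy()
    # per-parent force of infection on its patch's newborn cohort
    phi = (
        params.a
        * transmission_rate(inf_v, params)
        / (1.0 + params.a * newborns[inf_patch])
    )
    order = np.argsort(inf_patch, kind="stable")
    phi_sorted = phi[order]
    cum = np.cumsum(phi_sorted)
    seg_counts = np.bincount(inf_patch, minlength=n)
    seg_end = np.cumsum(seg_counts)  # one past the segment, in sorted order
    base = np.concatenate([[0.0], cum])[seg_end - seg_counts]
    total_force = cum[seg_end - 1] - base  # per patch; 0 where no parents
    total_force[seg_counts == 0] = 0.0
    p_infect = -np.expm1(-total_force)
    k_new = rng.binomial(newborns, p_infect)
    tot = int(k_new.sum())
    if tot == 0:
        e = np.empty(0, dtype=np.int64)
        return e, np.empty(0, dtype=np.float64), e.copy()
    new_patch = np.repeat(np.arange(n), k_new)
    # competitive lottery among strains, proportional to per-strain force
    u = base[new_patch] + rng.random(tot) * total_force[new_patch]
    idx = np.searchsorted(cum, u, side="left")
    idx = np.minimum(idx, seg_end[new_patch] - 1)
    parent = order[idx]
    return new_patch, inf_v[parent].copy(), inf_allele[parent].copy()


def transmit(
    patch_parents: PatchState, newborns: int, params: ModelParams, rng
) -> list[ParasiteGenotype]:
    """Infected-newborn genotype assignments for one patch (pre-mutation
    parental copies); the remaining newborns stay susceptible."""
    if newborns < 0:
        raise ValueError("newborns must be >= 0")
    inf_v = np.array([g.v for g in patch_parents.infected], dtype=float)
    inf_allele = np.array(
        [g.neutral_allele for g in patch_parents.infected], dtype=np.int64
    )
    inf_patch = np.zeros(len(inf_v), dtype=np.int64)
    _, v, a = _transmit_all(
        inf_patch, inf_v, inf_allele, np.array([newborns], dtype=np.int64), params, rng
    )
    return [ParasiteGenotype(float(vi), int(ai)) for vi, ai in zip(v, a)]


def _mutate_virulence_arr(v: np.ndarray, params: ModelParams, rng) -> np.ndarray:
    """Logit-scale virulence mutation, vectorized; returns a new array."""
    out = v.copy()
    if params.m_v <= 0 or len(v) == 0:
        return out
    mask = rng.random(len(v)) < params.m_v
    k = int(mask.sum())
    if k:
        x = logit(np.clip(out[mask], _V_EPS, 1.0 - _V_EPS))
        out[mask] = expit(x + rng.normal(0.0, params.sigma_v, size=k))
    return out


def _mutate_neutral_arr(
    alleles: np.ndarray, rate: float, next_allele: int, rng
) -> tuple[np.ndarray, int]:
    """Infinite-allele neutral mutation: mutants get brand-new identifiers."""
    out = alleles.copy()
    if rate <= 0 or len(alleles) == 0:
        return out, next_allele
    mask = rng.random(len(alleles)) < rate
    k = int(mask.sum())
    if k:
        out[mask] = next_allele + np.arange(k)
        next_allele += k
    return out, next_allele


def mutate_virulence(g: ParasiteGenotype, params: ModelParams, rng) -> ParasiteGenotype:
    """With probability ``m_v``, perturb logit(v) by Normal(0, sigma_v);
    the result always stays strictly inside (0, 1)."""
    v = _mutate_virulence_arr(np.array([g.v], dtype=float), params, rng)[0]
    return ParasiteGenotype(float(v), g.neutral_allele)


class AlleleCounter:
    """Supplies never-before-used neutral allele identifiers."""

    def __init__(self, start: int = 0) -> None:
        self.next = int(start)

    def take(self, k: int = 1) -> np.ndarray:
        out = np.arange(self.next, self.next + k, dtype=np.int64)
        self.next += k
        return out


def mutate_neutral(
    g: ParasiteGenotype, params: ModelParams, rng, allele_counter: AlleleCounter
) -> ParasiteGenotype:
    """With probability ``m_n`` replace the neutral allele with a fresh
    unique identifier (infinite-allele model)."""
    if rng.random() < params.neutral_mutation_rate:
        return ParasiteGenotype(g.v, int(allele_counter.take(1)[0]))
    return g


def shuffle_parasites(state: MetapopState, rng) -> MetapopState:
    """Permute parasite genotypes across all infected host slots in the
    landscape.  Per-patch S and I counts and the global genotype multiset
    are exactly preserved; only the genotype-to-patch assignment changes."""
    new = state.copy()
    if state.n_infected > 1:
        perm = rng.permutation(state.n_infected)
        new.inf_v = state.inf_v[perm]
        new.inf_allele = state.inf_allele[perm]
    return new


# ---------------------------------------------------------------------------
# Generation step and full runs
# ---------------------------------------------------------------------------


def step(
    state: MetapopState,
    g: LandscapeGraph,
    params: ModelParams,
    rng: RngStreams | np.random.Generator,
) -> MetapopState:
    """Advance one generation: disperse -> reproduce (parents die) ->
    transmit (+ mutation of new infections) -> optional shuffle."""
    if isinstance(rng, np.random.Generator):
        rng = RngStreams(rng, rng, rng, rng, rng)
    indptr, indices = g.neighbors()
    # dispersal
    S = _disperse_susceptibles(state.S, params.d, indptr, indices, rng.dispersal)
    inf_patch = _disperse_infected(
        state.inf_patch, params.d, indptr, indices, rng.dispersal
    )
    # reproduction (offspring all susceptible; parents die below)
    newborns = _offspring_counts(S, inf_patch, state.inf_v, params, rng.reproduction)
    # transmission from dead infected parents onto the newborn cohort
    new_patch, new_v, new_allele = _transmit_all(
        inf_patch, state.inf_v, state.inf_allele, newborns, params, rng.transmission
    )
    next_allele = state.next_allele
    if params.virulence_mode == "evolving":
        new_v = _mutate_virulence_arr(new_v, params, rng.mutation)
    new_allele, next_allele = _mutate_neutral_arr(
        new_allele, params.neutral_mutation_rate, next_allele, rng.mutation
    )
    new = MetapopState(
        S=newborns - np.bincount(new_patch, minlength=g.n_patches),
        inf_patch=new_patch,
        inf_v=new_v,
        inf_allele=new_allele,
        t=state.t + 1,
        next_allele=next_allele,
    )
    if params.shuffle:
        new = shuffle_parasites(new, rng.shuffle)
    return new


def initialize(
    g: LandscapeGraph, params: ModelParams, init: InitSpec, rng=None
) -> MetapopState:
    """Build the t=0 state: every patch at host carrying capacity with a
    fixed infected fraction; all initial neutral alleles distinct."""
    init.validate()
    n = g.n_patches
    k = int(round((params.lambda0 - 1.0) / params.alpha)) if params.lambda0 > 1 else 0
    k = max(k, 0)
    i0 = int(round(init.infected_fraction * k))
    v0 = params.fixed_v if params.virulence_mode == "fixed" else init.v0
    inf_patch = np.repeat(np.arange(n), i0)
    m = len(inf_patch)
    return MetapopState(
        S=np.full(n, k - i0, dtype=np.int64),
        inf_patch=inf_patch,
        inf_v=np.full(m, v0, dtype=np.float64),
        inf_allele=np.arange(m, dtype=np.int64),
        t=0,
        next_allele=m,
    )


def _patch_relatedness_meanv(
    state: MetapopState, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-patch probability of identity of two neutral alleles drawn with
    replacement (sum of squared frequencies) and mean virulence; NaN for
    parasite-free patches."""
    R = np.full(n, np.nan)
    meanv = np.full(n, np.nan)
    if state.n_infected == 0:
        return R, meanv
    I = np.bincount(state.inf_patch, minlength=n)
    key = state.inf_patch * (state.next_allele + 1) + state.inf_allele
    _, inverse, counts = np.unique(key, return_inverse=True, return_counts=True)
    patch_of_key = np.zeros(len(counts), dtype=np.int64)
    patch_of_key[inverse] = state.inf_patch
    sumsq = np.bincount(patch_of_key, weights=counts.astype(float) ** 2, minlength=n)
    occ = I > 0
    R[occ] = sumsq[occ] / I[occ].astype(float) ** 2
    sv = np.bincount(state.inf_patch, weights=state.inf_v, minlength=n)
    meanv[occ] = sv[occ] / I[occ]
    return R, meanv


@dataclass
class SimulationResult:
    """Recorded output of one simulation run.

    ``S`` and ``I`` have shape (T+1, n_patches) and cover every
    generation.  ``rec_times`` lists the generations (always including the
    trailing window) at which per-patch relatedness (``relatedness``) and
    mean virulence (``mean_v``) snapshots were taken; parasite-free
    patches hold NaN.
    """

    params: ModelParams
    landscape: LandscapeGraph
    seed: object
    S: np.ndarray
    I: np.ndarray
    rec_times: np.ndarray
    relatedness: np.ndarray
    mean_v: np.ndarray
    final_state: MetapopState
    parasite_extinct: bool
    parasite_extinction_time: int | None
    host_extinct: bool
    host_extinction_time: int | None

    @property
    def T(self) -> int:
        return self.S.shape[0] - 1

    def window_slice(self, window: int | None = None) -> slice:
        """Index slice over ``rec_times`` for the trailing ``window``
        recorded generations (default: all recorded times)."""
        if window is None:
            return slice(0, len(self.rec_times))
        return slice(max(0, len(self.rec_times) - window), len(self.rec_times))

    def to_dataframe(self):
        """Tidy per-(time, patch) table of S, I and, where recorded,
        relatedness and mean virulence."""
        import pandas as pd

        T1, n = self.S.shape
        t = np.repeat(np.arange(T1), n)
        x = np.tile(np.arange(n), T1)
        df = pd.DataFrame(
            {"t": t, "patch": x, "S": self.S.ravel(), "I": self.I.ravel()}
        )
        rec = pd.DataFrame(
            {
                "t": np.repeat(self.rec_times, n),
                "patch": np.tile(np.arange(n), len(self.rec_times)),
                "relatedness": self.relatedness.ravel(),
                "mean_v": self.mean_v.ravel(),
            }
        )
        return df.merge(rec, on=["t", "patch"], how="left")


def run(
    g: LandscapeGraph,
    params: ModelParams,
    seed,
    init: InitSpec | None = None,
    record_window: int = 100,
    sample_every: int | None = None,
) -> SimulationResult:
    """Run ``params.T`` generations on landscape ``g``.

    Per-patch S and I are recorded every generation; per-patch relatedness
    and mean virulence are recorded over the trailing ``record_window``
    generations and, if ``sample_every`` is given, at every multiple of it.
    A globally extinct parasite cannot reappear (no environmental
    reservoir), and an empty landscape is absorbing; runs always continue
    to T, with extinction times flagged.
    """
    params.validate()
    init = init or InitSpec()
    if g.n_patches < 1:
        raise ValueError("landscape has no patches")
    streams = RngStreams.from_seed(seed)
    state = initialize(g, params, init)
    n = g.n_patches
    T = params.T
    S_hist = np.zeros((T + 1, n), dtype=np.int64)
    I_hist = np.zeros((T + 1, n), dtype=np.int64)
    rec_start = max(0, T - record_window + 1)
    rec_times = sorted(
        set(range(rec_start, T + 1))
        | (
            set(range(0, T + 1, sample_every))
            if sample_every
            else set()
        )
    )
    rec_index = {t: i for i, t in enumerate(rec_times)}
    R_rec = np.full((len(rec_times), n), np.nan)
    v_rec = np.full((len(rec_times), n), np.nan)

    parasite_ext_t: int | None = None
    host_ext_t: int | None = None

    def record(st: MetapopState) -> None:
        S_hist[st.t] = st.S
        I_hist[st.t] = st.I
        i = rec_index.get(st.t)
        if i is not None:
            R_rec[i], v_rec[i] = _patch_relatedness_meanv(st, n)

    record(state)
    for _ in range(T):
        state = step(state, g, params, streams)
        record(state)
        if parasite_ext_t is None and state.n_infected == 0:
            parasite_ext_t = state.t
        if host_ext_t is None and state.n_infected == 0 and state.S.sum() == 0:
            host_ext_t = state.t
    return SimulationResult(
        params=params,
        landscape=g,
        seed=seed,
        S=S_hist,
        I=I_hist,
        rec_times=np.asarray(rec_times, dtype=np.int64),
        relatedness=R_rec,
        mean_v=v_rec,
        final_state=state,
        parasite_extinct=parasite_ext_t is not None,
        parasite_extinction_time=parasite_ext_t,
        host_extinct=host_ext_t is not None,
        host_extinction_time=host_ext_t,
    )
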