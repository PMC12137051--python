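"""Spatial networks for metapopulation simulations.

Two landscape families dominate the ecology of dispersal networks:
terrestrial-like landscapes, modelled as random geometric graphs (RGGs) —
spatially embedded and modular, with a fairly homogeneous degree
distribution — and river-like landscapes, modelled as optimal channel
networks (OCNs) — dendritic spanning trees with many degree-1 headwater
patches.  This module generates both, plus two degree-matched control
topologies (ring lattices and "spiky" hub-and-leaf networks), and reads
and writes landscapes as plain-text edge lists.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "LandscapeGraph",
    "OcnAnnealConfig",
    "generate_rgg",
    "generate_ocn",
    "generate_circular",
    "generate_spiky",
    "degree_stats",
    "read_landscape",
    "write_landscape",
]

_KINDS = {"rgg", "ocn", "circular", "spiky", "custom"}


@dataclass
class LandscapeGraph:
    """An undirected, connected network of habitat patches.

    Parameters
    ----------
    n_patches
        Number of patches (nodes); indices are 0-based.
    edges
        Unordered patch-index pairs, stored canonically as (i, j) with i < j.
    kind
        Generator provenance: one of ``rgg``, ``ocn``, ``circular``,
        ``spiky``, ``custom``.
    coords
        Optional (n_patches, 2) planar coordinates (unit square for RGGs,
        grid positions for OCNs).
    outlet
        Outlet patch index (OCNs only).
    seed
        RNG seed of the generator that produced this landscape.
    """

    n_patches: int
    edges: tuple[tuple[int, int], ...]
    kind: str = "custom"
    coords: np.ndarray | None = None
    outlet: int | None = None
    seed: int | None = None

    # CSR adjacency cache, built lazily
    _indptr: np.ndarray | None = field(default=None, repr=False, compare=False)
    _indices: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        canon = sorted({(min(i, j), max(i, j)) for i, j in self.edges})
        self.edges = tuple((int(i), int(j)) for i, j in canon)

    # -- structure ---------------------------------------------------------

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_patches, dtype=np.int64)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def neighbors(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR adjacency: (indptr, indices); neighbors of x are
        ``indices[indptr[x]:indptr[x + 1]]``."""
        if self._indptr is None:
            deg = self.degrees
            indptr = np.concatenate([[0], np.cumsum(deg)])
            indices = np.empty(indptr[-1], dtype=np.int64)
            fill = indptr[:-1].copy()
            for i, j in self.edges:
                indices[fill[i]] = j
                fill[i] += 1
                indices[fill[j]] = i
                fill[j] += 1
            self._indptr, self._indices = indptr, indices
        return self._indptr, self._indices

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_patches))
        g.add_edges_from(self.edges)
        return g

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated structural invariant."""
        if self.n_patches < 1:
            raise ValueError("n_patches must be positive")
        if self.kind not in _KINDS:
            raise ValueError(f"unknown landscape kind {self.kind!r}")
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop at patch {i}")
            if not (0 <= i < self.n_patches and 0 <= j < self.n_patches):
                raise ValueError(f"edge ({i}, {j}) out of range")
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges")
        g = self.to_networkx()
        if self.n_patches > 1 and not nx.is_connected(g):
            raise ValueError("landscape is not connected")
        if self.kind == "ocn":
            if self.n_edges != self.n_patches - 1:
                raise ValueError("OCN must be a spanning tree (|E| = n - 1)")
            if not nx.is_tree(g):
                raise ValueError("OCN must be acyclic")


@dataclass
class OcnAnnealConfig:
    """Simulated-annealing settings for optimal-channel-network generation.

    The network is a spanning tree of drainage directions on a square grid,
    relaxed by Metropolis annealing of the landscape energy
    ``E = sum_i A_i**gamma`` where ``A_i`` counts the cells draining
    through cell ``i`` (itself included) and ``gamma`` is
    ``energy_exponent``.

    Attributes
    ----------
    grid_side
        Side of the (un-aggregated) square grid; n_patches = grid_side**2.
    energy_exponent
        gamma in (0, 1); 0.5 is the standard choice for river networks.
    n_iterations
        Number of re-wiring proposals.  None means 50 * grid_side**2.
    t_initial
        Initial temperature; None estimates it from the standard deviation
        of energy changes over a 100-proposal pilot.
    cooling
        Per-proposal geometric decay is chosen so the temperature falls to
        ``cooling`` times its initial value by the final proposal.
    neighborhood
        4 or 8 lattice drainage directions.
    outlet_position
        Grid cell index of the (fixed) outlet; default corner cell 0.
    """

    grid_side: int = 10
    energy_exponent: float = 0.5
    n_iterations: int | None = None
    t_initial: float | None = None
    cooling: float = 1e-3
    neighborhood: int = 8
    outlet_position: int = 0

    def validate(self) -> None:
        if self.grid_side < 2:
            raise ValueError("grid_side must be >= 2")
        if not 0.0 < self.energy_exponent < 1.0:
            raise ValueError("energy_exponent must lie in (0, 1)")
        if self.n_iterations is not None and self.n_iterations <= 0:
            raise ValueError("n_iterations must be positive")
        if self.neighborhood not in (4, 8):
            raise ValueError("neighborhood must be 4 or 8")
        n = self.grid_side ** 2
        if not 0 <= self.outlet_position < n:
            raise ValueError("outlet_position out of range")
        if not 0.0 < self.cooling <= 1.0:
            raise ValueError("cooling must lie in (0, 1]")


# ---------------------------------------------------------------------------
# Random geometric graphs (terrestrial-like)
# ---------------------------------------------------------------------------


def generate_rgg(
    n: int, r: float, seed: int, max_retries: int = 1000
) -> LandscapeGraph:
    """Generate a connected random geometric graph on the unit square.

    ``n`` points are drawn from U[0,1]x[0,1] and pairs within Euclidean
    distance ``r`` become neighbors.  Disconnected draws are discarded and
    all coordinates redrawn (with a fresh sub-seed) until a connected
    realization is found or ``max_retries`` is exhausted.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if r <= 0.0:
        raise ValueError("r must be positive")
    for attempt in range(max_retries):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(attempt,)))
        coords = rng.random((n, 2))
        pairs = cKDTree(coords).query_pairs(r, output_type="ndarray")
        edges = tuple((int(i), int(j)) for i, j in pairs)
        g = LandscapeGraph(n, edges, kind="rgg", coords=coords, seed=seed)
        if nx.is_connected(g.to_networkx()):
            return g
    raise RuntimeError(
        f"no connected RGG found in {max_retries} attempts "
        f"(radius r={r} is likely too small for n={n})"
    )


# ---------------------------------------------------------------------------
# Optimal channel networks (river-like)
# ---------------------------------------------------------------------------


def _grid_neighbors(side: int, neighborhood: int) -> list[list[int]]:
    if neighborhood == 4:
        offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offs = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    nbrs: list[list[int]] = []
    for i in range(side):
        for j in range(side):
            cell = []
            for di, dj in offs:
                ii, jj = i + di, j + dj
                if 0 <= ii < side and 0 <= jj < side:
                    cell.append(ii * side + jj)
            nbrs.append(cell)
    return nbrs


def _random_drainage_tree(
    nbrs: list[list[int]], outlet: int, rng: np.random.Generator
) -> list[int]:
    """Random spanning tree of drainage directions rooted at the outlet
    (randomized Prim growth); parent[outlet] = -1."""
    n = len(nbrs)
    parent = [-2] * n
    parent[outlet] = -1
    frontier = [(c, outlet) for c in nbrs[outlet]]
    while frontier:
        k = int(rng.integers(len(frontier)))
        cell, par = frontier.pop(k)
        if parent[cell] != -2:
            continue
        parent[cell] = par
        for c in nbrs[cell]:
            if parent[c] == -2:
                frontier.append((c, cell))
    if any(p == -2 for p in parent):
        raise RuntimeError("grid is disconnected (internal error)")
    return parent


def _drainage_areas(parent: list[int]) -> list[int]:
    n = len(parent)
    area = [1] * n
    # accumulate leaf-to-root: process cells by decreasing depth
    depth = [0] * n
    for c in range(n):
        d, x = 0, c
        while parent[x] != -1:
            x = parent[x]
            d += 1
        depth[c] = d
    for c in sorted(range(n), key=lambda c: -depth[c]):
        if parent[c] != -1:
            area[parent[c]] += area[c]
    return area


def _path_to_root(parent: list[int], start: int) -> list[int]:
    path = []
    x = start
    while x != -1:
        path.append(x)
        x = parent[x]
    return path


def generate_ocn(config: OcnAnnealConfig | None = None, seed: int = 0) -> LandscapeGraph:
    """Generate an optimal channel network by simulated annealing.

    Starting from a random drainage-direction spanning tree directed toward
    a fixed outlet, single-cell re-wiring proposals (re-pointing one
    non-outlet cell's drainage to a different lattice neighbor) are
    accepted by the Metropolis rule on ``E = sum A_i**gamma``; proposals
    that would create a cycle are rejected outright.  The undirected
    skeleton of the final tree is returned, so the result always has
    exactly ``n_patches - 1`` edges (average degree 2(n-1)/n, i.e. 1.98
    for the default 100-patch grid).
    """
    config = config or OcnAnnealConfig()
    config.validate()
    side = config.grid_side
    n = side * side
    gamma = config.energy_exponent
    n_iter = config.n_iterations if config.n_iterations is not None else 50 * side * side
    outlet = config.outlet_position
    rng = np.random.default_rng(seed)

    nbrs = _grid_neighbors(side, config.neighborhood)
    parent = _random_drainage_tree(nbrs, outlet, rng)
    area = _drainage_areas(parent)
    energy = sum(a ** gamma for a in area)

    non_outlet = [c for c in range(n) if c != outlet]

    def propose(rng: np.random.Generator) -> tuple[int, int] | None:
        c = non_outlet[int(rng.integers(len(non_outlet)))]
        cand = [b for b in nbrs[c] if b != parent[c]]
        if not cand:
            return None
        return c, cand[int(rng.integers(len(cand)))]

    def delta_paths(c: int, nb: int) -> tuple[float, list[int], list[int]] | None:
        # reject if nb drains through c (cycle)
        new_path = []
        x = nb
        while x != -1:
            if x == c:
                return None
            new_path.append(x)
            x = parent[x]
        old_path = _path_to_root(parent, parent[c])
        old_set, new_set = set(old_path), set(new_path)
        ac = area[c]
        d_e = 0.0
        for cell in new_path:
            if cell not in old_set:
                d_e += (area[cell] + ac) ** gamma - area[cell] ** gamma
        for cell in old_path:
            if cell not in new_set:
                d_e += (area[cell] - ac) ** gamma - area[cell] ** gamma
        return d_e, old_path, new_path

    # pilot: estimate the scale of energy changes for the initial temperature
    if config.t_initial is None:
        pilot = []
        for _ in range(100):
            p = propose(rng)
            if p is None:
                continue
            res = delta_paths(*p)
            if res is not None:
                pilot.append(res[0])
        t0 = float(np.std(pilot)) if pilot else 1.0
        t0 = t0 if t0 > 0 else 1.0
    else:
        t0 = config.t_initial
    decay = config.cooling ** (1.0 / max(n_iter, 1))

    temp = t0
    for _ in range(n_iter):
        p = propose(rng)
        if p is not None:
            c, nb = p
            res = delta_paths(c, nb)
            if res is not None:
                d_e, old_path, new_path = res
                if d_e <= 0 or rng.random() < math.exp(-d_e / temp):
                    ac = area[c]
                    old_set, new_set = set(old_path), set(new_path)
                    for cell in old_path:
                        if cell not in new_set:
                            area[cell] -= ac
                    for cell in new_path:
                        if cell not in old_set:
                            area[cell] += ac
                    parent[c] = nb
                    energy += d_e
        temp *= decay

    edges = tuple(
        (min(c, parent[c]), max(c, parent[c])) for c in range(n) if parent[c] != -1
    )
    coords = np.array([(c // side, c % side) for c in range(n)], dtype=float)
    g = LandscapeGraph(n, edges, kind="ocn", coords=coords, outlet=outlet, seed=seed)
    g.validate()
    return g


def ocn_energy(g: LandscapeGraph, gamma: float = 0.5) -> float:
    """Energy ``sum_i A_i**gamma`` of a spanning tree rooted at its outlet."""
    if g.outlet is None:
        raise ValueError("landscape has no outlet")
    tree = g.to_networkx()
    parent = {g.outlet: -1}
    for u, v in nx.bfs_edges(tree, g.outlet):
        parent[v] = u
    parent_list = [parent[c] for c in range(g.n_patches)]
    return float(sum(a ** gamma for a in _drainage_areas(parent_list)))


# ---------------------------------------------------------------------------
# Control landscapes
# ---------------------------------------------------------------------------


def generate_circular(n: int, k: int = 1) -> LandscapeGraph:
    """Ring lattice: each patch connects to its k nearest neighbors on each
    side, so every degree is 2k.  With k=1 the average degree (2) is close
    to an OCN's 1.98 while the degree distribution is perfectly homogeneous.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    if not 1 <= k < n / 2:
        raise ValueError("k must satisfy 1 <= k < n/2")
    edges = tuple(
        (i, (i + step) % n) for i in range(n) for step in range(1, k + 1)
    )
    g = LandscapeGraph(n, edges, kind="circular")
    g.validate()
    return g


def generate_spiky(n_hubs: int, leaves_per_hub: int) -> LandscapeGraph:
    """Hub-and-leaf control: a cycle (path for two hubs) of hub patches,
    each bearing ``leaves_per_hub`` pendant degree-1 leaves.  Matches an
    OCN's average degree (~2) while keeping its heterogeneous, leaf-heavy
    degree distribution.
    """
    if n_hubs < 2:
        raise ValueError("n_hubs must be >= 2")
    if leaves_per_hub < 1:
        raise ValueError("leaves_per_hub must be >= 1")
    edges = []
    if n_hubs == 2:
        edges.append((0, 1))
    else:
        edges.extend((h, (h + 1) % n_hubs) for h in range(n_hubs))
    nxt = n_hubs
    for h in range(n_hubs):
        for _ in range(leaves_per_hub):
            edges.append((h, nxt))
            nxt += 1
    g = LandscapeGraph(nxt, tuple(edges), kind="spiky")
    g.validate()
    return g


# ---------------------------------------------------------------------------
# Statistics and I/O
# ---------------------------------------------------------------------------


def degree_stats(g: LandscapeGraph) -> tuple[float, dict[int, int]]:
    """Mean degree (2|E|/n) and a histogram over observed degrees."""
    deg = g.degrees
    values, counts = np.unique(deg, return_counts=True)
    return 2.0 * g.n_edges / g.n_patches, {int(v): int(c) for v, c in zip(values, counts)}


def write_landscape(g: LandscapeGraph, path, coords_path=None) -> None:
    """Write a landscape as an edge-list text file: one ``i j`` pair per
    line, 0-based indices, with a comment header recording provenance."""
    with open(path, "w") as fh:
        fh.write(f"# virunet landscape kind={g.kind} n_patches={g.n_patches}")
        if g.outlet is not None:
            fh.write(f" outlet={g.outlet}")
        if g.seed is not None:
            fh.write(f" seed={g.seed}")
        fh.write("\n")
        for i, j in g.edges:
            fh.write(f"{i} {j}\n")
    if coords_path is not None and g.coords is not None:
        with open(coords_path, "w") as fh:
            for i, (x, y) in enumerate(g.coords):
                fh.write(f"{i} {x} {y}\n")


def read_landscape(path, allow_disconnected: bool = False) -> LandscapeGraph:
    """Read an edge-list landscape file (inverse of :func:`write_landscape`).

    Lines starting with ``#`` are comments; a ``n_patches=`` token in a
    comment fixes the patch count (otherwise max index + 1 is used).
    Self-loops and out-of-range indices raise; duplicate edges are
    deduplicated with a warning; disconnected input raises unless
    ``allow_disconnected`` is set.
    """
    edges: list[tuple[int, int]] = []
    n_patches = None
    kind = "custom"
    outlet = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("n_patches="):
                        n_patches = int(tok.split("=", 1)[1])
                    elif tok.startswith("kind="):
                        kind = tok.split("=", 1)[1]
                    elif tok.startswith("outlet="):
                        outlet = int(tok.split("=", 1)[1])
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'i j', got {line!r}")
            try:
                i, j = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer index") from exc
            if i == j:
                raise ValueError(f"{path}:{lineno}: self-loop ({i}, {i})")
            if i < 0 or j < 0:
                raise ValueError(f"{path}:{lineno}: negative patch index")
            edges.append((min(i, j), max(i, j)))
    if n_patches is None:
        if not edges:
            raise ValueError(f"{path}: no edges and no n_patches header")
        n_patches = max(max(e) for e in edges) + 1
    for i, j in edges:
        if j >= n_patches:
            raise ValueError(f"{path}: edge ({i}, {j}) out of range for n_patches={n_patches}")
    if len(set(edges)) != len(edges):
        warnings.warn(f"{path}: duplicate edges deduplicated", stacklevel=2)
    if kind not in _KINDS:
        kind = "custom"
    g = LandscapeGraph(n_patches, tuple(set(edges)), kind=kind, outlet=outlet)
    if not allow_disconnected:
        if n_patches > 1 and not nx.is_connected(g.to_networkx()):
            raise ValueError(f"{path}: landscape is not connected")
    return g
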