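"""Brain parcellation and the two superposed graphs.

The cerebral parenchyma is represented by a parcellation into N parcels,
each a vertex of two graphs sharing the same vertex set:

* the **connectivity graph** G, whose symmetric nonnegative weights
  ``w^E_ij`` measure white-matter fibre connection strength (misfolded tau
  spreads here, along neural pathways), and
* the **proximity graph** Gamma, whose weights ``w^F_ij`` link spatially
  neighbouring parcels with distance-derived weights (extracellular
  amyloid-beta spreads here, through the parenchyma).

Diffusion on either graph uses the row-normalised weighted graph Laplacian

    (L g)(x_m) = (1/pi_m) * sum_j (g(x_m) - g(x_j)) w_mj,   pi_m = sum_j w_mj,

which is positive semidefinite; reaction-diffusion equations therefore use
it with a leading minus sign.  ``pi_m > 0`` is required for every node, so
isolated nodes are rejected at construction time.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np


class ConnectomeError(ValueError):
    """Malformed or inconsistent connectome input."""


class GraphValidationError(ConnectomeError):
    """A graph violates the weighted-graph invariants."""


class GenerationError(ConnectomeError):
    """Synthetic-connectome parameters cannot yield a valid graph."""


# ---------------------------------------------------------------------------
# Weighted graph
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WeightedGraph:
    """Symmetric weighted graph with strictly positive node weight-sums.

    Parameters
    ----------
    weights
        Dense ``(N, N)`` symmetric nonnegative weight matrix with zero
        diagonal.
    pi
        Per-node totals ``pi_m = sum_j w_mj`` (computed by
        :meth:`from_weights`); every entry must be strictly positive.
    """

    weights: np.ndarray
    pi: np.ndarray
    # Row-stochastic propagator W / pi, cached for fast Laplacian products.
    _prop: np.ndarray = field(repr=False, compare=False, default=None)

    @classmethod
    def from_weights(cls, weights: np.ndarray, *, atol: float = 1e-12) -> "WeightedGraph":
        w = np.asarray(weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise GraphValidationError(f"weight matrix must be square, got shape {w.shape}")
        if w.shape[0] < 1:
            raise GraphValidationError("graph needs at least one node")
        if not np.all(np.isfinite(w)):
            raise GraphValidationError("weights contain non-finite entries")
        if np.any(w < 0):
            raise GraphValidationError("weights must be nonnegative")
        scale = max(w.max(initial=0.0), 1.0)
        if np.max(np.abs(w - w.T)) > atol * scale:
            raise GraphValidationError("weight matrix is not symmetric")
        if np.any(np.diagonal(w) != 0.0):
            raise GraphValidationError("self-loops are not allowed (diagonal must be zero)")
        w = 0.5 * (w + w.T)  # remove round-off asymmetry
        pi = w.sum(axis=1)
        if np.any(pi <= 0):
            bad = int(np.argmin(pi))
            raise GraphValidationError(
                f"node {bad} has zero weight sum (pi_m = 0): isolated nodes are not allowed"
            )
        prop = w / pi[:, None]
        g = cls(weights=w, pi=pi, _prop=prop)
        return g

    @property
    def node_count(self) -> int:
        return self.weights.shape[0]

    def apply_laplacian(self, g: np.ndarray) -> np.ndarray:
        """Apply the row-normalised graph Laplacian to node values ``g``.

        ``g`` may be ``(N,)`` or ``(N, k)``; columns are treated
        independently.
        """
        g = np.asarray(g, dtype=float)
        if g.shape[0] != self.node_count:
            raise ValueError(
                f"node-value array has length {g.shape[0]}, graph has {self.node_count} nodes"
            )
        return g - self._prop @ g

    def content_hash(self) -> str:
        """Stable hex digest of the weight matrix (run-log provenance)."""
        return hashlib.sha256(np.ascontiguousarray(self.weights).tobytes()).hexdigest()[:16]


def laplacian_apply(graph: WeightedGraph, g: np.ndarray) -> np.ndarray:
    """Row-normalised graph Laplacian, ``(Lg)_m = (1/pi_m) sum_j (g_m - g_j) w_mj``."""
    return graph.apply_laplacian(g)


# ---------------------------------------------------------------------------
# Parcellation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Parcellation:
    """Partition of the vertex set into named regions, plus the tau seed set.

    ``region_index[m]`` gives the region of node ``m`` as an index into
    ``region_labels``; the regions partition the node set by construction.
    ``seed_nodes`` (``V_seed``) collects the vertices of the entorhinal
    cortex, where misfolded-tau production is seeded (Braak staging).
    """

    node_ids: tuple
    region_labels: tuple
    region_index: np.ndarray
    seed_nodes: np.ndarray
    coords: np.ndarray | None = None

    def __post_init__(self):
        ri = np.asarray(self.region_index, dtype=int)
        if ri.shape != (len(self.node_ids),):
            raise ConnectomeError("region_index must assign exactly one region per node")
        if ri.size and (ri.min() < 0 or ri.max() >= len(self.region_labels)):
            raise ConnectomeError("region_index refers to an unknown region")
        seeds = np.asarray(self.seed_nodes, dtype=int)
        if seeds.size and (seeds.min() < 0 or seeds.max() >= len(self.node_ids)):
            raise ConnectomeError("seed_nodes refers to an unknown node")
        object.__setattr__(self, "region_index", ri)
        object.__setattr__(self, "seed_nodes", seeds)

    @property
    def node_count(self) -> int:
        return len(self.node_ids)

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    def region_members(self, j: int) -> np.ndarray:
        """Node indices of region ``j``."""
        if not 0 <= j < self.n_regions:
            raise ConnectomeError(f"unknown region index {j}")
        return np.flatnonzero(self.region_index == j)

    def region_sizes(self) -> np.ndarray:
        return np.bincount(self.region_index, minlength=self.n_regions)

    def seed_region_indices(self) -> np.ndarray:
        """Regions whose node sets intersect ``V_seed``."""
        if self.seed_nodes.size == 0:
            return np.array([], dtype=int)
        return np.unique(self.region_index[self.seed_nodes])


def seed_indicator(parcellation: Parcellation) -> np.ndarray:
    """Per-node indicator of ``V_seed``: 1 on seed nodes, 0 elsewhere."""
    chi = np.zeros(parcellation.node_count)
    chi[parcellation.seed_nodes] = 1.0
    return chi


# ---------------------------------------------------------------------------
# File readers
# ---------------------------------------------------------------------------

_EDGE_HEADER = ("node_i", "node_j", "weight")


def load_graph(path, fmt: str | None = None, *, dialect: str = "strict") -> WeightedGraph:
    """Read a weighted graph from an edge-list CSV or a GraphML file.

    Edge-list files use 1-based node ids and the header
    ``node_i,node_j,weight``; undirected edges may be stored once.  When both
    orientations of an edge appear, ``dialect="strict"`` requires the weights
    to agree and ``dialect="sum"`` adds them.

    Parameters
    ----------
    path
        Input file.
    fmt
        ``"edge-list-csv"`` or ``"graphml"``; inferred from the file suffix
        when omitted.
    dialect
        Duplicate-entry policy for edge lists, ``"strict"`` (default) or
        ``"sum"``.
    """
    path = Path(path)
    if fmt is None:
        fmt = "graphml" if path.suffix.lower() == ".graphml" else "edge-list-csv"
    if fmt == "edge-list-csv":
        return _load_edge_list(path, dialect=dialect)
    if fmt == "graphml":
        return _load_graphml(path)
    raise ConnectomeError(f"unknown graph format {fmt!r}")


def _load_edge_list(path: Path, *, dialect: str) -> WeightedGraph:
    if dialect not in ("strict", "sum"):
        raise ConnectomeError(f"unknown duplicate-edge dialect {dialect!r}")
    entries: dict[tuple[int, int], float] = {}
    n_max = 0
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or tuple(h.strip() for h in header) != _EDGE_HEADER:
            raise ConnectomeError(
                f"{path}: expected header 'node_i,node_j,weight', got {header!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                i, j = int(row[0]), int(row[1])
                w = float(row[2])
            except (ValueError, IndexError) as exc:
                raise ConnectomeError(f"{path}:{lineno}: malformed edge row {row!r}") from exc
            if i < 1 or j < 1:
                raise ConnectomeError(f"{path}:{lineno}: node ids are 1-based, got ({i},{j})")
            if i == j:
                raise ConnectomeError(f"{path}:{lineno}: self-loop on node {i}")
            if not np.isfinite(w) or w < 0:
                raise ConnectomeError(f"{path}:{lineno}: weight must be finite and >= 0, got {w}")
            key = (min(i, j) - 1, max(i, j) - 1)
            if key in entries:
                if dialect == "sum":
                    entries[key] += w
                elif entries[key] != w:
                    raise ConnectomeError(
                        f"{path}:{lineno}: conflicting weights for edge {i}-{j} "
                        f"({entries[key]} vs {w}) under strict dialect"
                    )
            else:
                entries[key] = w
            n_max = max(n_max, i, j)
    if not entries:
        raise ConnectomeError(f"{path}: no edges found")
    w = np.zeros((n_max, n_max))
    for (a, b), val in entries.items():
        w[a, b] = w[b, a] = val
    return WeightedGraph.from_weights(w)


def _load_graphml(path: Path) -> WeightedGraph:
    import networkx as nx

    g = nx.read_graphml(path)
    if g.is_directed():
        g = g.to_undirected()
    nodes = sorted(g.nodes())
    index = {n: k for k, n in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)))
    for a, b, data in g.edges(data=True):
        if a == b:
            raise ConnectomeError(f"{path}: self-loop on node {a!r}")
        val = float(data.get("weight", 1.0))
        if val < 0:
            raise ConnectomeError(f"{path}: negative weight on edge {a!r}-{b!r}")
        w[index[a], index[b]] = w[index[b], index[a]] = val
    return WeightedGraph.from_weights(w)


def load_parcellation(path) -> Parcellation:
    """Read a parcel table CSV with columns ``node_id,region,seed[,x,y,z]``.

    ``node_id`` is 1-based and must enumerate 1..N; ``seed`` is 0 or 1.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"node_id", "region", "seed"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ConnectomeError(f"{path}: parcel table needs columns {sorted(required)}")
        has_xyz = {"x", "y", "z"}.issubset(reader.fieldnames)
        rows = []
        for lineno, row in enumerate(reader, start=2):
            try:
                nid = int(row["node_id"])
                seed = int(row["seed"])
                xyz = (
                    (float(row["x"]), float(row["y"]), float(row["z"])) if has_xyz else None
                )
            except (TypeError, ValueError) as exc:
                raise ConnectomeError(f"{path}:{lineno}: malformed parcel row") from exc
            if seed not in (0, 1):
                raise ConnectomeError(f"{path}:{lineno}: seed flag must be 0 or 1")
            rows.append((nid, row["region"].strip(), seed, xyz))
    rows.sort(key=lambda r: r[0])
    ids = [r[0] for r in rows]
    if ids != list(range(1, len(rows) + 1)):
        raise ConnectomeError(f"{path}: node_id column must enumerate 1..N exactly once")
    labels: list[str] = []
    region_index = []
    for _, region, _, _ in rows:
        if region not in labels:
            labels.append(region)
        region_index.append(labels.index(region))
    seeds = np.flatnonzero([r[2] for r in rows])
    coords = np.array([r[3] for r in rows]) if has_xyz else None
    return Parcellation(
        node_ids=tuple(ids),
        region_labels=tuple(labels),
        region_index=np.array(region_index),
        seed_nodes=seeds,
        coords=coords,
    )


# ---------------------------------------------------------------------------
# Synthetic connectomes
# ---------------------------------------------------------------------------


def synthesize_connectome(
    n_nodes: int,
    n_regions: int,
    rng_seed: int,
    *,
    k_neighbors: int = 4,
    region_scatter: float = 0.18,
    inter_edges_per_pair: int = 2,
) -> tuple[Parcellation, WeightedGraph, WeightedGraph]:
    """Generate a synthetic parcellation with its two superposed graphs.

    The generator emulates, without anatomical claims, the structure the
    model needs: parcels placed in 3D and grouped into spatially contiguous
    regions; two bilateral regions flagged as the "entorhinal cortex"
    analogue (``V_seed``); a proximity graph connecting k nearest neighbours
    with weights ``1/d`` decaying in distance; and a connected connectivity
    graph with heavy-tailed weights, heavier within regions and on edges
    adjacent to the seed regions.

    Returns ``(parcellation, connectivity, proximity)``; deterministic for a
    fixed ``rng_seed``.
    """
    if n_regions < 3:
        raise GenerationError("need n_regions >= 3 (two seed regions plus at least one other)")
    if n_nodes < 2 * n_regions:
        raise GenerationError("need n_nodes >= 2 * n_regions so every region has >= 2 parcels")
    rng = np.random.default_rng(rng_seed)

    # Region centres: bilateral seed pair on the x-axis, remaining regions on
    # a spherical-Fibonacci shell (deterministically well separated).
    centers = np.zeros((n_regions, 3))
    centers[0] = (-0.75, 0.15, -0.1)
    centers[1] = (0.75, 0.15, -0.1)
    k = n_regions - 2
    idx = np.arange(k)
    golden = (1 + 5**0.5) / 2
    theta = 2 * np.pi * idx / golden
    z = 1 - 2 * (idx + 0.5) / k
    r = np.sqrt(np.maximum(1 - z**2, 0.0))
    centers[2:, 0] = 0.9 * r * np.cos(theta)
    centers[2:, 1] = 0.9 * r * np.sin(theta)
    centers[2:, 2] = 0.9 * z
    centers[2:] += rng.normal(0.0, 0.04, size=(k, 3))

    sizes = np.full(n_regions, n_nodes // n_regions)
    sizes[: n_nodes - sizes.sum()] += 1
    region_index = np.repeat(np.arange(n_regions), sizes)
    coords = centers[region_index] + rng.normal(0.0, region_scatter, size=(n_nodes, 3))

    proximity = _proximity_graph(coords, k_neighbors)
    connectivity = _connectivity_graph(
        coords, centers, region_index, sizes, rng, inter_edges_per_pair
    )

    labels = ["EC_left", "EC_right"] + [f"region_{j:02d}" for j in range(3, n_regions + 1)]
    seeds = np.flatnonzero(region_index < 2)
    parc = Parcellation(
        node_ids=tuple(range(1, n_nodes + 1)),
        region_labels=tuple(labels),
        region_index=region_index,
        seed_nodes=seeds,
        coords=coords,
    )
    return parc, connectivity, proximity


def _proximity_graph(coords: np.ndarray, k_neighbors: int) -> WeightedGraph:
    from scipy.spatial import cKDTree

    n = coords.shape[0]
    if k_neighbors < 1 or k_neighbors >= n:
        raise GenerationError("k_neighbors must be in [1, n_nodes)")
    tree = cKDTree(coords)
    dist, nbr = tree.query(coords, k=k_neighbors + 1)
    w = np.zeros((n, n))
    for m in range(n):
        for d, j in zip(dist[m, 1:], nbr[m, 1:]):
            w[m, j] = 1.0 / max(d, 1e-9)
    w = np.maximum(w, w.T)
    _connect_components(w, coords)
    return WeightedGraph.from_weights(w)


def _connectivity_graph(coords, centers, region_index, sizes, rng, inter_edges_per_pair):
    n = coords.shape[0]
    n_regions = len(sizes)
    w = np.zeros((n, n))
    members = [np.flatnonzero(region_index == j) for j in range(n_regions)]
    # dense heavy edges inside each region
    for nodes in members:
        for a_i, a in enumerate(nodes):
            for b in nodes[a_i + 1 :]:
                w[a, b] = w[b, a] = rng.lognormal(0.0, 0.5)
    # sparse lighter inter-region edges, decaying with centre distance
    cdist = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
    for j in range(n_regions):
        for l in range(j + 1, n_regions):
            strength = 0.3 * np.exp(-cdist[j, l] / 1.5)
            for _ in range(max(1, inter_edges_per_pair)):
                a = rng.choice(members[j])
                b = rng.choice(members[l])
                val = strength * rng.lognormal(0.0, 1.0)
                w[a, b] += val
                w[b, a] += val
    # seed regions couple strongly to their nearest neighbours (the model's
    # "amygdala/hippocampus" analogue of strong entorhinal projections)
    for s in (0, 1):
        order = np.argsort(cdist[s])
        near = [j for j in order if j != s][:2]
        for j in near:
            blk = np.ix_(members[s], members[j])
            w[blk] *= 3.0
            w[np.ix_(members[j], members[s])] *= 3.0
    _connect_components(w, coords)
    return WeightedGraph.from_weights(w)


def _connect_components(w: np.ndarray, coords: np.ndarray) -> None:
    """Join disconnected components in-place via their closest node pair."""
    from scipy.sparse.csgraph import connected_components

    while True:
        n_comp, labels = connected_components((w > 0).astype(np.int8), directed=False)
        if n_comp == 1:
            return
        main = labels == labels[0]
        other = ~main
        d = np.linalg.norm(coords[main][:, None, :] - coords[other][None, :, :], axis=-1)
        a_i, b_i = np.unravel_index(np.argmin(d), d.shape)
        a = np.flatnonzero(main)[a_i]
        b = np.flatnonzero(other)[b_i]
        w[a, b] = w[b, a] = 1.0 / max(d[a_i, b_i], 1e-9)
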