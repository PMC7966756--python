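"""Proximity networks over bound waters and the three hydration motifs.

Three motifs recur on the ice-binding sites of DUF3494 antifreeze
proteins and are extracted here:

* **zigzag networks** — chains of waters in the IBS loop region whose
  O-O spacings (~2.9 A) and three-water angles (~110-120 deg) resemble
  the puckered hexagonal rings of the ice basal plane;
* **linear troughs** — rows of waters trapped between inward-facing
  hydrophobic residues of the IBS beta-sheet, with repeat intervals
  (~4.6 A) matching the prism plane;
* **hydration rings** — closed rings of waters clamped around a
  hydrophobic (aromatic) side chain, the signature of hydrophobic
  hydration at the IBS edge.

The proximity network connects waters within a distance cutoff (3.7 A by
default); motif statistics are computed on oxygen positions only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .structio import Atom, Structure, WaterSet

__all__ = [
    "WaterNetwork",
    "NetworkStats",
    "LinearTrough",
    "HydrationRing",
    "build_network",
    "network_stats",
    "find_linear_trough",
    "find_hydration_ring",
]

DEFAULT_NETWORK_CUTOFF = 3.7  # A, proximal-water connectivity
DEFAULT_RING_CUTOFF = 3.5  # A, ring-water connectivity


@dataclass
class WaterNetwork:
    """Undirected proximity graph over water oxygens."""

    waters: WaterSet
    cutoff: float
    edges: list[tuple[int, int, float]]  # (i, j, distance), i < j

    @property
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.waters)))
        g.add_weighted_edges_from(self.edges, weight="distance")
        return g

    def components(self) -> list[list[int]]:
        comps = [sorted(c) for c in nx.connected_components(self.graph)]
        comps.sort(key=lambda c: (-len(c), c))
        return comps

    def largest_component(self) -> "WaterNetwork":
        """Sub-network restricted to the largest connected component."""
        comp = self.components()[0]
        index = {old: new for new, old in enumerate(comp)}
        sub = self.waters.subset(comp)
        edges = [
            (index[i], index[j], d)
            for i, j, d in self.edges
            if i in index and j in index
        ]
        return WaterNetwork(sub, self.cutoff, edges)


@dataclass
class NetworkStats:
    """Edge-distance and triplet-angle statistics of a water network."""

    distances: np.ndarray  # per-edge, A
    angles: np.ndarray  # per connected triple, degrees, measured at the middle
    component_sizes: list[int]
    branch_count: int  # nodes with degree >= 3

    @property
    def mean_distance(self) -> float:
        return float(self.distances.mean())

    @property
    def mean_angle(self) -> float:
        return float(self.angles.mean()) if len(self.angles) else float("nan")

    def summary(self) -> dict:
        d, a = self.distances, self.angles
        return {
            "n_edges": int(len(d)),
            "distance_min": float(d.min()),
            "distance_max": float(d.max()),
            "distance_mean": float(d.mean()),
            "n_angles": int(len(a)),
            "angle_min": float(a.min()) if len(a) else None,
            "angle_max": float(a.max()) if len(a) else None,
            "angle_mean": float(a.mean()) if len(a) else None,
            "component_sizes": self.component_sizes,
            "branch_count": self.branch_count,
        }


@dataclass
class LinearTrough:
    """Waters aligned along a best-fit line in a hydrophobic surface trough."""

    water_ids: list[str]  # ordered by projection along the line
    coords: np.ndarray
    intervals: np.ndarray  # consecutive gaps along the ordering, A
    span: float  # end-to-end distance, A
    residual: float  # max perpendicular TLS residual, A
    found: bool = True

    @property
    def n_waters(self) -> int:
        return len(self.water_ids)

    @property
    def mean_interval(self) -> float:
        return float(self.intervals.mean()) if len(self.intervals) else float("nan")


@dataclass
class HydrationRing:
    """Cyclic (or open) water arrangement around a hydrophobic side chain."""

    water_ids: list[str]  # cyclic order (or path order when open)
    coords: np.ndarray
    adjacent_distances: np.ndarray
    mean_carbon_distance: float  # mean water -> nearest side-chain carbon, A
    ring_closure: bool

    @property
    def n_waters(self) -> int:
        return len(self.water_ids)

    @property
    def mean_adjacent_distance(self) -> float:
        return (
            float(self.adjacent_distances.mean())
            if len(self.adjacent_distances)
            else float("nan")
        )


# ---------------------------------------------------------------------------
# network construction and statistics
# ---------------------------------------------------------------------------

def build_network(
    waters: WaterSet, cutoff: float = DEFAULT_NETWORK_CUTOFF
) -> WaterNetwork:
    """Connect waters within ``cutoff`` (closed interval) of each other."""
    if len(waters) < 2:
        raise ValueError("at least 2 waters are required to build a network")
    d = cdist(waters.coords, waters.coords)
    edges = [
        (i, j, float(d[i, j]))
        for i in range(len(waters))
        for j in range(i + 1, len(waters))
        if d[i, j] <= cutoff
    ]
    return WaterNetwork(waters, cutoff, edges)


def network_stats(net: WaterNetwork) -> NetworkStats:
    """Distances over all edges; angles over all connected triples i-j-k.

    The angle of a triple is measured at the middle water j, for every
    unordered pair of edges (i-j), (j-k) sharing j.
    """
    if not net.edges:
        raise ValueError("network has no edges")
    coords = net.waters.coords
    dists = np.array([d for _, _, d in net.edges])
    g = net.graph
    angles = []
    for j in g.nodes:
        nbrs = sorted(g.neighbors(j))
        for i, k in combinations(nbrs, 2):
            u = coords[i] - coords[j]
            v = coords[k] - coords[j]
            cosang = float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
            angles.append(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    comp_sizes = [len(c) for c in net.components()]
    branch = sum(1 for n in g.nodes if g.degree[n] >= 3)
    return NetworkStats(dists, np.array(angles), comp_sizes, branch)


# ---------------------------------------------------------------------------
# linear trough
# ---------------------------------------------------------------------------

def _tls_line(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares line: centroid and unit direction."""
    c = pts.mean(axis=0)
    _, _, Vt = np.linalg.svd(pts - c)
    return c, Vt[0]


def _line_residuals(pts: np.ndarray, c: np.ndarray, u: np.ndarray) -> np.ndarray:
    d = pts - c
    proj = np.outer(d @ u, u)
    return np.linalg.norm(d - proj, axis=1)


def _trough_from_subset(waters: WaterSet, subset: tuple[int, ...]) -> LinearTrough:
    pts = waters.coords[list(subset)]
    c, u = _tls_line(pts)
    resid = _line_residuals(pts, c, u)
    t = (pts - c) @ u
    order = np.argsort(t)
    ordered = [subset[i] for i in order]
    coords = waters.coords[ordered]
    intervals = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    span = float(np.linalg.norm(coords[-1] - coords[0]))
    return LinearTrough(
        water_ids=[waters.ids[i] for i in ordered],
        coords=coords,
        intervals=intervals,
        span=span,
        residual=float(resid.max()),
    )


def _candidate_waters(
    waters: WaterSet,
    anchor_atoms: list[Atom],
    contact_cutoff: float,
) -> list[int]:
    if not anchor_atoms:
        raise ValueError("anchor residues contributed no side-chain atoms")
    tree = cKDTree(np.array([a.xyz for a in anchor_atoms]))
    d, _ = tree.query(waters.coords)
    return [i for i in range(len(waters)) if d[i] <= contact_cutoff]


def find_linear_trough(
    waters: WaterSet,
    anchor_atoms: list[Atom] | None = None,
    line_tolerance: float = 1.0,
    contact_cutoff: float = 3.5,
    exhaustive_limit: int = 12,
) -> LinearTrough:
    """Largest near-collinear water subset along a hydrophobic trough.

    Candidate waters lie within ``contact_cutoff`` of any anchor side-chain
    atom (all waters when ``anchor_atoms`` is None).  Among candidates, the
    largest subset of size >= 3 whose perpendicular total-least-squares
    residuals are all <= ``line_tolerance`` is returned, ordered by
    projection along the fitted line.  Ties are broken by minimal total
    residual, then lexicographic water ids.  Exhaustive subset search up to
    ``exhaustive_limit`` candidates; a pair-seeded inlier search above.

    Returns a ``found=False`` result (not an exception) when no subset of
    size >= 3 is sufficiently collinear.
    """
    if anchor_atoms is not None:
        cand = _candidate_waters(waters, anchor_atoms, contact_cutoff)
    else:
        cand = list(range(len(waters)))
    none = LinearTrough([], np.zeros((0, 3)), np.array([]), 0.0, 0.0, found=False)
    if len(cand) < 3:
        return none

    def admissible(subset: tuple[int, ...]) -> LinearTrough | None:
        tr = _trough_from_subset(waters, subset)
        return tr if tr.residual <= line_tolerance else None

    best: LinearTrough | None = None

    def better(a: LinearTrough, b: LinearTrough | None) -> bool:
        if b is None:
            return True
        if a.n_waters != b.n_waters:
            return a.n_waters > b.n_waters
        ra = _line_residuals(a.coords, *_tls_line(a.coords)).sum()
        rb = _line_residuals(b.coords, *_tls_line(b.coords)).sum()
        if abs(ra - rb) > 1e-12:
            return ra < rb
        return a.water_ids < b.water_ids

    if len(cand) <= exhaustive_limit:
        for size in range(len(cand), 2, -1):
            for subset in combinations(cand, size):
                tr = admissible(subset)
                if tr is not None and better(tr, best):
                    best = tr
            if best is not None:
                break
    else:
        # pair-seeded inlier growth: each candidate pair defines a trial line
        pts = waters.coords
        for i, j in combinations(cand, 2):
            u = pts[j] - pts[i]
            n = np.linalg.norm(u)
            if n < 1e-9:
                continue
            u = u / n
            resid = _line_residuals(pts[cand], pts[i], u)
            inliers = tuple(c for c, r in zip(cand, resid) if r <= line_tolerance)
            if len(inliers) < 3:
                continue
            tr = admissible(inliers)
            if tr is not None and better(tr, best):
                best = tr
    return best if best is not None else none


# ---------------------------------------------------------------------------
# hydration ring
# ---------------------------------------------------------------------------

_SIDECHAIN_SKIP = {"N", "CA", "C", "O", "OXT"}


def side_chain_carbons(structure: Structure, chain: str, residue_number: int) -> list[Atom]:
    """Side-chain carbon atoms of one residue (backbone excluded)."""
    return [
        a
        for a in structure.select(chain=chain, residue_numbers=[residue_number])
        if a.element == "C" and a.atom_name not in _SIDECHAIN_SKIP
    ]


def _longest_cycle(g: nx.Graph, limit: int = 15) -> list[int] | None:
    nodes = list(g.nodes)
    if len(nodes) > limit:
        # greedy fallback: longest cycle through the cycle basis
        basis = nx.cycle_basis(g)
        return max(basis, key=len) if basis else None
    best: list[int] | None = None
    for cycle in nx.simple_cycles(g):
        if len(cycle) >= 4 and (best is None or len(cycle) > len(best)):
            best = cycle
    return best


def _longest_path(g: nx.Graph) -> list[int]:
    # exhaustive DFS; intended for the motif scale (<= ~15 nodes)
    best: list[int] = []

    def dfs(node: int, path: list[int], seen: set[int]) -> None:
        nonlocal best
        if len(path) > len(best):
            best = list(path)
        for nb in g.neighbors(node):
            if nb not in seen:
                seen.add(nb)
                path.append(nb)
                dfs(nb, path, seen)
                path.pop()
                seen.discard(nb)

    for start in g.nodes:
        dfs(start, [start], {start})
    return best


def find_hydration_ring(
    waters: WaterSet,
    carbon_atoms: list[Atom],
    ring_cutoff: float = DEFAULT_RING_CUTOFF,
    contact_cutoff: float = 4.5,
) -> HydrationRing:
    """Largest water ring clamped around a hydrophobic side chain.

    Candidates are waters within ``contact_cutoff`` of any of the given
    side-chain carbon atoms.  On the candidate graph with edges at
    ``ring_cutoff``, the largest simple cycle (length >= 4) is returned,
    with adjacent distances and the mean water-to-nearest-carbon distance.
    With no cycle, the longest open chain is returned flagged
    ``ring_closure=False``.
    """
    if not carbon_atoms:
        raise ValueError("residue has no side-chain carbon atoms")
    cxyz = np.array([a.xyz for a in carbon_atoms])
    tree = cKDTree(cxyz)
    dmin, _ = tree.query(waters.coords)
    cand = [i for i in range(len(waters)) if dmin[i] <= contact_cutoff]
    if len(cand) < 2:
        return HydrationRing([], np.zeros((0, 3)), np.array([]), float("nan"), False)

    pts = waters.coords[cand]
    d = cdist(pts, pts)
    g = nx.Graph()
    g.add_nodes_from(range(len(cand)))
    for i in range(len(cand)):
        for j in range(i + 1, len(cand)):
            if d[i, j] <= ring_cutoff:
                g.add_edge(i, j)

    cycle = _longest_cycle(g)
    if cycle is not None:
        order = cycle
        closed = True
    else:
        order = _longest_path(g)
        closed = False
    idx = [cand[i] for i in order]
    coords = waters.coords[idx]
    if closed:
        nxt = np.roll(coords, -1, axis=0)
        adj = np.linalg.norm(nxt - coords, axis=1)
    else:
        adj = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    dmin_sel, _ = tree.query(coords)
    return HydrationRing(
        water_ids=[waters.ids[i] for i in idx],
        coords=coords,
        adjacent_distances=adj,
        mean_carbon_distance=float(dmin_sel.mean()) if len(idx) else float("nan"),
        ring_closure=closed,
    )
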