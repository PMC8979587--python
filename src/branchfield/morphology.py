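"""Neuronal morphology: tree data model, SWC I/O, on-path metrics and branch complexity.

A morphology is a rooted tree of tapered-cylinder segments.  Every node except
the root defines an *edge* from its parent to itself; sites (recording
locations) live on edges at a fractional offset.  The central morphometric is
the branch complexity

    Omega(lambda) = integral_0^inf beta(x) * exp(-x / lambda) dx

where beta(x) counts the distinct dendritic points at on-path (geodesic)
distance x from the site.  beta is piecewise constant -- it starts at 2 (one
point on each side of the site), gains 1 after every branch point and loses 1
at every terminal -- so the integral has an exact closed form per interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Node",
    "Morphology",
    "Site",
    "BranchProfile",
    "SWCError",
    "read_swc",
    "write_swc",
    "site_metrics",
    "branch_profile",
    "branch_complexity",
    "cut_subtrees",
    "match_site_pairs",
]

REGIONS = ("soma", "AIS", "axon", "dendrite")

# SWC structure-type codes.  1/2/3 are the standard assignments; the AIS has
# no standard code, so it is written with a declared custom code (default 7).
SWC_CODE = {"soma": 1, "axon": 2, "dendrite": 3}
DEFAULT_AIS_CODE = 7


class SWCError(ValueError):
    """Malformed SWC content (bad row, multiple roots, cycles, orphans)."""


@dataclass(frozen=True)
class Node:
    id: int
    parent_id: int | None
    position: np.ndarray  # (3,) in um
    radius: float  # um
    region: str

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.position.shape != (3,):
            raise ValueError("node position must be a 3-vector")
        if not self.radius > 0:
            raise ValueError(f"node {self.id}: radius must be positive")
        if self.region not in REGIONS:
            raise ValueError(f"node {self.id}: unknown region {self.region!r}")


class Morphology:
    """Rooted tree of nodes.  Exactly one root; parents precede children."""

    def __init__(self, nodes: Iterable[Node]):
        self.nodes: dict[int, Node] = {}
        roots = []
        for n in nodes:
            if n.id in self.nodes:
                raise ValueError(f"duplicate node id {n.id}")
            self.nodes[n.id] = n
            if n.parent_id is None:
                roots.append(n.id)
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        self.root_id = roots[0]
        self._children: dict[int, list[int]] = {i: [] for i in self.nodes}
        for n in self.nodes.values():
            if n.parent_id is not None:
                if n.parent_id not in self.nodes:
                    raise ValueError(f"node {n.id}: missing parent {n.parent_id}")
                self._children[n.parent_id].append(n.id)
        self._check_connected_acyclic()

    def _check_connected_acyclic(self):
        seen = set()
        stack = [self.root_id]
        while stack:
            i = stack.pop()
            if i in seen:
                raise ValueError("cycle detected in morphology")
            seen.add(i)
            stack.extend(self._children[i])
        if len(seen) != len(self.nodes):
            raise ValueError("morphology is not connected to the root")

    # -- topology ---------------------------------------------------------
    def children(self, node_id: int) -> list[int]:
        return list(self._children[node_id])

    def edge_ids(self) -> list[int]:
        """Edges are identified by their child node id."""
        return [i for i in self.topological_order() if i != self.root_id]

    def topological_order(self) -> list[int]:
        order, stack = [], [self.root_id]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(reversed(self._children[i]))
        return order

    def edge_length(self, edge_id: int) -> float:
        n = self.nodes[edge_id]
        p = self.nodes[n.parent_id]
        return float(np.linalg.norm(n.position - p.position))

    def edge_length_2d(self, edge_id: int) -> float:
        """Planar (max-projection) length, ignoring the z axis."""
        n = self.nodes[edge_id]
        p = self.nodes[n.parent_id]
        return float(np.linalg.norm((n.position - p.position)[:2]))

    def path_to_root(self, node_id: int) -> list[int]:
        """Edge ids (child node ids) from `node_id` up to the root."""
        path = []
        while node_id != self.root_id:
            path.append(node_id)
            node_id = self.nodes[node_id].parent_id
        return path

    def subtree(self, node_id: int) -> set[int]:
        out, stack = set(), [node_id]
        while stack:
            i = stack.pop()
            out.add(i)
            stack.extend(self._children[i])
        return out

    def total_length(self, regions: Sequence[str] = ("dendrite",)) -> float:
        return sum(
            self.edge_length(e)
            for e in self.edge_ids()
            if self.nodes[e].region in regions
        )

    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class Site:
    """A point on an edge of a morphology.

    ``edge_id`` is the child-node id of the edge; ``offset`` runs from 0 at
    the parent node to 1 at the child node.  A site that falls exactly on a
    bifurcation node is represented on the *parent* edge at offset 1, which
    keeps beta(0) = 2.
    """

    morphology: Morphology
    edge_id: int
    offset: float
    cell_id: str = "cell0"
    label: str = ""

    def __post_init__(self):
        if not 0.0 <= self.offset <= 1.0:
            raise ValueError("site offset must lie in [0, 1]")
        if self.edge_id == self.morphology.root_id or self.edge_id not in self.morphology.nodes:
            raise ValueError(f"edge {self.edge_id} does not exist")

    @property
    def position(self) -> np.ndarray:
        n = self.morphology.nodes[self.edge_id]
        p = self.morphology.nodes[n.parent_id]
        return p.position + self.offset * (n.position - p.position)

    @property
    def distance_to_soma(self) -> float:
        return site_metrics(self)[0]

    @property
    def branch_order(self) -> int:
        return site_metrics(self)[1]


@dataclass(frozen=True)
class BranchProfile:
    """Piecewise-constant branch count beta(x) versus on-path distance.

    ``breakpoints`` has length k+1 (starting at 0), ``counts`` length k;
    beta(x) = counts[i] on [breakpoints[i], breakpoints[i+1]).  Beyond the
    last breakpoint beta = 0.
    """

    breakpoints: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        bp = np.asarray(self.breakpoints, dtype=float)
        ct = np.asarray(self.counts)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "counts", ct)
        if bp.ndim != 1 or ct.ndim != 1 or len(bp) != len(ct) + 1:
            raise ValueError("breakpoints must be one longer than counts")
        if np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must be strictly ascending")
        if np.any(ct < 0):
            raise ValueError("branch counts must be non-negative")

    def beta(self, x):
        """Evaluate beta at x (scalar or array)."""
        x = np.asarray(x, dtype=float)
        idx = np.searchsorted(self.breakpoints, x, side="right") - 1
        out = np.where(
            (idx >= 0) & (idx < len(self.counts)),
            np.take(self.counts, np.clip(idx, 0, len(self.counts) - 1)),
            0,
        )
        return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def read_swc(path, ais_code: int = DEFAULT_AIS_CODE) -> Morphology:
    """Read a standard 7-column SWC file.

    Type codes: 1 soma, 2 axon, 3 dendrite (apical type 4 is also accepted as
    dendrite), and ``ais_code`` for the axon initial segment.
    """
    code_to_region = {1: "soma", 2: "axon", 3: "dendrite", 4: "dendrite", ais_code: "AIS"}
    nodes = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCError(f"line {lineno}: expected 7 columns, got {len(parts)}")
            try:
                nid, code = int(parts[0]), int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                pid = int(parts[6])
            except ValueError as exc:
                raise SWCError(f"line {lineno}: {exc}") from None
            if code not in code_to_region:
                raise SWCError(f"line {lineno}: unknown SWC type code {code}")
            if r <= 0:
                raise SWCError(f"line {lineno}: non-positive radius")
            nodes.append(
                Node(nid, None if pid == -1 else pid, np.array([x, y, z]), r,
                     code_to_region[code])
            )
    if not nodes:
        raise SWCError("empty SWC file")
    try:
        return Morphology(nodes)
    except ValueError as exc:
        raise SWCError(str(exc)) from None


def write_swc(morph: Morphology, path, ais_code: int = DEFAULT_AIS_CODE) -> None:
    """Write canonicalized SWC: ids renumbered 1..N in parent-first order."""
    region_to_code = {"soma": 1, "axon": 2, "dendrite": 3, "AIS": ais_code}
    order = morph.topological_order()
    newid = {old: i + 1 for i, old in enumerate(order)}
    with open(path, "w") as fh:
        for old in order:
            n = morph.nodes[old]
            pid = -1 if n.parent_id is None else newid[n.parent_id]
            x, y, z = n.position
            fh.write(
                f"{newid[old]} {region_to_code[n.region]} "
                f"{x:.6f} {y:.6f} {z:.6f} {n.radius:.6f} {pid}\n"
            )


# ---------------------------------------------------------------------------
# On-path metrics
# ---------------------------------------------------------------------------

def site_metrics(site: Site, planar: bool = False) -> tuple[float, int]:
    """On-path distance to the soma (um) and branch order of a site.

    Branch order counts bifurcation nodes strictly between the soma and the
    site.  ``planar=True`` measures edge lengths from the xy projection only,
    mimicking distance measurements made on maximum-intensity projections.
    """
    m = site.morphology
    length = m.edge_length_2d if planar else m.edge_length
    edge = site.edge_id
    dist = site.offset * length(edge)
    order = 0
    node = m.nodes[edge].parent_id
    while node != m.root_id:
        if len(m.children(node)) >= 2:
            order += 1
        dist += length(node)
        node = m.nodes[node].parent_id
    return float(dist), order


def _site_intervals(site: Site, cross_soma: bool = True,
                    include_axon: bool = False) -> list[tuple[float, float]]:
    """Distance intervals [a, b) covered by each edge, measured from the site.

    In a tree every edge is reached through exactly one of its endpoints, so
    each edge away from the site's own contributes one interval; the site's
    own edge contributes two (one per direction).
    """
    m = site.morphology
    if m.nodes[site.edge_id].region != "dendrite":
        raise ValueError("site must lie on a dendritic edge")
    excluded_regions = set() if include_axon else {"axon", "AIS"}

    def traversable(edge_id: int) -> bool:
        return m.nodes[edge_id].region not in excluded_regions

    def countable(edge_id: int) -> bool:
        # beta counts dendritic membrane; soma edges carry distance only
        region = m.nodes[edge_id].region
        return region == "dendrite" or (include_axon and region in ("axon", "AIS"))

    L = m.edge_length(site.edge_id)
    parent = m.nodes[site.edge_id].parent_id
    child = site.edge_id

    # node distances from the site, by DFS over the (undirected) node graph
    dist: dict[int, float] = {parent: site.offset * L, child: (1.0 - site.offset) * L}
    stack: list[int] = [parent, child]

    intervals: list[tuple[float, float]] = []
    if site.offset > 0:
        intervals.append((0.0, site.offset * L))
    if site.offset < 1:
        intervals.append((0.0, (1.0 - site.offset) * L))

    while stack:
        u = stack.pop()
        if not cross_soma and m.nodes[u].region == "soma":
            continue
        neighbours = m.children(u)
        pu = m.nodes[u].parent_id
        if pu is not None:
            neighbours = neighbours + [pu]
        for v in neighbours:
            if v in dist:
                continue
            # the edge between u and v is identified by the child node
            eid = v if m.nodes[v].parent_id == u else u
            if eid == site.edge_id or not traversable(eid):
                continue
            le = m.edge_length(eid)
            dist[v] = dist[u] + le
            if countable(eid):
                intervals.append((dist[u], dist[u] + le))
            stack.append(v)
    return intervals


def branch_profile(site: Site, cross_soma: bool = True,
                   include_axon: bool = False) -> BranchProfile:
    """Branch count beta(x) at every on-path distance x from the site.

    Traversal runs in both directions from the site; by default it crosses
    the soma into all reachable neurites but never enters axonal or AIS
    segments.
    """
    intervals = _site_intervals(site, cross_soma=cross_soma, include_axon=include_axon)
    if not intervals:
        raise ValueError("site has no traversable neighbourhood")
    # zero-length edges contribute nothing
    intervals = [(a, b) for a, b in intervals if b > a]
    points = np.unique(np.concatenate([[0.0], [e for iv in intervals for e in iv]]))
    counts = np.zeros(len(points) - 1, dtype=int)
    for a, b in intervals:
        i0 = np.searchsorted(points, a)
        i1 = np.searchsorted(points, b)
        counts[i0:i1] += 1
    # merge adjacent intervals with equal counts
    keep = np.ones(len(counts), dtype=bool)
    keep[1:] = counts[1:] != counts[:-1]
    bp = np.concatenate([points[:-1][keep], [points[-1]]])
    return BranchProfile(bp, counts[keep])


def branch_complexity(site: Site | BranchProfile, lambdas=(145.0,),
                      cross_soma: bool = True, include_axon: bool = False):
    """Branch complexity Omega per length constant (um of discounted length).

    Omega(lambda) = sum_i beta_i * lambda * (exp(-x_i/lambda) - exp(-x_{i+1}/lambda)),
    the exact integral of beta(x) e^{-x/lambda} over the finite tree.  Returns
    a float for a scalar lambda, else a dict {lambda: Omega}.
    """
    scalar = np.isscalar(lambdas)
    lams = [float(lambdas)] if scalar else [float(v) for v in lambdas]
    if any(l <= 0 for l in lams):
        raise ValueError("length constant lambda must be positive")
    prof = site if isinstance(site, BranchProfile) else branch_profile(
        site, cross_soma=cross_soma, include_axon=include_axon)
    x0 = prof.breakpoints[:-1]
    x1 = prof.breakpoints[1:]
    out = {}
    for lam in lams:
        terms = prof.counts * lam * (np.exp(-x0 / lam) - np.exp(-x1 / lam))
        out[lam] = float(terms.sum())
    return out[lams[0]] if scalar else out


# ---------------------------------------------------------------------------
# Tree editing
# ---------------------------------------------------------------------------

def cut_subtrees(morph: Morphology, edges_to_remove: Iterable[int],
                 protected_sites: Sequence[Site] = ()) -> Morphology:
    """Remove whole subtrees rooted at the child node of each listed edge.

    Refuses to cut an edge that lies on the soma path of any protected site
    (which would disconnect or delete the site).
    """
    edges_to_remove = set(edges_to_remove)
    for e in edges_to_remove:
        if e not in morph.nodes or e == morph.root_id:
            raise ValueError(f"edge {e} does not exist")
    for s in protected_sites:
        on_path = set(s.morphology.path_to_root(s.edge_id))
        bad = on_path & edges_to_remove
        if bad:
            raise ValueError(
                f"refusing to cut edge(s) {sorted(bad)} on the soma path of a protected site")
    removed: set[int] = set()
    for e in edges_to_remove:
        removed |= morph.subtree(e)
    kept = [n for i, n in morph.nodes.items() if i not in removed]
    return Morphology(kept)


def remap_site(site: Site, new_morph: Morphology) -> Site:
    """The same physical site on an edited copy of its morphology."""
    return Site(new_morph, site.edge_id, site.offset, site.cell_id, site.label)


# ---------------------------------------------------------------------------
# Pair matching
# ---------------------------------------------------------------------------

def _on_distinct_branches(a: Site, b: Site) -> bool:
    """True when neither site lies on the other's soma path (and edges differ)."""
    if a.edge_id == b.edge_id:
        return False
    path_a = set(a.morphology.path_to_root(a.edge_id))
    path_b = set(b.morphology.path_to_root(b.edge_id))
    return a.edge_id not in path_b and b.edge_id not in path_a


def match_site_pairs(sites: Sequence[Site], annotations: Sequence[float],
                     max_relative_distance: float = 20.0) -> list[tuple[int, int]]:
    """Within-cell, distance-matched site pairs on distinct branches.

    Returns index pairs (i, j) into ``sites`` with |d_i - d_j| below the
    threshold, ordered so the first member carries the larger annotation
    (e.g. the larger Omega or the larger bAP-evoked calcium transient).
    """
    if len(sites) != len(annotations):
        raise ValueError("sites and annotations must have equal length")
    dists = [site_metrics(s)[0] for s in sites]
    pairs = []
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            if sites[i].cell_id != sites[j].cell_id:
                continue
            if abs(dists[i] - dists[j]) >= max_relative_distance:
                continue
            if not _on_distinct_branches(sites[i], sites[j]):
                continue
            hi, lo = (i, j) if annotations[i] >= annotations[j] else (j, i)
            pairs.append((hi, lo))
    return pairs
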