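"""Zone neighbourhood structures.

A :class:`ZoneGraph` records the administrative zones of a study region
together with an undirected contiguity (or k-nearest-neighbour)
relation and, optionally, zone centroid coordinates.  It is the single
source of the Markov-random-field penalty and of the spatial weights
used by Moran's I, and it fixes the row/column order of every matrix
derived from it.

Graphs are read and written in a plain-text ``.gra`` adjacency format:
the first line holds the number of zones N, followed by one logical
record per zone with the zone label, its neighbour count, and its
neighbour references.  By default neighbour references are zone
*labels*; a strict positional dialect (1-based indices into the zone
list, as used by some legacy tools) is available via
``positional=True``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ZoneGraph",
    "GraphFormatError",
    "read_graph",
    "write_graph",
    "read_centroids",
    "write_centroids",
    "knn_graph",
    "validate_graph",
]


class GraphFormatError(ValueError):
    """Raised when a graph file violates the .gra dialect."""


@dataclass(frozen=True)
class ZoneGraph:
    """Undirected zone adjacency with a fixed zone order.

    Parameters
    ----------
    zone_ids
        Ordered, unique zone labels.  The order defines the row order
        of the adjacency matrix, the MRF penalty and spatial weights.
    edges
        Unordered zone-label pairs; stored as a frozenset of frozensets
        internally but accepted as any iterable of 2-tuples.
    centroids
        Optional mapping zone label -> (longitude, latitude) in degrees.
    """

    zone_ids: tuple
    edges: frozenset = field(default_factory=frozenset)
    centroids: dict | None = None

    def __post_init__(self):
        zone_ids = tuple(self.zone_ids)
        if len(set(zone_ids)) != len(zone_ids):
            raise ValueError("zone_ids must be unique")
        known = set(zone_ids)
        norm = set()
        for e in self.edges:
            a, b = tuple(e)
            if a == b:
                raise ValueError(f"self-edge on zone {a!r}")
            if a not in known or b not in known:
                raise ValueError(f"edge {a!r}-{b!r} references unknown zone")
            norm.add(frozenset((a, b)))
        if self.centroids is not None:
            for z in self.centroids:
                if z not in known:
                    raise ValueError(f"centroid for unknown zone {z!r}")
        object.__setattr__(self, "zone_ids", zone_ids)
        object.__setattr__(self, "edges", frozenset(norm))

    @property
    def n_zones(self) -> int:
        return len(self.zone_ids)

    def index(self) -> dict:
        """Zone label -> position in ``zone_ids``."""
        return {z: i for i, z in enumerate(self.zone_ids)}

    def neighbors(self, zone) -> list:
        """Neighbours of ``zone`` in zone order."""
        nb = set()
        for e in self.edges:
            a, b = tuple(e)
            if a == zone:
                nb.add(b)
            elif b == zone:
                nb.add(a)
        order = self.index()
        return sorted(nb, key=order.__getitem__)

    def degrees(self) -> np.ndarray:
        """Degree of every zone, in zone order."""
        idx = self.index()
        deg = np.zeros(self.n_zones, dtype=int)
        for e in self.edges:
            a, b = tuple(e)
            deg[idx[a]] += 1
            deg[idx[b]] += 1
        return deg

    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix in zone order."""
        idx = self.index()
        A = np.zeros((self.n_zones, self.n_zones))
        for e in self.edges:
            i, j = (idx[z] for z in tuple(e))
            A[i, j] = A[j, i] = 1.0
        return A

    def centroid_array(self) -> np.ndarray:
        """(n_zones, 2) array of (lon, lat) in zone order."""
        if self.centroids is None:
            raise ValueError("graph carries no centroids")
        missing = [z for z in self.zone_ids if z not in self.centroids]
        if missing:
            raise ValueError(f"missing centroids for zones {missing}")
        return np.array([self.centroids[z] for z in self.zone_ids], dtype=float)


def read_graph(path, positional: bool = False) -> ZoneGraph:
    """Read a ``.gra`` adjacency file.

    The dialect is: line 1 = number of zones N; then for each zone
    three logical tokens (whitespace/newline separated): zone label,
    neighbour count k, then k neighbour references.  References are
    zone labels by default, or 1-based zone positions when
    ``positional`` is true.  Neighbour lists must be mutually
    consistent (if A lists B then B must list A).
    """
    with open(path, "r", encoding="utf-8") as fh:
        tokens = fh.read().split()
    if not tokens:
        raise GraphFormatError(f"{path}: empty graph file")
    try:
        n = int(tokens[0])
    except ValueError:
        raise GraphFormatError(f"{path}: malformed count line {tokens[0]!r}") from None
    pos = 1
    zone_ids: list = []
    raw_nb: dict = {}
    for _ in range(n):
        if pos >= len(tokens):
            raise GraphFormatError(f"{path}: truncated file, expected {n} zones")
        label = tokens[pos]
        pos += 1
        if pos >= len(tokens):
            raise GraphFormatError(f"{path}: zone {label!r} missing neighbour count")
        try:
            k = int(tokens[pos])
        except ValueError:
            raise GraphFormatError(
                f"{path}: zone {label!r} has malformed neighbour count {tokens[pos]!r}"
            ) from None
        pos += 1
        if k < 0 or pos + k > len(tokens):
            raise GraphFormatError(f"{path}: zone {label!r} neighbour list truncated")
        raw_nb[label] = tokens[pos : pos + k]
        pos += k
        zone_ids.append(label)
    if pos != len(tokens):
        raise GraphFormatError(f"{path}: trailing tokens after {n} zones")
    if len(set(zone_ids)) != n:
        raise GraphFormatError(f"{path}: duplicate zone labels")

    neighbours: dict = {}
    for z, refs in raw_nb.items():
        out = []
        for r in refs:
            if positional:
                try:
                    j = int(r)
                except ValueError:
                    raise GraphFormatError(
                        f"{path}: zone {z!r} has non-integer positional reference {r!r}"
                    ) from None
                if not 1 <= j <= n:
                    raise GraphFormatError(
                        f"{path}: zone {z!r} neighbour index {j} out of range 1..{n}"
                    )
                out.append(zone_ids[j - 1])
            else:
                if r not in raw_nb:
                    raise GraphFormatError(
                        f"{path}: zone {z!r} lists unknown neighbour {r!r}"
                    )
                out.append(r)
        neighbours[z] = set(out)  # deduplicate
        neighbours[z].discard(z)

    for z, nbs in neighbours.items():
        for w in nbs:
            if z not in neighbours[w]:
                raise GraphFormatError(
                    f"{path}: asymmetric adjacency: zone {z!r} lists {w!r} "
                    f"but {w!r} does not list {z!r}"
                )
    edges = {frozenset((z, w)) for z, nbs in neighbours.items() for w in nbs}
    return ZoneGraph(tuple(zone_ids), frozenset(edges))


def write_graph(g: ZoneGraph, path, positional: bool = False) -> None:
    """Write ``g`` to a ``.gra`` file re-readable by :func:`read_graph`."""
    idx = g.index()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{g.n_zones}\n")
        for z in g.zone_ids:
            nbs = g.neighbors(z)
            refs = [str(idx[w] + 1) for w in nbs] if positional else [str(w) for w in nbs]
            fh.write(" ".join([str(z), str(len(nbs))] + refs) + "\n")


def read_centroids(path) -> dict:
    """Read a centroid CSV with header ``zone,lon,lat``."""
    out = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames[:3]] != [
            "zone", "lon", "lat",
        ]:
            raise ValueError(f"{path}: expected header 'zone,lon,lat'")
        for row in reader:
            out[row["zone"]] = (float(row["lon"]), float(row["lat"]))
    return out


def write_centroids(centroids: dict, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["zone", "lon", "lat"])
        for z, (lon, lat) in centroids.items():
            w.writerow([z, repr(lon), repr(lat)])


def knn_graph(centroids: dict, k: int) -> ZoneGraph:
    """k-nearest-neighbour graph from zone centroids.

    Each zone is linked to its ``k`` nearest zones by Euclidean
    distance on raw (lon, lat); the directed selection is symmetrized
    by union, so degrees may exceed ``k``.  Distance ties are broken by
    ascending zone order (insertion order of ``centroids``).
    """
    zones = list(centroids.keys())
    n = len(zones)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} requires at least k+1={k + 1} zones, got {n}")
    coords = np.array([centroids[z] for z in zones], dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite centroid coordinates")
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    edges = set()
    for i in range(n):
        # stable sort on (distance, zone order) => ties to earlier zone
        order = np.lexsort((np.arange(n), d2[i]))
        for j in order[:k]:
            edges.add(frozenset((zones[i], zones[int(j)])))
    return ZoneGraph(tuple(zones), frozenset(edges), centroids=dict(centroids))


def validate_graph(g: ZoneGraph) -> dict:
    """Structural report: connected components, islands, degrees.

    Returns a dict with keys ``n_zones``, ``n_edges``, ``components``
    (list of zone-label lists), ``n_components``, ``islands``
    (degree-0 zones) and ``degree`` (zone -> degree).
    """
    deg = g.degrees()
    idx = g.index()
    adj: dict = {z: [] for z in g.zone_ids}
    for e in g.edges:
        a, b = tuple(e)
        adj[a].append(b)
        adj[b].append(a)
    seen: set = set()
    components = []
    for z in g.zone_ids:
        if z in seen:
            continue
        stack, comp = [z], []
        seen.add(z)
        while stack:
            u = stack.pop()
            comp.append(u)
            for w in adj[u]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        components.append(sorted(comp, key=idx.__getitem__))
    return {
        "n_zones": g.n_zones,
        "n_edges": len(g.edges),
        "components": components,
        "n_components": len(components),
        "islands": [z for z, d in zip(g.zone_ids, deg) if d == 0],
        "degree": dict(zip(g.zone_ids, (int(d) for d in deg))),
    }
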