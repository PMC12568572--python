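"""Centerline graph extraction from binary vessel masks.

The vessel mask is reduced to a one-pixel-wide medial skeleton, short spurs
are pruned, and the skeleton is traced into an undirected multigraph of
*nodes* (endpoints and bifurcations) joined by *segments* (ordered centerline
polylines with a local radius at every point, estimated from the Euclidean
distance transform of the mask).

All coordinates follow the package convention (see :mod:`retinavasc.geometry`):
pixel-centered, origin top-left, x rightward, y downward.  Segment point
arrays have shape (N, 2) ordered as (x, y).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

__all__ = [
    "Node",
    "Segment",
    "VesselGraph",
    "skeletonize",
    "build_graph",
    "stamp_graph",
]

_NEIGH = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class Node:
    id: int
    position: tuple[float, float]  # (x, y) px
    degree: int
    kind: str  # "endpoint" | "bifurcation"


@dataclass
class Segment:
    id: int
    points: np.ndarray  # (N, 2) float, (x, y) px
    radii: np.ndarray  # (N,) float px
    label: str = "unknown"  # "artery" | "vein" | "unknown"
    nodes: tuple[int, int] = (-1, -1)
    excluded: bool = False  # truncated at the frame/aperture; kept out of truth tables

    @property
    def arc_length(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))

    @property
    def chord_length(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.linalg.norm(self.points[-1] - self.points[0]))


@dataclass
class VesselGraph:
    nodes: list[Node] = field(default_factory=list)
    segments: list[Segment] = field(default_factory=list)
    # Optional generator truth, populated by the synthetic module only.
    segment_truth: dict[int, dict] = field(default_factory=dict)
    branch_truth: dict[int, dict] = field(default_factory=dict)

    def node_by_id(self, nid: int) -> Node:
        for n in self.nodes:
            if n.id == nid:
                return n
        raise KeyError(f"no node with id {nid}")

    def bifurcations(self) -> list[Node]:
        return [n for n in self.nodes if n.kind == "bifurcation"]

    def incident_segments(self, nid: int) -> list[Segment]:
        return [s for s in self.segments if nid in s.nodes]

    def validate(self) -> None:
        """Check node/segment incidence consistency (handshake identity)."""
        ids = {n.id for n in self.nodes}
        if len(ids) != len(self.nodes):
            raise ValueError("duplicate node ids")
        end_count: dict[int, int] = {i: 0 for i in ids}
        for s in self.segments:
            for nid in s.nodes:
                if nid not in ids:
                    raise ValueError(f"segment {s.id} references unknown node {nid}")
                end_count[nid] += 1
        for n in self.nodes:
            if end_count[n.id] != n.degree:
                raise ValueError(
                    f"node {n.id}: degree {n.degree} != incident segment ends {end_count[n.id]}"
                )

    # ---------------------------------------------------------------- JSON IO
    def to_json(self) -> str:
        doc = {
            "nodes": [
                {
                    "id": int(n.id),
                    "position": [float(p) for p in n.position],
                    "degree": int(n.degree),
                    "kind": n.kind,
                }
                for n in self.nodes
            ],
            "segments": [
                {
                    "id": s.id,
                    "points": np.asarray(s.points, dtype=float).tolist(),
                    "radii": np.asarray(s.radii, dtype=float).tolist(),
                    "label": s.label,
                    "nodes": [int(n) for n in s.nodes],
                    "excluded": bool(s.excluded),
                }
                for s in self.segments
            ],
            "segment_truth": {str(k): v for k, v in self.segment_truth.items()},
            "branch_truth": {str(k): v for k, v in self.branch_truth.items()},
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "VesselGraph":
        doc = json.loads(text)
        g = cls()
        g.nodes = [
            Node(d["id"], tuple(d["position"]), d["degree"], d["kind"]) for d in doc["nodes"]
        ]
        g.segments = [
            Segment(
                d["id"],
                np.asarray(d["points"], dtype=float).reshape(-1, 2),
                np.asarray(d["radii"], dtype=float),
                d["label"],
                tuple(d["nodes"]),
                d.get("excluded", False),
            )
            for d in doc["segments"]
        ]
        g.segment_truth = {int(k): v for k, v in doc.get("segment_truth", {}).items()}
        g.branch_truth = {int(k): v for k, v in doc.get("branch_truth", {}).items()}
        return g


# -------------------------------------------------------------- skeletonize


def _neighbor_count(skel: np.ndarray) -> np.ndarray:
    k = np.ones((3, 3), dtype=int)
    k[1, 1] = 0
    return ndimage.convolve(skel.astype(int), k, mode="constant")


def skeletonize(mask: np.ndarray, spur_length: int = 5) -> np.ndarray:
    """Medial skeleton of a binary mask with short-spur pruning.

    Spurs (endpoint branches) shorter than ``spur_length`` pixels are removed
    iteratively; pruning preserves topology elsewhere.
    """
    skel = _sk_skeletonize(mask.astype(bool))
    if spur_length <= 0:
        return skel
    for _ in range(8):  # a few passes; spurs can cascade
        removed = _prune_pass(skel, spur_length)
        if not removed:
            break
    return skel


def _prune_pass(skel: np.ndarray, spur_length: int) -> bool:
    nc = _neighbor_count(skel)
    endpoints = np.argwhere(skel & (nc == 1))
    removed_any = False
    for ey, ex in endpoints:
        if not skel[ey, ex]:
            continue
        path = [(ey, ex)]
        prev = None
        cur = (ey, ex)
        hit_junction = False
        while len(path) <= spur_length:
            nxt = None
            for dy, dx in _NEIGH:
                y, x = cur[0] + dy, cur[1] + dx
                if 0 <= y < skel.shape[0] and 0 <= x < skel.shape[1] and skel[y, x]:
                    if (y, x) != prev and (y, x) not in path:
                        if nc[y, x] >= 3:
                            hit_junction = True
                            nxt = None
                            break
                        nxt = (y, x)
            if hit_junction or nxt is None:
                break
            path.append(nxt)
            prev, cur = cur, nxt
        if hit_junction and len(path) <= spur_length:
            for y, x in path:
                skel[y, x] = False
            removed_any = True
    return removed_any


# ------------------------------------------------- sub-pixel refinement


def _bilinear(arr: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of arr at (x, y) points."""
    h, w = arr.shape
    x = np.clip(pts[:, 0], 0.0, w - 1.001)
    y = np.clip(pts[:, 1], 0.0, h - 1.001)
    x0 = np.floor(x).astype(int)
    y0 = np.floor(y).astype(int)
    fx = x - x0
    fy = y - y0
    return (
        arr[y0, x0] * (1 - fx) * (1 - fy)
        + arr[y0, x0 + 1] * fx * (1 - fy)
        + arr[y0 + 1, x0] * (1 - fx) * fy
        + arr[y0 + 1, x0 + 1] * fx * fy
    )


def _refine_centerline(pts: np.ndarray, edt: np.ndarray, h: float = 0.75) -> np.ndarray:
    """Shift raster centerline points to the sub-pixel medial ridge.

    The Euclidean distance transform peaks on the medial axis; each point
    moves along the local normal to the vertex of the parabola through the
    EDT sampled at offsets {-h, 0, +h}.  Offsets are clamped to 0.45 px so
    points round back to their source pixels (8-connectivity preserved).
    """
    n = len(pts)
    if n < 3:
        return pts
    out = pts.copy()
    tang = np.empty_like(pts)
    tang[1:-1] = pts[2:] - pts[:-2]
    tang[0] = pts[1] - pts[0]
    tang[-1] = pts[-1] - pts[-2]
    norms = np.linalg.norm(tang, axis=1)
    norms[norms == 0] = 1.0
    tang /= norms[:, None]
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])
    e0 = _bilinear(edt, pts)
    em = _bilinear(edt, pts - h * normal)
    ep = _bilinear(edt, pts + h * normal)
    denom = em - 2.0 * e0 + ep
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(denom < -1e-9, 0.5 * h * (em - ep) / denom, 0.0)
    delta = np.clip(delta, -0.45, 0.45)
    out += delta[:, None] * normal
    return out


# --------------------------------------------------------------- build_graph


def build_graph(
    skeleton: np.ndarray,
    mask: np.ndarray,
    artery_mask: np.ndarray | None = None,
    vein_mask: np.ndarray | None = None,
    stub_length: float = 6.0,
) -> VesselGraph:
    """Trace a skeleton into a :class:`VesselGraph`.

    Nodes are placed at skeleton pixels with a neighbor count other than two
    (adjacent junction pixels are merged into a single node at their
    centroid); segments are the degree-2 chains between nodes.  The local
    radius at every centerline point is the Euclidean distance transform of
    ``mask`` at that point (sub-pixel refined to the medial ridge); a
    segment's artery/vein label is the majority of the label masks along
    its points.

    Wide-vessel junctions often skeletonize into two nearby branch nodes
    joined by a stub; junction-to-junction segments shorter than
    ``stub_length`` px are contracted into a single node, and short
    self-loops are dropped, so one physical bifurcation maps to one node.

    An empty skeleton yields an empty graph.
    """
    skel = skeleton.astype(bool)
    g = VesselGraph()
    if not skel.any():
        return g

    edt = ndimage.distance_transform_edt(mask.astype(bool))
    nc = _neighbor_count(skel)
    node_pix = skel & (nc != 2)

    # isolated pixels are single-point components; drop them
    node_lab, n_nodes = ndimage.label(node_pix, structure=np.ones((3, 3), int))
    node_of_pixel: dict[tuple[int, int], int] = {}
    centroids = ndimage.center_of_mass(node_pix, node_lab, range(1, n_nodes + 1))
    for nid in range(1, n_nodes + 1):
        g.nodes.append(Node(nid - 1, (centroids[nid - 1][1], centroids[nid - 1][0]), 0, "endpoint"))
    for y, x in np.argwhere(node_pix):
        node_of_pixel[(int(y), int(x))] = int(node_lab[y, x]) - 1

    visited = np.zeros_like(skel, dtype=bool)  # visited degree-2 chain pixels
    used_starts: set[tuple[int, int, int, int]] = set()
    seg_id = 0

    def neighbors(p):
        out = []
        for dy, dx in _NEIGH:
            y, x = p[0] + dy, p[1] + dx
            if 0 <= y < skel.shape[0] and 0 <= x < skel.shape[1] and skel[y, x]:
                out.append((y, x))
        return out

    def add_segment(pix_path: list[tuple[int, int]], n0: int, n1: int):
        nonlocal seg_id
        pts = np.array([(x, y) for y, x in pix_path], dtype=float)
        pts = _refine_centerline(pts, edt)
        radii = _bilinear(edt, pts)
        label = "unknown"
        if artery_mask is not None and vein_mask is not None:
            ys = [p[0] for p in pix_path]
            xs = [p[1] for p in pix_path]
            a = int(artery_mask[ys, xs].sum())
            v = int(vein_mask[ys, xs].sum())
            if a or v:
                label = "artery" if a >= v else "vein"
        g.segments.append(Segment(seg_id, pts, radii, label, (n0, n1)))
        seg_id += 1

    # trace from every node pixel through each degree-2 neighbor
    for (y0, x0), nid0 in node_of_pixel.items():
        for y1, x1 in neighbors((y0, x0)):
            if (y1, x1) in node_of_pixel:
                # adjacent node pixels: same cluster -> nothing to trace;
                # distinct clusters -> two-pixel segment (deduplicated)
                if node_of_pixel[(y1, x1)] == nid0:
                    continue
                key = tuple(sorted([(y0, x0), (y1, x1)]))
                k = (key[0][0], key[0][1], key[1][0], key[1][1])
                if k in used_starts:
                    continue
                used_starts.add(k)
                add_segment([(y0, x0), (y1, x1)], nid0, node_of_pixel[(y1, x1)])
                continue
            if visited[y1, x1]:
                continue
            path = [(y0, x0), (y1, x1)]
            visited[y1, x1] = True
            prev, cur = (y0, x0), (y1, x1)
            end_node = None
            while True:
                nbrs = [p for p in neighbors(cur) if p != prev]
                # prefer an adjacent node pixel as terminus
                node_nbrs = [p for p in nbrs if p in node_of_pixel]
                if node_nbrs:
                    term = node_nbrs[0]
                    path.append(term)
                    end_node = node_of_pixel[term]
                    break
                nbrs = [p for p in nbrs if not visited[p[0], p[1]]]
                if not nbrs:
                    end_node = None  # open end (shouldn't happen) or cycle closure
                    break
                nxt = nbrs[0]
                path.append(nxt)
                visited[nxt[0], nxt[1]] = True
                prev, cur = cur, nxt
            if end_node is None:
                # dangling chain: terminate with a synthetic endpoint node
                ny, nx_ = path[-1]
                end_node = len(g.nodes)
                g.nodes.append(Node(end_node, (float(nx_), float(ny)), 0, "endpoint"))
            add_segment(path, nid0, end_node)

    # pure cycles with no node pixel at all: trace remaining unvisited chain pixels
    remaining = skel & ~visited & ~node_pix
    while remaining.any():
        y0, x0 = map(int, np.argwhere(remaining)[0])
        start_node = len(g.nodes)
        g.nodes.append(Node(start_node, (float(x0), float(y0)), 0, "endpoint"))
        path = [(y0, x0)]
        visited[y0, x0] = True
        prev, cur = None, (y0, x0)
        while True:
            nbrs = [p for p in neighbors(cur) if p != prev and not visited[p[0], p[1]]]
            if not nbrs:
                break
            nxt = nbrs[0]
            path.append(nxt)
            visited[nxt[0], nxt[1]] = True
            prev, cur = cur, nxt
        path.append((y0, x0))  # close the loop
        add_segment(path, start_node, start_node)
        remaining = skel & ~visited & ~node_pix

    _contract_stubs(g, stub_length)
    # finalize degrees and kinds
    deg = {n.id: 0 for n in g.nodes}
    for s in g.segments:
        deg[s.nodes[0]] += 1
        deg[s.nodes[1]] += 1
    for n in g.nodes:
        n.degree = deg[n.id]
        n.kind = "bifurcation" if n.degree >= 3 else "endpoint"
    return g


def _contract_stubs(g: VesselGraph, stub_length: float) -> None:
    """Merge junction pairs joined by short stubs; drop short self-loops."""
    if stub_length <= 0:
        return
    while True:
        deg: dict[int, int] = {n.id: 0 for n in g.nodes}
        for s in g.segments:
            deg[s.nodes[0]] += 1
            deg[s.nodes[1]] += 1
        target = None
        for s in g.segments:
            if s.arc_length >= stub_length:
                continue
            a, b = s.nodes
            if a == b:
                target = ("loop", s)
                break
            if deg[a] >= 3 and deg[b] >= 3:
                target = ("stub", s)
                break
        if target is None:
            return
        kind, s = target
        if kind == "loop":
            g.segments.remove(s)
            continue
        a, b = s.nodes
        na, nb = g.node_by_id(a), g.node_by_id(b)
        pos = (
            (na.position[0] + nb.position[0]) / 2.0,
            (na.position[1] + nb.position[1]) / 2.0,
        )
        na.position = pos
        g.segments.remove(s)
        for other in g.segments:
            n0, n1 = other.nodes
            other.nodes = (a if n0 == b else n0, a if n1 == b else n1)
        g.nodes.remove(nb)


def stamp_graph(graph: VesselGraph, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a graph back to a mask by stamping disks of the local radius.

    Used for the mask -> graph -> mask round-trip consistency check.
    """
    out = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for s in graph.segments:
        for (x, y), r in zip(s.points, s.radii):
            r = max(float(r), 0.0)
            y0, y1 = int(max(0, y - r - 1)), int(min(shape[0], y + r + 2))
            x0, x1 = int(max(0, x - r - 1)), int(min(shape[1], x + r + 2))
            if y0 >= y1 or x0 >= x1:
                continue
            sub = (yy[y0:y1, x0:x1] - y) ** 2 + (xx[y0:y1, x0:x1] - x) ** 2 <= r * r
            out[y0:y1, x0:x1] |= sub
    return out
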