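"""Skeletonization, per-pixel tagging, object labelling, and the branch graph.

A binary mitochondrial mask is thinned to a unit-width 8-connected skeleton.
Each skeleton pixel is tagged by its 8-neighbour count (endpoint = 1,
slab = 2, junction >= 3), connected skeleton objects are labelled in
raster-scan order, and the skeleton is dissected into a graph whose nodes are
merged junction-pixel clusters and endpoints and whose edges are branches —
maximal slab paths — carrying physical path lengths (orthogonal step = 1 px,
diagonal step = sqrt(2) px).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy import ndimage
from skimage.morphology import thin as _thin

from .preprocess import BinaryMask

__all__ = [
    "Tag",
    "TaggedSkeleton",
    "SkeletonNode",
    "SkeletonBranch",
    "SkeletonGraph",
    "ContractViolation",
    "skeletonize",
    "tag_and_label",
    "build_graph",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)
_SQRT2 = math.sqrt(2.0)


class ContractViolation(ValueError):
    """Input violates a stage precondition (e.g. non-thin skeleton)."""


class Tag(IntEnum):
    """Per-pixel skeleton role; values double as the debug-TIFF palette."""

    BACKGROUND = 0
    SLAB = 1
    ENDPOINT = 2
    JUNCTION = 3


@dataclass(frozen=True)
class TaggedSkeleton:
    """Per-pixel role map plus per-object label map of a thin skeleton."""

    tags: np.ndarray  # uint8 raster of Tag values
    labels: np.ndarray  # int32 raster, 0 = background, objects 1..K
    pixel_size_um: float

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())


@dataclass(frozen=True)
class SkeletonNode:
    """A graph node: one merged junction-pixel cluster, one endpoint pixel,
    or the anchor pixel of a node-free cycle."""

    node_id: int
    kind: str  # "junction" | "endpoint" | "cycle"
    pixels: tuple[tuple[int, int], ...]
    centroid: tuple[float, float]
    object_id: int


@dataclass(frozen=True)
class SkeletonBranch:
    """A maximal path between two nodes (or a node and itself for loops)."""

    branch_id: int
    node_a: int
    node_b: int
    path: tuple[tuple[int, int], ...]  # ordered pixels, termini included
    length_um: float
    object_id: int


@dataclass(frozen=True)
class SkeletonGraph:
    nodes: tuple[SkeletonNode, ...]
    branches: tuple[SkeletonBranch, ...]
    pixel_size_um: float
    n_objects: int

    def nodes_of(self, object_id: int, kind: str | None = None):
        return [
            n
            for n in self.nodes
            if n.object_id == object_id and (kind is None or n.kind == kind)
        ]

    def branches_of(self, object_id: int):
        return [b for b in self.branches if b.object_id == object_id]

    @property
    def junction_count(self) -> int:
        return sum(1 for n in self.nodes if n.kind == "junction")

    @property
    def endpoint_count(self) -> int:
        return sum(1 for n in self.nodes if n.kind == "endpoint")

    @property
    def total_length_um(self) -> float:
        return float(sum(b.length_um for b in self.branches))


_RING = ((-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1))
# adjacency between ring positions (8-connectivity within the 3x3 ring)
_RING_ADJ = [
    {i for i, q in enumerate(_RING) if q != p and max(abs(q[0] - p[0]), abs(q[1] - p[1])) <= 1}
    for p in _RING
]


def _is_simple_point(sk: np.ndarray, r: int, c: int) -> bool:
    """True if deleting (r, c) preserves local 8-connectivity (and it is not
    an endpoint), i.e. its foreground ring neighbours form one component."""
    h, w = sk.shape
    fg = [
        bool(0 <= r + dr < h and 0 <= c + dc < w and sk[r + dr, c + dc])
        for dr, dc in _RING
    ]
    idx = [i for i, f in enumerate(fg) if f]
    if len(idx) < 2:
        return False  # endpoint or isolated: deleting would change topology
    seen = {idx[0]}
    stack = [idx[0]]
    while stack:
        i = stack.pop()
        for j in _RING_ADJ[i]:
            if fg[j] and j not in seen:
                seen.add(j)
                stack.append(j)
    return len(seen) == len(idx)


def _full_blocks(sk: np.ndarray) -> np.ndarray:
    return np.argwhere(sk[:-1, :-1] & sk[1:, :-1] & sk[:-1, 1:] & sk[1:, 1:])


def _has_reducible_block(sk: np.ndarray) -> bool:
    """True if some fully foreground 2x2 block contains a deletable pixel.

    A 2x2 block whose four pixels are all topologically essential (each
    deletion would disconnect crossing arms) is irreducible and counts as
    thin; its pixels are junction-tagged and merge into one junction node.
    """
    for r, c in _full_blocks(sk):
        for dr, dc in ((0, 0), (0, 1), (1, 0), (1, 1)):
            if _is_simple_point(sk, r + dr, c + dc):
                return True
    return False


def _prune_thick_blocks(sk: np.ndarray) -> np.ndarray:
    """Delete simple points from fully foreground 2x2 blocks until none is
    reducible, preserving component and loop counts.

    Iterative thinning occasionally leaves such blocks at dense crossings;
    rarely a block is irreducible (all four pixels essential) and is kept.
    """
    sk = sk.copy()
    for _ in range(256):
        progressed = False
        for r, c in _full_blocks(sk):
            if not (sk[r, c] and sk[r + 1, c] and sk[r, c + 1] and sk[r + 1, c + 1]):
                continue  # already resolved by an earlier deletion this pass
            for dr, dc in ((0, 0), (0, 1), (1, 0), (1, 1)):
                if _is_simple_point(sk, r + dr, c + dc):
                    sk[r + dr, c + dc] = False
                    progressed = True
                    break
        if not progressed:
            return sk
    raise ContractViolation("thick-block pruning did not converge")


def _canonical_thin(px: np.ndarray) -> np.ndarray:
    """Thin in a canonical orientation so the result is exactly equivariant
    under 90-degree rotations and mirror flips.

    Iterative thinning scans the raster directionally, so thinning a rotated
    mask does not in general rotate the skeleton.  Thinning the
    lexicographically smallest of the mask's eight dihedral transforms and
    transforming back makes every count and length a true D4 invariant.
    """
    best_key = None
    best = (0, False)
    for k in range(4):
        for flip in (False, True):
            t = np.rot90(px, k)
            if flip:
                t = np.fliplr(t)
            key = (t.shape, t.tobytes())
            if best_key is None or key < best_key:
                best_key, best = key, (k, flip)
    k, flip = best
    t = np.rot90(px, k)
    if flip:
        t = np.fliplr(t)
    sk = _prune_thick_blocks(_thin(t))
    if flip:
        sk = np.fliplr(sk)
    return np.ascontiguousarray(np.rot90(sk, -k))


def skeletonize(mask: BinaryMask) -> BinaryMask:
    """Thin a binary mask to a unit-width skeleton (homotopy preserving).

    Uses iterative morphological thinning in a canonical orientation (the
    skeleton of a rotated or mirrored mask is the rotated or mirrored
    skeleton); connected-component count and loop count of the mask are
    preserved, and the result contains no fully foreground 2x2 block
    (residual thick blocks at dense crossings are reduced by simple-point
    deletion).
    """
    return BinaryMask(_canonical_thin(mask.pixels), mask.pixel_size_um, mask.valid_mask)


def _neighbor_counts(sk: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), dtype=np.uint8)
    kernel[1, 1] = 0
    counts = ndimage.convolve(sk.astype(np.uint8), kernel, mode="constant", cval=0)
    return counts * sk


def _is_thin(sk: np.ndarray) -> bool:
    return not _has_reducible_block(sk)


def tag_and_label(skeleton: BinaryMask) -> TaggedSkeleton:
    """Tag every skeleton pixel by 8-neighbour count and label objects.

    Endpoints have exactly one skeleton neighbour, slabs two, junction pixels
    three or more.  An isolated pixel (zero neighbours) is a degenerate
    single-pixel object and is tagged as an endpoint.  Labels 1..K follow
    raster-scan order of each object's first pixel.
    """
    sk = skeleton.pixels
    if not _is_thin(sk):
        raise ContractViolation(
            "skeleton is not thin: found a reducible fully foreground 2x2 block"
        )
    counts = _neighbor_counts(sk)
    tags = np.zeros(sk.shape, dtype=np.uint8)
    tags[sk & (counts <= 1)] = Tag.ENDPOINT
    tags[sk & (counts == 2)] = Tag.SLAB
    tags[sk & (counts >= 3)] = Tag.JUNCTION
    labels, _ = ndimage.label(sk, structure=_STRUCT8)
    return TaggedSkeleton(tags=tags, labels=labels.astype(np.int32), pixel_size_um=skeleton.pixel_size_um)


def _neighbors(sk: np.ndarray, r: int, c: int):
    h, w = sk.shape
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and sk[rr, cc]:
                yield rr, cc


def _path_length(path, pixel_size_um: float) -> float:
    total = 0.0
    for (r0, c0), (r1, c1) in zip(path, path[1:]):
        total += _SQRT2 if (r0 != r1 and c0 != c1) else 1.0
    return total * pixel_size_um


def build_graph(tagged: TaggedSkeleton) -> SkeletonGraph:
    """Dissect a tagged skeleton into its node/branch graph.

    8-adjacent junction pixels merge into a single junction node (a raw
    crossing otherwise splits into several spurious junctions — a thinning
    artifact).  Branches are traced from node pixels through slab pixels;
    two directly adjacent node pixels form a slab-free branch of one step.
    A closed curve containing no node becomes one "cycle" anchor node with a
    single self-edge, so a loop counts as 1 object / 0 endpoints /
    0 junctions.  Isolated pixels become one-node, zero-branch objects.
    """
    tags, labels = tagged.tags, tagged.labels
    sk = tags > 0
    px_um = tagged.pixel_size_um

    junction_clusters, n_clusters = ndimage.label(tags == Tag.JUNCTION, structure=_STRUCT8)
    node_of_pixel = np.full(tags.shape, -1, dtype=np.int64)
    nodes: list[SkeletonNode] = []

    for cid in range(1, n_clusters + 1):
        pix = np.argwhere(junction_clusters == cid)
        pix = pix[np.lexsort((pix[:, 1], pix[:, 0]))]
        nid = len(nodes)
        node_of_pixel[pix[:, 0], pix[:, 1]] = nid
        centroid = (float(pix[:, 0].mean()), float(pix[:, 1].mean()))
        obj = int(labels[pix[0, 0], pix[0, 1]])
        nodes.append(SkeletonNode(nid, "junction", tuple(map(tuple, pix)), centroid, obj))

    for r, c in np.argwhere(tags == Tag.ENDPOINT):
        nid = len(nodes)
        node_of_pixel[r, c] = nid
        nodes.append(
            SkeletonNode(nid, "endpoint", ((int(r), int(c)),), (float(r), float(c)), int(labels[r, c]))
        )

    visited_slab = np.zeros(tags.shape, dtype=bool)
    branches: list[SkeletonBranch] = []

    def add_branch(node_a: int, node_b: int, path: list[tuple[int, int]]) -> None:
        # measure to node centroids: a branch leaving a merged junction
        # cluster starts at the cluster's geometric centre, not its rim pixel
        length = _path_length(path, px_um)
        for nid, terminus in ((node_a, path[0]), (node_b, path[-1])):
            cy, cx = nodes[nid].centroid
            length += math.hypot(cy - terminus[0], cx - terminus[1]) * px_um
        r, c = path[0]
        branches.append(
            SkeletonBranch(
                branch_id=len(branches),
                node_a=node_a,
                node_b=node_b,
                path=tuple(path),
                length_um=length,
                object_id=int(labels[r, c]),
            )
        )

    def trace(start_node: int, p: tuple[int, int], q: tuple[int, int]) -> None:
        """Walk from node pixel p through slab q until another node pixel."""
        path = [p, q]
        visited_slab[q] = True
        prev, cur = p, q
        while True:
            nxt = None
            for nb in _neighbors(sk, *cur):
                if nb != prev:
                    nxt = nb
                    break
            if nxt is None:  # dead-end slab cannot occur in a consistent tagging
                raise ContractViolation(f"slab pixel {cur} has no forward neighbour")
            path.append(nxt)
            if node_of_pixel[nxt] >= 0:
                add_branch(start_node, int(node_of_pixel[nxt]), path)
                return
            visited_slab[nxt] = True
            prev, cur = cur, nxt

    for node in nodes:
        for p in node.pixels:
            for q in sorted(_neighbors(sk, *p)):
                q_nid = int(node_of_pixel[q])
                if q_nid >= 0:
                    if q_nid == node.node_id:
                        continue  # intra-cluster adjacency
                    if p < q:  # dedup: each direct node-node contact once
                        add_branch(node.node_id, q_nid, [p, q])
                elif tags[q] == Tag.SLAB and not visited_slab[q]:
                    trace(node.node_id, p, q)

    # node-free cycles: remaining unvisited slab pixels
    leftover = (tags == Tag.SLAB) & ~visited_slab
    cyc_labels, n_cyc = ndimage.label(leftover, structure=_STRUCT8)
    for cid in range(1, n_cyc + 1):
        pix = np.argwhere(cyc_labels == cid)
        pix = pix[np.lexsort((pix[:, 1], pix[:, 0]))]
        anchor = (int(pix[0, 0]), int(pix[0, 1]))
        nid = len(nodes)
        node_of_pixel[anchor] = nid
        nodes.append(
            SkeletonNode(nid, "cycle", (anchor,), (float(anchor[0]), float(anchor[1])),
                         int(labels[anchor])),
        )
        start = min(_neighbors(sk, *anchor))
        trace(nid, anchor, start)

    return SkeletonGraph(
        nodes=tuple(nodes),
        branches=tuple(branches),
        pixel_size_um=px_um,
        n_objects=tagged.n_objects,
    )
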