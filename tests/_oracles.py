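"""Independent brute-force reference implementations used as test oracles.

These deliberately share no code with the package: the skeleton oracle is a
networkx pixel-graph construction, the tag oracle a per-pixel Python loop,
and the Otsu oracle an explicit loop over candidate thresholds.
"""

from __future__ import annotations

import numpy as np
import networkx as nx


def tag_oracle(sk: np.ndarray) -> np.ndarray:
    """Per-pixel 8-neighbour counts by explicit loop: 0 background, 1 slab,
    2 endpoint, 3 junction (matching the package's palette)."""
    h, w = sk.shape
    tags = np.zeros((h, w), dtype=np.uint8)
    for r in range(h):
        for c in range(w):
            if not sk[r, c]:
                continue
            n = 0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if (dr, dc) == (0, 0):
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and sk[rr, cc]:
                        n += 1
            tags[r, c] = 2 if n <= 1 else (1 if n == 2 else 3)
    return tags


def graph_counts_oracle(sk: np.ndarray) -> tuple[int, int, int, int]:
    """(objects, merged junction nodes, endpoint pixels, branches) of a thin
    skeleton, from a networkx pixel-adjacency graph.

    Branches are counted as: connected components of the slab-pixel subgraph
    (each maximal slab chain or node-free cycle is one branch) plus direct
    adjacencies between node pixels of different nodes (slab-free branches).
    Endpoint pixels include isolated single pixels (degree 0).
    """
    pts = [tuple(p) for p in np.argwhere(sk)]
    pset = set(pts)
    G = nx.Graph()
    G.add_nodes_from(pts)
    for r, c in pts:
        for dr, dc in ((-1, -1), (-1, 0), (-1, 1), (0, 1)):
            q = (r + dr, c + dc)
            if q in pset:
                G.add_edge((r, c), q)

    n_objects = nx.number_connected_components(G)
    deg = dict(G.degree)
    junction_px = {p for p, d in deg.items() if d >= 3}
    endpoint_px = {p for p, d in deg.items() if d <= 1}

    clusters = list(nx.connected_components(G.subgraph(junction_px)))
    node_of: dict[tuple[int, int], object] = {}
    for i, cl in enumerate(clusters):
        for p in cl:
            node_of[p] = ("j", i)
    for p in endpoint_px:
        node_of[p] = ("e", p)

    slab_px = set(pts) - junction_px - endpoint_px
    n_slab_chains = nx.number_connected_components(G.subgraph(slab_px))
    n_direct = sum(
        1
        for u, v in G.edges
        if u in node_of and v in node_of and node_of[u] != node_of[v]
    )
    return n_objects, len(clusters), len(endpoint_px), n_slab_chains + n_direct


def otsu_oracle(pixels: np.ndarray) -> float:
    """Otsu's threshold by an explicit loop over every candidate split.

    Returns the smallest intensity of the foreground class (mask is
    ``pixels >= threshold``), maximizing between-class variance; first
    maximum wins.
    """
    vals, counts = np.unique(pixels.ravel(), return_counts=True)
    assert vals.size >= 2, "zero-variance image"
    best_score, best_thr = -1.0, None
    total = counts.sum()
    for k in range(1, vals.size):
        bg_n = counts[:k].sum()
        fg_n = total - bg_n
        mu_bg = float((vals[:k] * counts[:k]).sum()) / bg_n
        mu_fg = float((vals[k:] * counts[k:]).sum()) / fg_n
        score = bg_n * fg_n * (mu_bg - mu_fg) ** 2
        if score > best_score:
            best_score, best_thr = score, float(vals[k])
    return best_thr


def random_stroke_mask(rng: np.random.Generator, size: int = 32) -> np.ndarray:
    """A random sparse mask of crossing strokes, blobs and isolated pixels;
    the package's skeletonize turns it into the thin skeleton under test."""
    from skimage.draw import disk as draw_disk
    from skimage.draw import line

    img = np.zeros((size, size), dtype=bool)
    for _ in range(rng.integers(2, 7)):
        r0, c0, r1, c1 = rng.integers(0, size, size=4)
        rr, cc = line(r0, c0, r1, c1)
        img[rr, cc] = True
    if rng.random() < 0.4:  # a thick blob, to exercise real thinning
        rr, cc = draw_disk(
            (int(rng.integers(4, size - 4)), int(rng.integers(4, size - 4))),
            int(rng.integers(2, 5)),
            shape=img.shape,
        )
        img[rr, cc] = True
    if rng.random() < 0.3:  # sprinkle isolated pixels
        for _ in range(rng.integers(1, 4)):
            img[rng.integers(0, size), rng.integers(0, size)] = True
    return img
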