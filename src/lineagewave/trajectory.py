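"""Branching pseudotime: cluster MST, principal curves, lineage weights.

The trajectory model follows the cluster-based minimum-spanning-tree /
principal-curve approach: Leiden communities on a k-NN graph of the latent
space provide cluster centroids; an MST over centroids is rooted at a
user-specified start cluster (biologically, the double-positive stage) and
the paths to the two user-specified endpoint clusters (mature CD4 and CD8)
define the lineages.  Each path is refined by an iterated principal-curve
procedure; per-cell pseudotime is arc length along the curve, and per-cell
lineage weights derive from the relative orthogonal distances to the two
curves.  Cells before the branch project onto a segment shared verbatim by
both lineage curves, so their pseudotime is identical across lineages.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist
from scipy.stats import spearmanr
from sklearn.neighbors import NearestNeighbors
from statsmodels.nonparametric.smoothers_lowess import lowess

log = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "cluster_cells",
    "fit_branching_curves",
    "assign_lineage_weights",
    "filter_by_lineage_weight",
    "bin_pseudotime",
]


@dataclass
class Trajectory:
    """Branching curve structure over a 2-D embedding or latent space."""

    cluster_labels: np.ndarray
    mst_edges: list                     # [(cluster_a, cluster_b), ...]
    paths: dict                         # lineage name -> ordered cluster list
    shared_prefix: list                 # clusters common to both paths
    curves: dict                        # lineage name -> polyline (m x dim)
    shared_arclength: float             # length of the shared segment
    pseudotime: np.ndarray              # per cell
    pseudotime_by_lineage: pd.DataFrame  # per cell, per lineage arc length
    weights: pd.DataFrame               # per cell, per lineage in [0, 1]
    assigned_lineage: np.ndarray        # argmax-weight lineage per cell
    cluster_lineage: dict = None        # cluster -> "shared" or lineage name


def _knn_graph(points: np.ndarray, k: int) -> ig.Graph:
    """Jaccard-weighted shared-nearest-neighbour graph (PhenoGraph-style).

    Edge weight = |N(i) & N(j)| / |N(i) | N(j)| over the k-neighbourhoods,
    which sharpens community boundaries relative to the unweighted graph.
    """
    nn = NearestNeighbors(n_neighbors=k + 1).fit(points)
    _, idx = nn.kneighbors(points)
    neigh = [set(int(j) for j in row[1:]) for row in idx]
    edges, weights, seen = [], [], set()
    for i, row in enumerate(idx):
        for j in row[1:]:
            j = int(j)
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            inter = len(neigh[i] & neigh[j])
            edges.append(key)
            weights.append(inter / (2 * k - inter) if inter else 1e-4)
    g = ig.Graph(n=points.shape[0], edges=edges)
    g.es["weight"] = weights
    return g


def cluster_cells(latent: np.ndarray, resolution: float = 0.6, seed: int = 0,
                  k: int = 15, merge_threshold: float = 8.0) -> np.ndarray:
    """Leiden community detection on a weighted k-NN graph of the latent space.

    Communities that remain embedded in one another -- more than
    ``merge_threshold`` cross k-NN edges per member of the smaller community
    -- are merged afterwards; over-splits of a single mode sit well above
    this (about 10+), genuinely adjacent developmental stages well below
    (about 6 or less).
    """
    latent = np.asarray(latent, dtype=float)
    if latent.shape[0] <= k:
        raise ValueError(f"need more than k={k} cells to build the graph")
    g = _knn_graph(latent, k)
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition, weights="weight",
        resolution_parameter=resolution, seed=seed, n_iterations=2)
    labels = np.asarray(part.membership, dtype=int)
    while True:
        ids = sorted(set(labels.tolist()))
        if len(ids) < 2:
            break
        conn = _cluster_connectivity(latent, labels, ids, k=k)
        iu = np.triu_indices(len(ids), 1)
        best = int(np.argmax(conn[iu]))
        if conn[iu][best] <= merge_threshold:
            break
        a, b = ids[iu[0][best]], ids[iu[1][best]]
        labels[labels == b] = a
    # consecutive relabelling for stable downstream handling
    remap = {c: i for i, c in enumerate(sorted(set(labels.tolist())))}
    return np.array([remap[c] for c in labels], dtype=int)


# ---------------------------------------------------------------------------
# polyline geometry


def _project_polyline(points: np.ndarray, verts: np.ndarray):
    """Project points onto a polyline.

    Returns (arclength of projection, orthogonal distance) per point.
    """
    p0 = verts[:-1]
    seg = verts[1:] - p0
    seg_len = np.linalg.norm(seg, axis=1)
    seg_len[seg_len == 0] = 1e-12
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    # (n_points, n_segments) parameter of the foot of the perpendicular
    diff = points[:, None, :] - p0[None, :, :]
    tpar = np.clip((diff * seg[None, :, :]).sum(-1) / (seg_len ** 2), 0.0, 1.0)
    foot = p0[None, :, :] + tpar[:, :, None] * seg[None, :, :]
    dist = np.linalg.norm(points[:, None, :] - foot, axis=-1)
    best = np.argmin(dist, axis=1)
    rows = np.arange(points.shape[0])
    s = cum[best] + tpar[rows, best] * seg_len[best]
    return s, dist[rows, best]


def _smooth_curve(points: np.ndarray, s: np.ndarray, span: float,
                  n_vertices: int) -> np.ndarray:
    """Re-smooth coordinates against arc length (lowess, tricube weights).

    Tied arc lengths (cells projecting onto the same vertex) are separated
    by a deterministic sub-resolution jitter so local windows keep nonzero
    width.
    """
    s = np.asarray(s, dtype=float)
    rank = np.argsort(np.argsort(s, kind="stable"), kind="stable")
    spread = max(float(np.ptp(s)), 1e-9)
    s = s + rank * (1e-9 * spread)
    grid = np.quantile(s, np.linspace(0.0, 1.0, n_vertices))
    grid = np.unique(grid)
    if len(grid) < 2:
        grid = np.linspace(s.min(), s.min() + 1e-6, 2)
    cols = []
    for dim in range(points.shape[1]):
        fit = lowess(points[:, dim], s, frac=span, it=0, xvals=grid)
        if np.isnan(fit).any():
            ok = ~np.isnan(fit)
            fit = np.interp(grid, grid[ok], fit[ok])
        cols.append(fit)
    return np.column_stack(cols)


def _principal_curve(points: np.ndarray, init: np.ndarray, span: float = 0.3,
                     max_iter: int = 20, tol: float = 1e-3,
                     n_vertices: int = 50) -> np.ndarray:
    """Iterated projection / re-smoothing starting from an initial polyline."""
    verts = init
    prev = np.inf
    for _ in range(max_iter):
        s, d = _project_polyline(points, verts)
        crit = float(np.mean(d ** 2))
        order = np.argsort(s, kind="stable")
        verts = _smooth_curve(points[order], s[order], span, n_vertices)
        if prev < np.inf and abs(prev - crit) <= tol * max(prev, 1e-12):
            prev = crit
            break
        prev = crit
    return verts


def _densify(verts: np.ndarray, per_segment: int = 4) -> np.ndarray:
    out = [verts[:1]]
    for a, b in zip(verts[:-1], verts[1:]):
        for frac in np.linspace(0, 1, per_segment + 1)[1:]:
            out.append((a + frac * (b - a))[None, :])
    return np.vstack(out)


# ---------------------------------------------------------------------------
# branching fit


def _cluster_connectivity(embedding: np.ndarray, labels: np.ndarray,
                          cluster_ids, k: int = 15) -> np.ndarray:
    """Inter-cluster connectivity from the cell k-NN graph.

    conn[i, j] = (# k-NN edges between clusters i and j) / min(n_i, n_j).
    Same-stage clusters of different lineages share few cell-level edges, so
    connectivity separates them even when their centroids are close.
    """
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    pos = {c: i for i, c in enumerate(cluster_ids)}
    n = len(cluster_ids)
    counts = np.zeros((n, n))
    lab_idx = np.array([pos[c] for c in labels])
    for i, row in enumerate(idx):
        a = lab_idx[i]
        for j in row[1:]:
            b = lab_idx[int(j)]
            if a != b:
                counts[a, b] += 1
                counts[b, a] += 1
    sizes = np.array([(labels == c).sum() for c in cluster_ids], dtype=float)
    return counts / np.minimum.outer(sizes, sizes)


def _mst_paths(centroids: dict, start, ends, connectivity=None):
    """MST over clusters; returns the start->end cluster paths.

    Edge costs are inverse connectivities when a connectivity matrix is
    given (clusters without shared k-NN edges are not adjacent), otherwise
    Euclidean centroid distances.  Ties between equal-weight edges break on
    cluster-label order (the cost matrix rows are sorted by label).
    """
    labels = sorted(centroids)
    pos = np.array([centroids[c] for c in labels])
    if connectivity is not None and (connectivity > 0).any():
        with np.errstate(divide="ignore"):
            dist = np.where(connectivity > 0, 1.0 / connectivity, 0.0)
    else:
        dist = cdist(pos, pos)
    mst = minimum_spanning_tree(dist).toarray()
    if connectivity is not None:
        # a disconnected connectivity graph leaves the MST short of edges;
        # fall back to centroid distances in that case
        n_components = len(labels) - (mst > 0).sum()
        if n_components > 1:
            dist = cdist(pos, pos)
            mst = minimum_spanning_tree(dist).toarray()
    adj = {c: [] for c in labels}
    for i in range(len(labels)):
        for j in range(len(labels)):
            if mst[i, j] > 0:
                adj[labels[i]].append(labels[j])
                adj[labels[j]].append(labels[i])
    paths = {}
    for end in ends:
        # BFS from start to end in the tree
        parent = {start: None}
        queue = [start]
        while queue:
            node = queue.pop(0)
            for nxt in sorted(adj[node]):
                if nxt not in parent:
                    parent[nxt] = node
                    queue.append(nxt)
        if end not in parent:
            raise ValueError(
                f"endpoint cluster {end} unreachable from start {start} in MST")
        path = [end]
        while parent[path[-1]] is not None:
            path.append(parent[path[-1]])
        paths[end] = path[::-1]
    edges = [(labels[i], labels[j]) for i in range(len(labels))
             for j in range(len(labels)) if mst[i, j] > 0]
    return paths, edges


def _ordered_insert(ordered: list, extras, centroids) -> list:
    """Insert unordered clusters after their nearest ordered neighbour."""
    out = list(ordered)
    for c in sorted(extras):
        nearest = min(out, key=lambda o: float(
            np.linalg.norm(centroids[c] - centroids[o])))
        out.insert(out.index(nearest) + 1, c)
    return out


def _fit_group_curve(embedding, labels, order, centroids, span, anchor=None):
    """Principal curve through the cells of an ordered cluster group.

    The iterated fit can fold back on itself when the group contains
    parallel same-stage clusters; if the fitted curve no longer orders the
    group's clusters consistently with ``order`` (|Spearman| < 0.8 of mean
    arc length vs position) the smoothed init polyline is used instead.
    The returned curve is oriented so arc length increases along ``order``.
    """
    init = np.array([centroids[c] for c in order])
    if anchor is not None:
        init = np.vstack([anchor[None, :], init])
    if init.shape[0] == 1:
        raise ValueError("cannot fit a curve through a single point")
    init = _densify(init)
    mask = np.isin(labels, order)
    curve = _principal_curve(embedding[mask], init, span=span)

    if len(order) == 1:
        if anchor is not None and (np.linalg.norm(curve[0] - anchor)
                                   > np.linalg.norm(curve[-1] - anchor)):
            curve = curve[::-1]
        return curve

    def order_rho(c):
        s, _ = _project_polyline(embedding[mask], c)
        mean_s = [float(s[labels[mask] == cl].mean()) for cl in order]
        rho = spearmanr(mean_s, np.arange(len(order))).statistic
        return float(rho), mean_s

    rho, _ = order_rho(curve)
    if abs(rho) < 0.8:
        curve = init          # fold: keep the monotone polyline
        rho, _ = order_rho(curve)
    if rho < 0:
        curve = curve[::-1]
    return curve


def _fit_two_branch(embedding, labels, centroids, start_cluster, assign,
                    lineage_names, span, order_hint):
    """Fit shared + per-lineage curves for one cluster-to-lineage assignment.

    ``order_hint`` maps "shared" and each lineage name to an MST-path cluster
    ordering used to seed the curve initialisations.  Returns (curves,
    shared_curve, shared_arclength, projections) where projections maps
    lineage -> (arclength, distance) per cell.
    """
    shared_clusters = [c for c in sorted(assign) if assign[c] == "shared"]
    start_centroid = centroids[start_cluster]

    hinted = [c for c in order_hint.get("shared", []) if c in shared_clusters]
    if not hinted:
        hinted = sorted(shared_clusters, key=lambda c: float(
            np.linalg.norm(centroids[c] - start_centroid)))[:1]
    shared_order = _ordered_insert(
        hinted, [c for c in shared_clusters if c not in hinted], centroids)
    if len(shared_order) == 1:
        # anchor a 1-cluster trunk toward the mean of the branch starts
        others = [centroids[c] for c in sorted(assign) if assign[c] != "shared"]
        anchor = 0.5 * (centroids[shared_order[0]] + np.mean(others, axis=0))
        shared_curve = _fit_group_curve(embedding, labels, shared_order,
                                        centroids, span, anchor=anchor)[::-1]
    else:
        shared_curve = _fit_group_curve(embedding, labels, shared_order,
                                        centroids, span)
    seg = float(np.linalg.norm(np.diff(shared_curve, axis=0), axis=1).sum())

    curves, projections = {}, {}
    for name in lineage_names:
        cl = [c for c in sorted(assign) if assign[c] == name]
        hinted = [c for c in order_hint.get(name, []) if c in cl]
        if not hinted:
            hinted = sorted(cl, key=lambda c: float(
                np.linalg.norm(centroids[c] - shared_curve[-1])))[:1]
        branch_order = _ordered_insert(
            hinted, [c for c in cl if c not in hinted], centroids)
        branch_curve = _fit_group_curve(embedding, labels, branch_order,
                                        centroids, span,
                                        anchor=shared_curve[-1])
        curves[name] = np.vstack([shared_curve, branch_curve])
    for name in lineage_names:
        projections[name] = _project_polyline(embedding, curves[name])
    return curves, shared_curve, seg, projections


def _ratio_weights(projections, lineage_names, shared_arclength,
                   prebranch_full: bool = True):
    """Inverse-distance-ratio weights, optionally with the pre-branch (1,1) rule."""
    d = np.column_stack([projections[n][1] for n in lineage_names])
    s = np.column_stack([projections[n][0] for n in lineage_names])
    total = d.sum(axis=1)
    total[total == 0] = 1.0
    w = d[:, ::-1] / total[:, None]
    if prebranch_full:
        prebranch = (s <= shared_arclength + 1e-9).all(axis=1)
        w[prebranch] = 1.0
    return np.clip(w, 0.0, 1.0)


def fit_branching_curves(embedding: np.ndarray, labels: np.ndarray, start_cluster,
                         endpoint_clusters, lineage_names=("CD4", "CD8"),
                         span: float = 0.3, span_scale: float | None = 12.0,
                         seed: int = 0) -> Trajectory:
    """Fit a two-branch trajectory rooted at ``start_cluster``.

    ``endpoint_clusters`` is the pair of terminal clusters, ordered to match
    ``lineage_names``.  The MST paths from the start to each endpoint seed a
    cluster-to-lineage assignment (common prefix = shared trunk); a single
    principal curve is fitted to the shared cells and lineage-specific curves
    continue from its end, so pre-branch cells receive identical pseudotime
    on both lineage paths.  Off-path clusters join the assignment of their
    nearest on-path cluster.  Weight ties on the trunk break by distance to
    the branch-specific curve segments.  When ``span_scale`` is set,
    pseudotime is rescaled so the longest lineage spans [0, span_scale]
    (unit bins then match the simulated span).
    """
    embedding = np.asarray(embedding, dtype=float)
    labels = np.asarray(labels)
    end_a, end_b = endpoint_clusters
    if end_a == end_b:
        raise ValueError("endpoint clusters must be distinct")
    present = set(np.unique(labels).tolist())
    for c in (start_cluster, end_a, end_b):
        if c not in present:
            raise ValueError(f"cluster {c} not present in labels")

    centroids = {c: embedding[labels == c].mean(axis=0) for c in present}
    conn = _cluster_connectivity(embedding, labels, sorted(present))
    paths, edges = _mst_paths(centroids, start_cluster, [end_a, end_b],
                              connectivity=conn)
    path_a, path_b = paths[end_a], paths[end_b]
    shared = []
    for u, v in zip(path_a, path_b):
        if u == v:
            shared.append(u)
        else:
            break
    if not shared:
        raise ValueError("lineage paths share no start cluster")

    # initial cluster-to-lineage assignment from the MST paths; off-path
    # clusters join the assignment of their nearest on-path cluster, and
    # endpoint clusters always belong to their own lineage (one endpoint may
    # lie on the other's path in degenerate, nearly collinear layouts)
    assign = {}
    on_path = set(path_a) | set(path_b)
    for c in present:
        if c in shared:
            assign[c] = "shared"
        elif c in path_a:
            assign[c] = lineage_names[0]
        elif c in path_b:
            assign[c] = lineage_names[1]
    for c in present - on_path:
        nearest = min(on_path, key=lambda o: float(
            np.linalg.norm(centroids[c] - centroids[o])))
        assign[c] = assign[nearest]
    assign[end_a] = lineage_names[0]
    assign[end_b] = lineage_names[1]
    shared = [c for c in shared if c not in (end_a, end_b)]
    if not shared:
        raise ValueError("no shared trunk cluster remains before the branch")

    order_hint = {"shared": shared,
                  lineage_names[0]: path_a[len(shared):],
                  lineage_names[1]: path_b[len(shared):]}
    curves, shared_curve, seg, projections = _fit_two_branch(
        embedding, labels, centroids, start_cluster, assign,
        lineage_names, span, order_hint)

    pt = {name: projections[name][0] for name in lineage_names}
    proj_cache = {name: projections[name] for name in lineage_names}
    pt_df = pd.DataFrame(pt)
    final_shared = sorted(
        (c for c in present if assign[c] == "shared"),
        key=lambda c: float(np.linalg.norm(centroids[c]
                                           - centroids[start_cluster])))
    traj = Trajectory(
        cluster_labels=labels,
        mst_edges=edges,
        paths={lineage_names[0]: path_a, lineage_names[1]: path_b},
        shared_prefix=final_shared,
        curves=curves,
        shared_arclength=float(seg),
        pseudotime=np.zeros(embedding.shape[0]),
        pseudotime_by_lineage=pt_df,
        weights=pd.DataFrame(index=range(embedding.shape[0])),
        assigned_lineage=np.empty(embedding.shape[0], dtype=object),
        cluster_lineage=dict(assign),
    )
    traj._proj_cache = proj_cache
    traj.weights = assign_lineage_weights(traj)
    w = traj.weights.to_numpy()
    names = list(traj.weights.columns)
    # pseudotime: weighted combination of per-lineage arc lengths
    wsum = w.sum(axis=1, keepdims=True)
    wsum[wsum == 0] = 1.0
    t = (pt_df.to_numpy() * w).sum(axis=1) / wsum.ravel()
    # argmax lineage; weight ties (trunk cells) break by distance to the two
    # branch parts, and only exactly-equidistant cells fall back to index
    # parity (so unassigned-genotype trunk cells split between the labels)
    n_sh = len(shared_curve)
    d_branch = np.column_stack([
        _project_polyline(embedding, curves[name][n_sh - 1:])[1]
        for name in lineage_names])
    tie_break = np.where(d_branch[:, 0] < d_branch[:, 1], 0,
                         np.where(d_branch[:, 1] < d_branch[:, 0], 1,
                                  np.arange(embedding.shape[0]) % 2))
    arg = np.where(w[:, 0] > w[:, 1], 0, np.where(w[:, 1] > w[:, 0], 1,
                   tie_break))
    traj.pseudotime = t
    traj.assigned_lineage = np.array([names[a] for a in arg], dtype=object)
    if span_scale is not None and t.max() > 0:
        scale = span_scale / t.max()
        traj.pseudotime = t * scale
        traj.pseudotime_by_lineage = pt_df * scale
        traj.shared_arclength = float(seg * scale)
    return traj


def assign_lineage_weights(traj: Trajectory) -> pd.DataFrame:
    """Per-cell lineage weights from relative curve distances.

    Post-branch cells get the inverse-distance ratio
    ``w_L = d_other / (d_L + d_other)`` (in [0, 1]; 0.5 when equidistant, 1 on
    the curve).  Cells whose projections fall on the shared pre-branch
    segment of both curves receive weight 1 on both lineages.
    """
    names = list(traj.curves)
    d = np.column_stack([
        _project_polyline_cached(traj, name)[1] for name in names])
    s = np.column_stack([
        _project_polyline_cached(traj, name)[0] for name in names])
    total = d.sum(axis=1)
    total[total == 0] = 1.0
    w = d[:, ::-1] / total[:, None]
    prebranch = (s <= traj.shared_arclength + 1e-9).all(axis=1)
    w[prebranch] = 1.0
    return pd.DataFrame(np.clip(w, 0.0, 1.0), columns=names)


def _project_polyline_cached(traj: Trajectory, name: str):
    cache = getattr(traj, "_proj_cache", None)
    if cache is None or name not in cache:
        raise RuntimeError("projection cache missing; call via fit_branching_curves")
    return cache[name]


def filter_by_lineage_weight(weights: pd.DataFrame, genotype: np.ndarray,
                             expected_lineage: dict, threshold: float = 0.5):
    """Exclude cells off their genotype-expected lineage.

    Lineage-restricted genotypes keep only cells with weight strictly greater
    than ``threshold`` on the expected lineage (a weight of exactly 0.5 is
    excluded).  Unassigned genotypes take the argmax-weight lineage and are
    never excluded.  Returns (keep mask, final lineage labels).
    """
    genotype = np.asarray(genotype)
    names = list(weights.columns)
    w = weights.to_numpy()
    keep = np.ones(len(genotype), dtype=bool)
    label = np.empty(len(genotype), dtype=object)
    for i, g in enumerate(genotype):
        if g not in expected_lineage:
            raise ValueError(f"genotype {g!r} missing from expected-lineage map")
        expected = expected_lineage[g]
        if expected in (None, "unassigned"):
            if w[i, 0] > w[i, 1]:
                label[i] = names[0]
            elif w[i, 1] > w[i, 0]:
                label[i] = names[1]
            else:
                label[i] = names[i % 2]
        else:
            j = names.index(expected)
            if w[i, j] > threshold:
                label[i] = expected
            else:
                keep[i] = False
                label[i] = None
    return keep, label


def bin_pseudotime(pseudotime: np.ndarray) -> np.ndarray:
    """Unit-width left-closed bins; the global maximum joins the last bin."""
    t = np.asarray(pseudotime, dtype=float)
    if t.size == 0:
        return np.zeros(0, dtype=int)
    if (t < 0).any():
        raise ValueError("pseudotime must be nonnegative")
    tmax = t.max()
    n_bins = int(tmax) if tmax == np.floor(tmax) and tmax > 0 \
        else int(np.floor(tmax)) + 1
    b = np.floor(t).astype(int)
    return np.clip(b, 0, max(n_bins - 1, 0))
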