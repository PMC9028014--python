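"""Lineage reconstruction and pseudotime over metabolic genes.

The expression matrix is restricted to a metabolic gene list, reduced by PCA,
and cluster centroids are joined by a minimum spanning tree; every path from
the root cluster (ISC/EB) to a leaf is a lineage.  Each cell's pseudotime on
a lineage is the arc-length position of its orthogonal projection onto the
piecewise-linear curve through that lineage's centroids (with an optional
project-average principal-curve refinement).  Gene-versus-pseudotime trends
are smoothed with a local regression and labelled decreasing / increasing /
flat / non-monotone.  A t-SNE embedding is provided for visualization only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import ExpressionMatrix, MidgutError


@dataclass
class ReducedSpace:
    coords: np.ndarray            # (n_cells, d)
    loadings: np.ndarray          # (n_genes, d)
    variance_explained: np.ndarray
    gene_ids: list
    cell_ids: list


@dataclass
class LineageTree:
    clusters: list
    centroids: dict               # cluster -> (d,) centroid in reduced space
    edges: list                   # (a, b, weight) undirected MST edges
    root: str
    lineages: list                # ordered root -> leaf cluster paths


# ---------------------------------------------------------------------------

def restrict_to_gene_list(em: ExpressionMatrix, gene_list) -> ExpressionMatrix:
    """Restrict rows to the listed genes, in list order; absent genes reported."""
    present = [g for g in gene_list if g in set(em.gene_ids)]
    absent = [g for g in gene_list if g not in set(em.gene_ids)]
    if len(present) < 2:
        raise MidgutError("fewer than 2 listed genes present in the matrix")
    if absent:
        warnings.warn(f"{len(absent)} listed gene(s) absent from the matrix")
    idx = [em.gene_index(g) for g in present]
    out = em.copy()
    out.values = em.values[idx]
    out.gene_ids = present
    if out.imputed_mask is not None:
        out.imputed_mask = out.imputed_mask[idx]
    return out


def pca_reduce(em: ExpressionMatrix, d: int = 10) -> ReducedSpace:
    """Centered PCA with a deterministic sign convention (largest-|loading| positive)."""
    X = em.values.T
    n, g = X.shape
    if d > min(n, g):
        raise MidgutError(f"d={d} exceeds min(n_cells, n_genes)={min(n, g)}")
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        raise MidgutError("constant matrix has no principal components")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: the largest-magnitude loading of each component is positive
    for k in range(min(d, Vt.shape[0])):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    coords = U[:, :d] * S[:d]
    var = S ** 2 / max(n - 1, 1)
    ratio = var / var.sum()
    return ReducedSpace(coords, Vt[:d].T, ratio[:d], list(em.gene_ids), list(em.cell_ids))


def embed_2d(data, perplexity: float = 30.0, seed: int = 0) -> np.ndarray:
    """Seeded t-SNE embedding (visualization only; nothing downstream reads it)."""
    X = data.coords if isinstance(data, ReducedSpace) else np.asarray(data.values).T
    n = X.shape[0]
    if n <= 3 * perplexity:
        raise MidgutError(
            f"perplexity {perplexity} too large for {n} cells; use < {n / 3:.1f}"
        )
    ts = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    return ts.fit_transform(X)


# ---------------------------------------------------------------------------

def _mst_edges(names: list, centroids: dict) -> list:
    """Kruskal MST with deterministic lexicographic tie-break."""
    cand = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            w = float(np.linalg.norm(centroids[a] - centroids[b]))
            pair = tuple(sorted((a, b)))
            cand.append((w, pair[0], pair[1]))
    cand.sort()
    parent = {n: n for n in names}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges = []
    for w, a, b in cand:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            edges.append((a, b, w))
    return edges


def build_lineages(rs: ReducedSpace, labels, root_cluster: str) -> LineageTree:
    """Centroid MST rooted at ``root_cluster``; lineages are root-to-leaf paths."""
    labels = np.asarray(list(labels))
    if labels.shape[0] != rs.coords.shape[0]:
        raise MidgutError("labels must provide one cluster per cell")
    names = sorted(set(labels.tolist()))
    if root_cluster not in names:
        raise MidgutError(f"root cluster {root_cluster!r} not among labels")
    if len(names) < 2:
        raise MidgutError("need at least 2 clusters")
    centroids = {t: rs.coords[labels == t].mean(axis=0) for t in names}
    edges = _mst_edges(names, centroids)
    adj = {n: [] for n in names}
    for a, b, _ in edges:
        adj[a].append(b)
        adj[b].append(a)
    # root-to-leaf paths by DFS with sorted neighbors (deterministic)
    lineages = []

    def walk(node, path, seen):
        nxt = [x for x in sorted(adj[node]) if x not in seen]
        if not nxt:
            lineages.append(list(path))
            return
        for x in nxt:
            walk(x, path + [x], seen | {x})

    walk(root_cluster, [root_cluster], {root_cluster})
    lineages.sort(key=lambda p: p[-1])
    return LineageTree(names, centroids, edges, root_cluster, lineages)


def _project_polyline(points: np.ndarray, verts: np.ndarray):
    """Arc-length position and distance of each point's nearest polyline point."""
    seg_vec = verts[1:] - verts[:-1]
    seg_len = np.linalg.norm(seg_vec, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    best_t = np.zeros(points.shape[0])
    best_d = np.full(points.shape[0], np.inf)
    for s in range(seg_vec.shape[0]):
        v = seg_vec[s]
        L2 = max(seg_len[s] ** 2, 1e-300)
        u = np.clip((points - verts[s]) @ v / L2, 0.0, 1.0)
        proj = verts[s] + u[:, None] * v
        d = np.linalg.norm(points - proj, axis=1)
        better = d < best_d
        best_d[better] = d[better]
        best_t[better] = cum[s] + u[better] * seg_len[s]
    return best_t, best_d


def pseudotime(rs: ReducedSpace, lt: LineageTree, refine_iters: int = 0,
               tol: float = 1e-4, labels=None) -> pd.DataFrame:
    """Per-cell (lineage, t) assignments.

    A cell is assigned to every lineage containing its cluster; t is its
    arc-length projection onto the piecewise-linear centroid curve.  With
    ``refine_iters`` > 0, interior curve vertices are iteratively replaced by
    the mean of the cells projecting to their neighbourhood (project-average
    principal-curve refinement, stopped at relative change < ``tol``).
    Cells whose cluster lies on no lineage get lineage 'unassigned'.
    """
    if labels is None:
        raise MidgutError("pseudotime requires the cluster labels")
    labels = np.asarray(list(labels))
    rows = []
    on_some = set(c for path in lt.lineages for c in path)
    for li, path in enumerate(lt.lineages):
        lineage_name = "->".join(path)
        member = np.isin(labels, path)
        pts = rs.coords[member]
        verts = np.array([lt.centroids[c] for c in path])
        for _ in range(max(0, min(refine_iters, 10))):
            t, _d = _project_polyline(pts, verts)
            seg_len = np.linalg.norm(verts[1:] - verts[:-1], axis=1)
            cum = np.concatenate([[0.0], np.cumsum(seg_len)])
            new_verts = verts.copy()
            for k in range(1, len(verts) - 1):
                near = np.abs(t - cum[k]) <= 0.5 * max(seg_len[k - 1], seg_len[k])
                if np.count_nonzero(near) >= 3:
                    new_verts[k] = pts[near].mean(axis=0)
            change = np.linalg.norm(new_verts - verts) / (np.linalg.norm(verts) + 1e-12)
            verts = new_verts
            if change < tol:
                break
        t, _d = _project_polyline(pts, verts)
        ids = np.asarray(rs.cell_ids, dtype=object)[member]
        for cid, tv in zip(ids, t):
            rows.append({"cell_id": cid, "lineage": lineage_name, "t": float(tv)})
    for cid, lab in zip(rs.cell_ids, labels):
        if lab not in on_some:
            rows.append({"cell_id": cid, "lineage": "unassigned", "t": float("nan")})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------

@dataclass
class GeneTrend:
    gene: str
    lineage: str
    grid_t: np.ndarray
    fitted: np.ndarray
    direction: str                # decreasing | increasing | non-monotone | flat


def _label_direction(fitted: np.ndarray, delta: float) -> str:
    total = fitted[-1] - fitted[0]
    diffs = np.diff(fitted)
    rise = diffs[diffs > 0].sum() if np.any(diffs > 0) else 0.0
    fall = -diffs[diffs < 0].sum() if np.any(diffs < 0) else 0.0
    if fitted.max() - fitted.min() <= delta:
        return "flat"
    # monotone within tolerance: counter-movement small in absolute terms or
    # relative to the net change (smoother boundary wiggles do not flip the call)
    tol = max(delta, 0.3 * abs(total))
    if total < -delta and rise <= tol:
        return "decreasing"
    if total > delta and fall <= tol:
        return "increasing"
    return "non-monotone"


def gene_trends(em: ExpressionMatrix, pseudotimes: pd.DataFrame, genes,
                lineages=None, span: float = 0.5, grid: int = 100,
                delta: float = 0.25, min_cells: int = 10) -> list:
    """Lowess-smoothed expression along pseudotime per (gene, lineage).

    ``delta`` (log2 units) separates real end-to-start change from noise both
    for the direction call and the monotonicity tolerance.
    """
    cidx = {c: i for i, c in enumerate(em.cell_ids)}
    out = []
    all_lineages = [l for l in pseudotimes["lineage"].unique() if l != "unassigned"]
    for lineage_name in (lineages or all_lineages):
        sub = pseudotimes[pseudotimes["lineage"] == lineage_name]
        if len(sub) < min_cells:
            warnings.warn(f"lineage {lineage_name!r}: only {len(sub)} cells; trends omitted")
            continue
        order = np.argsort(sub["t"].to_numpy(), kind="stable")
        tvals = sub["t"].to_numpy()[order]
        cells = [cidx[c] for c in sub["cell_id"].to_numpy()[order]]
        if tvals[0] == tvals[-1]:
            warnings.warn(f"lineage {lineage_name!r}: degenerate pseudotime range")
            continue
        # smooth against pseudotime rank so the span covers an even number of
        # cells (cells clump near cluster centroids, leaving gaps in raw t)
        n = len(tvals)
        ranks = np.arange(n, dtype=float)
        rank_grid = np.linspace(0, n - 1, grid)
        grid_t = np.interp(rank_grid, ranks, tvals)
        bump = np.cumsum(np.diff(grid_t, prepend=grid_t[0]) <= 0)
        grid_t = grid_t + bump * 1e-9 * max(tvals[-1] - tvals[0], 1.0)
        for gene in genes:
            if gene not in em.gene_ids:
                continue
            y = em.values[em.gene_index(gene), cells]
            if np.allclose(y, y[0]):
                fitted = np.full(grid, float(y[0]))
            else:
                fitted = lowess(y, ranks, frac=span, xvals=rank_grid)
            out.append(GeneTrend(gene, lineage_name, grid_t,
                                 np.asarray(fitted, dtype=float),
                                 _label_direction(np.asarray(fitted, dtype=float), delta)))
    return out


def trends_table(trends) -> pd.DataFrame:
    rows = [{"gene": tr.gene, "lineage": tr.lineage, "direction": tr.direction,
             "fitted_start": tr.fitted[0], "fitted_end": tr.fitted[-1]}
            for tr in trends]
    return pd.DataFrame(rows)
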