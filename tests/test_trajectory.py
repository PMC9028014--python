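"""Dimensionality reduction, MST lineages, pseudotime and gene trends."""

import itertools

import numpy as np
import pytest

import midgutmet as mm
from midgutmet.containers import ExpressionMatrix, MidgutError
from midgutmet.trajectory import ReducedSpace, _mst_edges


def _em(values, genes=None, scale="log2tpm"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(values, genes,
                            [f"c{i}" for i in range(values.shape[1])], scale=scale)


# ------------------------------------------------------------ gene restriction

def test_restrict_full_overlap_and_order(rng):
    em = _em(rng.normal(size=(5, 4)))
    out = mm.restrict_to_gene_list(em, ["g3", "g1"])
    assert out.gene_ids == ["g3", "g1"]
    np.testing.assert_array_equal(out.values, em.values[[3, 1]])


def test_restrict_disjoint_raises_and_mixed_warns(rng):
    em = _em(rng.normal(size=(4, 3)))
    with pytest.raises(MidgutError):
        mm.restrict_to_gene_list(em, ["x", "y"])
    with pytest.warns(UserWarning):
        out = mm.restrict_to_gene_list(em, ["g0", "nope", "g2"])
    assert out.n_genes == 2


# ------------------------------------------------------------ PCA

def test_pca_rank_one_variance():
    u = np.outer([1.0, 2.0, 3.0], [1.0, -1.0, 2.0, 0.5])
    rs = mm.pca_reduce(_em(u), d=3)
    assert rs.variance_explained[0] == pytest.approx(1.0)
    assert rs.variance_explained[1] == pytest.approx(0.0, abs=1e-12)


def test_pca_full_reconstruction_lossless(rng):
    em = _em(rng.normal(size=(6, 9)))
    rs = mm.pca_reduce(em, d=6)
    X = em.values.T
    recon = rs.coords @ rs.loadings.T + X.mean(axis=0)
    np.testing.assert_allclose(recon, X, atol=1e-8)
    # orthogonality of loadings
    np.testing.assert_allclose(rs.loadings.T @ rs.loadings, np.eye(6), atol=1e-8)


def test_pca_matches_eigendecomposition(rng):
    em = _em(rng.normal(size=(5, 8)))
    rs = mm.pca_reduce(em, d=5)
    X = em.values.T - em.values.T.mean(axis=0)
    evals, evecs = np.linalg.eigh(X.T @ X / (X.shape[0] - 1))
    order = np.argsort(evals)[::-1]
    np.testing.assert_allclose(rs.variance_explained,
                               evals[order] / evals.sum(), atol=1e-10)
    for k in range(5):
        v = evecs[:, order[k]]
        got = rs.loadings[:, k]
        assert abs(abs(v @ got) - 1.0) < 1e-8  # same axis up to sign
        assert got[np.argmax(np.abs(got))] > 0  # deterministic sign convention


def test_pca_constant_matrix_raises():
    with pytest.raises(MidgutError):
        mm.pca_reduce(_em(np.ones((4, 5))), d=2)


# ------------------------------------------------------------ embedding

def test_embedding_separates_types_and_is_reproducible():
    cfg = mm.SimConfig(
        n_cells=240, n_genes=200,
        cell_type_spec=[("A", 0.5, None), ("B", 0.5, None)],
        branch_spec={"A": ["B"]},
        cluster_map={"A": "ISC_EB", "B": "EE"},  # distinct built-in programs
        marker_spec={}, gradient_spec=[],
    )
    cm, gt = mm.simulate_midgut(cfg, seed=1)
    em = mm.log_transform(mm.tpm(cm, mm.GeneAnnotation.uniform(cm.gene_ids)))
    rs = mm.pca_reduce(em, d=10)
    emb = mm.embed_2d(rs, perplexity=20, seed=0)
    emb2 = mm.embed_2d(rs, perplexity=20, seed=0)
    np.testing.assert_allclose(emb, emb2)
    lab = np.asarray(gt.true_type)
    ca, cb = emb[lab == "A"].mean(axis=0), emb[lab == "B"].mean(axis=0)
    inter = np.linalg.norm(ca - cb)
    intra = np.mean([np.linalg.norm(emb[lab == t] - emb[lab == t].mean(axis=0), axis=1).mean()
                     for t in "AB"])
    assert inter > intra


def test_embedding_perplexity_limit():
    rs = ReducedSpace(np.random.default_rng(0).normal(size=(30, 3)),
                      np.zeros((5, 3)), np.ones(3), [], [f"c{i}" for i in range(30)])
    with pytest.raises(MidgutError, match="perplexity"):
        mm.embed_2d(rs, perplexity=10)


# ------------------------------------------------------------ MST lineages

def _rs_from_centroids(centroids, n_per=5, spread=1e-3, seed=0):
    r = np.random.default_rng(seed)
    coords, labels = [], []
    for name, c in centroids.items():
        pts = np.asarray(c) + spread * r.normal(size=(n_per, len(c)))
        coords.append(pts)
        labels += [name] * n_per
    coords = np.vstack(coords)
    rs = ReducedSpace(coords, np.zeros((2, coords.shape[1])),
                      np.ones(coords.shape[1]),
                      [], [f"c{i}" for i in range(coords.shape[0])])
    return rs, labels


def test_collinear_clusters_give_one_lineage():
    rs, labels = _rs_from_centroids({"A": [0, 0], "B": [1, 0], "C": [2, 0]})
    lt = mm.build_lineages(rs, labels, "A")
    assert [p for p in lt.lineages] == [["A", "B", "C"]]
    assert len(lt.edges) == 2


def test_star_gives_four_lineages():
    rs, labels = _rs_from_centroids(
        {"R": [0, 0], "T1": [2, 0], "T2": [-2, 0], "T3": [0, 2], "T4": [0, -2]})
    lt = mm.build_lineages(rs, labels, "R")
    assert sorted(p[-1] for p in lt.lineages) == ["T1", "T2", "T3", "T4"]
    assert all(len(p) == 2 for p in lt.lineages)


def test_default_synthetic_lineages_match_branch_spec(default_pipeline):
    lt = default_pipeline["tree"]
    assert len(lt.edges) == len(lt.clusters) - 1
    assert sorted(p[-1] for p in lt.lineages) == ["EE", "aEC", "mEC", "pEC"]
    assert len(lt.lineages) == 4


def test_mst_matches_brute_force_enumeration(rng):
    """Greedy MST total weight equals exhaustive minimum over spanning trees."""
    names = list("ABCDEF")
    cents = {n: rng.normal(size=3) for n in names}
    edges = _mst_edges(names, cents)
    total = sum(w for _, _, w in edges)
    all_pairs = list(itertools.combinations(names, 2))
    best = np.inf
    for subset in itertools.combinations(all_pairs, len(names) - 1):
        parent = {n: n for n in names}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x
        ok = True
        w = 0.0
        for a, b in subset:
            ra, rb = find(a), find(b)
            if ra == rb:
                ok = False
                break
            parent[ra] = rb
            w += float(np.linalg.norm(cents[a] - cents[b]))
        if ok:
            best = min(best, w)
    assert total == pytest.approx(best)


def test_missing_root_raises():
    rs, labels = _rs_from_centroids({"A": [0, 0], "B": [1, 0]})
    with pytest.raises(MidgutError):
        mm.build_lineages(rs, labels, "Z")


# ------------------------------------------------------------ pseudotime

def test_pseudotime_endpoints_and_rank_order():
    rs, labels = _rs_from_centroids({"A": [0.0, 0.0], "B": [10.0, 0.0]},
                                    n_per=20, spread=0.2, seed=1)
    lt = mm.build_lineages(rs, labels, "A")
    # plant two cells exactly at the centroids
    rs.coords[0] = lt.centroids["A"]
    rs.coords[20] = lt.centroids["B"]
    pt = mm.pseudotime(rs, lt, labels=labels)
    total = np.linalg.norm(lt.centroids["A"] - lt.centroids["B"])
    t = pt.set_index("cell_id")["t"]
    assert t["c0"] == pytest.approx(0.0, abs=1e-9)
    assert t["c20"] == pytest.approx(total, abs=1e-9)
    # rank order along the straight path equals coordinate rank order
    interior = (rs.coords[:, 0] > 0) & (rs.coords[:, 0] < total)
    ids = [f"c{i}" for i in np.flatnonzero(interior)]
    xs = rs.coords[interior, 0]
    ts = t[ids].to_numpy()
    assert np.array_equal(np.argsort(xs), np.argsort(ts))


def test_pseudotime_rigid_transform_invariance(default_pipeline):
    rs, lt = default_pipeline["reduced"], default_pipeline["tree"]
    labels = default_pipeline["cm"].labels
    pt = mm.pseudotime(rs, lt, labels=labels)
    d = rs.coords.shape[1]
    r = np.random.default_rng(3)
    Q, _ = np.linalg.qr(r.normal(size=(d, d)))
    shift = r.normal(size=d)
    rs2 = ReducedSpace(rs.coords @ Q + shift, rs.loadings, rs.variance_explained,
                       rs.gene_ids, rs.cell_ids)
    lt2 = mm.build_lineages(rs2, labels, lt.root)
    pt2 = mm.pseudotime(rs2, lt2, labels=labels)
    assert lt2.lineages == lt.lineages
    np.testing.assert_allclose(pt["t"], pt2["t"], atol=1e-8)


def test_root_cells_precede_terminal_cells(default_pipeline):
    pt = default_pipeline["pseudotime"]
    labels = dict(zip(default_pipeline["cm"].cell_ids, default_pipeline["cm"].labels))
    for lineage in pt["lineage"].unique():
        if lineage == "unassigned":
            continue
        sub = pt[pt["lineage"] == lineage]
        lab = sub["cell_id"].map(labels)
        terminal = lineage.split("->")[-1]
        assert sub[lab == "ISC_EB"]["t"].mean() < sub[lab == terminal]["t"].mean()


# ------------------------------------------------------------ gene trends

def _line_pt(n=200):
    import pandas as pd
    t = np.linspace(0, 10, n)
    return pd.DataFrame({"cell_id": [f"c{i}" for i in range(n)],
                         "lineage": "L", "t": t}), t


def test_trend_constant_gene_is_flat():
    pt, t = _line_pt()
    em = _em(np.full((1, len(t)), 3.0))
    tr = mm.gene_trends(em, pt, ["g0"])
    assert tr[0].direction == "flat"


def test_trend_linear_gene_recovered_within_tolerance():
    pt, t = _line_pt()
    em = _em((5.0 - 0.3 * t)[None, :])
    tr = mm.gene_trends(em, pt, ["g0"])
    assert tr[0].direction == "decreasing"
    truth = 5.0 - 0.3 * tr[0].grid_t
    assert np.max(np.abs(tr[0].fitted - truth)) < 0.1
    assert np.all(np.diff(tr[0].grid_t) > 0)


def test_trend_increasing_label():
    pt, t = _line_pt()
    em = _em((1.0 + 0.4 * t)[None, :])
    assert mm.gene_trends(em, pt, ["g0"])[0].direction == "increasing"


def test_configured_gradient_genes_decline_along_ec_lineages(default_pipeline):
    tr = mm.gene_trends(default_pipeline["imputed"], default_pipeline["pseudotime"],
                        mm.FAO_GENES,
                        lineages=["->".join(p) for p in default_pipeline["tree"].lineages
                                  if p[-1] != "EE"])
    assert len(tr) == 24
    assert all(t.direction == "decreasing" for t in tr)


def test_too_few_cells_warns():
    import pandas as pd
    pt = pd.DataFrame({"cell_id": ["c0", "c1"], "lineage": "L", "t": [0.0, 1.0]})
    em = _em(np.ones((1, 2)))
    with pytest.warns(UserWarning):
        assert mm.gene_trends(em, pt, ["g0"]) == []
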