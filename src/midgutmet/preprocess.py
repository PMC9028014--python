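"""Loading, TPM normalization, log transform and dropout-aware imputation.

Counts are gene-length normalized to transcripts per million (TPM) using the
longest annotated transcript per gene, log2 transformed with a pseudocount,
and zeros of high-dropout genes are imputed with a cluster-wise two-component
mixture model (a desk-scale re-specification of the scImpute idea: within
clusters of similar cells, a gene's log values are modelled as a near-zero
dropout component plus an expressed component; confident dropouts are replaced
by a similarity-weighted average over cells where the gene is reliably
observed).  Imputation is restricted to genes whose dropout rate exceeds a
threshold (default 50%) to avoid over-imputation.
"""

from __future__ import annotations

import logging
import os
import warnings

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .containers import CountMatrix, ExpressionMatrix, MidgutError, ParseError

log = logging.getLogger(__name__)

FORMATS = ("mtx_triplet_dir", "dense_tsv")


# ---------------------------------------------------------------------------
# annotation

class GeneAnnotation:
    """gene id -> transcript lengths (bp); the longest length is used for TPM."""

    def __init__(self, lengths: dict):
        self.lengths = {}
        for gene, ls in lengths.items():
            ls = [int(x) for x in (ls if hasattr(ls, "__iter__") else [ls])]
            if not ls or any(x <= 0 for x in ls):
                raise MidgutError(f"gene {gene!r}: transcript lengths must be positive")
            self.lengths[gene] = ls

    def longest_length(self, gene: str) -> int:
        return max(self.lengths[gene])

    def __contains__(self, gene) -> bool:
        return gene in self.lengths

    @classmethod
    def from_tsv(cls, path) -> "GeneAnnotation":
        """Read a (gene_id, transcript_id, length) TSV; header optional."""
        lengths: dict = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ParseError(f"{path}:{ln}: expected >=2 tab-separated fields")
                gene, length_str = parts[0], parts[-1]
                if ln == 1 and not length_str.isdigit():
                    continue  # header row
                try:
                    length = int(length_str)
                except ValueError:
                    raise ParseError(f"{path}:{ln}: non-integer length {length_str!r}") from None
                lengths.setdefault(gene, []).append(length)
        return cls(lengths)

    @classmethod
    def uniform(cls, gene_ids, length: int = 1000) -> "GeneAnnotation":
        """Equal-length annotation (useful when lengths are unknown/synthetic)."""
        return cls({g: [length] for g in gene_ids})


# ---------------------------------------------------------------------------
# readers / writers

def load_counts(path, format: str = "mtx_triplet_dir") -> CountMatrix:
    """Load a count matrix; zero rows/columns are preserved, never filtered."""
    if format not in FORMATS:
        raise MidgutError(f"format must be one of {FORMATS}, got {format!r}")
    if format == "dense_tsv":
        return _load_dense_tsv(path)
    return _load_mtx_dir(path)


def _read_id_column(path):
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                out.append(line.split("\t")[0])
    return out


def _load_mtx_dir(path) -> CountMatrix:
    mtx = os.path.join(path, "matrix.mtx")
    try:
        mat = scipy.io.mmread(mtx)
    except Exception as exc:  # pragma: no cover - scipy message passthrough
        raise ParseError(f"{mtx}: {exc}") from exc
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    if not np.all(np.equal(np.mod(dense, 1), 0)):
        raise ParseError(f"{mtx}: non-integer entries")
    gene_ids = _read_id_column(os.path.join(path, "genes.tsv"))
    cell_ids = _read_id_column(os.path.join(path, "barcodes.tsv"))
    labels = None
    labels_path = os.path.join(path, "labels.tsv")
    if os.path.exists(labels_path):
        labels = _read_id_column(labels_path)
    return CountMatrix(dense.astype(np.int64), gene_ids, cell_ids, labels=labels)


def _load_dense_tsv(path) -> CountMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    vals = df.to_numpy()
    bad = ~np.equal(np.mod(vals.astype(float), 1), 0)
    if bad.any():
        row = int(np.argwhere(bad)[0][0])
        raise ParseError(f"{path}: non-integer entry on data line {row + 1}")
    return CountMatrix(vals.astype(np.int64), list(df.index), list(df.columns))


def save_counts(cm: CountMatrix, path, format: str = "mtx_triplet_dir") -> None:
    if format not in FORMATS:
        raise MidgutError(f"format must be one of {FORMATS}, got {format!r}")
    if format == "dense_tsv":
        pd.DataFrame(cm.counts, index=cm.gene_ids, columns=cm.cell_ids).to_csv(
            path, sep="\t"
        )
        return
    os.makedirs(path, exist_ok=True)
    scipy.io.mmwrite(
        os.path.join(path, "matrix.mtx"), scipy.sparse.coo_matrix(cm.counts)
    )
    with open(os.path.join(path, "genes.tsv"), "w") as fh:
        fh.writelines(g + "\n" for g in cm.gene_ids)
    with open(os.path.join(path, "barcodes.tsv"), "w") as fh:
        fh.writelines(c + "\n" for c in cm.cell_ids)
    if cm.labels is not None:
        with open(os.path.join(path, "labels.tsv"), "w") as fh:
            fh.writelines(l + "\n" for l in cm.labels)


# ---------------------------------------------------------------------------
# TPM / log2

def tpm(cm, ann: GeneAnnotation, size_factors=None, missing_length: str = "drop") -> ExpressionMatrix:
    """Length-normalize to transcripts per million.

    ``cm`` may be a CountMatrix or an ExpressionMatrix on ``counts`` scale
    (e.g. the output of :func:`midgutmet.normalization.apply_size_factors`).
    Genes without a length annotation are dropped with a warning by default
    (``missing_length='median'`` substitutes the global median length instead).
    All-zero cells yield all-zero TPM columns and are recorded in
    ``zero_cells`` rather than becoming NaN.
    """
    values = np.asarray(cm.counts if isinstance(cm, CountMatrix) else cm.values, dtype=float)
    gene_ids = list(cm.gene_ids)
    labels = getattr(cm, "labels", None)
    sf_method = getattr(cm, "size_factor_method", None)

    if size_factors is not None:
        sf = np.asarray(size_factors, dtype=float)
        if sf.shape != (values.shape[1],):
            raise MidgutError("size_factors must provide one value per cell")
        if np.any(sf <= 0):
            raise MidgutError("size_factors must be positive")
        values = values / sf

    have = [g in ann for g in gene_ids]
    if not all(have):
        missing = [g for g, h in zip(gene_ids, have) if not h]
        if missing_length == "drop":
            warnings.warn(
                f"dropping {len(missing)} gene(s) without length annotation: "
                + ", ".join(missing[:5]) + ("..." if len(missing) > 5 else "")
            )
            keep = np.asarray(have)
            values = values[keep]
            gene_ids = [g for g, h in zip(gene_ids, have) if h]
        elif missing_length == "median":
            med = int(np.median([ann.longest_length(g) for g in gene_ids if g in ann]))
            lengths = np.array(
                [ann.longest_length(g) if g in ann else med for g in gene_ids], dtype=float
            )
        else:
            raise MidgutError("missing_length must be 'drop' or 'median'")
    if all(have) or missing_length == "drop":
        lengths = np.array([ann.longest_length(g) for g in gene_ids], dtype=float)

    rate = values / (lengths[:, None] / 1000.0)
    colsum = rate.sum(axis=0)
    zero_cells = [cm.cell_ids[i] for i in np.flatnonzero(colsum == 0)]
    scalefac = np.divide(1e6, colsum, out=np.zeros_like(colsum), where=colsum > 0)
    out = rate * scalefac
    return ExpressionMatrix(
        out, gene_ids, list(cm.cell_ids), scale="tpm", labels=labels,
        size_factor_method=sf_method, zero_cells=zero_cells,
    )


def log_transform(em: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(x + pseudocount); requires TPM-scale input."""
    if em.scale != "tpm":
        raise MidgutError(f"log_transform expects scale='tpm', got {em.scale!r}")
    if np.any(em.values < 0):
        raise MidgutError("negative expression values")
    out = em.copy()
    out.values = np.log2(em.values + pseudocount)
    out.scale = "log2tpm"
    out.pseudocount = pseudocount
    return out


# ---------------------------------------------------------------------------
# dropout + imputation

def dropout_rates(cm) -> np.ndarray:
    """Per-gene fraction of cells with zero signal."""
    values = cm.counts if isinstance(cm, CountMatrix) else cm.values
    if values.shape[1] < 1:
        raise MidgutError("dropout_rates requires at least one cell")
    return np.mean(values == 0, axis=1)


def impute(
    em: ExpressionMatrix,
    n_clusters: int = 8,
    dropout_gene_threshold: float = 0.5,
    dropout_prob_threshold: float = 0.5,
    seed: int = 0,
    counts: CountMatrix | None = None,
) -> ExpressionMatrix:
    """Cluster-wise mixture-model imputation of likely dropouts.

    Cells are clustered by k-means on the top principal components of the
    log2-TPM matrix.  For each gene with dropout rate > ``dropout_gene_threshold``
    (strictly greater; genes at or below the threshold are untouched) and each
    cluster, a two-component 1-D Gaussian mixture separates a near-zero dropout
    component from an expressed component.  Zero entries whose posterior
    dropout probability exceeds ``dropout_prob_threshold`` are replaced by a
    similarity-weighted average over same-cluster cells in which the gene is
    reliably expressed.  Non-zero entries are never modified.

    ``counts`` (the raw matrix) is only used to compute dropout rates when
    given; otherwise zeros of the log matrix itself define dropout.
    """
    if em.scale != "log2tpm":
        raise MidgutError(f"impute expects scale='log2tpm', got {em.scale!r}")
    n_genes, n_cells = em.values.shape
    if n_clusters > n_cells:
        raise MidgutError(f"n_clusters={n_clusters} exceeds n_cells={n_cells}")

    rates = dropout_rates(counts if counts is not None else em)
    candidates = np.flatnonzero(rates > dropout_gene_threshold)

    out = em.copy()
    mask = np.zeros_like(em.values, dtype=bool)
    out.imputed_mask = mask
    if candidates.size == 0 or not np.any(em.values == 0):
        return out

    # cluster cells on top PCs
    X = em.values.T - em.values.mean(axis=1)
    d = min(10, n_genes, n_cells)
    # deterministic PCA via SVD
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    pcs = U[:, :d] * S[:d]
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    assign = km.fit_predict(pcs)

    for g in candidates:
        v = em.values[g]
        for c in range(n_clusters):
            idx = np.flatnonzero(assign == c)
            vc = v[idx]
            zeros = idx[vc == 0]
            if zeros.size == 0:
                continue
            if np.unique(vc).size < 2:
                continue  # gene silent (or constant) in this cluster
            try:
                gm = GaussianMixture(
                    n_components=2, random_state=seed, covariance_type="spherical",
                    reg_covar=1e-4,
                )
                gm.fit(vc.reshape(-1, 1))
            except Exception:
                log.warning("EM failed for gene %s cluster %d; left unimputed",
                            em.gene_ids[g], c)
                continue
            if not gm.converged_:
                log.warning("EM did not converge for gene %s cluster %d; left unimputed",
                            em.gene_ids[g], c)
                continue
            drop_comp = int(np.argmin(gm.means_.ravel()))
            # impute only where the expressed component dominates the cluster:
            # a gene mostly silent in a cluster is off there, not dropped out
            if gm.weights_[1 - drop_comp] <= 0.5:
                continue
            post = gm.predict_proba(vc.reshape(-1, 1))[:, drop_comp]
            p_drop = dict(zip(idx, post))
            reliable = idx[(vc > 0) & (post <= dropout_prob_threshold)]
            if reliable.size == 0:
                continue
            for cell in zeros:
                if p_drop[cell] <= dropout_prob_threshold:
                    continue
                dist2 = np.sum((pcs[reliable] - pcs[cell]) ** 2, axis=1)
                sigma2 = np.median(dist2) + 1e-12
                w = np.exp(-dist2 / (2 * sigma2))
                val = float(np.sum(w * v[reliable]) / np.sum(w))
                if val > 0:
                    out.values[g, cell] = val
                    mask[g, cell] = True
    return out
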