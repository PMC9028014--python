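"""Cell-type pathway activity scores with a label-permutation null.

For a gene g and cell type t, relative expression r(g,t) is the mean linear
(TPM-scale) expression of g over cells of type t divided by g's grand mean
over all cells; 1 is neutral and the frequency-weighted mean of r over types
is exactly 1.  A pathway's activity score in type t is the unweighted mean of
r(g,t) over the pathway's genes present in the matrix.  Significance is a
two-sided permutation test: cell type labels are shuffled B times (default
5000) and the score's distance from the neutral value 1 is compared with the
null distances, with a +1 correction so p-values are never zero.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, MidgutError, ParseError

log = logging.getLogger(__name__)


class GeneSetCollection:
    """Named gene sets (GMT-style): set name -> ordered unique gene ids."""

    def __init__(self, sets: dict, descriptions: dict | None = None):
        self.sets = {}
        for name, genes in sets.items():
            genes = list(dict.fromkeys(genes))  # dedupe, keep order
            if not genes:
                raise MidgutError(f"gene set {name!r} is empty")
            self.sets[name] = genes
        self.descriptions = dict(descriptions or {})

    def __len__(self):
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name):
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def restricted_to(self, universe) -> "GeneSetCollection":
        uni = set(universe)
        kept = {n: [g for g in gs if g in uni] for n, gs in self.sets.items()}
        kept = {n: gs for n, gs in kept.items() if gs}
        return GeneSetCollection(kept, self.descriptions)


def load_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name TAB description TAB gene...)."""
    sets, desc = {}, {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{ln}: expected name, description and >=1 gene")
            name = parts[0]
            if name in sets:
                raise ParseError(f"{path}:{ln}: duplicate set name {name!r}")
            sets[name] = parts[2:]
            desc[name] = parts[1]
    return GeneSetCollection(sets, desc)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc] + list(genes)) + "\n")


# ---------------------------------------------------------------------------

def _type_means(values: np.ndarray, labels: np.ndarray, types: list) -> np.ndarray:
    """(genes x types) matrix of per-type mean expression."""
    out = np.empty((values.shape[0], len(types)))
    for j, t in enumerate(types):
        sel = labels == t
        if not np.any(sel):
            raise MidgutError(f"cell type {t!r} has no cells")
        out[:, j] = values[:, sel].mean(axis=1)
    return out


def relative_expression(em: ExpressionMatrix, labels=None) -> pd.DataFrame:
    """Gene x cell-type relative expression (type mean / grand mean).

    Expects non-negative linear-scale values (TPM); genes with zero grand
    mean are excluded and listed in the result's ``attrs['excluded']``.
    """
    labels = labels if labels is not None else em.labels
    if labels is None:
        raise MidgutError("cell type labels are required")
    if em.scale == "log2tpm":
        raise MidgutError("relative_expression expects linear-scale values, not log2")
    if np.any(em.values < 0):
        raise MidgutError("expression values must be non-negative")
    labels = np.asarray(list(labels))
    types = sorted(set(labels.tolist()))
    if len(types) < 2:
        raise MidgutError("need at least 2 cell types")
    grand = em.values.mean(axis=1)
    keep = grand > 0
    excluded = [g for g, k in zip(em.gene_ids, keep) if not k]
    if excluded:
        log.info("relative_expression: excluding %d zero-mean gene(s)", len(excluded))
    tm = _type_means(em.values[keep], labels, types)
    r = tm / grand[keep, None]
    df = pd.DataFrame(r, index=[g for g, k in zip(em.gene_ids, keep) if k], columns=types)
    df.attrs["excluded"] = excluded
    df.attrs["type_frequencies"] = {t: float(np.mean(labels == t)) for t in types}
    return df


def pathway_scores(r: pd.DataFrame, sets: GeneSetCollection) -> pd.DataFrame:
    """Mean relative expression per (pathway, cell type) over present set genes."""
    rows = []
    present_index = set(r.index)
    for name, genes in sets.items():
        present = [g for g in genes if g in present_index]
        if not present:
            warnings.warn(f"gene set {name!r} has no genes in the matrix; row omitted")
            continue
        sub = r.loc[present]
        for t in r.columns:
            rows.append({"pathway": name, "cell_type": t,
                         "score": float(sub[t].mean()), "n_genes_used": len(present)})
    if not rows:
        raise MidgutError("no gene set overlaps the expression matrix")
    return pd.DataFrame(rows)


def permutation_test(em: ExpressionMatrix, labels=None, sets: GeneSetCollection = None,
                     B: int = 5000, seed: int = 0) -> pd.DataFrame:
    """Label-permutation significance for pathway activity scores.

    p = (1 + #{permutations with |score - 1| >= |observed - 1|}) / (B + 1),
    a two-sided test on the distance from the neutral score 1.
    """
    if B < 1:
        raise MidgutError("B must be >= 1")
    labels = np.asarray(list(labels if labels is not None else em.labels))
    table = pathway_scores(relative_expression(em, labels), sets)
    types = sorted(set(labels.tolist()))

    # membership matrix over genes with positive grand mean, row-normalized
    grand = em.values.mean(axis=1)
    keep = grand > 0
    gidx = {g: i for i, g in enumerate(np.asarray(em.gene_ids)[keep])}
    V = em.values[keep]
    names = list(dict.fromkeys(table["pathway"]))
    S = np.zeros((len(names), V.shape[0]))
    for p, name in enumerate(names):
        present = [gidx[g] for g in sets[name] if g in gidx]
        S[p, present] = 1.0 / len(present)

    obs = np.empty((len(names), len(types)))
    tab_idx = table.set_index(["pathway", "cell_type"])["score"]
    for p, name in enumerate(names):
        for j, t in enumerate(types):
            obs[p, j] = tab_idx[(name, t)]

    rng = np.random.default_rng(seed)
    grand_kept = grand[keep]
    exceed = np.zeros_like(obs)
    obs_dist = np.abs(obs - 1.0)
    lab = labels.copy()
    for _ in range(B):
        rng.shuffle(lab)
        tm = _type_means(V, lab, types)
        perm = (S @ (tm / grand_kept[:, None]))
        exceed += (np.abs(perm - 1.0) >= obs_dist - 1e-12)
    pvals = (1.0 + exceed) / (B + 1.0)

    out = table.copy()
    pv = {(names[p], types[j]): pvals[p, j]
          for p in range(len(names)) for j in range(len(types))}
    out["p_value"] = [pv[(r.pathway, r.cell_type)] for r in out.itertuples()]
    return out
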