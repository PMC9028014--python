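"""miRNA target-list consensus and category over-representation.

Predicted-target lists from several prediction sources are intersected by a
hit-count rule (a gene enters the consensus if it appears in at least k of
the N lists; the study used k=3 of N=4, which for miR-277 yields eight fatty
acid metabolism genes).  The consensus set is then tested for
over-representation in annotation categories (GO/KEGG-style gene sets) with
an upper-tail hypergeometric test; Benjamini-Hochberg adjusted p-values are
reported alongside, with significance called on the raw p < alpha criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .containers import MidgutError
from .pathway_activity import GeneSetCollection


@dataclass
class TargetLists:
    """Per-source predicted-target gene sets plus the background universe."""

    sources: dict                  # source name -> set of gene ids
    universe: set

    def __post_init__(self):
        self.sources = {name: set(genes) for name, genes in self.sources.items()}
        self.universe = set(self.universe)
        for name, genes in self.sources.items():
            outside = genes - self.universe
            if outside:
                raise MidgutError(
                    f"source {name!r}: {len(outside)} gene(s) not in the universe, "
                    f"e.g. {sorted(outside)[:3]}"
                )

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    @classmethod
    def from_files(cls, paths: dict, universe_path=None) -> "TargetLists":
        """Each list is a one-gene-per-line text file; the universe defaults to
        the union of all lists when no universe file is given."""
        sources = {name: set(_read_gene_list(p)) for name, p in paths.items()}
        if universe_path is None:
            universe = set().union(*sources.values()) if sources else set()
        else:
            universe = set(_read_gene_list(universe_path))
        return cls(sources, universe)


def _read_gene_list(path) -> list:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line.split("\t")[0])
    return out


@dataclass
class ConsensusResult:
    genes: set
    hit_counts: dict               # gene -> number of source lists containing it
    k: int
    n_sources: int


def consensus(lists: TargetLists, k: int = 3) -> ConsensusResult:
    """Genes appearing in at least k of the N source lists."""
    if not 1 <= k <= lists.n_sources:
        raise MidgutError(f"k={k} must satisfy 1 <= k <= {lists.n_sources}")
    counts: dict = {}
    for genes in lists.sources.values():
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    selected = {g for g, c in counts.items() if c >= k}
    return ConsensusResult(selected, counts, k, lists.n_sources)


def enrichment(consensus_genes, categories: GeneSetCollection, universe,
               alpha: float = 0.05) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per category.

    p = P(X >= overlap) for X ~ Hypergeom(M=|universe|, K=|category|,
    n=|consensus|).  Categories are intersected with the universe first.
    """
    universe = set(universe)
    if not universe:
        raise MidgutError("empty universe")
    cons = set(consensus_genes)
    if not cons <= universe:
        raise MidgutError("consensus genes must lie inside the universe")
    M, n = len(universe), len(cons)
    rows = []
    for name, genes in categories.items():
        cat = set(genes) & universe
        if not cat:
            continue
        K = len(cat)
        overlap = len(cat & cons)
        p = float(hypergeom.sf(overlap - 1, M, K, n))
        rows.append({"category": name, "overlap": overlap, "category_size": K,
                     "p_value": min(p, 1.0)})
    if not rows:
        raise MidgutError("no category overlaps the universe")
    df = pd.DataFrame(rows)
    df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
    df["p_adjusted"] = np.maximum(df["p_adjusted"], df["p_value"])
    df["significant"] = df["p_value"] < alpha
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)


def fao_target_table() -> pd.DataFrame:
    """The packaged eight-gene miR-277 fatty-acid-metabolism target table."""
    with resources.files("midgutmet.data").joinpath("mir277_fao_targets.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
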