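import numpy as np
import pytest

import midgutmet as mm


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic midgut atlas (1500 cells, seed 1) plus truth."""
    cm, gt = mm.simulate_midgut(seed=1)
    return cm, gt


@pytest.fixture(scope="session")
def default_pipeline(default_dataset):
    """Counts -> TPM -> log2 -> impute -> PCA -> MST lineages -> pseudotime."""
    cm, gt = default_dataset
    ann = mm.GeneAnnotation.uniform(cm.gene_ids)
    em_tpm = mm.tpm(cm, ann)
    em_log = mm.log_transform(em_tpm)
    emi = mm.impute(em_log, seed=1, counts=cm)
    rs = mm.pca_reduce(emi, d=10)
    lt = mm.build_lineages(rs, cm.labels, "ISC_EB")
    pt = mm.pseudotime(rs, lt, labels=cm.labels)
    return {"cm": cm, "gt": gt, "ann": ann, "tpm": em_tpm, "log": em_log,
            "imputed": emi, "reduced": rs, "tree": lt, "pseudotime": pt}


@pytest.fixture()
def two_type_config():
    """Small two-population config with no markers/gradients (null-style tests)."""
    return mm.SimConfig(
        n_cells=240, n_genes=200,
        cell_type_spec=[("A", 0.5, None), ("B", 0.5, None)],
        branch_spec={"A": ["B"]}, cluster_map={"A": "A", "B": "B"},
        marker_spec={}, gradient_spec=[],
        library_size_range=(1000.0, 8000.0),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
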