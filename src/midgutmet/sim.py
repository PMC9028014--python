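"""Synthetic midgut-atlas count data with ground truth.

The generator emulates the statistical structure of the adult Drosophila
midgut single-cell atlas that the analysis assumes: a progenitor population
(quiescent ISC, proliferating ISC, enteroblasts, jointly forming the ISC/EB
cluster), a differentiating-enterocyte intermediate, three regionalized
enterocyte fates (anterior/mid/posterior EC) and enteroendocrine cells;
marker genes (esg, Dl, klu, pros) expressed as high-mean programs over a
near-zero background; fatty-acid beta-oxidation-like genes declining along
pseudotime; negative-binomial counts with per-cell library-size factors and
logistic dropout.  Ground truth (true type, pseudotime, size factor, dropout
mask, pre-dropout counts) is returned so every downstream stage can be tested
without external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import CountMatrix, MidgutError

try:  # config files are YAML; the library is optional at import time
    import yaml
except ImportError:  # pragma: no cover
    yaml = None

#: the eight fatty-acid-metabolism genes tracked along pseudotime
FAO_GENES = ["CG3902", "CG4860", "CG5599", "CG9547", "CG31075", "Mtpalpha", "whd", "yip2"]

MARKERS = ["esg", "Dl", "klu", "pros"]

DEFAULT_MARKER_SPEC = {
    "esg": {"qISC", "pISC", "EB"},
    "Dl": {"pISC"},
    "klu": {"EB"},
    "pros": {"EE"},
}

DEFAULT_BRANCH_SPEC = {
    "qISC": ["pISC"],
    "pISC": ["EB", "EE"],
    "EB": ["dEC"],
    "dEC": ["aEC", "mEC", "pEC"],
}

#: fine simulated type -> cluster label used by the trajectory analysis
DEFAULT_CLUSTER_MAP = {
    "qISC": "ISC_EB", "pISC": "ISC_EB", "EB": "ISC_EB",
    "dEC": "dEC", "aEC": "aEC", "mEC": "mEC", "pEC": "pEC", "EE": "EE",
}

DEFAULT_CELL_TYPE_SPEC = [
    ("qISC", 0.08, None),
    ("pISC", 0.09, None),
    ("EB", 0.08, None),
    ("dEC", 0.15, None),
    ("aEC", 0.15, None),
    ("mEC", 0.15, None),
    ("pEC", 0.15, None),
    ("EE", 0.15, None),
]

# module mean levels (relative expected counts, before per-cell library scaling)
_ACTIVE_MARKER_MEAN = 20.0
_BACKGROUND_MARKER_MEAN = 2e-5   # near-zero, not hard 0: a marker off a cell type
_FAO_BASE_MEAN = 6.0             # essentially never yields a count, yet thresholds
                                 # remain exercisable against the active program


@dataclass
class SimConfig:
    """Configuration of the synthetic midgut dataset.

    ``cell_type_spec`` entries are (type_name, proportion, program); a program
    of ``None`` uses the built-in midgut program for that type.  Programs are
    vectors of relative expected counts per gene (they are rescaled to the
    cell's library size, so only ratios matter).
    """

    n_cells: int = 1500
    n_genes: int = 200
    cell_type_spec: list = field(default_factory=lambda: [t[:] if isinstance(t, list) else t for t in DEFAULT_CELL_TYPE_SPEC])
    branch_spec: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_BRANCH_SPEC.items()})
    cluster_map: dict = field(default_factory=lambda: dict(DEFAULT_CLUSTER_MAP))
    marker_spec: dict = field(default_factory=lambda: {k: set(v) for k, v in DEFAULT_MARKER_SPEC.items()})
    gradient_spec: list = field(default_factory=lambda: [(g, -1.0, 1.5) for g in FAO_GENES])
    nb_dispersion: float = 0.3
    dropout_midpoint: float = 0.0
    dropout_slope: float = 1.0
    library_size_range: tuple = (2000.0, 4000.0)
    seed: int = 0

    # ------------------------------------------------------------------
    def type_names(self) -> list:
        return [t[0] for t in self.cell_type_spec]

    def proportions(self) -> np.ndarray:
        return np.array([t[1] for t in self.cell_type_spec], dtype=float)

    def validate(self) -> None:
        if self.n_cells <= 0:
            raise MidgutError("n_cells must be positive")
        if self.n_genes <= 0:
            raise MidgutError("n_genes must be positive")
        names = self.type_names()
        if len(set(names)) != len(names):
            raise MidgutError("cell_type_spec: duplicate type names")
        props = self.proportions()
        if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
            raise MidgutError("cell_type_spec: proportions must be non-negative and sum to 1")
        # branch tree: every node a declared type, exactly one root
        children = [c for cs in self.branch_spec.values() for c in cs]
        if len(set(children)) != len(children):
            raise MidgutError("branch_spec: a type appears as child more than once")
        nodes = set(self.branch_spec) | set(children)
        unknown = nodes - set(names)
        if unknown:
            raise MidgutError(f"branch_spec: unknown type(s) {sorted(unknown)}")
        if nodes != set(names):
            raise MidgutError("branch_spec: every cell type must appear exactly once in the tree")
        roots = [n for n in nodes if n not in set(children)]
        if len(roots) != 1:
            raise MidgutError(f"branch_spec: expected exactly one root, found {sorted(roots)}")
        gene_ids = self.gene_ids()
        gene_set = set(gene_ids)
        for marker in self.marker_spec:
            if marker not in gene_set:
                raise MidgutError(f"marker_spec: gene {marker!r} not among the simulated genes")
        for gene, _, _ in self.gradient_spec:
            if gene not in gene_set:
                raise MidgutError(f"gradient_spec: gene {gene!r} not among the simulated genes")
        if self.nb_dispersion < 0:
            raise MidgutError("nb_dispersion must be non-negative")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise MidgutError("library_size_range must satisfy 0 < min <= max")

    @property
    def root(self) -> str:
        children = {c for cs in self.branch_spec.values() for c in cs}
        return next(n for n in (set(self.branch_spec) | children) if n not in children)

    # ------------------------------------------------------------------
    def gene_ids(self) -> list:
        """Deterministic gene panel: markers, FAO genes, program modules, background."""
        core = list(DEFAULT_MARKER_SPEC) if set(self.marker_spec) == set(DEFAULT_MARKER_SPEC) else list(self.marker_spec)
        core = core + [g for g, _, _ in self.gradient_spec if g not in core]
        n_extra = self.n_genes - len(core)
        if n_extra < 0:
            raise MidgutError("n_genes too small for the configured markers and gradient genes")
        mods = _module_sizes(self.n_genes, len(core))
        names = list(core)
        for mod, size in mods.items():
            names += [f"{mod}{i:03d}" for i in range(size)]
        return names

    def depths(self) -> dict:
        """Tree depth per type (root = 0)."""
        depth = {self.root: 0}
        frontier = [self.root]
        while frontier:
            nxt = []
            for node in frontier:
                for child in self.branch_spec.get(node, []):
                    depth[child] = depth[node] + 1
                    nxt.append(child)
            frontier = nxt
        return depth

    def pseudotime_interval(self, type_name: str) -> tuple:
        """Types occupy consecutive depth-indexed slices of [0, 1]."""
        depth = self.depths()
        dmax = max(depth.values())
        d = depth[type_name]
        return (d / (dmax + 1), (d + 1) / (dmax + 1))

    # ------------------------------------------------------------------
    def programs(self) -> np.ndarray:
        """(n_genes, n_types) matrix of relative expected counts.

        Built from marker spec, shared background means (deterministic across
        seeds) and lineage modules; explicit per-type programs in
        ``cell_type_spec`` override the built-in ones.
        """
        gene_ids = self.gene_ids()
        names = self.type_names()
        prog = np.empty((len(gene_ids), len(names)))
        bg_rng = np.random.default_rng(12345)  # program construction is seed-independent
        background = bg_rng.lognormal(mean=0.0, sigma=1.0, size=len(gene_ids))
        prog[:] = background[:, None]

        gi = {g: i for i, g in enumerate(gene_ids)}
        for marker, active in self.marker_spec.items():
            row = gi[marker]
            for j, t in enumerate(names):
                prog[row, j] = _ACTIVE_MARKER_MEAN if t in active else _BACKGROUND_MARKER_MEAN
        for gene, _, _ in self.gradient_spec:
            prog[gi[gene], :] = _FAO_BASE_MEAN

        module_levels = _module_levels(self.cluster_map, self.depths())
        for g, gene in enumerate(gene_ids):
            mod = _module_of(gene)
            if mod is None:
                continue
            for j, t in enumerate(names):
                prog[g, j] = module_levels[mod].get(t, module_levels[mod]["_default"])

        for j, (name, _, program) in enumerate(self.cell_type_spec):
            if program is not None:
                program = np.asarray(program, dtype=float)
                if program.shape != (len(gene_ids),):
                    raise MidgutError(f"program for {name!r} must have length n_genes")
                prog[:, j] = program
        return prog

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        if yaml is None:  # pragma: no cover
            raise MidgutError("pyyaml is required to read config files")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("n_cells", "n_genes", "nb_dispersion", "dropout_midpoint",
                    "dropout_slope", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "library_size_range" in raw:
            kwargs["library_size_range"] = tuple(raw["library_size_range"])
        if "cell_type_spec" in raw:
            kwargs["cell_type_spec"] = [
                (e["name"], float(e["proportion"]), e.get("program")) for e in raw["cell_type_spec"]
            ]
        if "branch_spec" in raw:
            kwargs["branch_spec"] = {k: list(v) for k, v in raw["branch_spec"].items()}
        if "cluster_map" in raw:
            kwargs["cluster_map"] = dict(raw["cluster_map"])
        if "marker_spec" in raw:
            kwargs["marker_spec"] = {k: set(v) for k, v in raw["marker_spec"].items()}
        if "gradient_spec" in raw:
            kwargs["gradient_spec"] = [
                (e["gene"], float(e["direction"]), float(e["effect"])) for e in raw["gradient_spec"]
            ]
        return cls(**kwargs)


def _module_sizes(n_genes: int, n_core: int) -> dict:
    """Partition the non-core genes into lineage modules plus background."""
    rest = n_genes - n_core
    want = {"PROG": 30, "ECM": 30, "AEC": 12, "MEC": 12, "PEC": 12, "EEM": 20}
    total = sum(want.values())
    if rest < total:
        scale = rest / total
        want = {k: max(1, int(v * scale)) if rest >= 6 else 0 for k, v in want.items()}
    want["BG"] = rest - sum(want.values())
    return want


def _module_of(gene: str):
    for mod in ("PROG", "ECM", "AEC", "MEC", "PEC", "EEM", "BG"):
        if gene.startswith(mod) and gene[len(mod):].isdigit():
            return mod if mod != "BG" else None
    return None


def _module_levels(cluster_map: dict, depths: dict) -> dict:
    """Relative mean per module per type; geometry places dEC between the
    ISC/EB cluster and the enterocyte fates, and EE off the progenitors."""
    prog_types = [t for t, c in cluster_map.items() if c == "ISC_EB"] or ["qISC", "pISC", "EB"]
    lv = {
        "PROG": {"_default": 0.4, "dEC": 1.2, "EE": 2.0, **{t: 8.0 for t in prog_types}},
        "ECM": {"_default": 8.0, "dEC": 6.0, "EE": 0.3, **{t: 0.4 for t in prog_types}},
        "AEC": {"_default": 0.1, "aEC": 16.0},
        "MEC": {"_default": 0.1, "mEC": 16.0},
        "PEC": {"_default": 0.1, "pEC": 16.0},
        "EEM": {"_default": 0.15, "EE": 10.0},
    }
    return lv


@dataclass
class GroundTruth:
    """Per-cell/entry truth retained by the generator for oracle-style tests."""

    true_type: list
    true_pseudotime: np.ndarray
    true_size_factor: np.ndarray
    dropout_mask: np.ndarray       # True where an observed zero was created by dropout
    pre_dropout_counts: np.ndarray


# ---------------------------------------------------------------------------

def _dropout_probability(mu: np.ndarray, midpoint: float, slope: float) -> np.ndarray:
    """Logistic dropout in log-mean: p = 1 / (1 + exp(slope * (log mu - midpoint)))."""
    if np.isneginf(midpoint):
        return np.zeros_like(mu)
    with np.errstate(divide="ignore"):
        z = slope * (np.log(np.where(mu > 0, mu, np.finfo(float).tiny)) - midpoint)
    return 1.0 / (1.0 + np.exp(np.clip(z, -700, 700)))


def _draw_counts(rng, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 1e-12:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * mu)
    return rng.poisson(lam)


def simulate_midgut(config: SimConfig | None = None, seed: int | None = None):
    """Draw a synthetic midgut count matrix plus ground truth.

    Counts are negative-binomial (gamma-Poisson) with per-type programs,
    pseudotime-dependent gradient genes and per-cell library-size factors,
    then thinned by logistic dropout.  Identical (config, seed) gives bitwise
    identical output.  Returns ``(CountMatrix, GroundTruth)``; the matrix's
    ``labels`` are cluster labels (fine progenitor types collapse to ISC_EB
    under the default cluster map), the fine types live in the ground truth.
    """
    config = config or SimConfig()
    config.validate()
    if seed is None:
        seed = config.seed

    gene_ids = config.gene_ids()
    names = config.type_names()
    props = config.proportions()
    n = config.n_cells

    rng_assign = np.random.default_rng([int(seed), 1])
    rng_counts = np.random.default_rng([int(seed), 2])
    rng_drop = np.random.default_rng([int(seed), 3])

    type_idx = rng_assign.choice(len(names), size=n, p=props)
    true_type = [names[i] for i in type_idx]
    intervals = {t: config.pseudotime_interval(t) for t in names}
    u = rng_assign.uniform(size=n)
    t_cell = np.array([intervals[tt][0] + u[i] * (intervals[tt][1] - intervals[tt][0])
                       for i, tt in enumerate(true_type)])

    prog = config.programs()  # genes x types
    mu = prog[:, type_idx].astype(float)
    gi = {g: i for i, g in enumerate(gene_ids)}
    for gene, direction, effect in config.gradient_spec:
        mu[gi[gene], :] *= np.exp(direction * effect * t_cell)

    lib = rng_assign.uniform(config.library_size_range[0], config.library_size_range[1], size=n)
    colsum = mu.sum(axis=0)
    mu = mu * (lib / colsum)
    true_sf = lib / np.exp(np.mean(np.log(lib)))

    pre = _draw_counts(rng_counts, mu, config.nb_dispersion)
    p_drop = _dropout_probability(mu, config.dropout_midpoint, config.dropout_slope)
    U = rng_drop.uniform(size=mu.shape)
    mask = (U < p_drop) & (pre > 0)
    counts = np.where(mask, 0, pre)

    cell_ids = [f"cell{i:05d}" for i in range(n)]
    labels = [config.cluster_map.get(t, t) for t in true_type]
    cm = CountMatrix(counts.astype(np.int64), gene_ids, cell_ids, labels=labels)
    gt = GroundTruth(true_type, t_cell, true_sf, mask, pre.astype(np.int64))
    return cm, gt


def simulate_null(config: SimConfig | None = None, seed: int | None = None) -> CountMatrix:
    """Null dataset: cells carry type labels but share one expression program.

    Labels are exchangeable by construction, so any label-contrast statistic
    (e.g. the pathway-activity permutation test) should be null-calibrated.
    """
    config = config or SimConfig()
    config.validate()
    if seed is None:
        seed = config.seed
    gene_ids = config.gene_ids()
    names = config.type_names()
    n = config.n_cells

    rng_assign = np.random.default_rng([int(seed), 11])
    rng_counts = np.random.default_rng([int(seed), 12])
    rng_drop = np.random.default_rng([int(seed), 13])

    type_idx = rng_assign.choice(len(names), size=n, p=config.proportions())
    shared = config.programs().mean(axis=1)  # one program for everyone
    mu = np.repeat(shared[:, None], n, axis=1)
    lib = rng_assign.uniform(config.library_size_range[0], config.library_size_range[1], size=n)
    mu = mu * (lib / mu.sum(axis=0))

    pre = _draw_counts(rng_counts, mu, config.nb_dispersion)
    p_drop = _dropout_probability(mu, config.dropout_midpoint, config.dropout_slope)
    mask = (rng_drop.uniform(size=mu.shape) < p_drop) & (pre > 0)
    counts = np.where(mask, 0, pre)

    cell_ids = [f"cell{i:05d}" for i in range(n)]
    labels = [config.cluster_map.get(names[i], names[i]) for i in type_idx]
    return CountMatrix(counts.astype(np.int64), gene_ids, cell_ids, labels=labels)
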