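"""Marker-gate classification of midgut progenitors.

Cells are classified by combinatorial positivity of four marker genes:
esg (all progenitors), Dl (proliferating ISC), klu (enteroblasts) and pros
(enteroendocrine, excluded up front).  Among esg+/pros- cells, Dl+/klu- is a
proliferating ISC (pISC), Dl-/klu+ an enteroblast (EB), Dl-/klu- a quiescent
ISC (qISC); Dl+/klu+ is a conflict class which is expected to be empty since
the two markers are mutually exclusive.  Positivity defaults to log2
expression > 0 on imputed values (any nonzero normalized signal); thresholds
are configurable per marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, MidgutError

CLASS_NAMES = ("qISC", "pISC", "EB", "excluded_pros", "unassigned", "conflict")

PROGENITOR_CLASSES = ("qISC", "pISC", "EB")


@dataclass
class GateSchema:
    """Markers (name -> (gene id, positivity threshold)) and ordered class rules.

    Each rule is (class name, required-positive markers, required-negative
    markers); the first matching rule assigns the class, unmatched cells fall
    into ``default_class``.
    """

    markers: dict
    rules: list
    default_class: str = "unassigned"

    def __post_init__(self):
        names = [r[0] for r in self.rules]
        if len(set(names)) != len(names):
            raise MidgutError("gate schema: duplicate class names")
        for cls, pos, neg in self.rules:
            for m in set(pos) | set(neg):
                if m not in self.markers:
                    raise MidgutError(f"gate rule {cls!r} references undeclared marker {m!r}")

    @classmethod
    def default(cls, threshold: float = 0.0) -> "GateSchema":
        markers = {m: (m, threshold) for m in ("esg", "Dl", "klu", "pros")}
        rules = [
            ("excluded_pros", {"pros"}, set()),
            ("unassigned", set(), {"esg"}),
            ("pISC", {"esg", "Dl"}, {"klu", "pros"}),
            ("EB", {"esg", "klu"}, {"Dl", "pros"}),
            ("qISC", {"esg"}, {"Dl", "klu", "pros"}),
            ("conflict", {"esg", "Dl", "klu"}, {"pros"}),
        ]
        return cls(markers, rules)

    @classmethod
    def from_tsv(cls, path, threshold: float = 0.0) -> "GateSchema":
        """Read (marker, gene, threshold) rows; class rules stay the defaults."""
        df = pd.read_csv(path, sep="\t")
        markers = {r["marker"]: (r["gene"], float(r.get("threshold", threshold)))
                   for _, r in df.iterrows()}
        base = cls.default(threshold)
        return cls(markers, base.rules)


@dataclass
class GateResult:
    classes: list                    # one class per cell
    cell_ids: list
    counts: dict = field(init=False)

    def __post_init__(self):
        if len(self.classes) != len(self.cell_ids):
            raise MidgutError("one class per cell required")
        self.counts = {}
        for c in self.classes:
            self.counts[c] = self.counts.get(c, 0) + 1


def classify_cells(em: ExpressionMatrix, schema: GateSchema | None = None) -> GateResult:
    """Assign each cell the first gate rule it satisfies."""
    schema = schema or GateSchema.default()
    positive = {}
    for marker, (gene, thr) in schema.markers.items():
        if gene not in em.gene_ids:
            raise MidgutError(f"marker gene {gene!r} missing from the expression matrix")
        positive[marker] = em.values[em.gene_index(gene)] > thr

    n = em.n_cells
    classes = [schema.default_class] * n
    assigned = np.zeros(n, dtype=bool)
    for cls, pos, neg in schema.rules:
        match = ~assigned
        for m in pos:
            match &= positive[m]
        for m in neg:
            match &= ~positive[m]
        for i in np.flatnonzero(match):
            classes[i] = cls
        assigned |= match
    return GateResult(classes, list(em.cell_ids))


def gate_summary(gr: GateResult) -> pd.DataFrame:
    """Class -> (count, fraction); counts always sum to the number of cells."""
    n = len(gr.classes)
    rows = []
    seen = list(dict.fromkeys(list(CLASS_NAMES) + sorted(gr.counts)))
    for cls in seen:
        c = gr.counts.get(cls, 0)
        rows.append({"class": cls, "count": c, "fraction": c / n if n else 0.0})
    return pd.DataFrame(rows)
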