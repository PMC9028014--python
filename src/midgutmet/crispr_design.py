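"""SpCas9 guide finding, mismatch off-target counting and multiplex
Golden-Gate sgRNA-array primer design.

Protospacers are 20-nt windows immediately followed by an NGG PAM, scanned on
both strands.  Off-targets are counted by an exhaustive Hamming scan against
a genome sequence with configurable PAMs (NGG and NAG by default) and a
mismatch budget, excluding the single best on-target site.

The multiplex plan follows an alternating type-IIS scheme: for n guides,
n - 1 PCR fragments are amplified from a tRNA-gRNA vector.  Fragment i's
forward primer carries guide i behind a BbsI (odd fragments) or SapI (even
fragments) site; all but the last reverse primer are universal primers
carrying two internal sites of the *opposite* enzyme (so the next round of
digestion re-opens the growing plasmid), and the last guide rides on a final
BbsI reverse primer with no internal sites.  Sequential digestion-ligation is
scarless: the 4-nt overhangs (TGCA on the guide side, AAAC on the tRNA side)
come from the tRNA/scaffold sequence itself, so no recognition site survives
between cassettes.  The primer constants reproduce the published design
byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .containers import MidgutError

SCAFFOLD_ANCHOR = "GTTTCAGAGCTATGCTGGAAAC"   # anneals to the gRNA core
TRNA_ANCHOR = "TGCACCAGCCGGGAATCGAACC"       # anneals to the tRNA (reverse primers)

BBSI_SITE = "GAAGAC"
SAPI_SITE = "GCTCTTC"

_FWD_PREFIX = {"BbsI": "ATAAGAAGACCT", "SapI": "ATAAGCTCTTCC"}

UNIVERSAL_REVERSE = {
    "universal_2xSapI_BbsI": "ATAAGAAGACCCAAACTGAAGAGCTGAACGGCTCTTCTGCACCAGCCGGGAATCGAACC",
    "universal_2xBbsI_SapI": "ATAAGCTCTTCAAACTGGTCTTCTGAAGGGAAGACTATGCACCAGCCGGGAATCGAACC",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_guide(guide: str) -> str:
    guide = guide.upper()
    if len(guide) != 20 or any(b not in "ACGT" for b in guide):
        raise MidgutError(f"guide must be a 20-nt ACGT string, got {guide!r}")
    return guide


# ---------------------------------------------------------------------------
# target finding

@dataclass
class GuideTarget:
    protospacer: str               # 20-nt, 5'->3' on its own strand
    pam: str                       # 3-nt NGG immediately 3' of the protospacer
    strand: str                    # '+' or '-'
    start: int                     # 0-based protospacer start on the + strand
    sequence_id: str = ""

    def __post_init__(self):
        if len(self.protospacer) != 20:
            raise MidgutError("protospacer must be 20 nt")
        if self.pam[1:] != "GG":
            raise MidgutError(f"PAM must match NGG, got {self.pam!r}")


def find_targets(seq: str, length: int = 20, sequence_id: str = "") -> list:
    """All ``length``-nt windows followed by NGG, on both strands.

    Ordered by + strand position, then strand ('+' before '-').
    """
    seq = seq.upper()
    if any(b not in "ACGTN" for b in seq):
        raise MidgutError("sequence must be over the ACGTN alphabet")
    n = len(seq)
    hits = []
    if n >= length + 3:
        for i in range(n - length - 2):
            pam = seq[i + length:i + length + 3]
            if pam[1:] == "GG" and "N" not in seq[i:i + length] and "N" not in pam:
                hits.append((i, 0, GuideTarget(seq[i:i + length], pam, "+", i, sequence_id)))
        rc = reverse_complement(seq)
        for i in range(n - length - 2):
            pam = rc[i + length:i + length + 3]
            if pam[1:] == "GG" and "N" not in rc[i:i + length] and "N" not in pam:
                # protospacer occupies + strand positions [n-(i+length), n-i)
                start_plus = n - (i + length)
                hits.append((start_plus, 1,
                             GuideTarget(rc[i:i + length], pam, "-", start_plus, sequence_id)))
    hits.sort(key=lambda h: (h[0], h[1]))
    return [h[2] for h in hits]


def _hamming_le(a: str, b: str, budget: int) -> int:
    """Mismatch count, or budget+1 once exceeded (early exit)."""
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > budget:
                return mm
    return mm


def _pam_ok(pam: str, pams) -> bool:
    return any(len(pam) == len(p) and all(q == "N" or q == b for q, b in zip(p, pam))
               for p in pams)


def count_offtargets(guide: str, genome_seqs, pams=("NGG", "NAG"),
                     max_mismatch: int = 3) -> int:
    """Number of genomic sites matching the guide with <= max_mismatch
    mismatches and an allowed PAM, excluding the single best on-target site."""
    guide = _check_guide(guide)
    if isinstance(genome_seqs, str):
        genome_seqs = {"genome": genome_seqs}
    if not isinstance(genome_seqs, dict):
        genome_seqs = {f"seq{i}": s for i, s in enumerate(genome_seqs)}
    L = len(guide)
    matches = []
    for name, seq in genome_seqs.items():
        seq = seq.upper()
        for strand_seq, strand in ((seq, "+"), (reverse_complement(seq), "-")):
            n = len(strand_seq)
            for i in range(n - L - 2):
                pam = strand_seq[i + L:i + L + 3]
                if not _pam_ok(pam, pams):
                    continue
                mm = _hamming_le(strand_seq[i:i + L], guide, max_mismatch)
                if mm <= max_mismatch:
                    matches.append((mm, name, strand, i))
    if not matches:
        return 0
    matches.sort()
    return len(matches) - 1  # drop the single best on-target site


# ---------------------------------------------------------------------------
# primers

@dataclass
class PrimerPair:
    fragment_index: int            # 1-based
    forward: str
    reverse: str
    flanking_enzyme: str           # BbsI | SapI
    internal_enzyme: str | None    # enzyme whose dual sites ride on the reverse
    forward_guide: str
    reverse_guide: str | None = None


def forward_primer(guide: str, enzyme: str) -> str:
    """Flanking-site prefix + TGCA linker + guide + gRNA-scaffold anchor."""
    guide = _check_guide(guide)
    if enzyme not in _FWD_PREFIX:
        raise MidgutError(f"enzyme must be BbsI or SapI, got {enzyme!r}")
    return _FWD_PREFIX[enzyme] + "TGCA" + guide + SCAFFOLD_ANCHOR


def reverse_primer(kind: str, final_guide: str | None = None) -> str:
    """Universal dual-internal-site reverse primers, or the final guide-bearing one."""
    if kind in UNIVERSAL_REVERSE:
        return UNIVERSAL_REVERSE[kind]
    if kind == "final_BbsI":
        if final_guide is None:
            raise MidgutError("final_BbsI reverse primer requires the final guide")
        return "ATAAGAAGACCCAAAC" + _check_guide(final_guide) + TRNA_ANCHOR
    raise MidgutError(f"unknown reverse primer kind {kind!r}")


@dataclass
class MultiplexPlan:
    guides: list                   # ordered (gene, protospacer)
    fragments: list                # list of PrimerPair, len == n_guides - 1
    assembly_order: list           # enzyme used at each ligation step
    assembled_array: str           # predicted scarless guide-array sequence


def _assemble(guides: list) -> str:
    """Predicted top-strand guide array after sequential scarless ligation.

    Each cassette is guide + scaffold + tRNA; the tRNA's 3' end supplies the
    TGCA overhang that the next guide ligates onto, and the last guide
    (delivered by the final reverse primer) is followed by the vector's own
    scaffold.
    """
    trna_top = reverse_complement(TRNA_ANCHOR)  # ends in TGCA
    parts = []
    for _, proto in guides[:-1]:
        parts.append(proto + SCAFFOLD_ANCHOR + trna_top)
    parts.append(guides[-1][1] + SCAFFOLD_ANCHOR)
    return "".join(parts)


def _count_sites(seq: str, site: str) -> int:
    rc = reverse_complement(site)
    return sum(seq.count(s) for s in {site, rc})


def plan_multiplex(guides) -> MultiplexPlan:
    """Build the full alternating BbsI/SapI primer plan for an ordered guide list.

    n guides give n-1 fragments; the last guide rides on the final BbsI
    reverse primer, which requires the last fragment to be BbsI-flanked
    (odd index), i.e. an even number of guides.
    """
    guides = [(g, _check_guide(p)) for g, p in guides]
    n = len(guides)
    if n < 2:
        raise MidgutError("multiplex plan needs at least 2 guides")
    n_frag = n - 1
    if n_frag % 2 == 0:
        raise MidgutError(
            f"{n} guides give {n_frag} fragments, whose last would be SapI-flanked; "
            "the final reverse primer is BbsI-flanked, so an even guide count is required"
        )
    fragments = []
    order = []
    for i in range(1, n_frag + 1):
        enzyme = "BbsI" if i % 2 == 1 else "SapI"
        other = "SapI" if enzyme == "BbsI" else "BbsI"
        fwd = forward_primer(guides[i - 1][1], enzyme)
        if i < n_frag:
            rev = reverse_primer(f"universal_2x{other}_{enzyme}")
            pair = PrimerPair(i, fwd, rev, enzyme, other, guides[i - 1][1])
        else:
            rev = reverse_primer("final_BbsI", final_guide=guides[-1][1])
            pair = PrimerPair(i, fwd, rev, enzyme, None, guides[i - 1][1], guides[-1][1])
        fragments.append(pair)
        order.append(enzyme)

    assembled = _assemble(guides)
    for enzyme, site in (("BbsI", BBSI_SITE), ("SapI", SAPI_SITE)):
        if _count_sites(assembled, site):
            raise MidgutError(
                f"assembly is not scarless: a {enzyme} recognition site survives "
                "in the predicted array (check guide sequences)"
            )
    return MultiplexPlan(guides, fragments, order, assembled)


# ---------------------------------------------------------------------------
# packaged fixtures (published guide and primer tables)

def load_guide_table() -> pd.DataFrame:
    """Six CRC-model guides (gene, protospacer, reported off-target count)."""
    with resources.files("midgutmet.data").joinpath("crc_guides.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_primer_table() -> pd.DataFrame:
    """Published primer strings for the six-guide CRC multiplex array."""
    with resources.files("midgutmet.data").joinpath("crc_primers.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
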