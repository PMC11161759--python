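"""Promoter extraction and IUPAC consensus cis-element scanning.

A local degenerate-consensus scanner stands in for database lookups of
transcription-factor binding sites: each IUPAC code matches its
nucleotide set exactly, both strands are searched, and presence/absence
of sites is reported (no PWM scoring).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources

from .io_formats import GeneModel, GenomeSequence, revcomp

__all__ = [
    "MotifPattern",
    "MotifHit",
    "IUPAC",
    "extract_promoter",
    "scan_motifs",
    "scan_gene_promoters",
    "load_default_myb_patterns",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class MotifPattern:
    """An IUPAC degenerate consensus, e.g. the Myb core WAACCA."""

    motif_id: str
    consensus: str

    def __post_init__(self):
        cons = self.consensus.upper()
        if not cons:
            raise ValueError(f"empty consensus for motif {self.motif_id}")
        bad = set(cons) - set(IUPAC)
        if bad:
            raise ValueError(
                f"invalid IUPAC character(s) {sorted(bad)} in {self.motif_id}")
        object.__setattr__(self, "consensus", cons)

    def regex(self) -> str:
        return "".join(c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]"
                       for c in self.consensus)


@dataclass(frozen=True)
class MotifHit:
    """One match of a consensus in a promoter window.

    ``offset`` is the hit start relative to the TSS (negative = upstream);
    ``strand`` is the strand of the match relative to the gene.
    """

    gene_id: str
    motif_id: str
    offset: int
    strand: str
    matched_seq: str


def extract_promoter(gene: GeneModel, genome, window: int = 2000) -> str:
    """The ``window`` bases immediately 5' of the gene's TSS.

    Minus-strand promoters are reverse-complemented, so position 0 is the
    window start and the TSS-proximal base is last in either case.
    Windows running off the contig edge are truncated with a warning.
    """
    if isinstance(genome, dict):
        if gene.chrom not in genome:
            raise ValueError(f"chromosome {gene.chrom!r} absent from genome")
        seq = genome[gene.chrom].sequence
    else:
        seq = genome.sequence
    loc = gene.locus
    if gene.strand == "+":
        start = loc.start - window
        if start < 0:
            warnings.warn(
                f"promoter of {gene.gene_id} truncated to {loc.start} bp "
                "at contig edge")
            start = 0
        return seq[start:loc.start]
    end = loc.end + window
    if end > len(seq):
        warnings.warn(
            f"promoter of {gene.gene_id} truncated to {len(seq) - loc.end} bp "
            "at contig edge")
        end = len(seq)
    return revcomp(seq[loc.end:end])


def scan_motifs(promoter: str, patterns, gene_id: str = "") -> list[MotifHit]:
    """All exact degenerate-consensus matches on both strands.

    Offsets are reported relative to the TSS at the window's right edge
    (so every offset is negative or zero-adjacent); hits are sorted by
    offset, then motif id, then strand.
    """
    promoter = promoter.upper()
    rc = revcomp(promoter)
    w = len(promoter)
    hits: list[MotifHit] = []
    for p in patterns:
        L = len(p.consensus)
        # lookahead so overlapping occurrences are all reported
        rx = re.compile(f"(?=({p.regex()}))")
        for mobj in rx.finditer(promoter):
            hits.append(MotifHit(gene_id, p.motif_id, mobj.start() - w, "+",
                                 mobj.group(1)))
        # minus-strand hits: scan the reverse complement, map back
        for mobj in rx.finditer(rc):
            start = w - (mobj.start() + L)
            hits.append(MotifHit(gene_id, p.motif_id, start - w, "-",
                                 promoter[start:start + L]))
    hits.sort(key=lambda h: (h.offset, h.motif_id, h.strand))
    return hits


def scan_gene_promoters(genes, genome, patterns, window: int = 2000
                        ) -> list[MotifHit]:
    hits = []
    for g in genes:
        promoter = extract_promoter(g, genome, window=window)
        hits.extend(scan_motifs(promoter, patterns, gene_id=g.gene_id))
    return hits


def load_default_myb_patterns() -> list[MotifPattern]:
    """Curated default Myb-family binding-site consensus strings.

    These are widely used plant MYB core motifs (MBS/MYBCORE variants);
    they are replaceable defaults, not a database export.
    """
    text = (resources.files("vinekit") / "data" / "myb_motifs.tsv").read_text()
    patterns = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        motif_id, consensus = line.split("\t")[:2]
        if motif_id == "motif_id":
            continue
        patterns.append(MotifPattern(motif_id, consensus))
    return patterns
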