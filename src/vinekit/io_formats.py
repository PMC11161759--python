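"""Readers and writers for the on-disk formats the toolkit touches.

Coordinate convention, stated once and honored everywhere: all in-memory
intervals are 0-based half-open; GFF3 serialization converts to 1-based
inclusive. Gene features carry an explicit strand (+/-); the unstranded
"." is reserved for structural-variant records.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeSequence",
    "Interval",
    "TranscriptModel",
    "GeneModel",
    "CountsTable",
    "SampleMetadata",
    "SVRecord",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_counts",
    "read_metadata",
    "read_sv_tsv",
    "write_sv_tsv",
    "write_newick",
    "read_newick",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

_VALID_NUC = set("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """A contig: uppercase nucleotides over {A,C,G,T,N}.

    Any other character is collapsed to N at construction time.
    """

    seq_id: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"empty sequence for contig {self.seq_id!r}")
        if set(seq) - _VALID_NUC:
            seq = re.sub(r"[^ACGTN]", "N", seq)
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open stranded genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValueError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class TranscriptModel:
    """One isoform: sorted non-overlapping exons plus an optional CDS."""

    tx_id: str
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"transcript {self.tx_id} has no exons")
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        self.cds = sorted(self.cds, key=lambda iv: iv.start)
        chroms = {iv.chrom for iv in self.exons} | {iv.chrom for iv in self.cds}
        strands = {iv.strand for iv in self.exons} | {iv.strand for iv in self.cds}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"transcript {self.tx_id} mixes chroms or strands")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping exons in transcript {self.tx_id}")
        for c in self.cds:
            if not any(e.start <= c.start and c.end <= e.end for e in self.exons):
                raise ValueError(
                    f"CDS segment outside exons in transcript {self.tx_id}"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> Interval:
        return Interval(self.chrom, self.exons[0].start, self.exons[-1].end,
                        self.strand)

    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass
class GeneModel:
    """A gene locus with one or more transcript isoforms.

    The locus always spans the union of transcript exons; it is recomputed
    at construction so serialization round-trips are exact.
    """

    gene_id: str
    transcripts: list[TranscriptModel]
    biotype: str = "protein_coding"

    def __post_init__(self):
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        chroms = {t.chrom for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"gene {self.gene_id} mixes chroms or strands")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def locus(self) -> Interval:
        start = min(t.exons[0].start for t in self.transcripts)
        end = max(t.exons[-1].end for t in self.transcripts)
        return Interval(self.chrom, start, end, self.strand)

    def exonic_intervals(self) -> list[tuple[int, int]]:
        """Merged union of all transcript exons, as (start, end) pairs."""
        ivs = sorted((e.start, e.end) for t in self.transcripts for e in t.exons)
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [(s, e) for s, e in merged]

    def exonic_bp(self) -> int:
        return sum(e - s for s, e in self.exonic_intervals())


@dataclass
class CountsTable:
    """Raw RNA-seq counts (genes x samples) with per-gene feature lengths.

    Counts are integers by contract; normalized values live in
    :class:`vinekit.expression.NormalizedMatrix`, a distinct type, so
    normalization cannot be applied twice.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    gene_length_bp: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.gene_length_bp = np.asarray(self.gene_length_bp)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match gene/sample ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be integers")
        if (self.counts < 0).any():
            raise ValueError("negative count encountered")
        if len(self.gene_ids) != len(set(self.gene_ids)):
            raise ValueError("duplicate gene id in counts table")
        if (self.gene_length_bp <= 0).any():
            bad = self.gene_ids[int(np.argmax(self.gene_length_bp <= 0))]
            raise ValueError(f"non-positive length for gene {bad}")

    def row(self, gene_id: str) -> np.ndarray:
        try:
            return self.counts[self.gene_ids.index(gene_id)]
        except ValueError:
            raise KeyError(f"gene {gene_id} not in counts table") from None


@dataclass(frozen=True)
class SampleMetadata:
    """Curated descriptors for one RNA-seq sample."""

    sample_id: str
    organ: str = "unknown"
    cultivar: str = "unknown"
    skin_color: str = "unknown"
    stage: str = "unknown"
    project: str = "unknown"

    def __post_init__(self):
        if self.skin_color not in {"black", "white", "unknown"}:
            raise ValueError(f"bad skin_color {self.skin_color!r}")


@dataclass(frozen=True)
class SVRecord:
    """A structural variant between two haplotypes (SyRI-style).

    ``interval_a`` is on haplotype 1 coordinates, ``interval_b`` on
    haplotype 2; ``size`` is the larger of the two interval lengths.
    """

    type: str
    interval_a: Interval
    interval_b: Interval

    VALID_TYPES = ("INS", "DEL", "INV", "TRA", "DUP")

    def __post_init__(self):
        if self.type not in self.VALID_TYPES:
            raise ValueError(f"unknown SV type {self.type!r}")

    @property
    def size(self) -> int:
        return max(len(self.interval_a), len(self.interval_b))


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, GenomeSequence]:
    out: dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = GenomeSequence(rec.id, str(rec.seq))
    return out


def write_fasta(seqs, path) -> None:
    records = [SeqRecord(Seq(s.sequence), id=s.seq_id, description="")
               for s in (seqs.values() if isinstance(seqs, dict) else seqs)]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(path) -> list[GeneModel]:
    """Parse a gene/mRNA/exon/CDS GFF3 hierarchy into GeneModel objects.

    Coordinates are converted from GFF3's 1-based inclusive convention to
    the internal 0-based half-open one. Features whose Parent is missing
    are rejected with an error naming the offending line. Output order is
    deterministic: (chrom, locus start, gene_id).
    """
    genes: dict[str, dict] = {}
    tx_parent: dict[str, str] = {}
    tx_feats: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"line {lineno}: expected 9 columns, got {len(cols)}")
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attrs_s = cols
            start1, end1 = int(start_s), int(end_s)
            if end1 < start1:
                raise ValueError(f"line {lineno}: end < start ({start1} > {end1})")
            attrs = dict(
                kv.split("=", 1) for kv in attrs_s.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise ValueError(f"line {lineno}: gene without ID")
                genes[gid] = {"biotype": attrs.get("biotype", "protein_coding")}
            elif ftype in {"mRNA", "transcript"}:
                tid, parent = attrs.get("ID"), attrs.get("Parent")
                if tid is None or parent is None:
                    raise ValueError(f"line {lineno}: mRNA missing ID/Parent")
                tx_parent[tid] = parent
                tx_feats[tid] = {"exons": [], "cds": [], "line": lineno}
            elif ftype in {"exon", "CDS"}:
                parent = attrs.get("Parent")
                if parent is None:
                    raise ValueError(f"line {lineno}: {ftype} without Parent")
                if parent not in tx_feats:
                    raise ValueError(
                        f"line {lineno}: {ftype} Parent {parent!r} refers to "
                        f"no known mRNA: {line}"
                    )
                if strand not in {"+", "-"}:
                    raise ValueError(f"line {lineno}: gene feature needs +/- strand")
                iv = Interval(chrom, start1 - 1, end1, strand)
                tx_feats[parent]["exons" if ftype == "exon" else "cds"].append(iv)
    # assemble
    built: dict[str, list[TranscriptModel]] = {g: [] for g in genes}
    biotypes = {g: d["biotype"] for g, d in genes.items()}
    for tid, parent in tx_parent.items():
        if parent not in genes:
            raise ValueError(
                f"line {tx_feats[tid]['line']}: mRNA {tid!r} Parent {parent!r} "
                "refers to no known gene"
            )
        feats = tx_feats[tid]
        if not feats["exons"]:
            raise ValueError(f"mRNA {tid!r} has no exons")
        built[parent].append(TranscriptModel(tid, feats["exons"], feats["cds"]))
    models = []
    for gid, txs in built.items():
        if not txs:
            raise ValueError(f"gene {gid!r} has no mRNA children")
        txs.sort(key=lambda t: (t.span.start, t.tx_id))
        models.append(GeneModel(gid, txs, biotype=biotypes[gid]))
    models.sort(key=lambda g: (g.chrom, g.locus.start, g.gene_id))
    return models


def write_gff3(models, path, source: str = "vinekit") -> None:
    """Serialize gene models as sorted 1-based inclusive GFF3."""
    models = sorted(models, key=lambda g: (g.chrom, g.locus.start, g.gene_id))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            loc = g.locus
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{loc.start + 1}\t{loc.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id};biotype={g.biotype}\n"
            )
            for t in g.transcripts:
                sp = t.span
                fh.write(
                    f"{g.chrom}\t{source}\tmRNA\t{sp.start + 1}\t{sp.end}\t.\t"
                    f"{g.strand}\t.\tID={t.tx_id};Parent={g.gene_id}\n"
                )
                for e in t.exons:
                    fh.write(
                        f"{g.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{g.strand}\t.\tParent={t.tx_id}\n"
                    )
                for c in t.cds:
                    fh.write(
                        f"{g.chrom}\t{source}\tCDS\t{c.start + 1}\t{c.end}\t.\t"
                        f"{g.strand}\t.\tParent={t.tx_id}\n"
                    )


# ---------------------------------------------------------------------------
# Counts / metadata TSV

def read_counts(path, lengths_path) -> CountsTable:
    """Read a genes x samples integer TSV joined to a gene-length TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r} in counts")
    try:
        counts = df.to_numpy(dtype=np.int64)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-integer cell in counts table: {exc}") from exc
    if not (df.to_numpy() == counts).all():
        raise ValueError("non-integer cell in counts table")
    lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    missing = [g for g in df.index if g not in lengths.index]
    if missing:
        raise ValueError(f"gene {missing[0]!r} has no length entry")
    return CountsTable(
        gene_ids=list(df.index),
        sample_ids=list(df.columns),
        counts=counts,
        gene_length_bp=lengths.reindex(df.index).to_numpy(dtype=np.int64),
    )


def read_metadata(path) -> list[SampleMetadata]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("unknown")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    known = {"sample_id", "organ", "cultivar", "skin_color", "stage", "project"}
    rows = []
    for _, r in df.iterrows():
        rows.append(SampleMetadata(**{k: r[k] for k in known if k in df.columns}))
    return rows


# ---------------------------------------------------------------------------
# Structural variants

_SV_COLS = ["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b", "type"]


def read_sv_tsv(path) -> list[SVRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_SV_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"SV TSV missing columns: {sorted(missing)}")
    out = []
    for _, r in df.iterrows():
        out.append(SVRecord(
            type=str(r["type"]),
            interval_a=Interval(str(r["chrom_a"]), int(r["start_a"]),
                                int(r["end_a"])),
            interval_b=Interval(str(r["chrom_b"]), int(r["start_b"]),
                                int(r["end_b"])),
        ))
    return out


def write_sv_tsv(records, path) -> None:
    rows = [{
        "chrom_a": r.interval_a.chrom, "start_a": r.interval_a.start,
        "end_a": r.interval_a.end, "chrom_b": r.interval_b.chrom,
        "start_b": r.interval_b.start, "end_b": r.interval_b.end,
        "type": r.type,
    } for r in records]
    pd.DataFrame(rows, columns=_SV_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Newick

def _fmt_branch(x: float) -> str:
    # shortest decimal that round-trips the float
    short = f"{x:g}"
    return short if float(short) == x else repr(x)


def _quote_label(label: str) -> str:
    if re.search(r"[\s()\[\]:;,']", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _newick_node(node) -> str:
    # node: dendropy Node
    if node.is_leaf():
        s = _quote_label(node.taxon.label if node.taxon else (node.label or ""))
    else:
        s = "(" + ",".join(_newick_node(c) for c in node.child_nodes()) + ")"
        if node.label:
            s += _quote_label(node.label)
    if node.edge.length is not None:
        s += ":" + _fmt_branch(float(node.edge.length))
    return s


def write_newick(tree, path) -> None:
    """Write a tree as Newick with branch lengths at full precision.

    Accepts a :class:`vinekit.genotyping.PhyloTree` or a dendropy Tree.
    """
    dtree = tree.to_dendropy() if hasattr(tree, "to_dendropy") else tree
    text = "(" + ",".join(
        _newick_node(c) for c in dtree.seed_node.child_nodes()
    ) + ");\n"
    with open(path, "w") as fh:
        fh.write(text)


def read_newick(path):
    """Parse a Newick file into a dendropy Tree."""
    import dendropy

    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
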