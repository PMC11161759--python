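"""Multistep gene-model reconciliation against a reference annotation.

The procedure mirrors how an IsoSeq-derived annotation is merged with a
lifted-over reference model: lifted genes are accepted at >= 80% coverage
and identity, transcripts with nonsense-mediated-decay signatures or
RT-switch (template-switching) artifact introns are discarded, putative
pseudogenes (no protein hit) and genes without expression support are
dropped, and the survivors are classified against the reference as
novel / covered / fused / split-member / ambiguous.

Overlap throughout is computed on exonic bases and on the same strand
only: the models being reconciled are transcript-derived, so exon unions
are the meaningful footprint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import GeneModel, GenomeSequence, TranscriptModel, revcomp

__all__ = [
    "MappingStats",
    "ReconcileConfig",
    "ReconcileReport",
    "acceptance_filter",
    "exonic_overlap_fraction",
    "classify_genes",
    "expression_support_filter",
    "nmd_flag",
    "rtswitch_flag",
    "cds_has_stop",
    "pseudogene_filter",
    "reconcile_pipeline",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class MappingStats:
    """Liftover coverage/identity for one transferred gene."""

    gene_id: str
    coverage: float
    identity: float

    def __post_init__(self):
        for name in ("coverage", "identity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} {v} outside [0,1] for {self.gene_id}")


@dataclass
class ReconcileConfig:
    """Thresholds of the reconciliation procedure.

    min_coverage / min_identity: liftover acceptance, closed boundaries.
    covered_reciprocal_fraction: reciprocal exonic overlap for 'covered'.
    fusion_member_fraction: fraction of a reference gene a query gene must
        cover to count as one member of a fusion (and symmetrically for
        split members).
    min_support_count / min_support_samples: expression-support rule
        (raw count >= min_support_count in >= min_support_samples samples).
    nmd_rule_nt: a stop codon more than this many spliced nucleotides
        upstream of the final exon-exon junction flags the transcript.
    rtswitch_repeat_len: direct-repeat length at intron boundaries that
        flags a template-switch artifact.
    """

    min_coverage: float = 0.80
    min_identity: float = 0.80
    covered_reciprocal_fraction: float = 0.80
    fusion_member_fraction: float = 0.50
    min_support_count: int = 5
    min_support_samples: int = 2
    nmd_rule_nt: int = 50
    rtswitch_repeat_len: int = 8

    def __post_init__(self):
        for name in ("min_coverage", "min_identity",
                     "covered_reciprocal_fraction", "fusion_member_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0,1], got {v}")
        for name in ("min_support_count", "min_support_samples",
                     "nmd_rule_nt", "rtswitch_repeat_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class ReconcileReport:
    """Per-gene class assignments plus summary counts.

    ``classes`` maps each retained query gene to one of novel / covered /
    fused / split_member / ambiguous; ``counterparts`` lists the reference
    genes behind the call.  ``split_reference`` maps each split reference
    gene to its query members (split is counted on reference genes, fused
    on query genes).  ``funnel`` records how many genes survived each
    filtering stage.
    """

    classes: dict[str, str] = field(default_factory=dict)
    counterparts: dict[str, list[str]] = field(default_factory=dict)
    split_reference: dict[str, list[str]] = field(default_factory=dict)
    funnel: dict[str, int] = field(default_factory=dict)

    @property
    def summary(self) -> dict[str, int]:
        counts = {"total": len(self.classes), "novel": 0, "covered": 0,
                  "fused": 0, "split_member": 0, "ambiguous": 0}
        for cls in self.classes.values():
            counts[cls] += 1
        counts["split"] = len(self.split_reference)
        return counts


def acceptance_filter(stats, cfg: ReconcileConfig | None = None):
    """Partition lifted genes into accepted / rejected at the 80/80 rule.

    Acceptance requires coverage >= min_coverage AND identity >=
    min_identity, both boundaries closed.
    """
    cfg = cfg or ReconcileConfig()
    accepted, rejected = [], []
    for s in stats:
        if s.coverage >= cfg.min_coverage and s.identity >= cfg.min_identity:
            accepted.append(s.gene_id)
        else:
            rejected.append(s.gene_id)
    return {"accepted": accepted, "rejected": rejected}


def _exonic_overlap_bp(a: GeneModel, b: GeneModel) -> int:
    if a.chrom != b.chrom or a.strand != b.strand:
        return 0
    bp = 0
    ivs_b = b.exonic_intervals()
    for sa, ea in a.exonic_intervals():
        for sb, eb in ivs_b:
            bp += max(0, min(ea, eb) - max(sa, sb))
    return bp


def exonic_overlap_fraction(a: GeneModel, b: GeneModel):
    """Fraction of each gene's exonic bases shared with the other.

    Returns ``(|exonic(a) n exonic(b)| / |exonic(a)|, same for b)``.
    Different strands or chromosomes give (0.0, 0.0).
    """
    bp = _exonic_overlap_bp(a, b)
    return bp / a.exonic_bp(), bp / b.exonic_bp()


def classify_genes(query, reference, cfg: ReconcileConfig | None = None
                   ) -> ReconcileReport:
    """Assign every query gene a class against the reference annotation.

    novel: no same-strand exonic overlap with any reference gene.
    fused: covers >= fusion_member_fraction of two or more reference genes.
    split_member: one of >= 2 query genes each covering >=
        fusion_member_fraction of a single reference gene (that reference
        gene is reported split).
    covered: unique reciprocal-best partner with both overlap fractions >=
        covered_reciprocal_fraction.
    ambiguous: everything else.  The assignment is a total function.
    """
    cfg = cfg or ReconcileConfig()
    for name, genes in (("query", query), ("reference", reference)):
        ids = [g.gene_id for g in genes]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate gene ids within {name} set")

    # bucket reference genes by chrom for the pair scan
    by_chrom: dict[str, list[GeneModel]] = {}
    for r in reference:
        by_chrom.setdefault(r.chrom, []).append(r)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: g.locus.start)

    # overlap fractions for every overlapping same-strand pair
    q_hits: dict[str, dict[str, tuple[int, float, float]]] = {
        g.gene_id: {} for g in query}
    r_hits: dict[str, dict[str, tuple[int, float, float]]] = {
        g.gene_id: {} for g in reference}
    for q in query:
        qloc = q.locus
        for r in by_chrom.get(q.chrom, []):
            rloc = r.locus
            if rloc.start >= qloc.end:
                break
            if rloc.end <= qloc.start or r.strand != q.strand:
                continue
            bp = _exonic_overlap_bp(q, r)
            if bp > 0:
                fq, fr = bp / q.exonic_bp(), bp / r.exonic_bp()
                q_hits[q.gene_id][r.gene_id] = (bp, fq, fr)
                r_hits[r.gene_id][q.gene_id] = (bp, fq, fr)

    def best_partner(hits: dict[str, tuple[int, float, float]]) -> str | None:
        if not hits:
            return None
        # larger overlap wins; ties broken lexicographically by id
        return min(hits, key=lambda k: (-hits[k][0], k))

    # split detection on reference genes
    split_reference: dict[str, list[str]] = {}
    for r in reference:
        members = sorted(q for q, (_, _, fr) in r_hits[r.gene_id].items()
                         if fr >= cfg.fusion_member_fraction)
        if len(members) >= 2:
            split_reference[r.gene_id] = members
    split_members = {q for members in split_reference.values() for q in members}

    report = ReconcileReport(split_reference=split_reference)
    for q in query:
        hits = q_hits[q.gene_id]
        fused_refs = sorted(r for r, (_, _, fr) in hits.items()
                            if fr >= cfg.fusion_member_fraction)
        cls, cps = "ambiguous", []
        if not hits:
            cls = "novel"
        elif len(fused_refs) >= 2:
            cls, cps = "fused", fused_refs
        elif q.gene_id in split_members:
            cls = "split_member"
            cps = sorted(r for r, members in split_reference.items()
                         if q.gene_id in members)
        else:
            r_best = best_partner(hits)
            _, fq, fr = hits[r_best]
            reciprocal = best_partner(r_hits[r_best]) == q.gene_id
            if (reciprocal and fq >= cfg.covered_reciprocal_fraction
                    and fr >= cfg.covered_reciprocal_fraction):
                cls, cps = "covered", [r_best]
            else:
                cps = sorted(hits)
        report.classes[q.gene_id] = cls
        report.counterparts[q.gene_id] = cps
    return report


def expression_support_filter(genes, counts, cfg: ReconcileConfig | None = None):
    """Keep genes expressed at >= min_support_count in >= min_support_samples.

    A gene with no counts row is unsupported.
    """
    cfg = cfg or ReconcileConfig()
    supported, unsupported = [], []
    for g in genes:
        gid = g.gene_id if isinstance(g, GeneModel) else g
        try:
            row = counts.row(gid)
        except KeyError:
            unsupported.append(gid)
            continue
        n_ok = int((row >= cfg.min_support_count).sum())
        (supported if n_ok >= cfg.min_support_samples else unsupported).append(gid)
    return {"supported": supported, "unsupported": unsupported}


def _tx_coord(tx: TranscriptModel, genomic_pos: int) -> int:
    """Map a genomic position to spliced transcript coordinates (0-based).

    ``genomic_pos`` addresses the base at that offset; exons are walked in
    transcription order (reversed for minus-strand transcripts).
    """
    exons = tx.exons if tx.strand == "+" else list(reversed(tx.exons))
    offset = 0
    for e in exons:
        if e.start <= genomic_pos < e.end:
            within = (genomic_pos - e.start if tx.strand == "+"
                      else e.end - 1 - genomic_pos)
            return offset + within
        offset += len(e)
    raise ValueError(f"position {genomic_pos} not exonic in {tx.tx_id}")


def _cds_seq(tx: TranscriptModel, genome: GenomeSequence) -> str:
    parts = [genome.sequence[c.start:c.end] for c in tx.cds]
    seq = "".join(parts)
    return seq if tx.strand == "+" else revcomp(seq)


def cds_has_stop(tx: TranscriptModel, genome: GenomeSequence) -> bool:
    """True when the CDS terminates in a canonical stop codon."""
    seq = _cds_seq(tx, genome)
    return len(seq) >= 3 and seq[-3:] in STOP_CODONS


def nmd_flag(tx: TranscriptModel, genome: GenomeSequence,
             cfg: ReconcileConfig | None = None) -> bool:
    """Flag a transcript as a likely nonsense-mediated-decay target.

    The canonical junction rule: a stop codon ending more than
    ``nmd_rule_nt`` spliced nucleotides upstream of the final exon-exon
    junction marks the transcript. Single-exon transcripts are never
    flagged. Transcripts whose CDS lacks a stop codon are not NMD; use
    :func:`cds_has_stop` to separate those.
    """
    cfg = cfg or ReconcileConfig()
    if not tx.cds:
        raise ValueError(f"transcript {tx.tx_id} has no CDS")
    cds_len = sum(len(c) for c in tx.cds)
    if cds_len % 3 != 0:
        raise ValueError(f"CDS length {cds_len} of {tx.tx_id} not a multiple of 3")
    if len(tx.exons) < 2:
        return False
    if not cds_has_stop(tx, genome):
        return False
    # spliced coordinate of the last base of the stop codon
    if tx.strand == "+":
        stop_end = _tx_coord(tx, tx.cds[-1].end - 1)
    else:
        stop_end = _tx_coord(tx, tx.cds[0].start)
    # spliced coordinate just after the last exon-exon junction
    last_exon = tx.exons[-1] if tx.strand == "+" else tx.exons[0]
    junction = tx.spliced_length() - len(last_exon)
    return junction - 1 - stop_end > cfg.nmd_rule_nt


def rtswitch_flag(tx: TranscriptModel, genome: GenomeSequence,
                  cfg: ReconcileConfig | None = None) -> bool:
    """Detect the direct-repeat signature of reverse-transcriptase
    template switching.

    For each intron the k-mer ending at the 5' exon/intron boundary
    (exonic side) is compared with the k-mer ending at the intron/3'-exon
    boundary (intronic side); identity at any intron flags the transcript.
    Strand-aware: minus-strand transcripts are examined on the reverse
    complement.
    """
    cfg = cfg or ReconcileConfig()
    k = cfg.rtswitch_repeat_len
    seq = genome.sequence
    if len(tx.exons) < 2:
        return False
    for up, down in zip(tx.exons, tx.exons[1:]):
        if tx.strand == "+":
            # exonic k-mer ends at the donor site; intronic k-mer ends at
            # the acceptor site
            exonic = seq[up.end - k:up.end]
            intronic = seq[down.start - k:down.start]
        else:
            exonic = revcomp(seq[down.start:down.start + k])
            intronic = revcomp(seq[up.end:up.end + k])
        if len(exonic) == k and "N" not in exonic and exonic == intronic:
            return True
    return False


def pseudogene_filter(genes, hits: dict[str, bool]):
    """Discard genes with no protein-database hit (putative pseudogenes).

    A gene absent from the hit table counts as no-hit and is discarded.
    """
    coding, discarded = [], []
    for g in genes:
        gid = g.gene_id if isinstance(g, GeneModel) else g
        (coding if hits.get(gid, False) else discarded).append(gid)
    return {"coding": coding, "discarded": discarded}


def reconcile_pipeline(query, reference, stats=None, counts=None, hits=None,
                       genome=None, cfg: ReconcileConfig | None = None
                       ) -> ReconcileReport:
    """Run the full filter funnel, then classify the survivors.

    Stage order: liftover acceptance (applied only to genes that carry a
    mapping-stats record; IsoSeq-native genes are exempt), NMD / RT-switch
    transcript discard (a gene is dropped only when every isoform is
    flagged or lacks a valid stop), pseudogene discard, expression
    support, then :func:`classify_genes` against the reference.  Each
    stage runs only when its input is provided, so passing ``None``
    disables that filter.
    """
    cfg = cfg or ReconcileConfig()
    retained = list(query)
    funnel = {"input": len(retained)}

    if stats is not None:
        by_id = {s.gene_id: s for s in stats}
        part = acceptance_filter(list(by_id.values()), cfg)
        rejected = set(part["rejected"])
        retained = [g for g in retained if g.gene_id not in rejected]
        funnel["liftover_accepted"] = len(retained)

    if genome is not None:
        keep = []
        for g in retained:
            genome_seq = genome[g.chrom] if isinstance(genome, dict) else genome
            clean = []
            for t in g.transcripts:
                if t.cds and not cds_has_stop(t, genome_seq):
                    continue  # invalid CDS, tracked apart from NMD
                if t.cds and nmd_flag(t, genome_seq, cfg):
                    continue
                if rtswitch_flag(t, genome_seq, cfg):
                    continue
                clean.append(t)
            if clean:
                keep.append(GeneModel(g.gene_id, clean, biotype=g.biotype))
        retained = keep
        funnel["post_nmd_rtswitch"] = len(retained)

    if hits is not None:
        coding = set(pseudogene_filter(retained, hits)["coding"])
        retained = [g for g in retained if g.gene_id in coding]
        funnel["post_pseudogene"] = len(retained)

    if counts is not None:
        supported = set(expression_support_filter(retained, counts, cfg)["supported"])
        retained = [g for g in retained if g.gene_id in supported]
        funnel["expression_supported"] = len(retained)

    funnel["retained"] = len(retained)
    if retained:
        report = classify_genes(retained, reference, cfg)
    else:
        report = ReconcileReport()
    report.funnel = funnel
    report.retained_genes = retained  # type: ignore[attr-defined]
    return report
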