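"""Shared fixtures and independent oracles used across the suite.

The oracles here deliberately avoid the library's own code paths: gene
classification is recomputed from explicit per-base position sets, and
motif scanning from a position-by-position sliding-window comparison, so
they can arbitrate the package implementations.
"""

from __future__ import annotations

import numpy as np
import pytest

from vinekit.io_formats import GeneModel, Interval, TranscriptModel
from vinekit.motifs import IUPAC


def make_gene(gene_id, chrom, exon_pairs, strand="+", cds_pairs=()):
    """Build a single-transcript gene from raw (start, end) pairs."""
    exons = [Interval(chrom, s, e, strand) for s, e in exon_pairs]
    cds = [Interval(chrom, s, e, strand) for s, e in cds_pairs]
    return GeneModel(gene_id, [TranscriptModel(f"{gene_id}.t1", exons, cds)])


def oracle_classify(query, reference, cfg):
    """Brute-force reimplementation of the gene classification rules.

    Overlaps come from explicit python sets of exonic base positions
    (per chrom+strand), not from interval arithmetic, and every pair is
    enumerated. Returns ({gene_id: class}, {split_ref: [members]}).
    """

    def base_set(g):
        out = set()
        for t in g.transcripts:
            for e in t.exons:
                out.update(range(e.start, e.end))
        return out

    qb = {g.gene_id: (g.chrom, g.strand, base_set(g)) for g in query}
    rb = {g.gene_id: (g.chrom, g.strand, base_set(g)) for g in reference}

    pair_bp = {}
    for qid, (qc, qs, qset) in qb.items():
        for rid, (rc, rs, rset) in rb.items():
            if qc == rc and qs == rs:
                bp = len(qset & rset)
                if bp:
                    pair_bp[(qid, rid)] = bp

    def frac_q(qid, rid):
        return pair_bp[(qid, rid)] / len(qb[qid][2])

    def frac_r(qid, rid):
        return pair_bp[(qid, rid)] / len(rb[rid][2])

    split_ref = {}
    for rid in rb:
        members = sorted(q for q in qb
                         if (q, rid) in pair_bp
                         and frac_r(q, rid) >= cfg.fusion_member_fraction)
        if len(members) >= 2:
            split_ref[rid] = members
    split_members = {q for ms in split_ref.values() for q in ms}

    def best_ref(qid):
        cands = [r for r in rb if (qid, r) in pair_bp]
        return min(cands, key=lambda r: (-pair_bp[(qid, r)], r)) if cands else None

    def best_query(rid):
        cands = [q for q in qb if (q, rid) in pair_bp]
        return min(cands, key=lambda q: (-pair_bp[(q, rid)], q)) if cands else None

    classes = {}
    for qid in qb:
        hits = [r for r in rb if (qid, r) in pair_bp]
        fused = [r for r in hits if frac_r(qid, r) >= cfg.fusion_member_fraction]
        if not hits:
            classes[qid] = "novel"
        elif len(fused) >= 2:
            classes[qid] = "fused"
        elif qid in split_members:
            classes[qid] = "split_member"
        else:
            r = best_ref(qid)
            if (best_query(r) == qid
                    and frac_q(qid, r) >= cfg.covered_reciprocal_fraction
                    and frac_r(qid, r) >= cfg.covered_reciprocal_fraction):
                classes[qid] = "covered"
            else:
                classes[qid] = "ambiguous"
    return classes, split_ref


def oracle_scan(seq, consensus):
    """Sliding-window motif match positions on the forward strand only."""
    seq = seq.upper()
    L = len(consensus)
    sets = [set(IUPAC[c]) for c in consensus]
    out = []
    for i in range(len(seq) - L + 1):
        if all(seq[i + k] in sets[k] for k in range(L)):
            out.append(i)
    return out


def random_genes(rng, chrom, n, span, prefix, max_len=800):
    """Genes dropped independently (overlaps allowed) for stress tests."""
    genes = []
    for i in range(n):
        start = int(rng.integers(0, span - max_len))
        n_ex = int(rng.integers(1, 4))
        exons = []
        pos = start
        for k in range(n_ex):
            el = int(rng.integers(60, 200))
            exons.append((pos, pos + el))
            pos += el + int(rng.integers(40, 120))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(make_gene(f"{prefix}{i:04d}", chrom, exons, strand))
    return genes


@pytest.fixture
def rng():
    return np.random.default_rng(0)
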