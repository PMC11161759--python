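"""Seeded synthetic-data generators with known ground truth.

Each generator emulates one of the study designs the toolkit is meant to
analyze: paired annotations with planted novel/fused/split gene
relationships, berry expression matrices with a regulator-driven gene
module silent in white-skinned samples, haplotype pairs differing by
known structural variants, and marker panels evolved along a known tree.
All randomness flows through a single numpy Generator seeded from the
config, with a fixed draw order, so identical configs give identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .genotyping import GenotypePanel, MarkerDef, PhyloTree
from .io_formats import (CountsTable, GeneModel, GenomeSequence, Interval,
                         SampleMetadata, SVRecord, TranscriptModel, revcomp)

__all__ = [
    "SimulationConfig",
    "AnnotationPairSim",
    "ExpressionSim",
    "HaplotypeSim",
    "MarkerPanelSim",
    "simulate_annotation_pair",
    "simulate_expression",
    "simulate_haplotypes",
    "simulate_marker_panel",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Knobs of every generator; defaults reproduce the fixture designs
    used throughout the test-suite.

    The expression design follows the berry case study in miniature: a
    regulator gene plus a ``module_size``-gene module expressed in black
    but essentially silent in white samples, against independent noise
    genes. ``module_r`` targets the pairwise correlation among module
    genes within the black samples; across the full black+white panel
    the realized correlation is higher because of the on/off contrast.
    """

    seed: int = 0
    # annotation pair
    n_genes: int = 50
    n_planted_novel: int = 5
    n_planted_fused: int = 2
    n_planted_split: int = 1
    # expression
    n_black: int = 40
    n_white: int = 20
    n_noise_genes: int = 500
    module_size: int = 7
    module_r: float = 0.9
    nb_dispersion: float = 0.1
    library_size_range: tuple = (0.7, 1.3)
    gene_length_range: tuple = (500, 5000)
    # haplotypes: (sv_type, size in bp) per planted event
    sv_spec: tuple = (("DEL", 1500), ("DEL", 500), ("INV", 300),
                      ("INS", 2000), ("TRA", 1200), ("DUP", 800))
    # marker panel
    n_markers: int = 400
    tree_leaves: int = 45
    branch_length_range: tuple = (0.02, 0.12)
    flank_len: int = 60

    def __post_init__(self):
        if not 0.0 < self.module_r < 1.0:
            raise ValueError("module_r must lie in (0,1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        for name in ("n_genes", "n_planted_novel", "n_planted_fused",
                     "n_planted_split", "n_black", "n_white",
                     "n_noise_genes", "module_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _random_seq(rng, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _nb_draw(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean/dispersion parameterization
    (var = mu + dispersion * mu^2)."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


# ---------------------------------------------------------------------------
# Annotation pair


@dataclass
class AnnotationPairSim:
    reference: list
    query: list
    truth: pd.DataFrame
    genome: dict


def _place_gene(gene_id: str, chrom: str, cursor: int, strand: str,
                exon_lens, intron_lens) -> tuple[GeneModel, int]:
    exons = []
    pos = cursor
    for i, el in enumerate(exon_lens):
        exons.append(Interval(chrom, pos, pos + el, strand))
        pos += el
        if i < len(exon_lens) - 1:
            pos += intron_lens[i]
    tx = TranscriptModel(f"{gene_id}.1", exons)
    return GeneModel(gene_id, [tx]), pos


def simulate_annotation_pair(cfg: SimulationConfig) -> AnnotationPairSim:
    """Reference and query annotations with planted gene relationships.

    The reference holds ``n_genes`` non-overlapping multi-exon genes; the
    query copies most of them (covered), merges adjacent pairs (fused),
    bisects some (split), and adds extra loci absent from the reference
    (novel). The truth table lists one row per planted relationship.
    """
    n_cov = cfg.n_genes - 2 * cfg.n_planted_fused - cfg.n_planted_split
    if n_cov < 0:
        raise ValueError("planted fused/split events exceed n_genes")
    rng = np.random.default_rng(cfg.seed)
    units = (["covered"] * n_cov + ["fused"] * cfg.n_planted_fused
             + ["split"] * cfg.n_planted_split
             + ["novel"] * cfg.n_planted_novel)
    rng.shuffle(units)

    chrom = "chr1"
    reference: list[GeneModel] = []
    query: list[GeneModel] = []
    truth_rows = []
    cursor = 1000
    ref_i = q_i = 0
    for kind in units:
        strand = "+" if rng.random() < 0.5 else "-"
        if kind == "covered":
            ref_i += 1
            q_i += 1
            n_ex = int(rng.integers(2, 5))
            exon_lens = rng.integers(100, 300, size=n_ex)
            intron_lens = rng.integers(80, 200, size=n_ex - 1)
            rg, cursor = _place_gene(f"PN{ref_i:05d}", chrom, cursor, strand,
                                     exon_lens, intron_lens)
            qg = GeneModel(f"Vv01g{q_i:05d}", [
                TranscriptModel(f"Vv01g{q_i:05d}.1",
                                list(rg.transcripts[0].exons))])
            reference.append(rg)
            query.append(qg)
            truth_rows.append(("covered", qg.gene_id, rg.gene_id))
        elif kind == "fused":
            # two adjacent reference genes merged into one query gene
            pair = []
            for _ in range(2):
                ref_i += 1
                exon_lens = rng.integers(100, 300, size=2)
                intron_lens = rng.integers(80, 200, size=1)
                rg, cursor = _place_gene(f"PN{ref_i:05d}", chrom, cursor,
                                         strand, exon_lens, intron_lens)
                pair.append(rg)
                cursor += int(rng.integers(150, 400))
            q_i += 1
            merged = [Interval(chrom, e.start, e.end, strand)
                      for rg in pair for e in rg.transcripts[0].exons]
            qg = GeneModel(f"Vv01g{q_i:05d}", [
                TranscriptModel(f"Vv01g{q_i:05d}.1", merged)])
            reference.extend(pair)
            query.append(qg)
            truth_rows.append(("fused", qg.gene_id,
                               ";".join(r.gene_id for r in pair)))
        elif kind == "split":
            # one reference gene covered half-and-half by two query genes
            ref_i += 1
            el = int(rng.integers(100, 300))
            exon_lens = [el] * 4
            intron_lens = rng.integers(80, 200, size=3)
            rg, cursor = _place_gene(f"PN{ref_i:05d}", chrom, cursor, strand,
                                     exon_lens, intron_lens)
            exons = rg.transcripts[0].exons
            members = []
            for half in (exons[:2], exons[2:]):
                q_i += 1
                members.append(GeneModel(f"Vv01g{q_i:05d}", [
                    TranscriptModel(f"Vv01g{q_i:05d}.1", list(half))]))
            reference.append(rg)
            query.extend(members)
            truth_rows.append(("split",
                               ";".join(m.gene_id for m in members),
                               rg.gene_id))
        else:  # novel: present in the query only
            q_i += 1
            n_ex = int(rng.integers(2, 4))
            exon_lens = rng.integers(100, 300, size=n_ex)
            intron_lens = rng.integers(80, 200, size=n_ex - 1)
            qg, cursor = _place_gene(f"Vv01g{q_i:05d}", chrom, cursor, strand,
                                     exon_lens, intron_lens)
            query.append(qg)
            truth_rows.append(("novel", qg.gene_id, ""))
        cursor += int(rng.integers(500, 1500))

    genome_len = cursor + 1000
    genome = {chrom: GenomeSequence(chrom, _random_seq(rng, genome_len))}
    truth = pd.DataFrame(truth_rows, columns=["kind", "query_ids", "ref_ids"])
    return AnnotationPairSim(reference=reference, query=query, truth=truth,
                             genome=genome)


# ---------------------------------------------------------------------------
# Expression


@dataclass
class ExpressionSim:
    counts: CountsTable
    metadata: list
    regulator: str
    module_genes: list
    truth: pd.DataFrame


def simulate_expression(cfg: SimulationConfig) -> ExpressionSim:
    """Berry expression matrix with a planted black-specific gene module.

    A latent factor per black sample drives a regulator gene and
    ``module_size`` co-regulated genes; the slope is set so the pairwise
    log-scale correlation among them within black samples is about
    ``module_r``. In white samples the module is nearly silent (mean
    counts of a few reads against thousands in black). Background genes
    are independent of color and of each other. Counts are negative
    binomial with per-sample library-size factors.
    """
    rng = np.random.default_rng(cfg.seed)
    n_samples = cfg.n_black + cfg.n_white
    module = [f"VvM{i + 1:02d}" for i in range(cfg.module_size)]
    regulator = "VvREG01"
    noise = [f"VvN{i + 1:04d}" for i in range(cfg.n_noise_genes)]
    gene_ids = [regulator] + module + noise
    n_genes = len(gene_ids)

    lengths = rng.integers(cfg.gene_length_range[0],
                           cfg.gene_length_range[1] + 1, size=n_genes)
    lib = rng.uniform(*cfg.library_size_range, size=n_samples)
    colors = np.array(["black"] * cfg.n_black + ["white"] * cfg.n_white)

    # residual log2 sd of NB noise at high counts; slope tuned for module_r
    sigma_log2 = math.sqrt(math.log1p(cfg.nb_dispersion)) / math.log(2)
    slope = sigma_log2 * math.sqrt(cfg.module_r / (1.0 - cfg.module_r))

    f = rng.normal(size=cfg.n_black)  # latent anthocyanin program activity
    mean = np.zeros((n_genes, n_samples))
    n_mod = cfg.module_size + 1
    # per-gene expression profiles as evenly spaced log2 ramps, permuted
    # across genes: controlled spread keeps within-color sample profiles
    # reproducible (they drive Pearson sample distances on so few genes)
    black_base = rng.permutation(np.linspace(13.5, 16.5, n_mod))
    white_raw = rng.permutation(np.linspace(3.0, 8.3, n_mod))
    # residual white expression: faint and constructed orthogonal (log
    # scale) to the black program profile, so the two colors form
    # distinct correlation blocks rather than sharing shape
    bc = black_base - black_base.mean()
    wc = white_raw - white_raw.mean()
    white_log = np.clip(white_raw - (wc @ bc) / (bc @ bc) * bc, 3.0, None)
    for gi in range(n_mod):  # regulator + module genes
        mean[gi, :cfg.n_black] = 2.0 ** (black_base[gi] + slope * f)
        mean[gi, cfg.n_black:] = 2.0 ** white_log[gi]
    noise_base = rng.uniform(6.0, 11.5, size=cfg.n_noise_genes)
    mean[n_mod:, :] = (2.0 ** noise_base)[:, None]

    counts = _nb_draw(rng, mean * lib[None, :], cfg.nb_dispersion)
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    metadata = [SampleMetadata(sample_id=s, organ="berry",
                               cultivar=f"cv{i + 1:03d}",
                               skin_color=colors[i], stage="ripening",
                               project="sim")
                for i, s in enumerate(sample_ids)]
    table = CountsTable(gene_ids=gene_ids, sample_ids=sample_ids,
                        counts=counts.astype(np.int64),
                        gene_length_bp=lengths.astype(np.int64))
    truth = pd.DataFrame({
        "gene_id": [regulator] + module,
        "role": ["regulator"] + ["module"] * cfg.module_size,
    })
    return ExpressionSim(counts=table, metadata=metadata, regulator=regulator,
                         module_genes=module, truth=truth)


# ---------------------------------------------------------------------------
# Haplotypes with structural variants


@dataclass
class HaplotypeSim:
    hap1_genome: dict
    hap1_genes: list
    hap2_genome: dict
    hap2_genes: list
    sv_records: list
    truth_indel_impacted: set
    truth_invtra_impacted: set
    truth_all_impacted: set


def simulate_haplotypes(cfg: SimulationConfig,
                        min_indel_size: int = 1000) -> HaplotypeSim:
    """A haplotype pair differing by the configured structural variants.

    Each planted SV overlaps one distinct gene of haplotype 1; hap2 is
    hap1 with the variants applied left to right (deletions remove
    sequence, insertions add it, inversions reverse-complement in place,
    translocations move a segment to the contig end, duplications repeat
    it in tandem). Truth sets hold the genes overlapped by qualifying
    events under the strict size rule for insertions/deletions.
    """
    rng = np.random.default_rng(cfg.seed)
    chrom = "chr1"
    n_sv = len(cfg.sv_spec)
    n_genes = max(cfg.n_genes, n_sv + 2)

    genes: list[GeneModel] = []
    cursor = 2000
    for i in range(n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(2, 4))
        exon_lens = rng.integers(150, 400, size=n_ex)
        intron_lens = rng.integers(100, 300, size=n_ex - 1)
        g, cursor = _place_gene(f"Vv01g{i + 1:05d}", chrom, cursor, strand,
                                exon_lens, intron_lens)
        genes.append(g)
        cursor += 3000  # room so SV intervals never straddle two genes

    hap1_len = cursor + 2000
    hap1_seq = _random_seq(rng, hap1_len)

    # plant one SV inside each of the first n_sv genes
    svs: list[tuple[str, int, int]] = []  # (type, a_start, size)
    truth_indel: set[str] = set()
    truth_invtra: set[str] = set()
    for (sv_type, size), gene in zip(cfg.sv_spec, genes):
        loc = gene.locus
        a_start = loc.start + int(rng.integers(0, max(1, len(loc) // 2)))
        svs.append((sv_type, a_start, size))
        if sv_type in {"INS", "DEL"} and size > min_indel_size:
            truth_indel.add(gene.gene_id)
        elif sv_type in {"INV", "TRA"}:
            truth_invtra.add(gene.gene_id)
    svs.sort(key=lambda t: t[1])

    # apply left-to-right, tracking the hap1->hap2 offset
    pieces: list[str] = []
    records: list[SVRecord] = []
    pos = 0          # cursor on hap1
    offset = 0       # hap2 - hap1 coordinate shift at the cursor
    tail_moves: list[str] = []
    for sv_type, a_start, size in svs:
        pieces.append(hap1_seq[pos:a_start])
        b_start = a_start + offset
        if sv_type == "DEL":
            records.append(SVRecord("DEL",
                                    Interval(chrom, a_start, a_start + size),
                                    Interval(chrom, b_start, b_start + 1)))
            pos = a_start + size
            offset -= size
        elif sv_type == "INS":
            pieces.append(_random_seq(rng, size))
            records.append(SVRecord("INS",
                                    Interval(chrom, a_start, a_start + 1),
                                    Interval(chrom, b_start, b_start + size)))
            pos = a_start
            offset += size
        elif sv_type == "INV":
            pieces.append(revcomp(hap1_seq[a_start:a_start + size]))
            records.append(SVRecord("INV",
                                    Interval(chrom, a_start, a_start + size),
                                    Interval(chrom, b_start, b_start + size)))
            pos = a_start + size
        elif sv_type == "DUP":
            seg = hap1_seq[a_start:a_start + size]
            pieces.append(seg + seg)
            records.append(SVRecord("DUP",
                                    Interval(chrom, a_start, a_start + size),
                                    Interval(chrom, b_start,
                                             b_start + 2 * size)))
            pos = a_start + size
            offset += size
        else:  # TRA: segment moved to the contig end
            tail_moves.append(hap1_seq[a_start:a_start + size])
            records.append(SVRecord("TRA",
                                    Interval(chrom, a_start, a_start + size),
                                    Interval(chrom, b_start, b_start + 1)))
            pos = a_start + size
            offset -= size
    pieces.append(hap1_seq[pos:])
    hap2_seq = "".join(pieces)
    tra_positions = []
    for seg in tail_moves:
        tra_positions.append(len(hap2_seq))
        hap2_seq += seg
    # rewrite TRA destination intervals now that the end is known
    fixed_records = []
    ti = 0
    for r in records:
        if r.type == "TRA":
            start = tra_positions[ti]
            ti += 1
            fixed_records.append(SVRecord("TRA", r.interval_a,
                                          Interval(chrom, start,
                                                   start + len(r.interval_a))))
        else:
            fixed_records.append(r)
    records = fixed_records

    # lift gene models to hap2 where they survive intact
    disrupted = {(t, s, z) for t, s, z in svs if t in {"DEL", "TRA"}}
    hap2_genes = []
    for g in genes:
        loc = g.locus
        if any(s < loc.end and s + z > loc.start for t, s, z in disrupted):
            continue
        shift = 0
        for t, s, z in svs:
            if s >= loc.start:
                continue
            if t in {"DEL", "TRA"}:
                shift -= z
            elif t in {"INS", "DUP"}:
                shift += z
        exons = [Interval(chrom, e.start + shift, e.end + shift, g.strand)
                 for e in g.transcripts[0].exons]
        hap2_genes.append(GeneModel(g.gene_id, [
            TranscriptModel(f"{g.gene_id}.1", exons)]))

    return HaplotypeSim(
        hap1_genome={chrom: GenomeSequence(chrom, hap1_seq)},
        hap1_genes=genes,
        hap2_genome={chrom: GenomeSequence(chrom, hap2_seq)},
        hap2_genes=hap2_genes,
        sv_records=records,
        truth_indel_impacted=truth_indel,
        truth_invtra_impacted=truth_invtra,
        truth_all_impacted=truth_indel | truth_invtra,
    )


# ---------------------------------------------------------------------------
# Marker panel on a known tree


@dataclass
class MarkerPanelSim:
    markers: list
    panel: GenotypePanel
    query_genome: dict
    true_tree: PhyloTree
    source_leaf: str


def simulate_marker_panel(cfg: SimulationConfig) -> MarkerPanelSim:
    """A genotype panel evolved along a random tree, plus a query assembly.

    Leaves are homozygous accessions; each marker's binary allele state
    evolves down the tree with a per-branch flip probability equal to the
    branch length (capped at 0.45). One leaf's alleles are embedded in a
    synthetic assembly as flank+allele+flank sites so in-silico calling
    can be scored against the generator.
    """
    if cfg.tree_leaves < 4:
        raise ValueError("tree_leaves must be >= 4")
    rng = np.random.default_rng(cfg.seed)
    labels = [f"ACC{i + 1:03d}" for i in range(cfg.tree_leaves)]

    tns = dendropy.TaxonNamespace()
    subtrees = []
    for lab in labels:
        node = dendropy.Node(taxon=tns.require_taxon(lab))
        subtrees.append(node)
    lo, hi = cfg.branch_length_range
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        a, b = subtrees[i], subtrees[j]
        parent = dendropy.Node()
        a.edge.length = float(rng.uniform(lo, hi))
        b.edge.length = float(rng.uniform(lo, hi))
        parent.add_child(a)
        parent.add_child(b)
        subtrees = [s for k, s in enumerate(subtrees) if k not in (i, j)]
        subtrees.append(parent)
    dtree = dendropy.Tree(taxon_namespace=tns)
    dtree.seed_node = subtrees[0]
    dtree.is_rooted = False
    tree = PhyloTree(dtree)

    # evolve binary allele states root-to-leaves
    states: dict[int, np.ndarray] = {}
    root = dtree.seed_node
    states[id(root)] = rng.integers(0, 2, size=cfg.n_markers)
    leaf_states: dict[str, np.ndarray] = {}
    for node in dtree.preorder_node_iter():
        if node is root:
            continue
        p_flip = min(0.45, float(node.edge.length))
        flips = rng.random(cfg.n_markers) < p_flip
        state = np.where(flips, 1 - states[id(node.parent_node)],
                         states[id(node.parent_node)])
        states[id(node)] = state
        if node.is_leaf():
            leaf_states[node.taxon.label] = state

    dosages = np.column_stack([2.0 * leaf_states[lab] for lab in labels])
    marker_ids = [f"SNP{i + 1:05d}" for i in range(cfg.n_markers)]
    panel = GenotypePanel(marker_ids, labels, dosages)

    # marker definitions with random unique flanks
    markers = []
    for mid in marker_ids:
        left = _random_seq(rng, cfg.flank_len)
        right = _random_seq(rng, cfg.flank_len)
        ref, alt = rng.choice(4, size=2, replace=False)
        markers.append(MarkerDef(mid, left, right,
                                 (str(_BASES[ref]), str(_BASES[alt]))))

    # embed one leaf's alleles into a synthetic query assembly
    source_leaf = labels[int(rng.integers(0, len(labels)))]
    src = leaf_states[source_leaf]
    parts = []
    for m, allele_idx in zip(markers, src):
        parts.append(_random_seq(rng, 20))
        parts.append(m.left_flank + m.alleles[int(allele_idx)] + m.right_flank)
    parts.append(_random_seq(rng, 20))
    query_genome = {"qcontig": GenomeSequence("qcontig", "".join(parts))}

    return MarkerPanelSim(markers=markers, panel=panel,
                          query_genome=query_genome, true_tree=tree,
                          source_leaf=source_leaf)
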