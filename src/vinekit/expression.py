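"""Expression StatTools: normalization, profiling, correlation mining,
clustered heatmaps, weighted co-expression networks, and qPCR ddCt math.

Normalization is TPM — counts divided by feature length, column-rescaled
to one million — the canonical correction for both library size and gene
length. Correlations are, by convention throughout the toolkit, computed
on log2(TPM + 1), which stabilizes variance across the several orders of
magnitude a berry transcriptome spans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist, squareform

from .io_formats import CountsTable, SampleMetadata

__all__ = [
    "NormalizedMatrix",
    "CorrelationResult",
    "CorrelationNetwork",
    "ProfileSeries",
    "QPCRRecord",
    "normalize_tpm",
    "log_transform",
    "expression_profile",
    "pearson",
    "correlation_gene_finder",
    "correlation_circle_layout",
    "cluster_heatmap",
    "correlation_network",
    "ddct_relative_expression",
]


@dataclass
class NormalizedMatrix:
    """TPM (or log2-TPM) expression values; distinct from raw counts."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    log_transformed: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match gene/sample ids")
        if (self.values < 0).any():
            raise ValueError("negative normalized value")

    def row(self, gene_id: str) -> np.ndarray:
        try:
            return self.values[self.gene_ids.index(gene_id)]
        except ValueError:
            raise KeyError(f"gene {gene_id} not in matrix") from None

    def subset_samples(self, sample_ids) -> "NormalizedMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return NormalizedMatrix(self.gene_ids, list(sample_ids),
                                self.values[:, idx], self.log_transformed)


@dataclass(frozen=True)
class CorrelationResult:
    gene_id: str
    r: float
    n: int

    def __post_init__(self):
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"correlation {self.r} outside [-1,1]")
        if self.n < 3:
            raise ValueError("correlation needs n >= 3")

    @property
    def sign(self) -> str:
        return "positive" if self.r >= 0 else "negative"


@dataclass
class CorrelationNetwork:
    """Weighted co-expression network: weight = |r|^beta in [0, 1]."""

    nodes: list[str]
    edges: list[tuple[str, str, float]]
    beta: float
    signed: bool = False


@dataclass
class ProfileSeries:
    """Per-condition mean/sd/count for one gene (the line-chart profiler)."""

    gene_id: str
    conditions: list[str]
    mean: list[float]
    sd: list[float]
    n: list[int]


@dataclass
class QPCRRecord:
    """Ct replicates for a target gene plus its reference genes."""

    gene: str
    sample_group: str
    ct_replicates: list[float]
    reference_gene_cts: dict[str, list[float]]

    def __post_init__(self):
        if not self.ct_replicates:
            raise ValueError("empty Ct replicate list")
        if any(c <= 0 for c in self.ct_replicates):
            raise ValueError("Ct values must be positive")
        for ref, cts in self.reference_gene_cts.items():
            if not cts:
                raise ValueError(f"empty Ct list for reference gene {ref}")

    def delta_ct(self) -> float:
        """Mean target Ct minus the across-reference mean of per-reference
        mean Cts."""
        target = float(np.mean(self.ct_replicates))
        ref_means = [float(np.mean(cts))
                     for cts in self.reference_gene_cts.values()]
        return target - float(np.mean(ref_means)) if ref_means else target


def normalize_tpm(counts: CountsTable) -> NormalizedMatrix:
    """Transcripts-per-million normalization.

    value_gs = (count_gs / length_g) / sum_g'(count_g's / length_g') * 1e6,
    so every sample column sums to one million.
    """
    rate = counts.counts / counts.gene_length_bp[:, None]
    col = rate.sum(axis=0)
    zero = np.flatnonzero(col == 0)
    if zero.size:
        raise ValueError(
            f"sample {counts.sample_ids[int(zero[0])]!r} has an all-zero column")
    return NormalizedMatrix(list(counts.gene_ids), list(counts.sample_ids),
                            rate / col * 1e6)


def log_transform(m: NormalizedMatrix) -> NormalizedMatrix:
    """log2(value + 1); refuses to transform twice."""
    if m.log_transformed:
        raise ValueError("matrix is already log-transformed")
    return NormalizedMatrix(m.gene_ids, m.sample_ids, np.log2(m.values + 1.0),
                            log_transformed=True)


def expression_profile(m: NormalizedMatrix, metadata, gene_id: str,
                       group_by: str) -> ProfileSeries:
    """Per-group mean/sd/count of one gene's expression.

    Groups follow the order in which their labels first appear in the
    metadata. Sample sd uses ddof=1; single-sample groups report sd 0.
    Groups with no matching sample are omitted with a warning.
    """
    import warnings

    row = m.row(gene_id)
    meta = {s.sample_id: s for s in metadata}
    order: list[str] = []
    groups: dict[str, list[float]] = {}
    for s in metadata:
        label = getattr(s, group_by)
        if label not in groups:
            order.append(label)
            groups[label] = []
    for j, sid in enumerate(m.sample_ids):
        s = meta.get(sid)
        if s is None:
            continue
        groups[getattr(s, group_by)].append(float(row[j]))
    conditions, means, sds, ns = [], [], [], []
    for label in order:
        vals = groups[label]
        if not vals:
            warnings.warn(f"group {label!r} has no samples; omitted")
            continue
        conditions.append(label)
        means.append(float(np.mean(vals)))
        sds.append(float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0)
        ns.append(len(vals))
    return ProfileSeries(gene_id, conditions, means, sds, ns)


def pearson(x, y) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3).

    Zero-variance input is undefined and raises; callers that tolerate it
    (the finder) handle the exclusion themselves.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson needs two equal-length vectors")
    if x.size < 3:
        raise ValueError("pearson needs n >= 3")
    xc, yc = x - x.mean(), y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0:
        raise ValueError("zero-variance vector")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def _corr_against(m: NormalizedMatrix, target_gene: str) -> dict[str, float]:
    """Pearson r of every finite-variance gene against the target row."""
    t = m.row(target_gene)
    vals = m.values
    tc = t - t.mean()
    tnorm = math.sqrt(float(tc @ tc))
    if tnorm == 0:
        raise ValueError(f"target gene {target_gene} has zero variance")
    centered = vals - vals.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (centered @ tc) / (norms * tnorm)
    out = {}
    for gid, ri in zip(m.gene_ids, r):
        if gid != target_gene and np.isfinite(ri):
            out[gid] = float(np.clip(ri, -1.0, 1.0))
    return out


def correlation_gene_finder(m: NormalizedMatrix, target_gene: str,
                            threshold: float = 0.75, mode: str = "threshold",
                            top_k: int = 10) -> list[CorrelationResult]:
    """Genes co-expressed with a target gene.

    mode="threshold": all genes with r >= threshold ("positive" finder) or
    r <= -threshold ("negative"; pass mode="negative").  mode="topk": the
    top_k genes ranked by r.  Output is sorted by \\|r\\| descending, ties
    by gene id; zero-variance genes are silently excluded.
    """
    n = len(m.sample_ids)
    corr = _corr_against(m, target_gene)
    ranked = sorted(corr.items(), key=lambda kv: (-abs(kv[1]), kv[0]))
    if mode in {"threshold", "negative"}:
        if not 0.0 < threshold <= 1.0:
            raise ValueError(f"threshold {threshold} outside (0,1]")
        if mode == "threshold":
            hits = [(g, r) for g, r in ranked if r >= threshold]
        else:
            hits = [(g, r) for g, r in ranked if r <= -threshold]
    elif mode == "topk":
        hits = sorted(corr.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
        hits.sort(key=lambda kv: (-abs(kv[1]), kv[0]))
    else:
        raise ValueError(f"unknown finder mode {mode!r}")
    return [CorrelationResult(g, r, n) for g, r in hits]


def correlation_circle_layout(results, target_gene: str):
    """Polar layout for the correlation circle: radius = 1 - r.

    The target sits at the origin; the most correlated genes sit closest
    to it. Angles are spread uniformly by rank, starting at 0.
    """
    if not results:
        raise ValueError("no correlation results to lay out")
    out = [(target_gene, 0.0, 0.0)]
    step = 2 * math.pi / len(results)
    for i, res in enumerate(results):
        radius = min(max(1.0 - res.r, 0.0), 2.0)
        out.append((res.gene_id, radius, i * step))
    return out


def _pearson_distance_matrix(rows: np.ndarray, labels) -> np.ndarray:
    sd = rows.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(
            f"zero-variance row {labels[int(flat[0])]!r} under pearson distance")
    r = np.corrcoef(rows)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return squareform(np.clip(d, 0.0, 2.0), checks=False)


def cluster_heatmap(m: NormalizedMatrix, genes=None, samples=None,
                    distance: str = "euclidean", method: str = "average"):
    """Two-way agglomerative clustering for an expression heat map.

    distance: "euclidean" on expression levels, or "pearson" (1 - r).
    Returns a dict with scipy linkage matrices and leaf orders for both
    axes plus the reordered value matrix. Deterministic for fixed input.
    """
    genes = list(genes) if genes is not None else list(m.gene_ids)
    samples = list(samples) if samples is not None else list(m.sample_ids)
    if len(genes) < 2 or len(samples) < 2:
        raise ValueError("clustering needs >= 2 genes and >= 2 samples")
    gi = [m.gene_ids.index(g) for g in genes]
    si = [m.sample_ids.index(s) for s in samples]
    sub = m.values[np.ix_(gi, si)]

    def axis_linkage(rows, labels):
        if distance == "euclidean":
            d = pdist(rows, metric="euclidean")
        elif distance == "pearson":
            d = _pearson_distance_matrix(rows, labels)
        else:
            raise ValueError(f"unknown distance {distance!r}")
        return linkage(d, method=method)

    gene_z = axis_linkage(sub, genes)
    sample_z = axis_linkage(sub.T, samples)
    g_order = list(leaves_list(gene_z))
    s_order = list(leaves_list(sample_z))
    return {
        "gene_linkage": gene_z,
        "sample_linkage": sample_z,
        "gene_order": [genes[i] for i in g_order],
        "sample_order": [samples[i] for i in s_order],
        "matrix": sub[np.ix_(g_order, s_order)],
    }


def correlation_network(m: NormalizedMatrix, seed_genes, beta: float = 6.0,
                        min_weight: float = 0.3) -> CorrelationNetwork:
    """Soft-thresholded weighted co-expression network around seed genes.

    Edge weight = |r|^beta.  Nodes are the seeds plus every gene tied to a
    seed at weight >= min_weight; edges include seed-neighbor and
    neighbor-neighbor pairs above min_weight.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    seeds = list(seed_genes)
    for s in seeds:
        m.row(s)  # raises KeyError on absent seed
    neighbors: set[str] = set()
    weights_cache: dict[str, dict[str, float]] = {}
    for s in seeds:
        corr = _corr_against(m, s)
        weights_cache[s] = corr
        for g, r in corr.items():
            if abs(r) ** beta >= min_weight:
                neighbors.add(g)
    nodes = sorted(set(seeds) | neighbors)
    idx = {g: m.gene_ids.index(g) for g in nodes}
    sub = m.values[[idx[g] for g in nodes]]
    r_mat = np.corrcoef(sub)
    edges = []
    for i, gi_ in enumerate(nodes):
        for j in range(i + 1, len(nodes)):
            r = r_mat[i, j]
            if not np.isfinite(r):
                continue
            w = abs(float(r)) ** beta
            if w >= min_weight:
                edges.append((gi_, nodes[j], w))
    return CorrelationNetwork(nodes=nodes, edges=edges, beta=beta)


def ddct_relative_expression(test: QPCRRecord, calibrator: QPCRRecord) -> float:
    """Relative expression by the 2^(-ddCt) method.

    dCt = mean target Ct minus the mean of per-reference-gene mean Cts;
    ddCt = dCt_test - dCt_calibrator; the fold change is 2^(-ddCt).
    """
    if test.gene != calibrator.gene:
        raise ValueError("test and calibrator records must share the gene")
    if set(test.reference_gene_cts) != set(calibrator.reference_gene_cts):
        raise ValueError("reference-gene sets differ between records")
    ddct = test.delta_ct() - calibrator.delta_ct()
    return float(2.0 ** (-ddct))
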