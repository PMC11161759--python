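"""In-silico SNP genotyping and neighbor-joining phylogenetics.

Marker alleles are retrieved from an assembly by exact flank matching
(both strands), genotype distances are identity-by-state on allele
dosages, and trees are built by the Saitou-Nei neighbor-joining
agglomeration with deterministic tie-breaking — exact on additive
distance matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .io_formats import GenomeSequence, revcomp

__all__ = [
    "MarkerDef",
    "GenotypePanel",
    "DistanceMatrix",
    "PhyloTree",
    "call_marker",
    "calls_to_dosage",
    "ibs_distance",
    "closest_accessions",
    "robust_marker_subset",
    "build_distance_matrix",
    "neighbor_joining",
]


@dataclass(frozen=True)
class MarkerDef:
    """One SNP marker: flanking sequences plus its two alleles."""

    marker_id: str
    left_flank: str
    right_flank: str
    alleles: tuple[str, str]

    def __post_init__(self):
        object.__setattr__(self, "left_flank", self.left_flank.upper())
        object.__setattr__(self, "right_flank", self.right_flank.upper())
        object.__setattr__(self, "alleles",
                           tuple(a.upper() for a in self.alleles))
        if len(self.alleles) != 2 or self.alleles[0] == self.alleles[1]:
            raise ValueError(f"marker {self.marker_id}: alleles must be "
                             "two distinct bases")
        if any(len(a) != 1 or a not in "ACGT" for a in self.alleles):
            raise ValueError(f"marker {self.marker_id}: non-SNP allele")


@dataclass
class GenotypePanel:
    """Allele-dosage matrix: one row per marker, one column per accession.

    Dosages count the alt allele: 0, 1, 2, or NaN for missing.
    """

    marker_ids: list[str]
    accessions: list[str]
    dosages: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.marker_ids), len(self.accessions)):
            raise ValueError("dosage shape does not match marker/accession ids")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    def column(self, accession: str) -> np.ndarray:
        return self.dosages[:, self.accessions.index(accession)]

    @classmethod
    def from_tsv(cls, path) -> "GenotypePanel":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.dosages, index=self.marker_ids,
                          columns=self.accessions)
        df.to_csv(path, sep="\t", na_rep="NA",
                  float_format=lambda v: f"{v:g}")


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.matrix < -1e-12).any():
            raise ValueError("negative distance")


class PhyloTree:
    """Unrooted binary tree with branch lengths, backed by dendropy.

    Negative neighbor-joining branch estimates are clamped to zero; the
    total clamped deficit is kept on ``clamped_deficit``.
    """

    def __init__(self, tree: dendropy.Tree, clamped_deficit: float = 0.0):
        self._tree = tree
        self.clamped_deficit = clamped_deficit

    def to_dendropy(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(leaf.taxon.label for leaf in self._tree.leaf_node_iter())

    def as_newick(self) -> str:
        from .io_formats import _newick_node

        return "(" + ",".join(
            _newick_node(c) for c in self._tree.seed_node.child_nodes()
        ) + ");"

    def path_distances(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length distances along the tree."""
        pdm = self._tree.phylogenetic_distance_matrix()
        labels = self.leaf_labels
        taxa = {t.label: t for t in self._tree.taxon_namespace}
        n = len(labels)
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = pdm.distance(taxa[labels[i]],
                                                 taxa[labels[j]])
        return DistanceMatrix(labels, m)

    def are_sisters(self, label_a: str, label_b: str) -> bool:
        """True when the two leaves form a cherry (share one internal node)."""
        nodes = {leaf.taxon.label: leaf for leaf in self._tree.leaf_node_iter()}
        return nodes[label_a].parent_node is nodes[label_b].parent_node


# ---------------------------------------------------------------------------
# Marker calling

def _count_occurrences(haystack: str, needle: str) -> int:
    count = start = 0
    while True:
        pos = haystack.find(needle, start)
        if pos < 0:
            return count
        count += 1
        start = pos + 1


def call_marker(assembly, marker: MarkerDef, k: int = 50) -> str:
    """Retrieve a marker allele from an assembly by exact flank matching.

    The probe is ``left_flank[-k:] + allele + right_flank[:k]`` searched
    on both strands of every contig. Exactly one allele matching at
    exactly one locus gives that call ('ref' / 'alt'); zero matches or
    any ambiguity gives 'missing'.
    """
    contigs = (assembly.values() if isinstance(assembly, dict)
               else [assembly] if isinstance(assembly, GenomeSequence)
               else list(assembly))
    if k > len(marker.left_flank) or k > len(marker.right_flank):
        raise ValueError(f"k={k} exceeds flank length of {marker.marker_id}")
    left = marker.left_flank[-k:]
    right = marker.right_flank[:k]
    hit_counts = []
    for allele in marker.alleles:
        probe = left + allele + right
        rc = revcomp(probe)
        n = 0
        for contig in contigs:
            n += _count_occurrences(contig.sequence, probe)
            if rc != probe:
                n += _count_occurrences(contig.sequence, rc)
        hit_counts.append(n)
    ref_n, alt_n = hit_counts
    if ref_n == 1 and alt_n == 0:
        return "ref"
    if alt_n == 1 and ref_n == 0:
        return "alt"
    return "missing"


def calls_to_dosage(calls) -> np.ndarray:
    """Encode haploid assembly calls as alt-allele dosages {0, 2, NaN}."""
    code = {"ref": 0.0, "alt": 2.0, "missing": np.nan}
    return np.array([code[c] for c in calls], dtype=float)


# ---------------------------------------------------------------------------
# Distances and ranking

def ibs_distance(x, y, min_shared: int = 100) -> float:
    """Identity-by-state distance between two dosage vectors.

    Mean of |dose_x - dose_y| / 2 over markers non-missing in both;
    NaN when fewer than ``min_shared`` markers are shared.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("dosage vectors differ in length")
    shared = ~np.isnan(x) & ~np.isnan(y)
    if shared.sum() < max(min_shared, 1):
        return float("nan")
    return float(np.abs(x[shared] - y[shared]).mean() / 2.0)


def closest_accessions(panel: GenotypePanel, query, n: int = 40,
                       min_shared: int = 100):
    """Rank panel accessions by IBS distance to a query dosage vector.

    Returns up to ``n`` (accession, distance) pairs, distance ascending,
    ties by label; accessions sharing too few markers are skipped.
    """
    query = np.asarray(query, dtype=float)
    ranked = []
    for acc in panel.accessions:
        d = ibs_distance(query, panel.column(acc), min_shared=min_shared)
        if not np.isnan(d):
            ranked.append((acc, d))
    ranked.sort(key=lambda t: (t[1], t[0]))
    return ranked[:n]


def robust_marker_subset(panel: GenotypePanel, query_dosage_vectors,
                         min_call_rate: float = 0.95) -> list[int]:
    """Indices of markers called in every query and >= min_call_rate of
    the panel."""
    rate = 1.0 - np.isnan(panel.dosages).mean(axis=1)
    ok = rate >= min_call_rate
    for q in query_dosage_vectors:
        ok &= ~np.isnan(np.asarray(q, dtype=float))
    return [i for i in range(len(panel.marker_ids)) if ok[i]]


def build_distance_matrix(panel: GenotypePanel, extra=None,
                          accessions=None, min_shared: int = 100
                          ) -> DistanceMatrix:
    """IBS distance matrix over panel accessions plus optional extra
    genotypes (label -> dosage vector)."""
    cols = {acc: panel.column(acc)
            for acc in (accessions or panel.accessions)}
    if extra:
        cols.update({k: np.asarray(v, dtype=float) for k, v in extra.items()})
    labels = sorted(cols)
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = ibs_distance(cols[labels[i]], cols[labels[j]],
                             min_shared=min_shared)
            if np.isnan(d):
                raise ValueError(
                    f"too few shared markers between {labels[i]} and {labels[j]}")
            m[i, j] = m[j, i] = d
    return DistanceMatrix(labels, m)


# ---------------------------------------------------------------------------
# Neighbor joining

def neighbor_joining(d: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimizing the Q criterion is joined; exact
    ties are resolved toward the lexicographically lowest label pair.
    Negative branch-length estimates are clamped to zero with the deficit
    accumulated on the result. Additive matrices are recovered exactly.
    """
    n0 = len(d.labels)
    if n0 < 3:
        raise ValueError("neighbor joining needs >= 3 labels")
    tns = dendropy.TaxonNamespace()
    nodes: dict[str, dendropy.Node] = {}
    for label in d.labels:
        node = dendropy.Node(taxon=tns.require_taxon(label))
        nodes[label] = node

    active = list(d.labels)
    dist: dict[frozenset, float] = {}
    for i in range(n0):
        for j in range(i + 1, n0):
            dist[frozenset((d.labels[i], d.labels[j]))] = float(
                d.matrix[i, j])

    clamped = 0.0

    def get(a, b):
        return dist[frozenset((a, b))]

    def clamp(x):
        nonlocal clamped
        if x < 0:
            clamped += -x
            return 0.0
        return x

    next_internal = 0
    while len(active) > 3:
        m = len(active)
        r = {a: sum(get(a, b) for b in active if b != a) for a in active}
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                a, b = active[i], active[j]
                q = (m - 2) * get(a, b) - r[a] - r[b]
                key = (q, *sorted((a, b)))
                if best is None or key < best:
                    best = key
                    pair = (a, b)
        a, b = pair
        dab = get(a, b)
        la = clamp(dab / 2.0 + (r[a] - r[b]) / (2.0 * (m - 2)))
        lb = clamp(dab - (dab / 2.0 + (r[a] - r[b]) / (2.0 * (m - 2))))
        u = f"\x00internal{next_internal}"
        next_internal += 1
        unode = dendropy.Node()
        for child, length in ((a, la), (b, lb)):
            nodes[child].edge.length = length
            unode.add_child(nodes[child])
        nodes[u] = unode
        for c in active:
            if c in (a, b):
                continue
            duc = max(0.0, (get(a, c) + get(b, c) - dab) / 2.0)
            dist[frozenset((u, c))] = duc
        active = [c for c in active if c not in (a, b)] + [u]

    # join the last three at a single degree-3 center (three-point formulas)
    x, y, z = active
    dxy, dxz, dyz = get(x, y), get(x, z), get(y, z)
    lx = clamp((dxy + dxz - dyz) / 2.0)
    ly = clamp((dxy + dyz - dxz) / 2.0)
    lz = clamp((dxz + dyz - dxy) / 2.0)
    center = dendropy.Node()
    for child, length in ((x, lx), (y, ly), (z, lz)):
        nodes[child].edge.length = length
        center.add_child(nodes[child])

    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    return PhyloTree(tree, clamped_deficit=clamped)
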