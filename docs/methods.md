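# Methods and design notes

This note records the models behind each vinekit component, the defaults
that matter, what the synthetic generators do and do not emulate, and the
numerical conventions. Nothing here states a result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Coordinates and formats

All in-memory intervals are 0-based half-open; GFF3 I/O converts to
1-based inclusive at the file boundary, once, in `io_formats`. Gene
features require an explicit `+`/`-` strand; only structural-variant
records may be unstranded. Raw counts (`CountsTable`) and normalized
values (`NormalizedMatrix`) are distinct types so normalization cannot be
applied twice; the log₂(TPM+1) transform is likewise flagged and refuses
re-application. Newick output writes branch lengths with the shortest
decimal that round-trips the float, so serialize → parse → serialize is
byte-stable.

## Annotation reconciliation

The pipeline mirrors a multistep annotation build: a transcript-derived
query model is filtered, then classified against a reference annotation
on the same assembly.

Thresholds (all in `ReconcileConfig`):

| parameter | default | rationale |
|---|---|---|
| `min_coverage`, `min_identity` | 0.80 | the liftover acceptance rule; boundaries closed because a "threshold of acceptance" reads as inclusive, and closed bounds are cleanly testable |
| `covered_reciprocal_fraction` | 0.80 | "covered" mirrors the same 80% figure, applied reciprocally to both exonic footprints |
| `fusion_member_fraction` | 0.50 | a fusion/split member must cover half of its counterpart; prevents incidental UTR overlap from manufacturing fusions |
| `min_support_count`, `min_support_samples` | 5, 2 | expression support means ≥ 5 raw reads in ≥ 2 samples; no published cutoff exists for this step, so it is configurable |
| `nmd_rule_nt` | 50 | the canonical 50-nt exon-junction rule for nonsense-mediated decay |
| `rtswitch_repeat_len` | 8 | direct repeats of ≥ 8 bp spanning an exon/intron boundary are the classic template-switch signature |

Design choices that were genuinely open:

- Overlap is computed on **exonic bases, same strand only**. The models
  being reconciled are transcript-derived, so exon unions are the
  meaningful footprint; span overlap would conflate intron-nested genes
  with real conflicts.
- *Split* is attributed to reference genes and *fused* to query genes
  (one query gene absorbing several reference genes is a fusion; one
  reference gene shattering into several query genes is a split). Query
  genes participating in a split are classed `split_member`, so the
  per-gene classes still partition the retained query set.
- A gene is dropped by the NMD/RT-switch stage only when **every** isoform
  is flagged (or lacks a valid stop codon); flagged isoforms are removed,
  clean ones keep the gene alive. CDSs that do not end in a stop codon are
  treated as invalid rather than as decay targets.
- Reciprocal-best ties break by larger overlap, then lexicographic gene
  id — determinism over biological nuance, which at a tie does not exist.
- Each pipeline stage runs only when its input (mapping stats, genome,
  hit table, counts) is supplied, so "filters off" is simply the
  classification alone. Acceptance filtering applies only to genes that
  carry a mapping-stats record; native (non-lifted) genes are exempt.

Classification is verified in the tests against an independent oracle
that recomputes every overlap from explicit per-base position sets.

## Expression StatTools

Normalization is TPM: the platform description fixes only "library size
and gene feature length", and TPM is the canonical scheme correcting for
both while giving columns a fixed total (10⁶), which the tests assert to
1e-6 relative. Correlations default to log₂(TPM+1): berry expression
spans about four orders of magnitude and the log stabilizes variance;
raw-TPM remains available by skipping the transform.

The correlation gene finder excludes zero-variance genes silently (it is
an exploratory tool); clustering instead raises on zero-variance rows
under Pearson distance, naming the offending gene (a silent drop there
would change the dendrogram the user asked for). Hierarchical clustering
uses scipy's agglomerative implementation, average linkage by default,
with Pearson distance defined as 1 − r. Network weights follow the
soft-threshold convention w = |r|^β with β = 6 and an unsigned adjacency
by default.

ΔΔCt: per-reference-gene Ct replicates are averaged first, then averaged
across reference genes, ΔCt = Ct_target − Ct_ref, ΔΔCt relative to the
calibrator, fold change 2^(−ΔΔCt).

Group profiles use the sample standard deviation (ddof = 1); a
single-sample group reports sd 0 rather than NaN so line charts with
error bars degrade gracefully.

## SV impact

"Exceeding 1 kb" is strict (> 1000 bp) for insertions/deletions;
inversions and translocations have no size filter; duplications are
reported but excluded from both summary counts. Overlap is on the gene
span by default with an exon-only switch — a 1.5-kb deletion through an
intron still rearranges the locus, so span is the conservative default.
Impact is computed per haplotype side; summaries count distinct genes.

## Genotyping and neighbor joining

Marker retrieval is exact matching of `flank[-50:] + allele + flank[:50]`
on both strands of every contig: deterministic and adequate for
assemblies of the same species; a mismatch-tolerant mode is out of scope.
A call requires exactly one allele matching at exactly one locus —
anything else is `missing`, so paralogous placements degrade to missing
data rather than wrong calls.

The distance is identity-by-state on alt-allele dosages (haploid
assemblies encoded 0/2), averaging |Δdose|/2 over markers non-missing in
both genotypes, with a minimum shared-marker count (default 100) below
which the distance is reported missing. The "robust subset" used before
tree building keeps markers called in every query assembly with panel
call rate ≥ 95%.

Neighbor joining is the standard Saitou–Nei agglomeration on the Q
criterion. Exact ties are broken toward the lexicographically lowest
label pair, so degenerate (e.g. ultrametric-equidistant) inputs produce
one documented tree. Negative branch-length estimates are clamped to zero
and the total deficit is kept on the result (`clamped_deficit`). On
additive matrices the algorithm is exact; the tests verify Robinson–
Foulds distance 0 and path-length recovery within 1e-9 on random 8-leaf
trees, with dendropy handling tree comparison (never the reconstruction).

## Promoter motifs

Promoters are the 2,000 bp immediately 5′ of the TSS (the window length
is a convention, not a published figure), reverse-complemented for
minus-strand genes, truncated with a warning at contig edges. Scanning is
exact degenerate-consensus matching over IUPAC codes on both strands —
sites are reported present/absent, not scored — and overlapping
occurrences are all reported. The bundled Myb-family patterns
(`data/myb_motifs.tsv`) are curated textbook consensus strings
(MYBCORE, MBS, MYBPLANT, …), intended as replaceable defaults, not a
database export. The scanner is checked against a position-by-position
sliding-window oracle.

## Synthetic data generators

All generators draw from one `numpy.random.default_rng(seed)` stream in a
fixed order, so identical configs give byte-identical outputs.

**Annotation pairs.** The reference holds `n_genes` non-overlapping
multi-exon genes; the query copies most (covered), merges adjacent pairs
(fused — each merged reference gene is covered 100%), bisects four-exon
genes into two two-exon members (split — each member covers exactly half,
meeting the 0.5 member fraction at its closed boundary), and adds
query-only loci (novel). Defaults (50 genes, 5/2/1 planted events) are
the fixture the acceptance checks use.

**Berry expression.** 40 black + 20 white samples over 1 regulator + 7
module genes + 500 background genes. A latent factor per black sample
drives the regulator and module; the slope is set from the
negative-binomial log-scale noise so the pairwise module correlation
*within black samples* is `module_r` (0.9). Across the full panel the
realized correlation is higher still because the module is on in black
and nearly silent in white — as in the real anthocyanin pathway.
Per-gene log-expression profiles are evenly spaced ramps randomly
permuted across genes rather than i.i.d. draws: with only eight genes, a
sample-to-sample Pearson distance rests entirely on profile
reproducibility, and an unlucky compressed draw would make within-colour
correlation collapse for reasons that have nothing to do with the
method. The faint white-sample profile is constructed orthogonal (log
scale) to the black profile, so the two colours form distinct
correlation blocks; white module expression stays below 1% of black mean
TPM (asserted in the tests). Counts are negative binomial
(var = μ + 0.1 μ²) with per-sample library-size factors in [0.7, 1.3].
What this generator does **not** emulate: batch/project structure,
organ- or stage-dependent programs, correlated background modules,
GC/length biases, or partial penetrance of skin colour (every white
sample is fully "off"). Passing tests therefore show the tools behave
correctly under a clean two-state design, not that real berry panels
separate this cleanly.

**Haplotypes.** Each configured SV is planted inside one distinct gene of
haplotype 1 with enough intergenic room that events never straddle two
genes, then applied left-to-right to build haplotype 2 (deletions remove,
insertions add, inversions reverse-complement in place, translocations
move segments to the contig end, duplications repeat in tandem). Truth
sets are derived from the planting intent and the strict 1-kb rule. The
haplotype-2 gene lift is approximate for genes containing an internal
insertion or duplication (coordinates shift only from upstream events);
impact calling operates on the haplotype-1 side, which is exact.

**Marker panels.** A random binary tree (default 45 leaves) with branch
lengths in [0.02, 0.12]; binary allele states evolve root-to-leaf with a
per-branch flip probability equal to the branch length (capped at 0.45);
leaves are homozygous accessions (dosage 0/2). One leaf's alleles are
embedded into a synthetic assembly as flank+allele+flank sites with
random spacers. There is no back-mutation bookkeeping or rate
heterogeneity — adequate for topology-recovery and placement tests, not
a sequence-evolution model.

## Problem sizes

The test suite and acceptance script run, per invocation: one 50-gene
reconciliation fixture plus 20 oracle-comparison pairs of ≤ 100 genes;
100 replicates of the 508-gene × 60-sample expression fixture; 50 random
TPM matrices; 100 random 8-leaf additive matrices; one 45-accession ×
400-marker genotyping chain; six planted SVs; and 100 random 10-kb
promoters against the sliding-window oracle. These sizes make every
planted-truth check exact while keeping a full run in the tens of
seconds.

## Known limitations

- Reconciliation classes are assigned per gene, not per transcript; a
  gene that is simultaneously a fusion member and a split member reports
  the fusion (checked first).
- The liftover itself, protein-database searches, read mapping and
  quantification are consumed as inputs, never executed.
- Marker calling tolerates no mismatches; diverged accessions will
  return `missing` rather than approximate calls.
- The ΔΔCt implementation assumes amplification efficiency 2 exactly.
- `cluster_heatmap` is deterministic but inherits scipy's merge ordering
  for exactly tied distances beyond the first pair.
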