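# Methods

This note documents the models and numerical choices behind `scglioma`:
what each stage assumes, which defaults matter, what the synthetic
generator does and does not emulate, and the known limits.

## Molecule collapse

The collapse operates on records `(barcode, umi, gene, reads)` and is
read-conserving: every stage merges records, only the degenerate-barcode
filter discards reads, and `CollapseReport` itemizes that removal so
`reads_in == reads_out + degenerate_reads_removed` always holds.

*Degenerate barcodes.* Any `N`, or a run of five or more `G` (poly-G is
the signature of a failed synthesis cycle on two-channel sequencers).
A run of exactly four G survives.

*Truncated barcodes.* A bead synthesized one base short produces an
11-nt barcode; the read's 12-nt barcode field then captures the UMI's
first base and the UMI field shifts into the poly-T tail, so its last
base reads `T`. The detector requires at least 20 apparent molecules
(distinct UMI–gene pairs, counted before UMI collapse) and a terminal-T
fraction strictly above 90%. Each truncated cell appears as up to four
observed 12-nt barcodes (11-nt prefix + each possible UMI head base);
all four are corrected onto the same 11-nt barcode. The generator emits
truncation as the exact inverse of this correction, so repair is tested
as a round trip.

*Hamming-1 collapse.* Within a (barcode, gene) group, UMIs within
Hamming distance 1 merge. Order is deterministic: candidates descend by
read count with lexicographic tie-break, and a candidate merges into the
earliest-accepted survivor within distance 1 (UMI-tools-style directional
practice). Barcode collapse mirrors this at the barcode level: the
absorbed barcode needs ≥ 20 UMI–gene pairs and ≥ 75% overlap —
|intersection| / |smaller set|, the permissive reading that absorbs
error barcodes into true ones. The retained barcode is the member with
more pairs. Candidate pairs are found by enumerating the 3·L Hamming-1
variants of each sequence (packed 2-bit codes), not by all-pairs scan;
the contract is identical, the cost linear. After barcode collapse the
UMI collapse runs once more on the corrected barcodes.

*Cell calling.* Barcodes are ranked by total reads; on the
(rank fraction, cumulative read fraction) curve the knee is the point of
maximum perpendicular distance to the chord through the endpoints. Every
called barcode has at least as many reads as every uncalled one. A flat
curve (all totals equal, max distance < 1e-9) has no knee: all barcodes
are called. Consequence: a zero-error table of uniform-depth real cells
has no knee either, so exact-recovery checks run with calling disabled;
the knee is exercised where it is meaningful, on bimodal read totals
with an ambient/error barcode tail.

## QC

Four rules: mitochondrial molecule fraction > 0.10; gene-body/exon
molecule ratio > 1.5 (supplied per cell — an exon-only expression matrix
cannot produce it, so the generator simulates it with a dead-cell
subpopulation at ratio ≈ 2); and two-sided deviations beyond 2.5 SD of
the sample mean for reads-per-molecule and molecules-per-gene. Mean and
SD (population SD, ddof 0) are computed once on the full pre-filter
sample, not iteratively — so the two absolute rules are idempotent on
their output while the SD rules are defined relative to the original
cohort. Every removed cell carries the set of rules it violated.

## Gene scoring and clustering

Counts are column-normalized to sum to one only for this stage. Detected
genes are ordered by mean normalized expression and binned in 50s (the
last, smaller bin uses its own max); a gene's score is its bin's maximum
detection frequency minus its own, and scores > 0.15 define markers.
Ties at the bin max score 0. The score is invariant to per-cell depth
rescaling by construction.

The k-NN graph (k = 20) uses Spearman correlation over marker genes;
ties in correlation break by cell order, making the graph deterministic.
Cells with all-constant expression get correlation 0 by convention.
Clustering is the Phenograph construction: Jaccard reweighting of the
k-NN edges by neighborhood overlap, then Louvain modularity optimization
(seeded). Labels are re-indexed by each community's smallest member so
partitions are stable up to content. The force-directed view is a
Fruchterman–Reingold spring layout of the symmetrized adjacency with
default parameters; t-SNE/UMAP are out of scope — the module exports the
1 − correlation distance matrix instead.

Modularity optimization over-partitions featureless graphs: if cells
within a population are statistically exchangeable and low-dimensional
(few informative genes), the within-population k-NN graph is an
unstructured random graph whose best modularity partition splits it. We
measured this directly — 200-cell Gaussian blobs shatter in 2–10
dimensions (ARI 0.2–0.75) but stay whole at 50 dimensions. A green
clustering test therefore establishes recovery for populations with
realistically rich programs (the generator gives each population a
graded transcriptome-wide fold-change field plus ≥ ~30 focal markers),
not for populations distinguished by a handful of genes.

## Malignancy score

Per cell: log2(counts-per-thousand + 1), averaged over each autosome's
retained genes (expressed in ≥ 100 cells per sample; chr6 HLA genes
excluded because HLA expression in myeloid cells mimics a copy-number
variant; X/Y/MT never form columns). Rows are z-scored (zero-SD rows are
an error) and PCA (SVD of the column-centered z-matrix — the rows are
already standardized, so this is covariance PCA) yields candidate axes
PC1, PC2, PC1+PC2.

Axis auto-selection: the axis whose chromosome **loading vector** has
the highest excess kurtosis. A whole-chromosome gain/loss concentrates
the loading on the few altered chromosomes, while lineage-expression
axes spread small loadings over many; in our measurements this selects
the aneuploidy axis in every signal world, including ones where both a
1-D-separation silhouette and a cell-level burden correlation mis-select
a lineage axis (those two remain in the result as diagnostics). The sign
convention makes the aneuploidy-burdened side positive (orientation by
correlation with the per-cell z-profile kurtosis). A manual `axis=`
override preserves the per-tumor choice the original procedure made by
inspection.

Transformed call: an exact 1-D two-means split of the scores gives two
components; a cluster is transformed when its median score exceeds the
midpoint of the component means. The call is gated on the component
contrast — the two components' mean z-profiles must differ by ≥ 1.5 on
some chromosome. Calibration: a 1.5× dosage shift moves its chromosome
by ≈ 2–4 z-units (signal worlds measured 1.85–4.0), while diploid
population structure stays near ≈ 1 (nulls 0.88–1.4). Known limit: a
diploid population whose expression program happens to concentrate on
one chromosome is indistinguishable from dosage by expression alone (one
of ten measured null worlds reached contrast 1.97); this is precisely
why the score is backed by bulk WGS.

Relative chromosomal expression divides each transformed cell's
chromosome means by the untransformed-population average; bulk WGS copy
number is 2 · (tumor share / germline share) / median-over-chromosomes.
When more than half the chromosomes are diploid, the median ratio pins
diploid chromosomes to exactly 2.

## Differential expression and drop-out

The single canonical test, used by every signature operation: for gene
g, k of n in-group cells detect it; the null rate is the out-group
plug-in q = (k_out + 1)/(n_out + 1); p = min(1, 2·min(P[X ≥ k],
P[X ≤ k])) for X ~ Binomial(n, q); effect = the ratio of the same
+1-pseudocount frequencies; BH correction across genes. The "eightfold"
pervasiveness threshold is applied to this detection-frequency fold (the
whole DE framework operates on detection frequencies). Because q is a
plug-in, the test is anti-conservative for balanced group splits
(measured 0.14 rejections at p < 0.05 under a 100/100 null) and
near-nominal-to-conservative in the cluster-vs-rest regime it is used in
(0.052 at 40/160; discreteness dominates for small in-groups). The
pervasiveness ranking keeps genes with fold ≥ 8 and p_adj < 0.01 and
sorts by in-group detection frequency; the product score (frequency ×
fold) is reported alongside.

The drop-out curve is per-gene (mean CPT, detection frequency) with an
isotonic regression of frequency on log mean CPT as the expected curve —
monotone by construction, no parametric sigmoid is assumed. Deviation =
expected − observed; subpopulation-restricted genes sit above the 95th
percentile of uniform genes' deviations in simulation. Under Poisson
sampling at fixed depth the curve matches 1 − exp(−λ) to within 0.03
(sup-norm on the rate grid).

## Signatures

*Reference correlation.* Spearman between each subpopulation's average
CPT profile and each reference cell type over the shared gene universe
(constant profiles get rho 0). Reference types whose correlation SD
across subpopulations is at or below the median are dropped (strict
retention: ties at the median drop, so exactly half survive only when
SDs are unique there). Retained columns are z-standardized per reference
(column-wise — the axis that clusters cell types) and both axes get
average-linkage hierarchical clustering with Euclidean distance.

*Contamination-robust immune signature.* Step 1: binomial DE of the
group tumors' transformed cells vs all other tumors' transformed cells;
keep raw p < 0.01 and fold > 10 (raw p deliberately: the procedure says
FDR where it means FDR, as in the myeloid filter). Step 2: for each
group tumor with an immune compartment, drop every gene detected more
frequently in its immune cells than in its transformed cells — a strict,
gate-free comparison that errs toward removal. Whatever survives is
expressed too strongly in transformed cells to be explained by ambient
cross-contamination (~1% of a cell's molecules drawn from the pooled
lysate). Tumors without immune cells are skipped, mirroring the
no-myeloid-detected case.

*External signature filtering.* Candidates intersect the genes with
≥ 5-fold myeloid detection specificity at BH FDR < 0.01; the output is
always a subset of the candidate list, in candidate order.

## The synthetic generator

The generator states the world the tests certify. Per-gene rates are
log-normal (σ = 1) baselines times the population's program times
copy-number dosage (copies/2, MT pinned diploid), renormalized to the
target depth; counts are Poisson (optional gamma over-dispersion gives a
negative binomial for robustness tests). Defaults: 100 genes per
autosome, 20 mitochondrial, 10 HLA on chr6, 2 000 molecules per cell —
small enough for desk-scale runs, large enough for stable chromosome
averages. Populations carry graded transcriptome-wide fold-change fields
(log-normal, σ = 0.5) under focal markers, for the dimensionality reason
above. The preset mixtures emulate a branched proneural-like tumor
(astrocyte-, OPC-, oligodendrocyte-, neuroblast-like transformed
subpopulations at chr7×3/chr10×1 over myeloid/T/endothelial/pericyte/
oligodendrocyte microenvironment) and a mesenchymal one (lineage-poor,
immune-like transformed program, 45% myeloid). A SOX2-like gene is
expressed across every transformed subpopulation and nearly absent
outside. Marker gene sets are spread round-robin across chromosomes
(excluding 6, 7, 10) so lineage programs do not masquerade as
aneuploidies.

Read-level emission assigns each cell a random 12-nt barcode (pairwise
Hamming ≥ 3, no GGGG runs — bead barcode sets avoid G runs, and a
truncated barcode borrowing a G from the UMI head must not trip the
degenerate filter), distinct pairwise-Hamming-≥2 UMIs within each
(cell, gene) group (so a zero-error table collapses back to the source
matrix exactly), geometric-like read counts (1 + Poisson), and four
error classes: barcode truncation (inverse of the detector), per-UMI
substitutions (splitting reads onto a Hamming-1 UMI), per-read barcode
substitutions (Hamming-1 barcode records), and ambient
cross-contamination (molecules re-drawn from the pooled profile; also
available directly at the matrix level via multivariate-hypergeometric
swaps that preserve per-cell depth). WGS counts are multinomial with
weights ∝ chromosome length × copies/2; default lengths are the genome
model's genes-per-chromosome (the estimator itself is length-free).

Not emulated: doublets, FASTQ/alignment artifacts, UMI collisions within
a group (excluded by construction), batch effects, or per-cell depth
variation in the default worlds. A green test therefore certifies the
algorithms against this stated world, not against every pathology of
real libraries.

All randomness descends from a single integer seed per entry point; the
same seed reproduces bit-identical outputs.

## Numerical conventions

Counts per thousand use each cell's full molecule total. Log transforms
are log2(CPT + 1). Sequences are packed two bits per base with
lexicographic order preserved (A < C < G < T). The 1-D two-means split
is exact (prefix-sum scan over the sorted values). Hierarchical
clustering, isotonic regression, BH correction, Louvain, silhouette and
PCA/SVD are delegated to scipy / scikit-learn / statsmodels / networkx /
numpy; everything the collapse, scoring, and signature contracts define
is implemented here and checked against independent brute-force oracles
in the test suite.
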