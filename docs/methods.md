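# Methods

## Feature representation

Sequences are represented by canonical k-mer frequency profiles. The
canonical form of a k-mer is the lexicographic minimum of the k-mer and its
reverse complement; collapsing is essential because the strand on which an
assembler or sequencer reports a contig is arbitrary, and it halves the
feature space up to palindromes: 136 features at k = 4 (16 palindromic
4-mers plus 120 reverse-complement pairs), 512 at k = 5 (odd k has no
palindromes). Only k ∈ {4, 5} is supported — shorter k-mers carry too
little taxonomic signal and longer ones too much sampling noise at contig
scale.

Counting slides a width-k window at step 1. Windows containing N are
skipped deterministically (not randomized, which would break
reproducibility); a sequence whose every window contains N is rejected with
an error naming it. Counts are divided by the number of valid windows, so a
profile is a probability vector. "Normalization" here means frequency
normalization — no CLR or rank transform — the minimal reading that makes
profiles of different-length sequences comparable.

## Embedding

The 2D reduction operates on raw profiles by default; above 5000 sequences
profiles are first compressed by PCA to 50 components (deterministic full
SVD), trading a little variance for tractable neighbor searches. Both the
threshold and the dimensionality are exposed (`--compress/--compress-dims`).

Bundled backends: UMAP (default), t-SNE, and a PCA projection that serves
as a fast deterministic baseline. Other methods can be attached through
`register_embedder` without touching the dispatch. Distances are Euclidean
on the frequency vectors.

One deliberate departure from the backend defaults: UMAP runs with
`n_neighbors=50` (instead of 15). Genome binning needs macro-structure —
all fragments of a genome in one cloud — and at small neighborhood sizes
UMAP fragments a genome's cloud into islands that a density-based clusterer
then oversplits. A wide neighborhood preserves genome-level topology at
these sample sizes. `min_dist` and t-SNE's perplexity keep their published
defaults (perplexity is clamped to (n−1)/3 for small inputs).

Every backend receives the run seed; with a fixed seed, repeat runs are
bitwise identical (UMAP switches to its single-threaded deterministic path
when seeded).

## Clustering

Clustering happens in the 2D embedding for all methods (not in profile
space), with a menu of DBSCAN, HDBSCAN, k-means and spectral clustering.
HDBSCAN with `min_cluster_size=10` is the default because it requires no
cluster count and tolerates noise — matching unattended operation.
Noise points (label 0) are not a bin; they are candidates for classifier
assignment.

Labels are renumbered 1..n by decreasing cluster size, ties broken by the
smallest member id, so output is stable. Because k-means++ initialization
and HDBSCAN's internal tie-breaking depend on row order, rows are sorted by
sequence id before the backend runs and mapped back afterwards; the
id→cluster map is therefore invariant to input order.

## Semi-supervised assignment

The "confident subset" is the set of clustered, length-filtered sequences;
clusters with fewer than 5 members are dropped from training (too few
examples to generalize from) and their members rejoin the assignment pool.
The classifier is an L2-regularized multinomial logistic regression
(C = 100, lbfgs) over the k-mer profiles — not the 2D coordinates — so new
or held-out sequences can be assigned without re-embedding. A linear model
is fast, convex (hence deterministic), and sufficient for frequency
features; the `BinClassifier` wrapper keeps the family swappable.

A candidate receives the argmax bin when its posterior ≥ the confidence
threshold (default 0.5; at 0 everything is assigned, at 1 almost nothing).
Raising the threshold can only shrink the classifier-assigned set. The
assignment table covers every input sequence exactly once: kept cluster
labels, classifier assignments, and unassigned (bin 0) partition the input.

## Differential density

Per class, the KDE is a uniform mixture of axis-aligned Gaussians:
f_c(x, y) = (1/n_c) Σ_i (2π h_x h_y)^(−1) exp(−(x−x_i)²/2h_x² −
(y−y_i)²/2h_y²), evaluated at the centers of a G×G grid. The kernel is
separable, so the grid is an outer product of two axis-wise kernel
matrices — O(G·n + G²) instead of a naive O(G²·n) loop (the naive loop is
kept as the test oracle).

Both classes share the grid (union bounding box padded by 4·max(h)) and the
bandwidth, by Scott's rule h_i = σ_i·n^(−1/6) on the pooled labeled points.
Pooling is done in embedding row order, not class order, so a class swap
negates the result bitwise — the antisymmetry the per-cluster ranking
relies on. With default padding each class grid integrates to ≥ 0.99
(mass escapes only past the padded edges). Grid size is bounded to
[25, 1000] cells per axis (default 250) to keep memory and the test oracle
desk-scale.

Per-cluster scores evaluate the exact closed form (not grid interpolation)
of f_A − f_B at each member point and report the mean and sum along with
per-class member counts. Densities are per-class normalized, so scores
measure distributional shift, not absolute abundance; n_A/n_B allow
rescaling. No significance statistics are attached — the surface is a
visual/exploratory instrument, and two classes are required, exactly.

## Synthetic communities

Each genome is an order-3 Markov chain whose 64 transition rows are drawn
from Dirichlet(α) with α = 0.1 by default; order 3 guarantees that 4- and
5-mer profiles carry genome identity by construction, and small α makes
transition rows sparse and genome signatures distinct (the two-genome
4-mer distance exceeds 10× the within-genome distance at α = 0.05).
Fragments have lognormal lengths (median 5 kb, σ = 0.5, clipped to
[500 bp, genome length]) approximating the skewed length distributions of
metagenome assemblies and nanopore runs, with uniform start positions.
Defaults — 5 genomes of 200 kb, 200 fragments each — give a ~1000-fragment
community that exercises every pipeline stage in seconds.

The two-class design draws round(fragments_per_genome × abundance)
fragments per genome per class; a genome with abundance 0 in one class is
the planted class-exclusive differential signal.

What the generator does **not** model: sequencing errors (composition at
k ≤ 5 is robust far above realistic error rates, and an error model would
complicate the oracles without exercising new code paths), chimeras,
within-genome compositional heterogeneity (GC islands, horizontally
transferred regions), shared/conserved regions between genomes, and
coverage–abundance coupling. Passing tests therefore demonstrate the
correctness of the machinery and its behavior under clean compositional
signal; real communities, with overlapping signatures and heterogeneous
genomes, will bin less cleanly than the synthetic benchmarks.

## Numerical and design notes

- Length filter: inclusive (≥), default 500 bp — a conventional floor below
  which tetranucleotide signal is too noisy; below-filter sequences are
  still profiled (if ≥ k bp) and classifier-assigned.
- Duplicate FASTA ids are an error, not silently renamed; lowercase
  (soft-masked) residues are uppercased.
- All stochastic stages derive from one run seed, recorded with every
  parameter in `manifest.json`; outputs are written atomically
  (temp-file-and-rename) and a manifest replay reproduces every table
  byte-for-byte, the manifest's own timestamp aside.
- Problem sizes in the test-suite and acceptance checks (communities of
  3–5 genomes, 60–200 fragments each, 100-cell oracle grids) were chosen
  as the smallest sizes at which every stage's behavior is unambiguous.

## Known limitations

- Composition alone cannot split genomes with near-identical k-mer usage
  (e.g. closely related strains); coverage-based or hybrid binners are
  expected to win whenever multi-sample coverage exists.
- HDBSCAN on a 2D embedding inherits the embedding's artifacts; a genome
  can still split into multiple bins (observed occasionally as 6 bins for
  5 genomes), which the <1% minor-bin flag only partially mitigates.
- The differential surface is descriptive; it provides no error control
  for claiming a cluster differs between classes.
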