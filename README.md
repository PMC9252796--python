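# kmerbin

Composition-based metagenomic binning with differential two-class density
analysis.

When a metagenome comes from an environment with poor reference coverage —
or from a single sample, where co-abundance (coverage) profiles are not
available — contigs and long reads can still be grouped into putative
genome bins from sequence composition alone. `kmerbin` implements such a
reference-free pipeline for assembled contigs and long nanopore reads, plus
a visual comparative analysis between two sample classes, and a synthetic
community generator so every stage can be validated against known ground
truth.

## Method

1. **Features.** Each sequence passing a length filter (default ≥ 500 bp)
   is represented by its normalized canonical k-mer profile (k = 4 or 5).
   A canonical k-mer is min(w, revcomp(w)), collapsing strand ambiguity;
   this gives 136 features for k = 4 and 512 for k = 5. Windows containing
   N are skipped; counts are divided by the number of valid windows, so each
   profile sums to 1.
2. **Embedding.** Profiles (optionally PCA-compressed first) are reduced to
   2D with UMAP (default), t-SNE, or PCA; further methods can be registered
   as plugins.
3. **Clustering.** The 2D embedding is clustered with HDBSCAN (default),
   DBSCAN, k-means or spectral clustering. Clusters are renumbered
   1..n by decreasing size; 0 marks density-method noise.
4. **Bin assignment.** A multinomial logistic regression is trained on the
   k-mer profiles of the confidently clustered subset (clusters with ≥ 5
   members), then assigns every remaining sequence — noise points, members
   of tiny clusters, sequences below the length filter — to a bin when its
   posterior probability clears a confidence threshold (default 0.5).
5. **Differential density.** Given a two-class label table
   (e.g. long-read vs. short-read, case vs. control), a Gaussian 2D KDE

   f_c(x, y) = (1/n_c) Σ_i N(x | x_i, h_x²) · N(y | y_i, h_y²)

   is evaluated per class on a shared grid with a shared bandwidth
   (Scott's rule, h_i = σ_i·n^(−1/6), unless overridden), and the
   difference surface f_A − f_B plus per-cluster signed density scores
   reveal which bins are specific to one class.

## Worked example

Simulate a two-class community of three genomes where genome 2 occurs only
in class A, then bin it and rank clusters by differential density:

```sh
kmerbin simulate --out demo/sim --n-genomes 3 --genome-length 60000 \
    --fragments-per-genome 80 --abundance-a 0.34,0.33,0.33 \
    --abundance-b 0.5,0.5,0 --seed 42
kmerbin bin --input demo/sim/community.fasta --out demo/run \
    --embed umap --cluster hdbscan --seed 42
kmerbin diff --run demo/run --classes demo/sim/classes.tsv
```

This prints the per-stage counts and the per-cluster ranking:

```
read 159 sequences
length filter (>= 500 bp): kept 159, discarded 0
profiled 159 sequences (k=5)
embedded 159 sequences with umap
clustered into 3 clusters (0 noise points)
assigned: 159 by cluster, 0 by classifier, 0 unassigned
3 bins written to demo/run (0 sequences unassigned)

 cluster  n_A  n_B  mean_diff  sum_diff
       3   26    0   0.009509  0.247227
       2   26   40  -0.002302 -0.151904
       1   27   40  -0.002880 -0.192989
```

Cluster 3 holds 26 class-A sequences and none from class B, and its mean
density difference is the only positive one — the planted class-exclusive
genome. The negative values for clusters 1 and 2 reflect that class B
concentrates its (fewer) genomes there. `demo/run/bin_summary.tsv` reports
per-bin size, total bp, N50 and mean GC, and flags minor bins holding < 1%
of sequences:

```
bin  n_sequences  total_bp  n50   mean_gc  fraction_of_sequences  minor_flag
1    67           334826    5448  0.502    0.421                  False
2    66           401107    7443  0.372    0.415                  False
3    26           158962    7110  0.443    0.164                  False
```

All outputs are TSV tables plus a JSON run manifest that records every
parameter and seed; `kmerbin.run_from_manifest` replays a run
byte-identically.

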