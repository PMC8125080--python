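# Methods

`viroscope` re-creates, as a tested desk-scale pipeline, the analysis route
used in bulk-metagenome gut-virome studies: an ensemble screen that turns
per-contig virus-predictor evidence into viral/non-viral verdicts,
species-level clustering of the resulting viral genomes, genus-level
gene-sharing clusters, four-channel virus–host prediction, temperate/lytic
lifestyle classification, and the community-ecology statistics applied to
the resulting abundance tables.  Because the real inputs to such a study
(tens of millions of reads per sample plus four external predictor tools)
are out of desk scope, every stage is exercised on synthetic communities
with planted ground truth; the generator is first-class, tested code.

## Synthetic communities

Host genomes are sampled from independent order-3 Markov chains whose
transition rows are Dirichlet(1) draws.  This gives every host a distinct
compositional signature — exactly the assumption behind k-mer-based
virus–host prediction — without modelling any particular taxon.  Phages are
sampled from their assigned host's chain and then mutated at 2%
substitutions, so they are compositionally close to their host but not
identical to it.  Defaults (8 hosts of 30–50 kb, 20 phages of 15–30 kb,
three sample groups of five — a control and two perturbation groups)
mirror a small animal-cohort design at sizes that keep the full pipeline
in seconds; they are declared study conditions, not estimates of any real
community.

Planted features, all recorded as 0-based half-open coordinates in the
emitted sequences:

* **Prophages.**  Temperate phages (30% of phages by default) are wrapped
  in an exact att direct repeat (random 12–20 bp core) and inserted
  verbatim into their host with ≥1 kb of flanking host sequence.  The att
  core is redrawn whenever it already occurs in host or phage — without
  uniqueness the direct-repeat pair would be ambiguous by construction.
* **CRISPR arrays.**  Repeat 23–47 bp, spacers 26–50 bp, at least two
  repeat copies; spacers are protospacers copied verbatim (configurably
  mutated) from target phages of the same host.  Planting rejects draws in
  which consecutive spacers share a boundary base with each other or with
  the host at the array edges: an exact maximal-extension detector must be
  able to stop exactly at the planted repeat boundaries, and without this
  guard a ¼-probability chance match would extend a repeat by one base and
  corrupt the recovered spacers.  The same reasoning gives the in-frame
  stop codon planted directly upstream of every planted gene (so the ORF
  caller recovers exact coordinates) and the distinct-flank rule for att
  cores.
* **tRNAs.**  A library of random 70–90 bp sequences stands in for real
  tRNA genes; one library member is planted into each temperate phage (and
  hence into its host via the prophage copy).  Covariance-model scanning is
  out of scope — what is under test is the acceptance logic (perfect
  full-length identity plus prophage consistency), which is channel logic,
  not structure prediction.
* **Predictor scores.**  Four channels (a category-style sorter, a
  composition score with p-value, a random-forest probability, an
  annotation summary) are drawn from per-label distributions: Beta(8,2)
  scores for true phages, Beta(2,8) for host fragments, per-channel
  missingness.  No external predictor is ever invoked; the scores are
  inputs, as they were in the original workflow.
* **Counts.**  Relative abundances are lognormal(0,1) draws over phage
  features; responder features (15% per perturbation group, disjoint) are
  multiplied by an 8× fold-change in their group; a lognormal per-sample
  jitter (σ=0.3) adds biological-style noise; each sample is a multinomial
  draw of 200,000 counts.  Counts are generated directly rather than by
  simulating and mapping reads: the statistics layer consumes counts, and
  read mapping would add no tested logic.

What the generator does **not** emulate: sequencing error, assembly
artifacts and chimerism, degenerate CRISPR repeats, strain-level
microdiversity within populations, gene content shared across unrelated
phages, and compositional drift along genomes.  Passing tests therefore
demonstrate that each detector implements its stated decision rule exactly
and recovers planted signal under its own assumptions — not that those
rules have any particular sensitivity on real assemblies.

## Viral screen

The two-tier rule: length gate (linear ≥5 kb, circular ≥1.5 kb, circular
lengths taken after trimming the terminal repeat once), keep gate (any
sorter category 1–6, composition score ≥0.7 with p<0.05, or probability
≥70; annotation evidence alone never keeps a contig), tier 1 (category
1/2/4/5, score ≥0.9, or probability ≥90), tier 2 (at least two of:
category 3/6, score in [0.7,0.9) with p<0.05, probability in [70,90),
annotation support = called viral or <40% of genes non-viral).  All
boundaries follow the printed "≥" readings; the p<0.05 condition is applied
in the tier-2 band as well as the keep gate (the conservative reading).
Missing values never satisfy any criterion and never error, since real
predictor output is sparse.  The rule is verified cell-by-cell against an
independently coded oracle over the exhaustive boundary grid.

## Population (vOTU) clustering

Species-level populations are defined by ≥95% ANI over ≥80% of the shorter
genome.  The ANI engine finds exact shared 15-mers (unique in both
sequences, both strands), chains collinear anchors greedily (gap ≤5 kb,
diagonal drift ≤ max(100 bp, 20% of the gap) — the drift bound is
proportional to the gap so that a single chance off-diagonal k-mer repeat
cannot seed a spurious block), extends block flanks by up to 100 bp, and
aligns each block globally with edlib, summing matched over aligned
columns.  AF is the aligned fraction of the shorter sequence.  On
rearrangement-free pairs this agrees with full global alignment identity
within 0.5 points (tested).  Clustering is greedy longest-first with ties
broken by id, so the partition is independent of input order; thresholds
are inclusive.  Novelty against a reference set applies the same 95/80
criterion to population representatives.

## Gene-sharing genus clusters

ORFs are a deterministic six-frame scan (ATG-initiated, between stops,
≥60 aa, standard code) — a simplified stand-in for a trained gene finder,
adequate because downstream only consumes shared protein content.
Proteins cluster greedily (length-descending centroids, join at ≥30%
identity over ≥70% of the centroid, amino-acid 4-mer prefilter; note the
prefilter can in principle miss pairs near the 30% floor that share no
exact 4-mer — planted families sit well above it).  Pair significance is
the upper-tail hypergeometric probability of the shared-PC count in the PC
universe, weighted as −log10 p (floored at 10⁻³⁰⁰); viral clusters are
connected components of the graph thresholded at weight ≥1 (p ≤ 0.1),
rather than a ClusterONE-style density clustering — a declared
simplification that preserves the clustered / outlier / singleton
trichotomy: singletons share no PC with anyone, outliers share content but
retain no significant edge.

## Host prediction

* prophage: exact full-length embedding, either strand, with ≥1 kb host
  flank on at least one side (the flank requirement replaces web-service
  corroboration of prophage calls and separates integration from
  co-assembly).
* CRISPR: exact-repeat arrays (≥2 copies, repeat 23–47 bp, spacers
  26–50 bp) detected by seeding on repeated 23-mers at compatible spacing
  and maximal exact extension; spacer hits are full-length, ungapped,
  either strand, at ≥95% identity, i.e. at most ⌊0.05·L⌋ mismatches.
* tRNA: exact full-length shared sequence, accepted only when the same
  (virus, host) pair has an accepted prophage call.
* k-mer: per-host order-7 Markov models (k=8) with pseudocount 1.  Counts
  come from the given strand; the derived closed form (order-0 model on
  100 A's with pseudocount 1 gives P(A)=101/104) fixes this convention,
  and strand symmetry is obtained at scoring time by taking the maximum of
  the two query orientations.  The null model is a Gaussian fit to the
  virus's scores against ≥10 decoy hosts; "p of zero" is operationalized
  as p ≤ 1e−10 (a literal zero being a floating-point artifact of the
  original tool), and a moderate p (<0.05) is accepted only with an
  agreeing prophage call.

Consensus keeps all accepted calls and picks a primary host by the fixed
priority prophage > crispr > trna > kmer (ties within a channel break by
host id), a declared total order — the channels rarely conflict on planted
data, and the order reflects decreasing evidential strength.

## Lifestyle

Marker categories come from a case-insensitive keyword map over annotation
labels (integrase / site-specific recombinase; excisionase; repressor;
antirepressor, matched before repressor; ParA/ParB as whole tokens).
att pairs are exact direct repeats with core ≥12 bp, both copies fully in
noncoding intervals (not overlapping any annotated gene), separated by at
least half the contig, each copy within 2 kb of a contig end or of an
integrase gene; contigs without an integrase return no pairs.  The numeric
att thresholds are declared defaults — the att criterion is usually
applied by manual inspection, which has no published numbers.  Confident
temperate = integrase + att pair; any marker alone = candidate; otherwise
no evidence.  Confidence nests: every confident contig would still qualify
as candidate.

## Statistics

RPKM = count·10⁹/(length·total mapped).  The log transform is
log₂(x+1).  Bray–Curtis, classical-scaling PCoA (negative eigenvalues
reported, their axes dropped), Shannon's H in natural log (the convention
of the standard ecology packages), two-sided Wilcoxon rank-sum (exact
enumeration when combined n ≤ 12 without ties, midranks + normal
approximation otherwise) with Benjamini–Hochberg FDR per contrast family,
between/within-group dissimilarity sets, and Welch-t volcano tests on
log₂ abundances without empirical-Bayes moderation (a deliberate
simplification: self-contained and exactly testable).  The group
separation test is ANOSIM R — the statistic the workflow actually
computes even where it is labelled PERMANOVA — with seeded label
permutations and the add-one p estimator (never reports p = 0), or
exhaustive enumeration on tiny designs; a PERMANOVA pseudo-F is provided
as an optional alternative.  Heat-map clustering is per-row z-scores with
complete-linkage Euclidean agglomeration and a deterministic leaf order.

## Determinism and problem sizes

Every stochastic step draws from one `numpy` Generator seeded by the
global seed; identical configurations produce byte-identical bundles,
stage files and reports (wall time is kept out of the canonical report).
The shipped benchmark sizes — 40 planted populations of 10–50 kb for
clustering recovery, 10 well-separated hosts × 20 seeds for k-mer host
recovery with ≥20 kb phages, 100 simulated null datasets of 200 features
for the volcano false-positive rate — were chosen as the smallest sizes at
which each property is a meaningful statement rather than a coin flip, and
the full default pipeline runs in well under a minute on one core.

## Known limitations

Exact-match detectors (prophage, tRNA, CRISPR repeats, att cores) are
strict by specification and will miss real-world degenerate instances;
the ANI engine is validated on substitution-dominated pairs and makes no
claims about heavily rearranged genomes; the ORF caller has no gene model
and over-calls short spurious ORFs in random sequence (harmless for
shared-content clustering, wrong for annotation); abundance simulation is
compositional, so strong responders depress the relative abundance of
everything else — a real effect of relative data that the volcano output
of real studies shows as well, but one to keep in mind when reading the
synthetic volcano counts.
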