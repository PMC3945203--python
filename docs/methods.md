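# Methods

`homeosort` resolves and classifies homeolog-level gene expression in an
allopolyploid from bulk RNA-seq when no close reference genome exists for
either parent. This note documents the model behind each stage, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## The analysis model

An allopolyploid carries two diverged parental subgenomes in one nucleus.
For every gene there are two homeologs, and the scientific question is how
their joint expression relates to the expression of the corresponding
orthologs in the extant parents: unchanged (*parental expression
inheritance*), parental differences lost (*blending*), new differences
gained (*bias*), or flipped (*reversal*). On top of these relative
outcomes, *expression-level dominance* asks whether the combined homeolog
expression tracks one parent's level rather than the parental average.

Because neither parent has a usable genome assembly, all sequences are
interpreted against a surrogate reference: a well-annotated transcript
(gene-model) catalogue from a related species. The pipeline is:

1. **Diagnostic SNP discovery.** Reads from each parent and from the
   allopolyploid are mapped to the surrogate gene models at low stringency
   (mismatch bound `ceil(0.10 × read_length)` by default, wide enough for
   ~8% parent–reference divergence plus sequencing error). Variants are
   called per sample and partitioned by presence/absence into ancestry
   classes: `ancestral` (all three samples — substitutions on the reference
   strain's own branch), `p1_unique`/`p2_unique` (one parent only),
   `p1_shared`/`p2_shared` (one parent plus the allopolyploid: the
   homeolog-diagnostic classes), and allopolyploid-only variants
   (post-hybridization candidates). Variants found in both parents but not
   the allopolyploid go to a residual bin: they cannot be used for
   reference substitution because their presence in the hybrid is
   unverified. Allopolyploid-only variants are placed on a subgenome by
   read-level linkage (below) where possible.
2. **Homeolog reference construction.** Two parallel references are built
   from the surrogate models: the parent-1-like reference receives
   {ancestral, p1_shared, allo_p1} alleles, the parent-2-like reference
   {ancestral, p2_shared, allo_p2}. Positions where the two differ are the
   *discriminating positions*. The *informative region* of a gene is the
   union of windows `[p − (read_length − 1), p + read_length)` around its
   discriminating positions — exactly the footprint where a full-length
   read can overlap a discriminating site, hence the only footprint where
   homeolog assignment is possible. Everything outside is hard-masked to
   `N`. Genes with fewer than 5 reads in either parent or informative
   regions shorter than 150 bp (union length; bounds inclusive) are culled.
3. **Zero-mismatch homeolog assignment.** Allopolyploid fragments are
   mapped to both masked references; a fragment is counted for one homeolog
   of one gene only when it matches there full-length with zero mismatches
   and matches nowhere on the other reference. Matches on both references
   (no discriminating site in the span) or mates disagreeing are
   *ambiguous*; fragments with no zero-mismatch match (e.g. any sequencing
   error) are *unassigned*. Misassignment is therefore structurally rare: a
   wrong call requires an error that converts the one discriminating allele
   in the span into the other homeolog's allele. Parental ortholog
   expression is counted the same way against that parent's own masked
   reference, so all four measurements per gene share one effective target.
4. **Statistics.** Counts are pooled over replicates and normalized to
   reads per million of each source's assigned-read total. The fold ratio
   is fixed-orientation (parent-2 side over parent-1 side). Significance is
   Fisher's exact test on `[[c_a, T_a − c_a], [c_b, T_b − c_b]]` with
   Storey–Tibshirani q-values; differential expression always requires both
   `q < 0.05` and a ≥2-fold difference — with such deep libraries tiny
   proportional differences are significant, so the fold criterion carries
   the biological meaning.
5. **Fate classification.** The parental state and allopolyploid state
   (each: parent-1 side higher / parent-2 side higher / equal) define nine
   categories grouped into the four outcomes. Dominance is tested for
   parent-DE genes by comparing the combined homeolog expression (not
   halved for ploidy; totals are compared directly) against each parent
   with the same fold+q rule: indistinguishable from the high parent and
   different from the low parent is `dominant_high`, the converse
   `dominant_low`, anything else `intermediate`. "Resembles" is thereby
   operationalized as statistically-indistinguishable-plus-<2-fold rather
   than nearest-in-log-space. For dominance genes, the non-dominant
   parent's homeolog is tested against its own ortholog to decide whether
   that homeolog's change drives the pattern. Extreme differential
   expression (EDE) flags genes with ≥50-fold homeolog ratio or expression
   from only one homeolog, among genes with ≥5 allopolyploid reads; genes
   with zero reads from one or both homeologs (no read floor) are gene-loss
   candidates. EDE genes adjacent on a supercontig form physical clusters;
   culled genes are transparent to adjacency because they carry no
   expression information. A regulatory-independence trichotomy summarizes
   inheritance-of-biased-expression (full independence), bias (partial) and
   blending (none), with genes unbiased everywhere handled by an explicit
   treatment option and reversal genes reported separately.
6. **Dating.** Parent-private SNP counts bound the hybridization time from
   above: `T = S / (L × mu)` with `S` the SNP count on the shortest
   parental branch (`min(p1_unique, p2_unique)`, overridable), `L` the
   cumulative masked informative length, and `mu` the per-site yearly
   substitution rate (default 1e-9). The headline value is rounded to the
   nearest 100,000 years. No lower bound is possible from these data.

## Linkage assignment of allopolyploid-private SNPs

A new (post-hybridization) SNP is placed on a subgenome by the fragments
that carry its alternate allele and also cover at least one
homeolog-diagnostic site. Each such fragment votes: the alternate allele of
a `p1_shared` site — or the *reference* allele of a `p2_shared` site —
identifies the parent-1 subgenome, and symmetrically. Reference alleles are
used as evidence because at a `p1_shared` site the parent-2 subgenome
demonstrably carries the reference base; without them, subgenomes whose
diagnostic sites are sparse (the close parent, whose SNP spacing can exceed
the read length) would be nearly unreachable by linkage. A variant is
reclassified when at least `min_links = 3` voting fragments agree with at
most a `max_conflict_frac = 0.05` minority; fragments with internally
conflicting votes are discarded. Mate pairs count as one linkage unit.

## The mapper

Reads are aligned ungapped and full-length with a k-mer-seeded,
mismatch-bounded search. The read is partitioned into `floor(len/k)`
non-overlapping seeds; by pigeonhole the search is provably complete
whenever `floor(len/k) > max_mismatch` (the test suite checks equality with
an exhaustive all-offsets scan on randomized instances). Ungapped alignment
suffices because homeolog discrimination is SNP-based and the simulated
data contain no indels; externally produced gapped alignments can be
imported from SAM (indel CIGARs are skipped with a warning). Discovery
mapping uses `k = 9` so the guarantee holds at the 10-mismatch bound;
zero-mismatch assignment uses `k = 31`. Reads whose equal-best hits span
more than one gene are discarded to avoid paralog-inflated evidence.

## Variant-calling thresholds

Parent (haploid) calls require coverage ≥5 and a single best alternate
allele at ≥90% of reads (ties yield no call); the fraction is below 1.0
only to tolerate sequencing error. Allopolyploid (mixed) calls require ≥3
alternate reads at ≥10% frequency, keeping heterozygous-like sites where
one homeolog carries the reference base. The fraction threshold must sit
safely below the minor homeolog's read share — a 4-fold biased gene feeds
only ~20% of its reads from the minor homeolog, and a cutoff at that share
silently drops half of that subgenome's variants, leaving its parent-like
reference deficient; the deficient reference then depresses that parent's
zero-mismatch counts and manufactures spurious parental DE in the direction
of the allopolyploid bias. The 3-read floor keeps sequencing error
(1e-3/base) from producing false calls at any realistic coverage.
Multi-allelic sites are excluded entirely: the diagnostic framework is
bi-allelic.

## The synthetic-data generator

The generator emulates the study design end to end with full ground truth.
A random intron-free transcript catalogue (default 300 genes, length
N(1200, 250²) bp, minimum 300) is laid out on supercontigs (25 genes each,
500 bp gaps; coordinates exist solely for cluster analysis). Substitutions
are placed i.i.d. per site on five branches — shared ancestral (0.0015),
parent-1 private (0.004), parent-2 private (0.03; the order-of-magnitude
asymmetry between a close and a distant parent), and two allopolyploid
subgenome branches (5e-4 each) — with colliding sites re-drawn so each site
is bi-allelic. Clustered deletions (default two clusters of three adjacent
genes) remove a run of genes from one subgenome. Expression fates are drawn
per gene at proportions (0.561, 0.251, 0.156, 0.032) matching the published
outcome distribution, with a 4-fold (`bias_log2_effect = 2`) effect size,
25% of inheritance genes biased, log-normal base expression
(log2 mean 6, sd 1.5), and total allopolyploid expression set to the
parental mean. Reads (100 bp; parents single-end, allopolyploid paired-end
with 250 bp fragments, as in the study design) are drawn multinomially in
proportion to expression × effective length, with uniform positions, fair
strands, and i.i.d. base errors at 1e-3 (≈Q30); a sidecar table records
every read's true transcript of origin. One master seed drives named
per-stage child generators, so outputs are byte-identical for a fixed seed
and stages are reproducible in isolation.

Default library sizes (60k/60k/120k fragments per replicate, two
replicates) are a scaled-down version of the study's tens of millions of
reads, chosen to preserve its regime of deep per-gene coverage (hundreds of
fragments per gene) at desk-scale runtime. The acceptance script doubles
the catalogue and the libraries together (600 genes, same per-gene depth)
so that the multinomial noise of the category draw does not dominate the
reported proportions.

What the generator does **not** emulate: indels and structural variation
other than whole-gene deletion, splice isoforms, GC/positional coverage
bias, quality-score error profiles, rRNA contamination, or expression
overdispersion between biological replicates (replicates are resampled from
identical expression levels). Passing recovery tests therefore demonstrate
correctness of the inference machinery under the stated generative model,
not robustness to those real-data artifacts.

## Known ascertainment properties

Two behaviors of the method are worth naming because the simulator
reproduces them faithfully:

- **Presence/absence classes inherit coverage ascertainment.** A truly
  ancestral variant not covered in one parent is classified as shared with
  the other parent only; a parent-branch variant whose homeolog is weakly
  expressed in the allopolyploid is classified parent-unique. These
  misattributions are rare at deep coverage (<2% of discriminating sites in
  the error-free test experiment) but inflate the parent-unique bins, which
  makes the dating estimate conservative — it remains an upper bound.
- **Far-parent deletions are censored.** When a gene's far-parent homeolog
  is deleted from the allopolyploid, that parent's dense branch variants
  are no longer verifiable in the hybrid, its reference stays close to the
  surrogate, and the parent's own reads then fail zero-mismatch counting —
  the gene is culled as under-expressed. Close-parent deletions survive
  (the close parent's sparse variants barely affect its reference) and are
  recovered as one-sided EDE clusters. The same asymmetry exists in the
  real analysis and predicts that observed deletions are biased toward the
  close-parent subgenome.

## Numerical choices and degenerate inputs

- Storey q-values: `pi0(λ)` on the grid {0, 0.05, …, 0.95} smoothed with a
  cubic polynomial evaluated at λ = 0.95, clipped to `(1/m, 1]`; for fewer
  than 8 p-values the smoother is unreliable and `pi0 = 1` (conservative).
  q-values are monotone in p by construction.
- Fold ratios with a zero denominator are `+inf` and flagged one-sided;
  both-zero folds are flagged undefined and never DE. Pseudocounts (0.5)
  appear only in exported log-ratio tables for heat-map-style inspection,
  never in test statistics.
- Tie-breaks: variant calls with tied alternate alleles are dropped; reads
  whose equal-best hits span multiple genes are dropped; hits tied within
  one gene count the gene once.
- Gene culling bounds are inclusive (≥5 reads, ≥150 bp): the rules are
  phrased as "fewer than five" and "less than 150".
- The 150 bp informative rule is applied to the *union* length of a gene's
  informative intervals, not its longest single interval.
- Replicates are summed before testing; per-replicate counts are retained
  in outputs for inspection. Overdispersion-aware tests are out of scope.

## Limitations

Single-isoform, indel-free, ungapped-alignment assumptions throughout; no
base-quality modeling; Fisher's exact test treats biological replicates as
exchangeable sequencing of one pool; the dating clock ignores rate
uncertainty and assumes all parent-private SNPs postdate the hybrid's
divergence from that parent, which is exactly why the estimate is only an
upper bound.
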