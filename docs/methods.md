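# Methods

## The dual-source model

The package analyses paired metagenomes of the same gut sample: a
whole-microbial ("bulk") library and a viral-like-particle (VLP) library.
Their information content differs by construction. A temperate phage exists
in two states — the integrated prophage, which replicates with its host and
is sequenced as part of the host's genomic neighbourhood in the bulk
library, and the induced virion, which is the only state a VLP prep can
capture. A virulent phage exists only as virions and particles inside
lysing cells, visible to both assays. The analysis therefore treats the
bulk assay as the census of bacteria plus total phage biomass and the VLP
assay as the census of the lytic compartment.

## Viral catalog construction

Candidate viral genomes arrive annotated (the upstream callers — assembly,
binning, phage prediction, completeness estimation — are consumed as input
fields, not executed). The cascade is:

1. **Quality**: completeness ≥ 50% (inclusive) and contamination < 10%
   (strict), per the conventional CheckV-style thresholds.
2. **Dereplication** into species-level representative genomes (SRGs):
   greedy clustering in descending length order; a sequence joins a
   representative when its best infix alignment inside the longer sequence
   reaches 99% identity over 100% of its own length (identity =
   matches/shorter-length). The implementation prescreens candidate pairs
   by shared 21-mers (exact 2-bit rolling codes; pairs sharing < 50% of the
   shorter sequence's distinct 21-mers are skipped — at 99% identity ~81%
   of 21-mers survive, so the screen cannot lose true joins) and verifies
   with `edlib` infix alignment. Equal-length ties go to the
   lexicographically smaller identifier, for determinism. Partial-coverage
   clustering (short-coverage < 1.0) is deliberately unsupported: it would
   require true local alignment and has no use in this pipeline.
3. **Validation**: a genome must be called by at least one phage predictor,
   carry ≥ 1 phage structural protein (terminase, capsid, tail,
   N-acetylmuramoyl-L-alanine amidase — stored as `amidase` — baseplate,
   prohead, coat, virion), and is discarded as a likely non-viral giant when
   it has exactly one structural protein yet > 100 ORFs. The ORF count is
   the number of annotated genes on the contig, standing in for a gene
   caller's ORF count.
4. **Lifestyle**: temperate iff any lysogeny-cycle gene (integrase,
   transposase, recombinase, Cro/CI) is present **or** the genome shows
   homology to a bacterial SRG with flanking bacterial regions; otherwise
   virulent. A temperate SRG's host is the bin it was predicted from, else
   the SRG that triggered the homology evidence. Every validated genome is
   classified exactly once, so temperate + virulent = total by
   construction. This rule misclassifies fragmented genomes and
   unconventional lysogens; that is a limitation of marker-based lifestyle
   prediction generally, not of the implementation.

## Presence, abundance, and functional profiles

Coverage summaries follow the `samtools coverage` column set per (feature,
sample, assay): length, covered bases, breadth, mean depth.

* An SRG is **detected** when breadth ≥ 70% or an absolute floor of covered
  sequence is reached — 5 kb for viral, 100 kb for bacterial genomes. The
  floors admit long genomes whose sheer size makes 70% breadth an
  unreasonable bar at moderate depth; both comparisons are inclusive (≥).
* Raw abundance is the mean depth rounded half-away-from-zero where
  detected, 0 elsewhere. Features detected in fewer than 3 samples of an
  assay are dropped ("more than 2 samples", interpreted per assay: bulk and
  VLP tables are filtered independently, since the two assays census
  different compartments).
* Relative abundance divides each sample column by its own sum over the
  retained features (compositional treatment); all-zero columns are left at
  zero and flagged.
* Gene profiles use the stricter rule: an ORF counts only when its breadth
  strictly exceeds 70% ("higher than 70%"); mean depths of detected ORFs
  sharing a gene identifier are summed, then integerised half-away-from-zero
  after summation. SCFA enzyme groups (25 acetate, 8 butyrate, 6 propionate
  KEGG orthologs) are summed per sample from the relative gene table; a gene
  listed under two acids (K00925, K01895, K01913) contributes to both.

## Depth saturation

Rather than re-subsampling reads and re-assembling, coverage records are
thinned analytically: at a fraction *f* of native depth, mean depth becomes
*fλ* and expected breadth `1 − exp(−fλ)` (the Lander–Waterman expectation),
with binomial noise on covered positions capped at the original coverage.
This is a deliberate abstraction — it preserves the shape and plateau of
rarefaction curves but cannot model assembly dropout at low depth. The
default grids are 1–25 M paired-end reads (bulk) and 1–15 M (VLP) in
triplicate; read counts convert to bases as 2 × 150 bp. A curve plateaus at
the smallest grid depth after which every consecutive increase stays below
ε × the final count (ε = 0.02 by default, configurable and echoed in
output; the plateau of a rarefaction curve is conventionally judged by
eye, so ε is an explicit operationalisation, not an estimate). The capture
grid reports, per breadth threshold t ∈ {10, 25, 50, 70, 90}% and bulk
depth, the percentage of VLP-detected SRGs with bulk breadth ≥ t; the
thresholds bracket the adopted 70% operating point.

## Community statistics

* **Alpha diversity**: observed richness; classic Chao1 `S + F₁²/(2F₂)`
  (bias-corrected `S + F₁(F₁−1)/2` when F₂ = 0); ACE with rare threshold
  10; Shannon with natural log (the vegan convention); Simpson `1 − Σp²`.
* **Bray–Curtis** `Σ|x−y| / Σ(x+y)`; a pair of all-zero samples is defined
  as distance 0 and flagged.
* **PCoA** by Gower double-centering of −½D² and eigendecomposition;
  negative eigenvalues are dropped and counted (no Cailliez correction —
  the simplest defensible default, visible in the result object).
* **PERMANOVA** (one-way, Anderson pseudo-F from within-group squared
  distances). p = (b + 1)/(B + 1) over B label permutations, so p > 0
  always; `exhaustive=True` enumerates all distinct label assignments (≤
  10,000) for the exact permutation distribution. At the 4-vs-4 design there
  are 35 distinct bipartitions, so the exact p floors at 1/35 ≈ 0.0286 and
  the achievable type-I error at α = 0.05 is capped near 1/35 — a property
  of the design size, not of the implementation. The random-permutation
  branch is vectorised over permutations.
* **Procrustes randomisation**: both ordinations are centred, truncated to
  their common first k axes and scaled to unit trace; the optimal rotation
  comes from the SVD of the cross-product; m² = 1 − (Σ singular values)²,
  r = √(1 − m²), p by row permutation of the second configuration.
* **Gated comparisons**: Shapiro–Wilk on group-mean residuals and Levene's
  test (both at α = 0.05) choose between the t-test and the two-sided
  Wilcoxon–Mann–Whitney (exact when n ≤ 25 without ties, normal
  approximation with tie correction otherwise; identical groups return
  p = 1 directly). With > 2 groups the gates choose between one-way
  ANOVA + Tukey and Kruskal–Wallis + Dunn (z-tests on mean ranks with tie
  correction, BH-adjusted). The comparison takes a single factor; crossed
  two-factor designs are out of scope.
* **Batch correlations** (Pearson or Spearman) report r, p, df = n − 2 and
  BH-adjusted p across the submitted batch; zero-variance vectors are
  flagged rather than guessed.

## Consensus differential abundance

Three engines re-implement the core models of the three tool families the
field combines, rather than wrapping the tools themselves — recovery of
planted truth, not numeric identity with any package, is the validation
target:

* **NB-Wald** (DESeq family): median-of-ratios size factors (features with
  any zero excluded from the reference; geometric-mean fallback flagged when
  none remain), per-feature method-of-moments dispersion floored at 1e-8 and
  shrunk half-way toward the across-feature mean — at n = 4/group the raw
  moment estimate is noise-dominated, and empirical-Bayes dispersion pooling
  is the defining device of this family — log2FC of group means with
  pseudo-mean 0.5, delta-method SE, two-sided normal p.
* **log-TSS linear model** (MaAsLin family): total-sum scaling, log2 with a
  pseudo-fraction of half the smallest positive relative abundance,
  equal-variance two-group t (constant features return p = 1).
* **CSS-moderated t** (metagenomeSeq family): per-sample scaling by the
  cumulative sum of counts at or below the median positive count (samples
  with < 2 positive counts fall back to their total, flagged), log2(x + 1),
  per-feature variance shrunk half-way toward the across-feature mean. With
  shrink weight 0.5 the prior carries as much information as the data
  (limma's d₀ = d), so the t reference uses twice the pooled df; the null
  simulations in the test suite confirm ~5% type-I error at n = 4/group.

BH correction is applied per engine across all features of one table. The
consensus set contains a feature iff all three q < 0.05 **and** the NB
engine's |log2FC| > 2 (direction relative to the declared reference group);
the consensus is therefore a subset of each engine's significant set and is
strongly conservative under the null.

## The synthetic community generator

The generator emulates the study designs the pipeline targets: two
experiments (treatment vs control; low vs high fiber), 4 mice per group,
paired bulk+VLP assays, 20 M / 15 M paired-end reads per assay at 150 bp.
Defaults were fixed once, as follows, and the same defaults drive the test
suite:

* 40 bacterial hosts (genome 1.5–5 Mb, phylum labels drawn with the
  Bacillota-dominated composition of murine gut surveys), 60 temperate and
  25 virulent phages (20–80 kb) — temperate species outnumber virulent ones
  as observed in gut viromes. Every host carries ≥ 1 prophage.
* Cell abundances are lognormal: between-taxon spread sd 1.0, inter-mouse
  variation σ = 0.8 on the natural-log scale (large enough that group
  effects are a PERMANOVA question at n = 4/group, not a foregone
  conclusion). Base-scale weights multiply cell abundance by genome length;
  each (sample, assay) vector is normalised to 1.
* A prophage's bulk abundance is host abundance × copy factor (default 1.0
  — one integrated copy, the simplest model of replication alongside the
  host); its VLP abundance is induction_rate × host abundance, with
  induction rates drawn U(0.005, 0.05). No quantitative induction rates are
  available for mouse gut lysogens; these are free parameters, documented,
  and deliberately small enough that prophages are VLP-minor. Virulent
  virion abundances are lognormal around e^(−1.5) relative to host cells.
  These choices make temperate phages hold most bulk viral biomass while
  virulent virions dominate the VLP fraction — the asymmetry the analysis
  must expose — without hard-coding either result.
* The VLP assay carries 0.5% bacterial contamination (VLP preps are never
  perfectly clean; this stresses the presence thresholds).
* Diet scenario: 6 enriched and 4 depleted hosts at |log2FC| = 4, applied
  to the second group; enriched hosts carry extra fiber-degrading CAZymes
  (always including GH43), and their prophages inherit the shift through
  the host-riding abundance model. Effect taxa are centred symmetrically
  about the community mean (enriched start low, depleted start high), so
  the planted fold change is realised on the relative scale the profiling
  observes instead of being eaten by the community-wide mass shift —
  without this, a 16-fold planted effect appears compositionally as ~5-fold.
  The planted-truth set contains every feature with |planted log2FC| ≥ 2.
* Coverage: mean depth λ = rel_abundance × total bases / length, breadth
  from the Lander–Waterman form with binomial thinning on covered positions
  (no per-base or per-read simulation). Everything is bit-for-bit
  reproducible from (config, seed).
* Catalog inputs add 10 decoy contigs (low completeness, or no predictor
  support, or no structural genes) that the validation cascade must reject.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: assembly and binning error, strain-level
microdiversity, read-level sequencing noise, compositional bias of DNA
extraction, phage–host dynamics over time, and prophage boundary trimming
(contigs are consumed as given).

## Problem sizes and numerical choices

The test and acceptance suites run the full pipeline at the community scale
above (125 genomes, 16 libraries), 50-seed sweeps for planted-truth
recovery, 20-seed sweeps for the lifestyle asymmetry, and 10,000-replicate
null simulations (B = 999 permutations, the vegan default) for calibration
— sizes chosen so the whole suite completes in well under a minute of
statistics per check while keeping Monte-Carlo error below the asserted
margins. Sensitivity of the consensus at these study conditions is ~0.81
(pooled over 50 seeds) with empirical FDR ~0.01; the binding engine is the
log-TSS t-test with 6 degrees of freedom, whose power at |log2FC| = 4 and
σ = 0.8 is ~0.83 after BH feedback.

Ties and degenerate inputs are resolved explicitly throughout: half-up
rounding of depths and report percentages, lexicographic tie-breaks in
dereplication, p = 1 for constant features, flagged fallbacks for
zero-variance vectors, all-zero samples and libraries without a usable CSS
quantile. All permutation procedures are seed-deterministic and report
their permutation count.
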