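# dualvirome

Dual-source gut metagenome profiling of bacterial and phage populations.

Standard viral-like-particle (VLP) metagenomes only see the encapsidated,
extracellular fraction of the gut virome, so they systematically miss
**prophages** — the host-integrated state of temperate phages, which in the
murine gut carry most of the temperate viral biomass. Pairing each VLP
library with a whole-microbial ("bulk") metagenome of the same sample
recovers both states: the bulk assay sees bacterial genomes plus integrated
prophages and free virions, while the VLP assay isolates phages in the lytic
stage. `dualvirome` implements the downstream analysis of such paired
designs as a tested, reusable library and command-line pipeline:

* **Viral catalog construction** — quality filtering of candidate viral
  genomes (completeness ≥ 50%, contamination < 10%), greedy dereplication
  into species-level representative genomes (SRGs) at 99% identity over the
  full length of the shorter sequence, validation (phage-predictor support,
  ≥ 1 phage structural protein, no single-structural-gene giants with > 100
  ORFs), and lifestyle classification: *temperate* iff the genome carries a
  lysogeny-cycle gene (integrase, transposase, recombinase, Cro/CI) or shows
  host homology with flanking bacterial regions, else *virulent*.
* **Abundance profiling** — presence calls from breadth of coverage
  (detected iff breadth ≥ 70% or ≥ 5 kb covered for viral SRGs, ≥ 100 kb for
  bacterial SRGs), raw abundance = rounded mean depth, a ≥ 3-sample
  prevalence filter, lifestyle aggregates, and gene-level functional
  profiles (ORF detected iff breadth > 70%, abundances summed per gene ID)
  including short-chain-fatty-acid (SCFA) enzyme groups.
* **Depth saturation** — analytic rarefaction of SRG recovery against
  sequencing depth via Lander–Waterman thinning (breadth `1 − e^(−λ)`),
  plateau detection, and the breadth-threshold × depth grid measuring how
  much of the VLP catalog a bulk metagenome captures.
* **Community statistics** — alpha diversity (observed, Chao1, ACE,
  Shannon, Simpson), Bray–Curtis distances, PCoA, one-way PERMANOVA
  (pseudo-F, permutation p with exhaustive enumeration option), Procrustes
  randomisation between ordinations, gated two-group tests
  (Shapiro–Wilk/Levene → t-test or Wilcoxon–Mann–Whitney), and batch
  correlations with Benjamini–Hochberg FDR.
* **Consensus differential abundance** — three independent engines
  (negative-binomial Wald on median-of-ratios-normalised counts, linear
  model on log total-sum-scaled abundances, moderated t on
  cumulative-sum-scaled counts); a feature is reported only when **all
  three** are BH-significant (q < 0.05) and the NB |log2FC| > 2.
* **Synthetic community generator** — plants a ground-truth community
  (bacterial hosts with lognormal abundances, integrated prophages riding
  their hosts, induced virions, free virulent phages, VLP contamination,
  planted diet effects) so that every stage is testable without downloads.

## Worked example

Run the simulated diet intervention (two groups of 4 mice, paired bulk+VLP
assays, planted |log2FC| = 4 on 10 of 40 bacterial taxa and their
prophages):

```python
import dualvirome as dv

report = dv.run_experiment(dv.RunConfig(scenario="fiber", seed=11,
                                        n_permutations=999))
print(report["catalog"])                     # viral SRG catalog summary
print(report["lifestyle_totals"])            # temperate vs virulent shares
print(report["stats"]["bacterial_bulk"])     # PERMANOVA on Bray-Curtis
print(report["stats"]["procrustes_bulk"])    # viral vs bacterial ordination
print(report["differential_abundance"]["bacterial_bulk"]["confusion_vs_truth"])
```

prints (abridged):

```text
{'total': 85, 'temperate': 60, 'virulent': 25, ...,
 'discards': {'completeness': 4, 'no_predictor': 3, 'no_structural': 3}}
{'viral_bulk': {'temperate': 0.901, 'virulent': 0.099},
 'viral_vlp':  {'temperate': 0.221, 'virulent': 0.779}}
{'permanova_p': 0.029, 'permanova_r2': 0.508, 'permanova_f': 6.187, ...}
{'m2': 0.0063, 'r': 0.9968, 'p': 0.001}
{'tp': 8, 'fp': 0, 'fn': 2, 'sensitivity': 0.8, 'fdr': 0.0}
```

Reading the numbers: all 85 planted phage genomes pass the validation
cascade (the 10 decoy contigs are discarded with named reasons) and the
lifestyle partition is exact. Temperate phages hold ~90% of the viral
fraction in the bulk assay but only ~22% in the VLP assay — the
prophage/virion asymmetry the dual-source design exists to expose. The diet
effect explains ~51% of Bray–Curtis variance (p = .029, the exact floor of a
4-vs-4 permutation design), viral and bacterial ordinations superimpose
almost perfectly (Procrustes r = 0.997), and the three-engine consensus
recovers 8 of 10 planted taxa with no false positives.

The same pipeline is scriptable from the shell:

```bash
dualvirome run --scenario fiber --seed 11 --outdir out/
dualvirome simulate --scenario angii --seed 1 --outdir sim/
dualvirome discover --annotations sim/annotations.tsv --fasta sim/contigs.fasta
dualvirome profile --coverage sim/coverage.tsv --kind viral --assay vlp --out vlp.tsv
```

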