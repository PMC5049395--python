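# poolmap

Bulked-segregant mapping-by-sequencing for EMS suppressor screens, with the
phenotype statistics that go with them.

## The problem

A recessive suppressor found in an EMS (ethyl methanesulfonate) screen is
mapped by crossing the suppressor line back to its parent and pooling
phenotyped F2 individuals. Because EMS overwhelmingly induces G:C→A:T
transitions, induced SNPs read as G→A or C→T against the reference. For a
single recessive causal mutation the F2 segregates ~1 suppressed : 3
non-suppressed. Pooled sequencing of suppressed individuals then localizes
the lesion through the **SNP Proportion**:

    SNP Proportion = alt reads / (ref reads + alt reads)

At unlinked induced SNPs a backcross F2 pool sits near 0.5; approaching the
causal variant the proportion rises towards 1 (exactly 1 for a perfectly
phenotyped, error-free pool; ~0.9–0.95 in practice when one or two pool
members are misscored). The pipeline detects the linked region as a run of
consecutive variants with elevated windowed mean proportion, keeps variants
with proportion > 0.85, and funnels them to candidates: non-synonymous /
stop-gain coding changes and mutations at exon–intron junctions (the GT/AG
dinucleotides). Splice-site candidates can be followed through the
transcript: intron retention or a cryptic splice site removing extra exonic
bases shifts the frame unless the length change is a multiple of 3,
typically producing a premature stop.

Abscission phenotypes are quantified per flower as retained petals + sepals
(0–8) at floral positions 1–15; a genotype's score is the sum over positions
8–15 of per-position means (0–64). Genotypes are compared by pairwise Welch
t-tests with a Bonferroni threshold α / #pairs.

The package is aimed at plant geneticists running desk-scale analyses of
such screens: it simulates the whole experiment with known ground truth
(genome, gene models, EMS spectrum, Poisson-crossover meiosis, pooling with
optional misscoring, pooled read counts), ingests real data as minimal
VCF + GFF3 + FASTA, and implements the mapping statistic, filters, region
detection, candidate annotation and phenotype statistics as a library plus
a thin CLI.

## Worked example

```bash
poolmap full-run --seed 3 --outdir run1
```

simulates the default experiment (5 × 2 Mb genome at 4 cM/Mb, 20 genes,
200 EMS SNPs, F2 of 200, suppressed pool of 30 with 1 misscored member plus
a non-suppressed control pool, mean depth 50×, error rate 0.005) and runs
the funnel. The log records:

```
funnel with candidates: {'input_variants': 200, 'ems_variants': 200,
 'low_depth_excluded': 0, 'scored_variants': 200,
 'thresholded_variants': 38, 'regions': 1, 'thresholded_in_region': 38,
 'candidates': 1}
causal chr5:1295574 C>T recovered in candidates: True
```

200 induced variants pass the EMS spectrum filter; 38 exceed SNP Proportion
0.85, all inside the single detected linked region; annotation against the
gene models reduces them to 1 candidate — the planted causal lesion at a
splice junction (`candidates.tsv`, proportion 0.976, flagged
`origin=causal` by the truth file). The run directory also holds the
reference FASTA, gene GFF3, pooled VCF, per-chromosome proportion plots,
region and proportion TSVs, the phenotype table with its Welch/Bonferroni
test results, and the resolved config for exact reproduction.

The same stages are available separately (`simulate`, `map`, `annotate`,
`phenostats`) and as library functions (`poolmap.simulate_f2`,
`poolmap.snp_proportion`, `poolmap.detect_linked_region`,
`poolmap.candidate_funnel`, `poolmap.pairwise_welch`, ...).

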