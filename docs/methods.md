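# Methods

## Genetic model

The simulator emulates a recessive-suppressor backcross design. A
mutagenized line is homozygous for `n_mutations` induced SNPs, exactly one
of which is causal; the pre-mutagenesis parent carries the reference allele
everywhere. Their F1 is therefore heterozygous at every induced SNP, and an
F2 individual is the fusion of two independent F1 gametes. Phenotype is
purely recessive: suppressed iff homozygous for the alternative allele at
the causal SNP, which yields the expected 1:3 suppressed:non-suppressed
segregation and Hardy–Weinberg 1:2:1 dosage at every induced locus.

Meiosis uses a Poisson crossover process: per chromosome the crossover
count is Poisson with mean equal to the genetic length in Morgans
(`map_density`, default 4 cM/Mb — an Arabidopsis-like genome-wide average),
crossover positions are uniform, and the starting haplotype is a fair coin.
No interference is modeled, so two-locus recombination fractions follow the
Haldane map function r = (1 − e^(−2d))/2, which is also what the linkage
tests assert: among suppressed F2 the pooled alternative-allele frequency
at map distance d from the causal locus is 1 − r(d).

EMS mutagenesis is modeled purely as its read-out: G→A / C→T substitutions
at uniformly chosen distinct G/C reference sites. Accepting both
reference-strand spellings covers G:C→A:T events on either strand, so no
strand inference is attempted anywhere.

## Pooling and sequencing model

A pool holds `pool_size` (default 30) individuals of one phenotype class.
Misscored members — the phenomenon that keeps the observed causal-locus
proportion near 0.9 rather than 1 — are drawn uniformly from the *actual*
opposite phenotype class, so for a suppressed pool they are heterozygous or
wild type at the causal locus in the ~2:1 proportion the F2 provides. With
2 of 30 members misscored the expected causal-locus pool frequency is
(56 + 2·(2/3))/60 ≈ 0.956.

Pooled sequencing reduces each variant to counts: total depth is
Poisson(`mean_depth`, default 50 — a typical pooled-resequencing depth; the
value is exposed in config), and each read reports the alternative base
with probability p(1−e) + (1−p)e where p is the true pooled frequency and
`e` the per-read error rate (default 0.005, symmetric flip). There is no
read-level simulation (no FASTQ, alignment, base qualities or indels);
consequences: mapping bias, local coverage structure and error-rate
heterogeneity of real data are not represented, so passing tests show the
*statistic* behaves as designed, not that a particular aligner/caller
stack would reach the same counts.

## The mapping statistic and funnel

SNP Proportion is the exact ratio alt/(ref+alt). Zero- or low-depth
variants (below `min_depth`, default 1) are excluded and counted, never
scored 0. The funnel applies, in order: the EMS spectrum filter
(order-preserving, idempotent); genome-wide thresholding at proportion
strictly greater than `tau` (default 0.85); intersection with detected
linked regions. Whether the threshold precedes or follows the region
restriction is ambiguous in principle; applying it genome-wide and then
intersecting makes the two counts separately reportable and the nesting
property (`candidates ⊆ in-region ⊆ thresholded ⊆ EMS ⊆ input`) exact.

Region detection is a windowed scan the package defines explicitly, since
"a region of elevated proportion" is otherwise only a visual judgement:
windows of `window_n` (15) consecutive variants per chromosome qualify when
their mean proportion exceeds `t_link` (0.75); with a control (unselected)
pool the window must also exceed the control's mean by more than
`delta_min` (0.2) over the variants shared between pools — a window sharing
no variants with the control cannot qualify (the criterion is evidence of
contrast, not absence of evidence). Overlapping or touching qualifying
windows merge; merged regions with fewer than `min_snps` (10) variants are
dropped; ranking is by mean proportion, then variant count, then leftmost
position. All four constants are config-exposed; the defaults were chosen
so that at 4 cM/Mb an unlinked chromosome (proportions ≈ 0.5) essentially
never qualifies while the causal chromosome's elevated run does. An
exhaustive window-scan oracle in the tests pins the implementation to this
definition on random tables.

## Annotation

Location classes use 1-based closed coordinates and the precedence
splice_junction > cds > utr_or_noncoding_exon > intron > intergenic;
"splice junction" is fixed as the 2 canonical intronic bases at each intron
end (the donor GT / acceptor AG positions) — non-canonical splice-region
positions are deliberately not counted, as no wider definition is
defensible from the design. Coding effects rebuild the affected codon from
spliced CDS coordinates (minus-strand genes use the reverse complement of
both codon and variant base) and translate with the standard code;
start-codon loss counts as non-synonymous, and a variant hitting several
transcripts reports the most severe effect (stop_gained > nonsynonymous >
synonymous). The candidate funnel keeps exactly non-synonymous/stop-gain
CDS variants and splice-junction variants.

Splice consequences are computed on the mature CDS in transcription order:
intron retention inserts the intron sequence; a cryptic splice removes the
intron plus `extra_exonic_bases_removed` bases from the start of the
following exon. Frame is preserved iff the net length change is ≡ 0
(mod 3); `premature_stop` is true when translation of the edited CDS stops
before reaching the reference protein's length. Edits in introns not
spanned by the CDS are rejected as unsupported rather than guessed at.

The toy gene generator writes syntactically valid genes *into* the genome
(ATG start, stop-free sense codons, TAA end, GT..AG introns of 60–200 bp,
20 bp UTR stubs, either strand, non-overlapping placements with 500 bp
margins) and returns the patched genome with the models — the only way a
generated model can be guaranteed consistent with the sequence it
annotates. Generated models must round-trip through the package's own GFF3
writer/reader and translate cleanly; both are asserted at generation time
and in tests.

## Phenotype statistics

Flower score = petals + sepals, each 0–4. A genotype summary is the vector
of per-position means over individuals (positions 1–15) and the score
Σ_{p=8..15} mean_p ∈ [0, 64]. The test unit for group comparisons is the
per-individual summed score (not per-position values), since variability
between plants, not between flowers, is the relevant error term. Tests are
two-sided Welch (unequal-variance) t-tests with Welch–Satterthwaite df;
the Bonferroni threshold is α divided by the number of unordered genotype
pairs (10 pairs for 5 genotypes at α = 0.05 → 0.005). Degenerate inputs
follow a documented convention: both groups constant with equal means →
p = 1; with unequal means → p = 0.

Fluorescence quantification consumes region and background mean intensities
as numbers (image segmentation is out of scope): corrected = region mean −
mean of exactly three background readings (negative values are reported and
flagged, not clipped), normalized = corrected / wild-type corrected. Where
the upstream imaging procedure could be read as either pixel counting or
mean intensity, mean intensity is implemented.

## Synthetic phenotype generator

`simulate_phenotype_table` draws rounded, clamped Gaussians around supplied
per-position means. The default genotype set spans the phenotype range the
screen contrasts: a wild-type-like line (score ~0), a null receptor mutant
(~64), the weak-allele parent (~33), and two suppressor lines (~5), with
per-flower SD 1.0 and 10 individuals per genotype. Clamping at 0/8 makes
extreme-mean positions slightly biased towards the interior; tests account
for this rather than pretending the noise is unbounded Gaussian.

## Randomness, determinism, numerics

All randomness flows through `numpy.random.Generator`. Pipeline stages
derive their seeds from one master seed via `SeedSequence.spawn` (logged,
kept below 2^31), so identical config + seed reproduce byte-identical
outputs, which the CLI tests assert. Proportions are exact floating
ratios of integer counts; no smoothing or continuity correction is applied
anywhere. Ties in region ranking break towards more variants, then the
leftmost interval.

## Problem sizes and limitations

Default simulated experiments use a 5 × 2 Mb genome with 200 induced SNPs,
an F2 of 200, pools of 30 and depth 50; statistical checks use 10 000 F2
for segregation, 4 000 for linkage decay, 200 replicates for the
misscored-pool mean and 20 full experiments for causal recovery — sizes at
which the Monte-Carlo error bands in the tests are meaningful while a full
suite run stays well under a minute-scale budget. Known limitations: one
causal locus only; SNVs only (indels are skipped on ingestion, never
errored); no interference in meiosis; no read-level artifacts; candidate
annotation assumes validated gene models (CDS a positive multiple of 3,
exons non-overlapping) and rejects violations rather than repairing them;
DP4-style VCFs must be converted to AD before ingestion.
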